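"""Figure rendering for pipeline outputs.

Reads the CSV artefacts of a pipeline run and draws the standard panels:
information-criterion curves with 95% bands, per-cluster audiogram
profiles with quartile dashes and a normal-hearing band, cluster
proportions, age and sex summaries, the between-ear symmetry heat map and
the stability bar/line charts.  Missing stage outputs skip their figure
with a logged notice rather than failing.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .synthetic import AC_COLUMNS, FREQUENCIES_KHZ

log = logging.getLogger("audiophen")

#: Upper edge of the normal-hearing band drawn on profile plots (dB HL).
NORMAL_HEARING_DB = 20


def _save(fig, out: Path, name: str, made: list[Path]) -> None:
    path = out / name
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    made.append(path)


def render_report(outdir, normal_band_db: int = NORMAL_HEARING_DB) -> list[Path]:
    """Render all figures available from the artefacts in ``outdir``.

    Returns the list of figure paths written.
    """
    out = Path(outdir)
    made: list[Path] = []

    def have(*names: str) -> bool:
        missing = [n for n in names if not (out / n).exists()]
        if missing:
            log.info("report: skipping figure, missing %s", missing)
            return False
        return True

    freq_pos = np.arange(6)
    freq_labels = [f"{f:g}" for f in FREQUENCIES_KHZ]

    if have("selection_summary.csv"):
        s = pd.read_csv(out / "selection_summary.csv")
        fig, ax = plt.subplots(figsize=(6, 4))
        for crit, color in (("bic", "tab:blue"), ("aic", "tab:red")):
            ax.plot(s["k"], s[f"mean_{crit}"], color=color, label=crit.upper())
            ax.fill_between(
                s["k"], s[f"{crit}_ci_low"], s[f"{crit}_ci_high"],
                color=color, alpha=0.2,
            )
        ax.set_xlabel("number of clusters K")
        ax.set_ylabel("information criterion")
        ax.legend()
        _save(fig, out, "fig_model_selection.png", made)

    if have("profiles.csv"):
        prof = pd.read_csv(out / "profiles.csv")
        clusters = sorted(prof["cluster"].unique())
        ncol = min(3, len(clusters))
        nrow = int(np.ceil(len(clusters) / ncol))
        fig, axes = plt.subplots(
            nrow, ncol, figsize=(3.2 * ncol, 2.6 * nrow),
            sharex=True, sharey=True, squeeze=False,
        )
        for ax in axes.ravel()[len(clusters):]:
            ax.set_visible(False)
        for ax, c in zip(axes.ravel(), clusters):
            sub = prof[prof["cluster"] == c].set_index("frequency").loc[list(AC_COLUMNS)]
            ax.axhspan(-10, normal_band_db, color="0.85", zorder=0)
            ax.plot(freq_pos, sub["mean"], "b-", lw=2)
            ax.plot(freq_pos, sub["q1"], "b--", lw=1)
            ax.plot(freq_pos, sub["q3"], "b--", lw=1)
            ax.set_ylim(120, -10)  # audiogram convention: loss downwards
            ax.set_xticks(freq_pos, freq_labels)
            ax.set_title(f"cluster {c}", fontsize=9)
        fig.supxlabel("frequency (kHz)")
        fig.supylabel("threshold (dB HL)")
        _save(fig, out, "fig_cluster_profiles.png", made)

    if have("cluster_proportions.csv"):
        prop = pd.read_csv(out / "cluster_proportions.csv")
        prop = prop.sort_values("proportion", ascending=False)
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.bar(prop["cluster"].astype(str), prop["proportion"], color="tab:blue")
        ax.set_xlabel("cluster")
        ax.set_ylabel("proportion of ears")
        _save(fig, out, "fig_cluster_proportions.png", made)

    if have("ears.csv", "assignments.csv"):
        ears = pd.read_csv(out / "ears.csv")
        assign = pd.read_csv(out / "assignments.csv")
        age = pd.to_numeric(ears["age"], errors="coerce")
        clusters = sorted(assign["cluster"].unique())
        groups = [age[assign["cluster"] == c].dropna() for c in clusters]
        if all(len(g) for g in groups):
            fig, ax = plt.subplots(figsize=(6, 3.5))
            ax.violinplot(groups, positions=range(len(clusters)), showmedians=True)
            ax.set_xticks(range(len(clusters)), [str(c) for c in clusters])
            ax.set_xlabel("cluster")
            ax.set_ylabel("age (years)")
            _save(fig, out, "fig_age_by_cluster.png", made)
        sexes = ears["sex"].astype("string")
        male = [(sexes[assign["cluster"] == c] == "M").mean() for c in clusters]
        fig, ax = plt.subplots(figsize=(6, 3))
        ax.bar([str(c) for c in clusters], male, color="tab:orange", label="M")
        ax.bar([str(c) for c in clusters], [1 - m for m in male],
               bottom=male, color="tab:blue", label="F")
        ax.set_ylabel("sex proportion")
        ax.set_xlabel("cluster")
        ax.legend()
        _save(fig, out, "fig_sex_by_cluster.png", made)

    if have("symmetry_conditional.csv"):
        cond = pd.read_csv(out / "symmetry_conditional.csv", index_col=0)
        mat = cond.to_numpy(dtype=float)
        fig, ax = plt.subplots(figsize=(5.5, 5))
        im = ax.imshow(mat, cmap="Blues", vmin=0, vmax=1)
        for i in range(mat.shape[0]):
            for j in range(mat.shape[1]):
                if np.isfinite(mat[i, j]):
                    ax.text(j, i, f"{mat[i, j]:.2f}", ha="center", va="center",
                            fontsize=7,
                            color="white" if mat[i, j] > 0.5 else "black")
        ax.set_xlabel("right-ear cluster")
        ax.set_ylabel("left-ear cluster")
        fig.colorbar(im, ax=ax, label="P(right | left)")
        _save(fig, out, "fig_symmetry.png", made)

    for name, fname in (
        ("stability_bootstrap.csv", "fig_stability_bootstrap.png"),
        ("stability_initialization.csv", "fig_stability_initialization.png"),
    ):
        if have(name):
            st = pd.read_csv(out / name)
            fig, ax = plt.subplots(figsize=(5.5, 3))
            err = np.vstack(
                [st["mean_jaccard"] - st["ci_low"], st["ci_high"] - st["mean_jaccard"]]
            )
            ax.bar(st["cluster"].astype(str), st["mean_jaccard"],
                   yerr=np.nan_to_num(err), capsize=3, color="tab:blue")
            ax.set_ylim(0, 1.05)
            ax.set_xlabel("cluster")
            ax.set_ylabel("mean max Jaccard")
            _save(fig, out, fname, made)

    if have("stability_subsample.csv"):
        st = pd.read_csv(out / "stability_subsample.csv")
        fig, ax = plt.subplots(figsize=(5.5, 3))
        err = np.vstack(
            [st["mean_jaccard"] - st["ci_low"], st["ci_high"] - st["mean_jaccard"]]
        )
        ax.bar((st["fraction"] * 100).astype(int).astype(str), st["mean_jaccard"],
               yerr=np.nan_to_num(err), capsize=3, color="tab:green")
        ax.set_ylim(0, 1.05)
        ax.set_xlabel("subsample size (% of dataset)")
        ax.set_ylabel("mean Jaccard")
        _save(fig, out, "fig_stability_subsample.png", made)

    return made
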