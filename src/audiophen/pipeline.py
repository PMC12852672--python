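"""End-to-end orchestration: simulate → clean → fit → criteria → symmetry
→ stability → report, with a machine-readable run manifest.

The pipeline is driven by a single configuration mapping (usually a YAML
file).  Every stage writes plain CSV/JSON artefacts into the output
directory and the manifest records the configuration snapshot, seeds,
per-stage audit counts, the chosen model and SHA-256 checksums of every
output file, so a run can be replayed and verified byte-for-byte.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .cleaning import clean_pipeline, feature_matrix
from .criteria import absorption_profile, coles_notch, reverse_slope
from .gmm import GmmConfig, fit_gmm, model_selection, summarize_clusters
from .stability import bootstrap_stability, initialization_stability, subsample_curve
from .symmetry import ear_symmetry

log = logging.getLogger("audiophen")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "input": None,  # path to an existing curve CSV; otherwise simulate
    "demo_lookup": None,
    "synthetic": {
        "n_patients": 2000,
        "sd_scale": 1.0,
        "tests_per_patient_mean": 2.0,
        "corruption": {
            "empty_rate": 0.02,
            "exact_duplicate_rate": 0.02,
            "same_day_multiple_rate": 0.02,
            "invalid_value_rate": 0.01,
            "chl_rate": 0.05,
            "unilateral_rate": 0.03,
            "under18_rate": 0.02,
            "missing_demo_rate": 0.02,
            "ear_correlation": 0.7,
        },
    },
    "model": {
        "k_min": 2,
        "k_max": 15,
        "n_seeds": 21,
        "k": None,  # manual override of the plateau rule
        "covariance_type": "full",
        "reg_covar": 0.01,
        "tol": 1e-3,
        "max_iter": 500,
    },
    "stability": {
        "run": True,
        "bootstrap_replicates": 50,
        "subsample_replicates": 25,
        "fractions": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9],
    },
    "report": True,
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(source) -> dict:
    """Build a full configuration from a mapping or a YAML file path."""
    if source is None:
        override: dict = {}
    elif isinstance(source, dict):
        override = source
    else:
        with open(source) as fh:
            override = yaml.safe_load(fh) or {}
    cfg = _merge(DEFAULT_CONFIG, override)
    if cfg["model"]["k_max"] < cfg["model"]["k_min"]:
        raise ValueError("model.k_max must be >= model.k_min")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Record of one pipeline run sufficient to replay and verify it."""

    config: dict
    seed: int
    chosen_k: int
    chosen_seed: int
    audit: list
    files: dict[str, str] = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "seed": self.seed,
                    "chosen_k": self.chosen_k,
                    "chosen_seed": self.chosen_seed,
                    "audit": self.audit,
                    "files": self.files,
                },
                fh,
                indent=1,
                default=str,
            )

    def verify(self, outdir) -> list[str]:
        """Return the names of recorded files whose checksum no longer matches."""
        out = Path(outdir)
        bad = []
        for name, digest in self.files.items():
            p = out / name
            if not p.exists() or _sha256(p) != digest:
                bad.append(name)
        return bad


def run_pipeline(config=None, outdir="audiophen_run") -> RunManifest:
    """Execute the full analysis and write all artefacts under ``outdir``.

    Stages run in fixed order; a failure aborts with the stage named in the
    raised exception.  Returns the :class:`RunManifest` (also written as
    ``manifest.json``).
    """
    cfg = load_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    written: list[Path] = []

    def save(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False)
        written.append(path)

    # --- input -----------------------------------------------------------
    if cfg["input"]:
        log.info("stage simulate: skipped (reading %s)", cfg["input"])
        curves = synthetic.read_curve_table(cfg["input"])
    else:
        syn = cfg["synthetic"]
        log.info("stage simulate: n_patients=%s", syn["n_patients"])
        specs = synthetic.default_subtypes(sd_scale=syn.get("sd_scale", 1.0))
        corruption = synthetic.CorruptionSpec(**syn["corruption"])
        curves, truth = synthetic.generate_curve_table(
            specs,
            corruption,
            n_patients=int(syn["n_patients"]),
            seed=seed,
            tests_per_patient_mean=float(syn.get("tests_per_patient_mean", 2.0)),
        )
        save(curves, "curves.csv")
        save(truth.rows, "truth_rows.csv")
        save(truth.patients, "truth_patients.csv")
        save(truth.ears, "truth_ears.csv")

    demo = None
    if cfg["demo_lookup"]:
        demo = pd.read_csv(cfg["demo_lookup"], dtype={"patient_id": str})

    # --- clean -----------------------------------------------------------
    ears, audit = clean_pipeline(curves, demo_lookup=demo, seed=seed)
    log.info("stage clean: %d ear observations", len(ears))
    save(ears, "ears.csv")
    save(audit.to_frame(), "audit.csv")
    X = feature_matrix(ears)

    # --- model selection and fit ----------------------------------------
    m = cfg["model"]
    base = GmmConfig(
        covariance_type=m["covariance_type"],
        reg_covar=float(m["reg_covar"]),
        tol=float(m["tol"]),
        max_iter=int(m["max_iter"]),
    )
    selection = model_selection(
        X,
        k_range=range(int(m["k_min"]), int(m["k_max"]) + 1),
        seeds=range(int(m["n_seeds"])),
        base_config=base,
    )
    chosen_k = int(m["k"]) if m["k"] else selection.chosen_k
    chosen_seed = selection.chosen_seed
    log.info("stage select: chosen_k=%d chosen_seed=%d", chosen_k, chosen_seed)
    save(selection.grid, "selection_grid.csv")
    save(selection.summary, "selection_summary.csv")

    config_final = base.replace(n_components=chosen_k, seed=chosen_seed)
    fit = fit_gmm(X, config_final)
    solution = summarize_clusters(fit, X, demographics=ears[["age", "sex"]])
    assignments = ears[["patient_id", "ear"]].copy()
    assignments["cluster"] = fit.labels
    assignments["max_responsibility"] = fit.model.predict_proba(X).max(axis=1)
    save(assignments, "assignments.csv")
    save(solution.profiles, "profiles.csv")
    save(solution.demographics, "cluster_demographics.csv")
    save(
        solution.proportions.rename_axis("cluster").reset_index(),
        "cluster_proportions.csv",
    )
    solution.to_json(out / "model.json")
    written.append(out / "model.json")

    # --- clinical criteria ----------------------------------------------
    notch = absorption_profile("coles_notch", coles_notch(ears), fit.labels, X)
    rslope = absorption_profile("reverse_slope", reverse_slope(ears), fit.labels, X)
    flags = ears[["patient_id", "ear"]].copy()
    flags["coles_notch"] = notch.flags
    flags["reverse_slope"] = rslope.flags
    save(flags, "criteria_flags.csv")
    save(notch.by_cluster, "coles_notch_absorption.csv")
    save(notch.profile, "coles_notch_profile.csv")
    save(rslope.by_cluster, "reverse_slope_absorption.csv")
    save(rslope.profile, "reverse_slope_profile.csv")
    log.info(
        "stage criteria: %d notch ears, %d reverse-slope ears",
        notch.n_flagged, rslope.n_flagged,
    )

    # --- symmetry --------------------------------------------------------
    sym = ear_symmetry(assignments, n_clusters=chosen_k)
    save(sym.counts.reset_index(), "symmetry_counts.csv")
    save(sym.conditional.reset_index(), "symmetry_conditional.csv")

    # --- stability -------------------------------------------------------
    st = cfg["stability"]
    if st.get("run", True):
        boot = bootstrap_stability(
            X, config_final, fit.labels,
            n_bootstrap=int(st["bootstrap_replicates"]), seed=seed,
        )
        save(boot.per_cluster, "stability_bootstrap.csv")
        init = initialization_stability(
            X, config_final, fit.labels, seed_pool=range(int(m["n_seeds"]))
        )
        save(init.per_cluster, "stability_initialization.csv")
        sub = subsample_curve(
            X, config_final, fit.labels,
            fractions=st["fractions"],
            n_replicates=int(st["subsample_replicates"]), seed=seed,
        )
        save(sub.per_fraction, "stability_subsample.csv")

    # --- report ----------------------------------------------------------
    if cfg.get("report", True):
        from .report import render_report

        for fig in render_report(out):
            written.append(fig)

    manifest = RunManifest(
        config=cfg,
        seed=seed,
        chosen_k=chosen_k,
        chosen_seed=chosen_seed,
        audit=[list(s) for s in audit.stages],
        files={p.name: _sha256(p) for p in written},
    )
    manifest.write(out / "manifest.json")
    return manifest
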