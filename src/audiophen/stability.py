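"""Cluster-replicability suite: cluster-wise Jaccard stability.

Without ground truth, cluster quality is judged by replicability: does the
same structure re-emerge when the data or the fit is perturbed?  Following
the clusterboot procedure of Hennig, each original cluster is compared with
its most similar counterpart in a perturbed solution via the Jaccard
coefficient |A∩B| / |A∪B| over member index sets, and the maximum score is
averaged over perturbations.  Three regimes are provided:

* :func:`bootstrap_stability` — refit on resamples drawn with replacement;
  comparison restricted to indices present in both original and resample.
* :func:`initialization_stability` — refit on the full data from alternate
  random seeds (the original model's seed excluded from the pool).
* :func:`subsample_curve` — refit on subsets of 10–90% of the data, drawn
  without replacement, tracing stability against sample size.

Matching is one-directional (each original cluster takes its best
comparison cluster, with reuse allowed), as in clusterboot; an optimal
one-to-one assignment mode is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .gmm import GmmConfig, fit_gmm, _mean_ci


def jaccard(a, b) -> float:
    """Jaccard similarity |a∩b| / |a∪b| between two index sets.

    Duplicated indices count once.  1 means identical sets, 0 no overlap;
    two empty sets are defined to score 0 (a degenerate case flagged here
    rather than encountered in practice).
    """
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


@dataclass
class JaccardMatch:
    """Best-match scores of each original cluster against a comparison.

    ``scores`` has one row per original cluster: the best-matching
    comparison cluster index and the maximum Jaccard score; clusters with
    no member in the shared index set carry NaN and are excluded from
    means.
    """

    scores: pd.DataFrame

    def values(self) -> np.ndarray:
        return self.scores["jaccard"].to_numpy(dtype=float)

    def mean(self) -> float:
        return float(np.nanmean(self.values()))


def _jaccard_matrix(
    original: np.ndarray, comparison: np.ndarray, k_orig: int, k_comp: int
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Jaccard between original and comparison clusters.

    Both label arrays are aligned to the same (shared) observations, so the
    intersection/union counts reduce to a contingency table.
    """
    C = np.zeros((k_orig, k_comp), dtype=float)
    np.add.at(C, (original, comparison), 1.0)
    a = C.sum(axis=1, keepdims=True)
    b = C.sum(axis=0, keepdims=True)
    union = a + b - C
    with np.errstate(invalid="ignore", divide="ignore"):
        J = np.where(union > 0, C / union, 0.0)
    return J, a.ravel()


def clusterwise_match(
    original_labels: np.ndarray,
    comparison_labels: np.ndarray,
    indices: np.ndarray | None = None,
    n_original_clusters: int | None = None,
    one_to_one: bool = False,
) -> JaccardMatch:
    """Match each original cluster to its most similar comparison cluster.

    Parameters
    ----------
    original_labels : labels over the full index universe.
    comparison_labels : labels for the shared observations — aligned with
        ``indices`` when given, otherwise with the full universe.
    indices : distinct shared indices (e.g. the unique indices of a
        bootstrap resample); membership sets are intersected with it.
    n_original_clusters : number of original clusters (defaults to
        max label + 1), so empty clusters keep a row.
    one_to_one : if True, solve the optimal one-to-one assignment instead
        of the clusterboot best-match-with-reuse.

    Ties break toward the lower comparison cluster index.
    """
    original_labels = np.asarray(original_labels)
    comparison_labels = np.asarray(comparison_labels)
    if indices is None:
        indices = np.arange(len(original_labels))
    indices = np.asarray(indices)
    if len(np.unique(indices)) != len(indices):
        raise ValueError("shared indices must be distinct")
    if len(comparison_labels) != len(indices):
        raise ValueError("comparison_labels must align with the shared indices")

    orig_shared = original_labels[indices]
    k_orig = n_original_clusters or int(original_labels.max()) + 1
    k_comp = int(comparison_labels.max()) + 1 if len(comparison_labels) else 1
    J, row_sizes = _jaccard_matrix(orig_shared, comparison_labels, k_orig, k_comp)

    best_idx = np.full(k_orig, -1, dtype=int)
    best = np.full(k_orig, np.nan)
    if one_to_one:
        rows, cols = linear_sum_assignment(-J)
        for r, c in zip(rows, cols):
            best_idx[r], best[r] = c, J[r, c]
    else:
        best_idx[:] = np.argmax(J, axis=1)  # argmax takes the lowest index on ties
        best[:] = J[np.arange(k_orig), best_idx]
    empty = row_sizes == 0
    best[empty] = np.nan
    best_idx[empty] = -1

    return JaccardMatch(
        pd.DataFrame(
            {"cluster": np.arange(k_orig), "best_match": best_idx, "jaccard": best}
        )
    )


@dataclass
class StabilityReport:
    """Summary of one replicability regime.

    ``per_cluster`` gives mean max-Jaccard and 95% CI per original cluster
    over replicates; ``replicate_scores`` the raw per-replicate scores; for
    the subsample regime ``per_fraction`` summarises the replicate-mean
    score per subsample fraction.
    """

    regime: str
    per_cluster: pd.DataFrame
    replicate_scores: pd.DataFrame
    n_replicates: int
    n_failed: int = 0
    seeds: list[int] = field(default_factory=list)
    per_fraction: pd.DataFrame | None = None

    def overall_mean(self) -> float:
        return float(np.nanmean(self.replicate_scores["jaccard"].to_numpy()))


def _summarise_per_cluster(rows: list[dict]) -> pd.DataFrame:
    raw = pd.DataFrame(rows)
    out = []
    for c, grp in raw.groupby("cluster", sort=True):
        vals = grp["jaccard"].dropna().to_numpy()
        if len(vals):
            m, lo, hi = _mean_ci(vals)
        else:
            m = lo = hi = np.nan
        out.append(
            {"cluster": int(c), "mean_jaccard": m, "ci_low": lo, "ci_high": hi,
             "n_replicates": int(len(vals))}
        )
    return pd.DataFrame(out)


def bootstrap_stability(
    X: np.ndarray,
    config: GmmConfig,
    original_labels: np.ndarray,
    n_bootstrap: int = 50,
    seed: int = 0,
    one_to_one: bool = False,
) -> StabilityReport:
    """Cluster stability under bootstrap resampling.

    Each replicate resamples n observations with replacement, refits the
    mixture with the original configuration (including its chosen seed) on
    the resample, and matches clusters over the distinct indices present in
    both the original data and the resample.  Non-convergent replicate fits
    are excluded and counted.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    k = int(np.max(original_labels)) + 1
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    n_failed = 0
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        fit = fit_gmm(X[idx], config)
        if not fit.converged:
            n_failed += 1
            continue
        shared = np.unique(idx)
        comp = fit.predict(X[shared])
        match = clusterwise_match(
            original_labels, comp, shared, n_original_clusters=k,
            one_to_one=one_to_one,
        )
        for _, r in match.scores.iterrows():
            rows.append(
                {"replicate": b, "cluster": int(r["cluster"]),
                 "jaccard": r["jaccard"],
                 "shared_fraction": len(shared) / n}
            )
    return StabilityReport(
        regime="bootstrap",
        per_cluster=_summarise_per_cluster(rows),
        replicate_scores=pd.DataFrame(rows),
        n_replicates=n_bootstrap,
        n_failed=n_failed,
        seeds=[seed],
    )


def initialization_stability(
    X: np.ndarray,
    config: GmmConfig,
    original_labels: np.ndarray,
    seed_pool=range(21),
    one_to_one: bool = False,
) -> StabilityReport:
    """Cluster stability across EM initializations.

    The mixture is refitted on the full data once per alternate seed —
    the original model's own seed is excluded from the pool — and each
    refit is matched against the original labels over all observations.
    """
    X = np.asarray(X, dtype=float)
    k = int(np.max(original_labels)) + 1
    alt_seeds = [int(s) for s in seed_pool if int(s) != config.seed]
    rows: list[dict] = []
    n_failed = 0
    for i, s in enumerate(alt_seeds):
        fit = fit_gmm(X, config.replace(seed=s))
        if not fit.converged:
            n_failed += 1
            continue
        match = clusterwise_match(
            original_labels, fit.labels, n_original_clusters=k,
            one_to_one=one_to_one,
        )
        for _, r in match.scores.iterrows():
            rows.append(
                {"replicate": i, "cluster": int(r["cluster"]),
                 "jaccard": r["jaccard"], "seed": s}
            )
    return StabilityReport(
        regime="initialization",
        per_cluster=_summarise_per_cluster(rows),
        replicate_scores=pd.DataFrame(rows),
        n_replicates=len(alt_seeds),
        n_failed=n_failed,
        seeds=alt_seeds,
    )


def subsample_curve(
    X: np.ndarray,
    config: GmmConfig,
    original_labels: np.ndarray,
    fractions=None,
    n_replicates: int = 25,
    seed: int = 0,
    one_to_one: bool = False,
) -> StabilityReport:
    """Cluster stability as a function of sample size.

    For each fraction (default 0.1..0.9 in steps of 0.1) and replicate,
    ⌊fraction·n⌋ observations are drawn without replacement, the mixture is
    refitted on the subset and matched against the full-data labels
    restricted to the subset.  Cluster scores are averaged within a
    replicate first; ``per_fraction`` then summarises over replicates.
    Replicates whose subset is smaller than the component count are
    skipped and counted as failed.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    k = int(np.max(original_labels)) + 1
    if fractions is None:
        fractions = np.round(np.arange(0.1, 0.95, 0.1), 2)
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    n_failed = 0
    for frac in fractions:
        m = int(np.floor(float(frac) * n))
        for r_i in range(n_replicates):
            if m <= config.n_components:
                n_failed += 1
                continue
            idx = np.sort(rng.choice(n, size=m, replace=False))
            fit = fit_gmm(X[idx], config)
            if not fit.converged:
                n_failed += 1
                continue
            match = clusterwise_match(
                original_labels, fit.labels, idx, n_original_clusters=k,
                one_to_one=one_to_one,
            )
            rows.append(
                {"fraction": float(frac), "replicate": r_i,
                 "jaccard": match.mean()}
            )
    raw = pd.DataFrame(rows, columns=["fraction", "replicate", "jaccard"])
    per_fraction = []
    for frac, grp in raw.groupby("fraction", sort=True):
        m_, lo, hi = _mean_ci(grp["jaccard"].to_numpy())
        per_fraction.append(
            {"fraction": float(frac), "mean_jaccard": m_, "ci_low": lo,
             "ci_high": hi, "n_replicates": int(len(grp))}
        )
    return StabilityReport(
        regime="subsample",
        per_cluster=pd.DataFrame(
            columns=["cluster", "mean_jaccard", "ci_low", "ci_high", "n_replicates"]
        ),
        replicate_scores=raw,
        n_replicates=n_replicates,
        n_failed=n_failed,
        seeds=[seed],
        per_fraction=pd.DataFrame(per_fraction),
    )
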