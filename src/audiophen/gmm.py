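"""Gaussian-mixture subtype discovery with BIC/AIC model selection.

Audiometric subtypes are modelled as components of a multivariate Gaussian
mixture over the six-frequency AC threshold vector.  Mixtures are fitted by
expectation-maximisation with k-means initialization (full covariance,
diagonal regularisation 0.01 dB², convergence tolerance 1e-3 on the mean
per-sample log-likelihood).  The number of components is chosen from a
(K, seed) grid — K = 2..15 × 21 seeds, 294 fits — by a plateau rule on the
mean BIC curve, and the reporting seed is the one minimising AIC at the
chosen K.  Fitting is delegated to :class:`sklearn.mixture.GaussianMixture`;
this module owns the grid, the selection rule and the cluster summaries.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from .synthetic import AC_COLUMNS

_COV_TYPES = ("full", "diag", "tied", "spherical")

#: 95% normal-approximation half-width multiplier.
_Z95 = 1.959963984540054


@dataclass(frozen=True)
class GmmConfig:
    """Hyperparameters of one mixture fit.

    Defaults follow standard audiometric-phenotyping practice: full
    covariance, covariance regularisation 0.01, EM tolerance 1e-3,
    k-means initialization.
    """

    n_components: int = 9
    covariance_type: str = "full"
    reg_covar: float = 0.01
    tol: float = 1e-3
    max_iter: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.covariance_type == "diagonal":  # accept the spelled-out name
            object.__setattr__(self, "covariance_type", "diag")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.covariance_type not in _COV_TYPES:
            raise ValueError(f"covariance_type must be one of {_COV_TYPES}")
        if self.reg_covar < 0:
            raise ValueError("reg_covar must be nonnegative")

    def replace(self, **kw) -> "GmmConfig":
        d = asdict(self)
        d.update(kw)
        return GmmConfig(**d)


@dataclass
class FittedGmm:
    """A fitted mixture plus its EM diagnostics.

    ``log_likelihoods`` is the per-iteration mean log-likelihood trajectory
    of the EM run (non-decreasing); ``converged`` records whether the
    tolerance was reached within ``max_iter``.
    """

    config: GmmConfig
    model: GaussianMixture
    labels: np.ndarray
    converged: bool
    n_iter: int
    log_likelihoods: np.ndarray
    bic: float
    aic: float

    @property
    def weights(self) -> np.ndarray:
        return self.model.weights_

    @property
    def means(self) -> np.ndarray:
        return self.model.means_

    @property
    def covariances(self) -> np.ndarray:
        return self.model.covariances_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(X)


def fit_gmm(X: np.ndarray, config: GmmConfig) -> FittedGmm:
    """Fit one Gaussian mixture by EM from a k-means initialization.

    Hard labels are by maximum responsibility.  Non-convergence within
    ``max_iter`` is not an error: the fit is returned with
    ``converged=False`` (very tight tolerances may be unreachable on large
    clinical datasets).
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    if X.shape[0] <= config.n_components:
        raise ValueError("need more observations than mixture components")
    model = GaussianMixture(
        n_components=config.n_components,
        covariance_type=config.covariance_type,
        reg_covar=config.reg_covar,
        tol=config.tol,
        max_iter=config.max_iter,
        n_init=1,
        init_params="kmeans",
        random_state=config.seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        labels = model.fit_predict(X)
    return FittedGmm(
        config=config,
        model=model,
        labels=np.asarray(labels),
        converged=bool(model.converged_),
        n_iter=int(model.n_iter_),
        log_likelihoods=np.asarray(model.lower_bounds_, dtype=float),
        bic=float(model.bic(X)),
        aic=float(model.aic(X)),
    )


def _mean_ci(values: np.ndarray) -> tuple[float, float, float]:
    """Mean and normal-approximation 95% CI (mean ± 1.96·sd/√n)."""
    v = np.asarray(values, dtype=float)
    m = float(v.mean())
    half = _Z95 * float(v.std(ddof=1)) / np.sqrt(len(v)) if len(v) > 1 else 0.0
    return m, m - half, m + half


def select_k_plateau(
    k_values: np.ndarray, mean_bic: np.ndarray, rel_threshold: float = 0.01
) -> int:
    """Plateau rule for the number of components on a mean-BIC curve.

    The chosen K is the last K whose improvement over its predecessor is
    still material: scanning upward, the first step K−1→K whose BIC drop
    falls below ``rel_threshold`` of the total drop from K_min to K_max
    marks the plateau, and K−1 is returned.  If the curve never flattens,
    K_max is returned; if it never drops, K_min.
    """
    k_values = np.asarray(k_values)
    mean_bic = np.asarray(mean_bic, dtype=float)
    order = np.argsort(k_values)
    k_values, mean_bic = k_values[order], mean_bic[order]
    total_drop = mean_bic[0] - mean_bic.min()
    if total_drop <= 0:
        return int(k_values[0])
    for i in range(1, len(k_values)):
        drop = mean_bic[i - 1] - mean_bic[i]
        if drop < rel_threshold * total_drop:
            return int(k_values[i - 1])
    return int(k_values[-1])


@dataclass
class ModelSelectionResult:
    """The (K, seed) grid with its information-criterion summaries.

    ``grid`` has one row per (K, seed) cell with BIC, AIC and a convergence
    flag; ``summary`` one row per K with mean and 95% CI of both criteria
    over converged cells.  ``chosen_seed`` is the argmin-AIC seed at
    ``chosen_k``.
    """

    grid: pd.DataFrame
    summary: pd.DataFrame
    chosen_k: int
    chosen_seed: int
    k_range: tuple[int, ...]
    seeds: tuple[int, ...]


def model_selection(
    X: np.ndarray,
    k_range=range(2, 16),
    seeds=range(21),
    base_config: GmmConfig | None = None,
    rel_threshold: float = 0.01,
) -> ModelSelectionResult:
    """Fit the full (K × seed) grid and choose the number of subtypes.

    With the defaults (K = 2..15, 21 seeds) the grid enumerates 294 fits.
    Mean BIC/AIC and their 95% CIs are computed per K over seeds (converged
    cells only); K is chosen by :func:`select_k_plateau` on mean BIC and the
    reporting seed by lowest AIC at that K.
    """
    X = np.asarray(X, dtype=float)
    base = base_config or GmmConfig()
    k_range = tuple(int(k) for k in k_range)
    seeds = tuple(int(s) for s in seeds)
    records = []
    for k in k_range:
        for s in seeds:
            fit = fit_gmm(X, base.replace(n_components=k, seed=s))
            records.append(
                {"k": k, "seed": s, "bic": fit.bic, "aic": fit.aic,
                 "converged": fit.converged, "n_iter": fit.n_iter}
            )
    grid = pd.DataFrame(records)

    rows = []
    for k in k_range:
        cell = grid[(grid["k"] == k) & grid["converged"]]
        if cell.empty:  # fall back to all cells if none converged at this K
            cell = grid[grid["k"] == k]
        bic_m, bic_lo, bic_hi = _mean_ci(cell["bic"].to_numpy())
        aic_m, aic_lo, aic_hi = _mean_ci(cell["aic"].to_numpy())
        rows.append(
            {"k": k, "mean_bic": bic_m, "bic_ci_low": bic_lo, "bic_ci_high": bic_hi,
             "mean_aic": aic_m, "aic_ci_low": aic_lo, "aic_ci_high": aic_hi,
             "n_converged": int(grid[(grid["k"] == k) & grid["converged"]].shape[0])}
        )
    summary = pd.DataFrame(rows)

    chosen_k = select_k_plateau(
        summary["k"].to_numpy(), summary["mean_bic"].to_numpy(), rel_threshold
    )
    at_k = grid[grid["k"] == chosen_k]
    at_k_conv = at_k[at_k["converged"]]
    pool = at_k_conv if not at_k_conv.empty else at_k
    chosen_seed = int(pool.loc[pool["aic"].idxmin(), "seed"])
    return ModelSelectionResult(grid, summary, chosen_k, chosen_seed, k_range, seeds)


def hyperparameter_grid_search(
    X: np.ndarray,
    n_components: int,
    seeds=range(3),
    covariance_types=_COV_TYPES,
    reg_values=None,
) -> pd.DataFrame:
    """Mean BIC over a (covariance type × regularisation) grid.

    Defaults sweep the four covariance structures against regularisation
    0.001–0.01 in steps of 0.001 (40 configurations).  Returns one row per
    configuration, sorted by mean BIC ascending (best first).
    """
    if reg_values is None:
        reg_values = np.round(np.arange(0.001, 0.0105, 0.001), 4)
    rows = []
    for cov in covariance_types:
        for reg in reg_values:
            bics = [
                fit_gmm(
                    X,
                    GmmConfig(
                        n_components=n_components,
                        covariance_type=cov,
                        reg_covar=float(reg),
                        seed=int(s),
                    ),
                ).bic
                for s in seeds
            ]
            rows.append(
                {"covariance_type": cov, "reg_covar": float(reg),
                 "mean_bic": float(np.mean(bics))}
            )
    return (
        pd.DataFrame(rows)
        .sort_values("mean_bic", kind="stable")
        .reset_index(drop=True)
    )


@dataclass
class ClusterSolution:
    """A fitted mixture with per-cluster profiles and demographics.

    ``profiles`` holds mean/Q1/Q3 thresholds per cluster and frequency;
    ``demographics`` age quartiles and sex proportions per cluster;
    ``display_order`` lists cluster indices by descending proportion, the
    order used in reports (mixture numbering itself is arbitrary).
    """

    config: GmmConfig
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    labels: np.ndarray
    proportions: pd.Series
    profiles: pd.DataFrame
    demographics: pd.DataFrame
    display_order: list[int] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "config": asdict(self.config),
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @staticmethod
    def read_config(path) -> GmmConfig:
        with open(path) as fh:
            payload = json.load(fh)
        return GmmConfig(**payload["config"])


def summarize_clusters(
    fit: FittedGmm, X: np.ndarray, demographics: pd.DataFrame | None = None
) -> ClusterSolution:
    """Characterise each cluster by its audiometric profile and demographics.

    Per cluster: mean, lower quartile and upper quartile threshold at each
    frequency; age quartiles and sex proportions of the assigned ears (when
    ``demographics`` with ``age``/``sex`` columns aligned to ``X`` is
    given).  Clusters left empty by hard assignment are emitted with
    undefined (NaN) profiles and counted in the demographics table.
    """
    X = np.asarray(X, dtype=float)
    k = fit.config.n_components
    labels = fit.labels
    counts = np.bincount(labels, minlength=k)
    proportions = pd.Series(counts / counts.sum(), name="proportion")

    prof_rows = []
    for c in range(k):
        sub = X[labels == c]
        for j, col in enumerate(AC_COLUMNS):
            if len(sub):
                mean = float(sub[:, j].mean())
                q1, q3 = np.percentile(sub[:, j], [25, 75])
            else:
                mean = q1 = q3 = np.nan
            prof_rows.append(
                {"cluster": c, "frequency": col, "mean": mean,
                 "q1": float(q1) if len(sub) else np.nan,
                 "q3": float(q3) if len(sub) else np.nan}
            )
    profiles = pd.DataFrame(prof_rows)

    demo_rows = []
    for c in range(k):
        row: dict = {"cluster": c, "n": int(counts[c])}
        if demographics is not None and counts[c] > 0:
            sub = demographics.iloc[np.flatnonzero(labels == c)]
            age = pd.to_numeric(sub["age"], errors="coerce").dropna()
            if len(age):
                row["age_q1"], row["age_median"], row["age_q3"] = (
                    float(q) for q in np.percentile(age, [25, 50, 75])
                )
            sex = sub["sex"].dropna()
            if len(sex):
                row["male_fraction"] = float((sex == "M").mean())
        demo_rows.append(row)
    demo = pd.DataFrame(demo_rows)

    order = list(np.argsort(-proportions.to_numpy(), kind="stable"))
    return ClusterSolution(
        config=fit.config,
        weights=fit.weights.copy(),
        means=fit.means.copy(),
        covariances=np.asarray(fit.covariances).copy(),
        labels=labels.copy(),
        proportions=proportions,
        profiles=profiles,
        demographics=demo,
        display_order=[int(i) for i in order],
    )
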