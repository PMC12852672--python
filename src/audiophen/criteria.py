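"""Rule-based detection of established clinical audiogram configurations.

Two exemplar sensorineural patterns are detected on the cleaned per-ear
feature set and their absorption into model clusters quantified:

* Coles' noise-notch — a ≥10 dB worsening at 4 kHz relative to both the
  1–2 kHz region and 8 kHz, the audiometric signature of early
  noise-induced hearing loss.
* Reverse-slope loss — mean high-frequency (4, 8 kHz) thresholds at least
  10 dB better than mean low-frequency (0.25, 0.5 kHz) thresholds, the
  pattern typical of Ménière's disease.

Both rules are pure threshold differences, hence exactly invariant to
adding a constant to every frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import AC_COLUMNS


def _ac(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        X = X[list(AC_COLUMNS)].to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != 6:
        raise ValueError("expected 6 AC thresholds per ear")
    return X


def coles_notch(X, mid_comparator: str = "min") -> np.ndarray:
    """Coles' criterion for the 4 kHz noise notch.

    True where the 4 kHz threshold is at least 10 dB worse than the 1–2 kHz
    region AND at least 10 dB worse than 8 kHz.  The 1–2 kHz comparator is
    the better (minimum) of the two thresholds by default — the common
    reading of the criterion — or their mean with ``mid_comparator="mean"``.

    Accepts a single 6-vector, an n×6 array or an ear DataFrame; returns a
    boolean array of flags.
    """
    A = _ac(X)
    t1k, t2k, t4k, t8k = A[:, 2], A[:, 3], A[:, 4], A[:, 5]
    if mid_comparator == "min":
        mid = np.minimum(t1k, t2k)
    elif mid_comparator == "mean":
        mid = (t1k + t2k) / 2.0
    else:
        raise ValueError("mid_comparator must be 'min' or 'mean'")
    return (t4k - mid >= 10) & (t4k - t8k >= 10)


def reverse_slope(X) -> np.ndarray:
    """Reverse-slope (low-frequency) hearing loss.

    True where the mean of the 0.25 and 0.5 kHz thresholds exceeds the mean
    of the 4 and 8 kHz thresholds by 10 dB or more (boundary inclusive).
    """
    A = _ac(X)
    low = (A[:, 0] + A[:, 1]) / 2.0
    high = (A[:, 4] + A[:, 5]) / 2.0
    return low - high >= 10


@dataclass
class CriterionResult:
    """Flags for one clinical criterion and their spread over clusters.

    ``by_cluster`` lists, per cluster holding at least one flagged ear, the
    count and proportion of flagged ears, sorted descending (the order used
    for absorption bar charts).  ``profile`` is the pooled mean/Q1/Q3
    threshold profile of the flagged ears.
    """

    name: str
    flags: np.ndarray
    n_flagged: int
    by_cluster: pd.DataFrame
    profile: pd.DataFrame


def absorption_profile(
    name: str, flags: np.ndarray, labels: np.ndarray, X
) -> CriterionResult:
    """Quantify which clusters absorbed the ears flagged by a criterion."""
    flags = np.asarray(flags, dtype=bool)
    labels = np.asarray(labels)
    if flags.shape[0] != labels.shape[0]:
        raise ValueError("flags and labels must align by observation")
    A = _ac(X)

    flagged_labels = labels[flags]
    n = int(flags.sum())
    if n:
        clusters, counts = np.unique(flagged_labels, return_counts=True)
        by_cluster = (
            pd.DataFrame(
                {"cluster": clusters, "count": counts, "proportion": counts / n}
            )
            .sort_values(["count", "cluster"], ascending=[False, True], kind="stable")
            .reset_index(drop=True)
        )
        sub = A[flags]
        profile = pd.DataFrame(
            {
                "frequency": AC_COLUMNS,
                "mean": sub.mean(axis=0),
                "q1": np.percentile(sub, 25, axis=0),
                "q3": np.percentile(sub, 75, axis=0),
            }
        )
    else:
        by_cluster = pd.DataFrame(columns=["cluster", "count", "proportion"])
        profile = pd.DataFrame(columns=["frequency", "mean", "q1", "q3"])
    return CriterionResult(name, flags, n, by_cluster, profile)
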