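"""Between-ear symmetry of cluster assignment.

Each ear is clustered as an independent observation, but the two ears of a
patient are biologically linked.  This module cross-tabulates the left- and
right-ear cluster assignments of each patient and reports the conditional
probabilities P(right cluster | left cluster) — the heat-map analysis that
justifies (or challenges) treating ears independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class SymmetryTable:
    """Left×right contingency counts and row-conditional probabilities.

    ``conditional[i, j] = P(right = j | left = i)``; rows of left clusters
    with zero count are NaN (undefined) rather than fabricated zeros.
    ``n_excluded`` counts patients missing one of the two ears.
    """

    counts: pd.DataFrame
    conditional: pd.DataFrame
    n_patients: int
    n_excluded: int

    def diagonal_mean(self) -> float:
        """Mean of the defined diagonal conditional probabilities."""
        diag = np.diag(self.conditional.to_numpy())
        diag = diag[~np.isnan(diag)]
        return float(diag.mean()) if diag.size else float("nan")


def ear_symmetry(
    assignments: pd.DataFrame,
    n_clusters: int | None = None,
    given: str = "left",
) -> SymmetryTable:
    """Cross-tabulate per-patient cluster assignment between ears.

    Parameters
    ----------
    assignments : DataFrame with columns ``patient_id``, ``ear`` ('L'/'R')
        and ``cluster``.  Patients lacking either ear are excluded and
        counted.
    n_clusters : total number of clusters (defaults to max label + 1), so
        empty clusters keep their rows/columns.
    given : conditioning direction; ``"left"`` (default) yields
        P(right | left), ``"right"`` the transpose.
    """
    if given not in ("left", "right"):
        raise ValueError("given must be 'left' or 'right'")
    wide = assignments.pivot_table(
        index="patient_id", columns="ear", values="cluster", aggfunc="first"
    )
    for col in ("L", "R"):
        if col not in wide:
            wide[col] = np.nan
    complete = wide.dropna(subset=["L", "R"])
    n_excluded = len(wide) - len(complete)

    left = complete["L"].to_numpy(dtype=int)
    right = complete["R"].to_numpy(dtype=int)
    k = n_clusters or (int(max(left.max(initial=-1), right.max(initial=-1))) + 1)

    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (left, right), 1)
    if given == "right":
        counts = counts.T

    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        cond = np.where(row_sums > 0, counts / row_sums, np.nan)

    idx = pd.RangeIndex(k, name=f"{given}_cluster")
    other = "right" if given == "left" else "left"
    cols = pd.RangeIndex(k, name=f"{other}_cluster")
    return SymmetryTable(
        counts=pd.DataFrame(counts, index=idx, columns=cols),
        conditional=pd.DataFrame(cond, index=idx, columns=cols),
        n_patients=len(complete),
        n_excluded=int(n_excluded),
    )
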