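"""Cleaning of raw audiometric curve exports into a per-ear feature table.

The raw export has one row per (patient, ear, test date, modality) where
modality is air conduction (AC) or bone conduction (BC).  The pipeline:

1. optional demographic lookup (fills missing age/sex from a side table),
2. removal of empty and incomplete-AC curve records,
3. removal of exact same-day duplicates,
4. selection of a single curve per (patient, ear, date, modality),
5. AC–BC join into one audiogram row per hearing test,
6. validity filter (thresholds in [−10, 120] dB, multiples of 5),
7. conductive-hearing-loss (CHL) detection via the air-bone gap and
   restriction to bilateral adult sensorineural (SNHL) tests,
8. random selection of one test date per patient,
9. expansion to one row per ear (each ear an independent observation).

Every stage reports (rows in, rows out, rows removed) in a
:class:`CleaningAudit`; the composite SNHL filter additionally reports
per-reason exclusion counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import AC_COLUMNS, BC_COLUMNS, THRESHOLD_MIN, THRESHOLD_MAX, GRID_STEP

_JOIN_KEYS = ["patient_id", "ear", "test_date"]
_CHL_FREQS = [("t500", "b500"), ("t1000", "b1000"), ("t2000", "b2000")]

AGE_MIN = 18
AGE_MAX = 100


@dataclass
class CleaningAudit:
    """Ordered per-stage row accounting for a cleaning run.

    ``stages`` holds (stage name, rows in, rows out, rows removed) in
    pipeline order; rows_removed = rows_in − rows_out at every stage (it is
    negative for the final ear expansion, which doubles the rows).
    ``detail`` carries sub-reason counts for composite stages.
    """

    stages: list[tuple[str, int, int, int]] = field(default_factory=list)
    detail: dict[str, int] = field(default_factory=dict)

    def record(self, name: str, n_in: int, n_out: int) -> None:
        self.stages.append((name, n_in, n_out, n_in - n_out))

    def removed(self, name: str) -> int:
        for stage, _, _, rem in self.stages:
            if stage == name:
                return rem
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.stages, columns=["stage", "rows_in", "rows_out", "rows_removed"]
        )


def _n_present(df: pd.DataFrame) -> pd.Series:
    return df[list(AC_COLUMNS)].notna().sum(axis=1)


def apply_demographic_lookup(
    curves: pd.DataFrame, lookup: pd.DataFrame | None
) -> pd.DataFrame:
    """Fill missing age/sex from a patient-keyed demographic side table.

    Emulates record linkage to an external demographic source; rows whose
    demographics remain missing afterwards are excluded later, by the
    bilateral-SNHL completeness filter.
    """
    if lookup is None:
        return curves
    out = curves.merge(
        lookup[["patient_id", "age", "sex"]].drop_duplicates("patient_id"),
        on="patient_id",
        how="left",
        suffixes=("", "_lk"),
    )
    out["age"] = out["age"].fillna(out.pop("age_lk"))
    out["sex"] = out["sex"].fillna(out.pop("sex_lk"))
    return out


def remove_empty_curves(curves: pd.DataFrame) -> pd.DataFrame:
    """Drop empty records and incomplete AC curves.

    Rows with no threshold values at all are removed.  AC rows missing any
    of the six frequencies are also removed — the model feature vector is
    complete-case, with no imputation.  Partial BC rows are retained: BC is
    only consulted for the air-bone gap at 0.5/1/2 kHz.
    """
    n = _n_present(curves)
    keep = np.where(curves["modality"] == "AC", n == 6, n >= 1)
    return curves[keep].copy()


def drop_exact_duplicates(curves: pd.DataFrame) -> pd.DataFrame:
    """Remove re-indexed copies of the same curve.

    Within groups identical on (patient, ear, date, modality, thresholds),
    only the row with the smallest record_index survives.
    """
    keys = _JOIN_KEYS + ["modality"] + list(AC_COLUMNS)
    out = curves.sort_values("record_index", kind="stable")
    out = out.drop_duplicates(subset=keys, keep="first")
    return out.sort_values("record_index", kind="stable").reset_index(drop=True)


def select_same_day_curve(curves: pd.DataFrame) -> pd.DataFrame:
    """Keep a single curve per (patient, ear, date, modality).

    When non-duplicate curves exist for the same day, the one with the most
    recorded thresholds is kept; ties break toward the lowest record_index.
    """
    keys = _JOIN_KEYS + ["modality"]
    out = curves.copy()
    out["_n"] = _n_present(out)
    out = out.sort_values(["_n", "record_index"], ascending=[False, True], kind="stable")
    out = out.drop_duplicates(subset=keys, keep="first").drop(columns="_n")
    return out.sort_values("record_index", kind="stable").reset_index(drop=True)


def join_curves(curves: pd.DataFrame) -> pd.DataFrame:
    """Merge the AC and BC curves of one hearing test into a single row.

    AC-only tests yield audiograms without BC; BC-only rows are discarded,
    as no feature vector exists for them.
    """
    ac = curves[curves["modality"] == "AC"].drop(columns="modality")
    bc = curves[curves["modality"] == "BC"]
    bc = bc[_JOIN_KEYS + list(AC_COLUMNS)].rename(
        columns=dict(zip(AC_COLUMNS, BC_COLUMNS))
    )
    joined = ac.merge(bc, on=_JOIN_KEYS, how="left")
    for c in BC_COLUMNS:
        if c not in joined:
            joined[c] = pd.NA
        joined[c] = pd.array(joined[c], dtype="Float64")
    return joined.reset_index(drop=True)


def _valid_values(series: pd.Series) -> pd.Series:
    v = pd.to_numeric(series, errors="coerce")
    ok = v.notna() & (v >= THRESHOLD_MIN) & (v <= THRESHOLD_MAX) & (v % GRID_STEP == 0)
    return ok | series.isna()  # absent values do not invalidate a row


def validate_thresholds(audiograms: pd.DataFrame) -> pd.DataFrame:
    """Drop audiograms with any threshold off the audiometric grid.

    A present AC or BC value outside [−10, 120] dB or not a multiple of
    5 dB invalidates the whole audiogram.
    """
    ok = pd.Series(True, index=audiograms.index)
    for c in list(AC_COLUMNS) + list(BC_COLUMNS):
        ok &= _valid_values(audiograms[c])
    return audiograms[ok].reset_index(drop=True)


def detect_chl(audiograms: pd.DataFrame) -> pd.Series:
    """Flag conductive hearing loss via the air-bone gap.

    CHL iff (AC − BC) ≥ 25 dB at two or more of 0.5, 1 and 2 kHz, counted
    over frequencies where BC is present.  Audiograms without usable BC
    cannot exhibit a gap and return False: they remain SNHL candidates
    (flagged in the audit so the limitation can be quantified).
    """
    n_gaps = pd.Series(0, index=audiograms.index)
    for ac_c, bc_c in _CHL_FREQS:
        gap = audiograms[ac_c].astype("Float64") - audiograms[bc_c]
        n_gaps += (gap >= 25).fillna(False).astype(int)
    return n_gaps >= 2


def filter_bilateral_adult_snhl(
    audiograms: pd.DataFrame, audit: CleaningAudit | None = None
) -> pd.DataFrame:
    """Keep patient-dates with both ears tested, SNHL in both, adult age.

    Output is one row per (patient, date) holding both ears side by side
    (``left_*`` / ``right_*`` threshold columns).  A patient-date is
    excluded — and counted under the first applicable reason — if an ear is
    missing, either ear shows CHL, demographics are incomplete, or age is
    outside [18, 100].
    """
    df = audiograms.copy()
    df["chl"] = detect_chl(df)
    has_bc = df[list(BC_COLUMNS)].notna().any(axis=1)
    if audit is not None:
        audit.detail["ac_only_tests"] = int((~has_bc).sum())

    g = df.groupby(["patient_id", "test_date"], sort=True)
    summary = g.agg(
        n_ears=("ear", "nunique"),
        any_chl=("chl", "any"),
        age=("age", "first"),
        sex=("sex", "first"),
    ).reset_index()

    missing_ear = summary["n_ears"] < 2
    chl = ~missing_ear & summary["any_chl"]
    no_demo = ~missing_ear & ~chl & (summary["age"].isna() | summary["sex"].isna())
    age_num = pd.to_numeric(summary["age"], errors="coerce")
    bad_age = (
        ~missing_ear & ~chl & ~no_demo & ((age_num < AGE_MIN) | (age_num > AGE_MAX))
    )
    keep = ~(missing_ear | chl | no_demo | bad_age)
    if audit is not None:
        audit.detail.update(
            excluded_unilateral=int(missing_ear.sum()),
            excluded_chl=int(chl.sum()),
            excluded_missing_demo=int(no_demo.sum()),
            excluded_underage=int(bad_age.sum()),
        )

    kept = summary[keep][["patient_id", "test_date", "age", "sex"]]
    sides = {}
    for ear, prefix in (("L", "left_"), ("R", "right_")):
        side = df[df["ear"] == ear][
            ["patient_id", "test_date"] + list(AC_COLUMNS) + list(BC_COLUMNS)
        ].rename(columns={c: prefix + c for c in AC_COLUMNS + BC_COLUMNS})
        sides[ear] = side
    wide = kept.merge(sides["L"], on=["patient_id", "test_date"], how="inner")
    wide = wide.merge(sides["R"], on=["patient_id", "test_date"], how="inner")
    return wide.reset_index(drop=True)


def sample_one_per_patient(patient_dates: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Keep one uniformly random test date per patient.

    Random (rather than first) selection represents hearing loss across the
    disease trajectory instead of biasing toward early presentations.
    Deterministic given the seed; patients are processed in sorted order.
    """
    rng = np.random.default_rng(seed)
    df = patient_dates.sort_values(["patient_id", "test_date"], kind="stable")
    picks = []
    for _, group in df.groupby("patient_id", sort=True):
        picks.append(group.index[rng.integers(len(group))])
    return df.loc[picks].sort_values("patient_id", kind="stable").reset_index(drop=True)


def expand_ears(patient_dates: pd.DataFrame) -> pd.DataFrame:
    """Unfold the two ears of each patient-date into separate rows.

    Each ear is treated as an independent observation, so the output has
    exactly twice as many rows; patient linkage is retained for the
    between-ear symmetry analysis.
    """
    parts = []
    for ear, prefix in (("L", "left_"), ("R", "right_")):
        cols = {prefix + c: c for c in AC_COLUMNS + BC_COLUMNS}
        part = patient_dates[
            ["patient_id", "test_date", "age", "sex"] + list(cols)
        ].rename(columns=cols)
        part.insert(1, "ear", ear)
        parts.append(part)
    out = pd.concat(parts, ignore_index=True)
    return out.sort_values(["patient_id", "ear"], kind="stable").reset_index(drop=True)


def clean_pipeline(
    curves: pd.DataFrame,
    demo_lookup: pd.DataFrame | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, CleaningAudit]:
    """Run the full cleaning pipeline on a raw curve table.

    Returns the per-ear feature table (complete AC six-vectors, optional BC,
    age, sex) and the per-stage :class:`CleaningAudit`.  Stage order is
    fixed: deduplication precedes same-day selection, which precedes the
    AC–BC join; validity and SNHL filters run on joined audiograms.
    """
    required = {"patient_id", "ear", "test_date", "modality", "record_index",
                *AC_COLUMNS, "age", "sex"}
    missing = required - set(curves.columns)
    if missing:
        raise ValueError(f"curve table is missing columns: {sorted(missing)}")

    audit = CleaningAudit()
    df = apply_demographic_lookup(curves, demo_lookup)
    audit.record("input", len(curves), len(df))

    out = remove_empty_curves(df)
    audit.record("remove_empty_curves", len(df), len(out))
    df = out

    out = drop_exact_duplicates(df)
    audit.record("drop_exact_duplicates", len(df), len(out))
    df = out

    out = select_same_day_curve(df)
    audit.record("select_same_day_curve", len(df), len(out))
    df = out

    out = join_curves(df)
    audit.record("join_curves", len(df), len(out))
    df = out

    out = validate_thresholds(df)
    audit.record("validate_thresholds", len(df), len(out))
    df = out

    out = filter_bilateral_adult_snhl(df, audit)
    audit.record("bilateral_adult_snhl", len(df), len(out))
    df = out

    out = sample_one_per_patient(df, seed)
    audit.record("one_per_patient", len(df), len(out))
    df = out

    ears = expand_ears(df)
    audit.record("expand_ears", len(df), len(ears))
    return ears, audit


def feature_matrix(ears: pd.DataFrame) -> np.ndarray:
    """Extract the n×6 AC feature matrix (float dB) from an ear table."""
    return ears[list(AC_COLUMNS)].to_numpy(dtype=float)
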