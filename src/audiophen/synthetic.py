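"""Synthetic audiometric cohort generator with planted ground truth.

Real audiogram repositories of clinically useful size are access-restricted,
so every analysis stage in this package is exercised against cohorts drawn
from planted multivariate-Gaussian audiometric subtypes.  Two output forms
are provided:

* :func:`generate_mixture` — a clean n×6 feature matrix of air-conduction
  (AC) thresholds with subtype labels, for model-recovery tests.
* :func:`generate_curve_table` — a messy clinical-system-style "curve"
  export (one row per patient/ear/date/modality) with injectable record
  corruptions: empty records, exact same-day duplicates, same-day
  non-duplicate multiples, invalid threshold values, conductive hearing
  loss (CHL) cases, unilateral tests, under-18 patients and missing
  demographics.  A truth sidecar flags every corruption so the cleaning
  pipeline can be audited exactly.

Thresholds live on the clinical audiometric grid: multiples of 5 dB HL in
[−10, 120], at 0.25/0.5/1/2/4/8 kHz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd

#: Canonical test frequencies in kHz.
FREQUENCIES_KHZ: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0)

#: Air-conduction threshold columns of the curve/ear tables.
AC_COLUMNS: tuple[str, ...] = ("t250", "t500", "t1000", "t2000", "t4000", "t8000")

#: Bone-conduction columns of the joined audiogram/ear tables.
BC_COLUMNS: tuple[str, ...] = ("b250", "b500", "b1000", "b2000", "b4000", "b8000")

THRESHOLD_MIN = -10
THRESHOLD_MAX = 120
GRID_STEP = 5


def snap_to_grid(x: np.ndarray) -> np.ndarray:
    """Round to the nearest 5 dB, then clip to [−10, 120].

    Rounding precedes clipping so boundary values stay on the grid and
    survive the validity filter of the cleaning pipeline.
    """
    snapped = np.round(np.asarray(x, dtype=float) / GRID_STEP) * GRID_STEP
    return np.clip(snapped, THRESHOLD_MIN, THRESHOLD_MAX)


@dataclass(frozen=True)
class SubtypeSpec:
    """One planted audiometric subtype: a 6-D Gaussian plus demographics.

    Parameters
    ----------
    name : str
        Human-readable subtype label.
    weight : float
        Mixture weight in [0, 1]; weights across a spec set sum to 1.
    mean : array-like of shape (6,)
        Mean AC thresholds (dB HL) at 0.25/0.5/1/2/4/8 kHz, within [−10, 120].
    covariance : array-like of shape (6, 6)
        Symmetric positive-semidefinite covariance (dB²).
    age_mean, age_sd : float
        Parameters of the per-subtype age distribution (years); ages are
        drawn from a normal truncated to [18, 100].
    male_fraction : float
        Probability that a patient of this subtype is male.
    """

    name: str
    weight: float
    mean: np.ndarray
    covariance: np.ndarray
    age_mean: float = 60.0
    age_sd: float = 15.0
    male_fraction: float = 0.45

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.covariance, dtype=float)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", cov)
        if mean.shape != (6,):
            raise ValueError(f"subtype {self.name!r}: mean must be a 6-vector")
        if np.any(mean < THRESHOLD_MIN) or np.any(mean > THRESHOLD_MAX):
            raise ValueError(
                f"subtype {self.name!r}: mean thresholds must lie in "
                f"[{THRESHOLD_MIN}, {THRESHOLD_MAX}] dB"
            )
        if cov.shape != (6, 6):
            raise ValueError(f"subtype {self.name!r}: covariance must be 6×6")
        if not np.allclose(cov, cov.T, atol=1e-8):
            raise ValueError(f"subtype {self.name!r}: covariance is not symmetric")
        if np.linalg.eigvalsh(cov).min() < -1e-8:
            raise ValueError(
                f"subtype {self.name!r}: covariance is not positive semidefinite"
            )
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError(f"subtype {self.name!r}: weight must be in [0, 1]")


@dataclass(frozen=True)
class CorruptionSpec:
    """Rates of the record-level corruptions injected into a curve table.

    Each rate is a probability in [0, 1].  ``ear_correlation`` is the
    probability that a patient's two ears share the same planted subtype
    (otherwise the right-ear subtype is redrawn independently), which is
    what makes the between-ear symmetry analysis non-trivial.
    """

    empty_rate: float = 0.0
    exact_duplicate_rate: float = 0.0
    same_day_multiple_rate: float = 0.0
    invalid_value_rate: float = 0.0
    chl_rate: float = 0.0
    unilateral_rate: float = 0.0
    under18_rate: float = 0.0
    missing_demo_rate: float = 0.0
    ear_correlation: float = 0.7

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f.name} must be in [0, 1], got {v}")


@dataclass
class CohortTruth:
    """Ground truth sidecar for a generated curve table.

    Attributes
    ----------
    rows : pandas.DataFrame
        One entry per emitted curve row (keyed by ``record_index``) with
        boolean corruption flags ``injected_empty``, ``injected_duplicate``,
        ``injected_same_day`` and ``has_invalid``.
    patients : pandas.DataFrame
        Per-patient planted attributes: left/right subtype indices, age,
        sex, number of test dates and the patient-level corruption flags
        ``chl``, ``unilateral``, ``under18``, ``missing_demo``.
    ears : pandas.DataFrame
        One entry per emitted (patient, ear) with the planted subtype index.
    seed : int
        Seed the cohort was generated from.
    """

    rows: pd.DataFrame
    patients: pd.DataFrame
    ears: pd.DataFrame
    seed: int


def _validate_specs(specs: list[SubtypeSpec]) -> np.ndarray:
    if not specs:
        raise ValueError("specs must be non-empty")
    weights = np.array([s.weight for s in specs], dtype=float)
    if not np.isclose(weights.sum(), 1.0, atol=1e-6):
        raise ValueError(f"subtype weights must sum to 1, got {weights.sum():.6f}")
    return weights


def generate_mixture(
    specs: list[SubtypeSpec], n: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` audiograms from the planted subtype mixture.

    Returns
    -------
    X : ndarray of shape (n, 6)
        AC thresholds snapped to the audiometric grid.
    labels : ndarray of shape (n,)
        Index into ``specs`` of the generating subtype.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    weights = _validate_specs(specs)
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(specs), size=n, p=weights)
    X = np.empty((n, 6), dtype=float)
    for k, spec in enumerate(specs):
        idx = np.flatnonzero(labels == k)
        if idx.size:
            X[idx] = rng.multivariate_normal(spec.mean, spec.covariance, size=idx.size)
    return snap_to_grid(X), labels


def _ar1_covariance(sd: np.ndarray, rho: float = 0.6) -> np.ndarray:
    """Full covariance with AR(1)-style decay of inter-frequency correlation."""
    sd = np.asarray(sd, dtype=float)
    i = np.arange(6)
    corr = rho ** np.abs(i[:, None] - i[None, :])
    return sd[:, None] * corr * sd[None, :]


def default_subtypes(sd_scale: float = 1.0) -> list[SubtypeSpec]:
    """Nine illustrative audiometric subtypes.

    Qualitative re-creations of the configurations seen in clinical SNHL
    cohorts — normal hearing, two presbycusis-like ski-slopes, two
    flat-low/sloping-high patterns, three down-sloping losses of increasing
    severity, and one severe loss with a 4 kHz notch.  The shapes are
    illustrative defaults, not estimates from any real dataset.

    ``sd_scale`` scales every within-subtype standard deviation; values
    below 1 produce better-separated clusters for recovery experiments.
    """
    base_sd = np.array([9.0, 9.0, 10.0, 10.0, 11.0, 12.0]) * sd_scale

    def cov(scale: float = 1.0) -> np.ndarray:
        return _ar1_covariance(base_sd * scale)

    return [
        SubtypeSpec("normal", 0.14, [5, 5, 5, 10, 10, 15], cov(0.8), 38, 12, 0.42),
        SubtypeSpec("presbycusis_mild", 0.13, [10, 10, 15, 25, 45, 60], cov(), 68, 11, 0.50),
        SubtypeSpec("presbycusis_steep", 0.10, [15, 15, 20, 40, 65, 80], cov(), 74, 10, 0.52),
        SubtypeSpec("flat_slope_moderate", 0.12, [35, 35, 40, 45, 60, 70], cov(), 70, 12, 0.44),
        SubtypeSpec("flat_slope_severe", 0.10, [50, 50, 55, 60, 75, 85], cov(), 76, 10, 0.40),
        SubtypeSpec("downslope_mild", 0.13, [25, 30, 35, 45, 55, 65], cov(), 58, 14, 0.43),
        SubtypeSpec("downslope_moderate", 0.11, [40, 45, 50, 60, 70, 75], cov(), 66, 13, 0.41),
        SubtypeSpec("downslope_severe", 0.09, [60, 65, 70, 80, 90, 95], cov(), 72, 12, 0.38),
        SubtypeSpec("severe_notched", 0.08, [75, 80, 85, 90, 110, 95], cov(0.9), 52, 13, 0.62),
    ]


def _truncnorm_age(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal age truncated to the adult study range [18, 100], by rejection."""
    for _ in range(1000):
        a = rng.normal(mean, sd)
        if 18.0 <= a <= 100.0:
            return float(np.round(a))
    return float(np.clip(np.round(mean), 18, 100))


def generate_curve_table(
    specs: list[SubtypeSpec],
    corruption: CorruptionSpec,
    n_patients: int,
    seed: int,
    tests_per_patient_mean: float = 2.0,
    bc_probability: float = 0.5,
) -> tuple[pd.DataFrame, CohortTruth]:
    """Emit a raw clinical-system-style curve table plus its ground truth.

    Per patient and per ear, at least one test date is generated (the count
    is geometric with the given mean, capped at 6).  The AC thresholds of a
    test and its BC thresholds are SEPARATE rows sharing (patient, ear,
    date), mirroring how audiology systems store curves.  Sensorineural
    (non-CHL) tests carry BC at 0.5/1/2 kHz with an air-bone gap drawn from
    {0, 5, 10} dB; CHL tests are built with a 30 dB air-bone gap at all of
    0.5/1/2 kHz, which satisfies the ≥25 dB at ≥2 frequencies rule.

    Corruptions are injected at the ``corruption`` rates and flagged in the
    returned :class:`CohortTruth`.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    weights = _validate_specs(specs)
    if tests_per_patient_mean < 1.0:
        raise ValueError("tests_per_patient_mean must be >= 1")
    rng = np.random.default_rng(seed)

    rows: list[dict] = []
    truth_rows: list[dict] = []
    truth_patients: list[dict] = []
    truth_ears: list[dict] = []
    record_index = 0
    base_date = np.datetime64("2010-01-01")

    def emit(
        pid: str,
        ear: str,
        date: str,
        modality: str,
        thresholds: dict[str, object],
        age,
        sex,
        flags: dict[str, bool],
    ) -> None:
        nonlocal record_index
        rows.append(
            {
                "patient_id": pid,
                "ear": ear,
                "test_date": date,
                "modality": modality,
                **thresholds,
                "age": age,
                "sex": sex,
                "record_index": record_index,
            }
        )
        truth_rows.append(
            {
                "record_index": record_index,
                "patient_id": pid,
                "ear": ear,
                "test_date": date,
                "modality": modality,
                "injected_empty": flags.get("empty", False),
                "injected_duplicate": flags.get("duplicate", False),
                "injected_same_day": flags.get("same_day", False),
                "has_invalid": flags.get("invalid", False),
            }
        )
        record_index += 1

    for p in range(n_patients):
        pid = f"P{p:06d}"
        subtype_left = int(rng.choice(len(specs), p=weights))
        if rng.random() < corruption.ear_correlation:
            subtype_right = subtype_left
        else:
            subtype_right = int(rng.choice(len(specs), p=weights))
        spec_left = specs[subtype_left]

        under18 = rng.random() < corruption.under18_rate
        missing_demo = rng.random() < corruption.missing_demo_rate
        is_chl = rng.random() < corruption.chl_rate
        unilateral = rng.random() < corruption.unilateral_rate

        if under18:
            age: object = float(rng.integers(5, 18))
        else:
            age = _truncnorm_age(rng, spec_left.age_mean, spec_left.age_sd)
        sex: object = "M" if rng.random() < spec_left.male_fraction else "F"
        if missing_demo:
            age, sex = pd.NA, pd.NA

        p_geom = min(1.0, 1.0 / tests_per_patient_mean)
        n_dates = int(min(rng.geometric(p_geom), 6))
        offsets = rng.choice(3650, size=n_dates, replace=False)
        dates = sorted(str(base_date + np.timedelta64(int(o), "D")) for o in offsets)

        ears = ["L"] if unilateral else ["L", "R"]
        for ear, subtype in (("L", subtype_left), ("R", subtype_right)):
            if ear in ears:
                truth_ears.append({"patient_id": pid, "ear": ear, "subtype": subtype})

        for ear in ears:
            spec_ear = specs[subtype_left if ear == "L" else subtype_right]
            for date in dates:
                ac = snap_to_grid(
                    rng.multivariate_normal(spec_ear.mean, spec_ear.covariance)
                ).astype(int)
                bc: dict[str, object] | None = None
                if is_chl:
                    # Conductive component: raise AC in the speech range and
                    # keep BC 30 dB better, a gap the CHL rule must catch.
                    for j in (1, 2, 3):  # 0.5, 1, 2 kHz
                        ac[j] = min(int(ac[j]) + 30, THRESHOLD_MAX)
                    bc = {c: pd.NA for c in AC_COLUMNS}
                    for j, c in ((1, "t500"), (2, "t1000"), (3, "t2000")):
                        bc[c] = int(ac[j]) - 30
                elif rng.random() < bc_probability:
                    bc = {c: pd.NA for c in AC_COLUMNS}
                    for j, c in ((1, "t500"), (2, "t1000"), (3, "t2000")):
                        gap = int(rng.choice([0, 5, 10]))
                        bc[c] = max(int(ac[j]) - gap, THRESHOLD_MIN)

                ac_vals: dict[str, object] = {
                    c: int(v) for c, v in zip(AC_COLUMNS, ac)
                }
                invalid = rng.random() < corruption.invalid_value_rate
                if invalid:
                    j = int(rng.integers(6))
                    ac_vals[AC_COLUMNS[j]] = int(ac[j]) + 2  # off-grid value

                emit(pid, ear, date, "AC", ac_vals, age, sex, {"invalid": invalid})
                if rng.random() < corruption.exact_duplicate_rate:
                    emit(pid, ear, date, "AC", dict(ac_vals), age, sex,
                         {"duplicate": True, "invalid": invalid})
                if rng.random() < corruption.same_day_multiple_rate:
                    # Re-test shifted by one grid step; the shift direction
                    # flips at the ceiling so the row never equals the
                    # original (which would make it an exact duplicate).
                    retest = {
                        c: int(v) + 5 if int(v) + 5 <= THRESHOLD_MAX else int(v) - 5
                        for c, v in ac_vals.items()
                    }
                    emit(pid, ear, date, "AC", retest, age, sex, {"same_day": True})
                if bc is not None:
                    emit(pid, ear, date, "BC", bc, age, sex, {})
                if rng.random() < corruption.empty_rate:
                    emit(pid, ear, date, "AC", {c: pd.NA for c in AC_COLUMNS},
                         age, sex, {"empty": True})

        truth_patients.append(
            {
                "patient_id": pid,
                "subtype_left": subtype_left,
                "subtype_right": subtype_right,
                "age": age,
                "sex": sex,
                "n_dates": n_dates,
                "chl": is_chl,
                "unilateral": unilateral,
                "under18": under18,
                "missing_demo": missing_demo,
            }
        )

    curves = pd.DataFrame(rows)
    for c in AC_COLUMNS:
        curves[c] = curves[c].astype("Int64")
    curves["age"] = pd.array(curves["age"], dtype="Float64")
    curves["sex"] = curves["sex"].astype("string")
    truth = CohortTruth(
        rows=pd.DataFrame(truth_rows),
        patients=pd.DataFrame(truth_patients),
        ears=pd.DataFrame(truth_ears),
        seed=seed,
    )
    n_clean_expected = (
        (~truth.patients[["chl", "unilateral", "under18", "missing_demo"]].any(axis=1)).sum()
    )
    if n_clean_expected == 0:
        import warnings

        warnings.warn(
            "corruption settings leave no clean patients; the cleaned cohort "
            "will be empty",
            stacklevel=2,
        )
    return curves, truth


def write_cohort(curves: pd.DataFrame, truth: CohortTruth, outdir) -> None:
    """Write the curve table and truth sidecars as CSV files under ``outdir``."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    curves.to_csv(out / "curves.csv", index=False)
    truth.rows.to_csv(out / "truth_rows.csv", index=False)
    truth.patients.to_csv(out / "truth_patients.csv", index=False)
    truth.ears.to_csv(out / "truth_ears.csv", index=False)


def read_curve_table(path) -> pd.DataFrame:
    """Read a curve-table CSV, coercing thresholds to nullable integers.

    Non-numeric threshold text is preserved as missing-with-a-flag by the
    cleaning pipeline's validity filter; here it is coerced to NaN only if
    it cannot be parsed at all.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "sex": "string"})
    for c in AC_COLUMNS:
        df[c] = pd.array(pd.to_numeric(df[c], errors="coerce"), dtype="Float64")
    df["age"] = pd.array(pd.to_numeric(df.get("age"), errors="coerce"), dtype="Float64")
    return df
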