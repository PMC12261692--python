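"""Synthetic longitudinal hemoglobin cohorts.

The clinical dataset this kind of analysis runs on (routine primary-care Hb
panels spanning several years) is rarely shareable, so every downstream stage
of the package is exercised against cohorts simulated here.  The generator
reproduces the statistical structure the analysis assumes: a stable
per-patient setpoint, gender- and age-structured population moments, a smooth
non-linear age/time signal, irregular visit schedules with a right-skewed
per-patient visit count, within-subject biological variation, multiplicative
analytical imprecision, and (optionally) a slow monotone drift toward
abnormal values for a fraction of patients.

Hb values are in mmol/L throughout (the unit used by Dutch laboratories;
1 mmol/L = 1.611 g/dL).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "Cohort",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "MEASUREMENT_COLUMNS",
]

#: required columns of the tidy measurement table, in canonical order
MEASUREMENT_COLUMNS = ["patient_id", "date", "hb_mmol_l", "gender", "birth_year"]

#: study window start; dates are day offsets from here
STUDY_START = pd.Timestamp("2012-01-01")

#: log-sd of the visit-count log-normal; with median 13 this yields a count
#: standard deviation near 16, matching routine-monitoring cohorts
_VISIT_COUNT_LOG_SD = 0.8

_VALID_GENDERS = ("female", "male")


class ConfigurationError(ValueError):
    """A synthetic-cohort configuration field is out of its valid range."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the cohort simulator.

    Defaults emulate a seven-year routine-monitoring primary-care cohort:
    population Hb mean ~8.09 mmol/L with SD ~1.04, age mean 65.8 (SD 18.3,
    floor 17), 59.2% female, analytical CV 1.43%, and a right-skewed visit
    count with median 13 in [3, 100].
    """

    n_patients: int = 500
    female_fraction: float = 0.5923
    age_mean: float = 65.79
    age_sd: float = 18.34
    setpoint_mean_f: float = 7.80
    setpoint_mean_m: float = 8.50
    setpoint_sd: float = 0.95
    within_sd: float = 0.26
    analytical_cv: float = 0.0143
    study_span_days: int = 2556  # seven years
    measurements_min: int = 3
    measurements_max: int = 100
    visit_count_median: float = 13.0
    trend_amplitude: float = 0.15
    drift_fraction: float = 0.0
    drift_rate: float = 0.5  # mmol/L lost per year for drifting patients
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be a positive integer")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ConfigurationError("female_fraction must lie in [0, 1]")
        if not 0.0 <= self.drift_fraction <= 1.0:
            raise ConfigurationError("drift_fraction must lie in [0, 1]")
        for name in ("age_sd", "setpoint_sd", "within_sd", "analytical_cv"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.study_span_days < 1:
            raise ConfigurationError("study_span_days must be positive")
        if self.measurements_min < 3:
            raise ConfigurationError(
                "measurements_min must be >= 3 (fewer give no usable history)"
            )
        if self.measurements_max < self.measurements_min:
            raise ConfigurationError(
                "measurements_max must be >= measurements_min"
            )
        if self.visit_count_median <= 0:
            raise ConfigurationError("visit_count_median must be positive")


@dataclass
class Cohort:
    """A collection of timestamped Hb measurements, optionally with the
    simulator's ground truth attached.

    ``measurements`` is a tidy frame with columns ``patient_id, date,
    hb_mmol_l, gender, birth_year``.  ``generator_truth`` (present iff
    ``provenance == "synthetic"``) carries, per measurement, the noiseless
    trajectory value plus the patient's setpoint and drift label.
    """

    measurements: pd.DataFrame
    provenance: str = "file"
    generator_truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [c for c in MEASUREMENT_COLUMNS if c not in self.measurements.columns]
        if missing:
            raise ValueError(f"measurement table lacks required columns: {missing}")
        if (self.provenance == "synthetic") != (self.generator_truth is not None):
            raise ValueError("generator_truth must be present iff provenance is synthetic")

    @property
    def n_patients(self) -> int:
        return self.measurements["patient_id"].nunique()

    @property
    def n_measurements(self) -> int:
        return len(self.measurements)

    def copy(self) -> "Cohort":
        truth = None if self.generator_truth is None else self.generator_truth.copy()
        return Cohort(self.measurements.copy(), self.provenance, truth)


def _age_effect(age: np.ndarray, amplitude: float) -> np.ndarray:
    # full-period cosine over the adult age range [17, 100]: a smooth,
    # clearly non-linear bump with known closed form for recovery tests
    u = np.clip((age - 17.0) / 83.0, 0.0, 1.0)
    return amplitude * np.cos(2.0 * np.pi * u)


def _time_effect(t_days: np.ndarray, amplitude: float, span_days: int) -> np.ndarray:
    # one sinusoidal cycle over the follow-up window; t_days counts from the
    # patient's own first measurement, matching the model's time covariate
    return amplitude * np.sin(2.0 * np.pi * t_days / span_days)


def true_age_curve(age: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    """Noiseless age effect used by the simulator (mmol/L)."""
    return _age_effect(np.asarray(age, dtype=float), config.trend_amplitude)


def true_time_curve(t_days: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    """Noiseless effect of days since the patient's first measurement
    (mmol/L)."""
    return _time_effect(
        np.asarray(t_days, dtype=float), config.trend_amplitude, config.study_span_days
    )


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Simulate a longitudinal Hb cohort.

    Per patient: gender ~ Bernoulli(female_fraction); age at study start from
    a normal truncated below at 17; setpoint from the gender-specific normal;
    visit count from a rounded log-normal (median ``visit_count_median``)
    clipped to the configured range; visit days uniform over the study span.
    The observed value is

        setpoint + f_age(age) + f_time(t) [+ drift] + eps_bio + eps_analytical

    with ``eps_bio ~ N(0, within_sd)`` and ``eps_analytical ~ N(0,
    analytical_cv * |noiseless|)``.  Values are floored at 0.05 mmol/L; range
    filtering is the preprocessing stage's job.  Deterministic given
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    female = rng.random(n) < config.female_fraction
    # truncated-normal ages via rejection-free inverse CDF
    from scipy import stats

    lo = (17.0 - config.age_mean) / max(config.age_sd, 1e-12)
    age_start = stats.truncnorm.ppf(
        rng.random(n), lo, np.inf, loc=config.age_mean, scale=config.age_sd
    )
    setpoint = np.where(female, config.setpoint_mean_f, config.setpoint_mean_m)
    setpoint = setpoint + rng.normal(0.0, config.setpoint_sd, size=n)
    drifting = rng.random(n) < config.drift_fraction

    counts = np.rint(
        rng.lognormal(math.log(config.visit_count_median), _VISIT_COUNT_LOG_SD, size=n)
    ).astype(int)
    counts = np.clip(counts, config.measurements_min, config.measurements_max)

    frames = []
    truth_frames = []
    for i in range(n):
        m = counts[i]
        days = np.sort(rng.choice(config.study_span_days, size=m, replace=False)) if (
            m <= config.study_span_days
        ) else np.sort(rng.integers(0, config.study_span_days, size=m))
        age_at = age_start[i] + days / 365.25
        since_first = days - days[0]
        noiseless = (
            setpoint[i]
            + _age_effect(age_at, config.trend_amplitude)
            + _time_effect(since_first, config.trend_amplitude, config.study_span_days)
        )
        if drifting[i]:
            noiseless = noiseless - config.drift_rate * since_first / 365.25
        value = (
            noiseless
            + rng.normal(0.0, config.within_sd, size=m)
            + rng.normal(0.0, 1.0, size=m) * config.analytical_cv * np.abs(noiseless)
        )
        value = np.maximum(value, 0.05)
        pid = f"P{i:06d}"
        birth_year = STUDY_START.year - int(round(age_start[i]))
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": pid,
                    "date": STUDY_START + pd.to_timedelta(days, unit="D"),
                    "hb_mmol_l": value,
                    "gender": "female" if female[i] else "male",
                    "birth_year": birth_year,
                }
            )
        )
        truth_frames.append(
            pd.DataFrame(
                {
                    "patient_id": pid,
                    "date": STUDY_START + pd.to_timedelta(days, unit="D"),
                    "noiseless": noiseless,
                    "setpoint": setpoint[i],
                    "drift": bool(drifting[i]),
                }
            )
        )

    measurements = pd.concat(frames, ignore_index=True)
    truth = pd.concat(truth_frames, ignore_index=True)
    return Cohort(measurements, provenance="synthetic", generator_truth=truth)


# ---------------------------------------------------------------------------
# CSV round-trip


class SchemaError(ValueError):
    """A cohort file violates the expected schema."""


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the measurement table to CSV (ISO-8601 dates); the simulator
    truth, when present, goes to a ``<stem>.truth.csv`` sidecar."""
    path = Path(path)
    out = cohort.measurements.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
    if cohort.generator_truth is not None:
        truth = cohort.generator_truth.copy()
        truth["date"] = pd.to_datetime(truth["date"]).dt.strftime("%Y-%m-%d")
        truth.to_csv(path.with_suffix(".truth.csv"), index=False)


def read_cohort(path: str | Path, with_truth: bool = False) -> Cohort:
    """Read a cohort CSV written by :func:`write_cohort` (or hand-authored in
    the same layout).  Duplicate (patient, date) rows are accepted here and
    resolved by the preprocessing stage."""
    path = Path(path)
    try:
        table = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise SchemaError(f"malformed cohort file {path}: {exc}") from exc
    missing = [c for c in MEASUREMENT_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    table = table[MEASUREMENT_COLUMNS].copy()
    try:
        table["date"] = pd.to_datetime(table["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"{path}: unparseable date: {exc}") from exc
    values = pd.to_numeric(table["hb_mmol_l"], errors="coerce")
    if values.isna().any():
        row = int(np.flatnonzero(values.isna())[0]) + 2  # 1-based + header line
        raise SchemaError(f"{path}: non-numeric hb_mmol_l at line {row}")
    if (values <= 0).any():
        row = int(np.flatnonzero(values <= 0)[0]) + 2
        raise SchemaError(f"{path}: non-positive hb_mmol_l at line {row}")
    table["hb_mmol_l"] = values.astype(float)
    bad = ~table["gender"].isin(_VALID_GENDERS)
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 2
        raise SchemaError(f"{path}: gender must be one of {_VALID_GENDERS} (line {row})")

    truth = None
    provenance = "file"
    truth_path = path.with_suffix(".truth.csv")
    if with_truth:
        if not truth_path.exists():
            raise SchemaError(f"requested truth sidecar missing: {truth_path}")
        truth = pd.read_csv(truth_path)
        truth["date"] = pd.to_datetime(truth["date"], format="ISO8601")
        provenance = "synthetic"
    return Cohort(table, provenance=provenance, generator_truth=truth)
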