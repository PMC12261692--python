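"""Record-level cleaning, inclusion filters, feature construction, and the
hold-out-last train/test split.

The cleaning pipeline mirrors routine practice for longitudinal laboratory
records: same-day duplicates are collapsed, then whole patients are excluded
when (a) they are below the minimum age at their first measurement, (b) any
of their Hb values falls outside the plausible range, or (c) their
measurement count is outside the configured band.  Each stage emits an
attrition record so the cohort narrative is auditable.

Feature construction turns the cleaned cohort into model rows carrying, for
every measurement with at least one earlier observation: days since the
patient's first measurement, the mean of all *strictly earlier* Hb values
(the no-lookahead "past mean"), age at measurement, and gender.  The
hold-out-last split reserves each patient's most recent row as the test
point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .syncohort import Cohort

__all__ = [
    "FilterRules",
    "AttritionRecord",
    "SplitDataset",
    "deduplicate_same_day",
    "apply_inclusion_filters",
    "build_model_rows",
    "holdout_split",
    "MODEL_ROW_COLUMNS",
]

logger = logging.getLogger(__name__)

MODEL_ROW_COLUMNS = [
    "patient_id",
    "date",
    "y",
    "time_since_first_days",
    "past_mean",
    "age",
    "gender",
]


@dataclass(frozen=True)
class FilterRules:
    """Whole-patient inclusion rules.

    ``hb_min``/``hb_max`` apply to both genders unless the gender-specific
    bounds are given, in which case those take precedence for that gender
    (used for the refined gender-stratified subsets, e.g. 6–12 mmol/L for
    females and 7–13 mmol/L for males).
    """

    min_age: float = 16.0
    hb_min: float = 6.0
    hb_max: float = 16.5
    min_measurements: int = 3
    max_measurements: int = 100
    hb_min_f: float | None = None
    hb_max_f: float | None = None
    hb_min_m: float | None = None
    hb_max_m: float | None = None

    def validate(self) -> None:
        if not self.hb_min < self.hb_max:
            raise ValueError("hb_min must be < hb_max")
        if self.min_measurements < 1:
            raise ValueError("min_measurements must be >= 1")
        if self.max_measurements < self.min_measurements:
            raise ValueError("max_measurements must be >= min_measurements")
        for lo, hi, g in (
            (self.hb_min_f, self.hb_max_f, "female"),
            (self.hb_min_m, self.hb_max_m, "male"),
        ):
            if lo is not None and hi is not None and not lo < hi:
                raise ValueError(f"{g} hb bounds must satisfy lo < hi")

    def bounds_for(self, gender: str) -> tuple[float, float]:
        if gender == "female":
            return (
                self.hb_min if self.hb_min_f is None else self.hb_min_f,
                self.hb_max if self.hb_max_f is None else self.hb_max_f,
            )
        return (
            self.hb_min if self.hb_min_m is None else self.hb_min_m,
            self.hb_max if self.hb_max_m is None else self.hb_max_m,
        )


@dataclass(frozen=True)
class AttritionRecord:
    stage: str
    n_patients_before: int
    n_patients_after: int
    n_measurements_before: int
    n_measurements_after: int

    def __post_init__(self) -> None:
        if self.n_patients_after > self.n_patients_before:
            raise ValueError("patient count may not increase across a stage")
        if self.n_measurements_after > self.n_measurements_before:
            raise ValueError("measurement count may not increase across a stage")


def attrition_frame(log: list[AttritionRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in log])


def _sorted(measurements: pd.DataFrame) -> pd.DataFrame:
    return measurements.sort_values(
        ["patient_id", "date"], kind="stable"
    ).reset_index(drop=True)


def deduplicate_same_day(cohort: Cohort) -> tuple[Cohort, AttritionRecord]:
    """Keep at most one measurement per (patient, day).

    Tie-break: the first record in file order survives — deterministic and
    stable under re-runs.
    """
    m = cohort.measurements
    keep = ~m.duplicated(subset=["patient_id", "date"], keep="first")
    out = m.loc[keep].reset_index(drop=True)
    rec = AttritionRecord(
        "deduplicate_same_day",
        m["patient_id"].nunique(),
        out["patient_id"].nunique(),
        len(m),
        len(out),
    )
    logger.info(
        "dedup: %d -> %d measurements", rec.n_measurements_before, rec.n_measurements_after
    )
    truth = cohort.generator_truth
    if truth is not None:
        truth = truth.loc[
            ~truth.duplicated(subset=["patient_id", "date"], keep="first")
        ].reset_index(drop=True)
    return Cohort(_sorted(out), cohort.provenance, truth), rec


def apply_inclusion_filters(
    cohort: Cohort, rules: FilterRules
) -> tuple[Cohort, list[AttritionRecord]]:
    """Exclude whole patients by age at first measurement, out-of-range Hb
    values (any single offending value removes the patient), and measurement
    count.  Returns the filtered cohort and an ordered attrition log."""
    rules.validate()
    m = _sorted(cohort.measurements)
    log: list[AttritionRecord] = []

    def record(stage: str, before: pd.DataFrame, after: pd.DataFrame) -> None:
        log.append(
            AttritionRecord(
                stage,
                before["patient_id"].nunique(),
                after["patient_id"].nunique(),
                len(before),
                len(after),
            )
        )

    # stage 1: age at first measurement
    first = m.groupby("patient_id", sort=False).first()
    age_first = (
        first["date"].dt.year
        + (first["date"].dt.dayofyear - 1) / 365.25
        - first["birth_year"]
    )
    ok_age = set(first.index[age_first >= rules.min_age])
    m1 = m[m["patient_id"].isin(ok_age)].reset_index(drop=True)
    record("min_age", m, m1)

    # stage 2: any Hb outside the (gender-specific) reference band excludes
    # the whole patient
    lo_f, hi_f = rules.bounds_for("female")
    lo_m, hi_m = rules.bounds_for("male")
    lo = np.where(m1["gender"] == "female", lo_f, lo_m)
    hi = np.where(m1["gender"] == "female", hi_f, hi_m)
    out_of_range = (m1["hb_mmol_l"] < lo) | (m1["hb_mmol_l"] > hi)
    bad = set(m1.loc[out_of_range, "patient_id"])
    m2 = m1[~m1["patient_id"].isin(bad)].reset_index(drop=True)
    record("hb_range", m1, m2)

    # stage 3: measurement count band
    counts = m2.groupby("patient_id", sort=False).size()
    ok_n = set(
        counts.index[
            (counts >= rules.min_measurements) & (counts <= rules.max_measurements)
        ]
    )
    m3 = m2[m2["patient_id"].isin(ok_n)].reset_index(drop=True)
    record("measurement_count", m2, m3)

    truth = cohort.generator_truth
    if truth is not None:
        keys = pd.MultiIndex.from_frame(m3[["patient_id", "date"]])
        tk = pd.MultiIndex.from_frame(truth[["patient_id", "date"]])
        truth = truth[tk.isin(keys)].reset_index(drop=True)
    return Cohort(m3, cohort.provenance, truth), log


def build_model_rows(
    cohort: Cohort, past_mean_mode: str = "expanding_strict"
) -> pd.DataFrame:
    """Construct the model-row table from a cleaned cohort.

    Per patient (sorted by date): ``time_since_first_days`` counts from the
    patient's first retained measurement; ``past_mean`` is the arithmetic
    mean of all strictly earlier Hb values, so a row never sees its own value
    or any future one.  The first measurement of each patient has no history
    and is dropped.  ``past_mean_mode="train_constant"`` instead assigns every
    row the patient's mean over all measurements except the last (the
    constant training-mean reading); the no-lookahead default is
    ``expanding_strict``.
    """
    if past_mean_mode not in ("expanding_strict", "train_constant"):
        raise ValueError(f"unknown past_mean_mode: {past_mean_mode!r}")
    m = _sorted(cohort.measurements)
    rows = []
    for pid, g in m.groupby("patient_id", sort=False):
        if len(g) < 2:
            logger.warning("patient %s has < 2 measurements; skipped", pid)
            continue
        values = g["hb_mmol_l"].to_numpy()
        dates = g["date"].to_numpy()
        t_days = (
            (g["date"] - g["date"].iloc[0]).dt.total_seconds() / 86400.0
        ).to_numpy()
        if past_mean_mode == "expanding_strict":
            past = np.cumsum(values)[:-1] / np.arange(1, len(values))
        else:
            past = np.full(len(values) - 1, values[:-1].mean())
        age = (
            g["date"].dt.year
            + (g["date"].dt.dayofyear - 1) / 365.25
            - g["birth_year"]
        ).to_numpy()
        rows.append(
            pd.DataFrame(
                {
                    "patient_id": pid,
                    "date": dates[1:],
                    "y": values[1:],
                    "time_since_first_days": t_days[1:],
                    "past_mean": past,
                    "age": age[1:],
                    "gender": g["gender"].iloc[0],
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=MODEL_ROW_COLUMNS)
    return pd.concat(rows, ignore_index=True)


@dataclass
class SplitDataset:
    """Hold-out-last partition of the model rows: per patient the most recent
    row is the single test point; everything earlier is training data.
    Patients contributing no training row are excluded from both sides."""

    train: pd.DataFrame
    test: pd.DataFrame
    excluded_patients: list = field(default_factory=list)


def holdout_split(rows: pd.DataFrame) -> SplitDataset:
    if rows.empty:
        logger.warning("holdout_split called on an empty row table")
        return SplitDataset(rows.copy(), rows.copy())
    rows = rows.sort_values(["patient_id", "date"], kind="stable")
    is_last = ~rows.duplicated(subset=["patient_id"], keep="last")
    n_rows = rows.groupby("patient_id", sort=False)["y"].transform("size")
    eligible = n_rows >= 2  # need at least one train row besides the test row
    excluded = sorted(rows.loc[~eligible, "patient_id"].unique())
    if excluded:
        logger.info("holdout_split: %d patient(s) with a single row excluded", len(excluded))
    train = rows[eligible & ~is_last].reset_index(drop=True)
    test = rows[eligible & is_last].reset_index(drop=True)
    return SplitDataset(train, test, excluded)
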