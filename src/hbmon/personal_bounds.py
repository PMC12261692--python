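"""Individualized "normal" ranges.

Instead of population reference limits, each patient gets an interval built
from their own history: mean ± k·SD of all prior Hb values (sample SD,
n−1 denominator).  The default multiplier k = 2.5 is deliberately stricter
than the population mean ± 2 SD convention; a sweep grid down to 1.5 probes
sensitivity to that choice.  Classification against the range is
boundary-inclusive: a value exactly on a bound counts as normal
(conservative toward not flagging).

A zero-variance history yields a zero-width range rather than an error.  An
optional analytical floor widens the half-width to at least CVa·mean, for
use when assay imprecision should not produce spuriously tight ranges; it is
off by default so the mean ± k·SD formula is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PersonalRange", "compute_personal_range", "classify_value", "ranges_table"]

NORMAL = "normal"
OUT_OF_NORMAL = "out_of_normal"


@dataclass(frozen=True)
class PersonalRange:
    patient_id: str
    mean: float
    sd: float
    k: float
    low: float
    high: float
    n_history: int


def compute_personal_range(
    history,
    k: float = 2.5,
    patient_id: str = "",
    analytical_floor_cv: float | None = None,
) -> PersonalRange:
    """Range mean ± k·SD from a patient's historical values (which must
    already exclude the held-out measurement — the caller guarantees that).

    Raises ``ValueError`` for k ≤ 0 or fewer than 2 history values (the
    sample SD is undefined).
    """
    values = np.asarray(list(history), dtype=float)
    if k <= 0:
        raise ValueError("SD multiplier k must be positive")
    if values.size < 2:
        raise ValueError(
            f"need >= 2 historical values for a personal range (got {values.size})"
        )
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    half = k * sd
    if analytical_floor_cv is not None:
        half = max(half, analytical_floor_cv * abs(mean))
    return PersonalRange(
        patient_id=patient_id,
        mean=mean,
        sd=sd,
        k=float(k),
        low=mean - half,
        high=mean + half,
        n_history=int(values.size),
    )


def classify_value(value: float, prange: PersonalRange) -> str:
    """``"normal"`` iff low ≤ value ≤ high (bounds inclusive)."""
    return NORMAL if prange.low <= value <= prange.high else OUT_OF_NORMAL


def ranges_table(ranges) -> pd.DataFrame:
    """Tabulate PersonalRange records for CSV export."""
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "n_history": r.n_history,
                "mean": r.mean,
                "sd": r.sd,
                "k": r.k,
                "low": r.low,
                "high": r.high,
            }
            for r in ranges
        ]
    )
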