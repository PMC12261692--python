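"""Evaluation of the hold-out-last predictions.

Covers: mean squared prediction error (MSPE) and its root; the fraction of
predictions within an absolute error threshold; empirical coverage of the
prediction intervals; the fraction of actual values within 2 pooled SD of
the pooled mean; the normal / out-of-normal confusion matrix against each
patient's personalized range and its derived metrics; the SD-multiplier
robustness sweep; and the intraclass correlation coefficient (ICC).

Convention (important): the *positive* class is "within personal normal
bounds".  TP therefore counts patients whose actual and predicted values are
both inside their personal range, and the false-positive rate is the
fraction of truly out-of-normal patients the model predicted as normal.  A
complementary specificity/NPV view is included in the report for clinical
readability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .personal_bounds import NORMAL, OUT_OF_NORMAL, classify_value, compute_personal_range

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "EvaluationSummary",
    "mspe",
    "coverage_fractions",
    "confusion_from_classifications",
    "metrics_from_matrix",
    "threshold_sweep",
    "icc",
]

_LABELS = (NORMAL, OUT_OF_NORMAL)


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts; positive class = "within personal normal bounds"."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """Derived classification metrics; a metric whose denominator is zero is
    reported as ``None`` (undefined), never raised."""

    prevalence: float | None
    accuracy: float | None
    precision: float | None
    recall: float | None
    fpr: float | None
    f1: float | None
    specificity: float | None
    npv: float | None
    n: int
    k: float | None = None

    def as_percent_strings(self) -> dict:
        """Two-decimal percent formatting for display."""
        out = {}
        for name in ("prevalence", "accuracy", "precision", "recall", "fpr", "f1"):
            v = getattr(self, name)
            out[name] = "undefined" if v is None else f"{100 * v:.2f}%"
        return out


def mspe(predictions, actuals) -> float:
    """Mean squared prediction error, sum((y_hat - y)^2) / N."""
    yhat = np.asarray(predictions, dtype=float)
    y = np.asarray(actuals, dtype=float)
    if yhat.shape != y.shape:
        raise ValueError(f"length mismatch: {yhat.shape} vs {y.shape}")
    if yhat.size == 0:
        raise ValueError("need at least one prediction")
    return float(np.mean((yhat - y) ** 2))


def coverage_fractions(
    predictions: pd.DataFrame,
    actuals,
    delta: float = 0.5,
    pooled_sd: float | None = None,
    pooled_mean: float | None = None,
) -> tuple[float, float, float]:
    """(fraction |y_hat - y| <= delta, fraction y inside [ci_low, ci_high],
    fraction |y - pooled_mean| <= 2 * pooled_sd).

    ``predictions`` is the frame from ``predict_with_ci``.  When
    ``pooled_mean``/``pooled_sd`` are omitted they are computed from the
    actual values themselves.
    """
    y = np.asarray(actuals, dtype=float)
    if len(predictions) != y.size:
        raise ValueError("predictions and actuals must be paired")
    if delta <= 0:
        raise ValueError("delta must be positive")
    yhat = predictions["y_hat"].to_numpy(float)
    frac_delta = float(np.mean(np.abs(yhat - y) <= delta))
    ci_cov = float(
        np.mean(
            (y >= predictions["ci_low"].to_numpy(float))
            & (y <= predictions["ci_high"].to_numpy(float))
        )
    )
    mu = float(y.mean()) if pooled_mean is None else pooled_mean
    sd = float(y.std(ddof=1)) if pooled_sd is None else pooled_sd
    frac_2sd = float(np.mean(np.abs(y - mu) <= 2.0 * sd))
    return frac_delta, ci_cov, frac_2sd


def confusion_from_classifications(predicted_class, actual_class) -> ConfusionMatrix:
    pred = list(predicted_class)
    act = list(actual_class)
    if len(pred) != len(act):
        raise ValueError("label vectors must be paired")
    for lab in pred + act:
        if lab not in _LABELS:
            raise ValueError(f"unknown class label {lab!r}; expected one of {_LABELS}")
    tp = sum(1 for p, a in zip(pred, act) if a == NORMAL and p == NORMAL)
    fn = sum(1 for p, a in zip(pred, act) if a == NORMAL and p == OUT_OF_NORMAL)
    fp = sum(1 for p, a in zip(pred, act) if a == OUT_OF_NORMAL and p == NORMAL)
    tn = sum(1 for p, a in zip(pred, act) if a == OUT_OF_NORMAL and p == OUT_OF_NORMAL)
    return ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def metrics_from_matrix(m: ConfusionMatrix, k: float | None = None) -> MetricsReport:
    if m.total == 0:
        raise ValueError("empty confusion matrix")
    precision = _ratio(m.tp, m.tp + m.fp)
    recall = _ratio(m.tp, m.tp + m.fn)
    f1 = None
    if precision is not None and recall is not None and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricsReport(
        prevalence=_ratio(m.tp + m.fn, m.total),
        accuracy=_ratio(m.tp + m.tn, m.total),
        precision=precision,
        recall=recall,
        fpr=_ratio(m.fp, m.fp + m.tn),
        f1=f1,
        specificity=_ratio(m.tn, m.tn + m.fp),
        npv=_ratio(m.tn, m.tn + m.fn),
        n=m.total,
        k=k,
    )


def threshold_sweep(
    test_rows: pd.DataFrame,
    histories: dict,
    predictions: pd.DataFrame,
    k_grid,
) -> list[tuple[float, ConfusionMatrix, MetricsReport]]:
    """Re-run the range construction and classification at each SD multiplier.

    ``histories`` maps patient_id -> array of that patient's historical Hb
    values (all measurements before the held-out one); ``test_rows`` carries
    the actual held-out value per patient (column ``y``); ``predictions`` the
    matching ``y_hat``.  Returns one (k, matrix, metrics) triple per k.
    """
    k_grid = list(k_grid)
    if not k_grid:
        raise ValueError("k_grid is empty")
    if any(b <= a for a, b in zip(k_grid, k_grid[1:])):
        raise ValueError("k_grid must be strictly increasing")
    if any(k <= 0 for k in k_grid):
        raise ValueError("all k must be positive")
    merged = test_rows.merge(
        predictions[["patient_id", "y_hat"]], on="patient_id", validate="one_to_one"
    )
    out = []
    for k in k_grid:
        pred_labels, act_labels = [], []
        for _, row in merged.iterrows():
            pr = compute_personal_range(
                histories[row["patient_id"]], k=k, patient_id=row["patient_id"]
            )
            pred_labels.append(classify_value(row["y_hat"], pr))
            act_labels.append(classify_value(row["y"], pr))
        m = confusion_from_classifications(pred_labels, act_labels)
        out.append((k, m, metrics_from_matrix(m, k=k)))
    return out


def sweep_frame(sweep) -> pd.DataFrame:
    """Tabular view of a threshold sweep."""
    rows = []
    for k, m, rep in sweep:
        rows.append(
            {
                "k": k,
                "tp": m.tp,
                "fn": m.fn,
                "fp": m.fp,
                "tn": m.tn,
                "actual_out_of_normal": m.fp + m.tn,
                "prevalence": rep.prevalence,
                "accuracy": rep.accuracy,
                "precision": rep.precision,
                "recall": rep.recall,
                "fpr": rep.fpr,
                "f1": rep.f1,
            }
        )
    return pd.DataFrame(rows)


def icc(values, groups) -> float:
    """One-way random-effects ICC(1): between-patient variance over total.

    Variance components come from the ANOVA mean squares with the
    unbalanced-design group-size correction

        n0 = (N - sum(n_i^2) / N) / (k - 1),
        sigma_b^2 = (MSB - MSW) / n0,   ICC = sigma_b^2 / (sigma_b^2 + MSW),

    truncated at 0 when MSB < MSW.  Requires >= 2 groups with >= 2 values.
    """
    frame = pd.DataFrame({"value": np.asarray(list(values), float), "group": list(groups)})
    sizes = frame.groupby("group").size()
    frame = frame[frame["group"].isin(sizes.index[sizes >= 2])]
    sizes = sizes[sizes >= 2]
    k = len(sizes)
    if k < 2:
        raise ValueError("ICC needs >= 2 patients with >= 2 values each")
    N = len(frame)
    grand = frame["value"].mean()
    means = frame.groupby("group")["value"].mean()
    ssb = float((sizes * (means - grand) ** 2).sum())
    ssw = float(((frame["value"] - means.loc[frame["group"]].to_numpy()) ** 2).sum())
    msb = ssb / (k - 1)
    msw = ssw / (N - k)
    n0 = (N - float((sizes**2).sum()) / N) / (k - 1)
    sigma_b2 = max((msb - msw) / n0, 0.0)
    denom = sigma_b2 + msw
    return float(sigma_b2 / denom) if denom > 0 else 0.0


@dataclass
class EvaluationSummary:
    """Bundle of the headline evaluation quantities for one pipeline run."""

    mspe: float
    rmse: float
    frac_within_delta: float
    delta: float
    ci_coverage: float
    ci_level: float
    frac_within_2sd: float
    confusion: ConfusionMatrix
    metrics: MetricsReport
    sweep: list
    icc_pre: float
    icc_post: float
    deviance_explained: float
    n_test: int

    def report_text(self) -> str:
        """Human-readable run report: counts first, then metric lines."""
        m, rep = self.confusion, self.metrics
        pct = rep.as_percent_strings()
        lines = [
            "Confusion matrix (positive class = within personal normal bounds)",
            f"  TP (actual normal, predicted normal):        {m.tp}",
            f"  FN (actual normal, predicted out):           {m.fn}",
            f"  FP (actual out, predicted normal):           {m.fp}",
            f"  TN (actual out, predicted out):              {m.tn}",
            f"  Total:                                       {m.total}",
            "",
            f"Prevalence of normal Hb: (TP+FN)/Total: {pct['prevalence']}",
            f"Prediction accuracy: (TP+TN)/Total: {pct['accuracy']}",
            f"Precision (PPV): TP/(TP+FP): {pct['precision']}",
            f"Recall (sensitivity): TP/(TP+FN): {pct['recall']}",
            f"False positive rate: FP/(FP+TN): {pct['fpr']}",
            f"F1 score: 2PR/(P+R): {pct['f1']}",
            "",
            f"MSPE: {self.mspe:.4f} mmol^2/L^2 (RMSE {self.rmse:.4f} mmol/L)",
            f"|error| <= {self.delta} mmol/L: {100 * self.frac_within_delta:.2f}%",
            f"{100 * self.ci_level:.0f}% interval coverage: {100 * self.ci_coverage:.2f}%",
            f"within 2 pooled SD: {100 * self.frac_within_2sd:.2f}%",
            f"ICC pre-model: {self.icc_pre:.3f}   ICC of residuals: {self.icc_post:.3f}",
            f"Deviance explained (train): {100 * self.deviance_explained:.1f}%",
        ]
        return "\n".join(lines)
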