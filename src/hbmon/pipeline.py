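"""End-to-end orchestration: generate (or load) a cohort, clean it, fit the
additive model on the hold-out-last training split, build personalized
ranges, and evaluate — all from one config, reproducibly.

A single global seed is fanned out through ``numpy.random.SeedSequence`` to
the stages that draw randomness (cohort generation, subset sampling), so
adding a stage never perturbs the others.  Every artifact (cohort, model-row
table, attrition log, fitted-model archive, smooth-term summary, range
table, metric reports, sweep table) is written to the output directory
together with an echo of the fully resolved config.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluate as ev
from .additive_model import (
    ModelSpec,
    fit_additive_model,
    predict_with_ci,
    save_model,
)
from .personal_bounds import classify_value, compute_personal_range, ranges_table
from .preprocess import (
    FilterRules,
    apply_inclusion_filters,
    attrition_frame,
    build_model_rows,
    deduplicate_same_day,
    holdout_split,
)
from .syncohort import Cohort, SyntheticConfig, generate_cohort, read_cohort, write_cohort

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "run_subset_comparison"]

logger = logging.getLogger(__name__)

DEFAULT_K_GRID = (1.5, 1.75, 2.0, 2.25, 2.5)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    synthetic: SyntheticConfig | str = field(default_factory=SyntheticConfig)
    filters: FilterRules = field(default_factory=FilterRules)
    model: ModelSpec = field(default_factory=ModelSpec)
    k_default: float = 2.5
    k_grid: tuple = DEFAULT_K_GRID
    ci_level: float = 0.95
    delta: float = 0.5
    past_mean_mode: str = "expanding_strict"
    output_dir: str | None = None
    seed: int = 0

    def resolved_synthetic(self) -> SyntheticConfig | None:
        """The generator config with the pipeline seed fanned in, or None
        when the cohort comes from a file."""
        if isinstance(self.synthetic, str):
            return None
        child = np.random.SeedSequence(self.seed).spawn(1)[0]
        gen_seed = int(child.generate_state(1)[0] % (2**31))
        return dataclasses.replace(self.synthetic, seed=gen_seed)

    # -- YAML round-trip ----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "k_default": self.k_default,
            "k_grid": list(self.k_grid),
            "ci_level": self.ci_level,
            "delta": self.delta,
            "past_mean_mode": self.past_mean_mode,
            "output_dir": self.output_dir,
            "filters": dataclasses.asdict(self.filters),
            "model": {
                "smooth_terms": [list(t) for t in self.model.smooth_terms],
                "parametric_terms": list(self.model.parametric_terms),
                "random_intercept": self.model.random_intercept,
                "by_gender_smooths": self.model.by_gender_smooths,
                "smoothing_selection": self.model.smoothing_selection,
                "ci_mode": self.model.ci_mode,
            },
        }
        if isinstance(self.synthetic, str):
            d["input"] = self.synthetic
        else:
            d["synthetic"] = dataclasses.asdict(self.synthetic)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        if "input" in d:
            synthetic: SyntheticConfig | str = str(d["input"])
        else:
            synthetic = SyntheticConfig(**d.get("synthetic", {}))
        model_d = dict(d.get("model", {}))
        if "smooth_terms" in model_d:
            model_d["smooth_terms"] = tuple(
                (str(c), int(k)) for c, k in model_d["smooth_terms"]
            )
        if "parametric_terms" in model_d:
            model_d["parametric_terms"] = tuple(model_d["parametric_terms"])
        return cls(
            synthetic=synthetic,
            filters=FilterRules(**d.get("filters", {})),
            model=ModelSpec(**model_d),
            k_default=float(d.get("k_default", 2.5)),
            k_grid=tuple(d.get("k_grid", DEFAULT_K_GRID)),
            ci_level=float(d.get("ci_level", 0.95)),
            delta=float(d.get("delta", 0.5)),
            past_mean_mode=str(d.get("past_mean_mode", "expanding_strict")),
            output_dir=d.get("output_dir"),
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineResult:
    summary: ev.EvaluationSummary
    model: object
    split: object
    cohort: Cohort
    histories: dict
    predictions: pd.DataFrame
    attrition: pd.DataFrame
    artifacts: dict


def patient_histories(cohort: Cohort) -> dict:
    """Per patient, the Hb values of all measurements except the most recent
    one (the basis for that patient's personalized range)."""
    hist = {}
    m = cohort.measurements.sort_values(["patient_id", "date"], kind="stable")
    for pid, g in m.groupby("patient_id", sort=False):
        hist[pid] = g["hb_mmol_l"].to_numpy(float)[:-1]
    return hist


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages in order; see the module docstring."""
    out_dir = None
    if config.output_dir:
        out_dir = Path(config.output_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}

    def save_csv(frame: pd.DataFrame, name: str) -> None:
        if out_dir is not None:
            p = out_dir / name
            frame.to_csv(p, index=False, float_format="%.10g")
            artifacts[name] = p

    stage = "generate"
    try:
        if isinstance(config.synthetic, str):
            cohort = read_cohort(config.synthetic)
        else:
            cohort = generate_cohort(config.resolved_synthetic())
        logger.info("generate: %d patients, %d measurements", cohort.n_patients, cohort.n_measurements)
        if out_dir is not None:
            write_cohort(cohort, out_dir / "cohort.csv")
            artifacts["cohort.csv"] = out_dir / "cohort.csv"

        stage = "preprocess"
        cohort, dedup_rec = deduplicate_same_day(cohort)
        cohort, attr_log = apply_inclusion_filters(cohort, config.filters)
        attrition = attrition_frame([dedup_rec] + attr_log)
        save_csv(attrition, "attrition.csv")
        rows = build_model_rows(cohort, past_mean_mode=config.past_mean_mode)
        if rows.empty:
            raise StageError("no model rows survive preprocessing")
        split = holdout_split(rows)
        tagged = rows.sort_values(["patient_id", "date"], kind="stable").reset_index(drop=True)
        last = ~tagged.duplicated("patient_id", keep="last")
        tagged["partition"] = np.where(last, "test", "train")
        save_csv(tagged, "model_rows.csv")
        logger.info(
            "preprocess: %d train rows, %d test rows, %d patients excluded at split",
            len(split.train), len(split.test), len(split.excluded_patients),
        )

        stage = "fit"
        model = fit_additive_model(split.train, config.model)
        save_csv(model.smooth_table, "smooth_summary.csv")
        save_csv(model.parametric_table, "parametric_summary.csv")
        if out_dir is not None:
            save_model(model, out_dir / "model.npz")
            artifacts["model.npz"] = out_dir / "model.npz"
        logger.info("fit: edf %.2f, deviance explained %.1f%%", model.edf_total, 100 * model.deviance_explained)

        stage = "predict"
        preds = predict_with_ci(model, split.test, ci_level=config.ci_level)
        save_csv(preds, "predictions.csv")

        stage = "bounds"
        histories = patient_histories(cohort)
        test_pids = split.test["patient_id"].tolist()
        ranges = [
            compute_personal_range(histories[pid], k=config.k_default, patient_id=pid)
            for pid in test_pids
        ]
        save_csv(ranges_table(ranges), "ranges.csv")

        stage = "evaluate"
        y_test = split.test["y"].to_numpy(float)
        pred_labels = [classify_value(v, r) for v, r in zip(preds["y_hat"], ranges)]
        act_labels = [classify_value(v, r) for v, r in zip(y_test, ranges)]
        confusion = ev.confusion_from_classifications(pred_labels, act_labels)
        metrics = ev.metrics_from_matrix(confusion, k=config.k_default)
        mspe_val = ev.mspe(preds["y_hat"], y_test)
        train_mu = float(split.train["y"].mean())
        train_sd = float(split.train["y"].std(ddof=1))
        frac_delta, ci_cov, frac_2sd = ev.coverage_fractions(
            preds, y_test, delta=config.delta, pooled_sd=train_sd, pooled_mean=train_mu
        )
        sweep = ev.threshold_sweep(split.test, histories, preds, config.k_grid)
        save_csv(ev.sweep_frame(sweep), "sweep.csv")
        icc_pre = ev.icc(
            cohort.measurements["hb_mmol_l"], cohort.measurements["patient_id"]
        )
        resid = split.train["y"].to_numpy(float) - model.predict(split.train)
        icc_post = ev.icc(resid, split.train["patient_id"])
        summary = ev.EvaluationSummary(
            mspe=mspe_val,
            rmse=float(np.sqrt(mspe_val)),
            frac_within_delta=frac_delta,
            delta=config.delta,
            ci_coverage=ci_cov,
            ci_level=config.ci_level,
            frac_within_2sd=frac_2sd,
            confusion=confusion,
            metrics=metrics,
            sweep=sweep,
            icc_pre=icc_pre,
            icc_post=icc_post,
            deviance_explained=model.deviance_explained,
            n_test=len(split.test),
        )
        if out_dir is not None:
            (out_dir / "metrics_report.txt").write_text(summary.report_text() + "\n")
            artifacts["metrics_report.txt"] = out_dir / "metrics_report.txt"
            config.to_yaml(out_dir / "config_echo.yaml")
            artifacts["config_echo.yaml"] = out_dir / "config_echo.yaml"
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    return PipelineResult(
        summary=summary,
        model=model,
        split=split,
        cohort=cohort,
        histories=histories,
        predictions=preds,
        attrition=attrition,
        artifacts=artifacts,
    )


@dataclass(frozen=True)
class SubsetComparison:
    """Simple vs sophisticated model on the same random patient subset."""

    n_patients: int
    aic_simple: float
    aic_sophisticated: float
    bic_simple: float
    bic_sophisticated: float
    mspe_simple: float
    mspe_sophisticated: float


def run_subset_comparison(
    config: PipelineConfig, n_patients: int = 100, cohort: Cohort | None = None
) -> SubsetComparison:
    """Fit the plain spec and the by-gender-smooths spec on a random subset
    of patients and compare AIC/BIC and held-out MSPE."""
    if cohort is None:
        if isinstance(config.synthetic, str):
            cohort = read_cohort(config.synthetic)
        else:
            cohort = generate_cohort(config.resolved_synthetic())
    cohort, _ = deduplicate_same_day(cohort)
    cohort, _ = apply_inclusion_filters(cohort, config.filters)
    pids = pd.unique(cohort.measurements["patient_id"])
    if n_patients > len(pids):
        raise ValueError(
            f"subset of {n_patients} requested but only {len(pids)} patients survive filtering"
        )
    child = np.random.SeedSequence(config.seed).spawn(2)[1]
    rng = np.random.default_rng(child.generate_state(1)[0] % (2**31))
    chosen = set(rng.choice(pids, size=n_patients, replace=False))
    sub = cohort.measurements[cohort.measurements["patient_id"].isin(chosen)]
    truth = cohort.generator_truth
    if truth is not None:
        truth = truth[truth["patient_id"].isin(chosen)].reset_index(drop=True)
    subset = Cohort(sub.reset_index(drop=True), cohort.provenance, truth)
    rows = build_model_rows(subset, past_mean_mode=config.past_mean_mode)
    split = holdout_split(rows)
    if len(split.train) < 30:
        raise ValueError("subset too small to fit the additive model")
    simple_spec = dataclasses.replace(config.model, by_gender_smooths=False)
    soph_spec = dataclasses.replace(config.model, by_gender_smooths=True)
    y_test = split.test["y"].to_numpy(float)
    simple = fit_additive_model(split.train, simple_spec)
    soph = fit_additive_model(split.train, soph_spec)
    return SubsetComparison(
        n_patients=n_patients,
        aic_simple=simple.aic,
        aic_sophisticated=soph.aic,
        bic_simple=simple.bic,
        bic_sophisticated=soph.bic,
        mspe_simple=ev.mspe(predict_with_ci(simple, split.test)["y_hat"], y_test),
        mspe_sophisticated=ev.mspe(predict_with_ci(soph, split.test)["y_hat"], y_test),
    )
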