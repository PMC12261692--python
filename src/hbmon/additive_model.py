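"""Penalized-spline additive model for longitudinal Hb prediction.

The model is Gaussian with identity link,

    y_i = beta0 + gender_i * beta_g + sum_j f_j(x_ij) + b_{patient(i)} + e_i,

where each f_j is a centered penalized B-spline smooth (age at measurement,
strictly-past mean Hb, days since the first measurement), b is a per-patient
random intercept realized as a ridge-penalized indicator block, and e_i ~
N(0, sigma^2).  All penalty weights — one per smooth plus the ridge weight
of the random-intercept block, which plays the role of the between/within
variance ratio — are selected jointly by restricted maximum likelihood
(REML; generalized cross-validation is available as an alternative).

Fitting is penalized least squares: for penalty weights lam_j,

    beta_hat = argmin ||y - X beta||^2 + sum_j lam_j beta' S_j beta.

The REML score profiled over sigma^2 is

    (n - M_p) log(RSS + pen) + log|X'X + S(lam)| - log|S(lam)|_+,

with M_p the dimension of the total penalty null space; it is minimized
over log-penalties with a derivative-free simplex search.  Effective degrees
of freedom are the per-term sums of diag((X'X + S)^{-1} X'X); uncertainty
uses the Bayesian posterior covariance sigma^2 (X'X + S)^{-1}, whose
intervals account for smoothing bias.

Reported per-smooth F statistics are Wald-type approximations on the
posterior covariance, adequate for judging whether a term carries signal;
they are not an exact finite-sample test.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .splines import PSplineBasis

__all__ = [
    "ModelSpec",
    "FittedAdditiveModel",
    "ComparisonReport",
    "fit_additive_model",
    "fit_mixed_baseline",
    "predict_with_ci",
    "compare_models",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

_DEFAULT_SMOOTHS = (("age", 10), ("past_mean", 10), ("time_since_first_days", 10))


class FitError(RuntimeError):
    """Raised when the penalized fit cannot be computed."""


@dataclass(frozen=True)
class ModelSpec:
    """Declaration of the additive model structure."""

    smooth_terms: tuple = _DEFAULT_SMOOTHS
    parametric_terms: tuple = ("gender",)
    random_intercept: bool = True
    by_gender_smooths: bool = False
    smoothing_selection: str = "REML"
    ci_mode: str = "prediction"  # or "mean"

    def validate(self, columns) -> None:
        if self.smoothing_selection not in ("REML", "GCV"):
            raise ValueError("smoothing_selection must be 'REML' or 'GCV'")
        for cov, k in self.smooth_terms:
            if k < 3:
                raise ValueError(f"basis dimension for {cov} must be >= 3")
            if cov not in columns:
                raise ValueError(f"smooth covariate {cov!r} not in model rows")
        for term in self.parametric_terms:
            if term != "gender":
                raise ValueError(f"unsupported parametric term {term!r}")

    def term_names(self) -> list[str]:
        names = ["intercept"] + list(self.parametric_terms)
        for cov, _ in self.smooth_terms:
            if self.by_gender_smooths and cov == "past_mean":
                names += [f"s({cov}):female", f"s({cov}):male"]
            else:
                names.append(f"s({cov})")
        if self.random_intercept:
            names.append("random(patient_id)")
        return names


# ---------------------------------------------------------------------------
# design-block helpers


@dataclass
class _Block:
    name: str
    kind: str  # parametric | smooth | linear | random
    cols: slice = field(default=None)  # filled during assembly
    basis: PSplineBasis | None = None
    gender_level: str | None = None
    covariate: str | None = None
    levels: list | None = None  # random-intercept patient order
    center: float = 0.0  # linear terms: training mean

    @property
    def penalized(self) -> bool:
        return self.kind in ("smooth", "random")

    def design(self, rows: pd.DataFrame) -> np.ndarray:
        n = len(rows)
        if self.kind == "parametric":  # gender: male indicator
            g = rows["gender"]
            bad = ~g.isin(["female", "male"])
            if bad.any():
                raise FitError(f"unseen gender level {g[bad].iloc[0]!r}")
            return (g == "male").to_numpy(float)[:, None]
        if self.kind == "linear":
            return (rows[self.covariate].to_numpy(float) - self.center)[:, None]
        if self.kind == "smooth":
            X = self.basis.design(rows[self.covariate].to_numpy(float))
            if self.gender_level is not None:
                X = X * (rows["gender"] == self.gender_level).to_numpy(float)[:, None]
            return X
        if self.kind == "random":
            idx = pd.Index(self.levels)
            pos = idx.get_indexer(rows["patient_id"])
            X = np.zeros((n, len(self.levels)))
            seen = pos >= 0
            if not seen.all():
                warnings.warn(
                    "prediction rows contain patients unseen in training; "
                    "their random-intercept offset is 0",
                    stacklevel=2,
                )
            X[np.flatnonzero(seen), pos[seen]] = 1.0
            return X
        raise AssertionError(self.kind)

    def penalty(self) -> tuple[np.ndarray | None, int, float]:
        """(S, rank, log pseudo-determinant); S=None means identity ridge."""
        if self.kind == "smooth":
            return self.basis.S, self.basis.rank, self.basis.log_pdet
        if self.kind == "random":
            return None, len(self.levels), 0.0
        raise AssertionError


def _build_blocks(train: pd.DataFrame, spec: ModelSpec) -> list[_Block]:
    blocks: list[_Block] = []
    for term in spec.parametric_terms:
        blocks.append(_Block(name="gender", kind="parametric"))
    for cov, k in spec.smooth_terms:
        x = train[cov].to_numpy(float)
        if spec.by_gender_smooths and cov == "past_mean":
            for level in ("female", "male"):
                mask = (train["gender"] == level).to_numpy()
                if mask.sum() < k:
                    raise FitError(
                        f"too few {level} rows ({mask.sum()}) for a k={k} smooth"
                    )
                basis = PSplineBasis(x[mask], k=k)
                blocks.append(
                    _Block(
                        name=f"s({cov}):{level}",
                        kind="smooth",
                        basis=basis,
                        covariate=cov,
                        gender_level=level,
                    )
                )
        else:
            try:
                basis = PSplineBasis(x, k=k)
            except ValueError as exc:
                raise FitError(f"smooth term s({cov}): {exc}") from exc
            blocks.append(
                _Block(name=f"s({cov})", kind="smooth", basis=basis, covariate=cov)
            )
    if spec.random_intercept:
        levels = list(pd.unique(train["patient_id"]))
        blocks.append(_Block(name="random(patient_id)", kind="random", levels=levels))
    return blocks


def _assemble(blocks: list[_Block], rows: pd.DataFrame) -> np.ndarray:
    parts = [np.ones((len(rows), 1))]
    col = 1
    for b in blocks:
        Xb = b.design(rows)
        if b.kind in ("parametric", "linear") and np.ptp(Xb) == 0:
            raise FitError(
                f"term {b.name!r} is constant over the training rows "
                "(rank-deficient design)"
            )
        b.cols = slice(col, col + Xb.shape[1])
        col += Xb.shape[1]
        parts.append(Xb)
    return np.concatenate(parts, axis=1)


# ---------------------------------------------------------------------------
# fitted model container


@dataclass
class FittedAdditiveModel:
    """Fitted state: coefficients, penalties, bases, and inference pieces."""

    spec: ModelSpec
    blocks: list
    beta: np.ndarray
    A_inv: np.ndarray  # (X'X + S)^{-1}; posterior cov = scale * A_inv
    lambdas: dict
    scale: float  # residual variance sigma^2
    rss: float
    n_train: int
    edf_total: float
    edf1_total: float  # tr(2M - M^2); expected RSS drop per unit under the null
    edf_by_term: dict
    aic: float
    bic: float
    deviance_explained: float
    parametric_table: pd.DataFrame
    smooth_table: pd.DataFrame
    selection_info: dict

    @property
    def beta0(self) -> float:
        return float(self.beta[0])

    @property
    def random_intercepts(self) -> pd.Series | None:
        for b in self.blocks:
            if b.kind == "random":
                return pd.Series(self.beta[b.cols], index=b.levels, name="offset")
        return None

    # -- prediction --------------------------------------------------------

    def design_matrix(self, rows: pd.DataFrame) -> np.ndarray:
        parts = [np.ones((len(rows), 1))]
        for b in self.blocks:
            parts.append(b.design(rows))
        return np.concatenate(parts, axis=1)

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        return self.design_matrix(rows) @ self.beta

    def term_contributions(self, rows: pd.DataFrame) -> pd.DataFrame:
        """Per-term additive contributions; they sum (with the intercept) to
        the prediction exactly."""
        out = {"intercept": np.full(len(rows), self.beta0)}
        for b in self.blocks:
            out[b.name] = b.design(rows) @ self.beta[b.cols]
        return pd.DataFrame(out, index=rows.index)

    def partial_effect(self, term: str, grid: np.ndarray) -> np.ndarray:
        """Fitted smooth (or linear) curve for one covariate term on a grid."""
        for b in self.blocks:
            if b.name == term:
                if b.kind == "smooth":
                    return b.basis.design(np.asarray(grid, float)) @ self.beta[b.cols]
                if b.kind == "linear":
                    g = np.asarray(grid, float) - b.center
                    return g * self.beta[b.cols][0]
        raise KeyError(f"no term named {term!r}")

    def se_fit(self, rows: pd.DataFrame) -> np.ndarray:
        X = self.design_matrix(rows)
        return np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, self.A_inv, X), 0.0) * self.scale)


# ---------------------------------------------------------------------------
# fitting


def _penalty_matrices(blocks):
    pens = []
    for b in blocks:
        if b.penalized:
            S, rank, log_pdet = b.penalty()
            pens.append((b, S, rank, log_pdet))
    return pens


def _penalized_solve(XtX, Xty, pens, lams):
    A = XtX.copy()
    for (b, S, _, _), lam in zip(pens, lams):
        if S is None:
            idx = np.arange(b.cols.start, b.cols.stop)
            A[idx, idx] += lam
        else:
            A[b.cols, b.cols] += lam * S
    try:
        c = cho_factor(A, lower=True, check_finite=False)
    except np.linalg.LinAlgError as exc:
        raise FitError(f"penalized normal equations not positive definite: {exc}") from exc
    beta = cho_solve(c, Xty, check_finite=False)
    logdet = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
    return beta, c, logdet


def fit_additive_model(
    train: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    fixed_lambda: dict | None = None,
) -> FittedAdditiveModel:
    """Fit the additive model on training rows by penalized least squares
    with automatic smoothing selection.

    ``fixed_lambda`` pins the penalty weight of named terms (e.g.
    ``{"s(age)": 1e8}``); remaining weights are still selected.  Raises
    :class:`FitError` on degenerate designs or non-convergence.
    """
    if train.empty:
        raise FitError("training set is empty")
    spec.validate(train.columns)
    y = train["y"].to_numpy(float)
    n = len(y)

    blocks = _build_blocks(train, spec)
    X = _assemble(blocks, train)
    p = X.shape[1]
    if n <= 2:
        raise FitError("need more than 2 training rows")
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    pens = _penalty_matrices(blocks)
    ranks = [r for (_, _, r, _) in pens]
    log_pdets = [lp for (_, _, _, lp) in pens]
    M_p = p - sum(ranks)

    free = [i for i, (b, *_rest) in enumerate(pens) if not (fixed_lambda and b.name in fixed_lambda)]
    lam = np.ones(len(pens))
    for i, (b, S, _, _) in enumerate(pens):
        if fixed_lambda and b.name in fixed_lambda:
            lam[i] = float(fixed_lambda[b.name])
        else:
            tr_block = float(np.trace(XtX[b.cols, b.cols]))
            tr_S = float(np.trace(S)) if S is not None else (b.cols.stop - b.cols.start)
            lam[i] = max(tr_block, 1e-8) / max(tr_S, 1e-8)

    def rss_pen(beta, lams):
        quad = float(beta @ (XtX @ beta))
        rss = max(yty - 2.0 * float(beta @ Xty) + quad, 0.0)
        pen = 0.0
        for (b, S, _, _), lv in zip(pens, lams):
            bj = beta[b.cols]
            pen += lv * float(bj @ bj if S is None else bj @ S @ bj)
        return rss, pen

    use_gcv = spec.smoothing_selection == "GCV"

    def score(rho_free):
        lams = lam.copy()
        lams[free] = np.exp(np.clip(rho_free, -25.0, 25.0))
        try:
            beta, c, logdet = _penalized_solve(XtX, Xty, pens, lams)
        except FitError:
            return 1e12
        rss, pen = rss_pen(beta, lams)
        if use_gcv:
            edf = float(np.trace(cho_solve(c, XtX, check_finite=False)))
            denom = max(n - edf, 1e-3)
            return n * max(rss, 1e-12) / denom**2
        lsp = sum(r * np.log(lv) + lp for r, lv, lp in zip(ranks, lams, log_pdets))
        return (n - M_p) * np.log(max(rss + pen, 1e-10)) + logdet - lsp

    info = {"criterion": spec.smoothing_selection, "n_penalties": len(pens)}
    if free:
        rho0 = np.log(lam[free])
        res = optimize.minimize(
            score,
            rho0,
            method="Nelder-Mead",
            options={"fatol": 1e-7, "xatol": 1e-4, "maxiter": 200 * (len(free) + 1)},
        )
        if not np.isfinite(res.fun):
            raise FitError(f"smoothing selection diverged: {res.message}")
        lam[free] = np.exp(np.clip(res.x, -25.0, 25.0))
        info.update(iterations=int(res.nit), converged=bool(res.success), score=float(res.fun))
        if not res.success:
            logger.warning("smoothing selection stopped early: %s", res.message)

    beta, c, _ = _penalized_solve(XtX, Xty, pens, lam)
    rss, _pen = rss_pen(beta, lam)
    M = cho_solve(c, XtX, check_finite=False)
    diag_edf = np.diag(M).copy()
    edf_total = float(diag_edf.sum())
    diag_ref = np.diag(2.0 * M - M @ M).copy()
    scale = rss / max(n - edf_total, 1.0)
    A_inv = cho_solve(c, np.eye(p), check_finite=False)

    tss = float(((y - y.mean()) ** 2).sum())
    dev_expl = float(np.clip(1.0 - rss / tss, 0.0, 1.0)) if tss > 0 else 1.0
    sigma2_ml = max(rss / n, 1e-300)
    loglik = -0.5 * n * (np.log(2.0 * np.pi * sigma2_ml) + 1.0)
    aic = -2.0 * loglik + 2.0 * (edf_total + 1.0)
    bic = -2.0 * loglik + np.log(n) * (edf_total + 1.0)

    df_resid = max(n - edf_total, 1.0)
    par_rows, smooth_rows = [], []
    edf_by_term = {"intercept": float(diag_edf[0])}
    se0 = float(np.sqrt(max(A_inv[0, 0], 0.0) * scale))
    par_rows.append(
        {
            "term": "intercept",
            "estimate": float(beta[0]),
            "std_error": se0,
            "t_value": float(beta[0] / se0) if se0 > 0 else np.inf,
            "p_value": float(2 * stats.t.sf(abs(beta[0] / max(se0, 1e-300)), df_resid)),
        }
    )
    lambdas = {}
    for i, (bpen, *_r) in enumerate(pens):
        lambdas[bpen.name] = float(lam[i])
    for b in blocks:
        sl = b.cols
        edf_term = float(diag_edf[sl].sum())
        edf_by_term[b.name] = edf_term
        if b.kind == "parametric":
            est = float(beta[sl][0])
            se = float(np.sqrt(max(A_inv[sl, sl][0, 0], 0.0) * scale))
            tval = est / se if se > 0 else np.inf
            par_rows.append(
                {
                    "term": "gender(male)",
                    "estimate": est,
                    "std_error": se,
                    "t_value": tval,
                    "p_value": float(2 * stats.t.sf(abs(tval), df_resid)),
                }
            )
        elif b.kind in ("smooth", "linear", "random"):
            ncols = sl.stop - sl.start
            ref_df = float(np.clip(diag_ref[sl].sum(), edf_term, ncols))
            bj = beta[sl]
            Vjj = A_inv[sl, sl] * scale
            if edf_term < 1e-3:
                fval, pval = 0.0, 1.0
            else:
                try:
                    stat = float(bj @ np.linalg.solve(Vjj, bj))
                except np.linalg.LinAlgError:
                    stat = float(bj @ np.linalg.pinv(Vjj) @ bj)
                r = max(ref_df, 1e-2)
                fval = stat / r
                pval = float(stats.f.sf(fval, r, df_resid))
            smooth_rows.append(
                {
                    "term": b.name,
                    "edf": edf_term,
                    "ref_df": ref_df,
                    "F_value": fval,
                    "p_value": pval,
                }
            )

    model = FittedAdditiveModel(
        spec=spec,
        blocks=blocks,
        beta=beta,
        A_inv=A_inv,
        lambdas=lambdas,
        scale=float(scale),
        rss=float(rss),
        n_train=n,
        edf_total=edf_total,
        edf1_total=float(diag_ref.sum()),
        edf_by_term=edf_by_term,
        aic=float(aic),
        bic=float(bic),
        deviance_explained=dev_expl,
        parametric_table=pd.DataFrame(par_rows),
        smooth_table=pd.DataFrame(smooth_rows),
        selection_info=info,
    )
    return model


def fit_mixed_baseline(train: pd.DataFrame, spec: ModelSpec = ModelSpec()) -> FittedAdditiveModel:
    """Linear mixed-effects baseline: the same response and covariates but
    every covariate effect is a straight line (edf = 1), plus the
    REML-selected ridge random intercept.  Returns the same fitted-model
    shape as :func:`fit_additive_model`."""
    if train.empty:
        raise FitError("training set is empty")
    y = train["y"].to_numpy(float)
    blocks: list[_Block] = [_Block(name="gender", kind="parametric")]
    for cov, _k in spec.smooth_terms:
        x = train[cov].to_numpy(float)
        blocks.append(
            _Block(name=f"linear({cov})", kind="linear", covariate=cov, center=float(x.mean()))
        )
    if spec.random_intercept:
        blocks.append(
            _Block(name="random(patient_id)", kind="random", levels=list(pd.unique(train["patient_id"])))
        )
    return _fit_prebuilt(train, y, blocks, spec)


def _fit_prebuilt(train, y, blocks, spec):
    """Fit with externally constructed blocks (shared with the baseline)."""
    # temporarily reuse fit_additive_model's internals via a tiny spec shim:
    # assemble, penalize only the random block, REML-select its ridge weight.
    n = len(y)
    X = _assemble(blocks, train)
    p = X.shape[1]
    XtX, Xty, yty = X.T @ X, X.T @ y, float(y @ y)
    pens = _penalty_matrices(blocks)
    ranks = [r for (_, _, r, _) in pens]
    M_p = p - sum(ranks)
    lam = np.ones(len(pens))

    def solve(lams):
        return _penalized_solve(XtX, Xty, pens, lams)

    def score(rho):
        lams = np.exp(np.clip(rho, -25.0, 25.0))
        try:
            beta, c, logdet = solve(lams)
        except FitError:
            return 1e12
        quad = float(beta @ (XtX @ beta))
        rss = max(yty - 2 * float(beta @ Xty) + quad, 0.0)
        pen = sum(
            lv * float(beta[b.cols] @ beta[b.cols]) for (b, *_), lv in zip(pens, lams)
        )
        lsp = sum(r * lr for r, lr in zip(ranks, np.log(lams)))
        return (n - M_p) * np.log(max(rss + pen, 1e-10)) + logdet - lsp

    info = {"criterion": "REML", "n_penalties": len(pens)}
    if pens:
        res = optimize.minimize(
            score,
            np.zeros(len(pens)),
            method="Nelder-Mead",
            options={"fatol": 1e-7, "xatol": 1e-4, "maxiter": 200 * (len(pens) + 1)},
        )
        lam = np.exp(np.clip(res.x, -25.0, 25.0))
        info.update(iterations=int(res.nit), converged=bool(res.success))
    beta, c, _ = solve(lam)
    quad = float(beta @ (XtX @ beta))
    rss = max(yty - 2 * float(beta @ Xty) + quad, 0.0)
    M = cho_solve(c, XtX, check_finite=False)
    diag_edf = np.diag(M).copy()
    edf_total = float(diag_edf.sum())
    diag_ref = np.diag(2.0 * M - M @ M).copy()
    scale = rss / max(n - edf_total, 1.0)
    A_inv = cho_solve(c, np.eye(p), check_finite=False)
    tss = float(((y - y.mean()) ** 2).sum())
    sigma2_ml = max(rss / n, 1e-300)
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2_ml) + 1.0)
    edf_by_term = {"intercept": float(diag_edf[0])}
    df_resid = max(n - edf_total, 1.0)
    par_rows, smooth_rows = [], []
    for b in blocks:
        sl = b.cols
        edf_term = float(diag_edf[sl].sum())
        edf_by_term[b.name] = edf_term
        est = float(beta[sl][0]) if sl.stop - sl.start == 1 else np.nan
        if b.kind in ("parametric", "linear"):
            se = float(np.sqrt(max(A_inv[sl, sl][0, 0], 0.0) * scale))
            tval = est / se if se > 0 else np.inf
            par_rows.append(
                {
                    "term": b.name,
                    "estimate": est,
                    "std_error": se,
                    "t_value": tval,
                    "p_value": float(2 * stats.t.sf(abs(tval), df_resid)),
                }
            )
            smooth_rows.append(
                {"term": b.name, "edf": 1.0, "ref_df": 1.0,
                 "F_value": tval**2 if np.isfinite(tval) else np.inf,
                 "p_value": float(2 * stats.t.sf(abs(tval), df_resid))}
            )
        else:
            smooth_rows.append(
                {"term": b.name, "edf": edf_term, "ref_df": float(sl.stop - sl.start),
                 "F_value": np.nan, "p_value": np.nan}
            )
    lambdas = {b.name: float(lv) for (b, *_), lv in zip(pens, lam)}
    return FittedAdditiveModel(
        spec=spec,
        blocks=blocks,
        beta=beta,
        A_inv=A_inv,
        lambdas=lambdas,
        scale=float(scale),
        rss=float(rss),
        n_train=n,
        edf_total=edf_total,
        edf1_total=float(diag_ref.sum()),
        edf_by_term=edf_by_term,
        aic=float(-2 * loglik + 2 * (edf_total + 1)),
        bic=float(-2 * loglik + np.log(n) * (edf_total + 1)),
        deviance_explained=float(np.clip(1 - rss / tss, 0, 1)) if tss > 0 else 1.0,
        parametric_table=pd.DataFrame(par_rows),
        smooth_table=pd.DataFrame(smooth_rows),
        selection_info=info,
    )


# ---------------------------------------------------------------------------
# prediction with intervals


def predict_with_ci(
    model: FittedAdditiveModel,
    rows: pd.DataFrame,
    ci_level: float = 0.95,
    interval: str | None = None,
) -> pd.DataFrame:
    """Point predictions with symmetric Gaussian intervals.

    ``interval="prediction"`` (the default from the model spec) adds the
    residual variance to the fitted-mean variance, giving an interval for the
    next *observation*; ``interval="mean"`` covers the fitted mean only.
    """
    if not 0.0 < ci_level < 1.0:
        raise ValueError("ci_level must lie in (0, 1)")
    interval = interval or model.spec.ci_mode
    if interval not in ("prediction", "mean"):
        raise ValueError("interval must be 'prediction' or 'mean'")
    X = model.design_matrix(rows)
    y_hat = X @ model.beta
    var_fit = np.maximum(np.einsum("ij,jk,ik->i", X, model.A_inv, X), 0.0) * model.scale
    var = var_fit + (model.scale if interval == "prediction" else 0.0)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    half = z * np.sqrt(var)
    return pd.DataFrame(
        {
            "patient_id": rows["patient_id"].to_numpy(),
            "y_hat": y_hat,
            "ci_low": y_hat - half,
            "ci_high": y_hat + half,
            "ci_level": ci_level,
        },
        index=rows.index,
    )


# ---------------------------------------------------------------------------
# model comparison


@dataclass(frozen=True)
class ComparisonReport:
    """Nested-model comparison: information criteria, residual deviances, and
    an approximate F test on the drop in residual deviance per effective
    degree of freedom."""

    delta_aic: float  # reduced - full
    delta_bic: float
    deviance_full: float
    deviance_reduced: float
    edf_full: float
    edf_reduced: float
    f_statistic: float
    p_value: float


def compare_models(
    full: FittedAdditiveModel, reduced: FittedAdditiveModel, train: pd.DataFrame
) -> ComparisonReport:
    full_terms = {b.name for b in full.blocks}
    red_terms = {b.name for b in reduced.blocks}
    if not red_terms <= full_terms:
        raise ValueError(
            f"models are not nested: reduced has extra term(s) {red_terms - full_terms}"
        )
    if full.n_train != reduced.n_train:
        raise ValueError("models were fit on different numbers of rows")
    n = full.n_train
    # numerator df: difference of tr(2M - M^2), the expected RSS drop (in
    # sigma^2 units) a null extra term produces through shrinkage; using
    # plain edf here would make the test anti-conservative
    df1 = full.edf1_total - reduced.edf1_total
    df2 = max(n - full.edf_total, 1.0)
    num = reduced.rss - full.rss
    if df1 < 1e-3 or num <= 0:
        f_stat, p = 0.0, 1.0
    else:
        f_stat = (num / df1) / max(full.rss / df2, 1e-300)
        p = float(stats.f.sf(f_stat, df1, df2))
    return ComparisonReport(
        delta_aic=reduced.aic - full.aic,
        delta_bic=reduced.bic - full.bic,
        deviance_full=full.rss,
        deviance_reduced=reduced.rss,
        edf_full=full.edf_total,
        edf_reduced=reduced.edf_total,
        f_statistic=float(f_stat),
        p_value=float(p),
    )


# ---------------------------------------------------------------------------
# serialization (single .npz archive, bit-reproducible re-prediction)


def save_model(model: FittedAdditiveModel, path) -> None:
    arrays = {"beta": model.beta, "A_inv": model.A_inv}
    meta = {
        "spec": {
            "smooth_terms": [list(t) for t in model.spec.smooth_terms],
            "parametric_terms": list(model.spec.parametric_terms),
            "random_intercept": model.spec.random_intercept,
            "by_gender_smooths": model.spec.by_gender_smooths,
            "smoothing_selection": model.spec.smoothing_selection,
            "ci_mode": model.spec.ci_mode,
        },
        "scale": model.scale,
        "rss": model.rss,
        "n_train": model.n_train,
        "edf_total": model.edf_total,
        "edf1_total": model.edf1_total,
        "edf_by_term": model.edf_by_term,
        "aic": model.aic,
        "bic": model.bic,
        "deviance_explained": model.deviance_explained,
        "lambdas": model.lambdas,
        "selection_info": model.selection_info,
        "blocks": [],
    }
    for i, b in enumerate(model.blocks):
        entry = {
            "name": b.name,
            "kind": b.kind,
            "cols": [b.cols.start, b.cols.stop],
            "covariate": b.covariate,
            "gender_level": b.gender_level,
            "center": b.center,
        }
        if b.kind == "smooth":
            entry["k"] = b.basis.k
            entry["degree"] = b.basis.degree
            entry["x_lo"] = b.basis.x_lo
            entry["x_hi"] = b.basis.x_hi
            entry["rank"] = b.basis.rank
            entry["log_pdet"] = b.basis.log_pdet
            arrays[f"block{i}_knots"] = b.basis.knots
            arrays[f"block{i}_Z"] = b.basis.Z
            arrays[f"block{i}_S"] = b.basis.S
        if b.kind == "random":
            entry["levels"] = list(b.levels)
        meta["blocks"].append(entry)
    meta["parametric_table"] = model.parametric_table.to_dict(orient="list")
    meta["smooth_table"] = model.smooth_table.to_dict(orient="list")
    np.savez_compressed(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path) -> FittedAdditiveModel:
    data = np.load(path)
    meta = json.loads(bytes(data["meta"]).decode())
    sp = meta["spec"]
    spec = ModelSpec(
        smooth_terms=tuple(tuple(t) for t in sp["smooth_terms"]),
        parametric_terms=tuple(sp["parametric_terms"]),
        random_intercept=sp["random_intercept"],
        by_gender_smooths=sp["by_gender_smooths"],
        smoothing_selection=sp["smoothing_selection"],
        ci_mode=sp["ci_mode"],
    )
    blocks = []
    for i, e in enumerate(meta["blocks"]):
        b = _Block(
            name=e["name"],
            kind=e["kind"],
            covariate=e["covariate"],
            gender_level=e["gender_level"],
            center=e["center"] or 0.0,
        )
        b.cols = slice(e["cols"][0], e["cols"][1])
        if e["kind"] == "smooth":
            basis = PSplineBasis.__new__(PSplineBasis)
            basis.k = e["k"]
            basis.degree = e["degree"]
            basis.x_lo = e["x_lo"]
            basis.x_hi = e["x_hi"]
            basis.rank = e["rank"]
            basis.log_pdet = e["log_pdet"]
            basis.knots = data[f"block{i}_knots"]
            basis.Z = data[f"block{i}_Z"]
            basis.S = data[f"block{i}_S"]
            b.basis = basis
        if e["kind"] == "random":
            b.levels = e["levels"]
        blocks.append(b)
    return FittedAdditiveModel(
        spec=spec,
        blocks=blocks,
        beta=data["beta"],
        A_inv=data["A_inv"],
        lambdas=meta["lambdas"],
        scale=meta["scale"],
        rss=meta["rss"],
        n_train=meta["n_train"],
        edf_total=meta["edf_total"],
        edf1_total=meta["edf1_total"],
        edf_by_term=meta["edf_by_term"],
        aic=meta["aic"],
        bic=meta["bic"],
        deviance_explained=meta["deviance_explained"],
        parametric_table=pd.DataFrame(meta["parametric_table"]),
        smooth_table=pd.DataFrame(meta["smooth_table"]),
        selection_info=meta["selection_info"],
    )
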