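"""Penalized B-spline bases (P-splines) with sum-to-zero centering.

Each smooth f(x) is represented by a cubic B-spline basis on equally spaced
knots spanning the training range of x, with a second-order difference
penalty on the coefficients (Eilers & Marx).  Equally spaced knots make the
penalty null space correspond exactly to straight lines in x, so as the
roughness penalty grows the smooth collapses onto the least-squares line.

Identifiability: an additive model with its own intercept needs each smooth
to carry no constant component.  The basis is reparameterized onto the null
space of the constraint "mean of f over the training rows = 0", dropping one
coefficient; fitted smooths then sum to zero over the training covariate
values by construction.

Evaluation outside the training range clips x to the range boundary
(constant extrapolation), the conservative choice for clinical covariates.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import null_space

__all__ = ["PSplineBasis"]


class PSplineBasis:
    """Centered cubic P-spline basis for one covariate.

    Parameters
    ----------
    x_train : array
        Training covariate values; knots span their range.
    k : int
        Basis dimension before centering (columns in the model: ``k - 1``).
    degree : int
        Spline degree (3 = cubic).
    penalty_order : int
        Order of the difference penalty (2 penalizes curvature).
    """

    def __init__(
        self,
        x_train: np.ndarray,
        k: int = 10,
        degree: int = 3,
        penalty_order: int = 2,
    ) -> None:
        x_train = np.asarray(x_train, dtype=float)
        if k < max(3, degree + 1):
            raise ValueError(f"basis dimension k={k} too small for degree {degree}")
        lo, hi = float(np.min(x_train)), float(np.max(x_train))
        if not hi > lo:
            raise ValueError("smooth covariate needs >= 2 distinct values")
        self.degree = degree
        self.k = k
        self.x_lo, self.x_hi = lo, hi
        nseg = k - degree
        h = (hi - lo) / nseg
        # open uniform knot vector extended `degree` segments past each end
        self.knots = lo + h * np.arange(-degree, nseg + degree + 1)

        B = self._raw(x_train)
        constraint = B.mean(axis=0)
        self.Z = null_space(constraint[None, :])  # (k, k-1)
        D = np.diff(np.eye(k), n=penalty_order, axis=0)
        S0 = D.T @ D
        self.S = self.Z.T @ S0 @ self.Z
        self.rank = k - penalty_order
        eig = np.linalg.eigvalsh(self.S)
        self.log_pdet = float(np.sum(np.log(eig[-self.rank:])))

    @property
    def n_columns(self) -> int:
        return self.k - 1

    def _raw(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), self.x_lo, self.x_hi)
        return BSpline.design_matrix(x, self.knots, self.degree).toarray()

    def design(self, x: np.ndarray) -> np.ndarray:
        """Centered design columns for covariate values ``x``."""
        return self._raw(x) @ self.Z
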