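"""Closed-form OLS for the piecewise growth model, with linear contrasts.

Estimation follows the textbook normal-equations form

    beta_hat = (X'X)^{-1} X'y,     Var(beta_hat) = (X'X)^{-1} sigma2_hat

computed via a QR-based least-squares solve rather than explicit
inversion.  Two conventions for the residual variance are supported:

* ``"paper"`` (default): sigma2_hat = ||y - X beta_hat||^2 / (m - 1),
  matching the published analysis of this cohort;
* ``"standard"``: the usual unbiased ||r||^2 / (m - 4).

For m in the thousands the two differ by well under 0.1% and reported
standard errors agree to printed precision.  t-tests on contrasts a'beta
use m - 4 degrees of freedom either way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignMatrix

__all__ = [
    "A_SUMMER_VS_K",
    "A_SUMMER_VS_G1",
    "FitResult",
    "ContrastResult",
    "SingularDesignError",
    "DegenerateContrastError",
    "fit_ols",
    "contrast_test",
    "rescale_rates",
]

#: contrast picking out (summer rate - kindergarten rate) = b2 - b1
A_SUMMER_VS_K = np.array([0.0, -1.0, 1.0, 0.0])
#: contrast picking out (summer rate - 1st-grade rate) = b2 - b3
A_SUMMER_VS_G1 = np.array([0.0, 0.0, 1.0, -1.0])

COEF_NAMES = ("beta0", "beta1", "beta2", "beta3")


class SingularDesignError(ValueError):
    """X'X is rank deficient (e.g. no assessments in some segment)."""


class DegenerateContrastError(ValueError):
    """Contrast has zero variance but a nonzero estimate."""


@dataclass(frozen=True)
class FitResult:
    """OLS estimate of the piecewise growth model.

    ``beta_hat[0]`` is the intercept in score points; ``beta_hat[1:]``
    are the kindergarten / summer / 1st-grade rates in points per day.
    """

    beta_hat: np.ndarray
    cov_beta: np.ndarray
    sigma2_hat: float
    m: int
    df_t: int
    sigma2_mode: str = "paper"

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta_hat", np.asarray(self.beta_hat, dtype=float))
        object.__setattr__(self, "cov_beta", np.asarray(self.cov_beta, dtype=float))

    @property
    def se(self) -> np.ndarray:
        """Standard errors of the four coefficients (per-day scale for rates)."""
        return np.sqrt(np.diag(self.cov_beta))

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        """Two-sided t confidence intervals, shape (4, 2)."""
        crit = stats.t.ppf(0.5 + level / 2.0, self.df_t)
        half = crit * self.se
        return np.column_stack([self.beta_hat - half, self.beta_hat + half])


@dataclass(frozen=True)
class ContrastResult:
    """t-test of a linear contrast z = a'beta of the growth coefficients."""

    a: np.ndarray
    z_hat: float
    var_z: float
    t_stat: float
    df: int
    p_two_sided: float


def fit_ols(design: DesignMatrix, sigma2_mode: str = "paper") -> FitResult:
    """Fit the growth model by ordinary least squares.

    Raises
    ------
    SingularDesignError
        If X has column rank < 4 — typically a stratum with no
        assessments inside one of the three calendar segments.
    """
    if sigma2_mode not in ("paper", "standard"):
        raise ValueError(f"sigma2_mode must be 'paper' or 'standard', got {sigma2_mode!r}")
    X, y, m = design.X, design.y, design.m
    if m <= 4:
        raise SingularDesignError(f"need more than 4 scores to fit 4 coefficients, got m={m}")
    if np.linalg.matrix_rank(X) < 4:
        raise SingularDesignError(
            "design matrix is rank deficient; ensure assessments fall in "
            "every segment (kindergarten, summer, 1st grade)"
        )
    beta_hat, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_hat
    rss = float(resid @ resid)
    denom = (m - 1) if sigma2_mode == "paper" else (m - 4)
    sigma2 = rss / denom
    xtx_inv = np.linalg.inv(X.T @ X)
    return FitResult(
        beta_hat=beta_hat,
        cov_beta=xtx_inv * sigma2,
        sigma2_hat=sigma2,
        m=m,
        df_t=m - 4,
        sigma2_mode=sigma2_mode,
    )


def contrast_test(fit: FitResult, a: np.ndarray) -> ContrastResult:
    """Two-sided t-test of z = a'beta against zero.

    The degenerate case var_z = 0 with z_hat = 0 (e.g. an all-zero
    contrast) is reported with ``t_stat`` and ``p_two_sided`` as NaN.
    """
    a = np.asarray(a, dtype=float)
    if a.shape != (4,):
        raise ValueError("contrast must be a 4-vector")
    z = float(a @ fit.beta_hat)
    var_z = float(a @ fit.cov_beta @ a)
    if var_z < 0 and var_z > -1e-12:
        var_z = 0.0
    if var_z == 0.0:
        if abs(z) > 1e-12:
            raise DegenerateContrastError(
                f"contrast variance is zero but estimate is {z}; t undefined"
            )
        return ContrastResult(a=a, z_hat=z, var_z=0.0, t_stat=float("nan"),
                              df=fit.df_t, p_two_sided=float("nan"))
    t = z / np.sqrt(var_z)
    p = 2.0 * stats.t.sf(abs(t), fit.df_t)
    return ContrastResult(a=a, z_hat=z, var_z=var_z, t_stat=float(t),
                          df=fit.df_t, p_two_sided=float(p))


def rescale_rates(fit: FitResult, factor: float = 100.0) -> pd.DataFrame:
    """Coefficient table with rates (and their SEs) rescaled per ``factor`` days.

    The intercept row is untouched; the default factor of 100 reports
    rates as score points per 100 days, the convention used in the
    published tables.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    scale = np.array([1.0, factor, factor, factor])
    return pd.DataFrame(
        {
            "estimate": fit.beta_hat * scale,
            "se": fit.se * scale,
        },
        index=list(COEF_NAMES),
    )
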