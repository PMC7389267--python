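"""Contact-time kinetics of the interaction frequency.

The probability that a probe-substrate contact of duration t yields an
adhesion event saturates hyperbolically,

    f(t) = f_max * t / (k_half + t),

formally identical to a Michaelis-Menten law: f_max is the maximal
interaction frequency and k_half the contact time at half-maximal
frequency.  Two estimators are provided: the classical double-reciprocal
(Lineweaver-Burk style) linearisation, ordinary least squares of 1/f on
1/t, and a direct nonlinear fit of the hyperbola.  The linearisation
distorts the error structure, so the nonlinear fit is always computed as
a cross-check and a large discrepancy triggers a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator

__all__ = ["ContactKineticsFit", "HyperbolicKinetics", "fit_hyperbolic"]

#: relative k_half disagreement between the two methods that triggers a warning
DISCREPANCY_WARN = 0.25


@dataclass
class ContactKineticsFit:
    """Fitted hyperbola parameters with cross-check values from the other method."""

    f_max: float
    k_half: float
    method: str
    f_max_se: float
    k_half_se: float
    valid: bool
    alt_f_max: float
    alt_k_half: float
    discrepancy: bool


def _hyperbola(t, f_max, k_half):
    return f_max * t / (k_half + t)


def _fit_double_reciprocal(t: np.ndarray, f: np.ndarray):
    keep = f > 0
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} zero-frequency point(s) from the "
            "double-reciprocal fit",
            stacklevel=3,
        )
    t, f = t[keep], f[keep]
    if t.size < 3:
        raise ValueError("double-reciprocal fit needs >= 3 nonzero-frequency points")
    x, y = 1.0 / t, 1.0 / f
    # OLS y = b0 + b1 x with parameter covariance
    X = np.column_stack([np.ones_like(x), x])
    beta, res_ss, *_ = np.linalg.lstsq(X, y, rcond=None)
    b0, b1 = beta
    dof = x.size - 2
    resid = y - X @ beta
    s2 = float(resid @ resid) / dof if dof > 0 else np.nan
    cov = s2 * np.linalg.inv(X.T @ X) if dof > 0 else np.full((2, 2), np.nan)
    valid = b0 > 0
    f_max = 1.0 / b0 if b0 != 0 else np.inf
    k_half = b1 / b0 if b0 != 0 else np.inf
    # delta method: grad f_max = (-1/b0^2, 0); grad k_half = (-b1/b0^2, 1/b0)
    g1 = np.array([-1.0 / b0**2, 0.0])
    g2 = np.array([-b1 / b0**2, 1.0 / b0])
    f_max_se = float(np.sqrt(g1 @ cov @ g1)) if np.isfinite(cov).all() else np.nan
    k_half_se = float(np.sqrt(g2 @ cov @ g2)) if np.isfinite(cov).all() else np.nan
    if not valid:
        warnings.warn("non-positive double-reciprocal intercept; fit invalid", stacklevel=3)
    return float(f_max), float(k_half), f_max_se, k_half_se, bool(valid)


def _fit_nonlinear(t: np.ndarray, f: np.ndarray, p0=None):
    if p0 is None or not all(np.isfinite(p0)) or any(p <= 0 for p in p0):
        p0 = (max(f.max(), 1e-3), float(np.median(t)))
    p0 = (min(max(p0[0], 1e-6), 1.0), max(p0[1], 1e-6))  # keep inside bounds
    popt, pcov = curve_fit(
        _hyperbola, t, f, p0=p0, bounds=([1e-12, 1e-12], [1.0, np.inf]), maxfev=10000
    )
    se = np.sqrt(np.diag(pcov))
    return float(popt[0]), float(popt[1]), float(se[0]), float(se[1]), True


class HyperbolicKinetics(BaseEstimator):
    """Fit f(t) = f_max * t / (k_half + t) to (contact time, frequency) data.

    ``method`` selects which estimate populates the fitted attributes
    (``f_max_``, ``k_half_``); the other method is always run as a
    cross-check (``alt_f_max_``, ``alt_k_half_``).
    """

    def __init__(self, method: str = "double_reciprocal") -> None:
        self.method = method

    def fit(self, X, y):
        if self.method not in ("double_reciprocal", "nonlinear"):
            raise ValueError("method must be 'double_reciprocal' or 'nonlinear'")
        t = np.asarray(X, dtype=float).ravel()
        f = np.asarray(y, dtype=float).ravel()
        if t.size != f.size:
            raise ValueError("times and frequencies must have equal length")
        if np.unique(t[t > 0]).size < 3:
            raise ValueError("need >= 3 distinct positive contact times")
        if np.any(t <= 0):
            raise ValueError("contact times must be positive")
        if np.any((f < 0) | (f > 1)):
            raise ValueError("frequencies must be in [0, 1]")

        dr = _fit_double_reciprocal(t, f)
        try:
            nl = _fit_nonlinear(t, f, p0=(dr[0], dr[1]) if dr[4] else None)
        except RuntimeError:
            nl = (np.nan, np.nan, np.nan, np.nan, False)
            warnings.warn("nonlinear hyperbolic fit failed to converge", stacklevel=2)

        primary, alt = (dr, nl) if self.method == "double_reciprocal" else (nl, dr)
        self.f_max_, self.k_half_, self.f_max_se_, self.k_half_se_, self.valid_ = primary
        self.alt_f_max_, self.alt_k_half_ = alt[0], alt[1]
        self.discrepancy_ = bool(
            np.isfinite(self.k_half_)
            and np.isfinite(self.alt_k_half_)
            and self.k_half_ > 0
            and abs(self.k_half_ - self.alt_k_half_) / self.k_half_ > DISCREPANCY_WARN
        )
        if self.discrepancy_:
            warnings.warn(
                "double-reciprocal and nonlinear k_half estimates disagree by "
                "more than 25%; the reciprocal transform may be distorting "
                "the error structure",
                stacklevel=2,
            )
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float)
        return _hyperbola(t, self.f_max_, self.k_half_)

    def result_(self) -> ContactKineticsFit:
        return ContactKineticsFit(
            f_max=self.f_max_,
            k_half=self.k_half_,
            method=self.method,
            f_max_se=self.f_max_se_,
            k_half_se=self.k_half_se_,
            valid=self.valid_,
            alt_f_max=self.alt_f_max_,
            alt_k_half=self.alt_k_half_,
            discrepancy=self.discrepancy_,
        )


def fit_hyperbolic(times, frequencies, method: str = "double_reciprocal") -> ContactKineticsFit:
    """Functional wrapper over :class:`HyperbolicKinetics`."""
    return HyperbolicKinetics(method=method).fit(times, frequencies).result_()
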