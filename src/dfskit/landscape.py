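"""Two-regime (Friddle-Noy-de Yoreo) energy-landscape analysis of force spectra.

A dynamic force spectrum is the set of (loading rate r, rupture force F)
pairs collected over a range of pulling speeds.  Its mean is modelled by
the two-regime interpolation

    F(r) = f_eq + f_beta * ln(1 + e^(-gamma) * r / (k_off * f_beta)),

where f_eq (pN) is the equilibrium force - the plateau at vanishing
loading rate where rupture and rebinding balance - f_beta = k_B*T / x_t
(pN) is the thermal force setting the slope of the kinetic (F ~ ln r)
regime, k_off (1/s) is the dissociation rate at f_eq, and gamma is the
Euler-Mascheroni constant.  From a fitted (f_eq, f_beta, k_off) triple
the landscape descriptors follow exactly:

    x_t   = k_B*T / f_beta          (barrier width)
    |dG|  = f_eq^2 / (2 * k_c)      (binding free energy, cantilever k_c)
    tau_0 = 1 / k_off               (bond lifetime at f_eq)

dG is reported negative (binding is favourable).  Fitting uses
Levenberg-Marquardt least squares with an internal log-parameterisation
that keeps all three parameters positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .constants import DEFAULT_TEMPERATURE, EULER_GAMMA, K_B, KCAL_PER_MOL_TO_PN_NM
from .adhesion import GaussianForceFit

__all__ = [
    "DFSDataset",
    "EnergyLandscapeFit",
    "LandscapeDerived",
    "FNdYModel",
    "fndy_mean_force",
    "derive_landscape",
    "bin_dfs",
    "fit_fndy",
]


@dataclass
class DFSDataset:
    """(loading rate, rupture force) pairs, optionally with bin summaries."""

    loading_rate: np.ndarray
    rupture_force: np.ndarray
    probe_label: str = ""
    substrate_label: str = ""
    bins: pd.DataFrame | None = None  # columns: loading_rate, rupture_force, n
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.loading_rate = np.asarray(self.loading_rate, dtype=float)
        self.rupture_force = np.asarray(self.rupture_force, dtype=float)
        if self.loading_rate.shape != self.rupture_force.shape:
            raise ValueError("loading_rate and rupture_force must have equal shape")
        if np.any(self.loading_rate <= 0) or np.any(self.rupture_force <= 0):
            raise ValueError("loading rates and rupture forces must be positive")


class LandscapeDerived(NamedTuple):
    x_t_A: float
    delta_g_kcal_per_mol: float | None
    tau0_ms: float


@dataclass
class EnergyLandscapeFit:
    """Fitted two-regime parameters with derived landscape descriptors.

    Confidence intervals are 99% by default, from the linearised covariance
    with t-quantiles (df = n - 3); the prediction band adds the residual
    variance.
    """

    f_eq: float            # pN
    f_beta: float          # pN
    k_off: float           # 1/s
    x_t: float             # Angstrom
    delta_g: float | None  # kcal/mol, negative
    tau0: float            # ms
    k_c: float | None      # pN/nm used for delta_g
    temperature: float     # K
    ci99: dict[str, tuple[float, float]]
    band_r: np.ndarray
    band_lo: np.ndarray
    band_hi: np.ndarray
    chi2: float
    n_iter: int
    converged: bool
    n_points: int


def fndy_mean_force(r, f_eq: float, f_beta: float, k_off: float):
    """Model mean rupture force (pN) at loading rate(s) r (pN/s).

    Strictly increasing in r; F(0) = f_eq.
    """
    for name, v in (("f_eq", f_eq), ("f_beta", f_beta), ("k_off", k_off)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("loading rate must be >= 0")
    out = f_eq + f_beta * np.log1p(np.exp(-EULER_GAMMA) * r / (k_off * f_beta))
    return float(out) if out.ndim == 0 else out


def derive_landscape(
    f_eq: float,
    f_beta: float,
    k_off: float,
    k_c: float | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
) -> LandscapeDerived:
    """Barrier width x_t (Angstrom), binding free energy dG (kcal/mol,
    negative) and bond lifetime tau_0 (ms) from a fitted parameter triple.

    dG requires the cantilever spring constant k_c (pN/nm); without it the
    value is omitted with a warning rather than guessed.
    """
    for name, v in (("f_eq", f_eq), ("f_beta", f_beta), ("k_off", k_off), ("temperature", temperature)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    x_t_nm = K_B * temperature / f_beta
    tau0_ms = 1000.0 / k_off
    if k_c is None:
        warnings.warn(
            "spring constant k_c not given; delta_G omitted", stacklevel=2
        )
        delta_g = None
    else:
        if k_c <= 0:
            raise ValueError("k_c must be positive")
        delta_g = -(f_eq**2 / (2.0 * k_c)) / KCAL_PER_MOL_TO_PN_NM
    return LandscapeDerived(x_t_A=10.0 * x_t_nm, delta_g_kcal_per_mol=delta_g, tau0_ms=tau0_ms)


def bin_dfs(
    data: DFSDataset,
    n_bins: int = 8,
    gauss_bin_width: float = 10.0,
) -> DFSDataset:
    """Summarise a spectrum into log-spaced loading-rate bins.

    Per-bin representative force is the Gaussian-fit mode when the bin has
    >= 30 events, else the mean; representative rate is the geometric mean.
    Empty bins are dropped (with a warning when fewer than requested bins
    survive).
    """
    if n_bins < 3:
        raise ValueError("n_bins must be >= 3")
    r, F = data.loading_rate, data.rupture_force
    if np.unique(r).size < n_bins:
        warnings.warn(
            "fewer distinct loading rates than requested bins", stacklevel=2
        )
    edges = np.geomspace(r.min(), r.max(), n_bins + 1)
    edges[-1] *= 1 + 1e-12  # include the max
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (r >= lo) & (r < hi)
        n = int(mask.sum())
        if n == 0:
            continue
        if n >= 30:
            g = GaussianForceFit(bin_width=gauss_bin_width).fit(F[mask])
            f_repr = g.mu_  # mode of the fitted Gaussian
        else:
            f_repr = float(np.mean(F[mask]))
        rows.append((float(np.exp(np.mean(np.log(r[mask])))), f_repr, n))
    if len(rows) < n_bins:
        warnings.warn(f"only {len(rows)} non-empty bins returned", stacklevel=2)
    bins = pd.DataFrame(rows, columns=["loading_rate", "rupture_force", "n"])
    return DFSDataset(
        loading_rate=r,
        rupture_force=F,
        probe_label=data.probe_label,
        substrate_label=data.substrate_label,
        bins=bins,
        meta=dict(data.meta),
    )


class FNdYModel(BaseEstimator, RegressorMixin):
    """Three-parameter nonlinear fit of the two-regime mean-force model.

    Levenberg-Marquardt on (r, F) pairs, iteration cap ``max_iter`` and
    chi-square change tolerance ``chi2_tol`` (values below double-precision
    resolution are clamped to machine epsilon).  Parameters are fitted on a
    log scale so iterates stay positive; confidence intervals are mapped
    back through the exponential.

    Parameters
    ----------
    spring_constant : pN/nm; needed for the derived binding free energy.
    binned : fit the per-bin summaries (see :func:`bin_dfs`) instead of the
        raw per-event points.
    """

    def __init__(
        self,
        max_iter: int = 500,
        chi2_tol: float = 1e-15,
        temperature: float = DEFAULT_TEMPERATURE,
        spring_constant: float | None = None,
        binned: bool = False,
        n_bins: int = 8,
        confidence: float = 0.99,
    ) -> None:
        self.max_iter = max_iter
        self.chi2_tol = chi2_tol
        self.temperature = temperature
        self.spring_constant = spring_constant
        self.binned = binned
        self.n_bins = n_bins
        self.confidence = confidence

    # -- data plumbing ------------------------------------------------------
    @staticmethod
    def _as_dataset(X, y) -> DFSDataset:
        if isinstance(X, DFSDataset):
            return X
        X = np.asarray(X, dtype=float)
        if y is None:
            if X.ndim != 2 or X.shape[1] != 2:
                raise ValueError("without y, X must be an (n, 2) array of (r, F)")
            return DFSDataset(X[:, 0], X[:, 1])
        return DFSDataset(X.ravel(), np.asarray(y, dtype=float).ravel())

    @staticmethod
    def _initial_guess(r: np.ndarray, F: np.ndarray) -> np.ndarray:
        """Deterministic data-driven start: plateau from the weakest forces,
        slope of F vs ln r over the top decade, k_off from the model at the
        median point."""
        f_eq0 = max(float(np.min(F)), 1e-3)
        top = r >= r.max() / 10.0
        if np.unique(r[top]).size >= 2:
            f_b0 = float(np.polyfit(np.log(r[top]), F[top], 1)[0])
        else:
            f_b0 = 0.0
        if not np.isfinite(f_b0) or f_b0 <= 0:
            f_b0 = max(0.1 * f_eq0, 1.0)
        F_med, r_med = float(np.median(F)), float(np.median(r))
        denom = f_b0 * max(np.expm1((F_med - f_eq0) / f_b0), 1e-9)
        k_off0 = np.exp(-EULER_GAMMA) * r_med / denom
        if not np.isfinite(k_off0) or k_off0 <= 0:
            k_off0 = 1.0
        return np.log([f_eq0, f_b0, k_off0])

    # -- fitting ------------------------------------------------------------
    def fit(self, X, y=None):
        data = self._as_dataset(X, y)
        if self.binned:
            if data.bins is None:
                data = bin_dfs(data, n_bins=self.n_bins)
            r = data.bins["loading_rate"].to_numpy()
            F = data.bins["rupture_force"].to_numpy()
        else:
            r, F = data.loading_rate, data.rupture_force

        distinct = np.unique(r)
        if distinct.size < 5 or distinct.max() / distinct.min() < 10.0:
            warnings.warn(
                "poorly conditioned spectrum: need >= 5 distinct loading "
                "rates spanning >= 1 decade",
                stacklevel=2,
            )

        def residuals(logp):
            # clip keeps exp() finite when a weakly identified direction runs away
            f_eq, f_beta, k_off = np.exp(np.clip(logp, -60.0, 60.0))
            return fndy_mean_force(r, f_eq, f_beta, k_off) - F

        tol = max(self.chi2_tol, float(np.finfo(float).eps))
        res = least_squares(
            residuals,
            self._initial_guess(r, F),
            method="lm",
            ftol=tol,
            xtol=tol,
            gtol=tol,
            max_nfev=self.max_iter,
        )
        self.converged_ = bool(res.status > 0)
        if not self.converged_:
            warnings.warn(
                f"Levenberg-Marquardt did not converge within {self.max_iter} "
                "evaluations; returning last iterate",
                stacklevel=2,
            )
        logp = np.clip(res.x, -60.0, 60.0)
        self.f_eq_, self.f_beta_, self.k_off_ = (float(v) for v in np.exp(logp))
        self.n_points_ = int(r.size)
        self.n_iter_ = int(res.nfev)
        self.chi2_ = float(2.0 * res.cost)

        # linearised covariance in log-parameter space
        dof = max(self.n_points_ - 3, 0)
        s2 = self.chi2_ / dof if dof > 0 else 0.0
        J = res.jac
        JTJ = J.T @ J
        try:
            cov_log = np.linalg.inv(JTJ) * s2
        except np.linalg.LinAlgError:
            cov_log = np.linalg.pinv(JTJ) * s2
        self.cov_log_ = cov_log
        self.residual_variance_ = s2
        p = np.exp(logp)
        self.cov_ = np.diag(p) @ cov_log @ np.diag(p)  # natural parameters

        tq = stats.t.ppf(0.5 + self.confidence / 2.0, dof) if dof > 0 else np.inf
        se_log = np.sqrt(np.clip(np.diag(cov_log), 0.0, np.inf))
        names = ("f_eq", "f_beta", "k_off")
        self.ci99_ = {
            name: (float(v * np.exp(-tq * s)), float(v * np.exp(tq * s)))
            for name, v, s in zip(names, p, se_log)
        }
        self._t_quantile = float(tq)

        derived = derive_landscape(
            self.f_eq_, self.f_beta_, self.k_off_,
            k_c=self.spring_constant, temperature=self.temperature,
        )
        self.x_t_ = derived.x_t_A
        self.delta_g_ = derived.delta_g_kcal_per_mol
        self.tau0_ = derived.tau0_ms
        self._fit_range = (float(r.min()), float(r.max()))
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        r = X[:, 0] if X.ndim == 2 else X.ravel()
        return fndy_mean_force(r, self.f_eq_, self.f_beta_, self.k_off_)

    def _mean_gradient_log(self, r: np.ndarray) -> np.ndarray:
        """d F / d log-params at the fitted point, shape (n, 3)."""
        eps = 1e-7
        logp = np.log([self.f_eq_, self.f_beta_, self.k_off_])
        cols = []
        for i in range(3):
            up, dn = logp.copy(), logp.copy()
            up[i] += eps
            dn[i] -= eps
            cols.append(
                (fndy_mean_force(r, *np.exp(up)) - fndy_mean_force(r, *np.exp(dn)))
                / (2 * eps)
            )
        return np.stack(cols, axis=1)

    def prediction_interval(self, r) -> tuple[np.ndarray, np.ndarray]:
        """Prediction band for new rupture forces at loading rate(s) r."""
        r = np.atleast_1d(np.asarray(r, dtype=float))
        G = self._mean_gradient_log(r)
        var_mean = np.einsum("ij,jk,ik->i", G, self.cov_log_, G)
        se = np.sqrt(np.clip(var_mean + self.residual_variance_, 0.0, np.inf))
        mid = fndy_mean_force(r, self.f_eq_, self.f_beta_, self.k_off_)
        return mid - self._t_quantile * se, mid + self._t_quantile * se

    def result_(self, n_band: int = 50) -> EnergyLandscapeFit:
        band_r = np.geomspace(*self._fit_range, n_band)
        lo, hi = self.prediction_interval(band_r)
        return EnergyLandscapeFit(
            f_eq=self.f_eq_,
            f_beta=self.f_beta_,
            k_off=self.k_off_,
            x_t=self.x_t_,
            delta_g=self.delta_g_,
            tau0=self.tau0_,
            k_c=self.spring_constant,
            temperature=self.temperature,
            ci99=self.ci99_,
            band_r=band_r,
            band_lo=lo,
            band_hi=hi,
            chi2=self.chi2_,
            n_iter=self.n_iter_,
            converged=self.converged_,
            n_points=self.n_points_,
        )


def fit_fndy(
    loading_rate,
    rupture_force=None,
    **model_kwargs,
) -> EnergyLandscapeFit:
    """Functional wrapper over :class:`FNdYModel`.

    Accepts a :class:`DFSDataset` or two arrays (r, F).
    """
    model = FNdYModel(**model_kwargs)
    model.fit(loading_rate, rupture_force)
    return model.result_()
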