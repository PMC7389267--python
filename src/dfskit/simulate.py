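"""Synthetic data generators with known ground truth.

Every input the analysis pipeline consumes can be produced here:
stochastic rupture forces under a linear force ramp, full force-distance
curves with embedded tether-rupture events, force-volume maps with
spatially patterned adhesion (bud-scar-like patches), and contact-time
frequency tables.  All draws come from an explicit seeded generator - no
global random state - and every generator returns (or writes) a ground
truth sufficient to score any downstream stage.

Rupture-force sampling
----------------------
A bond pulled at constant loading rate r with an escape rate growing
exponentially above the equilibrium force has the first-passage survival

    S(F) = exp(-(1/a) * (e^((F - f_eq)/f_beta) - 1)),    F >= f_eq,

whose mean excess over f_eq is f_beta * e^(1/a) * E1(1/a).  The
two-regime interpolation used for fitting,
f_beta * ln(1 + e^(-gamma) * a), matches that expression only
asymptotically; in the crossover region the two differ by up to ~20% of
the mean force.  To make the simulator an exact Monte-Carlo counterpart
of the fitted model, the scale a is calibrated per loading rate: we
solve e^(1/a')E1(1/a') = ln(1 + e^(-gamma) * a) so that the ensemble
mean rupture force equals the model curve at every rate while the
first-passage shape of the scatter is preserved.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import exp1

from .constants import EULER_GAMMA
from .curves import (
    CurveMetadata,
    CurveValidationError,
    ForceCurve,
    ForceVolumeGrid,
    write_curve,
    write_grid_index,
)
from .landscape import DFSDataset

__all__ = [
    "RuptureSimConfig",
    "CurveSimConfig",
    "MapSimulation",
    "default_loading_rates",
    "sample_rupture_forces",
    "synthesize_curve",
    "synthesize_map",
    "synthesize_contact_series",
    "write_map_fixture",
]


def default_loading_rates(n: int = 12, lo: float = 100.0, hi: float = 20000.0) -> np.ndarray:
    """Log-spaced loading rates (pN/s) over the experimentally probed span."""
    return np.geomspace(lo, hi, n)


@dataclass
class RuptureSimConfig:
    """Ground-truth parameters for the ramp-rupture sampler."""

    f_eq: float
    f_beta: float
    k_off: float
    seed: int
    loading_rates: np.ndarray = field(default_factory=default_loading_rates)
    n_per_rate: int = 167

    def __post_init__(self) -> None:
        for name in ("f_eq", "f_beta", "k_off"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.loading_rates = np.asarray(self.loading_rates, dtype=float)
        if np.any(self.loading_rates <= 0) or self.n_per_rate < 1:
            raise ValueError("loading rates and n_per_rate must be positive")


def _exp1_scaled(x: np.ndarray) -> np.ndarray:
    """e^x * E1(x), stable for large x (asymptotic series beyond x = 50)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    out = np.empty_like(x)
    small = x < 50.0
    out[small] = np.exp(x[small]) * exp1(x[small])
    xs = x[~small]
    if xs.size:
        s = np.zeros_like(xs)
        term = np.ones_like(xs)
        for k in range(9):  # truncation error < 1e-9 relative at x >= 50
            s += term
            term *= -(k + 1) / xs
        out[~small] = s / xs
    return out


def _calibrated_scale(r: float, f_beta: float, k_off: float) -> float:
    """Effective first-passage scale a' whose exact mean excess equals the
    two-regime model's ln(1 + e^(-gamma) * a) at this loading rate."""
    target = float(np.log1p(np.exp(-EULER_GAMMA) * r / (k_off * f_beta)))
    sol = brentq(
        lambda lx: float(_exp1_scaled(np.exp(lx))[0]) - target,
        -45.0, 45.0, xtol=1e-14, rtol=8.9e-16,
    )
    return float(np.exp(-sol))  # a' = 1/x


def sample_rupture_forces(config: RuptureSimConfig | None = None, **kwargs) -> DFSDataset:
    """Draw rupture forces at each loading rate by inverse-CDF sampling of the
    calibrated first-passage law; ground truth is attached in ``meta``."""
    if config is None:
        config = RuptureSimConfig(**kwargs)
    rng = np.random.default_rng(config.seed)
    rates, forces = [], []
    for r in config.loading_rates:
        a = _calibrated_scale(r, config.f_beta, config.k_off)
        draws = config.f_eq + config.f_beta * np.log1p(a * rng.standard_exponential(config.n_per_rate))
        rates.append(np.full(config.n_per_rate, r))
        forces.append(draws)
    return DFSDataset(
        loading_rate=np.concatenate(rates),
        rupture_force=np.concatenate(forces),
        meta={
            "true_f_eq": config.f_eq,
            "true_f_beta": config.f_beta,
            "true_k_off": config.k_off,
            "seed": config.seed,
            "n_per_rate": config.n_per_rate,
        },
    )


@dataclass
class CurveSimConfig:
    """Geometry and noise of one synthetic force-distance cycle.

    events : list of (rupture distance nm, rupture force pN) to embed on the
        retract; each is a linear tether-loading dip reaching -force at the
        stated distance, then an instantaneous release.
    """

    seed: int
    noise_sigma: float = 5.0
    sampling_rate: float = 2000.0   # Hz
    retract_speed: float = 1.0      # um/s
    setpoint: float = 500.0         # pN
    events: tuple = ()
    tether_stiffness: float = 2.0   # pN/nm
    z_range: float = 600.0          # nm scanned away from contact
    contact_height: float = 0.0     # nm
    spring_constant: float = 10.0   # pN/nm
    temperature: float = 293.15
    curve_id: str = "sim-000"

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for d, f in self.events:
            if f > 10.0 * self.setpoint:
                raise CurveValidationError("embedded event deeper than 10x setpoint")
            if not 0 < d < self.z_range:
                raise CurveValidationError("embedded event outside scan range")


def synthesize_curve(config: CurveSimConfig | None = None, **kwargs) -> tuple[ForceCurve, dict]:
    """Build one noisy approach/retract cycle; returns (curve, ground truth)."""
    if config is None:
        config = CurveSimConfig(**kwargs)
    rng = np.random.default_rng(config.seed)
    v = config.retract_speed * 1000.0           # nm/s
    dz = v / config.sampling_rate               # nm per sample
    dt = 1.0 / config.sampling_rate
    indent = config.setpoint / config.spring_constant
    n = int(round((config.z_range + indent) / dz)) + 1

    top = config.contact_height + config.z_range
    bottom = config.contact_height - indent
    h_app = np.linspace(top, bottom, n)
    h_ret = np.linspace(bottom, top, n)

    def contact_force(h):
        return np.where(h < config.contact_height,
                        (config.contact_height - h) * config.spring_constant, 0.0)

    f_app = contact_force(h_app)
    f_ret = contact_force(h_ret)
    for d, amp in config.events:
        h_rupture = config.contact_height + d
        width = amp / config.tether_stiffness
        mask = (h_ret > h_rupture - width) & (h_ret <= h_rupture)
        f_ret = f_ret - np.where(
            mask, config.tether_stiffness * (h_ret - (h_rupture - width)), 0.0
        )
    if config.noise_sigma > 0:
        f_app = f_app + rng.normal(0.0, config.noise_sigma, n)
        f_ret = f_ret + rng.normal(0.0, config.noise_sigma, n)

    t = np.arange(2 * n) * dt
    curve = ForceCurve(
        metadata=CurveMetadata(
            curve_id=config.curve_id,
            spring_constant=config.spring_constant,
            retract_speed=config.retract_speed,
            temperature=config.temperature,
            setpoint_force=config.setpoint,
        ),
        time=t,
        height=np.concatenate([h_app, h_ret]),
        force=np.concatenate([f_app, f_ret]),
        segment=np.array(["approach"] * n + ["retract"] * n),
    )
    truth = {
        "curve_id": config.curve_id,
        "contact_height": config.contact_height,
        "noise_sigma": config.noise_sigma,
        "events": [
            {
                "distance_nm": d,
                "force_pN": amp,
                "loading_rate_pN_per_s": config.tether_stiffness * v,
            }
            for d, amp in config.events
        ],
    }
    return curve, truth


@dataclass
class MapSimulation:
    """A synthetic force-volume dataset: grid, curves, and ground truth."""

    grid: ForceVolumeGrid
    curves: dict[str, ForceCurve]
    truth: dict


def synthesize_map(
    n_rows: int = 32,
    n_cols: int = 32,
    background_p: float = 0.05,
    patches: tuple = (),
    seed: int = 0,
    force_mu: float = 83.0,
    force_sigma: float = 25.0,
    force_min: float = 30.0,
    distance_range: tuple[float, float] = (30.0, 150.0),
    curve_kwargs: dict | None = None,
) -> MapSimulation:
    """Force-volume grid with Bernoulli per-pixel adhesion.

    ``patches`` is a list of ((row, col), radius_pixels, probability)
    circular regions of elevated adhesion probability (bud-scar-like);
    elsewhere the background probability applies.  Event forces are
    Gaussian (clipped below ``force_min`` so events stay detectable above
    the noise floor); distances are uniform within ``distance_range``.
    """
    p_map = np.full((n_rows, n_cols), float(background_p))
    rr, cc = np.mgrid[0:n_rows, 0:n_cols]
    for (center, radius, p) in patches:
        disc = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
        p_map[disc] = p
    if np.any(p_map > 1.0):
        warnings.warn("patch probability > 1 clipped", stacklevel=2)
        p_map = np.clip(p_map, 0.0, 1.0)
    if np.any(p_map < 0.0):
        raise ValueError("probabilities must be in [0, 1]")

    base_kwargs = dict(z_range=300.0, sampling_rate=1000.0)
    base_kwargs.update(curve_kwargs or {})
    rng = np.random.default_rng(seed)
    has_event = rng.random((n_rows, n_cols)) < p_map

    pixel_curves: dict[tuple[int, int], str] = {}
    curves: dict[str, ForceCurve] = {}
    truth_events: dict[str, list] = {}
    for r in range(n_rows):
        for c in range(n_cols):
            cid = f"px-{r:03d}-{c:03d}"
            events = ()
            if has_event[r, c]:
                d = rng.uniform(*distance_range)
                amp = max(rng.normal(force_mu, force_sigma), force_min)
                events = ((float(d), float(amp)),)
            cfg = CurveSimConfig(
                seed=int(rng.integers(0, 2**31 - 1)),
                curve_id=cid,
                events=events,
                **base_kwargs,
            )
            curve, truth = synthesize_curve(cfg)
            pixel_curves[(r, c)] = cid
            curves[cid] = curve
            truth_events[cid] = truth["events"]
    grid = ForceVolumeGrid(n_rows, n_cols, pixel_curves)
    return MapSimulation(
        grid=grid,
        curves=curves,
        truth={
            "seed": seed,
            "p_map": p_map.tolist(),
            "has_event": has_event.tolist(),
            "events": truth_events,
        },
    )


def write_map_fixture(sim: MapSimulation, directory: str | Path) -> Path:
    """Write curve files, the grid index CSV, and a ground-truth sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for cid, curve in sim.curves.items():
        write_curve(curve, directory / f"{cid}.tsv")
        sim.grid.curve_paths[cid] = f"{cid}.tsv"
    index = directory / "grid_index.csv"
    write_grid_index(sim.grid, index)
    (directory / "ground_truth.json").write_text(
        json.dumps(sim.truth, indent=2, sort_keys=True), encoding="utf-8"
    )
    return index


def synthesize_contact_series(
    f_max: float,
    k_half: float,
    times,
    n_curves_per_time: int,
    seed: int,
) -> pd.DataFrame:
    """Binomially sampled adhesion counts along a hyperbolic contact-time law.

    Returns a frame with columns contact_time_s, n_curves, n_adhesive,
    frequency; t = 0 rows have frequency exactly 0.
    """
    if not 0 < f_max <= 1 or k_half <= 0:
        raise ValueError("need 0 < f_max <= 1 and k_half > 0")
    times = np.asarray(times, dtype=float)
    if np.any(times < 0) or n_curves_per_time < 1:
        raise ValueError("times must be >= 0 and n_curves_per_time >= 1")
    rng = np.random.default_rng(seed)
    p = f_max * times / (k_half + times)
    n_adh = rng.binomial(n_curves_per_time, p)
    return pd.DataFrame(
        {
            "contact_time_s": times,
            "n_curves": n_curves_per_time,
            "n_adhesive": n_adh,
            "frequency": n_adh / n_curves_per_time,
        }
    )
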