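"""Adhesion-force distributions (Gaussian fits) and force-volume adhesion maps.

Histograms of rupture forces are fitted with a single Gaussian, as is
conventional for reporting a mean unbinding force as "mu +- sigma pN".
Adhesion maps reduce a force-volume grid to a binary event/no-event
raster plus a quantitative per-pixel maximal specific rupture force.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator

from .curves import ForceVolumeGrid
from .events import AdhesionEvent, AdhesionFrequency

__all__ = [
    "AdhesionForceDistribution",
    "AdhesionMap",
    "GaussianForceFit",
    "fit_gaussian_histogram",
    "render_adhesion_map",
    "write_histogram_tsv",
    "write_map_csv",
    "write_map_pgm",
]


@dataclass
class AdhesionForceDistribution:
    """Binned rupture forces with a Gaussian fit (mu, sigma in pN)."""

    bin_edges: np.ndarray
    counts: np.ndarray
    mu: float
    sigma: float
    amplitude: float
    n_events: int
    fit_ok: bool

    def __str__(self) -> str:  # conventional "mu +- sigma" report format
        if self.fit_ok:
            return f"{self.mu:.0f} +- {self.sigma:.0f} pN (n={self.n_events})"
        return f"histogram only (n={self.n_events})"


def _gauss(x: np.ndarray, amplitude: float, mu: float, sigma: float) -> np.ndarray:
    return amplitude * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


class GaussianForceFit(BaseEstimator):
    """Least-squares Gaussian fit to a binned force histogram.

    Parameters
    ----------
    bin_width : pN; default 10 pN over [0, 300] pN, extended as needed to
        cover the data.
    method : "binned" (fit the histogram counts, the default) or "mle"
        (sample mean/SD of the raw values).
    min_events : below this the histogram is still built but no fit is
        attempted (``fit_ok_`` False).
    """

    def __init__(
        self,
        bin_width: float = 10.0,
        hist_range: tuple[float, float] = (0.0, 300.0),
        method: str = "binned",
        min_events: int = 30,
    ) -> None:
        self.bin_width = bin_width
        self.hist_range = hist_range
        self.method = method
        self.min_events = min_events

    def fit(self, X, y=None):
        forces = np.asarray(X, dtype=float).ravel()
        if forces.size == 0:
            raise ValueError("no forces given")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.method not in ("binned", "mle"):
            raise ValueError("method must be 'binned' or 'mle'")

        lo = min(self.hist_range[0], np.floor(forces.min() / self.bin_width) * self.bin_width)
        hi = max(self.hist_range[1], np.ceil(forces.max() / self.bin_width) * self.bin_width)
        n_bins = max(1, int(round((hi - lo) / self.bin_width)))
        edges = lo + self.bin_width * np.arange(n_bins + 1)
        counts, _ = np.histogram(forces, bins=edges)

        self.bin_edges_ = edges
        self.counts_ = counts
        self.n_events_ = forces.size
        self.mu_ = float(np.mean(forces))
        self.sigma_ = float(np.std(forces, ddof=1)) if forces.size > 1 else 0.0
        self.amplitude_ = float(counts.max()) if counts.size else 0.0
        self.fit_ok_ = False

        degenerate = np.ptp(forces) == 0.0
        if forces.size < self.min_events or degenerate:
            return self
        if self.method == "mle":
            self.fit_ok_ = self.sigma_ > 0
            if self.fit_ok_:
                self.amplitude_ = (
                    forces.size * self.bin_width / (np.sqrt(2 * np.pi) * self.sigma_)
                )
            return self
        centers = 0.5 * (edges[:-1] + edges[1:])
        p0 = (max(counts.max(), 1.0), self.mu_, max(self.sigma_, self.bin_width / 2))
        try:
            popt, _ = curve_fit(_gauss, centers, counts, p0=p0, maxfev=10000)
        except RuntimeError:
            warnings.warn("Gaussian fit did not converge; histogram only", stacklevel=2)
            return self
        self.amplitude_, self.mu_, self.sigma_ = float(popt[0]), float(popt[1]), abs(float(popt[2]))
        self.fit_ok_ = self.sigma_ > 0 and self.amplitude_ > 0
        return self

    def result_(self) -> AdhesionForceDistribution:
        return AdhesionForceDistribution(
            bin_edges=self.bin_edges_,
            counts=self.counts_,
            mu=self.mu_,
            sigma=self.sigma_,
            amplitude=self.amplitude_,
            n_events=self.n_events_,
            fit_ok=self.fit_ok_,
        )


def fit_gaussian_histogram(
    forces, bin_width: float = 10.0, **kwargs
) -> AdhesionForceDistribution:
    """Functional wrapper over :class:`GaussianForceFit`."""
    est = GaussianForceFit(bin_width=bin_width, **kwargs)
    return est.fit(forces).result_()


def write_histogram_tsv(dist: AdhesionForceDistribution, path: str | Path) -> None:
    """TSV with columns bin_left_pN, bin_right_pN, count."""
    lines = ["bin_left_pN\tbin_right_pN\tcount"]
    for left, right, count in zip(dist.bin_edges[:-1], dist.bin_edges[1:], dist.counts):
        lines.append(f"{left:g}\t{right:g}\t{int(count)}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclass
class AdhesionMap:
    """Per-pixel adhesion summary of a force-volume grid.

    binary    : True where the pixel shows >= 1 (specific) event
    max_force : maximal specific rupture force per pixel, NaN where no event
    measured  : False for pixels with no curve in the grid (missing data)
    frequency : adhesion frequency over the measured pixels
    """

    grid: ForceVolumeGrid
    binary: np.ndarray
    max_force: np.ndarray
    measured: np.ndarray
    frequency: AdhesionFrequency


def render_adhesion_map(
    events,
    grid: ForceVolumeGrid,
    specific_only: bool = True,
    pixel_summary: str = "max",
) -> AdhesionMap:
    """Reduce detected events to an adhesion map on the given grid.

    ``events`` is a flat iterable of :class:`AdhesionEvent` (curve_id is
    used to place each event) or a mapping curve_id -> event list.
    ``pixel_summary`` selects the per-pixel scalar: "max" (default),
    "first" (smallest rupture distance) or "sum".
    """
    if pixel_summary not in ("max", "first", "sum"):
        raise ValueError("pixel_summary must be 'max', 'first' or 'sum'")
    if isinstance(events, dict):
        flat: list[AdhesionEvent] = [e for evs in events.values() for e in evs]
    else:
        flat = list(events)
    id_to_pixel = {cid: px for px, cid in grid.pixel_curves.items()}

    per_pixel: dict[tuple[int, int], list[AdhesionEvent]] = {}
    for event in flat:
        if event.curve_id not in id_to_pixel:
            raise ValueError(f"event curve_id {event.curve_id!r} not in grid")
        if specific_only and not event.is_specific:
            continue
        per_pixel.setdefault(id_to_pixel[event.curve_id], []).append(event)

    shape = (grid.n_rows, grid.n_cols)
    binary = np.zeros(shape, dtype=bool)
    max_force = np.full(shape, np.nan)
    measured = np.zeros(shape, dtype=bool)
    for px in grid.pixel_curves:
        measured[px] = True
    for px, evs in per_pixel.items():
        binary[px] = True
        if pixel_summary == "max":
            max_force[px] = max(e.rupture_force for e in evs)
        elif pixel_summary == "sum":
            max_force[px] = sum(e.rupture_force for e in evs)
        else:
            max_force[px] = min(evs, key=lambda e: e.rupture_distance).rupture_force
    n_total = len(grid.pixel_curves)
    if n_total == 0:
        raise ValueError("grid has no curves")
    n_adh = int(binary.sum())
    return AdhesionMap(
        grid=grid,
        binary=binary,
        max_force=max_force,
        measured=measured,
        frequency=AdhesionFrequency(n_adh / n_total, n_adh, n_total),
    )


def write_map_csv(amap: AdhesionMap, path: str | Path) -> None:
    """Quantitative grid of max rupture force; empty cell = no event,
    'missing' = pixel without a curve."""
    rows = []
    for r in range(amap.grid.n_rows):
        row = []
        for c in range(amap.grid.n_cols):
            if not amap.measured[r, c]:
                row.append("missing")
            elif np.isnan(amap.max_force[r, c]):
                row.append("")
            else:
                row.append(f"{amap.max_force[r, c]:.6g}")
        rows.append(",".join(row))
    Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")


def write_map_pgm(amap: AdhesionMap, path: str | Path) -> None:
    """Plain-text PGM (P2): white (255) = adhesion event, black (0) = none."""
    lines = [
        "P2",
        f"{amap.grid.n_cols} {amap.grid.n_rows}",
        "255",
    ]
    for r in range(amap.grid.n_rows):
        lines.append(" ".join("255" if amap.binary[r, c] else "0" for c in range(amap.grid.n_cols)))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
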