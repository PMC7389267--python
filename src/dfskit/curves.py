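"""Force-distance curve data model, text I/O, and pre-processing.

A force curve is a time-ordered sequence of (time, piezo height, force)
samples split into an approach and a retract segment.  Heights increase
away from the surface; adhesive (attractive) forces are negative in the
raw channel and reported as positive magnitudes downstream.

The on-disk format is a UTF-8 TSV dialect: ``# key<TAB>value`` header
lines carrying acquisition metadata, a column-header line, then one row
per sample.  A force-volume grid is an N x N raster of such curves
described by a CSV index (row, col, curve_path).
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CurveFormatError",
    "CurveValidationError",
    "NoContactError",
    "CurveMetadata",
    "ForceCurve",
    "ForceVolumeGrid",
    "read_curve",
    "write_curve",
    "read_grid_index",
    "write_grid_index",
    "correct_baseline",
    "estimate_noise_sigma",
    "find_contact_point",
]

APPROACH = "approach"
RETRACT = "retract"

#: mandatory metadata keys of the curve-file dialect
MANDATORY_KEYS = (
    "curve_id",
    "spring_constant_pN_per_nm",
    "retract_speed_um_per_s",
    "temperature_K",
    "setpoint_pN",
)

_COLUMNS = ("segment", "time_s", "height_nm", "force_pN")

#: minimum samples a segment must have for any pre-processing operation
MIN_SEGMENT_SAMPLES = 16


class CurveFormatError(ValueError):
    """Raised when a curve file does not follow the documented dialect."""


class CurveValidationError(ValueError):
    """Raised when curve data violate a structural invariant."""


class NoContactError(CurveValidationError):
    """Raised when no tip-surface contact can be located on the approach."""


@dataclass
class CurveMetadata:
    """Acquisition metadata attached to one force curve.

    spring_constant : cantilever stiffness k_c, pN/nm
    retract_speed   : um/s
    setpoint_force  : applied force setpoint, pN
    temperature     : K
    height_mode     : "height" (raw piezo) or "separation" (tip-sample)
    """

    curve_id: str
    spring_constant: float
    retract_speed: float
    temperature: float = 293.15
    setpoint_force: float = 500.0
    probe_label: str = ""
    height_mode: str = "height"

    def __post_init__(self) -> None:
        if self.spring_constant <= 0:
            raise CurveValidationError("spring_constant must be > 0 pN/nm")
        if self.retract_speed <= 0:
            raise CurveValidationError("retract_speed must be > 0 um/s")
        if self.temperature <= 0:
            raise CurveValidationError("temperature must be > 0 K")
        if not 1.0 <= self.spring_constant <= 1000.0:
            warnings.warn(
                f"spring_constant {self.spring_constant} pN/nm outside the "
                "plausible [1, 1000] range",
                stacklevel=2,
            )
        if self.height_mode not in ("height", "separation"):
            raise CurveValidationError("height_mode must be 'height' or 'separation'")


@dataclass
class ForceCurve:
    """One calibrated force-distance cycle.

    Arrays are parallel and time-ordered; ``segment`` tags each sample as
    approach or retract.  Time must be strictly increasing within a segment.
    """

    metadata: CurveMetadata
    time: np.ndarray
    height: np.ndarray
    force: np.ndarray
    segment: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.height = np.asarray(self.height, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.segment = np.asarray(self.segment, dtype="U8")
        n = self.time.size
        if not (self.height.size == n and self.force.size == n and self.segment.size == n):
            raise CurveValidationError("sample arrays must have equal length")
        bad = set(np.unique(self.segment)) - {APPROACH, RETRACT}
        if bad:
            raise CurveValidationError(f"unknown segment labels: {sorted(bad)}")
        for name in (APPROACH, RETRACT):
            t = self.time[self.segment == name]
            if t.size > 1 and not np.all(np.diff(t) > 0):
                raise CurveValidationError(f"time not strictly increasing in {name} segment")

    def segment_arrays(self, name: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(time, height, force) of one segment, time-ordered."""
        mask = self.segment == name
        return self.time[mask], self.height[mask], self.force[mask]

    def n_samples(self, name: str | None = None) -> int:
        if name is None:
            return self.time.size
        return int(np.count_nonzero(self.segment == name))

    def require_segment(self, name: str, min_samples: int = MIN_SEGMENT_SAMPLES) -> None:
        if self.n_samples(name) < min_samples:
            raise CurveValidationError(
                f"{name} segment needs >= {min_samples} samples, "
                f"got {self.n_samples(name)}"
            )


@dataclass
class ForceVolumeGrid:
    """N x N (or rows x cols) force-volume raster; pixel -> curve_id, row-major."""

    n_rows: int
    n_cols: int
    pixel_curves: dict[tuple[int, int], str] = field(default_factory=dict)
    scan_extent: tuple[float, float] = (1000.0, 1000.0)
    curve_paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise CurveValidationError("grid dimensions must be positive")
        for (r, c) in self.pixel_curves:
            if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
                raise CurveValidationError(f"pixel ({r}, {c}) outside grid")
        ids = list(self.pixel_curves.values())
        if len(set(ids)) != len(ids):
            raise CurveValidationError("one curve_id mapped to several pixels")

    @property
    def complete(self) -> bool:
        return len(self.pixel_curves) == self.n_rows * self.n_cols


# ---------------------------------------------------------------------------
# text I/O

def write_curve(curve: ForceCurve, path: str | Path) -> None:
    """Write the TSV dialect; inverse of :func:`read_curve` on data fields."""
    for name in (APPROACH, RETRACT):
        if curve.n_samples(name) == 0:
            raise CurveValidationError(f"refusing to write curve without {name} samples")
    md = curve.metadata
    lines = [
        f"# curve_id\t{md.curve_id}",
        f"# spring_constant_pN_per_nm\t{md.spring_constant!r}",
        f"# retract_speed_um_per_s\t{md.retract_speed!r}",
        f"# temperature_K\t{md.temperature!r}",
        f"# setpoint_pN\t{md.setpoint_force!r}",
        f"# probe_label\t{md.probe_label}",
        f"# height_mode\t{md.height_mode}",
        "\t".join(_COLUMNS),
    ]
    rows = (
        f"{s}\t{t:.12e}\t{h:.12e}\t{f:.12e}"
        for s, t, h, f in zip(curve.segment, curve.time, curve.height, curve.force)
    )
    Path(path).write_text("\n".join(lines) + "\n" + "\n".join(rows) + "\n", encoding="utf-8")


def read_curve(path: str | Path) -> ForceCurve:
    """Parse a curve file; raises :class:`CurveFormatError` on dialect errors."""
    text = Path(path).read_text(encoding="utf-8")
    meta: dict[str, str] = {}
    body_start = 0
    for line in text.splitlines(keepends=True):
        if line.startswith("#"):
            parts = line[1:].strip().split("\t")
            if len(parts) == 1:  # empty value (e.g. blank probe_label)
                parts = [parts[0], ""]
            if len(parts) != 2:
                raise CurveFormatError(f"malformed header line: {line.strip()!r}")
            meta[parts[0].strip()] = parts[1]
            body_start += len(line)
        else:
            break
    for key in MANDATORY_KEYS:
        if key not in meta:
            raise CurveFormatError(f"missing mandatory header key: {key!r}")
    body = text[body_start:]
    first = body.splitlines()[0].strip() if body.strip() else ""
    if tuple(first.split("\t")) != _COLUMNS:
        raise CurveFormatError(
            f"expected column header {'/'.join(_COLUMNS)}, got {first!r}"
        )
    try:
        table = pd.read_csv(io.StringIO(body), sep="\t")
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise CurveFormatError(f"unparseable sample table: {exc}") from exc
    try:
        metadata = CurveMetadata(
            curve_id=meta["curve_id"],
            spring_constant=float(meta["spring_constant_pN_per_nm"]),
            retract_speed=float(meta["retract_speed_um_per_s"]),
            temperature=float(meta["temperature_K"]),
            setpoint_force=float(meta["setpoint_pN"]),
            probe_label=meta.get("probe_label", ""),
            height_mode=meta.get("height_mode", "height"),
        )
    except ValueError as exc:
        if isinstance(exc, CurveValidationError):
            raise
        raise CurveFormatError(f"non-numeric metadata value: {exc}") from exc
    return ForceCurve(
        metadata=metadata,
        time=table["time_s"].to_numpy(),
        height=table["height_nm"].to_numpy(),
        force=table["force_pN"].to_numpy(),
        segment=table["segment"].to_numpy(dtype="U8"),
    )


def write_grid_index(grid: ForceVolumeGrid, path: str | Path) -> None:
    """CSV index: row, col, curve_path (0-based, row-major order)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["row", "col", "curve_path"])
        for (r, c) in sorted(grid.pixel_curves):
            cid = grid.pixel_curves[(r, c)]
            writer.writerow([r, c, grid.curve_paths.get(cid, cid)])


def read_grid_index(
    path: str | Path, n_rows: int | None = None, n_cols: int | None = None
) -> ForceVolumeGrid:
    """Read a grid index CSV; dimensions default to the maximal indices seen."""
    table = pd.read_csv(path)
    for col in ("row", "col", "curve_path"):
        if col not in table.columns:
            raise CurveFormatError(f"grid index missing column {col!r}")
    pixel_curves: dict[tuple[int, int], str] = {}
    curve_paths: dict[str, str] = {}
    for _, rec in table.iterrows():
        r, c = int(rec["row"]), int(rec["col"])
        p = str(rec["curve_path"])
        cid = Path(p).stem
        if (r, c) in pixel_curves:
            raise CurveFormatError(f"duplicate pixel ({r}, {c}) in grid index")
        pixel_curves[(r, c)] = cid
        curve_paths[cid] = p
    if n_rows is None:
        n_rows = max((r for r, _ in pixel_curves), default=-1) + 1
    if n_cols is None:
        n_cols = max((c for _, c in pixel_curves), default=-1) + 1
    return ForceVolumeGrid(n_rows, n_cols, pixel_curves, curve_paths=curve_paths)


# ---------------------------------------------------------------------------
# pre-processing

def _mad_sigma(x: np.ndarray) -> float:
    """Robust noise SD: median absolute deviation scaled for a Gaussian."""
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def _diff_noise_sigma(x: np.ndarray) -> float:
    """Noise SD from first differences (MAD-based).

    Insensitive to slowly varying structure such as baseline tilt or
    tether-loading ramps, and robust to the few large single-sample jumps
    a rupture produces; diff of white noise has variance 2 sigma^2.
    """
    d = np.diff(x)
    return _mad_sigma(d) / np.sqrt(2.0)


def _baseline_fit(curve: ForceCurve, tail_fraction: float) -> tuple[np.ndarray, float]:
    """Fit a line to the far-from-surface retract tail.

    Returns (polynomial coefficients in height, noise sigma).  The window is
    shrunk (with a warning) while it contains excursions > 5 sigma, which
    would bias the fit; fewer than MIN_SEGMENT_SAMPLES clean samples is an
    error.
    """
    if not 0 < tail_fraction <= 0.5:
        raise ValueError("tail_fraction must be in (0, 0.5]")
    curve.require_segment(RETRACT)
    _, h, f = curve.segment_arrays(RETRACT)
    k = max(MIN_SEGMENT_SAMPLES, int(round(h.size * tail_fraction)))
    while True:
        hh, ff = h[-k:], f[-k:]
        coeffs = np.polyfit(hh, ff, 1)
        resid = ff - np.polyval(coeffs, hh)
        # difference-based noise estimate: a tether ramp inside the window
        # would inflate a residual-based MAD and mask its own presence
        sigma = _diff_noise_sigma(ff)
        scale = sigma if sigma > 0 else max(float(np.std(resid)), 1e-12)
        if np.max(np.abs(resid)) <= 5.0 * scale:
            return coeffs, scale
        new_k = int(k * 0.75)
        if new_k < MIN_SEGMENT_SAMPLES:
            raise CurveValidationError(
                "no clean far-field window for baseline correction"
            )
        warnings.warn(
            "force excursions detected in baseline window; shrinking window",
            stacklevel=3,
        )
        k = new_k


def correct_baseline(curve: ForceCurve, tail_fraction: float = 0.3) -> ForceCurve:
    """Remove tilt and offset from the force channel.

    A straight line (force vs height) fitted to the final ``tail_fraction``
    of the retract segment - the far-from-surface region - is subtracted
    from the whole curve, so the far-field mean force becomes ~0.
    Idempotent: a second application subtracts the zero line.
    """
    coeffs, _ = _baseline_fit(curve, tail_fraction)
    corrected = curve.force - np.polyval(coeffs, curve.height)
    return replace(curve, force=corrected)


def estimate_noise_sigma(curve: ForceCurve, tail_fraction: float = 0.3) -> float:
    """Noise SD (pN) from the detrended far-field retract tail (MAD-based)."""
    _, sigma = _baseline_fit(curve, tail_fraction)
    return sigma


def find_contact_point(
    curve: ForceCurve,
    noise_sigma_mult: float = 3.0,
    min_run: int = 5,
) -> float:
    """Piezo height (nm) where the approach force first persistently exceeds
    ``noise_sigma_mult`` times the baseline noise SD.

    Expects a baseline-corrected curve; defines the distance origin for
    rupture distances.  ``min_run`` consecutive above-threshold samples are
    required so single noise spikes do not qualify.
    """
    curve.require_segment(APPROACH)
    sigma = estimate_noise_sigma(curve)
    threshold = noise_sigma_mult * max(sigma, 1e-9)
    _, h, f = curve.segment_arrays(APPROACH)
    above = f > threshold
    run = np.convolve(above.astype(int), np.ones(min_run, dtype=int), mode="valid")
    hits = np.flatnonzero(run == min_run)
    if hits.size == 0:
        raise NoContactError("no contact: approach force never exceeds threshold")
    return float(h[hits[0]])
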