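"""Rupture-event detection on retract segments and adhesion-frequency summaries.

An adhesion (rupture) event is a transient attractive excursion of the
retract force channel: the force dips below baseline while a molecular
tether loads, then jumps back when the bond breaks.  Detection operates
on a median-smoothed copy of the signal for localisation; rupture forces
are always read from the unsmoothed channel so their magnitudes are not
attenuated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from sklearn.base import BaseEstimator

from .curves import RETRACT, CurveValidationError, ForceCurve, _diff_noise_sigma

__all__ = [
    "AdhesionEvent",
    "AdhesionFrequency",
    "BlockingReport",
    "RuptureEventDetector",
    "detect_events",
    "adhesion_frequency",
    "blocking_comparison",
    "write_events_table",
    "read_events_table",
]

EVENT_COLUMNS = (
    "curve_id",
    "rupture_force_pN",
    "rupture_distance_nm",
    "loading_rate_pN_per_s",
    "is_specific",
)


@dataclass(frozen=True)
class AdhesionEvent:
    """One detected rupture on a retract segment.

    rupture_force    : magnitude of the force at rupture, pN (> 0)
    rupture_distance : distance of the rupture from the contact point, nm
    loading_rate     : |dF/dt| measured just before rupture, pN/s
    is_specific      : True when the rupture distance falls inside the
                       configured specificity window
    """

    curve_id: str
    rupture_force: float
    rupture_distance: float
    loading_rate: float
    is_specific: bool

    def __post_init__(self) -> None:
        if self.rupture_force <= 0:
            raise ValueError("rupture_force must be > 0")
        if self.loading_rate <= 0:
            raise ValueError("loading_rate must be > 0")
        if self.rupture_distance < 0:
            raise ValueError("rupture_distance must be >= 0")


@dataclass(frozen=True)
class AdhesionFrequency:
    """Fraction of curves with at least one (specific) event, with the exact count."""

    fraction: float
    n_adhesive: int
    n_total: int


@dataclass(frozen=True)
class BlockingReport:
    """Before/after comparison of adhesion frequencies for a blocking control."""

    freq_before: float
    freq_after: float
    drop: float
    ratio: float | None
    blocked: bool


class RuptureEventDetector(BaseEstimator):
    """Detect rupture events on baseline-corrected retract segments.

    Parameters
    ----------
    smoothing_window : samples of the centred moving median used only for
        event localisation (forces are read from the raw channel).
    threshold_sigma : detection depth in units of the baseline noise SD
        (must be >= 2).
    min_separation : nm; candidate minima closer than this are merged,
        keeping the deeper one, and the post-rupture force recovery is
        required within this distance.
    distance_window : (min, max) nm; events inside are flagged specific.
    slope_window : samples immediately preceding the rupture over which
        the instantaneous loading rate |dF/dt| is regressed.
    """

    def __init__(
        self,
        smoothing_window: int = 7,
        threshold_sigma: float = 4.0,
        min_separation: float = 10.0,
        distance_window: tuple[float, float] = (20.0, 500.0),
        slope_window: int = 20,
    ) -> None:
        self.smoothing_window = smoothing_window
        self.threshold_sigma = threshold_sigma
        self.min_separation = min_separation
        self.distance_window = distance_window
        self.slope_window = slope_window

    # sklearn transformer protocol: stateless, fit is a no-op
    def fit(self, X=None, y=None):
        self._validate()
        return self

    def _validate(self) -> None:
        if self.threshold_sigma < 2:
            raise ValueError("threshold_sigma must be >= 2")
        lo, hi = self.distance_window
        if not lo < hi:
            raise ValueError("distance_window must satisfy min < max")
        if self.smoothing_window < 1 or self.slope_window < 2:
            raise ValueError("window sizes too small")

    def detect(self, curve: ForceCurve, contact_height: float = 0.0) -> list[AdhesionEvent]:
        """Events on one curve, sorted by rupture distance."""
        self._validate()
        curve.require_segment(RETRACT)
        t, h, f = curve.segment_arrays(RETRACT)

        tail = f[-max(16, f.size // 3):]
        sigma = max(_diff_noise_sigma(f), 1e-9)
        if abs(float(np.median(tail))) > 3.0 * sigma:
            raise CurveValidationError(
                "retract far-field mean force is far from zero; "
                "apply correct_baseline before event detection"
            )

        smooth = median_filter(f, size=self.smoothing_window, mode="nearest")
        depth_thr = self.threshold_sigma * sigma
        below = smooth < -depth_thr
        if not below.any():
            return []

        # contiguous below-threshold runs -> candidate minima (raw channel)
        edges = np.flatnonzero(np.diff(below.astype(int)))
        starts = list(edges[~below[edges]] + 1) if edges.size else []
        ends = list(edges[below[edges]] + 1) if edges.size else []
        if below[0]:
            starts.insert(0, 0)
        if below[-1]:
            ends.append(below.size)
        # localise on the smoothed channel (robust to single-sample noise
        # extremes); forces are then read from the raw channel at that index
        candidates = [int(s + np.argmin(smooth[s:e])) for s, e in zip(starts, ends)]

        # merge candidates closer than min_separation, keeping the deeper dip
        merged: list[int] = []
        for idx in candidates:
            if merged and h[idx] - h[merged[-1]] < self.min_separation:
                if smooth[idx] < smooth[merged[-1]]:
                    merged[-1] = idx
            else:
                merged.append(idx)

        events: list[AdhesionEvent] = []
        for idx in merged:
            depth = -float(f[idx])
            # rupture: force must jump back toward baseline by at least the
            # event magnitude (noise allowance 2 sigma) within min_separation
            after = (h > h[idx]) & (h <= h[idx] + self.min_separation)
            if not after.any():
                continue
            recovery = float(np.max(f[after])) - float(f[idx])
            if recovery < depth - 2.0 * sigma:
                continue
            lo = max(0, idx - self.slope_window + 1)
            if idx - lo < 2:
                continue
            slope = float(np.polyfit(t[lo : idx + 1], f[lo : idx + 1], 1)[0])
            rate = abs(slope)
            if rate <= 0:
                continue
            distance = float(h[idx] - contact_height)
            if distance < 0:
                continue
            wlo, whi = self.distance_window
            events.append(
                AdhesionEvent(
                    curve_id=curve.metadata.curve_id,
                    rupture_force=depth,
                    rupture_distance=distance,
                    loading_rate=rate,
                    is_specific=bool(wlo <= distance <= whi),
                )
            )
        events.sort(key=lambda e: e.rupture_distance)
        return events

    def transform(self, curves) -> list[list[AdhesionEvent]]:
        """Detect on an iterable of (curve, contact_height) pairs or curves."""
        out = []
        for item in curves:
            if isinstance(item, tuple):
                out.append(self.detect(item[0], contact_height=item[1]))
            else:
                out.append(self.detect(item))
        return out


def detect_events(curve: ForceCurve, contact_height: float = 0.0, **config) -> list[AdhesionEvent]:
    """Functional wrapper over :class:`RuptureEventDetector`."""
    return RuptureEventDetector(**config).detect(curve, contact_height=contact_height)


def adhesion_frequency(
    events_per_curve: list[list[AdhesionEvent]], specific_only: bool = True
) -> AdhesionFrequency:
    """Fraction of curves with >= 1 (specific) event."""
    if len(events_per_curve) == 0:
        raise ValueError("adhesion_frequency needs at least one curve")
    n_adh = sum(
        1
        for evs in events_per_curve
        if any((e.is_specific or not specific_only) for e in evs)
    )
    total = len(events_per_curve)
    return AdhesionFrequency(fraction=n_adh / total, n_adhesive=n_adh, n_total=total)


def blocking_comparison(
    freq_before: float | AdhesionFrequency,
    freq_after: float | AdhesionFrequency,
    blocked_ratio_cutoff: float = 0.5,
) -> BlockingReport:
    """Absolute drop and ratio of adhesion frequencies around a competitor-sugar
    blocking control; flags "blocked" when the ratio falls below the cutoff."""
    before = freq_before.fraction if isinstance(freq_before, AdhesionFrequency) else float(freq_before)
    after = freq_after.fraction if isinstance(freq_after, AdhesionFrequency) else float(freq_after)
    for v in (before, after):
        if not 0.0 <= v <= 1.0:
            raise ValueError("frequencies must be in [0, 1]")
    if before == 0.0:
        warnings.warn("freq_before is 0; blocking ratio undefined", stacklevel=2)
        return BlockingReport(before, after, before - after, None, False)
    ratio = after / before
    return BlockingReport(before, after, before - after, ratio, ratio < blocked_ratio_cutoff)


def write_events_table(events: list[AdhesionEvent], path: str | Path) -> None:
    """TSV with one row per event (columns as in EVENT_COLUMNS)."""
    frame = pd.DataFrame(
        [
            (e.curve_id, e.rupture_force, e.rupture_distance, e.loading_rate, e.is_specific)
            for e in events
        ],
        columns=list(EVENT_COLUMNS),
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_events_table(path: str | Path) -> list[AdhesionEvent]:
    frame = pd.read_csv(path, sep="\t")
    missing = set(EVENT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"events table missing columns: {sorted(missing)}")
    return [
        AdhesionEvent(
            curve_id=str(r.curve_id),
            rupture_force=float(r.rupture_force_pN),
            rupture_distance=float(r.rupture_distance_nm),
            loading_rate=float(r.loading_rate_pN_per_s),
            is_specific=bool(r.is_specific),
        )
        for r in frame.itertuples()
    ]
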