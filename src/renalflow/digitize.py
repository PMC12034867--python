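"""Envelope digitization: axis calibration, pixel-to-physical mapping, beat
extraction, and resampling onto the common 1000-point time grid.

This module replicates, as plain math, the manual plot-digitizer workflow used
to turn a spectral Doppler image into a numeric velocity-vs-time trace:

1. two reference points per axis define an affine pixel -> physical transform
   (:func:`calibrate`);
2. the traced outer-envelope pixels are mapped to (time s, velocity cm/s)
   samples (:func:`to_physical`);
3. a single cardiac cycle is isolated by detecting the systolic upstroke
   (:func:`extract_beat`);
4. the beat is linearly interpolated onto a fixed grid of 1000 timestamps
   spanning 0.1-2.5 s (:func:`resample_to_grid`).

The grid includes both endpoints (step = 2.4/999 s); a single beat is shorter
than the 2.4 s window, so grid points past the end of the trace hold the last
traced velocity rather than extrapolating.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CalibrationError, DataError, SignalQualityError

#: Common time grid shared by every resampled signal (seconds).
GRID_START = 0.1
GRID_END = 2.5
GRID_POINTS = 1000
TIME_GRID = np.linspace(GRID_START, GRID_END, GRID_POINTS)

LABELS = ("ARAS", "normal")
SITES = ("origin", "proximal", "middle", "distal")


@dataclass(frozen=True)
class PixelTrace:
    """Ordered pixel coordinates along a traced outer envelope.

    ``points`` is an (n, 2) array of (x_px, y_px). The x coordinates must be
    non-decreasing (the time axis is monotone); exact duplicates in x are
    tolerated here and averaged during :func:`to_physical`.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise DataError("pixel trace must be an (n, 2) array of (x_px, y_px)")
        if pts.shape[0] < 2:
            raise DataError("pixel trace needs at least 2 points")
        dx = np.diff(pts[:, 0])
        if np.any(dx < 0):
            idx = int(np.argmax(dx < 0)) + 1
            raise DataError(f"x_px decreases at point index {idx}")
        object.__setattr__(self, "points", pts)


@dataclass(frozen=True)
class AxisCalibration:
    """Two reference points per axis mapping pixels to physical units.

    ``x_refs``/``y_refs`` are pairs of (pixel_position, known_value); x in
    seconds, y in cm/s. Pixel y typically increases downward in images — the
    transform is fully determined by the two pairs, so no special flag is
    needed.
    """

    x_refs: tuple[tuple[float, float], tuple[float, float]]
    y_refs: tuple[tuple[float, float], tuple[float, float]]

    def __post_init__(self) -> None:
        for name, refs in (("x", self.x_refs), ("y", self.y_refs)):
            (p1, v1), (p2, v2) = refs
            if p1 == p2:
                raise CalibrationError(f"coincident {name}-axis reference pixels ({p1})")
            if v1 == v2:
                raise CalibrationError(f"identical {name}-axis reference values ({v1})")


@dataclass(frozen=True)
class AxisTransform:
    """Affine map value = slope * pixel + intercept."""

    slope: float
    intercept: float

    def __call__(self, pixel):
        return self.slope * np.asarray(pixel, dtype=float) + self.intercept


@dataclass(frozen=True)
class CalibratedTrace:
    """Physical (time s, velocity cm/s) samples with strictly increasing time."""

    times: np.ndarray
    velocities: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.velocities, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise DataError("times and velocities must be 1-D arrays of equal length")
        if t.size == 0:
            raise DataError("empty trace")
        dt = np.diff(t)
        if np.any(dt <= 0):
            idx = int(np.argmax(dt <= 0)) + 1
            raise DataError(f"time not strictly increasing at sample index {idx}")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "velocities", v)

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class ResampledSignal:
    """One beat's envelope on the common grid, with its study metadata."""

    velocities: np.ndarray
    label: str
    patient_id: str
    site: str
    grid: np.ndarray = field(default_factory=lambda: TIME_GRID, repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.velocities, dtype=float)
        if v.shape != (GRID_POINTS,):
            raise DataError(f"expected {GRID_POINTS} velocity values, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise DataError("non-finite velocity in resampled signal")
        if np.any(v < 0):
            raise DataError("negative velocity in resampled signal")
        if self.label not in LABELS:
            raise DataError(f"label must be one of {LABELS}, got {self.label!r}")
        object.__setattr__(self, "velocities", v)


def calibrate(cal: AxisCalibration) -> tuple[AxisTransform, AxisTransform]:
    """Build the per-axis affine transforms from the reference pairs.

    Each transform maps its two reference pixels exactly onto the known
    values; inverted image axes fall out naturally as a negative slope.
    """

    def _axis(refs) -> AxisTransform:
        (p1, v1), (p2, v2) = refs
        slope = (v2 - v1) / (p2 - p1)
        return AxisTransform(slope=slope, intercept=v1 - slope * p1)

    return _axis(cal.x_refs), _axis(cal.y_refs)


def to_physical(trace: PixelTrace, cal: AxisCalibration) -> CalibratedTrace:
    """Map a pixel trace into physical coordinates.

    Points sharing the same x pixel (manual traces often double back by one
    pixel) collapse into a single sample whose velocity is their mean.
    """
    tx, ty = calibrate(cal)
    times = tx(trace.points[:, 0])
    vels = ty(trace.points[:, 1])
    dt = np.diff(times)
    if np.any(dt < 0):
        idx = int(np.argmax(dt < 0)) + 1
        raise DataError(f"time not monotone after calibration at sample index {idx}")
    # collapse duplicate timestamps by averaging
    uniq, inverse = np.unique(times, return_inverse=True)
    if uniq.size < times.size:
        sums = np.bincount(inverse, weights=vels)
        counts = np.bincount(inverse)
        vels = sums / counts
        times = uniq
    return CalibratedTrace(times=times, velocities=vels)


def _onset_candidates(v: np.ndarray, run_length: int, rise_fraction: float) -> list[int]:
    """Indices of systolic onsets: last local minimum before each qualifying
    run of ``run_length`` strictly increasing samples whose total rise exceeds
    ``rise_fraction`` of the trace range."""
    rng_v = float(v.max() - v.min())
    if rng_v <= 0:
        return []
    onsets: list[int] = []
    n = v.size
    for i in range(n - run_length + 1):
        window = v[i : i + run_length]
        if np.all(np.diff(window) > 0) and (window[-1] - window[0]) > rise_fraction * rng_v:
            j = i
            while j > 0 and v[j - 1] < v[j]:
                j -= 1
            if not onsets or j > onsets[-1]:
                onsets.append(j)
    return onsets


def extract_beat(
    trace: CalibratedTrace, run_length: int = 3, rise_fraction: float = 0.1
) -> CalibratedTrace:
    """Isolate the first full cardiac cycle of a calibrated trace.

    The sub-trace runs from the first detected systolic onset up to (not
    including) the next onset. A trace already spanning exactly one beat is
    returned unchanged. A flat trace, where no upstroke can be detected,
    raises :class:`SignalQualityError` — the analogue of excluding images
    with inadequate signal extraction.
    """
    v = trace.velocities
    onsets = _onset_candidates(v, run_length, rise_fraction)
    if not onsets:
        raise SignalQualityError("no systolic upstroke detected (flat or noisy trace)")
    start = onsets[0]
    # the next onset must lie beyond the first beat's peak
    peak = start + int(np.argmax(v[start:]))
    nxt = [o for o in onsets[1:] if o > peak]
    end = nxt[0] if nxt else len(v)
    if start == 0 and end == len(v):
        return trace
    return CalibratedTrace(times=trace.times[start:end], velocities=v[start:end])


def resample_to_grid(
    trace: CalibratedTrace, *, label: str, patient_id: str, site: str
) -> ResampledSignal:
    """Linearly interpolate a beat onto the common 1000-point grid.

    The trace is first shifted so its first sample sits at 0.1 s. Grid points
    beyond the last traced time hold the final traced velocity (a single beat
    cannot fill the 2.4 s window; clamping neither invents data nor distorts
    the beat morphology).
    """
    if len(trace) < 2:
        raise DataError("resampling needs at least 2 samples")
    t = trace.times - trace.times[0] + GRID_START
    v = np.interp(TIME_GRID, t, trace.velocities)
    return ResampledSignal(velocities=v, label=label, patient_id=patient_id, site=site)


def read_trace_csv(path: str | Path) -> PixelTrace:
    """Read a traced-point CSV with columns ``x_px,y_px``."""
    df = pd.read_csv(path, comment="#")
    missing = {"x_px", "y_px"} - set(df.columns)
    if missing:
        raise DataError(f"trace file {path} missing columns {sorted(missing)}")
    return PixelTrace(points=df[["x_px", "y_px"]].to_numpy(dtype=float))


def read_calibration_csv(path: str | Path) -> AxisCalibration:
    """Read a sidecar calibration CSV with columns ``axis,pixel,value``.

    Exactly two rows per axis are required, mirroring the two reference
    points a digitizer user clicks per axis.
    """
    df = pd.read_csv(path, comment="#")
    missing = {"axis", "pixel", "value"} - set(df.columns)
    if missing:
        raise DataError(f"calibration file {path} missing columns {sorted(missing)}")
    refs: dict[str, list[tuple[float, float]]] = {"x": [], "y": []}
    for _, row in df.iterrows():
        ax = str(row["axis"]).strip().lower()
        if ax not in refs:
            raise DataError(f"unknown axis {ax!r} in calibration file {path}")
        refs[ax].append((float(row["pixel"]), float(row["value"])))
    for ax, pairs in refs.items():
        if len(pairs) != 2:
            raise DataError(f"need exactly 2 {ax}-axis reference rows, got {len(pairs)}")
    return AxisCalibration(x_refs=tuple(refs["x"]), y_refs=tuple(refs["y"]))
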