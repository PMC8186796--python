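"""Bright-field fall tracking: detect, track and fit the settling spheroid.

Image convention: origin top-left, x right, y down, so a sinking spheroid has
increasing y.  Pixel centers sit at integer coordinates and centroids are
sub-pixel.  The terminal velocity is an ordinary least-squares slope of the
vertical position over the steady (terminal) part of the track.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from . import physics
from .errors import FitError, TrackingError, ValidationError
from .physics import (BiophysicalMeasurement, ChannelGeometry, FluidMedium,
                      OPERATIVE_DIAMETER_RANGE_UM, REYNOLDS_THRESHOLD)

_MIN_AREA_PX = 20


@dataclass
class FrameSequence:
    """Ordered grayscale frames of one fall repetition.

    frames: (n, h, w) float array; timestamps: seconds, strictly increasing;
    pixel_size: um/pixel; polarity: 'dark' when the spheroid is darker than
    the background (bright-field default), else 'bright'.
    """

    frames: np.ndarray
    timestamps: np.ndarray
    pixel_size: float
    polarity: str = "dark"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValidationError("frames must be a (n, h, w) array")
        if len(self.frames) < 5:
            raise ValidationError("a frame sequence needs at least 5 frames")
        if len(self.timestamps) != len(self.frames):
            raise ValidationError("one timestamp per frame required")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValidationError("timestamps must be strictly increasing")
        if self.pixel_size <= 0:
            raise ValidationError("pixel_size must be > 0")
        if self.polarity not in ("dark", "bright"):
            raise ValidationError("polarity must be 'dark' or 'bright'")


@dataclass
class Detection:
    centroid: tuple[float, float]  # (x, y) pixels
    radius: float                  # equivalent-circle radius, pixels
    valid: bool


@dataclass
class SpheroidTrack:
    """Per-frame centroids (x, y), equivalent-circle radii and validity."""

    positions: np.ndarray   # (n, 2) float, (x, y)
    radii: np.ndarray       # (n,) float, pixels
    valid: np.ndarray       # (n,) bool
    interpolated: np.ndarray = field(default=None)  # (n,) bool

    def __post_init__(self) -> None:
        if self.interpolated is None:
            self.interpolated = np.zeros(len(self.valid), dtype=bool)


@dataclass
class VelocityFit:
    v: float        # m/s, positive = sinking
    se: float       # m/s
    r2: float
    window: tuple[int, int]  # [start, stop) indices into the track


def _candidates(frame: np.ndarray, polarity: str) -> list[Detection]:
    """All plausible spheroid components in one frame (may be empty)."""
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or not np.all(np.isfinite(frame)):
        raise ValidationError("frame must be a finite 2D array")
    if np.ptp(frame) == 0:
        return []
    thr = threshold_otsu(frame)
    fg = frame < thr if polarity == "dark" else frame > thr
    labels = cc_label(fg, connectivity=2)
    out: list[Detection] = []
    h, w = frame.shape
    # contrast weights give a coverage-weighted, sub-pixel centroid
    contrast = (thr - frame) if polarity == "dark" else (frame - thr)
    for lab in range(1, labels.max() + 1):
        mask = labels == lab
        area = int(mask.sum())
        ys, xs = np.nonzero(mask)
        touches = ys.min() == 0 or xs.min() == 0 or ys.max() == h - 1 or xs.max() == w - 1
        weights = np.clip(contrast[mask], 0.0, None)
        if weights.sum() <= 0:
            weights = np.ones(area)
        cx = float(np.average(xs, weights=weights))
        cy = float(np.average(ys, weights=weights))
        radius = math.sqrt(area / math.pi)
        out.append(Detection((cx, cy), radius, area >= _MIN_AREA_PX and not touches))
    return out


def detect_spheroid(frame: np.ndarray, polarity: str = "dark",
                    pixel_size: float | None = None) -> Detection:
    """Segment the largest component and return its sub-pixel centroid and radius.

    Otsu global threshold honoring polarity; centroid is the contrast-weighted
    center of the component; radius is the equivalent-circle radius
    ``sqrt(area/pi)``.  Invalid (never an exception) when the frame is blank,
    the component touches the border, or its area is below 20 px.
    """
    cands = _candidates(frame, polarity)
    if not cands:
        return Detection((math.nan, math.nan), math.nan, False)
    return max(cands, key=lambda d: d.radius)


def track(seq: FrameSequence) -> SpheroidTrack:
    """Follow one spheroid across the sequence with nearest-neighbor continuity.

    Gap frames (up to 2 consecutive misses) are filled by linear interpolation
    and flagged; fewer than 3 valid detections raises :class:`TrackingError`.
    """
    n = len(seq.frames)
    per_frame = [[d for d in _candidates(f, seq.polarity) if d.valid]
                 for f in seq.frames]

    positions = np.full((n, 2), np.nan)
    radii = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)

    prev: tuple[float, float] | None = None
    for i, cands in enumerate(per_frame):
        if not cands:
            continue
        if prev is None:
            best = max(cands, key=lambda d: d.radius)
        else:
            best = min(cands, key=lambda d: math.dist(d.centroid, prev))
        positions[i] = best.centroid
        radii[i] = best.radius
        valid[i] = True
        prev = best.centroid

    idx = np.nonzero(valid)[0]
    if len(idx) < 3:
        raise TrackingError("fewer than 3 valid detections in sequence")

    # gate outliers: jumps beyond 3x the median frame-to-frame displacement
    steps = np.linalg.norm(np.diff(positions[idx], axis=0), axis=1)
    med = float(np.median(steps))
    if med > 0:
        gate = 3.0 * med
        keep = np.ones(len(idx), dtype=bool)
        last = positions[idx[0]]
        for j in range(1, len(idx)):
            if np.linalg.norm(positions[idx[j]] - last) > gate * (idx[j] - idx[j - 1]):
                keep[j] = False
            else:
                last = positions[idx[j]]
        valid[idx[~keep]] = False
        idx = idx[keep]
        if len(idx) < 3:
            raise TrackingError("fewer than 3 valid detections after gating")

    # linear interpolation over gaps of at most 2 frames
    interpolated = np.zeros(n, dtype=bool)
    for a, b in zip(idx[:-1], idx[1:]):
        gap = b - a - 1
        if 0 < gap <= 2:
            for j in range(a + 1, b):
                frac = (j - a) / (b - a)
                positions[j] = (1 - frac) * positions[a] + frac * positions[b]
                radii[j] = (1 - frac) * radii[a] + frac * radii[b]
                valid[j] = True
                interpolated[j] = True

    return SpheroidTrack(positions, radii, valid, interpolated)


def _local_slopes(y: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Central 3-point slopes at interior samples."""
    return (y[2:] - y[:-2]) / (t[2:] - t[:-2])


def fit_velocity(track_: SpheroidTrack, timestamps: np.ndarray,
                 pixel_size: float, slope_tol: float = 0.05) -> VelocityFit:
    """OLS terminal velocity over the steady suffix of the track (m/s).

    The steady window is the longest suffix whose 3-point local slopes all lie
    within ``slope_tol`` (relative) of the suffix median slope.  Raises
    :class:`FitError` ('no_terminal_plateau') when no suffix of >= 3 frames
    qualifies (e.g. neutrally buoyant or still-accelerating spheroids).
    """
    timestamps = np.asarray(timestamps, dtype=float)
    mask = np.asarray(track_.valid, dtype=bool)
    if mask.sum() < 3:
        raise FitError("fewer than 3 valid frames")
    frame_idx = np.nonzero(mask)[0]
    t = timestamps[mask]
    y = track_.positions[mask, 1] * pixel_size * 1e-6  # px -> m, down positive

    slopes = _local_slopes(y, t)
    n = len(t)
    # measurement noise floor for the slope criterion: a robust sigma from
    # consecutive slope differences (insensitive to smooth trends, zero for
    # noiseless tracks, so the relative rule is untouched in the clean limit)
    if len(slopes) >= 3:
        ds = np.diff(slopes)
        sigma_s = 1.4826 * float(np.median(np.abs(ds - np.median(ds)))) / math.sqrt(2)
    else:
        sigma_s = 0.0
    start = None
    # a 3-frame suffix has a single local slope that trivially matches its own
    # median, so (except for 3-frame tracks) demand at least two slopes
    last_start = n - 3 if n == 3 else n - 4
    for k in range(0, last_start + 1):
        s = slopes[k:]  # local slopes at interior samples of the suffix [k, n)
        med = float(np.median(s))
        tol = max(slope_tol * abs(med), 4.0 * sigma_s)
        if np.all(np.abs(s - med) <= tol):
            start = k
            break
    if start is None or n - start < 3:
        raise FitError("no_terminal_plateau")

    tw, yw = t[start:], y[start:]
    res = sps.linregress(tw, yw)
    v = float(res.slope)
    se = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    ss_tot = float(np.sum((yw - yw.mean()) ** 2))
    if ss_tot == 0:
        r2 = 1.0
    else:
        pred = res.intercept + res.slope * tw
        r2 = 1.0 - float(np.sum((yw - pred) ** 2)) / ss_tot
    r2 = min(max(r2, 0.0), 1.0)
    return VelocityFit(v=v, se=se, r2=r2,
                       window=(int(frame_idx[start]), int(frame_idx[-1]) + 1))


def measure(seq: FrameSequence, fluid: FluidMedium, chan: ChannelGeometry,
            wall_correction: bool = False,
            reynolds_threshold: float = REYNOLDS_THRESHOLD,
            ) -> BiophysicalMeasurement:
    """Full per-video measurement: track -> fit velocity -> invert density.

    The radius is the median equivalent-circle radius over valid, directly
    detected frames; QC flags record the device operative range (50-500 um
    diameter), the Stokes-regime Reynolds guard, and poor plateau fits.
    """
    trk = track(seq)
    fit = fit_velocity(trk, seq.timestamps, seq.pixel_size)
    direct = trk.valid & ~trk.interpolated
    r_px = float(np.median(trk.radii[direct]))
    r_m = r_px * seq.pixel_size * 1e-6

    rho_s = physics.invert_density(fit.v, r_m, fluid, chan, wall_correction)
    mass_ug, weight_nn = physics.mass_and_weight(rho_s, r_m, fluid, chan.gravity)
    reynolds = physics.reynolds_number(fit.v, r_m, fluid)

    flags: list[str] = []
    d_um = 2.0 * r_m * 1e6
    lo, hi = OPERATIVE_DIAMETER_RANGE_UM
    if not (lo <= d_um <= hi):
        flags.append("outside_operative_range")
    if reynolds > reynolds_threshold:
        flags.append("stokes_regime_violated")
    if fit.r2 < 0.99:
        flags.append("poor_plateau_fit")

    return BiophysicalMeasurement(
        terminal_velocity=fit.v, velocity_se=fit.se, diameter=d_um,
        mass_density=rho_s / 1000.0, mass=mass_ug, buoyant_weight=weight_nn,
        reynolds=reynolds, n_repetitions=1, qc_flags=flags)


def aggregate_repetitions(measurements: list[BiophysicalMeasurement],
                          ) -> BiophysicalMeasurement:
    """Average repeated measurements of the same spheroid.

    Means of density, mass, weight, diameter and velocity; the velocity SE is
    pooled as the SE of the mean of independent estimates; QC flags are the
    union across repetitions.
    """
    if not measurements:
        raise ValidationError("need at least one measurement to aggregate")
    n = len(measurements)
    se = math.sqrt(sum(m.velocity_se**2 for m in measurements)) / n
    flags = sorted({f for m in measurements for f in m.qc_flags})
    return BiophysicalMeasurement(
        terminal_velocity=sum(m.terminal_velocity for m in measurements) / n,
        velocity_se=se,
        diameter=sum(m.diameter for m in measurements) / n,
        mass_density=sum(m.mass_density for m in measurements) / n,
        mass=sum(m.mass for m in measurements) / n,
        buoyant_weight=sum(m.buoyant_weight for m in measurements) / n,
        reynolds=sum(m.reynolds for m in measurements) / n,
        n_repetitions=sum(m.n_repetitions for m in measurements),
        qc_flags=flags)
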