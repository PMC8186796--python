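"""Seeded ground-truth generators for every pipeline input.

Falling-spheroid bright-field videos (trajectory from the transient settling
ODE, anti-aliased disk rendering), cleared-spheroid nuclear stacks with a
matching bright-field projection, measurement cohorts, and fluorescence
standard-curve tables.  Every generator is a pure function of
(scenario, seed): identical calls produce identical outputs, and the returned
ground truth is sufficient to score every downstream stage.

The noise models are deliberately simple and documented rather than claimed to
match any real instrument: additive Gaussian pixel noise plus Gaussian
centroid jitter on videos; Poisson shot noise (peak SNR defined as peak
amplitude over shot noise at the peak) plus a small Gaussian read-noise floor
on fluorescence stacks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from . import physics
from .errors import GeneratorError, ValidationError
from .nuclei import ImageStack3D
from .physics import ChannelGeometry, FluidMedium, SpheroidPhysics
from .stats import CONDITIONS, PARAMETERS, STATES
from .tracking import FrameSequence


# ---------------------------------------------------------------- fall videos

@dataclass(frozen=True)
class FallScenario:
    """Ground-truth settling experiment behind one synthetic video."""

    true_density: float = 1050.0          # kg/m^3
    true_radius_um: float = 100.0
    fluid: FluidMedium = field(default_factory=physics.dpbs_default)
    channel: ChannelGeometry = field(default_factory=lambda: ChannelGeometry(5e-4))
    fps: float = 50.0
    n_frames: int = 50
    pixel_size: float = 2.0               # um / pixel
    noise_sigma_px: float = 0.0           # centroid jitter, pixels
    pixel_noise: float = 0.0              # additive intensity noise (image units)
    contrast: float = 0.6                 # disk darkening depth
    background: float = 0.9
    v0: float = 0.0                       # initial velocity, m/s
    height_px: int | None = None          # None = auto-size to contain the fall
    wall_correction: bool = False

    def __post_init__(self) -> None:
        if min(self.true_density, self.true_radius_um, self.fps,
               self.pixel_size, self.contrast) <= 0 or self.n_frames < 5:
            raise ValidationError("invalid fall scenario")


@dataclass
class FallTruth:
    density: float                 # kg/m^3
    radius_um: float
    terminal_velocity: float       # m/s
    positions_px: np.ndarray       # (n, 2) true (x, y), unjittered
    timestamps: np.ndarray


def _render_disk(shape: tuple[int, int], cx: float, cy: float, r: float,
                 background: float, contrast: float) -> np.ndarray:
    """Anti-aliased dark disk: boundary pixels get area-weighted coverage."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dist = np.hypot(xx - cx, yy - cy)
    coverage = np.clip(r + 0.5 - dist, 0.0, 1.0)
    return background - contrast * coverage


def gen_fall_video(scenario: FallScenario, seed: int = 0,
                   ) -> tuple[FrameSequence, FallTruth]:
    """Render a settling spheroid video with known density/radius/velocity."""
    rng = np.random.default_rng(seed)
    sph = SpheroidPhysics(radius=scenario.true_radius_um * 1e-6,
                          mass_density=scenario.true_density)
    v_t = physics.terminal_velocity(sph, scenario.fluid, scenario.channel,
                                    scenario.wall_correction)
    r_px = scenario.true_radius_um / scenario.pixel_size
    dt = 1.0 / scenario.fps
    duration = (scenario.n_frames - 1) * dt
    t, y_m, _v = physics.settle_ode(
        sph, scenario.fluid, scenario.channel, v0=scenario.v0,
        duration=duration, dt=dt, wall_correction=scenario.wall_correction)
    t, y_m = t[:scenario.n_frames], y_m[:scenario.n_frames]

    y0_px = r_px + 5.0
    y_px = y0_px + y_m / (scenario.pixel_size * 1e-6)
    width = 2 * int(math.ceil(r_px)) + 21
    cx = (width - 1) / 2.0

    if scenario.height_px is None:
        height = int(math.ceil(float(y_px.max()) + r_px + 6.0))
    else:
        height = scenario.height_px
        inside = y_px + r_px + 1.0 < height
        if inside.sum() < 5:
            raise GeneratorError("frame_too_short")
        t, y_px = t[inside], y_px[inside]

    frames = np.empty((len(t), height, width))
    positions = np.column_stack([np.full(len(t), cx), y_px])
    for i, y in enumerate(y_px):
        jx, jy = (rng.normal(0.0, scenario.noise_sigma_px, size=2)
                  if scenario.noise_sigma_px > 0 else (0.0, 0.0))
        frame = _render_disk((height, width), cx + jx, y + jy, r_px,
                             scenario.background, scenario.contrast)
        if scenario.pixel_noise > 0:
            frame = frame + rng.normal(0.0, scenario.pixel_noise, frame.shape)
        frames[i] = frame

    seq = FrameSequence(frames=frames, timestamps=t,
                        pixel_size=scenario.pixel_size, polarity="dark")
    truth = FallTruth(density=scenario.true_density,
                      radius_um=scenario.true_radius_um,
                      terminal_velocity=v_t, positions_px=positions,
                      timestamps=t)
    return seq, truth


def fall_scenario_for(density: float, diameter_um: float, n_frames: int = 30,
                      fall_px: float = 150.0, **kwargs) -> FallScenario:
    """Acquisition-matched scenario for a given true (density, diameter).

    Picks a pixel size that keeps the spheroid ~50 px across and a frame rate
    at which the fall spans about ``fall_px`` pixels over ``n_frames`` frames
    (what an operator tuning the camera to the sample would do).
    """
    radius_um = diameter_um / 2.0
    pixel_size = max(1.0, diameter_um / 50.0)
    base = FallScenario(true_density=density, true_radius_um=radius_um,
                        pixel_size=pixel_size, n_frames=n_frames, **kwargs)
    sph = SpheroidPhysics(radius=radius_um * 1e-6, mass_density=density)
    v_t = abs(physics.terminal_velocity(sph, base.fluid, base.channel,
                                        base.wall_correction))
    if v_t > 0:
        fps = v_t * n_frames / (fall_px * pixel_size * 1e-6)
        fps = min(500.0, max(1.0, fps))
    else:
        fps = base.fps
    return replace(base, fps=fps)


# --------------------------------------------------------------- nuclei stacks

@dataclass(frozen=True)
class StackScenario:
    """Ground-truth cleared-spheroid stack: nuclei in a sphere, blurred, noisy."""

    spheroid_radius_um: float = 20.0
    n_nuclei: int = 50
    nucleus_radius_um: tuple[float, float] = (2.0, 0.2)   # (mean, sd)
    min_separation_um: float = 5.0
    voxel_size: tuple[float, float, float] = (1.0, 0.5, 0.5)
    psf_sigma_um: tuple[float, float, float] = (0.75, 0.3, 0.3)
    peak_snr: float = 20.0
    background_level: float = 0.05
    interior_level: float = 0.12          # haze above background inside the sphere
    margin_um: float = 4.0

    def __post_init__(self) -> None:
        if self.peak_snr <= 0 or self.spheroid_radius_um <= 0:
            raise ValidationError("invalid stack scenario")
        if self.n_nuclei < 0:
            raise ValidationError("n_nuclei must be >= 0")


@dataclass
class StackTruth:
    centers_um: np.ndarray      # (n, 3) physical (z, y, x) from stack origin
    centers_vox: np.ndarray     # (n, 3) integer voxel coordinates
    count: int
    radius_um: float


def _sample_centers(rng: np.random.Generator, n: int, radius: float,
                    min_sep: float, max_attempts: int) -> np.ndarray:
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < n:
        if attempts >= max_attempts:
            raise GeneratorError("density_too_high")
        attempts += 1
        p = rng.uniform(-radius, radius, size=3)
        if np.linalg.norm(p) > radius:
            continue
        if centers and np.min(np.linalg.norm(np.array(centers) - p, axis=1)) < min_sep:
            continue
        centers.append(p)
    return np.array(centers) if centers else np.empty((0, 3))


def gen_nuclei_stack(scenario: StackScenario, seed: int = 0,
                     ) -> tuple[ImageStack3D, np.ndarray, StackTruth]:
    """Generate (nuclear stack, bright-field 2D image, ground truth)."""
    rng = np.random.default_rng(seed)
    vz, vy, vx = scenario.voxel_size
    extent = scenario.spheroid_radius_um + scenario.margin_um
    shape = tuple(max(3, int(math.ceil(2 * extent / v)) + 1)
                  for v in scenario.voxel_size)
    origin = np.array([extent, extent, extent])  # sphere center, um

    r_place = scenario.spheroid_radius_um - scenario.nucleus_radius_um[0]
    centers = _sample_centers(rng, scenario.n_nuclei, r_place,
                              scenario.min_separation_um,
                              max_attempts=500 * max(scenario.n_nuclei, 1))
    centers_um = centers + origin

    clean = np.zeros(shape)
    vox = np.array(scenario.voxel_size)
    for c_um in centers_um:
        r_nuc = max(0.5, rng.normal(*scenario.nucleus_radius_um))
        sigma_um = r_nuc / 2.0
        sig_vox = sigma_um / vox
        c_vox = c_um / vox
        half = np.ceil(4 * sig_vox).astype(int)
        lo = np.maximum(np.floor(c_vox).astype(int) - half, 0)
        hi = np.minimum(np.floor(c_vox).astype(int) + half + 1, shape)
        zz, yy, xx = np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)],
                                 indexing="ij")
        d2 = (((zz - c_vox[0]) / sig_vox[0]) ** 2
              + ((yy - c_vox[1]) / sig_vox[1]) ** 2
              + ((xx - c_vox[2]) / sig_vox[2]) ** 2)
        clean[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += np.exp(-0.5 * d2)

    psf_vox = [s / v for s, v in zip(scenario.psf_sigma_um, scenario.voxel_size)]
    clean = ndi.gaussian_filter(clean, sigma=psf_vox)
    peak = float(clean.max()) if clean.max() > 0 else 1.0
    clean = clean / peak + scenario.background_level

    # faint interior haze: out-of-focus light and residual cytoplasmic
    # staining scattered from the labeled content, so an unstained spheroid
    # (no nuclei) renders as background only
    if scenario.interior_level > 0 and scenario.n_nuclei > 0:
        zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
        dist = np.sqrt(((zz * vz - origin[0]) ** 2)
                       + ((yy * vy - origin[1]) ** 2)
                       + ((xx * vx - origin[2]) ** 2))
        haze = np.clip((scenario.spheroid_radius_um - dist) / vx + 0.5, 0.0, 1.0)
        clean = clean + scenario.interior_level * haze

    # peak SNR = peak amplitude (1.0) / Poisson shot noise at the peak
    gain = scenario.peak_snr**2
    noisy = rng.poisson(np.clip(clean, 0, None) * gain) / gain
    noisy = noisy + rng.normal(0.0, 0.25 / scenario.peak_snr, shape)
    nuclear = ImageStack3D(np.clip(noisy, 0.0, None),
                           scenario.voxel_size, channel="nuclear")

    # bright-field: absorbing anti-aliased disk over a bright background
    ny, nx = shape[1], shape[2]
    yy, xx = np.mgrid[0:ny, 0:nx]
    dist = np.hypot((yy - origin[1] / vy) * vy, (xx - origin[2] / vx) * vx)
    coverage = np.clip((scenario.spheroid_radius_um - dist) / vx + 0.5, 0.0, 1.0)
    bf = 0.9 * np.power(10.0, -0.5 * coverage)
    bf = bf + rng.normal(0.0, 0.003, bf.shape)

    centers_vox = (np.round(centers_um / vox).astype(int)
                   if len(centers_um) else np.empty((0, 3), dtype=int))
    truth = StackTruth(centers_um=centers_um, centers_vox=centers_vox,
                       count=len(centers_um),
                       radius_um=scenario.spheroid_radius_um)
    return nuclear, bf, truth


# -------------------------------------------------------------------- cohorts

CellKey = tuple[str, str, str]  # (condition, state, parameter)


@dataclass(frozen=True)
class CohortScenario:
    """Per-cell Gaussian measurement model with optional injected outliers.

    ``cell_params`` maps (condition, state, parameter) to (mean, sd);
    ``outliers`` maps cells to (count, offset in SDs) injected on top.
    """

    cell_params: dict
    n_per_cell: int = 15
    outliers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_per_cell < 4:
            raise ValidationError("n_per_cell must be >= 4")
        for key, (mean, sd) in self.cell_params.items():
            if sd <= 0:
                raise ValidationError(f"cell {key}: sd must be > 0")


def _base_cells(density, weight, diameter) -> dict:
    """Expand per-condition (density, weight, diameter) means into all cells."""
    sds = {"density": 0.004, "weight": 0.5, "diameter": 12.0}
    out = {}
    for cond, vals in zip(CONDITIONS, zip(density, weight, diameter)):
        for par, mean in zip(PARAMETERS, vals):
            for state in STATES:
                out[(cond, state, par)] = (mean, sds[par])
    return out


def treatment_scenario(n_per_cell: int = 15) -> CohortScenario:
    """Dose response in the treated direction: density up, weight and
    diameter down with dose; identical in live and fixed states."""
    cells = _base_cells(density=(1.046, 1.056, 1.060),
                        weight=(4.5, 3.6, 3.2),
                        diameter=(200.0, 180.0, 170.0))
    return CohortScenario(cell_params=cells, n_per_cell=n_per_cell)


def null_scenario(n_per_cell: int = 15) -> CohortScenario:
    """All conditions share the control distribution (no treatment effect)."""
    cells = _base_cells(density=(1.046,) * 3, weight=(4.5,) * 3,
                        diameter=(200.0,) * 3)
    return CohortScenario(cell_params=cells, n_per_cell=n_per_cell)


def with_outliers(scenario: CohortScenario, cell: CellKey, count: int,
                  offset_sd: float) -> CohortScenario:
    outliers = dict(scenario.outliers)
    outliers[cell] = (count, offset_sd)
    return replace(scenario, outliers=outliers)


def gen_cohort(scenario: CohortScenario, seed: int = 0,
               ) -> tuple[pd.DataFrame, dict]:
    """Draw a long-format cohort table; ground truth records cell means and
    the exact injected outlier values per cell."""
    rng = np.random.default_rng(seed)
    rows = []
    injected: dict[CellKey, list[float]] = {}
    sid = 0
    for key in sorted(scenario.cell_params):
        cond, state, par = key
        mean, sd = scenario.cell_params[key]
        values = rng.normal(mean, sd, size=scenario.n_per_cell)
        if key in scenario.outliers:
            count, offset = scenario.outliers[key]
            signs = np.resize([1.0, -1.0], count)
            out_vals = mean + signs * offset * sd
            values = np.concatenate([values, out_vals])
            injected[key] = out_vals.tolist()
        for v in values:
            rows.append({"spheroid_id": f"S{sid:05d}", "condition": cond,
                         "state": state, "parameter": par, "value": float(v)})
            sid += 1
    table = pd.DataFrame(rows)
    truth = {"cell_params": dict(scenario.cell_params), "outliers": injected}
    return table, truth


# ------------------------------------------------------------- standard curve

def gen_standard_curve(slope: float, intercept: float, noise_sd: float = 0.0,
                       n: int = 8, seed: int = 0) -> pd.DataFrame:
    """Linear fluorescence-vs-concentration standards with Gaussian noise."""
    if n < 3:
        raise ValidationError("need at least 3 standards")
    rng = np.random.default_rng(seed)
    conc = np.linspace(0.0, 10.0, n)
    fluor = slope * conc + intercept
    if noise_sd > 0:
        fluor = fluor + rng.normal(0.0, noise_sd, n)
    return pd.DataFrame({"concentration": conc, "fluorescence": fluor})
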