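"""Forward and inverse Stokes sedimentation model for a spheroid in a channel.

A single spheroid released in a quiescent vertical fluid column reaches, after a
short exponential transient, a terminal velocity at which its buoyant weight
balances viscous drag.  In the creeping-flow (Stokes) regime,

    v_t = (2/9) * (rho_s - rho_f) * g * r**2 / mu,

optionally multiplied by an on-axis cylindrical wall-correction factor
``K(r/R) <= 1`` when the channel radius ``R`` is comparable to the spheroid
radius ``r``.  Measuring ``v_t`` and ``r`` therefore determines the spheroid
mass density ``rho_s``, its mass and its buoyant weight.  All quantities in
this module are SI unless a name says otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .errors import GeometryError, ValidationError

#: Standard gravity (m/s^2).
G_STANDARD = 9.80665

#: Device operative range for spheroid diameter, in micrometres.
OPERATIVE_DIAMETER_RANGE_UM = (50.0, 500.0)

#: Reynolds number above which Stokes drag degrades noticeably (~5% at 0.5).
REYNOLDS_THRESHOLD = 0.5


def _require_finite(**named: float) -> None:
    for name, value in named.items():
        if not math.isfinite(value):
            raise ValidationError(f"{name} must be finite, got {value!r}")


def _require_positive(**named: float) -> None:
    _require_finite(**named)
    for name, value in named.items():
        if value <= 0:
            raise ValidationError(f"{name} must be > 0, got {value!r}")


@dataclass(frozen=True)
class FluidMedium:
    """Suspending fluid: density (kg/m^3), dynamic viscosity (Pa*s).

    ``temperature`` (deg C) is an annotation; :func:`water_viscosity` can be
    used to derive a viscosity from it for water-like buffers such as DPBS.
    """

    density: float
    viscosity: float
    temperature: float | None = None

    def __post_init__(self) -> None:
        _require_positive(density=self.density, viscosity=self.viscosity)


def dpbs_default(temperature: float = 25.0) -> FluidMedium:
    """Water-like DPBS model: 1005 kg/m^3 with water viscosity at ``temperature``."""
    return FluidMedium(density=1005.0, viscosity=water_viscosity(temperature),
                       temperature=temperature)


@dataclass(frozen=True)
class ChannelGeometry:
    """Vertical flow channel: inner radius (m) and local gravity (m/s^2)."""

    radius: float
    gravity: float = G_STANDARD

    def __post_init__(self) -> None:
        _require_positive(radius=self.radius, gravity=self.gravity)


@dataclass(frozen=True)
class SpheroidPhysics:
    """A rigid-sphere idealization of a spheroid: radius (m), density (kg/m^3)."""

    radius: float
    mass_density: float

    def __post_init__(self) -> None:
        _require_positive(radius=self.radius, mass_density=self.mass_density)

    @property
    def volume(self) -> float:
        return (4.0 / 3.0) * math.pi * self.radius**3

    def qc_flags(self) -> list[str]:
        lo, hi = OPERATIVE_DIAMETER_RANGE_UM
        d_um = 2.0 * self.radius * 1e6
        if not (lo <= d_um <= hi):
            return ["outside_operative_range"]
        return []


@dataclass
class BiophysicalMeasurement:
    """Per-spheroid measurement record in reporting units.

    terminal_velocity m/s (positive = sinking), velocity_se m/s, diameter um,
    mass_density g/cm^3, mass ug, buoyant_weight nN, reynolds dimensionless.
    """

    terminal_velocity: float
    velocity_se: float
    diameter: float
    mass_density: float
    mass: float
    buoyant_weight: float
    reynolds: float
    n_repetitions: int = 1
    qc_flags: list[str] = field(default_factory=list)


def wall_correction_factor(lam: float) -> float:
    """On-axis cylindrical-tube drag correction ``K(lambda)``, ``lambda = r/R``.

    ``K(0) = 1`` and K decreases strictly as the sphere fills the tube; the
    terminal velocity in the tube is ``K`` times the unbounded value.
    """
    _require_finite(lam=lam)
    if lam < 0 or lam >= 1:
        raise GeometryError(f"r/R ratio must be in [0, 1), got {lam}")
    k = 1.0 - 2.104 * lam + 2.089 * lam**3 - 0.948 * lam**5
    return min(max(k, 1e-12), 1.0)


def terminal_velocity(sph: SpheroidPhysics, fluid: FluidMedium,
                      chan: ChannelGeometry, wall_correction: bool = False) -> float:
    """Stokes terminal velocity (m/s, signed; positive = sinking)."""
    if sph.radius >= chan.radius:
        raise GeometryError(
            f"spheroid radius {sph.radius} m must be smaller than channel "
            f"radius {chan.radius} m")
    v = (2.0 / 9.0) * (sph.mass_density - fluid.density) * chan.gravity \
        * sph.radius**2 / fluid.viscosity
    if wall_correction:
        v *= wall_correction_factor(sph.radius / chan.radius)
    return v


def invert_density(v: float, r: float, fluid: FluidMedium,
                   chan: ChannelGeometry, wall_correction: bool = False) -> float:
    """Spheroid mass density (kg/m^3) from terminal velocity and radius.

    Exact left-inverse of :func:`terminal_velocity` for matching flags.
    """
    _require_finite(v=v)
    _require_positive(r=r)
    k = 1.0
    if wall_correction:
        if r >= chan.radius:
            raise GeometryError("spheroid radius must be smaller than channel radius")
        k = wall_correction_factor(r / chan.radius)
    return fluid.density + 9.0 * fluid.viscosity * v / (2.0 * chan.gravity * r**2 * k)


def mass_and_weight(rho_s: float, r: float, fluid: FluidMedium,
                    g: float = G_STANDARD) -> tuple[float, float]:
    """(mass in ug, buoyant weight in nN) of a sphere of density ``rho_s``."""
    _require_positive(rho_s=rho_s, r=r, g=g)
    volume = (4.0 / 3.0) * math.pi * r**3
    mass_ug = rho_s * volume * 1e9          # kg -> ug
    weight_nn = (rho_s - fluid.density) * volume * g * 1e9  # N -> nN
    return mass_ug, weight_nn


def reynolds_number(v: float, r: float, fluid: FluidMedium) -> float:
    """Particle Reynolds number ``rho_f |v| d / mu`` with ``d = 2r``."""
    _require_finite(v=v, r=r)
    return fluid.density * abs(v) * (2.0 * r) / fluid.viscosity


def relaxation_time(sph: SpheroidPhysics, fluid: FluidMedium,
                    wall_factor: float = 1.0) -> float:
    """Exponential velocity relaxation time ``m / (6 pi mu r / K)`` in s."""
    drag = 6.0 * math.pi * fluid.viscosity * sph.radius / wall_factor
    return sph.mass_density * sph.volume / drag


def settle_ode(sph: SpheroidPhysics, fluid: FluidMedium, chan: ChannelGeometry,
               v0: float = 0.0, duration: float = 1.0, dt: float = 1e-3,
               wall_correction: bool = False, y0: float = 0.0,
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate the transient settling ODE; returns ``(t, y, v)`` arrays.

    Solves ``m dv/dt = (rho_s - rho_f) V g - 6 pi mu r v / K`` with
    ``m = rho_s V``; the position ``y`` (positive = down) is the integral of
    ``v``.  Serves as the transient model behind the synthetic video generator
    and as an independent numerical cross-check of the closed-form terminal
    velocity.
    """
    _require_positive(duration=duration, dt=dt)
    _require_finite(v0=v0, y0=y0)
    k = wall_correction_factor(sph.radius / chan.radius) if wall_correction else 1.0
    volume = sph.volume
    m_eff = sph.mass_density * volume
    drive = (sph.mass_density - fluid.density) * volume * chan.gravity
    drag_coeff = 6.0 * math.pi * fluid.viscosity * sph.radius / k

    def rhs(_t: float, state: np.ndarray) -> list[float]:
        y, v = state
        return [v, (drive - drag_coeff * v) / m_eff]

    t_eval = np.arange(0.0, duration + 0.5 * dt, dt)
    sol = solve_ivp(rhs, (0.0, t_eval[-1]), [y0, v0], t_eval=t_eval,
                    method="RK45", rtol=1e-11, atol=1e-14)
    return sol.t, sol.y[0], sol.y[1]


def water_viscosity(temperature: float) -> float:
    """Dynamic viscosity of water (Pa*s) from a Vogel-type empirical curve.

    Valid for 0 < T < 60 deg C; within ~0.2% of 1.002e-3 Pa*s at 20 deg C and
    strictly decreasing in temperature.
    """
    _require_finite(temperature=temperature)
    if not (0.0 < temperature < 60.0):
        raise ValidationError(
            f"temperature must be in (0, 60) deg C, got {temperature}")
    t_kelvin = temperature + 273.15
    return 2.939e-5 * math.exp(507.88 / (t_kelvin - 149.3))
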