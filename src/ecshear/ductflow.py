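"""Steady laminar flow in a rectangular flow channel.

Models one channel of the 96-well fluidic plate as fully developed
pressure-driven (Poiseuille) flow in a rectangular duct of width ``w``
(6.0 mm), height ``h`` (0.5 mm) and length ``L`` (125.77 mm), and
converts between the quantities a flow experiment is designed around:
volumetric flow rate Q, mean velocity U, axial pressure gradient
G = -dp/dx, pressure drop over the channel, Reynolds number and — the
headline quantity for endothelial mechanobiology — the wall shear
stress on the channel floor where the cells sit.

Two independent solutions of the cross-sectional problem

    ∂²u/∂y² + ∂²u/∂z² = -G/μ,   u = 0 on the walls

are provided: the classical Fourier (odd-term cosh/sin) series and a
five-point finite-difference solve.  Each serves as an oracle for the
other; both reduce to plane-Poiseuille flow, u(z) = G z (h - z) / (2μ),
in the wide-channel limit w/h → ∞, for which the floor shear stress is
τ = 6 μ Q / (w h²).

Coordinates: x is the flow axis, y ∈ [0, w] spans the width, z ∈ [0, h]
spans the height with z = 0 the channel floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from . import units

__all__ = [
    "ChannelGeometry",
    "FluidProps",
    "FlowState",
    "VelocityField",
    "ShearProfile",
    "DEVICE_GEOMETRY",
    "WATERLIKE_MEDIUM",
    "LAMINAR_RE_THRESHOLD",
    "plate_wall_shear",
    "shear_to_flowrate",
    "mean_velocity",
    "duct_velocity_series",
    "duct_flowrate",
    "duct_shape_factor",
    "wall_shear_profile",
    "pressure_drop",
    "pressure_gradient_for_flowrate",
    "reynolds_number",
    "is_laminar",
    "solve_crosssection_fd",
    "operating_point_summary",
]


class InvalidGeometryError(ValueError):
    """Raised for non-positive channel dimensions or fluid properties."""


@dataclass(frozen=True)
class ChannelGeometry:
    """Rectangular duct dimensions in metres."""

    width: float
    height: float
    length: float

    def __post_init__(self) -> None:
        for name in ("width", "height", "length"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise InvalidGeometryError(f"{name} must be positive and finite, got {v}")

    @property
    def aspect(self) -> float:
        """Width-to-height aspect ratio w/h."""
        return self.width / self.height

    @property
    def cross_section_area(self) -> float:
        return self.width * self.height

    @property
    def hydraulic_diameter(self) -> float:
        """D_h = 2wh/(w+h)."""
        return 2.0 * self.width * self.height / (self.width + self.height)


@dataclass(frozen=True)
class FluidProps:
    """Working fluid: dynamic viscosity (Pa·s) and density (kg/m³)."""

    viscosity: float = 0.75e-3
    density: float = 1000.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.viscosity) or self.viscosity <= 0:
            raise InvalidGeometryError(f"viscosity must be positive, got {self.viscosity}")
        if not np.isfinite(self.density) or self.density <= 0:
            raise InvalidGeometryError(f"density must be positive, got {self.density}")


#: One flow channel of the device: 6.0 mm wide, 0.5 mm high, 125.77 mm long.
DEVICE_GEOMETRY = ChannelGeometry(width=6.0e-3, height=0.5e-3, length=125.77e-3)

#: Water-like culture medium.  The default viscosity (0.75 mPa·s) is the
#: value that makes 14 mL/min correspond exactly to a 0.7 Pa floor shear
#: in this geometry under the plane-Poiseuille formula; water at 37 °C
#: (≈0.69 mPa·s) is close to it.
WATERLIKE_MEDIUM = FluidProps(viscosity=0.75e-3, density=1000.0)

LAMINAR_RE_THRESHOLD = 2000.0


@dataclass(frozen=True)
class FlowState:
    """A consistent operating point (Q, G, U) for one duct."""

    flow_rate: float
    pressure_gradient: float
    mean_velocity: float


@dataclass
class VelocityField:
    """Axial velocity sampled on a rectangular cross-sectional grid."""

    y: np.ndarray  # (ny,) positions across the width, m
    z: np.ndarray  # (nz,) positions across the height, m
    u: np.ndarray  # (ny, nz) axial velocity, m/s

    def flow_rate(self) -> float:
        """Integrate u over the cross-section (trapezoid rule)."""
        return float(np.trapezoid(np.trapezoid(self.u, self.z, axis=1), self.y))


@dataclass
class ShearProfile:
    """Floor shear stress τ(y) across the channel width."""

    y: np.ndarray       # (ny,) m
    tau: np.ndarray     # (ny,) Pa
    z_eval: float = 0.0  # height of the evaluation plane, m (0 = wall)


def _check_q(q: float) -> None:
    if not np.isfinite(q) or q < 0:
        raise ValueError(f"flow rate must be non-negative, got {q}")


def plate_wall_shear(q: float, geom: ChannelGeometry = DEVICE_GEOMETRY,
                     fluid: FluidProps = WATERLIKE_MEDIUM) -> float:
    """Floor wall shear stress (Pa) in the wide-channel approximation.

    τ = 6 μ Q / (w h²) — the plane-Poiseuille result, exact as w/h → ∞
    and the standard design formula for parallel-plate flow chambers.
    """
    _check_q(q)
    return 6.0 * fluid.viscosity * q / (geom.width * geom.height ** 2)


def shear_to_flowrate(tau: float, geom: ChannelGeometry = DEVICE_GEOMETRY,
                      fluid: FluidProps = WATERLIKE_MEDIUM) -> float:
    """Flow rate (m³/s) producing a target floor shear stress (Pa).

    Exact inverse of :func:`plate_wall_shear`.
    """
    if not np.isfinite(tau) or tau < 0:
        raise ValueError(f"target shear must be non-negative, got {tau}")
    return tau * geom.width * geom.height ** 2 / (6.0 * fluid.viscosity)


def mean_velocity(q: float, geom: ChannelGeometry = DEVICE_GEOMETRY) -> float:
    """Mean axial velocity U = Q / (w h) in m/s."""
    _check_q(q)
    return q / geom.cross_section_area


def reynolds_number(q: float, geom: ChannelGeometry = DEVICE_GEOMETRY,
                    fluid: FluidProps = WATERLIKE_MEDIUM) -> float:
    """Re = ρ U D_h / μ with the hydraulic diameter D_h = 2wh/(w+h)."""
    _check_q(q)
    u = mean_velocity(q, geom)
    return fluid.density * u * geom.hydraulic_diameter / fluid.viscosity


def is_laminar(re: float) -> bool:
    """Laminar-regime flag (Re below the ~2000 transition threshold)."""
    return re < LAMINAR_RE_THRESHOLD


def _odd_terms(n_terms: int) -> np.ndarray:
    if n_terms < 1:
        raise ValueError(f"n_terms must be >= 1, got {n_terms}")
    return np.arange(1, 2 * n_terms, 2, dtype=float)


def _cosh_ratio(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """cosh(a)/cosh(b) for |a| <= b, overflow-safe for large b."""
    a = np.abs(a)
    return np.exp(a - b) * (1.0 + np.exp(-2.0 * a)) / (1.0 + np.exp(-2.0 * b))


def duct_velocity_series(geom: ChannelGeometry, pressure_gradient: float,
                         fluid: FluidProps, y, z, n_terms: int = 51) -> np.ndarray:
    """Axial velocity u(y, z) from the Fourier-series duct solution.

    ``y`` and ``z`` broadcast against each other; pass ``y[:, None]`` and
    ``z[None, :]`` for a full grid.  The plane-Poiseuille part
    G z (h − z) / (2μ) is split off in closed form (the sine series sums
    exactly to it), so the summed correction decays exponentially away
    from the side walls and 51 odd harmonics are ample.  Wall values are
    exact zeros.
    """
    if pressure_gradient < 0:
        raise ValueError("pressure gradient must be non-negative")
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if np.any(y < -1e-12) or np.any(y > geom.width + 1e-12):
        raise ValueError("y outside [0, width]")
    if np.any(z < -1e-12) or np.any(z > geom.height + 1e-12):
        raise ValueError("z outside [0, height]")
    n = _odd_terms(n_terms)
    w, h, mu = geom.width, geom.height, fluid.viscosity
    yb = y - w / 2.0
    shape = np.broadcast_shapes(y.shape, z.shape)
    correction = np.zeros(shape)
    for nk in n:
        beta = nk * np.pi / h
        ratio = _cosh_ratio(beta * yb, np.asarray(beta * w / 2.0))
        correction = correction + ratio * np.sin(beta * z) / nk ** 3
    u = pressure_gradient * z * (h - z) / (2.0 * mu) \
        - 4.0 * pressure_gradient * h ** 2 / (np.pi ** 3 * mu) * correction
    on_side_wall = np.broadcast_to((y <= 0.0) | (y >= w), shape)
    u = np.where(on_side_wall, 0.0, np.clip(u, 0.0, None))
    return u


def duct_shape_factor(aspect: float, n_terms: int = 51) -> float:
    """Series correction F(w/h) so that Q = (G w h³ / 12 μ) · F.

    F = 1 − (192/π⁵)(h/w) Σ_odd tanh(nπw/2h)/n⁵; strictly in (0, 1) for
    finite aspect ratio and → 1 for a wide channel.
    """
    if aspect <= 0:
        raise InvalidGeometryError("aspect ratio must be positive")
    n = _odd_terms(n_terms)
    s = np.sum(np.tanh(n * np.pi * aspect / 2.0) / n ** 5)
    return float(1.0 - 192.0 / (np.pi ** 5 * aspect) * s)


def duct_flowrate(geom: ChannelGeometry, pressure_gradient: float,
                  fluid: FluidProps, n_terms: int = 51) -> float:
    """Volumetric flow rate (m³/s) for a given pressure gradient."""
    if pressure_gradient < 0:
        raise ValueError("pressure gradient must be non-negative")
    f = duct_shape_factor(geom.aspect, n_terms)
    return pressure_gradient * geom.width * geom.height ** 3 / (12.0 * fluid.viscosity) * f


def pressure_gradient_for_flowrate(q: float, geom: ChannelGeometry,
                                   fluid: FluidProps, n_terms: int = 51) -> float:
    """Invert :func:`duct_flowrate`: G such that the duct carries Q."""
    _check_q(q)
    f = duct_shape_factor(geom.aspect, n_terms)
    return 12.0 * fluid.viscosity * q / (geom.width * geom.height ** 3 * f)


def pressure_drop(q: float, geom: ChannelGeometry = DEVICE_GEOMETRY,
                  fluid: FluidProps = WATERLIKE_MEDIUM, n_terms: int = 51,
                  model: str = "duct") -> float:
    """Pressure drop ΔP = G·L over the channel length (Pa).

    ``model="duct"`` uses the full rectangular-duct resistance;
    ``model="plate"`` the parallel-plate approximation G = 12μQ/(wh³).
    """
    _check_q(q)
    if model == "plate":
        g = 12.0 * fluid.viscosity * q / (geom.width * geom.height ** 3)
    elif model == "duct":
        g = pressure_gradient_for_flowrate(q, geom, fluid, n_terms)
    else:
        raise ValueError(f"unknown model {model!r}")
    return g * geom.length


def wall_shear_profile(geom: ChannelGeometry, pressure_gradient: float,
                       fluid: FluidProps, n_terms: int = 51,
                       y_grid: np.ndarray | None = None,
                       z_eval: float = 0.0) -> ShearProfile:
    """Floor shear stress τ(y) = μ ∂u/∂z across the width.

    By default evaluated at the wall (z = 0).  ``z_eval`` moves the
    evaluation plane up, e.g. 10 µm above the floor, where τ is the
    viscous stress μ ∂u/∂z at that height.
    """
    if y_grid is None:
        y_grid = np.linspace(0.0, geom.width, 241)
    y_grid = np.asarray(y_grid, dtype=float)
    if np.any(y_grid < -1e-12) or np.any(y_grid > geom.width + 1e-12):
        raise ValueError("y_grid outside [0, width]")
    if z_eval < 0 or z_eval > geom.height:
        raise ValueError("z_eval outside [0, height]")
    n = _odd_terms(n_terms)
    w, h = geom.width, geom.height
    yb = y_grid - w / 2.0
    # split off the plane-Poiseuille part analytically: the "1" terms sum
    # in closed form (sum over odd n of cos(n pi z/h)/n^2 = pi^2/8 - pi^2 z/(4h)),
    # leaving only the exponentially decaying side-wall correction
    correction = np.zeros_like(yb)
    for nk in n:
        beta = nk * np.pi / h
        ratio = _cosh_ratio(beta * yb, np.asarray(beta * w / 2.0))
        correction = correction + ratio * np.cos(beta * z_eval) / nk ** 2
    tau = pressure_gradient * (h / 2.0 - z_eval) \
        - 4.0 * pressure_gradient * h / np.pi ** 2 * correction
    tau = np.where((y_grid <= 0.0) | (y_grid >= w), 0.0, np.abs(tau))
    return ShearProfile(y=y_grid, tau=tau, z_eval=z_eval)


def solve_crosssection_fd(geom: ChannelGeometry, pressure_gradient: float,
                          fluid: FluidProps, ny: int = 241, nz: int = 21) -> VelocityField:
    """Five-point finite-difference solution of the duct Poisson problem.

    Solves ∇²u = −G/μ on an (ny × nz) grid spanning the cross-section
    (boundary nodes included, clamped to zero) with a direct sparse
    factorisation.  Serves as the independent numerical oracle for the
    Fourier-series solution.
    """
    if ny < 8 or nz < 8:
        raise ValueError("grid must have at least 8 points per dimension")
    if pressure_gradient < 0:
        raise ValueError("pressure gradient must be non-negative")
    y = np.linspace(0.0, geom.width, ny)
    z = np.linspace(0.0, geom.height, nz)
    u = np.zeros((ny, nz))
    if pressure_gradient == 0:
        return VelocityField(y=y, z=z, u=u)
    dy = y[1] - y[0]
    dz = z[1] - z[0]
    niy, niz = ny - 2, nz - 2
    ey = np.ones(niy)
    ez = np.ones(niz)
    lap_y = sparse.diags([ey[:-1], -2.0 * ey, ey[:-1]], [-1, 0, 1]) / dy ** 2
    lap_z = sparse.diags([ez[:-1], -2.0 * ez, ez[:-1]], [-1, 0, 1]) / dz ** 2
    lap = sparse.kron(lap_y, sparse.identity(niz)) + sparse.kron(sparse.identity(niy), lap_z)
    rhs = np.full(niy * niz, -pressure_gradient / fluid.viscosity)
    interior = spsolve(lap.tocsr(), rhs).reshape(niy, niz)
    u[1:-1, 1:-1] = interior
    return VelocityField(y=y, z=z, u=u)


def operating_point_summary(q: float, geom: ChannelGeometry = DEVICE_GEOMETRY,
                            fluid: FluidProps = WATERLIKE_MEDIUM,
                            n_terms: int = 51) -> dict:
    """Design summary for a flow rate: {Q, U, τ_plate, τ_center, ΔP, Re}."""
    g = pressure_gradient_for_flowrate(q, geom, fluid, n_terms)
    tau_center = wall_shear_profile(
        geom, g, fluid, n_terms, y_grid=np.array([geom.width / 2.0])).tau[0]
    re = reynolds_number(q, geom, fluid)
    return {
        "flow_rate_ml_min": units.ml_per_min(q),
        "mean_velocity_m_s": mean_velocity(q, geom),
        "wall_shear_plate_pa": plate_wall_shear(q, geom, fluid),
        "wall_shear_plate_dyn_cm2": units.dyn_per_cm2(plate_wall_shear(q, geom, fluid)),
        "wall_shear_center_pa": float(tau_center),
        "pressure_drop_pa": pressure_drop(q, geom, fluid, n_terms),
        "reynolds_number": re,
        "laminar": is_laminar(re),
    }
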