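"""Tri-curve soft contact lens geometry.

The back surface is rotationally symmetric and split into three
concentric zones -- optic, transient, peripheral -- each a circular arc
in the meridian cross-section.  Zone radii derive from the base curve
``Bc`` as ``(Bc, Bc+2, Bc-2)`` and the zone centres are placed for sag
continuity at the zone joins.  The front surface is designed meridian by
meridian: a toric power profile (period 180 deg in meridian angle)
feeds the thick-lens maker's equation for the per-meridian front radius,
and the front sag follows a conic-like law with shape factor ``rho``.
A prism ballast thickens the lower half, and a minimum-thickness
iteration bumps the central thickness in 0.01 mm steps until the lens is
at least 0.1 mm thick everywhere.

Coordinates: back-surface apex at the origin, z positive anterior
(toward the incoming light), so back sag is <= 0 and the front apex sits
at z = Tc.  Lengths in mm, powers in diopters.

Two departures from the raw three-zone formulae make the published
parameter ranges feasible and are flagged where they occur:

* the peripheral-zone arc radius ``Bc - 2`` is smaller than the lens
  semi-diameter, so an on-axis arc centre cannot reach the edge; the
  peripheral arc centre is moved off-axis along the transient-zone
  normal at the join (tangent continuation) when needed;
* the optical front-sag law with a single per-meridian radius closes
  before the lens edge at high plus powers, so it governs the optic zone
  only and the periphery carries a thickness blend out to the edge
  thickness ``Te``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

__all__ = [
    "LensDesignSpec",
    "BackSurface",
    "PowerProfile",
    "LensGeometry",
    "zone_radii",
    "zone_centres",
    "back_sag",
    "power_profile",
    "front_radius",
    "front_sag",
    "ballast_thickness",
    "apply_ballast",
    "enforce_min_thickness",
    "build_lens",
    "write_lens_csv",
    "read_lens_csv",
    "write_lens_obj",
]

MIN_THICKNESS = 0.1  # mm, smallest admissible local thickness
THICKNESS_STEP = 0.01  # mm, central-thickness increment per iteration
MAX_THICKEN_ITERATIONS = 200


class GeometryError(ValueError):
    """Raised when a design parameter set yields impossible geometry."""


class DesignInfeasibleError(RuntimeError):
    """Raised when the minimum-thickness iteration fails to terminate."""


@dataclass(frozen=True)
class LensDesignSpec:
    """User-facing design parameters of one lens."""

    diameter: float = 14.0  # D, mm
    optic_zone_diameter: float = 8.0  # d1, mm
    base_curve: float = 8.5  # Bc, mm
    sph: float = 0.0  # spherical power, D
    cyl: float = 0.0  # cylindrical power, D
    cyl_axis: float = 90.0  # deg
    refractive_index: float = 1.3920  # wet
    shape_factor: float = 0.75  # rho
    central_thickness: float = 0.25  # Tc, mm
    edge_thickness: float = 0.4  # Te, mm
    transient_zone_diameter: float | None = None  # d2, mm; default (d1+D)/2
    ballast: bool = True
    n_meridians: int = 360
    n_radial: int = 101
    recompute_front_on_thicken: bool = True

    def __post_init__(self) -> None:
        d2 = self.transient_zone_diameter
        if d2 is None:
            # d2 is not a published value; symmetric split of the
            # non-optic annulus, exposed as a free parameter.
            d2 = 0.5 * (self.optic_zone_diameter + self.diameter)
            object.__setattr__(self, "transient_zone_diameter", d2)
        if not 0 < self.optic_zone_diameter < d2 < self.diameter:
            raise GeometryError(
                f"need 0 < d1 < d2 < D, got d1={self.optic_zone_diameter}, "
                f"d2={d2}, D={self.diameter}"
            )
        if self.base_curve <= 0 or self.central_thickness <= 0:
            raise GeometryError("base curve and central thickness must be positive")
        if not 0 < self.shape_factor <= 1:
            raise GeometryError(f"shape factor out of (0, 1]: {self.shape_factor}")
        if self.n_meridians < 4 or self.n_radial < 8:
            raise GeometryError("grid too coarse")


def zone_radii(base_curve: float) -> tuple[float, float, float]:
    """Back-zone radii ``(R1b, R2b, R3b) = (Bc, Bc+2, Bc-2)`` in mm."""
    if base_curve <= 2.0:
        raise GeometryError(
            f"base curve {base_curve} mm <= 2 mm gives a non-positive peripheral radius"
        )
    return base_curve, base_curve + 2.0, base_curve - 2.0


def zone_centres(
    radii: tuple[float, float, float], d1: float, d2: float
) -> tuple[float, float, float]:
    """Axial z-coordinates of the three zone-arc centres (x-centres 0).

    Chosen so the piecewise sag is continuous at X = d1/2 and X = d2/2.
    """
    r1, r2, r3 = radii
    for arg, r, name in ((d1, r1, "d1/(2*R1b)"), (d1, r2, "d1/(2*R2b)"), (d2, r2, "d2/(2*R2b)"), (d2, r3, "d2/(2*R3b)")):
        if abs(arg / (2.0 * r)) > 1.0:
            raise GeometryError(f"arcsin argument {name} out of range")
    zc1 = -r1
    zc2 = zc1 - r2 * math.cos(math.asin(d1 / (2.0 * r2))) + r1 * math.cos(
        math.asin(d1 / (2.0 * r1))
    )
    zc3 = zc2 - r3 * math.cos(math.asin(d2 / (2.0 * r3))) + r2 * math.cos(
        math.asin(d2 / (2.0 * r2))
    )
    return zc1, zc2, zc3


@dataclass(frozen=True)
class BackSurface:
    """Piecewise-arc back surface of a tri-curve lens.

    ``xc3``/``zc3_eff`` describe the peripheral arc actually used: when
    the on-axis arc of radius R3b cannot span the aperture, the arc
    centre moves off-axis along the transient-zone normal at the d2/2
    join so the same radius continues tangentially to the edge.
    """

    radii: tuple[float, float, float]
    centres: tuple[float, float, float]  # on-axis (Eqs.-style) centres
    d1: float
    d2: float
    semi_diameter: float
    xc3: float = 0.0
    zc3_eff: float | None = None

    @classmethod
    def design(
        cls, base_curve: float, d1: float, d2: float, semi_diameter: float
    ) -> "BackSurface":
        radii = zone_radii(base_curve)
        centres = zone_centres(radii, d1, d2)
        r2, r3 = radii[1], radii[2]
        xc3, zc3_eff = 0.0, centres[2]
        # On-axis peripheral arc reaches only X = R3b; move its centre
        # off-axis (tangent continuation from zone 2) when that is short
        # of the lens edge.
        if semi_diameter > 0.98 * r3:
            xj = d2 / 2.0
            zj = centres[1] + math.sqrt(r2 * r2 - xj * xj)  # join point on zone 2
            # unit vector from join towards zone-2 centre (0, zc2)
            ux, uz = (0.0 - xj) / r2, (centres[1] - zj) / r2
            xc3 = xj + r3 * ux
            zc3_eff = zj + r3 * uz
            if xc3 + r3 < semi_diameter:
                raise GeometryError("peripheral arc cannot span the lens aperture")
        elif d2 / 2.0 > r3:
            raise GeometryError("transient zone join lies beyond the peripheral radius")
        return cls(radii, centres, d1, d2, semi_diameter, xc3, zc3_eff)

    def sag(self, x: np.ndarray | float) -> np.ndarray:
        """Back sag Zb(X), mm (<= 0, apex at origin)."""
        x = np.asarray(x, dtype=float)
        if np.any(x < 0) or np.any(x > self.semi_diameter * (1 + 1e-12)):
            raise GeometryError("X outside [0, D/2]")
        r1, r2, r3 = self.radii
        zc1, zc2, _ = self.centres
        zc3 = self.zc3_eff if self.zc3_eff is not None else self.centres[2]
        z = np.where(
            x <= self.d1 / 2.0,
            zc1 + np.sqrt(np.maximum(r1 * r1 - x * x, 0.0)),
            np.where(
                x <= self.d2 / 2.0,
                zc2 + np.sqrt(np.maximum(r2 * r2 - x * x, 0.0)),
                zc3 + np.sqrt(np.maximum(r3 * r3 - (x - self.xc3) ** 2, 0.0)),
            ),
        )
        return z if z.ndim else float(z)


def back_sag(x: np.ndarray | float, surface: BackSurface) -> np.ndarray:
    """Back-surface height Zb at radial distance X (mm)."""
    return surface.sag(x)


@dataclass(frozen=True)
class PowerProfile:
    """Per-meridian optical power of a (possibly toric) lens."""

    meridians_deg: np.ndarray  # 360 equally spaced meridian angles
    power: np.ndarray  # D, per meridian
    p_max: float
    p_min: float
    p_mean: float
    p_amp: float


def power_profile(
    sph: float, cyl: float, cyl_axis: float = 90.0, n_meridians: int = 360
) -> PowerProfile:
    """Meridian power profile of a sphero-cylindrical prescription.

    The power runs as a cosine between ``Pmax = max(SPH+CYL, SPH)`` and
    ``Pmin = min(SPH+CYL, SPH)`` with period 180 deg in meridian angle
    (two full cosine cycles around the lens), then is circularly shifted
    -- with periodic cubic interpolation for sub-grid axes -- so its
    maxima sit on the cylinder-axis meridians.
    """
    p_max = max(sph + cyl, sph)
    p_min = min(sph + cyl, sph)
    p_mean = 0.5 * (p_max + p_min)
    p_amp = p_max - p_mean
    phi = np.linspace(0.0, 360.0, n_meridians, endpoint=False)
    theta = np.linspace(0.0, 4.0 * np.pi, n_meridians, endpoint=False)
    base = p_amp * np.cos(theta) + p_mean  # maxima at meridians 0 and 180
    if p_amp == 0.0:
        power = np.full(n_meridians, float(sph))
    else:
        step = 360.0 / n_meridians
        shift = cyl_axis / step
        k = int(round(shift))
        if abs(shift - k) < 1e-9:
            power = np.roll(base, k)
        else:
            # periodic cubic interpolation on the circle
            phi_ext = np.concatenate([phi, [360.0]])
            base_ext = np.concatenate([base, [base[0]]])
            spl = CubicSpline(phi_ext, base_ext, bc_type="periodic")
            power = spl((phi - cyl_axis) % 360.0)
    return PowerProfile(
        meridians_deg=phi,
        power=power,
        p_max=p_max,
        p_min=p_min,
        p_mean=p_mean,
        p_amp=p_amp,
    )


def front_radius(
    power_d: float | np.ndarray,
    n: float,
    tc: float,
    r1b: float,
) -> float | np.ndarray:
    """Front radius (mm) delivering thick-lens power ``power_d`` (D).

    Inverts the thick-lens maker's equation for a lens of index ``n``,
    central thickness ``tc`` mm and back radius ``r1b`` mm.  Powers are
    converted from diopters (1/m) to 1/mm internally.
    """
    p = np.asarray(power_d, dtype=float) / 1000.0  # D -> 1/mm
    denom = n * r1b * p + n * (n - 1.0)
    if np.any(np.abs(denom) < 1e-9):
        raise GeometryError("singular power: lens-maker denominator vanishes")
    rf = (tc * (n - 1.0) ** 2 + n * (n - 1.0) * r1b) / denom
    return rf if np.ndim(power_d) else float(rf)


def thick_lens_power(rf: float, rb: float, tc: float, n: float) -> float:
    """Paraxial equivalent power (D) of a meniscus lens in air.

    Independent check of :func:`front_radius`: front radius ``rf``, back
    radius ``rb``, axial thickness ``tc`` (all mm), index ``n``.
    """
    c1, c2 = 1.0 / rf, 1.0 / rb
    p = (n - 1.0) * (c1 - c2) + (n - 1.0) ** 2 * tc * c1 * c2 / n
    return 1000.0 * p


def front_sag(
    x: np.ndarray | float, rf: float, tc: float, rho: float
) -> np.ndarray | float:
    """Front-surface height for one meridian (mm).

    ``Zf = Tc - (1/rho) * (Rf - sqrt(Rf^2 - rho X^2))``; reduces to a
    spherical sag for ``rho = 1``.
    """
    x = np.asarray(x, dtype=float)
    arg = rf * rf - rho * x * x
    if np.any(arg < 0):
        raise GeometryError(
            f"front sag undefined: rho X^2 exceeds Rf^2 (Rf={rf:.4f} mm)"
        )
    z = tc - (rf - np.sqrt(arg)) / rho
    return z if z.ndim else float(z)


def ballast_thickness(tc: float, theta_rad: np.ndarray | float) -> np.ndarray | float:
    """Prism-ballast thickness law ``Tj = Tc (1 - W sin(theta))``.

    The weighting ``W`` is 0.2 on the upper half (0 <= theta <= pi) and
    1.0 on the lower half, so the lens thickens below the horizontal to
    resist rotation.
    """
    theta = np.asarray(theta_rad, dtype=float)
    th = np.mod(theta, 2.0 * np.pi)
    w = np.where(th <= np.pi, 0.2, 1.0)
    tj = tc * (1.0 - w * np.sin(th))
    return tj if tj.ndim else float(tj)


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


@dataclass(frozen=True)
class LensGeometry:
    """Discretised lens: meridian x radial grid of surface heights.

    ``zb`` is shared across meridians (rotationally symmetric back);
    ``zf[j, k]`` is the front height of meridian j at radial station k.
    """

    spec: LensDesignSpec
    meridians_deg: np.ndarray  # (M,)
    x: np.ndarray  # (K,) radial stations, 0 .. D/2
    zb: np.ndarray  # (K,)
    zf: np.ndarray  # (M, K)
    front_radii: np.ndarray  # (M,) per-meridian optical front radii, mm
    power: PowerProfile
    back: BackSurface
    final_tc: float  # central thickness after any thickening, mm

    @property
    def thickness(self) -> np.ndarray:
        """Axial thickness map (M, K), mm."""
        return self.zf - self.zb[None, :]

    def mean_thickness(self, area_weighted: bool = True) -> float:
        """Mean axial thickness over the lens (mm).

        Area weighting (weight ~ X on the uniform radial grid) reflects
        the annular area each station represents.
        """
        t = self.thickness
        if not area_weighted:
            return float(t.mean())
        w = np.broadcast_to(self.x[None, :], t.shape)
        return float(np.average(t, weights=np.maximum(w, 1e-9)))

    def front_nodes_3d(self) -> np.ndarray:
        """Front nodes as an (M, K, 3) array of (x, y, z)."""
        phi = np.deg2rad(self.meridians_deg)[:, None]
        return np.stack(
            [
                self.x[None, :] * np.cos(phi),
                self.x[None, :] * np.sin(phi),
                self.zf,
            ],
            axis=-1,
        )

    def back_nodes_3d(self) -> np.ndarray:
        """Back nodes as an (M, K, 3) array of (x, y, z)."""
        phi = np.deg2rad(self.meridians_deg)[:, None]
        zb = np.broadcast_to(self.zb[None, :], (self.meridians_deg.size, self.x.size))
        return np.stack(
            [
                self.x[None, :] * np.cos(phi),
                self.x[None, :] * np.sin(phi),
                zb,
            ],
            axis=-1,
        )


def _front_height_grid(
    spec: LensDesignSpec,
    back: BackSurface,
    x: np.ndarray,
    front_radii: np.ndarray,
    tc: float,
) -> np.ndarray:
    """Front heights (M, K): optic-zone sag law + peripheral thickness blend."""
    rho = spec.shape_factor
    a_oz = spec.optic_zone_diameter / 2.0
    a = spec.diameter / 2.0
    zb = back.sag(x)
    rf = front_radii[:, None]
    in_oz = x[None, :] <= a_oz
    arg = rf * rf - rho * x[None, :] ** 2
    bad = in_oz & (arg <= 0)
    if np.any(bad):
        raise GeometryError("front sag undefined inside the optic zone")
    z_oz = tc - (rf - np.sqrt(np.maximum(arg, 0.0))) / rho
    # Peripheral blend: carry the optic-zone-edge thickness smoothly to Te.
    arg_edge = rf * rf - rho * a_oz * a_oz
    z_oz_edge = tc - (rf - np.sqrt(np.maximum(arg_edge, 0.0))) / rho
    t_edge_oz = z_oz_edge - back.sag(a_oz)  # (M, 1) thickness at optic-zone edge
    u = _smoothstep((x[None, :] - a_oz) / (a - a_oz))
    t_blend = t_edge_oz * (1.0 - u) + spec.edge_thickness * u
    z_per = zb[None, :] + t_blend
    return np.where(in_oz, z_oz, z_per)


def apply_ballast(geometry: LensGeometry) -> LensGeometry:
    """Add the prism ballast to the front surface.

    The per-meridian offset ``Tj - Tc`` (Eq.-style thickness law in
    :func:`ballast_thickness`) is tapered radially with a smoothstep that
    is zero across the optic zone and full at the edge, so the apex stays
    single-valued and the optics are untouched while the lower half
    thickens toward the periphery.
    """
    spec = geometry.spec
    theta = np.deg2rad(geometry.meridians_deg)
    tj = np.asarray(ballast_thickness(geometry.final_tc, theta))
    offset = (tj - geometry.final_tc)[:, None]
    a_oz = spec.optic_zone_diameter / 2.0
    a = spec.diameter / 2.0
    g = _smoothstep((geometry.x[None, :] - a_oz) / (a - a_oz))
    return replace(geometry, zf=geometry.zf + offset * g)


def enforce_min_thickness(geometry: LensGeometry) -> LensGeometry:
    """Raise the front surface until the lens is >= 0.1 mm thick everywhere.

    Paper-literal variant: the central thickness grows in 0.01 mm steps
    and the whole front surface is re-elevated rigidly (front curvatures
    untouched), which preserves the surface shape but not the delivered
    thick-lens power.  ``build_lens`` defaults to a power-preserving
    variant instead; this operation is kept for the literal behaviour and
    is idempotent.
    """
    t_min = float(geometry.thickness.min())
    if t_min >= MIN_THICKNESS:
        return geometry
    steps = 0
    tc = geometry.final_tc
    while t_min < MIN_THICKNESS:
        steps += 1
        if steps > MAX_THICKEN_ITERATIONS:
            raise DesignInfeasibleError(
                f"minimum thickness not reached after {MAX_THICKEN_ITERATIONS} steps"
            )
        tc += THICKNESS_STEP
        t_min += THICKNESS_STEP
    lift = tc - geometry.final_tc
    return replace(geometry, zf=geometry.zf + lift, final_tc=tc)


def build_lens(spec: LensDesignSpec) -> LensGeometry:
    """Design one lens: back zones, toric front, ballast, thickness fix.

    By default the minimum-thickness iteration re-solves the front radii
    for the updated central thickness at each 0.01 mm step so the
    delivered per-meridian power stays on prescription; with
    ``recompute_front_on_thicken=False`` the front curvatures are frozen
    and only re-elevated (which lets the thick-lens power drift with the
    added thickness).
    """
    a = spec.diameter / 2.0
    back = BackSurface.design(
        spec.base_curve,
        spec.optic_zone_diameter,
        spec.transient_zone_diameter,
        a,
    )
    x = np.linspace(0.0, a, spec.n_radial)
    zb = np.asarray(back.sag(x))
    profile = power_profile(spec.sph, spec.cyl, spec.cyl_axis, spec.n_meridians)
    r1b = back.radii[0]

    def assemble(tc: float) -> tuple[np.ndarray, np.ndarray]:
        rf = np.asarray(
            front_radius(profile.power, spec.refractive_index, tc, r1b)
        )
        zf = _front_height_grid(spec, back, x, rf, tc)
        return rf, zf

    tc = spec.central_thickness
    rf, zf = assemble(tc)
    geometry = LensGeometry(
        spec=spec,
        meridians_deg=profile.meridians_deg,
        x=x,
        zb=zb,
        zf=zf,
        front_radii=rf,
        power=profile,
        back=back,
        final_tc=tc,
    )
    if spec.ballast:
        geometry = apply_ballast(geometry)

    if spec.recompute_front_on_thicken:
        steps = 0
        while float(geometry.thickness.min()) < MIN_THICKNESS:
            steps += 1
            if steps > MAX_THICKEN_ITERATIONS:
                raise DesignInfeasibleError(
                    f"minimum thickness not reached after {MAX_THICKEN_ITERATIONS} steps"
                )
            tc += THICKNESS_STEP
            rf, zf = assemble(tc)
            geometry = replace(geometry, zf=zf, front_radii=rf, final_tc=tc)
            if spec.ballast:
                geometry = apply_ballast(geometry)
    else:
        geometry = enforce_min_thickness(geometry)
    return geometry


# --- IO ---------------------------------------------------------------------


def write_lens_csv(geometry: LensGeometry, path: str | Path) -> None:
    """Long-format CSV of (meridian_deg, X_mm, Zb_mm, Zf_mm)."""
    m = geometry.meridians_deg.size
    k = geometry.x.size
    df = pd.DataFrame(
        {
            "meridian_deg": np.repeat(geometry.meridians_deg, k),
            "X_mm": np.tile(geometry.x, m),
            "Zb_mm": np.tile(geometry.zb, m),
            "Zf_mm": geometry.zf.ravel(),
        }
    )
    df.to_csv(path, index=False)


def read_lens_csv(path: str | Path) -> pd.DataFrame:
    """Read a lens-geometry CSV back as a DataFrame."""
    df = pd.read_csv(path)
    required = {"meridian_deg", "X_mm", "Zb_mm", "Zf_mm"}
    if not required.issubset(df.columns):
        raise ValueError(f"lens CSV needs columns {sorted(required)}")
    return df


def write_lens_obj(geometry: LensGeometry, path: str | Path, surface: str = "front") -> None:
    """Triangulated OBJ export of one surface for visualisation."""
    nodes = geometry.front_nodes_3d() if surface == "front" else geometry.back_nodes_3d()
    m, k, _ = nodes.shape
    lines = ["# onlenspower lens surface"]
    for j in range(m):
        for i in range(k):
            xx, yy, zz = nodes[j, i]
            lines.append(f"v {xx:.6f} {yy:.6f} {zz:.6f}")
    def vid(j: int, i: int) -> int:
        return (j % m) * k + i + 1
    for j in range(m):
        for i in range(k - 1):
            a_, b_, c_, d_ = vid(j, i), vid(j + 1, i), vid(j + 1, i + 1), vid(j, i + 1)
            lines.append(f"f {a_} {b_} {c_}")
            lines.append(f"f {a_} {c_} {d_}")
    Path(path).write_text("\n".join(lines) + "\n")
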