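"""3D sequential ray tracing through a soft contact lens in air.

The two lens interfaces (possibly after on-eye conformance) are fitted
with smooth bivariate polynomial height maps ``z = f(x, y)``.  A bundle
of rays parallel to the optical axis is refracted at the front
(air -> lens) and back (lens -> air) surfaces.  Refraction follows the
meridian-rotation construction: the frame is rotated about z so the
surface normal loses its y component, the refracted direction is built
by rotating the (oriented) normal through the refraction angle about the
plane-of-incidence axis, and the frame is rotated back.  The closed-form
vector Snell law is implemented separately (:func:`refract_vector`) and
serves as an independent oracle; the trace cross-checks every event
against it.

Power is reported two ways:

* ``slope`` (default): regress the exit-ray transverse slopes on the
  entry heights; the reciprocal slope is the equivalent focal length.
  Immune to prism and to the principal-plane offset, so it matches the
  design (thick-lens) power.
* ``crossing``: average the per-ray closest approach to the optical
  axis and measure the focal distance from the lens back apex, i.e.
  back-vertex power.

The effective power change (EPC) is the traced power of the conformed
lens minus that of the undeformed lens, both traced in air with
identical pupil settings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OpticalSurface",
    "Ray",
    "RefractionEvent",
    "BundleResult",
    "EPCResult",
    "fit_surface",
    "surface_normal",
    "incidence_angle",
    "snell",
    "meridian_rotation",
    "refract_vector",
    "refract_direction",
    "refract_ray",
    "hexapolar_pupil",
    "trace_bundle",
    "trace_meridian_fan",
    "surfaces_from_nodes",
    "trace_lens",
    "power_and_epc",
]


class TIRError(ValueError):
    """Total internal reflection: the Snell sine argument exceeded 1."""


class TraceError(RuntimeError):
    """Raised when an intersection fails or too few rays survive."""


class SurfaceFitError(RuntimeError):
    """Raised when the surface fit is rank deficient or too poor."""


# --- surfaces ---------------------------------------------------------------


def _monomial_exponents(degree: int) -> np.ndarray:
    return np.array(
        [(i, total - i) for total in range(degree + 1) for i in range(total + 1)],
        dtype=int,
    )


@dataclass(frozen=True)
class OpticalSurface:
    """Bivariate polynomial height map ``z = f(x, y)`` with analytic gradient.

    Coefficients act on coordinates normalised by ``aperture``; the fit
    residual RMS over the source points is retained for diagnostics.
    """

    coeffs: np.ndarray  # (T,)
    exponents: np.ndarray  # (T, 2)
    aperture: float  # mm, normalisation + validity radius
    residual_rms: float = 0.0  # mm

    def _power_tables(self, x, y) -> tuple[np.ndarray, np.ndarray, tuple]:
        u = np.atleast_1d(np.asarray(x, dtype=float)) / self.aperture
        v = np.atleast_1d(np.asarray(y, dtype=float)) / self.aperture
        u, v = np.broadcast_arrays(u, v)
        dmax = int(self.exponents.max()) + 1
        pu = u[..., None] ** np.arange(dmax)
        pv = v[..., None] ** np.arange(dmax)
        return pu, pv, u.shape

    def __call__(self, x, y):
        pu, pv, shape = self._power_tables(x, y)
        i, j = self.exponents[:, 0], self.exponents[:, 1]
        z = (pu[..., i] * pv[..., j]) @ self.coeffs
        return z.reshape(shape) if np.ndim(x) or np.ndim(y) else float(z.reshape(-1)[0])

    def gradient(self, x, y):
        """(df/dx, df/dy) at (x, y), per mm."""
        pu, pv, shape = self._power_tables(x, y)
        i, j = self.exponents[:, 0], self.exponents[:, 1]
        dui = np.where(i > 0, i, 0)[None, ...]
        dvj = np.where(j > 0, j, 0)[None, ...]
        pui = pu[..., np.maximum(i - 1, 0)] * dui
        pvj = pv[..., np.maximum(j - 1, 0)] * dvj
        gx = ((pui * pv[..., j]) @ self.coeffs) / self.aperture
        gy = ((pu[..., i] * pvj) @ self.coeffs) / self.aperture
        if np.ndim(x) or np.ndim(y):
            return gx.reshape(shape), gy.reshape(shape)
        return float(gx.reshape(-1)[0]), float(gy.reshape(-1)[0])


def fit_surface(
    points: np.ndarray,
    aperture_radius: float,
    degree: int = 8,
    max_residual_rms: float = 1e-3,
) -> OpticalSurface:
    """Least-squares polynomial fit to a surface node cloud.

    Parameters
    ----------
    points
        (N, 3) array of (x, y, z) nodes; only nodes with
        ``hypot(x, y) <= aperture_radius`` participate.
    aperture_radius
        Normalisation radius; the fit is valid inside it.
    degree
        Total polynomial degree of the expansion.
    max_residual_rms
        Reject fits whose residual RMS (mm) exceeds this bound.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    r = np.hypot(pts[:, 0], pts[:, 1])
    pts = pts[r <= aperture_radius * (1 + 1e-9)]
    exps = _monomial_exponents(degree)
    if pts.shape[0] < max(100, exps.shape[0]):
        raise SurfaceFitError(
            f"need >= {max(100, exps.shape[0])} nodes spanning the aperture, got {pts.shape[0]}"
        )
    u = pts[:, 0] / aperture_radius
    v = pts[:, 1] / aperture_radius
    design = np.stack([u**i * v**j for i, j in exps], axis=1)
    coeffs, _, rank, _ = np.linalg.lstsq(design, pts[:, 2], rcond=None)
    if rank < exps.shape[0]:
        raise SurfaceFitError(f"rank-deficient surface fit (rank {rank}/{exps.shape[0]})")
    resid = design @ coeffs - pts[:, 2]
    rms = float(np.sqrt(np.mean(resid**2)))
    if rms > max_residual_rms:
        raise SurfaceFitError(
            f"surface fit residual RMS {rms:.2e} mm exceeds {max_residual_rms:g} mm"
        )
    return OpticalSurface(coeffs=coeffs, exponents=exps, aperture=aperture_radius, residual_rms=rms)


# --- rays and refraction primitives ----------------------------------------


@dataclass(frozen=True)
class Ray:
    """A ray with origin ``S`` and unit direction ``d`` (mm)."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        d = d / np.linalg.norm(d)
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d)


@dataclass(frozen=True)
class RefractionEvent:
    """One refraction: where, against which normal, through which angles."""

    point: np.ndarray
    normal: np.ndarray  # unit, z-positive orientation
    phi_in: float  # rad
    phi_out: float  # rad
    theta_mer: float  # rad
    n_in: float
    n_out: float


def surface_normal(surface: OpticalSurface, point: np.ndarray) -> np.ndarray:
    """Unit normal of the implicit surface ``F = f(x, y) - z`` at *point*.

    Returned with positive z component (anterior-facing); the z
    component of the gradient of F is -1, so the normal never vanishes.
    """
    p = np.asarray(point, dtype=float)
    gx, gy = surface.gradient(p[0], p[1])
    n = np.array([-float(gx), -float(gy), 1.0])
    return n / np.linalg.norm(n)


def incidence_angle(direction: np.ndarray, normal: np.ndarray) -> float:
    """Angle between a unit ray direction and a unit normal, in [0, pi/2].

    Folded via the absolute dot product, so it is insensitive to the
    normal's sign convention.
    """
    c = abs(float(np.dot(direction, normal)))
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def snell(phi_in: float, n_in: float, n_out: float) -> float:
    """Refraction angle ``arcsin((n_in/n_out) sin(phi_in))``.

    Raises :class:`TIRError` on total internal reflection.
    """
    if n_in <= 0 or n_out <= 0:
        raise ValueError("refractive indices must be positive")
    s = n_in / n_out * np.sin(phi_in)
    if abs(s) > 1.0:
        raise TIRError(f"total internal reflection (sin argument {s:.6f})")
    return float(np.arcsin(s))


def meridian_rotation(normal: np.ndarray) -> tuple[float, np.ndarray]:
    """Meridian angle of a normal and the z-rotation that zeroes its y.

    Returns ``(theta_mer, R)`` with ``theta_mer = atan2(Ny, Nx)`` and
    ``R`` the rotation about z by ``theta_mer`` such that
    ``(R @ normal)[1] == 0``.
    """
    nx, ny = float(normal[0]), float(normal[1])
    theta = 0.0 if (nx == 0.0 and ny == 0.0) else float(np.arctan2(ny, nx))
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])
    return theta, rot


def refract_vector(direction: np.ndarray, normal: np.ndarray, n_in: float, n_out: float) -> np.ndarray:
    """Closed-form vector Snell refraction (independent oracle).

    ``t = mu d + (mu cos(phi_i) - cos(phi_t)) m`` with ``m`` the normal
    oriented against the incident ray and ``mu = n_in/n_out``.
    """
    d = np.asarray(direction, dtype=float)
    m = np.asarray(normal, dtype=float)
    if np.dot(d, m) > 0:
        m = -m
    mu = n_in / n_out
    cos_i = -float(np.dot(d, m))
    sin_t2 = mu * mu * (1.0 - cos_i * cos_i)
    if sin_t2 > 1.0:
        raise TIRError("total internal reflection")
    cos_t = np.sqrt(1.0 - sin_t2)
    t = mu * d + (mu * cos_i - cos_t) * m
    return t / np.linalg.norm(t)


def _rodrigues(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1.0 - c)


def refract_direction(
    direction: np.ndarray, normal: np.ndarray, n_in: float, n_out: float
) -> tuple[np.ndarray, float, float, float]:
    """Refract one unit direction by the meridian-rotation construction.

    The frame is rotated about z by the normal's meridian angle (so the
    normal lies in the x-z plane), the oriented normal is rotated
    through the refraction angle about the plane-of-incidence axis to
    give the transmitted direction, and the frame is rotated back.
    Returns ``(d_out, phi_in, phi_out, theta_mer)``.
    """
    d = np.asarray(direction, dtype=float)
    theta, rot = meridian_rotation(normal)
    d_r = rot @ d
    n_r = rot @ np.asarray(normal, dtype=float)  # y component is zero
    m = n_r if np.dot(d_r, n_r) < 0 else -n_r  # oriented against the ray
    phi_in = incidence_angle(d_r, m)
    phi_out = snell(phi_in, n_in, n_out)
    axis = np.cross(d_r, m)
    norm_axis = np.linalg.norm(axis)
    if norm_axis < 1e-14:  # normal incidence: direction unchanged
        return d, phi_in, phi_out, theta
    axis = axis / norm_axis
    d_out_r = _rodrigues(-m, axis, phi_out)
    d_out = rot.T @ d_out_r
    return d_out / np.linalg.norm(d_out), phi_in, phi_out, theta


# --- vectorised internals (mathematically identical to the scalar path) -----


def _intersect_bundle(
    surface: OpticalSurface,
    origins: np.ndarray,
    dirs: np.ndarray,
    max_iter: int = 40,
    tol: float = 1e-11,
) -> tuple[np.ndarray, np.ndarray]:
    """Newton intersection of many rays with a height-map surface.

    Returns ``(points, ok_mask)``; rays that fail to converge, land
    outside the fitted aperture, or hit behind their origin are masked.
    """
    n = origins.shape[0]
    tau = (float(surface(0.0, 0.0)) - origins[:, 2]) / dirs[:, 2]
    active = np.ones(n, dtype=bool)
    p = origins + tau[:, None] * dirs
    for _ in range(max_iter):
        g = p[:, 2] - surface(p[:, 0], p[:, 1])
        active = np.abs(g) > tol
        if not active.any():
            break
        gx, gy = surface.gradient(p[:, 0], p[:, 1])
        dg = dirs[:, 2] - gx * dirs[:, 0] - gy * dirs[:, 1]
        dg = np.where(np.abs(dg) < 1e-12, np.nan, dg)
        step = np.clip(g / dg, -surface.aperture, surface.aperture)
        tau = np.where(active, tau - step, tau)
        p = origins + tau[:, None] * dirs
    g = p[:, 2] - surface(p[:, 0], p[:, 1])
    ok = (
        (np.abs(g) <= 10 * tol)
        & (np.hypot(p[:, 0], p[:, 1]) <= surface.aperture * (1 + 1e-6))
        & (tau > 0)
        & np.isfinite(tau)
    )
    return p, ok


def _refract_bundle(
    dirs: np.ndarray,
    normals: np.ndarray,
    n_in: float,
    n_out: float,
    cross_check: float | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised refraction of many unit directions.

    Same construction as :func:`refract_direction` with the z-rotation
    conjugation carried out implicitly (it cancels algebraically).
    Returns ``(d_out, phi_in, phi_out, ok_mask)``; TIR rays are masked.
    """
    d = dirs
    sgn = -np.sign(np.einsum("ij,ij->i", d, normals))
    m = normals * np.where(sgn == 0, 1.0, sgn)[:, None]
    cos_i = np.clip(-np.einsum("ij,ij->i", d, m), -1.0, 1.0)
    phi_in = np.arccos(np.abs(cos_i))
    mu = n_in / n_out
    sin_arg = mu * np.sin(phi_in)
    ok = np.abs(sin_arg) <= 1.0
    phi_out = np.arcsin(np.clip(sin_arg, -1.0, 1.0))
    axis = np.cross(d, m)
    na = np.linalg.norm(axis, axis=1)
    straight = na < 1e-14
    axis = axis / np.where(straight, 1.0, na)[:, None]
    c = np.cos(phi_out)[:, None]
    s = np.sin(phi_out)[:, None]
    v = -m
    d_out = v * c + np.cross(axis, v) * s + axis * np.einsum("ij,ij->i", axis, v)[:, None] * (1.0 - c)
    d_out = np.where(straight[:, None], d, d_out)
    d_out = d_out / np.linalg.norm(d_out, axis=1, keepdims=True)
    if cross_check is not None:
        cos_t = np.sqrt(np.clip(1.0 - sin_arg**2, 0.0, 1.0))
        oracle = mu * d + (mu * cos_i - cos_t)[:, None] * m
        oracle = oracle / np.linalg.norm(oracle, axis=1, keepdims=True)
        bad = ok & (np.max(np.abs(d_out - oracle), axis=1) > cross_check)
        if bad.any():
            raise TraceError(
                "rotation-construction refraction disagrees with the vector Snell law"
            )
    return d_out, phi_in, phi_out, ok


def _bundle_normals(surface: OpticalSurface, points: np.ndarray) -> np.ndarray:
    gx, gy = surface.gradient(points[:, 0], points[:, 1])
    n = np.stack([-gx, -gy, np.ones_like(gx)], axis=1)
    return n / np.linalg.norm(n, axis=1, keepdims=True)


def refract_ray(
    ray: Ray,
    surface: OpticalSurface,
    n_in: float,
    n_out: float,
    cross_check: float | None = 1e-8,
) -> tuple[Ray, RefractionEvent]:
    """Refract *ray* at *surface*, returning the transmitted ray + event.

    With ``cross_check`` set, the rotation-construction output is
    compared per component against the closed-form vector Snell law and
    a discrepancy above the bound fails the trace.
    """
    p, ok = _intersect_bundle(surface, ray.origin[None, :], ray.direction[None, :])
    if not ok[0]:
        raise TraceError("ray misses the surface within the fitted aperture")
    p = p[0]
    n_hat = surface_normal(surface, p)
    d_out, phi_in, phi_out, theta = refract_direction(ray.direction, n_hat, n_in, n_out)
    if cross_check is not None:
        oracle = refract_vector(ray.direction, n_hat, n_in, n_out)
        if np.max(np.abs(d_out - oracle)) > cross_check:
            raise TraceError(
                "rotation-construction refraction disagrees with the vector Snell law"
            )
    event = RefractionEvent(
        point=p, normal=n_hat, phi_in=phi_in, phi_out=phi_out,
        theta_mer=theta, n_in=n_in, n_out=n_out,
    )
    return Ray(origin=p, direction=d_out), event


# --- bundles ----------------------------------------------------------------


def hexapolar_pupil(semi_aperture: float, n_rings: int = 6) -> np.ndarray:
    """(N, 2) hexapolar sample of a circular pupil (127 points at 6 rings)."""
    pts = [(0.0, 0.0)]
    for i in range(1, n_rings + 1):
        r = semi_aperture * i / n_rings
        for k in range(6 * i):
            a = 2.0 * np.pi * k / (6 * i)
            pts.append((r * np.cos(a), r * np.sin(a)))
    return np.asarray(pts)


@dataclass
class BundleResult:
    """Outcome of tracing one parallel bundle through a lens."""

    entry_xy: np.ndarray  # (N, 2) surviving rays' pupil coordinates
    exit_origins: np.ndarray  # (N, 3) exit points on the back surface
    exit_dirs: np.ndarray  # (N, 3) unit directions
    events: list[RefractionEvent]
    dropped: int
    power_slope: float  # D, equivalent-power estimate
    power_crossing: float  # D, back-vertex estimate (0 if afocal)
    focal_length: float  # mm (inf if afocal), from the slope estimate
    crossing_spread: float  # mm, SD of per-ray axial crossings
    mean_crossing_z: float  # mm (nan if afocal)

    def power(self, method: str = "slope") -> float:
        if method == "slope":
            return self.power_slope
        if method == "crossing":
            return self.power_crossing
        raise ValueError("method must be 'slope' or 'crossing'")


def _axis_crossings(origins: np.ndarray, dirs: np.ndarray) -> np.ndarray:
    """Axial position of each ray's closest approach to the z-axis."""
    dxy2 = dirs[:, 0] ** 2 + dirs[:, 1] ** 2
    keep = dxy2 > 1e-20
    o, d = origins[keep], dirs[keep]
    tau = -(o[:, 0] * d[:, 0] + o[:, 1] * d[:, 1]) / dxy2[keep]
    return o[:, 2] + tau * d[:, 2]


def trace_bundle(
    front: OpticalSurface,
    back: OpticalSurface,
    n_lens: float,
    pupil_semi_aperture: float = 1.5,
    n_rings: int = 6,
    n_air: float = 1.0,
    cross_check: float | None = 1e-8,
    min_rays: int = 10,
    collect_events: bool = False,
) -> BundleResult:
    """Trace a hexapolar bundle parallel to the axis through both surfaces.

    Rays start above the front surface travelling along ``(0, 0, -1)``,
    refract air -> lens at the front and lens -> air at the back.  Rays
    lost to TIR or misses are dropped and counted.  Per-event records
    are assembled only on request (``collect_events``) to keep sweeps
    cheap.
    """
    pupil = hexapolar_pupil(pupil_semi_aperture, n_rings)
    n = pupil.shape[0]
    z_start = float(front(0.0, 0.0)) + 5.0
    origins = np.column_stack([pupil, np.full(n, z_start)])
    dirs = np.tile(np.array([0.0, 0.0, -1.0]), (n, 1))

    p1, ok1 = _intersect_bundle(front, origins, dirs)
    n1 = _bundle_normals(front, p1)
    d1, phi_in1, phi_out1, ok_r1 = _refract_bundle(dirs, n1, n_air, n_lens, cross_check)
    p2, ok2 = _intersect_bundle(back, p1, d1)
    n2 = _bundle_normals(back, p2)
    d2, phi_in2, phi_out2, ok_r2 = _refract_bundle(d1, n2, n_lens, n_air, cross_check)
    alive = ok1 & ok_r1 & ok2 & ok_r2
    if int(alive.sum()) < min_rays:
        raise TraceError(f"only {int(alive.sum())} rays survived the trace")

    entry = pupil[alive]
    exit_o = p2[alive]
    exit_d = d2[alive]

    events: list[RefractionEvent] = []
    if collect_events:
        for k in np.flatnonzero(alive):
            th1 = float(np.arctan2(n1[k, 1], n1[k, 0])) if (n1[k, 0] or n1[k, 1]) else 0.0
            th2 = float(np.arctan2(n2[k, 1], n2[k, 0])) if (n2[k, 0] or n2[k, 1]) else 0.0
            events.append(RefractionEvent(p1[k], n1[k], float(phi_in1[k]), float(phi_out1[k]), th1, n_air, n_lens))
            events.append(RefractionEvent(p2[k], n2[k], float(phi_in2[k]), float(phi_out2[k]), th2, n_lens, n_air))

    # equivalent power: regress transverse exit slopes on entry heights;
    # cubic (Seidel) terms absorb spherical aberration so the linear
    # coefficient is the paraxial slope
    slopes = exit_d[:, :2] / exit_d[:, 2:3]
    x, y = entry[:, 0], entry[:, 1]
    beta = []
    for h, cross, s in ((x, y, slopes[:, 0]), (y, x, slopes[:, 1])):
        a_mat = np.stack([np.ones_like(h), h, h**3, h * cross**2], axis=1)
        sol, *_ = np.linalg.lstsq(a_mat, s, rcond=None)
        beta.append(sol[1])
    power_slope = 1000.0 * 0.5 * (beta[0] + beta[1])

    crossings = _axis_crossings(exit_o, exit_d)
    if crossings.size and abs(power_slope) > 1e-3:
        mean_cross = float(crossings.mean())
        spread = float(crossings.std())
        power_crossing = -1000.0 / mean_cross if mean_cross != 0 else float("nan")
    else:  # afocal: crossings diverge, report the sentinel
        mean_cross = float("nan")
        spread = float(crossings.std()) if crossings.size else 0.0
        power_crossing = 0.0
    focal = float("inf") if abs(power_slope) < 1e-9 else 1000.0 / power_slope
    return BundleResult(
        entry_xy=entry,
        exit_origins=exit_o,
        exit_dirs=exit_d,
        events=events,
        dropped=int(n - alive.sum()),
        power_slope=float(power_slope),
        power_crossing=float(power_crossing),
        focal_length=focal,
        crossing_spread=spread,
        mean_crossing_z=mean_cross,
    )


def trace_meridian_fan(
    front: OpticalSurface,
    back: OpticalSurface,
    n_lens: float,
    meridian_deg: float,
    pupil_semi_aperture: float = 1.5,
    n_rays: int = 21,
    cross_check: float | None = 1e-8,
) -> float:
    """Power (D) along one meridian from a fan of meridional rays."""
    phi = np.deg2rad(meridian_deg)
    h = np.linspace(-pupil_semi_aperture, pupil_semi_aperture, n_rays)
    h = h[np.abs(h) > 1e-9]
    z_start = float(front(0.0, 0.0)) + 5.0
    origins = np.column_stack([h * np.cos(phi), h * np.sin(phi), np.full(h.size, z_start)])
    dirs = np.tile(np.array([0.0, 0.0, -1.0]), (h.size, 1))
    p1, ok1 = _intersect_bundle(front, origins, dirs)
    d1, _, _, okr1 = _refract_bundle(dirs, _bundle_normals(front, p1), 1.0, n_lens, cross_check)
    p2, ok2 = _intersect_bundle(back, p1, d1)
    d2, _, _, okr2 = _refract_bundle(d1, _bundle_normals(back, p2), n_lens, 1.0, cross_check)
    alive = ok1 & okr1 & ok2 & okr2
    if int(alive.sum()) < 4:
        raise TraceError("too few rays survived the meridian fan")
    hh = h[alive]
    radial_slope = (d2[alive, 0] * np.cos(phi) + d2[alive, 1] * np.sin(phi)) / d2[alive, 2]
    a_mat = np.stack([np.ones_like(hh), hh, hh**3], axis=1)
    sol, *_ = np.linalg.lstsq(a_mat, radial_slope, rcond=None)
    return float(1000.0 * sol[1])


# --- lens-level helpers ------------------------------------------------------

#: default fitting aperture, safely inside the 8 mm optic zone so the
#: optic/periphery junction never pollutes the polynomial fit
DEFAULT_FIT_APERTURE = 3.5  # mm


def surfaces_from_nodes(
    front_nodes: np.ndarray,
    back_nodes: np.ndarray,
    fit_aperture: float = DEFAULT_FIT_APERTURE,
    degree: int = 8,
) -> tuple[OpticalSurface, OpticalSurface]:
    """Fit front/back optical surfaces from (…, 3) node clouds."""
    front = fit_surface(front_nodes.reshape(-1, 3), fit_aperture, degree)
    back = fit_surface(back_nodes.reshape(-1, 3), fit_aperture, degree)
    return front, back


def trace_lens(
    lens_or_conformed,
    n_lens: float,
    pupil_semi_aperture: float = 1.5,
    n_rings: int = 6,
    fit_aperture: float = DEFAULT_FIT_APERTURE,
    degree: int = 8,
    cross_check: float | None = 1e-8,
    collect_events: bool = False,
) -> BundleResult:
    """Fit surfaces to a LensGeometry or ConformedLens and trace a bundle."""
    front, back = surfaces_from_nodes(
        lens_or_conformed.front_nodes_3d(),
        lens_or_conformed.back_nodes_3d(),
        fit_aperture,
        degree,
    )
    return trace_bundle(
        front, back, n_lens,
        pupil_semi_aperture=pupil_semi_aperture,
        n_rings=n_rings,
        cross_check=cross_check,
        collect_events=collect_events,
    )


@dataclass(frozen=True)
class EPCResult:
    """Traced power of a conformed lens against its off-eye baseline."""

    focal_length: float  # mm, of the conformed lens
    traced_power: float  # D, conformed
    baseline_power: float  # D, undeformed traced (or labelled, per config)
    epc: float  # D, traced - baseline
    ray_count: int
    crossing_spread: float  # mm


def power_and_epc(conformed: BundleResult, baseline_power: float, method: str = "slope") -> EPCResult:
    """Assemble an :class:`EPCResult` from a traced conformed bundle."""
    traced = conformed.power(method)
    return EPCResult(
        focal_length=conformed.focal_length,
        traced_power=traced,
        baseline_power=baseline_power,
        epc=traced - baseline_power,
        ray_count=conformed.entry_xy.shape[0],
        crossing_spread=conformed.crossing_spread,
    )
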