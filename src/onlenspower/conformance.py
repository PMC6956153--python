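"""On-eye conformance of a soft lens against a rigid corneal model.

The cornea is a rigid sphere whose front radius comes from keratometric
curvature (``Rc = 337.5 / K``).  The lens is pressed onto it by two
uniform pressures -- tear-film surface tension P1 (tens of mPa) and
eyelid pressure P2 (~8 mmHg) -- and how far it conforms is set by a
dimensionless bending-stiffness number

    S = E t^3 / (12 (1 - nu^2) (P1 + P2) a^3)

(the plate bending stiffness over the pressure work scale, with mean
thickness t and semi-diameter a).  Each meridian of the back surface is
re-shaped by blending its tangent-angle profile with the corneal one at
weight ``w = S / (1 + S)`` and re-integrating at unit speed, which
preserves meridional arc length exactly: ``w -> 1`` reproduces the
undeformed lens (rigid limit) and ``w -> 0`` drapes the lens onto the
corneal sphere.  The front surface follows by co-rotating the original
back-to-front node offsets with the local surface rotation, so thickness
is transported unchanged (the material is nearly incompressible,
nu = 0.49, and thin).

This solver is a deliberate, desk-scale surrogate for a nonlinear
finite-element contact solution; :func:`export_fe_model` writes a full
FE input file (hex meshes, material cards, pressures, contact, boundary
conditions) for an external solver when the genuine article is wanted.
The surrogate is frictionless and quasi-static; the friction coefficient
in :class:`LoadCase` is carried only into the FE export.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import LensGeometry

__all__ = [
    "KERATOMETRIC_CONSTANT",
    "MMHG_TO_PA",
    "CornealModel",
    "LoadCase",
    "ConformedLens",
    "cornea_sag",
    "stiffness_number",
    "conform",
]

KERATOMETRIC_CONSTANT = 337.5  # D*mm, keratometric diopter convention
MMHG_TO_PA = 133.322387415


class ConformanceError(RuntimeError):
    """Raised when conformance produces self-intersecting geometry."""


@dataclass(frozen=True)
class CornealModel:
    """Rigid spherical cornea in the lens coordinate frame.

    The posterior surface (constant 545 um behind the front) matters
    only for FE export; the rigid-contact surrogate sees the front
    sphere alone.
    """

    keratometry: float = 43.7  # K, D
    thickness_um: float = 545.0
    rigid: bool = True

    @property
    def front_radius(self) -> float:
        """Front radius Rc = 337.5 / K (mm)."""
        return KERATOMETRIC_CONSTANT / self.keratometry

    def sag(self, x: np.ndarray | float) -> np.ndarray | float:
        """Spherical sag at radial distance X, apex at the origin (mm)."""
        rc = self.front_radius
        x = np.asarray(x, dtype=float)
        if np.any(np.abs(x) > rc):
            raise ValueError(f"X beyond the corneal radius {rc:.4f} mm")
        z = -(rc - np.sqrt(rc * rc - x * x))
        return z if z.ndim else float(z)


def cornea_sag(x: np.ndarray | float, cornea: CornealModel) -> np.ndarray | float:
    """Corneal front-surface height at radial distance X (mm)."""
    return cornea.sag(x)


@dataclass(frozen=True)
class LoadCase:
    """Uniform pressures squeezing the lens onto the eye.

    tear_pressure
        P1, tear-film surface-tension pressure on the lens back (Pa).
    eyelid_pressure
        P2, blink/eyelid pressure on the lens front (Pa);
        8 mmHg = 1066.58 Pa.
    friction_mu
        Contact friction coefficient (used by the FE export only).
    """

    tear_pressure: float = 0.0436  # Pa (43.6 mPa)
    eyelid_pressure: float = 8.0 * MMHG_TO_PA  # Pa
    friction_mu: float = 0.01

    def __post_init__(self) -> None:
        if min(self.tear_pressure, self.eyelid_pressure, self.friction_mu) < 0:
            raise ValueError("loads and friction must be non-negative")

    @property
    def total_pressure(self) -> float:
        """P1 + P2 in Pa."""
        return self.tear_pressure + self.eyelid_pressure


def stiffness_number(
    modulus_mpa: float,
    mean_thickness: float,
    semi_diameter: float,
    loads: LoadCase,
    poisson: float = 0.49,
) -> float:
    """Dimensionless bending-stiffness number S.

    ``S = E t^3 / (12 (1 - nu^2) (P1+P2) a^3)`` with E and the pressures
    in MPa and lengths in mm.  Infinite when the pressures vanish.
    """
    if min(modulus_mpa, mean_thickness, semi_diameter) <= 0:
        raise ValueError("modulus, thickness and semi-diameter must be positive")
    p_mpa = loads.total_pressure * 1e-6
    if p_mpa == 0.0:
        return float("inf")
    return modulus_mpa * mean_thickness**3 / (
        12.0 * (1.0 - poisson**2) * p_mpa * semi_diameter**3
    )


@dataclass(frozen=True)
class ConformedLens:
    """Lens node cloud after on-eye conformance.

    Same grid topology as the source :class:`LensGeometry`; nodes are
    stored per meridian in the (X, z) meridian plane.  ``back_x[j, k]``
    etc. give node positions; meridional arc length of the back surface
    is preserved by construction.
    """

    source: LensGeometry
    cornea: CornealModel
    loads: LoadCase
    weight: float  # w in (0, 1]
    stiffness: float  # S
    meridians_deg: np.ndarray  # (M,)
    back_x: np.ndarray  # (M, K)
    back_z: np.ndarray  # (M, K)
    front_x: np.ndarray  # (M, K)
    front_z: np.ndarray  # (M, K)

    def back_nodes_3d(self) -> np.ndarray:
        phi = np.deg2rad(self.meridians_deg)[:, None]
        return np.stack(
            [self.back_x * np.cos(phi), self.back_x * np.sin(phi), self.back_z],
            axis=-1,
        )

    def front_nodes_3d(self) -> np.ndarray:
        phi = np.deg2rad(self.meridians_deg)[:, None]
        return np.stack(
            [self.front_x * np.cos(phi), self.front_x * np.sin(phi), self.front_z],
            axis=-1,
        )

    def back_clearance(self) -> np.ndarray:
        """Signed clearance of back nodes above the corneal sphere (mm)."""
        rc = self.cornea.front_radius
        return np.hypot(self.back_x, self.back_z + rc) - rc

    def meridian_arc_lengths(self) -> np.ndarray:
        """Polyline arc length of the conformed back surface, per meridian."""
        return np.hypot(np.diff(self.back_x, axis=1), np.diff(self.back_z, axis=1)).sum(axis=1)


def _segment_angles(x: np.ndarray, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Chord lengths and chord angles of a per-meridian polyline (M, K-1)."""
    dx = np.diff(x, axis=1)
    dz = np.diff(z, axis=1)
    ds = np.hypot(dx, dz)
    psi = np.arctan2(dz, dx)
    return ds, psi


def conform(
    lens: LensGeometry,
    cornea: CornealModel,
    material,
    loads: LoadCase | None = None,
    local_stiffness: bool = False,
) -> ConformedLens:
    """Conform *lens* to *cornea* under *loads*.

    Per meridian the back polyline is decomposed into chord lengths and
    chord tangent angles; the chord angles are blended with the corneal
    circle's tangent field (evaluated at the chord-midpoint arc lengths,
    where chord direction equals arc-midpoint tangent exactly for a
    circle) at weight ``w = S/(1+S)``, and the polyline is re-assembled
    from the apex.  Chord lengths are untouched, so meridional arc
    length is preserved exactly and ``w = 1`` is an exact identity.

    *material* needs ``modulus`` (MPa) and ``poisson`` attributes.
    With ``local_stiffness=True`` the weight is computed per radial
    station from the local thickness instead of the lens mean.
    """
    loads = loads if loads is not None else LoadCase()
    if lens.spec.diameter / 2.0 >= cornea.front_radius:
        raise ConformanceError("lens semi-diameter exceeds the corneal aperture")
    rc = cornea.front_radius
    a = lens.spec.diameter / 2.0

    t_bar = lens.mean_thickness()
    s_number = stiffness_number(material.modulus, t_bar, a, loads, material.poisson)
    w_global = 1.0 if np.isinf(s_number) else s_number / (1.0 + s_number)

    m = lens.meridians_deg.size
    k = lens.x.size
    x0 = np.broadcast_to(lens.x[None, :], (m, k))
    zb0 = np.broadcast_to(lens.zb[None, :], (m, k))

    ds, psi_lens = _segment_angles(x0, zb0)  # (M, K-1)
    # chord-consistent corneal tangent field: chords of length ds placed
    # at angles -(sigma + dsigma/2) inscribe the corneal circle exactly,
    # so the w -> 0 limit lands on the sphere to machine precision
    dsig = 2.0 * np.arcsin(np.clip(ds / (2.0 * rc), -1.0, 1.0))
    sig_edges = np.concatenate([np.zeros((m, 1)), np.cumsum(dsig, axis=1)], axis=1)
    psi_cornea = -(sig_edges[:, :-1] + 0.5 * dsig)

    if local_stiffness:
        t_loc = lens.thickness
        t_seg = 0.5 * (t_loc[:, :-1] + t_loc[:, 1:])
        s_loc = (
            material.modulus
            * t_seg**3
            / (12.0 * (1.0 - material.poisson**2) * loads.total_pressure * 1e-6 * a**3)
        )
        w = s_loc / (1.0 + s_loc)
    else:
        w = w_global

    psi_new = w * psi_lens + (1.0 - w) * psi_cornea
    bx = np.concatenate(
        [np.zeros((m, 1)), np.cumsum(ds * np.cos(psi_new), axis=1)], axis=1
    )
    bz = np.concatenate(
        [np.zeros((m, 1)), np.cumsum(ds * np.sin(psi_new), axis=1)], axis=1
    )

    # co-rotate the original axial back-to-front offsets with the local
    # change in tangent angle (thin-shell director transport)
    dpsi_seg = psi_new - psi_lens
    dpsi = np.empty((m, k))
    dpsi[:, 0] = dpsi_seg[:, 0]
    dpsi[:, -1] = dpsi_seg[:, -1]
    dpsi[:, 1:-1] = 0.5 * (dpsi_seg[:, :-1] + dpsi_seg[:, 1:])
    vx = np.zeros((m, k))  # original offset is purely axial: (0, T)
    vz = lens.thickness
    cos_a, sin_a = np.cos(dpsi), np.sin(dpsi)
    fx = bx + cos_a * vx - sin_a * vz
    fz = bz + sin_a * vx + cos_a * vz

    # impenetrability: radially project any node that dipped below the sphere
    r_node = np.hypot(bx, bz + rc)
    pen = r_node < rc - 1e-12
    if np.any(pen):
        scale = rc / np.where(pen, r_node, rc)
        bx = np.where(pen, bx * scale, bx)
        bz = np.where(pen, (bz + rc) * scale - rc, bz)

    if np.any(np.diff(bx, axis=1) < -1e-9):
        raise ConformanceError("conformed back surface folds over itself")

    return ConformedLens(
        source=lens,
        cornea=cornea,
        loads=loads,
        weight=float(np.mean(w)),
        stiffness=float(s_number),
        meridians_deg=lens.meridians_deg,
        back_x=bx,
        back_z=bz,
        front_x=fx,
        front_z=fz,
    )
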