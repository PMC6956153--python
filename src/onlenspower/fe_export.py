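"""FE input-file writer for the cornea-lens contact problem.

Writes a structured-hexahedral (HEX8) model of the lens resting on the
rigid two-surface cornea as an XML input file in the FEBio dialect:
linear-elastic material cards (E, nu = 0.49), tear-film pressure P1 on
the lens back and cornea front, eyelid pressure P2 on the lens front
ramped in halfway through the analysis step, sliding contact with a
constant friction coefficient, the cornea fully constrained, and the
lens centre held in X and Y.  Solving is left to the external solver;
this module only guarantees a valid, non-inverted mesh.

The file uses the mm / N / MPa unit system, so the Pa pressures held in
:class:`~onlenspower.conformance.LoadCase` appear scaled by 1e-6.

Both meshes are annular about the optical axis (a polar structured grid
degenerates at the pole, so a small central hole of configurable radius
is left; its area is optically and mechanically negligible).  The lens
"centre node" boundary condition is applied to the innermost node ring.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .conformance import CornealModel, LoadCase
from .design import LensGeometry

__all__ = ["MeshParams", "HexMesh", "build_lens_mesh", "build_cornea_mesh", "export_fe_model"]


class MeshExportError(RuntimeError):
    """Raised when the generated mesh contains inverted elements."""


@dataclass(frozen=True)
class MeshParams:
    """Structured-mesh resolution for the FE export."""

    lens_rings: int = 12
    lens_sectors: int = 24
    lens_layers: int = 2
    cornea_rings: int = 12
    cornea_sectors: int = 24
    cornea_layers: int = 2
    hole_radius: float = 0.15  # mm, radius of the central hole


@dataclass(frozen=True)
class HexMesh:
    """A structured annular hex mesh with named boundary facet sets."""

    nodes: np.ndarray  # (N, 3)
    elements: np.ndarray  # (E, 8) 0-based HEX8 connectivity
    surfaces: dict[str, np.ndarray]  # name -> (F, 4) quad facets
    rings: int
    sectors: int
    layers: int

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def corner_jacobians(self) -> np.ndarray:
        """Trilinear Jacobian determinant at every hex corner (E, 8)."""
        # corner order: bottom ring CCW (0..3), top ring CCW (4..7)
        signs = np.array(
            [  # local (xi, eta, zeta) of each corner
                (-1, -1, -1), (1, -1, -1), (1, 1, -1), (-1, 1, -1),
                (-1, -1, 1), (1, -1, 1), (1, 1, 1), (-1, 1, 1),
            ],
            dtype=float,
        )
        coords = self.nodes[self.elements]  # (E, 8, 3)
        out = np.empty((self.n_elements, 8))
        for c, (xi, eta, zeta) in enumerate(signs):
            dn = np.empty((8, 3))
            for a, (sx, se, sz) in enumerate(signs):
                dn[a, 0] = 0.125 * sx * (1 + se * eta) * (1 + sz * zeta)
                dn[a, 1] = 0.125 * se * (1 + sx * xi) * (1 + sz * zeta)
                dn[a, 2] = 0.125 * sz * (1 + sx * xi) * (1 + se * eta)
            jac = np.einsum("eai,aj->eji", coords, dn)
            out[:, c] = np.linalg.det(jac)
        return out


def _annular_mesh(
    rings: int,
    sectors: int,
    layers: int,
    r_inner: float,
    r_outer: float,
    z_bottom,
    z_top,
) -> HexMesh:
    """Structured annular hex mesh between two height fields z(r, phi)."""
    r = np.linspace(r_inner, r_outer, rings + 1)
    phi = np.linspace(0.0, 2.0 * np.pi, sectors, endpoint=False)
    frac = np.linspace(0.0, 1.0, layers + 1)
    rr, pp = np.meshgrid(r, phi, indexing="ij")  # (R+1, S)
    zb = z_bottom(rr, pp)
    zt = z_top(rr, pp)

    def nid(i: int, j: int, k: int) -> int:
        return (k * (rings + 1) + i) * sectors + (j % sectors)

    n_nodes = (layers + 1) * (rings + 1) * sectors
    nodes = np.empty((n_nodes, 3))
    for k in range(layers + 1):
        z = zb + frac[k] * (zt - zb)
        for i in range(rings + 1):
            for j in range(sectors):
                nodes[nid(i, j, k)] = (
                    rr[i, j] * np.cos(pp[i, j]),
                    rr[i, j] * np.sin(pp[i, j]),
                    z[i, j],
                )

    elements = []
    for k in range(layers):
        for i in range(rings):
            for j in range(sectors):
                elements.append(
                    (
                        nid(i, j, k), nid(i + 1, j, k),
                        nid(i + 1, j + 1, k), nid(i, j + 1, k),
                        nid(i, j, k + 1), nid(i + 1, j, k + 1),
                        nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1),
                    )
                )
    elements = np.asarray(elements, dtype=int)

    def layer_facets(k: int, flip: bool) -> np.ndarray:
        quads = []
        for i in range(rings):
            for j in range(sectors):
                q = (nid(i, j, k), nid(i + 1, j, k), nid(i + 1, j + 1, k), nid(i, j + 1, k))
                quads.append(q[::-1] if flip else q)
        return np.asarray(quads, dtype=int)

    surfaces = {
        "bottom": layer_facets(0, flip=True),  # outward normal downward
        "top": layer_facets(layers, flip=False),
    }
    return HexMesh(nodes, elements, surfaces, rings, sectors, layers)


def build_lens_mesh(lens: LensGeometry, params: MeshParams) -> HexMesh:
    """Hex mesh of the lens between its back and front surfaces."""
    phi_grid = np.deg2rad(lens.meridians_deg)
    # periodic extension for interpolation across the wrap
    phi_ext = np.concatenate([phi_grid, [2.0 * np.pi]])
    zf_ext = np.vstack([lens.zf, lens.zf[:1]])
    front_itp = RegularGridInterpolator(
        (phi_ext, lens.x), zf_ext, bounds_error=False, fill_value=None
    )

    def z_back(rr, pp):
        return np.asarray(lens.back.sag(rr))

    def z_front(rr, pp):
        pts = np.stack([np.mod(pp, 2.0 * np.pi).ravel(), rr.ravel()], axis=-1)
        return front_itp(pts).reshape(rr.shape)

    mesh = _annular_mesh(
        params.lens_rings,
        params.lens_sectors,
        params.lens_layers,
        params.hole_radius,
        lens.spec.diameter / 2.0,
        z_back,
        z_front,
    )
    return mesh


def build_cornea_mesh(
    cornea: CornealModel, aperture: float, params: MeshParams
) -> HexMesh:
    """Hex mesh of the corneal slab (front sphere, constant thickness).

    The aperture is capped just inside the sphere's equator.
    """
    aperture = min(aperture, 0.98 * cornea.front_radius)
    t = cornea.thickness_um / 1000.0

    def z_front(rr, pp):
        return np.asarray(cornea.sag(rr))

    def z_back(rr, pp):
        return np.asarray(cornea.sag(rr)) - t

    return _annular_mesh(
        params.cornea_rings,
        params.cornea_sectors,
        params.cornea_layers,
        params.hole_radius,
        aperture,
        z_back,
        z_front,
    )


def export_fe_model(
    lens: LensGeometry,
    cornea: CornealModel,
    material,
    loads: LoadCase,
    path: str | Path,
    mesh_params: MeshParams | None = None,
) -> None:
    """Write the cornea-lens contact model as an FEBio-style XML file.

    *material* needs ``modulus`` (MPa) and ``poisson`` attributes.
    Raises :class:`MeshExportError` if either mesh contains a
    non-positive corner Jacobian.
    """
    params = mesh_params if mesh_params is not None else MeshParams()
    lens_mesh = build_lens_mesh(lens, params)
    cornea_mesh = build_cornea_mesh(
        cornea, lens.spec.diameter / 2.0 + 0.75, params
    )
    for name, mesh in (("lens", lens_mesh), ("cornea", cornea_mesh)):
        jac = mesh.corner_jacobians()
        if jac.min() <= 0:
            raise MeshExportError(
                f"{name} mesh has inverted hexes (min corner Jacobian {jac.min():.3e})"
            )

    pa_to_mpa = 1e-6
    root = ET.Element("febio_spec", version="3.0")
    ET.SubElement(root, "Module", type="solid")

    mats = ET.SubElement(root, "Material")
    m1 = ET.SubElement(mats, "material", id="1", name="lens_hydrogel", type="isotropic elastic")
    ET.SubElement(m1, "E").text = f"{material.modulus:.6g}"
    ET.SubElement(m1, "v").text = f"{material.poisson:.4g}"
    m2 = ET.SubElement(mats, "material", id="2", name="cornea_rigid", type="rigid body")
    ET.SubElement(m2, "density").text = "1e-9"

    mesh_el = ET.SubElement(root, "Mesh")
    offset = 0
    node_offsets = {}
    for name, mesh in (("lens", lens_mesh), ("cornea", cornea_mesh)):
        node_offsets[name] = offset
        nodes_el = ET.SubElement(mesh_el, "Nodes", name=name)
        for idx, (x, y, z) in enumerate(mesh.nodes, start=offset + 1):
            ET.SubElement(nodes_el, "node", id=str(idx)).text = (
                f"{x:.8g},{y:.8g},{z:.8g}"
            )
        offset += mesh.nodes.shape[0]
    for name, mesh, mat_id in (("lens", lens_mesh, 1), ("cornea", cornea_mesh, 2)):
        elems_el = ET.SubElement(
            mesh_el, "Elements", type="hex8", name=f"{name}_part", mat=str(mat_id)
        )
        for eidx, conn in enumerate(mesh.elements, start=1):
            ET.SubElement(elems_el, "elem", id=str(eidx)).text = ",".join(
                str(c + 1 + node_offsets[name]) for c in conn
            )

    def surface(name: str, mesh: HexMesh, key: str, part: str) -> None:
        surf_el = ET.SubElement(mesh_el, "Surface", name=name)
        for fidx, quad in enumerate(mesh.surfaces[key], start=1):
            ET.SubElement(surf_el, "quad4", id=str(fidx)).text = ",".join(
                str(c + 1 + node_offsets[part]) for c in quad
            )

    surface("lens_back", lens_mesh, "bottom", "lens")
    surface("lens_front", lens_mesh, "top", "lens")
    surface("cornea_front", cornea_mesh, "top", "cornea")

    # lens "centre": innermost node ring on the back layer
    centre_el = ET.SubElement(mesh_el, "NodeSet", name="lens_centre")
    for j in range(params.lens_sectors):
        ET.SubElement(centre_el, "n", id=str(1 + j))  # i=0, k=0 nodes

    boundary = ET.SubElement(root, "Boundary")
    bc = ET.SubElement(boundary, "bc", type="fix", node_set="lens_centre")
    ET.SubElement(bc, "dofs").text = "x,y"

    rigid = ET.SubElement(root, "Rigid")
    rc = ET.SubElement(rigid, "rigid_constraint", name="fix_cornea", type="fix")
    ET.SubElement(rc, "rb").text = "2"
    ET.SubElement(rc, "dofs").text = "Rx,Ry,Rz,Ru,Rv,Rw"

    contact = ET.SubElement(root, "Contact")
    ct = ET.SubElement(
        contact, "contact", type="sliding-elastic", surface_pair="lens_on_cornea"
    )
    ET.SubElement(ct, "fric_coeff").text = f"{loads.friction_mu:.4g}"
    ET.SubElement(ct, "penalty").text = "1.0"
    ET.SubElement(ct, "auto_penalty").text = "1"
    pair = ET.SubElement(mesh_el, "SurfacePair", name="lens_on_cornea")
    ET.SubElement(pair, "primary").text = "lens_back"
    ET.SubElement(pair, "secondary").text = "cornea_front"

    loads_el = ET.SubElement(root, "Loads")
    for surf_name, pressure_pa, lc in (
        ("lens_back", loads.tear_pressure, 1),
        ("cornea_front", loads.tear_pressure, 1),
        ("lens_front", loads.eyelid_pressure, 2),
    ):
        sl = ET.SubElement(loads_el, "surface_load", type="pressure", surface=surf_name)
        ET.SubElement(sl, "pressure", lc=str(lc)).text = f"{pressure_pa * pa_to_mpa:.8g}"
        ET.SubElement(sl, "symmetric_stiffness").text = "1"

    # P1 ramps over the whole step; P2 comes in halfway through
    load_data = ET.SubElement(root, "LoadData")
    lc1 = ET.SubElement(load_data, "load_controller", id="1", type="loadcurve")
    ET.SubElement(lc1, "points").text = "0,0; 1,1"
    lc2 = ET.SubElement(load_data, "load_controller", id="2", type="loadcurve")
    ET.SubElement(lc2, "points").text = "0,0; 0.5,0; 1,1"

    ET.indent(root)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")
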