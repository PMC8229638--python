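"""Layered skin domain, fringing-field electrode variants and structured meshes.

The skin is a stack of three layers under the electrode plane: stratum corneum
(micrometres, hydration-dependent thickness), epidermis/dermis (1 mm) and
hypodermis (2 mm).  Three electrode variants are supported:

* ``circular_conductance`` -- concentric sensing disc and driving annulus in
  galvanic contact with the skin, solved in axisymmetric (r, z) coordinates;
* ``interdigitated_conductance`` -- alternating finger pairs in galvanic
  contact, solved on a planar (x, z) cross-section;
* ``interdigitated_capacitance`` -- the same finger layout on top of a thin
  insulating film (capacitive coupling).

Meshes are structured: tensor-product point sets graded toward the electrode
edges (where the field is singular) and toward layer interfaces, triangulated
into right triangles.  Geometry is stored in metres internally; millimetres and
micrometres appear only at the API surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .sc_hydration import (
    DEFAULT_MODEL,
    SorptionModel,
    equilibrium_thickness,
    equilibrium_water_concentration,
)

__all__ = [
    "REGION_SC",
    "REGION_ED",
    "REGION_HYP",
    "REGION_INS",
    "TAG_DRIVE",
    "TAG_SENSE",
    "SkinStack",
    "ElectrodeSpec",
    "Mesh",
    "circular_electrode",
    "interdigitated_electrode",
    "build_skin_stack",
    "generate_mesh",
    "ensure_domain_size",
    "graded_points",
    "build_rect_mesh",
    "write_vtk",
]

REGION_SC, REGION_ED, REGION_HYP, REGION_INS = 1, 2, 3, 4
TAG_DRIVE, TAG_SENSE = 1, 2

#: Default insulation film for the capacitance electrode: 25 um polyimide-like.
DEFAULT_INSULATION = (25.0, 3.4)     # (thickness um, relative permittivity)


@dataclass(frozen=True)
class SkinStack:
    """Layered skin domain under the electrode plane."""

    sc_thickness: float              # um
    ed_thickness: float = 1.0        # mm
    hyp_thickness: float = 2.0       # mm
    lateral_extent: float = 12.0     # mm (half-width for planar, radius for axisym)
    Cw: float = 0.0                  # g/cm^3, bound to the SC dielectric model

    def __post_init__(self) -> None:
        for name in ("sc_thickness", "ed_thickness", "hyp_thickness", "lateral_extent"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SkinStack.{name} must be positive")


@dataclass(frozen=True)
class ElectrodeSpec:
    """One electrode variant with its dimension parameters (mm)."""

    variant: str
    # circular
    rs: float = 0.0
    d: float = 0.0
    r_drive_inner: float = 0.0
    r_drive_outer: float = 0.0
    # interdigitated
    w: float = 0.0
    n_fingers: int = 0
    finger_length: float = 5.0
    insulation: tuple[float, float] | None = None   # (thickness um, eps_r)
    excitation: float = 1.0                          # potential difference, V

    VARIANTS = ("circular_conductance", "interdigitated_conductance",
                "interdigitated_capacitance")

    def __post_init__(self) -> None:
        if self.variant not in self.VARIANTS:
            raise ValueError(f"unknown electrode variant {self.variant!r}")
        if self.variant == "interdigitated_capacitance" and self.insulation is None:
            raise ValueError("capacitance electrode requires an insulation layer")
        if self.variant.endswith("conductance") and self.insulation is not None:
            raise ValueError("conductance electrodes must not carry insulation")

    @property
    def is_axisymmetric(self) -> bool:
        return self.variant == "circular_conductance"

    @property
    def device_halfwidth_mm(self) -> float:
        """Lateral footprint: outer radius (circular) or half device width."""
        if self.is_axisymmetric:
            return self.r_drive_outer
        n_tot = 2 * self.n_fingers
        return 0.5 * (n_tot * self.w + (n_tot - 1) * self.d)


def circular_electrode(rs: float, d: float, excitation: float = 1.0) -> ElectrodeSpec:
    """Concentric conductance electrode: sensing disc radius ``rs``, gap ``d`` (mm).

    The driving annulus starts at ``rs + d`` and its outer radius is chosen so
    that the annulus area equals the sensing-disc area:
    ``r_out = sqrt(rs^2 + (rs + d)^2)``.
    """
    if rs <= 0 or d <= 0:
        raise ValueError("rs and d must be positive")
    r_in = rs + d
    r_out = math.sqrt(rs * rs + r_in * r_in)
    return ElectrodeSpec(
        variant="circular_conductance", rs=rs, d=d,
        r_drive_inner=r_in, r_drive_outer=r_out, excitation=excitation,
    )


def interdigitated_electrode(
    w: float, d: float, n_fingers: int = 5, finger_length: float = 5.0,
    insulated: bool = False, insulation: tuple[float, float] = DEFAULT_INSULATION,
    excitation: float = 1.0,
) -> ElectrodeSpec:
    """Interdigitated finger electrode: width ``w``, gap ``d`` (mm).

    ``n_fingers`` counts fingers per electrode (driving and sensing alternate,
    so the pitch is ``w + d`` and total areas are equal by construction).
    """
    if w <= 0 or d <= 0 or finger_length <= 0:
        raise ValueError("w, d and finger_length must be positive")
    if n_fingers < 2:
        raise ValueError("need at least 2 fingers per electrode")
    variant = "interdigitated_capacitance" if insulated else "interdigitated_conductance"
    return ElectrodeSpec(
        variant=variant, w=w, d=d, n_fingers=int(n_fingers),
        finger_length=finger_length,
        insulation=insulation if insulated else None, excitation=excitation,
    )


def build_skin_stack(
    aw: float | None = None,
    Cw: float | None = None,
    constant_thickness: float | None = None,
    model: SorptionModel = DEFAULT_MODEL,
    ed_thickness: float = 1.0,
    hyp_thickness: float = 2.0,
    lateral_extent: float = 12.0,
) -> SkinStack:
    """Skin stack at a given hydration (activity ``aw`` or concentration ``Cw``).

    The SC thickness follows the equilibrium swelling relation unless
    ``constant_thickness`` (um) overrides it; the SC dielectric model is bound
    to the same ``Cw`` either way.
    """
    if (aw is None) == (Cw is None):
        raise ValueError("give exactly one of aw or Cw")
    if Cw is None:
        Cw = equilibrium_water_concentration(aw, model)
    sc = constant_thickness if constant_thickness is not None \
        else equilibrium_thickness(Cw, model)
    return SkinStack(sc_thickness=float(sc), ed_thickness=ed_thickness,
                     hyp_thickness=hyp_thickness, lateral_extent=lateral_extent,
                     Cw=float(Cw))


# ----------------------------------------------------------------------------
# Structured meshing
# ----------------------------------------------------------------------------

def graded_points(a: float, b: float, n: int, cluster: str = "none",
                  strength: float = 2.0) -> np.ndarray:
    """``n+1`` points on [a, b], optionally clustered toward one or both ends."""
    if n < 1:
        raise ValueError("n must be >= 1")
    u = np.linspace(0.0, 1.0, n + 1)
    t = math.tanh(strength)
    if cluster == "none":
        s = u
    elif cluster == "left":
        s = 1.0 + np.tanh(strength * (u - 1.0)) / t
    elif cluster == "right":
        s = np.tanh(strength * u) / t
    elif cluster == "both":
        s = 0.5 * (1.0 + np.tanh(strength * (2.0 * u - 1.0)) / t)
    else:
        raise ValueError(f"unknown cluster mode {cluster!r}")
    pts = a + (b - a) * s
    pts[0], pts[-1] = a, b
    return pts


@dataclass
class Mesh:
    """Conforming triangle mesh with region and electrode-boundary tags."""

    points: np.ndarray               # (n_pts, 2) in metres: (x|r, z)
    triangles: np.ndarray            # (n_tri, 3) int
    region: np.ndarray               # (n_tri,) int
    boundary_edges: np.ndarray       # (n_edges, 2) int, tagged edges only
    boundary_tag: np.ndarray         # (n_edges,) int
    axisymmetric: bool = False

    def nodes_with_tag(self, tag: int) -> np.ndarray:
        edges = self.boundary_edges[self.boundary_tag == tag]
        return np.unique(edges)

    @property
    def drive_nodes(self) -> np.ndarray:
        return self.nodes_with_tag(TAG_DRIVE)

    @property
    def sense_nodes(self) -> np.ndarray:
        return self.nodes_with_tag(TAG_SENSE)

    def triangle_areas(self) -> np.ndarray:
        p = self.points[self.triangles]
        v1 = p[:, 1] - p[:, 0]
        v2 = p[:, 2] - p[:, 0]
        return 0.5 * (v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])


def build_rect_mesh(
    xs: np.ndarray,
    zs: np.ndarray,
    region_of: Callable[[float, float], int],
    top_tag_of: Callable[[float], int] | None = None,
    edge_tag_of: Callable[[float, float, float, float], int] | None = None,
    axisymmetric: bool = False,
) -> Mesh:
    """Triangulate the tensor grid ``xs x zs`` into right triangles.

    ``region_of(x_mid, z_mid)`` assigns a region tag per cell.  Electrode edges
    are tagged either on the top line ``z = zs[0]`` through ``top_tag_of(x_mid)``
    or, for arbitrary fixtures, through ``edge_tag_of(x0, z0, x1, z1)`` applied
    to every boundary edge; a tag of 0 leaves the edge untagged (natural,
    insulating boundary).
    """
    xs = np.asarray(xs, dtype=float)
    zs = np.asarray(zs, dtype=float)
    nx, nz = len(xs), len(zs)
    X, Z = np.meshgrid(xs, zs, indexing="xy")
    points = np.column_stack([X.ravel(), Z.ravel()])

    def nid(i: int, j: int) -> int:
        return j * nx + i

    tris, regions = [], []
    for j in range(nz - 1):
        for i in range(nx - 1):
            n00, n10 = nid(i, j), nid(i + 1, j)
            n01, n11 = nid(i, j + 1), nid(i + 1, j + 1)
            xm = 0.5 * (xs[i] + xs[i + 1])
            zm = 0.5 * (zs[j] + zs[j + 1])
            tag = region_of(xm, zm)
            # alternate the diagonal for symmetry
            if (i + j) % 2 == 0:
                tris.append((n00, n10, n11))
                tris.append((n00, n11, n01))
            else:
                tris.append((n00, n10, n01))
                tris.append((n10, n11, n01))
            regions.extend((tag, tag))
    triangles = np.asarray(tris, dtype=np.int64)
    region = np.asarray(regions, dtype=np.int64)

    edges, tags = [], []
    if top_tag_of is not None:
        j = 0
        for i in range(nx - 1):
            tag = top_tag_of(0.5 * (xs[i] + xs[i + 1]))
            if tag:
                edges.append((nid(i, j), nid(i + 1, j)))
                tags.append(tag)
    if edge_tag_of is not None:
        for (i0, j0, i1, j1) in _boundary_index_edges(nx, nz):
            a, b = nid(i0, j0), nid(i1, j1)
            tag = edge_tag_of(points[a, 0], points[a, 1], points[b, 0], points[b, 1])
            if tag:
                edges.append((a, b))
                tags.append(tag)
    boundary_edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    boundary_tag = np.asarray(tags, dtype=np.int64)

    mesh = Mesh(points, triangles, region, boundary_edges, boundary_tag,
                axisymmetric=axisymmetric)
    areas = mesh.triangle_areas()
    if np.any(areas <= 0):
        raise ValueError("mesh contains non-positively oriented triangles")
    return mesh


def _boundary_index_edges(nx: int, nz: int):
    for i in range(nx - 1):                       # top and bottom rows
        yield (i, 0, i + 1, 0)
        yield (i, nz - 1, i + 1, nz - 1)
    for j in range(nz - 1):                       # left and right columns
        yield (0, j, 0, j + 1)
        yield (nx - 1, j, nx - 1, j + 1)


def _scaled(n: float, refinement: int) -> int:
    # slightly more than doubling per level so that the graded (tanh) spacing
    # near electrode edges at least halves with each refinement step
    return max(2, int(math.ceil(n * 2.2 ** (refinement - 1))))


def _z_points(stack: SkinStack, electrode: ElectrodeSpec, refinement: int) -> np.ndarray:
    """Vertical point distribution: optional insulator, SC, E/D, HYP (z down, m)."""
    sc = stack.sc_thickness * 1e-6
    ed = stack.ed_thickness * 1e-3
    hyp = stack.hyp_thickness * 1e-3
    segs: list[np.ndarray] = []
    z0 = 0.0
    if electrode.insulation is not None:
        t_ins = electrode.insulation[0] * 1e-6
        segs.append(graded_points(-t_ins, 0.0, _scaled(10, refinement), "none"))
        z0 = -t_ins
    segs.append(graded_points(0.0, sc, _scaled(6, refinement), "none"))
    segs.append(graded_points(sc, sc + ed, _scaled(14, refinement), "left", 3.0))
    segs.append(graded_points(sc + ed, sc + ed + hyp, _scaled(8, refinement), "left", 3.0))
    zs = np.unique(np.concatenate(segs))
    return zs


def _region_fn(stack: SkinStack, electrode: ElectrodeSpec):
    sc = stack.sc_thickness * 1e-6
    ed = stack.ed_thickness * 1e-3

    def region_of(x: float, z: float) -> int:
        if z < 0.0:
            return REGION_INS
        if z < sc:
            return REGION_SC
        if z < sc + ed:
            return REGION_ED
        return REGION_HYP

    return region_of


def _electrode_intervals_mm(electrode: ElectrodeSpec) -> tuple[list, list]:
    """(drive, sense) lists of lateral intervals in mm (x from 0 for planar)."""
    if electrode.is_axisymmetric:
        sense = [(0.0, electrode.rs)]
        drive = [(electrode.r_drive_inner, electrode.r_drive_outer)]
        return drive, sense
    drive, sense = [], []
    x = 0.0
    for i in range(2 * electrode.n_fingers):
        iv = (x, x + electrode.w)
        (drive if i % 2 == 0 else sense).append(iv)
        x += electrode.w + electrode.d
    return drive, sense


def _x_points(stack: SkinStack, electrode: ElectrodeSpec, refinement: int) -> np.ndarray:
    """Lateral point distribution (m): graded toward every electrode edge."""
    drive, sense = _electrode_intervals_mm(electrode)
    intervals = sorted(drive + sense)
    extent = stack.lateral_extent
    segs: list[np.ndarray] = []
    if electrode.is_axisymmetric:
        # [0, rs] [rs, rs+d] [r_in, r_out] [r_out, extent]
        rs, r_in, r_out = electrode.rs, electrode.r_drive_inner, electrode.r_drive_outer
        if extent <= r_out:
            raise ValueError("lateral extent smaller than the electrode footprint")
        segs.append(graded_points(0.0, rs, _scaled(12, refinement), "right", 2.5))
        segs.append(graded_points(rs, r_in, _scaled(8, refinement), "both", 2.0))
        segs.append(graded_points(r_in, r_out, _scaled(12, refinement), "both", 2.0))
        segs.append(graded_points(r_out, extent, _scaled(16, refinement), "left", 3.0))
    else:
        half_w = electrode.device_halfwidth_mm
        if extent <= half_w:
            raise ValueError("lateral extent smaller than the electrode footprint")
        margin = extent - half_w
        # device centred: shift intervals by -half_w so x spans [-extent, extent]
        shift = -half_w
        segs.append(graded_points(-extent, shift, _scaled(24, refinement), "right", 3.0))
        prev = shift
        for (a, b) in intervals:
            a, b = a + shift, b + shift
            if a > prev:
                segs.append(graded_points(prev, a, _scaled(10, refinement), "both", 2.0))
            segs.append(graded_points(a, b, _scaled(12, refinement), "both", 2.0))
            prev = b
        segs.append(graded_points(prev, extent, _scaled(24, refinement), "left", 3.0))
    xs = np.unique(np.concatenate(segs)) * 1e-3
    return xs


def generate_mesh(stack: SkinStack, electrode: ElectrodeSpec,
                  refinement: int = 1) -> Mesh:
    """Structured triangle mesh of the stack under the given electrode.

    Axisymmetric (r, z) half-plane for the circular variant, planar (x, z)
    cross-section for the interdigitated variants.  Element size is graded
    toward the electrode edges, where the surface current concentrates.
    """
    xs = _x_points(stack, electrode, refinement)
    zs = _z_points(stack, electrode, refinement)
    drive, sense = _electrode_intervals_mm(electrode)
    if not electrode.is_axisymmetric:
        shift = -electrode.device_halfwidth_mm
        drive = [(a + shift, b + shift) for (a, b) in drive]
        sense = [(a + shift, b + shift) for (a, b) in sense]
    drive_m = [(a * 1e-3, b * 1e-3) for (a, b) in drive]
    sense_m = [(a * 1e-3, b * 1e-3) for (a, b) in sense]

    def top_tag_of(x: float) -> int:
        for a, b in drive_m:
            if a < x < b:
                return TAG_DRIVE
        for a, b in sense_m:
            if a < x < b:
                return TAG_SENSE
        return 0

    return build_rect_mesh(
        xs, zs, _region_fn(stack, electrode), top_tag_of=top_tag_of,
        axisymmetric=electrode.is_axisymmetric,
    )


def ensure_domain_size(
    stack: SkinStack,
    electrode: ElectrodeSpec,
    capacitance_of: Callable[[SkinStack, ElectrodeSpec], float],
    tol: float = 0.01,
    factor: float = 1.5,
    max_steps: int = 8,
) -> SkinStack:
    """Grow the lateral extent until the insulated outer boundary is innocuous.

    Applies the 1 %-influence rule: the extent is enlarged by ``factor`` until
    the capacitance changes by less than ``tol`` between successive sizes.
    """
    c_prev = capacitance_of(stack, electrode)
    current = stack
    for _ in range(max_steps):
        bigger = replace(current, lateral_extent=current.lateral_extent * factor)
        c_next = capacitance_of(bigger, electrode)
        if abs(c_next - c_prev) <= tol * abs(c_next):
            return current
        current, c_prev = bigger, c_next
    raise RuntimeError("domain size did not converge within the enlargement budget")


def write_vtk(mesh: Mesh, path: str,
              point_data: dict[str, np.ndarray] | None = None,
              cell_data: dict[str, np.ndarray] | None = None) -> None:
    """Write the mesh (plus optional fields) as a legacy-ASCII VTK file."""
    pts = mesh.points
    tris = mesh.triangles
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncornesim mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(pts)} double\n")
        for x, z in pts:
            fh.write(f"{x:.9e} {z:.9e} 0.0\n")
        fh.write(f"CELLS {len(tris)} {4 * len(tris)}\n")
        for t in tris:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        fh.write(f"CELL_TYPES {len(tris)}\n")
        fh.write("\n".join(["5"] * len(tris)) + "\n")
        if cell_data or True:
            fh.write(f"CELL_DATA {len(tris)}\n")
            fh.write("SCALARS region int 1\nLOOKUP_TABLE default\n")
            fh.write("\n".join(str(int(r)) for r in mesh.region) + "\n")
            for name, arr in (cell_data or {}).items():
                _write_scalar(fh, name, np.asarray(arr))
        if point_data:
            fh.write(f"POINT_DATA {len(pts)}\n")
            for name, arr in point_data.items():
                _write_scalar(fh, name, np.asarray(arr))


def _write_scalar(fh, name: str, arr: np.ndarray) -> None:
    if np.iscomplexobj(arr):
        _write_scalar(fh, name + "_re", arr.real)
        _write_scalar(fh, name + "_im", arr.imag)
        return
    if arr.ndim == 1:
        fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(f"{v:.9e}" for v in arr) + "\n")
    else:
        fh.write(f"VECTORS {name} double\n")
        for row in arr:
            vec = list(row) + [0.0] * (3 - len(row))
            fh.write(" ".join(f"{v:.9e}" for v in vec) + "\n")
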