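"""Complex quasi-static field solver: admittance, capacitance and current density.

At device scales far below the signal wavelength the field is curl-free and the
complex current density ``J = sigma* E`` obeys charge conservation
``div(sigma*(f) grad V) = 0`` with the complex conductivity
``sigma*(f) = j w eps0 eps_r(f)`` (the DC conductivity rides inside ``eps_r``).
Electrodes are equipotential boundary segments at ``+V/2`` and ``-V/2``; every
other boundary is insulating (``n . J = 0``).

First-order (P1) triangular elements on the structured meshes from
:mod:`cornesim.geometry`; the sparse complex-symmetric system is solved with a
direct factorization.  The admittance is extracted from the Dirichlet reaction
(the consistent discrete boundary current), with the unconjugated energy
functional available as a cross-check; then ``C = Im(Y)/w`` and ``G = Re(Y)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .dielectric_models import (
    DEFAULT_BETAS,
    SCDielectricBetas,
    complex_conductivity,
    cole_cole_permittivity,
    layer_params,
    sc_permittivity,
)
from .geometry import (
    REGION_ED,
    REGION_HYP,
    REGION_INS,
    REGION_SC,
    ElectrodeSpec,
    Mesh,
    SkinStack,
    generate_mesh,
)

__all__ = [
    "MaterialMap",
    "FieldSolution",
    "skin_material_map",
    "assemble",
    "solve_field",
    "electrode_admittance",
    "electrode_capacitance",
    "current_density_field",
]


@dataclass(frozen=True)
class MaterialMap:
    """Region tag -> complex conductivity ``sigma*(f)`` (S/m)."""

    materials: Mapping[int, Callable[[float], complex]]

    def sigma(self, tag: int, f: float) -> complex:
        try:
            return complex(self.materials[tag](f))
        except KeyError:
            raise KeyError(f"no material bound to region tag {tag}") from None


def skin_material_map(stack: SkinStack, electrode: ElectrodeSpec,
                      betas: SCDielectricBetas = DEFAULT_BETAS) -> MaterialMap:
    """Bind the hydration-dependent SC and the fixed deep layers to their regions."""
    Cw = stack.Cw
    mats: dict[int, Callable[[float], complex]] = {
        REGION_SC: lambda f: complex_conductivity(sc_permittivity(Cw, f, betas), f),
        REGION_ED: lambda f: complex_conductivity(
            cole_cole_permittivity(layer_params("E/D"), f), f),
        REGION_HYP: lambda f: complex_conductivity(
            cole_cole_permittivity(layer_params("HYP"), f), f),
    }
    if electrode.insulation is not None:
        eps_ins = electrode.insulation[1]
        mats[REGION_INS] = lambda f: complex_conductivity(eps_ins + 0.0j, f)
    return MaterialMap(mats)


@dataclass
class System:
    """Assembled linear system with its Dirichlet data."""

    mesh: Mesh
    K: sp.csr_matrix                 # full (unconstrained) stiffness
    f: float
    drive: float                     # potential difference V
    sigma_tri: np.ndarray            # per-element sigma*
    length_scale: float = 1.0        # out-of-plane factor (finger length, m)


@dataclass
class FieldSolution:
    """Solved complex potential with derived lumped quantities."""

    f: float
    potential: np.ndarray            # complex per node, V
    Y: complex                       # S
    C: float                         # F
    G: float                         # S
    mesh: Mesh
    sigma_tri: np.ndarray
    Y_energy: complex = 0.0j         # energy-functional cross-check

    def __post_init__(self) -> None:
        if self.G < 0 and abs(self.G) > 1e-12 * abs(self.Y):
            raise ValueError("negative conductance: passivity violated")


def _p1_gradients(points: np.ndarray, triangles: np.ndarray):
    p = points[triangles]                       # (nt, 3, 2)
    x, z = p[..., 0], p[..., 1]
    b = np.stack([z[:, 1] - z[:, 2], z[:, 2] - z[:, 0], z[:, 0] - z[:, 1]], axis=1)
    c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    area2 = x[:, 0] * b[:, 0] + x[:, 1] * b[:, 1] + x[:, 2] * b[:, 2]
    area = 0.5 * area2
    grads = np.stack([b, c], axis=2) / area2[:, None, None]   # (nt, 3, 2)
    return grads, area


def assemble(mesh: Mesh, materials: MaterialMap, f: float,
             drive: float = 1.0, length_scale: float = 1.0) -> System:
    """Assemble the P1 Galerkin system for ``div(sigma* grad V) = 0``.

    The axisymmetric variant weights each element by ``2 pi r`` at the
    centroid; planar variants assemble per unit out-of-plane length and scale
    the admittance by ``length_scale`` afterwards.
    """
    if f <= 0:
        raise ValueError("frequency must be positive")
    tags = np.unique(mesh.region)
    sigma_by_tag = {int(t): materials.sigma(int(t), f) for t in tags}
    sigma_tri = np.array([sigma_by_tag[int(t)] for t in mesh.region])

    grads, area = _p1_gradients(mesh.points, mesh.triangles)
    weight = area.astype(complex)
    if mesh.axisymmetric:
        r_c = mesh.points[mesh.triangles, 0].mean(axis=1)
        weight = weight * (2.0 * np.pi * r_c)
    coef = sigma_tri * weight                               # (nt,)

    local = np.einsum("tid,tjd->tij", grads, grads)          # (nt, 3, 3)
    vals = (coef[:, None, None] * local).ravel()
    rows = np.repeat(mesh.triangles, 3, axis=1).ravel()
    cols = np.tile(mesh.triangles, (1, 3)).ravel()
    n = len(mesh.points)
    K = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return System(mesh=mesh, K=K, f=f, drive=drive,
                  sigma_tri=sigma_tri, length_scale=length_scale)


def solve_field(system: System) -> FieldSolution:
    """Solve for the complex potential and extract Y, C, G.

    The drive electrode is held at ``+V/2``, the sense electrode at ``-V/2``.
    The admittance is the Dirichlet reaction current through the sensing
    electrode divided by the potential difference.
    """
    mesh, K = system.mesh, system.K
    n = K.shape[0]
    drive_nodes = mesh.drive_nodes
    sense_nodes = mesh.sense_nodes
    if len(drive_nodes) == 0 or len(sense_nodes) == 0:
        raise ValueError("mesh lacks drive or sense electrode boundaries")
    V = system.drive
    u = np.zeros(n, dtype=complex)
    u[drive_nodes] = +0.5 * V
    u[sense_nodes] = -0.5 * V
    fixed = np.zeros(n, dtype=bool)
    fixed[drive_nodes] = True
    fixed[sense_nodes] = True
    free = ~fixed

    K_ff = K[free][:, free].tocsc()
    rhs = -K[free][:, fixed] @ u[fixed]
    lu = spla.splu(K_ff)
    u_free = lu.solve(rhs)
    u[free] = u_free
    res = np.linalg.norm(K_ff @ u_free - rhs) / max(np.linalg.norm(rhs), 1e-300)
    if res > 1e-8:
        raise RuntimeError(f"direct solve residual too large: {res:.2e}")

    reaction = K @ u
    I_drive = complex(reaction[drive_nodes].sum())
    I_sense = complex(reaction[sense_nodes].sum())
    # current leaving the drive electrode into the domain equals the reaction
    Y = 0.5 * (I_drive - I_sense) / V * system.length_scale
    Y_energy = complex(u @ (K @ u)) / V**2 * system.length_scale
    w = 2.0 * np.pi * system.f
    return FieldSolution(
        f=system.f, potential=u, Y=Y, C=float(Y.imag / w), G=float(Y.real),
        mesh=mesh, sigma_tri=system.sigma_tri, Y_energy=Y_energy,
    )


def current_density_field(solution: FieldSolution):
    """Per-element complex current density ``J = -sigma* grad V`` and centroids."""
    mesh = solution.mesh
    grads, _ = _p1_gradients(mesh.points, mesh.triangles)
    gradV = np.einsum("tid,ti->td", grads, solution.potential[mesh.triangles])
    J = -solution.sigma_tri[:, None] * gradV
    centroids = mesh.points[mesh.triangles].mean(axis=1)
    return centroids, J


def export_field(solution: FieldSolution, path: str) -> None:
    """Write mesh, complex nodal potential and element current density (VTK)."""
    from .geometry import write_vtk
    _, J = current_density_field(solution)
    write_vtk(solution.mesh, path,
              point_data={"potential": solution.potential},
              cell_data={"current_density": J})


def electrode_admittance(
    stack: SkinStack,
    electrode: ElectrodeSpec,
    f: float,
    refinement: int = 1,
    betas: SCDielectricBetas = DEFAULT_BETAS,
    mesh: Mesh | None = None,
) -> FieldSolution:
    """Convenience composition: stack -> mesh -> materials -> solve at ``f``."""
    if mesh is None:
        mesh = generate_mesh(stack, electrode, refinement)
    materials = skin_material_map(stack, electrode, betas)
    length = electrode.finger_length * 1e-3 if not electrode.is_axisymmetric else 1.0
    system = assemble(mesh, materials, f, drive=electrode.excitation,
                      length_scale=length)
    return solve_field(system)


def electrode_capacitance(
    stack_or_aw,
    electrode: ElectrodeSpec,
    f: float,
    refinement: int = 1,
    constant_thickness: float | None = None,
    betas: SCDielectricBetas = DEFAULT_BETAS,
) -> float:
    """Capacitance (F) of an electrode on skin at a given hydration.

    ``stack_or_aw`` is either a prepared :class:`SkinStack` or a water activity,
    in which case the stack is built from the equilibrium sorption chain (with
    an optional constant-thickness override).
    """
    from .geometry import build_skin_stack
    if isinstance(stack_or_aw, SkinStack):
        stack = stack_or_aw
    else:
        stack = build_skin_stack(aw=float(stack_or_aw),
                                 constant_thickness=constant_thickness)
    return electrode_admittance(stack, electrode, f, refinement, betas).C
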