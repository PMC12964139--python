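"""Time-harmonic anisotropic viscoelastic wave solver on the voxel grid.

Solves div(C(x):grad u) + rho omega^2 u = 0 for the complex steady-state
displacement phasor u at the drive frequency, with prescribed (Dirichlet)
displacement on an actuation patch and traction-free boundaries elsewhere.
Material properties live on the voxel (element) grid; displacements on
the node grid (one more sample per axis).

Discretization: trilinear hexahedral voxel elements with 2x2x2 Gauss
integration of the deviatoric stiffness and single-point integration of
the volumetric (bulk-modulus) term — selective reduced integration, the
standard cure for volumetric locking of low-order elements in the
nearly incompressible regime.  Mass is lumped.  The complex symmetric
system is solved with a direct sparse LU factorization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .material import NITIVolume, PhysicsConstants, niti_voigt_batch

__all__ = [
    "ActuationSpec",
    "DisplacementField",
    "VoxelGrid",
    "solve_timeharmonic",
    "simulate_multi_excitation",
    "default_actuations",
]

_GAUSS = 1.0 / np.sqrt(3.0)
# local node offsets (i, j, k), C-order consistent with ravel of the node grid
_NODE_OFFSETS = np.array(
    [(0, 0, 0), (0, 0, 1), (0, 1, 0), (0, 1, 1), (1, 0, 0), (1, 0, 1), (1, 1, 0), (1, 1, 1)]
)


@dataclass
class ActuationSpec:
    """One excitation: boundary patch with a prescribed complex displacement."""

    excitation: str
    patch: np.ndarray  # boolean node-grid mask
    amplitude: np.ndarray  # complex 3-vector, meters
    frequency: float = 50.0

    def __post_init__(self) -> None:
        self.patch = np.asarray(self.patch, dtype=bool)
        self.amplitude = np.asarray(self.amplitude, dtype=complex)
        if self.amplitude.shape != (3,):
            raise ValueError("amplitude must be a complex 3-vector")
        if self.frequency <= 0:
            raise ValueError("frequency must be > 0")
        if not self.patch.any():
            raise ValueError("actuation patch is empty")

    def validate_on_boundary(self) -> None:
        interior = np.zeros_like(self.patch)
        interior[1:-1, 1:-1, 1:-1] = True
        if np.any(self.patch & interior):
            raise ValueError("actuation patch must lie on the domain boundary")


@dataclass
class DisplacementField:
    """Complex 3-vector displacement per node, meters."""

    data: np.ndarray  # (nx, ny, nz, 3) complex
    spacing_m: float
    frequency: float
    excitation: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 4 or self.data.shape[-1] != 3:
            raise ValueError("displacement data must have shape (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("displacement field contains non-finite values")

    @property
    def grid_shape(self) -> Tuple[int, int, int]:
        return self.data.shape[:3]

    def amplitude(self) -> np.ndarray:
        return np.linalg.norm(np.abs(self.data), axis=-1)


def _shape_gradients(h: float) -> Tuple[np.ndarray, np.ndarray]:
    """Trilinear shape-function gradients at the 8 Gauss points and the center.

    Returns (dN8, dN1): arrays of shape (8, 8, 3) and (1, 8, 3) —
    (quadrature point, local node, derivative axis), physical units 1/m.
    """
    signs = _NODE_OFFSETS * 2 - 1  # node corner signs in (-1, 1)^3

    def grads(points):
        out = np.empty((len(points), 8, 3))
        for q, xi in enumerate(points):
            for a in range(8):
                s = signs[a]
                out[q, a, 0] = s[0] * (1 + s[1] * xi[1]) * (1 + s[2] * xi[2]) / 8.0
                out[q, a, 1] = (1 + s[0] * xi[0]) * s[1] * (1 + s[2] * xi[2]) / 8.0
                out[q, a, 2] = (1 + s[0] * xi[0]) * (1 + s[1] * xi[1]) * s[2] / 8.0
        return out * (2.0 / h)  # d xi / dx

    gp = np.array([s * _GAUSS for s in signs], dtype=float)
    return grads(gp), grads(np.zeros((1, 3)))


def _b_matrices(dN: np.ndarray) -> np.ndarray:
    """Strain-displacement matrices, shape (nq, 6, 24); engineering Voigt."""
    nq = dN.shape[0]
    B = np.zeros((nq, 6, 24))
    for a in range(8):
        cx, cy, cz = 3 * a, 3 * a + 1, 3 * a + 2
        B[:, 0, cx] = dN[:, a, 0]
        B[:, 1, cy] = dN[:, a, 1]
        B[:, 2, cz] = dN[:, a, 2]
        B[:, 3, cy] = dN[:, a, 2]
        B[:, 3, cz] = dN[:, a, 1]
        B[:, 4, cx] = dN[:, a, 2]
        B[:, 4, cz] = dN[:, a, 0]
        B[:, 5, cx] = dN[:, a, 1]
        B[:, 5, cy] = dN[:, a, 0]
    return B


class VoxelGrid:
    """Geometry, quadrature and dof bookkeeping for a voxel-element mesh."""

    def __init__(self, elem_shape: Tuple[int, int, int], spacing_m: float):
        self.elem_shape = tuple(int(s) for s in elem_shape)
        self.node_shape = tuple(s + 1 for s in self.elem_shape)
        self.h = float(spacing_m)
        self.n_elems = int(np.prod(self.elem_shape))
        self.n_nodes = int(np.prod(self.node_shape))
        dN8, dN1 = _shape_gradients(self.h)
        self.B8 = _b_matrices(dN8)  # (8, 6, 24)
        self.B1 = _b_matrices(dN1)  # (1, 6, 24)
        self.w8 = (self.h / 2.0) ** 3  # Gauss weight x |J| per point
        self.w1 = self.h**3

        ex, ey, ez = np.meshgrid(*[np.arange(s) for s in self.elem_shape], indexing="ij")
        corners = np.stack([ex, ey, ez], axis=-1).reshape(-1, 1, 3) + _NODE_OFFSETS[None]
        node_idx = np.ravel_multi_index(
            (corners[..., 0], corners[..., 1], corners[..., 2]), self.node_shape
        )  # (n_elems, 8)
        self.edofs = (3 * node_idx[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 24)

    def element_matrices(self, C: np.ndarray, bulk_modulus: float) -> np.ndarray:
        """Element stiffness (n_elems, 24, 24) with SRI on the bulk term."""
        C_vol = np.zeros((6, 6))
        C_vol[:3, :3] = float(bulk_modulus)
        C_dev = C - C_vol[None]
        Ke = np.zeros((C.shape[0], 24, 24), dtype=complex)
        for q in range(8):
            Bq = self.B8[q]
            Ke += self.w8 * np.matmul(Bq.T[None], np.matmul(C_dev, Bq[None]))
        B0 = self.B1[0]
        Ke += (self.w1 * (B0.T @ C_vol @ B0))[None]
        return Ke

    def assemble(self, C: np.ndarray, constants: PhysicsConstants) -> sp.csr_matrix:
        """Global matrix A = K(C) - omega^2 M (lumped mass)."""
        Ke = self.element_matrices(C, constants.bulk_modulus)
        rows = np.repeat(self.edofs, 24, axis=1).ravel()
        cols = np.tile(self.edofs, (1, 24)).ravel()
        A = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(3 * self.n_nodes,) * 2).tocsr()
        m = np.zeros(3 * self.n_nodes)
        np.add.at(m, self.edofs.ravel(), constants.density * self.h**3 / 8.0)
        A -= sp.diags(constants.omega**2 * m)
        return A

    def element_strains(self, u_flat: np.ndarray) -> np.ndarray:
        """Strains at the 8 Gauss points: (n_elems, 8, 6)."""
        ue = u_flat[self.edofs]  # (n_elems, 24)
        return np.einsum("qca,ea->eqc", self.B8, ue)


def _stiffness_voigt(properties: NITIVolume, constants: PhysicsConstants) -> np.ndarray:
    return niti_voigt_batch(
        np.ravel(properties.mu2_storage),
        np.ravel(properties.mu2_loss),
        np.ravel(properties.phi),
        np.ravel(properties.zeta),
        properties.fibers.reshape(-1, 3),
        constants.bulk_modulus,
    )


def solve_dirichlet(
    A: sp.csr_matrix,
    dirichlet_mask: np.ndarray,
    dirichlet_values: np.ndarray,
    residual_tol: float = 1e-8,
) -> np.ndarray:
    """Solve A u = 0 with prescribed values on masked dofs; returns full u."""
    free = ~dirichlet_mask
    u = np.zeros(A.shape[0], dtype=complex)
    u[dirichlet_mask] = dirichlet_values
    b = -A[free][:, dirichlet_mask] @ dirichlet_values
    if np.linalg.norm(b) == 0.0:
        return u
    Aff = A[free][:, free].tocsc()
    lu = spla.splu(Aff)
    uf = lu.solve(b)
    rel = np.linalg.norm(Aff @ uf - b) / np.linalg.norm(b)
    if rel > residual_tol:
        raise RuntimeError(
            f"direct solve residual {rel:.2e} exceeds {residual_tol:.0e}; "
            "system may be singular (e.g., undamped resonance)"
        )
    u[free] = uf
    return u


def solve_timeharmonic(
    properties: NITIVolume,
    constants: PhysicsConstants,
    actuation: ActuationSpec,
    spacing_m: float = 2.0e-3,
) -> DisplacementField:
    """Solve one excitation's steady-state wave field on the phantom grid."""
    elem_shape = properties.shape
    grid = VoxelGrid(elem_shape, spacing_m)
    if actuation.patch.shape != grid.node_shape:
        raise ValueError(
            f"actuation patch shape {actuation.patch.shape} must match node grid {grid.node_shape}"
        )
    actuation.validate_on_boundary()
    consts = PhysicsConstants(constants.density, actuation.frequency, constants.bulk_modulus)
    C = _stiffness_voigt(properties, consts)
    A = grid.assemble(C, consts)

    dmask = np.repeat(actuation.patch.ravel(), 3)
    n_patch = int(actuation.patch.sum())
    dvals = np.tile(actuation.amplitude, n_patch)
    u = solve_dirichlet(A, dmask, dvals)
    return DisplacementField(
        data=u.reshape(grid.node_shape + (3,)),
        spacing_m=spacing_m,
        frequency=actuation.frequency,
        excitation=actuation.excitation,
    )


def simulate_multi_excitation(
    properties: NITIVolume,
    constants: PhysicsConstants,
    actuations: Iterable[ActuationSpec],
    spacing_m: float = 2.0e-3,
) -> Dict[str, DisplacementField]:
    """Independent solves of the same property volume for each excitation."""
    specs = list(actuations)
    ids = [a.excitation for a in specs]
    if len(set(ids)) != len(ids):
        raise ValueError(f"excitation ids must be distinct, got {ids}")
    return {a.excitation: solve_timeharmonic(properties, constants, a, spacing_m) for a in specs}


def default_actuations(
    node_shape: Tuple[int, int, int],
    amplitude_m: float = 10e-6,
    frequency: float = 50.0,
) -> Dict[str, ActuationSpec]:
    """AP (pillow, mainly along y) and LR (temple bottle, mainly along x) patches.

    The physical drive amplitude is not critical — the problem is linear —
    and defaults to 10 microns, a typical brain MRE displacement scale.
    Each drive carries a 40% superior-inferior component: skull-coupled
    actuators never produce purely uniaxial motion, and the oblique
    polarization excites fiber-parallel shear, improving the
    identifiability of the shear anisotropy.
    """
    nx, ny, nz = node_shape

    def central(n):
        return slice(round(0.25 * n), round(0.75 * n) + 1)

    ap = np.zeros(node_shape, dtype=bool)
    ap[central(nx), 0, central(nz)] = True
    lr = np.zeros(node_shape, dtype=bool)
    lr[0, central(ny), central(nz)] = True
    a = amplitude_m
    return {
        "AP": ActuationSpec("AP", ap, np.array([0.0, a, 0.4 * a], dtype=complex), frequency),
        "LR": ActuationSpec("LR", lr, np.array([a, 0.0, 0.4 * a], dtype=complex), frequency),
    }
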