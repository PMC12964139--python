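"""Nearly incompressible transversely isotropic (NITI) material model.

White matter is modeled as a fibrous solid with a single symmetry axis
(the local axon direction).  Three parameters describe the mechanics:

* the complex substrate shear modulus ``G2 = G' + iG''`` measured
  perpendicular to the fibers,
* the shear anisotropy ``phi = G1/G2 - 1`` (fractional excess of the
  fiber-parallel shear modulus), and
* the tensile anisotropy ``zeta = E1/E2 - 1`` (fractional excess of the
  fiber-parallel Young's modulus).

Near-incompressibility is imposed through a large real bulk modulus.
Damping is "isotropic" in the sense that the anisotropy ratios apply
identically to the storage and loss parts of the stiffness tensor, so a
single loss ratio ``G''/G'`` scales the whole deviatoric response.

The full stiffness tensor is constructed from engineering constants
``{E2, E1 = E2(1+zeta), G2, G1 = G2(1+phi), nu}`` through the standard
transversely isotropic compliance matrix, with ``E2`` tied to ``G2`` by
the isotropic relation so that ``phi = zeta = 0`` reproduces isotropic
elasticity exactly.  The exact volumetric coupling of the anisotropy
parameters is not uniquely pinned down by the three-parameter
description; this compliance-matrix construction is the documented
choice of this package (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ComplexShearModulus",
    "NITIParameters",
    "PhysicsConstants",
    "ElasticityTensor",
    "NITIVolume",
    "assemble_stiffness",
    "niti_voigt_batch",
    "shear_stiffness",
    "storage_from_stiffness",
    "parallel_stiffness",
    "wave_speeds",
    "rotation_to_axis",
    "voigt_to_tensor",
    "tensor_to_voigt",
    "rotate_voigt",
]

_UNIT_TOL = 1e-9


@dataclass(frozen=True)
class ComplexShearModulus:
    """Complex shear modulus G = storage + 1j * loss, in Pa."""

    storage: float
    loss: float = 0.0

    def __post_init__(self) -> None:
        if not self.storage > 0:
            raise ValueError(f"storage modulus must be > 0 Pa, got {self.storage}")
        if self.loss < 0:
            raise ValueError(f"loss modulus must be >= 0 Pa, got {self.loss}")

    @property
    def complex(self) -> complex:
        return complex(self.storage, self.loss)

    @property
    def magnitude(self) -> float:
        return abs(self.complex)


@dataclass(frozen=True)
class NITIParameters:
    """Per-voxel NITI description: substrate modulus, anisotropies, fiber axis."""

    mu2: ComplexShearModulus
    phi: float
    zeta: float
    fiber: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        if not self.phi > -1:
            raise ValueError(f"phi must be > -1 so that G1 > 0, got {self.phi}")
        if not self.zeta > -0.7:
            raise ValueError(
                f"zeta must be > -0.7 (near-incompressible TI positive definiteness), got {self.zeta}"
            )
        f = np.asarray(self.fiber, dtype=float)
        if f.shape != (3,):
            raise ValueError("fiber must be a 3-vector")
        if abs(np.linalg.norm(f) - 1.0) > _UNIT_TOL:
            raise ValueError(
                f"fiber must be unit length within {_UNIT_TOL}, got norm {np.linalg.norm(f)}"
            )
        object.__setattr__(self, "fiber", f)


@dataclass(frozen=True)
class PhysicsConstants:
    """Shared physical constants: density, drive frequency, bulk modulus.

    Density defaults to the soft-tissue convention 1000 kg/m^3; the bulk
    modulus is a near-incompressibility surrogate and should exceed
    1000x the shear-modulus magnitude wherever it is applied.
    """

    density: float = 1000.0
    frequency: float = 50.0
    bulk_modulus: float = 1.0e7

    def __post_init__(self) -> None:
        if not self.density > 0:
            raise ValueError(f"density must be > 0, got {self.density}")
        if not self.frequency > 0:
            raise ValueError(f"frequency must be > 0, got {self.frequency}")
        if not self.bulk_modulus > 0:
            raise ValueError(f"bulk_modulus must be > 0, got {self.bulk_modulus}")

    @property
    def omega(self) -> float:
        return 2.0 * np.pi * self.frequency


@dataclass(frozen=True)
class ElasticityTensor:
    """6x6 complex stiffness matrix in Voigt notation (engineering strains), Pa."""

    voigt: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.voigt, dtype=complex)
        if v.shape != (6, 6):
            raise ValueError("Voigt stiffness must be 6x6")
        object.__setattr__(self, "voigt", v)

    def tensor(self) -> np.ndarray:
        return voigt_to_tensor(self.voigt)


@dataclass
class NITIVolume:
    """Voxelwise NITI parameter fields on a regular grid.

    ``mu2_storage``/``mu2_loss`` are G' and G'' in Pa, ``phi`` and
    ``zeta`` dimensionless, ``fibers`` unit 3-vectors with a trailing
    axis of length 3.  All arrays share the leading grid shape.
    """

    mu2_storage: np.ndarray
    mu2_loss: np.ndarray
    phi: np.ndarray
    zeta: np.ndarray
    fibers: np.ndarray

    def __post_init__(self) -> None:
        shp = np.shape(self.mu2_storage)
        for name in ("mu2_loss", "phi", "zeta"):
            if np.shape(getattr(self, name)) != shp:
                raise ValueError(f"{name} shape {np.shape(getattr(self, name))} != {shp}")
        if np.shape(self.fibers) != shp + (3,):
            raise ValueError("fibers must have shape grid + (3,)")
        if np.any(np.asarray(self.mu2_storage) <= 0):
            raise ValueError("mu2_storage must be > 0 everywhere")

    @property
    def shape(self) -> tuple:
        return np.shape(self.mu2_storage)


# ---------------------------------------------------------------------------
# Voigt algebra helpers

_VOIGT_PAIRS = [(0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1)]
_V_INDEX = np.empty((3, 3), dtype=int)
for _a, (_i, _j) in enumerate(_VOIGT_PAIRS):
    _V_INDEX[_i, _j] = _a
    _V_INDEX[_j, _i] = _a


def voigt_to_tensor(C: np.ndarray) -> np.ndarray:
    """Voigt 6x6 stiffness (engineering strain convention) -> full C_ijkl."""
    C = np.asarray(C)
    T = np.empty(C.shape[:-2] + (3, 3, 3, 3), dtype=C.dtype)
    for i in range(3):
        for j in range(3):
            for k in range(3):
                for l in range(3):
                    T[..., i, j, k, l] = C[..., _V_INDEX[i, j], _V_INDEX[k, l]]
    return T


def tensor_to_voigt(T: np.ndarray) -> np.ndarray:
    T = np.asarray(T)
    C = np.empty(T.shape[:-4] + (6, 6), dtype=T.dtype)
    for a, (i, j) in enumerate(_VOIGT_PAIRS):
        for b, (k, l) in enumerate(_VOIGT_PAIRS):
            C[..., a, b] = T[..., i, j, k, l]
    return C


def rotate_voigt(C: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Rotate a (batched) Voigt stiffness by rotation matrices R (batched)."""
    T = voigt_to_tensor(C)
    T = np.einsum("...ia,...abcd->...ibcd", R, T)
    T = np.einsum("...jb,...ibcd->...ijcd", R, T)
    T = np.einsum("...kc,...ijcd->...ijkd", R, T)
    T = np.einsum("...ld,...ijkd->...ijkl", R, T)
    return tensor_to_voigt(T)


def rotation_to_axis(fiber: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping the z axis onto ``fiber`` (batched over leading axes)."""
    f = np.asarray(fiber, dtype=float)
    single = f.ndim == 1
    f = np.atleast_2d(f)
    z = np.array([0.0, 0.0, 1.0])
    R = np.empty(f.shape[:-1] + (3, 3))
    c = f @ z  # cos(angle)
    v = np.cross(np.broadcast_to(z, f.shape), f)
    s = np.linalg.norm(v, axis=-1)
    # Rodrigues formula; degenerate parallel / antiparallel handled explicitly.
    eye = np.eye(3)
    for idx in np.ndindex(f.shape[:-1]):
        if s[idx] < 1e-12:
            if c[idx] > 0:
                R[idx] = eye
            else:
                R[idx] = np.diag([1.0, -1.0, -1.0])  # flip about x
            continue
        k = v[idx] / s[idx]
        K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        R[idx] = eye + s[idx] * K + (1 - c[idx]) * (K @ K)
    return R[0] if single else R


# ---------------------------------------------------------------------------
# Stiffness construction


def _check_admissible(mu2r, mu2i, phi, zeta, bulk) -> None:
    mu2r = np.asarray(mu2r, dtype=float)
    if np.any(mu2r <= 0):
        raise ValueError("mu2 storage must be > 0 Pa")
    if np.any(np.asarray(mu2i) < 0):
        raise ValueError("mu2 loss must be >= 0 Pa")
    if np.any(np.asarray(phi) <= -1):
        raise ValueError("phi must be > -1 (G1 = G2(1+phi) must stay positive)")
    if np.any(np.asarray(zeta) <= -0.7):
        # near-incompressibility forces E2 = 2 G2 (1 + nu12) with
        # nu12 ~ 1 - 1/(2(1+zeta)); the tensor loses positive
        # definiteness as zeta approaches -3/4
        raise ValueError(
            "zeta must be > -0.7: a nearly incompressible transversely "
            "isotropic solid is not positive definite beyond that bound"
        )
    gmag = np.abs(mu2r + 1j * np.asarray(mu2i))
    if np.any(bulk < 1000.0 * gmag):
        raise ValueError("bulk_modulus must be >= 1000 x |mu2| for near-incompressibility")


def niti_voigt_batch(
    mu2_storage: np.ndarray,
    mu2_loss: np.ndarray,
    phi: np.ndarray,
    zeta: np.ndarray,
    fibers: np.ndarray,
    bulk_modulus: float,
    validate: bool = True,
) -> np.ndarray:
    """Vectorized NITI stiffness: (N,) parameter arrays -> (N, 6, 6) complex Voigt.

    Construction (fiber along z, then rotated onto each voxel's fiber):
    Poisson ratio ``nu = (3K - 2G')/(2(3K + G'))`` from the bulk modulus,
    transversely isotropic compliance from the storage engineering
    constants, inverted to the storage stiffness ``C'``, then the
    deviatoric part ``C' - C_vol`` is scaled by ``1 + i G''/G'`` so the
    bulk response stays lossless (isotropic damping).
    """
    mu2r = np.atleast_1d(np.asarray(mu2_storage, dtype=float))
    mu2i = np.atleast_1d(np.asarray(mu2_loss, dtype=float))
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    zeta = np.atleast_1d(np.asarray(zeta, dtype=float))
    fibers = np.atleast_2d(np.asarray(fibers, dtype=float))
    if validate:
        _check_admissible(mu2r, mu2i, phi, zeta, bulk_modulus)
    n = mu2r.shape[0]
    K = float(bulk_modulus)

    # Axial Poisson ratio from the isotropic (K, G') relation; the in-plane
    # ratio nu12 then follows from requiring the volumetric compliance under
    # hydrostatic stress to equal exactly 1/K for every zeta, which keeps the
    # material nearly incompressible and degenerates to isotropy at zeta = 0.
    nu31 = (3 * K - 2 * mu2r) / (2 * (3 * K + mu2r))
    gk = mu2r / K
    nu12 = (1 + (1 - 4 * nu31) / (2 * (1 + zeta)) - gk) / (1 + gk)
    E2 = 2 * mu2r * (1 + nu12)
    E1 = E2 * (1 + zeta)
    G1 = mu2r * (1 + phi)

    S = np.zeros((n, 6, 6))
    S[:, 0, 0] = S[:, 1, 1] = 1.0 / E2
    S[:, 2, 2] = 1.0 / E1
    S[:, 0, 1] = S[:, 1, 0] = -nu12 / E2
    S[:, 0, 2] = S[:, 2, 0] = -nu31 / E1
    S[:, 1, 2] = S[:, 2, 1] = -nu31 / E1
    S[:, 3, 3] = S[:, 4, 4] = 1.0 / G1
    S[:, 5, 5] = 1.0 / mu2r  # = 2(S11 - S12), keeps in-plane shear = G2
    C_store = np.linalg.inv(S)

    C_vol = np.zeros((6, 6))
    C_vol[:3, :3] = K
    eta = mu2i / mu2r
    C = C_vol[None] + (1.0 + 1j * eta)[:, None, None] * (C_store - C_vol[None])

    R = rotation_to_axis(fibers)
    C = rotate_voigt(C, R)
    # enforce exact symmetry lost to roundoff
    C = 0.5 * (C + np.swapaxes(C, -1, -2))
    return C


def assemble_stiffness(params: NITIParameters, constants: PhysicsConstants) -> ElasticityTensor:
    """Build the complex Voigt stiffness tensor of a NITI voxel."""
    gmag = params.mu2.magnitude
    if constants.bulk_modulus < 1000.0 * gmag:
        raise ValueError(
            f"bulk_modulus {constants.bulk_modulus} must be >= 1000 x |mu2| = {1000 * gmag}"
        )
    C = niti_voigt_batch(
        params.mu2.storage,
        params.mu2.loss,
        params.phi,
        params.zeta,
        params.fiber,
        constants.bulk_modulus,
    )[0]
    return ElasticityTensor(C)


def isotropic_voigt(G: complex, bulk_modulus: float) -> np.ndarray:
    """Isotropic Voigt stiffness with complex shear modulus and real bulk modulus."""
    lam = bulk_modulus - 2.0 * G / 3.0
    C = np.zeros((6, 6), dtype=complex)
    C[:3, :3] = lam
    C[0, 0] = C[1, 1] = C[2, 2] = lam + 2 * G
    C[3, 3] = C[4, 4] = C[5, 5] = G
    return C


# ---------------------------------------------------------------------------
# Derived scalar stiffness quantities


def shear_stiffness(G: ComplexShearModulus | complex) -> float:
    """Composite shear stiffness mu = 2|G|^2 / (G' + |G|), in Pa.

    Proportional to the squared shear-wave speed in a viscoelastic
    medium; collapses to G' in the lossless case.  mu >= G' always, and
    mu <= 2 G' whenever the loss ratio G''/G' stays below (1+sqrt(5))/2
    — comfortably satisfied by brain tissue at these frequencies.
    """
    if isinstance(G, ComplexShearModulus):
        g = G.complex
    else:
        g = complex(G)
    if g.real <= 0:
        raise ValueError("storage modulus must be > 0 Pa")
    if g.imag < 0:
        raise ValueError("loss modulus must be >= 0 Pa")
    mag = abs(g)
    return 2.0 * mag * mag / (g.real + mag)


def shear_stiffness_map(storage: np.ndarray, loss: np.ndarray) -> np.ndarray:
    """Voxelwise composite stiffness 2|G|^2/(G'+|G|)."""
    storage = np.asarray(storage, dtype=float)
    loss = np.asarray(loss, dtype=float)
    mag = np.hypot(storage, loss)
    return 2.0 * mag * mag / (storage + mag)


def storage_from_stiffness(mu: float | np.ndarray, loss_ratio: float) -> np.ndarray:
    """Invert the composite-stiffness formula at fixed loss ratio G''/G'.

    Solves 2|G|^2/(G'+|G|) = mu with G'' = loss_ratio * G', giving
    G' = mu (1 + sqrt(1+r^2)) / (2 (1 + r^2)).
    """
    r2 = 1.0 + loss_ratio * loss_ratio
    return np.asarray(mu) * (1.0 + np.sqrt(r2)) / (2.0 * r2)


def parallel_stiffness(mu2_stiffness: float | np.ndarray, phi: float | np.ndarray):
    """Fiber-parallel stiffness mu1 = mu2 (1 + phi)."""
    if np.any(np.asarray(phi) <= -1):
        raise ValueError("phi must be > -1")
    if np.any(np.asarray(mu2_stiffness) <= 0):
        raise ValueError("mu2 stiffness must be > 0")
    return np.asarray(mu2_stiffness) * (1.0 + np.asarray(phi))


# ---------------------------------------------------------------------------
# Plane-wave analysis


def wave_speeds(
    params: NITIParameters, constants: PhysicsConstants, direction: np.ndarray
) -> np.ndarray:
    """Sorted phase speeds (m/s) of plane waves along ``direction``.

    Eigen-speeds sqrt(lambda/rho) of the acoustic (Christoffel) tensor
    n_j C'_ijkl n_l built from the storage part of the stiffness: two
    shear-type modes and one quasi-longitudinal mode dominated by the
    bulk modulus.
    """
    n = np.asarray(direction, dtype=float)
    nrm = np.linalg.norm(n)
    if nrm < 1e-12:
        raise ValueError("direction must be a nonzero vector")
    n = n / nrm
    C = assemble_stiffness(params, constants).tensor().real
    gamma = np.einsum("j,ijkl,l->ik", n, C, n)
    evals = np.linalg.eigvalsh(0.5 * (gamma + gamma.T))
    evals = np.clip(evals, 0.0, None)
    return np.sort(np.sqrt(evals / constants.density))
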