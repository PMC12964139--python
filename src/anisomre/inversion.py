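"""Nonlinear inversion of multi-excitation wave fields for NITI parameters.

The inverse problem mirrors the forward one: given one or two measured
complex displacement fields and the voxelwise fiber axis, find the
parameter fields theta = (mu2', mu2'', phi, zeta) minimizing

    J(theta) = sum_excitations ||u_model(theta) - u_meas||^2 / ||u_meas||^2
               + alpha * ||grad theta||^2

where u_model solves the discretized time-harmonic wave equation with
the measured displacements imposed on the domain boundary (the standard
nonlinear-inversion boundary treatment: any consistent boundary data
leave the interior physics unchanged).  Gradients are computed by the
adjoint method — one extra linear solve per excitation — and the
minimization uses box-constrained L-BFGS with the shear moduli
parameterized in log space for positivity.

The isotropic variant fixes phi = zeta = 0 and uses a single wave
field, giving the conventional isotropic stiffness map ``mu_iso``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import scipy.optimize
import scipy.sparse.linalg as spla

from .forward import DisplacementField, VoxelGrid
from .material import (
    PhysicsConstants,
    niti_voigt_batch,
    parallel_stiffness,
    shear_stiffness_map,
)
from .preproc import QCResult

__all__ = [
    "InversionConfig",
    "PropertyMaps",
    "DerivedStiffnessMaps",
    "invert_ti",
    "invert_iso",
    "derived_maps",
]


@dataclass
class InversionConfig:
    """Settings of the iterative inversion."""

    max_iterations: int = 80
    misfit_tol: float = 1e-8  # stop when relative data misfit falls below
    mu2_storage_bounds: Tuple[float, float] = (100.0, 10000.0)  # Pa
    mu2_loss_bounds: Tuple[float, float] = (1.0, 10000.0)  # Pa
    phi_bounds: Tuple[float, float] = (-0.65, 2.0)
    zeta_bounds: Tuple[float, float] = (-0.65, 4.0)
    reg_weight: float = 1e-4  # Tikhonov weight on spatial gradients
    init_mu2_storage: float = 2500.0  # Pa
    init_mu2_loss: float = 1000.0  # Pa
    init_phi: float = 0.0
    init_zeta: float = 0.5
    oss_threshold: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mu2_storage_bounds", "mu2_loss_bounds", "phi_bounds", "zeta_bounds"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be ordered, got ({lo}, {hi})")
        if self.misfit_tol <= 0:
            raise ValueError("misfit_tol must be > 0")
        if self.zeta_bounds[0] <= -0.7:
            raise ValueError("zeta lower bound must be > -0.7 (positive definiteness)")

    def hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class PropertyMaps:
    """Inversion output: voxelwise NITI parameters plus convergence record."""

    mu2_storage: np.ndarray
    mu2_loss: np.ndarray
    phi: np.ndarray
    zeta: np.ndarray
    misfit_history: List[float]
    data_misfit: float
    status: str
    provenance: Dict[str, str] = field(default_factory=dict)


@dataclass
class DerivedStiffnessMaps:
    """Composite stiffness maps derived voxelwise from inverted parameters."""

    mu2: np.ndarray  # perpendicular (substrate) shear stiffness, Pa
    mu1: np.ndarray  # parallel shear stiffness mu2 (1 + phi), Pa
    mu_iso: np.ndarray | None = None  # from the single-field isotropic inversion


def _grad_operator(shape: Tuple[int, int, int]):
    """Forward-difference gradient energy ||D x||^2 and its gradient, matrix-free."""

    def energy_and_grad(x3d: np.ndarray):
        e = 0.0
        g = np.zeros_like(x3d)
        for ax in range(3):
            d = np.diff(x3d, axis=ax)
            e += float(np.sum(d * d))
            sl_hi = [slice(None)] * 3
            sl_lo = [slice(None)] * 3
            sl_hi[ax] = slice(1, None)
            sl_lo[ax] = slice(None, -1)
            g[tuple(sl_hi)] += 2.0 * d
            g[tuple(sl_lo)] -= 2.0 * d
        return e, g

    return energy_and_grad


class _Objective:
    """Data misfit + regularization with adjoint gradients.

    Optimization variables per voxel: [ln mu2', ln mu2'', phi, zeta]
    (``iso=True`` keeps only the first two and freezes phi = zeta = 0).
    """

    _FD_STEPS = {"lmu2s": 1e-5, "lmu2l": 1e-5, "phi": 1e-6, "zeta": 1e-6}

    def __init__(
        self,
        fields: Sequence[DisplacementField],
        fibers: np.ndarray,
        constants: PhysicsConstants,
        config: InversionConfig,
        iso: bool = False,
    ):
        f0 = fields[0]
        self.node_shape = f0.grid_shape
        self.elem_shape = tuple(s - 1 for s in self.node_shape)
        self.grid = VoxelGrid(self.elem_shape, f0.spacing_m)
        self.constants = PhysicsConstants(constants.density, f0.frequency, constants.bulk_modulus)
        self.config = config
        self.iso = iso
        self.n_elems = self.grid.n_elems
        self.fibers = fibers.reshape(-1, 3)

        boundary = np.zeros(self.node_shape, dtype=bool)
        boundary[0] = boundary[-1] = True
        boundary[:, 0] = boundary[:, -1] = True
        boundary[:, :, 0] = boundary[:, :, -1] = True
        self.dmask = np.repeat(boundary.ravel(), 3)
        self.free = ~self.dmask

        self.data = [f.data.reshape(-1) for f in fields]
        self.norm = sum(float(np.vdot(d[self.free], d[self.free]).real) for d in self.data)
        if self.norm == 0.0:
            raise ValueError("measured fields have zero energy on the interior")
        self.reg = _grad_operator(self.elem_shape)
        self.n_params = 2 if iso else 4
        self.history: List[float] = []
        self.last_data_misfit = np.inf

    # -- parameter packing -------------------------------------------------
    def pack(self, mu2s, mu2l, phi, zeta) -> np.ndarray:
        cols = [np.log(mu2s).ravel(), np.log(mu2l).ravel()]
        if not self.iso:
            cols += [np.asarray(phi).ravel(), np.asarray(zeta).ravel()]
        return np.concatenate(cols)

    def unpack(self, x: np.ndarray):
        parts = x.reshape(self.n_params, self.n_elems)
        mu2s = np.exp(parts[0])
        mu2l = np.exp(parts[1])
        if self.iso:
            z = np.zeros(self.n_elems)
            return mu2s, mu2l, z, z
        return mu2s, mu2l, parts[2], parts[3]

    def bounds(self) -> List[Tuple[float, float]]:
        c = self.config
        per = [
            (np.log(c.mu2_storage_bounds[0]), np.log(c.mu2_storage_bounds[1])),
            (np.log(c.mu2_loss_bounds[0]), np.log(c.mu2_loss_bounds[1])),
        ]
        if not self.iso:
            per += [c.phi_bounds, c.zeta_bounds]
        out = []
        for b in per:
            out += [b] * self.n_elems
        return out

    def x0(self) -> np.ndarray:
        c = self.config
        n = self.n_elems
        return self.pack(
            np.full(n, c.init_mu2_storage),
            np.full(n, c.init_mu2_loss),
            np.full(n, c.init_phi),
            np.full(n, c.init_zeta),
        )

    # -- stiffness and its parameter derivatives ---------------------------
    def _stiffness(self, mu2s, mu2l, phi, zeta) -> np.ndarray:
        return niti_voigt_batch(
            mu2s, mu2l, phi, zeta, self.fibers, self.constants.bulk_modulus, validate=False
        )

    def _stiffness_derivs(self, mu2s, mu2l, phi, zeta) -> List[np.ndarray]:
        """dC/d(optimization variable) by central differences, chain rule for logs."""
        derivs = []
        h = self._FD_STEPS["lmu2s"]
        derivs.append(
            (self._stiffness(mu2s * np.exp(h), mu2l, phi, zeta)
             - self._stiffness(mu2s * np.exp(-h), mu2l, phi, zeta)) / (2 * h)
        )
        derivs.append(
            (self._stiffness(mu2s, mu2l * np.exp(h), phi, zeta)
             - self._stiffness(mu2s, mu2l * np.exp(-h), phi, zeta)) / (2 * h)
        )
        if not self.iso:
            h = self._FD_STEPS["phi"]
            derivs.append(
                (self._stiffness(mu2s, mu2l, phi + h, zeta)
                 - self._stiffness(mu2s, mu2l, phi - h, zeta)) / (2 * h)
            )
            h = self._FD_STEPS["zeta"]
            derivs.append(
                (self._stiffness(mu2s, mu2l, phi, zeta + h)
                 - self._stiffness(mu2s, mu2l, phi, zeta - h)) / (2 * h)
            )
        return derivs

    # -- objective ---------------------------------------------------------
    def __call__(self, x: np.ndarray):
        mu2s, mu2l, phi, zeta = self.unpack(x)
        C = self._stiffness(mu2s, mu2l, phi, zeta)
        A = self.grid.assemble(C, self.constants)
        free, dmask = self.free, self.dmask
        Aff = A[free][:, free].tocsc()
        Afd = A[free][:, dmask]
        lu = spla.splu(Aff)

        J_data = 0.0
        grad = np.zeros((self.n_params, self.n_elems))
        dC = self._stiffness_derivs(mu2s, mu2l, phi, zeta)
        for d in self.data:
            b = -(Afd @ d[dmask])
            uf = lu.solve(b)
            r = uf - d[free]
            J_data += float(np.vdot(r, r).real)
            w = lu.solve(r, trans="H")
            u_full = np.array(d)
            u_full[free] = uf
            w_full = np.zeros_like(u_full)
            w_full[free] = w
            ue = u_full[self.grid.edofs]  # (n_elems, 24)
            we = w_full[self.grid.edofs]
            # strain-space inner products at the 8 Gauss points
            eu = np.einsum("qca,ea->eqc", self.grid.B8, ue)
            ew = np.einsum("qca,ea->eqc", self.grid.B8, we)
            for p, dCp in enumerate(dC):
                contrib = np.einsum("eqc,ecd,eqd->e", np.conj(ew), dCp, eu)
                grad[p] += -2.0 * self.grid.w8 * contrib.real
        J_data /= self.norm
        grad /= self.norm
        self.last_data_misfit = J_data

        J = J_data
        alpha = self.config.reg_weight
        if alpha > 0:
            parts = x.reshape(self.n_params, self.n_elems)
            for p in range(self.n_params):
                e, g = self.reg(parts[p].reshape(self.elem_shape))
                J += alpha * e
                grad[p] += alpha * g.ravel()
        return J, grad.ravel()


def _check_qc(
    fields: Sequence[DisplacementField],
    qc: Sequence[QCResult] | None,
    waive_qc: bool,
) -> None:
    for f in fields:
        if not np.any(f.data):
            raise ValueError(f"field {f.excitation!r} rejected: zero amplitude (fails QC)")
    if qc is None:
        return
    for f, q in zip(fields, qc):
        if not q.passed and not waive_qc:
            raise ValueError(
                f"field {f.excitation!r} rejected: OSS-SNR {q.oss_snr:.2f} "
                f"below threshold {q.threshold} (pass waive_qc=True to override)"
            )


def _minimize(obj: _Objective, config: InversionConfig) -> PropertyMaps:
    J0, _ = obj(obj.x0())
    obj.history = [J0]
    d0 = obj.last_data_misfit

    def cb(xk):
        obj.history.append(obj.last_J)

    # wrap to remember the last evaluated objective for the callback
    def fun(x):
        J, g = obj(x)
        obj.last_J = J
        return J, g

    status = "converged"
    if config.max_iterations > 0 and d0 > config.misfit_tol:
        res = scipy.optimize.minimize(
            fun,
            obj.x0(),
            jac=True,
            method="L-BFGS-B",
            bounds=obj.bounds(),
            callback=cb,
            options={"maxiter": config.max_iterations, "ftol": 1e-14, "gtol": 1e-14},
        )
        x_best = res.x
        if not res.success and "ABNORMAL" in str(res.message).upper():
            status = "stalled"
        elif res.nit >= config.max_iterations:
            status = "max_iterations"
    else:
        x_best = obj.x0()
    J_final, _ = obj(x_best)
    mu2s, mu2l, phi, zeta = obj.unpack(x_best)
    shape = obj.elem_shape
    return PropertyMaps(
        mu2_storage=mu2s.reshape(shape),
        mu2_loss=mu2l.reshape(shape),
        phi=phi.reshape(shape),
        zeta=zeta.reshape(shape),
        misfit_history=obj.history,
        data_misfit=obj.last_data_misfit,
        status=status,
        provenance={"config": config.hash(), "mode": "iso" if obj.iso else "ti"},
    )


def invert_ti(
    fields: Sequence[DisplacementField],
    fibers: np.ndarray,
    constants: PhysicsConstants,
    config: InversionConfig | None = None,
    qc: Sequence[QCResult] | None = None,
    waive_qc: bool = False,
) -> PropertyMaps:
    """Recover (mu2', mu2'', phi, zeta) maps from multi-excitation fields.

    ``fields`` are the measured displacement fields (typically AP and
    LR); ``fibers`` the unit fiber axis per voxel of the element grid.
    Fields failing their QC result are rejected unless ``waive_qc``.
    """
    config = config or InversionConfig()
    fields = list(fields)
    _check_qc(fields, qc, waive_qc)
    norms = np.linalg.norm(fibers.reshape(-1, 3), axis=1)
    if np.any(np.abs(norms - 1) > 1e-6):
        raise ValueError("fiber vectors must be unit length")
    obj = _Objective(fields, fibers, constants, config, iso=False)
    maps = _minimize(obj, config)
    maps.provenance["excitations"] = ",".join(f.excitation for f in fields)
    return maps


def invert_iso(
    field: DisplacementField,
    constants: PhysicsConstants,
    config: InversionConfig | None = None,
    qc: QCResult | None = None,
    waive_qc: bool = False,
) -> np.ndarray:
    """Single-field isotropic inversion; returns the mu_iso stiffness map (Pa)."""
    config = config or InversionConfig()
    _check_qc([field], [qc] if qc is not None else None, waive_qc)
    elem_shape = tuple(s - 1 for s in field.grid_shape)
    fibers = np.zeros(elem_shape + (3,))
    fibers[..., 2] = 1.0  # irrelevant at phi = zeta = 0
    obj = _Objective([field], fibers, constants, config, iso=True)
    maps = _minimize(obj, config)
    return shear_stiffness_map(maps.mu2_storage, maps.mu2_loss)


def derived_maps(maps: PropertyMaps, mu_iso: np.ndarray | None = None) -> DerivedStiffnessMaps:
    """Composite stiffness maps: mu2 = 2|G|^2/(G'+|G|), mu1 = mu2 (1+phi)."""
    mu2 = shear_stiffness_map(maps.mu2_storage, maps.mu2_loss)
    mu1 = parallel_stiffness(mu2, maps.phi)
    return DerivedStiffnessMaps(mu2=mu2, mu1=mu1, mu_iso=mu_iso)
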