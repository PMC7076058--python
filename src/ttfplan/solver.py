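"""Quasi-static volume-conductor solver on the voxel grid.

At 200 kHz in tissue the electric field is governed by the conductivity-
weighted Laplace equation ∇·(σ∇φ) = 0 (capacitive and inductive effects
neglected; permittivity is ignored, as field distributions in this regime
are dominated by conductivity). Each transducer channel is solved
independently: Dirichlet potentials ±V0/2 on the energized anode/cathode
electrode voxels, natural zero-flux conditions on every air boundary, and
the un-energized channel's gel/electrode voxels present only as passive
conductive material.

Discretization: cell-centered finite volumes with harmonic-mean face
conductivities, giving a symmetric positive-definite 7-point system that
conserves current exactly at the discrete level. The system is solved by
Jacobi-preconditioned conjugate gradients (sparse direct solve for small
systems) — deterministic, no randomness involved.

After solving at the unit drive voltage the solution is rescaled so the
delivered channel current matches the requested target (default 0.9 A);
field and current density scale linearly with the drive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .grids import VoxelGrid

__all__ = [
    "SolveSettings",
    "ChannelSolution",
    "SolverError",
    "solve_channel",
    "compute_field",
    "total_current",
    "combine_channels",
    "field_magnitude",
]

_MM = 1.0e-3  # mm -> m


class SolverError(RuntimeError):
    """Raised on singular systems or non-convergence."""


@dataclass
class SolveSettings:
    """Solver controls.

    ``target_current`` is the total current per channel in amperes; set it
    to ``None`` to keep the raw solve at ``applied_voltage`` volts between
    the electrode pairs. ``combine_mode`` is the default rule for summarizing
    the two channels downstream ("per_channel", "average" or "max").
    """

    target_current: float | None = 0.9
    applied_voltage: float = 1.0
    tol: float = 1.0e-8
    maxiter: int = 50_000
    method: str = "auto"  # auto | direct | cg
    combine_mode: str = "average"

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tolerance must be > 0")
        if self.target_current is not None and self.target_current <= 0:
            raise ValueError("target current must be > 0")
        if self.applied_voltage <= 0:
            raise ValueError("applied voltage must be > 0")
        if self.combine_mode not in ("per_channel", "average", "max"):
            raise ValueError(f"unknown combine mode {self.combine_mode!r}")


@dataclass
class ChannelSolution:
    """Field solution for one energized channel, current-normalized."""

    channel: str
    grid: VoxelGrid
    phi: np.ndarray        # V, 0 outside the domain
    E: np.ndarray          # V/m, (..., 3), 0 outside the domain
    J: np.ndarray          # A/m^2, (..., 3)
    applied_voltage: float  # V, after normalization
    current: float          # A, delivered total current
    anode_current: float
    cathode_current: float
    iterations: int
    residual: float


def _face_conductance(sigma: np.ndarray, grid: VoxelGrid, axis: int) -> np.ndarray:
    """Conductance (S) of faces between voxel i and i+1 along ``axis``.

    Harmonic mean of the two voxel conductivities times face area over
    center distance; zero wherever either voxel is outside the domain.
    """
    lo = [slice(None)] * 3
    hi = [slice(None)] * 3
    lo[axis] = slice(None, -1)
    hi[axis] = slice(1, None)
    sa, sb = sigma[tuple(lo)], sigma[tuple(hi)]
    harm = np.zeros_like(sa)
    both = (sa > 0) & (sb > 0)
    harm[both] = 2.0 * sa[both] * sb[both] / (sa[both] + sb[both])
    others = [a for a in range(3) if a != axis]
    area = grid.spacing[others[0]] * _MM * grid.spacing[others[1]] * _MM
    dist = grid.spacing[axis] * _MM
    return harm * (area / dist)


def solve_channel(
    sigma: np.ndarray,
    grid: VoxelGrid,
    anode: np.ndarray,
    cathode: np.ndarray,
    settings: SolveSettings | None = None,
    channel: str = "CHANNEL",
) -> ChannelSolution:
    """Solve one channel's potential, field and current density.

    Parameters
    ----------
    sigma
        Per-voxel conductivity (S/m); zero marks voxels excluded from the
        domain (air).
    anode, cathode
        (N, 3) integer voxel indices held at +V0/2 and -V0/2.
    """
    if settings is None:
        settings = SolveSettings()
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape != tuple(grid.shape):
        raise ValueError("sigma shape does not match grid")
    anode = np.atleast_2d(np.asarray(anode, dtype=int))
    cathode = np.atleast_2d(np.asarray(cathode, dtype=int))
    if anode.size == 0 or cathode.size == 0:
        raise ValueError("anode and cathode patches must be non-empty")

    domain = sigma > 0
    v0 = settings.applied_voltage / 2.0
    phi_d = np.zeros(grid.shape)
    is_dir = np.zeros(grid.shape, dtype=bool)
    for patch, value in ((anode, +v0), (cathode, -v0)):
        idx = tuple(patch.T)
        if not domain[idx].all():
            raise ValueError("electrode voxels must lie in the conductive domain")
        phi_d[idx] = value
        is_dir[idx] = True
    if np.any(phi_d[tuple(anode.T)] != v0):
        raise ValueError("anode and cathode patches overlap")

    unknown = domain & ~is_dir
    n_unknown = int(unknown.sum())
    if n_unknown == 0:
        raise SolverError("no unknown voxels: electrodes cover the whole domain")
    uidx = -np.ones(grid.shape, dtype=np.int64)
    uidx[unknown] = np.arange(n_unknown)

    rows, cols, vals = [], [], []
    diag = np.zeros(n_unknown)
    rhs = np.zeros(n_unknown)
    for axis in range(3):
        g = _face_conductance(sigma, grid, axis)
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        lo, hi = tuple(lo), tuple(hi)
        ua, ub = uidx[lo], uidx[hi]
        da, db = is_dir[lo], is_dir[hi]
        pa, pb = phi_d[lo], phi_d[hi]

        active = g > 0
        # unknown-unknown faces
        m = active & (ua >= 0) & (ub >= 0)
        ia, ib, gg = ua[m], ub[m], g[m]
        rows.extend((ia, ib))
        cols.extend((ib, ia))
        vals.extend((-gg, -gg))
        np.add.at(diag, ia, gg)
        np.add.at(diag, ib, gg)
        # unknown-Dirichlet faces
        m = active & (ua >= 0) & db
        np.add.at(diag, ua[m], g[m])
        np.add.at(rhs, ua[m], g[m] * pb[m])
        m = active & (ub >= 0) & da
        np.add.at(diag, ub[m], g[m])
        np.add.at(rhs, ub[m], g[m] * pa[m])

    if np.any(diag == 0):
        raise SolverError(
            "singular system: some voxels have no conductive connection "
            "(disconnected anode/cathode or isolated tissue islands)"
        )
    rows.append(np.arange(n_unknown))
    cols.append(np.arange(n_unknown))
    vals.append(diag)
    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_unknown, n_unknown),
    )

    x, iterations = _solve_spd(A, rhs, settings)
    residual = float(np.linalg.norm(rhs - A @ x) / max(np.linalg.norm(rhs), 1e-300))

    phi = np.where(is_dir, phi_d, 0.0)
    phi[unknown] = x

    current_in = total_current(sigma, phi, grid, anode)
    current_out = total_current(sigma, phi, grid, cathode)
    if current_in <= 0:
        raise SolverError("non-positive anode current: check electrode polarity")

    scale = 1.0
    if settings.target_current is not None:
        scale = settings.target_current / current_in
        phi = phi * scale

    E = compute_field(phi, grid, domain=domain)
    J = sigma[..., None] * E
    return ChannelSolution(
        channel=channel, grid=grid, phi=phi, E=E, J=J,
        applied_voltage=settings.applied_voltage * scale,
        current=current_in * scale,
        anode_current=current_in * scale,
        cathode_current=current_out * scale,
        iterations=iterations,
        residual=residual,
    )


def _solve_spd(A: sp.csr_matrix, b: np.ndarray, settings: SolveSettings):
    n = A.shape[0]
    method = settings.method
    if method == "auto":
        method = "direct" if n <= 2_000 else "cg"
    if method == "direct":
        return spla.spsolve(A.tocsc(), b), 0
    # Jacobi-preconditioned CG from a zero initial guess; the diagonal
    # scaling tames the 6-orders-of-magnitude conductivity contrast
    # between skull and electrode material
    d = 1.0 / A.diagonal()
    M = spla.LinearOperator(A.shape, lambda v: d * v)
    count = {"n": 0}

    def cb(_):
        count["n"] += 1

    x, info = spla.cg(
        A, b, rtol=settings.tol, atol=0.0, maxiter=settings.maxiter, M=M, callback=cb
    )
    if info > 0:
        res = float(np.linalg.norm(b - A @ x) / np.linalg.norm(b))
        raise SolverError(
            f"conjugate gradients did not converge in {settings.maxiter} "
            f"iterations (relative residual {res:.3e})"
        )
    if info < 0:
        raise SolverError("conjugate gradients failed with an illegal input")
    return x, count["n"]


def compute_field(
    phi: np.ndarray, grid: VoxelGrid, domain: np.ndarray | None = None
) -> np.ndarray:
    """E = -∇φ in V/m: central differences in the interior, one-sided at
    domain/material boundaries, zero outside the domain."""
    phi = np.asarray(phi, dtype=float)
    if phi.shape != tuple(grid.shape):
        raise ValueError("phi shape does not match grid")
    if domain is None:
        domain = np.ones(phi.shape, dtype=bool)
    E = np.zeros(phi.shape + (3,))
    for axis in range(3):
        h = grid.spacing[axis] * _MM
        fwd = np.zeros(phi.shape)
        fwd_ok = np.zeros(phi.shape, dtype=bool)
        bwd = np.zeros(phi.shape)
        bwd_ok = np.zeros(phi.shape, dtype=bool)
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        lo, hi = tuple(lo), tuple(hi)
        ok = domain[lo] & domain[hi]
        d = (phi[hi] - phi[lo]) / h
        fwd[lo] = np.where(ok, d, 0.0)
        fwd_ok[lo] = ok
        bwd[hi] = np.where(ok, d, 0.0)
        bwd_ok[hi] = ok
        both = fwd_ok & bwd_ok
        grad = np.where(
            both, 0.5 * (fwd + bwd), np.where(fwd_ok, fwd, np.where(bwd_ok, bwd, 0.0))
        )
        E[..., axis] = -np.where(domain, grad, 0.0)
    return E


def total_current(
    sigma: np.ndarray, phi: np.ndarray, grid: VoxelGrid, patch: np.ndarray
) -> float:
    """Net current (A) leaving an electrode patch.

    Discrete surface integral of J·n over all faces between patch voxels
    and non-patch domain voxels, using the same harmonic-mean face
    conductances as the solve, so current accounting is exact.
    """
    patch = np.atleast_2d(np.asarray(patch, dtype=int))
    if patch.size == 0:
        raise ValueError("empty electrode patch")
    in_patch = np.zeros(grid.shape, dtype=bool)
    in_patch[tuple(patch.T)] = True
    domain = np.asarray(sigma) > 0
    total = 0.0
    for axis in range(3):
        g = _face_conductance(np.asarray(sigma, float), grid, axis)
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        lo, hi = tuple(lo), tuple(hi)
        dphi = phi[lo] - phi[hi]
        # patch -> outside faces in both orientations
        m = in_patch[lo] & ~in_patch[hi] & domain[hi]
        total += float(np.sum(g[m] * dphi[m]))
        m = in_patch[hi] & ~in_patch[lo] & domain[lo]
        total += float(np.sum(-g[m] * dphi[m]))
    return total


def field_magnitude(solution: ChannelSolution, quantity: str = "E") -> np.ndarray:
    """|E| (V/m) or |J| (A/m^2) scalar volume of one channel."""
    vec = solution.E if quantity == "E" else solution.J
    return np.linalg.norm(vec, axis=-1)


def combine_channels(
    a: ChannelSolution, b: ChannelSolution, mode: str = "average", quantity: str = "E"
):
    """Summarize the two sequentially energized channels.

    The device alternates between channels, so a single summary map is a
    modelling choice: "per_channel" returns both magnitude maps,
    "average" their arithmetic mean (time-average of the alternation),
    "max" the voxelwise maximum.
    """
    if not a.grid.same_geometry(b.grid):
        raise ValueError("channel solutions live on different grids")
    ma, mb = field_magnitude(a, quantity), field_magnitude(b, quantity)
    if mode == "per_channel":
        return ma, mb
    if mode == "average":
        return 0.5 * (ma + mb)
    if mode == "max":
        return np.maximum(ma, mb)
    raise ValueError(f"unknown combine mode {mode!r}")
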