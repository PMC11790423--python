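"""Acoustic tensor and characteristic wave speeds.

The plane-wave speeds of the hyperbolic sub-system along a material unit
direction N are the square roots of ``eig(Q)/rho0`` where

    Q_ki = N_J (dP_kJ / dF_iL) N_L

is the acoustic tensor evaluated at the cell's deformation gradient with
the memory variables frozen (they enter P linearly during the transport
step, so the full AC stress is differentiated as-is). The derivative is
taken by central finite differences with step ``h = 1e-6 max(1, |F|)``;
the CFL speed is the maximum over all cells and over the axis directions.
"""

from __future__ import annotations

import numpy as np

from .constitutive import ACConfig, MaterialQLV, total_stress
from .errors import ConfigError, LossOfHyperbolicityError

__all__ = ["DirectionalSpeeds", "acoustic_tensor", "directional_speeds",
           "cell_speeds", "max_wave_speed"]

_FD_REL_STEP = 1e-6
_EIG_TOL = 1e-8  # relative clipping threshold for spurious eigenvalue parts
_LINEAR_SPEED_CACHE: dict = {}


class DirectionalSpeeds:
    """Characteristic speeds along one direction: ``speeds`` (m/s, sorted
    ascending) and their maximum ``c_max``."""

    def __init__(self, N, speeds):
        self.N = np.asarray(N, dtype=float)
        self.speeds = np.sort(np.asarray(speeds, dtype=float), axis=-1)
        self.c_max = float(np.max(self.speeds))


def acoustic_tensor(F: np.ndarray, S_v: np.ndarray | None, N,
                    ac: ACConfig, mat: MaterialQLV) -> np.ndarray:
    """Acoustic tensor ``Q = N^T (dP^T/dF) N`` by central differences.

    ``F``: deformation gradient(s) ``(..., 3, 3)``; ``S_v``: frozen
    memory variables ``(..., N, 3, 3)`` or None; ``N``: unit direction.
    Returns ``Q`` with shape ``(..., 3, 3)`` (generally non-symmetric).
    """
    F = np.asarray(F, dtype=float)
    N = np.asarray(N, dtype=float)
    if abs(np.linalg.norm(N) - 1.0) > 1e-12:
        raise ConfigError("direction N must be a unit vector")
    h = _FD_REL_STEP * np.maximum(1.0, np.linalg.norm(F, axis=(-2, -1)))
    Q = np.empty(F.shape[:-2] + (3, 3))
    for i in range(3):
        dF = np.zeros((3, 3))
        dF[i, :] = N
        Fp = F + h[..., None, None] * dF
        Fm = F - h[..., None, None] * dF
        Pp = total_stress(Fp, S_v, ac, mat)[1]
        Pm = total_stress(Fm, S_v, ac, mat)[1]
        # column i of Q: d(P N)_k / d(F in direction e_i x N)
        Q[..., :, i] = np.einsum("...kJ,J->...k", Pp - Pm, N) / (2.0 * h[..., None])
    return Q


def _speeds_from_Q(Q: np.ndarray, ac: ACConfig, mat: MaterialQLV) -> np.ndarray:
    """Wave speeds (m/s) from acoustic-tensor eigenvalues, with clipping
    of round-off-level negative/imaginary parts."""
    lam = np.linalg.eigvals(Q)
    scale = mat.rho0 * mat.c_inf ** 2 * max(1.0, 1.0 / ac.epsilon)
    if np.max(np.abs(lam.imag)) > _EIG_TOL * scale:
        raise LossOfHyperbolicityError("complex acoustic-tensor eigenvalues")
    lam = lam.real
    if np.min(lam) < -_EIG_TOL * scale:
        bad = np.argwhere(np.min(np.atleast_2d(lam), axis=-1) < -_EIG_TOL * scale)
        raise LossOfHyperbolicityError(cells=bad)
    return np.sqrt(np.clip(lam, 0.0, None) / mat.rho0)


def directional_speeds(q_cell_F, S_v, N, ac: ACConfig,
                       mat: MaterialQLV) -> DirectionalSpeeds:
    """Characteristic speeds of one or more cells along direction N."""
    Q = acoustic_tensor(q_cell_F, S_v, N, ac, mat)
    return DirectionalSpeeds(N, _speeds_from_Q(Q, ac, mat))


def cell_speeds(field, axis: int, ac: ACConfig, mat: MaterialQLV,
                with_ghosts: bool = True) -> np.ndarray:
    """Per-cell maximum speed along one axis direction, shape of the grid."""
    q = field.q if with_ghosts else field.interior
    N = np.zeros(3)
    N[axis] = 1.0
    if mat.linear:
        # the linearised stress is affine in F, so Q = mu I + (lam + mu) N x N
        # is state-independent: one (cached) evaluation serves every cell
        key = (axis, ac, mat)
        c = _LINEAR_SPEED_CACHE.get(key)
        if c is None:
            Q = acoustic_tensor(np.eye(3), None, N, ac, mat)
            c = float(_speeds_from_Q(Q, ac, mat).max())
            if len(_LINEAR_SPEED_CACHE) > 64:
                _LINEAR_SPEED_CACHE.clear()
            _LINEAR_SPEED_CACHE[key] = c
        return np.full(q.shape[:-1], c)
    F = field.F(q)
    S_v = field.S_v(q) if field.n_relax else None
    Q = acoustic_tensor(F, S_v, N, ac, mat)
    return _speeds_from_Q(Q, ac, mat).max(axis=-1)


def max_wave_speed(field, ac: ACConfig, mat: MaterialQLV,
                   axes=(0, 1, 2)) -> float:
    """Global CFL speed: max over cells and axis directions of the largest
    acoustic-tensor eigen-speed."""
    return float(max(np.max(cell_speeds(field, a, ac, mat, with_ghosts=False))
                     for a in axes))
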