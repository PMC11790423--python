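"""Quasi-linear viscoelastic (QLV) material law and its weakly compressible
artificial-compressibility (AC) variant.

The material combines a Mooney--Rivlin/Yeoh instantaneous elastic response

    W_bar = C10 (I1_bar - 3) + C01 (I2_bar - 3) + C20 (I1_bar - 3)^2

with ``N`` linear relaxation mechanisms acting on the deviatoric elastic
stress through stress-like memory variables ``S_l^v``,

    d/dt S_l^v = omega_l (g_l * S_bar_De - S_l^v).

Incompressibility is enforced approximately by a stiff quadratic
volumetric energy ``U(J) = K/2 (J-1)^2`` with bulk modulus ``K = mu/eps``;
the compressibility ratio ``eps = mu/K`` is the small AC parameter. The
total second Piola--Kirchhoff stress is

    S = J U'(J) C^-1 + J^(-2/3) Dev(S_bar_e) - sum_l S_l^v,

where ``Dev`` is taken with respect to the isochoric strain
``C_bar = J^(-2/3) C``, and the first Piola--Kirchhoff stress is ``P = F S``.

A ``linear`` material flag selects the small-strain limit of the AC law,
``P = lam tr(eps) I + 2 mu eps - sum_l S_l^v`` with ``lam = K - 2 mu/3``,
which is the constant-coefficient system used by the dispersion and
convergence analyses.

All stress routines are batched: they accept deformation gradients of
shape ``(..., 3, 3)`` and memory variables of shape ``(..., N, 3, 3)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._tensors import IDENTITY, ddot, det3, inv3, sym, trace
from .errors import ConfigError, ElementInversionError

__all__ = [
    "MaterialQLV",
    "ACConfig",
    "gelatin_tripathi",
    "MATERIAL_PRESETS",
    "invariants",
    "elastic_stress_bar",
    "dev_lagrangian",
    "ac_pressure",
    "total_stress",
    "deviatoric_drive",
    "relax_update",
    "convert_elastic_params",
    "rivlin_from_fourth_order",
]


@dataclass(frozen=True)
class MaterialQLV:
    """Parameters of an incompressible QLV solid.

    Parameters
    ----------
    rho0 : mass density (kg/m^3).
    C10, C01, C20 : Rivlin coefficients of the Mooney--Rivlin/Yeoh
        strain energy (Pa).
    g : relaxation magnitudes ``g_l`` (dimensionless, each in (0,1),
        sum < 1). An empty tuple means pure elasticity.
    omega : relaxation angular frequencies ``omega_l`` (rad/s).
    linear : evaluate the small-strain (linearised) constitutive law
        instead of the finite-strain one.
    """

    rho0: float
    C10: float
    C01: float = 0.0
    C20: float = 0.0
    g: tuple = field(default=())
    omega: tuple = field(default=())
    linear: bool = False

    def __post_init__(self):
        object.__setattr__(self, "g", tuple(float(x) for x in self.g))
        object.__setattr__(self, "omega", tuple(float(x) for x in self.omega))
        if self.rho0 <= 0:
            raise ConfigError("rho0 must be positive")
        if self.C10 + self.C01 <= 0:
            raise ConfigError("C10 + C01 must be positive (shear modulus > 0)")
        if len(self.g) != len(self.omega):
            raise ConfigError("g and omega must have the same length")
        if any(not 0 < gl < 1 for gl in self.g):
            raise ConfigError("each g_l must lie in (0, 1)")
        if sum(self.g) >= 1:
            raise ConfigError("sum of g_l must be < 1")
        if any(w <= 0 for w in self.omega):
            raise ConfigError("relaxation frequencies must be positive")

    @property
    def N(self) -> int:
        """Number of relaxation mechanisms."""
        return len(self.g)

    @property
    def mu(self) -> float:
        """Shear modulus ``mu = 2 (C10 + C01)`` (Pa)."""
        return 2.0 * (self.C10 + self.C01)

    @property
    def beta(self) -> float:
        """Parameter of nonlinearity ``beta = 3 C20 / (C10 + C01)``."""
        return 3.0 * self.C20 / (self.C10 + self.C01)

    @property
    def c_inf(self) -> float:
        """High-frequency (instantaneous) shear wave speed (m/s)."""
        return float(np.sqrt(self.mu / self.rho0))

    @property
    def c0(self) -> float:
        """Low-frequency (equilibrium) shear wave speed (m/s)."""
        return self.c_inf * float(np.sqrt(1.0 - sum(self.g)))

    def elastic(self) -> "MaterialQLV":
        """Copy of the material with all relaxation mechanisms removed."""
        return replace(self, g=(), omega=())

    def linearised(self) -> "MaterialQLV":
        """Copy of the material with the small-strain law selected."""
        return replace(self, linear=True)


@dataclass(frozen=True)
class ACConfig:
    """Artificial-compressibility settings.

    ``epsilon`` is the compressibility ratio ``mu/K``; the bulk modulus
    follows as ``K = mu/epsilon``. ``Gamma`` is the Courant number of
    the CFL condition. A mesh-dependent policy ``epsilon = A (dx/L)^alpha``
    (convergent for ``0 <= alpha < 2``) is available via
    :meth:`from_policy`.
    """

    epsilon: float
    Gamma: float = 0.95

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ConfigError("epsilon must be positive")
        if not 0 < self.Gamma <= 1:
            raise ConfigError("Courant number Gamma must lie in (0, 1]")

    @classmethod
    def from_policy(cls, A: float, alpha: float, dx: float, L: float,
                    Gamma: float = 0.95) -> "ACConfig":
        """Mesh-dependent AC parameter ``epsilon = A (dx/L)^alpha``."""
        if not 0 <= alpha < 2:
            raise ConfigError("policy exponent alpha must satisfy 0 <= alpha < 2")
        if A <= 0 or dx <= 0 or L <= 0:
            raise ConfigError("A, dx and L must be positive")
        return cls(epsilon=A * (dx / L) ** alpha, Gamma=Gamma)

    def bulk_modulus(self, mat: MaterialQLV) -> float:
        """Bulk modulus ``K = mu/epsilon`` (Pa)."""
        return mat.mu / self.epsilon

    def lame_lambda(self, mat: MaterialQLV) -> float:
        """First Lame coefficient ``lambda = K - 2 mu/3`` (Pa)."""
        return self.bulk_modulus(mat) - 2.0 * mat.mu / 3.0

    @property
    def poisson_ratio(self) -> float:
        """Equivalent Poisson ratio ``nu = (1 - 2 eps/3) / (2 (1 + eps/3))``."""
        return (1.0 - 2.0 * self.epsilon / 3.0) / (2.0 * (1.0 + self.epsilon / 3.0))


def gelatin_tripathi(linear: bool = False, elastic: bool = False) -> MaterialQLV:
    """Gelatin sample with three relaxation mechanisms.

    rho0 = 1000 kg/m^3, mu = 2.684 kPa, beta = 4.4 (C01 = 0), and
    relaxation pairs (g_l, omega_l) at 10, 100 and 1000 Hz. Derived
    constants: C10 = 1.342 kPa, C20 = 1.968 kPa, c_inf = 1.638 m/s.
    """
    C10, C20 = convert_elastic_params(2684.0, 4.4, 0.0)
    mat = MaterialQLV(
        rho0=1000.0,
        C10=C10,
        C01=0.0,
        C20=C20,
        g=(0.0434, 0.0466, 0.2213),
        omega=(2 * np.pi * 10.0, 2 * np.pi * 100.0, 2 * np.pi * 1000.0),
        linear=linear,
    )
    return mat.elastic() if elastic else mat


MATERIAL_PRESETS = {"gelatin_tripathi": gelatin_tripathi}


def invariants(C: np.ndarray) -> tuple:
    """Principal invariants ``I1 = tr C`` and ``I2 = (I1^2 - tr C^2)/2``.

    ``C`` must be symmetric (relative tolerance 1e-12).
    """
    C = np.asarray(C, dtype=float)
    scale = max(float(np.max(np.abs(C))), 1e-300)
    if np.max(np.abs(C - np.swapaxes(C, -1, -2))) > 1e-12 * scale:
        raise ConfigError("strain tensor must be symmetric")
    I1 = trace(C)
    I2 = 0.5 * (I1 ** 2 - trace(C @ C))
    return I1, I2


def _energy_derivatives(I1_bar: np.ndarray, mat: MaterialQLV) -> tuple:
    """Partial derivatives (W1, W2) of the Mooney-Rivlin/Yeoh energy."""
    W1 = mat.C10 + 2.0 * mat.C20 * (I1_bar - 3.0)
    W2 = np.broadcast_to(np.float64(mat.C01), np.shape(W1)) if np.ndim(W1) else mat.C01
    return W1, W2


def elastic_stress_bar(C_bar: np.ndarray, mat: MaterialQLV) -> np.ndarray:
    """Instantaneous elastic stress ``S_bar_e = 2(W1 + I1 W2) I - 2 W2 C_bar``.

    ``C_bar`` must be unimodular (|det - 1| <= 1e-10): pass the
    volume-preserving part of the strain.
    """
    C_bar = np.asarray(C_bar, dtype=float)
    if np.max(np.abs(det3(C_bar) - 1.0)) > 1e-10:
        raise ConfigError("C_bar must be unimodular (pass the isochoric strain)")
    I1b, _ = invariants(C_bar)
    W1, W2 = _energy_derivatives(I1b, mat)
    I1b = np.asarray(I1b)
    return (
        2.0 * np.asarray(W1 + I1b * mat.C01)[..., None, None] * IDENTITY
        - 2.0 * mat.C01 * C_bar
    )


def dev_lagrangian(S: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Lagrangian deviatoric projection ``Dev S = S - (S:C)/3 C^-1``.

    The result R satisfies ``R : C = 0`` to round-off.
    """
    S = np.asarray(S, dtype=float)
    C = np.asarray(C, dtype=float)
    Cinv = inv3(C)
    return S - (ddot(S, C) / 3.0)[..., None, None] * Cinv


def ac_pressure(J, ac: ACConfig, mat: MaterialQLV):
    """AC pressure ``p = -U'(J) = -K (J - 1)`` with ``K = mu/epsilon`` (Pa)."""
    J = np.asarray(J, dtype=float)
    if np.any(J <= 0):
        bad = np.argwhere(J <= 0) if J.ndim else None
        raise ElementInversionError(cells=bad)
    p = -ac.bulk_modulus(mat) * (J - 1.0)
    return float(p) if p.ndim == 0 else p


def total_stress(F: np.ndarray, S_v: np.ndarray | None, ac: ACConfig,
                 mat: MaterialQLV) -> tuple:
    """Total stresses of the AC constitutive law.

    Parameters
    ----------
    F : deformation gradient(s), shape ``(..., 3, 3)``.
    S_v : memory variables, shape ``(..., N, 3, 3)`` or None for N = 0.
    ac, mat : AC settings and material.

    Returns
    -------
    (S, P) : second and first Piola--Kirchhoff stresses, ``(..., 3, 3)``.
    """
    F = np.asarray(F, dtype=float)
    mem = None
    if S_v is not None and np.size(S_v):
        mem = np.asarray(S_v, dtype=float).sum(axis=-3)

    if mat.linear:
        eps_t = sym(F - IDENTITY)
        lam = ac.lame_lambda(mat)
        P = lam * trace(eps_t)[..., None, None] * IDENTITY + 2.0 * mat.mu * eps_t
        if mem is not None:
            P = P - mem
        return P.copy(), P

    J = det3(F)
    if np.any(J <= 0):
        raise ElementInversionError(cells=np.argwhere(np.atleast_1d(J) <= 0))
    C = np.swapaxes(F, -1, -2) @ F
    Jm23 = J ** (-2.0 / 3.0)
    C_bar = Jm23[..., None, None] * C
    S_bar = elastic_stress_bar(C_bar, mat)
    S = Jm23[..., None, None] * dev_lagrangian(S_bar, C_bar)
    K = ac.bulk_modulus(mat)
    S = S + (J * K * (J - 1.0))[..., None, None] * inv3(C, det=J ** 2)
    if mem is not None:
        S = S - mem
    return S, F @ S


def deviatoric_drive(F: np.ndarray, ac: ACConfig, mat: MaterialQLV) -> np.ndarray:
    """Relaxation drive ``S_bar_De = Dev(S_bar_e)`` at the current strain.

    In the linear branch this is the small-strain limit
    ``2 mu (eps - tr(eps)/3 I)``; it is trace-free in that limit.
    """
    F = np.asarray(F, dtype=float)
    if mat.linear:
        eps_t = sym(F - IDENTITY)
        return 2.0 * mat.mu * (eps_t - (trace(eps_t) / 3.0)[..., None, None] * IDENTITY)
    J = det3(F)
    if np.any(J <= 0):
        raise ElementInversionError(cells=np.argwhere(np.atleast_1d(J) <= 0))
    C = np.swapaxes(F, -1, -2) @ F
    C_bar = (J ** (-2.0 / 3.0))[..., None, None] * C
    return dev_lagrangian(elastic_stress_bar(C_bar, mat), C_bar)


def relax_update(S_v: np.ndarray, S_De_bar: np.ndarray, dt: float,
                 mat: MaterialQLV) -> np.ndarray:
    """Exact integration of the memory-variable relaxation over ``dt``.

    For each mechanism, ``S_l^v <- e^(-omega_l dt) S_l^v +
    (1 - e^(-omega_l dt)) g_l S_bar_De``. Unconditionally stable; the
    equilibrium ``S_l^v = g_l S_bar_De`` is an exact fixed point.

    ``S_v`` has shape ``(..., N, 3, 3)``; ``S_De_bar`` shape ``(..., 3, 3)``.
    """
    if dt < 0:
        raise ConfigError("dt must be non-negative")
    if mat.N == 0:
        return np.asarray(S_v, dtype=float)
    S_v = np.asarray(S_v, dtype=float)
    decay = np.exp(-np.asarray(mat.omega) * dt)  # (N,)
    gl = np.asarray(mat.g)
    shp = (-1,) + (1, 1)
    return (
        decay.reshape(shp) * S_v
        + ((1.0 - decay) * gl).reshape(shp) * np.asarray(S_De_bar)[..., None, :, :]
    )


def convert_elastic_params(mu: float, beta: float, C01: float = 0.0) -> tuple:
    """Rivlin coefficients from shear modulus and nonlinearity parameter.

    ``C10 = mu/2 - C01`` and ``C20 = beta (C10 + C01) / 3``; the
    round-trip through the derived material fields returns (mu, beta).
    """
    if mu <= 0:
        raise ConfigError("mu must be positive")
    C10 = mu / 2.0 - C01
    if C10 <= 0:
        raise ConfigError("C10 = mu/2 - C01 must be positive")
    C20 = beta * (C10 + C01) / 3.0
    return C10, C20


def rivlin_from_fourth_order(mu: float, A: float, D: float) -> tuple:
    """Rivlin coefficients (C10, C01, C20) from fourth-order elastic
    constants (mu, A, D) of the Landau-type energy
    ``mu tr(E^2) + A/3 tr(E^3) + D (tr E^2)^2`` (incompressible case).

    The links ``mu = 2(C10+C01)``, ``A = -8(C10+2C01)``,
    ``D = 2(C10+3C01+2C20)`` make both closed forms of the nonlinearity
    parameter agree: ``beta = 3C20/(C10+C01) = (3/2)(mu + A/2 + D)/mu``.
    """
    C01 = -(A / 8.0 + mu / 2.0) / 1.0  # from A = -8(C10 + 2 C01), mu = 2(C10+C01)
    C10 = mu / 2.0 - C01
    C20 = (D / 2.0 - C10 - 3.0 * C01) / 2.0
    return C10, C01, C20
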