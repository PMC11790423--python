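"""Closed-form and semi-analytic references for verification.

Covers the viscoelastic dispersion relation of infinitesimal harmonic
waves (shear and artificial-compression branches of the AC system), the
FFT-synthesised quasi-analytic solution of the forced 1D problem, the
von Neumann amplification factor of the linear LLF stencil, the
modified-equation order prediction for mesh-dependent AC parameters,
and the leading-order compression--shear coupling amplitude.

Conventions: harmonic fields ``exp(i(w t - kappa X))`` with complex wave
speed ``c`` on the branch ``Re c > 0`` (then ``Im kappa < 0`` and
right-going waves decay).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constitutive import ACConfig, MaterialQLV
from .errors import ConfigError

__all__ = [
    "DispersionResult",
    "complex_wave_speed",
    "dispersion",
    "compression_dissipation",
    "quasi_analytic_solution",
    "sample_signal",
    "amplification_factor",
    "predicted_order",
    "coupling_amplitude",
]


@dataclass(frozen=True)
class DispersionResult:
    """Complex wave speed and derived dispersion quantities at one
    angular frequency."""

    omega: float
    c_complex: complex

    @property
    def kappa(self) -> complex:
        return self.omega / self.c_complex

    @property
    def phase_velocity(self) -> float:
        """``omega / Re(kappa)`` (m/s)."""
        return self.omega / self.kappa.real

    @property
    def dissipation_factor(self) -> float:
        """``-Im(kappa^2) / Re(kappa^2)`` (reciprocal quality factor)."""
        k2 = self.kappa ** 2
        return -k2.imag / k2.real


def _relaxation_factor(omega, mat: MaterialQLV):
    """``1 - sum_l g_l omega_l / (omega_l + i omega)``."""
    omega = np.asarray(omega, dtype=float)
    if mat.N == 0:
        return np.ones_like(omega, dtype=complex) if omega.ndim else 1.0 + 0j
    g = np.asarray(mat.g)
    wl = np.asarray(mat.omega)
    return 1.0 - np.sum(
        g * wl / (wl + 1j * omega[..., None]), axis=-1
    )


def complex_wave_speed(omega, mat: MaterialQLV, ac: ACConfig | None = None,
                       mode: str = "shear"):
    """Complex wave speed ``c(omega)`` of the linearised AC system.

    Shear branch: ``c^2/c_inf^2 = 1 - sum_l g_l omega_l/(omega_l + i omega)``.
    Compression branch: ``c^2/c_inf^2 = (4/3) (1 - sum_l ...) + 1/eps``
    (the stiff volumetric term is purely elastic, so compression waves
    lose their attenuation in the incompressible limit). The principal
    square root already has ``Re c > 0``.
    """
    if mode not in ("shear", "compression"):
        raise ConfigError("mode must be 'shear' or 'compression'")
    r = _relaxation_factor(omega, mat)
    if mode == "compression":
        if ac is None:
            raise ConfigError("compression branch requires an ACConfig")
        c2 = (4.0 / 3.0) * r + 1.0 / ac.epsilon
    else:
        c2 = r
    return mat.c_inf * np.sqrt(c2 + 0j)


def dispersion(omega: float, mat: MaterialQLV, ac: ACConfig | None = None,
               mode: str = "shear") -> DispersionResult:
    """Dispersion result at a single angular frequency ``omega > 0``."""
    if omega <= 0:
        raise ConfigError("omega must be positive")
    return DispersionResult(float(omega),
                            complex(complex_wave_speed(omega, mat, ac, mode)))


def compression_dissipation(omega, mat: MaterialQLV, ac: ACConfig):
    """Dissipation factor of the artificial compression waves,

    ``sum_l g_l omega_l omega / (omega_l^2 + omega^2)`` over
    ``1 + 3/(4 eps) - sum_l g_l omega_l^2 / (omega_l^2 + omega^2)``.

    Vanishes for a purely elastic material and in the incompressible
    limit ``eps -> 0``.
    """
    omega = np.asarray(omega, dtype=float)
    if mat.N == 0:
        return np.zeros_like(omega) if omega.ndim else 0.0
    g = np.asarray(mat.g)
    wl = np.asarray(mat.omega)
    w = omega[..., None]
    num = np.sum(g * wl * w / (wl ** 2 + w ** 2), axis=-1)
    den = 1.0 + 3.0 / (4.0 * ac.epsilon) - np.sum(
        g * wl ** 2 / (wl ** 2 + w ** 2), axis=-1
    )
    out = num / den
    return float(out) if out.ndim == 0 else out


def sample_signal(signal_fn, Omega: float, samples_per_period: int = 500,
                  pad_periods: int = 10):
    """Discretise a one-period signal for FFT synthesis.

    Uses ``samples_per_period`` points per period and zero-padding of at
    least ``pad_periods`` further periods, rounding the total length up
    to a power of two. Returns ``(samples, dt)``.
    """
    T = 2.0 * np.pi / Omega
    dt = T / samples_per_period
    n_min = samples_per_period * (1 + pad_periods)
    n = 1 << int(np.ceil(np.log2(n_min)))
    t = np.arange(n) * dt
    return signal_fn(t), dt


def quasi_analytic_solution(X, t: float, src_samples: np.ndarray,
                            sample_dt: float, mat: MaterialQLV,
                            ac: ACConfig | None = None,
                            mode: str = "shear") -> np.ndarray:
    """Velocity profile of the forced 1D problem by Fourier synthesis.

    Evaluates ``v(X, t) = (1/2 pi) int_0^inf Re[ s_hat(w)/c(w)
    exp(i w t - i w X / c(w)) ] dw`` as an inverse FFT of the
    frequency-domain propagated spectrum; reduces to the d'Alembert
    solution ``s(t - X/c) / (2 c)`` in the non-dispersive elastic limit.

    ``X`` are non-negative positions (right-going branch); the source
    samples come from :func:`sample_signal`.
    """
    X = np.atleast_1d(np.asarray(X, dtype=float))
    if np.any(X < 0):
        raise ConfigError("positions must be non-negative (right-going branch)")
    n = len(src_samples)
    if t > (n - 1) * sample_dt:
        raise ConfigError("requested time exceeds the synthesised window; "
                          "increase the zero padding")
    S = np.fft.rfft(src_samples)
    omega = 2.0 * np.pi * np.fft.rfftfreq(n, d=sample_dt)
    c = np.empty(omega.shape, dtype=complex)
    c[0] = np.inf  # zero-frequency carries no propagating content
    c[1:] = complex_wave_speed(omega[1:], mat, ac, mode)
    out = np.empty(X.shape)
    # time index of the requested instant on the synthesis grid
    ti = t / sample_dt
    i0 = int(np.floor(ti))
    w_frac = ti - i0
    for k, x in enumerate(X):
        H = np.zeros_like(S)
        H[1:] = np.exp(-1j * omega[1:] / c[1:] * x) / (2.0 * c[1:])
        v = np.fft.irfft(S * H, n=n)
        out[k] = (1 - w_frac) * v[i0] + w_frac * v[min(i0 + 1, n - 1)]
    return out


def amplification_factor(kdx, Gamma: float, speed_ratio: float) -> np.ndarray:
    """Both roots of the von Neumann amplification factor of the linear
    LLF stencil,

        xi = 1 - Gamma + Gamma cos(k dx) +- i Gamma (c_I/cbar) sin(k dx).

    ``|xi| <= 1`` holds for ``0 < Gamma <= 1`` and ``0 < c_I/cbar <= 1``.
    Returns an array with the two roots stacked on the last axis.
    """
    if not 0 < Gamma <= 1:
        raise ConfigError("Gamma must lie in (0, 1]")
    if not 0 < speed_ratio <= 1:
        raise ConfigError("speed ratio c_I/cbar must lie in (0, 1]")
    kdx = np.asarray(kdx, dtype=float)
    re = 1.0 - Gamma + Gamma * np.cos(kdx)
    im = Gamma * speed_ratio * np.sin(kdx)
    return np.stack([re + 1j * im, re - 1j * im], axis=-1)


def predicted_order(alpha: float) -> float:
    """Leading order of accuracy in shear, ``1 - alpha/2``, when the AC
    parameter scales as ``dx^alpha`` (valid for ``0 <= alpha < 2``)."""
    if not 0 <= alpha < 2:
        raise ConfigError("alpha must satisfy 0 <= alpha < 2 (convergence window)")
    return 1.0 - alpha / 2.0


def coupling_amplitude(gamma, epsilon: float, beta: float):
    """Leading-order compression strain driven by a shear strain ``gamma``:
    ``(eps/3) gamma^2 (1 + (2/3) beta gamma^2)``."""
    gamma = np.asarray(gamma, dtype=float)
    out = (epsilon / 3.0) * gamma ** 2 * (1.0 + (2.0 / 3.0) * beta * gamma ** 2)
    return float(out) if out.ndim == 0 else out
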