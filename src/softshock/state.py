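"""Structured-grid state container and acoustic sources.

The conserved vector of each cell holds ``12 + 6N`` scalars ordered

    [F11 F12 F13 F21 F22 F23 F31 F32 F33  v1 v2 v3  S1v(6) ... SNv(6)]

with each symmetric memory tensor packed as (11, 12, 13, 22, 23, 33).
Slots 9-11 are the velocity components, so the slot for ``v2`` is the
unit vector ``e_(9+2)`` in 1-based numbering. The grid is a regular
(nx, ny, nz) lattice of cell centres at ``origin + index * spacing``
with ``ghost`` extra layers per side. 1D/2D problems are 3D fields with
singleton axes; sweeps along singleton axes are skipped by the solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.special import erf

from ._tensors import mat_from_sym6, sym6_from_mat
from .errors import ConfigError

__all__ = [
    "StateField",
    "SourceSpec",
    "signal",
    "apply_source",
    "apply_point_source",
    "apply_ring_source",
    "apply_gaussian_source",
    "fill_ghosts",
    "ring_cells",
    "n_components",
]

_V_SLOTS = (9, 10, 11)


def n_components(N: int) -> int:
    """Length of the conserved vector, ``12 + 6N``."""
    return 12 + 6 * N


@dataclass
class StateField:
    """Cell-centred state on a regular grid with ghost layers.

    ``q`` has shape ``(nx + 2g, ny + 2g, nz + 2g, ncomp)`` where ``g``
    is the number of ghost layers. ``origin`` is the coordinate of the
    interior cell with index (0, 0, 0). ``boundary`` selects the ghost
    filling rule: constant extrapolation (non-reflecting outflow) or
    periodic wrap-around.
    """

    shape: tuple
    spacing: tuple
    origin: tuple = (0.0, 0.0, 0.0)
    n_relax: int = 0
    ghost: int = 2
    boundary: str = "outflow"
    q: np.ndarray = dc_field(default=None, repr=False)

    def __post_init__(self):
        self.shape = tuple(int(n) for n in self.shape)
        self.spacing = tuple(float(d) for d in self.spacing)
        if len(self.shape) != 3 or len(self.spacing) != 3:
            raise ConfigError("shape and spacing must have three entries")
        if any(n < 1 for n in self.shape) or any(d <= 0 for d in self.spacing):
            raise ConfigError("grid extents must be >= 1 and spacings positive")
        if self.ghost < 1:
            raise ConfigError("at least one ghost layer is required")
        if self.boundary not in ("outflow", "periodic"):
            raise ConfigError("boundary must be 'outflow' or 'periodic'")
        ncomp = n_components(self.n_relax)
        padded = tuple(n + 2 * g for n, g in zip(self.shape, self.ghosts))
        if self.q is None:
            self.q = np.zeros(padded + (ncomp,))
            # undeformed rest state: F = I, v = 0, memory variables = 0
            self.q[..., 0] = 1.0
            self.q[..., 4] = 1.0
            self.q[..., 8] = 1.0
        elif self.q.shape != padded + (ncomp,):
            raise ConfigError("q has inconsistent shape")

    # -- views ---------------------------------------------------------
    @property
    def ncomp(self) -> int:
        return n_components(self.n_relax)

    @property
    def ghosts(self) -> tuple:
        """Ghost layers per axis: singleton axes carry none (no sweeps)."""
        return tuple(self.ghost if n > 1 else 0 for n in self.shape)

    @property
    def interior(self) -> np.ndarray:
        """View of the interior cells, shape ``(nx, ny, nz, ncomp)``."""
        return self.q[self.interior_slices]

    @property
    def interior_slices(self) -> tuple:
        return tuple(slice(g, g + n) for g, n in zip(self.ghosts, self.shape))

    @property
    def active_axes(self) -> tuple:
        """Axes with more than one cell (the sweep directions)."""
        return tuple(a for a in range(3) if self.shape[a] > 1)

    def F(self, q: np.ndarray | None = None) -> np.ndarray:
        q = self.q if q is None else q
        return q[..., 0:9].reshape(q.shape[:-1] + (3, 3))

    def v(self, q: np.ndarray | None = None) -> np.ndarray:
        q = self.q if q is None else q
        return q[..., 9:12]

    def S_v(self, q: np.ndarray | None = None) -> np.ndarray:
        """Memory variables as full tensors, shape ``(..., N, 3, 3)``."""
        q = self.q if q is None else q
        s6 = q[..., 12:].reshape(q.shape[:-1] + (self.n_relax, 6))
        return mat_from_sym6(s6)

    def set_S_v(self, S_v: np.ndarray, q: np.ndarray | None = None) -> None:
        q = self.q if q is None else q
        q[..., 12:] = sym6_from_mat(S_v).reshape(q.shape[:-1] + (6 * self.n_relax,))

    def axis_coords(self, axis: int, with_ghosts: bool = False) -> np.ndarray:
        """Cell-centre coordinates along one axis."""
        g = self.ghosts[axis] if with_ghosts else 0
        idx = np.arange(-g, self.shape[axis] + g)
        return self.origin[axis] + idx * self.spacing[axis]

    def coords(self, with_ghosts: bool = False) -> tuple:
        return tuple(self.axis_coords(a, with_ghosts) for a in range(3))

    def cell_index(self, point) -> tuple:
        """Interior index of the cell whose centre is closest to ``point``."""
        idx = []
        for a in range(3):
            i = int(round((point[a] - self.origin[a]) / self.spacing[a]))
            if not 0 <= i < self.shape[a]:
                raise ConfigError(f"point {point} outside the domain on axis {a}")
            idx.append(i)
        return tuple(idx)

    def copy(self) -> "StateField":
        return StateField(
            shape=self.shape, spacing=self.spacing, origin=self.origin,
            n_relax=self.n_relax, ghost=self.ghost, boundary=self.boundary,
            q=self.q.copy(),
        )

    @classmethod
    def centred(cls, lengths, spacing, **kw) -> "StateField":
        """Grid of a box centred at the origin with the given side lengths.

        Cell centres sit at ``i * d`` for integer ``i`` (a node lies
        exactly at the origin): ``n = 2 floor(L/2d) + 1`` cells per axis.
        """
        spacing = tuple(float(d) for d in np.broadcast_to(spacing, (3,)))
        shape, origin = [], []
        for L, d in zip(lengths, spacing):
            if L > 0:
                k = int(np.floor(L / (2 * d) + 1e-9))
                shape.append(2 * k + 1)
                origin.append(-k * d)
            else:
                shape.append(1)
                origin.append(0.0)
        return cls(shape=tuple(shape), spacing=spacing, origin=tuple(origin), **kw)


def fill_ghosts(field: StateField, axis: int | None = None) -> StateField:
    """Fill ghost layers (in place) along one axis, or all axes if None.

    Outflow boundaries copy the nearest interior cell (constant
    extrapolation, non-reflecting); periodic boundaries wrap. The
    operation is idempotent.
    """
    axes = range(3) if axis is None else (axis,)
    q = field.q
    for a in axes:
        g = field.ghosts[a]
        if g == 0:
            continue
        n = field.shape[a]
        lo = [slice(None)] * 4
        hi = [slice(None)] * 4
        src_lo = [slice(None)] * 4
        src_hi = [slice(None)] * 4
        lo[a], hi[a] = slice(0, g), slice(n + g, n + 2 * g)
        if field.boundary == "periodic":
            src_lo[a], src_hi[a] = slice(n, n + g), slice(g, 2 * g)
            q[tuple(lo)] = q[tuple(src_lo)]
            q[tuple(hi)] = q[tuple(src_hi)]
        else:
            src_lo[a], src_hi[a] = slice(g, g + 1), slice(n + g - 1, n + g)
            q[tuple(lo)] = q[tuple(src_lo)]
            q[tuple(hi)] = q[tuple(src_hi)]
    return field


def signal(t, Omega: float, A: float = 1.0):
    """Smooth one-period source signal ``A (sin Wt - sin(2Wt)/2)`` (m^2/s^2).

    Vanishes outside ``0 <= Omega t <= 2 pi`` and is C^1 at both ends.
    """
    t = np.asarray(t, dtype=float)
    phase = Omega * t
    s = A * (np.sin(phase) - 0.5 * np.sin(2.0 * phase))
    s = np.where((phase >= 0.0) & (phase <= 2.0 * np.pi), s, 0.0)
    return float(s) if s.ndim == 0 else s


@dataclass(frozen=True)
class SourceSpec:
    """Forcing term injected into a velocity slot after each time step.

    kind:
        ``point`` -- ``s(t) dt / prod(active dx)`` at a single cell;
        ``ring`` -- ``s(t) dt / (dx dy)`` on the cell columns nearest to
        the circle of radius ``radius`` (telescopic source, v3 slot);
        ``gaussian_sphere`` -- ``s(t) dt G(X)`` with a truncated,
        renormalised 3D Gaussian of width ``sigma`` (v2 slot).
    amplitude:
        dimensionless multiplier of the signal.
    Omega:
        fundamental angular frequency (rad/s).
    polarisation:
        velocity component index in {0, 1, 2} (point sources only; ring
        forces v3 and the Gaussian sphere forces v2 by construction).
    """

    kind: str
    Omega: float
    amplitude: float = 1.0
    polarisation: int = 1
    position: tuple = (0.0, 0.0, 0.0)
    radius: float = 0.2
    sigma: float = 0.018
    cutoff: float = 3.25

    def __post_init__(self):
        if self.kind not in ("point", "ring", "gaussian_sphere"):
            raise ConfigError(f"unknown source kind {self.kind!r}")
        if self.kind == "gaussian_sphere" and self.sigma <= 0:
            raise ConfigError("sigma must be positive")
        if self.polarisation not in (0, 1, 2):
            raise ConfigError("polarisation must be 0, 1 or 2")


def _point_injection(field: StateField, src: SourceSpec):
    idx = field.cell_index(src.position)
    scale = 1.0
    for a in field.active_axes:
        scale /= field.spacing[a]
    return idx, scale


def ring_cells(field: StateField, radius: float) -> np.ndarray:
    """(i, j) columns whose centre is nearest to the circle X^2+Y^2=R^2.

    One cell per angular ray: ``M = ceil(2 pi R / min(dx, dy))`` equally
    spaced angles are rasterised onto nearest cell centres and
    duplicates removed. ``R = 0`` degenerates to the single centre
    column.
    """
    dx, dy = field.spacing[0], field.spacing[1]
    x = field.axis_coords(0)
    y = field.axis_coords(1)
    if radius <= 0:
        return np.array([[int(np.argmin(np.abs(x))), int(np.argmin(np.abs(y)))]])
    # multiple of 4 so the rasterised cell set inherits the quarter-turn
    # symmetry of the circle on the centred grid
    M = 4 * max(int(np.ceil(np.pi * radius / (2 * min(dx, dy)))), 2)
    theta = 2 * np.pi * np.arange(M) / M
    px = radius * np.cos(theta)
    py = radius * np.sin(theta)
    if (px.min() < x.min() or px.max() > x.max()
            or py.min() < y.min() or py.max() > y.max()):
        raise ConfigError("ring source lies outside the domain")
    i = np.argmin(np.abs(x[None, :] - px[:, None]), axis=1)
    j = np.argmin(np.abs(y[None, :] - py[:, None]), axis=1)
    return np.unique(np.stack([i, j], axis=1), axis=0)


def gaussian_profile(field: StateField, src: SourceSpec) -> np.ndarray:
    """Truncated, renormalised 3D Gaussian sampled at the cell centres.

    ``G(X) = exp(-|X|^2 / 2 sigma^2) / ((2 pi)^{3/2} sigma^3) * 1_{|X| < R sigma}``
    divided by ``erf(R/sqrt(2)) - R sqrt(2/pi) exp(-R^2/2)`` so that the
    truncated mass integrates to one (default cutoff R = 3.25).
    """
    sig, R = src.sigma, src.cutoff
    x, y, z = field.coords()
    r2 = (x[:, None, None] ** 2 + y[None, :, None] ** 2 + z[None, None, :] ** 2)
    G = np.exp(-r2 / (2 * sig ** 2)) / ((2 * np.pi) ** 1.5 * sig ** 3)
    G = np.where(np.sqrt(r2) / sig < R, G, 0.0)
    norm = erf(R / np.sqrt(2.0)) - R * np.sqrt(2.0 / np.pi) * np.exp(-R ** 2 / 2.0)
    return G / norm


def apply_point_source(field: StateField, t_next: float, dt: float,
                       src: SourceSpec) -> StateField:
    """Add ``A s(t^{n+1}) dt / prod(active dx)`` to one cell's velocity slot."""
    idx, scale = _point_injection(field, src)
    gx, gy, gz = field.ghosts
    amp = signal(t_next, src.Omega, src.amplitude) * dt * scale
    field.q[idx[0] + gx, idx[1] + gy, idx[2] + gz,
            _V_SLOTS[src.polarisation]] += amp
    return field


def apply_ring_source(field: StateField, t_next: float, dt: float,
                      src: SourceSpec, _cache={}) -> StateField:
    """Add ``A s(t^{n+1}) dt/(dx dy)`` to the v3 slot of the ring columns."""
    key = (id(field.q), field.shape, field.spacing, src.radius)
    cells = _cache.get(key)
    if cells is None:
        cells = ring_cells(field, src.radius)
        _cache.clear()
        _cache[key] = cells
    amp = (signal(t_next, src.Omega, src.amplitude) * dt
           / (field.spacing[0] * field.spacing[1]))
    gx, gy, _ = field.ghosts
    field.q[cells[:, 0] + gx, cells[:, 1] + gy,
            field.interior_slices[2], _V_SLOTS[2]] += amp
    return field


def apply_gaussian_source(field: StateField, t_next: float, dt: float,
                          src: SourceSpec, _cache={}) -> StateField:
    """Add ``A s(t^{n+1}) dt G(X)`` to the v2 slot (truncated Gaussian)."""
    key = (id(field.q), field.shape, field.spacing, src.sigma, src.cutoff)
    G = _cache.get(key)
    if G is None:
        G = gaussian_profile(field, src)
        _cache.clear()
        _cache[key] = G
    amp = signal(t_next, src.Omega, src.amplitude) * dt
    field.interior[..., _V_SLOTS[1]] += amp * G
    return field


_APPLIERS = {
    "point": apply_point_source,
    "ring": apply_ring_source,
    "gaussian_sphere": apply_gaussian_source,
}


def apply_source(field: StateField, t_next: float, dt: float,
                 src: SourceSpec) -> StateField:
    """Dispatch on the source kind."""
    return _APPLIERS[src.kind](field, t_next, dt, src)
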