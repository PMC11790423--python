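"""Batched 3x3 tensor algebra helpers.

All routines operate on arrays whose last two axes are the tensor axes
(shape ``(..., 3, 3)``), so the same code path serves a single material
point and a whole grid of cells. Determinants and inverses use the
closed-form cofactor expressions; symmetric tensors are packed into
6-vectors in the fixed component order (11, 12, 13, 22, 23, 33).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "IDENTITY",
    "det3",
    "inv3",
    "trace",
    "ddot",
    "sym",
    "mat_from_sym6",
    "sym6_from_mat",
    "SYM6_INDICES",
]

IDENTITY = np.eye(3)

#: (row, col) pairs of the packed symmetric components, order (11,12,13,22,23,33).
SYM6_INDICES = ((0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2))


def det3(a: np.ndarray) -> np.ndarray:
    """Determinant of ``(..., 3, 3)`` arrays via cofactor expansion."""
    return (
        a[..., 0, 0] * (a[..., 1, 1] * a[..., 2, 2] - a[..., 1, 2] * a[..., 2, 1])
        - a[..., 0, 1] * (a[..., 1, 0] * a[..., 2, 2] - a[..., 1, 2] * a[..., 2, 0])
        + a[..., 0, 2] * (a[..., 1, 0] * a[..., 2, 1] - a[..., 1, 1] * a[..., 2, 0])
    )


def inv3(a: np.ndarray, det: np.ndarray | None = None) -> np.ndarray:
    """Inverse of ``(..., 3, 3)`` arrays from the adjugate.

    ``det`` may be passed to reuse a previously computed determinant.
    Raises ``np.linalg.LinAlgError`` on (near-)singular input.
    """
    a = np.asarray(a, dtype=float)
    if det is None:
        det = det3(a)
    if np.any(np.abs(det) < 1e-300):
        raise np.linalg.LinAlgError("singular 3x3 tensor")
    adj = np.empty_like(a)
    adj[..., 0, 0] = a[..., 1, 1] * a[..., 2, 2] - a[..., 1, 2] * a[..., 2, 1]
    adj[..., 0, 1] = a[..., 0, 2] * a[..., 2, 1] - a[..., 0, 1] * a[..., 2, 2]
    adj[..., 0, 2] = a[..., 0, 1] * a[..., 1, 2] - a[..., 0, 2] * a[..., 1, 1]
    adj[..., 1, 0] = a[..., 1, 2] * a[..., 2, 0] - a[..., 1, 0] * a[..., 2, 2]
    adj[..., 1, 1] = a[..., 0, 0] * a[..., 2, 2] - a[..., 0, 2] * a[..., 2, 0]
    adj[..., 1, 2] = a[..., 0, 2] * a[..., 1, 0] - a[..., 0, 0] * a[..., 1, 2]
    adj[..., 2, 0] = a[..., 1, 0] * a[..., 2, 1] - a[..., 1, 1] * a[..., 2, 0]
    adj[..., 2, 1] = a[..., 0, 1] * a[..., 2, 0] - a[..., 0, 0] * a[..., 2, 1]
    adj[..., 2, 2] = a[..., 0, 0] * a[..., 1, 1] - a[..., 0, 1] * a[..., 1, 0]
    return adj / det[..., None, None]


def trace(a: np.ndarray) -> np.ndarray:
    return a[..., 0, 0] + a[..., 1, 1] + a[..., 2, 2]


def ddot(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Double contraction ``a : b`` over the last two axes."""
    return np.einsum("...ij,...ij->...", a, b)


def sym(a: np.ndarray) -> np.ndarray:
    return 0.5 * (a + np.swapaxes(a, -1, -2))


def mat_from_sym6(s6: np.ndarray) -> np.ndarray:
    """Expand packed ``(..., 6)`` symmetric components to ``(..., 3, 3)``."""
    s6 = np.asarray(s6, dtype=float)
    out = np.empty(s6.shape[:-1] + (3, 3), dtype=s6.dtype)
    for k, (i, j) in enumerate(SYM6_INDICES):
        out[..., i, j] = s6[..., k]
        out[..., j, i] = s6[..., k]
    return out


def sym6_from_mat(a: np.ndarray) -> np.ndarray:
    """Pack a symmetric ``(..., 3, 3)`` tensor into 6 components."""
    a = np.asarray(a, dtype=float)
    out = np.empty(a.shape[:-2] + (6,), dtype=a.dtype)
    for k, (i, j) in enumerate(SYM6_INDICES):
        out[..., k] = a[..., i, j]
    return out
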