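"""Vectorised capsule (spherocylinder) geometry for the 2D colony engine.

A cell of length ``L`` and width ``w`` is a capsule: a centreline segment of
length ``L - w`` swept by a disc of radius ``w/2``.  Two capsules overlap
when their centreline distance is below the width, and their surfaces are
within ``gap`` when the centreline distance is below ``width + gap``.

These routines are the inner loop of the overlap-relaxation step, so they
avoid generic helpers in favour of fused array arithmetic.
"""

from __future__ import annotations

import numpy as np


def axis_vectors(angle: np.ndarray) -> np.ndarray:
    """Unit axis vectors, shape ``(n, 2)``, for orientation angles."""
    return np.column_stack([np.cos(angle), np.sin(angle)])


def half_lengths(length: np.ndarray, width: float) -> np.ndarray:
    """Half-length of the centreline segment of each capsule."""
    return np.maximum(length - width, 0.0) / 2.0


def pair_distances(
    centers: np.ndarray,
    u: np.ndarray,
    h: np.ndarray,
    pi: np.ndarray,
    pj: np.ndarray,
    want_direction: bool = True,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Centreline distances (and separation directions) for cell pairs.

    ``u`` are the per-cell unit axes and ``h`` the segment half-lengths.
    Segments are ``c + s*u`` with ``s`` in ``[-h, h]``; the closest pair of
    points is found with the standard clamped two-pass solution of the
    unconstrained minimiser (exact for non-parallel segments, a good
    relaxation direction for parallel ones).  ``direction`` points from cell
    j toward cell i at closest approach; coincident closest points fall back
    to the perpendicular of cell i's axis.
    """
    c1x, c1y = centers[pi, 0], centers[pi, 1]
    u1x, u1y = u[pi, 0], u[pi, 1]
    u2x, u2y = u[pj, 0], u[pj, 1]
    h1, h2 = h[pi], h[pj]
    rx = c1x - centers[pj, 0]
    ry = c1y - centers[pj, 1]

    B = u1x * u2x + u1y * u2y
    C = u1x * rx + u1y * ry
    F = u2x * rx + u2y * ry
    denom = 1.0 - B * B
    s = np.where(denom > 1e-9, (B * F - C) / np.where(denom > 1e-9, denom, 1.0), 0.0)
    np.clip(s, -h1, h1, out=s)
    t = B * s + F
    np.clip(t, -h2, h2, out=t)
    s = B * t - C
    np.clip(s, -h1, h1, out=s)

    dx = rx + s * u1x - t * u2x
    dy = ry + s * u1y - t * u2y
    dist = np.sqrt(dx * dx + dy * dy)
    if not want_direction:
        return dist, None
    safe = np.where(dist > 1e-12, dist, 1.0)
    direction = np.empty((len(dist), 2))
    direction[:, 0] = dx / safe
    direction[:, 1] = dy / safe
    degenerate = dist <= 1e-12
    if degenerate.any():
        direction[degenerate, 0] = -u1y[degenerate]
        direction[degenerate, 1] = u1x[degenerate]
    return dist, direction


def capsule_pair_distances(
    centers: np.ndarray,
    angles: np.ndarray,
    lengths: np.ndarray,
    width: float,
    pairs_i: np.ndarray,
    pairs_j: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Convenience wrapper of :func:`pair_distances` taking raw angles and
    lengths; returns ``(dist, direction)``."""
    u = axis_vectors(angles)
    h = half_lengths(lengths, width)
    dist, direction = pair_distances(centers, u, h, pairs_i, pairs_j)
    return dist, direction
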