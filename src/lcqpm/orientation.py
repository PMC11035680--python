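"""Local fringe orientation and direction estimation.

The spiral-phase quadrature transform needs the local fringe *direction*
beta(x, y) defined modulo 2 pi.  Gradient-based estimators only deliver the
*orientation* modulo pi (a fringe looks the same flipped by 180 degrees),
so the pipeline runs in two steps: a structure-tensor orientation estimate
with a coherence (anisotropy) confidence map, then a coherence-seeded
region-growing pass that resolves the pi-ambiguity into a spatially
consistent direction field.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "OrientationMap",
    "DirectionMap",
    "structure_tensor_orientation",
    "unwrap_direction",
    "fringe_direction",
]


@dataclass(frozen=True)
class OrientationMap:
    """Fringe-normal orientation in [0, pi) with per-pixel coherence in [0, 1]."""

    angle_mod_pi: np.ndarray
    coherence: np.ndarray

    def __post_init__(self) -> None:
        a, c = self.angle_mod_pi, self.coherence
        if np.any(a < 0) or np.any(a >= np.pi):
            raise ValueError("orientation angles must lie in [0, pi)")
        if np.any(c < -1e-9) or np.any(c > 1 + 1e-9):
            raise ValueError("coherence must lie in [0, 1]")


@dataclass(frozen=True)
class DirectionMap:
    """Fringe direction beta in [0, 2 pi), consistent up to one global sign."""

    beta: np.ndarray

    def __post_init__(self) -> None:
        b = self.beta
        if np.any(b < 0) or np.any(b >= 2 * np.pi):
            raise ValueError("direction must lie in [0, 2 pi)")


def structure_tensor_orientation(fringe: np.ndarray, sigma_grad: float = 1.0,
                                 sigma_window: float | None = None) -> OrientationMap:
    """Gradient structure-tensor estimate of the fringe-normal orientation.

    The tensor J = <g g^T> is formed from Gaussian-derivative gradients at
    scale ``sigma_grad`` and window-averaged at ``sigma_window`` (default:
    3 px; in the pipeline it is set to the local fringe period so the
    average spans at least one fringe).  The dominant eigenvector gives
    ``angle = 0.5 * atan2(2 Jxy, Jxx - Jyy)`` mapped to [0, pi); coherence
    is the tensor anisotropy (l1 - l2)/(l1 + l2).
    """
    img = np.asarray(fringe, float)
    if sigma_window is None:
        sigma_window = 3.0
    gx = gaussian_filter(img, sigma_grad, order=(0, 1), mode="mirror")
    gy = gaussian_filter(img, sigma_grad, order=(1, 0), mode="mirror")
    jxx = gaussian_filter(gx * gx, sigma_window, mode="mirror")
    jyy = gaussian_filter(gy * gy, sigma_window, mode="mirror")
    jxy = gaussian_filter(gx * gy, sigma_window, mode="mirror")
    angle = 0.5 * np.arctan2(2.0 * jxy, jxx - jyy)
    angle = np.mod(angle, np.pi)
    angle[angle >= np.pi] = 0.0  # guard against mod rounding at the boundary
    trace = jxx + jyy
    delta = np.sqrt((jxx - jyy) ** 2 + 4.0 * jxy**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        coher = np.where(trace > 1e-30, delta / np.maximum(trace, 1e-30), 0.0)
    return OrientationMap(angle, np.clip(coher, 0.0, 1.0))


def unwrap_direction(om: OrientationMap, coherence_floor: float = 0.0) -> DirectionMap:
    """Resolve the pi-ambiguity of an orientation field by region growing.

    Starting from the highest-coherence pixel, pixels are visited in
    descending coherence order (a best-first flood fill); each pixel takes
    the candidate beta in {angle, angle + pi} closest, on the circle, to
    the mean direction of its already-assigned neighbors.  The result is a
    direction field in [0, 2 pi), determined up to one global pi flip (the
    single sign degree of freedom of quadrature demodulation).
    """
    angle = om.angle_mod_pi
    coher = om.coherence
    if not np.any(coher > 0):
        raise ValueError("no reliable seed: coherence map is identically zero")
    rows, cols = angle.shape
    # accumulate assigned directions as unit vectors for neighbor voting
    ux = np.zeros((rows, cols))
    uy = np.zeros((rows, cols))
    assigned = np.zeros((rows, cols), bool)
    beta = np.mod(angle.copy(), 2 * np.pi)

    seed = np.unravel_index(np.argmax(coher), coher.shape)
    heap = [(-float(coher[seed]), int(seed[0]), int(seed[1]))]
    in_heap = np.zeros((rows, cols), bool)
    in_heap[seed] = True
    while heap:
        _, r, c = heapq.heappop(heap)
        if assigned[r, c]:
            continue
        # neighbor vote: mean unit vector of assigned 4-neighbors
        vx = vy = 0.0
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols and assigned[rr, cc]:
                vx += ux[rr, cc]
                vy += uy[rr, cc]
        a = angle[r, c]
        if vx == 0.0 and vy == 0.0:
            b = a  # seed (or isolated start): keep the raw orientation
        else:
            b = a if np.cos(a) * vx + np.sin(a) * vy >= 0.0 else a + np.pi
        beta[r, c] = np.mod(b, 2 * np.pi)
        ux[r, c] = np.cos(b)
        uy[r, c] = np.sin(b)
        assigned[r, c] = True
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols and not assigned[rr, cc] \
                    and not in_heap[rr, cc]:
                heapq.heappush(heap, (-float(coher[rr, cc]), rr, cc))
                in_heap[rr, cc] = True
    return DirectionMap(beta)


def fringe_direction(fringe: np.ndarray, sigma_grad: float = 1.0,
                     sigma_window: float | None = None) -> tuple:
    """Orientation + direction in one call; returns (OrientationMap, DirectionMap)."""
    om = structure_tensor_orientation(fringe, sigma_grad, sigma_window)
    return om, unwrap_direction(om)
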