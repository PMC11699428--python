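"""Agent-based homogenization of grayscale images (phase 1).

Every pixel is an agent holding one of 256 intensity states.  Each sweep,
an agent compares itself with its neighbourhood and takes the *sign
consensus*

    S(e0) = sign( sum_q sign(e_q - e0) )

over the available neighbours e_q, then moves its state by +delta
(S = +1), -delta (S = -1) or not at all (S = 0), clamped to [0, 255].
A uniform region is a fixed point, a perfectly balanced edge pixel is
left untouched, and noisy outliers are dragged toward the surrounding
region one step per sweep, so regions homogenize while edges survive.

Agents are updated sequentially along a raster path (rows top to bottom,
right-to-left within each row by default), so an agent updated earlier in
the sweep exposes its new value to agents visited later.  A synchronous
variant (all agents update from the previous sweep's states) is available
behind a config switch for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from numba import njit

__all__ = ["ABMConfig", "neighbor_consensus", "apply_rule", "abm_step", "run_abm"]

_OFFSETS_MOORE = ((-1, -1), (-1, 0), (-1, 1), (0, -1),
                  (0, 1), (1, -1), (1, 0), (1, 1))
_OFFSETS_VON_NEUMANN = ((-1, 0), (0, -1), (0, 1), (1, 0))


@dataclass(frozen=True)
class ABMConfig:
    """Settings of the homogenization phase.

    iter1
        Number of full sweeps over the grid (0 leaves the image unchanged).
    delta
        Integer intensity step per update, >= 1.  The per-sweep change of
        any pixel is bounded by delta, so delta trades smoothing speed
        against granularity.  The default of 1 is the smallest step that
        preserves integer states; larger values homogenize faster but
        drift region means further (see the methods note).
    neighborhood
        "moore" (8 neighbours, default) or "von_neumann" (4 neighbours).
        Boundary pixels use only the neighbours that exist (no padding).
    scan
        "right_to_left" (default) or "left_to_right" within each row; rows
        are always visited top to bottom.
    synchronous
        If True, all agents update simultaneously from the previous
        iteration's states instead of the sequential in-place scheme.
    """

    iter1: int = 100
    delta: int = 1
    neighborhood: str = "moore"
    scan: str = "right_to_left"
    synchronous: bool = False

    def __post_init__(self):
        if self.iter1 < 0:
            raise ValueError("iter1 must be >= 0")
        if int(self.delta) != self.delta or self.delta < 1:
            raise ValueError("delta must be an integer >= 1")
        if self.neighborhood not in ("moore", "von_neumann"):
            raise ValueError("neighborhood must be 'moore' or 'von_neumann'")
        if self.scan not in ("right_to_left", "left_to_right"):
            raise ValueError("scan must be 'right_to_left' or 'left_to_right'")


def _offsets(neighborhood: str):
    if neighborhood == "moore":
        return _OFFSETS_MOORE
    if neighborhood == "von_neumann":
        return _OFFSETS_VON_NEUMANN
    raise ValueError(f"unknown neighborhood {neighborhood!r}")


def neighbor_consensus(grid: np.ndarray, i: int, j: int,
                       neighborhood: str = "moore") -> int:
    """Sign consensus S in {-1, 0, +1} of pixel (i, j) with its neighbours."""
    g = np.asarray(grid)
    m, n = g.shape
    if not (0 <= i < m and 0 <= j < n):
        raise IndexError(f"position ({i}, {j}) outside {m}x{n} grid")
    center = int(g[i, j])
    total = 0
    for di, dj in _offsets(neighborhood):
        ni, nj = i + di, j + dj
        if 0 <= ni < m and 0 <= nj < n:
            d = int(g[ni, nj]) - center
            total += (d > 0) - (d < 0)
    return (total > 0) - (total < 0)


def apply_rule(e0_state: int, s: int, delta: int) -> int:
    """One rule application: move the state by s*delta, clamped to [0, 255]."""
    if s not in (-1, 0, 1):
        raise ValueError("S must be -1, 0 or +1")
    return int(min(255, max(0, int(e0_state) + s * int(delta))))


@njit(cache=True)
def _sweep_sequential(g, delta, moore, right_to_left):  # pragma: no cover
    m, n = g.shape
    for i in range(m):
        for col in range(n):
            j = n - 1 - col if right_to_left else col
            total = 0
            for di in range(-1, 2):
                for dj in range(-1, 2):
                    if di == 0 and dj == 0:
                        continue
                    if not moore and di != 0 and dj != 0:
                        continue
                    ni = i + di
                    nj = j + dj
                    if 0 <= ni < m and 0 <= nj < n:
                        d = g[ni, nj] - g[i, j]
                        if d > 0:
                            total += 1
                        elif d < 0:
                            total -= 1
            if total > 0:
                v = g[i, j] + delta
            elif total < 0:
                v = g[i, j] - delta
            else:
                v = g[i, j]
            if v < 0:
                v = 0
            elif v > 255:
                v = 255
            g[i, j] = v


def _sweep_synchronous(g: np.ndarray, delta: int, neighborhood: str) -> None:
    m, n = g.shape
    total = np.zeros((m, n), dtype=np.int64)
    for di, dj in _offsets(neighborhood):
        r0, r1 = max(0, -di), min(m, m - di)
        c0, c1 = max(0, -dj), min(n, n - dj)
        diff = g[r0 + di:r1 + di, c0 + dj:c1 + dj] - g[r0:r1, c0:c1]
        total[r0:r1, c0:c1] += np.sign(diff)
    g += np.sign(total) * delta
    np.clip(g, 0, 255, out=g)


def _sweep(g: np.ndarray, config: ABMConfig) -> None:
    if config.synchronous:
        _sweep_synchronous(g, int(config.delta), config.neighborhood)
    else:
        _sweep_sequential(g, int(config.delta),
                          config.neighborhood == "moore",
                          config.scan == "right_to_left")


def abm_step(grid: np.ndarray, config: ABMConfig) -> np.ndarray:
    """One full sweep over the grid; returns a new uint8 array."""
    g = np.asarray(grid).astype(np.int64)
    if g.ndim != 2:
        raise ValueError("grid must be 2-D")
    _sweep(g, config)
    return g.astype(np.uint8)


def run_abm(image: np.ndarray, config: ABMConfig,
            callback: Callable[[int, np.ndarray], None] | None = None) -> np.ndarray:
    """Run ``config.iter1`` sweeps and return the homogenized image IH.

    ``callback(t, grid)`` is invoked with the uint8 state after sweep t
    (and once with t=0 for the initial state), e.g. to trace a
    per-iteration dispersion diagnostic.
    """
    g = np.asarray(image).astype(np.int64)
    if g.ndim != 2:
        raise ValueError("image must be 2-D grayscale")
    if g.min() < 0 or g.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")
    if callback is not None:
        callback(0, g.astype(np.uint8))
    for t in range(1, config.iter1 + 1):
        _sweep(g, config)
        if callback is not None:
            callback(t, g.astype(np.uint8))
    return g.astype(np.uint8)
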