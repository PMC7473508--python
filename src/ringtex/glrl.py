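"""Gray-level run-length matrices and the seven Galloway features.

A run is a maximal set of consecutive collinear pixels sharing one gray
level.  Runs are enumerated along every lattice line of a direction —
rows (0°), anti-diagonals (45°), columns (90°) and main diagonals (135°);
diagonal directions include the corner lines of length 1.

Every pixel belongs to exactly one maximal run per direction, so
``sum_j j * r(g, j) = n_pixels`` always holds (pixel conservation).

LGRE/HGRE weight runs by the squared gray level; the level index is
1-based (level 0 would otherwise divide by zero).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .io_roi import QuantizedPatch

GLRL_DIRECTIONS = (0, 45, 90, 135)
GLRL_NAMES = ("SRE", "LRE", "GLN", "RP", "RLN", "LGRE", "HGRE")


@dataclass
class RunLengthMatrix:
    """r[g, j-1] = number of maximal runs of level g with length j."""

    r: np.ndarray           # L x Jmax counts
    L: int
    n_pixels: int
    direction: int

    @property
    def n_runs(self) -> int:
        return int(self.r.sum())


def _lines(a: np.ndarray, direction: int) -> Iterator[np.ndarray]:
    """Yield the lattice lines of the patch along one direction."""
    h, w = a.shape
    if direction == 0:
        yield from a
    elif direction == 90:
        yield from a.T
    elif direction == 45:
        # anti-diagonals run bottom-left to top-right
        f = np.flipud(a)
        for off in range(-(h - 1), w):
            yield np.diagonal(f, offset=off)
    elif direction == 135:
        for off in range(-(h - 1), w):
            yield np.diagonal(a, offset=off)
    else:
        raise ValueError(f"direction must be one of {GLRL_DIRECTIONS}")


def _run_lengths(line: np.ndarray) -> Iterator[tuple[int, int]]:
    """(level, run length) for each maximal run in a 1-D line."""
    if line.size == 0:
        return
    change = np.flatnonzero(np.diff(line) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [line.size]))
    for s, e in zip(starts, ends):
        yield int(line[s]), int(e - s)


def compute_rlm(patch: QuantizedPatch, direction: int) -> RunLengthMatrix:
    """Enumerate maximal runs along every line of the direction."""
    a = patch.levels
    jmax = max(a.shape)
    r = np.zeros((patch.L, jmax), dtype=np.int64)
    for line in _lines(a, direction):
        for level, length in _run_lengths(np.asarray(line)):
            r[level, length - 1] += 1
    return RunLengthMatrix(r=r, L=patch.L, n_pixels=a.size, direction=direction)


def glrl_features(m: RunLengthMatrix) -> dict[str, float]:
    """Galloway's seven run-length statistics of one matrix."""
    n_r = m.n_runs
    if n_r < 1:
        raise ValueError("empty run-length matrix")
    r = m.r.astype(float)
    j = np.arange(1, r.shape[1] + 1, dtype=float)      # run lengths
    g = np.arange(1, m.L + 1, dtype=float)             # 1-based levels

    runs_per_level = r.sum(axis=1)
    runs_per_length = r.sum(axis=0)
    return {
        "SRE": float(np.sum(runs_per_length / j**2)) / n_r,
        "LRE": float(np.sum(runs_per_length * j**2)) / n_r,
        "GLN": float(np.sum(runs_per_level**2)) / n_r,
        "RP": n_r / m.n_pixels,
        "RLN": float(np.sum(runs_per_length**2)) / n_r,
        "LGRE": float(np.sum(runs_per_level / g**2)) / n_r,
        "HGRE": float(np.sum(runs_per_level * g**2)) / n_r,
    }


def glrl_directional_average(patch: QuantizedPatch) -> dict[str, float]:
    """Features per direction, averaged over the four directions."""
    per_dir = [glrl_features(compute_rlm(patch, d)) for d in GLRL_DIRECTIONS]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLRL_NAMES}
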