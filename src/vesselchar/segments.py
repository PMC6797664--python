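"""Decomposition of the binary skeleton into ordered vessel-segment paths.

Junction pixels (three or more skeleton neighbours) are removed first so
that crossing vessels split into simple arcs; each remaining connected
arc is traced endpoint-to-endpoint into an ordered pixel path.  Arcs of
20 px or less are discarded — only longer segments carry usable
curvature information.  Every kept segment gets the reference geometry
used by the angle/distance indicators: point A at the head of the path
and point B one pixel along the image row axis, a fixed baseline shared
by all segments so the angle of a skeleton point about A is well
defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["VesselSegment", "SegmentSet", "extract_segments", "assign_reference"]

_NEIGH_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.uint8)
_EIGHT = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class VesselSegment:
    """An ordered 1-px-wide skeleton path with its reference points.

    ``path`` is an (n, 2) integer array of (row, col) coordinates whose
    consecutive entries are 8-neighbours.  ``ref_a`` is the first path
    pixel and ``ref_b`` is ``ref_a`` shifted by one column — the common
    baseline direction for the angle indicator.
    """

    path: np.ndarray
    ref_a: tuple[int, int]
    ref_b: tuple[int, int]

    @property
    def length_px(self) -> int:
        return len(self.path)


@dataclass(frozen=True)
class SegmentSet:
    segments: tuple[VesselSegment, ...]

    @property
    def M(self) -> int:
        """Number of vessel segments in the image."""
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)


def assign_reference(path: np.ndarray) -> VesselSegment:
    """Attach the reference points A (path head) and B (A + one column)."""
    path = np.asarray(path, dtype=int)
    if len(path) < 2:
        raise ValueError("cannot assign references to a single-pixel path")
    a = (int(path[0, 0]), int(path[0, 1]))
    return VesselSegment(path=path, ref_a=a, ref_b=(a[0], a[1] + 1))


def extract_segments(skeleton: np.ndarray, min_len: int = 21) -> SegmentSet:
    """Trace the skeleton into ordered vessel segments.

    Parameters
    ----------
    skeleton:
        Binary 1-px-wide skeleton mask.
    min_len:
        Minimum path length (in pixels) to keep; the default keeps
        segments strictly longer than 20 px.
    """
    sk = np.asarray(skeleton).astype(bool)
    if not sk.any():
        return SegmentSet(segments=())
    nb = ndimage.convolve(sk.astype(np.uint8), _NEIGH_KERNEL, mode="constant")
    arcs = sk & (nb < 3)  # drop junction pixels
    labels, n = ndimage.label(arcs, structure=_EIGHT)
    paths: list[np.ndarray] = []
    for i in range(1, n + 1):
        pix = np.argwhere(labels == i)
        if len(pix) < min_len:
            continue
        path = _trace_arc(pix)
        if len(path) >= min_len:
            paths.append(path)
    paths.sort(key=lambda p: (int(p[0, 0]), int(p[0, 1])))
    return SegmentSet(segments=tuple(assign_reference(p) for p in paths))


def _trace_arc(pixels: np.ndarray) -> np.ndarray:
    """Order the pixels of one connected arc into a path.

    The walk starts at the lexicographically smallest endpoint (pixel
    with at most one neighbour in the arc); a closed loop has no
    endpoint and is cut at its lexicographically smallest pixel.
    """
    cells = {(int(r), int(c)) for r, c in pixels}
    neigh = {p: _neighbours(p, cells) for p in cells}
    endpoints = sorted(p for p, nb in neigh.items() if len(nb) <= 1)
    start = endpoints[0] if endpoints else min(cells)
    path = [start]
    visited = {start}
    cur = start
    while True:
        nxt = [p for p in neigh[cur] if p not in visited]
        if not nxt:
            break
        cur = min(nxt)
        path.append(cur)
        visited.add(cur)
    return np.array(path, dtype=int)


def _neighbours(p: tuple[int, int], cells: set[tuple[int, int]]):
    r, c = p
    out = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == dc == 0:
                continue
            q = (r + dr, c + dc)
            if q in cells:
                out.append(q)
    return out
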