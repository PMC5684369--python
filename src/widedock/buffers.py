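"""Search-history storage: per-walker circular buffers and a shared octree.

Every visited point goes into its walker's bounded circular buffer
(capacity ``Q``); only the *end points* of local optimization -- the
high-quality points -- enter the shared, unbounded octree, indexed by
their three spatial dimensions.  Proximity queries first filter by
spatial distance (cutoff ``R``) and then order the survivors by full-N
distance, nearer to farther.

Point payloads live in flat, amortized-growth arrays owned by the
octree; tree leaves hold indices into them, so range queries reduce to
vectorized distance computations over the gathered indices.
"""

from __future__ import annotations

import threading
from collections import deque

import numpy as np

from .objectives import (DofLayout, InvalidArgumentError, SearchPoint,
                         SPATIAL_DIMS, WideDockError, distance_many)

#: Minimum octree cell width (Angstrom); takes priority over S_MAX.
W_MIN = 0.1
#: Maximum points per octree leaf before it splits (unless W_MIN forbids).
S_MAX = 8


class OutOfBoundsError(WideDockError, ValueError):
    """A point lies outside the octree root cell."""


# ---------------------------------------------------------------------------
# Circular (individual) buffer
# ---------------------------------------------------------------------------

class CircularBuffer:
    """Bounded per-walker history; newest entries first on iteration.

    Inserting into a full buffer evicts the oldest entry.  Entries keep a
    monotonically increasing insertion sequence number used to break
    distance ties (earlier first).
    """

    def __init__(self, capacity: int):
        if capacity < 1:
            raise InvalidArgumentError("capacity must be >= 1")
        self.capacity = capacity
        self._entries: deque[tuple[int, SearchPoint]] = deque(maxlen=capacity)
        self._seq = 0

    def push(self, point: SearchPoint) -> None:
        self._entries.append((self._seq, point))
        self._seq += 1

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        """Yield points newest first."""
        for _, p in reversed(self._entries):
            yield p

    def __contains__(self, point: SearchPoint) -> bool:
        return any(p is point for _, p in self._entries)

    def nearest(self, candidate, k: int,
                layout: DofLayout | None = None) -> list[SearchPoint]:
        """Up to ``k`` stored points closest to ``candidate`` in full-N
        distance, nearest first (ties: earlier insertion first)."""
        if k < 0:
            raise InvalidArgumentError("k must be >= 0")
        if k == 0 or not self._entries:
            return []
        cand = candidate.coords if isinstance(candidate, SearchPoint) else candidate
        seqs = np.fromiter((s for s, _ in self._entries), dtype=np.int64,
                           count=len(self._entries))
        coords = np.array([p.coords for _, p in self._entries])
        dists = distance_many(cand, coords, layout)
        order = np.lexsort((seqs, dists))[:k]
        points = [p for _, p in self._entries]
        return [points[i] for i in order]


# ---------------------------------------------------------------------------
# Octree (global buffer)
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("lo", "hi", "bounds", "mid", "indices", "children")

    def __init__(self, lo: np.ndarray, hi: np.ndarray):
        self.lo = lo
        self.hi = hi
        # scalar copies keep the traversal free of tiny-array overhead
        self.bounds = (float(lo[0]), float(lo[1]), float(lo[2]),
                       float(hi[0]), float(hi[1]), float(hi[2]))
        self.mid = ((self.bounds[0] + self.bounds[3]) / 2.0,
                    (self.bounds[1] + self.bounds[4]) / 2.0,
                    (self.bounds[2] + self.bounds[5]) / 2.0)
        self.indices: list[int] | None = []
        self.children: list["_Node"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def splittable(self, w_min: float) -> bool:
        return bool(np.all((self.hi - self.lo) / 2.0 >= w_min))


class Octree:
    """Octree over the spatial search box holding full search points.

    The tree indexes only the three spatial dimensions; torsion and
    orientation values ride along as payload.  A leaf that exceeds
    ``s_max`` points splits into eight children that exactly tile it --
    unless any child dimension would fall below ``w_min``, in which case
    the leaf simply over-fills (``w_min`` has priority over ``s_max``).
    Duplicate points are allowed.
    """

    def __init__(self, lo, hi, w_min: float = W_MIN, s_max: int = S_MAX):
        lo = np.asarray(lo, float)[:SPATIAL_DIMS].copy()
        hi = np.asarray(hi, float)[:SPATIAL_DIMS].copy()
        if np.any(hi <= lo):
            raise InvalidArgumentError("octree box must have positive extent")
        self.w_min = float(w_min)
        self.s_max = int(s_max)
        self.root = _Node(lo, hi)
        self._points: list[SearchPoint] = []
        self._spatial = np.empty((64, SPATIAL_DIMS))
        self._coords: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self._points)

    # storage ----------------------------------------------------------
    def _store(self, point: SearchPoint, spatial: np.ndarray) -> int:
        idx = len(self._points)
        if self._coords is None:
            self._coords = np.empty((64, point.coords.shape[0]))
        if idx == self._spatial.shape[0]:
            self._spatial = np.vstack([self._spatial,
                                       np.empty_like(self._spatial)])
            self._coords = np.vstack([self._coords,
                                      np.empty_like(self._coords)])
        self._points.append(point)
        self._spatial[idx] = spatial
        self._coords[idx] = point.coords
        return idx

    # insertion --------------------------------------------------------
    def insert(self, point: SearchPoint,
               spatial: np.ndarray | None = None) -> None:
        """Insert a point; raises :class:`OutOfBoundsError` outside the
        root cell.  ``spatial`` overrides the indexed position (used by
        the archive to clamp out-of-box end points)."""
        sp = np.asarray(point.coords[:SPATIAL_DIMS] if spatial is None
                        else spatial, float)
        if np.any(sp < self.root.lo) or np.any(sp > self.root.hi):
            raise OutOfBoundsError("point outside octree root cell")
        idx = self._store(point, sp)
        self._descend_insert(self.root, idx)

    def _child_index(self, node: _Node, sp: np.ndarray) -> int:
        mid = node.mid
        return ((sp[0] >= mid[0]) | ((sp[1] >= mid[1]) << 1)
                | ((sp[2] >= mid[2]) << 2))

    def _descend_insert(self, node: _Node, idx: int) -> None:
        sp = self._spatial[idx]
        while not node.is_leaf:
            node = node.children[self._child_index(node, sp)]
        node.indices.append(idx)
        if len(node.indices) > self.s_max and node.splittable(self.w_min):
            self._split(node)

    def _split(self, node: _Node) -> None:
        mid = (node.lo + node.hi) / 2.0
        children = []
        for i in range(8):
            lo = node.lo.copy()
            hi = node.hi.copy()
            for d in range(SPATIAL_DIMS):
                if i & (1 << d):
                    lo[d] = mid[d]
                else:
                    hi[d] = mid[d]
            children.append(_Node(lo, hi))
        indices = node.indices
        node.indices = None
        node.children = children
        for idx in indices:
            self._descend_insert(node, idx)

    # queries ----------------------------------------------------------
    def query(self, candidate, radius: float,
              layout: DofLayout | None = None) -> list[SearchPoint]:
        """Stored points with spatial distance <= radius, ordered by
        full-N distance nearer to farther (ties: earlier insertion
        first).  Cells wholly farther than ``radius`` are pruned without
        visiting their points."""
        if radius <= 0:
            raise InvalidArgumentError("radius must be > 0")
        cand = candidate.coords if isinstance(candidate, SearchPoint) else candidate
        cand = np.asarray(cand, float)
        csp = cand[:SPATIAL_DIMS]
        cx, cy, cz = float(csp[0]), float(csp[1]), float(csp[2])
        gathered: list[int] = []
        stack = [self.root]
        r2 = radius * radius
        while stack:
            node = stack.pop()
            lo0, lo1, lo2, hi0, hi1, hi2 = node.bounds
            gx = (lo0 - cx) if cx < lo0 else (cx - hi0 if cx > hi0 else 0.0)
            gy = (lo1 - cy) if cy < lo1 else (cy - hi1 if cy > hi1 else 0.0)
            gz = (lo2 - cz) if cz < lo2 else (cz - hi2 if cz > hi2 else 0.0)
            if gx * gx + gy * gy + gz * gz > r2:
                continue
            if node.children is None:
                gathered.extend(node.indices)
            else:
                stack.extend(node.children)
        if not gathered:
            return []
        idxs = np.asarray(gathered, dtype=np.int64)
        d = self._spatial[idxs] - csp[None, :]
        within = np.sum(d * d, axis=1) <= r2
        idxs = idxs[within]
        if idxs.size == 0:
            return []
        full = distance_many(cand, self._coords[idxs], layout)
        order = np.lexsort((idxs, full))
        return [self._points[i] for i in idxs[order]]

    # introspection used by structural-invariant tests -----------------
    def leaves(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                yield node
            else:
                stack.extend(node.children)

    def check_invariants(self) -> None:
        """Raise AssertionError if any structural invariant is violated."""
        count = 0
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                count += len(node.indices)
                for i in node.indices:
                    sp = self._spatial[i]
                    assert np.all(sp >= node.lo - 1e-12), "below cell bounds"
                    assert np.all(sp <= node.hi + 1e-12), "above cell bounds"
                if len(node.indices) > self.s_max:
                    assert not node.splittable(self.w_min), \
                        "over-full leaf that could still split"
            else:
                assert len(node.children) == 8
                mid = (node.lo + node.hi) / 2.0
                lows = sorted(tuple(c.lo) for c in node.children)
                expect = sorted(
                    tuple(np.where([i & (1 << d) for d in range(3)], mid,
                                   node.lo))
                    for i in range(8))
                assert lows == expect, "children do not tile parent"
                stack.extend(node.children)
        assert count == len(self._points), "stored point count drifted"


# ---------------------------------------------------------------------------
# Shared archive of end points
# ---------------------------------------------------------------------------

class HistoryArchive:
    """The shared global buffer: an octree of local-optimization end points.

    Only end points (outputs of the last local-optimization iteration)
    are archived; ordinary Monte Carlo visits never enter.  End points
    that fall outside the search box (the optimizer may step out) are
    clamped into the root cell for indexing while keeping their original
    coordinates as payload.  The archive grows without bound.
    """

    def __init__(self, box_lo, box_hi, layout: DofLayout | None = None,
                 w_min: float = W_MIN, s_max: int = S_MAX):
        self.box_lo = np.asarray(box_lo, float)[:SPATIAL_DIMS]
        self.box_hi = np.asarray(box_hi, float)[:SPATIAL_DIMS]
        self.layout = layout
        self.octree = Octree(self.box_lo, self.box_hi, w_min, s_max)

    def __len__(self) -> int:
        return len(self.octree)

    def add_end_point(self, point: SearchPoint) -> None:
        """Archive a local-optimization end point (must carry score and
        gradient)."""
        point.require_evaluated()
        clamped = np.clip(point.coords[:SPATIAL_DIMS],
                          self.box_lo, self.box_hi)
        self.octree.insert(point, spatial=clamped)

    def query(self, candidate, radius: float) -> list[SearchPoint]:
        return self.octree.query(candidate, radius, self.layout)

    def dump_rows(self):
        """Yield (seq, coords, score) rows for trace export."""
        for i, p in enumerate(self.octree._points):
            yield i, p.coords, p.score


def synchronized(archive: HistoryArchive) -> "SynchronizedArchive":
    """Wrap an archive in the synchronized-access contract."""
    return SynchronizedArchive(archive)


class SynchronizedArchive:
    """Synchronized reading/writing to the shared archive.

    Writers are exclusive and queries see a consistent snapshot (never a
    half-split node); a reentrant lock serializes both.  Under the
    deterministic round-robin scheduler this degenerates to sequential
    access with no contention.
    """

    def __init__(self, archive: HistoryArchive):
        self._archive = archive
        self._lock = threading.RLock()

    def __len__(self) -> int:
        with self._lock:
            return len(self._archive)

    @property
    def layout(self):
        return self._archive.layout

    def add_end_point(self, point: SearchPoint) -> None:
        with self._lock:
            self._archive.add_end_point(point)

    def query(self, candidate, radius: float) -> list[SearchPoint]:
        with self._lock:
            return self._archive.query(candidate, radius)

    def dump_rows(self):
        with self._lock:
            return list(self._archive.dump_rows())
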