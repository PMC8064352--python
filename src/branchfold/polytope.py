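"""Branching polytopes: the convex hull of a sequence's branching signatures.

For one sequence, every secondary structure has a signature (x, y, z, w);
the branching polytope is the convex hull of all achievable signatures.  Its
lower hull in the w-direction (with the w-coefficient fixed at +1) carries
all the parametric information: a signature is MFE-optimal for some branching
parameters (a, b, c) exactly when it is a vertex of that lower hull.

Construction is exact.  Candidate extreme points are gathered either by
exhaustive enumeration of structures (short sequences) or by a polytope-
valued dynamic program that mirrors the folding recursions, propagating the
per-(x, y, z) minimum and maximum of w through Minkowski sums of the DP
cells.  Candidates are then certified as hull vertices by exact rational
convex-combination membership tests; a floating-point hull is used only as a
conservative pre-screen (points are discarded only when they sit at least
half a lattice unit inside the float hull of integer-valued candidates,
which is orders of magnitude beyond any rounding error).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from math import gcd
from pathlib import Path

import numpy as np

from .energy import (
    BranchingSignature,
    EnergyTables,
    ScaledModel,
    iter_pair_tuples,
)
from .geometry import _solve_square, hull_membership
from .structures import RnaSequence, SecondaryStructure, StructureError

__all__ = [
    "BranchingPolytope",
    "build_polytope",
    "lower_hull",
    "facet_inequalities",
    "count_structures",
    "save_polytope",
    "load_polytope",
]

#: Sequences at most this long default to the exhaustive-enumeration strategy
#: (it doubles as the test oracle); longer ones use the polytope DP.
ENUMERATION_LENGTH_LIMIT = 40
#: ... unless they have more structures than this.
ENUMERATION_COUNT_LIMIT = 150_000

DEFAULT_LENGTH_LIMIT = 100

_F = Fraction


@dataclass
class BranchingPolytope:
    """Vertices (in convex position) of a branching polytope.

    ``vertex_structures[k]`` holds structures realizing ``vertices[k]``
    exactly; at least one each, capped with per-vertex truncation flags.
    ``dim`` is the affine dimension of the vertex set; polytopes of
    dimension < 4 are flagged ``lower_dimensional``.
    """

    sequence: RnaSequence
    vertices: list
    vertex_structures: list
    vertex_truncated: list
    dim: int
    lower_dimensional: bool
    is_lower_hull: bool = False
    strategy: str = "enumeration"
    facets: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.vertices)

    def signature_points(self) -> list:
        return [v.point() for v in self.vertices]


# ---------------------------------------------------------------------------
# Fast integer signatures
# ---------------------------------------------------------------------------

def scaled_signature(model: ScaledModel, pairs) -> tuple:
    """(x, y, z, w_scaled) for 0-based ``pairs`` on ``model``'s sequence."""
    n = model.n
    partner = [-1] * n
    for i, j in pairs:
        partner[i] = j
        partner[j] = i
    x = y = z = 0
    w = 0

    def children_of(lo: int, hi: int):
        kids = []
        unp = 0
        k = lo
        while k < hi:
            if partner[k] >= 0:
                kids.append((k, partner[k]))
                k = partner[k] + 1
            else:
                unp += 1
                k += 1
        return kids, unp

    ext, _ = children_of(0, n)
    for (i, j) in ext:
        w += model.term(i, j)
    stackq = list(ext)
    while stackq:
        i, j = stackq.pop()
        kids, unp = children_of(i + 1, j)
        stackq.extend(kids)
        if not kids:
            w += model.hp[j - i - 1] + model.term(i, j)
        elif len(kids) == 1:
            k, l = kids[0]
            size = (k - i - 1) + (j - l - 1)
            if size == 0:
                w += model.stack(i, j)
            else:
                w += model.il[size] + model.term(i, j) + model.term(k, l)
        else:
            x += 1
            y += unp
            z += len(kids) + 1
            w += model.term(i, j) + sum(model.term(a, b) for a, b in kids)
    return x, y, z, w


def count_structures(seq: RnaSequence) -> int:
    """Exact count of valid structures (independent of enumeration order)."""
    n = len(seq)
    model = ScaledModel(seq, EnergyTables.load())
    canon = model.canon
    memo: dict = {}

    def count(i: int, j: int) -> int:
        if j - i < 4:
            return 1
        key = (i, j)
        if key in memo:
            return memo[key]
        total = count(i + 1, j)
        for k in range(i + 4, j + 1):
            if canon[i][k]:
                total += count(i + 1, k - 1) * count(k + 1, j)
        memo[key] = total
        return total

    return count(0, n - 1)


# ---------------------------------------------------------------------------
# Candidate collection: exhaustive enumeration
# ---------------------------------------------------------------------------

class _Extreme:
    """Track per-(x,y,z) extreme w values with realizing structures."""

    __slots__ = ("wmin", "wmax", "smin", "smax", "tmin", "tmax")

    def __init__(self, w: int, pairs):
        self.wmin = self.wmax = w
        self.smin = [pairs]
        self.smax = [pairs]
        self.tmin = self.tmax = False


def _collect_enumeration(seq, model, cap: int):
    table: dict = {}
    for structure_pairs in _iter_pairs(seq):
        x, y, z, w = scaled_signature(model, structure_pairs)
        key = (x, y, z)
        ext = table.get(key)
        if ext is None:
            table[key] = _Extreme(w, structure_pairs)
            continue
        if w < ext.wmin:
            ext.wmin = w
            ext.smin = [structure_pairs]
            ext.tmin = False
        elif w == ext.wmin and len(ext.smin) < cap:
            ext.smin.append(structure_pairs)
        elif w == ext.wmin:
            ext.tmin = True
        if w > ext.wmax:
            ext.wmax = w
            ext.smax = [structure_pairs]
            ext.tmax = False
        elif w == ext.wmax and structure_pairs not in ext.smax and len(ext.smax) < cap:
            ext.smax.append(structure_pairs)
        elif w == ext.wmax and structure_pairs not in ext.smax:
            ext.tmax = True
    return table


def _iter_pairs(seq: RnaSequence):
    yield from iter_pair_tuples(seq, force=True)


# ---------------------------------------------------------------------------
# Candidate collection: polytope-valued dynamic program
# ---------------------------------------------------------------------------

def _cell_shift(cell, dx=0, dy=0, dz=0, dw=0):
    return {(x + dx, y + dy, z + dz): [lo + dw, hi + dw]
            for (x, y, z), (lo, hi) in cell.items()}


def _cell_merge(dst, src) -> None:
    for key, (lo, hi) in src.items():
        cur = dst.get(key)
        if cur is None:
            dst[key] = [lo, hi]
        else:
            if lo < cur[0]:
                cur[0] = lo
            if hi > cur[1]:
                cur[1] = hi


def _cell_minkowski(a, b, dst) -> None:
    for (xa, ya, za), (loa, hia) in a.items():
        for (xb, yb, zb), (lob, hib) in b.items():
            key = (xa + xb, ya + yb, za + zb)
            cur = dst.get(key)
            if cur is None:
                dst[key] = [loa + lob, hia + hib]
            else:
                if loa + lob < cur[0]:
                    cur[0] = loa + lob
                if hia + hib > cur[1]:
                    cur[1] = hia + hib


def _float_envelope_prunable(points, side_w, margin=0.49):
    """Indices strictly inside the float lower envelope (side_w=+1) or upper
    (side_w=-1) by more than ``margin`` lattice units.  Conservative: any
    qhull failure prunes nothing."""
    try:
        from scipy.spatial import ConvexHull, QhullError
    except ImportError:  # pragma: no cover
        return set()
    arr = np.array([[p[0], p[1], p[2], side_w * p[3]] for p in points], dtype=float)
    keep_axes = [k for k in range(4) if np.ptp(arr[:, k]) > 0]
    if len(keep_axes) < 2 or 3 not in keep_axes:
        return set()
    arr = arr[:, keep_axes]
    try:
        hull = ConvexHull(arr)
    except QhullError:
        return set()
    eqs = hull.equations  # n . p + off <= 0 inside
    lower = eqs[eqs[:, -2] < -1e-12]  # facets below in the last axis
    if not len(lower):
        return set()
    prunable = set()
    xy = arr[:, :-1]
    wvals = arr[:, -1]
    # lower envelope = max over lower-facet planes (convex support functions)
    planes_w = (-(lower[:, -1][None, :] + xy @ lower[:, :-2].T)) / lower[:, -2][None, :]
    env = planes_w.max(axis=1)
    for idx in np.nonzero(wvals - env > margin)[0]:
        prunable.add(int(idx))
    return prunable


def _prune_cell(cell, threshold: int = 24) -> None:
    """Drop (x,y,z) entries that cannot contribute to any hull vertex.

    An entry is removable only when its minimum-w point is a convex
    combination from below of other entries and its maximum-w point one from
    above.  Certified by exact midpoint domination, plus a conservative
    float-envelope screen for larger cells.
    """
    if len(cell) <= threshold:
        return
    keys = list(cell.keys())
    los = {k: cell[k][0] for k in keys}
    his = {k: cell[k][1] for k in keys}
    keyset = set(keys)

    def midpoint_dominated(vals, sign):
        out = set()
        for key in keys:
            v = vals[key]
            found = False
            for other in keys:
                if other == key:
                    continue
                mirror = (2 * key[0] - other[0], 2 * key[1] - other[1],
                          2 * key[2] - other[2])
                if mirror in keyset and mirror != key and mirror != other:
                    if sign * 2 * v >= sign * (vals[other] + vals[mirror]):
                        found = True
                        break
            if found:
                out.add(key)
        return out

    lo_prune = midpoint_dominated(los, +1)
    hi_prune = midpoint_dominated(his, -1)
    if len(cell) > 2 * threshold:
        pts_lo = [k + (los[k],) for k in keys]
        pts_hi = [k + (his[k],) for k in keys]
        for idx in _float_envelope_prunable(pts_lo, +1):
            lo_prune.add(keys[idx])
        for idx in _float_envelope_prunable(pts_hi, -1):
            hi_prune.add(keys[idx])
    for key in lo_prune & hi_prune:
        del cell[key]


class _PolytopeDP:
    """Polytope-valued folding DP over (x, y, z, w) extreme tables."""

    def __init__(self, model: ScaledModel):
        self.model = model
        n = model.n
        self.V = [[None] * n for _ in range(n)]
        self.B = [[None] * n for _ in range(n)]
        self.WM = [[None] * n for _ in range(n)]
        self.WM2 = [[None] * n for _ in range(n)]
        self.W = [None] * (n + 1)
        self._run()

    def _run(self) -> None:
        m = self.model
        n = m.n
        canon = m.canon
        for span in range(4, n):
            for i in range(n - span):
                j = i + span
                if canon[i][j]:
                    taij = m.term(i, j)
                    cell = {(0, 0, 0): [m.hp[span - 1] + taij] * 2}
                    if span >= 6 and canon[i + 1][j - 1] and self.V[i + 1][j - 1]:
                        _cell_merge(cell, _cell_shift(self.V[i + 1][j - 1],
                                                      dw=m.stack(i, j)))
                    for k in range(i + 1, j - 4):
                        for l in range(k + 4, j):
                            if (k == i + 1 and l == j - 1) or not self.V[k][l]:
                                continue
                            size = (k - i - 1) + (j - l - 1)
                            _cell_merge(cell, _cell_shift(
                                self.V[k][l],
                                dw=m.il[size] + taij + m.term(k, l)))
                    if self.WM2[i + 1][j - 1]:
                        _cell_merge(cell, _cell_shift(self.WM2[i + 1][j - 1],
                                                      dx=1, dz=1, dw=taij))
                    _prune_cell(cell)
                    self.V[i][j] = cell
                    self.B[i][j] = _cell_shift(cell, dz=1, dw=m.term(i, j))
                wm: dict = {}
                wm2: dict = {}
                if self.WM[i][j - 1]:
                    _cell_merge(wm, _cell_shift(self.WM[i][j - 1], dy=1))
                if self.WM2[i][j - 1]:
                    _cell_merge(wm2, _cell_shift(self.WM2[i][j - 1], dy=1))
                for k in range(i, j - 3):
                    branch = self.B[k][j]
                    if not branch:
                        continue
                    _cell_merge(wm, _cell_shift(branch, dy=k - i))
                    if k >= i + 5 and self.WM[i][k - 1]:
                        both: dict = {}
                        _cell_minkowski(self.WM[i][k - 1], branch, both)
                        _cell_merge(wm, both)
                        _cell_merge(wm2, both)
                _prune_cell(wm)
                _prune_cell(wm2)
                self.WM[i][j] = wm or None
                self.WM2[i][j] = wm2 or None
        self.W[0] = {(0, 0, 0): [0, 0]}
        for t in range(1, n + 1):
            cell = {k: list(v) for k, v in self.W[t - 1].items()}
            for k in range(0, t - 4):
                if self.V[k][t - 1]:
                    ext = _cell_shift(self.V[k][t - 1], dw=self.model.term(k, t - 1))
                    out: dict = {}
                    _cell_minkowski(self.W[k], ext, out)
                    _cell_merge(cell, out)
            _prune_cell(cell)
            self.W[t] = cell

    # -- traceback ----------------------------------------------------------

    def trace(self, xyz, w: int, side: int):
        """One structure with signature (xyz, w); ``side`` 0 = minimum-w
        chains, 1 = maximum-w chains."""
        return self._trace_W(self.model.n, xyz, w, side)

    def _val(self, cell, xyz, side):
        entry = cell.get(xyz) if cell else None
        return entry[side] if entry else None

    def _trace_W(self, t, xyz, w, side):
        if t == 0:
            return () if xyz == (0, 0, 0) and w == 0 else None
        m = self.model
        if self._val(self.W[t - 1], xyz, side) == w:
            got = self._trace_W(t - 1, xyz, w, side)
            if got is not None:
                return got
        for k in range(0, t - 4):
            cellV = self.V[k][t - 1]
            if not cellV:
                continue
            ta = m.term(k, t - 1)
            for sxyz, ext in self.W[k].items():
                sw = ext[side]
                txyz = (xyz[0] - sxyz[0], xyz[1] - sxyz[1], xyz[2] - sxyz[2])
                tv = self._val(cellV, txyz, side)
                if tv is None or sw + tv + ta != w:
                    continue
                left = self._trace_W(k, sxyz, sw, side)
                if left is None:
                    continue
                right = self._trace_V(k, t - 1, txyz, tv, side)
                if right is not None:
                    return left + right
        return None

    def _trace_V(self, i, j, xyz, w, side):
        m = self.model
        taij = m.term(i, j)
        if xyz == (0, 0, 0) and w == m.hp[j - i - 1] + taij:
            return ((i, j),)
        if j - i >= 6 and m.canon[i + 1][j - 1]:
            tv = self._val(self.V[i + 1][j - 1], xyz, side)
            if tv is not None and tv + m.stack(i, j) == w:
                got = self._trace_V(i + 1, j - 1, xyz, tv, side)
                if got is not None:
                    return got + ((i, j),)
        for k in range(i + 1, j - 4):
            for l in range(k + 4, j):
                if (k == i + 1 and l == j - 1) or not self.V[k][l]:
                    continue
                size = (k - i - 1) + (j - l - 1)
                tv = self._val(self.V[k][l], xyz, side)
                if tv is not None and tv + m.il[size] + taij + m.term(k, l) == w:
                    got = self._trace_V(k, l, xyz, tv, side)
                    if got is not None:
                        return got + ((i, j),)
        if xyz[0] >= 1 and xyz[2] >= 1:
            inner = (xyz[0] - 1, xyz[1], xyz[2] - 1)
            tv = self._val(self.WM2[i + 1][j - 1], inner, side)
            if tv is not None and tv + taij == w:
                got = self._trace_WM(i + 1, j - 1, inner, tv, side, two=True)
                if got is not None:
                    return got + ((i, j),)
        return None

    def _trace_WM(self, i, j, xyz, w, side, two: bool):
        m = self.model
        mat = self.WM2 if two else self.WM
        if j > i and xyz[1] >= 1:
            prev = (xyz[0], xyz[1] - 1, xyz[2])
            tv = self._val(mat[i][j - 1], prev, side)
            if tv is not None and tv == w:
                got = self._trace_WM(i, j - 1, prev, tv, side, two)
                if got is not None:
                    return got
        for k in range(i, j - 3):
            branch = self.B[k][j]
            if not branch:
                continue
            if not two:
                solo = (xyz[0], xyz[1] - (k - i), xyz[2])
                if solo[1] >= 0:
                    tv = self._val(branch, solo, side)
                    if tv is not None and tv == w:
                        got = self._trace_B(k, j, solo, tv, side)
                        if got is not None:
                            return got
            if k >= i + 5 and self.WM[i][k - 1]:
                for sxyz, ext in self.WM[i][k - 1].items():
                    sw = ext[side]
                    txyz = (xyz[0] - sxyz[0], xyz[1] - sxyz[1], xyz[2] - sxyz[2])
                    tv = self._val(branch, txyz, side)
                    if tv is None or sw + tv != w:
                        continue
                    left = self._trace_WM(i, k - 1, sxyz, sw, side, two=False)
                    if left is None:
                        continue
                    right = self._trace_B(k, j, txyz, tv, side)
                    if right is not None:
                        return left + right
        return None

    def _trace_B(self, k, j, xyz, w, side):
        if xyz[2] < 1:
            return None
        inner = (xyz[0], xyz[1], xyz[2] - 1)
        ta = self.model.term(k, j)
        tv = self._val(self.V[k][j], inner, side)
        if tv is not None and tv + ta == w:
            return self._trace_V(k, j, inner, tv, side)
        return None


# ---------------------------------------------------------------------------
# Hull certification and assembly
# ---------------------------------------------------------------------------

def _certify_vertices(points: list) -> list:
    """Exact full-hull vertices of an integer point set (order preserved)."""
    pts = list(dict.fromkeys(points))
    if len(pts) <= 1:
        return pts
    # conservative pre-screen: drop points provably interior
    pruned = _prescreen(pts)
    out = []
    for p in pruned:
        others = [q for q in pruned if q != p]
        member, _ = hull_membership(others, p)
        if not member:
            out.append(p)
    return out


def _prescreen(pts: list) -> list:
    if len(pts) <= 24:
        return pts
    lo_p = _float_envelope_prunable(pts, +1)
    hi_p = _float_envelope_prunable(pts, -1)
    drop = lo_p & hi_p
    return [p for i, p in enumerate(pts) if i not in drop]


def _affine_dim(points: list) -> int:
    if len(points) <= 1:
        return 0
    base = points[0]
    rows = [[_F(p[k]) - _F(base[k]) for k in range(4)] for p in points[1:]]
    rank = 0
    ncols = 4
    col = 0
    r = 0
    while r < len(rows) and col < ncols:
        piv = next((i for i in range(r, len(rows)) if rows[i][col] != 0), None)
        if piv is None:
            col += 1
            continue
        rows[r], rows[piv] = rows[piv], rows[r]
        pv = rows[r][col]
        rows[r] = [v / pv for v in rows[r]]
        for i in range(len(rows)):
            if i != r and rows[i][col] != 0:
                f = rows[i][col]
                rows[i] = [a - f * b for a, b in zip(rows[i], rows[r])]
        rank += 1
        r += 1
        col += 1
    return rank


def build_polytope(seq: RnaSequence, tables: EnergyTables,
                   max_structures_per_vertex: int = 10,
                   length_limit: int = DEFAULT_LENGTH_LIMIT,
                   strategy: str = "auto") -> BranchingPolytope:
    """Exact branching polytope (full 4D hull vertices) of ``seq``.

    ``strategy``: 'enumeration' (exhaustive structures, short sequences),
    'dp' (polytope-valued dynamic program), or 'auto' (enumeration up to
    40 nt and a manageable structure count, DP otherwise).
    """
    if len(seq) > length_limit:
        raise StructureError(
            f"sequence {seq.id!r} has {len(seq)} nt > limit {length_limit}; "
            f"raise length_limit explicitly to proceed"
        )
    model = ScaledModel(seq, tables)
    if strategy == "auto":
        if len(seq) <= ENUMERATION_LENGTH_LIMIT and \
                count_structures(seq) <= ENUMERATION_COUNT_LIMIT:
            strategy = "enumeration"
        else:
            strategy = "dp"

    if strategy == "enumeration":
        table = _collect_enumeration(seq, model, max_structures_per_vertex)
        points = []
        for key, ext in table.items():
            points.append(key + (ext.wmin,))
            if ext.wmax != ext.wmin:
                points.append(key + (ext.wmax,))
        vertices = _certify_vertices(points)

        def realize(point):
            key, w = point[:3], point[3]
            ext = table[key]
            if w == ext.wmin:
                return ext.smin, ext.tmin
            return ext.smax, ext.tmax
    elif strategy == "dp":
        dp = _PolytopeDP(model)
        root = dp.W[model.n]
        points = []
        for key, (lo, hi) in root.items():
            points.append(key + (lo,))
            if hi != lo:
                points.append(key + (hi,))
        vertices = _certify_vertices(points)

        def realize(point):
            key, w = point[:3], point[3]
            lo, hi = root[key]
            for side in ((0,) if w == lo else ()) + ((1,) if w == hi else ()):
                got = dp.trace(key, w, side)
                if got is not None:
                    return [got], True  # single witness; not exhaustive
            raise RuntimeError(f"failed to trace structure for hull vertex {point}")
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    denom = model.denominator
    sigs = []
    structs = []
    truncated = []
    for point in sorted(vertices):
        sigs.append(BranchingSignature(point[0], point[1], point[2],
                                       _F(point[3], denom)))
        pair_lists, trunc = realize(point)
        structs.append([
            SecondaryStructure(length=model.n,
                               pairs=frozenset((i + 1, j + 1) for i, j in pl))
            for pl in pair_lists
        ])
        truncated.append(bool(trunc))
    dim = _affine_dim([v.point() for v in sigs])
    return BranchingPolytope(
        sequence=seq,
        vertices=sigs,
        vertex_structures=structs,
        vertex_truncated=truncated,
        dim=dim,
        lower_dimensional=dim < 4,
        is_lower_hull=False,
        strategy=strategy,
    )


def lower_hull(poly: BranchingPolytope) -> BranchingPolytope:
    """Vertices optimal for some (a, b, c) with the w-coefficient fixed at 1.

    A vertex survives exactly when it is a vertex of the lower convex hull
    in the w-direction; the result is a subset of the input vertices.
    """
    if poly.is_lower_hull:
        return poly
    points = poly.signature_points()
    keep = []
    for idx, p in enumerate(points):
        others = [q for q in points if q != p]
        if not others:
            keep.append(idx)
            continue
        member, _ = hull_membership(others, p, lower=True)
        if not member:
            keep.append(idx)
    sigs = [poly.vertices[i] for i in keep]
    dim = _affine_dim([v.point() for v in sigs])
    return BranchingPolytope(
        sequence=poly.sequence,
        vertices=sigs,
        vertex_structures=[poly.vertex_structures[i] for i in keep],
        vertex_truncated=[poly.vertex_truncated[i] for i in keep],
        dim=dim,
        lower_dimensional=dim < 4,
        is_lower_hull=True,
        strategy=poly.strategy,
    )


def facet_inequalities(poly: BranchingPolytope, guard: int = 40) -> list:
    """Facet inequalities theta . (x,y,z,w) <= delta of the vertex hull.

    Brute-force supporting-hyperplane enumeration over vertex 4-subsets;
    exact, intended for diagnostics on small polytopes (refuses more than
    ``guard`` vertices).  Returns [] for lower-dimensional polytopes.
    """
    points = poly.signature_points()
    if poly.lower_dimensional or len(points) < 5:
        return []
    if len(points) > guard:
        raise StructureError(
            f"facet enumeration refused for {len(points)} vertices > {guard}")
    facets = {}
    for quad in combinations(points, 4):
        base = quad[0]
        rows = [[_F(q[k]) - _F(base[k]) for k in range(4)] for q in quad[1:]]
        # normal: null vector of the 3x4 difference matrix
        normal = None
        for drop in range(4):
            cols = [k for k in range(4) if k != drop]
            mat = [[rows[r][k] for k in cols] for r in range(3)]
            rhs = [-rows[r][drop] for r in range(3)]
            sol = _solve_square(mat, rhs)
            if sol is not None:
                vec = [None] * 4
                vec[drop] = _F(1)
                for k, v in zip(cols, sol):
                    vec[k] = v
                normal = vec
                break
        if normal is None:
            continue
        delta = sum(n * _F(v) for n, v in zip(normal, base))
        side_hi = any(sum(n * _F(v) for n, v in zip(normal, p)) > delta for p in points)
        side_lo = any(sum(n * _F(v) for n, v in zip(normal, p)) < delta for p in points)
        if side_hi and side_lo:
            continue
        if side_hi:  # flip so the hull satisfies <=
            normal = [-n for n in normal]
            delta = -delta
        key = _canonical_facet(normal, delta)
        facets[key] = key
    return sorted(facets.values())


def _canonical_facet(normal, delta):
    denom = 1
    for v in list(normal) + [delta]:
        denom = denom * v.denominator // gcd(denom, v.denominator)
    ints = [int(v * denom) for v in normal] + [int(delta * denom)]
    g = 0
    for v in ints:
        g = gcd(g, abs(v))
    ints = [v // g for v in ints]
    return tuple(_F(v) for v in ints[:4]), _F(ints[4])


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_polytope(poly: BranchingPolytope, path) -> None:
    doc = {
        "format": "branchfold-polytope",
        "version": 1,
        "sequence": {"id": poly.sequence.id, "residues": poly.sequence.residues},
        "is_lower_hull": poly.is_lower_hull,
        "strategy": poly.strategy,
        "dim": poly.dim,
        "lower_dimensional": poly.lower_dimensional,
        "vertices": [
            {
                "x": v.x, "y": v.y, "z": v.z, "w": str(v.w),
                "structures": [s.to_dotbracket() for s in structs],
                "truncated": trunc,
            }
            for v, structs, trunc in zip(poly.vertices, poly.vertex_structures,
                                         poly.vertex_truncated)
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_polytope(path, tables: EnergyTables | None = None) -> BranchingPolytope:
    """Load a polytope; with ``tables`` given, every stored structure is
    re-checked to realize its vertex signature."""
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "branchfold-polytope" or doc.get("version") != 1:
        raise ValueError("not a branchfold polytope document")
    seq = RnaSequence(doc["sequence"]["id"], doc["sequence"]["residues"])
    from .structures import parse_structure
    from .energy import branching_signature

    vertices, structs, truncated = [], [], []
    for entry in doc["vertices"]:
        sig = BranchingSignature(entry["x"], entry["y"], entry["z"],
                                 Fraction(entry["w"]))
        slist = [parse_structure(db, "dotbracket") for db in entry["structures"]]
        if not slist:
            raise ValueError(f"vertex {sig} stores no realizing structure")
        if tables is not None:
            for s in slist:
                got = branching_signature(seq, s, tables)
                if got.point() != sig.point():
                    raise ValueError(
                        f"stored structure does not realize vertex {sig}: {got}")
        vertices.append(sig)
        structs.append(slist)
        truncated.append(bool(entry["truncated"]))
    dim = _affine_dim([v.point() for v in vertices])
    return BranchingPolytope(
        sequence=seq, vertices=vertices, vertex_structures=structs,
        vertex_truncated=truncated, dim=dim, lower_dimensional=dim < 4,
        is_lower_hull=bool(doc["is_lower_hull"]), strategy=doc["strategy"],
    )
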