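"""Branch-and-bound search for the branching parameters maximizing average
MFE prediction accuracy over a set of sequences.

Each sequence i contributes a list of parameter regions Reg(i, j), ordered
by decreasing prediction accuracy Acc_i(Reg(i, j)).  The optimal parameters
lie in some nonempty intersection of one region per sequence; the incumbent
lower bound L on the best average accuracy drives the pruning:

* region pre-filter:  sum_k Max_k(Reg(i,j)) >= N*L, where Max_k(Reg(i,j))
  is the best accuracy sequence k can attain inside Reg(i,j) (found by
  scanning k's regions in accuracy order for the first nonempty pairwise
  intersection), and the k = i term is Acc_i(Reg(i,j));
* merge-time test: a candidate combination over sequences I survives only if
  sum_{i in I} Acc_i(Reg(i,k_i)) + sum_{j not in I} min_{i in I}
  Max_j(Reg(i,k_i)) >= N*L (with U_j = Acc_j(Reg(j,1)) replacing the Max
  bounds when the table is disabled);
* merges proceed along a linear chain or a balanced binary tree; at the
  root every surviving nonempty combination updates L with its exact
  average accuracy;
* for wide merges a pairwise pre-filter discards combinations containing a
  provably empty pair of member regions before any full emptiness test.

All accuracies and bounds are exact rationals; emptiness of intersections
is decided exactly with full-dimensional-interior semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import prod
from typing import Sequence

from .energy import EnergyTables
from .polytope import BranchingPolytope, lower_hull
from .regions import (
    ParameterRegion,
    intersect,
    region_accuracy,
    subdivide,
)
from .structures import SecondaryStructure

__all__ = [
    "RankedRegion",
    "RegionList",
    "MaxBoundTable",
    "BnbState",
    "MergePlan",
    "order_regions",
    "compute_max_bounds",
    "preprocess_filter",
    "pruning_test",
    "merge",
    "pairwise_prefilter",
    "optimize",
    "exhaustive_search",
    "build_region_lists",
]

_F = Fraction

#: Combinations within this accuracy window below the final L are recorded
#: as near-optimal (best-effort: only combinations the search computed).
DEFAULT_NEAR_WINDOW = _F(1, 50)

#: Pairwise pre-filtering activates at merges spanning this many sequences.
DEFAULT_PREFILTER_THRESHOLD = 10

EXHAUSTIVE_GUARD = 10 ** 6


@dataclass(frozen=True)
class RankedRegion:
    """A region together with its accuracy and rank (position after sorting
    by decreasing accuracy; ranks are the j of Reg(i, j))."""

    rank: int
    accuracy: Fraction
    region: ParameterRegion


@dataclass
class RegionList:
    """All regions of one sequence, ordered by decreasing accuracy."""

    seq_index: int
    regions: list  # of RankedRegion
    sequence_id: str = ""

    @property
    def U(self) -> Fraction:
        return self.regions[0].accuracy

    def __len__(self) -> int:
        return len(self.regions)


def order_regions(regions: Sequence[ParameterRegion],
                  reference: SecondaryStructure) -> RegionList:
    """Sort regions by decreasing accuracy (ties by construction index)."""
    if not regions:
        raise ValueError("no regions to order")
    accs = []
    for r in regions:
        acc = r.accuracy if r.accuracy is not None else region_accuracy(r, reference)
        r.accuracy = acc
        accs.append((acc, r))
    accs.sort(key=lambda pair: (-pair[0], pair[1].region_index))
    seq_index = regions[0].seq_index
    return RegionList(
        seq_index=seq_index,
        regions=[RankedRegion(rank=pos, accuracy=a, region=r)
                 for pos, (a, r) in enumerate(accs)],
    )


# ---------------------------------------------------------------------------
# Pairwise emptiness cache and Max bounds
# ---------------------------------------------------------------------------

class PairCache:
    """Memoized exact pairwise intersections of base regions.

    Stores the intersection region itself (or None when empty) so that the
    Max-bound scans, the two-sequence merges and the pairwise pre-filter all
    share one LP per region pair.  ``peek`` answers from memory only.
    """

    _MISS = object()

    def __init__(self, lists: Sequence[RegionList]):
        self.lists = {rl.seq_index: rl for rl in lists}
        self._cache: dict = {}
        self.checks = 0

    @staticmethod
    def _key(i, ji, k, jk):
        return ((i, ji), (k, jk)) if (i, ji) <= (k, jk) else ((k, jk), (i, ji))

    def pair_region(self, i: int, ji: int, k: int, jk: int):
        key = self._key(i, ji, k, jk)
        got = self._cache.get(key, self._MISS)
        if got is self._MISS:
            self.checks += 1
            got = intersect([self.lists[i].regions[ji].region,
                             self.lists[k].regions[jk].region])
            self._cache[key] = got
        return got

    def nonempty(self, i: int, ji: int, k: int, jk: int) -> bool:
        return self.pair_region(i, ji, k, jk) is not None

    def peek(self, i: int, ji: int, k: int, jk: int):
        """True/False if this pair's emptiness is already known, else None."""
        got = self._cache.get(self._key(i, ji, k, jk), self._MISS)
        if got is self._MISS:
            return None
        return got is not None


@dataclass
class MaxBoundTable:
    """Max_k(Reg(i, j)): the best accuracy sequence k can attain for
    parameters restricted to Reg(i, j); None when no region of k meets
    Reg(i, j) at all (the pair is infeasible)."""

    entries: dict  # (i, rank_j, k) -> Fraction | None

    def get(self, i: int, rank_j: int, k: int):
        return self.entries[(i, rank_j, k)]


def compute_max_bounds(lists: Sequence[RegionList],
                       cache: PairCache | None = None) -> MaxBoundTable:
    """Scan each foreign list in accuracy order; the first nonempty pairwise
    intersection yields the (exact) maximum by the sortedness of the list."""
    if cache is None:
        cache = PairCache(lists)
    entries: dict = {}
    for li in lists:
        for rr in li.regions:
            for lk in lists:
                if lk.seq_index == li.seq_index:
                    continue
                best = None
                for other in lk.regions:
                    if cache.nonempty(li.seq_index, rr.rank,
                                      lk.seq_index, other.rank):
                        best = other.accuracy
                        break
                entries[(li.seq_index, rr.rank, lk.seq_index)] = best
    return MaxBoundTable(entries=entries)


def preprocess_filter(lists: Sequence[RegionList], table: MaxBoundTable | None,
                      L: Fraction, N: int, audit: list | None = None):
    """Keep Reg(i, j) iff Acc_i + sum_{k != i} Max_k(Reg(i, j)) >= N * L.

    Without a Max table the bound falls back to the U_k maxima.  Regions
    whose Max entry is infeasible for some k can never occur in a full
    nonempty combination and are always discarded.  Returns filtered lists;
    discards are appended to ``audit``.
    """
    L = _F(L)
    out = []
    for li in lists:
        kept = []
        for rr in li.regions:
            total = rr.accuracy
            feasible = True
            for lk in lists:
                if lk.seq_index == li.seq_index:
                    continue
                bound = (table.get(li.seq_index, rr.rank, lk.seq_index)
                         if table is not None else lk.U)
                if bound is None:
                    feasible = False
                    break
                total += bound
            if feasible and total >= N * L:
                kept.append(rr)
            elif audit is not None:
                audit.append({"event": "preprocess_discard",
                              "seq": li.seq_index, "rank": rr.rank,
                              "bound": total if feasible else None})
        out.append(RegionList(seq_index=li.seq_index, regions=kept,
                              sequence_id=li.sequence_id))
    return out


def pruning_test(accs_fixed: Sequence, bound_terms: Sequence,
                 L, N: int) -> bool:
    """sum(fixed accuracies) + sum(optimistic bounds) >= N * L.

    ``bound_terms`` containing None (an infeasible Max entry) always fails:
    such a combination cannot be completed.
    """
    if any(b is None for b in bound_terms):
        return False
    total = sum(accs_fixed, _F(0)) + sum(bound_terms, _F(0))
    return total >= N * _F(L)


# ---------------------------------------------------------------------------
# Combinations and merging
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Combination:
    """A choice of one region per sequence in ``members`` with a nonempty
    parameter intersection."""

    members: tuple          # sorted ((seq_index, rank), ...)
    acc_sum: Fraction
    region: ParameterRegion
    maxvec: dict            # outside seq_index -> Fraction | None (min over members)

    def bound(self, N: int):
        """Optimistic total accuracy over all N sequences; None if some
        outside sequence is infeasible for every member region."""
        total = self.acc_sum
        for v in self.maxvec.values():
            if v is None:
                return None
            total += v
        return total


@dataclass
class BnbState:
    N: int
    L: Fraction
    L0: Fraction
    incumbent_combination: dict | None = None
    incumbent_region: ParameterRegion | None = None
    improved: bool = False
    message: str = ""
    near_optimal: list = field(default_factory=list)
    counters: dict = field(default_factory=lambda: {
        "pruned_by_test": 0,
        "emptiness_checks": 0,
        "intersections_computed": 0,
        "prefilter_discards": 0,
        "candidates_considered": 0,
    })
    audit: list = field(default_factory=list)

    def _update(self, avg: Fraction, combo: "Combination") -> None:
        if avg > self.L:
            self.L = avg
            self.incumbent_combination = dict(combo.members)
            self.incumbent_region = combo.region
            self.improved = True
            self.audit.append({"event": "L", "value": avg,
                               "members": combo.members})


@dataclass(frozen=True)
class MergePlan:
    """Binary tree over sequence indices; leaves are sequence positions."""

    root: object  # int (leaf) or (left_subtree, right_subtree)

    @classmethod
    def linear(cls, n: int) -> "MergePlan":
        node: object = 0
        for i in range(1, n):
            node = (node, i)
        return cls(root=node)

    @classmethod
    def binary(cls, n: int) -> "MergePlan":
        def build(lo: int, hi: int):
            if hi - lo == 1:
                return lo
            mid = (lo + hi + 1) // 2
            return (build(lo, mid), build(mid, hi))
        return cls(root=build(0, n))

    def leaves(self, node=None) -> list:
        node = self.root if node is None else node
        if isinstance(node, int):
            return [node]
        return self.leaves(node[0]) + self.leaves(node[1])


def pairwise_prefilter(left: Combination, right: Combination,
                       cache: PairCache) -> bool:
    """True unless some cross pair of member regions is provably empty.

    An empty pairwise intersection implies the whole combination is empty;
    the converse does not hold, so surviving candidates still require the
    full emptiness test.
    """
    for i1, j1 in left.members:
        for i2, j2 in right.members:
            if not cache.nonempty(i1, j1, i2, j2):
                return False
    return True


def _leaf_combos(rlist: RegionList, lists, table, use_max_bounds) -> list:
    combos = []
    i = rlist.seq_index
    for rr in rlist.regions:
        maxvec = {}
        for lk in lists:
            k = lk.seq_index
            if k == i:
                continue
            maxvec[k] = (table.get(i, rr.rank, k) if use_max_bounds else lk.U)
        combos.append(Combination(
            members=((i, rr.rank),),
            acc_sum=rr.accuracy,
            region=rr.region,
            maxvec=maxvec,
        ))
    return combos


def merge(left: list, right: list, state: BnbState, cache: PairCache,
          is_root: bool,
          prefilter_threshold: int = DEFAULT_PREFILTER_THRESHOLD) -> list:
    """All surviving combinations of one candidate from each side.

    Candidates are processed in decreasing optimistic-bound order (ties
    broken lexicographically by member indices), so the first failed
    pruning test removes every remaining candidate; at the root each
    nonempty intersection updates the incumbent L immediately, sharpening
    the test for later candidates.
    """
    N = state.N
    span = (len(left[0].members) if left else 0) + \
           (len(right[0].members) if right else 0)
    candidates = []
    for cl in left:
        for cr in right:
            members = tuple(sorted(cl.members + cr.members))
            maxvec = {}
            feasible = True
            total = cl.acc_sum + cr.acc_sum
            for k in cl.maxvec:
                if k in dict(cr.members):
                    continue
                vl, vr = cl.maxvec[k], cr.maxvec.get(k)
                v = None if (vl is None or vr is None) else min(vl, vr)
                maxvec[k] = v
                if v is None:
                    feasible = False
                else:
                    total += v
            candidates.append((total if feasible else None, members, cl, cr, maxvec))
    # decreasing optimistic bound, then lexicographic member indices
    candidates.sort(key=lambda c: (c[0] is None, -(c[0] or 0), c[1]))
    out = []
    cut = False
    for bound, members, cl, cr, maxvec in candidates:
        state.counters["candidates_considered"] += 1
        if cut or bound is None or bound < N * state.L:
            state.counters["pruned_by_test"] += 1
            state.audit.append({"event": "prune", "bound": bound,
                                "members": members})
            if bound is not None and not cut:
                cut = True  # sorted: every later bound also fails
            continue
        if span >= prefilter_threshold and not pairwise_prefilter(cl, cr, cache):
            state.counters["prefilter_discards"] += 1
            state.audit.append({"event": "prefilter_empty", "members": members})
            continue
        # free pre-screen from already-memoized pairwise answers: a known
        # empty cross pair implies the whole candidate is empty
        known_empty = any(
            cache.peek(i1, j1, i2, j2) is False
            for i1, j1 in cl.members for i2, j2 in cr.members)
        if known_empty:
            state.counters["prefilter_discards"] += 1
            state.audit.append({"event": "prefilter_empty", "members": members})
            continue
        if len(members) == 2:
            (i1, j1), (i2, j2) = members
            state.counters["emptiness_checks"] += 1
            region = cache.pair_region(i1, j1, i2, j2)
            if region is not None:
                region = ParameterRegion(
                    seq_index=None, region_index=-1,
                    inequalities=region.inequalities, signature=None,
                    truncated=region.truncated, accuracy=region.accuracy,
                    members=dict(region.members))
        else:
            state.counters["emptiness_checks"] += 1
            region = intersect([cl.region, cr.region])
        if region is None:
            state.audit.append({"event": "empty", "members": members})
            continue
        state.counters["intersections_computed"] += 1
        region.members = dict(members)
        region.accuracy = (cl.acc_sum + cr.acc_sum) / len(members)
        if len(region.inequalities) > 40:
            from .geometry import reduce_inequalities
            region.inequalities = reduce_inequalities(region.inequalities)
        combo = Combination(members=members, acc_sum=cl.acc_sum + cr.acc_sum,
                            region=region, maxvec=maxvec)
        out.append(combo)
        if is_root:
            avg = combo.acc_sum / N
            state.audit.append({"event": "root_combination", "members": members,
                                "accuracy": avg})
            state.near_optimal.append((avg, dict(members)))
            state._update(avg, combo)
    out.sort(key=lambda c: (-c.acc_sum, c.members))
    return out


def build_region_lists(polytopes: Sequence[BranchingPolytope],
                       references: Sequence[SecondaryStructure],
                       tables: EnergyTables,
                       max_structures: int = 100) -> list:
    """Subdivide every polytope and order its regions by accuracy."""
    if len(polytopes) != len(references):
        raise ValueError("one reference structure per polytope is required")
    lists = []
    for i, (poly, ref) in enumerate(zip(polytopes, references)):
        if ref.length != len(poly.sequence):
            raise ValueError(
                f"reference length {ref.length} != sequence length "
                f"{len(poly.sequence)} for input {i}")
        regions = subdivide(lower_hull(poly), tables, seq_index=i,
                            max_structures=max_structures)
        rl = order_regions(regions, ref)
        rl.sequence_id = poly.sequence.id
        lists.append(rl)
    return lists


def optimize(polytopes: Sequence[BranchingPolytope],
             references: Sequence[SecondaryStructure],
             tables: EnergyTables,
             L0=0,
             plan: str | MergePlan = "binary",
             use_max_bounds: bool = True,
             prefilter_threshold: int = DEFAULT_PREFILTER_THRESHOLD,
             near_window: Fraction = DEFAULT_NEAR_WINDOW,
             max_structures: int = 100) -> BnbState:
    """Find the parameter region with the best average accuracy.

    Provided the true optimum is at least ``L0``, the returned state has
    state.L equal to the exact optimum with a nonempty witness region;
    otherwise the state reports no improvement over L0.
    """
    lists = build_region_lists(polytopes, references, tables,
                               max_structures=max_structures)
    return optimize_lists(lists, L0=L0, plan=plan, use_max_bounds=use_max_bounds,
                          prefilter_threshold=prefilter_threshold,
                          near_window=near_window)


def optimize_lists(lists: Sequence[RegionList], L0=0,
                   plan: str | MergePlan = "binary",
                   use_max_bounds: bool = True,
                   prefilter_threshold: int = DEFAULT_PREFILTER_THRESHOLD,
                   near_window: Fraction = DEFAULT_NEAR_WINDOW,
                   cache: PairCache | None = None) -> BnbState:
    """Branch-and-bound over precomputed, accuracy-ordered region lists.

    ``cache`` may carry memoized pairwise emptiness answers between runs
    over subsets of one region-list pool (pure memoization; results do not
    change).
    """
    N = len(lists)
    if N == 0:
        raise ValueError("no sequences")
    L0 = _F(L0)
    if not (0 <= L0 <= 1):
        raise ValueError("L0 must lie in [0, 1]")
    state = BnbState(N=N, L=L0, L0=L0)
    if cache is None:
        cache = PairCache(lists)
    table = compute_max_bounds(lists, cache) if (use_max_bounds and N > 1) else None
    lists = preprocess_filter(lists, table, L0, N, audit=state.audit)
    if any(len(rl) == 0 for rl in lists):
        state.message = f"no improvement over L0={L0}"
        return state
    if isinstance(plan, str):
        plan = MergePlan.binary(N) if plan == "binary" else MergePlan.linear(N)
    index_of = {pos: rl for pos, rl in enumerate(lists)}

    def run(node, is_root: bool) -> list:
        if isinstance(node, int):
            combos = _leaf_combos(index_of[node], lists, table, use_max_bounds)
            if is_root:  # N == 1
                for combo in combos:
                    avg = combo.acc_sum
                    state.near_optimal.append((avg, dict(combo.members)))
                    state._update(avg, combo)
            return combos
        left = run(node[0], False)
        right = run(node[1], False)
        return merge(left, right, state, cache, is_root,
                     prefilter_threshold=prefilter_threshold)

    run(plan.root, True)
    state.counters["pairwise_cache_checks"] = cache.checks
    state.near_optimal = sorted(
        [(a, m) for a, m in state.near_optimal if a >= state.L - near_window],
        key=lambda t: (-t[0], sorted(t[1].items())))
    if not state.improved:
        state.message = f"no improvement over L0={L0}"
    return state


def exhaustive_search(polytopes: Sequence[BranchingPolytope],
                      references: Sequence[SecondaryStructure],
                      tables: EnergyTables,
                      guard: int = EXHAUSTIVE_GUARD,
                      max_structures: int = 100) -> BnbState:
    """Exact optimum by depth-first enumeration of all region combinations.

    The small-instance oracle for :func:`optimize`.  Refuses instances
    whose product of region counts exceeds ``guard``.  Branches whose
    partial intersection is already empty are skipped (their extensions are
    all empty), which does not affect exactness.
    """
    lists = build_region_lists(polytopes, references, tables,
                               max_structures=max_structures)
    return exhaustive_lists(lists, guard=guard)


def exhaustive_lists(lists: Sequence[RegionList],
                     guard: int = EXHAUSTIVE_GUARD,
                     cache: PairCache | None = None) -> BnbState:
    N = len(lists)
    total = prod(len(rl) for rl in lists)
    if total > guard:
        raise ValueError(
            f"exhaustive search refused: {total} combinations exceed the "
            f"guard of {guard}")
    state = BnbState(N=N, L=_F(0), L0=_F(0))
    order = sorted(lists, key=len)
    if cache is None:
        cache = PairCache(lists)

    def dfs(depth: int, chosen: list, acc: Fraction) -> None:
        if depth == N:
            members = dict(sorted(m for m, _ in chosen))
            avg = acc / N
            state.audit.append({"event": "root_combination",
                                "members": tuple(members.items()),
                                "accuracy": avg})
            if avg > state.L or state.incumbent_region is None:
                state.improved = state.improved or avg > state.L
                state.L = max(state.L, avg)
                state.incumbent_combination = members
                state.incumbent_region = chosen[-1][1]
            return
        rl = order[depth]
        prev_region = chosen[-1][1] if chosen else None
        for rr in rl.regions:
            # cheap memoized pairwise screen: an empty pair with any chosen
            # region already empties the whole extension
            if any(not cache.nonempty(rl.seq_index, rr.rank, i, j)
                   for (i, j), _ in chosen):
                continue
            parts = ([prev_region] if prev_region is not None else []) + [rr.region]
            state.counters["emptiness_checks"] += 1
            inter = intersect(parts)
            if inter is None:
                continue
            state.counters["intersections_computed"] += 1
            if len(inter.inequalities) > 40:
                from .geometry import reduce_inequalities
                inter.inequalities = reduce_inequalities(inter.inequalities)
            chosen.append(((rl.seq_index, rr.rank), inter))
            dfs(depth + 1, chosen, acc + rr.accuracy)
            chosen.pop()

    dfs(0, [], _F(0))
    state.counters["pairwise_cache_checks"] = cache.checks
    return state
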