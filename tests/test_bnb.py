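"""Branch-and-bound components: ordering, Max bounds, pruning tests, merge
plans, the pairwise pre-filter, and optimizer soundness on small instances."""

import random
from fractions import Fraction as F

import pytest

from branchfold.bnb import (
    BnbState,
    MergePlan,
    PairCache,
    RankedRegion,
    RegionList,
    compute_max_bounds,
    exhaustive_lists,
    merge,
    optimize_lists,
    order_regions,
    pairwise_prefilter,
    preprocess_filter,
    pruning_test,
)
from branchfold.regions import ParameterRegion


def _region(rows, accuracy, seq_index=0, index=0):
    return ParameterRegion(
        seq_index=seq_index, region_index=index,
        inequalities=[(tuple(F(c) for c in co), F(r)) for co, r in rows],
        signature=None, structures=[], accuracy=F(accuracy),
        members={seq_index: index})


def _rlist(seq_index, rows_accs):
    regions = [_region(rows, acc, seq_index, i)
               for i, (rows, acc) in enumerate(rows_accs)]
    rl = order_regions(regions, reference=None)
    return rl


WHOLE = []  # no inequalities: all of parameter space
LEFT = [((1, 0, 0), 0)]          # a <= 0
RIGHT = [((-1, 0, 0), 0)]        # a >= 0
FAR_RIGHT = [((-1, 0, 0), -5)]   # a >= 5


# -- ordering ----------------------------------------------------------------

def test_order_regions_sorts_by_accuracy():
    rl = _rlist(0, [(WHOLE, "0.2"), (LEFT, "0.9"), (RIGHT, "0.5")])
    assert [float(r.accuracy) for r in rl.regions] == [0.9, 0.5, 0.2]
    assert rl.U == F("0.9")
    assert [r.rank for r in rl.regions] == [0, 1, 2]


def test_order_regions_tie_break_is_stable():
    rl = _rlist(0, [(LEFT, "0.5"), (RIGHT, "0.5")])
    assert [r.region.region_index for r in rl.regions] == [0, 1]
    with pytest.raises(ValueError, match="no regions"):
        order_regions([], None)


# -- max bounds --------------------------------------------------------------

def test_max_bounds_whole_space_region_gets_U():
    l0 = _rlist(0, [(WHOLE, "0.6")])
    l1 = _rlist(1, [(LEFT, "0.9"), (RIGHT, "0.4")])
    table = compute_max_bounds([l0, l1])
    assert table.get(0, 0, 1) == F("0.9")  # whole space meets the best region


def test_max_bounds_scan_skips_empty_first_region():
    l0 = _rlist(0, [(FAR_RIGHT, "0.6")])       # a >= 5
    l1 = _rlist(1, [(LEFT, "0.9"), (RIGHT, "0.4")])  # best is a <= 0: disjoint
    table = compute_max_bounds([l0, l1])
    assert table.get(0, 0, 1) == F("0.4")


def test_max_bounds_infeasible_pair_marked():
    l0 = _rlist(0, [(FAR_RIGHT, "0.6")])
    l1 = _rlist(1, [(LEFT, "0.9")])
    table = compute_max_bounds([l0, l1])
    assert table.get(0, 0, 1) is None


def test_max_bounds_match_exhaustive_on_pool(bnb_pool):
    """Every table entry equals the exhaustive maximum accuracy over
    nonempty joint regions (the validity invariant, with equality)."""
    lists = bnb_pool["lists"][:3]
    cache = bnb_pool["cache"]
    table = compute_max_bounds(lists, cache)
    for li in lists:
        for rr in li.regions:
            for lk in lists:
                if lk.seq_index == li.seq_index:
                    continue
                feasible = [other.accuracy for other in lk.regions
                            if cache.nonempty(li.seq_index, rr.rank,
                                              lk.seq_index, other.rank)]
                expected = max(feasible) if feasible else None
                assert table.get(li.seq_index, rr.rank, lk.seq_index) == expected


# -- preprocessing and pruning -----------------------------------------------

def test_preprocess_filter_inequality_cases():
    # N=2: keep iff Acc_i + Max_k >= 2L
    l0 = _rlist(0, [(WHOLE, "0.8"), (WHOLE, "0.5")])
    l1 = _rlist(1, [(WHOLE, "0.9"), (WHOLE, "0.8")])
    table = compute_max_bounds([l0, l1])
    kept = preprocess_filter([l0, l1], table, F("0.74"), 2)
    # 0.8 + 0.9 = 1.7 >= 1.48 keep; 0.5 + 0.9 = 1.4 < 1.48 discard
    assert [r.accuracy for r in kept[0].regions] == [F("0.8")]
    # L = 0 discards nothing
    kept0 = preprocess_filter([l0, l1], table, 0, 2)
    assert [len(rl) for rl in kept0] == [2, 2]


def test_pruning_test_cases():
    assert pruning_test([F("0.6")], [F("0.9")], F("0.74"), 2)       # 1.5 >= 1.48
    assert not pruning_test([F("0.6")], [F("0.9")], F("0.76"), 2)   # 1.5 < 1.52
    assert pruning_test([F(1), F(1)], [F(1)], F(1), 3)
    assert not pruning_test([F(1), F("0.9")], [F(1)], F(1), 3)
    assert not pruning_test([F(1)], [None], F(0), 2)  # infeasible bound term


# -- merge -------------------------------------------------------------------

def _two_list_setup(rows0, rows1, acc0="0.8", acc1="0.6"):
    l0 = _rlist(0, [(rows0, acc0)])
    l1 = _rlist(1, [(rows1, acc1)])
    lists = [l0, l1]
    cache = PairCache(lists)
    table = compute_max_bounds(lists, cache)
    from branchfold.bnb import _leaf_combos
    left = _leaf_combos(l0, lists, table, True)
    right = _leaf_combos(l1, lists, table, True)
    state = BnbState(N=2, L=F(0), L0=F(0))
    return left, right, state, cache


def test_merge_single_regions_nonempty_updates_L():
    left, right, state, cache = _two_list_setup(LEFT, WHOLE)
    out = merge(left, right, state, cache, is_root=True)
    assert len(out) == 1
    assert state.L == F("0.7")  # mean of 0.8 and 0.6
    assert state.incumbent_combination == {0: 0, 1: 0}


def test_merge_single_regions_empty_leaves_L():
    left, right, state, cache = _two_list_setup(LEFT, FAR_RIGHT)
    out = merge(left, right, state, cache, is_root=True)
    assert out == []
    assert state.L == 0 and state.incumbent_combination is None


def test_pairwise_prefilter_implication():
    """A known-empty pair kills a combination outright; all-nonempty pairs
    do not certify the full intersection (three half-planes can overlap
    pairwise with empty common interior)."""
    # b = 0 plane sections: three half-plane-like regions in (a, c)
    r0 = _region([((0, 0, 1), 0)], "1", 0, 0)                 # c <= 0
    r1 = _region([((1, 0, -1), -1)], "1", 1, 0)               # a - c <= -1 -> a <= c - 1
    r2 = _region([((-1, 0, -1), -1)], "1", 2, 0)              # -a - c <= -1 -> a >= 1 - c
    lists = [RegionList(seq_index=i, regions=[
        RankedRegion(rank=0, accuracy=F(1), region=r)])
        for i, r in enumerate([r0, r1, r2])]
    cache = PairCache(lists)
    # all pairwise intersections are nonempty ...
    assert cache.nonempty(0, 0, 1, 0)
    assert cache.nonempty(0, 0, 2, 0)
    assert cache.nonempty(1, 0, 2, 0)
    # ... so the prefilter keeps the combination ...
    from branchfold.bnb import _leaf_combos
    table = compute_max_bounds(lists, cache)
    c0 = _leaf_combos(lists[0], lists, table, True)[0]
    c12_state = BnbState(N=3, L=F(0), L0=F(0))
    c12 = merge(_leaf_combos(lists[1], lists, table, True),
                _leaf_combos(lists[2], lists, table, True),
                c12_state, cache, is_root=False)[0]
    assert pairwise_prefilter(c0, c12, cache)
    # ... but the full emptiness test rejects it: c<=0, a<=c-1, a>=1-c
    # forces 1 - c <= a <= c - 1, i.e. c >= 1, contradicting c <= 0
    state = BnbState(N=3, L=F(0), L0=F(0))
    out = merge([c0], [c12], state, cache, is_root=True,
                prefilter_threshold=2)
    assert out == []


# -- plans -------------------------------------------------------------------

def test_merge_plans_cover_all_leaves():
    for n in range(1, 9):
        assert sorted(MergePlan.binary(n).leaves()) == list(range(n))
        assert sorted(MergePlan.linear(n).leaves()) == list(range(n))

    def depth(node):
        if isinstance(node, int):
            return 0
        return 1 + max(depth(node[0]), depth(node[1]))
    assert depth(MergePlan.binary(8).root) == 3   # balanced
    assert depth(MergePlan.linear(8).root) == 7   # chain


# -- optimizer ---------------------------------------------------------------

def test_optimize_single_sequence(bnb_pool):
    lists = [bnb_pool["lists"][0]]
    st = optimize_lists(lists, cache=bnb_pool["cache"])
    assert st.L == lists[0].U
    assert st.incumbent_combination == {0: 0}


def test_optimize_identical_sequences(bnb_pool, tables):
    """Copies of one sequence share their subdivision, so the best region
    combination is the diagonal with L = U."""
    from branchfold.bnb import build_region_lists
    poly = bnb_pool["polytopes"][0]
    ref = bnb_pool["references"][0]
    lists = build_region_lists([poly, poly, poly], [ref, ref, ref], tables)
    st = optimize_lists(lists)
    assert st.L == lists[0].U
    assert len(set(st.incumbent_combination.values())) == 1


def test_optimize_matches_exhaustive_small(bnb_pool):
    lists = bnb_pool["lists"][2:5]
    cache = bnb_pool["cache"]
    ex = exhaustive_lists(lists, guard=10 ** 9, cache=cache)
    st = optimize_lists(lists, cache=cache)
    assert st.L == ex.L
    assert st.incumbent_region is not None


def test_L0_safety_and_no_improvement_report(bnb_pool):
    lists = bnb_pool["lists"][2:5]
    cache = bnb_pool["cache"]
    base = optimize_lists(lists, cache=cache)
    eps = F(1, 1000)
    near = optimize_lists(lists, L0=base.L - eps, cache=cache)
    assert near.L == base.L
    # L0 above the optimum: explicit no-improvement report
    beyond = optimize_lists(lists, L0=min(F(1), base.L + eps), cache=cache)
    if base.L < 1:
        assert not beyond.improved
        assert "no improvement" in beyond.message


def test_incumbent_trace_is_nondecreasing(bnb_pool):
    lists = bnb_pool["lists"][4:8]
    st = optimize_lists(lists, cache=bnb_pool["cache"])
    trace = [e["value"] for e in st.audit if e["event"] == "L"]
    assert trace == sorted(trace)
    assert st.incumbent_region is not None


def test_exhaustive_guard_refuses():
    rl = _rlist(0, [(WHOLE, "0.5"), (LEFT, "0.4")])
    with pytest.raises(ValueError, match="guard"):
        exhaustive_lists([rl, rl, rl], guard=2)
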