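"""Parameter-space subdivision, emptiness queries, intersections,
representative points and rounding."""

import random
from fractions import Fraction as F

import pytest

from branchfold.energy import BranchingParameters, branching_signature, mfe_fold
from branchfold.fixtures import FixtureSpec, generate
from branchfold.polytope import build_polytope, lower_hull
from branchfold.regions import (
    ParameterRegion,
    intersect,
    is_empty,
    load_regions,
    region_accuracy,
    representative_point,
    round_parameters,
    sample_interior_points,
    save_regions,
    slice_polygon,
    subdivide,
)
from branchfold.structures import RnaSequence, SecondaryStructure


def _region(rows, accuracy=None, structures=(), index=0):
    return ParameterRegion(seq_index=0, region_index=index,
                           inequalities=[(tuple(F(c) for c in co), F(r))
                                         for co, r in rows],
                           signature=None, structures=list(structures),
                           accuracy=accuracy)


@pytest.fixture(scope="module")
def y3_subdivision(tables, oracle_fixtures):
    seq, ref = oracle_fixtures[2]
    poly = lower_hull(build_polytope(seq, tables))
    return seq, subdivide(poly, tables)


def test_point_polytope_gives_whole_space_region(tables):
    poly = build_polytope(RnaSequence("a", "A" * 10), tables)
    regions = subdivide(poly, tables)
    assert len(regions) == 1
    assert regions[0].inequalities == []
    assert regions[0].contains((100, -37, F(1, 3)))
    assert regions[0].structures[0].pairs == frozenset()


def test_two_vertex_lower_hull_gives_two_halfspaces(tables):
    # a pure hairpin: fold or stay open; regions split along one plane
    seq = RnaSequence("h", "GGGGAAAACCCC")
    poly = lower_hull(build_polytope(seq, tables))
    regions = subdivide(poly, tables)
    if len(regions) == 2:
        assert all(len(r.inequalities) == 1 for r in regions)
        (c1, d1), (c2, d2) = regions[0].inequalities[0], regions[1].inequalities[0]
        assert all(a == -b for a, b in zip(c1, c2)) and d1 == -d2


def test_fold_at_point_oracle(tables, y3_subdivision):
    """The region containing a random parameter point predicts exactly the
    signature that direct folding at that point yields."""
    seq, regions = y3_subdivision
    rng = random.Random(5)
    for _ in range(50):
        pt = tuple(F(rng.randint(-200, 200), 10) for _ in range(3))
        inside = [r for r in regions if r.contains(pt)]
        strict = [r for r in regions if r.contains(pt, strict=True)]
        assert len(inside) >= 1          # regions cover parameter space
        assert len(strict) <= 1          # interiors are pairwise disjoint
        fold = mfe_fold(seq, tables, BranchingParameters(*pt), max_structures=4)
        sig = branching_signature(seq, fold.structures[0], tables)
        assert any(r.signature.point() == sig.point() for r in inside)
        if strict:
            assert strict[0].signature.point() == sig.point()


def test_interior_samples_reproduce_signature(tables, y3_subdivision):
    seq, regions = y3_subdivision
    rng = random.Random(9)
    for region in regions[:3]:
        for p in sample_interior_points(region, 5, rng):
            fold = mfe_fold(seq, tables, p, max_structures=4)
            got = branching_signature(seq, fold.structures[0], tables)
            assert got.point() == region.signature.point()


def test_region_accuracy_is_mean_over_structures(tables, y3_subdivision):
    seq, regions = y3_subdivision
    ref = regions[0].structures[0]
    # single stored structure equal to the reference scores 1
    assert region_accuracy(regions[0], ref) == 1
    from branchfold.structures import f1_accuracy
    for region in regions[:4]:
        expected = sum(f1_accuracy(ref, s) for s in region.structures)
        assert region_accuracy(region, ref) == F(expected, len(region.structures))
    with pytest.raises(ValueError, match="no structures"):
        region_accuracy(_region([]), ref)


def test_accuracy_mean_of_two():
    r = _region([], structures=[])
    a = SecondaryStructure(length=12, pairs=frozenset({(1, 12), (2, 11)}))
    b = SecondaryStructure(length=12, pairs=frozenset())
    r.structures = [a, b]
    assert region_accuracy(r, a) == F(1, 2)  # F1 values 1 and 0


def test_is_empty_semantics():
    assert is_empty([((1, 0, 0), 0), ((-1, 0, 0), -1)])
    face = [((1, 0, 0), 0), ((-1, 0, 0), 0)]
    assert is_empty(face, interior=True)
    assert not is_empty(face, interior=False)


def test_is_empty_against_grid_witness():
    import itertools
    rng = random.Random(2)
    for _ in range(40):
        rows = [(tuple(F(rng.randint(-3, 3)) for _ in range(3)),
                 F(rng.randint(-5, 5))) for _ in range(6)]
        found = any(
            all(sum(c * x for c, x in zip(co, p)) < r or all(v == 0 for v in co)
                for co, r in rows)
            for p in itertools.product((-25, -10, 0, 10, 25), repeat=3))
        if found and not any(all(v == 0 for v in co) and r < 0 for co, r in rows):
            assert not is_empty(rows)


def test_intersect_properties():
    slab1 = _region([((1, 0, 0), 1), ((-1, 0, 0), 0)], accuracy=F(1, 2))
    with_self = intersect([slab1, slab1])
    assert with_self is not None and with_self.accuracy == F(1, 2)
    slab2 = _region([((1, 0, 0), 5), ((-1, 0, 0), -3)], accuracy=F(1))
    assert intersect([slab1, slab2]) is None  # parallel disjoint slabs
    half = _region([((0, 1, 0), 0)], accuracy=F(1))
    both = intersect([slab1, half])
    assert both.accuracy == F(3, 4)  # mean of member accuracies


def test_intersect_commutative_associative():
    a = _region([((1, 0, 0), 2)], accuracy=F(1))
    b = _region([((0, 1, 0), 2)], accuracy=F(1, 2))
    c = _region([((0, 0, 1), 2)], accuracy=F(0))
    ab_c = intersect([intersect([a, b]), c])
    a_bc = intersect([a, intersect([b, c])])
    assert sorted(ab_c.inequalities) == sorted(a_bc.inequalities)
    assert sorted(intersect([a, b]).inequalities) == \
        sorted(intersect([b, a]).inequalities)


def test_representative_point_cube_centroid():
    cube = _region([((1, 0, 0), 1), ((-1, 0, 0), 0), ((0, 1, 0), 1),
                    ((0, -1, 0), 0), ((0, 0, 1), 1), ((0, 0, -1), 0)])
    assert tuple(representative_point(cube)) == (F(1, 2), F(1, 2), F(1, 2))


def test_representative_point_unbounded_and_empty():
    half = _region([((-1, 0, 0), 0)])  # a >= 0
    p = representative_point(half)
    assert p.a > 0
    empty = _region([((1, 0, 0), 0), ((-1, 0, 0), -1)])
    with pytest.raises(ValueError, match="empty"):
        representative_point(empty)


def test_stepping_matches_reported_interior_point_construction():
    bbs = BranchingParameters(F("-5.7"), F("0.2"), F("3.5"))
    assert tuple(bbs.step((-3, 0, 1))) == (F("-8.7"), F("0.2"), F("4.5"))


def test_round_parameters():
    r, flag = round_parameters(BranchingParameters(F("3.44"), F("0.05"), F("0.351")))
    assert tuple(r) == (F("3.4"), F("0.1"), F("0.4"))
    assert flag is None
    t99 = BranchingParameters(F("3.4"), 0, F("0.4"))
    assert tuple(round_parameters(t99)[0]) == tuple(t99)
    # ties away from zero on the negative side
    assert tuple(round_parameters(BranchingParameters(F("-0.25"), 0, 0))[0])[0] \
        == F("-0.3")
    # membership flag against a region
    box = _region([((1, 0, 0), 1), ((-1, 0, 0), 0)])
    inside = round_parameters(BranchingParameters(F("0.52"), 0, 0), box)
    assert inside[1] is True
    outside = round_parameters(BranchingParameters(F("1.16"), 0, 0), box)
    assert outside[1] is False


def test_region_serialization_roundtrip(tmp_path, y3_subdivision):
    seq, regions = y3_subdivision
    path = tmp_path / "regions.json"
    save_regions(regions, path)
    back = load_regions(path)
    assert len(back) == len(regions)
    for r1, r2 in zip(regions, back):
        assert r1.inequalities == r2.inequalities
        assert r1.signature.point() == r2.signature.point()
        assert [s.pairs for s in r1.structures] == [s.pairs for s in r2.structures]


def test_slice_polygon_clips_to_box():
    half = _region([((-1, 0, 0), 0)])  # a >= 0
    poly = slice_polygon(half, b_value=0, box=5)
    assert len(poly) == 4
    assert all(0 <= v[0] <= 5 and -5 <= v[1] <= 5 for v in poly)
    empty = _region([((1, 0, 0), 0), ((-1, 0, 0), -1)])
    assert slice_polygon(empty, b_value=0) == []
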