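"""Subdivision of (a, b, c)-parameter space into regions of constant MFE
prediction, and exact polyhedral queries on those regions.

Each vertex v of the lower branching hull owns the region

    { (a,b,c) :  a(x_v - x_u) + b(y_v - y_u) + c(z_v - z_u) <= w_u - w_v
                 for every other lower-hull vertex u },

the set of parameters for which v is the energy-minimizing signature.  The
regions cover parameter space and have pairwise disjoint interiors.
Emptiness of region intersections is decided exactly; by default "nonempty"
means full-dimensional interior, because parameter ties on shared faces are
not robust to the one-decimal rounding convention of thermodynamic
parameter files (closed semantics are available via a flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

from . import geometry
from .energy import (
    BranchingParameters,
    BranchingSignature,
    EnergyTables,
    branching_signature,
    mfe_fold,
)
from .polytope import BranchingPolytope, lower_hull
from .structures import SecondaryStructure, f1_accuracy

__all__ = [
    "ParameterRegion",
    "subdivide",
    "region_accuracy",
    "is_empty",
    "intersect",
    "representative_point",
    "round_parameters",
    "sample_interior_points",
    "save_regions",
    "load_regions",
    "slice_polygon",
]

_F = Fraction


@dataclass
class ParameterRegion:
    """A convex polyhedron in (a, b, c)-space with one optimal signature.

    ``inequalities`` is a list of ((alpha, beta, gamma), delta) rows meaning
    alpha*a + beta*b + gamma*c <= delta, all rational.  For intersections of
    regions from several sequences, ``members`` maps sequence index to the
    region index used, ``signature`` is None and ``accuracy`` is the mean of
    the member accuracies.
    """

    seq_index: int | None
    region_index: int
    inequalities: list
    signature: BranchingSignature | None
    structures: list = field(default_factory=list)
    truncated: bool = False
    accuracy: Fraction | None = None
    members: dict = field(default_factory=dict)

    def contains(self, point, strict: bool = False) -> bool:
        pt = [_F(str(v)) if isinstance(v, float) else _F(v) for v in point]
        for coeffs, rhs in self.inequalities:
            val = sum(c * x for c, x in zip(coeffs, pt))
            if val > rhs or (strict and val == rhs):
                return False
        return True


def _region_rows(points: list, idx: int) -> list:
    xv, yv, zv, wv = points[idx]
    rows = []
    for j, (xu, yu, zu, wu) in enumerate(points):
        if j == idx:
            continue
        rows.append(((_F(xv) - xu, _F(yv) - yu, _F(zv) - zu), _F(wu) - wv))
    return rows


def subdivide(poly: BranchingPolytope, tables: EnergyTables,
              seq_index: int = 0, max_structures: int = 100,
              reference: SecondaryStructure | None = None) -> list:
    """One ParameterRegion per lower-hull vertex, redundancy-reduced.

    Region structures are all structures attaining the vertex signature
    (capped at ``max_structures``): taken from the polytope when it was
    built exhaustively, otherwise recovered by co-optimal folding at an
    interior point of the region.  With ``reference`` given, accuracies are
    filled in immediately.
    """
    if not poly.is_lower_hull:
        poly = lower_hull(poly)
    points = [v.point() for v in poly.vertices]
    seq = poly.sequence
    regions = []
    for idx, sig in enumerate(poly.vertices):
        rows = _region_rows(points, idx)
        if rows:
            witness = geometry.interior_point(rows)
            if witness is None:
                raise RuntimeError(
                    f"lower-hull vertex {sig} has an empty parameter region")
            rows = geometry.reduce_inequalities(rows)
        else:
            witness = (_F(0), _F(0), _F(0))
        if poly.strategy == "enumeration":
            structures = list(poly.vertex_structures[idx])[:max_structures]
            truncated = poly.vertex_truncated[idx] or \
                len(poly.vertex_structures[idx]) > max_structures
        else:
            fold = mfe_fold(seq, tables, BranchingParameters(*witness),
                            max_structures=max_structures)
            structures = fold.structures
            truncated = fold.truncated
            for s in structures:
                got = branching_signature(seq, s, tables)
                if got.point() != sig.point():
                    raise RuntimeError(
                        f"co-optimal structure at region witness has signature "
                        f"{got}, expected {sig}")
        region = ParameterRegion(
            seq_index=seq_index,
            region_index=idx,
            inequalities=rows,
            signature=sig,
            structures=structures,
            truncated=truncated,
            members={seq_index: idx},
        )
        if reference is not None:
            region.accuracy = region_accuracy(region, reference)
        regions.append(region)
    return regions


def region_accuracy(region: ParameterRegion,
                    reference: SecondaryStructure) -> Fraction:
    """Mean F1 of the reference against the region's stored MFE structures.

    This is the prediction accuracy of any parameter choice inside the
    region: the average over all (stored) co-optimal MFE structures.  The
    region's ``truncated`` flag says whether the structure list was capped.
    """
    if not region.structures:
        raise ValueError("region carries no structures")
    total = sum(f1_accuracy(reference, s) for s in region.structures)
    return _F(total, len(region.structures))


def is_empty(inequalities, interior: bool = True) -> bool:
    """Exact emptiness of {alpha a + beta b + gamma c <= delta}.

    ``interior=True`` (default): empty means no full-dimensional interior.
    ``interior=False``: empty means no point at all (closed semantics).
    """
    if interior:
        return geometry.interior_point(inequalities, dim=3) is None
    return geometry.is_empty_closed(inequalities)


def intersect(regions: Sequence[ParameterRegion], interior: bool = True,
              reduce: bool = False) -> ParameterRegion | None:
    """Intersection of regions from distinct sequences; None when empty.

    The result's accuracy is the mean of the member accuracies (the
    average-of-accuracies contract used by the optimizer); its ``members``
    map records one region index per sequence.
    """
    rows = [row for r in regions for row in r.inequalities]
    if is_empty(rows, interior=interior):
        return None
    if reduce:
        rows = geometry.reduce_inequalities(rows)
    members: dict = {}
    for r in regions:
        members.update(r.members)
    accs = [r.accuracy for r in regions]
    accuracy = None
    if all(a is not None for a in accs):
        accuracy = sum(accs, _F(0)) / len(accs)
    return ParameterRegion(
        seq_index=None,
        region_index=-1,
        inequalities=rows,
        signature=None,
        structures=[],
        truncated=any(r.truncated for r in regions),
        accuracy=accuracy,
        members=members,
    )


def representative_point(region: ParameterRegion) -> BranchingParameters:
    """An exact rational point in the region's interior.

    Bounded regions: the centroid of their vertices.  Unbounded regions:
    the centroid of the bounded vertices stepped one unit along the (summed
    primitive) recession direction, mirroring the convention of reporting a
    strictly interior point of an unbounded optimal region.  Falls back to
    an LP interior point whenever the constructed point is not strictly
    interior (e.g. regions with no vertices).
    """
    rows = region.inequalities
    ip = geometry.interior_point(rows, dim=3)
    if ip is None:
        raise ValueError("empty region has no representative point")
    verts = geometry.polyhedron_vertices(rows) if rows else []
    rays = geometry.recession_rays(rows) if rows else [(1, 0, 0)]
    candidate = None
    if verts:
        n = len(verts)
        centroid = tuple(sum(v[k] for v in verts) / n for k in range(3))
        if not rays:
            candidate = centroid
        else:
            direction = [sum(r[k] for r in rays) for k in range(3)]
            if all(v == 0 for v in direction):
                direction = list(rays[0])
            candidate = tuple(c + d for c, d in zip(centroid, direction))
    if candidate is not None and region.contains(candidate, strict=True):
        return BranchingParameters(*candidate)
    return BranchingParameters(*ip)


def _round_half_away(x: Fraction) -> Fraction:
    q = x * 10
    import math
    r = math.floor(q)
    frac = q - r
    if frac > _F(1, 2) or (frac == _F(1, 2) and q >= 0):
        r += 1
    return _F(r, 10)


def round_parameters(params: BranchingParameters,
                     region: ParameterRegion | None = None):
    """Round (a, b, c) to one decimal, ties away from zero.

    Returns (rounded, in_region) where ``in_region`` reports closed
    membership of the rounded point in ``region`` (None when no region is
    given).
    """
    rounded = BranchingParameters(*(_round_half_away(v) for v in params))
    in_region = None
    if region is not None:
        in_region = region.contains(tuple(rounded))
    return rounded, in_region


def save_regions(regions: Sequence[ParameterRegion], path) -> None:
    """Write a subdivision to JSON (rational strings, dot-bracket structures)."""
    import json

    doc = {
        "format": "branchfold-regions",
        "version": 1,
        "regions": [
            {
                "seq_index": r.seq_index,
                "region_index": r.region_index,
                "inequalities": [[[str(c) for c in coeffs], str(rhs)]
                                 for coeffs, rhs in r.inequalities],
                "signature": None if r.signature is None else
                    {"x": r.signature.x, "y": r.signature.y,
                     "z": r.signature.z, "w": str(r.signature.w)},
                "structures": [s.to_dotbracket() for s in r.structures],
                "truncated": r.truncated,
                "accuracy": None if r.accuracy is None else str(r.accuracy),
                "members": {str(k): v for k, v in r.members.items()},
            }
            for r in regions
        ],
    }
    from pathlib import Path
    Path(path).write_text(json.dumps(doc, indent=1))


def load_regions(path) -> list:
    import json
    from pathlib import Path

    from .energy import BranchingSignature
    from .structures import parse_structure

    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "branchfold-regions" or doc.get("version") != 1:
        raise ValueError("not a branchfold regions document")
    out = []
    for entry in doc["regions"]:
        sig = entry["signature"]
        out.append(ParameterRegion(
            seq_index=entry["seq_index"],
            region_index=entry["region_index"],
            inequalities=[(tuple(_F(c) for c in coeffs), _F(rhs))
                          for coeffs, rhs in entry["inequalities"]],
            signature=None if sig is None else BranchingSignature(
                sig["x"], sig["y"], sig["z"], _F(sig["w"])),
            structures=[parse_structure(db, "dotbracket")
                        for db in entry["structures"]],
            truncated=bool(entry["truncated"]),
            accuracy=None if entry["accuracy"] is None else _F(entry["accuracy"]),
            members={int(k): v for k, v in entry["members"].items()},
        ))
    return out


def slice_polygon(region: ParameterRegion, b_value, box=20):
    """Vertices of the region's 2D slice at fixed b, clipped to
    [-box, box]^2 in the (a, c)-plane; [] when the slice is empty.

    For plotting the subdivision one b-plane at a time.  Vertices are
    returned in counterclockwise order around the polygon centroid.
    """
    b_value = _F(str(b_value)) if isinstance(b_value, float) else _F(b_value)
    box = _F(box)
    rows2 = []
    for (alpha, beta, gamma), delta in region.inequalities:
        rows2.append(((alpha, gamma), delta - beta * b_value))
    rows2 += [((_F(1), _F(0)), box), ((_F(-1), _F(0)), box),
              ((_F(0), _F(1)), box), ((_F(0), _F(-1)), box)]
    from itertools import combinations

    from .geometry import _solve_square
    verts = set()
    for (c1, d1), (c2, d2) in combinations(rows2, 2):
        point = _solve_square([list(c1), list(c2)], [d1, d2])
        if point is None:
            continue
        if all(co[0] * point[0] + co[1] * point[1] <= rhs for co, rhs in rows2):
            verts.add(point)
    if not verts:
        return []
    import math
    cx = sum(v[0] for v in verts) / len(verts)
    cy = sum(v[1] for v in verts) / len(verts)
    return sorted(verts, key=lambda v: math.atan2(float(v[1] - cy), float(v[0] - cx)))


def sample_interior_points(region: ParameterRegion, count: int, rng) -> list:
    """``count`` exact rational points strictly inside the region.

    Seeded perturbations of an interior LP witness within its verified
    L-infinity safety margin; used to audit that every parameter choice in
    a region reproduces the region's MFE signature.
    """
    got = geometry.interior_point(region.inequalities, dim=3, with_margin=True)
    if got is None:
        raise ValueError("cannot sample from an empty region")
    center, eps = got
    out = [BranchingParameters(*center)]
    denom = 10_000
    while len(out) < count:
        delta = tuple(eps * _F(rng.randrange(-denom + 1, denom), 2 * denom)
                      for _ in range(3))
        pt = tuple(c + d for c, d in zip(center, delta))
        if region.contains(pt, strict=True):
            out.append(BranchingParameters(*pt))
    return out[:count]
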