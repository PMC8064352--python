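"""Exact rational linear programming and small polyhedral computations.

Everything downstream (hull certification, parameter-region emptiness,
redundancy removal, interior points) is phrased so that each linear program
has at most six rows: either a Farkas/membership system over nonnegative
multipliers, or the dual of a 3-4 variable program.  A dense two-phase
tableau simplex over ``fractions.Fraction`` with Bland's rule solves these
exactly; every certificate a caller relies on is re-verified by direct
substitution, so the answers do not depend on bookkeeping subtleties.

Inequalities are (coeffs, rhs) pairs meaning coeffs . x <= rhs.  "Interior"
emptiness semantics ask for a full-dimensional solution set (a point
satisfying every nontrivial inequality strictly); "closed" semantics ask for
any point.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import gcd
from typing import NamedTuple, Sequence

__all__ = [
    "SimplexResult",
    "simplex_max",
    "interior_point",
    "is_empty_closed",
    "maximize",
    "reduce_inequalities",
    "polyhedron_vertices",
    "recession_rays",
    "hull_membership",
]

F = Fraction
_ZERO = F(0)
_ONE = F(1)


class SimplexResult(NamedTuple):
    status: str          # 'optimal' | 'infeasible' | 'unbounded'
    x: list | None       # primal solution (structural variables)
    value: Fraction | None
    y: list | None       # row multipliers (Farkas certificate if infeasible)


def simplex_max(c: Sequence, A: Sequence[Sequence], b: Sequence) -> SimplexResult:
    """Maximize c.z subject to A z = b, z >= 0 (exact, Bland's rule).

    Designed for systems with few rows and many columns.  On infeasibility
    the returned ``y`` satisfies y.A <= 0 componentwise with y.b > 0.
    """
    m = len(A)
    n = len(c)
    A = [[F(v) for v in row] for row in A]
    b = [F(v) for v in b]
    c = [F(v) for v in c]
    flip = [False] * m
    for i in range(m):
        if b[i] < 0:
            A[i] = [-v for v in A[i]]
            b[i] = -b[i]
            flip[i] = True

    ncols = n + m  # structural + artificial
    T = [A[i] + [_ONE if k == i else _ZERO for k in range(m)] + [b[i]]
         for i in range(m)]
    basis = list(range(n, n + m))

    def pivot(r: int, e: int) -> None:
        piv = T[r][e]
        T[r] = [v / piv for v in T[r]]
        for i in range(m):
            if i != r and T[i][e] != 0:
                f = T[i][e]
                T[i] = [vi - f * vr for vi, vr in zip(T[i], T[r])]
        basis[r] = e

    def run(costs: list, allowed_max: int) -> str:
        # maintain reduced-cost row zrow[j] = cB.Tcol_j - costs[j]
        while True:
            cb = [costs[basis[i]] for i in range(m)]
            enter = -1
            for j in range(allowed_max):
                zj = sum(cb[i] * T[i][j] for i in range(m)) - costs[j]
                if zj < 0:
                    enter = j
                    break
            if enter < 0:
                return "optimal"
            leave = -1
            best = None
            for i in range(m):
                if T[i][enter] > 0:
                    ratio = T[i][-1] / T[i][enter]
                    if best is None or ratio < best or \
                            (ratio == best and basis[i] < basis[leave]):
                        best = ratio
                        leave = i
            if leave < 0:
                return "unbounded"
            pivot(leave, enter)

    # phase 1: drive artificials to zero
    costs1 = [_ZERO] * n + [-_ONE] * m
    run(costs1, ncols)
    art_value = sum(T[i][-1] for i in range(m) if basis[i] >= n)
    if art_value > 0:
        cb = [costs1[basis[i]] for i in range(m)]
        y = []
        for i in range(m):
            zj = sum(cb[r] * T[r][n + i] for r in range(m)) - costs1[n + i]
            yi = zj - _ONE  # cost of artificial i is -1
            y.append(-yi if flip[i] else yi)
        # y.A <= 0, y.b > 0 certifies infeasibility (caller verifies)
        return SimplexResult("infeasible", None, None, [-v for v in y])

    # drive any basic artificial (at zero level) out with a degenerate pivot;
    # rows that stay all-zero on structural columns are redundant and inert
    for i in range(m):
        if basis[i] >= n:
            for j in range(n):
                if T[i][j] != 0:
                    pivot(i, j)
                    break

    # phase 2: artificial columns barred from entering
    costs2 = c + [_ZERO] * m
    status = run(costs2, n)
    if status == "unbounded":
        return SimplexResult("unbounded", None, None, None)
    x = [_ZERO] * n
    for i in range(m):
        if basis[i] < n:
            x[basis[i]] = T[i][-1]
    cb = [costs2[basis[i]] for i in range(m)]
    y = []
    for i in range(m):
        zj = sum(cb[r] * T[r][n + i] for r in range(m))
        y.append(-zj if flip[i] else zj)
    value = sum(ci * xi for ci, xi in zip(c, x))
    return SimplexResult("optimal", x, value, y)


# ---------------------------------------------------------------------------
# Inequality-system queries (coeffs . x <= rhs)
# ---------------------------------------------------------------------------

def _split_trivial(rows):
    """Separate all-zero-coefficient rows; return (real rows, infeasible?)."""
    real = []
    for coeffs, rhs in rows:
        if any(v != 0 for v in coeffs):
            real.append((tuple(F(v) for v in coeffs), F(rhs)))
        elif F(rhs) < 0:
            return [], True
    return real, False


def interior_point(rows, dim: int | None = None, with_margin: bool = False):
    """An exact strictly-interior point of {x : A x <= b}, or None.

    Returns None when the solution set has empty interior (is not
    full-dimensional), including when it is empty altogether.  The witness
    is verified by substitution before being returned.  With
    ``with_margin`` the return value is (point, eps) where every point
    within L-infinity distance eps of the witness still satisfies the
    system (strictly inside that ball).
    """
    real, bad = _split_trivial(rows)
    if bad:
        return None
    if dim is None:
        dim = len(real[0][0]) if real else 3
    if not real:
        origin = tuple(_ZERO for _ in range(dim))
        return (origin, _ONE) if with_margin else origin
    m = len(real)
    norms = [sum(abs(v) for v in coeffs) for coeffs, _ in real]
    # Dual of: max eps s.t. A x + eps*norm <= b, eps <= 1.
    # min b.y + t  s.t.  A^T y = 0  (dim rows),  norm.y + t = 1,  y, t >= 0
    A_eq = [[real[j][0][k] for j in range(m)] + [_ZERO] for k in range(dim)]
    A_eq.append([norms[j] for j in range(m)] + [_ONE])
    b_eq = [_ZERO] * dim + [_ONE]
    cost = [-real[j][1] for j in range(m)] + [-_ONE]  # maximize -(b.y + t)
    res = simplex_max(cost, A_eq, b_eq)
    if res.status != "optimal":  # the dual is always feasible and bounded
        raise RuntimeError(f"interior-point dual solve failed: {res.status}")
    eps = -res.value
    if eps <= 0:
        return None
    point = tuple(-v for v in res.y[:dim])
    for (coeffs, rhs) in real:
        if sum(ci * xi for ci, xi in zip(coeffs, point)) >= rhs:
            raise RuntimeError("interior-point certificate failed verification")
    return (point, eps) if with_margin else point


def is_empty_interior(rows) -> bool:
    """True iff {x : A x <= b} is not full-dimensional (interior semantics)."""
    return interior_point(rows) is None


def is_empty_closed(rows) -> bool:
    """True iff {x : A x <= b} has no point at all (exact Farkas test)."""
    real, bad = _split_trivial(rows)
    if bad:
        return True
    if not real:
        return False
    dim = len(real[0][0])
    m = len(real)
    # feasible lambda >= 0 with A^T lambda = 0, b.lambda = -1  <=>  empty
    A_eq = [[real[j][0][k] for j in range(m)] for k in range(dim)]
    A_eq.append([real[j][1] for j in range(m)])
    b_eq = [_ZERO] * dim + [-_ONE]
    res = simplex_max([_ZERO] * m, A_eq, b_eq)
    if res.status == "optimal":
        lam = res.x
        assert all(v >= 0 for v in lam)
        return True
    return False


def maximize(rows, objective):
    """(status, value) for max objective.x over {A x <= b}.

    status is 'optimal', 'unbounded' or 'infeasible'.  Solved through the
    dual (few rows); value is exact.
    """
    real, bad = _split_trivial(rows)
    if bad:
        return "infeasible", None
    dim = len(objective)
    if not real:
        if all(v == 0 for v in objective):
            return "optimal", _ZERO
        return "unbounded", None
    m = len(real)
    # dual: min b.y s.t. A^T y = objective, y >= 0
    A_eq = [[real[j][0][k] for j in range(m)] for k in range(dim)]
    b_eq = [F(v) for v in objective]
    cost = [-real[j][1] for j in range(m)]
    res = simplex_max(cost, A_eq, b_eq)
    if res.status == "optimal":
        return "optimal", -res.value
    if res.status == "infeasible":
        # no dual solution: primal is unbounded or infeasible
        return ("infeasible", None) if is_empty_closed(real) else ("unbounded", None)
    # dual unbounded -> primal infeasible
    return "infeasible", None


def _normalize_row(coeffs, rhs):
    vals = [v for v in coeffs if v != 0]
    if not vals:
        return None
    scale = abs(vals[0])
    return tuple(v / scale for v in coeffs), F(rhs) / scale


def reduce_inequalities(rows):
    """Remove duplicate and LP-redundant inequalities (exact).

    The input system is assumed consistent (callers check emptiness first);
    the returned system defines the same solution set.
    """
    seen = {}
    for coeffs, rhs in rows:
        norm = _normalize_row([F(v) for v in coeffs], rhs)
        if norm is None:
            continue
        key = norm[0]
        if key not in seen or norm[1] < seen[key][1]:
            seen[key] = norm
    kept = list(seen.values())
    i = 0
    while i < len(kept):
        others = kept[:i] + kept[i + 1:]
        coeffs, rhs = kept[i]
        status, value = maximize(others, coeffs)
        if status == "optimal" and value <= rhs:
            kept.pop(i)
        else:
            i += 1
    return kept


def _solve_square(mat, rhs):
    """Exact solve of a small square system; None if singular."""
    n = len(mat)
    M = [list(row) + [rhs[i]] for i, row in enumerate(mat)]
    for col in range(n):
        piv = next((r for r in range(col, n) if M[r][col] != 0), None)
        if piv is None:
            return None
        M[col], M[piv] = M[piv], M[col]
        pv = M[col][col]
        M[col] = [v / pv for v in M[col]]
        for r in range(n):
            if r != col and M[r][col] != 0:
                f = M[r][col]
                M[r] = [vr - f * vc for vr, vc in zip(M[r], M[col])]
    return tuple(M[r][n] for r in range(n))


def polyhedron_vertices(rows, dim: int = 3):
    """All vertices of {A x <= b} by exact basis enumeration (small m)."""
    real, bad = _split_trivial(rows)
    if bad:
        return []
    verts = set()
    for subset in combinations(range(len(real)), dim):
        mat = [list(real[i][0]) for i in subset]
        rhs = [real[i][1] for i in subset]
        point = _solve_square(mat, rhs)
        if point is None:
            continue
        if all(sum(ci * xi for ci, xi in zip(coeffs, point)) <= r
               for coeffs, r in real):
            verts.add(point)
    return sorted(verts)


def _primitive(vec):
    denom = 1
    for v in vec:
        denom = denom * v.denominator // gcd(denom, v.denominator)
    ints = [int(v * denom) for v in vec]
    g = 0
    for v in ints:
        g = gcd(g, abs(v))
    if g == 0:
        return None
    return tuple(F(v, g) for v in ints)


def recession_rays(rows, dim: int = 3):
    """Extreme-ray candidates of the recession cone {d : A d <= 0}.

    Exact but deliberately simple: candidate directions come from pairs of
    tight constraints (plus coordinate axes for low-constraint systems) and
    are filtered by membership.  Callers verify any point they construct.
    """
    real, _ = _split_trivial(rows)
    cands = set()
    axes = [tuple(_ONE if k == i else _ZERO for k in range(dim)) for i in range(dim)]
    for d in axes:
        cands.add(d)
        cands.add(tuple(-v for v in d))
    for (c1, _), (c2, _) in combinations(real, 2):
        d = (c1[1] * c2[2] - c1[2] * c2[1],
             c1[2] * c2[0] - c1[0] * c2[2],
             c1[0] * c2[1] - c1[1] * c2[0]) if dim == 3 else None
        if d is not None:
            p = _primitive(d)
            if p is not None:
                cands.add(p)
                cands.add(tuple(-v for v in p))
    rays = []
    for d in sorted(cands):
        if any(v != 0 for v in d) and \
                all(sum(ci * di for ci, di in zip(coeffs, d)) <= 0 for coeffs, _ in real):
            rays.append(d)
    return rays


def hull_membership(points, target, lower: bool = False):
    """Is ``target`` a convex combination of ``points``?

    With ``lower=True`` the test is against the lower side in the last
    coordinate: is there a convex combination matching ``target`` on all
    other coordinates whose last coordinate is <= target's?  A point of a
    finite set is a vertex of its (lower) convex hull exactly when this
    membership test against the other points fails.

    Returns (member, certificate): ``certificate`` is the combination when
    member, else an exact separating functional theta such that
    theta . p > theta . target for every p in ``points`` (with theta's last
    component >= 0 when ``lower``).
    """
    if not points:
        return False, None
    dim = len(target)
    m = len(points)
    tgt = [F(v) for v in target]
    if lower:
        # rows: coords 0..dim-2 equal; sum lambda = 1; last coord <= target
        A_eq = [[F(p[k]) for p in points] + [_ZERO] for k in range(dim - 1)]
        A_eq.append([_ONE] * m + [_ZERO])
        A_eq.append([F(p[dim - 1]) for p in points] + [_ONE])  # slack
        b_eq = tgt[: dim - 1] + [_ONE, tgt[dim - 1]]
        ncols = m + 1
    else:
        A_eq = [[F(p[k]) for p in points] for k in range(dim)]
        A_eq.append([_ONE] * m)
        b_eq = tgt + [_ONE]
        ncols = m
    res = simplex_max([_ZERO] * ncols, A_eq, b_eq)
    if res.status == "optimal":
        return True, res.x[:m]
    # Farkas certificate y: y.col <= 0 for all columns, y.rhs > 0.
    y = res.y
    theta = [-v for v in y[:dim - 1]] if lower else [-v for v in y[:dim]]
    if lower:
        theta.append(-y[dim])  # multiplier of the slack row = last coordinate
    offset = -y[dim - 1] if lower else -y[dim]
    # verification: theta . p + offset... derive margin directly instead
    def val(p):
        return sum(t * F(v) for t, v in zip(theta, p))
    base = val(tgt)
    for p in points:
        if not val(p) > base:
            raise RuntimeError("hull-membership separation certificate failed")
    if lower and theta[-1] < 0:
        raise RuntimeError("lower-hull certificate has negative w coefficient")
    return False, theta
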