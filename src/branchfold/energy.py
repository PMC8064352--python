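"""Reduced nearest-neighbor energy model with a linear multiloop initiation term.

The free energy of a secondary structure S on a sequence decomposes as

    E(S) = w + a*x + b*y + c*z

where (x, y, z) count multiloops, unpaired nucleotides inside multiloops and
branching helices (the closing helix of each multiloop included), and w
collects every other contribution: helix stacking, hairpin and internal/bulge
loop initiation, and terminal AU/GU penalties.  The 4-tuple (x, y, z, w) is
the *branching signature* of the structure; the multiloop initiation
parameters (a, b, c) enter only through the affine form above, which is what
the parametric machinery in the rest of the package exploits.

The model is deliberately reduced relative to full Turner-style tables: no
dangles, no coaxial stacking, no single-strand stacking in multiloops, no
tabulated special loops; the exterior loop is free.  Stacking uses a fixed
table over canonical pair steps; hairpin and internal/bulge loops are scored
by size with a logarithmic (Jacobson-Stockmayer-style) extrapolation beyond
size 30, rounded to 0.1 kcal/mol so that every energy is an exact rational.
All arithmetic is exact: energies are Fractions externally and common-
denominator-scaled integers inside the dynamic programs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from itertools import islice
from math import gcd, inf
from typing import Iterator, NamedTuple

from .structures import (
    CANONICAL_PAIRS,
    RnaSequence,
    SecondaryStructure,
    StructureError,
    validate_bound,
)

__all__ = [
    "BranchingParameters",
    "BranchingSignature",
    "EnergyTables",
    "T89",
    "T99",
    "T04",
    "branching_signature",
    "score_structure",
    "mfe_fold",
    "enumerate_structures",
    "iter_structures",
    "FoldResult",
    "EnumerationResult",
]

_DEFAULT_TABLE_RESOURCE = "default_tables.json"

#: Maximum sequence length accepted by exhaustive enumeration without override.
ENUMERATION_GUARD_NT = 45


def _as_fraction(value) -> Fraction:
    """Exact rational from int/str/Fraction; floats via their decimal repr."""
    if isinstance(value, float):
        return Fraction(str(value))
    return Fraction(value)


@dataclass(frozen=True)
class BranchingParameters:
    """The multiloop initiation coefficients (a, b, c), in kcal/mol.

    ``a`` is the per-multiloop offset, ``b`` the penalty per unpaired
    nucleotide inside a multiloop, ``c`` the penalty per branching helix.
    Stored as exact rationals.
    """

    a: Fraction
    b: Fraction
    c: Fraction

    def __post_init__(self) -> None:
        object.__setattr__(self, "a", _as_fraction(self.a))
        object.__setattr__(self, "b", _as_fraction(self.b))
        object.__setattr__(self, "c", _as_fraction(self.c))

    def __iter__(self):
        return iter((self.a, self.b, self.c))

    def step(self, direction) -> "BranchingParameters":
        """One unit step along ``direction`` (a rational 3-vector)."""
        d = [_as_fraction(v) for v in direction]
        return BranchingParameters(self.a + d[0], self.b + d[1], self.c + d[2])

    def __sub__(self, other: "BranchingParameters"):
        return (self.a - other.a, self.b - other.b, self.c - other.c)


#: Historical Turner branching-parameter sets (a, b, c) in kcal/mol.
T89 = BranchingParameters(Fraction("4.6"), Fraction("0.4"), Fraction("0.1"))
T99 = BranchingParameters(Fraction("3.4"), Fraction(0), Fraction("0.4"))
T04 = BranchingParameters(Fraction("9.3"), Fraction(0), Fraction("-0.6"))


@dataclass(frozen=True)
class BranchingSignature:
    """(x, y, z, w): multiloop count, unpaired-in-multiloop count, branch
    count, and all non-multiloop-initiation free energy (kcal/mol)."""

    x: int
    y: int
    z: int
    w: Fraction

    def __post_init__(self) -> None:
        object.__setattr__(self, "w", _as_fraction(self.w))
        if self.x < 0 or self.y < 0 or self.z < 0:
            raise ValueError("signature counts must be nonnegative")
        if self.z < 3 * self.x:
            raise ValueError(f"z={self.z} < 3x={3 * self.x}: every multiloop has >= 3 branches")
        if self.x == 0 and (self.y != 0 or self.z != 0):
            raise ValueError("x = 0 forces y = z = 0")

    def energy(self, params: BranchingParameters) -> Fraction:
        return self.w + params.a * self.x + params.b * self.y + params.c * self.z

    def point(self) -> tuple:
        return (self.x, self.y, self.z, self.w)


# ---------------------------------------------------------------------------
# Energy tables
# ---------------------------------------------------------------------------

class EnergyTables:
    """Stacking, loop-initiation and terminal-penalty tables (exact rationals).

    ``stack`` maps "XY/ZW" (outer pair X-Y enclosing inner pair Z-W) to the
    stacking energy; it must satisfy the reverse-complement symmetry
    E[XY/ZW] == E[WZ/YX].  ``hairpin_init`` covers sizes 3..30 and
    ``internal_init`` sizes 1..30; larger loops are extrapolated as
    init(n) = init(30) + coeff * ln(n/30), rounded to the nearest 0.1.
    """

    def __init__(self, stack, hairpin_init, internal_init, terminal_au,
                 extrapolation_base: int = 30,
                 extrapolation_coefficient=Fraction(11, 10)):
        self.stack = {k: _as_fraction(v) for k, v in stack.items()}
        self.hairpin_init = {int(k): _as_fraction(v) for k, v in hairpin_init.items()}
        self.internal_init = {int(k): _as_fraction(v) for k, v in internal_init.items()}
        self.terminal_au = _as_fraction(terminal_au)
        self.extrapolation_base = int(extrapolation_base)
        self.extrapolation_coefficient = _as_fraction(extrapolation_coefficient)
        self._validate()

    def _validate(self) -> None:
        for size in range(3, self.extrapolation_base + 1):
            if size not in self.hairpin_init:
                raise ValueError(f"hairpin_init missing size {size}")
        for size in range(1, self.extrapolation_base + 1):
            if size not in self.internal_init:
                raise ValueError(f"internal_init missing size {size}")
        for key, val in self.stack.items():
            outer, inner = key.split("/")
            mirror = inner[::-1] + "/" + outer[::-1]
            if self.stack.get(mirror) != val:
                raise ValueError(f"stack table not symmetric at {key} vs {mirror}")

    # -- lookups ------------------------------------------------------------

    def _extrapolate(self, table: dict, size: int) -> Fraction:
        base = self.extrapolation_base
        bump = float(self.extrapolation_coefficient) * math.log(size / base)
        return table[base] + Fraction(round(bump * 10), 10)

    def hairpin_energy(self, size: int) -> Fraction:
        if size < 3:
            raise ValueError(f"hairpin loop of size {size} < 3")
        if size in self.hairpin_init:
            return self.hairpin_init[size]
        return self._extrapolate(self.hairpin_init, size)

    def internal_energy(self, size: int) -> Fraction:
        if size < 1:
            raise ValueError(f"internal/bulge loop of size {size} < 1")
        if size in self.internal_init:
            return self.internal_init[size]
        return self._extrapolate(self.internal_init, size)

    def stack_energy(self, outer: str, inner: str) -> Fraction:
        return self.stack[f"{outer}/{inner}"]

    def terminal_penalty(self, pair: str) -> Fraction:
        """Per-helix-end penalty for AU/UA/GU/UG closing pairs."""
        return self.terminal_au if "U" in pair else Fraction(0)

    # -- serialization ------------------------------------------------------

    @classmethod
    def load(cls, path=None) -> "EnergyTables":
        if path is None:
            text = resources.files("branchfold.data").joinpath(
                _DEFAULT_TABLE_RESOURCE).read_text()
        else:
            with open(path) as fh:
                text = fh.read()
        doc = json.loads(text)
        if doc.get("format") != "branchfold-energy-tables":
            raise ValueError("not a branchfold energy-table document")
        if doc.get("version") != 1:
            raise ValueError(f"unsupported energy-table version {doc.get('version')!r}")
        ex = doc.get("extrapolation", {})
        return cls(
            stack=doc["stack"],
            hairpin_init=doc["hairpin_init"],
            internal_init=doc["internal_init"],
            terminal_au=doc["terminal_au"],
            extrapolation_base=ex.get("base_size", 30),
            extrapolation_coefficient=ex.get("coefficient", "11/10"),
        )

    def dump(self, path) -> None:
        doc = {
            "format": "branchfold-energy-tables",
            "version": 1,
            "units": "kcal/mol",
            "stack": {k: str(v) for k, v in sorted(self.stack.items())},
            "hairpin_init": {str(k): str(v) for k, v in sorted(self.hairpin_init.items())},
            "internal_init": {str(k): str(v) for k, v in sorted(self.internal_init.items())},
            "terminal_au": str(self.terminal_au),
            "extrapolation": {
                "base_size": self.extrapolation_base,
                "coefficient": str(self.extrapolation_coefficient),
            },
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


# ---------------------------------------------------------------------------
# Integer-scaled view of the model for one sequence
# ---------------------------------------------------------------------------

class ScaledModel:
    """All model atoms for one sequence, scaled to a common integer grid.

    ``denominator`` D is the lcm of every rational denominator involved, so
    that D * energy is an integer for every structure.  The folding and
    polytope DPs run entirely on these integers.
    """

    def __init__(self, seq: RnaSequence, tables: EnergyTables, extra=()):
        self.seq = seq
        self.tables = tables
        n = len(seq)
        self.n = n
        res = seq.residues
        self.canon = [[False] * n for _ in range(n)]
        for i in range(n):
            for j in range(i + 4, n):
                if (res[i], res[j]) in CANONICAL_PAIRS:
                    self.canon[i][j] = True

        hp = [None, None, None] + [tables.hairpin_energy(s) for s in range(3, max(n, 4))]
        il = [None] + [tables.internal_energy(s) for s in range(1, max(n, 2))]
        atoms = [v for v in hp + il if v is not None]
        atoms.append(tables.terminal_au)
        atoms.extend(tables.stack.values())
        atoms.extend(_as_fraction(v) for v in extra)
        denom = 1
        for v in atoms:
            denom = denom * v.denominator // gcd(denom, v.denominator)
        self.denominator = denom

        self.hp = [None if v is None else int(v * denom) for v in hp]
        self.il = [None if v is None else int(v * denom) for v in il]
        self._ta_scaled = int(tables.terminal_au * denom)
        self._stack_scaled = {k: int(v * denom) for k, v in tables.stack.items()}
        self._res = res

    def term(self, i: int, j: int) -> int:
        """Scaled terminal AU/GU penalty for pair (i, j), 0-based."""
        r = self._res
        return self._ta_scaled if (r[i] == "U" or r[j] == "U") else 0

    def stack(self, i: int, j: int) -> int:
        """Scaled stacking energy for pair (i,j) on inner pair (i+1,j-1)."""
        r = self._res
        return self._stack_scaled[f"{r[i]}{r[j]}/{r[i + 1]}{r[j - 1]}"]

    def unscale(self, value: int) -> Fraction:
        return Fraction(value, self.denominator)


# ---------------------------------------------------------------------------
# Signature of a given structure
# ---------------------------------------------------------------------------

def _loop_children(partner: dict, i: int, j: int) -> tuple:
    """Direct child pairs and unpaired count of the loop closed by (i, j).

    1-based; use i=0, j=length+1 for the exterior loop.
    """
    children = []
    unpaired = 0
    k = i + 1
    while k < j:
        mate = partner.get(k)
        if mate is None:
            unpaired += 1
            k += 1
        else:
            children.append((k, mate))
            k = mate + 1
    return children, unpaired


def branching_signature(seq: RnaSequence, structure: SecondaryStructure,
                        tables: EnergyTables) -> BranchingSignature:
    """Branching signature (x, y, z, w) of ``structure`` on ``seq``.

    Terminal AU/GU penalties are charged once per helix end per adjacent
    loop: a pair is charged on its outer side when it borders the exterior,
    an internal loop or a multiloop, and on its inner side when it closes a
    hairpin, internal loop or multiloop; stacked steps carry no charge.
    Multiloop-adjacent terminal penalties count toward w, not the initiation
    term.
    """
    validate_bound(seq, structure)
    partner = structure.partner_map()
    res = seq.residues
    tab = tables

    def bases(p):
        return res[p[0] - 1] + res[p[1] - 1]

    x = y = z = 0
    w = Fraction(0)
    ext_children, _ = _loop_children(partner, 0, structure.length + 1)
    for child in ext_children:
        w += tab.terminal_penalty(bases(child))
    stackq = list(ext_children)
    while stackq:
        i, j = stackq.pop()
        children, unpaired = _loop_children(partner, i, j)
        stackq.extend(children)
        if not children:
            w += tab.hairpin_energy(j - i - 1) + tab.terminal_penalty(bases((i, j)))
        elif len(children) == 1:
            k, l = children[0]
            size = (k - i - 1) + (j - l - 1)
            if size == 0:
                w += tab.stack_energy(bases((i, j)), bases((k, l)))
            else:
                w += (tab.internal_energy(size)
                      + tab.terminal_penalty(bases((i, j)))
                      + tab.terminal_penalty(bases((k, l))))
        else:
            x += 1
            y += unpaired
            z += len(children) + 1
            w += tab.terminal_penalty(bases((i, j)))
            for child in children:
                w += tab.terminal_penalty(bases(child))
    return BranchingSignature(x=x, y=y, z=z, w=w)


def score_structure(seq: RnaSequence, structure: SecondaryStructure,
                    tables: EnergyTables, params: BranchingParameters) -> Fraction:
    """Exact free energy w + a*x + b*y + c*z of ``structure``."""
    return branching_signature(seq, structure, tables).energy(params)


# ---------------------------------------------------------------------------
# Exhaustive enumeration (test oracle; guarded)
# ---------------------------------------------------------------------------

class EnumerationResult(NamedTuple):
    structures: list
    truncated: bool


def iter_pair_tuples(seq: RnaSequence, force: bool = False) -> Iterator[tuple]:
    """Yield the 0-based pair tuple of every valid structure exactly once.

    The raw engine behind :func:`iter_structures`; exponential in length,
    refuses sequences longer than 45 nt unless ``force`` is given.
    """
    n = len(seq)
    if n > ENUMERATION_GUARD_NT and not force:
        raise StructureError(
            f"enumeration refused for {n} nt > {ENUMERATION_GUARD_NT} nt guard "
            f"(pass force=True to override)"
        )
    res = seq.residues
    canon = [[(res[i], res[j]) in CANONICAL_PAIRS and j - i >= 4 for j in range(n)]
             for i in range(n)]

    def gen(i: int, j: int):
        # all pair-tuples on residues[i..j], 0-based inclusive
        if i >= j:
            yield ()
            return
        for rest in gen(i + 1, j):  # i unpaired
            yield rest
        for k in range(i + 4, j + 1):
            if canon[i][k]:
                for inner in gen(i + 1, k - 1):
                    for outer in gen(k + 1, j):
                        yield ((i, k),) + inner + outer

    yield from gen(0, n - 1)


def iter_structures(seq: RnaSequence, force: bool = False) -> Iterator[SecondaryStructure]:
    """Yield every valid structure of ``seq`` exactly once (open chain first)."""
    n = len(seq)
    for pairs in iter_pair_tuples(seq, force=force):
        yield SecondaryStructure(length=n,
                                 pairs=frozenset((i + 1, j + 1) for i, j in pairs))


def enumerate_structures(seq: RnaSequence, max_count: int | None = None,
                         force: bool = False) -> EnumerationResult:
    """All valid structures up to ``max_count``, with a truncation flag."""
    it = iter_structures(seq, force=force)
    if max_count is None:
        return EnumerationResult(list(it), False)
    head = list(islice(it, max_count + 1))
    if len(head) > max_count:
        return EnumerationResult(head[:max_count], True)
    return EnumerationResult(head, False)


# ---------------------------------------------------------------------------
# MFE folding DP with co-optimal traceback
# ---------------------------------------------------------------------------

class FoldResult(NamedTuple):
    energy: Fraction
    structures: list
    truncated: bool


#: Default cap on the number of co-optimal structures returned.
DEFAULT_MAX_STRUCTURES = 100


def _fold_tables(model: ScaledModel, a: int, b: int, c: int):
    """Fill V / WM / WM2 / W matrices of scaled energies.

    V(i,j): minimum energy on [i,j] with (i,j) paired; inner-side terminal
    charges included, outer-side charged by the consuming context.
    WM(i,j) / WM2(i,j): multiloop segment with >= 1 / >= 2 branches; every
    unpaired nucleotide charged b, every branch charged c plus its outer
    terminal penalty.  W(t): exterior prefix of length t (free loop).
    """
    n = model.n
    canon = model.canon
    hp, il = model.hp, model.il
    term, stk = model.term, model.stack
    V = [[inf] * n for _ in range(n)]
    WM = [[inf] * n for _ in range(n)]
    WM2 = [[inf] * n for _ in range(n)]
    for span in range(4, n):
        for i in range(n - span):
            j = i + span
            if canon[i][j]:
                taij = term(i, j)
                best = hp[span - 1] + taij
                if span >= 6 and canon[i + 1][j - 1] and V[i + 1][j - 1] is not inf:
                    best = min(best, V[i + 1][j - 1] + stk(i, j))
                for k in range(i + 1, j - 4):
                    row = V[k]
                    for l in range(k + 4, j):
                        if (k == i + 1 and l == j - 1) or row[l] is inf:
                            continue
                        size = (k - i - 1) + (j - l - 1)
                        cand = row[l] + il[size] + taij + term(k, l)
                        if cand < best:
                            best = cand
                if WM2[i + 1][j - 1] is not inf:
                    cand = WM2[i + 1][j - 1] + taij + a + c
                    if cand < best:
                        best = cand
                V[i][j] = best
            # multiloop segment matrices
            wm = WM[i][j - 1] + b if WM[i][j - 1] is not inf else inf
            wm2 = WM2[i][j - 1] + b if WM2[i][j - 1] is not inf else inf
            for k in range(i, j - 3):
                if not canon[k][j] or V[k][j] is inf:
                    continue
                branch = V[k][j] + term(k, j) + c
                cand = branch + b * (k - i)  # only branch; unpaired prefix
                if cand < wm:
                    wm = cand
                if k >= i + 5 and WM[i][k - 1] is not inf:
                    cand = WM[i][k - 1] + branch
                    if cand < wm:
                        wm = cand
                    if cand < wm2:
                        wm2 = cand
            WM[i][j] = wm
            WM2[i][j] = wm2
    W = [0] * (n + 1)
    for t in range(1, n + 1):
        best = W[t - 1]
        for k in range(0, t - 4):
            if canon[k][t - 1] and V[k][t - 1] is not inf:
                cand = W[k] + V[k][t - 1] + term(k, t - 1)
                if cand < best:
                    best = cand
        W[t] = best
    return V, WM, WM2, W


class _Tracer:
    """Enumerate all optimal tracebacks, deduplicated by construction."""

    def __init__(self, model: ScaledModel, mats, a: int, b: int, c: int, cap: int):
        self.model = model
        self.V, self.WM, self.WM2, self.W = mats
        self.a, self.b, self.c = a, b, c
        self.cap = cap
        self.truncated = False
        self._memo: dict = {}

    def _trim(self, items: list) -> list:
        if len(items) > self.cap:
            self.truncated = True
            return items[: self.cap]
        return items

    def _product(self, lefts: list, rights: list, extra=()) -> list:
        out = []
        for lt in lefts:
            for rt in rights:
                out.append(lt + rt + tuple(extra))
                if len(out) > self.cap:
                    self.truncated = True
                    return out[: self.cap]
        return out

    def trace_V(self, i: int, j: int) -> list:
        key = ("V", i, j)
        if key in self._memo:
            return self._memo[key]
        m = self.model
        target = self.V[i][j]
        taij = m.term(i, j)
        out: list = []
        if target == m.hp[j - i - 1] + taij:
            out.append(((i, j),))
        if (j - i >= 6 and m.canon[i + 1][j - 1] and self.V[i + 1][j - 1] is not inf
                and self.V[i + 1][j - 1] + m.stack(i, j) == target):
            out = self._trim(out + self._product(self.trace_V(i + 1, j - 1), [()],
                                                 extra=((i, j),)))
        for k in range(i + 1, j - 4):
            for l in range(k + 4, j):
                if (k == i + 1 and l == j - 1) or self.V[k][l] is inf:
                    continue
                size = (k - i - 1) + (j - l - 1)
                if self.V[k][l] + m.il[size] + taij + m.term(k, l) == target:
                    out = self._trim(out + self._product(self.trace_V(k, l), [()],
                                                         extra=((i, j),)))
        if (self.WM2[i + 1][j - 1] is not inf
                and self.WM2[i + 1][j - 1] + taij + self.a + self.c == target):
            out = self._trim(out + self._product(self.trace_WM2(i + 1, j - 1), [()],
                                                 extra=((i, j),)))
        self._memo[key] = out
        return out

    def _trace_wm_common(self, i: int, j: int, mat, trace_self, two_plus: bool) -> list:
        m = self.model
        target = mat[i][j]
        out: list = []
        if j > i and mat[i][j - 1] is not inf and mat[i][j - 1] + self.b == target:
            out = self._trim(out + trace_self(i, j - 1))
        for k in range(i, j - 3):
            if not m.canon[k][j] or self.V[k][j] is inf:
                continue
            branch = self.V[k][j] + m.term(k, j) + self.c
            if not two_plus and branch + self.b * (k - i) == target:
                out = self._trim(out + self.trace_V(k, j))
            if k >= i + 5 and self.WM[i][k - 1] is not inf \
                    and self.WM[i][k - 1] + branch == target:
                out = self._trim(out + self._product(self.trace_WM(i, k - 1),
                                                     self.trace_V(k, j)))
        return out

    def trace_WM(self, i: int, j: int) -> list:
        key = ("WM", i, j)
        if key not in self._memo:
            self._memo[key] = self._trace_wm_common(i, j, self.WM, self.trace_WM, False)
        return self._memo[key]

    def trace_WM2(self, i: int, j: int) -> list:
        key = ("WM2", i, j)
        if key not in self._memo:
            self._memo[key] = self._trace_wm_common(i, j, self.WM2, self.trace_WM2, True)
        return self._memo[key]

    def trace_W(self, t: int) -> list:
        key = ("W", t)
        if key in self._memo:
            return self._memo[key]
        if t == 0:
            return [()]
        m = self.model
        target = self.W[t]
        out: list = []
        if self.W[t - 1] == target:
            out = self._trim(list(self.trace_W(t - 1)))
        for k in range(0, t - 4):
            if m.canon[k][t - 1] and self.V[k][t - 1] is not inf \
                    and self.W[k] + self.V[k][t - 1] + m.term(k, t - 1) == target:
                out = self._trim(out + self._product(self.trace_W(k),
                                                     self.trace_V(k, t - 1)))
        self._memo[key] = out
        return out


def mfe_fold(seq: RnaSequence, tables: EnergyTables, params: BranchingParameters,
             max_structures: int = DEFAULT_MAX_STRUCTURES) -> FoldResult:
    """Minimum free energy and all co-optimal structures at fixed (a, b, c).

    The energy is the exact minimum of :func:`score_structure` over every
    valid structure; the structure list holds distinct co-optimal minimizers
    in lexicographic dot-bracket order, truncated at ``max_structures`` with
    the ``truncated`` flag set.
    """
    if len(seq) < 5:
        raise StructureError(f"sequence {seq.id!r} shorter than 5 nt cannot fold")
    if max_structures < 1:
        raise ValueError("max_structures must be >= 1")
    model = ScaledModel(seq, tables, extra=tuple(params))
    d = model.denominator
    a, b, c = (int(params.a * d), int(params.b * d), int(params.c * d))
    mats = _fold_tables(model, a, b, c)
    energy = model.unscale(mats[3][model.n])
    tracer = _Tracer(model, mats, a, b, c, cap=max_structures)
    raw = tracer.trace_W(model.n)
    structures = sorted(
        {SecondaryStructure(length=model.n,
                            pairs=frozenset((i + 1, j + 1) for i, j in pairs))
         for pairs in raw},
        key=SecondaryStructure.to_dotbracket,
    )
    return FoldResult(energy=energy, structures=structures, truncated=tracer.truncated)
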