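# branchfold

Parametric analysis of RNA multiloop (branching) energetics: branching
polytopes, the subdivision of branching-parameter space into regions of
constant minimum-free-energy (MFE) prediction, and a branch-and-bound
search for the parameters with the best average prediction accuracy over a
set of sequences with known reference structures.

## The problem

Under the nearest-neighbor thermodynamic model, the initiation cost of a
multiloop (a branching junction with three or more radiating helices) is
the linear function

    ΔG_init = a + b · (unpaired nucleotides in the loop) + c · (branching helices)

The three coefficients (a, b, c) are among the few model parameters not
fitted to experiment, and branching is a notoriously hard feature to
predict: the tRNA cloverleaf has one 4-branch junction, 5S rRNA a 3-branch
one, and parameters that favor one configuration can disfavor the other.

Because every structure's free energy depends on (a, b, c) only through
the affine form `E = w + a·x + b·y + c·z` — where the *branching
signature* (x, y, z, w) counts multiloops, unpaired multiloop nucleotides,
branches, and all remaining energy terms — the set of signatures a
sequence can realize spans a 4D **branching polytope**.  Its lower convex
hull in the w-direction induces, by duality, a subdivision of (a, b, c)
space into convex **regions** inside which the MFE prediction is constant.
Given a reference structure, each region Reg(i, j) of sequence i has an
accuracy Acc_i(Reg(i, j)): the F1 measure `2|S∩S′| / (|S|+|S′|)` over base
pairs, averaged over all co-optimal MFE structures.  Finding the
parameters that maximize the average accuracy over N sequences means
finding the nonempty intersection `Reg(1,j₁) ∩ … ∩ Reg(N,j_N)` with the
best mean accuracy — a combinatorial search this package solves exactly
with a branch-and-bound algorithm (accuracy-ordered region lists,
Max_k(Reg(i,j)) upper bounds, a region pre-filter, merge-time pruning
tests against the incumbent L, binary or linear merge plans, and a
pairwise-emptiness pre-filter for wide merges).

All of it is exact: energies are rationals, polytope vertices are
certified by rational convex-combination tests, and region emptiness is
decided by exact rational linear programming (interior semantics: a region
intersection counts as nonempty only when it is full-dimensional).

The energy model is deliberately reduced (stacking, hairpin and
internal/bulge initiation by loop size, terminal AU/GU penalties, free
exterior loop; no dangles or coaxial stacking), preserving exactly the
affine dependence on (a, b, c) that the parametric machinery requires.
Absolute energies are therefore not comparable to full Turner-model tools.

## Worked example

```python
from branchfold import (EnergyTables, T99, FixtureSpec, generate,
                        build_polytope, lower_hull, subdivide, mfe_fold,
                        order_regions)

tables = EnergyTables.load()
seq, ref = generate(FixtureSpec(shape="Y3", helix_lengths=(4, 4, 4),
                                loop_sizes=(3, 3, 1, 1, 1), seed=0))
fold = mfe_fold(seq, tables, T99)
print(len(seq), fold.energy, fold.structures[0].pairs == ref.pairs)

poly = lower_hull(build_polytope(seq, tables))
ordered = order_regions(subdivide(poly, tables), ref)
print(len(poly), float(ordered.U),
      [float(r.accuracy) for r in ordered.regions[:3]])
```

prints

```
35 -15/2 True
32 1.0 [1.0, 0.9565217391304348, 0.8]
```

— the 35 nt toy 3-branch fixture folds to its reference at the T99
parameters (3.4, 0, 0.4) with exact energy −7.5 kcal/mol; its branching
polytope has 32 lower-hull vertices, hence 32 parameter regions, and the
best attainable accuracy U is 1: some choice of (a, b, c) predicts the
reference perfectly, while nearby regions (losing or gaining a helix)
score lower.

The same pipeline is scriptable from the shell:

```
branchfold fixtures --shape cloverleaf4 --n 4 --seed 0 --out fx/
branchfold fold fx/sequences.fasta --params T99
branchfold polytope fx/sequences.fasta --out polys/
branchfold optimize --polytopes polys/ --refs fx/ --plan binary
```

`branchfold optimize` prints a JSON result with the exact optimum L, the
winning region combination, an exact interior representative point and its
one-decimal rounding, near-optimal combinations, and search counters.

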