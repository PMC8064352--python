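# Methods

## The reduced nearest-neighbor model

A secondary structure on a sequence over {A,C,G,U} is a set of canonical
(Watson–Crick or G·U wobble), pseudoknot-free base pairs with at least
three unpaired nucleotides in every hairpin.  Its free energy decomposes
over loops:

* **stacked pair** (i,j) on (i+1,j-1): tabulated stacking energy for the
  pair step (36 entries obeying the reverse-complement symmetry
  E[XY/ZW] = E[WZ/YX]);
* **hairpin** of size s: tabulated initiation for s = 3..30;
* **internal/bulge loop** of total unpaired size s: one tabulated
  initiation for s = 1..30 (bulges and internals are not distinguished);
* loops beyond size 30: Jacobson–Stockmayer-style extrapolation
  `init(s) = init(30) + 1.1·ln(s/30)` kcal/mol, rounded to the nearest
  0.1 so every energy stays an exact rational;
* **terminal penalty** (0.5 kcal/mol) for each AU/GU helix end, charged
  once per adjacent loop side (a lone AU pair between two loops is
  charged twice, as in standard nearest-neighbor accounting);
* **exterior loop**: free;
* **multiloop** (three or more radiating helices):
  `a + b·(unpaired nucleotides) + c·(branches)`, the closing helix
  counted as a branch.

Omitted relative to full Turner-style models: dangles, coaxial stacking,
multiloop single-strand stacking, sequence-dependent loop bonuses and
tabulated small internal loops.  The reduction keeps the energy an exact
affine function `E = w + a·x + b·y + c·z` of the branching parameters,
which is the property the whole parametric analysis rests on; the price
is that absolute energies are not comparable to any published folding
tool.  Default tables (`branchfold/data/default_tables.json`) use
realistic stacking and loop magnitudes in units of 0.1 kcal/mol.

The historical branching-parameter sets are available as constants:
T89 = (4.6, 0.4, 0.1), T99 = (3.4, 0, 0.4), T04 = (9.3, 0, −0.6) kcal/mol.

## Exact arithmetic

Every energy, accuracy, bound and coordinate is a `fractions.Fraction`.
Inside the dynamic programs all atoms are scaled by the least common
denominator to plain integers.  Polyhedral questions are phrased so that
each linear program has at most six rows (Farkas/membership systems over
nonnegative multipliers, or the dual of a 3–4-variable program) and are
solved by a dense two-phase exact simplex with Bland's rule; every
certificate that a caller relies on (interior points, separating
functionals) is re-verified by direct substitution.  A floating-point
convex hull (qhull) is used only as a conservative pre-screen when
pruning candidate points: a point is discarded only if it sits at least
0.49 lattice units inside the float hull of integer-valued candidates,
many orders of magnitude beyond double-precision error at these
coordinate magnitudes (|x|≤8, |y|≤120, |z|≤24, |w|≤3000 deci-kcal).
Final hull membership is always certified exactly.

## Folding and co-optimal enumeration

MFE folding is a standard O(n³)-style recursion with separate matrices
for closed substructures (V), multiloop segments with at least one and at
least two branches (WM, WM2) and the exterior prefix (W); internal loops
are scanned without a size cap so the DP agrees exactly with brute-force
enumeration of all structures.  Traceback enumerates *all* co-optimal
structures through an unambiguous decomposition, deduplicated and
returned in lexicographic dot-bracket order, truncated at a cap
(default 100) with an explicit flag.  Exhaustive enumeration of the full
structure space is available as a test oracle and refuses sequences
longer than 45 nt without an override.

## Branching polytopes

For each (x, y, z) class only the minimum and maximum achievable w can be
extreme, so both construction strategies collect a per-(x,y,z) table of
w-extremes with realizing structures:

* **enumeration** (default up to 40 nt and ≤ 150 000 structures): iterate
  every structure;
* **dynamic program** (longer sequences): the folding recursion run over
  tables of per-(x,y,z) w-extremes, combined by Minkowski sums; cells are
  pruned by exact midpoint domination plus the float-envelope screen
  above, deleting an entry only when both its minimum-w and maximum-w
  points are provably interior.  Realizing structures for hull vertices
  are recovered by tracing minimum-w (or maximum-w) decomposition chains,
  which is complete for hull vertices because a vertex supported by a
  functional with positive (negative) w-weight decomposes into cell-wise
  w-minimal (w-maximal) parts.

Candidates are certified as hull vertices by exact convex-combination
membership tests against the surviving candidate set.  The lower hull
(w-coefficient fixed at +1) keeps exactly the vertices optimal for some
(a, b, c); a vertex set of affine dimension < 4 is flagged
lower-dimensional, and facet enumeration (diagnostics) is available for
full-dimensional polytopes with at most 40 vertices.

## Parameter regions

The region of lower-hull vertex v is
`{(a,b,c) : a·Δx + b·Δy + c·Δz ≤ Δw for every other lower vertex u}`,
redundancy-reduced by exact LP.  Region structures are all structures
attaining the vertex signature (from the enumeration table, or by
co-optimal folding at an exact interior witness), capped with a flag;
region accuracy is the mean F1 against the reference over the stored
structures, so a truncated structure list marks the accuracy as a
truncated mean.

**Emptiness semantics.**  "Nonempty" means full-dimensional interior by
default.  Regions meeting only in measure-zero faces correspond to
parameter ties, and tie points are not robust to the one-decimal
precision at which branching parameters are conventionally specified;
closed semantics remain available behind a flag.  Boundary ownership is
deliberately left undefined: closed containment queries may report a
boundary point in several regions, strict containment in at most one.

**Representative points.**  Bounded regions report the centroid of their
vertices; unbounded regions the vertex centroid stepped one unit along
the summed primitive recession direction (the construction used for
reporting an interior point of an unbounded optimal region), with an LP
interior point as fallback whenever the constructed point is not strictly
interior (e.g. regions without vertices).  Rounding to one decimal uses
ties-away-from-zero — the common convention of thermodynamic parameter
files; the membership of the rounded point in its region is reported,
never assumed.

## Branch-and-bound

Regions of each sequence are sorted by decreasing accuracy (ties by
construction index); U_i is the best accuracy of sequence i.  The search
maintains an incumbent lower bound L (initially L0, default 0) on the
best average accuracy and proceeds by merges along a balanced binary tree
(or a linear chain):

* `Max_k(Reg(i,j))` — the best accuracy k can attain inside Reg(i,j) — is
  found by scanning k's ordered regions for the first nonempty pairwise
  intersection; sortedness makes the first hit the exact maximum.
* Pre-filter: Reg(i,j) is kept only if
  `Acc_i(Reg(i,j)) + Σ_{k≠i} Max_k(Reg(i,j)) ≥ N·L`; regions whose Max
  entry is infeasible for some k can never complete a combination and are
  always dropped.
* Merge-time test: a candidate combination over sequences I survives only
  if `Σ_{i∈I} Acc_i + Σ_{j∉I} min_{i∈I} Max_j(Reg(i,k_i)) ≥ N·L` (U_j
  replaces the Max bounds when the table is disabled; both modes are kept
  for A/B soundness testing).  Candidates are processed in decreasing
  optimistic-bound order with lexicographic tie-breaks, so the first
  failed test removes all remaining candidates.
* At the root, every surviving nonempty intersection updates L with its
  exact average accuracy, immediately sharpening later tests.  The first
  candidate attaining the final L (in the deterministic processing order)
  is the reported incumbent; all root combinations computed within a
  window (default 0.02) of the final L are additionally reported as
  near-optimal.  This list is best-effort: combinations pruned by bound
  before being computed cannot appear in it.
* For merges spanning at least ten sequences (configurable), all cross
  pairwise intersections are checked first, and any candidate containing
  an empty pair is discarded without a full emptiness test (an empty pair
  implies an empty combination; the converse is false, so survivors are
  still tested).  Independently of that threshold, pairwise answers
  already memoized by the Max-bound scans are consulted for free before
  any new LP is solved; this is pure memoization and does not change
  which combinations survive.

The exhaustive oracle enumerates combinations depth-first (sequences in
increasing region count), skipping branches whose partial intersection is
empty — sound because extensions of an empty intersection are empty — and
refuses instances whose product of region counts exceeds a guard
(default 10⁶, configurable).

## The fixture generator

Toy families emulate the two branching configurations of interest: a
hairpin (no multiloop), a 3-branch "Y" (closing stem plus two arms, the
5S rRNA configuration) and a 4-branch cloverleaf (three arms, the tRNA
configuration).  Helices are perfect Watson–Crick runs with an *exact*
GC composition per helix (a binomial draw occasionally produces an all-AU
stem that misfolds); loops and junction gaps are adenosine runs; arms
within one fixture are forced to differ (identical arms zip with each
other instead of branching).  Seeded point mutations resample unpaired
bases freely and paired positions jointly to another canonical pair, so
references always survive noncanonical-pair cleaning unchanged and keep
their topology.  Family generation draws arm lengths, loop sizes and GC
fractions (0.25–0.9) per member, spreading GC content and attainable
accuracy.

With helices of length ≥ 4 and no mutations the reference is, for the
seeds exercised in the tests, the unique MFE structure at T99-like
parameters, giving optimizer tests attainable accuracy-1 optima.  This is
a designed tendency, not a guarantee: residual cross-arm complementarity
can occasionally produce a lower-energy alternative for particular seeds.

What the toys do *not* emulate: real tRNA/5S lengths (≈76/120 nt),
modified bases, covariation, biological loop sequences, or Turner-scale
energetics.  In particular the optimizer study set uses 2-bp helices,
which are thermodynamically marginal at the historical parameter sets —
on these fixtures T89/T99/T04 mostly predict open or sparse structures,
and the optimal toy parameters sit at strongly negative branch penalties.
Passing tests therefore demonstrate the exactness of the machinery
(polytopes, subdivisions, search), and reproduce the cross-family
parameter tension qualitatively, but say nothing quantitative about
accuracy on real RNA families.

## Problem sizes

Chosen so that every brute-force oracle remains exact and the whole suite
runs comfortably on one CPU:

* four enumerable oracle fixtures of 14–25 nt (44 to ≈15 000 structures)
  for the folding, polytope and subdivision oracles;
* an optimizer pool of four Y3 (18–24 nt) and four cloverleaf (26–32 nt)
  fixtures, mutation rate 0.12, with 4–19 regions per sequence;
* twenty seeded optimizer instances covering N = 2..8 sequences, each
  solved exhaustively and by branch-and-bound under both merge plans and
  both bound modes.

## Known limitations

* The reduced model's absolute energies match no published parameter set;
  only the parametric structure is faithful.
* Polytope construction is exponential-ish in practice above ~60 nt with
  this pure-Python implementation; real 5S-length sequences are out of
  reach (and out of scope).
* Co-optimal structure lists, and hence region accuracies, are truncated
  at a cap (default 100) with a flag; regions with astronomically many
  co-optimal structures report a truncated mean.
* The near-optimal list reports only combinations the search actually
  computed at the root.
* `exhaustive_search` cost is driven by the number of nonempty partial
  combinations (cells of the common fan refinement), not the nominal
  product guard.
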