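"""Deterministic toy sequence families with known reference structures.

The three shapes emulate the branching configurations that matter for
multiloop parameter analysis: a plain hairpin (no multiloop), a 3-branch
"Y" junction (the 5S rRNA configuration: closing stem plus two arms), and
a 4-branch cloverleaf (the tRNA configuration: closing stem plus three
arms).  Helices are perfect Watson-Crick runs whose GC fraction is drawn
per fixture, loops are adenosine runs, so that for unmutated fixtures with
reasonably long helices the reference is the unique MFE structure under
standard-like branching parameters — giving optimizer tests attainable
accuracy-1 optima.  Seeded point mutations resample unpaired bases freely
and paired positions jointly (to another canonical pair), so the reference
always survives :func:`branchfold.structures.clean_reference` unchanged.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .structures import RnaSequence, SecondaryStructure, write_fasta, write_structure

__all__ = ["FixtureSpec", "generate", "generate_family"]

MAX_FIXTURE_NT = 100

_SHAPES = ("hairpin", "Y3", "cloverleaf4")
#: Number of helices per shape (closing stem first).
_N_HELICES = {"hairpin": 1, "Y3": 3, "cloverleaf4": 4}


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one toy fixture.

    ``helix_lengths``: closing stem first, then one entry per arm (a single
    entry for hairpins).  ``loop_sizes``: the hairpin loop of each arm (>= 3),
    followed by the unpaired runs of the junction: before the first arm,
    between consecutive arms, and after the last arm (hairpins use a single
    loop entry).  ``mutation_rate`` is the per-position probability of a
    seeded point mutation.
    """

    shape: str
    helix_lengths: tuple = (4, 4, 4, 4)
    loop_sizes: tuple = (3, 3, 3, 1, 1, 1, 1)
    seed: int = 0
    mutation_rate: float = 0.0
    gc_fraction: float = 0.7
    tail: tuple = (1, 1)  # unpaired 5'/3' exterior nucleotides

    def __post_init__(self):
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}; choose from {_SHAPES}")
        n_helix = _N_HELICES[self.shape]
        n_arms = n_helix if self.shape == "hairpin" else n_helix - 1
        if len(self.helix_lengths) != n_helix:
            raise ValueError(
                f"{self.shape} needs {n_helix} helix lengths, got {self.helix_lengths}")
        want_loops = 1 if self.shape == "hairpin" else n_arms + (n_arms + 1)
        if len(self.loop_sizes) != want_loops:
            raise ValueError(
                f"{self.shape} needs {want_loops} loop sizes "
                f"(arm hairpin loops, then junction gaps), got {self.loop_sizes}")
        if any(h < 1 for h in self.helix_lengths):
            raise ValueError("helix lengths must be positive")
        hairpin_loops = self.loop_sizes[:1] if self.shape == "hairpin" \
            else self.loop_sizes[:n_arms]
        if any(l < 3 for l in hairpin_loops):
            raise ValueError("hairpin loops need >= 3 unpaired nucleotides")
        if any(l < 0 for l in self.loop_sizes) or any(t < 0 for t in self.tail):
            raise ValueError("loop sizes and tails must be nonnegative")
        if not (0 <= self.mutation_rate <= 1):
            raise ValueError("mutation_rate must lie in [0, 1]")


_PAIRS_BY_GC = {True: [("G", "C"), ("C", "G")], False: [("A", "U"), ("U", "A")]}
_CANONICAL_CHOICES = [("G", "C"), ("C", "G"), ("A", "U"), ("U", "A"), ("G", "U"), ("U", "G")]


def _helix_pairs(rng: random.Random, length: int, gc_fraction: float) -> list:
    """Pair types for one helix, 5' side outermost first.

    The GC composition is exact (round(length * gc_fraction) strong pairs,
    shuffled), so every helix of a fixture has the intended stability
    rather than a binomial draw that occasionally yields an all-AU stem.
    """
    n_gc = round(length * gc_fraction)
    kinds = [True] * n_gc + [False] * (length - n_gc)
    rng.shuffle(kinds)
    return [rng.choice(_PAIRS_BY_GC[k]) for k in kinds]


def generate(spec: FixtureSpec):
    """(sequence, reference structure) for ``spec``; deterministic in seed."""
    rng = random.Random(spec.seed)
    shape = spec.shape
    n_arms = 1 if shape == "hairpin" else _N_HELICES[shape] - 1

    # Lay out the molecule left to right, recording paired position indices.
    seq: list = []
    pairs: list = []  # (left_pos, right_pos), 0-based; bases filled later

    def add_loop(size: int) -> None:
        seq.extend("A" * size)

    used_arms: list = []

    def add_arm(length: int, loop: int) -> None:
        helix = _helix_pairs(rng, length, spec.gc_fraction)
        # identical arms would zip with each other instead of branching
        for _ in range(20):
            if helix not in used_arms:
                break
            helix = _helix_pairs(rng, length, spec.gc_fraction)
        used_arms.append(helix)
        left = []
        for five, three in helix:
            left.append((len(seq), three))
            seq.append(five)
        add_loop(loop)
        for pos, three in reversed(left):
            pairs.append((pos, len(seq)))
            seq.append(three)

    add_loop(spec.tail[0])
    if shape == "hairpin":
        add_arm(spec.helix_lengths[0], spec.loop_sizes[0])
    else:
        stem = _helix_pairs(rng, spec.helix_lengths[0], spec.gc_fraction)
        left = []
        for five, three in stem:
            left.append((len(seq), three))
            seq.append(five)
        arm_loops = spec.loop_sizes[:n_arms]
        gaps = spec.loop_sizes[n_arms:]
        add_loop(gaps[0])
        for arm in range(n_arms):
            add_arm(spec.helix_lengths[arm + 1], arm_loops[arm])
            add_loop(gaps[arm + 1])
        for pos, three in reversed(left):
            pairs.append((pos, len(seq)))
            seq.append(three)
    add_loop(spec.tail[1])

    if len(seq) > MAX_FIXTURE_NT:
        raise ValueError(f"fixture of {len(seq)} nt exceeds {MAX_FIXTURE_NT} nt")

    # seeded point mutations: joint resampling for paired positions,
    # free resampling for unpaired ones (reference pairs stay canonical)
    paired = {}
    for i, j in pairs:
        paired[i] = j
        paired[j] = i
    for pos in range(len(seq)):
        if rng.random() >= spec.mutation_rate:
            continue
        if pos in paired:
            mate = paired[pos]
            if pos < mate:
                five, three = rng.choice(_CANONICAL_CHOICES)
                seq[pos], seq[mate] = five, three
        else:
            seq[pos] = rng.choice("ACGU")

    name = f"{shape}-s{spec.seed}"
    sequence = RnaSequence(id=name, residues="".join(seq))
    reference = SecondaryStructure(
        length=len(seq),
        pairs=frozenset((i + 1, j + 1) for i, j in pairs),
    )
    return sequence, reference


def generate_family(spec: FixtureSpec, n: int, seed: int | None = None) -> list:
    """``n`` fixtures with seeded diversity in arm lengths, loop sizes and
    GC composition (accuracy and GC content spread is the design goal)."""
    if n < 1:
        raise ValueError("family size must be >= 1")
    base_seed = spec.seed if seed is None else seed
    master = random.Random(base_seed)
    out = []
    n_helix = _N_HELICES[spec.shape]
    n_arms = 1 if spec.shape == "hairpin" else n_helix - 1
    for k in range(n):
        helices = tuple(max(2, h + master.choice((-1, 0, 0, 1)))
                        for h in spec.helix_lengths)
        if spec.shape == "hairpin":
            loops = (max(3, spec.loop_sizes[0] + master.choice((-1, 0, 1))),)
        else:
            arm_loops = tuple(max(3, l + master.choice((-1, 0, 1)))
                              for l in spec.loop_sizes[:n_arms])
            gaps = tuple(max(0, g + master.choice((-1, 0, 1)))
                         for g in spec.loop_sizes[n_arms:])
            loops = arm_loops + gaps
        member = FixtureSpec(
            shape=spec.shape,
            helix_lengths=helices,
            loop_sizes=loops,
            seed=master.randrange(2 ** 30),
            mutation_rate=spec.mutation_rate,
            gc_fraction=0.25 + 0.65 * master.random(),
            tail=spec.tail,
        )
        out.append(generate(member))
    return out


def write_family(pairs, out_dir) -> None:
    """FASTA + dot-bracket files for a generated family."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_fasta(out_dir / "sequences.fasta", [s for s, _ in pairs])
    for seq, ref in pairs:
        write_structure(out_dir / f"{seq.id}.db", ref, "dotbracket", sequence=seq)
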