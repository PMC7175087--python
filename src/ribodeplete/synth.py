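"""Synthetic fixtures: rRNA-like alignments and read sets with known truth.

The alignment generator emulates the conservation structure the probe
designer exploits: an ancestral random sequence with fully conserved,
gap-free blocks (where all species are identical) separated by divergent
spacers in which each species independently substitutes bases and acquires
single-column gaps at configurable rates.  The generator returns the true
block coordinates so convergence of the optimizer onto conserved regions can
be measured against ground truth.

The read generator emulates depleted/undepleted sequencing samples: reads are
drawn from annotated regions by per-class weight (e.g. an rRNA mass fraction
of 0.95) with uniform placement inside the chosen region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment
from .errors import RecipeError
from .seqqc import ReadSet, RegionSet


@dataclass(frozen=True)
class AlignmentRecipe:
    """Recipe for a synthetic multi-species rRNA alignment."""

    n_species: int = 8
    total_length: int = 1500
    conserved_blocks: tuple[tuple[int, int], ...] = ()  # (start, length)
    divergence: float = 0.3
    gap_probability: float = 0.05
    seed: int | None = None

    def __post_init__(self):
        if self.n_species < 1 or self.total_length < 1:
            raise RecipeError("n_species and total_length must be >= 1")
        if not (0 <= self.divergence <= 1 and 0 <= self.gap_probability <= 1):
            raise RecipeError("probabilities must lie in [0, 1]")
        blocks = sorted(self.conserved_blocks)
        prev_end = 0
        for start, length in blocks:
            if length < 1 or start < 0 or start + length > self.total_length:
                raise RecipeError(f"block ({start}, {length}) out of bounds")
            if start < prev_end:
                raise RecipeError("conserved blocks overlap")
            prev_end = start + length

    @staticmethod
    def evenly_spaced(n_blocks: int = 10, block_length: int = 40,
                      total_length: int = 1500, **kwargs) -> "AlignmentRecipe":
        """Blocks of equal length spread evenly across the alignment."""
        if n_blocks * block_length > total_length:
            raise RecipeError("blocks do not fit in total_length")
        gap = (total_length - n_blocks * block_length) // (n_blocks + 1)
        blocks = tuple(
            (gap + i * (block_length + gap), block_length) for i in range(n_blocks)
        )
        return AlignmentRecipe(total_length=total_length,
                               conserved_blocks=blocks, **kwargs)


def make_alignment(r: AlignmentRecipe) -> tuple[Alignment, list[tuple[int, int]]]:
    """Generate the alignment plus the truth record of block coordinates."""
    rng = np.random.default_rng(r.seed)
    ancestral = rng.integers(0, 4, r.total_length).astype(np.int8)
    in_block = np.zeros(r.total_length, dtype=bool)
    for start, length in r.conserved_blocks:
        in_block[start:start + length] = True
    rows = []
    alphabet = "ACGU-"
    for _ in range(r.n_species):
        seq = ancestral.copy()
        outside = ~in_block
        n_out = int(outside.sum())
        if n_out:
            sub = rng.random(n_out) < r.divergence
            # substitute with one of the three alternative bases, uniformly
            shifts = rng.integers(1, 4, n_out)
            new = (ancestral[outside] + shifts) % 4
            vals = np.where(sub, new, ancestral[outside])
            gapped = rng.random(n_out) < r.gap_probability
            vals = np.where(gapped, 4, vals).astype(np.int8)
            seq[outside] = vals
        rows.append("".join(alphabet[c] for c in seq))
    species = [f"sp{i + 1}" for i in range(r.n_species)]
    return Alignment(species, rows), sorted(r.conserved_blocks)


@dataclass(frozen=True)
class ReadRecipe:
    """Recipe for a synthetic mapped-read set over annotated regions."""

    regions: RegionSet
    class_weights: dict[str, float] = field(default_factory=lambda: {"rRNA": 0.95,
                                                                     "CDS": 0.05})
    n_reads: int = 100_000
    read_length: int = 50
    seed: int | None = None

    def __post_init__(self):
        if self.n_reads < 1 or self.read_length < 1:
            raise RecipeError("n_reads and read_length must be >= 1")
        if any(w < 0 for w in self.class_weights.values()):
            raise RecipeError("class weights must be >= 0")
        if sum(self.class_weights.values()) <= 0:
            raise RecipeError("class weights must not all be zero")


def make_reads(r: ReadRecipe) -> ReadSet:
    """Draw reads class-by-weight, region uniformly within class, start uniform.

    Regions must be at least ``read_length`` long so every read fits inside
    its source region.
    """
    df = r.regions.regions
    classes = [c for c in r.class_weights if (df["cls"] == c).any()
               and r.class_weights[c] > 0]
    if not classes:
        raise RecipeError("no region matches any positively weighted class")
    lengths = df["end"] - df["start"]
    if (lengths[df["cls"].isin(classes)] < r.read_length).any():
        raise RecipeError("a sampled region is shorter than read_length")
    weights = np.array([r.class_weights[c] for c in classes], dtype=float)
    weights /= weights.sum()
    rng = np.random.default_rng(r.seed)
    cls_idx = rng.choice(len(classes), size=r.n_reads, p=weights)
    region_rows = {c: df.index[df["cls"] == c].to_numpy() for c in classes}
    refs = np.empty(r.n_reads, dtype=object)
    starts = np.empty(r.n_reads, dtype=np.int64)
    for i, ci in enumerate(cls_idx):
        rows = region_rows[classes[ci]]
        row = df.loc[rows[rng.integers(rows.size)]]
        s = row["start"] + rng.integers(row["end"] - row["start"] - r.read_length + 1)
        refs[i] = row["reference"]
        starts[i] = s
    return ReadSet.from_arrays(refs, starts, starts + r.read_length)
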