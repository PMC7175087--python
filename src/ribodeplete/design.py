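"""Stochastic optimization of depletion oligos on an rRNA alignment.

The search runs in sense space on the admissible (gap-free) columns of the
alignment.  A population of candidate oligos is initialized at random
positions with random lengths; each candidate's sequence is drawn per column
from the distinct bases present among the species, so every position matches
at least one target rRNA.  Each optimization cycle every candidate is mutated
``mutants_per_round`` times — moving, shrinking, or extending the window by
1-4 columns, or swapping one position to a different species' base — and a
successor is chosen probabilistically from the mutants plus the incumbent:
candidates with a *defined* minimum Tm are always preferred over undefined
ones, and among defined ones the pick probability is proportional to a normal
density centered on the target Tm (default 62.5 °C, σ = 2 °C).  The score of
a candidate is the minimum over species of its predicted Tm, i.e. its weakest
predicted binding.

After the configured number of cycles a final nonoverlapping probe set is
chosen by a greedy rule that automates the published hand-selection criteria:
drop candidates whose Tm is not above the floor (50 °C) for a majority of
species, rank by closeness of min-Tm to the target breaking ties toward
shorter oligos, and accept greedily subject to nonoverlap and minimum
spacing.  Probes are exported as antisense DNA (reverse complement of the
sense sequence) with a 5'-biotin annotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import BASES, Alignment, GapMask, decode_seq, encode_seq, gap_mask
from .errors import InfeasibleDesignError, InputError, ParameterError
from .thermo import NNParameterTable, ThermoConditions, ThermoEngine, TmProfile

_DNA_FROM_RNA = {"A": "A", "C": "C", "G": "G", "U": "T"}
_DNA_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def antisense_dna(sense_rna: str) -> str:
    """Reverse complement of an RNA-sense sequence, in the DNA alphabet."""
    dna = "".join(_DNA_FROM_RNA[c] for c in sense_rna.upper().replace("T", "U"))
    return "".join(_DNA_COMP[c] for c in reversed(dna))


@dataclass(frozen=True)
class OptimizerConfig:
    """All constants of the design algorithm.

    Defaults follow the published run for a 16S-scale target: 500 candidates
    of 15-24 nt, 100 cycles of 25 mutants each, selection centered at 62.5 °C
    with σ = 2 °C, move/shrink/extend steps of 1-4 nt.  The 23S profile
    doubles the population to 1000.  Length bounds during optimization
    ([12, 45] nt) are wider than the initialization range.
    """

    n_init: int = 500
    init_len: tuple[int, int] = (15, 24)
    cycles: int = 100
    mutants_per_round: int = 25
    target_tm: float = 62.5
    sigma: float = 2.0
    step_max: int = 4
    len_bounds: tuple[int, int] = (12, 45)
    seed: int | None = None
    max_mutation_retries: int = 50

    def __post_init__(self):
        if min(self.n_init, self.mutants_per_round, self.step_max) < 1:
            raise ParameterError("counts must be >= 1")
        if self.cycles < 0:
            raise ParameterError("cycles must be >= 0")
        if self.sigma <= 0:
            raise ParameterError("sigma must be > 0")
        lo, hi = self.init_len
        blo, bhi = self.len_bounds
        if not (blo <= lo <= hi <= bhi):
            raise ParameterError("init_len must lie within len_bounds")


#: Preset population sizes for the standard rRNA targets.
PROFILES = {
    "16S": OptimizerConfig(n_init=500),
    "23S": OptimizerConfig(n_init=1000),
    "5S": OptimizerConfig(n_init=500),
}


@dataclass
class OligoCandidate:
    """A sense-space oligo: an alignment window plus its sequence.

    ``codes`` is the int8-encoded RNA-sense sequence of the window.  The Tm
    profile is attached lazily (``min_tm`` NaN means undefined once set).
    """

    id: int
    start: int
    codes: np.ndarray
    min_tm: float = math.nan
    scored: bool = False
    profile: TmProfile | None = None

    @property
    def length(self) -> int:
        return self.codes.size

    @property
    def window(self) -> tuple[int, int]:
        return (self.start, self.start + self.length)

    @property
    def sense_seq(self) -> str:
        return decode_seq(self.codes)


@dataclass
class Trajectory:
    """Per-cycle optimization statistics.

    ``mean_min_tm`` averages the minimum-Tm score over candidates whose Tm is
    defined; ``n_undefined`` counts the rest.  When at least one cycle is run
    the first record (cycle 0) is the initialized population, so the decline
    of the undefined count is visible from its starting value.  ``snapshots``
    maps requested cycle indices to per-candidate (start, length, min_tm)
    records.
    """

    cycles: list[int] = field(default_factory=list)
    mean_min_tm: list[float] = field(default_factory=list)
    n_undefined: list[int] = field(default_factory=list)
    snapshots: dict[int, list[tuple[int, int, float]]] = field(default_factory=dict)

    def record(self, cycle: int, cands: list[OligoCandidate]) -> None:
        mtms = np.array([c.min_tm for c in cands])
        defined = np.isfinite(mtms)
        self.cycles.append(cycle)
        self.mean_min_tm.append(float(mtms[defined].mean()) if defined.any() else math.nan)
        self.n_undefined.append(int((~defined).sum()))

    def snapshot(self, cycle: int, cands: list[OligoCandidate]) -> None:
        self.snapshots[cycle] = [(c.start, c.length, c.min_tm) for c in cands]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cycle": self.cycles, "mean_min_tm": self.mean_min_tm,
             "n_undefined": self.n_undefined}
        )


class _ColumnBases:
    """Distinct bases present among species at each admissible column."""

    def __init__(self, a: Alignment, mask: GapMask):
        self.options: list[np.ndarray | None] = [None] * a.length
        for c in np.flatnonzero(mask.admissible):
            self.options[c] = np.unique(a.codes[:, c]).astype(np.int8)

    def sample(self, cols: range | np.ndarray, rng) -> np.ndarray:
        out = np.empty(len(cols), dtype=np.int8)
        for i, c in enumerate(cols):
            opts = self.options[c]
            out[i] = opts[rng.integers(opts.size)] if opts.size > 1 else opts[0]
        return out


def initialize_candidates(a: Alignment, mask: GapMask, cfg: OptimizerConfig,
                          rng: np.random.Generator) -> list[OligoCandidate]:
    """Draw the initial population: uniform lengths, uniform feasible placement.

    A length is feasible if at least one admissible run can host it; the
    placement is uniform over all feasible (run, start) pairs for the drawn
    length.  Per-position bases are drawn uniformly from the distinct bases
    present among species at that column.
    """
    widest = max((we - ws for ws, we in mask.windows), default=0)
    lengths = [l for l in range(cfg.init_len[0], cfg.init_len[1] + 1) if l <= widest]
    if not lengths:
        raise InfeasibleDesignError(
            f"no admissible run can host an oligo of length {cfg.init_len[0]} "
            f"(widest run: {widest} columns)"
        )
    colbases = _ColumnBases(a, mask)
    # cumulative feasible start counts per run, per length
    out = []
    for i in range(cfg.n_init):
        length = lengths[rng.integers(len(lengths))]
        counts = np.array([max(0, (we - ws) - length + 1) for ws, we in mask.windows])
        total = counts.sum()
        pick = rng.integers(total)
        run = int(np.searchsorted(np.cumsum(counts), pick, side="right"))
        start = mask.windows[run][0] + int(pick - counts[:run].sum())
        codes = colbases.sample(range(start, start + length), rng)
        out.append(OligoCandidate(id=i, start=start, codes=codes))
    return out


def _containing_run(mask: GapMask, start: int, end: int) -> tuple[int, int]:
    run = mask.window_containing(start, end)
    if run is None:
        raise InputError(f"candidate window [{start}, {end}) is not admissible")
    return run


def mutate(c: OligoCandidate, a: Alignment, mask: GapMask, cfg: OptimizerConfig,
           rng: np.random.Generator,
           colbases: _ColumnBases | None = None) -> OligoCandidate:
    """Apply exactly one mutation operator; resample infeasible proposals.

    Operators (uniform choice): move the window 1-4 columns left/right;
    shrink 1-4 columns off one end; extend 1-4 columns on one end, drawing
    bases for new columns by the initialization rule; swap one position to a
    *different* base carried by some species there.  Proposals that would
    cross a masked column, leave the length bounds, or swap at a fully
    conserved column are rejected and resampled up to a bounded retry count,
    after which the parent is duplicated.
    """
    if colbases is None:
        colbases = _ColumnBases(a, mask)
    ws, we = _containing_run(mask, c.start, c.start + c.length)
    lo, hi = cfg.len_bounds
    for _ in range(cfg.max_mutation_retries):
        op = rng.integers(4)
        k = int(rng.integers(1, cfg.step_max + 1))
        if op == 0:  # move
            delta = k if rng.integers(2) else -k
            ns = c.start + delta
            ne = ns + c.length
            if ns < ws or ne > we:
                continue
            codes = np.empty(c.length, dtype=np.int8)
            if delta > 0:
                codes[:c.length - delta] = c.codes[delta:]
                codes[c.length - delta:] = colbases.sample(range(ne - delta, ne), rng)
            else:
                codes[-delta:] = c.codes[:c.length + delta]
                codes[:-delta] = colbases.sample(range(ns, ns - delta), rng)
            return OligoCandidate(id=c.id, start=ns, codes=codes)
        if op == 1:  # shrink
            if c.length - k < lo:
                continue
            if rng.integers(2):  # 5' end
                return OligoCandidate(id=c.id, start=c.start + k, codes=c.codes[k:].copy())
            return OligoCandidate(id=c.id, start=c.start, codes=c.codes[:-k].copy())
        if op == 2:  # extend
            if c.length + k > hi:
                continue
            if rng.integers(2):  # 5' end
                ns = c.start - k
                if ns < ws:
                    continue
                new = colbases.sample(range(ns, c.start), rng)
                return OligoCandidate(id=c.id, start=ns,
                                      codes=np.concatenate([new, c.codes]))
            ne = c.start + c.length + k
            if ne > we:
                continue
            new = colbases.sample(range(ne - k, ne), rng)
            return OligoCandidate(id=c.id, start=c.start,
                                  codes=np.concatenate([c.codes, new]))
        # swap: pick a position whose column offers an alternative base
        pos = int(rng.integers(c.length))
        opts = colbases.options[c.start + pos]
        if opts.size < 2:
            continue
        alts = opts[opts != c.codes[pos]]
        codes = c.codes.copy()
        codes[pos] = alts[rng.integers(alts.size)]
        return OligoCandidate(id=c.id, start=c.start, codes=codes)
    # retries exhausted: keep the incumbent for this slot
    return OligoCandidate(id=c.id, start=c.start, codes=c.codes.copy(),
                          min_tm=c.min_tm, scored=c.scored)


def _score(c: OligoCandidate, engine: ThermoEngine) -> float:
    if not c.scored:
        c.min_tm = engine.min_tm(c.start, c.codes.astype(np.intp))
        c.scored = True
    return c.min_tm


def select_next(parent: OligoCandidate, mutants: list[OligoCandidate],
                cfg: OptimizerConfig, rng: np.random.Generator,
                engine: ThermoEngine) -> OligoCandidate:
    """Choose the next incumbent from mutants plus the parent.

    Candidates with a defined minimum Tm are always preferred; among them the
    pick probability is proportional to the normal density
    N(target_tm, sigma²) at their min-Tm, computed in log space.  If the
    whole pool is undefined the parent is returned unchanged.
    """
    if not mutants:
        raise InputError("mutant pool is empty")
    pool = mutants + [parent]
    scores = np.array([_score(m, engine) for m in pool])
    defined = np.flatnonzero(np.isfinite(scores))
    if defined.size == 0:
        return parent
    logw = -((scores[defined] - cfg.target_tm) ** 2) / (2.0 * cfg.sigma ** 2)
    w = np.exp(logw - logw.max())
    pick = defined[rng.choice(defined.size, p=w / w.sum())]
    return pool[int(pick)]


def optimize(a: Alignment, mask: GapMask | None = None,
             cfg: OptimizerConfig | None = None,
             table: NNParameterTable | None = None,
             cond: ThermoConditions | None = None,
             snapshot_cycles: tuple[int, ...] = ()) -> tuple[list[OligoCandidate], Trajectory]:
    """Run the full optimization; fully seeded and reproducible.

    Each cycle, every candidate independently generates ``mutants_per_round``
    mutants and is replaced by the probabilistic selection over mutants plus
    itself.  Returns the final population (with full Tm profiles attached)
    and the per-cycle trajectory.
    """
    mask = mask or gap_mask(a)
    cfg = cfg or OptimizerConfig()
    rng = np.random.default_rng(cfg.seed)
    engine = ThermoEngine(a, table, cond)
    colbases = _ColumnBases(a, mask)
    cands = initialize_candidates(a, mask, cfg, rng)
    for c in cands:
        _score(c, engine)
    traj = Trajectory()
    if cfg.cycles > 0:
        traj.record(0, cands)  # baseline: the initialized population
    if 0 in snapshot_cycles:
        traj.snapshot(0, cands)
    for cycle in range(1, cfg.cycles + 1):
        for i, c in enumerate(cands):
            muts = [mutate(c, a, mask, cfg, rng, colbases)
                    for _ in range(cfg.mutants_per_round)]
            cands[i] = select_next(c, muts, cfg, rng, engine)
        traj.record(cycle, cands)
        if cycle in snapshot_cycles:
            traj.snapshot(cycle, cands)
    for c in cands:
        c.profile = engine.profile(c.start, c.codes.astype(np.intp))
    return cands, traj


# ---------------------------------------------------------------------------
# Final probe selection and export
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionRules:
    """Automated stand-in for the published hand-selection criteria."""

    n_target: int = 8
    tm_floor: float = 50.0
    majority_fraction: float = 0.5
    min_spacing: int = 0
    target_label: str = "16S"


@dataclass(frozen=True)
class Probe:
    id: int
    target: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    sense_seq: str
    antisense_dna: str
    per_species_tm: dict[str, float]
    min_tm: float
    modification: str = "5Biotin"


@dataclass(frozen=True)
class ProbeSet:
    probes: list[Probe]
    provenance: dict


def select_probes(candidates: list[OligoCandidate], cfg: OptimizerConfig,
                  rules: SelectionRules | None = None) -> ProbeSet:
    """Greedy selection of a final nonoverlapping probe set.

    Candidates with undefined profiles are excluded, then those whose Tm does
    not exceed ``tm_floor`` for strictly more than ``majority_fraction`` of
    species.  Survivors are ranked by |min_tm - target_tm| ascending, ties
    broken by shorter length then lower start, and accepted greedily subject
    to nonoverlap plus ``min_spacing`` columns from every accepted probe.
    """
    rules = rules or SelectionRules()
    pool = [c for c in candidates if c.profile is not None and c.profile.defined]
    kept = []
    for c in pool:
        n_ok = int(np.sum(c.profile.tm > rules.tm_floor))
        if n_ok > rules.majority_fraction * c.profile.tm.size:
            kept.append(c)
    kept.sort(key=lambda c: (abs(c.profile.min_tm - cfg.target_tm), c.length, c.start))
    accepted: list[OligoCandidate] = []
    for c in kept:
        s, e = c.window
        if all(e + rules.min_spacing <= a.start or
               a.start + a.length + rules.min_spacing <= s
               for a in accepted):
            accepted.append(c)
        if len(accepted) == rules.n_target:
            break
    accepted.sort(key=lambda c: c.start)
    probes = [
        Probe(
            id=i,
            target=rules.target_label,
            start=c.start + 1,
            end=c.start + c.length,
            sense_seq=c.sense_seq,
            antisense_dna=antisense_dna(c.sense_seq),
            per_species_tm=c.profile.per_species,
            min_tm=c.profile.min_tm,
        )
        for i, c in enumerate(accepted)
    ]
    prov = {"config": cfg, "seed": cfg.seed, "rules": rules}
    if len(probes) < rules.n_target:
        prov["warning"] = (
            f"only {len(probes)} of {rules.n_target} requested probes selectable"
        )
    return ProbeSet(probes=probes, provenance=prov)


def export_probes(ps: ProbeSet, tsv_path, fasta_path=None) -> None:
    """Write the probe table as TSV (1-based inclusive coords) and FASTA.

    The FASTA carries the physical antisense DNA sequences.  The TSV round
    trips losslessly through :func:`read_probe_export`.
    """
    tsv_path = Path(tsv_path)
    species = list(ps.probes[0].per_species_tm) if ps.probes else []
    with open(tsv_path, "w") as fh:
        fh.write(f"# seed={ps.provenance.get('seed')}\n")
        cols = ["id", "target", "start", "end", "antisense_dna", "sense_seq",
                "min_tm", "modification"] + [f"tm_{s}" for s in species]
        fh.write("\t".join(cols) + "\n")
        for p in ps.probes:
            row = [str(p.id), p.target, str(p.start), str(p.end),
                   p.antisense_dna, p.sense_seq, f"{p.min_tm:.2f}",
                   p.modification]
            row += [f"{p.per_species_tm[s]:.2f}" for s in species]
            fh.write("\t".join(row) + "\n")
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for p in ps.probes:
                fh.write(f">{p.target}_probe_{p.id} 5Biotin\n{p.antisense_dna}\n")


def read_probe_export(tsv_path) -> ProbeSet:
    """Read a probe TSV written by :func:`export_probes`."""
    tsv_path = Path(tsv_path)
    seed = None
    with open(tsv_path) as fh:
        first = fh.readline()
        if first.startswith("# seed="):
            raw = first.strip().split("=", 1)[1]
            seed = None if raw == "None" else int(raw)
    df = pd.read_csv(tsv_path, sep="\t", comment="#")
    species = [c[3:] for c in df.columns if c.startswith("tm_")]
    probes = [
        Probe(
            id=int(r["id"]), target=str(r["target"]), start=int(r["start"]),
            end=int(r["end"]), sense_seq=str(r["sense_seq"]),
            antisense_dna=str(r["antisense_dna"]),
            per_species_tm={s: float(r[f"tm_{s}"]) for s in species},
            min_tm=float(r["min_tm"]), modification=str(r["modification"]),
        )
        for _, r in df.iterrows()
    ]
    return ProbeSet(probes=probes, provenance={"seed": seed})


# ---------------------------------------------------------------------------
# Published-style probe table (vendored synthetic stand-in)
# ---------------------------------------------------------------------------

GRAM_NEGATIVE = ["Ec", "Pa", "Rp", "Cc"]
GRAM_POSITIVE = ["Bs", "Ms", "Mtb", "Sa"]
ORGANISMS = GRAM_NEGATIVE + GRAM_POSITIVE


def read_probe_table(path=None) -> pd.DataFrame:
    """Read a depletion-oligo catalog (the vendored synthetic table by default).

    Rows carry a scope: ``common`` oligos (16S/23S) apply to every organism,
    ``gram_negative``/``gram_positive`` 23S-end oligos to their group, and
    ``species`` 5S oligos to a single organism.
    """
    if path is None:
        with resources.as_file(
            resources.files("ribodeplete.data").joinpath("probe_catalog_synthetic.tsv")
        ) as p:
            return read_probe_table(p)
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"name", "target", "scope", "organisms", "sequence", "modification"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"probe table missing columns: {sorted(missing)}")
    df["length"] = df["sequence"].str.len()
    return df


def probe_table_stats(df: pd.DataFrame) -> pd.DataFrame:
    """Per-organism accounting of a probe catalog.

    Returns one row per organism with the total probe count, the number of
    shared (common) 16S/23S probes, the number of probes addressing the 23S
    (common plus Gram-group), and the mean length of the common probes.
    """
    rows = []
    for org in ORGANISMS:
        applies = df["organisms"].apply(
            lambda o: o == "all" or org in str(o).split(",")
        )
        sub = df[applies]
        common = sub[sub["scope"] == "common"]
        rows.append({
            "organism": org,
            "n_total": len(sub),
            "n_common": len(common),
            "n_23s": int((sub["target"] == "23S").sum()),
            "n_16s": int((sub["target"] == "16S").sum()),
            "n_5s": int((sub["target"] == "5S").sum()),
            "mean_common_length": float(common["length"].mean()),
        })
    return pd.DataFrame(rows).set_index("organism")
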