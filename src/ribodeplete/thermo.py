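"""Melting temperature of probe:rRNA heteroduplexes by nearest-neighbor sums.

The physical duplex is the biotinylated antisense DNA oligo hybridized to an
rRNA.  Internally the package works in *sense* space: a candidate carries the
RNA-sense sequence of its alignment window, and the DNA probe is its reverse
complement.  At position ``i`` the probe base pairs with the target rRNA base;
the pairing is Watson-Crick exactly when the sense base equals the target
base, and a mismatch otherwise.

Tm is predicted as::

    Tm(K) = 1000 * dH / (dS + dS_salt + R * ln(C_eff))

with ``dH`` (kcal/mol) and ``dS`` (cal/mol/K) summed over the duplex
initiation term and every dinucleotide stack, ``R = 1.987`` cal/(mol K),
``C_eff = [probe] - [target]/2`` and the SantaLucia (1998) entropic salt
correction ``dS_salt = 0.368 * (N - 1) * ln[Na+]``.  Perfect-match stacks use
the Sugimoto (1995) RNA:DNA hybrid set; stacks containing one mismatched
pairing fall back to the DNA internal-mismatch set, the de-facto
approximation for hybrids.  A stack with no tabulated parameters — notably
two sequential mismatches — makes the whole Tm *undefined* (returned as
NaN), not merely low; the optimizer treats such candidates as strictly worse
than any defined one.

Parameter tables are shipped as TSV data files with provenance labels and
loaded at first use; nothing thermodynamic is hard-coded here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .alignment import BASES, Alignment, GapMask, encode_seq
from .errors import InputError, ParameterError, PlacementError

R_GAS = 1.987  # cal / (mol K)

_DNA = "ACGT"
_DNA_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

MIN_DUPLEX_LEN = 8


def _load_tsv(name: str) -> dict[str, tuple[float, float]]:
    out: dict[str, tuple[float, float]] = {}
    text = resources.files("ribodeplete.data").joinpath(name).read_text()
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("stack\t"):
            continue
        stack, dh, ds, _source = line.split("\t")
        out[stack] = (float(dh), float(ds))
    return out


@dataclass(frozen=True)
class NNParameterTable:
    """Nearest-neighbor stack parameters keyed ``XY/WZ`` (top 5'->3' / bottom 3'->5').

    ``stacks`` holds perfect-match RNA:DNA entries plus the ``init`` term;
    ``mismatches`` the internal-mismatch fallback entries.  ``lookup_dh`` /
    ``lookup_ds`` are 256-entry arrays indexed by
    ``16 * state_i + state_j`` with per-position pairing state
    ``state = 4 * target_base + sense_base`` (NaN where no parameters exist).
    """

    stacks: dict[str, tuple[float, float]]
    mismatches: dict[str, tuple[float, float]]
    provenance: str
    lookup_dh: np.ndarray = field(repr=False)
    lookup_ds: np.ndarray = field(repr=False)
    init_dh: float
    init_ds: float

    @staticmethod
    def default() -> "NNParameterTable":
        stacks = _load_tsv("nn_rna_dna_sugimoto1995.tsv")
        mm = _load_tsv("nn_dna_internal_mismatch.tsv")
        return NNParameterTable.from_dicts(
            stacks, mm, "sugimoto1995 + allawi_santalucia_imm"
        )

    @staticmethod
    def from_dicts(stacks, mismatches, provenance) -> "NNParameterTable":
        init_dh, init_ds = stacks.get("init", (0.0, 0.0))
        lookup_dh = np.full(256, np.nan)
        lookup_ds = np.full(256, np.nan)
        for ti in range(4):
            for si in range(4):
                for tj in range(4):
                    for sj in range(4):
                        top = _DNA[ti] + _DNA[tj]
                        bot = _DNA_COMP[_DNA[si]] + _DNA_COMP[_DNA[sj]]
                        key = top + "/" + bot
                        perfect = ti == si and tj == sj
                        if (ti != si) and (tj != sj):
                            # two mismatched pairings in one stack: always
                            # undefined, whatever the tables contain
                            continue
                        params = None
                        for table, k in (
                            (mismatches, key),
                            (mismatches, key[::-1]),
                            (stacks, key),
                            (stacks, key[::-1]),
                        ):
                            if k in table:
                                params = table[k]
                                break
                        if perfect and params is None:  # pragma: no cover
                            raise ParameterError(f"missing perfect-match stack {key}")
                        if params is not None:
                            code = (4 * ti + si) * 16 + (4 * tj + sj)
                            lookup_dh[code] = params[0]
                            lookup_ds[code] = params[1]
        obj = object.__new__(NNParameterTable)
        object.__setattr__(obj, "stacks", dict(stacks))
        object.__setattr__(obj, "mismatches", dict(mismatches))
        object.__setattr__(obj, "provenance", provenance)
        object.__setattr__(obj, "lookup_dh", lookup_dh)
        object.__setattr__(obj, "lookup_ds", lookup_ds)
        object.__setattr__(obj, "init_dh", init_dh)
        object.__setattr__(obj, "init_ds", init_ds)
        return obj


@dataclass(frozen=True)
class ThermoConditions:
    """Hybridization conditions for Tm prediction.

    Defaults are the documented defaults of the nearest-neighbor routine this
    model reproduces: equal 25 nM strand concentrations, 50 mM monovalent
    salt, entropic SantaLucia-1998 salt correction.
    """

    probe_nM: float = 25.0
    target_nM: float = 25.0
    monovalent_mM: float = 50.0
    salt_scheme: str = "santalucia1998_entropy"

    def __post_init__(self):
        if self.probe_nM <= 0 or self.target_nM <= 0:
            raise ParameterError("strand concentrations must be > 0")
        if self.monovalent_mM < 0:
            raise ParameterError("salt concentration must be >= 0")
        if self.salt_scheme not in ("santalucia1998_entropy", "none"):
            raise ParameterError(f"unknown salt scheme {self.salt_scheme!r}")

    @property
    def c_effective(self) -> float:
        return (self.probe_nM - self.target_nM / 2.0) * 1e-9

    def salt_ds(self, n: int) -> float:
        if self.salt_scheme == "none" or self.monovalent_mM == 0:
            return 0.0
        return 0.368 * (n - 1) * math.log(self.monovalent_mM * 1e-3)


@dataclass(frozen=True)
class TmProfile:
    """Per-species Tm of one candidate; undefined entries are NaN."""

    species_ids: list[str]
    tm: np.ndarray
    defined: bool
    min_tm: float  # NaN unless defined

    @staticmethod
    def from_tms(species_ids, tm: np.ndarray) -> "TmProfile":
        defined = bool(np.all(np.isfinite(tm)))
        min_tm = float(np.min(tm)) if defined else math.nan
        return TmProfile(list(species_ids), tm, defined, min_tm)

    @property
    def per_species(self) -> dict[str, float]:
        return dict(zip(self.species_ids, (float(t) for t in self.tm)))


class ThermoEngine:
    """Vectorized Tm evaluation of sense-space windows against an alignment.

    Precomputes the alignment's integer codes and the 256-entry stack lookup
    so a candidate's whole per-species profile costs a handful of numpy ops.
    """

    def __init__(self, a: Alignment, table: NNParameterTable | None = None,
                 cond: ThermoConditions | None = None):
        self.alignment = a
        self.table = table or NNParameterTable.default()
        self.cond = cond or ThermoConditions()
        self._targets = a.codes.astype(np.intp)
        self._ln_k = math.log(self.cond.c_effective)

    def tms(self, start: int, sense_codes: np.ndarray) -> np.ndarray:
        """Per-species Tm (°C, NaN = undefined) for a window starting at ``start``."""
        n = sense_codes.size
        tc = self._targets[:, start:start + n]
        states = 4 * tc + sense_codes[np.newaxis, :]
        codes = 16 * states[:, :-1] + states[:, 1:]
        dh = self.table.init_dh + self.table.lookup_dh[codes].sum(axis=1)
        ds = self.table.init_ds + self.table.lookup_ds[codes].sum(axis=1)
        ds = ds + self.cond.salt_ds(n) + R_GAS * self._ln_k
        with np.errstate(invalid="ignore"):
            return 1000.0 * dh / ds - 273.15

    def profile(self, start: int, sense_codes: np.ndarray) -> TmProfile:
        return TmProfile.from_tms(self.alignment.species_ids,
                                  self.tms(start, sense_codes))

    def min_tm(self, start: int, sense_codes: np.ndarray) -> float:
        """Minimum per-species Tm; NaN if any species is undefined."""
        tm = self.tms(start, sense_codes)
        if np.isnan(tm).any():
            return math.nan
        return float(tm.min())


def duplex_tm(probe_sense: str, target: str,
              table: NNParameterTable | None = None,
              cond: ThermoConditions | None = None) -> float:
    """Tm (°C) of the antisense-DNA probe of ``probe_sense`` against RNA ``target``.

    Returns NaN ("undefined") when any dinucleotide stack lacks tabulated
    parameters, which is guaranteed for two sequential mismatches.  Raises on
    unequal lengths, duplexes shorter than 8 nt, or alphabet violations.
    """
    if len(probe_sense) != len(target):
        raise InputError(
            f"length mismatch: probe {len(probe_sense)} vs target {len(target)}"
        )
    if len(probe_sense) < MIN_DUPLEX_LEN:
        raise InputError(f"duplex shorter than {MIN_DUPLEX_LEN} nt")
    s = encode_seq(probe_sense)
    t = encode_seq(target)
    if (s > 3).any() or (t > 3).any():
        raise InputError("gap characters not allowed in duplex sequences")
    table = table or NNParameterTable.default()
    cond = cond or ThermoConditions()
    states = 4 * t.astype(np.intp) + s.astype(np.intp)
    codes = 16 * states[:-1] + states[1:]
    dh = table.init_dh + table.lookup_dh[codes].sum()
    ds = table.init_ds + table.lookup_ds[codes].sum()
    if math.isnan(dh) or math.isnan(ds):
        return math.nan
    ds += cond.salt_ds(len(target)) + R_GAS * math.log(cond.c_effective)
    return 1000.0 * dh / ds - 273.15


def tm_profile(window: tuple[int, int], sense_seq: str, a: Alignment,
               mask: GapMask, table: NNParameterTable | None = None,
               cond: ThermoConditions | None = None) -> TmProfile:
    """Per-species Tm profile of a sense sequence placed at an alignment window.

    The window (half-open columns) must lie entirely inside one admissible
    run of the gap mask; each species' target is its ungapped substring there.
    """
    start, end = window
    if end - start != len(sense_seq):
        raise InputError("sense sequence length does not match window")
    if start < 0 or end > a.length or mask.window_containing(start, end) is None:
        raise PlacementError(
            f"window [{start}, {end}) touches a masked column or alignment edge"
        )
    engine = ThermoEngine(a, table, cond)
    codes = encode_seq(sense_seq).astype(np.intp)
    if (codes > 3).any():
        raise InputError("gap characters not allowed in sense sequence")
    return engine.profile(start, codes)
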