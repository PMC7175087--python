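"""Multiple sequence alignments of rRNAs and per-column conservation.

Depletion oligos are designed on a multiple sequence alignment of the target
rRNAs, one row per species.  Only columns where *no* species has a gap are
admissible for oligo placement; the maximal runs of such columns form the
search space of the optimizer.  Conservation is summarized per column as
information content, ``ic = 2 - H`` bits, where ``H`` is the Shannon entropy
of the base frequencies among species at that column (2 bits = fully
conserved).

Coordinates are 0-based, half-open throughout; exported probe tables convert
to 1-based inclusive (oligo-vendor convention).  Sequences are stored in the
RNA alphabet (``U``); ``T`` is accepted on input.  Ambiguity codes are
rejected outright.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentFormatError, AlphabetError, InputError, ParameterError

# Canonical base order used for integer encoding everywhere in the package.
BASES = "ACGU"
GAP = "-"
GAP_CODE = 4

_ENCODE = {c: i for i, c in enumerate(BASES)}
_ENCODE[GAP] = GAP_CODE
_ENCODE["T"] = _ENCODE["U"]


def encode_seq(seq: str) -> np.ndarray:
    """Encode an RNA/gap string as int8 codes (A=0, C=1, G=2, U=3, gap=4)."""
    out = np.empty(len(seq), dtype=np.int8)
    for i, ch in enumerate(seq.upper()):
        code = _ENCODE.get(ch)
        if code is None:
            raise AlphabetError(f"illegal character {ch!r} at position {i}")
        out[i] = code
    return out


def decode_seq(codes: np.ndarray) -> str:
    return "".join((BASES + GAP)[c] for c in codes)


@dataclass(frozen=True)
class Alignment:
    """An aligned set of rRNA sequences, one row per species.

    ``codes`` is the integer-encoded (n_species, length) matrix; rows are the
    canonical uppercase RNA strings.  All rows have identical length and
    species ids are unique and nonempty.
    """

    species_ids: list[str]
    rows: list[str]
    codes: np.ndarray = field(repr=False)

    def __init__(self, species_ids, rows):
        species_ids = list(species_ids)
        rows = [str(r).upper().replace("T", "U") for r in rows]
        if len(species_ids) != len(rows):
            raise AlignmentFormatError("species_ids and rows differ in length")
        if not rows:
            raise InputError("alignment has no records")
        if any(not s for s in species_ids):
            raise InputError("empty species id")
        if len(set(species_ids)) != len(species_ids):
            raise InputError("duplicate species ids")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise AlignmentFormatError(
                f"rows have unequal lengths: {sorted(lengths)}"
            )
        if next(iter(lengths)) == 0:
            raise AlignmentFormatError("zero-length alignment")
        mat = np.empty((len(rows), len(rows[0])), dtype=np.int8)
        for i, (sid, row) in enumerate(zip(species_ids, rows)):
            try:
                mat[i] = encode_seq(row)
            except AlphabetError as exc:
                raise AlphabetError(f"record {sid!r}: {exc}") from None
        object.__setattr__(self, "species_ids", species_ids)
        object.__setattr__(self, "rows", rows)
        object.__setattr__(self, "codes", mat)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def length(self) -> int:
        return self.codes.shape[1]

    def subset(self, species: list[str]) -> "Alignment":
        """Restrict to a subset of species (e.g. a Gram group), keeping order."""
        missing = [s for s in species if s not in self.species_ids]
        if missing:
            raise InputError(f"unknown species: {missing}")
        idx = {s: self.species_ids.index(s) for s in species}
        return Alignment(species, [self.rows[idx[s]] for s in species])


@dataclass(frozen=True)
class GapMask:
    """Admissible (gap-free-in-all-species) columns and their maximal runs.

    ``windows`` are disjoint, sorted half-open intervals exactly covering the
    admissible column set.
    """

    admissible: np.ndarray
    windows: list[tuple[int, int]]

    def window_containing(self, start: int, end: int) -> tuple[int, int] | None:
        """Return the admissible run fully containing [start, end), if any."""
        for ws, we in self.windows:
            if ws <= start and end <= we:
                return (ws, we)
        return None


@dataclass(frozen=True)
class ConservationTrack:
    """Per-column information content in bits, NaN at masked columns.

    ``smoothed`` is a centered moving mean computed over admissible columns
    only (masked columns do not enter the window average).
    """

    ic: np.ndarray
    smoothed: np.ndarray
    window: int


def read_alignment(path, min_records: int = 2) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    ``min_records`` may be lowered to 1 for the per-species 5S workflow, where
    a single-row "alignment" is run through the same engine.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"no FASTA records in {path}")
    if len(records) < min_records:
        raise InputError(
            f"{path} has {len(records)} record(s); at least {min_records} required"
        )
    return Alignment([r.id for r in records], [str(r.seq) for r in records])


def write_alignment(a: Alignment, path) -> None:
    records = [
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(a.species_ids, a.rows)
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def gap_mask(a: Alignment) -> GapMask:
    """Columns admissible iff no species has a gap; windows = maximal runs."""
    admissible = ~np.any(a.codes == GAP_CODE, axis=0)
    windows: list[tuple[int, int]] = []
    start = None
    for c, ok in enumerate(admissible):
        if ok and start is None:
            start = c
        elif not ok and start is not None:
            windows.append((start, c))
            start = None
    if start is not None:
        windows.append((start, a.length))
    return GapMask(admissible=admissible, windows=windows)


def information_content(a: Alignment, mask: GapMask, window: int = 20) -> ConservationTrack:
    """Information content ``2 - H`` (bits) per admissible column.

    ``H`` is the base-2 Shannon entropy of per-species base frequencies;
    zero-frequency terms contribute 0.  The smoothed track is the centered
    moving mean over the subsequence of admissible columns, mapped back onto
    alignment coordinates.
    """
    if window < 1:
        raise ParameterError(f"window must be >= 1, got {window}")
    n, L = a.codes.shape
    ic = np.full(L, np.nan)
    # per-column base counts over the 4 bases (gaps cannot occur at admissible cols)
    for c in np.flatnonzero(mask.admissible):
        counts = np.bincount(a.codes[:, c], minlength=4)[:4]
        freqs = counts[counts > 0] / n
        h = -np.sum(freqs * np.log2(freqs))
        ic[c] = 2.0 - h
    adm_idx = np.flatnonzero(mask.admissible)
    smoothed = np.full(L, np.nan)
    if adm_idx.size:
        vals = ic[adm_idx]
        half = window // 2
        for k, c in enumerate(adm_idx):
            lo = max(0, k - half)
            hi = min(vals.size, k - half + window)
            smoothed[c] = vals[lo:hi].mean()
    return ConservationTrack(ic=ic, smoothed=smoothed, window=window)


def write_conservation(track: ConservationTrack, path) -> None:
    """Write the conservation track as 3-column TSV (column, ic_bits, smoothed)."""
    with open(path, "w") as fh:
        fh.write("column\tic_bits\tsmoothed\n")
        for c, (v, s) in enumerate(zip(track.ic, track.smoothed)):
            fh.write(f"{c}\t{'' if np.isnan(v) else f'{v:.6f}'}\t"
                     f"{'' if np.isnan(s) else f'{s:.6f}'}\n")
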