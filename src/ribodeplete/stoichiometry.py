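"""Reaction stoichiometry for the depletion bench step.

From micrograms of input total RNA the moles of ribosome are estimated
assuming a fixed rRNA mass fraction (default 90% by weight) and a ribosomal
RNA molar mass.  Each 16S/23S oligo is dosed at a fixed probe:rRNA molar
ratio (default 2.25); 5S oligos at twice that (default 4.5).  The
streptavidin bead volume is sized from the theoretical bead binding capacity
(default 5e-12 mol biotinylated oligo per µl) times a safety excess, since an
excess of beads over oligos is critical for capture efficiency.

The default rRNA molar mass can be computed from the actual rRNA lengths
(``rrna_molar_mass_from_lengths``); otherwise a documented constant for an
E. coli-like ribosome (~4,566 nt of rRNA) is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ParameterError

#: Mean molar mass of one nucleotide residue in RNA, g/mol.
MEAN_NT_MASS = 321.0

#: 16S + 23S + 5S rRNA nucleotides for an E. coli-like ribosome
#: (1542 + 2904 + 120 nt).
DEFAULT_RRNA_NT = 4566

DEFAULT_RRNA_MOLAR_MASS = DEFAULT_RRNA_NT * MEAN_NT_MASS  # ~1.466e6 g/mol


def rrna_molar_mass_from_lengths(*lengths_nt: int,
                                 nt_mass: float = MEAN_NT_MASS) -> float:
    """Molar mass (g/mol) of the rRNA complement given rRNA lengths in nt."""
    if not lengths_nt or any(l <= 0 for l in lengths_nt):
        raise ParameterError("rRNA lengths must be positive")
    return sum(lengths_nt) * nt_mass


@dataclass(frozen=True)
class ReactionSpec:
    """Inputs of the depletion reaction calculator."""

    total_rna_ug: float = 1.0
    rrna_mass_fraction: float = 0.9
    rrna_molar_mass: float = DEFAULT_RRNA_MOLAR_MASS
    probe_ratio_16s23s: float = 2.25
    probe_ratio_5s: float = 4.5
    n_probes_16s23s: int = 19
    n_probes_5s: int = 2
    bead_capacity_mol_per_ul: float = 5e-12
    bead_excess: float = 2.0

    def __post_init__(self):
        if self.total_rna_ug <= 0:
            raise ParameterError("total RNA mass must be > 0")
        if not (0 < self.rrna_mass_fraction <= 1):
            raise ParameterError("rRNA mass fraction must be in (0, 1]")
        if self.rrna_molar_mass <= 0:
            raise ParameterError("rRNA molar mass must be > 0")
        if self.probe_ratio_16s23s <= 0 or self.probe_ratio_5s <= 0:
            raise ParameterError("probe:rRNA ratios must be > 0")
        if self.n_probes_16s23s < 0 or self.n_probes_5s < 0:
            raise ParameterError("probe counts must be >= 0")
        if self.bead_capacity_mol_per_ul <= 0:
            raise ParameterError("bead capacity must be > 0")
        if self.bead_excess < 1:
            raise ParameterError("bead excess must be >= 1")


@dataclass(frozen=True)
class ReactionPlan:
    """Computed amounts for one depletion reaction."""

    ribosome_moles: float
    per_probe_moles_16s23s: float
    per_probe_moles_5s: float
    total_probe_moles: float
    min_bead_volume_ul: float
    oligo_bead_ratio: float


def ribosome_moles(mass_ug: float, fraction: float, molar_mass: float) -> float:
    """Moles of ribosome (rRNA complement) in ``mass_ug`` µg of total RNA."""
    if mass_ug <= 0 or not (0 < fraction <= 1) or molar_mass <= 0:
        raise ParameterError("mass, fraction and molar mass must be positive "
                             "(fraction <= 1)")
    return mass_ug * 1e-6 * fraction / molar_mass


def reaction_plan(spec: ReactionSpec) -> ReactionPlan:
    """Full reaction plan: per-oligo moles, totals, and minimum bead volume."""
    ribo = ribosome_moles(spec.total_rna_ug, spec.rrna_mass_fraction,
                          spec.rrna_molar_mass)
    per_main = spec.probe_ratio_16s23s * ribo
    per_5s = spec.probe_ratio_5s * ribo
    total = per_main * spec.n_probes_16s23s + per_5s * spec.n_probes_5s
    bead_vol = spec.bead_excess * total / spec.bead_capacity_mol_per_ul
    ratio = total / (bead_vol * spec.bead_capacity_mol_per_ul)
    return ReactionPlan(
        ribosome_moles=ribo,
        per_probe_moles_16s23s=per_main,
        per_probe_moles_5s=per_5s,
        total_probe_moles=total,
        min_bead_volume_ul=bead_vol,
        oligo_bead_ratio=ratio,
    )
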