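"""Monoisotopic mass chemistry for modified peptides.

Residue masses, modification deltas, peptide monoisotopic mass and
precursor m/z. All masses are monoisotopic and in daltons; charging uses
the proton mass (1.007276 Da), which is what reproduces the printed m/z
values of high-resolution Orbitrap work (e.g. a triply protonated
pentamethylated histone H3 K27-R40 peptide at m/z 501.9755).

Positions are in protein numbering throughout: a peptide knows where it
starts in its parent protein, and modification sites are addressed by
protein position (so "K27me3" stays K27 after digestion).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

from pyteomics import mass as _pt_mass

__all__ = [
    "WATER",
    "PROTON",
    "RESIDUE_MASSES",
    "ModKind",
    "Modification",
    "Peptide",
    "peptide_mass",
    "precursor_mz",
    "ppm_error",
]

#: Monoisotopic mass of H2O in Da.
WATER = 18.010565
#: Mass of a proton in Da (charging uses protons, not hydrogen atoms).
PROTON = 1.007276

#: One-letter residue code -> monoisotopic residue mass (Da), the 20
#: standard amino acids. Values are the standard monoisotopic residue
#: masses (frozen from pyteomics at import).
RESIDUE_MASSES: Mapping[str, float] = {
    aa: _pt_mass.std_aa_mass[aa]
    for aa in "ACDEFGHIKLMNPQRSTVWY"
}


class ModKind(str, enum.Enum):
    """Supported variable modifications."""

    METHYL = "methyl"
    ACETYL = "acetyl"
    PHOSPHO = "phospho"
    OXIDATION = "oxidation"


#: Mass added per unit of each modification (Da).
MOD_UNIT_DELTAS: Mapping[ModKind, float] = {
    ModKind.METHYL: 14.015650,
    ModKind.ACETYL: 42.010565,
    ModKind.PHOSPHO: 79.966331,
    ModKind.OXIDATION: 15.994915,
}

#: Residues each modification is chemically valid on.
MOD_TARGETS: Mapping[ModKind, str] = {
    ModKind.METHYL: "KR",
    ModKind.ACETYL: "K",
    ModKind.PHOSPHO: "ST",
    ModKind.OXIDATION: "M",
}


@dataclass(frozen=True)
class Modification:
    """A variable modification with a multiplicity.

    ``Modification(ModKind.METHYL, 3)`` is trimethylation: total delta is
    ``multiplicity`` x the per-unit delta.
    """

    kind: ModKind
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.multiplicity < 1:
            raise ValueError(f"multiplicity must be >= 1, got {self.multiplicity}")
        if self.kind is ModKind.METHYL and self.multiplicity > 3:
            raise ValueError("lysine/arginine methylation multiplicity is at most 3")

    @property
    def delta(self) -> float:
        """Total mass shift in Da."""
        return self.multiplicity * MOD_UNIT_DELTAS[self.kind]

    def __str__(self) -> str:  # e.g. "me3", "ac"
        short = {
            ModKind.METHYL: "me",
            ModKind.ACETYL: "ac",
            ModKind.PHOSPHO: "ph",
            ModKind.OXIDATION: "ox",
        }[self.kind]
        if self.kind is ModKind.METHYL:
            return f"{short}{self.multiplicity}"
        return short if self.multiplicity == 1 else f"{short}{self.multiplicity}"


@dataclass(frozen=True)
class Peptide:
    """A peptide with site-resolved modifications in protein numbering.

    Parameters
    ----------
    sequence
        One-letter residue string, N- to C-terminal.
    start_position
        Protein-numbering position of the first residue (e.g. 27 for the
        histone H3 K27-R40 peptide).
    mods
        Mapping of protein position -> :class:`Modification`.
    """

    sequence: str
    start_position: int = 1
    mods: Mapping[int, Modification] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        for ch in self.sequence:
            if ch not in RESIDUE_MASSES:
                raise ValueError(f"unknown residue code {ch!r} in {self.sequence!r}")
        object.__setattr__(self, "mods", dict(self.mods))
        end = self.start_position + len(self.sequence) - 1
        for site, mod in self.mods.items():
            if not self.start_position <= site <= end:
                raise ValueError(
                    f"modification site {site} outside peptide "
                    f"[{self.start_position}, {end}]"
                )
            res = self.residue_at(site)
            if res not in MOD_TARGETS[mod.kind]:
                raise ValueError(
                    f"{mod.kind.value} is not valid on residue {res}{site}"
                )

    @property
    def end_position(self) -> int:
        return self.start_position + len(self.sequence) - 1

    def residue_at(self, position: int) -> str:
        """Residue one-letter code at a protein position."""
        return self.sequence[position - self.start_position]

    def mod_at(self, position: int) -> Modification | None:
        return self.mods.get(position)

    def name(self) -> str:
        """Human-readable label, e.g. ``K27me3-K36me2/27-40``."""
        parts = [
            f"{self.residue_at(site)}{site}{mod}"
            for site, mod in sorted(self.mods.items())
        ]
        label = "-".join(parts) if parts else "unmod"
        return f"{label}/{self.start_position}-{self.end_position}"


def peptide_mass(p: Peptide) -> float:
    """Monoisotopic mass of a (modified) peptide in Da.

    Sum of residue masses + one water + all modification deltas. Isobaric
    placements of the same modification composition give the identical
    float: the sum is accumulated in a placement-independent order.
    """
    total = WATER
    for ch in p.sequence:
        total += RESIDUE_MASSES[ch]
    # summing deltas sorted by value makes the accumulation order depend
    # only on the modification multiset, so isobaric placements agree bitwise
    for delta in sorted(mod.delta for mod in p.mods.values()):
        total += delta
    return total


def precursor_mz(p: Peptide, z: int) -> float:
    """m/z of the peptide carrying ``z`` protons."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return (peptide_mass(p) + z * PROTON) / z


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6
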