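"""Canonical histone H3 peptides used throughout the package.

The workhorse analyte is the tryptic H3 peptide spanning K27–R40
(KSAPATGGVKKPHR). Carrying five methyl groups split between K27 and
K36, it exists as two isobaric positional isomers — K27me3-K36me2 and
K27me2-K36me3 — that coelute and share every precursor charge state but
fragment into distinguishable y5–y13 and b1–b9 ions. The constitutive,
modification-free D123–R128 peptide (DIQLAR) serves as the
normalization reference for relative abundance.
"""

from __future__ import annotations

from .chem import ModKind, Modification, Peptide
from .fragments import IsobaricGroup

__all__ = [
    "K27_R40_SEQUENCE",
    "L20_R52_SEQUENCE",
    "k27_r40",
    "l20_r52",
    "pentamethyl_pair",
    "normalizer_d123_r128",
]

#: H3 residues 27..40.
K27_R40_SEQUENCE = "KSAPATGGVKKPHR"
#: H3 residues 20..52 (a long form whose tryptic digestion yields K27-R40).
L20_R52_SEQUENCE = "LATKAARKSAPATGGVKKPHRYRPGTVALREIR"


def _methyls(k27: int, k36: int) -> dict[int, Modification]:
    mods: dict[int, Modification] = {}
    if k27:
        mods[27] = Modification(ModKind.METHYL, k27)
    if k36:
        mods[36] = Modification(ModKind.METHYL, k36)
    return mods


def k27_r40(k27_methyls: int = 0, k36_methyls: int = 0) -> Peptide:
    """The H3 K27-R40 peptide with the given methyl counts."""
    return Peptide(
        K27_R40_SEQUENCE, start_position=27, mods=_methyls(k27_methyls, k36_methyls)
    )


def l20_r52(k27_methyls: int = 0, k36_methyls: int = 0) -> Peptide:
    """The long H3 L20-R52 peptide with the given methyl counts."""
    return Peptide(
        L20_R52_SEQUENCE, start_position=20, mods=_methyls(k27_methyls, k36_methyls)
    )


def pentamethyl_pair() -> IsobaricGroup:
    """The isobaric K27-R40 pentamethyl pair.

    Isoform ids follow the field's naming: ``K27me3-K36me2`` and
    ``K27me2-K36me3``.
    """
    return IsobaricGroup(
        isoforms={
            "K27me3-K36me2": k27_r40(3, 2),
            "K27me2-K36me3": k27_r40(2, 3),
        }
    )


def normalizer_d123_r128() -> Peptide:
    """The constitutive H3 D123-R128 peptide (DIQLAR), unmodified."""
    return Peptide("DIQLAR", start_position=123)
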