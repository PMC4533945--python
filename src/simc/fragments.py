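"""Theoretical b/y fragment ions, isobaric isoform groups and their
discriminating "specific ions", and in-silico tryptic digestion with
methylation-dependent cleavage blocking.

A *specific ion* is a fragment (series, index, charge) whose theoretical
m/z differs between the isoforms of an isobaric group — which happens
exactly when the residue window the fragment covers contains an unequal
share of the differing modifications. For the pentamethylated histone H3
K27-R40 pair (K27me3-K36me2 vs K27me2-K36me3) these are the y5–y13 and
b1–b9 ions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .chem import (
    PROTON,
    RESIDUE_MASSES,
    WATER,
    ModKind,
    Modification,
    Peptide,
    peptide_mass,
)

__all__ = [
    "FragmentIon",
    "IsobaricGroup",
    "CleavageRule",
    "generate_fragments",
    "find_specific_ions",
    "digest",
    "fragment_table",
    "read_fasta",
]

#: Da tolerance below which two theoretical fragment masses count as equal.
SPECIFICITY_TOL = 1e-6


@dataclass(frozen=True)
class FragmentIon:
    """One theoretical backbone fragment ion.

    ``index`` counts residues in the fragment: b_i covers the first *i*
    residues, y_i the last *i*.
    """

    series: str  # "b" or "y"
    index: int
    charge: int
    mz: float
    isoform_id: str = ""

    @property
    def label(self) -> str:
        return f"{self.series}{self.index}^{self.charge}+"


def _fragment_neutral(p: Peptide, series: str, index: int) -> float:
    """Neutral mass of a b/y fragment (b: residue sum; y: residues + water).

    b(i) + y(n-i) therefore equals the peptide's neutral mass exactly.
    """
    n = len(p.sequence)
    if not 1 <= index <= n - 1:
        raise ValueError(f"fragment index {index} outside 1..{n - 1}")
    if series == "b":
        positions = range(p.start_position, p.start_position + index)
    elif series == "y":
        positions = range(p.end_position - index + 1, p.end_position + 1)
    else:
        raise ValueError(f"unknown ion series {series!r}")
    total = 0.0
    for pos in positions:
        total += RESIDUE_MASSES[p.residue_at(pos)]
    for delta in sorted(
        mod.delta for site, mod in p.mods.items() if site in positions
    ):
        total += delta
    if series == "y":
        total += WATER
    return total


def generate_fragments(
    p: Peptide,
    series_set: Iterable[str] = ("b", "y"),
    max_charge: int = 2,
    isoform_id: str = "",
) -> list[FragmentIon]:
    """Complete b/y ladders for all charges ``1..max_charge``.

    Modification deltas are assigned to every fragment whose residue
    window contains the modified site.
    """
    if max_charge < 1:
        raise ValueError(f"max_charge must be >= 1, got {max_charge}")
    ions: list[FragmentIon] = []
    n = len(p.sequence)
    for series in series_set:
        for index in range(1, n):
            neutral = _fragment_neutral(p, series, index)
            for z in range(1, max_charge + 1):
                ions.append(
                    FragmentIon(
                        series=series,
                        index=index,
                        charge=z,
                        mz=(neutral + z * PROTON) / z,
                        isoform_id=isoform_id or p.name(),
                    )
                )
    return ions


@dataclass
class IsobaricGroup:
    """A set of same-sequence isoforms sharing total modification mass.

    The isoforms are indistinguishable at the precursor (MS1) level; the
    group's ``specific_ions`` — populated by :func:`find_specific_ions` —
    are the fragments that tell them apart in MS/MS.
    """

    isoforms: Mapping[str, Peptide]
    specific_ions: dict[str, list[FragmentIon]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.isoforms = dict(self.isoforms)
        if len(self.isoforms) < 2:
            raise ValueError("an isobaric group needs at least two isoforms")
        peps = list(self.isoforms.values())
        first = peps[0]
        for p in peps[1:]:
            if p.sequence != first.sequence or p.start_position != first.start_position:
                raise ValueError("isoforms must share sequence and start position")
            if abs(peptide_mass(p) - peptide_mass(first)) > SPECIFICITY_TOL:
                raise ValueError(
                    "isoforms are not isobaric: "
                    f"{p.name()} vs {first.name()} differ in mass"
                )

    @property
    def peptide_mass(self) -> float:
        return peptide_mass(next(iter(self.isoforms.values())))

    def precursor_mz(self, z: int) -> float:
        if z < 1:
            raise ValueError("charge must be >= 1")
        return (self.peptide_mass + z * PROTON) / z


def find_specific_ions(
    group: IsobaricGroup,
    series_set: Iterable[str] = ("b", "y"),
    charge_set: Iterable[int] = (1, 2),
) -> dict[str, list[FragmentIon]]:
    """Find the fragment slots that discriminate the group's isoforms.

    A (series, index, charge) slot is specific when the theoretical m/z
    values of all isoforms at that slot are pairwise distinct (beyond
    ``SPECIFICITY_TOL``), i.e. each isoform's ion differs from every
    other isoform's. The result maps isoform id -> its specific ions,
    and is also stored on ``group.specific_ions``.
    """
    series_set = tuple(series_set)
    charge_set = tuple(sorted(set(charge_set)))
    ids = list(group.isoforms)
    ladders = {
        iid: {
            (f.series, f.index, f.charge): f
            for f in generate_fragments(
                group.isoforms[iid], series_set, max(charge_set), isoform_id=iid
            )
            if f.charge in charge_set
        }
        for iid in ids
    }
    slots = ladders[ids[0]].keys()
    specific: dict[str, list[FragmentIon]] = {iid: [] for iid in ids}
    for slot in sorted(slots, key=lambda s: (s[0], s[2], s[1])):
        mzs = [ladders[iid][slot].mz for iid in ids]
        if all(abs(a - b) > SPECIFICITY_TOL for a, b in combinations(mzs, 2)):
            for iid in ids:
                specific[iid].append(ladders[iid][slot])
    group.specific_ions = specific
    return specific


@dataclass(frozen=True)
class CleavageRule:
    """Tryptic cleavage with modification-state blocking.

    Trypsin cuts after K and R, not before proline. Lysine methylation
    interferes progressively: monomethyl-lysine is still cleavable, but
    di-/trimethyl and acetyl block the site.
    """

    cleave_after: frozenset[str] = frozenset({"K", "R"})
    blocking_next: frozenset[str] = frozenset({"P"})
    max_missed_cleavages: int = 5

    def is_cleavable(self, p: Peptide, position: int) -> bool:
        """Can the bond after ``position`` (protein numbering) be cut?"""
        if position >= p.end_position:  # C-terminus: no bond to cut
            return False
        res = p.residue_at(position)
        if res not in self.cleave_after:
            return False
        if p.residue_at(position + 1) in self.blocking_next:
            return False
        mod = p.mod_at(position)
        if res == "K" and mod is not None:
            if mod.kind is ModKind.ACETYL:
                return False
            if mod.kind is ModKind.METHYL and mod.multiplicity >= 2:
                return False
        return True


def digest(p: Peptide, rule: CleavageRule | None = None) -> list[Peptide]:
    """In-silico digestion products with up to ``max_missed_cleavages``.

    Returns every product spanning consecutive cleavage boundaries with
    at most the allowed number of internal (missed) sites; the fully
    cleaved products are always included. Products inherit the parent's
    modifications and protein numbering.
    """
    rule = rule or CleavageRule()
    sites = [
        pos
        for pos in range(p.start_position, p.end_position)
        if rule.is_cleavable(p, pos)
    ]
    # boundaries: product start positions are start or site+1; ends are sites or end
    bounds = [p.start_position - 1] + sites + [p.end_position]
    products: list[Peptide] = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, len(bounds)):
            missed = j - i - 1
            if missed > rule.max_missed_cleavages:
                break
            start, end = bounds[i] + 1, bounds[j]
            seq = p.sequence[start - p.start_position : end - p.start_position + 1]
            mods = {s: m for s, m in p.mods.items() if start <= s <= end}
            products.append(Peptide(seq, start_position=start, mods=mods))
    return products


def fragment_table(ions: Sequence[FragmentIon]) -> pd.DataFrame:
    """Tabulate fragment ions (exportable as CSV)."""
    return pd.DataFrame(
        [
            {
                "isoform": f.isoform_id,
                "series": f.series,
                "index": f.index,
                "charge": f.charge,
                "mz": round(f.mz, 4),
            }
            for f in ions
        ]
    )


def read_fasta(path: str) -> dict[str, Peptide]:
    """Read protein sequences from FASTA as unmodified peptides at position 1."""
    from pyteomics import fasta

    out: dict[str, Peptide] = {}
    with fasta.read(path) as reader:
        for header, seq in reader:
            out[header.split()[0]] = Peptide(seq.upper(), start_position=1)
    return out
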