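"""Declarative TOML configuration for peptides, isoform groups and runs.

Peptide definitions carry a sequence, a protein-numbering start
position and modification entries in ``site:mod:multiplicity`` form,
e.g. ``"27:methyl:3"``::

    [peptide]
    sequence = "KSAPATGGVKKPHR"
    start = 27
    mods = ["27:methyl:3", "36:methyl:2"]

An isoform file defines one ``[isoforms.<id>]`` table per isoform with
the same keys; the set must be isobaric.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

from .chem import ModKind, Modification, Peptide
from .fragments import IsobaricGroup

__all__ = [
    "parse_mod_entry",
    "peptide_from_dict",
    "load_peptide",
    "load_isoforms",
]

_MOD_ALIASES = {
    "methyl": ModKind.METHYL,
    "me": ModKind.METHYL,
    "acetyl": ModKind.ACETYL,
    "ac": ModKind.ACETYL,
    "phospho": ModKind.PHOSPHO,
    "ph": ModKind.PHOSPHO,
    "oxidation": ModKind.OXIDATION,
    "ox": ModKind.OXIDATION,
}


def parse_mod_entry(entry: str) -> tuple[int, Modification]:
    """Parse a ``site:mod[:multiplicity]`` entry, e.g. ``"36:methyl:2"``."""
    parts = entry.split(":")
    if len(parts) not in (2, 3):
        raise ValueError(
            f"modification entry {entry!r} is not site:mod[:multiplicity]"
        )
    try:
        site = int(parts[0])
    except ValueError:
        raise ValueError(f"bad site in modification entry {entry!r}") from None
    kind = _MOD_ALIASES.get(parts[1].strip().lower())
    if kind is None:
        raise ValueError(
            f"unknown modification {parts[1]!r} (expected one of "
            f"{sorted(set(a for a in _MOD_ALIASES))})"
        )
    mult = int(parts[2]) if len(parts) == 3 else 1
    return site, Modification(kind, mult)


def peptide_from_dict(d: dict) -> Peptide:
    """Build a peptide from a config table."""
    if "sequence" not in d:
        raise ValueError("peptide definition needs a 'sequence' key")
    mods = dict(parse_mod_entry(e) for e in d.get("mods", []))
    return Peptide(
        sequence=str(d["sequence"]).upper(),
        start_position=int(d.get("start", 1)),
        mods=mods,
    )


def _load_toml(path: str | Path) -> dict:
    p = Path(path)
    if not p.exists():
        raise ValueError(f"config file not found: {p}")
    with open(p, "rb") as fh:
        return tomllib.load(fh)


def load_peptide(path: str | Path) -> Peptide:
    """Read a single-peptide config (``[peptide]`` table or top level)."""
    data = _load_toml(path)
    return peptide_from_dict(data.get("peptide", data))


def load_isoforms(path: str | Path) -> IsobaricGroup:
    """Read an isoform-group config (``[isoforms.<id>]`` tables)."""
    data = _load_toml(path)
    tables = data.get("isoforms")
    if not tables:
        raise ValueError(f"{path}: no [isoforms.<id>] tables found")
    return IsobaricGroup(
        isoforms={iid: peptide_from_dict(t) for iid, t in tables.items()}
    )
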