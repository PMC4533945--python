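"""End-to-end analysis: select scans, quantify, normalize, summarize.

``run_pipeline`` drives the whole method over one or more runs
(replicates): MS/MS-level constituent percentages for the isobaric
group, MS1 selected-ion chromatogram totals for the target and the
normalization peptide, normalized relative abundances, and — when more
than one run is given — the across-replicate mean and standard
deviation. The report embeds every effective parameter for provenance
and an ion-match ledger per run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .chem import Peptide
from .config import _load_toml, peptide_from_dict
from .fragments import IsobaricGroup
from .histone import normalizer_d123_r128, pentamethyl_pair
from .quant import (
    MIN_SIC_POINTS,
    QuantResult,
    relative_abundance,
    replicate_summary,
    sic,
    simc,
)
from .spectra_io import read_run

__all__ = ["AnalysisConfig", "run_pipeline"]

logger = logging.getLogger("simc")


@dataclass
class AnalysisConfig:
    """Everything one quantification needs, in one declarative object."""

    runs: list[str]
    group: IsobaricGroup = field(default_factory=pentamethyl_pair)
    tol_mode: str = "ppm"
    tol: float = 10.0
    series: tuple[str, ...] = ("y",)
    fragment_charges: tuple[int, ...] = (2,)
    precursor_charge: int = 3
    iso_window: float = 2.0
    sic_charges: tuple[int, ...] = (1, 2, 3, 4)
    normalizer: Peptide | None = field(default_factory=normalizer_d123_r128)
    normalizer_charges: tuple[int, ...] = (1, 2)
    out_json: str | None = None
    out_ledger: str | None = None

    def __post_init__(self) -> None:
        if self.tol_mode not in ("ppm", "Da"):
            raise ValueError(
                f"tolerance mode must be 'ppm' or 'Da', got {self.tol_mode!r}"
            )
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")
        if not self.runs:
            raise ValueError("at least one run path is required")
        for r in self.runs:
            if not Path(r).exists():
                raise ValueError(f"run file not found: {r}")

    @classmethod
    def from_toml(cls, path: str | Path) -> "AnalysisConfig":
        data = _load_toml(path)
        kwargs: dict = {"runs": list(data.get("runs", []))}
        if "isoforms" in data:
            kwargs["group"] = IsobaricGroup(
                isoforms={
                    iid: peptide_from_dict(t)
                    for iid, t in data["isoforms"].items()
                }
            )
        if "normalizer" in data:
            kwargs["normalizer"] = peptide_from_dict(data["normalizer"])
        for key in (
            "tol_mode", "tol", "precursor_charge", "iso_window",
            "out_json", "out_ledger",
        ):
            if key in data:
                kwargs[key] = data[key]
        for key in ("series", "fragment_charges", "sic_charges", "normalizer_charges"):
            if key in data:
                kwargs[key] = tuple(data[key])
        return cls(**kwargs)


def _params_dict(cfg: AnalysisConfig) -> dict:
    return {
        "tolerance": f"{cfg.tol} {cfg.tol_mode}",
        "series": list(cfg.series),
        "fragment_charges": list(cfg.fragment_charges),
        "precursor_charge": cfg.precursor_charge,
        "isolation_window": cfg.iso_window,
        "sic_charges": list(cfg.sic_charges),
        "normalizer": cfg.normalizer.name() if cfg.normalizer else None,
        "normalizer_charges": list(cfg.normalizer_charges),
        "isoforms": {iid: p.name() for iid, p in cfg.group.isoforms.items()},
    }


def run_pipeline(cfg: AnalysisConfig) -> dict:
    """Execute the full method and return (and optionally write) a report."""
    per_run: list[dict] = []
    quants: list[QuantResult] = []
    ledgers: list[pd.DataFrame] = []
    target = next(iter(cfg.group.isoforms.values()))
    for path in cfg.runs:
        stage = "read_run"
        try:
            run = read_run(path)
            stage = "simc"
            q = simc(
                run,
                cfg.group,
                precursor_charge=cfg.precursor_charge,
                iso_window=cfg.iso_window,
                series=cfg.series,
                fragment_charges=cfg.fragment_charges,
                tol_mode=cfg.tol_mode,
                tol=cfg.tol,
            )
            logger.info("%s: %d MS/MS scans used", path, q.n_ms2_scans)
            for w in q.warnings:
                logger.warning("%s: %s", path, w)
            stage = "sic"
            t_sic = sic(
                run, target, cfg.sic_charges, tol_mode=cfg.tol_mode, tol=cfg.tol
            )
            n_ms1 = len(run.ms1())
            if n_ms1 < MIN_SIC_POINTS:
                logger.warning(
                    "%s: SIC trace has only %d MS1 points (<%d)",
                    path, n_ms1, MIN_SIC_POINTS,
                )
            entry = {
                "run": path,
                "n_ms2_scans": q.n_ms2_scans,
                "n_ms1_scans": n_ms1,
                "percentages": (
                    {k: round(v, 2) for k, v in q.percentages.items()}
                    if q.defined else None
                ),
                "target_sic": {
                    "per_charge": t_sic.per_charge, "total": t_sic.total
                },
                "warnings": q.warnings,
            }
            if cfg.normalizer is not None:
                stage = "normalization"
                n_sic = sic(
                    run,
                    cfg.normalizer,
                    cfg.normalizer_charges,
                    tol_mode=cfg.tol_mode,
                    tol=cfg.tol,
                )
                if n_sic.total <= 0:
                    raise ValueError(
                        f"no MS1 signal for normalization peptide "
                        f"{cfg.normalizer.sequence} ({cfg.normalizer.name()})"
                    )
                entry["normalizer_sic"] = {
                    "per_charge": n_sic.per_charge, "total": n_sic.total
                }
                if q.defined:
                    entry["relative_abundance"] = relative_abundance(
                        q, t_sic, n_sic
                    )
            per_run.append(entry)
            quants.append(q)
            lg = q.ledger.copy()
            lg.insert(0, "run", path)
            ledgers.append(lg)
        except ValueError as exc:
            raise ValueError(f"[{stage}] {path}: {exc}") from exc
    report = {
        "schema": "simc-report/1",
        "parameters": _params_dict(cfg),
        "runs": per_run,
    }
    if len(quants) >= 2 and all(q.defined for q in quants):
        summary = replicate_summary(quants)
        report["replicates"] = {
            iid: {"mean": row["mean"], "sd": row["sd"], "n": int(row["n"])}
            for iid, row in summary.iterrows()
        }
    if cfg.out_json:
        Path(cfg.out_json).write_text(json.dumps(report, indent=2))
    if cfg.out_ledger and ledgers:
        pd.concat(ledgers, ignore_index=True).to_csv(cfg.out_ledger, index=False)
    return report
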