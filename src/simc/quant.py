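"""SIMC quantification core, plus MS1 selected-ion chromatograms.

SIMC (specific ions of isobaric modification chromatogram) quantifies
coeluting isobaric peptide isoforms from their MS/MS spectra: for every
fragmentation scan of the shared precursor, the intensities of each
isoform's specific fragment ions (by default the doubly charged y ions)
are summed; the per-scan sums traced over retention time form one
chromatogram per isoform, and the ratio of the integrated chromatograms
is the constituent percentage of each isoform.

MS1-level quantity comes from selected-ion chromatograms (SIC) summed
over charge states; dividing by the SIC of a constitutive peptide gives
a normalized relative abundance per isoform.

Peak selection follows the smallest-|mass error| rule with no
signal-to-noise threshold; ties go to the higher-intensity peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chem import Peptide, ppm_error, precursor_mz
from .fragments import FragmentIon, IsobaricGroup, find_specific_ions
from .spectra_io import Run, Spectrum, select_ms2

__all__ = [
    "IonMatch",
    "SIMCTrace",
    "QuantResult",
    "SICResult",
    "match_ions",
    "simc",
    "sic",
    "relative_abundance",
    "replicate_summary",
]

#: Fewer contributing MS/MS scans than this triggers a reliability warning.
MIN_MS2_SCANS = 6
#: Fewer MS1 points than this in a SIC trace triggers a warning.
MIN_SIC_POINTS = 22


@dataclass(frozen=True)
class IonMatch:
    """One observed peak assigned to a theoretical fragment ion."""

    target: FragmentIon
    scan_id: str
    rt: float
    observed_mz: float
    intensity: float
    mass_error: float  # in the units of the tolerance mode (ppm or Da)
    tol_mode: str = "ppm"


@dataclass
class SIMCTrace:
    """Per-isoform summed specific-ion intensity vs retention time."""

    isoform_id: str
    points: list[tuple[float, float]] = field(default_factory=list)

    @property
    def cumulative(self) -> float:
        """Integrated intensity (trapezoid over RT; plain sum for <2 points)."""
        if len(self.points) < 2:
            return float(sum(i for _rt, i in self.points))
        rts = np.array([rt for rt, _ in self.points])
        vals = np.array([i for _, i in self.points])
        return float(np.trapezoid(vals, rts))

    def summed(self) -> float:
        """Plain per-scan intensity sum (integration alternative)."""
        return float(sum(i for _rt, i in self.points))


@dataclass
class QuantResult:
    """SIMC output: percentages, traces and the full ion-match ledger."""

    percentages: dict[str, float] | None
    traces: dict[str, SIMCTrace]
    ledger: pd.DataFrame
    n_ms2_scans: int
    warnings: list[str] = field(default_factory=list)

    @property
    def defined(self) -> bool:
        return self.percentages is not None


@dataclass
class SICResult:
    """Selected-ion chromatogram areas per charge state."""

    peptide: Peptide
    per_charge: dict[int, float]

    @property
    def total(self) -> float:
        return float(sum(self.per_charge.values()))


def _window(theoretical: float, tol_mode: str, tol: float) -> float:
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    if tol_mode == "ppm":
        return theoretical * tol * 1e-6
    if tol_mode == "Da":
        return tol
    raise ValueError(f"unknown tolerance mode {tol_mode!r} (expected 'ppm' or 'Da')")


def _best_peak(
    s: Spectrum, theoretical: float, tol_mode: str, tol: float
) -> tuple[float, float] | None:
    """(m/z, intensity) of the in-window peak with smallest |mass error|.

    Equal |error| ties are broken toward the higher-intensity peak.
    """
    half = _window(theoretical, tol_mode, tol)
    lo = np.searchsorted(s.mz, theoretical - half, side="left")
    hi = np.searchsorted(s.mz, theoretical + half, side="right")
    if lo == hi:
        return None
    idx = min(
        range(lo, hi),
        key=lambda i: (abs(s.mz[i] - theoretical), -s.intensity[i]),
    )
    return float(s.mz[idx]), float(s.intensity[idx])


def match_ions(
    s: Spectrum,
    targets: Sequence[FragmentIon],
    tol_mode: str = "ppm",
    tol: float = 10.0,
) -> list[IonMatch]:
    """Match theoretical fragment ions against one MS/MS scan.

    For each target the in-window peak with the smallest absolute mass
    error is taken; no signal-to-noise threshold is applied. Targets
    with no peak in the window yield no match.
    """
    if s.ms_level != 2:
        raise ValueError("match_ions expects an MS/MS (ms_level=2) scan")
    out: list[IonMatch] = []
    for t in targets:
        hit = _best_peak(s, t.mz, tol_mode, tol)
        if hit is None:
            continue
        obs, inten = hit
        err = ppm_error(obs, t.mz) if tol_mode == "ppm" else obs - t.mz
        out.append(
            IonMatch(
                target=t,
                scan_id=s.scan_id,
                rt=s.rt,
                observed_mz=obs,
                intensity=inten,
                mass_error=err,
                tol_mode=tol_mode,
            )
        )
    return out


def simc(
    run: Run,
    group: IsobaricGroup,
    precursor_charge: int = 3,
    iso_window: float = 2.0,
    series: Iterable[str] = ("y",),
    fragment_charges: Iterable[int] = (2,),
    tol_mode: str = "ppm",
    tol: float = 10.0,
    integration: str = "trapezoid",
    accept_unknown_charge: bool = False,
) -> QuantResult:
    """Quantify the constituent percentage of each isoform in a run.

    Defaults follow the validated method: doubly charged y ions as the
    quantification set, the triply charged precursor, a 2 Th isolation
    window and a 10 ppm match tolerance (use ``tol_mode='Da', tol=0.4``
    for low-resolution ion-trap MS/MS).

    Every selected scan contributes one trace point per isoform (zero
    height when none of that isoform's ions matched); per-isoform
    cumulative intensity is the trace's peak area over RT, and
    percentages are the cumulative values normalized to 100.
    """
    _window(100.0, tol_mode, tol)  # validate early
    if integration not in ("trapezoid", "sum"):
        raise ValueError("integration must be 'trapezoid' or 'sum'")
    specific = find_specific_ions(
        group, series_set=tuple(series), charge_set=tuple(fragment_charges)
    )
    if not any(specific.values()):
        raise ValueError("group has no specific ions for the requested series/charges")
    target_mz = group.precursor_mz(precursor_charge)
    scans = select_ms2(
        run,
        target_mz,
        charge=precursor_charge,
        iso_window=iso_window,
        accept_unknown_charge=accept_unknown_charge,
    )
    warnings_: list[str] = []
    traces = {iid: SIMCTrace(iid) for iid in group.isoforms}
    rows = []
    for s in scans:
        for iid, ions in specific.items():
            matches = match_ions(s, ions, tol_mode=tol_mode, tol=tol)
            traces[iid].points.append(
                (s.rt, float(sum(m.intensity for m in matches)))
            )
            for m in matches:
                rows.append(
                    {
                        "isoform": iid,
                        "ion": m.target.label,
                        "scan": m.scan_id,
                        "rt": m.rt,
                        "intensity": m.intensity,
                        "mz": round(m.observed_mz, 4),
                        "mass_error": m.mass_error,
                        "tol_mode": m.tol_mode,
                    }
                )
    ledger = pd.DataFrame(
        rows,
        columns=[
            "isoform", "ion", "scan", "rt", "intensity", "mz",
            "mass_error", "tol_mode",
        ],
    )
    if len(scans) < MIN_MS2_SCANS:
        warnings_.append(
            f"only {len(scans)} MS/MS scans contributed (fewer than "
            f"{MIN_MS2_SCANS}); quantification may be unstable"
        )
    cumulative = {
        iid: (t.cumulative if integration == "trapezoid" else t.summed())
        for iid, t in traces.items()
    }
    total = sum(cumulative.values())
    if total <= 0:
        warnings_.append("no specific-ion intensity observed; percentages undefined")
        percentages = None
    else:
        percentages = {iid: c / total * 100.0 for iid, c in cumulative.items()}
    return QuantResult(
        percentages=percentages,
        traces=traces,
        ledger=ledger,
        n_ms2_scans=len(scans),
        warnings=warnings_,
    )


def sic(
    run: Run,
    p: Peptide,
    charges: Iterable[int] = (1, 2, 3, 4),
    tol_mode: str = "ppm",
    tol: float = 10.0,
    peak_mode: str = "best",
) -> SICResult:
    """Selected-ion chromatogram area of a peptide, summed over charges.

    For each charge state, each MS1 scan contributes the intensity of
    the best-matching in-window peak (``peak_mode='sum'`` adds all
    in-window peaks instead); the per-charge trace is integrated by
    trapezoid over RT and the total is the sum over charge states.
    """
    if peak_mode not in ("best", "sum"):
        raise ValueError("peak_mode must be 'best' or 'sum'")
    ms1 = run.ms1()
    if not ms1:
        raise ValueError("run contains no MS1 scans; cannot compute a SIC")
    per_charge: dict[int, float] = {}
    for z in sorted(set(charges)):
        theo = precursor_mz(p, z)
        rts, vals = [], []
        for s in ms1:
            if peak_mode == "best":
                hit = _best_peak(s, theo, tol_mode, tol)
                inten = hit[1] if hit else 0.0
            else:
                half = _window(theo, tol_mode, tol)
                lo = np.searchsorted(s.mz, theo - half, side="left")
                hi = np.searchsorted(s.mz, theo + half, side="right")
                inten = float(s.intensity[lo:hi].sum())
            rts.append(s.rt)
            vals.append(inten)
        if len(rts) >= 2:
            area = float(np.trapezoid(np.array(vals), np.array(rts)))
        else:
            area = float(sum(vals))
        per_charge[z] = area
    return SICResult(peptide=p, per_charge=per_charge)


def relative_abundance(
    q: QuantResult, target_sic: SICResult, norm_sic: SICResult
) -> dict[str, float]:
    """Normalized per-isoform abundance.

    Total MS1 amount of the target peptide (its SIC summed over charges)
    is split by the SIMC percentages and divided by the SIC of the
    normalization peptide.
    """
    if not q.defined:
        raise ValueError("quantification has undefined percentages")
    if norm_sic.total <= 0:
        raise ValueError(
            f"normalization peptide {norm_sic.peptide.name()} has zero SIC"
        )
    return {
        iid: target_sic.total * pct / 100.0 / norm_sic.total
        for iid, pct in q.percentages.items()
    }


def replicate_summary(results: Sequence[QuantResult]) -> pd.DataFrame:
    """Mean and sample standard deviation of percentages across replicates."""
    if len(results) < 2:
        raise ValueError("replicate summary needs at least two replicates")
    keysets = [frozenset(r.percentages or {}) for r in results]
    if len(set(keysets)) != 1 or not keysets[0]:
        raise ValueError("replicates must share one non-empty isoform set")
    rows = []
    for iid in sorted(keysets[0]):
        vals = [r.percentages[iid] for r in results]
        mean = sum(vals) / len(vals)
        sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (len(vals) - 1))
        rows.append({"isoform": iid, "mean": mean, "sd": sd, "n": len(vals)})
    return pd.DataFrame(rows).set_index("isoform")
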