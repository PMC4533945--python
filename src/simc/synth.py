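"""Seeded synthetic LC-MS/MS runs of coeluting isobaric isoform mixtures.

The generator emulates the data-dependent acquisition that the
quantification method consumes: MS1 scans carrying the shared precursor
envelope of an isobaric group (charges 1–4, Gaussian elution around
13.5 min) plus a constitutive normalization peptide, interleaved with
CID MS/MS scans triggered on the triply charged precursor. Fragment
intensities scale as mixing fraction x series/charge efficiency x a
per-scan, per-ion lognormal jitter (the "unstable fragmentation
efficiency" the method integrates over); doubly charged y ions dominate
by an order of magnitude. Random noise peaks (uniform in m/z,
exponential in intensity) exercise the smallest-mass-error selection
rule, and every written m/z carries Gaussian ppm error.

A ground-truth record (true fractions, per-scan written intensities,
per-charge MS1 areas) is returned alongside every run, so parameter
recovery can be asserted exactly.

What this emulates — and what it does not: real runs add isotope
envelopes, chimeric precursor selection and correlated (not
independent) fragmentation noise; recovery on these runs demonstrates
the pipeline's correctness, not instrument-level performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .chem import Peptide, peptide_mass, PROTON
from .fragments import CleavageRule, IsobaricGroup, digest, generate_fragments
from .histone import normalizer_d123_r128, pentamethyl_pair
from .spectra_io import Run, Spectrum

__all__ = ["SimulationConfig", "simulate_run", "simulate_digest_sample"]


def _default_isoforms() -> dict[str, Peptide]:
    return dict(pentamethyl_pair().isoforms)


@dataclass
class SimulationConfig:
    """Parameters of one synthetic run. Defaults emulate the validated
    acquisition: a single coeluting peak at ~13.5 min, a 3+-dominated
    precursor envelope, cycles of 1 MS1 + 3 MS/MS scans, y2+ fragments
    ten-fold more efficient than other series."""

    isoforms: Mapping[str, Peptide] = field(default_factory=_default_isoforms)
    fractions: Mapping[str, float] = field(
        default_factory=lambda: {"K27me3-K36me2": 0.5, "K27me2-K36me3": 0.5}
    )
    rt_center: float = 13.5  # min
    rt_sigma: float = 0.12  # min
    rt_start: float = 12.0
    rt_end: float = 14.8
    ms1_interval: float = 0.05  # min between MS1 scans
    ms2_per_cycle: int = 3
    precursor_charge: int = 3  # charge triggered for fragmentation
    envelope: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.05, 2: 0.10, 3: 0.55, 4: 0.30}
    )
    ms1_amplitude: float = 5e6
    ms2_amplitude: float = 1e6
    frag_efficiency: Mapping[tuple[str, int], float] = field(
        default_factory=lambda: {
            ("y", 2): 0.30,
            ("y", 1): 0.03,
            ("b", 1): 0.03,
            ("b", 2): 0.03,
        }
    )
    jitter_sigma: float = 0.3  # lognormal sigma, per ion per scan; 0 = noiseless
    noise_peaks: int = 30  # random peaks per scan; 0 = noiseless
    noise_mean: float = 200.0  # exponential intensity scale
    mz_range: tuple[float, float] = (300.0, 1600.0)
    ppm_sigma: float = 2.0  # Gaussian m/z error; 0 = exact masses
    normalizer: Peptide | None = field(default_factory=normalizer_d123_r128)
    normalizer_envelope: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.40, 2: 0.60}
    )
    normalizer_amplitude: float = 2e7
    normalizer_rt_center: float = 12.6
    normalizer_rt_sigma: float = 0.15
    seed: int = 0

    def noiseless(self) -> "SimulationConfig":
        """Copy with jitter, noise peaks and m/z error switched off."""
        return replace(self, jitter_sigma=0.0, noise_peaks=0, ppm_sigma=0.0)


def _gauss(rt: float, center: float, sigma: float) -> float:
    return float(np.exp(-0.5 * ((rt - center) / sigma) ** 2))


def simulate_run(
    cfg: SimulationConfig, seed: int | None = None
) -> tuple[Run, dict]:
    """Generate one run and its ground-truth record.

    The same config and seed reproduce the identical run. Raises if the
    mixing fractions do not sum to 1.
    """
    fractions = dict(cfg.fractions)
    if set(fractions) != set(cfg.isoforms):
        raise ValueError("fractions must be given for exactly the isoform ids")
    if abs(sum(fractions.values()) - 1.0) > 1e-9 or min(fractions.values()) < 0:
        raise ValueError(
            f"fractions must be non-negative and sum to 1, got {fractions}"
        )
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    group = IsobaricGroup(isoforms=dict(cfg.isoforms))

    # per-isoform fragment ladders (b/y, charges 1-2), merged on shared m/z
    ladders = {
        iid: generate_fragments(p, ("b", "y"), max_charge=2, isoform_id=iid)
        for iid, p in cfg.isoforms.items()
    }
    specific_y2: dict[str, set[float]] = {}
    from .fragments import find_specific_ions

    spec = find_specific_ions(group, ("y",), (2,))
    for iid, ions in spec.items():
        specific_y2[iid] = {round(f.mz, 6) for f in ions}

    spectra: list[Spectrum] = []
    scan_no = 0
    truth_scans: list[dict] = []
    frag_totals = {iid: 0.0 for iid in cfg.isoforms}
    y2_totals = {iid: 0.0 for iid in cfg.isoforms}
    ms1_rts: list[float] = []
    ms1_traces: dict[int, list[float]] = {z: [] for z in cfg.envelope}
    norm_traces: dict[int, list[float]] = {
        z: [] for z in (cfg.normalizer_envelope if cfg.normalizer else {})
    }

    def perturb(mz: float) -> float:
        if cfg.ppm_sigma <= 0:
            return mz
        return mz * (1.0 + rng.normal(0.0, cfg.ppm_sigma) * 1e-6)

    def noise(mzs: list[float], intens: list[float]) -> None:
        for _ in range(cfg.noise_peaks):
            mzs.append(float(rng.uniform(*cfg.mz_range)))
            intens.append(float(rng.exponential(cfg.noise_mean)))

    rt = cfg.rt_start
    while rt <= cfg.rt_end + 1e-9:
        # ---- MS1 scan
        scan_no += 1
        mzs: list[float] = []
        intens: list[float] = []
        g = _gauss(rt, cfg.rt_center, cfg.rt_sigma)
        ms1_rts.append(rt)
        for z, w in cfg.envelope.items():
            inten = cfg.ms1_amplitude * w * g
            ms1_traces[z].append(inten)
            if inten > 0:
                mzs.append(perturb((group.peptide_mass + z * PROTON) / z))
                intens.append(inten)
        if cfg.normalizer is not None:
            gn = _gauss(rt, cfg.normalizer_rt_center, cfg.normalizer_rt_sigma)
            nmass = peptide_mass(cfg.normalizer)
            for z, w in cfg.normalizer_envelope.items():
                inten = cfg.normalizer_amplitude * w * gn
                norm_traces[z].append(inten)
                if inten > 0:
                    mzs.append(perturb((nmass + z * PROTON) / z))
                    intens.append(inten)
        noise(mzs, intens)
        spectra.append(
            Spectrum(1, rt, mzs, intens, scan_id=f"scan={scan_no}")
        )
        # ---- MS/MS scans triggered on the selected precursor charge
        ms2_dt = cfg.ms1_interval / (cfg.ms2_per_cycle + 1)
        prec_mz = group.precursor_mz(cfg.precursor_charge)
        for k in range(cfg.ms2_per_cycle):
            scan_no += 1
            ms2_rt = rt + (k + 1) * ms2_dt
            g2 = _gauss(ms2_rt, cfg.rt_center, cfg.rt_sigma)
            # accumulate fragment peaks, merging ions shared across isoforms
            peaks: dict[float, float] = {}
            contrib = {iid: 0.0 for iid in cfg.isoforms}
            y2_contrib = {iid: 0.0 for iid in cfg.isoforms}
            for iid, ions in ladders.items():
                frac = fractions[iid]
                if frac <= 0:
                    continue
                for ion in ions:
                    eff = cfg.frag_efficiency.get((ion.series, ion.charge), 0.0)
                    if eff <= 0:
                        continue
                    jit = (
                        float(rng.lognormal(0.0, cfg.jitter_sigma))
                        if cfg.jitter_sigma > 0
                        else 1.0
                    )
                    inten = cfg.ms2_amplitude * g2 * frac * eff * jit
                    key = round(ion.mz, 6)
                    peaks[key] = peaks.get(key, 0.0) + inten
                    contrib[iid] += inten
                    if key in specific_y2[iid]:
                        y2_contrib[iid] += inten
            mzs = [perturb(mz) for mz in peaks]
            intens = list(peaks.values())
            noise(mzs, intens)
            sid = f"scan={scan_no}"
            spectra.append(
                Spectrum(
                    2,
                    ms2_rt,
                    mzs,
                    intens,
                    precursor_mz=prec_mz,
                    precursor_charge=cfg.precursor_charge,
                    scan_id=sid,
                )
            )
            truth_scans.append(
                {"scan": sid, "rt": ms2_rt, "specific_y2": dict(y2_contrib)}
            )
            for iid in cfg.isoforms:
                frag_totals[iid] += contrib[iid]
                y2_totals[iid] += y2_contrib[iid]
        rt += cfg.ms1_interval

    rts = np.array(ms1_rts)
    sic_areas = {
        z: float(np.trapezoid(np.array(v), rts)) for z, v in ms1_traces.items()
    }
    norm_areas = {
        z: float(np.trapezoid(np.array(v), rts)) for z, v in norm_traces.items()
    }
    truth = {
        "fractions": fractions,
        "fragment_intensity": frag_totals,
        "specific_y2_intensity": y2_totals,
        "ms1_areas": sic_areas,
        "ms1_total_area": float(sum(sic_areas.values())),
        "normalizer_areas": norm_areas,
        "normalizer_total_area": float(sum(norm_areas.values())),
        "ms2_scans": truth_scans,
        "precursor_mz": group.precursor_mz(cfg.precursor_charge),
    }
    return Run(spectra=spectra, metadata={"id": "synthetic"}), truth


def simulate_digest_sample(
    long_isoforms: Mapping[str, Peptide],
    fractions: Mapping[str, float],
    rule: CleavageRule | None = None,
    cfg: SimulationConfig | None = None,
    digestion_skew: Mapping[str, float] | None = None,
    seed: int | None = None,
) -> tuple[Run, dict]:
    """Digest long precursor peptides in silico, then simulate the run on
    the resulting quantifiable products.

    ``digestion_skew`` scales each isoform's effective yield (e.g. 0.95
    emulates a ~5% slower-digesting species); effective fractions are
    renormalized, so a skew of s on one of two equal species shifts its
    recovered share to s/(1+s).
    """
    rule = rule or CleavageRule()
    cfg = cfg or SimulationConfig()
    skew = dict(digestion_skew or {})
    products: dict[str, Peptide] = {}
    for iid, long_pep in long_isoforms.items():
        cands = [
            q
            for q in digest(long_pep, rule)
            if set(q.mods) == set(long_pep.mods)
        ]
        if not cands:
            raise ValueError(
                f"digestion of {long_pep.name()} yields no product retaining "
                "all modification sites"
            )
        products[iid] = min(cands, key=lambda q: len(q.sequence))
    weights = {
        iid: fractions[iid] * skew.get(iid, 1.0) for iid in long_isoforms
    }
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("effective fractions are all zero")
    eff_fractions = {iid: w / total for iid, w in weights.items()}
    run_cfg = replace(cfg, isoforms=products, fractions=eff_fractions)
    run, truth = simulate_run(run_cfg, seed=seed)
    truth["input_fractions"] = dict(fractions)
    truth["digestion_skew"] = skew
    truth["products"] = {iid: p.name() for iid, p in products.items()}
    return run, truth
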