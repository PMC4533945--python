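"""The quantification core: smallest-error ion matching, per-isoform
chromatograms and percentages, MS1 selected-ion areas, normalization."""

import numpy as np
import pytest

from simc.fragments import FragmentIon, find_specific_ions
from simc.histone import k27_r40, normalizer_d123_r128, pentamethyl_pair
from simc.quant import (
    match_ions,
    relative_abundance,
    replicate_summary,
    sic,
    simc,
)
from simc.spectra_io import Run, Spectrum


def ms2(rt, peaks, scan_id="s", precursor=501.9755, charge=3):
    mz = sorted(peaks)
    return Spectrum(2, rt, mz, [peaks[k] for k in mz],
                    precursor_mz=precursor, precursor_charge=charge,
                    scan_id=scan_id)


Y13A = FragmentIon("y", 13, 2, 667.3886, "A")


class TestMatchIons:
    def test_smallest_error_wins_among_in_window_peaks(self):
        # both peaks within 10 ppm; 667.3890 (+0.6 ppm) beats 667.3950 (+9.6)
        s = ms2(13.3, {667.3890: 1e5, 667.3950: 5e4})
        (m,) = match_ions(s, [Y13A], "ppm", 10.0)
        assert m.observed_mz == pytest.approx(667.3890)
        assert m.mass_error == pytest.approx(0.60, abs=0.01)
        assert m.intensity == 1e5

    def test_no_peak_in_window_gives_no_match(self):
        s = ms2(13.3, {668.0: 1e5})
        assert match_ions(s, [Y13A], "Da", 0.4) == []

    def test_equal_error_tie_breaks_to_higher_intensity(self):
        s = ms2(13.3, {667.3886 - 0.01: 10.0, 667.3886 + 0.01: 99.0})
        (m,) = match_ions(s, [Y13A], "Da", 0.4)
        assert m.intensity == 99.0

    def test_da_mode_records_da_error(self):
        s = ms2(13.3, {667.40: 5.0})
        (m,) = match_ions(s, [Y13A], "Da", 0.4)
        assert m.mass_error == pytest.approx(667.40 - 667.3886, abs=1e-9)

    def test_requires_ms2_scan(self):
        s1 = Spectrum(1, 0.0, [667.389], [1.0])
        with pytest.raises(ValueError):
            match_ions(s1, [Y13A])


def build_run(scan_specs, ms1=()):
    """scan_specs: list of (rt, intensity_A, intensity_B) written onto the
    two isoforms' specific y2+ ions."""
    pair = pentamethyl_pair()
    spec = find_specific_ions(pair, ("y",), (2,))
    spectra = [
        Spectrum(1, rt, mzs, ints, scan_id=f"ms1-{i}")
        for i, (rt, mzs, ints) in enumerate(ms1)
    ]
    for i, (rt, ia, ib) in enumerate(scan_specs):
        peaks = {}
        for f in spec["K27me3-K36me2"]:
            peaks[f.mz] = ia
        for f in spec["K27me2-K36me3"]:
            peaks[f.mz] = ib
        spectra.append(ms2(rt, peaks, scan_id=f"ms2-{i}"))
    return Run(spectra=spectra), pair


class TestSimc:
    def test_pure_isoform_yields_100_0(self):
        run, pair = build_run([(13.3, 1e5, 0.0), (13.4, 2e5, 0.0)])
        q = simc(run, pair)
        assert q.percentages["K27me3-K36me2"] == pytest.approx(100.0)
        assert q.percentages["K27me2-K36me3"] == pytest.approx(0.0)

    def test_equal_intensities_yield_50_50(self):
        run, pair = build_run([(13.3, 5e4, 5e4), (13.4, 8e4, 8e4)])
        q = simc(run, pair)
        assert q.percentages["K27me3-K36me2"] == pytest.approx(50.0)

    def test_matches_hand_tally_on_tiny_run(self):
        # 9 specific y2+ ions per isoform, per-scan sum = 9*h; trapezoid
        # over two scans 0.1 min apart: area = 0.1*(sum0+sum1)/2
        run, pair = build_run([(13.3, 10.0, 30.0), (13.4, 20.0, 20.0)])
        q = simc(run, pair)
        area_a = 0.1 * (9 * 10 + 9 * 20) / 2
        area_b = 0.1 * (9 * 30 + 9 * 20) / 2
        assert q.percentages["K27me3-K36me2"] == pytest.approx(
            100 * area_a / (area_a + area_b)
        )
        # ledger mirrors the matched ions: 2 scans x 2 isoforms x 9 ions
        assert len(q.ledger) == 36
        assert set(q.ledger.columns) >= {
            "isoform", "scan", "rt", "intensity", "mz", "mass_error"
        }

    def test_sum_integration_alternative(self):
        run, pair = build_run([(13.3, 10.0, 0.0), (13.4, 20.0, 10.0)])
        q = simc(run, pair, integration="sum")
        assert q.percentages["K27me3-K36me2"] == pytest.approx(
            100 * 30 / 40
        )

    def test_zero_signal_flagged_not_divided(self):
        run, pair = build_run([(13.3, 0.0, 0.0)])
        q = simc(run, pair)
        assert q.percentages is None
        assert not q.defined
        assert any("undefined" in w for w in q.warnings)

    def test_few_scans_warning(self):
        run, pair = build_run([(13.3, 1.0, 1.0)] )
        q = simc(run, pair)
        assert any("MS/MS scans" in w for w in q.warnings)

    def test_label_swap_swaps_percentages(self):
        run, pair = build_run([(13.3, 10.0, 30.0), (13.4, 25.0, 15.0)])
        q = simc(run, pair)
        swapped = pentamethyl_pair()
        swapped.isoforms = {
            "K27me3-K36me2": swapped.isoforms["K27me2-K36me3"],
            "K27me2-K36me3": swapped.isoforms["K27me3-K36me2"],
        }
        q2 = simc(run, swapped)
        assert q.percentages["K27me3-K36me2"] == pytest.approx(
            q2.percentages["K27me2-K36me3"]
        )


class TestSic:
    def make_ms1_run(self, heights, peptide, z=3, rts=None):
        from simc.chem import precursor_mz as pmz

        mz = pmz(peptide, z)
        rts = rts or [13.0 + 0.1 * i for i in range(len(heights))]
        spectra = [
            Spectrum(1, rt, [mz], [h], scan_id=f"ms1-{i}")
            for i, (rt, h) in enumerate(zip(rts, heights))
        ]
        return Run(spectra=spectra)

    def test_single_charge_species(self):
        p = k27_r40(3, 2)
        run = self.make_ms1_run([10.0, 20.0, 10.0], p, z=3)
        res = sic(run, p, charges=(1, 2, 3, 4))
        assert res.per_charge[3] == pytest.approx(np.trapezoid(
            [10, 20, 10], [13.0, 13.1, 13.2]
        ))
        assert res.per_charge[1] == res.per_charge[2] == res.per_charge[4] == 0
        assert res.total == res.per_charge[3]

    def test_linearity_in_intensity(self):
        p = k27_r40(3, 2)
        r1 = self.make_ms1_run([5.0, 10.0, 5.0], p)
        r2 = self.make_ms1_run([10.0, 20.0, 10.0], p)
        assert sic(r2, p).total == pytest.approx(2 * sic(r1, p).total)

    def test_no_ms1_is_error(self):
        run, pair = build_run([(13.3, 1.0, 1.0)])
        with pytest.raises(ValueError, match="MS1"):
            sic(run, k27_r40(3, 2))


class TestRelativeAbundance:
    def _quant(self, pa=85.0, pb=15.0):
        run, pair = build_run([(13.3, pa, pb), (13.4, pa, pb)])
        return simc(run, pair)

    def test_arithmetic_contract(self):
        q = self._quant()
        t = sic_result(10.0)
        n = sic_result(100.0)
        ab = relative_abundance(q, t, n)
        assert ab["K27me3-K36me2"] == pytest.approx(0.085)
        assert ab["K27me2-K36me3"] == pytest.approx(0.015)

    def test_scaling_law(self):
        q = self._quant()
        t = sic_result(10.0)
        ab1 = relative_abundance(q, t, sic_result(100.0))
        ab2 = relative_abundance(q, t, sic_result(300.0))
        for k in ab1:
            assert ab2[k] == pytest.approx(ab1[k] / 3)

    def test_zero_normalizer_is_error(self):
        with pytest.raises(ValueError, match="zero"):
            relative_abundance(self._quant(), sic_result(10.0), sic_result(0.0))


def sic_result(total):
    from simc.quant import SICResult

    return SICResult(peptide=normalizer_d123_r128(), per_charge={1: total})


class TestReplicateSummary:
    def _quant(self, pa):
        run, pair = build_run([(13.3, pa, 100 - pa), (13.4, pa, 100 - pa)])
        return simc(run, pair)

    def test_identical_replicates_have_zero_sd(self):
        df = replicate_summary([self._quant(60.0)] * 3)
        assert (df["sd"] == 0).all()

    def test_sample_sd_of_40_50_60(self):
        reps = [self._quant(p) for p in (40.0, 50.0, 60.0)]
        df = replicate_summary(reps)
        assert df.loc["K27me3-K36me2", "mean"] == pytest.approx(50.0)
        assert df.loc["K27me3-K36me2", "sd"] == pytest.approx(10.0)

    def test_single_replicate_is_error(self):
        with pytest.raises(ValueError):
            replicate_summary([self._quant(50.0)])
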