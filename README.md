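# simc — quantifying isobaric peptide isoforms from their specific fragment ions

Positional isomers of modified peptides that share the same total
modification mass — *isobaric* peptides — coelute in reversed-phase LC
and are indistinguishable at the MS1 level. The canonical case is the
pentamethylated histone H3 peptide K27–R40 (K₂₇SAPATGGVKKPHR₄₀ + 5
methyls), which exists as **K27me3-K36me2** and **K27me2-K36me3**: two
biologically opposite chromatin marks with the identical precursor, m/z
501.9755 at 3+.

They *fragment* differently. Any y ion covering K36 but not K27
(y5–y13), and any b ion covering K27 but not K36 (b1–b9), shifts by
k·14.0157/z between the isoforms. `simc` quantifies the constituent
percentage of each isoform by summing the intensities of its specific
ions (by default the doubly charged y ions, matched at 10 ppm with the
smallest-mass-error rule and no signal-to-noise cutoff) across **all**
MS/MS scans of the shared precursor, integrating each isoform's
summed-intensity chromatogram over retention time, and normalizing:

```
pct(i) = 100 · ∫ Σ_ions I_i(t) dt / Σ_j ∫ Σ_ions I_j(t) dt
```

Around that core the package provides:

- monoisotopic mass chemistry for site-resolved modifications
  (methyl/acetyl/phospho/oxidation) in protein numbering;
- b/y fragment-ion generation and automatic discovery of the
  discriminating "specific ions" of any isobaric group;
- methylation-aware in-silico trypsin digestion (cuts after K/R, never
  before P; me2/me3/acetyl-lysine block, monomethyl does not);
- MS1 selected-ion chromatograms (SIC) summed over charge states, and
  normalization to a constitutive peptide (H3 D123–R128, DIQLAR) to
  convert percentages into relative abundances;
- mzML/MGF I/O and a seeded synthetic-run generator with ground truth,
  so the whole pipeline is testable without instrument data;
- a `simc` command-line tool (`simulate`, `quantify`, `sic`, `digest`,
  `fragments`, `report`).

## Worked example

```python
from simc import pentamethyl_pair, simc as quantify
from simc.synth import SimulationConfig, simulate_run

A, B = "K27me3-K36me2", "K27me2-K36me3"
cfg = SimulationConfig(fractions={A: 0.75, B: 0.25}, seed=42)
run, truth = simulate_run(cfg)           # synthetic 3:1 mixture
q = quantify(run, pentamethyl_pair())    # y2+ specific-ion quantification
print(q.percentages)
```

Running the bundled mixing series (`python examples/02_simulate_and_quantify.py`)
prints:

```
 mixture   true %  recovered %  MS2 scans
     1:0   100.00       100.00        171
     6:1    85.71        85.09        171
     3:1    75.00        74.05        171
     1:1    50.00        48.75        171
     1:3    25.00        24.07        171
     0:1     0.00         0.00        171
```

Each row compares the generator's true share of K27me3-K36me2 with the
percentage recovered from its specific-ion chromatograms under
fragmentation jitter, noise peaks and ppm mass error; with the noise
switched off the recovery is exact. The remaining `examples/` scripts
show specific-ion discovery, digestion behaviour, and the full
replicate report with SIC normalization.

## Layout

| path | contents |
| --- | --- |
| `src/simc/chem.py` | residue masses, modifications, peptide mass, m/z |
| `src/simc/fragments.py` | b/y ladders, specific ions, tryptic digestion |
| `src/simc/spectra_io.py` | mzML/MGF reading and writing, scan selection |
| `src/simc/quant.py` | specific-ion quantification, SIC, normalization |
| `src/simc/synth.py` | seeded synthetic-run generator with ground truth |
| `src/simc/pipeline.py`, `src/simc/cli.py` | end-to-end analysis and CLI |
| `docs/methods.md` | model, parameters, numerical choices, limitations |
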