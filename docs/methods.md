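# Methods

## The quantification model

Two (or more) isoforms of an isobarically modified peptide share the
elemental composition, hence every precursor charge state, and coelute
in reversed-phase LC. Each MS/MS scan of the shared precursor is
therefore a *mixture spectrum*: fragment ions whose residue window
contains an unequal share of the differing modification sites appear at
isoform-specific m/z, with intensities proportional to (isoform amount
in the selected population) × (fragmentation efficiency of that ion).

Per-scan ratios of a single ion pair are unstable because fragmentation
efficiency varies scan to scan. The method integrates over both sources
of variance:

1. **ion set** — all specific ions of one series and charge are summed
   per scan (default: the doubly charged y ions; for the H3 K27-R40
   pentamethyl pair, y5–y13²⁺). The defaults follow the empirical
   finding that y²⁺ ions dominate CID spectra of the 3+ precursor and
   track composition, while y¹⁺/b¹⁺/b²⁺ are sporadic; those series
   remain available as diagnostics via `series`/`fragment_charges`.
2. **scan set** — every MS/MS scan whose precursor lies in the
   isolation window contributes one point per isoform to a
   summed-intensity chromatogram; the per-isoform quantity is the
   chromatogram's peak area over retention time.

Percentage(i) = 100 · area(i) / Σⱼ area(j). Relative abundance scales
the target peptide's MS1 amount (selected-ion chromatogram summed over
charge states 1–4) by the percentages and divides by the SIC of a
constitutive normalization peptide (H3 D123–R128, DIQLAR, charges
1–2), making values comparable across samples of differing digestion
efficiency and loading.

## Ion matching

Candidate peaks within the tolerance window of each theoretical m/z
are ranked by absolute mass error; the smallest-error peak is taken,
with ties broken toward the higher-intensity peak (deterministic, and
favors signal). **No signal-to-noise threshold is applied** — absence
of a peak simply contributes zero. Tolerances: 10 ppm for
high-resolution MS/MS, 0.4 Da for ion-trap data; the mode is chosen
per analysis, never auto-detected.

## Key parameters

| parameter | default | meaning |
| --- | --- | --- |
| `tol_mode`, `tol` | `ppm`, 10 | fragment/precursor match window (0.4 Da for low-res) |
| `iso_window` | 2.0 Th | full isolation-window width; acceptance is ±1.0 |
| `series`, `fragment_charges` | `y`, `{2}` | quantification ion set |
| `precursor_charge` | 3 | charge state targeted for fragmentation |
| `sic_charges` | 1–4 | charge states summed for the target's MS1 amount |
| `normalizer_charges` | 1–2 | charge states summed for DIQLAR |
| `integration` | trapezoid | peak area over RT; `sum` = plain per-scan tally |
| `CleavageRule.max_missed_cleavages` | 5 | tryptic missed-cleavage depth |

Masses: standard monoisotopic residue masses; water 18.010565 Da,
proton 1.007276 Da (charging uses protons — this is what reproduces
the 3+ precursor at 501.9755); methyl 14.015650, acetyl 42.010565,
phospho 79.966331, oxidation 15.994915 Da. m/z is reported to 4
decimals; internal arithmetic is full double precision. Mass sums
accumulate modification deltas in a placement-independent order so
isobaric placements agree bitwise.

## Numerical and design choices

- **Peak area** is trapezoidal integration over RT in minutes — robust
  to uneven scan spacing; scans with no matched intensity contribute
  zero-height points so traces share one RT grid. Traces with a single
  point fall back to the plain sum.
- **Specificity tolerance**: theoretical fragment m/z within 1e-6 Da
  count as equal; a slot is specific only when every isoform pair
  differs, so each reported ion genuinely discriminates.
- **Unknown precursor charge** (common in MGF) excludes a scan from
  charge-filtered selection unless explicitly accepted, since the
  method targets one charge state.
- **SIC** takes the best-matching peak per MS1 scan (sum-all-in-window
  behind `peak_mode="sum"`) and integrates the whole run without RT
  gating.
- **Trypsin rule**: cleave after K/R, blocked before P; K with me≥2 or
  acetyl blocks, monomethyl-K cleaves. Acetyl blocking is a standard
  assumption; arginine methylation is not treated as blocking. Digest
  products keep protein numbering so modified sites stay addressable.
- **Zero total intensity** yields explicitly undefined percentages plus
  a flag, never 0/0. Fewer than 6 contributing MS/MS scans, or fewer
  than 22 MS1 points behind a SIC, emits a stability warning.
- mzML parsing is a hand-written streaming reader (lxml iterparse;
  64/32-bit float arrays, optional zlib) paired with a minimal writer
  (uncompressed 64-bit, little-endian); the two round-trip to 1e-4 m/z.
  MGF goes through pyteomics. RTs are normalized to minutes.

## The synthetic-run generator

`synth.simulate_run` emulates the acquisition the method consumes:
cycles of 1 MS1 + 3 MS/MS scans every 0.05 min over 12.0–14.8 min; a
single coeluting Gaussian peak (center 13.5 min, σ 0.12 min) carrying
the precursor envelope {1+: 5%, 2+: 10%, 3+: 55%, 4+: 30%}; MS/MS
triggered on the 3+ precursor. Fragment intensity = amplitude ×
elution × mixing fraction × series efficiency × lognormal per-ion
jitter (σ 0.3); y²⁺ efficiency is 10× the other series. Each scan adds
30 noise peaks (uniform m/z over 300–1600, exponential intensity) and
every m/z carries Gaussian error (σ 2 ppm). The jitter magnitude is a
free parameter — real per-scan variability is only qualitatively
characterized — and the noise model is deliberately the simplest that
exercises the smallest-error selection rule. A DIQLAR normalizer peak
(charges 1–2, center 12.6 min) is included by default. The generator
returns exact bookkeeping (per-scan written intensities, per-charge
MS1 areas, true fractions), and a fixed seed reproduces the run
exactly.

What passing recovery tests on these runs shows: the selection,
matching, tracing, integration and normalization chain is correct and
unbiased under independent multiplicative noise. What they do not
show: robustness to isotope envelopes, chimeric precursor selection,
correlated fragmentation drift, or detector saturation — none of which
the generator models.

`simulate_digest_sample` first digests long precursor species in
silico (keeping the shortest product that retains all modified sites),
optionally skewing per-isoform digestion efficiency; a skew *s* on one
of two equal species shifts its recovered share to s/(1+s).

## Problem sizes

Tests and examples use runs of 57 MS1 + 171 MS/MS scans per condition
(about 29 MS/MS scans carry appreciable signal through the elution
peak); the mixture-recovery suite covers six mixing ratios × three
seeds plus noiseless runs, and randomized invariant suites run several
hundred cases. These sizes make the full suite run in seconds while
leaving every scan count above the stability thresholds.

## Limitations

- Identification is assumed: the isobaric group's candidate isoforms
  are inputs, not inferred (no database search, no localization score,
  no FDR).
- Only b/y fragments (CID) are generated — no a/x/c/z, no neutral
  losses; quantification presumes the specific ions are resolvable at
  the configured tolerance.
- No MS1 isotope-envelope deconvolution and no cross-run RT alignment;
  replicates are summarized, not aligned.
- Isoforms whose differing sites are adjacent leave very few specific
  slots (a single y/b pair), where the averaging that stabilizes the
  method cannot operate.
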