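"""Find the fragment ions that discriminate two isobaric isoforms.

The pentamethylated histone H3 K27-R40 peptide (KSAPATGGVKKPHR + 5
methyls) exists as K27me3-K36me2 and K27me2-K36me3. Both isoforms have
the same mass and precursor m/z, so MS1 cannot tell them apart — but
every y ion covering K36 without K27 (y5-y13), and every b ion covering
K27 without K36 (b1-b9), shifts by a multiple of 14.0157/z between
them.
"""

from simc import find_specific_ions, peptide_mass, pentamethyl_pair, precursor_mz

pair = pentamethyl_pair()
for iid, p in pair.isoforms.items():
    print(f"{iid}: mass {peptide_mass(p):.4f} Da, "
          f"3+ precursor m/z {precursor_mz(p, 3):.4f}")

spec = find_specific_ions(pair, series_set=("b", "y"), charge_set=(1, 2))
print("\ndiscriminating y2+ ions (the quantification set):")
for iid, ions in spec.items():
    y2 = {f.index: f.mz for f in ions if f.series == "y" and f.charge == 2}
    row = "  ".join(f"y{i}={mz:.4f}" for i, mz in sorted(y2.items()))
    print(f"  {iid}\n    {row}")

# Both isoforms print identical precursor m/z (501.9755) yet their y13 2+
# ions differ by 7.008 Th (one methyl over two charges) -- that difference
# is what the quantification reads out.
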