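"""Methylation-aware in-silico trypsin digestion.

Trypsin cuts after K/R (never before proline) and is blocked by di-/
trimethyl- and acetyl-lysine, while monomethyl-lysine remains
cleavable. Digesting the long H3 L20-R52 peptide therefore keeps
K27-R40 intact exactly when K27 carries two or more methyls — which is
why tryptic digestion enriches the highly methylated forms the
quantification targets.
"""

from simc import CleavageRule, digest, l20_r52

rule = CleavageRule(max_missed_cleavages=0)
for k27, k36 in [(3, 2), (2, 3), (1, 2), (0, 0)]:
    p = l20_r52(k27, k36)
    products = digest(p, rule)
    spans = ", ".join(
        f"{q.start_position}-{q.end_position}" for q in products
    )
    keeps = any(
        (q.start_position, q.end_position) == (27, 40) for q in products
    )
    print(f"K27me{k27}/K36me{k36}: fully cleaved -> {spans}")
    print(f"    K27-R40 retained: {keeps}")

# With K27me>=2 the K27-R40 peptide survives full digestion (K37-P38 is
# protected by the proline rule); hypomethylated K27 is cut, splitting
# the two sites into separate products.
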