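"""Test whether affinity-optimizing SNVs are enriched for GOF expression.

Simulates a saturation-mutagenesis MPRA over a 300-bp enhancer (all 900
substitutions) in which 36% of affinity-optimizing SNVs carry a +1.5 SD
expression shift, then runs the grouped enrichment analysis: classify
every SNV, BH-adjust the p values, and compare the direction-signed
-log10(p_adj) of the optimizing group against everything else with a
one-tailed Mann-Whitney U test.
"""

from affopt import ETS, GeneratorConfig, gen_enhancer, gen_mpra_table, \
    gen_pbm_table, run_mpra_enrichment

cfg = GeneratorConfig(seed=1, effect_size=1.5)
table = gen_pbm_table(cfg)
seq, _ = gen_enhancer(cfg, ETS)
assoc, truth = gen_mpra_table(cfg, seq, table, ETS)

report = run_mpra_enrichment({"enh": seq}, assoc, ETS, table)

print(f"{report.n_records} SNVs analysed; groups: {report.group_counts}")
for name, cmp in report.comparisons.items():
    print(f"{name}: U={cmp.U:.0f}, one-tailed p={cmp.p_one_tailed:.2e} "
          f"({cmp.method})")
print("GOF rates:", {k: None if v is None else round(v, 3)
                     for k, v in report.gof_rates.items()})
if report.enrichment:
    e = report.enrichment
    print(f"fold enrichment (optimizing vs all): {e['fold_enrichment']:.2f} "
          f"(Fisher p={e['fisher_p']:.2e})")

print("\nA small optimizing-vs-other p with a neutral-vs-other p near 1 "
      "means the gain-of-function signal is specific to SNVs that increase "
      "binding affinity, not to merely sitting inside a binding site.")
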