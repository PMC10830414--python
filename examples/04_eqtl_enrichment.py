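"""eQTL-style enrichment with Bonferroni adjustment and gene reduction.

Simulates an association table where variants carry signed betas on target
genes (a minority associated with two genes), Bonferroni-adjusts raw p
values over the study-wide number of tests, keeps each variant's most
significant gene, and asks whether affinity-optimizing SNVs are enriched
for positive-beta (increased-expression) associations - stratifying over
increasing fold-change cutoffs.
"""

from affopt import ETS, GeneratorConfig, gen_enhancer, gen_eqtl_table, \
    gen_pbm_table, run_eqtl_enrichment

cfg = GeneratorConfig(seed=2, effect_size=1.5, gof_fraction=1.0)
table = gen_pbm_table(cfg)
seq, _ = gen_enhancer(cfg, ETS)
assoc, _ = gen_eqtl_table(cfg, seq, table, ETS)

report = run_eqtl_enrichment({"enh": seq}, assoc, ETS, table,
                             m_total_tests=cfg.m_tests)

print(f"{len(assoc)} association rows -> {report.n_records} variants after "
      "most-significant-gene reduction")
print(f"adjustment: {report.adjustment}; groups: {report.group_counts}")
cmp = report.comparisons["optimizing_vs_other"]
print(f"optimizing vs other: one-tailed MWU p={cmp.p_one_tailed:.2e}")
print("stratified by minimum fold change:")
for s in report.stratified:
    p = "n/a" if s["p"] is None else f"{s['p']:.2e}"
    print(f"  fold >= {s['fold_cutoff']}: n={s['n_optimizing']}, p={p}")

print("\nEnrichment that persists (or sharpens) at higher fold cutoffs "
      "indicates that larger affinity gains drive stronger increases in "
      "target-gene expression.")
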