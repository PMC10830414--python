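# affopt

Affinity-optimizing enhancer variant analysis: PBM-derived relative-affinity
scoring of transcription-factor binding sites, SNV fold-change
classification, and enrichment testing of gain-of-function expression in
MPRA and eQTL variant tables.

## The problem

Enhancers are littered with sequence variation, and deciding which
single-nucleotide variants (SNVs) are causal is a central problem in
regulatory genomics. Many functional binding sites are *low-affinity* —
bound at 10–40% of a factor's optimal strength — and are invisible to
conventional thresholded motif scans. Yet a subtle variant that nudges a
weak site toward the optimum can be enough to drive ectopic, pathogenic
gene expression. `affopt` implements that logic as a reusable pipeline for
anyone analysing enhancer variants: MPRA analysts prioritizing hits,
human geneticists triaging eQTL or disease variants, and developmental
biologists dissecting enhancer architecture.

## The method

1. **Relative affinity.** A universal protein-binding microarray (PBM)
   measures a factor's median signal intensity for every 8-mer. The
   relative affinity of 8-mer *w* is

   *a(w) = I(w) / max<sub>v</sub> I(v)* ∈ (0, 1],

   so the optimal site scores exactly 1.00. Lookup is strand-symmetric:
   *a(w) = a(revcomp(w))*.

2. **Site scanning.** Binding-site families are defined by degenerate
   8-base cores (ETS = `NNGGAWNN`, AP-1 = `NTKANNMA`, IRF = `NWNNGANA`).
   Every matching window, on either strand, is a putative site carrying its
   PBM affinity — no affinity threshold is applied, which is precisely what
   lets low-affinity sites be seen.

3. **SNV classification.** For an SNV, every covering window is rescored
   with the reference and alternate allele; the per-window fold change is
   *a(alt)/a(ref)*. An SNV is **affinity-optimizing** when some window
   reaches the family threshold (≥1.59× for ETS, ≥1.5× for AP-1/IRF),
   **neutral in site** when all folds lie in [0.8, 1.25], with further
   labels for decreasing, de-novo-site and site-ablating changes.

4. **Enrichment.** Joining classifications to expression associations
   (MPRA effects with Benjamini–Hochberg-adjusted p, or eQTL betas with
   Bonferroni adjustment over the study-wide test count and a
   most-significant-gene reduction), the pipeline compares the
   direction-signed −log₁₀ p<sub>adj</sub> of affinity-optimizing SNVs
   against all other SNVs with a one-tailed Mann–Whitney U test, and
   reports gain-of-function (GOF: p<sub>adj</sub> < 0.05 and direction up)
   rates and the fold enrichment of the optimizing group over all SNVs.

5. **Affinity–occupancy correlation.** Predicted sites are binned by
   affinity (0–0.1, …, 0.9–1.0), window-mean ChIP-style signal is averaged
   per (bin, chromosome), and Spearman's ρ over all points asks whether in
   vitro affinity predicts in vivo occupancy.

A first-class synthetic-data generator (`affopt.simulate`) produces every
input format — UniProbe-dialect PBM tables, FASTA enhancers with planted
sites, saturation-mutagenesis MPRA tables, eQTL tables, bedGraph tracks —
with known ground truth, so the whole pipeline is verifiable at desk scale.

## Worked example

```bash
python examples/03_mpra_enrichment.py
```

simulates a saturation-mutagenesis MPRA over a 300-bp enhancer (all 900
substitutions; 36% of affinity-optimizing SNVs carry a +1.5 SD expression
shift) and prints:

```
900 SNVs analysed; groups: {'optimizing': 29, 'in-site-no-change': 48, 'all-other': 823}
optimizing_vs_other: U=16181, one-tailed p=4.96e-03 (asymptotic)
neutral_vs_other: U=20446, one-tailed p=5.01e-01 (asymptotic)
GOF rates: {'optimizing': 0.448, 'in-site-no-change': 0.188, 'all-other': 0.226, 'all': 0.231}
fold enrichment (optimizing vs all): 1.94 (Fisher p=1.14e-02)
```

The optimizing group is significantly shifted toward gain-of-function
expression (p ≈ 0.005) while merely sitting inside a binding site is not
(p ≈ 0.5) — the enrichment is specific to affinity gains. The other
examples cover site scanning (`01`), per-SNV classification (`02`), the
eQTL stage with Bonferroni adjustment and fold-change stratification
(`04`), and the binned affinity–occupancy Spearman correlation (`05`).

A thin CLI mirrors the library stages:

```bash
affopt simulate --seed 7 --out demo/
affopt scan --fasta demo/enhancer.fa --pbm demo/pbm_8mers.tsv --out demo/scan/
affopt mpra-enrich --fasta demo/enhancer.fa --pbm demo/pbm_8mers.tsv \
    --associations demo/mpra.tsv --out demo/enrich/
```

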