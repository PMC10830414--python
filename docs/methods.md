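# Methods

## Relative affinity from PBM tables

The quantitative backbone is the protein-binding microarray (PBM) 8-mer
table: for a given transcription factor, every 8-mer's median signal
intensity, normalized by the maximum over all 8-mers, gives a relative
affinity in (0, 1]. The reader accepts the UniProbe "8mers" tab-separated
dialect (forward 8-mer, reverse-complement 8-mer, E-score, median
intensity, Z-score; header auto-detected) and normalizes on the
median-intensity column — the E-score is a rank-based enrichment statistic
and is not proportional to binding strength, so it is tolerated but
ignored. The column choice is configurable for non-standard exports.

Rows with missing or non-positive intensity are dropped before
normalization (a relative affinity must be a positive fraction); the count
is logged. Duplicate 8-mers with conflicting intensities are an error
naming the 8-mer. Strand collapsing happens at *lookup* (max of the two
orientations), not at load, so tables whose two orientation columns
disagree remain usable. An unknown 8-mer raises an error rather than
returning 0: a silent zero would silently corrupt every downstream fold
change. Ties at the maximal intensity are allowed and all tied 8-mers
score 1.0; nothing downstream assumes a unique optimum.

## Site scanning

Families are degenerate 8-base cores over the codes A, C, G, T, N ({ACGT}),
W ({AT}), K ({GT}), M ({AC}): ETS = `NNGGAWNN`, AP-1 = `NTKANNMA`,
IRF = `NWNNGANA`. Every 8-base window on either strand whose
motif-orientation 8-mer fits the core is reported as a site with its
affinity; overlapping windows and both-strand matches are all reported as
separate records. Whether such records should be merged into "one site" is
a bookkeeping convention with no effect on the variant analysis, so a
merged-interval count is provided alongside (`merged_site_intervals`) for
comparison with window counts. Windows containing N are skipped (masked
reference tolerated). Coordinates are 0-based half-open internally;
writers emit 1-based columns alongside, labelled.

Cross-species site conservation is assessed by projecting site starts
through a user-supplied gapped pairwise alignment; a pair is conserved
when projected starts differ by ≤ `loc_tol` columns (default 0) and
affinities by ≤ `aff_tol` (default 0.05), matched greedily by smallest
projected distance. The tolerances have no canonical published values, so
both are mandatory, logged configuration.

## SNV classification

For an SNV, all covering windows (up to 8 per strand) are rescored with
reference and alternate alleles. A window-strand is retained when either
allele's 8-mer matches the pattern; when both match, the fold change is
a(alt)/a(ref). `best_fold` maximizes over dual-match windows — the
question is whether *any* site is optimized — with the full window list
retained for audit. Label precedence:

1. `affinity_optimizing` — any dual-match fold ≥ `opt_fold`
   (ETS 1.59; AP-1/IRF 1.5);
2. `de_novo_site` — no dual-match window, but the alternate allele creates
   a match (tracked separately: creating a site is a different mechanism
   from optimizing one, and never counted as optimizing);
3. `site_ablating` — no dual-match window, reference-only match;
4. `affinity_neutral_in_site` — all dual-match folds within [0.8, 1.25];
5. `affinity_decreasing` — some fold below 0.8, none optimizing;
6. `affinity_increasing_subthreshold` — dual-match folds above the neutral
   band but below `opt_fold`. This label closes a genuine gap in the rule
   set: a fold of, say, 1.4 is neither neutral nor optimizing, and mapping
   it to either would distort both groups;
7. `not_in_site` — no retained window.

For enrichment the labels collapse to three analysis groups: optimizing,
in-site-no-change (the neutral label), and all-other (everything else,
including de novo and ablating). The relaxed `opt_fold > 1.0`
configuration supports sparse datasets where almost no variant reaches the
standard threshold. A dense-architecture filter (off by default) drops
SNVs whose position lies inside ≥ 2 distinct sites, where a per-site fold
change is ill-defined — appropriate for enhanceosome-like regions with
overlapping sites.

The reference-allele check against the sequence is a hard error reporting
expected vs observed base: it is the guard that catches 1-based/0-based
conversion mistakes, the most likely silent failure mode in this analysis.

## Enrichment statistics

Association records carry a signed effect (MPRA expression change or eQTL
β), raw and adjusted p, and the plotted metric: direction-signed
−log₁₀ p_adj (positive = increased expression). p_adj is floored at
1e−300 before the log. GOF requires p_adj strictly below α = 0.05 *and*
an upward direction.

- **Adjustment.** MPRA tables: a provided adjusted-p column is used as
  published; otherwise Benjamini–Hochberg across the table (the path
  taken is recorded in the report). eQTL tables: Bonferroni with an
  explicit study-wide test count m (the number of genotype–gene
  associations tested, not the number of rows at hand), then a
  most-significant-association reduction per variant (smallest p_adj,
  ties by raw p, then lexicographic gene label, logged).
- **Group comparison.** One-tailed Mann–Whitney U ("optimizing
  stochastically greater than the rest"), computed on the signed log-p
  metric by default — the quantity the analysis visualizes — with raw
  effect sizes available via `metric="effect"` since either choice is
  defensible. Exact null distribution when n_a·n_b ≤ 400 and the data are
  tie-free; otherwise the normal approximation with tie and continuity
  corrections. The path is recorded per comparison.
- **Fisher's exact test** for 2×k count tables is an in-package
  margin-fixed enumeration summing null probabilities ≤ the observed
  table's (relative slack 1e−7 against round-off), because a deterministic
  exact p is required and general-k library routines resample. It is
  validated exhaustively against the hypergeometric closed form on 2×2
  tables.
- **Fold enrichment** is rate_subset / rate_all (e.g. GOF rate among
  optimizing SNVs over GOF rate among all SNVs), reported with both rates
  and, when counts are supplied, the Fisher p on the 2×2.
- Box-plot summaries (quartiles, 1.5×IQR whiskers) are emitted as numbers;
  plotting is left to the caller.

## Affinity–occupancy correlation

Sites are binned by affinity into 0.1-wide bins (half-open [lo, hi), top
bin closed so affinity 1.0 lands in 0.9–1.0; a 1e−9 tolerance keeps
affinities like 0.3, not exactly representable in binary, on their nominal
edge). The per-site signal is the arithmetic mean over the 8-base window;
windows with any uncovered base are skipped by default (simplest
defensible policy; a partial-coverage mean is available and the choice is
logged). Means are taken per (bin, chromosome) and Spearman's ρ is
computed over all points with average-rank ties. Constant signal yields
NaN with a warning rather than an arbitrary value. Tracks are consumed as
bedGraph text, the standard bigWig-derived export at this scale.

## Synthetic data generator

The generator's defaults define the study conditions used throughout the
tests:

| parameter | default | rationale |
|---|---|---|
| `consensus_kmer` | `CCGGAAGT` | an ETS-family optimum containing the GGAW core |
| `affinity_decay` | 0.5 | affinity = decay^(Hamming distance to consensus, strand-minimized); gives a ladder 1, 0.5, 0.25, 0.125 … whose low rungs match the 0.1–0.4 range where functional enhancer sites sit |
| `enhancer_length` | 300 bp | saturation mutagenesis then yields 3L = 900 SNVs, the scale of a single-enhancer MPRA |
| `planted_sites` | 6 sites, affinities 0.125–0.5 | a low-affinity site ladder across both strands |
| `gof_fraction` | 0.36 | the observed fraction of affinity-optimizing SNVs driving GOF expression in saturation mutagenesis of the ZRS limb enhancer |
| `effect_size` | 1.0 (in units of `noise_sd`) | a standardized +1 SD expression shift |
| `noise_sd`, `n_replicates` | 1.0, 8 | per-replicate measurement noise and replicate count of the z-test model |
| `m_tests` | 10,000 | a study-wide Bonferroni denominator far exceeding the rows at hand, as in real eQTL catalogues |
| `track_noise_sd` | 0.05 | per-base track noise around the affinity link |

The Hamming-decay affinity model guarantees a strand-symmetric table with
a unique optimal family and a tunable low-affinity tail. Expression
effects follow an explicit replicate model — per-SNV true effect =
baseline Normal(0, noise_sd) plus the planted shift for effect-carrying
optimizing SNVs; observed effect = mean of `n_replicates` noisy
replicates; p from a two-sided z-test of that mean — so multiple-testing
behaviour is exercised on realistically generated p values rather than
values drawn directly from a distribution. One integer seed makes every
output byte-identical; independent sub-streams decorrelate the enhancer,
MPRA, eQTL and track stages.

What the generator does **not** emulate: barcode-level MPRA counts and
sequencing error, linkage disequilibrium among eQTL variants, chromatin
context, and inter-site cooperativity. Passing tests therefore demonstrate
that the pipeline recovers planted enrichment under an idealized noise
model, not that any particular biological dataset will show enrichment.

## Problem sizes and determinism

Test and validation runs use desk-scale problems chosen to exercise every
code path: 300-bp enhancers (900 SNVs), exhaustive 65,536-entry PBM
tables, 100-seed power runs (a +1 SD planted shift on optimizing SNVs is
detected in ≥ 80% of seeds; the false-flag rate with no planted effect
stays ≤ 10%), a 2,000-replicate null calibration of the grouped
Mann–Whitney test (rejection rate at α = 0.05 within [0.035, 0.065]), and
500-site affinity–occupancy tracks (ρ ≥ 0.8 at σ = 0.05 noise; ρ = 1 at
zero noise). Exact tests are validated by exhaustive enumeration
(Mann–Whitney for all tie-free inputs with n_a + n_b ≤ 8; Fisher 2×2 for
all tables with total ≤ 20).

## Known limitations

- Only 8-mer patterns and tables (k = 8) are supported; no PWM or energy
  model, by design — affinity is a pure lookup.
- Indels, multi-nucleotide variants and haplotypes are out of scope.
- Alignments are consumed, never computed.
- The eQTL stage consumes published association statistics; it fits no
  model and handles no linkage disequilibrium.
- bigWig is not read natively; convert to bedGraph text first.
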