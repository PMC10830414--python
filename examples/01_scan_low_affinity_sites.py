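"""Scan a synthetic enhancer for ETS sites and score them by PBM affinity.

Builds an exhaustive synthetic PBM table (optimal 8-mer CCGGAAGT, affinity
halving per mismatch), plants six low-affinity ETS sites in a random
300-bp enhancer, and scans both strands with the degenerate ETS core
NNGGAWNN. Sites well below affinity 1.0 are the interesting ones:
functional enhancer sites typically sit at 0.1-0.4 of the optimum.
"""

from affopt import ETS, GeneratorConfig, gen_enhancer, gen_pbm_table, scan_sequence

cfg = GeneratorConfig(seed=1)
table = gen_pbm_table(cfg)
seq, truth = gen_enhancer(cfg, ETS)

print(f"optimal 8-mer: {table.optimal_kmer} (relative affinity "
      f"{table.affinity(table.optimal_kmer):.2f})")
print(f"enhancer: {len(seq)} bp with {len(truth)} planted ETS sites\n")

sites = scan_sequence(seq, ETS, table, sequence_id="enh")
print(f"{'start':>5} {'strand':>6} {'kmer':>10} {'affinity':>8}")
for s in sites:
    print(f"{s.start:>5} {s.strand:>6} {s.kmer:>10} {s.affinity:>8.3f}")

planted = {r["offset"] for r in truth}
recovered = planted & {s.start for s in sites}
print(f"\n{len(sites)} windows match the ETS core; {len(recovered)}/{len(planted)} "
      "planted sites recovered. Affinity is the PBM signal relative to the "
      "optimal 8-mer, so 0.25 means a site bound at a quarter of maximal "
      "strength - weak, but in the range where real enhancer sites operate.")
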