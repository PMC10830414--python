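"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the statistical structure of the real inputs —
PBM 8-mer intensity tables, enhancers with planted binding sites of chosen
affinities, saturation-mutagenesis MPRA tables, eQTL tables with signed
betas, and ChIP-style signal tracks monotonically linked to site affinity
— at desk scale, so classification and enrichment can be validated against
planted truth without downloads.

Affinity model: relative affinity of an 8-mer is ``decay ** d`` where
``d`` is its Hamming distance to a designated consensus, minimized over
strand. This guarantees a strand-symmetric table with a unique optimum
(up to reverse complement) and a tunable low-affinity tail, mirroring the
observation that functional enhancer sites sit far below the optimum
(relative affinities around 0.1-0.4).

Expression model: each SNV has a baseline true effect drawn from
``Normal(0, noise_sd)``; affinity-optimizing SNVs additionally receive a
planted shift of ``effect_size`` standard deviations with probability
``gof_fraction``. The observed effect is the mean of ``n_replicates``
noisy replicate measurements and the p value is a two-sided z-test of
that mean — so adjusted-p behaviour is exercised on realistically
generated, not directly drawn, p values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .motifs import DEGENERACY, MotifPattern, Site, matches, scan_sequence
from .pbm import PbmTable, revcomp
from .variants import ClassThresholds, Variant, classify_variant, default_thresholds

BASES = "ACGT"

# Default planted-site ladder: offsets spaced to keep 8-mer windows (and
# their single-base neighbourhoods) disjoint; affinities span the
# low-affinity range where functional enhancer sites live.
_DEFAULT_SITES: tuple[tuple[int, str, float], ...] = (
    (20, "+", 0.125),
    (60, "+", 0.25),
    (100, "-", 0.25),
    (150, "+", 0.25),
    (200, "-", 0.5),
    (250, "+", 0.125),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs for the synthetic study, with one seed for full determinism.

    ``gof_fraction`` defaults to 0.36 — the observed fraction of
    affinity-optimizing SNVs driving gain-of-function expression in the
    saturation-mutagenesis analysis of the ZRS limb enhancer — and
    ``effect_size`` is in units of ``noise_sd`` (standardized shift).
    """

    seed: int = 0
    consensus_kmer: str = "CCGGAAGT"
    affinity_decay: float = 0.5
    enhancer_length: int = 300
    planted_sites: tuple[tuple[int, str, float], ...] = _DEFAULT_SITES
    n_snvs: int | None = None  # None = all 3L single-base substitutions
    gof_fraction: float = 0.36
    effect_size: float = 1.0
    noise_sd: float = 1.0
    n_replicates: int = 8
    multi_gene_fraction: float = 0.1
    m_tests: int = 10_000
    track_noise_sd: float = 0.05
    track_baseline: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.affinity_decay < 1:
            raise ValueError("affinity_decay must lie in (0, 1)")
        if len(self.consensus_kmer) != 8 or set(self.consensus_kmer) - set(BASES):
            raise ValueError("consensus_kmer must be an A/C/G/T 8-mer")
        for frac in (self.gof_fraction, self.multi_gene_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        spans = sorted((off, off + 8) for off, _s, _a in self.planted_sites)
        for (lo1, hi1), (lo2, hi2) in zip(spans, spans[1:]):
            if lo2 < hi1:
                raise ValueError("planted sites overlap")
        if spans and spans[-1][1] > self.enhancer_length:
            raise ValueError("planted sites exceed enhancer length")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one sub-stream of the simulation."""
        return np.random.default_rng(np.random.SeedSequence((self.seed, stream)))


def _all_kmers_array() -> np.ndarray:
    """All 65,536 8-mers as a (65536, 8) base-index array."""
    idx = np.arange(4 ** 8, dtype=np.uint32)
    out = np.empty((idx.size, 8), dtype=np.uint8)
    for j in range(8):
        out[:, 7 - j] = (idx >> (2 * j)) & 3
    return out


def gen_pbm_table(cfg: GeneratorConfig) -> PbmTable:
    """Exhaustive synthetic PBM table over all 65,536 8-mers.

    Relative affinity = ``affinity_decay ** HammingDistance(kmer,
    consensus)`` minimized over strand, so the consensus (and its reverse
    complement) scores exactly 1.0 and the table is strand-symmetric by
    construction.
    """
    arr = _all_kmers_array()
    cons = np.frombuffer(cfg.consensus_kmer.encode(), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
    cons_idx = lut[cons]
    rc_idx = (3 - cons_idx)[::-1]
    d_fwd = (arr != cons_idx).sum(axis=1)
    d_rev = (arr != rc_idx).sum(axis=1)
    d = np.minimum(d_fwd, d_rev)
    aff = cfg.affinity_decay ** d.astype(float)
    base_chars = np.frombuffer(BASES.encode(), dtype=np.uint8)
    kmers = base_chars[arr].tobytes().decode()
    affinities = {
        kmers[i * 8 : i * 8 + 8]: float(aff[i]) for i in range(arr.shape[0])
    }
    return PbmTable(tf_name="synthetic", affinities=affinities)


def write_uniprobe_file(table: PbmTable, path: str | Path, scale: float = 65536.0) -> None:
    """Write a table in the UniProbe 8-mers dialect (tab-separated, header).

    Intensities are ``affinity * scale``; re-reading divides by the
    maximum, so affinities round-trip exactly. Each double-stranded 8-mer
    family is written once with its reverse complement in column 2.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("8-mer\t8-mer\tE-score\tMedian\tZ-score\n")
        for kmer in sorted(table.affinities):
            rc = revcomp(kmer)
            if rc < kmer:
                continue  # family already written under its smaller key
            a = table.affinities[kmer]
            fh.write(f"{kmer}\t{rc}\t{a * 0.5:.5f}\t{a * scale!r}\t{a * 10:.4f}\n")


def _kmer_at_distance(
    cfg: GeneratorConfig,
    pattern: MotifPattern,
    d: int,
    rng: np.random.Generator,
) -> str:
    """A kmer ``d`` mismatches from the consensus that still matches ``pattern``."""
    cons = cfg.consensus_kmer
    mutable = [
        i for i in range(8)
        if len(DEGENERACY[pattern.consensus[i]] - {cons[i]}) > 0
    ]
    if d > len(mutable):
        raise ValueError(
            f"cannot place a pattern-matching kmer at Hamming distance {d}"
        )
    for _attempt in range(200):
        pos = rng.choice(mutable, size=d, replace=False)
        k = list(cons)
        for i in pos:
            choices = sorted(DEGENERACY[pattern.consensus[i]] - {cons[i]})
            k[i] = choices[rng.integers(len(choices))]
        kmer = "".join(k)
        # strand-minimized distance must still be d (revcomp could be closer)
        d_rc = sum(a != b for a, b in zip(revcomp(kmer), cons))
        if d_rc >= d:
            return kmer
    raise RuntimeError(f"failed to sample a distance-{d} pattern kmer")


def gen_enhancer(
    cfg: GeneratorConfig,
    pattern: MotifPattern,
    motif_free_background: bool = False,
    max_tries: int = 2000,
) -> tuple[str, list[dict]]:
    """Random enhancer with planted motif sites of requested affinities.

    Returns ``(sequence, truth)`` where truth records, per planted site,
    the offset, strand, planted kmer and the nearest achievable affinity
    (``affinity_decay`` quantizes the ladder, so the achieved value is
    reported rather than the request). With ``motif_free_background`` the
    background is rejection-sampled until scanning finds sites only at the
    planted windows.
    """
    rng = cfg.rng(stream=1)
    truth: list[dict] = []
    planted: list[tuple[int, str]] = []
    for offset, strand, target in cfg.planted_sites:
        d = round(np.log(target) / np.log(cfg.affinity_decay))
        d = max(0, min(8, d))
        achieved = cfg.affinity_decay ** d
        kmer = _kmer_at_distance(cfg, pattern, d, rng)
        truth.append(
            {"offset": offset, "strand": strand, "kmer": kmer,
             "target_affinity": target, "affinity": achieved}
        )
        planted.append((offset, strand))
        if abs(achieved - target) > 1e-9 and achieved == 0:
            raise ValueError(f"unsatisfiable target affinity {target}")

    for _attempt in range(max_tries):
        seq = "".join(rng.choice(list(BASES), size=cfg.enhancer_length))
        chars = list(seq)
        for rec in truth:
            ins = rec["kmer"] if rec["strand"] == "+" else revcomp(rec["kmer"])
            chars[rec["offset"] : rec["offset"] + 8] = ins
        seq = "".join(chars)
        if not motif_free_background:
            return seq, truth
        hits = {
            (s, st) for s in range(len(seq) - 7)
            for st, km in (("+", seq[s : s + 8]), ("-", revcomp(seq[s : s + 8])))
            if matches(km, pattern)
        }
        if hits == set(planted):
            return seq, truth
    raise RuntimeError("could not sample a motif-free background; "
                       "shorten the enhancer or relax the constraint")


def _simulate_assoc(
    cfg: GeneratorConfig,
    seq: str,
    table: PbmTable,
    pattern: MotifPattern,
    th: ClassThresholds,
    stream: int,
    sequence_id: str,
) -> pd.DataFrame:
    """Shared machinery: enumerate SNVs, classify, plant effects, measure."""
    rng = cfg.rng(stream)
    variants = [
        Variant(sequence_id, pos, seq[pos], alt)
        for pos in range(len(seq))
        for alt in BASES
        if alt != seq[pos]
    ]
    if cfg.n_snvs is not None and cfg.n_snvs < len(variants):
        keep = rng.choice(len(variants), size=cfg.n_snvs, replace=False)
        variants = [variants[i] for i in sorted(keep)]

    labels, groups, folds = [], [], []
    for v in variants:
        eff = classify_variant(seq, v, pattern, table, th)
        labels.append(eff.label)
        groups.append(eff.analysis_group)
        folds.append(eff.best_fold)

    n = len(variants)
    baseline = rng.normal(0.0, cfg.noise_sd, size=n)
    is_opt = np.array([g == "optimizing" for g in groups])
    carries = is_opt & (rng.random(n) < cfg.gof_fraction)
    true_effect = baseline + carries * cfg.effect_size * cfg.noise_sd
    reps = rng.normal(
        true_effect[:, None], cfg.noise_sd, size=(n, cfg.n_replicates)
    )
    observed = reps.mean(axis=1)
    se = cfg.noise_sd / np.sqrt(cfg.n_replicates)
    from scipy.stats import norm

    p = 2 * norm.sf(np.abs(observed) / se)
    return pd.DataFrame(
        {
            "sequence_id": sequence_id,
            "pos_1based": [v.pos + 1 for v in variants],
            "ref": [v.ref for v in variants],
            "alt": [v.alt for v in variants],
            "effect": observed,
            "p": p,
            "true_label": labels,
            "true_group": groups,
            "true_fold": folds,
            "planted_effect": carries,
        }
    )


def gen_mpra_table(
    cfg: GeneratorConfig,
    seq: str,
    table: PbmTable,
    pattern: MotifPattern,
    th: ClassThresholds | None = None,
    sequence_id: str = "enh",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Saturation-mutagenesis MPRA table for every SNV of ``seq``.

    Returns ``(associations, truth)``: the association frame carries the
    pipeline's input columns (sequence_id, pos_1based, ref, alt, effect,
    p), the truth frame the generator's labels and which SNVs carry a
    planted effect.
    """
    if th is None:
        th = default_thresholds(pattern.name)
    df = _simulate_assoc(cfg, seq, table, pattern, th, stream=2,
                         sequence_id=sequence_id)
    assoc = df[["sequence_id", "pos_1based", "ref", "alt", "effect", "p"]].copy()
    truth = df.drop(columns=["effect", "p"])
    return assoc, truth


def gen_eqtl_table(
    cfg: GeneratorConfig,
    seq: str,
    table: PbmTable,
    pattern: MotifPattern,
    th: ClassThresholds | None = None,
    sequence_id: str = "enh",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """eQTL-style table with signed betas and gene labels.

    A ``multi_gene_fraction`` of variants receives an extra null
    association with a second gene, exercising the most-significant-gene
    reduction downstream.
    """
    if th is None:
        th = default_thresholds(pattern.name)
    df = _simulate_assoc(cfg, seq, table, pattern, th, stream=3,
                         sequence_id=sequence_id)
    rng = cfg.rng(stream=4)
    df = df.rename(columns={"effect": "beta"})
    df["gene"] = [f"GENE{i % 7}" for i in range(len(df))]
    assoc = df[["sequence_id", "pos_1based", "ref", "alt", "gene", "beta", "p"]].copy()

    extra_mask = rng.random(len(assoc)) < cfg.multi_gene_fraction
    if extra_mask.any():
        extra = assoc[extra_mask].copy()
        extra["gene"] = extra["gene"] + "_ALT"
        extra["beta"] = rng.normal(0.0, cfg.noise_sd, size=len(extra))
        extra["p"] = rng.uniform(0.05, 1.0, size=len(extra))
        assoc = pd.concat([assoc, extra], ignore_index=True)
    truth = df.drop(columns=["beta", "p", "gene"])
    return assoc, truth


def gen_signal_track(
    cfg: GeneratorConfig,
    sites: Sequence[Site],
    lengths: dict[str, int],
    link: Callable[[float], float] | None = None,
    noise_sd: float | None = None,
) -> dict[str, np.ndarray]:
    """Per-base signal tracks monotonically linked to site affinity.

    Bases inside a site window get ``link(affinity) + Normal(0,
    noise_sd)``; all other bases get the background baseline plus noise.
    ``link`` defaults to identity and must be monotone increasing for the
    affinity-occupancy correlation to be planted.
    """
    rng = cfg.rng(stream=5)
    if link is None:
        link = lambda a: a  # noqa: E731
    sd = cfg.track_noise_sd if noise_sd is None else noise_sd
    tracks = {
        chrom: np.full(n, cfg.track_baseline)
        + (rng.normal(0, sd, size=n) if sd > 0 else 0.0)
        for chrom, n in lengths.items()
    }
    for site in sites:
        arr = tracks[site.sequence_id]
        base = link(site.affinity)
        noise = rng.normal(0, sd, size=8) if sd > 0 else 0.0
        arr[site.start : site.end] = base + noise
    return tracks


def null_mwu_rejection_rate(
    cfg: GeneratorConfig,
    pattern: MotifPattern,
    table: PbmTable,
    n_replicates: int = 2000,
    alpha: float = 0.05,
) -> float:
    """Type-I error of the grouped one-tailed Mann-Whitney test under the null.

    The enhancer is generated and its SNVs classified once; each replicate
    then redraws expression effects with no planted shift, recomputes BH-
    adjusted signed log p values, and tests optimizing-vs-rest. The
    returned rejection rate at ``alpha`` should sit near ``alpha`` if the
    test is correctly calibrated on this data shape.
    """
    from .stats import bh_adjust, mwu_one_tailed

    null_cfg = replace(cfg, effect_size=0.0)
    seq, _ = gen_enhancer(null_cfg, pattern)
    th = default_thresholds(pattern.name)
    groups = []
    for pos in range(len(seq)):
        for alt in BASES:
            if alt == seq[pos]:
                continue
            eff = classify_variant(seq, Variant("enh", pos, seq[pos], alt),
                                   pattern, table, th)
            groups.append(eff.analysis_group)
    is_opt = np.array([g == "optimizing" for g in groups])
    n = len(groups)
    se = null_cfg.noise_sd / np.sqrt(null_cfg.n_replicates)
    rng = null_cfg.rng(stream=6)
    from scipy.stats import norm

    n_reject = 0
    for _rep in range(n_replicates):
        baseline = rng.normal(0.0, null_cfg.noise_sd, size=n)
        observed = rng.normal(
            baseline, se
        )  # mean of n_replicates measurements, drawn directly
        p = 2 * norm.sf(np.abs(observed) / se)
        p_adj = bh_adjust(p)
        slp = np.sign(observed) * -np.log10(np.maximum(p_adj, 1e-300))
        cmp = mwu_one_tailed(slp[is_opt], slp[~is_opt])
        n_reject += cmp.p_one_tailed < alpha
    return n_reject / n_replicates


def write_bedgraph(tracks: dict[str, np.ndarray], path: str | Path) -> None:
    """Write dense tracks as bedGraph text (one interval per base)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for chrom in sorted(tracks):
            for i, v in enumerate(tracks[chrom]):
                fh.write(f"{chrom}\t{i}\t{i + 1}\t{v:.6g}\n")
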