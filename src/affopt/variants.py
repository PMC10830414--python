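"""SNV application, window rescoring, and affinity fold-change classification.

A single-nucleotide variant inside a binding site changes the 8-mer of
every window that covers it. Rescoring the reference and alternate 8-mers
against the PBM table gives a fold change (alt/ref) per window, and the
fold change classifies the SNV: *affinity-optimizing* variants increase a
site's affinity by at least a family-specific threshold (1.59x for ETS,
1.5x for AP-1/IRF), *neutral* variants stay within a 0.8-1.25x band, and
SNVs can also create a motif match de novo or ablate an existing one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .motifs import MotifPattern, Site, matches
from .pbm import PbmTable, revcomp

LABELS = (
    "affinity_optimizing",
    "affinity_neutral_in_site",
    "affinity_decreasing",
    "affinity_increasing_subthreshold",
    "de_novo_site",
    "site_ablating",
    "not_in_site",
)

GROUP_OPTIMIZING = "optimizing"
GROUP_NEUTRAL = "in-site-no-change"
GROUP_OTHER = "all-other"


@dataclass(frozen=True)
class Variant:
    """A single-base substitution at a 0-based offset on a named sequence."""

    sequence_id: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"{self}: ref equals alt")
        for b in (self.ref, self.alt):
            if b not in "ACGT":
                raise ValueError(f"{self}: allele {b!r} not in ACGT")

    def __str__(self) -> str:  # 1-based for human readability
        return f"{self.sequence_id}:{self.pos + 1}{self.ref}>{self.alt}"


@dataclass(frozen=True)
class WindowEffect:
    """Rescoring of one window-strand combination covering a variant."""

    start: int
    strand: str
    ref_kmer: str
    alt_kmer: str
    ref_affinity: float | None
    alt_affinity: float | None
    fold: float | None  # alt/ref, only when both kmers match the pattern
    match: str  # 'dual' | 'ref_only' | 'alt_only'


@dataclass
class VariantEffect:
    """Per-SNV affinity consequences over all motif windows covering it."""

    variant: Variant
    pattern_name: str
    windows: list[WindowEffect] = field(default_factory=list)
    best_fold: float | None = None
    ref_best_affinity: float | None = None
    alt_best_affinity: float | None = None
    label: str | None = None

    @property
    def analysis_group(self) -> str:
        """Three-way grouping used in enrichment comparisons."""
        if self.label is None:
            raise ValueError("classify_snv has not been applied")
        if self.label == "affinity_optimizing":
            return GROUP_OPTIMIZING
        if self.label == "affinity_neutral_in_site":
            return GROUP_NEUTRAL
        return GROUP_OTHER


@dataclass(frozen=True)
class ClassThresholds:
    """Fold-change cutoffs for SNV classification.

    ``opt_fold`` is the minimum alt/ref fold for an affinity-optimizing
    call (1.59 for ETS; 1.5 for AP-1 and IRF); ``neutral_band`` is the
    inclusive fold interval treated as not changing affinity.
    """

    opt_fold: float = 1.59
    neutral_band: tuple[float, float] = (0.8, 1.25)

    def __post_init__(self) -> None:
        lo, hi = self.neutral_band
        if not (self.opt_fold > hi > lo > 0):
            raise ValueError(
                f"require opt_fold > neutral upper > neutral lower > 0, "
                f"got {self.opt_fold}, {self.neutral_band}"
            )


ETS_THRESHOLDS = ClassThresholds(opt_fold=1.59)
AP1_IRF_THRESHOLDS = ClassThresholds(opt_fold=1.5)


def default_thresholds(pattern_name: str) -> ClassThresholds:
    """Family-specific defaults: 1.59x for ETS, 1.5x for AP-1/IRF."""
    return ETS_THRESHOLDS if pattern_name.upper() == "ETS" else AP1_IRF_THRESHOLDS


class RefMismatchError(ValueError):
    """Raised when a variant's stated reference base disagrees with the sequence."""


def apply_snv(seq: str, v: Variant) -> str:
    """Return ``seq`` with the variant applied; the original is unchanged.

    Raises :class:`RefMismatchError` if the sequence base at ``v.pos``
    differs from ``v.ref`` — the guard that catches 0- vs 1-based
    coordinate mistakes before they silently corrupt every fold change.
    """
    if not 0 <= v.pos < len(seq):
        raise ValueError(f"{v}: position outside sequence of length {len(seq)}")
    observed = seq[v.pos].upper()
    if observed != v.ref:
        raise RefMismatchError(
            f"{v}: expected ref {v.ref} but sequence has {observed} at "
            f"0-based position {v.pos}"
        )
    return seq[: v.pos] + v.alt + seq[v.pos + 1 :]


def variant_window_effects(
    seq: str,
    v: Variant,
    pattern: MotifPattern,
    table: PbmTable,
) -> VariantEffect:
    """Rescore all 8 windows (x 2 strands) covering an SNV against a pattern.

    A window-strand is retained when its reference or alternate 8-mer
    matches the pattern. Where both match, ``fold = alt_affinity /
    ref_affinity``; ref-only matches are candidate site ablations and
    alt-only matches candidate de-novo sites. ``best_fold`` maximizes over
    dual-match windows — the question being asked is whether *any* site's
    affinity is optimized — and the full window list is kept for audit.
    """
    seq = seq.upper()
    alt_seq = apply_snv(seq, v)
    windows: list[WindowEffect] = []
    lo = max(0, v.pos - 7)
    hi = min(v.pos, len(seq) - 8)
    for start in range(lo, hi + 1):
        ref_win = seq[start : start + 8]
        alt_win = alt_seq[start : start + 8]
        if "N" in ref_win:
            continue
        for strand in "+-":
            ref_kmer = ref_win if strand == "+" else revcomp(ref_win)
            alt_kmer = alt_win if strand == "+" else revcomp(alt_win)
            ref_match = matches(ref_kmer, pattern)
            alt_match = matches(alt_kmer, pattern)
            if not ref_match and not alt_match:
                continue
            ref_aff = table.affinity(ref_kmer) if ref_match else None
            alt_aff = table.affinity(alt_kmer) if alt_match else None
            if ref_match and alt_match:
                kind, fold = "dual", alt_aff / ref_aff
            elif ref_match:
                kind, fold = "ref_only", None
            else:
                kind, fold = "alt_only", None
            windows.append(
                WindowEffect(start, strand, ref_kmer, alt_kmer, ref_aff, alt_aff,
                             fold, kind)
            )
    effect = VariantEffect(variant=v, pattern_name=pattern.name, windows=windows)
    dual = [w for w in windows if w.match == "dual"]
    if dual:
        best = max(dual, key=lambda w: w.fold)
        effect.best_fold = best.fold
        effect.ref_best_affinity = best.ref_affinity
        effect.alt_best_affinity = best.alt_affinity
    else:
        refs = [w.ref_affinity for w in windows if w.ref_affinity is not None]
        alts = [w.alt_affinity for w in windows if w.alt_affinity is not None]
        effect.ref_best_affinity = max(refs) if refs else None
        effect.alt_best_affinity = max(alts) if alts else None
    return effect


def classify_snv(effect: VariantEffect, th: ClassThresholds) -> VariantEffect:
    """Assign the fold-change class label (in place; also returned).

    Precedence: optimizing (any dual fold >= opt_fold) > de novo (alt-only
    match, no dual window) > ablating (ref-only, no dual) > neutral (all
    dual folds inside the neutral band) > decreasing (some dual fold below
    the band, none optimizing) > sub-threshold increase (dual folds above
    the band but below opt_fold) > not-in-site (no retained window).
    """
    dual_folds = [w.fold for w in effect.windows if w.match == "dual"]
    has_alt_only = any(w.match == "alt_only" for w in effect.windows)
    has_ref_only = any(w.match == "ref_only" for w in effect.windows)
    lo, hi = th.neutral_band
    if not effect.windows:
        effect.label = "not_in_site"
    elif dual_folds and max(dual_folds) >= th.opt_fold:
        effect.label = "affinity_optimizing"
    elif not dual_folds and has_alt_only:
        effect.label = "de_novo_site"
    elif not dual_folds and has_ref_only:
        effect.label = "site_ablating"
    elif all(lo <= f <= hi for f in dual_folds):
        effect.label = "affinity_neutral_in_site"
    elif any(f < lo for f in dual_folds):
        effect.label = "affinity_decreasing"
    else:
        effect.label = "affinity_increasing_subthreshold"
    return effect


def classify_variant(
    seq: str,
    v: Variant,
    pattern: MotifPattern,
    table: PbmTable,
    th: ClassThresholds | None = None,
) -> VariantEffect:
    """Convenience: window rescoring followed by classification."""
    if th is None:
        th = default_thresholds(pattern.name)
    return classify_snv(variant_window_effects(seq, v, pattern, table), th)


def exclude_overlapping_site_snvs(
    effects: list[VariantEffect],
    sites: list[Site],
) -> tuple[list[VariantEffect], list[tuple[VariantEffect, int]]]:
    """Drop SNVs whose position falls inside two or more distinct sites.

    Used for dense architectures (e.g. the IFN-beta enhanceosome) where a
    nucleotide can belong to overlapping binding sites, making a per-site
    fold change ill-defined. ``sites`` should be the scan of the same
    sequence with every pattern under study; distinctness is by
    (start, strand, kmer). Returns (survivors, exclusion log of
    (effect, n_covering_sites)).
    """
    survivors: list[VariantEffect] = []
    excluded: list[tuple[VariantEffect, int]] = []
    for eff in effects:
        pos = eff.variant.pos
        n_cover = len(
            {(s.start, s.strand, s.kmer) for s in sites
             if s.sequence_id == eff.variant.sequence_id and s.covers(pos)}
        )
        if n_cover >= 2:
            excluded.append((eff, n_cover))
        else:
            survivors.append(eff)
    return survivors, excluded
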