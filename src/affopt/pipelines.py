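"""End-to-end enrichment pipelines joining SNV classifications to
expression associations.

Two stages share one core: the MPRA stage consumes per-variant reporter
effects (saturation-mutagenesis style tables with an effect size and a raw
or adjusted p per SNV), the eQTL stage consumes per-variant association
betas with Bonferroni adjustment over the study-wide number of tests and a
most-significant-gene reduction. Both classify every SNV against a motif
pattern and PBM table, form three analysis groups — affinity-optimizing
SNVs, in-site SNVs that do not change affinity, and all other SNVs — and
ask whether the optimizing group is enriched for gain-of-function (GOF)
expression with a one-tailed Mann-Whitney U test, alongside GOF rates and
the fold enrichment of the optimizing group over all SNVs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from . import stats
from .motifs import MotifPattern, scan_sequence
from .pbm import PbmTable
from .stats import AssociationRecord, GroupComparison
from .variants import (
    ClassThresholds,
    Variant,
    VariantEffect,
    classify_variant,
    default_thresholds,
    exclude_overlapping_site_snvs,
    GROUP_NEUTRAL,
    GROUP_OPTIMIZING,
    GROUP_OTHER,
)

logger = logging.getLogger(__name__)

GROUPS = (GROUP_OPTIMIZING, GROUP_NEUTRAL, GROUP_OTHER)


@dataclass
class EnrichmentReport:
    """Grouped enrichment summary for one pattern/threshold configuration."""

    pattern_name: str
    opt_fold: float
    neutral_band: tuple[float, float]
    alpha: float
    metric: str
    adjustment: str
    n_records: int
    group_counts: dict[str, int]
    group_boxplots: dict[str, dict]
    comparisons: dict[str, GroupComparison | None]
    gof_rates: dict[str, float | None]
    enrichment: dict | None
    stratified: list[dict] = field(default_factory=list)
    per_variant: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        out = asdict(self)
        out.pop("per_variant")
        out["comparisons"] = {
            k: (None if v is None else asdict(v)) for k, v in self.comparisons.items()
        }
        return out


def _is_snv_row(row: pd.Series) -> bool:
    ref, alt = str(row["ref"]).upper(), str(row["alt"]).upper()
    return len(ref) == 1 and len(alt) == 1 and ref in "ACGT" and alt in "ACGT" \
        and ref != alt


def _classify_rows(
    df: pd.DataFrame,
    sequences: dict[str, str],
    pattern: MotifPattern,
    table: PbmTable,
    th: ClassThresholds,
) -> list[VariantEffect]:
    effects = []
    for row in df.itertuples(index=False):
        seq = sequences.get(row.sequence_id)
        if seq is None:
            raise KeyError(f"association row names unknown sequence {row.sequence_id!r}")
        v = Variant(row.sequence_id, int(row.pos_1based) - 1,
                    str(row.ref).upper(), str(row.alt).upper())
        effects.append(classify_variant(seq, v, pattern, table, th))
    return effects


def _grouped_report(
    effects: list[VariantEffect],
    records: list[AssociationRecord],
    pattern_name: str,
    th: ClassThresholds,
    alpha: float,
    metric: str,
    adjustment: str,
) -> EnrichmentReport:
    assert len(effects) == len(records)
    values = np.array(
        [r.signed_logp if metric == "signed_logp" else r.effect for r in records]
    )
    groups = np.array([e.analysis_group for e in effects])
    gof = np.array([stats.is_gof(r, alpha) for r in records])

    group_counts = {g: int((groups == g).sum()) for g in GROUPS}
    group_boxplots = {g: stats.boxplot_stats(values[groups == g]) for g in GROUPS}
    gof_rates: dict[str, float | None] = {
        g: (float(gof[groups == g].mean()) if group_counts[g] else None)
        for g in GROUPS
    }
    gof_rates["all"] = float(gof.mean()) if len(records) else None

    comparisons: dict[str, GroupComparison | None] = {}
    for name, g in (("optimizing_vs_other", GROUP_OPTIMIZING),
                    ("neutral_vs_other", GROUP_NEUTRAL)):
        in_g = groups == g
        if in_g.sum() == 0 or (~in_g).sum() == 0:
            logger.warning("%s: group %s empty, MWU not applicable", pattern_name, g)
            comparisons[name] = None
            continue
        cmp = stats.mwu_one_tailed(values[in_g], values[~in_g],
                                   group_a=g, group_b="rest")
        cmp.gof_rate_a = float(gof[in_g].mean())
        cmp.gof_rate_b = float(gof[~in_g].mean())
        comparisons[name] = cmp

    enrichment = None
    n_opt = group_counts[GROUP_OPTIMIZING]
    if n_opt and gof_rates["all"]:
        in_opt = groups == GROUP_OPTIMIZING
        enrichment = stats.fold_enrichment(
            gof_rates[GROUP_OPTIMIZING],
            gof_rates["all"],
            counts=(int(gof[in_opt].sum()), n_opt,
                    int(gof[~in_opt].sum()), int((~in_opt).sum())),
        )

    per_variant = pd.DataFrame(
        {
            "variant": [str(e.variant) for e in effects],
            "label": [e.label for e in effects],
            "group": groups,
            "best_fold": [e.best_fold for e in effects],
            "ref_affinity": [e.ref_best_affinity for e in effects],
            "alt_affinity": [e.alt_best_affinity for e in effects],
            "effect": [r.effect for r in records],
            "p_raw": [r.p_raw for r in records],
            "p_adj": [r.p_adj for r in records],
            "signed_logp": [r.signed_logp for r in records],
            "gof": gof,
        }
    )
    return EnrichmentReport(
        pattern_name=pattern_name,
        opt_fold=th.opt_fold,
        neutral_band=th.neutral_band,
        alpha=alpha,
        metric=metric,
        adjustment=adjustment,
        n_records=len(records),
        group_counts=group_counts,
        group_boxplots=group_boxplots,
        comparisons=comparisons,
        gof_rates=gof_rates,
        enrichment=enrichment,
        per_variant=per_variant,
    )


def run_mpra_enrichment(
    sequences: dict[str, str],
    associations: pd.DataFrame,
    pattern: MotifPattern,
    table: PbmTable,
    th: ClassThresholds | None = None,
    alpha: float = 0.05,
    metric: str = "signed_logp",
    exclude_overlapping: bool = False,
    overlap_patterns: Sequence[MotifPattern] = (),
) -> EnrichmentReport:
    """MPRA enrichment stage.

    ``associations`` carries one row per tested variant with columns
    sequence_id, pos_1based, ref, alt, effect, p (optional p_adj). When an
    adjusted-p column is present it is used as published; otherwise raw p
    values are Benjamini-Hochberg adjusted across the table (the path
    taken is recorded in the report). Direction comes from the sign of the
    effect; effect-free rows are dropped with a logged count.
    ``exclude_overlapping`` enables the dense-architecture filter that
    drops SNVs inside two or more overlapping sites (scanned with
    ``overlap_patterns``, defaulting to the analysis pattern) — applied in
    published form only to enhanceosome-like regions, hence off by default.
    """
    if th is None:
        th = default_thresholds(pattern.name)
    df = associations.copy()
    n0 = len(df)
    df = df[df.apply(_is_snv_row, axis=1)].reset_index(drop=True)
    if len(df) < n0:
        logger.info("dropped %d non-SNV rows", n0 - len(df))
    df = df.dropna(subset=["effect", "p"]).reset_index(drop=True)

    if "p_adj" in df.columns and df["p_adj"].notna().all():
        adjustment = "provided"
        p_adj = df["p_adj"].to_numpy(dtype=float)
    else:
        adjustment = "bh"
        p_adj = stats.bh_adjust(df["p"].to_numpy(dtype=float))
    logger.info("adjusted p values: %s", adjustment)

    effects = _classify_rows(df, sequences, pattern, table, th)
    records = [
        AssociationRecord.build(str(e.variant), float(eff), float(p), float(pa))
        for e, eff, p, pa in zip(effects, df["effect"], df["p"], p_adj)
    ]

    if exclude_overlapping:
        pats = list(overlap_patterns) or [pattern]
        sites = []
        for sid, seq in sequences.items():
            for pat in pats:
                sites.extend(scan_sequence(seq, pat, table, sequence_id=sid))
        kept, excluded = exclude_overlapping_site_snvs(effects, sites)
        keep_keys = {id(e) for e in kept}
        records = [r for e, r in zip(effects, records) if id(e) in keep_keys]
        effects = kept
        logger.info("overlap filter excluded %d SNVs", len(excluded))

    return _grouped_report(effects, records, pattern.name, th, alpha,
                           metric, adjustment)


def select_top_association(records: list[AssociationRecord]) -> list[AssociationRecord]:
    """Per variant, keep only the most significant gene association.

    Smallest adjusted p wins; ties broken by smallest raw p, then
    lexicographically smallest gene label (logged). Output preserves the
    order of first appearance of each variant.
    """
    best: dict[str, AssociationRecord] = {}
    order: list[str] = []
    for rec in records:
        key = rec.variant_key
        if key not in best:
            best[key] = rec
            order.append(key)
            continue
        cur = best[key]
        a = (rec.p_adj, rec.p_raw, rec.gene or "")
        b = (cur.p_adj, cur.p_raw, cur.gene or "")
        if a < b:
            if a[:2] == b[:2]:
                logger.info("variant %s: gene tie resolved to %s", key, rec.gene)
            best[key] = rec
    return [best[k] for k in order]


def run_eqtl_enrichment(
    sequences: dict[str, str],
    associations: pd.DataFrame,
    pattern: MotifPattern,
    table: PbmTable,
    m_total_tests: int,
    th: ClassThresholds | None = None,
    alpha: float = 0.05,
    metric: str = "signed_logp",
    fold_cutoffs: Sequence[float] = (1.25, 1.5, 2.0),
) -> EnrichmentReport:
    """eQTL enrichment stage.

    ``associations`` additionally carries ``gene`` and ``beta`` columns;
    the beta sign defines direction (positive = increased target-gene
    expression). Raw p values are Bonferroni-adjusted with the supplied
    study-wide number of genotype-gene tests ``m_total_tests``; variants
    associated with several genes are reduced to their most significant
    association. A stratified pass re-runs the optimizing-vs-other
    comparison at increasing fold-change cutoffs, probing whether larger
    affinity gains show stronger enrichment.
    """
    if th is None:
        th = default_thresholds(pattern.name)
    df = associations.copy()
    if "beta" not in df.columns:
        raise ValueError("eQTL table requires a 'beta' column")
    df["effect"] = df["beta"]
    n0 = len(df)
    df = df[df.apply(_is_snv_row, axis=1)].reset_index(drop=True)
    if len(df) < n0:
        logger.info("dropped %d non-SNV rows", n0 - len(df))
    df = df.dropna(subset=["effect", "p"]).reset_index(drop=True)

    p_adj = stats.bonferroni_adjust(df["p"].to_numpy(dtype=float), m_total_tests)
    records_all = [
        AssociationRecord.build(
            f"{row.sequence_id}:{row.pos_1based}{row.ref}>{row.alt}",
            float(row.effect), float(row.p), float(pa),
            gene=getattr(row, "gene", None),
        )
        for row, pa in zip(df.itertuples(index=False), p_adj)
    ]
    top = select_top_association(records_all)
    # keep rows whose record object survived the reduction
    surviving = {id(r) for r in top}
    keep_idx = [i for i, r in enumerate(records_all) if id(r) in surviving]
    df = df.iloc[keep_idx].reset_index(drop=True)
    records = [records_all[i] for i in keep_idx]

    effects = _classify_rows(df, sequences, pattern, table, th)
    report = _grouped_report(effects, records, pattern.name, th, alpha,
                             metric, adjustment=f"bonferroni(m={m_total_tests})")

    values = np.array(
        [r.signed_logp if metric == "signed_logp" else r.effect for r in records]
    )
    for cutoff in fold_cutoffs:
        is_opt = np.array(
            [e.best_fold is not None and e.best_fold >= cutoff for e in effects]
        )
        if is_opt.sum() == 0 or (~is_opt).sum() == 0:
            report.stratified.append(
                {"fold_cutoff": cutoff, "n_optimizing": int(is_opt.sum()), "p": None}
            )
            continue
        cmp = stats.mwu_one_tailed(values[is_opt], values[~is_opt],
                                   group_a=f"fold>={cutoff}", group_b="rest")
        report.stratified.append(
            {"fold_cutoff": cutoff, "n_optimizing": int(is_opt.sum()),
             "p": cmp.p_one_tailed, "U": cmp.U}
        )
    return report
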