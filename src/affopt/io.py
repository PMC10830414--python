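"""Format readers/writers shared by all stages.

Coordinate conventions: everything in memory is 0-based half-open. VCF and
human-oriented variant tables are 1-based and converted at the boundary;
BED and bedGraph are already 0-based half-open. All writers are
byte-deterministic given their inputs and write via a temp file + atomic
rename so no output is ever left half-written.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from pathlib import Path
from typing import IO, Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO

from .motifs import Site
from .variants import Variant

logger = logging.getLogger(__name__)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {record id: uppercase sequence}."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    lines = []
    for name, seq in seqs.items():
        lines.append(f">{name}")
        lines.extend(seq[i : i + width] for i in range(0, len(seq), width))
    _atomic_write_text("\n".join(lines) + "\n", path)


def read_variants_tsv(path: str | Path) -> list[Variant]:
    """Read a variant TSV with columns sequence_id, pos_1based, ref, alt.

    A header row is required; extra columns are ignored. Positions are
    1-based in the file and converted to 0-based internally.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sequence_id", "pos_1based", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                Variant(
                    sequence_id=row["sequence_id"],
                    pos=int(row["pos_1based"]) - 1,
                    ref=row["ref"].upper(),
                    alt=row["alt"].upper(),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: bad variant at data row {i + 1}: {exc}") from None
    return out


def read_vcf_snvs(path: str | Path) -> list[Variant]:
    """Read SNVs from a VCF; non-SNV records are skipped with a logged count.

    VCF POS is 1-based; internal positions are 0-based. Multi-allelic
    records contribute one variant per single-base ALT.
    """
    import pysam

    out: list[Variant] = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            for alt in rec.alts or ():
                if len(rec.ref) == 1 and len(alt) == 1 and alt in "ACGT":
                    out.append(Variant(rec.chrom, rec.pos - 1, rec.ref.upper(), alt))
                else:
                    n_skipped += 1
    if n_skipped:
        logger.info("read_vcf_snvs(%s): skipped %d non-SNV alleles", path, n_skipped)
    return out


def read_association_tsv(
    path: str | Path,
    column_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read an association table (MPRA effects or eQTL betas) as a DataFrame.

    Canonical columns after mapping: sequence_id, pos_1based, ref, alt,
    effect, p; optional p_adj, gene, beta. ``column_map`` renames source
    columns to canonical names, e.g. ``{"pvalue": "p"}``.
    """
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns=column_map)
    required = {"sequence_id", "pos_1based", "ref", "alt", "p"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_bedgraph(path: str | Path) -> dict[str, np.ndarray]:
    """Read a bedGraph text track into dense per-base arrays per chromosome.

    Uncovered bases are NaN. Intervals are 0-based half-open, as the
    format specifies. Intended for enhancer-scale and desk-scale tracks.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        comment="t",  # skips 'track ...' header lines; data lines start with chrom
        header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    df = df.dropna()
    tracks: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        length = int(sub["end"].max())
        arr = np.full(length, np.nan)
        for start, end, value in sub[["start", "end", "value"]].itertuples(index=False):
            arr[int(start) : int(end)] = float(value)
        tracks[chrom] = arr
    if not tracks:
        raise ValueError(f"no bedGraph intervals in {path}")
    return tracks


def _atomic_write_text(text: str, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_bed(sites: Iterable[Site], path: str | Path) -> None:
    """Write sites as BED6 (0-based half-open; score = round(1000 * affinity))."""
    lines = [
        "\t".join(
            (
                s.sequence_id,
                str(s.start),
                str(s.end),
                s.kmer,
                str(round(1000 * s.affinity)),
                s.strand,
            )
        )
        for s in sites
    ]
    _atomic_write_text("\n".join(lines) + ("\n" if lines else ""), path)


def write_sites_tsv(sites: Iterable[Site], path: str | Path) -> None:
    """Full site table with exact affinities and both coordinate conventions."""
    header = "sequence_id\tstart_0based\tend\tstart_1based_incl\tstrand\tkmer\taffinity"
    lines = [header]
    for s in sites:
        lines.append(
            f"{s.sequence_id}\t{s.start}\t{s.end}\t{s.start + 1}\t{s.strand}"
            f"\t{s.kmer}\t{s.affinity:.6g}"
        )
    _atomic_write_text("\n".join(lines) + "\n", path)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    _atomic_write_text(df.to_csv(sep="\t", index=False), path)


def write_json_report(obj: dict, path: str | Path) -> None:
    _atomic_write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", path)
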