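"""Protein-binding-microarray (PBM) 8-mer tables and relative binding affinity.

A universal PBM measures a transcription factor's binding signal for every
8-mer. The *relative affinity* of an 8-mer is its median signal intensity
divided by the intensity of the optimal (highest-signal) 8-mer, so the
optimal site scores exactly 1.0 and functional low-affinity sites typically
score well below that (0.1-0.4). Tables are strand-symmetric: an 8-mer and
its reverse complement describe the same double-stranded site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_BASES = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class MissingKmerError(KeyError):
    """Raised when neither an 8-mer nor its reverse complement is in a table."""


class DuplicateKmerError(ValueError):
    """Raised when an 8-mer appears twice with conflicting intensities."""


@dataclass
class PbmTable:
    """Normalized map from 8-mer to relative affinity for one transcription factor.

    Parameters
    ----------
    tf_name : str
        Label for the factor the array was run with (e.g. ``"ETS-1"``).
    affinities : dict
        Map from uppercase 8-mer to relative affinity in ``(0, 1]``. The
        maximum over all keys is 1.0. Lookups are strand-symmetric via
        :meth:`affinity`.
    k : int
        Motif length; fixed at 8 for universal PBM designs.
    """

    tf_name: str
    affinities: dict[str, float]
    k: int = 8

    def __post_init__(self) -> None:
        if not self.affinities:
            raise ValueError("PbmTable requires at least one 8-mer")
        for kmer in self.affinities:
            if len(kmer) != self.k or not set(kmer) <= VALID_BASES:
                raise ValueError(f"invalid {self.k}-mer key: {kmer!r}")
        vals = self.affinities.values()
        if min(vals) <= 0:
            raise ValueError("relative affinities must be positive")
        if abs(max(vals) - 1.0) > 1e-12:
            raise ValueError("maximum relative affinity must equal 1.0")

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.affinities or revcomp(kmer) in self.affinities

    def __len__(self) -> int:
        return len(self.affinities)

    @property
    def optimal_kmer(self) -> str:
        """An 8-mer attaining relative affinity 1.0."""
        return max(self.affinities, key=lambda q: (self.affinities[q], q))

    def affinity(self, kmer: str) -> float:
        """Strand-symmetric relative affinity of ``kmer``.

        Returns the larger of the values stored under the 8-mer and its
        reverse complement (tables whose two orientation columns disagree
        remain usable; the max is the defensible double-stranded readout).

        Raises
        ------
        MissingKmerError
            If neither orientation is present. A silent 0 would corrupt
            downstream fold changes, so absence is always an error.
        """
        kmer = kmer.upper()
        if len(kmer) != self.k or not set(kmer) <= VALID_BASES:
            raise ValueError(f"invalid query {self.k}-mer: {kmer!r}")
        rc = revcomp(kmer)
        fwd = self.affinities.get(kmer)
        rev = self.affinities.get(rc)
        if fwd is None and rev is None:
            raise MissingKmerError(
                f"8-mer {kmer} (rc {rc}) absent from PBM table {self.tf_name!r}"
            )
        if fwd is None:
            return rev  # type: ignore[return-value]
        if rev is None:
            return fwd
        return max(fwd, rev)


def relative_affinity(kmer: str, table: PbmTable) -> float:
    """Relative affinity of ``kmer`` in ``table`` (strand-symmetric lookup)."""
    return table.affinity(kmer)


def _looks_like_header(fields: list[str]) -> bool:
    if len(fields) < 2:
        return True
    kmer = fields[0].strip().upper()
    if len(kmer) != 8 or not set(kmer) <= VALID_BASES:
        return True
    return False


def read_uniprobe_table(
    stream: IO[str] | Iterable[str],
    tf_name: str = "TF",
    intensity_column: int | None = None,
) -> PbmTable:
    """Read a UniProbe-dialect 8-mer table and normalize to relative affinity.

    The UniProbe "8mers" export is tab-separated with columns
    ``8-mer, 8-mer reverse complement, E-score, median intensity, Z-score``;
    a header row is auto-detected and skipped. Each 8-mer's relative
    affinity is its median intensity divided by the maximum median
    intensity over all retained rows, so the optimal 8-mer scores 1.0.
    Both the forward 8-mer and its reverse complement key to the same
    value. Rows with missing or non-positive intensity are dropped (count
    logged): a relative affinity must be a positive fraction.

    Parameters
    ----------
    stream : text stream or iterable of lines
    tf_name : str
        Factor label stored on the returned table.
    intensity_column : int, optional
        0-based index of the intensity column. Defaults to column 3 when
        the row has >= 4 fields (the UniProbe median-intensity position),
        else the last column. Set explicitly for non-standard dialects.

    Raises
    ------
    ValueError
        If no usable rows remain after filtering.
    DuplicateKmerError
        If the same 8-mer occurs twice with different intensities.
    """
    raw: dict[str, float] = {}
    n_dropped = 0
    n_rows = 0
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\r\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if n_rows == 0 and not raw and _looks_like_header(fields):
            continue
        n_rows += 1
        kmer = fields[0].strip().upper()
        if len(kmer) != 8 or not set(kmer) <= VALID_BASES:
            raise ValueError(f"line {lineno}: malformed 8-mer {fields[0]!r}")
        # Second column, when present and sequence-like, is the reverse
        # complement key; remaining numeric columns are E-score, median, Z.
        rc_col = None
        if len(fields) >= 2:
            cand = fields[1].strip().upper()
            if len(cand) == 8 and set(cand) <= VALID_BASES:
                rc_col = cand
        if intensity_column is not None:
            col = intensity_column
        elif len(fields) >= 4 and rc_col is not None:
            col = 3
        else:
            col = len(fields) - 1
        try:
            intensity = float(fields[col])
        except (IndexError, ValueError) as exc:
            raise ValueError(
                f"line {lineno}: cannot read intensity from column {col}: {exc}"
            ) from None
        if not intensity > 0:
            n_dropped += 1
            continue
        for key in filter(None, (kmer, rc_col)):
            if key in raw and abs(raw[key] - intensity) > 1e-9 * max(abs(intensity), 1):
                raise DuplicateKmerError(
                    f"8-mer {key} has conflicting intensities "
                    f"{raw[key]} and {intensity}"
                )
            raw[key] = intensity
    if n_dropped:
        logger.info(
            "read_uniprobe_table(%s): dropped %d rows with non-positive/missing "
            "intensity", tf_name, n_dropped,
        )
    if not raw:
        raise ValueError(f"PBM table {tf_name!r}: no usable rows after filtering")
    peak = max(raw.values())
    affinities = {q: v / peak for q, v in raw.items()}
    return PbmTable(tf_name=tf_name, affinities=affinities)


def write_affinity_tsv(table: PbmTable, stream: IO[str]) -> None:
    """Write a two-column TSV (8-mer, relative_affinity) for caching.

    Round-trips through :func:`read_affinity_tsv` at full float precision.
    """
    stream.write("kmer\trelative_affinity\n")
    for kmer in sorted(table.affinities):
        stream.write(f"{kmer}\t{table.affinities[kmer]!r}\n")


def read_affinity_tsv(stream: IO[str] | Iterable[str], tf_name: str = "TF") -> PbmTable:
    """Read the two-column cache format written by :func:`write_affinity_tsv`."""
    affinities: dict[str, float] = {}
    for line in stream:
        line = line.rstrip("\r\n")
        if not line or line.startswith("kmer\t"):
            continue
        kmer, value = line.split("\t")
        affinities[kmer.upper()] = float(value)
    if not affinities:
        raise ValueError("empty affinity cache")
    return PbmTable(tf_name=tf_name, affinities=affinities)
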