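"""Degenerate binding-site patterns and double-stranded sequence scanning.

Transcription-factor families are described here by 8-base degenerate
consensus cores (IUPAC subset): every 8-mer window on either strand whose
motif-orientation sequence fits the core is a putative site, and its
quantitative strength comes from a PBM relative-affinity lookup rather
than from the pattern itself. This deliberately casts a wide net — the
point is to score low-affinity sites that conventional thresholded motif
scans discard.
"""

from __future__ import annotations

from dataclasses import dataclass

from .pbm import PbmTable, revcomp

DEGENERACY: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "N": frozenset("ACGT"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
}


@dataclass(frozen=True)
class MotifPattern:
    """A length-8 degenerate consensus defining a TFBS family.

    Allowed codes: A, C, G, T plus N={ACGT}, W={AT}, K={GT}, M={AC}.
    """

    name: str
    consensus: str

    def __post_init__(self) -> None:
        if len(self.consensus) != 8:
            raise ValueError(f"pattern {self.name!r}: consensus must be length 8")
        bad = set(self.consensus) - set(DEGENERACY)
        if bad:
            raise ValueError(
                f"pattern {self.name!r}: unsupported degeneracy codes {sorted(bad)}"
            )

    @property
    def n_matching_kmers(self) -> int:
        """Number of distinct 8-mers matching the pattern (product of degeneracies)."""
        n = 1
        for code in self.consensus:
            n *= len(DEGENERACY[code])
        return n


# Core patterns for the three factor families under study.
ETS = MotifPattern("ETS", "NNGGAWNN")
AP1 = MotifPattern("AP-1", "NTKANNMA")
IRF = MotifPattern("IRF", "NWNNGANA")

BUILTIN_PATTERNS: dict[str, MotifPattern] = {"ETS": ETS, "AP-1": AP1, "IRF": IRF}


def get_pattern(name: str) -> MotifPattern:
    """Look up a built-in pattern by name (case-insensitive, 'AP1' accepted)."""
    key = name.upper().replace("AP1", "AP-1")
    try:
        return BUILTIN_PATTERNS[key]
    except KeyError:
        raise KeyError(
            f"unknown pattern {name!r}; built-ins: {sorted(BUILTIN_PATTERNS)}"
        ) from None


def matches(kmer: str, pattern: MotifPattern) -> bool:
    """True iff each base of ``kmer`` is in the degeneracy set at its position."""
    kmer = kmer.upper()
    if len(kmer) != 8 or not set(kmer) <= frozenset("ACGT"):
        raise ValueError(f"malformed 8-mer: {kmer!r}")
    return all(b in DEGENERACY[c] for b, c in zip(kmer, pattern.consensus))


@dataclass(frozen=True)
class Site:
    """A matched motif window on a sequence.

    ``start`` is the 0-based offset of the window's first base on the
    forward strand; ``kmer`` is the 8-mer read in motif orientation (the
    reverse complement of the forward-strand window for '-' sites);
    ``affinity`` is the PBM relative affinity of that 8-mer.
    """

    sequence_id: str
    start: int
    strand: str
    kmer: str
    affinity: float

    @property
    def end(self) -> int:
        return self.start + 8

    def covers(self, pos: int) -> bool:
        return self.start <= pos < self.end


def scan_sequence(
    seq: str,
    pattern: MotifPattern,
    table: PbmTable,
    sequence_id: str = "seq",
) -> list[Site]:
    """Scan every 8-base window on both strands for pattern matches.

    Windows containing N are skipped (masked reference tolerated). A window
    matching on both strands yields two Site records; overlapping windows
    are all reported. Sites are sorted by start, '+' before '-'. Sequences
    shorter than 8 give an empty list.
    """
    seq = seq.upper()
    if not set(seq) <= frozenset("ACGTN"):
        bad = sorted(set(seq) - frozenset("ACGTN"))
        raise ValueError(f"sequence {sequence_id!r}: invalid characters {bad}")
    sites: list[Site] = []
    for start in range(len(seq) - 7):
        window = seq[start : start + 8]
        if "N" in window:
            continue
        for strand, kmer in (("+", window), ("-", revcomp(window))):
            if matches(kmer, pattern):
                sites.append(
                    Site(sequence_id, start, strand, kmer, table.affinity(kmer))
                )
    return sites


def merged_site_intervals(sites: list[Site]) -> list[tuple[int, int]]:
    """Merge overlapping site windows into maximal intervals.

    Companion count for the all-windows scan: whether a both-strand or
    overlapping match is one site or several is a bookkeeping convention,
    so the merged interval count is reported alongside the window count.
    """
    if not sites:
        return []
    spans = sorted((s.start, s.end) for s in sites)
    merged = [list(spans[0])]
    for lo, hi in spans[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


def _alignment_column_map(aligned: str) -> dict[int, int]:
    """Map ungapped sequence offsets to alignment column indices."""
    out: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(aligned):
        if ch != "-":
            out[pos] = col
            pos += 1
    return out


def map_sites_through_alignment(
    aligned_a: str,
    aligned_b: str,
    sites_a: list[Site],
    sites_b: list[Site],
    loc_tol: int = 0,
    aff_tol: float = 0.05,
) -> list[tuple[Site, Site]]:
    """Pair sites conserved in location and affinity across a pairwise alignment.

    Both sequences' site starts are projected into alignment columns; a
    pair is conserved when the projected starts differ by at most
    ``loc_tol`` columns and the affinities differ by at most ``aff_tol``.
    Matching is greedy by smallest projected distance (ties to the lower
    coordinate pair) and each site pairs with at most one partner.

    ``aligned_a``/``aligned_b`` are the two gapped rows of the alignment
    (gap character '-'); they must have equal length and their ungapped
    lengths must cover every site.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("alignment rows have different lengths")
    col_a = _alignment_column_map(aligned_a)
    col_b = _alignment_column_map(aligned_b)
    for s in sites_a:
        if s.start not in col_a:
            raise ValueError(f"site at {s.start} outside aligned sequence A")
    for s in sites_b:
        if s.start not in col_b:
            raise ValueError(f"site at {s.start} outside aligned sequence B")

    candidates: list[tuple[int, int, int, int]] = []  # (dist, ia, ib) keyed for sort
    for ia, sa in enumerate(sites_a):
        for ib, sb in enumerate(sites_b):
            dist = abs(col_a[sa.start] - col_b[sb.start])
            if dist <= loc_tol and abs(sa.affinity - sb.affinity) <= aff_tol:
                candidates.append((dist, min(sa.start, sb.start), ia, ib))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[Site, Site]] = []
    for _dist, _lo, ia, ib in candidates:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        pairs.append((sites_a[ia], sites_b[ib]))
    pairs.sort(key=lambda p: (p[0].start, p[0].strand))
    return pairs
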