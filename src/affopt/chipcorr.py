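"""PBM affinity versus ChIP signal correlation.

Predicted motif windows are scored by PBM relative affinity, placed into
ten affinity bins (0-0.1, 0.1-0.2, ..., 0.9-1.0), and the mean per-base
ChIP signal over each 8-base window is averaged within each (bin,
chromosome) group. The Spearman rank correlation between bin affinity and
mean signal, over all (bin, chromosome) points, asks whether in vitro
affinity predicts in vivo occupancy across the whole affinity range.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .motifs import Site

logger = logging.getLogger(__name__)

BIN_EDGES = np.round(np.linspace(0.0, 1.0, 11), 10)


@dataclass(frozen=True)
class AffinityBinSummary:
    """Mean window signal of the sites in one affinity bin on one chromosome."""

    bin_lo: float
    bin_hi: float
    chromosome: str
    mean_signal: float
    n_sites: int

    @property
    def bin_mid(self) -> float:
        return (self.bin_lo + self.bin_hi) / 2


def affinity_bin(affinity: float) -> tuple[float, float]:
    """Half-open [lo, hi) bin from the 0.1-wide ladder; the top bin is closed."""
    if not 0 < affinity <= 1:
        raise ValueError(f"affinity {affinity} outside (0, 1]")
    # tolerance keeps affinities like 0.3 (not representable in binary)
    # on the lower edge of their nominal bin
    idx = min(int(affinity * 10 + 1e-9), 9)
    return float(BIN_EDGES[idx]), float(BIN_EDGES[idx + 1])


def mean_window_signal(
    track: np.ndarray,
    site: Site,
    require_full_coverage: bool = True,
) -> float | None:
    """Arithmetic mean of per-base signal over a site's 8-base window.

    ``track`` is a dense per-base array for the site's chromosome with NaN
    at uncovered bases. With ``require_full_coverage`` (default) a window
    containing any uncovered base returns None and the site is skipped;
    set False to average over the covered bases instead.
    """
    window = track[site.start : site.end]
    if window.size < 8:
        return None
    covered = ~np.isnan(window)
    if require_full_coverage:
        if not covered.all():
            return None
        return float(window.mean())
    if not covered.any():
        return None
    return float(window[covered].mean())


def summarize_bins(
    sites: list[Site],
    tracks: dict[str, np.ndarray],
    require_full_coverage: bool = True,
) -> list[AffinityBinSummary]:
    """Group sites by (affinity bin, chromosome) and average window signals.

    Site ``sequence_id`` doubles as chromosome label. Sites with no usable
    signal are skipped with a logged count; empty groups are omitted.
    """
    rows = []
    n_skipped = 0
    for site in sites:
        track = tracks.get(site.sequence_id)
        sig = None if track is None else mean_window_signal(
            track, site, require_full_coverage
        )
        if sig is None:
            n_skipped += 1
            continue
        lo, hi = affinity_bin(site.affinity)
        rows.append((lo, hi, site.sequence_id, sig))
    if n_skipped:
        logger.info("summarize_bins: skipped %d sites without full coverage",
                    n_skipped)
    if not rows:
        return []
    df = pd.DataFrame(rows, columns=["lo", "hi", "chrom", "signal"])
    grouped = df.groupby(["lo", "hi", "chrom"], sort=True)["signal"].agg(
        ["mean", "size"]
    )
    return [
        AffinityBinSummary(lo, hi, chrom, float(m), int(n))
        for (lo, hi, chrom), (m, n) in grouped.iterrows()
    ]


def spearman_over_bins(summaries: list[AffinityBinSummary]) -> float:
    """Spearman rho between bin midpoint and mean signal over all points.

    Uses average-rank tie handling. All (bin, chromosome) points enter as
    individual observations. Returns NaN (with a warning) when the signal
    is constant, where rank correlation is undefined.
    """
    if len(summaries) < 3:
        raise ValueError("need at least 3 (bin, chromosome) points")
    x = [s.bin_mid for s in summaries]
    y = [s.mean_signal for s in summaries]
    if len(set(y)) == 1:
        logger.warning("spearman_over_bins: constant signal, rho undefined")
        return math.nan
    rho, _p = sps.spearmanr(x, y)
    return float(rho)
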