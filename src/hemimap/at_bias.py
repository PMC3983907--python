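"""AT-richness census and representation analysis of cleavage fragments.

Strongly AT-rich templates are under-recovered by the sequencing pipeline.
This module measures that bias the way the analysis requires: a census of
maximal genomic segments at least ``min_at`` A+T over a fixed window (the
length scale of a CDEII), normalized fragment coverage over aligned anchors
(1 = random expectation), and percent-of-expected cleavage-site
representation for arbitrary intervals together with its correlation with
AT-richness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fragment_io import FragmentSet, Genome

__all__ = [
    "ATSegment",
    "find_at_rich_segments",
    "normalized_coverage",
    "representation_stats",
    "representation_at_correlation",
]


@dataclass(frozen=True)
class ATSegment:
    """A maximal run of qualifying AT-rich windows."""

    chrom: str
    start: int
    end: int
    at_fraction: float
    window: int


def find_at_rich_segments(
    genome: Genome, window: int = 83, min_at: float = 0.90
) -> list[ATSegment]:
    """Maximal non-overlapping segments >= ``min_at`` A+T over ``window`` bp.

    A window qualifies when its A+T fraction (ambiguous bases count as non-AT;
    the A+T content of a window is strand-symmetric) is at least ``min_at``;
    overlapping or adjacent qualifying windows merge into one maximal segment.
    Chromosomes shorter than the window are skipped with a warning.
    """
    segments = []
    for chrom in genome.chroms():
        at = genome.at_indicator(chrom)
        if at.size < window:
            warnings.warn(f"{chrom} shorter than {window} bp; skipped")
            continue
        cum = np.concatenate([[0], np.cumsum(at)])
        win_at = (cum[window:] - cum[:-window]) / window
        ok = win_at >= min_at
        if not ok.any():
            continue
        # merge runs of qualifying window starts into maximal segments
        starts = np.nonzero(ok)[0]
        breaks = np.nonzero(np.diff(starts) > 1)[0]
        run_start = np.concatenate([[starts[0]], starts[breaks + 1]])
        run_end = np.concatenate([starts[breaks], [starts[-1]]])
        for s, e in zip(run_start, run_end):
            seg_start, seg_end = int(s), int(e) + window
            frac = float((cum[seg_end] - cum[seg_start]) / (seg_end - seg_start))
            segments.append(ATSegment(chrom, seg_start, seg_end, frac, window))
    return segments


def segments_to_bed(segments, path) -> None:
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.at_fraction:.4f}\n")


def normalized_coverage(
    fragments: FragmentSet,
    anchors: pd.DataFrame,
    flank: int,
    genome: Genome,
) -> np.ndarray:
    """Per-offset fragment coverage over stacked anchors, / genome-wide mean.

    Coverage counts fragments overlapping each position; anchors on the minus
    strand are coordinate-reflected before stacking.  A value of 1 is the
    random expectation under uniform recovery.
    """
    if len(fragments) == 0:
        raise ValueError("empty fragment set")
    genome_cov = float(fragments.length.sum()) / genome.total_length()
    if genome_cov == 0:
        raise ValueError("zero genome-wide coverage")
    size = 2 * flank + 1
    acc = np.zeros(size)
    by_chrom = dict(fragments.per_chrom())
    for _, a in anchors.iterrows():
        sub = by_chrom.get(a["chrom"])
        if sub is None:
            continue
        lo = int(a["pos"]) - flank
        s = np.clip(sub["start"].to_numpy() - lo, 0, size)
        e = np.clip(sub["end"].to_numpy() - lo, 0, size)
        delta = np.zeros(size + 1)
        np.add.at(delta, s, 1)
        np.add.at(delta, e, -1)
        cov = np.cumsum(delta[:-1])
        if a.get("strand", "+") == "-":
            cov = cov[::-1]
        acc += cov
    return acc / (len(anchors) * genome_cov)


def representation_stats(
    fragments: FragmentSet,
    intervals: pd.DataFrame,
    genome: Genome,
) -> pd.DataFrame:
    """Observed vs expected cleavage-site (fragment-end) counts per interval.

    ``intervals`` needs columns (chrom, start, end).  The expected end count
    is the genome-wide end density times the interval length; percent of
    expected is 100 * observed / expected.  The interval A+T fraction is
    reported alongside.
    """
    if len(intervals) == 0:
        raise ValueError("empty interval list")
    if (intervals["end"] <= intervals["start"]).any():
        raise ValueError("intervals must have end > start")
    n_ends = 2 * len(fragments)
    density = n_ends / genome.total_length()
    by_chrom = dict(fragments.per_chrom())
    rows = []
    for _, iv in intervals.iterrows():
        sub = by_chrom.get(iv["chrom"])
        observed = 0
        if sub is not None:
            left = sub["start"].to_numpy()
            right = sub["end"].to_numpy() - 1
            observed = int(
                ((left >= iv["start"]) & (left < iv["end"])).sum()
                + ((right >= iv["start"]) & (right < iv["end"])).sum()
            )
        length = int(iv["end"] - iv["start"])
        expected = density * length
        rows.append(
            {
                "chrom": iv["chrom"],
                "start": int(iv["start"]),
                "end": int(iv["end"]),
                "observed": observed,
                "expected": expected,
                "percent_of_expected": 100.0 * observed / expected,
                "at_fraction": genome.at_fraction(iv["chrom"], int(iv["start"]), int(iv["end"])),
            }
        )
    return pd.DataFrame(rows)


def representation_at_correlation(stats: pd.DataFrame) -> float:
    """Signed Pearson correlation between percent-of-expected and A+T fraction.

    Reported with its sign: under an AT-dependent recovery bias the
    correlation is negative (representation falls as AT-richness rises).
    """
    r, _ = sps.pearsonr(stats["percent_of_expected"], stats["at_fraction"])
    return float(r)
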