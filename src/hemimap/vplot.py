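"""V-plot matrices: fragment feature position vs fragment length around anchors.

A V-plot places each fragment at (feature offset, fragment length).  The
feature is the fragment midpoint (floor of the two-end average) or, for
cleavage mapping where the exact end positions matter, the left or right end.
Matrices hold counts; rendering to dot/density plots is a separate concern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fragment_io import FragmentSet

__all__ = ["VPlotMatrix", "build_vplot", "build_left_right_vplots", "equalize_coverage"]

_MODES = ("midpoint", "left_end", "right_end")


@dataclass
class VPlotMatrix:
    """Counts indexed by (fragment length 1..max_length, offset -flank..+flank)."""

    mode: str
    flank: int
    max_length: int
    counts: np.ndarray  # shape (max_length, 2*flank + 1); row i = length i + 1

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.flank, self.flank + 1)

    @property
    def lengths(self) -> np.ndarray:
        return np.arange(1, self.max_length + 1)

    def column_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.lengths, columns=self.offsets)


def _feature_positions(sub: pd.DataFrame, mode: str, strand: str) -> np.ndarray:
    start = sub["start"].to_numpy()
    end = sub["end"].to_numpy()
    if mode == "midpoint":
        return (start + end - 1) // 2
    # Under reflection a genomic right end plays the left-end role.
    if strand == "-":
        mode = "right_end" if mode == "left_end" else "left_end"
    return start if mode == "left_end" else end - 1


def build_vplot(
    fragments: FragmentSet,
    anchors: pd.DataFrame,
    mode: str = "midpoint",
    flank: int = 1000,
    max_length: int = 500,
) -> VPlotMatrix:
    """Accumulate one count per qualifying fragment per anchor.

    A fragment qualifies when its feature offset lies within ``flank`` and its
    length within ``max_length``; minus-strand anchors are reflected.
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")
    if max_length < 1:
        raise ValueError("max_length must be >= 1")
    size = 2 * flank + 1
    counts = np.zeros((max_length, size), dtype=np.int64)
    by_chrom = dict(fragments.per_chrom())
    for _, a in anchors.iterrows():
        sub = by_chrom.get(a["chrom"])
        if sub is None:
            continue
        strand = a.get("strand", "+")
        feat = _feature_positions(sub, mode, strand)
        off = (a["pos"] - feat) if strand == "-" else (feat - a["pos"])
        length = (sub["end"] - sub["start"]).to_numpy()
        sel = (np.abs(off) <= flank) & (length <= max_length)
        np.add.at(counts, (length[sel] - 1, off[sel] + flank), 1)
    return VPlotMatrix(mode=mode, flank=flank, max_length=max_length, counts=counts)


def build_left_right_vplots(
    fragments: FragmentSet,
    anchors: pd.DataFrame,
    flank: int = 1000,
    max_length: int = 500,
) -> tuple[VPlotMatrix, VPlotMatrix]:
    """The paired left-end/right-end V-plots used for cleavage-position display."""
    return (
        build_vplot(fragments, anchors, "left_end", flank, max_length),
        build_vplot(fragments, anchors, "right_end", flank, max_length),
    )


def equalize_coverage(
    fragments: FragmentSet,
    anchors: pd.DataFrame,
    flank: int = 1000,
    seed: int | np.random.Generator = 0,
) -> FragmentSet:
    """Randomly downsample per-anchor fragment pools to the smallest pool.

    A fragment belongs to an anchor's pool when its midpoint lies within
    ``flank`` of the anchor.  Pools are sampled without replacement down to
    the least populated non-empty pool; anchors with zero fragments are
    dropped with a warning.  Seeded and reproducible.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mid = fragments.midpoint
    chroms = fragments.chrom.to_numpy()
    pools = []
    for _, a in anchors.iterrows():
        idx = np.nonzero((chroms == a["chrom"]) & (np.abs(mid - a["pos"]) <= flank))[0]
        if idx.size == 0:
            warnings.warn(f"anchor {a['chrom']}:{a['pos']} has no fragments; dropped")
            continue
        pools.append(idx)
    if not pools:
        raise ValueError("no anchor has any fragments")
    quota = min(p.size for p in pools)
    chosen = np.concatenate([rng.choice(p, size=quota, replace=False) for p in pools])
    keep = np.zeros(len(fragments), dtype=bool)
    keep[chosen] = True
    out = fragments.subset(keep, note=f"equalize_coverage:quota={quota}")
    return out
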