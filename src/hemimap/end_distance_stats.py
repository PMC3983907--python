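"""Empirical fragment-end distance distributions (W-C, W-W', C-C').

For every left end L and right end R on the same chromosome with L - R inside
the lag window, the W-C distribution counts one pair at lag L - R (a
fragment's own two ends are excluded).  Same-strand distributions count
ordered pairs of distinct left (or right) ends at positive lags 1..40.
Counts are normalized by the total number of pairs inside the window.

Computed genome-wide or for the centromere-proximal subset: fragments with
either end within a fixed radius (default 125 bp) of a mid-Cen anchor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cleavage_model import (
    DEFAULT_SAME_STRAND_RANGE,
    DEFAULT_WC_RANGE,
    DistanceDistribution,
    Pairing,
)
from .fragment_io import CentromereAnnotation, FragmentSet

__all__ = ["SubsetSpec", "select_subset", "wc_distribution", "same_strand_distribution"]


@dataclass(frozen=True)
class SubsetSpec:
    """Which fragments enter the distance statistics."""

    mode: str = "genome_wide"  # or "near_centromere"
    radius: int = 125

    def __post_init__(self) -> None:
        if self.mode not in ("genome_wide", "near_centromere"):
            raise ValueError(f"unknown subset mode {self.mode!r}")
        if self.mode == "near_centromere" and self.radius <= 0:
            raise ValueError("radius must be > 0 in near_centromere mode")


def select_subset(
    fragments: FragmentSet,
    subset: SubsetSpec,
    annotation: CentromereAnnotation | None = None,
) -> FragmentSet:
    """Apply the subset rule (either fragment end within ``radius`` of a mid-Cen)."""
    if subset.mode == "genome_wide":
        return fragments
    if annotation is None:
        raise ValueError("near_centromere subset requires a centromere annotation")
    keep = np.zeros(len(fragments), dtype=bool)
    df = fragments.df
    for _, cen in annotation.df.iterrows():
        on_chrom = (df["chrom"] == cen["chrom"]).to_numpy()
        left = df["start"].to_numpy()
        right = df["end"].to_numpy() - 1
        near = (np.abs(left - cen["mid_cen"]) <= subset.radius) | (
            np.abs(right - cen["mid_cen"]) <= subset.radius
        )
        keep |= on_chrom & near
    return fragments.subset(keep, note=f"subset:near_centromere(r={subset.radius})")


def _position_counts(pos: np.ndarray) -> tuple[np.ndarray, int]:
    base = int(pos.min())
    return np.bincount(pos - base), base


def _cross_lag_counts(a: np.ndarray, b: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """counts[k] = #{(i, j): a_i - b_j = lo + k} via dense position histograms."""
    ca, base_a = _position_counts(a)
    cb, base_b = _position_counts(b)
    out = np.zeros(hi - lo + 1, dtype=np.int64)
    for k, lag in enumerate(range(lo, hi + 1)):
        # a = b + lag  =>  align index ia in ca with ib = ia + base_a - lag - base_b
        shift = base_a - lag - base_b
        ia_lo = max(0, -shift)
        ia_hi = min(ca.size, cb.size - shift)
        if ia_hi > ia_lo:
            out[k] = int(
                np.dot(ca[ia_lo:ia_hi], cb[ia_lo + shift : ia_hi + shift])
            )
    return out


def wc_distribution(
    fragments: FragmentSet,
    subset: SubsetSpec = SubsetSpec(),
    annotation: CentromereAnnotation | None = None,
    lag_range: tuple[int, int] = DEFAULT_WC_RANGE,
) -> DistanceDistribution:
    """Distribution of left-end minus right-end distances over ``lag_range``."""
    sub = select_subset(fragments, subset, annotation)
    if len(sub) == 0:
        raise ValueError("empty fragment subset")
    lo, hi = lag_range
    counts = np.zeros(hi - lo + 1, dtype=np.int64)
    for _, per in sub.per_chrom():
        left = per["start"].to_numpy()
        right = per["end"].to_numpy() - 1
        counts += _cross_lag_counts(left, right, lo, hi)
        # exclude each fragment's own (left, right) pair: lag = -(length - 1)
        self_lag = left - right
        in_range = (self_lag >= lo) & (self_lag <= hi)
        if in_range.any():
            counts -= np.bincount(self_lag[in_range] - lo, minlength=counts.size)
    total = counts.sum()
    if total == 0:
        raise ValueError("no end pairs inside the lag range")
    return DistanceDistribution(
        Pairing.WC, np.arange(lo, hi + 1), counts / total, n_pairs=float(total)
    )


def same_strand_distribution(
    fragments: FragmentSet,
    which: str,
    subset: SubsetSpec = SubsetSpec(),
    annotation: CentromereAnnotation | None = None,
    lag_range: tuple[int, int] = DEFAULT_SAME_STRAND_RANGE,
) -> DistanceDistribution:
    """W-W' (``which="W"``: left ends) or C-C' (``which="C"``: right ends).

    Counts ordered pairs of ends at positive lags; identical fragments each
    contribute their ends (duplicates count), but lag 0 is excluded.
    """
    if which not in ("W", "C"):
        raise ValueError("which must be 'W' or 'C'")
    sub = select_subset(fragments, subset, annotation)
    if len(sub) == 0:
        raise ValueError("empty fragment subset")
    lo, hi = lag_range
    if lo < 1:
        raise ValueError("same-strand lags start at 1 (lag 0 is excluded)")
    counts = np.zeros(hi - lo + 1, dtype=np.int64)
    for _, per in sub.per_chrom():
        ends = (
            per["start"].to_numpy() if which == "W" else per["end"].to_numpy() - 1
        )
        counts += _cross_lag_counts(ends, ends, lo, hi)
    total = counts.sum()
    if total == 0:
        raise ValueError("no end pairs inside the lag range")
    pairing = Pairing.WW if which == "W" else Pairing.CC
    return DistanceDistribution(
        pairing, np.arange(lo, hi + 1), counts / total, n_pairs=float(total)
    )
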