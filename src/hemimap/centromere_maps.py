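"""Fragment-end count tracks, composite centromere histograms, and peak spacing.

Each sequenced fragment contributes exactly two ends — a left end (Watson
cleavage) and a right end (Crick cleavage) — so the total end count across any
track equals twice the fragment count.  Composite histograms stack per-bp
left/right end counts over anchors (mid-Cen by default), reflecting
minus-strand loci so CDEI is always on the left.  Peak maxima of the composite
and their spacings (intra-cluster, inner, outer) are the quantities that
discriminate a symmetric two-H4 particle from junction-anchored hemisomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fragment_io import CentromereAnnotation, FragmentSet

__all__ = [
    "EndCountTrack",
    "CompositeHistogram",
    "PeakSet",
    "end_count_track",
    "composite_histogram",
    "call_peak_maxima",
    "end_bias_histogram",
    "ratio_track",
]


@dataclass
class EndCountTrack:
    """Per-window left/right fragment-end counts for one chromosome."""

    chrom: str
    window: int
    left: np.ndarray
    right: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.left + self.right

    def most_cleaved_position(self) -> int:
        """bp (or window start) with the highest total end count."""
        return int(np.argmax(self.total)) * self.window

    def to_bedgraph(self, path, which: str = "total") -> None:
        arr = {"total": self.total, "left": self.left, "right": self.right}[which]
        with open(path, "w") as fh:
            for i, v in enumerate(arr):
                if v:
                    fh.write(
                        f"{self.chrom}\t{i * self.window}\t{(i + 1) * self.window}\t{v}\n"
                    )


def end_count_track(
    fragments: FragmentSet, window: int = 1, chrom_lengths: dict[str, int] | None = None
) -> dict[str, EndCountTrack]:
    """Count fragment left/right ends in successive windows, per chromosome."""
    if window < 1:
        raise ValueError("window must be >= 1")
    tracks = {}
    for chrom, sub in fragments.per_chrom():
        left = sub["start"].to_numpy()
        right = sub["end"].to_numpy() - 1
        length = (
            chrom_lengths[chrom]
            if chrom_lengths is not None
            else int(right.max()) + 1
        )
        n_win = (length + window - 1) // window
        lc = np.bincount(left // window, minlength=n_win)
        rc = np.bincount(right // window, minlength=n_win)
        tracks[chrom] = EndCountTrack(chrom, window, lc, rc)
    return tracks


@dataclass
class CompositeHistogram:
    """Anchor-aligned, strand-reflected, pooled per-offset end counts.

    ``left`` and ``right`` counts are kept separate; the stacked display
    quantity (and the input to peak calling) is their sum.
    """

    offsets: np.ndarray
    left: np.ndarray
    right: np.ndarray
    n_anchors: int = 0
    length_class: tuple | None = None

    @property
    def total(self) -> np.ndarray:
        return self.left + self.right

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "left": self.left, "right": self.right,
             "total": self.total}
        )


def _stack_ends(fragments: FragmentSet, anchors: pd.DataFrame, flank: int):
    """Accumulate reflected left/right end offsets over anchors.

    On a minus-strand anchor the genomic right end plays the left-end role
    (it is the CDEI-proximal cleavage after reflection).
    """
    size = 2 * flank + 1
    left = np.zeros(size, dtype=np.int64)
    right = np.zeros(size, dtype=np.int64)
    by_chrom = dict(fragments.per_chrom())
    for _, a in anchors.iterrows():
        sub = by_chrom.get(a["chrom"])
        if sub is None:
            continue
        l_end = sub["start"].to_numpy()
        r_end = sub["end"].to_numpy() - 1
        strand = a.get("strand", "+")
        if strand == "-":
            l_off = a["pos"] - r_end
            r_off = a["pos"] - l_end
        else:
            l_off = l_end - a["pos"]
            r_off = r_end - a["pos"]
        for arr, acc in ((l_off, left), (r_off, right)):
            sel = arr[(arr >= -flank) & (arr <= flank)]
            acc += np.bincount(sel + flank, minlength=size)
    return left, right


def composite_histogram(
    fragments: FragmentSet,
    annotation: CentromereAnnotation | pd.DataFrame,
    length_class=None,
    flank: int = 100,
) -> CompositeHistogram:
    """Pool per-bp end counts over mid-Cen anchors of a centromere length class.

    ``annotation`` may instead be an arbitrary anchor table with columns
    (chrom, pos[, strand]) — e.g. the most-cleaved positions per chromosome —
    in which case ``length_class`` must be None.
    """
    if isinstance(annotation, CentromereAnnotation):
        ann = annotation
        if length_class is not None:
            ann = ann.subset_by_length(length_class)
        anchors = ann.anchors()
    else:
        if length_class is not None:
            raise ValueError("length_class requires a CentromereAnnotation")
        anchors = annotation
    if len(anchors) == 0:
        raise ValueError("empty anchor set")
    left, right = _stack_ends(fragments, anchors, flank)
    return CompositeHistogram(
        offsets=np.arange(-flank, flank + 1),
        left=left,
        right=right,
        n_anchors=len(anchors),
        length_class=tuple(length_class) if length_class is not None else None,
    )


@dataclass
class PeakSet:
    """Called peak maxima (offsets ascending) and their pairwise spacings."""

    offsets: np.ndarray
    heights: np.ndarray

    def __post_init__(self) -> None:
        order = np.argsort(self.offsets)
        self.offsets = np.asarray(self.offsets)[order]
        self.heights = np.asarray(self.heights)[order]

    @property
    def spacings(self) -> np.ndarray:
        return np.diff(self.offsets)

    # the four-peak composite geometry: two clusters of two rotational phases
    @property
    def intra_cluster(self) -> tuple[int, int]:
        self._require(4)
        return int(self.offsets[1] - self.offsets[0]), int(self.offsets[3] - self.offsets[2])

    @property
    def inner(self) -> int:
        self._require(4)
        return int(self.offsets[2] - self.offsets[1])

    @property
    def outer(self) -> int:
        self._require(4)
        return int(self.offsets[3] - self.offsets[0])

    def _require(self, n: int) -> None:
        if len(self.offsets) != n:
            raise ValueError(f"spacing defined for {n} peaks, have {len(self.offsets)}")


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y.astype(float)
    if window % 2 == 0:
        raise ValueError("smooth_window must be odd")
    kernel = np.ones(window) / window
    return np.convolve(y.astype(float), kernel, mode="same")


def _local_maxima(y: np.ndarray) -> np.ndarray:
    """Indices of local maxima; a flat run counts once, at its first index."""
    n = y.size
    idx = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and y[j + 1] == y[i]:
            j += 1
        left_ok = i == 0 or y[i - 1] < y[i]
        right_ok = j == n - 1 or y[j + 1] < y[i]
        if left_ok and right_ok and y[i] > 0:
            idx.append(i)
        i = j + 1
    return np.array(idx, dtype=int)


def call_peak_maxima(
    hist: CompositeHistogram,
    n_peaks: int = 4,
    smooth_window: int = 3,
    min_separation: int = 5,
) -> PeakSet:
    """Greedy selection of the ``n_peaks`` highest local maxima.

    The total (left+right) profile is moving-average smoothed, local maxima
    are found, and peaks are picked tallest-first subject to
    ``min_separation``; ties break toward smaller ``|offset|``.
    """
    y = _smooth(hist.total, smooth_window)
    if not np.any(y > 0):
        raise ValueError("no maxima in an all-zero histogram")
    cand = _local_maxima(y)
    offs = hist.offsets[cand]
    heights = y[cand]
    order = sorted(range(len(cand)), key=lambda k: (-heights[k], abs(offs[k]), offs[k]))
    chosen: list[int] = []
    for k in order:
        if all(abs(offs[k] - offs[c]) >= min_separation for c in chosen):
            chosen.append(k)
        if len(chosen) == n_peaks:
            break
    if len(chosen) < n_peaks:
        raise ValueError(
            f"found only {len(chosen)} maxima >= {min_separation} bp apart, "
            f"need {n_peaks}"
        )
    return PeakSet(offsets=offs[chosen], heights=heights[chosen])


def end_bias_histogram(
    fragments: FragmentSet,
    anchors: pd.DataFrame,
    flank: int = 500,
    window: int = 10,
) -> pd.DataFrame:
    """Separate left/right end counts in windows around pooled anchors.

    Returns a frame with (offset, left, right, bias) where ``offset`` is the
    window start relative to the anchor and ``bias = (left - right) /
    (left + right)`` (NaN for empty windows).  A symmetric, unbiased library
    has bias ~ 0 everywhere; AT-dependent fragment loss drives the bias
    negative where left-end-marked (rightward, anchor-spanning) fragments are
    lost and positive where right-end-marked fragments are lost.
    """
    left, right = _stack_ends(fragments, anchors, flank)
    n_win = (2 * flank + 1) // window
    trim = n_win * window
    lw = left[:trim].reshape(n_win, window).sum(axis=1)
    rw = right[:trim].reshape(n_win, window).sum(axis=1)
    offsets = -flank + window * np.arange(n_win)
    with np.errstate(invalid="ignore", divide="ignore"):
        bias = (lw - rw) / (lw + rw)
    return pd.DataFrame({"offset": offsets, "left": lw, "right": rw, "bias": bias})


def ratio_track(
    treatment: np.ndarray, control: np.ndarray, pseudocount: float = 0.5
) -> np.ndarray:
    """log2((treatment + eps) / (control + eps)) with a fixed pseudo-count.

    Positions where both inputs are zero map to exactly 0.
    """
    t = np.asarray(treatment, dtype=float)
    c = np.asarray(control, dtype=float)
    if t.shape != c.shape:
        raise ValueError("treatment and control tracks must have matching windows")
    return np.log2((t + pseudocount) / (c + pseudocount))
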