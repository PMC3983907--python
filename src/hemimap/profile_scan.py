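"""Centromere cleavage-profile construction, genome scanning, and jackknife.

A profile of per-bp total end counts is built from centromeres of similar
length, each aligned at its left-most cleavage peak (after reflecting
minus-strand loci so CDEI is leftmost) and truncated/padded to a fixed number
of positions (default 111).  Per-position mean, standard deviation, minimum
and maximum are recorded, along with the smallest member maximum — the
occupancy floor used as a scan filter.

Scanning slides the profile over every ungapped alignment start on the
forward strand of a per-bp count track.  Two filters are applied in order:
(1) at most ``max_z_violations`` positions may have |z| >= ``z_thresh``
relative to the profile (positions with sd = 0 contribute z = 0); (2) the
window must contain at least one position >= the smallest member maximum.
Passing windows are scored by the Pearson correlation with the profile mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .centromere_maps import EndCountTrack, _local_maxima, _smooth
from .fragment_io import CentromereAnnotation

__all__ = [
    "Profile",
    "ScanResult",
    "build_profile",
    "scan_chromosome",
    "rank_and_classify",
    "jackknife",
]


@dataclass
class Profile:
    """Per-position statistics of aligned centromere cleavage vectors."""

    mean: np.ndarray
    sd: np.ndarray
    minimum: np.ndarray
    maximum: np.ndarray
    members: list
    smallest_member_maximum: float

    @property
    def length(self) -> int:
        return self.mean.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(self.length),
                "mean": self.mean,
                "sd": self.sd,
                "min": self.minimum,
                "max": self.maximum,
            }
        )


def _member_vector(
    track: EndCountTrack,
    cen_row: pd.Series,
    profile_length: int,
    smooth_window: int,
    search_margin: int = 30,
    rel_height: float = 0.5,
):
    """Alignment vector for one centromere: counts from its left-most peak.

    The anchor is the left-most prominent local maximum (height at least
    ``rel_height`` of the tallest position in the centromere window) so that
    background-cut noise spikes cannot shift the alignment.  Returns None when
    no cleavage peak is detectable within the centromere.
    """
    total = track.total
    lo = max(0, int(cen_row["cen_start"]) - search_margin)
    hi = min(total.size, int(cen_row["cen_end"]) + search_margin)
    window = total[lo:hi].astype(float)
    if cen_row["strand"] == "-":
        window = window[::-1]
    smoothed = _smooth(window, smooth_window)
    maxima = _local_maxima(smoothed)
    maxima = maxima[smoothed[maxima] >= rel_height * smoothed.max()]
    if maxima.size == 0:
        return None
    anchor = int(maxima[0])  # left-most prominent peak, CDEI->CDEIII orientation
    vec = window[anchor : anchor + profile_length]
    if vec.size < profile_length:
        vec = np.pad(vec, (0, profile_length - vec.size))
    return vec


def build_profile(
    tracks: dict[str, EndCountTrack],
    annotation: CentromereAnnotation,
    profile_length: int = 111,
    member_length_range: tuple[int, int] = (117, 120),
    smooth_window: int = 1,
) -> Profile:
    """Aggregate aligned member centromeres into a scan profile."""
    lo, hi = member_length_range
    members = []
    vectors = []
    for _, cen in annotation.df.iterrows():
        if not (lo <= cen["total_length"] <= hi):
            continue
        track = tracks.get(cen["chrom"])
        if track is None or track.window != 1:
            raise ValueError("build_profile requires 1-bp tracks for every member chrom")
        vec = _member_vector(track, cen, profile_length, smooth_window)
        if vec is None:
            warnings.warn(f"centromere on {cen['chrom']} has no detectable peak; excluded")
            continue
        members.append(cen["chrom"])
        vectors.append(vec)
    if len(vectors) < 2:
        raise ValueError(f"need >=2 profile members, have {len(vectors)}")
    mat = np.vstack(vectors)
    return Profile(
        mean=mat.mean(axis=0),
        sd=mat.std(axis=0),
        minimum=mat.min(axis=0),
        maximum=mat.max(axis=0),
        members=members,
        smallest_member_maximum=float(mat.max(axis=1).min()),
    )


def scan_chromosome(
    profile: Profile,
    track: EndCountTrack,
    z_thresh: float = 3.0,
    max_z_violations: int = 3,
) -> pd.DataFrame:
    """Score every ungapped forward-strand alignment of the profile.

    Returns a frame with one row per start position: (start, r, passed,
    n_z_violations, has_min_max).  ``r`` is NaN for zero-variance windows,
    which are recorded as failed.
    """
    total = track.total.astype(float)
    P = profile.length
    if total.size < P:
        raise ValueError("track shorter than profile")
    win = np.lib.stride_tricks.sliding_window_view(total, P)

    sd = profile.sd.copy()
    live = sd > 0
    inv_sd = np.zeros_like(sd)
    inv_sd[live] = 1.0 / sd[live]
    z = (win - profile.mean) * inv_sd  # sd == 0 positions contribute z = 0
    n_viol = (np.abs(z) >= z_thresh).sum(axis=1)
    has_min_max = win.max(axis=1) >= profile.smallest_member_maximum
    passed = (n_viol <= max_z_violations) & has_min_max

    mu_w = win.mean(axis=1)
    sd_w = win.std(axis=1)
    mu_p = profile.mean.mean()
    sd_p = profile.mean.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = win @ profile.mean / P - mu_w * mu_p
        r = cov / (sd_w * sd_p)
    degenerate = (sd_w == 0) | (sd_p == 0)
    r[degenerate] = np.nan
    passed &= ~degenerate

    return pd.DataFrame(
        {
            "start": np.arange(win.shape[0]),
            "r": r,
            "passed": passed,
            "n_z_violations": n_viol,
            "has_min_max": has_min_max,
        }
    )


@dataclass
class ScanResult:
    """Per-chromosome scan summary mirroring the profile-scan report columns."""

    chrom: str
    n_aligned: int
    n_pass: int
    first_cen_r: float  # NaN when the centromere is excluded by the filters
    first_cen_rank: int  # rank among passing hits by r (1 = best); -1 if absent
    first_fp_r: float
    centromere_outranks_all: bool


def rank_and_classify(
    hits: pd.DataFrame,
    annotation: CentromereAnnotation,
    chrom: str,
    profile_length: int = 111,
) -> ScanResult:
    """Identify the best-scoring centromere and non-centromere alignments.

    A hit overlaps the centromere when its window intersects the annotated
    span.  Ties in r favour the centromere hit.  Only hits passing both
    filters are ranked.
    """
    cen = annotation.df[annotation.df["chrom"] == chrom]
    passing = hits[hits["passed"]].copy()
    if cen.empty:
        is_cen = np.zeros(len(passing), dtype=bool)
    else:
        s = int(cen.iloc[0]["cen_start"])
        e = int(cen.iloc[0]["cen_end"])
        starts = passing["start"].to_numpy()
        is_cen = (starts < e) & (starts + profile_length > s)
    passing["is_cen"] = is_cen
    # sort by r descending; centromere hits first on exact ties
    passing = passing.sort_values(
        ["r", "is_cen"], ascending=[False, False], kind="mergesort"
    )
    cen_hits = passing[passing["is_cen"]]
    fp_hits = passing[~passing["is_cen"]]
    first_cen_r = float(cen_hits.iloc[0]["r"]) if len(cen_hits) else float("nan")
    first_fp_r = float(fp_hits.iloc[0]["r"]) if len(fp_hits) else float("nan")
    if len(cen_hits):
        rank = int(np.searchsorted(-passing["r"].to_numpy(), -first_cen_r) + 1)
        outranks = not len(fp_hits) or first_cen_r > first_fp_r
    else:
        rank = -1
        outranks = False
    return ScanResult(
        chrom=chrom,
        n_aligned=len(hits),
        n_pass=int(hits["passed"].sum()),
        first_cen_r=first_cen_r,
        first_cen_rank=rank,
        first_fp_r=first_fp_r,
        centromere_outranks_all=outranks,
    )


def scan_genome(
    profile: Profile,
    tracks: dict[str, EndCountTrack],
    annotation: CentromereAnnotation,
    **scan_kwargs,
) -> pd.DataFrame:
    """Scan every chromosome and summarize per-chrom results plus medians.

    The median row aggregates across chromosomes (alignment and pass counts,
    first-centromere r, first-false-positive r); NaN entries (e.g. excluded
    centromeres) are ignored by the median, and the convention is recorded in
    the column name.
    """
    rows = []
    for chrom, track in tracks.items():
        hits = scan_chromosome(profile, track, **scan_kwargs)
        res = rank_and_classify(hits, annotation, chrom, profile.length)
        rows.append(res.__dict__)
    return pd.DataFrame(rows)


def jackknife(
    tracks: dict[str, EndCountTrack],
    annotation: CentromereAnnotation,
    profile_length: int = 111,
    member_length_range: tuple[int, int] = (117, 120),
    smooth_window: int = 1,
    **scan_kwargs,
) -> pd.DataFrame:
    """Delete-one jackknife: rebuild the profile without each member and
    rescan that member's chromosome.

    Returns one row per deleted member with its centromere r under the reduced
    profile (NaN when the deleted centromere itself no longer passes the
    filters — exclusion, not a score) and the first false-positive r.
    """
    full = build_profile(tracks, annotation, profile_length, member_length_range, smooth_window)
    if len(full.members) < 3:
        raise ValueError("jackknife requires >=3 profile members")
    rows = []
    for left_out in full.members:
        sub_ann = CentromereAnnotation(
            annotation.df[annotation.df["chrom"] != left_out][
                [c for c in annotation.df.columns
                 if c in ("chrom", "cde1_start", "cde1_end", "cde2_start",
                          "cde2_end", "cde3_start", "cde3_end", "strand")]
            ]
        )
        reduced = build_profile(
            tracks, sub_ann, profile_length, member_length_range, smooth_window
        )
        hits = scan_chromosome(reduced, tracks[left_out], **scan_kwargs)
        res = rank_and_classify(hits, annotation, left_out, profile_length)
        rows.append(
            {
                "deleted": left_out,
                "excluded_by_filters": np.isnan(res.first_cen_r),
                "cen_r": res.first_cen_r,
                "first_fp_r": res.first_fp_r,
                "n_pass": res.n_pass,
            }
        )
    return pd.DataFrame(rows)
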