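"""Contact geometry of H4S47C-phenanthroline-Cu(+) cleavage and its enumeration oracles.

A phenanthroline-copper adduct on histone H4 residue 47 directs hydroxy-radical
cleavage to a handful of fixed positions around the nucleosome dyad: the copper
reaches the C1' hydrogen of the deoxyribose at dyad-relative offsets -2, -3, -4
on the Watson strand and -5, -6 on the Crick strand.  In a particle with two H4
copies (octasome or tetrasome) the second copy contributes the mirror-image
contacts (+5, +6 Watson; +2, +3, +4 Crick).  Cleavage removes the attacked
nucleotide; after sequencing-library end polishing (3' overhang trimming, 5'
fill-in) the downstream fragment's left end maps to ``watson_pos + 1`` and the
upstream fragment's right end maps to ``crick_pos - 1``.  That convention is the
single source of truth used by both the simulator and the oracles here.

The enumeration oracles in this module predict, exactly, the distributions of
distances between observed fragment ends (left-to-right "W-C", left-to-left
"W-W'", right-to-right "C-C'") generated by cleavage events around a single
dyad.  They are the reference against which all empirical distance statistics
are checked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Pairing",
    "ContactModel",
    "CutSite",
    "DistanceDistribution",
    "observed_ends",
    "predict_distance_distribution",
    "predict_cleavage_profile",
    "DEFAULT_WC_RANGE",
    "DEFAULT_SAME_STRAND_RANGE",
]

#: Lag window over which opposite-strand (W-C) end distances are tabulated.
DEFAULT_WC_RANGE = (-40, 40)
#: Lag window for same-strand (W-W' / C-C') end distances; lag 0 is excluded.
DEFAULT_SAME_STRAND_RANGE = (1, 40)

# Frozen calibration of contact probabilities.  The structural model fixes the
# offsets; the relative probabilities are encoded only as shading in the source
# structure, so they are calibrated once such that the predicted mode sets are
# {-2, +5, +12} (W-C) and {+1, +7} (W-W'/C-C'), and then frozen.
_DEFAULT_COPY1_WATSON = ((-2, 0.7), (-3, 0.2), (-4, 0.1))
_DEFAULT_COPY1_CRICK = ((-5, 0.8), (-6, 0.2))


class Pairing(str, Enum):
    """Which pair of observed fragment-end classes a distance distribution uses."""

    WC = "WC"  # left end vs right end (opposite strands)
    WW = "WW"  # left end vs left end (Watson cleavages)
    CC = "CC"  # right end vs right end (Crick cleavages)


Contacts = tuple[tuple[int, float], ...]


def _normalize_contacts(contacts: Iterable[tuple[int, float]]) -> Contacts:
    items = tuple((int(o), float(w)) for o, w in contacts)
    if not items:
        raise ValueError("contact list must not be empty")
    if any(w <= 0 for _, w in items):
        raise ValueError("contact weights must be > 0")
    total = sum(w for _, w in items)
    if abs(total - 1.0) <= 1e-9:  # keep already-normalized weights bit-exact
        return items
    return tuple((o, w / total) for o, w in items)


def _mirror(contacts: Contacts) -> Contacts:
    """Dyad reflection: a Watson contact at offset o maps to a Crick contact at -o."""
    return tuple((-o, w) for o, w in contacts)


@dataclass(frozen=True)
class ContactModel:
    """Dyad-relative cleavage offsets with contact probabilities, per H4 copy.

    ``copy1`` is the H4 whose contacts lie on the negative (left) side of the
    dyad; in a two-copy particle ``copy2`` is its mirror image under the dyad
    reflection (Watson offset ``o`` <-> Crick offset ``-o``).
    """

    copy1_watson: Contacts = _DEFAULT_COPY1_WATSON
    copy1_crick: Contacts = _DEFAULT_COPY1_CRICK
    copy2_watson: Contacts | None = None
    copy2_crick: Contacts | None = None
    n_h4_copies: int = 2

    def __post_init__(self) -> None:
        if self.n_h4_copies not in (1, 2):
            raise ValueError("n_h4_copies must be 1 or 2")
        object.__setattr__(self, "copy1_watson", _normalize_contacts(self.copy1_watson))
        object.__setattr__(self, "copy1_crick", _normalize_contacts(self.copy1_crick))
        if self.n_h4_copies == 2:
            cw = self.copy2_watson if self.copy2_watson is not None else _mirror(self.copy1_crick)
            cc = self.copy2_crick if self.copy2_crick is not None else _mirror(self.copy1_watson)
            object.__setattr__(self, "copy2_watson", _normalize_contacts(cw))
            object.__setattr__(self, "copy2_crick", _normalize_contacts(cc))
        else:
            object.__setattr__(self, "copy2_watson", None)
            object.__setattr__(self, "copy2_crick", None)

    # -- constructors -------------------------------------------------------

    @classmethod
    def default_two_copy(cls) -> "ContactModel":
        """The frozen calibrated model for particles with two H4 copies."""
        return cls()

    @classmethod
    def single_copy(cls) -> "ContactModel":
        """The frozen calibrated model restricted to one H4 copy (hemisome)."""
        return cls(n_h4_copies=1)

    def mirrored(self) -> "ContactModel":
        """Reflect the model through the dyad (swap strands, negate offsets).

        Used for hemisomes in the opposite orientation.
        """
        if self.n_h4_copies == 1:
            return ContactModel(
                copy1_watson=_mirror(self.copy1_crick),
                copy1_crick=_mirror(self.copy1_watson),
                n_h4_copies=1,
            )
        return ContactModel(
            copy1_watson=_mirror(self.copy2_crick),
            copy1_crick=_mirror(self.copy2_watson),
            copy2_watson=_mirror(self.copy1_crick),
            copy2_crick=_mirror(self.copy1_watson),
            n_h4_copies=2,
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "n_h4_copies": self.n_h4_copies,
            "copy1_watson": [list(c) for c in self.copy1_watson],
            "copy1_crick": [list(c) for c in self.copy1_crick],
        }
        if self.n_h4_copies == 2:
            d["copy2_watson"] = [list(c) for c in self.copy2_watson]
            d["copy2_crick"] = [list(c) for c in self.copy2_crick]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ContactModel":
        kwargs = {
            "n_h4_copies": int(d.get("n_h4_copies", 2)),
            "copy1_watson": [tuple(c) for c in d["copy1_watson"]],
            "copy1_crick": [tuple(c) for c in d["copy1_crick"]],
        }
        if "copy2_watson" in d:
            kwargs["copy2_watson"] = [tuple(c) for c in d["copy2_watson"]]
        if "copy2_crick" in d:
            kwargs["copy2_crick"] = [tuple(c) for c in d["copy2_crick"]]
        return cls(**kwargs)

    # -- derived quantities --------------------------------------------------

    def copies(self) -> list[tuple[Contacts, Contacts]]:
        out = [(self.copy1_watson, self.copy1_crick)]
        if self.n_h4_copies == 2:
            out.append((self.copy2_watson, self.copy2_crick))
        return out

    def left_end_offsets(self) -> dict[int, float]:
        """Marginal distribution of observed left-end offsets (dyad-relative)."""
        out: dict[int, float] = {}
        per_copy = 1.0 / self.n_h4_copies
        for watson, _ in self.copies():
            for o, w in watson:
                out[o + 1] = out.get(o + 1, 0.0) + w * per_copy
        return out

    def right_end_offsets(self) -> dict[int, float]:
        """Marginal distribution of observed right-end offsets (dyad-relative)."""
        out: dict[int, float] = {}
        per_copy = 1.0 / self.n_h4_copies
        for _, crick in self.copies():
            for o, w in crick:
                out[o - 1] = out.get(o - 1, 0.0) + w * per_copy
        return out


@dataclass(frozen=True)
class CutSite:
    """A double-strand cleavage: the genomic bp lost on each strand.

    ``source`` records whether the cut came from a nucleosomal particle,
    background (linker/NDR) cleavage, or a fixed restriction site.
    """

    watson_pos: int
    crick_pos: int
    source: str = "particle"

    def __post_init__(self) -> None:
        if self.watson_pos is None or self.crick_pos is None:
            raise ValueError("cut requires both strand positions")
        if self.source == "particle" and self.watson_pos == self.crick_pos:
            raise ValueError(
                "identical-offset particle cut cannot arise under the default model"
            )


def observed_ends(cut: CutSite) -> tuple[int, int]:
    """Blunt-end coordinates observed after base loss and end polishing.

    Returns ``(left_end, right_end)`` where ``left_end`` is the 0-based start of
    the downstream fragment (``watson_pos + 1``) and ``right_end`` the 0-based
    inclusive last base of the upstream fragment (``crick_pos - 1``).
    """
    return cut.watson_pos + 1, cut.crick_pos - 1


@dataclass
class DistanceDistribution:
    """Normalized distribution of fragment-end distances over a lag window."""

    pairing: Pairing
    lags: np.ndarray
    frequency: np.ndarray
    n_pairs: float = np.nan  # total (weighted) pair count inside the window

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=int)
        self.frequency = np.asarray(self.frequency, dtype=float)
        if self.lags.shape != self.frequency.shape:
            raise ValueError("lags and frequency must have equal shapes")
        if np.any(self.frequency < 0):
            raise ValueError("frequencies must be >= 0")

    def modes(self) -> list[int]:
        """Lags of the local maxima of the distribution, in increasing lag order.

        A position is a local maximum if its frequency exceeds both neighbours
        (window edges compare against an implicit zero outside).
        """
        f = self.frequency
        padded = np.concatenate([[0.0], f, [0.0]])
        is_max = (padded[1:-1] > padded[:-2]) & (padded[1:-1] > padded[2:]) & (f > 0)
        return [int(l) for l in self.lags[is_max]]

    def major_modes(self, rel_height: float = 0.2) -> list[int]:
        """Local maxima whose frequency is at least ``rel_height`` of the peak.

        Noise on empirical distributions produces shallow local maxima; a
        relative-height cutoff keeps only the peaks a reader would call modes.
        """
        peak = float(self.frequency.max())
        return [m for m in self.modes() if self.frequency_at(m) >= rel_height * peak]

    def frequency_at(self, lag: int) -> float:
        idx = np.where(self.lags == lag)[0]
        return float(self.frequency[idx[0]]) if idx.size else 0.0

    def to_tsv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.lags, self.frequency]),
            fmt=("%d", "%.8g"),
            delimiter="\t",
            header="lag\tfrequency",
            comments="",
        )


def _cut_events(model: ContactModel) -> list[tuple[int, int, float]]:
    """All (left_end_offset, right_end_offset, probability) cut events."""
    events = []
    per_copy = 1.0 / model.n_h4_copies
    for watson, crick in model.copies():
        for wo, ww in watson:
            for co, cw in crick:
                events.append((wo + 1, co - 1, ww * cw * per_copy))
    return events


def predict_distance_distribution(
    model: ContactModel,
    pairing: Pairing | str,
    lag_range: tuple[int, int] | None = None,
) -> DistanceDistribution:
    """Brute-force enumeration of the end-distance distribution around one dyad.

    Every ordered pair of observed ends produced by two independent cleavage
    events is enumerated with probability equal to the product of its contact
    weights; for the WC pairing the distance is ``left_end - right_end``, for
    WW (CC) the positive distance between two distinct left (right) ends.  The
    result is normalized over ``lag_range``.
    """
    pairing = Pairing(pairing)
    if lag_range is None:
        lag_range = DEFAULT_WC_RANGE if pairing is Pairing.WC else DEFAULT_SAME_STRAND_RANGE
    lo, hi = lag_range
    lags = np.arange(lo, hi + 1)
    mass = np.zeros(lags.size)

    if pairing is Pairing.WC:
        lefts = model.left_end_offsets()
        rights = model.right_end_offsets()
        for l, wl in lefts.items():
            for r, wr in rights.items():
                d = l - r
                if lo <= d <= hi:
                    mass[d - lo] += wl * wr
    else:
        ends = model.left_end_offsets() if pairing is Pairing.WW else model.right_end_offsets()
        items = list(ends.items())
        for x, wx in items:
            for y, wy in items:
                d = y - x
                if d == 0:
                    continue  # lag 0 excluded for same-strand pairings
                if lo <= d <= hi:
                    mass[d - lo] += wx * wy

    total = mass.sum()
    if total == 0:
        raise ValueError("no end pairs fall inside the lag range")
    return DistanceDistribution(pairing, lags, mass / total, n_pairs=total)


def predict_cleavage_profile(
    template_length: int,
    model: ContactModel,
    dyad_index: int | None = None,
) -> dict:
    """Expected per-bp cleavage frequency on each strand of a linear template.

    ``dyad_index`` is 1-based when supplied by the caller (as it is in
    user-facing reports); the default places the dyad at the center of the
    template, e.g. base 74 of a 147-bp duplex.  Offsets falling outside the
    template are clipped and reported under ``"clipped"``.
    """
    if dyad_index is None:
        dyad_index = (template_length + 1) // 2
    if not (1 <= dyad_index <= template_length):
        raise ValueError("dyad_index outside template")
    d0 = dyad_index - 1  # 0-based internal
    watson = np.zeros(template_length)
    crick = np.zeros(template_length)
    clipped = []
    per_copy = 1.0 / model.n_h4_copies
    for w_contacts, c_contacts in model.copies():
        for strand, contacts in (("watson", w_contacts), ("crick", c_contacts)):
            arr = watson if strand == "watson" else crick
            for o, w in contacts:
                pos = d0 + o
                if 0 <= pos < template_length:
                    arr[pos] += w * per_copy
                else:
                    clipped.append((strand, o))
    return {
        "watson": watson,
        "crick": crick,
        "dyad_index": dyad_index,
        "clipped": clipped,
    }
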