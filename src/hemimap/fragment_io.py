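"""Readers/writers and fragment algebra shared by all analysis stages.

Coordinates are 0-based half-open (BED convention) everywhere internally.  A
fragment ``[start, end)`` has ``left_end = start`` (the Watson-strand cleavage
position after base loss and polishing), ``right_end = end - 1`` (the Crick
cleavage position), and ``midpoint = floor((start + end - 1) / 2)``.  1-based
coordinates appear only in user-facing reports.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Genome",
    "CentromereAnnotation",
    "FragmentSet",
    "read_inputs",
    "read_centromere_tsv",
    "filter_by_length",
    "length_distribution",
]

_CEN_COLUMNS = [
    "chrom",
    "cde1_start",
    "cde1_end",
    "cde2_start",
    "cde2_end",
    "cde3_start",
    "cde3_end",
    "strand",
]


class Genome:
    """Chromosome sequences with cached AT indicators.

    Thin wrapper so the analysis code works identically on a synthetic
    in-memory genome and on a FASTA file read through pyfaidx.
    """

    def __init__(self, sequences: dict[str, str]):
        self._seqs = {c: s.upper() for c, s in sequences.items()}
        self._at_cache: dict[str, np.ndarray] = {}

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path))
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def chroms(self) -> list[str]:
        return list(self._seqs)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def seq(self, chrom: str) -> str:
        return self._seqs[chrom]

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def total_length(self) -> int:
        return sum(len(s) for s in self._seqs.values())

    def at_indicator(self, chrom: str) -> np.ndarray:
        """uint8 array: 1 where the base is A or T (ambiguous bases count 0)."""
        if chrom not in self._at_cache:
            arr = np.frombuffer(self._seqs[chrom].encode("ascii"), dtype=np.uint8)
            self._at_cache[chrom] = ((arr == ord("A")) | (arr == ord("T"))).astype(np.uint8)
        return self._at_cache[chrom]

    def at_fraction(self, chrom: str, start: int, end: int) -> float:
        if end <= start:
            raise ValueError("empty interval")
        return float(self.at_indicator(chrom)[start:end].mean())

    def reverse_complement(self) -> "Genome":
        comp = str.maketrans("ACGTN", "TGCAN")
        return Genome({c: s.translate(comp)[::-1] for c, s in self._seqs.items()})

    def to_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self._seqs.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


class CentromereAnnotation:
    """CDEI/CDEII/CDEIII intervals and strand for each centromere.

    Derived anchors: ``mid_cen`` (midpoint of CDEII, the composite-alignment
    anchor) and ``total_length`` (CDEI+CDEII+CDEIII span).  Centromeres
    annotated on the minus strand have CDEI genomically rightmost; analysis
    code reflects coordinates through ``mid_cen`` so CDEI is always leftmost
    in composite/profile space.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in _CEN_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"centromere table missing columns: {missing}")
        df = df.reset_index(drop=True).copy()
        self._validate(df)
        df["mid_cen"] = (df["cde2_start"] + df["cde2_end"] - 1) // 2
        lo = df[["cde1_start", "cde2_start", "cde3_start"]].min(axis=1)
        hi = df[["cde1_end", "cde2_end", "cde3_end"]].max(axis=1)
        df["cen_start"] = lo
        df["cen_end"] = hi
        df["total_length"] = hi - lo
        self.df = df

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        for i, row in df.iterrows():
            for ele in ("cde1", "cde2", "cde3"):
                if row[f"{ele}_end"] <= row[f"{ele}_start"]:
                    raise ValueError(f"centromere row {i}: empty {ele.upper()} interval")
            if row["strand"] not in ("+", "-"):
                raise ValueError(f"centromere row {i}: strand must be '+' or '-'")
            order = ["cde1", "cde2", "cde3"]
            if row["strand"] == "-":
                order = order[::-1]
            prev_end = None
            for ele in order:
                s, e = row[f"{ele}_start"], row[f"{ele}_end"]
                if prev_end is not None:
                    gap = s - prev_end
                    if gap < 0 or gap > 2:
                        raise ValueError(
                            f"centromere row {i}: CDE elements out of order or "
                            f"separated by more than 2 bp on the annotated strand"
                        )
                prev_end = e

    def __len__(self) -> int:
        return len(self.df)

    def subset_by_length(self, lengths) -> "CentromereAnnotation":
        lengths = set(int(x) for x in lengths)
        sub = self.df[self.df["total_length"].isin(lengths)]
        if sub.empty:
            raise ValueError(f"no centromeres with total length in {sorted(lengths)}")
        return CentromereAnnotation(sub[_CEN_COLUMNS])

    def anchors(self) -> pd.DataFrame:
        """(chrom, pos, strand) anchor table at mid-Cen, for composite stacking."""
        return self.df[["chrom", "mid_cen", "strand"]].rename(columns={"mid_cen": "pos"})

    def to_tsv(self, path) -> None:
        self.df[_CEN_COLUMNS].to_csv(path, sep="\t", index=False)


def read_centromere_tsv(path) -> CentromereAnnotation:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    except Exception as exc:  # pragma: no cover - pandas formats the message
        raise ValueError(f"malformed centromere TSV {path}: {exc}") from exc
    return CentromereAnnotation(df)


@dataclass
class FragmentSet:
    """Mapped paired-end fragments, grouped by chromosome and sorted.

    ``provenance`` records source files and filters, append-only.
    """

    df: pd.DataFrame
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.df
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise ValueError(f"fragment table missing column {col!r}")
        bad = df["end"] <= df["start"]
        if bad.any():
            raise ValueError(f"{int(bad.sum())} fragment(s) with end <= start")
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        self.df = df

    # -- construction -------------------------------------------------------

    @classmethod
    def from_arrays(cls, chrom, start, end, provenance=None) -> "FragmentSet":
        return cls(
            pd.DataFrame({"chrom": chrom, "start": start, "end": end}),
            provenance=list(provenance or []),
        )

    @classmethod
    def from_bed(cls, *paths) -> "FragmentSet":
        """Read and pool one or more BED3 files (one record per fragment)."""
        frames = []
        for path in paths:
            rows = []
            with open(path) as fh:
                for ln, line in enumerate(fh, start=1):
                    line = line.strip()
                    if not line or line.startswith(("#", "track", "browser")):
                        continue
                    parts = line.split("\t")
                    if len(parts) < 3:
                        raise ValueError(f"{path}:{ln}: fewer than 3 BED columns")
                    try:
                        start, end = int(parts[1]), int(parts[2])
                    except ValueError as exc:
                        raise ValueError(f"{path}:{ln}: non-integer coordinates") from exc
                    if end <= start:
                        raise ValueError(f"{path}:{ln}: end <= start")
                    rows.append((parts[0], start, end))
            frames.append(pd.DataFrame(rows, columns=["chrom", "start", "end"]))
        df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["chrom", "start", "end"]
        )
        return cls(df, provenance=[f"bed:{p}" for p in paths])

    def to_bed(self, path) -> None:
        self.df[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)

    # -- derived columns ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def chrom(self) -> pd.Series:
        return self.df["chrom"]

    @property
    def start(self) -> np.ndarray:
        return self.df["start"].to_numpy()

    @property
    def end(self) -> np.ndarray:
        return self.df["end"].to_numpy()

    @property
    def left_end(self) -> np.ndarray:
        return self.start

    @property
    def right_end(self) -> np.ndarray:
        return self.end - 1

    @property
    def length(self) -> np.ndarray:
        return self.end - self.start

    @property
    def midpoint(self) -> np.ndarray:
        return (self.start + self.end - 1) // 2

    def per_chrom(self):
        for chrom, sub in self.df.groupby("chrom", sort=True, observed=True):
            yield chrom, sub

    def subset(self, mask, note: str | None = None) -> "FragmentSet":
        out = FragmentSet(self.df[np.asarray(mask)], provenance=list(self.provenance))
        if note:
            out.provenance.append(note)
        return out

    def pooled_with(self, other: "FragmentSet") -> "FragmentSet":
        return FragmentSet(
            pd.concat([self.df, other.df], ignore_index=True),
            provenance=self.provenance + other.provenance,
        )


def read_inputs(genome_path, centromere_path, *fragment_paths):
    """Load genome FASTA, centromere TSV, and pooled fragment BED3 files.

    Chromosome names are cross-validated: fragments or centromeres on a
    chromosome absent from the genome raise with the offending names listed.
    """
    genome = Genome.from_fasta(genome_path)
    annotation = read_centromere_tsv(centromere_path)
    fragments = FragmentSet.from_bed(*fragment_paths)

    unknown = sorted(set(fragments.df["chrom"]) - set(genome.chroms()))
    if unknown:
        raise ValueError(f"fragments reference unknown chromosomes: {unknown}")
    unknown = sorted(set(annotation.df["chrom"]) - set(genome.chroms()))
    if unknown:
        raise ValueError(f"centromeres reference unknown chromosomes: {unknown}")
    for _, row in annotation.df.iterrows():
        if row["cen_end"] > genome.length(row["chrom"]):
            raise ValueError(f"centromere on {row['chrom']} extends past chromosome end")
    return genome, annotation, fragments


def filter_by_length(fragments: FragmentSet, min_length: int = 147) -> FragmentSet:
    """Drop fragments shorter than ``min_length`` (default 147 bp).

    Nucleosome center-to-center distances are at least one wrap, so shorter
    fragments cannot be particle-to-particle products.
    """
    return fragments.subset(
        fragments.length >= min_length, note=f"filter:min_length>={min_length}"
    )


def length_distribution(fragments: FragmentSet) -> pd.Series:
    """Percentage of fragments at each observed length; sums to 100."""
    if len(fragments) == 0:
        raise ValueError("empty fragment set")
    counts = pd.Series(fragments.length).value_counts().sort_index()
    return 100.0 * counts / counts.sum()
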