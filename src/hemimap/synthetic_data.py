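"""Synthetic genomes, particle placements, and paired-end cleavage fragments.

The generator emulates the statistical structure that the analysis assumes:

* a multi-chromosome genome with one point centromere per chromosome, built
  from an 8-bp CDEI, a 78-86 bp CDEII of >=90% A+T, and a 26-bp CDEIII;
* phased arm nucleosomes (H3/H4 octasomes, two H4 copies) at regular spacing,
  with nucleosome-depleted regions and a centromere-proximal exclusion zone;
* centromeric particles under a configurable architecture: octasome,
  tetrasome, a hemisome mixture (two reflectional orientations x two
  rotational phases, mutually exclusive per molecule), or none;
* per-molecule double-strand cuts drawn from the contact model, plus uniform
  background cleavage in linkers and elevated background in NDRs, plus an
  optional fixed-site (restriction) cutting mode;
* fragments formed between consecutive cuts with the base-loss/end-polishing
  offsets of :mod:`hemimap.cleavage_model`;
* an AT-dependent recovery bias that discards fragments carrying strongly
  AT-rich stretches, emulating the sequencing-platform bias against >90% A+T
  templates.

Hemisome placement is junction-anchored: the cleavage anchor sits a fixed
``junction_anchor_offset`` (default 22 bp) from the nearer CDE junction, and
the second rotational phase is shifted one helical turn (10 bp) toward the
CDEII midpoint.  With the frozen contact model this geometry places composite
cleavage maxima 10 bp apart within clusters and, pooled over 117-120 bp
centromeres, 33 bp (inner) and 53 bp (outer) apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cleavage_model import ContactModel
from .fragment_io import CentromereAnnotation, FragmentSet, Genome

__all__ = [
    "SyntheticGenomeSpec",
    "ParticleModel",
    "ATBiasModel",
    "BackgroundModel",
    "SimulationResult",
    "generate_genome",
    "simulate_fragments",
    "apply_recovery_bias",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Layout and composition of a synthetic genome."""

    n_chromosomes: int = 16
    chrom_length: int = 8000
    n_centromeres: int = 16  # one per chromosome, taken in chromosome order
    cde1_len: int = 8
    cde2_len: tuple[int, int] | int = (78, 86)  # sampled inclusive range, or fixed
    cde3_len: int = 26
    cde2_min_at: float = 0.90
    cde2_max_at: float = 0.98
    genome_at: float = 0.62  # background A+T fraction (yeast-like)
    arm_nucleosome_spacing: int = 165
    cen_exclusion: int = 200  # no arm dyad within this distance of mid-Cen
    ndr_positions: tuple[int, ...] = ()  # per-chromosome bp positions
    ndr_halfwidth: int = 80
    edge_margin: int = 100  # no arm dyad closer than this to a chromosome end
    cen_strands: str = "+"  # "+", "-", or "alternate"
    seed: int = 0

    def cde2_lengths(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if isinstance(self.cde2_len, int):
            return np.full(n, self.cde2_len)
        lo, hi = self.cde2_len
        return rng.integers(lo, hi + 1, size=n)


@dataclass(frozen=True)
class ParticleModel:
    """Architecture of the centromeric particle.

    ``hemisome_mixture`` places, per molecule, exactly one hemisome in one of
    four mutually exclusive configurations: orientation (CDEI-proximal vs
    CDEIII-proximal) x rotational phase (0 or 1 helical turn from the
    junction-anchored position).
    """

    kind: str = "hemisome_mixture"  # octasome | tetrasome | hemisome_mixture | none
    orientation_proportions: tuple[float, float] = (0.5, 0.5)
    phase_offset: int = 10
    phase_proportions: tuple[float, float] = (0.5, 0.5)
    junction_anchor_offset: int = 22

    def __post_init__(self) -> None:
        if self.kind not in ("octasome", "tetrasome", "hemisome_mixture", "none"):
            raise ValueError(f"unknown particle kind {self.kind!r}")
        for props in (self.orientation_proportions, self.phase_proportions):
            if abs(sum(props) - 1.0) > 1e-9 or any(p < 0 for p in props):
                raise ValueError("proportions must be non-negative and sum to 1")
        if self.phase_offset <= 0:
            raise ValueError("phase_offset must be > 0")
        if self.junction_anchor_offset < 0:
            raise ValueError("junction_anchor_offset must be >= 0")


@dataclass(frozen=True)
class ATBiasModel:
    """AT-dependent fragment-recovery bias.

    Retention is 1 for fragments whose AT statistic is below ``at_threshold``
    and declines monotonically to ``floor`` at 100% A+T.  The statistic is, by
    default, the maximum A+T fraction over any ``stat_window``-bp window inside
    the fragment (``stat="window_max"``): what is discriminated against in
    sequencing is the presence of a long extremely AT-rich stretch, not the
    fragment-average composition.  ``stat="whole"`` uses the fragment-wide
    fraction instead.
    """

    at_threshold: float = 0.90
    floor: float = 0.05
    shape: float = 0.5
    stat: str = "window_max"
    stat_window: int = 50

    def retention(self, at_fraction: np.ndarray) -> np.ndarray:
        a = np.asarray(at_fraction, dtype=float)
        t = self.at_threshold
        if t >= 1.0:  # threshold above any possible A+T fraction: no bias
            return np.ones_like(a)
        excess = np.clip((a - t) / (1.0 - t), 0.0, 1.0)
        return 1.0 - (1.0 - self.floor) * excess**self.shape


@dataclass(frozen=True)
class BackgroundModel:
    """Non-nucleosomal cleavage: uniform linker background, elevated NDR
    background, and an optional fixed-site (restriction) cutting mode."""

    linker_rate: float = 2e-4  # cuts per bp per molecule
    ndr_rate: float = 1e-3
    fixed_site: str | None = None  # e.g. "AGCT"; cut to completion when set
    fixed_site_cut_offset: int = 2  # blunt cut after this many motif bases

    def __post_init__(self) -> None:
        if self.linker_rate < 0 or self.ndr_rate < 0:
            raise ValueError("background rates must be >= 0")


def _random_sequence(rng: np.random.Generator, n: int, at: float) -> np.ndarray:
    """Random uint8 base array with expected A+T fraction ``at``."""
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _cde2_sequence(rng: np.random.Generator, n: int, min_at: float, max_at: float) -> np.ndarray:
    """AT-rich CDEII draw with an exact A+T count >= ceil(n * min_at)."""
    frac = rng.uniform(min_at, max_at)
    n_at = max(int(np.ceil(n * min_at)), int(round(n * frac)))
    n_at = min(n_at, n)
    seq = np.empty(n, dtype=np.uint8)
    at_choices = np.frombuffer(b"AT", dtype=np.uint8)
    gc_choices = np.frombuffer(b"GC", dtype=np.uint8)
    seq[:n_at] = at_choices[rng.integers(0, 2, size=n_at)]
    seq[n_at:] = gc_choices[rng.integers(0, 2, size=n - n_at)]
    return seq[rng.permutation(n)]


def generate_genome(
    spec: SyntheticGenomeSpec,
    particle_model: ParticleModel = ParticleModel(),
) -> tuple[Genome, CentromereAnnotation, pd.DataFrame]:
    """Build genome sequence, centromere annotation, and particle placements.

    The placement table has one row per arm nucleosome and, for centromeres,
    one row per candidate particle configuration with its occupancy
    proportion (four rows for a hemisome mixture, one for octasome/tetrasome,
    none for ``kind="none"``).  Columns: chrom, particle_id, kind, anchor
    (dyad, or hemisome cleavage anchor), orientation (+1: contact model used
    as-is, i.e. single-copy cleavages fall genomically left of the anchor;
    -1: mirrored), orientation_label, phase, proportion, cen_index.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.n_centromeres > spec.n_chromosomes:
        raise ValueError("n_centromeres may not exceed n_chromosomes")

    cde2_lens = spec.cde2_lengths(rng, spec.n_centromeres)
    cen_totals = spec.cde1_len + cde2_lens + spec.cde3_len
    if np.any(cen_totals > spec.chrom_length):
        raise ValueError("centromere longer than chromosome")

    seqs: dict[str, str] = {}
    cen_rows = []
    placements = []
    pid = 0
    d = particle_model.junction_anchor_offset
    p_off = particle_model.phase_offset

    for ci in range(spec.n_chromosomes):
        chrom = f"chr{ci + 1}"
        L = spec.chrom_length
        seq = _random_sequence(rng, L, spec.genome_at)

        has_cen = ci < spec.n_centromeres
        mid_cen = None
        if has_cen:
            L2 = int(cde2_lens[ci])
            total = spec.cde1_len + L2 + spec.cde3_len
            cen_start = (L - total) // 2
            if spec.cen_strands == "alternate":
                strand = "+" if ci % 2 == 0 else "-"
            else:
                strand = spec.cen_strands
            # element order along the genome: CDEI first on '+', last on '-'
            if strand == "+":
                b1 = (cen_start, cen_start + spec.cde1_len)
                b2 = (b1[1], b1[1] + L2)
                b3 = (b2[1], b2[1] + spec.cde3_len)
            else:
                b3 = (cen_start, cen_start + spec.cde3_len)
                b2 = (b3[1], b3[1] + L2)
                b1 = (b2[1], b2[1] + spec.cde1_len)
            seq[b2[0] : b2[1]] = _cde2_sequence(rng, L2, spec.cde2_min_at, spec.cde2_max_at)
            mid_cen = (b2[0] + b2[1] - 1) // 2
            cen_rows.append(
                dict(
                    chrom=chrom,
                    cde1_start=b1[0],
                    cde1_end=b1[1],
                    cde2_start=b2[0],
                    cde2_end=b2[1],
                    cde3_start=b3[0],
                    cde3_end=b3[1],
                    strand=strand,
                )
            )
            strand_sign = 1 if strand == "+" else -1
            # local coordinates run CDEI -> CDEIII; J1/J2 are the CDEII junctions
            j1_local = spec.cde1_len
            j2_local = spec.cde1_len + L2

            def to_genomic(local: float) -> int:
                if strand == "+":
                    return cen_start + int(local)
                return cen_start + total - 1 - int(local)

            kind = particle_model.kind
            if kind in ("octasome", "tetrasome"):
                placements.append(
                    dict(
                        chrom=chrom,
                        particle_id=pid,
                        kind=kind,
                        anchor=mid_cen,
                        orientation=1,
                        orientation_label="symmetric",
                        phase=0,
                        proportion=1.0,
                        cen_index=ci,
                    )
                )
                pid += 1
            elif kind == "hemisome_mixture":
                for oi, (o_label, o_prop) in enumerate(
                    zip(("cde1_proximal", "cde3_proximal"), particle_model.orientation_proportions)
                ):
                    for phase, ph_prop in enumerate(particle_model.phase_proportions):
                        if o_label == "cde1_proximal":
                            local = j1_local + d + phase * p_off
                            local_orient = 1
                        else:
                            local = j2_local - d - phase * p_off
                            local_orient = -1
                        placements.append(
                            dict(
                                chrom=chrom,
                                particle_id=pid,
                                kind="hemisome",
                                anchor=to_genomic(local),
                                orientation=local_orient * strand_sign,
                                orientation_label=o_label,
                                phase=phase,
                                proportion=o_prop * ph_prop,
                                cen_index=ci,
                            )
                        )
                        pid += 1

        # phased arm nucleosomes (H3/H4 octasomes) outside exclusion zones
        ndrs = [int(x) for x in spec.ndr_positions]
        for dy in range(spec.arm_nucleosome_spacing // 2, L, spec.arm_nucleosome_spacing):
            if dy < spec.edge_margin or dy > L - spec.edge_margin:
                continue
            if mid_cen is not None and abs(dy - mid_cen) < spec.cen_exclusion:
                continue
            if any(abs(dy - x) < spec.ndr_halfwidth + 73 for x in ndrs):
                continue
            placements.append(
                dict(
                    chrom=chrom,
                    particle_id=pid,
                    kind="arm",
                    anchor=dy,
                    orientation=1,
                    orientation_label="symmetric",
                    phase=0,
                    proportion=1.0,
                    cen_index=-1,
                )
            )
            pid += 1

        seqs[chrom] = seq.tobytes().decode("ascii")

    columns = [
        "chrom", "cde1_start", "cde1_end", "cde2_start", "cde2_end",
        "cde3_start", "cde3_end", "strand",
    ]
    annotation = CentromereAnnotation(pd.DataFrame(cen_rows, columns=columns))
    placement_df = pd.DataFrame(placements)
    return Genome(seqs), annotation, placement_df


@dataclass
class SimulationResult:
    """Fragments plus ground-truth sidecar labels and the raw cut-event table."""

    fragments: FragmentSet
    events: pd.DataFrame  # one row per double-strand cut that was drawn

    def fragment_labels(self) -> pd.DataFrame:
        """Sidecar label columns aligned with ``fragments.df`` rows."""
        cols = [c for c in self.fragments.df.columns if c not in ("chrom", "start", "end")]
        return self.fragments.df[cols]


def _contact_samplers(model: ContactModel):
    """Per-copy (watson_offsets, watson_probs, crick_offsets, crick_probs)."""
    out = []
    for watson, crick in model.copies():
        wo = np.array([o for o, _ in watson])
        wp = np.array([w for _, w in watson])
        co = np.array([o for o, _ in crick])
        cp = np.array([w for _, w in crick])
        out.append((wo, wp, co, cp))
    return out


def simulate_fragments(
    genome: Genome,
    placements: pd.DataFrame,
    contact_model: ContactModel,
    background: BackgroundModel = BackgroundModel(),
    n_molecules: int = 500,
    seed: int | np.random.Generator = 0,
    fire_prob: float = 0.3,
    ndr_positions: Sequence[int] = (),
    ndr_halfwidth: int = 80,
) -> SimulationResult:
    """Draw per-molecule cuts and assemble fragments between consecutive cuts.

    Each molecule is one copy of each chromosome.  Every particle copy fires
    at most one double-strand cut per molecule with probability ``fire_prob``;
    for a hemisome mixture exactly one of the candidate configurations is
    active per molecule, chosen by its occupancy proportion.  Cuts are sorted
    along the molecule and consecutive cuts delimit a fragment whose observed
    ends follow the base-loss/end-polishing convention (left = watson + 1,
    end-exclusive = crick).  Terminal pieces with a native chromosome end are
    not sequenceable (both fragment ends must come from cleavages) and are
    dropped.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base_samplers = _contact_samplers(contact_model)
    single = contact_model if contact_model.n_h4_copies == 1 else ContactModel(
        copy1_watson=contact_model.copy1_watson,
        copy1_crick=contact_model.copy1_crick,
        n_h4_copies=1,
    )
    hemi_fwd = _contact_samplers(single)[0]
    hemi_rev = _contact_samplers(single.mirrored())[0]

    frag_frames = []
    event_frames = []
    event_offset = 0
    meta = placements.set_index("particle_id")

    for chrom in genome.chroms():
        L = genome.length(chrom)
        rows = placements[placements["chrom"] == chrom]
        mols, watsons, cricks, pids = [], [], [], []

        def emit(mol_idx, w_pos, c_pos, particle_ids):
            mols.append(mol_idx)
            watsons.append(w_pos)
            cricks.append(c_pos)
            pids.append(particle_ids)

        # --- two-copy particles (arm nucleosomes, centromeric octa/tetrasomes)
        two_copy = rows[rows["kind"].isin(["arm", "octasome", "tetrasome"])]
        if len(two_copy):
            dyads = two_copy["anchor"].to_numpy()
            ids = two_copy["particle_id"].to_numpy()
            for wo, wp, co, cp in base_samplers:
                fires = rng.random((n_molecules, dyads.size)) < fire_prob
                mi, pj = np.nonzero(fires)
                n = mi.size
                if n:
                    w = dyads[pj] + rng.choice(wo, size=n, p=wp)
                    c = dyads[pj] + rng.choice(co, size=n, p=cp)
                    emit(mi, w, c, ids[pj])

        # --- hemisome mixtures: one configuration active per molecule
        hemis = rows[rows["kind"] == "hemisome"]
        for _, group in hemis.groupby("cen_index"):
            props = group["proportion"].to_numpy()
            props = props / props.sum()
            anchors = group["anchor"].to_numpy()
            orients = group["orientation"].to_numpy()
            ids = group["particle_id"].to_numpy()
            config = rng.choice(len(group), size=n_molecules, p=props)
            fires = rng.random(n_molecules) < fire_prob
            mi = np.nonzero(fires)[0]
            if mi.size:
                cfg = config[mi]
                w = np.empty(mi.size, dtype=np.int64)
                c = np.empty(mi.size, dtype=np.int64)
                for oi, sampler in ((1, hemi_fwd), (-1, hemi_rev)):
                    sel = orients[cfg] == oi
                    n = int(sel.sum())
                    if n:
                        wo, wp, co, cp = sampler
                        w[sel] = anchors[cfg[sel]] + rng.choice(wo, size=n, p=wp)
                        c[sel] = anchors[cfg[sel]] + rng.choice(co, size=n, p=cp)
                emit(mi, w, c, ids[cfg])

        # --- background: uniform linker cuts plus elevated NDR cuts
        if background.linker_rate > 0:
            counts = rng.poisson(background.linker_rate * L, size=n_molecules)
            total = int(counts.sum())
            if total:
                mi = np.repeat(np.arange(n_molecules), counts)
                x = rng.integers(1, L - 1, size=total)
                emit(mi, x, x, np.full(total, -1))
        if background.ndr_rate > 0 and len(ndr_positions):
            for ndr in ndr_positions:
                lo = max(1, int(ndr) - ndr_halfwidth)
                hi = min(L - 1, int(ndr) + ndr_halfwidth)
                if hi <= lo:
                    continue
                counts = rng.poisson(background.ndr_rate * (hi - lo), size=n_molecules)
                total = int(counts.sum())
                if total:
                    mi = np.repeat(np.arange(n_molecules), counts)
                    x = rng.integers(lo, hi, size=total)
                    emit(mi, x, x, np.full(total, -2))

        # --- fixed-site (restriction) mode: every site cut in every molecule
        if background.fixed_site:
            seq = genome.seq(chrom)
            sites = []
            k = seq.find(background.fixed_site)
            while k != -1:
                sites.append(k + background.fixed_site_cut_offset)
                k = seq.find(background.fixed_site, k + 1)
            if sites:
                sites = np.array(sites)
                mi = np.repeat(np.arange(n_molecules), sites.size)
                cut = np.tile(sites, n_molecules)
                # blunt cut between cut-1 and cut: no base loss
                emit(mi, cut - 1, cut, np.full(cut.size, -3))

        if not mols:
            continue
        mol = np.concatenate(mols)
        w = np.concatenate(watsons).astype(np.int64)
        c = np.concatenate(cricks).astype(np.int64)
        pid = np.concatenate(pids)

        in_bounds = (w >= 0) & (w < L - 1) & (c >= 1) & (c < L)
        mol, w, c, pid = mol[in_bounds], w[in_bounds], c[in_bounds], pid[in_bounds]
        order = np.lexsort((w + c, mol))
        mol, w, c, pid = mol[order], w[order], c[order], pid[order]
        event_id = event_offset + np.arange(mol.size)
        event_offset += mol.size

        ev = pd.DataFrame(
            {
                "event_id": event_id,
                "chrom": chrom,
                "molecule": mol,
                "watson": w,
                "crick": c,
                "particle_id": pid,
            }
        )
        for col in ("kind", "orientation_label", "phase", "cen_index"):
            vals = meta[col].reindex(pid).to_numpy()
            ev[col] = vals
        ev.loc[ev["particle_id"] == -1, "kind"] = "background_linker"
        ev.loc[ev["particle_id"] == -2, "kind"] = "background_ndr"
        ev.loc[ev["particle_id"] == -3, "kind"] = "fixed_site"
        ev["orientation_label"] = ev["orientation_label"].where(
            ev["orientation_label"].notna(), "none"
        )
        for col in ("cen_index", "phase"):
            ev[col] = (
                pd.to_numeric(ev[col], errors="coerce").fillna(-1).astype(int)
            )
        event_frames.append(ev)

        same_mol = mol[:-1] == mol[1:]
        start = w[:-1] + 1
        end = c[1:]
        valid = same_mol & (end > start)
        frag_frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": start[valid],
                    "end": end[valid],
                    "molecule": mol[:-1][valid],
                    "left_event": event_id[:-1][valid],
                    "right_event": event_id[1:][valid],
                }
            )
        )

    if not frag_frames:
        fragments = FragmentSet.from_arrays([], [], [], provenance=["simulate:empty"])
        return SimulationResult(fragments, pd.DataFrame())

    frag_df = pd.concat(frag_frames, ignore_index=True)
    events = pd.concat(event_frames, ignore_index=True)
    ev_idx = events.set_index("event_id")
    for side in ("left", "right"):
        for col in ("kind", "cen_index", "orientation_label", "phase"):
            frag_df[f"{side}_{col}"] = ev_idx[col].reindex(frag_df[f"{side}_event"]).to_numpy()
    fragments = FragmentSet(frag_df, provenance=[f"simulate:n_molecules={n_molecules}"])
    return SimulationResult(fragments, events)


def _fragment_at_stat(fragments: FragmentSet, genome: Genome, bias: ATBiasModel) -> np.ndarray:
    """Per-fragment AT statistic (whole-fragment or max-window A+T fraction)."""
    stat = np.empty(len(fragments))
    for chrom, sub in fragments.per_chrom():
        at = genome.at_indicator(chrom)
        cum = np.concatenate([[0], np.cumsum(at)])
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        if np.any(s < 0) or np.any(e > genome.length(chrom)):
            raise ValueError(f"fragment out of genome bounds on {chrom}")
        whole = (cum[e] - cum[s]) / (e - s)
        vals = whole
        if bias.stat == "window_max":
            W = bias.stat_window
            long = (e - s) > W
            if long.any() and len(at) >= W:
                win = (cum[W:] - cum[:-W]).astype(float)  # A+T count per W-bp window
                win_pad = np.concatenate([win, [-1.0]])
                starts = s[long]
                ends = e[long] - W + 1  # windows fully inside the fragment
                idx = np.empty(2 * starts.size, dtype=np.int64)
                idx[0::2] = starts
                idx[1::2] = ends
                vals = whole.copy()
                vals[long] = np.maximum.reduceat(win_pad, idx)[0::2] / W
        stat[sub.index] = vals
    return stat


def apply_recovery_bias(
    fragments: FragmentSet,
    genome: Genome,
    bias: ATBiasModel,
    seed: int | np.random.Generator = 0,
) -> FragmentSet:
    """Retain each fragment with probability given by the bias retention curve."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if len(fragments) == 0:
        return fragments.subset(np.zeros(0, dtype=bool), note="at_bias:empty")
    stat = _fragment_at_stat(fragments, genome, bias)
    keep = rng.random(len(fragments)) < bias.retention(stat)
    return fragments.subset(keep, note=f"at_bias:threshold={bias.at_threshold}")
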