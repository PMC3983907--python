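"""End-to-end orchestration: simulate -> filter -> maps -> distances -> scan ->
AT bias -> V-plots, driven by a single serializable configuration.

Every random operation receives an explicit seed derived from the run seed;
the full configuration is written into the output directory next to a
machine-readable ``summary.json`` holding the headline numbers (fragment
counts, peak spacings, distribution modes, scan medians, representation).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import at_bias as ab
from . import centromere_maps as cm
from . import end_distance_stats as eds
from . import profile_scan as ps
from . import synthetic_data as syn
from . import vplot as vp
from .cleavage_model import ContactModel, predict_distance_distribution
from .fragment_io import (
    CentromereAnnotation,
    FragmentSet,
    Genome,
    filter_by_length,
    length_distribution,
    read_inputs,
)

log = logging.getLogger("hemimap")

ALL_STAGES = (
    "simulate",
    "lengths",
    "tracks",
    "composite",
    "distances",
    "scan",
    "atbias",
    "vplot",
)


@dataclass
class RunConfig:
    """Fully explicit run description; every numeric default is a config key."""

    outdir: str = "hemimap_run"
    seed: int = 0
    stages: tuple = ALL_STAGES
    # input mode A: simulation
    simulate: dict = field(default_factory=dict)  # SyntheticGenomeSpec overrides
    particle: dict = field(default_factory=dict)  # ParticleModel overrides
    background: dict = field(default_factory=dict)  # BackgroundModel overrides
    at_bias_model: dict | None = field(default_factory=dict)  # None disables the bias
    contact_model: dict | None = None  # ContactModel override (serialized form)
    n_molecules: int = 500
    fire_prob: float = 0.3
    # input mode B: mapped data
    genome_path: str | None = None
    centromere_path: str | None = None
    fragment_paths: tuple = ()
    # stage parameters
    min_fragment_length: int = 147
    composite_length_class: tuple = (117, 118, 119, 120)
    composite_flank: int = 100
    n_peaks: int = 4
    peak_smooth_window: int = 1
    peak_min_separation: int = 5
    distance_radius: int = 125
    profile_length: int = 111
    member_length_range: tuple = (117, 120)
    z_thresh: float = 3.0
    max_z_violations: int = 3
    at_window: int = 83
    at_min: float = 0.90
    coverage_flank: int = 400
    vplot_flank: int = 1000
    vplot_max_length: int = 500
    vplot_equalize: bool = True
    plot: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _contact_model(config: RunConfig) -> ContactModel:
    if config.contact_model:
        return ContactModel.from_dict(config.contact_model)
    return ContactModel.default_two_copy()


def run(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order; return the summary."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    logging.basicConfig(level=logging.INFO)
    summary: dict = {"seed": config.seed, "stages": list(config.stages)}
    stages = set(config.stages)
    rng = np.random.default_rng(config.seed)
    model = _contact_model(config)

    # ---- inputs -----------------------------------------------------------
    if "simulate" in stages:
        spec = syn.SyntheticGenomeSpec(**{"seed": config.seed, **config.simulate})
        particle = syn.ParticleModel(**config.particle)
        background = syn.BackgroundModel(**config.background)
        genome, annotation, placements = syn.generate_genome(spec, particle)
        sim = syn.simulate_fragments(
            genome,
            placements,
            model,
            background,
            n_molecules=config.n_molecules,
            seed=rng,
            fire_prob=config.fire_prob,
            ndr_positions=spec.ndr_positions,
            ndr_halfwidth=spec.ndr_halfwidth,
        )
        fragments = sim.fragments
        if config.at_bias_model is not None:
            bias = syn.ATBiasModel(**config.at_bias_model)
            fragments = syn.apply_recovery_bias(fragments, genome, bias, seed=rng)
        genome.to_fasta(out / "genome.fa")
        annotation.to_tsv(out / "centromeres.tsv")
        fragments.to_bed(out / "fragments.bed")
        sim.events.to_csv(out / "cut_events.tsv", sep="\t", index=False)
        fragments.df.to_csv(out / "fragment_labels.tsv", sep="\t", index=False)
        summary["n_fragments"] = len(fragments)
        summary["n_cut_events"] = len(sim.events)
        log.info("simulated %d fragments (%d cut events)", len(fragments), len(sim.events))
    else:
        if not config.genome_path:
            raise ValueError("stage inputs missing: no simulate stage and no genome_path")
        genome, annotation, fragments = read_inputs(
            config.genome_path, config.centromere_path, *config.fragment_paths
        )
        summary["n_fragments"] = len(fragments)

    chrom_lengths = {c: genome.length(c) for c in genome.chroms()}
    filtered = filter_by_length(fragments, config.min_fragment_length)
    summary["n_fragments_length_filtered"] = len(filtered)

    # ---- per-stage analyses ----------------------------------------------
    if "lengths" in stages:
        dist = length_distribution(fragments)
        dist.rename("percent").to_csv(out / "length_distribution.tsv", sep="\t")
        summary["modal_fragment_length"] = int(dist.idxmax())

    tracks1 = cm.end_count_track(filtered, 1, chrom_lengths)
    if "tracks" in stages:
        tracks10 = cm.end_count_track(filtered, 10, chrom_lengths)
        for chrom, tr in tracks10.items():
            tr.to_bedgraph(out / f"ends_10bp_{chrom}.bedgraph")
        summary["most_cleaved_positions"] = {
            c: tr.most_cleaved_position() for c, tr in tracks1.items()
        }

    if "composite" in stages:
        hist = cm.composite_histogram(
            filtered, annotation, config.composite_length_class, config.composite_flank
        )
        hist.to_frame().to_csv(out / "composite.tsv", sep="\t", index=False)
        peaks = cm.call_peak_maxima(
            hist, config.n_peaks, config.peak_smooth_window, config.peak_min_separation
        )
        pd.DataFrame({"offset": peaks.offsets, "height": peaks.heights}).to_csv(
            out / "peaks.tsv", sep="\t", index=False
        )
        summary["peak_offsets"] = [int(o) for o in peaks.offsets]
        if config.n_peaks == 4:
            summary["peak_spacings"] = {
                "intra_cluster": list(peaks.intra_cluster),
                "inner": peaks.inner,
                "outer": peaks.outer,
            }
        if config.plot:
            from .plots import plot_composite

            plot_composite(hist, peaks, out / "composite.png")

    if "distances" in stages:
        dists = {}
        for scope, subset in (
            ("genome_wide", eds.SubsetSpec()),
            ("centromere", eds.SubsetSpec("near_centromere", config.distance_radius)),
        ):
            wc = eds.wc_distribution(filtered, subset, annotation)
            ww = eds.same_strand_distribution(filtered, "W", subset, annotation)
            cc = eds.same_strand_distribution(filtered, "C", subset, annotation)
            for name, d in (("wc", wc), ("ww", ww), ("cc", cc)):
                d.to_tsv(out / f"distances_{scope}_{name}.tsv")
                dists[f"{scope}_{name}_modes"] = d.major_modes()
        oracle_wc = predict_distance_distribution(model, "WC").modes()
        across = [m for m in oracle_wc if m not in
                  predict_distance_distribution(
                      ContactModel(model.copy1_watson, model.copy1_crick, n_h4_copies=1),
                      "WC").modes()]
        cen_modes = set(dists["centromere_wc_modes"])
        dists["across_dyad_wc_modes"] = across
        dists["across_dyad_wc_modes_present_at_centromere"] = bool(
            set(across) & cen_modes
        )
        summary["distances"] = dists

    if "scan" in stages:
        profile = ps.build_profile(
            tracks1, annotation, config.profile_length,
            tuple(config.member_length_range),
        )
        profile.to_frame().to_csv(out / "profile.tsv", sep="\t", index=False)
        scan = ps.scan_genome(
            profile, tracks1, annotation,
            z_thresh=config.z_thresh, max_z_violations=config.max_z_violations,
        )
        scan.to_csv(out / "scan.tsv", sep="\t", index=False)
        jk = ps.jackknife(
            tracks1, annotation, config.profile_length,
            tuple(config.member_length_range),
            z_thresh=config.z_thresh, max_z_violations=config.max_z_violations,
        )
        jk.to_csv(out / "jackknife.tsv", sep="\t", index=False)
        summary["scan"] = {
            "median_first_cen_r": float(np.nanmedian(scan["first_cen_r"])),
            "median_first_fp_r": float(np.nanmedian(scan["first_fp_r"])),
            "n_chrom_cen_outranks_all": int(scan["centromere_outranks_all"].sum()),
            "jackknife_median_cen_r": float(np.nanmedian(jk["cen_r"])),
        }

    if "atbias" in stages:
        segments = ab.find_at_rich_segments(genome, config.at_window, config.at_min)
        ab.segments_to_bed(segments, out / "at_segments.bed")
        cde2 = annotation.df[["chrom", "cde2_start", "cde2_end"]].rename(
            columns={"cde2_start": "start", "cde2_end": "end"}
        )
        rep = ab.representation_stats(fragments, cde2, genome)
        rep.to_csv(out / "cde2_representation.tsv", sep="\t", index=False)
        cov = ab.normalized_coverage(
            fragments, annotation.anchors(), config.coverage_flank, genome
        )
        pd.DataFrame(
            {"offset": np.arange(-config.coverage_flank, config.coverage_flank + 1),
             "normalized": cov}
        ).to_csv(out / "normalized_coverage.tsv", sep="\t", index=False)
        summary["at_bias"] = {
            "n_at_segments": len(segments),
            "median_cde2_percent_of_expected": float(rep["percent_of_expected"].median()),
            "coverage_minimum_offset": int(np.argmin(cov) - config.coverage_flank),
        }

    if "vplot" in stages:
        vp_frags = filtered
        if config.vplot_equalize:
            vp_frags = vp.equalize_coverage(
                filtered, annotation.anchors(), config.vplot_flank, seed=rng
            )
        mid = vp.build_vplot(
            vp_frags, annotation.anchors(), "midpoint",
            config.vplot_flank, config.vplot_max_length,
        )
        lv, rv = vp.build_left_right_vplots(
            vp_frags, annotation.anchors(), config.vplot_flank, config.vplot_max_length
        )
        mid.to_frame().to_csv(out / "vplot_midpoint.tsv", sep="\t")
        lv.to_frame().to_csv(out / "vplot_left.tsv", sep="\t")
        rv.to_frame().to_csv(out / "vplot_right.tsv", sep="\t")
        occupied = np.nonzero(mid.counts[:, mid.flank])[0]
        summary["vplot"] = {
            "n_fragments_plotted": int(mid.counts.sum()),
            "min_protected_length_at_anchor": int(occupied[0] + 1) if occupied.size else None,
        }
        if config.plot:
            from .plots import plot_vplot

            plot_vplot(mid, out / "vplot_midpoint.png")

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
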