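"""Profile construction, scan filters, ranking, and the delete-one jackknife."""

import numpy as np
import pandas as pd
import pytest

import hemimap as hm
import hemimap.centromere_maps as cm
import hemimap.profile_scan as ps


def _tracks_from_arrays(arrays):
    return {
        chrom: cm.EndCountTrack(chrom, 1, counts, np.zeros_like(counts))
        for chrom, counts in arrays.items()
    }


def _annotation_for(chroms, start=300, length=117):
    rows = []
    for c in chroms:
        rows.append(dict(chrom=c, cde1_start=start, cde1_end=start + 8,
                         cde2_start=start + 8, cde2_end=start + length - 26,
                         cde3_start=start + length - 26, cde3_end=start + length,
                         strand="+"))
    return hm.CentromereAnnotation(pd.DataFrame(rows))


def _synthetic_member(rng, start=300, noise=0.0, length=1000):
    """A count vector with a 4-peak centromere pattern at ``start``."""
    y = np.zeros(length)
    for off, h in ((16, 180), (26, 200), (49, 190), (59, 170)):
        y[start + off] = h
    if noise:
        y += rng.poisson(noise, size=length)
    return y


class TestBuildProfile:
    def test_identical_members_have_zero_sd(self):
        rng = np.random.default_rng(0)
        v = _synthetic_member(rng)
        tracks = _tracks_from_arrays({"c1": v.copy(), "c2": v.copy()})
        ann = _annotation_for(["c1", "c2"])
        prof = ps.build_profile(tracks, ann)
        assert prof.length == 111
        np.testing.assert_array_equal(prof.sd, 0.0)
        assert prof.members == ["c1", "c2"]

    def test_smallest_member_maximum(self):
        rng = np.random.default_rng(0)
        a = _synthetic_member(rng)
        b = _synthetic_member(rng)
        b[b > 0] = b[b > 0] / 200 * 250  # member maxima 200 and 250
        a[a > 0] = a[a > 0] / 200 * 186
        tracks = _tracks_from_arrays({"c1": a, "c2": b})
        prof = ps.build_profile(tracks, _annotation_for(["c1", "c2"]))
        assert prof.smallest_member_maximum == pytest.approx(186.0)

    def test_too_few_members_rejected(self):
        rng = np.random.default_rng(0)
        tracks = _tracks_from_arrays({"c1": _synthetic_member(rng)})
        with pytest.raises(ValueError, match=">=2"):
            ps.build_profile(tracks, _annotation_for(["c1"]))

    def test_length_range_filters_members(self):
        rng = np.random.default_rng(0)
        tracks = _tracks_from_arrays(
            {"c1": _synthetic_member(rng), "c2": _synthetic_member(rng),
             "c3": _synthetic_member(rng)}
        )
        ann111 = _annotation_for(["c3"], length=111)
        ann = hm.CentromereAnnotation(
            pd.concat([_annotation_for(["c1", "c2"]).df, ann111.df])[
                ["chrom", "cde1_start", "cde1_end", "cde2_start", "cde2_end",
                 "cde3_start", "cde3_end", "strand"]
            ]
        )
        prof = ps.build_profile(tracks, ann, member_length_range=(117, 120))
        assert prof.members == ["c1", "c2"]  # the 111-bp member is excluded

    def test_synthetic_hemisome_profile_shows_four_peaks(self, hemisome_run):
        lens = {c: hemisome_run["genome"].length(c) for c in hemisome_run["genome"].chroms()}
        tracks = cm.end_count_track(hemisome_run["filtered"], 1, lens)
        prof = ps.build_profile(tracks, hemisome_run["annotation"])
        m = prof.mean
        # alignment anchors the first rotational-phase doublet at 0 and 10
        assert set(np.argsort(m)[-2:]) == {0, 10}
        # the opposite-orientation cluster pair sits ~33-53 bp further right,
        # smeared by the 117-120 bp length mix but far above background
        background = m[20:35].sum()
        assert m[36:46].sum() > 10 * background
        assert m[46:56].sum() > 10 * background


class TestScan:
    def _profile_from(self, members):
        tracks = _tracks_from_arrays(members)
        return ps.build_profile(tracks, _annotation_for(list(members)))

    def test_exact_copy_of_mean_scores_r_one(self):
        rng = np.random.default_rng(1)
        a = _synthetic_member(rng, noise=2.0)
        b = _synthetic_member(rng, noise=2.0)
        prof = self._profile_from({"c1": a, "c2": b})
        target = np.zeros(600)
        target[200:311] = prof.mean
        hits = ps.scan_chromosome(prof, cm.EndCountTrack("t", 1, target, np.zeros_like(target)))
        best = hits.loc[hits["r"].idxmax()]
        assert best["start"] == 200
        assert best["r"] == pytest.approx(1.0)
        assert bool(best["passed"])

    def test_alignment_count_is_track_minus_profile_plus_one(self):
        rng = np.random.default_rng(2)
        prof = self._profile_from(
            {"c1": _synthetic_member(rng, noise=2.0),
             "c2": _synthetic_member(rng, noise=2.0)}
        )
        track = cm.EndCountTrack("t", 1, np.ones(500), np.zeros(500))
        hits = ps.scan_chromosome(prof, track)
        assert len(hits) == 500 - 111 + 1

    def test_z_violation_filter(self):
        rng = np.random.default_rng(3)
        a = _synthetic_member(rng, noise=3.0)
        b = _synthetic_member(rng, noise=3.0)
        prof = self._profile_from({"c1": a, "c2": b})
        window = prof.mean.copy()
        live = np.nonzero(prof.sd > 0)[0]
        bad = window.copy()
        bad[live[:4]] += 10 * prof.sd[live[:4]]  # 4 positions beyond 3 sd
        track = np.zeros(400)
        track[100:211] = bad
        hits = ps.scan_chromosome(prof, cm.EndCountTrack("t", 1, track, np.zeros(400)))
        row = hits[hits["start"] == 100].iloc[0]
        assert row["n_z_violations"] >= 4
        assert not row["passed"]

    def test_all_zero_window_fails_minimum_maximum_filter(self):
        rng = np.random.default_rng(4)
        prof = self._profile_from(
            {"c1": _synthetic_member(rng, noise=2.0),
             "c2": _synthetic_member(rng, noise=2.0)}
        )
        track = cm.EndCountTrack("t", 1, np.zeros(300), np.zeros(300))
        hits = ps.scan_chromosome(prof, track)
        assert not hits["passed"].any()
        assert not hits["has_min_max"].any()


N_SEEDS = 20


@pytest.fixture(scope="module")
def multi_seed_scans(contact_model):
    """Full pipeline scans over independent seeds (compact genomes)."""
    results = []
    for seed in range(N_SEEDS):
        spec = hm.SyntheticGenomeSpec(
            n_chromosomes=8, chrom_length=3000, n_centromeres=8,
            cde2_len=(83, 86), seed=seed,
        )
        genome, ann, plac = hm.generate_genome(spec)
        sim = hm.simulate_fragments(
            genome, plac, contact_model, hm.BackgroundModel(),
            n_molecules=600, seed=seed + 1000,
        )
        frags = hm.apply_recovery_bias(
            sim.fragments, genome, hm.ATBiasModel(), seed=seed + 2000
        )
        filt = hm.filter_by_length(frags)
        lens = {c: genome.length(c) for c in genome.chroms()}
        tracks = cm.end_count_track(filt, 1, lens)
        prof = ps.build_profile(tracks, ann)
        scan = ps.scan_genome(prof, tracks, ann)
        jk = ps.jackknife(tracks, ann)
        results.append((scan, jk))
    return results

class TestRecoveryAndJackknife:
    def test_centromere_outranks_all_arm_alignments_every_chromosome(
        self, multi_seed_scans
    ):
        for scan, _ in multi_seed_scans:
            assert scan["centromere_outranks_all"].all()

    def test_jackknife_lowers_deleted_member_r_in_expectation(self, multi_seed_scans):
        drops = []
        for scan, jk in multi_seed_scans:
            full = scan.set_index("chrom")["first_cen_r"].reindex(jk["deleted"])
            drops.append(np.nanmean(full.to_numpy() - jk["cen_r"].to_numpy()))
        assert np.nanmean(drops) > 0

    def test_jackknife_excluded_members_reported_not_scored(self, multi_seed_scans):
        for _, jk in multi_seed_scans:
            excl = jk[jk["excluded_by_filters"]]
            assert excl["cen_r"].isna().all()

    def test_deleting_a_mean_identical_member_keeps_r(self):
        rng = np.random.default_rng(5)
        v = _synthetic_member(rng)
        tracks = _tracks_from_arrays({f"c{i}": v.copy() for i in range(4)})
        ann = _annotation_for([f"c{i}" for i in range(4)])
        jk = ps.jackknife(tracks, ann)
        # all members identical: removing one cannot change its correlation
        assert np.allclose(jk["cen_r"], 1.0)
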