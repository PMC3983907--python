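"""Generator contracts: genome layout, determinism, cut formation, AT bias."""

import numpy as np
import pandas as pd
import pytest

import hemimap as hm


def _spec(**kw):
    defaults = dict(n_chromosomes=4, chrom_length=3000, n_centromeres=4, seed=3)
    defaults.update(kw)
    return hm.SyntheticGenomeSpec(**defaults)


class TestGenerateGenome:
    def test_element_lengths(self):
        genome, ann, _ = hm.generate_genome(_spec(n_chromosomes=16, n_centromeres=16,
                                                  chrom_length=4000))
        df = ann.df
        assert len(df) == 16
        assert ((df["cde1_end"] - df["cde1_start"]) == 8).all()
        assert ((df["cde3_end"] - df["cde3_start"]) == 26).all()
        assert df["total_length"].between(112, 120).all()

    def test_determinism_same_seed(self):
        a = hm.generate_genome(_spec())
        b = hm.generate_genome(_spec())
        assert a[0].seq("chr1") == b[0].seq("chr1")
        pd.testing.assert_frame_equal(a[1].df, b[1].df)
        pd.testing.assert_frame_equal(a[2], b[2])

    def test_cde2_at_content_constraint(self):
        genome, ann, _ = hm.generate_genome(_spec(cde2_min_at=0.90))
        for _, row in ann.df.iterrows():
            frac = genome.at_fraction(row["chrom"], row["cde2_start"], row["cde2_end"])
            assert frac >= 0.90

    def test_all_at_cde2(self):
        genome, ann, _ = hm.generate_genome(_spec(cde2_min_at=1.0, cde2_max_at=1.0))
        for _, row in ann.df.iterrows():
            seq = genome.seq(row["chrom"])[row["cde2_start"]: row["cde2_end"]]
            assert set(seq) <= {"A", "T"}

    def test_centromere_longer_than_chromosome_rejected(self):
        with pytest.raises(ValueError, match="longer than chromosome"):
            hm.generate_genome(_spec(chrom_length=100))

    def test_hemisome_mixture_places_four_configs_per_centromere(self):
        _, _, plac = hm.generate_genome(_spec())
        hemi = plac[plac["kind"] == "hemisome"]
        per_cen = hemi.groupby("cen_index").size()
        assert (per_cen == 4).all()
        assert hemi.groupby("cen_index")["proportion"].sum().round(9).eq(1.0).all()

    def test_minus_strand_placements_mirror_plus_strand(self):
        """Anchors of a '-' centromere are reflections of the '+' layout."""
        plus = hm.generate_genome(_spec(cde2_len=83, cen_strands="+"))
        minus = hm.generate_genome(_spec(cde2_len=83, cen_strands="-"))
        pa = plus[2][(plus[2]["kind"] == "hemisome") & (plus[2]["cen_index"] == 0)]
        ma = minus[2][(minus[2]["kind"] == "hemisome") & (minus[2]["cen_index"] == 0)]
        cen = plus[1].df.iloc[0]
        lo, hi = cen["cen_start"], cen["cen_end"]
        reflected = sorted(lo + hi - 1 - pa["anchor"].to_numpy())
        assert reflected == sorted(ma["anchor"].to_numpy())
        # and orientation signs flip
        assert sorted(pa["orientation"]) == sorted(-ma["orientation"])


class TestSimulateFragments:
    def test_fragment_coordinates_strictly_increase_within_molecule(self, hemisome_run):
        df = hemisome_run["sim"].fragments.df
        g = df.sort_values(["chrom", "molecule", "start"]).groupby(
            ["chrom", "molecule"], observed=True
        )
        # consecutive fragments of one molecule never overlap: tiling minus lost bases
        assert (g["start"].diff().dropna() > 0).all()
        prev_end = g["end"].shift()
        gaps = (df.sort_values(["chrom", "molecule", "start"])["start"] - prev_end).dropna()
        assert (gaps >= 0).all()

    def test_octasome_only_zero_background_ends_near_dyads(self, contact_model):
        spec = _spec(n_chromosomes=1, n_centromeres=1, cde2_len=83)
        genome, ann, plac = hm.generate_genome(spec, hm.ParticleModel(kind="octasome"))
        bg = hm.BackgroundModel(linker_rate=0.0, ndr_rate=0.0)
        sim = hm.simulate_fragments(genome, plac, contact_model, bg,
                                    n_molecules=200, seed=4)
        dyads = plac["anchor"].to_numpy()
        for ends in (sim.fragments.start, sim.fragments.end - 1):
            dist = np.min(np.abs(ends[:, None] - dyads[None, :]), axis=1)
            assert dist.max() <= 7  # contact-offset envelope

    def test_fixed_site_mode_cuts_every_molecule_at_the_motif(self, contact_model):
        genome = hm.Genome({"t": "G" * 150 + "AGCT" + "G" * 150})
        plac = pd.DataFrame(
            columns=["chrom", "particle_id", "kind", "anchor", "orientation",
                     "orientation_label", "phase", "proportion", "cen_index"]
        )
        bg = hm.BackgroundModel(linker_rate=1e-3, ndr_rate=0.0, fixed_site="AGCT")
        sim = hm.simulate_fragments(genome, plac, contact_model, bg,
                                    n_molecules=50, seed=5)
        site_cuts = sim.events[sim.events["kind"] == "fixed_site"]
        assert len(site_cuts) == 50  # every molecule, cleaved to completion
        # blunt cut between the G and C of AG^CT: no base loss
        assert (site_cuts["watson"] == 151).all()
        assert (site_cuts["crick"] == 152).all()
        df = sim.fragments.df
        assert (df["end"] == 152).any() and (df["start"] == 152).any()

    def test_zero_cut_molecules_yield_no_fragments(self, contact_model):
        spec = _spec(n_chromosomes=1, n_centromeres=0)
        genome, _, plac = hm.generate_genome(spec)
        bg = hm.BackgroundModel(linker_rate=0.0, ndr_rate=0.0)
        sim = hm.simulate_fragments(genome, plac, contact_model, bg,
                                    n_molecules=5, seed=6, fire_prob=0.0)
        assert len(sim.fragments) == 0

    def test_mixture_proportions_recovered_from_sidecar_labels(self, contact_model):
        """Equal-proportion hemisome mixture: each of the four orientation x
        phase configurations receives 0.25 +/- 0.01 of centromeric cuts."""
        spec = _spec(n_chromosomes=16, chrom_length=800, n_centromeres=16,
                     cde2_len=(78, 86), cen_exclusion=250, seed=21)
        genome, _, plac = hm.generate_genome(spec)
        sim = hm.simulate_fragments(genome, plac, contact_model,
                                    hm.BackgroundModel(), n_molecules=5000, seed=22)
        cen = sim.events[sim.events["kind"] == "hemisome"]
        assert len(cen) >= 17_000  # 3-sigma-safe sample for a 0.01 band
        shares = cen.groupby(["orientation_label", "phase"]).size() / len(cen)
        assert len(shares) == 4
        assert np.allclose(shares, 0.25, atol=0.01)


class TestRecoveryBias:
    def test_retention_one_is_identity(self, hemisome_run):
        bias = hm.ATBiasModel(at_threshold=1.1)  # nothing crosses the threshold
        out = hm.apply_recovery_bias(
            hemisome_run["sim"].fragments, hemisome_run["genome"], bias, seed=9
        )
        assert len(out) == len(hemisome_run["sim"].fragments)

    def test_retention_zero_above_threshold_empties_all_at_genome(self, contact_model):
        genome = hm.Genome({"t": "AT" * 2000})
        plac = pd.DataFrame(
            columns=["chrom", "particle_id", "kind", "anchor", "orientation",
                     "orientation_label", "phase", "proportion", "cen_index"]
        )
        bg = hm.BackgroundModel(linker_rate=5e-3, ndr_rate=0.0)
        sim = hm.simulate_fragments(genome, plac, contact_model, bg,
                                    n_molecules=100, seed=7)
        assert len(sim.fragments) > 0
        bias = hm.ATBiasModel(at_threshold=0.5, floor=0.0, shape=1e-9)
        out = hm.apply_recovery_bias(sim.fragments, genome, bias, seed=8)
        assert len(out) == 0

    def test_out_of_bounds_fragment_rejected(self, hemisome_run):
        bad = hm.FragmentSet.from_arrays(["chr1"], [0], [10**7])
        with pytest.raises(ValueError, match="bounds"):
            hm.apply_recovery_bias(bad, hemisome_run["genome"], hm.ATBiasModel(), 1)

    def test_retention_curve_monotone_non_increasing(self):
        bias = hm.ATBiasModel()
        a = np.linspace(0.0, 1.0, 201)
        r = bias.retention(a)
        assert np.all(np.diff(r) <= 1e-12)
        assert np.all((r >= 0) & (r <= 1))
        assert np.all(r[a <= bias.at_threshold] == 1.0)
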