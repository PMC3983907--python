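import numpy as np
import pandas as pd
import pytest

import hemimap as hm

DEFAULT_MODEL = hm.ContactModel.default_two_copy()


@pytest.fixture(scope="session")
def contact_model():
    return DEFAULT_MODEL


@pytest.fixture(scope="session")
def hemisome_run():
    """Default hemisome-mixture simulation: 16 loci of 117-120 bp, AT bias on.

    Session-scoped because several analysis stages reuse the same fragments.
    """
    spec = hm.SyntheticGenomeSpec(cde2_len=(83, 86), seed=11)
    genome, annotation, placements = hm.generate_genome(spec)
    sim = hm.simulate_fragments(
        genome, placements, DEFAULT_MODEL, hm.BackgroundModel(),
        n_molecules=520, seed=12,
    )
    biased = hm.apply_recovery_bias(sim.fragments, genome, hm.ATBiasModel(), seed=13)
    return {
        "spec": spec,
        "genome": genome,
        "annotation": annotation,
        "placements": placements,
        "sim": sim,
        "fragments": biased,
        "filtered": hm.filter_by_length(biased),
    }


@pytest.fixture(scope="session")
def octasome_run():
    """Octasome-architecture counterpart of ``hemisome_run`` (no AT bias)."""
    spec = hm.SyntheticGenomeSpec(cde2_len=(83, 86), seed=11)
    genome, annotation, placements = hm.generate_genome(
        spec, hm.ParticleModel(kind="octasome")
    )
    sim = hm.simulate_fragments(
        genome, placements, DEFAULT_MODEL, hm.BackgroundModel(),
        n_molecules=400, seed=12,
    )
    return {
        "genome": genome,
        "annotation": annotation,
        "sim": sim,
        "filtered": hm.filter_by_length(sim.fragments),
    }


def toy_fragments(records):
    """FragmentSet from (chrom, start, end) tuples."""
    chrom, start, end = zip(*records)
    return hm.FragmentSet.from_arrays(list(chrom), list(start), list(end))


def toy_annotation(rows=None):
    """Single +strand centromere: CDEI [100,108) CDEII [108,191) CDEIII [191,217)."""
    if rows is None:
        rows = [
            dict(chrom="chr1", cde1_start=100, cde1_end=108, cde2_start=108,
                 cde2_end=191, cde3_start=191, cde3_end=217, strand="+")
        ]
    return hm.CentromereAnnotation(pd.DataFrame(rows))
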