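"""Shared fixtures: one small synthetic genome and its control panel."""

import pytest

import plasmacna as pc
from plasmacna import profiling


@pytest.fixture(scope="session")
def genome():
    """Two 60 Mb chromosomes: 2400 50 kb bins, plenty of genes and tracks."""
    return pc.make_genome(n_chrom=2, chrom_length=60_000_000, seed=1)


@pytest.fixture(scope="session")
def panel_counts(genome):
    return pc.simulate_control_panel(genome, 10, pc.SimulationConfig(seed=3))


@pytest.fixture(scope="session")
def panel_profiles(genome, panel_counts):
    """Panel run through binning + total normalization + GC correction."""
    return [
        profiling.process_sample(profiling.profile_from_counts(c, genome, f"ctl{i}"))
        for i, c in enumerate(panel_counts)
    ]


@pytest.fixture(scope="session")
def annotation(genome):
    from plasmacna.focal import AnnotationBundle

    return AnnotationBundle.from_genome(genome)
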