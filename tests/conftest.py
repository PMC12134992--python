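"""Shared fixtures: one session-scoped synthetic genome drives most tests."""

import pytest

from asmcurate import satellites, synth, telomeres, windows
from asmcurate.containers import ScaffoldPlan


@pytest.fixture(scope="session")
def genome():
    """Default desk-scale genome with every feature planted (seed fixed)."""
    spec = synth.GenomeSpec(seed=1)
    scaffolds, truth = synth.generate_genome(spec)
    return spec, scaffolds, truth


@pytest.fixture(scope="session")
def small_spec():
    """A minimal spec for fast construction-level tests."""
    return synth.GenomeSpec(
        n_macro=2,
        n_micro=2,
        macro_len_range=(1_100_000, 1_300_000),
        micro_len_range=(1_000_000, 1_050_000),
        x_len=1_050_000,
        par_len=100_000,
        y_fragment_lens=(200_000,),
        cen_monomers=((187, 112_200),),
        misjoin_count=1,
        rdna_scaffolds=1,
        sat_only_scaffolds=1,
        n_unassigned=1,
        seed=7,
    )


@pytest.fixture(scope="session")
def plan(genome):
    _, scaffolds, _ = genome
    return ScaffoldPlan.from_scaffolds(scaffolds)


@pytest.fixture(scope="session")
def telomere_calls(genome):
    _, scaffolds, _ = genome
    return telomeres.call_telomeres(scaffolds)


@pytest.fixture(scope="session")
def gc_track(genome):
    _, scaffolds, _ = genome
    return windows.gc_windows(scaffolds)


@pytest.fixture(scope="session")
def satellite_families(genome):
    _, scaffolds, _ = genome
    return satellites.discover_satellite_families(scaffolds)


@pytest.fixture(scope="session")
def alignments(genome):
    _, _, truth = genome
    return synth.simulate_alignments(truth, seed=2)
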