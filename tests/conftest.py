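"""Shared fixtures: one synthetic reference world and one mock-community run,
generated once per session."""

import pytest

from metaprimer.formats import PrimerInput
from metaprimer.pipeline import run_main
from metaprimer.synthetic import (
    CommunityMember,
    CommunitySpec,
    default_mock_spec,
    generate_mock_genomes,
    make_reference_world,
    simulate_reads,
)

SEED = 11

F515 = PrimerInput("F515", "GTGCCAGC(A/C)GCCGCGGTAA", "F")
R806 = PrimerInput("R806", "GGACTACC(A/C/G)GGGTATCTAAT", "R")


@pytest.fixture(scope="session")
def world():
    return make_reference_world(seed=SEED)


@pytest.fixture(scope="session")
def primer_inputs():
    return [F515, R806]


@pytest.fixture(scope="session")
def mock_data(world):
    spec = default_mock_spec(world, seed=SEED)
    genomes, truth = generate_mock_genomes(spec)
    reads, rtruth = simulate_reads(genomes, spec, truth)
    return spec, genomes, truth, reads, rtruth


@pytest.fixture(scope="session")
def pipeline_result(world, mock_data, primer_inputs):
    _, _, _, reads, _ = mock_data
    return run_main(reads, world.alignment, primer_inputs, seed=SEED)


@pytest.fixture(scope="session")
def rrna_reads(world):
    """Error-free 400-base reads drawn purely from the rRNA genes."""
    members = [
        CommunityMember(g, world.lineages[g], len(world.genes[g].seq),
                        (world.genes[g],))
        for g in sorted(world.genes)
    ]
    spec = CommunitySpec(members, read_length=400, coverage=4.0,
                         error_model="exact", seed=SEED)
    genomes, truth = generate_mock_genomes(spec)
    reads, rtruth = simulate_reads(genomes, spec, truth)
    return reads, rtruth
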