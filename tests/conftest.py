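import numpy as np
import pytest

from nanomock.design import AbundanceSpec, OrganismSpec, SampleDesign
from nanomock.ref_io import generate_random_reference, write_reference_fasta
from nanomock.sim_core import LengthModel


@pytest.fixture(scope="session")
def ref_dir(tmp_path_factory):
    """Synthetic reference FASTAs shared across the suite."""
    d = tmp_path_factory.mktemp("refs")
    write_reference_fasta(
        generate_random_reference("orgA", 1, 50_000, seed=101), d / "orgA.fasta"
    )
    write_reference_fasta(
        generate_random_reference("orgB", 2, 20_000, seed=102), d / "orgB.fasta"
    )
    write_reference_fasta(
        generate_random_reference("host", 1, 100_000, gc=0.45, seed=103),
        d / "host.fasta",
    )
    write_reference_fasta(
        generate_random_reference("virus", 1, 10_000, gc=0.55, seed=104),
        d / "virus.fasta",
    )
    return d


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def short_length_model():
    # keeps per-test simulations fast
    return LengthModel(mean=300, sd=30, min_len=50)


@pytest.fixture
def simple_design(ref_dir, short_length_model):
    return SampleDesign(
        entries=[
            OrganismSpec("orgA", str(ref_dir / "orgA.fasta"), AbundanceSpec("absolute", 120)),
            OrganismSpec("orgB", str(ref_dir / "orgB.fasta"), AbundanceSpec("absolute", 80)),
        ],
        seed=42,
        sample_name="simple",
        length_model=short_length_model,
    )


@pytest.fixture
def host_pathogen_design(ref_dir, short_length_model):
    return SampleDesign(
        entries=[
            OrganismSpec("virus", str(ref_dir / "virus.fasta"), AbundanceSpec("absolute", 500)),
            OrganismSpec("host", str(ref_dir / "host.fasta")),
        ],
        seed=7,
        sample_name="hostpath",
        total_reads=100_000,
        scenario="host_microbiome",
        host="host",
        fill_remainder=True,
        length_model=short_length_model,
    )
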