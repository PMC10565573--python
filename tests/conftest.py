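import pytest
from hypothesis import settings

from aseskip import SimTruth, example_gene

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from aseskip.sim import simulate_alignments


@pytest.fixture(scope="session")
def model():
    return example_gene()


@pytest.fixture(scope="session")
def tumor_truth():
    """Allele-specific tumor: strongly skewed RNA, alt-specific skipping."""
    return SimTruth(
        rna_alt_fraction=0.95, psi_ref=0.0, psi_alt=0.95, seed=11
    )


@pytest.fixture(scope="session")
def normal_truth():
    """Matched normal: balanced expression, background-level skipping."""
    return SimTruth(
        rna_alt_fraction=0.5, psi_ref=0.02, psi_alt=0.02, seed=12
    )


@pytest.fixture(scope="session")
def clean_truth():
    """Error-free heterozygote at high depth."""
    return SimTruth(error_rate=0.0, dna_depth=120.0, rna_depth=150.0, seed=13)


@pytest.fixture(scope="session")
def tumor_paths(model, tumor_truth, tmp_path_factory):
    return simulate_alignments(
        model, tumor_truth, tmp_path_factory.mktemp("tumor"), prefix="tumor"
    )


@pytest.fixture(scope="session")
def normal_paths(model, normal_truth, tmp_path_factory):
    return simulate_alignments(
        model, normal_truth, tmp_path_factory.mktemp("normal"), prefix="normal"
    )


@pytest.fixture(scope="session")
def clean_paths(model, clean_truth, tmp_path_factory):
    return simulate_alignments(
        model, clean_truth, tmp_path_factory.mktemp("clean"), prefix="clean"
    )
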