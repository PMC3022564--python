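import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mitosurvey import synthetic_data as sd
from mitosurvey.codon_engine import default_code
from mitosurvey.io_formats import AlignedGenomeSet, GeneModel
from mitosurvey.variant_catalog import build_catalog

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def code():
    return default_code()


@pytest.fixture(scope="session")
def small_bundle():
    """Small synthetic study (3 kb genome, 40 + 120 genomes)."""
    return sd.generate_bundle(sd.small_simulation_spec(seed=5))


@pytest.fixture(scope="session")
def small_catalog(small_bundle):
    b = small_bundle
    return build_catalog(b.genomes, b.gene_models, b.effects, b.catalogue)


@pytest.fixture(scope="session")
def bundle_paths(small_bundle, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    return sd.write_bundle(small_bundle, outdir)


@pytest.fixture()
def tiny_alignment():
    """Four genomes, one protein gene (codons TTT AAA GGG), one tRNA."""
    seqs = [
        "TTTAAAGGGACG",
        "TTCAAAGGGACG",
        "TTTAAAAGGACG",
        "TTTAAAGGGTCG",
    ]
    ids = [f"g{i}" for i in range(4)]
    pops = {"g0": "African", "g1": "African", "g2": "non-African", "g3": "non-African"}
    return AlignedGenomeSet.from_sequences(ids, seqs, pops)


@pytest.fixture()
def tiny_genes():
    return [
        GeneModel("G1", 0, 9, "+", "protein"),
        GeneModel("T1", 9, 12, "+", "tRNA"),
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
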