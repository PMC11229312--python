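import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ripfoot.io_formats import GeneModel, GenomeLayout, Transcript
from ripfoot.pipeline import run_pipeline
from ripfoot.simulate import SynthConfig, generate

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_genome():
    return GenomeLayout({"chr1": 10_000, "chr2": 5_000})


@pytest.fixture()
def two_gene_models():
    """One plus- and one minus-strand coding gene on a shared chromosome."""
    plus = GeneModel(
        "gA", "chr1", "+", 1000, 2000,
        (Transcript("gA.1", 1000, 2000, exons=((1000, 1400), (1500, 2000)),
                    cds_5prime=1050, first_cds=(1050, 1400)),),
    )
    minus = GeneModel(
        "gB", "chr1", "-", 4000, 5000,
        (Transcript("gB.1", 4000, 5000, exons=((4000, 4500), (4600, 5000)),
                    cds_5prime=4949, first_cds=(4600, 4950)),),
    )
    return [plus, minus]


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic study conditions (fixed seed)."""
    return generate(SynthConfig())


@pytest.fixture(scope="session")
def default_run(default_bundle):
    """Full pipeline on the default bundle, shared across tests."""
    b = default_bundle
    return run_pipeline(
        b.genome, b.genes, b.tss_records, b.ip_alignments, b.control_alignments,
        b.acceptor_sites, b.junctions, null_reps=10, seed=0,
    )
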