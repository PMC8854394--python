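import pytest

from taqing.genome_forge import GenomeSpec, generate_reference
from taqing.pipeline import run_demo
from taqing.taq_simulator import MutantGenome


@pytest.fixture(scope="session")
def small_ref():
    """Two 40 kb triploid chromosomes, default variant rates."""
    spec = GenomeSpec(n_chromosomes=2, chrom_lengths=(40_000, 40_000), seed=11)
    return generate_reference(spec)


@pytest.fixture(scope="session")
def small_wt(small_ref):
    return MutantGenome.wild_type(small_ref)


@pytest.fixture(scope="session")
def demo_result():
    """One end-to-end run of the default scenario (shared across tests)."""
    return run_demo(seed=42)
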