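import numpy as np
import pytest

from ctlforge.fixtures import FixtureSpec, make_genome_bundle
from ctlforge.genome_io import GeneticMap, GenomeAssembly, GenomicRegion


@pytest.fixture(scope="session")
def bundle():
    """The standard synthetic genome bundle with planted truth (seed 0)."""
    return make_genome_bundle(FixtureSpec(seed=0))


@pytest.fixture(scope="session")
def ctl_region(bundle):
    t = bundle.truth["ctl_region"]
    return GenomicRegion.from_bp(bundle.gmap, t["chrom"], t["start_bp"], t["end_bp"])


@pytest.fixture()
def simple_map():
    """One chromosome, linear 1 cM per Mb, plus one with a plateau."""
    return GeneticMap(
        {
            "chr1": (np.array([0.0, 1e6]), np.array([0.0, 1.0])),
            "chr2": (np.array([0.0, 1e6, 2e6, 3e6]), np.array([0.0, 1.0, 1.0, 2.0])),
            "chr3": (np.array([0.0, 2e6, 3e6]), np.array([0.0, 1.0, 3.0])),
        }
    )


@pytest.fixture()
def toy_assembly():
    rng = np.random.default_rng(42)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return GenomeAssembly(
        {
            "chr1": bases[rng.integers(0, 4, 10_000)].tobytes().decode(),
            "chr2": bases[rng.integers(0, 4, 5_000)].tobytes().decode(),
        }
    )
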