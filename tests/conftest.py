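import pytest

from imprintscan.classify import ScanParameters
from imprintscan.io import CpGCall
from imprintscan.simulate import SimulationConfig, simulate_panel


@pytest.fixture
def params() -> ScanParameters:
    return ScanParameters()


def make_call(pos=100, meth=None, n_meth=10, n_total=20, chrom="chr1", context="CpG", strand="+"):
    """Convenience CpGCall builder with consistent counts."""
    if meth is not None:
        n_meth = round(meth * n_total)
    level = n_meth / n_total if n_total else 0.0
    return CpGCall(
        chrom=chrom, pos=pos, strand=strand, context=context,
        meth_level=level, n_meth=n_meth, n_total=n_total,
    )


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A scaled-down study used by unit tests that need a full manifest."""
    return SimulationConfig(
        seed=11,
        n_candidates=6,
        candidate_size_bp=(5_000, 15_000),
        n_dmrs=4,
        dmr_n_cpgs=(8, 40),
        n_qc_reads=2_000,
    )


@pytest.fixture(scope="session")
def small_manifest(small_config):
    return simulate_panel(small_config)
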