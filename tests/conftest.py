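import numpy as np
import pytest
from hypothesis import settings

from mechsnp import locus_candidates as lc
from mechsnp import proteoforms as pf
from mechsnp import synthetic_data as synth

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def demo_locus():
    """Default synthetic risk locus: (spec, disease model, marker id)."""
    return synth.build_demo_locus()


@pytest.fixture(scope="session")
def demo_panel(demo_locus):
    spec, _, _ = demo_locus
    return synth.gen_haplotype_panel(spec, 4000, seed=7)


@pytest.fixture(scope="session")
def two_site_panel():
    """Exact panel built from the worked 2x2 haplotype table
    {11: 0.5, 01: 0.1, 10: 0.1, 00: 0.3}."""
    counts = {"11": 50, "01": 10, "10": 10, "00": 30}
    rows = []
    for hap, n in counts.items():
        rows.extend([[int(hap[0]), int(hap[1])]] * n)
    return lc.HaplotypePanel(np.array(rows, dtype=np.uint8), ["a", "b"],
                             np.array([100, 200]))


@pytest.fixture(scope="session")
def msp_analog():
    """Synthetic MSPβ-like template plus its native disulfide topology."""
    return synth.gen_msp_beta_analog(seed=0)


@pytest.fixture(scope="session")
def msp_mutant(msp_analog):
    """The engineered R689C construct: template + C672S + R689C."""
    template, topology = msp_analog
    mutant = pf.apply_substitutions(template, {672: "S", 689: "C"})
    return mutant, topology
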