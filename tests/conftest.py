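import numpy as np
import pytest

import segment_scan as ss


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_panel():
    """300-subject, 40-variant panel with block AR(1) LD."""
    template = ss.ar1_block_ld(40, np.random.default_rng(5), block_size=10)
    return ss.simulate_genotypes(300, target_ld=template, seed=6)


@pytest.fixture(scope="session")
def multitissue_sim():
    """Two-tissue expression simulation with a shared causal architecture."""
    return ss.simulate_multitissue_expression(
        n_tissues=2, n_samples=[200, 80], similarity=0.9, h2_expr=0.4,
        n_causal=2, n_variants=20, seed=11,
    )
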