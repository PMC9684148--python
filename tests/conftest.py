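import numpy as np
import pytest

import chitopa as cp


@pytest.fixture(scope="session")
def hydrolases():
    return cp.preset_hydrolases()


@pytest.fixture(scope="session")
def deacetylases():
    return cp.preset_deacetylases()


@pytest.fixture
def make_ensemble():
    def _make(*seqs, abundances=None):
        chains = [cp.ChitosanChain(s, id=f"c{i}") for i, s in enumerate(seqs)]
        return cp.ChainEnsemble(chains, abundances)

    return _make


@pytest.fixture(scope="session")
def bernoulli_034_large():
    """200 chains of DP 700, Pr(A) = 0.34 (random-pattern reference)."""
    return cp.generate_bernoulli(0.34, np.full(200, 700), seed=20_034)


@pytest.fixture(scope="session")
def markov_block_large():
    """500 chains of DP 800 from the block-pattern Markov generator
    (transitions Pr(A->D) = 0.201, Pr(D->A) = 0.099)."""
    spec = cp.MarkovPASpec.from_transitions(0.201, 0.099)
    return cp.generate_markov(spec, np.full(500, 800), seed=20_033)
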