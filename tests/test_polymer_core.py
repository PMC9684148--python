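import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import chitopa as cp
from chitopa.polymer_core import DyadStats


class TestChainTypes:
    def test_chain_basics(self):
        c = cp.ChitosanChain("aAdDa", id="x")
        assert c.text == "AADDA"
        assert c.dp == 5 and c.n_acetyl == 3

    def test_empty_chain_rejected(self):
        with pytest.raises(ValueError, match="at least one residue"):
            cp.ChitosanChain("")

    def test_bad_alphabet_reports_position(self):
        with pytest.raises(ValueError, match="position 3"):
            cp.ChitosanChain("ADXDA")

    def test_ensemble_invariants(self, make_ensemble):
        with pytest.raises(ValueError, match="empty"):
            cp.ChainEnsemble([])
        with pytest.raises(ValueError, match="> 0"):
            make_ensemble("AD", abundances=[0.0])
        e = make_ensemble("AD", "ADD", abundances=[2.0, 1.0])
        assert e.total_monomers == 2 * 2 + 3


class TestComputeFa:
    def test_single_chain(self, make_ensemble):
        assert cp.compute_fa(make_ensemble("AADDA")) == pytest.approx(0.6)

    def test_all_d(self, make_ensemble):
        assert cp.compute_fa(make_ensemble("DDDD", "DD")) == 0.0

    def test_bernoulli_within_three_se(self):
        # 1e5 Bernoulli(0.34) monomers; binomial SE = sqrt(p(1-p)/n)
        ens = cp.generate_bernoulli(0.34, np.full(100, 1000), seed=1)
        se = math.sqrt(0.34 * 0.66 / 1e5)
        assert cp.compute_fa(ens) == pytest.approx(0.34, abs=3 * se)

    def test_abundance_weighting(self, make_ensemble):
        e = make_ensemble("AA", "DD", abundances=[3.0, 1.0])
        assert cp.compute_fa(e) == pytest.approx(0.75)


class TestDyads:
    def test_alternating(self, make_ensemble):
        d = cp.dyad_fractions(make_ensemble("ADAD"))
        assert d.f_ad == pytest.approx(2 / 3)
        assert d.f_da == pytest.approx(1 / 3)
        assert d.f_aa == d.f_dd == 0
        assert cp.p_sigma(d) == pytest.approx(2.0)

    def test_homopolymer_convention(self, make_ensemble):
        d = cp.dyad_fractions(make_ensemble("AAAA"))
        assert d.f_aa == 1.0
        assert d.p_ad == 0.0
        assert d.p_da == 0.0  # undefined -> 0 by convention
        assert cp.p_sigma(d) == 0.0

    def test_no_dyads_error(self, make_ensemble):
        with pytest.raises(ValueError, match="no dyads"):
            cp.dyad_fractions(make_ensemble("A", "D"))

    def test_dyads_never_span_chains(self, make_ensemble):
        # "AD" + "DA" has no AD..DA junction dyads
        d = cp.dyad_fractions(make_ensemble("AD", "DA"))
        assert d.f_ad == pytest.approx(0.5)
        assert d.f_da == pytest.approx(0.5)

    def test_markov_stationary_fractions(self, markov_block_large):
        # closed-form oracle: F_AA = F_A (1 - P_AD) etc. with
        # F_A = 0.33, P_AD = 0.201, P_DA = 0.099
        expected = (0.33 * 0.799, 0.33 * 0.201, 0.67 * 0.099, 0.67 * 0.901)
        assert expected == pytest.approx((0.2637, 0.0663, 0.0663, 0.6037), abs=5e-4)
        got = cp.dyad_fractions(markov_block_large).as_tuple()
        assert got == pytest.approx(expected, abs=0.005)

    def test_p_sigma_paper_quadruple(self):
        d = DyadStats(0.2637, 0.0663, 0.0663, 0.6037)
        assert cp.p_sigma(d) == pytest.approx(0.30, abs=0.005)

    def test_degenerate_composition_error(self):
        with pytest.raises(ValueError, match="sum to 1"):
            DyadStats(0, 0, 0, 0)


class TestBlockProfile:
    def test_toy_decomposition(self, make_ensemble):
        p = cp.block_profile_from_sequences(make_ensemble("AADDDA"))
        assert dict(p.a_blocks) == {2: 1.0, 1: 1.0}
        assert dict(p.d_blocks) == {3: 1.0}
        # reducing-end run flagged terminal (right-censored)
        assert dict(p.a_terminal) == {1: 1.0}

    def test_all_d(self, make_ensemble):
        p = cp.block_profile_from_sequences(make_ensemble("DDDD"))
        assert dict(p.d_blocks) == {4: 1.0}
        assert not p.a_blocks

    def test_monomer_conservation_exact(self, make_ensemble):
        e = make_ensemble("AADDDA", "DADDA", "AAAA", abundances=[1.0, 2.0, 0.5])
        p = cp.block_profile_from_sequences(e)
        assert p.total_monomers == e.total_monomers

    def test_geometric_run_law(self):
        # Bernoulli(0.33): D-run mean = 1/0.33 ~ 3.03
        ens = cp.generate_bernoulli(0.33, np.full(300, 700), seed=4)
        p = cp.block_profile_from_sequences(ens)
        assert p.number_average("D") == pytest.approx(1 / 0.33, rel=0.03)
        # pmf close to geometric in total variation
        th = cp.bernoulli_theory(0.33)
        freqs = p.frequencies("D")
        tv = 0.5 * sum(
            abs(freqs.get(k, 0.0) - float(th.d_run_pmf(k))) for k in range(1, 60)
        )
        assert tv < 0.02


class TestDPMoments:
    def test_monodisperse(self, make_ensemble):
        m = cp.dp_moments(make_ensemble(*(["A" * 100] * 5)))
        assert m.dpn == m.dpw == 100
        assert m.dispersity == 1.0

    def test_two_chain_hand_computation(self, make_ensemble):
        m = cp.dp_moments(make_ensemble("A" * 100, "D" * 300))
        assert m.dpn == pytest.approx(200)
        assert m.dpw == pytest.approx(250)
        assert m.dispersity == pytest.approx(1.25)

    def test_schulz_zimm_dispersity(self):
        spec = cp.DPDistributionSpec(family="schulz_zimm", dpn=800, dispersity=1.9)
        lengths = cp.sample_lengths(spec, 20_000, seed=6)
        chains = [cp.ChitosanChain(np.zeros(int(l), dtype=np.uint8)) for l in lengths[:50]]
        del chains  # moments computed directly from the lengths
        dpn = lengths.mean()
        dpw = (lengths.astype(float) ** 2).sum() / lengths.sum()
        assert dpw / dpn == pytest.approx(1.9, abs=0.05)


class TestBernoulliTheory:
    def test_mean_d_block_rounds_to_three(self):
        th = cp.bernoulli_theory(0.33)
        assert th.mean_d_block == pytest.approx(1 / 0.33)
        assert round(th.mean_d_block) == 3

    def test_heptamer_frequency(self):
        th = cp.bernoulli_theory(0.1)
        assert th.block_frequency(7, "A") == pytest.approx(1e-7)
        assert th.expected_blocks_per_polymer(7, 1000, "A") == pytest.approx(1e-4)
        # i.e. one heptamer block per 10,000 polymers of DP 1000
        assert 1 / th.expected_blocks_per_polymer(7, 1000, "A") == pytest.approx(1e4)

    def test_exact_interior_frequency_is_smaller(self):
        th = cp.bernoulli_theory(0.1)
        assert th.block_frequency(7, "A", exact=True) == pytest.approx(0.81e-7)

    def test_half_fa_dyads(self):
        th = cp.bernoulli_theory(0.5)
        assert th.dyads.as_tuple() == pytest.approx((0.25,) * 4)
        assert th.dyads.p_sigma == pytest.approx(1.0)

    def test_domain_error(self):
        for fa in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                cp.bernoulli_theory(fa)


class TestProperties:
    @given(st.floats(min_value=0.01, max_value=0.99))
    def test_bernoulli_p_sigma_is_one(self, fa):
        th = cp.bernoulli_theory(fa)
        assert cp.p_sigma(th.dyads) == pytest.approx(1.0, abs=1e-9)

    @given(
        st.lists(
            st.text(alphabet="AD", min_size=2, max_size=30), min_size=1, max_size=10
        )
    )
    @settings(max_examples=60)
    def test_dyad_fraction_sum_and_fa_consistency(self, seqs):
        ens = cp.ChainEnsemble([cp.ChitosanChain(s, id=str(i)) for i, s in enumerate(seqs)])
        d = cp.dyad_fractions(ens)
        assert sum(d.as_tuple()) == pytest.approx(1.0)
        dpn = cp.dp_moments(ens).dpn
        assert abs(d.fa - cp.compute_fa(ens)) <= 2 / dpn + 1e-12

    @given(
        st.lists(
            st.text(alphabet="AD", min_size=1, max_size=40), min_size=1, max_size=8
        )
    )
    @settings(max_examples=60)
    def test_block_profile_conservation(self, seqs):
        ens = cp.ChainEnsemble([cp.ChitosanChain(s, id=str(i)) for i, s in enumerate(seqs)])
        p = cp.block_profile_from_sequences(ens)
        assert p.total_monomers == pytest.approx(ens.total_monomers)
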