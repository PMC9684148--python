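import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import chitopa as cp
from chitopa.digestion import ProductRecord, ProductTable
from chitopa.fingerprint import BlockAverages, excluded_monomer_fraction


def _table(*rows, provenance=None):
    """rows of (dp, na, end_flag, abundance[, sequence])"""
    records = []
    for row in rows:
        dp, na, flag, ab = row[:4]
        seq = row[4] if len(row) > 4 else None
        records.append(ProductRecord(dp=dp, na=na, nd=dp - na, end_flag=flag,
                                     abundance=ab, sequence=seq))
    return ProductTable(records, provenance=provenance or {"enzyme": "chitinosanase"})


class TestNormalizeWindow:
    def test_single_product(self):
        t = cp.normalize_window(_table((3, 1, "interior", 5.0)))
        assert t.records[0].fraction == pytest.approx(1.0)

    def test_two_products(self):
        t = cp.normalize_window(_table((2, 1, "interior", 3.0), (3, 1, "interior", 1.0)))
        assert [r.fraction for r in t.records] == pytest.approx([0.75, 0.25])

    def test_out_of_window_flagged(self):
        t = cp.normalize_window(_table((2, 1, "interior", 1.0), (15, 5, "interior", 1.0)))
        assert t.records[0].fraction == pytest.approx(1.0)
        assert t.records[1].fraction is None

    def test_empty_window_errors(self):
        with pytest.raises(ValueError, match="no products in DP window"):
            cp.normalize_window(_table((15, 5, "interior", 1.0)))

    def test_chitinosanase_digest_tail_below_ten_percent(self, hydrolases):
        ens = cp.generate_bernoulli(0.34, np.full(100, 700), seed=1)
        table = cp.digest(ens, hydrolases["chitinosanase"], seed=2)
        assert excluded_monomer_fraction(table, 2, 10) < 0.10


class TestEstimateFa:
    def test_fully_acetylated(self):
        t = _table((2, 2, "interior", 1.0), (4, 4, "interior", 2.0))
        assert cp.estimate_fa(t) == pytest.approx(1.0)

    def test_unwindowed_equals_substrate_fa(self, hydrolases):
        ens = cp.generate_bernoulli(0.4, np.full(20, 120), seed=3)
        table = cp.digest(ens, hydrolases["chitinosanase"], seed=4)
        assert cp.estimate_fa(table, window=None) == pytest.approx(
            cp.compute_fa(ens), abs=1e-12
        )

    def test_windowed_estimate_on_bernoulli_digest(self, hydrolases):
        ens = cp.generate_bernoulli(0.34, np.full(150, 700), seed=5)
        table = cp.digest(ens, hydrolases["chitinosanase"], seed=6)
        assert cp.estimate_fa(table, window=(2, 10)) == pytest.approx(0.34, abs=0.03)

    def test_window_bias_bounded_by_excluded_fraction(self, hydrolases):
        for fa, seed in [(0.2, 7), (0.34, 8), (0.5, 9)]:
            ens = cp.generate_bernoulli(fa, np.full(60, 400), seed=seed)
            table = cp.digest(ens, hydrolases["chitinosanase"], seed=seed + 1)
            bound = excluded_monomer_fraction(table, 2, 10)
            err = abs(cp.estimate_fa(table, (2, 10)) - cp.compute_fa(ens))
            assert err <= bound + 1e-12


class TestInferBlockProfile:
    def test_interior_product(self):
        t = _table((5, 3, "interior", 2.0))
        p = cp.infer_block_profile(t)
        assert dict(p.a_blocks) == {3: 2.0}
        assert dict(p.d_blocks) == {2: 2.0}

    def test_toy_digest_matches_run_decomposition(self, hydrolases, make_ensemble):
        ens = make_ensemble("AADDDAADDA")
        table = cp.digest(ens, hydrolases["chitinosanase"], seed=0)
        inferred = cp.infer_block_profile(table)
        oracle = cp.block_profile_from_sequences(ens)
        assert dict(inferred.a_blocks) == dict(oracle.a_blocks)
        assert dict(inferred.d_blocks) == dict(oracle.d_blocks)
        assert dict(inferred.a_terminal) == dict(oracle.a_terminal)
        # reducing-terminal product (na=2, nd=2) contributes A-block 2 and D-block 2
        assert inferred.a_blocks[2] == 2.0 and inferred.d_blocks[2] == 1.0

    def test_bernoulli_d_block_average_matches_oracle(self, hydrolases):
        ens = cp.generate_bernoulli(0.33, np.full(150, 500), seed=10)
        table = cp.digest(ens, hydrolases["chitinosanase"], seed=11)
        inferred = cp.infer_block_profile(table)
        oracle = cp.block_profile_from_sequences(ens)
        assert inferred.number_average("D") == pytest.approx(
            oracle.number_average("D"), abs=1e-9
        )
        assert inferred.number_average("D") == pytest.approx(3.0, abs=0.1)

    def test_inconsistent_interior_product_rejected(self):
        t = _table((3, 0, "interior", 1.0))
        with pytest.raises(ValueError, match="inconsistent with DA/XX"):
            cp.infer_block_profile(t)

    def test_provenance_enforced(self):
        t = _table((3, 2, "interior", 1.0), provenance={"enzyme": "ChiB"})
        with pytest.raises(ValueError, match="not a chitinosanase"):
            cp.infer_block_profile(t)
        cp.infer_block_profile(t, enforce_provenance=False)  # override works

    @given(
        seqs=st.lists(st.text(alphabet="AD", min_size=1, max_size=50), min_size=1, max_size=5),
        seed=st.integers(min_value=0, max_value=2**31),
    )
    @settings(max_examples=80, deadline=None)
    def test_oracle_equivalence_property(self, seqs, seed):
        # complete unwindowed chitinosanase digest == direct run-length oracle
        hyd = cp.preset_hydrolases()["chitinosanase"]
        ens = cp.ChainEnsemble([cp.ChitosanChain(s, id=str(i)) for i, s in enumerate(seqs)])
        table = cp.digest(ens, hyd, seed=seed)
        inferred = cp.infer_block_profile(table)
        oracle = cp.block_profile_from_sequences(ens)
        assert dict(inferred.a_blocks) == dict(oracle.a_blocks)
        assert dict(inferred.d_blocks) == dict(oracle.d_blocks)
        assert dict(inferred.a_terminal) == dict(oracle.a_terminal)
        assert dict(inferred.d_terminal) == dict(oracle.d_terminal)


class TestAverages:
    def test_uniform_blocks(self):
        p = cp.BlockProfile()
        p.add("A", 2, 3.0)
        p.add("D", 2, 5.0)
        avg = cp.average_block_sizes(p, kind="number")
        assert avg == BlockAverages(a=2.0, d=2.0)
        assert cp.average_block_sizes(p, kind="weight") == BlockAverages(a=2.0, d=2.0)

    def test_hand_computation(self):
        p = cp.BlockProfile()
        p.add("A", 1, 1.0)
        p.add("A", 3, 1.0)
        p.add("D", 2, 1.0)
        avg_n = cp.average_block_sizes(p, kind="number")
        avg_w = cp.average_block_sizes(p, kind="weight")
        assert avg_n.a == pytest.approx(2.0)
        assert avg_w.a == pytest.approx(2.5)

    def test_empty_profile_errors(self):
        with pytest.raises(ValueError, match="empty"):
            cp.average_block_sizes(cp.BlockProfile())

    @given(
        sizes=st.lists(st.tuples(st.integers(1, 30), st.floats(0.1, 10)), min_size=1, max_size=10)
    )
    def test_weight_at_least_number(self, sizes):
        p = cp.BlockProfile()
        for s, c in sizes:
            p.add("A", s, c)
            p.add("D", s, c)
        n = cp.average_block_sizes(p, kind="number")
        w = cp.average_block_sizes(p, kind="weight")
        assert w.a >= n.a - 1e-9 and w.d >= n.d - 1e-9


class TestCompareProfiles:
    def test_identical(self):
        p = cp.BlockProfile()
        p.add("A", 2, 1.0)
        p.add("D", 3, 1.0)
        cmpres = cp.compare_profiles(p, p)
        assert all(v == 0 for v in cmpres.delta_a.values())
        assert cmpres.tv_a == cmpres.tv_d == 0

    def test_block_pa_enriched_in_large_a_blocks(self):
        lengths = np.full(200, 500)
        block = cp.block_profile_from_sequences(
            cp.generate_markov(cp.MarkovPASpec(fa=0.33, p_sigma=0.3), lengths, seed=1)
        )
        random_pa = cp.block_profile_from_sequences(
            cp.generate_bernoulli(0.33, lengths, seed=2)
        )
        cmpres = cp.compare_profiles(block, random_pa)
        assert sum(v for s, v in cmpres.delta_a.items() if s >= 3) > 0

    def test_regular_pattern_suppresses_aa(self):
        lengths = np.full(100, 500)
        regular = cp.block_profile_from_sequences(cp.generate_regular(0.33, lengths))
        random_pa = cp.block_profile_from_sequences(
            cp.generate_bernoulli(0.33, lengths, seed=3)
        )
        cmpres = cp.compare_profiles(regular, random_pa)
        assert sum(v for s, v in cmpres.delta_a.items() if s >= 2) < 0


class TestMsNoise:
    def test_cv_zero_identity(self):
        t = _table((2, 1, "interior", 3.0), (3, 2, "interior", 1.0))
        out = cp.add_ms_noise(t, 0.0, seed=1)
        assert [r.abundance for r in out.records] == [3.0, 1.0]

    def test_deterministic_under_seed(self):
        t = _table((2, 1, "interior", 3.0), (3, 2, "interior", 1.0))
        a = cp.add_ms_noise(t, 0.1, seed=5)
        b = cp.add_ms_noise(t, 0.1, seed=5)
        assert [r.abundance for r in a.records] == [r.abundance for r in b.records]

    def test_total_abundance_preserved(self):
        t = _table((2, 1, "interior", 3.0), (7, 2, "interior", 2.0))
        out = cp.add_ms_noise(t, 0.2, seed=6)
        assert sum(r.abundance for r in out.records) == pytest.approx(5.0)

    def test_fa_estimate_bias_small(self, hydrolases):
        ens = cp.generate_bernoulli(0.34, np.full(40, 300), seed=7)
        table = cp.digest(ens, hydrolases["chitinosanase"], seed=8)
        base = cp.estimate_fa(table, (2, 10))
        estimates = [
            cp.estimate_fa(cp.add_ms_noise(table, 0.1, seed=s), (2, 10))
            for s in range(100)
        ]
        assert abs(np.mean(estimates) - base) < 0.01
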