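import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from refstab import (genorm_m, genorm_stepwise, normalization_factor,
                     pairwise_variation, to_quantities, v_series)
from refstab.errors import ContractError, InsufficientDataError
from refstab.genorm import STABLE_M_CUTOFF

from .conftest import make_dataset


def brute_force_m(cq: np.ndarray) -> np.ndarray:
    """Independent oracle: M from the textbook definition, plain loops.

    V_jk = sd over samples of log2(q_j/q_k) with n-1 denominator;
    M_j = mean over k != j.  Works directly on Cq since
    log2(q_j/q_k) = (Cq_k - Cq_j) + const per gene pair.
    """
    n_s, n_g = cq.shape
    m = np.zeros(n_g)
    for j in range(n_g):
        vs = []
        for k in range(n_g):
            if k == j:
                continue
            ratios = [cq[i, k] - cq[i, j] for i in range(n_s)]
            mean = sum(ratios) / n_s
            var = sum((r - mean) ** 2 for r in ratios) / (n_s - 1)
            vs.append(math.sqrt(var))
        m[j] = sum(vs) / len(vs)
    return m


class TestPairwiseVariation:
    def test_identical_profiles_give_zero(self):
        ds = make_dataset([[20.0, 20.0], [21.0, 21.0], [22.0, 22.0]])
        q = to_quantities(ds)
        assert pairwise_variation(q, "g1", "g2") == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        # log2 ratios are Cq_k - Cq_j = {0, 1, -1, 0}; sd (n-1) = 0.8165
        ds = make_dataset([[20.0, 20.0], [21.0, 22.0], [22.0, 21.0], [23.0, 23.0]])
        q = to_quantities(ds)
        assert pairwise_variation(q, "g1", "g2") == pytest.approx(
            math.sqrt(2.0 / 3.0), abs=1e-4)
        assert pairwise_variation(q, "g1", "g2") == pytest.approx(0.8165, abs=1e-4)

    def test_shift_invariance(self):
        base = np.array([[20.0, 20.0], [21.0, 22.0], [22.0, 21.0], [23.0, 23.0]])
        shifted = base + np.array([0.0, 3.0])
        v0 = pairwise_variation(to_quantities(make_dataset(base)), "g1", "g2")
        v1 = pairwise_variation(to_quantities(make_dataset(shifted)), "g1", "g2")
        assert v0 == pytest.approx(v1, abs=1e-12)

    def test_too_few_common_samples(self):
        ds = make_dataset([[20.0, 20.0], [21.0, np.nan], [22.0, 21.0]])
        q = to_quantities(ds)
        with pytest.raises(InsufficientDataError):
            pairwise_variation(q, "g1", "g2")

    def test_unknown_gene(self):
        ds = make_dataset([[20.0, 20.0]] * 3)
        with pytest.raises(ContractError):
            pairwise_variation(to_quantities(ds), "g1", "nope")


class TestGenormM:
    def test_identical_pair_shares_minimum(self, rng):
        noisy = 20 + rng.normal(0, 1.0, 5)
        cq = np.column_stack([
            20 + rng.normal(0, 0.05, 5),
            np.zeros(5), noisy])
        cq[:, 1] = cq[:, 0]  # genes 1 and 2 identical
        res = genorm_m(to_quantities(make_dataset(cq)))
        assert res.values["g1"] == pytest.approx(res.values["g2"], abs=1e-12)
        assert res.values["g3"] > res.values["g1"]
        assert set(res.ranks[["g1", "g2"]]) == {1, 2}

    @pytest.mark.parametrize("n_genes,n_samples", [(3, 4), (4, 5), (5, 6)])
    def test_oracle_equivalence(self, rng, n_genes, n_samples):
        cq = 20 + rng.normal(0, 1.0, size=(n_samples, n_genes))
        res = genorm_m(to_quantities(make_dataset(cq)))
        np.testing.assert_allclose(res.values.values, brute_force_m(cq),
                                   atol=1e-12)

    def test_stable_flag_cutoff(self, rng):
        cq = 20 + rng.normal(0, 0.1, size=(6, 3))
        res = genorm_m(to_quantities(make_dataset(cq)))
        assert (res.values < STABLE_M_CUTOFF).all()
        assert res.diagnostics["stable_flag"].all()

    def test_per_sample_scaling_invariance(self, rng):
        # adding a per-sample constant to all genes leaves M unchanged
        cq = 20 + rng.normal(0, 0.5, size=(6, 4))
        shifts = rng.normal(0, 2.0, size=(6, 1))
        m0 = genorm_m(to_quantities(make_dataset(cq))).values
        m1 = genorm_m(to_quantities(make_dataset(cq + shifts))).values
        np.testing.assert_allclose(m0.values, m1.values, atol=1e-10)

    def test_m_nonnegative_and_zero_iff_constant_ratios(self, rng):
        shifts = rng.normal(0, 1.0, size=(5, 1))
        cq = np.array([20.0, 22.0, 24.0]) + shifts  # perfectly co-varying panel
        res = genorm_m(to_quantities(make_dataset(cq)))
        np.testing.assert_allclose(res.values.values, 0.0, atol=1e-12)

    @given(arrays(np.float64, (5, 4),
                  elements=st.floats(min_value=15, max_value=30)))
    @settings(max_examples=30, deadline=None)
    def test_property_oracle_and_nonnegative(self, cq):
        res = genorm_m(to_quantities(make_dataset(cq)))
        assert (res.values.values >= -1e-15).all()
        np.testing.assert_allclose(res.values.values, brute_force_m(cq),
                                   atol=1e-10)

    def test_needs_three_genes(self):
        ds = make_dataset([[20.0, 21.0]] * 4)
        with pytest.raises(InsufficientDataError):
            genorm_m(to_quantities(ds))

    def test_noise_monotonicity(self):
        # more noise on one gene never decreases its expected M
        out = []
        for sigma in (0.1, 0.5, 1.5):
            ms = []
            for seed in range(30):
                r = np.random.default_rng(seed)
                cq = 20 + r.normal(0, 0.2, size=(10, 4))
                cq[:, 0] += r.normal(0, sigma, size=10)
                ms.append(genorm_m(to_quantities(make_dataset(cq))).values["g1"])
            out.append(np.mean(ms))
        assert out[0] < out[1] < out[2]


class TestStepwise:
    def test_worst_gene_excluded_first(self, rng):
        cq = 20 + rng.normal(0, 0.1, size=(6, 4))
        cq[:, 3] += rng.normal(0, 2.0, size=6)
        res = genorm_stepwise(to_quantities(make_dataset(cq)))
        assert res.ranks["g4"] == 4
        assert res.diagnostics["mode"] == "stepwise"

    def test_final_pair_shares_value(self, rng):
        cq = 20 + rng.normal(0, 0.5, size=(6, 5))
        res = genorm_stepwise(to_quantities(make_dataset(cq)))
        pair = res.diagnostics["final_pair"]
        assert res.values[pair[0]] == res.values[pair[1]]
        assert set(res.ranks[list(pair)]) == {1, 2}


class TestNormalizationFactor:
    def test_single_gene_is_identity(self, rng):
        cq = 20 + rng.normal(0, 0.5, size=(5, 3))
        q = to_quantities(make_dataset(cq))
        nf = normalization_factor(q, ["g2"])
        np.testing.assert_allclose(nf.values, q.q["g2"].values)

    def test_geometric_mean_of_two(self):
        ds = make_dataset([[20.0, 20.0], [20.0, 22.0]])
        q = to_quantities(ds)  # sample 2: q = {1, 0.25}
        nf = normalization_factor(q, ["g1", "g2"])
        assert nf.iloc[1] == pytest.approx(0.5)

    def test_homogeneity(self, rng):
        cq = 20 + rng.normal(0, 0.5, size=(4, 3))
        q = to_quantities(make_dataset(cq))
        nf = normalization_factor(q, ["g1", "g2", "g3"])
        q2 = q.q.copy()
        q2.iloc[0] *= 8.0  # scale every gene of sample 1 by c
        nf2 = normalization_factor(q2, ["g1", "g2", "g3"])
        assert nf2.iloc[0] == pytest.approx(8.0 * nf.iloc[0])
        np.testing.assert_allclose(nf2.iloc[1:], nf.iloc[1:])

    def test_missing_quantity_is_error(self):
        ds = make_dataset([[20.0, np.nan], [21.0, 22.0], [22.0, 23.0]])
        q = to_quantities(ds)
        with pytest.raises(InsufficientDataError, match="g2"):
            normalization_factor(q, ["g1", "g2"])

    def test_empty_gene_list_is_contract_error(self, rng):
        q = to_quantities(make_dataset(20 + rng.normal(0, 1, (3, 3))))
        with pytest.raises(ContractError):
            normalization_factor(q, [])


class TestVSeries:
    def test_proportional_added_gene_gives_zero_v(self, rng):
        shifts = rng.normal(0, 1.0, size=(6, 1))
        cq = np.array([20.0, 22.0, 24.0]) + shifts  # all genes co-vary exactly
        q = to_quantities(make_dataset(cq))
        res = genorm_m(q)
        vs = v_series(q, res)
        assert vs.v[2] == pytest.approx(0.0, abs=1e-12)
        assert vs.recommended_n == 2

    def test_recommended_n_is_first_below_threshold(self, rng):
        cq = 20 + rng.normal(0, 0.05, size=(8, 5))
        q = to_quantities(make_dataset(cq))
        vs = v_series(q, genorm_m(q), threshold=0.15)
        assert vs.recommended_n == int(vs.v.index[vs.v < 0.15].min())

    def test_no_v_below_threshold_recommends_full_panel(self, rng):
        cq = 20 + rng.normal(0, 3.0, size=(6, 4))
        q = to_quantities(make_dataset(cq))
        vs = v_series(q, genorm_m(q), threshold=1e-6)
        assert vs.recommended_n == 4

    def test_oracle_v23(self, rng):
        cq = 20 + rng.normal(0, 0.5, size=(6, 4))
        q = to_quantities(make_dataset(cq))
        res = genorm_m(q)
        vs = v_series(q, res)
        top = res.ordered_genes()
        nf2 = np.exp(np.log(q.q[top[:2]]).mean(axis=1))
        nf3 = np.exp(np.log(q.q[top[:3]]).mean(axis=1))
        expected = np.std(np.log2(nf2 / nf3), ddof=1)
        assert vs.v[2] == pytest.approx(expected, abs=1e-12)

    def test_ranking_must_cover_genes(self, rng):
        cq = 20 + rng.normal(0, 0.5, size=(6, 4))
        q = to_quantities(make_dataset(cq))
        res = genorm_m(to_quantities(make_dataset(cq[:, :3])))
        with pytest.raises(ContractError):
            v_series(q, res)
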