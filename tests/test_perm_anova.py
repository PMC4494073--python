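"""Permutation ANOVA, two-group test, and BH-FDR against independent oracles."""

import itertools

import numpy as np
import numpy.linalg as la
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import acclimkit as ak
from acclimkit.design import ValidationError

# ---------------------------------------------------------------------------
# independent oracles (naive least squares / explicit enumeration)
# ---------------------------------------------------------------------------


def naive_type2_f(y, treatment, day):
    """Type-II F statistics via raw normal equations, no shared code."""

    def rss(X):
        beta, *_ = la.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    n = len(y)
    I = np.ones((n, 1))
    Da = pd.get_dummies(pd.Series(treatment)).to_numpy(float)
    Db = pd.get_dummies(pd.Series(day)).to_numpy(float)
    X_a, X_b, X_ab = np.hstack([I, Da]), np.hstack([I, Db]), np.hstack([I, Da, Db])
    r_a, r_b, r_ab = rss(X_a), rss(X_b), rss(X_ab)
    df_a = la.matrix_rank(X_ab) - la.matrix_rank(X_b)
    df_b = la.matrix_rank(X_ab) - la.matrix_rank(X_a)
    df_res = n - la.matrix_rank(X_ab)
    return (
        ((r_b - r_ab) / df_a) / (r_ab / df_res),
        ((r_a - r_ab) / df_b) / (r_ab / df_res),
    )


def exhaustive_anova_p(y, treatment, day):
    """p over all n! response permutations, naive F at every step."""
    f_obs = naive_type2_f(y, treatment, day)
    counts, total = [0, 0], 0
    for perm in itertools.permutations(range(len(y))):
        f = naive_type2_f(y[list(perm)], treatment, day)
        for k in range(2):
            counts[k] += f[k] >= f_obs[k] - 1e-12
        total += 1
    return counts[0] / total, counts[1] / total


# ---------------------------------------------------------------------------


class TestObservedF:
    def test_constant_response_is_zero_zero(self, design6):
        y = pd.Series(7.0, index=design6.sample_ids)
        assert ak.fit_two_factor_f(y, design6) == (0.0, 0.0)

    def test_perfect_separation_infinite_sentinel(self, design6):
        y = pd.Series(
            [0, 0, 1, 1, 0, 0], index=design6.sample_ids, dtype=float
        )  # +1 exactly on stable31
        f_trt, f_day = ak.fit_two_factor_f(y, design6)
        assert np.isinf(f_trt) and f_day == 0.0

    def test_matches_normal_equations_oracle(self, design6, rng):
        y = rng.normal(size=6)
        ours = ak.fit_two_factor_f(pd.Series(y, index=design6.sample_ids), design6)
        oracle = naive_type2_f(
            y, design6.table["treatment"].to_numpy(), design6.table["day"].to_numpy()
        )
        assert ours == pytest.approx(oracle, rel=1e-10)

    def test_unbalanced_design_matches_oracle(self, design6_2x2, rng):
        y = rng.normal(size=6)
        ours = ak.fit_two_factor_f(pd.Series(y, index=design6_2x2.sample_ids), design6_2x2)
        oracle = naive_type2_f(
            y,
            design6_2x2.table["treatment"].to_numpy(),
            design6_2x2.table["day"].to_numpy(),
        )
        assert ours == pytest.approx(oracle, rel=1e-10)

    def test_single_level_factor_errors(self):
        from conftest import toy_design

        d = toy_design(
            treatments=["control29"] * 4, days=[7, 7, 11, 11]
        )
        with pytest.raises(ValidationError, match="levels"):
            ak.fit_two_factor_f(pd.Series(np.arange(4.0), index=d.sample_ids), d)


class TestPermutationPvalues:
    def test_exhaustive_matches_enumeration_oracle(self, design6, rng):
        y = rng.normal(size=6)
        ours = ak.permutation_anova(
            pd.Series(y, index=design6.sample_ids), design6, exhaustive=True
        )
        p_trt, p_day = exhaustive_anova_p(
            y, design6.table["treatment"].to_numpy(), design6.table["day"].to_numpy()
        )
        assert ours["p_treatment"] == pytest.approx(p_trt, abs=1e-12)
        assert ours["p_day"] == pytest.approx(p_day, abs=1e-12)

    def test_constant_gene_p_is_one(self, design6):
        Y = pd.DataFrame(
            [[3.0] * 6, [0.0] * 6], index=["g0", "g1"], columns=design6.sample_ids
        )
        tab = ak.permutation_pvalues(Y, design6, 99, seed=0)
        assert (tab[["p_treatment", "p_day"]] == 1.0).all().all()

    def test_seed_reproducibility_and_gene_order_invariance(self, stressed72, rng):
        Y = pd.DataFrame(
            rng.normal(size=(20, 72)),
            index=[f"g{i}" for i in range(20)],
            columns=stressed72.sample_ids,
        )
        a = ak.permutation_pvalues(Y, stressed72, 199, seed=5)
        b = ak.permutation_pvalues(Y, stressed72, 199, seed=5)
        pd.testing.assert_frame_equal(a, b)
        perm = list(rng.permutation(Y.index))
        c = ak.permutation_pvalues(Y.loc[perm], stressed72, 199, seed=5)
        pd.testing.assert_frame_equal(a.loc[perm], c)

    def test_too_few_permutations_rejected(self, design6):
        y = pd.DataFrame(
            np.zeros((2, 6)), index=["g0", "g1"], columns=design6.sample_ids
        )
        with pytest.raises(ValidationError, match="99"):
            ak.permutation_pvalues(y, design6, n_permutations=10)

    def test_p_floor(self, stressed72, rng):
        expr, _ = ak.planted_effect_matrix(stressed72, n_genes=20, n_true=10,
                                           effect=5.0, noise_sd=0.1, seed=1)
        tab = ak.permutation_pvalues(expr, stressed72, 199, seed=2)
        assert tab["p_treatment"].min() >= 1 / 200


class TestBH:
    def test_hand_example(self):
        q = ak.bh_fdr([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert np.allclose(ak.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_single_p(self):
        assert ak.bh_fdr([0.2]) == pytest.approx([0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ak.bh_fdr([0.5, 0.0])
        with pytest.raises(ValueError):
            ak.bh_fdr([0.5, 1.2])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0, allow_nan=False), min_size=1, max_size=60))
    def test_agrees_with_statsmodels(self, ps):
        from statsmodels.stats.multitest import multipletests

        ours = ak.bh_fdr(ps)
        theirs = multipletests(ps, method="fdr_bh")[1]
        assert np.allclose(ours, theirs, atol=1e-12)

    def test_monotone_in_p(self, rng):
        p = rng.uniform(1e-4, 1, size=200)
        q = ak.bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
        assert (q >= p).all()


class TestSelectSignificant:
    def test_boundary_inclusive(self):
        tab = pd.DataFrame(
            {"q_treatment": [0.01, 0.010000001, 1.0]},
            index=["g0", "g1", "g2"],
        )
        sel = ak.select_significant(tab, "treatment", alpha=0.01)
        assert list(sel) == ["g0"]

    def test_all_q_one_gives_empty(self):
        tab = pd.DataFrame({"q_treatment": [1.0, 1.0]}, index=["a", "b"])
        assert len(ak.select_significant(tab, "treatment", 0.01)) == 0

    def test_bad_alpha_rejected(self):
        tab = pd.DataFrame({"q_treatment": [0.5]}, index=["a"])
        with pytest.raises(ValueError):
            ak.select_significant(tab, "treatment", alpha=2.0)


class TestTwoGroupTest:
    def test_exhaustive_matches_enumeration(self, rng):
        from conftest import toy_design

        d = toy_design(
            treatments=["stable31"] * 4 + ["variable29_33"] * 4,
            days=[7] * 8,
        )
        Y = pd.DataFrame(
            rng.normal(size=(3, 8)), index=["g0", "g1", "g2"], columns=d.sample_ids
        )
        res = ak.two_group_test(
            Y, d, list(d.sample_ids[:4]), list(d.sample_ids[4:]), exhaustive=True
        )
        assert res["n_permutations"].iloc[0] == 70
        for g in range(3):
            v = Y.iloc[g].to_numpy()
            obs = abs(v[:4].mean() - v[4:].mean())
            count = 0
            for combo in itertools.combinations(range(8), 4):
                m = np.zeros(8, bool)
                m[list(combo)] = True
                count += abs(v[m].mean() - v[~m].mean()) >= obs - 1e-12
            assert res["p"].iloc[g] == pytest.approx(count / 70, abs=1e-12)

    def test_identical_groups_zero_variance_p_one(self):
        from conftest import toy_design

        d = toy_design(
            treatments=["stable31"] * 2 + ["variable29_33"] * 2, days=[7] * 4
        )
        Y = pd.DataFrame([[2.0] * 4, [2.0] * 4], index=["g0", "g1"], columns=d.sample_ids)
        res = ak.two_group_test(Y, d, list(d.sample_ids[:2]), list(d.sample_ids[2:]), 99, seed=0)
        assert (res["p"] == 1.0).all()

    def test_small_group_rejected(self, design144, rng):
        Y = pd.DataFrame(
            rng.normal(size=(2, 144)), index=["g0", "g1"], columns=design144.sample_ids
        )
        with pytest.raises(ValidationError, match=">=2"):
            ak.two_group_test(Y, design144, list(design144.sample_ids[:1]),
                              list(design144.sample_ids[1:5]))

    def test_overlapping_groups_rejected(self, design144, rng):
        Y = pd.DataFrame(
            rng.normal(size=(2, 144)), index=["g0", "g1"], columns=design144.sample_ids
        )
        with pytest.raises(ValidationError, match="disjoint"):
            ak.two_group_test(Y, design144, list(design144.sample_ids[:3]),
                              list(design144.sample_ids[2:6]))
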