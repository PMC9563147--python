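import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcistate import A0, TumorCausalModel, log_marginal_likelihood, score_tumor

from .oracles import (exact_log_marginal_likelihood, exact_marginal_likelihood,
                      naive_tumor_posteriors)


class TestMarginalLikelihood:
    def test_empty_table_scores_probability_one(self):
        assert log_marginal_likelihood([[0, 0], [0, 0]], alpha=1.0) == 0.0
        assert log_marginal_likelihood([[0, 0]], alpha=0.5) == 0.0

    def test_uniform_prior_worked_example(self):
        # N_00=2, N_01=0, N_10=1, N_11=1 with alpha=1 gives exactly 1/18
        got = log_marginal_likelihood([[2, 0], [1, 1]], alpha=1.0)
        assert exact_marginal_likelihood([[2, 0], [1, 1]], 1) == \
            pytest.approx(1 / 18)
        assert got == pytest.approx(math.log(1 / 18), abs=1e-12)

    def test_log_space_stability_at_huge_counts(self):
        big = [[10**6, 2 * 10**6], [5 * 10**5, 10**6]]
        val = log_marginal_likelihood(big, alpha=2.0)
        assert np.isfinite(val)
        assert np.isfinite(log_marginal_likelihood(np.array(big) * 2, alpha=4.0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            log_marginal_likelihood([[-1, 0], [0, 0]])
        with pytest.raises(ValueError):
            log_marginal_likelihood([[1, 0], [0, 0]], alpha=0.0)

    @settings(derandomize=True, max_examples=150, deadline=None)
    @given(
        counts=st.lists(st.integers(0, 30), min_size=4, max_size=4),
        alpha=st.sampled_from([0.5, 1.0, 2.0]),
    )
    def test_matches_exact_gamma_product_oracle(self, counts, alpha):
        table = [counts[:2], counts[2:]]
        got = log_marginal_likelihood(table, alpha=alpha)
        want = exact_log_marginal_likelihood(table, alpha)
        assert got == pytest.approx(want, rel=1e-10, abs=1e-10)

    def test_single_block_cause_absent_model(self):
        got = log_marginal_likelihood([[3, 2]], alpha=1.0)
        want = exact_log_marginal_likelihood([[3, 2]], 1)
        assert got == pytest.approx(want, rel=1e-12)


class TestScoreTumor:
    def test_identical_candidates_split_posterior_equally(self):
        # single tumor: every candidate (incl. A0) has marginal likelihood 1/2
        sga = pd.DataFrame({"GA": [1], "GB": [1]}, index=["T1"])
        deg = pd.DataFrame({"E": [1]}, index=["T1"])
        table = score_tumor("T1", sga, deg, full=True)
        assert np.allclose(table["posterior"], 1 / 3)
        win = score_tumor("T1", sga, deg)
        assert win["cause"].iloc[0] == A0  # tie broken towards A0, then lexicographic

    def test_tumor_without_sga_assigns_all_to_a0(self):
        sga = pd.DataFrame({"G": [0, 1]}, index=["T1", "T2"])
        deg = pd.DataFrame({"E1": [1, 0], "E2": [1, 1]}, index=["T1", "T2"])
        win = score_tumor("T1", sga, deg)
        assert (win["cause"] == A0).all()
        assert (win["posterior"] == 1.0).all()

    def test_tumor_without_deg_yields_empty_result(self):
        sga = pd.DataFrame({"G": [1]}, index=["T1"])
        deg = pd.DataFrame({"E": [0]}, index=["T1"])
        assert len(score_tumor("T1", sga, deg)) == 0

    def test_posterior_ratios_follow_likelihood_ratios(self, rng):
        # with equal priors, posterior_i / posterior_j = exp(log_ml_i - log_ml_j)
        from .conftest import random_binary_cohort

        sga, deg = random_binary_cohort(rng)
        t = sga.index[int(np.argmax(sga.sum(axis=1) >= 2))]
        table = score_tumor(t, sga, deg, full=True)
        for _, grp in table.groupby("effect"):
            p = grp["posterior"].to_numpy()
            lml = grp["log_ml"].to_numpy()
            ratio = np.log(p[1:] / p[0])
            assert np.allclose(ratio, lml[1:] - lml[0], atol=1e-9)


class TestScoreCohort:
    def test_posteriors_normalize_per_effect(self, rng):
        from .conftest import random_binary_cohort

        sga, deg = random_binary_cohort(rng, n_tumors=60)
        res = TumorCausalModel(sga, deg).fit()
        for t in sga.index[:10]:
            table = res.candidate_table(t)
            if len(table) == 0:
                continue
            sums = table.groupby("effect")["posterior"].sum()
            assert np.allclose(sums, 1.0, atol=1e-10)

    def test_matches_naive_exact_enumeration(self, rng):
        from .conftest import random_binary_cohort

        for trial in range(3):
            sga, deg = random_binary_cohort(rng, n_tumors=25, n_sga=5, n_deg=5)
            model = TumorCausalModel(sga, deg)
            res = model.fit()
            for t_idx, t in enumerate(sga.index):
                want = naive_tumor_posteriors(sga.values.tolist(),
                                              deg.values.tolist(), t_idx)
                table = res.candidate_table(t)
                for e_idx, posts in want.items():
                    effect = deg.columns[e_idx]
                    sub = table[table["effect"] == effect]
                    for _, row in sub.iterrows():
                        cause = row["cause"]
                        key = "A0" if cause == A0 else sga.columns.get_loc(cause)
                        assert row["posterior"] == pytest.approx(
                            float(posts[key]), rel=1e-8)

    def test_tumor_order_invariance(self, rng):
        from .conftest import random_binary_cohort

        sga, deg = random_binary_cohort(rng, n_tumors=30)
        res1 = TumorCausalModel(sga, deg).fit()
        perm = rng.permutation(len(sga))
        res2 = TumorCausalModel(sga.iloc[perm], deg.iloc[perm]).fit()
        key = ["tumor_id", "effect"]
        a = res1.arcs.sort_values(key, ignore_index=True)
        b = res2.arcs.sort_values(key, ignore_index=True)
        pd.testing.assert_frame_equal(a, b)

    def test_perfect_cooccurrence_wins_everywhere(self, rng):
        n = 50
        tumors = [f"T{i}" for i in range(n)]
        a_col = (rng.random(n) < 0.4).astype(int)
        sga = pd.DataFrame({
            "CAUSE": a_col,
            "OTHER1": (rng.random(n) < 0.3).astype(int),
            "OTHER2": (rng.random(n) < 0.3).astype(int),
        }, index=tumors)
        deg = pd.DataFrame({"E": a_col}, index=tumors)  # DEG iff CAUSE altered
        res = TumorCausalModel(sga, deg).fit()
        hosting = res.arcs[res.arcs["tumor_id"].isin(np.array(tumors)[a_col == 1])]
        assert (hosting["cause"] == "CAUSE").all()
        assert (hosting["edge_p"] <= 0.05).all()

    def test_disjoint_tumor_sets_rejected(self):
        sga = pd.DataFrame({"G": [1]}, index=["T1"])
        deg = pd.DataFrame({"E": [1]}, index=["T2"])
        with pytest.raises(ValueError, match="tumor set"):
            TumorCausalModel(sga, deg)

    def test_contingency_counts_match_crosstab(self, rng):
        from tcistate.tci import _pair_log_ml
        from .conftest import random_binary_cohort

        sga, deg = random_binary_cohort(rng, n_tumors=35, n_sga=3, n_deg=3)
        lml = _pair_log_ml(sga.values, deg.values, alpha=1.0)
        for i, s in enumerate(sga.columns):
            for j, e in enumerate(deg.columns):
                tab = pd.crosstab(sga[s], deg[e]).reindex(
                    index=[0, 1], columns=[0, 1], fill_value=0).values
                assert lml[i, j] == pytest.approx(
                    log_marginal_likelihood(tab, 1.0), rel=1e-12)

    def test_permutation_pvalues_monotone_in_posterior(self, rng):
        from .conftest import random_binary_cohort

        sga, deg = random_binary_cohort(rng, n_tumors=40)
        res = TumorCausalModel(sga, deg).fit(pvalue_mode="permutation",
                                             permutations=5, seed=3)
        arcs = res.arcs[res.arcs["cause"] != A0].sort_values("posterior")
        assert (arcs["edge_p"].diff().dropna() <= 1e-12).all()
        assert arcs["edge_p"].between(0, 1).all()


def test_frequency_prior_weights_by_cohort_frequency(rng):
    from .conftest import random_binary_cohort

    sga, deg = random_binary_cohort(rng, n_tumors=50)
    model = TumorCausalModel(sga, deg, prior="frequency", a0_mass=0.25)
    res = model.fit()
    t = sga.index[int(np.argmax(sga.sum(axis=1) >= 2))]
    table = res.candidate_table(t)
    a0_prior = table.loc[table["cause"] == A0, "prior"].iloc[0]
    assert a0_prior == pytest.approx(0.25)
    sums = table.groupby("effect")["prior"].sum()
    assert np.allclose(sums, 1.0)
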