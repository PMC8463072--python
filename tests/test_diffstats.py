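"""Moderated-t model, Storey q-values, Welch test and significance rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from tmtruler import (
    FoldChangeDistribution,
    ModerationPrior,
    ModeratedTTest,
    classify_significance,
    exclusive_proteins,
    fit_moderation_prior,
    log_transform,
    select_enrichment_candidates,
    storey_qvalues,
    welch_t,
)


def oracle_moderated_t(a, b, d0, s0_sq):
    """Step-by-step scalar implementation of the moderated t for one gene."""
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    df = na + nb - 2
    ss = sum((x - ma) ** 2 for x in a) + sum((x - mb) ** 2 for x in b)
    s2 = ss / df
    if np.isinf(d0):  # fully moderated limit: fixed variance, normal reference
        s2_post = s0_sq
        t = (ma - mb) / np.sqrt(s2_post * (1 / na + 1 / nb))
        return t, 2 * stats.norm.sf(abs(t))
    s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
    t = (ma - mb) / np.sqrt(s2_post * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(abs(t), d0 + df)
    return t, p


class TestLogTransform:
    def test_values_and_errors(self):
        df = pd.DataFrame([[0.0, 3.0]], index=["g"], columns=["a", "b"])
        out = log_transform(df, pseudocount=1.0)
        assert out.loc["g", "a"] == 0.0
        assert out.loc["g", "b"] == 2.0
        with pytest.raises(ValueError, match="negative"):
            log_transform(pd.DataFrame([[-1.0]]))
        with pytest.raises(ValueError, match="pseudocount"):
            log_transform(df, pseudocount=-1)


class TestModerationPrior:
    def test_equal_variances_give_infinite_d0(self):
        prior = fit_moderation_prior(np.full(100, 2.5), residual_df=4)
        assert np.isinf(prior.d0)
        # s0^2 is the (geometric-moment) common value, bias-corrected for df
        assert prior.s0_sq == pytest.approx(
            2.5 * np.exp(-special.digamma(2.0) + np.log(2.0)), rel=1e-12
        )

    def test_parameter_recovery_from_scaled_f(self):
        """s^2 ~ s0^2 F(d, d0) with d0=4, s0^2=1: recover d0 +-25%, s0^2 +-10%."""
        rng = np.random.default_rng(2024)
        d, d0, s0_sq = 4, 4.0, 1.0
        s2 = s0_sq * rng.f(d, d0, size=5000)
        prior = fit_moderation_prior(s2, residual_df=d)
        assert prior.d0 == pytest.approx(d0, rel=0.25)
        assert prior.s0_sq == pytest.approx(s0_sq, rel=0.10)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="zero"):
            fit_moderation_prior(np.zeros(50), residual_df=4)
        with pytest.raises(ValueError, match=">= 10"):
            fit_moderation_prior(np.array([1.0, 2.0]), residual_df=4)


class TestModeratedT:
    @pytest.fixture
    def random_matrix(self):
        # heterogeneous per-gene variances so the estimated prior d0 is finite
        rng = np.random.default_rng(77)
        sd = np.exp(rng.normal(0.0, 0.7, size=50))
        data = rng.normal(8.0, 1.0, size=(50, 7)) * sd[:, None]
        return pd.DataFrame(
            data,
            index=[f"g{i}" for i in range(50)],
            columns=[f"A_r{j}" for j in range(1, 4)] + [f"B_r{j}" for j in range(1, 5)],
        )

    def test_matches_stepwise_oracle(self, random_matrix):
        """t and p equal an independent per-gene computation (rel err < 1e-10)."""
        a_cols = ["A_r1", "A_r2", "A_r3"]
        b_cols = ["B_r1", "B_r2", "B_r3", "B_r4"]
        res = ModeratedTTest(random_matrix, a_cols, b_cols).fit()
        d0, s0 = res.prior.d0, res.prior.s0_sq
        for gid in random_matrix.index:
            t, p = oracle_moderated_t(
                list(random_matrix.loc[gid, a_cols]), list(random_matrix.loc[gid, b_cols]),
                d0, s0,
            )
            assert res.table.loc[gid, "t"] == pytest.approx(t, rel=1e-10)
            assert res.table.loc[gid, "p_value"] == pytest.approx(p, rel=1e-10)

    def test_d0_zero_is_ordinary_pooled_t(self, random_matrix):
        a_cols = ["A_r1", "A_r2", "A_r3"]
        b_cols = ["B_r1", "B_r2", "B_r3", "B_r4"]
        prior = ModerationPrior(d0=0.0, s0_sq=1.0, residual_df=5)
        res = ModeratedTTest(random_matrix, a_cols, b_cols, prior=prior).fit()
        ref = stats.ttest_ind(
            random_matrix[a_cols], random_matrix[b_cols], axis=1, equal_var=True
        )
        np.testing.assert_allclose(res.table["t"], ref.statistic, rtol=1e-10)
        np.testing.assert_allclose(res.table["p_value"], ref.pvalue, rtol=1e-10)

    def test_zero_fold_change_gives_p_one(self):
        data = pd.DataFrame(
            [[1.0, 2.0, 1.0, 2.0], [3.0, 5.0, 4.0, 4.0]],
            index=["flat", "noisy"],
            columns=["A_r1", "A_r2", "B_r1", "B_r2"],
        )
        res = ModeratedTTest(data, ["A_r1", "A_r2"], ["B_r1", "B_r2"]).fit()
        assert res.table.loc["flat", "t"] == 0.0
        assert res.table.loc["flat", "p_value"] == 1.0

    def test_posterior_variance_between_prior_and_sample(self, random_matrix):
        """Moderation interpolates: s~^2 lies between min(s^2, s0^2) and max."""
        res = ModeratedTTest(random_matrix, ["A_r1", "A_r2", "A_r3"],
                             ["B_r1", "B_r2", "B_r3", "B_r4"]).fit()
        s2 = res.table["s2"].to_numpy()
        post = res.table["s2_post"].to_numpy()
        lo = np.minimum(s2, res.prior.s0_sq)
        hi = np.maximum(s2, res.prior.s0_sq)
        assert np.all(post >= lo - 1e-12) and np.all(post <= hi + 1e-12)

    def test_overlapping_groups_rejected(self, random_matrix):
        with pytest.raises(ValueError, match="overlap"):
            ModeratedTTest(random_matrix, ["A_r1", "A_r2"], ["A_r2", "B_r1"])
        with pytest.raises(ValueError, match=">= 2"):
            ModeratedTTest(random_matrix, ["A_r1"], ["B_r1", "B_r2"])

    def test_summary_mentions_prior(self, random_matrix):
        res = ModeratedTTest(random_matrix, ["A_r1", "A_r2", "A_r3"],
                             ["B_r1", "B_r2", "B_r3", "B_r4"]).fit()
        text = res.summary()
        assert "prior d0" in text and "proteins tested" in text


class TestStoreyQ:
    def test_all_p_one(self):
        np.testing.assert_allclose(storey_qvalues(np.ones(30)), np.ones(30))

    def test_pi0_one_reduces_to_bh(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = rng.uniform(size=40)
        q = storey_qvalues(p, lambda_grid=None, min_for_estimation=10**9)  # force pi0=1
        bh = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q, bh, rtol=1e-12)

    def test_fixed_lambda_matches_hand_stepped_oracle(self):
        """pi0 = #{p > 0.5} / (m/2); q_i = min_{p_j >= p_i} pi0 m p_j / rank."""
        rng = np.random.default_rng(11)
        p = np.concatenate([[0.001, 0.01, 0.02, 0.8, 0.9], rng.uniform(size=20)])
        m = p.size
        pi0 = min((p > 0.5).sum() / (m * 0.5), 1.0)
        order = np.argsort(p)
        expected = np.empty(m)
        for i in range(m):
            cands = [
                pi0 * m * p[order[j]] / (j + 1) for j in range(m) if p[order[j]] >= p[order[i]]
            ]
            expected[order[i]] = min(1.0, min(cands))
        q = storey_qvalues(p, lambda_grid=[0.5])
        np.testing.assert_allclose(q, expected, rtol=1e-12)

    def test_monotone_in_p_and_bounded(self):
        rng = np.random.default_rng(8)
        p = np.concatenate([rng.uniform(size=200) ** 3, rng.uniform(size=300)])
        q = storey_qvalues(p)
        assert np.all((q >= 0) & (q <= 1))
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="empty"):
            storey_qvalues([])
        with pytest.raises(ValueError, match="lie in"):
            storey_qvalues([0.5, 1.5])


class TestWelch:
    def test_identical_groups(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_hand_stepped_example(self):
        a, b = [1.0, 2.0, 3.0], [1.0, 2.0, 3.0, 4.0, 5.0]
        va, vb = 1.0, 2.5
        se = np.sqrt(va / 3 + vb / 5)
        t_exp = (2.0 - 3.0) / se
        df_exp = (va / 3 + vb / 5) ** 2 / ((va / 3) ** 2 / 2 + (vb / 5) ** 2 / 4)
        p_exp = 2 * stats.t.sf(abs(t_exp), df_exp)
        t, df, p = welch_t(a, b)
        assert t == pytest.approx(t_exp, rel=1e-12)
        assert df == pytest.approx(df_exp, rel=1e-12)
        assert p == pytest.approx(p_exp, rel=1e-9)

    def test_antisymmetry(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=5), rng.normal(1.0, 1.0, size=6)
        t1, _, p1 = welch_t(a, b)
        t2, _, p2 = welch_t(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_too_few_values(self):
        with pytest.raises(ValueError, match=">= 2"):
            welch_t([1.0], [1.0, 2.0])


class TestSignificanceRules:
    dist = FoldChangeDistribution(median=0.2, sd=0.5)

    @pytest.mark.parametrize(
        "p, fc_offset_sd, expected",
        [
            (5e-4, 1.2, "**"),
            (5e-5, -1.6, "***"),
            (1e-2, 3.0, "ns"),       # fails both p gates
            (5e-4, 0.5, "ns"),       # inside 1 sd
            (5e-5, 1.2, "**"),       # p passes *** but fold change only 1 sd
            (5e-4, -1.2, "**"),      # symmetric downward
        ],
    )
    def test_star_rules(self, p, fc_offset_sd, expected):
        fc = self.dist.median + fc_offset_sd * self.dist.sd
        star = classify_significance([fc], [p], self.dist)
        assert star[0] == expected

    def test_zero_sd_suppresses_stars(self, caplog):
        with caplog.at_level("WARNING"):
            star = classify_significance([10.0], [1e-10], FoldChangeDistribution(0.0, 0.0))
        assert star[0] == "ns"

    def test_candidate_selection(self):
        results = pd.DataFrame(
            {
                "log2fc": [self.dist.median + 2 * self.dist.sd,
                           self.dist.median,
                           self.dist.median - 1.6 * self.dist.sd,
                           self.dist.median + 2 * self.dist.sd],
                "p_value": [1e-4, 1e-4, 5e-4, 0.5],
            },
            index=["up_hit", "centre", "down_hit", "not_sig"],
        )
        up, down = select_enrichment_candidates(results, self.dist)
        assert up == {"up_hit"}
        assert down == {"down_hit"}
        assert not up & down


class TestExclusive:
    def test_partition(self):
        vals = pd.DataFrame(
            {
                "A_r1": [5.0, 0.0, 1.0, 0.0],
                "A_r2": [3.0, 0.0, 2.0, 0.0],
                "B_r1": [0.0, 4.0, 3.0, 0.0],
                "B_r2": [0.0, 6.0, 1.0, 0.0],
            },
            index=["onlyA", "onlyB", "both", "neither"],
        )
        only_a, only_b = exclusive_proteins(vals, ["A_r1", "A_r2"], ["B_r1", "B_r2"])
        assert only_a == {"onlyA"}
        assert only_b == {"onlyB"}
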