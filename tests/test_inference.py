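"""Study-level statistics against independent oracles.

The RM-ANOVA is checked against an explicit design-matrix GLM oracle
and pingouin; the sign-flip omnibus against exhaustive enumeration; the
BH step-up against its brute-force definition and statsmodels.
"""

import numpy as np
import pytest

from oscillomap.inference import (
    FeaturePanel,
    bh_fdr,
    paired_t,
    permutation_posthoc_family,
    permutation_posthoc_omnibus,
    rm_anova_per_feature,
    spatial_correlation_test,
)
from oscillomap.synth import ReceptorTemplate


def _panel(values, feature_ids=None):
    n, D, S, F = values.shape
    return FeaturePanel(
        values=values,
        feature_ids=feature_ids or [f"f{i}" for i in range(F)],
        subjects=[f"s{i}" for i in range(n)],
        drugs=["active", "placebo"][:D],
        sessions=["pre", "post1", "post2", "post3"][:S],
    )


def _glm_rm_anova_oracle(y):
    """Two-way within-subject ANOVA for one feature via explicit
    projection onto effect subspaces; y has shape (n, D, S)."""
    n, D, S = y.shape
    m = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_d = y.mean(axis=(0, 2))
    m_t = y.mean(axis=(0, 1))
    m_sd = y.mean(axis=2)
    m_st = y.mean(axis=1)
    m_dt = y.mean(axis=0)
    ss_d = n * S * np.sum((m_d - m) ** 2)
    ss_sd = S * np.sum((m_sd - m_s[:, None] - m_d[None, :] + m) ** 2)
    ss_t = n * D * np.sum((m_t - m) ** 2)
    ss_st = D * np.sum((m_st - m_s[:, None] - m_t[None, :] + m) ** 2)
    ss_dt = n * np.sum((m_dt - m_d[:, None] - m_t[None, :] + m) ** 2)
    resid = (
        y - m_sd[:, :, None] - m_st[:, None, :] - m_dt[None, :, :]
        + m_s[:, None, None] + m_d[None, :, None] + m_t[None, None, :] - m
    )
    ss_r = np.sum(resid**2)
    F_d = (ss_d / (D - 1)) / (ss_sd / ((D - 1) * (n - 1)))
    F_t = (ss_t / (S - 1)) / (ss_st / ((S - 1) * (n - 1)))
    F_i = (ss_dt / ((D - 1) * (S - 1))) / (ss_r / ((D - 1) * (S - 1) * (n - 1)))
    return F_d, F_t, F_i


class TestRmAnova:
    def test_zero_condition_variance_gives_zero_f(self):
        rng = np.random.default_rng(0)
        subj = rng.standard_normal((6, 1, 1, 3))
        values = np.broadcast_to(subj, (6, 2, 4, 3)).copy()
        res = rm_anova_per_feature(_panel(values))
        np.testing.assert_allclose(res.F_drug, 0.0)
        np.testing.assert_allclose(res.F_session, 0.0)
        np.testing.assert_allclose(res.F_interaction, 0.0)

    def test_matches_glm_projection_oracle(self):
        rng = np.random.default_rng(1)
        values = rng.standard_normal((6, 2, 4, 4))
        res = rm_anova_per_feature(_panel(values))
        assert res.df_drug == (1, 5)
        assert res.df_session == (3, 15)
        assert res.df_interaction == (3, 15)
        for f in range(4):
            F_d, F_t, F_i = _glm_rm_anova_oracle(values[:, :, :, f])
            assert res.F_drug[f] == pytest.approx(F_d, abs=1e-8)
            assert res.F_session[f] == pytest.approx(F_t, abs=1e-8)
            assert res.F_interaction[f] == pytest.approx(F_i, abs=1e-8)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(2)
        values = rng.standard_normal((8, 2, 4, 1))
        res = rm_anova_per_feature(_panel(values))
        rows = []
        for si in range(8):
            for di, d in enumerate(["active", "placebo"]):
                for ti, t in enumerate(["pre", "post1", "post2", "post3"]):
                    rows.append(dict(subject=si, drug=d, session=t,
                                     y=values[si, di, ti, 0]))
        df = pd.DataFrame(rows)
        aov = pg.rm_anova(
            data=df, dv="y", within=["drug", "session"], subject="subject",
            detailed=True,
        )
        by = {r["Source"]: r["F"] for _, r in aov.iterrows()}
        assert res.F_drug[0] == pytest.approx(by["drug"], rel=1e-6)
        assert res.F_session[0] == pytest.approx(by["session"], rel=1e-6)
        assert res.F_interaction[0] == pytest.approx(by["drug * session"], rel=1e-6)

    def test_pure_interaction_pattern_dominates(self):
        rng = np.random.default_rng(3)
        values = 0.1 * rng.standard_normal((8, 2, 4, 1))
        values[:, 0, 1:, 0] += 2.0   # active post sessions shifted, placebo flat
        res = rm_anova_per_feature(_panel(values))
        # the shift loads on drug, session AND interaction; interaction must
        # be decisively nonzero and its p the smallest or comparable
        assert res.F_interaction[0] > 10
        assert res.p_interaction[0] < 1e-4

    def test_incomplete_panel_rejected(self):
        rng = np.random.default_rng(4)
        values = rng.standard_normal((4, 2, 4, 2))
        values[1, 0, 2, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            _panel(values)

    def test_too_few_subjects_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError, match="3 subjects"):
            _panel(rng.standard_normal((2, 2, 4, 1)))


class TestPairedT:
    def test_formula(self):
        a = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        b = np.zeros(6)
        d = a - b
        expected = d.mean() / (d.std(ddof=1) / np.sqrt(6))
        assert paired_t(a, b) == pytest.approx(expected, abs=1e-12)
        from scipy import stats

        assert paired_t(a, b) == pytest.approx(stats.ttest_rel(a, b).statistic)

    def test_antisymmetry(self):
        rng = np.random.default_rng(6)
        a, b = rng.standard_normal((2, 10))
        assert paired_t(a, b) == pytest.approx(-paired_t(b, a))

    def test_degenerate_differences_rejected(self):
        a = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="zero-variance"):
            paired_t(a, a)
        with pytest.raises(ValueError, match="zero-variance"):
            paired_t(a + 1.0, a)


def _exhaustive_signflip_p(diffs):
    """Corrected p per feature by full enumeration of all 2^n sign flips."""
    n, F = diffs.shape
    ssq = np.sum(diffs**2, axis=0)

    def tstat(d):
        m = d.mean(axis=0)
        v = (ssq - n * m**2) / (n - 1)
        return m / np.sqrt(v / n)

    t_obs = np.abs(tstat(diffs))
    count = np.zeros(F)
    total = 0
    for code in range(2**n):
        signs = np.array([1.0 if code >> i & 1 else -1.0 for i in range(n)])
        t = np.max(np.abs(tstat(diffs * signs[:, None])))
        count += t >= t_obs
        total += 1
    return count / total


class TestPermutationOmnibus:
    def _diff_panel(self, diffs):
        n, F = diffs.shape
        values = np.zeros((n, 2, 2, F))
        values[:, 0, 1, :] = diffs
        values[:, 0, 0, :] = 0.0
        values[:, 1, :, :] = np.random.default_rng(99).standard_normal((n, 2, F))
        return FeaturePanel(
            values=values,
            feature_ids=[f"f{i}" for i in range(F)],
            subjects=[f"s{i}" for i in range(n)],
            drugs=["active", "placebo"],
            sessions=["pre", "post1"],
        )

    def test_pvalues_valid_and_ordered(self):
        rng = np.random.default_rng(7)
        panel = self._diff_panel(rng.standard_normal((8, 5)) + [2, 0, 0, 0, 0])
        res = permutation_posthoc_omnibus(panel, "active", "post1", n_perm=500, seed=1)
        assert np.all(res.p_corrected >= res.p_uncorrected)
        assert np.all(res.p_corrected >= 1 / 501)
        assert np.all(res.p_corrected <= 1.0)
        # p monotone decreasing in |t|
        order = np.argsort(-np.abs(res.t))
        assert np.all(np.diff(res.p_corrected[order]) >= 0)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(8)
        diffs = rng.standard_normal((8, 4)) + np.array([1.5, 0.5, 0.0, -1.0])
        panel = self._diff_panel(diffs)
        res = permutation_posthoc_omnibus(
            panel, "active", "post1", n_perm=20000, seed=2
        )
        exact = _exhaustive_signflip_p(diffs)
        np.testing.assert_allclose(res.p_corrected, exact, atol=0.01)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        panel = self._diff_panel(rng.standard_normal((6, 3)))
        a = permutation_posthoc_omnibus(panel, "active", "post1", n_perm=200, seed=3)
        b = permutation_posthoc_omnibus(panel, "active", "post1", n_perm=200, seed=3)
        np.testing.assert_array_equal(a.p_corrected, b.p_corrected)

    def test_degenerate_feature_excluded_with_warning(self):
        rng = np.random.default_rng(10)
        diffs = rng.standard_normal((6, 3))
        diffs[:, 1] = 2.0  # constant difference -> zero variance
        panel = self._diff_panel(diffs)
        with pytest.warns(UserWarning, match="degenerate"):
            res = permutation_posthoc_omnibus(panel, "active", "post1", n_perm=100, seed=4)
        assert res.excluded == ["f1"]
        assert len(res.feature_ids) == 2

    def test_family_reduces_to_single_contrast(self):
        rng = np.random.default_rng(11)
        panel = self._diff_panel(rng.standard_normal((7, 4)))
        single = permutation_posthoc_omnibus(panel, "active", "post1", n_perm=300, seed=5)
        fam = permutation_posthoc_family(panel, [("active", "post1")], n_perm=300, seed=5)
        res = fam[("active", "post1")]
        np.testing.assert_allclose(res.t, single.t)
        np.testing.assert_array_equal(res.p_corrected, single.p_corrected)

    def test_family_correction_is_stricter(self):
        rng = np.random.default_rng(12)
        values = rng.standard_normal((8, 2, 4, 6))
        panel = _panel(values)
        single = permutation_posthoc_omnibus(panel, "active", "post1", n_perm=400, seed=6)
        fam = permutation_posthoc_family(
            panel,
            [(d, s) for d in ("active", "placebo") for s in ("post1", "post2", "post3")],
            n_perm=400, seed=6,
        )
        assert np.all(
            fam[("active", "post1")].p_corrected >= single.p_corrected - 1e-12
        )


class TestBhFdr:
    def test_stepup_by_hand(self):
        p = np.array([0.01, 0.02, 0.03, 0.04, 0.05])
        reject, adj = bh_fdr(p, 0.05)
        assert reject.all()  # p_(5)=0.05 <= 5*0.05/5

    def test_all_ones_none_rejected(self):
        reject, adj = bh_fdr(np.ones(10), 0.05)
        assert not reject.any()
        np.testing.assert_allclose(adj, 1.0)

    def test_matches_bruteforce_definition_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(1000):
            m = rng.integers(1, 30)
            p = rng.random(m)
            reject, adj = bh_fdr(p, 0.05)
            order = np.argsort(p)
            k = 0
            for i, idx in enumerate(order, start=1):
                if p[idx] <= i * 0.05 / m:
                    k = i
            expected = np.zeros(m, dtype=bool)
            expected[order[:k]] = True
            np.testing.assert_array_equal(reject, expected)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(14)
        for _ in range(20):
            p = rng.random(50)
            reject, adj = bh_fdr(p, 0.05)
            r2, a2, *_ = sm.multipletests(p, alpha=0.05, method="fdr_bh")
            np.testing.assert_array_equal(reject, r2)
            np.testing.assert_allclose(adj, a2, atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.1, 1.2]), 0.05)


class TestSpatialCorrelation:
    def test_template_equals_map(self):
        rng = np.random.default_rng(15)
        v = np.abs(rng.standard_normal(30)) + 0.1
        tpl = ReceptorTemplate(node_values=v, target_rho=1.0)
        res = spatial_correlation_test({"post1": v}, tpl, n_perm=99, seed=0)
        assert res[0].r == pytest.approx(1.0)
        assert res[0].p_corrected == pytest.approx(1 / 100)

    def test_independent_map_mostly_null(self):
        rng = np.random.default_rng(16)
        tpl = ReceptorTemplate(node_values=np.abs(rng.standard_normal(90)) + 1, target_rho=0.0)
        ok = 0
        for s in range(20):
            m = np.abs(np.random.default_rng(1000 + s).standard_normal(90))
            res = spatial_correlation_test({"m": m}, tpl, n_perm=200, seed=s)
            ok += (abs(res[0].r) < 0.3) and (res[0].p_corrected > 0.05)
        assert ok >= 18

    def test_family_correction_uses_max_r(self):
        rng = np.random.default_rng(17)
        tpl_v = np.abs(rng.standard_normal(40)) + 0.5
        tpl = ReceptorTemplate(node_values=tpl_v, target_rho=0.0)
        fam = {
            "a": tpl_v + 0.05 * rng.standard_normal(40),
            "b": np.abs(rng.standard_normal(40)),
        }
        res = {r.name: r for r in spatial_correlation_test(fam, tpl, n_perm=500, seed=3)}
        assert res["a"].r > 0.9
        assert res["a"].p_corrected < 0.05
        assert res["b"].p_corrected > res["a"].p_corrected

    def test_constant_inputs_rejected(self):
        tpl = ReceptorTemplate(node_values=np.ones(20), target_rho=0.0)
        with pytest.raises(ValueError, match="constant"):
            spatial_correlation_test({"m": np.arange(20.0)}, tpl, n_perm=10, seed=0)

    def test_node_permutation_null_inflated_by_spatial_smoothness(self):
        """The node-shuffle null assumes exchangeable nodes; on spatially
        smoothed (autocorrelated) maps the test over-rejects, while on
        white maps it stays near the nominal level.  This is a known
        limitation of naive map-vs-map correlation inference, shown here
        rather than fixed."""
        from oscillomap.evaluate import smoothed_map_null_inflation

        rates = smoothed_map_null_inflation(n_pairs=100, n_perm=300, seed=3)
        assert rates["white"] < 0.12
        assert rates["smoothed"] > 2 * rates["white"]
        assert rates["smoothed"] > 0.2
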