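"""Mixed ANOVA vs independent oracles; pairwise tests; Spearman; Bonferroni."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

import stoptask as st
from stoptask.group_stats import _spearman_exact_p


# ---------------------------------------------------------------------------
# brute-force projection oracle: sums of squares as residual-SS differences
# between nested OLS fits on dummy design matrices
# ---------------------------------------------------------------------------

def _dummies(df, cols):
    if not cols:
        return np.ones((len(df), 1))
    key = df[list(cols)].astype(str).agg("|".join, axis=1)
    return pd.get_dummies(key).to_numpy(float)


def _rss(y, X):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def oracle_split_plot(df, dv, within, between, subject):
    """Split-plot SS via nested-model residual comparisons (balanced data).

    Each effect's SS = RSS(model with all sub-margins) - RSS(+ effect margin).
    """
    y = df[dv].to_numpy(float)

    def ss_between(margin, sub_margins):
        Xs = np.hstack([_dummies(df, m) for m in sub_margins])
        Xm = np.hstack([Xs, _dummies(df, margin)])
        return _rss(y, Xs) - _rss(y, Xm)

    out = {}
    out[between] = ss_between((between,), [()])
    out["subject"] = ss_between((subject,), [(between,)])
    for r in range(1, len(within) + 1):
        for eff in itertools.combinations(within, r):
            subs = [sub for k in range(r) for sub in itertools.combinations(eff, k)]
            out[" * ".join(eff)] = ss_between(eff, subs or [()])
            # interaction with group: margin eff+G minus eff and G margins
            subs_g = subs + [eff] + [sub + (between,) for sub in subs]
            out[" * ".join(eff) + f" * {between}"] = ss_between(
                eff + (between,), subs_g)
            # error: eff x subject margin minus everything it contains
            subs_s = (subs + [eff] + [sub + (between,) for sub in subs]
                      + [eff + (between,)]
                      + [sub + (subject,) for sub in subs] + [(subject,)])
            out[" * ".join(eff) + " * subject"] = ss_between(
                eff + (subject,), subs_s)
    return out


def _toy_data(seed=0, n_per_group=3, n_ctx=4, n_stim=2):
    rng = np.random.default_rng(seed)
    rows = []
    for grp in ["control", "gambler"]:
        for s in range(n_per_group):
            sid = f"{grp}{s}"
            subj_eff = rng.normal(0, 20)
            for c in range(n_ctx):
                for t in range(n_stim):
                    rows.append(dict(
                        subject_id=sid, group=grp, context=f"c{c}",
                        stimulus_type=f"s{t}",
                        y=rng.normal(500 + 30 * c + 10 * t
                                     + 15 * (grp == "gambler") + subj_eff, 25),
                    ))
    return pd.DataFrame(rows)


class TestMixedAnovaOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_projection_oracle(self, seed):
        df = _toy_data(seed)
        tab = st.mixed_rm_anova(df, "y", ["context", "stimulus_type"], "group")
        oracle = oracle_split_plot(df, "y", ("context", "stimulus_type"),
                                   "group", "subject_id")
        for eff in ["context", "stimulus_type", "context * stimulus_type"]:
            assert tab.loc[eff, "ss"] == pytest.approx(oracle[eff], rel=1e-10)
            assert tab.loc[f"{eff} * group", "ss"] == pytest.approx(
                oracle[f"{eff} * group"], rel=1e-10)
            # F against the oracle's own SS ratio, at oracle error terms
            f_oracle = (oracle[eff] / tab.loc[eff, "df1"]) / (
                oracle[f"{eff} * subject"] / tab.loc[eff, "df2"])
            assert tab.loc[eff, "F"] == pytest.approx(f_oracle, rel=1e-10)
        assert tab.loc["group", "ss"] == pytest.approx(oracle["group"], rel=1e-10)
        f_group = (oracle["group"] / tab.loc["group", "df1"]) / (
            oracle["subject"] / tab.loc["group", "df2"])
        assert tab.loc["group", "F"] == pytest.approx(f_group, rel=1e-10)

    def test_matches_pingouin_one_within(self):
        pg = pytest.importorskip("pingouin")
        df = _toy_data(3)
        d1 = df.groupby(["subject_id", "group", "context"], as_index=False)["y"].mean()
        mine = st.mixed_rm_anova(d1, "y", ["context"], "group")
        ref = pg.mixed_anova(d1, dv="y", within="context", between="group",
                             subject="subject_id").set_index("Source")
        for eff, key in [("group", "group"), ("context", "context"),
                         ("context * group", "Interaction")]:
            assert mine.loc[eff, "F"] == pytest.approx(ref.loc[key, "F"], rel=1e-9)
            assert mine.loc[eff, "p"] == pytest.approx(ref.loc[key, "p_unc"], rel=1e-9)
            assert mine.loc[eff, "partial_eta_sq"] == pytest.approx(
                ref.loc[key, "np2"], rel=1e-6)

    def test_matches_statsmodels_within_only(self):
        smanova = pytest.importorskip("statsmodels.stats.anova")
        df = _toy_data(4)
        d1 = df.groupby(["subject_id", "context"], as_index=False)["y"].mean()
        mine = st.mixed_rm_anova(d1, "y", ["context"], between=None)
        ref = smanova.AnovaRM(d1, "y", "subject_id", within=["context"]).fit()
        row = ref.anova_table.loc["context"]
        assert mine.loc["context", "F"] == pytest.approx(row["F Value"], rel=1e-9)
        assert mine.loc["context", "df1"] == row["Num DF"]
        assert mine.loc["context", "df2"] == row["Den DF"]

    def test_location_invariance(self):
        df = _toy_data(5)
        t1 = st.mixed_rm_anova(df, "y", ["context", "stimulus_type"], "group")
        df2 = df.assign(y=df.y + 1234.5)
        t2 = st.mixed_rm_anova(df2, "y", ["context", "stimulus_type"], "group")
        pd.testing.assert_frame_equal(t1, t2)

    def test_partial_eta_sq_definition_and_bounds(self):
        df = _toy_data(6)
        tab = st.mixed_rm_anova(df, "y", ["context", "stimulus_type"], "group")
        assert ((tab.partial_eta_sq >= 0) & (tab.partial_eta_sq <= 1)).all()
        assert (tab.F >= 0).all()

    def test_unbalanced_raises(self):
        df = _toy_data(0).iloc[:-1]
        with pytest.raises(ValueError, match="balanced|missing"):
            st.mixed_rm_anova(df, "y", ["context", "stimulus_type"], "group")

    def test_too_few_subjects_raises(self):
        df = _toy_data(0, n_per_group=1)
        with pytest.raises(ValueError, match="2 subjects"):
            st.mixed_rm_anova(df, "y", ["context", "stimulus_type"], "group")

    def test_gg_epsilon_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        df = _toy_data(7)
        d1 = df.groupby(["subject_id", "context"], as_index=False)["y"].mean()
        mine = st.MixedAnova(d1, "y", ["context"]).fit(gg_correction=True)
        eps_ref = pg.epsilon(d1, dv="y", within="context", subject="subject_id",
                             correction="gg")
        assert mine.anova_table.loc["context", "gg_eps"] == pytest.approx(
            float(eps_ref), rel=1e-6)


class TestPairwise:
    def test_noiseless_ordering(self):
        means = pd.DataFrame({
            "green": [800.0, 810], "yellow": [850.0, 860],
            "orange": [875.0, 885], "red": [900.0, 910],
        })
        out = st.pairwise_context_tests(means)
        assert len(out) == 6
        assert out.attrs["ordering"] == "red > orange > yellow > green"

    def test_identical_contexts_null(self):
        means = pd.DataFrame({"a": [1.0, 2, 3], "b": [1.0, 2, 3]})
        out = st.pairwise_context_tests(means)
        assert out.t.iloc[0] == 0.0 and out.p_bonferroni.iloc[0] == 1.0

    def test_single_subject_raises(self):
        with pytest.raises(ValueError, match="2 subjects"):
            st.pairwise_context_tests(pd.DataFrame({"a": [1.0], "b": [2.0]}))


class TestSpearman:
    def test_perfect_monotone(self):
        r = st.spearman([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert r.rho == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # Sum d^2 = 4 -> rho = 1 - 24/120 = 0.8; exact two-sided p = 16/120
        r = st.spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert r.rho == pytest.approx(0.8)
        assert r.p == pytest.approx(16 / 120)

    def test_antitone(self):
        r = st.spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert r.rho == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        r = st.spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert r.undefined_variance and np.isnan(r.rho)

    def test_t_approximation_for_larger_n(self):
        from scipy import stats
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=30), rng.normal(size=30)
        mine = st.spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert mine.rho == pytest.approx(ref.statistic)
        assert mine.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_exact_p_symmetric_under_sign_flip(self):
        from scipy import stats
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = np.array([2.0, 1, 3, 6, 4, 5])
        rho = stats.spearmanr(x, y).statistic
        p1 = _spearman_exact_p(stats.rankdata(x), stats.rankdata(y), rho)
        p2 = _spearman_exact_p(stats.rankdata(x), stats.rankdata(-y), -rho)
        assert p1 == pytest.approx(p2)


class TestBonferroni:
    def test_examples(self):
        assert list(st.bonferroni([0.01, 0.04])) == [0.02, 0.08]
        assert list(st.bonferroni([0.3])) == [0.3]
        assert list(st.bonferroni([0.7, 0.9])) == [1.0, 1.0]

    @given(hst.lists(hst.floats(0, 1), min_size=1, max_size=10))
    @settings(max_examples=200, deadline=None)
    def test_monotone_and_idempotent_on_capped(self, pvals):
        adj = st.bonferroni(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        assert np.all(adj <= 1.0)
        # idempotent once capped: adjusting m=1 changes nothing
        assert np.allclose(st.bonferroni(adj, m=1), adj)

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            st.bonferroni([1.5])
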