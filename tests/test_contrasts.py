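import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fcgrad.contrasts import (
    Design,
    ancova_group_post,
    association_ols,
    attach_fdr,
    fdr_bh,
    parcelwise_contrast,
    rm_anova_effects,
    run_contrast,
    synergy_rm_anova,
    within_group_ancova,
)


def make_design(drug, placebo, metric="m"):
    """drug/placebo: list of (pre, post) per subject."""
    rows = []
    for g, entries in (("drug", drug), ("placebo", placebo)):
        for i, (pre, post) in enumerate(entries):
            rows.append(dict(subject=f"{g}{i}", group=g, session="pre",
                             metric=metric, value=pre))
            rows.append(dict(subject=f"{g}{i}", group=g, session="post",
                             metric=metric, value=post))
    return Design(pd.DataFrame(rows))


def random_design(rng, n1=6, n2=6):
    return make_design(
        [(rng.normal(), rng.normal()) for _ in range(n1)],
        [(rng.normal(), rng.normal()) for _ in range(n2)],
    )


class TestSynergy:
    def test_no_variance_gives_f_zero_p_one(self):
        d = make_design([(1.0, 1.0)] * 3, [(1.0, 1.0)] * 3)
        r = synergy_rm_anova(d, "m")
        assert r.statistic == 0.0
        assert r.p == 1.0

    def test_hand_example(self):
        # drug diffs (2, 0), placebo diffs (0, -2): t on diffs = sqrt(2)
        d = make_design([(0, 2), (0, 0)], [(0, 0), (0, -2)])
        r = synergy_rm_anova(d, "m")
        assert r.statistic == pytest.approx(2.0)
        assert r.df == (1, 2)

    def test_interaction_f_equals_squared_difference_t(self, rng):
        for _ in range(50):
            d = random_design(rng)
            r = synergy_rm_anova(d, "m")
            wide = d.wide("m")
            a = wide.loc[wide.group == "drug", "post"] - wide.loc[wide.group == "drug", "pre"]
            b = wide.loc[wide.group == "placebo", "post"] - wide.loc[wide.group == "placebo", "pre"]
            t = stats.ttest_ind(a, b).statistic
            assert r.statistic == pytest.approx(t**2, rel=1e-8)

    def test_matches_pingouin_mixed_anova(self, rng):
        pg = pytest.importorskip("pingouin")
        for _ in range(3):
            d = random_design(rng, 8, 8)
            aov = pg.mixed_anova(data=d.table, dv="value", within="session",
                                 subject="subject", between="group")
            ours = rm_anova_effects(d, "m")
            for src, key in (("Interaction", "interaction"),
                             ("group", "group"), ("session", "time")):
                theirs = float(aov.loc[aov.Source == src, "F"].iloc[0])
                assert ours[key].statistic == pytest.approx(theirs, rel=1e-6)

    def test_missing_session_rejected(self):
        rows = [
            dict(subject="a", group="drug", session="pre", metric="m", value=1.0),
            dict(subject="b", group="drug", session="pre", metric="m", value=1.0),
            dict(subject="b", group="drug", session="post", metric="m", value=2.0),
            dict(subject="c", group="placebo", session="pre", metric="m", value=0.0),
            dict(subject="c", group="placebo", session="post", metric="m", value=0.0),
            dict(subject="d", group="placebo", session="pre", metric="m", value=0.0),
            dict(subject="d", group="placebo", session="post", metric="m", value=0.0),
        ]
        with pytest.raises(ValueError, match="missing a session"):
            synergy_rm_anova(Design(pd.DataFrame(rows)), "m")


def normal_equations_ols(x, y):
    """Independent textbook oracle: beta, t-values, residual df."""
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    df = len(y) - x.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    return beta, beta / se, df


class TestAncovaGroupPost:
    def test_post_equals_pre_no_group_signal(self, rng):
        pre = rng.normal(size=8)
        d = make_design(
            [(pre[i], pre[i]) for i in range(4)],
            [(pre[i + 4], pre[i + 4]) for i in range(4)],
        )
        r = ancova_group_post(d, "m")
        assert abs(r.statistic) < 1e-8

    def test_matches_normal_equations_oracle(self, rng):
        d = random_design(rng, 3, 3)
        r = ancova_group_post(d, "m")
        wide = d.wide("m")
        g = (wide["group"] == "drug").astype(float).to_numpy()
        x = np.column_stack([np.ones(6), g, wide["pre"].to_numpy()])
        beta, tvals, df = normal_equations_ols(x, wide["post"].to_numpy())
        assert r.estimate == pytest.approx(beta[1], abs=1e-10)
        assert r.statistic == pytest.approx(tvals[1], abs=1e-10)
        assert r.df == (df,)

    def test_shift_changes_intercept_only(self, rng):
        d1 = random_design(rng, 5, 5)
        shifted = d1.table.copy()
        shifted.loc[shifted.session == "post", "value"] += 10.0
        d2 = Design(shifted)
        r1, r2 = ancova_group_post(d1, "m"), ancova_group_post(d2, "m")
        assert r1.estimate == pytest.approx(r2.estimate, abs=1e-10)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-10)

    def test_constant_pre_rejected(self):
        d = make_design([(1.0, 2.0)] * 4, [(1.0, 1.5)] * 4)
        with pytest.raises(ValueError, match="constant"):
            ancova_group_post(d, "m")


class TestWithinGroupAncova:
    def test_null_change_gives_zero_t(self, rng):
        pre = rng.normal(size=10)
        d = make_design(
            [(pre[i], pre[i]) for i in range(5)],
            [(pre[i + 5], pre[i + 5]) for i in range(5)],
        )
        for group in ("drug", "placebo"):
            r = within_group_ancova(d, "m", group)
            assert abs(r.statistic) < 1e-8

    def test_power_against_planted_uniform_shift(self, rng):
        """delta=0.3, sigma=0.1, n=20 -> reject in >= 95% of 200 sims."""
        rejections = 0
        signs_ok = 0
        for _ in range(200):
            pre = rng.normal(0.0, 0.1, 20)
            post = pre + 0.3 + rng.normal(0.0, 0.1, 20)
            d = make_design(
                list(zip(pre, post)),
                [(rng.normal(), rng.normal()) for _ in range(20)],
            )
            r = within_group_ancova(d, "m", "drug")
            rejections += r.p < 0.05
            signs_ok += r.estimate > 0
        assert rejections >= 190
        assert signs_ok == 200

    def test_group_labels_validated(self, rng):
        d = random_design(rng)
        with pytest.raises(ValueError, match="unknown group"):
            within_group_ancova(d, "m", "control")

    def test_contrast_names_route_to_groups(self, rng):
        d = random_design(rng)
        assert run_contrast(d, "m", "Meditation").contrast == "Meditation"
        assert run_contrast(d, "m", "PsychMed").contrast == "PsychMed"
        with pytest.raises(ValueError, match="unknown contrast"):
            run_contrast(d, "m", "Placebo")


def brute_force_bh(p, q_level):
    """Literal step-up definition, independent of the implementation."""
    m = len(p)
    order = np.argsort(p)
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank / m * q_level:
            k_star = rank
    rejected = np.zeros(m, dtype=bool)
    rejected[order[:k_star]] = True
    return rejected


class TestFdrBH:
    def test_hand_step_up(self):
        rej, q = fdr_bh(np.array([0.01, 0.02, 0.04]), 0.05)
        assert rej.all()
        np.testing.assert_allclose(q, [0.03, 0.03, 0.04])

    def test_all_large_none_rejected(self):
        rej, _ = fdr_bh(np.full(10, 0.9), 0.05)
        assert not rej.any()

    def test_empty_input(self):
        rej, q = fdr_bh(np.array([]))
        assert rej.size == 0 and q.size == 0

    def test_matches_brute_force_and_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(200):
            m = rng.integers(1, 40)
            p = rng.uniform(0, 1, m)
            rej, q = fdr_bh(p, 0.05)
            np.testing.assert_array_equal(rej, brute_force_bh(p, 0.05))
            sm_rej, sm_q, *_ = multipletests(p, 0.05, method="fdr_bh")
            np.testing.assert_array_equal(rej, sm_rej)
            np.testing.assert_allclose(q, sm_q, atol=1e-12)

    def test_never_fewer_rejections_than_bonferroni(self, rng):
        for _ in range(100):
            p = rng.uniform(0, 1, rng.integers(1, 30))
            rej, _ = fdr_bh(p, 0.05)
            bonf = p <= 0.05 / len(p)
            assert rej.sum() >= bonf.sum()
            assert np.all(rej[bonf])  # BH rejects a superset

    def test_q_at_least_p(self, rng):
        p = rng.uniform(0, 1, 25)
        _, q = fdr_bh(p)
        assert np.all(q >= p - 1e-15)


class TestParcelwise:
    @staticmethod
    def _maps(rng, n_per_group=10, parcels=30, effect_parcels=(), delta=0.0):
        rows = []
        groups = {}
        for g, n in (("drug", n_per_group), ("placebo", n_per_group)):
            for i in range(n):
                s = f"{g}{i}"
                groups[s] = g
                for p in range(parcels):
                    pre = rng.normal()
                    post = rng.normal()
                    if g == "drug" and p in effect_parcels:
                        post += delta
                    rows.append(dict(subject=s, session="pre", parcel=f"P{p:03d}",
                                     value=pre))
                    rows.append(dict(subject=s, session="post", parcel=f"P{p:03d}",
                                     value=post))
        return pd.DataFrame(rows), groups

    def test_planted_parcels_dominate_rejections(self, rng):
        effect = set(range(20))
        maps, groups = self._maps(rng, n_per_group=20, parcels=60,
                                  effect_parcels=effect, delta=3.0)
        res = parcelwise_contrast(maps, groups, "Synergy")
        hits = set(int(p[1:]) for p in res.loc[res.rejected, "parcel"])
        sensitivity = len(hits & effect) / len(effect)
        assert sensitivity >= 0.9

    def test_parcel_permutation_equivariance(self, rng):
        maps, groups = self._maps(rng, n_per_group=5, parcels=10)
        res1 = parcelwise_contrast(maps, groups, "Synergy").set_index("parcel")
        shuffled = maps.sample(frac=1.0, random_state=0)
        res2 = parcelwise_contrast(shuffled, groups, "Synergy").set_index("parcel")
        for parcel in res1.index:
            assert res1.loc[parcel, "p"] == pytest.approx(
                res2.loc[parcel, "p"], abs=1e-12
            )

    def test_unknown_contrast_rejected(self, rng):
        maps, groups = self._maps(rng, n_per_group=3, parcels=4)
        with pytest.raises(ValueError, match="unknown contrast"):
            parcelwise_contrast(maps, groups, "Anova")


def make_association_data(rng, n_per_group=20, interaction=0.5, noise=0.02,
                          questionnaires=("MEQ",)):
    groups = {}
    fc_rows = {}
    score_rows = []
    for g in ("drug", "placebo"):
        for i in range(n_per_group):
            s = f"{g}{i}"
            groups[s] = g
            score = rng.uniform(0, 10)
            gi = 1.0 if g == "drug" else 0.0
            fc = 0.1 + 0.05 * score + 0.2 * gi + interaction * score * gi
            fc += rng.normal(0.0, noise)
            fc_rows[s] = fc
            for q in questionnaires:
                score_rows.append(dict(subject=s, questionnaire=q, day=2, value=score))
                score_rows.append(dict(subject=s, questionnaire=q, day=1,
                                       value=rng.uniform(0, 10)))
    return pd.Series(fc_rows), pd.DataFrame(score_rows), groups


class TestAssociationOLS:
    def test_recovers_planted_interaction_slope(self, rng):
        fc, scores, groups = make_association_data(rng, interaction=0.5)
        res = association_ols(fc, scores, groups)
        assert res[0].coef_interaction == pytest.approx(0.5, abs=0.05)

    def test_null_interaction_nominal_rejection_rate(self, rng):
        rejections = 0
        n_sims = 500
        for _ in range(n_sims):
            fc, scores, groups = make_association_data(
                rng, n_per_group=10, interaction=0.0, noise=1.0
            )
            res = association_ols(fc, scores, groups)
            rejections += res[0].interaction_p < 0.05
        rate = rejections / n_sims
        half_width = 1.96 * np.sqrt(0.05 * 0.95 / n_sims)
        assert abs(rate - 0.05) < half_width

    def test_group_constant_scores_collinear(self, rng):
        fc, scores, groups = make_association_data(rng, n_per_group=5)
        scores.loc[scores["day"] == 2, "value"] = 3.0  # no within-group variation
        with pytest.raises(ValueError, match="[Cc]ollinear"):
            association_ols(fc, scores, groups)

    def test_bh_applied_across_questionnaire_family(self, rng):
        fc, scores, groups = make_association_data(
            rng, questionnaires=("MEQ", "EBI", "NADA-S", "PIS", "TMS")
        )
        res = association_ols(fc, scores, groups)
        assert len(res) == 5
        for r in res:
            assert r.interaction_q is not None
            assert r.interaction_q >= r.interaction_p - 1e-15

    def test_delta_mode_uses_day_difference(self, rng):
        fc, scores, groups = make_association_data(rng)
        raw = association_ols(fc, scores, groups, delta_mode=False)
        delta = association_ols(fc, scores, groups, delta_mode=True)
        assert raw[0].coef_interaction != pytest.approx(delta[0].coef_interaction)

    def test_attach_fdr_fills_q(self, rng):
        d = random_design(rng)
        results = [synergy_rm_anova(d, "m")]
        attach_fdr(results)
        assert results[0].q is not None
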