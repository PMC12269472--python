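import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from megpac_rsn.rsn import ReductionPlan, select_even_subset
from megpac_rsn.simulate import CONDITIONS
from megpac_rsn.stats import (
    MatchedRun,
    _fdr_bh,
    binarize_map,
    hc_overlap,
    jackknife_inflate,
    lowfreq_anova,
    match_ensemble,
    match_to_template,
    phi_coefficient,
    run_jackknife,
    student_t,
    twoway_anova_type2,
    vertex_anova,
    welch_t,
)


class TestBinarize:
    def test_threshold_arithmetic(self):
        flags = binarize_map(np.array([1.0, 0.5, 0.39]), 0.4)
        assert flags.tolist() == [True, True, False]

    def test_zero_threshold_flags_everything(self):
        flags = binarize_map(np.array([1.0, 0.2, 0.0]), 0.0)
        assert flags.tolist() == [True, True, True]

    def test_constant_map_fully_flagged(self):
        assert binarize_map(np.full(5, 0.7)).all()

    def test_all_zero_map_rejected(self):
        with pytest.raises(ValueError):
            binarize_map(np.zeros(5))


class TestPhi:
    def test_identical_maps(self):
        a = np.array([1, 0, 1, 1, 0], bool)
        assert phi_coefficient(a, a) == pytest.approx(1.0)

    def test_exact_complements(self):
        a = np.array([1, 0, 1, 1, 0], bool)
        assert phi_coefficient(a, ~a) == pytest.approx(-1.0)

    def test_hand_computed_table(self):
        # n11=3, n10=1, n01=1, n00=5 -> phi = 14/24
        a = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0], bool)
        b = np.array([1, 1, 1, 0, 1, 0, 0, 0, 0, 0], bool)
        assert phi_coefficient(a, b) == pytest.approx(14 / 24)
        assert phi_coefficient(b, a) == pytest.approx(14 / 24)

    def test_equals_pearson_of_indicator_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a = rng.random(60) < rng.uniform(0.2, 0.8)
            b = rng.random(60) < rng.uniform(0.2, 0.8)
            if a.all() or b.all() or not a.any() or not b.any():
                continue
            r = np.corrcoef(a.astype(float), b.astype(float))[0, 1]
            assert phi_coefficient(a, b) == pytest.approx(r, abs=1e-10)

    def test_degenerate_marginal_returns_zero_with_warning(self):
        a = np.ones(5, bool)
        b = np.array([1, 0, 1, 0, 1], bool)
        with pytest.warns(UserWarning, match="degenerate"):
            assert phi_coefficient(a, b) == 0.0


class TestTTests:
    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.standard_normal(rng.integers(5, 30))
            y = 2.5 * rng.standard_normal(rng.integers(5, 30)) + 0.3
            t, df, p = welch_t(x[:, None], y[:, None])
            ref = sp_stats.ttest_ind(x, y, equal_var=False)
            assert t[0] == pytest.approx(ref.statistic, abs=1e-10)
            assert p[0] == pytest.approx(ref.pvalue, abs=1e-10)
            assert df[0] == pytest.approx(ref.df, abs=1e-8)

    def test_student_matches_scipy(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(12)
        y = rng.standard_normal(17) + 1.0
        t, df, p = student_t(x[:, None], y[:, None])
        ref = sp_stats.ttest_ind(x, y, equal_var=True)
        assert np.asarray(t).ravel()[0] == pytest.approx(ref.statistic,
                                                         abs=1e-10)
        assert df == 27


class TestJackknifeInflate:
    def test_mean_preserved_and_sd_scaled(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(18)
        y = jackknife_inflate(x)
        assert y.mean() == pytest.approx(x.mean())
        assert y.std(ddof=1) == pytest.approx(17 * x.std(ddof=1))


class TestTwoWayAnova:
    @staticmethod
    def _statsmodels_typ2(y, med, sess):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        df = pd.DataFrame({"y": y, "med": med, "sess": sess})
        model = ols("y ~ C(med) * C(sess)", data=df).fit()
        return sm.stats.anova_lm(model, typ=2)

    def test_balanced_design_matches_closed_form(self):
        """On a balanced 2x2 design the Type II F's equal the textbook
        cell-means decomposition."""
        rng = np.random.default_rng(4)
        n = 8
        cells = {(a, b): rng.standard_normal(n) + a * 0.5 + b * 1.5
                 for a in (0, 1) for b in (0, 1)}
        y = np.concatenate([cells[a, b] for a in (0, 1) for b in (0, 1)])
        med = np.repeat([0, 0, 1, 1], n).astype(float)
        sess = np.repeat([0, 1, 0, 1], n).astype(float)
        res = twoway_anova_type2(y[:, None], med, sess)
        # closed form for a balanced two-way layout
        means = {k: v.mean() for k, v in cells.items()}
        grand = np.mean(list(means.values()))
        ma = {a: np.mean([means[a, 0], means[a, 1]]) for a in (0, 1)}
        mb = {b: np.mean([means[0, b], means[1, b]]) for b in (0, 1)}
        ss_a = 2 * n * sum((ma[a] - grand) ** 2 for a in (0, 1))
        ss_b = 2 * n * sum((mb[b] - grand) ** 2 for b in (0, 1))
        ss_ab = n * sum(
            (means[a, b] - ma[a] - mb[b] + grand) ** 2
            for a in (0, 1) for b in (0, 1)
        )
        sse = sum(((cells[a, b] - means[a, b]) ** 2).sum()
                  for a in (0, 1) for b in (0, 1))
        df_e = 4 * n - 4
        assert res["F_A"][0] == pytest.approx((ss_a / 1) / (sse / df_e),
                                              abs=1e-8)
        assert res["F_B"][0] == pytest.approx((ss_b / 1) / (sse / df_e),
                                              abs=1e-8)
        assert res["F_A:B"][0] == pytest.approx((ss_ab / 1) / (sse / df_e),
                                                abs=1e-8)

    def test_unbalanced_design_matches_statsmodels(self):
        rng = np.random.default_rng(5)
        sizes = {(0, 0): 18, (0, 1): 18, (1, 0): 17, (1, 1): 19}
        ys, meds, sesss = [], [], []
        for (a, b), n in sizes.items():
            ys.append(rng.standard_normal(n) + 0.4 * a - 0.2 * b)
            meds.append(np.full(n, a, float))
            sesss.append(np.full(n, b, float))
        y = np.concatenate(ys)
        med = np.concatenate(meds)
        sess = np.concatenate(sesss)
        res = twoway_anova_type2(y[:, None], med, sess)
        table = self._statsmodels_typ2(y, med, sess)
        assert res["F_A"][0] == pytest.approx(table.loc["C(med)", "F"],
                                              abs=1e-8)
        assert res["F_B"][0] == pytest.approx(table.loc["C(sess)", "F"],
                                              abs=1e-8)
        assert res["F_A:B"][0] == pytest.approx(
            table.loc["C(med):C(sess)", "F"], abs=1e-8)
        assert res["p_A"][0] == pytest.approx(table.loc["C(med)", "PR(>F)"],
                                              abs=1e-10)


class TestFdr:
    def test_monotonicity_in_q(self):
        rng = np.random.default_rng(6)
        p = np.concatenate([rng.uniform(0, 1, 200),
                            rng.uniform(0, 0.001, 10)])
        strict = _fdr_bh(p, 0.01)
        loose = _fdr_bh(p, 0.05)
        assert np.all(loose[strict])  # q=0.01 rejections within q=0.05 set


def _fake_series(rng, n_subjects, n_vertices=12, n_samples=40, shift=0.0):
    return {
        f"s{k}": rng.standard_normal((n_vertices, n_samples)) + shift
        for k in range(n_subjects)
    }


class TestJackknife:
    def test_run_count_and_distinct_omissions(self, ico0):
        rng = np.random.default_rng(7)
        series = _fake_series(rng, 5, ico0.n_vertices)
        plan = select_even_subset(ico0, ico0.n_vertices)
        ens = run_jackknife(series, plan, n_modes=4, condition="first-OFF")
        assert ens.n_runs == 5
        assert sorted(lo for lo, _ in ens.runs) == sorted(series)

    def test_cohort_of_one_rejected(self, ico0):
        rng = np.random.default_rng(8)
        series = _fake_series(rng, 1, ico0.n_vertices)
        plan = select_even_subset(ico0, ico0.n_vertices)
        with pytest.raises(ValueError, match=">= 2"):
            run_jackknife(series, plan, 4)

    def test_cohort_of_two_boundary(self, ico0):
        rng = np.random.default_rng(9)
        series = _fake_series(rng, 2, ico0.n_vertices)
        plan = select_even_subset(ico0, ico0.n_vertices)
        ens = run_jackknife(series, plan, n_modes=3)
        assert ens.n_runs == 2

    def test_duplicate_subjects_give_identical_runs(self, ico0):
        rng = np.random.default_rng(10)
        one = rng.standard_normal((ico0.n_vertices, 50))
        series = {f"s{k}": one.copy() for k in range(4)}
        plan = select_even_subset(ico0, ico0.n_vertices)
        ens = run_jackknife(series, plan, n_modes=3)
        template = ens.runs[0][1].modes[0]
        matched = match_ensemble(ens, {"net": template})["net"]
        maps = np.vstack([m.map for m in matched])
        assert np.allclose(maps - maps[0], 0.0, atol=1e-10)


class TestMatching:
    def test_template_equal_to_mode_matches_perfectly(self, ico0):
        rng = np.random.default_rng(11)
        series = _fake_series(rng, 3, ico0.n_vertices)
        plan = select_even_subset(ico0, ico0.n_vertices)
        ens = run_jackknife(series, plan, n_modes=4)
        rsns = ens.runs[0][1]
        idx, phi = match_to_template(rsns, rsns.modes[2].copy())
        assert idx == 2
        assert phi == pytest.approx(1.0)

    def test_disjoint_template_flags_invalid(self, ico0):
        rng = np.random.default_rng(12)
        n = ico0.n_vertices
        series = {}
        for k in range(3):
            s = np.zeros((n, 60))
            s[: n // 2] = rng.standard_normal((n // 2, 60))
            s[n // 2:] = 1e-3 * rng.standard_normal((n - n // 2, 60))
            series[f"s{k}"] = s
        plan = ReductionPlan(np.arange(n // 2), "manual", n // 2)
        ens = run_jackknife(series, plan, n_modes=2)
        # template supported only where the modes are (numerically) zero
        template = np.zeros(n)
        template[-2:] = 1.0
        matched = match_ensemble(ens, {"net": template})["net"]
        assert all(m.phi <= 0 for m in matched)
        assert not any(m.valid for m in matched)


def _synthetic_matched(rng, n_vertices=30, effect=0.0, effect_vertices=(),
                       sizes=(18, 18, 17, 19), noise=0.08):
    """MatchedRun scaffolding with leave-one-out structure: per condition,
    run values are jackknife means of per-subject maps."""
    matched = {}
    templates = {}
    base = rng.uniform(0.1, 1.0, n_vertices)  # some vertices sub-threshold
    for cond, n in zip(CONDITIONS, sizes):
        subj_maps = base + noise * rng.standard_normal((n, n_vertices))
        if effect and cond.startswith("second"):
            subj_maps[:, list(effect_vertices)] += effect
        runs = []
        for i in range(n):
            keep = np.ones(n, bool)
            keep[i] = False
            runs.append(MatchedRun(f"s{i}", 0, 1.0, subj_maps[keep].mean(0)))
        matched[cond] = {"net": runs}
        templates[cond] = {"net": base}
    return matched, templates


class TestExclusiveAssignment:
    def test_templates_claim_distinct_modes(self, ico0):
        from megpac_rsn.stats import assign_modes

        rng = np.random.default_rng(30)
        series = _fake_series(rng, 3, ico0.n_vertices)
        plan = select_even_subset(ico0, ico0.n_vertices)
        ens = run_jackknife(series, plan, n_modes=5)
        rsns = ens.runs[0][1]
        # two near-identical templates compete for the same mode
        templates = {"a": rsns.modes[1].copy(),
                     "b": np.clip(rsns.modes[1] + 0.01, 0, 1)}
        assignment = assign_modes(rsns, templates)
        modes = {assignment["a"][0], assignment["b"][0]}
        assert len(modes) == 2
        assert 1 in modes  # the best match keeps the contested mode


class TestVertexAnova:
    def test_identical_cells_yield_no_significance(self):
        rng = np.random.default_rng(13)
        matched, templates = _synthetic_matched(rng)
        res = vertex_anova(matched, templates, correction=True)["net"]
        assert res.included.sum() > 0
        for pair, mask in res.fdr_significant.items():
            assert mask.sum() == 0

    def test_planted_session_effect_detected_in_session_contrasts(self):
        rng = np.random.default_rng(14)
        eff = range(10)
        matched, templates = _synthetic_matched(rng, n_vertices=80,
                                                effect=0.4,
                                                effect_vertices=eff)
        res = vertex_anova(matched, templates, correction=True)["net"]
        sess_hits = res.significant_session_vertices()
        assert sess_hits[list(eff)].mean() >= 0.8
        others = np.setdiff1d(np.nonzero(res.included)[0], list(eff))
        assert sess_hits[others].mean() <= 0.05

    def test_missing_condition_rejected(self):
        rng = np.random.default_rng(15)
        matched, templates = _synthetic_matched(rng)
        del matched["second-ON"]
        with pytest.raises(ValueError, match="missing"):
            vertex_anova(matched, templates)

    def test_correction_shrinks_t_values(self):
        rng = np.random.default_rng(16)
        matched, templates = _synthetic_matched(rng)
        on = vertex_anova(matched, templates, correction=True)["net"]
        off = vertex_anova(matched, templates, correction=False)["net"]
        inc = on.included
        t_on = np.abs(on.posthoc["session@OFF"]["t"][inc])
        t_off = np.abs(off.posthoc["session@OFF"]["t"][inc])
        assert np.nanmedian(t_on) < np.nanmedian(t_off)


class TestHcOverlap:
    def test_identical_template_gives_phi_one_everywhere(self):
        rng = np.random.default_rng(17)
        matched, templates = _synthetic_matched(rng)
        hc = {"net": matched["first-OFF"]["net"][0].map.copy()}
        # force all runs to the same map
        for cond in CONDITIONS:
            matched[cond]["net"] = [
                MatchedRun(m.left_out, 0, 1.0, hc["net"].copy())
                for m in matched[cond]["net"]
            ]
        res = hc_overlap(matched, hc, correction=True)
        assert np.allclose(res.runs["phi"], 1.0)
        assert not res.tests["significant"].any()

    def test_run_vector_lengths_and_welch_df_oracle(self):
        rng = np.random.default_rng(18)
        matched, _ = _synthetic_matched(rng, noise=0.3)
        hc = {"net": rng.uniform(0.05, 1.0, 30)}  # sub-threshold vertices too
        res = hc_overlap(matched, hc, correction=False)
        counts = res.summary.set_index("condition")["n"]
        assert counts["first-OFF"] == 18 and counts["second-OFF"] == 17
        # recompute one Welch df from the raw phi vectors
        row = res.tests.iloc[0]
        x = res.runs.query("condition == @row.cond1")["phi"].to_numpy()
        y = res.runs.query("condition == @row.cond2")["phi"].to_numpy()
        ref = sp_stats.ttest_ind(x, y, equal_var=False)
        assert row.t_welch == pytest.approx(ref.statistic, abs=1e-10)
        assert row.df_welch == pytest.approx(ref.df, abs=1e-8)
        # Bonferroni over 6 pairs x 1 network
        assert row.p_bonferroni == pytest.approx(min(1.0, row.p_welch * 6))


class TestLowFreq:
    @staticmethod
    def _freq_maps_and_matched(rng, by_network, jitter=0.0,
                               sizes=(6, 6, 5, 7), n_vertices=30):
        third = n_vertices // 3
        masks = {
            "SMN": slice(0, third),
            "visual": slice(third, 2 * third),
            "frontal": slice(2 * third, n_vertices),
        }
        freq_maps = {}
        matched = {}
        for cond, n in zip(CONDITIONS, sizes):
            freq_maps[cond] = {}
            matched[cond] = {net: [] for net in by_network}
            for i in range(n):
                fmap = np.zeros(n_vertices)
                for net, f in by_network.items():
                    fmap[masks[net]] = f + jitter * rng.standard_normal()
                freq_maps[cond][f"s{i}"] = fmap
                for net in by_network:
                    m = np.zeros(n_vertices)
                    m[masks[net]] = 1.0
                    matched[cond][net].append(MatchedRun(f"s{i}", 0, 1.0, m))
        return freq_maps, matched

    def test_identical_frequencies_give_zero_f(self):
        rng = np.random.default_rng(19)
        freq_maps, matched = self._freq_maps_and_matched(
            rng, {"SMN": 8.0, "visual": 8.0, "frontal": 8.0})
        res = lowfreq_anova(freq_maps, matched, correction=False)
        effects = res.anova.set_index("effect")
        for eff in effects.index:
            if eff == "Residual":
                continue
            assert effects.loc[eff, "F"] == pytest.approx(0.0, abs=1e-8)
            assert effects.loc[eff, "eta2_partial"] == pytest.approx(0.0)

    def test_network_effect_only_with_planted_frequencies(self):
        rng = np.random.default_rng(20)
        freq_maps, matched = self._freq_maps_and_matched(
            rng, {"SMN": 12.0, "visual": 8.0, "frontal": 5.0}, jitter=0.3)
        res = lowfreq_anova(freq_maps, matched, correction=True)
        effects = res.anova.set_index("effect")
        assert effects.loc["network", "p"] < 0.05
        for eff in effects.index:
            if eff in ("network", "Residual"):
                continue
            assert effects.loc[eff, "p"] >= 0.05
        # eta2_partial reproduces the SS ratio of an independent computation
        med = res.medians
        assert effects.loc["network", "eta2_partial"] == pytest.approx(
            effects.loc["network", "sum_sq"]
            / (effects.loc["network", "sum_sq"]
               + effects.loc["Residual", "sum_sq"]))
        # medians recover the planted frequencies
        by_net = med.groupby("network")["median_fphi"].median()
        assert by_net["SMN"] == pytest.approx(12.0, abs=0.5)
        assert by_net["frontal"] == pytest.approx(5.0, abs=0.5)

    def test_posthoc_only_for_significant_effects(self):
        rng = np.random.default_rng(21)
        freq_maps, matched = self._freq_maps_and_matched(
            rng, {"SMN": 12.0, "visual": 8.0, "frontal": 5.0}, jitter=0.3)
        res = lowfreq_anova(freq_maps, matched, correction=True)
        assert set(res.posthoc["effect"]) <= {"network"}
        assert len(res.posthoc) == 3  # the 3 network pairs
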