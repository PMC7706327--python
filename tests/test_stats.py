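import logging

import numpy as np
import pytest
from scipy import stats as sps

from rhizocore.stats import (
    PowerCurve,
    QDAModel,
    RankDeficiencyError,
    TOSTConfig,
    ZeroVarianceError,
    anova_tukey,
    anova_two_way,
    classify,
    fit_qda,
    qda_experiment,
    resampling_power,
    tost_equivalence,
)

from tests.oracles import qda_score_by_formula


class TestTOSTConfig:
    @pytest.mark.parametrize(
        "kwargs", [dict(margin=0.0), dict(margin=-1.0), dict(alpha=0.0), dict(alpha=1.0), dict(margin_type="x")]
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            TOSTConfig(**kwargs)


class TestTOSTEquivalence:
    def test_hand_computed_example(self):
        # frozen from an independent Welch/TOST computation on these numbers
        a = [10.1, 9.8, 10.3, 10.0, 9.9]
        r = [10.5, 10.2, 10.6, 10.4, 10.3]
        cfg = TOSTConfig(margin_type="absolute", margin=1.0)
        res = tost_equivalence(a, r, cfg)
        assert res.mean_difference == pytest.approx(-0.38)
        assert res.p_value == pytest.approx(0.0003014957540829373, rel=1e-9)
        assert res.equivalent

    def test_hand_computed_example_reconstructed(self):
        # independent recomputation of the same example from first principles
        a = np.array([10.1, 9.8, 10.3, 10.0, 9.9])
        r = np.array([10.5, 10.2, 10.6, 10.4, 10.3])
        delta = 1.0
        va, vr = a.var(ddof=1), r.var(ddof=1)
        se = np.sqrt(va / 5 + vr / 5)
        df = (va / 5 + vr / 5) ** 2 / ((va / 5) ** 2 / 4 + (vr / 5) ** 2 / 4)
        diff = a.mean() - r.mean()
        expected = max(sps.t.sf((diff + delta) / se, df), sps.t.cdf((diff - delta) / se, df))
        res = tost_equivalence(a, r, TOSTConfig(margin_type="absolute", margin=1.0))
        assert res.p_value == pytest.approx(expected, rel=1e-12)

    def test_same_distribution_large_n_equivalent(self):
        rng = np.random.default_rng(1)
        a = rng.normal(10.0, 0.5, size=100)
        r = rng.normal(10.0, 0.5, size=100)
        res = tost_equivalence(a, r, TOSTConfig(margin=0.2))
        assert res.equivalent

    def test_difference_beyond_margin_not_equivalent(self):
        rng = np.random.default_rng(2)
        r = rng.normal(10.0, 0.1, size=50)
        a = r + 6.0  # 3x the 20% margin
        res = tost_equivalence(a, r, TOSTConfig(margin=0.2))
        assert not res.equivalent
        assert res.p_value > 0.5

    def test_zero_variance_equal_means_equivalent(self):
        res = tost_equivalence([5.0] * 4, [5.0] * 4, TOSTConfig(margin=0.2))
        assert res.equivalent
        assert res.p_value < 1e-300

    def test_zero_variance_unequal_means_error(self):
        with pytest.raises(ZeroVarianceError):
            tost_equivalence([5.0] * 4, [9.0] * 4, TOSTConfig(margin=0.2))

    def test_too_small_sample(self):
        with pytest.raises(ValueError):
            tost_equivalence([1.0], [1.0, 2.0], TOSTConfig())

    def test_self_equivalence_improves_with_n(self):
        rng = np.random.default_rng(3)
        pops = {n: rng.normal(10, 1, size=n) for n in (5, 50, 500)}
        ps = {}
        for n, x in pops.items():
            y = rng.normal(10, 1, size=n)
            ps[n] = tost_equivalence(x, y, TOSTConfig(margin=0.2)).p_value
        assert ps[500] < ps[5]
        assert ps[500] < 1e-10

    def test_true_difference_at_twice_margin_rarely_equivalent(self):
        # calibration: equivalence rate under a 2x-margin shift stays near 0
        rng = np.random.default_rng(4)
        margin = 0.5
        hits = 0
        n_sim = 400
        for _ in range(n_sim):
            r = rng.normal(10.0, 1.0, size=20)
            a = rng.normal(10.0 + 2 * margin, 1.0, size=20)
            cfg = TOSTConfig(margin_type="absolute", margin=margin)
            if tost_equivalence(a, r, cfg).equivalent:
                hits += 1
        assert hits / n_sim <= 0.07


class TestAnovaTukey:
    def test_identical_groups_nothing_significant(self):
        groups = {"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0], "c": [1.0, 1.0, 1.0]}
        res = anova_tukey(groups)
        assert res.significant_pairs() == []

    def test_separated_group_detected(self):
        rng = np.random.default_rng(5)
        groups = {
            "a": rng.normal(0, 0.01, 10),
            "b": rng.normal(0, 0.01, 10),
            "c": rng.normal(10, 0.01, 10),
        }
        res = anova_tukey(groups)
        sig = set(res.significant_pairs())
        assert ("a", "c") in sig and ("b", "c") in sig
        assert ("a", "b") not in sig

    def test_f_statistic_matches_hand_computation(self):
        groups = {
            "a": [1.0, 2.0, 1.5, 1.8, 1.2],
            "b": [2.1, 2.5, 2.2, 2.8, 2.4],
            "c": [3.0, 3.3, 2.9, 3.5, 3.1],
        }
        res = anova_tukey(groups)
        # frozen from explicit between/within mean-square arithmetic
        assert res.f_statistic == pytest.approx(34.184818481848176, rel=1e-9)

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey({"a": [1.0], "b": [2.0, 3.0]})

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey({"a": [1.0, 2.0]})

    def test_two_way_anova_table(self):
        import pandas as pd

        rng = np.random.default_rng(6)
        rows = []
        for phen in ("s", "d"):
            for d in (5, 15):
                for _ in range(10):
                    base = 1.0 if phen == "s" else 2.0
                    rows.append({"phenotype": phen, "depth": d, "rld": base + 0.1 * d + rng.normal(0, 0.1)})
        table = anova_two_way(pd.DataFrame(rows), "rld", "phenotype", "depth")
        assert table.index[0] == "phenotype"
        assert table.loc[table.index[0], "PR(>F)"] < 0.001


class TestQDA:
    def make_model(self):
        mean1, mean2 = np.array([1.0, 2.0]), np.array([4.0, 0.0])
        S1 = np.array([[2.0, 0.5], [0.5, 1.0]])
        S2 = np.array([[1.0, -0.2], [-0.2, 1.5]])
        rng = np.random.default_rng(7)
        X1 = rng.multivariate_normal(mean1, S1, size=200)
        X2 = rng.multivariate_normal(mean2, S2, size=200)
        return fit_qda({"one": X1, "two": X2})

    def test_score_matches_formula_oracle(self):
        mean = np.array([1.0, 2.0])
        S = np.array([[2.0, 0.5], [0.5, 1.0]])
        X = np.random.default_rng(8).multivariate_normal(mean, S, size=400)
        # rebuild a model whose parameters are known exactly
        model = fit_qda({"a": X, "b": X + 10.0})
        x = np.array([1.5, 1.0])
        got = model.scores(x)
        for i, cls in enumerate(model.classes):
            expected = qda_score_by_formula(x, model.means[i], model.covariances[i], model.priors[i])
            assert got[i] == pytest.approx(expected, abs=1e-10)

    def test_score_fixed_numeric_example(self):
        # frozen value: score of x=(1.5, 1.0) for mean=(1,2), S=[[2,.5],[.5,1]], p=0.5
        model = QDAModel(
            classes=("a",),
            means=np.array([[1.0, 2.0]]),
            covariances=np.array([[[2.0, 0.5], [0.5, 1.0]]]),
            priors=np.array([0.5]),
            _inv=np.linalg.inv(np.array([[[2.0, 0.5], [0.5, 1.0]]])),
            _logdet=np.array([np.log(np.linalg.det(np.array([[2.0, 0.5], [0.5, 1.0]])))]),
        )
        assert model.scores([1.5, 1.0])[0] == pytest.approx(-1.7586693602419423, abs=1e-10)

    def test_constant_vectors_rank_deficient(self):
        X = np.ones((20, 3))
        with pytest.raises(RankDeficiencyError):
            fit_qda({"a": X, "b": X + 1})

    def test_n_not_exceeding_dimension_rank_deficient(self):
        rng = np.random.default_rng(9)
        with pytest.raises(RankDeficiencyError, match="n="):
            fit_qda({"a": rng.normal(size=(6, 6)), "b": rng.normal(size=(10, 6))})

    def test_context_in_error_message(self):
        X = np.ones((20, 3))
        with pytest.raises(RankDeficiencyError, match="location 4"):
            fit_qda({"a": X, "b": X}, context="location 4")

    def test_well_separated_classes_low_error(self):
        rng = np.random.default_rng(10)
        d = 6
        X1 = rng.normal(0.0, 1.0, size=(50, d))
        X2 = rng.normal(10.0, 1.0, size=(50, d))
        model = fit_qda({"near": X1, "far": X2})
        test1 = rng.normal(0.0, 1.0, size=(500, d))
        test2 = rng.normal(10.0, 1.0, size=(500, d))
        errs = sum(classify(model, x) != "near" for x in test1)
        errs += sum(classify(model, x) != "far" for x in test2)
        assert errs / 1000 < 0.02

    def test_classify_class_mean(self):
        model = self.make_model()
        assert classify(model, model.means[0]) == model.classes[0]
        assert classify(model, model.means[1]) == model.classes[1]

    def test_tie_logged_and_first_class_returned(self, caplog):
        S = np.eye(2)
        model = QDAModel(
            classes=("a", "b"),
            means=np.array([[-1.0, 0.0], [1.0, 0.0]]),
            covariances=np.array([S, S]),
            priors=np.array([0.5, 0.5]),
            _inv=np.array([S, S]),
            _logdet=np.array([0.0, 0.0]),
        )
        with caplog.at_level(logging.INFO, logger="rhizocore.stats"):
            got = classify(model, [0.0, 0.0])
        assert got == "a"
        assert any("tie" in r.message for r in caplog.records)

    def test_1d_decision_boundary_closed_form(self):
        # class 1: N(0, 1); class 2: N(3, 4); equal priors.  The boundary
        # solves a quadratic whose roots are -3.41834... and 1.41834...
        model = QDAModel(
            classes=("one", "two"),
            means=np.array([[0.0], [3.0]]),
            covariances=np.array([[[1.0]], [[4.0]]]),
            priors=np.array([0.5, 0.5]),
            _inv=np.array([[[1.0]], [[0.25]]]),
            _logdet=np.array([0.0, np.log(4.0)]),
        )
        roots = sorted(np.roots([-3.0, -6.0, 9.0 + 4.0 * np.log(4.0)]))
        assert roots[0] == pytest.approx(-3.4183449881051273)
        assert roots[1] == pytest.approx(1.418344988105127)
        for x, expected in [(-4.0, "two"), (0.0, "one"), (1.2, "one"), (2.0, "two")]:
            assert classify(model, [x]) == expected
        # scores cross exactly at the roots
        for r in roots:
            s = model.scores([r])
            assert s[0] == pytest.approx(s[1], abs=1e-9)

    def test_prior_scaling_shifts_scores_equally(self):
        model = self.make_model()
        x = [2.0, 1.0]
        base = model.scores(x)
        # halving both priors shifts both scores by log(1/2)
        model2 = QDAModel(
            classes=model.classes,
            means=model.means,
            covariances=model.covariances,
            priors=model.priors / 2,
            _inv=model._inv,
            _logdet=model._logdet,
        )
        shifted = model2.scores(x)
        np.testing.assert_allclose(shifted - base, np.log(0.5), rtol=1e-12)
        assert np.argmax(shifted) == np.argmax(base)

    def test_equal_covariances_reduce_to_linear_rule(self):
        # with shared covariance the boundary is linear: midpoint classifies
        # as a tie and points are assigned by the sign of a linear form
        S = np.array([[1.0, 0.3], [0.3, 2.0]])
        m1, m2 = np.array([0.0, 0.0]), np.array([2.0, 2.0])
        Sinv = np.linalg.inv(S)
        model = QDAModel(
            classes=("a", "b"),
            means=np.array([m1, m2]),
            covariances=np.array([S, S]),
            priors=np.array([0.5, 0.5]),
            _inv=np.array([Sinv, Sinv]),
            _logdet=np.array([np.log(np.linalg.det(S))] * 2),
        )
        w = Sinv @ (m2 - m1)
        b = -0.5 * (m2 + m1) @ Sinv @ (m2 - m1)
        rng = np.random.default_rng(11)
        for _ in range(50):
            x = rng.normal(1.0, 2.0, size=2)
            linear = w @ x + b
            expected = "b" if linear > 0 else "a"
            assert classify(model, x) == expected

    def test_invalid_priors(self):
        rng = np.random.default_rng(12)
        data = {"a": rng.normal(size=(20, 2)), "b": rng.normal(size=(20, 2))}
        with pytest.raises(ValueError):
            fit_qda(data, priors=[0.9, 0.3])

    def test_xy_pair_input(self):
        rng = np.random.default_rng(13)
        X = np.vstack([rng.normal(0, 1, (30, 2)), rng.normal(5, 1, (30, 2))])
        y = np.array(["a"] * 30 + ["b"] * 30)
        model = fit_qda((X, y))
        assert model.classes == ("a", "b")


class TestQDAExperiment:
    def test_chance_level_on_identical_classes(self):
        rng = np.random.default_rng(14)
        pool = rng.normal(0, 1, size=(300, 6))
        classes = {f"c{i}": pool[rng.permutation(300)[:100]] for i in range(3)}
        sweep = qda_experiment(
            classes, training_sizes=(40,), n_test=40, n_draws=15, rng=rng
        )
        rate = float(sweep.misclassification.iloc[0])
        assert rate == pytest.approx(1 - 1 / 3, abs=0.06)

    def test_monotone_in_training_size_on_separable_classes(self):
        rng = np.random.default_rng(15)
        classes = {
            "a": rng.normal(0.0, 1.0, size=(100, 6)),
            "b": rng.normal(1.2, 1.0, size=(100, 6)),
        }
        sweep = qda_experiment(
            classes, training_sizes=(8, 15, 30, 50), n_test=50, n_draws=15, rng=rng
        )
        rates = sweep.misclassification.to_numpy()
        ses = sweep.se.to_numpy()
        for i in range(len(rates) - 1):
            assert rates[i + 1] <= rates[i] + 2 * (ses[i] + ses[i + 1]) + 0.03

    def test_training_size_exceeding_pool_rejected(self):
        rng = np.random.default_rng(16)
        classes = {"a": rng.normal(size=(60, 6)), "b": rng.normal(size=(60, 6))}
        with pytest.raises(ValueError, match="training size"):
            qda_experiment(classes, training_sizes=(50,), n_test=50, rng=rng)

    def test_reproducible_with_seeded_rng(self):
        rng_data = np.random.default_rng(17)
        classes = {
            "a": rng_data.normal(0, 1, size=(80, 6)),
            "b": rng_data.normal(2, 1, size=(80, 6)),
        }
        s1 = qda_experiment(classes, training_sizes=(20,), n_test=20, n_draws=5, rng=np.random.default_rng(1))
        s2 = qda_experiment(classes, training_sizes=(20,), n_test=20, n_draws=5, rng=np.random.default_rng(1))
        assert s1.equals(s2)


class TestResamplingPower:
    def test_type_one_error_on_identical_phenotypes(self):
        rng = np.random.default_rng(18)
        pool = rng.normal(20.0, 3.0, size=300)
        values = {"a": pool, "b": pool, "c": pool}
        curve = resampling_power(
            values, location_id=3, metric_p=50, n_range=(5, 10), reps=2000, rng=rng
        )
        for prop in curve.proportion_significant:
            assert prop == pytest.approx(0.05, abs=0.02)

    def test_extreme_separation_full_power(self):
        rng = np.random.default_rng(19)
        values = {
            "a": rng.normal(10, 0.1, 100),
            "b": rng.normal(20, 0.1, 100),
            "c": rng.normal(30, 0.1, 100),
        }
        curve = resampling_power(values, 1, 50, n_range=(3, 5, 10), reps=500, rng=rng)
        assert (curve.proportion_significant > 0.99).all()

    def test_power_nondecreasing_in_n(self):
        rng = np.random.default_rng(20)
        values = {
            "a": rng.normal(10.0, 2.0, 200),
            "b": rng.normal(11.5, 2.0, 200),
            "c": rng.normal(13.0, 2.0, 200),
        }
        curve = resampling_power(values, 1, 50, n_range=tuple(range(2, 21, 3)), reps=1500, rng=rng)
        props = curve.proportion_significant
        mc_se = np.sqrt(props * (1 - props) / curve.n_replicates)
        for i in range(len(props) - 1):
            assert props[i + 1] >= props[i] - 2 * (mc_se[i] + mc_se[i + 1])

    def test_reproducible(self):
        rng_data = np.random.default_rng(21)
        values = {"a": rng_data.normal(10, 1, 50), "b": rng_data.normal(12, 1, 50), "c": rng_data.normal(14, 1, 50)}
        c1 = resampling_power(values, 1, 50, n_range=(4,), reps=200, rng=np.random.default_rng(2))
        c2 = resampling_power(values, 1, 50, n_range=(4,), reps=200, rng=np.random.default_rng(2))
        np.testing.assert_array_equal(c1.proportion_significant, c2.proportion_significant)

    def test_needs_two_phenotypes(self):
        with pytest.raises(ValueError):
            resampling_power({"a": [1.0, 2.0]}, 1, 50)

    def test_proportions_validated(self):
        with pytest.raises(ValueError):
            PowerCurve(1, 50, np.array([2]), np.array([1.5]), 100)
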