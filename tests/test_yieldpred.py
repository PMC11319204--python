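"""Penalized logistic diagnostic-yield model: design encoding, solver
correctness against an independent IRLS oracle, KKT conditions,
cross-validation, prediction, AUC machinery and path export."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from raredx import yieldpred as yp


def _toy_cohort(n=120, n_sub=6, seed=0, beta=None, n_sites=2):
    rng = np.random.default_rng(seed)
    subcats = [f"S{j:02d}" for j in range(n_sub)]
    ind = pd.DataFrame(
        rng.binomial(1, 0.3, size=(n, n_sub)),
        columns=subcats,
        index=[f"p{i}" for i in range(n)],
    )
    if beta is None:
        beta = np.zeros(n_sub)
    lp = ind.to_numpy() @ beta - 0.3
    cohort = pd.DataFrame(
        {
            "patient_id": ind.index,
            "age_class": rng.choice(["adult", "child"], n),
            "sex": rng.choice(["m", "f"], n),
            "site": rng.choice([f"lab{i}" for i in range(n_sites)], n),
            "image_flag": rng.binomial(1, 0.2, n),
            "solved": rng.binomial(1, expit(lp)),
        }
    )
    return cohort, ind


class TestBuildDesign:
    def test_site_reference_dropped(self):
        cohort, ind = _toy_cohort(n=40, n_sites=2)
        design = yp.build_design(cohort, ind)
        site_cols = [c for c in design.columns if c.startswith("site_")]
        assert len(site_cols) == 1

    def test_column_count_and_roles(self):
        cohort, ind = _toy_cohort(n=100, n_sub=49, n_sites=5)
        design = yp.build_design(cohort, ind)
        # 49 penalized + age + sex + 4 site one-hots + image flag
        assert len(design.columns) == 49 + 2 + 4 + 1
        assert (design.penalty_factors[:49] == 1.0).all()
        assert set(design.confounders) == set(design.columns[49:])

    def test_all_zero_indicator_case_retained(self):
        cohort, ind = _toy_cohort(n=40)
        ind.iloc[0] = 0
        design = yp.build_design(cohort, ind)
        assert design.X.shape[0] == 40

    def test_missing_indicators_rejected(self):
        cohort, ind = _toy_cohort(n=40)
        with pytest.raises(ValueError):
            yp.build_design(cohort, ind.iloc[:-1])


class TestFitPath:
    def test_all_zero_at_lambda_max_and_confounder_match(self):
        """At the top of the grid the penalized block is exactly zero and
        the confounder coefficients match an unpenalized confounder-only
        logistic fit."""
        import statsmodels.api as sm

        cohort, ind = _toy_cohort(n=200, seed=1)
        design = yp.build_design(cohort, ind)
        model = yp.fit_path(design, n_lambda=30)
        top = model.coef_at(0)
        assert (top[model.penalized] == 0.0).all()
        conf = design.X[model.confounders].to_numpy()
        fit = sm.GLM(
            design.y, sm.add_constant(conf), family=sm.families.Binomial()
        ).fit()
        ours = np.r_[model.intercepts[0], top[model.confounders]]
        assert np.abs(ours - fit.params).max() < 1e-5

    def test_lambda_zero_matches_irls_oracle(self):
        """The unpenalized end of the path agrees with an independent
        iteratively-reweighted least-squares fit to 1e-4 per coefficient."""
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        n, p = 200, 6
        X = rng.binomial(1, 0.4, (n, p)).astype(float)
        beta = np.array([1.0, -0.8, 0.5, 0.0, 0.0, 0.3])
        y = rng.binomial(1, expit(-0.4 + X @ beta)).astype(float)
        w = np.array([1.0, 1.0, 1.0, 1.0, 0.0, 0.0])
        model = yp.fit_path(X, y, w, lambdas=[0.0])
        oracle = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial()).fit()
        ours = np.r_[model.intercepts[0], model.coefs[0]]
        assert np.abs(ours - oracle.params).max() < 1e-4

    def test_kkt_along_path(self):
        cohort, ind = _toy_cohort(
            n=300, n_sub=10, seed=2, beta=np.r_[1.0, -1.0, np.zeros(8)]
        )
        design = yp.build_design(cohort, ind)
        model = yp.fit_path(design, n_lambda=40)
        viol = yp.kkt_max_violation(model, design)
        assert viol.max() <= 1e-6

    def test_confounders_never_shrunk(self):
        """Confounder coefficients at any lambda match a refit where the
        penalized block is frozen at its fitted values."""
        import statsmodels.api as sm

        cohort, ind = _toy_cohort(n=250, n_sub=8, seed=4,
                                  beta=np.r_[1.2, np.zeros(7)])
        design = yp.build_design(cohort, ind)
        model = yp.fit_path(design, n_lambda=20)
        i = 10
        coef = model.coef_at(i)
        pen_cols = model.penalized
        offset = design.X[pen_cols].to_numpy() @ coef[pen_cols].to_numpy()
        conf = design.X[model.confounders].to_numpy()
        refit = sm.GLM(
            design.y, sm.add_constant(conf),
            family=sm.families.Binomial(), offset=offset,
        ).fit()
        ours = np.r_[model.intercepts[i], coef[model.confounders]]
        assert np.abs(ours - refit.params).max() < 1e-5

    def test_n_nonzero_recorded(self):
        cohort, ind = _toy_cohort(n=200, n_sub=8, seed=5,
                                  beta=np.r_[1.5, -1.5, np.zeros(6)])
        design = yp.build_design(cohort, ind)
        model = yp.fit_path(design, n_lambda=25)
        assert model.n_nonzero[0] == 0
        assert model.n_nonzero[-1] >= 2

    def test_complete_separation_flagged(self):
        rng = np.random.default_rng(0)
        n = 60
        x = rng.binomial(1, 0.5, n).astype(float)
        X = np.c_[x, rng.binomial(1, 0.5, n)]
        y = x.copy()  # perfectly separated by the first column
        with pytest.warns(yp.SeparationWarning):
            model = yp.fit_path(
                X, y, np.array([1.0, 1.0]), n_lambda=60,
                lambda_min_ratio=1e-8,
            )
        assert model.separation_flagged
        assert len(model.lambdas) < 60

    def test_requires_both_classes_and_minimum_n(self):
        X = np.ones((30, 2))
        with pytest.raises(ValueError):
            yp.fit_path(X, np.ones(30), np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            yp.fit_path(X[:10], np.r_[np.ones(5), np.zeros(5)],
                        np.array([1.0, 1.0]))


class TestCrossValidation:
    def test_deviance_at_selected_not_worse_than_lambda_max(self):
        cohort, ind = _toy_cohort(n=300, n_sub=10, seed=6,
                                  beta=np.r_[1.0, 1.0, np.zeros(8)])
        design = yp.build_design(cohort, ind)
        model = yp.cv_select(design, k=5, seed=1, n_lambda=30)
        dev = model.cv_mean_deviance
        assert dev[model.selected_index] <= dev[0] + 1e-12

    def test_pure_noise_selects_sparse_models(self):
        """With outcome independent of the indicators, the selected model
        keeps at most 2 penalized coefficients in >= 90% of replicates."""
        sparse = 0
        reps = 20
        for seed in range(reps):
            cohort, ind = _toy_cohort(n=150, n_sub=8, seed=100 + seed)
            design = yp.build_design(cohort, ind)
            model = yp.cv_select(design, k=5, seed=seed, n_lambda=30)
            sparse += model.n_nonzero[model.selected_index] <= 2
        assert sparse >= int(0.9 * reps)

    def test_leave_one_out_runs(self):
        cohort, ind = _toy_cohort(n=30, n_sub=4, seed=7,
                                  beta=np.r_[1.0, np.zeros(3)])
        design = yp.build_design(cohort, ind)
        model = yp.cv_select(design, k=30, seed=1, n_lambda=15)
        assert np.isfinite(model.cv_mean_deviance).all()

    def test_seed_reproducible(self):
        cohort, ind = _toy_cohort(n=200, n_sub=6, seed=8,
                                  beta=np.r_[1.0, np.zeros(5)])
        design = yp.build_design(cohort, ind)
        m1 = yp.cv_select(design, k=5, seed=11, n_lambda=20)
        m2 = yp.cv_select(design, k=5, seed=11, n_lambda=20)
        assert m1.selected_index == m2.selected_index
        assert np.allclose(m1.cv_mean_deviance, m2.cv_mean_deviance)


@pytest.fixture(scope="module")
def fitted_predictive():
    cohort, ind = _toy_cohort(n=400, n_sub=6, seed=9,
                              beta=np.r_[1.5, -1.0, np.zeros(4)])
    design = yp.build_design(cohort, ind)
    model = yp.cv_select(design, k=5, seed=1, n_lambda=30)
    return design, model


class TestPrediction:
    def test_baseline_is_intercept_plus_means(self, fitted_predictive):
        design, model = fitted_predictive
        with pytest.warns(UserWarning, match="baseline"):
            prob = yp.predict_yield(model)
        coef = model.coef_selected
        lp = model.intercepts[model.selected_index] + sum(
            coef[c] * model.confounder_means[c] for c in model.confounders
        )
        assert prob == pytest.approx(float(expit(lp)))

    def test_positive_coefficient_increases_probability(self, fitted_predictive):
        design, model = fitted_predictive
        coef = model.coef_selected[model.penalized]
        positive = coef[coef > 0].index[0]
        base = yp.predict_yield(model, indicators={}, age_class="child",
                                sex="f")
        more = yp.predict_yield(model, indicators={positive: 1},
                                age_class="child", sex="f")
        assert more > base

    def test_unseen_site_maps_to_training_means(self, fitted_predictive):
        design, model = fitted_predictive
        p_unseen = yp.predict_yield(model, indicators={}, age_class="adult",
                                    sex="m", site="lab_never_seen")
        p_means = yp.predict_yield(model, indicators={}, age_class="adult",
                                   sex="m")
        assert p_unseen == pytest.approx(p_means)

    def test_json_round_trip(self, fitted_predictive, tmp_path):
        design, model = fitted_predictive
        path = tmp_path / "model.json"
        model.to_json(path)
        back = yp.PenalizedLogisticModel.from_json(path)
        p1 = yp.predict_yield(model, indicators={"S00": 1}, age_class="child",
                              sex="f")
        p2 = yp.predict_yield(back, indicators={"S00": 1}, age_class="child",
                              sex="f")
        assert p1 == pytest.approx(p2)

    def test_term_count_correlates_with_probability(self, small_ontology):
        """More phenotype terms (hence more active subcategories) raise
        the predicted probability on a planted-signal cohort."""
        from scipy.stats import spearmanr

        from raredx.synthetic import SimulationParams, simulate_cohort

        params = SimulationParams(
            n_patients=800, seed=2, n_planted_negative=0
        )
        sim = simulate_cohort(small_ontology, params)
        design = yp.build_design(sim.cohort, sim.indicators)
        model = yp.cv_select(design, k=5, seed=1, n_lambda=30)
        probs = model.predict_proba(design.X.to_numpy())
        n_terms = np.array([len(sim.terms[p]) for p in sim.cohort["patient_id"]])
        rho, _ = spearmanr(n_terms, probs)
        assert rho > 0


class TestAuc:
    def test_perfect_separation(self):
        auc, _ = yp.roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], n_boot=100)
        assert auc == 1.0

    def test_null_scores_near_half(self, rng):
        n = 10_000
        scores = rng.uniform(size=n)
        labels = rng.binomial(1, 0.4, n)
        auc, _ = yp.roc_auc(scores, labels, n_boot=50, seed=1)
        assert 0.48 < auc < 0.52

    def test_binary_marker_closed_form(self):
        # marker with sensitivity 0.8, specificity 0.6
        y = np.r_[np.ones(100), np.zeros(100)]
        x = np.r_[np.ones(80), np.zeros(20), np.ones(40), np.zeros(60)]
        auc, _ = yp.roc_auc(x, y, n_boot=50)
        assert auc == pytest.approx((0.8 + 0.6) / 2)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            yp.roc_auc([0.1, 0.2], [1, 1])


class TestPerTermAuc:
    def test_null_term_near_half(self, rng):
        n = 5000
        labels = rng.binomial(1, 0.3, n)
        sets = [{"T"} if rng.random() < 0.2 else set() for _ in range(n)]
        auc = yp.per_term_auc(sets, labels)
        assert abs(auc["T"] - 0.5) < 0.02

    def test_solved_only_term_above_half(self):
        sets = [{"T"}, {"T"}, set(), set()]
        auc = yp.per_term_auc(sets, [1, 1, 0, 0])
        assert auc["T"] > 0.5

    def test_universal_term_uninformative(self):
        sets = [{"T"}] * 6
        auc = yp.per_term_auc(sets, [1, 1, 1, 0, 0, 0])
        assert auc["T"] == pytest.approx(0.5)


@pytest.fixture(scope="module")
def fitted_paths():
    cohort, ind = _toy_cohort(n=500, n_sub=8, seed=10,
                              beta=np.r_[2.0, 0.6, np.zeros(6)])
    design = yp.build_design(cohort, ind)
    return design, yp.cv_select(design, k=5, seed=1, n_lambda=40)


class TestPathsAndSplit:
    def test_low_prevalence_features_excluded(self, fitted_paths):
        design, model = fitted_paths
        model.train_prevalence[model.penalized[0]] = 0.01
        table = yp.export_paths(model, min_prevalence=0.05)
        assert model.penalized[0] not in set(table["feature"])

    def test_exported_paths_zero_at_lambda_max(self, fitted_paths):
        design, model = fitted_paths
        table = yp.export_paths(model)
        lam_max = model.lambdas[0]
        at_top = table[table["lambda"] == lam_max]
        assert (at_top["coefficient"] == 0.0).all()

    def test_strong_feature_enters_before_weak(self, fitted_paths):
        design, model = fitted_paths

        def entry_lambda(col):
            j = model.columns.index(col)
            nz = np.nonzero(model.coefs[:, j])[0]
            return model.lambdas[nz[0]] if len(nz) else 0.0

        assert entry_lambda("S00") > entry_lambda("S01")  # beta 2.0 vs 0.6

    def test_reference_cohort_split_shape(self):
        y = np.r_[np.ones(499), np.zeros(1577 - 499)]
        train, test = yp.split_cohort(y, seed=1)
        assert len(train) == 1256
        assert len(test) == 321
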