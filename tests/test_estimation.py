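"""Two-stage estimation: likelihoods, stage-1 fits, sandwich, stage 2."""

import numpy as np
import pytest

from pedsem import (Individual, Pedigree, SimulationConfig,
                    build_model_matrices, conditional_loglik_ascertained,
                    fit_model, generate_starting_values, minimum_distance_fit,
                    parse_model, pedigree_loglik, saturated_estimates,
                    simulate_dataset)
from pedsem.estimation import (_weight_matrix, fit_bivariate_vc,
                               fit_univariate_vc, prepare_fit_data)
from pedsem.moments import moment_labels

from conftest import sib_pair


class TestPedigreeLoglik:
    def test_standard_normal_density(self):
        ll = pedigree_loglik([0.0], [0.0], [[1.0]])
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi))

    def test_all_missing_contributes_zero(self):
        assert pedigree_loglik([np.nan, np.nan], [0, 0], np.eye(2)) == 0.0

    def test_partial_missingness_deletes_rows(self):
        S = np.array([[2.0, 0.7], [0.7, 1.5]])
        ll = pedigree_loglik([1.0, np.nan], [0.0, 0.0], S)
        assert ll == pytest.approx(pedigree_loglik([1.0], [0.0], [[2.0]]))

    def test_independence_factorizes(self):
        y = np.array([0.3, -1.2])
        S = np.diag([1.5, 2.5])
        ll = pedigree_loglik(y, np.zeros(2), S)
        parts = sum(pedigree_loglik([yi], [0.0], [[si]])
                    for yi, si in zip(y, np.diag(S)))
        assert ll == pytest.approx(parts)

    def test_non_pd_gives_minus_inf(self):
        assert pedigree_loglik([1.0, 1.0], [0, 0],
                               [[1.0, 2.0], [2.0, 1.0]]) == -np.inf


class TestConditionalLoglik:
    def test_no_proband_equals_unconditional(self):
        y, mu, S = [0.5, -0.2], [0.0, 0.0], np.eye(2)
        assert conditional_loglik_ascertained(y, mu, S, []) == \
            pytest.approx(pedigree_loglik(y, mu, S))

    def test_proband_only_pedigree_contributes_zero(self):
        assert conditional_loglik_ascertained([1.3], [0.0], [[2.0]], [0]) == \
            pytest.approx(0.0)

    def test_missing_proband_values_fall_back(self):
        y = [np.nan, 0.4]
        with pytest.warns(UserWarning, match="proband"):
            ll = conditional_loglik_ascertained(y, [0, 0], np.eye(2), [0])
        assert ll == pytest.approx(pedigree_loglik(y, [0, 0], np.eye(2)))


def _singleton_peds(rng, n, with_cov=True):
    peds = []
    for i in range(n):
        ind = Individual(f"i{i}")
        if with_cov:
            ind.covariates["age"] = float(rng.normal())
        peds.append(Pedigree(f"F{i}", [ind]))
    return peds


class TestStageOne:
    def test_iid_case_reduces_to_ols(self):
        """Unrelated singletons, one 'e' component: beta = OLS, sigma = ML var."""
        rng = np.random.default_rng(0)
        n = 400
        peds = _singleton_peds(rng, n)
        x = np.array([p.members[0].covariates["age"] for p in peds])
        y = 0.5 + 1.5 * x + rng.normal(0, 1.3, size=n)
        for p, yi in zip(peds, y):
            p.members[0].phenotypes["resp"] = float(yi)
        mm = build_model_matrices(parse_model("resp ~ age + <e>\n"))
        fd = prepare_fit_data(peds, mm)
        est, _ = fit_univariate_vc(fd, 0)
        X = np.column_stack([np.ones(n), x])
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta_ols
        assert np.allclose(est[:2], beta_ols, atol=1e-5)
        assert est[2] == pytest.approx(np.mean(resid ** 2), rel=1e-4)

    def test_unconstrained_variances_go_negative(self):
        """Zero-heritability data: sigma_p estimates scatter around 0."""
        rng = np.random.default_rng(1)
        sigma_p = []
        mm = build_model_matrices(parse_model("y ~ <p,e>\n"))
        for rep in range(12):
            peds = []
            for i in range(40):
                ped = sib_pair()
                ped.family_id = f"F{i}"
                ped._index = {m.person_id: k
                              for k, m in enumerate(ped.members)}
                for m in ped.members:
                    m.phenotypes["y"] = float(rng.normal())
                peds.append(ped)
            fd = prepare_fit_data(peds, mm)
            est, _ = fit_univariate_vc(fd, 0, seed=rep)
            sigma_p.append(est[1])  # (intercept, sigma_p, sigma_e)
        sigma_p = np.array(sigma_p)
        assert np.any(sigma_p < 0)
        assert abs(np.mean(sigma_p)) < 3 * np.std(sigma_p) / np.sqrt(len(sigma_p)) + 0.05

    def test_independent_traits_have_zero_cross_covariance(self):
        rng = np.random.default_rng(2)
        mm = build_model_matrices(parse_model(
            "A ~ <p,e>\nB ~ <p,e>\ncov(A,B,p)\ncov(A,B,e)\n"))
        peds = []
        for i in range(150):
            ped = sib_pair()
            ped.family_id = f"F{i}"
            for m in ped.members:
                m.phenotypes["A"] = float(rng.normal())
                m.phenotypes["B"] = float(rng.normal())
            peds.append(ped)
        sat = saturated_estimates(peds, mm)
        by = dict(zip(sat.labels, sat.s))
        se = dict(zip(sat.labels, sat.se()))
        for c in ("p", "e"):
            assert abs(by[f"cov(A,B,{c})"]) < 3 * se[f"cov(A,B,{c})"] + 0.05

    def test_duplicated_trait_cross_equals_variance(self):
        """A perfectly duplicated trait drives the correlation to 1."""
        rng = np.random.default_rng(3)
        mm = build_model_matrices(parse_model(
            "A ~ <e>\nB ~ <e>\ncov(A,B,e)\n"))
        peds = []
        for i in range(60):
            ped = sib_pair()
            ped.family_id = f"F{i}"
            for m in ped.members:
                v = float(rng.normal())
                m.phenotypes["A"] = v
                m.phenotypes["B"] = v
            peds.append(ped)
        fd = prepare_fit_data(peds, mm)
        ua, _ = fit_univariate_vc(fd, 0)
        ub, _ = fit_univariate_vc(fd, 1)
        cross, _ = fit_bivariate_vc(fd, 0, 1, ua, ub)
        assert cross[0] == pytest.approx(ua[1], rel=0.02)

    def test_sandwich_matches_classical_iid_variance(self):
        """For an iid normal mean, Gamma[mean,mean] ~ sigma^2 / N."""
        rng = np.random.default_rng(4)
        n = 500
        peds = _singleton_peds(rng, n, with_cov=False)
        y = rng.normal(2.0, 1.5, size=n)
        for p, yi in zip(peds, y):
            p.members[0].phenotypes["y"] = float(yi)
        mm = build_model_matrices(parse_model("y ~ <e>\n"))
        sat = saturated_estimates(peds, mm)
        i = sat.labels.index("mean(y)")
        classical = np.var(y) / n
        assert sat.Gamma[i, i] == pytest.approx(classical, rel=0.1)

    def test_permutation_invariance(self):
        cfg = SimulationConfig(model="y ~ <p,e>\n", theta_true=1.0,
                               structures="nuclear75", n_pedigrees=30, seed=8)
        data = simulate_dataset(cfg)
        mm = data.mm
        sat1 = saturated_estimates(data.peds, mm)
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(len(data.peds)))
        sat2 = saturated_estimates([data.peds[i] for i in perm], mm)
        assert np.allclose(sat1.s, sat2.s, atol=1e-6)
        assert np.allclose(sat1.Gamma, sat2.Gamma, atol=1e-6)


class TestEngineAgreement:
    def test_dense_and_eigen_paths_agree(self):
        """The rotated fast path and the dense path are the same likelihood."""
        from pedsem.estimation import (_BivDense, _BivEigen, _UniDense,
                                       _UniEigen)

        cfg = SimulationConfig(model="A ~ <p,e>\nB ~ <p,e>\n"
                                     "cov(A,B,p)\ncov(A,B,e)\n",
                               theta_true={"cov(A,B,p)": 0.4,
                                           "cov(A,B,e)": 0.2},
                               structures="extended5", n_pedigrees=10,
                               seed=17)
        data = simulate_dataset(cfg)
        fd = prepare_fit_data(data.peds, data.mm)
        assert fd.eigen is not None
        rng = np.random.default_rng(0)
        for trait in (0, 1):
            ue = _UniEigen(fd, trait, ascertained=False)
            ud = _UniDense(fd, trait, ascertained=False)
            for _ in range(3):
                x = np.array([0.3, 1.2, 0.8]) \
                    + 0.2 * rng.standard_normal(3)
                fe, ge = ue.value_grad(x)
                fdv, gd = ud.value_grad(x)
                assert fe == pytest.approx(fdv, rel=1e-9)
                assert np.allclose(ge, gd, atol=1e-7)
                assert np.allclose(ue.scores(x), ud.scores(x), atol=1e-7)
        be = _BivEigen(fd, 0, 1, ascertained=False)
        bd = _BivDense(fd, 0, 1, ascertained=False)
        ui = np.array([0.9, 1.1, 0.9])
        uj = np.array([1.1, 0.9, 1.2])
        cross = np.array([0.3, 0.15])
        fe, ge = be.value_grad(ui, uj, cross)
        fdv, gd = bd.value_grad(ui, uj, cross)
        assert fe == pytest.approx(fdv, rel=1e-9)
        assert np.allclose(ge, gd, atol=1e-7)
        assert np.allclose(be.scores(ui, uj, cross),
                           bd.scores(ui, uj, cross), atol=1e-7)

    def test_three_component_household_model_end_to_end(self):
        """Polygenic + household + environment fit on the dense path."""
        cfg = SimulationConfig(model="y ~ <p,c,e>\n",
                               theta_true={"var(y,p)": 1.0, "var(y,c)": 0.8,
                                           "var(y,e)": 1.2, "mean(y)": 0.5},
                               structures="nuclear75", n_pedigrees=150,
                               seed=23)
        data = simulate_dataset(cfg)
        fd = prepare_fit_data(data.peds, data.mm)
        assert fd.eigen is None  # three components force the dense engine
        fm = fit_model(data.peds, data.mm, seed=0, check_ident=False,
                       compute_indices=False)
        by = dict(zip(fm.param_names, fm.theta))
        se = dict(zip(fm.param_names, fm.se))
        for name, truth in [("var(y,p)", 1.0), ("var(y,c)", 0.8),
                            ("var(y,e)", 1.2), ("mean(y)", 0.5)]:
            assert abs(by[name] - truth) < 4 * se[name] + 0.05, name


class TestAscertainmentConditioning:
    def test_conditioning_reduces_intercept_bias(self):
        """Stage-1 intercepts on ascertained data: conditioning de-biases."""
        mm = build_model_matrices(parse_model("y ~ <p,e>\n"))
        cfg = SimulationConfig(
            model="y ~ <p,e>\n", theta_true=1.0, structures="nuclear75",
            n_pedigrees=40, ascertainment={"prevalence": 0.1,
                                           "proband_probability": 0.5})
        wins = 0
        biases = []
        reps = 30
        for rep in range(reps):
            data = simulate_dataset(cfg, seed=100 + rep)
            fd_u = prepare_fit_data(data.peds, mm)
            est_u, _ = fit_univariate_vc(fd_u, 0, ascertained=False)
            est_c, _ = fit_univariate_vc(fd_u, 0, ascertained=True)
            b_u, b_c = est_u[0] - 1.0, est_c[0] - 1.0
            biases.append((b_u, b_c))
            if abs(b_c) < abs(b_u):
                wins += 1
        b_u, b_c = np.mean(biases, axis=0)
        # uncorrected intercepts are systematically inflated
        assert b_u > 0.1
        assert abs(b_c) < b_u / 2
        # sign test: conditioning wins in the clear majority of replicates
        assert wins >= int(0.75 * reps)


class TestStageTwo:
    def test_saturated_model_exact_fit(self):
        rng = np.random.default_rng(5)
        text = "A ~ <p,e>\nB ~ <p,e>\ncov(A,B,p)\ncov(A,B,e)\n"
        cfg = SimulationConfig(model=text, theta_true={"cov(A,B,p)": 0.5,
                                                       "cov(A,B,e)": 0.3},
                               structures="nuclear75", n_pedigrees=40, seed=9)
        data = simulate_dataset(cfg)
        fm = fit_model(data.peds, data.mm, seed=0, check_ident=False)
        assert fm.Q_min < 1e-10
        assert fm.df == 0
        # theta reproduces the stage-1 moments exactly
        by_moment = dict(zip(fm.sat.labels, fm.sat.s))
        for name, est in zip(fm.param_names, fm.theta):
            assert est == pytest.approx(by_moment[name], abs=1e-6)
        assert np.isnan(fm.fit.unadjusted[2])  # indices NA at df 0

    def test_starting_values_deterministic_and_elitist(self, example_models):
        mm = example_models["association"]
        rng = np.random.default_rng(6)
        s = np.ones(len(moment_labels(mm))) + 0.1 * rng.standard_normal(18)
        W, half = _weight_matrix(np.eye(18) * 0.01, "diag")

        def Q(theta):
            from pedsem.moments import moment_map
            try:
                r = half(s - moment_map(mm, theta))
            except Exception:
                return np.inf
            return float(r @ r)

        starts1 = generate_starting_values(mm, s, Q, seed=3)
        starts2 = generate_starting_values(mm, s, Q, seed=3)
        assert all(np.array_equal(a, b) for a, b in zip(starts1, starts2))
        center = starts1[-1] if len(starts1) > 5 else starts1[0]
        assert Q(starts1[0]) <= Q(center) + 1e-12

    def test_wald_outputs_consistent(self):
        cfg = SimulationConfig(model="y ~ <p,e>\n", theta_true=1.0,
                               structures="nuclear75", n_pedigrees=60, seed=10)
        data = simulate_dataset(cfg)
        fm = fit_model(data.peds, data.mm, seed=0, check_ident=False,
                       compute_indices=False)
        assert np.all(fm.se >= 0)
        assert np.all((fm.p >= 0) & (fm.p <= 1))
        assert np.allclose(fm.se, np.sqrt(np.diag(fm.vcov)))
        assert fm.Q_min >= 0

    def test_full_weight_runs(self):
        cfg = SimulationConfig(model="y ~ <p,e>\n", theta_true=1.0,
                               structures="nuclear75", n_pedigrees=60, seed=12)
        data = simulate_dataset(cfg)
        fm = fit_model(data.peds, data.mm, seed=0, weight="full",
                       check_ident=False, compute_indices=False)
        assert fm.converged
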