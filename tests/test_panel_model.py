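"""Transition-model estimation against closed forms and independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import vaxdyn as v
from vaxdyn.panel_model import (
    ClusterPlan,
    ModelSpec,
    _penalized_loglik,
    build_design,
    cluster_robust_vcov,
    fit_weighted_logit,
    predict_transition_probs,
)


def _table(n=60, seed=0, n_units=3, n_rounds=4, weights=None):
    """Small analysis table with one continuous covariate ``x``."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "household_id": [f"H{i}" for i in range(n)],
            "round": rng.integers(1, n_rounds + 1, n),
            "unit_id": rng.choice([f"U{k}" for k in range(1, n_units + 1)], n),
            "x": rng.normal(0, 1, n),
            "response_lag": rng.integers(0, 2, n),
            "weight": weights if weights is not None else np.ones(n),
        }
    )
    eta = 0.3 + 0.8 * df.x + df.response_lag * (0.5 - 0.2 * df.x)
    df["response"] = (rng.random(n) < expit(eta)).astype(int)
    return df


SPEC_X = ModelSpec(covariate_names=("x",))


class TestBuildDesign:
    def test_column_count_one_covariate_three_units_four_rounds(self):
        """2 (x block) + 2 (lag interaction) + 2 unit + 3 round dummies = 9."""
        df = _table(n=400, n_units=3, n_rounds=4)
        d = build_design(df, SPEC_X)
        assert d.X.shape[1] == 9
        assert d.colnames[0] == "theta0:intercept"

    def test_interaction_block_zero_or_copy_of_x_block(self):
        df = _table(n=100)
        d = build_design(df, SPEC_X)
        lag = df.sort_values(["household_id", "round"]).response_lag  # noqa: F841
        x_block, g_block = d.X[:, :2], d.X[:, 2:4]
        y_lag = df.response_lag.to_numpy()
        assert np.allclose(g_block[y_lag == 0], 0.0)
        assert np.allclose(g_block[y_lag == 1], x_block[y_lag == 1])

    def test_constant_covariate_rejected(self):
        df = _table(n=50)
        df["x"] = 1.7
        with pytest.raises(ValueError, match="constant"):
            build_design(df, SPEC_X)

    def test_nonpositive_weights_rejected(self):
        df = _table(n=50)
        df.loc[0, "weight"] = 0.0
        with pytest.raises(ValueError, match="positive"):
            build_design(df, SPEC_X)


class TestFit:
    def test_balanced_responses_give_half_probability(self):
        """Symmetric data: intercept 0, slope 0, fitted probability one half."""
        df = pd.DataFrame(
            {
                "household_id": [f"H{i}" for i in range(8)],
                "round": 2,
                "unit_id": "U1",
                "x": [-1, -1, 1, 1, -1, -1, 1, 1],
                "response_lag": 0,
                "weight": 1.0,
                # each x value sees one success and one failure
                "response": [0, 1, 0, 1, 0, 1, 0, 1],
            }
        )
        spec = ModelSpec(
            covariate_names=("x",), include_unit_fe=False, include_round_fe=False,
            include_lag_interaction=False,
        )
        f = fit_weighted_logit(build_design(df, spec), spec)
        assert f.theta0[0] == pytest.approx(0.0, abs=1e-8)
        assert f.theta0[1] == pytest.approx(0.0, abs=1e-8)

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(4)
        w = rng.uniform(0.5, 2.0, 200)
        df1 = _table(n=200, seed=5, weights=w)
        df2 = df1.copy()
        df2["weight"] = 2.0 * w
        f1 = fit_weighted_logit(build_design(df1, SPEC_X), SPEC_X)
        f2 = fit_weighted_logit(build_design(df2, SPEC_X), SPEC_X)
        np.testing.assert_allclose(f1.theta0, f2.theta0, atol=1e-10)
        np.testing.assert_allclose(f1.gamma, f2.gamma, atol=1e-10)

    def test_matches_grid_search_oracle(self):
        """20-row, 2-parameter fit agrees with a dense grid maximizer to 1e-4."""
        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            {
                "household_id": [f"H{i}" for i in range(20)],
                "round": 2,
                "unit_id": "U1",
                "x": rng.normal(0, 1, 20),
                "response_lag": 0,
                "weight": 1.0,
            }
        )
        df["response"] = (rng.random(20) < expit(0.4 + 0.9 * df.x)).astype(int)
        spec = ModelSpec(
            covariate_names=("x",), include_unit_fe=False, include_round_fe=False,
            include_lag_interaction=False,
        )
        design = build_design(df, spec)
        f = fit_weighted_logit(design, spec)

        # iterative grid refinement, independent of the Newton path
        def ll(b0, b1):
            return _penalized_loglik(design, np.array([b0, b1]), 0.0)

        c0, c1, width = 0.0, 0.0, 4.0
        for _ in range(12):
            b0s = np.linspace(c0 - width, c0 + width, 41)
            b1s = np.linspace(c1 - width, c1 + width, 41)
            vals = np.array([[ll(a, b) for b in b1s] for a in b0s])
            i, j = np.unravel_index(np.argmax(vals), vals.shape)
            c0, c1, width = b0s[i], b1s[j], width / 4
        assert f.beta_std[0] == pytest.approx(c0, abs=1e-4)
        assert f.beta_std[1] == pytest.approx(c1, abs=1e-4)

    def test_matches_statsmodels_glm(self):
        """Unpenalized weighted fit agrees with the GLM IRLS implementation."""
        import statsmodels.api as sm

        rng = np.random.default_rng(10)
        w = rng.uniform(0.5, 2.0, 300)
        df = _table(n=300, seed=11, weights=w / w.mean())
        spec = ModelSpec(covariate_names=("x",), include_unit_fe=False, include_round_fe=False)
        design = build_design(df, spec)
        f = fit_weighted_logit(design, spec)
        glm = sm.GLM(
            design.y, design.X, family=sm.families.Binomial(), var_weights=design.w
        ).fit()
        np.testing.assert_allclose(f.beta_std, glm.params, atol=1e-7)

    def test_penalized_loglik_nondecreasing(self):
        df = _table(n=500, seed=13, n_units=4, n_rounds=5)
        f = fit_weighted_logit(build_design(df, SPEC_X), SPEC_X)
        trace = np.array(f.ll_trace)
        assert (np.diff(trace) >= -1e-12).all()

    def test_perfect_separation_raises_with_diagnostics(self):
        df = _table(n=80, seed=14)
        df["response"] = (df.x > 0).astype(int)  # perfectly separated on x
        spec = ModelSpec(covariate_names=("x",), include_unit_fe=False, include_round_fe=False)
        with pytest.raises(v.ConvergenceError) as exc:
            fit_weighted_logit(build_design(df, spec), spec)
        assert "max_score" in exc.value.diagnostics

    def test_large_coefficient_warning_names_column(self):
        """A converged fit with an implausibly large standardized coefficient
        triggers the separation warning naming the column."""
        rng = np.random.default_rng(17)
        n = 400
        df = pd.DataFrame(
            {
                "household_id": [f"H{i}" for i in range(n)],
                "round": 2,
                "unit_id": "U1",
                "x": rng.normal(0, 1, n),
                "response_lag": 0,
                "weight": 1.0,
            }
        )
        # extreme but not perfect separation: a handful of contrarian rows
        df["response"] = (df.x > 0).astype(int)
        flip = rng.choice(n, 3, replace=False)
        df.loc[flip, "response"] = 1 - df.loc[flip, "response"]
        spec = ModelSpec(
            covariate_names=("x",), include_unit_fe=False, include_round_fe=False,
            include_lag_interaction=False,
        )
        with pytest.warns(RuntimeWarning, match="x"):
            fit_weighted_logit(build_design(df, spec), spec)

    def test_equivariance_under_rescaling(self):
        """Scaling x by 10 divides its coefficients by 10, predictions fixed."""
        df = _table(n=400, seed=15)
        f1 = fit_weighted_logit(build_design(df, SPEC_X), SPEC_X)
        df2 = df.copy()
        df2["x"] = 10.0 * df2["x"]
        f2 = fit_weighted_logit(build_design(df2, SPEC_X), SPEC_X)
        assert f2.theta0[1] == pytest.approx(f1.theta0[1] / 10.0, rel=1e-8)
        assert f2.gamma[1] == pytest.approx(f1.gamma[1] / 10.0, rel=1e-8)
        x0 = 0.37
        p1 = predict_transition_probs(f1, [x0])
        p2 = predict_transition_probs(f2, [10.0 * x0])
        assert p1 == pytest.approx(p2, abs=1e-10)


class TestClusterVcov:
    def _fit(self, df, spec):
        d = build_design(df, spec)
        return fit_weighted_logit(d, spec), d

    def test_singleton_clusters_reduce_to_hc_sandwich(self):
        """One observation per cluster on both dimensions = plain HC sandwich
        (up to the CR1 factor, removed here by G = n)."""
        df = _table(n=120, seed=20)
        df["unit_id"] = [f"U{i}" for i in range(120)]
        df["round"] = np.arange(120)
        spec = ModelSpec(
            covariate_names=("x",), include_unit_fe=False, include_round_fe=False,
            ridge_penalty=0.0,
        )
        f, d = self._fit(df, spec)
        V = cluster_robust_vcov(f, d)
        # direct heteroskedasticity-robust sandwich
        p = expit(d.X @ f.beta_std)
        g = d.X * (d.w * (d.y - p))[:, None]
        H = d.X.T @ (d.X * (d.w * p * (1 - p))[:, None])
        bread = np.linalg.inv(H)
        n = len(d.y)
        hc = bread @ ((n / (n - 1)) * g.T @ g) @ bread
        hc = f.transform @ hc @ f.transform.T
        np.testing.assert_allclose(V, hc, rtol=1e-8, atol=1e-12)

    def test_constant_round_dimension_collapses_to_one_way(self):
        """If rounds coincide with units, inclusion-exclusion collapses."""
        df = _table(n=150, seed=21, n_units=5)
        df["round"] = df["unit_id"].str.replace("U", "").astype(int)  # same partition
        spec = ModelSpec(covariate_names=("x",), include_unit_fe=False, include_round_fe=False, ridge_penalty=0.0)
        f, d = self._fit(df, spec)
        V = cluster_robust_vcov(f, d)
        # one-way oracle by unit, independently coded with explicit loops
        p = expit(d.X @ f.beta_std)
        g = d.X * (d.w * (d.y - p))[:, None]
        H = d.X.T @ (d.X * (d.w * p * (1 - p))[:, None])
        bread = np.linalg.inv(H)
        labels = d.unit_labels
        G = len(set(labels))
        meat = np.zeros((d.X.shape[1], d.X.shape[1]))
        for u in set(labels):
            s = g[labels == u].sum(axis=0)
            meat += np.outer(s, s)
        Vo = bread @ ((G / (G - 1)) * meat) @ bread
        Vo = f.transform @ Vo @ f.transform.T
        np.testing.assert_allclose(V, Vo, rtol=1e-8, atol=1e-12)

    def test_two_way_matches_independent_implementation(self):
        df = _table(n=200, seed=22, n_units=4, n_rounds=4)
        spec = ModelSpec(covariate_names=("x",), include_unit_fe=False, include_round_fe=False, ridge_penalty=0.0)
        f, d = self._fit(df, spec)
        V = cluster_robust_vcov(f, d)

        p = expit(d.X @ f.beta_std)
        g = d.X * (d.w * (d.y - p))[:, None]
        H = d.X.T @ (d.X * (d.w * p * (1 - p))[:, None])
        bread = np.linalg.inv(H)

        def meat_for(labels):
            labs = list(labels)
            uniq = sorted(set(labs))
            G = len(uniq)
            m = np.zeros((d.X.shape[1], d.X.shape[1]))
            for u in uniq:
                s = np.zeros(d.X.shape[1])
                for i, lab in enumerate(labs):
                    if lab == u:
                        s += g[i]
                m += np.outer(s, s)
            return (G / (G - 1)) * m

        inter = [f"{a}|{b}" for a, b in zip(d.unit_labels, d.round_labels)]
        Vo = bread @ (meat_for(d.unit_labels) + meat_for(d.round_labels) - meat_for(inter)) @ bread
        evals, evecs = np.linalg.eigh(0.5 * (Vo + Vo.T))
        Vo = (evecs * np.clip(evals, 0, None)) @ evecs.T
        Vo = f.transform @ Vo @ f.transform.T
        np.testing.assert_allclose(V, 0.5 * (Vo + Vo.T), rtol=1e-7, atol=1e-10)

    def test_single_cluster_errors(self):
        df = _table(n=50, seed=23, n_units=1)
        spec = ModelSpec(covariate_names=("x",), include_unit_fe=False, include_round_fe=False)
        f, d = self._fit(df, spec)
        with pytest.raises(ValueError, match="single cluster"):
            cluster_robust_vcov(f, d)


class TestPredict:
    def _null_fit(self, theta0, gamma):
        m = len(theta0) - 1
        return v.FitResult(
            covariate_names=[f"c{i}" for i in range(m)],
            theta0=np.asarray(theta0, dtype=float),
            gamma=np.asarray(gamma, dtype=float),
            unit_effects={},
            round_effects={},
            vcov=np.eye(2 * (m + 1)),
            param_names=[],
            n_obs=0,
            log_likelihood=0.0,
            converged=True,
            n_iter=0,
            beta_std=np.zeros(2 * (m + 1)),
            transform=np.eye(2 * (m + 1)),
        )

    def test_all_zero_coefficients(self):
        f = self._null_fit([0.0, 0.0], [0.0, 0.0])
        assert predict_transition_probs(f, [1.3]) == pytest.approx((0.5, 0.5))

    def test_reproduces_headline_matrix_pattern(self):
        """Coefficients placed at logit(0.35) and logit(0.96) give exactly the
        printed no->yes / yes->yes probabilities."""
        f = self._null_fit([logit(0.35), 0.0], [logit(0.96) - logit(0.35), 0.0])
        p01, p11 = predict_transition_probs(f, [0.0])
        assert p01 == pytest.approx(0.35)
        assert p11 == pytest.approx(0.96)

    def test_monotone_in_positive_covariate(self):
        f = self._null_fit([0.1, 0.7], [0.2, 0.1])
        p_low = predict_transition_probs(f, [0.0])
        p_high = predict_transition_probs(f, [1.0])
        assert p_high[0] > p_low[0] and p_high[1] > p_low[1]

    def test_dimension_mismatch(self):
        f = self._null_fit([0.0, 0.0], [0.0, 0.0])
        with pytest.raises(ValueError, match="shape"):
            predict_transition_probs(f, [1.0, 2.0])

    def test_theta1_identity(self):
        f = self._null_fit([0.2, -0.4], [0.1, 0.5])
        np.testing.assert_array_equal(f.theta1, f.theta0 + f.gamma)


class TestFitSerialization:
    def test_fit_json_roundtrip(self, tmp_path):
        df = _table(n=200, seed=30)
        spec = ModelSpec(covariate_names=("x",))
        d = build_design(df, spec)
        f = fit_weighted_logit(d, spec)
        p = tmp_path / "fit.json"
        f.to_json(p)
        back = v.FitResult.from_json(p)
        np.testing.assert_allclose(back.theta0, f.theta0)
        np.testing.assert_allclose(back.vcov, f.vcov)
        assert back.unit_effects == f.unit_effects
        assert back.round_effects == {int(k): val for k, val in f.round_effects.items()}
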