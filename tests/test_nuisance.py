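import numpy as np
import pytest
import statsmodels.api as sm
from scipy.special import logit

from longiv.dgm import DGMParams, simulate
from longiv.errors import DegenerateFitError, InstabilityWarning
from longiv.nuisance import (
    PmfModel,
    delta_from_model,
    fit_instrument_model,
    fit_logistic,
    fit_marginal_treatment_model,
    fit_treatment_model,
)
from longiv.panel_data import HistorySpec, PanelData


def _panel(Z, A, Y=None, L=None):
    Z = np.atleast_2d(Z).T if np.ndim(Z) == 1 else Z
    A = np.atleast_2d(A).T if np.ndim(A) == 1 else A
    return PanelData(Y=np.zeros(Z.shape[0]) if Y is None else Y, A=A, Z=Z, L=L)


def _two_point_treatment_model(n, p_z0, p_z1, z):
    """Hand-built model with P(A=1|Z=0)=p_z0, P(A=1|Z=1)=p_z1."""
    c0 = logit(p_z0)
    c1 = logit(p_z1) - c0
    X = np.column_stack([np.ones(n), z])
    from scipy.special import expit

    return PmfModel(
        target="A", period=1, design_cols=["const", "Z1"],
        coef=np.array([c0, c1]), X=X, fitted=expit(X @ np.array([c0, c1])),
        z_index=1,
    )


class TestLogisticFits:
    def test_intercept_only_equals_sample_mean(self):
        panel = _panel(Z=np.array([0, 1, 0, 1]), A=np.array([0, 0, 1, 1]))
        model = fit_instrument_model(panel, 1)
        assert np.allclose(model.fitted, 0.5, atol=1e-8)

    def test_marginal_model_pmf_at_observed(self):
        panel = _panel(Z=np.array([0, 1, 0, 1]), A=np.array([1, 1, 1, 0]))
        model = fit_marginal_treatment_model(panel, 1)
        pmf = model.pmf_observed(panel.A[:, 0].astype(float))
        assert np.allclose(pmf, [0.75, 0.75, 0.75, 0.25], atol=1e-8)

    def test_matches_statsmodels_glm(self, strong_panel):
        """Dual-route check of the Newton solver against statsmodels."""
        spec = HistorySpec(confounder_subset=(0,))
        for t in (1, 2, 3):
            model = fit_treatment_model(strong_panel, t, spec)
            ref = sm.GLM(
                strong_panel.A[:, t - 1], model.X, family=sm.families.Binomial()
            ).fit()
            assert np.allclose(model.coef, ref.params, atol=1e-6)
            assert np.allclose(model.fitted, ref.fittedvalues, atol=1e-8)

    def test_instrument_carryover_coefficient(self, big_panel):
        # the mechanism feeds Z_{t-1} into Z_t with log-odds 0.5
        model = fit_instrument_model(big_panel, 2)
        j = model.design_cols.index("Z1")
        assert model.coef[j] == pytest.approx(0.5, abs=0.05)

    def test_constant_response_errors(self):
        panel = _panel(Z=np.array([1, 1, 1, 1]), A=np.array([0, 1, 0, 1]))
        with pytest.raises(DegenerateFitError, match="Z1"):
            fit_instrument_model(panel, 1)

    def test_separation_errors(self):
        z = np.tile([0, 1], 50)
        panel = _panel(Z=z, A=z)  # A identical to Z: perfect separation
        with pytest.raises(DegenerateFitError, match="A1"):
            fit_treatment_model(panel, 1)

    def test_pmf_complement_identity(self, strong_panel):
        model = fit_treatment_model(strong_panel, 2, HistorySpec())
        ones = model.pmf_observed(np.ones(strong_panel.n))
        zeros = model.pmf_observed(np.zeros(strong_panel.n))
        assert np.all((ones > 0) & (ones < 1))
        assert np.allclose(ones + zeros, 1.0)

    def test_design_uses_only_past(self, strong_panel):
        model = fit_instrument_model(strong_panel, 2, HistorySpec())
        assert set(model.design_cols) == {"const", "A1", "Z1"}
        tmodel = fit_treatment_model(strong_panel, 2, HistorySpec())
        assert set(tmodel.design_cols) == {"const", "Z2", "A1", "Z1"}


class TestDelta:
    @pytest.mark.parametrize("a_obs,expected", [(1, 0.5), (0, -0.5)])
    def test_two_point_example(self, a_obs, expected):
        n = 8
        z = np.tile([0, 1], 4)
        model = _two_point_treatment_model(n, p_z0=0.3, p_z1=0.8, z=z)
        panel = _panel(Z=z, A=np.full(n, a_obs))
        d = delta_from_model(model, panel, 1)
        assert np.allclose(d.delta, expected, atol=1e-12)

    def test_null_instrument_gives_exact_zero_and_warns(self):
        n = 8
        z = np.tile([0, 1], 4)
        model = _two_point_treatment_model(n, p_z0=0.4, p_z1=0.4, z=z)
        model.coef[1] = 0.0  # exactly null effect of Z
        panel = _panel(Z=z, A=np.tile([0, 1], 4))
        with pytest.warns(InstabilityWarning, match="8 subject"):
            d = delta_from_model(model, panel, 1)
        assert np.all(d.delta == 0.0)
        assert d.n_unstable == n

    @pytest.mark.parametrize("alpha,strength", [(0.0, 0.5), (0.5, 0.6915)])
    def test_mean_delta_recovers_phi_alpha(self, alpha, strength):
        panel = simulate(DGMParams(alpha=alpha), n=100_000, seed=21)
        spec = HistorySpec(confounder_subset=(0,))
        deltas = []
        for t in (1, 2, 3):
            model = fit_treatment_model(panel, t, spec)
            deltas.append(np.mean(model.predict_with_z(1) - model.predict_with_z(0)))
        assert np.allclose(deltas, strength, atol=0.015)

    def test_constant_mode_is_constant(self, strong_panel):
        model = fit_treatment_model(strong_panel, 2, HistorySpec())
        d = delta_from_model(model, strong_panel, 2, mode="constant")
        assert len(np.unique(np.abs(d.delta))) == 1

    def test_requires_model_with_instrument(self, strong_panel):
        marginal = fit_marginal_treatment_model(strong_panel, 2)
        with pytest.raises(ValueError):
            delta_from_model(marginal, strong_panel, 2)


def test_fit_logistic_recovers_known_coefficients():
    rng = np.random.default_rng(3)
    n = 50_000
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    from scipy.special import expit

    truth = np.array([-0.3, 0.8])
    y = rng.random(n) < expit(X @ truth)
    coef = fit_logistic(X, y.astype(float))
    assert np.allclose(coef, truth, atol=0.05)
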