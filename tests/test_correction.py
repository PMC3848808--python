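"""Protocol bias-correction transforms: hand-computed oracles and invariants."""

import numpy as np
import pytest
from sklearn.base import clone

from conftest import make_null_model
from lvatlas.cohort import FRAMES, PopulationModel, generate_paired_cohort
from lvatlas.correction import (TRANSFORM_KINDS, ProtocolBiasCorrector,
                                apply_transform, fit_transform_variant)


def fit(kind, X, Y, **kw):
    est = ProtocolBiasCorrector(kind=kind, **kw)
    with pytest.warns(UserWarning):  # small training sets warn
        est.fit(np.asarray(X, float), np.asarray(Y, float))
    return est


# ---------------------------------------------------------------------------
# hand-computed three-case oracle: GRE = (1, 2, 3), SSFP = (2, 4, 6)
# ---------------------------------------------------------------------------

X3 = np.array([[1.0], [2.0], [3.0]])
Y3 = 2.0 * X3


def test_mle_zscore_three_case_hand_computation():
    """ML (divide-by-n) moments of the toy pairs, and the mapped values."""
    est = fit("mle_zscore", X3, Y3)
    assert est.mu_gre_[0] == pytest.approx(2.0)
    assert est.mu_ssfp_[0] == pytest.approx(4.0)
    assert est.sigma_gre_[0] == pytest.approx(np.sqrt(2.0 / 3.0))
    assert est.sigma_ssfp_[0] == pytest.approx(np.sqrt(8.0 / 3.0))
    # (1 - 2)/sqrt(2/3) * sqrt(8/3) + 4 = 2
    assert est.transform(np.array([1.0]))[0] == pytest.approx(2.0)
    # at the GRE mean the output is exactly the SSFP mean
    assert est.transform(np.array([2.0]))[0] == pytest.approx(4.0)


def test_slope_only_three_case():
    est = fit("slope_only", X3, Y3)
    assert est.slope_[0] == pytest.approx(28.0 / 14.0)
    assert est.intercept_[0] == 0.0


def test_identity_cohort_gives_identity_map():
    rng = np.random.default_rng(0)
    X = rng.normal(0.7, 0.1, (20, 6))
    est = ProtocolBiasCorrector("mle_zscore").fit(X, X.copy())
    np.testing.assert_allclose(est.mu_gre_, est.mu_ssfp_)
    np.testing.assert_allclose(est.sigma_gre_, est.sigma_ssfp_)
    np.testing.assert_allclose(est.transform(X), X, atol=1e-12)


def test_degenerate_equal_moments_is_identity():
    est = ProtocolBiasCorrector("mle_zscore")
    est.n_features_in_ = 3
    est.n_train_ = 10
    est.mu_gre_ = est.mu_ssfp_ = np.array([1.0, 2.0, 3.0])
    est.sigma_gre_ = est.sigma_ssfp_ = np.array([0.5, 0.5, 0.5])
    est.fallback_mask_ = np.zeros(3, bool)
    x = np.array([0.3, 2.5, 9.0])
    np.testing.assert_allclose(est.transform(x), x, atol=1e-14)


def test_slope_intercept_recovers_exact_linear_map():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(30, 4))
    Y = 3.0 * X - 1.0
    est = ProtocolBiasCorrector("slope_intercept").fit(X, Y)
    np.testing.assert_allclose(est.slope_, 3.0, atol=1e-12)
    np.testing.assert_allclose(est.intercept_, -1.0, atol=1e-12)


def test_identity_intercept_is_mean_difference():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(25, 3))
    Y = X + rng.normal(size=(25, 3))
    est = ProtocolBiasCorrector("identity_intercept").fit(X, Y)
    np.testing.assert_allclose(est.intercept_, (Y - X).mean(axis=0), atol=1e-12)
    np.testing.assert_allclose(est.slope_, 1.0)


def test_nodal_grouped_recovers_blockwise_linear_map():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(40, 8))
    A1, A2 = rng.normal(size=(4, 4)), rng.normal(size=(4, 4))
    c = rng.normal(size=8)
    Y = np.hstack([X[:, :4] @ A1.T, X[:, 4:] @ A2.T]) + c
    est = ProtocolBiasCorrector("nodal_grouped").fit(X, Y)
    np.testing.assert_allclose(est.block_matrices_[0], A1, atol=1e-9)
    np.testing.assert_allclose(est.block_matrices_[1], A2, atol=1e-9)
    np.testing.assert_allclose(est.block_intercepts_.ravel(), c, atol=1e-9)
    np.testing.assert_allclose(est.transform(X), Y, atol=1e-9)


def test_pseudo_inverse_interpolates_training_data():
    """With more parameters than cases the global map fits training exactly."""
    rng = np.random.default_rng(4)
    X = rng.normal(size=(10, 30))
    Y = rng.normal(size=(10, 30))
    est = ProtocolBiasCorrector("pseudo_inverse_global").fit(X, Y)
    np.testing.assert_allclose(est.transform(X), Y, atol=1e-8)


# ---------------------------------------------------------------------------
# invariants
# ---------------------------------------------------------------------------

def test_training_population_moment_matching(paired46):
    """Corrected training GRE set reproduces SSFP mean and ML SD exactly."""
    for frame in FRAMES:
        est = fit_transform_variant(paired46, "mle_zscore", frame)
        corrected = est.transform(paired46.gre[frame])
        np.testing.assert_allclose(corrected.mean(axis=0), est.mu_ssfp_,
                                   rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(corrected.std(axis=0), est.sigma_ssfp_,
                                   rtol=1e-10)


def test_affine_equivariance():
    """Rescaling all values by a > 0 rescales the corrected output by a."""
    rng = np.random.default_rng(5)
    X = rng.normal(1.0, 0.2, (30, 5))
    Y = rng.normal(1.1, 0.25, (30, 5))
    a = 3.7
    out1 = ProtocolBiasCorrector("mle_zscore").fit(X, Y).transform(X[:3]) * a
    out2 = ProtocolBiasCorrector("mle_zscore").fit(a * X, a * Y).transform(a * X[:3])
    np.testing.assert_allclose(out1, out2, rtol=1e-10)


def test_oracle_recovery_of_generative_parameters(pop):
    """With zero noise the fit recovers the true (s, delta) as n grows."""
    p = pop.n_parameters
    model = PopulationModel(
        prolate=pop.prolate, grid_shape=pop.grid_shape, mu_max=pop.mu_max,
        mean={fr: pop.mean[fr].copy() for fr in FRAMES},
        param_sd={fr: np.full(p, 0.03) for fr in FRAMES},
        bias_delta={fr: pop.bias_delta[fr].copy() for fr in FRAMES},
        bias_scale={fr: pop.bias_scale[fr].copy() for fr in FRAMES},
        noise_sd={fr: np.zeros(p) for fr in FRAMES},
        name="noise-free")
    coh = generate_paired_cohort(model, 2000, seed=8)
    est = fit_transform_variant(coh, "mle_zscore", "ED")
    ratio = est.sigma_ssfp_ / est.sigma_gre_
    np.testing.assert_allclose(ratio, model.bias_scale["ED"], rtol=0.02)
    np.testing.assert_allclose(est.mu_ssfp_ - est.mu_gre_,
                               model.bias_delta["ED"], atol=0.002)


def test_zero_sigma_raises_naming_parameter():
    X = np.ones((12, 3))
    X[:, 0] = np.arange(12)
    Y = X + 1.0
    with pytest.raises(ValueError, match=r"\[1, 2\]"):
        ProtocolBiasCorrector("mle_zscore").fit(X, Y)
    est = ProtocolBiasCorrector("mle_zscore", fallback_intercept=True).fit(X, Y)
    out = est.transform(X)
    np.testing.assert_allclose(out[:, 1:], Y[:, 1:].mean(axis=0)[None].repeat(12, 0))


def test_degenerate_design_raises_for_slope_families():
    X = np.ones((12, 2))
    Y = X * 2.0
    with pytest.raises(ValueError, match="degenerate design"):
        ProtocolBiasCorrector("slope_intercept").fit(X, Y)


def test_parameter_count_mismatch_rejected(paired12):
    est = fit_transform_variant(paired12, "mle_zscore", "ED")
    with pytest.raises(ValueError, match="does not match"):
        est.transform(np.zeros(5))


def test_sklearn_estimator_interface():
    est = ProtocolBiasCorrector("slope_intercept", block_size=8)
    params = est.get_params()
    assert params["kind"] == "slope_intercept"
    assert params["block_size"] == 8
    est2 = clone(est).set_params(kind="mle_zscore")
    assert est2.get_params()["kind"] == "mle_zscore"
    rng = np.random.default_rng(6)
    X, Y = rng.normal(size=(15, 4)), rng.normal(size=(15, 4))
    out = est2.fit_transform(X, Y)  # TransformerMixin path
    np.testing.assert_allclose(out, est2.transform(X))


def test_all_kinds_fit_and_apply(paired12):
    for kind in TRANSFORM_KINDS:
        est = fit_transform_variant(paired12, kind, "ED")
        out = apply_transform(est, paired12.gre["ED"])
        assert out.shape == paired12.gre["ED"].shape
        assert np.all(np.isfinite(out))
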