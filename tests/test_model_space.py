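"""Subset enumeration, RMSE/AIC, fitting, sweeps and the analyses on top."""

import numpy as np
import pytest

import enhancerkit as ek
from enhancerkit.model_space import (FitConfig, aic, enumerate_subsets,
                                     fit_model, hb_threshold_histogram,
                                     parameter_landscape, rearrangement_test,
                                     rmse, sweep_model_space)
from enhancerkit.motif import BindingSite, EnhancerAnnotation
from enhancerkit.thermo import ExpressionProfile, predict_expression


def _profile(grid, values):
    return ExpressionProfile(np.asarray(grid, float),
                             np.asarray(values, float))


def test_enumerate_subsets_counts(truth):
    subs = enumerate_subsets(truth.annotation)  # 5 sites
    assert len(subs) == 32
    assert subs[0] == ()
    assert len(set(subs)) == 32
    # binary counting order: subset index i contains site j iff bit j set
    ids = truth.annotation.site_ids
    for i in (1, 2, 3, 21):
        assert subs[i] == tuple(ids[j] for j in range(5) if i >> j & 1)


def test_enumerate_subsets_empty_annotation():
    ann = EnhancerAnnotation("none", 10, [])
    assert enumerate_subsets(ann) == [()]


def test_rmse_examples():
    g = [0.0, 1.0, 2.0]
    assert rmse(_profile(g, [0, 0, 1]), _profile(g, [0, 0, 1])) == 0.0
    assert rmse(_profile(g, [0.3, 0.3, 0.3]),
                _profile(g, [0.1, 0.1, 0.1])) == pytest.approx(0.2)
    assert rmse(_profile(g, [0, 1, 1]),
                _profile(g, [0, 0, 1])) == pytest.approx(np.sqrt(1 / 3))
    with pytest.raises(ValueError):
        rmse(_profile(g, [0, 0, 0]), _profile([0, 1, 2, 3], [0, 0, 0, 0]))


def test_aic_formula():
    assert aic(1.0, 1, 0) == pytest.approx(0.0)
    # linear in the parameter count: doubling k adds 2*dk
    assert aic(0.5, 10, 8) - aic(0.5, 10, 4) == pytest.approx(8.0)
    assert aic(0.1, 86, 10) == pytest.approx(86 * np.log(0.01) + 20)
    with pytest.warns(UserWarning):
        assert aic(0.0, 10, 2) == float("-inf")


def _two_site_setup(gradients):
    a = BindingSite("BCD", 10, "+", 8, 5.0, -9.0, "activator")
    r = BindingSite("KR", 40, "+", 8, 4.0, -9.0, "repressor")
    ann = EnhancerAnnotation("toy2", 100, [a, r])
    params = ek.ThermoParams(k={a.site_id: 6.0, r.site_id: 2.0},
                             q={(r.site_id, a.site_id): 0.25})
    clean = predict_expression(ann, params, gradients)
    return ann, params, clean


def test_fit_recovers_noiseless_truth(gradients):
    ann, params, clean = _two_site_setup(gradients)
    cfg = FitConfig(n_starts=3, max_nfev=800, fit_c=False, fit_q=True,
                    seed=1)
    fit = fit_model(tuple(ann.site_ids), ann, clean, gradients, cfg)
    assert fit.rmse <= 1e-3
    assert fit.n_params == 3  # two K, one Q


def test_fit_empty_subset(gradients):
    ann, _, clean = _two_site_setup(gradients)
    fit = fit_model((), ann, clean, gradients, FitConfig())
    assert np.allclose(fit.predictions.mean, 0.0)
    assert fit.rmse == pytest.approx(float(np.sqrt(np.mean(clean.mean**2))))
    assert fit.n_params == 0


def test_fit_zero_observation(gradients):
    ann, _, clean = _two_site_setup(gradients)
    zero = _profile(clean.ap_grid, np.zeros_like(clean.mean))
    fit = fit_model(tuple(ann.site_ids), ann, zero, gradients,
                    FitConfig(fit_c=False, fit_q=False, seed=0))
    assert fit.rmse <= 1e-6  # all-activator-K -> 0 is feasible and exact


def test_fit_matches_grid_search_oracle(gradients):
    """1-parameter model: optimizer matches a dense K grid search."""
    a = BindingSite("BCD", 10, "+", 8, 5.0, -9.0, "activator")
    ann = EnhancerAnnotation("toy1", 50, [a])
    truth_p = ek.ThermoParams(k={a.site_id: 3.7})
    clean = predict_expression(ann, truth_p, gradients)
    noisy = _profile(clean.ap_grid,
                     clean.mean + 0.05 * np.sin(clean.ap_grid / 3))
    fit = fit_model((a.site_id,), ann, noisy, gradients,
                    FitConfig(fit_c=False, fit_q=False, seed=0))
    ks = np.linspace(0, 50, 20001)
    c = gradients.at("BCD", clean.ap_grid)
    grid_rmse = np.sqrt(np.mean(
        (ks[:, None] * c / (1 + ks[:, None] * c) - noisy.mean) ** 2,
        axis=1)).min()
    assert fit.rmse == pytest.approx(grid_rmse, abs=1e-3)


def test_sweep_structure_and_reproducibility(gradients):
    ann, params, clean = _two_site_setup(gradients)
    cfg = FitConfig(n_starts=2, max_nfev=200, fit_c=False, fit_q=True,
                    seed=7)
    r1 = sweep_model_space(ann, clean, gradients, cfg)
    r2 = sweep_model_space(ann, clean, gradients, cfg)
    assert len(r1.fits) == 4
    assert [f.rmse for f in r1.fits] == [f.rmse for f in r2.fits]
    assert r1.best_fit.subset == tuple(ann.site_ids)
    # absent sites have K = 0 in the table
    assert r1.k_value_table.iloc[0].tolist() == [0.0, 0.0]
    assert r1.n_failed == 0


def test_threshold_histogram_covers_hb_subsets(gradients,
                                               three_site_annotation):
    ann = three_site_annotation  # one HB site among three
    obs = predict_expression(
        ann, ek.ThermoParams(
            k={s: 2.0 for s in ann.site_ids},
            k_hb_repressor={ann.site_ids[2]: 1.0},
            q={(ann.site_ids[1], ann.site_ids[0]): 0.3},
            hb_threshold=25,
            hb_switch_direction="activator_to_repressor"),
        gradients)
    cfg = FitConfig(n_starts=1, max_nfev=120, fit_c=False, fit_q=False,
                    switching="activator_to_repressor", tau_stride=6,
                    coarse_max_nfev=60, seed=3)
    res = sweep_model_space(ann, obs, gradients, cfg)
    hist = hb_threshold_histogram(res, "activator_to_repressor")
    # subsets containing the HB site: 2^3 - 2^2 = 4
    assert sum(hist.values()) == 4
    with pytest.raises(ValueError):
        hb_threshold_histogram(res, "repressor_to_activator")


def test_parameter_landscape_pools_per_site(gradients):
    ann, params, clean = _two_site_setup(gradients)
    cfg = FitConfig(n_starts=1, max_nfev=100, fit_c=False, fit_q=False,
                    seed=5)
    res = sweep_model_space(ann, clean, gradients, cfg)
    land = parameter_landscape(res)
    # each site appears in exactly 2^(n-1) = 2 models
    assert set(land.per_site["n_models"]) == {2}
    assert land.matrix.shape == (4, 2)
    # rows for models lacking a site carry 0 in that column
    mask0 = res.k_value_table.iloc[0]
    assert (mask0 == 0).all()


def test_rearrangement_order_free_model_is_flat(gradients):
    """With C = Q = 1 the model ignores site order: permutations tie."""
    a = BindingSite("BCD", 10, "+", 8, 5.0, -9.0, "activator")
    b = BindingSite("HB", 40, "+", 8, 4.0, -9.0, "dual")
    r = BindingSite("KR", 70, "+", 8, 4.0, -9.0, "repressor")
    ann = EnhancerAnnotation("flat", 120, [a, b, r])
    obs = predict_expression(
        ann, ek.ThermoParams(k={a.site_id: 5.0, b.site_id: 2.0,
                                r.site_id: 1.0},
                             hb_fixed_role="activator"), gradients)
    cfg = FitConfig(n_starts=2, max_nfev=300, fit_c=False, fit_q=False,
                    hb_fixed_role="activator", seed=2)
    out = rearrangement_test(ann, obs, gradients, n_perm=6, seed=0,
                             fit_config=cfg)
    assert out["actual_rmse"] <= 1e-6
    assert np.all(np.abs(out["perm_rmses"] - out["actual_rmse"]) < 1e-4)
    assert out["n_below_actual"] == 0 or \
        np.all(out["perm_rmses"][out["perm_rmses"] <
                                 out["actual_rmse"]] > -1e-12)


def test_rearrangement_rejects_bad_nperm(gradients, three_site_annotation):
    obs = _profile(np.linspace(10, 90, 52), np.zeros(52))
    with pytest.raises(ValueError):
        rearrangement_test(three_site_annotation, obs, gradients, n_perm=0)
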