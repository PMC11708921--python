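"""Occupancy-state model: weights, quenching, HB switching, predictions."""

import numpy as np
import pytest

import enhancerkit as ek
from enhancerkit.motif import BindingSite, EnhancerAnnotation
from enhancerkit.thermo import (activation_fraction, concatenate_annotations,
                                default_grid, effective_hb_role, pair_key,
                                predict_expression, state_weight)

from conftest import random_instance
from oracles import brute_force_expression


def _sites3():
    s1 = BindingSite("BCD", 0, "+", 8, 1.0, -9.0, "activator")
    s2 = BindingSite("KR", 20, "+", 8, 1.0, -9.0, "repressor")
    s3 = BindingSite("HB", 40, "+", 8, 1.0, -9.0, "dual")
    return s1, s2, s3


def test_state_weight_empty_and_single():
    s1, s2, s3 = _sites3()
    ann = EnhancerAnnotation("e", 100, [s1, s2, s3])
    p = ek.ThermoParams(k={s1.site_id: 2.0})
    conc = {"BCD": 0.5, "KR": 1.0, "HB": 1.0}
    assert state_weight([], ann, p, conc) == 1.0
    assert state_weight([s1], ann, p, conc) == pytest.approx(1.0)


def test_state_weight_adjacency_gates_cooperativity():
    """C multiplies only pairs bound with nothing bound between them."""
    s1, s2, s3 = _sites3()
    ann = EnhancerAnnotation("e", 100, [s1, s2, s3])
    c12, c13, c23 = 5.0, 7.0, 11.0
    p = ek.ThermoParams(
        k={s.site_id: 1.0 for s in (s1, s2, s3)},
        k_hb_repressor={s3.site_id: 1.0},
        c={pair_key(s1.site_id, s2.site_id): c12,
           pair_key(s1.site_id, s3.site_id): c13,
           pair_key(s2.site_id, s3.site_id): c23})
    conc = {"BCD": 1.0, "KR": 1.0, "HB": 1.0}
    # sites 1,3 bound: adjacent because 2 is unbound -> C13 applies
    assert state_weight([s1, s3], ann, p, conc) == pytest.approx(c13)
    # all three bound: consecutive pairs only, no C13
    assert state_weight([s1, s2, s3], ann, p, conc) == pytest.approx(
        c12 * c23)


def test_activation_fraction_rules():
    s1, s2, s3 = _sites3()
    ann = EnhancerAnnotation("e", 100, [s1, s2, s3])
    q21 = 0.3
    p = ek.ThermoParams(q={(s2.site_id, s1.site_id): q21,
                           (s3.site_id, s1.site_id): 0.5})
    # repressors only -> no successful contribution
    assert activation_fraction([s2], ann, p) == 0.0
    # lone activator, no adjacent repressor -> 1
    assert activation_fraction([s1], ann, p) == 1.0
    # activator with one adjacent repressor -> Q
    assert activation_fraction([s1, s2], ann, p) == pytest.approx(q21)
    # two adjacent repressors (HB repressor regime) -> product of Qs
    assert activation_fraction([s1, s2, s3], ann, p,
                               hb_role="repressor") == pytest.approx(
        q21 * 1.0)  # s3 not adjacent to s1 when s2 bound


def test_effective_hb_role_threshold_semantics():
    a2r = ek.ThermoParams(hb_threshold=14,
                          hb_switch_direction="activator_to_repressor")
    assert effective_hb_role(4, a2r) == "activator"
    assert effective_hb_role(14, a2r) == "repressor"
    r2a = ek.ThermoParams(hb_threshold=3,
                          hb_switch_direction="repressor_to_activator")
    assert effective_hb_role(1, r2a) == "repressor"
    assert effective_hb_role(10, r2a) == "activator"
    fixed = ek.ThermoParams(hb_fixed_role="repressor")
    assert effective_hb_role(30, fixed) == "repressor"
    with pytest.raises(ValueError):
        effective_hb_role(1, ek.ThermoParams(
            hb_threshold=99, hb_switch_direction="activator_to_repressor"))


def test_params_validation():
    with pytest.raises(ValueError):
        ek.ThermoParams(k={"a": -1.0})
    with pytest.raises(ValueError):
        ek.ThermoParams(q={("a", "b"): 1.5})
    with pytest.raises(ValueError):
        ek.ThermoParams(hb_switch_direction="activator_to_repressor")


def test_single_activator_closed_form(gradients):
    site = BindingSite("BCD", 10, "+", 8, 5.0, -9.0, "activator")
    ann = EnhancerAnnotation("e", 100, [site])
    for K in (0.0, 0.5, 4.0, 100.0):
        prof = predict_expression(ann, ek.ThermoParams(k={site.site_id: K}),
                                  gradients)
        c = gradients.at("BCD", prof.ap_grid)
        assert np.allclose(prof.mean, K * c / (1 + K * c), atol=1e-12)


def test_zero_k_equals_site_removal(truth):
    ann = truth.annotation
    params = truth.params
    removed = ann.subset([s for s in ann.site_ids if not s.startswith("KR")])
    k0 = {**params.k, **{s: 0.0 for s in ann.site_ids if s.startswith("KR")}}
    p0 = ek.ThermoParams(k=k0, k_hb_repressor=params.k_hb_repressor,
                         q=params.q, hb_threshold=params.hb_threshold,
                         hb_switch_direction=params.hb_switch_direction)
    pr = ek.ThermoParams(k={s: params.k[s] for s in removed.site_ids},
                         k_hb_repressor=params.k_hb_repressor,
                         q=params.q, hb_threshold=params.hb_threshold,
                         hb_switch_direction=params.hb_switch_direction)
    e0 = predict_expression(ann, p0, truth.gradients).mean
    er = predict_expression(removed, pr, truth.gradients).mean
    assert np.allclose(e0, er, atol=1e-12)


def test_expression_bounded_zero_one():
    rng = np.random.default_rng(42)
    for _ in range(25):
        ann, params, grads, _ = random_instance(rng, max_sites=8)
        e = predict_expression(ann, params, grads).mean
        assert np.all(e >= -1e-12) and np.all(e <= 1 + 1e-12)


def test_monotone_in_activator_strength(gradients):
    """With all C = 1, Q = 1, E rises with activator K everywhere."""
    site = BindingSite("BCD", 10, "+", 8, 5.0, -9.0, "activator")
    rep = BindingSite("KR", 40, "+", 8, 5.0, -9.0, "repressor")
    ann = EnhancerAnnotation("e", 100, [site, rep])
    prev = None
    for K in (0.1, 1.0, 5.0, 50.0):
        e = predict_expression(
            ann, ek.ThermoParams(k={site.site_id: K, rep.site_id: 2.0}),
            gradients).mean
        if prev is not None:
            assert np.all(e >= prev - 1e-12)
        prev = e


def test_no_switch_ignores_threshold(gradients, three_site_annotation):
    base = dict(k={s: 2.0 for s in three_site_annotation.site_ids},
                k_hb_repressor={three_site_annotation.site_ids[2]: 1.0})
    e_none = predict_expression(
        three_site_annotation, ek.ThermoParams(**base), gradients).mean
    # threshold present but direction 'none': must not matter
    p_tau = ek.ThermoParams(**base, hb_threshold=30)
    e_tau = predict_expression(three_site_annotation, p_tau, gradients).mean
    assert np.array_equal(e_none, e_tau)


@pytest.mark.parametrize("seed", [0, 1])
def test_matches_independent_enumerator(seed):
    """Vectorized prediction equals the explicit state-by-state oracle."""
    rng = np.random.default_rng(seed)
    grid = default_grid()
    for _ in range(15):
        ann, params, grads, (osites, oparams, direction, tau) = \
            random_instance(rng, max_sites=7)
        e = predict_expression(ann, params, grads).mean
        conc = {tf: grads.at(tf, grid) for tf in grads.tfs}
        expect = brute_force_expression(osites, oparams, conc, grid.size,
                                        direction=direction, tau=tau)
        assert np.allclose(e, expect, atol=1e-9), (direction, tau)


def test_refuses_state_explosion():
    sites = [BindingSite("BCD", 12 * i, "+", 8, 1.0, -9.0, "activator")
             for i in range(21)]
    ann = EnhancerAnnotation("big", 300, sites)
    with pytest.raises(ValueError, match="force"):
        predict_expression(ann, ek.ThermoParams(), ek.synth_gradients(0))


def test_concatenate_annotations(truth):
    a = truth.annotation
    empty = EnhancerAnnotation("b", 0, [])
    cat = concatenate_annotations(a, empty)
    assert [s.start for s in cat.sites] == [s.start for s in a.sites]

    b = EnhancerAnnotation(
        "b", 300, [BindingSite("BCD", 10, "+", 8, 1.0, -9.0, "activator"),
                   BindingSite("KR", 60, "+", 8, 1.0, -9.0, "repressor")])
    cat2 = concatenate_annotations(a, b)
    assert len(cat2.sites) == len(a.sites) + 2
    assert cat2.sequence_length == a.sequence_length + 300
    # b's coordinates shifted by len(a) exactly
    assert cat2.sites[-1].start == 60 + a.sequence_length
    # junction ordering preserved: a's sites first
    assert [s.start for s in cat2.sites[:len(a.sites)]] == \
        [s.start for s in a.sites]


def test_concatenate_renames_duplicate_ids(truth):
    a = truth.annotation
    cat = concatenate_annotations(a, a)
    assert cat.enhancer_id != f"{a.enhancer_id}+{a.enhancer_id}"
    assert len(cat.sites) == 2 * len(a.sites)


def test_gradientset_contracts():
    with pytest.raises(ValueError):
        ek.GradientSet(np.array([1.0, 2.0]), {"BCD": np.array([-1.0, 1.0])})
    g = ek.GradientSet(np.array([0.0, 1.0]), {"BCD": np.array([2.0, 4.0])})
    assert np.allclose(g.concentrations["BCD"], [0.5, 1.0])
    with pytest.raises(KeyError):
        g.at("HB", np.array([0.5]))
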