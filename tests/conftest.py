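import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests.oracles

import enhancerkit as ek
from enhancerkit.motif import BindingSite, EnhancerAnnotation


@pytest.fixture(scope="session")
def pwms():
    return ek.example_pwms()


@pytest.fixture(scope="session")
def gradients():
    return ek.synth_gradients(seed=0)


@pytest.fixture(scope="session")
def truth():
    return ek.make_synthetic_truth(seed=1)


@pytest.fixture
def three_site_annotation():
    """BCD activator, KR repressor, HB dual at increasing positions."""
    sites = [
        BindingSite("BCD", 10, "+", 8, 5.0, -9.0, "activator"),
        BindingSite("KR", 40, "+", 8, 4.0, -8.0, "repressor"),
        BindingSite("HB", 70, "-", 8, 4.5, -8.5, "dual"),
    ]
    return EnhancerAnnotation("toy3", 120, sites)


def random_instance(rng, max_sites=12):
    """A random annotation + parameters + gradients for oracle checks.

    Returns (annotation, ThermoParams, GradientSet, oracle_inputs).
    """
    tfs = ["BCD", "CAD", "HB", "KNI", "KR"]
    n = int(rng.integers(1, max_sites + 1))
    starts = np.sort(rng.choice(np.arange(0, 60) * 10, size=n, replace=False))
    sites = []
    for i, st in enumerate(starts):
        tf = tfs[int(rng.integers(0, 5))]
        role = ek.DEFAULT_ROLES[tf]
        sites.append(BindingSite(tf, int(st), "+", 8, 1.0, -5.0, role))
    ann = EnhancerAnnotation("rand", int(starts[-1]) + 20, sites)
    direction = ["none", "activator_to_repressor",
                 "repressor_to_activator"][int(rng.integers(0, 3))]
    tau = int(rng.integers(1, 53)) if direction != "none" else None
    k = {s.site_id: float(10 ** rng.uniform(-1, 1.5)) for s in ann.sites}
    k_rep = {s.site_id: float(10 ** rng.uniform(-1, 1.5))
             for s in ann.sites if s.role == "dual"}
    c, q, c_sw, q_sw = {}, {}, {}, {}
    ids = ann.site_ids
    for i, a in enumerate(ann.sites):
        for b in ann.sites[i + 1:]:
            if rng.random() < 0.5:
                key = tuple(sorted((a.site_id, b.site_id)))
                c[key] = float(10 ** rng.uniform(-1, 1.5))
                if "dual" in (a.role, b.role) and rng.random() < 0.5:
                    c_sw[key] = float(10 ** rng.uniform(-1, 1.5))
            for r, t in ((a, b), (b, a)):
                if rng.random() < 0.4:
                    q[(r.site_id, t.site_id)] = float(rng.uniform(0, 1))
                    if "dual" in (r.role, t.role) and rng.random() < 0.5:
                        q_sw[(r.site_id, t.site_id)] = float(
                            rng.uniform(0, 1))
    params = ek.ThermoParams(
        k=k, k_hb_repressor=k_rep, c=c, q=q, c_switched=c_sw,
        q_switched=q_sw, hb_threshold=tau, hb_switch_direction=direction,
        hb_fixed_role="repressor")
    grads = ek.synth_gradients(seed=int(rng.integers(0, 2**31)))
    oracle_sites = [(s.site_id, s.tf_name, s.start, s.role)
                    for s in ann.sites]
    oracle_params = {
        "k": k, "k_rep": k_rep,
        "c": {frozenset(kk): v for kk, v in c.items()},
        "q": dict(q),
        "c_sw": {frozenset(kk): v for kk, v in c_sw.items()},
        "q_sw": dict(q_sw),
    }
    return ann, params, grads, (oracle_sites, oracle_params, direction, tau)
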