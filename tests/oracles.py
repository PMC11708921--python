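"""Independent brute-force oracles used by the test suite.

The expression oracle below shares no code with the package's vectorized
state-space implementation: it works on plain tuples/dicts with explicit
Python loops, enumerating occupancy states one by one.
"""

import itertools

import numpy as np

ACT, REP, DUAL = "activator", "repressor", "dual"


def brute_force_expression(sites, params, conc_by_tf, n_positions,
                           direction="none", tau=None,
                           fixed_role=REP):
    """Expression profile by explicit state enumeration.

    sites: list of (site_id, tf, start, role) sorted by start.
    params: dict with keys 'k', 'k_rep' (HB repressor-regime K),
        'c' (frozenset pair -> C), 'q' ((rep_id, act_id) -> Q),
        'c_sw', 'q_sw' (switched-regime overrides for HB pairs).
    conc_by_tf: tf -> array of length n_positions.
    direction: 'none' | 'activator_to_repressor' | 'repressor_to_activator'.
    tau: 1-based switching nucleus (positions are nuclei 1..n_positions).
    """
    sites = sorted(sites, key=lambda s: s[2])
    n = len(sites)
    out = np.zeros(n_positions)
    for pos in range(1, n_positions + 1):
        if direction == "none":
            hb_role = fixed_role
            switched = False
        else:
            pre, post = ((ACT, REP) if direction == "activator_to_repressor"
                         else (REP, ACT))
            hb_role = pre if pos < tau else post
            switched = pos >= tau
        num = 0.0
        den = 0.0
        for r in range(n + 1):
            for state in itertools.combinations(range(n), r):
                w = 1.0
                for i in state:
                    sid, tf, _, role = sites[i]
                    if role == DUAL and hb_role == REP:
                        k = params["k_rep"].get(sid, params["k"].get(sid, 0))
                    else:
                        k = params["k"].get(sid, 0.0)
                    w *= k * conc_by_tf[tf][pos - 1]
                # adjacent = consecutive among bound sites
                for a, b in zip(state, state[1:]):
                    ia, ib = sites[a], sites[b]
                    key = frozenset((ia[0], ib[0]))
                    hb_pair = DUAL in (ia[3], ib[3])
                    if switched and hb_pair and key in params.get("c_sw", {}):
                        w *= params["c_sw"][key]
                    else:
                        w *= params["c"].get(key, 1.0)
                roles = [hb_role if sites[i][3] == DUAL else sites[i][3]
                         for i in state]
                if ACT not in roles:
                    f = 0.0
                else:
                    f = 1.0
                    for (a, ra), (b, rb) in zip(
                            zip(state, roles), zip(state[1:], roles[1:])):
                        pair = None
                        if ra == REP and rb == ACT:
                            pair = (sites[a][0], sites[b][0])
                        elif ra == ACT and rb == REP:
                            pair = (sites[b][0], sites[a][0])
                        if pair is not None:
                            hb_pair = DUAL in (sites[a][3], sites[b][3])
                            if switched and hb_pair and \
                                    pair in params.get("q_sw", {}):
                                f *= params["q_sw"][pair]
                            else:
                                f *= params["q"].get(pair, 1.0)
                num += w * f
                den += w
        out[pos - 1] = num / den
    return out


def exhaustive_ln_pvalue(matrix, background, score):
    """ln P(word score >= score) by enumerating all 4**W words."""
    W = matrix.shape[0]
    with np.errstate(divide="ignore"):
        lod = np.log(matrix) - np.log(background)
    count = 0.0
    for word in itertools.product(range(4), repeat=W):
        s = sum(lod[j, b] for j, b in enumerate(word))
        if s >= score - 1e-12:
            count += np.prod([background[b] for b in word])
    return float(np.log(count)) if count > 0 else float("-inf")
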