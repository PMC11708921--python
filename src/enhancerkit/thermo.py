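"""Thermodynamic occupancy model of enhancer-driven expression.

The enhancer is modeled at equilibrium: every subset of its annotated
binding sites is a possible occupancy *state*. A state's statistical weight
is the product, over bound sites, of a site strength ``K`` times the local
TF concentration, further multiplied by a cooperativity factor ``C`` for
every *adjacently bound* pair — two bound sites with no other bound site
between them on the sequence. Expression at an AP position is the ratio of
the weight of "successful" states to the total weight:

    E(x) = sum_s w(s, x) * f(s, x) / sum_s w(s, x)

where a state is successful iff at least one effective activator is bound,
and its activating fraction ``f`` is the product of quenching factors
``Q in [0, 1]`` over adjacently bound (repressor, activator) pairs — the
proportion of that state still contributing to activation despite
short-range repression. BICOID activates; CAUDAL, KNIRPS and KRUPPEL
repress; HUNCHBACK is dual: a single threshold nucleus ``tau`` on the AP
axis switches its role (activator->repressor or the reverse), with
regime-specific ``K`` and, optionally, regime-specific interaction entries
for pairs involving an HB site.

This defining equation is the package's stated interpretation of the
successful-states ratio: minimal, pairwise-only (no higher-order
cooperativity), with quenching acting multiplicatively per adjacent
repressor-activator pair.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .motif import (ACTIVATOR, DUAL, REPRESSOR, BindingSite,
                    EnhancerAnnotation)
from .utils import check_grid

A_TO_R = "activator_to_repressor"
R_TO_A = "repressor_to_activator"
NO_SWITCH = "none"

#: Default modeled AP window and nucleus count: 52 nuclei spanning 10-90% AP.
N_NUCLEI = 52
AP_MIN, AP_MAX = 10.0, 90.0


def nucleus_to_ap(i, n_nuclei: int = N_NUCLEI,
                  ap_min: float = AP_MIN, ap_max: float = AP_MAX):
    """%AP of nucleus index i (1-based): linear map over the modeled window."""
    i = np.asarray(i, dtype=float)
    return ap_min + (i - 1) * (ap_max - ap_min) / (n_nuclei - 1)


def default_grid(n_nuclei: int = N_NUCLEI) -> np.ndarray:
    """%AP positions of the default modeling grid (one per nucleus)."""
    return nucleus_to_ap(np.arange(1, n_nuclei + 1), n_nuclei)


PairKey = Tuple[str, str]


def pair_key(a: str, b: str) -> PairKey:
    """Canonical unordered key for a site pair."""
    return (a, b) if a <= b else (b, a)


@dataclass
class GradientSet:
    """Per-TF concentration profiles on a common %AP grid, each normalized
    to a maximum of 1."""

    ap_grid: np.ndarray
    concentrations: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.ap_grid = check_grid(self.ap_grid)
        norm = {}
        for tf, c in self.concentrations.items():
            c = np.asarray(c, dtype=float)
            if c.shape != self.ap_grid.shape:
                raise ValueError(f"gradient {tf}: shape mismatch with grid")
            if np.any(c < 0):
                raise ValueError(f"gradient {tf}: negative concentration")
            m = c.max()
            norm[tf] = c / m if m > 0 else c
        self.concentrations = norm

    @property
    def tfs(self) -> List[str]:
        return list(self.concentrations)

    def at(self, tf: str, grid: np.ndarray) -> np.ndarray:
        """Concentration of ``tf`` linearly interpolated onto ``grid``
        (clamped at the span ends)."""
        if tf not in self.concentrations:
            raise KeyError(f"missing gradient: {tf}")
        return np.interp(grid, self.ap_grid, self.concentrations[tf])


@dataclass
class ExpressionProfile:
    """Intensity versus %AP at a fixed %DV line."""

    ap_grid: np.ndarray
    mean: np.ndarray
    se: Optional[np.ndarray] = None
    n_embryos: Optional[int] = None

    def __post_init__(self) -> None:
        self.ap_grid = check_grid(self.ap_grid)
        self.mean = np.asarray(self.mean, dtype=float)
        if self.mean.shape != self.ap_grid.shape:
            raise ValueError("mean/grid shape mismatch")
        if not np.all(np.isfinite(self.mean)):
            raise ValueError("mean must be finite")
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)
            if self.se.shape != self.ap_grid.shape:
                raise ValueError("se/grid shape mismatch")


@dataclass
class ThermoParams:
    """Parameters of the occupancy model.

    ``k`` maps site id -> K (>= 0). For an HB site under switching, ``k``
    holds its strength in the *activator* regime and ``k_hb_repressor`` its
    strength in the repressor regime. ``c`` maps unordered site-id pairs to
    cooperativity (>= 0, default 1); ``q`` maps ordered
    (repressor site, activator site) pairs to quenching in [0, 1]
    (default 1). ``c_switched``/``q_switched`` override entries for pairs
    involving an HB site at AP positions where HB activity is switched.
    ``hb_threshold`` is the 1-based nucleus index tau; nuclei with index
    < tau take the pre-switch role, >= tau the post-switch role.
    """

    k: Dict[str, float] = field(default_factory=dict)
    k_hb_repressor: Dict[str, float] = field(default_factory=dict)
    c: Dict[PairKey, float] = field(default_factory=dict)
    q: Dict[PairKey, float] = field(default_factory=dict)
    c_switched: Dict[PairKey, float] = field(default_factory=dict)
    q_switched: Dict[PairKey, float] = field(default_factory=dict)
    hb_threshold: Optional[int] = None
    hb_switch_direction: str = NO_SWITCH
    hb_fixed_role: str = REPRESSOR

    def __post_init__(self) -> None:
        for sid, v in self.k.items():
            if v < 0:
                raise ValueError(f"K[{sid}] must be >= 0")
        for sid, v in self.k_hb_repressor.items():
            if v < 0:
                raise ValueError(f"K_R[{sid}] must be >= 0")
        for d in (self.c, self.c_switched):
            for p, v in d.items():
                if v < 0:
                    raise ValueError(f"C[{p}] must be >= 0")
        for d in (self.q, self.q_switched):
            for p, v in d.items():
                if not 0 <= v <= 1:
                    raise ValueError(f"Q[{p}] must be in [0, 1]")
        if self.hb_switch_direction not in (A_TO_R, R_TO_A, NO_SWITCH):
            raise ValueError(
                f"bad switch direction {self.hb_switch_direction!r}")
        if self.hb_switch_direction != NO_SWITCH and self.hb_threshold is None:
            raise ValueError("switching enabled but hb_threshold unset")

    def get_c(self, a: str, b: str, switched: bool = False) -> float:
        key = pair_key(a, b)
        if switched and key in self.c_switched:
            return self.c_switched[key]
        return self.c.get(key, 1.0)

    def get_q(self, repressor: str, activator: str,
              switched: bool = False) -> float:
        key = (repressor, activator)
        if switched and key in self.q_switched:
            return self.q_switched[key]
        return self.q.get(key, 1.0)


def effective_hb_role(nucleus: int, params: ThermoParams,
                      n_nuclei: int = N_NUCLEI) -> str:
    """Effective HB role at a 1-based nucleus index.

    With direction ``activator_to_repressor``, nuclei anterior to the
    threshold (index < tau) see HB as an activator and nuclei at or
    posterior to it (index >= tau) as a repressor; reversed for
    ``repressor_to_activator``. With direction ``none`` the configured
    fixed role applies everywhere.
    """
    if params.hb_switch_direction == NO_SWITCH:
        return params.hb_fixed_role
    tau = params.hb_threshold
    if not 1 <= tau <= n_nuclei:
        raise ValueError(f"hb_threshold {tau} outside grid 1..{n_nuclei}")
    pre, post = ((ACTIVATOR, REPRESSOR)
                 if params.hb_switch_direction == A_TO_R
                 else (REPRESSOR, ACTIVATOR))
    return pre if nucleus < tau else post


def _site_role(site: BindingSite, hb_role: str) -> str:
    return hb_role if site.role == DUAL else site.role


def state_weight(state: Sequence[BindingSite],
                 annotation: EnhancerAnnotation,
                 params: ThermoParams,
                 conc: Mapping[str, float],
                 hb_switched: bool = False,
                 hb_role: str = ACTIVATOR) -> float:
    """Statistical weight of one occupancy state at one AP position.

    ``conc`` maps TF name -> concentration at the position. Cooperativity
    ``C`` multiplies each *adjacently bound* pair: bound sites i < j with no
    bound site between them. The empty state has weight 1.
    """
    bound = sorted(state, key=lambda s: s.start)
    ids = {s.site_id for s in bound}
    if not ids <= set(annotation.site_ids):
        raise ValueError("state contains sites outside the annotation")
    w = 1.0
    for s in bound:
        if s.tf_name not in conc:
            raise KeyError(f"missing concentration for {s.tf_name}")
        k = params.k.get(s.site_id, 0.0)
        if s.role == DUAL and hb_role == REPRESSOR:
            k = params.k_hb_repressor.get(s.site_id, k)
        w *= k * conc[s.tf_name]
    for a, b in zip(bound, bound[1:]):
        sw = hb_switched and (a.role == DUAL or b.role == DUAL)
        w *= params.get_c(a.site_id, b.site_id, switched=sw)
    return w


def activation_fraction(state: Sequence[BindingSite],
                        annotation: EnhancerAnnotation,
                        params: ThermoParams,
                        hb_switched: bool = False,
                        hb_role: str = ACTIVATOR) -> float:
    """Fraction of a state's weight contributing to activation.

    Zero when no effective activator is bound; otherwise the product of
    quenching Q over adjacently bound (repressor, activator) pairs.
    """
    bound = sorted(state, key=lambda s: s.start)
    roles = [_site_role(s, hb_role) for s in bound]
    if ACTIVATOR not in roles:
        return 0.0
    f = 1.0
    for (a, ra), (b, rb) in zip(zip(bound, roles), zip(bound[1:], roles[1:])):
        sw = hb_switched and (a.role == DUAL or b.role == DUAL)
        if ra == REPRESSOR and rb == ACTIVATOR:
            f *= params.get_q(a.site_id, b.site_id, switched=sw)
        elif ra == ACTIVATOR and rb == REPRESSOR:
            f *= params.get_q(b.site_id, a.site_id, switched=sw)
    return f


class StateSpace:
    """Precompiled occupancy-state machinery for one annotation.

    Enumerates the 2**n states once, together with which unordered site
    pairs are adjacently bound in each state, so that expression can be
    evaluated with a handful of matrix products per parameter vector. Used
    internally by :func:`predict_expression` and heavily by the fitting
    code, which re-evaluates the same structure thousands of times.
    """

    MAX_SITES = 20

    def __init__(self, annotation: EnhancerAnnotation, force: bool = False):
        n = len(annotation.sites)
        if n > self.MAX_SITES and not force:
            raise ValueError(
                f"{n} sites would enumerate 2^{n} states; pass force=True")
        self.annotation = annotation
        self.sites = annotation.sites  # ordered by start
        self.n = n
        self.pairs: List[Tuple[int, int]] = list(
            itertools.combinations(range(n), 2))
        pair_index = {p: i for i, p in enumerate(self.pairs)}
        S = 1 << n
        self.bound = np.zeros((S, n), dtype=float)
        self.pair_bound = np.zeros((S, len(self.pairs)), dtype=float)
        for s in range(S):
            idx = [i for i in range(n) if s >> i & 1]
            self.bound[s, idx] = 1.0
            for a, b in zip(idx, idx[1:]):
                self.pair_bound[s, pair_index[(a, b)]] = 1.0

    def predict(self, params: ThermoParams, gradients: GradientSet,
                grid: Optional[np.ndarray] = None,
                n_nuclei: int = N_NUCLEI) -> np.ndarray:
        """E(x) on ``grid`` (%AP; defaults to the nucleus grid)."""
        if grid is None:
            grid = default_grid(n_nuclei)
        grid = np.asarray(grid, dtype=float)
        P = grid.size
        n = self.n
        sites = self.sites

        # per-position HB regime
        if params.hb_switch_direction == NO_SWITCH:
            switched = np.zeros(P, dtype=bool)
            hb_role = np.full(P, params.hb_fixed_role == ACTIVATOR)
        else:
            nuc = np.clip(np.rint(
                1 + (grid - AP_MIN) * (n_nuclei - 1) / (AP_MAX - AP_MIN)),
                1, n_nuclei).astype(int)
            switched = nuc >= params.hb_threshold
            pre_act = params.hb_switch_direction == A_TO_R
            hb_role = np.where(switched, not pre_act, pre_act)
        # hb_role: True where HB is an effective activator

        conc = np.zeros((n, P))
        log_kc = np.full((n, P), -np.inf)
        is_act = np.zeros((n, P), dtype=float)
        for i, s in enumerate(sites):
            conc[i] = gradients.at(s.tf_name, grid)
            if s.role == DUAL:
                k_act = params.k.get(s.site_id, 0.0)
                k_rep = params.k_hb_repressor.get(s.site_id, k_act)
                k = np.where(hb_role, k_act, k_rep)
                is_act[i] = hb_role.astype(float)
            else:
                k = np.full(P, params.k.get(s.site_id, 0.0))
                is_act[i] = float(s.role == ACTIVATOR)
            with np.errstate(divide="ignore"):
                log_kc[i] = np.log(k * conc[i])

        log_c = np.zeros((len(self.pairs), P))
        log_q = np.zeros((len(self.pairs), P))
        with np.errstate(divide="ignore"):
            for pi, (a, b) in enumerate(self.pairs):
                sa, sb = sites[a], sites[b]
                involves_hb = sa.role == DUAL or sb.role == DUAL
                c_base = params.get_c(sa.site_id, sb.site_id, switched=False)
                if involves_hb:
                    c_alt = params.get_c(sa.site_id, sb.site_id, switched=True)
                    log_c[pi] = np.where(switched, np.log(c_alt),
                                         np.log(c_base))
                else:
                    log_c[pi] = np.log(c_base)
                # quenching applies where one is an effective repressor and
                # the other an effective activator (order on the sequence is
                # immaterial; the repressor quenches its neighbor)
                ra = is_act[a] > 0
                rb = is_act[b] > 0
                lq = np.zeros(P)
                mask_ab = (~ra) & rb  # a represses b
                mask_ba = ra & (~rb)
                if mask_ab.any():
                    q_b = params.get_q(sa.site_id, sb.site_id, switched=False)
                    q_b_alt = params.get_q(sa.site_id, sb.site_id,
                                           switched=True)
                    vals = np.where(switched & involves_hb, np.log(q_b_alt),
                                    np.log(q_b))
                    lq = np.where(mask_ab, vals, lq)
                if mask_ba.any():
                    q_a = params.get_q(sb.site_id, sa.site_id, switched=False)
                    q_a_alt = params.get_q(sb.site_id, sa.site_id,
                                           switched=True)
                    vals = np.where(switched & involves_hb, np.log(q_a_alt),
                                    np.log(q_a))
                    lq = np.where(mask_ba, vals, lq)
                log_q[pi] = lq

        with np.errstate(invalid="ignore"):
            log_w = self.bound @ np.nan_to_num(log_kc, neginf=-745.0) \
                + self.pair_bound @ np.nan_to_num(log_c, neginf=-745.0)
        has_act = (self.bound @ is_act) > 0
        log_f = self.pair_bound @ np.nan_to_num(log_q, neginf=-745.0)

        m = log_w.max(axis=0)
        w = np.exp(log_w - m)
        den = w.sum(axis=0)
        num = (w * np.exp(log_f) * has_act).sum(axis=0)
        return num / den


def predict_expression(annotation: EnhancerAnnotation,
                       params: ThermoParams,
                       gradients: GradientSet,
                       grid: Optional[np.ndarray] = None,
                       n_nuclei: int = N_NUCLEI,
                       force: bool = False) -> ExpressionProfile:
    """Predicted expression E(x) in [0, 1] across the AP axis.

    Enumerates all 2**n occupancy states of the annotation (refused above
    20 sites unless ``force``), resolving the HB regime per position before
    evaluating weights and activating fractions.
    """
    space = StateSpace(annotation, force=force)
    if grid is None:
        grid = default_grid(n_nuclei)
    e = space.predict(params, gradients, grid, n_nuclei=n_nuclei)
    return ExpressionProfile(np.asarray(grid, dtype=float), e)


def concatenate_annotations(a: EnhancerAnnotation,
                            b: EnhancerAnnotation) -> EnhancerAnnotation:
    """Concatenate two enhancer annotations end to end.

    ``b``'s site coordinates are re-offset past ``a``'s sequence; the
    junction pair (last site of ``a``, first site of ``b``) thereby becomes
    eligible for adjacency interactions in the occupancy model.
    """
    offset = a.sequence_length
    new_id = (a.enhancer_id if a.enhancer_id != b.enhancer_id
              else a.enhancer_id + "_a")
    b_id = b.enhancer_id if a.enhancer_id != b.enhancer_id \
        else b.enhancer_id + "_b"
    shifted = [replace(s, start=s.start + offset) for s in b.sites]
    roles = dict(a.roles_by_tf)
    roles.update(b.roles_by_tf)
    return EnhancerAnnotation(
        f"{new_id}+{b_id}", a.sequence_length + b.sequence_length,
        list(a.sites) + shifted, roles)
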