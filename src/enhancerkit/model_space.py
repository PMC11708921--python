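"""Exhaustive model-space fitting and selection.

Every subset of an enhancer's candidate binding sites defines a model: the
occupancy model restricted to those sites (an absent site is equivalent to
fixing its K at zero). Each model is fit to an observed AP expression
profile by bounded nonlinear least squares on its free parameters (site
strengths K, optionally pairwise cooperativities C and quenching factors
Q, and — for models containing an HB site — the switching threshold
nucleus tau, handled by discrete scan with continuous inner fits). Models
are compared by RMSE and by AIC with a Gaussian-likelihood form,

    AIC = n * ln(RMSE^2) + 2 * n_params,

which trades goodness of fit against model complexity. A 10-site
annotation yields 1,024 models per enhancer; the 768 of them containing at
least one HB site contribute to the switching-threshold histogram.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.optimize import least_squares

from .motif import ACTIVATOR, DUAL, REPRESSOR, EnhancerAnnotation
from .thermo import (A_TO_R, NO_SWITCH, R_TO_A, ExpressionProfile,
                     GradientSet, StateSpace, ThermoParams, default_grid,
                     pair_key)
from .utils import derived_seed

logger = logging.getLogger(__name__)


def enumerate_subsets(annotation: EnhancerAnnotation
                      ) -> List[Tuple[str, ...]]:
    """All 2**n subsets of the annotation's site ids, empty set included,
    in binary-counting order on the site index."""
    ids = annotation.site_ids
    n = len(ids)
    if n > StateSpace.MAX_SITES:
        raise ValueError(f"{n} sites exceeds the {StateSpace.MAX_SITES}-site "
                         "enumeration limit")
    return [tuple(ids[j] for j in range(n) if mask >> j & 1)
            for mask in range(1 << n)]


def rmse(predicted: ExpressionProfile, observed: ExpressionProfile) -> float:
    """Root mean square error between two profiles on identical grids."""
    if predicted.ap_grid.shape != observed.ap_grid.shape or \
            not np.allclose(predicted.ap_grid, observed.ap_grid):
        raise ValueError("profiles are on different grids")
    return float(np.sqrt(np.mean((predicted.mean - observed.mean) ** 2)))


def aic(rmse_value: float, n_points: int, n_params: int) -> float:
    """Gaussian-likelihood AIC with constant terms dropped."""
    if rmse_value < 0:
        raise ValueError("rmse must be >= 0")
    if rmse_value == 0:
        warnings.warn("rmse is exactly 0; AIC is -inf", stacklevel=2)
        return float("-inf")
    return n_points * float(np.log(rmse_value ** 2)) + 2 * n_params


@dataclass
class FitConfig:
    """Budget and structure of a model fit.

    ``fit_c``/``fit_q`` control whether pairwise cooperativity and
    quenching are free parameters (otherwise fixed at 1);
    ``fit_switched_interactions`` additionally frees regime-specific C/Q
    entries for HB-involving pairs. ``switching`` selects the HB regime
    structure (none / activator_to_repressor / repressor_to_activator).

    The threshold tau is enumerated over nuclei with stride ``tau_stride``
    using cheap warm-started fits (each candidate initialized from its
    neighbor's solution); the ``tau_topk`` best candidates are then
    refitted, together with their +-``tau_refine`` neighbors, at the full
    budget. The default stride of 1 matters: the tau likelihood landscape
    can have a basin a single nucleus wide, which any coarser scan can
    miss regardless of the inner optimizer.
    """

    n_starts: int = 3
    max_nfev: int = 2000
    fit_c: bool = True
    fit_q: bool = True
    fit_switched_interactions: bool = False
    switching: str = NO_SWITCH
    hb_fixed_role: str = REPRESSOR
    tau_stride: int = 1
    tau_refine: int = 1
    tau_topk: int = 2
    coarse_starts: int = 1
    coarse_max_nfev: int = 80
    k_max: float = 1e4
    c_max: float = 1e4
    n_nuclei: int = 52
    seed: int = 0


@dataclass
class FitResult:
    subset: Tuple[str, ...]
    params: ThermoParams
    rmse: float
    aic: float
    n_params: int
    predictions: ExpressionProfile
    optimizer_trace: Dict = field(default_factory=dict)


@dataclass
class ModelSpaceResult:
    site_ids: List[str]
    fits: List[FitResult]
    best_by_aic: int
    k_value_table: pd.DataFrame
    threshold_histogram: Dict[int, int]
    direction: str
    n_failed: int = 0

    @property
    def best_fit(self) -> FitResult:
        return self.fits[self.best_by_aic]

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for mask, f in enumerate(self.fits):
            rows.append({
                "subset_mask": mask,
                "sites": ",".join(f.subset),
                "n_sites": len(f.subset),
                "rmse": f.rmse,
                "aic": f.aic,
                "n_params": f.n_params,
                "tau": f.params.hb_threshold,
                "seed": f.optimizer_trace.get("seed"),
            })
        return pd.DataFrame(rows)


class _ParamSpec:
    """Maps a flat optimizer vector onto a ThermoParams for one subset."""

    def __init__(self, sub: EnhancerAnnotation, cfg: FitConfig):
        self.cfg = cfg
        sites = sub.sites
        self.names: List[Tuple[str, object]] = []
        self.lower: List[float] = []
        self.upper: List[float] = []
        switching = cfg.switching != NO_SWITCH
        self.has_hb = any(s.role == DUAL for s in sites)
        for s in sites:
            self._add(("k", s.site_id), 0.0, cfg.k_max)
            if s.role == DUAL and switching:
                self._add(("k_rep", s.site_id), 0.0, cfg.k_max)
        pairs = [(a, b) for i, a in enumerate(sites) for b in sites[i + 1:]]
        if cfg.fit_c:
            for a, b in pairs:
                self._add(("c", pair_key(a.site_id, b.site_id)), 0.0,
                          cfg.c_max)
                if cfg.fit_switched_interactions and switching and \
                        DUAL in (a.role, b.role):
                    self._add(("c_sw", pair_key(a.site_id, b.site_id)), 0.0,
                              cfg.c_max)
        if cfg.fit_q:
            for a, b in pairs:
                for r, t in ((a, b), (b, a)):
                    r_rep = r.role == REPRESSOR or (
                        r.role == DUAL and (switching or
                                            cfg.hb_fixed_role == REPRESSOR))
                    t_act = t.role == ACTIVATOR or (
                        t.role == DUAL and (switching or
                                            cfg.hb_fixed_role == ACTIVATOR))
                    if r.role == DUAL and t.role == DUAL:
                        continue  # both HB: same regime, never rep+act
                    if r_rep and t_act:
                        self._add(("q", (r.site_id, t.site_id)), 0.0, 1.0)
                        if cfg.fit_switched_interactions and switching and \
                                DUAL in (r.role, t.role):
                            self._add(("q_sw", (r.site_id, t.site_id)),
                                      0.0, 1.0)

    def _add(self, name, lo, hi):
        self.names.append(name)
        self.lower.append(lo)
        self.upper.append(hi)

    @property
    def size(self) -> int:
        return len(self.names)

    def initial(self, rng: Optional[np.random.Generator],
                zero_k: bool = False) -> np.ndarray:
        """One starting vector.

        With rng=None a deterministic default (K=1, C=1, Q=1); with
        ``zero_k`` the K entries start at the lower bound, which lets a
        silent profile be fit exactly.
        """
        x = np.empty(self.size)
        for i, (kind, _) in enumerate(self.names):
            if kind in ("k", "k_rep"):
                x[i] = (0.0 if zero_k else
                        1.0 if rng is None else 10 ** rng.uniform(-1, 1.5))
            elif kind in ("c", "c_sw"):
                x[i] = 1.0 if rng is None else 10 ** rng.uniform(-0.7, 1.2)
            else:
                x[i] = 1.0 if rng is None else rng.uniform(0.1, 1.0)
        return x

    def to_params(self, x: np.ndarray, tau: Optional[int]) -> ThermoParams:
        k, k_rep, c, q, c_sw, q_sw = {}, {}, {}, {}, {}, {}
        for (kind, key), v in zip(self.names, x):
            {"k": k, "k_rep": k_rep, "c": c, "q": q,
             "c_sw": c_sw, "q_sw": q_sw}[kind][key] = float(v)
        return ThermoParams(
            k=k, k_hb_repressor=k_rep, c=c, q=q,
            c_switched=c_sw, q_switched=q_sw,
            hb_threshold=tau,
            hb_switch_direction=(self.cfg.switching
                                 if self.has_hb and
                                 self.cfg.switching != NO_SWITCH and
                                 tau is not None else NO_SWITCH),
            hb_fixed_role=self.cfg.hb_fixed_role)


def _fit_continuous(space: StateSpace, spec: _ParamSpec, observed_mean,
                    gradients, grid, tau, cfg: FitConfig, n_starts,
                    max_nfev, seed,
                    warm_start: Optional[np.ndarray] = None,
                    tol: float = 1e-8) -> Tuple[float, np.ndarray]:
    """Multi-start bounded least squares at a fixed tau. Returns
    (rmse, best x)."""

    def residuals(x):
        p = spec.to_params(x, tau)
        return space.predict(p, gradients, grid, n_nuclei=cfg.n_nuclei) \
            - observed_mean

    # start order: warm start (when given), the K=C=Q=1 default, the K=0
    # boundary (lets a silent profile fit exactly), seeded random draws;
    # the first n_starts of these are run
    starts: List[np.ndarray] = []
    if warm_start is not None:
        starts.append(np.asarray(warm_start, dtype=float))
    starts.append(spec.initial(None))
    starts.append(spec.initial(None, zero_k=True))
    i = 0
    while len(starts) < n_starts:
        starts.append(spec.initial(
            np.random.default_rng(derived_seed(seed, 2 + i))))
        i += 1

    best = (np.inf, None)
    for x0 in starts[:max(1, n_starts)]:
        try:
            res = least_squares(residuals, x0,
                                bounds=(spec.lower, spec.upper),
                                max_nfev=max_nfev, method="trf",
                                ftol=tol, xtol=tol, gtol=tol)
        except Exception as exc:  # pragma: no cover - optimizer robustness
            logger.warning("fit start failed: %s", exc)
            continue
        r = float(np.sqrt(np.mean(res.fun ** 2)))
        if r < best[0]:
            best = (r, res.x)
    if best[1] is None:
        raise RuntimeError("optimizer produced no feasible evaluation")
    return best


def fit_model(subset: Sequence[str],
              annotation: EnhancerAnnotation,
              observed: ExpressionProfile,
              gradients: GradientSet,
              fit_config: Optional[FitConfig] = None,
              subset_index: int = 0) -> FitResult:
    """Fit the occupancy model restricted to ``subset`` to an observed
    profile by minimizing RMSE within parameter bounds.

    K and C are bounded in [0, k_max]/[0, c_max], Q in [0, 1]; when the
    model contains an HB site and switching is enabled, tau is scanned
    discretely (coarse stride, then refinement) with an inner continuous
    fit per candidate. The multi-start seed is recorded in the trace.
    """
    cfg = fit_config or FitConfig()
    grid = observed.ap_grid
    n_pts = grid.size
    seed = derived_seed(cfg.seed, subset_index)

    if len(subset) == 0:
        pred = ExpressionProfile(grid, np.zeros(n_pts))
        r = float(np.sqrt(np.mean(observed.mean ** 2)))
        return FitResult(tuple(subset),
                         ThermoParams(hb_fixed_role=cfg.hb_fixed_role),
                         r, aic(r, n_pts, 0), 0, pred,
                         {"seed": seed, "tau_scanned": False})

    sub = annotation.subset(subset)
    if len(sub.sites) != len(subset):
        raise ValueError("subset contains unknown site ids")
    space = StateSpace(sub)
    spec = _ParamSpec(sub, cfg)
    switching = cfg.switching != NO_SWITCH and spec.has_hb

    if not switching:
        r, x = _fit_continuous(space, spec, observed.mean, gradients, grid,
                               None, cfg, cfg.n_starts, cfg.max_nfev, seed)
        best_tau, best_x, best_r = None, x, r
        scanned = 0
    else:
        # dense scan over tau with cheap warm-started fits: each candidate
        # starts from its neighbor's solution, so the whole sweep costs
        # little more than one converged fit per basin
        candidates = list(range(1, cfg.n_nuclei + 1, cfg.tau_stride))
        coarse = []
        warm = None
        for tau in candidates:
            # the coarse stage only ranks candidates, so loose tolerances
            r, x = _fit_continuous(space, spec, observed.mean, gradients,
                                   grid, tau, cfg, cfg.coarse_starts,
                                   cfg.coarse_max_nfev,
                                   derived_seed(seed, tau),
                                   warm_start=warm, tol=1e-6)
            warm = x
            coarse.append((r, tau, x))
        ranked = sorted(coarse, key=lambda t: t[0])
        # refit the top candidates and their neighbors at the full budget
        refine: Dict[int, Optional[np.ndarray]] = {}
        coarse_x = {tau: x for _, tau, x in coarse}
        for _, tau, x in ranked[:cfg.tau_topk]:
            for t in range(tau - cfg.tau_refine, tau + cfg.tau_refine + 1):
                if 1 <= t <= cfg.n_nuclei and t not in refine:
                    refine[t] = coarse_x.get(t, x)
        best_r, best_tau, best_x = np.inf, None, None
        for tau, wx in sorted(refine.items()):
            r, x = _fit_continuous(space, spec, observed.mean, gradients,
                                   grid, tau, cfg, cfg.n_starts,
                                   cfg.max_nfev, derived_seed(seed, tau, 1),
                                   warm_start=wx)
            if r < best_r:
                best_r, best_tau, best_x = r, tau, x
        scanned = len(candidates) + len(refine)

    params = spec.to_params(best_x, best_tau)
    pred = ExpressionProfile(
        grid, space.predict(params, gradients, grid, n_nuclei=cfg.n_nuclei))
    n_params = spec.size + (1 if switching else 0)
    return FitResult(tuple(subset), params, best_r,
                     aic(best_r, n_pts, n_params) if best_r > 0
                     else float("-inf"),
                     n_params, pred,
                     {"seed": seed, "n_starts": cfg.n_starts,
                      "tau_scanned": bool(switching),
                      "tau_candidates": scanned if switching else 0})


def sweep_model_space(annotation: EnhancerAnnotation,
                      observed: ExpressionProfile,
                      gradients: GradientSet,
                      fit_config: Optional[FitConfig] = None
                      ) -> ModelSpaceResult:
    """Fit every subset of the annotation's sites and select by AIC.

    Returns per-subset fits (binary-counting order), the argmin-AIC subset,
    the models x sites K-value table (absent site -> 0; HB sites expand to
    activator/repressor-regime columns under switching) and the histogram
    of fitted switching thresholds over HB-containing subsets. Failed fits
    are logged and excluded from the histogram, not fatal.
    """
    cfg = fit_config or FitConfig()
    subsets = enumerate_subsets(annotation)
    fits: List[FitResult] = []
    n_failed = 0
    for idx, subset in enumerate(subsets):
        try:
            fits.append(fit_model(subset, annotation, observed, gradients,
                                  cfg, subset_index=idx))
        except Exception as exc:
            logger.warning("subset %d failed: %s", idx, exc)
            n_failed += 1
            fits.append(FitResult(subset, ThermoParams(), float("inf"),
                                  float("inf"), 0,
                                  ExpressionProfile(
                                      observed.ap_grid,
                                      np.zeros(observed.ap_grid.size)),
                                  {"failed": True}))
    finite = [i for i, f in enumerate(fits)
              if np.isfinite(f.aic) or f.aic == float("-inf")]
    best = min(finite, key=lambda i: fits[i].aic)

    switching = cfg.switching != NO_SWITCH
    columns: List[str] = []
    for s in annotation.sites:
        if s.role == DUAL and switching:
            columns += [f"{s.site_id}(A)", f"{s.site_id}(R)"]
        else:
            columns.append(s.site_id)
    table = np.zeros((len(fits), len(columns)))
    for row, f in enumerate(fits):
        if f.optimizer_trace.get("failed"):
            continue
        col = 0
        for s in annotation.sites:
            if s.role == DUAL and switching:
                table[row, col] = f.params.k.get(s.site_id, 0.0)
                table[row, col + 1] = f.params.k_hb_repressor.get(
                    s.site_id, 0.0)
                col += 2
            else:
                table[row, col] = f.params.k.get(s.site_id, 0.0)
                col += 1
    k_table = pd.DataFrame(table, columns=columns)

    hist: Dict[int, int] = {}
    if switching:
        hb_ids = {s.site_id for s in annotation.sites if s.role == DUAL}
        for f in fits:
            if f.optimizer_trace.get("failed") or not (set(f.subset) & hb_ids):
                continue
            tau = f.params.hb_threshold
            if tau is not None:
                hist[tau] = hist.get(tau, 0) + 1
    return ModelSpaceResult(annotation.site_ids, fits, best, k_table, hist,
                            cfg.switching, n_failed)


def hb_threshold_histogram(results: ModelSpaceResult,
                           direction: str) -> Dict[int, int]:
    """Histogram of fitted switching thresholds tau over all subsets that
    contain at least one HB site."""
    if results.direction != direction or results.direction == NO_SWITCH:
        raise ValueError(
            f"sweep was run with direction {results.direction!r}, "
            f"not {direction!r}")
    return dict(results.threshold_histogram)


@dataclass
class ParameterLandscape:
    per_site: pd.DataFrame          # median/quartiles/outlier counts
    matrix: pd.DataFrame            # models x sites, clustered row order
    row_order: np.ndarray


def parameter_landscape(results: ModelSpaceResult) -> ParameterLandscape:
    """Per-site K summaries over the models containing each site, and the
    hierarchically clustered models x sites K matrix (absent site -> 0)."""
    table = results.k_value_table
    rows = []
    for col in table.columns:
        base = col.split("(")[0]
        included = np.array([base in f.subset for f in results.fits])
        vals = table[col].to_numpy()[included]
        if vals.size == 0:
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        outliers = int(np.sum((vals < q1 - 1.5 * iqr) |
                              (vals > q3 + 1.5 * iqr)))
        rows.append({"site": col, "n_models": int(included.sum()),
                     "median": med, "q1": q1, "q3": q3,
                     "n_outliers": outliers})
    per_site = pd.DataFrame(rows)
    mat = table.to_numpy()
    if mat.shape[0] > 2 and np.ptp(mat) > 0:
        link = hierarchy.linkage(mat, method="average")
        order = hierarchy.leaves_list(link)
    else:
        order = np.arange(mat.shape[0])
    ordered = table.iloc[order].reset_index(drop=True)
    return ParameterLandscape(per_site, ordered, order)


def rearrangement_test(annotation: EnhancerAnnotation,
                       observed: ExpressionProfile,
                       gradients: GradientSet,
                       n_perm: int = 100,
                       seed: int = 0,
                       fit_config: Optional[FitConfig] = None
                       ) -> Dict[str, object]:
    """Refit the model after randomly rearranging the retained sites.

    Each rearrangement permutes which site (TF identity, role, strand and
    width travel with it) occupies which of the original positions, so only
    order-dependent structure (adjacency-gated C and Q) can distinguish
    arrangements. Returns the actual arrangement's RMSE, all permutation
    RMSEs, and the count of permutations strictly below the actual.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    cfg = fit_config or FitConfig()
    slots = [s.start for s in annotation.sites]
    sites = list(annotation.sites)
    all_ids = tuple(annotation.site_ids)

    actual = fit_model(all_ids, annotation, observed, gradients, cfg)
    rng = np.random.default_rng(seed)
    perm_rmses = []
    for p in range(n_perm):
        perm = rng.permutation(len(sites))
        rearranged = [replace(sites[j], start=slots[i])
                      for i, j in enumerate(perm)]
        ann_p = EnhancerAnnotation(
            f"{annotation.enhancer_id}_perm{p}", annotation.sequence_length,
            rearranged, dict(annotation.roles_by_tf))
        fit = fit_model(tuple(ann_p.site_ids), ann_p, observed, gradients,
                        replace_cfg_seed(cfg, derived_seed(seed, p)))
        perm_rmses.append(fit.rmse)
    perm_rmses = np.array(perm_rmses)
    return {
        "actual_rmse": actual.rmse,
        "perm_rmses": perm_rmses,
        "n_below_actual": int(np.sum(perm_rmses < actual.rmse)),
        "actual_fit": actual,
    }


def replace_cfg_seed(cfg: FitConfig, seed: int) -> FitConfig:
    new = FitConfig(**{**cfg.__dict__})
    new.seed = seed
    return new
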