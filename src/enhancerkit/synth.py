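"""Synthetic inputs for every pipeline stage.

Real measurements for this system (transgenic embryo images and the atlas
TF gradients) are not redistributable, so the package generates stand-ins
with the right qualitative structure: stage-5-like AP gradients for the
five patterning TFs, enhancer sequences with planted motif instances,
noisy per-embryo AP intensity profiles drawn around a known thermodynamic
truth, and lateral-view embryo images with a planted expression pattern.
Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .motif import (DEFAULT_ROLES, BindingSite, EnhancerAnnotation, PWM)
from .thermo import (ExpressionProfile, GradientSet, ThermoParams,
                     default_grid, predict_expression)
from .utils import BASES, derived_seed, revcomp

#: Default per-position intensity noise, as a fraction of the (normalized)
#: expression scale, emulating embryo-to-embryo measurement scatter.
DEFAULT_NOISE_SD = 0.02

#: Default number of embryos per transgenic line (the measured lines had
#: 8-17 embryos each).
DEFAULT_N_EMBRYOS = 12


@dataclass
class SyntheticTruth:
    """A known ground truth tying together all model inputs."""

    annotation: EnhancerAnnotation
    params: ThermoParams
    gradients: GradientSet
    clean_profile: ExpressionProfile
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0


def synth_gradients(seed: int = 0,
                    grid: Optional[np.ndarray] = None,
                    jitter: float = 0.10) -> GradientSet:
    """Stage-5-like AP gradients for BCD, CAD, HB, KNI and KR.

    Shapes: BCD decays exponentially from the anterior; CAD rises toward
    the posterior (sigmoid); HB has an anterior plateau that falls off
    sharply mid-embryo plus a minor posterior peak; KNI is a posterior
    band and KR a central band (Gaussians). Shape parameters are jittered
    by ``jitter`` (fractional, seed-determined) and each profile is
    normalized to max 1.
    """
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size < 20:
        raise ValueError("grid must have at least 20 positions")
    rng = np.random.default_rng(seed)

    def j(x):
        return x * (1 + rng.uniform(-jitter, jitter))

    x = grid
    bcd = np.exp(-(x - x.min()) / j(22.0))
    cad = 1.0 / (1.0 + np.exp(-(x - j(55.0)) / j(8.0)))
    hb_plateau = 1.0 / (1.0 + np.exp((x - j(47.0)) / j(3.5)))
    hb_bump = j(0.45) * np.exp(-0.5 * ((x - j(83.0)) / j(4.0)) ** 2)
    hb = hb_plateau + hb_bump
    kni = np.exp(-0.5 * ((x - j(65.0)) / j(6.0)) ** 2)
    kr = np.exp(-0.5 * ((x - j(50.0)) / j(7.0)) ** 2)
    return GradientSet(grid, {"BCD": bcd, "CAD": cad, "HB": hb,
                              "KNI": kni, "KR": kr})


SitePlan = Sequence[Tuple[str, int, str]]  # (tf, offset, strand)


def synth_enhancer(pwms: Mapping[str, PWM],
                   site_plan: SitePlan,
                   seed: int = 0,
                   length: Optional[int] = None,
                   gc_content: float = 0.40
                   ) -> Tuple[str, EnhancerAnnotation]:
    """Random background sequence with planted PWM consensus sites.

    Each planned (tf, offset, strand) embeds the PWM's consensus word (its
    reverse complement on '-'); planned sites must not overlap. Returns the
    sequence and the truth annotation of planted sites.
    """
    rng = np.random.default_rng(seed)
    plan = sorted(site_plan, key=lambda t: t[1])
    for (tf_a, off_a, _), (tf_b, off_b, _) in zip(plan, plan[1:]):
        if off_a + pwms[tf_a].width > off_b:
            raise ValueError(
                f"planned sites overlap: {tf_a}@{off_a} and {tf_b}@{off_b}")
    min_len = max((off + pwms[tf].width for tf, off, _ in plan), default=0)
    if length is None:
        length = max(min_len + 50, 200)
    if length < min_len:
        raise ValueError("sequence length too short for the site plan")
    p_gc = gc_content / 2
    p_at = (1 - gc_content) / 2
    seq = list(rng.choice(list(BASES), size=length,
                          p=[p_at, p_gc, p_gc, p_at]))
    sites = []
    for tf, offset, strand in plan:
        pwm = pwms[tf]
        word = pwm.consensus if strand == "+" else revcomp(pwm.consensus)
        seq[offset:offset + pwm.width] = list(word)
        score = float(pwm.log_odds.max(axis=1).sum())
        sites.append(BindingSite(tf, offset, strand, pwm.width, score,
                                 ln_p=-score if score > 0 else -1.0,
                                 role=DEFAULT_ROLES.get(tf, "activator")))
    ann = EnhancerAnnotation("synthetic", length, sites)
    return "".join(seq), ann


def example_pwms(width: int = 8, strength: float = 0.85,
                 seed: int = 7) -> Dict[str, PWM]:
    """Synthetic example PWMs for the five AP patterning TFs.

    Each matrix has a distinct random consensus with per-position
    probability ``strength`` on the consensus base; these are illustrative
    stand-ins, not measured motifs.
    """
    rng = np.random.default_rng(seed)
    pwms = {}
    for tf in DEFAULT_ROLES:
        cons = rng.integers(0, 4, size=width)
        mat = np.full((width, 4), (1 - strength) / 3)
        mat[np.arange(width), cons] = strength
        pwms[tf] = PWM(tf, mat, ln_p_cutoff=-8.0)
    return pwms


def synth_expression(truth: SyntheticTruth,
                     n_embryos: int = DEFAULT_N_EMBRYOS,
                     seed: int = 0,
                     noise_sd: Optional[float] = None,
                     peak_jitter_ap: float = 0.0
                     ) -> List[ExpressionProfile]:
    """Noisy per-embryo profiles around the clean thermodynamic truth.

    Adds i.i.d. Gaussian noise (sd ``noise_sd``, clamped at 0) per position
    per embryo; optional per-embryo AP shift up to ``peak_jitter_ap`` %AP
    emulates embryo-to-embryo peak-location variation.
    """
    if n_embryos < 1:
        raise ValueError("n_embryos must be >= 1")
    sd = truth.noise_sd if noise_sd is None else noise_sd
    rng = np.random.default_rng(seed)
    grid = truth.clean_profile.ap_grid
    out = []
    for _ in range(n_embryos):
        mean = truth.clean_profile.mean
        if peak_jitter_ap > 0:
            shift = rng.uniform(-peak_jitter_ap, peak_jitter_ap)
            mean = np.interp(grid, grid + shift, mean)
        noisy = np.clip(mean + rng.normal(0.0, sd, size=grid.size), 0, None)
        out.append(ExpressionProfile(grid, noisy))
    return out


def make_synthetic_truth(site_plan: Optional[SitePlan] = None,
                         params: Optional[ThermoParams] = None,
                         seed: int = 0,
                         noise_sd: float = DEFAULT_NOISE_SD,
                         grid: Optional[np.ndarray] = None
                         ) -> SyntheticTruth:
    """Convenience constructor: plant an enhancer, draw gradients, and
    compute the clean expression profile from known parameters."""
    pwms = example_pwms()
    if site_plan is None:
        site_plan = [("BCD", 20, "+"), ("CAD", 60, "+"), ("HB", 100, "+"),
                     ("KNI", 140, "+"), ("KR", 180, "+")]
    _, ann = synth_enhancer(pwms, site_plan, seed=derived_seed(seed, 1))
    gradients = synth_gradients(seed=derived_seed(seed, 2), grid=grid)
    if params is None:
        # With C = 1 and Q = 1 sites are independent and repressors have no
        # effect (E reduces to the probability that an activator is bound);
        # short-range quenching is the repression mechanism, so the default
        # truth gives every repressor a strong quench on an activator whose
        # gradient overlaps its own. HB switches repressor -> activator at
        # nucleus 20: it damps the BCD-driven anterior domain and is the
        # sole activator behind the posterior domain, where the CAD, KNI
        # and KR bands all have leverage.
        ids = {s.tf_name: s.site_id for s in ann.sites}
        params = ThermoParams(
            k={s.site_id: k for s, k in zip(
                ann.sites, [8.0, 2.0, 6.0, 2.0, 2.5])},
            k_hb_repressor={s.site_id: 3.0 for s in ann.sites
                            if s.role == "dual"},
            q={(ids["HB"], ids["BCD"]): 0.4,
               (ids["CAD"], ids["HB"]): 0.3,
               (ids["KNI"], ids["HB"]): 0.25,
               (ids["KR"], ids["HB"]): 0.35},
            hb_threshold=20,
            hb_switch_direction="repressor_to_activator")
    clean = predict_expression(ann, params, gradients, grid=grid)
    return SyntheticTruth(ann, params, gradients, clean, noise_sd, seed)


@dataclass
class EmbryoGeometry:
    """Ellipse geometry and framing of a synthetic embryo image."""

    width_px: int = 360
    height_px: int = 200
    a_fraction: float = 0.44     # semi-major axis / frame width
    b_fraction: float = 0.30     # semi-minor axis / frame height
    background: float = 10.0
    amplitude: float = 100.0
    rotation_deg: float = 0.0


def synth_embryo_image(ap_profile: ExpressionProfile,
                       geometry: Optional[EmbryoGeometry] = None,
                       noise_sd: float = 0.0,
                       seed: int = 0,
                       dv_fraction: float = 0.25,
                       dv_sigma: float = 0.18
                       ) -> Tuple[np.ndarray, ExpressionProfile]:
    """Lateral-view embryo image with a planted separable expression
    pattern.

    Inside an elliptical mask the intensity is
    ``background + amplitude * f(%AP) * g(%DV)`` where ``f`` interpolates
    the given AP profile and ``g`` is a Gaussian band centered on the
    ``dv_fraction`` line; Gaussian pixel noise and a known rotation can be
    added. Returns the image and the planted truth profile along the
    ``dv_fraction`` DV line (i.e. the AP profile itself, on its grid).
    """
    geo = geometry or EmbryoGeometry()
    if geo.a_fraction <= 0 or geo.b_fraction <= 0:
        raise ValueError("ellipse axes must be positive")
    h, w = geo.height_px, geo.width_px
    cy, cx = (h - 1) / 2, (w - 1) / 2
    a, b = geo.a_fraction * w, geo.b_fraction * h
    yy, xx = np.mgrid[0:h, 0:w]
    mask = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0

    # embryo-relative coordinates: %AP from the mask bounding box, %DV per
    # column from the local dorsal (top) edge — matching how the
    # quantification pipeline measures the DV line
    ys, xs = np.nonzero(mask)
    x0, x1 = xs.min(), xs.max()
    ap = 100.0 * (xx - x0) / (x1 - x0)
    col_any = mask.any(axis=0)
    top = np.where(col_any, mask.argmax(axis=0), 0)
    bot = np.where(col_any, h - 1 - mask[::-1].argmax(axis=0), 1)
    height = np.maximum(1, bot - top)
    dv = (yy - top[None, :]) / height[None, :]

    # clamp to the end values outside the profile's AP span so the planted
    # pattern has no artificial cliff at the window edges
    f = np.interp(ap, ap_profile.ap_grid, ap_profile.mean)
    g = np.exp(-0.5 * ((dv - dv_fraction) / dv_sigma) ** 2)
    img = np.zeros((h, w), dtype=float)
    img[mask] = geo.background + geo.amplitude * (f * g)[mask]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img[mask] += rng.normal(0.0, noise_sd, size=int(mask.sum()))
        img = np.clip(img, 0.0, None)
    if geo.rotation_deg != 0.0:
        from skimage import transform
        img = transform.rotate(img, geo.rotation_deg, resize=True,
                               preserve_range=True, order=3)
        img = np.clip(img, 0.0, None)
    return img, ExpressionProfile(ap_profile.ap_grid,
                                  ap_profile.mean.copy())
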