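"""Quantification of reporter expression from lateral-view embryo images.

The pipeline mirrors a standard six-step in situ image workflow: binary
mask generation (Otsu threshold), rotation of the embryo's major axis to
horizontal (principal axis of the mask), resizing to a standard width,
uniform background subtraction (mean intensity in a non-expressing window
at 45-55% AP x 20-50% DV), normalization against a reference group's mean
anterior peak, and intensity extraction along the 25% DV line using
nucleus-neighborhood averaging: the AP axis of a lateral-view blastoderm
embryo spans ~65 nuclei, so one nucleus diameter is (AP pixel length)/65
and each profile value is the mean of in-mask pixels within a one-nucleus
radius.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage, stats
from skimage import measure, transform
from skimage.filters import threshold_multiotsu, threshold_otsu

from .gradients import resample
from .thermo import ExpressionProfile
from .utils import check_grid

#: Nuclei across the AP axis of a lateral-view stage-5 embryo.
NUCLEI_PER_AP_AXIS = 65

#: Default anterior-peak search window (%AP); anterior peaks of the
#: measured enhancers fall at 17-34% AP, so the window is padded.
ANTERIOR_WINDOW = (10.0, 45.0)

DEFAULT_PROFILE_GRID = np.arange(10.0, 95.0 + 1e-9, 0.5)


@dataclass
class EmbryoImage:
    """A single lateral-view embryo image with its segmentation mask."""

    pixels: np.ndarray
    mask: Optional[np.ndarray] = None
    anterior_side: str = "left"
    stage_label: str = ""
    group_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        if self.anterior_side not in ("left", "right"):
            raise ValueError("anterior_side must be 'left' or 'right'")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.pixels.shape:
                raise ValueError("mask/pixels shape mismatch")


@dataclass
class ProfileSummary:
    """Group-level summary of AP expression profiles."""

    mean_profile: ExpressionProfile
    peak_ap: np.ndarray
    peak_height: np.ndarray
    n: int


def _principal_angle(mask: np.ndarray) -> float:
    """Angle (degrees, counter-clockwise in image x/y) of the mask's major
    principal axis relative to horizontal."""
    ys, xs = np.nonzero(mask)
    x = xs - xs.mean()
    y = ys - ys.mean()
    cov = np.cov(np.vstack([x, y]))
    evals, evecs = np.linalg.eigh(cov)
    vx, vy = evecs[:, np.argmax(evals)]
    angle = float(np.degrees(np.arctan2(vy, vx)))
    # an axis has no direction: normalize to (-90, 90] so that correcting
    # the tilt never flips the embryo end-for-end
    if angle > 90:
        angle -= 180
    elif angle <= -90:
        angle += 180
    return angle


def segment_and_align(image: EmbryoImage,
                      standard_width: int = 400,
                      min_area_fraction: float = 0.05,
                      bright_embryo: bool = True) -> EmbryoImage:
    """Segment the embryo, rotate its major axis to horizontal, resize to a
    standard width, and place the anterior end on the left.

    The mask is the largest connected component of the Otsu-thresholded
    frame (polarity set by ``bright_embryo``); a component smaller than
    ``min_area_fraction`` of the frame is a segmentation error.
    """
    px = image.pixels
    # mask is computed on a lightly smoothed copy so pixel noise cannot
    # fragment the embryo component; intensities are taken from `px`
    sm = ndimage.gaussian_filter(px, 2.0)

    def _component(threshold):
        binary = sm > threshold if bright_embryo else sm < threshold
        binary = ndimage.binary_fill_holes(binary)
        labels, n = ndimage.label(binary)
        if n == 0:
            return None
        sizes = ndimage.sum(binary, labels, index=np.arange(1, n + 1))
        return labels == int(np.argmax(sizes)) + 1

    if image.mask is not None:
        mask = image.mask
        if mask.sum() < min_area_fraction * px.size:
            raise ValueError("provided mask below minimum embryo area")
        return _align_masked(image, mask, standard_width)

    # A frame with a bright expression domain on a dim embryo body is
    # trimodal (exterior | body | domain) and plain Otsu then splits the
    # domain from the body; three-class Otsu's outermost threshold
    # separates exterior from embryo in both the bimodal and trimodal case.
    try:
        thresholds = threshold_multiotsu(sm, classes=3)
        t = thresholds[0] if bright_embryo else thresholds[-1]
    except ValueError:  # fewer than 3 distinct gray levels
        t = threshold_otsu(sm)
    mask = _component(t)
    if mask is None or mask.sum() < min_area_fraction * px.size:
        mask = _component(threshold_otsu(sm))
    if mask is None or mask.sum() < min_area_fraction * px.size:
        raise ValueError("largest component below minimum embryo area")
    return _align_masked(image, mask, standard_width)


def _align_masked(image: EmbryoImage, mask: np.ndarray,
                  standard_width: int) -> EmbryoImage:
    px = image.pixels
    angle = _principal_angle(mask)
    # rotate so the major axis is horizontal; skimage rotates CCW in the
    # displayed image (y down), so rotating by `angle` cancels it
    rot_px = transform.rotate(px, angle, resize=True, preserve_range=True,
                              order=3)
    rot_mask = transform.rotate(mask.astype(float), angle, resize=True,
                                preserve_range=True, order=0) > 0.5

    ys, xs = np.nonzero(rot_mask)
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    crop_px = rot_px[y0:y1, x0:x1]
    crop_mask = rot_mask[y0:y1, x0:x1]

    scale = standard_width / crop_px.shape[1]
    out_shape = (max(2, int(round(crop_px.shape[0] * scale))), standard_width)
    res_px = transform.resize(crop_px, out_shape, preserve_range=True,
                              order=1, anti_aliasing=True)
    res_mask = transform.resize(crop_mask.astype(float), out_shape,
                                preserve_range=True, order=0,
                                anti_aliasing=False) > 0.5
    if image.anterior_side == "right":
        res_px = res_px[:, ::-1]
        res_mask = res_mask[:, ::-1]
    return EmbryoImage(res_px, res_mask, anterior_side="left",
                       stage_label=image.stage_label,
                       group_id=image.group_id)


def subtract_background(image: EmbryoImage,
                        ap_window: Tuple[float, float] = (0.45, 0.55),
                        dv_window: Tuple[float, float] = (0.20, 0.50)
                        ) -> EmbryoImage:
    """Uniform background subtraction.

    The mean intensity of in-mask pixels within the non-expressing window
    (fractions of the mask bounding box; AP from the anterior/left edge, DV
    from the dorsal/top edge) is subtracted from all in-mask pixels;
    negative values clamp to 0.
    """
    if image.mask is None:
        raise ValueError("image must be segmented first")
    ys, xs = np.nonzero(image.mask)
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    h, w = y1 - y0, x1 - x0
    xa = x0 + int(np.floor(ap_window[0] * w))
    xb = x0 + int(np.ceil(ap_window[1] * w))
    ya = y0 + int(np.floor(dv_window[0] * h))
    yb = y0 + int(np.ceil(dv_window[1] * h))
    region = np.zeros_like(image.mask)
    region[ya:yb, xa:xb] = True
    region &= image.mask
    if not region.any():
        raise ValueError("background window does not intersect the mask")
    bg = image.pixels[region].mean()
    px = image.pixels.copy()
    px[image.mask] = np.clip(px[image.mask] - bg, 0.0, None)
    return replace(image, pixels=px)


def extract_ap_profile(image: EmbryoImage,
                       dv_fraction: float = 0.25,
                       ap_range: Tuple[float, float] = (0.10, 0.95),
                       grid: Optional[np.ndarray] = None
                       ) -> ExpressionProfile:
    """Nucleus-averaged intensity along the ``dv_fraction`` DV line.

    The DV position is measured from the dorsal (top) edge of the mask in
    each AP column. Each sample is the mean of in-mask pixels within one
    nucleus radius, where the nucleus diameter is the AP pixel length
    divided by 65. The profile is returned on a common %AP grid.
    """
    if image.mask is None:
        raise ValueError("image must be segmented first")
    mask = image.mask
    ys, xs = np.nonzero(mask)
    x0, x1 = xs.min(), xs.max()  # inclusive span: 0 and 100 %AP columns
    ap_len = x1 - x0
    nucleus_diameter = ap_len / NUCLEI_PER_AP_AXIS
    radius = max(1, int(round(nucleus_diameter)))

    # disk-mean via convolution of masked intensities and the mask
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    disk = (yy ** 2 + xx ** 2 <= radius ** 2).astype(float)
    num = ndimage.convolve(image.pixels * mask, disk, mode="constant")
    den = ndimage.convolve(mask.astype(float), disk, mode="constant")

    cols = np.arange(x0 + int(np.floor(ap_range[0] * ap_len)),
                     x0 + int(np.ceil(ap_range[1] * ap_len)) + 1)
    ap_percent, values = [], []
    for cx in cols:
        rows = np.nonzero(mask[:, cx])[0]
        if rows.size == 0:
            continue
        ytop, ybot = rows.min(), rows.max()
        cy = int(round(ytop + dv_fraction * (ybot - ytop)))
        if not mask[cy, cx]:
            continue
        if den[cy, cx] <= 0:
            continue
        ap_percent.append(100.0 * (cx - x0) / ap_len)
        values.append(num[cy, cx] / den[cy, cx])
    if len(values) < 2:
        raise ValueError("DV line lies outside the mask")
    prof = ExpressionProfile(np.array(ap_percent), np.array(values))
    target = DEFAULT_PROFILE_GRID if grid is None else check_grid(grid)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return resample(prof, target)


def _anterior_peak(profile: ExpressionProfile,
                   window: Tuple[float, float] = ANTERIOR_WINDOW
                   ) -> Tuple[float, float]:
    sel = (profile.ap_grid >= window[0]) & (profile.ap_grid <= window[1])
    if not sel.any():
        raise ValueError("anterior window outside profile grid")
    i = int(np.argmax(profile.mean[sel]))
    return float(profile.ap_grid[sel][i]), float(profile.mean[sel][i])


def normalize_group(images: Sequence[EmbryoImage],
                    group_ids: Sequence[str],
                    reference_group_id: str,
                    dv_fraction: float = 0.25) -> List[EmbryoImage]:
    """Scale all images by the reference group's mean anterior-peak
    intensity, so that the reference group's mean peak equals 1."""
    ref_peaks = []
    for img, gid in zip(images, group_ids):
        if gid == reference_group_id:
            prof = extract_ap_profile(img, dv_fraction=dv_fraction)
            ref_peaks.append(_anterior_peak(prof)[1])
    if not ref_peaks:
        raise ValueError(f"reference group {reference_group_id!r} is empty")
    scale = float(np.mean(ref_peaks))
    if scale <= 0:
        raise ValueError("reference group peak intensity is 0")
    out = []
    for img in images:
        px = img.pixels.copy()
        if img.mask is not None:
            px[img.mask] /= scale
        else:
            px /= scale
        out.append(replace(img, pixels=px))
    return out


def summarize_group(profiles: Sequence[ExpressionProfile],
                    anterior_window: Tuple[float, float] = ANTERIOR_WINDOW
                    ) -> ProfileSummary:
    """Pointwise mean and standard error over embryos, plus per-embryo
    anterior peak location and height."""
    if len(profiles) == 0:
        raise ValueError("need at least one profile")
    grid = profiles[0].ap_grid
    for p in profiles[1:]:
        if p.ap_grid.shape != grid.shape or not np.allclose(p.ap_grid, grid):
            raise ValueError("profiles are on different grids")
    stack = np.vstack([p.mean for p in profiles])
    mean = stack.mean(axis=0)
    n = len(profiles)
    if n == 1:
        warnings.warn("single profile: standard error set to 0", stacklevel=2)
        se = np.zeros_like(mean)
    else:
        se = stack.std(axis=0, ddof=1) / np.sqrt(n)
    peaks = [_anterior_peak(p, anterior_window) for p in profiles]
    return ProfileSummary(
        ExpressionProfile(grid, mean, se, n),
        np.array([p[0] for p in peaks]),
        np.array([p[1] for p in peaks]), n)


def compare_groups(summary_a: ProfileSummary,
                   summary_b: ProfileSummary,
                   exact_threshold: int = 8) -> Dict[str, object]:
    """Pearson correlation of mean profiles plus Mann-Whitney U tests on
    per-embryo anterior peak heights and locations.

    The U test p-value is exact when both groups have at most
    ``exact_threshold`` embryos, otherwise the tie-corrected normal
    approximation is used.
    """
    pa, pb = summary_a.mean_profile, summary_b.mean_profile
    if pa.ap_grid.shape != pb.ap_grid.shape or \
            not np.allclose(pa.ap_grid, pb.ap_grid):
        raise ValueError("mean profiles are on different grids")
    if np.ptp(pa.mean) == 0 or np.ptp(pb.mean) == 0:
        r, r_p = float("nan"), float("nan")
    else:
        r, r_p = stats.pearsonr(pa.mean, pb.mean)

    def _u(x, y):
        method = ("exact" if len(x) <= exact_threshold and
                  len(y) <= exact_threshold else "asymptotic")
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method=method)
        return float(res.statistic), float(res.pvalue)

    u_h, p_h = _u(summary_a.peak_height, summary_b.peak_height)
    u_l, p_l = _u(summary_a.peak_ap, summary_b.peak_ap)
    return {
        "pearson_r": float(r),
        "pearson_p": float(r_p),
        "peak_height_u": u_h, "peak_height_p": p_h,
        "peak_location_u": u_l, "peak_location_p": p_l,
        "n_a": summary_a.n, "n_b": summary_b.n,
    }


def correlation_matrix(summaries: Dict[str, ProfileSummary]):
    """Pairwise Pearson correlation matrix of group mean profiles."""
    import pandas as pd
    names = list(summaries)
    mat = np.eye(len(names))
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            r = compare_groups(summaries[a], summaries[names[j]])["pearson_r"]
            mat[i, j] = mat[j, i] = r
    return pd.DataFrame(mat, index=names, columns=names)
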