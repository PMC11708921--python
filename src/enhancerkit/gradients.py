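"""TF concentration inputs for the occupancy model.

Protein gradients (BCD, HB, KR) are used directly; for CAD and KNI only
mRNA profiles are available at the relevant stage, so a simple translation
model converts mRNA measured 10 minutes earlier into predicted protein:
linear production from the mRNA template with optional first-order protein
decay,

    dP/dt = r * M - lambda * P,   P(0) = P0,

integrated in closed form over ``delta_t`` minutes. With ``lambda = 0``
(the default) the protein profile is shape-identical to the mRNA profile.
All gradients are normalized to a maximum of 1 before modeling; any
absolute scale is absorbed into the fitted site strengths K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .thermo import ExpressionProfile, GradientSet
from .utils import check_grid


@dataclass
class TranslationConfig:
    """Parameters of the mRNA -> protein translation step.

    production_rate and decay_rate are per minute; delta_t is the elapsed
    time in minutes between the mRNA and protein snapshots.
    """

    production_rate: float = 1.0
    decay_rate: float = 0.0
    delta_t: float = 10.0
    initial_protein: float | np.ndarray = 0.0

    def __post_init__(self) -> None:
        if self.delta_t <= 0:
            raise ValueError("delta_t must be > 0")
        if self.production_rate < 0 or self.decay_rate < 0:
            raise ValueError("rates must be >= 0")


def load_gradient_table(path) -> GradientSet:
    """Read a gradient TSV with columns tf, position, value.

    ``position`` may be %AP or a nucleus index, as long as it is consistent
    within the file. TFs measured on different grids are linearly resampled
    onto the union grid (endpoints clamped); each TF is normalized to a
    maximum of 1.
    """
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        return GradientSet(np.array([0.0, 1.0]), {})
    required = {"tf", "position", "value"}
    if not required <= set(df.columns):
        raise ValueError(f"gradient table needs columns {sorted(required)}")
    if (df["value"] < 0).any():
        raise ValueError("negative concentration values in gradient table")
    grid = np.unique(df["position"].to_numpy(dtype=float))
    conc = {}
    for tf, sub in df.groupby("tf"):
        sub = sub.sort_values("position")
        conc[str(tf)] = np.interp(grid, sub["position"].to_numpy(dtype=float),
                                  sub["value"].to_numpy(dtype=float))
    return GradientSet(grid, conc)


def write_gradient_table(gradients: GradientSet, path) -> None:
    rows = [(tf, p, v)
            for tf, vec in gradients.concentrations.items()
            for p, v in zip(gradients.ap_grid, vec)]
    pd.DataFrame(rows, columns=["tf", "position", "value"]).to_csv(
        path, sep="\t", index=False)


def translate_mrna_to_protein(mrna: np.ndarray,
                              cfg: Optional[TranslationConfig] = None,
                              normalize: bool = True) -> np.ndarray:
    """Predict protein from an mRNA profile under the translation ODE.

    Closed form per position, with M constant over the interval:
    ``P = M * (r/lambda) * (1 - exp(-lambda dt)) + P0 * exp(-lambda dt)``
    for ``lambda > 0`` and ``P = P0 + r * M * dt`` for ``lambda = 0``.
    The result is renormalized to max 1 unless ``normalize=False``.
    """
    if cfg is None:
        cfg = TranslationConfig()
    m = np.asarray(mrna, dtype=float)
    if np.any(m < 0):
        raise ValueError("mRNA concentrations must be >= 0")
    p0 = np.broadcast_to(np.asarray(cfg.initial_protein, dtype=float),
                         m.shape)
    lam, r, dt = cfg.decay_rate, cfg.production_rate, cfg.delta_t
    if lam > 0:
        p = m * (r / lam) * (1.0 - np.exp(-lam * dt)) + p0 * np.exp(-lam * dt)
    else:
        p = p0 + r * m * dt
    if normalize and p.max() > 0:
        p = p / p.max()
    return p


def resample(profile: ExpressionProfile,
             target_grid: np.ndarray) -> ExpressionProfile:
    """Linear resampling of a profile onto ``target_grid``.

    Exact on piecewise-linear inputs; points outside the source span clamp
    to the nearest endpoint with a warning.
    """
    target_grid = check_grid(target_grid)
    lo, hi = profile.ap_grid[0], profile.ap_grid[-1]
    if target_grid[0] < lo or target_grid[-1] > hi:
        warnings.warn("target grid extends beyond source span; clamping",
                      stacklevel=2)
    mean = np.interp(target_grid, profile.ap_grid, profile.mean)
    se = (np.interp(target_grid, profile.ap_grid, profile.se)
          if profile.se is not None else None)
    return ExpressionProfile(target_grid, mean, se, profile.n_embryos)
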