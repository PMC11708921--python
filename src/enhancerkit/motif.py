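"""PWM-based binding-site prediction with exact p-values.

A position weight matrix (PWM) models a transcription factor's binding
preference as per-position base probabilities. Windows of a sequence are
scored as log-odds against a background base composition, on both strands.
Significance is assessed with the *exact* p-value of a score: the
probability that a random background word of the motif's width scores at
least as high, computed by dynamic programming over the discretized score
distribution (the classic Patser/TFM-pvalue construction). Sites are kept
when ln(p) falls at or below a per-TF cutoff, and the strongest few sites
per TF are retained for thermodynamic modeling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO

from .utils import BASES, BASE_INDEX, revcomp

logger = logging.getLogger(__name__)

#: Regulatory roles of the five anterior-posterior patterning factors used
#: throughout: BICOID activates, CAUDAL/KNIRPS/KRUPPEL repress, and
#: HUNCHBACK is dual (activator or repressor depending on AP position).
DEFAULT_ROLES: Dict[str, str] = {
    "BCD": "activator",
    "CAD": "repressor",
    "HB": "dual",
    "KNI": "repressor",
    "KR": "repressor",
}

ACTIVATOR, REPRESSOR, DUAL = "activator", "repressor", "dual"


@dataclass
class PWM:
    """Position weight matrix over {A, C, G, T}.

    Parameters
    ----------
    tf_name : str
        Label of the factor the matrix models.
    matrix : (W, 4) array
        Per-position base probabilities; each row sums to 1.
    background : (4,) array
        Background base frequencies, strictly positive, summing to 1.
    ln_p_cutoff : float, optional
        Natural-log p-value cutoff used by :func:`find_sites`; negative.
    pseudocount : float
        Pseudocount that was added when building from counts (kept for
        provenance; already folded into ``matrix``).
    """

    tf_name: str
    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    ln_p_cutoff: Optional[float] = None
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (W, 4)")
        if np.any(self.background <= 0):
            raise ValueError("background frequencies must be > 0")
        if abs(self.background.sum() - 1.0) > 1e-6:
            raise ValueError("background frequencies must sum to 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if self.ln_p_cutoff is not None and not self.ln_p_cutoff < 0:
            raise ValueError("ln_p_cutoff must be negative")
        # Regularize zero-probability cells so log-odds are finite, then
        # renormalize each column.
        if self.pseudocount > 0 and np.any(self.matrix == 0):
            self.matrix = self.matrix + self.pseudocount
        rowsum = self.matrix.sum(axis=1, keepdims=True)
        if np.any(rowsum <= 0):
            raise ValueError("PWM has an empty column")
        self.matrix = self.matrix / rowsum
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")
        self._pvalue_cache: dict = {}

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(W, 4) natural-log odds ln(p_ij / bg_j)."""
        with np.errstate(divide="ignore"):
            return np.log(self.matrix) - np.log(self.background)

    @property
    def consensus(self) -> str:
        return "".join(BASES[j] for j in np.argmax(self.matrix, axis=1))

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=1).sum())

    @classmethod
    def from_counts(cls, tf_name: str, counts: np.ndarray,
                    background: Optional[np.ndarray] = None,
                    ln_p_cutoff: Optional[float] = None,
                    pseudocount: float = 0.01) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        mat = counts + pseudocount
        mat = mat / mat.sum(axis=1, keepdims=True)
        bg = np.full(4, 0.25) if background is None else background
        return cls(tf_name, mat, bg, ln_p_cutoff, pseudocount)


@dataclass(frozen=True)
class BindingSite:
    """A scored PWM match. Coordinates are 0-based, half-open; minus-strand
    sites are reported by the plus-strand start of the window."""

    tf_name: str
    start: int
    strand: str
    width: int
    score: float
    ln_p: float
    role: str = ACTIVATOR

    @property
    def end(self) -> int:
        return self.start + self.width

    def overlaps(self, other: "BindingSite") -> bool:
        return self.start < other.end and other.start < self.end

    @property
    def site_id(self) -> str:
        return f"{self.tf_name}@{self.start}{self.strand}"


@dataclass
class EnhancerAnnotation:
    """Ordered binding-site annotation of one enhancer."""

    enhancer_id: str
    sequence_length: int
    sites: List[BindingSite]
    roles_by_tf: Dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_ROLES))

    def __post_init__(self) -> None:
        self.sites = sorted(self.sites, key=lambda s: (s.start, s.strand))
        for a, b in zip(self.sites, self.sites[1:]):
            if a.tf_name == b.tf_name and a.overlaps(b):
                raise ValueError(
                    f"overlapping sites for {a.tf_name} at {a.start}/{b.start}")

    @property
    def site_ids(self) -> List[str]:
        return [s.site_id for s in self.sites]

    def subset(self, site_ids: Iterable[str]) -> "EnhancerAnnotation":
        keep = set(site_ids)
        return EnhancerAnnotation(
            self.enhancer_id, self.sequence_length,
            [s for s in self.sites if s.site_id in keep],
            dict(self.roles_by_tf))


def _window_scores(pwm: PWM, window: str) -> float:
    lod = pwm.log_odds
    total = 0.0
    for j, base in enumerate(window):
        if base == "N":
            continue  # ambiguous base: background-neutral, contributes 0
        try:
            total += lod[j, BASE_INDEX[base]]
        except KeyError:
            raise ValueError(f"non-ACGTN character {base!r} in window")
    return total


def score_window(pwm: PWM, window: str, strand: str = "+") -> float:
    """Log-odds score of one window; strand '-' scores the reverse
    complement of the given (plus-strand) window."""
    window = window.upper()
    if len(window) != pwm.width:
        raise ValueError(
            f"window length {len(window)} != PWM width {pwm.width}")
    if strand not in "+-":
        raise ValueError("strand must be '+' or '-'")
    if strand == "-":
        window = revcomp(window)
    return _window_scores(pwm, window)


def _score_distribution(pwm: PWM, n_bins: int) -> Tuple[np.ndarray, np.ndarray]:
    """Discretized background score distribution.

    Returns (sorted unique integer-scaled scores, ln survival probability
    P(S >= s)) for the sum of per-column log-odds under the background.
    """
    if n_bins < 100:
        raise ValueError("p-value discretization needs >= 100 bins")
    lod = pwm.log_odds
    finite = np.isfinite(lod)
    if not finite.all():
        # zero-probability cells (pseudocount 0): floor far below every
        # attainable finite score so such words rank strictly last
        floor = lod[finite].min() - 100.0
        lod = np.where(finite, lod, floor)
    span = float(lod.max(axis=1).sum() - lod.min(axis=1).sum())
    delta = span / n_bins if span > 0 else 1.0
    iscores = np.rint(lod / delta).astype(np.int64)  # (W, 4)
    # Convolve the per-column distributions over an integer score lattice.
    lo = 0  # minimum integer sum represented by dist[0]
    dist = np.array([1.0])
    for j in range(pwm.width):
        col = iscores[j]
        cmin, cmax = int(col.min()), int(col.max())
        new = np.zeros(len(dist) + cmax - cmin)
        for b in range(4):
            shift = int(col[b]) - cmin
            new[shift:shift + len(dist)] += pwm.background[b] * dist
        dist = new
        lo += cmin
    values = lo + np.arange(len(dist))
    # survival: P(S >= v)
    surv = np.cumsum(dist[::-1])[::-1]
    surv = np.clip(surv, 0.0, 1.0)
    with np.errstate(divide="ignore"):
        ln_surv = np.log(surv)
    return values.astype(float) * delta, ln_surv


def site_pvalue(pwm: PWM, score: float, n_bins: int = 10_000) -> float:
    """Natural log of the exact p-value P(background score >= score).

    Computed by dynamic programming on the discretized per-column score
    distribution; monotone non-increasing in ``score``. The default 10,000
    bins keep |error in ln p| well under 0.01 for motif widths <= 8.
    """
    if score == -np.inf:
        return 0.0  # every word scores >= -inf
    if not np.isfinite(score):
        raise ValueError("score must be finite")
    key = ("dist", n_bins)
    if key not in pwm._pvalue_cache:
        pwm._pvalue_cache[key] = _score_distribution(pwm, n_bins)
    values, ln_surv = pwm._pvalue_cache[key]
    # Per-column rounding shifts a word's lattice total by at most W/2
    # bins, so thresholding with that margin guarantees every word whose
    # true score is >= `score` is counted (a one-sided, vanishing error).
    delta = values[1] - values[0] if len(values) > 1 else 1.0
    margin = (pwm.width / 2 + 0.5) * delta
    idx = int(np.searchsorted(values, score - margin, side="left"))
    if idx >= len(values):
        return float(ln_surv[-1])
    return float(ln_surv[idx])


def find_sites(pwm: PWM, sequence: str,
               ln_p_cutoff: Optional[float] = None,
               role: Optional[str] = None,
               n_bins: int = 10_000) -> List[BindingSite]:
    """Scan both strands of ``sequence`` for PWM matches with
    ln(p) <= cutoff; overlapping hits of the same PWM are resolved greedily
    in favor of the better score. Returned sites are ordered by start."""
    sequence = sequence.upper()
    if len(sequence) == 0:
        raise ValueError("empty sequence")
    W = pwm.width
    if len(sequence) < W:
        raise ValueError(f"sequence shorter than PWM width {W}")
    cutoff = ln_p_cutoff if ln_p_cutoff is not None else pwm.ln_p_cutoff
    if cutoff is None:
        raise ValueError("no ln_p_cutoff given and PWM carries none")
    if role is None:
        role = DEFAULT_ROLES.get(pwm.tf_name, ACTIVATOR)

    hits: List[BindingSite] = []
    for start in range(len(sequence) - W + 1):
        window = sequence[start:start + W]
        for strand in "+-":
            s = score_window(pwm, window, strand)
            lp = site_pvalue(pwm, s, n_bins=n_bins)
            if lp <= cutoff:
                hits.append(BindingSite(pwm.tf_name, start, strand, W, s, lp,
                                        role))
    # greedy overlap resolution: best score first; ties -> smaller start,
    # then + strand
    hits.sort(key=lambda h: (-h.score, h.start, h.strand))
    kept: List[BindingSite] = []
    for h in hits:
        if not any(h.overlaps(k) for k in kept):
            kept.append(h)
    kept.sort(key=lambda h: (h.start, h.strand))
    return kept


def select_strongest(sites_by_tf: Mapping[str, Sequence[BindingSite]],
                     k_per_tf: int = 2,
                     enhancer_id: str = "enhancer",
                     sequence_length: Optional[int] = None,
                     roles_by_tf: Optional[Mapping[str, str]] = None,
                     ) -> EnhancerAnnotation:
    """Retain the ``k_per_tf`` strongest non-overlapping sites per TF and
    merge them into one annotation ordered by start.

    Ties in score break toward the smaller start, then the + strand. A TF
    with fewer than ``k_per_tf`` usable sites triggers a warning and keeps
    whatever is available.
    """
    roles = dict(DEFAULT_ROLES)
    if roles_by_tf:
        roles.update(roles_by_tf)
    retained: List[BindingSite] = []
    for tf, sites in sites_by_tf.items():
        ranked = sorted(sites, key=lambda s: (-s.score, s.start, s.strand))
        chosen: List[BindingSite] = []
        for s in ranked:
            if len(chosen) >= k_per_tf:
                break
            if any(s.overlaps(c) for c in chosen):
                continue
            chosen.append(s)
        if len(chosen) < k_per_tf:
            warnings.warn(
                f"{tf}: only {len(chosen)} non-overlapping site(s) "
                f"available (requested {k_per_tf})", stacklevel=2)
        role = roles.get(tf, ACTIVATOR)
        retained.extend(replace(s, role=role) for s in chosen)
    if sequence_length is None:
        sequence_length = max((s.end for s in retained), default=0)
    return EnhancerAnnotation(enhancer_id, sequence_length, retained,
                              {tf: roles.get(tf, ACTIVATOR)
                               for tf in sites_by_tf})


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path) -> Dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def read_pwms(path, background: Optional[np.ndarray] = None,
              pseudocount: float = 0.01) -> Dict[str, PWM]:
    """Read PWMs from a plain-text file.

    Dialect (JASPAR-like): a ``>name [ln_p_cutoff]`` header followed by four
    whitespace-delimited rows in A, C, G, T order; rows may be counts or
    probabilities (anything with non-negative entries normalizes by column
    of the 4xW block). Comment lines start with '#'.
    """
    pwms: Dict[str, PWM] = {}
    name, cutoff, rows = None, None, []

    def flush():
        if name is None:
            return
        if len(rows) != 4:
            raise ValueError(f"PWM {name}: expected 4 rows, got {len(rows)}")
        counts = np.array(rows, dtype=float).T  # (W, 4)
        if np.any(counts < 0):
            raise ValueError(f"PWM {name}: negative entries")
        bg = np.full(4, 0.25) if background is None else background
        # rows normalize per position; zeros are regularized by the
        # pseudocount only when present, so probability matrices round-trip
        pwms[name] = PWM(name, counts, bg, ln_p_cutoff=cutoff,
                         pseudocount=pseudocount)

    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            flush()
            parts = line[1:].split()
            name = parts[0]
            cutoff = float(parts[1]) if len(parts) > 1 else None
            rows = []
        else:
            rows.append([float(x) for x in line.replace(",", " ").split()])
    flush()
    return pwms


def write_pwms(pwms: Mapping[str, PWM], path) -> None:
    """Write PWMs in the 4-row text dialect read by :func:`read_pwms`."""
    lines = []
    for name, pwm in pwms.items():
        header = f">{name}"
        if pwm.ln_p_cutoff is not None:
            header += f" {pwm.ln_p_cutoff}"
        lines.append(header)
        for j in range(4):  # rows A, C, G, T
            lines.append(" ".join(f"{v:.6f}" for v in pwm.matrix[:, j]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_sites_tsv(annotation: EnhancerAnnotation, path) -> None:
    """Write a site table: enhancer_id, tf, start, end, strand, score,
    ln_p, role."""
    df = pd.DataFrame(
        [(annotation.enhancer_id, s.tf_name, s.start, s.end, s.strand,
          s.score, s.ln_p, s.role) for s in annotation.sites],
        columns=["enhancer_id", "tf", "start", "end", "strand", "score",
                 "ln_p", "role"])
    df.to_csv(path, sep="\t", index=False)
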