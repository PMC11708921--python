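"""Small shared helpers: sequence alphabet, coordinate arithmetic, seeding."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def inclusive_span_length(start: int, end: int) -> int:
    """Length in bp of the inclusive genomic span [start, end].

    Both endpoints are 1-based genomic coordinates and are counted, matching
    how PCR product sizes are quoted from the outermost primer positions.
    """
    if end < start:
        raise ValueError(f"end ({end}) precedes start ({start})")
    return end - start + 1


def derived_seed(root: int, *path: int) -> int:
    """Deterministic child seed below 2**31 from a root seed and a path."""
    ss = np.random.SeedSequence([int(root), *[int(p) for p in path]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def check_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError("grid must be a 1-D array with >= 2 positions")
    if not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing")
    return grid
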