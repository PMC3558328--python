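"""Niche overlap and breadth statistics on habitat-suitability grids.

Operates on rectangular grids of non-negative suitability scores (e.g.
Maxent output) with an optional validity mask.  After normalizing each
grid's scores to sum to one over valid cells (p_i), the statistics are:

* Schoener's D = 1 - 1/2 * sum |p1_i - p2_i|
* Warren's   I = 1 - 1/2 * sum (sqrt(p1_i) - sqrt(p2_i))**2
* relative rank RR = proportion of valid cell pairs whose suitability
  ordering agrees between the two grids (a pair tied in exactly one
  grid counts 1/2); computed
  exactly up to 2000 cells and by seeded pair sampling above
* Levins' standardized breadth B = (1 / sum p_i**2 - 1) / (n - 1)

All overlap statistics range from 0 (disjoint niches) to 1 (identical);
they are invariant to positive rescaling of the raw scores but not to
monotone transforms.  RR is implemented as pairwise (Kendall-style) rank
concordance scaled to [0, 1]; the reference tool's exact estimator is not
published, so this is a documented dialect choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InputError

__all__ = [
    "SuitabilityGrid",
    "read_grid",
    "normalize_suitability",
    "niche_overlap_stats",
    "niche_breadth",
]


@dataclass(frozen=True)
class SuitabilityGrid:
    """Non-negative suitability scores with a validity mask."""

    values: np.ndarray
    mask: np.ndarray  # True where the cell is valid

    def __post_init__(self) -> None:
        v, m = np.asarray(self.values, float), np.asarray(self.mask, bool)
        if v.ndim != 2 or v.shape != m.shape:
            raise InputError("grid must be 2-D with a mask of the same shape")
        vv = v[m]
        if vv.size == 0 or not np.all(np.isfinite(vv)) or np.any(vv < 0):
            raise InputError("grid needs finite non-negative scores on valid cells")
        if not np.any(vv > 0):
            raise InputError("all-zero grid")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "mask", m)

    @classmethod
    def from_array(cls, values: np.ndarray, mask: np.ndarray | None = None) -> "SuitabilityGrid":
        values = np.asarray(values, float)
        if mask is None:
            mask = np.isfinite(values)
        return cls(values=values, mask=np.asarray(mask, bool))

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]


def read_grid(path: str | Path) -> SuitabilityGrid:
    """Read a plain-text matrix, or an ESRI-ASCII-style grid with a
    key/value header (``ncols``/``nrows``/.../``NODATA_value``)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    header: dict[str, float] = {}
    body_start = 0
    for k, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            body_start = k + 1
        else:
            break
    try:
        values = np.loadtxt(lines[body_start:], ndmin=2)
    except ValueError as exc:
        raise InputError(f"cannot parse grid {path}: {exc}") from exc
    mask = np.isfinite(values)
    if "nodata_value" in header:
        mask &= values != header["nodata_value"]
    return SuitabilityGrid(values=np.where(mask, values, 0.0), mask=mask)


def normalize_suitability(grid: SuitabilityGrid) -> SuitabilityGrid:
    """Rescale so scores over valid cells sum to 1 (idempotent)."""
    total = grid.valid_values().sum()
    values = np.where(grid.mask, grid.values / total, 0.0)
    return SuitabilityGrid(values=values, mask=grid.mask)


def _rank_concordance(v1: np.ndarray, v2: np.ndarray, max_exact: int,
                      n_samples: int, seed: int) -> float:
    n = v1.size
    if n < 2:
        raise InputError("need at least 2 valid cells")
    def score(a, b):
        # agreement per pair: 1 when the orderings agree (a tie in both
        # grids agrees trivially), 1/2 when tied in exactly one grid only
        agree = (a == b).astype(float)
        half = (a == 0) ^ (b == 0)
        return float(np.mean(np.where(half, 0.5, agree)))

    if n <= max_exact:
        s1 = np.sign(v1[:, None] - v1[None, :])
        s2 = np.sign(v2[:, None] - v2[None, :])
        iu = np.triu_indices(n, k=1)
        return score(s1[iu], s2[iu])
    rng = np.random.default_rng(seed)
    i = rng.integers(0, n, size=n_samples)
    j = rng.integers(0, n - 1, size=n_samples)
    j = np.where(j >= i, j + 1, j)  # uniform over off-diagonal pairs
    return score(np.sign(v1[i] - v1[j]), np.sign(v2[i] - v2[j]))


def niche_overlap_stats(
    g1: SuitabilityGrid,
    g2: SuitabilityGrid,
    max_exact: int = 2000,
    n_samples: int = 200_000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """(D, I, RR) between two normalized grids of identical shape/mask."""
    if g1.values.shape != g2.values.shape or not np.array_equal(g1.mask, g2.mask):
        raise InputError("grids differ in shape or mask")
    p1, p2 = g1.valid_values(), g2.valid_values()
    for p in (p1, p2):
        if abs(p.sum() - 1.0) > 1e-8:
            raise InputError("grids must be normalized first (see normalize_suitability)")
    d = 1.0 - 0.5 * np.abs(p1 - p2).sum()
    i_stat = 1.0 - 0.5 * ((np.sqrt(p1) - np.sqrt(p2)) ** 2).sum()
    rr = _rank_concordance(p1, p2, max_exact, n_samples, seed)
    return float(d), float(i_stat), rr


def niche_breadth(grid: SuitabilityGrid) -> float:
    """Levins' standardized breadth of a normalized grid: 1 for a uniform
    distribution, 0 when all mass sits on a single cell."""
    p = grid.valid_values()
    if p.size < 2:
        raise InputError("breadth needs at least 2 valid cells")
    if abs(p.sum() - 1.0) > 1e-8:
        raise InputError("grid must be normalized first")
    return float((1.0 / np.sum(p**2) - 1.0) / (p.size - 1))
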