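"""Day-to-day site fidelity: pairwise UD overlap and aggregate scores.

Overlap between two daily UDs is the Bhattacharyya coefficient
sum_q sqrt(U1(q) * U2(q)), ranging 0 (disjoint) to 1 (identical). Aggregate
site fidelity averages pairwise overlaps: the canonical scheme averages
consecutive-day pairs; all-pairs and distance-weighted variants are kept
for robustness checks.

The S11-S16 battery restricts each daily UD to a region (whole barn, F, or
C_T), truncates at an isopleth level (full 0.95 or core 0.50) of the
restricted UD, renormalizes, and aggregates with the consecutive scheme.
That restrict-then-truncate order is fixed; swapping it changes results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .geometry import BarnGeometry
from .ud import GridMismatchError, UtilityDistribution, restrict_ud, truncate_ud

SCHEMES = ("consecutive", "all_pairs", "weighted_pairs")

#: (region, isopleth level) context for each fidelity measure
FIDELITY_CONTEXTS = {
    "S11": ("barn", 0.95),
    "S12": ("F", 0.95),
    "S13": ("C_T", 0.95),
    "S14": ("barn", 0.50),
    "S15": ("F", 0.50),
    "S16": ("C_T", 0.50),
}


def bhattacharyya(
    ud1: UtilityDistribution, ud2: UtilityDistribution, *, sqrt_form: bool = True
) -> float:
    """Overlap of two normalized UDs on the same grid, in [0, 1].

    ``sqrt_form=False`` computes the plain product sum instead (kept for
    comparison only; it does not reach 1 for identical non-degenerate UDs).
    NaN if either UD is flagged empty.
    """
    if ud1.grid != ud2.grid:
        raise GridMismatchError("UDs live on different grids")
    if ud1.empty or ud2.empty:
        return math.nan
    if sqrt_form:
        val = float(np.sqrt(ud1.flat * ud2.flat).sum())
    else:
        val = float((ud1.flat * ud2.flat).sum())
    return min(max(val, 0.0), 1.0)


@dataclass
class AggregateFidelity:
    score: float
    n_pairs: int
    scheme: str

    @property
    def missing(self) -> bool:
        return self.n_pairs == 0


def aggregate_fidelity(
    daily_uds: list[UtilityDistribution],
    scheme: str = "consecutive",
    *,
    sqrt_form: bool = True,
) -> AggregateFidelity:
    """Average pairwise overlap across study days.

    consecutive: mean over the n-1 adjacent-day pairs. all_pairs: mean over
    all C(n, 2) unordered pairs. weighted_pairs: all pairs weighted by
    1/|i-j| (normalized). Flagged-empty days drop the pairs they belong to;
    fewer than one usable pair yields a flagged-missing result.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    n = len(daily_uds)
    usable = [i for i in range(n) if not daily_uds[i].empty]
    if scheme == "consecutive":
        pairs = [(i, i + 1) for i in range(n - 1)]
    else:
        pairs = list(combinations(range(n), 2))
    pairs = [(i, j) for i, j in pairs if i in usable and j in usable]
    if not pairs:
        return AggregateFidelity(math.nan, 0, scheme)
    vals = np.array(
        [
            bhattacharyya(daily_uds[i], daily_uds[j], sqrt_form=sqrt_form)
            for i, j in pairs
        ]
    )
    if scheme == "weighted_pairs":
        w = np.array([1.0 / abs(i - j) for i, j in pairs])
        score = float((vals * w).sum() / w.sum())
    else:
        score = float(vals.mean())
    return AggregateFidelity(score, len(pairs), scheme)


def pairwise_matrix(
    daily_uds: list[UtilityDistribution], *, sqrt_form: bool = True
) -> np.ndarray:
    """Symmetric matrix of pairwise overlaps (NaN rows for empty days)."""
    n = len(daily_uds)
    m = np.full((n, n), math.nan)
    for i in range(n):
        if not daily_uds[i].empty:
            m[i, i] = 1.0
        for j in range(i + 1, n):
            v = bhattacharyya(daily_uds[i], daily_uds[j], sqrt_form=sqrt_form)
            m[i, j] = m[j, i] = v
    return m


def fidelity_battery(
    daily_uds: list[UtilityDistribution],
    geometry: BarnGeometry,
    *,
    scheme: str = "consecutive",
    sqrt_form: bool = True,
) -> dict[str, float]:
    """Compute S11-S16 for one cow.

    For each (region, level) context: restrict each daily UD to the region,
    truncate at the isopleth level of the restricted UD, renormalize, then
    aggregate. Zero-mass restricted days are flagged empty and drop out of
    the pair averaging; if no pairs remain the score is NaN.
    """
    out: dict[str, float] = {}
    for name, (region_name, level) in FIDELITY_CONTEXTS.items():
        region = geometry.region(region_name)
        prepped = []
        for ud in daily_uds:
            r = restrict_ud(ud, region)
            prepped.append(r if r.empty else truncate_ud(r, level))
        out[name] = aggregate_fidelity(prepped, scheme, sqrt_form=sqrt_form).score
    return out
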