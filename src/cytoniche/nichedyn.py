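"""Niche-change indices and resampling-based niche optima and breadths.

Expansion / stability / unfilling decompose how the niche of a higher ploidy
level relates to that of a lower one inside a shared analysis region:

    E   = share of the higher niche's mass lying where the lower niche is absent
    S_e = 1 - E   (shared share of the higher niche)
    U   = share of the lower niche's mass lying where the higher niche is absent
    S_n = 1 - U   (shared share of the lower niche)

The analysis region trims rare, marginal environments: for each group, cells
are kept where that group's background density reaches the threshold holding
p% (75 or 95) of its total density mass, and the region is the intersection.
"Quantile of environmental density" is interpreted as this mass threshold;
a value-based percentile switch is exposed for comparison.

Niche optimum and breadth are the mean and variance of axis scores of cells
resampled from the occupied grid (z > 0): ``n_cells`` cells per draw,
``reps`` draws, summarized by their central 95% intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .envspace import NicheGrid


@dataclass(frozen=True)
class DynamicsEntry:
    p: float
    expansion: float  # E
    stability_e: float  # S_e = 1 - E
    unfilling: float  # U
    stability_n: float  # S_n = 1 - U


@dataclass
class NicheDynamics:
    pair: tuple  # (lower ploidy label, higher ploidy label)
    entries: dict = field(default_factory=dict)  # p -> DynamicsEntry

    def as_dict(self) -> dict:
        return {
            str(int(p)): {
                "E": e.expansion,
                "S_e": e.stability_e,
                "U": e.unfilling,
                "S_n": e.stability_n,
            }
            for p, e in sorted(self.entries.items())
        }


def _mass_threshold_region(density: np.ndarray, p: float) -> np.ndarray:
    """Cells holding the top p% of a density's mass (densest cells first)."""
    flat = np.sort(density.ravel())[::-1]
    csum = np.cumsum(flat)
    target = p / 100.0 * csum[-1]
    k = int(np.searchsorted(csum, target))
    t = flat[min(k, len(flat) - 1)]
    return density >= t


def _value_threshold_region(density: np.ndarray, p: float) -> np.ndarray:
    """Value-based alternative: cells above the (100-p)th percentile of positive densities."""
    pos = density[density > 0]
    t = np.percentile(pos, 100.0 - p)
    return density >= t


def dynamics_indices(
    g_low: NicheGrid,
    g_high: NicheGrid,
    p: float,
    quantile_mode: str = "mass",
) -> DynamicsEntry:
    """E / S_e / U / S_n for one quantile setting on a shared frame.

    Presence is z > 0 after flooring; the indices weight cells by occupancy
    mass, so E is the z-mass of the higher niche falling on cells where the
    lower niche is absent (and symmetrically for U).  Identical grids give
    exactly (E, U) = (0, 0).
    """
    if not g_low.same_frame(g_high):
        raise ValueError("grids were not built on the same frame")
    region_fn = {"mass": _mass_threshold_region, "value": _value_threshold_region}[quantile_mode]
    region = region_fn(g_low.env_density, p) & region_fn(g_high.env_density, p)
    if not region.any():
        raise ValueError(
            f"empty analysis region at p={p}: the two backgrounds do not share "
            "dense environmental space"
        )
    zl = np.where(region, g_low.z, 0.0)
    zh = np.where(region, g_high.z, 0.0)
    if zh.sum() <= 0 or zl.sum() <= 0:
        raise ValueError(f"a niche has no occupancy mass inside the p={p} region")
    e = float(zh[zl == 0].sum() / zh.sum())
    u = float(zl[zh == 0].sum() / zl.sum())
    return DynamicsEntry(p=p, expansion=e, stability_e=1.0 - e, unfilling=u, stability_n=1.0 - u)


def niche_dynamics(
    g_low: NicheGrid,
    g_high: NicheGrid,
    quantiles=(75, 95),
    quantile_mode: str = "mass",
    pair=None,
) -> NicheDynamics:
    dyn = NicheDynamics(pair=pair or (g_low.cytotype, g_high.cytotype))
    for p in quantiles:
        dyn.entries[float(p)] = dynamics_indices(g_low, g_high, float(p), quantile_mode)
    return dyn


# ---------------------------------------------------------------------------
# niche optimum and breadth


@dataclass
class NicheSummary:
    """Resampling distributions of niche optimum (mean) and breadth (variance)."""

    cytotype: str
    optimum_samples: np.ndarray  # (reps, 2)
    breadth_samples: np.ndarray  # (reps, 2)
    reps: int
    n_cells: int
    seed: int

    def optimum_interval(self, axis: int, level: float = 0.95) -> tuple:
        tail = (1.0 - level) / 2.0
        lo, hi = np.quantile(self.optimum_samples[:, axis], [tail, 1.0 - tail])
        return float(lo), float(hi)

    def breadth_interval(self, axis: int, level: float = 0.95) -> tuple:
        tail = (1.0 - level) / 2.0
        lo, hi = np.quantile(self.breadth_samples[:, axis], [tail, 1.0 - tail])
        return float(lo), float(hi)

    def as_dict(self) -> dict:
        return {
            "cytotype": self.cytotype,
            "reps": self.reps,
            "n_cells": self.n_cells,
            "optimum_mean": [float(m) for m in self.optimum_samples.mean(axis=0)],
            "optimum_ci95": [list(self.optimum_interval(a)) for a in (0, 1)],
            "breadth_mean": [float(m) for m in self.breadth_samples.mean(axis=0)],
            "breadth_ci95": [list(self.breadth_interval(a)) for a in (0, 1)],
        }


def optimum_breadth(
    g: NicheGrid,
    n_cells: int = 100,
    reps: int = 1000,
    seed: int = 0,
    weighted: bool = True,
) -> NicheSummary:
    """Resample occupied cells and summarize their axis scores.

    Per rep, ``n_cells`` cells are drawn with replacement from cells with
    z > 0 — proportionally to z by default, mirroring procedures that
    resample occurrence records, or uniformly over occupied cells with
    ``weighted=False`` (which estimates the centroid of the smoothed niche
    support instead and is sensitive to outlying occurrences) — and the mean
    (optimum) and variance (breadth) of their scores along each axis
    recorded.
    """
    if reps < 1 or n_cells < 1:
        raise ValueError("reps and n_cells must be >= 1")
    occupied = np.flatnonzero(g.z.ravel() > 0)
    if len(occupied) == 0:
        raise ValueError("no occupied cells (z > 0)")
    scores = g.cell_scores()[occupied]
    rng = np.random.default_rng(seed)
    if weighted:
        w = g.z.ravel()[occupied]
        idx = rng.choice(len(occupied), size=(reps, n_cells), p=w / w.sum())
    else:
        idx = rng.integers(0, len(occupied), size=(reps, n_cells))
    draws = scores[idx]  # (reps, n_cells, 2)
    opt = draws.mean(axis=1)
    ddof = 1 if n_cells > 1 else 0
    breadth = draws.var(axis=1, ddof=ddof)
    return NicheSummary(
        cytotype=g.cytotype,
        optimum_samples=opt,
        breadth_samples=breadth,
        reps=reps,
        n_cells=n_cells,
        seed=seed,
    )


def compare_summaries(
    a: NicheSummary, b: NicheSummary, axis: int, what: str = "optimum"
) -> str:
    """'different' iff the two 95% central intervals are disjoint."""
    if a.reps != b.reps:
        raise ValueError("summaries built with different rep counts")
    get = NicheSummary.optimum_interval if what == "optimum" else NicheSummary.breadth_interval
    lo_a, hi_a = get(a, axis)
    lo_b, hi_b = get(b, axis)
    return "different" if (hi_a < lo_b or hi_b < lo_a) else "not_different"
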