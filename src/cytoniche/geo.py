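"""Great-circle geometry, spatial thinning and buffered background sampling.

Occurrence records from unevenly surveyed ranges are spatially stratified
before niche analysis: within each region stratum no two retained points may
lie closer than the stratum's threshold distance (40 km in densely surveyed
regions, 15 km elsewhere, in the reference survey design).  Thinning keeps as
many points as possible.  Environmental availability ("background") is then
sampled from candidate sites within a geographic buffer (default 20 km) of the
retained occurrences, at a fixed multiple (default 100x) of their number.

All distances are spherical great-circle (haversine, Earth radius 6371 km);
no projected CRS is supported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

#: Strata with at most this many mutually conflicting points are thinned by an
#: exact maximum-independent-set search; larger ones by randomized greedy
#: deletion with restarts.
EXACT_THINNING_MAX = 18


@dataclass(frozen=True)
class GeoPoint:
    lon: float
    lat: float

    def __post_init__(self) -> None:
        if not -90 <= self.lat <= 90:
            raise ValueError(f"latitude out of range: {self.lat}")
        if not -180 <= self.lon <= 180:
            raise ValueError(f"longitude out of range: {self.lon}")


@dataclass
class ThinningPolicy:
    """Region label -> minimum inter-point distance (km)."""

    thresholds_km: dict

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.thresholds_km.values()):
            raise ValueError("thinning thresholds must be positive")

    def threshold(self, region: str) -> float:
        try:
            return float(self.thresholds_km[region])
        except KeyError:
            raise KeyError(f"no thinning threshold for region {region!r}") from None


def haversine_km(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance between two points, km."""
    return float(
        pairwise_distance_km(
            np.array([a.lon]), np.array([a.lat]), np.array([b.lon]), np.array([b.lat])
        )[0, 0]
    )


def pairwise_distance_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Haversine distance matrix (len(lon1) x len(lon2)), km."""
    lon1, lat1 = np.radians(lon1)[:, None], np.radians(lat1)[:, None]
    lon2, lat2 = np.radians(lon2)[None, :], np.radians(lat2)[None, :]
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


# ---------------------------------------------------------------------------
# thinning


def _components(adj: list) -> list:
    n = len(adj)
    seen = [False] * n
    comps = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for w in adj[v]:
                if not seen[w]:
                    seen[w] = True
                    stack.append(w)
        comps.append(sorted(comp))
    return comps


def _exact_mis(vertices: list, neighbor_mask: dict) -> list:
    """Maximum independent set by branch and bound; deterministic."""
    best: list = []

    order = sorted(vertices)
    index = {v: i for i, v in enumerate(order)}
    nmask = [0] * len(order)
    for v in order:
        m = 0
        for w in neighbor_mask[v]:
            if w in index:
                m |= 1 << index[w]
        nmask[index[v]] = m

    full = (1 << len(order)) - 1

    def search(remaining: int, chosen: list) -> None:
        nonlocal best
        if remaining == 0:
            if len(chosen) > len(best):
                best = list(chosen)
            return
        if len(chosen) + bin(remaining).count("1") <= len(best):
            return  # bound: cannot beat incumbent
        # branch on the remaining vertex of highest degree
        degs = [(bin(remaining & nmask[i]).count("1"), i) for i in range(len(order)) if remaining >> i & 1]
        _, v = max(degs)
        # include v
        search(remaining & ~(1 << v) & ~nmask[v], chosen + [v])
        # exclude v
        search(remaining & ~(1 << v), chosen)

    search(full, [])
    return sorted(order[i] for i in best)


def _greedy_mis(vertices: list, neighbors: dict, rng: np.random.Generator, restarts: int) -> list:
    """Iteratively delete the point with most sub-threshold neighbours,
    random tie-break; best of ``restarts`` runs."""
    best: list = []
    for _ in range(max(1, restarts)):
        active = set(vertices)
        deg = {v: sum(w in active for w in neighbors[v]) for v in active}
        while True:
            conflicted = [v for v in active if deg[v] > 0]
            if not conflicted:
                break
            dmax = max(deg[v] for v in conflicted)
            ties = sorted(v for v in conflicted if deg[v] == dmax)
            drop = ties[int(rng.integers(len(ties)))]
            active.discard(drop)
            for w in neighbors[drop]:
                if w in active:
                    deg[w] -= 1
        if len(active) > len(best):
            best = sorted(active)
    return best


def thin(
    points: pd.DataFrame,
    policy: ThinningPolicy,
    seed: int = 0,
    restarts: int = 10,
) -> pd.DataFrame:
    """Spatially thin points (columns lon, lat, region) per region stratum.

    Returns the retained rows (original index preserved).  Within each
    stratum the retained set is a valid independent set of the sub-threshold
    conflict graph; small strata are solved exactly, large ones by seeded
    randomized greedy deletion keeping the run that retains most points.
    """
    for region in points["region"].unique():
        policy.threshold(str(region))  # raises if missing
    rng = np.random.default_rng(seed)
    keep_index = []
    for region in sorted(points["region"].astype(str).unique()):
        sub = points.loc[points["region"].astype(str) == region]
        idx = list(sub.index)
        n = len(idx)
        if n == 1:
            keep_index.extend(idx)
            continue
        d = pairwise_distance_km(
            sub["lon"].to_numpy(), sub["lat"].to_numpy(), sub["lon"].to_numpy(), sub["lat"].to_numpy()
        )
        thr = policy.threshold(region)
        conflict = (d < thr) & ~np.eye(n, dtype=bool)
        adj = [list(np.flatnonzero(conflict[i])) for i in range(n)]
        neighbors = {i: set(adj[i]) for i in range(n)}
        for comp in _components(adj):
            if len(comp) <= EXACT_THINNING_MAX:
                kept = _exact_mis(comp, neighbors)
            else:
                kept = _greedy_mis(comp, neighbors, rng, restarts)
            keep_index.extend(idx[i] for i in kept)
    return points.loc[points.index.isin(keep_index)]


def sample_background(
    occ: pd.DataFrame,
    candidate_sites: pd.DataFrame,
    buffer_km: float = 20.0,
    factor: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample availability sites within ``buffer_km`` of any occurrence.

    Draws ``factor * len(occ)`` candidate rows uniformly with replacement
    from candidates lying within the buffer of at least one occurrence (the
    target count generally exceeds the number of distinct ~1-km cells in a
    20-km buffer, so sampling is with replacement by design).
    """
    if len(occ) == 0:
        raise ValueError("no occurrences to buffer around")
    d = pairwise_distance_km(
        candidate_sites["lon"].to_numpy(),
        candidate_sites["lat"].to_numpy(),
        occ["lon"].to_numpy(),
        occ["lat"].to_numpy(),
    )
    within = (d <= buffer_km).any(axis=1)
    eligible = candidate_sites.loc[within]
    if len(eligible) == 0:
        raise ValueError(f"no candidate site within {buffer_km} km of any occurrence")
    rng = np.random.default_rng(seed)
    pick = rng.integers(0, len(eligible), size=factor * len(occ))
    out = eligible.iloc[pick].reset_index(drop=True)
    return out


def buffer_audit_km(background: pd.DataFrame, occ: pd.DataFrame) -> float:
    """Max distance from any background site to its nearest occurrence (km)."""
    d = pairwise_distance_km(
        background["lon"].to_numpy(),
        background["lat"].to_numpy(),
        occ["lon"].to_numpy(),
        occ["lat"].to_numpy(),
    )
    return float(d.min(axis=1).max())


def is_valid_thinning(points: pd.DataFrame, policy: ThinningPolicy) -> bool:
    """Pairwise distance scan: no two points in a stratum under its threshold."""
    for region in points["region"].astype(str).unique():
        sub = points.loc[points["region"].astype(str) == region]
        if len(sub) < 2:
            continue
        d = pairwise_distance_km(
            sub["lon"].to_numpy(), sub["lat"].to_numpy(), sub["lon"].to_numpy(), sub["lat"].to_numpy()
        )
        np.fill_diagonal(d, np.inf)
        if (d < policy.threshold(region)).any():
            return False
    return True


__all__ = [
    "GeoPoint",
    "ThinningPolicy",
    "haversine_km",
    "pairwise_distance_km",
    "thin",
    "sample_background",
    "buffer_audit_km",
    "is_valid_thinning",
    "EARTH_RADIUS_KM",
]
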