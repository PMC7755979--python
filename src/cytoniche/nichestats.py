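"""Niche overlap (Schoener's D) and permutation-based equivalency/similarity tests.

D = 1 - 0.5 * sum(|z1 - z2|) over the shared grid, with both occupancy
surfaces normalized to unit mass: 0 for disjoint niches, 1 for identical ones.

The equivalency (identity) test pools the occurrences of two groups, re-splits
them at random into sets of the original sizes, and recomputes D; the observed
D is judged against the lower/upper 2.5% quantiles of the null ("less
equivalent" / "more equivalent", otherwise no verdict).  The similarity test
asks whether the observed overlap differs from the overlap between one
group's observed niche and niches resampled from the *other* group's
background; it is applied in both directions.  Verdicts are reported with the
empirical quantile position of the observed D rather than a p-value.

The grid frame (PCA, axes, bandwidths, availability surfaces) is held fixed
across permutations; only occurrence densities are re-smoothed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .envspace import NicheGrid, NicheSpace


@dataclass
class OverlapResult:
    D: float
    null_Ds: np.ndarray
    verdict: str
    direction: str | None
    reps: int
    seed: int
    quantile_position: float  # fraction of null draws below the observed D

    def summary(self) -> dict:
        return {
            "D": float(self.D),
            "verdict": self.verdict,
            "direction": self.direction,
            "reps": int(self.reps),
            "seed": int(self.seed),
            "quantile_position": float(self.quantile_position),
            "null_mean": float(np.mean(self.null_Ds)),
            "null_q025": float(np.quantile(self.null_Ds, 0.025)),
            "null_q975": float(np.quantile(self.null_Ds, 0.975)),
        }


def schoener_d(g1: NicheGrid, g2: NicheGrid) -> float:
    """Schoener's D between two occupancy grids sharing one frame."""
    if not g1.same_frame(g2):
        raise ValueError("grids were not built on the same frame")
    return float(1.0 - 0.5 * np.abs(g1.z - g2.z).sum())


def _verdict(observed: float, null: np.ndarray, alpha_tail: float, kind: str) -> tuple:
    lo = float(np.quantile(null, alpha_tail))
    hi = float(np.quantile(null, 1.0 - alpha_tail))
    below = float(np.mean(null < observed) + 0.5 * np.mean(null == observed))
    if observed >= hi and observed > lo:
        return ("more_equivalent" if kind == "equivalency" else "more_similar", below)
    if observed <= lo and observed < hi:
        return ("less_equivalent" if kind == "equivalency" else "more_dissimilar", below)
    return ("ns", below)


def equivalency_test(
    space: NicheSpace,
    occ_scores1: np.ndarray,
    occ_scores2: np.ndarray,
    groups: tuple,
    reps: int = 1000,
    alpha_tail: float = 0.025,
    seed: int = 0,
    corrected: bool = True,
) -> OverlapResult:
    """Niche equivalency (identity) test for two groups in one frame.

    Occurrences are pooled and randomly re-split into two sets of the original
    sizes ``reps`` times; each split is re-gridded against the respective
    group's availability and D recomputed.  The null distribution is invariant
    to swapping the group labels (same pooled set, same frame).
    """
    if reps < 20:
        raise ValueError("reps < 20: null quantiles would be meaningless")
    g1, g2 = groups
    if len(occ_scores1) < 5 or len(occ_scores2) < 5:
        raise ValueError("both groups need at least 5 occurrences")
    obs = schoener_d(
        space.occupancy(occ_scores1, g1, corrected=corrected),
        space.occupancy(occ_scores2, g2, corrected=corrected),
    )
    pooled = np.vstack([occ_scores1, occ_scores2])
    n1 = len(occ_scores1)
    rng = np.random.default_rng(seed)
    null = np.empty(reps)
    for i in range(reps):
        perm = rng.permutation(len(pooled))
        a = space.occupancy(pooled[perm[:n1]], g1, corrected=corrected)
        b = space.occupancy(pooled[perm[n1:]], g2, corrected=corrected)
        null[i] = schoener_d(a, b)
    verdict, pos = _verdict(obs, null, alpha_tail, "equivalency")
    return OverlapResult(obs, null, verdict, None, reps, seed, pos)


def similarity_test(
    space: NicheSpace,
    focal_scores: np.ndarray,
    other_scores: np.ndarray,
    groups: tuple,
    reps: int = 1000,
    alpha_tail: float = 0.025,
    seed: int = 0,
    corrected: bool = True,
    n_draw: int | None = None,
) -> OverlapResult:
    """One direction of the niche similarity test.

    ``groups = (focal, other)``.  Per rep, ``n_draw`` sites (default: the
    other group's occurrence count) are drawn from the other group's
    background, re-gridded as that group's niche, and compared to the focal
    observed niche.  High observed D relative to the null means the niches
    are more similar than chance; low, more dissimilar.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    focal, other = groups
    n_draw = n_draw if n_draw is not None else len(other_scores)
    bg = space.bg_scores[other]
    rng = np.random.default_rng(seed)
    g_focal = space.occupancy(focal_scores, focal, corrected=corrected)
    g_other = space.occupancy(other_scores, other, corrected=corrected)
    obs = schoener_d(g_focal, g_other)
    replace = n_draw > len(bg)
    null = np.empty(reps)
    for i in range(reps):
        pick = rng.choice(len(bg), size=n_draw, replace=replace)
        g_rand = space.occupancy(bg[pick], other, corrected=corrected)
        null[i] = schoener_d(g_focal, g_rand)
    verdict, pos = _verdict(obs, null, alpha_tail, "similarity")
    return OverlapResult(obs, null, verdict, f"resample:{other}", reps, seed, pos)


def similarity_both_directions(
    space: NicheSpace,
    scores1: np.ndarray,
    scores2: np.ndarray,
    groups: tuple,
    reps: int = 1000,
    alpha_tail: float = 0.025,
    seed: int = 0,
    corrected: bool = True,
) -> dict:
    """Similarity test resampling each group's background in turn."""
    g1, g2 = groups
    return {
        f"{g1}->{g2}": similarity_test(
            space, scores1, scores2, (g1, g2), reps, alpha_tail, seed, corrected
        ),
        f"{g2}->{g1}": similarity_test(
            space, scores2, scores1, (g2, g1), reps, alpha_tail, seed + 1, corrected
        ),
    }
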