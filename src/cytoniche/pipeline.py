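"""End-to-end orchestration: simulate or load, thin, background, PCA-env,
grids, overlap tests, dynamics and optima — one reproducible run.

For every ordered cytotype pair (lower ploidy first, so the expansion /
unfilling direction reads "higher vs lower"), the run thins each cytotype's
occurrence points per region, samples its buffered background, calibrates a
pairwise PCA-env frame on the pooled backgrounds, builds availability-
corrected occupancy grids, and computes Schoener's D, the equivalency and
(both-direction) similarity tests, the niche-change indices at each quantile
setting, and resampled niche optima/breadths.  Each pair gets a JSON report;
a summary table collects the Table-of-pairs layout across pairs.  All
randomness flows from one global seed through named child streams, and every
report embeds the config hash, the seed and the package version, so two runs
with equal hashes are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from ._seeds import child_seed
from .composition import composition_report, frame_from_records
from .cytometry import ploidy_level
from .envspace import build_space, filter_correlated
from .geo import ThinningPolicy, sample_background, thin
from .nichedyn import compare_summaries, niche_dynamics, optimum_breadth
from .nichestats import equivalency_test, schoener_d, similarity_both_directions
from .synthetic import (
    LatentEnvModel,
    MixtureSpec,
    NicheSpec,
    generate_env_sites,
    sample_occurrences,
    sample_population_table,
)

log = logging.getLogger("cytoniche")


@dataclass
class RunConfig:
    """Validated configuration of a full pairwise run."""

    seed: int = 1
    n_sites: int = 4000
    lattice_extent_km: float = 500.0
    niches: list = field(
        default_factory=lambda: [
            NicheSpec("4x", (-0.4, 0.2), (1.0, 1.0), 0.03),
            NicheSpec("5x", (0.3, -0.1), (0.8, 0.8), 0.03),
            NicheSpec("6x", (0.6, -0.5), (0.6, 0.6), 0.03),
        ]
    )
    mixture: MixtureSpec = field(default_factory=MixtureSpec)
    thinning_km: dict = field(default_factory=lambda: {"core": 40.0, "margin": 15.0})
    buffer_km: float = 20.0
    background_factor: int = 100
    r_max: float = 0.70
    grid_resolution: int = 200
    corrected: bool = True
    reps_equivalency: int = 1000
    reps_similarity: int = 1000
    reps_optimum: int = 1000
    n_resample_cells: int = 100
    quantiles: tuple = (75, 95)
    min_occurrences: int = 5

    def __post_init__(self) -> None:
        if self.reps_equivalency < 20 or self.reps_similarity < 20:
            raise ValueError("permutation reps must be >= 20")
        if self.grid_resolution < 10:
            raise ValueError("grid resolution must be >= 10")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "niches" in raw:
            raw["niches"] = [
                NicheSpec(
                    d["cytotype"],
                    tuple(d["optimum"]),
                    tuple(d["breadth"]),
                    float(d["prevalence"]),
                )
                for d in raw["niches"]
            ]
        if "mixture" in raw:
            raw["mixture"] = MixtureSpec(**raw["mixture"])
        if "quantiles" in raw:
            raw["quantiles"] = tuple(raw["quantiles"])
        return cls(**raw)

    def as_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_sites": self.n_sites,
            "lattice_extent_km": self.lattice_extent_km,
            "niches": [s.as_dict() for s in self.niches],
            "mixture": {
                "base_mixing_rate": self.mixture.base_mixing_rate,
                "support_threshold": self.mixture.support_threshold,
            },
            "thinning_km": dict(self.thinning_km),
            "buffer_km": self.buffer_km,
            "background_factor": self.background_factor,
            "r_max": self.r_max,
            "grid_resolution": self.grid_resolution,
            "corrected": self.corrected,
            "reps": {
                "equivalency": self.reps_equivalency,
                "similarity": self.reps_similarity,
                "optimum": self.reps_optimum,
            },
            "n_resample_cells": self.n_resample_cells,
            "quantiles": list(self.quantiles),
        }

    def hash(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _provenance(cfg: RunConfig) -> dict:
    return {"config_hash": cfg.hash(), "seed": cfg.seed, "version": __version__}


def run_pairwise_analysis(cfg: RunConfig, out_dir) -> dict:
    """Execute the full pipeline; returns the summary bundle it also writes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    env_model = LatentEnvModel(n_sites=cfg.n_sites, lattice_extent_km=cfg.lattice_extent_km)
    env = generate_env_sites(env_model, seed=child_seed(cfg.seed, "env"))
    occ = sample_occurrences(env, cfg.niches, seed=child_seed(cfg.seed, "occ"))
    pops = sample_population_table(occ, cfg.mixture, seed=child_seed(cfg.seed, "pops"))
    pop_frame = frame_from_records(pops)

    comp = composition_report(pops)
    comp["provenance"] = _provenance(cfg)
    (out / "composition.json").write_text(json.dumps(comp, indent=2, sort_keys=True))

    policy = ThinningPolicy(cfg.thinning_km)
    cytotypes = sorted(pop_frame["ploidy"].unique(), key=ploidy_level)

    occ_sites, backgrounds = {}, {}
    site_env = env.frame.set_index("site_id")
    usable = []
    for cyt in cytotypes:
        pts = pop_frame.loc[pop_frame["ploidy"] == cyt, ["site_id", "lon", "lat", "region"]]
        pts = pts.drop_duplicates("site_id").reset_index(drop=True)
        thinned = thin(pts, policy, seed=child_seed(cfg.seed, f"thin:{cyt}"))
        rows = site_env.loc[thinned["site_id"].to_numpy()].reset_index()
        if len(rows) < cfg.min_occurrences:
            log.warning("cytotype %s has %d thinned occurrences; skipped", cyt, len(rows))
            continue
        occ_sites[cyt] = rows
        backgrounds[cyt] = sample_background(
            rows,
            env.frame,
            buffer_km=cfg.buffer_km,
            factor=cfg.background_factor,
            seed=child_seed(cfg.seed, f"bg:{cyt}"),
        )
        usable.append(cyt)

    pooled_occ = pd.concat(occ_sites.values(), ignore_index=True) if usable else None
    retained_vars = (
        filter_correlated(pooled_occ, env.var_names, r_max=cfg.r_max) if usable else []
    )

    pairs = [
        (a, b)
        for i, a in enumerate(usable)
        for b in usable[i + 1 :]
        if ploidy_level(a) < ploidy_level(b)
    ]
    if not pairs:
        log.warning("fewer than two usable cytotypes; no pairwise comparisons")

    summary_rows, reports = [], {}
    for low, high in pairs:
        pair_name = f"{low}-{high}"
        try:
            report = _analyse_pair(cfg, low, high, occ_sites, backgrounds, retained_vars)
        except Exception as exc:  # keep other pairs running
            log.error("pair %s failed: %s", pair_name, exc)
            report = {"pair": [low, high], "error": str(exc)}
        report["provenance"] = _provenance(cfg)
        reports[pair_name] = report
        pair_dir = out / pair_name
        pair_dir.mkdir(exist_ok=True)
        (pair_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        if "error" not in report:
            summary_rows.append(_summary_row(report))

    summary = pd.DataFrame(summary_rows)
    summary.to_csv(out / "summary.csv", index=False)
    bundle = {
        "provenance": _provenance(cfg),
        "retained_variables": retained_vars,
        "cytotypes": usable,
        "n_pairs": len(pairs),
        "pairs": reports,
        "composition": comp,
    }
    (out / "run.json").write_text(json.dumps(bundle, indent=2, sort_keys=True))
    return bundle


def _analyse_pair(cfg, low, high, occ_sites, backgrounds, retained_vars) -> dict:
    space = build_space(
        {low: backgrounds[low][retained_vars], high: backgrounds[high][retained_vars]},
        retained_vars,
        R=cfg.grid_resolution,
    )
    s_low = space.model.transform(occ_sites[low])
    s_high = space.model.transform(occ_sites[high])
    g_low = space.occupancy(s_low, low, corrected=cfg.corrected, cytotype=low)
    g_high = space.occupancy(s_high, high, corrected=cfg.corrected, cytotype=high)

    d_obs = schoener_d(g_low, g_high)
    equiv = equivalency_test(
        space,
        s_low,
        s_high,
        (low, high),
        reps=cfg.reps_equivalency,
        seed=child_seed(cfg.seed, f"equiv:{low}-{high}"),
        corrected=cfg.corrected,
    )
    simil = similarity_both_directions(
        space,
        s_low,
        s_high,
        (low, high),
        reps=cfg.reps_similarity,
        seed=child_seed(cfg.seed, f"simil:{low}-{high}"),
        corrected=cfg.corrected,
    )
    dyn = niche_dynamics(g_low, g_high, quantiles=cfg.quantiles, pair=(low, high))
    summaries = {
        cyt: optimum_breadth(
            grid,
            n_cells=cfg.n_resample_cells,
            reps=cfg.reps_optimum,
            seed=child_seed(cfg.seed, f"opt:{cyt}:{low}-{high}"),
        )
        for cyt, grid in ((low, g_low), (high, g_high))
    }
    comparisons = {
        f"axis{ax + 1}": {
            what: compare_summaries(summaries[low], summaries[high], ax, what)
            for what in ("optimum", "breadth")
        }
        for ax in (0, 1)
    }
    return {
        "pair": [low, high],
        "n_occurrences": {low: int(len(s_low)), high: int(len(s_high))},
        "variance_explained": [float(v) for v in space.model.explained],
        "D": d_obs,
        "equivalency": equiv.summary(),
        "similarity": {k: v.summary() for k, v in simil.items()},
        "dynamics": dyn.as_dict(),
        "summaries": {c: s.as_dict() for c, s in summaries.items()},
        "interval_comparisons": comparisons,
    }


def _summary_row(report: dict) -> dict:
    low, high = report["pair"]
    row = {
        "cytotype_low": low,
        "cytotype_high": high,
        "D": report["D"],
        "equivalency": report["equivalency"]["verdict"],
        "similarity_low_to_high": report["similarity"][f"{low}->{high}"]["verdict"],
        "similarity_high_to_low": report["similarity"][f"{high}->{low}"]["verdict"],
    }
    for p, entry in report["dynamics"].items():
        for key in ("E", "S_e", "U", "S_n"):
            row[f"{key}_p{p}"] = entry[key]
    return row
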