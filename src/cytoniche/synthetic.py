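"""Seeded generators for every input the niche pipeline consumes.

The generator emulates a continental occurrence survey of a mixed-ploidy
plant with known ground truth:

* **Environment** — sites on a regular lattice carry two latent gradients
  (a humidity/soil gradient and a seasonality/continentality gradient) that
  drive a panel of correlated climate/soil variables through a linear-Gaussian
  loading model: ``observed = loadings @ latents + noise``.  The latents are
  partly tied to lattice position so that environmental distance correlates
  with geographic distance, which is what makes geographic buffers meaningful
  backgrounds.
* **Occurrences** — each cytotype occupies a Gaussian niche envelope in
  latent-gradient space; sites are accepted with probability proportional to
  the envelope density (acceptance thinning, exact for envelope shapes).
* **Populations** — placed at occurrence sites; where two or more envelopes
  both exceed a support threshold (a contact zone) the population is mixed
  with a configurable probability.  Individuals per population follow a
  shifted negative binomial (mean ~13, SD ~14, minimum 2), matching the
  strongly right-skewed sample sizes of real surveys.
* **Flow cytometry** — per-individual relative fluorescence drawn from the
  per-ploidy calibration mean with configurable SD, plus CV values of which a
  configurable fraction fails the 5% acceptance gate.

No attempt is made to simulate real geography, glaciation history or
genome-size variation.  All generators are deterministic under their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .composition import PopulationRecord
from .cytometry import CalibrationIntervals, ploidy_level

KM_PER_DEG_LAT = 111.195  # 2*pi*6371/360

#: Default variable panel: loading of each observed variable on the two latent
#: gradients (humidity/soil, seasonality).  Within-block implied correlations
#: stay at or below ~0.65 so the default panel survives a |r| <= 0.70 filter.
DEFAULT_LOADINGS = {
    "gai": (0.80, 0.00),
    "bio18_prec_warmq": (0.70, 0.10),
    "ph_kcl": (-0.65, 0.05),
    "orcdrc_soil_carbon": (0.60, -0.05),
    "cecsol_cation_exch": (0.55, 0.00),
    "crfvol_coarse_frag": (0.60, 0.05),
    "clyppt_clay_pct": (-0.55, 0.00),
    "elevation": (0.50, -0.15),
    "bio4_temp_seasonality": (-0.05, -0.75),
    "bio15_prec_seasonality": (0.00, -0.60),
    "bio9_temp_driestq": (0.10, 0.70),
    "bio11_temp_coldestq": (0.05, 0.75),
    "solar_radiation": (-0.10, 0.45),
}


@dataclass
class EnvDataset:
    """Sites-by-variables table with optional latent gradients and group label."""

    frame: pd.DataFrame
    var_names: list
    group: str | None = None
    niches: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class LatentEnvModel:
    """Two latent gradients driving a correlated environmental variable panel."""

    n_sites: int = 2500
    gradient_loadings: dict = field(default_factory=lambda: dict(DEFAULT_LOADINGS))
    noise_sd: float = 0.55
    lattice_extent_km: float = 1500.0
    spatial_structure: float = 0.6  # share of latent SD tied to lattice position
    origin_lon: float = 5.0
    origin_lat: float = 44.0

    def __post_init__(self) -> None:
        if len(self.gradient_loadings) < 2:
            raise ValueError("need at least 2 observed variables")
        if np.any(np.asarray(self.noise_sd) < 0):
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.spatial_structure <= 1:
            raise ValueError("spatial_structure must be in [0, 1]")
        self._check_psd()

    @property
    def var_names(self) -> list:
        return list(self.gradient_loadings)

    def loadings_matrix(self) -> np.ndarray:
        return np.array([self.gradient_loadings[v] for v in self.var_names], dtype=float)

    def noise_vector(self) -> np.ndarray:
        sd = np.asarray(self.noise_sd, dtype=float)
        if sd.ndim == 0:
            return np.full(len(self.gradient_loadings), float(sd))
        if len(sd) != len(self.gradient_loadings):
            raise ValueError("noise_sd length does not match the variable panel")
        return sd

    def implied_covariance(self) -> np.ndarray:
        ll = self.loadings_matrix()
        return ll @ ll.T + np.diag(self.noise_vector() ** 2)

    def implied_correlation(self) -> np.ndarray:
        cov = self.implied_covariance()
        d = np.sqrt(np.diag(cov))
        return cov / np.outer(d, d)

    def _check_psd(self) -> None:
        eig = np.linalg.eigvalsh(self.implied_correlation())
        if eig.min() < -1e-10:
            raise ValueError(
                f"implied correlation matrix is not positive semi-definite "
                f"(min eigenvalue {eig.min():.3g})"
            )


@dataclass
class NicheSpec:
    """Ground-truth Gaussian niche envelope of one cytotype in latent space."""

    cytotype: str
    optimum: tuple  # 2-vector in latent-gradient space
    breadth: tuple  # envelope SDs per gradient
    prevalence: float  # acceptance probability at the optimum

    def __post_init__(self) -> None:
        ploidy_level(self.cytotype)  # validates the label
        if not all(b > 0 for b in self.breadth):
            raise ValueError("breadth must be positive")
        if not 0 < self.prevalence <= 1:
            raise ValueError("prevalence must be in (0, 1]")

    def envelope(self, latents: np.ndarray) -> np.ndarray:
        """Envelope density relative to the optimum (1 at the optimum)."""
        z = (np.asarray(latents) - np.asarray(self.optimum)) / np.asarray(self.breadth)
        return np.exp(-0.5 * (z**2).sum(axis=-1))

    def as_dict(self) -> dict:
        return {
            "cytotype": self.cytotype,
            "optimum": list(self.optimum),
            "breadth": list(self.breadth),
            "prevalence": self.prevalence,
        }


@dataclass
class MixtureSpec:
    """Contact-zone mixing and per-population sampling-effort parameters.

    The mixing rate is a free parameter of the generator, not an estimate of
    any observed mixed-population frequency.  Individuals per population are
    2 + NegBin(r, q) with mean ~13 and SD ~14.
    """

    base_mixing_rate: float = 0.25
    support_threshold: float = 0.05  # envelope density defining a contact zone
    nb_r: float = 0.654
    nb_q: float = 0.0561
    min_individuals: int = 2

    def __post_init__(self) -> None:
        if not 0 <= self.base_mixing_rate <= 1:
            raise ValueError("base_mixing_rate must be in [0, 1]")
        if not 0 < self.support_threshold < 1:
            raise ValueError("support_threshold must be in (0, 1)")


# ---------------------------------------------------------------------------
# generators


def generate_env_sites(model: LatentEnvModel, seed: int = 0) -> EnvDataset:
    """Generate the site lattice with latent gradients and observed variables.

    Sites sit on a regular square lattice of the stated extent, mapped to
    lon/lat by an equirectangular projection (downstream geometry only needs
    great-circle distances).  Latent gradient 1 partly follows the west-east
    axis and gradient 2 the south-north axis.  Each gradient has a *uniform*
    marginal on [-sqrt(3), sqrt(3)] (unit variance), obtained by rank-
    transforming a position-plus-noise field: a flat availability of latent
    conditions means Gaussian-envelope acceptance sampling reproduces the
    envelope itself as the occurrence distribution, so NicheSpec optima and
    breadths are the exact moments of the occurrence process — the property
    recovery tests rely on.  Observed variables are ``loadings @ latents``
    plus iid Gaussian noise.  Deterministic under the seed.
    """
    rng = np.random.default_rng(seed)
    n = model.n_sites
    side = int(np.ceil(np.sqrt(n)))
    step = model.lattice_extent_km / side
    ix, iy = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    x_km = (ix.ravel()[:n] + 0.5) * step
    y_km = (iy.ravel()[:n] + 0.5) * step
    lat = model.origin_lat + y_km / KM_PER_DEG_LAT
    lon = model.origin_lon + x_km / (KM_PER_DEG_LAT * np.cos(np.radians(model.origin_lat)))

    w = model.spatial_structure
    resid = np.sqrt(1.0 - w**2)

    def standardized(v):
        return (v - v.mean()) / v.std() if v.std() > 0 else np.zeros_like(v)

    def rank_uniform(u):
        order = np.argsort(u, kind="stable")
        ranks = np.empty(n)
        ranks[order] = np.arange(n)
        return ((ranks + 0.5) / n - 0.5) * 2.0 * np.sqrt(3.0)

    g1 = rank_uniform(w * standardized(x_km) + resid * rng.standard_normal(n))
    g2 = rank_uniform(w * standardized(y_km) + resid * rng.standard_normal(n))
    latents = np.column_stack([g1, g2])
    ll = model.loadings_matrix()
    noise = model.noise_vector()
    obs = latents @ ll.T + rng.standard_normal((n, ll.shape[0])) * noise

    frame = pd.DataFrame(
        {"site_id": np.arange(n), "lon": lon, "lat": lat, "g1": g1, "g2": g2}
    )
    for j, name in enumerate(model.var_names):
        frame[name] = obs[:, j]
    # region stratification for thinning: a densely surveyed core block vs margin
    cx = (x_km > 0.25 * model.lattice_extent_km) & (x_km < 0.75 * model.lattice_extent_km)
    cy = (y_km > 0.25 * model.lattice_extent_km) & (y_km < 0.75 * model.lattice_extent_km)
    frame["region"] = np.where(cx & cy, "core", "margin")
    return EnvDataset(frame=frame, var_names=model.var_names)


def sample_occurrences(env: EnvDataset, niches, seed: int = 0) -> EnvDataset:
    """Thin sites into cytotype occurrences by Gaussian-envelope acceptance.

    A site becomes an occurrence of cytotype k with probability
    ``prevalence_k * envelope_k(latents)``; the same site may be accepted by
    several cytotypes.  Raises if any cytotype ends with fewer than 5
    occurrences (increase n_sites or prevalence).
    """
    if not {"g1", "g2"}.issubset(env.frame.columns):
        raise ValueError("env dataset lacks latent-gradient columns g1/g2")
    rng = np.random.default_rng(seed)
    latents = env.frame[["g1", "g2"]].to_numpy()
    parts = []
    for spec in niches:
        p = spec.prevalence * spec.envelope(latents)
        accept = rng.random(len(env.frame)) < p
        n_acc = int(accept.sum())
        if n_acc < 5:
            raise ValueError(
                f"cytotype {spec.cytotype} produced only {n_acc} occurrences; "
                "increase n_sites or prevalence"
            )
        sub = env.frame.loc[accept].copy()
        sub["cytotype"] = spec.cytotype
        parts.append(sub)
    out = pd.concat(parts, ignore_index=True)
    return EnvDataset(frame=out, var_names=env.var_names, niches=list(niches))


def sample_population_table(
    occ: EnvDataset, mix: MixtureSpec, seed: int = 0
) -> list:
    """Aggregate occurrences into populations with contact-zone mixing.

    One population per occupied site.  Where >= 2 envelopes exceed the
    support threshold the population becomes mixed with probability
    ``base_mixing_rate`` (three-cytotype mixtures with the squared rate when
    a third envelope is also in support).  Individual counts follow the
    shifted negative binomial; mixed populations also get a larger sampled
    area, mirroring the greater effort such populations attract.
    """
    if not occ.niches:
        raise ValueError("occurrence dataset carries no niche ground truth")
    rng = np.random.default_rng(seed)
    specs = {s.cytotype: s for s in occ.niches}
    pops = []
    for site_id, grp in occ.frame.groupby("site_id", sort=True):
        first = grp.iloc[0]
        latent = np.array([first["g1"], first["g2"]])
        present = sorted(grp["cytotype"].unique(), key=ploidy_level)
        support = sorted(
            (c for c, s in specs.items() if s.envelope(latent[None, :])[0] >= mix.support_threshold),
            key=ploidy_level,
        )
        primary = present[int(rng.integers(len(present)))]
        members = [primary]
        others = [c for c in support if c != primary]
        if others and rng.random() < mix.base_mixing_rate:
            members.append(others[int(rng.integers(len(others)))])
            third = [c for c in others if c not in members]
            if third and rng.random() < mix.base_mixing_rate**2:
                members.append(third[int(rng.integers(len(third)))])
        total = mix.min_individuals + int(rng.negative_binomial(mix.nb_r, mix.nb_q))
        counts = _split_individuals(total, sorted(members, key=ploidy_level), rng)
        area = float(np.exp(rng.normal(np.log(300.0 if len(members) > 1 else 80.0), 1.0)))
        pops.append(
            PopulationRecord(
                pop_id=f"pop{int(site_id):05d}",
                lon=float(first["lon"]),
                lat=float(first["lat"]),
                region=str(first["region"]),
                counts=counts,
                area_m2=round(area, 1),
                site_id=int(site_id),
            )
        )
    return pops


def _split_individuals(total: int, members, rng: np.random.Generator) -> dict:
    """Split a population's individuals across member cytotypes, every member >= 1."""
    counts = {c: 1 for c in members}
    remaining = total - len(members)
    if remaining < 0:
        # tiny population; keep one individual per member, trimming to total
        counts = {c: 1 for c in members[:total]}
        return counts
    if len(members) == 1:
        counts[members[0]] += remaining
        return counts
    shares = rng.dirichlet(np.linspace(3.0, 1.0, len(members)))
    extra = rng.multinomial(remaining, shares)
    for c, e in zip(members, extra):
        counts[c] += int(e)
    return counts


def sample_rf(
    populations,
    calib: CalibrationIntervals | None = None,
    sd_per_ploidy: dict | None = None,
    stain: str = "PI",
    cv_fail_fraction: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate relative-fluorescence measurements for every individual.

    RF ~ Normal(calibration mean of the ploidy, sd); default SDs come from
    the calibration table.  CVs are drawn so that ``cv_fail_fraction`` of
    histograms exceed the 5.0% acceptance gate.  Returns a measurement table
    with the true ploidy attached as ground truth.
    """
    calib = calib or CalibrationIntervals.default()
    rng = np.random.default_rng(seed)
    rows = []
    for pop in populations:
        for cyt in pop.cytotypes:
            if (stain, cyt) not in calib.rows:
                raise KeyError(f"no calibration row for ploidy {cyt!r} with stain {stain!r}")
            bounds = calib.rows[(stain, cyt)]
            mean = calib.mean_rf(stain, cyt)
            if sd_per_ploidy is not None:
                sd = float(sd_per_ploidy.get(cyt, 0.0))
            else:
                sd = float(bounds[3]) if len(bounds) > 3 else 0.0
            for k in range(pop.counts[cyt]):
                rf = float(rng.normal(mean, sd)) if sd > 0 else mean
                if rng.random() < cv_fail_fraction:
                    cv = float(rng.uniform(5.0, 8.0))
                else:
                    cv = float(rng.uniform(1.5, 4.5))
                rows.append(
                    {
                        "sample_id": f"{pop.pop_id}-{cyt}-{k:03d}",
                        "pop_id": pop.pop_id,
                        "stain": stain,
                        "rf": max(rf, 1e-6),
                        "cv_percent": cv,
                        "true_ploidy": cyt,
                    }
                )
    return pd.DataFrame(rows)


def map_latent_to_scores(model: LatentEnvModel, pca, latent_point) -> np.ndarray:
    """Project a latent-gradient point into a fitted PCA-env score space.

    The expected observed variables at the point are ``loadings @ latents``
    (noise has zero mean); standardization and projection then follow the
    fitted model.  Used to express ground-truth niche optima on the same
    axes as the estimated ones.
    """
    x = np.asarray(latent_point, dtype=float) @ model.loadings_matrix().T
    frame = pd.DataFrame([dict(zip(model.var_names, x))])
    return pca.transform(frame[pca.var_names])[0]


# ---------------------------------------------------------------------------
# writers


def write_simulation(out_dir, env: EnvDataset, occ: EnvDataset, pops, rf=None) -> None:
    """Write the generated tables as CSV plus a ground-truth JSON sidecar."""
    from pathlib import Path

    from .composition import frame_from_records

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    env.frame.to_csv(out / "env_sites.csv", index=False)
    occ.frame.to_csv(out / "occurrences.csv", index=False)
    frame_from_records(pops).to_csv(out / "populations.csv", index=False)
    if rf is not None:
        rf.to_csv(out / "rf_measurements.csv", index=False)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump({"niches": [s.as_dict() for s in occ.niches]}, fh, indent=2, sort_keys=True)
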