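"""Environmental space: variable filtering, PCA-env, kernel occupancy grids.

The niche of each cytotype is described in the plane of the first two
principal components of the standardized environmental variables, calibrated
on the pooled availability (background) sample of the groups being compared.
That plane is divided into an R x R grid (default 200 x 200); occurrence and
background densities are estimated at cell centers with a separable Gaussian
product kernel, and the occupancy surface

    z = occurrence density / background density   (where the environment
                                                   is actually available)

is normalized to unit mass.  The availability correction removes the imprint
of what environments exist in the study area, so z reflects selection rather
than supply; an uncorrected mode (z proportional to raw occurrence density)
is also provided.

Numerical guards: cells whose background density falls below 1e-6 of its
maximum are marked unavailable (z forced to 0) to avoid ratio blow-ups in
essentially absent environments, and occurrence density below 1e-6 of its own
maximum is treated as zero so the occupied region of a Gaussian-smoothed
niche has finite support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AVAILABILITY_FLOOR = 1e-6  # relative to the surface's own maximum
OCCUPANCY_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# variable filtering


def filter_correlated(frame: pd.DataFrame, var_names=None, r_max: float = 0.70) -> list:
    """Greedy collinearity filter: retain variables with all pairwise |r| <= r_max.

    While any pair exceeds the threshold, the variable with the largest mean
    absolute correlation to the other retained variables is dropped.
    Zero-variance variables are dropped up front with a warning.
    """
    cols = list(var_names) if var_names is not None else list(frame.columns)
    values = frame[cols]
    keep = []
    for c in cols:
        if values[c].std(ddof=1) == 0 or values[c].isna().all():
            warnings.warn(f"dropping constant variable {c!r}", stacklevel=2)
        else:
            keep.append(c)
    while len(keep) >= 2:
        r = values[keep].corr().abs().to_numpy()
        np.fill_diagonal(r, 0.0)
        if r.max() <= r_max:
            break
        mean_abs = r.sum(axis=1) / (len(keep) - 1)
        # ties broken toward the later-listed variable, keeping earlier ones
        worst = max(range(len(keep)), key=lambda i: (mean_abs[i], i))
        keep.pop(worst)
    return keep


# ---------------------------------------------------------------------------
# PCA-env


@dataclass
class PcaEnvModel:
    """Standardization + first-two-axes projection fitted on background sites."""

    var_names: list
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray  # shape (2, V), rows orthonormal
    explained: np.ndarray  # variance fraction per axis, axis1 >= axis2

    def transform(self, frame: pd.DataFrame) -> np.ndarray:
        """Project sites onto the two PCA-env axes; returns (n, 2) scores."""
        x = (frame[self.var_names].to_numpy(dtype=float) - self.means) / self.sds
        return x @ self.loadings.T


def fit_pca_env(background: pd.DataFrame, var_names=None) -> PcaEnvModel:
    """PCA of the correlation structure of the pooled background sample.

    Variables are standardized to zero mean and unit SD over the background;
    axes 1–2 of the eigen-decomposition are retained with the sign convention
    that each loading vector's largest-magnitude entry is positive.  A single
    informative variable yields a degenerate (zero) second axis.
    """
    cols = list(var_names) if var_names is not None else list(background.columns)
    x = background[cols].to_numpy(dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 background sites")
    sds = x.std(axis=0, ddof=1)
    informative = sds > 0
    if not informative.any():
        raise ValueError("all variables constant over the background")
    dropped = [c for c, ok in zip(cols, informative) if not ok]
    if dropped:
        warnings.warn(f"dropping constant variables {dropped}", stacklevel=2)
    cols = [c for c, ok in zip(cols, informative) if ok]
    x = x[:, informative]
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1)
    xs = (x - means) / sds
    v = len(cols)
    if v == 1:
        loadings = np.array([[1.0], [0.0]])
        explained = np.array([1.0, 0.0])
    else:
        _, s, vt = np.linalg.svd(xs, full_matrices=False)
        eig = s**2 / (x.shape[0] - 1)
        loadings = vt[:2].copy()
        explained = eig[:2] / eig.sum()
        if loadings.shape[0] < 2:  # rank 1 data with >= 2 variables
            loadings = np.vstack([loadings, np.zeros((1, v))])
            explained = np.array([explained[0], 0.0])
    for k in range(2):
        j = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, j] < 0:
            loadings[k] = -loadings[k]
    return PcaEnvModel(
        var_names=cols, means=means, sds=sds, loadings=loadings, explained=explained
    )


# ---------------------------------------------------------------------------
# kernel occupancy grids


def _nrd_bandwidth(x: np.ndarray) -> float:
    """Normal-reference (Silverman-type) kernel SD for one axis."""
    n = len(x)
    sd = float(np.std(x, ddof=1))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        raise ValueError("degenerate score spread; cannot choose a bandwidth")
    return 1.06 * spread * n ** (-1 / 5)


def _separable_density(scores: np.ndarray, xc: np.ndarray, yc: np.ndarray, hx: float, hy: float) -> np.ndarray:
    """Gaussian product-kernel density of ``scores`` at the grid cell centers.

    Factorizes over axes, so the full R x R surface is one rank-n matmul.
    Returned as cell masses summing to 1.
    """
    gx = np.exp(-0.5 * ((xc[None, :] - scores[:, 0][:, None]) / hx) ** 2)
    gy = np.exp(-0.5 * ((yc[None, :] - scores[:, 1][:, None]) / hy) ** 2)
    d = gx.T @ gy
    total = d.sum()
    if total <= 0:
        raise ValueError("all occurrences fall outside the grid")
    return d / total


@dataclass
class NicheGrid:
    """R x R occupancy surfaces for one group in a fixed PCA-env frame."""

    cytotype: str
    x_centers: np.ndarray
    y_centers: np.ndarray
    bandwidths: tuple
    occ_density: np.ndarray
    env_density: np.ndarray
    z: np.ndarray
    corrected: bool
    n_occurrences: int

    @property
    def R(self) -> int:
        return len(self.x_centers)

    def same_frame(self, other: "NicheGrid") -> bool:
        return (
            self.x_centers.shape == other.x_centers.shape
            and np.allclose(self.x_centers, other.x_centers)
            and np.allclose(self.y_centers, other.y_centers)
        )

    def cell_scores(self) -> np.ndarray:
        """(R*R, 2) array of cell-center scores, row-major over (x, y)."""
        xx, yy = np.meshgrid(self.x_centers, self.y_centers, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel()])

    def to_dataset(self):
        """Grid as an xarray Dataset (serializable to netCDF via the scipy engine)."""
        import xarray as xr

        return xr.Dataset(
            {
                "occ_density": (("x", "y"), self.occ_density),
                "env_density": (("x", "y"), self.env_density),
                "z": (("x", "y"), self.z),
            },
            coords={"x": self.x_centers, "y": self.y_centers},
            attrs={
                "cytotype": self.cytotype,
                "bandwidth_x": self.bandwidths[0],
                "bandwidth_y": self.bandwidths[1],
                "corrected": int(self.corrected),
                "n_occurrences": self.n_occurrences,
            },
        )

    def save(self, path) -> None:
        path = str(path)
        if path.endswith(".nc"):
            self.to_dataset().to_netcdf(path, engine="scipy")
        else:  # CSV fallback: long format
            xx, yy = np.meshgrid(self.x_centers, self.y_centers, indexing="ij")
            pd.DataFrame(
                {
                    "x": xx.ravel(),
                    "y": yy.ravel(),
                    "occ_density": self.occ_density.ravel(),
                    "env_density": self.env_density.ravel(),
                    "z": self.z.ravel(),
                }
            ).to_csv(path, index=False)


@dataclass
class NicheSpace:
    """A fixed comparison frame: PCA model, grid axes, bandwidths and the
    availability surfaces of each group.

    Holding the frame fixed means permutation tests only re-smooth occurrence
    scores; backgrounds (and hence the PCA, grid and bandwidths) do not change
    under relabeling.
    """

    model: PcaEnvModel
    x_centers: np.ndarray
    y_centers: np.ndarray
    bandwidths: tuple
    env_density: dict = field(default_factory=dict)  # group -> R x R masses
    bg_scores: dict = field(default_factory=dict)  # group -> (n, 2) scores

    @property
    def R(self) -> int:
        return len(self.x_centers)

    def occupancy(
        self,
        occ_scores: np.ndarray,
        group,
        corrected: bool = True,
        cytotype: str | None = None,
    ) -> NicheGrid:
        """Kernel occupancy grid of a set of occurrence scores for ``group``."""
        occ_scores = np.asarray(occ_scores, dtype=float)
        if occ_scores.ndim != 2 or occ_scores.shape[1] != 2:
            raise ValueError("occ_scores must be (n, 2)")
        occ = _separable_density(
            occ_scores, self.x_centers, self.y_centers, *self.bandwidths
        )
        occ = np.where(occ >= OCCUPANCY_FLOOR * occ.max(), occ, 0.0)
        env = self.env_density[group]
        avail = env >= AVAILABILITY_FLOOR * env.max()
        if corrected:
            z = np.where(avail, np.divide(occ, env, out=np.zeros_like(occ), where=avail), 0.0)
        else:
            z = np.where(avail, occ, 0.0)
        total = z.sum()
        if total <= 0:
            raise ValueError("occupancy is zero everywhere on the available grid")
        return NicheGrid(
            cytotype=cytotype or str(group),
            x_centers=self.x_centers,
            y_centers=self.y_centers,
            bandwidths=self.bandwidths,
            occ_density=occ,
            env_density=env,
            z=z / total,
            corrected=corrected,
            n_occurrences=len(occ_scores),
        )


def build_space(backgrounds: dict, var_names, R: int = 200) -> NicheSpace:
    """Calibrate a comparison frame on the pooled backgrounds of the groups.

    ``backgrounds`` maps group label -> background site table.  The PCA is fit
    on the pooled sites; the grid spans the pooled score range per axis padded
    by one bandwidth; bandwidths follow the normal-reference rule on the
    pooled background scores.
    """
    if R < 2:
        raise ValueError("grid resolution must be >= 2")
    labels = list(backgrounds)
    pooled = pd.concat([backgrounds[g] for g in labels], ignore_index=True)
    model = fit_pca_env(pooled, var_names)
    pooled_scores = model.transform(pooled)
    hx = _nrd_bandwidth(pooled_scores[:, 0])
    hy = _nrd_bandwidth(pooled_scores[:, 1]) if np.std(pooled_scores[:, 1]) > 0 else hx
    xc = np.linspace(pooled_scores[:, 0].min() - hx, pooled_scores[:, 0].max() + hx, R)
    yc = np.linspace(pooled_scores[:, 1].min() - hy, pooled_scores[:, 1].max() + hy, R)
    space = NicheSpace(
        model=model, x_centers=xc, y_centers=yc, bandwidths=(hx, hy)
    )
    for g in labels:
        scores = model.transform(backgrounds[g])
        space.env_density[g] = _separable_density(scores, xc, yc, hx, hy)
        space.bg_scores[g] = scores
    return space


def build_niche_grid(
    occ: pd.DataFrame,
    background: pd.DataFrame,
    var_names,
    R: int = 200,
    corrected: bool = True,
    cytotype: str = "occ",
) -> NicheGrid:
    """Single-group convenience: calibrate a frame on one background and grid
    its occurrences (requires >= 5 occurrences)."""
    if len(occ) < 5:
        raise ValueError("need at least 5 occurrences")
    space = build_space({cytotype: background}, var_names, R=R)
    scores = space.model.transform(occ)
    return space.occupancy(scores, cytotype, corrected=corrected, cytotype=cytotype)
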