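import numpy as np
import pandas as pd
import pytest

import cytoniche as cn
from cytoniche._seeds import child_seed
from cytoniche.geo import sample_background

# Published cytotype-composition row counts of the reference survey (858
# populations with >= 2 analysed individuals): combination -> population count.
TABLE2_ROWS = {
    ("3x",): 12,
    ("4x",): 114,
    ("5x",): 450,
    ("6x",): 123,
    ("7x",): 9,
    ("8x",): 1,
    ("3x", "4x"): 1,
    ("3x", "5x"): 2,
    ("4x", "5x"): 51,
    ("4x", "6x"): 10,
    ("4x", "7x"): 1,
    ("4x", "8x"): 1,
    ("5x", "6x"): 74,
    ("5x", "7x"): 1,
    ("4x", "5x", "6x"): 8,
}


def populations_from_rows(rows=TABLE2_ROWS, n_per_cytotype=2):
    """Expand combination counts into PopulationRecords (2 plants/cytotype)."""
    pops = []
    k = 0
    for combo, n in rows.items():
        for _ in range(n):
            pops.append(
                cn.PopulationRecord(
                    pop_id=f"p{k:04d}",
                    lon=10.0,
                    lat=50.0,
                    region="core",
                    counts={c: n_per_cytotype for c in combo},
                )
            )
            k += 1
    return pops


@pytest.fixture(scope="session")
def table2_populations():
    return populations_from_rows()


def whitened(n, v, seed=0):
    """(n, v) matrix with exactly zero sample means and identity sample covariance."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, v))
    x -= x.mean(axis=0)
    chol = np.linalg.cholesky(np.cov(x.T))
    return x @ np.linalg.inv(chol).T


@pytest.fixture(scope="session")
def nested_pair():
    """Shared-background grids where the high-ploidy niche sits strictly
    inside the low-ploidy one (niche-contraction geometry)."""
    model = cn.LatentEnvModel(n_sites=4000, lattice_extent_km=300.0)
    specs = [
        cn.NicheSpec("4x", (0.0, 0.0), (0.9, 0.9), 0.15),
        cn.NicheSpec("6x", (0.0, 0.0), (0.25, 0.25), 0.5),
    ]
    env = cn.generate_env_sites(model, seed=child_seed(11, "env"))
    occ = cn.sample_occurrences(env, specs, seed=child_seed(11, "occ"))
    o_low = occ.frame[occ.frame.cytotype == "4x"]
    o_high = occ.frame[occ.frame.cytotype == "6x"]
    both = pd.concat([o_low, o_high], ignore_index=True)
    bg = sample_background(both, env.frame, seed=child_seed(11, "bg"))
    space = cn.build_space(
        {"4x": bg[env.var_names], "6x": bg[env.var_names]}, env.var_names, R=100
    )
    g_low = space.occupancy(space.model.transform(o_low), "4x", cytotype="4x")
    g_high = space.occupancy(space.model.transform(o_high), "6x", cytotype="6x")
    return space, g_low, g_high


@pytest.fixture(scope="session")
def small_survey():
    """A compact two-cytotype survey with backgrounds, reused across tests."""
    model = cn.LatentEnvModel(n_sites=3000, lattice_extent_km=300.0)
    specs = [
        cn.NicheSpec("4x", (-0.5, 0.0), (0.7, 0.7), 0.06),
        cn.NicheSpec("5x", (0.4, 0.2), (0.6, 0.6), 0.06),
    ]
    env = cn.generate_env_sites(model, seed=child_seed(21, "env"))
    occ = cn.sample_occurrences(env, specs, seed=child_seed(21, "occ"))
    groups = {}
    for s in specs:
        sub = occ.frame[occ.frame.cytotype == s.cytotype]
        bg = sample_background(sub, env.frame, seed=child_seed(21, "bg" + s.cytotype))
        groups[s.cytotype] = (sub, bg)
    return model, env, specs, groups
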