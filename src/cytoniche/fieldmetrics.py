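"""Field-site metrics: heat-load index and Gower dissimilarity.

Heat load estimates the solar heating a site receives from its latitude,
slope and aspect.  Aspect is folded about the southwest axis — in the
northern hemisphere a SW-facing slope is the warmest and a NE-facing the
coolest at a given steepness — and a published regression on latitude, slope
and folded aspect gives log-scale incident radiation, which is exponentiated
to an arithmetic scale.

Gower dissimilarity compares habitat records with mixed field types:
range-normalized absolute difference for quantitative and (rank-coded)
ordinal fields, 0/1 mismatch for binary and categorical ones, averaged with
pairwise deletion of missing fields.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

# Coefficients of McCune & Keon (2002) J. Veg. Sci. 13:603-606, equation 2,
# transcribed verbatim; predicts ln(incident radiation) from latitude L,
# slope S and folded aspect A (all radians).  Stated validity: 30-60 deg N.
_HEAT_LOAD_EQ2 = {
    "intercept": -1.236,
    "cosL_cosS": 1.350,
    "cosA_sinS_cosL": -1.376,
    "sinL_sinS": -0.331,
    "sinA_sinS": 0.294,
}
_VALID_LAT_RANGE = (30.0, 60.0)


@dataclass(frozen=True)
class SiteTopo:
    slope_deg: float
    aspect_deg: float
    latitude_deg: float

    def __post_init__(self) -> None:
        if not 0 <= self.slope_deg <= 90:
            raise ValueError(f"slope out of [0, 90]: {self.slope_deg}")
        if not 0 <= self.aspect_deg < 360:
            raise ValueError(f"aspect out of [0, 360): {self.aspect_deg}")


def fold_aspect_deg(aspect_deg: float) -> float:
    """Fold aspect about the NE-SW axis: SW (225 deg) -> 180, NE (45) -> 0.

    The regression's aspect term is -c * cos(A'), so A' = 180 (southwest)
    maximizes heat load and A' = 0 (northeast) minimizes it.
    """
    return abs(180.0 - abs(aspect_deg - 225.0))


def heat_load(t: SiteTopo) -> float:
    """Heat-load index on an arithmetic (exponentiated) scale; unitless.

    2*pi-periodic in aspect and symmetric about the NE-SW folding axis; at
    zero slope every aspect term vanishes and the value depends on latitude
    alone.  Outside the regression's stated latitude range a warning is
    emitted and the extrapolated value still returned.
    """
    if not _VALID_LAT_RANGE[0] <= t.latitude_deg <= _VALID_LAT_RANGE[1]:
        warnings.warn(
            f"latitude {t.latitude_deg} outside the regression's stated "
            f"validity range {_VALID_LAT_RANGE}; value is an extrapolation",
            stacklevel=2,
        )
    L = math.radians(t.latitude_deg)
    S = math.radians(t.slope_deg)
    A = math.radians(fold_aspect_deg(t.aspect_deg))
    c = _HEAT_LOAD_EQ2
    ln_rad = (
        c["intercept"]
        + c["cosL_cosS"] * math.cos(L) * math.cos(S)
        + c["cosA_sinS_cosL"] * math.cos(A) * math.sin(S) * math.cos(L)
        + c["sinL_sinS"] * math.sin(L) * math.sin(S)
        + c["sinA_sinS"] * math.sin(A) * math.sin(S)
    )
    return math.exp(ln_rad)


def heat_load_frame(frame: pd.DataFrame) -> pd.Series:
    """Vector form over a (lat, slope, aspect) table; returns the index column."""
    return pd.Series(
        [
            heat_load(SiteTopo(float(r.slope), float(r.aspect), float(r.lat)))
            for r in frame.itertuples(index=False)
        ],
        index=frame.index,
        name="heat_load",
    )


# ---------------------------------------------------------------------------
# Gower dissimilarity


@dataclass
class HabitatSchema:
    """Field kinds and ranges for Gower comparisons.

    ``kinds`` maps field -> one of {"quantitative", "ordinal", "binary",
    "categorical"}; ``ranges`` supplies (min, max) for quantitative and
    ordinal fields (ordinal levels are treated as equally spaced ranks).
    """

    kinds: dict
    ranges: dict

    @classmethod
    def infer_ranges(cls, kinds: dict, frame: pd.DataFrame) -> "HabitatSchema":
        ranges = {}
        for f, kind in kinds.items():
            if kind in ("quantitative", "ordinal"):
                col = pd.to_numeric(frame[f], errors="coerce")
                ranges[f] = (float(col.min()), float(col.max()))
        return cls(kinds=kinds, ranges=ranges)


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def gower(a: dict, b: dict, schema: HabitatSchema) -> float:
    """Gower dissimilarity between two habitat records, in [0, 1].

    Missing fields are dropped pairwise with weight renormalization; a
    quantitative/ordinal field whose range is zero is dropped with a warning.
    """
    parts = []
    for field, kind in schema.kinds.items():
        va, vb = a.get(field), b.get(field)
        if _is_missing(va) or _is_missing(vb):
            continue
        if kind in ("quantitative", "ordinal"):
            lo, hi = schema.ranges[field]
            rng = hi - lo
            if rng <= 0:
                warnings.warn(f"zero range for field {field!r}; dropped", stacklevel=2)
                continue
            parts.append(abs(float(va) - float(vb)) / rng)
        elif kind in ("binary", "categorical"):
            parts.append(0.0 if va == vb else 1.0)
        else:
            raise ValueError(f"unknown field kind {kind!r}")
    if not parts:
        raise ValueError("no comparable fields between the two records")
    return float(np.mean(parts))


def gower_matrix(frame: pd.DataFrame, kinds: dict, ranges: dict | None = None) -> pd.DataFrame:
    """Square Gower dissimilarity matrix over the rows of a habitat table."""
    schema = (
        HabitatSchema(kinds=kinds, ranges=ranges)
        if ranges is not None
        else HabitatSchema.infer_ranges(kinds, frame)
    )
    records = frame.to_dict("records")
    n = len(records)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = gower(records[i], records[j], schema)
    return pd.DataFrame(out, index=frame.index, columns=frame.index)
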