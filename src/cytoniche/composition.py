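"""Population-level cytotype composition statistics.

A population survey of a mixed-ploidy plant yields, per sampled population,
the number of individuals of each cytotype.  This module tabulates the exact
cytotype combinations found (e.g. pure 5x, 4x+5x, 4x+5x+6x), the odds of a
cytotype occurring in a uniform vs mixed population, the overall fraction of
mixed-ploidy populations, and individual-level cytotype frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .cytometry import ploidy_level


@dataclass
class PopulationRecord:
    """One sampled population: location, region label and per-cytotype counts."""

    pop_id: str
    lon: float
    lat: float
    region: str
    counts: dict  # cytotype label -> number of individuals
    area_m2: float | None = None
    habitat: dict = field(default_factory=dict)
    site_id: int | None = None

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError(f"negative count in population {self.pop_id}")
        if not any(v > 0 for v in self.counts.values()):
            raise ValueError(f"population {self.pop_id} has no individuals")

    @property
    def cytotypes(self) -> tuple:
        return tuple(sorted((c for c, n in self.counts.items() if n > 0), key=ploidy_level))

    @property
    def n_individuals(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def is_mixed(self) -> bool:
        return len(self.cytotypes) >= 2


@dataclass
class CompositionTable:
    """Rows keyed by sorted cytotype combination, with counts and percents."""

    frame: pd.DataFrame  # columns: combination (tuple), n_populations, percent
    total: int

    def row_count(self, combination) -> int:
        key = tuple(sorted(combination, key=ploidy_level))
        hit = self.frame.loc[self.frame["combination"] == key, "n_populations"]
        return int(hit.iloc[0]) if len(hit) else 0

    def cytotypes(self) -> list:
        seen = {c for combo in self.frame["combination"] for c in combo}
        return sorted(seen, key=ploidy_level)


def build_composition(pops, min_individuals: int = 2) -> CompositionTable:
    """Tabulate cytotype combinations over populations.

    Populations with fewer than ``min_individuals`` analysed plants are
    excluded (singleton samples cannot reveal mixture).  Each remaining
    population contributes one count to its exact combination row.
    Permutation-invariant in input order.
    """
    kept = [p for p in pops if p.n_individuals >= min_individuals]
    if not kept:
        raise ValueError("no populations left after the minimum-individuals filter")
    combos: dict = {}
    for p in kept:
        combos[p.cytotypes] = combos.get(p.cytotypes, 0) + 1
    total = len(kept)
    rows = sorted(combos.items(), key=lambda kv: (len(kv[0]), [ploidy_level(c) for c in kv[0]]))
    frame = pd.DataFrame(
        {
            "combination": [k for k, _ in rows],
            "n_populations": [v for _, v in rows],
            "percent": [round(100.0 * v / total, 2) for _, v in rows],
        }
    )
    return CompositionTable(frame=frame, total=total)


def mixing_odds(cytotype: str, table: CompositionTable) -> float | None:
    """Uniform-to-mixed odds for one cytotype.

    Ratio of the number of uniform-ploidy populations of ``cytotype`` to the
    number of mixed-ploidy populations containing it; ``None`` (undefined)
    when the cytotype never occurs in a mixed population.
    """
    if cytotype not in table.cytotypes():
        raise ValueError(f"cytotype {cytotype!r} absent from the composition table")
    uniform = table.row_count((cytotype,))
    mixed = int(
        table.frame.loc[
            table.frame["combination"].map(lambda c: cytotype in c and len(c) >= 2),
            "n_populations",
        ].sum()
    )
    if mixed == 0:
        return None
    return uniform / mixed


def mixed_fraction(table: CompositionTable) -> float:
    """Proportion of populations holding two or more cytotypes."""
    if table.total <= 0:
        raise ValueError("empty composition table")
    mixed = int(
        table.frame.loc[table.frame["combination"].map(len) >= 2, "n_populations"].sum()
    )
    return mixed / table.total


def individual_frequencies(pops) -> dict:
    """Fraction of all analysed individuals belonging to each cytotype."""
    totals: dict = {}
    for p in pops:
        for c, n in p.counts.items():
            if n > 0:
                totals[c] = totals.get(c, 0) + int(n)
    grand = sum(totals.values())
    if grand == 0:
        raise ValueError("no individuals")
    return {c: totals[c] / grand for c in sorted(totals, key=ploidy_level)}


# ---------------------------------------------------------------------------
# frame <-> record conversion for CSV round-tripping


def records_from_frame(frame: pd.DataFrame) -> list:
    """Build PopulationRecords from a long table (pop_id, lon, lat, region, ploidy, n_individuals[, area_m2])."""
    recs = []
    for pop_id, grp in frame.groupby("pop_id", sort=True):
        first = grp.iloc[0]
        counts = {str(r.ploidy): int(r.n_individuals) for r in grp.itertuples(index=False)}
        recs.append(
            PopulationRecord(
                pop_id=str(pop_id),
                lon=float(first["lon"]),
                lat=float(first["lat"]),
                region=str(first["region"]),
                counts=counts,
                area_m2=float(first["area_m2"]) if "area_m2" in grp.columns and pd.notna(first.get("area_m2")) else None,
                site_id=int(first["site_id"]) if "site_id" in grp.columns and pd.notna(first.get("site_id")) else None,
            )
        )
    return recs


def frame_from_records(pops) -> pd.DataFrame:
    rows = []
    for p in pops:
        for c in p.cytotypes:
            rows.append(
                {
                    "pop_id": p.pop_id,
                    "lon": p.lon,
                    "lat": p.lat,
                    "region": p.region,
                    "ploidy": c,
                    "n_individuals": p.counts[c],
                    "area_m2": p.area_m2,
                    "site_id": p.site_id,
                }
            )
    return pd.DataFrame(rows)


def composition_report(pops, min_individuals: int = 2) -> dict:
    """JSON-ready summary: table rows, odds per cytotype, mixed fraction."""
    table = build_composition(pops, min_individuals=min_individuals)
    odds = {}
    for c in table.cytotypes():
        o = mixing_odds(c, table)
        odds[c] = None if o is None else round(o, 1)
    return {
        "total_populations": table.total,
        "rows": [
            {"combination": "+".join(k), "n": int(n), "percent": float(pct)}
            for k, n, pct in table.frame.itertuples(index=False)
        ],
        "odds_uniform_to_mixed": odds,
        "mixed_fraction": mixed_fraction(table),
        "individual_frequencies": individual_frequencies(
            [p for p in pops if p.n_individuals >= min_individuals]
        ),
    }
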