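"""DNA-ploidy calling from flow-cytometry relative fluorescence.

A sample's ploidy level is inferred from the position of its G0/G1 peak
relative to the G0/G1 peak of a co-processed internal standard ("relative
fluorescence", RF).  Calls are made against calibration envelopes — per-stain,
per-ploidy [min, max] RF intervals established on plants with directly counted
chromosome numbers.  Histograms with a coefficient of variation at or above
the gate (default 5.0%) are rejected outright.

The default calibration ships with the package: RF envelopes for the six
*Allium oleraceum* cytotypes (3x–8x) measured with propidium iodide (PI) and
DAPI against a *Triticum aestivum* internal standard.  Neighbouring envelopes
may overlap (notably 4x/5x under PI); a measurement falling inside two or more
envelopes is flagged ``ambiguous`` with the full candidate set rather than
forced to a call — in practice such plants are resolved by chromosome counting
or by the spatial coherence of RF values, which is outside this module's scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

DEFAULT_CV_GATE = 5.0

#: Reference calibration envelopes (stain, ploidy) -> (min_rf, max_rf, mean_rf, sd_rf)
#: for Allium oleraceum cytotypes against a Triticum aestivum standard.
DEFAULT_CALIBRATION_ROWS = {
    ("PI", "3x"): (1.19, 1.29, 1.25, 0.03),
    ("PI", "4x"): (1.41, 1.71, 1.56, 0.08),
    ("PI", "5x"): (1.66, 1.98, 1.84, 0.05),
    ("PI", "6x"): (2.01, 2.24, 2.10, 0.05),
    ("PI", "7x"): (2.36, 2.52, 2.46, 0.06),
    ("PI", "8x"): (2.62, 2.69, 2.65, 0.05),
    ("DAPI", "4x"): (2.36, 2.59, 2.45, 0.09),
    ("DAPI", "5x"): (2.51, 3.04, 2.84, 0.10),
    ("DAPI", "6x"): (3.16, 3.27, 3.20, 0.06),
}


def ploidy_level(cytotype: str) -> int:
    """Numeric ploidy of a cytotype label: ``"5x" -> 5``."""
    if not cytotype.endswith("x"):
        raise ValueError(f"not a cytotype label: {cytotype!r}")
    return int(cytotype[:-1])


@dataclass(frozen=True)
class RFMeasurement:
    """One relative-fluorescence reading (possibly a 2–3 plant pooled run)."""

    sample_id: str
    stain: str  # "PI" or "DAPI"
    rf: float  # sample G0/G1 peak / internal-standard peak
    cv_percent: float  # histogram coefficient of variation

    def __post_init__(self) -> None:
        if not self.rf > 0:
            raise ValueError(f"rf must be positive, got {self.rf}")
        if not math.isfinite(self.cv_percent) or self.cv_percent < 0:
            raise ValueError(f"cv_percent must be finite and >= 0, got {self.cv_percent}")


@dataclass
class CalibrationIntervals:
    """Per-(stain, ploidy) RF envelopes used to call ploidy.

    ``rows`` maps ``(stain, cytotype)`` to ``(min_rf, max_rf)`` with an
    optional mean as a third element; containment is closed ([min, max]),
    the bounds being observed extremes of karyologically verified plants.
    """

    rows: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, bounds in self.rows.items():
            lo, hi = bounds[0], bounds[1]
            if not 0 < lo <= hi:
                raise ValueError(f"invalid interval {bounds} for {key}")
            if len(bounds) > 2 and bounds[2] is not None and not lo <= bounds[2] <= hi:
                raise ValueError(f"mean outside [min, max] for {key}")

    @classmethod
    def default(cls) -> "CalibrationIntervals":
        return cls(rows=dict(DEFAULT_CALIBRATION_ROWS))

    @classmethod
    def from_csv(cls, path) -> "CalibrationIntervals":
        df = pd.read_csv(path)
        rows = {}
        for _, r in df.iterrows():
            mean = r["mean_rf"] if "mean_rf" in df.columns and pd.notna(r.get("mean_rf")) else None
            rows[(str(r["stain"]), str(r["ploidy"]))] = (float(r["min_rf"]), float(r["max_rf"]), mean)
        return cls(rows=rows)

    def stains(self) -> set:
        return {s for s, _ in self.rows}

    def intervals_for(self, stain: str) -> dict:
        return {p: b for (s, p), b in self.rows.items() if s == stain}

    def mean_rf(self, stain: str, cytotype: str) -> float:
        bounds = self.rows[(stain, cytotype)]
        if len(bounds) > 2 and bounds[2] is not None:
            return float(bounds[2])
        return 0.5 * (bounds[0] + bounds[1])


@dataclass(frozen=True)
class PloidyCall:
    """Outcome of calling one measurement.

    status is one of ``called`` (rf inside exactly one envelope), ``ambiguous``
    (inside two or more; ``candidates`` lists them), ``out_of_range`` (inside
    none) or ``rejected_cv`` (failed the CV gate before calling).
    """

    sample_id: str
    status: str
    ploidy: str | None = None
    candidates: tuple = ()


def gate_cv(m: RFMeasurement, threshold_percent: float = DEFAULT_CV_GATE) -> bool:
    """Accept a histogram iff its CV is strictly below the gate."""
    if m.cv_percent < 0:
        raise ValueError("negative CV")
    return m.cv_percent < threshold_percent


def rf_variation(min_rf: float, max_rf: float) -> float:
    """Within-cytotype RF variation, percent: 100 * (max - min) / min, 1 d.p."""
    if min_rf <= 0:
        raise ValueError("min_rf must be positive")
    if max_rf < min_rf:
        raise ValueError("max_rf < min_rf")
    return round(100.0 * (max_rf - min_rf) / min_rf, 1)


def assign_ploidy(m: RFMeasurement, calib: CalibrationIntervals) -> PloidyCall:
    """Call ploidy of a CV-gated measurement against the calibration envelopes.

    Deterministic and scale-free: rescaling rf together with all interval
    bounds leaves the call unchanged.
    """
    intervals = calib.intervals_for(m.stain)
    if not intervals:
        raise ValueError(f"no calibration intervals for stain {m.stain!r}")
    hits = sorted(
        (p for p, b in intervals.items() if b[0] <= m.rf <= b[1]),
        key=ploidy_level,
    )
    if len(hits) == 1:
        return PloidyCall(m.sample_id, "called", ploidy=hits[0])
    if len(hits) >= 2:
        return PloidyCall(m.sample_id, "ambiguous", candidates=tuple(hits))
    return PloidyCall(m.sample_id, "out_of_range")


def call_ploidy(
    m: RFMeasurement,
    calib: CalibrationIntervals,
    cv_threshold: float = DEFAULT_CV_GATE,
) -> PloidyCall:
    """CV-gate then assign; the one-stop entry point for a raw measurement."""
    if not gate_cv(m, cv_threshold):
        return PloidyCall(m.sample_id, "rejected_cv")
    return assign_ploidy(m, calib)


def call_table(
    measurements: pd.DataFrame,
    calib: CalibrationIntervals | None = None,
    cv_threshold: float = DEFAULT_CV_GATE,
) -> pd.DataFrame:
    """Vector form: call every row of a (sample_id, stain, rf, cv_percent) table."""
    calib = calib or CalibrationIntervals.default()
    out = []
    for r in measurements.itertuples(index=False):
        c = call_ploidy(
            RFMeasurement(str(r.sample_id), str(r.stain), float(r.rf), float(r.cv_percent)),
            calib,
            cv_threshold,
        )
        out.append(
            {
                "sample_id": c.sample_id,
                "status": c.status,
                "ploidy": c.ploidy or "",
                "candidates": "|".join(c.candidates),
            }
        )
    return pd.DataFrame(out)
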