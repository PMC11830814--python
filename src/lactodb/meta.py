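"""Meta-analysis pooling of study-level means and dispersions.

Study observations arrive as a mean with an SD, SE or CV from ``n`` subjects,
at a point postpartum time or a time range. Records are normalized (SE and CV
converted to SD, time ranges collapsed to their midpoint, units unified) and
pooled per time stratum with subject-count weights:

    weighted mean   X = sum(n_j x_j) / sum(n_j)
    overall SS      SS = sum(n_j (SD_j^2 + x_j^2)) - N X^2
    overall SD      SD = sqrt(SS / N)
    overall CV      CV = SD / X

The SS identity is exact when each SD_j is the population (divide-by-n) SD of
that study's subject values; pooling then reproduces the population mean and
SD of the concatenated subject-level values. A sample-SD (n-1) compatibility
convention is also provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

CSV_COLUMNS = [
    "study_id",
    "param_id",
    "t_lo_months",
    "t_hi_months",
    "mean",
    "dispersion_kind",
    "dispersion_value",
    "n",
    "units",
]

#: multiplicative factors for unit unification, keyed (from_unit, to_unit)
UNIT_FACTORS: dict[tuple[str, str], float] = {
    ("g/L", "g/dL"): 0.1,
    ("g/dL", "g/L"): 10.0,
    ("mg/dL", "g/L"): 0.01,
    ("mg/L", "g/L"): 0.001,
    ("mL/min", "L/h"): 0.06,
    ("L/h", "mL/min"): 1.0 / 0.06,
    ("mL", "L"): 0.001,
    ("L", "mL"): 1000.0,
    ("mL/day", "L/day"): 0.001,
    ("mL/kg/day", "L/kg/day"): 0.001,
    ("fraction", "%"): 100.0,
    ("%", "fraction"): 0.01,
}


class ConversionError(ValueError):
    """No known factor between the reported and target units."""


class InconsistencyError(ValueError):
    """Pooled sum of squares negative beyond numerical tolerance."""


def unit_factor(from_unit: str, to_unit: str) -> float:
    if from_unit == to_unit:
        return 1.0
    try:
        return UNIT_FACTORS[(from_unit, to_unit)]
    except KeyError:
        raise ConversionError(f"no unit conversion from {from_unit!r} to {to_unit!r}") from None


@dataclass(frozen=True)
class StudyRecord:
    """One study-level observation of one parameter.

    ``t_hi`` is None for point times. ``dispersion_value`` None marks a record
    reported without any dispersion (accepted, flagged, SD treated as 0).
    """

    study_id: str
    param_id: str
    t_lo: float
    t_hi: float | None
    mean: float
    dispersion_kind: str  # "SD" | "SE" | "CV"
    dispersion_value: float | None
    n: int
    units: str
    flagged: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.mean):
            raise ValueError(f"{self.study_id}: mean must be finite")
        if self.n < 1:
            raise ValueError(f"{self.study_id}: n must be >= 1, got {self.n}")
        if self.dispersion_kind not in ("SD", "SE", "CV"):
            raise ValueError(f"{self.study_id}: dispersion_kind must be SD/SE/CV")
        if self.dispersion_value is not None and self.dispersion_value < 0:
            raise ValueError(f"{self.study_id}: dispersion_value must be >= 0")

    @property
    def t(self) -> float:
        """Point time; midpoint when a range was reported."""
        return self.t_lo if self.t_hi is None else 0.5 * (self.t_lo + self.t_hi)


@dataclass(frozen=True)
class PooledEstimate:
    """Subject-count-weighted pooled summary for one time stratum."""

    param_id: str
    t: float
    weighted_mean: float
    overall_ss: float
    overall_sd: float
    overall_cv: float
    n_total: int
    j_studies: int


def normalize_record(rec: StudyRecord, target_units: str | None = None) -> StudyRecord:
    """Return ``rec`` with SD dispersion, point time, and ``target_units``.

    SE -> SD via SD = SE * sqrt(n); CV -> SD via SD = CV * mean. Unit factors
    apply identically to the mean and the SD (CV is unit-free and converted
    to SD *after* the mean's unit change, which is equivalent). A record with
    no dispersion is flagged with SD 0.
    """
    factor = 1.0 if target_units is None else unit_factor(rec.units, target_units)
    mean = rec.mean * factor
    if rec.dispersion_value is None:
        sd, flagged = 0.0, True
    elif rec.dispersion_kind == "SD":
        sd, flagged = rec.dispersion_value * factor, rec.flagged
    elif rec.dispersion_kind == "SE":
        sd, flagged = rec.dispersion_value * math.sqrt(rec.n) * factor, rec.flagged
    else:  # CV: dimensionless
        sd, flagged = rec.dispersion_value * abs(mean), rec.flagged
    return replace(
        rec,
        t_lo=rec.t,
        t_hi=None,
        mean=mean,
        dispersion_kind="SD",
        dispersion_value=sd,
        units=target_units or rec.units,
        flagged=flagged,
    )


def pool(records: list[StudyRecord], convention: str = "population") -> PooledEstimate:
    """Pool normalized records from one stratum into a weighted estimate.

    ``convention`` selects how study SDs enter the overall SS: "population"
    (divide-by-n SDs; the identity-closing default) or "sample" (n-1 SDs,
    SS = sum((n_j-1) SD_j^2 + n_j x_j^2) - N X^2). Flagged records (no
    reported dispersion) contribute to the weighted mean only.
    """
    if not records:
        raise ValueError("pool() requires at least one record")
    if convention not in ("population", "sample"):
        raise ValueError(f"convention must be 'population' or 'sample', got {convention!r}")
    param_ids = {r.param_id for r in records}
    units = {r.units for r in records}
    if len(param_ids) > 1 or len(units) > 1:
        raise ValueError(f"records mix parameters/units: {param_ids}, {units}")
    for r in records:
        if r.dispersion_kind != "SD" or r.t_hi is not None:
            raise ValueError(f"{r.study_id}: pool() expects normalized records")

    n = np.array([r.n for r in records], dtype=float)
    x = np.array([r.mean for r in records], dtype=float)
    sd = np.array([r.dispersion_value for r in records], dtype=float)
    ok = np.array([not r.flagged for r in records])  # SS uses unflagged only

    n_total = n.sum()
    xbar = float(np.sum(n * x) / n_total)

    n_ss, x_ss, sd_ss = n[ok], x[ok], sd[ok]
    n_ss_total = n_ss.sum()
    sd_term = np.sum(n_ss * sd_ss**2) if convention == "population" else np.sum((n_ss - 1) * sd_ss**2)
    if ok.all():
        # the printed shortcut: sum n(SD^2 + x^2) - N Xbar^2
        ss = float(sd_term + np.sum(n_ss * x_ss**2) - n_ss_total * xbar**2)
    else:
        # flagged records shift Xbar without entering the SS, so the shortcut
        # no longer telescopes; use the equivalent expanded form (always >= 0)
        ss = float(sd_term + np.sum(n_ss * (x_ss - xbar) ** 2))
    scale = max(float(np.sum(n_ss * (sd_ss**2 + x_ss**2))), 1.0)
    if ss < -1e-9 * scale:
        raise InconsistencyError(
            f"negative pooled sum of squares ({ss:.6g}); inconsistent study summaries"
        )
    ss = max(ss, 0.0)
    sd_overall = math.sqrt(ss / n_ss_total) if n_ss_total > 0 else 0.0
    return PooledEstimate(
        param_id=records[0].param_id,
        t=float(np.sum(n * np.array([r.t for r in records])) / n_total),
        weighted_mean=xbar,
        overall_ss=ss,
        overall_sd=sd_overall,
        overall_cv=sd_overall / xbar if xbar != 0 else math.nan,
        n_total=int(n_total),
        j_studies=len(records),
    )


def stratify_monthly(records: list[StudyRecord], convention: str = "population") -> list[PooledEstimate]:
    """Pool normalized records per postpartum month bin.

    Bins are [0,1), [1,2), ... [11,12] (last closed); empty bins are omitted
    and each returned estimate is labelled with its bin midpoint.
    """
    bins: dict[int, list[StudyRecord]] = {}
    for r in records:
        t = r.t
        if not 0.0 <= t <= 12.0:
            raise ValueError(f"{r.study_id}: time {t} outside [0, 12] months")
        b = min(int(t), 11)
        bins.setdefault(b, []).append(r)
    out = []
    for b in sorted(bins):
        est = pool(bins[b], convention=convention)
        out.append(replace(est, t=b + 0.5))
    return out


def read_records_csv(path: str | Path) -> list[StudyRecord]:
    """Read study records from the package's CSV schema.

    Malformed rows raise with the (1-based, header-inclusive) line number.
    """
    df = pd.read_csv(
        path,
        dtype={"study_id": str, "param_id": str, "units": str},
        float_precision="round_trip",
    )
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records = []
    for idx, row in df.iterrows():
        line = int(idx) + 2
        try:
            t_hi = None if pd.isna(row["t_hi_months"]) else float(row["t_hi_months"])
            disp = None if pd.isna(row["dispersion_value"]) else float(row["dispersion_value"])
            records.append(
                StudyRecord(
                    study_id=str(row["study_id"]),
                    param_id=str(row["param_id"]),
                    t_lo=float(row["t_lo_months"]),
                    t_hi=t_hi,
                    mean=float(row["mean"]),
                    dispersion_kind=str(row["dispersion_kind"]),
                    dispersion_value=disp,
                    n=int(row["n"]),
                    units=str(row["units"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}, line {line}: {exc}") from exc
    return records


def write_records_csv(records: list[StudyRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "study_id": [r.study_id for r in records],
            "param_id": [r.param_id for r in records],
            "t_lo_months": [r.t_lo for r in records],
            "t_hi_months": [r.t_hi for r in records],
            "mean": [r.mean for r in records],
            "dispersion_kind": [r.dispersion_kind for r in records],
            "dispersion_value": [r.dispersion_value for r in records],
            "n": [r.n for r in records],
            "units": [r.units for r in records],
        },
        columns=CSV_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.17g")  # lossless float round-trip


def write_pooled_csv(estimates: list[PooledEstimate], path: str | Path) -> None:
    pd.DataFrame([vars(e) for e in estimates]).to_csv(path, index=False)


def read_pooled_csv(path: str | Path) -> list[PooledEstimate]:
    df = pd.read_csv(path)
    return [
        PooledEstimate(
            param_id=str(r["param_id"]),
            t=float(r["t"]),
            weighted_mean=float(r["weighted_mean"]),
            overall_ss=float(r["overall_ss"]),
            overall_sd=float(r["overall_sd"]),
            overall_cv=float(r["overall_cv"]),
            n_total=int(r["n_total"]),
            j_studies=int(r["j_studies"]),
        )
        for _, r in df.iterrows()
    ]
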