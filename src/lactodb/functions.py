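"""Registry of postpartum physiological time-course functions.

Thirteen maternal and milk parameters (milk volume, pH, fat, protein, water,
infant intake, haematocrit, AGP, HSA, breast volume, plasma volume, cardiac
output, GFR) are described as piecewise continuous functions of postpartum
age over 0-12 months, each with a constant coefficient of variation that
captures the between-subject variability observed across studies.

The shipped registry is a JSON document (``lactodb/data/registry.json``)
transcribing the fitted coefficients; users may load an alternative registry
from disk. Two transcription ambiguities in the source coefficients are
resolved by convention flags (see :func:`load_registry`).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

from .families import coefficient_names, evaluate_family

#: days per month used to convert user-supplied postpartum ages given in days
DAYS_PER_MONTH = 30.4375

#: registry validity range in months postpartum
T_MIN, T_MAX = 0.0, 12.0

#: default Lucas creamatocrit-to-fat conversion constants (fat g/L = (crct% - intercept)/slope)
LUCAS_INTERCEPT = 0.59
LUCAS_SLOPE = 0.146


class UnknownParameterError(KeyError):
    """Requested parameter id is not in the registry."""


class TimeRangeError(ValueError):
    """Postpartum time outside the registry's 0-12 month validity range."""


def days_to_months(days: float) -> float:
    """Convert postpartum age in days to months (30.4375 days/month)."""
    return days / DAYS_PER_MONTH


@dataclass(frozen=True)
class FunctionSegment:
    """One function family valid on a half-open time interval [t_lo, t_hi).

    The final segment of a parameter is closed at 12 months.
    """

    family: str
    coefficients: dict
    t_lo: float
    t_hi: float

    def __post_init__(self) -> None:
        if not self.t_lo < self.t_hi:
            raise ValueError(f"segment interval degenerate: [{self.t_lo}, {self.t_hi})")
        coefficient_names(self.family, self.coefficients)  # validates family + completeness

    def __call__(self, t):
        return evaluate_family(self.family, self.coefficients, t)

    def contains(self, t: float, *, last: bool) -> bool:
        if last:
            return self.t_lo <= t <= self.t_hi
        return self.t_lo <= t < self.t_hi


@dataclass(frozen=True)
class ParameterDefinition:
    """A physiological parameter: ordered segments + constant CV + units."""

    id: str
    name: str
    units: str
    segments: tuple[FunctionSegment, ...]
    cv: float
    distribution: str = "lognormal"

    def __post_init__(self) -> None:
        if not 0.0 < self.cv < 1.0:
            raise ValueError(f"{self.id}: cv must lie in (0, 1), got {self.cv}")
        segs = tuple(self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ValueError(f"{self.id}: at least one segment required")
        if segs[0].t_lo != T_MIN or segs[-1].t_hi != T_MAX:
            raise ValueError(f"{self.id}: segments must span [{T_MIN}, {T_MAX}]")
        for a, b in zip(segs, segs[1:]):
            if a.t_hi != b.t_lo:
                raise ValueError(f"{self.id}: gap/overlap between segments at {a.t_hi} vs {b.t_lo}")

    def segment_at(self, t: float) -> FunctionSegment:
        for i, seg in enumerate(self.segments):
            if seg.contains(t, last=i == len(self.segments) - 1):
                return seg
        raise TimeRangeError(
            f"postpartum time {t} months outside [{T_MIN}, {T_MAX}] for {self.id!r}"
        )

    def __call__(self, t: float) -> float:
        return float(self.segment_at(float(t))(float(t)))


@dataclass
class Registry:
    """Lookup table of :class:`ParameterDefinition` keyed by id."""

    parameters: dict[str, ParameterDefinition] = field(default_factory=dict)
    source: str = "builtin"

    def __getitem__(self, param_id: str) -> ParameterDefinition:
        try:
            return self.parameters[param_id]
        except KeyError:
            known = ", ".join(sorted(self.parameters))
            raise UnknownParameterError(
                f"unknown parameter {param_id!r}; registry has: {known}"
            ) from None

    def __contains__(self, param_id: str) -> bool:
        return param_id in self.parameters

    def __iter__(self):
        return iter(self.parameters.values())

    def ids(self) -> list[str]:
        return list(self.parameters)

    def evaluate(self, param_id: str, t: float) -> float:
        """Mean function value for ``param_id`` at ``t`` months postpartum."""
        t = float(t)
        if not T_MIN <= t <= T_MAX:
            raise TimeRangeError(
                f"postpartum time {t} months outside [{T_MIN}, {T_MAX}]; no extrapolation"
            )
        return self[param_id](t)

    def evaluate_trajectory(self, param_id: str, times) -> np.ndarray:
        """Element-wise :meth:`evaluate` over a sorted sequence of times."""
        times = np.asarray(times, dtype=float)
        if times.size and np.any(np.diff(times) < 0):
            raise ValueError("times must be sorted ascending")
        return np.array([self.evaluate(param_id, t) for t in np.atleast_1d(times)])

    def segment_continuity_gap(self, param_id: str) -> list[tuple[float, float]]:
        """Relative mismatch at each internal segment boundary.

        Returns ``(boundary_time, |left limit - right value| / right value)``
        per boundary; empty for single-segment parameters.
        """
        p = self[param_id]
        gaps = []
        for left, right in zip(p.segments, p.segments[1:]):
            tb = left.t_hi
            left_limit = float(left(tb))
            right_value = float(right(tb))
            gaps.append((tb, abs(left_limit - right_value) / right_value))
        return gaps

    def checksum(self) -> str:
        """SHA-256 of the canonical JSON serialization (for run logging)."""
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()

    def to_dict(self) -> dict:
        return {
            "schema": "lactodb-registry/1",
            "parameters": [
                {
                    "id": p.id,
                    "name": p.name,
                    "units": p.units,
                    "cv": p.cv,
                    "distribution": p.distribution,
                    "segments": [
                        {
                            "family": s.family,
                            "t_lo": s.t_lo,
                            "t_hi": s.t_hi,
                            "coefficients": s.coefficients,
                        }
                        for s in p.segments
                    ],
                }
                for p in self
            ],
        }

    @classmethod
    def from_dict(cls, doc: dict, source: str = "dict") -> "Registry":
        params = {}
        for entry in doc["parameters"]:
            segments = tuple(
                FunctionSegment(
                    family=s["family"],
                    coefficients=dict(s["coefficients"]),
                    t_lo=float(s["t_lo"]),
                    t_hi=float(s["t_hi"]),
                )
                for s in entry["segments"]
            )
            p = ParameterDefinition(
                id=entry["id"],
                name=entry.get("name", entry["id"]),
                units=entry["units"],
                segments=segments,
                cv=float(entry["cv"]),
                distribution=entry.get("distribution", "lognormal"),
            )
            params[p.id] = p
        return cls(parameters=params, source=source)

    @classmethod
    def from_json(cls, path: str | Path) -> "Registry":
        path = Path(path)
        return cls.from_dict(json.loads(path.read_text()), source=str(path))


def load_registry(
    path: str | Path | None = None,
    *,
    agp_slope_sign: str = "negative",
    hsa_grouping: str = "centered",
) -> Registry:
    """Load the built-in registry (or one from ``path``) with convention flags.

    Parameters
    ----------
    agp_slope_sign : {"negative", "printed"}
        The late (1-12 month) AGP segment is linear. The default ``negative``
        uses slope -0.016/month so AGP declines back to pre-pregnancy levels
        by 12 months, matching the described trend and the plotted curve;
        ``printed`` uses the literally printed +0.016 slope.
    hsa_grouping : {"centered", "printed"}
        HSA follows a logistic rise. ``centered`` (default) reads the exponent
        as -7.16*(t - 0.866); ``printed`` reads it as (-7.16*t) - 0.866,
        i.e. midpoint at -0.866/7.16 months.
    """
    if agp_slope_sign not in ("negative", "printed"):
        raise ValueError(f"agp_slope_sign must be 'negative' or 'printed', got {agp_slope_sign!r}")
    if hsa_grouping not in ("centered", "printed"):
        raise ValueError(f"hsa_grouping must be 'centered' or 'printed', got {hsa_grouping!r}")

    if path is None:
        with resources.files("lactodb.data").joinpath("registry.json").open() as fh:
            reg = Registry.from_dict(json.load(fh), source="builtin")
    else:
        reg = Registry.from_json(path)

    if agp_slope_sign == "printed" and "agp" in reg:
        p = reg.parameters["agp"]
        segs = list(p.segments)
        for i, s in enumerate(segs):
            if s.family == "linear":
                coeffs = dict(s.coefficients)
                coeffs["slope"] = abs(coeffs["slope"])
                segs[i] = replace(s, coefficients=coeffs)
        reg.parameters["agp"] = replace(p, segments=tuple(segs))
    if hsa_grouping == "printed" and "hsa" in reg:
        p = reg.parameters["hsa"]
        segs = list(p.segments)
        for i, s in enumerate(segs):
            if s.family == "logistic":
                coeffs = dict(s.coefficients)
                # exp(-rate*t - 0.866) == exp(-rate*(t - (-0.866/rate)))
                coeffs["t_mid"] = -abs(coeffs["t_mid"]) / coeffs["rate"]
                segs[i] = replace(s, coefficients=coeffs)
        reg.parameters["hsa"] = replace(p, segments=tuple(segs))
    return reg


_DEFAULT: Registry | None = None


def default_registry() -> Registry:
    """Cached built-in registry with default conventions."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_registry()
    return _DEFAULT


def evaluate(param_id: str, t: float, registry: Registry | None = None) -> float:
    """Evaluate a registry parameter's mean function at ``t`` months."""
    return (registry or default_registry()).evaluate(param_id, t)


def evaluate_trajectory(param_id: str, times, registry: Registry | None = None) -> np.ndarray:
    return (registry or default_registry()).evaluate_trajectory(param_id, times)


def segment_continuity_gap(param_id: str, registry: Registry | None = None):
    return (registry or default_registry()).segment_continuity_gap(param_id)


def creamatocrit_to_fat(
    crct: float,
    *,
    intercept: float = LUCAS_INTERCEPT,
    slope: float = LUCAS_SLOPE,
) -> float:
    """Convert a creamatocrit reading (%) to milk fat in g/dL (Lucas equation).

    fat [g/L] = (creamatocrit% - intercept) / slope, then /10 for g/dL.
    The conversion constants come from the original creamatocrit calibration
    and are exposed as arguments so alternative calibrations can be applied.
    """
    crct = float(crct)
    if crct < intercept:
        raise ValueError(
            f"creamatocrit {crct}% below the calibration intercept {intercept}%: "
            "would imply negative fat"
        )
    return (crct - intercept) / slope / 10.0
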