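"""Virtual lactating population sampling.

Virtual subjects are drawn around the registry mean functions using each
parameter's constant CV. A subject keeps a single multiplicative deviation
(scalar frailty) across its whole trajectory, so individuals stay
systematically high or low over time while the cross-sectional cloud at each
time point has mean ``f(t)`` and SD ``cv * f(t)``.

Two sampling distributions are available:

* ``lognormal`` (default for strictly positive quantities): moment-matched so
  the arithmetic mean and CV are preserved exactly in expectation;
* ``normal_truncated`` (used for pH and haematocrit): Normal(1, cv) frailty
  truncated at +/- 3 SD, which keeps values in a physiologically tight band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .functions import Registry, default_registry

DISTRIBUTIONS = ("lognormal", "normal_truncated")


@dataclass(frozen=True)
class PopulationSpec:
    """What to simulate: parameters, cohort size, time grid, distribution, seed.

    ``distribution`` None defers to each parameter's registry default.
    """

    param_ids: tuple[str, ...]
    n_subjects: int
    times: tuple[float, ...]
    distribution: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "param_ids", tuple(self.param_ids))
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.distribution is not None and self.distribution not in DISTRIBUTIONS:
            raise ValueError(f"unknown distribution {self.distribution!r}; choose from {DISTRIBUTIONS}")
        if any(not 0.0 <= t <= 12.0 for t in self.times):
            raise ValueError("time grid must lie within [0, 12] months")


def _frailty(distribution: str, cv: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative subject factors with mean 1 and relative SD ~ cv."""
    if distribution == "lognormal":
        sigma2 = np.log1p(cv**2)
        return rng.lognormal(mean=-0.5 * sigma2, sigma=np.sqrt(sigma2), size=size)
    if distribution == "normal_truncated":
        return stats.truncnorm.rvs(-3.0, 3.0, loc=1.0, scale=cv, size=size, random_state=rng)
    raise ValueError(f"unknown distribution {distribution!r}")


def sample(spec: PopulationSpec, registry: Registry | None = None) -> pd.DataFrame:
    """Draw the virtual population described by ``spec``.

    Returns a long-format frame with columns ``subject_id, param_id,
    t_months, value``; reproducible for a fixed spec (seed included).
    """
    reg = registry or default_registry()
    rng = np.random.default_rng(spec.seed)
    times = np.asarray(spec.times, dtype=float)
    frames = []
    for pid in spec.param_ids:
        p = reg[pid]
        dist = spec.distribution or p.distribution
        factors = _frailty(dist, p.cv, spec.n_subjects, rng)
        means = reg.evaluate_trajectory(pid, np.sort(times))
        order = np.argsort(times)
        means_in_input_order = np.empty_like(means)
        means_in_input_order[order] = means
        values = np.outer(factors, means_in_input_order)  # (subject, time)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": np.repeat(np.arange(spec.n_subjects), times.size),
                    "param_id": pid,
                    "t_months": np.tile(times, spec.n_subjects),
                    "value": values.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def summarize(samples: pd.DataFrame, quantiles=(0.025, 0.5, 0.975)) -> pd.DataFrame:
    """Per (param, time) mean, population SD, CV and quantiles."""
    if samples.empty:
        raise ValueError("cannot summarize an empty sample table")
    rows = []
    for (pid, t), grp in samples.groupby(["param_id", "t_months"], sort=True):
        v = grp["value"].to_numpy()
        mean = float(v.mean())
        sd = float(v.std(ddof=0))
        row = {
            "param_id": pid,
            "t_months": float(t),
            "mean": mean,
            "sd": sd,
            "cv": sd / mean if mean != 0 else np.nan,
            "n": int(v.size),
        }
        for q in quantiles:
            row[f"q{q:g}"] = float(np.quantile(v, q))
        rows.append(row)
    return pd.DataFrame(rows)
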