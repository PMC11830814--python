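"""Synthetic study-level datasets with known ground truth.

Emulates the structure of the literature corpus the registry was built from:
each synthetic study reports a mean with an SD, SE or CV from n subjects at
some postpartum time, where the underlying truth is a registry function with
a constant CV. With ``subject_level=True`` the generator also draws the raw
subject values and reports their exact population mean/SD, making the pooling
identity (pooled estimate == statistics of the concatenated raw values)
testable to machine precision.

Study times default to a Beta(0.6, 2.2) profile scaled to [0, 12] months,
mirroring the heavy concentration of published observations in the first
postpartum month and the sparsity beyond month 7.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .functions import ParameterDefinition, Registry, default_registry
from .meta import StudyRecord, read_records_csv, write_records_csv

#: Beta shape parameters of the default study-time profile on [0, 12] months
TIME_PROFILE_BETA = (0.6, 2.2)


@dataclass
class SyntheticStudySet:
    """Generated study records plus the truth that produced them."""

    truth: ParameterDefinition
    records: list[StudyRecord]
    subject_values: dict[str, np.ndarray] = field(default_factory=dict)
    seed: int = 0


def beta_time_sampler(rng: np.random.Generator, size: int) -> np.ndarray:
    a, b = TIME_PROFILE_BETA
    return 12.0 * rng.beta(a, b, size=size)


def generate_studies(
    param_id: str,
    j_studies: int,
    *,
    cv: float | None = None,
    n_range: tuple[int, int] = (5, 200),
    time_sampler=None,
    dispersion_mix: tuple[float, float, float] = (0.5, 0.25, 0.25),
    subject_level: bool = False,
    seed: int = 0,
    registry: Registry | None = None,
) -> SyntheticStudySet:
    """Simulate ``j_studies`` study-level observations of one parameter.

    Parameters
    ----------
    cv : between-subject coefficient of variation of the truth; defaults to
        the registry CV of ``param_id``.
    n_range : inclusive bounds for each study's subject count.
    time_sampler : callable ``(rng, size) -> times`` in months; defaults to
        the Beta-profile sampler.
    dispersion_mix : probabilities of reporting dispersion as SD, SE, CV.
    subject_level : also draw raw subject values and report their exact
        population mean/SD (dispersion then always reported as SD).
    """
    if j_studies < 1:
        raise ValueError("j_studies must be >= 1")
    reg = registry or default_registry()
    truth = reg[param_id]
    cv = truth.cv if cv is None else float(cv)
    if cv <= 0:
        raise ValueError("cv must be > 0")
    if time_sampler is None:
        time_sampler = beta_time_sampler

    rng = np.random.default_rng(seed)
    times = np.asarray(time_sampler(rng, j_studies), dtype=float)
    if times.size == 0:
        raise ValueError("time sampler returned no times")
    times = np.clip(times, 0.0, 12.0)
    ns = rng.integers(n_range[0], n_range[1] + 1, size=j_studies)
    kinds = rng.choice(["SD", "SE", "CV"], size=j_studies, p=dispersion_mix)

    records: list[StudyRecord] = []
    subject_values: dict[str, np.ndarray] = {}
    for j in range(j_studies):
        study_id = f"synth-{param_id}-{j:03d}"
        t = float(times[j])
        n = int(ns[j])
        m_true = truth(t)
        sd_true = cv * m_true
        if subject_level:
            raw = rng.normal(m_true, sd_true, size=n)
            mean = float(raw.mean())
            sd = float(raw.std(ddof=0))  # population SD: closes the pooling identity
            kind, value = "SD", sd
            subject_values[study_id] = raw
        else:
            mean = float(rng.normal(m_true, sd_true / np.sqrt(n)))
            kind = str(kinds[j])
            if kind == "SD":
                value = sd_true
            elif kind == "SE":
                value = sd_true / np.sqrt(n)
            else:
                value = sd_true / abs(mean)
        records.append(
            StudyRecord(
                study_id=study_id,
                param_id=param_id,
                t_lo=t,
                t_hi=None,
                mean=mean,
                dispersion_kind=kind,
                dispersion_value=float(value),
                n=n,
                units=truth.units,
            )
        )
    return SyntheticStudySet(truth=truth, records=records, subject_values=subject_values, seed=seed)


def generate_record_csv(study_set: SyntheticStudySet, path: str | Path) -> Path:
    """Write the set's records in the standard study-record CSV schema."""
    path = Path(path)
    write_records_csv(study_set.records, path)
    return path


def roundtrip_records(study_set: SyntheticStudySet, path: str | Path) -> list[StudyRecord]:
    """Write then re-read the records (lossless by construction)."""
    return read_records_csv(generate_record_csv(study_set, path))
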