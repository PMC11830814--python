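"""Function families used to describe postpartum time courses.

Every family maps postpartum age ``t`` (months) to a parameter value. The
catalogue mirrors the model classes commonly used when fitting longitudinal
physiological data: constants, lines, low-order polynomials, exponentials and
several saturating (sigmoidal) forms.

Coefficients are carried as plain ``{name: value}`` dicts so families can be
serialized to JSON and fitted generically.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

#: maximum polynomial degree considered during model selection
MAX_POLY_DEGREE = 4

POLY_COEFF_NAMES = tuple(f"c{i}" for i in range(MAX_POLY_DEGREE + 1))


def _poly_names(coefficients: dict) -> list[str]:
    names = sorted((k for k in coefficients if k.startswith("c")), key=lambda k: int(k[1:]))
    if not names:
        raise ValueError("polynomial requires coefficients c0..cN")
    return names


def eval_constant(t, c):
    return np.broadcast_to(np.asarray(c["value"], dtype=float), np.shape(t)).copy() if np.ndim(t) else float(c["value"])


def eval_linear(t, c):
    return c["intercept"] + c["slope"] * np.asarray(t, dtype=float)


def eval_polynomial(t, c):
    names = _poly_names(c)
    coeffs = [c[k] for k in names]  # ascending order c0 + c1 t + ...
    return np.polynomial.polynomial.polyval(np.asarray(t, dtype=float), coeffs)


def eval_mono_exponential(t, c):
    """amplitude * exp(-rate * t); rate > 0 is a decay."""
    return c["amplitude"] * np.exp(-c["rate"] * np.asarray(t, dtype=float))


def eval_double_exponential(t, c):
    t = np.asarray(t, dtype=float)
    return c["a1"] * np.exp(-c["k1"] * t) + c["a2"] * np.exp(-c["k2"] * t)


def eval_exp_decay_to_baseline(t, c):
    """baseline + amplitude * exp(-rate * t): exponential return to a floor."""
    return c["baseline"] + c["amplitude"] * np.exp(-c["rate"] * np.asarray(t, dtype=float))


def eval_hill(t, c):
    """Saturating Hill (sigmoid Emax) curve emax * t^n / (t50^n + t^n)."""
    t = np.asarray(t, dtype=float)
    tn = np.power(t, c["n"])
    return c["emax"] * tn / (c["t50"] ** c["n"] + tn)


def eval_offset_hill(t, c):
    """baseline + (plateau - baseline) * t^n / (t50^n + t^n)."""
    t = np.asarray(t, dtype=float)
    tn = np.power(t, c["n"])
    return c["baseline"] + (c["plateau"] - c["baseline"]) * tn / (c["t50"] ** c["n"] + tn)


def eval_logistic(t, c):
    """baseline + span / (1 + exp(-rate * (t - t_mid)))."""
    t = np.asarray(t, dtype=float)
    return c["baseline"] + c["span"] / (1.0 + np.exp(-c["rate"] * (t - c["t_mid"])))


def eval_double_weibull(t, c):
    """exp(-k1 t) - exp(-k2 t) + offset: a rise-then-fall pulse on an offset.

    With k2 > k1 > 0 the curve starts at ``offset``, peaks at
    ln(k2/k1)/(k2-k1) and relaxes back towards ``offset``.
    """
    t = np.asarray(t, dtype=float)
    return np.exp(-c["k1"] * t) - np.exp(-c["k2"] * t) + c["offset"]


#: family name -> (coefficient names, evaluator)
FAMILIES: dict[str, tuple[tuple[str, ...], Callable]] = {
    "constant": (("value",), eval_constant),
    "linear": (("intercept", "slope"), eval_linear),
    "polynomial": (POLY_COEFF_NAMES, eval_polynomial),  # any contiguous c0..cN subset
    "mono_exponential": (("amplitude", "rate"), eval_mono_exponential),
    "double_exponential": (("a1", "k1", "a2", "k2"), eval_double_exponential),
    "exp_decay_to_baseline": (("baseline", "amplitude", "rate"), eval_exp_decay_to_baseline),
    "hill": (("emax", "n", "t50"), eval_hill),
    "offset_hill": (("baseline", "plateau", "n", "t50"), eval_offset_hill),
    "logistic": (("baseline", "span", "rate", "t_mid"), eval_logistic),
    "double_weibull": (("k1", "k2", "offset"), eval_double_weibull),
}


def coefficient_names(family: str, coefficients: dict | None = None) -> tuple[str, ...]:
    """Ordered coefficient names for ``family``.

    Polynomials are variable-order: when ``coefficients`` is given, the names
    present in it (c0..cN, ascending) are returned.
    """
    if family not in FAMILIES:
        raise KeyError(f"unknown function family: {family!r}")
    if family == "polynomial" and coefficients is not None:
        return tuple(_poly_names(coefficients))
    return FAMILIES[family][0]


def evaluate_family(family: str, coefficients: dict, t):
    """Evaluate ``family`` with ``coefficients`` at time(s) ``t`` (months)."""
    if family not in FAMILIES:
        raise KeyError(f"unknown function family: {family!r}")
    names, fn = FAMILIES[family]
    if family == "polynomial":
        names = coefficient_names(family, coefficients)
    missing = [k for k in names if k not in coefficients]
    if missing:
        raise ValueError(f"family {family!r} missing coefficients {missing}")
    return fn(t, coefficients)
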