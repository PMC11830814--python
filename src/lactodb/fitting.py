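"""Subject-count-weighted nonlinear least squares with model selection.

Pooled study points ``(t_j, x_j, n_j)`` are fitted by minimizing the weighted
sum of squares ``sum n_j (x_j - f(t_j))^2`` over the coefficients of a
candidate function family. Goodness of fit is summarized by the weighted SS
and a weighted r-squared about the n-weighted mean.

Model selection follows the procedure used to build the registry:

* candidates whose characteristic shape contradicts the observed data shape
  (supplied by the caller, mirroring visual inspection) are excluded before
  fitting — e.g. a saturating monotone rise rules out lines and polynomials;
* among the surviving fits the lowest weighted SS wins;
* a higher-order polynomial replaces the next lower order only if it improves
  both the weighted SS (by more than 1% relative) and r-squared (by more than
  0.005) — otherwise the lower order is kept;
* when observations stop short of 12 months, a heavily weighted simulated
  baseline point for non-pregnant, non-lactating women can be appended so the
  fitted curve returns to baseline (:func:`add_baseline_anchor`).

Linear-in-coefficients families (constant/linear/polynomial) are solved in
closed form; nonlinear families use bounded trust-region least squares with
data-driven initials and a small seeded multi-start to escape local minima.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .families import FAMILIES, coefficient_names, evaluate_family

SHAPE_CLASSES = ("monotone_up", "monotone_down", "rise_then_fall", "decay_to_floor", "unconstrained")

#: characteristic shape of each family, used for pre-fit exclusion
FAMILY_SHAPES = {
    "constant": "unconstrained",
    "linear": "unconstrained",
    "polynomial": "unconstrained",
    "mono_exponential": "monotone_down",
    "double_exponential": "unconstrained",
    "exp_decay_to_baseline": "decay_to_floor",
    "hill": "monotone_up",
    "offset_hill": "monotone_up",
    "logistic": "monotone_up",
    "double_weibull": "rise_then_fall",
}

#: data shapes -> family shape classes still considered. Monotone saturating
#: or floor-decaying data exclude unconstrained (linear/polynomial) families.
_COMPATIBLE = {
    "monotone_up": {"monotone_up"},
    "monotone_down": {"monotone_down", "decay_to_floor"},
    "decay_to_floor": {"decay_to_floor", "monotone_down"},
    "rise_then_fall": {"rise_then_fall", "unconstrained"},
    "unconstrained": set(FAMILY_SHAPES.values()),
}

_LINEAR_FAMILIES = ("constant", "linear", "polynomial")


class ShapeConflictError(ValueError):
    """Every candidate was excluded by the observed data shape."""


class UnderdeterminedError(ValueError):
    """Fewer points than coefficients plus one."""


@dataclass(frozen=True)
class FitCandidate:
    """A function family plus starting values, bounds and a shape class."""

    family: str
    p0: dict
    lower: dict = field(default_factory=dict)
    upper: dict = field(default_factory=dict)
    shape_class: str = "unconstrained"

    def __post_init__(self) -> None:
        if self.shape_class not in SHAPE_CLASSES:
            raise ValueError(f"unknown shape class {self.shape_class!r}")
        for k, v in self.p0.items():
            lo = self.lower.get(k, -np.inf)
            hi = self.upper.get(k, np.inf)
            if not lo <= v <= hi:
                raise ValueError(f"{self.family}.{k}: initial {v} outside [{lo}, {hi}]")

    @property
    def names(self) -> tuple[str, ...]:
        return coefficient_names(self.family, self.p0)


@dataclass(frozen=True)
class FitResult:
    family: str
    coefficients: dict
    weighted_ss: float
    weighted_r2: float
    converged: bool
    n_points: int

    def __call__(self, t):
        return evaluate_family(self.family, self.coefficients, t)


def _as_points(points) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("points must be (t, x, n) triples")
    t, x, n = arr[:, 0], arr[:, 1], arr[:, 2]
    if np.any(n < 1):
        raise ValueError("all weights n_j must be >= 1")
    return t, x, n


def weighted_mean(x: np.ndarray, n: np.ndarray) -> float:
    return float(np.sum(n * x) / np.sum(n))


def weighted_ss(points, fitted) -> float:
    t, x, n = _as_points(points)
    return float(np.sum(n * (x - np.asarray(fitted(t), dtype=float)) ** 2))


def weighted_r2(points, fitted) -> float:
    """1 - SS_res,w / SS_tot,w with the total SS about the n-weighted mean."""
    t, x, n = _as_points(points)
    if np.unique(x).size < 2:
        raise ValueError("weighted r2 undefined: all responses identical")
    ss_tot = float(np.sum(n * (x - weighted_mean(x, n)) ** 2))
    if ss_tot == 0.0:
        raise ValueError("weighted r2 undefined: zero total sum of squares")
    return 1.0 - weighted_ss(points, fitted) / ss_tot


def add_baseline_anchor(points, t_anchor: float, value: float, pseudo_n: int = 1000):
    """Append a simulated non-pregnant/non-lactating baseline point.

    The anchor must fall after the last observation (typically at 12 months)
    and is weighted by ``pseudo_n`` simulated subjects. The original points
    are returned untouched plus one extra row.
    """
    t, x, n = _as_points(points)
    t_last = float(t.max())
    if not t_last < t_anchor <= 12.0:
        raise ValueError(
            f"anchor time {t_anchor} must lie in (last observation {t_last}, 12]"
        )
    out = np.vstack([np.column_stack([t, x, n]), [t_anchor, value, pseudo_n]])
    return out


# ---------------------------------------------------------------------------
# initial-guess heuristics (data-driven; never see the generating truth)
# ---------------------------------------------------------------------------

def _guess_crossing(t, x, level) -> float:
    """First t where x crosses ``level`` (linear interpolation)."""
    s = np.argsort(t)
    t, x = t[s], x[s]
    above = x >= level
    if above.all() or not above.any():
        return float(np.median(t))
    i = int(np.argmax(above)) if not above[0] else int(np.argmax(~above))
    i = max(i, 1)
    x0, x1, t0, t1 = x[i - 1], x[i], t[i - 1], t[i]
    if x1 == x0:
        return float(t[i])
    return float(t0 + (level - x0) * (t1 - t0) / (x1 - x0))


def _tail_loglinear(t, x, frac=0.4):
    """Log-linear regression on the latest ``frac`` of positive points."""
    s = np.argsort(t)
    t, x = t[s], x[s]
    k = max(2, int(math.ceil(frac * t.size)))
    tt, xx = t[-k:], x[-k:]
    mask = xx > 0
    if mask.sum() < 2:
        return max(x.mean(), 1e-6), 0.1
    b, a = np.polyfit(tt[mask], np.log(xx[mask]), 1)
    return float(np.exp(a)), float(-b)


def initial_guess(family: str, points) -> dict:
    """Heuristic starting coefficients for a nonlinear family."""
    t, x, n = _as_points(points)
    s = np.argsort(t)
    t, x = t[s], x[s]
    xmin, xmax = float(x.min()), float(x.max())
    span = max(xmax - xmin, 1e-9 * max(abs(xmax), 1.0))

    if family == "mono_exponential":
        amp, rate = _tail_loglinear(t, x, frac=1.0)
        return {"amplitude": amp, "rate": rate}
    if family == "exp_decay_to_baseline":
        decaying = x[0] >= x[-1]
        baseline = xmin if decaying else xmax
        resid = np.abs(x - baseline)
        mask = resid > 1e-12 * max(abs(baseline), 1.0)
        if mask.sum() >= 2:
            b, a = np.polyfit(t[mask], np.log(resid[mask]), 1)
            amp = float(np.exp(a)) * (1.0 if decaying else -1.0)
            rate = float(-b)
        else:
            amp, rate = (span if decaying else -span), 1.0
        return {"baseline": float(baseline), "amplitude": amp, "rate": max(rate, 1e-3)}
    if family == "hill":
        emax = 1.05 * xmax
        t50 = max(_guess_crossing(t, x, emax / 2.0), 1e-3)
        return {"emax": emax, "n": 2.0, "t50": t50}
    if family == "offset_hill":
        t50 = max(_guess_crossing(t, x, 0.5 * (xmin + xmax)), 1e-3)
        return {"baseline": float(x[0]), "plateau": float(x[-1]), "n": 2.0, "t50": t50}
    if family == "logistic":
        t_mid = _guess_crossing(t, x, 0.5 * (xmin + xmax))
        # max slope of a logistic is rate*span/4
        dx = np.gradient(x, t) if t.size > 2 else np.array([span])
        rate = float(np.clip(4.0 * np.nanmax(np.abs(dx)) / span, 0.2, 50.0))
        return {"baseline": xmin, "span": span, "rate": rate, "t_mid": float(t_mid)}
    if family == "double_exponential":
        # peel-off: slow component from the tail, fast from the early residual
        a2, k2 = _tail_loglinear(t, x, frac=0.5)
        resid = x - a2 * np.exp(-k2 * t)
        mask = resid > 1e-10 * max(abs(xmax), 1.0)
        if mask.sum() >= 2:
            b, a = np.polyfit(t[mask], np.log(resid[mask]), 1)
            a1, k1 = float(np.exp(a)), float(-b)
        else:
            a1, k1 = span, 5.0
        return {"a1": a1, "k1": max(k1, 1e-3), "a2": a2, "k2": k2}
    if family == "double_weibull":
        # exp(0)-exp(0) vanishes, so the earliest observation approximates the offset
        offset = float(x[np.argmin(t)])
        return {"k1": 1.0, "k2": 5.0, "offset": offset}
    raise KeyError(f"no initial-guess heuristic for family {family!r}")


_DEFAULT_BOUNDS = {
    "mono_exponential": ({"amplitude": 0.0, "rate": -2.0}, {"rate": 60.0}),
    "exp_decay_to_baseline": ({"rate": 1e-4}, {"rate": 60.0}),
    "hill": ({"emax": 0.0, "n": 0.1, "t50": 1e-4}, {"n": 20.0, "t50": 12.0}),
    "offset_hill": ({"n": 0.1, "t50": 1e-4}, {"n": 20.0, "t50": 12.0}),
    "logistic": ({"rate": 0.01}, {"rate": 100.0}),
    "double_exponential": ({"k1": -2.0, "k2": -2.0}, {"k1": 60.0, "k2": 60.0}),
    "double_weibull": ({"k1": 1e-3, "k2": 1e-3}, {"k1": 60.0, "k2": 60.0}),
}


def default_candidate(family: str, points, shape_class: str | None = None) -> FitCandidate:
    """Build a candidate with data-driven initials and default bounds."""
    if family in _LINEAR_FAMILIES:
        p0 = {"value": 0.0} if family == "constant" else (
            {"intercept": 0.0, "slope": 0.0} if family == "linear" else {"c0": 0.0, "c1": 0.0, "c2": 0.0}
        )
        lower, upper = {}, {}
    else:
        p0 = initial_guess(family, points)
        lower, upper = (dict(b) for b in _DEFAULT_BOUNDS.get(family, ({}, {})))
        for k, v in list(p0.items()):  # keep heuristics inside the box
            p0[k] = float(np.clip(v, lower.get(k, -np.inf), upper.get(k, np.inf)))
    return FitCandidate(
        family=family,
        p0=p0,
        lower=lower,
        upper=upper,
        shape_class=shape_class or FAMILY_SHAPES[family],
    )


def polynomial_candidate(degree: int) -> FitCandidate:
    return FitCandidate(
        family="polynomial",
        p0={f"c{i}": 0.0 for i in range(degree + 1)},
        shape_class="unconstrained",
    )


#: named candidate sets for the CLI ``fit`` verb
CANDIDATE_SETS = {
    "polynomials": ["constant", "linear", "poly2", "poly3", "poly4"],
    "sigmoidal": ["hill", "offset_hill", "logistic"],
    "exponential": ["mono_exponential", "exp_decay_to_baseline", "double_exponential"],
    "all": [
        "constant", "linear", "poly2", "poly3", "poly4",
        "mono_exponential", "exp_decay_to_baseline", "double_exponential",
        "hill", "offset_hill", "logistic", "double_weibull",
    ],
}


def build_candidates(names: list[str], points) -> list[FitCandidate]:
    out = []
    for name in names:
        if name.startswith("poly") and name[4:].isdigit():
            out.append(polynomial_candidate(int(name[4:])))
        else:
            out.append(default_candidate(name, points))
    return out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _fit_linear_family(candidate: FitCandidate, t, x, n) -> tuple[dict, bool]:
    names = candidate.names
    if candidate.family == "constant":
        design = np.ones((t.size, 1))
    elif candidate.family == "linear":
        design = np.column_stack([np.ones_like(t), t])
    else:
        degree = len(names) - 1
        design = np.vander(t, degree + 1, increasing=True)
    w = np.sqrt(n)
    beta, *_ = np.linalg.lstsq(design * w[:, None], x * w, rcond=None)
    return dict(zip(names, map(float, beta))), True


def fit_weighted(points, candidate: FitCandidate, *, seed: int = 0, n_starts: int = 5) -> FitResult:
    """Fit one candidate family to ``(t, x, n)`` points by weighted least squares.

    Nonlinear families are refit from ``n_starts`` jittered copies of the
    initial coefficients (seeded, hence deterministic) and the best weighted
    SS is kept; non-convergence is reported on the result, not raised.
    """
    t, x, n = _as_points(points)
    names = candidate.names
    if t.size < len(names) + 1:
        raise UnderdeterminedError(
            f"{candidate.family}: {t.size} points cannot constrain {len(names)} coefficients"
        )

    if candidate.family in _LINEAR_FAMILIES:
        coeffs, converged = _fit_linear_family(candidate, t, x, n)
    else:
        lo = np.array([candidate.lower.get(k, -np.inf) for k in names])
        hi = np.array([candidate.upper.get(k, np.inf) for k in names])
        p0 = np.array([candidate.p0[k] for k in names], dtype=float)
        w = np.sqrt(n)

        def residuals(theta):
            c = dict(zip(names, theta))
            return w * (x - np.asarray(evaluate_family(candidate.family, c, t), dtype=float))

        rng = np.random.default_rng(seed)
        starts = [p0]
        for _ in range(n_starts - 1):
            jitter = p0 * rng.lognormal(0.0, 0.3, size=p0.size) + rng.normal(0.0, 1e-3, p0.size)
            starts.append(np.clip(jitter, lo, hi))
        best, converged = None, False
        for start in starts:
            try:
                sol = least_squares(
                    residuals, start, bounds=(lo, hi), method="trf",
                    xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=20000,
                )
            except Exception:
                continue
            cost = float(np.sum(sol.fun**2))
            if best is None or cost < best[0]:
                best = (cost, sol)
        if best is None:
            coeffs, converged = dict(candidate.p0), False
        else:
            coeffs = dict(zip(names, map(float, best[1].x)))
            converged = bool(best[1].success)

    fitted = lambda tt: evaluate_family(candidate.family, coeffs, tt)  # noqa: E731
    ss = weighted_ss(points, fitted)
    try:
        r2 = weighted_r2(points, fitted)
    except ValueError:
        r2 = math.nan
    return FitResult(
        family=candidate.family,
        coefficients=coeffs,
        weighted_ss=ss,
        weighted_r2=r2,
        converged=converged,
        n_points=int(t.size),
    )


#: thresholds encoding "did not outperform" for the polynomial parsimony rule
SS_IMPROVEMENT = 0.01
R2_IMPROVEMENT = 0.005


def select_model(points, candidates: list[FitCandidate], observed_shape: str, *, seed: int = 0) -> FitResult:
    """Fit surviving candidates and pick the winner.

    ``observed_shape`` is the caller's reading of the pooled data (standing in
    for visual inspection); candidates whose shape class contradicts it are
    dropped before any fitting. Polynomial orders are walked upward and a
    higher order is retained only if it improves both weighted SS and
    r-squared beyond tolerance; the final winner is the surviving fit with
    the lowest weighted SS.
    """
    if observed_shape not in SHAPE_CLASSES:
        raise ValueError(f"unknown observed shape {observed_shape!r}")
    allowed = _COMPATIBLE[observed_shape]
    survivors = [c for c in candidates if c.shape_class in allowed]
    if not survivors:
        excluded = sorted({c.shape_class for c in candidates})
        raise ShapeConflictError(
            f"observed shape {observed_shape!r} excludes every candidate (shape classes {excluded})"
        )

    fits = [fit_weighted(points, c, seed=seed) for c in survivors]
    is_poly = [f.family in ("constant", "linear", "polynomial") for f in fits]
    poly_chain = sorted(
        (f for f, p in zip(fits, is_poly) if p), key=lambda f: len(f.coefficients)
    )
    others = [f for f, p in zip(fits, is_poly) if not p]

    finalists = list(others)
    if poly_chain:
        keep = poly_chain[0]
        for nxt in poly_chain[1:]:
            ss_gain = (keep.weighted_ss - nxt.weighted_ss) / keep.weighted_ss if keep.weighted_ss > 0 else 0.0
            r2_gain = (nxt.weighted_r2 - keep.weighted_r2) if math.isfinite(nxt.weighted_r2) else 0.0
            if ss_gain > SS_IMPROVEMENT and r2_gain > R2_IMPROVEMENT:
                keep = nxt
        finalists.append(keep)
    return min(finalists, key=lambda f: f.weighted_ss)


def refit_segment(segment_points, family: str, *, seed: int = 0) -> FitResult:
    """Convenience: fit one registry family to points with default candidate."""
    return fit_weighted(segment_points, default_candidate(family, segment_points), seed=seed)
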