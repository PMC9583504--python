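"""Baseline estimators of the optimal marker combination.

Three classical alternatives to the spherical pattern search, all
returning unit-norm coefficient vectors so achieved objective values are
directly comparable:

* ``nm_maximize`` — sphere-anchored simplex search: the first coordinate
  is fixed at +/-1 (whichever orientation maximizes marker 1's individual
  EHUM) and the remaining coordinates are optimized by Nelder-Mead in
  unconstrained space; the result is normalized.
* ``step_down`` — markers are ranked by individual EHUM; the best
  marker's coefficient is fixed at its best sign and each further
  marker's scalar coefficient is found by a one-dimensional search
  holding earlier coefficients fixed.
* ``min_max`` — each subject's d markers are reduced to their maximum
  and minimum; the single free direction of the resulting 2-dimensional
  combination is found by dense angular search on the unit circle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import optimize as sopt

from .data import OrderedBiomarkerData
from .objectives import ObjectiveKind, individual_ehum, make_objective
from .optimizer import SCORConfig, scor_fit

__all__ = ["ComparatorResult", "nm_maximize", "step_down", "min_max",
           "reduce_min_max", "fit", "METHODS"]


@dataclass
class ComparatorResult:
    beta: np.ndarray            # unit norm
    value: float                # achieved objective at beta
    method: str
    objective_kind: ObjectiveKind
    reduction: Callable | None = None  # subject-level map for min_max


def _normalize(beta: np.ndarray) -> np.ndarray:
    return beta / np.linalg.norm(beta)


def nm_maximize(data: OrderedBiomarkerData,
                kind: ObjectiveKind | str = ObjectiveKind.EHUM) -> ComparatorResult:
    """Nelder-Mead with the first coordinate anchored at its best sign.

    The remaining ``d - 1`` coordinates start at zero with a unit-step
    initial simplex (the objectives are piecewise constant, so the
    simplex must start large enough to cross decision boundaries).
    """
    kind = ObjectiveKind(kind)
    f = make_objective(kind, data)
    d = data.n_markers
    anchor, _ = individual_ehum(data, 1)
    if d == 1:
        beta = np.array([float(anchor)])
        return ComparatorResult(beta, f(beta), "nm", kind)

    def neg(rest: np.ndarray) -> float:
        return -f(np.concatenate(([float(anchor)], rest)))

    x0 = np.zeros(d - 1)
    simplex = np.vstack([x0, x0 + np.eye(d - 1)])
    res = sopt.minimize(neg, x0, method="Nelder-Mead",
                        options={"initial_simplex": simplex,
                                 "xatol": 1e-4, "fatol": 1e-4})
    beta = _normalize(np.concatenate(([float(anchor)], res.x)))
    return ComparatorResult(beta, f(beta), "nm", kind)


def step_down(data: OrderedBiomarkerData,
              kind: ObjectiveKind | str = ObjectiveKind.EHUM,
              grid: int = 401, bound: float = 5.0) -> ComparatorResult:
    """Greedy one-marker-at-a-time estimation in individual-EHUM order.

    The inner 1-D search is a dense grid on ``[-bound, bound]`` refined
    by a bounded scalar minimization between the best grid point's
    neighbours; marker-ranking ties keep the original column order.
    """
    kind = ObjectiveKind(kind)
    f = make_objective(kind, data)
    d = data.n_markers
    ranked = sorted(range(1, d + 1),
                    key=lambda k: -individual_ehum(data, k)[1])
    beta = np.zeros(d)
    first = ranked[0]
    beta[first - 1] = float(individual_ehum(data, first)[0])
    cgrid = np.linspace(-bound, bound, grid)
    for k in ranked[1:]:
        j = k - 1

        def val(c: float) -> float:
            trial = beta.copy()
            trial[j] = c
            return f(trial)

        vals = np.array([val(c) for c in cgrid])
        top = np.flatnonzero(vals == vals.max())
        b = int(top[np.argmin(np.abs(cgrid[top]))])  # tie -> smallest |c|
        best_c, best_v = cgrid[b], vals[b]
        lo, hi = cgrid[max(b - 1, 0)], cgrid[min(b + 1, grid - 1)]
        if hi > lo:
            res = sopt.minimize_scalar(lambda c: -val(c), bounds=(lo, hi), method="bounded")
            if -res.fun > best_v:
                best_c, best_v = float(res.x), -res.fun
        beta[j] = best_c
    beta = _normalize(beta)
    return ComparatorResult(beta, f(beta), "stepdown", kind)


def reduce_min_max(g: np.ndarray) -> np.ndarray:
    """Subject-level reduction to (max over markers, min over markers)."""
    return np.column_stack([g.max(axis=1), g.min(axis=1)])


def min_max(data: OrderedBiomarkerData,
            kind: ObjectiveKind | str = ObjectiveKind.EHUM,
            n_angles: int = 3600) -> ComparatorResult:
    """Min-max combination: dense search over the unit circle of the
    reduced (max, min) score. The returned coefficients live in the
    reduced 2-marker space; ``reduction`` maps subjects into it."""
    if data.n_markers < 2:
        raise ValueError("min-max reduction requires at least two markers")
    kind = ObjectiveKind(kind)
    reduced = data.map_markers(reduce_min_max)
    f = make_objective(kind, reduced)
    angles = np.linspace(0.0, 2.0 * math.pi, n_angles, endpoint=False)
    best_beta, best_val = None, -np.inf
    for th in angles:
        b = np.array([math.cos(th), math.sin(th)])
        v = f(b)
        if v > best_val:
            best_val, best_beta = v, b
    return ComparatorResult(best_beta, best_val, "minmax", kind, reduction=reduce_min_max)


def _fit_scor(data, kind, config=None):
    res = scor_fit(data, kind, config)
    return ComparatorResult(res.beta, res.value, "scor", ObjectiveKind(kind))


METHODS = {
    "scor": _fit_scor,
    "nm": lambda data, kind, config=None: nm_maximize(data, kind),
    "stepdown": lambda data, kind, config=None: step_down(data, kind),
    "minmax": lambda data, kind, config=None: min_max(data, kind),
}


def fit(method, data: OrderedBiomarkerData,
        kind: ObjectiveKind | str = ObjectiveKind.EHUM,
        config: SCORConfig | None = None) -> ComparatorResult:
    """Fit a combination vector by name (or by a callable ``data -> beta``)."""
    if callable(method):
        beta = _normalize(np.asarray(method(data), dtype=float))
        f = make_objective(kind, data)
        return ComparatorResult(beta, f(beta), getattr(method, "__name__", "custom"),
                                ObjectiveKind(kind))
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(METHODS)}")
    return METHODS[method](data, kind, config)
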