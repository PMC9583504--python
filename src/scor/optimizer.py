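"""SCOR: derivative-free pattern search on the surface of the unit sphere.

The optimizer maximizes a black-box objective ``f(beta)`` subject to
``||beta|| = 1``. At each iteration, for every coordinate ``i`` and both
signs, the coordinate is perturbed by a step ``s`` and a scalar
*adjustment* ``t`` is added to the remaining (active) coordinates so the
candidate lands back on the sphere. With ``m`` active adjustment
coordinates, ``b = sum of active beta_k`` and ``z`` the squared norm of
coordinates zeroed by the sparsity threshold, ``t`` solves

    m t^2 + 2 b t + (2 s beta_i + s^2 - z) = 0,

and of the two real roots the one of smaller magnitude is chosen so the
move vanishes as ``s -> 0``. A negative discriminant means no on-sphere
move exists for that ``(i, s)``; the direction's local step is divided by
the decay rate ``rho`` until a real root appears or the step falls below
the threshold ``phi`` (such a step always exists for small enough ``|s|``
whenever the active-coordinate sum is nonzero).

The search is organized in *runs*: within a run the global step starts at
``s_initial`` and is divided by ``rho`` whenever the best candidate
improves the incumbent by less than ``tol_fun``; the run ends when the
step drops below ``phi``. Each run restarts the step at ``s_initial``
from the previous run's solution, and the chain stops when two
consecutive runs agree component-wise or when ``stall_runs`` consecutive
runs fail to improve the objective.

The objectives this package maximizes are piecewise constant, so flat
plateaus are the norm rather than the exception. When no candidate
strictly improves the incumbent but one ties it, the tying candidate is
adopted: drifting across a plateau relocates the exploration ladder and
is frequently what carries the search off a plateau onto a better one.
The incumbent objective value never decreases either way.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .data import OrderedBiomarkerData
from .objectives import ObjectiveKind, individual_ehum, make_objective

__all__ = [
    "SCORConfig",
    "IterationState",
    "OptimizationTrace",
    "SCORResult",
    "apply_sparsity",
    "adjustment_step",
    "candidate_set",
    "scor_iterate",
    "scor_run",
    "scor_maximize",
    "default_start",
    "sign_adjusted_start",
    "scor_fit",
]

logger = logging.getLogger(__name__)

_RUN_EQ_TOL = 1e-12  # component-wise agreement declaring two runs equal
_UNIT_TOL = 1e-8


@dataclass
class SCORConfig:
    """Tuning parameters of the spherical pattern search.

    s_initial : float
        Initial (and per-run reset) step size; large values promote
        distant exploratory moves early in a run.
    rho : float
        Step decay rate (> 1); divisor applied to the step whenever the
        iteration improves the objective by less than ``tol_fun``.
    phi : float
        Step-size threshold ending a run's iterations.
    tol_fun : float
        Minimum improvement that keeps the current step size.
    lam : float
        Sparsity threshold: coefficients (other than the perturbed one)
        with magnitude below ``lam`` are zeroed before the adjustment
        step is computed. 0 disables sparsification.
    max_iter, max_runs : int
        Caps on iterations per run and on runs.
    stall_runs : int
        Number of consecutive runs without objective improvement after
        which the run chain stops (plateau drift can move the solution
        point without improving the value, so value stagnation rather
        than solution equality is the robust stopping signal). Larger
        values buy extra plateau exploration at proportional cost.
    parallel : int
        Maximum concurrent candidate evaluations (candidate order, and
        hence tie-breaking, is independent of this setting).
    maximize : bool
        Orientation flag; ``False`` minimizes the objective instead.
    """

    s_initial: float = 2.0
    rho: float = 2.0
    phi: float = 1e-6
    tol_fun: float = 1e-6
    lam: float = 0.0
    max_iter: int = 50_000
    max_runs: int = 1_000
    stall_runs: int = 10
    parallel: int = 1
    maximize: bool = True

    def __post_init__(self):
        if not self.s_initial > self.phi > 0:
            raise ValueError("require s_initial > phi > 0")
        if self.rho <= 1:
            raise ValueError("step decay rate rho must exceed 1")
        if self.tol_fun < 0 or self.lam < 0:
            raise ValueError("tol_fun and lam must be non-negative")
        if self.max_iter < 1 or self.max_runs < 1 or self.stall_runs < 1:
            raise ValueError("max_iter, max_runs and stall_runs must be at least 1")

    @classmethod
    def from_file(cls, path) -> "SCORConfig":
        """Load a config from a YAML or JSON mapping of field names."""
        import json

        import yaml

        text = open(path).read()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls(**data)


@dataclass
class IterationState:
    """Mutable state of one pattern-search iteration."""

    beta: np.ndarray
    step: float
    value: float
    local_plus: np.ndarray = None
    local_minus: np.ndarray = None
    iteration: int = 0
    run: int = 0

    def __post_init__(self):
        d = self.beta.size
        if self.local_plus is None:
            self.local_plus = np.full(d, self.step)
        if self.local_minus is None:
            self.local_minus = np.full(d, -self.step)


@dataclass
class OptimizationTrace:
    """History of a :func:`scor_maximize` call."""

    run_solutions: list[np.ndarray] = field(default_factory=list)
    values: list[float] = field(default_factory=list)  # incumbent per iteration
    steps: list[float] = field(default_factory=list)
    n_evaluations: int = 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"iteration": range(len(self.values)),
                             "step_size": self.steps, "objective": self.values})


@dataclass
class SCORResult:
    beta: np.ndarray
    value: float
    trace: OptimizationTrace
    n_runs: int
    converged: bool


def _unit(beta: np.ndarray) -> np.ndarray:
    nrm = np.linalg.norm(beta)
    if nrm == 0:
        raise ValueError("zero vector cannot be normalized onto the sphere")
    return beta / nrm


def apply_sparsity(beta: np.ndarray, i: int, lam: float) -> tuple[np.ndarray, np.ndarray]:
    """Zero small coordinates (except ``i``) and return (active mask, vector).

    The active mask marks the coordinates that receive the adjustment
    step: everything except ``i`` and the zeroed coordinates.
    """
    beta = np.asarray(beta, dtype=float)
    zeroed = np.abs(beta) < lam
    zeroed[i] = False
    out = np.where(zeroed, 0.0, beta)
    active = ~zeroed
    active[i] = False
    return active, out


def adjustment_step(beta: np.ndarray, i: int, s: float,
                    active: np.ndarray | None = None) -> float | None:
    """Adjustment ``t`` restoring unit norm after ``beta_i += s``.

    Solves ``m t^2 + 2 b t + (2 s beta_i + s^2 - z) = 0`` over the active
    coordinates and returns the real root of smaller magnitude (the one
    vanishing as ``s -> 0``), or ``None`` when the discriminant is
    negative ("no real root" is a normal outcome, not an error).
    """
    beta = np.asarray(beta, dtype=float)
    d = beta.size
    if active is None:
        active = np.ones(d, dtype=bool)
        active[i] = False
    m = int(active.sum())
    zero_mask = ~active
    zero_mask[i] = False
    z = float(np.sum(beta[zero_mask] ** 2))
    c = 2.0 * s * beta[i] + s * s - z
    if m == 0:
        # nothing to adjust: the move is valid only if it happens to stay
        # on the sphere by itself
        return 0.0 if abs(c) <= 1e-12 else None
    b = float(beta[active].sum())
    disc = b * b - m * c
    if disc < 0:
        return None
    root = math.sqrt(disc)
    t1 = (-b + root) / m
    t2 = (-b - root) / m
    return t1 if abs(t1) <= abs(t2) else t2


def _make_candidate(beta: np.ndarray, i: int, s: float, lam: float) -> np.ndarray | None:
    active, base = apply_sparsity(beta, i, lam)
    t = adjustment_step(beta, i, s, active)
    if t is None:
        return None
    cand = base.copy()
    cand[i] += s
    cand[active] += t
    # the quadratic restores the norm analytically; renormalize to keep
    # the unit invariant exact against accumulated rounding
    return _unit(cand)


def candidate_set(state: IterationState, config: SCORConfig) -> list[tuple[int, int, np.ndarray]]:
    """Up to ``2d`` on-sphere candidates for the current iteration.

    For each coordinate ``i`` the ``(i, +)`` move uses the local step
    ``s_i^+`` and ``(i, -)`` uses ``s_i^-``; a local step is divided by
    ``rho`` until a real adjustment root exists and the direction is
    dropped for this iteration once its magnitude falls below ``phi``.
    Returned in deterministic order: ascending ``i``, "+" before "-".
    """
    beta = state.beta
    d = beta.size
    out = []
    for i in range(d):
        for sign, local in ((+1, state.local_plus), (-1, state.local_minus)):
            s = float(local[i])
            cand = None
            while abs(s) >= config.phi:
                cand = _make_candidate(beta, i, s, config.lam)
                if cand is not None:
                    break
                s /= config.rho
            local[i] = s
            if cand is not None and abs(s) >= config.phi:
                out.append((i, sign, cand))
    return out


def _evaluate_candidates(cands: Sequence[np.ndarray], f: Callable, parallel: int) -> list[float]:
    if parallel > 1 and len(cands) > 1:
        from joblib import Parallel, delayed

        return Parallel(n_jobs=parallel, backend="threading")(delayed(f)(c) for c in cands)
    return [f(c) for c in cands]


def scor_iterate(state: IterationState, f: Callable[[np.ndarray], float],
                 config: SCORConfig, trace: OptimizationTrace | None = None) -> IterationState:
    """One pattern-search iteration: propose, evaluate, adopt, decay.

    The best of {current solution, candidates} becomes the new solution
    (candidate ties broken by lowest coordinate index, "+" before "-").
    A candidate that merely *ties* the incumbent is adopted as well:
    the objectives are piecewise constant and drifting along a plateau
    repositions the exploration ladder (the objective value itself never
    decreases). If the improvement is below ``tol_fun`` the global step
    is divided by ``rho``.
    """
    cands = candidate_set(state, config)
    values = _evaluate_candidates([c for _, _, c in cands], f, config.parallel)
    if trace is not None:
        trace.n_evaluations += len(values)
    best_val = state.value
    best_beta = state.beta
    moved = False
    for (i, sign, cand), val in zip(cands, values):
        if val > best_val:  # first strict improver at the running max wins
            best_val, best_beta, moved = val, cand, True
        elif not moved and val == state.value and best_val == state.value:
            best_beta, moved = cand, True  # plateau drift
    improvement = best_val - state.value
    state.beta = best_beta
    state.value = best_val
    if improvement < config.tol_fun:
        state.step /= config.rho
    state.iteration += 1
    state.local_plus = np.full(state.beta.size, state.step)
    state.local_minus = np.full(state.beta.size, -state.step)
    if trace is not None:
        trace.values.append(state.value)
        trace.steps.append(state.step)
    return state


def scor_run(start: np.ndarray, f: Callable[[np.ndarray], float], config: SCORConfig,
             trace: OptimizationTrace | None = None, run_index: int = 0) -> tuple[np.ndarray, float]:
    """One run: iterate from ``s_initial`` until ``step < phi`` or ``max_iter``."""
    beta = _unit(np.asarray(start, dtype=float))
    if beta.size == 1:
        # degenerate sphere {+1, -1}
        vals = _evaluate_candidates([np.array([1.0]), np.array([-1.0])], f, 1)
        if trace is not None:
            trace.n_evaluations += 2
        return (np.array([1.0]), vals[0]) if vals[0] >= vals[1] else (np.array([-1.0]), vals[1])
    value = f(beta)
    if trace is not None:
        trace.n_evaluations += 1
    state = IterationState(beta=beta, step=config.s_initial, value=value, run=run_index)
    while state.step >= config.phi and state.iteration < config.max_iter:
        state = scor_iterate(state, f, config, trace)
    return state.beta, state.value


def scor_maximize(objective: Callable[[np.ndarray], float], start,
                  config: SCORConfig | None = None) -> SCORResult:
    """Global spherical pattern search chaining runs until stabilization.

    Each run is seeded by the previous run's solution; the search stops
    when two consecutive runs return the same point (component-wise
    within 1e-12), when ``stall_runs`` consecutive runs fail to improve
    the objective (plateau drift can relocate the solution indefinitely
    at constant value), or after ``max_runs`` runs. ``start`` is
    normalized on entry (with a logged warning if it was off the sphere).
    """
    config = config or SCORConfig()
    f = objective if config.maximize else (lambda b: -objective(b))
    beta = np.asarray(start, dtype=float).copy()
    if abs(np.linalg.norm(beta) - 1.0) > _UNIT_TOL:
        logger.warning("start point has norm %.6g; normalizing onto the unit sphere",
                       np.linalg.norm(beta))
    beta = _unit(beta)
    trace = OptimizationTrace()
    converged = False
    n_runs = 0
    prev = None
    best_val = None
    stall = 0
    for run_index in range(config.max_runs):
        beta, val = scor_run(beta, f, config, trace, run_index)
        trace.run_solutions.append(beta.copy())
        n_runs += 1
        if prev is not None and np.max(np.abs(beta - prev)) <= _RUN_EQ_TOL:
            converged = True
            break
        if best_val is not None and val <= best_val:
            stall += 1
            if stall >= config.stall_runs:
                converged = True
                break
        else:
            stall = 0
        best_val = val
        prev = beta
    value = val if config.maximize else -val
    return SCORResult(beta=beta, value=value, trace=trace, n_runs=n_runs, converged=converged)


def default_start(data: OrderedBiomarkerData) -> np.ndarray:
    """Neutral equal-weight start ``(1, ..., 1) / sqrt(d)``.

    A deliberately uninformative on-sphere point: informative starts
    (e.g. :func:`sign_adjusted_start`) can sit so close to the truth on
    well-behaved data that the fitted vector inherits the start rather
    than the data, which distorts resampling studies of the estimator.
    """
    d = data.n_markers
    return np.full(d, 1.0 / math.sqrt(d))


def sign_adjusted_start(data: OrderedBiomarkerData) -> np.ndarray:
    """Equal-magnitude start with each sign set to the orientation that
    maximizes the marker's individual EHUM — an informative alternative
    start for hard or high-dimensional problems."""
    d = data.n_markers
    signs = np.array([individual_ehum(data, k)[0] for k in range(1, d + 1)], dtype=float)
    return signs / math.sqrt(d)


def scor_fit(data: OrderedBiomarkerData, kind: ObjectiveKind | str = ObjectiveKind.EHUM,
             config: SCORConfig | None = None, start=None) -> SCORResult:
    """Fit the optimal unit-norm marker combination on ordered data."""
    f = make_objective(kind, data)
    if start is None:
        start = default_start(data)
    return scor_maximize(f, start, config)
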