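"""Scenario generators and the train/test replication harness.

Three synthetic designs emulate common biomarker configurations with
``M`` ordered disease categories (class index ``i = 0..M-1``, marker
index ``j = 1..d``):

* Scenario 1 — independent d-variate normals, class means
  ``mu_ij = (-1)^j * i * (1 + 0.1 (j - 1))``, identity covariance. The
  alternating signs make single markers individually weak while the
  full combination separates classes well.
* Scenario 2 — same means with AR(0.5) covariance
  ``a_st = 0.5 ** |s - t|`` (correlated predictors).
* Scenario 3 — independent three-parameter Weibull margins: marker ``j``
  in class ``i`` is ``gamma_j + lambda_i * W`` with ``W`` standard
  Weibull of shape ``k_j``; ``lambda_i = i + 1``, ``k_j = 0.5 j``,
  ``gamma_j = (-5)**j`` (skewed, heavy-tailed, wildly different marker
  locations — classes differ only through scale).

The replication harness mirrors a train/test design: per replication a
training set is simulated, a combination vector fitted by the chosen
method/objective, an independent test set of the same design simulated,
and the test-set EHUM at the fitted vector recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .comparators import fit
from .data import OrderedBiomarkerData
from .objectives import ObjectiveKind, ehum
from .optimizer import SCORConfig

__all__ = ["ScenarioSpec", "ExperimentResult", "generate", "run_experiment",
           "coefficient_mse", "scenario_means"]


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the simulation design."""

    scenario: int                 # 1, 2 or 3
    d: int                        # number of markers
    M: int = 2                    # number of ordered categories
    n_per_class: tuple[int, ...] | int = 15

    def __post_init__(self):
        if self.scenario not in (1, 2, 3):
            raise ValueError("scenario must be 1, 2 or 3")
        if self.d < 1 or self.M < 2:
            raise ValueError("require d >= 1 and M >= 2")
        n = self.n_per_class
        if isinstance(n, int):
            n = (n,) * self.M
        n = tuple(int(v) for v in n)
        if len(n) != self.M or any(v < 1 for v in n):
            raise ValueError("need one positive sample size per class")
        object.__setattr__(self, "n_per_class", n)


def scenario_means(d: int, M: int) -> np.ndarray:
    """Class means of Scenarios 1-2: ``mu_ij = (-1)^j i (1 + 0.1(j-1))``."""
    j = np.arange(1, d + 1)
    base = (-1.0) ** j * (1.0 + 0.1 * (j - 1))
    return np.arange(M)[:, None] * base[None, :]


def _ar_cholesky(d: int, rho: float = 0.5) -> np.ndarray:
    idx = np.arange(d)
    cov = rho ** np.abs(idx[:, None] - idx[None, :])
    return np.linalg.cholesky(cov)


def generate(spec: ScenarioSpec, rng: np.random.Generator) -> OrderedBiomarkerData:
    """Draw one dataset under the scenario's design."""
    d, M = spec.d, spec.M
    groups = []
    if spec.scenario in (1, 2):
        means = scenario_means(d, M)
        chol = _ar_cholesky(d) if spec.scenario == 2 else None
        for i in range(M):
            z = rng.standard_normal((spec.n_per_class[i], d))
            if chol is not None:
                z = z @ chol.T
            groups.append(z + means[i])
    else:
        j = np.arange(1, d + 1)
        shape = 0.5 * j                      # k_j
        loc = (-5.0) ** j                    # gamma_j
        for i in range(M):
            scale = i + 1.0                  # lambda_i
            w = rng.weibull(shape, size=(spec.n_per_class[i], d))
            groups.append(loc + scale * w)
    return OrderedBiomarkerData(tuple(groups))


@dataclass
class ExperimentResult:
    """Per-replication test-set EHUM values and their summary."""

    test_ehum: np.ndarray
    method: str
    objective_kind: ObjectiveKind
    spec: ScenarioSpec
    betas: list[np.ndarray] = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(np.mean(self.test_ehum))

    @property
    def sd(self) -> float:
        """Standard deviation across replications."""
        return float(np.std(self.test_ehum, ddof=1)) if self.test_ehum.size > 1 else 0.0

    @property
    def se(self) -> float:
        """Standard error of the replication mean (sd / sqrt(reps))."""
        return self.sd / np.sqrt(self.test_ehum.size)

    def summary(self) -> dict:
        return {"scenario": self.spec.scenario, "d": self.spec.d, "M": self.spec.M,
                "n_per_class": list(self.spec.n_per_class), "method": self.method,
                "objective": str(self.objective_kind.value), "reps": int(self.test_ehum.size),
                "mean_test_ehum": self.mean, "sd": self.sd, "se": self.se}


def run_experiment(spec: ScenarioSpec, method,
                   objective_kind: ObjectiveKind | str = ObjectiveKind.EHUM,
                   reps: int = 100,
                   rng: np.random.Generator | int | None = None,
                   config: SCORConfig | None = None) -> ExperimentResult:
    """Train/test replication experiment for one design cell.

    Per replication: simulate training data, fit the combination vector
    by ``method`` maximizing ``objective_kind`` on it, simulate an
    independent test set of identical design, and record the test-set
    EHUM at the fitted vector. Bit-identical under a fixed seed.
    """
    if reps < 1:
        raise ValueError("reps must be at least 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    kind = ObjectiveKind(objective_kind)
    values = np.empty(reps)
    betas = []
    for r in range(reps):
        train = generate(spec, rng)
        result = fit(method, train, kind, config)
        test = generate(spec, rng)
        if result.reduction is not None:
            test_eval = test.map_markers(result.reduction)
        else:
            test_eval = test
        values[r] = ehum(result.beta, test_eval)
        betas.append(result.beta)
    name = result.method
    return ExperimentResult(values, name, kind, spec, betas)


def coefficient_mse(estimates: Sequence[np.ndarray], truth: np.ndarray) -> float:
    """Mean squared Euclidean error of unit-vector estimates.

    ``beta`` and ``-beta`` define the same direction up to orientation,
    so each estimate is flipped into the truth's halfspace before the
    squared distance is taken.
    """
    truth = np.asarray(truth, dtype=float)
    errs = []
    for est in estimates:
        est = np.asarray(est, dtype=float)
        if est.shape != truth.shape:
            raise ValueError("estimate and truth dimensions differ")
        if est @ truth < 0:
            est = -est
        errs.append(float(np.sum((est - truth) ** 2)))
    return float(np.mean(errs))
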