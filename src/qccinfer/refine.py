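"""Continuous angle refinement over a fixed entangling topology.

After the discrete search fixes the gate set and order, every CRX(pi/2)
gate is promoted to CRX(theta_i) and the angle vector is optimized with a
gradient-free local method, starting from theta = 0 as the model's
interaction-free reference point.

A subtlety of CRX circuits on real amplitude encodings: each outcome
probability is an even function of every angle around zero (amplitudes mix
as cos^2/sin^2 with no interference term for real states), so theta = 0 is
an exact stationary point of the cost. A trust-region method with a finite
initial step (COBYLA) escapes it reliably and is the default; the bounded
quasi-Newton path (L-BFGS-B with numerical differences) is kept for smooth
refinement away from zero and benefits from the optional seeded jitter.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import pi

import numpy as np
from scipy.optimize import minimize

from .quantum_core import Topology, cost
from .state import ProbDist, StateVector

ANGLE_BOUND = 2 * pi  # outcome probabilities are periodic in theta


@dataclass
class RefinementResult:
    topology: Topology  # with optimized angles
    kl_before: float  # cost at theta = 0 (interaction-free circuit)
    kl_after: float
    optimizer: str
    n_evals: int
    converged: bool


def optimize_angles(topology: Topology, initial: StateVector,
                    q_ct1: ProbDist, q_ct2: ProbDist,
                    optimizer: str = "cobyla", seed: int | None = None,
                    jitter: float = 0.0, maxiter: int = 500) -> RefinementResult:
    """Locally minimize the marginal-KL cost over gate angles in [-2pi, 2pi].

    ``jitter`` > 0 perturbs the zero initialization by seeded Gaussian noise
    of that scale (off by default); useful to nudge the quasi-Newton path
    off the theta = 0 stationary point.
    """
    k = len(topology)
    if k == 0:
        c0 = cost(topology, initial, q_ct1, q_ct2).total
        return RefinementResult(Topology([]), c0, c0, optimizer, 0, True)

    n_evals = 0
    bad_evals = 0

    def objective(theta: np.ndarray) -> float:
        nonlocal n_evals, bad_evals
        n_evals += 1
        v = cost(topology.with_angles(theta), initial, q_ct1, q_ct2).total
        if not np.isfinite(v):
            bad_evals += 1
            return 1e6  # bounded penalty; smoothed KL is finite in practice
        return v

    theta0 = np.zeros(k)
    if jitter > 0:
        theta0 = theta0 + np.random.default_rng(seed).normal(0.0, jitter, k)
    kl_before = objective(np.zeros(k))
    bounds = [(-ANGLE_BOUND, ANGLE_BOUND)] * k

    if optimizer == "cobyla":
        res = minimize(objective, theta0, method="COBYLA", bounds=bounds, tol=1e-10,
                       options={"rhobeg": 1.0, "maxiter": max(maxiter, 200) * 10})
    elif optimizer == "lbfgsb_numeric":
        res = minimize(objective, theta0, method="L-BFGS-B", bounds=bounds,
                       options={"eps": 1e-6, "ftol": 1e-12, "maxiter": maxiter})
    else:
        raise ValueError(f"unknown optimizer {optimizer!r}")
    if bad_evals:
        # retry once from the best point found, per the bounded-retry contract
        res2 = minimize(objective, np.clip(res.x, -ANGLE_BOUND, ANGLE_BOUND),
                        method="COBYLA", bounds=bounds, tol=1e-10,
                        options={"rhobeg": 0.1, "maxiter": maxiter})
        if bad_evals > n_evals // 2:
            raise RuntimeError("non-finite cost persisted during angle refinement")
        res = res2 if res2.fun < res.fun else res
    theta_opt = np.clip(res.x, -ANGLE_BOUND, ANGLE_BOUND)
    kl_after = objective(theta_opt)
    return RefinementResult(topology.with_angles(theta_opt), kl_before,
                            kl_after, optimizer, n_evals, bool(res.success))
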