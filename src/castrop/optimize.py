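"""Formula-constant optimization by projected Levenberg-Marquardt.

Constants are optimised *en bloc* by minimising the root-mean-squared
refraction prediction error rmsPE = sqrt(mean(PE^2)) on a training set,
where PE = SE - predSE is the achieved minus the formula-predicted
spherical equivalent.  The solver is a damped Gauss-Newton iteration on the
per-case residual vector (sum of squares = N * rmsPE^2, so minimising the
SSE and the rmsPE are equivalent), with

* forward finite-difference Jacobian (step 1e-6 per constant),
* Marquardt diagonal damping, initial lambda 1e-2, x10 on rejection and
  /10 on acceptance,
* box constraints enforced by clipping trial steps to the bounds
  (plain LM is unconstrained; the constant boxes, e.g. C in [0.35, 0.45],
  require the projected variant),
* termination when the accepted step falls below 1e-14, when the rmsPE
  improvement falls below 1e-16, or after 100 iterations.

The per-iteration SSE trajectory is recorded and is non-increasing by
construction (only improving steps are accepted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "prediction_error",
    "rms_pe",
    "sum_squared_error",
    "LMConfig",
    "OptimizationResult",
    "levenberg_marquardt",
    "optimize_constants",
]


def prediction_error(se, pred_se):
    """Refraction prediction error PE = SE - predSE (dpt), achieved minus
    formula-predicted spherical equivalent."""
    return np.asarray(se, dtype=float) - np.asarray(pred_se, dtype=float)


def sum_squared_error(residuals) -> float:
    r = np.asarray(residuals, dtype=float)
    if r.size == 0:
        raise ValueError("empty residual vector")
    return float(r @ r)


def rms_pe(residuals) -> float:
    """Root-mean-squared prediction error sqrt(mean(PE^2)) in dioptres."""
    r = np.asarray(residuals, dtype=float)
    if r.size == 0:
        raise ValueError("empty residual vector")
    return float(np.sqrt(np.mean(r**2)))


@dataclass
class LMConfig:
    """Levenberg-Marquardt settings.

    ``init`` must lie inside the (ordered) box; ``damping`` is the initial
    lambda; ``step_tol`` terminates on small accepted steps, ``ftol`` on
    small rmsPE improvement.
    """

    init: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    max_iter: int = 100
    damping: float = 1e-2
    step_tol: float = 1e-14
    ftol: float = 1e-16
    fd_step: float = 1e-6
    lambda_factor: float = 10.0

    def __post_init__(self):
        self.init = np.atleast_1d(np.asarray(self.init, dtype=float))
        self.lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
        self.upper = np.atleast_1d(np.asarray(self.upper, dtype=float))
        if np.any(self.lower > self.upper):
            raise ValueError("lower bounds exceed upper bounds")
        if np.any(self.init < self.lower) or np.any(self.init > self.upper):
            raise ValueError("initial constants outside bounds")
        if min(self.step_tol, self.ftol, self.fd_step, self.damping) <= 0:
            raise ValueError("tolerances and damping must be positive")


@dataclass
class OptimizationResult:
    """Outcome of a constant optimization run."""

    constants: np.ndarray
    iterations: int
    sse_trajectory: list[float] = field(default_factory=list)
    converged_by: str = "max_iter"  # step | ftol | max_iter

    @property
    def sse(self) -> float:
        return self.sse_trajectory[-1]

    @property
    def rms_pe(self) -> float:
        return float(np.sqrt(self.sse / self._n))

    _n: int = 1


def _finite_residuals(fn, theta):
    r = np.asarray(fn(theta), dtype=float)
    bad = ~np.isfinite(r)
    if np.any(bad):
        idx = int(np.flatnonzero(bad)[0])
        raise FloatingPointError(
            f"non-finite residual for record {idx} at constants {theta!r}"
        )
    return r


def _jacobian(fn, theta, r0, step, lower, upper):
    J = np.empty((r0.size, theta.size))
    for j in range(theta.size):
        t = theta.copy()
        h = step
        if t[j] + h > upper[j]:  # step inward at the upper bound
            h = -step
        t[j] += h
        J[:, j] = (_finite_residuals(fn, t) - r0) / h
    return J


def levenberg_marquardt(residual_fn, config: LMConfig) -> OptimizationResult:
    """Minimise ||residual_fn(theta)||^2 over a box by projected LM.

    ``residual_fn`` maps a constant vector to the per-case PE vector.
    Deterministic: identical inputs yield identical results.
    """
    theta = np.clip(config.init.copy(), config.lower, config.upper)
    r = _finite_residuals(residual_fn, theta)
    n = r.size
    sse = float(r @ r)
    lam = config.damping
    trajectory = [sse]
    converged_by = "max_iter"
    iterations = 0

    for _ in range(config.max_iter):
        J = _jacobian(residual_fn, theta, r, config.fd_step, config.lower, config.upper)
        A = J.T @ J
        g = J.T @ r
        diag = np.maximum(np.diag(A), 1e-12)

        accepted = False
        while lam < 1e15:
            try:
                step = np.linalg.solve(A + lam * np.diag(diag), -g)
            except np.linalg.LinAlgError:
                lam *= config.lambda_factor
                continue
            trial = np.clip(theta + step, config.lower, config.upper)
            r_trial = _finite_residuals(residual_fn, trial)
            sse_trial = float(r_trial @ r_trial)
            if sse_trial < sse:
                accepted = True
                lam = max(lam / config.lambda_factor, 1e-15)
                break
            lam *= config.lambda_factor

        if not accepted:
            # No improving step exists at any damping: (constrained) minimum.
            converged_by = "ftol"
            break

        iterations += 1
        step_size = float(np.linalg.norm(trial - theta))
        improvement = np.sqrt(sse / n) - np.sqrt(sse_trial / n)
        theta, r, sse = trial, r_trial, sse_trial
        trajectory.append(sse)
        if step_size < config.step_tol:
            converged_by = "step"
            break
        if improvement < config.ftol:
            converged_by = "ftol"
            break

    result = OptimizationResult(
        constants=theta,
        iterations=iterations,
        sse_trajectory=trajectory,
        converged_by=converged_by,
    )
    result._n = n
    return result


def optimize_constants(X, y, formula, config: LMConfig | None = None):
    """Fit a formula's constants on a training set; returns the result.

    Thin functional wrapper over the estimator interface: clones nothing,
    fits ``formula`` in place and returns its ``optimization_result_``.
    """
    from .formulas import make_formula

    if isinstance(formula, str):
        formula = make_formula(formula)
    formula.fit(X, y, config=config)
    return formula.optimization_result_
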