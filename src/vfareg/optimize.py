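"""Quasi-Newton (BFGS) minimization with Armijo backtracking line search.

A small, dependency-free implementation tailored to the 6-parameter rigid
registration objective: inverse-Hessian BFGS updates, backtracking from a
unit step along the quasi-Newton direction, monotone accepted-step sequence,
and best-visited-point tracking (line-search probes included).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import NonFiniteObjectiveError

__all__ = ["MinimizeResult", "quasi_newton_minimize"]


@dataclass
class MinimizeResult:
    x: np.ndarray
    fun: float
    n_iterations: int
    converged: bool
    trace: list = field(default_factory=list)  # accepted objective values, incl. f(x0)
    n_evaluations: int = 0


def quasi_newton_minimize(objective, jacobian, x0, *,
                          max_iterations: int = 500,
                          gradient_tolerance: float = 1e-6,
                          function_tolerance: float = 1e-9,
                          shrink: float = 0.5,
                          armijo_c: float = 1e-4,
                          max_halvings: int = 30) -> MinimizeResult:
    """Minimize ``objective`` from ``x0`` with BFGS + Armijo backtracking.

    The accepted-step objective sequence is non-increasing by construction of
    the Armijo condition.  The returned point is the best point *visited*,
    which with a monotone line search is the last accepted point.  Terminates
    when the gradient inf-norm falls below ``gradient_tolerance``, the
    accepted function decrease falls below ``function_tolerance``, or
    ``max_iterations`` is reached (then ``converged=False``).

    Raises :class:`NonFiniteObjectiveError` if the objective or jacobian
    produces NaN/Inf at a visited point.
    """
    x = np.asarray(x0, dtype=float).copy()
    n = x.size
    evals = 0

    best_f = np.inf
    best_x = x.copy()

    def f(z):
        nonlocal evals, best_f, best_x
        evals += 1
        val = float(objective(z))
        if not np.isfinite(val):
            raise NonFiniteObjectiveError(f"objective returned {val} at {z}")
        if val < best_f:
            best_f = val
            best_x = np.asarray(z, float).copy()
        return val

    def g(z):
        grad = np.asarray(jacobian(z), dtype=float)
        if not np.isfinite(grad).all():
            raise NonFiniteObjectiveError(f"jacobian returned non-finite values at {z}")
        return grad

    fx = f(x)
    gx = g(x)
    trace = [fx]
    hinv = np.eye(n)
    first_update = True
    converged = False
    it = 0

    for it in range(1, max_iterations + 1):
        if np.linalg.norm(gx, ord=np.inf) < gradient_tolerance:
            converged = True
            break

        direction = -hinv @ gx
        slope = float(direction @ gx)
        if slope >= 0:  # not a descent direction: reset to steepest descent
            hinv = np.eye(n)
            first_update = True
            direction = -gx
            slope = float(direction @ gx)
            if slope >= 0:  # zero gradient
                converged = True
                break

        # Armijo backtracking from unit step
        alpha = 1.0
        accepted = False
        for _ in range(max_halvings + 1):
            x_new = x + alpha * direction
            f_new = f(x_new)
            if f_new <= fx + armijo_c * alpha * slope:
                accepted = True
                break
            alpha *= shrink

        if not accepted:
            if np.allclose(hinv, np.eye(n)):
                break  # steepest descent failed too: stop at current point
            hinv = np.eye(n)  # retry this iterate with a fresh Hessian
            first_update = True
            continue

        g_new = g(x_new)
        s = x_new - x
        y = g_new - gx
        sy = float(s @ y)
        if sy > 1e-20 * max(1.0, float(np.linalg.norm(s)) * float(np.linalg.norm(y))):
            if first_update:
                hinv *= sy / float(y @ y)
                first_update = False
            rho = 1.0 / sy
            i_mat = np.eye(n)
            v = i_mat - rho * np.outer(s, y)
            hinv = v @ hinv @ v.T + rho * np.outer(s, s)

        decrease = fx - f_new
        x, fx, gx = x_new, f_new, g_new
        trace.append(fx)
        if decrease < function_tolerance:
            converged = True
            break

    # a line-search probe may have improved on the last accepted point without
    # satisfying the Armijo decrease; honor the best-visited contract
    if best_f < fx:
        x, fx = best_x, best_f
        trace.append(fx)

    return MinimizeResult(x=x, fun=fx, n_iterations=it, converged=converged,
                          trace=trace, n_evaluations=evals)
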