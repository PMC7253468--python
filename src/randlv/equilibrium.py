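"""Equilibria of the Lotka-Volterra community model and mean-field formulas.

Setting the time derivatives of ``dN_i/dt = N_i (r_i + sum_j a_ij N_j)`` to
zero gives the interior equilibrium as the solution of the linear system
``A N* = -r``.  The equilibrium is *feasible* when every ``N_i* > 0``, the
basic requirement for a viable community.

The deterministic 'uniform model' (every interacting pair at strength ``m``)
admits the closed form ``N* = 1 / [1 - (n-1) m C P]``, which blows up at
``m = 1/(n-1)`` for ``C = P = 1``.  For Chen-Cohen communities the effective
mean strength of a mutualistic entry is the half-normal mean
``sigma * sqrt(2/pi)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np

from .errors import BlowupError, ParameterError
from .matrix_gen import GenParams, InteractionMatrix, generate_chen_cohen

__all__ = [
    "EquilibriumState",
    "solve_equilibrium",
    "mean_field_nstar",
    "blowup_bound",
    "may_condition",
    "MayCondition",
    "feasibility_probability",
    "FeasibilityEstimate",
    "effective_mean_strength",
    "HALF_NORMAL_MEAN",
]

#: Mean of |N(0,1)|; a half-normal magnitude with scale sigma has mean
#: sigma * HALF_NORMAL_MEAN.
HALF_NORMAL_MEAN = math.sqrt(2.0 / math.pi)

# Condition numbers above COND_WARN trigger a warning; above COND_SINGULAR the
# solve is treated as having no unique equilibrium.
COND_WARN = 1e12
COND_SINGULAR = 1e15


def effective_mean_strength(sigma: float) -> float:
    """Mean strength E(a_ij) of a half-normal mutualistic entry of scale sigma."""
    return sigma * HALF_NORMAL_MEAN


@dataclass
class EquilibriumState:
    """Interior equilibrium of a Lotka-Volterra community.

    Attributes
    ----------
    Nstar : ndarray
        Equilibrium densities solving ``A N* = -r``.
    r : ndarray
        Growth-rate vector used (default all +1).
    feasible : bool
        True iff every density is strictly positive.
    Nmin, Nmean : float
        Minimum and mean of ``Nstar``.
    residual : float
        Infinity norm of ``A N* + r``.
    cond : float
        2-norm condition number of ``A``.
    """

    Nstar: np.ndarray
    r: np.ndarray
    feasible: bool
    Nmin: float
    Nmean: float
    residual: float
    cond: float


def _as_matrix(A) -> np.ndarray:
    if isinstance(A, InteractionMatrix):
        return A.A
    return np.asarray(A, dtype=float)


def solve_equilibrium(A, r=None) -> EquilibriumState:
    """Solve ``A N* = -r`` and flag feasibility.

    Parameters
    ----------
    A : InteractionMatrix or ndarray
        Square interaction matrix.
    r : ndarray, optional
        Growth rates; defaults to all ones (the standard scaling r_i = +1).

    Raises
    ------
    BlowupError
        If ``A`` is singular or numerically so ill-conditioned (cond > 1e15)
        that no unique equilibrium exists.
    """
    A = _as_matrix(A)
    n = A.shape[0]
    if A.ndim != 2 or A.shape[1] != n:
        raise ParameterError(f"A must be square, got shape {A.shape}")
    r = np.ones(n) if r is None else np.asarray(r, dtype=float)
    if r.shape != (n,):
        raise ParameterError(f"r must have length {n}, got shape {r.shape}")

    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > COND_SINGULAR:
        raise BlowupError(
            f"blow-up / no unique equilibrium: condition number {cond:.3g}"
        )
    if cond > COND_WARN:
        warnings.warn(
            f"interaction matrix is ill-conditioned (cond = {cond:.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
    try:
        Nstar = np.linalg.solve(A, -r)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - caught by cond
        raise BlowupError("blow-up / no unique equilibrium: singular matrix") from exc

    residual = float(np.max(np.abs(A @ Nstar + r)))
    return EquilibriumState(
        Nstar=Nstar,
        r=r,
        feasible=bool(np.all(Nstar > 0)),
        Nmin=float(Nstar.min()),
        Nmean=float(Nstar.mean()),
        residual=residual,
        cond=float(cond),
    )


def mean_field_nstar(n: int, m: float, C: float = 1.0, P: float = 1.0) -> float:
    """Mean-field equilibrium density ``1 / [1 - (n-1) m C P]``.

    For ``C = P = 1`` this is the regular-model value ``1 / [1 - (n-1) m]``.

    Raises
    ------
    BlowupError
        If ``(n-1) m C P >= 1`` (feasibility lost; densities diverge).
    """
    if n < 2:
        raise ParameterError(f"n must be >= 2, got {n}")
    x = (n - 1) * m * C * P
    if x >= 1.0:
        raise BlowupError(
            f"mean-field blow-up: (n-1)*m*C*P = {x:.6g} >= 1 (feasibility lost)"
        )
    return 1.0 / (1.0 - x)


def blowup_bound(n: int) -> float:
    """Largest uniform mutualistic strength compatible with feasibility, 1/(n-1)."""
    if n < 2:
        raise ParameterError(f"n must be >= 2, got {n}")
    return 1.0 / (n - 1)


class MayCondition(NamedTuple):
    value: float
    satisfied: bool


def may_condition(n: int, sigma: float, m: float = 0.0) -> MayCondition:
    """Evaluate May's complexity-stability ratio ``n sigma^2 / (1+m)^2``.

    Returns the ratio and whether it is below one (the classical stability
    condition for large random communities, which here also tracks the
    feasibility constraint for n below ~100).
    """
    if sigma < 0:
        raise ParameterError(f"sigma must be >= 0, got {sigma}")
    if m == -1:
        raise ParameterError("m = -1 makes the May ratio undefined (division by zero)")
    value = n * sigma**2 / (1.0 + m) ** 2
    return MayCondition(value=float(value), satisfied=bool(value < 1.0))


class FeasibilityEstimate(NamedTuple):
    probability: float
    std_error: float
    n_feasible: int
    reps: int


def feasibility_probability(
    params: GenParams, reps: int, seed: int | None = None
) -> FeasibilityEstimate:
    """Monte-Carlo estimate of the probability that a random draw is feasible.

    Generates ``reps`` independent Chen-Cohen matrices (child seeds spawned
    from ``seed``, default ``params.seed``) and reports the fraction whose
    equilibrium is feasible, with its binomial standard error.  Draws whose
    matrix is singular count as infeasible.
    """
    if reps < 1:
        raise ParameterError(f"reps must be >= 1, got {reps}")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n_feasible = 0
    for _ in range(reps):
        child = int(rng.integers(0, 2**31 - 1))
        im = generate_chen_cohen(replace(params, seed=child))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                eq = solve_equilibrium(im)
        except BlowupError:
            continue
        n_feasible += int(eq.feasible)
    p = n_feasible / reps
    se = math.sqrt(p * (1.0 - p) / reps)
    return FeasibilityEstimate(probability=p, std_error=se, n_feasible=n_feasible, reps=reps)
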