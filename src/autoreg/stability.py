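"""Linear stability of the unique steady state.

At a steady state (m*, p*) the Jacobian of the dimensionless system is

    J = [ -eta3                        -2*(eta1/eta2)*p/(1+p^2/eta2)^2 ]
        [ (eta4+p^2)/(1+p^2)          -Q(p)/((eta4+p^2)*(1+p^2))       ]

with quartic Q(p) = p^4 + p^2*(3*eta4-1) + eta4 — the same quartic whose
roots are the p-nullcline turning points. The determinant is positive at
the unique steady state, so instability is governed entirely by the trace:
tr(J) > 0 exactly when p* lies in an open interval (p_c-, p_c+) that exists
only for sufficiently small eta3 and eta4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import turning_points
from .params import DimensionlessParams
from .steady_state import NonUniqueSteadyStateError, SteadyState, steady_state

__all__ = [
    "StabilityReport",
    "jacobian_at",
    "trace_det",
    "instability_interval",
    "necessary_condition_eta3",
    "eta1_band",
    "dimensional_region",
    "classify",
]

_MARGINAL_TOL = 1e-12


def _quartic(p2: float, eta4: float) -> float:
    """Q = p^4 + p^2*(3*eta4 - 1) + eta4, evaluated stably.

    Below eta4 = 1/9 the factored form (p^2 - p1^2)*(p^2 - p2^2) avoids
    cancellation near the turning points.
    """
    tp = turning_points(eta4)
    if tp.exists:
        return (p2 - tp.p1**2) * (p2 - tp.p2**2)
    return p2 * p2 + p2 * (3.0 * eta4 - 1.0) + eta4


def jacobian_at(params: DimensionlessParams, steady: SteadyState) -> np.ndarray:
    """The 2x2 Jacobian at (m*, p*); refuses non-unique steady states."""
    if not steady.unique:
        raise NonUniqueSteadyStateError(
            "stability classification requires a unique steady state; "
            f"found roots {steady.all_roots}"
        )
    e1, e2, e3, e4 = params.astuple()
    p = steady.p_star
    p2 = p * p
    j11 = -e3
    j12 = -2.0 * (e1 / e2) * p / (1.0 + p2 / e2) ** 2
    j21 = (e4 + p2) / (1.0 + p2)
    j22 = -_quartic(p2, e4) / ((e4 + p2) * (1.0 + p2))
    return np.array([[j11, j12], [j21, j22]])


def trace_det(
    params: DimensionlessParams, steady: SteadyState
) -> tuple[float, float, tuple[complex, complex]]:
    """(trace, determinant, eigenvalues) at the steady state.

    The determinant must come out positive at a unique steady state; a
    non-positive value indicates an implementation bug and raises.
    """
    jac = jacobian_at(params, steady)
    p2 = steady.p_star**2
    e4 = params.eta4
    trace = -params.eta3 - _quartic(p2, e4) / ((e4 + p2) * (1.0 + p2))
    det = float(jac[0, 0] * jac[1, 1] - jac[0, 1] * jac[1, 0])
    if det <= 0.0:
        raise AssertionError(
            f"determinant {det} <= 0 at a unique steady state: internal inconsistency"
        )
    # eigenvalues from the characteristic quadratic lambda^2 - tr*lambda + det
    disc = complex(trace * trace - 4.0 * det)
    root = disc**0.5
    eigs = ((trace + root) / 2.0, (trace - root) / 2.0)
    return float(trace), det, eigs


def instability_interval(eta3: float, eta4: float) -> tuple[float, float] | None:
    """Open interval (p_c-, p_c+) of p* with positive trace, or None.

    The boundaries are the positive roots of
    p^4*(1+eta3) - p^2*(1-3*eta4-eta3*(1+eta4)) + eta4*(1+eta3) = 0,
    real and distinct only when 1-3*eta4-eta3*(1+eta4) > 0 and the
    discriminant is positive (equivalently eta4 < ((eta3-1)/(3+eta3))^2).
    A zero discriminant (marginal, single tangency point) counts as empty.
    """
    if eta3 <= 0 or eta4 <= 0:
        raise ValueError("eta3 and eta4 must be positive")
    s = 1.0 - 3.0 * eta4 - eta3 * (1.0 + eta4)
    if s <= 0.0:
        return None
    disc = s * s - 4.0 * eta4 * (1.0 + eta3) ** 2
    if disc <= 0.0:
        return None
    root = math.sqrt(disc)
    denom = 2.0 * (1.0 + eta3)
    return (math.sqrt((s - root) / denom), math.sqrt((s + root) / denom))


def necessary_condition_eta3(eta4: float) -> float:
    """Upper bound (1 - 3*sqrt(eta4))/(1 + sqrt(eta4)) on eta3 for instability.

    Returns 0 when eta4 >= 1/9 (no instability interval can exist). The
    bound is < 1 for all eta4 > 0: mRNA must be more stable than protein.
    """
    if eta4 <= 0:
        raise ValueError("eta4 must be positive")
    s = math.sqrt(eta4)
    bound = (1.0 - 3.0 * s) / (1.0 + s)
    return bound if bound > 0.0 else 0.0


def eta1_band(params: DimensionlessParams) -> tuple[float, float]:
    """Open bounds on eta1/eta3 for a middle-branch nullcline intersection.

    ((1 + eta4/eta2)/(2*sqrt(eta4)), 2*(1 + 1/eta2)); membership is a
    necessary condition for limit cycles. Requires eta4 < 1/9.
    """
    if not params.eta4 < 1.0 / 9.0:
        raise ValueError("eta1 band requires eta4 < 1/9")
    lower = (1.0 + params.eta4 / params.eta2) / (2.0 * math.sqrt(params.eta4))
    upper = 2.0 * (1.0 + 1.0 / params.eta2)
    return (lower, upper)


def dimensional_region(
    k2_over_k5: float, k4_over_k3: float, alpha_over_X0: float
) -> tuple[bool, float]:
    """Small-eta4 approximation of the oscillatory region in rate ratios.

    Evaluates k2/k5 < 1 - 4*sqrt(X0/alpha + k3/k4) and returns
    (satisfied, margin = RHS - k2/k5). Sweeping the RHS over (k4/k3,
    alpha/X0) grids reproduces the oscillation-region surface; positivity
    of the RHS needs both ratios above 16.
    """
    if min(k2_over_k5, k4_over_k3, alpha_over_X0) <= 0:
        raise ValueError("ratios must be positive")
    rhs = 1.0 - 4.0 * math.sqrt(1.0 / alpha_over_X0 + 1.0 / k4_over_k3)
    margin = rhs - k2_over_k5
    return margin > 0.0, margin


def batch_trace_det(eta1, eta2, eta3, eta4, p_star):
    """Vectorised (trace, determinant) at steady states, for parameter sweeps.

    Inputs broadcast; ``p_star`` must already solve the quintic for its
    parameter set (see ``steady_state.batch_positive_roots``).
    """
    eta1, eta2, eta3, eta4, p = np.broadcast_arrays(
        *(np.asarray(a, float) for a in (eta1, eta2, eta3, eta4, p_star))
    )
    p2 = p * p
    quartic = p2 * p2 + p2 * (3.0 * eta4 - 1.0) + eta4
    denom = (eta4 + p2) * (1.0 + p2)
    j11 = -eta3
    j12 = -2.0 * (eta1 / eta2) * p / (1.0 + p2 / eta2) ** 2
    j21 = (eta4 + p2) / (1.0 + p2)
    j22 = -quartic / denom
    return j11 + j22, j11 * j22 - j12 * j21


@dataclass(frozen=True)
class StabilityReport:
    jacobian: np.ndarray
    trace: float
    determinant: float
    eigenvalues: tuple[complex, complex]
    classification: str
    pc_interval: tuple[float, float] | None
    conditions: dict
    steady: SteadyState


def classify(params: DimensionlessParams) -> StabilityReport:
    """Full linear-stability report at the unique steady state.

    Because the determinant is always positive there are no saddles:
    the state is unstable exactly when the trace is positive, a focus when
    the eigenvalues are complex, and "marginal (Hopf)" at trace zero
    (within 1e-12).
    """
    steady = steady_state(params)
    jac = jacobian_at(params, steady)  # raises for non-unique
    trace, det, eigs = trace_det(params, steady)
    disc = trace * trace - 4.0 * det
    if abs(trace) <= _MARGINAL_TOL:
        classification = "marginal (Hopf)"
    else:
        kind = "focus" if disc < 0.0 else "node"
        classification = f"{'unstable' if trace > 0 else 'stable'} {kind}"
    interval = instability_interval(params.eta3, params.eta4)
    bound = necessary_condition_eta3(params.eta4)
    conditions = {
        "eta4_below_one_ninth": params.eta4 < 1.0 / 9.0,
        "eta2_below_eta4": params.eta2 < params.eta4,
        "eta3_below_necessary_bound": params.eta3 < bound,
        "pstar_in_instability_interval": bool(
            interval is not None and interval[0] < steady.p_star < interval[1]
        ),
    }
    if params.eta4 < 1.0 / 9.0:
        lo, hi = eta1_band(params)
        conditions["eta1_in_middle_branch_band"] = lo < params.eta1 / params.eta3 < hi
    else:
        conditions["eta1_in_middle_branch_band"] = False
    return StabilityReport(
        jacobian=jac,
        trace=trace,
        determinant=det,
        eigenvalues=eigs,
        classification=classification,
        pc_interval=interval,
        conditions=conditions,
        steady=steady,
    )
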