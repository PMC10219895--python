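"""Analytic Hopf locus in the eta1-eta3 plane and criticality classification.

The instability interval (p_c-, p_c+) of steady-state protein levels is
closed-form, and the steady-state protein level is a monotonically
increasing function of eta1, so each boundary maps through the nullcline
identity to a Hopf eta1 value. This gives the Hopf locus exactly, where a
continuation package would trace it numerically.

Criticality (sub- vs supercritical) comes from the first Lyapunov
coefficient of the planar system at the bifurcation. The system is brought
to the rotational normal-form frame by an explicit linear change of
variables and the standard planar cubic normal-form formula

    16*a1 = F_XXX + F_XYY + G_XXY + G_YYY
            + (1/w) * ( F_XY*(F_XX + F_YY) - G_XY*(G_XX + G_YY)
                        - F_XX*G_XX + F_YY*G_YY )

is evaluated with hand-derived second- and third-order partial derivatives
of the right-hand side (a1 < 0: supercritical; a1 > 0: subcritical).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import p_nullcline
from .params import DimensionlessParams
from .stability import instability_interval
from .steady_state import eta1_for_pstar

__all__ = [
    "HopfPoint",
    "hopf_points",
    "hopf_locus",
    "criticality",
    "lyapunov_coefficient",
    "rhs_partials",
]

_TRACE_TOL = 1e-9
_LYAPUNOV_TOL = 1e-10


@dataclass(frozen=True)
class HopfPoint:
    """A Hopf bifurcation point of the dimensionless system."""

    eta1: float
    eta3: float
    p_star: float
    criticality: str  # "supercritical" | "subcritical" | "undecided"
    lyapunov_coefficient: float


def rhs_partials(params: DimensionlessParams, m: float, p: float):
    """First/second/third partial derivative tensors of the right-hand side.

    Returns (jac, D2, D3) where D2[i] is the symmetric 2x2 Hessian of
    component i with respect to (m, p) and D3[i] the symmetric 2x2x2 tensor
    of third partials. Component 0 is dm/dtau, component 1 is dp/dtau.
    """
    e1, e2, e3, e4 = params.astuple()
    p2 = p * p
    # transcription term q(p) = e1*e2/(e2 + p^2) and its derivatives
    den = e2 + p2
    q1 = -2.0 * e1 * e2 * p / den**2
    q2 = -2.0 * e1 * e2 * (e2 - 3.0 * p2) / den**3
    q3 = 24.0 * e1 * e2 * p * (e2 - p2) / den**4
    # translation factor g(p) = (e4 + p^2)/(1 + p^2) = 1 - c*u, u = 1/(1+p^2)
    c = 1.0 - e4
    u = 1.0 / (1.0 + p2)
    g = 1.0 - c * u
    g1 = 2.0 * c * p * u * u
    g2 = 2.0 * c * (u * u - 4.0 * p2 * u**3)
    g3 = 24.0 * c * p * u**3 * (2.0 * p2 * u - 1.0)

    jac = np.array([[-e3, q1], [g, m * g1 - 1.0]])
    D2 = np.zeros((2, 2, 2))
    D2[0, 1, 1] = q2
    D2[1, 0, 1] = D2[1, 1, 0] = g1
    D2[1, 1, 1] = m * g2
    D3 = np.zeros((2, 2, 2, 2))
    D3[0, 1, 1, 1] = q3
    D3[1, 0, 1, 1] = D3[1, 1, 0, 1] = D3[1, 1, 1, 0] = g2
    D3[1, 1, 1, 1] = m * g3
    return jac, D2, D3


def lyapunov_coefficient(params: DimensionlessParams, p_star: float) -> float:
    """First Lyapunov coefficient at a Hopf point with protein level p_star.

    Requires the Jacobian trace at (m*, p*) to vanish (within 1e-6; the
    closed-form Hopf points are far tighter) and a positive determinant.
    """
    m_star = p_nullcline(p_star, params.eta4)
    jac, D2, D3 = rhs_partials(params, m_star, p_star)
    a, b = jac[0, 0], jac[0, 1]
    trace = jac[0, 0] + jac[1, 1]
    det = jac[0, 0] * jac[1, 1] - jac[0, 1] * jac[1, 0]
    if det <= 0.0:
        raise ValueError(f"not a Hopf point: determinant {det} <= 0")
    if abs(trace) > 1e-6 * max(1.0, math.sqrt(det)):
        raise ValueError(f"not a Hopf point: trace {trace} != 0")
    w = math.sqrt(det)

    # Linear frame in which the linearisation is the rotation [[0,-w],[w,0]]:
    # X = (a*x + b*y)/w, Y = x  with (x, y) the shifted (m, p) coordinates,
    # so x = Y and y = (w*X - a*Y)/b.
    S = np.array([[0.0, 1.0], [w / b, -a / b]])  # rows: x, y in terms of (X, Y)
    R = np.array([[a / w, b / w], [1.0, 0.0]])  # rows: F, G in terms of (f1, f2)

    T2 = np.einsum("ijk,jb,kc->ibc", D2, S, S)
    T3 = np.einsum("ijkl,jb,kc,ld->ibcd", D3, S, S, S)
    F2, G2 = np.einsum("ri,ibc->rbc", R, T2)
    F3, G3 = np.einsum("ri,ibcd->rbcd", R, T3)

    a1 = (
        F3[0, 0, 0]
        + F3[0, 1, 1]
        + G3[0, 0, 1]
        + G3[1, 1, 1]
        + (1.0 / w)
        * (
            F2[0, 1] * (F2[0, 0] + F2[1, 1])
            - G2[0, 1] * (G2[0, 0] + G2[1, 1])
            - F2[0, 0] * G2[0, 0]
            + F2[1, 1] * G2[1, 1]
        )
    ) / 16.0
    return float(a1)


def _classify(l1: float) -> str:
    if l1 < -_LYAPUNOV_TOL:
        return "supercritical"
    if l1 > _LYAPUNOV_TOL:
        return "subcritical"
    return "undecided"


def hopf_points(eta2: float, eta3: float, eta4: float) -> list[HopfPoint]:
    """The zero or two Hopf points along eta1 at fixed (eta2, eta3, eta4).

    The trace vanishes exactly at p* = p_c-, p_c+; each maps to its eta1
    through the steady-state relation. Empty when no instability interval
    exists.
    """
    interval = instability_interval(eta3, eta4)
    if interval is None:
        return []
    points = []
    for p_c in interval:
        e1 = eta1_for_pstar(p_c, eta2, eta3, eta4)
        params = DimensionlessParams(e1, eta2, eta3, eta4)
        l1 = lyapunov_coefficient(params, p_c)
        points.append(HopfPoint(e1, eta3, p_c, _classify(l1), l1))
    return points


def hopf_locus(eta2: float, eta4: float, eta3_grid):
    """Hopf locus rows (eta3, eta1_low, eta1_high) over an eta3 grid.

    The two branches close into a loop at the maximal eta3 admitting an
    instability interval; that endpoint matches the closed-form necessary
    bound on eta3 and is independent of eta2 (only the eta1 values move
    with eta2). Returns a pandas DataFrame, empty for an empty grid.
    """
    import pandas as pd

    rows = []
    for e3 in np.atleast_1d(np.asarray(eta3_grid, dtype=float)):
        pts = hopf_points(eta2, float(e3), eta4)
        if pts:
            rows.append(
                {
                    "eta3": float(e3),
                    "eta1_low": pts[0].eta1,
                    "eta1_high": pts[1].eta1,
                    "criticality_low": pts[0].criticality,
                    "criticality_high": pts[1].criticality,
                }
            )
    return pd.DataFrame(
        rows, columns=["eta3", "eta1_low", "eta1_high", "criticality_low", "criticality_high"]
    )


def cycle_fold_eta1(
    eta2: float,
    eta3: float,
    eta4: float,
    rel_bracket: float = 0.90,
    rel_tol: float = 1e-3,
    t_end: float = 4000.0,
) -> tuple[float, float]:
    """Behavioural saddle-node-of-cycles location below the lower Hopf point.

    Returns ``(eta1_fold, eta1_hopf)``. A state on the stable limit cycle
    slightly above the lower Hopf point is used as a warm start, and eta1 is
    bisected on whether the cycle survives. For a subcritical Hopf the fold
    sits strictly below eta1_hopf (hysteresis/coexistence window between the
    two); for a supercritical Hopf the bisection collapses onto eta1_hopf
    (no window). No Floquet machinery is involved.
    """
    from .dynamics import characterise_attractor

    pts = hopf_points(eta2, eta3, eta4)
    if not pts:
        raise ValueError("no Hopf points for these parameters")
    eta1_h = pts[0].eta1

    def survives(eta1: float, init) -> tuple[bool, tuple[float, float]]:
        params = DimensionlessParams(eta1, eta2, eta3, eta4)
        _, rep = characterise_attractor(params, init=init, t_end=t_end)
        return rep.kind == "limit_cycle", rep.final_state

    ok, warm = survives(1.05 * eta1_h, (0.0, 0.0))
    if not ok:
        raise RuntimeError("no stable cycle found just above the lower Hopf point")
    lo, hi = rel_bracket * eta1_h, eta1_h
    alive, state = survives(lo, warm)
    if alive:
        return lo, eta1_h  # fold below the bracket; caller widens if needed
    while (hi - lo) > rel_tol * eta1_h:
        mid = 0.5 * (lo + hi)
        alive, state = survives(mid, warm)
        if alive:
            hi = mid
            warm = state
        else:
            lo = mid
    return 0.5 * (lo + hi), eta1_h


def criticality(point: HopfPoint, eta2: float, eta4: float) -> str:
    """Re-derive the criticality label of a Hopf point from scratch.

    Validates the Hopf conditions (zero trace, positive determinant) and
    returns the sign classification of the first Lyapunov coefficient.
    """
    params = DimensionlessParams(point.eta1, eta2, point.eta3, eta4)
    l1 = lyapunov_coefficient(params, point.p_star)
    return _classify(l1)
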