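"""Fast-slow (relaxation-limit) period and amplitude estimates.

When mRNA kinetics (eta1, eta3) are much slower than protein kinetics, the
limit cycle hugs the outer branches of the p nullcline with fast vertical
jumps between them at the turning points. To leading order in small eta4
the cycle is the closed path A -> B -> C -> D with corners (m, p):

    A = (2 - 2*eta4,            2*eta4)
    B = ((1+eta4)/(2*sqrt(eta4)), sqrt(eta4)*(1 + 2*eta4))
    C = ((1+eta4)/(2*sqrt(eta4)), (1+eta4)/(2*sqrt(eta4)))
    D = (2 - 2*eta4,            1 - 2*eta4)

(m is constant along the fast jumps B->C and D->A). The slow segments give
a lower bound for the period,

    T ~ T_AB + T_CD = 1/(2*eta1*sqrt(eta4)) + (1/eta3)*ln(1/(4*sqrt(eta4))),

and the amplitudes are A_p = p_C - p_A = 1/(2*sqrt(eta4)) - 2*eta4 and
A_m = m_B - m_A, both ~ 1/(2*sqrt(eta4)) at leading order. (The exact
corner difference m_B - m_A = (1+eta4)/(2*sqrt(eta4)) - (2-2*eta4) is
noticeably below the leading-order figure at moderate eta4; both are
exposed.) Dimensional counterparts are provided in two flavours: the
leading-order closed forms in the rate constants, and the exact rescaling
of the dimensionless estimates by the model scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import DimensionalParams, DimensionlessParams, nondimensionalise

__all__ = [
    "RelaxationEstimate",
    "corner_points",
    "period_estimate",
    "amplitude_estimate",
    "amplitude_leading_order",
    "relaxation_estimate",
    "dimensional_period",
    "dimensional_period_exact",
    "dimensional_amplitudes",
    "dimensional_amplitudes_exact",
]


def _require_relaxation_eta4(eta4: float) -> None:
    if eta4 <= 0:
        raise ValueError("eta4 must be positive")
    if not eta4 < 1.0 / 9.0:
        raise ValueError("relaxation analysis requires eta4 < 1/9")


def corner_points(eta4: float) -> dict[str, tuple[float, float]]:
    """The four (m, p) corner points A, B, C, D of the relaxation cycle."""
    _require_relaxation_eta4(eta4)
    s = math.sqrt(eta4)
    mB = (1.0 + eta4) / (2.0 * s)
    return {
        "A": (2.0 - 2.0 * eta4, 2.0 * eta4),
        "B": (mB, s * (1.0 + 2.0 * eta4)),
        "C": (mB, mB),
        "D": (2.0 - 2.0 * eta4, 1.0 - 2.0 * eta4),
    }


def period_estimate(eta1: float, eta3: float, eta4: float) -> tuple[float, float, float]:
    """(T_AB, T_CD, period): the slow-segment durations and their sum.

    A lower bound for the true oscillator period (it neglects the time
    spent near the local maximum of the p nullcline). Requires the log
    argument 1/(4*sqrt(eta4)) >= 1, i.e. eta4 <= 1/16; at eta4 = 1/16
    exactly, T_CD = 0 (degenerate boundary of the relaxation regime).
    """
    if min(eta1, eta3) <= 0:
        raise ValueError("eta1 and eta3 must be positive")
    _require_relaxation_eta4(eta4)
    s = math.sqrt(eta4)
    log_arg = 1.0 / (4.0 * s)
    if log_arg < 1.0:
        raise ValueError(
            "period estimate requires eta4 <= 1/16 (the relaxation-regime "
            f"assumption 4*sqrt(eta4) <= 1 fails for eta4 = {eta4})"
        )
    t_ab = 1.0 / (2.0 * eta1 * s)
    t_cd = math.log(log_arg) / eta3
    return t_ab, t_cd, t_ab + t_cd


def amplitude_estimate(eta4: float) -> tuple[float, float]:
    """(amp_p, amp_m) from exact corner arithmetic.

    amp_p = p_C - p_A = 1/(2*sqrt(eta4)) - 2*eta4;
    amp_m = m_B - m_A = (1+eta4)/(2*sqrt(eta4)) - (2 - 2*eta4).
    """
    _require_relaxation_eta4(eta4)
    s = math.sqrt(eta4)
    amp_p = 1.0 / (2.0 * s) - 2.0 * eta4
    amp_m = (1.0 + eta4) / (2.0 * s) - (2.0 - 2.0 * eta4)
    return amp_p, amp_m


def amplitude_leading_order(eta4: float) -> float:
    """Leading-order amplitude 1/(2*sqrt(eta4)) shared by both variables."""
    _require_relaxation_eta4(eta4)
    return 1.0 / (2.0 * math.sqrt(eta4))


@dataclass(frozen=True)
class RelaxationEstimate:
    corners: dict[str, tuple[float, float]]
    T_AB: float
    T_CD: float
    period: float
    amp_p: float
    amp_m: float
    amp_leading_order: float


def relaxation_estimate(params: DimensionlessParams) -> RelaxationEstimate:
    """Bundle corners, period terms and amplitudes for a parameter set."""
    t_ab, t_cd, period = period_estimate(params.eta1, params.eta3, params.eta4)
    amp_p, amp_m = amplitude_estimate(params.eta4)
    return RelaxationEstimate(
        corners=corner_points(params.eta4),
        T_AB=t_ab,
        T_CD=t_cd,
        period=period,
        amp_p=amp_p,
        amp_m=amp_m,
        amp_leading_order=amplitude_leading_order(params.eta4),
    )


def dimensional_period(dim: DimensionalParams) -> float:
    """Leading-order dimensional period formula ("printed" flavour).

    T = k5*P0*(alpha/X0) / (2*k1*k4*sqrt(1 + (alpha/X0)*(k3/k4)))
        + (1/k2)*ln( sqrt(k4/k3)*sqrt(alpha/X0) / (4*sqrt(k4/k3 + alpha/X0)) )

    Valid in the relaxation limit with large k4/k3 and alpha/X0; agreement
    with the exact rescaling improves as those ratios grow.
    """
    _check_dim_regime(dim)
    a = dim.alpha / dim.X0
    r = dim.k4 / dim.k3
    first = dim.k5 * dim.P0 * a / (2.0 * dim.k1 * dim.k4 * math.sqrt(1.0 + a / r))
    second = math.log(math.sqrt(r) * math.sqrt(a) / (4.0 * math.sqrt(r + a))) / dim.k2
    return first + second


def dimensional_period_exact(dim: DimensionalParams) -> float:
    """Exact rescaling T~ * period_estimate(eta's) ("exact-rescaled" flavour)."""
    etas, scales = nondimensionalise(dim)
    return scales.T_tilde * period_estimate(etas.eta1, etas.eta3, etas.eta4)[2]


def dimensional_amplitudes(dim: DimensionalParams) -> tuple[float, float, float]:
    """(A_P, A_M, A_P/A_M) at leading order in the relaxation limit.

    A_P = (P0/2)*(alpha/X0)/sqrt(1 + (alpha/X0)*(k3/k4)),
    A_M = (k5/k4)*A_P, so the ratio is exactly k4/k5: both amplitudes are
    independent of mRNA production and degradation rates.
    """
    _check_dim_regime(dim)
    a = dim.alpha / dim.X0
    r = dim.k4 / dim.k3
    A_P = 0.5 * dim.P0 * a / math.sqrt(1.0 + a / r)
    A_M = A_P * dim.k5 / dim.k4
    return A_P, A_M, dim.k4 / dim.k5


def dimensional_amplitudes_exact(dim: DimensionalParams) -> tuple[float, float]:
    """(P~ * amp_p, M~ * amp_m): exact rescaling of the corner amplitudes."""
    etas, scales = nondimensionalise(dim)
    amp_p, amp_m = amplitude_estimate(etas.eta4)
    return scales.P_tilde * amp_p, scales.M_tilde * amp_m


def _check_dim_regime(dim: DimensionalParams) -> None:
    etas, _ = nondimensionalise(dim)
    _require_relaxation_eta4(etas.eta4)
    if 4.0 * math.sqrt(etas.eta4) > 1.0:
        raise ValueError(
            "dimensional relaxation formulas require eta4 <= 1/16 "
            f"(mapped eta4 = {etas.eta4})"
        )
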