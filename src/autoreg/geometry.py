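"""Nullclines of the dimensionless system and the p-nullcline turning points.

The p nullcline m = p*(1+p^2)/(eta4+p^2) is cubic-shaped ("N"-shaped) when
eta4 < 1/9, with a local maximum (p1, m1) and local minimum (p2, m2) whose
abscissae solve the biquadratic p^4 + p^2*(3*eta4 - 1) + eta4 = 0. The m
nullcline is a monotonically decreasing Hill curve with plateau eta1/eta3
and IC50 at p = sqrt(eta2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TurningPoints",
    "p_nullcline",
    "m_nullcline",
    "turning_point_discriminant",
    "turning_points",
    "turning_points_approx",
]

# Turning points degenerate into a double point when the biquadratic
# discriminant (1-3*eta4)^2 - 4*eta4 vanishes, i.e. at eta4 = 1/9.
_DEGENERATE_ATOL = 1e-14


def _check_p(p):
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("protein level p must be non-negative")
    return p


def p_nullcline(p, eta4: float):
    """m value on the p nullcline: p*(1+p^2)/(eta4+p^2)."""
    if eta4 <= 0:
        raise ValueError("eta4 must be positive")
    p = _check_p(p)
    out = p * (1.0 + p * p) / (eta4 + p * p)
    return float(out) if out.ndim == 0 else out


def m_nullcline(p, eta1: float, eta2: float, eta3: float):
    """m value on the m nullcline: (eta1/eta3) / (1 + p^2/eta2).

    Monotonically decreasing for p > 0, plateau eta1/eta3 at p = 0 and
    half-maximum at the IC50 p = sqrt(eta2).
    """
    if min(eta1, eta2, eta3) <= 0:
        raise ValueError("eta1, eta2, eta3 must be positive")
    p = _check_p(p)
    out = (eta1 / eta3) / (1.0 + p * p / eta2)
    return float(out) if out.ndim == 0 else out


def turning_point_discriminant(eta4: float) -> float:
    """Discriminant of the biquadratic in p^2; zero exactly at eta4 = 1/9."""
    return (1.0 - 3.0 * eta4) ** 2 - 4.0 * eta4


@dataclass(frozen=True)
class TurningPoints:
    """Turning points of the p nullcline.

    ``(p1, m1)`` is the local maximum, ``(p2, m2)`` the local minimum;
    ``exists`` is True only when the two are distinct and real (eta4 < 1/9);
    ``degenerate`` marks the double root at eta4 = 1/9 (then p1 == p2).
    """

    p1: float
    m1: float
    p2: float
    m2: float
    exists: bool
    degenerate: bool


def turning_points(eta4: float) -> TurningPoints:
    """Closed-form turning points of the p nullcline.

    Solves p^4 + p^2*(3*eta4 - 1) + eta4 = 0 as a quadratic in p^2 and maps
    the roots through the p nullcline for the m coordinates.
    """
    if eta4 <= 0:
        raise ValueError("eta4 must be positive")
    disc = turning_point_discriminant(eta4)
    if abs(disc) <= _DEGENERATE_ATOL:
        p = math.sqrt((1.0 - 3.0 * eta4) / 2.0)
        m = p_nullcline(p, eta4)
        return TurningPoints(p, m, p, m, exists=False, degenerate=True)
    if disc < 0.0 or eta4 >= 1.0 / 9.0:
        nan = float("nan")
        return TurningPoints(nan, nan, nan, nan, exists=False, degenerate=False)
    half = (1.0 - 3.0 * eta4) / 2.0
    root = math.sqrt(disc) / 2.0
    p1 = math.sqrt(half - root)
    p2 = math.sqrt(half + root)
    return TurningPoints(
        p1, p_nullcline(p1, eta4), p2, p_nullcline(p2, eta4), exists=True, degenerate=False
    )


def turning_points_approx(eta4: float) -> TurningPoints:
    """Small-eta4 approximations (sqrt(eta4), 1/(2*sqrt(eta4))) and (1, 2)."""
    if not eta4 < 1.0 / 9.0:
        raise ValueError("turning-point approximation requires eta4 < 1/9")
    if eta4 <= 0:
        raise ValueError("eta4 must be positive")
    s = math.sqrt(eta4)
    return TurningPoints(s, 1.0 / (2.0 * s), 1.0, 2.0, exists=True, degenerate=False)
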