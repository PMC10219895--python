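"""Steady states of the dimensionless oscillator via the quintic condition.

Eliminating m between the two nullclines, the steady-state protein level p*
satisfies

    h(p) = p^5 + p^3*(eta2 + 1) - p^2*eta1*eta2/eta3 + eta2*p
           - eta1*eta2*eta4/eta3 = 0.

The coefficient signs (+, 0, +, -, +, -) give a Descartes bound of three
positive roots, and h(0) < 0 with h -> +inf guarantees at least one. Over
the biologically relevant region the root is unique (no bistability); the
code nevertheless handles multi-root sets gracefully by flagging them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import p_nullcline, turning_points
from .params import DimensionlessParams

__all__ = [
    "SteadyState",
    "NonUniqueSteadyStateError",
    "quintic_coefficients",
    "descartes_bound",
    "positive_roots",
    "steady_state",
    "branch_of",
    "eta1_for_pstar",
    "batch_positive_roots",
]

_IMAG_TOL = 1e-9
_REAL_TOL = 1e-12


class NonUniqueSteadyStateError(RuntimeError):
    """Raised by consumers that require a unique steady state."""


@dataclass(frozen=True)
class SteadyState:
    """A steady state (m*, p*) with branch label and uniqueness flag.

    ``branch`` locates p* relative to the p-nullcline turning points
    (left / middle / right); ``residual`` is h(p*); ``all_roots`` carries
    every positive root found (length 1 when ``unique``).
    """

    p_star: float
    m_star: float
    branch: str
    unique: bool
    residual: float
    all_roots: tuple[float, ...]


def quintic_coefficients(params: DimensionlessParams) -> np.ndarray:
    """Coefficients of h(p), degree 5 down to 0."""
    e1, e2, e3, e4 = params.astuple()
    return np.array(
        [1.0, 0.0, e2 + 1.0, -e1 * e2 / e3, e2, -e1 * e2 * e4 / e3], dtype=float
    )


def descartes_bound(params: DimensionlessParams) -> int:
    """Number of sign changes in the nonzero coefficients of h (always 3)."""
    coeffs = quintic_coefficients(params)
    signs = np.sign(coeffs[coeffs != 0.0])
    return int(np.sum(signs[:-1] != signs[1:]))


def _h_and_deriv(p: float, coeffs: np.ndarray) -> tuple[float, float]:
    return float(np.polyval(coeffs, p)), float(np.polyval(np.polyder(coeffs), p))


def _polish(root: float, coeffs: np.ndarray, iterations: int = 8) -> float:
    # Damped Newton refinement; the companion-matrix root is already close.
    p = root
    for _ in range(iterations):
        h, dh = _h_and_deriv(p, coeffs)
        if dh == 0.0:
            break
        step = h / dh
        while p - step <= 0.0:  # stay in the positive domain
            step *= 0.5
        p -= step
        if abs(step) <= 1e-16 * max(1.0, abs(p)):
            break
    return p


def positive_roots(params: DimensionlessParams) -> list[float]:
    """All real positive roots of h, ascending; guaranteed non-empty.

    Roots come from the companion-matrix eigenvalues, are accepted when
    |Im| <= 1e-9 * max(1, |Re|) and Re > 1e-12, and are polished by damped
    Newton steps on h.
    """
    coeffs = quintic_coefficients(params)
    roots = np.roots(coeffs)
    keep = []
    for z in roots:
        if z.real > _REAL_TOL and abs(z.imag) <= _IMAG_TOL * max(1.0, abs(z.real)):
            keep.append(float(_polish(float(z.real), coeffs)))
    keep.sort()
    # collapse near-duplicates the polish may have merged
    out: list[float] = []
    for p in keep:
        if not out or abs(p - out[-1]) > 1e-9 * max(1.0, p):
            out.append(p)
    return out


def batch_positive_roots(
    eta1: np.ndarray, eta2: np.ndarray, eta3: np.ndarray, eta4: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised positive-root extraction for parameter sweeps.

    Returns ``(p_star, n_roots)`` where ``p_star`` is the smallest positive
    root per set (the unique one over the sampled region) and ``n_roots``
    counts the accepted positive roots. Uses batched companion-matrix
    eigenvalues; roots are not Newton-polished (eigenvalue accuracy is ample
    for sweep-scale checks).
    """
    eta1, eta2, eta3, eta4 = np.broadcast_arrays(
        np.atleast_1d(np.asarray(eta1, float)),
        np.atleast_1d(np.asarray(eta2, float)),
        np.atleast_1d(np.asarray(eta3, float)),
        np.atleast_1d(np.asarray(eta4, float)),
    )
    n = eta1.size
    comp = np.zeros((n, 5, 5))
    comp[:, 1:, :-1] = np.eye(4)
    comp[:, 0, 1] = -(eta2 + 1.0)
    comp[:, 0, 2] = eta1 * eta2 / eta3
    comp[:, 0, 3] = -eta2
    comp[:, 0, 4] = eta1 * eta2 * eta4 / eta3
    roots = np.linalg.eigvals(comp)
    positive = (roots.real > _REAL_TOL) & (
        np.abs(roots.imag) <= _IMAG_TOL * np.maximum(1.0, np.abs(roots.real))
    )
    n_roots = positive.sum(axis=1)
    masked = np.where(positive, roots.real, np.inf)
    return masked.min(axis=1), n_roots


def branch_of(p_star: float, eta4: float) -> str:
    """Label p* relative to the turning points: left / middle / right.

    For eta4 >= 1/9 the p nullcline is monotone and the taxonomy collapses;
    the label "left" is returned by convention.
    """
    tp = turning_points(eta4)
    if not tp.exists:
        return "left"
    if p_star < tp.p1:
        return "left"
    if p_star > tp.p2:
        return "right"
    return "middle"


def eta1_for_pstar(p_star: float, eta2: float, eta3: float, eta4: float) -> float:
    """The unique eta1 for which p_star is a steady state (nullcline equality)."""
    if p_star <= 0:
        raise ValueError("p_star must be positive")
    p2 = p_star * p_star
    return eta3 * p_star * (1.0 + p2) * (1.0 + p2 / eta2) / (eta4 + p2)


def steady_state(params: DimensionlessParams) -> SteadyState:
    """Locate the steady state(s); flags (never raises on) non-uniqueness."""
    roots = positive_roots(params)
    coeffs = quintic_coefficients(params)
    p = roots[0]
    m = p_nullcline(p, params.eta4)
    return SteadyState(
        p_star=p,
        m_star=m,
        branch=branch_of(p, params.eta4),
        unique=(len(roots) == 1),
        residual=float(np.polyval(coeffs, p)),
        all_roots=tuple(roots),
    )
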