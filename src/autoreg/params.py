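"""Parameter sets, characteristic scales and the nondimensionalisation map.

The dimensional model tracks mRNA ``M`` and protein ``P`` of a gene whose
protein dimer represses its own transcription while, through a fast
intermediary ``X`` under the same transcriptional control, de-repressing its
own translation (a coupled negative + positive feedback loop, as in the
Hes/Her segmentation-clock oscillator)::

    dM/dt = k1 / (1 + (P/P0)^2) - k2*M
    dP/dt = M * (k3 + k4 / (1 + (alpha/X0) / (1 + (P/P0)^2))) - k5*P

Rescaling ``m = M/M~``, ``p = P/P~`` and ``tau = t/T~`` with

    M~ = (k5*P0/k3) * sqrt(1 + alpha/X0) / (1 + k4/k3)
    P~ = P0 * sqrt(1 + alpha/X0)
    T~ = 1/k5                      (protein degradation timescale)

collapses the eight dimensional constants onto four dimensionless groups::

    eta1 = k1*(k3 + k4) / (k5^2 * P0 * sqrt(1 + alpha/X0))   scaled transcription
    eta2 = 1 / (1 + alpha/X0)                                transcription IC50^2
    eta3 = k2 / k5                                           mRNA/protein degradation ratio
    eta4 = (1 + k4/k3 + alpha/X0) /
           ((1 + k4/k3) * (1 + alpha/X0))                    translation-switch strength

and the dynamics become::

    dm/dtau = eta1 / (1 + p^2/eta2) - eta3*m
    dp/dtau = m * (eta4 + p^2) / (1 + p^2) - p

Two algebraic facts about the map are worth noting (and are enforced as
invariants elsewhere): ``eta2 < eta4`` for every positive dimensional set,
and ``eta4 <= 1`` with equality only in the alpha -> 0 limit where the
translational switch disappears.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ValidationError",
    "DimensionalParams",
    "DimensionlessParams",
    "Scales",
    "RegimeReport",
    "nondimensionalise",
    "redimensionalise_state",
    "nondimensionalise_state",
    "check_regime",
]


class ValidationError(ValueError):
    """A parameter value violates its positivity/range constraint."""


def _require_positive(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value <= 0.0:
        raise ValidationError(
            f"parameter {name!r} must be strictly positive and finite, got {value!r}"
        )
    return value


@dataclass(frozen=True)
class DimensionalParams:
    """The eight rate/affinity constants of the dimensional model.

    Attributes
    ----------
    k1 : maximal transcription rate (concentration / time).
    k2 : mRNA degradation rate (1 / time).
    k3 : basal translation rate (1 / time).
    k4 : translation rate that is inhibited by the intermediary X (1 / time).
    k5 : protein degradation rate (1 / time).
    P0 : protein concentration at which transcription is half-maximal.
    X0 : IC50 constant for translational activation (same units as alpha).
    alpha : maximal steady-state level of X.
    """

    k1: float
    k2: float
    k3: float
    k4: float
    k5: float
    P0: float
    X0: float
    alpha: float

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3", "k4", "k5", "P0", "X0", "alpha"):
            object.__setattr__(self, name, _require_positive(name, getattr(self, name)))

    @property
    def alpha_over_X0(self) -> float:
        """The only combination of (alpha, X0) the dimensionless model sees."""
        return self.alpha / self.X0

    @property
    def k4_over_k3(self) -> float:
        return self.k4 / self.k3


@dataclass(frozen=True)
class DimensionlessParams:
    """The four dimensionless groups eta1..eta4 (canonical model coordinates).

    eta1: scaled transcription rate; eta2: squared IC50 of transcriptional
    inhibition (always < 1); eta3: mRNA-to-protein degradation-rate ratio;
    eta4: strength of the sigmoidal translation switch (<= 1, smaller means
    a stronger switch).
    """

    eta1: float
    eta2: float
    eta3: float
    eta4: float

    def __post_init__(self) -> None:
        for name in ("eta1", "eta2", "eta3", "eta4"):
            object.__setattr__(self, name, _require_positive(name, getattr(self, name)))
        if self.eta2 > 1.0:
            raise ValidationError(
                f"parameter 'eta2' must satisfy eta2 <= 1 (eta2 = 1/(1+alpha/X0)), got {self.eta2!r}"
            )
        if self.eta4 > 1.0:
            raise ValidationError(
                f"parameter 'eta4' must satisfy eta4 <= 1, got {self.eta4!r}"
            )

    def astuple(self) -> tuple[float, float, float, float]:
        return (self.eta1, self.eta2, self.eta3, self.eta4)


@dataclass(frozen=True)
class Scales:
    """Characteristic concentration/time scales used in nondimensionalisation."""

    M_tilde: float
    P_tilde: float
    T_tilde: float

    def __post_init__(self) -> None:
        for name in ("M_tilde", "P_tilde", "T_tilde"):
            object.__setattr__(self, name, _require_positive(name, getattr(self, name)))


@dataclass(frozen=True)
class RegimeReport:
    """Outcome of the printed oscillation-regime conditions.

    Every inequality is evaluated strictly: boundary equality counts as
    "condition not satisfied".
    """

    nullcline_bistable_branch: bool  # eta4 < 1/9: p nullcline has two turning points
    dimensional_consistency: bool  # eta2 < eta4: holds for any dimensional origin
    instability_possible: bool  # eta3 below its necessary upper bound
    eq15_band: tuple[float, float] | None  # open eta1 interval, or None
    messages: tuple[str, ...]


def nondimensionalise(dim: DimensionalParams) -> tuple[DimensionlessParams, Scales]:
    """Map a dimensional parameter set to (eta1..eta4, scales).

    Exact arithmetic per the scale definitions in the module docstring; no
    iteration is involved. Raises :class:`ValidationError` (naming the field)
    for non-positive inputs via the dataclass constructors.
    """
    a = dim.alpha / dim.X0
    r = dim.k4 / dim.k3
    root = math.sqrt(1.0 + a)
    eta1 = dim.k1 * (dim.k3 + dim.k4) / (dim.k5**2 * dim.P0 * root)
    eta2 = 1.0 / (1.0 + a)
    eta3 = dim.k2 / dim.k5
    eta4 = (1.0 + r + a) / ((1.0 + r) * (1.0 + a))
    scales = Scales(
        M_tilde=(dim.k5 * dim.P0 / dim.k3) * root / (1.0 + r),
        P_tilde=dim.P0 * root,
        T_tilde=1.0 / dim.k5,
    )
    return DimensionlessParams(eta1, eta2, eta3, eta4), scales


def redimensionalise_state(m, p, tau, scales: Scales):
    """(m, p, tau) dimensionless -> (M, P, t) dimensional."""
    return m * scales.M_tilde, p * scales.P_tilde, tau * scales.T_tilde


def nondimensionalise_state(M, P, t, scales: Scales):
    """(M, P, t) dimensional -> (m, p, tau) dimensionless; exact inverse."""
    return M / scales.M_tilde, P / scales.P_tilde, t / scales.T_tilde


def check_regime(params: DimensionlessParams) -> RegimeReport:
    """Evaluate each printed oscillation-regime condition for ``params``.

    Conditions (all strict inequalities):

    * ``eta4 < 1/9`` — the p nullcline has two positive turning points, the
      geometric prerequisite for an unstable middle branch;
    * ``eta2 < eta4`` — automatic for parameters of dimensional origin;
    * ``eta3 < (1 - 3*sqrt(eta4)) / (1 + sqrt(eta4))`` — necessary (not
      sufficient) for instability; in particular mRNA must be more stable
      than protein (``eta3 < 1``);
    * membership band for ``eta1`` so that the nullclines intersect on the
      middle branch (necessary for limit cycles).
    """
    from .stability import eta1_band, necessary_condition_eta3

    msgs: list[str] = []
    bistable = params.eta4 < 1.0 / 9.0
    msgs.append(
        f"eta4 = {params.eta4:g} {'<' if bistable else '>='} 1/9: p nullcline "
        f"{'has' if bistable else 'lacks'} two positive turning points"
        + ("" if bistable else " (condition not satisfied)")
    )
    consistent = params.eta2 < params.eta4
    msgs.append(
        f"eta2 = {params.eta2:g} {'<' if consistent else '>='} eta4 = {params.eta4:g}: "
        + (
            "consistent with positive dimensional parameters"
            if consistent
            else "no positive dimensional parameter set maps here (condition not satisfied)"
        )
    )
    bound = necessary_condition_eta3(params.eta4)
    unstable_possible = bistable and params.eta3 < bound
    msgs.append(
        f"eta3 = {params.eta3:g} vs necessary bound {bound:g}: instability "
        f"{'possible' if unstable_possible else 'impossible (condition not satisfied)'}"
    )

    band: tuple[float, float] | None = None
    if bistable:
        lo, hi = eta1_band(params)
        lo_eta1, hi_eta1 = lo * params.eta3, hi * params.eta3
        if lo_eta1 < hi_eta1:
            band = (lo_eta1, hi_eta1)
            inside = lo_eta1 < params.eta1 < hi_eta1
            msgs.append(
                f"middle-branch intersection band eta1 in ({lo_eta1:g}, {hi_eta1:g}); "
                f"eta1 = {params.eta1:g} is {'inside' if inside else 'outside'}"
            )
        else:
            msgs.append("middle-branch intersection band is empty")
    else:
        msgs.append("middle-branch band undefined (eta4 >= 1/9)")

    return RegimeReport(
        nullcline_bistable_branch=bistable,
        dimensional_consistency=consistent,
        instability_possible=unstable_possible,
        eq15_band=band,
        messages=tuple(msgs),
    )
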