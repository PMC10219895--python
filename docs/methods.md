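# Methods

## Model and assumptions

The package analyses a planar ODE model of a self-regulating gene: protein
dimer represses transcription (Hill coefficient 2, IC50 `P0`), and an
intermediary `X` — produced under the same promoter and assumed at fast
quasi-equilibrium — inhibits translation, so that translation switches
sigmoidally from the basal rate `k3` to `k3 + k4` as protein accumulates.
All analysis is done on the nondimensional form (time in units of the
protein lifetime `1/k5`); the dimensional layer is an exact, invertible
rescaling kept in `params.py`. The map is degenerate in one known way:
`alpha` and `X0` enter only through `alpha/X0`, which the API accepts
separately but reports as a ratio.

Parameter validation rejects zero as well as negative values; limiting
regimes (e.g. the vanishing-intermediary limit `alpha -> 0`, where
`eta2, eta4 -> 1` and the translation switch disappears) are exercised with
small positive values. All printed regime inequalities are evaluated
strictly: boundary equality (e.g. `eta4 = 1/9` exactly) reports "condition
not satisfied", matching the open-region character of every statement the
analysis makes.

## Nullclines and steady states

Turning points of the p nullcline solve a biquadratic and are computed in
closed form (no iteration); degeneracy is declared when the discriminant
`(1-3 eta4)^2 - 4 eta4` is within 1e-14 of zero. The steady state solves a
quintic; roots come from companion-matrix eigenvalues, are accepted as
real-positive when `|Im| <= 1e-9 max(1, |Re|)` and `Re > 1e-12`, and are
polished by damped Newton steps (residual contract `|h(p*)| <= 1e-9`).
Steady-state uniqueness is not proved symbolically; it is enforced as a
sampled falsification target over the biologically relevant region,
operationalised as log-uniform draws with `eta4 in (1e-4, 1/9)`,
`eta2 in (1e-5, eta4)` (so a positive dimensional origin exists),
`eta3 in (1e-3, 10)`, `eta1 in (1e-3, 10)` (`sampling.py`). Multi-root
outcomes outside that region are flagged (`unique=False`), never raised;
downstream stability analysis refuses them explicitly.

The Jacobian's (2,2) entry shares its quartic numerator with the
turning-point condition; below `eta4 = 1/9` it is evaluated in the factored
form `(p^2 - p1^2)(p^2 - p2^2)` to avoid cancellation near the turning
points. Determinant positivity at a unique steady state is a checked
assertion (a violation is an implementation bug by construction) plus a
1e5-draw sweep in the acceptance layer.

## Hopf locus and criticality

The locus is analytic: trace zero happens exactly at the closed-form
interval boundaries `p_c±`, and the monotone steady-state relation
`eta1(p*)` maps them to the two Hopf `eta1` values. No continuation
machinery is used — where a continuation package would trace the loop in
the `eta1`–`eta3` plane numerically, the closed form is exact. Criticality
is the sign of the first Lyapunov coefficient, computed by transforming the
system to the rotational normal-form frame with an explicit linear change
of variables and applying the standard planar cubic formula; the second-
and third-order partial derivatives of the right-hand side are hand-derived
and unit-tested against central finite differences (relative step 1e-4,
agreement 1e-4 with magnitude-scaled absolute floors, since one tensor
entry crosses zero near `p = sqrt(eta2/3)`). Coefficients below 1e-10 in
magnitude are reported "undecided" rather than forced into a class.

The saddle-node of limit cycles below a subcritical Hopf point is located
behaviourally: a state on the stable cycle just above the Hopf point warm-
starts a bisection on "does the cycle survive at this eta1", with relative
tolerance 1e-3. For a supercritical Hopf the same bisection collapses onto
the Hopf point, which doubles as the no-hysteresis control. At the
canonical set (`eta3 = 0.02`) the window is ≈1.4% of `eta1_Hopf` wide, so
coexistence probes must target it precisely; probing at, say, 5% below the
Hopf point lands outside the window and correctly finds only the steady
state.

## Time integration and attractor detection

`solve_ivp` with LSODA (stiffness-switching), defaults `rtol = 1e-8`,
`atol = 1e-10`, dense output on. Protein maxima are solver *events* on
`dp/dtau` (falling zero-crossings of the right-hand side along the dense
solution), not finite differences of output samples — sampling-grid
aliasing would otherwise dominate in the stiff relaxation regime.
Trajectories are confined to `[0, C_m] x [0, C_p]` with
`C_m = max(m0, eta1/eta3)`; excursions below `-1e-9` (relative) abort.

Attractor classification, applied after discarding the first half of the
run: *steady* if the trailing 10% window varies under 1e-6 relative (or
under 1e-5 while anchored at the computed fixed point to 1e-5 — solver
interpolation noise sits near the 1e-6 line at default tolerances);
*limit cycle* if there are at least six protein maxima in total, at least
three post-transient inter-peak intervals agreeing to 0.1%, peak heights
agreeing to 0.1%, and the peak-to-trough amplitude at the start and end of
the window agreeing to 0.5% — the amplitude check is what separates a true
cycle from a slowly decaying spiral near a weakly stable focus, whose peaks
are evenly spaced and of nearly constant height; anything else is
*undecided*, and the driver re-runs with doubled `t_end` (up to three
doublings). Default initial condition is `(0, 0)`; the coexistence probe
draws its extra initial conditions log-uniformly in the confined box behind
a single seed, and `eta1` scans warm-start each run from the previous final
state (continuation on the stable attractor).

Periods reported by simulation are means of the late inter-peak intervals;
they are invariant to ±0.2% under halving the solver tolerances at the
canonical set (convergence check in the suite).

## Relaxation asymptotics

The corner points, two-segment period lower bound and amplitudes are exact
evaluations of the fast–slow leading-order formulas. The regime boundary is
`eta4 = 1/16` (log argument 1): exactly there the slow-return term is zero
and the estimate degenerates to `1/(2 eta1 sqrt(eta4))`; beyond it the
function raises rather than return a negative "period" term. The correction
for time spent near the p nullcline's local maximum is deliberately out of
contract: the estimate is documented as a lower bound only, and the
simulated/estimated ratio at the stiff reference set (`eta1 = 0.009`,
`eta3 = 0.0003`) is ≈1.065, decreasing monotonically toward 1 as the mRNA
timescale is slowed by further factors of 10 and 100.

Two subtleties of the leading-order corner arithmetic worth knowing: the
exact corner difference `m_B - m_A = (1+eta4)/(2 sqrt(eta4)) - (2-2 eta4)`
is noticeably below the leading-order amplitude `1/(2 sqrt(eta4))` at
moderate `eta4` (3.07 vs 5 at `eta4 = 0.01`), and the corner abscissae
coincide with the exact turning points only to leading order (`p_B` sits a
hair below the exact `p1`, `p_D` a hair above the exact `p2`). The module
exposes both the exact corner values and the leading-order figure.

The dimensional period/amplitude formulas come in two flavours:
the closed forms in rate constants (leading order in large `k4/k3`,
`alpha/X0` — they drop "+1" terms) and the exact rescaling of the
dimensionless estimates by the model scales. At the canonical dimensional
set they differ by ≈0.5%; the difference shrinks like the inverse ratios.
The amplitude ratio `A_P/A_M = k4/k5` is exact in both flavours.

## Problem sizes and numerical defaults

Sweep sizes are chosen so the full suite runs in well under half an hour on
one CPU: 1e5 draws for determinant positivity, 1e4 for uniqueness and for
trace/interval consistency, 1e3 for sign-structure checks; simulations use
`t_end` between 500 (canonical set, period ≈84) and ≈12.5 estimated periods
(stiff sets), with the doubling fallback absorbing slow cases. The Hopf
locus grids use 140 points over `eta3 in (0.01, 0.7)`, resolving the loop
closure at the necessary bound (≈0.636 for `eta4 = 0.01`) to within one
grid step. The `eta1` period scan uses 12 points spanning the band
(0.25–4.4), enough to exhibit the fall–rise–fall shape of the period curve.

## Known limitations

* The analysis layer trusts the planar structure: no delays, no
  stochasticity, no intercellular coupling.
* Uniqueness and determinant positivity are sampled properties, not proofs;
  the sampled region is the package's operational definition of
  "biologically relevant".
* The relaxation estimate is a lower bound; no higher-order correction or
  matched asymptotics are implemented.
* Criticality near the sign change of the Lyapunov coefficient (between
  `eta3 = 0.2` and `0.6` at the canonical `eta2`, `eta4`) is numerically
  delicate; the exact switch point is located by bisection and reported,
  not asserted against any external value.
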