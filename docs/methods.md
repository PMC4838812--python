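# Methods

## Model

The package implements the four-population extension of the Jansen–Rit
cortical column used throughout the Wendling line of epilepsy models.
Pyramidal cells receive recurrent excitation (gain A, rate a), slow
dendritic inhibition (B, b), fast somatic inhibition (G, g) and an external
pulse density p(t); the fast interneurons are themselves inhibited by the
slow ones (connectivity C6). Every pathway is the critically damped
second-order filter ÿ = K·k·u − 2k·ẏ − k²·y, whose DC gain is K/k — all
steady-state algebra in `dynamics` uses A/a, B/b, G/g. Population firing is
the sigmoid S(v) = 2e₀/(1+e^{r(v₀−v)}), evaluated through the logistic
`expit` so it is exact and overflow-free for any voltage.

Connectivity and rate constants are fixed at the standard values
(a=100 s⁻¹, b=50 s⁻¹, g=350 s⁻¹; C1=135, C2=C7=0.8·C1, C3=C4=0.25·C1,
C5=0.3·C1, C6=0.1·C1). The synaptic gains default to A=5 mV, G=20 mV with
B the principal bifurcation parameter. G=20 is used for all four standard
regimes; it is the unique value consistent with the published equilibrium
PSPs (inverting y₃ = (G/g)·C7·S(C5·y₀ − C6·y₄) at the background
equilibrium gives G = 20.0).

### Full and reduced formulations

The full system has ten equations because the slow-inhibition firing rate
S(C3·y₀) is filtered twice by the same (B, b) filter — once scaled by C4
toward the pyramidal cells, once unscaled toward the fast interneurons.
From zero initial conditions the two filter outputs satisfy y₂ = C4·y₄ and
y₇ = C4·y₉ identically, so one filter can be dropped. The reduced
8-equation system keeps the unscaled PSP (renamed y₂), multiplies it by C4
in the pyramidal sum (output y₁ − C4·y₂ − y₃) and drives the fast
interneurons with C6·y₂. State mappings in both directions are provided;
mapping a full state that violates y₂ = C4·y₄ beyond tolerance is an error
rather than a silent projection, because such states are unreachable from
rest and the reduction is not defined for them.

Two transcription choices in the reduced system deserve a note. First, the
fast-inhibition drive must couple to the slow-inhibition PSP (the renamed
y₂), not to the pyramidal velocity that inherited the name y₄ after
renaming — the latter reading breaks the exact full/reduced equivalence
that the reduction exists to provide. The equivalence is enforced by a test
that integrates both systems with identical noise for 10 s under all three
schemes and requires agreement to 10⁻⁹ mV. Second, the reduced output
projection y₁ − C4·y₂ − y₃ is forced by the identity y₂(full) = C4·y₂(reduced).

### Input noise

p(t) has mean m = 90 s⁻¹ and standard deviation σ = 30 s⁻¹ (variance 900).
The dispersion of this drive is often quoted as "30" with an ambiguous σ²
notation; taking 30 as the SD is the reading under which the package
reproduces the published output variances of both integration schemes
(≈0.075 mV² for classical RK4 at h=1 ms, ≈0.078 mV² for the stochastic
Euler), whereas variance 30 gives output variances ~30× too small. The
noise level affects only the stochastic experiments; equilibria and
bifurcations use the mean drive.

## Integration

All schemes are fixed-step with one standard-normal draw per step from a
seeded PCG64 generator; a run is fully determined by (parameters, scheme,
h, duration, seed), and repeated runs are bit-identical.

* `euler_classical` / `rk4_classical` substitute p_n = m + σ·r_n as a
  constant input for the whole step (held across all four RK4 stages).
  This is the legacy treatment: the noise term enters the update scaled by
  h, so the output variance scales ∝ h instead of converging. Holding the
  draw across RK4 stages (rather than redrawing per stage) is what makes
  the h=1 ms classical run identical between Euler-family and RK4-family
  noise handling conventions and reproduces the published variance decade
  decay 0.075 → 0.0065 → 0.0006 for h = 1, 0.1, 0.01 ms.
* `euler_sde` advances the drift (evaluated with the mean drive m) by h and
  adds the Wiener increment A·a·σ·√(h_ref·h)·r_n to the pyramidal-input
  velocity (y₆ full / y₅ reduced), the only equation containing noise. The
  reference step h_ref = 1 ms calibrates the noise so that at h = h_ref
  the update is algebraically identical to classical Euler — a property
  asserted to 10⁻¹⁰ over 10 s — while at other steps the √h scaling keeps
  the output variance stable (≈0.07–0.08 mV² from h = 1 ms to 0.01 ms).

Variance experiments simulate 11 s from rest and discard the first 1 s;
variances are population (divide-by-N) over the remaining 10 s (≥10⁴
samples, where the convention is immaterial but fixed for
reproducibility). A 10-s variance estimate of this strongly autocorrelated
output fluctuates by roughly ±15% across seeds; quantities quoted from
these experiments are means over several seeds (8 for the 1 ms classical
and 0.01 ms stochastic runs, 3 for the expensive 0.01 ms classical run).

The phase driver runs an ordered list of (B, G) regimes with the state
carried continuously across boundaries and a single continuous noise
stream, reporting per-segment means and variances after a per-segment
transient discard. DC removal offers exact mean subtraction and a
first-order recursive high-pass (coefficient α = 1/(1+2πf_c h)), validated
against the analytic one-pole response.

Divergent integrations (non-finite state) raise an error naming the step
rather than returning garbage; this triggers readily when h exceeds the
stability limit ≈ 2/g ≈ 5.7 ms of the fast-inhibition filter.

## Equilibria and bifurcations

Setting all derivatives to zero collapses the system to one scalar
equation for the output voltage,
y_out = (A/a)(p + C2·S(C1·y₀)) − (B/b)·C4·S(C3·y₀) − (G/g)·C7·S(C5·y₀ − C6·y₄)
with y₀ = (A/a)·S(y_out) and y₄ = (B/b)·S(C3·y₀). Roots are located by a
sign-change scan over y_out ∈ [−20, 40] mV in 0.01 mV steps (a bracket
that covers the sigmoid's entire responsive range with margin), refined by
Brent's method to |F| < 10⁻¹⁰, and merged when closer than 10⁻⁴ mV. Each
root is lifted to the ten-dimensional state by back-substitution and
polished with a Newton–Krylov-free `scipy.optimize.root` (hybr) solve
against the exact drift with the analytic Jacobian, to drift max-norm
< 10⁻⁹. Stability is classified from the eigenvalues of the analytic
Jacobian (dense nonsymmetric solver) with a ±10⁻⁶ marginality band on real
parts; the analytic Jacobian is validated against central finite
differences of the drift to 10⁻⁶ relative error.

The saddle-node in B is localized by bisection on the nullcline root count
and the stability transition by bisection on the sign of the leading
eigenvalue real part at the lone equilibrium; both terminate on bracket
width (defaults 0.01 and 0.005 mV) and report the final bracket midpoint.
At every equilibrium the full spectrum equals the reduced spectrum plus a
double eigenvalue at −b = −50 s⁻¹ (the dropped redundant filter); this is
asserted on a 50-point B sweep. The numerical comparison allows ~10⁻⁵
because the −50 pair is defective (a Jordan block), so round-off splits it
by the square root of the working precision.

Limit-cycle existence in the sustained-spiking regime is established only
indirectly (unique unstable equilibrium plus bounded noise-free
oscillation in simulation); no Floquet analysis is performed.

## Known discrepancies with the published low-B analysis

Two published results could not be reproduced from the model's own
equations, and the corresponding checks in `tests/test_acceptance.py`
fail by design rather than being weakened:

1. **Eigenvalues of the gamma-regime (B=8) equilibrium.** At the verified
   equilibrium (y_out = 10.004 mV, reproduced to the printed precision)
   the spectrum is {−376.4±86.5i, −100.5, −99.5, −68.9±73.1i, −54.7±39.9i,
   −50, −50} s⁻¹, not the published column containing −172.0. A
   least-squares inversion of the Jacobian couplings shows the published
   column corresponds to a B=8 Jacobian evaluated at a state on the
   *background branch* (sigmoid-slope arguments near (−0.4, 0.6, 0.2,
   −2.0) instead of the true (10.0, 30.5, 7.6, 1.4)), i.e. to a wrong
   linearization point. The published unstable-branch spectra of the
   three-root regimes also deviate by up to several s⁻¹ in single entries
   — those eigenvalues are extremely sensitive to the linearization state
   and cannot be pinned down from 3-decimal printed equilibria. The stable
   columns and the B=37 column reproduce to ≤0.06 s⁻¹ per part.
2. **Location of the low-B stability transition.** The leading eigenvalue
   real part of the lone equilibrium crosses zero at B ≈ 13.147 (a
   supercritical Hopf: downward continuation of the limit cycle shows it
   dying there with no hysteresis), not between 9.21 and 9.22. This is
   consistent with discrepancy 1: both stem from the same low-B
   linearization. The saddle-node at B = 37.29, by contrast, reproduces
   the published 37.3 exactly.

All other published quantities used as references — the eight equilibrium
points, their stability labels, the saddle-node location, the classical
variance decade decay and the stochastic-scheme variance stability — are
reproduced within the stated tolerances.

## Problem sizes

Acceptance-level computations use: 6001-point nullcline scans; ≤12
bisection steps per bifurcation; 11-s simulations (10⁴–10⁶ steps depending
on h) for the variance experiments; 10-s, 10⁴-step runs for the
equivalence identities; 5-s noise-free runs for the perturbation
cross-checks. Everything runs in a few minutes on one CPU.

## What the tests do and do not show

The simulations here are the model's own study conditions, not synthetic
stand-ins for clinical data: every reference quantity is produced by the
model itself. Passing tests therefore demonstrate correctness of the
implementation and reproducibility of the published *model* analysis; they
say nothing about how well the model describes physiological depth-EEG
(in particular, the DC offsets it predicts have no electrochemical
mechanism behind them, and the ictal regime's parameters are not
published — the phase driver exposes them via config but nothing validates
them).
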