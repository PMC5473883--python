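# Methods

## The model

A network of N two-level sites (plus, optionally, a reaction center) is
prepared in a state ρ₀, node A is measured at time 0 with a POVM
{F_{a|x}}, and the post-measurement branches

ρ_{a|x} = (√F_{a|x} ⊗ 1) ρ₀ (√F_{a|x} ⊗ 1)

are propagated with a Markovian (Haken-Strobl type) master equation

ρ̇ = −i[H, ρ] + Σ_k γ_k (2 A_k ρ A_k† − A_k†A_k ρ − ρ A_k†A_k),   ħ = 1.

Reducing each evolved branch to the target node's qubit gives the
spatio-temporal assemblage σ_{a|x}(t).  Note the *prefactor-free*
dissipator convention: there is no factor ½ in front of the sandwich term.
A σ_z dephaser at rate γ therefore damps site-vacuum coherences at 4γ and
site-site coherences at 8γ.  Because D[σ_z] = 4·D[P_e] = 8·D_std[P_e]
(P_e the excited-state projector, D_std the standard ½-prefactor form),
rates quoted in other conventions must be divided by 4 or 8 before being
used here; `ststeer.units` provides the helpers.

### Restricted state space

Every shipped scenario starts in the span of the vacuum and the
single-excitation states, and the generators preserve that sector: hopping
Hamiltonians conserve excitation number, σ_z dephasers are diagonal in the
site basis, and the sink moves the excitation from site 3 to the reaction
center inside the sector.  All operators are therefore represented on the
(N+1)- or (N+2)-dimensional 0/1-excitation sector instead of the full 2^N
tensor space.  This is exact — the test suite propagates three-qubit cases
in both representations and checks agreement to 1e−8 — and makes the FMO
model a 9×9 problem.  The measurement embedding is likewise the sector
restriction of √F ⊗ 1; it is exact whenever the initial state carries no
excitation outside the measured site, which holds for every shipped
scenario and is the regime in which the sector picture is meaningful.

The vacuum and reaction-center energies are set to zero.  Only energy
*differences* between the excited states and the vacuum enter the target
qubit's coherence, and those are the site energies themselves, so the
choice amounts to a fixed unitary on the target qubit; both steering
measures are invariant under such conjugations (tested).

### Units

Site energies and rates for the FMO model are entered in cm⁻¹ and
converted to angular frequencies by 2πc = 0.188365 rad/ps per cm⁻¹, with
time in picoseconds.  Whether *rates* should carry the same 2πc factor as
energies is a convention; converting both reproduces the expected
timescales — site-3 population drains into the reaction center on the
~1 ps scale at Γ = 5.3 cm⁻¹, and intersite coherences decay on the
~100 fs scale at γ_dp = 7.7 cm⁻¹ — so that is the default, switchable via
`FmoParameters(convert_rates_with_2pic=False)`.  The chain model is
dimensionless (times in 1/J).

### Dephasing rate versus temperature

An Ohmic environment treated in the Born-Markov limit gives a pure
dephasing rate proportional to temperature.  The proportionality constant
is anchored at the single calibration point (15 K, 7.7 cm⁻¹):
γ_dp(T) = (7.7/15)·T cm⁻¹.  No spectral-density machinery is implemented.

## The steering programs

With m settings and o outcomes, the hidden-state model can be restricted
to the o^m deterministic response strategies without loss of generality
(convex weights are absorbed into ρ_λ = p(λ)σ_λ); the enumeration is
capped at 4096 strategies (configurable).  All programs receive members
that are Hermitized and eigenvalue-clipped at 0 (members below −1e−6 are
rejected as invalid) to absorb integrator noise.

* **Weight**: min 1 − tr Σ ρ_λ s.t. σ_{a|x} − Σ_λ d_λ(a|x)ρ_λ ⪰ 0, ρ_λ ⪰ 0.
* **Robustness**: min tr Σ ρ_λ − 1 s.t. Σ_λ d_λ(a|x)ρ_λ − σ_{a|x} ⪰ 0, ρ_λ ⪰ 0.
  The optimal noise assemblage is recovered from the certificate as
  τ_{a|x} = (Σ_λ d_λ(a|x)ρ_λ − σ_{a|x})/α; it is not a separate decision
  variable (algebraically equivalent, fewer variables).
* **Feasibility** is solved independently of both measures in two phases:
  the linear system σ_{a|x} = Σ_λ d_λ(a|x)ρ_λ, tr Σρ_λ = 1 over Hermitian
  ρ_λ by least squares (signalling assemblages — which no hidden-state
  model can produce — already fail here), then minimisation of the uniform
  eigenvalue shift t with ρ_λ + tI ⪰ 0 over the affine solution set.
  Feasible iff both the linear residual and t* are ≤ 1e−7.

Signalling assemblages are deliberately legal inputs: measurement
disturbance propagating through the channel is the phenomenon being
quantified, so validation reports the signalling deviation but never
rejects.  Zero-probability members are retained (they only weaken
constraints).

"Steerable" is declared when a measure exceeds 1e−6 and "feasible" at
constraint residual 1e−7; both thresholds are configurable and were chosen
comfortably above solver accuracy (~1e−9) and below any physical value in
the shipped scenarios.

### SDP solver

The programs are tiny (≤ ~40 constraints, 2×2 Hermitian blocks), so the
package carries its own dense primal-dual interior-point solver (HKM
search direction, Mehrotra predictor-corrector, infeasible start) with all
block operations batched over equally-sized blocks.  Defaults: duality-gap
tolerance 1e−9, residual tolerance 1e−8, at most 200 iterations; on
boundary optima (rank-deficient members, e.g. pure conditional states) the
solver returns its best iterate once progress stalls, which in practice
still carries a ≲1e−8 gap.  A typical steering solve takes 5–10 ms.

Correctness is cross-checked three ways in the test suite: against
closed forms for the Werner family derived by symmetrising the programs
(STSW = (√3p−1)/(√3−1), STSR = (√3p−1)/(√3+1) above the p = 1/√3
threshold, zero below), against a second, independently coded encoding of
each program (inequality/LMI form over the Hermitian components of ρ_λ
versus equality-constrained conic form with slack blocks), and against the
mutual zero-set agreement of all three programs on batches of steerable
and unsteerable assemblages.

### Integration

The master equation is vectorized (row-major) into a d²-dimensional linear
ODE and integrated with an adaptive high-order Runge-Kutta scheme
(DOP853), rtol 1e−10 and atol 1e−12 by default.  The tight tolerances keep
the SDP inputs clean; a trajectory whose trace drifts by more than 1e−6 is
rejected outright.  Scans evolve each measurement branch once over the
whole grid, then solve one SDP per time point.

## Synthetic generators

* `unsteerable_fixture(seed, ...)` draws Dirichlet hidden-state weights,
  deterministic response tables and Ginibre-random qubit states and builds
  the assemblage directly from the hidden-state model, so it is
  unsteerable by construction — these fixtures probe the *zero* sets of
  the programs, not their positive values.
* `werner_scenario(p)` is the identity-channel (EPR) reduction with a
  calibrated steerable/unsteerable family and known closed-form measure
  values.
* `discard_channel_scenario()` replaces the target by a fixed state — a
  null model of a fully broken link whose measures vanish identically.

What these generators do *not* emulate: non-Markovian environments,
finite-temperature detailed balance, multi-excitation states, generalized
(non-projective) measurements, and measurement imprecision.  Passing tests
therefore certify the programs and the Markovian sector dynamics, not the
behaviour of real FMO spectroscopy data.

## Problem sizes

The test suite runs the SDP batch at 200 unsteerable + 50 steerable cases,
the chain scans at 100 points per dephasing rate, and the FMO scans at 60
points per target site; the reproduction script uses 50 fixtures, 60-point
chain scans and 40-point FMO scans.  These sizes give grid resolutions
(0.1/J and 17–26 fs) well below the structure in the curves while keeping
a full run in the seconds-to-minutes range on one CPU.

## Known limitations

* The FMO dephasing convention is ambiguous in the literature: the same
  "7.7 cm⁻¹ at 15 K" figure can be read as the σ_z-jump rate used here or
  as a projector-convention rate (factors 4 or 8 smaller when translated).
  The default takes it literally as the σ_z rate, which reproduces the
  ~100 fs dephasing timescale.  Under this reading the site-6→site-5
  robustness dominates and site 7 carries the second-largest peak, but the
  site-7 peak *precedes* site 5's and its death time is shorter; under the
  divided-by-8 (or /4) readings the site-7 peak is instead delayed (and,
  for /4, longest-lived), at the price of slower-than-~100 fs dephasing.
  `FmoParameters(gamma_dp_cm1=...)` exposes the choice.
* The chain's dephasing dissipator form (σ_z jump on qubit 2) is chosen
  for consistency with the FMO model; published chain plots depend on this
  unstated convention, so chain behaviour is asserted qualitatively
  (oscillation, peak suppression, delayed growth), never numerically.
* Only one measured node and one target node; no multipartite steering,
  no measurement-incompatibility analysis, no optimisation over POVMs.
* The eighth FMO site, excitonic fluorescence relaxation (~1 ns) and
  hierarchy-equation (non-Markovian) treatments are out of scope.
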