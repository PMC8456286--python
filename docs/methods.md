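# Methods

This note records the models implemented in `efield-orient`, the defaults
and units, the design choices that were genuinely open, and what the
synthetic generators do and do not capture.

## Units and constants

All public interfaces use ns (time), nm (length), V/nm (field), e
(charge), amu (mass), eV (energy) and eV/Å (force). PDB coordinates are
converted Å → nm on read. Fixed constants: 1 e·nm = 48.0321 D;
kB = 8.617333262×10⁻⁵ eV/K; 1 eV = 9.648533×10⁷ amu·nm²/ns² (the internal
energy unit of the integrator). Unit names appear in every file header
(`time_ns`, `mux` [e·nm], `rmsd_nm`, `fmag` [eV/Å]) and are never guessed.

## Field protocol

`E(t) = E0·exp(−(t−t0)²/(2σ²))` for `t < t0`, `E0` afterwards; both
branches equal `E0` at `t = t0`, so the pulse is continuous, bounded by
`[0, E0]` and nondecreasing on the ramp. The width σ is not dictated by
the problem; the default σ = t0/3 makes `E(0) = E0·e^{−4.5} ≈ 1.1% E0`, so
the pulse effectively starts from zero and degenerates cleanly to the
step case at `t0 = 0`. σ is a configuration field, so other choices are
testable. Time starts at t = 0 (the simulation clock); no field before
t = 0 is modelled.

## Orientation statistic and decay fit

The dipole is `μ = Σ qᵢ (rᵢ − r_COM)` with a **mass-weighted center of
mass** as reference point. For a net-charged molecule (electrosprayed
ubiquitin carries +7 e) the dipole is origin-dependent; the COM is chosen
because rotation about the COM is the frame in which the field torque
acts, making it the physically relevant reference for orientation
dynamics.

Θ = 1 − cos θ is dimensionless, magnitude-independent and lies in [0, 2].
Frames with an exactly vanishing dipole have no defined angle; they are
flagged and carried as NaN, never dropped silently.

The decay fit is a single-parameter nonlinear least squares of
`f(t) = exp(−k t)` (scipy `curve_fit`, log-linear starting value) against
the **replica-mean** Θ̄(t): averaging precedes fitting; per-replica fits
are a diagnostic only. The amplitude is fixed at 1 — the replica starting
geometry (dipole ⊥ field) makes Θ̄(0) ≈ 1, and the fitted form carries no
amplitude — with a free-amplitude mode available but off by default. No
smoothing or normalization is applied before fitting; the oscillations in
Θ̄ are treated as residuals of the least-squares problem. τ = ln(10)/k, so
under the fitted model exactly 90% of the initial orientation is lost at
τ; k ≤ 0 or a failed fit yields an explicit infinite-τ / not-oriented
flag, and E(τ) for such a fit raises rather than returning a number.

The dipole projection map measures alignment as the **polar angle to the
field axis** (a cone, default half-angle 15°), not a per-plane angle;
frames with the dipole exactly on the axis have no azimuth and are
excluded from the azimuth histogram but counted as aligned. For uniformly
random orientations the aligned fraction equals the spherical-cap area
fraction (1 − cos 15°)/2 ≈ 0.0170.

## Structure metrics

RMSD is computed after least-squares optimal rigid superposition (Kabsch,
via `scipy.spatial.transform.Rotation.align_vectors`, proper rotation
enforced; the residual is evaluated explicitly because the SVD by-product
loses ~8 digits to cancellation for near-identical sets). Superposition
is unweighted over the supplied atoms — conventionally Cα only. The
trajectory reference defaults to the first production frame and can be
set to the crystal structure; both are supported because the "earlier
time point" convention is ambiguous. Preservation uses RMSD ≤ 0.5 nm with
the boundary counted as preserved. `rmsd_at` interpolates linearly; RMSD
series are sampled densely enough that the interpolation choice is
second-order. The plateau RMSD averages over `[t0 + 5 ns, end]`, which is
why long-ramp (t0 = 9 ns) runs must last 14 ns.

## Force analysis

Bond forces are tabulated energy / equilibrium length. The shipped table
(C–N, C–C, C–S, C–O, S–S and four hydrogen bonds) reconstructs standard
textbook energy/length pairs, recorded per entry in `forces.py`; the
quotients land on the conventional ~2.0/2.2/1.4/2.5/1.3 eV/Å (covalent)
and 0.08–0.20 eV/Å (hydrogen-bond) values. The 1 eV/Å dissociation
threshold is a named constant justified qualitatively by the ~25%
bond-extension failure criterion; it is ~76% of the S–S force — a lower
estimate, deliberately conservative. The mean relative force implements
`(1/N) Σ (|Fᵢ(E)| − |Fᵢ(0)|)` literally: magnitudes per atom first, no
outer absolute value, negative terms retained. Subtracting the zero-field
magnitudes removes the center-of-mass and vibrational contributions, so
only the field-induced force survives. The breaking field is the first
threshold crossing of the scan, linearly interpolated; a non-monotone
curve warns but still reports the first crossing, and a scan that starts
above threshold returns a flagged lower bound.

## Rigid-dipole Langevin rotor

State: orientation quaternion q and body-frame angular momentum l.
Dynamics: `dl/dt = torque(μ×E) − γ l + noise`, with noise variance
`2γ·kB·T·I_a` per principal component (fluctuation–dissipation), entering
the angular momentum — not the orientation. Integrator: symmetric
splitting (half torque kick → half free rotation → exact
Ornstein–Uhlenbeck friction/noise step → half free rotation → half torque
kick), with the free rotation done by the axis-splitting propagator
(half-steps about principal axes 3 and 2, a full step about 1, and back).
This propagator conserves the lab-frame angular momentum exactly and
shows no secular energy drift; quaternions are renormalized every step.
The inner loop is numba-compiled; all randomness (initial thermal
momenta, OU noise) flows through one numpy Generator seeded per replica
by a documented counter scheme (SeedSequence keyed by master seed,
condition index, replica index), so trajectories are bitwise reproducible
and grid conditions independent.

Stability guard: `dt ≤ 10⁻³·√(I_min/(μ E0))` (the fastest field-libration
time); a larger explicit dt is rejected with the computed bound, and
`dt = None` picks 0.9× the bound, additionally capped by the thermal
rotation rate and by `γ·dt ≤ 0.05`.

Default system (`ubiquitin_like_rotor`): principal moments
(7000, 7700, 8400) amu·nm² — an 8.6 kDa globule of ~1.5 nm radius with
mild asymmetry — dipole 10.4 e·nm (≈500 D) along body z, net charge +7 e
(recorded only: a homogeneous field exerts no torque through the
monopole), T = 300 K. Friction defaults to γ = 650/ns, which places the
zero-field orientational correlation time near 1 ns via rotational
diffusion (D_r = kB·T/(I·γ), τ_c ≈ 1/(2 D_r)); this is the overdamped
regime. γ is configurable, and the choice matters: a nearly free rotor
(γ → 0) decorrelates ballistically in ~0.06 ns and librates persistently
under the field, while large γ gives clean monotone alignment. No
polarizability is modelled (field-induced electron shifts are local), and
translational motion of the net charge is out of scope.

Study replicas start with the lab dipole along z and the field along x
(Θ(0) = 1, the production-run starting geometry) and draw independent
thermal angular momenta.

## Damage process

`dR/dt = κ·E(t)^p·(1 − R/R_sat)`, integrated with the exact one-step
solution of the linear ODE using the midpoint field, so a constant field
reproduces the closed form `R(t) = R_sat − (R_sat−R0)·e^{−κE^p t/R_sat}`
to machine precision; R is nondecreasing and bounded by R_sat for any
protocol. Defaults κ = 0.015 nm/ns·(nm/V)², p = 2, R_sat = 1.2 nm,
R0 = 0.15 nm were chosen once so that on 10 ns runs fields ≤ 1.5 V/nm
keep R below the 0.5 nm preservation threshold while fields ≥ 2.5 V/nm
cross it within a few ns — the published plateau phenomenology. The
quadratic field dependence reflects that both the force on a partial
charge and the number of destabilised contacts grow with E.

## Θ-ensemble generator

`Θ_r(t) = clip(exp(−k t)·(1 + A sin(ωt + φ_r)) + ε_r(t), 0, 2)` with a
uniform random phase per replica and iid Gaussian noise per sample.
Defaults A = 0.2, noise sd = 0.05, oscillation period 0.5 ns, 10
replicas, 10 ns at 10 ps sampling — an ensemble that oscillates visibly
but decays clearly, as replica MD ensembles do. Random phases make the
oscillation average toward zero across replicas, which is what lets the
single-exponential fit recover k to ~1% (well inside the 5% recovery
budget) despite 20% oscillation amplitude.

## Study orchestration

The reference grid is E0 ∈ {0.1, 0.2, 0.5, 0.8, 1.0, 1.5, 2.5, 3.0} V/nm
× t0 ∈ {0, 2, 5, 9} ns × 10 replicas = 320 runs, 10 ns each, extended to
14 ns for t0 = 9 ns so the plateau window fits. Per condition the
orchestrator reports the final-window Θ̄ (default last 2 ns), the decay
fit, τ, E(τ), RMSD(τ), plateau RMSD and preservation flags; a failing
condition is recorded in its row without aborting the grid.

## What the synthetic stand-ins do and do not show

The rotor and the damage/Θ generators replace all-atom MD because the
analysis chain only needs trajectories with the right statistical
structure. Tests on them therefore validate the *pipeline* —
statistics, fitting, metrics, orchestration — and the *qualitative*
physics: τ decreases with E0, increases with ramp time t0, and structure
is preserved at the orientation time ("orientation before destruction").
They do not reproduce absolute all-atom numbers (orientation times from
ns down to ps, the ~0.5 V/nm minimal orienting field, the ~45 V/nm
breaking field): those require all-atom MD and electronic-structure
calculations, which are out of scope here.

One qualitative feature is also out of the rotor's reach: the near
t0-independence of E(τ). A rigid 500 D dipole at 300 K orients at fields
of order kT/μ ≈ 0.003–0.03 V/nm, far below the study grid, so its
orientation is ramp-rate-limited and E(τ) tracks the ramp (measured
variation across t0 is a factor ~2–5, not ~1). The flat ~0.5 V/nm
threshold of the real protein reflects internal friction and structural
coupling that a rigid body does not have. E(τ) is still computed and
reported per condition, but no flatness is asserted.

## Problem sizes used by the test suite

Tests run desk-scale versions of every check: the integrator conservation
test uses 10⁶ steps of a free spherical top (conservation is exact there;
an asymmetric-top variant runs 10⁵ steps), equipartition uses a 16-replica
ensemble totalling ~2×10⁶ steps, the pendulum-frequency check ~2×10⁴
steps, and the trend study a 3×3 grid (E0 ∈ {0.5, 1, 2} V/nm,
t0 ∈ {0, 0.3, 0.6} ns, 8 replicas, 1 ns runs) — sizes at which the
assertions are deterministic for the fixed seeds while the full suite
stays fast. The reference 320-run design is enumerated and its seeds
checked without simulating all of it.

## Known limitations

- The exponential fit is a summary statistic: for strongly sigmoidal Θ̄
  (long ramps, strong fields) k is an effective rate and τ inherits that
  smearing. This mirrors the fitting convention rather than improving it.
- The damage model is phenomenological; κ, p, R_sat have no microscopic
  derivation and are calibrated to reproduce plateau behaviour only.
- Hydrogen-bond "forces" from energy/length division are order-of-
  magnitude markers, not mechanics.
- CSV ingestion covers the documented dialects only; binary MD trajectory
  formats are intentionally unsupported.
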