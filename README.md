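# efield-orient

Analysis toolkit for the orientation of gas-phase proteins in
**time-dependent electric fields**, aimed at single-particle-imaging (SPI)
style experiments where electrosprayed proteins must be field-aligned
before an x-ray pulse arrives. The package implements the full analysis
chain around that problem — the field pulse protocol, the orientation
statistic and its exponential decay, structural-preservation metrics, and
bond-force limits — plus a rigid-dipole Langevin rotor simulator and noise
generators that provide seed-reproducible synthetic ensembles in place of
all-atom MD trajectories.

## The model

**Field protocol.** The field ramps up as a Gaussian and then stays at its
peak:

    E(t) = E0 · exp(−(t − t0)² / (2σ²))   for t < t0
    E(t) = E0                              for t ≥ t0

with strength `E0` (V/nm), ramp end `t0` (ns) and width `σ` (default
`t0/3`, so `E(0) ≈ 0.011·E0`). `t0 = 0` is a constant field.

**Degree of orientation.** With θ the angle between the molecular dipole μ
and the field direction,

    Θ = 1 − cos θ ∈ [0, 2],

so Θ = 0 means aligned, Θ = 1 perpendicular (also the expectation for a
randomly oriented molecule) and Θ = 2 antiparallel. The replica-averaged
Θ̄(t) decays roughly exponentially; fitting `f(t) = exp(−k t)` gives the
**orientation time**

    τ = ln(10) / k,

the time at which 90% of the initial orientation is lost, and `E(τ)` — the
instantaneous field strength at that moment.

**Structural preservation.** Cα RMSD after Kabsch superposition; a
structure counts as preserved while RMSD ≤ 0.5 nm. The package evaluates
RMSD(τ) ("orientation before destruction") and the plateau RMSD reached
5 ns after the field tops out.

**Force limits.** Equilibrium bond forces (tabulated bond energy /
equilibrium length) motivate a bond-dissociation-force threshold of
1 eV/Å; the per-atom mean relative force
`⟨|F(E)|⟩ = (1/N) Σᵢ (|Fᵢ(E)| − |Fᵢ(0)|)` compared against that threshold
along a field scan yields a breaking-field estimate.

**Synthetic engine.** A rigid body with ubiquitin-like inertia and a fixed
body-frame dipole evolves under the torque μ × E(t) with Langevin
friction/noise (fluctuation–dissipation obeyed, axis-splitting free-rotor
propagator, numba-compiled). A saturating damage ODE
`dR/dt = κ E(t)^p (1 − R/R_sat)` emulates field-induced RMSD growth, and a
direct Θ-ensemble generator (exponential trend × oscillation + Gaussian
noise) exercises the fitting pipeline without any dynamics.

## Worked example

```python
import numpy as np
from efield_orient import (
    make_protocol, generate_theta_ensemble, ensemble_mean,
    fit_decay, final_orientation,
)

protocol = make_protocol(e0=0.5, t0=2.0, sigma_rule="t0/3", direction=(1, 0, 0))
replicas = generate_theta_ensemble(
    k_true=1.0, oscillation_amplitude=0.2, noise_sd=0.05,
    n_replicas=10, dt=0.01, duration=10.0, seed=42,
)
mean = ensemble_mean(replicas)
fit = fit_decay(mean)
print(fit.summary())
theta_mean, theta_sd = final_orientation(mean, window=2.0)
print(f"final orientation (last 2 ns): {theta_mean:.4f} +/- {theta_sd:.4f}")
print(f"tau = {fit.tau:.3f} ns, E(tau) = {fit.field_at_tau(protocol):.3f} V/nm")
```

prints

```
      Exponential Orientation Decay Fit
================================================
Model:            theta(t) = A exp(-k t)
Amplitude A:      1  (fixed)
No. observations: 1001
Fit window [ns]:  [0, 10]
Converged:        True
------------------------------------------------
k  [1/ns]:        0.987695   (se 0.00377)
tau = ln(10)/k [ns]: 2.33127
================================================
final orientation (last 2 ns): 0.0192 +/- 0.0097
tau = 2.331 ns, E(tau) = 0.500 V/nm
```

Ten replicas generated with a true rate of 1.0/ns (plus 20% oscillation
and Θ-noise of 0.05) are averaged and fitted: the recovered rate 0.988/ns
is within 1.3% of truth, the molecule is 90% oriented after 2.33 ns, and —
because τ exceeds the 2 ns ramp — the field is already at its 0.5 V/nm
plateau when orientation completes. The final-window Θ̄ ≈ 0.02 confirms a
strongly aligned ensemble.

The same pipeline runs over a full study grid (eight field strengths ×
four ramp times × ten replicas = 320 runs by default) with
`efield_orient.run_study(StudyConfig(...))`, or from the shell:

```bash
efield-orient field eval --e0 2.5 --t0 2 --t 3
efield-orient generate theta --k 1.0 --n 10 --seed 42 --out ens/
efield-orient analyze orient --traj-glob 'ens/theta_replica*.csv' --e0 0.5 --t0 2
efield-orient study run --config study.yaml --out results/
```

## Layout

- `efield_orient.field` — field protocol (`FieldProtocol`, `make_protocol`).
- `efield_orient.orientation` — dipoles, Θ, ensemble averaging,
  `ExponentialDecayModel`/`DecayFitResults`, E(τ), dipole plane projection.
- `efield_orient.structure` — Kabsch superposition, RMSD, preservation.
- `efield_orient.forces` — bond-force table, BDF threshold, mean relative
  force, breaking-field estimate.
- `efield_orient.rotor` — Langevin rotor, damage process, Θ generator.
- `efield_orient.study` — grid orchestration (`StudyConfig`, `run_study`).
- `efield_orient.io` / `efield_orient.cli` — PDB/CSV/YAML formats and the
  `efield-orient` command.

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
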