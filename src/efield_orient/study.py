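"""Study orchestration: the E0 × t0 × replica grid.

The reference study design crosses eight plateau field strengths with four
ramp times and ten replicas — 320 independent runs.  For every (E0, t0)
condition the orchestrator simulates the replica ensemble (rigid rotor or
direct Θ generator), averages Θ over replicas, extracts the final degree
of orientation, fits the exponential decay, derives τ and E(τ), runs the
damage process and evaluates RMSD(τ), the plateau RMSD and the
preservation flags.  Failures are recorded per condition without aborting
the grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as _dc_field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .constants import PRESERVATION_THRESHOLD_NM
from .field import FieldProtocol, make_protocol
from .orientation import (
    NotOrientedError,
    OrientationSeries,
    ensemble_mean,
    final_orientation,
    fit_decay,
    theta_series,
)
from .rotor import (
    DamageParams,
    RotorSystem,
    damage_process,
    generate_theta_ensemble,
    simulate_ensemble,
    ubiquitin_like_rotor,
)
from .structure import is_preserved, plateau_rmsd, rmsd_at

__all__ = ["StudyConfig", "RunSpec", "ConditionResult", "StudyResult",
           "enumerate_runs", "run_study", "replica_seed"]

#: Reference grid: eight field strengths × four ramp times.
DEFAULT_E0_GRID = (0.1, 0.2, 0.5, 0.8, 1.0, 1.5, 2.5, 3.0)
DEFAULT_T0_GRID = (0.0, 2.0, 5.0, 9.0)


@dataclass
class StudyConfig:
    """Configuration of a full orientation study.

    Defaults reproduce the reference design: E0 over eight strengths
    0.1–3.0 V/nm, t0 ∈ {0, 2, 5, 9} ns, σ = t0/3, field along x, 10
    replicas, 10 ns runs extended to 14 ns when t0 = 9 ns (so the plateau
    window t0 + 5 ns fits), preservation threshold 0.5 nm, 2 ns final
    window, 5 ns plateau delay.
    """

    e0_vnm: Sequence[float] = DEFAULT_E0_GRID
    t0_ns: Sequence[float] = DEFAULT_T0_GRID
    sigma_ns: object = "auto"  # "auto" -> t0/3, or explicit ns value
    direction: Sequence[float] = (1.0, 0.0, 0.0)
    n_replicas: int = 10
    seed: int = 0
    duration_ns: object = "auto"  # "auto" -> max(10, t0 + plateau window)
    base_duration_ns: float = 10.0
    dt_ns: Optional[float] = None  # None -> stability-bound based
    engine: str = "rotor"  # "rotor" | "theta"
    system: Optional[RotorSystem] = None  # rotor engine; default ubiquitin-like
    # theta engine: k = k_coefficient * E0 (crude response rule) unless fixed
    theta_k_coefficient: float = 1.0  # (1/ns)/(V/nm)
    theta_k_fixed: Optional[float] = None
    theta_oscillation_amplitude: float = 0.2
    theta_noise_sd: float = 0.05
    theta_dt_ns: float = 0.01
    damage: DamageParams = _dc_field(default_factory=DamageParams)
    preservation_threshold_nm: float = PRESERVATION_THRESHOLD_NM
    final_window_ns: float = 2.0
    plateau_delay_ns: float = 5.0

    def duration_for(self, t0: float) -> float:
        if self.duration_ns == "auto":
            return max(self.base_duration_ns, t0 + self.plateau_delay_ns)
        return float(self.duration_ns)

    def protocol_for(self, e0: float, t0: float) -> FieldProtocol:
        sigma_rule = "auto" if self.sigma_ns == "auto" else float(self.sigma_ns)
        return make_protocol(e0, t0, sigma_rule, self.direction)


@dataclass(frozen=True)
class RunSpec:
    """One planned simulation: a (E0, t0) condition and a replica."""

    e0_vnm: float
    t0_ns: float
    replica: int
    seed: int


def replica_seed(master_seed: int, condition_index: int, replica: int = 0) -> int:
    """Documented counter scheme: seeds are derived from the master seed
    via a SeedSequence keyed by (master, condition index, replica), so
    grids are reproducible and conditions independent."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(condition_index, replica))
    return int(ss.generate_state(1)[0] % (2**31))


def enumerate_runs(config: StudyConfig) -> list[RunSpec]:
    """All runs the grid implies (len = |E0| × |t0| × n_replicas)."""
    runs = []
    cond = 0
    for t0 in config.t0_ns:
        for e0 in config.e0_vnm:
            for r in range(config.n_replicas):
                runs.append(
                    RunSpec(
                        e0_vnm=float(e0),
                        t0_ns=float(t0),
                        replica=r,
                        seed=replica_seed(config.seed, cond, r),
                    )
                )
            cond += 1
    return runs


@dataclass
class ConditionResult:
    """Per-condition outputs: the ensemble-mean Θ̄ series, the decay fit,
    the damage RMSD series and the derived summary scalars."""

    e0_vnm: float
    t0_ns: float
    mean_series: Optional[OrientationSeries] = None
    fit: object = None
    damage_times: Optional[np.ndarray] = None
    damage_rmsd: Optional[np.ndarray] = None
    row: dict = _dc_field(default_factory=dict)
    error: Optional[str] = None


@dataclass
class StudyResult:
    """Grid-level result: one summary row per (E0, t0) condition."""

    summary: pd.DataFrame
    conditions: dict
    config: StudyConfig

    def to_csv(self, path) -> None:
        self.summary.to_csv(path, index=False)

    def condition(self, e0: float, t0: float) -> ConditionResult:
        return self.conditions[(float(e0), float(t0))]


_ROW_COLUMNS = [
    "e0_vnm", "t0_ns", "n_replicas", "theta_final_mean", "theta_final_sd",
    "k_per_ns", "k_stderr", "converged", "tau_ns", "e_at_tau_vnm",
    "rmsd_at_tau_nm", "preserved_at_tau", "plateau_rmsd_nm",
    "preserved_plateau", "error",
]


def _analyze_condition(
    config: StudyConfig, e0: float, t0: float, cond_index: int
) -> ConditionResult:
    protocol = config.protocol_for(e0, t0)
    duration = config.duration_for(t0)
    res = ConditionResult(e0_vnm=e0, t0_ns=t0)

    if config.engine == "rotor":
        system = config.system if config.system is not None else ubiquitin_like_rotor()
        trajs = simulate_ensemble(
            system,
            protocol,
            duration=duration,
            dt=config.dt_ns,
            n_replicas=config.n_replicas,
            seed=replica_seed(config.seed, cond_index),
            initial_orientation="dipole_z",
        )
        series = [theta_series(tr.to_dipole_trajectory(), protocol.direction) for tr in trajs]
    elif config.engine == "theta":
        k_true = (
            config.theta_k_fixed
            if config.theta_k_fixed is not None
            else config.theta_k_coefficient * e0
        )
        series = generate_theta_ensemble(
            k_true=k_true,
            oscillation_amplitude=config.theta_oscillation_amplitude,
            noise_sd=config.theta_noise_sd,
            n_replicas=config.n_replicas,
            dt=config.theta_dt_ns,
            duration=duration,
            seed=replica_seed(config.seed, cond_index),
        )
    else:
        raise ValueError(f"unknown engine {config.engine!r}")

    mean = ensemble_mean(series)
    res.mean_series = mean
    th_mean, th_sd = final_orientation(mean, config.final_window_ns)
    fit = fit_decay(mean)
    res.fit = fit
    tau = fit.tau

    dmg_dt = duration / 5000.0
    d_times, d_rmsd = damage_process(protocol, config.damage, dmg_dt, duration)
    res.damage_times, res.damage_rmsd = d_times, d_rmsd

    e_at_tau = math.nan
    rmsd_tau = math.nan
    preserved_tau = None
    if fit.oriented and tau <= duration:
        e_at_tau = fit.field_at_tau(protocol)
        rmsd_tau = rmsd_at(d_times, d_rmsd, tau)
        preserved_tau = is_preserved(rmsd_tau, config.preservation_threshold_nm)

    plateau = math.nan
    preserved_plateau = None
    if d_times[-1] >= t0 + config.plateau_delay_ns - 1e-9:
        plateau = plateau_rmsd(d_times, d_rmsd, t0, config.plateau_delay_ns)
        preserved_plateau = is_preserved(plateau, config.preservation_threshold_nm)

    res.row = {
        "e0_vnm": e0, "t0_ns": t0, "n_replicas": config.n_replicas,
        "theta_final_mean": th_mean, "theta_final_sd": th_sd,
        "k_per_ns": fit.k, "k_stderr": fit.k_stderr, "converged": fit.converged,
        "tau_ns": tau, "e_at_tau_vnm": e_at_tau,
        "rmsd_at_tau_nm": rmsd_tau, "preserved_at_tau": preserved_tau,
        "plateau_rmsd_nm": plateau, "preserved_plateau": preserved_plateau,
        "error": None,
    }
    return res


def run_study(config: StudyConfig) -> StudyResult:
    """Run the full grid and summarize one row per condition.

    A condition that raises is recorded with its error message; the rest
    of the grid still completes.
    """
    if len(config.e0_vnm) == 0 or len(config.t0_ns) == 0:
        raise ValueError("grid must be nonempty")
    rows = []
    conditions = {}
    cond_index = 0
    for t0 in config.t0_ns:
        for e0 in config.e0_vnm:
            try:
                res = _analyze_condition(config, float(e0), float(t0), cond_index)
            except Exception as exc:  # recorded per row, grid continues
                res = ConditionResult(e0_vnm=float(e0), t0_ns=float(t0), error=str(exc))
                res.row = {
                    **{c: math.nan for c in _ROW_COLUMNS},
                    "e0_vnm": float(e0), "t0_ns": float(t0),
                    "n_replicas": config.n_replicas, "error": str(exc),
                }
            rows.append(res.row)
            conditions[(float(e0), float(t0))] = res
            cond_index += 1
    summary = pd.DataFrame(rows, columns=_ROW_COLUMNS)
    return StudyResult(summary=summary, conditions=conditions, config=config)
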