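"""Dipole orientation statistics and exponential decay fitting.

The central observable is the degree of orientation

    Θ = 1 − cos θ,

where θ is the angle between the molecular dipole moment and the external
field direction.  Θ = 0 for a dipole aligned with the field, Θ = 1 for a
perpendicular dipole (and also the expectation value over uniformly random
orientations, because parallel and antiparallel are then equally likely),
and Θ = 2 for an antiparallel dipole.

The ensemble-averaged Θ̄(t) of replica simulations shows, despite large
oscillations, a clear exponential decay; fitting f(t) = exp(−k t) yields
the rate k from which the orientation time

    τ = ln(10) / k

follows — the time at which the fitted model has lost 90% of its initial
orientation.  The fit is exposed statsmodels-style as
:class:`ExponentialDecayModel` (construct from data, call ``fit()``) whose
:class:`DecayFitResults` carries the estimate, its standard error, τ and a
``summary()`` table; :func:`fit_decay` is the one-call functional form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as _dc_field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .constants import DEBYE_PER_E_NM, ORIENTATION_LOSS_FRACTION
from .field import FieldProtocol

__all__ = [
    "DipoleTrajectory",
    "OrientationSeries",
    "DecayFitResults",
    "ExponentialDecayModel",
    "ZeroDipoleError",
    "NotOrientedError",
    "compute_dipole",
    "dipole_magnitude_debye",
    "degree_of_orientation",
    "theta_series",
    "ensemble_mean",
    "final_orientation",
    "fit_decay",
    "orientation_time",
    "field_at_orientation_time",
    "plane_projection",
    "PlaneProjection",
]

_GRID_TOL_NS = 1e-9


class ZeroDipoleError(ValueError):
    """The dipole vector vanishes; its angle to the field is undefined."""


class NotOrientedError(ValueError):
    """The fit implies the molecule never reaches the orientation criterion."""


@dataclass
class DipoleTrajectory:
    """Time-stamped lab-frame dipole vectors of one replica.

    times are in ns (strictly increasing, ≥ 2 samples), dipoles in e·nm.
    """

    times: np.ndarray
    dipoles: np.ndarray
    replica_id: str = "replica-0"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.dipoles = np.asarray(self.dipoles, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ValueError("trajectory needs at least 2 time samples")
        if self.dipoles.shape != (len(self.times), 3):
            raise ValueError(
                f"dipoles shape {self.dipoles.shape} does not match "
                f"{len(self.times)} times"
            )
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.dipoles))):
            raise ValueError("times and dipoles must be finite")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class OrientationSeries:
    """Θ(t) of one replica (``n_replicas = 1``) or an ensemble mean.

    ``zero_dipole`` flags frames whose dipole vanished; Θ is NaN there
    (flagged, never silently dropped).
    """

    times: np.ndarray
    theta: np.ndarray
    n_replicas: int = 1
    zero_dipole: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.times.shape != self.theta.shape or self.times.ndim != 1:
            raise ValueError("times and theta must be equal-length 1-d arrays")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.zero_dipole is None:
            self.zero_dipole = np.zeros(len(self.times), dtype=bool)
        else:
            self.zero_dipole = np.asarray(self.zero_dipole, dtype=bool)
        valid = ~self.zero_dipole
        th = self.theta[valid]
        if th.size and (np.nanmin(th) < -1e-9 or np.nanmax(th) > 2 + 1e-9):
            raise ValueError("theta must lie in [0, 2]")
        if self.n_replicas < 1:
            raise ValueError("n_replicas must be >= 1")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


# ---------------------------------------------------------------------------
# dipole construction and the Θ statistic
# ---------------------------------------------------------------------------

def compute_dipole(
    coordinates: np.ndarray, charges: np.ndarray, masses: np.ndarray
) -> np.ndarray:
    """Molecular dipole moment μ = Σᵢ qᵢ (rᵢ − r_COM), e·nm.

    The reference point is the mass-weighted center of mass: for a
    net-charged molecule (electrosprayed ubiquitin carries +7 e) the
    dipole is origin-dependent, and rotation about the COM is the frame
    in which the field torque μ × E acts.

    coordinates in nm (N, 3); charges in e (N,); masses in amu (N,).
    """
    r = np.asarray(coordinates, dtype=float).reshape(-1, 3)
    q = np.asarray(charges, dtype=float).ravel()
    m = np.asarray(masses, dtype=float).ravel()
    if not (len(r) == len(q) == len(m)):
        raise ValueError(
            f"length mismatch: {len(r)} coordinates, {len(q)} charges, {len(m)} masses"
        )
    if len(r) == 0:
        raise ValueError("need at least one atom")
    total_mass = m.sum()
    if total_mass <= 0:
        raise ValueError("total mass must be positive")
    com = (m[:, None] * r).sum(axis=0) / total_mass
    return (q[:, None] * (r - com)).sum(axis=0)


def dipole_magnitude_debye(dipole: np.ndarray) -> float:
    """Magnitude of a dipole vector given in e·nm, expressed in Debye."""
    return float(np.linalg.norm(dipole)) * DEBYE_PER_E_NM


def degree_of_orientation(dipole: np.ndarray, field_direction: np.ndarray) -> float:
    """Θ = 1 − cos θ for one dipole vector against the field direction.

    Independent of the dipole magnitude.  Raises :class:`ZeroDipoleError`
    for a vanishing dipole (the angle is undefined).
    """
    mu = np.asarray(dipole, dtype=float)
    f = np.asarray(field_direction, dtype=float)
    fnorm = np.linalg.norm(f)
    if fnorm == 0:
        raise ValueError("field direction must be nonzero")
    mnorm = np.linalg.norm(mu)
    if mnorm == 0:
        raise ZeroDipoleError("zero dipole vector: orientation angle undefined")
    cos_theta = float(np.dot(mu, f) / (mnorm * fnorm))
    cos_theta = min(1.0, max(-1.0, cos_theta))
    return 1.0 - cos_theta


def theta_series(
    traj: DipoleTrajectory, field_direction: np.ndarray
) -> OrientationSeries:
    """Framewise Θ(t) of a dipole trajectory.

    Frames with a vanishing dipole are flagged in ``zero_dipole`` and get
    Θ = NaN rather than being dropped.
    """
    f = np.asarray(field_direction, dtype=float)
    fnorm = np.linalg.norm(f)
    if fnorm == 0:
        raise ValueError("field direction must be nonzero")
    f = f / fnorm
    norms = np.linalg.norm(traj.dipoles, axis=1)
    zero = norms == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_theta = (traj.dipoles @ f) / norms
    cos_theta = np.clip(cos_theta, -1.0, 1.0)
    theta = 1.0 - cos_theta
    theta[zero] = np.nan
    return OrientationSeries(
        times=traj.times.copy(), theta=theta, n_replicas=1, zero_dipole=zero
    )


def ensemble_mean(series: Sequence[OrientationSeries]) -> OrientationSeries:
    """Pointwise replica mean Θ̄(t) ≡ ⟨Θ(t)⟩ over series on a common grid.

    All series must share the time grid to within 1e-9 ns; resampling is
    the caller's job.
    """
    if len(series) == 0:
        raise ValueError("need at least one series")
    ref = series[0]
    for s in series[1:]:
        if len(s) != len(ref) or np.max(np.abs(s.times - ref.times)) > _GRID_TOL_NS:
            raise ValueError("series time grids differ beyond 1e-9 ns tolerance")
    stack = np.vstack([s.theta for s in series])
    return OrientationSeries(
        times=ref.times.copy(),
        theta=stack.mean(axis=0),
        n_replicas=int(sum(s.n_replicas for s in series)),
        zero_dipole=np.any(np.vstack([s.zero_dipole for s in series]), axis=0),
    )


def final_orientation(
    series: OrientationSeries, window: float = 2.0
) -> tuple[float, float]:
    """Mean ± sd of Θ over the final ``window`` ns of the series."""
    if window <= 0:
        raise ValueError("window must be positive")
    if window >= series.duration:
        raise ValueError(
            f"window {window} ns is not shorter than the series duration "
            f"{series.duration} ns"
        )
    mask = series.times >= series.times[-1] - window - _GRID_TOL_NS
    vals = series.theta[mask]
    return float(np.nanmean(vals)), float(np.nanstd(vals))


# ---------------------------------------------------------------------------
# exponential decay model (statsmodels-style Model / Results pair)
# ---------------------------------------------------------------------------

@dataclass
class DecayFitResults:
    """Results of fitting f(t) = exp(−k t) to an orientation series.

    Attributes
    ----------
    k : float
        Decay rate, 1/ns. ``inf`` flags an unbounded fit (all-zero data),
        NaN a failed one.
    k_stderr : float
        Standard error of k from the least-squares covariance, 1/ns.
    converged : bool
        False when the optimizer failed or the data admit no bounded rate.
    amplitude : float
        Fitted amplitude (fixed at 1.0 unless the model frees it).
    fit_window : tuple
        (t_start, t_end) of the samples used, ns.
    nobs : int
        Number of fitted samples.
    """

    k: float
    k_stderr: float
    converged: bool
    amplitude: float
    amplitude_stderr: float
    fit_window: tuple[float, float]
    nobs: int
    model: "ExponentialDecayModel" = _dc_field(repr=False, default=None)

    @property
    def tau(self) -> float:
        """Orientation time τ = ln(10)/k, ns; inf when k ≤ 0 or not converged."""
        if not self.converged or not np.isfinite(self.k) or self.k <= 0:
            return math.inf
        return math.log(10.0) / self.k

    @property
    def oriented(self) -> bool:
        """Whether the fit implies the orientation criterion is ever met."""
        return self.converged and np.isfinite(self.k) and self.k > 0

    def predict(self, t: np.ndarray) -> np.ndarray:
        """Fitted model evaluated at times ``t``."""
        return self.amplitude * np.exp(-self.k * np.asarray(t, dtype=float))

    def field_at_tau(self, protocol: FieldProtocol) -> float:
        """Field strength E(τ) at the orientation time, V/nm."""
        return field_at_orientation_time(protocol, self.tau)

    def summary(self) -> str:
        """Plain-text summary table in the style of statsmodels results."""
        lines = [
            "      Exponential Orientation Decay Fit",
            "=" * 48,
            f"Model:            theta(t) = A exp(-k t)",
            f"Amplitude A:      {self.amplitude:.6g}"
            + ("  (fixed)" if self.model is None or not self.model.free_amplitude else f"  (se {self.amplitude_stderr:.3g})"),
            f"No. observations: {self.nobs}",
            f"Fit window [ns]:  [{self.fit_window[0]:.6g}, {self.fit_window[1]:.6g}]",
            f"Converged:        {self.converged}",
            "-" * 48,
            f"k  [1/ns]:        {self.k:.6g}   (se {self.k_stderr:.3g})",
            f"tau = ln(10)/k [ns]: "
            + (f"{self.tau:.6g}" if math.isfinite(self.tau) else "inf (not oriented)"),
            "=" * 48,
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot the data and the fitted decay; returns the matplotlib axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.model is not None:
            ax.plot(self.model.times, self.model.theta, "k-", lw=0.8, label="data")
            tt = np.linspace(self.fit_window[0], self.fit_window[1], 400)
            ax.plot(tt, self.predict(tt), color="tab:orange", label="fit exp(-kt)")
        ax.set_xlabel("time [ns]")
        ax.set_ylabel(r"degree of orientation $\Theta$")
        ax.legend()
        return ax


class ExponentialDecayModel:
    """Single-rate exponential decay model for a Θ(t) series.

    The fit function is f(t) = exp(−k t) with the amplitude fixed at 1:
    the replica starting geometry (dipole perpendicular to the field)
    makes Θ(0) ≈ 1, and the published fitting form carries no amplitude.
    ``free_amplitude=True`` switches to A·exp(−k t) as a diagnostic.

    Parameters
    ----------
    times, theta : array
        The series to fit (typically an ensemble mean Θ̄).
    fit_window : (float, float), optional
        Restrict the fit to t in [t_start, t_end]; default is the whole
        series starting at its first sample.
    """

    def __init__(
        self,
        times: np.ndarray,
        theta: np.ndarray,
        fit_window: Optional[tuple[float, float]] = None,
        free_amplitude: bool = False,
    ) -> None:
        times = np.asarray(times, dtype=float)
        theta = np.asarray(theta, dtype=float)
        if times.shape != theta.shape or times.ndim != 1:
            raise ValueError("times and theta must be equal-length 1-d arrays")
        self.times = times
        self.theta = theta
        self.free_amplitude = bool(free_amplitude)
        if fit_window is None:
            fit_window = (float(times[0]), float(times[-1]))
        self.fit_window = (float(fit_window[0]), float(fit_window[1]))
        mask = (times >= self.fit_window[0] - _GRID_TOL_NS) & (
            times <= self.fit_window[1] + _GRID_TOL_NS
        )
        mask &= np.isfinite(theta)
        self._t = times[mask]
        self._y = theta[mask]
        if len(self._t) < 5:
            raise ValueError("need at least 5 finite samples in the fit window")
        if np.any(self._y < -1e-9):
            raise ValueError("theta values must be >= 0")

    @classmethod
    def from_series(
        cls,
        series: OrientationSeries,
        fit_window: Optional[tuple[float, float]] = None,
        free_amplitude: bool = False,
    ) -> "ExponentialDecayModel":
        return cls(series.times, series.theta, fit_window, free_amplitude)

    @classmethod
    def from_dataframe(
        cls,
        df,
        time_col: str = "time_ns",
        theta_col: str = "theta",
        **kwargs,
    ) -> "ExponentialDecayModel":
        return cls(df[time_col].to_numpy(), df[theta_col].to_numpy(), **kwargs)

    def fit(self) -> DecayFitResults:
        t, y = self._t, self._y
        window = (float(t[0]), float(t[-1]))
        if np.all(y < 1e-12):
            # exp(-kt) can only reach an all-zero series as k -> inf
            return DecayFitResults(
                k=math.inf, k_stderr=math.nan, converged=False,
                amplitude=1.0, amplitude_stderr=math.nan,
                fit_window=window, nobs=len(t), model=self,
            )
        # log-linear starting value from the strictly positive samples
        pos = y > 1e-12
        if pos.sum() >= 2 and np.ptp(t[pos]) > 0:
            slope = np.polyfit(t[pos], np.log(y[pos]), 1)[0]
            k0 = -float(slope)
        else:
            k0 = 1.0
        if not np.isfinite(k0):
            k0 = 1.0
        try:
            if self.free_amplitude:
                popt, pcov = curve_fit(
                    lambda tt, a, k: a * np.exp(-k * tt), t, y,
                    p0=[max(y[0], 1e-6), k0], maxfev=10000,
                )
                a, k = popt
                a_se, k_se = np.sqrt(np.maximum(np.diag(pcov), 0.0))
            else:
                popt, pcov = curve_fit(
                    lambda tt, k: np.exp(-k * tt), t, y, p0=[k0], maxfev=10000,
                )
                a, k = 1.0, popt[0]
                a_se = 0.0
                k_se = float(np.sqrt(max(pcov[0, 0], 0.0)))
        except RuntimeError:
            return DecayFitResults(
                k=math.nan, k_stderr=math.nan, converged=False,
                amplitude=1.0, amplitude_stderr=math.nan,
                fit_window=window, nobs=len(t), model=self,
            )
        return DecayFitResults(
            k=float(k), k_stderr=float(k_se), converged=True,
            amplitude=float(a), amplitude_stderr=float(a_se),
            fit_window=window, nobs=len(t), model=self,
        )


def fit_decay(
    series: OrientationSeries,
    window: Optional[tuple[float, float]] = None,
    free_amplitude: bool = False,
) -> DecayFitResults:
    """Fit f(t) = exp(−k t) to an orientation series (ensemble mean fitted
    directly, per the published procedure: no smoothing, least squares over
    the window)."""
    return ExponentialDecayModel.from_series(series, window, free_amplitude).fit()


def orientation_time(fit: DecayFitResults) -> float:
    """Orientation time τ = ln(10)/k of a converged fit, ns.

    Under the fitted model exp(−k τ) = 0.1 exactly: the molecule has lost
    90% (``ORIENTATION_LOSS_FRACTION``) of its initial orientation.
    Infinite for k ≤ 0 (flagged via ``fit.oriented``).
    """
    if not fit.converged:
        raise ValueError("orientation_time requires a converged fit")
    assert abs((1.0 - ORIENTATION_LOSS_FRACTION) - 0.1) < 1e-12
    return fit.tau


def field_at_orientation_time(protocol: FieldProtocol, tau: float) -> float:
    """E(τ): instantaneous field strength at the orientation time, V/nm.

    Raises :class:`NotOrientedError` for infinite τ — "never oriented" is
    an explicit outcome, not a number.
    """
    if not np.isfinite(tau):
        raise NotOrientedError("orientation time is infinite: never oriented")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    return float(protocol.evaluate(tau))


# ---------------------------------------------------------------------------
# dipole projection onto the plane perpendicular to the field
# ---------------------------------------------------------------------------

@dataclass
class PlaneProjection:
    """Per-frame alignment angles and azimuths of the dipole about the field.

    ``alignment_deg`` is the polar angle between dipole and field (0° =
    perfect alignment); ``azimuth_deg`` the azimuth of the dipole component
    in the plane perpendicular to the field (NaN where the dipole is
    parallel to the field and the azimuth is undefined — those frames are
    flagged ``degenerate`` and counted as aligned).
    ``aligned_fraction`` is the fraction of frames within the cone
    ``cone_deg`` about the field axis.
    """

    times: np.ndarray
    alignment_deg: np.ndarray
    azimuth_deg: np.ndarray
    degenerate: np.ndarray
    aligned_fraction: float
    cone_deg: float


def plane_projection(
    traj: DipoleTrajectory,
    field_direction: np.ndarray,
    cone_deg: float = 15.0,
) -> PlaneProjection:
    """Project the dipole onto the plane perpendicular to the field.

    The alignment criterion is the polar angle to the field axis (a cone
    of half-angle ``cone_deg``), matching the "spread of ±15° with respect
    to perfect alignment" reading of dipole-projection maps.
    """
    f = np.asarray(field_direction, dtype=float)
    fn = np.linalg.norm(f)
    if fn == 0:
        raise ValueError("field direction must be nonzero")
    f = f / fn
    # deterministic in-plane basis
    helper = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(helper, f)) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(helper, f)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(f, e1)

    mu = traj.dipoles
    norms = np.linalg.norm(mu, axis=1)
    if np.any(norms == 0):
        raise ZeroDipoleError("trajectory contains zero-dipole frames")
    cos_a = np.clip((mu @ f) / norms, -1.0, 1.0)
    align = np.degrees(np.arccos(cos_a))
    p1 = mu @ e1
    p2 = mu @ e2
    in_plane = np.hypot(p1, p2)
    degenerate = in_plane < 1e-12 * norms
    azimuth = np.degrees(np.arctan2(p2, p1))
    azimuth[degenerate] = np.nan
    aligned = (align <= cone_deg) | degenerate
    return PlaneProjection(
        times=traj.times.copy(),
        alignment_deg=align,
        azimuth_deg=azimuth,
        degenerate=degenerate,
        aligned_fraction=float(np.mean(aligned)),
        cone_deg=float(cone_deg),
    )
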