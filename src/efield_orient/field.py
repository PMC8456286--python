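"""Time-dependent electric field protocols.

The protocol is a Gaussian ramp that plateaus at its peak: the field rises
as ``E0·exp(-(t - t0)² / (2σ²))`` for ``t < t0`` and stays constant at
``E0`` for ``t ≥ t0``.  With ``t0 = 0`` it degenerates to a constant
field.  Both branches equal ``E0`` at ``t = t0``, so the protocol is
continuous at the ramp end.

Units: time in ns, field strength in V/nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as _dc_field
from typing import Sequence, Union

import numpy as np

__all__ = ["FieldProtocol", "make_protocol", "evaluate_field", "field_vector"]

ArrayLike = Union[float, Sequence[float], np.ndarray]


@dataclass(frozen=True)
class FieldProtocol:
    """A Gaussian-ramp-to-plateau field protocol.

    Parameters
    ----------
    e0 : float
        Plateau field strength, V/nm. Must be ≥ 0.
    t0 : float
        Ramp end time, ns. Must be ≥ 0. ``t0 = 0`` means a constant field.
    sigma : float or None
        Gaussian ramp width, ns. Required (> 0) whenever ``t0 > 0``;
        unused (may be None) when ``t0 = 0``.
    direction : ndarray
        Unit 3-vector giving the lab-frame field direction.
    """

    e0: float
    t0: float
    sigma: float | None
    direction: np.ndarray = _dc_field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))

    def __post_init__(self) -> None:
        if self.e0 < 0:
            raise ValueError(f"field strength E0 must be >= 0, got {self.e0}")
        if self.t0 < 0:
            raise ValueError(f"ramp end time t0 must be >= 0, got {self.t0}")
        if self.t0 > 0:
            if self.sigma is None or self.sigma <= 0:
                raise ValueError(
                    f"sigma must be > 0 when t0 > 0, got {self.sigma}"
                )
        d = np.asarray(self.direction, dtype=float)
        if d.shape != (3,):
            raise ValueError(f"direction must be a 3-vector, got shape {d.shape}")
        norm = float(np.linalg.norm(d))
        if norm == 0.0:
            raise ValueError("direction must be a nonzero vector")
        object.__setattr__(self, "direction", d / norm)

    def evaluate(self, t: ArrayLike) -> Union[float, np.ndarray]:
        """Scalar field strength at time(s) ``t`` (ns), V/nm."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("field is only defined for t >= 0")
        if self.t0 == 0:
            out = np.full_like(t_arr, self.e0, dtype=float)
        else:
            ramp = self.e0 * np.exp(-((t_arr - self.t0) ** 2) / (2.0 * self.sigma**2))
            out = np.where(t_arr < self.t0, ramp, self.e0)
        if np.isscalar(t) or t_arr.ndim == 0:
            return float(out)
        return out

    def vector(self, t: ArrayLike) -> np.ndarray:
        """Field vector(s) at time(s) ``t``: scalar strength × direction."""
        e = self.evaluate(t)
        if np.isscalar(e):
            return e * self.direction
        return np.asarray(e)[..., None] * self.direction


def make_protocol(
    e0: float,
    t0: float,
    sigma_rule: Union[str, float, None] = "t0/3",
    direction: Sequence[float] = (1.0, 0.0, 0.0),
) -> FieldProtocol:
    """Build a :class:`FieldProtocol`, resolving the ramp width rule.

    ``sigma_rule`` may be an explicit width in ns, or the string
    ``"t0/3"`` (also accepted: ``"auto"``), which sets σ = t0/3 so that
    the field at t = 0 is E0·exp(-4.5) ≈ 1.1% of E0 — the pulse
    effectively starts from zero.  σ is irrelevant when t0 = 0.
    """
    if isinstance(sigma_rule, str):
        if sigma_rule not in ("t0/3", "auto"):
            raise ValueError(f"unknown sigma rule {sigma_rule!r}")
        sigma = t0 / 3.0 if t0 > 0 else None
    else:
        sigma = None if (sigma_rule is None and t0 == 0) else float(sigma_rule)
    return FieldProtocol(e0=float(e0), t0=float(t0), sigma=sigma, direction=np.asarray(direction, float))


def evaluate_field(protocol: FieldProtocol, t: ArrayLike) -> Union[float, np.ndarray]:
    """Scalar field strength of ``protocol`` at time(s) ``t`` (ns), V/nm."""
    return protocol.evaluate(t)


def field_vector(protocol: FieldProtocol, t: ArrayLike) -> np.ndarray:
    """Field vector of ``protocol`` at time(s) ``t``, V/nm."""
    return protocol.vector(t)
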