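"""Time discretization and light profiles for diurnal simulations."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["TimeGrid", "LightProfile", "make_grid"]

LIGHT = "light"
DARK = "dark"


@dataclass(frozen=True)
class TimeGrid:
    """A uniform partition of the period ``[0, T]`` into ``n_t`` intervals.

    ``phase[k]`` labels interval ``k`` (between boundaries ``t_k`` and
    ``t_{k+1}``) as ``"light"`` or ``"dark"``.  Times are in hours.
    """

    T: float
    n_t: int
    boundaries: np.ndarray
    phase: tuple[str, ...]

    @property
    def dt(self) -> np.ndarray:
        return np.diff(self.boundaries)

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.boundaries[:-1] + self.boundaries[1:])

    @property
    def is_light(self) -> np.ndarray:
        return np.array([p == LIGHT for p in self.phase])

    @property
    def light_hours(self) -> float:
        return float(self.dt[self.is_light].sum())


def make_grid(T: float, n_t: int, light_hours: float, *, allow_rounding: bool = False) -> TimeGrid:
    """Uniform grid over a period of ``T`` hours with a leading light phase.

    The first ``ceil(n_t * light_hours / T)`` intervals are labelled light.
    If the light/dark split does not fall on an interval boundary a
    ``ValueError`` is raised unless ``allow_rounding`` is set.
    """
    if n_t < 1:
        raise ValueError("n_t must be a positive integer")
    if not (0 <= light_hours <= T):
        raise ValueError("light_hours must lie in [0, T]")
    if T <= 0:
        raise ValueError("period T must be positive")
    exact = n_t * light_hours / T
    n_light = math.ceil(exact - 1e-9)
    if abs(exact - round(exact)) > 1e-9 and not allow_rounding:
        raise ValueError(
            f"light phase of {light_hours} h does not align with {n_t} intervals over {T} h; "
            "pass allow_rounding=True to round up to the next boundary"
        )
    boundaries = np.linspace(0.0, T, n_t + 1)
    phase = tuple(LIGHT if k < n_light else DARK for k in range(n_t))
    return TimeGrid(T=float(T), n_t=int(n_t), boundaries=boundaries, phase=phase)


@dataclass(frozen=True)
class LightProfile:
    """Per-interval light environment.

    ``gamma[k]`` multiplies the inverse kcats of light-modulated capacity
    rows in interval ``k`` (the inverse of the effective catalytic
    efficiency of light harvesting).  ``dark[k]`` marks intervals in which
    light-driven reactions (photon uptake) are shut off entirely; gamma is
    kept at 1 there rather than using infinite coefficients.
    """

    gamma: np.ndarray
    dark: np.ndarray

    def __post_init__(self):
        g = np.asarray(self.gamma, dtype=float)
        d = np.asarray(self.dark, dtype=bool)
        if g.shape != d.shape:
            raise ValueError("gamma and dark must have identical shapes")
        if np.any(g < 0) or np.any(~np.isfinite(g)):
            raise ValueError("gamma must be finite and non-negative")
        object.__setattr__(self, "gamma", g)
        object.__setattr__(self, "dark", d)

    @property
    def n_t(self) -> int:
        return len(self.gamma)
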