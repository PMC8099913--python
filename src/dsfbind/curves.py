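"""Containers for melting curves and binding studies."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MeltingCurve", "BindingStudy", "SIGNAL_TYPES"]

SIGNAL_TYPES = ("F330", "F350", "Ratio")

#: Minimum number of points a usable melting curve must have.
MIN_POINTS = 20


@dataclass
class MeltingCurve:
    """One temperature-vs-signal trace at a single ligand concentration.

    ``t_celsius`` must be strictly increasing and finite; ``y`` is the
    fluorescence signal (F330, F350 or the 350/330 ratio); ``l0`` is the
    total ligand concentration in molar.
    """

    t_celsius: np.ndarray
    y: np.ndarray
    l0: float
    label: str = ""
    signal_type: str = "Ratio"

    def __post_init__(self):
        self.t_celsius = np.asarray(self.t_celsius, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t_celsius.ndim != 1 or self.t_celsius.shape != self.y.shape:
            raise ValueError("t_celsius and y must be 1-D arrays of equal length")
        if len(self.t_celsius) < MIN_POINTS:
            raise ValueError(
                f"melting curve needs >= {MIN_POINTS} points, got {len(self.t_celsius)}"
            )
        if not (np.all(np.isfinite(self.t_celsius)) and np.all(np.isfinite(self.y))):
            raise ValueError("non-finite values in melting curve (clean input first)")
        if np.any(np.diff(self.t_celsius) <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        if self.l0 < 0:
            raise ValueError("l0 must be non-negative")
        if self.signal_type not in SIGNAL_TYPES:
            raise ValueError(f"signal_type must be one of {SIGNAL_TYPES}")

    def __len__(self):
        return len(self.t_celsius)


@dataclass
class BindingStudy:
    """A ligand dilution series of melting curves at fixed protein concentration.

    All curves must share the temperature grid and signal type.  ``window``
    is the analysis window in °C; it defaults to the full grid.
    """

    curves: list[MeltingCurve]
    p0: float
    window: tuple[float, float] | None = field(default=None)

    def __post_init__(self):
        if not self.curves:
            raise ValueError("study has no curves")
        if self.p0 <= 0:
            raise ValueError("p0 must be positive")
        grid = self.curves[0].t_celsius
        sig = self.curves[0].signal_type
        for c in self.curves[1:]:
            if len(c) != len(grid) or not np.allclose(c.t_celsius, grid):
                raise ValueError("all curves must share a common temperature grid")
            if c.signal_type != sig:
                raise ValueError("all curves must share the signal type")
        if self.window is None:
            self.window = (float(grid[0]), float(grid[-1]))
        lo, hi = self.window
        if not lo < hi:
            raise ValueError("window must satisfy Tmin < Tmax")
        self.window = (float(lo), float(hi))

    @property
    def t_celsius(self) -> np.ndarray:
        return self.curves[0].t_celsius

    @property
    def l0_values(self) -> np.ndarray:
        return np.array([c.l0 for c in self.curves])

    @property
    def signal_type(self) -> str:
        return self.curves[0].signal_type

    def apo_curve(self) -> MeltingCurve | None:
        """The ligand-free curve, if present (first match)."""
        for c in self.curves:
            if c.l0 == 0:
                return c
        return None

    def __len__(self):
        return len(self.curves)
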