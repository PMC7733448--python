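"""Reference free-energy landscape for the release coordinate.

A monotone piecewise-cubic (PCHIP) interpolant through a small set of knots
plays the role of the true potential of mean force U(d) along the
N17–COM(Glu-12, Glu-14) distance.  The default knots trace the characteristic
four-upward-step shape of the release PMF — stationary points A through H —
with the single hard constraint that the main barrier, peak F minus valley C,
equals 14.6 kJ/mol.  Everything else about the default shape is a package
choice and can be overridden knot-by-knot.

The Langevin sampler and umbrella-window generator draw their forces from
this landscape, so WHAM recovery can be judged against an exactly known
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from ..errors import OutOfRangeError, ParameterError

__all__ = ["ReferenceLandscape", "build_reference_landscape", "DEFAULT_KNOTS"]

# (distance Å, free energy kJ/mol); A..H are the stationary points of the
# four-step release profile.  F(15.5) - C(8.0) = 14.6 kJ/mol is the main
# barrier.  The 3.75 Å boundary knot closes the evaluable range on the left
# and keeps A the left-hand minimum.
DEFAULT_KNOTS: tuple[tuple[float, float], ...] = (
    (3.75, 0.5),
    (4.0, 0.0),    # A — protected state
    (6.5, 6.0),    # B
    (8.0, 3.0),    # C — valley before the main barrier
    (11.5, 12.0),  # D
    (13.0, 8.0),   # E
    (15.5, 17.6),  # F — main peak: F - C = 14.6 kJ/mol
    (17.0, 10.0),  # G
    (20.0, 13.0),  # H
    (21.12, 13.5),
)


@dataclass
class ReferenceLandscape:
    """Monotone piecewise-cubic U(d) with an analytic derivative."""

    knots: tuple[tuple[float, float], ...] = DEFAULT_KNOTS
    _spline: PchipInterpolator = field(init=False, repr=False)
    _derivative: PchipInterpolator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        pts = sorted((float(d), float(u)) for d, u in self.knots)
        d = np.array([p[0] for p in pts])
        u = np.array([p[1] for p in pts])
        if len(d) < 2:
            raise ParameterError("landscape needs at least two knots")
        if np.any(np.diff(d) <= 0):
            raise ParameterError("knot positions must be strictly increasing")
        self.knots = tuple(pts)
        self._spline = PchipInterpolator(d, u, extrapolate=False)
        self._derivative = self._spline.derivative()

    @property
    def d_min(self) -> float:
        return self.knots[0][0]

    @property
    def d_max(self) -> float:
        return self.knots[-1][0]

    def _check_range(self, d) -> np.ndarray:
        d = np.asarray(d, dtype=np.float64)
        if np.any(d < self.d_min) or np.any(d > self.d_max):
            raise OutOfRangeError(
                f"evaluation outside knot range [{self.d_min}, {self.d_max}] Å")
        return d

    def energy(self, d):
        """U(d) in kJ/mol; raises outside the knot range."""
        d = self._check_range(d)
        return self._spline(d)

    def derivative(self, d):
        """U'(d) in kJ/mol/Å; raises outside the knot range."""
        d = self._check_range(d)
        return self._derivative(d)

    __call__ = energy

    def force_table(self, spacing: float = 1e-3) -> tuple[np.ndarray, np.ndarray]:
        """Dense (positions, U') table for fast force lookup in samplers."""
        grid = np.arange(self.d_min, self.d_max + spacing / 2, spacing)
        grid[-1] = min(grid[-1], self.d_max)
        return grid, np.asarray(self._derivative(grid))


def build_reference_landscape(overrides=None) -> ReferenceLandscape:
    """The packaged landscape, optionally with a replacement knot list."""
    return ReferenceLandscape(knots=tuple(overrides) if overrides is not None
                              else DEFAULT_KNOTS)
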