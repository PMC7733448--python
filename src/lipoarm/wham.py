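"""Weighted Histogram Analysis Method (WHAM) and barrier extraction.

Umbrella sampling restrains the reaction coordinate ``d`` (here the
N17–COM(Glu-12, Glu-14) distance, Å) in a series of windows with harmonic
biases ``w_j(d) = k_j (d - d0_j)^2 / 2``.  WHAM recombines the biased window
histograms into the unbiased probability by self-consistent iteration of

    P(x)    = sum_i n_i(x) / sum_j N_j f_j exp(-beta w_j(x))
    f_j^-1  = sum_x P(x) exp(-beta w_j(x))

where ``n_i(x)`` are per-window bin counts, ``N_j`` window sample counts and
``beta = 1/kBT``.  The potential of mean force is ``F(x) = -kBT ln P(x)``,
anchored so its minimum over occupied bins is zero.  Convergence is measured
as the maximum change of ``ln f_j`` between iterations (dimensionless).

Bins that received no samples are masked, never interpolated: a masked bin
simply carries no free-energy estimate.  Samples are treated as independent;
a subsampling stride is exposed for correlated input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import IntervalError, ParameterError, WhamInputError

__all__ = [
    "GAS_CONSTANT_KJ_PER_MOL_K", "UmbrellaWindow", "PMFProfile",
    "EnergyBarrier", "wham", "window_overlap", "barrier",
    "profile_from_curve",
]

GAS_CONSTANT_KJ_PER_MOL_K = 8.314e-3  # kJ/mol/K


@dataclass
class UmbrellaWindow:
    """Biased samples of the reaction coordinate from one umbrella window."""

    center: float          # d0_j, Å
    spring_k: float        # k_j, kJ/mol/Å^2
    samples: np.ndarray    # d values, Å

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or len(self.samples) == 0:
            raise WhamInputError(
                f"window at {self.center} Å has no samples")
        if self.spring_k < 0:
            raise ParameterError("spring constant must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def bias_energy(self, x: np.ndarray) -> np.ndarray:
        """Harmonic bias w_j(x) = k_j (x - d0_j)^2 / 2 in kJ/mol."""
        return 0.5 * self.spring_k * (np.asarray(x) - self.center) ** 2


@dataclass
class PMFProfile:
    """WHAM output on a uniform grid; ``occupied`` masks sampled bins."""

    grid: np.ndarray              # bin centers, Å
    free_energy: np.ndarray       # kJ/mol, NaN on unoccupied bins
    probability: np.ndarray       # normalized over occupied bins
    occupied: np.ndarray
    window_factors: np.ndarray    # f_j
    converged: bool
    iterations: int
    temperature: float

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({"d_A": self.grid, "F_kJmol": self.free_energy,
                      "occupied": self.occupied}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PMFProfile":
        import pandas as pd
        df = pd.read_csv(path)
        occ = df["occupied"].to_numpy(dtype=bool)
        fe = df["F_kJmol"].to_numpy(dtype=np.float64)
        beta_f = np.where(occ, fe, np.inf)
        prob = np.exp(-(beta_f - np.nanmin(fe)))
        prob[~occ] = 0.0
        prob /= prob.sum()
        return cls(grid=df["d_A"].to_numpy(), free_energy=fe,
                   probability=prob, occupied=occ,
                   window_factors=np.array([]), converged=True,
                   iterations=0, temperature=300.0)


@dataclass
class EnergyBarrier:
    valley_position: float
    valley_value: float
    peak_position: float
    peak_value: float

    @property
    def height(self) -> float:
        return self.peak_value - self.valley_value

    def to_json(self, path=None) -> str:
        payload = json.dumps({
            "valley_position_A": self.valley_position,
            "valley_value_kJmol": self.valley_value,
            "peak_position_A": self.peak_position,
            "peak_value_kJmol": self.peak_value,
            "barrier_kJmol": self.height,
        }, sort_keys=True, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _make_grid(windows, bin_width: float) -> np.ndarray:
    lo = min(w.samples.min() for w in windows)
    hi = max(w.samples.max() for w in windows)
    # align bin edges to multiples of the bin width for reproducibility
    first = np.floor(lo / bin_width) * bin_width
    n_bins = int(np.ceil((hi - first) / bin_width)) + 1
    return first + bin_width * (np.arange(n_bins) + 0.5)


def wham(windows, bin_width: float = 0.1, temperature: float = 300.0,
         tolerance: float = 1e-6, max_iter: int = 100_000,
         stride: int = 1) -> PMFProfile:
    """Self-consistent WHAM estimate of the PMF from umbrella windows.

    ``stride`` subsamples each window before histogramming (for correlated
    samples).  Convergence: max |Δ ln f_j| < ``tolerance``.
    """
    windows = list(windows)
    if not windows:
        raise WhamInputError("wham needs at least one window")
    if bin_width <= 0:
        raise ParameterError("bin_width must be positive")
    if stride < 1:
        raise ParameterError("stride must be >= 1")
    kBT = GAS_CONSTANT_KJ_PER_MOL_K * temperature
    beta = 1.0 / kBT

    samples = [w.samples[::stride] for w in windows]
    grid = _make_grid(
        [UmbrellaWindow(w.center, w.spring_k, s)
         for w, s in zip(windows, samples)], bin_width)
    edges = np.concatenate([grid - bin_width / 2, [grid[-1] + bin_width / 2]])
    counts = np.stack([np.histogram(s, bins=edges)[0] for s in samples])
    n_total = counts.sum(axis=0).astype(np.float64)      # (n_bins,)
    occupied = n_total > 0
    n_samples = counts.sum(axis=1).astype(np.float64)    # N_j

    bias = np.stack([w.bias_energy(grid) for w in windows])  # (n_win, n_bins)
    boltz = np.exp(-beta * bias)

    ln_f = np.zeros(len(windows))
    converged = False
    iteration = 0
    for iteration in range(1, max_iter + 1):
        denom = (n_samples * np.exp(ln_f)) @ boltz           # (n_bins,)
        p = np.where(occupied, n_total / np.maximum(denom, 1e-300), 0.0)
        p /= p.sum()
        ln_f_new = -np.log(np.maximum(boltz @ p, 1e-300))
        ln_f_new -= ln_f_new[0]                              # fix the gauge
        delta = np.max(np.abs(ln_f_new - ln_f))
        ln_f = ln_f_new
        if delta < tolerance:
            converged = True
            break

    with np.errstate(divide="ignore"):
        free = -kBT * np.log(np.where(occupied, p, np.nan))
    free -= np.nanmin(free)
    return PMFProfile(grid=grid, free_energy=free, probability=p,
                      occupied=occupied, window_factors=np.exp(ln_f),
                      converged=converged, iterations=iteration,
                      temperature=temperature)


@dataclass
class OverlapReport:
    """Shared-bin counts for adjacent windows; zero-overlap pairs flagged."""

    pairs: list[dict] = field(default_factory=list)

    @property
    def flagged(self) -> list[dict]:
        return [p for p in self.pairs if p["shared_bins"] == 0]


def window_overlap(windows, bin_width: float = 0.1) -> OverlapReport:
    """Histogram-overlap diagnostic for adjacent windows (by center)."""
    windows = sorted(windows, key=lambda w: w.center)
    if len(windows) < 2:
        raise WhamInputError("overlap diagnostic needs >= 2 windows")
    grid = _make_grid(windows, bin_width)
    edges = np.concatenate([grid - bin_width / 2, [grid[-1] + bin_width / 2]])
    occ = [np.histogram(w.samples, bins=edges)[0] > 0 for w in windows]
    report = OverlapReport()
    for a, b in zip(range(len(windows) - 1), range(1, len(windows))):
        shared = int(np.sum(occ[a] & occ[b]))
        report.pairs.append({
            "center_a": windows[a].center, "center_b": windows[b].center,
            "shared_bins": shared, "ok": shared > 0})
    return report


def barrier(profile: PMFProfile, valley_interval, peak_interval) -> EnergyBarrier:
    """Barrier height: max F over the peak interval minus min F over the
    valley interval (the valley must precede the peak)."""
    v_lo, v_hi = valley_interval
    p_lo, p_hi = peak_interval
    if not v_hi <= p_lo:
        raise ParameterError("valley interval must precede peak interval")

    def _extremum(lo, hi, kind):
        mask = (profile.grid >= lo) & (profile.grid <= hi) & profile.occupied
        if not mask.any():
            raise IntervalError(
                f"no occupied bins in interval [{lo}, {hi}] Å")
        vals = profile.free_energy[mask]
        pos = profile.grid[mask]
        i = np.nanargmin(vals) if kind == "min" else np.nanargmax(vals)
        return float(pos[i]), float(vals[i])

    v_pos, v_val = _extremum(v_lo, v_hi, "min")
    p_pos, p_val = _extremum(p_lo, p_hi, "max")
    return EnergyBarrier(valley_position=v_pos, valley_value=v_val,
                         peak_position=p_pos, peak_value=p_val)


def profile_from_curve(grid: np.ndarray, free_energy: np.ndarray,
                       temperature: float = 300.0) -> PMFProfile:
    """Wrap an explicit F(d) curve (e.g. a reference landscape evaluated on a
    grid) as a PMFProfile so barrier extraction can run on it."""
    grid = np.asarray(grid, dtype=np.float64)
    free = np.asarray(free_energy, dtype=np.float64)
    kBT = GAS_CONSTANT_KJ_PER_MOL_K * temperature
    p = np.exp(-(free - free.min()) / kBT)
    p /= p.sum()
    return PMFProfile(grid=grid, free_energy=free, probability=p,
                      occupied=np.ones_like(grid, dtype=bool),
                      window_factors=np.array([]), converged=True,
                      iterations=0, temperature=temperature)
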