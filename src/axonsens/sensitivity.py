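"""Sensitivity of the diffusion signal to axon diameter, and noise-limited
resolvability.

The figure of merit is the derivative of the (proton-density-normalized,
optionally T2-weighted) signal with respect to axon diameter,

    |S*'(a)| = exp(-TE/T2) * f * |dS_r/da|,

evaluated by central finite differences (the hindered compartment carries no
diameter dependence).  On top of it this module computes:

* the plateau separation ``Delta_0`` beyond which the restricted signal stops
  changing with the waveform separation (1% criterion),
* exhaustive grid-search optima of the sensitivity over the sequence space,
* noise-threshold quantities: the diameter contrast ``|S*(a) - S*(a-eps)|``
  compared against the noise standard deviation
  ``sigma = exp(-TE0/T2)/SNR``, the resolvable-diameter intervals, and the
  smallest diameter distinguishable from zero, ``a_0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .dispersion import WatsonModel, _rotation_to, log_kummer_m_half, spherical_quadrature
from .sequence import (
    EffectiveWaveform,
    ParameterGrid,
    SequenceParams,
    build_effective_waveform,
    bvalue_numeric,
    enumerate_grid,
)
from .signal import (
    CylinderGPDBasis,
    FiberGeometry,
    TissueModel,
    bessel_prime_roots,
    gpd_perp_log_attenuation_multi,
    gpd_perp_log_attenuation_vs_separation,
)

__all__ = [
    "Scenario",
    "NoiseModel",
    "SensitivityMap",
    "OptimalSequence",
    "noise_sigma",
    "diameter_derivative",
    "signals_vs_diameter",
    "sensitivity_restricted",
    "sensitivity_full",
    "delta0_plateau",
    "sensitivity_map",
    "optimize_sensitivity",
    "contrast",
    "resolvable_range",
    "a0_limit",
]

#: default finite-difference step for d/da, m (0.01 um)
DEFAULT_H = 0.01e-6


@dataclass(frozen=True)
class Scenario:
    """Fiber-orientation scenario for a sensitivity computation.

    ``theta_deg`` is the deviation of the gradient from perpendicularity to
    the fiber axis (parallel-fiber model).  If ``kappa`` is set, a Watson
    distribution with that concentration and mean axis perpendicular to the
    gradient replaces the single orientation.  ``include_T2`` applies the
    exp(-TE/T2) echo-time weighting.
    """

    theta_deg: float = 0.0
    kappa: float | None = None
    include_T2: bool = True

    @property
    def dispersed(self) -> bool:
        return self.kappa is not None

    def label(self) -> str:
        t2 = "T2" if self.include_T2 else "noT2"
        if self.dispersed:
            return f"watson{self.kappa:g}-{t2}"
        return f"theta{self.theta_deg:g}-{t2}"


PERPENDICULAR = Scenario(theta_deg=0.0, include_T2=True)


@dataclass(frozen=True)
class NoiseModel:
    """Noise level of the unweighted signal back-projected to TE0.

    sigma = exp(-TE0/T2) / SNR.
    """

    SNR: float
    TE0: float = 0.120
    T2: float = 0.070

    def __post_init__(self) -> None:
        if self.SNR <= 0 or self.TE0 < 0 or self.T2 <= 0:
            raise ValueError("SNR and T2 must be positive, TE0 nonnegative")

    @property
    def sigma(self) -> float:
        return noise_sigma(self.SNR, self.TE0, self.T2)


def noise_sigma(SNR: float, TE0: float, T2: float) -> float:
    """sigma = exp(-TE0/T2) / SNR (signal units of the normalized signal)."""
    return math.exp(-TE0 / T2) / SNR


def diameter_derivative(
    signal_fn: Callable[[float], float], a: float, h: float = DEFAULT_H
) -> float:
    """Finite-difference d(signal)/d(diameter) at ``a``.

    Central difference for a >= h, forward one-sided below (diameters cannot
    be negative).
    """
    if a < 0 or h <= 0:
        raise ValueError("need a >= 0 and h > 0")
    if a >= h:
        lo, hi = signal_fn(a - h), signal_fn(a + h)
        d = (hi - lo) / (2.0 * h)
    else:
        lo, hi = signal_fn(a), signal_fn(a + h)
        d = (hi - lo) / h
    if not (math.isfinite(lo) and math.isfinite(hi)):
        raise ValueError("signal function returned non-finite values")
    return d


# ---------------------------------------------------------------------------
# Vectorized signal-vs-diameter evaluation (shared by all scan operations)
# ---------------------------------------------------------------------------

def _restricted_vs_diameter(
    p: SequenceParams,
    tissue: TissueModel,
    scenario: Scenario,
    basis: CylinderGPDBasis,
    diameters: np.ndarray,
    w: EffectiveWaveform | None = None,
) -> np.ndarray:
    """Restricted-compartment signal fraction S_r(a) for an array of diameters.

    Under dispersion this is the Watson-averaged restricted signal.
    """
    if w is None:
        w = build_effective_waveform(p)
    diameters = np.asarray(diameters, dtype=float)
    b = bvalue_numeric(w)
    ln_perp = gpd_perp_log_attenuation_multi(w, diameters / 2.0, tissue.D_par, basis)
    if not scenario.dispersed:
        geom = FiberGeometry.from_theta_deg(scenario.theta_deg)
        return np.exp(-b * geom.cos2 * tissue.D_par + geom.sin2 * ln_perp)
    watson = WatsonModel.perpendicular_to_gradient(scenario.kappa)
    quad = spherical_quadrature(kappa=watson.kappa)
    nodes = quad.nodes @ _rotation_to(watson.mu).T
    t = nodes @ watson.mu
    log_c = math.log(4.0 * math.pi) + log_kummer_m_half(watson.kappa)
    wgt = quad.weights * np.exp(watson.kappa * t**2 - log_c)
    cos2 = (nodes @ np.array([1.0, 0.0, 0.0])) ** 2  # gradient along x
    sin2 = 1.0 - cos2
    # (nA, nodes) matrix of per-orientation restricted signals
    sr = np.exp(-b * tissue.D_par * cos2[None, :] + ln_perp[:, None] * sin2[None, :])
    return sr @ wgt


def _hindered_fraction(
    p: SequenceParams,
    tissue: TissueModel,
    scenario: Scenario,
    w: EffectiveWaveform | None = None,
) -> float:
    if w is None:
        w = build_effective_waveform(p)
    b = bvalue_numeric(w)
    if not scenario.dispersed:
        geom = FiberGeometry.from_theta_deg(scenario.theta_deg)
        return math.exp(-b * (tissue.D_par * geom.cos2 + tissue.D_perp * geom.sin2))
    watson = WatsonModel.perpendicular_to_gradient(scenario.kappa)
    quad = spherical_quadrature(kappa=watson.kappa)
    nodes = quad.nodes @ _rotation_to(watson.mu).T
    t = nodes @ watson.mu
    log_c = math.log(4.0 * math.pi) + log_kummer_m_half(watson.kappa)
    wgt = quad.weights * np.exp(watson.kappa * t**2 - log_c)
    cos2 = (nodes @ np.array([1.0, 0.0, 0.0])) ** 2
    sh = np.exp(-b * (tissue.D_par * cos2 + tissue.D_perp * (1.0 - cos2)))
    return float(wgt @ sh)


def signals_vs_diameter(
    p: SequenceParams,
    tissue: TissueModel,
    scenario: Scenario,
    basis: CylinderGPDBasis,
    diameters: np.ndarray,
    w: EffectiveWaveform | None = None,
) -> np.ndarray:
    """Composite signal S*(a) over an array of diameters (single waveform pass)."""
    if w is None:
        w = build_effective_waveform(p)
    sr = _restricted_vs_diameter(p, tissue, scenario, basis, diameters, w=w)
    sh = _hindered_fraction(p, tissue, scenario, w=w)
    s = tissue.f * sr + (1.0 - tissue.f) * sh
    if scenario.include_T2:
        s = s * math.exp(-p.te / tissue.T2)
    return s


# ---------------------------------------------------------------------------
# Sensitivity |S'(a)|
# ---------------------------------------------------------------------------

def _fd_diameters(a: float, h: float) -> tuple[np.ndarray, float]:
    if a >= h:
        return np.array([a - h, a + h]), 2.0 * h
    return np.array([a, a + h]), h


def sensitivity_restricted(
    p: SequenceParams,
    tissue: TissueModel,
    basis: CylinderGPDBasis,
    scenario: Scenario | None = None,
    a: float | None = None,
    h: float = DEFAULT_H,
) -> float:
    """|dS_r/da| of the restricted compartment alone (no T2, no f), 1/m."""
    if scenario is None:
        scenario = Scenario(include_T2=False)
    a = tissue.a if a is None else a
    d, span = _fd_diameters(a, h)
    sr = _restricted_vs_diameter(p, tissue, scenario, basis, d)
    return abs(float(sr[1] - sr[0])) / span


def sensitivity_full(
    p: SequenceParams,
    tissue: TissueModel,
    basis: CylinderGPDBasis,
    scenario: Scenario = PERPENDICULAR,
    a: float | None = None,
    h: float = DEFAULT_H,
) -> float:
    """|S*'(a)| = w_T2 * f * |dS_r/da| of the full signal, 1/m.

    The hindered compartment is diameter-independent and drops out of the
    derivative; under dispersion the derivative is of the Watson-averaged
    restricted signal.
    """
    a = tissue.a if a is None else a
    d, span = _fd_diameters(a, h)
    sr = _restricted_vs_diameter(p, tissue, scenario, basis, d)
    val = tissue.f * abs(float(sr[1] - sr[0])) / span
    if scenario.include_T2:
        val *= math.exp(-p.te / tissue.T2)
    return val


# ---------------------------------------------------------------------------
# Plateau separation Delta_0
# ---------------------------------------------------------------------------

def delta0_plateau(
    G: float,
    delta: float,
    N: int,
    tissue: TissueModel,
    basis: CylinderGPDBasis,
    slew_rate: float = 200.0,
    step: float = 1e-4,
    Delta_max: float = 0.100,
    rel_tol: float = 0.01,
) -> tuple[float, bool]:
    """Smallest Delta_0 such that the perpendicular restricted signal varies
    by less than ``rel_tol`` relative to its value at ``Delta_max`` for every
    Delta >= delta + Delta_0.

    Scanned on a ``step`` grid of separations; returns ``(Delta_0, met)``
    where ``met`` is False if the criterion never holds (then
    ``Delta_0 = Delta_max - delta``).
    """
    p = SequenceParams(G=G, delta=delta, Delta=Delta_max, N=N, slew_rate=slew_rate)
    if not p.slew_feasible():
        raise ValueError("slew-infeasible sequence")
    n = int(math.floor((Delta_max - delta) / step + 1e-9))
    offsets = np.arange(n + 1) * step
    ln = gpd_perp_log_attenuation_vs_separation(
        p, tissue.R, tissue.D_par, basis, delta + offsets
    )
    s = np.exp(ln)
    ref = s[-1]
    rel = np.abs(s - ref) / ref
    # reverse running max: largest future violation from each offset onward
    worst = np.maximum.accumulate(rel[::-1])[::-1]
    ok = worst < rel_tol
    if not ok.any():
        return Delta_max - delta, False
    return float(offsets[int(np.argmax(ok))]), True


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OptimalSequence:
    """Argmax of a sensitivity map; value in 1/um to match the field's plots."""

    params: SequenceParams
    value_per_um: float


@dataclass(frozen=True)
class SensitivityMap:
    """Tidy per-grid-point sensitivities (infeasible points absent)."""

    table: pd.DataFrame  # columns: G, delta, N, Delta, sensitivity_per_um
    scenario: Scenario
    a: float

    @property
    def optimum(self) -> OptimalSequence:
        if len(self.table) == 0:
            raise ValueError("empty feasible grid")
        i = int(self.table["sensitivity_per_um"].to_numpy().argmax())
        row = self.table.iloc[i]
        p = SequenceParams(
            G=float(row.G), delta=float(row.delta), Delta=float(row.Delta),
            N=int(row.N),
        )
        return OptimalSequence(params=p, value_per_um=float(row.sensitivity_per_um))


def sensitivity_map(
    grid: ParameterGrid,
    a: float,
    tissue: TissueModel,
    scenario: Scenario,
    basis: CylinderGPDBasis,
    h: float = DEFAULT_H,
    restricted_only: bool = False,
) -> SensitivityMap:
    """Exhaustive sensitivity evaluation over the feasible grid.

    Enumeration order is (N, delta, G) ascending and the argmax keeps the
    first maximizer, so ties break toward smaller N, then delta, then G.
    """
    rows = []
    tis = replace(tissue, a=a)
    for p in enumerate_grid(grid):
        if restricted_only:
            v = sensitivity_restricted(p, tis, basis, scenario=scenario, a=a, h=h)
        else:
            v = sensitivity_full(p, tis, basis, scenario=scenario, a=a, h=h)
        rows.append((p.G, p.delta, p.N, p.Delta, v * 1e-6))
    table = pd.DataFrame(
        rows, columns=["G", "delta", "N", "Delta", "sensitivity_per_um"]
    )
    return SensitivityMap(table=table, scenario=scenario, a=a)


def optimize_sensitivity(
    grid: ParameterGrid,
    a: float,
    tissue: TissueModel,
    scenario: Scenario,
    basis: CylinderGPDBasis,
    h: float = DEFAULT_H,
    restricted_only: bool = False,
) -> OptimalSequence:
    """Deterministic argmax of the scenario sensitivity over the grid."""
    best: OptimalSequence | None = None
    tis = replace(tissue, a=a)
    for p in enumerate_grid(grid):
        if restricted_only:
            v = sensitivity_restricted(p, tis, basis, scenario=scenario, a=a, h=h)
        else:
            v = sensitivity_full(p, tis, basis, scenario=scenario, a=a, h=h)
        if best is None or v * 1e-6 > best.value_per_um:
            best = OptimalSequence(params=p, value_per_um=v * 1e-6)
    if best is None:
        raise ValueError("empty feasible grid")
    return best


# ---------------------------------------------------------------------------
# Noise-threshold quantities
# ---------------------------------------------------------------------------

def contrast(
    a: float,
    epsilon: float,
    p: SequenceParams,
    tissue: TissueModel,
    scenario: Scenario,
    basis: CylinderGPDBasis,
) -> float:
    """Diameter contrast |S*(a) - S*(a - epsilon)| of the full T2-weighted signal."""
    if epsilon < 0 or a < epsilon:
        raise ValueError("need a >= epsilon >= 0")
    if epsilon == 0:
        return 0.0
    s = signals_vs_diameter(p, tissue, scenario, basis, np.array([a - epsilon, a]))
    return abs(float(s[1] - s[0]))


def _diameter_grid(a_max: float, step: float) -> np.ndarray:
    return np.arange(int(round(a_max / step)) + 1) * step


def resolvable_range(
    epsilon: float,
    noise: NoiseModel,
    p: SequenceParams,
    tissue: TissueModel,
    scenario: Scenario,
    basis: CylinderGPDBasis,
    a_max: float = 10e-6,
    step: float = 0.1e-6,
) -> list[tuple[float, float]]:
    """Maximal diameter interval(s) where the epsilon-contrast exceeds sigma.

    Scans ``a`` from ``epsilon`` to ``a_max`` on a ``step`` grid.  Returns a
    (possibly empty) list of (low, high) intervals in metres.
    """
    grid = _diameter_grid(a_max, step)
    s = signals_vs_diameter(p, tissue, scenario, basis, grid)
    k = int(round(epsilon / step))
    if abs(k * step - epsilon) > 1e-12:
        # epsilon off-grid: evaluate the shifted diameters separately
        lo = signals_vs_diameter(p, tissue, scenario, basis, grid - epsilon)
        c = np.abs(s - lo)
        mask = (grid >= epsilon - 1e-15) & (c > noise.sigma)
    else:
        c = np.full_like(s, np.nan)
        c[k:] = np.abs(s[k:] - s[:len(s) - k])
        mask = np.zeros(len(s), dtype=bool)
        mask[k:] = c[k:] > noise.sigma
    out: list[tuple[float, float]] = []
    i = 0
    while i < len(mask):
        if mask[i]:
            j = i
            while j + 1 < len(mask) and mask[j + 1]:
                j += 1
            out.append((float(grid[i]), float(grid[j])))
            i = j + 1
        else:
            i += 1
    return out


def a0_limit(
    noise: NoiseModel,
    p: SequenceParams,
    tissue: TissueModel,
    scenario: Scenario,
    basis: CylinderGPDBasis,
    a_max: float = 10e-6,
    step: float = 0.1e-6,
) -> float | None:
    """Smallest diameter distinguishable from zero: |S*(a) - S*(0)| > sigma.

    Scanned on a ``step`` grid up to ``a_max``; ``None`` if the threshold is
    never exceeded.
    """
    grid = _diameter_grid(a_max, step)
    s = signals_vs_diameter(p, tissue, scenario, basis, grid)
    diff = np.abs(s - s[0])
    above = diff > noise.sigma
    if not above.any():
        return None
    return float(grid[int(np.argmax(above))])
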