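"""Stochastic oracles for the deterministic pipeline.

Two generators:

* a Monte Carlo random-walk simulator of restricted diffusion inside an
  impermeable cylinder (specular wall reflection), which provides an
  independent estimate of the perpendicular echo attenuation that the GPD
  engine computes analytically;
* a noisy-signal generator that draws repeated noisy realizations of the
  composite signal, turning the deterministic threshold criterion
  ``contrast > sigma`` into an empirical detection rate.

Both are seed-deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .sequence import GAMMA, EffectiveWaveform, SequenceParams
from .signal import CylinderGPDBasis, TissueModel
from .sensitivity import Scenario, NoiseModel, signals_vs_diameter

__all__ = ["WalkerEnsembleSpec", "mc_cylinder_signal", "empirical_distinguishability"]


@dataclass(frozen=True)
class WalkerEnsembleSpec:
    """Monte Carlo ensemble: walker count, time step and RNG seed."""

    n_walkers: int = 50_000
    dt: float = 5e-6
    seed: int = 0


def mc_cylinder_signal(
    w: EffectiveWaveform,
    R: float,
    D: float,
    spec: WalkerEnsembleSpec = WalkerEnsembleSpec(),
) -> tuple[float, float]:
    """Monte Carlo estimate of the perpendicular restricted signal.

    Walkers diffuse in a disc of radius ``R`` (2-D cross-section; the axial
    coordinate is irrelevant for a gradient perpendicular to the axis) with
    per-step displacement ``sqrt(2 D dt)`` per dimension and specular (radial)
    reflection at the wall.  Phase accumulates as
    ``phi = gamma * sum g(t_i) x(t_i) dt``; the echo signal is ``<cos phi>``.

    Returns ``(estimate, standard_error)``.
    """
    step = math.sqrt(2.0 * D * spec.dt)
    if step >= R / 10.0:
        raise ValueError(
            f"time step too coarse: step length {step:.3g} m >= R/10 = {R / 10:.3g} m"
        )
    rng = np.random.default_rng(spec.seed)
    # phase only accumulates while the gradient is on: simulate that window
    if w.segments:
        t_lo, t_hi = w.segments[0].t0, w.segments[-1].t1
    else:
        t_lo, t_hi = 0.0, 0.0
    n_steps = int(math.ceil((t_hi - t_lo) / spec.dt))
    t_mid = t_lo + (np.arange(n_steps) + 0.5) * spec.dt
    g = w.sample(t_mid)

    # uniform start positions in the disc
    u = rng.random(spec.n_walkers)
    phi0 = rng.random(spec.n_walkers) * 2.0 * math.pi
    r0 = R * np.sqrt(u)
    x = r0 * np.cos(phi0)
    y = r0 * np.sin(phi0)
    phase = np.zeros(spec.n_walkers)
    for i in range(n_steps):
        if g[i] != 0.0:
            phase += GAMMA * g[i] * x * spec.dt
        dx, dy = rng.standard_normal((2, spec.n_walkers))
        x = x + step * dx
        y = y + step * dy
        r2 = x * x + y * y
        out = r2 > R * R
        if out.any():
            r = np.sqrt(r2[out])
            scale = (2.0 * R - r) / r  # specular radial reflection
            x[out] *= scale
            y[out] *= scale
    c = np.cos(phase)
    est = float(c.mean())
    se = float(c.std(ddof=1) / math.sqrt(spec.n_walkers))
    return est, se


def empirical_distinguishability(
    a: float,
    epsilon: float,
    p: SequenceParams,
    tissue: TissueModel,
    scenario: Scenario,
    noise: NoiseModel,
    basis: CylinderGPDBasis,
    n_repeats: int = 10_000,
    seed: int = 0,
    rician: bool = False,
) -> float:
    """Fraction of noisy repeats where the diameter contrast survives the noise.

    Draws paired noisy realizations of S*(a) and S*(a - epsilon) with additive
    Gaussian noise of standard deviation ``noise.sigma`` (Rician magnitude
    optionally) and reports the rate at which the realized difference has the
    true sign and magnitude above sigma.  The deterministic criterion
    ``contrast > sigma`` sits at the 50% crossing of this detection curve.
    """
    if epsilon < 0 or a < epsilon:
        raise ValueError("need a >= epsilon >= 0")
    s = signals_vs_diameter(p, tissue, scenario, basis, np.array([a - epsilon, a]))
    rng = np.random.default_rng(seed)
    noisy = s[None, :] + noise.sigma * rng.standard_normal((n_repeats, 2))
    if rician:
        imag = noise.sigma * rng.standard_normal((n_repeats, 2))
        noisy = np.sqrt(noisy**2 + imag**2)
    d = noisy[:, 0] - noisy[:, 1]  # true difference is >= 0 (signal decays with a)
    hits = (d > 0) & (np.abs(d) > noise.sigma)
    if epsilon == 0:
        hits = np.abs(d) > noise.sigma
    return float(hits.mean())
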