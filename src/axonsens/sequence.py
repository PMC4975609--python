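"""Trapezoidal PGSE/OGSE sequence construction, b-values and parameter grids.

A sequence is specified by gradient amplitude ``G`` (T/m), total waveform
duration ``delta`` (s), waveform separation ``Delta`` (s, onset-to-onset) and
the number of alternating lobes ``N`` (``N = 1`` is the classical PGSE pulse
pair).  Each of the two waveforms consists of ``N`` alternating-polarity
trapezoidal lobes of duration ``delta/N``, ramped at the maximum slew rate
(rise time ``t_r = G/SR``), the first lobe positive.  The effective gradient
inverts the sign of the second waveform to account for the 180-degree
refocusing pulse, so the net area of the effective waveform is zero.

All quantities are strictly SI internally (T/m, s, m); unit conversion happens
only at config/CLI boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

#: proton gyromagnetic ratio, rad s^-1 T^-1
GAMMA = 2.675e8


class FeasibilityError(ValueError):
    """Sequence violates the slew-rate constraint (delta/N < 2 G/SR)."""


class GeometryError(ValueError):
    """Sequence timing is geometrically impossible (waveform overlap)."""


@dataclass(frozen=True)
class SequenceParams:
    """Trapezoidal OGSE specification.

    Parameters
    ----------
    G : float
        Gradient amplitude, T/m.
    delta : float
        Duration of each gradient waveform, s.
    Delta : float
        Separation between waveform onsets, s.
    N : int
        Number of alternating trapezoidal lobes per waveform (>= 1).
    slew_rate : float
        Maximum gradient slew rate, T/m/s.
    tau1, tau2 : float
        Dead times before the first waveform / after the second, s.
    P180 : float
        Refocusing-pulse block duration (incl. crushers), s.
    """

    G: float
    delta: float
    Delta: float
    N: int = 1
    slew_rate: float = 200.0
    tau1: float = 0.010
    tau2: float = 0.020
    P180: float = 0.010

    def __post_init__(self) -> None:
        if not (isinstance(self.N, (int, np.integer)) and self.N >= 1):
            raise ValueError(f"N must be a positive integer, got {self.N!r}")
        for name in ("G", "delta", "Delta", "slew_rate", "tau1", "tau2", "P180"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.G > 0 and self.slew_rate <= 0:
            raise ValueError("slew_rate must be positive for nonzero G")

    @property
    def rise_time(self) -> float:
        """Ramp duration t_r = G/SR, s."""
        return self.G / self.slew_rate if self.G > 0 else 0.0

    @property
    def te(self) -> float:
        """Echo time TE = delta + Delta + tau1 + tau2, s."""
        return self.delta + self.Delta + self.tau1 + self.tau2

    def slew_feasible(self) -> bool:
        """Each lobe of duration delta/N must fit its two ramps."""
        if self.G == 0:
            return True
        if self.delta == 0:
            return False
        return self.delta / self.N >= 2.0 * self.rise_time - 1e-15

    def geometry_valid(self) -> bool:
        """Second waveform must clear the refocusing block: Delta >= delta + P180."""
        return self.Delta >= self.delta + self.P180 - 1e-15

    def is_feasible(self) -> bool:
        return self.slew_feasible() and self.geometry_valid()


def te_of(p: SequenceParams) -> float:
    """Echo time TE(delta, Delta) = delta + Delta + tau1 + tau2 in seconds."""
    return p.te


@dataclass(frozen=True)
class Segment:
    """One linear piece of the effective gradient: g(t) = g0 + slope*(t - t0)."""

    t0: float
    duration: float
    g0: float
    slope: float

    @property
    def t1(self) -> float:
        return self.t0 + self.duration

    @property
    def g1(self) -> float:
        return self.g0 + self.slope * self.duration

    @property
    def area(self) -> float:
        return self.g0 * self.duration + 0.5 * self.slope * self.duration**2


@dataclass(frozen=True)
class EffectiveWaveform:
    """Piecewise-linear effective gradient on [0, TE].

    ``segments`` cover only the intervals where the gradient may be nonzero;
    the gradient is identically zero in any gap between consecutive segments
    and outside them.  Segments are ordered and non-overlapping.
    """

    segments: tuple[Segment, ...]
    te: float
    refocus_time: float

    def __post_init__(self) -> None:
        t = 0.0
        for s in self.segments:
            if s.t0 < t - 1e-12 or s.duration < 0:
                raise ValueError("segments must be ordered and non-overlapping")
            t = s.t1
        if t > self.te + 1e-12:
            raise ValueError("segments extend beyond TE")

    @property
    def net_area(self) -> float:
        return sum(s.area for s in self.segments)

    def breakpoints(self) -> np.ndarray:
        """(time, amplitude) array; jump discontinuities emit duplicate times."""
        pts: list[tuple[float, float]] = [(0.0, 0.0)]
        t = 0.0
        for s in self.segments:
            if s.t0 > t + 1e-15:
                pts.append((s.t0, 0.0))
            if abs(s.g0 - pts[-1][1]) > 1e-15 or abs(s.t0 - pts[-1][0]) > 1e-15:
                pts.append((s.t0, s.g0))
            pts.append((s.t1, s.g1))
            t = s.t1
        if t < self.te - 1e-15:
            if abs(pts[-1][1]) > 1e-15:
                pts.append((t, 0.0))
            pts.append((self.te, 0.0))
        return np.asarray(pts)

    def sample(self, t: np.ndarray) -> np.ndarray:
        """Evaluate g_eff at times ``t`` (exact, no interpolation error)."""
        t = np.asarray(t, dtype=float)
        g = np.zeros_like(t)
        for s in self.segments:
            m = (t >= s.t0) & (t <= s.t1)
            g[m] = s.g0 + s.slope * (t[m] - s.t0)
        return g

    def scaled(self, c: float) -> "EffectiveWaveform":
        """Waveform with all amplitudes multiplied by ``c``."""
        segs = tuple(Segment(s.t0, s.duration, c * s.g0, c * s.slope) for s in self.segments)
        return EffectiveWaveform(segs, self.te, self.refocus_time)


def _lobe_train(t0: float, p: SequenceParams, sign: float) -> list[Segment]:
    """N alternating return-to-zero trapezoidal lobes starting at t0."""
    tr = p.rise_time
    lob = p.delta / p.N
    segs: list[Segment] = []
    for k in range(p.N):
        s = sign * (1.0 if k % 2 == 0 else -1.0)
        a = t0 + k * lob
        amp = s * p.G
        if tr > 0:
            segs.append(Segment(a, tr, 0.0, amp / tr))
            plateau = lob - 2 * tr
            if plateau > 1e-15:
                segs.append(Segment(a + tr, plateau, amp, 0.0))
            segs.append(Segment(a + lob - tr, tr, amp, -amp / tr))
        # G == 0: no segments needed (gradient identically zero)
    return segs


def build_effective_waveform(p: SequenceParams) -> EffectiveWaveform:
    """Construct the effective gradient of a trapezoidal OGSE sequence.

    Two identical lobe trains of duration ``delta`` start at ``tau1`` and
    ``tau1 + Delta``; the second is sign-inverted (effective gradient after
    the refocusing pulse).

    Raises
    ------
    FeasibilityError
        if ``delta/N < 2 t_r`` (lobes cannot fit their ramps).
    GeometryError
        if ``Delta < delta + P180`` (second waveform overlaps the 180 block).
    """
    if not p.slew_feasible():
        raise FeasibilityError(
            f"delta/N = {p.delta / p.N:.6g} s < 2 t_r = {2 * p.rise_time:.6g} s"
        )
    if not p.geometry_valid():
        raise GeometryError(
            f"Delta = {p.Delta:.6g} s < delta + P180 = {p.delta + p.P180:.6g} s"
        )
    segs = _lobe_train(p.tau1, p, +1.0) + _lobe_train(p.tau1 + p.Delta, p, -1.0)
    refocus = p.tau1 + 0.5 * (p.delta + p.Delta)
    return EffectiveWaveform(tuple(segs), te_of(p), refocus)


def rectangular_pgse_waveform(
    G: float, delta: float, Delta: float, tau1: float = 0.010, tau2: float = 0.020
) -> EffectiveWaveform:
    """Idealized rectangular PGSE effective waveform (zero rise time).

    Used as the analytic reference geometry for the van Gelderen closed form;
    physical trapezoidal waveforms come from :func:`build_effective_waveform`.
    """
    segs = (
        Segment(tau1, delta, G, 0.0),
        Segment(tau1 + Delta, delta, -G, 0.0),
    )
    te = delta + Delta + tau1 + tau2
    return EffectiveWaveform(segs, te, tau1 + 0.5 * (delta + Delta))


def bvalue_numeric(w: EffectiveWaveform) -> float:
    """b = gamma^2 * int_0^TE q(t)^2 dt with q(t) = int_0^t g_eff.

    Exact per-segment integration of the piecewise-quadratic q(t); no
    sampling error.  Returns s/m^2.
    """
    total = 0.0
    q = 0.0
    t = 0.0
    for s in w.segments:
        gap = s.t0 - t
        if gap > 0:
            total += q * q * gap
        L, c, sl = s.duration, s.g0, s.slope
        # q(u) = q + c u + sl u^2 / 2 on the segment
        total += (
            q * q * L
            + q * c * L**2
            + (c * c / 3.0 + q * sl / 3.0) * L**3
            + (c * sl / 4.0) * L**4
            + (sl * sl / 20.0) * L**5
        )
        q += s.area
        t = s.t1
    if w.te > t:
        total += q * q * (w.te - t)
    return GAMMA**2 * total


def bvalue_closed_form(p: SequenceParams) -> float:
    """Closed-form b-value of the trapezoidal OGSE sequence, s/m^2.

    First term: diffusion weighting accumulated within the lobe trains.
    Second term: the inter-waveform plateau of q, present only for odd N
    (factor ``1 - (-1)^N``), proportional to ``Delta - delta``.
    """
    if p.G == 0 or p.delta == 0:
        return 0.0
    tr = p.rise_time
    d, N, G = p.delta, p.N, p.G
    term1 = (
        2.0 * G**2 * GAMMA**2 * d**3 / (15.0 * N**2)
        * (5.0 - 15.0 * tr * N / (2.0 * d) - 5.0 * tr**2 * N**2 / (4.0 * d**2)
           + 4.0 * tr**3 * N**3 / d**3)
    )
    term2 = (
        G**2 * GAMMA**2 * (p.Delta - d)
        * ((1.0 - (-1.0) ** N) * (d - N * tr) / (2.0 * N)) ** 2
    )
    return term1 + term2


@dataclass(frozen=True)
class ParameterGrid:
    """Finite, deterministic enumeration of the sequence-parameter space.

    ``Delta_rule`` is either the string ``"optimal"`` (Delta = delta + P180,
    the shortest geometrically valid separation) or an explicit
    ``(min, max, step)`` range in seconds.
    """

    G_values: tuple[float, ...]
    delta_values: tuple[float, ...]
    N_values: tuple[int, ...] = (1,)
    Delta_rule: str | tuple[float, float, float] = "optimal"
    slew_rate: float = 200.0
    tau1: float = 0.010
    tau2: float = 0.020
    P180: float = 0.010

    @staticmethod
    def regular(
        G_max: float = 0.300,
        G_step: float = 0.001,
        delta_max: float = 0.060,
        delta_step: float = 0.001,
        N_values: Sequence[int] = (1,),
        G_min: float = 0.0,
        delta_min: float = 0.0,
        **kw,
    ) -> "ParameterGrid":
        nG = int(round((G_max - G_min) / G_step))
        nd = int(round((delta_max - delta_min) / delta_step))
        return ParameterGrid(
            G_values=tuple(G_min + i * G_step for i in range(nG + 1)),
            delta_values=tuple(delta_min + i * delta_step for i in range(nd + 1)),
            N_values=tuple(int(n) for n in N_values),
            **kw,
        )


def enumerate_grid(grid: ParameterGrid) -> list[SequenceParams]:
    """Deterministic ordered enumeration of feasible sequences in the grid.

    Order is (N, delta, G) ascending.  Slew-infeasible combinations and
    geometrically invalid Delta are dropped silently; an empty grid yields an
    empty list.
    """
    out: list[SequenceParams] = []
    for N in grid.N_values:
        for d in grid.delta_values:
            for G in grid.G_values:
                if isinstance(grid.Delta_rule, str):
                    if grid.Delta_rule != "optimal":
                        raise ValueError(f"unknown Delta rule {grid.Delta_rule!r}")
                    Deltas = [d + grid.P180]
                else:
                    lo, hi, step = grid.Delta_rule
                    n = int(round((hi - lo) / step))
                    Deltas = [lo + i * step for i in range(n + 1)]
                for D in Deltas:
                    p = SequenceParams(
                        G=G, delta=d, Delta=D, N=N, slew_rate=grid.slew_rate,
                        tau1=grid.tau1, tau2=grid.tau2, P180=grid.P180,
                    )
                    if p.is_feasible():
                        out.append(p)
    return out


def export_waveform(w: EffectiveWaveform, path, header: str = "") -> None:
    """Write breakpoints as two-column plain text (time_s, amplitude_T_per_m)."""
    bp = w.breakpoints()
    lines = [f"# {line}" for line in header.splitlines() if line]
    lines.append("# time_s amplitude_T_per_m")
    lines += [f"{t:.9e} {g:.9e}" for t, g in bp]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
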