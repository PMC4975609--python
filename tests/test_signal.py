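"""GPD cylinder engine and the two-compartment signal model."""

import math

import numpy as np
import pytest
from scipy.special import jvp

from axonsens import (
    FiberGeometry,
    SequenceParams,
    TissueModel,
    bessel_prime_roots,
    build_effective_waveform,
    bvalue_numeric,
    composite_signal,
    gpd_perp_log_attenuation,
    hindered_signal,
    rectangular_pgse_waveform,
    restricted_signal,
    vangelderen_pgse_log,
)
from axonsens.sequence import EffectiveWaveform, Segment
from axonsens.signal import (
    gpd_perp_log_attenuation_discretized,
    gpd_perp_log_attenuation_vs_separation,
)

D_PAR = 1.7e-9


def bracketed_j1p_roots(M):
    """Independent oracle: sign-change bracketing of J1' on a fine grid."""
    xs = np.linspace(1e-6, 5.0 + math.pi * M, 200 * M)
    vals = jvp(1, xs)
    roots = []
    for lo, hi in zip(xs[:-1], xs[1:]):
        if jvp(1, lo) * jvp(1, hi) < 0:
            for _ in range(200):
                mid = 0.5 * (lo + hi)
                if jvp(1, lo) * jvp(1, mid) <= 0:
                    hi = mid
                else:
                    lo = mid
            roots.append(0.5 * (lo + hi))
    return np.array(roots[:M])


class TestBesselBasis:
    def test_first_root_value(self, basis):
        assert basis.mu[0] == pytest.approx(1.841184, abs=1e-6)

    def test_roots_match_bracketing_oracle(self, basis):
        oracle = bracketed_j1p_roots(5)
        assert np.allclose(basis.mu[:5], oracle, atol=1e-8)

    def test_ascending_with_pi_gaps(self):
        mu = bessel_prime_roots(20).mu
        assert np.all(np.diff(mu) > 0)
        assert np.diff(mu)[-1] == pytest.approx(math.pi, abs=0.01)

    def test_residuals_small(self, basis):
        assert np.max(np.abs(jvp(1, basis.mu))) < 1e-10

    def test_zero_modes_rejected(self):
        with pytest.raises(ValueError):
            bessel_prime_roots(0)


class TestGPDEngine:
    @pytest.mark.parametrize("R_um", [1.0, 2.0, 5.0])
    @pytest.mark.parametrize("delta_ms,Delta_ms", [(20, 40), (36, 46), (50, 90)])
    def test_matches_van_gelderen_on_rectangular_pgse(self, basis, R_um, delta_ms, Delta_ms):
        G, d, D = 0.15, delta_ms * 1e-3, Delta_ms * 1e-3
        w = rectangular_pgse_waveform(G, d, D)
        engine = gpd_perp_log_attenuation(w, R_um * 1e-6, D_PAR, basis)
        closed = vangelderen_pgse_log(G, d, D, R_um * 1e-6, D_PAR, basis)
        assert engine == pytest.approx(closed, rel=1e-8)

    def test_vanishing_pore_no_attenuation(self, basis):
        w = build_effective_waveform(SequenceParams(G=0.3, delta=0.03, Delta=0.05))
        assert gpd_perp_log_attenuation(w, 0.0, D_PAR, basis) == 0.0

    def test_nonpositive_diffusivity_rejected(self, basis):
        w = build_effective_waveform(SequenceParams(G=0.3, delta=0.03, Delta=0.05))
        with pytest.raises(ValueError):
            gpd_perp_log_attenuation(w, 2e-6, 0.0, basis)

    def test_matches_discretized_oracle_on_trapezoid(self, basis):
        p = SequenceParams(G=0.06, delta=0.030, Delta=0.045, N=3)
        w = build_effective_waveform(p)
        exact = gpd_perp_log_attenuation(w, 2e-6, D_PAR, basis)
        approx = gpd_perp_log_attenuation_discretized(w, 2e-6, D_PAR, basis, dt=1e-5)
        assert exact == pytest.approx(approx, rel=5e-4)

    def test_polarity_and_time_reversal_invariance(self, basis):
        p = SequenceParams(G=0.2, delta=0.040, Delta=0.055, N=2)
        w = build_effective_waveform(p)
        ref = gpd_perp_log_attenuation(w, 3e-6, D_PAR, basis)
        flipped = gpd_perp_log_attenuation(w.scaled(-1.0), 3e-6, D_PAR, basis)
        segs = tuple(
            Segment(w.te - s.t1, s.duration, s.g1, -s.slope)
            for s in reversed(w.segments)
        )
        reversed_w = EffectiveWaveform(segs, w.te, w.refocus_time)
        assert flipped == pytest.approx(ref, rel=1e-12)
        assert gpd_perp_log_attenuation(reversed_w, 3e-6, D_PAR, basis) == pytest.approx(
            ref, rel=1e-10
        )

    @pytest.mark.parametrize("a_um", [1, 4, 10, 20])
    def test_truncation_converged_at_default_order(self, a_um):
        p = SequenceParams(G=0.3, delta=0.036, Delta=0.046)
        w = build_effective_waveform(p)
        b20 = bessel_prime_roots(20)
        b40 = bessel_prime_roots(40)
        s20 = gpd_perp_log_attenuation(w, a_um * 0.5e-6, D_PAR, b20)
        s40 = gpd_perp_log_attenuation(w, a_um * 0.5e-6, D_PAR, b40)
        assert s20 == pytest.approx(s40, rel=1e-8, abs=1e-10)

    def test_separation_profile_equals_direct_evaluation(self, basis):
        p = SequenceParams(G=0.2, delta=0.020, Delta=0.100, N=1)
        Deltas = np.array([0.030, 0.045, 0.080])
        prof = gpd_perp_log_attenuation_vs_separation(p, 4e-6, D_PAR, basis, Deltas)
        for Dl, expected in zip(Deltas, prof):
            w = build_effective_waveform(
                SequenceParams(G=0.2, delta=0.020, Delta=Dl, N=1)
            )
            assert gpd_perp_log_attenuation(w, 4e-6, D_PAR, basis) == pytest.approx(
                expected, rel=1e-10
            )

    def test_restricted_signal_flattens_with_separation(self, basis):
        p = SequenceParams(G=0.3, delta=0.010, Delta=0.100, N=1)
        Deltas = np.array([0.020, 0.030, 0.060, 0.070, 0.095, 0.100])
        s = np.exp(gpd_perp_log_attenuation_vs_separation(p, 5e-6, D_PAR, basis, Deltas))
        assert abs(s[5] - s[4]) < abs(s[1] - s[0])
        assert abs(s[3] - s[2]) < abs(s[1] - s[0])


class TestCompartments:
    def test_perpendicular_restricted_is_pure_gpd(self, basis, tissue):
        p = SequenceParams(G=0.2, delta=0.030, Delta=0.045)
        w = build_effective_waveform(p)
        sr = restricted_signal(p, tissue, FiberGeometry.perpendicular(), basis, w=w)
        assert sr == pytest.approx(
            math.exp(gpd_perp_log_attenuation(w, tissue.R, tissue.D_par, basis)), rel=1e-12
        )

    def test_axial_restricted_is_free_diffusion(self, basis, tissue):
        p = SequenceParams(G=0.2, delta=0.030, Delta=0.045)
        w = build_effective_waveform(p)
        b = bvalue_numeric(w)
        for a in (1e-6, 8e-6):
            tis = TissueModel(f=tissue.f, D_par=tissue.D_par, a=a, T2=tissue.T2)
            sr = restricted_signal(p, tis, FiberGeometry(psi=0.0), basis, w=w)
            assert sr == pytest.approx(math.exp(-b * tissue.D_par), rel=1e-12)

    def test_larger_pores_attenuate_more_at_strong_pgse(self, basis, tissue):
        p = SequenceParams(G=0.3, delta=0.030, Delta=0.045)
        geom = FiberGeometry.perpendicular()
        small = restricted_signal(p, TissueModel(a=2e-6), geom, basis)
        large = restricted_signal(p, TissueModel(a=10e-6), geom, basis)
        assert small > large

    def test_tortuosity_perpendicular_diffusivity(self, tissue):
        assert tissue.D_perp == pytest.approx(0.51e-9)

    def test_hindered_limits(self, tissue):
        geom = FiberGeometry.perpendicular()
        assert hindered_signal(0.0, geom, tissue) == 1.0
        iso = TissueModel(f=0.0, D_par=1.7e-9)
        b = 1e9
        assert hindered_signal(b, geom, iso) == pytest.approx(math.exp(-b * 1.7e-9))

    def test_composite_normalization_and_t2(self, basis, tissue):
        p = SequenceParams(G=0.0, delta=0.036, Delta=0.046)
        geom = FiberGeometry.perpendicular()
        assert composite_signal(p, tissue, geom, basis=basis) == pytest.approx(1.0)
        with_t2 = composite_signal(p, tissue, geom, include_T2=True, basis=basis)
        assert with_t2 == pytest.approx(math.exp(-0.112 / 0.070), rel=1e-12)

    def test_single_compartment_limit(self, basis):
        tis = TissueModel(f=1.0, a=4e-6)
        p = SequenceParams(G=0.25, delta=0.030, Delta=0.045)
        w = build_effective_waveform(p)
        s = composite_signal(p, tis, FiberGeometry.perpendicular(), basis=basis, w=w)
        assert s == pytest.approx(
            math.exp(gpd_perp_log_attenuation(w, tis.R, tis.D_par, basis)), rel=1e-12
        )

    @pytest.mark.parametrize("theta_deg", [0.0, 10.0, 45.0])
    def test_signals_bounded_in_unit_interval(self, basis, tissue, theta_deg):
        p = SequenceParams(G=0.3, delta=0.040, Delta=0.055, N=2)
        geom = FiberGeometry.from_theta_deg(theta_deg)
        s = composite_signal(p, tissue, geom, basis=basis)
        assert 0.0 < s <= 1.0
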