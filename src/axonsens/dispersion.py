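"""Watson orientation dispersion of the two-compartment signal.

Fiber orientations ``n`` are distributed on the sphere with the antipodally
symmetric Watson density

    W(n) = exp(kappa (mu . n)^2) / (4 pi M(1/2, 3/2, kappa)),

where ``mu`` is the mean axis, ``kappa >= 0`` the concentration (kappa = 0 is
uniform; coherent white matter has kappa around 8-32) and M the confluent
hypergeometric (Kummer) function.  Both compartments — restricted and
hindered — are averaged over the same distribution.

The average is computed with a product quadrature, Gauss-Legendre in the
polar cosine times a uniform azimuth rule, on one hemisphere with doubled
weights (antipodal symmetry).  Because every per-orientation signal is a
closed form in ``b`` and ``ln S_perp`` of the fixed waveform, the average
costs one GPD evaluation regardless of the quadrature order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import dawsn

from .sequence import EffectiveWaveform, SequenceParams, build_effective_waveform, bvalue_numeric
from .signal import CylinderGPDBasis, TissueModel, gpd_perp_log_attenuation

__all__ = [
    "WatsonModel",
    "SphericalQuadrature",
    "spherical_quadrature",
    "kummer_m_half",
    "log_kummer_m_half",
    "watson_density",
    "dispersed_compartments",
    "dispersed_signal",
]

_X_AXIS = np.array([1.0, 0.0, 0.0])
_Z_AXIS = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class WatsonModel:
    """Watson distribution: mean axis ``mu`` (unit 3-vector) and ``kappa >= 0``."""

    mu: np.ndarray = field(default_factory=lambda: _Z_AXIS.copy())
    kappa: float = 16.0

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        nrm = np.linalg.norm(mu)
        if not math.isclose(nrm, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError("mean axis mu must be a unit vector")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0 (bipolar Watson not supported)")
        object.__setattr__(self, "mu", mu)

    @staticmethod
    def perpendicular_to_gradient(kappa: float) -> "WatsonModel":
        """Mean axis along z with the gradient understood to be along x."""
        return WatsonModel(mu=_Z_AXIS.copy(), kappa=kappa)


def kummer_m_half(kappa: float) -> float:
    """Kummer function M(1/2, 3/2, kappa) = int_0^1 exp(kappa t^2) dt.

    Dawson-function identity exp(k) dawsn(sqrt(k)) / sqrt(k) for k >= 1e-6,
    Taylor series below; continuous across the switch.  Overflows for
    kappa >~ 709; use :func:`log_kummer_m_half` there.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if kappa < 1e-6:
        return 1.0 + kappa / 3.0 + kappa**2 / 10.0
    rk = math.sqrt(kappa)
    return math.exp(kappa) * dawsn(rk) / rk


def log_kummer_m_half(kappa: float) -> float:
    """log M(1/2, 3/2, kappa), stable for arbitrarily large kappa."""
    if kappa < 1e-6:
        return math.log(kummer_m_half(kappa))
    rk = math.sqrt(kappa)
    return kappa + math.log(dawsn(rk) / rk)


def watson_density(n: np.ndarray, model: WatsonModel) -> float | np.ndarray:
    """Watson probability density (1/sr) at unit vector(s) ``n``."""
    n = np.asarray(n, dtype=float)
    t = n @ model.mu
    log_c = math.log(4.0 * math.pi) + log_kummer_m_half(model.kappa)
    return np.exp(model.kappa * t**2 - log_c)


@dataclass(frozen=True)
class SphericalQuadrature:
    """Nodes (unit vectors) and positive weights summing to 4 pi."""

    nodes: np.ndarray
    weights: np.ndarray
    n_polar: int = 0
    n_azimuth: int = 0


def _polar_panels(kappa: float) -> list[tuple[float, float]]:
    """Panel breakpoints in s = 1 - cos(polar), refined toward the pole.

    For concentrated Watson densities the mass sits in a boundary layer of
    width ~ 1/(2 kappa) in cos(polar) around the mean axis; geometric panels
    resolve it at any kappa.
    """
    if kappa <= 32.0:
        return [(0.0, 1.0)]
    edges = [0.0]
    s = 1.0 / (4.0 * kappa)
    while s < 1.0:
        edges.append(s)
        s *= 4.0
    edges.append(1.0)
    return list(zip(edges[:-1], edges[1:]))


@lru_cache(maxsize=32)
def _quadrature_cached(n_polar: int, n_azimuth: int, kappa: float) -> SphericalQuadrature:
    panels = _polar_panels(kappa)
    cts, wcts = [], []
    x, wx = np.polynomial.legendre.leggauss(n_polar)
    for s0, s1 in panels:
        # s = 1 - cos(polar) on the panel; ct near 1 is the quadrature pole
        s = s0 + 0.5 * (x + 1.0) * (s1 - s0)
        cts.append(1.0 - s)
        wcts.append(0.5 * (s1 - s0) * wx)
    ct = np.concatenate(cts)
    wct = np.concatenate(wcts)
    st = np.sqrt(np.clip(1.0 - ct**2, 0.0, None))
    phi = 2.0 * math.pi * (np.arange(n_azimuth) + 0.5) / n_azimuth
    wphi = 2.0 * math.pi / n_azimuth
    nodes = np.stack(
        [
            np.outer(st, np.cos(phi)).ravel(),
            np.outer(st, np.sin(phi)).ravel(),
            np.outer(ct, np.ones(n_azimuth)).ravel(),
        ],
        axis=1,
    )
    # hemisphere weights doubled: antipodally symmetric integrands only
    weights = 2.0 * np.outer(wct, np.full(n_azimuth, wphi)).ravel()
    return SphericalQuadrature(nodes=nodes, weights=weights,
                               n_polar=n_polar, n_azimuth=n_azimuth)


def spherical_quadrature(
    n_polar: int = 48, n_azimuth: int = 96, kappa: float = 0.0
) -> SphericalQuadrature:
    """Product quadrature exact for constants; integrates (mu.n)^2 to 4 pi/3.

    ``n_polar`` Gauss-Legendre nodes per polar panel times a uniform azimuth
    rule on one hemisphere with doubled weights.  ``kappa`` adapts the polar
    panel layout to the concentration of the Watson density to be integrated
    (the quadrature pole must then be aligned with the mean axis).
    """
    return _quadrature_cached(n_polar, n_azimuth, float(kappa))


def _rotation_to(axis: np.ndarray) -> np.ndarray:
    """Orthonormal matrix whose third column is ``axis``."""
    z = np.asarray(axis, dtype=float)
    helper = _X_AXIS if abs(z[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(helper, z)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(z, e1)
    return np.stack([e1, e2, z], axis=1)


def _per_orientation_compartments(
    cos_psi2: np.ndarray, b: float, ln_perp: float, tissue: TissueModel
) -> tuple[np.ndarray, np.ndarray]:
    sin_psi2 = 1.0 - cos_psi2
    sr = np.exp(-b * cos_psi2 * tissue.D_par + sin_psi2 * ln_perp)
    sh = np.exp(-b * (tissue.D_par * cos_psi2 + tissue.D_perp * sin_psi2))
    return sr, sh


def dispersed_compartments(
    p: SequenceParams,
    tissue: TissueModel,
    watson: WatsonModel,
    g_axis: np.ndarray = _X_AXIS,
    basis: CylinderGPDBasis | None = None,
    w: EffectiveWaveform | None = None,
    quad: SphericalQuadrature | None = None,
    ln_perp: float | None = None,
    b: float | None = None,
) -> tuple[float, float]:
    """Watson-averaged (restricted, hindered) signal fractions.

    ``ln_perp``/``b`` may be supplied to reuse waveform-level quantities
    across diameters; otherwise they are computed from ``p``.
    """
    if w is None and (ln_perp is None or b is None):
        w = build_effective_waveform(p)
    if b is None:
        b = bvalue_numeric(w)
    if ln_perp is None:
        if basis is None:
            raise ValueError("basis required to evaluate the GPD attenuation")
        ln_perp = gpd_perp_log_attenuation(w, tissue.R, tissue.D_par, basis)
    if quad is None:
        quad = spherical_quadrature(kappa=watson.kappa)
    # rotate the quadrature so its pole coincides with the mean axis
    nodes = quad.nodes @ _rotation_to(watson.mu).T
    t = nodes @ watson.mu
    log_c = math.log(4.0 * math.pi) + log_kummer_m_half(watson.kappa)
    wgt = quad.weights * np.exp(watson.kappa * t**2 - log_c)
    cos_psi2 = (nodes @ np.asarray(g_axis, dtype=float)) ** 2
    sr, sh = _per_orientation_compartments(cos_psi2, b, ln_perp, tissue)
    return float(wgt @ sr), float(wgt @ sh)


def dispersed_signal(
    p: SequenceParams,
    tissue: TissueModel,
    watson: WatsonModel,
    g_axis: np.ndarray = _X_AXIS,
    basis: CylinderGPDBasis | None = None,
    include_T2: bool = False,
    quad: SphericalQuadrature | None = None,
    verify: bool = False,
) -> float:
    """Orientation-averaged composite signal S* under Watson dispersion.

    With ``verify=True`` the quadrature order is doubled and a change above
    1e-6 raises ``RuntimeError``.
    """
    if basis is None:
        from .signal import DEFAULT_BASIS_SIZE, bessel_prime_roots

        basis = bessel_prime_roots(DEFAULT_BASIS_SIZE)
    w = build_effective_waveform(p)
    sr, sh = dispersed_compartments(p, tissue, watson, g_axis, basis, w=w, quad=quad)
    s = tissue.f * sr + (1.0 - tissue.f) * sh
    if verify:
        q = quad if quad is not None else spherical_quadrature(kappa=watson.kappa)
        q2 = spherical_quadrature(2 * q.n_polar, 2 * q.n_azimuth, kappa=watson.kappa)
        sr2, sh2 = dispersed_compartments(p, tissue, watson, g_axis, basis, w=w, quad=q2)
        s2 = tissue.f * sr2 + (1.0 - tissue.f) * sh2
        if abs(s2 - s) > 1e-6:
            raise RuntimeError(
                f"spherical quadrature not converged: change {abs(s2 - s):.3e} on doubling"
            )
    if include_T2:
        s *= math.exp(-p.te / tissue.T2)
    return float(s)
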