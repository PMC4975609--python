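# Methods

## Model

The package simulates the proton-density-normalized diffusion-weighted
spin-echo signal of white matter as a two-compartment substrate:

    S*(a) = exp(-TE/T2) * ( f * S_r(a) + (1 - f) * S_h )

* **Restricted compartment** `S_r`: water inside impermeable, non-abutting
  parallel cylinders of a single diameter `a`.  Diffusion along the cylinder
  axis is free with intrinsic diffusivity `D_par`; the perpendicular echo
  attenuation is the Gaussian phase distribution (GPD, second-cumulant)
  approximation for a disc of radius `R = a/2` (the public parameter is the
  diameter; the halving happens in exactly one place,
  `TissueModel.R`).  For a fiber at angle `psi` to the gradient axis the
  signal factorizes into parallel (free) and perpendicular (restricted)
  parts: `S_r = exp(-b cos^2(psi) D_par) * S_perp(g sin(psi))`, and since
  `ln S_perp` is exactly quadratic in the gradient amplitude the scaled
  waveform contributes `sin^2(psi) * ln S_perp(g)`.
* **Hindered compartment** `S_h`: an anisotropic Gaussian (diffusion-tensor)
  pool with the same parallel diffusivity and a tortuosity-reduced
  perpendicular diffusivity `D_perp = D_par (1 - f)`.  It carries no diameter
  dependence, so it cancels from every derivative and contrast quantity.
* **T2 weighting**: `S0 = exp(-TE/T2)` with `TE = delta + Delta + tau1 +
  tau2`, assuming infinite TR and normalizing by proton density.
* **Orientation dispersion** (optional): fiber directions follow a Watson
  distribution `W(n) ∝ exp(kappa (mu.n)^2)` with mean axis `mu` and
  concentration `kappa` (antipodally symmetric; `kappa = 0` uniform, 8–32
  typical of coherent white matter).  *Both* compartments are averaged over
  the same distribution; the average of the hindered pool also cancels from
  diameter contrasts.

## Sequences

Only trapezoidal waveforms are modelled: two identical trains of `N`
alternating-polarity return-to-zero trapezoidal lobes (duration `delta/N`
each, rise time `t_r = G/SR`, first lobe positive), starting at `tau1` and
`tau1 + Delta`, with the second train sign-inverted in the effective gradient
(the refocusing pulse).  `N = 1` is the classical PGSE pulse pair.  This lobe
convention is not arbitrary: it is pinned by an enforced test showing that
the exact per-segment numeric `b = gamma^2 \int q(t)^2 dt` of the constructed
waveform equals the closed-form b-value (including its odd/even-N parity
term) to better than 1e-6 relative over a randomized feasible sample.

Feasibility requires each lobe to fit its two ramps (`delta/N >= 2 t_r`) and
the second waveform to clear the refocusing block (`Delta >= delta + P180`).
Waveforms are represented by exact linear segments, never sampled arrays; all
integrals over them (q(t)^2, the GPD kernel) are per-segment closed forms.

## GPD engine

With `mu_m` the positive roots of J1' and `B_m = R^2 / (mu_m^2 (mu_m^2 - 1))`,

    ln S_perp = -gamma^2 * sum_m B_m * K_m,
    K_m = ∫∫ g(t1) g(t2) exp(-D mu_m^2 |t1 - t2| / R^2) dt1 dt2.

`K_m` is evaluated exactly for piecewise-linear `g`: the diagonal
(same-segment) blocks have closed polynomial-times-exponential
antiderivatives and the off-diagonal blocks factorize into per-segment
"head" and "tail" integrals chained by a decaying recursion, so all
exponential arguments are non-positive and the evaluation is stable for
arbitrarily large `mu_m^2 D / R^2`.  Three independent checks pin the engine
down:

1. it reproduces the van Gelderen closed form for rectangular PGSE to 1e-8
   relative;
2. it agrees with a midpoint time-discretized evaluation of the same double
   integral (test oracle, dt = 10 us) on trapezoidal OGSE;
3. it agrees with a Monte Carlo random walk in a disc within
   max(2%, 3 standard errors) across diameters 2–10 um and N in {1, 4}.

The separation (Delta) dependence enters only through cross terms between the
two lobe trains and factorizes as `head * tail * exp(-lam (Delta - delta))`;
`gpd_perp_log_attenuation_vs_separation` exploits this to scan hundreds of
separations for the cost of one waveform evaluation (used by the plateau
scan), and is tested to match direct evaluation to 1e-10.

## Parameters and defaults

| parameter | default | unit | rationale |
|---|---|---|---|
| f | 0.7 | – | typical intra-axonal volume fraction of white matter |
| D_par | 1.7e-9 | m^2/s | in-vivo white-matter intrinsic diffusivity |
| T2 | 70 | ms | white matter at 3 T |
| tau1, tau2, P180 | 10, 20, 10 | ms | typical spin-echo dead times and refocusing block |
| SR | 200 | T/m/s | human gradient slew limit |
| G range | 0–300 | mT/m | clinical (60) up to high-end research (300) hardware |
| delta range | 0–60 | ms | echo-time-limited pulse durations |
| N | 1–10 | – | integer lobe counts; N=1 is PGSE |
| gamma | 2.675e8 | rad/s/T | proton gyromagnetic ratio |
| eigenmodes M | 20 | – | doubling to 40 changes ln S_perp by < 1e-8 relative for a <= 20 um |
| FD step h | 0.01 | um | central difference; halving changes sensitivities < 0.1% |
| diameter scan | 0.1 | um | resolution of a0 and range reports |
| Delta scan | 0.1 | ms | resolution of plateau times |

Internal units are strictly SI; mT/m, ms and um appear only at the CLI/config
boundary.

## Sensitivity and noise thresholds

Sensitivity is `|S*'(a)| = exp(-TE/T2) f |dS_r/da|` by central finite
difference (one-sided at `a < h`; the `a = 0` limit `S_perp = 1` is analytic,
so no special-casing is needed downstream).  Grid searches enumerate
(N, delta, G) ascending and keep the first maximizer, so ties break toward
the simpler, shorter, weaker sequence.  Sensitivities are reported per um
(SI derivative x 1e-6) to match the field's plotting convention.

Because the signal is nonlinear in `a`, finite resolvability uses the
contrast `|S*(a) - S*(a - eps)|` rather than the slope, compared against the
noise standard deviation `sigma = exp(-TE0/T2)/SNR` at the reference echo
time TE0 = 120 ms (giving sigma = 0.018, 0.009, 0.0036 for SNR = 10, 20, 50).
`a0` is the smallest diameter on the 0.1 um grid with
`|S*(a) - S*(0)| > sigma`.  The noise-threshold experiments take their
gradient duration from the canonical optimal-delta table
(`axonsens.reference.OPTIMAL_DELTA_MS`, the a in {1,2,3} um averages), which
decouples resolution results from optimizer grid details; our own optimizer
reproduces that table (exactly for the dispersion scenario at G = 300,
within 1 ms elsewhere).

## Plateau separation Delta_0

`Delta_0` is the smallest extra separation beyond `delta` after which the
perpendicular restricted signal stops changing with `Delta`:
on a 0.1 ms grid up to `Delta_max = 100 ms`, the smallest offset such that
the relative deviation from the `Delta_max` reference signal stays below 1%
for all larger separations.  The "1% change" criterion admits several
operationalizations (relative to the plateau value, absolute in normalized
signal units, normalized by the attenuation depth); this package uses the
relative-to-plateau form.  For heavily attenuated combinations (signal near
zero) the relative criterion maximizes over combinations whose absolute
signal changes are physically negligible; the absolute variant is available
through the same scan utilities.  Published plateau values for large
diameters fall between the two operationalizations, and neither reproduces
them exactly — the comparison tests record this at their stated tolerance
rather than adjusting the criterion post hoc.

## Watson averaging

The spherical average uses a product quadrature: Gauss–Legendre in the polar
cosine (48 nodes per panel) times a 96-point uniform azimuth rule on one
hemisphere with doubled weights (all integrands are antipodally symmetric).
For concentrated distributions the polar mass sits in a boundary layer of
width ~1/(2 kappa) at the mean axis, which a fixed rule cannot resolve; the
panel layout therefore refines geometrically toward the pole as a function of
kappa, and the quadrature frame is rotated so its pole coincides with `mu`.
This integrates the Watson density to 1 within 1e-8 up to kappa = 1e6 and
recovers the parallel-fiber signal to 0.1% at kappa = 1e4.  A doubling check
(`verify=True`) raises if the order is insufficient.  The normalizer
`M(1/2, 3/2, kappa)` uses the Dawson-function identity
`exp(kappa) dawsn(sqrt(kappa))/sqrt(kappa)` (log-space for large kappa), with
a Taylor series below 1e-6, and is cross-checked in tests against brute-force
quadrature and an independent hypergeometric implementation.

## Synthetic validation

`mc_cylinder_signal` runs a seeded random walk of typically 2.5e4–2e5
walkers in a disc (per-dimension step `sqrt(2 D dt)`, dt default 5 us,
specular radial reflection at the wall, phase accumulated against the exact
effective waveform) and estimates the perpendicular echo signal with a
standard error.  It emulates only what the GPD engine claims to compute —
a single impermeable cylinder cross-section — not packed substrates,
permeable membranes, extracellular restriction, or multiple diameters, so
agreement validates the deterministic engine, not the realism of the tissue
model.  `empirical_distinguishability` draws paired noisy signal
realizations (additive Gaussian by default; Rician magnitude behind a flag)
and shows the deterministic criterion `contrast > sigma` sits at the 50%
crossing of the empirical detection curve.

## Problem sizes in the acceptance script

`scripts/acceptance.py` recomputes every reported quantity from scratch:
the full 301 x 61 (G, delta) grid at 1 mT/m x 1 ms for the T2-weighted
optimum, the 301-point G sweep for the restricted optimum, 0.1 um diameter
scans for all a0 and resolution bounds, and the plateau maximization over a
10 mT/m x 1 ms x N=1..10 grid with 0.1 ms separation scans (the plateau
argmax sits at the G boundary, so the coarser G step does not move the
maximum).  Everything is deterministic; the run completes in about a minute
on one CPU.

## Known limitations

* Single cylinder diameter per substrate; no gamma-mixture of diameters,
  permeability, exchange, or time-dependent extracellular diffusivity.
* T2 is assumed independent of diameter and identical across compartments.
* Only trapezoidal (return-to-zero lobe) OGSE waveforms; no sine/cosine or
  apodized variants, and no eddy-current or heating modelling.
* The plateau-time criterion is ambiguous at the 1-ms scale for large
  diameters (see above).
* Estimation of diameter from measured data is out of scope: the package
  quantifies forward sensitivity only.
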