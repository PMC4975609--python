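"""Config-driven experiment pipeline.

Each named experiment is a deterministic computation that writes tidy CSV
tables plus a JSON manifest (parameters, version, checksums).  The
experiments reproduce, as machine-readable tables, the standard outputs of
the sequence-optimization study this package implements:

===========================  ====================================================
name                         output
===========================  ====================================================
``signal_decay``             restricted signal and its diameter derivative
                             vs (G, Delta) for a PGSE at delta = 5 ms
``delta_plateau``            plateau separation Delta_0 vs diameter, maximized
                             over the sequence space
``sensitivity_map_restricted``  |S_r'(a)| over (G, delta, N), no T2, with argmax
``sensitivity_map_t2``       |S*'(a)| over (G, delta, N), T2-weighted
``sensitivity_map_angle``    as above for gradients theta degrees off
                             perpendicular
``sensitivity_map_dispersion``  as above under Watson dispersion
``optimal_delta_table``      optimal delta per (scenario, G, N), averaged over
                             a in {1, 2, 3} um
``resolution_curves``        S*(a) and epsilon-contrast curves vs diameter for
                             N = 1..5 with threshold crossings
``a0_table``                 smallest-resolvable diameter a0 per
                             (scenario, G, SNR, N)
``robustness_curves``        scenario-optimal sequences evaluated across
                             mismatched orientation conditions
===========================  ====================================================
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import reference
from .dispersion import WatsonModel
from .sequence import ParameterGrid, SequenceParams, build_effective_waveform, bvalue_closed_form
from .signal import DEFAULT_BASIS_SIZE, TissueModel, bessel_prime_roots
from .sensitivity import (
    DEFAULT_H,
    NoiseModel,
    Scenario,
    a0_limit,
    delta0_plateau,
    optimize_sensitivity,
    resolvable_range,
    sensitivity_map,
    signals_vs_diameter,
)

__version__ = "0.1.0"

SCENARIOS: dict[str, Scenario] = {
    "perpendicular": Scenario(theta_deg=0.0, include_T2=True),
    "theta10": Scenario(theta_deg=10.0, include_T2=True),
    "kappa16": Scenario(kappa=16.0, include_T2=True),
}

EXPERIMENT_NAMES = (
    "signal_decay",
    "delta_plateau",
    "sensitivity_map_restricted",
    "sensitivity_map_t2",
    "sensitivity_map_angle",
    "sensitivity_map_dispersion",
    "optimal_delta_table",
    "resolution_curves",
    "a0_table",
    "robustness_curves",
)


@dataclass(frozen=True)
class ExperimentSpec:
    """A named experiment plus option overrides and an output directory."""

    name: str
    out_dir: str = "results"
    options: dict = field(default_factory=dict)
    tissue: TissueModel = TissueModel()

    def __post_init__(self) -> None:
        if self.name not in EXPERIMENT_NAMES:
            raise ValueError(
                f"unknown experiment {self.name!r}; choose from {EXPERIMENT_NAMES}"
            )


def load_config(path: str | Path) -> list[ExperimentSpec]:
    """Parse a YAML config: a list of {experiment, out_dir, options, tissue}."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    specs = []
    for entry in doc.get("experiments", []):
        tis = entry.get("tissue", {})
        tissue = TissueModel(
            f=tis.get("f", 0.7),
            D_par=tis.get("D_par_m2_per_s", 1.7e-9),
            a=tis.get("diameter_um", 4.0) * 1e-6,
            T2=tis.get("T2_ms", 70.0) * 1e-3,
        )
        specs.append(
            ExperimentSpec(
                name=entry["experiment"],
                out_dir=entry.get("out_dir", "results"),
                options=entry.get("options", {}),
                tissue=tissue,
            )
        )
    return specs


def _basis():
    return bessel_prime_roots(DEFAULT_BASIS_SIZE)


def _map_grid(options: dict, N_values) -> ParameterGrid:
    return ParameterGrid.regular(
        G_step=options.get("G_step_mT", 5) * 1e-3,
        delta_step=options.get("delta_step_ms", 1) * 1e-3,
        N_values=N_values,
    )


def _refine_G(
    coarse, a, tissue, scenario, basis, restricted_only, G_step_mT
) -> tuple[SequenceParams, float]:
    """Re-sweep G at 1 mT/m around a coarse optimum (delta, N fixed)."""
    p0 = coarse.params
    lo = max(0, int(round(p0.G * 1e3)) - G_step_mT)
    hi = min(300, int(round(p0.G * 1e3)) + G_step_mT)
    grid = ParameterGrid(
        G_values=tuple(g * 1e-3 for g in range(lo, hi + 1)),
        delta_values=(p0.delta,),
        N_values=(p0.N,),
    )
    best = optimize_sensitivity(
        grid, a, tissue, scenario, basis, restricted_only=restricted_only
    )
    return best.params, best.value_per_um


def _sensitivity_map_experiment(
    spec: ExperimentSpec, scenarios: dict[str, Scenario], diameters_um, restricted_only
) -> dict[str, pd.DataFrame]:
    basis = _basis()
    G_step = spec.options.get("G_step_mT", 5)
    grid = _map_grid(spec.options, tuple(spec.options.get("N_values", range(1, 11))))
    maps = []
    stars = []
    for label, scen in scenarios.items():
        for a_um in diameters_um:
            m = sensitivity_map(
                grid, a_um * 1e-6, spec.tissue, scen, basis,
                restricted_only=restricted_only,
            )
            t = m.table.copy()
            t.insert(0, "a_um", a_um)
            t.insert(0, "scenario", label)
            maps.append(t)
            p, v = _refine_G(
                m.optimum, a_um * 1e-6, spec.tissue, scen, basis, restricted_only, G_step
            )
            stars.append(
                (label, a_um, round(p.G * 1e3), p.delta * 1e3, p.N, v)
            )
    return {
        "map": pd.concat(maps, ignore_index=True),
        "optima": pd.DataFrame(
            stars,
            columns=["scenario", "a_um", "G_mT", "delta_ms", "N", "sensitivity_per_um"],
        ),
    }


def _run_signal_decay(spec: ExperimentSpec) -> dict[str, pd.DataFrame]:
    basis = _basis()
    from .signal import gpd_perp_log_attenuation_vs_separation

    rows = []
    delta = spec.options.get("delta_ms", 5) * 1e-3
    h = DEFAULT_H
    for a_um in spec.options.get("diameters_um", (2, 10)):
        for G_mT in spec.options.get("G_mT", range(20, 301, 20)):
            p = SequenceParams(G=G_mT * 1e-3, delta=delta, Delta=0.100, N=1)
            off = np.arange(0, int(round((0.100 - delta) / 1e-3)) + 1) * 1e-3
            a = a_um * 1e-6
            s = np.exp(gpd_perp_log_attenuation_vs_separation(
                p, a / 2, spec.tissue.D_par, basis, delta + off))
            s_lo = np.exp(gpd_perp_log_attenuation_vs_separation(
                p, (a - h) / 2, spec.tissue.D_par, basis, delta + off))
            s_hi = np.exp(gpd_perp_log_attenuation_vs_separation(
                p, (a + h) / 2, spec.tissue.D_par, basis, delta + off))
            der = np.abs(s_hi - s_lo) / (2 * h) * 1e-6
            for o, sv, dv in zip(off, s, der):
                rows.append((a_um, G_mT, (delta + o) * 1e3, sv, dv))
    return {
        "curves": pd.DataFrame(
            rows, columns=["a_um", "G_mT", "Delta_ms", "S_restricted", "dS_da_per_um"]
        )
    }


def _run_delta_plateau(spec: ExperimentSpec) -> dict[str, pd.DataFrame]:
    basis = _basis()
    from dataclasses import replace

    rows = []
    for a_um in spec.options.get("diameters_um", range(1, 11)):
        tis = replace(spec.tissue, a=a_um * 1e-6)
        best = (0.0, None)
        for N in spec.options.get("N_values", range(1, 11)):
            for d_ms in range(1, 61, spec.options.get("delta_step_ms", 1)):
                for G_mT in range(
                    spec.options.get("G_step_mT", 10), 301, spec.options.get("G_step_mT", 10)
                ):
                    G, d = G_mT * 1e-3, d_ms * 1e-3
                    if d / N < 2 * G / 200.0:
                        continue
                    d0, met = delta0_plateau(G, d, N, tis, basis)
                    if d0 > best[0]:
                        best = (d0, (G_mT, d_ms, N, met))
        G_mT, d_ms, N, met = best[1] if best[1] else (None, None, None, True)
        rows.append((a_um, best[0] * 1e3, G_mT, d_ms, N, met))
    return {
        "delta0": pd.DataFrame(
            rows, columns=["a_um", "Delta0_ms", "argmax_G_mT", "argmax_delta_ms", "argmax_N", "criterion_met"]
        )
    }


def _run_optimal_delta_table(spec: ExperimentSpec) -> dict[str, pd.DataFrame]:
    basis = _basis()
    rows = []
    for label, scen in SCENARIOS.items():
        for G_mT in spec.options.get("G_mT", (60, 80, 150, 300)):
            for N in spec.options.get("N_values", (1, 2, 3, 4, 5)):
                deltas = []
                for a_um in (1, 2, 3):
                    grid = ParameterGrid(
                        G_values=(G_mT * 1e-3,),
                        delta_values=tuple(d * 1e-3 for d in range(1, 61)),
                        N_values=(N,),
                    )
                    best = optimize_sensitivity(grid, a_um * 1e-6, spec.tissue, scen, basis)
                    deltas.append(best.params.delta * 1e3)
                rows.append((label, G_mT, N, round(float(np.mean(deltas)))))
    return {
        "optimal_delta": pd.DataFrame(
            rows, columns=["scenario", "G_mT", "N", "delta_ms"]
        )
    }


def _resolution_sequence(scen_key: str, G_mT: int, N: int) -> SequenceParams:
    d = reference.optimal_delta_s(scen_key, G_mT, N)
    return SequenceParams(G=G_mT * 1e-3, delta=d, Delta=d + 0.010, N=N)


def _run_resolution_curves(spec: ExperimentSpec) -> dict[str, pd.DataFrame]:
    basis = _basis()
    diam = np.arange(0, 101) * 0.1e-6
    rows = []
    ranges = []
    for label, scen in SCENARIOS.items():
        for G_mT in spec.options.get("G_mT", (60, 300)):
            for N in spec.options.get("N_values", (1, 2, 3, 4, 5)):
                p = _resolution_sequence(label, G_mT, N)
                s = signals_vs_diameter(p, spec.tissue, scen, basis, diam)
                b = bvalue_closed_form(p) * 1e-6  # s/mm^2
                for a, sv in zip(diam, s):
                    rows.append((label, G_mT, N, a * 1e6, sv, b))
                for eps_um in (0.5, 1.0):
                    for SNR in (10, 20, 50):
                        nm = NoiseModel(SNR=SNR, T2=spec.tissue.T2)
                        iv = resolvable_range(
                            eps_um * 1e-6, nm, p, spec.tissue, scen, basis
                        )
                        lo = min((x[0] for x in iv), default=np.nan)
                        hi = max((x[1] for x in iv), default=np.nan)
                        ranges.append(
                            (label, G_mT, N, eps_um, SNR, lo * 1e6, hi * 1e6)
                        )
    return {
        "signal": pd.DataFrame(
            rows, columns=["scenario", "G_mT", "N", "a_um", "S", "b_s_per_mm2"]
        ),
        "ranges": pd.DataFrame(
            ranges,
            columns=["scenario", "G_mT", "N", "epsilon_um", "SNR", "low_um", "high_um"],
        ),
    }


def _run_a0_table(spec: ExperimentSpec) -> dict[str, pd.DataFrame]:
    basis = _basis()
    rows = []
    for label, scen in SCENARIOS.items():
        for G_mT in spec.options.get("G_mT", (60, 80, 150, 300)):
            for N in spec.options.get("N_values", (1, 2, 3, 4, 5)):
                p = _resolution_sequence(label, G_mT, N)
                for SNR in spec.options.get("SNR", (10, 20, 50)):
                    nm = NoiseModel(SNR=SNR, T2=spec.tissue.T2)
                    a0 = a0_limit(nm, p, spec.tissue, scen, basis)
                    rows.append(
                        (label, G_mT, SNR, N, np.nan if a0 is None else a0 * 1e6)
                    )
    return {"a0": pd.DataFrame(rows, columns=["scenario", "G_mT", "SNR", "N", "a0_um"])}


def _run_robustness_curves(spec: ExperimentSpec) -> dict[str, pd.DataFrame]:
    basis = _basis()
    diam = np.arange(0, 101) * 0.1e-6
    G_mT = spec.options.get("G_mT", 300)
    optimal_N = {"perpendicular": 1, "theta10": 4, "kappa16": 4}
    conditions: list[tuple[str, Scenario]] = [
        (f"theta{t}", Scenario(theta_deg=t)) for t in (0, 2, 6, 10)
    ] + [(f"kappa{k}", Scenario(kappa=float(k))) for k in (8, 16)]
    rows = []
    for opt_label, N in optimal_N.items():
        p = _resolution_sequence(opt_label, G_mT, N)
        for cond_label, cond in conditions:
            s = signals_vs_diameter(p, spec.tissue, cond, basis, diam)
            for a, sv in zip(diam, s):
                rows.append((opt_label, N, cond_label, a * 1e6, sv))
    return {
        "curves": pd.DataFrame(
            rows, columns=["optimized_for", "N", "condition", "a_um", "S"]
        )
    }


_RUNNERS = {
    "signal_decay": _run_signal_decay,
    "delta_plateau": _run_delta_plateau,
    "optimal_delta_table": _run_optimal_delta_table,
    "resolution_curves": _run_resolution_curves,
    "a0_table": _run_a0_table,
    "robustness_curves": _run_robustness_curves,
}


def run_experiment(spec: ExperimentSpec) -> dict[str, pd.DataFrame]:
    """Run one experiment, write its CSVs and manifest, return the tables."""
    if spec.name == "sensitivity_map_restricted":
        tables = _sensitivity_map_experiment(
            spec, {"perpendicular": Scenario(include_T2=False)},
            spec.options.get("diameters_um", (2, 4, 6, 8)), restricted_only=True,
        )
    elif spec.name == "sensitivity_map_t2":
        tables = _sensitivity_map_experiment(
            spec, {"perpendicular": SCENARIOS["perpendicular"]},
            spec.options.get("diameters_um", (2, 4, 6, 8)), restricted_only=False,
        )
    elif spec.name == "sensitivity_map_angle":
        scen = {
            f"theta{t}": Scenario(theta_deg=float(t))
            for t in spec.options.get("theta_deg", (1, 6, 10))
        }
        tables = _sensitivity_map_experiment(
            spec, scen, spec.options.get("diameters_um", (2, 4, 6)), restricted_only=False
        )
    elif spec.name == "sensitivity_map_dispersion":
        scen = {
            f"kappa{k}": Scenario(kappa=float(k))
            for k in spec.options.get("kappa", (8, 16))
        }
        tables = _sensitivity_map_experiment(
            spec, scen, spec.options.get("diameters_um", (2, 4, 6)), restricted_only=False
        )
    else:
        tables = _RUNNERS[spec.name](spec)

    out = Path(spec.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    checksums = {}
    for key, df in tables.items():
        path = out / f"{spec.name}_{key}.csv"
        df.to_csv(path, index=False, float_format="%.10g")
        checksums[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest = {
        "experiment": spec.name,
        "version": __version__,
        "options": spec.options,
        "tissue": {
            "f": spec.tissue.f,
            "D_par_m2_per_s": spec.tissue.D_par,
            "T2_ms": spec.tissue.T2 * 1e3,
        },
        "defaults": {
            "basis_modes": DEFAULT_BASIS_SIZE,
            "fd_step_um": DEFAULT_H * 1e6,
            "diameter_grid_um": 0.1,
            "Delta_scan_step_ms": 0.1,
        },
        "checksums": checksums,
    }
    with open(out / f"{spec.name}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return tables


def compare_to_reference(
    result: pd.DataFrame,
    ref: pd.DataFrame,
    value_col: str,
    tolerance: float,
    keys: list[str] | None = None,
) -> pd.DataFrame:
    """Cell-by-cell comparison of a recomputed table against a benchmark.

    Joins on ``keys`` (all shared non-value columns by default) and flags
    cells whose absolute difference exceeds ``tolerance`` (0 means exact).
    Raises ``ValueError`` on shape mismatch (unmatched benchmark rows).
    """
    if keys is None:
        keys = [c for c in ref.columns if c != value_col]
    merged = ref.merge(result, on=keys, suffixes=("_ref", ""), how="left")
    if merged[value_col].isna().any():
        raise ValueError("result table does not cover all benchmark cells")
    diff = (merged[value_col] - merged[f"{value_col}_ref"]).abs()
    merged["abs_diff"] = diff
    merged["ok"] = diff <= tolerance if tolerance > 0 else diff == 0
    return merged
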