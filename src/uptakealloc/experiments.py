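"""Reproduction driver: concentration sweeps, PTS-vs-ABC comparisons, sensitivity.

Each optimal-cell solve answers "what is the best physiology at one
external nutrient concentration?"; the functions here chain such solves
into the standard computational experiments: growth-rate and geometry
profiles across an environmental concentration gradient, effective
half-saturation and capacity-ratio profiles, multiplicative parameter
sensitivity scans, and head-to-head PTS/ABC comparison records.  All
results are plain pandas tables with units in the column documentation,
exportable to CSV with a JSON provenance sidecar.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .allocation_solver import OptimalSolution, SolverConfig, SolverFailure, solve_allocation
from .cell_model import CellParameters

__all__ = [
    "SweepSpec",
    "SensitivitySpec",
    "concentration_sweep",
    "capacity_ratio_profile",
    "sensitivity_sweep",
    "crossover_concentration",
    "compare_summary",
    "export_results",
    "default_grid",
]

#: sweep-table columns, in order (units: mM, s, um; see docs/methods.md)
SWEEP_COLUMNS = [
    "S_ext", "transport_type", "converged", "mu", "r", "f_p", "sa_v",
    "phi_BP", "phi_T", "phi_E", "phi_M", "phi_R",
    "S_p", "S_c", "A", "W", "P",
    "V_max", "K_eff", "K_M_mm", "specific_affinity", "bp_t_ratio",
    "capacity_ratio", "transport_proteome_fraction",
    "cyto_density_margin", "peri_density_margin", "real_estate_margin",
    "error",
]


def default_grid(n: int = 40, lo: float = 1e-6, hi: float = 1e2) -> np.ndarray:
    """Log-spaced external-concentration grid (mM), 1 nM to 100 mM."""
    return np.logspace(math.log10(lo), math.log10(hi), n)


@dataclass(frozen=True)
class SweepSpec:
    """A concentration sweep: grid, transport types, solver settings, overrides."""

    grid: np.ndarray = field(default_factory=default_grid)
    transport_types: tuple[str, ...] = ("pts", "abc")
    n_starts: int = 12
    seed: int = 1
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        if g.ndim != 1 or np.any(g <= 0) or np.any(np.diff(g) <= 0):
            raise ValueError("grid must be strictly increasing and positive")
        object.__setattr__(self, "grid", g)

    def parameters(self, base: CellParameters | None = None) -> CellParameters:
        p = base if base is not None else CellParameters()
        return p.with_(**self.overrides) if self.overrides else p


@dataclass(frozen=True)
class SensitivitySpec:
    """Multiplicative scan of one parameter around a baseline sweep."""

    parameter: str
    factors: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)
    base: SweepSpec = field(default_factory=SweepSpec)

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.factors):
            raise ValueError("factors must be positive")


def _solution_row(s_ext: float, tt: str, sol: OptimalSolution | None,
                  error: str = "") -> dict:
    row = {c: math.nan for c in SWEEP_COLUMNS}
    row.update(S_ext=s_ext, transport_type=tt, converged=sol is not None, error=error)
    if sol is not None:
        row.update(sol.to_record())
        row["converged"] = True
    return row


def concentration_sweep(spec: SweepSpec, base: CellParameters | None = None) -> pd.DataFrame:
    """Solve the allocation problem at every grid concentration, both transport types.

    The grid is traversed from high to low concentration and each point is
    warm-started from its neighbor's optimum in addition to the random
    multi-starts, which keeps the solution on the global branch through
    the crossover region.  Failed points are recorded (``converged``
    False, error message kept), never silently dropped.
    """
    p0 = spec.parameters(base)
    rows = []
    for tt in spec.transport_types:
        prev = None
        for s_ext in spec.grid[::-1]:
            p = p0.with_(S_ext=s_ext)
            cfg = SolverConfig.for_parameters(p, n_starts=spec.n_starts, seed=spec.seed)
            try:
                sol = solve_allocation(p, tt, cfg,
                                       extra_starts=[prev.x_star] if prev else None)
            except SolverFailure as exc:
                rows.append(_solution_row(s_ext, tt, None, str(exc)))
                continue
            prev = sol
            rows.append(_solution_row(s_ext, tt, sol))
    df = pd.DataFrame(rows, columns=SWEEP_COLUMNS)
    return df.sort_values(["transport_type", "S_ext"]).reset_index(drop=True)


def capacity_ratio_profile(sweep_table: pd.DataFrame, p: CellParameters | None = None) -> pd.DataFrame:
    """Append the transport-to-metabolic capacity ratio, recomputed from columns.

    Capacity ratio = V_max / (5*kE*phi_E*alpha_E*P): maximal uptake over
    maximal substrate-processing rate, both on the cytoplasmic volume
    basis.  A zero metabolic pool yields an infinite ratio with
    ``capacity_flag`` set.
    """
    if p is None:
        p = CellParameters()
    out = sweep_table.copy()
    met = 5.0 * p.kE * out["phi_E"] * p.alpha["E"] * out["P"]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = out["V_max"] / met
    ratio = ratio.where(met > 0, np.inf)
    out["capacity_ratio_check"] = ratio
    out["capacity_flag"] = ~np.isfinite(ratio)
    return out


def crossover_concentration(sweep_table: pd.DataFrame) -> float | None:
    """External concentration where the ABC and PTS growth-rate curves cross.

    Returns the geometric midpoint of the bracketing grid interval where
    mu_ABC - mu_PTS changes sign (ABC ahead on the low side), or None if
    the curves do not cross inside the grid.
    """
    pts = sweep_table[sweep_table.transport_type == "pts"].set_index("S_ext")["mu"]
    abc = sweep_table[sweep_table.transport_type == "abc"].set_index("S_ext")["mu"]
    common = pts.index.intersection(abc.index).sort_values()
    diff = (abc - pts).loc[common].to_numpy()
    grid = common.to_numpy()
    ok = np.isfinite(diff)
    diff, grid = diff[ok], grid[ok]
    for i in range(len(diff) - 1):
        if diff[i] > 0 >= diff[i + 1]:
            return float(math.sqrt(grid[i] * grid[i + 1]))
    return None


def sensitivity_sweep(spec: SensitivitySpec, base: CellParameters | None = None
                      ) -> tuple[dict[float, pd.DataFrame], pd.DataFrame]:
    """Run the baseline sweep under multiplicative scalings of one parameter.

    Returns one sweep table per factor and a summary with, per factor,
    whether the ABC-over-PTS growth advantage at the low end and the
    PTS-over-ABC advantage at the high end both persist (i.e. the
    rate–affinity crossover survives the perturbation) and where the
    crossover sits.
    """
    p0 = spec.base.parameters(base)
    baseline_value = _lookup_parameter(p0, spec.parameter)
    tables: dict[float, pd.DataFrame] = {}
    summary = []
    for f in spec.factors:
        p = p0.with_(**{spec.parameter: baseline_value * f})
        tab = concentration_sweep(spec.base, base=p)
        tables[f] = tab
        xc = crossover_concentration(tab)
        summary.append({
            "parameter": spec.parameter,
            "factor": f,
            "value": baseline_value * f,
            "crossover_mM": xc if xc is not None else math.nan,
            "crossover_present": xc is not None,
        })
    return tables, pd.DataFrame(summary)


def _lookup_parameter(p: CellParameters, name: str) -> float:
    if name in ("k1", "k2", "k0f", "k0r", "k1p", "k2p", "k3p"):
        return getattr(p.transport, name)
    if name in {f.name for f in fields(p)}:
        return getattr(p, name)
    raise ValueError(f"unknown parameter {name!r}")


def compare_summary(pts_sol: OptimalSolution, abc_sol: OptimalSolution,
                    s_ext: float) -> dict:
    """Head-to-head PTS/ABC comparison at one matched external concentration.

    Ratios are ABC-relative-to-PTS except the affinity ratio, which is
    reported as K_M(PTS)/K_eff(ABC) (how many-fold lower the ABC cell's
    half-saturation is).
    """
    if pts_sol.transport_type != "pts" or abc_sol.transport_type != "abc":
        raise ValueError("expected (pts_sol, abc_sol) in that order")
    return {
        "S_ext": s_ext,
        "mu_pts": pts_sol.mu,
        "mu_abc": abc_sol.mu,
        "mu_ratio_abc_to_pts": abc_sol.mu / pts_sol.mu,
        "transport_proteome_ratio_abc_to_pts":
            abc_sol.transport_proteome_fraction / pts_sol.transport_proteome_fraction,
        "vmax_ratio_pts_to_abc": pts_sol.V_max / abc_sol.V_max,
        "km_pts_over_keff_abc": pts_sol.K_eff / abc_sol.K_eff,
        "sa_v_ratio_abc_to_pts": abc_sol.sa_v / pts_sol.sa_v,
    }


# ---------------------------------------------------------------------------
# export


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def export_results(tables: dict[str, pd.DataFrame], out_dir: str | Path,
                   config: dict | None = None) -> list[Path]:
    """Write one CSV per table plus a JSON provenance sidecar.

    Each CSV starts with comment lines stating units and the config hash;
    the sidecar records the full configuration (parameters, seeds, grid)
    so a run can be reproduced bit-for-bit from it.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = _jsonable(config or {})
    h = _config_hash(config)
    written = []
    for name, tab in tables.items():
        path = out / f"{name}.csv"
        header = (
            "# uptakealloc results; units: concentration mM, time s, length um, "
            "rate mM/s, density g/L\n"
            f"# config_hash: {h}\n"
        )
        path.write_text(header + tab.to_csv(index=False))
        written.append(path)
    sidecar = out / "run_config.json"
    sidecar.write_text(json.dumps({"config_hash": h, "config": config},
                                  indent=2, sort_keys=True) + "\n")
    written.append(sidecar)
    return written


def sweep_config_record(spec: SweepSpec, p: CellParameters) -> dict:
    """Provenance payload for :func:`export_results` sidecars."""
    from dataclasses import asdict as dc_asdict

    return {
        "grid": spec.grid.tolist(),
        "transport_types": list(spec.transport_types),
        "n_starts": spec.n_starts,
        "seed": spec.seed,
        "overrides": _jsonable(spec.overrides),
        "parameters": {**dc_asdict(p.transport), **{
            f.name: getattr(p, f.name) for f in fields(p) if f.name != "transport"
        }},
    }
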