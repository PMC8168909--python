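"""Multi-start constrained maximization of steady-state growth rate.

The proteome-allocation problem is a smooth nonlinear program: maximize
the growth rate ``mu`` over the decision vector x = (x_m, phi, r, f_p,
mu) subject to the five steady-state metabolite balances, proteome
closure and membrane coverage (equalities) and the two density caps and
the inner-membrane real-estate limit (inequalities), with x >= 0,
r >= r_min and f_p in (0, 1).  ``mu`` is an ordinary optimization
variable coupled to the state through the balance equations, and the
objective is the variable itself.

The problem is non-convex, so a local SQP solver (scipy's SLSQP) is run
from many starting points.  Variables are rescaled so every component is
O(1) at a typical optimum, and constraints are normalized by natural
magnitudes (supply concentration, required membrane area, density caps).
Each random start is first *projected onto the balanced-growth manifold*:
at the drawn (phi, r, f_p) the square steady-state system is solved for
(S_p, S_c, A, P, mu) with the membrane-unit pool fixed by the coverage
equality — starting SQP from a feasible point makes convergence far more
reliable than starting from a raw random draw.  The best feasible
converged point wins; feasibility is always re-verified in unscaled
space before a solution is accepted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize, root

from . import cell_model as cm
from .kinetics import (
    MMFit,
    abc_mm_approx,
    abc_steady_state,
    effective_half_saturation,
    pts_uptake,
    specific_affinity,
)
from .cell_model import (
    CellParameters,
    DecisionVariables,
    density_margins,
    diffusive_uptake,
    growth_balance_residuals,
    membrane_coverage_residual,
    real_estate_margin,
    transport_pools,
)

__all__ = [
    "SolverConfig",
    "StartRecord",
    "OptimalSolution",
    "scale",
    "unscale",
    "random_start",
    "solve_allocation",
    "validate_solution",
    "SolverFailure",
]

_NV = 13  # [S_p, S_c, A, W, P, phi_BP, phi_T, phi_E, phi_M, phi_R, r, f_p, mu]


class SolverFailure(RuntimeError):
    """No feasible converged start; carries the full per-start log."""

    def __init__(self, message: str, log: list["StartRecord"]):
        super().__init__(message)
        self.log = log


@dataclass(frozen=True)
class SolverConfig:
    """Settings of the multi-start NLP solve.

    ``scales`` holds per-variable magnitudes so that scaled variables are
    approximately 1 near an optimum; :func:`SolverConfig.for_parameters`
    adapts the substrate scale to the environment.  Tolerances apply to
    the *scaled* problem.
    """

    n_starts: int = 50
    seed: int = 1
    constraint_tol: float = 1e-8
    optimality_tol: float = 1e-9
    maxiter: int = 500
    r_max: float = 10.0
    fp_margin: float = 1e-6
    state_max: float = 2.0e4
    mu_max: float = 0.1
    scales: np.ndarray = field(
        default_factory=lambda: np.array(
            [1e-3, 1.0, 1.0, 1e2, 1e3, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.3, 1e-4]
        )
    )

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if min(self.constraint_tol, self.optimality_tol) <= 0:
            raise ValueError("tolerances must be positive")
        object.__setattr__(self, "scales", np.asarray(self.scales, dtype=float))
        if self.scales.shape != (_NV,) or np.any(self.scales <= 0):
            raise ValueError("scales must be a positive vector of length 13")

    @staticmethod
    def for_parameters(p: CellParameters, **kw) -> "SolverConfig":
        """Config with the periplasmic-substrate scale tied to S_ext."""
        cfg = SolverConfig(**kw)
        s = cfg.scales.copy()
        s[0] = max(p.S_ext, 1e-9)
        return replace(cfg, scales=s)


@dataclass(frozen=True)
class StartRecord:
    """Convergence log entry for one start."""

    start_index: int
    converged: bool
    mu: float
    residual_norm: float
    message: str


@dataclass(frozen=True)
class OptimalSolution:
    """Best feasible point of the allocation problem plus derived observables.

    Observables: cytoplasmic-basis maximal uptake rate ``V_max`` (mM/s),
    exact effective half-saturation ``K_eff`` and its closed-form
    approximation ``K_M_mm`` (mM), specific affinity ``V_max/K_eff``
    (/s), binding-protein:transport-unit ratio, surface-area-to-volume
    ratio 3/r (/um), transport-to-metabolic capacity ratio, and the
    transport proteome fraction phi_BP + phi_T.
    """

    transport_type: str
    x_star: DecisionVariables
    mu: float
    equality_residuals: np.ndarray
    inequality_margins: np.ndarray
    active_inequalities: tuple[bool, bool, bool]
    start_log: tuple[StartRecord, ...]
    V_max: float
    K_eff: float
    K_M_mm: float
    specific_affinity: float
    bp_t_ratio: float
    sa_v: float
    capacity_ratio: float
    transport_proteome_fraction: float
    keff_fit: MMFit | None

    def to_record(self) -> dict[str, float | str]:
        """Flat record of the solution (one value per key) for tabular export."""
        x = self.x_star
        rec: dict[str, float | str] = {"transport_type": self.transport_type, "mu": self.mu}
        for name in ("S_p", "S_c", "A", "W", "P", *cm.PHI_NAMES, "r", "f_p"):
            rec[name] = getattr(x, name)
        rec.update(
            V_max=self.V_max, K_eff=self.K_eff, K_M_mm=self.K_M_mm,
            specific_affinity=self.specific_affinity, bp_t_ratio=self.bp_t_ratio,
            sa_v=self.sa_v, capacity_ratio=self.capacity_ratio,
            transport_proteome_fraction=self.transport_proteome_fraction,
            cyto_density_margin=float(self.inequality_margins[0]),
            peri_density_margin=float(self.inequality_margins[1]),
            real_estate_margin=float(self.inequality_margins[2]),
        )
        return rec


def scale(x: DecisionVariables, config: SolverConfig) -> np.ndarray:
    """Map a decision vector to the O(1) scaled space."""
    return x.to_array() / config.scales


def unscale(z: np.ndarray, config: SolverConfig) -> DecisionVariables:
    """Inverse of :func:`scale` (exact round trip up to float rounding)."""
    return DecisionVariables.from_array(np.asarray(z, dtype=float) * config.scales)


# ---------------------------------------------------------------------------
# constraint functions on the scaled vector


def _eq_constraints(z: np.ndarray, p: CellParameters, tt: str, config: SolverConfig) -> np.ndarray:
    x = unscale(z, config)
    bal = growth_balance_residuals(x, p, tt)
    # S_p balance in units of concentration (multiply by f_p r^2 / 3D) and
    # normalize by the supply concentration: O(1) even when v_diff is huge
    c_sp = bal[0] * x.f_p * x.r**2 / (3.0 * p.D) / max(p.S_ext, 1e-9)
    req_area = 4.0 * math.pi * (1.0 + (1.0 - x.f_p) ** (2.0 / 3.0)) * x.r**2
    return np.array([
        c_sp,
        bal[1],
        bal[2],
        bal[3] / 0.1,
        bal[4],
        cm.proteome_closure_residual(x, p),
        membrane_coverage_residual(x, p) / req_area,
    ])


def _ineq_constraints(z: np.ndarray, p: CellParameters, config: SolverConfig) -> np.ndarray:
    x = unscale(z, config)
    d_cyto, d_peri = density_margins(x, p)
    avail = p.f_SA * 4.0 * math.pi * (1.0 - x.f_p) ** (2.0 / 3.0) * x.r**2
    return np.array([
        d_cyto / p.rho_cyto,
        d_peri / p.rho_peri,
        real_estate_margin(x, p) / avail,
    ])


def _bounds(p: CellParameters, tt: str, config: SolverConfig) -> list[tuple[float, float]]:
    lb = np.zeros(_NV)
    ub = np.array([
        p.S_ext, config.state_max, config.state_max, config.state_max, config.state_max,
        *([p.phi_budget] * 5), config.r_max, 1.0 - config.fp_margin, config.mu_max,
    ])
    lb[10] = p.r_min
    lb[11] = config.fp_margin
    if tt == "pts":
        ub[5] = 0.0
    return list(zip(lb / config.scales, ub / config.scales))


# ---------------------------------------------------------------------------
# starting points


def random_start(seed: int, start_index: int, config: SolverConfig,
                 p: CellParameters, transport_type: str = "abc") -> DecisionVariables:
    """Deterministic log-uniform draw of a starting point within bounds.

    The same ``(seed, start_index)`` always yields the same draw.  The
    proteome split is drawn as log-uniform weights normalized onto the
    available budget; ``r`` and ``f_p`` are drawn within their bounds.
    """
    rng = np.random.default_rng([int(seed), int(start_index)])
    s_ext = max(p.S_ext, 1e-12)
    S_p = s_ext * rng.uniform(0.05, 0.99)
    S_c = 10.0 ** rng.uniform(-3, 1)
    A = 10.0 ** rng.uniform(-3, 1)
    P = 10.0 ** rng.uniform(2.3, 3.6)
    w = 10.0 ** rng.uniform(-2, 0, size=5)
    if transport_type == "pts":
        w[0] = 0.0
    phi = w / w.sum() * p.phi_budget
    r = 10.0 ** rng.uniform(math.log10(p.r_min), math.log10(min(config.r_max, 2.0)))
    f_p = rng.uniform(0.03, 0.9)
    W = _w_from_geometry(r, f_p, p)
    mu = 10.0 ** rng.uniform(-7, -3)
    return DecisionVariables(S_p, S_c, A, W, P, *phi, r, f_p, mu)


def _w_from_geometry(r: float, f_p: float, p: CellParameters) -> float:
    """Membrane-unit pool (mM) satisfying the coverage equality at (r, f_p)."""
    req = 4.0 * math.pi * (1.0 + (1.0 - f_p) ** (2.0 / 3.0)) * r**2
    vol = 4.0 * math.pi * r**3 / 3.0
    if p.strict_volume_basis:
        vol *= 1.0 - f_p
    return req / (cm.MOLECULES_PER_UM3_PER_MM * vol * p.a_w)


def _project_to_manifold(x0: DecisionVariables, p: CellParameters, tt: str) -> DecisionVariables | None:
    """Solve the square steady-state system at fixed (phi, r, f_p).

    With the membrane pool W pinned by the coverage equality, the five
    balance equations determine (S_p, S_c, A, P, mu).  Concentrations are
    solved in log space to keep them positive.  Returns None if no
    physical root is found from a short ladder of initial guesses.
    """
    phi = tuple(x0.phi)
    r, f_p = x0.r, x0.f_p
    W = _w_from_geometry(r, f_p, p)
    s_ext = max(p.S_ext, 1e-12)

    def make_x(zv: np.ndarray) -> DecisionVariables:
        S_p, S_c, A, P = np.exp(np.clip(zv[:4], -80, 40))
        return DecisionVariables(S_p, S_c, A, W, P, *phi, r, f_p, zv[4])

    def F(zv: np.ndarray) -> np.ndarray:
        return growth_balance_residuals(make_x(zv), p, tt)

    # supply-based growth-rate estimate anchors the guess ladder
    mu_sup = 1.2 * 3.0 * p.D * s_ext / (r * r) / 1000.0
    for mu_g in (1e-4, mu_sup, 1e-5, 1e-6, 1e-3):
        if not (0 < mu_g < 1):
            continue
        for sp_frac in (0.9, 0.3, 0.01):
            z0 = np.array([math.log(s_ext * sp_frac), 0.0, 0.0, math.log(800.0), mu_g])
            with np.errstate(all="ignore"):
                sol = root(F, z0, method="hybr", options={"maxfev": 3000})
            if not sol.success:
                continue
            x = make_x(sol.x)
            if x.mu >= 0 and x.S_p <= s_ext * (1 + 1e-9):
                return x
    return None


def _heuristic_starts(p: CellParameters, tt: str) -> list[DecisionVariables]:
    """Two deterministic physiology-pattern starts, projected to the manifold.

    A copiotroph-like pattern (little transport protein, moderate cell,
    thin periplasm) and an oligotroph-like one (transport-dominated
    proteome, minimal radius, inflated periplasm).  These seed the basins
    that matter at the grid extremes even when few random starts are used.
    """
    budget = p.phi_budget
    t = p.transport
    kcat = t.k2 if tt == "pts" else t.k2p * t.k3p / (t.k2p + t.k3p)
    # copiotroph pattern: transport sized so saturated uptake matches
    # saturated metabolic demand, 5*kE*[E] = kcat*[T] (cytoplasmic basis)
    phi_E = 0.35 * budget
    phi_M = 0.08 * budget
    phi_T = min(5.0 * p.kE * phi_E * p.n_T / (p.n_E * kcat), 0.35 * budget)
    phi_BP = 0.0 if tt == "pts" else 0.5 * phi_T
    phi_R = budget - phi_E - phi_M - phi_T - phi_BP
    copiotroph = ((phi_BP, phi_T, phi_E, phi_M, max(phi_R, 0.02 * budget)),
                  0.2, 0.15)
    if tt == "pts":
        oligotroph = ((0.0, 0.60, 0.15, 0.10, 0.15), p.r_min, 0.40)
    else:
        oligotroph = ((0.50, 0.30, 0.08, 0.04, 0.08), p.r_min, 0.45)
    patterns = [copiotroph, oligotroph]
    out = []
    for weights, r, f_p in patterns:
        w = np.array(weights)
        phi = w / w.sum() * p.phi_budget
        draw = DecisionVariables(
            max(p.S_ext, 1e-12) * 0.5, 0.5, 0.5, _w_from_geometry(r, f_p, p),
            1000.0, *phi, r, f_p, 1e-4)
        proj = _project_to_manifold(draw, p, tt)
        if proj is not None:
            out.append(proj)
    return out


# ---------------------------------------------------------------------------
# main solve


def _trust_constr_polish(x0: DecisionVariables, p: CellParameters, tt: str,
                         config: SolverConfig) -> np.ndarray | None:
    """Interior-point polish, then an SQP cleanup to solver tolerance."""
    from scipy.optimize import NonlinearConstraint

    bounds = _bounds(p, tt, config)
    keep = [i for i in range(_NV) if not (tt == "pts" and i == 5)]
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def expand(zr: np.ndarray) -> np.ndarray:
        # clamp to the box: trust-constr finite differences may step
        # epsilon outside it, where the physics raises on negative state
        z = np.zeros(_NV)
        z[keep] = zr
        return np.clip(z, lo, hi)

    z0 = np.clip(scale(x0, config), lo, hi)[keep]
    try:
        with np.errstate(all="ignore"):
            res = minimize(
                lambda zr: -zr[-1], z0, method="trust-constr",
                bounds=[bounds[i] for i in keep],
                constraints=[
                    NonlinearConstraint(
                        lambda zr: _eq_constraints(expand(zr), p, tt, config), 0, 0),
                    NonlinearConstraint(
                        lambda zr: _ineq_constraints(expand(zr), p, config), 0, np.inf),
                ],
                options={"maxiter": 1000},
            )
    except (ValueError, ArithmeticError, FloatingPointError):
        return None
    try:
        z_out, success, _ = _run_sqp(unscale(expand(res.x), config), p, tt, config)
    except (ValueError, ArithmeticError):
        return None
    return z_out if success else None


def _run_sqp(x0: DecisionVariables, p: CellParameters, tt: str, config: SolverConfig):
    """One SLSQP run in scaled space; returns (z_full, success, message).

    For PTS cells ``phi_BP`` is structurally zero and is removed from the
    optimization vector entirely — a pinned variable (equal lower and
    upper bounds) makes the SQP working-set matrix singular.
    """
    bounds = _bounds(p, tt, config)
    keep = [i for i in range(_NV) if not (tt == "pts" and i == 5)]

    def expand(zr: np.ndarray) -> np.ndarray:
        z = np.zeros(_NV)
        z[keep] = zr
        return z

    z0 = np.clip(scale(x0, config),
                 [b[0] for b in bounds], [b[1] for b in bounds])[keep]
    with np.errstate(all="ignore"):
        res = minimize(
            lambda zr: -zr[-1],
            z0,
            method="SLSQP",
            bounds=[bounds[i] for i in keep],
            constraints=[
                {"type": "eq",
                 "fun": lambda zr: _eq_constraints(expand(zr), p, tt, config)},
                {"type": "ineq",
                 "fun": lambda zr: _ineq_constraints(expand(zr), p, config)},
            ],
            options={"maxiter": config.maxiter, "ftol": config.optimality_tol},
        )
    return expand(res.x), bool(res.success), str(res.message)


def _feasibility(z: np.ndarray, p: CellParameters, tt: str, config: SolverConfig):
    eq = _eq_constraints(z, p, tt, config)
    iq = _ineq_constraints(z, p, config)
    resid = max(float(np.max(np.abs(eq))), float(max(0.0, -np.min(iq))))
    return eq, iq, resid


def solve_allocation(
    p: CellParameters,
    transport_type: str,
    config: SolverConfig | None = None,
    extra_starts: list[DecisionVariables] | None = None,
) -> OptimalSolution:
    """Maximize growth rate over the allocation problem by multi-start SQP.

    ``extra_starts`` (e.g. a neighboring optimum during a concentration
    sweep) are tried before the ``config.n_starts`` random starts.  The
    best feasible converged point is returned with its derived
    observables; if no start converges to a feasible point a
    :class:`SolverFailure` carrying the full log is raised.
    """
    if transport_type not in ("pts", "abc"):
        raise ValueError(f"unknown transport type {transport_type!r}")
    if config is None:
        config = SolverConfig.for_parameters(p)
    log: list[StartRecord] = []
    candidates: list[tuple[float, float, int, np.ndarray]] = []

    starts: list[tuple[int, DecisionVariables | None]] = []
    if extra_starts:
        starts.extend((-(i + 1), x) for i, x in enumerate(extra_starts))
    for j, guess in enumerate(_heuristic_starts(p, transport_type)):
        starts.append((-(1001 + j), guess))
    for i in range(config.n_starts):
        starts.append((i, None))

    for idx, warm in starts:
        if warm is None:
            draw = random_start(config.seed, idx, config, p, transport_type)
            x0 = _project_to_manifold(draw, p, transport_type) or draw
        else:
            x0 = warm
        # a feasible start is itself a candidate: SQP must beat it, not lose it
        z0 = scale(x0, config)
        try:
            _, _, resid0 = _feasibility(z0, p, transport_type, config)
        except (ValueError, ArithmeticError):
            resid0 = math.inf
        if resid0 <= config.constraint_tol and x0.mu > 0:
            candidates.append((x0.mu, resid0, idx, z0, "projected"))
        try:
            z_out, success, message = _run_sqp(x0, p, transport_type, config)
        except (ValueError, ArithmeticError, FloatingPointError) as exc:
            log.append(StartRecord(idx, False, math.nan, math.inf, f"error: {exc}"))
            continue
        eq, iq, resid = _feasibility(z_out, p, transport_type, config)
        mu = float(z_out[-1] * config.scales[-1])
        ok = success and resid <= config.constraint_tol
        log.append(StartRecord(idx, ok, mu if ok else math.nan, resid, message))
        if ok:
            candidates.append((mu, resid, idx, z_out.copy(), "sqp"))

    if not candidates:
        raise SolverFailure(
            f"no feasible converged start out of {len(starts)} "
            f"({transport_type}, S_ext={p.S_ext:g} mM)", log)

    # best mu; ties within 1e-9 relative broken by residual norm, then index
    mu_best = max(c[0] for c in candidates)
    tol = 1e-9 * max(abs(mu_best), 1e-300)
    tied = [c for c in candidates if mu_best - c[0] <= tol]
    tied.sort(key=lambda c: (c[1], c[2]))
    _, _, _, z_star, origin = tied[0]

    if origin == "projected":
        # SQP never improved on the bare projected start (a symptom of a
        # degenerate working set); escalate to an interior-point polish
        z_tc = _trust_constr_polish(unscale(z_star, config), p, transport_type, config)
        if z_tc is not None:
            _, _, resid = _feasibility(z_tc, p, transport_type, config)
            if resid <= config.constraint_tol and z_tc[-1] * config.scales[-1] >= mu_best:
                z_star, mu_best = z_tc, float(z_tc[-1] * config.scales[-1])

    # polish once from the winner (often sharpens the last digits)
    z_out, success, _msg = _run_sqp(unscale(z_star, config), p, transport_type, config)
    if success:
        _, _, resid = _feasibility(z_out, p, transport_type, config)
        if resid <= config.constraint_tol and z_out[-1] * config.scales[-1] >= mu_best:
            z_star = z_out.copy()

    x_star = unscale(z_star, config)
    eq, iq, _ = _feasibility(z_star, p, transport_type, config)
    return _attach_observables(x_star, p, transport_type, eq, iq, tuple(log), config)


def _attach_observables(
    x: DecisionVariables, p: CellParameters, tt: str,
    eq: np.ndarray, iq: np.ndarray, log: tuple[StartRecord, ...],
    config: SolverConfig,
) -> OptimalSolution:
    pools = transport_pools(x, p)
    basis = x.f_p / (1.0 - x.f_p)  # periplasmic -> cytoplasmic rate basis
    keff_fit = None
    if tt == "pts":
        v_max = p.transport.k2 * pools.T_total * basis
        k_eff = p.transport.K_T
        k_mm = p.transport.K_T
    else:
        _, mm = abc_mm_approx(0.0, pools, p.transport)
        k_mm = mm.K_M
        keff_fit = effective_half_saturation(
            lambda s: abc_steady_state(s, pools, p.transport).v_c)
        k_eff = keff_fit.K_M
        v_max = keff_fit.V_max * basis
    # metabolic capacity: maximal substrate-processing rate 5*kE*[E],
    # cytoplasmic basis, matching V_max's basis
    met_cap = 5.0 * p.kE * x.phi_E * p.alpha["E"] * x.P
    cap_ratio = math.inf if met_cap == 0 else v_max / met_cap
    tol = config.constraint_tol
    return OptimalSolution(
        transport_type=tt,
        x_star=x,
        mu=x.mu,
        equality_residuals=eq,
        inequality_margins=iq,
        active_inequalities=tuple(bool(m < tol * 10) for m in iq),
        start_log=log,
        V_max=v_max,
        K_eff=k_eff,
        K_M_mm=k_mm,
        specific_affinity=v_max / k_eff,
        bp_t_ratio=(pools.BP_total / pools.T_total) if pools.T_total > 0 else math.inf,
        sa_v=3.0 / x.r,
        capacity_ratio=cap_ratio,
        transport_proteome_fraction=x.phi_BP + x.phi_T,
        keff_fit=keff_fit,
    )


def validate_solution(sol: OptimalSolution, p: CellParameters,
                      config: SolverConfig | None = None) -> dict:
    """Recompute every residual from scratch at x_star in unscaled units.

    Returns a report dict; raises ``AssertionError`` if any equality
    residual exceeds tolerance or any inequality margin is violated.
    """
    if config is None:
        config = SolverConfig.for_parameters(p)
    z = scale(sol.x_star, config)
    eq, iq, resid = _feasibility(z, p, sol.transport_type, config)
    closure = cm.proteome_closure_residual(sol.x_star, p)
    report = {
        "equality_residuals": eq,
        "inequality_margins": iq,
        "max_violation": resid,
        "closure_residual": closure,
        "active": tuple(bool(m < config.constraint_tol * 10) for m in iq),
    }
    if resid > config.constraint_tol:
        raise AssertionError(f"solution fails validation: max violation {resid:.3e}")
    return report
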