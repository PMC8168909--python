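"""Coarse-grained self-replicator cell model for PTS vs ABC transport.

The cell is a sphere of radius ``r`` whose volume is split into a
cytoplasm and a periplasm (volume fraction ``f_p``).  A generic carbon
substrate diffuses through the porous outer membrane into the periplasm,
is transported into the cytoplasm by either a phosphotransferase system
(PTS) or an ABC transport system, is metabolized into a generic amino-acid
precursor, and the precursor is consumed by membrane biosynthesis and by
protein synthesis.  The proteome is divided into five optimized groups —
ABC binding proteins (BP), transport units (T), metabolic enzymes (E),
membrane-biosynthesis enzymes (M), ribosomes (R) — plus two fixed "other"
fractions (cytoplasmic and periplasmic housekeeping protein).

This module provides the parameter container (with a plain-text parameter
file loader), the decision-variable container, and every constraint
function of the steady-state growth-maximization problem: the five
metabolite balances, proteome closure, membrane coverage, the cytoplasmic
and periplasmic density caps, and the inner-membrane "real estate"
constraint for membrane-bound transport units.

Units: concentration mM, time s, length um, molecular mass kDa (so a
mass density in kDa*mM is numerically a density in g/L).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np

from .kinetics import AbcPools, TransportParameters, abc_steady_state, pts_uptake

__all__ = [
    "CellParameters",
    "DecisionVariables",
    "ReactionRates",
    "load_parameters",
    "save_parameters",
    "diffusive_uptake",
    "periplasm_to_cytoplasm",
    "transport_pools",
    "reaction_rates",
    "growth_balance_residuals",
    "membrane_coverage_residual",
    "density_margins",
    "real_estate_margin",
]

#: molecules per um^3 in a 1 mM solution (Avogadro * 1e-18 L/um^3 * 1e-3 mol/L)
MOLECULES_PER_UM3_PER_MM = 6.02214076e5

PHI_NAMES = ("phi_BP", "phi_T", "phi_E", "phi_M", "phi_R")


@dataclass(frozen=True)
class CellParameters:
    """All parameters of the whole-cell allocation problem.

    The transport rate constants come from the measured glucose-PTS /
    maltose-ABC systems (see :meth:`TransportParameters.baseline`); the
    metabolic, geometric and density parameters are generic coarse-grained
    values chosen from bacterial physiology and documented, with
    rationale, in ``docs/methods.md``.
    """

    transport: TransportParameters = field(default_factory=TransportParameters.baseline)
    #: boundary-layer/periplasmic diffusivity of the free substrate (um^2/s)
    D: float = 100.0
    #: metabolic-enzyme turnover (/s) and half-saturation (mM); one enzyme
    #: "unit" lumps the whole catabolic pathway (hence a low turnover per
    #: unit of its large amino-acid cost n_E)
    kE: float = 0.5
    K_ME: float = 0.1
    #: membrane-biosynthesis turnover (/s) and half-saturation (mM)
    kW: float = 1.0
    K_MW: float = 0.1
    #: ribosome elongation rate (amino acids /s) and half-saturation (mM)
    kR: float = 20.0
    K_MR: float = 0.1
    #: amino acids per protein copy; alpha_X = 1/n_X converts the proteome
    #: amino-acid pool phi_X*[P] into copy concentration. n_BP = n_T/4: a
    #: binding protein costs four-fold fewer amino acids than a transport unit.
    n_T: float = 2000.0
    n_BP: float = 500.0
    n_E: float = 1000.0
    n_M: float = 1000.0
    n_R: float = 7459.0
    #: membrane area per membrane unit and per transport unit (um^2)
    a_w: float = 6.0e-7
    a_T: float = 5.0e-5
    #: fraction of inner-membrane area available to transport units
    f_SA: float = 0.5
    #: maximal cytoplasmic / periplasmic mass densities (g/L); the periplasm
    #: holds less protein per volume than the cytoplasm (no ribosomes or
    #: nucleoid), which is what makes inflating it worthwhile for an
    #: oligotroph packing binding proteins
    rho_cyto: float = 300.0
    rho_peri: float = 100.0
    #: molecular masses (kDa): substrate, precursor, amino acid in protein,
    #: membrane unit
    m_S: float = 0.18
    m_A: float = 0.1
    m_aa: float = 0.1
    m_W: float = 0.75
    #: fixed "other"-protein proteome fractions
    phi_O_cyto: float = 0.45
    phi_O_peri: float = 0.05
    #: minimum cell radius (um); r = 0.06 um corresponds to a maximal
    #: surface-area-to-volume ratio of 50 /um
    r_min: float = 0.06
    #: external substrate concentration (mM) — the environmental control
    S_ext: float = 1.0e-6
    #: count membrane units in the cytoplasmic density sum
    include_W_in_cyto_density: bool = False
    #: use count-consistent volume factors in the membrane-coverage and
    #: real-estate constraints (default); False multiplies the
    #: per-compartment concentrations by the total cell volume instead
    strict_volume_basis: bool = True

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name in ("transport", "include_W_in_cyto_density", "strict_volume_basis", "S_ext"):
                continue
            v = getattr(self, f.name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"parameter {f.name} must be strictly positive, got {v}")
        if self.S_ext < 0:
            raise ValueError("S_ext must be nonnegative")
        if self.phi_O_cyto + self.phi_O_peri >= 1:
            raise ValueError("fixed 'other' proteome fractions must sum below 1")

    @property
    def alpha(self) -> dict[str, float]:
        """Copy-concentration conversion factors alpha_X = 1/n_X (per aa)."""
        return {
            "BP": 1.0 / self.n_BP,
            "T": 1.0 / self.n_T,
            "E": 1.0 / self.n_E,
            "M": 1.0 / self.n_M,
            "R": 1.0 / self.n_R,
        }

    @property
    def phi_budget(self) -> float:
        """Proteome fraction available to the five optimized groups."""
        return 1.0 - self.phi_O_cyto - self.phi_O_peri

    def with_(self, **kw) -> "CellParameters":
        """Copy with selected fields (or transport rates) replaced."""
        tkw = {k: kw.pop(k) for k in list(kw) if k in
               ("k1", "k2", "k0f", "k0r", "k1p", "k2p", "k3p")}
        transport = replace(self.transport, **tkw) if tkw else self.transport
        return replace(self, transport=transport, **kw)


@dataclass(frozen=True)
class DecisionVariables:
    """The optimization vector x = (x_m, phi, r, f_p, mu).

    ``S_p`` is on the periplasmic volume basis; ``S_c``, ``A``, ``W`` and
    ``P`` on the cytoplasmic basis.  ``P`` counts amino acids incorporated
    into protein.  For a PTS cell ``phi_BP`` is structurally zero.
    """

    S_p: float
    S_c: float
    A: float
    W: float
    P: float
    phi_BP: float
    phi_T: float
    phi_E: float
    phi_M: float
    phi_R: float
    r: float
    f_p: float
    mu: float

    @property
    def phi(self) -> np.ndarray:
        return np.array([self.phi_BP, self.phi_T, self.phi_E, self.phi_M, self.phi_R])

    def to_array(self) -> np.ndarray:
        return np.array([self.S_p, self.S_c, self.A, self.W, self.P,
                         self.phi_BP, self.phi_T, self.phi_E, self.phi_M, self.phi_R,
                         self.r, self.f_p, self.mu])

    @staticmethod
    def from_array(x: np.ndarray) -> "DecisionVariables":
        return DecisionVariables(*(float(v) for v in x))


@dataclass(frozen=True)
class ReactionRates:
    """Michaelis–Menten reaction rates at a point of the feasible domain.

    ``v_diff`` and ``v_c`` are on the periplasmic-concentration basis;
    ``v_E`` (reaction events), ``v_W`` and ``v_R`` on the cytoplasmic
    basis.  All in mM/s.
    """

    v_diff: float
    v_c: float
    v_E: float
    v_W: float
    v_R: float


def diffusive_uptake(S_ext: float, S_p: float, f_p: float, r: float, D: float) -> float:
    """Diffusion-limited supply through the outer membrane (mM/s, periplasmic basis).

    The quasi-steady diffusive flux to a sphere of radius ``r``,
    4*pi*D*r*(S_ext - S_p), divided by the periplasmic volume
    f_p*(4/3)*pi*r^3, gives 3*D*(S_ext - S_p)/(f_p*r^2).  Porins are
    assumed abundant enough that the outer membrane itself is not
    limiting.
    """
    if r <= 0:
        raise ValueError("r must be positive")
    if not 0.0 < f_p < 1.0:
        raise ValueError("f_p must lie in (0, 1)")
    return 3.0 * D * (S_ext - S_p) / (f_p * r * r)


def periplasm_to_cytoplasm(rate_peri: float, f_p: float) -> float:
    """Convert a periplasmic-basis rate to the cytoplasmic basis: * f_p/(1-f_p)."""
    if not 0.0 < f_p < 1.0:
        raise ValueError("f_p must lie in (0, 1)")
    return rate_peri * f_p / (1.0 - f_p)


def transport_pools(x: DecisionVariables, p: CellParameters) -> AbcPools:
    """Periplasmic-basis transport-protein pools implied by the allocation.

    Copy concentrations on the cytoplasmic basis are phi_X*alpha_X*[P];
    division by the periplasm-to-cytoplasm volume ratio f_p/(1-f_p) puts
    them on the periplasmic basis used by the uptake kinetics (transport
    units are counted per periplasmic volume because they face the
    periplasm from the inner membrane).
    """
    ratio = (1.0 - x.f_p) / x.f_p
    bp = x.phi_BP * p.alpha["BP"] * x.P * ratio
    t = x.phi_T * p.alpha["T"] * x.P * ratio
    return AbcPools(BP_total=max(bp, 0.0), T_total=max(t, 0.0))


def reaction_rates(x: DecisionVariables, p: CellParameters, transport_type: str) -> ReactionRates:
    """Evaluate the five reaction rates of the model at ``x``.

    ``transport_type`` selects the cytoplasmic uptake mechanism: ``"pts"``
    (two-step scheme, phi_BP unused) or ``"abc"`` (exact four-step steady
    state at the current periplasmic substrate level).
    """
    if transport_type not in ("pts", "abc"):
        raise ValueError(f"unknown transport type {transport_type!r}")
    if min(x.S_p, x.S_c, x.A, x.W, x.P) < 0 or min(x.phi) < 0:
        raise ValueError("concentrations and proteome fractions must be nonnegative")
    pools = transport_pools(x, p)
    if transport_type == "pts":
        v_c = pts_uptake(x.S_p, pools.T_total, p.transport)
    else:
        v_c = abc_steady_state(x.S_p, pools, p.transport).v_c
    E = x.phi_E * p.alpha["E"] * x.P
    M = x.phi_M * p.alpha["M"] * x.P
    R = x.phi_R * p.alpha["R"] * x.P
    return ReactionRates(
        v_diff=diffusive_uptake(p.S_ext, x.S_p, x.f_p, x.r, p.D),
        v_c=v_c,
        v_E=p.kE * E * x.S_c / (p.K_ME + x.S_c),
        v_W=p.kW * M * x.A / (p.K_MW + x.A),
        v_R=p.kR * R * x.A / (p.K_MR + x.A),
    )


def growth_balance_residuals(x: DecisionVariables, p: CellParameters, transport_type: str) -> np.ndarray:
    """Steady-state balance residuals N*v_r - mu*x_m for the five metabolites.

    Stoichiometry: diffusion feeds S_p; transport drains S_p (periplasmic
    basis) and feeds S_c (converted to the cytoplasmic basis); metabolism
    converts 5 S_c into 6 A per reaction event; membrane synthesis drains
    one A per membrane unit; protein synthesis drains one A per amino acid
    incorporated.  Each residual is zero on the balanced-growth manifold.
    """
    v = reaction_rates(x, p, transport_type)
    v_c_cyto = periplasm_to_cytoplasm(v.v_c, x.f_p)
    return np.array([
        v.v_diff - v.v_c - x.mu * x.S_p,
        v_c_cyto - 5.0 * v.v_E - x.mu * x.S_c,
        6.0 * v.v_E - v.v_W - v.v_R - x.mu * x.A,
        v.v_W - x.mu * x.W,
        v.v_R - x.mu * x.P,
    ])


def proteome_closure_residual(x: DecisionVariables, p: CellParameters) -> float:
    """Proteome closure: optimized fractions plus fixed fractions sum to one."""
    return float(np.sum(x.phi)) + p.phi_O_cyto + p.phi_O_peri - 1.0


def membrane_coverage_residual(x: DecisionVariables, p: CellParameters) -> float:
    """Membrane-unit requirement residual (um^2).

    Required area: outer sphere plus inner sphere,
    4*pi*(1 + (1-f_p)^(2/3))*r^2.  Provided area: the membrane-unit pool
    [W] times the cell volume 4*pi*r^3/3 times the per-unit area a_w (the
    printed total-volume form; with ``strict_volume_basis`` the
    cytoplasmic volume (1-f_p)*4*pi*r^3/3 is used instead, consistent
    with [W] being a per-cytoplasmic-volume concentration).
    """
    req = 4.0 * math.pi * (1.0 + (1.0 - x.f_p) ** (2.0 / 3.0)) * x.r**2
    vol = 4.0 * math.pi * x.r**3 / 3.0
    if p.strict_volume_basis:
        vol *= 1.0 - x.f_p
    provided = x.W * MOLECULES_PER_UM3_PER_MM * vol * p.a_w
    return req - provided


def density_margins(x: DecisionVariables, p: CellParameters) -> tuple[float, float]:
    """Slack of the cytoplasmic and periplasmic density caps (g/L); >= 0 when feasible.

    The cytoplasmic sum counts substrate, precursor, and the protein
    residing in the cytoplasm (everything except binding proteins and the
    periplasmic "other" fraction); membrane units are excluded by default
    (``include_W_in_cyto_density`` switches them in).  The periplasmic sum
    counts free substrate plus the binding-protein and periplasmic-other
    protein mass, converted from the cytoplasmic to the periplasmic
    volume basis.
    """
    phi_peri = x.phi_BP + p.phi_O_peri
    cyto = p.m_S * x.S_c + p.m_A * x.A + p.m_aa * (1.0 - phi_peri) * x.P
    if p.include_W_in_cyto_density:
        cyto += p.m_W * x.W
    ratio = (1.0 - x.f_p) / x.f_p
    peri = p.m_S * x.S_p + p.m_aa * phi_peri * x.P * ratio
    return p.rho_cyto - cyto, p.rho_peri - peri


def real_estate_margin(x: DecisionVariables, p: CellParameters) -> float:
    """Inner-membrane area slack for transport units (um^2); >= 0 when feasible.

    Available: f_SA * 4*pi*(1-f_p)^(2/3)*r^2.  Occupied: the periplasmic-
    basis transport-unit pool times the cell volume times the per-unit
    area a_T (printed total-volume form; ``strict_volume_basis`` uses the
    periplasmic volume so the product is the actual unit count).
    """
    avail = p.f_SA * 4.0 * math.pi * (1.0 - x.f_p) ** (2.0 / 3.0) * x.r**2
    vol = 4.0 * math.pi * x.r**3 / 3.0
    if p.strict_volume_basis:
        vol *= x.f_p
    t_peri = transport_pools(x, p).T_total
    occupied = t_peri * MOLECULES_PER_UM3_PER_MM * vol * p.a_T
    return avail - occupied


# ---------------------------------------------------------------------------
# parameter file I/O

_BOOL_FIELDS = ("include_W_in_cyto_density", "strict_volume_basis")
_TRANSPORT_KEYS = ("k1", "k2", "k0f", "k0r", "k1p", "k2p", "k3p")


def load_parameters(path: str | Path) -> CellParameters:
    """Load a flat ``key = value`` parameter file (``#`` comments, units in comments).

    Keys are the field names of :class:`CellParameters` plus the seven
    transport rate constants.  Missing keys keep their defaults; unknown
    keys raise.  Derived dissociation constants are never read — they are
    recomputed from the rates.
    """
    values: dict[str, float | bool] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        if key in _BOOL_FIELDS:
            values[key] = val.lower() in ("true", "1", "yes")
        else:
            values[key] = float(val)
    known = {f.name for f in fields(CellParameters)} - {"transport"}
    unknown = set(values) - known - set(_TRANSPORT_KEYS)
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    tvals = {k: values.pop(k) for k in _TRANSPORT_KEYS if k in values}
    transport = replace(TransportParameters.baseline(), **tvals) if tvals \
        else TransportParameters.baseline()
    return CellParameters(transport=transport, **values)


def save_parameters(p: CellParameters, path: str | Path) -> None:
    """Write ``p`` in the flat key/value format read by :func:`load_parameters`."""
    lines = ["# uptakealloc cell parameters (mM, s, um, kDa)"]
    for k in _TRANSPORT_KEYS:
        lines.append(f"{k} = {getattr(p.transport, k)!r}")
    for f in fields(p):
        if f.name == "transport":
            continue
        v = getattr(p, f.name)
        lines.append(f"{f.name} = {str(v).lower() if isinstance(v, bool) else repr(v)}")
    Path(path).write_text("\n".join(lines) + "\n")
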