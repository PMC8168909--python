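# Methods

## Scope and model structure

`uptakealloc` computes optimal steady-state physiologies of an idealized
bacterium that takes up a single generic carbon substrate either by a
phosphotransferase system (PTS) or by a binding-protein-dependent ABC
transport system, and uses the comparison to quantify the rate–affinity
trade-off between the two strategies.  The package has four layers:

1. **kinetics** — exact and approximate uptake-rate laws for both systems;
2. **cell_model** — the self-replicator cell: parameters, geometry,
   metabolite balances, and all constraint functions;
3. **allocation_solver** — multi-start constrained maximization of growth
   rate over the joint allocation/geometry/state vector;
4. **experiments** — concentration sweeps, sensitivity scans, comparisons,
   tabular export.

Internal units are mM, s, µm, and kDa throughout; conversions happen once
at parameter load.  A mass density expressed in kDa·mM is numerically a
density in g/L.

## Transport kinetics

PTS is a two-step scheme (bind, translocate); its steady-state uptake is
Michaelis–Menten with V_max = k2·[T]_total and K_M = K_T = k2/k1 — an
intrinsic constant.

ABC transport is a four-step scheme: reversible substrate capture by a
periplasmic binding protein (k0f, k0r), docking of the loaded binding
protein on the membrane transport unit (k1p), irreversible translocation
(k2p), and undocking of the empty binding protein (k3p).  Translocation
and the docking/undocking steps are treated as irreversible, which keeps
the parameter count minimal.  At steady state the system closes over four
unknowns (free BP, S:BP, free T, T:S:BP, with the post-translocation T:BP
complex eliminated through its stationarity relation [T:BP] =
(k2p/k3p)[T:S:BP]).  Substituting the two conservation identities into
the docking equilibrium reduces the system to a single quadratic in
[S:BP] with positive leading coefficient and nonpositive constant term,
hence exactly one nonnegative root; it is evaluated with the
cancellation-safe quadratic formula.  Returned states satisfy both
conservation identities to 1e-8 relative or the solver raises.

An independent oracle (`ode_relaxation_oracle`) integrates the raw
five-species mass-action ODEs (LSODA, rtol 1e-8) with the free periplasmic
substrate clamped, then sharpens the terminal state by Newton iteration on
the mass-action stationarity equations with the two conservation rows
substituted for the linearly dependent ones.  It shares no algebra with
the quadratic solution and agrees with it to better than 1e-6 relative
across randomized rate sets spanning ±2 decades around baseline (observed
worst case ~1e-13).

The closed-form Michaelis–Menten approximation
(V'_max = kcat·T·BP/(K'_T+BP), K'_M = K'_T·K_D/(K'_T+BP),
kcat = k2p·k3p/(k2p+k3p)) holds when binding proteins greatly outnumber
occupied transport units and free transport units are scarce
([T] ≪ k0r/k1p).  Both the exact and the approximate half-saturation are
always computed and reported; "K_eff" in outputs refers to the exact-model
value.

**Effective half-saturation extraction.**  Given any monotone uptake
curve, V_max is the rate at a saturating concentration (default: the top
of a 60-point log grid spanning 1e-7–1e2 mM) and K_M is the concentration
at half that rate, bracketed on the grid and refined by bisection to 1e-10
relative.  A full-curve least-squares MM fit is available as a diagnostic,
and the extractor reports the worst relative deviation of the sampled
curve from the two-parameter MM form.  For an optimal cell, K_eff is
computed from the transport equations alone at the optimal protein pools
— the default isolates the transport system's intrinsic affinity.  The
extractor accepts any concentration→rate callable, so the diffusive
outer-membrane step can be composed in front of the transport curve when
the whole-cell uptake affinity is wanted instead.

## The cell model

The cell is a sphere of radius r ≥ 60 nm (maximal surface-to-volume ratio
50 /µm) whose volume is split into periplasm (fraction f_p) and cytoplasm.
Five processes run at Michaelis–Menten rates: diffusive supply
v_diff = 3D(S_ext−S_p)/(f_p r²) (periplasmic basis; porins assumed
non-limiting), transport v_c (PTS or exact ABC), metabolism converting
5 S_c → 6 A per reaction event, membrane synthesis A → W, and protein
synthesis A → P.  Enzyme concentrations are φ_X·α_X·[P] with α_X = 1/n_X
(amino acids per enzyme copy).  Transport-protein pools enter the kinetics
on the periplasmic volume basis via the factor (1−f_p)/f_p; uptake rates
convert back to the cytoplasmic basis via f_p/(1−f_p).

Constraints: the five steady-state balances N·v_r = μ·x_m; proteome
closure Σφ + φ_O,cyto + φ_O,peri = 1; membrane coverage (membrane-unit
pool must cover inner plus outer sphere areas); density caps on cytoplasm
(S_c, A, and resident protein; membrane units excluded by default,
switchable) and periplasm (S_p plus binding-protein and periplasmic
housekeeping protein mass); and the inner-membrane real-estate limit
f_SA·4π(1−f_p)^{2/3}r² ≥ (transport-unit count)·a_T.

Two bookkeeping choices deserve note:

* **Volume basis in the coverage/real-estate constraints.**  [W] and [T]
  are per-compartment concentrations, so the package multiplies them by
  the volume of their own compartment when converting to counts
  (`strict_volume_basis=True`, the default).  The alternative form that
  multiplies the per-compartment concentration by the *total* cell volume
  is retained behind the switch; it makes the real-estate constraint
  spuriously relax as the periplasm grows and inverts the periplasm-size
  trend at high nutrient, which is why it is not the default.
* **Stoichiometry of metabolism.**  v_E is a reaction-event rate with
  coefficients (−5, +6); reading it instead as a substrate-consumption
  rate only rescales kE by 5 and is not separately implemented.

## Parameter values

Transport rate constants are measured values: k2 = k2p = 200 /s and
K_T = K'_T = 10 µM (glucose PTS), K_D = 1 µM with k0f = 1e5 /mM/s
(maltose–MalE).  The binding-protein docking and undocking steps are
~100-fold slower than their PTS counterparts because they are limited by
diffusion of the ~40 kDa binding protein rather than of the free
substrate: k3p = 0.01·k2p exactly, and k1p = 198.02 /mM/s fixed by
K'_T = 10 µM (equivalently k1p ≈ 0.0099·k1).

The remaining physiological parameters are the package's own
coarse-grained choices, fixed once from generic bacterial physiology and
shipped in `src/uptakealloc/data/baseline.params`:

| parameter | value | rationale |
|---|---|---|
| D | 100 µm²/s | small-metabolite diffusivity in water, conservative |
| kR, n_R | 20 aa/s, 7459 aa | ribosome elongation rate; protein content of a ribosome |
| kE, n_E | 0.5 /s, 1000 aa | lumped whole-pathway catabolic unit: ~5e-4 flux (mM/s) per mM·aa of enzyme, so a replete cell spends ~20% of proteome on metabolism |
| kW, n_M | 1 /s, 1000 aa | membrane synthesis a minor proteome cost (~4%) at fast growth |
| K_ME, K_MW, K_MR | 0.1 mM | typical intracellular half-saturations |
| n_T, n_BP | 2000, 500 aa | ABC transporter complex vs single binding protein; the 4-fold cost ratio is a structural assumption of the comparison |
| a_T, a_w | 5e-5, 6e-7 µm² | transporter footprint ~50 nm²; lipid headgroup ~0.6 nm² |
| f_SA | 0.5 | half the inner membrane available to transporters |
| ρ_cyto | 300 g/L | macromolecular crowding limit |
| ρ_peri | 100 g/L | the periplasm holds no ribosomes or nucleoid; periplasmic protein density estimates sit well below cytoplasmic crowding limits.  This asymmetry is what makes periplasm inflation profitable for a binding-protein-heavy cell, and the model's periplasm-size trend is sensitive to it |
| φ_O,cyto, φ_O,peri | 0.45, 0.05 | fixed housekeeping proteome |
| m_S, m_A, m_aa, m_W | 0.18, 0.1, 0.1, 0.75 kDa | glucose-like substrate; amino-acid masses; lipid |

Because this half of the parameter set is generic rather than fitted,
whole-cell outputs are quantitatively order-of-magnitude: the package's
tests and acceptance computations assert the orderings and magnitudes the
mechanism produces (crossover existence and persistence, affinity
separation ≥ 2 orders of magnitude, capacity-ratio behavior, constraint
activity, geometry trends), not digit-level values.  The kinetics layer,
whose parameters are measured, is asserted tightly.

## The optimization

μ is an ordinary decision variable coupled through the balance equations,
and the objective is the variable itself; the problem is a smooth
non-convex NLP in 13 variables (12 for PTS — φ_BP is removed from the
vector, since pinning a variable by equal bounds makes the SQP working
set singular) with 7 equalities and 3 inequalities plus bounds.

Numerical treatment:

* **Scaling.**  Variables are divided by magnitude targets (substrate
  scale tied to S_ext; proteome fractions 0.1; r 0.1 µm; μ 1e-4 /s) so
  scaled components are O(1) near optima.  Constraints are normalized:
  the S_p balance by supply concentration (multiplied by f_p·r²/3D), the
  coverage equality by required membrane area, densities by their caps,
  real estate by available area.
* **Multi-start.**  Default 50 log-uniform random starts, deterministic
  per (seed, index).  Each draw is first projected onto the
  balanced-growth manifold: at fixed (φ, r, f_p) the membrane pool is set
  by the coverage equality and the five balances are solved for
  (S_p, S_c, A, P, μ) in log space (`scipy.optimize.root`, a short ladder
  of initial guesses including a supply-based μ estimate).  Two
  deterministic physiology-pattern starts are added: a copiotroph pattern
  whose transport fraction equates saturated uptake with saturated
  metabolic capacity, and an oligotroph pattern (minimal radius, inflated
  periplasm, transport-dominated proteome).  Feasible projected starts
  are themselves kept as candidates so a diverging SQP run can never lose
  a feasible point.
* **Solver.**  SLSQP (ftol 1e-9 scaled, 500 iterations).  A start counts
  as converged only if the recomputed scaled residuals are ≤ 1e-8.  If
  the best candidate is an unimproved projected start — the signature of
  a degenerate SQP working set, which occurs in saturated regimes where
  some balances go flat — the solver escalates to a trust-region
  interior-point polish (`trust-constr`) followed by an SQP cleanup.
  Ties within 1e-9 relative in μ break by smaller residual norm, then
  lower start index.  Feasibility is always re-verified in unscaled space
  before a solution is accepted; an infeasible "best" raises with the
  full per-start log.
* **Sweeps** traverse the concentration grid from high to low and
  warm-start each point from its neighbor's optimum in addition to the
  random starts, which keeps the solution on the global branch through
  the crossover region.  Failed grid points are recorded, never dropped.

Determinism: identical (parameters, seed, config) reproduce bitwise
identical logs and solutions; the 1 nM optimum agrees across seeds
{1, 2, 3} to well within 0.5%.

## Problem sizes used by the shipped tests and acceptance run

Oracle agreement uses 100 randomized rate sets; single-condition solves
use 50 starts; concentration sweeps use a 9-point grid (1 nM–100 mM) at
10 starts per point with warm-starting; the k3p = k2p sensitivity case
uses a 5-point grid at 8 starts.  These sizes give seed-stable optima
(≤0.5% scatter) while keeping the full acceptance run around two minutes
on one CPU; denser grids and more starts reproduce the same trends.

## Known limitations

* No energy/ATP accounting: transport costs are proteomic and geometric
  only, and reversible translocation is deliberately excluded.
* The outer membrane is modeled as diffusion-limited; porin-limited
  uptake is out of scope.
* Homogeneous, constant environments; no regulation or dynamic shifts —
  capacity-ratio mismatches are interpreted, not simulated.
* The degenerate limits f_p → 0, 1 are excluded by an interior bound
  margin (1e-6); S_p is bounded by S_ext (diffusion cannot concentrate).
* At saturating nutrient the optimal radius becomes nearly flat in a
  broad range (membrane costs vanish as 1/r while nothing else penalizes
  size until diffusion binds), so reported optimal radii in rich
  conditions identify a plateau rather than a sharp optimum; growth rate
  and proteome observables are insensitive across it.
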