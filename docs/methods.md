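# Methods

## The model

Every alchemical end state — one substituent choice per substitution
site, in one phase (ligand in solution, or ligand bound in the receptor
complex) — is a 1-D potential

U_i(x) = E₀,i + elec_i + (k_i/2)(x − x₀,i)²

in kcal/mol, with x a dimensionless coordinate, one independent
coordinate per site. The complex phase differs from the solution phase by
substituent-specific offsets, which is the smallest model with nonzero
relative binding free energies. Because the configurational integral of a
harmonic well is Gaussian, the free energy of substituent i relative to
the site reference is exactly

ΔA_i = (E₀,i + elec_i) − (E₀,ref + elec_ref) + (kT/2)·ln(k_i/k_ref),

with k_B = 0.0019872 kcal·mol⁻¹·K⁻¹ and T = 298 K by default. The `elec`
component is physically identical to `E₀`; it exists only so the staged
electrostatic (de)coupling schedule of the FEP route has a term to act
on. An optional soft-core pair interaction with a fixed environment site,

U_sc(r, λ) = λ·ε·[s² − 2s],  s = (σ²/(r² + ασ²(1−λ)))³,

is available for systems that should exercise the λ-scaled nonbonded
path; it equals the full pair energy at λ = 1, vanishes at λ = 0, and is
finite at r = 0 for λ < 1 (no end-point singularity). Systems using it
lose the closed form and are validated against numerical quadrature of
the partition function instead.

## Sampling

The thermostat is overdamped Langevin by Euler–Maruyama with unit
mobility: y′ = y − ∇U dt + √(2kT dt)·ξ. The default step dt = 0.05
keeps k·dt well below stability limits for the default stiffnesses
(k ≲ 8); the equipartition and χ² tests use dt = 0.01–0.02, where the
O(dt) discretization bias of the stationary variance (a factor
1/(1 − k·dt/2)) is below their tolerances.

λ vectors live on the per-site probability simplex. They are
parameterized as a softmax of unconstrained auxiliaries θ_i, which
enforces λ_i ≥ 0 and Σλ_i = 1 by construction and — because softmax and
the reflecting box |θ_i| ≤ θ_max (default 6) are symmetric under
substituent permutation — gives identical end-state measures for
identical substituents. Pinning one auxiliary (a tempting
degeneracy-removal trick) was rejected for exactly this reason: it breaks
the permutation symmetry of the vertex regions and biases populations
when more than two substituents share a site. The box keeps the θ
marginal normalizable while leaving the λ ≥ 0.99 end-state regions
positive measure.

The auxiliaries get a mobility multiplier (`theta_mobility`, default 10)
relative to the coordinates. The biased alchemical landscape is smooth
and nearly flat, so the auxiliaries tolerate a much larger effective step
than the stiff coordinate dynamics; the multiplier raises the end-state
transition rate — the quantity that controls the statistical quality of
population ratios — by roughly the same factor, without changing the
stationary density being sampled. With the defaults, a production run of
120,000 steps yields several hundred end-state crossings.

Fixed biases enter the λ-dynamics potential as U − Σ b_i·λ_i, so a larger
b_i raises state i's occupancy and reweighting must *remove* e^(+βb_i)
from the counts; the estimator therefore uses Ñ_i = N_i·e^(−βb_i). Adding
any constant to all biases cancels exactly.

## ALF

Adaptive landscape flattening estimates those biases by population
matching: after each short run, b_i ← b_i − kT·ln(p̂_i/p̂_ref), whose
fixed point is b_i = ΔA_i (equal occupancies). Raw end-state counts carry
an additive pseudocount of 1, so a never-visited state receives the
largest admissible push instead of producing a division by zero;
pseudocounts are confined to ALF — production estimates report +inf with
a flag for unvisited states rather than silently regularizing. ALF bins
internally with a looser λ ≥ 0.8 criterion purely to harvest more counts
per short run; only relative occupancies matter for the update. The
schedule follows the canonical shape (many short runs to locate the
biases, fewer long runs to refine, defaults 10 × 4,000 + 6 × 20,000
steps), and the final long run is a validation run: it must visit every
end state and keep the max/min occupancy ratio ≤ 10 (configurable), else
a non-convergence error names the offending substituent.

## Estimators

**Population route.** Frames are assigned to a substituent combination
iff λ ≥ 0.99 at *every* site, otherwise counted unassigned. Reweighted
counts give ΔΔG_i = −kT·ln(Ñ_i/Ñ_ref) per phase; phases are differenced
per replica and the replica SD (n = 5 by default) is the reported
uncertainty. Reweighting acts on binned counts, not per-frame weights —
with constant biases the two are identical up to the binning itself.

**BAR.** For each adjacent window pair the estimate solves

Σ_F f(β(W_F − ΔG) + M) = Σ_R f(β(W_R + ΔG) − M),  M = ln(n_F/n_R),

with f the Fermi function, by bisection on a monotone residual to
10⁻⁸ kcal/mol (log-sum-exp throughout). The variance is the standard
asymptotic (maximum-likelihood) form; pair variances add over the ladder.
Overlap failure is detected at the solution, not by bracketing — the
residual is globally monotone and always has a root — as a vanishing mean
Fermi weight (< 10⁻⁸) in either direction, and produces a warning plus a
flagged estimate rather than an exception.

**Convergence.** The forward series re-estimates a leg from the first
f·n samples of every window, the reverse series from the last f·n; a leg
is marked equilibrated when the two agree within a half-width
0.5 kcal/mol band for all f ≥ 0.5. The band mirrors the usual "errors
beyond 0.5 kcal/mol are unreliable" working threshold and is
configurable.

**FEP schedule.** Windows are evenly spaced on [0, 1]; outgoing
electrostatics scale as max(0, 1 − 2λ), incoming as max(0, 2λ − 1), and
the steric mixing spans the full interval. Because the endpoints are the
exact end states, the leg ΔG is independent of the staging — the schedule
is exercised without breaking the closed-form oracle.

## Topology bookkeeping

Molecular graphs are undirected with element labels only. The common core
is the exact maximum common connected node-induced subgraph, found by
enumerating connected subgraphs of the smallest input (largest first) and
testing embedding into the others; determinism comes from a fixed
tie-break (smallest sorted label multiset, then smallest atom-id tuple,
then smallest embeddings). The exact search is limited to 20 atoms in the
smallest graph — ample for the fragment scale this package models.

Charge renormalization makes every substituent at a site carry the same
net partial charge: the target is the arithmetic mean of the non-exempt
substituent nets, and each substituent's correction is spread uniformly
over its atoms, which minimizes the largest per-atom perturbation and
makes the operation idempotent. (De)protonated substituents used for
net-charge perturbations are exempt: they keep their charges and their
integer offset. After renormalization every combinatorial compound must
land on its declared integer total (base integer plus protonation
offsets) within 10⁻⁶ e, or a consistency error is raised.

## Cycles and charge routing

Compounds and valued edges form a perturbation network. Edge values
compose additively along paths with quadrature uncertainties (legs are
independent simulations — the package has no cross-replica covariance to
exploit). Cycle closure reports the signed sum and quadrature σ around
every independent cycle; |sum| ≤ 2σ passes. Net-charge-changing
perturbations are never routed directly: the planner inserts the neutral
protonation form of the charged endpoint, so each hop either preserves
charge or changes it by ±1 through a single (de)protonation. No
finite-size or net-charge correction is applied to charged edges; the
toy systems have no periodic electrostatics for such corrections to
address.

## Budgets and conversions

The FEP cost calculator counts n_edges × directions × phases × replicas
simulations; collection time (n_simulations × windows × t_collect) is
reported separately from the total including equilibration, because the
collection-only convention is the one under which the benchmarked
protocol (20 windows, 1 ns collection, 2 directions, 2 phases, 3
replicas) costs 12 simulations and 240 ns per edge, and 168 simulations
and 3,360 ns for 14 edges. The MSλD budget computes from an explicit plan
(per-phase ALF schedules, production lengths, replica count) and echoes
whether replicas were counted — published MSλD totals are sensitive to
that convention, so it is never implicit. pIC50 differences convert as
ΔΔG = RT·ln(10)·ΔpIC50.

## What the synthetic generator does and does not emulate

`generate_fixture` builds systems with exactly specified solution-phase
ΔGs and binding ΔΔGs: seed-dependent jitter perturbs stiffnesses and
minima, but identical per-substituent stiffness across phases and
offset compensation keep the stated targets exact. It emulates the
statistical structure of the estimation problem — multi-substituent λ
trajectories with known end-state populations, window ladders with known
analytic ΔG, perturbation networks with charged and neutral members — at
realistic per-replica noise (replica SD near 0.05–0.1 kcal/mol, the scale
typical of well-converged alchemical studies). It does not emulate
rugged molecular energy landscapes, slow orthogonal degrees of freedom,
explicit solvent, force-field error, or periodic-electrostatics artifacts
of charged perturbations. Passing tests therefore demonstrate estimator
and bookkeeping correctness — unbiasedness given adequate sampling of the
stated model — not the conformational-sampling adequacy of any real
protein–ligand study.

## Problem sizes and numerical choices

Default desk-scale sizes, chosen to keep each pipeline run in tens of
seconds while leaving replica scatter well inside the 0.15 kcal/mol
verification tolerance: MSλD production 120,000 steps × 5 replicas per
phase after 10,000 discarded; ALF 10 × 4,000 + 6 × 20,000 steps; FEP
4,000 collection steps per window over 20 windows × 5 replicas. BAR
bisection tolerance 10⁻⁸ kcal/mol; simplex tolerance 10⁻⁹; quadrature
cross-checks to 10⁻⁶. Spearman correlation uses average ranks for ties
and refuses constant vectors. Degenerate inputs fail loudly: empty sample
sets, zero reference counts, λ cutoffs outside (0.5, 1], non-simplex λ
frames, and inadmissible graph edges all raise typed errors.

## Known limitations

- The λ-landscape is 1-D per site and unimodal per end state; ALF never
  has to fight metastability in x, so its schedule requirements are far
  milder than in molecular systems.
- Linear per-substituent biases only; no quadratic or cross-site bias
  terms, and no biasing-potential replica exchange.
- The population estimator's vertex-region measure is exactly symmetric
  only for substituents with identical stiffness; for unequal k the
  residual geometric bias is second-order in the (1 − cutoff) width and
  empirically below 0.02 kcal/mol at the defaults — small against the
  stochastic scatter, but not identically zero.
- MBAR, thermodynamic integration, and WHAM are out of scope; BAR is the
  only window estimator.
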