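"""Analytically solvable alchemical toy systems.

A :class:`ToySystem` stands in for the two legs of a relative binding
free energy (RBFE) thermodynamic cycle: the ligand free in solution and
the ligand bound in a receptor complex. Each alchemical substituent at
each substitution site is represented by a 1-D potential acting on that
site's coordinate; the "complex" phase differs from the "solution" phase
by substituent-specific energy offsets, which is the smallest model in
which binding selectivity (ΔΔG_bind ≠ 0) appears.

Because every per-substituent potential is harmonic (optionally plus a
constant electrostatic offset), all alchemical free energy differences
have Gaussian closed forms:

    ΔA_i - ΔA_ref = (E0_i - E0_ref) + (kT/2) ln(k_i / k_ref)

which makes every estimator in the package testable against exact truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import integrate

from .constants import DEFAULT_TEMPERATURE, kt

__all__ = [
    "ToyPotential",
    "SoftcoreParams",
    "ToySystem",
    "AnalyticTruth",
    "FixtureSpec",
    "analytic_free_energy",
    "quadrature_free_energy",
    "compute_truth",
    "generate_fixture",
    "two_substituent_system",
]

PHASES = ("solution", "complex")


@dataclass(frozen=True)
class ToyPotential:
    """1-D harmonic potential for one substituent in one phase.

    U(x) = e0 + elec + k/2 (x - x0)^2

    ``elec`` is a constant "electrostatic" component of the offset; it is
    separated from ``e0`` only so that staged electrostatic (de)coupling
    schedules have something to act on. Both enter the free energy
    identically.
    """

    k: float
    x0: float = 0.0
    e0: float = 0.0
    elec: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.k) or self.k <= 0:
            raise ValueError(f"force constant must be positive, got {self.k}")
        for name in ("x0", "e0", "elec"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def offset(self) -> float:
        """Total constant offset e0 + elec."""
        return self.e0 + self.elec

    def energy(self, x):
        """Potential energy at coordinate(s) x, kcal/mol."""
        return self.offset + 0.5 * self.k * np.square(np.asarray(x) - self.x0)


@dataclass(frozen=True)
class SoftcoreParams:
    """Parameters of the soft-core pair interaction (see engine.softcore_energy)."""

    epsilon: float = 0.5
    sigma: float = 1.0
    alpha: float = 0.5

    def __post_init__(self) -> None:
        if self.epsilon < 0 or self.sigma <= 0 or self.alpha <= 0:
            raise ValueError("softcore params require epsilon >= 0, sigma > 0, alpha > 0")


@dataclass(frozen=True)
class ToySystem:
    """Per-site, per-substituent potentials for both phases.

    Parameters
    ----------
    sites:
        One list of substituent names per substitution site. The first
        name at each site is that site's reference substituent.
    potentials:
        Mapping ``(phase, site_index, substituent_name) -> ToyPotential``.
        Every phase must define every substituent.
    temperature:
        Simulation temperature, K.
    softcore:
        Soft-core parameters used when a substituent couples to an
        explicit environment site (optional feature of the engine).
    """

    sites: tuple[tuple[str, ...], ...]
    potentials: dict
    temperature: float = DEFAULT_TEMPERATURE
    softcore: SoftcoreParams = field(default_factory=SoftcoreParams)

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not self.sites or any(len(s) < 1 for s in self.sites):
            raise ValueError("each site needs at least one substituent")
        object.__setattr__(self, "sites", tuple(tuple(s) for s in self.sites))
        for phase in PHASES:
            for s, subs in enumerate(self.sites):
                for name in subs:
                    if (phase, s, name) not in self.potentials:
                        raise ValueError(
                            f"missing potential for phase={phase!r}, site={s}, "
                            f"substituent={name!r}"
                        )

    @property
    def kt(self) -> float:
        return kt(self.temperature)

    def potential(self, phase: str, site: int, name: str) -> ToyPotential:
        try:
            return self.potentials[(phase, site, name)]
        except KeyError:
            raise KeyError(
                f"unknown substituent {name!r} at site {site} in phase {phase!r}"
            ) from None

    def reference(self, site: int) -> str:
        return self.sites[site][0]


def analytic_free_energy(
    system: ToySystem, phase: str, substituent: str, site: int = 0
) -> float:
    """Exact alchemical free energy of ``substituent`` relative to the
    site's reference substituent, in kcal/mol.

    For harmonic potentials the configurational integral is Gaussian and

        ΔA = (E0_i + elec_i) - (E0_ref + elec_ref) + (kT/2) ln(k_i/k_ref).
    """
    if phase not in PHASES:
        raise ValueError(f"phase must be one of {PHASES}, got {phase!r}")
    p_i = system.potential(phase, site, substituent)
    p_ref = system.potential(phase, site, system.reference(site))
    return p_i.offset - p_ref.offset + 0.5 * system.kt * np.log(p_i.k / p_ref.k)


def quadrature_free_energy(
    system: ToySystem,
    phase: str,
    substituent: str,
    site: int = 0,
    half_width: float = 30.0,
) -> float:
    """Free energy vs the site reference by numerical quadrature of the
    partition function. Independent cross-check of the closed form."""
    beta = 1.0 / system.kt
    p_i = system.potential(phase, site, substituent)
    p_ref = system.potential(phase, site, system.reference(site))

    def z(p: ToyPotential) -> float:
        val, _ = integrate.quad(
            lambda x: np.exp(-beta * p.energy(x)),
            p.x0 - half_width,
            p.x0 + half_width,
            limit=200,
        )
        return val

    return -system.kt * np.log(z(p_i) / z(p_ref))


@dataclass(frozen=True)
class AnalyticTruth:
    """Exact per-substituent free energies for one ToySystem.

    ``dg[phase][(site, name)]`` is the alchemical ΔG of the substituent
    relative to the site reference in that phase; ``ddg_bind[(site, name)]``
    is the relative binding free energy ΔG_complex − ΔG_solution.
    """

    dg: dict
    ddg_bind: dict

    def dg_of(self, phase: str, site: int, name: str) -> float:
        return self.dg[phase][(site, name)]


def compute_truth(system: ToySystem) -> AnalyticTruth:
    """Tabulate exact free energies for every substituent of the system."""
    dg = {phase: {} for phase in PHASES}
    ddg = {}
    for s, subs in enumerate(system.sites):
        for name in subs:
            for phase in PHASES:
                dg[phase][(s, name)] = analytic_free_energy(system, phase, name, s)
            ddg[(s, name)] = dg["complex"][(s, name)] - dg["solution"][(s, name)]
    return AnalyticTruth(dg=dg, ddg_bind=ddg)


@dataclass(frozen=True)
class FixtureSpec:
    """Specification for the synthetic fixture generator.

    ``ddg_bind`` and ``dg_solution`` give, per site, the target relative
    binding free energy and solution-phase free energy of each non-reference
    substituent (reference values are 0 by definition). ``k`` and ``x0_spread``
    control the harmonic stiffness and how far minima are scattered;
    ``jitter`` adds reproducible seed-dependent variation to stiffness.
    """

    ddg_bind: tuple[tuple[float, ...], ...] = ((1.0,),)
    dg_solution: tuple[tuple[float, ...], ...] | None = None
    k: float = 2.0
    x0_spread: float = 0.0
    jitter: float = 0.0
    temperature: float = DEFAULT_TEMPERATURE


def two_substituent_system(
    ddg_bind: float = 1.0,
    dg_solution: float = -0.25,
    k: float = 2.0,
    temperature: float = DEFAULT_TEMPERATURE,
) -> ToySystem:
    """One site, two substituents A (reference) and B.

    Solution phase: ΔG(B) = ``dg_solution``; complex phase:
    ΔG(B) = ``dg_solution + ddg_bind``; hence ΔΔG_bind(B) = ``ddg_bind``
    exactly. Equal force constants keep every λ-mixture potential harmonic
    with the same stiffness, the cleanest possible estimator testbed.
    """
    pots = {
        ("solution", 0, "A"): ToyPotential(k=k),
        ("solution", 0, "B"): ToyPotential(k=k, e0=dg_solution),
        ("complex", 0, "A"): ToyPotential(k=k),
        ("complex", 0, "B"): ToyPotential(k=k, e0=dg_solution + ddg_bind),
    }
    return ToySystem(sites=(("A", "B"),), potentials=pots, temperature=temperature)


def poor_overlap_system(
    ddg_bind: float = 1.0,
    dg_solution: float = -0.25,
    k_ref: float = 1.0,
    k_alt: float = 25.0,
    x0_alt: float = 2.5,
    temperature: float = DEFAULT_TEMPERATURE,
) -> ToySystem:
    """Two substituents whose potentials barely overlap.

    The alternative substituent sits in a much stiffer well displaced from
    the reference, so coarse window ladders have poor phase-space overlap
    between neighbours — the regime where window count dominates BAR
    variance. Offsets are chosen so ΔG(solution) = ``dg_solution`` and
    ΔΔG_bind = ``ddg_bind`` exactly.
    """
    dk = 0.5 * kt(temperature) * np.log(k_alt / k_ref)
    pots = {
        ("solution", 0, "A"): ToyPotential(k=k_ref),
        ("solution", 0, "B"): ToyPotential(k=k_alt, x0=x0_alt, e0=dg_solution - dk),
        ("complex", 0, "A"): ToyPotential(k=k_ref),
        ("complex", 0, "B"): ToyPotential(
            k=k_alt, x0=x0_alt, e0=dg_solution + ddg_bind - dk
        ),
    }
    return ToySystem(sites=(("A", "B"),), potentials=pots, temperature=temperature)


def generate_fixture(spec: FixtureSpec, seed: int) -> tuple[ToySystem, AnalyticTruth]:
    """Build a reproducible ToySystem + exact truth table from a spec.

    The same (spec, seed) pair always yields an identical system. Stated
    free energy targets are honoured exactly: seed-dependent jitter is
    applied to force constants symmetrically (same k per substituent in
    both phases) so it cancels from ΔΔG_bind, and offsets are adjusted to
    absorb the stiffness contribution to each single-phase ΔG.
    """
    if spec.k <= 0:
        raise ValueError("force constant k must be positive")
    if spec.jitter < 0 or spec.jitter >= 1:
        raise ValueError("jitter must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    kT = kt(spec.temperature)

    dg_solution = spec.dg_solution
    if dg_solution is None:
        dg_solution = tuple(tuple(0.0 for _ in site) for site in spec.ddg_bind)
    if len(dg_solution) != len(spec.ddg_bind) or any(
        len(a) != len(b) for a, b in zip(dg_solution, spec.ddg_bind)
    ):
        raise ValueError("dg_solution shape must match ddg_bind shape")

    sites = []
    pots: dict = {}
    for s, (ddgs, dgs) in enumerate(zip(spec.ddg_bind, dg_solution)):
        names = tuple(chr(ord("A") + i) for i in range(len(ddgs) + 1))
        sites.append(names)
        # per-substituent stiffness, identical across phases
        ks = spec.k * (1.0 + spec.jitter * rng.uniform(-1, 1, size=len(names)))
        x0s = spec.x0_spread * rng.uniform(-1, 1, size=len(names))
        for i, name in enumerate(names):
            # stiffness term of ΔG vs reference, cancelled via e0
            dk = 0.5 * kT * np.log(ks[i] / ks[0])
            dg_sol = 0.0 if i == 0 else dgs[i - 1]
            ddg = 0.0 if i == 0 else ddgs[i - 1]
            pots[("solution", s, name)] = ToyPotential(
                k=float(ks[i]), x0=float(x0s[i]), e0=float(dg_sol - dk)
            )
            pots[("complex", s, name)] = ToyPotential(
                k=float(ks[i]), x0=float(x0s[i]), e0=float(dg_sol + ddg - dk)
            )

    system = ToySystem(
        sites=tuple(sites), potentials=pots, temperature=spec.temperature
    )
    return system, compute_truth(system)


def with_temperature(system: ToySystem, temperature: float) -> ToySystem:
    """Copy of the system at a different temperature."""
    return replace(system, temperature=temperature)
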