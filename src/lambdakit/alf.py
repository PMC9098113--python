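"""Adaptive landscape flattening (ALF).

λ-dynamics only samples end states whose free energy is within a few kT of
the best one; everything else is effectively invisible. ALF iteratively
estimates fixed per-substituent biases b_i that flatten the alchemical
landscape so every end state is visited. The update is population matching:
after each short run, the observed end-state occupancies p̂_i give

    b_i ← b_i − kT ln(p̂_i / p̂_ref),

which converges to b_i ≈ ΔG_i (the analytic free energy vs the reference),
the point where all occupancies are equal. Raw counts carry an additive
pseudocount of 1 so never-visited states receive the maximal push instead
of a division by zero.

The schedule mirrors the canonical shape: many short exploratory runs to
locate the biases, then fewer, longer runs to refine them, then one
validation run whose occupancies must satisfy the flatness criterion
(max/min occupancy ratio ≤ ``flatness_ratio``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import sample_msld
from .estimators import bin_endstates
from .toy_systems import ToySystem

__all__ = ["AlfSchedule", "BiasSet", "NonConvergenceError", "run_alf", "flatness"]


class NonConvergenceError(RuntimeError):
    """ALF failed to surface some end state within the schedule."""


@dataclass(frozen=True)
class AlfSchedule:
    """Counts and lengths (in engine steps) of the two ALF stages."""

    n_short: int = 10
    len_short: int = 4000
    n_long: int = 6
    len_long: int = 20000

    def __post_init__(self) -> None:
        if min(self.n_short, self.len_short, self.n_long, self.len_long) <= 0:
            raise ValueError("all schedule counts and lengths must be positive")


@dataclass
class BiasSet:
    """Converged flattening biases plus their iteration history.

    ``biases[s]`` has one entry per substituent at site s; the reference
    substituent (index 0) is pinned to 0. ``trace`` holds the bias vectors
    after every ALF iteration, ``flatness_trace`` the per-iteration
    occupancy max/min ratio.
    """

    site_names: tuple
    biases: tuple
    trace: list = field(default_factory=list)
    flatness_trace: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.biases = tuple(np.asarray(b, dtype=float) for b in self.biases)
        for b in self.biases:
            if not np.isfinite(b).all():
                raise ValueError("biases must be finite")
            if b[0] != 0.0:
                raise ValueError("reference substituent bias must be pinned to 0")

    def bias_of(self, site: int, name: str) -> float:
        return float(self.biases[site][self.site_names[site].index(name)])


def _site_populations(system: ToySystem, traj, cutoff: float, pseudocount: float):
    """Per-site pseudocounted end-state populations from a trajectory."""
    counts = bin_endstates(traj, cutoff=cutoff)
    pops = []
    for s, names in enumerate(system.sites):
        c = np.full(len(names), pseudocount, dtype=float)
        for combo, n in counts.raw.items():
            c[names.index(combo[s])] += n
        pops.append(c / c.sum())
    return pops


def flatness(populations) -> float:
    """Max/min end-state occupancy ratio across all sites (1 = perfectly flat)."""
    worst = 1.0
    for p in populations:
        worst = max(worst, float(p.max() / p.min()))
    return worst


def run_alf(
    system: ToySystem,
    phase: str,
    schedule: AlfSchedule = AlfSchedule(),
    seed: int = 0,
    dt: float = 0.05,
    cutoff: float = 0.8,
    pseudocount: float = 1.0,
    flatness_ratio: float = 10.0,
    theta_max: float = 6.0,
) -> BiasSet:
    """Estimate flattening biases for one phase of a toy system.

    A lower binning cutoff (default 0.8) than the production criterion is
    used internally: the updates only need relative occupancies, and the
    looser bin yields far more counts per short run. Raises
    :class:`NonConvergenceError`, naming the offending substituent, if some
    end state has zero raw visits in the final validation run.
    """
    rng = np.random.default_rng(seed)
    biases = [np.zeros(len(names)) for names in system.sites]
    bias_set = BiasSet(site_names=system.sites, biases=tuple(biases))
    kT = system.kt

    runs = [(schedule.len_short, True)] * schedule.n_short + [
        (schedule.len_long, True)
    ] * (schedule.n_long - 1) + [(schedule.len_long, False)]

    last_pops = None
    for length, update in runs:
        run_seed = int(rng.integers(0, 2**31 - 1))
        traj = sample_msld(
            system,
            phase,
            biases,
            n_eq=length // 5,
            n_collect=length,
            dt=dt,
            seed=run_seed,
            theta_max=theta_max,
        )
        pops = _site_populations(system, traj, cutoff, pseudocount)
        last_pops = pops
        if update:
            for s, p in enumerate(pops):
                delta = -kT * np.log(p / p[0])
                biases[s] = biases[s] + delta
                biases[s] -= biases[s][0]  # keep reference pinned at 0
        bias_set.trace.append(tuple(np.array(b) for b in biases))
        bias_set.flatness_trace.append(flatness(pops))

    # validation-run checks on the final (non-updating) run
    raw = _site_populations(system, traj, cutoff, 0.0)
    for s, (names, p) in enumerate(zip(system.sites, raw)):
        dead = np.where(p == 0.0)[0]
        if dead.size:
            raise NonConvergenceError(
                f"substituent(s) {[names[i] for i in dead]} at site {s} never "
                f"sampled after the full ALF schedule"
            )
    final_flatness = flatness(last_pops)
    if final_flatness > flatness_ratio:
        raise NonConvergenceError(
            f"validation run occupancy ratio {final_flatness:.2f} exceeds the "
            f"flatness criterion {flatness_ratio}"
        )

    bias_set.biases = tuple(np.array(b) for b in biases)
    return bias_set
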