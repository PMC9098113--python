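"""Free-energy and statistical estimators.

Population route (MSλD): frames of a λ trajectory are assigned to physical
end states with a λ ≥ cutoff criterion (default 0.99 at every site), the
counts are Boltzmann-reweighted to remove the applied flattening biases,
and relative free energies follow from the residence-time ratio

    ΔΔG_i = −kT ln(Ñ_i / Ñ_ref),   Ñ_i = N_i exp(−β b_i).

Window route (FEP): adjacent-window forward/reverse energy differences are
combined with the Bennett acceptance ratio (BAR), the minimum-variance
two-state estimator; per-pair estimates sum over the ladder to the leg ΔG.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .constants import DEFAULT_TEMPERATURE, kt
from .engine import LambdaTrajectory, WindowSamples

__all__ = [
    "EndStateCounts",
    "FreeEnergyEstimate",
    "OverlapWarning",
    "bin_endstates",
    "population_ddg",
    "bar",
    "bar_leg",
    "convergence_series",
    "replicate_stats",
    "spearman",
]


class OverlapWarning(UserWarning):
    """Raised when BAR forward/reverse distributions barely overlap."""


@dataclass
class EndStateCounts:
    """Raw and reweighted end-state counts from one λ trajectory.

    Keys of ``raw`` are substituent-name tuples, one name per site.
    ``reweighted`` is populated by :func:`population_ddg`.
    """

    raw: dict
    unassigned: int
    cutoff: float
    site_names: tuple
    biases: tuple
    temperature: float
    reweighted: dict = field(default_factory=dict)

    @property
    def total_frames(self) -> int:
        return sum(self.raw.values()) + self.unassigned


@dataclass
class FreeEnergyEstimate:
    """A ΔG or ΔΔG with its uncertainty, kcal/mol."""

    value: float
    sigma: float
    method: str
    n_replicas: int = 1
    flags: tuple = ()

    def __post_init__(self) -> None:
        if self.sigma < 0 and not math.isnan(self.sigma):
            raise ValueError("sigma must be non-negative")
        if not self.method:
            raise ValueError("method tag required")


# ---------------------------------------------------------------------------
# population route


def bin_endstates(traj: LambdaTrajectory, cutoff: float = 0.99) -> EndStateCounts:
    """Assign trajectory frames to physical end states.

    A frame belongs to the substituent combination (i_1, ..., i_S) iff
    λ_{s, i_s} ≥ cutoff at every site s; otherwise it is unassigned
    (an alchemical intermediate).
    """
    if not 0.5 < cutoff <= 1.0:
        raise ValueError(f"cutoff must lie in (0.5, 1], got {cutoff}")
    n = traj.n_frames
    # index of the above-cutoff substituent per site, or -1
    winners = []
    for arr in traj.lambdas:
        hit = arr >= cutoff  # at most one per frame since cutoff > 0.5
        idx = np.where(hit.any(axis=1), hit.argmax(axis=1), -1)
        winners.append(idx)
    winners = np.stack(winners, axis=1)  # (n_frames, n_sites)
    assigned = np.all(winners >= 0, axis=1)

    raw = {
        combo: 0
        for combo in itertools.product(*[tuple(s) for s in traj.site_names])
    }
    if n:
        combos, counts = np.unique(winners[assigned], axis=0, return_counts=True)
        for combo, c in zip(combos, counts):
            key = tuple(traj.site_names[s][i] for s, i in enumerate(combo))
            raw[key] += int(c)
    return EndStateCounts(
        raw=raw,
        unassigned=int(n - assigned.sum()),
        cutoff=cutoff,
        site_names=traj.site_names,
        biases=traj.biases,
        temperature=traj.temperature,
    )


def _combo_bias(counts: EndStateCounts, combo) -> float:
    total = 0.0
    for s, name in enumerate(combo):
        total += counts.biases[s][counts.site_names[s].index(name)]
    return total


def population_ddg(
    counts: EndStateCounts,
    biases=None,
    temperature: float | None = None,
    reference=None,
) -> dict:
    """Relative free energies from reweighted end-state populations.

    The flattening bias applied during sampling inflates state i's
    occupancy by exp(+β b_i); reweighting multiplies each raw count by
    exp(−β b_i) to recover unbiased populations, then
    ΔΔG_i = −kT ln(Ñ_i / Ñ_ref). Adding a constant to every bias cancels
    exactly.

    Returns a dict mapping substituent-combination tuples to
    :class:`FreeEnergyEstimate`. Combinations never sampled get value
    +inf and the 'zero-count' flag rather than silent regularization.
    """
    if biases is not None:
        counts.biases = tuple(np.asarray(b, dtype=float) for b in biases)
    T = counts.temperature if temperature is None else temperature
    kT = kt(T)
    beta = 1.0 / kT

    if reference is None:
        reference = tuple(s[0] for s in counts.site_names)
    reference = tuple(reference)
    if reference not in counts.raw:
        raise KeyError(f"reference combination {reference} not in counts")
    n_ref = counts.raw[reference] * math.exp(-beta * _combo_bias(counts, reference))
    if n_ref <= 0:
        raise ValueError(
            "reference end state has zero reweighted count; estimate undefined"
        )

    out = {}
    for combo, n_raw in counts.raw.items():
        n_eff = n_raw * math.exp(-beta * _combo_bias(counts, combo))
        counts.reweighted[combo] = n_eff
        if n_eff == 0.0:
            out[combo] = FreeEnergyEstimate(
                value=math.inf, sigma=math.nan, method="population",
                flags=("zero-count",),
            )
        else:
            out[combo] = FreeEnergyEstimate(
                value=-kT * math.log(n_eff / n_ref), sigma=0.0, method="population"
            )
    return out


# ---------------------------------------------------------------------------
# BAR


def _fermi(x: np.ndarray) -> np.ndarray:
    # numerically safe 1 / (1 + exp(x))
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = np.exp(-x[pos]) / (1.0 + np.exp(-x[pos]))
    out[~pos] = 1.0 / (1.0 + np.exp(x[~pos]))
    return out


def _bar_residual(dg: float, w_f, w_r, beta: float, m: float) -> float:
    """log Σ f(β(W_F − ΔG) + M) − log Σ f(β(W_R + ΔG) − M); increasing in ΔG."""
    from scipy.special import logsumexp

    lf = logsumexp(-np.logaddexp(0.0, beta * (w_f - dg) + m))
    lr = logsumexp(-np.logaddexp(0.0, beta * (w_r + dg) - m))
    return lf - lr


def bar(
    forward,
    reverse,
    temperature: float = DEFAULT_TEMPERATURE,
    tol: float = 1e-8,
) -> FreeEnergyEstimate:
    """Bennett acceptance ratio estimate for one window pair.

    ``forward`` holds work samples W_F = U_1 − U_0 collected in state 0;
    ``reverse`` holds W_R = U_0 − U_1 collected in state 1 (kcal/mol).
    ΔG solves the self-consistency condition

        Σ_F f(β(W_F − ΔG) + M) = Σ_R f(β(W_R + ΔG) − M),   M = ln(n_F/n_R)

    with f the Fermi function, found here by bisection to ``tol`` kcal/mol.
    The uncertainty is the standard asymptotic variance of the maximum
    likelihood estimator.
    """
    w_f = np.asarray(forward, dtype=float)
    w_r = np.asarray(reverse, dtype=float)
    if w_f.size == 0 or w_r.size == 0:
        raise ValueError("both forward and reverse sample sets must be non-empty")
    kT = kt(temperature)
    beta = 1.0 / kT
    m = math.log(w_f.size / w_r.size)

    # bracket the root; residual is increasing in dg
    lo = min(w_f.min(), -w_r.max()) - 10.0 * kT
    hi = max(w_f.max(), -w_r.min()) + 10.0 * kT
    f_lo = _bar_residual(lo, w_f, w_r, beta, m)
    f_hi = _bar_residual(hi, w_f, w_r, beta, m)
    flags = ()
    if not (f_lo < 0 < f_hi):
        # the residual is monotone increasing; expand until bracketed
        while f_lo >= 0:
            lo -= 100.0 * kT
            f_lo = _bar_residual(lo, w_f, w_r, beta, m)
        while f_hi <= 0:
            hi += 100.0 * kT
            f_hi = _bar_residual(hi, w_f, w_r, beta, m)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _bar_residual(mid, w_f, w_r, beta, m) < 0.0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    dg = 0.5 * (lo + hi)

    # asymptotic variance (Bennett 1976 / maximum-likelihood form)
    ff = _fermi(beta * (w_f - dg) + m)
    fr = _fermi(beta * (w_r + dg) - m)
    if np.mean(ff) < 1e-8 or np.mean(fr) < 1e-8:
        # no sample carries acceptance weight at the solution: the two
        # distributions are effectively disjoint
        warnings.warn(
            "BAR forward/reverse work distributions do not overlap; the "
            "estimate is unreliable",
            OverlapWarning,
        )
        flags = flags + ("overlap-failure",)
    with np.errstate(divide="ignore", invalid="ignore"):
        var = kT**2 * (
            (np.mean(ff**2) / np.mean(ff) ** 2 - 1.0) / w_f.size
            + (np.mean(fr**2) / np.mean(fr) ** 2 - 1.0) / w_r.size
        )
    sigma = float(np.sqrt(var)) if np.isfinite(var) and var >= 0 else math.nan
    if math.isnan(sigma) and "overlap-failure" not in flags:
        flags = flags + ("variance-undefined",)
    return FreeEnergyEstimate(
        value=float(dg),
        sigma=sigma if not math.isnan(sigma) else math.nan,
        method="BAR",
        flags=flags,
    )


def bar_leg(samples: WindowSamples, temperature: float | None = None) -> FreeEnergyEstimate:
    """Leg ΔG: per-pair BAR estimates summed over the window ladder.

    Pair variances add (independent windows), so σ_leg is their quadrature
    sum.
    """
    T = samples.temperature if temperature is None else temperature
    total = 0.0
    var = 0.0
    flags: tuple = ()
    for w_f, w_r in zip(samples.forward, samples.reverse):
        est = bar(w_f, w_r, temperature=T)
        total += est.value
        if math.isfinite(est.sigma):
            var += est.sigma**2
        flags = flags + tuple(f for f in est.flags if f not in flags)
    return FreeEnergyEstimate(
        value=total, sigma=math.sqrt(var), method="BAR", flags=flags
    )


# ---------------------------------------------------------------------------
# convergence and replicate statistics


def convergence_series(
    samples: WindowSamples,
    fractions=(0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
    band: float = 0.5,
    temperature: float | None = None,
):
    """Forward/reverse data-fraction ΔG series for convergence assessment.

    The forward series re-estimates the leg from the first f·n samples of
    every window, the reverse series from the last f·n. Agreement of the
    two within a ±``band``/2-width region (default half-width 0.5 kcal/mol)
    over f ≥ 0.5 marks the leg as equilibrated.

    Returns (fractions_used, forward_values, reverse_values, converged).
    """
    fr = sorted(set(float(f) for f in fractions))
    if any(f <= 0 or f > 1 for f in fr):
        raise ValueError("fractions must lie in (0, 1]")
    T = samples.temperature if temperature is None else temperature

    used, fwd, rev = [], [], []
    for f in fr:
        cut = [max(0, int(round(f * a.size))) for a in samples.forward]
        if any(c < 2 for c in cut):
            warnings.warn(f"fraction {f} leaves <2 samples in a window; skipped")
            continue
        head = WindowSamples(
            lambdas=samples.lambdas,
            forward=[a[:c] for a, c in zip(samples.forward, cut)],
            reverse=[a[:c] for a, c in zip(samples.reverse, cut)],
            n_eq=samples.n_eq,
            n_collect=samples.n_collect,
            temperature=samples.temperature,
        )
        tail = WindowSamples(
            lambdas=samples.lambdas,
            forward=[a[a.size - c :] for a, c in zip(samples.forward, cut)],
            reverse=[a[a.size - c :] for a, c in zip(samples.reverse, cut)],
            n_eq=samples.n_eq,
            n_collect=samples.n_collect,
            temperature=samples.temperature,
        )
        used.append(f)
        fwd.append(bar_leg(head, temperature=T).value)
        rev.append(bar_leg(tail, temperature=T).value)

    converged = all(
        abs(a - b) <= band
        for f, a, b in zip(used, fwd, rev)
        if f >= 0.5
    )
    return np.array(used), np.array(fwd), np.array(rev), converged


def replicate_stats(estimates) -> FreeEnergyEstimate:
    """Mean and sample standard deviation over independent replicas.

    With a single replica the mean is reported and σ flagged undefined
    (NaN) rather than zero.
    """
    vals = np.asarray(
        [e.value if isinstance(e, FreeEnergyEstimate) else float(e) for e in estimates]
    )
    if vals.size == 0:
        raise ValueError("need at least one replica")
    if vals.size == 1:
        return FreeEnergyEstimate(
            value=float(vals[0]), sigma=math.nan, method="replicate-mean",
            n_replicas=1, flags=("sigma-undefined",),
        )
    return FreeEnergyEstimate(
        value=float(vals.mean()),
        sigma=float(vals.std(ddof=1)),
        method="replicate-mean",
        n_replicas=int(vals.size),
    )


def spearman(x, y) -> float:
    """Spearman rank correlation with average-rank tie handling.

    Raises for length mismatch, n < 3, or a constant input (rank order
    undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for a constant vector")
    r, _ = stats.spearmanr(x, y)
    return float(r)
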