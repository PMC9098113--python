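"""Estimator correctness: binning, population reweighting, BAR (with an
independently coded reference solver), convergence series, replica stats,
rank correlation."""

import math
import warnings

import numpy as np
import pytest
from scipy.optimize import brentq

from lambdakit.constants import kt
from lambdakit.engine import LambdaTrajectory, WindowSamples
from lambdakit.estimators import (
    OverlapWarning,
    bar,
    bar_leg,
    bin_endstates,
    convergence_series,
    population_ddg,
    replicate_stats,
    spearman,
)

KT298 = kt(298.0)


def make_traj(lams, biases=(0.0, 0.0), T=298.0):
    arr = np.asarray(lams, dtype=float)
    return LambdaTrajectory(
        site_names=(("A", "B"),),
        lambdas=(arr,),
        biases=(np.asarray(biases, dtype=float),),
        temperature=T,
        seed=0,
        dt=0.05,
    )


# ---------------------------------------------------------------------------
# binning


def test_bin_counts_and_unassigned():
    traj = make_traj([(1.0, 0.0), (0.995, 0.005), (0.5, 0.5), (0.005, 0.995)])
    counts = bin_endstates(traj, cutoff=0.99)
    assert counts.raw[("A",)] == 2
    assert counts.raw[("B",)] == 1
    assert counts.unassigned == 1
    assert counts.total_frames == 4


def test_bin_all_reference():
    traj = make_traj([(1.0, 0.0)] * 7)
    counts = bin_endstates(traj)
    assert counts.raw[("A",)] == 7 and counts.unassigned == 0


def test_bin_cutoff_domain():
    traj = make_traj([(1.0, 0.0)])
    with pytest.raises(ValueError):
        bin_endstates(traj, cutoff=1.01)
    with pytest.raises(ValueError):
        bin_endstates(traj, cutoff=0.5)


def test_bin_multisite_requires_all_sites_above_cutoff():
    traj = LambdaTrajectory(
        site_names=(("A", "B"), ("X", "Y")),
        lambdas=(
            np.array([[1.0, 0.0], [1.0, 0.0], [0.5, 0.5]]),
            np.array([[1.0, 0.0], [0.4, 0.6], [1.0, 0.0]]),
        ),
        biases=(np.zeros(2), np.zeros(2)),
        temperature=298.0,
        seed=0,
        dt=0.05,
    )
    counts = bin_endstates(traj)
    assert counts.raw[("A", "X")] == 1
    assert counts.unassigned == 2


# ---------------------------------------------------------------------------
# population free energies


def test_equal_counts_zero_bias_zero_ddg():
    traj = make_traj([(1.0, 0.0), (0.0, 1.0)] * 10)
    est = population_ddg(bin_endstates(traj))
    assert est[("B",)].value == pytest.approx(0.0)
    assert est[("A",)].value == 0.0


def test_count_ratio_e_inverse():
    # N_B/N_A = e^-1 at zero bias -> ΔΔG_B = +kT = 0.5922
    n_a, n_b = 1000, int(round(1000 * math.exp(-1)))
    frames = [(1.0, 0.0)] * n_a + [(0.0, 1.0)] * n_b
    est = population_ddg(bin_endstates(make_traj(frames)))
    assert est[("B",)].value == pytest.approx(-KT298 * math.log(n_b / n_a))
    assert est[("B",)].value == pytest.approx(0.5922, abs=2e-3)


def test_bias_reweighting_recovers_kt():
    # equal raw counts, b_B = +kT: reweighted ratio e^-1 -> ΔΔG_B = +kT
    frames = [(1.0, 0.0), (0.0, 1.0)] * 500
    traj = make_traj(frames, biases=(0.0, KT298))
    est = population_ddg(bin_endstates(traj))
    assert est[("B",)].value == pytest.approx(KT298)
    assert est[("B",)].value == pytest.approx(0.5922, abs=1e-3)


def test_bias_shift_invariance_exact():
    frames = [(1.0, 0.0)] * 700 + [(0.0, 1.0)] * 300
    traj1 = make_traj(frames, biases=(0.0, 0.4))
    traj2 = make_traj(frames, biases=(123.456, 123.856))
    e1 = population_ddg(bin_endstates(traj1))
    e2 = population_ddg(bin_endstates(traj2))
    assert e1[("B",)].value == pytest.approx(e2[("B",)].value, abs=1e-12)


def test_zero_count_flagged_not_dropped():
    traj = make_traj([(1.0, 0.0)] * 5)
    est = population_ddg(bin_endstates(traj))
    assert math.isinf(est[("B",)].value)
    assert "zero-count" in est[("B",)].flags


def test_zero_reference_count_errors():
    traj = make_traj([(0.0, 1.0)] * 5)
    with pytest.raises(ValueError, match="reference"):
        population_ddg(bin_endstates(traj))


# ---------------------------------------------------------------------------
# BAR


def _oracle_bar(w_f, w_r, T):
    """Independent reference solver: plain-sum Fermi residual + brentq."""
    beta = 1.0 / kt(T)
    m = math.log(len(w_f) / len(w_r))

    def fermi(x):
        return 1.0 / (1.0 + np.exp(np.clip(x, -500, 500)))

    def resid(dg):
        return np.sum(fermi(beta * (w_f - dg) + m)) - np.sum(
            fermi(beta * (w_r + dg) - m)
        )

    return brentq(resid, -50, 50, xtol=1e-12)


def test_bar_zero_work_zero_dg():
    est = bar(np.zeros(100), np.zeros(100))
    assert est.value == pytest.approx(0.0, abs=1e-8)


def test_bar_constant_offset_exact():
    # same-stiffness states differing by E0 = 1.0: work is exactly 1.0
    est = bar(np.full(50, 1.0), np.full(80, -1.0))
    assert est.value == pytest.approx(1.0, abs=1e-8)


def test_bar_antisymmetry():
    rng = np.random.default_rng(3)
    w_f = rng.normal(1.2, 0.8, 400)
    w_r = rng.normal(-0.7, 0.6, 300)
    a = bar(w_f, w_r)
    b = bar(w_r, w_f)
    assert a.value == pytest.approx(-b.value, abs=1e-7)


def test_bar_gaussian_two_state_recovery():
    # x sampled from each harmonic state; ΔU = U1 - U0 analytic ΔA known
    T, k0, k1, de = 298.0, 2.0, 4.0, 1.0
    kT = kt(T)
    truth = de + 0.5 * kT * math.log(k1 / k0)
    rng = np.random.default_rng(8)
    x0 = rng.normal(0, math.sqrt(kT / k0), 10000)
    x1 = rng.normal(0, math.sqrt(kT / k1), 10000)
    du = lambda x: de + 0.5 * (k1 - k0) * x**2
    est = bar(du(x0), -du(x1), temperature=T)
    assert est.value == pytest.approx(truth, abs=0.05)
    assert 0 < est.sigma < 0.05


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_bar_matches_independent_reference(seed):
    rng = np.random.default_rng(seed)
    w_f = rng.normal(0.8, 1.1, 2000)
    w_r = rng.normal(-0.5, 0.9, 1500)
    mine = bar(w_f, w_r).value
    ref = _oracle_bar(w_f, w_r, 298.0)
    assert abs(mine - ref) < 1e-6


def test_bar_overlap_failure_warns_and_flags():
    with pytest.warns(OverlapWarning):
        est = bar(np.full(50, 500.0), np.full(50, 400.0))
    assert "overlap-failure" in est.flags


def test_bar_empty_direction_rejected():
    with pytest.raises(ValueError):
        bar(np.array([]), np.array([1.0]))


# ---------------------------------------------------------------------------
# convergence series


def _iid_samples(rng, n_windows=5, n=400, mu=0.2, sd=0.5):
    lams = np.linspace(0, 1, n_windows)
    fwd = [rng.normal(mu, sd, n) for _ in range(n_windows - 1)]
    rev = [rng.normal(-mu, sd, n) for _ in range(n_windows - 1)]
    return WindowSamples(lambdas=lams, forward=fwd, reverse=rev, n_eq=0, n_collect=n)


def test_convergence_full_fraction_equals_full_estimate(rng):
    s = _iid_samples(rng)
    full = bar_leg(s).value
    fr, fwd, rev, _ = convergence_series(s, fractions=[0.5, 1.0])
    assert fwd[-1] == pytest.approx(full)
    assert rev[-1] == pytest.approx(full)


def test_convergence_stationary_series_within_noise():
    # i.i.d. samples: all fractions fluctuate around the full estimate
    devs = []
    for seed in range(5):
        r = np.random.default_rng(100 + seed)
        s = _iid_samples(r, n=600)
        full = bar_leg(s).value
        _, fwd, rev, conv = convergence_series(s)
        devs.append(max(np.abs(np.concatenate([fwd, rev]) - full)))
        assert conv
    assert np.median(devs) < 0.25


def test_convergence_detects_nonequilibration(rng):
    s = _iid_samples(rng, n=600)
    # contaminate the first half of every window with a +5 kcal/mol shift
    s.forward = [np.concatenate([f[: f.size // 2] + 5.0, f[f.size // 2 :]]) for f in s.forward]
    _, _, _, converged = convergence_series(s)
    assert not converged


def test_convergence_skips_tiny_fractions(rng):
    s = _iid_samples(rng, n=10)
    with pytest.warns(UserWarning, match="skipped"):
        used, _, _, _ = convergence_series(s, fractions=[0.05, 1.0])
    assert 0.05 not in used


# ---------------------------------------------------------------------------
# replica statistics and rank correlation


def test_replicate_stats_examples():
    est = replicate_stats([1.0, 1.0, 1.0])
    assert (est.value, est.sigma) == (1.0, 0.0)
    est = replicate_stats([0.5, 1.0, 1.5])
    assert est.value == pytest.approx(1.0)
    assert est.sigma == pytest.approx(0.5)


def test_replicate_single_flagged():
    est = replicate_stats([2.0])
    assert est.value == 2.0
    assert math.isnan(est.sigma)
    assert "sigma-undefined" in est.flags


def test_spearman_examples():
    assert spearman([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)
    assert spearman([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)
    assert spearman([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)


def test_spearman_errors():
    with pytest.raises(ValueError):
        spearman([1, 2], [2, 1])
    with pytest.raises(ValueError):
        spearman([1.0, 1.0, 1.0], [1, 2, 3])
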