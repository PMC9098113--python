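"""Stochastic sampling engine.

Two sampling modes drive everything downstream:

* fixed-λ windows (:func:`run_fep`) — overdamped Langevin sampling of the
  coordinate at a ladder of alchemical intermediate states, emitting the
  forward/reverse energy-difference samples that feed the BAR estimator;
* multisite λ-dynamics (:func:`sample_msld`) — joint propagation of the
  coordinate and one alchemical λ vector per substitution site, emitting a
  :class:`LambdaTrajectory` whose end-state residence populations carry the
  free energy information.

λ vectors live on the probability simplex (λ_i ≥ 0, Σλ_i = 1). They are
represented through unconstrained auxiliary variables θ_i mapped by a
softmax, which enforces the simplex constraint by construction and is
symmetric under substituent permutation. The auxiliaries are confined to a
reflecting box |θ_i| ≤ θ_max so the marginal density is normalizable while
the λ ≥ 0.99 end-state regions keep positive measure.

The thermostat is overdamped Langevin (Euler–Maruyama, unit mobility):

    y' = y − ∇U(y) dt + sqrt(2 kT dt) ξ,   ξ ~ N(0, 1)

applied to coordinates and θ auxiliaries alike. Fixed biases b_i enter the
λ-dynamics potential as U − Σ_i b_i λ_i, so a larger b_i increases the
occupancy of end state i.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_TEMPERATURE
from .toy_systems import SoftcoreParams, ToySystem

__all__ = [
    "LambdaState",
    "LambdaTrajectory",
    "LambdaWindow",
    "WindowSamples",
    "softcore_energy",
    "fep_schedule",
    "sample_fixed_lambda",
    "run_fep",
    "sample_msld",
]

SIMPLEX_TOL = 1e-9
_NOISE_CHUNK = 4096  # steps of pre-generated noise per RNG call


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class LambdaState:
    """Per-site alchemical coupling vectors on the simplex."""

    lambdas: tuple

    def __post_init__(self) -> None:
        clean = []
        for vec in self.lambdas:
            arr = np.asarray(vec, dtype=float)
            if arr.ndim != 1:
                raise ValueError("each site's lambda vector must be 1-D")
            if np.any(arr < -SIMPLEX_TOL) or np.any(arr > 1 + SIMPLEX_TOL):
                raise ValueError("lambda components must lie in [0, 1]")
            if abs(arr.sum() - 1.0) > SIMPLEX_TOL:
                raise ValueError(
                    f"lambda vector must sum to 1 (got {arr.sum():.12f})"
                )
            clean.append(arr)
        object.__setattr__(self, "lambdas", tuple(clean))


@dataclass
class LambdaTrajectory:
    """Time series of per-site λ vectors from one MSλD run.

    ``lambdas[s]`` has shape (n_frames, n_substituents(s)). ``biases[s]``
    is the fixed bias vector applied during the run (constant over the
    run by construction).
    """

    site_names: tuple
    lambdas: tuple
    biases: tuple
    temperature: float
    seed: int
    dt: float
    stride: int = 1

    def __post_init__(self) -> None:
        self.site_names = tuple(tuple(s) for s in self.site_names)
        self.lambdas = tuple(np.asarray(a, dtype=float) for a in self.lambdas)
        self.biases = tuple(np.asarray(b, dtype=float) for b in self.biases)
        n = {a.shape[0] for a in self.lambdas}
        if len(n) > 1:
            raise ValueError("all sites must have the same number of frames")
        for names, arr, b in zip(self.site_names, self.lambdas, self.biases):
            if arr.shape[1] != len(names) or b.shape[0] != len(names):
                raise ValueError("lambda/bias width must match substituent count")
        if not all(np.isfinite(b).all() for b in self.biases):
            raise ValueError("biases must be finite")

    @property
    def n_frames(self) -> int:
        return self.lambdas[0].shape[0] if self.lambdas else 0

    def check_simplex(self, tol: float = SIMPLEX_TOL) -> bool:
        """True iff every frame satisfies the simplex invariant."""
        for arr in self.lambdas:
            if arr.size == 0:
                continue
            if np.any(arr < -tol) or np.any(arr > 1 + tol):
                return False
            if np.max(np.abs(arr.sum(axis=1) - 1.0)) > tol:
                return False
        return True


@dataclass(frozen=True)
class LambdaWindow:
    """One FEP window: global λ plus derived coupling factors."""

    lam: float
    elec_outgoing: float
    elec_incoming: float
    steric: float


@dataclass
class WindowSamples:
    """Forward/reverse energy-difference samples from a FEP window ladder.

    ``forward[w]`` holds U_{w+1} − U_w evaluated on window-w frames;
    ``reverse[w]`` holds U_w − U_{w+1} evaluated on window-(w+1) frames,
    both in kcal/mol.
    """

    lambdas: np.ndarray
    forward: list
    reverse: list
    n_eq: int
    n_collect: int
    temperature: float = DEFAULT_TEMPERATURE
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if np.any(np.diff(self.lambdas) <= 0):
            raise ValueError("windows must be strictly ordered in lambda")
        if np.any(self.lambdas < 0) or np.any(self.lambdas > 1):
            raise ValueError("window lambdas must lie in [0, 1]")
        self.forward = [np.asarray(a, dtype=float) for a in self.forward]
        self.reverse = [np.asarray(a, dtype=float) for a in self.reverse]
        npairs = len(self.lambdas) - 1
        if len(self.forward) != npairs or len(self.reverse) != npairs:
            raise ValueError("need one forward and one reverse set per window pair")

    @property
    def n_windows(self) -> int:
        return len(self.lambdas)


# ---------------------------------------------------------------------------
# potentials and schedules


def softcore_energy(r, lam: float, params: SoftcoreParams) -> np.ndarray:
    """λ-scaled soft-core pair energy, kcal/mol.

    A Lennard-Jones-like interaction with a λ-padded squared separation,

        U(r, λ) = λ ε [ s^2 − 2 s ],   s = (σ² / (r² + α σ² (1−λ)))³,

    so U(·, 1) is the full pair energy, U(·, 0) ≡ 0, and the energy is
    finite at r = 0 whenever λ < 1 (no end-point singularity).
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("separation r must be non-negative")
    if lam == 0.0:
        return np.zeros_like(r)
    denom = r * r + params.alpha * params.sigma**2 * (1.0 - lam)
    s = (params.sigma**2 / denom) ** 3
    return lam * params.epsilon * (s * s - 2.0 * s)


def fep_schedule(n_windows: int) -> list[LambdaWindow]:
    """Evenly spaced λ window ladder with staged electrostatics.

    Electrostatics of outgoing atoms are decoupled over λ ∈ [0, 0.5]
    (factor max(0, 1 − 2λ)) and of incoming atoms coupled over
    λ ∈ [0.5, 1] (factor max(0, 2λ − 1)); the steric soft-core factor
    spans the full [0, 1].
    """
    if n_windows < 2:
        raise ValueError(f"need at least 2 windows, got {n_windows}")
    lams = np.linspace(0.0, 1.0, n_windows)
    return [
        LambdaWindow(
            lam=float(l),
            elec_outgoing=float(max(0.0, 1.0 - 2.0 * l)),
            elec_incoming=float(max(0.0, 2.0 * l - 1.0)),
            steric=float(l),
        )
        for l in lams
    ]


def _hybrid_terms(system: ToySystem, phase: str, pair, site: int):
    """Coefficient arrays of the pairwise alchemical hybrid potential."""
    out_name, in_name = pair
    p_out = system.potential(phase, site, out_name)
    p_in = system.potential(phase, site, in_name)
    return p_out, p_in


def hybrid_energy(system: ToySystem, phase: str, pair, window: LambdaWindow, x, site: int = 0):
    """Energy of the dual-topology hybrid at one window, kcal/mol.

    Steric (harmonic + e0) parts mix linearly in λ; the electrostatic
    offsets follow the staged (de)coupling factors. At λ=0 and λ=1 the
    hybrid equals the pure end states exactly.
    """
    p_out, p_in = _hybrid_terms(system, phase, pair, site)
    x = np.asarray(x, dtype=float)
    lam = window.steric
    steric = (1.0 - lam) * (p_out.e0 + 0.5 * p_out.k * (x - p_out.x0) ** 2) + lam * (
        p_in.e0 + 0.5 * p_in.k * (x - p_in.x0) ** 2
    )
    return steric + window.elec_outgoing * p_out.elec + window.elec_incoming * p_in.elec


def _hybrid_force(system: ToySystem, phase: str, pair, window: LambdaWindow, x, site: int = 0):
    p_out, p_in = _hybrid_terms(system, phase, pair, site)
    lam = window.steric
    return (1.0 - lam) * p_out.k * (x - p_out.x0) + lam * p_in.k * (x - p_in.x0)


# ---------------------------------------------------------------------------
# fixed-lambda sampling (FEP)


def sample_fixed_lambda(
    system: ToySystem,
    phase: str,
    pair,
    windows,
    n_eq: int,
    n_collect: int,
    dt: float = 0.05,
    seed: int = 0,
    site: int = 0,
) -> np.ndarray:
    """Langevin-sample the hybrid coordinate at fixed λ windows.

    Returns an array of shape (n_collect, n_windows): one coordinate
    column per window, the first ``n_eq`` steps discarded. All windows
    are propagated in parallel with independent noise; the stream is
    reproducible under ``seed``.
    """
    if isinstance(windows, LambdaWindow):
        windows = [windows]
    if n_eq < 0 or n_collect < 0:
        raise ValueError("n_eq and n_collect must be non-negative")
    nw = len(windows)
    rng = np.random.default_rng(seed)
    kT = system.kt
    sigma_step = np.sqrt(2.0 * kT * dt)

    # per-window force coefficients (each hybrid is harmonic in x)
    keff = np.empty(nw)
    mu = np.empty(nw)
    for j, w in enumerate(windows):
        p_out, p_in = _hybrid_terms(system, phase, pair, site)
        keff[j] = (1.0 - w.steric) * p_out.k + w.steric * p_in.k
        mu[j] = ((1.0 - w.steric) * p_out.k * p_out.x0 + w.steric * p_in.k * p_in.x0) / keff[j]

    x = mu.copy()
    out = np.empty((n_collect, nw))
    total = n_eq + n_collect
    step = 0
    while step < total:
        block = min(_NOISE_CHUNK, total - step)
        noise = rng.standard_normal((block, nw)) * sigma_step
        for i in range(block):
            x = x - dt * keff * (x - mu) + noise[i]
            idx = step + i
            if idx >= n_eq:
                out[idx - n_eq] = x
        step += block
    return out


def run_fep(
    system: ToySystem,
    phase: str,
    pair,
    n_windows: int = 20,
    n_eq: int = 500,
    n_collect: int = 2000,
    dt: float = 0.05,
    seed: int = 0,
    site: int = 0,
) -> WindowSamples:
    """Full FEP leg: sample every window, emit forward/reverse ΔU sets."""
    windows = fep_schedule(n_windows)
    coords = sample_fixed_lambda(
        system, phase, pair, windows, n_eq, n_collect, dt=dt, seed=seed, site=site
    )
    forward, reverse = [], []
    for w in range(n_windows - 1):
        xw, xw1 = coords[:, w], coords[:, w + 1]
        u_w_on_w = hybrid_energy(system, phase, pair, windows[w], xw, site)
        u_w1_on_w = hybrid_energy(system, phase, pair, windows[w + 1], xw, site)
        u_w_on_w1 = hybrid_energy(system, phase, pair, windows[w], xw1, site)
        u_w1_on_w1 = hybrid_energy(system, phase, pair, windows[w + 1], xw1, site)
        forward.append(u_w1_on_w - u_w_on_w)
        reverse.append(u_w_on_w1 - u_w1_on_w1)
    return WindowSamples(
        lambdas=np.array([w.lam for w in windows]),
        forward=forward,
        reverse=reverse,
        n_eq=n_eq,
        n_collect=n_collect,
        temperature=system.temperature,
        seed=seed,
        meta={"phase": phase, "pair": tuple(pair), "site": site},
    )


# ---------------------------------------------------------------------------
# multisite lambda dynamics


def _softmax(theta: np.ndarray) -> np.ndarray:
    z = theta - theta.max(axis=-1, keepdims=True)
    e = np.exp(z)
    lam = e / e.sum(axis=-1, keepdims=True)
    # renormalize so the simplex invariant holds to SIMPLEX_TOL exactly
    return lam / lam.sum(axis=-1, keepdims=True)


def _reflect(theta: np.ndarray, bound: float) -> np.ndarray:
    theta = np.where(theta > bound, 2.0 * bound - theta, theta)
    theta = np.where(theta < -bound, -2.0 * bound - theta, theta)
    return np.clip(theta, -bound, bound)


def sample_msld(
    system: ToySystem,
    phase: str,
    biases,
    n_eq: int,
    n_collect: int,
    dt: float = 0.05,
    seed: int = 0,
    n_replicas: int = 1,
    theta_max: float = 6.0,
    stride: int = 1,
    theta_mobility: float = 10.0,
):
    """Propagate coordinates and λ auxiliaries jointly; return trajectories.

    ``biases`` is one bias vector per site (kcal/mol, one entry per
    substituent); the sampled potential is U(x, λ) − Σ b_i λ_i. With
    ``n_replicas > 1`` the replicas are propagated in parallel with
    independent noise from one seeded stream and returned as a list of
    :class:`LambdaTrajectory`, one per replica.

    ``theta_mobility`` scales the auxiliary-variable mobility relative to
    the coordinates. The alchemical landscape is smooth and nearly flat
    once biased, so the auxiliaries tolerate a much larger effective step;
    a high mobility multiplies the end-state transition rate (hence the
    number of independent population samples) without destabilizing the
    stiff coordinate dynamics. Both choices sample the same stationary
    density.

    Returns a single trajectory when ``n_replicas == 1``.
    """
    biases = [np.asarray(b, dtype=float) for b in biases]
    if len(biases) != len(system.sites):
        raise ValueError("need one bias vector per site")
    for b, names in zip(biases, system.sites):
        if b.shape != (len(names),):
            raise ValueError(
                f"bias vector length {b.shape} does not match substituent count "
                f"{len(names)}"
            )
        if not np.isfinite(b).all():
            raise ValueError("biases must be finite")
    if n_eq < 0 or n_collect < 0:
        raise ValueError("n_eq and n_collect must be non-negative")
    if stride < 1:
        raise ValueError("stride must be >= 1")

    rng = np.random.default_rng(seed)
    kT = system.kt
    R = n_replicas
    n_sites = len(system.sites)

    # per-site parameter arrays
    ks, x0s, offs = [], [], []
    for s, names in enumerate(system.sites):
        pots = [system.potential(phase, s, n) for n in names]
        ks.append(np.array([p.k for p in pots]))
        x0s.append(np.array([p.x0 for p in pots]))
        offs.append(np.array([p.offset for p in pots]))

    x = [np.zeros(R) for _ in range(n_sites)]
    theta = [rng.uniform(-1.0, 1.0, size=(R, len(names))) for names in system.sites]

    n_out = (n_collect + stride - 1) // stride if n_collect else 0
    frames = [np.empty((n_out, R, len(names))) for names in system.sites]

    if theta_mobility <= 0:
        raise ValueError("theta_mobility must be positive")
    dt_t = dt * theta_mobility
    sig_x = np.sqrt(2.0 * kT * dt)
    sig_t = np.sqrt(2.0 * kT * dt_t)

    total = n_eq + n_collect
    step = 0
    rec = 0
    while step < total:
        block = min(_NOISE_CHUNK, total - step)
        noise_x = [rng.standard_normal((block, R)) * sig_x for _ in range(n_sites)]
        noise_t = [
            rng.standard_normal((block, R, len(names))) * sig_t
            for names in system.sites
        ]
        for i in range(block):
            idx = step + i
            record = idx >= n_eq and (idx - n_eq) % stride == 0
            for s in range(n_sites):
                lam = _softmax(theta[s])
                dx = x[s][:, None] - x0s[s]
                u = offs[s] + 0.5 * ks[s] * dx * dx  # (R, n_s)
                a = u - biases[s]
                fx = np.sum(lam * ks[s] * dx, axis=1)
                mean_a = np.sum(lam * a, axis=1, keepdims=True)
                gtheta = lam * (a - mean_a)
                x[s] = x[s] - dt * fx + noise_x[s][i]
                theta[s] = _reflect(theta[s] - dt_t * gtheta + noise_t[s][i], theta_max)
                if record:
                    frames[s][rec] = _softmax(theta[s])
            if record:
                rec += 1
        step += block

    trajs = []
    for r in range(R):
        trajs.append(
            LambdaTrajectory(
                site_names=system.sites,
                lambdas=tuple(frames[s][:, r, :] for s in range(n_sites)),
                biases=tuple(biases),
                temperature=system.temperature,
                seed=seed,
                dt=dt,
                stride=stride,
            )
        )
    return trajs[0] if n_replicas == 1 else trajs
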