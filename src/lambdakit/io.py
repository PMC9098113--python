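"""File formats and run configuration.

Everything is plain text: λ trajectories and window samples as
tab-separated tables with a ``#``-prefixed provenance header (seed,
temperature, units, protocol), bias sets and results tables likewise,
molecular graphs and perturbation networks as JSON, run configuration as
YAML. Writers and readers round-trip exactly (floats via repr).
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alf import AlfSchedule, BiasSet
from .constants import DEFAULT_TEMPERATURE
from .engine import LambdaTrajectory, WindowSamples
from .toy_systems import (
    FixtureSpec,
    SoftcoreParams,
    ToyPotential,
    ToySystem,
    generate_fixture,
)

__all__ = [
    "RunConfig",
    "write_trajectory",
    "read_trajectory",
    "write_window_samples",
    "read_window_samples",
    "write_bias_set",
    "read_bias_set",
    "write_table",
    "load_config",
    "system_from_config",
]


def _header(kind: str, meta: dict) -> str:
    lines = [f"# lambdakit {kind} v{__version__}"]
    for k, v in meta.items():
        lines.append(f"# {k}: {json.dumps(v)}")
    return "\n".join(lines) + "\n"


def _read_meta(path: Path) -> tuple:
    meta = {}
    body_start = 0
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        if ":" in line:
            key, _, val = line[1:].partition(":")
            try:
                meta[key.strip()] = json.loads(val.strip())
            except json.JSONDecodeError:
                meta[key.strip()] = val.strip()
    return meta, "".join(lines[body_start:])


# ---------------------------------------------------------------------------
# trajectories


def write_trajectory(traj: LambdaTrajectory, path) -> None:
    path = Path(path)
    meta = {
        "units": "dimensionless lambda; biases kcal/mol",
        "temperature_K": traj.temperature,
        "seed": traj.seed,
        "dt": traj.dt,
        "stride": traj.stride,
        "site_names": [list(s) for s in traj.site_names],
        "biases": [list(map(float, b)) for b in traj.biases],
    }
    cols = {}
    for s, names in enumerate(traj.site_names):
        for i, name in enumerate(names):
            cols[f"s{s}_{name}"] = traj.lambdas[s][:, i]
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(_header("lambda-trajectory", meta))
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_trajectory(path) -> LambdaTrajectory:
    meta, body = _read_meta(Path(path))
    df = pd.read_csv(_io.StringIO(body), sep="\t", float_precision="round_trip")
    site_names = tuple(tuple(s) for s in meta["site_names"])
    lambdas = tuple(
        df[[f"s{s}_{n}" for n in names]].to_numpy()
        for s, names in enumerate(site_names)
    )
    return LambdaTrajectory(
        site_names=site_names,
        lambdas=lambdas,
        biases=tuple(np.asarray(b) for b in meta["biases"]),
        temperature=meta["temperature_K"],
        seed=meta["seed"],
        dt=meta["dt"],
        stride=meta.get("stride", 1),
    )


# ---------------------------------------------------------------------------
# window samples


def write_window_samples(samples: WindowSamples, path) -> None:
    path = Path(path)
    meta = {
        "units": "delta_u kcal/mol",
        "temperature_K": samples.temperature,
        "seed": samples.seed,
        "n_eq": samples.n_eq,
        "n_collect": samples.n_collect,
        "lambdas": [float(l) for l in samples.lambdas],
        **{k: (list(v) if isinstance(v, tuple) else v) for k, v in samples.meta.items()},
    }
    rows = []
    for w, (f, r) in enumerate(zip(samples.forward, samples.reverse)):
        for v in f:
            rows.append((w, "forward", v))
        for v in r:
            rows.append((w, "reverse", v))
    df = pd.DataFrame(rows, columns=["pair", "direction", "delta_u"])
    with open(path, "w") as fh:
        fh.write(_header("window-samples", meta))
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_window_samples(path) -> WindowSamples:
    meta, body = _read_meta(Path(path))
    df = pd.read_csv(_io.StringIO(body), sep="\t", float_precision="round_trip")
    lambdas = np.asarray(meta["lambdas"], dtype=float)
    forward, reverse = [], []
    for w in range(len(lambdas) - 1):
        sel = df[df["pair"] == w]
        forward.append(sel[sel["direction"] == "forward"]["delta_u"].to_numpy())
        reverse.append(sel[sel["direction"] == "reverse"]["delta_u"].to_numpy())
    return WindowSamples(
        lambdas=lambdas,
        forward=forward,
        reverse=reverse,
        n_eq=meta["n_eq"],
        n_collect=meta["n_collect"],
        temperature=meta["temperature_K"],
        seed=meta["seed"],
    )


# ---------------------------------------------------------------------------
# bias sets


def write_bias_set(bias_set: BiasSet, path) -> None:
    path = Path(path)
    meta = {
        "units": "kcal/mol",
        "site_names": [list(s) for s in bias_set.site_names],
        "flatness_trace": [float(f) for f in bias_set.flatness_trace],
    }
    rows = []
    for it, vecs in enumerate(bias_set.trace):
        for s, vec in enumerate(vecs):
            for name, b in zip(bias_set.site_names[s], vec):
                rows.append((it, s, name, b))
    for s, vec in enumerate(bias_set.biases):
        for name, b in zip(bias_set.site_names[s], vec):
            rows.append(("final", s, name, b))
    df = pd.DataFrame(rows, columns=["iteration", "site", "substituent", "bias"])
    with open(path, "w") as fh:
        fh.write(_header("bias-set", meta))
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_bias_set(path) -> BiasSet:
    meta, body = _read_meta(Path(path))
    df = pd.read_csv(_io.StringIO(body), sep="\t", float_precision="round_trip")
    site_names = tuple(tuple(s) for s in meta["site_names"])
    final = df[df["iteration"] == "final"]
    biases = []
    for s, names in enumerate(site_names):
        sel = final[final["site"] == s].set_index("substituent")["bias"]
        biases.append(np.array([sel[n] for n in names]))
    bs = BiasSet(site_names=site_names, biases=tuple(biases))
    bs.flatness_trace = list(meta.get("flatness_trace", []))
    iters = sorted(
        int(i) for i in df["iteration"].unique() if str(i) != "final"
    )
    for it in iters:
        sub = df[df["iteration"].astype(str) == str(it)]
        vecs = []
        for s, names in enumerate(site_names):
            sel = sub[sub["site"] == s].set_index("substituent")["bias"]
            vecs.append(np.array([sel[n] for n in names]))
        bs.trace.append(tuple(vecs))
    return bs


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Results table as TSV with a provenance header."""
    with open(Path(path), "w") as fh:
        fh.write(_header("table", meta or {}))
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Validated run configuration shared by the CLI subcommands."""

    temperature: float = DEFAULT_TEMPERATURE
    seed: int = 0
    fixture: dict | None = None
    system: dict | None = None
    msld: dict = field(default_factory=dict)
    alf: dict = field(default_factory=dict)
    fep: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("config: temperature must be positive")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("config: seed must be an integer")
        if self.fixture is None and self.system is None:
            raise ValueError("config: provide either 'fixture' or 'system'")
        cutoff = self.msld.get("cutoff", 0.99)
        if not 0.5 < cutoff <= 1.0:
            raise ValueError(f"config: msld.cutoff must lie in (0.5, 1], got {cutoff}")


def load_config(path) -> RunConfig:
    with open(Path(path)) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {"temperature", "seed", "fixture", "system", "msld", "alf", "fep"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"config: unknown keys {sorted(unknown)}")
    return RunConfig(**raw)


def system_from_config(cfg: RunConfig, seed: int | None = None) -> ToySystem:
    """Build the ToySystem from either the fixture spec or an explicit
    per-site potential table."""
    seed = cfg.seed if seed is None else seed
    if cfg.fixture is not None:
        fx = dict(cfg.fixture)
        for key in ("ddg_bind", "dg_solution"):
            if key in fx and fx[key] is not None:
                fx[key] = tuple(tuple(float(v) for v in site) for site in fx[key])
        spec = FixtureSpec(temperature=cfg.temperature, **fx)
        system, _ = generate_fixture(spec, seed)
        return system
    sites = []
    pots = {}
    for s, site in enumerate(cfg.system["sites"]):
        names = tuple(site["names"])
        sites.append(names)
        for phase in ("solution", "complex"):
            for name, p in zip(names, site["potentials"][phase]):
                pots[(phase, s, name)] = ToyPotential(**p)
    sc = SoftcoreParams(**cfg.system.get("softcore", {}))
    return ToySystem(
        sites=tuple(sites),
        potentials=pots,
        temperature=cfg.temperature,
        softcore=sc,
    )


def alf_schedule_from_config(cfg: RunConfig) -> AlfSchedule:
    return AlfSchedule(**cfg.alf) if cfg.alf else AlfSchedule()
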