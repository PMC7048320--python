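"""Sweep orchestration: named presets, grid execution, and reporting.

A sweep is described by a declarative mapping (YAML-friendly): a ``kind``
(``snr``, ``energy``, ``rf``, or ``rd``) plus parameter grids.  Each grid
point receives a child seed spawned deterministically from the master seed,
so re-running a sweep with the same configuration is byte-identical.
"""

from __future__ import annotations

import json
from copy import deepcopy
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analytics import (
    DEFAULT_EPSILON,
    allocate_energy,
    mutual_information,
    optimal_order,
    rate_distortion_bound,
    transition_energy,
    ube_error,
)
from .channel import ChannelConfig, simulate
from .codes import CodeSpec, StimulusSpace
from .errors import InvalidConfigurationError
from .rf import rf_sweep

#: Named presets mirroring commonly used study settings (reduced trial
#: counts so each runs in minutes on one CPU).
PRESETS: dict[str, dict] = {
    "fig2a": {
        "kind": "snr",
        "K": 3,
        "n": 5,
        "orders": [1, 2, 3],
        "snr_grid": [1, 2, 3, 5, 7, 9, 12, 15, 20],
        "n_trials": 2000,
        "noise": "gaussian",
        "energy_variant": "variance",
    },
    "fig2c-right": {
        "kind": "energy",
        "K": 3,
        "n": 5,
        "energy_grid": list(np.linspace(20, 400, 96)),
        "epsilon": DEFAULT_EPSILON,
    },
    "fig3": {
        "kind": "rf",
        "K": 3,
        "n": 10,
        "orders": [1, 2, 3],
        "rf_widths": [1, 2],
        "total_energy": 3000.0,
        "epsilon": DEFAULT_EPSILON,
        "n_trials": 2000,
    },
    "s4": {
        "kind": "rd",
        "K": 3,
        "n": 5,
        "orders": [1, 2, 3],
        "snr_grid": [1, 2, 3, 5, 7, 9],
        "n_trials": 2000,
    },
}

_REQUIRED = {
    "snr": ("K", "n", "orders", "snr_grid", "n_trials"),
    "energy": ("K", "n", "energy_grid"),
    "rf": ("K", "n", "orders", "rf_widths", "total_energy", "n_trials"),
    "rd": ("K", "n", "orders", "snr_grid", "n_trials"),
}


def resolve_config(config: dict | None = None, preset: str | None = None) -> dict:
    """Merge a preset with explicit overrides and validate required fields."""
    merged: dict = {}
    if preset is not None:
        if preset not in PRESETS:
            raise InvalidConfigurationError(
                f"unknown preset {preset!r}; available: {sorted(PRESETS)}"
            )
        merged.update(deepcopy(PRESETS[preset]))
    if config:
        merged.update(config)
    kind = merged.get("kind")
    if kind not in _REQUIRED:
        raise InvalidConfigurationError(
            f"config field 'kind' must be one of {sorted(_REQUIRED)}, got {kind!r}"
        )
    for key in _REQUIRED[kind]:
        if key not in merged:
            raise InvalidConfigurationError(f"missing config field '{key}' ({kind})")
    merged.setdefault("seed", 0)
    merged.setdefault("epsilon", DEFAULT_EPSILON)
    merged.setdefault("energy_variant", "variance")
    merged.setdefault("noise", "gaussian")
    return merged


def run_sweep(config: dict | None = None, preset: str | None = None):
    """Execute a sweep; returns ``(DataFrame, manifest)``.

    The manifest records the resolved configuration, the package version,
    and the master seed — a sweep is regenerable from its manifest alone.
    """
    cfg = resolve_config(config, preset)
    kind = cfg["kind"]
    if kind == "snr":
        df = _snr_sweep(cfg)
    elif kind == "energy":
        df = _energy_sweep(cfg)
    elif kind == "rf":
        df, _ = rf_sweep(
            StimulusSpace(cfg["K"], cfg["n"]),
            cfg["orders"],
            cfg["rf_widths"],
            cfg["total_energy"],
            cfg["epsilon"],
            cfg["n_trials"],
            seed=cfg["seed"],
            energy_variant=cfg["energy_variant"],
        )
    else:
        df = _rd_sweep(cfg)
    manifest = {
        "config": {k: _jsonable(v) for k, v in cfg.items()},
        "preset": preset,
        "version": __version__,
    }
    return df, manifest


def _jsonable(v):
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, (np.integer, np.floating)):
        return v.item()
    return v


def _child_rngs(seed: int, count: int) -> list[np.random.Generator]:
    return [np.random.default_rng(c) for c in np.random.SeedSequence(seed).spawn(count)]


def _snr_sweep(cfg: dict) -> pd.DataFrame:
    space = StimulusSpace(cfg["K"], cfg["n"])
    grid = [(O, s) for O in cfg["orders"] for s in cfg["snr_grid"]]
    rngs = _child_rngs(cfg["seed"], len(grid))
    rows = []
    for i, (O, snr) in enumerate(grid):
        spec = CodeSpec(O, energy_variant=cfg["energy_variant"])
        res = simulate(
            space,
            spec,
            ChannelConfig(noise=cfg["noise"]),
            cfg["n_trials"],
            seed=cfg["seed"],
            snr=snr,
            rng=rngs[i],
        )
        rows.append(
            {
                "K": cfg["K"],
                "n": cfg["n"],
                "order": O,
                "snr": snr,
                "n_trials": cfg["n_trials"],
                "seed_index": i,
                "pe": res.pe,
                "pe_se": res.pe_se,
                "mse": res.mse,
                "ube_full": ube_error(
                    cfg["K"], cfg["n"], O, snr, "full_sum", cfg["energy_variant"]
                ),
                "ube_nearest": ube_error(
                    cfg["K"], cfg["n"], O, snr, "nearest_only", cfg["energy_variant"]
                ),
            }
        )
    return pd.DataFrame(rows)


def _energy_sweep(cfg: dict) -> pd.DataFrame:
    """Analytic optimal-order map over a total-energy grid."""
    K, n = cfg["K"], cfg["n"]
    rows = []
    transitions = {O: transition_energy(K, n, O) for O in range(1, K)}
    for E in cfg["energy_grid"]:
        best = optimal_order(K, n, total_energy=E, epsilon=cfg["epsilon"])
        row = {
            "K": K,
            "n": n,
            "E": E,
            "epsilon": cfg["epsilon"],
            "best_order": best.order,
            "best_delta": best.delta,
            "feasible": best.feasible,
        }
        for O in range(1, K + 1):
            b = allocate_energy(E, cfg["epsilon"], K, n, O)
            row[f"delta_sq_O{O}"] = b.delta_sq if b.feasible else np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["transition_energies"] = transitions
    return df


def _rd_sweep(cfg: dict) -> pd.DataFrame:
    """Simulated (mutual information, PE) points with the rate-distortion
    bound evaluated at each point's PE."""
    space = StimulusSpace(cfg["K"], cfg["n"])
    M = space.n_stimuli
    grid = [(O, s) for O in cfg["orders"] for s in cfg["snr_grid"]]
    rngs = _child_rngs(cfg["seed"], len(grid))
    rows = []
    for i, (O, snr) in enumerate(grid):
        spec = CodeSpec(O, energy_variant=cfg["energy_variant"])
        res = simulate(
            space,
            spec,
            ChannelConfig(noise=cfg["noise"]),
            cfg["n_trials"],
            seed=cfg["seed"],
            snr=snr,
            rng=rngs[i],
        )
        mi = mutual_information(res.confusion)
        pe_capped = min(res.pe, 1.0 - 1.0 / M)
        rows.append(
            {
                "K": cfg["K"],
                "n": cfg["n"],
                "order": O,
                "snr": snr,
                "seed_index": i,
                "pe": res.pe,
                "mutual_information": mi,
                "rd_bound_rate": rate_distortion_bound(M, pe_capped),
                "rd_gap": mi - rate_distortion_bound(M, pe_capped),
            }
        )
    return pd.DataFrame(rows)


def write_results(df: pd.DataFrame, manifest: dict, outdir) -> tuple[Path, Path]:
    """Write tidy CSV plus a JSON manifest; returns the two paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / "results.csv"
    manifest_path = outdir / "manifest.json"
    df.to_csv(csv_path, index=False)
    manifest = dict(manifest)
    if "transition_energies" in df.attrs:
        manifest["transition_energies"] = {
            str(k): v for k, v in df.attrs["transition_energies"].items()
        }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return csv_path, manifest_path


def report(df: pd.DataFrame) -> str:
    """Human-readable summary of a sweep results table."""
    if df is None or len(df) == 0:
        return "empty sweep: no results\n"
    lines = []
    if {"order", "snr", "pe"}.issubset(df.columns):
        lines.append("PE by order and SNR:")
        pivot = df.pivot_table(index="snr", columns="order", values="pe")
        lines.append(pivot.to_string(float_format=lambda x: f"{x:.4g}"))
        if "ube_full" in df.columns:
            gap = (df["ube_full"] - df["pe"]).abs()
            lines.append(f"max |UBE - PE| over grid: {gap.max():.4g}")
    if {"order", "rf_width", "pe", "mse"}.issubset(df.columns):
        lines.append("PE / MSE by order and RF width:")
        sub = df[df.get("feasible", True) == True]  # noqa: E712
        lines.append(
            sub[["order", "rf_width", "pe", "mse"]].to_string(index=False)
        )
    if "best_order" in df.columns:
        lines.append("optimal order by total energy (first E per order):")
        firsts = df.dropna(subset=["best_order"]).groupby("best_order")["E"].min()
        lines.append(firsts.to_string())
    if "mutual_information" in df.columns:
        lines.append("rate-distortion feasibility (min gap per order):")
        lines.append(df.groupby("order")["rd_gap"].min().to_string())
    if not lines:
        missing = {"order", "pe"} - set(df.columns)
        raise InvalidConfigurationError(
            f"results table missing expected columns: {sorted(missing)}"
        )
    return "\n".join(lines) + "\n"
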