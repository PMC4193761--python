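"""Experiment orchestration: build -> distort -> compensate -> simulate ->
analyze pipelines, parameter sweeps, and the standard protocols
(synfire loss scans, pattern completion, attentional blink)."""

from __future__ import annotations

import itertools
import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import criteria
from .compensation import compensate_loss_by_weights
from .distortions import DistortionConfig, apply_distortions
from .models import build_ai, build_l23, build_synfire
from .network import NetworkSpec
from .simulator import simulate
from .spikes import SpikeData

_BUILDERS: Dict[str, Callable[..., NetworkSpec]] = {
    "synfire": build_synfire,
    "ai": build_ai,
    "l23": build_l23,
}


@dataclass
class ExperimentConfig:
    """Declarative experiment description.

    ``sweep`` maps dotted config paths (e.g. ``"model.params.g_exc"``) to
    value lists; the run expands their Cartesian product.  Each grid cell
    is repeated ``repetitions`` times with per-cell derived seeds, so any
    cell can be re-run bit-identically in isolation.
    """

    model: Dict = field(default_factory=lambda: {"name": "synfire"})
    distortion: Optional[Dict] = None
    compensation: Optional[Dict] = None
    sweep: Dict[str, Sequence] = field(default_factory=dict)
    repetitions: int = 1
    seed: int = 0
    duration: float = 1000.0
    dt: float = 0.1
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


@dataclass
class SweepResult:
    cells: List[dict]
    config: Dict
    seed: int

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"config": self.config, "seed": self.seed, "cells": self.cells},
            indent=1, default=_jsonify))

    def table(self):
        import pandas as pd
        rows = []
        for cell in self.cells:
            row = dict(cell["axes"])
            row["repetition"] = cell["repetition"]
            row["error"] = cell.get("error")
            rep = cell.get("report") or {}
            for k, v in rep.items():
                if np.isscalar(v) or v is None:
                    row[k] = v
            rows.append(row)
        return pd.DataFrame(rows)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _set_path(cfg: Dict, path: str, value) -> None:
    keys = path.split(".")
    node = cfg
    for k in keys[:-1]:
        node = node.setdefault(k, {})
    node[keys[-1]] = value


def cell_seed(master: int, cell_index: int, repetition: int) -> int:
    """Deterministic per-cell seed derived from the master seed."""
    return int(np.random.SeedSequence([master, cell_index, repetition])
               .generate_state(1)[0] % (2 ** 31))


def _pipeline(cfg_dict: Dict, seed: int, duration: float, dt: float
              ) -> Tuple[NetworkSpec, SpikeData]:
    model = dict(cfg_dict.get("model", {"name": "synfire"}))
    name = model.pop("name")
    builder = _BUILDERS[name]
    net = builder(**model).instantiate(seed)
    dist = cfg_dict.get("distortion")
    if dist:
        dcfg = DistortionConfig(**{**dist, "seed": seed})
        net, _ = apply_distortions(net, dcfg)
    comp = cfg_dict.get("compensation")
    if comp and comp.get("kind") == "loss_by_weights":
        net, _ = compensate_loss_by_weights(net, comp["p"])
    spikes = simulate(net, duration, dt=dt, seed=seed + 1).spikes
    return net, spikes


def _analyze(name: str, net: NetworkSpec, spikes: SpikeData,
             duration: float) -> dict:
    if name == "ai":
        stats = criteria.ai_statistics(spikes)
        return stats.as_dict()
    if name == "synfire":
        n_groups = net.meta["n_groups"]
        t_c = net.meta["config"]["stim"]["t_center"]
        d = net.meta["config"]["d_intergroup"]
        points = []
        for g in range(n_groups):
            w = (t_c + (g + 1) * d - 10.0, t_c + (g + 1) * d + 12.0)
            pt = criteria.measure_pulse_packet(spikes, f"RS_{g}", w, group_index=g)
            points.append({"group": g, "a": pt.a, "sigma": pt.sigma})
        last = points[-1]
        return {"points": points, "a_last": last["a"],
                "success": bool(last["a"] >= 0.5)}
    if name == "l23":
        patterns = {int(k): _pattern_pyr_ids(net, int(k))
                    for k in net.meta["patterns"]}
        eps = criteria.detect_attractors(spikes, patterns)
        dwells, comp_time = criteria.dwell_and_competition(eps, duration)
        return {"n_episodes": len(eps),
                "mean_dwell": float(dwells.mean()) if dwells.size else None,
                "competition_time": comp_time}
    return {}


def _pattern_pyr_ids(net: NetworkSpec, pattern: int) -> np.ndarray:
    cfg = net.meta["config"]
    n_mc, n_pyr = cfg["n_mc_per_hc"], cfg["n_pyr_per_mc"]
    ids = []
    for hc in range(cfg["n_hc"]):
        base = (hc * n_mc + pattern) * n_pyr
        ids.append(np.arange(base, base + n_pyr))
    return np.concatenate(ids)


def run_experiment(cfg: ExperimentConfig) -> SweepResult:
    """Expand the sweep grid and run every cell x repetition.

    A failing cell records its traceback and the sweep continues; outputs
    of other cells are unaffected (crash isolation)."""
    axes = list(cfg.sweep.items())
    grids = [vals for _, vals in axes] or [[None]]
    cells = []
    base = {"model": dict(cfg.model), "distortion": cfg.distortion,
            "compensation": cfg.compensation}
    for ci, combo in enumerate(itertools.product(*grids)):
        for rep in range(cfg.repetitions):
            cell_cfg = json.loads(json.dumps(base, default=_jsonify))
            axis_values = {}
            if axes:
                for (path, _), val in zip(axes, combo):
                    _set_path(cell_cfg, path, val)
                    axis_values[path] = val
            seed = cell_seed(cfg.seed, ci, rep)
            record = {"axes": axis_values, "repetition": rep, "seed": seed}
            try:
                net, spikes = _pipeline(cell_cfg, seed, cfg.duration, cfg.dt)
                record["report"] = _analyze(cfg.model["name"], net, spikes,
                                            cfg.duration)
            except Exception:
                record["error"] = traceback.format_exc(limit=3)
            cells.append(record)
    result = SweepResult(cells, config=json.loads(json.dumps(
        {"model": cfg.model, "distortion": cfg.distortion,
         "compensation": cfg.compensation, "sweep": {k: list(v) for k, v in cfg.sweep.items()},
         "repetitions": cfg.repetitions, "duration": cfg.duration, "dt": cfg.dt},
        default=_jsonify)), seed=cfg.seed)
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.to_json(out / "sweep_result.json")
        result.table().to_csv(out / "sweep_table.csv", index=False)
    return result


# ---------------------------------------------------------------------------
# synfire loss scan
# ---------------------------------------------------------------------------

def synfire_loss_scan(loss_grid: Sequence[float], compensated: bool = False,
                      repetitions: int = 5, seed: int = 0,
                      duration: float = 250.0, dt: float = 0.1,
                      model_params: Optional[Dict] = None,
                      threshold: float = 0.5) -> dict:
    """Propagation success vs. synapse loss, majority-voted over seeds.

    Loss hits the internal and stimulus projections (external background is
    exempt).  With ``compensated=True`` every surviving weight is scaled by
    1/(1-p) after the loss draw.  Reports per-grid-value vote counts, the
    first loss value that fails the majority vote, and the largest one that
    passes it.
    """
    votes: Dict[float, int] = {}
    for gi, p in enumerate(loss_grid):
        succ = 0
        for rep in range(repetitions):
            s = cell_seed(seed, gi, rep)
            net = build_synfire(params=model_params).instantiate(s)
            if p > 0:
                dcfg = DistortionConfig(loss_p=float(p), exempt_external=True,
                                        seed=s + 1)
                from .distortions import apply_synapse_loss
                net, _ = apply_synapse_loss(net, dcfg)
                if compensated:
                    net, _ = compensate_loss_by_weights(
                        net, {proj.label: float(p) for proj in net.projections
                              if not proj.external})
            spikes = simulate(net, duration, dt=dt, seed=s + 2).spikes
            rep_an = _analyze("synfire", net, spikes, duration)
            succ += int(rep_an["a_last"] >= threshold)
        votes[float(p)] = succ
    majority = repetitions / 2.0
    first_fail = next((p for p in loss_grid if votes[float(p)] <= majority), None)
    last_ok = None
    for p in loss_grid:
        if votes[float(p)] > majority:
            last_ok = float(p)
    return {"votes": votes, "first_failure": first_fail,
            "last_success": last_ok, "repetitions": repetitions,
            "compensated": compensated}


# ---------------------------------------------------------------------------
# pattern completion and attentional blink protocols
# ---------------------------------------------------------------------------

def _default_l23_backend(duration: float, dt: float, stim_rate: float,
                         stim_window: Tuple[float, float]):
    """Returns a simulate_fn(net, stimuli, seed) -> SpikeData where
    ``stimuli`` is a list of (pattern, n_mcs, t_on) tuples realized by
    raising the corresponding L4 source rates inside the window."""

    def fn(net: NetworkSpec, stimuli, seed: int) -> SpikeData:
        cfg = net.meta["config"]
        n_mc, n_l4 = cfg["n_mc_per_hc"], cfg["n_l4_per_mc"]
        work = net.copy()
        l4 = work.population("L4")
        rates = np.zeros(l4.size)
        t_on = min((s[2] for s in stimuli), default=0.0)
        for pattern, n_mcs, _ in stimuli:
            for hc in range(min(n_mcs, cfg["n_hc"])):
                base = (hc * n_mc + pattern) * n_l4
                rates[base:base + n_l4] = stim_rate
        l4.source = {"kind": "poisson", "rates": rates,
                     "start": t_on + stim_window[0],
                     "stop": t_on + stim_window[1]}
        return simulate(work, duration, dt=dt, seed=seed).spikes

    return fn


def pattern_protocols(net: NetworkSpec, mode: str,
                      stim_mc_counts: Sequence[int],
                      delta_t_grid: Sequence[float] = (),
                      trials: int = 25, seed: int = 0,
                      duration: float = 1000.0, dt: float = 0.1,
                      stim_rate: float = 600.0,
                      stim_window: Tuple[float, float] = (100.0, 150.0),
                      simulate_fn: Optional[Callable] = None,
                      detection_kwargs: Optional[Dict] = None) -> dict:
    """Pattern-completion / attentional-blink activation probabilities.

    ``completion``: for each stimulated-MC count, the fraction of trials in
    which the stimulated pattern activates (an attractor episode of that
    pattern after stimulus onset).  ``blink``: a full first stimulus is
    followed after ``delta_t`` by a partial second stimulus; reported is
    the second pattern's activation ratio per (delta_t, count) cell, plus
    the 50% iso-contour (per delta_t, the smallest count reaching 50%).

    ``simulate_fn(net, stimuli, seed) -> SpikeData`` may replace the
    built-in backend (e.g. a scripted mock for testing the protocol logic).
    """
    if mode not in ("completion", "blink"):
        raise ValueError("mode must be 'completion' or 'blink'")
    fn = simulate_fn or _default_l23_backend(duration, dt, stim_rate,
                                             stim_window)
    n_patterns = len(net.meta["patterns"])
    det = detection_kwargs or {}
    rng = np.random.default_rng(seed)

    def activated(spikes: SpikeData, pattern: int, t_after: float) -> bool:
        patterns = {p: _pattern_pyr_ids(net, p) for p in range(n_patterns)}
        eps = criteria.detect_attractors(spikes, patterns, **det)
        return any(e.pattern == pattern and e.t_end > t_after for e in eps)

    if mode == "completion":
        out = {"mode": mode, "counts": list(stim_mc_counts), "ratio": []}
        for ci, m in enumerate(stim_mc_counts):
            hits = 0
            for tr in range(trials):
                pattern = int(rng.integers(n_patterns))
                s = cell_seed(seed, ci, tr)
                spikes = fn(net, [(pattern, int(m), stim_window[0])], s)
                hits += activated(spikes, pattern, stim_window[0])
            out["ratio"].append(hits / trials)
        return out

    out = {"mode": mode, "counts": list(stim_mc_counts),
           "delta_t": list(delta_t_grid), "ratio": {}, "iso50": {}}
    for di, dt_lag in enumerate(delta_t_grid):
        row = []
        for ci, m in enumerate(stim_mc_counts):
            hits = 0
            for tr in range(trials):
                p1, p2 = rng.choice(n_patterns, size=2, replace=False)
                s = cell_seed(seed, 1000 + di * 100 + ci, tr)
                stimuli = [(int(p1), n_patterns, stim_window[0]),
                           (int(p2), int(m), stim_window[0] + dt_lag)]
                spikes = fn(net, stimuli, s)
                hits += activated(spikes, int(p2), stim_window[0] + dt_lag)
            row.append(hits / trials)
        out["ratio"][float(dt_lag)] = row
        iso = next((c for c, r in zip(stim_mc_counts, row) if r >= 0.5), None)
        out["iso50"][float(dt_lag)] = iso
    return out
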