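"""Editable network specification: populations, projections, instantiation.

A :class:`NetworkSpec` is the object that distortions and compensations
transform.  It separates the *rules* (connectivity recipes, delay rules,
synapse templates) from the *instantiated* synapse lists, so that the same
specification re-instantiated with the same seed yields a bit-identical
network — a requirement for fixed-pattern distortion studies and for the
iterative compensation loop.

Global neuron ids enumerate populations in declaration order.  Source
populations (Poisson generators, pulse-packet emitters) occupy ids in the
same space but carry no membrane dynamics.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .params import AdExParams, SynapseParams


class NetworkError(ValueError):
    pass


@dataclass
class Population:
    """A homogeneous group of neurons or spike sources.

    ``params is None`` marks a source population; ``source`` then describes
    the emission process, e.g. ``{"kind": "poisson", "rate": 2000.0}`` or
    ``{"kind": "pulse_packet", "a": 1.0, "sigma": 1.0, "t_center": 50.0}``.
    Positions (mm) are present only for models with distance-dependent
    connectivity or delays.
    """

    name: str
    size: int
    cell_type: str
    params: Optional[AdExParams] = None
    tau_syn_exc: float = 5.0
    e_rev_exc: float = 0.0
    tau_syn_inh: float = 10.0
    e_rev_inh: float = -80.0
    positions: Optional[np.ndarray] = None
    source: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.size < 1:
            raise NetworkError(f"population {self.name}: size must be >= 1")
        if (self.params is None) == (self.source is None):
            raise NetworkError(
                f"population {self.name}: exactly one of params/source required")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
            if self.positions.shape != (self.size, 2):
                raise NetworkError(f"population {self.name}: bad positions shape")

    @property
    def is_source(self) -> bool:
        return self.params is None


@dataclass
class Projection:
    """Connection recipe from one population to another.

    ``rule`` kinds: ``all_to_all``, ``one_to_one``, ``bernoulli`` (p,
    optional ``target_range``), ``fixed_in`` (k distinct sources per
    target), ``distance_gaussian`` (p(d) = p0 exp(-d^2 / 2 sigma^2) on the
    torus; ``p0`` explicit or derived from ``k_target`` expected in-degree),
    ``pairs`` (explicit index arrays), ``pairs_bernoulli`` (candidate index
    arrays thinned with probability p).

    ``delay`` kinds: ``constant`` (d in ms) or ``velocity`` (delay =
    distance / v, floored at ``min``).

    ``external=True`` marks projections that mediate external input; these
    can be exempted from synapse loss.
    """

    source: str
    target: str
    rule: dict
    synapse: SynapseParams
    delay: dict
    label: str = ""
    external: bool = False

    def __post_init__(self) -> None:
        if not self.label:
            self.label = f"{self.source}->{self.target}"
        p = self.rule.get("p")
        if p is not None and not 0.0 <= p <= 1.0:
            raise NetworkError(f"projection {self.label}: p must be in [0, 1]")
        v = self.delay.get("v")
        if v is not None and v <= 0:
            raise NetworkError(f"projection {self.label}: velocity must be > 0")


@dataclass
class ConnectionSet:
    """Instantiated synapses of one projection (global ids, ms, nS)."""

    pre: np.ndarray
    post: np.ndarray
    weight: np.ndarray
    delay: np.ndarray

    def __len__(self) -> int:
        return int(self.pre.size)

    def copy(self) -> "ConnectionSet":
        return ConnectionSet(self.pre.copy(), self.post.copy(),
                             self.weight.copy(), self.delay.copy())


def torus_distance(a: np.ndarray, b: np.ndarray, side: float) -> np.ndarray:
    """Minimum-image (wrap-around) Euclidean distance on a square torus."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))
    d = np.minimum(d, side - d)
    return np.sqrt((d ** 2).sum(axis=-1))


class NetworkSpec:
    """Populations + projections + (optionally) instantiated synapses."""

    def __init__(self, populations: Sequence[Population],
                 projections: Sequence[Projection],
                 meta: Optional[dict] = None) -> None:
        self.populations: List[Population] = list(populations)
        self.projections: List[Projection] = list(projections)
        self.meta: dict = dict(meta or {})
        self.connections: Optional[List[ConnectionSet]] = None
        self.instantiation_seed: Optional[int] = None
        # per-neuron AdEx parameter overrides: field name -> {global_id: value}
        self.overrides: Dict[str, Dict[int, float]] = {}
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise NetworkError("duplicate population names")
        self._index = {p.name: i for i, p in enumerate(self.populations)}
        sizes = np.array([p.size for p in self.populations])
        self._offsets = np.concatenate([[0], np.cumsum(sizes)])
        for proj in self.projections:
            for nm in (proj.source, proj.target):
                if nm not in self._index:
                    raise NetworkError(f"projection {proj.label}: unknown population {nm}")

    # -- id arithmetic ---------------------------------------------------

    @property
    def n_units(self) -> int:
        return int(self._offsets[-1])

    @property
    def n_neurons(self) -> int:
        return sum(p.size for p in self.populations if not p.is_source)

    def population(self, name: str) -> Population:
        return self.populations[self._index[name]]

    def id_range(self, name: str) -> Tuple[int, int]:
        i = self._index[name]
        return int(self._offsets[i]), int(self._offsets[i + 1])

    def global_ids(self, name: str) -> np.ndarray:
        lo, hi = self.id_range(name)
        return np.arange(lo, hi)

    def population_of(self, global_id: int) -> str:
        i = int(np.searchsorted(self._offsets, global_id, side="right")) - 1
        return self.populations[i].name

    def population_map(self) -> Dict[str, Tuple[int, int]]:
        return {p.name: self.id_range(p.name) for p in self.populations}

    def positions_of(self, name: str) -> np.ndarray:
        pos = self.population(name).positions
        if pos is None:
            raise NetworkError(f"population {name} has no positions")
        return pos

    # -- instantiation ---------------------------------------------------

    def instantiate(self, seed: int) -> "NetworkSpec":
        """Materialize the synapse lists; deterministic per seed."""
        master = np.random.SeedSequence(seed)
        children = master.spawn(len(self.projections))
        self.connections = [
            self._instantiate_projection(proj, np.random.default_rng(child))
            for proj, child in zip(self.projections, children)
        ]
        self.instantiation_seed = seed
        return self

    def _instantiate_projection(self, proj: Projection,
                                rng: np.random.Generator) -> ConnectionSet:
        src_lo, src_hi = self.id_range(proj.source)
        tgt_lo, tgt_hi = self.id_range(proj.target)
        n_src, n_tgt = src_hi - src_lo, tgt_hi - tgt_lo
        kind = proj.rule["kind"]

        if kind == "all_to_all":
            pre, post = np.meshgrid(np.arange(n_src), np.arange(n_tgt), indexing="ij")
            pre, post = pre.ravel(), post.ravel()
            if proj.source == proj.target and not proj.rule.get("allow_self", False):
                keep = pre != post
                pre, post = pre[keep], post[keep]
        elif kind == "one_to_one":
            if n_src != n_tgt:
                raise NetworkError(f"{proj.label}: one_to_one needs equal sizes")
            pre = post = np.arange(n_src)
        elif kind == "bernoulli":
            p = proj.rule["p"]
            t0, t1 = proj.rule.get("target_range", (0, n_tgt))
            mask = rng.random((n_src, t1 - t0)) < p
            pre, post = np.nonzero(mask)
            post = post + t0
            if proj.source == proj.target and not proj.rule.get("allow_self", False):
                keep = pre != post
                pre, post = pre[keep], post[keep]
        elif kind == "fixed_in":
            k = int(proj.rule["k"])
            pool = n_src - (1 if proj.source == proj.target else 0)
            if k > pool:
                raise NetworkError(f"{proj.label}: in-degree {k} exceeds source size")
            pres = []
            for tgt in range(n_tgt):
                if proj.source == proj.target:
                    # sample from the pool without the target, then re-index
                    choices = rng.choice(n_src - 1, size=k, replace=False)
                    choices[choices >= tgt] += 1
                else:
                    choices = rng.choice(n_src, size=k, replace=False)
                pres.append(choices)
            pre = np.concatenate(pres)
            post = np.repeat(np.arange(n_tgt), k)
        elif kind == "distance_gaussian":
            pre, post = self._distance_gaussian(proj, rng)
        elif kind == "distance_fixed_in":
            pre, post = self._distance_fixed_in(proj, rng)
        elif kind == "pairs":
            pre = np.asarray(proj.rule["pre"], dtype=np.int64)
            post = np.asarray(proj.rule["post"], dtype=np.int64)
        elif kind == "pairs_bernoulli":
            cand_pre = np.asarray(proj.rule["pre"], dtype=np.int64)
            cand_post = np.asarray(proj.rule["post"], dtype=np.int64)
            keep = rng.random(cand_pre.size) < proj.rule["p"]
            pre, post = cand_pre[keep], cand_post[keep]
        else:
            raise NetworkError(f"unknown connection rule {kind!r}")

        pre = np.asarray(pre, dtype=np.int64) + src_lo
        post = np.asarray(post, dtype=np.int64) + tgt_lo
        weight = np.full(pre.size, proj.synapse.weight, dtype=float)
        delay = self._delays(proj, pre, post)
        return ConnectionSet(pre, post, weight, delay)

    def _distance_gaussian(self, proj: Projection, rng: np.random.Generator
                           ) -> Tuple[np.ndarray, np.ndarray]:
        sigma = proj.rule["sigma"]
        side = self.meta.get("torus_side")
        src_pos = self.positions_of(proj.source)
        tgt_pos = self.positions_of(proj.target)
        if side is None:
            raise NetworkError("distance_gaussian requires meta['torus_side']")
        if sigma >= side / 2:
            import warnings
            warnings.warn(f"{proj.label}: sigma_space >= torus_side/2, "
                          "profile is effectively uniform")
        if "p0" in proj.rule:
            p0 = proj.rule["p0"]
        else:
            # Expected in-degree K = rho * p0 * 2 pi sigma^2 on the (infinite)
            # plane; with wrap-around the integral over the torus is computed
            # numerically from the actual source density.
            k_target = proj.rule["k_target"]
            rho = len(src_pos) / side ** 2
            p0 = k_target / (rho * 2.0 * np.pi * sigma ** 2)
            if p0 > 1.0:
                raise NetworkError(f"{proj.label}: k_target {k_target} infeasible (p0={p0:.2f})")
        pres, posts = [], []
        # chunk over targets to bound memory: (n_src x chunk) probability blocks
        chunk = max(1, int(2e6 / max(len(src_pos), 1)))
        for t0 in range(0, len(tgt_pos), chunk):
            t1 = min(t0 + chunk, len(tgt_pos))
            d = torus_distance(src_pos[:, None, :], tgt_pos[None, t0:t1, :], side)
            p = p0 * np.exp(-d ** 2 / (2.0 * sigma ** 2))
            mask = rng.random(p.shape) < p
            pr, po = np.nonzero(mask)
            pres.append(pr)
            posts.append(po + t0)
        pre = np.concatenate(pres)
        post = np.concatenate(posts)
        if proj.source == proj.target and not proj.rule.get("allow_self", False):
            keep = pre != post
            pre, post = pre[keep], post[keep]
        return pre, post

    def _distance_fixed_in(self, proj: Projection, rng: np.random.Generator
                           ) -> Tuple[np.ndarray, np.ndarray]:
        """Exactly k presynaptic partners per target, sampled without
        replacement with probability proportional to the Gaussian distance
        kernel (weighted sampling via Gumbel top-k).  Gives every neuron an
        identical afferent count while preserving the spatial footprint."""
        sigma = proj.rule["sigma"]
        k = int(proj.rule["k"])
        side = self.meta.get("torus_side")
        if side is None:
            raise NetworkError("distance_fixed_in requires meta['torus_side']")
        src_pos = self.positions_of(proj.source)
        tgt_pos = self.positions_of(proj.target)
        n_src = len(src_pos)
        self_proj = proj.source == proj.target
        pool = n_src - (1 if self_proj else 0)
        if k > pool:
            raise NetworkError(f"{proj.label}: in-degree {k} exceeds source pool")
        pres = np.empty((len(tgt_pos), k), dtype=np.int64)
        chunk = max(1, int(2e6 / max(n_src, 1)))
        for t0 in range(0, len(tgt_pos), chunk):
            t1 = min(t0 + chunk, len(tgt_pos))
            d = torus_distance(src_pos[None, :, :], tgt_pos[t0:t1, None, :], side)
            logw = -d ** 2 / (2.0 * sigma ** 2)
            if self_proj:
                rows = np.arange(t0, t1)
                inside = rows < n_src
                logw[np.flatnonzero(inside), rows[inside]] = -np.inf
            keys = logw + rng.gumbel(size=logw.shape)
            part = np.argpartition(keys, n_src - k, axis=1)[:, n_src - k:]
            pres[t0:t1] = part
        post = np.repeat(np.arange(len(tgt_pos)), k)
        return pres.ravel(), post

    def _delays(self, proj: Projection, pre: np.ndarray, post: np.ndarray
                ) -> np.ndarray:
        kind = proj.delay["kind"]
        if kind == "constant":
            d = float(proj.delay["d"])
            if d <= 0:
                raise NetworkError(f"{proj.label}: delay must be > 0")
            return np.full(pre.size, d, dtype=float)
        if kind == "velocity":
            v = float(proj.delay["v"])  # mm / ms
            d_min = float(proj.delay.get("min", 0.1))
            src_pos = self.positions_of(proj.source)
            tgt_pos = self.positions_of(proj.target)
            src_lo, _ = self.id_range(proj.source)
            tgt_lo, _ = self.id_range(proj.target)
            side = self.meta.get("torus_side")
            if side is not None:
                dist = torus_distance(src_pos[pre - src_lo], tgt_pos[post - tgt_lo], side)
            else:
                diff = src_pos[pre - src_lo] - tgt_pos[post - tgt_lo]
                dist = np.sqrt((diff ** 2).sum(axis=-1))
            return np.maximum(dist / v, d_min)
        raise NetworkError(f"unknown delay rule {kind!r}")

    # -- bookkeeping -----------------------------------------------------

    def require_instantiated(self) -> List[ConnectionSet]:
        if self.connections is None:
            raise NetworkError("network not instantiated; call instantiate(seed)")
        return self.connections

    def copy(self) -> "NetworkSpec":
        new = NetworkSpec([copy.deepcopy(p) for p in self.populations],
                          [copy.deepcopy(p) for p in self.projections],
                          copy.deepcopy(self.meta))
        if self.connections is not None:
            new.connections = [c.copy() for c in self.connections]
        new.instantiation_seed = self.instantiation_seed
        new.overrides = {k: dict(v) for k, v in self.overrides.items()}
        return new

    def total_synapses(self) -> int:
        return sum(len(c) for c in self.require_instantiated())

    def mean_fan_in(self, target: str, cell_weighted: bool = False) -> float:
        """Average number of synapses per neuron of ``target`` population
        (or average summed weight if ``cell_weighted``)."""
        lo, hi = self.id_range(target)
        total = 0.0
        for conn in self.require_instantiated():
            sel = (conn.post >= lo) & (conn.post < hi)
            total += conn.weight[sel].sum() if cell_weighted else np.count_nonzero(sel)
        return total / (hi - lo)

    def set_override(self, param: str, ids: np.ndarray, values: np.ndarray) -> None:
        d = self.overrides.setdefault(param, {})
        for i, v in zip(np.asarray(ids).tolist(), np.asarray(values).tolist()):
            d[int(i)] = float(v)

    # -- serialization ---------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        def syn(s: SynapseParams) -> dict:
            d = {"weight": s.weight, "e_rev": s.e_rev, "tau_syn": s.tau_syn}
            if s.stp is not None:
                d["stp"] = {"u": s.stp.u, "tau_rec": s.stp.tau_rec,
                            "tau_facil": s.stp.tau_facil, "mode": s.stp.mode}
            return d

        doc = {
            "meta": self.meta,
            "seed": self.instantiation_seed,
            "populations": [
                {"name": p.name, "size": p.size, "cell_type": p.cell_type,
                 "params": None if p.params is None else vars(p.params).copy(),
                 "source": p.source,
                 "channels": {"tau_syn_exc": p.tau_syn_exc, "e_rev_exc": p.e_rev_exc,
                              "tau_syn_inh": p.tau_syn_inh, "e_rev_inh": p.e_rev_inh},
                 "has_positions": p.positions is not None}
                for p in self.populations
            ],
            "projections": [
                {"source": pr.source, "target": pr.target, "label": pr.label,
                 "external": pr.external, "synapse": syn(pr.synapse),
                 "rule": {k: v for k, v in pr.rule.items()
                          if not isinstance(v, np.ndarray)},
                 "delay": pr.delay}
                for pr in self.projections
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    def connections_to_csv(self, path: str | Path) -> None:
        """Expanded synapse table: source, target, weight_nS, delay_ms,
        E_rev, tau_syn (one row per instantiated synapse)."""
        rows = []
        for proj, conn in zip(self.projections, self.require_instantiated()):
            e_rev = proj.synapse.e_rev
            tau = proj.synapse.tau_syn
            for i in range(len(conn)):
                rows.append((int(conn.pre[i]), int(conn.post[i]),
                             conn.weight[i], conn.delay[i], e_rev, tau))
        import pandas as pd
        pd.DataFrame(rows, columns=["source", "target", "weight_nS",
                                    "delay_ms", "E_rev", "tau_syn"]
                     ).to_csv(path, index=False)
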