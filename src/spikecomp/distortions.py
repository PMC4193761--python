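"""Hardware-inspired network distortions: synapse loss, multiplicative
weight noise, and non-configurable (uniform) delays.

All three transforms are seedable, composable in any order, and return a
modified copy of the network together with a report of the realized
distortion statistics.  Weight noise can be *fixed-pattern* (frozen with
the network; required by the iterative compensation) or redrawn per call
to emulate trial-to-trial variability — the distinction is simply whether
the caller reuses the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple, Union

import numpy as np
from scipy.stats import norm

from .network import NetworkSpec


@dataclass(frozen=True)
class DistortionConfig:
    """Configuration of the three distortion mechanisms.

    ``loss_p`` is either a single probability applied to every non-exempt
    projection or a mapping from projection label to probability (to replay
    heterogeneous, mapping-induced loss scenarios).  ``noise_ratio`` is the
    standard-deviation-to-mean ratio of the weight noise (0-0.5 typical);
    ``uniform_delay`` replaces every delay when set.  ``exempt_external``
    keeps synapses that mediate external input untouched by loss.
    """

    loss_p: Union[float, Mapping[str, float]] = 0.0
    exempt_external: bool = True
    noise_ratio: float = 0.0
    uniform_delay: Optional[float] = None
    recenter_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (self.loss_p.values() if isinstance(self.loss_p, Mapping)
                 else [self.loss_p])
        for p in probs:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"loss probability {p} outside [0, 1]")
        if self.noise_ratio < 0:
            raise ValueError("noise_ratio must be non-negative")
        if self.uniform_delay is not None and self.uniform_delay <= 0:
            raise ValueError("uniform_delay must be positive")


def _loss_p_for(cfg: DistortionConfig, label: str) -> float:
    if isinstance(cfg.loss_p, Mapping):
        return float(cfg.loss_p.get(label, 0.0))
    return float(cfg.loss_p)


def apply_synapse_loss(net: NetworkSpec, cfg: DistortionConfig
                       ) -> Tuple[NetworkSpec, Dict[str, dict]]:
    """Delete each non-exempt synapse independently with its projection's
    loss probability.  Returns the distorted copy and a per-projection
    report of realized loss fractions."""
    conns = net.require_instantiated()
    out = net.copy()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x10]))
    report: Dict[str, dict] = {}
    for proj, conn in zip(out.projections, out.connections):
        n_before = len(conn)
        p = _loss_p_for(cfg, proj.label)
        if (cfg.exempt_external and proj.external) or p == 0.0 or n_before == 0:
            report[proj.label] = {"p": 0.0 if proj.external and cfg.exempt_external
                                  else p, "n_before": n_before,
                                  "n_after": n_before, "realized": 0.0}
            continue
        keep = rng.random(n_before) >= p
        conn.pre, conn.post = conn.pre[keep], conn.post[keep]
        conn.weight, conn.delay = conn.weight[keep], conn.delay[keep]
        report[proj.label] = {
            "p": p, "n_before": n_before, "n_after": len(conn),
            "realized": 1.0 - len(conn) / n_before,
        }
    out.meta.setdefault("distortions", []).append(
        {"kind": "synapse_loss", "report": report})
    return out, report


def apply_weight_noise(net: NetworkSpec, cfg: DistortionConfig
                       ) -> Tuple[NetworkSpec, Dict[str, dict]]:
    """Draw every weight from N(w, (r w)^2), clipped at zero.

    Clipping keeps receptor identity fixed (an excitatory synapse can never
    flip sign) and inflates the mean by the closed-form factor returned by
    :func:`expected_clipped_mean_shift`; ``recenter_noise`` divides the
    samples by that factor (off by default, matching the observation that
    the shift is negligible for the studied noise levels)."""
    net.require_instantiated()
    out = net.copy()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x20]))
    r = cfg.noise_ratio
    report: Dict[str, dict] = {}
    for proj, conn in zip(out.projections, out.connections):
        if len(conn) == 0 or r == 0.0:
            report[proj.label] = {"mean_shift": 0.0, "realized_cv": 0.0}
            continue
        w0 = conn.weight
        w = np.maximum(0.0, rng.normal(w0, r * w0))
        if cfg.recenter_noise:
            w = w / (1.0 + expected_clipped_mean_shift(r))
        conn.weight = w
        base = np.mean(w0)
        report[proj.label] = {
            "mean_shift": float(np.mean(w) / base - 1.0) if base > 0 else 0.0,
            "realized_cv": float(np.std(w) / np.mean(w)) if np.mean(w) > 0 else 0.0,
        }
    out.meta.setdefault("distortions", []).append(
        {"kind": "weight_noise", "ratio": r, "report": report})
    return out, report


def apply_uniform_delays(net: NetworkSpec, d: float) -> NetworkSpec:
    """Set every synaptic delay to the constant ``d`` (ms), emulating the
    non-configurable transmission delay of the substrate.  The original
    delay statistics are retained in the metadata for reporting."""
    if d <= 0:
        raise ValueError("uniform delay must be positive")
    conns = net.require_instantiated()
    out = net.copy()
    stats = {}
    for proj, conn in zip(out.projections, out.connections):
        if len(conn) == 0:
            continue
        stats[proj.label] = {"mean": float(conn.delay.mean()),
                             "min": float(conn.delay.min()),
                             "max": float(conn.delay.max())}
        conn.delay = np.full(len(conn), float(d))
    out.meta.setdefault("distortions", []).append(
        {"kind": "uniform_delays", "d": d, "original_delays": stats})
    return out


def expected_clipped_mean_shift(noise_ratio: float) -> float:
    """Relative mean increase of a zero-clipped Gaussian N(mu, (r mu)^2).

    E[max(0, X)] / mu - 1  =  Phi(1/r) + r phi(1/r) - 1, independent of mu.
    For r = 0.5 this evaluates to ~0.425%.
    """
    if noise_ratio < 0:
        raise ValueError("noise_ratio must be non-negative")
    if noise_ratio == 0.0:
        return 0.0
    z = 1.0 / noise_ratio
    return float(norm.cdf(z) + noise_ratio * norm.pdf(z) - 1.0)


def apply_distortions(net: NetworkSpec, cfg: DistortionConfig
                      ) -> Tuple[NetworkSpec, Dict[str, dict]]:
    """Canonical composition: loss, then weight noise, then uniform delays."""
    report: Dict[str, dict] = {}
    out = net
    has_loss = (any(v > 0 for v in cfg.loss_p.values())
                if isinstance(cfg.loss_p, Mapping) else cfg.loss_p > 0)
    if has_loss:
        out, rep = apply_synapse_loss(out, cfg)
        report["synapse_loss"] = rep
    if cfg.noise_ratio > 0:
        out, rep = apply_weight_noise(out, cfg)
        report["weight_noise"] = rep
    if cfg.uniform_delay is not None:
        out = apply_uniform_delays(out, cfg.uniform_delay)
        report["uniform_delays"] = {"d": cfg.uniform_delay}
    return out, report
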