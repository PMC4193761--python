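"""Neuron, synapse and stimulus parameter types.

Units follow the conventions of conductance-based point-neuron modelling:
capacitance in nF, conductances in nS, voltages in mV, times in ms and
currents in pA.  With these units ``C dV/dt`` and ``g (E - V)`` are both in
pA after scaling, so no hidden unit conversions are needed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional


@dataclass(frozen=True)
class ShortTermPlasticity:
    """Tsodyks-Markram style short-term plasticity.

    A synapse releases a fraction ``u`` of its recovered resource ``R`` on
    every presynaptic spike; ``R`` recovers exponentially with ``tau_rec``.
    In ``depression`` mode the utilization is pinned at the baseline ``U``;
    in ``facilitation`` mode ``u`` jumps by ``U * (1 - u)`` per spike and
    decays back to ``U`` with ``tau_facil``.  The two modes are mutually
    exclusive (mirroring synapse drivers that implement only one at a time).
    """

    u: float
    tau_rec: float
    tau_facil: float = 0.0
    mode: str = "depression"

    def __post_init__(self) -> None:
        if not 0.0 <= self.u <= 1.0:
            raise ValueError(f"U must be in [0, 1], got {self.u}")
        if self.tau_rec <= 0:
            raise ValueError("tau_rec must be positive")
        if self.mode not in ("depression", "facilitation"):
            raise ValueError(f"unknown STP mode {self.mode!r}")
        if self.mode == "facilitation" and self.tau_facil <= 0:
            raise ValueError("facilitation requires tau_facil > 0")


@dataclass(frozen=True)
class AdExParams:
    """Adaptive-exponential integrate-and-fire neuron parameters.

    ``delta_t == 0`` removes the exponential spike-initiation term and the
    model reduces to a plain leaky integrate-and-fire neuron; in that case
    the spike condition is ``V >= v_t`` and ``v_spike`` is unused.

    Attributes
    ----------
    c_m : membrane capacitance (nF)
    g_l : leak conductance (nS)
    e_l : leak (resting) potential (mV)
    v_t : spike-initiation threshold (mV)
    delta_t : threshold slope factor (mV); 0 disables the exponential term
    tau_w : adaptation time constant (ms)
    a : subthreshold adaptation conductance (nS)
    b : spike-triggered adaptation increment (pA)
    v_reset : post-spike reset potential (mV)
    v_spike : spike detection threshold (mV), used only when delta_t > 0
    tau_ref : absolute refractory period (ms)
    """

    c_m: float
    g_l: float
    e_l: float
    v_t: float
    delta_t: float = 0.0
    tau_w: float = 100.0
    a: float = 0.0
    b: float = 0.0
    v_reset: float = -70.0
    v_spike: float = -40.0
    tau_ref: float = 0.0

    def __post_init__(self) -> None:
        if self.c_m <= 0:
            raise ValueError("c_m must be positive")
        if self.g_l <= 0:
            raise ValueError("g_l must be positive")
        if self.tau_w <= 0:
            raise ValueError("tau_w must be positive")
        if self.tau_ref < 0:
            raise ValueError("tau_ref must be non-negative")
        if self.delta_t < 0:
            raise ValueError("delta_t must be non-negative")

    @property
    def tau_m(self) -> float:
        """Passive membrane time constant C_m / g_L in ms (nF/nS = s)."""
        return 1000.0 * self.c_m / self.g_l

    def with_(self, **kw) -> "AdExParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class SynapseParams:
    """Exponential conductance synapse template.

    ``weight`` is the peak conductance jump per presynaptic spike (nS) and is
    always non-negative; the sign of the effect is carried entirely by the
    reversal potential ``e_rev`` (separate excitatory/inhibitory inputs).
    """

    weight: float
    e_rev: float
    tau_syn: float
    stp: Optional[ShortTermPlasticity] = None

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("synaptic weight must be non-negative")
        if self.tau_syn <= 0:
            raise ValueError("tau_syn must be positive")

    @property
    def is_excitatory(self) -> bool:
        # Receptor identity inferred from the reversal potential: anything
        # at or above -40 mV depolarizes from typical operating points.
        return self.e_rev >= -40.0

    def with_(self, **kw) -> "SynapseParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class PulsePacket:
    """Gaussian pulse-packet stimulus: ``n_sources`` sources emit ``a``
    spikes each (``a`` may be fractional across the population), drawn from
    a normal distribution centred at ``t_center`` with spread ``sigma``."""

    n_sources: int
    a: float
    sigma: float
    t_center: float

    def __post_init__(self) -> None:
        if self.n_sources < 1:
            raise ValueError("n_sources must be >= 1")
        if self.a < 0:
            raise ValueError("a must be non-negative")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
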