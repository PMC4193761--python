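"""Shared fixtures: small neurons, networks, and synthetic rasters."""

from __future__ import annotations

import numpy as np
import pytest

from spikecomp.network import NetworkSpec, Population, Projection
from spikecomp.params import AdExParams, SynapseParams
from spikecomp.spikes import SpikeData


@pytest.fixture
def lif_params() -> AdExParams:
    # tau_m = 10 ms passive cell, threshold far from rest
    return AdExParams(c_m=0.25, g_l=25.0, e_l=-70.0, v_t=-55.0, delta_t=0.0,
                      tau_w=100.0, a=0.0, b=0.0, v_reset=-70.0, tau_ref=2.0)


@pytest.fixture
def adex_params() -> AdExParams:
    return AdExParams(c_m=0.25, g_l=12.5, e_l=-60.0, v_t=-50.0, delta_t=2.5,
                      tau_w=300.0, a=2.0, b=30.0, v_reset=-58.0,
                      v_spike=-30.0, tau_ref=2.5)


@pytest.fixture
def single_neuron(lif_params) -> NetworkSpec:
    return NetworkSpec([Population("N", 1, "RS", params=lif_params,
                                   tau_syn_exc=1.5, tau_syn_inh=8.0)],
                       []).instantiate(0)


def make_driven_neuron(neuron: AdExParams, spike_times, weight: float,
                       e_rev: float = 0.0, tau_syn: float = 1.5,
                       tau_syn_inh: float = 8.0) -> NetworkSpec:
    """One neuron receiving a fixed spike train through one synapse,
    realized as a degenerate sigma=0 pulse-packet source per spike time."""
    pops = [Population("N", 1, "RS", params=neuron, tau_syn_exc=tau_syn,
                       tau_syn_inh=tau_syn_inh)]
    projs = []
    syn = SynapseParams(weight=weight, e_rev=e_rev,
                        tau_syn=tau_syn if e_rev >= -40 else tau_syn_inh)
    for k, t in enumerate(spike_times):
        pops.append(Population(f"S{k}", 1, "source",
                               source={"kind": "pulse_packet", "a": 1.0,
                                       "sigma": 0.0, "t_center": float(t)}))
        projs.append(Projection(f"S{k}", "N", {"kind": "all_to_all"}, syn,
                                {"kind": "constant", "d": 1.0}))
    return NetworkSpec(pops, projs).instantiate(0)


@pytest.fixture
def scripted_attractor_raster():
    """Raster with three scripted attractor episodes plus sparse noise.

    Returns (SpikeData, patterns map, episode list [(pattern, t0, t1)])."""
    rng = np.random.default_rng(7)
    n_pat, n_per = 4, 30
    episodes = [(0, 1000.0, 1500.0), (1, 2000.0, 2600.0), (2, 3200.0, 3700.0)]
    trains = {}
    for p in range(n_pat):
        for k in range(n_per):
            nid = p * n_per + k
            ts = [rng.uniform(0, 5000, size=4)]  # sparse background
            for (pp, a, b) in episodes:
                if p == pp:
                    ts.append(rng.uniform(a, b, size=int((b - a) * 0.08)))
            t = np.sort(np.concatenate(ts))
            t = t[np.concatenate([[True], np.diff(t) > 0.2])]
            trains[nid] = t
    sd = SpikeData(trains, {"PYR": (0, n_pat * n_per)}, 5000.0)
    patterns = {p: list(range(p * n_per, (p + 1) * n_per))
                for p in range(n_pat)}
    return sd, patterns, episodes


def solve_adex_ode(neuron: AdExParams, input_spikes, weights, e_revs,
                   tau_syns, t_end: float, dt_out: float = 0.1,
                   i_ext: float = 0.0):
    """Independent adaptive-step reference integration of the AdEx/LIF
    subthreshold dynamics under fixed input spikes (scipy solve_ivp,
    tight tolerances).  Conductances are evaluated analytically.  Only
    valid while the trajectory stays subthreshold."""
    from scipy.integrate import solve_ivp

    input_spikes = [np.asarray(s, dtype=float) for s in input_spikes]

    def g_syn(t):
        out = []
        for s, w, tau in zip(input_spikes, weights, tau_syns):
            past = s[s <= t]
            out.append(w * np.sum(np.exp(-(t - past) / tau)))
        return out

    c = 1000.0 * neuron.c_m  # nS * ms

    def rhs(t, y):
        v, w_ad = y
        gs = g_syn(t)
        i_syn = sum(g * (e - v) for g, e in zip(gs, e_revs))
        i_exp = 0.0
        if neuron.delta_t > 0:
            i_exp = neuron.g_l * neuron.delta_t * np.exp(
                min((v - neuron.v_t) / neuron.delta_t, 16.0))
        dv = (-neuron.g_l * (v - neuron.e_l) + i_exp + i_syn + i_ext - w_ad) / c
        dw = (neuron.a * (v - neuron.e_l) - w_ad) / neuron.tau_w
        return [dv, dw]

    t_eval = np.arange(0.0, t_end + dt_out / 2, dt_out)
    sol = solve_ivp(rhs, (0.0, t_end), [neuron.e_l, 0.0], t_eval=t_eval,
                    rtol=1e-10, atol=1e-10, max_step=0.25)
    return sol.t, sol.y[0]
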