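"""Fixed-step simulation of AdEx/LIF networks with conductance synapses.

Integration scheme
------------------
The membrane equation is advanced with exponential Euler: at each step the
instantaneous equilibrium voltage and total conductance are computed from
the (piecewise-constant over one step) synaptic conductances, and V decays
toward that equilibrium with the instantaneous membrane time constant
C_m / g_tot.  The exponential spike-initiation current (when delta_t > 0)
and the adaptation current enter as explicit currents evaluated at the
start of the step.  Synaptic conductances decay exponentially (exact per
step) and jump by the synaptic weight on arrival of a presynaptic spike.
Delays are rounded to the nearest multiple of dt (minimum one step) and
realized with a ring buffer of pending conductance increments.

With no synaptic input and delta_t = 0 the stepping is exact, so the LIF
relaxation test holds at machine precision.

Short-term plasticity state lives per synapse and is updated only at
presynaptic events using the closed-form inter-spike recursions, which is
exact for exponential recovery/facilitation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .network import NetworkSpec
from .params import AdExParams, PulsePacket, ShortTermPlasticity
from .spikes import SpikeData

#: argument cap for the spike-initiation exponential; beyond this the neuron
#: is guaranteed to cross v_spike within the step anyway
_EXP_ARG_MAX = 16.0


class SimulationError(RuntimeError):
    """Raised when the membrane integration diverges (non-finite voltage)."""


@dataclass
class VoltageTraces:
    times: np.ndarray                  # (n_samples,) ms
    traces: Dict[int, np.ndarray]      # global neuron id -> (n_samples,) mV

    def to_csv(self, path) -> None:
        import pandas as pd
        df = pd.DataFrame({"time_ms": self.times})
        for nid, v in self.traces.items():
            df[f"v_{nid}"] = v
        df.to_csv(path, index=False)


@dataclass
class SimResult:
    spikes: SpikeData
    voltages: Optional[VoltageTraces] = None


# ---------------------------------------------------------------------------
# stand-alone stimulus generators
# ---------------------------------------------------------------------------

def poisson_sources(n: int, rate: float, duration: float, seed: int,
                    t_start: float = 0.0) -> SpikeData:
    """Independent homogeneous Poisson spike trains (rate in Hz, times ms)."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(seed)
    trains: Dict[int, np.ndarray] = {}
    if rate > 0:
        scale = 1000.0 / rate  # mean ISI in ms
        for i in range(n):
            # draw gaps in blocks until the window is covered
            t, times = t_start, []
            while True:
                gaps = rng.exponential(scale, size=max(16, int((duration - t) / scale * 1.5) + 16))
                cum = t + np.cumsum(gaps)
                inside = cum[cum < duration]
                times.append(inside)
                if inside.size < cum.size:
                    break
                t = cum[-1]
            arr = np.concatenate(times)
            if arr.size:
                trains[i] = arr
    return SpikeData(trains, {"poisson": (0, n)}, duration)


def pulse_packet_spikes(pp: PulsePacket, seed: int,
                        duration: Optional[float] = None) -> SpikeData:
    """Realize a Gaussian pulse packet as per-source spike trains.

    Each source emits floor(a) spikes; the remaining
    ``round(n_sources * a) - n_sources * floor(a)`` spikes are assigned
    round-robin to sources 0, 1, ... so the total count is deterministic
    and equals the nearest integer to ``n_sources * a``.
    """
    n, a = pp.n_sources, pp.a
    total = int(round(n * a))
    base = total // n
    extra = total - base * n
    counts = np.full(n, base, dtype=int)
    counts[:extra] += 1
    rng = np.random.default_rng(seed)
    trains: Dict[int, np.ndarray] = {}
    t_max = pp.t_center
    for i in range(n):
        if counts[i] == 0:
            continue
        if pp.sigma == 0.0:
            # coincident spikes collapse onto one grid time; keep one event
            # per source per time to preserve strictly-increasing trains
            times = np.full(counts[i], pp.t_center)
            times = np.unique(times)
        else:
            times = np.sort(rng.normal(pp.t_center, pp.sigma, size=counts[i]))
            # de-duplicate pathological ties
            times = np.unique(times)
        times = times[times >= 0.0]
        if times.size:
            trains[i] = times
            t_max = max(t_max, times[-1])
    dur = duration if duration is not None else t_max + 1.0
    return SpikeData(trains, {"pulse_packet": (0, n)}, dur)


# ---------------------------------------------------------------------------
# short-term plasticity
# ---------------------------------------------------------------------------

def apply_stp(pre_spike_times: Sequence[float], stp: ShortTermPlasticity,
              weight: float) -> np.ndarray:
    """Effective weight of each spike in a presynaptic train.

    Implements the inter-spike closed forms: between spikes the recovered
    resource relaxes as ``R -> 1 - (1 - R+) exp(-dt/tau_rec)`` where ``R+``
    is the post-release value ``R (1 - u)``; in facilitation mode the
    utilization relaxes toward the baseline as
    ``u -> U + (u+ - U) exp(-dt/tau_facil)`` and jumps by ``U (1 - u)``
    immediately before release.
    """
    times = np.asarray(pre_spike_times, dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValueError("spike times must be sorted")
    out = np.empty(times.size)
    R = 1.0
    u = stp.u
    last = None
    for i, t in enumerate(times):
        if last is not None:
            dt = t - last
            R = 1.0 - (1.0 - R) * np.exp(-dt / stp.tau_rec)
            if stp.mode == "facilitation":
                u = stp.u + (u - stp.u) * np.exp(-dt / stp.tau_facil)
        if stp.mode == "facilitation":
            u = u + stp.u * (1.0 - u)
        else:
            u = stp.u
        out[i] = weight * u * R
        R = R * (1.0 - u)
        last = t
    return out


# ---------------------------------------------------------------------------
# network simulation
# ---------------------------------------------------------------------------

class _CompiledNet:
    """Flat arrays extracted from a NetworkSpec for the integration loop."""

    def __init__(self, net: NetworkSpec, dt: float):
        conns = net.require_instantiated()
        self.dt = dt

        # --- unit bookkeeping: dynamic neurons get contiguous slot indices
        n_units = net.n_units
        self.dyn_of_global = np.full(n_units, -1, dtype=np.int64)
        dyn_ids = []
        for pop in net.populations:
            lo, hi = net.id_range(pop.name)
            if not pop.is_source:
                dyn_ids.append(np.arange(lo, hi))
        self.dyn_ids = np.concatenate(dyn_ids) if dyn_ids else np.empty(0, dtype=np.int64)
        self.dyn_of_global[self.dyn_ids] = np.arange(self.dyn_ids.size)
        n = self.n_dyn = self.dyn_ids.size

        # --- per-neuron parameter arrays (units: nF, nS, mV, ms, pA)
        def arr(fill=0.0):
            return np.full(n, fill, dtype=float)

        self.c_m, self.g_l, self.e_l = arr(1.0), arr(1.0), arr(-70.0)
        self.v_t, self.delta_t, self.v_reset = arr(-50.0), arr(0.0), arr(-70.0)
        self.v_spike, self.tau_ref = arr(-40.0), arr(0.0)
        self.adapt_a, self.adapt_b, self.tau_w = arr(0.0), arr(0.0), arr(100.0)
        self.e_exc, self.e_inh = arr(0.0), arr(-80.0)
        tau_e, tau_i = arr(5.0), arr(10.0)
        for pop in net.populations:
            if pop.is_source:
                continue
            lo, hi = net.id_range(pop.name)
            sl = self.dyn_of_global[lo:hi]
            p = pop.params
            for name, val in (("c_m", p.c_m), ("g_l", p.g_l), ("e_l", p.e_l),
                              ("v_t", p.v_t), ("delta_t", p.delta_t),
                              ("v_reset", p.v_reset), ("v_spike", p.v_spike),
                              ("tau_ref", p.tau_ref), ("adapt_a", p.a),
                              ("adapt_b", p.b), ("tau_w", p.tau_w)):
                getattr(self, name)[sl] = val
            self.e_exc[sl] = pop.e_rev_exc
            self.e_inh[sl] = pop.e_rev_inh
            tau_e[sl] = pop.tau_syn_exc
            tau_i[sl] = pop.tau_syn_inh
        # per-neuron overrides (iterative compensation etc.)
        override_map = {"a": "adapt_a", "b": "adapt_b"}
        for param, entries in net.overrides.items():
            attr = override_map.get(param, param)
            target = getattr(self, attr)
            for gid, val in entries.items():
                di = self.dyn_of_global[gid]
                if di >= 0:
                    target[di] = val

        self.decay_e = np.exp(-dt / tau_e)
        self.decay_i = np.exp(-dt / tau_i)
        self.decay_w = np.exp(-dt / self.tau_w)
        self.ref_steps = np.round(self.tau_ref / dt).astype(np.int64)
        self.threshold = np.where(self.delta_t > 0, self.v_spike, self.v_t)
        self.has_exp = bool(np.any(self.delta_t > 0))

        # --- synapses flattened and CSR-indexed by presynaptic unit
        pres, posts, weights, delays, chans, stp_of = [], [], [], [], [], []
        self.stp_params: List[ShortTermPlasticity] = []
        n_stp = 0
        for proj, conn in zip(net.projections, conns):
            m = len(conn)
            if m == 0:
                continue
            pres.append(conn.pre)
            posts.append(self.dyn_of_global[conn.post])
            if np.any(posts[-1] < 0):
                raise SimulationError(f"projection {proj.label} targets a source population")
            weights.append(conn.weight)
            steps = np.maximum(np.round(conn.delay / dt).astype(np.int64), 1)
            delays.append(steps)
            chans.append(np.full(m, 0 if proj.synapse.is_excitatory else 1, dtype=np.int8))
            if proj.synapse.stp is not None:
                stp_of.append(np.arange(n_stp, n_stp + m))
                n_stp += m
                self.stp_params.append(proj.synapse.stp)
                self.stp_group = getattr(self, "stp_group", [])
            else:
                stp_of.append(np.full(m, -1, dtype=np.int64))
        if pres:
            pre = np.concatenate(pres)
            order = np.argsort(pre, kind="stable")
            self.syn_pre = pre[order]
            self.syn_post = np.concatenate(posts)[order]
            self.syn_w = np.concatenate(weights)[order]
            self.syn_delay = np.concatenate(delays)[order]
            self.syn_chan = np.concatenate(chans)[order]
            self.syn_stp = np.concatenate(stp_of)[order]
            counts = np.bincount(self.syn_pre, minlength=n_units)
            self.indptr = np.concatenate([[0], np.cumsum(counts)])
            self.max_delay = int(self.syn_delay.max())
        else:
            self.syn_pre = np.empty(0, dtype=np.int64)
            self.syn_post = np.empty(0, dtype=np.int64)
            self.syn_w = np.empty(0)
            self.syn_delay = np.empty(0, dtype=np.int64)
            self.syn_chan = np.empty(0, dtype=np.int8)
            self.syn_stp = np.empty(0, dtype=np.int64)
            self.indptr = np.zeros(n_units + 1, dtype=np.int64)
            self.max_delay = 1

        # STP per-synapse state, aligned with flattened order
        self.n_stp_syn = n_stp
        if n_stp:
            # map flattened synapse -> (tau_rec, tau_facil, U, facil?) arrays
            self.stp_R = np.ones(n_stp)
            self.stp_u = np.empty(n_stp)
            self.stp_last = np.full(n_stp, -np.inf)
            self.stp_U = np.empty(n_stp)
            self.stp_tau_rec = np.empty(n_stp)
            self.stp_tau_fac = np.empty(n_stp)
            self.stp_facil = np.zeros(n_stp, dtype=bool)
            idx = 0
            for proj, conn in zip(net.projections, conns):
                if proj.synapse.stp is None or len(conn) == 0:
                    continue
                m = len(conn)
                s = proj.synapse.stp
                sl = slice(idx, idx + m)
                self.stp_U[sl] = s.u
                self.stp_u[sl] = s.u
                self.stp_tau_rec[sl] = s.tau_rec
                self.stp_tau_fac[sl] = s.tau_facil if s.tau_facil > 0 else 1.0
                self.stp_facil[sl] = s.mode == "facilitation"
                idx += m

    def gather_synapses(self, units: np.ndarray) -> np.ndarray:
        """Indices of all outgoing synapses of the given presynaptic units."""
        starts = self.indptr[units]
        stops = self.indptr[units + 1]
        lens = stops - starts
        total = int(lens.sum())
        if total == 0:
            return np.empty(0, dtype=np.int64)
        # vectorized multi-range arange
        rep_starts = np.repeat(starts, lens)
        offs = np.arange(total) - np.repeat(np.cumsum(lens) - lens, lens)
        return rep_starts + offs


def simulate(net: NetworkSpec, duration: float, dt: float = 0.01,
             seed: int = 0, record_voltages: Iterable[int] = (),
             i_ext: Optional[Dict[str, float]] = None,
             record_sources: bool = False,
             v_init: Optional[float] = None) -> SimResult:
    """Simulate an instantiated network for ``duration`` ms.

    Bitwise reproducible for identical (net, duration, dt, seed).

    Parameters
    ----------
    record_voltages : global neuron ids whose membrane traces to keep
    i_ext : optional constant current injection per population name (pA)
    record_sources : include source-population spikes in the output raster
    v_init : initial membrane voltage (defaults to each neuron's E_L)
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    comp = _CompiledNet(net, dt)
    n_steps = int(round(duration / dt))
    n = comp.n_dyn
    rng_root = np.random.SeedSequence(seed)
    pop_seeds = rng_root.spawn(len(net.populations))

    # --- source emission schedules
    poisson_pops = []   # (rng, lam_per_step, id_lo, start_step, stop_step)
    event_pops = []     # (steps array, unit ids array) pre-realized spikes
    src_records: List[Tuple[int, float]] = []
    for pop, pseed in zip(net.populations, pop_seeds):
        if not pop.is_source:
            continue
        lo, hi = net.id_range(pop.name)
        desc = pop.source
        if desc["kind"] == "poisson":
            if "rates" in desc:   # heterogeneous per-unit rates
                lam = np.asarray(desc["rates"], dtype=float) * dt / 1000.0
                if lam.size != hi - lo:
                    raise SimulationError(f"{pop.name}: rates array size mismatch")
            else:
                lam = desc["rate"] * dt / 1000.0
            start = int(round(desc.get("start", 0.0) / dt))
            stop = int(round(desc.get("stop", duration) / dt))
            poisson_pops.append((np.random.default_rng(pseed), lam, lo, hi, start, stop))
        elif desc["kind"] == "spike_train":
            # explicit per-unit spike times: {"times": {unit_idx: [...]}} or a
            # single list applied to unit 0
            raw = desc["times"]
            tmap = raw if isinstance(raw, dict) else {0: raw}
            steps_list, units_list = [], []
            for i, times in tmap.items():
                st_ = np.round(np.asarray(times, dtype=float) / dt).astype(np.int64)
                st_ = st_[st_ < n_steps]
                steps_list.append(st_)
                units_list.append(np.full(st_.size, lo + int(i), dtype=np.int64))
            if steps_list:
                steps = np.concatenate(steps_list)
                units = np.concatenate(units_list)
                order = np.argsort(steps, kind="stable")
                event_pops.append((steps[order], units[order]))
        elif desc["kind"] == "pulse_packet":
            pp = PulsePacket(n_sources=pop.size, a=desc["a"],
                             sigma=desc["sigma"], t_center=desc["t_center"])
            sd = pulse_packet_spikes(pp, np.random.default_rng(pseed).integers(2 ** 31),
                                     duration=duration)
            steps_list, units_list = [], []
            for i, times in sd.trains.items():
                st = np.round(times / dt).astype(np.int64)
                st = st[st < n_steps]
                steps_list.append(st)
                units_list.append(np.full(st.size, lo + i, dtype=np.int64))
            if steps_list:
                steps = np.concatenate(steps_list)
                units = np.concatenate(units_list)
                order = np.argsort(steps, kind="stable")
                event_pops.append((steps[order], units[order]))
        else:
            raise SimulationError(f"unknown source kind {desc['kind']!r}")

    # --- state
    V = comp.e_l.copy() if v_init is None else np.full(n, float(v_init))
    w_ad = np.zeros(n)          # adaptation current, pA
    g_e = np.zeros(n)
    g_i = np.zeros(n)
    refr = np.zeros(n, dtype=np.int64)
    L = comp.max_delay + 1
    buf_e = np.zeros((L, n))
    buf_i = np.zeros((L, n))

    stim = np.zeros(n)
    for pname, amp in (i_ext or {}).items():
        lo, hi = net.id_range(pname)
        stim[comp.dyn_of_global[lo:hi]] = amp

    rec_ids = np.asarray(sorted(set(record_voltages)), dtype=np.int64)
    rec_idx = comp.dyn_of_global[rec_ids] if rec_ids.size else np.empty(0, dtype=np.int64)
    if rec_ids.size and np.any(rec_idx < 0):
        raise SimulationError("cannot record voltage of a source unit")
    v_store = np.empty((n_steps + 1, rec_ids.size)) if rec_ids.size else None
    if v_store is not None:
        v_store[0] = V[rec_idx]

    spike_steps: List[np.ndarray] = []
    spike_units: List[np.ndarray] = []
    ev_ptr = [0] * len(event_pops)

    for t in range(n_steps):
        slot = t % L
        g_e *= comp.decay_e
        g_i *= comp.decay_i
        g_e += buf_e[slot]
        g_i += buf_i[slot]
        buf_e[slot] = 0.0
        buf_i[slot] = 0.0

        # adaptation (exponential relaxation toward a (V - E_L))
        w_eq = comp.adapt_a * (V - comp.e_l)
        w_ad = w_eq + (w_ad - w_eq) * comp.decay_w

        # membrane update
        if comp.has_exp:
            arg = np.minimum((V - comp.v_t) / np.where(comp.delta_t > 0, comp.delta_t, 1.0),
                             _EXP_ARG_MAX)
            i_exp = np.where(comp.delta_t > 0,
                             comp.g_l * comp.delta_t * np.exp(arg), 0.0)
        else:
            i_exp = 0.0
        g_tot = comp.g_l + g_e + g_i
        v_eq = (comp.g_l * comp.e_l + g_e * comp.e_exc + g_i * comp.e_inh
                + i_exp + stim - w_ad) / g_tot
        V = v_eq + (V - v_eq) * np.exp(-dt * g_tot / (1000.0 * comp.c_m))

        active_refr = refr > 0
        if np.any(active_refr):
            V[active_refr] = comp.v_reset[active_refr]
            refr[active_refr] -= 1

        spiked = np.flatnonzero((V >= comp.threshold) & ~active_refr)
        if spiked.size:
            V[spiked] = comp.v_reset[spiked]
            w_ad[spiked] += comp.adapt_b[spiked]
            refr[spiked] = np.maximum(comp.ref_steps[spiked], 1)
            spike_steps.append(np.full(spiked.size, t, dtype=np.int64))
            spike_units.append(comp.dyn_ids[spiked])

        if not np.all(np.isfinite(V)) or np.any(V > 200.0):
            # voltage left the physical range without triggering spike
            # detection: exponential runaway with an unreachable v_spike
            raise SimulationError(f"membrane voltage diverged at t={t * dt:.3f} ms")

        if v_store is not None:
            v_store[t + 1] = V[rec_idx]

        # --- collect this step's presynaptic events
        ev_units = []
        ev_counts = []
        if spiked.size:
            ev_units.append(comp.dyn_ids[spiked])
            ev_counts.append(np.ones(spiked.size, dtype=np.int64))
        for rng, lam, lo, hi, start, stop in poisson_pops:
            if not np.any(lam > 0) or not (start <= t < stop):
                continue
            cnt = rng.poisson(lam, size=hi - lo)
            nz = np.flatnonzero(cnt)
            if nz.size:
                ev_units.append(nz + lo)
                ev_counts.append(cnt[nz])
                if record_sources:
                    for u, c in zip(nz + lo, cnt[nz]):
                        src_records.extend([(int(u), t)] * int(c))
        for k, (steps, units) in enumerate(event_pops):
            p = ev_ptr[k]
            while p < steps.size and steps[p] == t:
                p += 1
            if p > ev_ptr[k]:
                uu = units[ev_ptr[k]:p]
                uniq, cc = np.unique(uu, return_counts=True)
                ev_units.append(uniq)
                ev_counts.append(cc)
                if record_sources:
                    for u, c in zip(uniq, cc):
                        src_records.extend([(int(u), t)] * int(c))
                ev_ptr[k] = p

        if not ev_units:
            continue
        units = np.concatenate(ev_units)
        counts = np.concatenate(ev_counts)
        sidx = comp.gather_synapses(units)
        if sidx.size == 0:
            continue
        lens = comp.indptr[units + 1] - comp.indptr[units]
        mult = np.repeat(counts, lens).astype(float)
        w_eff = comp.syn_w[sidx] * mult

        if comp.n_stp_syn:
            st = comp.syn_stp[sidx]
            has = np.flatnonzero(st >= 0)
            if has.size:
                si = st[has]
                t_ms = t * dt
                gap = t_ms - comp.stp_last[si]
                first = ~np.isfinite(gap)
                R = comp.stp_R[si]
                u = comp.stp_u[si]
                dec_r = np.where(first, 0.0, np.exp(-np.where(first, 0.0, gap)
                                                    / comp.stp_tau_rec[si]))
                R = 1.0 - (1.0 - R) * dec_r
                fac = comp.stp_facil[si]
                dec_f = np.where(first, 0.0, np.exp(-np.where(first, 0.0, gap)
                                                    / comp.stp_tau_fac[si]))
                u = np.where(fac,
                             comp.stp_U[si] + (u - comp.stp_U[si]) * dec_f,
                             comp.stp_U[si])
                u = np.where(fac, u + comp.stp_U[si] * (1.0 - u), u)
                w_eff[has] *= u * R
                comp.stp_R[si] = R * (1.0 - u)
                comp.stp_u[si] = u
                comp.stp_last[si] = t_ms

        dest = (t + comp.syn_delay[sidx]) % L
        post = comp.syn_post[sidx]
        exc = comp.syn_chan[sidx] == 0
        if np.any(exc):
            np.add.at(buf_e, (dest[exc], post[exc]), w_eff[exc])
        if not np.all(exc):
            inh = ~exc
            np.add.at(buf_i, (dest[inh], post[inh]), w_eff[inh])

    # --- package results
    trains: Dict[int, np.ndarray] = {}
    if spike_steps:
        steps = np.concatenate(spike_steps)
        units = np.concatenate(spike_units)
        times = (steps + 1) * dt
        order = np.lexsort((times, units))
        units, times = units[order], times[order]
        bounds = np.flatnonzero(np.diff(units)) + 1
        for uu, tt in zip(np.split(units, bounds), np.split(times, bounds)):
            trains[int(uu[0])] = tt
    if record_sources and src_records:
        by_unit: Dict[int, List[float]] = {}
        for u, t in src_records:
            by_unit.setdefault(u, []).append((t + 1) * dt)
        for u, ts in by_unit.items():
            arr = np.unique(np.asarray(ts))
            trains[u] = arr
    spikes = SpikeData(trains, net.population_map(), duration)
    voltages = None
    if v_store is not None:
        times = np.arange(n_steps + 1) * dt
        voltages = VoltageTraces(times, {int(g): v_store[:, k]
                                         for k, g in enumerate(rec_ids)})
    return SimResult(spikes, voltages)
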