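"""Compensation strategies that restore distorted network functionality.

Five mechanisms, each targeting one distortion/model combination:

* :func:`compensate_loss_by_weights` — scale surviving weights by 1/(1-p)
  per projection so the summed synaptic conductance per target neuron is
  conserved in expectation.
* :func:`multi_source_background` — replace one-source-per-neuron diffuse
  background by k sources drawn from a shared pool (each at 1/k of the
  rate), averaging out per-synapse weight noise.
* :func:`compensate_noise_via_rest_potential` — raise the resting potential
  while lowering the background weight so the free-membrane mean and
  variance match the undistorted values under multiplicative weight noise.
* :func:`compensate_delay_via_inhibition` — emulate a longer local
  inhibition delay by stretching the inhibitory synaptic time constant and
  rescaling the inhibitory weight.
* :func:`mean_field_compensate` / :func:`iterative_compensate` — restore
  the self-sustained firing rate either globally (time rescaling by the
  ratio of gain-function fixed points) or per neuron (threshold tuning
  toward a target rate under frozen distortions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .network import NetworkSpec, Population, Projection
from .params import AdExParams, SynapseParams
from .spikes import SpikeData


class CompensationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# synapse loss
# ---------------------------------------------------------------------------

def compensate_loss_by_weights(net: NetworkSpec,
                               p_loss: Union[float, Mapping[str, float]]
                               ) -> Tuple[NetworkSpec, Dict[str, float]]:
    """Multiply every surviving weight of projection j by 1/(1 - p_j).

    The expected total conductance per target neuron is thereby restored:
    deletion keeps a fraction (1 - p) of synapses, each now 1/(1 - p) as
    strong.  Weight noise variance increases accordingly — that is the
    documented cost of this strategy.
    """
    conns = net.require_instantiated()
    out = net.copy()
    factors: Dict[str, float] = {}
    for proj, conn in zip(out.projections, out.connections):
        p = (p_loss.get(proj.label, 0.0) if isinstance(p_loss, Mapping)
             else float(p_loss))
        if p == 0.0:
            continue
        if not 0.0 <= p < 1.0:
            raise CompensationError(
                f"{proj.label}: cannot compensate total loss (p={p})")
        factor = 1.0 / (1.0 - p)
        conn.weight = conn.weight * factor
        proj.synapse = proj.synapse.with_(weight=proj.synapse.weight * factor)
        factors[proj.label] = factor
    out.meta.setdefault("compensations", []).append(
        {"kind": "loss_by_weights", "factors": factors})
    return out, factors


# ---------------------------------------------------------------------------
# multi-source background
# ---------------------------------------------------------------------------

def multi_source_background(net: NetworkSpec, pool_size: int,
                            k_per_neuron: int,
                            total_rate_per_neuron: float,
                            bg_population: str = "bg",
                            seed: int = 0) -> NetworkSpec:
    """Rewire the diffuse background from one private source per neuron to
    ``k_per_neuron`` sources drawn without replacement from a shared pool.

    Each pool source fires at ``total_rate_per_neuron / k_per_neuron`` so
    the expected background conductance per neuron is conserved exactly;
    per-synapse weight noise then averages out as 1/sqrt(k).  The expected
    pairwise overlap between the source sets of two neurons is
    k^2 / pool_size.
    """
    if k_per_neuron > pool_size:
        raise CompensationError("k_per_neuron exceeds pool size")
    net.require_instantiated()
    out = net.copy()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x36]))
    try:
        old = out.population(bg_population)
    except KeyError as e:
        raise CompensationError(f"no background population {bg_population!r}") from e
    if not old.is_source:
        raise CompensationError(f"{bg_population} is not a source population")
    if out.populations[-1].name != bg_population:
        # resizing shifts every later global id; keep the pool last instead
        raise CompensationError("background population must be declared last")
    old.size = pool_size
    old.source = {"kind": "poisson",
                  "rate": total_rate_per_neuron / k_per_neuron}
    # rebuild the id offsets after the size change
    out._offsets = np.concatenate(
        [[0], np.cumsum([p.size for p in out.populations])])
    bg_lo, _ = out.id_range(bg_population)
    for idx, proj in enumerate(out.projections):
        if proj.source != bg_population:
            continue
        tgt_lo, tgt_hi = out.id_range(proj.target)
        n_tgt = tgt_hi - tgt_lo
        pre = np.concatenate([
            rng.choice(pool_size, size=k_per_neuron, replace=False)
            for _ in range(n_tgt)])
        post = np.repeat(np.arange(n_tgt), k_per_neuron)
        proj.rule = {"kind": "pairs", "pre": pre, "post": post}
        conn = out.connections[idx]
        d = float(conn.delay[0]) if len(conn) else float(proj.delay.get("d", 1.0))
        conn.pre = pre + bg_lo
        conn.post = post + tgt_lo
        conn.weight = np.full(pre.size, proj.synapse.weight)
        conn.delay = np.full(pre.size, d)
    out.meta.setdefault("compensations", []).append(
        {"kind": "multi_source_background", "pool": pool_size,
         "k": k_per_neuron, "rate_per_source":
         total_rate_per_neuron / k_per_neuron})
    return out


# ---------------------------------------------------------------------------
# weight noise: resting-potential / background-weight rebalancing
# ---------------------------------------------------------------------------

def _clipped_moments(r: float) -> Tuple[float, float]:
    """First and second moments of max(0, N(1, r^2))."""
    if r == 0.0:
        return 1.0, 1.0
    from scipy.stats import norm
    z = 1.0 / r
    m1 = norm.cdf(z) + r * norm.pdf(z)
    # E[X^2] for X = max(0, N(1, r^2)):
    # integral x^2 phi((x-1)/r)/r dx over x>0 = (1 + r^2) Phi(1/r) + r phi(1/r)
    m2 = (1.0 + r ** 2) * norm.cdf(z) + r * norm.pdf(z)
    return float(m1), float(m2)


def _free_membrane_moments(neuron: AdExParams, rate: float, weight: float,
                           tau_syn: float, e_rev: float,
                           m1: float = 1.0, m2: float = 1.0
                           ) -> Tuple[float, float]:
    """Stationary mean and variance of the free membrane under Poisson
    bombardment, in the effective-current (diffusion) approximation.

    The mean conductance shifts the operating point self-consistently; the
    variance follows Campbell's theorem for the double-exponential voltage
    kernel with random weight marks (moments m1, m2 of the multiplicative
    noise factor).
    """
    nu = rate / 1000.0                       # spikes per ms
    g_mean = nu * weight * m1 * tau_syn      # nS
    mu = ((neuron.g_l * neuron.e_l + g_mean * e_rev)
          / (neuron.g_l + g_mean))
    tau_eff = 1000.0 * neuron.c_m / (neuron.g_l + g_mean)  # ms
    c = 1000.0 * neuron.c_m                  # nS * ms (so tau = c / g)
    amp = weight * (e_rev - mu) / c          # kernel prefactor, mV/ms per nS..
    if abs(tau_eff - tau_syn) < 1e-9:
        tau_syn = tau_syn * (1.0 + 1e-9)
    k = amp / (1.0 / tau_syn - 1.0 / tau_eff)
    # integral of (e^{-t/tau_eff} - e^{-t/tau_syn})^2 dt
    integral = (tau_eff / 2.0 + tau_syn / 2.0
                - 2.0 / (1.0 / tau_eff + 1.0 / tau_syn))
    var = nu * m2 * k ** 2 * integral
    return float(mu), float(var)


def compensate_noise_via_rest_potential(
        neuron: AdExParams,
        background: Tuple[float, float, float, float],
        noise_ratio: float,
        max_iter: int = 200) -> Tuple[float, float]:
    """Return (E_L', w') restoring the free-membrane mean and variance
    under multiplicative weight noise on the background synapses.

    ``background`` is (rate_Hz, weight_nS, tau_syn_ms, e_rev_mV).  The
    noisy weights are w' X with X = max(0, N(1, r^2)); matching the second
    moment fixes w' = w sqrt(m1_0 m2_0 / m2(r)) (evaluated self-
    consistently because the effective membrane time constant shifts with
    the mean conductance), and the mean is then restored by raising E_L.
    """
    rate, w0, tau_syn, e_rev = background
    r = float(noise_ratio)
    if r == 0.0:
        return neuron.e_l, w0
    mu0, var0 = _free_membrane_moments(neuron, rate, w0, tau_syn, e_rev)

    # quadrature nodes of the clipped multiplicative factor X = max(0, 1+rZ):
    # each neuron's single noisy synapse sits at its own operating point, so
    # the population-average moments are averages over X, not moments of X
    # plugged into one global operating point (that overestimates the
    # variance of strong synapses, whose driving force saturates).
    z = np.linspace(-5.0, 5.0, 81)
    pz = np.exp(-z ** 2 / 2.0)
    pz /= pz.sum()
    x_nodes = np.maximum(0.0, 1.0 + r * z)

    def population_moments(e_l: float, w: float) -> Tuple[float, float]:
        cell = neuron.with_(e_l=e_l)
        mus, vars_ = [], []
        for x in x_nodes:
            m, v = _free_membrane_moments(cell, rate, w * x, tau_syn, e_rev)
            mus.append(m)
            vars_.append(v)
        return (float(np.dot(pz, mus)), float(np.dot(pz, vars_)))

    w, e_l = w0, neuron.e_l
    for _ in range(max_iter):
        mu, var = population_moments(e_l, w)
        if var <= 0:
            raise CompensationError("no positive-weight solution")
        w_new = w * np.sqrt(var0 / var)
        # restore the mean through E_L at the current mean conductance
        nu = rate / 1000.0
        g_mean = nu * w_new * float(np.dot(pz, x_nodes)) * tau_syn
        e_l_new = (mu0 * (neuron.g_l + g_mean)
                   - g_mean * e_rev) / neuron.g_l
        if abs(w_new - w) < 1e-10 and abs(e_l_new - e_l) < 1e-10:
            w, e_l = w_new, e_l_new
            break
        w = 0.5 * (w + w_new)
        e_l = 0.5 * (e_l + e_l_new)
    if w < 0:
        raise CompensationError("no non-negative background weight solution")
    return float(e_l), float(w)


# ---------------------------------------------------------------------------
# delay compensation via prolonged inhibition
# ---------------------------------------------------------------------------

def compensate_delay_via_inhibition(net: NetworkSpec, tau_factor: float = 3.0,
                                    w_inh_scale: float = 1.0,
                                    label_prefix: str = "FS"
                                    ) -> NetworkSpec:
    """Stretch local inhibition: multiply the inhibitory synaptic time
    constant of local FS->RS projections by ``tau_factor`` and their
    weight by ``w_inh_scale``.

    Used when the substrate forces a short, fixed local-inhibition delay:
    prolonging the inhibitory conductance restores the temporal gating that
    a longer axonal delay would have provided, and the separatrix position
    can then be steered with ``w_inh_scale``.
    """
    net.require_instantiated()
    out = net.copy()
    touched = []
    for idx, proj in enumerate(out.projections):
        if not proj.source.startswith(label_prefix):
            continue
        if proj.synapse.is_excitatory:
            continue
        new_tau = proj.synapse.tau_syn * tau_factor
        proj.synapse = proj.synapse.with_(
            weight=proj.synapse.weight * w_inh_scale, tau_syn=new_tau)
        out.connections[idx].weight = out.connections[idx].weight * w_inh_scale
        out.population(proj.target).tau_syn_inh = new_tau
        touched.append(proj.label)
    out.meta.setdefault("compensations", []).append(
        {"kind": "delay_via_inhibition", "tau_factor": tau_factor,
         "w_inh_scale": w_inh_scale, "projections": touched})
    return out


def inhibitory_charge(net: NetworkSpec, label_prefix: str = "FS") -> float:
    """Total inhibitory charge transfer per presynaptic event,
    proportional to sum(w * tau_syn) over local inhibitory projections."""
    total = 0.0
    for proj in net.projections:
        if proj.source.startswith(label_prefix) and not proj.synapse.is_excitatory:
            total += proj.synapse.weight * proj.synapse.tau_syn
    return total


# ---------------------------------------------------------------------------
# gain function and mean-field compensation
# ---------------------------------------------------------------------------

@dataclass
class GainFunction:
    """Single-neuron output rate vs. afferent Poisson rate."""

    cell_type: str
    rates_in: np.ndarray
    rates_out: np.ndarray
    stderr: np.ndarray
    context: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rates_in = np.asarray(self.rates_in, dtype=float)
        self.rates_out = np.asarray(self.rates_out, dtype=float)
        self.stderr = np.asarray(self.stderr, dtype=float)
        if np.any(np.diff(self.rates_in) <= 0):
            raise ValueError("rate grid must be strictly increasing")
        if np.any(self.rates_out < 0):
            raise ValueError("output rates must be non-negative")

    def __call__(self, nu: float | np.ndarray) -> np.ndarray:
        return np.interp(nu, self.rates_in, self.rates_out)

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({"rate_in_Hz": self.rates_in,
                      "rate_out_Hz": self.rates_out,
                      "stderr": self.stderr}).to_csv(path, index=False)


def measure_gain_function(cell: AdExParams, synapse_exc: SynapseParams,
                          synapse_inh: SynapseParams, k_exc: int, k_inh: int,
                          p_loss: float, rate_grid: Sequence[float],
                          trials: int = 3, duration: float = 2000.0,
                          dt: float = 0.1, seed: int = 0,
                          cell_type: str = "PY",
                          channels: Optional[dict] = None) -> GainFunction:
    """Measure the single-neuron gain function under Poisson bombardment.

    For each grid rate nu the neuron receives (1-p) k_exc excitatory and
    (1-p) k_inh inhibitory independent Poisson inputs at rate nu; the mean
    output rate over ``trials`` independent realizations is recorded.
    """
    from .simulator import simulate
    if len(rate_grid) == 0:
        raise ValueError("rate grid must be non-empty")
    n_exc = max(int(round((1.0 - p_loss) * k_exc)), 0)
    n_inh = max(int(round((1.0 - p_loss) * k_inh)), 0)
    chan = channels or {}
    out_rates, errs = [], []
    for gi, nu in enumerate(rate_grid):
        rates = []
        for tr in range(trials):
            pops = [Population("N", 1, cell_type, params=cell, **chan)]
            projs = []
            if n_exc and nu > 0:
                pops.append(Population("E", n_exc, "source",
                                       source={"kind": "poisson", "rate": nu}))
                projs.append(Projection("E", "N", {"kind": "all_to_all"},
                                        synapse_exc,
                                        {"kind": "constant", "d": 1.0}))
            if n_inh and nu > 0:
                pops.append(Population("I", n_inh, "source",
                                       source={"kind": "poisson", "rate": nu}))
                projs.append(Projection("I", "N", {"kind": "all_to_all"},
                                        synapse_inh,
                                        {"kind": "constant", "d": 1.0}))
            net = NetworkSpec(pops, projs).instantiate(seed)
            res = simulate(net, duration, dt=dt,
                           seed=int(np.random.SeedSequence(
                               [seed, gi, tr]).generate_state(1)[0] % (2 ** 31)))
            rates.append(res.spikes.n_spikes("N") / (duration / 1000.0))
        out_rates.append(float(np.mean(rates)))
        errs.append(float(np.std(rates) / np.sqrt(max(len(rates), 1))))
    return GainFunction(cell_type, np.asarray(rate_grid, float),
                        np.asarray(out_rates), np.asarray(errs),
                        context={"k_exc": k_exc, "k_inh": k_inh,
                                 "p_loss": p_loss, "trials": trials})


def self_consistent_rate(g: GainFunction) -> float:
    """Stable fixed point of the gain function: nu* with g(nu*) = nu* and
    g'(nu*) < 1, located by sign-change bracketing on the grid followed by
    bisection on the linear interpolant."""
    nu = g.rates_in
    f = g.rates_out - nu
    crossings = []
    for i in range(len(nu) - 1):
        if f[i] >= 0 and f[i + 1] < 0:
            # downward crossing of g(nu) - nu: stable (slope < 1)
            crossings.append(i)
    if not crossings:
        if f[0] == 0.0 and np.all(f[1:] < 0):
            return float(nu[0])      # fixed point sits exactly on the grid edge
        raise CompensationError("no self-sustained solution "
                                "(gain function never crosses the diagonal)")
    i = crossings[-1]
    lo, hi = nu[i], nu[i + 1]
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if g(mid) - mid > 0:
            lo = mid
        else:
            hi = mid
    return float(0.5 * (lo + hi))


def rescale_time(net: NetworkSpec, lam: float,
                 scale_weights: bool = True) -> NetworkSpec:
    """Apply the time-rescaling transition x(t) -> x(lambda t).

    All characteristic times contract by lambda: the membrane time constant
    via g_L (C_m fixed), the synaptic and adaptation time constants, the
    refractory period and every synaptic delay; current-like quantities
    (the spike-triggered adaptation increment b) scale with lambda.

    With ``scale_weights=True`` (default) the conductance jump per
    presynaptic spike also scales with lambda, which makes the mapping
    exact: the rescaled autonomous system reproduces the original spike
    pattern with all times divided by lambda, and every firing rate is
    multiplied by lambda.  ``scale_weights=False`` keeps the jumps
    untouched (convenient on substrates where weights are the scarce
    configurable resource) at the price of the mapping — and hence the
    rate prediction — becoming approximate.
    """
    if lam <= 0:
        raise CompensationError("lambda must be positive")
    out = net.copy()
    for pop in out.populations:
        if pop.is_source:
            continue
        p = pop.params
        pop.params = p.with_(g_l=p.g_l * lam, a=p.a * lam, b=p.b * lam,
                             tau_w=p.tau_w / lam, tau_ref=p.tau_ref / lam)
        pop.tau_syn_exc /= lam
        pop.tau_syn_inh /= lam
    for proj in out.projections:
        w = proj.synapse.weight * (lam if scale_weights else 1.0)
        proj.synapse = proj.synapse.with_(
            weight=w, tau_syn=proj.synapse.tau_syn / lam)
        if proj.delay.get("kind") == "constant":
            proj.delay = dict(proj.delay, d=proj.delay["d"] / lam)
        elif proj.delay.get("kind") == "velocity":
            proj.delay = dict(proj.delay, v=proj.delay["v"] * lam,
                              min=proj.delay.get("min", 0.1) / lam)
    if out.connections is not None:
        for conn in out.connections:
            conn.delay = conn.delay / lam
            if scale_weights:
                conn.weight = conn.weight * lam
    out.meta.setdefault("compensations", []).append(
        {"kind": "time_rescaling", "lambda": lam,
         "scale_weights": scale_weights})
    return out


def mean_field_compensate(net: NetworkSpec, g_ref: GainFunction,
                          g_dist: GainFunction) -> Tuple[NetworkSpec, float]:
    """Restore the self-sustained rate of a distorted network by rescaling
    its dynamics in time.

    lambda is the ratio of the reference fixed point to the distorted one;
    running the distorted dynamics lambda-times adjusted shifts its
    self-consistent rate onto the reference value.
    """
    nu_ref = self_consistent_rate(g_ref)
    nu_dist = self_consistent_rate(g_dist)
    if nu_dist <= 0:
        raise CompensationError("distorted gain function has no positive fixed point")
    lam = nu_ref / nu_dist
    out = rescale_time(net, lam)
    return out, lam


# ---------------------------------------------------------------------------
# iterative per-neuron compensation
# ---------------------------------------------------------------------------

@dataclass
class IterationTrace:
    mean_rate: List[float] = field(default_factory=list)
    cv_rates: List[float] = field(default_factory=list)
    max_shift: List[float] = field(default_factory=list)
    converged: bool = False
    aborted: bool = False

    def as_dict(self) -> dict:
        return {"mean_rate": self.mean_rate, "cv_rates": self.cv_rates,
                "max_shift": self.max_shift, "converged": self.converged,
                "aborted": self.aborted}


def iterative_compensate(net_distorted: NetworkSpec, nu_target: float,
                         alpha: float = 0.1, n_iter: int = 10,
                         simulate_fn: Optional[Callable[[NetworkSpec, int], SpikeData]] = None,
                         seed: int = 0,
                         populations: Optional[Sequence[str]] = None,
                         t_transient: float = 500.0,
                         duration: float = 2000.0, dt: float = 0.1,
                         deadband: float = 0.0
                         ) -> Tuple[NetworkSpec, IterationTrace]:
    """Per-neuron threshold calibration toward a target rate.

    Each iteration simulates the frozen distorted network, measures each
    neuron's rate nu_i over the post-transient window, and shifts its spike
    initiation threshold by ``alpha (nu_i - nu_target)`` mV (too-fast
    neurons get a higher threshold).  Requires fixed-pattern distortions:
    the instantiated synapse list is reused unchanged across iterations.

    Aborts (with the partial trace) if the absolute mean-rate error grows
    over three consecutive iterations.
    """
    net = net_distorted.copy()
    net.require_instantiated()
    if simulate_fn is None:
        from .simulator import simulate

        def simulate_fn(n: NetworkSpec, s: int) -> SpikeData:
            return simulate(n, duration, dt=dt, seed=s).spikes

    pops = populations
    if pops is None:
        pops = [p.name for p in net.populations if not p.is_source]
    ids = np.concatenate([net.global_ids(p) for p in pops])
    shifts = np.zeros(ids.size)
    base_vt = np.concatenate([
        np.full(net.population(p).size, net.population(p).params.v_t)
        for p in pops])
    # honour pre-existing overrides as the starting point
    for k, gid in enumerate(ids):
        if "v_t" in net.overrides and int(gid) in net.overrides["v_t"]:
            shifts[k] = net.overrides["v_t"][int(gid)] - base_vt[k]

    trace = IterationTrace()
    errors: List[float] = []
    seeds = np.random.SeedSequence(seed).generate_state(n_iter) % (2 ** 31)
    for it in range(n_iter):
        spikes = simulate_fn(net, int(seeds[it]))
        window = (spikes.duration - t_transient) / 1000.0
        rates = np.zeros(ids.size)
        for k, gid in enumerate(ids):
            t = spikes.train(int(gid))
            rates[k] = np.count_nonzero(t >= t_transient) / window
        mean_rate = float(rates.mean())
        cv = float(rates.std() / mean_rate) if mean_rate > 0 else float("inf")
        err = abs(mean_rate - nu_target)
        trace.mean_rate.append(mean_rate)
        trace.cv_rates.append(cv)
        errors.append(err)
        stalled = (len(errors) >= 4
                   and all(errors[-j] >= errors[-j - 1] - 1e-9 for j in (1, 2, 3))
                   and errors[-1] > errors[0])
        if stalled:
            # error has grown past the starting point and stopped improving
            trace.aborted = True
            break
        delta = rates - nu_target
        delta[np.abs(delta) < deadband] = 0.0
        shifts = shifts + alpha * delta
        trace.max_shift.append(float(np.max(np.abs(shifts))))
        net.set_override("v_t", ids, base_vt + shifts)
    trace.converged = (not trace.aborted and len(trace.mean_rate) > 0
                       and abs(trace.mean_rate[-1] - nu_target)
                       <= 0.05 * max(nu_target, 1e-9))
    return net, trace
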