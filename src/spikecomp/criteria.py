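"""Functionality criteria: attractor episodes, pulse-packet state space,
separatrix fitting, and asynchronous-irregular statistics.

Each benchmark network is judged by the measures its original study used:

* attractor memory — dwell times of automatically detected attractor
  episodes, competition time, UP/DOWN membrane averages;
* synfire chain — the (sigma, a) volley descriptors per group, propagation
  success at the last group, and the separatrix between surviving and
  extinguished stimuli;
* AI network — survival, mean/CV of rates, CV_ISI, pairwise correlation
  coefficient and the non-zero peak of the population-rate power spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import periodogram

from .simulator import VoltageTraces
from .spikes import SpikeData


# ---------------------------------------------------------------------------
# attractor memory criteria
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AttractorEpisode:
    pattern: int
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("episode must have positive length")

    @property
    def dwell(self) -> float:
        return self.t_end - self.t_start


def detect_attractors(spikes: SpikeData,
                      patterns: Mapping[int, Sequence[int]],
                      bin_ms: float = 5.0,
                      smooth_ms: float = 20.0,
                      lambda_on: float = 3.0,
                      lambda_off: float = 2.0,
                      min_dwell: float = 20.0) -> List[AttractorEpisode]:
    """Detect active-attractor episodes from pyramidal spike data.

    ``patterns`` maps a pattern id to the global ids of its PYR members.
    The per-pattern population rate is binned and smoothed with a Gaussian
    kernel; a pattern becomes active when its rate exceeds ``lambda_on``
    times the all-pattern mean rate and stays active until it drops below
    ``lambda_off`` times the mean (hysteresis).  Simultaneously
    super-threshold patterns are resolved winner-take-all by rate, so
    episodes never overlap.  Episodes shorter than ``min_dwell`` are
    discarded as detection noise.
    """
    duration = spikes.duration
    edges = np.arange(0.0, duration + bin_ms, bin_ms)
    n_bins = edges.size - 1
    ids = sorted(patterns)
    rates = np.zeros((len(ids), n_bins))
    for k, pid in enumerate(ids):
        members = patterns[pid]
        pooled = [spikes.train(i) for i in members]
        pooled = [t for t in pooled if t.size]
        if pooled:
            counts, _ = np.histogram(np.concatenate(pooled), edges)
            rates[k] = counts / (len(members) * bin_ms / 1000.0)
    if smooth_ms > 0:
        rates = gaussian_filter1d(rates, smooth_ms / bin_ms, axis=1)
    grand_mean = rates.mean()
    if grand_mean <= 0:
        return []
    on_thr = lambda_on * grand_mean
    off_thr = lambda_off * grand_mean

    episodes: List[AttractorEpisode] = []
    active: Optional[int] = None
    start = 0.0
    for b in range(n_bins):
        t = edges[b]
        col = rates[:, b]
        if active is None:
            k = int(np.argmax(col))
            if col[k] >= on_thr:
                active, start = k, t
        else:
            challenger = int(np.argmax(col))
            if col[active] < off_thr:
                if t > start:
                    episodes.append(AttractorEpisode(ids[active], start, t))
                active = None
                if col[challenger] >= on_thr:
                    active, start = challenger, t
            elif (challenger != active and col[challenger] >= on_thr
                  and col[challenger] > col[active]):
                # winner-take-all switch
                episodes.append(AttractorEpisode(ids[active], start, t))
                active, start = challenger, t
    if active is not None and duration > start:
        episodes.append(AttractorEpisode(ids[active], start, duration))
    return [e for e in episodes if e.dwell >= min_dwell]


def dwell_and_competition(episodes: Sequence[AttractorEpisode],
                          duration: float) -> Tuple[np.ndarray, float]:
    """Dwell times of all episodes and total competition time (the part of
    the record with no active attractor)."""
    dwells = np.asarray([e.dwell for e in episodes])
    return dwells, duration - float(dwells.sum())


def up_down_voltage_profile(traces: VoltageTraces,
                            episodes: Sequence[AttractorEpisode],
                            parent: Mapping[int, int],
                            n_multiples: float = 3.0,
                            n_points: int = 61) -> Dict[str, np.ndarray]:
    """Average PYR membrane voltage around active periods of the parent
    attractor (UP) and of foreign attractors (DOWN).

    The abscissa is expressed in multiples of the mean dwell time, from
    ``-n_multiples`` (before activation) to ``+n_multiples`` after; the
    window [0, 1] covers the active period itself.  ``parent`` maps a
    recorded neuron id to its home pattern.
    """
    if not episodes:
        raise ValueError("no attractor episodes to average over")
    mean_dwell = float(np.mean([e.dwell for e in episodes]))
    axis = np.linspace(-n_multiples, 1.0 + n_multiples, n_points)
    t = traces.times
    acc = {"up": np.zeros(n_points), "down": np.zeros(n_points)}
    cnt = {"up": np.zeros(n_points), "down": np.zeros(n_points)}
    for nid, v in traces.traces.items():
        home = parent.get(nid)
        if home is None:
            continue
        for ep in episodes:
            key = "up" if ep.pattern == home else "down"
            # sample times in units of mean dwell relative to episode start,
            # with the episode itself mapped onto [0, 1]
            for j, x in enumerate(axis):
                if 0.0 <= x <= 1.0:
                    ts = ep.t_start + x * ep.dwell
                else:
                    ts = (ep.t_start if x < 0 else ep.t_end) + \
                        (x if x < 0 else x - 1.0) * mean_dwell
                if t[0] <= ts <= t[-1]:
                    vi = np.interp(ts, t, v)
                    acc[key][j] += vi
                    cnt[key][j] += 1
    out = {"axis": axis}
    for key in ("up", "down"):
        with np.errstate(invalid="ignore"):
            out[key] = np.where(cnt[key] > 0, acc[key] / np.maximum(cnt[key], 1),
                                np.nan)
    out["mean_dwell"] = np.asarray([mean_dwell])
    return out


# ---------------------------------------------------------------------------
# population-rate power spectrum
# ---------------------------------------------------------------------------

def rate_spectrum(spikes: SpikeData, population: str | None = None,
                  bin_ms: float = 1.0, smooth_hz: float = 2.0,
                  f_min: float = 2.0, t_start: float = 0.0
                  ) -> Dict[str, np.ndarray | float | None]:
    """Power spectral density of the binned population rate and the
    location of its non-zero peak (argmax of the Gaussian-smoothed PSD
    above ``f_min``).  Returns ``peak=None`` for silent data."""
    if population is not None:
        pooled = spikes.population_spikes(population)
    else:
        parts = [t for t in spikes.trains.values() if t.size]
        pooled = np.sort(np.concatenate(parts)) if parts else np.empty(0)
    pooled = pooled[pooled >= t_start]
    if pooled.size < 10:
        return {"freqs": np.empty(0), "psd": np.empty(0),
                "psd_smooth": np.empty(0), "peak": None}
    edges = np.arange(t_start, spikes.duration + bin_ms, bin_ms)
    counts, _ = np.histogram(pooled, edges)
    fs = 1000.0 / bin_ms
    freqs, psd = periodogram(counts - counts.mean(), fs=fs)
    df = freqs[1] - freqs[0] if freqs.size > 1 else 1.0
    psd_smooth = gaussian_filter1d(psd, max(smooth_hz / df, 1e-9))
    sel = freqs > f_min
    if not np.any(sel):
        return {"freqs": freqs, "psd": psd, "psd_smooth": psd_smooth, "peak": None}
    peak = float(freqs[sel][np.argmax(psd_smooth[sel])])
    return {"freqs": freqs, "psd": psd, "psd_smooth": psd_smooth, "peak": peak}


# ---------------------------------------------------------------------------
# synfire chain criteria
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StateSpacePoint:
    """Volley descriptor of one synfire group: activation ``a`` (spikes per
    RS neuron) and temporal spread ``sigma`` (ms; NaN when undefined)."""

    a: float
    sigma: float
    group: int = 0

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError("activation must be non-negative")

    @property
    def fired(self) -> bool:
        return self.a > 0


def measure_pulse_packet(spikes: SpikeData, group: str, window: Tuple[float, float],
                         group_index: int = 0, n_rs: Optional[int] = None
                         ) -> StateSpacePoint:
    """Measure (a, sigma) of a group's response volley inside ``window``.

    ``a`` is the spike count divided by the RS population size; ``sigma``
    the sample standard deviation of the spike times.  A silent group
    yields a = 0 with sigma = NaN (flagged, not an error).
    """
    lo, hi = spikes.populations[group]
    size = n_rs if n_rs is not None else hi - lo
    times = spikes.population_spikes(group)
    t = times[(times >= window[0]) & (times < window[1])]
    if t.size == 0:
        return StateSpacePoint(a=0.0, sigma=float("nan"), group=group_index)
    sigma = float(t.std(ddof=1)) if t.size > 1 else 0.0
    return StateSpacePoint(a=t.size / size, sigma=sigma, group=group_index)


def classify_propagation(last_group: StateSpacePoint,
                         threshold: float = 0.5) -> bool:
    """Successful propagation iff the last group's activation reaches the
    threshold (closed boundary; a clusters near 0 and 1 in the undistorted
    chain, so the cut sits between the two fixed points)."""
    return last_group.a >= threshold


def spike_filter(spikes: SpikeData, window_ms: float = 2.0,
                 min_coactive: int = 10,
                 populations: Optional[Sequence[str]] = None) -> SpikeData:
    """Remove spikes that do not belong to a volley.

    A spike survives if at least ``min_coactive`` spikes of the same
    population (itself included) fall within ``+- window_ms``.  Volleys are
    dense enough to always pass; spontaneous background spikes are isolated
    and removed.  The filter is idempotent on its own output for any volley
    that passes intact.
    """
    pops = populations if populations is not None else list(spikes.populations)
    out_trains: Dict[int, np.ndarray] = {}
    for pop in pops:
        lo, hi = spikes.populations[pop]
        pooled = spikes.population_spikes(pop)
        if pooled.size == 0:
            continue
        for i in range(lo, hi):
            t = spikes.train(i)
            if t.size == 0:
                continue
            left = np.searchsorted(pooled, t - window_ms, side="left")
            right = np.searchsorted(pooled, t + window_ms, side="right")
            keep = (right - left) >= min_coactive
            if np.any(keep):
                out_trains[i] = t[keep]
    return SpikeData(out_trains, dict(spikes.populations), spikes.duration)


@dataclass
class Separatrix:
    """Boundary between surviving and extinguished stimuli in the
    (sigma, a) plane: a(sigma) at 50% success probability, plus the width
    of the transition band (5%-95%)."""

    coef_sigma: np.ndarray      # polynomial coefficients on sigma
    coef_a: float               # coefficient on a
    intercept: float
    degree: int
    transition_width: float

    def boundary(self, sigma: np.ndarray) -> np.ndarray:
        """a at which the success probability crosses 1/2."""
        sigma = np.asarray(sigma, dtype=float)
        poly = sum(c * sigma ** (k + 1) for k, c in enumerate(self.coef_sigma))
        return -(self.intercept + poly) / self.coef_a

    def predict(self, sigma: np.ndarray, a: np.ndarray) -> np.ndarray:
        sigma, a = np.asarray(sigma, float), np.asarray(a, float)
        poly = sum(c * sigma ** (k + 1) for k, c in enumerate(self.coef_sigma))
        z = self.intercept + poly + self.coef_a * a
        return 1.0 / (1.0 + np.exp(-z))


def fit_separatrix(samples: Sequence[Tuple[float, float, bool]],
                   degree: int = 2) -> Separatrix:
    """Fit the separatrix by logistic regression of success on
    (sigma, sigma^2, ..., a).  Requires both outcome classes.

    The 50% probability contour is the boundary; the transition width is
    the mean vertical (a-direction) distance between the 5% and 95%
    contours, which for a logistic model is ``2 ln(19) / |coef_a|``.
    """
    arr = np.asarray([(s, a, bool(y)) for s, a, y in samples], dtype=float)
    if arr.size == 0:
        raise ValueError("no samples")
    y = arr[:, 2].astype(bool)
    if y.all() or (~y).all():
        raise ValueError("need both successful and extinguished samples")
    sigma, a = arr[:, 0], arr[:, 1]
    X = np.column_stack([sigma ** (k + 1) for k in range(degree)] + [a])
    from sklearn.linear_model import LogisticRegression
    clf = LogisticRegression(C=1e4, max_iter=5000)
    clf.fit(X, y.astype(int))
    coef = clf.coef_[0]
    coef_a = float(coef[-1])
    width = float(2.0 * np.log(19.0) / abs(coef_a)) if coef_a != 0 else np.inf
    return Separatrix(coef_sigma=coef[:degree].copy(), coef_a=coef_a,
                      intercept=float(clf.intercept_[0]), degree=degree,
                      transition_width=width)


# ---------------------------------------------------------------------------
# asynchronous-irregular statistics
# ---------------------------------------------------------------------------

@dataclass
class AIStats:
    mean_rate: float
    cv_rates: float
    cv_isi: float
    cc: float
    spectrum_peak: Optional[float]
    survived: bool

    def as_dict(self) -> dict:
        return {"mean_rate": self.mean_rate, "cv_rates": self.cv_rates,
                "cv_isi": self.cv_isi, "cc": self.cc,
                "spectrum_peak": self.spectrum_peak,
                "survived": bool(self.survived)}


def ai_statistics(spikes: SpikeData, population: str = "PY",
                  t_start: float = 500.0, bin_ms: float = 2.0,
                  n_pairs: int = 1000, survival_window: float = 100.0,
                  spectrum_bin_ms: float = 1.0, seed: int = 0) -> AIStats:
    """Compute the AI-state criteria for one simulation.

    survived    — the network still emits spikes in the final
                  ``survival_window`` ms of the record;
    mean_rate   — mean per-neuron rate (Hz) over [t_start, duration];
    cv_rates    — std/mean of the per-neuron rates;
    cv_isi      — mean over neurons (with >= 3 ISIs) of the per-neuron
                  ISI std/mean;
    cc          — mean pairwise Pearson correlation of spike counts in
                  ``bin_ms`` bins over ``n_pairs`` random pairs;
    spectrum_peak — non-zero peak of the population-rate PSD.
    """
    duration = spikes.duration
    last = spikes.last_spike_time()
    survived = last is not None and last >= duration - survival_window
    rates = spikes.rates(population, t_start, duration)
    if rates.sum() == 0:
        return AIStats(0.0, 0.0, float("nan"), float("nan"), None, survived)
    mean_rate = float(rates.mean())
    cv_rates = float(rates.std() / mean_rate) if mean_rate > 0 else 0.0

    lo, hi = spikes.populations[population]
    cvs = []
    for i in range(lo, hi):
        t = spikes.train(i)
        t = t[t >= t_start]
        if t.size >= 4:
            isi = np.diff(t)
            cvs.append(isi.std() / isi.mean())
    cv_isi = float(np.mean(cvs)) if cvs else float("nan")

    rng = np.random.default_rng(seed)
    ids = [i for i in range(lo, hi) if spikes.train(i).size >= 3]
    edges = np.arange(t_start, duration + bin_ms, bin_ms)
    cc = float("nan")
    if len(ids) >= 2:
        n_pick = min(len(ids), max(2, int(np.sqrt(2 * n_pairs)) + 1))
        picked = rng.choice(ids, size=n_pick, replace=False)
        counts = np.stack([np.histogram(spikes.train(i), edges)[0] for i in picked])
        sd = counts.std(axis=1)
        ok = sd > 0
        counts, sd = counts[ok], sd[ok]
        if counts.shape[0] >= 2:
            ccs = []
            m = counts.shape[0]
            pairs_seen = 0
            centered = counts - counts.mean(axis=1, keepdims=True)
            for i in range(m):
                for j in range(i + 1, m):
                    ccs.append(float(np.dot(centered[i], centered[j])
                                     / (counts.shape[1] * sd[i] * sd[j])))
                    pairs_seen += 1
                    if pairs_seen >= n_pairs:
                        break
                if pairs_seen >= n_pairs:
                    break
            cc = float(np.mean(ccs))

    spec = rate_spectrum(spikes, population, bin_ms=spectrum_bin_ms,
                         t_start=t_start)
    return AIStats(mean_rate, cv_rates, cv_isi, cc, spec["peak"], survived)
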