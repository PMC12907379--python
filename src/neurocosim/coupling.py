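"""Bidirectional spike<->rate translation and the epoch exchange loop.

The micro (spiking) and macro (mean-field) models advance in *epochs* no
longer than the smallest inter-region conduction delay tau_min.  Within an
epoch both sides integrate independently; at the boundary they exchange

  micro -> macro : the population activity nu_P(t), computed from spikes
                   either by binning (count / (N dt)) or through an
                   exponential calcium-like kernel, scaled by the gain
                   G_A and driving the proxy region's gating variable;
  macro -> micro : synthetic spike events whose intensity follows each
                   connected region's mean rate, dispatched to every cell
                   after a fixed cross-scale delay >= tau_min.

Because every cross-boundary influence carries a delay of at least
tau_min >= epoch length, the exchange is exact: the coupled trajectories
do not depend on the epoch length (bit-identical traces when the exchange
interval is halved, in deterministic event mode).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .connectome import Connectome
from .macro_rww import RwwNetwork, RwwParams, min_delay
from .micro_net import MicroNetwork, SpikeEvent


# ---------------------------------------------------------------------------
# spike -> rate converters


def spikes_to_rate_binned(spike_times, n_cells: int, bin_width: float,
                          window: tuple[float, float]) -> np.ndarray:
    """Per-bin population rate, spikes / (cell * ms).

    rate[k] = count in bin k / (n_cells * bin_width); the identity
    sum(rate) * n_cells * bin_width == total spike count holds exactly.
    """
    t0, t1 = window
    n_bins_f = (t1 - t0) / bin_width
    n_bins = int(round(n_bins_f))
    if abs(n_bins_f - n_bins) > 1e-9 * max(1.0, abs(n_bins_f)):
        raise ValueError(
            f"bin width {bin_width} does not evenly divide window "
            f"{window}")
    spikes = np.asarray(spike_times, dtype=float)
    if np.any((spikes < t0) | (spikes >= t1)):
        raise ValueError("spikes outside the window")
    idx = np.minimum(((spikes - t0) / bin_width).astype(np.int64),
                     n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return counts / (n_cells * bin_width)


@dataclass
class CalciumParams:
    """Exponential activity kernel: per-spike jump beta, decay tau_ca.

    Each cell's calcium-like trace C_p jumps by ``beta`` at its own spikes
    and decays with time constant ``tau_ca``; the population activity is
    the average <C_p> over cells, so each population spike contributes
    beta/N -- the normalisation that makes the measure independent of the
    cell count N.
    """

    tau_ca: float = 100.0  # ms
    beta: float = 0.1      # per-spike increment (per cell)

    def __post_init__(self) -> None:
        if self.tau_ca <= 0 or self.beta <= 0:
            raise ValueError("tau_ca and beta must be positive")


@dataclass
class CalciumState:
    """Aggregated population calcium sum_p C_p at time t_last."""

    total: float = 0.0
    t_last: float = 0.0


def spikes_to_rate_calcium(spike_times, n_cells: int,
                           params: CalciumParams,
                           sample_times: np.ndarray,
                           state: CalciumState | None = None) -> np.ndarray:
    """Event-driven exact population activity on a sample grid.

    Exploits linearity of the average: the population sum A = sum_p C_p
    decays exponentially between spikes and jumps by ``beta`` at every
    spike of any cell, so nu_P(t) = A(t)/N.  Equals the closed form
    (beta/N) * sum_{t_s <= t} exp(-(t - t_s)/tau) to floating-point
    accuracy.  Passing a ``state`` carries the population calcium across
    successive calls (epochs); it is updated in place.  The state stays
    anchored at the last spike, so splitting a spike train over several
    calls is bit-for-bit identical to one call.
    """
    st = state if state is not None else CalciumState(
        0.0, float(sample_times[0]) if len(sample_times) else 0.0)
    spikes = np.sort(np.asarray(spike_times, dtype=float))
    out = np.empty(len(sample_times))
    tau = params.tau_ca
    i = 0
    a, t_last = st.total, st.t_last
    for k, ts in enumerate(np.asarray(sample_times, dtype=float)):
        while i < spikes.size and spikes[i] <= ts:
            a *= math.exp(-(spikes[i] - t_last) / tau)
            a += params.beta
            t_last = spikes[i]
            i += 1
        out[k] = a * math.exp(-(ts - t_last) / tau) / n_cells
    while i < spikes.size:  # spikes past the last sample still count
        a *= math.exp(-(spikes[i] - t_last) / tau)
        a += params.beta
        t_last = spikes[i]
        i += 1
    if state is not None:
        state.total, state.t_last = a, t_last
    return out


# ---------------------------------------------------------------------------
# rate -> events


@dataclass
class TranslationConfig:
    """Gains, modes and seeds of the cross-scale translation layer."""

    spike_to_rate: str = "calcium"        # "binned" | "calcium"
    bin_width: float = 0.1                # ms; binned mode (= dt_macro)
    calcium: CalciumParams = field(default_factory=CalciumParams)
    G_A: float = 100.0                    # proxy output gain
    kappa_in: float = 1.0                 # input event intensity gain
    n_equiv: float = 1.0                  # source-population equivalent
    event_mode: str = "deterministic_carry"  # | "poisson"
    w_ext: float = 0.5                    # weight of injected events
    ext_delay: float | None = None        # ms; default: tau_min
    proxy_mode: str = "rate_substitution"  # | "direct"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.G_A <= 0:
            raise ValueError("G_A must be positive")
        if self.spike_to_rate not in ("binned", "calcium"):
            raise ValueError(f"unknown converter {self.spike_to_rate!r}")
        if self.event_mode not in ("deterministic_carry", "poisson"):
            raise ValueError(f"unknown event mode {self.event_mode!r}")
        if self.proxy_mode not in ("rate_substitution", "direct"):
            raise ValueError(f"unknown proxy mode {self.proxy_mode!r}")


def rate_to_events(nu, source: int, c_ip: float, config: TranslationConfig,
                   dt_macro: float, t0: float,
                   rng: np.random.Generator | None = None,
                   carry: float = 0.0):
    """Synthetic events whose intensity follows a region's rate series.

    For macro step k the expected count is
    lambda_k = kappa_in * c_ip * nu[k] * dt_macro * n_equiv; the count is
    Poisson(lambda_k) in "poisson" mode or floor(lambda_k + carry) with
    carry propagation in "deterministic_carry" mode.  Event times lie
    within step k (uniform draws, or evenly spaced in deterministic mode).

    Returns (event_times, new_carry).
    """
    nu = np.asarray(nu, dtype=float)
    if np.any(nu < 0):
        raise ValueError("rates must be nonnegative")
    if c_ip == 0.0:
        return np.empty(0), carry
    lam = config.kappa_in * c_ip * nu * dt_macro * config.n_equiv
    times = []
    if config.event_mode == "poisson":
        if rng is None:
            raise ValueError("poisson mode requires an rng")
        counts = rng.poisson(lam)
        for k, c in enumerate(counts):
            if c:
                times.append(t0 + (k + rng.random(c)) * dt_macro)
    else:
        for k, lk in enumerate(lam):
            carry += lk
            c = int(math.floor(carry))
            carry -= c
            if c:
                offs = (np.arange(1, c + 1)) / (c + 1)
                times.append(t0 + (k + offs) * dt_macro)
    if times:
        return np.concatenate(times), carry
    return np.empty(0), carry


# ---------------------------------------------------------------------------
# proxy drive


@dataclass
class ProxyGate:
    """Synaptic gating of the proxy region driven by micro activity.

    In the default ``rate_substitution`` mode the micro activity nu_P
    (spikes/ms/cell) scaled by G_A plays the role of the region's firing
    rate H_P (kHz; the two scales coincide numerically) in the gating
    equation dS/dt = -S/tau_s + (1-S) gamma H_P, which keeps S in [0, 1].
    In ``direct`` mode S_P = clip(G_A nu_P, 0, 1).
    """

    params: RwwParams
    G_A: float = 100.0
    mode: str = "rate_substitution"
    S: float = 0.0

    def step_series(self, nu: np.ndarray, dt: float) -> np.ndarray:
        """Advance over one epoch of macro steps; returns S_P per step."""
        p = self.params
        out = np.empty(len(nu))
        s = self.S
        if self.mode == "direct":
            out = np.clip(self.G_A * np.asarray(nu), 0.0, 1.0)
            s = float(out[-1]) if len(out) else s
        else:
            for k, v in enumerate(np.asarray(nu)):
                h = self.G_A * v
                s = s + dt * (-s / p.tau_s + (1.0 - s) * p.gamma_kin * h)
                s = min(max(s, 0.0), 1.0)
                out[k] = s
        self.S = s
        return out

    def fixed_point(self, nu: float) -> float:
        """Equilibrium S for a constant drive (rate_substitution mode)."""
        p = self.params
        g = p.gamma_kin * self.G_A * nu
        return g / (1.0 / p.tau_s + g)


# ---------------------------------------------------------------------------
# the co-simulation loop


@dataclass
class EpochSchedule:
    """Exchange interval and the two integration steps.

    The epoch must not exceed the connectome's smallest conduction delay
    and must be an integer multiple of both dt_micro and dt_macro.
    """

    epoch_length: float
    dt_micro: float = 0.05
    dt_macro: float = 0.1

    def __post_init__(self) -> None:
        for name, dt in (("dt_micro", self.dt_micro),
                         ("dt_macro", self.dt_macro)):
            k = self.epoch_length / dt
            if abs(k - round(k)) > 1e-9 * max(1.0, k):
                raise ValueError(
                    f"{name}={dt} must evenly divide epoch_length="
                    f"{self.epoch_length}")

    @property
    def steps_micro(self) -> int:
        return int(round(self.epoch_length / self.dt_micro))

    @property
    def steps_macro(self) -> int:
        return int(round(self.epoch_length / self.dt_macro))


@dataclass
class CoSimResult:
    """Full coupled traces of one co-simulation run."""

    t_macro: np.ndarray          # macro sample times (ms)
    nu_P: np.ndarray             # proxy activity per macro step
    S_proxy: np.ndarray          # proxy gating fed to the macro network
    S: np.ndarray                # (steps, regions) gating
    H: np.ndarray                # (steps, regions) rates (kHz)
    spike_times: np.ndarray      # micro raster
    spike_cells: np.ndarray
    exchange_log: list = field(default_factory=list)


class CoSimulation:
    """Epoch-synchronised in-process co-simulation micro <-> macro.

    Per epoch: (1) the micro network advances, consuming the external
    events generated from the previous macro epoch; (2) its spikes are
    converted to the proxy activity nu_P on the macro grid; (3) the macro
    network advances the same epoch with the proxy gating substituted;
    (4) the macro rates of regions connected to the proxy are converted to
    events for later delivery (fixed cross-scale delay >= tau_min).
    """

    def __init__(self, micro: MicroNetwork, conn: Connectome,
                 params: RwwParams | None = None,
                 schedule: EpochSchedule | None = None,
                 config: TranslationConfig | None = None,
                 macro: RwwNetwork | None = None,
                 zero_delay_replacement: float = 1.0):
        if conn.proxy_region is None:
            raise ValueError("connectome must designate a proxy region")
        self.micro = micro
        self.conn = conn
        self.config = config or TranslationConfig()
        params = params or RwwParams()
        tau_min = min_delay(conn, zero_delay_replacement)
        self.schedule = schedule or EpochSchedule(epoch_length=tau_min)
        if self.schedule.epoch_length > tau_min + 1e-9:
            raise ValueError(
                f"epoch length {self.schedule.epoch_length} exceeds "
                f"tau_min={tau_min}")
        self.macro = macro or RwwNetwork(
            conn, params, dt=self.schedule.dt_macro,
            zero_delay_replacement=zero_delay_replacement)
        self.gate = ProxyGate(params=self.macro.params,
                              G_A=self.config.G_A,
                              mode=self.config.proxy_mode)
        self._ca_state = CalciumState(0.0, micro.time)
        self._carry = np.zeros(conn.n_regions)
        ss = np.random.SeedSequence(self.config.seed)
        self._rngs = [np.random.default_rng(s)
                      for s in ss.spawn(conn.n_regions)]
        self._pending: list[SpikeEvent] = []
        self.ext_delay = (self.config.ext_delay
                          if self.config.ext_delay is not None else tau_min)
        if self.ext_delay < self.schedule.epoch_length - 1e-9:
            raise ValueError("cross-scale delay must cover one epoch")

    def _nu_from_spikes(self, times: np.ndarray, t0: float,
                        t_grid: np.ndarray) -> np.ndarray:
        cfg = self.config
        n = self.micro.n_cells
        if cfg.spike_to_rate == "binned":
            return spikes_to_rate_binned(
                times, n, self.schedule.dt_macro, (t0, float(t_grid[-1])))
        return spikes_to_rate_calcium(times, n, cfg.calcium, t_grid,
                                      state=self._ca_state)

    def run(self, duration: float, record_micro_v: bool = False):
        """Run ``duration`` ms of coupled simulation (whole epochs)."""
        sched = self.schedule
        E = sched.epoch_length
        n_epochs = int(round(duration / E))
        if abs(n_epochs * E - duration) > 1e-6:
            raise ValueError(
                f"duration {duration} must be a whole number of epochs "
                f"({E} ms)")
        proxy = self.conn.proxy_region
        nu_all, sp_all, t_all = [], [], []
        S_all, H_all = [], []
        spike_t, spike_c = [], []
        for e in range(n_epochs):
            t0 = self.micro.time
            t1 = t0 + E
            due = [ev for ev in self._pending if ev.delivery_time < t1]
            self._pending = [ev for ev in self._pending
                             if ev.delivery_time >= t1]
            (times, cells), _ = self.micro.advance(t1, external_events=due)
            spike_t.append(times)
            spike_c.append(cells)
            # sample times from the global macro step index so that the
            # grid is bit-identical for any epoch chunking
            g0 = self.macro._step
            t_grid = (g0 + np.arange(1, sched.steps_macro + 1)) \
                * sched.dt_macro
            nu = self._nu_from_spikes(times, t0, t_grid)
            s_proxy = self.gate.step_series(nu, sched.dt_macro)
            S, H = self.macro.simulate_epoch(E, proxy_series=s_proxy)
            n_events = 0
            for region in range(self.conn.n_regions):
                if region == proxy:
                    continue
                c_ip = self.conn.weights[proxy, region]
                if c_ip == 0.0:
                    continue
                ev_t, self._carry[region] = rate_to_events(
                    H[:, region], region, c_ip, self.config,
                    sched.dt_macro, t0, rng=self._rngs[region],
                    carry=self._carry[region])
                for tt in ev_t:
                    self._pending.append(SpikeEvent(
                        source=region, time=float(tt),
                        weight=self.config.w_ext, delay=self.ext_delay))
                n_events += len(ev_t)
            if not hasattr(self, "exchange_log"):
                self.exchange_log = []
            self.exchange_log.append(dict(
                epoch=e, spikes_sent=int(times.size),
                nu_mean=float(np.mean(nu)) if len(nu) else 0.0,
                events_injected=n_events))
            nu_all.append(nu)
            sp_all.append(s_proxy)
            t_all.append(t_grid)
            S_all.append(S)
            H_all.append(H)
        return CoSimResult(
            t_macro=np.concatenate(t_all),
            nu_P=np.concatenate(nu_all),
            S_proxy=np.concatenate(sp_all),
            S=np.vstack(S_all),
            H=np.vstack(H_all),
            spike_times=np.concatenate(spike_t),
            spike_cells=np.concatenate(spike_c),
            exchange_log=self.exchange_log)
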