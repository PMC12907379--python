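"""Networks of ion-concentration neurons with exponential synapses.

Cells are coupled conductance-based: each incoming spike increments the
target's synaptic conductance ``g_syn`` by the connection weight after the
connection delay, and ``g_syn`` decays exponentially between events.  The
synaptic current density is ``i_syn = g_syn (E_rev - V)``, depolarizing
for the default excitatory reversal of 0 mV.

Networks support a tonic/SLE mixture (two bath-potassium values across the
population), all-to-all or custom topology, fixed or truncated-normal
positive weights, mid-run reconfiguration that preserves cell states and
pending deliveries, and injection of external (cross-scale) events that are
dispatched to every cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ion_neuron import (IonNeuronParams, IonNeuronState, njit,
                         resting_state)


@dataclass
class SynapseParams:
    """Exponential synapse kinetics and internal connection delay."""

    tau_syn: float = 2.0   # decay time constant, ms
    E_rev: float = 0.0     # reversal potential, mV (excitatory)
    delay: float = 1.0     # internal connection delay, ms

    def __post_init__(self) -> None:
        if self.tau_syn <= 0:
            raise ValueError("tau_syn must be positive")
        if self.delay <= 0:
            raise ValueError("delay must be positive")


@dataclass
class SpikeEvent:
    """A delivered or emitted spike with per-connection weight and delay."""

    source: int
    time: float            # emission time, ms
    weight: float = 0.5
    delay: float = 0.0     # delivery = time + delay

    @property
    def delivery_time(self) -> float:
        return self.time + self.delay


@dataclass
class NetworkSpec:
    """Composition and wiring of a micro network.

    ``f`` is the fraction of SLE cells: round(f*N) cells are assigned
    ``kbath_sle``, the remainder ``kbath_tonic``.  SLE cells occupy the
    lowest cell ids.
    """

    N: int = 100
    f: float = 0.2
    kbath_tonic: float = 9.5
    kbath_sle: float = 17.0
    weight_mode: str = "fixed"       # "fixed" | "truncated_normal"
    w: float = 0.5
    weight_mu: float = 0.5
    weight_sigma: float = 0.5
    topology: str = "all_to_all"     # "all_to_all" | "none" | "custom"
    adjacency: np.ndarray | None = None  # used when topology == "custom"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError("N must be positive")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("f must lie in [0, 1]")
        if self.weight_mode not in ("fixed", "truncated_normal"):
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")
        if self.topology not in ("all_to_all", "none", "custom"):
            raise ValueError(f"unknown topology {self.topology!r}")

    @property
    def n_sle(self) -> int:
        return round(self.f * self.N)


def _truncated_normal(rng: np.random.Generator, mu: float, sigma: float,
                      shape) -> np.ndarray:
    """Rejection-sample a normal truncated to strictly positive values."""
    out = rng.normal(mu, sigma, shape)
    bad = out <= 0
    while np.any(bad):
        out[bad] = rng.normal(mu, sigma, int(bad.sum()))
        bad = out <= 0
    return out


def build_weight_matrix(spec: NetworkSpec) -> np.ndarray:
    """Directed weight matrix W[target, source]; zero diagonal."""
    n = spec.N
    rng = np.random.default_rng(spec.seed)
    if spec.topology == "none":
        return np.zeros((n, n))
    if spec.topology == "custom":
        if spec.adjacency is None:
            raise ValueError("custom topology requires an adjacency matrix")
        adj = np.asarray(spec.adjacency, dtype=float)
        if adj.shape != (n, n):
            raise ValueError(
                f"adjacency must be {n}x{n}, got {adj.shape}")
        mask = adj > 0
    else:
        mask = ~np.eye(n, dtype=bool)
    if spec.weight_mode == "fixed":
        w = np.full((n, n), spec.w)
    else:
        w = _truncated_normal(rng, spec.weight_mu, spec.weight_sigma,
                              (n, n))
    w = np.where(mask, w, 0.0)
    np.fill_diagonal(w, 0.0)
    return w


@njit(cache=True)
def _net_kernel(V, n, dki, kg, gsyn, kbath, W, connected, delay_steps,
                n_steps, step0, carry, ext_inc, dt,
                g0K, glK, g0Na, glNa, g0Cl, rho, gamma, eps, beta, pump_kf,
                tau, cm, C, K0i, K0o, Na0i, Na0o, Cl0i, Cl0o,
                tau_syn, e_rev, thresh, sample_every,
                V_out, spk_t, spk_cell):  # pragma: no cover - numba kernel
    """Advance all cells n_steps; returns number of spikes recorded.

    carry: (delay_steps, n_cells) conductance increments scheduled by
    spikes of previous calls, carry[k] applying at local step k.  On exit
    it holds the increments that fall beyond this call.
    """
    n_cells = V.shape[0]
    L = delay_steps + 1
    ring = np.zeros((L, n_cells))
    for k in range(min(delay_steps, n_steps)):
        ring[k % L] = carry[k]
    # increments beyond this call stay in carry (shifted), rest cleared
    for k in range(delay_steps):
        if k < n_steps:
            carry[k, :] = 0.0
    ecl = C * math.log(Cl0i / Cl0o)
    decay = math.exp(-dt / tau_syn)
    n_spk = 0
    max_spk = spk_t.shape[0]
    k_out = 0
    for step in range(n_steps):
        slot = step % L
        for j in range(n_cells):
            gsyn[j] += ring[slot, j] + ext_inc[step]
        ring[slot, :] = 0.0
        for j in range(n_cells):
            v = V[j]
            ki = K0i + dki[j]
            ko = K0o - beta * dki[j] + kg[j]
            nai = Na0i - dki[j]
            nao = Na0o + beta * dki[j]
            if ki <= 0.0 or ko <= 0.0 or nai <= 0.0 or nao <= 0.0:
                V[j] = np.nan
                continue
            ek = C * math.log(ko / ki)
            ena = C * math.log(nao / nai)
            ninf = 1.0 / (1.0 + math.exp(-(19.0 + v) / 18.0))
            minf = 1.0 / (1.0 + math.exp(-(2.0 + v / 12.0)))
            h = 1.1 - 1.0 / (1.0 + math.exp(3.2 - 8.0 * n[j]))
            gk = g0K * n[j] + glK
            gna = g0Na * minf * h + glNa
            ip = rho / ((1.0 + math.exp(10.5 - 0.5 * nai)) *
                        (1.0 + math.exp(5.5 - ko)))
            gtot = gk + gna + g0Cl + gsyn[j]
            vinf = (gk * ek + gna * ena + g0Cl * ecl + gsyn[j] * e_rev
                    - ip) / gtot
            vnew = vinf + (v - vinf) * math.exp(-gtot * dt / cm)
            nnew = ninf + (n[j] - ninf) * math.exp(-dt / tau)
            ik = gk * (v - ek)
            dki[j] += dt * (-gamma * (ik - pump_kf * ip))
            kg[j] += dt * (eps * (kbath[j] - ko))
            if v < thresh <= vnew:
                if n_spk < max_spk:
                    frac = (thresh - v) / (vnew - v)
                    spk_t[n_spk] = (step0 + step + frac) * dt
                    spk_cell[n_spk] = j
                    n_spk += 1
                if connected:
                    target = step + delay_steps
                    if target < n_steps:
                        tslot = target % L
                        for i in range(n_cells):
                            ring[tslot, i] += W[i, j]
                    else:
                        for i in range(n_cells):
                            carry[target - n_steps, i] += W[i, j]
            V[j] = vnew
            n[j] = nnew
            gsyn[j] *= decay
        if sample_every > 0 and (step + 1) % sample_every == 0:
            for j in range(n_cells):
                V_out[k_out, j] = V[j]
            k_out += 1
    return n_spk


class MicroNetwork:
    """All-to-all (or custom) network of ion-concentration neurons.

    The network holds persistent cell states, synaptic conductances and
    pending spike deliveries, so simulation can be paused, reconfigured
    and resumed (``advance`` / ``reconfigure``).
    """

    def __init__(self, spec: NetworkSpec,
                 neuron: IonNeuronParams | None = None,
                 synapse: SynapseParams | None = None,
                 dt: float = 0.05, spike_threshold: float = 0.0,
                 initial_state: IonNeuronState | None = None):
        self.spec = spec
        self.neuron = neuron or IonNeuronParams()
        self.synapse = synapse or SynapseParams()
        self.dt = float(dt)
        self.spike_threshold = float(spike_threshold)
        if self.synapse.delay < dt:
            raise ValueError("synaptic delay must be >= dt")
        self.delay_steps = max(1, int(round(self.synapse.delay / dt)))
        n = spec.N
        self.kbath = np.where(np.arange(n) < spec.n_sle,
                              spec.kbath_sle, spec.kbath_tonic)
        self.W = build_weight_matrix(spec)
        s0 = initial_state or resting_state(self.neuron)
        self.V = np.full(n, s0.V)
        self.n = np.full(n, s0.n)
        self.dki = np.full(n, s0.DeltaK_i)
        self.kg = np.full(n, s0.K_g)
        self.gsyn = np.zeros(n)
        self._carry = np.zeros((self.delay_steps, n))
        self._step = 0
        self.spike_times: list[np.ndarray] = []
        self.spike_cells: list[np.ndarray] = []

    @property
    def time(self) -> float:
        return self._step * self.dt

    @property
    def n_cells(self) -> int:
        return self.spec.N

    def reconfigure(self, new_adjacency: np.ndarray | None = None,
                    topology: str | None = None) -> None:
        """Replace the wiring, keeping cell states and pending deliveries.

        Either pass an explicit weight matrix, or a topology name
        ("all_to_all" | "none") re-wired under the current weight mode.
        """
        n = self.spec.N
        if new_adjacency is not None:
            w = np.asarray(new_adjacency, dtype=float)
            if w.shape != (n, n):
                raise ValueError(f"adjacency must be {n}x{n}, got {w.shape}")
            self.W = w.copy()
            np.fill_diagonal(self.W, 0.0)
        elif topology is not None:
            from dataclasses import replace as _replace

            self.W = build_weight_matrix(
                _replace(self.spec, topology=topology))
        else:
            raise ValueError("give new_adjacency or topology")

    def advance(self, t_until: float,
                external_events: list[SpikeEvent] | None = None,
                sample_every: int = 20):
        """Integrate all cells up to time ``t_until`` (ms).

        ``external_events`` are spikes from outside the network; each is
        dispatched to *every* cell, incrementing its synaptic conductance
        by the event weight at the event's delivery time (which must not
        lie in the past).  Emitted spikes are recorded and also returned
        as (times, cell_ids); the sampled V traces cover this call.
        """
        if t_until < self.time - 1e-9:
            raise ValueError(
                f"t_until={t_until} lies before current time {self.time}")
        n_steps = int(round((t_until - self.time) / self.dt))
        if n_steps == 0:
            return (np.empty(0), np.empty(0, dtype=int)), \
                np.empty((0, self.spec.N))
        ext = np.zeros(n_steps)
        for ev in external_events or ():
            t_d = ev.delivery_time
            rel = t_d - self.time
            step = int(math.floor(rel / self.dt + 1e-9))
            if step < 0:
                raise ValueError(
                    f"external event from source {ev.source} delivers at "
                    f"{t_d} ms, before current time {self.time} ms")
            if step < n_steps:
                ext[step] += ev.weight
            else:
                # beyond this call: fold into the carry if in range,
                # otherwise refuse (caller exchanges per epoch)
                idx = step - n_steps
                if idx < self.delay_steps:
                    self._carry[idx] += ev.weight
                else:
                    raise ValueError(
                        f"external event at {t_d} ms lies beyond the "
                        f"reachable horizon of this advance call")
        n_samples = n_steps // sample_every if sample_every > 0 else 0
        V_out = np.empty((n_samples, self.spec.N))
        max_spk = max(1000, n_steps * max(1, self.spec.N // 4))
        spk_t = np.empty(max_spk)
        spk_cell = np.empty(max_spk, dtype=np.int64)
        p = self.neuron
        connected = bool(np.any(self.W > 0))
        n_spk = _net_kernel(
            self.V, self.n, self.dki, self.kg, self.gsyn, self.kbath,
            self.W, connected, self.delay_steps, n_steps, self._step,
            self._carry, ext, self.dt,
            p.g0_K, p.gl_K, p.g0_Na, p.gl_Na, p.g0_Cl, p.rho,
            p.gamma_flux, p.epsilon, p.beta_vol, p.pump_k_stoich,
            p.tau_gate, p.c_m, p.nernst_prefactor,
            p.K0_i, p.K0_o, p.Na0_i, p.Na0_o, p.Cl0_i, p.Cl0_o,
            self.synapse.tau_syn, self.synapse.E_rev, self.spike_threshold,
            sample_every, V_out, spk_t, spk_cell)
        if np.any(~np.isfinite(self.V)):
            bad = int(np.flatnonzero(~np.isfinite(self.V))[0])
            raise FloatingPointError(
                f"integration failure in cell {bad} "
                f"(K_bath={self.kbath[bad]} mM) before t={t_until} ms")
        self._step += n_steps
        times = spk_t[:n_spk].copy()
        cells = spk_cell[:n_spk].copy()
        self.spike_times.append(times)
        self.spike_cells.append(cells)
        return (times, cells), V_out

    def population_spikes(self, window: tuple[float, float] | None = None):
        """All recorded spikes in [window), ordered by (time, cell id)."""
        if self.spike_times:
            t = np.concatenate(self.spike_times)
            c = np.concatenate(self.spike_cells)
        else:
            t = np.empty(0)
            c = np.empty(0, dtype=int)
        if window is not None:
            m = (t >= window[0]) & (t < window[1])
            t, c = t[m], c[m]
        order = np.lexsort((c, t))
        return t[order], c[order]

    def spikes_per_cell(self, window: tuple[float, float] | None = None):
        t, c = self.population_spikes(window)
        return [t[c == j] for j in range(self.spec.N)]


def synaptic_current(g_syn: float, V: float, E_rev: float) -> float:
    """Conductance-based synaptic current density, depolarizing-positive."""
    if g_syn < 0:
        raise ValueError("g_syn must be nonnegative")
    return g_syn * (E_rev - V)
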