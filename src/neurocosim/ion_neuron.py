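"""Single-compartment neuron with slow ion-concentration dynamics.

The model couples a reduced Hodgkin-Huxley fast subsystem (membrane
potential ``V`` and a single potassium gating variable ``n``) to slow
bookkeeping of intra/extracellular potassium and sodium.  The cell sits in
a bath that buffers extracellular potassium at a fixed concentration
``K_bath``; this single parameter moves the neuron through a sequence of
firing regimes: resting state (RS), spike train (ST), tonic spiking (TS),
bursting, seizure-like events (SLE), sustained ictal activity (SIA) and
depolarization block (DB).

State variables
---------------
V        membrane potential (mV)
n        potassium activation gate (dimensionless)
DeltaK_i deviation of intracellular potassium from baseline (mM)
K_g      potassium gained from the bath (mM)

All six ion concentrations are derived algebraically from ``DeltaK_i`` and
``K_g`` (mass conservation between the intracellular space and a thin
extracellular shell with volume ratio ``beta_vol``), so the slow subsystem
has only two degrees of freedom.

Units: time in ms, voltage in mV, current density in uA/cm^2, conductance
density in mS/cm^2, concentration in mM.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@dataclass
class IonNeuronParams:
    """Biophysical parameters of the ion-concentration neuron.

    The structural constants (gating curves, saturating pump form, Nernst
    scale, baseline concentrations) follow the published single-compartment
    ion-exchange neuron model family; the conductance densities and slow
    flux rates are calibrated so that the default model reproduces the
    bath-potassium firing-pattern sequence and its depolarization-block
    threshold (see docs/methods.md for the calibration rationale).

    Attributes
    ----------
    g0_K, g0_Na, g0_Cl : float
        Maximal voltage-gated conductance densities (mS/cm^2).
    gl_K, gl_Na : float
        Leak conductance densities (mS/cm^2).
    rho : float
        Maximal Na/K pump current density (uA/cm^2).
    gamma_flux : float
        Conversion from current density to molar flux, per ms
        (mM cm^2 / (uA ms)); the surface-to-volume factor of the cell.
    epsilon : float
        Bath <-> extracellular-shell potassium exchange rate (1/ms).
    beta_vol : float
        Intracellular-to-extracellular volume ratio (dimensionless).
    pump_k_stoich : float
        Weight of the pump current in the potassium flux balance; 2.0 for
        the physiological 3Na/2K stoichiometry.
    tau_gate : float
        Gating relaxation time constant (ms).
    c_m : float
        Specific membrane capacitance (uF/cm^2).
    nernst_prefactor : float
        Thermal voltage scale C in E_X = C log(X_o/X_i)/z (mV).
    K_bath : float
        Bath potassium concentration (mM) -- the control parameter.
    """

    g0_K: float = 22.0
    g0_Na: float = 55.2
    g0_Cl: float = 8.42
    gl_K: float = 0.12
    gl_Na: float = 0.02
    rho: float = 280.0
    gamma_flux: float = 1.17e-5
    epsilon: float = 2.38e-3
    beta_vol: float = 3.86
    pump_k_stoich: float = 1.89
    tau_gate: float = 4.0
    c_m: float = 1.0
    nernst_prefactor: float = 26.64
    K_bath: float = 4.0
    K0_i: float = 130.0
    K0_o: float = 4.8
    Na0_i: float = 16.0
    Na0_o: float = 138.0
    Cl0_i: float = 5.0
    Cl0_o: float = 112.0

    def __post_init__(self) -> None:
        for name in ("g0_K", "g0_Na", "g0_Cl", "gl_K", "gl_Na", "rho",
                     "c_m", "K0_i", "K0_o", "Na0_i", "Na0_o", "Cl0_i",
                     "Cl0_o"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.K_bath <= 0:
            raise ValueError("K_bath must be positive")
        if self.beta_vol <= 0:
            raise ValueError("beta_vol must be positive")
        if self.tau_gate <= 0:
            raise ValueError("tau_gate must be positive")

    def with_kbath(self, kbath: float) -> "IonNeuronParams":
        return replace(self, K_bath=float(kbath))


@dataclass
class IonNeuronState:
    """Dynamical state of one cell."""

    V: float = -70.0
    n: float = 0.03
    DeltaK_i: float = 0.0
    K_g: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.V, self.n, self.DeltaK_i, self.K_g])


class FiringPattern(str, enum.Enum):
    RS = "RS"
    ST = "ST"
    TS = "TS"
    BURST = "BURST"
    SLE = "SLE"
    SIA = "SIA"
    DB = "DB"
    UNCLASSIFIED = "UNCLASSIFIED"


def resting_state(params: IonNeuronParams,
                  settle_ms: float = 2000.0) -> IonNeuronState:
    """Baseline-concentration resting state of the fast subsystem.

    The (V, n) subsystem is settled for ``settle_ms`` with the slow ion
    variables clamped at baseline; the endpoint is the common initial
    state used for bath-potassium sweeps.
    """
    from dataclasses import replace as _replace

    clamped = _replace(params, gamma_flux=0.0, epsilon=0.0)
    s0 = IonNeuronState(V=-70.0, n=gating_steady(-70.0)[0], DeltaK_i=0.0,
                        K_g=0.0)
    tr = integrate(clamped, s0, settle_ms, dt=0.05,
                   sample_every=max(1, int(settle_ms / 0.05)))
    return IonNeuronState(V=float(tr.V[-1, 0]), n=float(tr.n[-1, 0]),
                          DeltaK_i=0.0, K_g=0.0)


# ---------------------------------------------------------------------------
# elementary pieces


def nernst(conc_out: float, conc_in: float, prefactor: float,
           valence: int) -> float:
    """Reversal potential E = prefactor * log(out/in) / valence (mV)."""
    if conc_out <= 0 or conc_in <= 0:
        raise ValueError(
            f"nernst requires positive concentrations, got out={conc_out}, "
            f"in={conc_in}")
    if valence not in (1, -1):
        raise ValueError("valence must be +1 or -1")
    return prefactor * math.log(conc_out / conc_in) / valence


def pump_current(params: IonNeuronParams, Na_i: float, K_o: float) -> float:
    """Saturating Na/K pump current density (uA/cm^2), in (0, rho)."""
    return params.rho / ((1.0 + math.exp(10.5 - 0.5 * Na_i)) *
                         (1.0 + math.exp(5.5 - K_o)))


def gating_steady(V: float) -> tuple[float, float]:
    """Steady-state activation (n_inf, m_inf) at membrane potential V."""
    n_inf = 1.0 / (1.0 + math.exp(-(19.0 + V) / 18.0))
    m_inf = 1.0 / (1.0 + math.exp(-(2.0 + V / 12.0)))
    return n_inf, m_inf


def h_of_n(n: float) -> float:
    """Sodium inactivation slaved to n: h = 1.1 - 1/(1+exp(-8(n-0.4)))."""
    return 1.1 - 1.0 / (1.0 + math.exp(3.2 - 8.0 * n))


def conductances(params: IonNeuronParams, n: float,
                 V: float) -> tuple[float, float, float]:
    """(gK, gNa, gCl) in mS/cm^2; gNa uses instantaneous m_inf(V)h(n)."""
    _, m_inf = gating_steady(V)
    g_k = params.g0_K * n + params.gl_K
    g_na = params.g0_Na * m_inf * h_of_n(n) + params.gl_Na
    return g_k, g_na, params.g0_Cl


def concentrations(params: IonNeuronParams, DeltaK_i: float,
                   K_g: float) -> tuple[float, float, float, float, float,
                                        float]:
    """(K_i, K_o, Na_i, Na_o, Cl_i, Cl_o) in mM from the two slow variables."""
    k_i = params.K0_i + DeltaK_i
    k_o = params.K0_o - params.beta_vol * DeltaK_i + K_g
    na_i = params.Na0_i - DeltaK_i
    na_o = params.Na0_o + params.beta_vol * DeltaK_i
    return k_i, k_o, na_i, na_o, params.Cl0_i, params.Cl0_o


def reversal_potentials(params: IonNeuronParams, DeltaK_i: float,
                        K_g: float) -> tuple[float, float, float]:
    """(E_K, E_Na, E_Cl) in mV at the current slow state."""
    k_i, k_o, na_i, na_o, cl_i, cl_o = concentrations(params, DeltaK_i, K_g)
    c = params.nernst_prefactor
    return (nernst(k_o, k_i, c, 1), nernst(na_o, na_i, c, 1),
            nernst(cl_o, cl_i, c, -1))


def derivatives(params: IonNeuronParams, state: IonNeuronState,
                i_syn: float = 0.0) -> np.ndarray:
    """Right-hand side (dV, dn, dDeltaK_i, dK_g) of the 4-ODE system.

    Currents are outward-positive, i_X = g_X (V - E_X); the synaptic input
    ``i_syn`` is depolarizing-positive.
    """
    k_i, k_o, na_i, na_o, cl_i, cl_o = concentrations(
        params, state.DeltaK_i, state.K_g)
    if min(k_i, k_o, na_i, na_o) <= 0:
        raise FloatingPointError(
            f"nonpositive ion concentration at state {state}")
    e_k, e_na, e_cl = reversal_potentials(params, state.DeltaK_i, state.K_g)
    g_k, g_na, g_cl = conductances(params, state.n, state.V)
    i_k = g_k * (state.V - e_k)
    i_na = g_na * (state.V - e_na)
    i_cl = g_cl * (state.V - e_cl)
    i_p = pump_current(params, na_i, k_o)
    dv = -(i_k + i_na + i_cl + i_p - i_syn) / params.c_m
    n_inf, _ = gating_steady(state.V)
    dn = (n_inf - state.n) / params.tau_gate
    ddk = -params.gamma_flux * (i_k - params.pump_k_stoich * i_p)
    dkg = params.epsilon * (params.K_bath - k_o)
    out = np.array([dv, dn, ddk, dkg])
    if not np.all(np.isfinite(out)):
        raise FloatingPointError(f"non-finite derivative at state {state}")
    return out


# ---------------------------------------------------------------------------
# fixed-step integrator (operator-split: exponential updates for the fast
# variables, explicit Euler for the slow ion bookkeeping)


@njit(cache=True)
def _run_lanes(V, n, dki, kg, kbath, i_ext, dt, n_steps,
               g0K, glK, g0Na, glNa, g0Cl, rho, gamma, eps, beta, pump_kf,
               tau, cm, C, K0i, K0o, Na0i, Na0o, Cl0i, Cl0o,
               thresh, sample_every,
               V_out, n_out, dki_out, kg_out,
               spk_t, spk_count):  # pragma: no cover - numba kernel
    n_lanes = V.shape[0]
    ecl = C * math.log(Cl0i / Cl0o)
    max_spk = spk_t.shape[1]
    k_out = 0
    for step in range(n_steps):
        ie = i_ext[step]
        for j in range(n_lanes):
            v = V[j]
            ki = K0i + dki[j]
            ko = K0o - beta * dki[j] + kg[j]
            nai = Na0i - dki[j]
            nao = Na0o + beta * dki[j]
            if ki <= 0.0 or ko <= 0.0 or nai <= 0.0 or nao <= 0.0:
                # integration failure: mark lane with NaN and freeze it
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
            gtot = gk + gna + g0Cl
            vinf = (gk * ek + gna * ena + g0Cl * ecl - ip + ie) / gtot
            vnew = vinf + (v - vinf) * math.exp(-gtot * dt / cm)
            nnew = ninf + (n[j] - ninf) * math.exp(-dt / tau)
            ik = gk * (v - ek)
            dki[j] += dt * (-gamma * (ik - pump_kf * ip))
            kg[j] += dt * (eps * (kbath[j] - ko))
            if v < thresh <= vnew:
                c = spk_count[j]
                if c < max_spk:
                    frac = (thresh - v) / (vnew - v)
                    spk_t[j, c] = (step + frac) * dt
                    spk_count[j] = c + 1
            V[j] = vnew
            n[j] = nnew
        if (step + 1) % sample_every == 0:
            for j in range(n_lanes):
                V_out[k_out, j] = V[j]
                n_out[k_out, j] = n[j]
                dki_out[k_out, j] = dki[j]
                kg_out[k_out, j] = kg[j]
            k_out += 1


@dataclass
class Trace:
    """Sampled trajectory of one or more lanes of the ion neuron."""

    t: np.ndarray          # (n_samples,) ms, sample times
    V: np.ndarray          # (n_samples, n_lanes) mV
    n: np.ndarray
    DeltaK_i: np.ndarray
    K_g: np.ndarray
    spikes: list = field(default_factory=list)  # per lane, spike times (ms)
    dt: float = 0.05

    def lane(self, j: int = 0) -> "Trace":
        sl = (slice(None), slice(j, j + 1))
        return Trace(self.t, self.V[sl], self.n[sl], self.DeltaK_i[sl],
                     self.K_g[sl], [self.spikes[j]], self.dt)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "time_ms": self.t,
            "V_mV": self.V[:, 0],
            "n": self.n[:, 0],
            "DeltaK_i_mM": self.DeltaK_i[:, 0],
            "K_g_mM": self.K_g[:, 0],
        })


def integrate(params: IonNeuronParams, state0: IonNeuronState,
              duration: float, dt: float = 0.05, i_syn_fn=None,
              sample_every: int = 1, spike_threshold: float = 0.0,
              kbath_lanes=None) -> Trace:
    """Integrate the 4-ODE system for ``duration`` ms at step ``dt``.

    Operator-split fixed-step scheme: V and n are advanced by exponential
    (semi-implicit) updates, the slow ion variables by explicit Euler.
    Deterministic; step count = ceil(duration/dt).

    ``kbath_lanes`` vectorizes the run over several K_bath values sharing
    ``state0`` (used by :func:`sweep_kbath`).  ``i_syn_fn`` maps time (ms)
    to a shared synaptic current density.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration < 0:
        raise ValueError("duration must be nonnegative")
    n_steps = math.ceil(duration / dt)
    if kbath_lanes is None:
        kbath = np.array([params.K_bath], dtype=float)
    else:
        kbath = np.asarray(kbath_lanes, dtype=float)
    n_lanes = kbath.size
    V = np.full(n_lanes, state0.V, dtype=float)
    n = np.full(n_lanes, state0.n, dtype=float)
    dki = np.full(n_lanes, state0.DeltaK_i, dtype=float)
    kg = np.full(n_lanes, state0.K_g, dtype=float)
    if n_steps == 0:
        t = np.array([0.0])
        one = lambda a: a[None, :].copy()
        return Trace(t, one(V), one(n), one(dki), one(kg),
                     [np.empty(0)] * n_lanes, dt)
    if i_syn_fn is None:
        i_ext = np.zeros(n_steps)
    else:
        i_ext = np.array([float(i_syn_fn(step * dt))
                          for step in range(n_steps)])
    n_samples = n_steps // sample_every
    V_out = np.empty((n_samples, n_lanes))
    n_out = np.empty((n_samples, n_lanes))
    dki_out = np.empty((n_samples, n_lanes))
    kg_out = np.empty((n_samples, n_lanes))
    max_spk = max(1000, n_steps // 5)
    spk_t = np.empty((n_lanes, max_spk))
    spk_count = np.zeros(n_lanes, dtype=np.int64)
    p = params
    _run_lanes(V, n, dki, kg, kbath, i_ext, dt, n_steps,
               p.g0_K, p.gl_K, p.g0_Na, p.gl_Na, p.g0_Cl, p.rho,
               p.gamma_flux, p.epsilon, p.beta_vol, p.pump_k_stoich,
               p.tau_gate, p.c_m, p.nernst_prefactor,
               p.K0_i, p.K0_o, p.Na0_i, p.Na0_o, p.Cl0_i, p.Cl0_o,
               spike_threshold, sample_every,
               V_out, n_out, dki_out, kg_out, spk_t, spk_count)
    if np.any(~np.isfinite(V)):
        bad = int(np.flatnonzero(~np.isfinite(V))[0])
        raise FloatingPointError(
            f"integration failure (non-finite state or negative "
            f"concentration) in lane {bad} (K_bath={kbath[bad]} mM)")
    t = (np.arange(1, n_samples + 1) * sample_every) * dt
    spikes = [spk_t[j, :spk_count[j]].copy() for j in range(n_lanes)]
    return Trace(t, V_out, n_out, dki_out, kg_out, spikes, dt)


def detect_spikes(V_trace: np.ndarray, threshold: float = 0.0,
                  dt: float = 0.05, t0: float = 0.0) -> np.ndarray:
    """Times (ms) of upward threshold crossings of a uniformly sampled trace.

    Crossing times are linearly interpolated between samples; one spike per
    upward crossing.
    """
    v = np.asarray(V_trace, dtype=float).ravel()
    if v.size == 0:
        return np.empty(0)
    below = v[:-1] < threshold
    above = v[1:] >= threshold
    idx = np.flatnonzero(below & above)
    frac = (threshold - v[idx]) / (v[idx + 1] - v[idx])
    return t0 + (idx + frac) * dt


# ---------------------------------------------------------------------------
# firing-pattern classification


@dataclass
class ClassifierConfig:
    """Operational constants of the firing-pattern classifier.

    All thresholds are heuristic separators of the seven regimes and are
    exposed for tuning; defaults separate the canonical K_bath taxonomy.
    """

    transient_fraction: float = 0.25   # discarded leading fraction of trace
    event_gap_ms: float = 300.0        # ISI gap splitting spike events
    long_event_ms: float = 1000.0      # minimum SLE event duration
    quiescent_gap_ms: float = 500.0    # minimum SLE inter-event gap
    cv_tonic_max: float = 0.3          # ISI CV bound separating TS from SIA
    coverage_fraction: float = 0.9     # window coverage for TS/SIA
    rs_mean_v_max: float = -50.0       # mV, resting-state plateau bound
    db_mean_v_min: float = -30.0       # mV, depolarization-block bound
    sia_mean_v_min: float = -40.0      # mV, elevated-V bound marking SIA
    osc_amplitude_min: float = 20.0    # mV, peak-to-peak for subthreshold
                                       # oscillation to count as sustained
    repol_v: float = -55.0             # mV; a depolarized episode lasts
                                       # until V repolarizes below this


def _spike_events(spikes: np.ndarray, gap_ms: float) -> list[np.ndarray]:
    if spikes.size == 0:
        return []
    cuts = np.flatnonzero(np.diff(spikes) >= gap_ms)
    return np.split(spikes, cuts + 1)


def _episodes(events: list[np.ndarray], t: np.ndarray, v: np.ndarray,
              repol_v: float) -> list[tuple[float, float]]:
    """Depolarized episodes (start, end): an episode begins at its first
    spike and lasts until V first repolarizes below ``repol_v`` after the
    last spike; overlapping episodes merge."""
    out: list[list[float]] = []
    for e in events:
        idx = np.searchsorted(t, e[-1])
        below = np.flatnonzero(v[idx:] < repol_v)
        end = float(t[idx + below[0]]) if below.size else float(t[-1])
        end = max(end, float(e[-1]))
        if out and e[0] <= out[-1][1]:
            out[-1][1] = max(out[-1][1], end)
        else:
            out.append([float(e[0]), end])
    return [(a, b) for a, b in out]


def classify_pattern(V_trace: np.ndarray, spikes: np.ndarray,
                     t: np.ndarray | None = None,
                     config: ClassifierConfig | None = None,
                     dt: float = 1.0) -> FiringPattern:
    """Assign exactly one firing-pattern label to a voltage trace.

    ``V_trace`` is the sampled membrane potential, ``spikes`` the detected
    spike times (ms) over the whole trace, ``t`` the sample times (ms,
    defaults to a uniform grid of step ``dt``).  The leading
    ``transient_fraction`` of the trace is excluded from analysis.

    Decision rules (on the analysis window of duration W):
      no spikes: mean V < -50 mV -> RS; mean V > -30 mV -> DB; sustained
        large subthreshold oscillation at intermediate mean V -> SIA
      spiking spanning >= 0.9 W at elevated mean V (> -40 mV) -> SIA
      one event covering >= 0.9 W: ISI CV < 0.3 -> TS, else SIA
      all spiking ends before 0.9 W -> ST
      >= 3 events, all shorter than 1 s (gaps >= 300 ms) -> BURST
      >= 2 events of >= 1 s separated by quiescence -> SLE
      otherwise UNCLASSIFIED
    """
    cfg = config or ClassifierConfig()
    v = np.asarray(V_trace, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("cannot classify an empty trace")
    if t is None:
        t = np.arange(v.size) * dt
    t = np.asarray(t, dtype=float).ravel()
    t_start = t[0] + cfg.transient_fraction * (t[-1] - t[0])
    win = t >= t_start
    v_win = v[win]
    w_len = t[-1] - t_start
    spikes = np.asarray(spikes, dtype=float)
    sp = spikes[spikes >= t_start]
    mean_v = float(np.mean(v_win))

    if sp.size == 0:
        if mean_v < cfg.rs_mean_v_max:
            return FiringPattern.RS
        if mean_v > cfg.db_mean_v_min:
            return FiringPattern.DB
        if np.ptp(v_win) >= cfg.osc_amplitude_min:
            return FiringPattern.SIA  # sustained elevated-V oscillation
        return FiringPattern.UNCLASSIFIED

    events = _spike_events(sp, cfg.event_gap_ms)
    episodes = _episodes(events, t, v, cfg.repol_v)
    cover = (sp[-1] - t_start) / w_len if w_len > 0 else 1.0
    span = (sp[-1] - sp[0]) / w_len if w_len > 0 else 1.0

    if span >= cfg.coverage_fraction and mean_v > cfg.sia_mean_v_min:
        return FiringPattern.SIA  # pathological depolarized firing
    if len(episodes) == 1 and span >= cfg.coverage_fraction:
        isi = np.diff(sp)
        cv = float(np.std(isi) / np.mean(isi)) if isi.size > 1 else 0.0
        return (FiringPattern.TS if cv < cfg.cv_tonic_max
                else FiringPattern.SIA)
    durations = np.array([b - a for a, b in episodes])
    if cover < cfg.coverage_fraction:
        # spiking confined to the early window, then silence
        if len(episodes) >= 2 and durations.max() >= cfg.long_event_ms:
            pass  # fall through: several long episodes that stopped early
        else:
            return FiringPattern.ST
    if len(episodes) >= 3 and np.all(durations < cfg.long_event_ms):
        return FiringPattern.BURST
    long_idx = [i for i, d in enumerate(durations)
                if d >= cfg.long_event_ms]
    if len(long_idx) >= 2:
        gaps = [episodes[b][0] - episodes[a][1]
                for a, b in zip(long_idx[:-1], long_idx[1:])]
        if min(gaps) >= cfg.quiescent_gap_ms:
            return FiringPattern.SLE
    return FiringPattern.UNCLASSIFIED


def sweep_kbath(kbath_grid, duration: float = 60_000.0, dt: float = 0.05,
                params: IonNeuronParams | None = None,
                state0: IonNeuronState | None = None,
                config: ClassifierConfig | None = None,
                spike_threshold: float = 0.0,
                sample_every: int = 20) -> dict[float, FiringPattern]:
    """Classify the firing pattern at each bath-potassium value.

    All grid values are integrated in one vectorized run from a common
    resting initial state; deterministic.
    """
    grid = np.atleast_1d(np.asarray(kbath_grid, dtype=float))
    if grid.size == 0:
        raise ValueError("kbath_grid must be nonempty")
    p = params or IonNeuronParams()
    s0 = state0 or resting_state(p)
    trace = integrate(p, s0, duration, dt=dt, sample_every=sample_every,
                      spike_threshold=spike_threshold, kbath_lanes=grid)
    out: dict[float, FiringPattern] = {}
    for j, kb in enumerate(grid):
        out[float(kb)] = classify_pattern(
            trace.V[:, j], trace.spikes[j], t=trace.t, config=config)
    return out
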