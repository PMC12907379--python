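"""Delayed reduced Wong-Wang network over a connectome.

Each region I carries a mean synaptic gating variable S_I in [0, 1]:

    dS_I/dt = -S_I / tau_s + (1 - S_I) * gamma * H(x_I)
    H(x)    = (a x - b) / (1 - exp(-d (a x - b)))
    x_I     = w J_N S_I + G J_N sum_K c_IK S_K(t - tau_IK) + I_0

with the transfer function H in kHz, synaptic input x in nA and conduction
delays tau_IK derived from tract lengths.  One region may be designated as
a *proxy*: its gating trajectory is supplied externally (by the embedded
spiking network through the coupling layer) instead of being integrated
from the mean-field equations, while all other regions read its delayed
values through the ordinary history buffer.

Integration is fixed-step (explicit Euler by default, Heun optional) with
delays rounded to the nearest multiple of the step and kept in a ring
buffer.  The integrator is deterministic; an optional additive-noise hook
is off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .connectome import Connectome


@dataclass
class RwwParams:
    """Reduced Wong-Wang parameters (units as conventionally printed)."""

    a: float = 0.27          # gain, 1/nC
    b: float = 0.108         # threshold, kHz
    d: float = 154.0         # shape, ms
    gamma_kin: float = 0.641  # kinetic rate (applied per ms with H in kHz)
    tau_s: float = 100.0     # gating time constant, ms
    w_local: float = 1.0     # local excitatory recurrence
    J_N: float = 0.2609      # NMDA synaptic coupling, nA
    I0: float = 0.33         # baseline external input, nA
    G: float = 0.096         # global coupling

    def __post_init__(self) -> None:
        if self.tau_s <= 0 or self.d <= 0:
            raise ValueError("tau_s and d must be positive")


def transfer_H(x, params: RwwParams):
    """Mean firing rate H(x) in kHz; removable singularity at a*x = b.

    H(x) = (a x - b)/(1 - exp(-d (a x - b))), continuous and positive,
    H -> 1/d at a x = b and H ~ a x - b for large drive.
    """
    z = params.a * np.asarray(x, dtype=float) - params.b
    out = np.empty_like(z)
    small = np.abs(z) < 1e-9
    with np.errstate(over="ignore"):
        denom = -np.expm1(-params.d * np.where(small, 1.0, z))
    out = np.where(small, 1.0 / params.d, np.where(small, 1.0, z) / denom)
    return out if out.ndim else float(out)


def gating_derivative(S, H, params: RwwParams):
    """dS/dt = -S/tau_s + (1 - S) gamma H (1/ms, H in kHz)."""
    return -np.asarray(S) / params.tau_s + \
        (1.0 - np.asarray(S)) * params.gamma_kin * np.asarray(H)


def min_delay(conn: Connectome, zero_replacement: float = 1.0) -> float:
    """Smallest conduction delay over connections with positive weight.

    Zero delays on existing (positive-weight) connections are replaced by
    ``zero_replacement`` before taking the minimum; delays on zero-weight
    entries are ignored entirely.
    """
    if conn.n_regions == 0:
        raise ValueError("empty connectome")
    if zero_replacement <= 0:
        raise ValueError("zero_replacement must be positive")
    mask = conn.weights > 0
    if not np.any(mask):
        raise ValueError("connectome has no connections")
    d = conn.delays[mask]
    d = np.where(d == 0.0, zero_replacement, d)
    return float(d.min())


def synaptic_input(region: int, S_now: np.ndarray, S_delayed: np.ndarray,
                   params: RwwParams, weights: np.ndarray) -> float:
    """x_I = w J_N S_I + G J_N sum_K c_IK S_K(t - tau_IK) + I0.

    ``S_delayed`` is the row of already-delay-resolved gating values
    S_K(t - tau_IK) for this region.
    """
    coupling = float(weights[region] @ S_delayed)
    return (params.w_local * params.J_N * S_now[region]
            + params.G * params.J_N * coupling + params.I0)


class RwwNetwork:
    """Fixed-step delayed Wong-Wang simulator with an optional proxy region.

    Parameters
    ----------
    conn : Connectome
        Weights and tract lengths; ``conn.proxy_region`` (if set) marks the
        region whose gating is supplied externally.
    params : RwwParams
    dt : float
        Integration step (ms); delays are rounded to multiples of dt.
    zero_delay_replacement : float
        Finite delay substituted for zero-delay connections (ms).
    method : {"euler", "heun"}
    """

    def __init__(self, conn: Connectome, params: RwwParams | None = None,
                 dt: float = 0.1, zero_delay_replacement: float = 1.0,
                 method: str = "euler", noise_std: float = 0.0,
                 noise_rng: np.random.Generator | None = None,
                 proxy_region: int | None | str = "from_connectome"):
        if method not in ("euler", "heun"):
            raise ValueError("method must be 'euler' or 'heun'")
        self.conn = conn
        self.proxy_region = (conn.proxy_region
                             if proxy_region == "from_connectome"
                             else proxy_region)
        self.params = params or RwwParams()
        self.dt = float(dt)
        self.method = method
        self.noise_std = float(noise_std)
        self.noise_rng = noise_rng
        n = conn.n_regions
        delays = conn.delays.copy()
        delays[(conn.weights > 0) & (delays == 0.0)] = zero_delay_replacement
        self.delay_steps = np.rint(delays / dt).astype(np.int64)
        self.delay_steps[conn.weights == 0] = 0
        self.tau_min = min_delay(conn, zero_delay_replacement)
        self._hist_len = int(self.delay_steps.max()) + 1
        self._hist = np.zeros((self._hist_len, n))
        self._step = 0  # global step index (time = _step * dt)
        self.S = np.zeros(n)
        self._rows = np.arange(n)

    # -- state management ---------------------------------------------------

    def set_initial(self, S0) -> None:
        S0 = np.broadcast_to(np.asarray(S0, dtype=float),
                             (self.conn.n_regions,)).copy()
        if np.any((S0 < 0) | (S0 > 1)):
            raise ValueError("S must lie in [0, 1]")
        self.S = S0
        self._hist[:] = S0[None, :]
        self._step = 0

    @property
    def time(self) -> float:
        return self._step * self.dt

    def _delayed_matrix(self) -> np.ndarray:
        """S_K(t - tau_IK) as an (n, n) matrix indexed [I, K]."""
        idx = (self._step - self.delay_steps) % self._hist_len
        return self._hist[idx, self._rows[None, :]]

    def _drive(self, S: np.ndarray) -> np.ndarray:
        p = self.params
        S_del = self._delayed_matrix()
        coupling = np.einsum("ik,ik->i", self.conn.weights, S_del)
        x = p.w_local * p.J_N * S + p.G * p.J_N * coupling + p.I0
        return x

    def simulate_epoch(self, epoch_length: float,
                       proxy_series: np.ndarray | None = None,
                       record: bool = True):
        """Advance all regions by ``epoch_length`` ms.

        ``proxy_series`` supplies the proxy region's gating value for each
        step of the epoch (shape (n_steps,)); required when the connectome
        designates a proxy.  Cross-region influences are read through the
        delay buffer, so the caller must guarantee epoch_length <= tau_min
        for exchange correctness (enforced).

        Returns (S_record, H_record) with one row per step if ``record``.
        """
        n_steps_f = epoch_length / self.dt
        n_steps = int(round(n_steps_f))
        if abs(n_steps_f - n_steps) > 1e-9 * max(1.0, n_steps_f):
            raise ValueError(
                f"dt={self.dt} must evenly divide epoch_length="
                f"{epoch_length}")
        if epoch_length > self.tau_min + 1e-9:
            raise ValueError(
                f"epoch_length {epoch_length} ms exceeds the minimum "
                f"conduction delay {self.tau_min} ms; exchange would be "
                f"incorrect")
        proxy = self.proxy_region
        if proxy is not None:
            if proxy_series is None:
                raise ValueError("network has a proxy region; "
                                 "proxy_series is required")
            proxy_series = np.asarray(proxy_series, dtype=float)
            if proxy_series.shape != (n_steps,):
                raise ValueError(
                    f"proxy_series must have shape ({n_steps},), got "
                    f"{proxy_series.shape}")
        p = self.params
        S_rec = np.empty((n_steps, self.conn.n_regions)) if record else None
        H_rec = np.empty_like(S_rec) if record else None
        for k in range(n_steps):
            x = self._drive(self.S)
            H = transfer_H(x, p)
            dS = gating_derivative(self.S, H, p)
            if self.method == "heun":
                S_pred = np.clip(self.S + self.dt * dS, 0.0, 1.0)
                # predictor-corrector sharing the same delayed history
                x2 = self._drive(S_pred)
                H2 = transfer_H(x2, p)
                dS = 0.5 * (dS + gating_derivative(S_pred, H2, p))
            S_new = self.S + self.dt * dS
            if self.noise_std > 0.0 and self.noise_rng is not None:
                S_new += self.noise_std * math.sqrt(self.dt) * \
                    self.noise_rng.standard_normal(S_new.shape)
            S_new = np.clip(S_new, 0.0, 1.0)
            if proxy is not None:
                S_new[proxy] = proxy_series[k]
            self._step += 1
            self._hist[self._step % self._hist_len] = S_new
            self.S = S_new
            if record:
                S_rec[k] = S_new
                H_rec[k] = H
        return (S_rec, H_rec) if record else (None, None)

    def run(self, duration: float, proxy_series: np.ndarray | None = None):
        """Convenience: advance in epochs of tau_min (last one truncated)."""
        total_steps = int(round(duration / self.dt))
        epoch_steps = max(1, int(self.tau_min / self.dt))
        S_all, H_all = [], []
        done = 0
        while done < total_steps:
            k = min(epoch_steps, total_steps - done)
            ps = None
            if proxy_series is not None:
                ps = proxy_series[done:done + k]
            S, H = self.simulate_epoch(k * self.dt, proxy_series=ps)
            S_all.append(S)
            H_all.append(H)
            done += k
        return np.vstack(S_all), np.vstack(H_all)


def isolated_fixed_point(params: RwwParams, tol: float = 1e-12) -> float:
    """Equilibrium S* of an isolated region (G = 0) by bisection on
    f(S) = -S/tau_s + (1-S) gamma H(w J_N S + I0)."""
    p = params

    def f(S):
        return float(gating_derivative(
            S, transfer_H(p.w_local * p.J_N * S + p.I0, p), p))

    lo, hi = 0.0, 1.0
    if f(lo) < 0:
        return 0.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)
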