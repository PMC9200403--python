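"""Conductance-based LIF recurrent network of a local frontal circuit.

605 neurons (80% excitatory), sparse connectivity with over-represented
bidirectional E-E motifs and log-normal weights, AMPA/NMDA/GABA-A/GABA-B
recurrent synapses (first- or second-order kinetics, one conduction delay),
spike-triggered calcium driving CAN and AHP currents in excitatory neurons,
constant AMPA feed-forward drive, and per-neuron balance of recurrent
excitation and inhibition at the mean membrane potential.

Area presets LPFCm and MCCm differ only in the AHP and GABA-B maximal
conductances; the two cross presets swap one conductance at a time.

Integration is forward Euler at dt = 0.5 ms. The kernel tracks, for every
postsynaptic neuron, the weighted sums of presynaptic opening probabilities;
their linear dynamics let first-order receptors be updated event-wise and
second-order drives be scattered through the sparse weight matrix, keeping a
600-s simulation to a couple of minutes on one core. Dynamics contain no
runtime randomness (chaos does the mixing): a (parameters, seed) pair fixes
the connectivity and initial condition, hence the whole raster, and any
snapshot of the state vector can be resumed bit-identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit

from .spike_data import PopulationRaster, SpikeTrain, bin_raster

__all__ = [
    "NetworkParams",
    "SynapticMatrix",
    "SimResult",
    "PRESETS",
    "preset",
    "build_network",
    "simulate_network",
    "spiking_statistics",
    "sweep_network",
]

# state-vector rows (n_state_vars x N) used for snapshots/resume
STATE_ROWS = (
    "V", "refr", "Ca", "p_CAN", "p_AHP",
    "p_AMPA", "q_NMDA", "p_NMDA", "p_GABA_A", "q_GABA_B", "p_GABA_B",
    "spiked_last_step",
)
N_STATE = len(STATE_ROWS)


@dataclass(frozen=True)
class NetworkParams:
    """Standard network parameter values (conductances mS/cm^2, mV, ms)."""

    N: int = 605
    p_exc: float = 0.8
    # connection probabilities, convention p[pre -> post]
    p_EE: float = 0.3
    p_EI: float = 0.3   # Exc -> Inh
    p_II: float = 0.3
    p_IE: float = 0.55  # Inh -> Exc
    reciprocity_factor: float = 4.0  # E-E bidirectional over-representation
    mu_w: float = 0.03
    sigma_w: float = 0.02
    lognormal_underlying: bool = False  # True: mu/sigma are log-scale params
    # LIF
    C: float = 1.0
    g_L: float = 0.05
    V_L: float = -70.0
    V_rest: float = -65.0
    theta: float = -50.0
    dt_AP: float = 3.0          # refractory, ms
    dt: float = 0.5
    dt_syn: float = 0.5         # conduction + transmission delay
    # intrinsic currents (excitatory neurons only)
    g_CAN: float = 0.025
    V_CAN: float = 30.0
    alpha_CAN: float = 0.0015
    beta_CAN: float = 0.005
    g_AHP: float = 0.022
    V_AHP: float = -90.0
    alpha_AHP: float = 0.025
    beta_AHP: float = 0.025
    Ca0: float = 0.1
    tau_Ca: float = 25.0
    dCa: float = 0.2
    # synapses
    g_AMPA: float = 0.23
    g_NMDA: float = 0.35
    g_GABA_A_scale: float = 0.4
    g_GABA_B_scale: float = 0.0035
    tau_AMPA: float = 2.5
    tau_NMDA_rise: float = 4.65
    tau_NMDA_decay: float = 75.0
    alpha_NMDA: float = 0.275
    tau_GABA_A: float = 10.0
    tau_GABA_B_rise: float = 90.0
    tau_GABA_B_decay: float = 160.0
    alpha_GABA_B: float = 0.015
    dx: float = 0.1
    Mg: float = 1.5
    V_AMPA: float = 0.0
    V_NMDA: float = 0.0
    V_GABA_A: float = -70.0
    V_GABA_B: float = -90.0
    # feed-forward drive
    g_AMPA_FF: float = 0.23
    p_AMPA_FF: float = 0.101

    @property
    def n_exc(self) -> int:
        return int(round(self.N * self.p_exc))

    @property
    def n_inh(self) -> int:
        return self.N - self.n_exc

    @property
    def V_mean(self) -> float:
        return 0.5 * (self.V_rest + self.theta)


PRESETS: dict[str, dict[str, float]] = {
    "LPFCm": {"g_CAN": 0.025, "g_AHP": 0.022, "g_GABA_B_scale": 0.0035},
    "MCCm": {"g_CAN": 0.025, "g_AHP": 0.087, "g_GABA_B_scale": 0.0143},
    "MCCm_LPFC_AHP": {"g_CAN": 0.025, "g_AHP": 0.022,
                      "g_GABA_B_scale": 0.0143},
    "MCCm_LPFC_GABA_B": {"g_CAN": 0.025, "g_AHP": 0.087,
                         "g_GABA_B_scale": 0.0035},
}


def preset(name: str, **overrides) -> NetworkParams:
    """Area preset: LPFCm, MCCm, or the single-conductance swaps."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {list(PRESETS)}")
    return NetworkParams(**{**PRESETS[name], **overrides})


@dataclass
class SynapticMatrix:
    """Realised connectivity: dense weights, types, balanced GABA conductances.

    ``W[i, j]`` is the weight of the connection from presynaptic i to
    postsynaptic j (0 = absent). ``g_gaba_a_post``/``g_gaba_b_post`` hold the
    per-postsynaptic-neuron balanced maximal conductances.
    """

    W: np.ndarray
    is_exc: np.ndarray
    g_gaba_a_post: np.ndarray
    g_gaba_b_post: np.ndarray
    seed: int

    @property
    def n(self) -> int:
        return self.W.shape[0]


def _draw_block(rng, n_pre, n_post, p):
    return rng.random((n_pre, n_post)) < p


def build_network(p: NetworkParams, seed: int = 0) -> SynapticMatrix:
    """Draw the synaptic matrix: sparse blocks, reciprocal E-E motifs,
    log-normal weights, per-neuron E/I balance.

    E-E pairs are drawn as {absent, unidirectional, bidirectional} with the
    bidirectional probability set to ``reciprocity_factor * p_EE**2`` while
    the marginal connection probability stays ``p_EE``. The factor is capped
    at the feasibility bound 1/p_EE (with a warning): above it no pair
    distribution with the requested marginal exists.
    """
    rng = np.random.default_rng(seed)
    nE, nI, N = p.n_exc, p.n_inh, p.N
    A = np.zeros((N, N), dtype=bool)

    # E-E pairs with over-represented bidirectional motifs
    pee = p.p_EE
    b = p.reciprocity_factor * pee**2
    if b > pee:
        warnings.warn(
            f"reciprocity factor {p.reciprocity_factor} infeasible at "
            f"p_EE={pee}; capped at {1 / pee:.2f}"
        )
        b = pee
    u = 2.0 * (pee - b)  # total unidirectional probability
    iu, ju = np.triu_indices(nE, k=1)
    r = rng.random(len(iu))
    bi = r < b
    uni = (~bi) & (r < b + u)
    fwd = rng.random(len(iu)) < 0.5
    A[iu[bi], ju[bi]] = True
    A[ju[bi], iu[bi]] = True
    A[iu[uni & fwd], ju[uni & fwd]] = True
    A[ju[uni & ~fwd], iu[uni & ~fwd]] = True

    A[:nE, nE:] = _draw_block(rng, nE, nI, p.p_EI)
    A[nE:, :nE] = _draw_block(rng, nI, nE, p.p_IE)
    A[nE:, nE:] = _draw_block(rng, nI, nI, p.p_II)
    np.fill_diagonal(A, False)

    # make sure every neuron receives inhibition (balance is undefined
    # otherwise); redraw empty inhibitory input rows
    for j in range(N):
        guard = 0
        while not A[nE:, j].any():
            warnings.warn(f"neuron {j} had no inhibitory input; redrawn")
            pin = p.p_IE if j < nE else p.p_II
            col = rng.random(nI) < pin
            col[j - nE if j >= nE else -1] &= (j < nE)
            A[nE:, j] = col
            np.fill_diagonal(A, False)
            guard += 1
            if guard > 100:
                raise RuntimeError("could not realise inhibitory inputs")

    if p.lognormal_underlying:
        mu_ln, sd_ln = p.mu_w, p.sigma_w
    else:
        sd_ln = np.sqrt(np.log1p(p.sigma_w**2 / p.mu_w**2))
        mu_ln = np.log(p.mu_w) - 0.5 * sd_ln**2
    W = np.zeros((N, N))
    W[A] = rng.lognormal(mu_ln, sd_ln, size=int(A.sum()))

    is_exc = np.zeros(N, dtype=bool)
    is_exc[:nE] = True
    sum_exc = W[:nE, :].sum(axis=0)
    sum_inh = W[nE:, :].sum(axis=0)
    Vm = p.V_mean
    ratio = sum_exc / sum_inh
    ga = p.g_GABA_A_scale * (-(Vm - p.V_AMPA) / (Vm - p.V_GABA_A)) * ratio
    gb = p.g_GABA_B_scale * (-(Vm - p.V_AMPA) / (Vm - p.V_GABA_B)) * ratio
    return SynapticMatrix(W, is_exc, ga, gb, seed)


@dataclass
class SimResult:
    """Raster plus restorable state snapshots of one network simulation."""

    spike_neurons: np.ndarray       # int32
    spike_times: np.ndarray         # ms, multiples of dt
    params: NetworkParams
    matrix: SynapticMatrix
    seed: int
    t_start: float
    duration: float
    snapshots: dict[float, np.ndarray] = field(default_factory=dict)

    @property
    def t_stop(self) -> float:
        return self.t_start + self.duration

    def to_spike_trains(self, area: str = "other") -> list[SpikeTrain]:
        trains = []
        order = np.lexsort((self.spike_times, self.spike_neurons))
        sn, st = self.spike_neurons[order], self.spike_times[order]
        bounds = np.searchsorted(sn, np.arange(self.matrix.n + 1))
        for i in range(self.matrix.n):
            t = st[bounds[i]:bounds[i + 1]]
            trains.append(SpikeTrain(
                unit_id=f"n{i:03d}", times=t,
                t_start=self.t_start, t_stop=self.t_stop, area=area,
                cell_type="RS" if self.matrix.is_exc[i] else "FS",
            ))
        return trains

    def to_raster(self, bin_width: float | None = None) -> PopulationRaster:
        bw = self.params.dt if bin_width is None else bin_width
        return bin_raster(
            self.to_spike_trains(), bw, (self.t_start, self.t_stop)
        )


# ---------------------------------------------------------------------------
# kernel


@njit(cache=True, fastmath=True)
def _net_kernel(  # noqa: C901
    n_steps, dt, state,
    indptr, indices, wdata, is_exc,
    ga_post, gb_post,
    C, g_L, V_L, V_rest, theta, refr_steps,
    g_CAN, V_CAN, a_CAN, b_CAN, g_AHP, V_AHP, a_AHP, b_AHP,
    Ca0, tau_Ca, dCa,
    g_AMPA, g_NMDA, V_AMPA, V_NMDA, V_GA, V_GB,
    tau_ampa, tau_nr, tau_nd, alpha_n, tau_ga, tau_gr, tau_gd, alpha_g,
    dx, Mg, I_FF_g,
    snap_steps, snap_out,
    sp_neuron, sp_step,
):
    N = state.shape[1]
    V = state[0]
    refr = state[1]
    Ca = state[2]
    p_can = state[3]
    p_ahp = state[4]
    p_a = state[5]
    q_n = state[6]
    p_n = state[7]
    p_ga = state[8]
    q_gb = state[9]
    p_gb = state[10]
    buf = state[11]

    # weighted presynaptic sums per postsynaptic neuron
    G_a = np.zeros(N)
    G_n = np.zeros(N)
    G_ga = np.zeros(N)
    G_gb = np.zeros(N)
    for i in range(N):
        for k in range(indptr[i], indptr[i + 1]):
            j = indices[k]
            w = wdata[k]
            if is_exc[i]:
                G_a[j] += w * p_a[i]
                G_n[j] += w * p_n[i]
            else:
                G_ga[j] += w * p_ga[i]
                G_gb[j] += w * p_gb[i]

    d_ampa = 1.0 - dt / tau_ampa
    d_ga = 1.0 - dt / tau_ga
    d_nd = 1.0 - dt / tau_nd
    d_gd = 1.0 - dt / tau_gd
    d_nr = 1.0 - dt / tau_nr
    d_gr = 1.0 - dt / tau_gr

    n_sp = 0
    snap_i = 0
    n_snap = len(snap_steps)
    max_spikes = len(sp_neuron)

    for step in range(n_steps):
        # 1. deliver spikes emitted in the previous step (delay = 1 step):
        #    first-order jumps scatter into the postsynaptic sums
        for i in range(N):
            if buf[i] > 0.5:
                if is_exc[i]:
                    jump = dx * (1.0 - p_a[i])
                    p_a[i] += jump
                    for k in range(indptr[i], indptr[i + 1]):
                        G_a[indices[k]] += wdata[k] * jump
                    q_n[i] += dx * (1.0 - q_n[i])
                else:
                    jump = dx * (1.0 - p_ga[i])
                    p_ga[i] += jump
                    for k in range(indptr[i], indptr[i + 1]):
                        G_ga[indices[k]] += wdata[k] * jump
                    q_gb[i] += dx * (1.0 - q_gb[i])
                buf[i] = 0.0

        # 2. synaptic kinetics: uniform decays on p and the tracked sums,
        #    second-order drives scattered sparsely
        for j in range(N):
            G_a[j] *= d_ampa
            G_ga[j] *= d_ga
            G_n[j] *= d_nd
            G_gb[j] *= d_gd
        for i in range(N):
            if is_exc[i]:
                p_a[i] *= d_ampa
                if q_n[i] > 1e-12:
                    u = dt * alpha_n * q_n[i] * (1.0 - p_n[i])
                    p_n[i] = p_n[i] * d_nd + u
                    for k in range(indptr[i], indptr[i + 1]):
                        G_n[indices[k]] += wdata[k] * u
                    q_n[i] *= d_nr
                else:
                    p_n[i] *= d_nd
            else:
                p_ga[i] *= d_ga
                if q_gb[i] > 1e-12:
                    u = dt * alpha_g * q_gb[i] * (1.0 - p_gb[i])
                    p_gb[i] = p_gb[i] * d_gd + u
                    for k in range(indptr[i], indptr[i + 1]):
                        G_gb[indices[k]] += wdata[k] * u
                    q_gb[i] *= d_gr
                else:
                    p_gb[i] *= d_gd

        # 3. membrane, calcium, intrinsic gating, threshold
        for j in range(N):
            Ca[j] += dt * (Ca0 - Ca[j]) / tau_Ca
            if is_exc[j]:
                p_can[j] += dt * (a_CAN * Ca[j] * (1.0 - p_can[j])
                                  - b_CAN * p_can[j])
                p_ahp[j] += dt * (a_AHP * Ca[j] * (1.0 - p_ahp[j])
                                  - b_AHP * p_ahp[j])
            if refr[j] > 0.5:
                refr[j] -= 1.0
                V[j] = V_rest
                continue
            v = V[j]
            xn = 1.0 / (1.0 + Mg * np.exp(-0.062 * v) / 3.57)
            I_syn = (g_AMPA * G_a[j] * (v - V_AMPA)
                     + g_NMDA * G_n[j] * xn * (v - V_NMDA)
                     + ga_post[j] * G_ga[j] * (v - V_GA)
                     + gb_post[j] * G_gb[j] * (v - V_GB)
                     + I_FF_g * (v - V_AMPA))
            I_ion = g_L * (v - V_L)
            if is_exc[j]:
                I_ion += (g_CAN * p_can[j] * (v - V_CAN)
                          + g_AHP * p_ahp[j] * p_ahp[j] * (v - V_AHP))
            v += dt * (-(I_ion + I_syn)) / C
            if not np.isfinite(v):
                return n_sp, -1, step
            if v > theta:
                V[j] = V_rest
                refr[j] = refr_steps
                Ca[j] += dCa
                buf[j] = 1.0
                if n_sp < max_spikes:
                    sp_neuron[n_sp] = j
                    sp_step[n_sp] = step
                    n_sp += 1
                else:
                    return n_sp, -2, step
            else:
                V[j] = v

        if snap_i < n_snap and step == snap_steps[snap_i]:
            for r in range(state.shape[0]):
                for j in range(N):
                    snap_out[snap_i, r, j] = state[r, j]
            snap_i += 1

    return n_sp, 0, n_steps


def _fresh_state(p: NetworkParams, m: SynapticMatrix, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    state = np.zeros((N_STATE, p.N))
    state[0] = rng.uniform(p.V_rest, p.theta, size=p.N)
    state[2] = p.Ca0
    state[3] = p.alpha_CAN * p.Ca0 / (p.alpha_CAN * p.Ca0 + p.beta_CAN)
    state[4] = p.alpha_AHP * p.Ca0 / (p.alpha_AHP * p.Ca0 + p.beta_AHP)
    return state


def simulate_network(
    p: NetworkParams,
    m: SynapticMatrix,
    duration: float,
    seed: int = 0,
    snapshot_times: np.ndarray | None = None,
    init_state: np.ndarray | None = None,
    t_start: float = 0.0,
    max_rate_cap: float = 100.0,
) -> SimResult:
    """Simulate the network for ``duration`` ms (forward Euler, dt = 0.5 ms).

    ``init_state`` (a snapshot from a previous run, rows ``STATE_ROWS``)
    resumes a trajectory bit-identically; otherwise membrane potentials are
    initialised uniformly in [V_rest, theta) from ``seed``. ``snapshot_times``
    (absolute ms) are captured after the corresponding step. Raises on
    non-finite state or if spiking exceeds ``max_rate_cap`` Hz per neuron on
    average (runaway dynamics).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n_steps = int(round(duration / p.dt))
    if p.dt_syn != p.dt:
        raise NotImplementedError("delay must equal one integration step")
    state = (_fresh_state(p, m, seed) if init_state is None
             else init_state.copy())

    Wcsr = m.W  # dense but row-sparse; build CSR over nonzeros
    nz = Wcsr != 0
    indptr = np.zeros(p.N + 1, dtype=np.int64)
    indptr[1:] = np.cumsum(nz.sum(axis=1))
    indices = np.nonzero(nz)[1].astype(np.int64)
    wdata = Wcsr[nz].astype(np.float64)

    if snapshot_times is None:
        snap_steps = np.empty(0, dtype=np.int64)
    else:
        rel = (np.asarray(snapshot_times, dtype=float) - t_start) / p.dt
        # state captured after step s is the state at time (s + 1) * dt
        snap_steps = np.unique(np.round(rel).astype(np.int64) - 1)
        if np.any(snap_steps < 0) or np.any(snap_steps >= n_steps):
            raise ValueError("snapshot times outside the simulated window")
    snap_out = np.zeros((len(snap_steps), N_STATE, p.N))

    max_spikes = int(p.N * duration / 1000.0 * max_rate_cap) + 1000
    sp_neuron = np.zeros(max_spikes, dtype=np.int64)
    sp_step = np.zeros(max_spikes, dtype=np.int64)

    n_sp, status, last = _net_kernel(
        n_steps, p.dt, state,
        indptr, indices, wdata, m.is_exc,
        m.g_gaba_a_post, m.g_gaba_b_post,
        p.C, p.g_L, p.V_L, p.V_rest, p.theta,
        float(round(p.dt_AP / p.dt)),
        p.g_CAN, p.V_CAN, p.alpha_CAN, p.beta_CAN,
        p.g_AHP, p.V_AHP, p.alpha_AHP, p.beta_AHP,
        p.Ca0, p.tau_Ca, p.dCa,
        p.g_AMPA, p.g_NMDA, p.V_AMPA, p.V_NMDA, p.V_GABA_A, p.V_GABA_B,
        p.tau_AMPA, p.tau_NMDA_rise, p.tau_NMDA_decay, p.alpha_NMDA,
        p.tau_GABA_A, p.tau_GABA_B_rise, p.tau_GABA_B_decay, p.alpha_GABA_B,
        p.dx, p.Mg, p.g_AMPA_FF * p.p_AMPA_FF,
        snap_steps, snap_out,
        sp_neuron, sp_step,
    )
    if status == -1:
        raise FloatingPointError(
            f"non-finite state at t = {t_start + last * p.dt:.1f} ms"
        )
    if status == -2:
        raise RuntimeError("spike budget exceeded; runaway dynamics")

    times = t_start + (sp_step[:n_sp] + 1) * p.dt
    snapshots = {
        t_start + (s + 1) * p.dt: snap_out[k]
        for k, s in enumerate(snap_steps)
    }
    return SimResult(
        sp_neuron[:n_sp].astype(np.int32), times, p, m, seed,
        t_start, duration, snapshots,
    )


# ---------------------------------------------------------------------------
# statistics and sweeps


def spiking_statistics(
    result: SimResult | list[SpikeTrain],
    min_spikes: int = 100,
    fano_window: float = 100.0,
) -> pd.DataFrame:
    """Per-neuron firing statistics: rate, CV, CV2, Lv and Fano factor.

    CV is sd/mean of ISIs; CV2 and Lv are the consecutive-ISI local
    variability measures; the Fano factor uses counts in 100-ms windows.
    Neurons with fewer than ``min_spikes`` spikes are excluded from the
    table (their row is dropped, so means ignore them).
    """
    trains = (result.to_spike_trains() if isinstance(result, SimResult)
              else result)
    rows = []
    for tr in trains:
        if len(tr) < min_spikes:
            continue
        isi = np.diff(tr.times)
        cv = isi.std() / isi.mean() if isi.mean() > 0 else np.nan
        s = isi[:-1] + isi[1:]
        d = np.abs(np.diff(isi))
        ok = s > 0
        cv2 = float(np.mean(2.0 * d[ok] / s[ok])) if ok.any() else np.nan
        lv = float(np.mean(3.0 * (np.diff(isi)[ok] / s[ok]) ** 2)) \
            if ok.any() else np.nan
        edges = np.arange(tr.t_start, tr.t_stop + fano_window, fano_window)
        counts = np.histogram(tr.times, bins=edges)[0]
        fano = counts.var() / counts.mean() if counts.mean() > 0 else np.nan
        rows.append(dict(unit_id=tr.unit_id, is_exc=tr.cell_type == "RS",
                         rate=tr.rate, CV=cv, CV2=cv2, Lv=lv, Fano=fano))
    return pd.DataFrame(rows)


def population_signature(
    result: SimResult,
    min_spikes: int = 300,
    n_restarts: int = 20,
    seed: int = 0,
    max_neurons: int | None = None,
) -> pd.DataFrame:
    """Temporal signature of every neuron in a simulation.

    Returns a table (neuron, is_exc, lat, tau, rate, excluded); used by the
    conductance sweeps and the similarity maps.
    """
    from .temporal_signature import extract_signature

    trains = result.to_spike_trains()
    is_exc = result.matrix.is_exc
    idx = np.arange(len(trains))
    if max_neurons is not None and len(idx) > max_neurons:
        rng = np.random.default_rng(seed)
        keep_e = rng.choice(np.flatnonzero(is_exc),
                            int(max_neurons * 0.8), replace=False)
        keep_i = rng.choice(np.flatnonzero(~is_exc),
                            max_neurons - len(keep_e), replace=False)
        idx = np.sort(np.concatenate([keep_e, keep_i]))
    rows = []
    for i in idx:
        sig = extract_signature(trains[i], min_spikes=min_spikes,
                                n_restarts=n_restarts, seed=seed + i)
        rows.append(dict(neuron=i, is_exc=bool(is_exc[i]), lat=sig.lat,
                         tau=sig.tau, rate=sig.rate, excluded=sig.excluded,
                         reason=sig.exclusion_reason))
    return pd.DataFrame(rows)


def sweep_network(
    g_ahp_values: np.ndarray,
    g_gaba_b_values: np.ndarray,
    duration: float = 300_000.0,
    reps: int = 5,
    seed: int = 0,
    base: NetworkParams | None = None,
    min_spikes: int = 300,
    max_neurons: int | None = 120,
) -> pd.DataFrame:
    """Two-dimensional (g_AHP, g_GABA-B) exploration.

    For each grid cell and repetition: build a network, simulate, extract
    all neurons' signatures, and record mean LAT/TAU per population. Cells
    where more than half the neurons fail signature extraction are flagged.
    """
    base = base or NetworkParams()
    rows = []
    for i, ga in enumerate(np.atleast_1d(g_ahp_values)):
        for j, gb in enumerate(np.atleast_1d(g_gaba_b_values)):
            for r in range(reps):
                run_seed = (seed * 1_000_003 + i * 10_007 + j * 101 + r) \
                    & 0x7FFFFFFF
                p = replace(base, g_AHP=float(ga), g_GABA_B_scale=float(gb))
                mat = build_network(p, seed=run_seed)
                res = simulate_network(p, mat, duration, seed=run_seed)
                sig = population_signature(
                    res, min_spikes=min_spikes, seed=run_seed,
                    max_neurons=max_neurons,
                )
                ok = ~sig.excluded
                exc = sig.is_exc
                rows.append(dict(
                    g_AHP=float(ga), g_GABA_B=float(gb), rep=r,
                    lat_exc=sig.lat[ok & exc].mean(),
                    tau_exc=sig.tau[ok & exc].mean(),
                    lat_inh=sig.lat[ok & ~exc].mean(),
                    tau_inh=sig.tau[ok & ~exc].mean(),
                    mean_rate=sig.rate.mean(),
                    frac_failed=float(sig.excluded.mean()),
                    flagged=bool(sig.excluded.mean() > 0.5),
                ))
    return pd.DataFrame(rows)
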