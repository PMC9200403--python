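"""Conductance-based single-neuron model of a frontal pyramidal cell.

A Hodgkin-Huxley point neuron with leak, spike (Na/K), high- and low-
threshold calcium (CaL, CaT), calcium-activated non-specific cationic (CAN),
medium after-hyperpolarization potassium (AHP) and hyperpolarization-
activated (H) currents, driven by stochastic in-vivo-like synaptic
bombardment: AMPA, NMDA, GABA-A and GABA-B opening probabilities follow
Ornstein-Uhlenbeck processes whose means equal the steady state of the
corresponding network synaptic kinetics, with feed-forward excitation and
inhibition balanced at the mean membrane potential.

Integration is forward Euler at dt = 0.1 ms (numba-compiled); the OU
processes use the exact one-step update with reflection into [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .spike_data import SpikeTrain

__all__ = [
    "CellularParams",
    "OUBackgroundParams",
    "configure_background",
    "simulate_cell",
    "sweep_cellular",
    "nmda_mg_block",
]

FARADAY = 96_500.0  # C/mol


@dataclass(frozen=True)
class CellularParams:
    """Ionic parameters (conductances mS/cm^2, potentials mV, times ms).

    Defaults are the standard operating point of the model. The CaL
    activation Boltzmann (V_half, k) and rate constants (alpha, beta of the
    voltage-dependent time constant tau_CaL = 10/(alpha + beta V), floored
    at 0.1 ms) are order-of-magnitude values for L-type channels; a constant
    time constant can be substituted via ``tau_CaL_const``.
    """

    C: float = 1.0
    g_L: float = 0.05
    V_L: float = -70.0
    g_Na: float = 30.0
    V_Na: float = 50.0
    g_K: float = 2.0
    V_K: float = -90.0
    V_T: float = -65.0          # spike-kinetics threshold shift; places the
                                # AP threshold so the balanced background
                                # drives ~5 Hz irregular firing
    g_CaL: float = 0.01
    V_CaL: float = 150.0
    V_half_CaL: float = -10.0
    k_CaL: float = 6.0
    alpha_CaL: float = 2.0      # tau_CaL(V) = 10/(alpha + beta V) ms
    beta_CaL: float = -0.01
    tau_CaL_const: float | None = None
    g_CAN: float = 0.05
    V_CAN: float = 30.0
    alpha_CAN: float = 0.0015   # 1/(uM ms)
    beta_CAN: float = 0.005     # 1/ms
    g_AHP: float = 0.1
    V_AHP: float = -90.0
    alpha_AHP: float = 0.025
    beta_AHP: float = 0.025
    g_CaT: float = 0.0
    V_CaT: float = 120.0
    g_H: float = 0.0
    V_H: float = -40.0
    V_tauH_half: float = -105.0
    k_tauH: float = 10.0
    tau_H_min: float = 1000.0
    tau_H_max: float = 6000.0
    Ca0: float = 0.1            # uM
    tau_Ca: float = 25.0        # ms
    r0: float = 4e-4            # cm, soma radius
    r1: float = 0.25e-4         # cm, shell thickness

    @property
    def shell_surface_to_volume(self) -> float:
        """S/V of the sub-membrane calcium shell (1/cm)."""
        r0, r1 = self.r0, self.r1
        return (r1 * (1 - r1 / r0 + r1**2 / (3 * r0**2))) ** -1


_RECEPTORS = ("AMPA", "NMDA", "GABA_A", "GABA_B")


@dataclass(frozen=True)
class OUBackgroundParams:
    """Stochastic synaptic background (per-receptor OU opening probabilities).

    ``g`` holds maximal conductances; the two GABA entries are solved by
    :func:`configure_background` from the balance condition at ``V_mean``
    (``g_GABA_A_scale``/``g_GABA_B_scale`` are the printed scale factors).
    ``m``/``sigma`` are the OU means and standard deviations; sigma = m/2.
    """

    g_AMPA: float = 0.02
    g_NMDA: float = 0.03
    g_GABA_A_scale: float = 0.0063
    g_GABA_B_scale: float = 3.125e-4
    tau_decay: dict = field(default_factory=lambda: {
        "AMPA": 2.5, "NMDA": 75.0, "GABA_A": 10.0, "GABA_B": 160.0})
    tau_rise: dict = field(default_factory=lambda: {
        "NMDA": 4.65, "GABA_B": 90.0})
    alpha: dict = field(default_factory=lambda: {
        "NMDA": 0.275, "GABA_B": 0.015})
    dp: float = 0.1
    V_rev: dict = field(default_factory=lambda: {
        "AMPA": 0.0, "NMDA": 0.0, "GABA_A": -70.0, "GABA_B": -90.0})
    n_exc: int = 484
    n_inh: int = 121
    f_exc: float = 7.0          # Hz
    f_inh: float = 7.0
    Mg: float = 1.5             # mM
    V_mean: float = -57.5
    # filled by configure_background
    m: dict | None = None
    sigma: dict | None = None
    g_GABA_A: float | None = None
    g_GABA_B: float | None = None


def _steady_first_order(tau_d: float, dp: float, f_hz: float, n: int) -> float:
    drive = tau_d * dp * (f_hz / 1000.0) * n
    return 1.0 / (1.0 + 1.0 / drive)


def _steady_second_order(
    tau_d: float, tau_r: float, alpha: float, dp: float, f_hz: float, n: int
) -> float:
    q = _steady_first_order(tau_r, dp, f_hz, n)
    return 1.0 / (1.0 + 1.0 / (alpha * tau_d * q))


def nmda_mg_block(V: float, Mg: float = 1.5) -> float:
    """Voltage-dependent magnesium block of the NMDA channel."""
    return 1.0 / (1.0 + Mg * np.exp(-0.062 * V) / 3.57)


def configure_background(p: OUBackgroundParams) -> OUBackgroundParams:
    """Complete the background: OU means, sigmas and balanced GABA conductances.

    Means follow the steady state of first-order (AMPA, GABA-A) or
    second-order (NMDA, GABA-B) synaptic kinetics under ``n`` presynaptic
    neurons firing at ``f``; sigma = m/2. The GABA maximal conductances are
    scaled so the feed-forward inhibitory currents balance excitation at
    ``V_mean`` under the printed driving-force and count ratios.
    """
    if p.n_exc <= 0 or p.n_inh <= 0 or p.f_exc <= 0 or p.f_inh <= 0:
        raise ValueError("presynaptic counts and rates must be positive "
                         "(balance degenerate otherwise)")
    m = {
        "AMPA": _steady_first_order(p.tau_decay["AMPA"], p.dp, p.f_exc, p.n_exc),
        "NMDA": _steady_second_order(
            p.tau_decay["NMDA"], p.tau_rise["NMDA"], p.alpha["NMDA"],
            p.dp, p.f_exc, p.n_exc),
        "GABA_A": _steady_first_order(
            p.tau_decay["GABA_A"], p.dp, p.f_inh, p.n_inh),
        "GABA_B": _steady_second_order(
            p.tau_decay["GABA_B"], p.tau_rise["GABA_B"], p.alpha["GABA_B"],
            p.dp, p.f_inh, p.n_inh),
    }
    sigma = {k: 0.5 * v for k, v in m.items()}
    ratio = p.n_exc / p.n_inh
    V_exc = p.V_rev["AMPA"]
    g_a = p.g_GABA_A_scale * (
        -(p.V_mean - V_exc) / (p.V_mean - p.V_rev["GABA_A"])) * ratio
    g_b = p.g_GABA_B_scale * (
        -(p.V_mean - V_exc) / (p.V_mean - p.V_rev["GABA_B"])) * ratio
    return replace(p, m=m, sigma=sigma, g_GABA_A=g_a, g_GABA_B=g_b)


# ---------------------------------------------------------------------------
# numba kernel


@njit(cache=True, fastmath=True)
def _cell_kernel(  # noqa: C901 - single hot loop on purpose
    n_steps, dt, seed,
    C, g_L, V_L, g_Na, V_Na, g_K, V_K, V_T,
    g_CaL, V_CaL, Vh_CaL, k_CaL, a_CaL, b_CaL, tau_CaL_const,
    g_CAN, V_CAN, a_CAN, b_CAN,
    g_AHP, V_AHP, a_AHP, b_AHP,
    g_CaT, V_CaT, g_H, V_H, Vh_tauH, k_tauH, tauH_min, tauH_max,
    Ca0, tau_Ca, sv_ratio,
    g_syn, V_syn, m_syn, s_syn, tau_syn, Mg,
    record_stride, max_spikes,
):
    np.random.seed(seed)
    V = V_L
    Ca = Ca0
    # spike gating at steady state
    m_na = 0.0
    h_na = 1.0
    n_k = 0.0
    p_cal = 1.0 / (1.0 + np.exp(-(V - Vh_CaL) / k_CaL))
    p_can = a_CAN * Ca / (a_CAN * Ca + b_CAN)
    p_ahp = a_AHP * Ca / (a_AHP * Ca + b_AHP)
    h_cat = 1.0
    r_h = 1.0 / (1.0 + np.exp((V + 75.0) / 5.5))
    p_syn = m_syn.copy()

    n_rec = n_steps // record_stride if record_stride > 0 else 0
    trace_V = np.empty(n_rec)
    trace_Ca = np.empty(n_rec)
    spikes = np.empty(max_spikes)
    n_sp = 0
    above = V > -20.0

    two_F = 2.0 * FARADAY
    for step in range(n_steps):
        # --- OU synaptic background (exact update, reflected into [0, 1])
        I_syn = 0.0
        for s in range(4):
            a = np.exp(-dt / tau_syn[s])
            sd = s_syn[s] * np.sqrt(1.0 - a * a)
            p = m_syn[s] + (p_syn[s] - m_syn[s]) * a + sd * np.random.normal()
            if p < 0.0:
                p = -p
            if p > 1.0:
                p = 2.0 - p
            if p < 0.0:
                p = 0.0
            elif p > 1.0:
                p = 1.0
            p_syn[s] = p
            gate = 1.0
            if s == 1:  # NMDA magnesium block
                gate = 1.0 / (1.0 + Mg * np.exp(-0.062 * V) / 3.57)
            I_syn += g_syn[s] * p * gate * (V - V_syn[s])

        # --- spike currents (Traub-Miles kinetics shifted by V_T)
        vt = V - V_T
        am = 0.32 * (13.0 - vt) / (np.exp((13.0 - vt) / 4.0) - 1.0)
        bm = 0.28 * (vt - 40.0) / (np.exp((vt - 40.0) / 5.0) - 1.0)
        ah = 0.128 * np.exp((17.0 - vt) / 18.0)
        bh = 4.0 / (1.0 + np.exp((40.0 - vt) / 5.0))
        an = 0.032 * (15.0 - vt) / (np.exp((15.0 - vt) / 5.0) - 1.0)
        bn = 0.5 * np.exp((10.0 - vt) / 40.0)
        m_na += dt * (am * (1.0 - m_na) - bm * m_na)
        h_na += dt * (ah * (1.0 - h_na) - bh * h_na)
        n_k += dt * (an * (1.0 - n_k) - bn * n_k)
        if m_na < 0.0:
            m_na = 0.0
        elif m_na > 1.0:
            m_na = 1.0
        if h_na < 0.0:
            h_na = 0.0
        elif h_na > 1.0:
            h_na = 1.0
        if n_k < 0.0:
            n_k = 0.0
        elif n_k > 1.0:
            n_k = 1.0
        I_Na = g_Na * m_na**3 * h_na * (V - V_Na)
        I_K = g_K * n_k**4 * (V - V_K)

        # --- CaL with voltage-dependent time constant (floored at 0.1 ms)
        p_inf = 1.0 / (1.0 + np.exp(-(V - Vh_CaL) / k_CaL))
        if tau_CaL_const > 0.0:
            tau_cal = tau_CaL_const
        else:
            denom = a_CaL + b_CaL * V
            tau_cal = 10.0 / denom if denom > 0.0 else 0.1
            if tau_cal < 0.1:
                tau_cal = 0.1
        p_cal += dt * (p_inf - p_cal) / tau_cal
        if p_cal < 0.0:
            p_cal = 0.0
        elif p_cal > 1.0:
            p_cal = 1.0
        I_CaL = g_CaL * p_cal * p_cal * (V - V_CaL)

        # --- CaT (instantaneous activation, slow inactivation)
        I_CaT = 0.0
        if g_CaT > 0.0:
            m_cat = 1.0 / (1.0 + np.exp(-(V + 57.0) / 6.2))
            h_inf = 1.0 / (1.0 + np.exp((V + 81.0) / 4.0))
            tau_h = 30.0 + 200.0 / (1.0 + np.exp((V + 78.0) / 5.0))
            h_cat += dt * (h_inf - h_cat) / tau_h
            if h_cat < 0.0:
                h_cat = 0.0
            elif h_cat > 1.0:
                h_cat = 1.0
            I_CaT = g_CaT * m_cat * m_cat * h_cat * (V - V_CaT)

        # --- H current (Boltzmann-shaped time constant)
        I_H = 0.0
        if g_H > 0.0:
            r_inf = 1.0 / (1.0 + np.exp((V + 75.0) / 5.5))
            tau_r = tauH_min + (tauH_max - tauH_min) / (
                1.0 + np.exp((V - Vh_tauH) / k_tauH))
            r_h += dt * (r_inf - r_h) / tau_r
            if r_h < 0.0:
                r_h = 0.0
            elif r_h > 1.0:
                r_h = 1.0
            I_H = g_H * r_h * (V - V_H)

        # --- calcium-gated CAN and AHP
        p_can += dt * (a_CAN * Ca * (1.0 - p_can) - b_CAN * p_can)
        p_ahp += dt * (a_AHP * Ca * (1.0 - p_ahp) - b_AHP * p_ahp)
        if p_can < 0.0:
            p_can = 0.0
        elif p_can > 1.0:
            p_can = 1.0
        if p_ahp < 0.0:
            p_ahp = 0.0
        elif p_ahp > 1.0:
            p_ahp = 1.0
        I_CAN = g_CAN * p_can * (V - V_CAN)
        I_AHP = g_AHP * p_ahp * p_ahp * (V - V_AHP)

        # --- calcium dynamics; (uA/cm^2)(1/cm)/(C/mol) is uM/ms exactly
        influx = -(I_CaL + I_CaT) / two_F * sv_ratio
        if influx < 0.0:
            influx = 0.0
        Ca += dt * (influx + (Ca0 - Ca) / tau_Ca)
        if Ca < 0.0:
            Ca = 0.0

        I_ionic = (g_L * (V - V_L) + I_Na + I_K + I_CaL + I_CAN + I_AHP
                   + I_CaT + I_H)
        V += dt * (-(I_ionic + I_syn)) / C
        if np.abs(V) > 200.0:
            return spikes[:n_sp], trace_V[:0], trace_Ca[:0], -1, step

        if V > -20.0 and not above:
            if n_sp < max_spikes:
                spikes[n_sp] = (step + 1) * dt
                n_sp += 1
            above = True
        elif V <= -20.0:
            above = False

        if record_stride > 0 and step % record_stride == 0:
            idx = step // record_stride
            if idx < n_rec:
                trace_V[idx] = V
                trace_Ca[idx] = Ca
    return spikes[:n_sp], trace_V, trace_Ca, 0, n_steps


def simulate_cell(
    cp: CellularParams,
    bg: OUBackgroundParams,
    duration: float,
    dt: float = 0.1,
    seed: int = 0,
    record_stride: int = 0,
    unit_id: str = "cell",
) -> tuple[SpikeTrain, dict]:
    """Forward-Euler simulation of the cell under OU synaptic bombardment.

    Returns the spike train (upward crossings of -20 mV) and a dict with the
    membrane/calcium traces (decimated by ``record_stride`` steps when > 0)
    and the realised mean rate. A numerical blow-up (|V| > 200 mV) raises.
    """
    if bg.m is None:
        bg = configure_background(bg)
    n_steps = int(round(duration / dt))
    g_syn = np.array([bg.g_AMPA, bg.g_NMDA, bg.g_GABA_A, bg.g_GABA_B])
    V_syn = np.array([bg.V_rev[r] for r in _RECEPTORS])
    m_syn = np.array([bg.m[r] for r in _RECEPTORS])
    s_syn = np.array([bg.sigma[r] for r in _RECEPTORS])
    tau_syn = np.array([bg.tau_decay[r] for r in _RECEPTORS])
    max_spikes = int(duration / 1000.0 * 300.0) + 1000
    tau_cal_const = -1.0 if cp.tau_CaL_const is None else cp.tau_CaL_const

    spikes, tv, tca, status, last = _cell_kernel(
        n_steps, dt, seed & 0x7FFFFFFF,
        cp.C, cp.g_L, cp.V_L, cp.g_Na, cp.V_Na, cp.g_K, cp.V_K, cp.V_T,
        cp.g_CaL, cp.V_CaL, cp.V_half_CaL, cp.k_CaL, cp.alpha_CaL,
        cp.beta_CaL, tau_cal_const,
        cp.g_CAN, cp.V_CAN, cp.alpha_CAN, cp.beta_CAN,
        cp.g_AHP, cp.V_AHP, cp.alpha_AHP, cp.beta_AHP,
        cp.g_CaT, cp.V_CaT, cp.g_H, cp.V_H, cp.V_tauH_half, cp.k_tauH,
        cp.tau_H_min, cp.tau_H_max,
        cp.Ca0, cp.tau_Ca, cp.shell_surface_to_volume,
        g_syn, V_syn, m_syn, s_syn, tau_syn, bg.Mg,
        record_stride, max_spikes,
    )
    if status < 0:
        raise FloatingPointError(
            f"membrane potential blew up at t = {last * dt:.1f} ms"
        )
    train = SpikeTrain(unit_id, spikes, 0.0, duration)
    info = {"mean_rate": train.rate, "V": tv, "Ca": tca, "dt": dt,
            "record_stride": record_stride}
    return train, info


def sweep_cellular(
    g_can_values: np.ndarray,
    g_ahp_values: np.ndarray,
    duration: float = 100_000.0,
    base_params: CellularParams | None = None,
    bg: OUBackgroundParams | None = None,
    seed: int = 0,
    reps: int = 1,
    min_spikes: int = 500,
) -> "pd.DataFrame":
    """Grid exploration over (g_CAN, g_AHP): signature and rate per cell.

    Each grid point is simulated ``reps`` times with derived seeds; LAT,
    TAU and mean rate are recorded, cells firing above 20 Hz are flagged
    discarded, and failed signature extractions are recorded as missing.
    """
    import pandas as pd

    from .similarity import RATE_CEILING_HZ
    from .temporal_signature import extract_signature

    base = base_params or CellularParams()
    bg = configure_background(bg or OUBackgroundParams())
    rows = []
    for i, g_can in enumerate(np.atleast_1d(g_can_values)):
        for j, g_ahp in enumerate(np.atleast_1d(g_ahp_values)):
            for r in range(reps):
                cp = replace(base, g_CAN=float(g_can), g_AHP=float(g_ahp))
                run_seed = (seed * 100_003 + i * 1009 + j * 101 + r) & 0x7FFFFFFF
                train, info = simulate_cell(cp, bg, duration, seed=run_seed)
                sig = extract_signature(train, min_spikes=min_spikes,
                                        seed=run_seed)
                rows.append(dict(
                    g_CAN=float(g_can), g_AHP=float(g_ahp), rep=r,
                    lat=sig.lat, tau=sig.tau,
                    mean_rate=info["mean_rate"],
                    discarded=info["mean_rate"] > RATE_CEILING_HZ,
                    excluded=sig.excluded, reason=sig.exclusion_reason,
                ))
    return pd.DataFrame(rows)
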