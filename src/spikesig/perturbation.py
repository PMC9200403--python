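"""State-transition perturbation protocol.

Starting from an unperturbed network simulation segmented into HMM states,
the dynamical state (membrane potential, refractory/spiking state, calcium,
and all synaptic opening variables) of a random subset of excitatory or
inhibitory neurons is substituted, 50 ms after the onset of an ongoing-state
period, by the values those neurons had 50 ms after the onset of a period of
a distinct target state. The network is then resumed to the end of the
original ongoing period and re-decoded with the frozen HMM parameters
(forward filtering); the escape probability is the fraction of that time
spent outside the ongoing state, the reach probability the fraction spent
in the target state (so reach <= escape by construction).

Because the network dynamics are deterministic given a snapshot, a
substitution fraction of zero reproduces the unperturbed trajectory exactly
and measures the basal escape/reach probabilities, which the sweep also
reports offset-subtracted and normalised ((raw - basal)/(1 - basal),
clipped at zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metastability import HMMConfig, HMMFit, StateSequence, decode_states, fit_hmm
from .network import NetworkParams, SimResult, SynapticMatrix, simulate_network

__all__ = [
    "PerturbationSpec",
    "PerturbationContext",
    "prepare_context",
    "run_perturbation",
    "transition_sweep",
]

SNAPSHOT_OFFSET_MS = 50.0
MIN_PERIOD_MS = 100.0


@dataclass(frozen=True)
class PerturbationSpec:
    """One perturbation condition."""

    population: str                  # "Exc" | "Inh" | "Both" (diagnostic)
    fraction: float
    snapshot_offset: float = SNAPSHOT_OFFSET_MS
    min_period: float = MIN_PERIOD_MS

    def __post_init__(self) -> None:
        if self.population not in ("Exc", "Inh", "Both"):
            raise ValueError("population must be 'Exc', 'Inh' or 'Both'")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")


@dataclass
class PerturbationContext:
    """A fully analysed unperturbed run ready for perturbations."""

    params: NetworkParams
    matrix: SynapticMatrix
    sim: SimResult
    hmm: HMMFit
    seq: StateSequence
    periods: pd.DataFrame            # qualifying periods (state, t0, t1)
    snapshots: dict[float, np.ndarray] = field(default_factory=dict)

    def ensure_snapshots(self, times: np.ndarray) -> None:
        """Capture missing snapshots by re-running the (deterministic)
        unperturbed simulation once for the union of requested times."""
        need = sorted(set(float(t) for t in times) - set(self.snapshots))
        if not need:
            return
        res = simulate_network(
            self.params, self.matrix, self.sim.duration, seed=self.sim.seed,
            snapshot_times=np.asarray(need), t_start=self.sim.t_start,
        )
        self.snapshots.update(res.snapshots)


def prepare_context(
    params: NetworkParams,
    matrix: SynapticMatrix,
    duration: float,
    seed: int = 0,
    cfg: HMMConfig | None = None,
    min_period: float = MIN_PERIOD_MS,
    sim: SimResult | None = None,
    hmm: HMMFit | None = None,
) -> PerturbationContext:
    """Simulate (or reuse) an unperturbed run, fit/decode its HMM, and list
    the periods long enough (> ``min_period`` ms) to be perturbed."""
    cfg = cfg or HMMConfig()
    if sim is None:
        sim = simulate_network(params, matrix, duration, seed=seed)
    raster = sim.to_raster()
    if hmm is None:
        hmm = fit_hmm(raster, cfg, seed=seed)
    seq = decode_states(hmm.posteriors(raster), cfg,
                        bin_width=raster.bin_width)
    per = seq.periods()
    per = per[(per.state >= 0) & (per.duration > min_period)].reset_index(
        drop=True)
    per["t0"] += sim.t_start
    per["t1"] += sim.t_start
    return PerturbationContext(params, matrix, sim, hmm, seq, per)


def run_perturbation(
    ctx: PerturbationContext,
    ongoing_idx: int,
    target_idx: int,
    spec: PerturbationSpec,
    rng: np.random.Generator,
) -> dict:
    """Perturb one ongoing period with one target period's state.

    Returns the raw escape and reach probabilities (fractions of decoded
    post-perturbation time), with the ongoing and target state labels.
    """
    ongoing = ctx.periods.iloc[ongoing_idx]
    target = ctx.periods.iloc[target_idx]
    if int(ongoing.state) == int(target.state):
        raise ValueError("ongoing and target states must differ")
    t_pert = float(ongoing.t0) + spec.snapshot_offset
    t_snap = float(target.t0) + spec.snapshot_offset
    ctx.ensure_snapshots(np.array([t_pert, t_snap]))
    state = ctx.snapshots[t_pert].copy()
    donor = ctx.snapshots[t_snap]

    if spec.population == "Both":
        pool = np.arange(ctx.matrix.n)
    else:
        pool = np.flatnonzero(ctx.matrix.is_exc if spec.population == "Exc"
                              else ~ctx.matrix.is_exc)
    n_sub = int(round(spec.fraction * len(pool)))
    if n_sub > 0:
        chosen = rng.choice(pool, size=n_sub, replace=False)
        state[:, chosen] = donor[:, chosen]

    remaining = float(ongoing.t1) - t_pert
    res = simulate_network(
        ctx.params, ctx.matrix, remaining, seed=ctx.sim.seed,
        init_state=state, t_start=t_pert,
    )
    raster = res.to_raster()
    filt = ctx.hmm.filtered(raster)
    # the perturbed segment is re-decoded from the frozen HMM's filtered
    # state probabilities; the most probable state is taken per bin (the
    # null-state convention belongs to the segmentation stage, not here,
    # where transient evidence dips would masquerade as transitions)
    lab = filt.argmax(axis=1)
    escape = float(np.mean(lab != int(ongoing.state)))
    reach = float(np.mean(lab == int(target.state)))
    return dict(escape=escape, reach=reach,
                ongoing_state=int(ongoing.state),
                target_state=int(target.state),
                fraction=spec.fraction, population=spec.population,
                n_bins=len(lab))


def _sample_pairs(
    periods: pd.DataFrame, n_states: int, n_combinations: int,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Random (ongoing, target) period pairs for each ordered state pair."""
    by_state = {s: periods.index[periods.state == s].to_numpy()
                for s in range(n_states)}
    pairs = []
    for a in range(n_states):
        for b in range(n_states):
            if a == b or len(by_state[a]) == 0 or len(by_state[b]) == 0:
                continue
            for _ in range(n_combinations):
                i = int(rng.choice(by_state[a]))
                j = int(rng.choice(by_state[b]))
                pairs.append((i, j))
    return pairs


def transition_sweep(
    contexts: list[PerturbationContext],
    fractions: np.ndarray,
    populations: tuple[str, ...] = ("Exc", "Inh"),
    n_combinations: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Escape/reach probability curves over substitution fractions.

    For every network context, random period combinations are drawn for each
    of the ordered state pairs; each combination is perturbed at every
    fraction and population. Basal probabilities come from the fraction-0
    runs (population-independent) and are used to offset and normalise the
    curves. Returns one row per (population, fraction) with means, s.e.m.,
    and both corrected variants; basal values are reported in the
    ``escape_basal``/``reach_basal`` columns.
    """
    fractions = np.asarray(sorted(set(np.atleast_1d(fractions).tolist()
                                      + [0.0])))
    rng = np.random.default_rng(seed)
    records = []
    for ci, ctx in enumerate(contexts):
        n_states = ctx.hmm.n_states
        have = ctx.periods.state.nunique()
        if have < 2:
            warnings.warn(f"context {ci}: fewer than 2 states with long "
                          "periods; skipped")
            continue
        pairs = _sample_pairs(ctx.periods, n_states, n_combinations, rng)
        # capture every snapshot in one deterministic rerun
        times = []
        for i, j in pairs:
            times.append(float(ctx.periods.t0[i]) + SNAPSHOT_OFFSET_MS)
            times.append(float(ctx.periods.t0[j]) + SNAPSHOT_OFFSET_MS)
        ctx.ensure_snapshots(np.asarray(times))
        for i, j in pairs:
            for frac in fractions:
                pops = ("Exc",) if frac == 0.0 else populations
                for pop in pops:
                    out = run_perturbation(
                        ctx, i, j, PerturbationSpec(pop, float(frac)), rng
                    )
                    out["network"] = ci
                    records.append(out)
    runs = pd.DataFrame(records)
    if runs.empty:
        raise ValueError("no perturbation run could be performed")

    basal = runs[runs.fraction == 0.0]
    b_esc = float(basal.escape.mean())
    b_reach = float(basal.reach.mean())

    rows = []
    for pop in populations:
        for frac in fractions:
            sel = runs[(runs.fraction == frac)
                       & ((runs.population == pop) | (frac == 0.0))]
            if sel.empty:
                continue
            esc, rea = sel.escape, sel.reach
            rows.append(dict(
                population=pop, fraction=float(frac),
                escape=float(esc.mean()),
                escape_sem=float(esc.sem()) if len(esc) > 1 else 0.0,
                reach=float(rea.mean()),
                reach_sem=float(rea.sem()) if len(rea) > 1 else 0.0,
                escape_offset=float(esc.mean() - b_esc),
                reach_offset=float(rea.mean() - b_reach),
                escape_norm=max(0.0, (esc.mean() - b_esc) / (1.0 - b_esc))
                if b_esc < 1 else 0.0,
                reach_norm=max(0.0, (rea.mean() - b_reach) / (1.0 - b_reach))
                if b_reach < 1 else 0.0,
                escape_basal=b_esc, reach_basal=b_reach,
                n_runs=len(sel),
            ))
    return pd.DataFrame(rows)
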