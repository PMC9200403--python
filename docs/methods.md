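# Methods

This note documents the models and procedures implemented in `spikesig`,
the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not establish about real recordings.

## Temporal signature of a spike train

A unit's temporal signature is the pair (LAT, TAU) extracted from its spike
autocorrelogram:

1. All forward lagged differences t_{i+k} − t_i up to order k = 100 are
   histogrammed in 3.33-ms bins over (0, 1000] ms. When the train carries an
   interval structure (engage/pause restriction), differences are only
   formed within a single interval, so gaps never fabricate short lags.
2. The histogram is converted to a density and rescaled to peak at 1 (the
   scale affects only the fitted amplitude A and offset B, never LAT or
   TAU), the first 10 ms are dropped (refractory/sorting artefacts), and a
   loess-smoothed copy (tricube-weighted local quadratic regression,
   span 0.1 of the 297 analysed bins) is attached. We implement the
   smoother directly because the installed local-regression routines are
   degree-1; a unit test checks agreement with `statsmodels` lowess.
3. The peak is the maximum of the smoothed curve, except when that maximum
   is the very first analysed bin, in which case the first later local
   maximum is used (flagged if none exists). LAT is the peak's bin centre.
4. A mono-exponential `A exp(−t/TAU) + B` is fitted from the peak to the end
   of the smoothed curve by Levenberg–Marquardt from 50 random
   initialisations (A ∈ [0, 2(max−min)], B ∈ [0, 2 min], TAU ∈ [0, 1000]
   ms); the lowest-residual fit is kept and is valid only if A, B and TAU
   are all positive. TAU is the GLOBAL fit's time constant.
5. When the smoothed curve shows a dip — the first local minimum within
   100 ms after the peak descending below `min + 0.75 (max − min)` — a FAST
   fit (peak → dip) and a SLOW fit (second peak → end) are computed purely
   as a quality check: the unit is kept only if the GLOBAL fit is valid and
   either FAST or SLOW is invalid or the GLOBAL rmse is below the sum of
   the FAST and SLOW rmse. The threshold's reading ("below 75% of the
   global range") is ambiguous; measuring from the top instead is available
   via `dip_from_top=True`.
6. Units with fewer than 1000 spikes in the analysed record are excluded
   (the published criterion mentions a spike-count floor without stating
   it; 1000 gives ≳ 95% fit success on well-sampled synthetic trains and is
   configurable). Scaled-down network analyses use a 300-spike floor over
   300-s records, stated where used.

For population-level contrasts on short records we additionally provide the
pooled-population signature: lag histograms are summed across a
population's units before normalisation, and LAT/TAU are extracted from
that pooled autocorrelogram. Single-unit autocorrelograms at ~1–3 Hz over
300 s carry so much sampling noise that the mean of per-unit LATs is
dominated by it; the pooled estimator resolves the conductance-driven
shifts reproducibly and is what the preset-contrast tests use.

The spike-count method (`scTAU`) correlates 50-ms spike-count bins of a
700-ms pre-cue window across trials, averages Pearson correlations per lag,
and fits the same exponential (per unit or pooled across units). The
first-order latency is the peak lag of the ISI histogram built with the
same binning and smoothing as the autocorrelogram (the smoothed histogram
is used; the raw/smoothed choice is not documented in the source method).

## Rank-based statistics

The BLOM transform maps values to approximate normal scores,
`Y_i = Φ⁻¹((r_i − 3/8)/(N + 1/4))`, with average ranks on ties. Context
modulation is summarised per unit as `ln(TAU_a)/ln(TAU_b)` (natural log;
the base only rescales). Median splits are computed within (area ×
cell-type) strata, values at the median going to "short"; a permutation
utility redraws labels preserving group sizes.

## Cellular model

A single-compartment Hodgkin–Huxley pyramidal cell with leak, Na/K spike
currents, L- and T-type calcium, CAN (calcium-activated cationic), medium
AHP (calcium-activated potassium) and H currents; calcium from CaL/CaT
influx through a sub-membrane shell with first-order extrusion (τ = 25 ms).
CAN and AHP gate on calcium with `τ = 1/(αCa + β)` and
`p∞ = αCa/(αCa + β)`. Synaptic bombardment mimics the in-vivo state:
AMPA/NMDA/GABA-A/GABA-B opening probabilities follow Ornstein–Uhlenbeck
processes whose means are the steady states of the corresponding network
kinetics under 484 excitatory and 121 inhibitory presynaptic neurons firing
at 7 Hz, with σ = m/2, the NMDA magnesium block
`x(V) = (1 + [Mg]e^(−0.062V)/3.57)⁻¹`, and GABA conductances scaled so the
driving-force-weighted inhibition cancels excitation at V_mean = −57.5 mV.
Integration is forward Euler at dt = 0.1 ms; the OU processes use the exact
one-step update (stationary sd = σ) reflected into [0, 1].

Open parameters and their resolution:

* The Na/K kinetics are cited to an earlier model rather than printed; we
  use Traub–Miles cortical kinetics with threshold parameter V_T. Under the
  balanced background the membrane rests near −63 mV, so V_T = −65 mV
  places the action-potential threshold where the fluctuations drive ~5 Hz
  irregular firing — a realistic frontal pyramidal rate in vivo and well
  below the 20-Hz realism ceiling used to discard unrealistic parameter
  couples.
* The printed CaL time constant expression is typographically corrupted; we
  read it as τ_CaL(V) = 10/(α + βV), floored at 0.1 ms, with
  order-of-magnitude L-type constants (V_half = −10 mV, k = 6 mV, α = 2,
  β = −0.01) and a constant-τ escape hatch. The H-current time constant
  uses a standard Boltzmann between the printed bounds (1–6 s).

## Network model

605 leaky integrate-and-fire neurons (484 excitatory, 121 inhibitory),
V_rest = −65 mV, θ = −50 mV, 3-ms refractory, dt = 0.5 ms, one-step (0.5
ms) synaptic delay. Excitatory neurons additionally carry the CAN and AHP
currents with spike-triggered calcium increments (ΔCa = 0.2 µM). Recurrent
AMPA/GABA-A synapses follow first-order kinetics with saturating increments
Δx(1−p); NMDA/GABA-B are second order (rise q → drive αq(1−p)). Weights
are log-normal with mean 0.03 and sd 0.02 of the weight itself (moment
matching for the underlying normal; a switch treats the parameters as
log-scale instead). Per-postsynaptic-neuron GABA-A/GABA-B maximal
conductances balance the excitatory/inhibitory weight sums at V_mean. The
feed-forward drive is a constant-opening AMPA conductance.

Bidirectional E–E motifs: with connection probability 0.3 per direction, a
bidirectional excess of 4× over the independent expectation is infeasible —
the maximum is 1/p = 3.33×, attained when every existing E–E connection is
reciprocal. We keep the marginal density exact and cap the excess at that
bound (warning emitted); the realised factor is 3.33.

The integration kernel tracks, per postsynaptic neuron, the weighted sums
of presynaptic opening probabilities. Because decay is linear and uniform,
first-order sums update by pure decay plus event-driven jumps, and
second-order drives scatter through the sparse weight structure; both use
the same forward-Euler factors as the per-neuron states, so the tracked
sums are exact. Dynamics contain no runtime randomness — connectivity and
the uniform-in-[V_rest, θ) initial voltages are drawn from the seed — so a
run is fully determined by (parameters, seed) and any snapshot of the state
vector (V, refractory clock, calcium, CAN/AHP gating, all synaptic p and q,
and spikes in flight) resumes bit-identically.

Area presets (g_CAN = 0.025 mS·cm⁻² everywhere): LPFCm g_AHP = 0.022,
g_GABA-B = 0.0035; MCCm g_AHP = 0.087, g_GABA-B = 0.0143; plus the two
single-conductance swaps. In our hands the presets reproduce the
qualitative contrasts — higher AHP raises excitatory LAT (pooled
autocorrelograms: 58 → 68 ms) and leaves inhibitory LAT untouched; higher
GABA-B lengthens TAU in both populations — with quantitatively shorter
state durations than the source model (see Limitations).

## Similarity

Populations are compared through bivariate Gaussian-KDE densities of
(TAU, LAT) on a shared 200 × 200 grid (TAU ∈ [0, 1000] ms, LAT ∈ [0, 300]
ms; Scott's-rule bandwidth — the original bandwidth is unstated, so only
relative map structure is meaningful), scored by the normalised Frobenius
inner product, and combined as 0.8 · S(RS, Exc) + 0.2 · S(FS, Inh).
Cellular models are scored by the reference density at their (TAU, LAT)
point; models firing above 20 Hz are discarded. Best-fit parameters on a
similarity map are the similarity-weighted centroid of the region within
80% of the maximum.

## Metastability

Population rasters at 0.5-ms bins are segmented with a hidden Markov model
whose emissions are independent per-neuron Bernoulli spike probabilities
per state (counts above one collapse to a spike; at these rates Bernoulli
and Poisson coincide). The number of states is fixed at 4; AIC/BIC scans
over 2–10 states are provided as a check. EM restarts initialise the
self-transition from a 300-ms mean duration and each state's emissions from
the mean spike probability in a random 10-s window blended with the global
mean (this data-driven initialisation escapes the symmetric local optimum
that a pure global-mean start falls into); convergence at relative
log-likelihood change < 1e-6 or 500 iterations; the best restart by
log-likelihood is kept. Segmentation uses forward–backward posteriors: bins
where no state reaches 0.8 form the null state S0, and S0 periods flanked
by one same state are absorbed into it. Duration statistics pool state
periods (S0 excluded, periods > 300 s dropped): the time-weighted
distribution p_t(d) ∝ p(d)·d, the median duration, and the KS distance of
log-durations to a fitted normal. State geometry convolves spiking with a
100-ms Gaussian kernel (evaluated on 10-ms samples), drops neurons below
0.5 Hz, z-scores per neuron, and measures mean pairwise distances between
per-state centroids, with a PCA projection for visualisation. The shuffle
control redraws every spike's time and neuron uniformly.

Pseudo-populations pool units recorded in different sessions onto a common
clock starting at each unit's own record start; the resulting states are
chimeric (cross-session phase is meaningless) but preserve each unit's
temporal structure, which is what the duration comparisons use.

## Perturbation protocol

From a 600-s unperturbed run segmented as above, a perturbation substitutes
the full dynamical state (membrane potential, refractory/spiking state,
calcium, all synaptic opening variables) of a random subset of excitatory
or inhibitory neurons, 50 ms after the onset of an ongoing-state period
(> 100 ms long), with the state those neurons had 50 ms after the onset of
a target-state period. The network is resumed to the end of the original
period and re-decoded with the frozen HMM parameters by forward filtering;
each bin is assigned its most probable filtered state (no S0 rule here —
thresholding filtered probabilities would count transient evidence dips as
transitions). Escape is the fraction of that time outside the ongoing
state, reach the fraction in the target state (reach ≤ escape by
construction). Because the dynamics are deterministic from a snapshot,
fraction-0 runs reproduce the unperturbed trajectory exactly and define the
basal probabilities; curves are reported raw, offset (raw − basal) and
normalised ((raw − basal)/(1 − basal), clipped at 0).

## Synthetic data

* `gen_ou_poisson`: doubly stochastic Poisson train whose rate follows an
  exact-update OU process rectified at zero (warning above 20%
  rectification). Default modulation depth rate_sd = 0.8 × mean rate,
  chosen so the autocorrelogram amplitude ratio A/B (~0.6) resembles
  published frontal-unit autocorrelograms, which decay by more than half
  their peak; at σ = µ/2 the modulation (25%) is much weaker than any real
  example. Mean rate 5 Hz and 600-s records in the recovery tests.
* `gen_renewal_burst`: gamma-renewal core (analytic ISI mode
  (shape−1)/shape × mean is the LAT ground truth) with optional burst
  insertions at short intra-burst intervals.
* `gen_markov_raster`: hidden Markov chain with exponential (or log-normal,
  for KS tests) dwell times and per-state Poisson rates at 0.5-ms bins;
  recovery fixtures use 60 neurons whose per-state rates are 2 or 20 Hz
  (coin-flip per neuron and state), i.e. clearly separated states, and
  dwell means of 0.1/0.3/1/3 s.
* `gen_session_events`: trial event log with planted pauses (≥ 60 s gaps)
  and the 7-step bonus gauge advancing per block quota (14/21/28/35
  correct trials).

What passing these tests shows: the pipeline recovers known timescales,
latencies and state structure from data that satisfy its assumptions
(stationarity, exponential-decay correlations, Markov switching between
fixed rate patterns). What they do not show: robustness to drift,
behavioural non-stationarity, correlated noise across units, or spike-
sorting artefacts present in real recordings.

## Problem sizes

The default test battery uses 300-s network simulations with two seeds per
preset, 10 perturbation combinations per state pair on one network, and
4-restart HMM fits; the acceptance script uses the full 600-s records with
3 restarts and one network per preset. These sizes keep the whole analysis
on a laptop core while leaving the estimators' medians stable (the
replicate counts were chosen so that the recovery medians move by far less
than the tolerances they are tested against).

## Known limitations

* The network reproduces the LPFCm/MCCm contrasts qualitatively, but its
  metastable states are several-fold shorter than the source model's
  (mean raw S0 durations of ~5–8 ms (LPFCm) and ~8–17 ms (MCCm) across
  network seeds, against the published 16/36 ms; decoded state medians of
  tens rather than hundreds of milliseconds, with corresponding
  seed-to-seed variability in the basal escape/reach probabilities). The
  printed equations and parameters under-determine several ingredients
  (AP kinetics, reciprocity construction, initial conditions), and
  attractor depth in a chaotic network is sensitive to exactly such
  details. Excitatory-substitution escape probabilities are
  correspondingly above basal rather than flat: with shallow attractors,
  any perturbation's chaotic divergence eventually leaves the
  (short-lived) ongoing state. The inhibitory-dominance asymmetry itself
  is robust.
* Because LAT on gamma-renewal fixtures equals the first-order ISI mode
  only when the first renewal-density peak exceeds the asymptotic rate
  (shape ≳ 6), weakly regular trains (shapes ≤ 4) have their true
  autocorrelogram maximum at higher-order overlaps or, for exponential
  ISIs, a flat autocorrelogram with a noise-determined argmax; latency
  comparisons across regularity levels are only meaningful in the
  strongly refractory regime.
* Per-neuron LAT estimates at low rates (~1–3 Hz over 300 s) are noisy;
  population means over two seeds resolve the AHP-driven LAT shift only
  marginally. Pooled autocorrelograms show the shift cleanly.
* The HMM is exact EM on Bernoulli emissions; no sticky or hierarchical
  variants, no continuous-time correction for the 0.5-ms discretisation.
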