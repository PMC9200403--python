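# spikesig

Frontal-cortex neurons differ systematically in the *temporal signature* of
their spiking: the latency (LAT) of the peak of the spike autocorrelogram,
which reflects refractoriness and burstiness, and the time constant (TAU)
of its exponential decay, the neuron's intrinsic spiking timescale.
Midcingulate (MCC) units show longer LAT and TAU than lateral prefrontal
(LPFC) units, and these signatures relate to how populations organise into
metastable activity states. `spikesig` implements the full analysis chain
connecting these levels for computational neuroscientists:

* **Signature extraction** — spike autocorrelograms from lagged differences
  (3.33-ms bins, loess smoothing, mono-exponential fits
  `AC ~ A e^(−t/TAU) + B` with dip-aware fit selection), the spike-count
  timescale `scTAU` from cross-trial 50-ms bin correlations, first-order
  (ISI) latencies, engage/pause segmentation of session logs.
* **Biophysical models** — a Hodgkin–Huxley pyramidal cell under balanced
  stochastic synaptic bombardment, and a 605-neuron conductance-based LIF
  recurrent network with CAN/AHP intrinsic currents and
  AMPA/NMDA/GABA-A/GABA-B synapses, whose AHP and GABA-B conductances move
  the population signature between LPFC-like and MCC-like regimes
  (presets `LPFCm`, `MCCm` and single-conductance swaps).
* **Metastability** — Bernoulli-emission hidden Markov segmentation of
  population rasters at 0.5-ms bins (4 states, 0.8 posterior threshold,
  null-state S0 handling), state-duration statistics including the
  time-weighted distribution `p_t(d) ∝ p(d)·d`, state geometry/PCA, AIC/BIC
  scans and shuffle controls.
* **Perturbation** — substitution of the dynamical state of a chosen
  fraction of excitatory or inhibitory neurons mid-state, with escape/reach
  probabilities measured under frozen-HMM forward decoding.
* **Synthetic data** — seeded generators (OU-rate Poisson trains,
  gamma-renewal/burst trains, Markov rasters, session event logs) that
  carry their ground truth, so every stage is testable without recordings.
* **Statistics** — BLOM rank-normal scores, log-ratio modulation indices,
  stratified median splits with permutation nulls, and bivariate-KDE
  Frobenius similarity between model and reference signature distributions.

## Worked example

Recover a known timescale from a synthetic unit, then contrast the two
area presets:

```python
import numpy as np
from spikesig.synthetic import gen_ou_poisson
from spikesig.temporal_signature import extract_signature

taus = []
for rep in range(5):
    train, truth = gen_ou_poisson(mean_rate=5.0, tau=300.0, rate_sd=4.0,
                                  duration=600_000.0, seed=11 + rep)
    sig = extract_signature(train, seed=11 + rep)
    taus.append(sig.tau)
print(np.round(taus, 1), "median", round(float(np.median(taus)), 1))
```

```
[614.5 245.1 221.5 356.1 262.6] median 262.6
```

Individual fits scatter (the autocorrelogram of a 600-s, 5-Hz train is
noisy) but the median recovers the generating 300-ms timescale within the
pipeline's ~20% tolerance; across 50 replicates the median error drops
below 15% (see `tests/test_acceptance.py`).

```sh
python analysis/03_network_presets.py --seed 1 --duration 120000 \
    --presets LPFCm MCCm
```

```
LPFCm              Exc (pooled): LAT   58.3 ms  TAU    274 ms  rate  2.36 Hz
LPFCm              Inh (pooled): LAT   55.0 ms  TAU    348 ms  rate  4.03 Hz
MCCm               Exc (pooled): LAT   78.3 ms  TAU    358 ms  rate  1.61 Hz
MCCm               Inh (pooled): LAT   58.3 ms  TAU    343 ms  rate  2.78 Hz
```

The MCC-like preset (higher AHP and GABA-B conductances) shifts excitatory
neurons to a longer pooled-population latency and a slower timescale while
inhibitory latency barely moves — the key area contrast the models exist
to explain. (Inhibitory TAU separates too once records reach ~300 s; the
per-unit signature table is written alongside.)

The numbered scripts under `analysis/` run the remaining stages (cellular
exploration, similarity maps, metastability, perturbation) and write their
tables under `results/`; each accepts `--seed` and size flags.

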