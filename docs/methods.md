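# Methods

`spikelink` infers signed, directed functional connectivity between spiking
channels (micro-electrode array electrodes or simulated neurons) from
cross-correlation histograms, and validates the estimator on simulated
networks whose wiring is known exactly. This note records the model, the
numerical choices, and what the bundled synthetic benchmarks do and do not
demonstrate.

## The estimator

For a reference train *x* and target train *y* the normalized
cross-correlation histogram (NCCH) is

C_xy(τ) = (1 / √(N_x·N_y)) · #{(s, t) : t_y(t) − t_x(s) falls in lag bin τ},

computed over an odd number of bins of width Δ covering lags
[−W/2, +W/2]. With this normalization C lies in [0, 1] whenever each train
carries at most one spike per lag bin (Cauchy–Schwarz; neuronal
refractoriness guarantees this at the ≤1 ms bins used here, and the
autocorrelogram of any such train has C(0) = 1) and obeys
C_xy(τ) = C_yx(−τ), so only one correlogram per unordered pair is needed.
The histogram is built by a direct sweep over the spike time stamps: each
stamp is first quantized to a lag-bin index on the sampling grid, then a
forward-moving pointer collects, for every reference spike, the target
spikes inside the window. The cost scales with the number of spike pairs
inside windows, not with the recording duration divided by Δ, and the
result is bit-identical to a brute-force binned shifted-product computation
(this equivalence is an acceptance test).

The filtered histogram (FNCCH) subtracts the within-window mean
(the average over the lag bins — the only reading under which a flat
correlogram maps to zero everywhere) and takes the bin with the largest
absolute filtered value. The signed value at that bin — the *entity* of the
peak — classifies the link: positive = excitatory (a peak), negative =
inhibitory (a trough). The peak's lag gives the putative conduction delay,
and its sign the direction: a peak at positive lag (target fires after
reference) is a reference→target link. Mean subtraction is what makes
troughs competitive with peaks; the unfiltered maximum can never select a
trough, which is why the plain NCCH misses inhibition entirely and is kept
only as the comparison estimator.

Tie-breaks in the argmax go to the smaller |lag| and then to the positive
lag, favouring causal, short-latency links; ties are exact floating-point
equalities and occur mainly on tiny fixtures.

### Window span

The correlation window of the three named presets (simulation: 25 ms / 1 ms
bins; MEA-60: 25 ms / 0.1 ms; MEA-4k: 24 ms / 0.12 ms) is interpreted as a
*half*-window: lags cover ± the quoted span (the model's `window` parameter
is the full span, default 50 ms). The deciding observation is physical:
excitatory conduction delays in the validation networks run up to 20 ms,
and the delay distributions recovered from thresholded matrices span that
range. A ±12.5 ms lag axis cannot contain 40% of the true excitatory
links, which caps the attainable excitatory ROC AUC near 0.8 regardless of
estimator quality; with lags to ±25 ms every structural delay is inside
the window.

### Boundary re-search

Window-edge bins of jagged correlograms occasionally carry the largest
absolute filtered value with negative sign, creating false inhibitory
links. When an inhibitory peak lies in the outer quarter of either
half-window (`tail_fraction` = 0.25, configurable), the peak search is
re-run restricted to the central half of the window and the restricted
result replaces the original (it may be excitatory). Excitatory and
central inhibitory peaks are never touched.

### Skipped pairs

Pairs in which both trains carry fewer than 10 spikes are skipped
(entity 0): with so few events the correlogram is variance-dominated and
any peak is noise. The threshold is configurable.

## Pruning

Two independent refinements produce the thresholded connectivity matrix:

* **Spatio-temporal filter** — a link of electrode distance L (µm) and peak
  delay D (ms) implies a propagation velocity L/D µm/ms = L/D mm/s. Links
  faster than 400 mm/s, or with D below the ~1 ms synaptic minimum
  (including zero-lag co-activations), are non-physiological and removed.
* **Hard threshold** — within each sign class, survivors must exceed
  μ + n·σ strictly, with μ, σ computed over the nonzero entries of that
  class (|values| for the inhibitory class); defaults n = 2 (excitatory)
  and n = 1 (inhibitory). Computing the statistics per sign class over
  detected entries (rather than over the full matrix including structural
  zeros) keeps the thresholds independent of matrix density; an
  `all_entries` mode is available. With σ = 0 the strict inequality keeps
  nothing — the conservative choice for degenerate inputs.

The spatio-temporal filter runs before thresholding so that
non-physiological links do not inflate μ and σ; the order is a parameter
and is recorded in the output provenance. Both operations are idempotent
(re-thresholding a thresholded matrix with the same multipliers reuses the
stored cutoffs).

## The simulated validation substrate

The ground-truth generator builds networks of two-variable quadratic
integrate-and-reset (Izhikevich) neurons: regular-spiking excitatory
(a = 0.02, b = 0.2, c = −65, d = 8) and fast-spiking inhibitory
(a = 0.1, b = 0.2, c = −65, d = 2) populations in a 4:1 ratio.

Random wiring rule: every neuron receives exactly `in_degree` (default 100)
afferents drawn uniformly without replacement — excitatory neurons 80%
excitatory / 20% inhibitory, inhibitory neurons 100% excitatory — with no
autapses. Weights are drawn from N(6, 1) (excitatory) and N(−5, 1)
(inhibitory); delays are 1 ms on inhibitory links and uniform integers in
[1, 20] ms on excitatory links (the 1 ms lower bound respects the synaptic
minimum). A scale-free variant wires the same populations by directed
preferential attachment (heavy-tailed in-degree; log-log fit R² ≥ 0.9 at
n = 1000 is a generator self-test).

Dynamics are integrated on a 1 ms event grid with two 0.5 ms membrane
substeps (the model family's reference scheme): v' = 0.04v² + 5v + 140 − u
+ I, u' = a(bv − u), reset v→c, u→u+d at v = 30 mV. A presynaptic spike
adds its weight to the postsynaptic input current after the link delay
(impulse synapse). Excitatory weights evolve by pair-based STDP with both
time constants 20 ms and amplitudes A+ = 0.1 / A− = 0.12; updates
accumulate in a per-synapse derivative that is applied once per simulated
second together with a +0.01 drift, then damped by 0.9, and weights are
clipped to [0, 10]. This once-per-second application with drift is the
reference plasticity scheme of the cited neuron-model family; applying the
pair updates instantaneously instead lets depression (A− > A+) drain all
weights to zero under weakly correlated activity and decouples the
network. Inhibitory weights are fixed.

Spontaneous activity is driven by stimulating one uniformly chosen neuron
per 1 ms step with a current pulse drawn from N(11, 2²) (excitatory
targets) or N(7, 2²) (inhibitory targets). The pulse amplitude alone,
applied for a single millisecond, cannot lift a resting neuron over
threshold (the membrane relaxes back within a few ms), so a pulse duration
parameter sets how long the drawn current persists; the default of 2 ms is
the shortest duration at which the 1000-neuron network self-ignites and
sustains the target regime — excitatory rates of a few spikes/s,
inhibitory rates an order of magnitude higher, and synchronized
network-wide rate peaks (bursts) superimposed on asynchronous firing.
Longer pulses push the network into tonic asynchronous firing and destroy
the bursty regime.

At these defaults a 30-minute, 1000-neuron simulation produces ~4 spikes/s
(excitatory) and ~16 spikes/s (inhibitory), takes well under a minute of
wall time (numba-compiled kernel), and the full inference + scoring
pipeline on its 499 500 channel pairs runs in a few minutes on one CPU.

### Scale considerations

Detection quality is a property of the network's dynamical regime, and the
regime does not survive naive down-scaling: recurrent drive is proportional
to the in-degree, so a network with in-degree 25 and unchanged weights sits
far below the avalanche threshold, never bursts, and inhibitory links
become nearly undetectable (inhibition needs a strong firing background to
leave a visible trough). Rescaling weights by the in-degree ratio
overshoots instead — a single 24-unit kick fires a resting neuron outright
and the network runs away. The validation benchmarks therefore run at the
generator's native scale (n = 1000, in-degree 100) with the recording
shortened to 30 minutes, which the recording-time analysis shows is the
shortest duration at which inhibition detectability is preserved.

## Scoring

Truth is binarized from the post-plasticity synaptic weight matrix (any
nonzero entry of the matching sign is a link; plasticity moves weights, not
topology, though weights driven exactly to zero drop out of the truth set).
Confusion counts are taken over all n² − n ordered pairs; a predicted link
is a true positive only if the ordered pair and the polarity both match, so
a wrong-polarity detection is a false positive for its own class and
leaves the true link undetected. ROC curves sweep the detection threshold
over the |entity| scores of one sign class (pairs without a score of that
sign rank at zero), AUC is trapezoidal with tied blocks traversed
diagonally, and the MCC curve evaluates the Matthews correlation
coefficient at the same thresholds with the 0/0 → 0 convention. The
threshold sweep is implemented in-house (the MCC curve needs per-threshold
confusion counts anyway) and is cross-checked against an independent
library implementation in the tests.

Degree-distribution fits: Gaussian by maximum likelihood with R² measured
between the Freedman–Diaconis density histogram and the fitted density;
power laws by linear regression of log-density on log-degree over
logarithmically spaced bins (linear bins systematically under-weight the
tail). Box-plot summaries report median, 25–75th percentiles (linear
interpolation), 5th/95th percentiles and the mean.

## Graph topology

Directed thresholded matrices are projected to simple undirected graphs per
sign class before any topology metric. Clustering is the standard
neighbourhood coefficient (nodes with < 2 neighbours contribute 0); the
characteristic path length averages shortest-path distances over connected
unordered pairs, excluding disconnected pairs from numerator and
denominator and reporting their fraction. The small-world index
(C_net/C_rnd)/(L_net/L_rnd) and the rich-club normalization use ensembles
of 100 random equivalents; the default null model preserves each node's
degree by double-edge-swap rewiring, with a density-matched G(n, m)
fallback for graphs too small or too dense to rewire (a warning is
emitted). The rich-club coefficient RCC(k) is the edge density among nodes
of degree > k; levels with fewer than two such nodes are undefined and
dropped, and the normalized curve's maximum above 1 flags a privileged
sub-network, reported with its node set.

The electrode-decimation study subsamples a grid layout at the largest
uniform stride that still yields the requested channel count (trimming in
row-major order), reruns the full inference + pruning + topology pipeline
on the subset, and tabulates the small-world index of the excitatory class
against electrode count.

## Synthetic data: what it shows and what it does not

The simulator reproduces the features the estimator is sensitive to —
recurrent excitation and inhibition with known wiring, conduction delays,
bursty population dynamics, realistic firing-rate ranges — and gives exact
ground truth. It does not model extracellular recording realism: no spike
detection errors or missed spikes, no electrode noise, no multi-unit mixing
at an electrode, no spatial correlation of neighbouring channels, and the
impulse synapse ignores conductance dynamics. Passing benchmarks therefore
demonstrates estimator correctness under the generative assumptions, not
performance on raw MEA recordings; the hooks for real data (HDF5/CSV
ingestion, layout presets, the MEA parameter presets) are exercised only by
round-trip tests.

## Degenerate inputs and conventions

* Empty trains or all-zero correlograms yield a flagged null result, not a
  link; flat correlograms (mean subtraction annihilates constants) likewise.
* Duplicate same-channel time stamps are collapsed with a logged warning
  (physiological refractoriness makes true duplicates impossible).
* Spike times are stored as integer sample indices; all binning is integer
  arithmetic after one deterministic quantization.
* Zero-lag peaks are retained in the FCM but flagged; the minimum-delay
  rule of the spatio-temporal filter removes them.
* Simulation determinism: a run is fully determined by the structural seed
  and the simulation seed; the spike buffer is sized for 50 spikes/s per
  neuron and overflow aborts with an error naming the step, as does a
  non-finite membrane potential.

## Known limitations

* The plain-NCCH comparison inherits the estimator's direction convention
  (peak-lag sign), which is generous to the raw peak on burst-dominated
  pairs; its benchmark AUC runs slightly above the historical value.
* Polysynaptic and common-input motifs produce genuine false positives at
  short lags (inflated functional in-degrees); no leniency is applied when
  scoring them.
* The STDP amplitudes and clipping ceiling follow the cited model family's
  canonical values; they are exposed in `SimulationConfig` but the
  benchmarks have only been run at the defaults.
* Inhibitory-inhibitory links do not exist in the generator (by the wiring
  rule), so inhibitory detection is only ever tested on inhibitory→
  excitatory links.
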