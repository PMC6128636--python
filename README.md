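# spikelink

Excitatory **and inhibitory** functional connectivity from multi-electrode
spike trains, via filtered normalized cross-correlation histograms.

Cross-correlogram methods detect excitatory links as peaks, but inhibition
leaves only a shallow trough that the raw correlogram maximum can never
select — so standard correlogram pipelines silently report purely
excitatory networks. `spikelink` implements the filtered estimator that
fixes this: for a reference train *x* and target train *y* it computes the
normalized cross-correlation histogram

&nbsp;&nbsp;&nbsp;&nbsp;C\_xy(τ) = (1/√(N\_x·N\_y)) Σ\_s x(t\_s)·y(t\_s − τ),  τ ∈ [−W/2, W/2],

subtracts the within-window mean, and takes the lag with the largest
*absolute* filtered value. The signed value at that lag (the "entity" of
the peak) classifies the link — positive → excitatory, negative →
inhibitory — while its lag gives the conduction delay and direction.
Physiological pruning (a 400 mm/s maximum-propagation-velocity filter and
sign-specific μ + n·σ hard thresholds) turns the full matrix into a
thresholded connectivity graph, which the topology suite characterizes
(small-world index against degree-preserving surrogates, rich-club
curves, degree/delay/length distributions).

The package also contains the validation substrate: an Izhikevich
spiking-network simulator (regular-spiking/fast-spiking populations 4:1,
in-degree 100 random or scale-free wiring, N(6,1)/N(−5,1) weights,
1–20 ms delays, STDP on excitatory synapses, stochastic single-neuron
stimulation) whose synaptic weight matrix is exact ground truth for
ROC/AUC and Matthews-correlation scoring of the inferred links.

Audience: electrophysiologists analysing micro-electrode array (MEA)
recordings of cultured or ex-vivo networks, and methodologists
benchmarking connectivity estimators against networks with known wiring.

## Worked example

```python
import spikelink as sl

# ground-truth network + 10 minutes of activity
net = sl.build_random_network(1000, seed=1)          # 800 exc / 200 inh
cfg = sl.SimulationConfig(duration_s=600.0, seed=1)
spikes, swm_final = sl.simulate_network(net, cfg)

# fit the connectivity model (lag span ±25 ms, 1 ms bins)
model = sl.NcchConnectivity(spikes, window=0.050, binwidth=0.001)
res = model.fit()
print(res.summary())

# score against the known wiring
print("inhibitory AUC:",
      round(sl.roc_auc(res.fcm, swm_final, "inhibitory").auc, 3))
tcm = res.hard_threshold()
print(tcm.summary())
```

Output:

```
FCM: 1000 channels, W=50 ms, bin=1 ms
  excitatory links: 430191
  inhibitory links: 69309
  inhibitory fraction: 13.9%
  median |peak lag|: 7.00 ms
inhibitory AUC: 0.835
TCM (thresholded): 1000 channels, W=50 ms, bin=1 ms
  excitatory links: 21968
  inhibitory links: 10416
  inhibitory fraction: 32.2%
  median |peak lag|: 7.00 ms
```

The raw functional connectivity matrix (FCM) has one signed entry per
detected pair — nearly every pair gets some peak, so the matrix is dense
and only the ranking matters at this stage. Its inhibitory ROC AUC of 0.84
after only 10 simulated minutes says the negative filtered peaks rank true
inhibitory links far above chance (1.0 = perfect, 0.5 = random; the
30-minute benchmark scores 0.92). The hard threshold (μ+2σ excitatory,
μ+1σ inhibitory) then keeps the ~32 000 strongest links for graph
analysis.

A command-line workflow mirrors the library:

```bash
spikelink simulate --n 1000 --hours 0.5 --seed 7 --out sim.h5
spikelink infer    --spikes sim.h5 --w 50 --bin 1.0 --out fcm.h5
spikelink prune    --fcm fcm.h5 --out tcm.h5
spikelink evaluate --fcm fcm.h5 --truth sim.h5 --out eval.json
spikelink topology --tcm tcm.h5 --sign excitatory --out topo.json
```

Every subcommand writes a `.provenance.json` (parameters, seeds, package
version) sufficient to re-execute it; reruns are byte-identical.

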