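"""Ground-truth spiking networks: wiring generators and Izhikevich dynamics.

The in-silico validation substrate is a recurrent network of Izhikevich
neurons (regular-spiking excitatory, fast-spiking inhibitory, 4:1 ratio)
with random or scale-free wiring, delayed impulse synapses, additive STDP on
the excitatory weights, and spontaneous activity driven by stimulating one
uniformly chosen neuron per millisecond with a noisy current pulse. The
synaptic weight matrix (SWM) of the generator is the ground truth against
which inferred functional connectivity is scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from numba import njit

from .data import SpikeTrainSet

__all__ = [
    "NeuronParameters",
    "StructuralNetwork",
    "SimulationConfig",
    "build_random_network",
    "build_scale_free_network",
    "simulate_network",
    "SimulationError",
]

IN_DEGREE_DEFAULT = 100
EXC_WEIGHT_MEAN, EXC_WEIGHT_SD = 6.0, 1.0
INH_WEIGHT_MEAN, INH_WEIGHT_SD = -5.0, 1.0
INH_DELAY_MS = 1
EXC_DELAY_RANGE_MS = (1, 20)


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class NeuronParameters:
    """Two-variable quadratic integrate-and-reset (Izhikevich) parameters."""

    kind: str
    a: float
    b: float
    c: float
    d: float

    @classmethod
    def regular_spiking(cls):
        """Canonical RS preset used for the excitatory population."""
        return cls("excitatory_RS", 0.02, 0.2, -65.0, 8.0)

    @classmethod
    def fast_spiking(cls):
        """Canonical FS preset used for the inhibitory population."""
        return cls("inhibitory_FS", 0.1, 0.2, -65.0, 2.0)


@dataclass
class StructuralNetwork:
    """Directed weighted ground-truth wiring.

    ``swm[i, j]`` is the synaptic weight of link i -> j (positive =
    excitatory source, negative = inhibitory); ``delays_ms[i, j]`` the
    conduction delay in integer milliseconds.
    """

    n_neurons: int
    is_excitatory: np.ndarray       # bool per neuron
    swm: np.ndarray                 # (n, n) float
    delays_ms: np.ndarray           # (n, n) int
    seed: int | None = None
    wiring: str = "random"

    def __post_init__(self):
        if np.any(np.diag(self.swm)):
            raise ValueError("autapses are not allowed")

    @property
    def n_excitatory(self) -> int:
        return int(self.is_excitatory.sum())

    @property
    def n_inhibitory(self) -> int:
        return int((~self.is_excitatory).sum())

    def in_degrees(self) -> np.ndarray:
        return np.count_nonzero(self.swm, axis=0)

    def channel_ids(self) -> list[str]:
        return [f"n{i:04d}" for i in range(self.n_neurons)]

    def simulate(self, config: "SimulationConfig"):
        return simulate_network(self, config)


@dataclass
class SimulationConfig:
    """Simulation run parameters (times in the stated units)."""

    duration_s: float = 3600.0
    stim_exc_mean: float = 11.0     # current pulse to a stimulated RS neuron
    stim_exc_sd: float = 2.0
    stim_inh_mean: float = 7.0      # current pulse to a stimulated FS neuron
    stim_inh_sd: float = 2.0
    stim_pulse_ms: int = 2          # duration each stimulation pulse persists
    bias_current: float = 0.0       # constant current to every neuron (testing)
    stdp_enabled: bool = True
    stdp_tau_ms: float = 20.0
    stdp_a_plus: float = 0.1
    stdp_a_minus: float = 0.12
    stdp_drift: float = 0.01        # per-second additive drift on plastic weights
    stdp_damping: float = 0.9       # per-second decay of the accumulated derivative
    w_max: float = 10.0             # ceiling for plastic excitatory weights
    sampling_rate: float = 10_000.0  # nominal rate stamped on the output
    seed: int | None = None

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.stdp_tau_ms <= 0 or self.w_max <= 0:
            raise ValueError("stdp_tau_ms and w_max must be positive")

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        """Load a config from a YAML (or JSON) mapping of field names."""
        import dataclasses

        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)


def _assign_types(n: int) -> np.ndarray:
    """First 4n/5 neurons excitatory, last n/5 inhibitory (4:1 ratio)."""
    if n % 5:
        raise ValueError("n must be divisible by 5 for the 4:1 ratio")
    is_exc = np.zeros(n, dtype=bool)
    is_exc[: 4 * n // 5] = True
    return is_exc


def build_random_network(n: int = 1000, seed: int | None = None,
                         in_degree: int = IN_DEGREE_DEFAULT) -> StructuralNetwork:
    """Random wiring: every neuron receives exactly `in_degree` afferents.

    Excitatory neurons draw 80% excitatory / 20% inhibitory afferents
    (mirroring the population ratio); inhibitory neurons draw only
    excitatory afferents. Sources are sampled uniformly without replacement,
    autapses excluded. Weights: N(6, 1) excitatory, N(-5, 1) inhibitory.
    Delays: 1 ms on inhibitory links, uniform integers on [1, 20] ms on
    excitatory links.
    """
    is_exc = _assign_types(n)
    n_exc = int(is_exc.sum())
    n_inh = n - n_exc
    k_exc_aff = int(round(0.8 * in_degree))
    k_inh_aff = in_degree - k_exc_aff
    if n_exc - 1 < in_degree or n_inh < k_inh_aff or n_exc < in_degree:
        raise ValueError(
            f"in-degree {in_degree} infeasible for n={n} at the 4:1 ratio")
    rng = np.random.default_rng(seed)
    exc_ids = np.flatnonzero(is_exc)
    inh_ids = np.flatnonzero(~is_exc)
    swm = np.zeros((n, n))
    delays = np.zeros((n, n), dtype=np.int64)
    lo, hi = EXC_DELAY_RANGE_MS
    for j in range(n):
        if is_exc[j]:
            pool = exc_ids[exc_ids != j]
            src_exc = rng.choice(pool, size=k_exc_aff, replace=False)
            src_inh = rng.choice(inh_ids, size=k_inh_aff, replace=False)
        else:
            src_exc = rng.choice(exc_ids, size=in_degree, replace=False)
            src_inh = np.empty(0, dtype=int)
        swm[src_exc, j] = rng.normal(EXC_WEIGHT_MEAN, EXC_WEIGHT_SD,
                                     size=src_exc.size)
        delays[src_exc, j] = rng.integers(lo, hi + 1, size=src_exc.size)
        if src_inh.size:
            swm[src_inh, j] = rng.normal(INH_WEIGHT_MEAN, INH_WEIGHT_SD,
                                         size=src_inh.size)
            delays[src_inh, j] = INH_DELAY_MS
    return StructuralNetwork(n, is_exc, swm, delays, seed=seed, wiring="random")


def build_scale_free_network(n: int, seed: int | None = None,
                             alpha: float = 0.41, beta: float = 0.54,
                             gamma: float = 0.05) -> StructuralNetwork:
    """Scale-free wiring via directed preferential attachment.

    The heavy-tailed topology comes from a Bollobas-style growth process;
    neuron types, weight distributions and delay conventions follow the
    random rule (4:1 ratio, no autapses, inhibitory afferents only onto
    excitatory neurons).
    """
    if n < 50:
        raise ValueError("scale-free generator needs n >= 50")
    if not np.isclose(alpha + beta + gamma, 1.0) or min(alpha, beta, gamma) < 0:
        raise ValueError("attachment probabilities must be >= 0 and sum to 1")
    is_exc = _assign_types(n)
    rng = np.random.default_rng(seed)
    g = nx.scale_free_graph(n, alpha=alpha, beta=beta, gamma=gamma,
                            seed=int(rng.integers(2**31)))
    # relabel so hub indices are spread over both populations
    perm = rng.permutation(n)
    swm = np.zeros((n, n))
    delays = np.zeros((n, n), dtype=np.int64)
    lo, hi = EXC_DELAY_RANGE_MS
    for u, v in set(g.edges()):
        i, j = int(perm[u]), int(perm[v])
        if i == j or swm[i, j]:
            continue
        if not is_exc[i] and not is_exc[j]:
            continue  # inhibitory neurons receive only excitatory afferents
        if is_exc[i]:
            swm[i, j] = rng.normal(EXC_WEIGHT_MEAN, EXC_WEIGHT_SD)
            delays[i, j] = rng.integers(lo, hi + 1)
        else:
            swm[i, j] = rng.normal(INH_WEIGHT_MEAN, INH_WEIGHT_SD)
            delays[i, j] = INH_DELAY_MS
    return StructuralNetwork(n, is_exc, swm, delays, seed=seed,
                             wiring="scale_free")


@njit(cache=True)
def _run_dynamics(n_steps, a, b, c, d, is_exc, bias,
                  syn_pre, syn_post, syn_delay, w, syn_plastic,
                  out_indptr, out_syn, in_indptr, in_syn,
                  stim_exc_mean, stim_exc_sd, stim_inh_mean, stim_inh_sd,
                  stim_pulse_ms, stim_on, stdp_on, trace_decay,
                  a_plus, a_minus, drift, damping, w_max,
                  max_delay, seed, spike_t, spike_id):
    """1 ms event loop with two 0.5 ms membrane substeps per neuron.

    Synapses are flat arrays indexed by `out_syn` (grouped by presynaptic
    neuron) and `in_syn` (grouped by postsynaptic neuron); `w` is updated in
    place by STDP. Returns the number of recorded spikes, or -(step+1) on
    numerical blow-up / spike-buffer overflow at that step.
    """
    np.random.seed(seed)
    n = a.shape[0]
    v = np.full(n, -65.0)
    u = b * v
    ibuf = np.zeros((max_delay + 1, n))
    trace = np.zeros(n)
    wderiv = np.zeros(w.shape[0])
    fired = np.empty(n, dtype=np.int64)
    pulse_val = np.zeros(n)
    pulse_left = np.zeros(n, dtype=np.int64)
    cap = spike_t.shape[0]
    count = 0
    for t in range(n_steps):
        slot = t % (max_delay + 1)
        current = ibuf[slot] + bias
        ibuf[slot, :] = 0.0
        if stim_on:
            s = np.random.randint(0, n)
            if is_exc[s]:
                pulse_val[s] = stim_exc_mean + stim_exc_sd * np.random.randn()
            else:
                pulse_val[s] = stim_inh_mean + stim_inh_sd * np.random.randn()
            pulse_left[s] = stim_pulse_ms
            for i in range(n):
                if pulse_left[i] > 0:
                    current[i] += pulse_val[i]
                    pulse_left[i] -= 1
        n_fired = 0
        for i in range(n):
            vi = v[i]
            vi += 0.5 * (0.04 * vi * vi + 5.0 * vi + 140.0 - u[i] + current[i])
            vi += 0.5 * (0.04 * vi * vi + 5.0 * vi + 140.0 - u[i] + current[i])
            u[i] += a[i] * (b[i] * vi - u[i])
            if not np.isfinite(vi):
                return -(t + 1)
            if vi >= 30.0:
                fired[n_fired] = i
                n_fired += 1
                v[i] = c[i]
                u[i] += d[i]
            else:
                v[i] = vi
        if stdp_on:
            trace *= trace_decay
        for fi in range(n_fired):
            i = fired[fi]
            if count >= cap:
                return -(t + 1)
            spike_t[count] = t
            spike_id[count] = i
            count += 1
            # synaptic delivery after the link delay
            for k in range(out_indptr[i], out_indptr[i + 1]):
                si = out_syn[k]
                dslot = (t + syn_delay[si]) % (max_delay + 1)
                ibuf[dslot, syn_post[si]] += w[si]
            if stdp_on:
                # post spike: potentiate plastic afferents by the pre trace;
                # pre spike: depress plastic efferents by the post trace.
                # Updates accumulate in a derivative applied once per second.
                for k in range(in_indptr[i], in_indptr[i + 1]):
                    si = in_syn[k]
                    if syn_plastic[si]:
                        wderiv[si] += a_plus * trace[syn_pre[si]]
                for k in range(out_indptr[i], out_indptr[i + 1]):
                    si = out_syn[k]
                    if syn_plastic[si]:
                        wderiv[si] -= a_minus * trace[syn_post[si]]
        if stdp_on:
            for fi in range(n_fired):
                trace[fired[fi]] += 1.0
            if (t + 1) % 1000 == 0:
                for si in range(w.shape[0]):
                    if syn_plastic[si]:
                        nw = w[si] + drift + wderiv[si]
                        w[si] = min(max(nw, 0.0), w_max)
                        wderiv[si] *= damping
    return count


def _flatten_synapses(net: StructuralNetwork):
    pre, post = np.nonzero(net.swm)
    order = np.lexsort((post, pre))
    pre, post = pre[order], post[order]
    weights = net.swm[pre, post].copy()
    delays = net.delays_ms[pre, post].astype(np.int64)
    plastic = weights > 0  # STDP acts on excitatory weights only
    n = net.n_neurons
    out_indptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(out_indptr, pre + 1, 1)
    out_indptr = np.cumsum(out_indptr)
    out_syn = np.arange(pre.size, dtype=np.int64)  # already grouped by pre
    in_order = np.argsort(post, kind="stable")
    in_syn = in_order.astype(np.int64)
    in_indptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(in_indptr, post + 1, 1)
    in_indptr = np.cumsum(in_indptr)
    return (pre.astype(np.int64), post.astype(np.int64), delays, weights,
            plastic, out_indptr, out_syn, in_indptr, in_syn)


def simulate_network(net: StructuralNetwork, config: SimulationConfig,
                     spike_buffer_rate: float = 50.0):
    """Simulate the network's spontaneous activity.

    Returns ``(spike_set, swm_final)``: one spike train per neuron (times on
    a nominal 10 kHz grid at 1 ms resolution) and the synaptic weight matrix
    after STDP (inhibitory weights are untouched by construction).
    """
    n_steps = int(round(config.duration_s * 1000.0))
    (pre, post, delays, w, plastic,
     out_indptr, out_syn, in_indptr, in_syn) = _flatten_synapses(net)
    rs = NeuronParameters.regular_spiking()
    fs = NeuronParameters.fast_spiking()
    is_exc = net.is_excitatory.astype(np.bool_)
    a = np.where(is_exc, rs.a, fs.a).astype(np.float64)
    b = np.where(is_exc, rs.b, fs.b).astype(np.float64)
    c = np.where(is_exc, rs.c, fs.c).astype(np.float64)
    d = np.where(is_exc, rs.d, fs.d).astype(np.float64)
    max_delay = int(delays.max()) if delays.size else 1
    cap = max(int(net.n_neurons * config.duration_s * spike_buffer_rate), 1000)
    spike_t = np.empty(cap, dtype=np.int64)
    spike_id = np.empty(cap, dtype=np.int64)
    stim_on = (config.stim_exc_mean != 0 or config.stim_exc_sd != 0
               or config.stim_inh_mean != 0 or config.stim_inh_sd != 0)
    seed = config.seed if config.seed is not None else 0
    trace_decay = float(np.exp(-1.0 / config.stdp_tau_ms))
    bias = np.broadcast_to(np.asarray(config.bias_current, dtype=np.float64),
                           net.n_neurons).copy()
    count = _run_dynamics(
        n_steps, a, b, c, d, is_exc, bias,
        pre, post, delays, w, plastic,
        out_indptr, out_syn, in_indptr, in_syn,
        config.stim_exc_mean, config.stim_exc_sd,
        config.stim_inh_mean, config.stim_inh_sd,
        int(config.stim_pulse_ms), stim_on, config.stdp_enabled, trace_decay,
        config.stdp_a_plus, config.stdp_a_minus, config.stdp_drift,
        config.stdp_damping, config.w_max,
        max_delay, seed, spike_t, spike_id,
    )
    if count < 0:
        raise SimulationError(
            f"simulation failed at step {-count - 1} "
            "(non-finite membrane potential or spike buffer overflow)")
    spike_t = spike_t[:count]
    spike_id = spike_id[:count]
    samples_per_ms = config.sampling_rate / 1000.0
    ids = net.channel_ids()
    spikes = {ids[i]: np.round(spike_t[spike_id == i] * samples_per_ms
                               ).astype(np.int64)
              for i in range(net.n_neurons)}
    spike_set = SpikeTrainSet(spikes, config.sampling_rate, config.duration_s,
                              from_indices=True)
    swm_final = np.zeros_like(net.swm)
    swm_final[pre, post] = w
    return spike_set, swm_final
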