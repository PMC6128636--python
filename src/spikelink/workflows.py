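"""End-to-end in-silico validation pipeline.

Generates ground-truth random networks, simulates their spontaneous
activity, infers connectivity with both the filtered (FNCCH) and plain
(NCCH) correlogram-peak estimators, and scores each against the synaptic
weight matrix. This is the workflow behind the `reproduce-insilico`
subcommand and the reproduction script.
"""

from __future__ import annotations

import logging

import numpy as np

from .connectivity import NcchConnectivity
from .simulation import SimulationConfig, build_random_network, simulate_network
from .validation import mcc_curve, roc_auc

logger = logging.getLogger(__name__)

__all__ = ["insilico_validation", "score_network"]


def score_network(fcm: np.ndarray, raw_ncch: np.ndarray,
                  truth_swm: np.ndarray) -> dict:
    """ROC AUC and max MCC per sign class, plus the plain-NCCH comparison."""
    out = {
        "inhibitory_auc": roc_auc(fcm, truth_swm, "inhibitory").auc,
        "inhibitory_max_mcc": mcc_curve(fcm, truth_swm, "inhibitory").max_mcc,
        "excitatory_auc": roc_auc(fcm, truth_swm, "excitatory").auc,
        "excitatory_max_mcc": mcc_curve(fcm, truth_swm, "excitatory").max_mcc,
    }
    if raw_ncch is not None:
        out["excitatory_auc_plain_ncch"] = roc_auc(
            raw_ncch, truth_swm, "excitatory").auc
    return out


def insilico_validation(n_neurons: int = 1000, in_degree: int = 100,
                        duration_s: float = 1800.0, seeds=(1, 2),
                        window: float = 0.050, binwidth: float = 0.001) -> dict:
    """Simulate seeded random networks and score the inferred connectivity.

    Returns per-network scores plus their across-network means. Truth links
    are taken from the post-plasticity weight matrix (plasticity changes
    weights, not topology, so the link set equals the initial wiring).
    """
    per_network = []
    for seed in seeds:
        logger.info("network seed %s: generating and simulating", seed)
        net = build_random_network(n_neurons, seed=seed, in_degree=in_degree)
        config = SimulationConfig(duration_s=duration_s, seed=seed)
        spike_set, swm_final = simulate_network(net, config)
        rates = spike_set.spike_counts().to_numpy() / duration_s
        logger.info("seed %s: mean rate exc %.2f / inh %.2f spikes/s", seed,
                    rates[net.is_excitatory].mean(),
                    rates[~net.is_excitatory].mean())
        res = NcchConnectivity(spike_set, window=window,
                               binwidth=binwidth).fit(progress=True)
        scores = score_network(res.fcm, res.raw_ncch, swm_final)
        scores["seed"] = seed
        scores["mean_rate_exc"] = float(rates[net.is_excitatory].mean())
        scores["mean_rate_inh"] = float(rates[~net.is_excitatory].mean())
        per_network.append(scores)
    keys = [k for k in per_network[0] if k != "seed"]
    summary = {
        "networks": per_network,
        "mean": {k: float(np.mean([p[k] for p in per_network])) for k in keys},
        "parameters": dict(n_neurons=n_neurons, in_degree=in_degree,
                           duration_s=duration_s, window=window,
                           binwidth=binwidth, seeds=list(seeds)),
    }
    return summary
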