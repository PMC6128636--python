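"""Physiological pruning of a functional connectivity matrix.

Two independent, idempotent refinement steps turn the raw FCM into a
thresholded connectivity matrix (TCM):

* a spatio-temporal filter discarding links whose electrode distance and
  peak delay imply a propagation velocity above a physiological maximum
  (default 400 mm/s) or a delay below the synaptic minimum (~1 ms, which
  also prunes zero-lag co-activations);
* sign-specific hard thresholds mu + n*sigma computed over the nonzero
  entries of each sign class (default n=2 for excitatory, n=1 for
  inhibitory link strengths).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["PruningParams", "spatiotemporal_filter", "hard_threshold"]


@dataclass
class PruningParams:
    """Defaults follow the validated in-silico parameterization."""

    v_max_mm_s: float = 400.0   # maximum propagation velocity
    d_min_ms: float = 1.0       # minimum synaptic delay
    n_exc: float = 2.0          # threshold multiplier, excitatory strengths
    n_inh: float = 1.0          # threshold multiplier, |inhibitory| strengths
    stats_over: str = "sign_nonzero"  # or "all_entries" (includes zeros)

    def __post_init__(self):
        if self.v_max_mm_s <= 0:
            raise ValueError("v_max_mm_s must be positive")
        if self.d_min_ms < 0 or self.n_exc < 0 or self.n_inh < 0:
            raise ValueError("d_min_ms, n_exc, n_inh must be non-negative")


def spatiotemporal_filter(results, layout, params: PruningParams | None = None):
    """Drop links whose implied propagation velocity is non-physiological.

    A link i->j of Euclidean length L (um) and peak delay D (ms) travels at
    L/D um/ms = L/D mm/s; it is removed when D < d_min or L/D > v_max.
    """
    params = params or PruningParams()
    if layout is None:
        raise ValueError("spatio-temporal filter requires an electrode layout")
    for ch in results.channel_ids:
        if ch not in layout:
            raise ValueError(f"channel {ch!r} missing from layout")
    fcm = results.fcm.copy()
    delays = results.delays_ms.copy()
    src, dst = np.nonzero(fcm)
    removed = 0
    for i, j in zip(src, dst):
        d = delays[i, j]
        dist_um = layout.distance_um(results.channel_ids[i],
                                     results.channel_ids[j])
        # um/ms is numerically equal to mm/s
        if d < params.d_min_ms or (d > 0 and dist_um / d > params.v_max_mm_s):
            fcm[i, j] = 0.0
            delays[i, j] = 0.0
            removed += 1
    logger.info("spatio-temporal filter removed %d links", removed)
    return results._replace(fcm=fcm, delays_ms=delays, layout=layout)


def hard_threshold(results, params: PruningParams | None = None):
    """Keep only links stronger than mu + n*sigma within their sign class.

    mu and sigma are computed over the nonzero entries of the given sign
    (absolute values for the inhibitory class); survivors must exceed the
    threshold strictly, so a degenerate class (sigma = 0) keeps nothing.
    """
    params = params or PruningParams()
    fcm = results.fcm
    out = np.zeros_like(fcm)
    # survivors of a previous pass already exceed the stored thresholds, so
    # re-applying with the same multipliers reuses them (idempotence)
    stored = results.params.get("thresholds") if results.is_thresholded else None
    if stored is not None and (stored.get("n_exc"), stored.get("n_inh")) != \
            (params.n_exc, params.n_inh):
        stored = None
    new_thresholds = {"n_exc": params.n_exc, "n_inh": params.n_inh}
    for sign, n_mult in (("excitatory", params.n_exc),
                         ("inhibitory", params.n_inh)):
        if sign == "excitatory":
            vals = fcm[fcm > 0]
            mask = fcm > 0
            mag = fcm
        else:
            vals = -fcm[fcm < 0]
            mask = fcm < 0
            mag = -fcm
        if stored is not None:
            thr = stored[sign]
        elif params.stats_over == "all_entries":
            n = fcm.shape[0]
            flat = np.abs(fcm[~np.eye(n, dtype=bool)])
            thr = float(flat.mean()) + n_mult * float(flat.std())
        else:
            if vals.size == 0:
                warnings.warn(f"no {sign} entries to threshold")
                new_thresholds[sign] = float("inf")
                continue
            thr = float(vals.mean()) + n_mult * float(vals.std())
        new_thresholds[sign] = thr
        keep = mask & (mag > thr)
        out[keep] = fcm[keep]
        logger.info("%s threshold %.4g kept %d / %d links",
                    sign, thr, int(keep.sum()), int(mask.sum()))
    delays = np.where(out != 0, results.delays_ms, 0.0)
    new_params = dict(results.params)
    new_params["thresholds"] = new_thresholds
    return results._replace(fcm=out, delays_ms=delays, is_thresholded=True,
                            params=new_params)
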