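"""Scoring inferred connectivity against ground truth, and link summaries.

The prediction is a signed connectivity matrix (FCM or TCM); the observation
is the generator's synaptic weight matrix (SWM). Links are evaluated as
ordered node pairs (diagonal excluded). For a sign class, a predicted link
is a true positive only when both the ordered pair and the polarity match;
a wrong-polarity prediction on a true link counts as a false positive for
its own class and leaves the true link undetected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "ScoreCurve",
    "confusion",
    "class_scores",
    "roc_auc",
    "mcc_curve",
    "accuracy",
    "matthews",
    "degree_distributions",
    "delay_length_distributions",
    "inhibitory_fraction_vs_time",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if self.fp + self.tn else 0.0


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    return (c.tp + c.tn) / c.total if c.total else 0.0


def matthews(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when the denominator vanishes."""
    num = float(c.tp * c.tn - c.fp * c.fn)
    den = (float(c.tp + c.fp) * float(c.tp + c.fn)
           * float(c.tn + c.fp) * float(c.tn + c.fn))
    return num / np.sqrt(den) if den > 0 else 0.0


@dataclass
class ScoreCurve:
    """Threshold-sweep classifier curve (ROC or MCC-vs-FPR)."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray | None = None
    mcc: np.ndarray | None = None
    auc: float | None = None

    @property
    def max_mcc(self) -> float:
        return float(np.max(self.mcc)) if self.mcc is not None else float("nan")


def _offdiag_mask(n: int) -> np.ndarray:
    return ~np.eye(n, dtype=bool)


def _class_labels(mat: np.ndarray, sign_class: str) -> np.ndarray:
    if sign_class == "excitatory":
        return mat > 0
    if sign_class == "inhibitory":
        return mat < 0
    if sign_class == "all":
        return mat != 0
    raise ValueError(f"unknown sign class {sign_class!r}")


def confusion(pred: np.ndarray, truth: np.ndarray,
              sign_class: str = "all") -> ConfusionCounts:
    """Link-level confusion counts over all n^2 - n ordered pairs."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape or pred.ndim != 2:
        raise ValueError("prediction and truth must be same-shape square matrices")
    off = _offdiag_mask(pred.shape[0])
    p = _class_labels(pred, sign_class)[off]
    t = _class_labels(truth, sign_class)[off]
    if sign_class == "all":
        # a detected link only matches when the polarity agrees
        same_sign = (np.sign(pred) == np.sign(truth))[off]
        tp = int(np.sum(p & t & same_sign))
        fp = int(np.sum(p) - tp)
        fn = int(np.sum(t & ~(p & same_sign) & ~p))
        tn = int(off.sum() - tp - fp - fn)
    else:
        tp = int(np.sum(p & t))
        fp = int(np.sum(p & ~t))
        fn = int(np.sum(~p & t))
        tn = int(np.sum(~p & ~t))
    return ConfusionCounts(tp, tn, fp, fn)


def class_scores(score_matrix: np.ndarray, sign_class: str) -> np.ndarray:
    """|entity| for entries of the class sign, 0 elsewhere."""
    labels = _class_labels(score_matrix, sign_class)
    return np.where(labels, np.abs(score_matrix), 0.0)


def _sweep(score_matrix, truth, sign_class):
    n = score_matrix.shape[0]
    off = _offdiag_mask(n)
    scores = class_scores(score_matrix, sign_class)[off]
    positives = _class_labels(truth, sign_class)[off]
    n_pos = int(positives.sum())
    n_neg = scores.size - n_pos
    if n_pos == 0:
        raise ValueError("no ground-truth positives: TPR undefined")
    order = np.argsort(-scores, kind="stable")
    sorted_pos = positives[order]
    sorted_scores = scores[order]
    # cumulative TP/FP after including each ranked pair
    cum_tp = np.cumsum(sorted_pos)
    cum_fp = np.cumsum(~sorted_pos)
    # evaluate only at threshold boundaries (last index of each tied block)
    boundary = np.flatnonzero(np.diff(sorted_scores) != 0)
    idx = np.concatenate([boundary, [scores.size - 1]])
    thresholds = sorted_scores[idx]
    tps = cum_tp[idx]
    fps = cum_fp[idx]
    return thresholds, tps, fps, n_pos, n_neg


def roc_auc(score_matrix: np.ndarray, truth: np.ndarray,
            sign_class: str) -> ScoreCurve:
    """ROC curve and trapezoidal AUC for one sign class.

    Scores rank all ordered pairs; pairs carrying no score of the class sign
    rank at 0. The curve runs from (0, 0) to (1, 1).
    """
    thresholds, tps, fps, n_pos, n_neg = _sweep(score_matrix, truth, sign_class)
    tpr = np.concatenate([[0.0], tps / n_pos])
    fpr = np.concatenate([[0.0], fps / max(n_neg, 1)])
    if tpr[-1] != 1.0 or fpr[-1] != 1.0:
        tpr = np.concatenate([tpr, [1.0]])
        fpr = np.concatenate([fpr, [1.0]])
    auc = float(np.trapezoid(tpr, fpr))
    return ScoreCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def mcc_curve(score_matrix: np.ndarray, truth: np.ndarray,
              sign_class: str) -> ScoreCurve:
    """MCC versus FPR over the same threshold sweep as the ROC."""
    thresholds, tps, fps, n_pos, n_neg = _sweep(score_matrix, truth, sign_class)
    mccs = np.empty(thresholds.size)
    fprs = np.empty(thresholds.size)
    for i in range(thresholds.size):
        c = ConfusionCounts(int(tps[i]), int(n_neg - fps[i]),
                            int(fps[i]), int(n_pos - tps[i]))
        mccs[i] = matthews(c)
        fprs[i] = c.fpr
    return ScoreCurve(thresholds=thresholds, fpr=fprs, mcc=mccs)


@dataclass
class DistributionFit:
    degrees: np.ndarray
    hist_density: np.ndarray
    bin_centers: np.ndarray
    gaussian: dict | None = None   # mean, sd, r2, degenerate flag
    powerlaw: dict | None = None   # slope, intercept, r2


def _r2(observed, predicted) -> float:
    ss_res = float(np.sum((observed - predicted) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")


def degree_distributions(tcm: np.ndarray, sign_class: str = "all",
                         fit=("gaussian",), samples=None) -> DistributionFit:
    """In-degree histogram of a connectivity matrix with optional fits.

    Gaussian parameters come from the maximum-likelihood fit (sample mean
    and sd); the reported R^2 compares the Freedman-Diaconis density
    histogram with the fitted density. The power-law fit is a linear
    regression on the log-log binned histogram.
    """
    if samples is not None:
        degrees = np.asarray(samples, dtype=float)
    else:
        labels = _class_labels(np.asarray(tcm), sign_class)
        degrees = labels.sum(axis=0).astype(float)  # in-degree per node
    if np.unique(degrees).size < 3:
        raise ValueError("need at least 3 distinct degrees to fit")
    density, edges = np.histogram(degrees, bins="fd", density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    out = DistributionFit(degrees, density, centers)
    if "gaussian" in fit:
        mean, sd = stats.norm.fit(degrees)
        degenerate = sd < 1e-9
        pdf = stats.norm.pdf(centers, mean, sd) if not degenerate else \
            np.zeros_like(centers)
        out.gaussian = dict(mean=float(mean), sd=float(sd),
                            r2=_r2(density, pdf), degenerate=bool(degenerate))
    if "powerlaw" in fit:
        # heavy tails need logarithmic binning before the log-log regression
        pos_deg = degrees[degrees > 0]
        if pos_deg.size < 3:
            raise ValueError("too few positive degrees for a power-law fit")
        edges = np.logspace(np.log10(pos_deg.min()),
                            np.log10(pos_deg.max() + 1), 15)
        dens, edges = np.histogram(pos_deg, bins=edges, density=True)
        log_centers = np.sqrt(edges[:-1] * edges[1:])
        keep = dens > 0
        if keep.sum() < 3:
            raise ValueError("too few populated bins for a power-law fit")
        res = stats.linregress(np.log10(log_centers[keep]),
                               np.log10(dens[keep]))
        out.powerlaw = dict(slope=float(res.slope),
                            intercept=float(res.intercept),
                            r2=float(res.rvalue ** 2))
    return out


def _box_summary(values: np.ndarray) -> dict:
    """Median, quartiles (linear interpolation), 5th/95th percentiles, mean."""
    if values.size == 0:
        return {k: float("nan") for k in
                ("median", "q25", "q75", "p5", "p95", "mean", "n")} | {"n": 0}
    return dict(
        median=float(np.percentile(values, 50)),
        q25=float(np.percentile(values, 25)),
        q75=float(np.percentile(values, 75)),
        p5=float(np.percentile(values, 5)),
        p95=float(np.percentile(values, 95)),
        mean=float(values.mean()),
        n=int(values.size),
    )


def delay_length_distributions(results, layout=None) -> pd.DataFrame:
    """Per-class delay (ms) and Euclidean length (um) box-plot summaries."""
    layout = layout if layout is not None else results.layout
    rows = []
    for sign, mask in (("excitatory", results.fcm > 0),
                       ("inhibitory", results.fcm < 0)):
        delays = results.delays_ms[mask]
        rows.append({"class": sign, "quantity": "delay_ms",
                     **_box_summary(delays)})
        if layout is not None:
            src, dst = np.nonzero(mask)
            lengths = np.array([
                layout.distance_um(results.channel_ids[i],
                                   results.channel_ids[j])
                for i, j in zip(src, dst)
            ])
            rows.append({"class": sign, "quantity": "length_um",
                         **_box_summary(lengths)})
    return pd.DataFrame(rows)


def inhibitory_fraction_vs_time(spike_set, durations, window=0.050,
                                binwidth=0.001, layout=None,
                                pruning_params=None, threshold=True,
                                **model_kwargs) -> pd.DataFrame:
    """Inhibitory share of detected links when only the first T seconds
    of the recording are analysed, for each T in `durations`."""
    from .connectivity import NcchConnectivity
    from .pruning import PruningParams

    pruning_params = pruning_params or PruningParams()
    rows = []
    for T in durations:
        if T <= 0 or T > spike_set.duration + 1e-9:
            raise ValueError("durations must lie in (0, recording duration]")
        truncated = spike_set.truncate(min(T, spike_set.duration))
        if truncated.total_spikes == 0:
            import warnings
            warnings.warn(f"truncation to {T} s leaves no spikes; skipped")
            continue
        res = NcchConnectivity(truncated, window=window, binwidth=binwidth,
                               layout=layout, **model_kwargs).fit()
        if layout is not None:
            res = res.spatiotemporal_filter(pruning_params, layout)
        if threshold:
            res = res.hard_threshold(pruning_params)
        counts = res.link_counts()
        total = counts["excitatory"] + counts["inhibitory"]
        rows.append({
            "duration_s": float(T),
            "n_excitatory": counts["excitatory"],
            "n_inhibitory": counts["inhibitory"],
            "inhibitory_fraction": counts["inhibitory"] / total if total
            else float("nan"),
        })
    return pd.DataFrame(rows)
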