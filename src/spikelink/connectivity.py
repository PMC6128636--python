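"""Functional connectivity model: pairwise correlogram peaks -> signed matrix.

`NcchConnectivity` is the modelling entry point: construct it from a
`SpikeTrainSet`, call :meth:`fit`, and get a `ConnectivityResults` holding
the signed functional connectivity matrix (FCM), the peak-lag (delay) matrix
and, for comparison, the unfiltered correlogram-peak matrix. Pruning
(spatio-temporal filter, hard threshold) hangs off the results object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .data import ElectrodeLayout, SpikeTrainSet

logger = logging.getLogger(__name__)

__all__ = ["NcchConnectivity", "ConnectivityResults", "build_fcm"]


class NcchConnectivity:
    """Pairwise normalized cross-correlogram connectivity model.

    Parameters
    ----------
    spike_set : SpikeTrainSet
        The recording; needs at least two non-empty channels.
    window : float
        Full correlation-window span in seconds; lags cover
        [-window/2, +window/2]. The default 50 ms spans lags of up to
        +-25 ms, wide enough to contain the longest physiological
        conduction delays (~20 ms).
    binwidth : float
        Lag bin width in seconds (default 1 ms).
    layout : ElectrodeLayout, optional
        Electrode geometry; required later for the spatio-temporal filter.
    min_spikes : int
        Pairs where both trains have fewer spikes are skipped (entity 0):
        correlogram variance dominates below this count.
    apply_boundary_filter : bool
        Re-search inhibitory peaks found in the outer window tail.
    tail_fraction : float
        Width of each discarded tail as a fraction of the window.
    """

    def __init__(self, spike_set: SpikeTrainSet, window: float = 0.050,
                 binwidth: float = 0.001, layout: ElectrodeLayout | None = None,
                 min_spikes: int = 10, apply_boundary_filter: bool = True,
                 tail_fraction: float = 0.25):
        if spike_set.n_channels < 2:
            raise ValueError("need at least two channels")
        if all(spike_set.spike_indices(ch).size == 0
               for ch in spike_set.channel_ids):
            raise ValueError("all channels are empty")
        self.spike_set = spike_set
        self.window = float(window)
        self.binwidth = float(binwidth)
        self.layout = layout
        self.min_spikes = int(min_spikes)
        self.apply_boundary_filter = bool(apply_boundary_filter)
        self.tail_fraction = float(tail_fraction)

    # named presets for the three recording modalities; the lag range spans
    # +- the quoted correlation window of each parameterization
    PRESETS = {
        "simulation": dict(window=0.050, binwidth=0.001),
        "mea60": dict(window=0.050, binwidth=0.0001),
        "mea4k": dict(window=0.048, binwidth=0.00012),
    }

    @classmethod
    def from_preset(cls, spike_set, preset: str, **kwargs):
        params = dict(cls.PRESETS[preset])
        params.update(kwargs)
        return cls(spike_set, **params)

    def fit(self, progress: bool = False) -> "ConnectivityResults":
        """Compute one correlogram per unordered channel pair and assemble
        the signed FCM, delays, and the unfiltered peak matrix.

        All pair correlograms are built in one batched direct sweep; peak
        extraction (mean subtraction, tie-breaking, boundary re-search) is
        vectorized over pairs and reproduces the scalar per-pair functions
        exactly.
        """
        from .correlogram import _n_half_bins, _sweep_counts_batch, \
            quantize_to_bins

        s = self.spike_set
        channels = s.channel_ids
        n = len(channels)
        fs = s.sampling_rate
        fcm = np.zeros((n, n))
        delays = np.zeros((n, n))
        raw = np.zeros((n, n))
        raw_delays = np.zeros((n, n))
        zero_lag = np.zeros((n, n), dtype=bool)
        sizes = np.array([s.spike_indices(ch).size for ch in channels])
        qtrains = [quantize_to_bins(s.spike_times(ch), self.binwidth, fs)
                   for ch in channels]
        indptr = np.zeros(n + 1, dtype=np.int64)
        indptr[1:] = np.cumsum(sizes)
        flat = (np.concatenate(qtrains) if indptr[-1]
                else np.zeros(0, dtype=np.int64))
        refs, tgts = [], []
        for i in range(n):
            for j in range(i + 1, n):
                if sizes[i] < self.min_spikes and sizes[j] < self.min_spikes:
                    continue
                if sizes[i] == 0 or sizes[j] == 0:
                    continue
                # the sparser train is the target; symmetry recovers the rest
                if sizes[j] <= sizes[i]:
                    refs.append(i)
                    tgts.append(j)
                else:
                    refs.append(j)
                    tgts.append(i)
        if refs:
            if progress:
                logger.info("correlograms: %d channel pairs", len(refs))
            ref_a = np.asarray(refs, dtype=np.int64)
            tgt_a = np.asarray(tgts, dtype=np.int64)
            half = _n_half_bins(self.window, self.binwidth)
            counts = _sweep_counts_batch(flat, indptr, ref_a, tgt_a, half)
            norm = np.sqrt(sizes[ref_a] * sizes[tgt_a]).astype(float)
            values = counts / norm[:, None]
            lags = np.arange(-half, half + 1)
            lag_ms_axis = lags * self.binwidth * 1e3
            # column preference: larger value, then smaller |lag|, then
            # positive lag (argmax picks the first of exact ties)
            pref = np.lexsort((-np.sign(lags), np.abs(lags)))
            has_counts = values.any(axis=1)
            filtered = values - values.mean(axis=1, keepdims=True)
            absf = np.abs(filtered)
            nonflat = absf.max(axis=1) >= 1e-12
            col = pref[np.argmax(absf[:, pref], axis=1)]
            rows = np.arange(len(refs))
            entity = filtered[rows, col]
            peak_lag = lag_ms_axis[col]
            if self.apply_boundary_filter:
                central_max_ms = ((1.0 - 2.0 * self.tail_fraction)
                                  * self.window / 2.0 * 1e3)
                central_pref = pref[np.abs(lag_ms_axis[pref])
                                    <= central_max_ms + 1e-9]
                redo = (entity < 0) & (np.abs(peak_lag) * 1e-3
                                       > central_max_ms * 1e-3 + 1e-12)
                if redo.any() and central_pref.size:
                    sub = absf[redo][:, central_pref]
                    col_c = central_pref[np.argmax(sub, axis=1)]
                    entity[redo] = filtered[np.flatnonzero(redo), col_c]
                    peak_lag[redo] = lag_ms_axis[col_c]
            col_r = pref[np.argmax(values[:, pref], axis=1)]
            raw_entity = values[rows, col_r]
            raw_lag = lag_ms_axis[col_r]
            for p in range(len(refs)):
                if not has_counts[p]:
                    continue
                if nonflat[p]:
                    self._store(fcm, delays, zero_lag, refs[p], tgts[p],
                                float(entity[p]), float(peak_lag[p]))
                self._store(raw, raw_delays, None, refs[p], tgts[p],
                            float(raw_entity[p]), float(raw_lag[p]))
        return ConnectivityResults(
            fcm=fcm, delays_ms=delays, raw_ncch=raw, raw_delays_ms=raw_delays,
            zero_lag=zero_lag, channel_ids=list(channels),
            params=dict(window=self.window, binwidth=self.binwidth,
                        min_spikes=self.min_spikes,
                        boundary_filter=self.apply_boundary_filter,
                        tail_fraction=self.tail_fraction),
            spike_set=s, layout=self.layout,
        )

    @staticmethod
    def _store(mat, delays, zero_lag, ref, tgt, entity, lag_ms):
        # lag > 0 (target fires after reference) => reference -> target
        if lag_ms > 0:
            src, dst = ref, tgt
        elif lag_ms < 0:
            src, dst = tgt, ref
        else:
            src, dst = ref, tgt
            if zero_lag is not None:
                zero_lag[src, dst] = True
        mat[src, dst] = entity
        delays[src, dst] = abs(lag_ms)


@dataclass
class ConnectivityResults:
    """Signed functional connectivity matrix with peak delays.

    ``fcm[i, j]`` is the filtered-peak entity of the detected link i -> j
    (0 when none); ``delays_ms`` the corresponding |peak lag|. ``raw_ncch``
    holds the unfiltered correlogram maxima for the same pairs. A thresholded
    instance (TCM) is produced by :meth:`spatiotemporal_filter` /
    :meth:`hard_threshold` (methods delegate to :mod:`spikelink.pruning`).
    """

    fcm: np.ndarray
    delays_ms: np.ndarray
    channel_ids: list[str]
    params: dict
    raw_ncch: np.ndarray | None = None
    raw_delays_ms: np.ndarray | None = None
    zero_lag: np.ndarray | None = None
    spike_set: SpikeTrainSet | None = None
    layout: ElectrodeLayout | None = None
    is_thresholded: bool = False

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    def link_counts(self) -> dict:
        return {
            "excitatory": int(np.count_nonzero(self.fcm > 0)),
            "inhibitory": int(np.count_nonzero(self.fcm < 0)),
        }

    def inhibitory_fraction(self) -> float:
        c = self.link_counts()
        total = c["excitatory"] + c["inhibitory"]
        return c["inhibitory"] / total if total else float("nan")

    def spatiotemporal_filter(self, params=None, layout=None):
        from .pruning import PruningParams, spatiotemporal_filter
        return spatiotemporal_filter(self, layout or self.layout,
                                     params or PruningParams())

    def hard_threshold(self, params=None):
        from .pruning import PruningParams, hard_threshold
        return hard_threshold(self, params or PruningParams())

    def edge_list(self) -> pd.DataFrame:
        src, dst = np.nonzero(self.fcm)
        return pd.DataFrame({
            "source": [self.channel_ids[i] for i in src],
            "target": [self.channel_ids[j] for j in dst],
            "entity": self.fcm[src, dst],
            "delay_ms": self.delays_ms[src, dst],
        })

    def _replace(self, **kw) -> "ConnectivityResults":
        import dataclasses
        return dataclasses.replace(self, **kw)

    def summary(self) -> str:
        c = self.link_counts()
        kind = "TCM (thresholded)" if self.is_thresholded else "FCM"
        lines = [
            f"{kind}: {self.n_channels} channels, "
            f"W={self.params.get('window', float('nan'))*1e3:g} ms, "
            f"bin={self.params.get('binwidth', float('nan'))*1e3:g} ms",
            f"  excitatory links: {c['excitatory']}",
            f"  inhibitory links: {c['inhibitory']}",
        ]
        total = c["excitatory"] + c["inhibitory"]
        if total:
            lines.append(f"  inhibitory fraction: "
                         f"{100 * c['inhibitory'] / total:.1f}%")
            d = self.delays_ms[self.fcm != 0]
            lines.append(f"  median |peak lag|: {np.median(d):.2f} ms")
        return "\n".join(lines)

    def to_hdf5(self, path) -> None:
        with h5py.File(Path(path), "w") as f:
            f.create_dataset("fcm", data=self.fcm)
            f.create_dataset("delays_ms", data=self.delays_ms)
            if self.raw_ncch is not None:
                f.create_dataset("raw_ncch", data=self.raw_ncch)
            f.create_dataset(
                "channel_ids",
                data=np.array(self.channel_ids, dtype=h5py.string_dtype()),
            )
            for k, v in self.params.items():
                if isinstance(v, (int, float, bool, str, np.number)):
                    f.attrs[k] = v
            f.attrs["is_thresholded"] = self.is_thresholded

    @classmethod
    def from_hdf5(cls, path) -> "ConnectivityResults":
        with h5py.File(Path(path), "r") as f:
            ids = [c.decode() if isinstance(c, bytes) else str(c)
                   for c in f["channel_ids"][()]]
            params = {k: v for k, v in f.attrs.items() if k != "is_thresholded"}
            return cls(
                fcm=f["fcm"][()], delays_ms=f["delays_ms"][()],
                raw_ncch=f["raw_ncch"][()] if "raw_ncch" in f else None,
                channel_ids=ids, params=params,
                is_thresholded=bool(f.attrs.get("is_thresholded", False)),
            )


def build_fcm(spike_set: SpikeTrainSet, window: float = 0.050,
              binwidth: float = 0.001, **options) -> ConnectivityResults:
    """Functional wrapper: fit an `NcchConnectivity` model in one call."""
    return NcchConnectivity(spike_set, window=window, binwidth=binwidth,
                            **options).fit()
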