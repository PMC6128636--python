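"""Spike-train containers, electrode layouts, file I/O and basic statistics.

Spike times are stored internally as integer sample indices on the recording's
sampling grid, which makes binning and round-trip persistence exact; the public
API exposes times in seconds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SpikeTrainSet",
    "ElectrodeLayout",
    "Burst",
    "FiringStatistics",
    "load_spike_data",
    "save_spike_data",
    "firing_statistics",
    "detect_bursts",
]


class SpikeTrainSet:
    """Per-channel spike time stamps with a common sampling grid.

    Parameters
    ----------
    spikes : dict
        Mapping ``channel_id -> array of spike times`` (seconds) or, when
        ``from_indices=True``, integer sample indices.
    sampling_rate : float
        Sampling frequency in Hz. All spike times are snapped to this grid.
    duration : float
        Recording duration in seconds.
    """

    def __init__(self, spikes, sampling_rate, duration, *, from_indices=False):
        if sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if duration <= 0:
            raise ValueError("duration must be positive")
        self.sampling_rate = float(sampling_rate)
        self.duration = float(duration)
        max_index = int(round(self.duration * self.sampling_rate))
        self._indices: dict[str, np.ndarray] = {}
        for ch, values in spikes.items():
            values = np.asarray(values)
            if from_indices:
                idx = values.astype(np.int64)
            else:
                if values.size and (np.any(values < 0) or np.any(values > duration)):
                    raise ValueError(
                        f"channel {ch!r}: spike times outside [0, {duration}] s"
                    )
                idx = np.round(values * self.sampling_rate).astype(np.int64)
            if from_indices and idx.size and (idx.min() < 0 or idx.max() > max_index):
                raise ValueError(f"channel {ch!r}: sample indices outside recording")
            idx = np.sort(idx)
            uniq = np.unique(idx)
            if uniq.size != idx.size:
                logger.warning(
                    "channel %s: %d duplicate time stamps collapsed",
                    ch, idx.size - uniq.size,
                )
            self._indices[str(ch)] = uniq

    @property
    def channel_ids(self) -> list[str]:
        return list(self._indices.keys())

    @property
    def n_channels(self) -> int:
        return len(self._indices)

    def spike_indices(self, channel) -> np.ndarray:
        """Integer sample indices of the channel's spikes (sorted, unique)."""
        return self._indices[str(channel)]

    def spike_times(self, channel) -> np.ndarray:
        """Spike times of one channel in seconds."""
        return self._indices[str(channel)] / self.sampling_rate

    def spike_counts(self) -> pd.Series:
        return pd.Series(
            {ch: idx.size for ch, idx in self._indices.items()}, name="n_spikes"
        )

    @property
    def total_spikes(self) -> int:
        return int(sum(idx.size for idx in self._indices.values()))

    def truncate(self, duration: float) -> "SpikeTrainSet":
        """Restrict the recording to its first `duration` seconds."""
        if duration <= 0 or duration > self.duration + 1e-12:
            raise ValueError("truncation duration outside (0, duration]")
        max_index = int(round(duration * self.sampling_rate))
        spikes = {
            ch: idx[idx <= max_index] for ch, idx in self._indices.items()
        }
        return SpikeTrainSet(
            spikes, self.sampling_rate, duration, from_indices=True
        )

    def subset(self, channels) -> "SpikeTrainSet":
        spikes = {str(ch): self._indices[str(ch)] for ch in channels}
        return SpikeTrainSet(
            spikes, self.sampling_rate, self.duration, from_indices=True
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, SpikeTrainSet):
            return NotImplemented
        return (
            self.sampling_rate == other.sampling_rate
            and self.duration == other.duration
            and self.channel_ids == other.channel_ids
            and all(
                np.array_equal(self._indices[ch], other._indices[ch])
                for ch in self._indices
            )
        )

    def __repr__(self) -> str:
        return (
            f"SpikeTrainSet(n_channels={self.n_channels}, "
            f"duration={self.duration:g}s, fs={self.sampling_rate:g}Hz, "
            f"total_spikes={self.total_spikes})"
        )


@dataclass
class ElectrodeLayout:
    """Channel -> grid position mapping for a planar micro-electrode array."""

    channel_ids: list[str]
    rows: np.ndarray
    cols: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    pitch_um: float

    def __post_init__(self):
        if self.pitch_um <= 0:
            raise ValueError("pitch_um must be positive")
        self.rows = np.asarray(self.rows, dtype=int)
        self.cols = np.asarray(self.cols, dtype=int)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        pos = set(zip(self.rows.tolist(), self.cols.tolist()))
        if len(pos) != len(self.channel_ids):
            raise ValueError("electrode positions must be unique")
        self._index = {str(ch): i for i, ch in enumerate(self.channel_ids)}

    @classmethod
    def from_grid(cls, n_rows, n_cols, pitch_um, *, skip_corners=False, prefix="ch"):
        ids, rows, cols = [], [], []
        corners = {(0, 0), (0, n_cols - 1), (n_rows - 1, 0), (n_rows - 1, n_cols - 1)}
        for r in range(n_rows):
            for c in range(n_cols):
                if skip_corners and (r, c) in corners:
                    continue
                ids.append(f"{prefix}{r:02d}_{c:02d}")
                rows.append(r)
                cols.append(c)
        rows = np.array(rows)
        cols = np.array(cols)
        return cls(ids, rows, cols, cols * pitch_um, rows * pitch_um, pitch_um)

    @classmethod
    def mea60(cls):
        """8x8 grid minus corners, 200 um pitch (60 channels)."""
        return cls.from_grid(8, 8, 200.0, skip_corners=True)

    @classmethod
    def mea4k(cls):
        """64x64 grid, 42 um pitch (4096 channels)."""
        return cls.from_grid(64, 64, 42.0)

    def position_um(self, channel) -> tuple[float, float]:
        i = self._index[str(channel)]
        return float(self.x_um[i]), float(self.y_um[i])

    def distance_um(self, channel_a, channel_b) -> float:
        xa, ya = self.position_um(channel_a)
        xb, yb = self.position_um(channel_b)
        return float(np.hypot(xa - xb, ya - yb))

    def __contains__(self, channel) -> bool:
        return str(channel) in self._index

    def subset(self, channels) -> "ElectrodeLayout":
        idx = [self._index[str(ch)] for ch in channels]
        return ElectrodeLayout(
            [str(ch) for ch in channels],
            self.rows[idx], self.cols[idx],
            self.x_um[idx], self.y_um[idx],
            self.pitch_um,
        )


@dataclass(frozen=True)
class Burst:
    """Run of >= `min_spikes` spikes with all consecutive ISIs <= `max_isi`."""

    channel_id: str
    start: float
    end: float
    n_spikes: int


@dataclass
class FiringStatistics:
    mfr: pd.Series          # spikes/s per channel
    ifr: np.ndarray         # population IFR trace, spikes/s per active channel
    ifr_bin: float          # s
    n_active_channels: int


def load_spike_data(path, format_hint=None) -> SpikeTrainSet:
    """Read a spike-train set from HDF5 (native schema) or CSV.

    The HDF5 schema stores root attributes ``sampling_rate`` and ``duration_s``
    and one integer dataset of sample indices per channel under ``/spikes``;
    the CSV fallback has columns ``channel_id,time_s`` plus sidecar attributes
    inferred as fs=10 kHz, duration=max time unless a header comment gives them.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    fmt = format_hint or ("csv" if path.suffix.lower() == ".csv" else "hdf5")
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            fs = float(f.attrs["sampling_rate"])
            duration = float(f.attrs["duration_s"])
            spikes = {}
            if "spikes" in f:
                for ch in f["spikes"]:
                    spikes[ch] = f["spikes"][ch][()]
        return SpikeTrainSet(spikes, fs, duration, from_indices=True)
    if fmt == "csv":
        df = pd.read_csv(path)
        if not {"channel_id", "time_s"} <= set(df.columns):
            raise IOError("CSV must have columns channel_id,time_s")
        if df["time_s"].min() < 0:
            bad = df.loc[df["time_s"].idxmin(), "channel_id"]
            raise ValueError(f"channel {bad!r}: negative spike time")
        fs = 10_000.0
        duration = float(df["time_s"].max()) if len(df) else 1.0
        spikes = {
            str(ch): grp["time_s"].to_numpy()
            for ch, grp in df.groupby("channel_id", sort=True)
        }
        return SpikeTrainSet(spikes, fs, max(duration, 1.0 / fs))
    raise ValueError(f"unknown format hint {format_hint!r}")


def save_spike_data(spike_set: SpikeTrainSet, path, layout: ElectrodeLayout | None = None,
                    extra_writer=None) -> None:
    """Write a SpikeTrainSet (and optional layout) to the native HDF5 schema."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["sampling_rate"] = spike_set.sampling_rate
        f.attrs["duration_s"] = spike_set.duration
        g = f.create_group("spikes")
        for ch in spike_set.channel_ids:
            g.create_dataset(ch, data=spike_set.spike_indices(ch), dtype="int64")
        if layout is not None:
            lg = f.create_group("layout")
            lg.create_dataset(
                "channel_id",
                data=np.array(layout.channel_ids, dtype=h5py.string_dtype()),
            )
            lg.create_dataset("row", data=layout.rows)
            lg.create_dataset("col", data=layout.cols)
            lg.create_dataset("x_um", data=layout.x_um)
            lg.create_dataset("y_um", data=layout.y_um)
            lg.attrs["pitch_um"] = layout.pitch_um
        if extra_writer is not None:
            extra_writer(f)


def load_layout(path) -> ElectrodeLayout:
    """Read an electrode layout from the HDF5 schema or a CSV file."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        pitch = float(df.attrs.get("pitch_um", 0)) if hasattr(df, "attrs") else 0.0
        if not pitch:
            # infer pitch from the coordinate grid
            xs = np.unique(df["x_um"])
            pitch = float(np.min(np.diff(xs))) if xs.size > 1 else 1.0
        return ElectrodeLayout(
            [str(c) for c in df["channel_id"]],
            df["row"].to_numpy(), df["col"].to_numpy(),
            df["x_um"].to_numpy(), df["y_um"].to_numpy(), pitch,
        )
    with h5py.File(path, "r") as f:
        lg = f["layout"]
        ids = [c.decode() if isinstance(c, bytes) else str(c)
               for c in lg["channel_id"][()]]
        return ElectrodeLayout(
            ids, lg["row"][()], lg["col"][()],
            lg["x_um"][()], lg["y_um"][()], float(lg.attrs["pitch_um"]),
        )


def firing_statistics(spike_set: SpikeTrainSet, ifr_bin: float = 0.1) -> FiringStatistics:
    """Mean firing rate per channel and the population IFR trace.

    The IFR trace is the population spike count per `ifr_bin`, divided by
    (`ifr_bin` x number of active channels), i.e. spikes/s per active channel.
    """
    if ifr_bin <= 0:
        raise ValueError("ifr_bin must be positive")
    if spike_set.duration <= 0:
        raise ValueError("zero-duration recording")
    mfr = spike_set.spike_counts() / spike_set.duration
    mfr.name = "mfr"
    n_bins = int(np.ceil(spike_set.duration / ifr_bin))
    counts = np.zeros(n_bins)
    n_active = 0
    for ch in spike_set.channel_ids:
        t = spike_set.spike_times(ch)
        if t.size:
            n_active += 1
            b = np.minimum((t / ifr_bin).astype(int), n_bins - 1)
            counts += np.bincount(b, minlength=n_bins)
    ifr = counts / (ifr_bin * max(n_active, 1))
    return FiringStatistics(mfr, ifr, ifr_bin, n_active)


def detect_bursts(times, channel_id="", min_spikes: int = 5,
                  max_isi: float = 0.100) -> list[Burst]:
    """Maximal runs of >= `min_spikes` spikes with consecutive ISIs <= `max_isi`.

    `times` is a sorted 1-D array of spike times in seconds. Runs are maximal,
    so bursts never overlap and every spike belongs to at most one burst.
    """
    times = np.asarray(times, dtype=float)
    if times.size < min_spikes:
        return []
    isi_ok = np.diff(times) <= max_isi + 1e-12
    bursts = []
    run_start = 0
    for i in range(len(isi_ok) + 1):
        if i == len(isi_ok) or not isi_ok[i]:
            run_len = i - run_start + 1
            if run_len >= min_spikes:
                bursts.append(Burst(
                    channel_id=str(channel_id),
                    start=float(times[run_start]),
                    end=float(times[i]),
                    n_spikes=int(run_len),
                ))
            run_start = i + 1
    return bursts
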