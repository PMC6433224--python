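"""Domain containers and file I/O for MEA recordings.

A :class:`Recording` is a channels x samples voltage matrix in microvolts
with acquisition metadata; an :class:`ElectrodeLayout` maps electrode ids to
planar positions in micrometres. Readers and writers cover the INTAN
RHD2000 v1.x data file (read-only), an HDF5 container used throughout the
toolkit, and plain CSV tables for layouts and spike events.

Conventions
-----------
* Voltages are stored and processed as float32 microvolts; raw integer ADC
  codes are not retained after import.
* Time is seconds from the start of the recording (``t0 = 0`` by default);
  time -> sample-index conversion is floor-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from . import _rhd
from .errors import ParameterError, SchemaError

#: Default acquisition metadata: 20 kSamples/s, amplifier bandwidth
#: 1-10000 Hz, 5 Hz software high-pass.
DEFAULT_SAMPLING_RATE = 20_000.0
DEFAULT_BANDWIDTH = (1.0, 10_000.0)
DEFAULT_SOFTWARE_HIGHPASS = 5.0

#: Standard 60-electrode grid: 8 x 8 minus the four corners, 100 um
#: electrode diameter, 700 um centre-to-centre pitch.
DEFAULT_ELECTRODE_DIAMETER_UM = 100.0
DEFAULT_ELECTRODE_PITCH_UM = 700.0


@dataclass
class Recording:
    """Multichannel extracellular voltage recording.

    Parameters
    ----------
    data
        ``(n_channels, n_samples)`` voltage matrix in microvolts.
    sampling_rate
        Samples per second per channel.
    bandwidth_low, bandwidth_high
        Hardware amplifier band edges in Hz.
    software_highpass
        Software high-pass corner applied upstream, in Hz (metadata only;
        the pipeline treats the data it is given as already filtered).
    channel_ids
        Ordered channel labels; generated as ``ch00 ...`` when omitted.
    t0
        Time of the first sample in seconds.
    """

    data: np.ndarray
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    bandwidth_low: float = DEFAULT_BANDWIDTH[0]
    bandwidth_high: float = DEFAULT_BANDWIDTH[1]
    software_highpass: float = DEFAULT_SOFTWARE_HIGHPASS
    channel_ids: list[str] | None = None
    t0: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 2:
            raise ParameterError("data must be a 2-D channels x samples matrix")
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be > 0")
        if self.channel_ids is None:
            self.channel_ids = [f"ch{i:02d}" for i in range(self.data.shape[0])]
        else:
            self.channel_ids = [str(c) for c in self.channel_ids]
        if len(self.channel_ids) != self.data.shape[0]:
            raise ParameterError(
                f"{len(self.channel_ids)} channel ids for "
                f"{self.data.shape[0]} data rows"
            )
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ParameterError("channel ids must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def channel(self, channel_id: str) -> np.ndarray:
        return self.data[self.channel_ids.index(channel_id)]

    def time_to_index(self, t: float) -> int:
        """Floor-based conversion from seconds to sample index."""
        return int(math.floor((t - self.t0) * self.sampling_rate))

    def index_to_time(self, i: int) -> float:
        return self.t0 + i / self.sampling_rate


@dataclass
class ElectrodeLayout:
    """Planar electrode geometry: id -> (x, y) positions in micrometres."""

    positions: dict[str, tuple[float, float]]
    diameter: float = DEFAULT_ELECTRODE_DIAMETER_UM
    pitch: float = DEFAULT_ELECTRODE_PITCH_UM

    def __post_init__(self):
        self.positions = {
            str(k): (float(v[0]), float(v[1])) for k, v in self.positions.items()
        }
        if self.diameter <= 0:
            raise ParameterError("electrode diameter must be > 0")
        if self.pitch <= 0:
            raise ParameterError("electrode pitch must be > 0")
        coords = list(self.positions.values())
        if len(set(coords)) != len(coords):
            raise ParameterError("electrode positions must be distinct")

    @classmethod
    def default_60(
        cls,
        pitch: float = DEFAULT_ELECTRODE_PITCH_UM,
        diameter: float = DEFAULT_ELECTRODE_DIAMETER_UM,
    ) -> "ElectrodeLayout":
        """8 x 8 grid minus the four corners (60 electrodes).

        Electrode ids follow the column-row convention of commercial
        60-channel chips: ``"12"`` is column 1, row 2.
        """
        positions = {}
        for col in range(1, 9):
            for row in range(1, 9):
                if (col, row) in {(1, 1), (1, 8), (8, 1), (8, 8)}:
                    continue
                positions[f"{col}{row}"] = ((col - 1) * pitch, (row - 1) * pitch)
        return cls(positions, diameter=diameter, pitch=pitch)

    @property
    def ids(self) -> list[str]:
        return list(self.positions.keys())

    def coords(self, ids=None) -> np.ndarray:
        """Positions as an ``(n, 2)`` float array, ordered as ``ids``."""
        ids = self.ids if ids is None else ids
        return np.array([self.positions[i] for i in ids], dtype=float)

    def distance(self, a: str, b: str) -> float:
        """Centre-to-centre distance in micrometres."""
        (xa, ya), (xb, yb) = self.positions[a], self.positions[b]
        return math.hypot(xb - xa, yb - ya)

    def diagonal(self) -> float:
        """Largest centre-to-centre distance across the array, in um."""
        xy = self.coords()
        lo, hi = xy.min(axis=0), xy.max(axis=0)
        return float(np.hypot(*(hi - lo)))


@dataclass
class ChannelStats:
    """Per-channel noise statistics used for threshold detection.

    ``sd`` is the sample standard deviation over the full session presented
    to the estimator; the detection threshold is ``k * sd``.
    """

    channel_id: str
    sd: float
    rms: float
    n_samples_used: int
    flagged: bool = False  # True when sd == 0 (dead/constant trace)


# ---------------------------------------------------------------------------
# INTAN RHD2000 reader


def read_rhd(path) -> Recording:
    """Read amplifier channels from an INTAN RHD2000 v1.x data file.

    Amplifier samples are scaled to microvolts at 0.195 uV per 16-bit step
    around the 32768 midpoint code. Auxiliary, supply, ADC and digital
    streams are skipped. Raises :class:`~meakit.errors.FormatError` for
    non-RHD or v2/.rhs files and
    :class:`~meakit.errors.TruncatedFileError` when the file ends inside a
    data block.
    """
    header, data = _rhd.read_rhd_file(path)
    return Recording(
        data=data,
        sampling_rate=header.sample_rate,
        bandwidth_low=header.lower_bandwidth,
        bandwidth_high=header.upper_bandwidth,
        software_highpass=header.dsp_cutoff if header.dsp_enabled else 0.0,
        channel_ids=header.amplifier_names or None,
    )


# ---------------------------------------------------------------------------
# HDF5 container

_REC_ATTRS = {
    "sampling_rate_hz": "sampling_rate",
    "bandwidth_low_hz": "bandwidth_low",
    "bandwidth_high_hz": "bandwidth_high",
    "highpass_hz": "software_highpass",
    "t0_s": "t0",
}

_ID_DTYPE = h5py.string_dtype(encoding="utf-8")


def write_container(recording: Recording, layout: ElectrodeLayout | None, path):
    """Write a recording (and optionally its layout) to the HDF5 container.

    Schema: ``/recording/data`` (float32, channels x samples, uV) with
    attributes ``sampling_rate_hz``, ``bandwidth_low_hz``,
    ``bandwidth_high_hz``, ``highpass_hz``, ``t0_s``;
    ``/recording/channel_ids``; ``/layout/positions`` (id, x_um, y_um) with
    attributes ``diameter_um``, ``pitch_um``. ``/ground_truth/*`` groups are
    written only by the simulator.
    """
    with h5py.File(path, "w") as f:
        grp = f.create_group("recording")
        ds = grp.create_dataset("data", data=recording.data, dtype="float32")
        for attr, fieldname in _REC_ATTRS.items():
            ds.attrs[attr] = float(getattr(recording, fieldname))
        grp.create_dataset(
            "channel_ids", data=np.array(recording.channel_ids, dtype=object),
            dtype=_ID_DTYPE,
        )
        if layout is not None:
            _write_layout_group(f, layout)


def _write_layout_group(f: h5py.File, layout: ElectrodeLayout):
    dt = np.dtype([("id", _ID_DTYPE), ("x_um", "f8"), ("y_um", "f8")])
    rows = np.array(
        [(i, x, y) for i, (x, y) in layout.positions.items()], dtype=dt
    )
    grp = f.require_group("layout")
    ds = grp.create_dataset("positions", data=rows)
    ds.attrs["diameter_um"] = float(layout.diameter)
    ds.attrs["pitch_um"] = float(layout.pitch)


def read_container(path) -> tuple[Recording, ElectrodeLayout | None]:
    """Read a recording (and layout, when present) from the HDF5 container."""
    with h5py.File(path, "r") as f:
        if "recording" not in f or "data" not in f["recording"]:
            raise SchemaError("container has no /recording/data dataset")
        ds = f["recording/data"]
        kwargs = {}
        for attr, fieldname in _REC_ATTRS.items():
            if attr not in ds.attrs:
                raise SchemaError(f"container missing required attribute {attr!r}")
            kwargs[fieldname] = float(ds.attrs[attr])
        channel_ids = None
        if "channel_ids" in f["recording"]:
            channel_ids = [_as_str(c) for c in f["recording/channel_ids"][()]]
        recording = Recording(ds[()], channel_ids=channel_ids, **kwargs)
        layout = _read_layout_group(f) if "layout" in f else None
    return recording, layout


def _read_layout_group(f: h5py.File) -> ElectrodeLayout:
    if "positions" not in f["layout"]:
        raise SchemaError("container missing /layout/positions dataset")
    ds = f["layout/positions"]
    for attr in ("diameter_um", "pitch_um"):
        if attr not in ds.attrs:
            raise SchemaError(f"container missing required attribute {attr!r}")
    rows = ds[()]
    positions = {
        _as_str(r["id"]): (float(r["x_um"]), float(r["y_um"])) for r in rows
    }
    return ElectrodeLayout(
        positions,
        diameter=float(ds.attrs["diameter_um"]),
        pitch=float(ds.attrs["pitch_um"]),
    )


def _as_str(v) -> str:
    return v.decode("utf-8") if isinstance(v, bytes) else str(v)


# ---------------------------------------------------------------------------
# CSV tables

LAYOUT_COLUMNS = ("electrode_id", "x_um", "y_um")
SPIKE_COLUMNS = ("electrode_id", "t_s", "amplitude_uV")


def read_layout_csv(path) -> ElectrodeLayout:
    """Read an electrode layout table.

    Requires columns ``electrode_id, x_um, y_um``; ``diameter_um`` is
    optional. The pitch is inferred as the minimum centre-to-centre
    distance between electrodes.
    """
    df = pd.read_csv(path, dtype={"electrode_id": str})
    for col in LAYOUT_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"layout CSV missing required column {col!r}")
    dupes = df["electrode_id"][df["electrode_id"].duplicated()]
    if len(dupes):
        raise SchemaError(
            f"duplicate electrode_id in layout CSV: {dupes.iloc[0]!r}"
        )
    for col in ("x_um", "y_um"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise SchemaError(
                f"non-numeric {col} value in layout CSV at row {row + 2} "
                f"(counting the header as row 1)"
            )
        df[col] = coerced
    positions = {
        r.electrode_id: (r.x_um, r.y_um) for r in df.itertuples(index=False)
    }
    diameter = (
        float(df["diameter_um"].iloc[0])
        if "diameter_um" in df.columns
        else DEFAULT_ELECTRODE_DIAMETER_UM
    )
    pitch = _infer_pitch(np.column_stack([df["x_um"], df["y_um"]]))
    return ElectrodeLayout(positions, diameter=diameter, pitch=pitch)


def _infer_pitch(xy: np.ndarray) -> float:
    if len(xy) < 2:
        return DEFAULT_ELECTRODE_PITCH_UM
    from scipy.spatial.distance import pdist

    return float(pdist(xy).min())


def write_layout_csv(layout: ElectrodeLayout, path):
    df = pd.DataFrame(
        [(i, x, y, layout.diameter) for i, (x, y) in layout.positions.items()],
        columns=[*LAYOUT_COLUMNS, "diameter_um"],
    )
    df.to_csv(path, index=False)


def write_spike_table(spiketrains, path):
    """Write detected spikes as a CSV with columns electrode_id, t_s, amplitude_uV.

    ``spiketrains`` is an iterable of :class:`meakit.detect.SpikeTrain` (or
    any objects with ``electrode_id`` and ``events``); rows are sorted by
    time.
    """
    rows = [
        (train.electrode_id, ev.t, ev.amplitude)
        for train in spiketrains
        for ev in train.events
    ]
    df = pd.DataFrame(rows, columns=list(SPIKE_COLUMNS))
    df = df.sort_values(["t_s", "electrode_id"], kind="stable")
    df.to_csv(path, index=False)


def read_spike_table(path) -> pd.DataFrame:
    """Read a spike table CSV, returning a time-sorted DataFrame."""
    df = pd.read_csv(path, dtype={"electrode_id": str})
    for col in SPIKE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"spike table missing required column {col!r}")
    return df.sort_values("t_s", kind="stable").reset_index(drop=True)
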