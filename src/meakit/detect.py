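"""Threshold-crossing spike detection.

The detector declares a spike whenever a channel first crosses ``k`` times
its own standard deviation (default ``k = 4``, negative-going), with the
standard deviation computed over the whole recording session. An amplitude
window then discards events whose negative peak falls outside
[-400, -80] uV — small threshold-grazing noise events and large artifacts —
and an activity criterion selects electrodes with enough spikes for
further analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_io import ChannelStats, Recording
from .errors import ParameterError


@dataclass
class DetectionParams:
    """Detection settings.

    ``k`` scales the per-channel SD into a threshold. ``dead_time``
    suppresses re-triggering on one waveform. The snippet window is
    ``window_pre`` before to ``window_post`` after the crossing. The keep
    window ``[amp_keep_min, amp_keep_max]`` (closed) is an artifact filter
    on the signed negative-peak amplitude. Electrode selection keeps
    electrodes with more than ``min_spike_count`` events per session, or,
    in strict mode (``min_rate`` set), with a rate above ``min_rate`` Hz.
    """

    k: float = 4.0
    polarity: str = "negative"  # negative | positive | both
    dead_time: float = 0.003
    window_pre: float = 0.002
    window_post: float = 0.006
    amp_keep_min: float = -400.0
    amp_keep_max: float = -80.0
    min_spike_count: int = 20
    min_rate: float | None = None

    def __post_init__(self):
        if self.k <= 0:
            raise ParameterError("k must be > 0")
        if self.dead_time < 0:
            raise ParameterError("dead_time must be >= 0")
        if self.polarity not in ("negative", "positive", "both"):
            raise ParameterError(f"unknown polarity {self.polarity!r}")
        if not self.amp_keep_min < self.amp_keep_max < 0:
            raise ParameterError(
                "amplitude keep window must satisfy amp_keep_min < amp_keep_max < 0"
            )


@dataclass
class SpikeEvent:
    """One threshold crossing: time, signed peak amplitude, snippet."""

    electrode_id: str
    t: float
    amplitude: float
    waveform: np.ndarray | None = None
    padded: bool = False  # snippet extended past a recording edge


@dataclass
class SpikeTrain:
    """Time-ordered spike events on one electrode."""

    electrode_id: str
    events: list[SpikeEvent]
    duration: float

    def __post_init__(self):
        times = self.times
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ParameterError("spike events must be strictly increasing in time")

    @property
    def times(self) -> np.ndarray:
        return np.array([e.t for e in self.events])

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([e.amplitude for e in self.events])

    @property
    def rate(self) -> float:
        """Mean firing rate over the session, Hz."""
        return len(self.events) / self.duration if self.duration > 0 else 0.0

    @property
    def mean_amplitude(self) -> float:
        return float(self.amplitudes.mean()) if self.events else float("nan")

    def __len__(self) -> int:
        return len(self.events)


def estimate_channel_sd(trace, channel_id: str = "") -> ChannelStats:
    """Sample SD and RMS of a full-session trace.

    A constant trace yields ``sd = 0`` and is flagged; detection on such a
    channel returns an empty train with a warning.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ParameterError("trace is empty")
    sd = float(trace.std(ddof=1)) if trace.size > 1 else 0.0
    rms = float(np.sqrt(np.mean(trace**2)))
    return ChannelStats(
        channel_id=channel_id,
        sd=sd,
        rms=rms,
        n_samples_used=trace.size,
        flagged=sd == 0.0,
    )


def _first_crossings(trace: np.ndarray, thr: float, downward: bool) -> np.ndarray:
    """Sample indices where the trace first passes the threshold."""
    if trace.size == 0:
        return np.empty(0, dtype=int)
    beyond = trace < thr if downward else trace > thr
    idx = np.flatnonzero(beyond[1:] & ~beyond[:-1]) + 1
    if beyond[0]:
        idx = np.concatenate([[0], idx])
    return idx


def detect_spikes(
    trace,
    stats: ChannelStats,
    params: DetectionParams,
    sampling_rate: float,
    electrode_id: str | None = None,
) -> SpikeTrain:
    """Threshold-crossing detection on one channel.

    Events are the samples where the trace first crosses ``-k * sd``
    downward (default polarity); crossings within ``dead_time`` of an
    accepted event are suppressed. Each event carries the signed extreme
    amplitude within ``[t - window_pre, t + window_post]`` and a snippet of
    that window, zero-padded (and flagged) when it extends past a
    recording edge.
    """
    trace = np.asarray(trace, dtype=float)
    eid = electrode_id if electrode_id is not None else stats.channel_id
    duration = trace.size / sampling_rate
    if stats.sd <= 0:
        warnings.warn(
            f"channel {eid!r}: sd = 0 (constant trace), no detection performed",
            stacklevel=2,
        )
        return SpikeTrain(eid, [], duration)

    thr = params.k * stats.sd
    if params.polarity == "negative":
        idx = _first_crossings(trace, -thr, downward=True)
    elif params.polarity == "positive":
        idx = _first_crossings(trace, thr, downward=False)
    else:
        idx = np.union1d(
            _first_crossings(trace, -thr, downward=True),
            _first_crossings(trace, thr, downward=False),
        )

    dead = int(round(params.dead_time * sampling_rate))
    kept = []
    last = -np.inf
    for i in idx:
        if i - last >= dead or not kept:
            kept.append(int(i))
            last = i

    pre = int(round(params.window_pre * sampling_rate))
    post = int(round(params.window_post * sampling_rate))
    events = []
    for i in kept:
        lo, hi = i - pre, i + post
        clo, chi = max(lo, 0), min(hi, trace.size)
        window = trace[clo:chi]
        snippet = window
        padded = False
        if clo != lo or chi != hi:
            snippet = np.zeros(pre + post)
            snippet[clo - lo : clo - lo + window.size] = window
            padded = True
        if params.polarity == "negative":
            amp = float(window.min())
        elif params.polarity == "positive":
            amp = float(window.max())
        else:
            amp = float(window[np.argmax(np.abs(window))])
        events.append(
            SpikeEvent(
                electrode_id=eid,
                t=i / sampling_rate,
                amplitude=amp,
                waveform=np.asarray(snippet, dtype=float),
                padded=padded,
            )
        )
    return SpikeTrain(eid, events, duration)


def filter_spikes_by_amplitude(
    train: SpikeTrain, params: DetectionParams
) -> SpikeTrain:
    """Keep events whose signed amplitude lies in the closed keep window.

    With the defaults this retains negative peaks between -400 and -80 uV
    (magnitude 80-400 uV), discarding threshold-grazing noise events and
    oversized artifacts. Order-preserving and idempotent.
    """
    kept = [
        e
        for e in train.events
        if params.amp_keep_min <= e.amplitude <= params.amp_keep_max
    ]
    return SpikeTrain(train.electrode_id, kept, train.duration)


def select_active_electrodes(
    trains: dict[str, SpikeTrain],
    params: DetectionParams,
    recording_duration: float,
) -> tuple[dict[str, SpikeTrain], dict]:
    """Keep electrodes with enough activity for further analysis.

    Default mode keeps electrodes with more than ``min_spike_count`` events
    in the session; when ``params.min_rate`` is set, strict mode keeps
    electrodes whose rate exceeds ``min_rate`` Hz instead. Returns the
    selected trains and a metadata dict recording the mode used.
    """
    if recording_duration <= 0:
        raise ParameterError("recording_duration must be > 0")
    if params.min_rate is not None:
        selected = {
            e: tr
            for e, tr in trains.items()
            if len(tr) / recording_duration > params.min_rate
        }
        meta = {"selection_mode": "rate", "min_rate_hz": params.min_rate}
    else:
        selected = {
            e: tr for e, tr in trains.items() if len(tr) > params.min_spike_count
        }
        meta = {"selection_mode": "count", "min_spike_count": params.min_spike_count}
    return selected, meta


def run_detection(
    recording: Recording, params: DetectionParams | None = None
) -> tuple[dict[str, SpikeTrain], dict]:
    """Full per-recording detection: SD estimate, threshold detection,
    amplitude filter, electrode selection.

    Returns the selected spike trains keyed by electrode id and the
    selection metadata.
    """
    params = params or DetectionParams()
    trains = {}
    for i, eid in enumerate(recording.channel_ids):
        trace = recording.data[i]
        stats = estimate_channel_sd(trace, eid)
        if stats.flagged:
            trains[eid] = SpikeTrain(eid, [], recording.duration)
            continue
        train = detect_spikes(trace, stats, params, recording.sampling_rate, eid)
        trains[eid] = filter_spikes_by_amplitude(train, params)
    return select_active_electrodes(trains, params, recording.duration)


def match_events(
    detected_times, truth_times, tolerance: float = 0.001
) -> tuple[int, list[tuple[int, int]]]:
    """Greedy one-to-one matching of detected to true event times.

    Each true event is matched to the nearest unused detected event within
    ``tolerance`` seconds, in time order. Returns the number of matches and
    the matched (detected_index, truth_index) pairs; recall is
    ``n / len(truth_times)`` and precision ``n / len(detected_times)``.
    """
    det = np.sort(np.asarray(detected_times, dtype=float))
    tru = np.sort(np.asarray(truth_times, dtype=float))
    pairs = []
    used = np.zeros(det.size, dtype=bool)
    j = 0
    for ti, t in enumerate(tru):
        while j < det.size and det[j] < t - tolerance:
            j += 1
        best, best_d = -1, tolerance
        for jj in range(j, det.size):
            if det[jj] > t + tolerance:
                break
            d = abs(det[jj] - t)
            if not used[jj] and d <= best_d:
                best, best_d = jj, d
        if best >= 0:
            used[best] = True
            pairs.append((best, ti))
    return len(pairs), pairs
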