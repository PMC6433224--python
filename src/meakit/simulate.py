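"""Synthetic MEA recordings with ground truth.

Emulates spontaneous activity of a beating cardiomyocyte (HL-1 style)
monolayer on a 60-electrode array: quasi-periodic wavefront events that
propagate as a planar front at constant velocity across the grid, deposit
a triphasic extracellular action potential on every electrode, and sit on
additive white Gaussian noise optionally quantized to the acquisition
system's ADC step. Electroporation experiments are emulated by switching
the target electrode to an intracellular-like waveform that relaxes
exponentially back to the extracellular shape as the membrane reseals.

Every generated spike, wavefront and electroporation event is recorded in
a :class:`GroundTruth` object so that detection, SNR and velocity
estimators can be validated against known truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .core_io import (
    DEFAULT_SAMPLING_RATE,
    ElectrodeLayout,
    Recording,
    write_container,
    _as_str,
)
from .errors import ParameterError, SchemaError

# Defaults matching the activity statistics of spontaneously beating HL-1
# monolayers on commercial 60-electrode chips: 1.94 events/s per electrode,
# negative-peak amplitude -123.4 uV (SD 39.12 uV across electrodes),
# conduction velocity 0.047-0.32 m/s. The ADC step is 0.195 uV.
DEFAULT_FIRING_RATE_HZ = 1.94
DEFAULT_AMP_MEAN_UV = -123.4
DEFAULT_AMP_SD_UV = 39.12
DEFAULT_VELOCITY_M_PER_S = 0.1
ADC_STEP_UV = 0.195
#: Baseline noise chosen to place per-electrode SNR of the default
#: simulation in the 9-18 dB band typical of planar gold electrodes
#: (a ~34 uV peak-to-peak Gaussian baseline has an RMS near 5 uV).
DEFAULT_NOISE_RMS_UV = 5.0

#: Mean electrode impedance (kOhm) of commercial gold MEAs at the three
#: standard test frequencies, with across-electrode SDs (N = 64).
IMPEDANCE_MEAN_KOHM = {100.0: 1235.4, 1000.0: 160.06, 7500.0: 39.28}
IMPEDANCE_SD_KOHM = {100.0: 124.75, 1000.0: 12.88, 7500.0: 1.12}


@dataclass
class SimulationParams:
    """Parameters of a synthetic MEA recording.

    ``firing_rate`` is the rate of wavefront events (quasi-periodic with
    Gaussian jitter of ``jitter_sd`` seconds, cardiac-like rather than
    Poisson). Amplitudes are hierarchical, matching how per-electrode
    average amplitudes are reported for real arrays: each electrode draws
    a mean negative-peak amplitude from ``N(amp_mean, amp_sd)`` once, and
    individual spikes scatter around it with relative SD ``amp_rel_sd``.
    ``quantization_step`` of 0 disables ADC quantization.
    """

    duration: float = 60.0
    firing_rate: float = DEFAULT_FIRING_RATE_HZ
    amp_mean: float = DEFAULT_AMP_MEAN_UV
    amp_sd: float = DEFAULT_AMP_SD_UV
    amp_rel_sd: float = 0.15
    noise_rms: float = DEFAULT_NOISE_RMS_UV
    velocity: float = DEFAULT_VELOCITY_M_PER_S
    origin: tuple[float, float] = (0.0, 0.0)
    direction: tuple[float, float] = (1.0, 0.0)
    jitter_sd: float = 0.01
    quantization_step: float = ADC_STEP_UV
    seed: int | None = None

    def __post_init__(self):
        if self.duration <= 0:
            raise ParameterError("duration must be > 0")
        if self.firing_rate < 0:
            raise ParameterError("firing_rate must be >= 0")
        if self.noise_rms < 0:
            raise ParameterError("noise_rms must be >= 0")
        if self.velocity <= 0:
            raise ParameterError("velocity must be > 0")
        if self.amp_mean >= 0:
            raise ParameterError("amp_mean must be negative (negative-peak amplitude)")
        if self.amp_rel_sd < 0:
            raise ParameterError("amp_rel_sd must be >= 0")
        if self.quantization_step < 0:
            raise ParameterError("quantization_step must be >= 0")
        norm = float(np.hypot(*self.direction))
        if norm == 0:
            raise ParameterError("direction must be a nonzero vector")
        self.direction = (self.direction[0] / norm, self.direction[1] / norm)


@dataclass
class WaveEvent:
    """One planar wavefront: reference time, geometry, speed."""

    t: float
    origin: tuple[float, float]
    direction: tuple[float, float]
    velocity: float


@dataclass
class GroundTruth:
    """Everything the simulator deposited, for recovery tests.

    ``spike_times[e]`` holds the exact (un-rounded) negative-peak times of
    the spikes on electrode ``e``; ``spike_amps[e]`` the corresponding true
    negative-peak amplitudes in uV.
    """

    spike_times: dict[str, np.ndarray] = field(default_factory=dict)
    spike_amps: dict[str, np.ndarray] = field(default_factory=dict)
    events: list[WaveEvent] = field(default_factory=list)
    electroporation: list[tuple[str, float, float]] = field(default_factory=list)

    @property
    def n_spikes(self) -> int:
        return sum(len(t) for t in self.spike_times.values())

    def spikes_frame(self) -> pd.DataFrame:
        rows = [
            (e, t, a)
            for e in self.spike_times
            for t, a in zip(self.spike_times[e], self.spike_amps[e])
        ]
        df = pd.DataFrame(rows, columns=["electrode_id", "t_s", "amplitude_uV"])
        return df.sort_values("t_s", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Waveform templates


def _gauss(t_ms: np.ndarray, centre_ms: float, width_ms: float) -> np.ndarray:
    return np.exp(-0.5 * ((t_ms - centre_ms) / width_ms) ** 2)


def _finalize(shape: np.ndarray, amp_neg: float) -> np.ndarray:
    # remove the linear ramp between the endpoints so the waveform starts
    # and ends at exactly zero, then scale so the sampled minimum equals
    # amp_neg exactly (x / -x == -1.0 and -1.0 * -amp == amp in IEEE754)
    ramp = np.linspace(shape[0], shape[-1], len(shape))
    shape = shape - ramp
    shape = shape / -shape.min()
    return shape * -amp_neg


def make_extracellular_template(
    duration_ms: float = 8.0,
    amp_neg: float = DEFAULT_AMP_MEAN_UV,
    fs: float = 20_000.0,
    *,
    pos_frac: float = 0.45,
    hump_frac: float = 0.35,
    t_pos_ms: float = 2.0,
    t_neg_ms: float = 3.0,
    t_hump_ms: float = 4.8,
    w_pos_ms: float = 0.45,
    w_neg_ms: float = 0.25,
    w_hump_ms: float = 0.8,
) -> np.ndarray:
    """Triphasic extracellular AP template (uV).

    Three Gaussian lobes — a positive peak, the dominant negative peak, a
    trailing positive hump — with defaults proportioned so that, at the
    typical amplitudes of HL-1 extracellular APs, both positive phases stay
    below 100 uV while the negative peak spans roughly 80-300 uV. The
    sampled minimum equals ``amp_neg`` exactly and the waveform starts and
    ends at zero.
    """
    if amp_neg >= 0:
        raise ParameterError("amp_neg must be negative")
    if fs <= 0 or duration_ms <= 0:
        raise ParameterError("fs and duration_ms must be > 0")
    n = int(round(duration_ms * 1e-3 * fs))
    t_ms = np.arange(n) / fs * 1e3
    shape = (
        pos_frac * _gauss(t_ms, t_pos_ms, w_pos_ms)
        - _gauss(t_ms, t_neg_ms, w_neg_ms)
        + hump_frac * _gauss(t_ms, t_hump_ms, w_hump_ms)
    )
    return _finalize(shape, amp_neg)


def make_intracellular_template(
    duration_ms: float = 12.0,
    amp: float = -100.0,
    fs: float = 20_000.0,
    *,
    pos_frac: float = 0.15,
    t_pos_ms: float = 2.0,
    t_neg_ms: float = 3.0,
    w_pos_ms: float = 0.45,
    w_neg_ms: float = 0.3,
    plateau_width_ms: float = 4.0,
    plateau_frac: float = 0.35,
    plateau_gap_ms: float = 1.2,
    plateau_ramp_ms: float = 0.8,
) -> np.ndarray:
    """Intracellular-like AP template seen after electroporation (uV).

    A dominant negative deflection followed by a wide plateau and no
    trailing positive hump. The plateau is a smoothstep-edged trapezoid
    holding ``plateau_frac`` of the peak amplitude: flat over its stated
    ``plateau_width_ms`` (well within 10% of the plateau level), with
    ``plateau_ramp_ms`` transitions on both sides. With
    ``plateau_width_ms = 0`` the waveform degenerates to a biphasic spike.
    """
    if fs <= 0 or duration_ms <= 0:
        raise ParameterError("fs and duration_ms must be > 0")
    if amp >= 0:
        raise ParameterError("amp must be negative")
    if plateau_width_ms < 0:
        raise ParameterError("plateau_width_ms must be >= 0")
    n = int(round(duration_ms * 1e-3 * fs))
    t_ms = np.arange(n) / fs * 1e3
    shape = pos_frac * _gauss(t_ms, t_pos_ms, w_pos_ms) - _gauss(
        t_ms, t_neg_ms, w_neg_ms
    )
    if plateau_width_ms > 0:
        t0 = t_neg_ms + plateau_gap_ms  # flat region start
        t1 = t0 + plateau_width_ms
        up = _smoothstep((t_ms - (t0 - plateau_ramp_ms)) / plateau_ramp_ms)
        down = _smoothstep((t1 + plateau_ramp_ms - t_ms) / plateau_ramp_ms)
        shape = shape - plateau_frac * up * down
    return _finalize(shape, amp)


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def template_peak_index(template: np.ndarray) -> int:
    """Sample index of the negative peak within a template."""
    return int(np.argmin(template))


# ---------------------------------------------------------------------------
# Recording simulation


def _event_times(params: SimulationParams, rng: np.random.Generator) -> np.ndarray:
    if params.firing_rate == 0:
        return np.empty(0)
    period = 1.0 / params.firing_rate
    n = int(np.floor(params.duration / period))
    base = (np.arange(n) + 0.5) * period
    times = base + rng.normal(0.0, params.jitter_sd, size=n)
    return times[(times > 0) & (times < params.duration)]


def _latencies_s(layout: ElectrodeLayout, event: WaveEvent) -> np.ndarray:
    xy = layout.coords()
    rel = xy - np.asarray(event.origin)
    proj_um = rel @ np.asarray(event.direction)
    return proj_um * 1e-6 / event.velocity


def _deposit(data_row: np.ndarray, waveform: np.ndarray, start: int):
    n = data_row.shape[0]
    lo, hi = max(start, 0), min(start + len(waveform), n)
    if lo < hi:
        data_row[lo:hi] += waveform[lo - start : hi - start].astype(np.float32)


def _quantize(data: np.ndarray, step: float):
    if step > 0:
        np.round(data / np.float32(step), out=data)
        data *= np.float32(step)


def simulate_recording(
    params: SimulationParams,
    layout: ElectrodeLayout | None = None,
    *,
    template_kwargs: dict | None = None,
) -> tuple[Recording, GroundTruth]:
    """Simulate a multichannel extracellular recording.

    Each wavefront event deposits one extracellular template per electrode
    at latency ``((position - origin) . direction) / velocity``; spike
    amplitudes are drawn per electrode and event from
    ``N(amp_mean, amp_sd)`` (sign forced negative); white Gaussian noise at
    ``noise_rms`` is added and the result optionally quantized to
    ``quantization_step``. Identical seeds give bit-identical output.
    """
    if layout is None:
        layout = ElectrodeLayout.default_60()
    rng = np.random.default_rng(params.seed)
    fs = DEFAULT_SAMPLING_RATE
    n_samples = int(round(params.duration * fs))
    ids = layout.ids
    data = np.empty((len(ids), n_samples), dtype=np.float32)
    for i in range(len(ids)):
        data[i] = rng.normal(0.0, params.noise_rms, size=n_samples)

    unit = make_extracellular_template(
        amp_neg=-1.0, fs=fs, **(template_kwargs or {})
    )
    peak_off = template_peak_index(unit)

    gt = GroundTruth(
        spike_times={e: [] for e in ids}, spike_amps={e: [] for e in ids}
    )
    elec_amp = -np.abs(rng.normal(params.amp_mean, params.amp_sd, size=len(ids)))
    tmpl_len_s = len(unit) / fs
    prev_event_end = -np.inf
    for t_event in _event_times(params, rng):
        event = WaveEvent(
            t=float(t_event),
            origin=params.origin,
            direction=params.direction,
            velocity=params.velocity,
        )
        lat = _latencies_s(layout, event)
        if t_event + lat.min() < prev_event_end:
            warnings.warn(
                "wavefront events closer than the template length; "
                "spikes are superposed",
                stacklevel=2,
            )
        prev_event_end = t_event + lat.max() + tmpl_len_s
        amps = elec_amp * np.clip(
            1.0 + params.amp_rel_sd * rng.standard_normal(len(ids)), 0.05, None
        )
        for i, e in enumerate(ids):
            t_peak = t_event + lat[i]
            if not (0.0 <= t_peak < params.duration):
                continue
            start = int(round(t_peak * fs)) - peak_off
            # unit template has min -1, so scale by |amp| to make the
            # deposited negative peak equal the drawn amplitude
            _deposit(data[i], unit * -amps[i], start)
            gt.spike_times[e].append(t_peak)
            gt.spike_amps[e].append(amps[i])
        gt.events.append(event)

    _quantize(data, params.quantization_step)
    for e in ids:
        gt.spike_times[e] = np.asarray(gt.spike_times[e])
        gt.spike_amps[e] = np.asarray(gt.spike_amps[e])
    rec = Recording(data, sampling_rate=fs, channel_ids=ids)
    return rec, gt


def simulate_electroporation(
    params: SimulationParams,
    electrode_id: str,
    t_onset: float,
    reseal_tau: float,
    layout: ElectrodeLayout | None = None,
) -> tuple[Recording, GroundTruth]:
    """Simulate a recording with one electroporated electrode.

    On ``electrode_id``, spikes after ``t_onset`` are a mixture
    ``m * intracellular + (1 - m) * extracellular`` with
    ``m = exp(-(t - t_onset) / reseal_tau)``, emulating membrane resealing
    over minutes: immediately after the pulse the waveform is fully
    intracellular-like, and it relaxes back to the extracellular shape with
    time constant ``reseal_tau`` (seconds). Other electrodes are unaffected.
    """
    if layout is None:
        layout = ElectrodeLayout.default_60()
    if electrode_id not in layout.positions:
        raise ParameterError(f"unknown electrode_id {electrode_id!r}")
    if not (0.0 <= t_onset < params.duration):
        raise ParameterError("t_onset must lie within the recording duration")
    if reseal_tau <= 0:
        raise ParameterError("reseal_tau must be > 0")

    rng = np.random.default_rng(params.seed)
    fs = DEFAULT_SAMPLING_RATE
    n_samples = int(round(params.duration * fs))
    ids = layout.ids
    data = np.empty((len(ids), n_samples), dtype=np.float32)
    for i in range(len(ids)):
        data[i] = rng.normal(0.0, params.noise_rms, size=n_samples)

    duration_ms = 12.0
    extra = make_extracellular_template(duration_ms, amp_neg=-1.0, fs=fs)
    intra = make_intracellular_template(duration_ms, amp=-1.0, fs=fs)
    peak_off = template_peak_index(extra)
    target_idx = ids.index(electrode_id)

    gt = GroundTruth(
        spike_times={e: [] for e in ids},
        spike_amps={e: [] for e in ids},
        electroporation=[(electrode_id, float(t_onset), float(reseal_tau))],
    )
    elec_amp = -np.abs(rng.normal(params.amp_mean, params.amp_sd, size=len(ids)))
    for t_event in _event_times(params, rng):
        event = WaveEvent(
            t=float(t_event),
            origin=params.origin,
            direction=params.direction,
            velocity=params.velocity,
        )
        lat = _latencies_s(layout, event)
        amps = elec_amp * np.clip(
            1.0 + params.amp_rel_sd * rng.standard_normal(len(ids)), 0.05, None
        )
        for i, e in enumerate(ids):
            t_peak = t_event + lat[i]
            if not (0.0 <= t_peak < params.duration):
                continue
            unit = extra
            if i == target_idx and t_peak >= t_onset:
                m = float(np.exp(-(t_peak - t_onset) / reseal_tau))
                unit = m * intra + (1.0 - m) * extra
            start = int(round(t_peak * fs)) - peak_off
            _deposit(data[i], unit * -amps[i], start)
            gt.spike_times[e].append(t_peak)
            gt.spike_amps[e].append(amps[i])
        gt.events.append(event)

    _quantize(data, params.quantization_step)
    for e in ids:
        gt.spike_times[e] = np.asarray(gt.spike_times[e])
        gt.spike_amps[e] = np.asarray(gt.spike_amps[e])
    rec = Recording(data, sampling_rate=fs, channel_ids=ids)
    return rec, gt


# ---------------------------------------------------------------------------
# Impedance simulation


def _impedance_anchors() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    f = np.array(sorted(IMPEDANCE_MEAN_KOHM))
    mean = np.array([IMPEDANCE_MEAN_KOHM[x] for x in f])
    sd = np.array([IMPEDANCE_SD_KOHM[x] for x in f])
    return f, mean, sd


def _mean_sd_at(frequency: float) -> tuple[float, float]:
    if frequency in IMPEDANCE_MEAN_KOHM:
        return IMPEDANCE_MEAN_KOHM[frequency], IMPEDANCE_SD_KOHM[frequency]
    # gold electrodes are log-linear in |Z| vs frequency: interpolate /
    # extrapolate the anchor points in log-log space
    f, mean, sd = _impedance_anchors()
    logm = np.interp(np.log10(frequency), np.log10(f), np.log10(mean))
    cv = np.interp(np.log10(frequency), np.log10(f), sd / mean)
    m = 10.0 ** float(logm)
    return m, m * float(cv)


def simulate_impedance_set(
    n_electrodes: int = 64,
    frequencies=(100.0, 1000.0, 7500.0),
    spread: float = 1.0,
    distortion=None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate an electrode x frequency impedance measurement table.

    Per-electrode "true" impedances are drawn log-normally around the
    per-frequency gold-electrode means (median anchored at the mean, so
    ``spread = 0`` reproduces the means exactly); ``spread`` scales the
    nominal across-electrode SD. ``distortion`` maps true to raw readings:
    either a single ``(a, b)`` pair or a ``{frequency: (a, b)}`` dict with
    ``raw = a * true + b`` (identity when None); this affine distortion is
    what the calibration module is expected to undo.

    Returns a DataFrame with columns
    ``electrode_id, frequency_hz, true_kohm, raw_kohm``.
    """
    if spread < 0:
        raise ParameterError("spread must be >= 0")
    frequencies = [float(f) for f in frequencies]
    if not frequencies or any(f <= 0 for f in frequencies):
        raise ParameterError("frequencies must be non-empty and positive")
    rng = np.random.default_rng(seed)
    rows = []
    for f in frequencies:
        mean, sd = _mean_sd_at(f)
        sigma_log = spread * sd / mean  # log-normal shape ~ coefficient of variation
        true = mean * np.exp(sigma_log * rng.standard_normal(n_electrodes))
        a, b = _distortion_for(distortion, f)
        raw = a * true + b
        for i in range(n_electrodes):
            rows.append((f"el{i:02d}", f, true[i], raw[i]))
    return pd.DataFrame(
        rows, columns=["electrode_id", "frequency_hz", "true_kohm", "raw_kohm"]
    )


def _distortion_for(distortion, frequency: float) -> tuple[float, float]:
    if distortion is None:
        return 1.0, 0.0
    if isinstance(distortion, dict):
        return distortion.get(frequency, (1.0, 0.0))
    a, b = distortion
    return float(a), float(b)


# ---------------------------------------------------------------------------
# Persistence of simulations (container + /ground_truth groups)


def save_simulation(path, recording: Recording, layout: ElectrodeLayout, gt: GroundTruth):
    """Write recording, layout and ground truth to one HDF5 container."""
    write_container(recording, layout, path)
    sdt = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "a") as f:
        grp = f.create_group("ground_truth")
        spikes = gt.spikes_frame()
        dt = np.dtype([("electrode_id", sdt), ("t_s", "f8"), ("amplitude_uV", "f8")])
        arr = np.array(
            list(spikes.itertuples(index=False, name=None)), dtype=dt
        ) if len(spikes) else np.empty(0, dtype=dt)
        grp.create_dataset("spikes", data=arr)
        edt = np.dtype(
            [
                ("t_s", "f8"),
                ("origin_x_um", "f8"),
                ("origin_y_um", "f8"),
                ("direction_x", "f8"),
                ("direction_y", "f8"),
                ("velocity_m_per_s", "f8"),
            ]
        )
        earr = np.array(
            [
                (ev.t, ev.origin[0], ev.origin[1], ev.direction[0], ev.direction[1], ev.velocity)
                for ev in gt.events
            ],
            dtype=edt,
        ) if gt.events else np.empty(0, dtype=edt)
        grp.create_dataset("events", data=earr)
        pdt = np.dtype(
            [("electrode_id", sdt), ("t_onset_s", "f8"), ("reseal_tau_s", "f8")]
        )
        parr = np.array(gt.electroporation, dtype=pdt) if gt.electroporation else np.empty(0, dtype=pdt)
        grp.create_dataset("electroporation", data=parr)


def load_ground_truth(path) -> GroundTruth:
    """Read the /ground_truth groups written by :func:`save_simulation`."""
    gt = GroundTruth()
    with h5py.File(path, "r") as f:
        if "ground_truth" not in f:
            raise SchemaError("container has no /ground_truth group")
        grp = f["ground_truth"]
        spikes = grp["spikes"][()]
        by_e: dict[str, list[tuple[float, float]]] = {}
        for r in spikes:
            by_e.setdefault(_as_str(r["electrode_id"]), []).append(
                (float(r["t_s"]), float(r["amplitude_uV"]))
            )
        for e, rows in by_e.items():
            rows.sort()
            gt.spike_times[e] = np.array([t for t, _ in rows])
            gt.spike_amps[e] = np.array([a for _, a in rows])
        for r in grp["events"][()]:
            gt.events.append(
                WaveEvent(
                    t=float(r["t_s"]),
                    origin=(float(r["origin_x_um"]), float(r["origin_y_um"])),
                    direction=(float(r["direction_x"]), float(r["direction_y"])),
                    velocity=float(r["velocity_m_per_s"]),
                )
            )
        for r in grp["electroporation"][()]:
            gt.electroporation.append(
                (_as_str(r["electrode_id"]), float(r["t_onset_s"]), float(r["reseal_tau_s"]))
            )
    return gt
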