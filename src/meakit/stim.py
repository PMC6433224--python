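"""Electroporation pulse-train design and rendering.

Pulse trains are monophasic square waves delivered through the analog
outputs of the acquisition board, which can supply -3.3 to +3.3 V.
Rendering refuses out-of-range trains rather than clipping them: a
silently clipped train would misrepresent the charge actually delivered
to the electrode.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .errors import ParameterError

#: Analog output range of the acquisition board, volts.
OUTPUT_LIMIT_V = 3.3


@dataclass(frozen=True)
class PulseTrain:
    """Monophasic square pulse train.

    The output alternates between ``offset`` (low) and
    ``offset + amplitude`` (high); both levels must stay within the
    +-3.3 V hardware range. ``duty_cycle`` is the high fraction of each
    period.
    """

    amplitude: float  # V
    pulse_width: float  # s
    duty_cycle: float  # fraction of the period spent high
    duration: float  # s
    offset: float = 0.0  # V
    polarity: str = "monophasic"

    @property
    def period(self) -> float:
        """Pulse period in seconds: ``pulse_width / duty_cycle``."""
        return self.pulse_width / self.duty_cycle

    @property
    def n_pulses(self) -> int:
        """Whole pulses in the train: ``floor(duration / period)``."""
        # guard against float-division dust (1.0 / (1e-3 / 0.5) != 500.0)
        return int(np.floor(self.duration / self.period + 1e-9))

    def to_json(self) -> str:
        d = asdict(self)
        d.update(period_s=self.period, n_pulses=self.n_pulses)
        return json.dumps(d, indent=2, sort_keys=True)


def design_pulse_train(
    amplitude: float,
    pulse_width: float,
    duty_cycle: float,
    duration: float,
    offset: float = 0.0,
) -> PulseTrain:
    """Validate and build a pulse train within the hardware envelope.

    Raises a range error when either output level would exceed +-3.3 V and
    parameter errors for a non-positive width, a duty cycle outside
    (0, 1], or a duration shorter than one pulse.
    """
    for name, v in [
        ("amplitude", amplitude),
        ("pulse_width", pulse_width),
        ("duty_cycle", duty_cycle),
        ("duration", duration),
        ("offset", offset),
    ]:
        if not np.isfinite(v):
            raise ParameterError(f"{name} must be finite")
    if abs(offset) > OUTPUT_LIMIT_V or abs(amplitude + offset) > OUTPUT_LIMIT_V:
        raise ParameterError(
            f"pulse levels [{offset:g}, {amplitude + offset:g}] V exceed the "
            f"+-{OUTPUT_LIMIT_V} V analog output limit"
        )
    if not 0 < duty_cycle <= 1:
        raise ParameterError("duty_cycle must lie in (0, 1]")
    if pulse_width <= 0:
        raise ParameterError("pulse_width must be > 0")
    if duration < pulse_width:
        raise ParameterError("duration must be >= pulse_width")
    return PulseTrain(
        amplitude=float(amplitude),
        pulse_width=float(pulse_width),
        duty_cycle=float(duty_cycle),
        duration=float(duration),
        offset=float(offset),
    )


def render_pulse_train(
    train: PulseTrain, fs: float, quantization_step: float | None = None
) -> np.ndarray:
    """Render a train as a sample vector at sampling rate ``fs``.

    High samples equal ``offset + amplitude``, low samples ``offset``; the
    vector has ``round(duration * fs)`` samples and, when the period is an
    integer number of samples, the fraction of high samples equals the
    duty cycle exactly. An optional ``quantization_step`` (volts) rounds
    the output to DAC levels; none is applied by default.
    """
    # re-validate: PulseTrain is a plain dataclass and may be hand-built
    train = design_pulse_train(
        train.amplitude, train.pulse_width, train.duty_cycle, train.duration, train.offset
    )
    if fs * train.pulse_width < 1:
        raise ParameterError(
            f"sampling rate {fs:g} Hz cannot resolve a {train.pulse_width:g} s pulse"
        )
    n = int(round(train.duration * fs))
    i = np.arange(n)
    period_samples = train.period * fs
    width_samples = train.pulse_width * fs
    if abs(period_samples - round(period_samples)) < 1e-9:
        # exact integer arithmetic avoids fmod drift over long trains
        phase = i % int(round(period_samples))
    else:
        phase = np.mod(i, period_samples)
    high = phase < width_samples - 1e-9
    out = np.where(high, train.offset + train.amplitude, train.offset)
    if quantization_step:
        out = np.round(out / quantization_step) * quantization_step
    return out.astype(float)


def count_rising_edges(samples: np.ndarray, train: PulseTrain) -> int:
    """Rising edges (low to high transitions) in a rendered vector."""
    high = samples > train.offset + train.amplitude / 2 if train.amplitude > 0 else samples < train.offset + train.amplitude / 2
    high = np.asarray(high, dtype=bool)
    edges = int(np.count_nonzero(high[1:] & ~high[:-1]))
    return edges + int(high[0])
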