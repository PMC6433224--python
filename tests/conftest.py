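"""Shared fixtures: electrode layouts, small simulations, and an
independent INTAN RHD2000 v1.x file writer used as the read-back oracle."""

import struct

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from meakit import core_io, simulate

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def layout60() -> core_io.ElectrodeLayout:
    return core_io.ElectrodeLayout.default_60()


@pytest.fixture(scope="session")
def small_sim(layout60):
    """20 s default-parameter simulation shared by read-only tests."""
    params = simulate.SimulationParams(duration=20.0, seed=11)
    rec, gt = simulate.simulate_recording(params, layout60)
    return params, rec, gt


# ---------------------------------------------------------------------------
# Minimal independent RHD2000 v1.x writer (the oracle for the reader).
# Written directly from the published data-file layout, deliberately not
# sharing any code with meakit._rhd.


def _qstr(s: str) -> bytes:
    raw = s.encode("utf-16-le")
    return struct.pack("<I", len(raw)) + raw


def write_rhd_v1(
    path,
    codes: np.ndarray,
    fs: float = 20_000.0,
    lower_bw: float = 1.0,
    upper_bw: float = 10_000.0,
    version: tuple[int, int] = (1, 3),
    magic: int = 0xC6912702,
    truncate_bytes: int = 0,
):
    """Write unsigned 16-bit amplifier codes as an RHD v1.x file.

    ``codes`` is (n_channels, n_samples) with n_samples a multiple of 60.
    """
    codes = np.asarray(codes, dtype="<u2")
    n_ch, n_samples = codes.shape
    assert n_samples % 60 == 0
    out = bytearray()
    out += struct.pack("<I", magic)
    out += struct.pack("<hh", *version)
    out += struct.pack("<f", fs)
    out += struct.pack("<h", 0)  # dsp disabled
    out += struct.pack("<fff", 1.0, lower_bw, upper_bw)  # actual cutoffs
    out += struct.pack("<fff", 1.0, lower_bw, upper_bw)  # desired cutoffs
    out += struct.pack("<h", 0)  # notch off
    out += struct.pack("<ff", 0.0, 0.0)  # impedance test freqs
    out += _qstr("") * 3  # notes
    if version >= (1, 1):
        out += struct.pack("<h", 0)  # temp sensors
    if version >= (1, 3):
        out += struct.pack("<h", 0)  # board mode
    out += struct.pack("<h", 1)  # one signal group
    out += _qstr("Port A") + _qstr("A")
    out += struct.pack("<hhh", 1, n_ch, n_ch)  # enabled, channels, amp channels
    for i in range(n_ch):
        out += _qstr(f"A-{i:03d}") * 2
        out += struct.pack("<hh", i, i)  # native, custom order
        out += struct.pack("<hh", 0, 1)  # amplifier type, enabled
        out += struct.pack("<hh", i, 0)  # chip channel, board stream
        out += struct.pack("<hhhh", 0, 0, 0, 0)  # trigger settings
        out += struct.pack("<ff", 0.0, 0.0)  # impedance mag, phase
    for b in range(n_samples // 60):
        out += np.arange(b * 60, (b + 1) * 60, dtype="<i4").tobytes()
        out += codes[:, b * 60 : (b + 1) * 60].tobytes()
    if truncate_bytes:
        out = out[:-truncate_bytes]
    with open(path, "wb") as fh:
        fh.write(bytes(out))
    return path
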