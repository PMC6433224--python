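"""Reader for INTAN RHD2000 v1.x data files.

Only the subset of the published RHD2000 application note needed to recover
amplifier traces is implemented: the full header is parsed, amplifier
channels are returned scaled to microvolts (0.195 uV per 16-bit step,
midpoint code 32768), and auxiliary / supply / ADC / digital streams are
skipped over. Version 2.x (.rhd) and .rhs files are rejected.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, TruncatedFileError

RHD_MAGIC = 0xC6912702
UV_PER_BIT = 0.195
AMPLIFIER_MIDPOINT = 32768

# signal_type codes from the RHD2000 header
_T_AMPLIFIER = 0
_T_AUX = 1
_T_SUPPLY = 2
_T_ADC = 3
_T_DIG_IN = 4
_T_DIG_OUT = 5

_SAMPLES_PER_BLOCK = 60  # v1.x data blocks hold 60 amplifier samples


@dataclass
class RhdHeader:
    version: tuple[int, int]
    sample_rate: float
    dsp_enabled: bool
    dsp_cutoff: float
    lower_bandwidth: float
    upper_bandwidth: float
    notch_filter_mode: int
    notes: list[str]
    num_temp_sensors: int
    board_mode: int
    amplifier_names: list[str] = field(default_factory=list)
    n_aux: int = 0
    n_supply: int = 0
    n_adc: int = 0
    n_dig_in: int = 0
    n_dig_out: int = 0

    @property
    def n_amplifier(self) -> int:
        return len(self.amplifier_names)


class _Cursor:
    """Sequential binary reader with offset tracking for error reports."""

    def __init__(self, buf: bytes):
        self.buf = buf
        self.pos = 0

    def read(self, fmt: str):
        size = struct.calcsize(fmt)
        if self.pos + size > len(self.buf):
            raise TruncatedFileError("file ends inside header field", self.pos)
        out = struct.unpack_from(fmt, self.buf, self.pos)
        self.pos += size
        return out if len(out) > 1 else out[0]

    def read_qstring(self) -> str:
        length = self.read("<I")
        if length == 0xFFFFFFFF:  # Qt null string
            return ""
        if self.pos + length > len(self.buf):
            raise TruncatedFileError("file ends inside string field", self.pos)
        raw = self.buf[self.pos : self.pos + length]
        self.pos += length
        return raw.decode("utf-16-le")


def _parse_header(cur: _Cursor) -> RhdHeader:
    magic = cur.read("<I")
    if magic != RHD_MAGIC:
        raise FormatError(
            "not an INTAN RHD2000 data file: first 4 bytes are "
            f"0x{magic:08X}, expected 0x{RHD_MAGIC:08X}"
        )
    major = cur.read("<h")
    minor = cur.read("<h")
    if major != 1:
        raise FormatError(
            f"RHD file version {major}.{minor} is not supported; "
            "only v1.x files can be read"
        )
    sample_rate = cur.read("<f")
    dsp_enabled = cur.read("<h")
    actual_dsp_cutoff = cur.read("<f")
    actual_lower_bw = cur.read("<f")
    actual_upper_bw = cur.read("<f")
    cur.read("<fff")  # desired dsp cutoff / lower bw / upper bw
    notch_mode = cur.read("<h")
    cur.read("<ff")  # desired / actual impedance test frequency
    notes = [cur.read_qstring() for _ in range(3)]
    num_temp = cur.read("<h") if (major, minor) >= (1, 1) else 0
    board_mode = cur.read("<h") if (major, minor) >= (1, 3) else 0

    header = RhdHeader(
        version=(major, minor),
        sample_rate=float(sample_rate),
        dsp_enabled=bool(dsp_enabled),
        dsp_cutoff=float(actual_dsp_cutoff),
        lower_bandwidth=float(actual_lower_bw),
        upper_bandwidth=float(actual_upper_bw),
        notch_filter_mode=int(notch_mode),
        notes=notes,
        num_temp_sensors=int(num_temp),
        board_mode=int(board_mode),
    )

    n_groups = cur.read("<h")
    for _ in range(n_groups):
        cur.read_qstring()  # group name
        cur.read_qstring()  # group prefix
        group_enabled = cur.read("<h")
        n_channels = cur.read("<h")
        cur.read("<h")  # amplifier channel count within the group
        for _ in range(n_channels):
            native_name = cur.read_qstring()
            cur.read_qstring()  # custom name
            cur.read("<hh")  # native order, custom order
            signal_type = cur.read("<h")
            enabled = cur.read("<h")
            cur.read("<hh")  # chip channel, board stream
            cur.read("<hhhh")  # spike-scope trigger settings
            cur.read("<ff")  # electrode impedance magnitude, phase
            if not (group_enabled and enabled):
                continue
            if signal_type == _T_AMPLIFIER:
                header.amplifier_names.append(native_name)
            elif signal_type == _T_AUX:
                header.n_aux += 1
            elif signal_type == _T_SUPPLY:
                header.n_supply += 1
            elif signal_type == _T_ADC:
                header.n_adc += 1
            elif signal_type == _T_DIG_IN:
                header.n_dig_in += 1
            elif signal_type == _T_DIG_OUT:
                header.n_dig_out += 1
    return header


def _block_size_bytes(h: RhdHeader) -> int:
    n = _SAMPLES_PER_BLOCK * 4  # timestamps (int32)
    n += _SAMPLES_PER_BLOCK * 2 * h.n_amplifier
    n += (_SAMPLES_PER_BLOCK // 4) * 2 * h.n_aux  # aux sampled at fs/4
    n += 1 * 2 * h.n_supply
    n += 1 * 2 * h.num_temp_sensors
    n += _SAMPLES_PER_BLOCK * 2 * h.n_adc
    if h.n_dig_in > 0:
        n += _SAMPLES_PER_BLOCK * 2  # digital inputs are bit-packed
    if h.n_dig_out > 0:
        n += _SAMPLES_PER_BLOCK * 2
    return n


def read_rhd_file(path) -> tuple[RhdHeader, np.ndarray]:
    """Read an RHD2000 v1.x file.

    Returns the parsed header and the amplifier data as a float32
    ``(n_channels, n_samples)`` matrix in microvolts.
    """
    with open(path, "rb") as fh:
        buf = fh.read()
    if len(buf) < 4:
        raise FormatError(
            "not an INTAN RHD2000 data file: file is shorter than the "
            "4-byte magic number"
        )
    cur = _Cursor(buf)
    header = _parse_header(cur)

    body = len(buf) - cur.pos
    bsz = _block_size_bytes(header)
    n_blocks, leftover = divmod(body, bsz)
    if leftover:
        raise TruncatedFileError(
            f"data section ends inside a block ({leftover} of {bsz} bytes)",
            cur.pos + n_blocks * bsz,
        )

    n_amp = header.n_amplifier
    data = np.empty((n_amp, n_blocks * _SAMPLES_PER_BLOCK), dtype=np.float32)
    pos = cur.pos
    spb = _SAMPLES_PER_BLOCK
    for b in range(n_blocks):
        pos += spb * 4  # skip timestamps
        if n_amp:
            codes = np.frombuffer(
                buf, dtype="<u2", count=spb * n_amp, offset=pos
            ).reshape(n_amp, spb)
            data[:, b * spb : (b + 1) * spb] = (
                codes.astype(np.float32) - AMPLIFIER_MIDPOINT
            ) * np.float32(UV_PER_BIT)
        pos += spb * 2 * n_amp
        pos += (spb // 4) * 2 * header.n_aux
        pos += 2 * header.n_supply
        pos += 2 * header.num_temp_sensors
        pos += spb * 2 * header.n_adc
        if header.n_dig_in > 0:
            pos += spb * 2
        if header.n_dig_out > 0:
            pos += spb * 2
    return header, data
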