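"""Containers, RHD import and CSV tables."""

import h5py
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from meakit import core_io
from meakit.errors import FormatError, ParameterError, SchemaError, TruncatedFileError

from conftest import write_rhd_v1


class TestRecording:
    def test_defaults_match_acquisition_settings(self):
        rec = core_io.Recording(np.zeros((2, 10), dtype=np.float32))
        assert rec.sampling_rate == 20_000.0
        assert (rec.bandwidth_low, rec.bandwidth_high) == (1.0, 10_000.0)
        assert rec.software_highpass == 5.0
        assert rec.duration == pytest.approx(10 / 20_000)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"sampling_rate": 0.0},
            {"sampling_rate": -1.0},
            {"channel_ids": ["a"]},  # 2 rows, 1 id
            {"channel_ids": ["a", "a"]},
        ],
    )
    def test_invalid_construction(self, kwargs):
        with pytest.raises(ParameterError):
            core_io.Recording(np.zeros((2, 10)), **kwargs)

    def test_time_index_conversion_is_floor_based(self):
        rec = core_io.Recording(np.zeros((1, 100)), sampling_rate=1000.0)
        assert rec.time_to_index(0.0019) == 1
        assert rec.time_to_index(0.002) == 2
        assert rec.index_to_time(2) == pytest.approx(0.002)


class TestElectrodeLayout:
    def test_default_grid_geometry(self, layout60):
        assert len(layout60.positions) == 60
        assert layout60.diameter == 100.0 and layout60.pitch == 700.0
        # corners removed
        for missing in ("11", "18", "81", "88"):
            assert missing not in layout60.positions
        assert layout60.distance("12", "13") == pytest.approx(700.0)

    def test_distinct_positions_required(self):
        with pytest.raises(ParameterError):
            core_io.ElectrodeLayout({"a": (0, 0), "b": (0, 0)})


class TestRhdReader:
    def test_known_codes_scale_to_microvolts(self, tmp_path):
        rng = np.random.default_rng(0)
        codes = rng.integers(0, 2**16, size=(2, 1980), dtype=np.uint16)
        path = write_rhd_v1(tmp_path / "a.rhd", codes)
        rec = core_io.read_rhd(path)
        expected = (codes.astype(np.float32) - 32768) * np.float32(0.195)
        np.testing.assert_array_equal(rec.data, expected)
        assert rec.sampling_rate == 20_000.0
        assert rec.channel_ids == ["A-000", "A-001"]
        assert rec.bandwidth_low == 1.0 and rec.bandwidth_high == 10_000.0

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.rhd"
        p.write_bytes(b"")
        with pytest.raises(FormatError):
            core_io.read_rhd(p)

    def test_bad_magic_names_leading_bytes(self, tmp_path):
        p = tmp_path / "bad.rhd"
        p.write_bytes(b"\xde\xad\xbe\xef" + b"\x00" * 100)
        with pytest.raises(FormatError, match="EFBEADDE"):
            core_io.read_rhd(p)

    def test_v2_files_rejected(self, tmp_path):
        codes = np.zeros((1, 60), dtype=np.uint16)
        p = write_rhd_v1(tmp_path / "v2.rhd", codes, version=(2, 0))
        with pytest.raises(FormatError, match="2.0"):
            core_io.read_rhd(p)

    def test_truncated_block_reports_offset(self, tmp_path):
        codes = np.zeros((2, 120), dtype=np.uint16)
        p = write_rhd_v1(tmp_path / "t.rhd", codes, truncate_bytes=7)
        with pytest.raises(TruncatedFileError) as err:
            core_io.read_rhd(p)
        assert err.value.byte_offset > 0

    def test_container_round_trip_bit_identical(self, tmp_path):
        codes = np.random.default_rng(1).integers(
            0, 2**16, size=(3, 180), dtype=np.uint16
        )
        rec = core_io.read_rhd(write_rhd_v1(tmp_path / "a.rhd", codes))
        core_io.write_container(rec, None, tmp_path / "a.h5")
        rec2, layout = core_io.read_container(tmp_path / "a.h5")
        assert layout is None
        np.testing.assert_array_equal(rec.data, rec2.data)
        assert rec2.sampling_rate == rec.sampling_rate


class TestContainer:
    @given(
        n_ch=st.integers(1, 5),
        n_s=st.integers(1, 50),
        fs=st.floats(1.0, 1e5),
        seed=st.integers(0, 2**16),
    )
    def test_round_trip_identity(self, tmp_path_factory, n_ch, n_s, fs, seed):
        rng = np.random.default_rng(seed)
        rec = core_io.Recording(
            rng.normal(size=(n_ch, n_s)).astype(np.float32),
            sampling_rate=fs,
            bandwidth_low=0.1,
            bandwidth_high=fs / 2,
            software_highpass=5.0,
        )
        path = tmp_path_factory.mktemp("h5") / "r.h5"
        core_io.write_container(rec, None, path)
        rec2, _ = core_io.read_container(path)
        np.testing.assert_array_equal(rec.data, rec2.data)
        for f in ("sampling_rate", "bandwidth_low", "bandwidth_high",
                  "software_highpass", "t0", "channel_ids"):
            assert getattr(rec, f) == getattr(rec2, f)

    def test_layout_round_trip(self, tmp_path, layout60):
        rec = core_io.Recording(np.zeros((60, 4), dtype=np.float32))
        core_io.write_container(rec, layout60, tmp_path / "r.h5")
        _, layout2 = core_io.read_container(tmp_path / "r.h5")
        assert layout2.positions == layout60.positions
        assert layout2.pitch == layout60.pitch
        assert layout2.diameter == layout60.diameter

    def test_per_channel_rms_preserved(self, small_sim, tmp_path, layout60):
        _, rec, _ = small_sim
        core_io.write_container(rec, layout60, tmp_path / "r.h5")
        rec2, _ = core_io.read_container(tmp_path / "r.h5")
        rms = np.sqrt(np.mean(rec.data.astype(float) ** 2, axis=1))
        rms2 = np.sqrt(np.mean(rec2.data.astype(float) ** 2, axis=1))
        np.testing.assert_array_equal(rms, rms2)

    def test_missing_sampling_rate_is_schema_error(self, tmp_path):
        rec = core_io.Recording(np.zeros((1, 4), dtype=np.float32))
        path = tmp_path / "r.h5"
        core_io.write_container(rec, None, path)
        with h5py.File(path, "a") as f:
            del f["recording/data"].attrs["sampling_rate_hz"]
        with pytest.raises(SchemaError, match="sampling_rate_hz"):
            core_io.read_container(path)


class TestCsvTables:
    def test_default_grid_pitch_inferred(self, tmp_path, layout60):
        path = tmp_path / "layout.csv"
        core_io.write_layout_csv(layout60, path)
        layout = core_io.read_layout_csv(path)
        assert len(layout.positions) == 60
        assert layout.pitch == pytest.approx(700.0)
        assert layout.positions == layout60.positions

    def test_duplicate_electrode_id_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "electrode_id,x_um,y_um\n12,0,0\n13,700,0\n12,1400,0\n"
        )
        with pytest.raises(SchemaError, match="12"):
            core_io.read_layout_csv(path)

    def test_non_numeric_coordinate_names_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("electrode_id,x_um,y_um\n12,0,0\n13,oops,0\n")
        with pytest.raises(SchemaError, match="row 3"):
            core_io.read_layout_csv(path)

    def test_spike_table_round_trip(self, tmp_path):
        from meakit.detect import SpikeEvent, SpikeTrain

        events = [
            SpikeEvent("12", 0.1, -120.5),
            SpikeEvent("12", 0.6, -90.25),
        ]
        trains = [
            SpikeTrain("12", events, 1.0),
            SpikeTrain("13", [SpikeEvent("13", 0.35, -150.0)], 1.0),
        ]
        path = tmp_path / "spikes.csv"
        core_io.write_spike_table(trains, path)
        df = core_io.read_spike_table(path)
        assert list(df["electrode_id"]) == ["12", "13", "12"]
        assert list(df["t_s"]) == [0.1, 0.35, 0.6]
        assert list(df["amplitude_uV"]) == [-120.5, -150.0, -90.25]

    def test_spike_table_requires_columns(self, tmp_path):
        path = tmp_path / "s.csv"
        pd.DataFrame({"electrode_id": ["12"], "time": [0.1]}).to_csv(
            path, index=False
        )
        with pytest.raises(SchemaError, match="t_s"):
            core_io.read_spike_table(path)
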