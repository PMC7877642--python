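"""Data model, I/O round-trips, frame subsampling and segment geometry."""

import numpy as np
import pytest

from gutmotion import (
    DiameterMatrix,
    read_diameter_matrix,
    write_diameter_matrix,
    subsample_frames,
    slice_time,
    partition_segments,
    render_st_map,
)
from gutmotion.diameter_map import FormatError, segment_of_position


class TestDiameterMatrix:
    def test_identity_invariants(self, small_dm):
        assert small_dm.intestine_length_mm == 3.0
        assert small_dm.n_positions == 3 and small_dm.n_frames == 3
        assert np.allclose(small_dm.positions_mm, [0.5, 1.5, 2.5])

    @pytest.mark.parametrize("bad", [
        dict(values=np.full((3, 3), -1.0)),
        dict(values=np.full((3, 1), 5.0)),
        dict(values=np.full((3, 3), np.nan)),
        dict(values=np.full((3, 3), 5.0), frame_interval_s=0.0),
        dict(values=np.full((3, 3), 5.0), intestine_length_mm=10.0),
        dict(values=np.full((3, 3), 5.0), treatment="nonsense"),
    ])
    def test_invalid_matrices_rejected(self, bad):
        kw = dict(position_spacing_mm=1.0, frame_interval_s=1.0)
        kw.update(bad)
        with pytest.raises(ValueError):
            DiameterMatrix(**kw)


class TestRoundTrip:
    def test_tsv_round_trip(self, small_dm, tmp_path):
        path = tmp_path / "m.tsv"
        write_diameter_matrix(small_dm, path)
        back = read_diameter_matrix(path)
        assert np.array_equal(back.values, small_dm.values)
        assert back.position_spacing_mm == small_dm.position_spacing_mm
        assert back.frame_interval_s == small_dm.frame_interval_s
        assert back.t0_offset_s == small_dm.t0_offset_s
        assert back.preparation_id == small_dm.preparation_id
        assert back.treatment == small_dm.treatment

    def test_generated_matrix_round_trip(self, tmp_path, cellulose_params):
        from gutmotion.synthetic_data import draw_preparation, render_preparation

        truth = draw_preparation(cellulose_params, "rt", np.random.SeedSequence(5),
                                 horizon_s=900.0, length_mm=55.0)
        dm = render_preparation(truth, frame_rate=0.35)
        path = tmp_path / "gen.tsv"
        write_diameter_matrix(dm, path)
        back = read_diameter_matrix(path)
        assert np.allclose(back.values, dm.values, atol=1e-9)

    def test_missing_sidecar_is_format_error(self, small_dm, tmp_path):
        path = tmp_path / "m.tsv"
        np.savetxt(path, small_dm.values, delimiter="\t")
        with pytest.raises(FormatError):
            read_diameter_matrix(path)

    def test_negative_cell_is_validation_error(self, small_dm, tmp_path):
        path = tmp_path / "m.tsv"
        write_diameter_matrix(small_dm, path)
        vals = small_dm.values.copy()
        vals[1, 1] = -0.5
        np.savetxt(path, vals, delimiter="\t")
        with pytest.raises(ValueError):
            read_diameter_matrix(path)


class TestSubsampleFrames:
    def test_stride_ten_gives_validated_rate(self):
        dm = DiameterMatrix(np.ones((4, 35)) * 5, 1.0, 1 / 3.5)
        out = subsample_frames(dm, 10)
        assert out.n_frames == 4
        assert out.frame_rate == pytest.approx(0.35)
        assert out.t0_offset_s == dm.t0_offset_s

    def test_stride_one_is_identity(self, small_dm):
        out = subsample_frames(small_dm, 1)
        assert np.array_equal(out.values, small_dm.values)
        assert out.frame_interval_s == small_dm.frame_interval_s

    def test_stride_three_gives_motility_rate(self):
        dm = DiameterMatrix(np.ones((4, 36)) * 5, 1.0, 1 / 3.5)
        out = subsample_frames(dm, 3)
        assert out.frame_interval_s == pytest.approx(3 / 3.5)
        assert out.frame_rate == pytest.approx(3.5 / 3)

    @pytest.mark.parametrize("a,b", [(2, 3), (5, 2), (1, 7)])
    def test_composition(self, a, b):
        rng = np.random.default_rng(0)
        dm = DiameterMatrix(rng.uniform(2, 6, (5, 64)), 1.0, 1.0)
        lhs = subsample_frames(dm, a * b)
        rhs = subsample_frames(subsample_frames(dm, a), b)
        assert np.array_equal(lhs.values, rhs.values)
        assert lhs.frame_interval_s == rhs.frame_interval_s

    def test_bad_stride(self, small_dm):
        with pytest.raises(ValueError):
            subsample_frames(small_dm, 0)


class TestPartitionSegments:
    def test_default_boundaries_100mm(self):
        dm = DiameterMatrix(np.ones((100, 2)) * 5, 1.0, 1.0)
        part = partition_segments(dm)
        assert part.boundaries_mm == pytest.approx((0, 39, 62, 85, 100))

    def test_segment1_is_39pct_of_70mm(self):
        dm = DiameterMatrix(np.ones((280, 2)) * 5, 0.25, 1.0)
        part = partition_segments(dm)
        assert part.boundaries_mm[1] == pytest.approx(0.39 * 70.0)
        assert part.segment_length_mm(1) == pytest.approx(27.3)

    def test_bad_fractions_rejected(self, small_dm):
        with pytest.raises(ValueError):
            partition_segments(small_dm, (1.0, 0.0, 0.0, 0.0))
        with pytest.raises(ValueError):
            partition_segments(small_dm, (0.5, 0.2, 0.2, 0.2))

    def test_total_and_exclusive(self):
        dm = DiameterMatrix(np.ones((173, 2)) * 5, 0.37, 1.0)
        part = partition_segments(dm)
        counts = np.zeros(dm.n_positions, dtype=int)
        for seg in range(1, 5):
            sl = part.segment_slice(seg)
            counts[sl] += 1
        assert np.all(counts == 1)
        for x in np.linspace(0, dm.intestine_length_mm - 1e-6, 57):
            seg = segment_of_position(part, x)
            assert part.boundaries_mm[seg - 1] <= x < part.boundaries_mm[seg]


class TestSliceTime:
    def test_half_open_selection(self):
        dm = DiameterMatrix(np.tile(np.arange(10.0) + 1, (3, 1)), 1.0, 1.0)
        out = slice_time(dm, 2.0, 6.0)
        assert out.n_frames == 4
        assert out.t0_offset_s == 2.0
        assert np.array_equal(out.values[0], [3, 4, 5, 6])

    def test_too_short_slice_rejected(self, small_dm):
        with pytest.raises(ValueError):
            slice_time(small_dm, 0.0, 0.5)


class TestRenderStMap:
    def test_render_is_deterministic(self, small_dm, tmp_path):
        p1, p2 = tmp_path / "a.png", tmp_path / "b.png"
        render_st_map(small_dm, p1)
        render_st_map(small_dm, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_constant_matrix_gives_uniform_interior(self, small_dm, tmp_path):
        from PIL import Image

        out = tmp_path / "c.png"
        render_st_map(small_dm, out)
        img = np.asarray(Image.open(out).convert("RGB"), dtype=int)
        # the data panel occupies the image centre; a constant field maps
        # to a single colour there
        h, w, _ = img.shape
        panel = img[h // 2 - 10:h // 2 + 10, w // 3:w // 2]
        assert panel.std(axis=(0, 1)).max() < 1.0
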