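"""Per-VOI offsets, clamped standardization, delay invariance, thresholds."""

import numpy as np
import pytest

import tdcperf as tp
from tdcperf.preprocessing import TtpMap, smooth_curves, detect_first_pass_window, compute_ttp_map
from tdcperf.standardization import (
    voi_offsets,
    standardize,
    exclude_low_zf,
    threshold_map,
    stdz_threshold_volume,
    voi_labels,
    VoiStandardizer,
    ThresholdSpec,
    FIXED_THRESHOLDS,
)
from tdcperf.tdc import empirical_quantile


def _ttp_from_frames(frames, tr=1.0):
    frames = np.asarray(frames)
    return TtpMap(frames=frames, tr=tr, defined_mask=frames >= 0)


def _ttp_map(phantom, smoothing=3):
    series, truth = phantom
    sm = smooth_curves(series, smoothing)
    win = detect_first_pass_window(sm, truth.brain_mask, baseline_frames=8)
    return compute_ttp_map(sm, win, truth.brain_mask)


class TestOffsets:
    def test_constant_voi_offset_is_the_constant(self):
        frames = np.full((10, 10, 1), 9)
        offs = voi_offsets(_ttp_from_frames(frames, tr=0.689), p=0.03)
        assert offs.offset(0) == pytest.approx(9 * 0.689)

    def test_matches_shared_quantile_oracle(self):
        rng = np.random.default_rng(2)
        frames = rng.integers(5, 40, size=(10, 10, 1))
        ttp = _ttp_from_frames(frames, tr=1.0)
        offs = voi_offsets(ttp, p=0.03)
        assert offs.offset(0) == pytest.approx(empirical_quantile(frames.ravel().astype(float), 0.03))

    def test_small_voi_inherits_global_offset(self):
        frames = np.full((10, 10, 2), 12)
        frames[:, :, 1] = -1
        frames[0, 0, 1] = 20  # a single defined voxel: too few for p=0.03
        ttp = _ttp_from_frames(frames)
        offs = voi_offsets(ttp, p=0.03)
        assert offs.entries[1].fallback
        assert not offs.entries[0].fallback
        # fallback equals the whole-brain quantile
        all_frames = frames[frames >= 0].astype(float)
        assert offs.offset(1) == pytest.approx(empirical_quantile(all_frames, 0.03))

    def test_no_qualifying_voi_raises(self):
        frames = np.full((2, 2, 2), -1)
        frames[0, 0, 0] = 5
        with pytest.raises(ValueError, match="VOI"):
            voi_offsets(_ttp_from_frames(frames), p=0.03)

    def test_offset_table_csv(self, tmp_path):
        frames = np.full((10, 10, 2), 9)
        offs = voi_offsets(_ttp_from_frames(frames), p=0.03)
        path = tmp_path / "offsets.csv"
        offs.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert set(df["voi_id"]) == {0, 1}
        assert (df["p"] == 0.03).all()


class TestStandardize:
    def test_clamp_below_and_at_offset(self):
        # slice of values 0..99: offset = 2.97; values below/at offset -> 0
        frames = np.arange(100).reshape(10, 10, 1)
        ttp = _ttp_from_frames(frames)
        offs = voi_offsets(ttp, p=0.03)
        std = standardize(ttp, offs)
        assert std.values[0, 0, 0] == 0.0  # ttp 0 < offset
        assert std.values[0, 2, 0] == 0.0  # ttp 2 < offset 2.97
        assert std.values[0, 3, 0] == pytest.approx(3 - 2.97)
        assert np.all(std.values[np.isfinite(std.values)] >= 0)

    def test_per_slice_shift_cancels_bit_identically(self, phantom):
        ttp = _ttp_map(phantom)
        std_a = standardize(ttp, voi_offsets(ttp, p=0.03))
        shifts = np.array([3, 0, 7, 1, 5, 2, 9, 4])
        shifted = TtpMap(
            frames=np.where(ttp.defined_mask, ttp.frames + shifts[None, None, :], -1),
            tr=ttp.tr,
            defined_mask=ttp.defined_mask,
        )
        std_b = standardize(shifted, voi_offsets(shifted, p=0.03))
        assert np.array_equal(std_a.values, std_b.values, equal_nan=True)

    def test_ordering_preserved_within_voi(self, phantom):
        ttp = _ttp_map(phantom)
        std = standardize(ttp, voi_offsets(ttp, p=0.03))
        z = 3
        sel = ttp.defined_mask[:, :, z]
        order_in = np.argsort(ttp.frames[:, :, z][sel], kind="stable")
        order_out = np.argsort(std.values[:, :, z][sel], kind="stable")
        # clamped zeros tie; compare above-offset voxels only
        above = std.values[:, :, z][sel] > 0
        assert np.all(np.diff(std.values[:, :, z][sel][order_in][above[order_in]]) >= 0)
        assert order_out.size == order_in.size

    def test_clamped_fraction_approaches_p(self, phantom):
        # on the phantom (discrete, heavily tied TTP) the clamp absorbs at
        # least the offset tail ...
        ttp = _ttp_map(phantom)
        std = standardize(ttp, voi_offsets(ttp, p=0.03))
        vals = std.values[np.isfinite(std.values)]
        assert np.mean(vals == 0.0) >= 0.03
        # ... and approaches p exactly as the TTP distribution becomes
        # continuous (here: thousands of distinct frame values)
        rng = np.random.default_rng(6)
        frames = rng.integers(0, 100_000, size=(100, 100, 1))
        fine = _ttp_from_frames(frames, tr=1e-3)
        std_fine = standardize(fine, voi_offsets(fine, p=0.03))
        frac = np.mean(std_fine.values[np.isfinite(std_fine.values)] == 0.0)
        assert frac == pytest.approx(0.03, abs=0.005)

    def test_missing_voi_rejected(self):
        frames = np.full((10, 10, 2), 9)
        ttp = _ttp_from_frames(frames)
        offs = voi_offsets(ttp, p=0.03)
        del offs.entries[1]
        with pytest.raises(ValueError, match="VOIs"):
            standardize(ttp, offs)

    def test_estimator_wrapper_equivalent(self, phantom):
        ttp = _ttp_map(phantom)
        direct = standardize(ttp, voi_offsets(ttp, p=0.03))
        est = VoiStandardizer(p=0.03)
        wrapped = est.fit_transform(ttp)
        assert np.array_equal(direct.values, wrapped.values, equal_nan=True)
        assert est.get_params() == {"p": 0.03}


class TestStdZ:
    def test_low_zf_excluded_then_standardized_nonnegative(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 1, size=(20, 20, 2))
        vals[0, 0, 0] = -5.0  # below the [-3, +inf) inclusion interval
        zmap = tp.ParameterMap(name="z_f", values=vals)
        incl = exclude_low_zf(zmap)
        assert np.isnan(incl.values[0, 0, 0])
        offs = voi_offsets(incl, p=0.02275)
        std = standardize(incl, offs)
        assert std.name == "stdZ"
        assert np.isnan(std.values[0, 0, 0])
        finite = std.values[np.isfinite(std.values)]
        assert np.all(finite >= 0)

    def test_stdz_threshold_volume_clamped(self):
        vals = np.tile(np.linspace(-1, 3, 100).reshape(10, 10, 1), (1, 1, 2))
        zmap = tp.ParameterMap(name="z_f", values=vals)
        offs = voi_offsets(zmap, p=0.02275)
        thr = stdz_threshold_volume(0.5, offs, vals.shape)
        for z in (0, 1):
            assert np.allclose(thr[:, :, z], max(0.0, 0.5 - offs.offset(z)))


class TestThresholding:
    def test_published_thresholds_fixed(self):
        assert FIXED_THRESHOLDS["Tmax"].value == 6.0
        assert FIXED_THRESHOLDS["stdTTP"].value == 7.0

    def test_stdttp_seven_second_rule(self):
        vals = np.array([[[5.0, 7.0], [7.1, np.nan]]])
        pmap = tp.ParameterMap(name="stdTTP", values=vals)
        mask = threshold_map(pmap, FIXED_THRESHOLDS["stdTTP"])
        assert mask.values.tolist() == [[[False, True], [True, False]]]

    def test_all_zero_map_empty_mask(self):
        pmap = tp.ParameterMap(name="stdTTP", values=np.zeros((4, 4, 2)))
        assert threshold_map(pmap, 7.0).n_voxels == 0

    def test_parameter_mismatch_rejected(self):
        pmap = tp.ParameterMap(name="stdTTP", values=np.zeros((4, 4, 2)))
        with pytest.raises(ValueError, match="stdTTP"):
            threshold_map(pmap, FIXED_THRESHOLDS["Tmax"])

    def test_threshold_spec_unit_consistency(self):
        with pytest.raises(ValueError, match="units"):
            ThresholdSpec("stdTTP", 7.0, "dimensionless", "fixed")

    def test_phantom_lesion_recovered_at_seven_seconds(self, phantom):
        series, truth = phantom
        ttp = _ttp_map(phantom)
        std = standardize(ttp, voi_offsets(ttp, p=0.03))
        pred = threshold_map(std, 7.0)
        inter = np.sum(pred.values & truth.lesion_mask.values)
        union = np.sum(pred.values | truth.lesion_mask.values)
        assert inter / union >= 0.9
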