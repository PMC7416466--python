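"""Median+2SD thresholding, area-fraction quantification, associations."""
import numpy as np
import pytest
from scipy import stats as sps

from enrichtraj.histology import (
    BehaviorRecord,
    TwoChannelImage,
    aggregate_by_animal,
    associate,
    count_blobs,
    quantify,
    read_two_channel_image,
    threshold_channel,
    write_two_channel_image,
)
from enrichtraj.synthetic import generate_images


class TestThreshold:
    def test_constant_image_empty_mask(self):
        mask, thr = threshold_channel(np.full((32, 32), 7.0))
        assert mask.sum() == 0
        assert thr == pytest.approx(7.0)

    def test_threshold_matches_independent_one_pass(self):
        rng = np.random.default_rng(0)
        img = rng.normal(10, 2, (64, 64))
        _, thr = threshold_channel(img)
        flat = np.sort(img.ravel())
        n = flat.size
        med = (flat[n // 2 - 1] + flat[n // 2]) / 2 if n % 2 == 0 else flat[n // 2]
        sd = np.sqrt(np.mean((flat - flat.mean()) ** 2))  # population definition
        assert thr == pytest.approx(med + 2 * sd, abs=1e-9)

    def test_painted_blob_recovered(self):
        image, vmask, smask = generate_images(0.1, 0.02, shape=(128, 128), rng_seed=1)
        got, _ = threshold_channel(image.vessel_channel)
        mismatch = np.mean(got != vmask)
        assert mismatch < 0.01
        got_s, _ = threshold_channel(image.stain_channel)
        assert np.mean(got_s != smask) < 0.01


class TestQuantify:
    def test_generator_truth_ten_percent(self):
        # ~1000 vessel px vs ~100 stain px on a 100x100 grid
        image, vmask, smask = generate_images(0.1, 0.01, shape=(100, 100), rng_seed=2)
        rec = quantify(image, image_id="img1")
        assert rec.vessel_area_px == int(vmask.sum())
        assert rec.stain_area_px == int(smask.sum())
        assert rec.pct_positive == pytest.approx(10.0, rel=0.01)

    def test_zero_stain(self):
        # noise-free background: nothing painted means a constant stain
        # channel, an empty mask, and a zero area ratio
        image, _, smask = generate_images(
            0.1, 0.0, shape=(64, 64), rng_seed=3, background_sd=0.0
        )
        assert smask.sum() == 0
        assert quantify(image).pct_positive == 0.0

    def test_stain_equals_vessel_mask_is_100(self):
        image, vmask, _ = generate_images(0.1, 0.0, shape=(64, 64), rng_seed=4)
        same = TwoChannelImage(image.vessel_channel, image.vessel_channel.copy())
        rec = quantify(same)
        assert rec.pct_positive == pytest.approx(100.0)

    def test_zero_vessel_flagged_undefined(self):
        rng = np.random.default_rng(5)
        image = TwoChannelImage(
            np.full((16, 16), 3.0), rng.normal(10, 1, (16, 16)).clip(0)
        )
        rec = quantify(image)
        assert rec.undefined and np.isnan(rec.pct_positive)

    def test_rotation_and_translation_invariance(self):
        image, _, _ = generate_images(0.15, 0.03, shape=(64, 64), rng_seed=6)
        base = quantify(image)
        rot = TwoChannelImage(
            np.rot90(image.vessel_channel), np.rot90(image.stain_channel)
        )
        rolled = TwoChannelImage(
            np.roll(image.vessel_channel, 7, axis=1),
            np.roll(image.stain_channel, 7, axis=1),
        )
        for variant in (rot, rolled):
            rec = quantify(variant)
            assert rec.vessel_area_px == base.vessel_area_px
            assert rec.stain_area_px == base.stain_area_px
            assert rec.pct_positive == pytest.approx(base.pct_positive)

    def test_pct_scales_linearly_with_stain_area(self):
        pcts = []
        for frac in (0.01, 0.02, 0.04):
            image, _, _ = generate_images(0.2, frac, shape=(100, 100), rng_seed=7)
            pcts.append(quantify(image).pct_positive)
        assert pcts[1] == pytest.approx(2 * pcts[0], rel=0.02)
        assert pcts[2] == pytest.approx(4 * pcts[0], rel=0.02)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            TwoChannelImage(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_count_blobs(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[2:5, 2:5] = True
        mask[10:12, 10:15] = True
        assert count_blobs(mask) == 2
        assert count_blobs(mask, min_size=10) == 1


class TestBehaviorRecord:
    def test_si_quotient_definition(self):
        rec = BehaviorRecord("m1", "HC", 120.0, 60.0, 20)
        assert rec.si_quotient == pytest.approx(2.0)

    def test_zero_empty_time_is_undefined(self):
        rec = BehaviorRecord("m1", "HC", 120.0, 0.0, 20)
        assert np.isnan(rec.si_quotient)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            BehaviorRecord("m1", "HC", -1.0, 5.0, 2)


class TestAssociate:
    def behavior(self, ys, field="si_quotient"):
        recs = []
        for i, y in enumerate(ys):
            if field == "si_quotient":
                recs.append(BehaviorRecord(f"m{i}", "CSD", y * 10.0, 10.0, 5))
            else:
                recs.append(BehaviorRecord(f"m{i}", "CSD", 10.0, 10.0, int(y)))
        return recs

    def test_perfect_negative_fit(self):
        x = {f"m{i}": float(i) for i in range(6)}
        recs = self.behavior([-2 * i + 10 for i in range(6)])
        res = associate(x, recs)
        assert res.pearson_r == pytest.approx(-1.0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(-2.0)
        assert res.p_pearson < 1e-8

    def test_r_squared_equals_pearson_squared(self):
        rng = np.random.default_rng(1)
        x = {f"m{i}": float(v) for i, v in enumerate(rng.normal(size=20))}
        recs = self.behavior(rng.normal(2, 0.5, size=20))
        res = associate(x, recs)
        assert res.r_squared == pytest.approx(res.pearson_r**2, abs=1e-9)
        assert res.f_stat == pytest.approx(res.pearson_r**2 / (1 - res.pearson_r**2) * (res.n - 2), rel=1e-6)

    def test_planted_slope_recovered_without_bias(self):
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            xv = rng.normal(0, 1, 100)
            yv = -0.5 * xv + 1.0 + rng.normal(0, 0.1, 100)
            x = {f"m{i}": float(v) for i, v in enumerate(xv)}
            recs = [
                BehaviorRecord(f"m{i}", "CSD", max(0.0, y * 10), 10.0, 5)
                for i, y in enumerate(yv)
            ]
            errs.append(associate(x, recs).slope - (-0.5))
        assert abs(float(np.mean(errs))) < 0.05
        assert max(abs(e) for e in errs) < 0.05 * 5  # no wild outliers

    def test_null_p_values_uniform(self):
        ps = []
        for seed in range(300):
            rng = np.random.default_rng(1000 + seed)
            x = {f"m{i}": float(v) for i, v in enumerate(rng.normal(size=20))}
            recs = self.behavior(np.abs(rng.normal(2, 0.5, size=20)))
            ps.append(associate(x, recs).p_regression)
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_zero_variance_x_rejected(self):
        x = {f"m{i}": 1.0 for i in range(5)}
        with pytest.raises(ValueError):
            associate(x, self.behavior([1, 2, 3, 4, 5]))

    def test_too_few_pairs_rejected(self):
        x = {"m0": 1.0, "m1": 2.0}
        with pytest.raises(ValueError):
            associate(x, self.behavior([1, 2]))

    def test_undefined_si_excluded(self):
        x = {f"m{i}": float(i) for i in range(5)}
        recs = self.behavior([1, 2, 3, 4, 5])
        recs[0] = BehaviorRecord("m0", "CSD", 10.0, 0.0, 5)  # SI undefined
        assert associate(x, recs).n == 4


class TestAggregationAndIO:
    def test_aggregate_mean_over_sections(self):
        from enrichtraj.histology import AreaQuantRecord

        recs = [
            AreaQuantRecord("im1", 100, 10, 10.0, 1.0, 1.0),
            AreaQuantRecord("im2", 100, 20, 20.0, 1.0, 1.0),
            AreaQuantRecord("im3", 100, 30, 30.0, 1.0, 1.0),
        ]
        mapping = {"im1": "m1", "im2": "m1", "im3": "m2"}
        agg = aggregate_by_animal(recs, mapping)
        assert agg == {"m1": pytest.approx(15.0), "m2": pytest.approx(30.0)}

    def test_tiff_round_trip(self, tmp_path):
        image, _, _ = generate_images(0.1, 0.02, shape=(32, 32), rng_seed=8)
        write_two_channel_image(image, tmp_path / "im.tif")
        back = read_two_channel_image(tmp_path / "im.tif")
        np.testing.assert_allclose(back.vessel_channel, image.vessel_channel, rtol=1e-6)
        np.testing.assert_allclose(back.stain_channel, image.stain_channel, rtol=1e-6)
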