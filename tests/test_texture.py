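"""Texture families: toy values, symmetries, and brute-force oracles."""

import numpy as np
import pytest

from oracles import brute_com_features, brute_com_matrix, brute_rlm_features, brute_runs
from radiomic.prep import QuantizedROI, compute_norm_params, quantize_roi
from radiomic.registry import COM_OFFSETS, RLM_DIRECTIONS, all_names, family_names
from radiomic.texture import (
    arm_features,
    com_features,
    com_matrix,
    gra_features,
    his_features,
    rlm_features,
    rlm_runs,
    wav_features,
)
from radiomic.extract import extract_all

HARALICK_TOY = np.array(
    [[0, 0, 1, 1], [0, 0, 1, 1], [0, 2, 2, 2], [2, 2, 3, 3]]
) + 1  # gray values 0..3 as levels 1..4

_RLM_STEPS = {"Horzl": (0, 1), "Vertl": (1, 0), "45dgr": (-1, 1), "135dr": (1, 1)}


def _const_roi(value=5, shape=(6, 6), n_levels=8):
    return QuantizedROI.from_levels(np.full(shape, value), n_levels)


class TestHIS:
    def test_four_point_set(self):
        q = QuantizedROI.from_levels(np.array([[1, 2, 3, 4]]), 8)
        f = his_features(q)
        assert f["Mean"] == 2.5 and f["Variance"] == 1.25

    def test_constant_roi_zero_variance_rule(self):
        f = his_features(_const_roi())
        assert f["Variance"] == 0 and f["Skewness"] == 0 and f["Kurtosis"] == 0

    def test_median_of_uniform_levels_against_sort_oracle(self):
        rng = np.random.default_rng(3)
        lv = rng.integers(1, 65, size=1000)
        q = QuantizedROI.from_levels(lv.reshape(40, 25), 64)
        f = his_features(q)
        assert 30 <= f["Perc.50%"] <= 35
        srt = np.sort(lv)
        for pct, name in [(10, "Perc.10%"), (90, "Perc.90%")]:
            oracle = np.percentile(srt, pct)
            assert f[name] == pytest.approx(oracle)


class TestCOM:
    def test_haralick_toy_pair_counts(self):
        q = QuantizedROI.from_levels(HARALICK_TOY, 4)
        m = com_matrix(q, (1, 0))
        assert m.p.sum() == pytest.approx(1.0)
        assert m.p[0, 0] == pytest.approx(4 / 24)
        assert m.p[0, 1] == pytest.approx(2 / 24)
        assert m.p[1, 0] == pytest.approx(2 / 24)
        assert m.p[1, 1] == pytest.approx(4 / 24)

    def test_haralick_toy_contrast(self):
        q = QuantizedROI.from_levels(HARALICK_TOY, 4)
        f = com_features(com_matrix(q, (1, 0)))
        assert f["Contrast"] == pytest.approx(14 / 24)

    def test_constant_roi_single_cell(self):
        m = com_matrix(_const_roi(), (1, 0))
        assert m.p[4, 4] == 1.0
        f = com_features(m)
        assert f["AngScMom"] == 1 and f["Contrast"] == 0
        assert f["Entropy"] == 0 and f["InvDfMom"] == 1

    def test_checkerboard_forced_two_cells(self):
        lv = np.indices((6, 6)).sum(axis=0) % 2 + 1
        q = QuantizedROI.from_levels(lv, 2)
        f = com_features(com_matrix(q, (1, 0)))
        assert f["Contrast"] == pytest.approx(1.0)
        assert f["Entropy"] == pytest.approx(np.log(2))

    def test_rotation_maps_horizontal_to_vertical_offset(self):
        rng = np.random.default_rng(5)
        lv = rng.integers(1, 7, size=(9, 9))
        q = QuantizedROI.from_levels(lv, 6)
        rot = QuantizedROI.from_levels(np.rot90(lv), 6)
        m_h = com_matrix(q, (1, 0))
        m_v = com_matrix(rot, (0, 1))
        np.testing.assert_allclose(m_h.p, m_v.p)

    def test_degenerate_offset_yields_zeros(self):
        q = QuantizedROI.from_levels(np.array([[3]]), 4)
        m = com_matrix(q, (1, 0))
        assert m.degenerate
        assert all(v == 0 for v in com_features(m).values())


class TestRLM:
    def test_toy_row_hand_enumeration(self):
        q = QuantizedROI.from_levels(np.array([[1, 1, 1, 2, 2]]), 4)
        f = rlm_features(q, "Horzl")
        assert f["Horzl_LngREmph"] == pytest.approx(6.5)
        assert f["Horzl_ShrtREmp"] == pytest.approx((1 / 9 + 1 / 4) / 2)
        assert f["Horzl_Fraction"] == pytest.approx(0.4)

    def test_single_run(self):
        n = 7
        q = QuantizedROI.from_levels(np.full((1, n), 3), 4)
        f = rlm_features(q, "Horzl")
        assert f["Horzl_Fraction"] == pytest.approx(1 / n)
        assert f["Horzl_LngREmph"] == pytest.approx(n**2)

    def test_alternating_row_all_unit_runs(self):
        q = QuantizedROI.from_levels(np.array([[1, 2, 1, 2, 1, 2]]), 2)
        f = rlm_features(q, "Horzl")
        assert f["Horzl_Fraction"] == 1
        assert f["Horzl_LngREmph"] == 1
        assert f["Horzl_ShrtREmp"] == 1

    @pytest.mark.parametrize("direction", RLM_DIRECTIONS)
    def test_run_conservation_on_random_masks(self, direction):
        rng = np.random.default_rng(8)
        for _ in range(10):
            lv = rng.integers(1, 5, size=(10, 10))
            mask = rng.random((10, 10)) < 0.6
            q = QuantizedROI.from_levels(np.where(mask, lv, 0), 4, mask=mask)
            runs, traversed = rlm_runs(q, direction)
            assert traversed == mask.sum()
            assert sum(l * r for (_, l), r in runs.items()) == mask.sum()


class TestGRA:
    def test_constant_roi(self):
        f = gra_features(_const_roi())
        assert f["GrMean"] == 0 and f["GrNonZeros"] == 0

    def test_horizontal_ramp_forced_central_difference(self):
        lv = np.tile(np.arange(1, 11), (6, 1))
        q = QuantizedROI.from_levels(lv, 16)
        f = gra_features(q)
        assert f["GrMean"] == pytest.approx(2.0)
        assert f["GrVariance"] == 0 and f["GrNonZeros"] == 1

    def test_random_roi_against_loop_oracle(self):
        rng = np.random.default_rng(13)
        lv = rng.integers(1, 17, size=(16, 16))
        mask = np.ones((16, 16), bool)
        q = QuantizedROI.from_levels(lv, 16, mask=mask)
        f = gra_features(q)
        mags = []
        for r in range(1, 15):
            for c in range(1, 15):
                gx = lv[r, c + 1] - lv[r, c - 1]
                gy = lv[r + 1, c] - lv[r - 1, c]
                mags.append(np.hypot(gx, gy))
        mags = np.array(mags)
        assert f["GrMean"] == pytest.approx(mags.mean())
        assert f["GrVariance"] == pytest.approx(mags.var())
        assert f["GrNonZeros"] == pytest.approx((mags > 0).mean())


class TestARM:
    def test_west_copy_image_minimum_norm_solution(self):
        lv = np.tile(np.arange(1, 11)[:, None], (1, 12))  # rows constant
        q = QuantizedROI.from_levels(lv, 16)
        fit = arm_features(q)
        # pseudoinverse oracle on the same design
        assert fit.sigma == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(fit.theta, [1, 0, 0, 0], atol=1e-9)

    def test_constant_roi_zero_residual(self):
        fit = arm_features(_const_roi(shape=(8, 8)))
        assert fit.sigma == pytest.approx(0.0, abs=1e-9)

    def test_white_noise_small_weights(self):
        rng = np.random.default_rng(21)
        lv = rng.integers(1, 65, size=(100, 100))
        q = QuantizedROI.from_levels(lv, 64)
        fit = arm_features(q)
        assert np.all(np.abs(fit.theta) < 0.05)

    def test_too_few_pixels_degenerate(self):
        q = QuantizedROI.from_levels(np.full((3, 4), 2), 4)
        fit = arm_features(q)
        assert fit.sigma == 0 and (fit.theta == 0).all()


class TestWAV:
    def test_constant_roi_energies(self):
        c = 3
        q = QuantizedROI.from_levels(np.full((4, 4), c), 8)
        w = wav_features(q)
        assert w["WavEnLL_s-1"] == pytest.approx(4 * c * c)
        for sb in ("LH", "HL", "HH"):
            assert w[f"WavEn{sb}_s-1"] == 0

    def test_vertical_stripes_orientation_selectivity(self):
        lv = np.tile(np.array([1, 2] * 4), (8, 1))  # varies along x
        q = QuantizedROI.from_levels(lv, 2)
        w = wav_features(q)
        assert w["WavEnHL_s-1"] > 0
        assert w["WavEnLH_s-1"] == 0

    def test_parseval_bookkeeping(self):
        rng = np.random.default_rng(2)
        lv = rng.integers(1, 9, size=(32, 32))
        q = QuantizedROI.from_levels(lv, 8)
        w = wav_features(q)
        # recompute independently: iterate the orthonormal analysis and sum
        # squared coefficients over counted positions
        block = lv.astype(float)
        support = np.ones((32, 32), bool)
        total_direct = 0.0
        total_from_energies = 0.0
        for scale in range(1, 6):
            p, qq = block[0::2, 0::2], block[0::2, 1::2]
            r, s = block[1::2, 0::2], block[1::2, 1::2]
            subs = {
                "LL": (p + qq + r + s) / 2,
                "HL": (-p + qq - r + s) / 2,
                "LH": (-p - qq + r + s) / 2,
                "HH": (p - qq - r + s) / 2,
            }
            sup = (
                support[0::2, 0::2]
                | support[0::2, 1::2]
                | support[1::2, 0::2]
                | support[1::2, 1::2]
            )
            n_sup = sup.sum()
            for sb, coef in subs.items():
                total_direct += (coef[sup] ** 2).sum()
                total_from_energies += n_sup * w[f"WavEn{sb}_s-{scale}"]
            block, support = subs["LL"], sup
        assert total_from_energies == pytest.approx(total_direct)

    def test_small_roi_missing_scales_zero(self):
        q = QuantizedROI.from_levels(np.full((2, 2), 1), 4)
        w = wav_features(q)
        assert all(w[f"WavEn{sb}_s-{k}"] == 0 for k in (2, 3, 4, 5) for sb in ("LH", "HL", "HH"))


class TestOracleEquivalence:
    """COM/RLM features match direct pair/run enumeration on random lesions."""

    def test_com_oracle_random_images(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            lv = rng.integers(1, 7, size=(8, 8))
            mask = rng.random((8, 8)) < 0.7
            mask[4, 4] = True
            q = QuantizedROI.from_levels(np.where(mask, lv, 0), 6, mask=mask)
            for dx, dy in [(1, 0), (0, 1), (2, 2), (3, -3)]:
                m = com_matrix(q, (dx, dy))
                bp = brute_com_matrix(np.where(mask, lv, 0), mask, dx, dy, 6)
                np.testing.assert_allclose(m.p, bp, atol=1e-12)
                ours = com_features(m)
                if bp.sum() > 0:
                    theirs = brute_com_features(bp)
                    for k, v in theirs.items():
                        assert ours[k] == pytest.approx(v, rel=1e-10, abs=1e-12), k

    def test_rlm_oracle_random_images(self):
        rng = np.random.default_rng(43)
        for _ in range(10):
            lv = rng.integers(1, 5, size=(8, 8))
            mask = rng.random((8, 8)) < 0.7
            mask[4, 4] = True
            q = QuantizedROI.from_levels(np.where(mask, lv, 0), 4, mask=mask)
            for direction, step in _RLM_STEPS.items():
                runs, trav = rlm_runs(q, direction)
                bruns, btrav = brute_runs(np.where(mask, lv, 0), mask, step)
                assert runs == bruns and trav == btrav
                ours = rlm_features(q, direction)
                theirs = brute_rlm_features(bruns, btrav)
                for k, v in theirs.items():
                    assert ours[f"{direction}_{k}"] == pytest.approx(v, rel=1e-10), k


class TestExtractAll:
    def test_full_row_length_and_names(self, smooth_lesion):
        img, mask = smooth_lesion
        row = extract_all(img, mask)
        assert list(row) == all_names()
        assert len(row) == 352
        assert all(np.isfinite(v) for v in row.values())

    def test_family_counts(self):
        sizes = {f: len(family_names(f)) for f in ("HIS", "COM", "RLM", "GRA", "ARM", "WAV", "GEO")}
        assert sizes == {"HIS": 9, "COM": 220, "RLM": 20, "GRA": 5, "ARM": 5, "WAV": 20, "GEO": 73}

    def test_constant_lesion_cross_family_consistency(self, disk_mask):
        img = np.full(disk_mask.shape, 500)
        row = extract_all(img, disk_mask)
        assert row["Variance"] == 0
        assert all(row[f"S({dx},{dy})Contrast"] == 0 for dx, dy in COM_OFFSETS)
        assert row["GrNonZeros"] == 0

    def test_gray_shift_invariance(self, smooth_lesion):
        img, mask = smooth_lesion
        row1 = extract_all(img.astype(np.int64), mask)
        row2 = extract_all(img.astype(np.int64) + 137, mask)
        for k in row1:
            assert row1[k] == pytest.approx(row2[k], rel=1e-9), k

    def test_mirror_lesion_direction_pooled_multisets(self, smooth_lesion):
        """Mirroring swaps the 45/135-degree families consistently."""
        img, mask = smooth_lesion
        row = extract_all(img, mask)
        rowm = extract_all(img[:, ::-1], mask[:, ::-1])
        for d in range(1, 6):
            for stat in ("Contrast", "Entropy", "SumAverg"):
                assert row[f"S({d},{d}){stat}"] == pytest.approx(
                    rowm[f"S({d},-{d}){stat}"], rel=1e-9
                )
                assert row[f"S({d},0){stat}"] == pytest.approx(
                    rowm[f"S({d},0){stat}"], rel=1e-9
                )
        for stat in ("ShrtREmp", "LngREmph", "Fraction"):
            assert row[f"45dgr_{stat}"] == pytest.approx(rowm[f"135dr_{stat}"], rel=1e-9)
            assert row[f"Horzl_{stat}"] == pytest.approx(rowm[f"Horzl_{stat}"], rel=1e-9)
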