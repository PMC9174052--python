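"""Region-wise IDP extraction, lesion contrast, confound regressors."""

import numpy as np
import pytest

from qsmpipe import (
    ParameterError,
    erode_mask_2d,
    extract_subcortical_idps,
    extract_wmh_idp,
    field_gradient_confound,
    regress_out_scalar,
)
from qsmpipe.idp import build_idp_table


class TestErosionAndMedians:
    def test_constant_roi_invariant_to_erosion(self):
        vol = np.zeros((12, 12, 6))
        labels = np.zeros(vol.shape, int)
        labels[2:9, 2:9, 1:5] = 1
        vol[labels == 1] = 50.0
        out = extract_subcortical_idps(vol, labels, {1: "caudate_L"})
        assert out["caudate_L"] == 50.0

    def test_three_wide_roi_erodes_to_spine(self):
        # 3-voxel-wide in-plane strip: 2D 3x3 erosion leaves the 1-voxel spine
        labels = np.zeros((9, 9, 3), int)
        labels[3:6, 1:8, 1] = 1
        expected = np.zeros_like(labels, bool)
        expected[4, 2:7, 1] = True
        np.testing.assert_array_equal(erode_mask_2d(labels == 1), expected)
        vol = np.where(labels == 1, 10.0, 0.0)
        vol[4, 2:7, 1] = [1, 2, 3, 4, 5]  # spine values
        out = extract_subcortical_idps(vol, labels, {1: "putamen_R"})
        assert out["putamen_R"] == 3.0

    def test_substantia_nigra_excludes_negative_without_erosion(self):
        labels = np.zeros((8, 8, 4), int)
        labels[2:6, 2:6, 1] = 1
        vol = np.zeros(labels.shape)
        vol[2:6, 2:4, 1] = 40.0
        vol[2:6, 4:6, 1] = -10.0
        out = extract_subcortical_idps(vol, labels, {1: "substantia_nigra_L"})
        assert out["substantia_nigra_L"] == 40.0
        # with the refinement disabled (T2* convention) the median mixes both
        out2 = extract_subcortical_idps(
            vol, labels, {1: "substantia_nigra_L"}, sn_exclude_negative=False
        )
        assert out2["substantia_nigra_L"] == pytest.approx(15.0)

    def test_empty_after_erosion_is_missing(self):
        labels = np.zeros((6, 6, 3), int)
        labels[2, 2, 1] = 1  # single voxel: erosion clears it
        out = extract_subcortical_idps(np.ones(labels.shape), labels, {1: "thalamus_L"})
        assert np.isnan(out["thalamus_L"])

    def test_invariant_to_other_labels(self):
        rng = np.random.default_rng(0)
        vol = rng.normal(size=(10, 10, 5))
        labels = np.zeros(vol.shape, int)
        labels[1:6, 1:6, 1:4] = 1
        out1 = extract_subcortical_idps(vol, labels, {1: "caudate_L"}, roi_names=["caudate_L"])
        labels2 = labels.copy()
        labels2[7:9, 7:9, :] = 2
        out2 = extract_subcortical_idps(
            vol, labels2, {1: "caudate_L", 2: "pallidum_L"}, roi_names=["caudate_L"]
        )
        assert out1 == out2


class TestWMHContrast:
    def test_arithmetic(self):
        vol = np.zeros((8, 8, 4))
        wm = np.zeros(vol.shape, bool)
        wm[1:7, 1:7, 1:3] = True
        wmh = np.zeros(vol.shape, bool)
        wmh[2:4, 2:4, 1] = True
        vol[wm] = -35.0
        vol[wmh] = -20.0
        assert extract_wmh_idp(vol, wmh, wm) == pytest.approx(15.0)

    def test_constant_map_gives_zero(self):
        wm = np.ones((6, 6, 3), bool)
        wmh = np.zeros(wm.shape, bool)
        wmh[2, 2, 1] = True
        assert extract_wmh_idp(np.full(wm.shape, 7.0), wmh, wm) == 0.0

    def test_reference_offset_cancels(self):
        rng = np.random.default_rng(2)
        vol = rng.normal(size=(8, 8, 4))
        wm = np.zeros(vol.shape, bool)
        wm[1:7, 1:7, :] = True
        wmh = np.zeros(vol.shape, bool)
        wmh[3:5, 3:5, 1:3] = True
        a = extract_wmh_idp(vol, wmh, wm)
        b = extract_wmh_idp(vol - 37.0, wmh, wm)
        assert a == pytest.approx(b)

    def test_empty_wmh_missing_empty_nawm_error(self):
        wm = np.ones((6, 6, 3), bool)
        assert np.isnan(extract_wmh_idp(np.ones(wm.shape), np.zeros(wm.shape, bool), wm))
        with pytest.raises(ParameterError):
            extract_wmh_idp(np.ones(wm.shape), wm, wm)


class TestRegressOutScalar:
    def test_exact_linear_relation_gives_zero_residuals(self):
        vol = np.arange(20.0)
        idp = 2.0 * vol + 1.0
        res = regress_out_scalar(idp, vol)
        np.testing.assert_allclose(res, 0.0, atol=1e-10)

    def test_orthogonal_covariate_gives_centered_idp(self):
        x = np.array([-1.0, 1.0] * 10)
        idp = np.arange(20.0)
        idp = idp - np.polyval(np.polyfit(x, idp, 1), x) + idp.mean()  # r=0 by construction
        res = regress_out_scalar(idp, x)
        np.testing.assert_allclose(res, idp - idp.mean(), atol=1e-9)

    def test_residuals_orthogonal_to_covariate(self):
        rng = np.random.default_rng(3)
        vol = rng.normal(size=200)
        idp = 0.5 * vol + rng.normal(scale=0.2, size=200)
        res = regress_out_scalar(idp, vol)
        r = np.corrcoef(res, vol)[0, 1]
        assert abs(r) < 1e-10

    def test_constant_covariate_warns_and_centers(self):
        idp = np.arange(10.0)
        with pytest.warns(UserWarning):
            res = regress_out_scalar(idp, np.full(10, 3.0))
        np.testing.assert_allclose(res, idp - idp.mean())

    def test_missing_propagates(self):
        idp = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        res = regress_out_scalar(idp, np.arange(5.0))
        assert np.isnan(res[2]) and np.isfinite(res[[0, 1, 3, 4]]).all()


class TestFieldGradientConfound:
    def test_linear_field_gives_slope(self):
        shape = (8, 8, 10)
        z = np.arange(shape[2], dtype=float)
        field = np.broadcast_to(1.7 * z, shape).copy()
        labels = np.zeros(shape, int)
        labels[2:6, 2:6, 2:8] = 1
        out = field_gradient_confound(field, labels, {1: "accumbens_L"})
        assert out["accumbens_L"] == pytest.approx(1.7)

    def test_zero_field_zero_confound(self):
        labels = np.zeros((6, 6, 6), int)
        labels[1:5, 1:5, 1:5] = 1
        out = field_gradient_confound(np.zeros((6, 6, 6)), labels, {1: "caudate_R"})
        assert out["caudate_R"] == 0.0

    def test_deconfounding_removes_gradient_bias(self):
        # inject a T2*-like bias proportional to the per-participant gradient
        rng = np.random.default_rng(4)
        n = 200
        grad = rng.gamma(2.0, 1.0, size=n)
        idp = 40.0 - 3.0 * grad + rng.normal(scale=0.5, size=n)
        res = regress_out_scalar(idp, grad)
        assert abs(np.corrcoef(res, grad)[0, 1]) < 0.05


class TestIDPTable:
    def test_eighteen_idps_per_modality(self):
        rng = np.random.default_rng(5)
        from qsmpipe.phantom import SUBCORTICAL_STRUCTURES

        rows, volumes = {}, {}
        for i in range(5):
            row = {}
            for s in SUBCORTICAL_STRUCTURES:
                for side in ("L", "R"):
                    row[f"qsm_{s}_{side}"] = rng.normal(50, 10)
                    row[f"t2star_{s}_{side}"] = rng.normal(40, 5)
            row["qsm_wmh"] = rng.normal(15, 3)
            row["t2star_wmh"] = rng.normal(5, 1)
            rows[f"sub{i}"] = row
            volumes[f"sub{i}"] = rng.gamma(3.0)
        table = build_idp_table(rows, wmh_volume=volumes, wmh_column="qsm_wmh")
        table = build_idp_table(
            {pid: {**rows[pid], "qsm_wmh_volreg": table.loc[pid, "qsm_wmh_volreg"]}
             for pid in rows},
            wmh_volume=volumes, wmh_column="t2star_wmh",
        )
        qsm_cols = [c for c in table.columns if c.startswith("qsm_")]
        t2_cols = [c for c in table.columns if c.startswith("t2star_")]
        assert len(qsm_cols) == 18
        assert len(t2_cols) == 18
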