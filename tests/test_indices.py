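"""Index arithmetic, diagnosis boundaries, correlation and ROC cut-offs."""

import numpy as np
import pandas as pd
import pytest

from lsmunet.indices import (
    build_index_table,
    correlate,
    cutoff_table,
    derive_cutoff,
    diagnose_l3smi,
    find_diagnostic_boundary,
    mean_cross_sectional_area,
    pearson_r,
    smi,
)
from lsmunet.ioprep import LabelVolume, MUSCLE_CLASSES


class TestAreas:
    def test_unit_conversion(self):
        # 100 voxels per slice over 4 slices at 0.8 mm -> 0.64 cm^2
        lab = np.zeros((4, 20, 20), dtype=np.int64)
        lab[:, 0, :] = 1
        lab[:, 1, :] = 1
        lab[:, 2, :] = 1
        lab[:, 3, :] = 1
        lab[:, 4, :20] = 1  # 100 voxels per slice total
        areas = mean_cross_sectional_area(lab, (5.0, 0.8, 0.8), 4)
        assert areas[1] == pytest.approx(100 * 0.64 / 100)

    def test_empty_region_zero(self):
        lab = np.zeros((2, 4, 4), dtype=np.int64)
        lab[:, 0, 0] = 1
        areas = mean_cross_sectional_area(lab, (5.0, 1.0, 1.0), 2)
        assert areas[2] == 0.0

    def test_matches_phantom_bookkeeping(self, small_case):
        _, labels, meta = small_case
        areas = mean_cross_sectional_area(labels)
        assert areas == meta.true_region_areas_cm2

    def test_padded_slices_excluded(self):
        lab = np.zeros((4, 4, 4), dtype=np.int64)
        lab[:2, 1, 1] = 1
        lab[2:, :, :] = 1  # padding garbage, must be ignored
        a2 = mean_cross_sectional_area(lab, (5.0, 1.0, 1.0), 2)
        assert a2[1] == pytest.approx(1 * 1.0 / 100)

    def test_zero_true_slices_rejected(self):
        with pytest.raises(ValueError):
            mean_cross_sectional_area(np.zeros((2, 2, 2), int), (5, 1, 1), 0)


class TestSmi:
    def test_examples(self):
        assert smi(45.0, 1.5) == pytest.approx(20.0)
        assert smi(0.0, 1.8) == 0.0
        assert smi(33.3, 1.0) == pytest.approx(33.3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            smi(10.0, 0.0)
        with pytest.raises(ValueError):
            smi(-1.0, 1.7)


class TestDiagnosis:
    @pytest.mark.parametrize(
        "value,sex,expected",
        [
            (49.9, "male", "sarcopenia"),
            (50.0, "male", "non-sarcopenia"),
            (38.9, "female", "sarcopenia"),
            (39.0, "female", "non-sarcopenia"),
        ],
    )
    def test_cutoffs_and_boundary_policy(self, value, sex, expected):
        assert diagnose_l3smi(value, sex) == expected

    def test_unknown_sex(self):
        with pytest.raises(ValueError):
            diagnose_l3smi(40.0, "unknown")

    def test_bisection_recovers_boundaries(self):
        assert find_diagnostic_boundary("male") == pytest.approx(50.0, abs=1e-6)
        assert find_diagnostic_boundary("female") == pytest.approx(39.0, abs=1e-6)


class TestCorrelation:
    def test_perfect_linear(self):
        x = np.arange(5, dtype=float)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_matches_direct_formula(self, rng):
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        xm, ym = x - x.mean(), y - y.mean()
        ref = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
        assert pearson_r(x, y) == pytest.approx(ref, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            pearson_r([1.0, 2.0], [1.0, 2.0])


class TestDeriveCutoff:
    def test_perfect_separation(self):
        vals = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        y = np.array([True, True, True, False, False, False])
        res = derive_cutoff(vals, y)
        assert res.auc == 1.0 and res.accuracy == 1.0
        assert 3.0 < res.cutoff < 10.0

    def test_no_signal_auc_near_half(self, rng):
        vals = rng.normal(size=2000)
        y = rng.uniform(size=2000) < 0.5
        res = derive_cutoff(vals, y)
        assert res.auc == pytest.approx(0.5, abs=0.05)

    def test_auc_equals_mann_whitney_identity(self, rng):
        for _ in range(30):
            vals = np.round(rng.normal(size=8), 1)  # ties likely
            y = rng.uniform(size=8) < 0.5
            if y.all() or not y.any():
                continue
            res = derive_cutoff(vals, y)
            pos, neg = vals[y], vals[~y]
            conc = sum(
                1.0 if p < n else (0.5 if p == n else 0.0) for p in pos for n in neg
            )
            assert res.auc == pytest.approx(conc / (len(pos) * len(neg)), abs=1e-12)

    def test_matches_sklearn_auc(self, rng):
        from sklearn.metrics import roc_auc_score

        vals = rng.normal(size=50)
        y = rng.uniform(size=50) < 0.4
        res = derive_cutoff(vals, y)
        # low value indicates disease -> score is the negated index
        assert res.auc == pytest.approx(roc_auc_score(y, -vals), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            derive_cutoff([1.0, 2.0], [True, True])

    def test_recovers_planted_threshold(self, rng):
        # plant: sarcopenic iff value < 7 plus small label noise-free margin
        vals = np.concatenate([rng.uniform(2, 6.5, 40), rng.uniform(7.5, 12, 40)])
        y = vals < 7.0
        res = derive_cutoff(vals, y)
        assert 6.5 <= res.cutoff <= 7.5
        assert res.auc == 1.0


@pytest.fixture(scope="module")
def table():
    rows = []
    segs = {}
    for i in range(12):
        pid = f"p{i:03d}"
        lab = np.zeros((4, 32, 32), dtype=np.int64)
        # muscle blocks scale with a per-patient factor; at 8 mm pixels
        # and height 1.6 m the resulting L3SMI is 7*f, spanning both
        # sides of each sex-specific cut-off
        f = 2 + (i % 4) * 3
        lab[:, 1 : 1 + f, 2:12] = 1
        lab[:, 8 : 8 + f, 2:6] = 2
        lab[:, 8 : 8 + f, 10:14] = 3
        lab[:, 16 : 16 + f, 2:12] = 4
        segs[pid] = LabelVolume(lab, (5.0, 8.0, 8.0), 4, pid)
        rows.append(
            {
                "patient_id": pid,
                "sex": "female" if i % 2 else "male",
                "height_m": 1.6,
            }
        )
    return build_index_table(segs, pd.DataFrame(rows))

def test_tpi_is_sum_of_psoas_indices(table):
    np.testing.assert_allclose(table.tpi, table.rpi + table.lpi, atol=1e-12)

def test_l3smi_dominates_regional_indices(table):
    for col in ("rai", "rpi", "lpi", "pi", "tpi"):
        assert (table.l3smi >= table[col] - 1e-12).all()

def test_scale_equivariance(table):
    h = table.height_m.to_numpy()
    area = table.area_cm2_total.to_numpy()
    np.testing.assert_allclose(table.l3smi, area / h**2, atol=1e-12)

def test_correlate_layout(table):
    corr = correlate(table)
    assert list(corr["group"]) == [
        "sarcopenia", "non-sarcopenia", "female", "male", "all",
    ]
    row_all = corr[corr.group == "all"].iloc[0]
    for col in ("rai", "rpi", "lpi", "pi", "tpi"):
        assert -1.0 <= row_all[col] <= 1.0

def test_cutoff_table_layout(table):
    result = cutoff_table(table)
    assert set(result["sex"]) == {"female", "male"}
    assert len(result) == 10
    assert ((result.auc >= 0) & (result.auc <= 1)).all()
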