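"""Initial rates, Lineweaver-Burk and direct Michaelis-Menten fits."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from udgx.exceptions import InsufficientDataError, KineticsFitError
from udgx.kinetics import (
    DEFAULT_S_GRID_NM,
    REFERENCE_KINETICS,
    KineticsDataset,
    MichaelisMentenModel,
    TimeCourse,
    fold_change,
    initial_rate,
    kcat,
    substrate_series,
)
from udgx.simulate import KineticsTruth, generate_kinetics


def mm_dataset(vmax=22.97, km=174.76, s_grid=DEFAULT_S_GRID_NM):
    s = np.asarray(s_grid, dtype=float)
    return KineticsDataset(tuple(s), tuple(vmax * s / (km + s)))


class TestInitialRate:
    def test_exact_line(self):
        tc = TimeCourse((2.0, 4.0, 6.0, 8.0), (5.0, 10.0, 15.0, 20.0))
        est = initial_rate(tc)
        assert est.value == pytest.approx(2.5) and est.se == pytest.approx(0.0, abs=1e-12)

    def test_constant_product_zero_rate(self):
        tc = TimeCourse((2.0, 4.0, 6.0), (3.0, 3.0, 3.0))
        assert initial_rate(tc).value == pytest.approx(0.0)

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            initial_rate(TimeCourse((2.0, 4.0), (1.0, 2.0)))

    def test_times_must_increase(self):
        with pytest.raises(ValueError):
            TimeCourse((2.0, 2.0, 4.0), (1.0, 2.0, 3.0))

    def test_half_saturation_rate_from_linear_course(self):
        # noiseless course at S = Km: slope recovers v = Vmax/2
        truth = KineticsTruth(vmax=22.97, km=174.76)
        v_half = truth.vmax / 2
        tc = TimeCourse((2.0, 4.0, 6.0, 8.0), tuple(v_half * t for t in (2, 4, 6, 8)))
        assert initial_rate(tc).value == pytest.approx(11.485, rel=0.05)


class TestLineweaverBurk:
    def test_noiseless_recovery_to_six_significant_figures(self):
        res = MichaelisMentenModel(mm_dataset()).fit("lb")
        assert res.vmax == pytest.approx(22.97, rel=1e-6)
        assert res.km == pytest.approx(174.76, rel=1e-6)
        assert res.method == "lb" and res.nobs == 10

    @given(
        vmax=st.floats(0.5, 100.0),
        km=st.floats(10.0, 2000.0),
        n=st.integers(3, 12),
    )
    def test_exact_recovery_any_positive_grid(self, vmax, km, n):
        s = np.linspace(20.0, 3000.0, n)
        res = MichaelisMentenModel(mm_dataset(vmax, km, s)).fit("lb")
        assert res.vmax == pytest.approx(vmax, rel=1e-8)
        assert res.km == pytest.approx(km, rel=1e-8)

    def test_two_point_saturated_fit(self):
        res = MichaelisMentenModel(mm_dataset(s_grid=(100.0, 1000.0))).fit("lb")
        assert res.saturated
        assert res.vmax == pytest.approx(22.97, rel=1e-9)
        assert res.vmax_se == 0.0 and res.km_se == 0.0

    def test_nonpositive_rates_excluded(self, caplog):
        data = KineticsDataset((10.0, 100.0, 500.0, 1000.0), (-1.0, 8.0, 16.0, 19.0))
        with caplog.at_level("WARNING"):
            res = MichaelisMentenModel(data).fit("lb")
        assert "non-positive rate" in caplog.text
        assert res.nobs == 3

    def test_negative_intercept_rejected(self):
        # 1/v = -0.1 + 0.5 / S  ->  negative double-reciprocal intercept
        s = np.array([2.0, 4.0, 8.0])
        v = 1.0 / (-0.1 + 0.5 / s)
        with pytest.raises(KineticsFitError, match="intercept"):
            MichaelisMentenModel(KineticsDataset(tuple(s), tuple(v))).fit("lb")

    def test_noisy_median_recovery_within_5_percent(self):
        vm, km = [], []
        for seed in range(200):
            d = generate_kinetics(KineticsTruth(noise_sd_fraction=0.05, seed=seed))
            res = MichaelisMentenModel(d).fit("lb")
            vm.append(res.vmax)
            km.append(res.km)
        assert np.median(vm) == pytest.approx(22.97, rel=0.05)
        assert np.median(km) == pytest.approx(174.76, rel=0.05)


class TestMichaelisMentenFit:
    def test_noiseless_equivalence_with_lb(self):
        model = MichaelisMentenModel(mm_dataset())
        lb, mm = model.fit("lb"), model.fit("mm")
        assert mm.vmax == pytest.approx(lb.vmax, rel=1e-6)
        assert mm.km == pytest.approx(lb.km, rel=1e-6)

    def test_residuals_vanish_at_definitional_point(self):
        truth = KineticsTruth(vmax=10.0, km=200.0)
        data = mm_dataset(10.0, 200.0, (50.0, 200.0, 800.0))
        res = MichaelisMentenModel(data).fit("mm")
        assert res.predict([200.0])[0] == pytest.approx(5.0, rel=1e-6)
        assert truth.rate(200.0) == pytest.approx(5.0)

    def test_less_biased_than_lb_under_multiplicative_noise(self):
        vml, vmm = [], []
        for seed in range(300):
            d = generate_kinetics(KineticsTruth(noise_sd_fraction=0.15, seed=seed))
            vml.append(MichaelisMentenModel(d).fit("lb").vmax)
            try:
                vmm.append(MichaelisMentenModel(d).fit("mm").vmax)
            except KineticsFitError:
                continue
        assert abs(np.mean(vmm) - 22.97) < abs(np.mean(vml) - 22.97)

    def test_fitted_curve_monotone_and_bounded(self):
        res = MichaelisMentenModel(mm_dataset()).fit("mm")
        grid = np.linspace(1.0, 50000.0, 500)
        v = res.predict(grid)
        assert np.all(np.diff(v) > 0)
        assert np.all(v < res.vmax)


class TestDerivedQuantities:
    @pytest.mark.parametrize(
        "vmax,expected",
        [(22.97, 0.115), (11.57, 0.058), (0.0, 0.0)],
    )
    def test_kcat_from_vmax(self, vmax, expected):
        assert round(kcat(vmax, 200.0), 3) == expected

    def test_kcat_requires_positive_et(self):
        with pytest.raises(ValueError):
            kcat(10.0, 0.0)

    def test_published_kcat_column_consistency(self):
        # kcat = Vmax/200 rounded to 3 dp matches the printed turnover for
        # every mutant except the double mutant with the known misprint
        consistent = [
            "H109K", "H109Q", "H109G", "H109S", "H109C", "H109A",
            "H109S/Q53A", "H109S/R184A",
        ]
        for name in consistent:
            row = REFERENCE_KINETICS.loc[name]
            assert round(kcat(row["Vmax_nM_per_min"], 200.0), 3) == row["kcat_per_min"]
        e52n = REFERENCE_KINETICS.loc["H109S/E52N"]
        assert round(kcat(e52n["Vmax_nM_per_min"], 200.0), 3) != e52n["kcat_per_min"]

    def test_efficiency_internal_consistency(self):
        res = MichaelisMentenModel(mm_dataset()).fit("lb")
        assert res.efficiency == pytest.approx(res.kcat / res.km, rel=1e-12)

    @pytest.mark.parametrize(
        "a,b,ratio,label",
        [
            (1063.17, 154.92, 6.86, "≈7-fold"),
            (308.05, 154.92, 1.99, "≈2-fold"),
            (5.0, 5.0, 1.0, "≈1-fold"),
        ],
    )
    def test_fold_change(self, a, b, ratio, label):
        fc = fold_change(a, b)
        assert fc.ratio == pytest.approx(ratio, abs=0.005)
        assert fc.label == label

    def test_fold_change_requires_positive_denominator(self):
        with pytest.raises(ValueError):
            fold_change(1.0, 0.0)

    @pytest.mark.parametrize(
        "unlabelled,expected",
        [(0.5, 60.0), (30.0, 3010.0)],
    )
    def test_substrate_series_conversion(self, unlabelled, expected):
        assert substrate_series(0.1, [unlabelled], 10.0)[0] == pytest.approx(expected)

    def test_substrate_series_zero_amounts(self):
        assert substrate_series(0.0, [0.0], 10.0) == [0.0]

    def test_substrate_series_rejects_bad_volume(self):
        with pytest.raises(ValueError):
            substrate_series(0.1, [1.0], 0.0)

    def test_default_grid_matches_assay_design(self):
        assert DEFAULT_S_GRID_NM[0] == pytest.approx(60.0)
        assert DEFAULT_S_GRID_NM[-1] == pytest.approx(3010.0)
        assert len(DEFAULT_S_GRID_NM) == 10


def test_summary_reports_all_parameters():
    res = MichaelisMentenModel(mm_dataset()).fit("lb")
    text = res.summary()
    for token in ("Vmax", "Km", "kcat", "kcat/Km", "200 nM"):
        assert token in text
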