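"""Stress-strain parameter extraction: modulus, offset yield, plateau."""

import numpy as np
import pytest

from osteolattice import (
    CompressionSpecimen,
    CurveParams,
    StressStrainCurve,
    analyze_curve,
    curve_truth,
    extract_modulus,
    extract_offset_yield,
    extract_plateau,
    gen_curve,
    gen_record,
    to_stress_strain,
)
from osteolattice.curves import read_curve_csv, write_parameters_csv

from conftest import piecewise_linear_curve


class TestToStressStrain:
    def test_engineering_conversion(self, canonical_specimen):
        # 282.7 N over pi*9 mm^2 = 10 MPa; 0.12 mm over 12 mm = 1 % strain
        c = to_stress_strain(
            np.array([0.0, 282.7]), np.array([0.0, 0.12]), canonical_specimen
        )
        assert c.stress == pytest.approx([0.0, 10.0], abs=2e-3)
        assert c.strain == pytest.approx([0.0, 0.01])

    def test_zero_force_gives_zero_stress(self, canonical_specimen):
        disp = np.linspace(0, 1.0, 50)
        c = to_stress_strain(np.zeros(50), disp, canonical_specimen)
        assert np.all(c.stress == 0.0)
        assert len(c.strain) == 50

    def test_preconditioning_loop_removed(self, canonical_specimen):
        p = CurveParams(
            E_true=150.0, sigma_y_true=3.1, sigma_p_true=2.4, seed=3,
            preconditioning=True,
        )
        force, disp = gen_record(p, canonical_specimen)
        # raw record is non-monotonic in displacement (the hysteresis loop)
        assert np.any(np.diff(disp) < 0)
        c = to_stress_strain(force, disp, canonical_specimen)
        assert np.all(np.diff(c.strain) > 0)
        # ramp restarts from the loop's lower preload bound
        assert c.stress[0] == pytest.approx(0.16, abs=1e-9)
        assert c.strain[0] == 0.0
        assert c.stress.max() == pytest.approx(gen_curve(p).stress.max(), rel=1e-9)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            CompressionSpecimen(0.0, 12.0)

    def test_non_monotonic_ramp_rejected(self, canonical_specimen):
        disp = np.array([0.0, 0.5, 0.4, 0.8])
        force = np.array([0.0, 100.0, 120.0, 150.0])
        with pytest.raises(ValueError, match="strictly increasing"):
            to_stress_strain(force, disp, canonical_specimen)


class TestModulus:
    def test_exact_linear_slope(self):
        eps = np.linspace(0, 0.3, 400)
        c = StressStrainCurve(eps, 150.0 * eps)
        assert extract_modulus(c) == pytest.approx(150.0, rel=1e-9)

    def test_toe_then_linear_then_softening(self):
        # toe slope 20, quasilinear slope 100, then softening: max window = 100
        eps, sig = piecewise_linear_curve(
            [(0.0, 0.0), (0.02, 0.4), (0.10, 8.4), (0.30, 6.0)]
        )
        c = StressStrainCurve(eps, sig)
        assert extract_modulus(c) == pytest.approx(100.0, rel=1e-6)

    def test_all_zero_stress(self):
        eps = np.linspace(0, 0.3, 300)
        c = StressStrainCurve(eps, np.zeros_like(eps))
        assert extract_modulus(c) == 0.0

    def test_too_little_data_below_search_limit(self):
        c = StressStrainCurve([0.0, 0.001, 0.002], [0.0, 0.1, 0.2])
        with pytest.raises(ValueError):
            extract_modulus(c)


class TestOffsetYield:
    def test_bilinear_plateau_level(self):
        # slope 100 up to 2.0 MPa then flat: offset line meets the flat branch
        eps, sig = piecewise_linear_curve([(0.0, 0.0), (0.02, 2.0), (0.2, 2.0)])
        c = StressStrainCurve(eps, sig)
        assert extract_offset_yield(c, E=100.0) == pytest.approx(2.0, rel=1e-9)

    def test_purely_linear_has_no_yield(self):
        eps = np.linspace(0, 0.15, 500)
        c = StressStrainCurve(eps, 100.0 * eps)
        with pytest.raises(ValueError, match="no yield"):
            extract_offset_yield(c, E=100.0)

    def test_hardening_curve_against_dense_oracle(self):
        p = CurveParams(
            E_true=150.0, sigma_y_true=3.1, sigma_p_true=2.4, seed=5, hardening=25.0
        )
        c = gen_curve(p)
        E = extract_modulus(c)
        got = extract_offset_yield(c, E)
        # brute-force oracle: first sign change of curve - offset line on a
        # 10x-dense resampling
        dense = np.linspace(0.002, 0.2, 50001)
        f = np.interp(dense, c.strain, c.stress) - E * (dense - 0.002)
        k = np.nonzero((f[:-1] > 0) & (f[1:] <= 0))[0][0]
        oracle = float(np.interp(dense[k], c.strain, c.stress))
        assert got == pytest.approx(oracle, rel=2e-3)
        assert got == pytest.approx(p.sigma_y_true, rel=5e-3)


class TestPlateau:
    def test_constant_plateau(self):
        eps, sig = piecewise_linear_curve([(0.0, 0.0), (0.15, 2.0), (0.45, 2.0)])
        c = StressStrainCurve(eps, sig)
        assert extract_plateau(c) == pytest.approx(2.0, rel=1e-9)

    def test_linear_ramp_midpoint(self):
        # 1 -> 3 MPa across exactly 20-40 %: integral mean is the midpoint
        eps = np.linspace(0.0, 0.45, 901)
        sig = np.interp(eps, [0.0, 0.20, 0.40, 0.45], [0.0, 1.0, 3.0, 3.0])
        c = StressStrainCurve(eps, sig)
        assert extract_plateau(c) == pytest.approx(2.0, rel=1e-6)

    def test_zero_mean_ripple_averages_out(self):
        p = CurveParams(
            E_true=150.0, sigma_y_true=3.1, sigma_p_true=2.4, seed=2,
            ripple=0.3, ripple_periods=4,
        )
        c = gen_curve(p)
        assert extract_plateau(c) == pytest.approx(2.4, rel=2e-3)

    def test_short_curve_rejected(self):
        eps = np.linspace(0, 0.3, 300)
        c = StressStrainCurve(eps, np.full_like(eps, 2.0))
        with pytest.raises(ValueError, match="plateau"):
            extract_plateau(c)


class TestAnalyzeCurve:
    @pytest.mark.parametrize(
        "E,sy,sp",
        [(150.0, 3.1, 2.4), (420.0, 7.5, 4.2), (30.0, 2.0, 1.2), (100.0, 4.3, 4.1)],
    )
    def test_zero_noise_recovery(self, E, sy, sp):
        p = CurveParams(E_true=E, sigma_y_true=sy, sigma_p_true=sp, seed=1)
        got = analyze_curve(gen_curve(p))
        truth = curve_truth(p)
        assert got.E == pytest.approx(truth.E, rel=5e-3)
        assert got.sigma_y == pytest.approx(truth.sigma_y, rel=5e-3)
        assert got.sigma_p == pytest.approx(truth.sigma_p, rel=5e-3)

    def test_stress_scaling_scales_parameters(self, default_params):
        c = gen_curve(default_params)
        base = analyze_curve(c)
        k = 3.7
        scaled = analyze_curve(StressStrainCurve(c.strain, k * c.stress))
        assert scaled.E == pytest.approx(k * base.E, rel=1e-9)
        assert scaled.sigma_y == pytest.approx(k * base.sigma_y, rel=1e-6)
        assert scaled.sigma_p == pytest.approx(k * base.sigma_p, rel=1e-9)

    def test_resampling_invariance(self, default_params):
        c = gen_curve(default_params)
        base = analyze_curve(c)
        dense_eps = np.linspace(c.strain[0], c.strain[-1], 10 * len(c.strain))
        dense = StressStrainCurve(dense_eps, np.interp(dense_eps, c.strain, c.stress))
        fine = analyze_curve(dense)
        assert fine.E == pytest.approx(base.E, rel=5e-3)
        assert fine.sigma_y == pytest.approx(base.sigma_y, rel=5e-3)
        assert fine.sigma_p == pytest.approx(base.sigma_p, rel=5e-3)

    def test_partial_record_flags_missing_plateau(self, default_params):
        c = gen_curve(default_params)
        keep = c.strain < 0.35
        short = StressStrainCurve(c.strain[keep], c.stress[keep])
        res = analyze_curve(short)
        assert res.sigma_p is None
        assert res.warnings


class TestCsvInterface:
    def test_round_trip(self, tmp_path, default_params, canonical_specimen):
        import pandas as pd

        c = gen_curve(default_params)
        path = tmp_path / "curve.csv"
        pd.DataFrame({"strain": c.strain, "stress": c.stress}).to_csv(path, index=False)
        c2 = read_curve_csv(path)
        assert np.allclose(c2.strain, c.strain)

        force, disp = gen_record(default_params, canonical_specimen)
        path2 = tmp_path / "record.csv"
        pd.DataFrame({"force_N": force, "displacement_mm": disp}).to_csv(
            path2, index=False
        )
        c3 = read_curve_csv(path2, canonical_specimen)
        got = analyze_curve(c3)
        assert got.E == pytest.approx(default_params.E_true, rel=5e-3)

        out = tmp_path / "params.csv"
        write_parameters_csv(out, [got])
        df = pd.read_csv(out)
        assert list(df.columns) == ["id", "E_MPa", "sigma_y_MPa", "sigma_p_MPa"]
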