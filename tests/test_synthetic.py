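"""Synthetic generators: determinism, identities with the extractors."""

import numpy as np
import pytest

from osteolattice import (
    CurveParams,
    PowerLaw,
    analyze_curve,
    classify_tscore,
    fit_power,
    gen_curve,
    gen_hu_property,
    gen_phantom,
    gen_pullout,
    gen_record,
    threshold_fill,
)
from osteolattice.curvefit import fit_exponential, fit_linear
from osteolattice.synthetic import (
    load_bundled_calibration,
    load_donor_table,
    load_printed_vertebrae,
    load_pullout_fits,
)


class TestDeterminism:
    def test_curves_byte_identical(self, default_params):
        a = gen_curve(default_params)
        b = gen_curve(default_params)
        assert np.array_equal(a.stress, b.stress)

    def test_tables_byte_identical(self):
        law = PowerLaw(0.094, 1.25)
        a = gen_hu_property(law, noise_cv=0.5, seed=9)
        b = gen_hu_property(law, noise_cv=0.5, seed=9)
        assert a.equals(b)
        fits = load_pullout_fits()
        pa = gen_pullout(fits["power"], noise_cv=0.3, seed=4)
        pb = gen_pullout(fits["power"], noise_cv=0.3, seed=4)
        assert pa.equals(pb)

    def test_phantom_byte_identical(self):
        a = gen_phantom(seed=2)
        b = gen_phantom(seed=2)
        assert np.array_equal(a.data, b.data)


class TestCurveGenerator:
    def test_zero_noise_composition_is_identity(self, default_params):
        got = analyze_curve(gen_curve(default_params))
        assert got.E == pytest.approx(default_params.E_true, rel=5e-3)
        assert got.sigma_y == pytest.approx(default_params.sigma_y_true, rel=5e-3)
        assert got.sigma_p == pytest.approx(default_params.sigma_p_true, rel=5e-3)

    def test_noise_perturbs_but_preserves_scale(self, default_params):
        noisy = CurveParams(
            E_true=150.0, sigma_y_true=3.1, sigma_p_true=2.4, seed=7, noise_sd=0.05
        )
        got = analyze_curve(gen_curve(noisy))
        assert got.sigma_p == pytest.approx(2.4, rel=0.05)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(E_true=-1.0, sigma_y_true=3.0, sigma_p_true=2.0),
            dict(E_true=100.0, sigma_y_true=3.0, sigma_p_true=2.0, toe_span=0.01),
            dict(E_true=100.0, sigma_y_true=3.0, sigma_p_true=2.0, hardening=200.0),
            dict(E_true=400.0, sigma_y_true=2.0, sigma_p_true=1.0),  # short branch
            dict(E_true=100.0, sigma_y_true=3.0, sigma_p_true=2.0, max_strain=0.3),
        ],
    )
    def test_inconsistent_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CurveParams(seed=0, **kwargs)

    def test_record_without_preconditioning_matches_curve(self, default_params):
        from osteolattice import CompressionSpecimen, to_stress_strain

        spec = CompressionSpecimen(6.0, 12.0)
        force, disp = gen_record(default_params, spec)
        c = to_stress_strain(force, disp, spec)
        ref = gen_curve(default_params)
        assert np.allclose(c.stress, ref.stress, atol=1e-9)


class TestHuPropertyGenerator:
    def test_zero_cv_refit_is_exact(self):
        law = PowerLaw(0.001, 1.34)
        df = gen_hu_property(law, n=43, noise_cv=0.0, seed=3)
        f = fit_power(df["hu"], df["y"])
        assert f.constant == pytest.approx(law.constant, rel=1e-9)
        assert f.exponent == pytest.approx(law.exponent, rel=1e-9)
        assert df["hu"].between(61, 364).all()

    def test_noisy_r2_strictly_inside_unit_interval(self):
        df = gen_hu_property(PowerLaw(0.094, 1.25), n=43, noise_cv=0.5, seed=1)
        f = fit_power(df["hu"], df["y"])
        assert 0.0 < f.r_squared < 1.0

    def test_tiny_table_fails_downstream(self):
        df = gen_hu_property(PowerLaw(1.0, 1.0), n=2, seed=0)
        with pytest.raises(ValueError):
            fit_power(df["hu"], df["y"])


class TestPhantomGenerator:
    def test_zero_thickness_cortex_equals_interior(self):
        v = gen_phantom(
            interior_means=(300.0, 310.0),
            cortical_thickness_mm=0.0,
            interior_sd=0.0,
            seed=5,
        )
        m = threshold_fill(v, lo=150.0)
        interior = v.data > -1000.0
        assert np.array_equal(m.data, interior)

    def test_symmetric_means_give_equal_sides(self):
        from osteolattice import erode, hemisphere_means

        v = gen_phantom(interior_means=(200.0, 200.0), seed=8)
        h = hemisphere_means(v, erode(threshold_fill(v), 3.0))
        assert h.hu_left == pytest.approx(h.hu_right, abs=1.0)

    def test_cortex_thicker_than_semiaxis_rejected(self):
        with pytest.raises(ValueError):
            gen_phantom(cortical_thickness_mm=50.0, seed=0)


class TestPulloutGenerator:
    def test_zero_noise_within_observed_span(self):
        fits = load_pullout_fits()
        df = gen_pullout(fits["power"], n=50, noise_cv=0.0, seed=6)
        assert df["f_max"].between(183.0, 1567.0).all()
        assert df["hu"].between(58.0, 343.0).all()

    def test_zero_noise_refit_recovers_law(self):
        fits = load_pullout_fits()
        df = gen_pullout(fits["power"], n=24, noise_cv=0.0, seed=2)
        f = fit_power(df["hu"], df["f_max"])
        assert f.constant == pytest.approx(2.77, rel=1e-9)
        assert f.exponent == pytest.approx(1.04, rel=1e-9)


class TestClassifyTscore:
    @pytest.mark.parametrize(
        "t,expected",
        [
            (0.8, "normal"),
            (1.1, "normal"),
            (-1.0, "normal"),
            (-1.01, "osteopenia"),
            (-2.4, "osteopenia"),
            (-2.5, "osteoporosis"),
            (-3.2, "osteoporosis"),
            (-3.4, "osteoporosis"),
        ],
    )
    def test_who_bands(self, t, expected):
        assert classify_tscore(t) == expected

    def test_matches_donor_roster(self):
        df = load_donor_table()
        for _, row in df.iterrows():
            assert classify_tscore(row["t_score"]) == row["bone_quality"]


class TestBundledTables:
    def test_calibration_constants(self, bone_cal, tough_cal, clear_cal):
        assert bone_cal.laws["E"].constant == pytest.approx(0.094)
        assert bone_cal.laws["E"].exponent == pytest.approx(1.25)
        assert tough_cal.laws["sigma_y"].constant == pytest.approx(33.32)
        assert clear_cal.laws["sigma_p"].exponent == pytest.approx(3.65)
        # the rounded-away plateau constant is flagged non-invertible
        assert not bone_cal.laws["sigma_p"].usable

    def test_printed_vertebrae_table(self):
        df = load_printed_vertebrae()
        assert len(df) == 3
        assert sorted(df["t_over_l"]) == [0.13, 0.17, 0.35]

    def test_pullout_fit_families(self):
        fits = load_pullout_fits()
        assert set(fits) == {"linear", "power", "exponential"}
        assert fits["linear"].constant == pytest.approx(5.65)
        assert fits["exponential"].exponent == pytest.approx(0.01)
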