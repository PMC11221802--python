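import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sstats

from laflow import metrics
from laflow.errors import ConfigError, InputError
from laflow.metrics import (
    KeBundle,
    PhysicalConstants,
    component_ke_series,
    linear_fit,
    normalize_components,
    particle_ke,
    two_sample_t,
    volumetric_indices,
)
from laflow.timing import CardiacTiming

RHO = 1060.0


class TestParticleKe:
    def test_direct_value(self):
        # v = 1 m/s, V = 0.008 mL -> 0.5 * 1060 * 1 * 8e-9 m^3 = 4.24e-6 J
        assert particle_ke(1.0, 0.008) == pytest.approx(4.24e-6, rel=1e-12)

    def test_zero_speed(self):
        assert particle_ke(0.0, 0.008) == 0.0

    @settings(deadline=None, max_examples=100)
    @given(v=st.floats(1e-3, 10.0), vol=st.floats(1e-6, 10.0))
    def test_quadratic_in_speed_linear_in_volume(self, v, vol):
        assert particle_ke(2 * v, vol) == pytest.approx(4 * particle_ke(v, vol))
        assert particle_ke(v, 2 * vol) == pytest.approx(2 * particle_ke(v, vol))


class TestComponentKeSeries:
    def _bundle(self, labels, speeds, inside=None, vols=None):
        labels = np.array(labels, dtype=object)
        speeds = np.asarray(speeds, dtype=float)
        n, r = speeds.shape
        return KeBundle(
            labels=labels,
            volumes_ml=np.ones(n) * 0.008 if vols is None else np.asarray(vols),
            rec_times=np.arange(r) * 0.1,
            rec_speed=speeds,
            rec_inside=np.ones((n, r), bool) if inside is None else inside,
        )

    def test_uniform_speed_gives_half_rho_v2_for_every_label(self):
        labels = ["CONDUIT", "RESERVOIR", "RESIDUAL_VOLUME", "CONDUIT"]
        vols = [0.008, 0.001, 0.5, 0.03]  # KE/volume must not depend on V
        b = self._bundle(labels, np.full((4, 3), 0.5), vols=vols)
        df = component_ke_series([b], sorted(set(labels)))
        assert np.allclose(df["ke_j_per_m3"], 0.5 * RHO * 0.25, rtol=1e-12)

    def test_absent_labels_yield_no_rows(self):
        b = self._bundle(["CONDUIT"], np.full((1, 2), 0.3))
        df = component_ke_series([b], ["CONDUIT", "RESERVOIR"])
        assert set(df["component"]) == {"CONDUIT"}

    def test_time_average_is_mean_over_defined_times(self):
        speeds = np.array([[1.0, 2.0]])
        b = self._bundle(["CONDUIT"], speeds)
        df = component_ke_series([b], ["CONDUIT"])
        avg = metrics.time_average_ke(df)["CONDUIT"]
        a = 0.5 * RHO * 1.0
        bb = 0.5 * RHO * 4.0
        assert avg == pytest.approx((a + bb) / 2)

    def test_outside_particles_excluded(self):
        inside = np.array([[True, False]])
        b = self._bundle(["CONDUIT"], np.array([[1.0, 2.0]]), inside=inside)
        df = component_ke_series([b], ["CONDUIT"])
        assert len(df) == 1  # the second time point is undefined, not zero


class TestVolumetricIndices:
    TM = CardiacTiming(1.0, t_mv_open=0.4, t_pre_a=0.7)

    def _curve(self, la_max=100.0, la_pre_a=80.0, la_min=50.0):
        # max at t_mv_open, plateau at pre-A, min at end of cycle
        t = np.array([0.0, 0.2, 0.4, 0.55, 0.7, 0.85, 0.999])
        v = np.array([la_min, 75.0, la_max, 90.0, la_pre_a, 60.0, la_min])
        return t, v

    def test_ef_and_expansion_index(self):
        t, v = self._curve()
        vi = volumetric_indices(t, v, self.TM)
        assert vi.la_ef == pytest.approx(50.0)
        assert vi.la_expansion_index == pytest.approx(1.0)

    def test_passive_and_active_indices(self):
        t, v = self._curve()
        vi = volumetric_indices(t, v, self.TM)
        assert vi.la_passive_ef == pytest.approx(20.0)
        assert vi.la_active_ef == pytest.approx(37.5)
        assert vi.la_passive_volume_change == pytest.approx(20.0)
        assert vi.la_active_volume_change == pytest.approx(30.0)

    def test_lvsv_minus_lasv(self):
        t, v = self._curve()
        vi = volumetric_indices(t, v, self.TM, lvsv=98.0)
        assert vi.lvsv_minus_lasv == pytest.approx(98.0 - 50.0)

    def test_ef_expansion_identity(self):
        # (EF/100) * (expansion index + 1) == expansion index, exactly
        for la_min in (30.0, 50.0, 77.0):
            t, v = self._curve(la_min=la_min)
            v = np.where(v < la_min, la_min, v)
            vi = volumetric_indices(t, v, self.TM)
            assert (vi.la_ef / 100.0) * (vi.la_expansion_index + 1.0) == pytest.approx(
                vi.la_expansion_index, rel=1e-12
            )

    def test_missing_pre_a_without_detection(self):
        tm = CardiacTiming(1.0, t_mv_open=0.4)
        t, v = self._curve()
        vi = volumetric_indices(t, v, tm, detect_pre_a=False)
        assert vi.la_passive_ef is None
        assert vi.la_active_ef is None

    def test_diastasis_detection_finds_plateau(self, case_factory):
        case = case_factory("reservoir_mix")
        t, v = case.masks.la_volume_curve()
        tm = CardiacTiming(1.0, t_mv_open=0.4)  # no pre-A given
        vi = volumetric_indices(t, v, tm)
        assert vi.la_pre_a is not None
        assert vi.la_min <= vi.la_pre_a <= vi.la_max


class TestNormalization:
    VOLS = {"CONDUIT": 20.0, "RESERVOIR": 10.0}

    def test_schemes_and_units(self):
        out = normalize_components(self.VOLS, la_es_volume=40.0, bsa=2.0, lvsv=100.0)
        assert out[("CONDUIT", "LA_ES")] == pytest.approx(50.0)  # %
        assert out[("CONDUIT", "BSA")] == pytest.approx(10.0)  # mL/m^2
        assert out[("CONDUIT", "LVSV")] == pytest.approx(20.0)  # %

    def test_partition_normalizes_to_100(self):
        vols = {"A": 12.0, "B": 28.0}
        out = normalize_components(vols, la_es_volume=40.0)
        assert out[("A", "LA_ES")] + out[("B", "LA_ES")] == pytest.approx(100.0)

    def test_missing_denominator_scheme_absent(self):
        out = normalize_components(self.VOLS, la_es_volume=40.0)  # no BSA, no LVSV
        assert ("CONDUIT", "BSA") not in out
        assert ("CONDUIT", "LVSV") not in out
        assert ("CONDUIT", "LA_ES") in out

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ConfigError):
            normalize_components(self.VOLS, bsa=0.0)


class TestTwoSampleT:
    def test_textbook_pooled_value(self):
        # pooled-variance t for {1,2,3} vs {2,3,4}: t = -1/sqrt(2/3), df = 4
        res = two_sample_t([1, 2, 3], [2, 3, 4])
        t_hand = -1.0 / np.sqrt(2.0 / 3.0)
        p_hand = 2.0 * sstats.t.cdf(t_hand, df=4)
        assert res.t == pytest.approx(t_hand, abs=1e-10)
        assert res.p == pytest.approx(p_hand, abs=1e-10)
        assert res.df == 4

    def test_identical_groups_null(self):
        res = two_sample_t([1.0, 1.0, 2.0], [1.0, 1.0, 2.0])
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_zero_variance_degenerate(self):
        res = two_sample_t([0.0, 0.0], [0.0, 0.0])
        assert res.p == 1.0 and res.degenerate
        res = two_sample_t([0.0, 0.0], [1.0, 1.0])
        assert res.p == 0.0 and res.degenerate

    def test_separation_limit(self):
        for eps in (1e-2, 1e-4, 1e-6):
            res = two_sample_t([0.0, eps], [1.0, 1.0 + eps])
            assert res.p < eps  # p -> 0 as the jitter vanishes

    @settings(deadline=None, max_examples=100)
    @given(
        a=st.lists(st.floats(-5, 5), min_size=3, max_size=8),
        b=st.lists(st.floats(-5, 5), min_size=3, max_size=8),
    )
    def test_antisymmetric_under_group_swap(self, a, b):
        if np.var(a) == 0 and np.var(b) == 0:
            return
        r1 = two_sample_t(a, b)
        r2 = two_sample_t(b, a)
        assert r1.t == pytest.approx(-r2.t, rel=1e-9, abs=1e-12)
        assert r1.p == pytest.approx(r2.p, rel=1e-9, abs=1e-12)

    def test_group_too_small(self):
        with pytest.raises(InputError):
            two_sample_t([1.0], [1.0, 2.0])


class TestLinearFit:
    def test_perfect_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = linear_fit(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=25)
        y = 1.3 * x - 0.4 + rng.normal(scale=0.5, size=25)
        y[3] += 8.0  # single outlier
        fit = linear_fit(x, y)
        X = np.column_stack([x, np.ones_like(x)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        r2 = 1.0 - resid @ resid / np.sum((y - y.mean()) ** 2)
        assert fit.slope == pytest.approx(beta[0], abs=1e-10)
        assert fit.intercept == pytest.approx(beta[1], abs=1e-10)
        assert fit.r_squared == pytest.approx(r2, abs=1e-10)

    def test_r2_for_noise_around_mean(self):
        # y independent of x: R^2 equals the brute-force sum-of-squares form
        x = np.arange(10.0)
        y = np.array([1.0, -1.0] * 5) + 3.0
        fit = linear_fit(x, y)
        X = np.column_stack([x, np.ones_like(x)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        r2 = 1.0 - resid @ resid / np.sum((y - y.mean()) ** 2)
        assert fit.r_squared == pytest.approx(r2, abs=1e-12)

    @settings(deadline=None, max_examples=100)
    @given(
        a=st.floats(0.1, 10), b=st.floats(-5, 5),
        c=st.floats(0.1, 10), d=st.floats(-5, 5),
    )
    def test_r2_invariant_under_affine_rescaling(self, a, b, c, d):
        rng = np.random.default_rng(11)
        x = rng.normal(size=20)
        y = 0.8 * x + rng.normal(scale=0.7, size=20)
        r2 = linear_fit(x, y).r_squared
        r2_scaled = linear_fit(a * x + b, c * y + d).r_squared
        assert r2_scaled == pytest.approx(r2, rel=1e-9)

    def test_constant_x_rejected(self):
        with pytest.raises(InputError):
            linear_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
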