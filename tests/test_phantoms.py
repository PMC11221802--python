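import numpy as np
import pytest

from laflow import phantoms
from laflow.errors import ConfigError
from laflow.phantoms import (
    Phantom,
    PocketBox,
    SineLobe,
    TrapezoidLobe,
    characteristics_oracle,
    continuity_audit,
    make_phantom,
)
from laflow.timing import CardiacTiming

from conftest import get_case


class TestWaveforms:
    def test_sine_lobe_integrates_to_volume(self):
        lo = SineLobe(0.2, 0.5, 12_000.0)
        t = np.linspace(0.2, 0.5, 20001)
        num = np.trapezoid(lo.q(t), t)
        assert num == pytest.approx(12_000.0, rel=1e-6)
        assert lo.cum(np.array([0.5]))[0] == pytest.approx(12_000.0)

    def test_trapezoid_lobe_volume_and_frame_exactness(self):
        lo = TrapezoidLobe(0.4, 1.0, 0.05, 96_000.0)
        assert lo.volume_mm3 == pytest.approx(96_000.0 * 0.55)
        # sampled at the frame grid, linear interpolation reproduces it
        frames = np.arange(20) * 0.05
        qs = lo.q(frames)
        mid = 0.5 * (frames[:-1] + frames[1:])
        assert np.allclose(lo.q(mid), 0.5 * (qs[:-1] + qs[1:]))

    def test_continuity_violation_rejected(self):
        timing = CardiacTiming(1.0, t_mv_open=0.4)
        with pytest.raises(ConfigError, match="periodicity"):
            Phantom(
                name="bad", L=50.0, W=20.0, H_min=24.0, tube_len=10.0, n_pv=1,
                timing=timing,
                q_in_lobes=(SineLobe(0.0, 0.4, 10_000.0),),
                q_out_lobes=(SineLobe(0.4, 1.0, 5_000.0),),
                pocket=None, spacing=2.0,
            )


class TestPresets:
    def test_unknown_preset_rejected(self):
        with pytest.raises(ConfigError):
            make_phantom("no_such_flow")

    def test_pure_conduit_truth_structure(self):
        case = get_case("pure_conduit")
        assert case.truth["PV_BACKFLOW"] == 0.0
        assert case.truth["RESERVOIR"] == 0.0
        assert case.truth["RESIDUAL_VOLUME"] == 0.0
        assert case.truth["CONDUIT"] > 0.0
        # the rigid chamber is fully flushed each diastole
        assert case.truth["DELAYED_EJECTION"] == pytest.approx(
            case.truth_meta["chamber_volume_es_ml"]
        )

    def test_stagnant_pocket_truth(self):
        case = get_case("stagnant_pocket")
        assert case.truth["RESIDUAL_VOLUME"] >= case.truth_meta["pocket_volume_ml"] - 1e-9

    def test_reservoir_mix_has_reservoir_and_retained(self):
        case = get_case("reservoir_mix")
        assert case.truth["RESERVOIR"] > 0
        assert case.truth["RETAINED_INFLOW"] > 0
        assert case.truth["PV_BACKFLOW"] == 0.0

    def test_atrial_maximum_at_seed_instant(self):
        for preset in ("reservoir_mix", "backflow", "full_mix"):
            case = get_case(preset)
            t = np.linspace(0, 1, 1001)
            vol = case.phantom.chamber_volume_mm3(t)
            t_max = t[np.argmax(vol)]
            assert t_max == pytest.approx(case.timing.t_mv_open, abs=1e-3), preset

    def test_jitter_is_seeded_and_reproducible(self):
        a = make_phantom("reservoir_mix", jitter=0.1, seed=3, compute_truth=False)
        b = make_phantom("reservoir_mix", jitter=0.1, seed=3, compute_truth=False)
        c = make_phantom("reservoir_mix", jitter=0.1, seed=4, compute_truth=False)
        assert np.allclose(a.phantom.q_in_f, b.phantom.q_in_f)
        assert not np.allclose(a.phantom.q_in_f, c.phantom.q_in_f)


class TestContinuity:
    def test_sampled_field_continuity_audit(self):
        """Net boundary flux of the sampled field matches the wall-motion
        volume rate frame by frame."""
        for preset in phantoms.PRESETS:
            assert continuity_audit(get_case(preset)) < 0.005, preset


def test_halving_tracking_step_is_inert(report_factory, case_factory):
    """Grazing-crossing robustness: re-running with the tracking step
    halved changes every component volume by < 0.5 %."""
    from laflow import pipeline

    case = case_factory("backflow")
    rep_default = report_factory("backflow")
    rep_fine = pipeline.analyze(
        case.field, case.masks, case.planes, case.timing,
        pipeline.AnalysisParams(dt=case.timing.cycle_length / 2000),
    )
    for label, d in rep_default.volumes.items():
        h = rep_fine.volumes[label]
        assert abs(h - d) <= max(0.005 * d, 0.02), (label, d, h)


class TestOracle:
    def test_zero_flow_all_residual(self):
        timing = CardiacTiming(1.0, t_mv_open=0.4)
        ph = Phantom(
            name="still", L=50.0, W=20.0, H_min=24.0, tube_len=10.0, n_pv=1,
            timing=timing, q_in_lobes=(), q_out_lobes=(), pocket=None, spacing=2.0,
        )
        truth = characteristics_oracle(ph)
        assert truth["RESIDUAL_VOLUME"] == pytest.approx(24.0)
        for k in ("CONDUIT", "RESERVOIR", "DELAYED_EJECTION", "RETAINED_INFLOW", "PV_BACKFLOW"):
            assert truth[k] == 0.0

    def test_self_convergence_in_step_size(self):
        """Halving-by-ten the oracle step changes no component by > 0.1 %."""
        ph = get_case("backflow").phantom
        coarse = characteristics_oracle(ph, dt=1e-3)
        fine = characteristics_oracle(ph, dt=1e-4)
        for k, v in fine.items():
            scale = max(abs(v), 1.0)
            assert abs(coarse[k] - v) / scale < 1e-3, k

    def test_backflow_truth_converges_to_flux_integral(self):
        """With the release interval refined, vein-returner volume matches
        the analytic integral of the reversed inflow."""
        case = get_case("backflow")
        truth = characteristics_oracle(case.phantom, release_interval=0.001)
        assert truth["PV_BACKFLOW"] == pytest.approx(
            case.truth_meta["backflow_analytic_ml"], rel=0.02
        )

    def test_conduit_truth_converges_to_transit_formula(self):
        case = get_case("pure_conduit")
        truth = characteristics_oracle(case.phantom, release_interval=0.001)
        assert truth["CONDUIT"] == pytest.approx(
            case.truth_meta["conduit_analytic_ml"], rel=0.01
        )

    def test_pocket_monotonicity(self):
        """A larger sealed pocket strictly increases the residual volume and
        leaves every other component untouched."""
        base = get_case("stagnant_pocket")
        timing = base.timing
        big = Phantom(
            name="bigger_pocket",
            L=50.0, W=20.0, H_min=24.0, tube_len=10.0, n_pv=1,
            timing=timing,
            q_in_lobes=base.phantom.q_in_lobes,
            q_out_lobes=base.phantom.q_out_lobes,
            pocket=PocketBox(6.0, 38.0, 28.0, 32.0, 0.0, 24.0),
            spacing=2.0,
        )
        t_small = base.truth
        t_big = characteristics_oracle(big)
        assert t_big["RESIDUAL_VOLUME"] > t_small["RESIDUAL_VOLUME"]
        for k in ("CONDUIT", "RESERVOIR", "DELAYED_EJECTION", "RETAINED_INFLOW", "PV_BACKFLOW"):
            assert t_big[k] == pytest.approx(t_small[k], abs=1e-9), k
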