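import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from laflow import components as comp
from laflow.fields import LV, OUTSIDE, pv_code
from laflow.timing import CardiacTiming

PV1 = pv_code(1)
NONE = -1
NAN = np.nan

TM = CardiacTiming(cycle_length=1.0, t_mv_open=0.4, t_mv_close=0.0)
# seed instant t0 = 0.4; backward window [-0.6, 0.4]; preceding systole
# [0.0, 0.4]; previous diastole [-0.6, 0.0); following diastole [0.4, 1.0)


class TestVolumeSeededRules:
    @pytest.mark.parametrize(
        "entry_t,entry_r,exit_t,exit_r,lost,expected",
        [
            # entered mid-systole, left through MV mid-diastole -> reservoir
            (0.2, PV1, 0.7, LV, False, comp.RESERVOIR),
            # entered previous diastole, left during diastole -> delayed
            (-0.3, PV1, 0.7, LV, False, comp.DELAYED_EJECTION),
            # no entry found, left during diastole -> delayed (was in LA before)
            (NAN, NONE, 0.7, LV, False, comp.DELAYED_EJECTION),
            # entered previous cycle, never left -> retained inflow
            (-0.3, PV1, NAN, NONE, False, comp.RETAINED_INFLOW),
            # entered during systole, never left -> retained inflow
            (0.1, PV1, NAN, NONE, False, comp.RETAINED_INFLOW),
            # neither entered nor left over both cycles -> residual volume
            (NAN, NONE, NAN, NONE, False, comp.RESIDUAL_VOLUME),
            # left through a vein -> PV backflow, regardless of entry
            (0.2, PV1, 0.9, PV1, False, comp.PV_BACKFLOW),
            (NAN, NONE, 0.9, PV1, False, comp.PV_BACKFLOW),
            # numerically lost through the wall
            (NAN, NONE, 0.6, OUTSIDE, True, comp.LOST),
        ],
    )
    def test_rule_table(self, entry_t, entry_r, exit_t, exit_r, lost, expected):
        labels, _ = comp.classify_volume_seeded_arrays(
            [entry_t], [entry_r], [exit_t], [exit_r], [lost], TM
        )
        assert labels[0] == expected

    def test_vein_exit_overrides_mitral_rules(self):
        # the vein-exit clause takes precedence over everything else
        labels, _ = comp.classify_volume_seeded_arrays(
            [0.2], [PV1], [0.5], [PV1], [False], TM
        )
        assert labels[0] == comp.PV_BACKFLOW

    def test_mitral_exit_after_diastole_is_flagged(self):
        labels, anomaly = comp.classify_volume_seeded_arrays(
            [0.2], [PV1], [1.2], [LV], [False], TM
        )
        assert anomaly[0]
        assert labels[0] == comp.RESERVOIR  # still classified by entry rule

    @settings(deadline=None, max_examples=300)
    @given(
        entry=st.one_of(st.none(), st.floats(-0.6, 0.4)),
        exit_kind=st.sampled_from(["none", "mv", "pv", "lost"]),
        exit_t=st.floats(0.4, 1.4),
    )
    def test_every_particle_gets_exactly_one_label(self, entry, exit_kind, exit_t):
        entry_t = NAN if entry is None else entry
        entry_r = NONE if entry is None else PV1
        exit_r = {"none": NONE, "mv": LV, "pv": PV1, "lost": OUTSIDE}[exit_kind]
        labels, _ = comp.classify_volume_seeded_arrays(
            [entry_t],
            [entry_r],
            [NAN if exit_kind == "none" else exit_t],
            [exit_r],
            [exit_kind == "lost"],
            TM,
        )
        assert labels[0] in comp.VOLUME_SEEDED_LABELS


class TestPvSeededRules:
    @pytest.mark.parametrize(
        "release,exit_t,exit_r,expected",
        [
            # released early diastole, out through MV late same diastole
            (0.45, 0.95, LV, comp.CONDUIT),
            # released early diastole, MV exit only in the next diastole
            (0.45, 1.5, LV, comp.UNATTRIBUTED),
            # released during systole: never conduit
            (0.2, 0.7, LV, comp.UNATTRIBUTED),
            # returned to a vein within one cycle
            (0.45, 0.9, PV1, comp.PV_BACKFLOW),
            # vein return later than one cycle after release is not counted
            (0.45, 1.6, PV1, comp.UNATTRIBUTED),
            # still inside at the end of tracking
            (0.2, NAN, NONE, comp.UNATTRIBUTED),
        ],
    )
    def test_rule_table(self, release, exit_t, exit_r, expected):
        labels = comp.classify_pv_seeded_arrays(
            [release], [exit_t], [exit_r], [False], TM
        )
        assert labels[0] == expected


def _mk_set(origin, labels, vols, release, entry, exit_t, exit_r):
    return comp.ClassifiedSet(
        origin=origin,
        labels=np.array(labels, dtype=object),
        volumes_ml=np.array(vols, dtype=float),
        release_time=np.array(release, dtype=float),
        entry_time=np.array(entry, dtype=float),
        exit_time=np.array(exit_t, dtype=float),
        exit_region=np.array(exit_r),
    )


class TestMerge:
    def test_deduplication_of_vein_returners(self):
        vol = _mk_set(
            "VOLUME",
            [comp.PV_BACKFLOW],
            [1.0],
            [0.4],
            [NAN],
            [0.9],
            [PV1],
        )
        pv = _mk_set(
            "PV_1",
            [comp.PV_BACKFLOW] * 3,
            [0.5, 0.5, 0.5],
            # released: after snapshot / before with early return / before
            # with late return (this one is the volume seeding's particle)
            [0.5, 0.1, 0.1],
            [0.52, 0.12, 0.12],
            [0.9, 0.3, 0.9],
            [PV1, PV1, PV1],
        )
        rep = comp.merge_components(vol, [pv], TM)
        # 1.0 (volume) + 0.5 (after snapshot) + 0.5 (returned before snapshot)
        assert rep.volumes[comp.PV_BACKFLOW] == pytest.approx(2.0)

    def test_conduit_only_from_vein_seeding(self):
        vol = _mk_set("VOLUME", [comp.RESIDUAL_VOLUME], [2.0], [0.4], [NAN], [NAN], [NONE])
        pv = _mk_set("PV_1", [comp.CONDUIT], [0.7], [0.5], [0.52], [0.9], [LV])
        rep = comp.merge_components(vol, [pv], TM)
        assert rep.volumes[comp.CONDUIT] == pytest.approx(0.7)
        assert rep.volumes[comp.RESIDUAL_VOLUME] == pytest.approx(2.0)

    def test_bias_is_inflow_minus_outflow(self):
        vol = _mk_set(
            "VOLUME",
            [comp.RESERVOIR, comp.DELAYED_EJECTION],
            [1.0, 2.0],
            [0.4, 0.4],
            [0.2, NAN],
            [0.7, 0.8],
            [LV, LV],
        )
        pv = _mk_set("PV_1", [comp.CONDUIT], [0.5], [0.5], [0.52], [0.9], [LV])
        rep = comp.merge_components(vol, [pv], TM)
        assert rep.bias_ml == pytest.approx(0.5 - (0.5 + 1.0 + 2.0))


class TestSeriesOnPhantoms:
    def test_partition_of_volume_seed_is_exact(self, report_factory):
        for preset in ("pure_conduit", "full_mix"):
            rep = report_factory(preset)
            breakdown = rep.meta["volume_seeded_components_ml"]
            assert sum(breakdown.values()) == pytest.approx(
                rep.meta["volume_seeded_total_ml"], abs=1e-9
            )

    def test_in_la_volumes_at_seed_instant_sum_to_seed_total(self, case_factory, report_factory):
        case = case_factory("reservoir_mix")
        rep = report_factory("reservoir_mix")
        vol = rep.volume_series
        at0 = vol[np.isclose(vol["time_s"], case.timing.t_mv_open)]
        assert at0["in_la_ml"].sum() == pytest.approx(
            rep.meta["volume_seeded_total_ml"], abs=1e-6
        )

    def test_mv_rate_integrates_to_outflow_components(self, report_factory):
        rep = report_factory("backflow")
        mv_total = rep.rate_series["mv_out_ml"].sum()
        expected = (
            rep.volumes[comp.CONDUIT]
            + rep.volumes[comp.RESERVOIR]
            + rep.volumes[comp.DELAYED_EJECTION]
        )
        assert mv_total == pytest.approx(expected, abs=1e-6)

    def test_pv_exit_rate_integrates_to_backflow(self, report_factory):
        rep = report_factory("backflow")
        assert rep.rate_series["pv_out_ml"].sum() == pytest.approx(
            rep.volumes[comp.PV_BACKFLOW], abs=1e-6
        )

    def test_conservation_on_periodic_phantoms(self, report_factory, case_factory):
        """PV inflow − backflow = mitral outflow = conduit+reservoir+delayed.

        At the default release interval the identity carries two structural
        quanta of the discrete vein seeding: up to one release parcel
        (Q·Δt_release, blood whose marginal parcel straddles the transit
        cutoff and is booked in the neighboring cycle) plus the standing
        inventory between the seed plane and the atrial inlet. The bound
        asserted here is 2 % plus those quanta; refining the release
        interval shrinks the parcel term (checked in the next test)."""
        for preset in ("pure_conduit", "reservoir_mix", "backflow"):
            rep = report_factory(preset)
            case = case_factory(preset)
            inflow = rep.meta["pv_inflow_total_ml"]
            outflow_mv = (
                rep.volumes[comp.CONDUIT]
                + rep.volumes[comp.RESERVOIR]
                + rep.volumes[comp.DELAYED_EJECTION]
            )
            ph = case.phantom
            parcel = float(np.max(ph.q_in_f)) * 0.025 / 1000.0  # mL
            float_ml = ph.spacing / 2 * ph.W * ph.H_min / 1000.0
            gap = abs(inflow - rep.volumes[comp.PV_BACKFLOW] - outflow_mv)
            assert gap <= 0.02 * inflow + parcel + float_ml, preset

    def test_conservation_tightens_with_release_refinement(self, case_factory):
        """With the release interval refined 5x, the conservation identity
        closes within 2 % on the steady-channel phantom."""
        from laflow import pipeline
        from laflow.seeding import SeedSpec

        case = case_factory("pure_conduit")
        params = pipeline.AnalysisParams(
            seed_spec=SeedSpec(plane_spacing=2.0, release_interval=0.005)
        )
        rep = pipeline.analyze(
            case.field, case.masks, case.planes, case.timing, params
        )
        inflow = rep.meta["pv_inflow_total_ml"]
        outflow = rep.total_outflow_ml()
        assert abs(inflow - outflow) <= 0.02 * inflow
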