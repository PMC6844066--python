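"""Generator correctness: waveform integrals, conservation, rendering, cohorts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from pulmoflow import pbvv, quant, synth
from pulmoflow.exceptions import (
    AliasingRiskError,
    InfeasibleTargetError,
    InvalidParameterError,
)
from pulmoflow.types import VEINS, FlowCurve


class TestArterialWaveform:
    def test_zero_stroke_volume_gives_zero_curve(self):
        c = synth.make_arterial_waveform(1000.0, 0.0, 35, seed=0)
        assert np.all(c.flow == 0.0) and c.net_flow() == 0.0

    def test_net_flow_matches_requested_stroke_volume(self, arterial):
        assert arterial.net_flow() == pytest.approx(106.0, rel=1e-3)

    def test_single_systolic_peak_in_first_half(self, arterial):
        peak = int(np.argmax(arterial.flow))
        assert peak < arterial.n_frames / 2
        # single prominent maximum: no other local max above 20% of the peak
        f = arterial.flow
        others = [
            f[i]
            for i in range(1, f.size - 1)
            if f[i] > f[i - 1] and f[i] > f[i + 1] and i != peak
        ]
        assert all(v < 0.2 * f[peak] for v in others)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_trapezoid_oracle_agrees_with_rectangle_net_flow(self, seed):
        c = synth.make_arterial_waveform(900.0, 80.0, 35, seed=seed)
        # independent oracle: trapezoid rule on the periodic extension
        f = np.append(c.flow, c.flow[0])
        trap = np.trapezoid(f, dx=c.frame_duration / 1000.0)
        assert trap == pytest.approx(c.net_flow(), rel=0.02)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(rr_interval=0.0, stroke_volume=80.0, n_frames=35),
            dict(rr_interval=-5.0, stroke_volume=80.0, n_frames=35),
            dict(rr_interval=900.0, stroke_volume=80.0, n_frames=7),
            dict(rr_interval=900.0, stroke_volume=-1.0, n_frames=35),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            synth.make_arterial_waveform(**kwargs)


class TestVenousWaveforms:
    def test_zero_target_returns_arterial_frame_by_frame(self, arterial):
        veins, _ = synth.make_venous_waveforms(arterial, 0.0)
        total = np.sum([veins[v].flow for v in VEINS], axis=0)
        np.testing.assert_allclose(total, arterial.flow, atol=1e-12)

    @pytest.mark.parametrize("target", [5.0, 25.0, 46.0, 60.0])
    def test_round_trip_pbvv_recovery(self, arterial, target):
        veins, truth = synth.make_venous_waveforms(arterial, target)
        res = pbvv.compute_pbvv(arterial, list(veins.values()))
        frame_volume = float(np.max(np.abs(res.diff_volume)))
        assert abs(res.pbvv - target) <= frame_volume
        assert truth.true_pbvv["bilateral"] == target

    def test_conservation_of_net_flow(self, arterial):
        veins, _ = synth.make_venous_waveforms(arterial, 46.0)
        venous_net = sum(veins[v].net_flow() for v in VEINS)
        assert venous_net == pytest.approx(arterial.net_flow(), rel=1e-3)

    def test_summed_venous_curve_is_biphasic(self, arterial):
        veins, _ = synth.make_venous_waveforms(arterial, 46.0)
        qv = np.sum([veins[v].flow for v in VEINS], axis=0)
        peak = qv.max()
        maxima = [
            i for i in range(1, qv.size - 1)
            if qv[i] > qv[i - 1] and qv[i] > qv[i + 1] and qv[i] > 0.3 * peak
        ]
        assert len(maxima) >= 2  # systolic and diastolic waves

    def test_infeasible_target_raises(self, arterial):
        with pytest.raises(InfeasibleTargetError):
            synth.make_venous_waveforms(arterial, 500.0)

    def test_bad_split_rejected(self, arterial):
        with pytest.raises(InvalidParameterError):
            synth.make_venous_waveforms(arterial, 40.0, venous_split=(0.5, 0.5, 0.5, 0.5))

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        sv=hst.floats(min_value=40.0, max_value=150.0),
        rel=hst.floats(min_value=0.0, max_value=0.8),
    )
    def test_conservation_property(self, sv, rel):
        art = synth.make_arterial_waveform(1000.0, sv, 35)
        veins, _ = synth.make_venous_waveforms(art, rel * sv)
        venous_net = sum(veins[v].net_flow() for v in VEINS)
        assert abs(venous_net - art.net_flow()) <= 1e-3 * max(sv, 1.0)


class TestSplitLungs:
    def test_even_split_gives_identical_branch_arteries(self, arterial):
        veins, _ = synth.make_venous_waveforms(arterial, 46.0)
        split = synth.split_lungs(arterial, veins, 0.5)
        np.testing.assert_allclose(split["RPA"].flow, split["LPA"].flow)

    def test_branch_arteries_sum_to_main(self, arterial):
        veins, _ = synth.make_venous_waveforms(arterial, 46.0)
        split = synth.split_lungs(arterial, veins, 0.61)
        np.testing.assert_allclose(
            split["RPA"].flow + split["LPA"].flow, arterial.flow, atol=1e-12
        )
        assert split["RPA"].net_flow() + split["LPA"].net_flow() == pytest.approx(
            arterial.net_flow(), abs=0.01
        )

    def test_right_fraction_recovered_from_net_flows(self, arterial):
        veins, _ = synth.make_venous_waveforms(arterial, 46.0)
        split = synth.split_lungs(arterial, veins, 0.52)
        frac = pbvv.flow_fraction_right(split["RPA"].net_flow(), split["LPA"].net_flow())
        assert frac == pytest.approx(52.0, abs=1e-9)
        venous_right = split["RSPV"].net_flow() + split["RIPV"].net_flow()
        venous_total = sum(split[v].net_flow() for v in VEINS)
        assert venous_right / venous_total == pytest.approx(0.52, abs=1e-9)

    def test_degenerate_fraction_rejected(self, arterial):
        veins, _ = synth.make_venous_waveforms(arterial, 46.0)
        with pytest.raises(InvalidParameterError):
            synth.split_lungs(arterial, veins, 1.0)


class TestRenderPcSeries:
    def test_plug_profile_flow_is_exactly_velocity_times_area(self):
        c = FlowCurve("MPA", np.full(10, 20.0), 100.0, 1000.0)
        r = synth.render_pc_series(c, 400.0, venc=100.0, profile="plug")
        measured = quant.measure_roi_flow(r.series, r.vessel_masks, allow_uncorrected=True)
        area = quant.measure_area(r.vessel_masks).mean_area  # pixelated lumen area
        v_cm_s = 20.0 / 400.0 * 100.0  # uniform plug velocity: flow / nominal area
        np.testing.assert_allclose(measured.flow, v_cm_s * area * 0.01, rtol=1e-12)

    def test_noiseless_identity_round_trip(self, arterial):
        r = synth.render_pc_series(arterial, 700.0, venc=175.0)
        measured = quant.measure_roi_flow(r.series, r.vessel_masks, allow_uncorrected=True)
        scale = np.max(np.abs(arterial.flow))
        assert np.max(np.abs(measured.flow - arterial.flow)) / scale < 0.02

    def test_aliasing_refusal(self, arterial):
        with pytest.raises(AliasingRiskError):
            synth.render_pc_series(arterial, 700.0, venc=100.0)  # parabolic peak ~141 cm/s

    def test_known_eddy_surface_recovered(self, rendered):
        coeffs, _ = quant.fit_eddy_background(rendered.series, rendered.static_mask)
        np.testing.assert_allclose(coeffs, rendered.truth.eddy_coeffs, atol=1e-6)


class TestGenerateCohort:
    def test_same_seed_gives_bit_identical_cohorts(self):
        r1, t1 = synth.generate_cohort(n_subjects=3, seed=9)
        r2, t2 = synth.generate_cohort(n_subjects=3, seed=9)
        for a, b in zip(r1, r2):
            assert a.subject_id == b.subject_id and a.position == b.position
            for v in a.curves:
                np.testing.assert_array_equal(a.curves[v].flow, b.curves[v].flow)
        for key in t1.per_record:
            assert t1.per_record[key].true_pbvv == t2.per_record[key].true_pbvv

    def test_cardiac_output_has_no_positional_effect(self, noiseless_cohort):
        records, _ = noiseless_cohort
        for sid in {r.subject_id for r in records}:
            cos = [
                pbvv.cardiac_output(r.heart_rate, r.curves["MPA"].net_flow())
                for r in records
                if r.subject_id == sid
            ]
            assert max(cos) / min(cos) < 1.25  # only position-level noise

    def test_dependent_lung_receives_more_flow_in_most_subjects(self):
        records, _ = synth.generate_cohort(n_subjects=10, seed=11, flow_noise_sd=0.0)
        by = {(r.subject_id, r.position): r for r in records}
        wins = 0
        for s in {r.subject_id for r in records}:
            sup = pbvv.analyze_record(by[(s, "supine")])["flow_fraction_right"]
            lat = pbvv.analyze_record(by[(s, "right_lateral")])["flow_fraction_right"]
            wins += lat > sup
        assert wins >= 9

    def test_null_cohort_positions_exchangeable(self):
        effects = {
            p: synth.PositionEffectConfig(
                position=p,
                dependent_flow_gain=0.0,
                dependent_venous_area_gain=0.0,
                nondependent_pvdr_gain=0.0,
            )
            for p in synth.POSITIONS
        }
        records, _ = synth.generate_cohort(n_subjects=8, effects=effects, seed=21)
        by = {(r.subject_id, r.position): r for r in records}
        from pulmoflow import stats

        matrix = np.array(
            [
                [
                    pbvv.analyze_record(by[(s, p)])["pbvv"]["bilateral"].relative_pbvv
                    for p in synth.POSITIONS
                ]
                for s in sorted({r.subject_id for r in records})
            ]
        )
        _, p_value = stats.friedman(matrix)
        assert p_value > 0.01

    def test_too_small_cohort_rejected(self):
        with pytest.raises(InvalidParameterError):
            synth.generate_cohort(n_subjects=1, seed=0)
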