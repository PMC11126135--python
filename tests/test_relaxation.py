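"""Three-compartment relaxation model: weights, forward/inverse maps, scans."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ivimfield import (
    FIG_PERTURBATION_PRESETS,
    CompartmentWeights,
    DomainError,
    PerfusionState,
    SequenceProtocol,
    UsageError,
    compartment_weight,
    cross_field_prediction,
    estimate_venous_arterial_ratio,
    forward_perfusion_fraction,
    invert_perfusion_fraction,
    load_relaxation_set,
    sensitivity_curves,
)


class TestCompartmentWeight:
    @pytest.mark.parametrize(
        "t1, t2, expected",
        [
            (1122.0, 148.0, 0.6285),  # venous blood at 0.55 T
            (701.0, 44.0, 0.2749),  # muscle at 0.55 T
            (1122.0, 207.0, 0.7001),  # arterial blood at 0.55 T
        ],
    )
    def test_study_protocol_values(self, protocol, t1, t2, expected):
        assert compartment_weight(t1, t2, protocol) == pytest.approx(expected, abs=1e-4)

    def test_degenerate_limit_is_one(self):
        # vanishing TE and TR >> T1 remove both exponential factors
        protocol = SequenceProtocol(te=1e-9, tr=1e12)
        assert compartment_weight(1000.0, 100.0, protocol) == pytest.approx(1.0, abs=1e-6)

    def test_long_tr_protocol_drops_t1_factor(self):
        protocol = SequenceProtocol(te=100.0, tr=2800.0).long_tr()
        assert compartment_weight(586.0, 46.0, protocol) == pytest.approx(
            math.exp(-100.0 / 46.0), rel=1e-12
        )

    @pytest.mark.parametrize("t1, t2", [(-1.0, 50.0), (1000.0, 0.0)])
    def test_nonpositive_times_name_the_field(self, protocol, t1, t2):
        with pytest.raises(DomainError, match="t1|t2"):
            compartment_weight(t1, t2, protocol)

    def test_bad_protocol_timing_rejected(self):
        with pytest.raises(DomainError, match="te"):
            SequenceProtocol(te=0.0, tr=2800.0)
        with pytest.raises(DomainError, match="tr"):
            SequenceProtocol(te=56.0, tr=30.0)


class TestForwardInverse:
    def test_zero_f0_gives_zero_f(self, weights055):
        state = PerfusionState(f0_total=0.0, ratio_v_a=4.0)
        assert forward_perfusion_fraction(state, weights055) == 0.0

    @pytest.mark.parametrize("ratio", [0.5, 1.0, 4.0, 9.0])
    def test_equal_weights_are_proton_density_limit(self, ratio):
        weights = CompartmentWeights(0.4, 0.4, 0.4)
        state = PerfusionState(f0_total=0.123, ratio_v_a=ratio)
        assert forward_perfusion_fraction(state, weights) == pytest.approx(0.123, abs=1e-15)

    def test_forward_reproduces_measured_gm_fraction(self, weights055):
        # the f0 behind the cohort-mean baseline measurement maps back to it
        state = PerfusionState(f0_total=0.0339, ratio_v_a=4.0)
        f = forward_perfusion_fraction(state, weights055)
        assert f == pytest.approx(0.0759, abs=3e-4)

    def test_two_pool_consistency(self, weights055):
        # equal blood weights collapse the three-pool form onto the two-pool one
        wb = 0.65
        weights = CompartmentWeights(wb, wb, weights055.w_muscle)
        for f0 in (0.01, 0.05, 0.2, 0.49):
            three = forward_perfusion_fraction(
                PerfusionState(f0_total=f0, ratio_v_a=3.3), weights
            )
            two = f0 * wb / (f0 * wb + (1 - f0) * weights055.w_muscle)
            assert three == pytest.approx(two, abs=1e-14)

    @pytest.mark.parametrize(
        "f, expected_f0_percent",
        [(0.0759, 3.393), (0.1403, 6.524)],
    )
    def test_inversion_of_cohort_means(self, weights055, f, expected_f0_percent):
        f0 = invert_perfusion_fraction(f, 4.0, weights055)
        assert 100 * f0 == pytest.approx(expected_f0_percent, abs=2e-3)

    def test_inversion_of_zero_is_zero(self, weights055):
        assert invert_perfusion_fraction(0.0, 4.0, weights055) == 0.0

    @pytest.mark.parametrize("bad_f", [1.0, 1.5, -0.1])
    def test_inversion_rejects_out_of_range_f(self, weights055, bad_f):
        with pytest.raises(DomainError):
            invert_perfusion_fraction(bad_f, 4.0, weights055)

    def test_forward_rejects_f0_at_one(self):
        with pytest.raises(DomainError):
            PerfusionState(f0_total=1.0, ratio_v_a=4.0)

    def test_f0_additivity_is_exact(self):
        for ratio in np.linspace(0.1, 10, 37):
            state = PerfusionState(f0_total=0.0437, ratio_v_a=float(ratio))
            assert state.f0_arterial + state.f0_venous == state.f0_total

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        f0=st.floats(0.0, 0.4999),
        ratio=st.floats(0.5, 10.0),
        wa=st.floats(0.05, 1.0),
        wv=st.floats(0.05, 1.0),
        wm=st.floats(0.05, 1.0),
    )
    def test_round_trip_property(self, f0, ratio, wa, wv, wm):
        weights = CompartmentWeights(wa, wv, wm)
        f = forward_perfusion_fraction(PerfusionState(f0_total=f0, ratio_v_a=ratio), weights)
        assert invert_perfusion_fraction(f, ratio, weights) == pytest.approx(f0, abs=1e-12)

    def test_monotonicity_in_both_directions(self, weights055):
        f0_grid = np.linspace(0, 0.99, 200)
        f = [
            forward_perfusion_fraction(PerfusionState(f0_total=x, ratio_v_a=4.0), weights055)
            for x in f0_grid
        ]
        assert np.all(np.diff(f) > 0)
        f_grid = np.linspace(0, 0.99, 200)
        f0 = [invert_perfusion_fraction(x, 4.0, weights055) for x in f_grid]
        assert np.all(np.diff(f0) > 0)


class TestRatioEstimation:
    def test_degenerate_identical_inputs_return_grid_minimum(self, relax055, protocol):
        result = estimate_venous_arterial_ratio(
            0.07, 0.07, relax055, relax055, protocol, grid=np.arange(1.0, 5.0, 0.5)
        )
        # objective vanishes everywhere; ties break to the smallest ratio
        assert result.ratio == 1.0
        assert result.objective.max() == 0.0

    def test_empty_grid_rejected(self, relax055, relax7, protocol):
        with pytest.raises(UsageError):
            estimate_venous_arterial_ratio(0.07, 0.04, relax055, relax7, protocol, grid=[])

    def test_recovers_known_ratio_noise_free(self, relax055, relax7, protocol):
        # forward-model self-consistency: synthesize both fields from r=3
        true_ratio, f0 = 3.0, 0.031
        f_low = forward_perfusion_fraction(
            PerfusionState(f0_total=f0, ratio_v_a=true_ratio), relax055.weights(protocol)
        )
        f_high = forward_perfusion_fraction(
            PerfusionState(f0_total=f0, ratio_v_a=true_ratio), relax7.weights(protocol)
        )
        result = estimate_venous_arterial_ratio(f_low, f_high, relax055, relax7, protocol)
        assert result.ratio == pytest.approx(3.0, abs=0.01)

    def test_gm_means_imply_ratio_near_six(self, relax055, relax7_table, protocol):
        # measured baseline GM fractions at the two fields; tabulated 7 T set
        result = estimate_venous_arterial_ratio(
            0.0708, 0.0384, relax055, relax7_table, protocol
        )
        assert result.ratio == pytest.approx(6.0, abs=1.0)


class TestCrossFieldPrediction:
    def test_identical_conditions_give_unit_ratio(self, relax055, protocol):
        pred = cross_field_prediction(0.07, relax055, relax055, 4.0, protocol)
        assert pred.ratio_ref_over_target == pytest.approx(1.0, abs=1e-12)
        assert pred.f_target == pytest.approx(0.07, abs=1e-13)

    def test_liver_ratio_four_predicts_field_dependence(self):
        protocol = SequenceProtocol(te=100.0, tr=5000.0).long_tr()
        pred = cross_field_prediction(
            0.286,
            load_relaxation_set("liver_1.5T"),
            load_relaxation_set("liver_3T"),
            4.0,
            protocol,
        )
        assert pred.ratio_ref_over_target == pytest.approx(1.258, abs=0.002)

    def test_liver_equal_volumes_predict_no_field_dependence(self):
        protocol = SequenceProtocol(te=100.0, tr=5000.0).long_tr()
        pred = cross_field_prediction(
            0.286,
            load_relaxation_set("liver_1.5T"),
            load_relaxation_set("liver_3T"),
            1.0,
            protocol,
        )
        assert 1.0 / pred.ratio_ref_over_target == pytest.approx(1.011, abs=0.002)


class TestSensitivityCurves:
    def test_empty_perturbations_give_single_curve(self, relax055, protocol):
        table = sensitivity_curves(np.linspace(0, 0.1, 11), 4.0, relax055, protocol)
        assert set(table["perturbation_label"]) == {"unperturbed"}
        assert len(table) == 11

    def test_presets_produce_one_curve_each(self, relax7, protocol):
        table = sensitivity_curves(
            np.linspace(0, 0.1, 11), 4.0, relax7, protocol,
            perturbations=FIG_PERTURBATION_PRESETS,
        )
        assert len(set(table["perturbation_label"])) == 1 + len(FIG_PERTURBATION_PRESETS)

    def test_curves_strictly_increase_in_f0(self, relax7, protocol):
        table = sensitivity_curves(
            np.linspace(0, 0.99, 50), 4.0, relax7, protocol,
            perturbations=FIG_PERTURBATION_PRESETS,
        )
        for _, grp in table.groupby("perturbation_label"):
            assert np.all(np.diff(grp["f"].to_numpy()) > 0)

    def test_ratio_spread_wider_at_high_field(self, relax055, relax7, protocol):
        # at fixed f0 the model's ratio dependence separates at 7 T but not
        # at 0.55 T, where venous and arterial weights nearly coincide
        def relative_spread(relax):
            fs = [
                forward_perfusion_fraction(
                    PerfusionState(f0_total=0.03, ratio_v_a=r), relax.weights(protocol)
                )
                for r in (2, 3, 4, 5, 6)
            ]
            return (max(fs) - min(fs)) / np.mean(fs)

        assert relative_spread(relax7) > 2 * relative_spread(relax055)

    def test_perturbation_to_nonpositive_time_rejected(self, relax055, protocol):
        with pytest.raises(DomainError):
            sensitivity_curves(
                [0.0, 0.05], 4.0, relax055, protocol,
                perturbations={"bad": {"t2_muscle": -1.0}},
            )

    def test_unknown_perturbation_field_rejected(self, relax055):
        with pytest.raises(UsageError):
            relax055.perturb(t2_blood=-0.1)


class TestRelaxationSetValidation:
    def test_t2_exceeding_t1_rejected(self, relax055):
        import dataclasses

        with pytest.raises(DomainError, match="t2_muscle"):
            dataclasses.replace(relax055, t2_muscle=800.0)

    def test_fixture_metadata_present(self, relax055, relax7, relax7_table):
        assert relax055.field_strength == 0.55
        assert relax7.t1_arterial == 2990.0  # running-text variant (default)
        assert relax7_table.t1_arterial == 2290.0  # tabulated variant
        assert relax055.citations
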