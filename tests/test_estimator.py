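"""Two-breath ELV/FRC estimator, weights, kinetics fitting and QC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rebreathe.errors import (
    InsufficientBreathsError,
    KineticsFitError,
    NonRisingPetError,
)
from rebreathe.estimator import (
    DeadSpaceConfig,
    EstimatorConfig,
    compute_deltas,
    convert_elv_to_frc,
    estimate_elv,
    estimate_from_trace,
    fit_pet_geometric,
    fit_rebreathing_kinetics,
    qc_measurement,
    second_breath_weight,
)
from rebreathe.capnogram import BreathSegment, segment_breaths
from rebreathe.simulator import SimulatorParams, simulate_pet_sequence, simulate_trace


def _segments(pets, period=5.0):
    return [
        BreathSegment(index=i, t_exp_start=i * period, t_exp_end=i * period + 3.0,
                      pet=p)
        for i, p in enumerate(pets)
    ]


class TestComputeDeltas:
    @pytest.mark.parametrize(
        "pets, expected",
        [
            ((5.0, 5.2, 5.4), (5.0, 0.2, 0.4)),
            ((5.0, 5.2, 5.37), (5.0, 0.2, 0.37)),
        ],
    )
    def test_cumulative_convention(self, pets, expected):
        av, d1, d2 = compute_deltas(_segments(pets))
        assert (av, d1, d2) == pytest.approx(expected)

    def test_matches_simulator_ground_truth(self):
        p = SimulatorParams()
        gt = simulate_pet_sequence(p, 4)
        av, d1, d2 = compute_deltas(gt.pet[:3])
        assert av == pytest.approx(gt.pet[0])
        assert d1 == pytest.approx(gt.pet[1] - gt.pet[0])
        assert d2 == pytest.approx(gt.pet[2] - gt.pet[0])

    def test_too_few_breaths(self):
        with pytest.raises(InsufficientBreathsError):
            compute_deltas(_segments((5.0, 5.2)))

    def test_non_rising_raises(self):
        with pytest.raises(NonRisingPetError):
            compute_deltas(_segments((5.0, 4.8, 5.1)))


class TestSecondBreathWeight:
    def test_linear_limit_is_half(self):
        assert second_breath_weight(0.0, 5.0) == pytest.approx(0.5)

    def test_typical_operating_point(self):
        # k = 0.06 1/s, T = 5 s -> 1/(1+e^-0.3) = 0.574, the fixed 0.57
        assert second_breath_weight(0.06, 5.0) == pytest.approx(0.574, abs=5e-4)
        assert round(second_breath_weight(0.06, 5.0), 2) == 0.57

    def test_fast_equilibration_limit(self):
        assert second_breath_weight(1e6, 5.0) == pytest.approx(1.0)


class TestEstimateElv:
    def test_linear_case_collapses_to_single_breath_formula(self):
        # w=0.5, d2=2*d1: identical to avPet*DV/d1
        elv = estimate_elv(5.0, 0.148, 0.2, 0.4, weight=0.5)
        assert elv == pytest.approx(2 * 5 * 0.148 / 0.4)
        assert elv == pytest.approx(5 * 0.148 / 0.2)

    def test_unit_invariance_mmhg(self):
        s = 7.50062  # mmHg per kPa
        kpa = estimate_elv(5.0, 0.148, 0.2, 0.37, weight=0.57)
        mmhg = estimate_elv(5.0 * s, 0.148, 0.2 * s, 0.37 * s, weight=0.57)
        assert mmhg == pytest.approx(kpa, rel=1e-12)

    def test_non_positive_denominator(self):
        with pytest.raises(NonRisingPetError):
            estimate_elv(5.0, 0.148, -0.3, 0.1, weight=0.5)

    @given(
        av=st.floats(2.0, 8.0),
        d1=st.floats(0.05, 0.5),
        d2=st.floats(0.05, 1.0),
        dv=st.floats(0.05, 0.3),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotonicity(self, av, d1, d2, dv):
        base = estimate_elv(av, dv, d1, d2)
        assert estimate_elv(av, dv, d1 * 1.01, d2) < base
        assert estimate_elv(av, dv, d1, d2 * 1.01) < base
        assert estimate_elv(av * 1.01, dv, d1, d2) > base
        assert estimate_elv(av, dv * 1.01, d1, d2) > base


class TestConvertElvToFrc:
    @pytest.mark.parametrize(
        "elv, k, frc",
        [(1.0, 0.82, 0.82), (3.7, 0.82, 3.034), (2.5, 1.0, 2.5)],
    )
    def test_proportionality(self, elv, k, frc):
        assert convert_elv_to_frc(elv, k) == pytest.approx(frc)

    def test_disease_specific_constants_accepted(self):
        assert convert_elv_to_frc(3.0, 0.88) == pytest.approx(2.64)
        assert convert_elv_to_frc(3.0, 0.77) == pytest.approx(2.31)

    def test_rejects_bad_constant(self):
        with pytest.raises(ValueError):
            convert_elv_to_frc(3.0, 1.2)


class TestExactRecovery:
    def test_pipeline_recovers_elv_with_auto_weight(
        self, ideal_trace, dead_space, auto_config
    ):
        trace, _ = ideal_trace
        est = estimate_from_trace(trace, dead_space, auto_config)
        assert est.elv == pytest.approx(3.0, rel=1e-9)
        assert est.frc == pytest.approx(0.82 * 3.0, rel=1e-9)
        assert not est.qc_flags

    def test_analytic_weight_also_exact(self):
        p = SimulatorParams(
            elv_true=3.0, rr=12.0, k_rate=0.06,
            noise_sd=0.0, analyzer_tau=0.0, transport_delay=0.0,
        )
        gt = simulate_pet_sequence(p, 3)
        av, d1, d2 = compute_deltas(gt.pet)
        w = second_breath_weight(p.k_rate, p.breath_period)
        elv = estimate_elv(av, p.dead_space, d1, d2, weight=w)
        assert elv == pytest.approx(3.0, rel=1e-12)

    def test_estimate_invariants_hold(self, ideal_trace, dead_space, auto_config):
        trace, _ = ideal_trace
        est = estimate_from_trace(trace, dead_space, auto_config)
        assert est.delta_pet == pytest.approx(
            0.5 * (est.delta_pet1 + est.weight_w * est.delta_pet2), rel=1e-12
        )
        assert est.elv == pytest.approx(
            est.av_pet * dead_space.volume / est.delta_pet, rel=1e-12
        )
        assert est.frc == pytest.approx(est.k_constant * est.elv, rel=1e-12)


class TestFixedWeightBias:
    def test_bias_bounded_and_sign_predictable_across_rr(self, dead_space):
        # w=0.57 is exact near RR 12.8; too small at low RR -> ELV biased high
        errors = {}
        for rr in (4.6, 8.0, 11.0, 16.8):
            p = SimulatorParams(
                elv_true=3.0, rr=rr, noise_sd=0.0,
                analyzer_tau=0.0, transport_delay=0.0,
            )
            trace, _ = simulate_trace(p, 6)
            est = estimate_from_trace(trace, dead_space, EstimatorConfig(weight=0.57))
            errors[rr] = (est.elv - 3.0) / 3.0
        assert all(abs(e) < 0.10 for e in errors.values())
        assert errors[4.6] > errors[8.0] > errors[11.0] > errors[16.8]
        assert errors[4.6] > 0 and errors[11.0] > 0 and errors[16.8] < 0


class TestKineticsFit:
    def test_noiseless_recovery_is_exact(self):
        p = SimulatorParams(k_rate=0.06, rr=11.0)
        gt = simulate_pet_sequence(p, 8)
        t = np.arange(8) * gt.breath_period
        fit = fit_rebreathing_kinetics(t, gt.pet)
        assert fit.k_rate == pytest.approx(0.06, abs=1e-6)
        assert fit.pet0 == pytest.approx(p.pet0, abs=1e-6)
        assert fit.delta_p_inf == pytest.approx(gt.delta_p_inf, rel=1e-6)

    def test_noisy_median_recovery_within_10pct(self):
        p = SimulatorParams(k_rate=0.06, rr=11.0)
        gt = simulate_pet_sequence(p, 8)  # ~38 s record
        t = np.arange(8) * gt.breath_period
        ks = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            ks.append(
                fit_rebreathing_kinetics(t, gt.pet + rng.normal(0, 0.05, 8)).k_rate
            )
        assert abs(np.median(ks) - 0.06) < 0.006

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_rebreathing_kinetics([0.0, 20.0], [5.0, 5.5])

    def test_geometric_fit_rejects_non_rising_sequence(self):
        with pytest.raises(KineticsFitError):
            fit_pet_geometric([5.0, 4.9, 5.1])


class TestQc:
    def test_dv_tv_low_flag(self, dead_space):
        segs = _segments((5.0, 5.2, 5.4, 5.6))
        flags = qc_measurement(segs, dead_space=dead_space, tv_estimate=1.7)
        assert "dv_tv_low" in flags  # 0.148/1.7 = 0.087 < 0.10

    def test_dv_tv_high_flag(self, dead_space):
        segs = _segments((5.0, 5.2, 5.4, 5.6))
        flags = qc_measurement(segs, dead_space=dead_space, tv_estimate=0.5)
        assert "dv_tv_high" in flags  # 0.148/0.5 = 0.296 > 0.25

    def test_in_range_dv_tv_not_flagged(self, dead_space):
        segs = _segments((5.0, 5.2, 5.4, 5.6))
        flags = qc_measurement(segs, dead_space=dead_space, tv_estimate=1.1)
        assert flags == frozenset()

    def test_equal_periods_not_irregular(self):
        assert "irregular" not in qc_measurement(_segments((5.0, 5.2, 5.4, 5.6)))

    def test_jittered_periods_irregular(self):
        segs = [
            BreathSegment(index=i, t_exp_start=t0, t_exp_end=t0 + 1.0, pet=p)
            for i, (t0, p) in enumerate(
                zip((0.0, 3.0, 10.0, 13.0), (5.0, 5.2, 5.4, 5.6))
            )
        ]
        assert "irregular" in qc_measurement(segs)

    def test_pet_drop_flags_irregular(self):
        assert "irregular" in qc_measurement(_segments((5.0, 5.2, 5.4, 5.1)))

    def test_too_few_segments(self):
        assert qc_measurement(_segments((5.0, 5.2))) == frozenset(
            {"insufficient_breaths"}
        )


def test_averaging_two_measurements_shrinks_sd_by_sqrt2(dead_space):
    """SD of ELV over repeats shrinks ~ sqrt(2) when two runs are averaged."""
    single, averaged = [], []
    for seed in range(0, 120, 2):
        elvs = []
        for s in (seed, seed + 1):
            p = SimulatorParams(elv_true=3.0, seed=s)
            trace, _ = simulate_trace(p, 6)
            est = estimate_from_trace(trace, dead_space, EstimatorConfig())
            elvs.append(est.elv)
        single.append(elvs[0])
        averaged.append(np.mean(elvs))
    ratio = np.std(single, ddof=1) / np.std(averaged, ddof=1)
    assert ratio == pytest.approx(np.sqrt(2.0), rel=0.35)
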