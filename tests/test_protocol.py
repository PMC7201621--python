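"""Dosing-engine tests: body-parameter formulas, flow rates, prescriptions."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmtrial.errors import (
    ContractError,
    ImplausibleInputError,
    InvalidInputError,
)
from cmtrial.protocol import (
    Arm,
    ContrastAgent,
    PatientProfile,
    ScanContext,
    ScanProtocol,
    Sex,
    derive_bsa,
    derive_co_katori,
    derive_lbw_hume,
    flow_rate,
    injection_durations,
    prescribe,
    round_half_away,
)


class TestHumeLBW:
    @pytest.mark.parametrize(
        "sex,weight,height,expected",
        [
            (Sex.MALE, 80.0, 180.0, 57.7866),
            (Sex.FEMALE, 70.0, 165.0, 46.39645),
        ],
    )
    def test_frozen_examples(self, sex, weight, height, expected):
        assert derive_lbw_hume(sex, weight, height) == pytest.approx(
            expected, abs=1e-4
        )

    def test_linearity_in_weight(self):
        # the male weight coefficient is exactly 0.32810 kg per kg
        delta = derive_lbw_hume(Sex.MALE, 81, 180) - derive_lbw_hume(Sex.MALE, 80, 180)
        assert delta == pytest.approx(0.32810, abs=1e-12)

    @pytest.mark.parametrize("weight,height", [(0, 170), (-5, 170), (70, 0)])
    def test_invalid_inputs(self, weight, height):
        with pytest.raises(InvalidInputError):
            derive_lbw_hume(Sex.MALE, weight, height)

    def test_implausible_anthropometry(self):
        # formally positive inputs can still produce a negative lean mass
        with pytest.raises(ImplausibleInputError):
            derive_lbw_hume(Sex.FEMALE, 5, 50)


class TestBSA:
    def test_dubois_example(self):
        assert derive_bsa(83.1, 173) == pytest.approx(1.97, abs=0.01)

    def test_cohort_mean_matches_printed_bsa(self):
        # the cohort-mean covariates should land on the printed 2.0 +/- 0.2
        assert derive_bsa(83.3, 173) == pytest.approx(2.0, abs=0.1)

    def test_power_law_scaling(self):
        assert derive_bsa(160, 173) / derive_bsa(80, 173) == pytest.approx(
            2**0.425, rel=1e-12
        )

    def test_mosteller_alternative(self):
        assert derive_bsa(83.1, 173, method="mosteller") == pytest.approx(
            math.sqrt(83.1 * 173 / 3600), rel=1e-12
        )

    def test_unknown_method(self):
        with pytest.raises(InvalidInputError):
            derive_bsa(80, 170, method="boyd")


class TestKatoriCO:
    def test_frozen_example(self):
        assert derive_co_katori(60, 2.0) == pytest.approx(6.988, abs=1e-3)

    def test_cohort_mean_consistent_with_printed_co(self):
        bsa = derive_bsa(83.3, 173)
        assert derive_co_katori(60, bsa) == pytest.approx(6.85, abs=0.3)

    def test_linear_in_age(self):
        bsa = 1.9
        slope = derive_co_katori(61, bsa) - derive_co_katori(60, bsa)
        assert slope == pytest.approx(-0.023 * bsa, abs=1e-12)


class TestFlowRate:
    @pytest.mark.parametrize(
        "arm,kv,kwargs,expected",
        [
            (Arm.BW, 70, {"weight": 83.1}, 4.6396),
            (Arm.LBW, 80, {"lbw": 55.0}, 4.8444),
            (Arm.CO, 80, {"co": 6.9}, 4.9216),
        ],
    )
    def test_frozen_examples(self, arm, kv, kwargs, expected):
        assert flow_rate(arm, kv, **kwargs) == pytest.approx(expected, abs=1e-4)

    def test_mismatched_parameter_is_contract_error(self):
        with pytest.raises(ContractError):
            flow_rate(Arm.BW, 70, lbw=55.0)
        with pytest.raises(ContractError):
            flow_rate(Arm.CO, 70, co=6.9, weight=80.0)

    def test_disallowed_voltage(self):
        with pytest.raises(InvalidInputError):
            flow_rate(Arm.BW, 95, weight=80.0)

    @given(
        kv=st.sampled_from([70, 80, 90, 100, 110, 120]),
        value=st.floats(1.0, 200.0),
        scale=st.floats(1.01, 3.0),
        arm=st.sampled_from(list(Arm)),
    )
    @settings(max_examples=60, derandomize=True)
    def test_homogeneous_and_increasing(self, kv, value, scale, arm):
        key = {Arm.BW: "weight", Arm.LBW: "lbw", Arm.CO: "co"}[arm]
        base = flow_rate(arm, kv, **{key: value})
        assert flow_rate(arm, kv, **{key: value * scale}) == pytest.approx(
            base * scale, rel=1e-12
        )
        assert flow_rate(arm, kv, **{key: value * scale}) > base


class TestDurationsAndPrescription:
    @pytest.mark.parametrize(
        "protocol,expected",
        [
            (ScanProtocol.FLASH, (2, 8)),
            (ScanProtocol.ADAPTIVE_SEQUENCE, (2, 10)),
            (ScanProtocol.HELICAL, (2, 10)),
        ],
    )
    def test_fixed_injection_times(self, protocol, expected):
        assert injection_durations(protocol) == expected

    def test_unknown_protocol(self):
        with pytest.raises(InvalidInputError):
            injection_durations("spiral")

    def test_composed_prescription(self):
        patient = PatientProfile("p1", Sex.MALE, 60, 173.0, 83.1, 65.0)
        rx = prescribe(patient, ScanContext(ScanProtocol.FLASH, 70), Arm.BW)
        assert rx.flow_rate == pytest.approx(4.6396, abs=1e-4)
        assert rx.test_bolus_volume == pytest.approx(9.279, abs=1e-3)
        assert rx.main_bolus_volume == pytest.approx(37.117, abs=1e-3)
        assert rx.idr == pytest.approx(1.392, abs=1e-3)
        assert rx.til == pytest.approx(11.135, abs=1e-3)
        assert not rx.requires_high_flow_needle

    def test_group_mean_flow_reproduces_printed_idr_til(self):
        # printed one-decimal summaries: flow 5.1 -> IDR 1.5; volume 47.5 -> TIL 14.3
        assert round_half_away(5.1 * 0.3) == 1.5
        assert round_half_away(47.5 * 0.3) == 14.3

    def test_needle_threshold_is_strict(self):
        agent = ContrastAgent()
        patient = PatientProfile("p2", Sex.MALE, 60, 173.0, 125.376, 65.0)
        # choose voltages/weights bracketing exactly 7 mL/s
        rx_at = prescribe(
            patient, ScanContext(ScanProtocol.FLASH, 70), Arm.BW, agent
        )
        assert rx_at.flow_rate == pytest.approx(7.0, abs=1e-3)
        assert not rx_at.requires_high_flow_needle
        heavier = PatientProfile("p3", Sex.MALE, 60, 173.0, 126.0, 65.0)
        assert prescribe(
            heavier, ScanContext(ScanProtocol.FLASH, 70), Arm.BW, agent
        ).requires_high_flow_needle

    def test_implausible_flow_warns_but_prescribes(self, caplog):
        heavy = PatientProfile("p4", Sex.MALE, 40, 200.0, 180.0, 65.0)
        with caplog.at_level("WARNING", logger="cmtrial.protocol"):
            rx = prescribe(heavy, ScanContext(ScanProtocol.FLASH, 120), Arm.BW)
        assert rx.flow_rate > 12
        assert any("outside plausible window" in r.message for r in caplog.records)

    @given(data=st.data())
    @settings(max_examples=80, derandomize=True)
    def test_concentration_and_timing_conservation(self, data):
        """TIL/volume and IDR/flow equal the agent concentration exactly;
        bolus volumes are exactly flow x {2, 8 or 10} s."""
        sex = data.draw(st.sampled_from(list(Sex)))
        patient = PatientProfile(
            "h",
            sex,
            data.draw(st.integers(18, 90)),
            data.draw(st.floats(145, 200)),
            data.draw(st.floats(45, 150)),
            65.0,
        )
        context = ScanContext(
            data.draw(st.sampled_from(list(ScanProtocol))),
            data.draw(st.sampled_from([70, 80, 90, 100, 110, 120])),
        )
        arm = data.draw(st.sampled_from(list(Arm)))
        rx = prescribe(patient, context, arm)
        assert rx.til / rx.main_bolus_volume == pytest.approx(0.3, rel=1e-12)
        assert rx.idr / rx.flow_rate == pytest.approx(0.3, rel=1e-12)
        assert rx.test_bolus_volume == rx.flow_rate * 2.0
        assert rx.main_bolus_volume in (rx.flow_rate * 8.0, rx.flow_rate * 10.0)

    def test_mean_patient_flows_inside_printed_ranges(self, mean_patient):
        """Across arms and 70-120 kV the mean patient stays within the
        printed flow-rate range 2.1-9.1 mL/s."""
        for arm in Arm:
            for kv in (70, 80, 90, 100, 110, 120):
                rx = prescribe(
                    mean_patient, ScanContext(ScanProtocol.FLASH, kv), arm
                )
                assert 2.1 <= rx.flow_rate <= 9.1


class TestProfileInvariants:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"age": 17},
            {"height": 99.0},
            {"weight": 260.0},
            {"heart_rate": 0.0},
        ],
    )
    def test_rejects_out_of_range(self, kwargs):
        base = dict(
            id="x", sex=Sex.MALE, age=50, height=170.0, weight=80.0, heart_rate=60.0
        )
        base.update(kwargs)
        with pytest.raises(InvalidInputError):
            PatientProfile(**base)

    def test_rounding_is_half_away_from_zero(self):
        assert round_half_away(14.25) == 14.3
        assert round_half_away(-14.25) == -14.3
        assert round_half_away(2.5, 0) == 3.0
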