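"""Kinetic fits: velocities, Michaelis-Menten, activation model, EC50, hits."""

import numpy as np
import pandas as pd
import pytest

from crypticscreen.errors import ContractError, InsufficientDataError
from crypticscreen.kinetics import (
    ActivationModel,
    AssayTrace,
    DoseResponseModel,
    KineticParameters,
    MichaelisMentenModel,
    activation_velocity,
    call_hits,
    dose_response_curve,
    efficiency_change,
    initial_velocity,
    mm_velocity,
)


class TestInitialVelocity:
    def test_exact_linear_slope(self):
        t = tuple(range(11))
        trace = AssayTrace(times=t, signal=tuple(0.05 * x + 0.002 for x in t))
        assert initial_velocity(trace) == pytest.approx(0.05)

    def test_quadratic_matches_normal_equations(self):
        t = np.arange(0.0, 11.0)
        y = 0.001 * t**2
        trace = AssayTrace(times=tuple(t), signal=tuple(y))
        # independent closed-form least squares on the same points
        X = np.vstack([t, np.ones_like(t)]).T
        slope_oracle = np.linalg.lstsq(X, y, rcond=None)[0][0]
        assert initial_velocity(trace, window=10) == pytest.approx(slope_oracle)

    def test_points_outside_window_insufficient(self):
        t = tuple(range(20, 71, 10))
        trace = AssayTrace(times=t, signal=tuple(float(x) for x in t))
        with pytest.raises(InsufficientDataError):
            initial_velocity(trace, window=10)

    def test_conversion_factor_applied(self):
        t = tuple(range(11))
        trace = AssayTrace(times=t, signal=tuple(0.01 * x for x in t),
                           conversion_factor=50.0)
        assert initial_velocity(trace) == pytest.approx(0.5)


class TestMichaelisMenten:
    S = np.array([10.0, 25.0, 50.0, 100.0, 200.0])

    def test_noiseless_round_trip(self):
        v = mm_velocity(self.S, 100.0, 100.0, 0.001)
        res = MichaelisMentenModel(self.S, v, 0.001).fit()
        assert res.params.kcat == pytest.approx(100.0, rel=1e-6)
        assert res.params.km == pytest.approx(100.0, rel=1e-6)

    def test_saturated_design_warns(self):
        v = np.full_like(self.S, 0.1)
        with pytest.warns(UserWarning, match="poorly determined"):
            res = MichaelisMentenModel(self.S, v, 0.001).fit()
        assert res.ill_determined

    def test_zero_enzyme_rejected(self):
        with pytest.raises(ContractError):
            MichaelisMentenModel(self.S, self.S, 0.0)

    def test_too_few_substrate_levels_rejected(self):
        with pytest.raises(InsufficientDataError):
            MichaelisMentenModel([10, 10, 10], [1, 1, 1], 0.001)

    def test_mean_efficiency_recovered_under_noise(self):
        # 5% proportional noise, 100 simulated triplicate series
        rng = np.random.default_rng(42)
        effs = []
        for _ in range(100):
            S = np.tile(self.S, 3)
            v = mm_velocity(S, 100.0, 100.0, 0.001)
            v = v * (1 + 0.05 * rng.standard_normal(v.shape))
            p = MichaelisMentenModel(S, v, 0.001).fit().params
            effs.append(p.efficiency)
        assert np.mean(effs) == pytest.approx(1.0, rel=0.02)

    def test_summary_mentions_parameters(self):
        v = mm_velocity(self.S, 100.0, 100.0, 0.001)
        text = MichaelisMentenModel(self.S, v, 0.001).fit().summary()
        assert "kcat" in text and "Km" in text


class TestActivationModel:
    A = np.array([0.0, 6.25, 12.5, 25.0, 50.0, 100.0, 200.0])

    def test_reduces_to_mm_at_zero_compound(self, rng):
        for _ in range(20):
            kcat, km, beta, kact = rng.uniform(0.5, 300, size=4)
            S = rng.uniform(1, 500)
            assert activation_velocity(S, 0.0, kcat, km, beta, kact, 0.001) == (
                pytest.approx(mm_velocity(S, kcat, km, 0.001))
            )

    def test_direct_substitution(self):
        # S = 50, Km = 100, beta = 2, [A] = K_act: v = kcat E S (1+2)/ (100+100)
        v = activation_velocity(50.0, 162.0, 100.0, 100.0, 2.0, 162.0, 0.001)
        assert v == pytest.approx(100 * 0.001 * 50 * 3 / (100 + 50 * 2))
        assert v == pytest.approx(0.075)

    def test_saturating_compound_limit(self):
        # v -> beta * kcat * [E] for any fixed S > 0
        for S in (5.0, 50.0, 500.0):
            v = activation_velocity(S, 1e6 * 162.0, 100.0, 100.0, 2.0, 162.0, 0.001)
            assert v == pytest.approx(2.0 * 100.0 * 0.001, rel=1e-4)

    def test_noiseless_round_trip(self):
        S = np.full_like(self.A, 50.0)
        v = activation_velocity(S, self.A, 100.0, 100.0, 0.8424, 162.0, 0.001)
        res = ActivationModel(S, self.A, v, km_fixed=100.0, enzyme_conc=0.001).fit()
        assert res.beta == pytest.approx(0.8424, rel=1e-6)
        assert res.kact == pytest.approx(162.0, rel=1e-6)
        assert res.identifiable

    def test_free_kcat_policy_noiseless(self):
        S = np.full_like(self.A, 50.0)
        v = activation_velocity(S, self.A, 100.0, 100.0, 2.0, 80.0, 0.001)
        res = ActivationModel(S, self.A, v, km_fixed=100.0, enzyme_conc=0.001,
                              kcat_policy="free").fit()
        assert res.kcat == pytest.approx(100.0, rel=1e-5)
        assert res.kact == pytest.approx(80.0, rel=1e-5)

    def test_anchor_requires_zero_compound_points(self):
        A = self.A[1:]
        S = np.full_like(A, 50.0)
        v = activation_velocity(S, A, 100.0, 100.0, 2.0, 80.0, 0.001)
        with pytest.raises(ContractError, match=r"\[A\] = 0"):
            ActivationModel(S, A, v, km_fixed=100.0, enzyme_conc=0.001)


class TestDoseResponse:
    A = np.array([0.0, 1.0, 5.0, 10.0, 25.0, 50.0, 100.0, 200.0, 400.0])

    def test_noiseless_round_trip(self):
        y = dose_response_curve(self.A, 60.0, 0.5)
        res = DoseResponseModel(self.A, y).fit()
        assert res.ec50 == pytest.approx(60.0, rel=1e-6)
        assert res.amplitude == pytest.approx(0.5, rel=1e-6)

    def test_half_maximal_at_ec50(self):
        assert dose_response_curve(60.0, 60.0, 0.5) - 1 == pytest.approx(0.25)

    def test_inhibitor_direction_auto_detected(self):
        y = dose_response_curve(self.A, 57.0, -0.59)
        res = DoseResponseModel(self.A, y).fit()
        assert res.amplitude == pytest.approx(-0.59, rel=1e-6)

    def test_direction_constraint_enforced(self):
        y = dose_response_curve(self.A, 57.0, -0.59)
        res = DoseResponseModel(self.A, y, direction="inhibitor").fit()
        assert res.amplitude < 0

    def test_too_few_doses_rejected(self):
        with pytest.raises(InsufficientDataError):
            DoseResponseModel([0, 10, 20], [1, 1.1, 1.2])


class TestHitCalling:
    def _plate(self, effects_by_compound, v0=1.0, n_rep=3):
        rows = [
            {"compound_id": "control", "compound_uM": 0.0, "velocity": v0}
            for _ in range(n_rep)
        ]
        for cid, effects in effects_by_compound.items():
            for conc, eff in zip((0.5, 50.0, 100.0), effects):
                for _ in range(n_rep):
                    rows.append({"compound_id": cid, "compound_uM": conc,
                                 "velocity": v0 * (1 + eff)})
        return pd.DataFrame(rows)

    def test_graded_inhibitor_is_hit(self):
        calls = call_hits(self._plate({"c1": (-0.05, -0.25, -0.40)}))
        (call,) = calls
        assert call.dose_dependent
        assert call.max_effect == pytest.approx(-0.40)
        assert call.is_hit

    def test_weak_effect_is_not_hit(self):
        (call,) = call_hits(self._plate({"c1": (-0.01, -0.02, -0.03)}))
        assert call.dose_dependent
        assert not call.is_hit

    def test_sign_flips_break_dose_dependence(self):
        (call,) = call_hits(self._plate({"c1": (0.50, -0.40, 0.60)}))
        assert not call.dose_dependent
        assert not call.is_hit

    def test_scale_invariance_of_calls(self):
        plate = self._plate({"c1": (-0.05, -0.25, -0.40), "c2": (0.0, 0.1, 0.15)})
        base = call_hits(plate)
        scaled = plate.assign(velocity=plate.velocity * 37.5)
        assert [(c.compound_id, c.is_hit) for c in call_hits(scaled)] == [
            (c.compound_id, c.is_hit) for c in base
        ]

    def test_missing_control_rejected(self):
        plate = self._plate({"c1": (-0.05, -0.25, -0.40)})
        with pytest.raises(ContractError, match="control"):
            call_hits(plate[plate.compound_id != "control"])


class TestEfficiencyChange:
    def test_identity_is_zero(self):
        p = KineticParameters(kcat=100.0, km=100.0)
        assert efficiency_change(p, p)[0] == pytest.approx(0.0)

    def test_activation_arithmetic(self):
        with_c = KineticParameters(kcat=114.0, km=75.0)
        without = KineticParameters(kcat=100.0, km=100.0)
        assert efficiency_change(with_c, without)[0] == pytest.approx(52.0)

    def test_inhibition_arithmetic(self):
        with_c = KineticParameters(kcat=41.0, km=100.0)
        without = KineticParameters(kcat=100.0, km=100.0)
        assert efficiency_change(with_c, without)[0] == pytest.approx(-59.0)

    def test_ratio_antisymmetry(self, rng):
        for _ in range(20):
            a = KineticParameters(kcat=rng.uniform(1, 200), km=rng.uniform(1, 200))
            b = KineticParameters(kcat=rng.uniform(1, 200), km=rng.uniform(1, 200))
            d_ab = efficiency_change(a, b)[0]
            d_ba = efficiency_change(b, a)[0]
            assert (1 + d_ab / 100) * (1 + d_ba / 100) == pytest.approx(1.0)
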