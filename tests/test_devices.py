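"""Device emulation: curves, pulse programming, noise and bank handling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memtd import (
    DeviceBank,
    MemristorSynapse,
    SynapseArray,
    generate_synthetic_bank,
    generate_synthetic_curve,
    load_cycles_csv,
)
from memtd.devices import DeviceError

from conftest import cycles_frame, make_synapse


class TestCurveShape:
    def test_zero_nonlinearity_is_linear(self):
        c = generate_synthetic_curve(0.0, 0.0, n_pulses=200)
        p = np.linspace(0, 200, 11)
        np.testing.assert_allclose(c.pot(p), p / 200)
        np.testing.assert_allclose(c.dep(p), 1 - p / 200)

    @pytest.mark.parametrize("nu", [0.0, 0.5, 3.0, 8.0])
    def test_endpoints_normalized(self, nu):
        c = generate_synthetic_curve(nu, nu)
        assert c.pot(0) == pytest.approx(0.0)
        assert c.pot(c.n_pulses) == pytest.approx(1.0)
        assert c.dep(0) == pytest.approx(1.0)
        assert c.dep(c.n_pulses) == pytest.approx(0.0)

    def test_half_range_value_nu3(self):
        # (1 - e^-1.5) / (1 - e^-3)
        c = generate_synthetic_curve(3.0, 3.0, n_pulses=200)
        assert c.pot(100) == pytest.approx(0.81757448, abs=1e-6)

    @given(nu=st.floats(0, 6), w=st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_inverse_roundtrip(self, nu, w):
        c = generate_synthetic_curve(nu, nu)
        assert float(c.pot(c.pot_inv(w))) == pytest.approx(w, abs=1e-9)
        assert float(c.dep(c.dep_inv(w))) == pytest.approx(w, abs=1e-9)

    @pytest.mark.parametrize("kw", [
        dict(n_pulses=0), dict(sigma_update=-0.1),
        dict(sigma_cycle=-1e-9), dict(nu_pot=-1.0),
    ])
    def test_invalid_parameters_rejected(self, kw):
        base = dict(nu_pot=1.0, nu_dep=1.0, n_pulses=200,
                    sigma_update=0.0, sigma_cycle=0.0)
        base.update(kw)
        with pytest.raises(DeviceError):
            generate_synthetic_curve(**base)


class TestApplyPulses:
    def test_linear_noiseless_update(self, linear_curve):
        syn = make_synapse(linear_curve, 0.25)
        syn.apply_pulses(20)
        assert syn.weight == pytest.approx(0.35)

    def test_zero_pulses_is_identity(self, nonlinear_curve):
        syn = make_synapse(nonlinear_curve, 0.4)
        syn.apply_pulses(0)
        assert syn.weight == 0.4

    def test_nonlinear_update_from_zero(self, nonlinear_curve):
        # epsilon_1: the realized change 0.8175 exceeds the linear 0.5
        syn = make_synapse(nonlinear_curve, 0.0)
        syn.apply_pulses(100)
        assert syn.weight == pytest.approx(0.81757448, abs=1e-6)

    def test_saturation_clips_without_error(self, linear_curve):
        syn = make_synapse(linear_curve, 0.9)
        syn.apply_pulses(100)
        assert syn.weight == 1.0
        syn.apply_pulses(-1000)
        assert syn.weight == 0.0

    @given(nu=st.floats(0, 5), w0=st.floats(0, 1),
           dp=st.integers(-300, 300))
    @settings(max_examples=80, deadline=None)
    def test_noise_free_monotonicity(self, nu, w0, dp):
        c = generate_synthetic_curve(nu, nu)
        syn = make_synapse(c, w0)
        syn.apply_pulses(dp)
        if dp > 0:
            assert syn.weight >= w0 - 1e-12
        elif dp < 0:
            assert syn.weight <= w0 + 1e-12

    def test_linear_round_trip_away_from_saturation(self, linear_curve):
        syn = make_synapse(linear_curve, 0.5)
        syn.apply_pulses(30)
        syn.apply_pulses(-30)
        assert syn.weight == pytest.approx(0.5, abs=1e-12)

    def test_single_pulses_compose_linearly(self, linear_curve):
        one = make_synapse(linear_curve, 0.1)
        for _ in range(17):
            one.apply_pulses(1)
        batch = make_synapse(linear_curve, 0.1)
        batch.apply_pulses(17)
        assert one.weight == pytest.approx(batch.weight, abs=1e-12)

    def test_per_update_noise_mode_sd(self):
        c = generate_synthetic_curve(0.0, 0.0, sigma_update=0.02)
        deltas = []
        for seed in range(2000):
            syn = MemristorSynapse(c, 0.5, np.random.default_rng(seed),
                                   noise_mode="per_update")
            syn.apply_pulses(16)
            deltas.append(syn.weight - 0.58)
        assert np.std(deltas) == pytest.approx(0.02, rel=0.15)

    def test_sqrt_noise_mode_scales_with_pulses(self):
        c = generate_synthetic_curve(0.0, 0.0, sigma_update=0.005)
        deltas = []
        for seed in range(2000):
            syn = MemristorSynapse(c, 0.3, np.random.default_rng(seed))
            syn.apply_pulses(16)  # noise SD = 0.005 * 4
            deltas.append(syn.weight - 0.38)
        assert np.std(deltas) == pytest.approx(0.02, rel=0.15)


class TestRead:
    def test_noiseless_read_exact(self, nonlinear_curve):
        syn = make_synapse(nonlinear_curve, 0.37)
        assert syn.read(0.0) == 0.37

    def test_read_statistics(self, linear_curve):
        syn = make_synapse(linear_curve, 0.5, seed=7)
        reads = np.array([syn.read(0.01) for _ in range(10_000)])
        assert syn.weight == 0.5  # read never mutates
        assert reads.mean() == pytest.approx(0.5, abs=3 * 0.01 / 100)

    def test_read_clipped_at_bounds(self, linear_curve):
        syn = make_synapse(linear_curve, 1.0)
        assert all(syn.read(0.5) <= 1.0 for _ in range(100))

    def test_negative_sigma_rejected(self, linear_curve):
        syn = make_synapse(linear_curve, 0.5)
        with pytest.raises(DeviceError):
            syn.read(-0.01)


class TestSynapseArray:
    def test_matches_scalar_curve_math_noise_free(self):
        curves = [generate_synthetic_curve(nu, nu) for nu in (0.0, 2.0, 4.0)]
        arr = SynapseArray(curves, [0, 1, 2, 1], np.random.default_rng(0))
        arr.weights[:] = [0.2, 0.2, 0.2, 0.8]
        dp = np.array([10, 10, 10, -30])
        realized = arr.apply_pulses(dp)
        for i, (k, w0, d) in enumerate(zip([0, 1, 2, 1], [0.2, 0.2, 0.2, 0.8], dp)):
            syn = make_synapse(curves[k], w0)
            syn.apply_pulses(int(d))
            assert arr.weights[i] == pytest.approx(syn.weight, abs=1e-12)
            assert realized[i] == pytest.approx(syn.weight - w0, abs=1e-12)

    def test_weights_stay_in_unit_interval_under_noise(self):
        c = generate_synthetic_curve(2.0, 2.0, sigma_update=0.1)
        arr = SynapseArray([c], np.zeros(50, dtype=int),
                           np.random.default_rng(3))
        for _ in range(40):
            arr.apply_pulses(np.random.default_rng(1).integers(-40, 40, 50))
            assert np.all(arr.weights >= 0.0) and np.all(arr.weights <= 1.0)


class TestBank:
    def test_synthetic_bank_reproducible(self):
        b1 = generate_synthetic_bank(27, bank_seed=5)
        b2 = generate_synthetic_bank(27, bank_seed=5)
        assert len(b1.curves) == 27
        assert all(c1.nu_pot == c2.nu_pot and c1.sigma_update == c2.sigma_update
                   for c1, c2 in zip(b1.curves, b2.curves))

    def test_identity_assignment_when_enough_curves(self):
        bank = generate_synthetic_bank(27, bank_seed=0)
        np.testing.assert_array_equal(bank.assign(27), np.arange(27))

    def test_random_assignment_reuses_curves(self, rng):
        bank = generate_synthetic_bank(27, bank_seed=0)
        a = bank.assign(1089, rng)
        assert a.shape == (1089,)
        assert set(a) <= set(range(27))

    def test_json_round_trip(self, tmp_path):
        bank = generate_synthetic_bank(5, bank_seed=9)
        path = tmp_path / "bank.json"
        bank.to_json(path)
        back = DeviceBank.from_json(path)
        assert back.bank_seed == 9
        for c1, c2 in zip(bank.curves, back.curves):
            assert c1.nu_pot == c2.nu_pot
            assert c1.sigma_update == c2.sigma_update

    def test_sigma_override(self):
        bank = generate_synthetic_bank(5, bank_seed=0)
        low = bank.with_sigma_update(0.001)
        assert all(c.sigma_update == 0.001 for c in low.curves)
        assert bank.min_sigma_update >= 0.005


class TestLoadCyclesCsv:
    def _write(self, tmp_path, frames):
        path = tmp_path / "cycles.csv"
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
        return path

    def test_identical_cycles_zero_sigma(self, tmp_path):
        ramp = np.linspace(0, 1, 11)
        path = self._write(tmp_path, [
            cycles_frame(0, "pot", [ramp, ramp]),
            cycles_frame(0, "dep", [ramp[::-1], ramp[::-1]]),
        ])
        bank = load_cycles_csv(path)
        assert bank.curves[0].sigma_update == pytest.approx(0.0)
        np.testing.assert_allclose(bank.curves[0].pot_table, ramp)

    def test_plus_minus_c_cycles_give_sigma_c(self, tmp_path):
        ramp = np.linspace(0, 1, 21)
        c = 0.013
        path = self._write(tmp_path, [
            cycles_frame(0, "pot", [ramp + c, ramp - c]),
            cycles_frame(0, "dep", [ramp[::-1] + c, ramp[::-1] - c]),
        ])
        bank = load_cycles_csv(path)
        assert bank.curves[0].sigma_update == pytest.approx(c, abs=1e-12)

    def test_sigma_matches_brute_force_pooled_sd(self, tmp_path, rng):
        ramp = np.linspace(0, 1, 31)
        pot_cycles = [ramp + rng.normal(0, 0.02, ramp.size)
                      for _ in range(10)]
        dep_cycles = [ramp[::-1] + rng.normal(0, 0.02, ramp.size)
                      for _ in range(10)]
        path = self._write(tmp_path, [
            cycles_frame(0, "pot", pot_cycles),
            cycles_frame(0, "dep", dep_cycles),
        ])
        bank = load_cycles_csv(path)
        # independent brute-force oracle over the pooled deviation list
        devs = []
        for cycles in (pot_cycles, dep_cycles):
            mat = np.vstack(cycles)
            mean = mat.mean(axis=0)
            span = mean.max() - mean.min()
            devs.extend(((mat - mean) / span).ravel())
        assert bank.curves[0].sigma_update == pytest.approx(
            float(np.std(devs)), abs=1e-12)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"device_id": [0], "cycle_id": [0],
                      "pulse_index": [0], "weight": [0.0]}).to_csv(path, index=False)
        with pytest.raises(DeviceError, match="missing columns"):
            load_cycles_csv(path)

    def test_non_monotone_pulse_index_rejected(self, tmp_path):
        df = cycles_frame(0, "pot", [np.linspace(0, 1, 5)])
        df.loc[3, "pulse_index"] = 1  # duplicates an earlier index
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(DeviceError, match="non-monotone"):
            load_cycles_csv(path)

    def test_out_of_range_weight_rejected(self, tmp_path):
        df = cycles_frame(0, "pot", [np.array([0.0, 0.5, 1.3])])
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(DeviceError, match="row"):
            load_cycles_csv(path)

    def test_tabulated_bank_drives_synapse(self, tmp_path):
        ramp = np.linspace(0, 1, 201)
        path = self._write(tmp_path, [
            cycles_frame(0, "pot", [ramp]),
            cycles_frame(0, "dep", [ramp[::-1]]),
        ])
        bank = load_cycles_csv(path)
        syn = make_synapse(bank.curves[0], 0.25)
        syn.apply_pulses(20)
        assert syn.weight == pytest.approx(0.35, abs=1e-9)
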