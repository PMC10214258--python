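"""Device-model unit and property tests: dynamics, readout, serialization."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_pulse_programs
from egtrc.device import (
    DeviceTrace,
    EGTParams,
    GateState,
    Pulse,
    PulseTrain,
    RelaxationNotReached,
    default_params,
    paired_pulse_report,
    params_from_json,
    params_from_toml,
    params_to_json,
    params_to_toml,
    read_current,
    relaxation_time,
    rest_state,
    simulate,
    step,
    trace_from_csv,
    trace_to_csv,
    trains_from_jsonl,
    trains_to_jsonl,
)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"gamma": 0.5},
        {"tau0": 0.0},
        {"a_sat": -1.0},
        {"dt": 0.0},
        {"i_rest": 0.0},
        {"gate_jitter": 0.2},
        {"a_tau_cap": 0.0},
    ],
)
def test_invalid_params_rejected(kwargs):
    with pytest.raises(ValueError):
        EGTParams(**kwargs)


def test_rest_is_fixed_point(device):
    state = rest_state(device)
    out = step(state, np.zeros(device.n_gates), 50.0, device)
    assert np.allclose(out.a, 0.0)
    assert read_current(out, device) == pytest.approx(device.i_rest)


def test_closed_form_exponential_decay(device):
    """With state-independent tau, decay over one tau0 is exactly 1/e."""
    p = replace(device, tau_slope=0.0)
    state = GateState(a=np.array([1.0, 0.0]))
    out = step(state, np.zeros(2), p.tau0, p)
    assert out.a[0] == pytest.approx(math.exp(-1.0), rel=1e-12)


def test_positive_drive_is_inert(device):
    state = rest_state(device)
    out = step(state, np.array([1.5, 1.5]), 50.0, device)
    assert np.allclose(out.a, 0.0)


def test_subthreshold_drive_is_inert(device):
    state = rest_state(device)
    out = step(state, np.array([-0.2, 0.0]), 50.0, device)
    assert np.allclose(out.a, 0.0)


def test_drive_length_mismatch_rejected(device):
    with pytest.raises(ValueError):
        step(rest_state(device), np.array([-1.0]), 10.0, device)


@given(a0=st.floats(0.05, 3.5), h=st.floats(1.0, 3000.0))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_undriven_decay_is_monotone_and_positive(a0, h):
    p = default_params()
    state = GateState(a=np.array([a0 / 2, a0 / 2]))
    out = step(state, np.zeros(2), h, p)
    assert 0.0 <= out.a.sum() < a0
    # longer decay loses strictly more
    out2 = step(state, np.zeros(2), 2 * h, p)
    assert out2.a.sum() < out.a.sum()


def test_fading_memory_to_rest(device):
    """After 5x the slowest time constant, the current rise is below 1%."""
    state = GateState(a=np.full(2, device.a_sat / 2))
    peak_rise = read_current(state, device) - device.i_rest
    horizon = 5.0 * device.tau_of(device.a_sat)
    out = step(state, np.zeros(2), horizon, device)
    assert read_current(out, device) - device.i_rest < 0.01 * peak_rise


def test_step_matches_fine_integration(device):
    """Default-step integration tracks a 100x-finer reference to 0.1%."""
    rng = np.random.default_rng(3)
    fine = replace(device, dt=device.dt / 100.0)
    for trains in random_pulse_programs(10, rng):
        coarse_tr = simulate(trains, device, t_end=2500.0, sample_every=50.0)
        fine_tr = simulate(trains, fine, t_end=2500.0, sample_every=50.0)
        rel = np.abs(coarse_tr.i_ds - fine_tr.i_ds) / np.maximum(fine_tr.i_ds, 1.0)
        assert rel.max() < 1e-3


def test_read_current_monotone_convex(device):
    s = np.linspace(0.0, device.a_sat, 50)
    i = np.array([read_current(x, device) for x in s])
    assert i[0] == pytest.approx(device.i_rest)
    assert np.all(np.diff(i) > 0)
    assert np.all(np.diff(i, 2) > -1e-9)  # convex for gamma > 1


def test_supralinearity_algebra_gamma_two():
    """With gamma=2 equal increments on two gates give 4x, not 2x."""
    p = replace(default_params(), gamma=2.0)
    da = 0.3
    together = read_current(2 * da, p) - p.i_rest
    separate = 2 * (read_current(da, p) - p.i_rest)
    assert together == pytest.approx(2.0 * separate)


def test_simulate_empty_trains_flat(device):
    trace = simulate([], device, t_end=500.0, sample_every=50.0)
    assert np.allclose(trace.i_ds, device.i_rest)


def test_simulate_rejects_duplicate_channels(device):
    tr = PulseTrain("g1", (Pulse(0.0, 50.0, -1.0),))
    with pytest.raises(ValueError, match="distinct"):
        simulate([tr, tr], device, t_end=200.0, sample_every=50.0)


def test_simulate_rejects_excess_channels(device):
    trains = [PulseTrain(f"g{k}", ()) for k in range(device.n_gates + 1)]
    with pytest.raises(ValueError, match="gates"):
        simulate(trains, device, t_end=100.0, sample_every=50.0)


def test_pulse_train_overlap_rejected():
    with pytest.raises(ValueError, match="overlap"):
        PulseTrain("g1", (Pulse(0.0, 100.0, -1.0), Pulse(50.0, 50.0, -1.0)))


def test_gate_jitter_requires_rng():
    p = replace(default_params(), gate_jitter=0.05)
    tr = PulseTrain("g1", (Pulse(0.0, 50.0, -1.5),))
    with pytest.raises(ValueError, match="rng"):
        simulate([tr], p, t_end=200.0, sample_every=50.0)
    trace = simulate([tr], p, t_end=200.0, sample_every=50.0,
                     rng=np.random.default_rng(0))
    assert trace.i_ds.max() > p.i_rest


def test_higher_pulse_rate_builds_more_current(device):
    """Ten identical pulses: final current decreases with pulse interval."""
    finals = []
    for gap in (50.0, 150.0, 250.0, 350.0):
        period = 50.0 + gap
        train = PulseTrain(
            "g1", tuple(Pulse(k * period, 50.0, -1.5) for k in range(10))
        )
        t_read = 9 * period + 50.0 + 100.0
        trace = simulate([train], device, t_end=t_read, sample_times=[t_read])
        finals.append(trace.i_ds[-1])
    assert all(a > b for a, b in zip(finals, finals[1:]))


def test_sample_grid_matches_dense_output(device):
    """Coarse sampling returns the same values the dense trace holds."""
    train = PulseTrain("g1", (Pulse(0.0, 50.0, -1.5),))
    coarse = simulate([train], device, t_end=1000.0, sample_every=200.0)
    dense = simulate([train], device, t_end=1000.0, sample_every=10.0)
    dense_at = np.interp(coarse.times, dense.times, dense.i_ds)
    assert np.allclose(coarse.i_ds, dense_at, rtol=1e-3)


class TestRelaxationTime:
    def test_constant_trace_at_rest_is_zero(self, device):
        t = np.arange(0.0, 500.0, 10.0)
        trace = DeviceTrace(times=t, i_ds=np.full_like(t, device.i_rest))
        assert relaxation_time(trace, device) == 0.0

    def test_synthetic_exponential_closed_form(self, device):
        """i_rest + A*exp(-t/tau) settles at tau*ln(1/rel_tol)."""
        tau, amp = 300.0, 50.0
        t = np.arange(0.0, 3000.0, 5.0)
        trace = DeviceTrace(times=t, i_ds=device.i_rest + amp * np.exp(-t / tau))
        measured = relaxation_time(trace, device, rel_tol=0.05, t_stim_end=0.0)
        assert abs(measured - tau * math.log(20.0)) <= 5.0

    def test_unrelaxed_trace_signals_distinctly(self, device):
        t = np.arange(0.0, 200.0, 10.0)
        trace = DeviceTrace(times=t, i_ds=np.full_like(t, device.i_rest + 50.0))
        with pytest.raises(RelaxationNotReached):
            relaxation_time(trace, device, t_stim_end=0.0)

    def test_dual_gate_retention_outlasts_single(self, device):
        """Simultaneous dual-gate pulses relax much slower than one gate."""
        pulse = (Pulse(0.0, 50.0, -1.2),)
        single = simulate(
            [PulseTrain("g1", pulse)], device, t_end=3000.0, sample_every=10.0
        )
        dual = simulate(
            [PulseTrain("g1", pulse), PulseTrain("g2", pulse)],
            device, t_end=4000.0, sample_every=10.0,
        )
        t_single = relaxation_time(single, device, t_stim_end=50.0)
        t_dual = relaxation_time(dual, device, t_stim_end=50.0)
        assert t_dual > t_single


class TestPairedPulse:
    def test_default_amplitude_supralinear(self, device):
        report = paired_pulse_report(-1.2, 50.0, device)
        assert report.i12 > report.i1 + report.i2

    def test_zero_amplitude_all_zero(self, device):
        report = paired_pulse_report(0.0, 50.0, device)
        assert report.i1 == report.i2 == report.i12 == 0.0

    def test_positive_amplitude_rejected(self, device):
        with pytest.raises(ValueError):
            paired_pulse_report(1.2, 50.0, device)

    def test_linear_model_is_additive(self, device):
        """gamma=1 with saturation and decay-slowdown off: exact additivity."""
        p = replace(device, gamma=1.0, a_sat=1e9, tau_slope=0.0, tau0=500.0)
        report = paired_pulse_report(-1.2, 50.0, p)
        assert report.i12 == pytest.approx(report.i1 + report.i2, rel=1e-6)


def test_params_roundtrip_toml_json(device, tmp_path):
    params_to_toml(device, tmp_path / "dev.toml")
    params_to_json(device, tmp_path / "dev.json")
    assert params_from_toml(tmp_path / "dev.toml") == device
    assert params_from_json(tmp_path / "dev.json") == device


def test_trains_jsonl_roundtrip(tmp_path):
    trains = [
        PulseTrain("left", (Pulse(0.0, 50.0, -1.2), Pulse(300.0, 45.0, -1.2))),
        PulseTrain("right", ()),
    ]
    trains_to_jsonl(trains, tmp_path / "trains.jsonl")
    assert trains_from_jsonl(tmp_path / "trains.jsonl") == trains


def test_trace_csv_roundtrip(device, tmp_path):
    train = PulseTrain("g1", (Pulse(0.0, 50.0, -1.5),))
    trace = simulate([train], device, t_end=500.0, sample_every=50.0)
    trace_to_csv(trace, tmp_path / "trace.csv")
    back = trace_from_csv(tmp_path / "trace.csv")
    assert np.allclose(back.times, trace.times)
    assert np.allclose(back.i_ds, trace.i_ds, rtol=1e-8)
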