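"""Volatile multi-gate electrolyte-gated transistor (EGT) reservoir model.

The device is a p-type organic transistor whose channel conductance is
transiently enhanced by anions accumulating at the electrolyte/channel
interface under negative gate pulses, and relaxes spontaneously as the ions
diffuse back (short-term plasticity / fading memory).  Each gate ``i``
carries a dimensionless accumulation state ``a_i``; with ``S = sum(a)``:

* during a negative pulse of amplitude ``v`` (|v| > v_thresh) the gate
  accumulates at rate ``eta * (|v| / v_ref) * (1 - S / a_sat)`` — linear in
  drive, with a shared saturation ceiling ``a_sat``;
* all gates decay together, ``da_i/dt = -a_i / tau(S)`` with the
  state-dependent time constant
  ``tau(S) = tau0 + tau_slope * min(S, a_tau_cap)**tau_exp`` (default
  quadratic with a saturating slowdown) — stronger accumulation relaxes
  disproportionately slower, which is what stretches the dual-gate
  retention (≈1650 ms) well beyond the single-gate one (≈800 ms), while
  the bounded slowdown keeps later-firing pulse strings ahead of
  early-stacked ones (recency encoding);
* the shared channel reads out supralinearly,
  ``i_ds = i_rest + i_gain * S**gamma`` with ``gamma > 1``, so simultaneous
  multi-gate stimulation yields ``I_{1+2} > I_1 + I_2``.

The integrator is event-driven: across pulse-free spans the decay ODE is
solved exactly through its implicit closed form, while driven spans use
fixed-step RK4 with a substep that tracks the local decay constant.  At the
default ``dt`` = 10 ms it agrees with a 100x-finer reference to well within
0.1%.

Units: time in ms, current in nA, voltage in V; accumulation dimensionless.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "EGTParams",
    "GateState",
    "Pulse",
    "PulseTrain",
    "DeviceTrace",
    "SupralinearityReport",
    "RelaxationNotReached",
    "default_params",
    "step",
    "read_current",
    "simulate",
    "relaxation_time",
    "paired_pulse_report",
    "params_to_toml",
    "params_from_toml",
    "params_to_json",
    "params_from_json",
    "trains_to_jsonl",
    "trains_from_jsonl",
    "trace_to_csv",
    "trace_from_csv",
]


class RelaxationNotReached(RuntimeError):
    """The trace never settles back to the resting current."""


# Frozen one-time calibration against the printed device response
# (rest ~1 nA -> peak ~100 nA under -1.5 V/50 ms; 800 ms single-gate and
# 1650 ms simultaneous dual-gate (-1.2 V) relaxation to within 5% of the
# peak rise).  Produced by analysis/01_calibrate_device.py; see
# egtrc.calibrate.fit_device_params.
_CALIBRATED = {
    "i_gain": 172.123143,
    "tau0": 5.852624,
    "tau_slope": 2755.872303,
}


@dataclass(frozen=True)
class EGTParams:
    """Calibrated constants of the volatile device model.

    Attributes
    ----------
    i_rest : resting read current, nA.
    i_gain : current scale mapping accumulation to current rise, nA.
    gamma : supralinearity exponent of the readout (> 1).
    eta : accumulation rate at full reference drive, 1/ms.
    a_sat : saturation ceiling of the total accumulation.
    tau0 : decay time constant at zero accumulation, ms.
    tau_slope : decay slowdown, ms per (unit accumulation)**tau_exp.
    tau_exp : exponent of the state dependence of the decay constant.
    a_tau_cap : accumulation beyond which the decay slowdown saturates
        (``min(S, a_tau_cap)`` enters tau; ``inf`` disables the cap).
    v_thresh : minimum pulse magnitude that drives accumulation, V.
    v_ref : drive normalisation voltage, V.
    v_read : source-drain read bias, V (constant; its scale is absorbed
        into i_gain).
    dt : integration step, ms.
    n_gates : number of input gates.
    gate_jitter : relative s.d. of the per-gate eta (0 disables; applied
        only when an explicit rng is passed to :func:`simulate`).
    """

    i_rest: float = 1.0
    i_gain: float = _CALIBRATED["i_gain"]
    gamma: float = 3.0
    eta: float = 0.02
    a_sat: float = 4.0
    tau0: float = _CALIBRATED["tau0"]
    tau_slope: float = _CALIBRATED["tau_slope"]
    tau_exp: float = 2.0
    a_tau_cap: float = 0.88
    v_thresh: float = 0.3
    v_ref: float = 1.5
    v_read: float = 0.1
    dt: float = 10.0
    n_gates: int = 2
    gate_jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.gamma < 1.0:
            raise ValueError("gamma must be >= 1")
        if self.tau0 <= 0 or self.tau_slope < 0 or self.tau_exp <= 0:
            raise ValueError("tau0 > 0, tau_slope >= 0, tau_exp > 0 required")
        if self.a_tau_cap <= 0:
            raise ValueError("a_tau_cap must be > 0")
        if self.a_sat <= 0:
            raise ValueError("a_sat must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.i_rest <= 0:
            raise ValueError("i_rest must be > 0")
        if not 0.0 <= self.gate_jitter <= 0.1:
            raise ValueError("gate_jitter must lie in [0, 0.1]")
        if self.eta < 0 or self.v_ref <= 0 or self.v_thresh < 0:
            raise ValueError("eta >= 0, v_ref > 0, v_thresh >= 0 required")
        if self.n_gates < 1:
            raise ValueError("n_gates must be >= 1")

    def tau_of(self, s: float) -> float:
        """Decay time constant at total accumulation ``s``, ms."""
        return self.tau0 + self.tau_slope * min(s, self.a_tau_cap) ** self.tau_exp


def default_params() -> EGTParams:
    """The repository's frozen calibrated parameter set."""
    return EGTParams()


@dataclass
class GateState:
    """Per-gate accumulations ``a`` (>= 0, sum <= a_sat) at time ``t`` (ms)."""

    a: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        if np.any(self.a < -1e-12):
            raise ValueError("accumulations must be non-negative")

    @property
    def total(self) -> float:
        return float(self.a.sum())


def rest_state(params: EGTParams) -> GateState:
    return GateState(a=np.zeros(params.n_gates), t=0.0)


@dataclass(frozen=True)
class Pulse:
    """A timed gate-voltage pulse; negative amplitude is excitatory."""

    onset: float
    duration: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("pulse duration must be > 0")
        if self.onset < 0:
            raise ValueError("pulse onset must be >= 0")

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class PulseTrain:
    """Ordered, non-overlapping pulses on one input channel."""

    channel_id: str
    pulses: tuple[Pulse, ...]

    def __post_init__(self) -> None:
        pulses = tuple(sorted(self.pulses, key=lambda p: p.onset))
        object.__setattr__(self, "pulses", pulses)
        for prev, nxt in zip(pulses, pulses[1:]):
            if nxt.onset < prev.end - 1e-9:
                raise ValueError(
                    f"overlapping pulses on channel {self.channel_id!r} "
                    f"at t={nxt.onset} ms"
                )

    @property
    def t_last(self) -> float:
        return self.pulses[-1].end if self.pulses else 0.0


@dataclass(frozen=True)
class DeviceTrace:
    """Read current (nA) on a strictly increasing time grid (ms)."""

    times: np.ndarray
    i_ds: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "i_ds", np.asarray(self.i_ds, dtype=float))
        if self.times.shape != self.i_ds.shape:
            raise ValueError("times and i_ds must have the same length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class SupralinearityReport:
    """Peak current rises (nA): gates alone (i1, i2) and simultaneous (i12)."""

    i1: float
    i2: float
    i12: float

    @property
    def supralinear(self) -> bool:
        return self.i12 > self.i1 + self.i2


# ---------------------------------------------------------------------------
# Core integrator: exact sub-flows + Strang composition
# ---------------------------------------------------------------------------


def _decay_total(s0: float, h: float, params: EGTParams) -> float:
    """Total accumulation after decaying for ``h`` ms from ``s0``.

    Solves dS/dt = -S / tau(S) exactly: the implicit closed form
    tau0*ln(S0/S) + (tau_slope/e)*(S0**e - S**e) = h is inverted with a
    Newton iteration in log-space (monotone convergence for this concave
    residual).
    """
    if s0 <= 0.0 or h <= 0.0:
        return max(s0, 0.0)
    if params.tau_slope == 0.0:
        return s0 * math.exp(-h / params.tau0)
    e = params.tau_exp
    c = params.tau_slope
    cap = params.a_tau_cap
    if s0 > cap:
        # constant tau above the cap: exponential until S reaches the cap
        tau_c = params.tau0 + c * cap**e
        t_to_cap = tau_c * math.log(s0 / cap)
        if h <= t_to_cap:
            return s0 * math.exp(-h / tau_c)
        s0, h = cap, h - t_to_cap
    x0 = math.log(s0)
    se0 = s0**e
    # first Newton step from x0 (residual there is exactly -h)
    x = x0 - h / (params.tau0 + c * se0)
    for _ in range(80):
        ee = math.exp(e * x)
        psi = params.tau0 * (x0 - x) + (c / e) * (se0 - ee) - h
        dx = psi / (params.tau0 + c * ee)
        x += dx
        if abs(dx) < 1e-13:
            break
    return math.exp(x)


def _apply_decay(a: np.ndarray, h: float, params: EGTParams) -> None:
    s0 = float(a.sum())
    if s0 <= 0.0 or h <= 0.0:
        return
    s1 = _decay_total(s0, h, params)
    a *= s1 / s0


def _apply_accumulation(
    a: np.ndarray, rates: np.ndarray, h: float, params: EGTParams
) -> None:
    """Exact saturating accumulation flow (decay switched off)."""
    u_tot = float(rates.sum())
    if u_tot <= 0.0 or h <= 0.0:
        return
    s0 = float(a.sum())
    s1 = params.a_sat + (s0 - params.a_sat) * math.exp(-u_tot * h / params.a_sat)
    a += rates * ((s1 - s0) / u_tot)


def _drive_rates(drive: np.ndarray, params: EGTParams, eta_vec: np.ndarray) -> np.ndarray:
    """Per-gate accumulation rates for a gate-voltage vector.

    Only negative drives beyond the threshold excite; positive voltages are
    inert for this p-type channel.
    """
    mag = np.abs(drive)
    active = (drive < 0.0) & (mag > params.v_thresh)
    return np.where(active, eta_vec * (mag / params.v_ref), 0.0)


def _advance(
    a: np.ndarray,
    rates: np.ndarray,
    h: float,
    params: EGTParams,
) -> None:
    """Advance state in place over ``h`` ms under constant per-gate rates."""
    if h <= 0.0:
        return
    if not np.any(rates > 0.0):
        _apply_decay(a, h, params)
        return

    def deriv(state: np.ndarray) -> np.ndarray:
        s = float(state.sum())
        return rates * (1.0 - s / params.a_sat) - state / params.tau_of(s)

    # Classic RK4 on the coupled rise/decay ODE; near rest the decay
    # constant tau(S) can undercut the nominal step, so the substep tracks
    # it to stay out of the stiff regime.
    remaining = h
    while remaining > 1e-12:
        hs = min(remaining, 0.5 * params.dt,
                 0.25 * params.tau_of(float(a.sum())))
        k1 = deriv(a)
        k2 = deriv(a + 0.5 * hs * k1)
        k3 = deriv(a + 0.5 * hs * k2)
        k4 = deriv(a + hs * k3)
        a += (hs / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        np.clip(a, 0.0, None, out=a)
        remaining -= hs


def step(
    state: GateState,
    drive: Sequence[float],
    dt: float,
    params: EGTParams,
) -> GateState:
    """One integration step under a constant per-gate drive voltage.

    Gates with negative drive beyond ``v_thresh`` accumulate with the
    shared saturation factor; all gates then relax with the common
    state-dependent time constant.  Returns a new state at ``t + dt``.
    """
    drive = np.asarray(drive, dtype=float)
    if drive.shape != (params.n_gates,):
        raise ValueError(
            f"drive must have {params.n_gates} entries, got shape {drive.shape}"
        )
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if state.a.shape != (params.n_gates,):
        raise ValueError("state has wrong number of gates")
    a = state.a.copy()
    rates = _drive_rates(drive, params, np.full(params.n_gates, params.eta))
    _advance(a, rates, dt, params)
    return GateState(a=a, t=state.t + dt)


def read_current(state: GateState | float, params: EGTParams) -> float:
    """Shared-channel read current (nA): i_rest + i_gain * S**gamma."""
    s = state.total if isinstance(state, GateState) else float(state)
    return params.i_rest + params.i_gain * s**params.gamma


# ---------------------------------------------------------------------------
# Trace-level simulation
# ---------------------------------------------------------------------------


def simulate(
    trains: Sequence[PulseTrain],
    params: EGTParams,
    t_end: float,
    sample_every: float | None = None,
    sample_times: Sequence[float] | None = None,
    rng: np.random.Generator | None = None,
    state0: GateState | None = None,
) -> DeviceTrace:
    """Integrate the device from rest under per-channel pulse trains.

    ``trains[k]`` drives gate ``k``.  The integrator is event-driven:
    between pulse edges the drive is constant and the exact sub-flows
    apply, so accuracy does not degrade with long gaps.  Sampling defaults
    to a grid every ``sample_every`` ms starting at 0 (``params.dt`` if
    neither argument is given); pass explicit ``sample_times`` to override.

    Deterministic unless ``params.gate_jitter > 0``, in which case an
    explicit ``rng`` must be supplied for the per-gate rate heterogeneity.
    ``state0`` overrides the rest initial condition (used e.g. to probe the
    echo-state property).
    """
    ids = [tr.channel_id for tr in trains]
    if len(set(ids)) != len(ids):
        raise ValueError("channel_ids must be distinct")
    if len(trains) > params.n_gates:
        raise ValueError(
            f"{len(trains)} trains exceed the {params.n_gates} device gates"
        )
    for tr in trains:
        if tr.t_last > t_end + 1e-9:
            raise ValueError(
                f"t_end={t_end} ms does not cover the last pulse on "
                f"channel {tr.channel_id!r} (ends {tr.t_last} ms)"
            )

    eta_vec = np.full(params.n_gates, params.eta)
    if params.gate_jitter > 0.0:
        if rng is None:
            raise ValueError("gate_jitter > 0 requires an explicit rng")
        eta_vec = eta_vec * np.clip(
            1.0 + params.gate_jitter * rng.standard_normal(params.n_gates),
            0.1,
            None,
        )

    if sample_times is None:
        se = sample_every if sample_every is not None else params.dt
        sample_times = np.arange(0.0, t_end + 1e-9, se)
    sample_times = np.asarray(sample_times, dtype=float)
    if sample_times.size == 0:
        raise ValueError("no sample times requested")
    if np.any(sample_times < 0) or np.any(sample_times > t_end + 1e-9):
        raise ValueError("sample times must lie in [0, t_end]")

    # Edge events: (time, order, gate, amplitude-or-None).  Pulse ends are
    # processed before onsets so back-to-back pulses hand over cleanly.
    events: list[tuple[float, int, int, float | None]] = []
    for gate, tr in enumerate(trains):
        for p in tr.pulses:
            events.append((p.onset, 1, gate, p.amplitude))
            events.append((p.end, 0, gate, None))
    events.sort(key=lambda ev: (ev[0], ev[1]))

    breaks = np.unique(
        np.concatenate(
            [sample_times, [0.0, t_end], [ev[0] for ev in events]]
        )
    )
    breaks = breaks[(breaks >= 0.0) & (breaks <= t_end + 1e-9)]
    is_sample = np.isin(breaks, sample_times)

    if state0 is not None:
        if state0.a.shape != (params.n_gates,):
            raise ValueError("state0 has wrong number of gates")
        a = state0.a.astype(float).copy()
    else:
        a = np.zeros(params.n_gates)
    amp = np.zeros(params.n_gates)  # currently applied gate voltages
    out_t: list[float] = []
    out_i: list[float] = []
    ev_idx = 0
    t_prev = breaks[0]

    def _process_events_at(t: float) -> None:
        nonlocal ev_idx
        while ev_idx < len(events) and events[ev_idx][0] <= t + 1e-9:
            _, kind, gate, value = events[ev_idx]
            amp[gate] = 0.0 if kind == 0 else float(value)
            ev_idx += 1

    _process_events_at(t_prev)
    if is_sample[0]:
        out_t.append(float(t_prev))
        out_i.append(read_current(float(a.sum()), params))
    for k in range(1, len(breaks)):
        t_next = breaks[k]
        rates = _drive_rates(amp, params, eta_vec)
        _advance(a, rates, float(t_next - t_prev), params)
        _process_events_at(t_next)
        if is_sample[k]:
            out_t.append(float(t_next))
            out_i.append(read_current(float(a.sum()), params))
        t_prev = t_next

    return DeviceTrace(times=np.array(out_t), i_ds=np.array(out_i))


def relaxation_time(
    trace: DeviceTrace,
    params: EGTParams,
    rel_tol: float = 0.05,
    t_stim_end: float | None = None,
) -> float:
    """Time (ms) from end of stimulation until the current stays at rest.

    "At rest" means within ``rel_tol * (peak - i_rest)`` of ``i_rest``.
    ``t_stim_end`` defaults to the time of the trace maximum (the peak of a
    pulse response sits at the last pulse's end).  Raises
    :class:`RelaxationNotReached` if the trace never settles.
    """
    i = trace.i_ds
    peak = float(i.max())
    if t_stim_end is None:
        t_stim_end = float(trace.times[int(np.argmax(i))])
    thresh = rel_tol * (peak - params.i_rest)
    dev = np.abs(i - params.i_rest)
    start = int(np.searchsorted(trace.times, t_stim_end - 1e-9))
    suffix_max = np.maximum.accumulate(dev[::-1])[::-1]
    settled = np.flatnonzero(suffix_max[start:] <= thresh + 1e-12)
    if settled.size == 0:
        raise RelaxationNotReached(
            f"current never stays within {rel_tol:.0%} of the peak rise"
        )
    return float(trace.times[start + settled[0]] - t_stim_end)


def paired_pulse_report(
    amplitude: float,
    width: float,
    params: EGTParams,
) -> SupralinearityReport:
    """Peak current rises for gate 1 alone, gate 2 alone, both together.

    With ``gamma > 1`` the simultaneous response exceeds the sum of the
    individual ones (supralinear multi-gate integration).
    """
    if amplitude > 0:
        raise ValueError("amplitude must be <= 0 (excitatory pulses)")
    if params.n_gates < 2:
        raise ValueError("paired-pulse protocol needs at least two gates")
    pulse = (Pulse(onset=0.0, duration=width, amplitude=amplitude),)
    empty: tuple[Pulse, ...] = ()
    t_end = width + 100.0

    def _peak_rise(pulses_by_gate: tuple[tuple[Pulse, ...], ...]) -> float:
        trains = [
            PulseTrain(channel_id=f"g{k + 1}", pulses=p)
            for k, p in enumerate(pulses_by_gate)
        ]
        tr = simulate(trains, params, t_end=t_end, sample_every=min(params.dt, width))
        return float(tr.i_ds.max() - params.i_rest)

    i1 = _peak_rise((pulse, empty))
    i2 = _peak_rise((empty, pulse))
    i12 = _peak_rise((pulse, pulse))
    return SupralinearityReport(i1=i1, i2=i2, i12=i12)


# ---------------------------------------------------------------------------
# Serialization: TOML/JSON parameters, JSON Lines pulse trains, CSV traces
# ---------------------------------------------------------------------------

_UNIT_KEYS = {
    "i_rest": "i_rest_nA",
    "i_gain": "i_gain_nA",
    "gamma": "gamma",
    "eta": "eta_per_ms",
    "a_sat": "a_sat",
    "tau0": "tau0_ms",
    "tau_slope": "tau_slope_ms",
    "tau_exp": "tau_exp",
    "a_tau_cap": "a_tau_cap",
    "v_thresh": "v_thresh_V",
    "v_ref": "v_ref_V",
    "v_read": "v_read_V",
    "dt": "dt_ms",
    "n_gates": "n_gates",
    "gate_jitter": "gate_jitter",
}


def _params_dict(params: EGTParams) -> dict:
    return {unit: getattr(params, name) for name, unit in _UNIT_KEYS.items()}


def _params_from_dict(d: dict) -> EGTParams:
    inverse = {unit: name for name, unit in _UNIT_KEYS.items()}
    kwargs = {inverse[k]: v for k, v in d.items() if k in inverse}
    return EGTParams(**kwargs)


def params_to_toml(params: EGTParams, path: str | Path) -> None:
    lines = ["[device]"]
    for key, value in _params_dict(params).items():
        lines.append(f"{key} = {value!r}" if isinstance(value, int) else f"{key} = {value}")
    Path(path).write_text("\n".join(lines) + "\n")


def params_from_toml(path: str | Path) -> EGTParams:
    import tomllib

    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return _params_from_dict(data["device"])


def params_to_json(params: EGTParams, path: str | Path) -> None:
    Path(path).write_text(json.dumps({"device": _params_dict(params)}, indent=2))


def params_from_json(path: str | Path) -> EGTParams:
    data = json.loads(Path(path).read_text())
    return _params_from_dict(data["device"])


def trains_to_jsonl(trains: Iterable[PulseTrain], path: str | Path) -> None:
    with open(path, "w") as fh:
        for tr in trains:
            fh.write(
                json.dumps(
                    {
                        "channel_id": tr.channel_id,
                        "pulses": [
                            {
                                "onset_ms": p.onset,
                                "duration_ms": p.duration,
                                "amplitude_V": p.amplitude,
                            }
                            for p in tr.pulses
                        ],
                    }
                )
                + "\n"
            )


def trains_from_jsonl(path: str | Path) -> list[PulseTrain]:
    trains = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            trains.append(
                PulseTrain(
                    channel_id=d["channel_id"],
                    pulses=tuple(
                        Pulse(p["onset_ms"], p["duration_ms"], p["amplitude_V"])
                        for p in d["pulses"]
                    ),
                )
            )
    return trains


def trace_to_csv(trace: DeviceTrace, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_ms", "i_ds_nA"])
        for t, i in zip(trace.times, trace.i_ds):
            writer.writerow([f"{t:.6g}", f"{i:.9g}"])


def trace_from_csv(path: str | Path) -> DeviceTrace:
    times, i_ds = [], []
    with open(path) as fh:
        reader = csv.reader(fh)
        next(reader)
        for row in reader:
            times.append(float(row[0]))
            i_ds.append(float(row[1]))
    return DeviceTrace(times=np.array(times), i_ds=np.array(i_ds))
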