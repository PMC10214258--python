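"""Synthetic dual-channel gait pressure-event streams and their transduction.

Four gait classes are emulated as timed foot–ground contact events (~50 ms
contacts, class-specific cadence, uniform jitter on durations and gaps):

* WALKING — strictly alternating left/right steps at a steady cadence;
* JUMPING — both feet land simultaneously, at a lower frequency;
* FSG (festinating gait) — alternating steps whose gaps shrink across the
  sample (the patient speeds up), with occasional double landings;
* FOG (freezing of gait) — irregular stepping that mixes alternating and
  simultaneous landings and is interrupted by at least one freeze of the
  order of seconds before walking resumes.

Contacts are transduced into gate-voltage pulses by the resistive
pressure-sensor voltage divider (V0 = 3.3 V source, R0 = 4 kOhm series
resistor): pressing the sensor drops its resistance to ``rs_on`` and the
voltage across the transistor gate becomes -V0*R0/(rs_on + R0); unloaded,
the drive is negligible and is clamped to zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .device import Pulse, PulseTrain

__all__ = [
    "GaitClass",
    "GaitGenParams",
    "ContactStream",
    "CircuitParams",
    "GaitSample",
    "divider_amplitude",
    "make_contacts",
    "contacts_to_trains",
    "generate_dataset",
    "split_dataset",
    "dataset_to_jsonl",
    "dataset_from_jsonl",
    "dataset_manifest",
]


class GaitClass(str, Enum):
    WALKING = "WALKING"
    JUMPING = "JUMPING"
    FSG = "FSG"
    FOG = "FOG"


Contact = tuple[float, float]  # (onset ms, duration ms)


@dataclass(frozen=True)
class GaitGenParams:
    """Generator settings; defaults are the study conditions.

    contact_ms : mean foot-ground contact duration (ms).
    interval_ms : base gap between successive contacts for alternating
        gaits (ms; must stay within 300 ms).
    duration_s : sample length (s).
    jitter_frac : relative uniform jitter on contact durations and gaps.
    jump_interval_ms : gap between simultaneous jumps (lower frequency
        than walking).
    fsg_interval0_ms / fsg_accel : festinating gait starts at the base
        gap and shrinks linearly by the fractional amount across the
        sample.
    fsg_double_prob : per-step probability of a simultaneous landing.
    fog_freeze_ms : (lo, hi) freeze-gap duration range (ms).
    fog_sync_prob : probability a FOG step lands on both feet.
    """

    contact_ms: float = 50.0
    interval_ms: float = 250.0
    duration_s: float = 6.0
    jitter_frac: float = 0.2
    jump_interval_ms: float = 450.0
    fsg_interval0_ms: float = 300.0
    fsg_accel: float = 0.6
    fsg_double_prob: float = 0.1
    fog_freeze_ms: tuple[float, float] = (1000.0, 2000.0)
    fog_sync_prob: float = 0.3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.contact_ms <= 0:
            raise ValueError("contact_ms must be > 0")
        if not 0 < self.interval_ms <= 300:
            raise ValueError("interval_ms must lie in (0, 300] ms")
        if not 0 <= self.jitter_frac <= 0.5:
            raise ValueError("jitter_frac must lie in [0, 0.5]")
        for p in (self.fsg_double_prob, self.fog_sync_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0 <= self.fsg_accel < 1:
            raise ValueError("fsg_accel must lie in [0, 1)")
        lo, hi = self.fog_freeze_ms
        if not 0 < lo <= hi:
            raise ValueError("fog_freeze_ms must be an increasing positive range")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")

    @property
    def duration_ms(self) -> float:
        return self.duration_s * 1000.0


@dataclass(frozen=True)
class ContactStream:
    """Per-foot (onset, duration) contact events, sorted, non-overlapping."""

    left: tuple[Contact, ...]
    right: tuple[Contact, ...]

    def __post_init__(self) -> None:
        for name in ("left", "right"):
            events = tuple(sorted(getattr(self, name)))
            object.__setattr__(self, name, events)
            for (o1, d1), (o2, _) in zip(events, events[1:]):
                if o2 < o1 + d1 - 1e-9:
                    raise ValueError(f"overlapping contacts on {name} foot")

    def all_onsets(self) -> np.ndarray:
        return np.sort(np.array([o for o, _ in self.left + self.right]))


@dataclass(frozen=True)
class CircuitParams:
    """Pressure-sensor voltage-divider circuit (V0, R0 from the setup)."""

    v0: float = 3.3
    r0: float = 4000.0
    rs_on: float = 7000.0
    rs_off: float = 1.0e7

    def __post_init__(self) -> None:
        if self.v0 <= 0 or self.r0 <= 0 or self.rs_on <= 0:
            raise ValueError("v0, r0 and rs_on must be positive")
        if self.rs_off < 10 * self.rs_on:
            raise ValueError("rs_off must be much larger than rs_on")


def divider_amplitude(circuit: CircuitParams, loaded: bool = True) -> float:
    """Gate voltage from the divider: -V0*R0/(Rs + R0)."""
    rs = circuit.rs_on if loaded else circuit.rs_off
    return -circuit.v0 * circuit.r0 / (rs + circuit.r0)


@dataclass(frozen=True)
class GaitSample:
    """One labelled classification instance: contacts plus derived trains."""

    gait_class: GaitClass
    contacts: ContactStream
    trains: tuple[PulseTrain, PulseTrain]
    sample_id: str
    seed_used: int
    duration_ms: float = 6000.0


def _jittered(base: float, jitter_frac: float, rng: np.random.Generator) -> float:
    return base * (1.0 + jitter_frac * (2.0 * rng.random() - 1.0))


def make_contacts(
    gait_class: GaitClass,
    params: GaitGenParams,
    rng: np.random.Generator,
) -> ContactStream:
    """Draw one contact-event stream for the given gait class."""
    t_max = params.duration_ms
    left: list[Contact] = []
    right: list[Contact] = []
    feet = (left, right)

    def gap(base: float) -> float:
        return _jittered(base, params.jitter_frac, rng)

    def dur() -> float:
        return _jittered(params.contact_ms, params.jitter_frac, rng)

    t = float(rng.uniform(0.0, 100.0))
    foot = int(rng.integers(2))

    if gait_class is GaitClass.WALKING:
        while True:
            d = dur()
            if t + d > t_max:
                break
            feet[foot].append((t, d))
            foot = 1 - foot
            t += d + gap(params.interval_ms)

    elif gait_class is GaitClass.JUMPING:
        while True:
            d = dur()
            if t + d > t_max:
                break
            left.append((t, d))
            right.append((t, d))
            t += d + gap(params.jump_interval_ms)

    elif gait_class is GaitClass.FSG:
        while True:
            d = dur()
            if t + d > t_max:
                break
            if rng.random() < params.fsg_double_prob:
                left.append((t, d))
                right.append((t, d))
            else:
                feet[foot].append((t, d))
            foot = 1 - foot
            progress = t / t_max
            base = params.fsg_interval0_ms * (1.0 - params.fsg_accel * progress)
            t += d + gap(base)

    elif gait_class is GaitClass.FOG:
        # schedule 1-2 freezes; the first is placed early enough that the
        # longest freeze still leaves room to resume stepping afterwards
        freeze_hi = params.fog_freeze_ms[1]
        first_hi = max(t_max - freeze_hi - 800.0, 900.0)
        freeze_at = [float(rng.uniform(min(800.0, 0.5 * first_hi), first_hi))]
        if rng.random() < 0.35:
            freeze_at.append(float(rng.uniform(first_hi, t_max)))
        next_freeze = 0
        while True:
            d = dur()
            if t + d > t_max:
                break
            if next_freeze < len(freeze_at) and t >= freeze_at[next_freeze]:
                freeze = float(rng.uniform(*params.fog_freeze_ms))
                next_freeze += 1
                # a freeze only counts if stepping can resume before the end
                if t + freeze + 600.0 <= t_max:
                    t += freeze
                    continue
            if rng.random() < params.fog_sync_prob:
                left.append((t, d))
                right.append((t, d))
            else:
                feet[foot].append((t, d))
            foot = 1 - foot
            t += d + gap(params.interval_ms)

    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"unknown gait class {gait_class!r}")

    return ContactStream(left=tuple(left), right=tuple(right))


def contacts_to_trains(
    contacts: ContactStream,
    circuit: CircuitParams = CircuitParams(),
    v_thresh: float = 0.3,
    channel_ids: tuple[str, str] = ("left", "right"),
) -> tuple[PulseTrain, PulseTrain]:
    """Transduce contacts through the divider into gate-voltage trains.

    During a contact the gate sees -V0*R0/(rs_on + R0); off-contact the
    divider output is below the device threshold and is clamped to zero
    (no pulse emitted).
    """
    amp_on = divider_amplitude(circuit, loaded=True)
    amp_off = divider_amplitude(circuit, loaded=False)
    if abs(amp_off) >= v_thresh:
        raise ValueError(
            "off-contact divider output exceeds the device threshold; "
            "the stream is not representable as discrete pulses"
        )
    trains = tuple(
        PulseTrain(
            channel_id=cid,
            pulses=tuple(Pulse(onset, d, amp_on) for onset, d in events),
        )
        for cid, events in zip(channel_ids, (contacts.left, contacts.right))
    )
    return trains  # type: ignore[return-value]


def generate_dataset(
    n_per_class: int,
    params: GaitGenParams = GaitGenParams(),
    master_seed: int = 0,
    circuit: CircuitParams = CircuitParams(),
) -> list[GaitSample]:
    """Class-balanced labelled dataset, bit-for-bit reproducible.

    Child seeds are spawned deterministically from ``master_seed`` (one per
    sample), so any sample can be regenerated independently.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    children = np.random.SeedSequence(master_seed).spawn(4 * n_per_class)
    samples: list[GaitSample] = []
    idx = 0
    for gait_class in GaitClass:
        for k in range(n_per_class):
            child = children[idx]
            rng = np.random.default_rng(child)
            contacts = make_contacts(gait_class, params, rng)
            trains = contacts_to_trains(contacts, circuit)
            samples.append(
                GaitSample(
                    gait_class=gait_class,
                    contacts=contacts,
                    trains=trains,
                    sample_id=f"{gait_class.value}_{k:04d}",
                    seed_used=int(child.generate_state(1)[0]),
                    duration_ms=params.duration_ms,
                )
            )
            idx += 1
    return samples


def split_dataset(
    samples: Sequence[GaitSample],
    train_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[list[GaitSample], list[GaitSample]]:
    """Stratified-by-class shuffle split into disjoint train/test lists.

    Per class the training count is ``round(n * train_fraction)``
    (round-half-even), clipped so that both sides keep at least one sample.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train: list[GaitSample] = []
    test: list[GaitSample] = []
    for gait_class in GaitClass:
        members = [s for s in samples if s.gait_class is gait_class]
        if not members:
            continue
        if len(members) < 2:
            raise ValueError(
                f"class {gait_class.value} has fewer than 2 samples"
            )
        order = rng.permutation(len(members))
        n_train = int(np.clip(round(len(members) * train_fraction), 1,
                              len(members) - 1))
        train.extend(members[i] for i in order[:n_train])
        test.extend(members[i] for i in order[n_train:])
    return train, test


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def _sample_to_dict(sample: GaitSample) -> dict:
    return {
        "sample_id": sample.sample_id,
        "label": sample.gait_class.value,
        "seed_used": sample.seed_used,
        "duration_ms": sample.duration_ms,
        "contacts": {
            "left": [list(c) for c in sample.contacts.left],
            "right": [list(c) for c in sample.contacts.right],
        },
        "trains": [
            {
                "channel_id": tr.channel_id,
                "pulses": [
                    {"onset_ms": p.onset, "duration_ms": p.duration,
                     "amplitude_V": p.amplitude}
                    for p in tr.pulses
                ],
            }
            for tr in sample.trains
        ],
    }


def _sample_from_dict(d: dict) -> GaitSample:
    trains = tuple(
        PulseTrain(
            channel_id=tr["channel_id"],
            pulses=tuple(
                Pulse(p["onset_ms"], p["duration_ms"], p["amplitude_V"])
                for p in tr["pulses"]
            ),
        )
        for tr in d["trains"]
    )
    return GaitSample(
        gait_class=GaitClass(d["label"]),
        contacts=ContactStream(
            left=tuple(tuple(c) for c in d["contacts"]["left"]),
            right=tuple(tuple(c) for c in d["contacts"]["right"]),
        ),
        trains=trains,  # type: ignore[arg-type]
        sample_id=d["sample_id"],
        seed_used=d["seed_used"],
        duration_ms=d.get("duration_ms", 6000.0),
    )


def dataset_to_jsonl(samples: Iterable[GaitSample], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample in samples:
            fh.write(json.dumps(_sample_to_dict(sample)) + "\n")


def dataset_from_jsonl(path: str | Path) -> list[GaitSample]:
    samples = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                samples.append(_sample_from_dict(json.loads(line)))
    return samples


def dataset_manifest(
    samples: Sequence[GaitSample],
    split: tuple[Sequence[GaitSample], Sequence[GaitSample]] | None = None,
) -> pd.DataFrame:
    """Manifest table (sample_id, class, split)."""
    assignment: dict[str, str] = {}
    if split is not None:
        train, test = split
        assignment.update({s.sample_id: "train" for s in train})
        assignment.update({s.sample_id: "test" for s in test})
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "class": [s.gait_class.value for s in samples],
            "split": [assignment.get(s.sample_id, "") for s in samples],
        }
    )
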