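"""Gait-synthesis tests: class grammar, transduction, dataset protocol."""

import json

import numpy as np
import pytest

from egtrc.gait import (
    CircuitParams,
    ContactStream,
    GaitClass,
    GaitGenParams,
    contacts_to_trains,
    dataset_from_jsonl,
    dataset_manifest,
    dataset_to_jsonl,
    divider_amplitude,
    generate_dataset,
    make_contacts,
    split_dataset,
)


def _onsets(events):
    return np.array([o for o, _ in events])


def _streams(gait_class, params, n=50, seed0=100):
    return [
        make_contacts(gait_class, params, np.random.default_rng(seed0 + k))
        for k in range(n)
    ]


class TestClassGrammar:
    def test_walking_alternates_never_synchronized(self, gait_params):
        for s in _streams(GaitClass.WALKING, gait_params):
            shared = set(_onsets(s.left)) & set(_onsets(s.right))
            assert not shared
            # alternation: merged onsets switch feet every step
            merged = sorted(
                [(o, "L") for o in _onsets(s.left)]
                + [(o, "R") for o in _onsets(s.right)]
            )
            feet = [f for _, f in merged]
            assert all(a != b for a, b in zip(feet, feet[1:]))

    def test_jumping_fully_synchronized_and_slower(self, gait_params):
        walk_rate, jump_rate = [], []
        for cls, rates in (
            (GaitClass.JUMPING, jump_rate),
            (GaitClass.WALKING, walk_rate),
        ):
            for s in _streams(cls, gait_params, n=25):
                if cls is GaitClass.JUMPING:
                    assert np.array_equal(_onsets(s.left), _onsets(s.right))
                landings = np.unique(
                    np.concatenate([_onsets(s.left), _onsets(s.right)])
                )
                rates.append(len(landings))
        # jumping lands at a lower cadence than walking steps
        assert np.mean(jump_rate) < 0.75 * np.mean(walk_rate)

    def test_fsg_speeds_up_across_sample(self, gait_params):
        for s in _streams(GaitClass.FSG, gait_params):
            onsets = np.sort(
                np.unique(np.concatenate([_onsets(s.left), _onsets(s.right)]))
            )
            gaps = np.diff(onsets)
            third = len(gaps) // 3
            assert gaps[-third:].mean() < gaps[:third].mean()

    def test_fog_contains_a_freeze_gap(self, gait_params):
        lo = gait_params.fog_freeze_ms[0]
        for s in _streams(GaitClass.FOG, gait_params):
            onsets = np.sort(np.concatenate([_onsets(s.left), _onsets(s.right)]))
            assert np.max(np.diff(onsets)) >= lo

    def test_contact_durations_within_jitter_band(self, gait_params):
        lo = gait_params.contact_ms * (1 - gait_params.jitter_frac)
        hi = gait_params.contact_ms * (1 + gait_params.jitter_frac)
        for cls in GaitClass:
            for s in _streams(cls, gait_params, n=10):
                for _, d in s.left + s.right:
                    assert lo - 1e-9 <= d <= hi + 1e-9

    def test_alternating_gait_intervals_within_300ms(self, gait_params):
        """Walking inter-contact gaps respect the 300 ms design bound."""
        cap = 300.0 * (1 + gait_params.jitter_frac)
        for s in _streams(GaitClass.WALKING, gait_params, n=25):
            events = sorted(s.left + s.right)
            for (o1, d1), (o2, _) in zip(events, events[1:]):
                assert o2 - (o1 + d1) <= cap + 1e-9

    def test_zero_jitter_walking_is_periodic(self, gait_params):
        from dataclasses import replace

        p = replace(gait_params, jitter_frac=0.0)
        s = make_contacts(GaitClass.WALKING, p, np.random.default_rng(5))
        onsets = np.sort(np.concatenate([_onsets(s.left), _onsets(s.right)]))
        assert np.std(np.diff(onsets)) == pytest.approx(0.0, abs=1e-9)

    def test_all_events_inside_sample_window(self, gait_params):
        for cls in GaitClass:
            for s in _streams(cls, gait_params, n=10):
                for o, d in s.left + s.right:
                    assert 0.0 <= o and o + d <= gait_params.duration_ms


class TestTransduction:
    def test_divider_closed_form(self):
        c = CircuitParams(v0=3.3, r0=4000.0, rs_on=7000.0)
        assert divider_amplitude(c) == pytest.approx(-1.2)

    def test_divider_monotone_in_sensor_resistance(self):
        amps = [
            abs(divider_amplitude(CircuitParams(rs_on=r)))
            for r in (2000.0, 7000.0, 20000.0)
        ]
        assert amps[0] > amps[1] > amps[2]

    def test_off_contact_drive_negligible(self):
        assert abs(divider_amplitude(CircuitParams(), loaded=False)) < 0.01

    def test_contacts_map_onto_pulses(self):
        contacts = ContactStream(
            left=((0.0, 50.0), (300.0, 45.0)), right=((150.0, 55.0),)
        )
        left, right = contacts_to_trains(contacts)
        assert [(p.onset, p.duration) for p in left.pulses] == [
            (0.0, 50.0), (300.0, 45.0)
        ]
        assert all(p.amplitude == pytest.approx(-1.2) for p in left.pulses)
        assert len(right.pulses) == 1

    def test_empty_contacts_give_empty_trains(self):
        left, right = contacts_to_trains(ContactStream(left=(), right=()))
        assert left.pulses == () and right.pulses == ()

    def test_overlapping_same_foot_contacts_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ContactStream(left=((0.0, 100.0), (50.0, 50.0)), right=())


class TestDatasetProtocol:
    def test_balanced_counts(self, gait_params):
        samples = generate_dataset(5, gait_params, master_seed=0)
        assert len(samples) == 20
        for cls in GaitClass:
            assert sum(s.gait_class is cls for s in samples) == 5

    def test_bit_for_bit_reproducible(self, gait_params, tmp_path):
        a = generate_dataset(5, gait_params, master_seed=123)
        b = generate_dataset(5, gait_params, master_seed=123)
        dataset_to_jsonl(a, tmp_path / "a.jsonl")
        dataset_to_jsonl(b, tmp_path / "b.jsonl")
        assert (tmp_path / "a.jsonl").read_text() == (tmp_path / "b.jsonl").read_text()

    def test_different_seeds_differ(self, gait_params):
        a = generate_dataset(5, gait_params, master_seed=1)
        b = generate_dataset(5, gait_params, master_seed=2)
        assert any(x.contacts != y.contacts for x, y in zip(a, b))

    def test_split_stratified_disjoint_exhaustive(self, gait_params):
        samples = generate_dataset(8, gait_params, master_seed=7)
        train, test = split_dataset(samples, 0.5, seed=0)
        assert len(train) == len(test) == 16
        for cls in GaitClass:
            assert sum(s.gait_class is cls for s in train) == 4
        ids = {s.sample_id for s in train} | {s.sample_id for s in test}
        assert len(ids) == 32 and not (
            {s.sample_id for s in train} & {s.sample_id for s in test}
        )

    def test_split_identical_under_same_seed(self, gait_params):
        samples = generate_dataset(4, gait_params, master_seed=7)
        s1 = split_dataset(samples, 0.5, seed=3)
        s2 = split_dataset(samples, 0.5, seed=3)
        assert [x.sample_id for x in s1[0]] == [x.sample_id for x in s2[0]]

    def test_split_rounding_small_n(self, gait_params):
        """Inexact stratification rounds deterministically per class."""
        samples = generate_dataset(3, gait_params, master_seed=7)
        train, test = split_dataset(samples, 0.4, seed=0)
        # round(3 * 0.4) = 1 per class, 4 classes
        assert len(train) == 4 and len(test) == 8

    def test_split_rejects_tiny_class(self, gait_params):
        samples = generate_dataset(1, gait_params, master_seed=0)
        with pytest.raises(ValueError, match="fewer than 2"):
            split_dataset(samples, 0.5, seed=0)

    def test_jsonl_roundtrip_preserves_samples(self, gait_params, tmp_path):
        samples = generate_dataset(2, gait_params, master_seed=11)
        dataset_to_jsonl(samples, tmp_path / "ds.jsonl")
        back = dataset_from_jsonl(tmp_path / "ds.jsonl")
        assert back == samples

    def test_manifest_columns(self, gait_params):
        samples = generate_dataset(2, gait_params, master_seed=1)
        split = split_dataset(samples, 0.5, seed=0)
        mf = dataset_manifest(samples, split)
        assert list(mf.columns) == ["sample_id", "class", "split"]
        assert set(mf["split"]) == {"train", "test"}


def test_invalid_gen_params_rejected():
    with pytest.raises(ValueError):
        GaitGenParams(interval_ms=400.0)
    with pytest.raises(ValueError):
        GaitGenParams(jitter_frac=0.8)
    with pytest.raises(ValueError):
        GaitGenParams(fog_freeze_ms=(2000.0, 1000.0))
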