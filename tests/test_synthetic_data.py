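import json

import numpy as np
import pytest

from arhar import eda
from arhar.ar_model import extract_features, simulate_ar
from arhar.exceptions import ParameterError
from arhar.signal_io import read_recording, remove_gravity, segment
from arhar.synthetic_data import (
    DEFAULT_ACTIVITIES,
    GeneratorConfig,
    PositionTransform,
    default_position_transforms,
    generate_dataset,
    generate_recording,
    jitter_profile,
    make_default_profiles,
)

MOVEMENT = [a for a in DEFAULT_ACTIVITIES if a != "standing"]


class TestProfiles:
    def test_every_axis_process_is_stable(self, default_profiles):
        for profile in default_profiles:
            for axis in range(3):
                assert profile.axis_model(axis).is_stable(), profile.activity_name

    def test_same_seed_reproduces_profiles(self):
        p1 = make_default_profiles(order=10, seed=3)
        p2 = make_default_profiles(order=10, seed=3)
        for a, b in zip(p1, p2):
            np.testing.assert_array_equal(a.ar_coefficients, b.ar_coefficients)
            np.testing.assert_array_equal(a.innovation_variances, b.innovation_variances)

    def test_walking_signal_strongly_autocorrelated(self, walking_profile):
        x = simulate_ar(walking_profile.axis_model(0), 2000, seed=7)
        acf = eda.autocorrelation(x, max_lag=1, normalized=True, demean=True)
        assert acf.values[1] > 0.5

    def test_all_movement_profiles_autocorrelated(self, default_profiles):
        for profile in default_profiles:
            if profile.activity_name == "standing":
                continue
            x = simulate_ar(profile.axis_model(0), 2000, seed=11)
            acf = eda.autocorrelation(x, max_lag=1, normalized=True, demean=True)
            assert acf.values[1] > 0.5, profile.activity_name

    def test_requested_order_respected(self):
        for order in (4, 10):
            for profile in make_default_profiles(order=order, seed=0):
                assert profile.order == order


class TestPositions:
    def test_default_transforms_are_valid_and_five(self):
        transforms = default_position_transforms()
        assert len(transforms) == 5
        for t in transforms:
            np.testing.assert_allclose(t.rotation @ t.rotation.T, np.eye(3), atol=1e-8)
            assert np.all(t.gain > 0)

    def test_non_orthonormal_rotation_rejected(self):
        with pytest.raises(ParameterError):
            PositionTransform("bad", np.eye(3) * 2.0, np.ones(3), np.zeros(3))


class TestGenerateRecording:
    def test_identity_transform_is_process_plus_gravity(self, walking_profile):
        identity = PositionTransform("flat", np.eye(3), np.ones(3), np.zeros(3))
        rec = generate_recording(
            walking_profile, identity, subject_seed=5, duration=10.0, jitter=0.0
        )
        rng = np.random.default_rng(5)
        _ = jitter_profile(walking_profile, 0.0, rng)
        seeds = rng.integers(0, 2**31 - 1, size=3)
        raw = np.column_stack(
            [
                simulate_ar(walking_profile.axis_model(j), 200, seed=int(seeds[j]))
                for j in range(3)
            ]
        )
        expected = raw + 9.81 * walking_profile.gravity_orientation
        np.testing.assert_allclose(rec.samples, expected, atol=1e-12)

    def test_movement_activity_autocorrelated_after_gravity_removal(self, walking_profile):
        rec = generate_recording(
            walking_profile, default_position_transforms()[0], subject_seed=2,
            duration=30.0,
        )
        clean = remove_gravity(rec)
        acf = eda.autocorrelation(clean.x, max_lag=1, normalized=True, demean=True)
        assert acf.values[1] > 0.5

    def test_positions_change_signal_but_not_label(self, walking_profile):
        t1, t2 = default_position_transforms()[:2]
        r1 = generate_recording(walking_profile, t1, subject_seed=9, duration=10.0)
        r2 = generate_recording(walking_profile, t2, subject_seed=9, duration=10.0)
        assert np.max(np.abs(r1.samples - r2.samples)) > 0
        assert r1.activity_label == r2.activity_label == "walking"

    def test_too_short_duration_rejected(self, walking_profile):
        with pytest.raises(ParameterError):
            generate_recording(
                walking_profile, default_position_transforms()[0],
                subject_seed=0, duration=0.5,
            )

    def test_jittered_profiles_remain_stable(self, walking_profile):
        rng = np.random.default_rng(0)
        for _ in range(20):
            jittered = jitter_profile(walking_profile, 0.2, rng)
            for axis in range(3):
                assert jittered.axis_model(axis).is_stable()


class TestGenerateDataset:
    def test_product_count(self):
        config = GeneratorConfig(n_subjects=2, session_seconds=10.0, seed=1)
        recs = generate_dataset(config)
        assert len(recs) == 2 * 6 * 5

    def test_same_master_seed_reproduces_corpus(self):
        config = GeneratorConfig(n_subjects=1, session_seconds=10.0, seed=4)
        c1 = generate_dataset(config)
        c2 = generate_dataset(config)
        for a, b in zip(c1, c2):
            np.testing.assert_array_equal(a.samples, b.samples)

    def test_corpus_written_with_manifest(self, tmp_path):
        config = GeneratorConfig(n_subjects=1, session_seconds=10.0, seed=2)
        generate_dataset(config, out_dir=tmp_path)
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert len(manifest["recordings"]) == 30
        first = manifest["recordings"][0]
        rec = read_recording(tmp_path / first["file"])
        assert rec.activity_label == first["activity"]

    def test_disjoint_subject_ranges(self):
        train = generate_dataset(GeneratorConfig(n_subjects=2, session_seconds=10.0, seed=0))
        evaluation = generate_dataset(
            GeneratorConfig(n_subjects=1, first_subject=2, session_seconds=10.0, seed=0)
        )
        train_subjects = {r.subject_id for r in train}
        eval_subjects = {r.subject_id for r in evaluation}
        assert not (train_subjects & eval_subjects)


def _corpus_features(recordings, order=10):
    features, labels = [], []
    for rec in recordings:
        clean = remove_gravity(rec)
        for window in segment(clean, window_seconds=3.0):
            fv = extract_features(window, order=order)
            features.append(fv.values)
            labels.append(fv.activity_label)
    return np.asarray(features), np.asarray(labels)


class TestCorpusGeometry:
    def test_activities_separable_at_zero_jitter(self):
        config = GeneratorConfig(
            n_subjects=1, session_seconds=15.0, seed=3, subject_jitter=0.0,
            orientation_wobble_degrees=0.0, gain_jitter=0.0,
            positions=(PositionTransform("flat", np.eye(3), np.ones(3), np.zeros(3)),),
        )
        x, labels = _corpus_features(generate_dataset(config))
        centroids = {c: x[labels == c].mean(axis=0) for c in np.unique(labels)}
        for cls in np.unique(labels):
            within = np.linalg.norm(x[labels == cls] - centroids[cls], axis=1).mean()
            between = min(
                np.linalg.norm(centroids[cls] - centroids[other])
                for other in centroids if other != cls
            )
            assert between > within, cls

    def test_positions_increase_within_class_scatter(self):
        base = dict(n_subjects=1, session_seconds=15.0, seed=3, subject_jitter=0.0)
        single = GeneratorConfig(
            positions=(default_position_transforms()[0],),
            orientation_wobble_degrees=0.0, gain_jitter=0.0, **base,
        )
        multi = GeneratorConfig(**base)

        def within_trace(config):
            x, labels = _corpus_features(generate_dataset(config))
            total = 0.0
            for cls in np.unique(labels):
                xc = x[labels == cls]
                total += ((xc - xc.mean(axis=0)) ** 2).sum(axis=0).sum() / xc.shape[0]
            return total

        assert within_trace(multi) > within_trace(single)
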