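"""Tests for trajectory distances, reference libraries and validation."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ttcoach import coaching, dmm
from ttcoach import lstm_core as lc
from ttcoach.dataio import ScalerParams, StrokeSequence
from ttcoach.dmm import LatentTrajectory


def _traj(z, subject="coach", skill="forehand_stroke", rep=0, split="train"):
    return LatentTrajectory(subject, skill, rep, split, np.asarray(z, float))


class TestTrajectoryDistance:
    def test_identical_is_zero(self, rng):
        z = rng.normal(size=(9, 2))
        assert coaching.trajectory_distance(_traj(z), _traj(z)) == 0.0
        assert coaching.trajectory_distance(z, z, method="dtw") == 0.0

    def test_constant_offset_gives_offset_norm(self, rng):
        z = rng.normal(size=(12, 3))
        delta = np.array([0.3, -0.4, 1.2])
        d = coaching.trajectory_distance(z, z + delta)
        assert abs(d - np.linalg.norm(delta)) < 1e-12

    def test_symmetric_across_lengths(self, rng):
        a, b = rng.normal(size=(9, 2)), rng.normal(size=(14, 2))
        assert coaching.trajectory_distance(a, b) == coaching.trajectory_distance(b, a)

    def test_triangle_inequality_over_random_triples(self, rng):
        for _ in range(100):
            a, b, c = (rng.normal(size=(8, 2)) for _ in range(3))
            dab = coaching.trajectory_distance(a, b)
            dbc = coaching.trajectory_distance(b, c)
            dac = coaching.trajectory_distance(a, c)
            assert dac <= dab + dbc + 1e-12

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a=arrays(float, (7, 2), elements=st.floats(-5, 5)),
        b=arrays(float, (11, 2), elements=st.floats(-5, 5)),
    )
    def test_metric_properties_hold_for_arbitrary_trajectories(self, a, b):
        d = coaching.trajectory_distance(a, b)
        assert d >= 0.0
        assert d == coaching.trajectory_distance(b, a)
        assert coaching.trajectory_distance(a, a) == 0.0

    def test_latent_dim_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="latent_dim"):
            coaching.trajectory_distance(
                rng.normal(size=(5, 2)), rng.normal(size=(5, 3))
            )

    def test_resampling_aligns_time_scales(self):
        """A trajectory and its linear 2x upsampling are distance ~0."""
        t9 = np.linspace(0, 1, 9)
        t17 = np.linspace(0, 1, 17)
        a = np.stack([t9, t9**1], axis=1)
        b = np.stack([t17, t17**1], axis=1)
        assert coaching.trajectory_distance(a, b) < 1e-12


class TestLibraryAndValidation:
    def _library(self, rng, n_cells=4, n_train=5, T=8, L=2, spread=0.05):
        """Well-separated synthetic cells on a circle."""
        cells = [("coach", f"s{i}") for i in range(n_cells // 2)] + [
            ("beginner", f"s{i}") for i in range(n_cells - n_cells // 2)
        ]
        train, test = [], []
        for j, (subj, skill) in enumerate(cells):
            center = 3.0 * np.array([np.cos(j), np.sin(j)])
            base = center + 0.3 * rng.normal(size=(T, L))
            for r in range(n_train):
                train.append(
                    _traj(base + spread * rng.normal(size=(T, L)), subj, skill, r)
                )
            for r in range(2):
                test.append(
                    _traj(base + spread * rng.normal(size=(T, L)), subj, skill,
                          r, "test")
                )
        return coaching.ReferenceLibrary.build(train), train, test

    def test_summary_is_pointwise_mean(self, rng):
        lib, train, _ = self._library(rng)
        cell = ("coach", "s0")
        mine = np.mean(
            [t.z for t in train if (t.subject_id, t.skill_id) == cell], axis=0
        )
        assert np.allclose(lib.summaries[cell], mine)

    def test_validation_passes_when_test_equals_train(self, rng):
        lib, train, _ = self._library(rng)
        as_test = [dataclasses.replace(t, split="test") for t in train]
        res = coaching.holdout_validate(lib, as_test)
        assert all(v["passed"] for v in res.values())
        assert all(v["margin"] > 0 for v in res.values())

    def test_validation_on_separated_cells(self, rng):
        lib, _, test = self._library(rng)
        res = coaching.holdout_validate(lib, test)
        assert all(v["passed"] for v in res.values())

    def test_shuffled_labels_fail_validation(self, rng):
        lib, _, test = self._library(rng, n_cells=6)
        rolled = [
            dataclasses.replace(
                t,
                subject_id=test[(i + 2) % len(test)].subject_id,
                skill_id=test[(i + 2) % len(test)].skill_id,
            )
            for i, t in enumerate(test)
        ]
        res = coaching.holdout_validate(lib, rolled)
        assert sum(v["passed"] for v in res.values()) <= len(res) // 2

    def test_empty_cell_warns_and_skips(self, rng):
        lib, _, test = self._library(rng)
        partial = [t for t in test if t.skill_id != "s0" or t.subject_id != "coach"]
        with pytest.warns(UserWarning, match="no test trajectories"):
            res = coaching.holdout_validate(lib, partial)
        assert ("coach", "s0") not in res


class TestCoachCompare:
    def _bundle(self, rng):
        clf = lc.init_params("bi", hidden=4, input_size=18, seed=0)
        gen = dmm.GenerativeParams.create(2, 8, hidden=8, rng=rng)
        inf = dmm.InferenceParams.create(2, 8, summary_dim=6, hidden=8, rng=rng)
        scaler = ScalerParams(np.zeros(18), np.ones(18))
        trajs = [
            _traj(rng.normal(size=(27, 2)), subj, skill, r)
            for subj in ("coach", "beginner")
            for skill in ("forehand_stroke", "forehand_drive")
            for r in range(3)
        ]
        lib = coaching.ReferenceLibrary.build(trajs)
        return coaching.PipelineBundle(scaler, clf, gen, inf, lib)

    def test_report_ranking_consistent_with_distances(self, rng):
        bundle = self._bundle(rng)
        stroke = StrokeSequence(
            "beginner", "forehand_drive", 0, "test", rng.uniform(size=(27, 18))
        )
        rep = coaching.coach_compare(stroke, bundle)
        dists = [rep.distances[c] for c in rep.ranking]
        assert dists == sorted(dists)
        assert rep.closest == rep.ranking[0]
        assert all(d >= 0 for d in dists)

    def test_query_distance_matches_direct_computation(self, rng):
        bundle = self._bundle(rng)
        stroke = StrokeSequence(
            "coach", "forehand_stroke", 0, "test", rng.uniform(size=(27, 18))
        )
        rep = coaching.coach_compare(stroke, bundle)
        emb = dmm.embed_sequence(bundle.classifier, stroke.samples)
        z = dmm.infer_trajectory(bundle.gen, bundle.inf, emb)
        cell = ("coach", "forehand_stroke")
        direct = coaching.trajectory_distance(z, bundle.library.summaries[cell])
        assert rep.distances[cell] == direct

    def test_empty_library_raises(self, rng):
        bundle = self._bundle(rng)
        bundle.library.summaries.clear()
        stroke = StrokeSequence(
            "coach", "forehand_stroke", 0, "test", rng.uniform(size=(27, 18))
        )
        with pytest.raises(ValueError, match="empty"):
            coaching.coach_compare(stroke, bundle)

    def test_inconsistent_bundle_rejected(self, rng):
        clf = lc.init_params("bi", hidden=4, input_size=18, seed=0)
        gen = dmm.GenerativeParams.create(2, 5, rng=rng)  # wrong obs_dim
        inf = dmm.InferenceParams.create(2, 5, rng=rng)
        with pytest.raises(ValueError, match="inconsistent bundle"):
            coaching.PipelineBundle(
                ScalerParams(np.zeros(18), np.ones(18)), clf, gen, inf,
                coaching.ReferenceLibrary(),
            )


class TestRendering:
    def test_ten_panels_and_byte_stable(self, tmp_path, rng):
        trajs = []
        for subj in ("coach", "beginner"):
            for skill in ("s0", "s1", "s2", "s3", "s4"):
                for r, split in [(0, "train"), (1, "test")]:
                    trajs.append(_traj(rng.normal(size=(9, 2)), subj, skill, r, split))
        p1 = coaching.render_trajectories(trajs, tmp_path / "a")
        p2 = coaching.render_trajectories(trajs, tmp_path / "b")
        assert len(p1) == 10
        for f1, f2 in zip(p1, p2):
            with open(f1, "rb") as a, open(f2, "rb") as b:
                assert a.read() == b.read()

    def test_empty_raises(self, tmp_path):
        with pytest.raises(ValueError, match="no trajectories"):
            coaching.render_trajectories([], tmp_path)
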