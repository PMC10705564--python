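"""Pose search, clustering and merging."""

from __future__ import annotations

import numpy as np
import pytest

from glowives import geometry
from glowives.mol_io import Atom, Ligand, Pose, Receptor, make_provenance
from glowives.sampling import (PoseSet, SamplerConfig, SearchBox, cluster_poses,
                               merge_pose_sets, sample_poses)
from glowives.scoring import ScoringParams
from glowives.synthetic import make_ligand


def _single_atom_ligand():
    return Ligand([Atom("C", [0.0, 0.0, 0.0], 1.7, 0)], [])


def _single_atom_receptor(coords=(0.0, 0.0, 0.0), element="C"):
    key = ("A", 1, "")
    atom = Atom(element, list(coords), 1.7, 0, residue_id=key)
    return Receptor([atom], {key: [0]})


class TestSearchBox:
    def test_validation(self):
        with pytest.raises(ValueError):
            SearchBox((0, 0, 0), (1.0, -1.0, 1.0))

    def test_autobox_contains_coords(self, rng):
        coords = rng.normal(size=(10, 3)) * 2
        box = SearchBox.around(coords, margin=4.0)
        for c in coords:
            assert box.contains(c)


class TestSamplerConfig:
    def test_zero_steps_rejected(self):
        with pytest.raises(ValueError, match="steps"):
            SamplerConfig(n_steps=0)

    def test_positive_fields_enforced(self):
        with pytest.raises(ValueError):
            SamplerConfig(max_poses=0)
        with pytest.raises(ValueError):
            SamplerConfig(temperature=0.0)


class TestSamplePoses:
    def test_empty_receptor_scores_zero(self, fast_sampler):
        ligand = make_ligand("rigid4")
        receptor = Receptor([], {})
        box = SearchBox((0, 0, 0), (5, 5, 5))
        ps = sample_poses(receptor, ligand, box, ScoringParams(), fast_sampler)
        assert len(ps) >= 1
        assert ps.best.score == pytest.approx(0.0, abs=1e-12)

    def test_same_seed_is_bitwise_identical(self, holo_complex, holo_box,
                                            fast_sampler, normal_params):
        receptor, ligand, _ = holo_complex
        a = sample_poses(receptor, ligand, holo_box, normal_params, fast_sampler)
        b = sample_poses(receptor, ligand, holo_box, normal_params, fast_sampler)
        assert len(a) == len(b)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.coords, pb.coords)
            assert pa.score == pb.score
            assert pa.provenance == pb.provenance

    def test_single_atom_beats_grid_oracle(self):
        # exhaustive 0.1 Å translation grid is the oracle for a 1-atom ligand
        receptor = _single_atom_receptor()
        ligand = _single_atom_ligand()
        box = SearchBox((1.5, 0.0, 0.0), (1.6, 1.6, 1.6))
        params = ScoringParams()
        config = SamplerConfig(seed=2, n_chains=4, n_steps=400)
        ps = sample_poses(receptor, ligand, box, params, config)
        grid_best = _grid_oracle_best(receptor, ligand, box, params)
        assert ps.best.score <= grid_best + 0.05

    def test_rigid_ligand_beats_grid_oracle(self, holo_complex, holo_box):
        # translation-only grid at the reference orientation bounds the optimum
        receptor, _, reference = holo_complex
        ligand = make_ligand("rigid4")
        params = ScoringParams()
        config = SamplerConfig(seed=2, n_chains=4, n_steps=400)
        ps = sample_poses(receptor, ligand, holo_box, params, config)
        grid_best = _grid_oracle_best(receptor, ligand, holo_box, params,
                                      step=0.2)
        assert ps.best.score <= grid_best + 0.05

    def test_ligand_larger_than_box_rejected(self, holo_complex, normal_params,
                                             fast_sampler):
        receptor, ligand, _ = holo_complex
        tiny = SearchBox((0, 0, 0), (0.5, 0.5, 0.5))
        with pytest.raises(ValueError, match="bounding radius"):
            sample_poses(receptor, ligand, tiny, normal_params, fast_sampler)

    def test_poses_stay_in_box_and_are_separated(self, holo_complex, holo_box,
                                                 fast_sampler, normal_params):
        receptor, ligand, _ = holo_complex
        ps = sample_poses(receptor, ligand, holo_box, normal_params, fast_sampler)
        heavy = ligand.heavy_indices
        perms = geometry.automorphisms(ligand)
        for pose in ps:
            assert holo_box.contains(pose.coords[heavy].mean(axis=0))
        for i in range(len(ps)):
            for j in range(i + 1, len(ps)):
                rmsd = geometry.min_rmsd_over_perms(
                    ps[i].coords[heavy], ps[j].coords[heavy], perms)
                assert rmsd > fast_sampler.cluster_cutoff

    def test_scores_sorted_and_consistent(self, holo_complex, holo_box,
                                          fast_sampler, normal_params):
        receptor, ligand, _ = holo_complex
        ps = sample_poses(receptor, ligand, holo_box, normal_params, fast_sampler)
        scores = [p.score for p in ps]
        assert scores == sorted(scores)
        for rank, pose in enumerate(ps):
            assert pose.provenance["rank"] == rank
            assert pose.provenance["potential"] == "normal"


def _grid_oracle_best(receptor, ligand, box, params, step=0.1):
    from glowives.scoring import ScoringContext
    ctx = ScoringContext(receptor, ligand, params)
    center = np.asarray(box.center, float)
    half = np.asarray(box.half_widths, float)
    axes = [np.arange(c - h, c + h + step / 2, step)
            for c, h in zip(center, half)]
    template = ligand.coords - ligand.coords[ligand.heavy_indices].mean(axis=0)
    best = np.inf
    for x in axes[0]:
        for y in axes[1]:
            for z in axes[2]:
                e = ctx.total(template + np.array([x, y, z]))
                if e < best:
                    best = e
    return best


def _pose_at(ligand, offset, score):
    return Pose(ligand.coords + np.asarray(offset, float), score,
                make_provenance("normal"))


class TestClusterPoses:
    def test_duplicates_collapse_to_best(self):
        ligand = make_ligand("rigid4")
        poses = [_pose_at(ligand, (0, 0, 0), -5.0), _pose_at(ligand, (0, 0, 0), -4.0)]
        kept = cluster_poses(poses, 1.0, ligand)
        assert len(kept) == 1
        assert kept[0].score == -5.0

    def test_distant_poses_all_kept(self):
        ligand = make_ligand("rigid4")
        poses = [_pose_at(ligand, (5 * k, 0, 0), float(k)) for k in range(4)]
        assert len(cluster_poses(poses, 1.0, ligand)) == 4

    def test_matches_bruteforce_leader_oracle(self, rng):
        ligand = make_ligand("flex6")
        heavy = ligand.heavy_indices
        perms = geometry.automorphisms(ligand)
        poses = sorted((_pose_at(ligand, rng.normal(scale=1.2, size=3), float(k))
                        for k in range(10)), key=lambda p: p.score)
        cutoff = 1.5
        kept = cluster_poses(poses, cutoff, ligand)
        # independent reimplementation
        oracle: list[Pose] = []
        for p in poses:
            if all(geometry.min_rmsd_over_perms(p.coords[heavy],
                                                q.coords[heavy], perms) > cutoff
                   for q in oracle):
                oracle.append(p)
        assert [id(p) for p in kept] == [id(p) for p in oracle]

    def test_negative_cutoff_rejected(self):
        ligand = make_ligand("rigid4")
        with pytest.raises(ValueError, match="negative|non-negative"):
            cluster_poses([_pose_at(ligand, (0, 0, 0), 0.0)], -1.0, ligand)

    def test_unsorted_input_rejected(self):
        ligand = make_ligand("rigid4")
        poses = [_pose_at(ligand, (0, 0, 0), 1.0), _pose_at(ligand, (9, 0, 0), 0.0)]
        with pytest.raises(ValueError, match="sorted"):
            cluster_poses(poses, 1.0, ligand)


class TestMergePoseSets:
    def _set(self, ligand, offsets, scores):
        poses = sorted((_pose_at(ligand, o, s) for o, s in zip(offsets, scores)),
                       key=lambda p: p.score)
        return PoseSet(poses, ligand)

    def test_self_merge_is_idempotent(self):
        ligand = make_ligand("rigid4")
        s = self._set(ligand, [(0, 0, 0), (6, 0, 0)], [-2.0, -1.0])
        merged = merge_pose_sets([s, s], cutoff=0.5, max_poses=None)
        assert len(merged) == 2
        np.testing.assert_array_equal(merged[0].coords, s[0].coords)

    def test_merge_with_empty_is_identity(self):
        ligand = make_ligand("rigid4")
        s = self._set(ligand, [(0, 0, 0), (6, 0, 0)], [-2.0, -1.0])
        empty = PoseSet([], ligand)
        merged = merge_pose_sets([s, empty], cutoff=0.5, max_poses=None)
        assert [p.score for p in merged] == [-2.0, -1.0]

    def test_zero_cutoff_keeps_all_sorted(self):
        ligand = make_ligand("rigid4")
        a = self._set(ligand, [(k * 3, 0, 0) for k in range(5)],
                      [-5.0, -4.0, -3.0, -2.0, -1.0])
        b = self._set(ligand, [(k * 3, 20, 0) for k in range(5)],
                      [-4.5, -3.5, -2.5, -1.5, -0.5])
        merged = merge_pose_sets([a, b], cutoff=0.0, max_poses=None)
        scores = [p.score for p in merged]
        assert len(merged) == 10
        assert scores == sorted(scores)

    def test_mixed_ligands_rejected(self):
        a = self._set(make_ligand("rigid4"), [(0, 0, 0)], [0.0])
        b = self._set(make_ligand("flex6"), [(0, 0, 0)], [0.0])
        with pytest.raises(ValueError, match="ligand"):
            merge_pose_sets([a, b], cutoff=0.5, max_poses=None)

    def test_truncation_and_rank_reassignment(self):
        ligand = make_ligand("rigid4")
        s = self._set(ligand, [(k * 4, 0, 0) for k in range(6)],
                      [float(k) for k in range(6)])
        merged = merge_pose_sets([s], cutoff=0.5, max_poses=3)
        assert len(merged) == 3
        assert [p.provenance["rank"] for p in merged] == [0, 1, 2]


def test_more_chains_never_worsen_best(holo_complex, holo_box, normal_params):
    receptor, ligand, _ = holo_complex
    few = SamplerConfig(seed=9, n_chains=2, n_steps=240)
    many = SamplerConfig(seed=9, n_chains=4, n_steps=240)
    best_few = sample_poses(receptor, ligand, holo_box, normal_params, few).best
    best_many = sample_poses(receptor, ligand, holo_box, normal_params, many).best
    assert best_many.score <= best_few.score + 1e-12
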