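"""Scoring function: pair terms, pose sums, soft-mode ordering, gradients."""

from __future__ import annotations

import numpy as np
import pytest

from glowives.mol_io import Atom, Ligand, Pose, Receptor, make_provenance
from glowives.scoring import (GAUSS_WIDTH, EnergyBreakdown, ScoringContext,
                              ScoringParams, pair_vdw, score_pose)
from glowives.synthetic import make_ligand


def _pair(r, r0, **kw):
    return pair_vdw(r, r0, ScoringParams(**kw))


class TestPairVdw:
    def test_contact_has_zero_repulsion(self):
        for mode in ("normal", "soft"):
            att, rep = _pair(3.4, 3.4, mode=mode)
            assert rep == 0.0
            assert att == pytest.approx(1.0 + 0.12 * np.exp(-(1.0 / 1.5) ** 2))

    def test_soft_cap_limits_overlap_penalty(self):
        assert _pair(2.4, 3.4).repulsive == pytest.approx(1.0)
        assert _pair(2.4, 3.4, mode="soft").repulsive == pytest.approx(0.25)

    def test_beyond_cutoff_is_exactly_zero(self):
        att, rep = _pair(8.5, 3.4)
        assert att == 0.0 and rep == 0.0

    def test_coincident_atoms_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            _pair(0.0, 3.4)
        with pytest.raises(ValueError, match="coincident"):
            _pair(-1.0, 3.4)

    @pytest.mark.parametrize("point", ["contact", "cap", "cutoff"])
    def test_continuity(self, point):
        params_n = ScoringParams()
        params_s = ScoringParams(mode="soft")
        r0 = 3.4
        center = {"contact": r0,
                  "cap": r0 - np.sqrt(params_s.e_cap),
                  "cutoff": params_n.cutoff}[point]
        grid = center + np.linspace(-5e-4, 5e-4, 41)
        for params in (params_n, params_s):
            vals = np.array([pair_vdw(float(r), r0, params) for r in grid])
            assert np.all(np.abs(np.diff(vals, axis=0)) < 5e-3)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ScoringParams(e_cap=0.0)
        with pytest.raises(ValueError):
            ScoringParams(cutoff=5.0)
        with pytest.raises(ValueError):
            ScoringParams(mode="fuzzy")


def _random_system(rng, n_lig=8, n_rec=50):
    """Random ligand chain + random receptor cloud for oracle checks."""
    lig_elements = ["C", "N", "O", "S"]
    coords = np.cumsum(rng.normal(scale=1.0, size=(n_lig, 3)), axis=0)
    atoms = [Atom(lig_elements[i % 4], coords[i], 1.5 + 0.1 * (i % 4), i)
             for i in range(n_lig)]
    bonds = [(i, i + 1, 1.0) for i in range(n_lig - 1)]
    ligand = Ligand(atoms, bonds)
    rec_coords = rng.uniform(-6, 6, size=(n_rec, 3))
    rec_atoms = []
    residues = {}
    for i in range(n_rec):
        key = ("A", i, "")
        rec_atoms.append(Atom("C", rec_coords[i], 1.7, i, residue_id=key))
        residues[key] = [i]
    receptor = Receptor(rec_atoms, residues)
    pose = Pose(coords + rng.normal(scale=0.5, size=coords.shape), 0.0,
                make_provenance("normal"))
    return receptor, ligand, pose


def _brute_force_breakdown(receptor, ligand, pose, params):
    """All-pairs double-loop oracle for score_pose."""
    att = rep = 0.0
    for i in ligand.heavy_indices:
        for j in receptor.heavy_indices:
            r = float(np.linalg.norm(pose.coords[i] - receptor.coords[j]))
            if r > params.cutoff:
                continue
            a, b = pair_vdw(r, ligand.atoms[i].vdw_radius
                            + receptor.atoms[j].vdw_radius, params)
            att += a
            rep += b
    internal = 0.0
    for i, j in ligand.internal_pairs:
        r = float(np.linalg.norm(pose.coords[i] - pose.coords[j]))
        d = r - (ligand.atoms[i].vdw_radius + ligand.atoms[j].vdw_radius)
        if d < 0:
            internal += params.w_rep * d * d
    total = params.w_att * att + params.w_rep * rep + internal
    return EnergyBreakdown(att, rep, internal, total)


class TestScorePose:
    def test_far_ligand_scores_zero(self, holo_complex, normal_params):
        receptor, ligand, reference = holo_complex
        far = Pose(reference.coords + 50.0, 0.0, make_provenance("normal"))
        bd = score_pose(receptor, ligand, far, normal_params)
        assert bd.vdw_attractive == 0.0
        assert bd.vdw_repulsive == 0.0
        assert bd.total == 0.0

    def test_clash_fixture_soft_repulsion_capped(self, clash_case):
        bd_n = score_pose(clash_case.receptor_dock, clash_case.ligand,
                          clash_case.reference, ScoringParams())
        bd_s = score_pose(clash_case.receptor_dock, clash_case.ligand,
                          clash_case.reference, ScoringParams(mode="soft"))
        assert bd_n.vdw_repulsive > 0
        assert bd_s.vdw_repulsive <= bd_n.vdw_repulsive
        assert bd_s.total <= bd_n.total

    @pytest.mark.parametrize("mode", ["normal", "soft"])
    def test_matches_bruteforce_all_pairs(self, rng, mode):
        params = ScoringParams(mode=mode)
        for _ in range(5):
            receptor, ligand, pose = _random_system(rng)
            got = score_pose(receptor, ligand, pose, params)
            want = _brute_force_breakdown(receptor, ligand, pose, params)
            assert got.vdw_attractive == pytest.approx(want.vdw_attractive, abs=1e-9)
            assert got.vdw_repulsive == pytest.approx(want.vdw_repulsive, abs=1e-9)
            assert got.internal == pytest.approx(want.internal, abs=1e-9)
            assert got.total == pytest.approx(want.total, abs=1e-9)
            # the sampler's dense context path agrees too
            ctx = ScoringContext(receptor, ligand, params)
            assert ctx.total(pose.coords) == pytest.approx(want.total, abs=1e-9)

    def test_breakdown_total_identity(self, rng, normal_params):
        receptor, ligand, pose = _random_system(rng)
        bd = score_pose(receptor, ligand, pose, normal_params)
        assert bd.total == pytest.approx(
            normal_params.w_att * bd.vdw_attractive
            + normal_params.w_rep * bd.vdw_repulsive + bd.internal, abs=1e-12)

    def test_soft_total_never_above_normal(self, rng):
        normal = ScoringParams()
        soft = ScoringParams(mode="soft")
        for _ in range(10):
            receptor, ligand, pose = _random_system(rng)
            bd_n = score_pose(receptor, ligand, pose, normal)
            bd_s = score_pose(receptor, ligand, pose, soft)
            assert bd_s.total <= bd_n.total + 1e-12
            # equality whenever no pair is deeper than sqrt(e_cap)
            deepest = _deepest_overlap(receptor, ligand, pose)
            if deepest > -np.sqrt(soft.e_cap):
                assert bd_s.total == pytest.approx(bd_n.total, abs=1e-12)

    def test_rigid_motion_invariance(self, rng, normal_params):
        from scipy.spatial.transform import Rotation
        receptor, ligand, pose = _random_system(rng)
        before = score_pose(receptor, ligand, pose, normal_params)
        rot = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        shift = np.array([5.0, -3.0, 2.0])
        rec2 = Receptor(
            [Atom(a.element, a.coords @ rot.T + shift, a.vdw_radius, a.serial,
                  residue_id=a.residue_id) for a in receptor.atoms],
            {k: list(v) for k, v in receptor.residues.items()})
        pose2 = Pose(pose.coords @ rot.T + shift, 0.0, make_provenance("normal"))
        after = score_pose(rec2, ligand, pose2, normal_params)
        assert after.total == pytest.approx(before.total, abs=1e-9)

    def test_atom_count_mismatch_rejected(self, holo_complex, normal_params):
        receptor, ligand, _ = holo_complex
        bad = Pose(np.zeros((2, 3)) + 30.0, 0.0, make_provenance("normal"))
        with pytest.raises(ValueError, match="atom"):
            score_pose(receptor, ligand, bad, normal_params)


def _deepest_overlap(receptor, ligand, pose):
    deepest = 0.0
    for i in ligand.heavy_indices:
        for j in receptor.heavy_indices:
            r = float(np.linalg.norm(pose.coords[i] - receptor.coords[j]))
            d = r - (ligand.atoms[i].vdw_radius + receptor.atoms[j].vdw_radius)
            deepest = min(deepest, d)
    return deepest


class TestGradient:
    @pytest.mark.parametrize("mode", ["normal", "soft"])
    def test_matches_finite_differences(self, holo_complex, mode):
        receptor, ligand, reference = holo_complex
        ctx = ScoringContext(receptor, ligand, ScoringParams(mode=mode))
        coords = reference.coords + 0.25
        energy, grad = ctx.energy_grad(coords)
        assert energy == pytest.approx(ctx.total(coords), abs=1e-9)
        h = 1e-6
        for i in range(coords.shape[0]):
            for ax in range(3):
                cp = coords.copy()
                cp[i, ax] += h
                cm = coords.copy()
                cm[i, ax] -= h
                num = (ctx.total(cp) - ctx.total(cm)) / (2 * h)
                assert grad[i, ax] == pytest.approx(num, abs=1e-5)

    def test_internal_term_penalizes_self_clash(self):
        # 6-atom chain folded so atoms 0 and 5 (5 bonds apart) overlap
        coords = np.array([[0, 0, 0], [1.5, 0, 0], [3.0, 0, 0], [3.0, 1.5, 0],
                           [1.5, 1.5, 0], [0.4, 0.4, 0]], float)
        atoms = [Atom("C", coords[i], 1.7, i) for i in range(6)]
        lig = Ligand(atoms, [(i, i + 1, 1.0) for i in range(5)])
        empty = Receptor([], {})
        for mode in ("normal", "soft"):
            ctx = ScoringContext(empty, lig, ScoringParams(mode=mode))
            bd = ctx.breakdown(coords)
            assert bd.internal > 0  # uncapped in both modes
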