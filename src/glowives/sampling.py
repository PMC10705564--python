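"""Rigid-receptor stochastic pose search, pose clustering and merging.

The search is a Monte-Carlo iterated local search (basin hopping) over the
ligand's rigid-body + torsion degrees of freedom: several independent
chains propose randomized perturbations, minimize them locally with an
analytic-gradient descent, and accept by a Metropolis test on the
minimized energies under an annealed temperature. Visited minima are
pooled, re-polished, leader-clustered at an RMSD cutoff and truncated.
Fully reproducible: chain k draws from a stream seeded with seed + k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from glowives import geometry
from glowives.mol_io import Ligand, Pose, Receptor, Torsion, make_provenance
from glowives.scoring import ScoringContext, ScoringParams

#: Basin-hopping perturbation sizes: one hop = a large randomized move
#: followed by greedy local minimization, accepted by a Metropolis test on
#: the minimized energies (iterated local search).
HOP_TRANSLATION = 1.2              # Å
HOP_ROTATION = math.radians(45.0)
HOP_TORSION = math.radians(120.0)
STEPS_PER_HOP = 40                 # n_steps is a step budget; hops = steps / 40
REFINE_ITERS = 60                  # descent iterations per hop
FINAL_REFINE_ITERS = 300           # full polish of the pooled best minima


@dataclass(frozen=True)
class SearchBox:
    """Axis-aligned binding-site box: the ligand centroid is confined to it."""

    center: tuple[float, float, float]
    half_widths: tuple[float, float, float]

    def __post_init__(self) -> None:
        hw = np.asarray(self.half_widths, float)
        if hw.shape != (3,) or not np.all(hw > 0):
            raise ValueError("half_widths must be three positive numbers")

    @property
    def center_arr(self) -> np.ndarray:
        return np.asarray(self.center, float)

    @property
    def half_arr(self) -> np.ndarray:
        return np.asarray(self.half_widths, float)

    def contains(self, point: np.ndarray) -> bool:
        return bool(np.all(np.abs(point - self.center_arr) <= self.half_arr + 1e-9))

    @classmethod
    def around(cls, coords: np.ndarray, margin: float = 4.0) -> "SearchBox":
        """Autobox: centered on the coordinates with a margin per side."""
        coords = np.asarray(coords, float)
        center = coords.mean(axis=0)
        extent = np.abs(coords - center).max(axis=0) + margin
        return cls(tuple(center), tuple(extent))


@dataclass(frozen=True)
class SamplerConfig:
    seed: int = 0
    n_chains: int = 8
    n_steps: int = 2000
    temperature: float = 1.5
    max_poses: int = 300
    cluster_cutoff: float = 1.0

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1 (zero-step search is undefined)")
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")
        if self.max_poses < 1:
            raise ValueError("max_poses must be >= 1")
        if self.cluster_cutoff < 0:
            raise ValueError("cluster_cutoff must be non-negative")


@dataclass
class PoseSet:
    """Poses sorted by ascending score, mutually > cluster cutoff apart."""

    poses: list[Pose]
    ligand_ref: Ligand

    def __len__(self) -> int:
        return len(self.poses)

    def __iter__(self) -> Iterator[Pose]:
        return iter(self.poses)

    def __getitem__(self, i):
        return self.poses[i]

    @property
    def best(self) -> Pose:
        return self.poses[0]


# ---------------------------------------------------------------------------
# Internal pose state: translation + rotation + torsion angles
# ---------------------------------------------------------------------------

class _PoseBuilder:
    """Maps (shift, rotation, torsion angles) to full-atom coordinates.

    The template is the input ligand conformation. Torsions are applied
    sequentially in detection order, the result is re-centered on its
    heavy-atom centroid, rotated, and shifted — so the shift *is* the
    heavy-atom centroid and the box constraint is a test on it alone.
    """

    def __init__(self, ligand: Ligand) -> None:
        self.template = ligand.coords.copy()
        self.heavy = ligand.heavy_indices
        self.torsions: list[Torsion] = ligand.torsions
        self._moving = [np.array(sorted(t.moving), int) for t in self.torsions]
        self._axes = [t.axis for t in self.torsions]
        heavy_set = set(self.heavy.tolist())
        self._moving_heavy = [np.array([i for i in m if i in heavy_set], int)
                              for m in self._moving]

    @property
    def n_torsions(self) -> int:
        return len(self.torsions)

    def build(self, shift: np.ndarray, rot: np.ndarray,
              angles: np.ndarray) -> np.ndarray:
        coords = self.template.copy()
        for (a, b), moving, angle in zip(self._axes, self._moving, angles):
            if angle == 0.0:
                continue
            origin = coords[a]
            axis = coords[b] - origin
            norm = np.linalg.norm(axis)
            if norm < 1e-9:
                continue
            rmat = _rotvec_matrix(axis / norm * angle)
            coords[moving] = (coords[moving] - origin) @ rmat.T + origin
        center = coords[self.heavy].mean(axis=0)
        return (coords - center) @ rot.T + shift


def _rotvec_matrix(v: np.ndarray) -> np.ndarray:
    """Rotation matrix for a rotation vector (Rodrigues formula)."""
    angle = math.sqrt(float(v @ v))
    if angle < 1e-12:
        return np.eye(3)
    x, y, z = v / angle
    c, s = math.cos(angle), math.sin(angle)
    t = 1.0 - c
    return np.array([
        [c + x * x * t, x * y * t - z * s, x * z * t + y * s],
        [x * y * t + z * s, c + y * y * t, y * z * t - x * s],
        [x * z * t - y * s, y * z * t + x * s, c + z * z * t]])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    return Rotation.from_quat(q).as_matrix()


@dataclass
class _Candidate:
    energy: float
    chain: int
    step: int
    shift: np.ndarray
    rot: np.ndarray
    angles: np.ndarray


def _run_chain(ctx: ScoringContext, builder: _PoseBuilder, box: SearchBox,
               config: SamplerConfig, chain_idx: int) -> list[_Candidate]:
    """One basin-hopping chain: random placement, then Metropolis over
    locally minimized poses. Every visited minimum (accepted or not) is
    recorded as a candidate."""
    rng = np.random.default_rng((config.seed + chain_idx) % (2 ** 31))
    k = builder.n_torsions
    shift = box.center_arr + rng.uniform(-1.0, 1.0, 3) * box.half_arr
    rot = _random_rotation(rng)
    angles = rng.uniform(-math.pi, math.pi, k) if k else np.empty(0)
    start = _Candidate(ctx.total(builder.build(shift, rot, angles)),
                       chain_idx, -1, shift, rot, angles)
    current = _refine(ctx, builder, box, start, config, max_iters=REFINE_ITERS)
    current = _Candidate(current.energy, chain_idx, 0, current.shift,
                         current.rot, current.angles)
    minima = [current]
    n_hops = max(config.n_steps // STEPS_PER_HOP, 1)
    n_move_types = 3 if k else 2
    for hop in range(1, n_hops + 1):
        # anneal: hot early for basin coverage, cold late to settle
        frac = (hop - 1) / max(n_hops - 1, 1)
        temperature = config.temperature * (2.0 * (0.1 / 2.0) ** frac)
        move = int(rng.integers(n_move_types))
        shift = current.shift.copy()
        rot = current.rot.copy()
        angles = current.angles.copy()
        if move == 0:
            direction = rng.normal(size=3)
            direction /= max(np.linalg.norm(direction), 1e-12)
            shift = shift + direction * rng.uniform(0.2, HOP_TRANSLATION)
            if not box.contains(shift):
                continue
        elif move == 1:
            axis = rng.normal(size=3)
            axis /= max(np.linalg.norm(axis), 1e-12)
            rot = Rotation.from_rotvec(
                axis * rng.uniform(0.1, HOP_ROTATION)).as_matrix() @ rot
        else:
            t = int(rng.integers(k))
            angles = angles.copy()
            angles[t] += rng.uniform(-HOP_TORSION, HOP_TORSION)
        trial = _Candidate(ctx.total(builder.build(shift, rot, angles)),
                           chain_idx, hop, shift, rot, angles)
        refined = _refine(ctx, builder, box, trial, config,
                          max_iters=REFINE_ITERS)
        refined = _Candidate(refined.energy, chain_idx, hop, refined.shift,
                             refined.rot, refined.angles)
        minima.append(refined)
        delta = refined.energy - current.energy
        if delta <= 0 or rng.random() < math.exp(-delta / temperature):
            current = refined
    minima.sort(key=lambda c: (c.energy, c.step))
    return minima[:config.max_poses]


def _refine(ctx: ScoringContext, builder: _PoseBuilder, box: SearchBox,
            cand: _Candidate, config: SamplerConfig,
            max_iters: int = 150) -> _Candidate:
    """Greedy local refinement: steepest descent with backtracking over the
    pose degrees of freedom (translation, rigid rotation, torsions), using
    the analytic gradient of the scoring function."""
    shift, rot, angles = cand.shift.copy(), cand.rot.copy(), cand.angles.copy()
    coords = builder.build(shift, rot, angles)
    energy, grad = ctx.energy_grad(coords)
    heavy = builder.heavy
    n_heavy = len(heavy)
    lo = box.center_arr - box.half_arr
    hi = box.center_arr + box.half_arr
    for _it in range(max_iters):
        c = coords[heavy].mean(axis=0)
        f_trans = grad.sum(axis=0)
        torque = np.sum(np.cross(coords - c, grad), axis=0)
        t_grads = np.zeros(builder.n_torsions)
        for t, ((a, b), moving) in enumerate(zip(builder._axes, builder._moving)):
            axis = coords[b] - coords[a]
            norm = np.linalg.norm(axis)
            if norm < 1e-9:
                continue
            axis /= norm
            arms = np.cross(coords[moving] - coords[a], grad[moving])
            raw = float(axis @ arms.sum(axis=0))
            # recentering correction: twisting shifts the heavy centroid
            mh = builder._moving_heavy[t]
            if mh.size:
                dc = np.cross(axis, coords[mh] - coords[a]).sum(axis=0) / n_heavy
                raw -= float(dc @ f_trans)
            t_grads[t] = raw
        radius = max(float(np.linalg.norm(coords - c, axis=1).max()), 1e-6)
        denom = (np.linalg.norm(f_trans) + np.linalg.norm(torque) * radius
                 + np.abs(t_grads).sum() * radius)
        if denom < 1e-10:
            break
        lr = 0.3 / denom
        accepted = False
        for _bt in range(14):
            new_shift = np.clip(shift - lr * f_trans, lo, hi)
            new_rot = _rotvec_matrix(-lr * torque) @ rot
            new_angles = angles - lr * t_grads
            new_coords = builder.build(new_shift, new_rot, new_angles)
            e_new, g_new = ctx.energy_grad(new_coords)
            if e_new < energy - 1e-12:
                gain = energy - e_new
                shift, rot, angles = new_shift, new_rot, new_angles
                coords, energy, grad = new_coords, e_new, g_new
                accepted = True
                if gain < 1e-7:
                    return _Candidate(energy, cand.chain,
                                      cand.step + 1_000_000, shift, rot, angles)
                break
            lr *= 0.5
        if not accepted:
            break
    return _Candidate(energy, cand.chain, cand.step + 1_000_000, shift, rot, angles)


def sample_poses(receptor: Receptor, ligand: Ligand, box: SearchBox,
                 params: ScoringParams, config: SamplerConfig, *,
                 conformation_id: str = "input", iteration: int = 0) -> PoseSet:
    """Run the Monte-Carlo pose search against one rigid receptor conformation.

    Returns a clustered, score-sorted :class:`PoseSet` of at most
    ``config.max_poses`` poses. Deterministic for a fixed ``config.seed``.
    """
    if ligand.bounding_radius > max(box.half_widths):
        raise ValueError(
            f"ligand bounding radius {ligand.bounding_radius:.2f} Å exceeds the "
            f"largest box half-width {max(box.half_widths):.2f} Å")
    ctx = ScoringContext(receptor, ligand, params)
    builder = _PoseBuilder(ligand)
    candidates: list[_Candidate] = []
    for chain in range(config.n_chains):
        candidates.extend(_run_chain(ctx, builder, box, config, chain))
    candidates.sort(key=lambda c: (c.energy, c.chain, c.step))
    # final polish: fully refine the best geometry-diverse minima from the
    # pooled chains
    heavy = ligand.heavy_indices
    polish_starts: list[_Candidate] = []
    polish_coords: list[np.ndarray] = []
    for cand in candidates[:200]:
        if len(polish_starts) >= 25:
            break
        hc = builder.build(cand.shift, cand.rot, cand.angles)[heavy]
        if any(np.sqrt(np.mean(np.sum((hc - sc) ** 2, axis=1))) < 0.8
               for sc in polish_coords):
            continue
        polish_starts.append(cand)
        polish_coords.append(hc)
    candidates.extend(_refine(ctx, builder, box, c, config,
                              max_iters=FINAL_REFINE_ITERS)
                      for c in polish_starts)
    candidates.sort(key=lambda c: (c.energy, c.chain, c.step))
    coords = np.stack([builder.build(c.shift, c.rot, c.angles) for c in candidates])
    perms = geometry.automorphisms(ligand)
    heavy = coords[:, ligand.heavy_indices, :]
    kept = geometry.leader_cluster_indices(heavy, config.cluster_cutoff, perms)
    kept = kept[:config.max_poses]
    poses = []
    for rank, idx in enumerate(kept):
        c = candidates[idx]
        bd = ctx.breakdown(coords[idx])
        poses.append(Pose(coords[idx], bd.total, make_provenance(
            potential=params.mode, conformation_id=conformation_id,
            iteration=iteration, rank=rank, chain=c.chain, step=c.step),
            breakdown=bd))
    return PoseSet(poses, ligand)


# ---------------------------------------------------------------------------
# Clustering and merging
# ---------------------------------------------------------------------------

def cluster_poses(poses: Sequence[Pose], cutoff: float,
                  ligand: Ligand) -> list[Pose]:
    """Greedy leader clustering of a best-first-sorted pose list.

    Keeps a pose iff its symmetry-corrected heavy-atom RMSD to every
    already-kept pose exceeds ``cutoff``. Stable and deterministic.
    """
    if cutoff < 0:
        raise ValueError("cluster cutoff must be non-negative")
    poses = list(poses)
    if not poses:
        return []
    scores = [p.score for p in poses]
    if any(b < a - 1e-12 for a, b in zip(scores, scores[1:])):
        raise ValueError("poses must be sorted by ascending score")
    heavy = np.stack([p.coords[ligand.heavy_indices] for p in poses])
    perms = geometry.automorphisms(ligand)
    kept = geometry.leader_cluster_indices(heavy, cutoff, perms)
    return [poses[i] for i in kept]


def _merge_sort_key(pose: Pose):
    prov = pose.provenance
    return (pose.score, str(prov.get("potential", "")),
            str(prov.get("conformation_id", "")), int(prov.get("iteration", 0)),
            int(prov.get("chain", -1)), int(prov.get("step", -1)))


def merge_pose_sets(sets: Sequence[PoseSet], cutoff: float,
                    max_poses: int | None) -> PoseSet:
    """Concatenate pose sets of the same ligand, sort by score, cluster at
    ``cutoff`` and truncate to ``max_poses`` (``None`` = no truncation).

    The sort key is a total order (score, then provenance), so the merge is
    invariant under permutations of the input sets.
    """
    if not sets:
        raise ValueError("need at least one pose set to merge")
    ligand = sets[0].ligand_ref
    sig = ligand.element_signature()
    for s in sets[1:]:
        if s.ligand_ref.element_signature() != sig:
            raise ValueError("cannot merge pose sets of different ligands")
    pool = sorted((p for s in sets for p in s.poses), key=_merge_sort_key)
    clustered = cluster_poses(pool, cutoff, ligand)
    if max_poses is not None:
        clustered = clustered[:max_poses]
    out = [replace_pose_rank(p, rank) for rank, p in enumerate(clustered)]
    return PoseSet(out, ligand)


def replace_pose_rank(pose: Pose, rank: int) -> Pose:
    return Pose(pose.coords, pose.score, {**pose.provenance, "rank": rank},
                breakdown=pose.breakdown)
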