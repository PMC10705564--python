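"""GLOW and IVES pose-sampling protocols, plus the Default baseline.

* **Default** — one normal-potential rigid docking run, truncated to 20
  poses (the typical docking scenario).
* **GLOW** — pools poses from a normal-potential run and a soft-potential
  run; soft-run poses are rescored under the normal potential so a single
  consistent scale orders the merged list.
* **IVES** — soft-potential rigid docking seeds pocket minimization: the
  top N poses each produce a relaxed receptor conformation, the ligand is
  redocked onto every conformation with both potentials, and everything is
  merged. Per-conformation runs are independent, so the merged result does
  not depend on processing order. Optionally iterated by re-seeding from
  the merged set.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

from glowives.mol_io import Ligand, Pose, Receptor
from glowives.pocket_min import MinimizeConfig, minimize_pocket, select_movable_residues
from glowives.sampling import (PoseSet, SamplerConfig, SearchBox, merge_pose_sets,
                               sample_poses)
from glowives.scoring import ScoringContext, ScoringParams

logger = logging.getLogger(__name__)

#: Pose cap of the "Default" baseline (typical docking scenario).
DEFAULT_POSE_CAP = 20


@dataclass(frozen=True)
class IvesConfig:
    """IVES knobs: N seed poses / protein conformations, per-conformation
    pose cap, iteration count and the movable-shell radius."""

    n_seeds: int = 20
    max_poses_per_conf: int = 300
    iterations: int = 1
    shell_radius: float = 8.0
    seed_scorer: str | Callable[[Pose], float] = "docking_score"

    def __post_init__(self) -> None:
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.max_poses_per_conf < 1:
            raise ValueError("max_poses_per_conf must be >= 1")
        if not self.shell_radius > 0:
            raise ValueError("shell_radius must be positive")


@dataclass
class ProtocolResult:
    poses: PoseSet
    ensemble: list[Receptor] = field(default_factory=list)
    ensemble_info: list[dict] = field(default_factory=list)
    run_log: dict = field(default_factory=dict)


def derive_seed(master: int, label: str) -> int:
    """Deterministic sub-seed from a master seed and a stage label (< 2^31)."""
    return (int(master) * 2654435761 + zlib.crc32(label.encode())) % (2 ** 31 - 1)


def _rescore_normal(pose_set: PoseSet, receptor: Receptor,
                    params: ScoringParams) -> PoseSet:
    """Rescore poses under the normal potential on the given conformation,
    keeping provenance (including the source potential) intact."""
    ctx = ScoringContext(receptor, pose_set.ligand_ref, params.as_mode("normal"))
    rescored = []
    for p in pose_set:
        bd = ctx.breakdown(p.coords)
        rescored.append(Pose(p.coords, bd.total, dict(p.provenance), breakdown=bd))
    rescored.sort(key=lambda p: p.score)
    return PoseSet(rescored, pose_set.ligand_ref)


def run_default(receptor: Receptor, ligand: Ligand, box: SearchBox, *,
                scoring: ScoringParams | None = None,
                sampler: SamplerConfig | None = None,
                seed: int | None = None,
                max_poses: int = DEFAULT_POSE_CAP) -> ProtocolResult:
    """The Default baseline: one normal-potential run, at most 20 poses."""
    scoring = scoring or ScoringParams()
    sampler = sampler or SamplerConfig()
    master = sampler.seed if seed is None else seed
    cfg = replace(sampler, seed=derive_seed(master, "normal"))
    ps = sample_poses(receptor, ligand, box, scoring.as_mode("normal"), cfg)
    poses = ps.poses[:max_poses]
    return ProtocolResult(
        poses=PoseSet(poses, ligand),
        run_log={"protocol": "default", "sampled": len(ps), "returned": len(poses)})


def run_glow(receptor: Receptor, ligand: Ligand, box: SearchBox, *,
             scoring: ScoringParams | None = None,
             sampler: SamplerConfig | None = None,
             seed: int | None = None) -> ProtocolResult:
    """GLOW: normal + softened-potential runs, pooled and deduplicated."""
    scoring = scoring or ScoringParams()
    sampler = sampler or SamplerConfig()
    master = sampler.seed if seed is None else seed
    normal_ps = sample_poses(receptor, ligand, box, scoring.as_mode("normal"),
                             replace(sampler, seed=derive_seed(master, "normal")))
    soft_ps = sample_poses(receptor, ligand, box, scoring.as_mode("soft"),
                           replace(sampler, seed=derive_seed(master, "soft")))
    soft_rescored = _rescore_normal(soft_ps, receptor, scoring)
    merged = merge_pose_sets([normal_ps, soft_rescored],
                             cutoff=sampler.cluster_cutoff, max_poses=None)
    return ProtocolResult(
        poses=merged,
        run_log={"protocol": "glow", "normal": len(normal_ps),
                 "soft": len(soft_ps), "merged": len(merged)})


def select_seed_poses(poses: PoseSet, n: int,
                      scorer: str | Callable[[Pose], float] = "docking_score"
                      ) -> list[Pose]:
    """Top-``n`` poses under the chosen scorer (docking score by default;
    a callable hook reorders before truncation, ties broken by prior rank)."""
    if len(poses) == 0:
        raise ValueError("cannot select seed poses from an empty pose set")
    if len(poses) < n:
        logger.warning("only %d poses available for %d requested seeds",
                       len(poses), n)
    if scorer == "docking_score":
        ordered = list(poses)
    elif callable(scorer):
        ordered = [p for _, _, p in
                   sorted((scorer(p), i, p) for i, p in enumerate(poses))]
    else:
        raise ValueError(f"unknown seed scorer: {scorer!r}")
    return ordered[:min(n, len(ordered))]


def run_ives(receptor: Receptor, ligand: Ligand, box: SearchBox, *,
             scoring: ScoringParams | None = None,
             sampler: SamplerConfig | None = None,
             ives: IvesConfig | None = None,
             minimize: MinimizeConfig | None = None,
             seed: int | None = None,
             process_order: Sequence[int] | None = None,
             minimizer: Callable[..., Receptor] | None = None) -> ProtocolResult:
    """IVES: seed-pose-guided ensemble generation and ensemble redocking.

    ``process_order`` permutes the order in which ensemble members are
    docked (results are independent of it; exposed for verification).
    ``minimizer`` swaps the pocket-minimization backend: any callable with
    the :func:`glowives.pocket_min.minimize_pocket` signature, e.g. an
    :class:`glowives.pocket_min.ExternalCommandMinimizer`. Defaults to the
    internal minimizer.
    """
    scoring = scoring or ScoringParams()
    sampler = sampler or SamplerConfig()
    ives = ives or IvesConfig()
    minimize = minimize or MinimizeConfig()
    master = sampler.seed if seed is None else seed

    stage1 = sample_poses(
        receptor, ligand, box, scoring.as_mode("soft"),
        replace(sampler, seed=derive_seed(master, "ives.stage1.soft")),
        conformation_id="input", iteration=0)
    run_log: dict = {"protocol": "ives", "stage1_soft": len(stage1), "stages": []}

    pose_sets: list[PoseSet] = [_rescore_normal(stage1, receptor, scoring)]
    seed_poses = select_seed_poses(stage1, ives.n_seeds, ives.seed_scorer)
    ensemble: list[Receptor] = []
    ensemble_info: list[dict] = []
    merged: PoseSet = pose_sets[0]
    for it in range(1, ives.iterations + 1):
        members: list[Receptor] = []
        backend = minimizer or minimize_pocket
        for k, seed_pose in enumerate(seed_poses):
            shell = select_movable_residues(receptor, seed_pose,
                                            ives.shell_radius, ligand=ligand)
            conf = backend(receptor, ligand, seed_pose, shell, scoring,
                           minimize)
            members.append(conf)
        ensemble = members
        ensemble_info = [{"iteration": it, "seed_rank": k,
                          "conformation_id": f"iter{it}_conf{k:03d}"}
                         for k in range(len(members))]
        order = list(process_order) if process_order is not None \
            else list(range(len(members)))
        for k in order:
            conf = members[k]
            cid = f"iter{it}_conf{k:03d}"
            for mode in ("normal", "soft"):
                cfg = replace(sampler,
                              seed=derive_seed(master, f"ives.it{it}.conf{k}.{mode}"),
                              max_poses=ives.max_poses_per_conf)
                ps = sample_poses(conf, ligand, box, scoring.as_mode(mode), cfg,
                                  conformation_id=cid, iteration=it)
                if mode == "soft":
                    ps = _rescore_normal(ps, conf, scoring)
                pose_sets.append(ps)
                run_log["stages"].append({"conformation_id": cid, "mode": mode,
                                          "poses": len(ps)})
        merged = merge_pose_sets(pose_sets, cutoff=sampler.cluster_cutoff,
                                 max_poses=None)
        if it < ives.iterations:
            seed_poses = select_seed_poses(merged, ives.n_seeds, ives.seed_scorer)
            pose_sets = [merged]
    run_log["merged"] = len(merged)
    return ProtocolResult(poses=merged, ensemble=ensemble,
                          ensemble_info=ensemble_info, run_log=run_log)
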