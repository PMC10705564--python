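"""Success metrics and cross-docking benchmark aggregation.

A sampled pose counts as *correct* when its heavy-atom RMSD to the
reference pose is at most 2.0 Å (inclusive). Poses and references share
the receptor frame, so no re-superposition is performed. RMSD is
minimized over the ligand's bond-graph automorphisms (see
:mod:`glowives.geometry`); the naive atom-order value is reported
alongside it.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from glowives import geometry
from glowives.mol_io import (Ligand, Pose, Receptor, make_provenance, read_ligand,
                             read_receptor, write_ligand, write_receptor)
from glowives.sampling import PoseSet, SamplerConfig, SearchBox
from glowives.scoring import ScoringParams

SUCCESS_THRESHOLD = 2.0  # Å, inclusive


@dataclass(eq=False)
class BenchmarkCase:
    """One cross-docking case: dock receptor, ligand, known-correct pose."""

    receptor_dock: Receptor
    ligand: Ligand
    reference: Pose
    box: SearchBox
    case_id: str
    difficulty: str = "typical"

    def __post_init__(self) -> None:
        if self.reference.coords.shape[0] != self.ligand.n_atoms:
            raise ValueError("reference pose does not match the ligand atom count")
        centroid = self.reference.coords[self.ligand.heavy_indices].mean(axis=0)
        if not self.box.contains(centroid):
            raise ValueError("search box does not contain the reference centroid")


@dataclass
class BenchmarkReport:
    protocol: str
    threshold: float
    per_case: dict[str, dict] = field(default_factory=dict)

    @property
    def success_rate(self) -> float:
        """Percentage of cases with any pose at RMSD <= threshold."""
        if not self.per_case:
            return 0.0
        n_ok = sum(1 for v in self.per_case.values() if v.get("success"))
        return 100.0 * n_ok / len(self.per_case)

    def to_json(self, path: str | Path) -> None:
        payload = {"protocol": self.protocol, "threshold": self.threshold,
                   "success_rate": self.success_rate, "per_case": self.per_case}
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["case_id", "min_rmsd", "success", "protocol"])
            for cid in sorted(self.per_case):
                v = self.per_case[cid]
                writer.writerow([cid, f"{v['min_rmsd']:.4f}",
                                 int(bool(v["success"])), self.protocol])


def symmetry_rmsd(pose: Pose, reference: Pose, ligand: Ligand,
                  cap: int = geometry.AUTOMORPHISM_CAP) -> float:
    """Heavy-atom RMSD minimized over ligand bond-graph automorphisms.

    No re-superposition: both poses are assumed to live in the receptor
    frame. Never exceeds the identity-mapping RMSD.
    """
    if pose.coords.shape != reference.coords.shape:
        raise ValueError("pose and reference have different atom counts")
    heavy = ligand.heavy_indices
    perms = geometry.automorphisms(ligand, cap=cap)
    return geometry.min_rmsd_over_perms(pose.coords[heavy],
                                        reference.coords[heavy], perms)


def naive_rmsd(pose: Pose, reference: Pose, ligand: Ligand) -> float:
    """Heavy-atom RMSD with the identity atom mapping."""
    heavy = ligand.heavy_indices
    return geometry.rmsd_fixed_mapping(pose.coords[heavy], reference.coords[heavy])


def is_success(poses: PoseSet | list[Pose], reference: Pose, ligand: Ligand,
               threshold: float = SUCCESS_THRESHOLD) -> tuple[bool, float]:
    """Whether any pose is within ``threshold`` (inclusive) of the reference.

    Returns ``(success, min_rmsd)``; an empty set fails with ``inf``.
    """
    pose_list = list(poses)
    if not pose_list:
        return False, math.inf
    heavy = ligand.heavy_indices
    perms = geometry.automorphisms(ligand)
    batch = np.stack([p.coords[heavy] for p in pose_list])
    rmsds = geometry.min_rmsd_many(batch, reference.coords[heavy], perms)
    min_rmsd = float(rmsds.min())
    return min_rmsd <= threshold, min_rmsd


def run_benchmark(cases: list[BenchmarkCase], protocol: str, *,
                  scoring: ScoringParams | None = None,
                  sampler: SamplerConfig | None = None,
                  ives=None, minimize=None, seed: int = 0,
                  threshold: float = SUCCESS_THRESHOLD) -> BenchmarkReport:
    """Run a protocol over all cases with case-derived seeds and aggregate.

    Per-case failures are recorded (not fatal); an error is raised only if
    every case failed to run.
    """
    from glowives import protocols  # local import: avoids a module cycle

    if not cases:
        raise ValueError("need at least one benchmark case")
    if protocol not in ("default", "glow", "ives"):
        raise ValueError(f"unknown protocol: {protocol!r}")
    report = BenchmarkReport(protocol=protocol, threshold=threshold)
    n_errors = 0
    for case in cases:
        case_seed = protocols.derive_seed(seed, f"case.{case.case_id}")
        try:
            if protocol == "default":
                result = protocols.run_default(case.receptor_dock, case.ligand,
                                               case.box, scoring=scoring,
                                               sampler=sampler, seed=case_seed)
            elif protocol == "glow":
                result = protocols.run_glow(case.receptor_dock, case.ligand,
                                            case.box, scoring=scoring,
                                            sampler=sampler, seed=case_seed)
            else:
                result = protocols.run_ives(case.receptor_dock, case.ligand,
                                            case.box, scoring=scoring,
                                            sampler=sampler, ives=ives,
                                            minimize=minimize, seed=case_seed)
        except Exception as exc:  # recorded, not fatal
            n_errors += 1
            report.per_case[case.case_id] = {
                "min_rmsd": math.inf, "naive_min_rmsd": math.inf, "n_poses": 0,
                "success": False, "difficulty": case.difficulty,
                "error": f"{type(exc).__name__}: {exc}"}
            continue
        success, min_rmsd = is_success(result.poses, case.reference,
                                       case.ligand, threshold)
        naive_min = min(naive_rmsd(p, case.reference, case.ligand)
                        for p in result.poses) if len(result.poses) else math.inf
        report.per_case[case.case_id] = {
            "min_rmsd": min_rmsd, "naive_min_rmsd": naive_min,
            "n_poses": len(result.poses), "success": success,
            "difficulty": case.difficulty}
    if n_errors == len(cases):
        raise RuntimeError("every benchmark case failed to run")
    return report


# ---------------------------------------------------------------------------
# Benchmark manifest I/O (one directory per case)
# ---------------------------------------------------------------------------

def save_case(case: BenchmarkCase, directory: str | Path) -> None:
    """Serialize a case as receptor.pdb + ligand.sdf + reference.sdf + case.yaml."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_receptor(case.receptor_dock, directory / "receptor.pdb")
    write_ligand(case.ligand, directory / "ligand.sdf")
    write_ligand(case.ligand, directory / "reference.sdf",
                 coords=case.reference.coords)
    meta = {"case_id": case.case_id, "difficulty": case.difficulty,
            "box": {"center": [float(x) for x in case.box.center],
                    "half_widths": [float(x) for x in case.box.half_widths]}}
    (directory / "case.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))


def load_case(directory: str | Path) -> BenchmarkCase:
    directory = Path(directory)
    meta = yaml.safe_load((directory / "case.yaml").read_text())
    receptor = read_receptor(directory / "receptor.pdb")
    ligand = read_ligand(directory / "ligand.sdf")
    ref_lig = read_ligand(directory / "reference.sdf")
    reference = Pose(ref_lig.coords, 0.0,
                     make_provenance("reference", conformation_id="reference"))
    box = SearchBox(tuple(meta["box"]["center"]),
                    tuple(meta["box"]["half_widths"]))
    return BenchmarkCase(receptor, ligand, reference, box,
                         case_id=meta["case_id"],
                         difficulty=meta.get("difficulty", "typical"))


def load_benchmark(directory: str | Path) -> list[BenchmarkCase]:
    """Load every case directory (those containing case.yaml), sorted by name."""
    directory = Path(directory)
    cases = [load_case(d) for d in sorted(directory.iterdir())
             if d.is_dir() and (d / "case.yaml").exists()]
    if not cases:
        raise ValueError(f"no benchmark cases found under {directory}")
    return cases
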