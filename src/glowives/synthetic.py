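"""Self-contained synthetic cross-docking fixtures.

The generator reproduces, at desk scale, the core failure mode of rigid
cross-docking: a pseudo-receptor pocket is built around a reference ligand
pose (the *holo* complex, clash-free by construction), and an *apo-like*
variant is derived by displacing the pocket atoms nearest the ligand into
its volume — so the correct pose clashes with the docking structure and a
normal-potential rigid search tends to discard it.

Pocket atoms are placed as *sockets*: each sits at near-contact distance
from one ligand atom, with alternating O/S chemistry so mis-registered
poses mismatch contact distances everywhere — the reference pose is the
constructed global optimum. Every pocket atom is its own single-atom
residue, so the movable-shell logic is exercised at atom granularity while
honoring the residue-level contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Geometry import Point3D

from glowives.evaluation import BenchmarkCase, save_case
from glowives.mol_io import (Atom, Ligand, Pose, Receptor, ligand_from_rdkit,
                             make_provenance, vdw_radius)
from glowives.protocols import derive_seed
from glowives.sampling import SearchBox
from glowives.scoring import ScoringParams, score_pose

#: built-in ligand templates: name -> (element list, coords, bond list)
_TEMPLATES: dict[str, tuple[list[str], list[tuple], list[tuple[int, int, float]]]] = {
    # rigid 4-atom ring (oxetane/azetidine-like square): no rotatable bonds
    "rigid4": (
        ["C", "N", "C", "O"],
        [(0.0, 0.0, 0.0), (1.55, 0.0, 0.0), (1.55, 1.55, 0.0), (0.0, 1.55, 0.0)],
        [(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0), (3, 0, 1.0)],
    ),
    # 6 heavy atoms, one rotatable torsion (the C2-C3 bond of a
    # 2,3-disubstituted-butane-like skeleton); heteroatoms with contrasting
    # vdW radii break the end-to-end pseudo-symmetry so the pocket can
    # discriminate the correct registration
    "flex6": (
        ["F", "C", "C", "S", "O", "C"],
        [(-0.514, 1.452, 0.0),            # C1 on C2
         (0.0, 0.0, 0.0),                 # C2
         (1.54, 0.0, 0.0),                # C3
         (2.054, 1.452, 0.0),             # C4 on C3
         (-0.514, -0.726, 1.257),         # C5 on C2
         (2.054, -0.726, -1.257)],        # C6 on C3
        [(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0), (1, 4, 1.0), (2, 5, 1.0)],
    ),
    # benzene-like planar hexagon (treated as a rigid ring)
    "ring6": (
        ["C"] * 6,
        [(1.39 * math.cos(k * math.pi / 3), 1.39 * math.sin(k * math.pi / 3), 0.0)
         for k in range(6)],
        [(k, (k + 1) % 6, 1.0) for k in range(6)],
    ),
}

#: Frozen challenging fixture used by the clash-rescue regression checks:
#: calibrated so the Default baseline misses the reference pose while the
#: soft-potential protocols recover it.
CLASH_FIXTURE_TOY_SEED = 3
CLASH_FIXTURE_CLASH_MAGNITUDE = 2.2
CLASH_FIXTURE_N_CLASH_ATOMS = 10


@dataclass(frozen=True)
class ToyComplexSpec:
    n_pocket_atoms: int = 18
    pocket_radius: float = 6.0
    ligand_template: str = "flex6"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pocket_atoms < 6:
            raise ValueError("n_pocket_atoms must be >= 6")
        if self.ligand_template not in _TEMPLATES:
            raise ValueError(f"unknown ligand template {self.ligand_template!r}; "
                             f"choose from {sorted(_TEMPLATES)}")


@dataclass(frozen=True)
class CrossDockSpec:
    clash_magnitude: float = 1.5
    n_clash_atoms: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.clash_magnitude < 0:
            raise ValueError("clash_magnitude must be >= 0")
        if self.n_clash_atoms < 0:
            raise ValueError("n_clash_atoms must be >= 0")


def make_ligand(template: str) -> Ligand:
    """Instantiate a built-in ligand template, centered at the origin."""
    elements, raw_coords, bonds = _TEMPLATES[template]
    coords = np.asarray(raw_coords, float)
    coords = coords - coords.mean(axis=0)
    em = Chem.RWMol()
    for sym in elements:
        em.AddAtom(Chem.Atom(sym))
    for i, j, _order in bonds:
        em.AddBond(i, j, Chem.BondType.SINGLE)
    mol = em.GetMol()
    conf = Chem.Conformer(len(elements))
    for i in range(len(elements)):
        conf.SetAtomPosition(i, Point3D(*coords[i]))
    mol.AddConformer(conf)
    mol.UpdatePropertyCache(strict=False)
    return ligand_from_rdkit(mol, origin=f"<template:{template}>")


def make_toy_complex(spec: ToyComplexSpec) -> tuple[Receptor, Ligand, Pose]:
    """Build the holo complex: ligand at the origin, pocket atoms socketed
    around it at near-contact distance (no clashes), approach left open
    from the top.

    Deterministic per seed. The reference pose is the placed ligand, scored
    with the default normal-potential parameters.
    """
    ligand = make_ligand(spec.ligand_template)
    lig_coords = ligand.coords[ligand.heavy_indices]
    lig_radii = ligand.heavy_radii
    if spec.pocket_radius <= ligand.bounding_radius:
        raise ValueError(
            f"pocket_radius {spec.pocket_radius} Å must exceed the ligand "
            f"bounding radius {ligand.bounding_radius:.2f} Å")
    rng = np.random.default_rng(spec.seed % (2 ** 31))
    n_lig = lig_coords.shape[0]
    # two-element pocket chemistry with a large vdW-radius contrast, so
    # mis-registered poses mismatch contact distances at every socket
    pocket_elements = ["O", "S"]
    # each pocket atom sockets one ligand atom at near-contact distance;
    # targets cycle over the ligand so every atom is held by ~equally many
    placed: list[np.ndarray] = []
    elements: list[str] = []
    for slot in range(spec.n_pocket_atoms):
        element = pocket_elements[slot % len(pocket_elements)]
        radius = vdw_radius(element)
        attempts = 0
        while True:
            attempts += 1
            if attempts > 2000:
                raise ValueError("infeasible pocket geometry: could not place "
                                 f"{spec.n_pocket_atoms} atoms at radius "
                                 f"{spec.pocket_radius} Å")
            # prefer cycling through the ligand atoms; fall back to random
            # targets for atoms too buried to socket
            t = (slot if attempts <= 100 else int(rng.integers(n_lig))) % n_lig
            direction = lig_coords[t] + rng.normal(size=3) * 1.2
            norm = np.linalg.norm(direction)
            if norm < 0.3:
                continue
            direction /= norm
            if direction[2] > 0.0:    # open approach hemisphere above the ligand
                continue
            gap = rng.uniform(0.05, 0.15)
            pos = lig_coords[t] + (lig_radii[t] + radius + gap) * direction
            if np.linalg.norm(pos) > spec.pocket_radius + 1.0:
                continue
            surf = (np.linalg.norm(lig_coords - pos, axis=1)
                    - (lig_radii + radius))
            if surf.min() < 0.04:     # must not clash with any other ligand atom
                continue
            if placed and np.min(np.linalg.norm(np.stack(placed) - pos,
                                                axis=1)) < 2.2:
                continue
            placed.append(pos)
            elements.append(element)
            break

    atoms = []
    residues: dict[tuple, list[int]] = {}
    resnames: dict[tuple, str] = {}
    for i, (pos, element) in enumerate(zip(placed, elements)):
        key = ("P", i + 1, "")
        atoms.append(Atom(element, pos, vdw_radius(element), i,
                          residue_id=key, name=element))
        residues[key] = [i]
        resnames[key] = "PKT"
    receptor = Receptor(atoms, residues, resnames)

    params = ScoringParams()
    provisional = Pose(ligand.coords, 0.0,
                       make_provenance("reference", conformation_id="holo"))
    bd = score_pose(receptor, ligand, provisional, params)
    if bd.vdw_repulsive > 1e-9:
        raise ValueError("construction failed: reference pose clashes with pocket")
    reference = Pose(ligand.coords, bd.total,
                     make_provenance("reference", conformation_id="holo"),
                     breakdown=bd)
    return receptor, ligand, reference


def make_cross_dock_case(holo: tuple[Receptor, Ligand, Pose],
                         spec: CrossDockSpec,
                         case_id: str | None = None) -> BenchmarkCase:
    """Derive an apo-like case: displace the ``n_clash_atoms`` pocket atoms
    nearest the ligand by ``clash_magnitude`` Å toward their nearest ligand
    atom. The reference pose is unchanged; difficulty is labeled
    ``challenging`` iff the resulting normal-potential repulsion at the
    reference pose exceeds the soft-mode cap ``e_cap``."""
    receptor, ligand, reference = holo
    lig_coords = ligand.coords[ligand.heavy_indices]
    lig_centroid = lig_coords.mean(axis=0)
    rec_coords = receptor.coords
    dists = np.array([np.linalg.norm(lig_coords - rec_coords[i], axis=1).min()
                      for i in range(receptor.n_atoms)])
    order = np.lexsort((np.arange(receptor.n_atoms), dists))
    n_clash = min(spec.n_clash_atoms, receptor.n_atoms)
    new_atoms = list(receptor.atoms)
    for i in order[:n_clash]:
        atom = receptor.atoms[i]
        if spec.clash_magnitude >= np.linalg.norm(atom.coords - lig_centroid):
            raise ValueError(
                f"clash_magnitude {spec.clash_magnitude} Å would move atom "
                f"{i} past the ligand centroid")
        nearest = lig_coords[np.linalg.norm(lig_coords - atom.coords,
                                            axis=1).argmin()]
        direction = nearest - atom.coords
        direction = direction / np.linalg.norm(direction)
        new_coords = atom.coords + spec.clash_magnitude * direction
        new_atoms[i] = Atom(atom.element, new_coords, atom.vdw_radius,
                            atom.serial, residue_id=atom.residue_id,
                            name=atom.name)
    receptor_dock = Receptor(new_atoms,
                             {k: list(v) for k, v in receptor.residues.items()},
                             dict(receptor.residue_names))
    params = ScoringParams()
    bd = score_pose(receptor_dock, ligand, reference, params)
    difficulty = "challenging" if bd.vdw_repulsive > params.e_cap else "typical"
    box = SearchBox.around(reference.coords[ligand.heavy_indices], margin=2.0)
    if case_id is None:
        case_id = f"case_s{spec.seed}_m{spec.clash_magnitude:.2f}"
    return BenchmarkCase(receptor_dock, ligand, reference, box,
                         case_id=case_id, difficulty=difficulty)


def make_clash_fixture() -> BenchmarkCase:
    """The frozen challenging fixture: regenerated from fixed constants."""
    holo = make_toy_complex(ToyComplexSpec(seed=CLASH_FIXTURE_TOY_SEED))
    return make_cross_dock_case(
        holo, CrossDockSpec(clash_magnitude=CLASH_FIXTURE_CLASH_MAGNITUDE,
                            n_clash_atoms=CLASH_FIXTURE_N_CLASH_ATOMS,
                            seed=CLASH_FIXTURE_TOY_SEED),
        case_id="clash_fixture")


def make_benchmark(n_cases: int, seed: int, difficulty_mix: float = 0.5,
                   out_dir: str | Path | None = None,
                   template: str = "flex6") -> list[BenchmarkCase]:
    """Generate a synthetic cross-docking benchmark.

    The first ``round(n_cases * difficulty_mix)`` cases are drawn with
    clash magnitudes in [1.0, 2.0] Å (challenging regime), the rest in
    [0.0, 0.3] Å (typical). Per-case seeds derive from ``seed``. If
    ``out_dir`` is given, cases are serialized in the evaluation manifest
    layout (one directory per case).
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    if not 0.0 <= difficulty_mix <= 1.0:
        raise ValueError("difficulty_mix must be in [0, 1]")
    n_challenging = int(round(n_cases * difficulty_mix))
    cases = []
    for i in range(n_cases):
        challenging = i < n_challenging
        case_seed = derive_seed(seed, f"bench.case{i}")
        rng = np.random.default_rng(case_seed)
        holo = make_toy_complex(ToyComplexSpec(seed=case_seed,
                                               ligand_template=template))
        if challenging:
            magnitude = float(rng.uniform(1.0, 2.0))
            n_clash = int(rng.integers(3, 6))
        else:
            magnitude = float(rng.uniform(0.0, 0.3))
            n_clash = 2
        case = make_cross_dock_case(
            holo, CrossDockSpec(magnitude, n_clash, seed=case_seed),
            case_id=f"case_{i:03d}")
        cases.append(case)
    if out_dir is not None:
        out_dir = Path(out_dir)
        for case in cases:
            save_case(case, out_dir / case.case_id)
    return cases
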