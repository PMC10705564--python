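"""Molecular structure I/O and ligand topology.

Receptors are read from PDB (via gemmi), ligands from SDF/MOL2 (via RDKit).
Everything is reduced to plain dataclasses carrying numpy coordinate arrays
so the scoring and sampling code never touches a toolkit object. Hydrogens
are kept but flagged; scoring, RMSD and torsion detection operate on heavy
atoms only, which matches the heavy-atom conventions of docking benchmarks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import TYPE_CHECKING, Any, Sequence

import gemmi
import networkx as nx
import numpy as np
from rdkit import Chem
from rdkit.Geometry import Point3D

if TYPE_CHECKING:  # pragma: no cover
    from glowives.scoring import EnergyBreakdown

logger = logging.getLogger(__name__)

#: Element -> van der Waals radius in Angstrom (Bondi-style values).
#: A fixed built-in table; unknown elements fall back to the carbon radius.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "B": 1.92, "SE": 1.90, "SI": 2.10,
}
DEFAULT_VDW_RADIUS = 1.70

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O", "TIP", "TIP3"}

#: SDF data tags used when serializing pose sets.
POSE_TAGS = ("GI_score", "GI_vdw_att", "GI_vdw_rep", "GI_internal",
             "GI_potential", "GI_conf_id", "GI_iteration", "GI_rank")

PROVENANCE_KEYS = ("potential", "conformation_id", "iteration", "rank")


class MolIOError(ValueError):
    """Base error for structure I/O and topology problems."""


class ParseError(MolIOError):
    """A file could not be parsed."""


class EmptyStructureError(MolIOError):
    """A receptor file yielded zero protein atoms."""


def vdw_radius(element: str) -> float:
    """Van der Waals radius for an element symbol (Å)."""
    return VDW_RADII.get(element.upper(), DEFAULT_VDW_RADIUS)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class Atom:
    """A single atom with coordinates in Å.

    ``residue_id`` is an opaque ``(chain, resseq, icode)`` key for receptor
    atoms and ``None`` for ligand atoms.
    """

    element: str
    coords: np.ndarray
    vdw_radius: float
    serial: int
    residue_id: tuple | None = None
    name: str = ""
    is_hydrogen: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise MolIOError(f"atom {self.serial}: coordinates must be a finite 3-vector")
        if not self.vdw_radius > 0:
            raise MolIOError(f"atom {self.serial}: vdW radius must be positive")
        if self.element.upper() == "H":
            self.is_hydrogen = True


@dataclass(frozen=True)
class Torsion:
    """A rotatable bond: ``axis=(fixed_end, moving_end)`` atom indices and the
    set of atoms that rotate with the moving end (axis atoms excluded)."""

    axis: tuple[int, int]
    moving: frozenset[int]


@dataclass(eq=False)
class Ligand:
    """A small molecule: atoms, explicit bond graph and rotatable torsions."""

    atoms: list[Atom]
    bonds: list[tuple[int, int, float]]
    torsions: list[Torsion] = field(default_factory=list)
    source_mol: Any = field(default=None, repr=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @cached_property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) array of input coordinates."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    @cached_property
    def heavy_indices(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if not a.is_hydrogen],
                        dtype=int)

    @cached_property
    def heavy_radii(self) -> np.ndarray:
        return np.array([self.atoms[i].vdw_radius for i in self.heavy_indices])

    @cached_property
    def graph(self) -> nx.Graph:
        """Full bond graph (all atoms)."""
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        for i, j, order in self.bonds:
            g.add_edge(i, j, order=float(order))
        return g

    @cached_property
    def heavy_graph(self) -> nx.Graph:
        """Bond graph restricted to heavy atoms, with element node labels."""
        g = nx.Graph()
        heavy = set(self.heavy_indices.tolist())
        for i in heavy:
            g.add_node(i, element=self.atoms[i].element.upper())
        for i, j, order in self.bonds:
            if i in heavy and j in heavy:
                g.add_edge(i, j, order=float(order))
        return g

    @cached_property
    def internal_pairs(self) -> np.ndarray:
        """Heavy-atom index pairs separated by >= 4 bonds (self-clash pairs)."""
        heavy = self.heavy_indices.tolist()
        g = self.heavy_graph
        close = {i: set(nx.single_source_shortest_path_length(g, i, cutoff=3))
                 for i in heavy}
        pairs = [(i, j) for ii, i in enumerate(heavy) for j in heavy[ii + 1:]
                 if j not in close[i]]
        return np.array(pairs, dtype=int).reshape(-1, 2)

    @cached_property
    def bounding_radius(self) -> float:
        """Max distance of any atom from the heavy-atom centroid (Å)."""
        center = self.coords[self.heavy_indices].mean(axis=0)
        return float(np.linalg.norm(self.coords - center, axis=1).max())

    def element_signature(self) -> tuple[str, ...]:
        return tuple(a.element.upper() for a in self.atoms)


@dataclass(eq=False)
class Receptor:
    """Protein heavy atoms grouped into residues."""

    atoms: list[Atom]
    residues: dict[tuple, list[int]]
    residue_names: dict[tuple, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for key, idxs in self.residues.items():
            for i in idxs:
                if i in seen:
                    raise MolIOError(f"atom {i} assigned to more than one residue")
                seen.add(i)
        if seen != set(range(len(self.atoms))):
            raise MolIOError("residue partition does not cover all atoms exactly")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @cached_property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)

    @cached_property
    def heavy_indices(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if not a.is_hydrogen],
                        dtype=int)

    @cached_property
    def heavy_coords(self) -> np.ndarray:
        return self.coords[self.heavy_indices].reshape(-1, 3)

    @cached_property
    def heavy_radii(self) -> np.ndarray:
        return np.array([self.atoms[i].vdw_radius for i in self.heavy_indices])


@dataclass(eq=False)
class Pose:
    """A ligand coordinate set with score and provenance.

    ``provenance`` always carries ``potential`` (normal|soft), a
    ``conformation_id`` naming the receptor conformation it was docked
    against, the ``iteration`` it was generated in and its ``rank`` in the
    final sorted set (-1 until assigned).
    """

    coords: np.ndarray
    score: float
    provenance: dict
    breakdown: "EnergyBreakdown | None" = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise MolIOError("pose coords must be an (n, 3) array")
        if not np.all(np.isfinite(self.coords)):
            raise MolIOError("pose coords must be finite")
        if not np.isfinite(self.score):
            raise MolIOError("pose score must be finite")
        missing = [k for k in PROVENANCE_KEYS if k not in self.provenance]
        if missing:
            raise MolIOError(f"pose provenance missing fields: {missing}")


def make_provenance(potential: str, conformation_id: str = "input",
                    iteration: int = 0, rank: int = -1, **extra) -> dict:
    return {"potential": potential, "conformation_id": conformation_id,
            "iteration": iteration, "rank": rank, **extra}


# ---------------------------------------------------------------------------
# Receptor I/O
# ---------------------------------------------------------------------------

def _element_from_name(name: str) -> str:
    """Infer an element symbol from a PDB atom name."""
    stripped = "".join(c for c in name if c.isalpha())
    if not stripped:
        return "C"
    two = stripped[:2].upper()
    if two in {"CL", "BR", "SE", "FE", "ZN", "MG", "MN", "NA"} and len(stripped) >= 2:
        return two.capitalize()
    return stripped[0].upper()


def read_receptor(path: str | Path, fmt: str = "pdb") -> Receptor:
    """Read a receptor from a PDB file.

    ATOM records become atoms grouped into residues keyed by
    ``(chain, resseq, icode)``. Waters and HETATM records (co-crystallized
    ligands, ions) are dropped. For alternate locations the highest-occupancy
    copy is kept (ties: first). Only the first MODEL is used.
    """
    if fmt != "pdb":
        raise MolIOError(f"unsupported receptor format: {fmt}")
    try:
        st = gemmi.read_pdb(str(path), split_chain_on_ter=False)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"could not parse PDB file {path}: {exc}") from None
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models in file")
    if len(st) > 1:
        logger.warning("%s: %d MODELs present; keeping the first only", path, len(st))
    model = st[0]

    atoms: list[Atom] = []
    residues: dict[tuple, list[int]] = {}
    resnames: dict[tuple, str] = {}
    serial = 0
    for chain in model:
        for res in chain:
            if res.name.upper() in WATER_NAMES or res.is_water():
                continue
            if res.het_flag == "H":
                continue  # co-crystallized ligands / ions
            key = (chain.name, res.seqid.num, (res.seqid.icode or "").strip())
            # altloc resolution: keep highest occupancy per atom name
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for at in res:
                if at.name not in best:
                    best[at.name] = at
                    order.append(at.name)
                elif at.occ > best[at.name].occ:
                    best[at.name] = at
            for nm in order:
                at = best[nm]
                elem = at.element.name if at.element.name not in ("X", "") \
                    else _element_from_name(nm)
                atom = Atom(elem, [at.pos.x, at.pos.y, at.pos.z],
                            vdw_radius(elem), serial, residue_id=key, name=nm)
                residues.setdefault(key, []).append(serial)
                atoms.append(atom)
                serial += 1
            resnames[key] = res.name
    if not atoms:
        raise EmptyStructureError(f"{path}: no protein ATOM records after filtering")
    return Receptor(atoms, residues, resnames)


def write_receptor(receptor: Receptor, path: str | Path) -> None:
    """Write a receptor back to PDB (ATOM records, one chain per input chain)."""
    st = gemmi.Structure()
    st.name = "glowives"
    model = gemmi.Model(1)
    chains: dict[str, gemmi.Chain] = {}
    for key in receptor.residues:
        chain_id = str(key[0]) if key and key[0] else "A"
        if chain_id not in chains:
            chains[chain_id] = gemmi.Chain(chain_id)
        res = gemmi.Residue()
        res.name = receptor.residue_names.get(key, "UNK")
        res.seqid = gemmi.SeqId(int(key[1]), key[2] if len(key) > 2 and key[2] else " ")
        res.het_flag = "A"
        for i in receptor.residues[key]:
            a = receptor.atoms[i]
            at = gemmi.Atom()
            at.name = a.name or a.element
            at.element = gemmi.Element(a.element)
            at.pos = gemmi.Position(*a.coords)
            at.occ = 1.0
            res.add_atom(at)
        chains[chain_id].add_residue(res)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Ligand I/O
# ---------------------------------------------------------------------------

def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".sdf", ".sd", ".mol"):
        return "sdf"
    if suffix == ".mol2":
        return "mol2"
    raise MolIOError(f"cannot infer ligand format from suffix {suffix!r}")


def read_ligand(path: str | Path, fmt: str | None = None) -> Ligand:
    """Read a single-molecule ligand file (SDF V2000 or MOL2) with explicit bonds."""
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
        mols = list(supplier)
        if not mols:
            raise ParseError(f"{path}: no molecule records found")
        if len(mols) > 1:
            raise MolIOError(
                f"{path}: contains {len(mols)} molecule records; extract the "
                "record you want into its own file (or use read_poses for pose sets)")
        mol = mols[0]
    elif fmt == "mol2":
        mol = Chem.MolFromMol2File(str(path), sanitize=False, removeHs=False)
    else:
        raise MolIOError(f"unsupported ligand format: {fmt}")
    if mol is None:
        raise ParseError(f"{path}: RDKit could not parse the molecule record")
    return ligand_from_rdkit(mol, origin=str(path))


def ligand_from_rdkit(mol: "Chem.Mol", origin: str = "<rdkit>") -> Ligand:
    """Convert an RDKit molecule (with a conformer and explicit bonds) to a Ligand."""
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        mol.UpdatePropertyCache(strict=False)
    if mol.GetNumConformers() == 0:
        raise ParseError(f"{origin}: molecule has no 3D coordinates")
    if mol.GetNumBonds() == 0 and mol.GetNumAtoms() > 1:
        raise ParseError(f"{origin}: missing bond block (explicit bonds required)")
    conf = mol.GetConformer()
    atoms = []
    for i, at in enumerate(mol.GetAtoms()):
        sym = at.GetSymbol()
        pos = conf.GetAtomPosition(i)
        atoms.append(Atom(sym, [pos.x, pos.y, pos.z], vdw_radius(sym), i,
                          name=f"{sym}{i + 1}"))
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
             for b in mol.GetBonds()]
    lig = Ligand(atoms, bonds, [], source_mol=mol)
    if lig.n_atoms > 1 and not nx.is_connected(lig.graph):
        raise MolIOError(f"{origin}: bond graph is disconnected")
    lig.torsions = detect_rotatable_bonds(lig)
    return lig


def detect_rotatable_bonds(ligand: Ligand) -> list[Torsion]:
    """Find rotatable torsions: single, acyclic bonds whose two ends each have
    >= 2 heavy-atom neighbors.

    The moving set is the smaller component after cutting the bond (the moving
    axis atom itself excluded); ties go to the component of the higher-index
    axis atom. Bonds that would rotate only hydrogens are excluded by the
    >=2-heavy-neighbor condition. Output is ordered by (min, max) atom index.
    """
    g = ligand.graph
    if ligand.n_atoms > 1 and not nx.is_connected(g):
        raise MolIOError("bond graph is disconnected")
    hg = ligand.heavy_graph
    bridges = {frozenset(e) for e in nx.bridges(hg)} if hg.number_of_edges() else set()
    heavy_deg = dict(hg.degree())
    out: list[Torsion] = []
    for i, j, order in sorted((min(i, j), max(i, j), o) for i, j, o in ligand.bonds):
        if i not in heavy_deg or j not in heavy_deg:
            continue
        if abs(order - 1.0) > 1e-6:
            continue
        if frozenset((i, j)) not in bridges:
            continue
        if heavy_deg[i] < 2 or heavy_deg[j] < 2:
            continue
        cut = g.copy()
        cut.remove_edge(i, j)
        comp_i = nx.node_connected_component(cut, i)
        comp_j = nx.node_connected_component(cut, j)
        if len(comp_j) <= len(comp_i):
            axis, moving = (i, j), frozenset(comp_j) - {j}
        else:
            axis, moving = (j, i), frozenset(comp_i) - {i}
        if not moving:
            continue
        out.append(Torsion(axis, moving))
    return out


# ---------------------------------------------------------------------------
# Pose set I/O (multi-record SDF with tagged fields)
# ---------------------------------------------------------------------------

def _to_rdkit(ligand: Ligand) -> "Chem.Mol":
    if ligand.source_mol is not None:
        return Chem.Mol(ligand.source_mol)
    em = Chem.RWMol()
    for a in ligand.atoms:
        em.AddAtom(Chem.Atom(a.element))
    order_map = {1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE,
                 3.0: Chem.BondType.TRIPLE, 1.5: Chem.BondType.AROMATIC}
    for i, j, order in ligand.bonds:
        em.AddBond(int(i), int(j), order_map.get(float(order), Chem.BondType.SINGLE))
    mol = em.GetMol()
    conf = Chem.Conformer(ligand.n_atoms)
    for i, a in enumerate(ligand.atoms):
        conf.SetAtomPosition(i, Point3D(*a.coords))
    mol.AddConformer(conf)
    mol.UpdatePropertyCache(strict=False)
    return mol


def write_ligand(ligand: Ligand, path: str | Path,
                 coords: np.ndarray | None = None) -> None:
    """Write a single SDF record for the ligand (optionally with other coords)."""
    mol = _to_rdkit(ligand)
    if coords is not None:
        conf = mol.GetConformer()
        for i in range(ligand.n_atoms):
            conf.SetAtomPosition(i, Point3D(*coords[i]))
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    writer.write(mol)
    writer.close()


def write_poses(poses: Sequence[Pose], ligand: Ligand, path: str | Path) -> None:
    """Write poses as a multi-record SDF with score/provenance tags."""
    if not poses:
        raise MolIOError("cannot write an empty pose list")
    base = _to_rdkit(ligand)
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for rank, pose in enumerate(poses):
            if pose.coords.shape[0] != ligand.n_atoms:
                raise MolIOError(
                    f"pose {rank}: {pose.coords.shape[0]} coordinates for a "
                    f"{ligand.n_atoms}-atom ligand")
            mol = Chem.Mol(base)
            conf = mol.GetConformer()
            for i in range(ligand.n_atoms):
                conf.SetAtomPosition(i, Point3D(*pose.coords[i]))
            mol.SetProp("GI_score", f"{pose.score:.6f}")
            if pose.breakdown is not None:
                mol.SetProp("GI_vdw_att", f"{pose.breakdown.vdw_attractive:.6f}")
                mol.SetProp("GI_vdw_rep", f"{pose.breakdown.vdw_repulsive:.6f}")
                mol.SetProp("GI_internal", f"{pose.breakdown.internal:.6f}")
            prov = pose.provenance
            mol.SetProp("GI_potential", str(prov["potential"]))
            mol.SetProp("GI_conf_id", str(prov["conformation_id"]))
            mol.SetProp("GI_iteration", str(prov["iteration"]))
            rk = prov.get("rank", -1)
            mol.SetProp("GI_rank", str(rk if rk >= 0 else rank))
            writer.write(mol)
    finally:
        writer.close()


def read_poses(path: str | Path) -> tuple[Ligand, list[Pose]]:
    """Read a pose-set SDF written by :func:`write_poses`.

    Returns the ligand topology (from the first record) and the pose list.
    """
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    mols = [m for m in supplier if m is not None]
    if not mols:
        raise ParseError(f"{path}: no molecule records found")
    ligand = ligand_from_rdkit(mols[0], origin=str(path))
    poses = []
    for rank, mol in enumerate(mols):
        conf = mol.GetConformer()
        coords = np.array([[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y,
                            conf.GetAtomPosition(i).z]
                           for i in range(mol.GetNumAtoms())])
        score = float(mol.GetProp("GI_score")) if mol.HasProp("GI_score") else 0.0
        prov = make_provenance(
            potential=mol.GetProp("GI_potential") if mol.HasProp("GI_potential") else "normal",
            conformation_id=mol.GetProp("GI_conf_id") if mol.HasProp("GI_conf_id") else "input",
            iteration=int(mol.GetProp("GI_iteration")) if mol.HasProp("GI_iteration") else 0,
            rank=int(mol.GetProp("GI_rank")) if mol.HasProp("GI_rank") else rank,
        )
        poses.append(Pose(coords, score, prov))
    return ligand, poses
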