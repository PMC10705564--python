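"""Constrained pocket minimization around a seed pose.

This is the step that manufactures new receptor conformations: residues
with any heavy atom within ``radius`` (default 8 Å) of the seed pose may
move; everything else — including the seed pose itself — stays fixed.

The objective is deliberately minimal: it only needs to make the pocket
relax away from the seed pose's volume without collapsing or flying apart.

* receptor-ligand vdW energy (normal, uncapped mode) between movable atoms
  and the seed pose;
* a receptor-receptor soft-sphere overlap term for pairs involving a
  movable atom; the per-pair contact distance is min(r0, initial r), so
  pre-existing (e.g. covalent) contacts are not penalized but *new*
  interpenetration is;
* harmonic positional tethers ``tether_k * ||x - x_start||^2`` on movable
  atoms.

Minimization is a derivative-free per-atom axis descent with shrinking
steps — robust and exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

from glowives.mol_io import Ligand, Pose, Receptor
from glowives.scoring import GAUSS_WIDTH, ScoringParams, _MIN_DIST


@dataclass(frozen=True)
class ShellSpec:
    """Partition of receptor residues into movable shell and frozen rest."""

    radius: float
    movable: frozenset
    frozen: frozenset

    def __post_init__(self) -> None:
        if self.movable & self.frozen:
            raise ValueError("movable and frozen residue sets overlap")


@dataclass(frozen=True)
class MinimizeConfig:
    max_iters: int = 200
    step0: float = 0.2
    tol: float = 1e-4
    tether_k: float = 1.0

    def __post_init__(self) -> None:
        for name in ("max_iters", "step0", "tol", "tether_k"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


class ExternalCommandMinimizer:
    """Adapter for an external minimization backend.

    The command is run with two arguments — a receptor PDB and the seed
    pose SDF — plus the output path for the relaxed conformation:

        cmd receptor.pdb seed.sdf out.pdb

    The returned structure must keep the residue layout of the input;
    frozen-residue coordinates are restored from the input afterwards, so
    backends need not implement the freezing themselves.
    """

    def __init__(self, command: list[str]):
        self.command = list(command)

    def __call__(self, receptor: Receptor, ligand: Ligand, seed: Pose,
                 shell: "ShellSpec", params: ScoringParams,
                 mcfg: "MinimizeConfig") -> Receptor:
        import subprocess
        import tempfile
        from pathlib import Path

        from glowives.mol_io import read_receptor, write_ligand, write_receptor

        with tempfile.TemporaryDirectory() as tmp:
            tmp = Path(tmp)
            write_receptor(receptor, tmp / "receptor.pdb")
            write_ligand(ligand, tmp / "seed.sdf", coords=seed.coords)
            out = tmp / "conf.pdb"
            subprocess.run(self.command + [str(tmp / "receptor.pdb"),
                                           str(tmp / "seed.sdf"), str(out)],
                           check=True)
            relaxed = read_receptor(out)
        if set(relaxed.residues) != set(receptor.residues):
            raise ValueError("external minimizer changed the residue layout")
        atoms = list(relaxed.atoms)
        for key in shell.frozen:
            for i_new, i_old in zip(relaxed.residues[key],
                                    receptor.residues[key]):
                atoms[i_new] = receptor.atoms[i_old]
        return Receptor(atoms, {k: list(v) for k, v in relaxed.residues.items()},
                        dict(relaxed.residue_names))


def select_movable_residues(receptor: Receptor, seed: Pose, radius: float,
                            ligand: Ligand | None = None) -> ShellSpec:
    """Residues with any heavy atom within ``radius`` of any seed-pose heavy
    atom are movable; the rest are frozen. Atom-to-atom distances."""
    if not radius > 0:
        raise ValueError("shell radius must be positive")
    seed_coords = seed.coords if ligand is None else seed.coords[ligand.heavy_indices]
    tree = cKDTree(np.asarray(seed_coords, float))
    movable = set()
    for key, idxs in receptor.residues.items():
        heavy = [i for i in idxs if not receptor.atoms[i].is_hydrogen]
        if not heavy:
            continue
        dists, _ = tree.query(receptor.coords[heavy], k=1)
        if np.any(dists <= radius):
            movable.add(key)
    frozen = set(receptor.residues) - movable
    return ShellSpec(radius, frozenset(movable), frozenset(frozen))


def minimize_pocket(receptor: Receptor, ligand: Ligand, seed: Pose,
                    shell: ShellSpec, params: ScoringParams,
                    mcfg: MinimizeConfig, *,
                    return_trace: bool = False):
    """Relax the movable shell around the seed pose.

    Returns the new receptor (frozen residues and the ligand untouched,
    bit-identical coordinates); with ``return_trace=True`` also returns the
    list of objective values after each accepted sweep (non-increasing).
    """
    if shell.movable | shell.frozen != set(receptor.residues):
        raise ValueError("shell spec does not match this receptor's residues")
    movable_atoms = sorted(i for key in shell.movable
                           for i in receptor.residues[key]
                           if not receptor.atoms[i].is_hydrogen)
    if not movable_atoms:
        return (receptor, [0.0]) if return_trace else receptor

    norm_params = params.as_mode("normal")
    coords = receptor.coords.copy()
    start = coords[movable_atoms].copy()
    rec_radii = np.array([a.vdw_radius for a in receptor.atoms])
    lig_coords = np.asarray(seed.coords, float)[ligand.heavy_indices]
    lig_radii = ligand.heavy_radii

    # pair lists from the initial geometry, with a margin for atom motion
    heavy_all = receptor.heavy_indices
    tree = cKDTree(coords[heavy_all])
    reach = float(rec_radii.max() * 2 + 2.5)
    movable_set = set(movable_atoms)
    neighbors: dict[int, list[int]] = {i: [] for i in movable_atoms}
    contact: dict[tuple[int, int], float] = {}
    for ii, jj in tree.query_pairs(reach):
        i, j = int(heavy_all[ii]), int(heavy_all[jj])
        if i not in movable_set and j not in movable_set:
            continue
        if receptor.atoms[i].residue_id == receptor.atoms[j].residue_id:
            continue
        r_init = float(np.linalg.norm(coords[i] - coords[j]))
        c = min(rec_radii[i] + rec_radii[j], r_init)
        contact[(i, j)] = contact[(j, i)] = c
        if i in movable_set:
            neighbors[i].append(j)
        if j in movable_set:
            neighbors[j].append(i)

    k_t = mcfg.tether_k
    w_att, w_rep = norm_params.w_att, norm_params.w_rep
    cutoff = norm_params.cutoff

    def atom_energy(i: int, pos: np.ndarray, x0: np.ndarray) -> float:
        e = k_t * float(np.sum((pos - x0) ** 2))
        dist = np.maximum(np.linalg.norm(lig_coords - pos, axis=1), _MIN_DIST)
        d = dist - (lig_radii + rec_radii[i])
        inrange = dist <= cutoff
        att = np.where(inrange, np.exp(-np.square(d / GAUSS_WIDTH)), 0.0)
        rep = np.where(inrange, np.square(np.minimum(d, 0.0)), 0.0)
        e += w_att * float(att.sum()) + w_rep * float(rep.sum())
        for j in neighbors[i]:
            r = max(float(np.linalg.norm(pos - coords[j])), _MIN_DIST)
            d_rr = r - contact[(i, j)]
            if d_rr < 0:
                e += w_rep * d_rr * d_rr
        return e

    def total_objective() -> float:
        e = 0.0
        for idx, i in enumerate(movable_atoms):
            e += atom_energy(i, coords[i], start[idx])
        # movable-movable soft-sphere pairs were counted twice above
        for idx, i in enumerate(movable_atoms):
            for j in neighbors[i]:
                if j in movable_set and j > i:
                    r = max(float(np.linalg.norm(coords[i] - coords[j])), _MIN_DIST)
                    d_rr = r - contact[(i, j)]
                    if d_rr < 0:
                        e -= w_rep * d_rr * d_rr
        return e

    energy = total_objective()
    trace = [energy]
    step = mcfg.step0
    for _it in range(mcfg.max_iters):
        sweep_delta = 0.0
        improved = False
        for idx, i in enumerate(movable_atoms):
            for axis in range(3):
                for sign in (1.0, -1.0):
                    trial = coords[i].copy()
                    trial[axis] += sign * step
                    d_e = atom_energy(i, trial, start[idx]) - \
                        atom_energy(i, coords[i], start[idx])
                    if d_e < -1e-12:
                        coords[i] = trial
                        energy += d_e
                        sweep_delta += d_e
                        improved = True
        trace.append(energy)
        if not improved:
            step *= 0.5
            if step < mcfg.step0 / 128:
                break
        elif -sweep_delta < mcfg.tol:
            break

    new_atoms = list(receptor.atoms)
    for idx, i in enumerate(movable_atoms):
        new_atoms[i] = replace(receptor.atoms[i], coords=coords[i].copy())
    out = Receptor(new_atoms, {k: list(v) for k, v in receptor.residues.items()},
                   dict(receptor.residue_names))
    return (out, trace) if return_trace else out
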