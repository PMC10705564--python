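"""Ligand graph automorphisms and symmetry-aware RMSD primitives.

Docked poses share the receptor coordinate frame, so RMSD is computed
without re-superposition. For symmetric ligands (rings, equivalent
substituents) the naive atom-order RMSD overstates the error; we minimize
over the bond-graph automorphism group (element- and bond-order-preserving
self-mappings), enumerated by backtracking with a hard cap.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
from networkx.algorithms import isomorphism

from glowives.mol_io import Ligand

logger = logging.getLogger(__name__)

AUTOMORPHISM_CAP = 10_000


def automorphisms(ligand: Ligand, cap: int = AUTOMORPHISM_CAP) -> np.ndarray:
    """Heavy-atom automorphism permutations of the ligand bond graph.

    Returns an (m, n_heavy) integer array; row k maps heavy-atom position i
    to position perm[k, i]. Mappings must preserve element and bond order
    (aromatic bonds compare as order 1.5). If more than ``cap`` mappings
    exist, falls back to the identity mapping with a warning.
    """
    cached = getattr(ligand, "_automorphism_cache", None)
    if cached is not None and cached[0] == cap:
        return cached[1]
    heavy = ligand.heavy_indices.tolist()
    pos = {atom_idx: k for k, atom_idx in enumerate(heavy)}
    g = ligand.heavy_graph
    node_match = isomorphism.categorical_node_match("element", "")
    edge_match = isomorphism.numerical_edge_match("order", 1.0, atol=0.01)
    matcher = isomorphism.GraphMatcher(g, g, node_match=node_match,
                                       edge_match=edge_match)
    perms: list[list[int]] = []
    capped = False
    for mapping in matcher.isomorphisms_iter():
        perms.append([pos[mapping[i]] for i in heavy])
        if len(perms) > cap:
            capped = True
            break
    if capped:
        logger.warning("ligand has > %d graph automorphisms; falling back to "
                       "the identity mapping for RMSD", cap)
        perms = [list(range(len(heavy)))]
    out = np.array(perms, dtype=int)
    ligand._automorphism_cache = (cap, out)  # type: ignore[attr-defined]
    return out


def rmsd_fixed_mapping(a: np.ndarray, b: np.ndarray) -> float:
    """Plain RMSD between two (n, 3) coordinate sets, no superposition."""
    diff = np.asarray(a, float) - np.asarray(b, float)
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def min_rmsd_over_perms(a: np.ndarray, b: np.ndarray, perms: np.ndarray) -> float:
    """min over permutations p of RMSD(a[p], b), no superposition."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    diff = a[perms] - b[None, :, :]           # (m, n, 3)
    rms = np.sqrt(np.mean(np.sum(diff * diff, axis=2), axis=1))
    return float(rms.min())


def min_rmsd_many(batch: np.ndarray, ref: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Symmetry-minimized RMSD of each coordinate set in ``batch`` (k, n, 3)
    against a single reference (n, 3). Returns a (k,) array."""
    batch = np.asarray(batch, float)
    permuted = batch[:, perms, :]             # (k, m, n, 3)
    diff = permuted - ref[None, None, :, :]
    rms = np.sqrt(np.mean(np.sum(diff * diff, axis=3), axis=2))
    return rms.min(axis=1)


def leader_cluster_indices(coord_sets: np.ndarray, cutoff: float,
                           perms: np.ndarray) -> list[int]:
    """Greedy leader clustering over pre-sorted coordinate sets.

    Walk the (k, n, 3) batch in its given (best-to-worst) order; keep an
    entry iff its symmetry-minimized RMSD to every kept entry exceeds
    ``cutoff``. Returns the kept indices in order.
    """
    if cutoff < 0:
        raise ValueError("cluster cutoff must be non-negative")
    kept: list[int] = []
    kept_coords: list[np.ndarray] = []
    for idx in range(coord_sets.shape[0]):
        cand = coord_sets[idx]
        if kept:
            arr = np.stack(kept_coords)        # (n_kept, n, 3)
            permuted = cand[perms]             # (m, n, 3)
            diff = arr[:, None, :, :] - permuted[None, :, :, :]
            rms = np.sqrt(np.mean(np.sum(diff * diff, axis=3), axis=2))
            if rms.min() <= cutoff:
                continue
        kept.append(idx)
        kept_coords.append(cand)
    return kept
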