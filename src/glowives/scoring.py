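"""Steric pose scoring in normal and softened van-der-Waals variants.

The function is a minimal two-term potential in the surface distance
d = r - r0 (r0 = sum of the pair's vdW radii):

* attraction: a unit-depth Gaussian well centered at d = 0 (width 0.5 Å),
  weighted by ``w_att`` (negative, so contacts are rewarded);
* repulsion: d^2 for d < 0, weighted by ``w_rep``; in **soft** mode the
  per-pair repulsion is capped at ``e_cap``, so a pose that interpenetrates
  the receptor pays a bounded clash penalty instead of an unbounded one.

A ligand internal term penalizes self-clashes between atoms >= 4 bonds
apart; it uses the uncapped repulsion in both modes so softening never
rewards self-clashing conformers. All terms vanish beyond ``cutoff``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

from glowives.mol_io import Ligand, Pose, Receptor

#: The attraction is a pair of Gaussians in the surface distance d = r - r0:
#: a narrow unit-depth well at contact (d = 0) that rewards near-perfect
#: shape complementarity, plus a weak broad well centered outside contact
#: that gives the energy landscape a long-range funnel for the search.
GAUSS_WIDTH = 0.3
GAUSS2_CENTER = 1.0
GAUSS2_WIDTH = 1.5
GAUSS2_DEPTH = 0.12

_MIN_DIST = 1e-6  # clamp for vectorized paths; exact zeros raise in pair_vdw


@dataclass(frozen=True)
class ScoringParams:
    """Weights and shape parameters of the vdW scoring function.

    ``e_cap`` is the soft-mode per-pair repulsion plateau (energy units);
    with the default 0.25 and quadratic repulsion, overlaps deeper than
    0.5 Å cost no extra. ``d_soft`` is reserved for an alternative
    linear-switch softening variant and is unused by the cap form.
    """

    w_att: float = -0.8
    w_rep: float = 1.6
    d_soft: float = 0.0
    e_cap: float = 0.25
    cutoff: float = 8.0
    mode: str = "normal"

    def __post_init__(self) -> None:
        if not self.e_cap > 0:
            raise ValueError("e_cap must be positive")
        if not self.cutoff >= 8.0:
            raise ValueError("cutoff must be at least 8 Å")
        if not (math.isfinite(self.w_att) and math.isfinite(self.w_rep)):
            raise ValueError("weights must be finite")
        if self.mode not in ("normal", "soft"):
            raise ValueError(f"mode must be 'normal' or 'soft', got {self.mode!r}")

    def as_mode(self, mode: str) -> "ScoringParams":
        return replace(self, mode=mode)


@dataclass(frozen=True)
class EnergyBreakdown:
    """Per-term energies; total = w_att*vdw_attractive + w_rep*vdw_repulsive
    + internal (the internal term is stored pre-weighted)."""

    vdw_attractive: float
    vdw_repulsive: float
    internal: float
    total: float


class PairEnergy(NamedTuple):
    attractive: float
    repulsive: float


def pair_vdw(r: float, r0: float, params: ScoringParams) -> PairEnergy:
    """Unweighted attractive/repulsive components for one atom pair.

    ``r`` is the center-center distance, ``r0`` the sum of the two vdW
    radii. Raises for non-positive ``r`` (coincident atoms).
    """
    if r <= 0:
        raise ValueError(f"coincident atoms: pair distance r = {r} must be positive")
    if r > params.cutoff:
        return PairEnergy(0.0, 0.0)
    d = r - r0
    att = math.exp(-((d / GAUSS_WIDTH) ** 2)) \
        + GAUSS2_DEPTH * math.exp(-(((d - GAUSS2_CENTER) / GAUSS2_WIDTH) ** 2))
    rep = d * d if d < 0 else 0.0
    if params.mode == "soft":
        rep = min(rep, params.e_cap)
    return PairEnergy(att, rep)


def _pair_terms(dist: np.ndarray, r0: np.ndarray,
                params: ScoringParams) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pair components; distances clamped away from zero."""
    dist = np.maximum(dist, _MIN_DIST)
    d = dist - r0
    att = np.exp(-np.square(d / GAUSS_WIDTH)) \
        + GAUSS2_DEPTH * np.exp(-np.square((d - GAUSS2_CENTER) / GAUSS2_WIDTH))
    rep = np.square(np.minimum(d, 0.0))
    if params.mode == "soft":
        rep = np.minimum(rep, params.e_cap)
    inrange = dist <= params.cutoff
    return np.where(inrange, att, 0.0), np.where(inrange, rep, 0.0)


def internal_energy(ligand: Ligand, coords: np.ndarray,
                    params: ScoringParams) -> float:
    """Ligand self-clash energy over heavy-atom pairs >= 4 bonds apart.

    Uncapped quadratic repulsion in both modes, pre-weighted by ``w_rep``.
    """
    pairs = ligand.internal_pairs
    if pairs.shape[0] == 0:
        return 0.0
    xi = coords[pairs[:, 0]]
    xj = coords[pairs[:, 1]]
    r = np.maximum(np.linalg.norm(xi - xj, axis=1), _MIN_DIST)
    radii = {i: ligand.atoms[i].vdw_radius for i in set(pairs.flatten().tolist())}
    r0 = np.array([radii[i] + radii[j] for i, j in pairs])
    d = np.minimum(r - r0, 0.0)
    return float(params.w_rep * np.sum(d * d))


def score_pose(receptor: Receptor, ligand: Ligand, pose: Pose,
               params: ScoringParams) -> EnergyBreakdown:
    """Score a pose: neighbor-searched receptor-ligand vdW sum plus the
    ligand internal term. Heavy atoms only; deterministic."""
    if pose.coords.shape[0] != ligand.n_atoms:
        raise ValueError(f"pose has {pose.coords.shape[0]} coordinates for a "
                         f"{ligand.n_atoms}-atom ligand")
    lig_coords = pose.coords[ligand.heavy_indices]
    lig_radii = ligand.heavy_radii
    att = rep = 0.0
    if receptor.heavy_coords.shape[0] > 0:
        tree = cKDTree(receptor.heavy_coords)
        neighbor_lists = tree.query_ball_point(lig_coords, params.cutoff)
        for k, idxs in enumerate(neighbor_lists):
            if not idxs:
                continue
            rc = receptor.heavy_coords[idxs]
            dist = np.linalg.norm(rc - lig_coords[k], axis=1)
            if np.any(dist <= 0):
                raise ValueError("coincident receptor and ligand atoms")
            r0 = lig_radii[k] + receptor.heavy_radii[idxs]
            a_terms, r_terms = _pair_terms(dist, r0, params)
            att += float(a_terms.sum())
            rep += float(r_terms.sum())
    internal = internal_energy(ligand, pose.coords, params)
    total = params.w_att * att + params.w_rep * rep + internal
    return EnergyBreakdown(att, rep, internal, total)


@njit(cache=True, fastmath=False)
def _pair_energy_grad(lig, rec, r0, cutoff, w_att, w_rep, e_cap, soft,
                      grad_out):  # pragma: no cover - exercised via wrapper
    """Receptor-ligand pair energy and per-ligand-atom gradient (jitted)."""
    energy = 0.0
    inv_w1sq = 1.0 / (GAUSS_WIDTH * GAUSS_WIDTH)
    inv_w2sq = 1.0 / (GAUSS2_WIDTH * GAUSS2_WIDTH)
    for i in range(lig.shape[0]):
        for j in range(rec.shape[0]):
            dx = lig[i, 0] - rec[j, 0]
            dy = lig[i, 1] - rec[j, 1]
            dz = lig[i, 2] - rec[j, 2]
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            if r > cutoff:
                continue
            if r < _MIN_DIST:
                r = _MIN_DIST
            d = r - r0[i, j]
            e1 = math.exp(-d * d * inv_w1sq)
            d2 = d - GAUSS2_CENTER
            e2 = math.exp(-d2 * d2 * inv_w2sq)
            att = e1 + GAUSS2_DEPTH * e2
            datt = -2.0 * d * inv_w1sq * e1 \
                - GAUSS2_DEPTH * 2.0 * d2 * inv_w2sq * e2
            rep = 0.0
            drep = 0.0
            if d < 0.0:
                rep = d * d
                drep = 2.0 * d
                if soft and rep >= e_cap:
                    rep = e_cap
                    drep = 0.0
            energy += w_att * att + w_rep * rep
            c = (w_att * datt + w_rep * drep) / r
            grad_out[i, 0] += c * dx
            grad_out[i, 1] += c * dy
            grad_out[i, 2] += c * dz
    return energy


class ScoringContext:
    """Precomputed receptor/ligand arrays for fast repeated scoring.

    Used by the sampler's inner loop; mathematically identical to
    :func:`score_pose` (dense all-pairs evaluation with the same cutoff).
    """

    def __init__(self, receptor: Receptor, ligand: Ligand,
                 params: ScoringParams) -> None:
        self.params = params
        self.ligand = ligand
        self.lig_heavy = ligand.heavy_indices
        self.lig_radii = ligand.heavy_radii
        self.rec_coords = receptor.heavy_coords
        self.rec_radii = receptor.heavy_radii
        self.r0 = self.lig_radii[:, None] + self.rec_radii[None, :]
        pairs = ligand.internal_pairs
        self._int_i = pairs[:, 0]
        self._int_j = pairs[:, 1]
        radii = np.array([a.vdw_radius for a in ligand.atoms])
        self._int_r0 = radii[self._int_i] + radii[self._int_j] \
            if pairs.shape[0] else np.empty(0)

    def _internal(self, coords: np.ndarray) -> float:
        if self._int_i.shape[0] == 0:
            return 0.0
        r = np.maximum(np.linalg.norm(coords[self._int_i] - coords[self._int_j],
                                      axis=1), _MIN_DIST)
        d = np.minimum(r - self._int_r0, 0.0)
        return float(self.params.w_rep * np.sum(d * d))

    def breakdown(self, coords: np.ndarray) -> EnergyBreakdown:
        """Full energy breakdown for an (n_atoms, 3) coordinate set."""
        att = rep = 0.0
        if self.rec_coords.shape[0] > 0:
            lig = coords[self.lig_heavy]
            diff = lig[:, None, :] - self.rec_coords[None, :, :]
            dist = np.sqrt(np.sum(diff * diff, axis=2))
            a_terms, r_terms = _pair_terms(dist, self.r0, self.params)
            att = float(a_terms.sum())
            rep = float(r_terms.sum())
        internal = self._internal(coords)
        total = self.params.w_att * att + self.params.w_rep * rep + internal
        return EnergyBreakdown(att, rep, internal, total)

    def total(self, coords: np.ndarray) -> float:
        return self.breakdown(coords).total

    def energy_grad(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        """Total energy and its analytic gradient w.r.t. atom positions.

        The gradient is zero for hydrogens (they carry no energy terms).
        """
        p = self.params
        grad = np.zeros_like(coords)
        energy = 0.0
        if self.rec_coords.shape[0] > 0:
            lig = np.ascontiguousarray(coords[self.lig_heavy])
            g = np.zeros_like(lig)
            energy += _pair_energy_grad(
                lig, self.rec_coords, self.r0, p.cutoff, p.w_att, p.w_rep,
                p.e_cap, p.mode == "soft", g)
            grad[self.lig_heavy] += g
        if self._int_i.shape[0]:
            diff = coords[self._int_i] - coords[self._int_j]
            dist = np.maximum(np.linalg.norm(diff, axis=1), _MIN_DIST)
            d = np.minimum(dist - self._int_r0, 0.0)
            energy += float(p.w_rep * np.sum(d * d))
            dint = p.w_rep * 2.0 * d / dist
            np.add.at(grad, self._int_i, dint[:, None] * diff)
            np.add.at(grad, self._int_j, -dint[:, None] * diff)
        return energy, grad
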