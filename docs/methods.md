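# Methods

## The problem

Rigid-receptor docking fails systematically when the receptor structure was
determined without the query ligand (cross-docking): pocket atoms sit where
the ligand's correct pose needs to be, the correct pose accrues a large van
der Waals (vdW) repulsion, and the search discards it. `glowives`
implements two protocols that attack this failure mode at the *sampling*
level, without using any knowledge of the correct pose:

* **GLOW** pools the poses of two rigid docking runs — one under the normal
  vdW potential, one under a *softened* potential whose short-range
  repulsion is capped — so clash-tolerant poses survive into the candidate
  set. Soft-run poses are rescored under the normal potential before
  merging, so one consistent scale orders the pooled list.
* **IVES** uses the softened potential to generate *seed poses*, relaxes
  the receptor pocket around each seed (residues within 8 Å may move;
  everything else, including the seed pose, stays fixed), redocks the
  ligand onto each relaxed conformation with both potentials, and merges
  all pose sets. Because per-conformation runs are independent, the merged
  result does not depend on processing order. The workflow can iterate by
  re-seeding from the merged set; one iteration is the default.

A third protocol, **Default**, is the baseline: one normal-potential run
truncated to 20 poses.

## Scoring model

The engine scores receptor–ligand heavy-atom pairs in the surface distance
`d = r − r0`, with `r0` the sum of the two Bondi-style vdW radii (built-in
element table, carbon fallback 1.70 Å):

* attraction `A(d) = exp(−(d/0.3)²) + 0.12·exp(−((d−1.0)/1.5)²)`, weighted
  by `w_att = −0.8`. The narrow unit-depth well rewards near-perfect
  contacts; the weak broad well gives the landscape a long-range funnel so
  local optimization can home in on the pocket. (A single well produced an
  energy surface the search could not navigate: no gradient information
  beyond ~1 Å of contact.)
* repulsion `R(d) = d²` for `d < 0`, weighted by `w_rep = 1.6`. In **soft**
  mode the per-pair repulsion is capped at `e_cap = 0.25`, i.e. overlaps
  deeper than 0.5 Å cost no more than the cap — the soft-core plateau that
  lets clashing poses survive. `d_soft` is reserved for an alternative
  linear-switch softening and is unused by the cap form.
* all terms vanish beyond `cutoff = 8 Å` (the Gaussians are numerically
  zero there, so the truncation is continuous in practice).
* a ligand-internal term penalizes self-clashes between heavy atoms four or
  more bonds apart, with the *uncapped* repulsion in both modes, so
  softening never rewards self-clashing conformers. It is stored
  pre-weighted, making `total = w_att·att + w_rep·rep + internal` exact.

There are no electrostatic, hydrogen-bond, hydrophobic or torsion-count
terms: the mechanism under study is purely steric, and extra terms would be
invented chemistry. Scores are in arbitrary units; only orderings and
differences matter. Hydrogens are carried through I/O but excluded from
scoring, RMSD and torsion detection.

## Pose search

`sample_poses` is an iterated local search (basin hopping), the search
character of the Vina family:

* `n_chains` independent chains (default 8), chain *k* seeded with
  `seed + k`. Each starts from a uniform random placement in the search
  box (uniform orientation, uniform torsions) and is immediately locally
  minimized.
* one *hop* = one randomized perturbation — translation ≤ 1.2 Å, rigid
  rotation ≤ 45°, or a single-torsion twist ≤ 120°, chosen uniformly —
  followed by greedy local minimization, accepted by a Metropolis test on
  the minimized energies. `n_steps` is a step budget; each hop accounts
  for 40 steps (default 2000 steps → 50 hops per chain).
* the Metropolis temperature anneals geometrically from 2× to 0.1× the
  configured `temperature` (default 1.5 in energy units) across the chain:
  hot early for basin coverage, cold late to settle.
* local minimization is steepest descent with backtracking line search
  over the pose degrees of freedom (translation, rigid rotation, torsion
  angles), using the analytic gradient of the scoring function (the pair
  terms are Gaussians and quadratics; rotational and torsional components
  come from the standard torque formulas). The ligand's heavy-atom
  centroid is clamped to the box.
* every visited minimum is recorded; the pooled minima are re-minimized
  from the best geometry-diverse candidates, sorted by energy (ties broken
  by chain then hop index — a total order), deduplicated by greedy leader
  clustering at `cluster_cutoff = 1.0 Å` symmetry-corrected RMSD, and
  truncated to `max_poses = 300`.

Identical seeds give bitwise-identical pose sets; pooling more chains can
only improve the best energy because per-chain streams are independent.

An earlier design followed the more literal plain-Metropolis scheme (small
moves, single end-of-chain refinement). It could not reliably enter
concave pockets: chains froze in the first acceptable basin and
coordinate-wise refinement stalled at the pocket rim. Minimized-hop
Metropolis fixed both failure modes at equal cost, so it is the shipped
design.

## Pocket minimization (IVES)

`minimize_pocket` relaxes the movable shell under a deliberately minimal
objective — the only property IVES needs is "the pocket yields to the seed
pose without collapsing or flying apart":

* normal-mode receptor–ligand vdW energy between movable atoms and the
  (fixed) seed pose;
* a receptor–receptor soft-sphere overlap for pairs involving a movable
  atom, with per-pair contact distance `min(r0, r_initial)` — pre-existing
  contacts (covalent neighbors, native packing) are free, but *new*
  interpenetration is penalized;
* harmonic tethers `tether_k·‖x − x_start‖²` (default `tether_k = 1`
  energy/Å²) keeping the conformation near the input.

Minimization is a derivative-free per-atom axis sweep with shrinking steps
(`step0 = 0.2 Å`, halved when a sweep makes no progress, floor
`step0/128`; convergence when a sweep improves less than `tol = 1e-4`;
at most `max_iters = 200` sweeps). Only energy decreases are accepted, so
the objective trace is non-increasing and the result is exactly
reproducible. Whole residues are movable if any heavy atom lies within the
shell radius (atom-to-atom distance to the seed pose); the granularity is
residue-level by design, and the shell radius default is 8 Å.

## Success metric

A pose is *correct* if its heavy-atom RMSD to the reference pose is at
most 2.0 Å, inclusive. Poses share the receptor frame, so no
re-superposition is applied. RMSD is minimized over the ligand bond-graph
automorphism group (element- and bond-order-preserving self-mappings,
enumerated by backtracking with a 10,000-mapping cap; beyond the cap the
identity mapping is used with a warning). Symmetry correction only
tightens fairness — it never exceeds the naive value, and both are
reported. Benchmark success rates are the percentage of cases with any
correct pose.

## Synthetic cross-docking fixtures

The generator builds a pseudo-receptor around a known reference pose:

* Ligand templates: `rigid4` (4-membered ring, rigid), `flex6` (six heavy
  atoms, one rotatable torsion; default), `ring6` (benzene-like hexagon,
  used mainly to exercise symmetry-corrected RMSD). `flex6` carries
  high-contrast heteroatoms (F/S ends, O/C substituents) so that
  end-swapped registrations are energetically distinguishable — with an
  all-carbon ligand the pocket cannot tell near-mirror poses apart and the
  "correct pose" is not well defined energetically.
* Pocket: `n_pocket_atoms` (default 18) single-atom residues placed as
  *sockets* — each at near-contact distance (gap 0.05–0.15 Å) from one
  ligand atom, cycling over the ligand so every atom is held — with
  alternating O/S chemistry (vdW radii 1.52/1.80 Å) so mis-registered
  poses mismatch contact distances at every socket. Directions avoid an
  open approach cone at the top and keep ≥ 2.2 Å between pocket atoms.
  This makes the reference pose the global minimum of the normal-mode
  energy by construction while leaving the pocket enterable.
* Apo-like variant: the `n_clash_atoms` pocket atoms nearest the ligand
  move `clash_magnitude` Å straight toward their nearest ligand atom.
  The reference-pose repulsion is monotone non-decreasing in the clash
  magnitude (the dial), and a case is labeled *challenging* when that
  repulsion exceeds the soft-mode cap `e_cap`.
* Benchmarks draw challenging cases with clash magnitudes in [1.0, 2.0] Å
  (3–5 clash atoms) and typical cases in [0, 0.3] Å, from per-case derived
  seeds; cases serialize to a one-directory-per-case manifest
  (receptor.pdb, ligand.sdf, reference.sdf, case.yaml).
* The frozen challenging fixture (`make_clash_fixture`) uses toy seed 3
  with 10 clash atoms at 2.2 Å, calibrated once so that the Default
  baseline misses the reference pose while GLOW and IVES recover it, then
  frozen.

What the toys do **not** emulate: real protein topology (bonded residues,
backbones, rotamers), chemistry beyond sterics, solvent, conformational
strain, or AlphaFold-specific error modes. Passing tests demonstrate that
the protocols' *mechanisms* work — soft-potential pooling and
pocket-relaxation rescue clash-blocked poses, success is monotone across
protocol strength — not that any particular accuracy transfers to real
complexes.

## Problem sizes and reproducibility

Tests and the acceptance script run at desk scale by choice: 18-atom
pockets, 4–6-atom ligands, sampler budgets of 3–6 chains × 240–1200 steps,
IVES with 2–5 conformations, and 10-case benchmarks. The library defaults
(8 chains × 2000 steps, 20 conformations, 300 poses per conformation)
are larger. All randomness flows from explicit integer seeds; sub-run
seeds derive from a master seed and a stage label via CRC32, so parallel
stages are reproducible and order-independent.

## Known limitations

* The scoring function is a steric stand-in, not a calibrated force field;
  absolute energies are meaningless outside the package.
* The softened potential's cap form is one declared choice among several
  plausible soft-core variants; it is isolated behind `ScoringParams` so a
  switch-based variant can be swapped in.
* The pocket minimizer moves atoms independently (no bonded terms), which
  is appropriate for the single-atom-residue toys but would distort real
  side chains; `run_ives` accepts any callable with the
  `minimize_pocket` signature as a backend, and
  `pocket_min.ExternalCommandMinimizer` shells out to an external program
  (receptor PDB + seed SDF in, relaxed PDB out) for production use.
* Graph-automorphism RMSD enumerates at most 10,000 mappings; highly
  symmetric ligands beyond the cap fall back to the identity mapping with
  a warning.
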