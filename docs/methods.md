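# Methods

## The boundary-value model

The package treats folding as a two-point boundary-value problem.  A path
{q_j}, j = 0…P, connects a fixed "reactant" frame q_0 (extended chain) to a
fixed "product" frame q_P (native structure) with time increment Δ, total
duration τ = PΔ, and discretized action

    S = Σ_{j=0}^{P−1} L_j Δ,
    L_j = Σ_I m_I/(2Δ²) |q_{I,j} − q_{I,j+1}|² − V(q_j).

Stationary points of S over the interior frames are discrete Newtonian
trajectories.  Plain stationarity neither fixes the energy of the motion
nor yields a well-posed minimization (the −V term alone is unbounded), so
the working objective is the penalized action

    Θ = S + μ Σ_{j=0}^{P−1} (E_j − E_target)²,
    E_j = K_j + V(q_j),   K_j = Σ_I m_I/(2Δ²)|q_{I,j} − q_{I,j+1}|²,

minimized with L-BFGS over the flattened interior coordinates using the
analytic gradient (each interior frame couples to its two neighbours
through the kinetic terms plus ∇V of its own frame; the penalty adds the
chain-rule terms of E_{j−1} and E_j).  Endpoint frames carry no gradient
entries and are bit-identical before and after optimization.

### Parameters

| name | meaning | default | notes |
|------|---------|---------|-------|
| P (`n_segments`) | time slices; path has P+1 frames | 100 | 2000 mirrors production-scale runs; toys use P ≤ 100 |
| Δ (`delta_t`) | reduced time increment | 1.0 | 0.02 on the Müller-Brown surface (its well depths are ~10² units) |
| μ (`penalty_weight`) | conservation weight | 1.0 | variance of E_j along the converged path decreases monotonically in μ |
| `target_energy` | E_target | max(V(q_0), V(q_P)) + `target_margin` | margin default 0 |
| `noise_amplitude` | Gaussian σ per coordinate of the trial path | 0.5 Å | interpolation+noise; a fully random initialization is selectable |
| `gradient_tolerance` | max-norm stop | 1e-6 | 1e-4 for the 23-bead runs (energies in ε ≈ 1) |

### Lowest-barrier refinement

With E_target fixed below the lowest ridge between the basins, the penalty
is minimized by crossing the ridge at its lowest point — but a single fixed
target leaves a systematic overshoot in the peak energy (≈ 3.6 units on
Müller-Brown, independent of μ, because the crossing geometry is set by
the penalty-vs-kinetic balance, not by the saddle).  The refinement used
for barrier localization therefore ratchets the target: optimize, set
E_target ← max_j V(q_j) − offset, re-optimize, and keep the lowest-barrier
path; the loop stops when the barrier stops improving, which happens once
the target has fallen below the lowest crossing.  With offset 0.5 and ≤ 12
rounds the selected peak frame on Müller-Brown lands within 0.01 units of
the independently located saddle.  On funneled (essentially barrierless)
landscapes the refinement is unnecessary and disabled by default
(`anneal_rounds = 0`).

### Ensemble and selection

`run_ensemble` performs independent seeded minimizations and selects by
(1) smallest potential-energy barrier max_j V(q_j) − V(q_0), ties broken by
(2) smaller mean potential energy, then (3) seed order.  Individual run
failures (non-finite action) are recorded; the ensemble proceeds while at
least one run converges.  Identical configuration and seeds give
bit-identical selected pathways and metrics tables.

## Potentials

* **Toys** (harmonic well, 1-D double well, Müller-Brown with the canonical
  four-Gaussian constants) have closed-form gradients and known stationary
  points; they are the oracle landscapes of the test suite.
* **Gō model** (Cα beads, reduced units: ε = 1, bead mass = 1): harmonic
  bonds k(b − b₀)² with k = 100 ε/Å² pinned at the native bond lengths,
  12-10 wells ε[5(σ_ij/r)¹² − 6(σ_ij/r)¹⁰] pinned at the native distance of
  each contact pair (depth −ε at r = σ_ij), and (σ/r)¹² repulsion with
  σ = 4 Å for every other pair with |i−j| ≥ 2.  The native structure is a
  local minimum (gradient < 1e-6 after polishing) and the global funnel
  bottom.
* **All-atom relaxation** (`StericChainPotential`): harmonic restraints on
  covalent 1-2 and 1-3 distances at their ideal-geometry reference values
  (bonds detected by a covalent-radius rule, r < 1.3(r_i + r_j)), plus
  truncated (σ/r)¹² repulsion beyond 1-4 connectivity with per-element
  contact radii.  It is a geometric regularizer: built structures are near
  its minimum, so local minimization removes residual clashes without
  unfolding the chain.
* **External engines** attach through `external_engine_adapter`, which
  validates the gradient against central finite differences before
  returning; a missing backend raises a configuration error and leaves the
  rest of the package fully usable.

## Structure building

`build_extended` places the backbone with internal coordinates (NeRF) at
ideal bond lengths/angles and uniform (φ, ψ, ω), then grafts side chains
and hydrogens from ideal-geometry residue templates superposed on each
N-CA-C triad.  Lower-case sequence letters are D-amino acids (mirrored
template; D-proline uses its own template).  Proline φ is fixed at −75°
(+75° for D-proline) regardless of the requested φ — the ring leaves no
choice, and an unconstrained φ drives the ring into the preceding
carbonyl.  Default extended dihedrals are (−135°, 135°, 180°); with them
the minimized 23-residue chain has a mass-weighted Rg of 23.0 Å.  Carbonyl
oxygens are placed in the ψ-defined peptide plane anti to the next
nitrogen; amide hydrogens on the in-plane bisector of the two N bonds
(N-H 1.01 Å).  A chain without a C-terminal cap uses a fixed trans
convention for the last carbonyl plane, so a single residue is independent
of the requested dihedrals.

Rg is mass-weighted over all atoms by default; uniform and Cα-only
weightings are selectable.  RMSD is the minimum over rigid superpositions
(Kabsch); local RMSD superposes on the selected residue range only.

## Analysis criteria

* **Native contact**: residue pair with |i−j| ≥ 3 ("separated by more than
  two residues") and Cα-Cα distance < 6.5 Å.  The native pair set is
  detected on the native structure; per-frame counts re-test only the
  distance.
* **Backbone hydrogen bond**: acceptor carbonyl O and donor amide N closer
  than 2.5 Å with the O···H-N angle at the hydrogen > 135°.  The O-N
  dialect is the default as printed, although 2.5 Å is short for an O-N
  separation (an ideal α-helix has O-N ≈ 3.1 Å and is found by the O-H
  dialect, also provided); no intent is assumed.  Missing amide hydrogens
  are placed at ideal geometry.
* **Formation step**: first frame from which the criterion holds for ≥ 5
  consecutive frames (configurable) — transient on/off flicker of a
  marginal pair is not a formation event.  Orders are sorted by step, ties
  by pair index.
* **Collapse milestone**: `fraction_formed_at_rg(metrics, f)` finds the
  first frame at which the Rg series has completed fraction f of its total
  initial→final reduction and reports the percentage of native contacts
  and hydrogen bonds formed there.  The headline diagnostic uses f = 0.7
  (the chain has come within 30 % of its native Rg along the
  extended→native range).

## The synthetic ββα system

`make_bba5_mimic` builds a 23-bead Cα chain whose contact topology follows
the ββα architecture: hairpin contacts among residues 1–10 ((1,7), (1,8),
(1,9), (2,7), (3,6)), helix (i,i+3)/(i,i+4) ladders over residues 11–23,
and the hairpin-helix core ((8,14), (14,17), (14,18)).  The native
geometry is produced by distance-restraint embedding (bonds at 3.8 Å,
helix pairs at 5.15/6.15 Å, other contacts at 5.5 Å, lower-bound
repulsion) from a crude planar-hairpin + ideal-helix layout, polished
under its own Gō potential, with the contact map re-detected until the
model's native state realizes exactly its own contact list (35 pairs, the
25 requested plus packing neighbours).  The whole construction is seeded
and deterministic.  The extended endpoint is the exact 3.8 Å rod
(Rg = 25.2 Å by the discrete-rod formula); it is deliberately not
minimized under the Gō potential, whose long-ranged contact tails leave no
extended local minimum to relax into.

On a bead chain there are no O/H/N atoms, so hydrogen bonds are proxied by
the contact pairs that correspond to actual H-bond registries: (i, i+4)
within the helix (an α-helix hydrogen bond links residue i's carbonyl to
residue i+4's amide) plus the hairpin rung pairs (1,8), (2,7), (3,6).
(i, i+3) contacts are side contacts, not hydrogen-bond registries, and are
excluded from the proxy set.

What the mimic does and does not show: it reproduces, as emergent
properties of action minimization on a funnel, the qualitative folding
order of the ββα architecture — compaction before secondary structure
(0 % of H-bond proxies and ~26 % of contacts formed at the 70 % collapse
milestone) and helix before hairpin (mean persistent-formation step ≈ 62
vs ≈ 88 of 100).  It does not model solvation, side-chain packing,
salt bridges, or energetic frustration; its nearly barrierless funnel and
very smooth optimized paths (top principal components cover essentially
all path variance, far above what a thermally noisy trajectory would give)
are idealizations.  Passing tests on the mimic validate the machinery and
the ordering logic, not quantitative claims about real BBA5 energetics.

## Numerical choices

* L-BFGS-B throughout; `local_minimize` finishes small systems (≤ 300
  degrees of freedom) with a Newton root solve on the gradient when the
  line search stalls on a flat quadratic basin.
* Minimization never accepts an uphill result; action histories are
  recorded per accepted iterate and are non-increasing.
* Covariance uses population normalization 1/(P+1) over all frames; frames
  are by default superposed onto the final (native) frame before
  covariance assembly so rigid-body drift does not contaminate the
  fluctuations (`alignment_mode="none"` gives the literal unaligned form).
* Eigenvalues below 1e-8 × trace are clamped to zero; eigenvector signs
  are fixed so each component's largest-magnitude entry is positive.
* PDB coordinates are written as fixed-point %8.3f (occupancy 1.00,
  B-factor 0.00) and stored in single precision by the I/O layer, so
  round-trips are exact to ~5e-4 Å.
* Random trial paths use `numpy.random.default_rng(seed)`; every stochastic
  step in the package takes an explicit seed.

## Problem sizes

The shipped study conditions are desk-scale by design: P = 100 segments
and 10 seeds for the mimic ensemble (P = 2000, matching production-scale
discretization, remains fully configurable), P ≤ 100 for the toy-system
validations, and 100 randomized instances per metric oracle.

## Known limitations

* The Gō mimic's contact energies are uniform (ε = 1); no attempt is made
  to reproduce real BBA5 energetics or NMR geometry.
* The all-atom relaxation potential has no torsional or electrostatic
  terms; it is for removing clashes near ideal geometry, not for folding.
* Barrier localization assumes the two endpoints lie in distinct basins of
  a smooth potential; on rugged landscapes the ratcheted target can stall
  at a locally lowest pass.
* H-bond detection requires resolvable backbone N/H/C/O atoms (or ideal-
  geometry H placement); bead models must use the registry-proxy route.
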