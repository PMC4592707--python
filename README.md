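# admdpath

Folding-pathway models from boundary-value trajectory optimization.

Molecular dynamics answers "what happens next" from an initial state.  Many
questions about protein folding are better posed the other way around: given
the two end states — an extended chain and the folded native structure —
what is the most probable trajectory connecting them?  `admdpath` solves
this boundary-value problem by minimizing a penalized discretized classical
action over the interior frames of a path, and then reads the folding order
off the optimized pathway: chain compaction (radius of gyration), native
contacts, backbone hydrogen bonds, per-segment RMSD, formation orders, and
principal components of the Cα fluctuations.

It is aimed at people studying folding mechanisms of small proteins (the
shipped synthetic system mimics the 23-residue ββα mini-protein BBA5,
Ace-YRVpSYDFSRSDELAKLLRQHAG-NH2, with a D-proline at position 4) and at
people developing path-optimization methods who need a tested reference
implementation with analytic-oracle landscapes.

## The method

A path is a sequence of frames q_0 … q_P with fixed endpoints and time
increment Δ.  Its discretized action is

    S = Σ_{j=0}^{P−1} L_j Δ,
    L_j = Σ_I  m_I/(2Δ²) |q_{I,j} − q_{I,j+1}|²  −  V(q_j),

whose stationary points are discrete Newtonian trajectories (δS = 0).
Because stationarity alone does not select the energy of the motion, the
working objective adds a total-energy-conservation penalty,

    Θ = S + μ Σ_j (E_j − E_target)²,       E_j = K_j + V(q_j),

minimized with L-BFGS over the interior frames (endpoints never move).
Independent seeded runs from randomized trial paths form an ensemble; the
pathway with the lowest potential-energy barrier, max_j V(q_j) − V(q_0), is
selected.  An optional refinement ratchets E_target down to just below the
current peak energy, which drives the crossing through the lowest pass
between the end basins (on the Müller-Brown surface the selected path's
peak frame lands on the known saddle to better than 0.01 energy units).

Potentials are pluggable: analytic toys (harmonic, double-well,
Müller-Brown) for validation, a coarse-grained Cα Gō model (12-10
native-contact wells, harmonic bonds, short-range repulsion) as the
shipped desk-scale stand-in for an all-atom force field, and an adapter
contract for hanging an external all-atom engine on the same interface.

## Worked example

```python
from admdpath import ActionParams, run_ensemble
from admdpath.analysis import (compute_metrics, fraction_formed_at_rg,
                               formation_order, distance_series)
from admdpath.pca import compute_covariance, eigendecompose, variance_fraction
from admdpath.synthetic import make_bba5_mimic

system = make_bba5_mimic()                    # 23-bead ββα mimic + Gō model
params = ActionParams(n_segments=100, seed=0, penalty_weight=1.0,
                      max_iterations=2000, gradient_tolerance=1e-4)
ensemble = run_ensemble((system.extended, system.native), system.potential,
                        params, n_runs=3)
best = ensemble.selected
print(f"selected seed {best.seed}, barrier {best.barrier:.3f} eps "
      f"at frame {best.barrier_index}")

proxies = [p for p in system.spec.hbond_proxy_pairs
           if p in system.go_spec.contact_map]
metrics = compute_metrics(best.path, system.potential, system.native,
                          hbond_proxy_pairs=proxies, rg_weighting="uniform")
d = fraction_formed_at_rg(metrics, 0.7)
print(f"Rg {metrics.rg[0]:.1f} -> {metrics.rg[-1]:.1f} A; at 70% compaction "
      f"(frame {d.frame_index}): {d.percent_contacts:.1f}% contacts, "
      f"{d.percent_hbonds:.1f}% H-bond proxies")

series = {p: distance_series(best.path, p) for p in system.go_spec.contact_map}
order = formation_order(series, cutoff=6.5, persistence=5)
print("first contacts formed:", " -> ".join(str(p) for p, _ in order[:5]))

pca = eigendecompose(compute_covariance(best.path))
print(f"top-3 principal components cover "
      f"{100*variance_fraction(pca, 3):.1f}% of the variance")
```

Output:

```
selected seed 1, barrier 0.092 eps at frame 1
Rg 25.2 -> 7.3 A; at 70% compaction (frame 64): 25.7% contacts, 0.0% H-bond proxies
first contacts formed: (14, 17) -> (16, 19) -> (12, 15) -> (15, 18) -> (13, 16)
top-3 principal components cover 100.0% of the variance
```

Reading the numbers: the funneled Gō landscape gives an almost barrierless
pathway (0.092 ε).  By the frame where 70 % of the total Rg reduction is
complete, only a quarter of the native contacts and none of the
hydrogen-bond-registry proxies have formed — compaction leads, secondary
structure follows (the hydrophobic-collapse picture).  The first persistent
contacts are all local helix-segment pairs in residues 11–23; hairpin
contacts among residues 1–10 form last (helix before hairpin).  The
optimized path is a smooth curve in configuration space, so very few
principal components carry its variance.

A `admd` command-line tool wraps the same steps: `admd run --config
cfg.yaml`, `admd select RUNDIR`, `admd analyze traj.pdb --native n.pdb`,
`admd pca traj.pdb --components 3`, `admd make-fixtures --out dir/`.

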