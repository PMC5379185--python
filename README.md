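# switchscape

Conformational-state analysis of GTPase switch loops.

Small GTPases (Ras, RhoA, Rac1, Cdc42, …) act as molecular switches: the
switch I loop (residues 28–40 in RhoA numbering) adopts distinct
conformations in the GDP-bound "off" and GTP-bound "on" states, and the
"on" ensemble can itself split into sub-states ("state 1"/"state 2") that
differ in effector affinity.  `switchscape` is a toolkit for
characterising such loop ensembles, written for computational structural
biologists who have conformational ensembles (from simulation or
multi-model experimental structures) and want reproducible state analysis:

* **Two-reference projections.**  Distance-matrix RMSD
  (DRMSD = √[(1/P) Σ_{i<j} (d_ij − d_ij^ref)²], superposition-free) and a
  dihedral-similarity collective variable
  S = Σ_i (1 + cos(θ_i − θ_i^ref))/2 ∈ [0, n_angles], both computed
  against an inactive *and* an active reference so degenerate
  single-reference distances cannot conflate distant states.  Crystal-
  structure sets map onto the same (S_GDP, S_GTP) plane as the ensembles.
* **Well-tempered metadynamics (desk scale).**  An overdamped Langevin
  engine biased in 1–2 CVs with tempered hills
  (height W·e^{−V(s,t)/k_BΔT}, ΔT = (γ−1)T), free-energy surfaces from
  the final bias (F = −(γ/(γ−1))V) and from time-dependent bias-offset
  reweighting, plus watershed basin/barrier analysis.  Validated on
  analytic landscapes with exact free-energy oracles; it does not run
  all-atom MD.
* **Sub-state discovery.**  Seeded k-means (k = 4 by default) on
  (sin, cos)-embedded φ/ψ/χ1 features, per-system populations,
  χ-angle histograms, and threshold-rule open/closed/intermediate
  classification of reporter side chains.
* **Hydration & energetics.**  Water counts within 4 Å of each residue
  with block-averaged standard errors, and Coulomb + Lennard-Jones
  interaction-energy decomposition of a focal loop against
  protein/water/nucleotide/ion groups (1 nm cutoff), including
  ΔE = E_active − E_inactive tables and residue-wise partitions.
* **Synthetic data with ground truth.**  Seeded generators for von Mises
  multi-state loop ensembles (rebuilt in 3-D by internal-coordinate chain
  extension), reference pairs, Poisson point solvent and charged/LJ toy
  systems — every stage of the pipeline is testable offline.

See `docs/methods.md` for the models, defaults and validation scope.

## Worked example

Generate a two-state loop ensemble, project it, cluster it, and recover a
known free-energy difference by metadynamics:

```python
import numpy as np
from switchscape import (StateSpec, gen_loop_ensemble, gen_reference_pair,
                         s_projection)
from switchscape.core import KT_300, extract_dihedrals
from switchscape.metad import (DoubleWell1D, IdentityCV, wt_metad,
                               fes_from_bias, reweight, find_basins_barriers,
                               integrated_delta_g)
from switchscape.states import build_features, kmeans

# 13-residue loop (numbered 28-40), two dihedral states 90 deg apart
spec = StateSpec.two_state(separation_deg=90.0, kappa=50.0, weights=(0.6, 0.4))
ens, labels = gen_loop_ensemble(spec, n_res=13, n_frames=500, seed=1)
refs = gen_reference_pair(spec, n_res=13)

proj = s_projection(ens, refs)   # (S_GDP, S_GTP) per frame
print("S_GDP of state-0 frames: %.2f" % proj.x[labels == 0].mean())
print("S_GDP of state-1 frames: %.2f" % proj.x[labels == 1].mean())

series = extract_dihedrals(ens, range(28, 41), ["phi", "psi"])
model = kmeans(build_features([("demo", series)]), k=2, seed=2)
print("cluster populations:", np.bincount(model.assignments) / 500)

# double well calibrated to dG = 2.0, barrier = 4.0 kcal/mol at 300 K
pot = DoubleWell1D.with_free_energy(delta_g=2.0, barrier=4.0, kT=KT_300)
traj, bias = wt_metad(pot, [IdentityCV(pot.domain)], W=0.1, widths=0.1,
                      stride_ps=0.5, bias_factor=10.0, kT=KT_300, dt=0.002,
                      n_steps=1_000_000, seed=7, x0=pot.minima()[0])
grid = [np.linspace(-2, 2, 161)]
print("dG (bias):     %.3f" % integrated_delta_g(fes_from_bias(bias, grid), KT_300))
print("dG (reweight): %.3f" % integrated_delta_g(reweight(traj, bias, grid), KT_300))
basins, barriers, _ = find_basins_barriers(fes_from_bias(bias, grid))
print("barrier A->B: %.2f kcal/mol" % barriers[0, 1])
```

Output:

```
S_GDP of state-0 frames: 23.88
S_GDP of state-1 frames: 11.98
cluster populations: [0.61 0.39]
dG (bias):     2.037
dG (reweight): 2.012
barrier A->B: 4.00 kcal/mol
```

State-0 frames score ≈ 24 (all 24 φ/ψ angles match the inactive
reference) while state-1 frames score ≈ 12, cleanly separating the
states; k-means recovers the planted 0.6/0.4 mixture; and the two
independent free-energy estimators agree with the calibrated
ΔG = 2.0 kcal/mol and barrier = 4.0 kcal/mol to within a few hundredths.

## Command line

Every stage is also a subcommand over a single YAML config
(`examples/demo.yaml`); stages communicate through files and the full run
is byte-reproducible per seed:

```sh
switchscape pipeline -c examples/demo.yaml   # simulate -> ... -> manifest
switchscape metad    -c examples/demo.yaml   # just one stage
```

`pipeline` writes a manifest (config hash, seeds, per-output SHA-256);
running it twice with the same config produces identical manifests.

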