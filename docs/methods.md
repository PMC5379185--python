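# Methods

`switchscape` analyses the conformational sub-states of small-GTPase switch
loops — the flexible segments (switch I in RhoA spans residues 28–40) whose
geometry differs between the GDP-bound "off" state and the GTP-bound "on"
state.  The package implements the full analysis chain around such an
ensemble: two-reference structural projections, a dihedral-similarity
collective variable, a well-tempered metadynamics engine with two
free-energy estimators, k-means sub-state discovery, hydration profiling
and interaction-energy decomposition.  Because solvated-protein molecular
dynamics is outside the package's scope, every stage is validated on
synthetic systems with exact ground truth; this note records the models,
the defaults, and what those validations do and do not show.

## Units and conventions

Internal units are Angstrom, kcal/mol, ps and radians (k_B = 0.0019872041
kcal mol⁻¹ K⁻¹; analyses default to 300 K, kT ≈ 0.596 kcal/mol).  File
interfaces report degrees where that is conventional (dihedral tables).
Author residue numbering from the source file is preserved end to end, so
a switch-I-like loop keeps its 28–40 labels and documented selections read
as in the structural literature.  Dihedrals follow the IUPAC sign
convention (cis = 0, trans = pi, positive for a right-handed twist);
angular differences are always minimum-image on the circle.  Ensembles are
treated as whole molecules: no periodic imaging anywhere.

## Structural projections

**DRMSD.**  The distance-matrix RMSD between a conformation and a
reference is sqrt((1/P) Σ_{i<j} [d_ij − d_ij^ref]²) over all P = N(N−1)/2
unordered pairs of the selected atoms (loop C-alphas by default; heavy
atoms behind a flag).  It is superposition-free by construction and a
pseudometric on the selection.  Because RMSD-like quantities are
degenerate far from a single reference, projections are always computed
against a *pair* of references (inactive/"GDP-bound", active/"GTP-bound"),
mapping each frame to a point in the plane.

**Dihedral similarity S.**  S scores the proximity of a frame's backbone
phi/psi angles to a reference row; it is maximal (= n_angles) iff every
angle matches.  Two forms are implemented:

* half-cosine (default): S = Σ_i (1 + cos Δθ_i)/2 — smooth, bounded, and
  broad enough to resolve basins in the (S_GDP, S_GTP) plane;
* Gaussian kernel: S = Σ_i exp(−Δθ_i²/2σ²) with configurable σ.

The half-cosine form is the default because a narrow kernel (a few
degrees) vanishes almost everywhere in angle space and cannot produce
extended basins; the kernel form is kept as a config switch for
sensitivity checks.  χ1 is defined by N–CA–CB–X with X from a built-in
per-residue-type table (Tyr and Phe use CG); χ2 is not currently a feature
option.

## Well-tempered metadynamics

The sampler is overdamped Euler–Maruyama Langevin dynamics,
x ← x − (dt/γ_f)∇U + sqrt(2 kT dt/γ_f) η, with friction γ_f = 1 ps⁻¹ and
dt = 0.002 ps by default.  Every `stride_ps` (default 2 ps) a Gaussian
hill of initial height W = 0.1 kcal/mol and per-CV width σ is deposited at
the current CV value with the well-tempered height
W·exp(−V(s,t)/k_B ΔT), ΔT = (γ−1)T.  The bias factor γ is not a quantity
the analysis can infer, so it defaults to a mid-range γ = 10 and is
configurable; γ → ∞ recovers standard metadynamics (constant heights), and
the implementation treats that limit exactly.

During propagation the bias force is interpolated from a gridded
accumulation of the hills (400 points per CV dimension by default,
linear/bilinear interpolation), which makes the per-step cost independent
of the hill count; analysis-side evaluation (`BiasPotential.potential`)
sums the Gaussians exactly.  The interpolation error is bounded by the
grid spacing relative to the hill width (0.01 vs σ = 0.1 on the default
double-well grid) and is far below the statistical error of any run the
package performs.

Two estimators produce free-energy surfaces:

* **Final bias:** F(s) = −(γ/(γ−1)) V(s, t_final) + C, with C chosen so
  the unmasked minimum is zero.  Bins farther than 3 hill widths from
  every hill center are masked as unexplored rather than extrapolated.
* **Reweighting:** frame weights w(t) ∝ exp[(V(s(t),t) − c(t))/kT], with
  the bias offset c(t) = kT ln[Σ exp(βγV/(γ−1)) / Σ exp(βV/(γ−1))]
  refreshed from the running grid estimate after every hill (c = 0 before
  the first hill).  The weighted histogram of any observable gives
  −kT log(hist), min-shifted.  Bins with zero weight — or carrying less
  than 10⁻⁸ of the maximum bin weight, where the log estimate is pure shot
  noise — are masked, not reported as zero.

**Basins and barriers.**  Local minima are found by an ascending
flood-fill (watershed) over the unmasked grid.  A minimum survives as a
basin when its topographic persistence — the level at which its catchment
first merges into a deeper one, minus its own value — reaches `min_depth`
(default 0.5 kcal/mol); the global minimum always survives, and basins in
regions not connected through explored bins to the global minimum are
discarded (their barriers are undefined).  The barrier from basin i to j
is the lowest connecting saddle level minus the value at minimum i; the
basin ΔG is the difference of minima, and `integrated_delta_g` offers the
Boltzmann-integrated alternative used for double-well comparisons.  Basin
labels run A, B, C, … in order of increasing free energy.  On nested
grids the flood-fill saddle level can only decrease with refinement, which
the tests exploit as a no-spurious-saddle check.

**Validation systems.**  The engine is exercised on landscapes with exact
oracles instead of a solvated protein:

* `DoubleWell1D` — quartic double well with a smooth-step (tanh pair)
  tilt that is flat at both minima and at the saddle, so the constructed
  potential-energy gap and barrier land on the requested values;
  `DoubleWell1D.with_free_energy` further calibrates the tilt by solving
  for an exact quadrature *free-energy* difference at the stated kT.  In
  1-D overdamped dynamics the FES equals the potential, so the quadrature
  oracle is exact and independent of any sampling.
* `MuellerLike2D` — the standard three-basin bent-channel surface, scaled
  to kcal/mol magnitudes.
* `DihedralChain` — independent per-angle double wells on the torus with
  minima at two prescribed angle states, letting the S CV itself be the
  biased variable end to end: biasing (S_ref0, S_ref1) drives transitions
  that the unbiased control cannot make.

The standard desk-scale run (1e6 steps, hills every 0.5 ps, γ = 10,
σ = 0.1 CV units) recovers the calibrated ΔG = 2.0 kcal/mol within
~0.1 kcal/mol by both estimators and the 4.0 kcal/mol barrier within
~0.1–0.2 kcal/mol; the dual-estimator gap is the run's internal
consistency check, and convergence is declared when the basin ΔG estimate
changes by less than ~0.05 kcal/mol over the last 20% of hills
(`delta_g_convergence`).

## Sub-state discovery

Dihedral features (phi/psi of the loop residues, plus χ1 of reporter
residues when present) are embedded as (sin θ, cos θ) pairs before
clustering, so Euclidean distance is the chord length 2|sin(Δθ/2)| and the
±180° seam disappears; a raw-angle mode exists for fidelity comparisons
with pipelines that clustered bare dihedrals.  k-means uses k-means++
initialisation and Lloyd iterations (tolerance 1e-6, up to 500
iterations, best of 10 restarts), fully seeded; k defaults to 4, matching
the four-cluster protocol conventional for switch-loop sub-states, and a
silhouette diagnostic is reported but never used to auto-select k.
Populations and assignment accuracies are only ever computed after optimal
(Hungarian) label matching, since k-means labels carry no meaning.

Side-chain signature classification (open/closed/intermediate) uses
threshold bands over one observable — a minimum side-chain-to-partner
distance or a χ1 angle.  Bands are [lower, upper): a frame exactly at a
threshold belongs to the band above it.  Defaults: closed below 3.5 Å
(hydrogen-bond range), open above 5.5 Å, intermediate between; rule gaps
are rejected when the signature is constructed, not at classification
time.

## Hydration and energetics

Hydration numbers count water molecules with their **oxygen** within the
cutoff (default 4 Å) of any heavy atom of the residue; any-atom criteria
are configurable but oxygen-only is the standard convention.  Standard
errors use block averaging (default block length 100 frames, configurable)
so positively correlated frames do not understate the uncertainty; for
i.i.d. data the block SE converges to the naive SE, and for AR(1)-type
correlation it exceeds it, both of which are tested.  The polar/nonpolar
split assigns Ala/Val/Leu/Ile/Phe/Pro/Met/Gly/Trp to the nonpolar class
and everything else to polar.

Interaction energies are plain cutoff sums (default 10 Å = 1 nm, no Ewald,
no imaging) over focal×partner atom pairs of

* Coulomb: k_e q_i q_j / r, k_e = 332.0636 kcal·Å·mol⁻¹·e⁻²;
* Lennard-Jones in Rmin form: ε_ij[(Rmin_ij/r)¹² − 2(Rmin_ij/r)⁶] with
  geometric-mean ε and additive Rmin/2 — the CHARMM-family convention the
  sidecar parameter table is written in.

ΔE tables report ⟨E⟩_active − ⟨E⟩_inactive per partner group
(protein/water/nucleotide/ion) with block-averaged SEs; a group absent
from one system is reported as missing, never as zero.  The residue-wise
decomposition excludes the whole loop from every partner set so the
per-residue values partition the loop total exactly.  These are mean
interaction-energy differences, not free energies: no entropic correction
is attempted.

## Synthetic data: what it emulates and what it does not

Generators are seed-deterministic and emit their ground truth alongside
the data.  The default loop is 13 residues numbered 28–40, mirroring a
switch-I-sized segment.  Backbone coordinates come from
internal-coordinate chain extension (NeRF) with ideal geometry (N–CA
1.458 Å, CA–C 1.525 Å, C–N 1.329 Å; ω fixed trans), and dihedral noise is
von Mises — chosen over the wrapped normal because its closed-form density
makes the distributional tests exact.  Default study conditions follow the
scenarios the analyses are specified against: two states 90° apart in
phi/psi at κ = 50 for projection and classification tests; four states
≥60° apart at κ = 50 with weights 0.4/0.3/0.2/0.1 and n = 4000 for the
clustering recovery surface; reporter distances 3.0 ± 0.3 Å (closed-like)
vs 6.5 ± 0.5 Å (open-like).  The point solvent is a homogeneous Poisson
field of oxygen-only sites; the demo density 0.0334 Å⁻³ is bulk water's
number density.  The energetics toy realises the "see-saw" sign pattern —
solvation loss in the active-like state overcompensated by a larger
nucleotide gain — verified against the energy module at generation time.

These synthetics establish that the machinery is correct: estimators hit
analytic values, clustering recovers planted mixtures, counts match
Poisson expectations.  They do not establish anything about real switch
loops: there is no excluded volume, no side-chain packing, no correlated
solvent structure, no force-field realism, and the loop geometry shares
only residue count and state topology with a real protein.  Passing tests
mean the method is implemented correctly, not that a given biological
conclusion would be recovered.

## Pipeline reproducibility

The CLI chains the stages through files only; every stochastic stage
derives its seed from the single config seed, floats are written with
fixed formats, and the manifest (config hash, package version, seeds,
per-output SHA-256) contains no timestamps — two runs of the same config
are byte-identical, which the test suite asserts.  Unknown config keys are
rejected with the offending key named (exit 2); stage failures exit 1 with
the stage name.

## Known limitations

* The metadynamics engine supports at most two CVs and is a toy-system
  engine by design; it does not bias all-atom systems.
* Hill evaluation during propagation is grid-interpolated; pathological
  hill widths far below the grid spacing would degrade the bias force
  (the defaults keep 10 grid points per width).
* `read_structure` handles multi-MODEL PDB and whitespace coordinate
  tables; binary trajectory formats are out of scope (ecosystem readers
  can be wrapped externally).
* Block-averaged SEs assume the block length exceeds the correlation
  time; the default (100 frames) is a convention, not an estimate, and
  should be checked against the data's autocorrelation when it matters.
* The χ1 atom table covers the 20 standard residues; nonstandard residues
  fall back to CG and may need explicit configuration.
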