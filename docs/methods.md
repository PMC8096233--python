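# Methods

## Site-exposure proteolysis kinetics

**Model.** Trypsin attack on the disordered H3 tail is treated as a probe
of a rapid conformational pre-equilibrium between DNA-occluded and exposed
tail states. In that limit the observed digestion of full-length H3 is
first order, `f(t) = A0·exp(−k_obs·t)`, with `k_obs` first order in enzyme
concentration and proportional to the site-exposure equilibrium constant.
Ratios of fitted `k_obs` between particle species are therefore relative
accessibility constants; the validity conditions (rapid pre-equilibrium,
[exposed tails] ≪ K_m, steady state, digestion reporting on the native
conformation) are assumptions of the analysis, not results of it.

**Normalization.** The fraction of full-length H3 is the ratio of a digest
lane's band volume to the pre-digest lane of the same replicate. Tables
written by the generator carry an explicit `lane = "reference"` row per
replicate; for plain gel tables the t = 0 lane is the reference, making the
t = 0 fraction 1 by construction. Replicate means and sample SDs are taken
per timepoint.

**Fit.** Weighted least squares on the replicate-averaged course,
minimizing `Σ_t [(mean_t − A0·e^{−k·t})/σ_t]²` with box constraints
`k ≥ 0`, `0 < A0 ≤ 1` and no constant offset (the curve decays to zero).
The intercept below one absorbs particles that dissociate during initial
mixing. Weights are `1/σ_t²`; zero or missing SDs are floored at the median
nonzero SD of the series so no point carries infinite weight. Parameter
errors are square roots of the covariance diagonal with the covariance
rescaled by reduced χ², which makes the fit and its errors invariant to a
uniform rescaling of all σ_t. Fits that land on the `A0 = 1` bound, or
whose decay over the sampled window is unmeasurable (`k·t_max < 10⁻³`,
reported as the k = 0 boundary), are flagged rather than rejected.

**Ratio error.** The rate-ratio uncertainty uses standard first-order
propagation, `σ_r = r·√((σ_k1/k1)² + (σ_k2/k2)²)`. For the rate pair
0.19 ± 0.02 and 0.012 ± 0.002 min⁻¹ this gives roughly ±3 on a ratio of
~15.8; published values quoting a much smaller uncertainty for the same
pair cannot be reproduced by this (or any standard) propagation rule, so
the package reports the propagated value and leaves the discrepancy to the
reader.

**Mixture test.** The hexasome prediction is `Σ w_j·A0_j·e^{−k_j t}` with
weights summing to one (half/half for one nucleosome-like and one
tetrasome-like tail). Observed per-timepoint means are compared with the
predicted values by Welch's two-sample t-test — the named variant is a
package choice; the comparison is deliberately coarse (whole-curve offset,
not pointwise lack of fit).

**Endpoints.** Fixed-time digestion endpoints across species × trypsin
level are analyzed by two-way fixed-effects ANOVA (type II, via
statsmodels) followed by Tukey HSD among species within each trypsin
level, α = 0.05. Cells with fewer than two replicates or empty cells are
rejected.

## NMR peak-table analysis

Combined amide shift differences use `Δδ = √(ΔδH² + (0.154·ΔδN)²)`; the
0.154 nitrogen weight is fixed (an override is possible but warned about).
Matching is by residue number; unmatched residues are reported, never
silently dropped, and overlap-flagged residues are excluded from summary
means.

Hexasome peaks are classified hex-N/hex-T by Δδ proximity to the
nucleosome and tetrasome reference positions. For doubled residues the
joint assignment minimizing the total Δδ of the two pairings is used, so
each label occurs at most once per residue; near-ties
(|Δδ_N − Δδ_T| < 0.005 ppm) go to hex-N and carry an `ambiguous` flag,
preserving the honest uncertainty of assignments that cannot be made
definitively.

Relaxation times come from per-residue fits of `H(d) = H0·e^{−d/T}`
without offset; duplicate delays are independent observations; T errors
are covariance-based, rates `R = 1/T` and T₁/T₂ ratios use first-order
propagation. hetNOE is the saturated/reference height ratio with error
`|NOE|·√((σ_sat/H_sat)² + (σ_ref/H_ref)²)` from user-supplied per-spectrum
noise estimates (raw spectra, and hence noise floors, are out of scope).
The default delay schedules mirror common interleaved T₁
(10…2000 ms, ×2) and CPMG T₂ (16.96…203.52 ms, ×2) loop lengths.

## Trajectory metrics

Trajectories are plain `(frames, atoms, 3)` arrays in Å with a topology
table (chain, residue, atom, heavy flag, role). H3 residues 1–37 are the
tail, 38–55 the initial core region. The default equilibration trim drops
the first 40% of frames (the 100 ns/250 ns convention).

* **Superposition** is Kabsch (SVD with the determinant correction, so
  improper rotations are never applied); the reference is the mean
  structure obtained by aligning to the first frame and refining once.
* **RMSF** is `√⟨|x − ⟨x⟩|²⟩` per atom after superposition; replicate
  profiles are summarized as mean ± SEM.
* **RAC(τ)** averages, over all `N − τ + 1` window starts, the RMSD of the
  τ-frame running-average coordinates against the whole-trajectory
  average; no refit is applied to the window averages (the trajectory is
  already superposed). RAC(1) equals the mean per-frame RMSD to the
  average structure and RAC(N) is identically zero.
* **SASA** is Shrake–Rupley with a 1.4 Å probe and a golden-spiral point
  lattice (default 960 points, within 1% of the closed form for a single
  sphere); pseudo-atoms must carry explicit radii, standard elements use a
  built-in vdW table.
* **Contacts** are heavy-atom pairs within 4.5 Å (inclusive), counted per
  frame by KD-tree query, grouped by (tail residue, DNA bp) and reported
  as per-frame means. A tail's "total contacts" is the sum of those means
  rounded to an integer — an aggregation convention of this package, since
  per-frame-sum versus union conventions differ between published tables.
* **SHL** of a 1-based bp is `(bp − dyad)/10` rounded half-up to the
  nearest 0.5 and clamped to [−7, 7]; the dyad (bp 74 of 147 by default)
  is SHL 0.
* **KLD** between dihedral ensembles is computed on 60-bin histograms over
  [−180°, 180°) with a 0.5 pseudo-count per bin, direction
  KLD(system ‖ reference); a Jensen–Shannon variant is provided.
  Significance uses permutation of replicate-run labels (≥1000
  permutations, seeded). For coarse bead chains, dihedrals are
  pseudo-torsions over four consecutive beads; for all-atom input, pass
  backbone φ/ψ atoms.
* **PCA** eigendecomposes the pooled 3n×3n covariance of tail-Cα
  coordinates after tail-only superposition. PC1's sign is fixed so the
  most extended pooled conformation (largest end-to-end distance) projects
  negative, making "more negative PC1 = more extended" a stable reading
  across runs.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *statistical structure* the analyses assume,
with planted parameters:

* **Gels** — band volumes are `scale·(Σ w_j A0_j e^{−k_j t} + ε)`,
  `ε ~ N(0, σ)` clamped at zero (densitometry is non-negative), plus an
  exact pre-digest reference lane per replicate. Defaults are the
  reference-condition truths: nucleosome (0.012 min⁻¹, 0.87), tetrasome
  (0.19 min⁻¹, 1.0), hexasome the half/half mixture, timepoints
  0, 2, 5, 10, 15, 20, 30, 50 min, triplicates. The densitometry noise
  magnitude is not a published quantity; σ = 0.02 (fraction units) is the
  package default, chosen to give replicate scatter comparable to typical
  gel error bars, and is a tunable.
* **Peak lists** — nucleosome positions drawn once in the disordered-amide
  region (7.8–8.7 / 108–126 ppm), tetrasome offsets Gaussian per residue
  (σ_H = 0.06, σ_N = 0.40 ppm, floored at 0.02 ppm combined separation so
  classification is well-posed), hexasome carrying hex-N and hex-T peaks
  at the parent positions with optional positional noise, and hex-T
  heights a planted fold (default 2.4) of hex-N heights before
  multiplicative height noise (default 5%).
* **Relaxation** — exact exponentials plus additive height noise.
* **Toy particle** — DNA base-pair centers on an ideal left-handed
  superhelix (radius 41.9 Å, pitch 25.9 Å, 1.84 turns over 147 bp —
  literature-typical geometry used as a generator convention, not a claim
  about any specific structure), three heavy pseudo-atoms per bp (two
  backbone beads at ±3 Å on strands I/J, one base bead), unwrapped bp
  continued on straight tangent lines with arc length preserved. Tail
  beads follow independent per-coordinate AR(1)
  (discretized Ornstein–Uhlenbeck) processes about anchor points, so the
  stationary per-axis SD is exactly σ and RMSF, RAC and autocorrelation
  have closed-form expectations. The hexasome preset unwraps the low-bp
  side (the convention here: the retained dimer sits on the high-bp,
  TA-rich-analog side) and gives the adjacent tail the larger σ.

What the toy particle does *not* model: base identity or sequence, force
fields, solvent, realistic DNA groove geometry, or any energetics. Tests
passing on it demonstrate that the pipeline recovers planted geometry and
statistics — they say nothing about the magnitudes of RMSF, contacts or
SASA in microsecond all-atom simulations, which are outside desk scale and
deliberately not reproduced.

## Problem sizes and numerical choices

Seed-median recovery checks use 50 seed pairs of triplicate courses
(seconds of runtime); relaxation recovery uses 100 noisy repeats; KLD
closed-form comparison uses 10⁵ samples; AR(1) RMSF/SD recovery uses 5000
frames; contact-oracle equivalence uses ≤600-atom systems. Demo trajectory
runs default to 150 frames of the toy particle. All generators and
analyses that involve randomness take explicit seeds; the pipeline derives
per-stage substreams from one root seed via CRC-mixed `SeedSequence`, so
every reported number is reproducible bit-for-bit from (config, seed).

Degenerate inputs are handled explicitly rather than silently: flat decay
courses report the k = 0 boundary with a warning; zero reference bands,
empty selections, collinear superposition selections, residues with more
than two hexasome peaks, and weights not summing to one are errors; fits
at the A0 bound are flagged. Tukey comparisons in a trypsin level with
zero within-cell variance return "no pair differs" rather than NaNs.

## Known limitations

* The two-sample mixture comparison tests only for a whole-curve offset;
  it will not detect compensating shape differences.
* The intensity-asymmetry mean is a mean of per-residue ratios; with
  multiplicative height noise this estimator carries a small (≪1%)
  positive bias, negligible at the default 5% noise.
* Contact totals depend on the stated aggregation convention; comparisons
  with other software should normalize conventions first.
* The NMR-STAR reader extracts only the assigned-chemical-shift loop; it
  is not a general STAR schema implementation.
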