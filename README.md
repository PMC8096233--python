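# subnuc

Quantitative analysis of histone **H3 tail conformation, dynamics and
accessibility** in the nucleosome and its subnucleosomal species, the
**hexasome** (one H2A/H2B dimer lost, ~30–40 bp of DNA unwrapped on the
dimer-free side) and the **tetrasome** (both dimers lost, ~66 bp wrapped).
The package is aimed at chromatin biophysicists who combine limited
proteolysis, solution NMR of the disordered H3 tail (residues 1–37), and
coarse or all-atom trajectory analysis, and who want every stage of that
pipeline reproducible from tables rather than from raw gels or spectra.

Three analysis streams share one library:

1. **Proteolysis kinetics (`subnuc.proteolysis`).** Under a rapid
   pre-equilibrium between DNA-occluded and exposed tail states, the
   fraction of full-length H3 remaining decays as
   `f(t) = A0·exp(−k_obs·t)`, and `k_obs` is proportional to the
   site-exposure equilibrium constant. The module normalizes gel band
   volumes, performs the weighted fit constrained to decay to zero with
   intercept `A0 ≤ 1` (the intercept absorbs particles dissociated on
   mixing), forms rate ratios `k_tet/k_nuc` with first-order error
   propagation, predicts the hexasome course as the half-weighted sum of
   the nucleosome and tetrasome decays, and compares digestion endpoints by
   two-way ANOVA with Tukey post-hoc tests.
2. **NMR peak-table analysis (`subnuc.nmr`).** Combined amide shift
   differences `Δδ = √(ΔδH² + (0.154·ΔδN)²)`, classification of the
   hexasome's doubled peaks into nucleosome-like (**hex-N**) and
   tetrasome-like (**hex-T**) subsets by shift overlap, hex-T/hex-N peak
   height (intensity) ratios, and ¹⁵N relaxation: single-exponential
   `H(d) = H0·exp(−d/T)` fits without offset for T₁/T₂, hetNOE from
   saturated/reference height pairs, all with propagated errors. A
   read-only NMR-STAR chemical-shift reader (`subnuc.bmrb`) ingests
   deposited shift lists.
3. **Trajectory metrics (`subnuc.traj`).** Kabsch superposition, per-residue
   RMSF with across-replicate SEM, the RMS-average-correlation (RAC)
   convergence diagnostic, radius of gyration, Shrake–Rupley SASA,
   heavy-atom tail–DNA contacts (4.5 Å cutoff) binned by superhelical
   location (SHL −7…+7, dyad at SHL 0), inter-residue distance maps,
   histogram Kullback–Leibler divergence between dihedral ensembles with a
   permutation test, and PCA of tail-Cα coordinates.

A synthetic-data package (`subnuc.simulate`) generates all three streams
with planted, recoverable parameters — exponential gel decays with
densitometry noise, paired peak lists with controlled offsets and intensity
asymmetry, relaxation decays, and a coarse superhelical toy particle
(147 pseudo-bp, two 37-bead H3 tails with AR(1) dynamics, tunable DNA
unwrapping) — so the full pipeline is testable without external data.

## Worked example

Run the bundled demonstration (simulate → analyze → report):

```bash
subnuc demo --seed 1 --mode proteolysis --out demo_out
cat demo_out/kinetics.json
```

```json
{
  "fits": {
    "nucleosome": {"k_obs_per_min": 0.01161, "k_err": 0.00029,
                   "intercept": 0.8736, "intercept_err": 0.0033},
    "tetrasome":  {"k_obs_per_min": 0.19618, "k_err": 0.00293,
                   "intercept": 1.0000, "at_bound": true}
  },
  "site_exposure_ratio": {"tetrasome_over_nucleosome": 16.90, "error": 0.49},
  "hexasome_vs_half_mixture": {"p_value": 0.986}
}
```

Reading this: triplicate digestion courses were simulated at
t = 0…50 min from nucleosome-state truth (k = 0.012 min⁻¹, A0 = 0.87) and
tetrasome-state truth (k = 0.19 min⁻¹, A0 = 1.0) with 2% densitometry
noise, then refit. The fitted rates recover the truth; their ratio (~16)
is the relative site-exposure equilibrium constant — the tetrasomal H3
tail is an order of magnitude more accessible than the nucleosomal tail.
The tetrasome intercept sits on the `A0 ≤ 1` bound and is flagged. The
simulated hexasome course is statistically indistinguishable (p = 0.986)
from the half-weighted sum of the two component decays, the signature of
one nucleosome-like plus one tetrasome-like tail.

The same CLI exposes the individual stages (`subnuc simulate`,
`subnuc proteolysis --gel …`, `subnuc nmr --mode csd|classify|…`,
`subnuc traj --pdb … --metric rmsf|rac|contacts|shl|…`); exit codes are
0 (success), 2 (config error), 3 (input error), 4 (fit error).

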