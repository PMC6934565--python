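# Methods

This note documents the models, parameter choices and numerical decisions
behind `ubidyn`, and what the synthetic-data tests do and do not
demonstrate about measured data.

## Observable models

**Chemical-shift perturbation.** Two assigned ¹H–¹⁵N peak lists are
compared on their residue intersection only; the combined perturbation is
Δω = √((Δ¹H² + (Δ¹⁵N/5)²)/2) in ppm. The 1/5 nitrogen weighting reflects
the ~5-fold wider ¹⁵N shift dispersion, and makes Δω symmetric in the two
nuclei after scaling. Mean and SD thresholds are computed per dataset over
observed residues only — prolines (positions 19, 37, 38 of ubiquitin) and
exchange-broadened peaks simply do not enter. All observed residues are
included in the statistics, including those at a mutation/conjugation site;
we found no principled reason to exclude them and excluding them would make
the thresholds depend on an annotation the data do not carry. Peaks present
in only one state are reported in separate appeared/vanished lists, never
converted to a Δω value. The intensity-attenuation flag defaults to 75%
signal loss and is configurable.

**Amide-proton exchange.** The build-up of solvent-exchanged amide signal
relative to a reference spectrum is
S(t) = k_HX/(R₁+R₁w) · (e^(−R₁w t) − e^(−(R₁+k_HX) t)), with S(0) = 0 for
all parameters. R₁w (water-proton longitudinal rate) is a measured
constant, 0.31 s⁻¹ by default, and is held fixed during fitting; jointly
fitting it is available but off by default because the experiment
determines it independently and the joint problem is poorly conditioned at
typical sampling (10–250 ms). Fits are Levenberg-style weighted least
squares with inverse-variance weights when point errors exist; k_HX starts
from the initial slope of the curve and R₁ from 1 s⁻¹ (deterministic
starts, no random restarts). Non-convergence and an all-zero signal yield
flagged results rather than exceptions; a fit driven to the k_HX ≥ 0 bound
is clipped and flagged.

**Spin relaxation.** T₁/T₂ decays are I(t) = I₀ e^(−t/T), initialized from
log-linear regression (which is exact on noiseless data, and the unit
tests hold the nonlinear fit to that oracle at 1e-9). When a decay table
carries replicate delay points, the mean standard deviation over replicate
groups supplies a uniform intensity error — the replicate-based error rule
— otherwise explicit per-point errors or unweighted fitting apply. A
fitted T beyond 100× the longest delay is flagged non-decaying rather than
reported as a number. The hetNOE is the per-residue ratio of saturated to
unsaturated peak intensity; with replicate pairs its error is the mean
over residues of the replicate SD, without replicates the error is 0 and
the series is marked "no replicate error available".

**R₂/R₁ mobility classification.** The ratio estimates the rotational
correlation time; residues deviating more than one SD from a robust
average carry additional internal motion (below) or exchange contributions
(above). "10% trimmed mean" removes ⌊0.1·n⌋ values from *each* tail — the
standard definition of the symmetric trimmed estimator; the fraction is
configurable so the 10%-total reading is one flag away. The ±1 SD band
uses the SD of the same trimmed subset by default (`use_trimmed_sd=False`
switches to the untrimmed SD); the trimmed choice keeps a single extreme
outlier from inflating the band it should be flagged by. Exchange suspects
are residues that are both ratio outliers and R₂ outliers (trimmed
mean + SD on R₂), the signature distinguishing µs–ms exchange from slow
tumbling.

**Diffusion.** Stejskal–Tanner echo decay
I(G) = I₀ e^(−G²γ²δ²D(Δ−δ/3)). The fit is a weighted linear regression of
ln I on the diffusion weighting b(G) — exact for this model and free of
initialization choices — with an optional nonlinear refinement. Repeated
gradient strengths provide scatter-derived weights (the acquisition
convention repeats ~4 gradient values for error estimation); otherwise
errors come from the regression covariance. γ defaults to the ¹H value,
2.675×10⁸ rad s⁻¹ T⁻¹. Gradient calibration is out of scope: G values are
taken as given in T/m. Synthetic tests use a 21-point ramp over
0.005–0.5 T/m with δ = 6 ms and Δ = 100 ms, a typical bipolar-gradient
stimulated-echo setup; absolute gradient values only rescale D through
G²D and do not affect round-trip identities.

**Binding.** Fast exchange is assumed throughout (peak positions move,
lineshape analysis is out of scope). The quadratic single-site isotherm is
the exact solution of the 1:n equilibrium in total concentrations; it is
zero at [L]ₜ = 0, monotone, bounded by Δω_max, and invariant under joint
rescaling of K_D and the concentrations. Stoichiometry n is fixed to 1 by
default and fitting it is opt-in. Per-point [P]ₜ/[L]ₜ come from series
metadata (dilution bookkeeping is the data producer's responsibility,
since experiments report start concentrations and molar ratios, not
aliquot volumes). Per-residue mode fits (K_D, Δω_max) per titration
profile and summarizes by the inverse-variance-weighted mean (plain mean
with SD spread when errors are degenerate, e.g. noiseless data); global
mode fits one shared K_D with per-residue Δω_max jointly. Residues with a
maximal observed shift change below 0.01 ppm (configurable) or attenuated
beyond threshold are excluded. K_D identifiability is checked through the
Jacobian sensitivity, not only the covariance: a saturating design yields
a "poorly determined" flag even when residuals vanish.

## Ensemble operators

**SASA.** Shrake–Rupley with a golden-spiral point set (960 points per
atom by default; doubling changes the packaged fixture's total by
< 0.5%), probe radius 1.4 Å (0.14 nm), and a fixed van der Waals table
(C 1.70, N 1.55, O 1.52, S 1.80, H 1.20, P 1.80 Å; toy beads 2.30 Å). The
radius set is a documented package choice — structure files do not carry
radii and common SASA tools differ in their defaults; the implementation
is cross-checked against biotite's independent Shrake–Rupley to 1% on the
packaged fixture. ΔSASA is frame-averaged monomer minus chain-in-dimer,
so burial by the partner domain is positive.

**RMSF.** Windows are counted in frames; the trajectory timestep is
metadata, so "a 10 ns window" maps to whatever frame stride produced the
ensemble. Within each window frames are Kabsch-aligned to the
window-average structure, iterated three times to self-consistency; atoms
aggregate to residues as the RMS over atoms and windows average
arithmetically. A trailing window shorter than half the nominal length is
dropped. Note a finite-size property the statistical test accounts for:
rigid-body superposition absorbs 6 of the 3N noise degrees of freedom, so
pure isotropic jitter of width σ converges to σ√3·√(1−2/N) per atom, not
σ√3.

**Clustering.** Pairwise backbone RMSD (Kabsch superposition per pair,
default selection: backbone atoms of core residues 1–72 per chain,
excluding the flexible C-terminal tails), Ward agglomeration on the
condensed RMSD matrix, cut at k = 12 clusters by default. Feeding Ward the
RMSD matrix directly (rather than squared or re-embedded distances) is the
documented default. Centroids minimize summed within-cluster RMSD;
populations allow the "top three clusters" fraction to be read off.
Stride is exposed, not hard-coded.

**Collective variables and landscapes.** One minimum Cα–Cα inter-domain
distance per core residue of each chain (144 components for two
72-residue cores); all-atom minimum distances are a config option. The 2D
reduction defaults to a principal-component projection of the CV matrix;
the interface accepts any precomputed frames×2 embedding, because
published landscape constructions use bespoke reductions and PCA is a
substitute, not a claim of equivalence. The landscape is
F = −ln(ρ/ρ_max) in k_BT (300 K default) on a 50×50 grid; empty bins are
NaN (undefined), not infinite, and basin minima are local minima of the
binned surface. A two-state sample reproduces ΔF = ln(p₁/p₂) within
binning error.

## Synthetic data: what it emulates and what it does not

The generators produce (i) peak lists with localized perturbation
clusters and per-residue attenuation on a deterministic reference
dispersion covering all 72 observable ubiquitin amides; (ii) decay curves
that are exact forward evaluations of the four observable models plus
additive homoscedastic Gaussian noise — the simplest model consistent
with the weighted-fit machinery; (iii) titration series whose per-point
displacements follow the isotherm exactly along fixed per-residue
directions; and (iv) two-domain bead ensembles: compact lattice clusters
of 2.3 Å beads with substates placed at distinct approach directions and
rotations, recorded ground-truth labels, and interface contacts defined by
the SASA occlusion distance (r_i + r_j + 2·probe). A synthetic 76-residue
spherical-spiral backbone (`tests/data/synthetic_ub_like.pdb`, also
generated by `ubidyn.synth.ubiquitin_like_ensemble`) stands in for a real
fold in surface-area and gyration tests.

None of these reproduce spectrometer artifacts (phase, baseline, peak
overlap), chemical-shift referencing errors, force-field physics, or real
conformational ensembles. Passing tests therefore demonstrate estimator
correctness — that each fit inverts its own forward model, agrees with
independent oracles, and recovers ground truth under controlled noise —
not instrument- or force-field-level realism. Quantities that require
large-scale simulated ensembles (absolute radii of gyration, cluster
population statements for real dimers) are deliberately not asserted
anywhere.

## Problem sizes

Test and validation runs use desk-scale instances chosen to exercise every
code path: 20–60-bead domains with 2 substates and ≤ 400 frames, 5-point
titrations over 4–8 reporter residues, 100–200 seeded noise replicates for
bias checks, and 960-point SASA spheres. These sizes are the package's
validation defaults; all operators accept arbitrarily larger inputs.

## Known limitations

- The CSP module does not transfer assignments between strongly shifted
  spectra; inputs must be assigned peak lists.
- No model-free (Lipari–Szabo) analysis or diffusion-tensor estimation:
  R₂/R₁ is used only as an empirical classifier.
- Binding is single-site fast exchange; intermediate exchange and
  cooperative models are out of scope.
- Ensembles travel as multi-model PDB only; converting MD engine formats
  is upstream of this package.
- The landscape embedding is pluggable precisely because no single 2D
  reduction is canonical; PCA results should not be over-interpreted
  metrically.
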