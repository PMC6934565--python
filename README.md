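# ubidyn

Residue-resolved analysis of covalently linked ubiquitin dimers (Ub₂):
per-residue solution-NMR observable fitting combined with
structure-ensemble operators, for mapping how the position of the
inter-unit linkage (Lys11, Lys27, Lys48, Lys63, …) controls the
domain–domain conformation and dynamics of a two-domain protein.

It is written for structural biologists and biophysicists who have
per-residue NMR data on one unit of a dimer (typically the isotopically
labeled proximal moiety) and coordinate ensembles of the full dimer, and
who want a tested, scriptable pipeline instead of ad-hoc spreadsheets.

## What it computes

**NMR observables** (one value ± error per backbone amide):

- Chemical-shift perturbations between two states,
  Δω = √((Δ¹H² + Δ¹⁵N²/25)/2), with significance calls at the mean and the
  mean + 1 SD of the observed perturbations and flagging of peaks
  attenuated by more than 75%.
- Amide-proton exchange rate constants k_HX from the double-exponential
  build-up S(t) = k_HX/(R₁+R₁w)·(e^(−R₁w t) − e^(−(R₁+k_HX)t)), with the
  water-proton rate R₁w held at its separately measured value
  (0.31 s⁻¹ by default), and Δk_HX differences between species.
- ¹⁵N T₁/T₂ relaxation times from single-exponential decays
  I(t) = I₀ e^(−t/T), the steady-state heteronuclear NOE as the
  saturated/unsaturated intensity ratio, and an empirical mobility
  classification from R₂/R₁ ratios against their 10% trimmed mean ± 1 SD.
- Translational diffusion coefficients from Stejskal–Tanner
  pulsed-field-gradient decays
  I(G) = I₀ e^(−G²γ²δ²D(Δ−δ/3)), fitted by exact log-linear regression.
- Dissociation constants from fast-exchange ligand titrations via the
  quadratic single-site isotherm
  Δω_obs = Δω_max · (n[P]ₜ+[L]ₜ+K_D − √((n[P]ₜ+[L]ₜ+K_D)² − 4n[P]ₜ[L]ₜ)) / (2n[P]ₜ),
  per residue or as a joint global fit.

**Ensemble operators** (on multi-model PDB coordinate sets):

Shrake–Rupley SASA (1.4 Å probe) and residue-wise ΔSASA of a dimer chain
versus the free monomer; windowed backbone RMSF; mass-weighted radius of
gyration; pairwise backbone-RMSD matrices with Ward clustering, cluster
populations and centroids; inter-domain minimum-distance collective
variables (144 components for two 72-residue cores); 2D embeddings and
free-energy landscapes F = −ln(ρ/ρ_max) in k_BT.

**Integration**: Pearson correlation between CSP and ΔSASA profiles and a
consensus interface (residues flagged by ≥ 2 modalities), plus a manifest
driven pipeline writing TSV reports.

A synthetic-data module generates every input the pipeline consumes —
perturbed peak lists, model-shaped decay curves with controllable noise,
titration series, and toy two-domain bead ensembles with known substates
and interface contacts — so the whole chain is testable offline.

## Worked example

```python
import numpy as np
import ubidyn as u
from ubidyn.synth import TitrationScheme, gen_titration

# A noiseless UBA2-binding titration of a Lys11-linked dimer:
# [P]t = 130 uM, ligand ratios 0/0.3/0.9/1.7/3.1, K_D = 90 uM,
# saturation shift change 0.2 ppm on hydrophobic-patch residues.
ref = u.reference_peaklist()
dmax = u.ResidueSeries({k: (0.2, 0.0) for k in ref if k.index in (8, 44, 70)},
                       unit="ppm")
scheme = TitrationScheme.from_ratios(130.0, [0, 0.3, 0.9, 1.7, 3.1])
series = gen_titration(scheme, k_d=90.0, n=1.0, dmax=dmax, seed=1)

fit = u.fit_kd(series, mode="per-residue", n_fixed=1.0)
print(f"K_D = {fit.k_d:.1f} uM from {len(fit.residues_used)} residues")
```

prints

```
K_D = 90.0 uM from 3 residues
```

i.e. the per-residue isotherm regression recovers the dissociation
constant that generated the series; on measured peak lists the same call
reports the averaged affinity and flags residues whose fits are attenuated
or unidentifiable.

The same workflow is available from the shell:

```sh
ubidyn gen titration --kd 90 --p-total 130 --ratios 0,0.3,0.9,1.7,3.1 --outdir tit/
ubidyn titrate tit/manifest.json          # -> K_D = 90.0 +- 0.0 uM (per-residue, n = 1.0)
ubidyn gen toy-ensemble --out toy.pdb
ubidyn cluster toy.pdb -k 2
```

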