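# methylrap

Tools for quantifying methyl-group dynamics and proton dilution in
perdeuterated proteins studied by proton-detected magic-angle-spinning
(MAS) solid-state NMR.

Sparse protonation makes ¹H detection possible in the solid state. Two
labelling strategies are compared throughout this package:

* **5% GlcRAP** (reduced adjoining protonation): expression in D₂O with a
  small fraction of protonated glucose leaves every non-exchangeable site
  randomly ¹H with low probability (~3.5% at methyl positions);
* **Leu/Val ¹³CHD₂** precursor labelling: an α-ketoisovalerate precursor
  places a single ¹³CHD₂ isotopomer on one of the two prochiral methyls of
  each Leu and Val (site probability ⅙ ≈ 16.7%).

The package implements, as a tested library plus a thin CLI:

1. **Two-spin REDOR simulation** — rotational-echo double-resonance
   dephasing ℑ(t) = (S₀ − S)/S₀ of an isolated ¹H,¹³C pair under MAS, with
   finite, ζ-shifted π pulses and powder averaging, including the ideal
   (δ-pulse) limit and fast (|δ_aniso|, η) grid generation.
2. **Dipolar tensor fitting** — the traceless tensor
   D = δ_aniso·diag(1−η, 1+η, −2) is fitted to experimental peak-volume
   tables by χ² grid search (joint fits for methyl pairs), with parametric
   Monte-Carlo uncertainties. The rigid limit
   δ_aniso = −S·μ₀ħ/(8π²)·γ_H γ_C/r³ at the effective methyl C–H bond
   length r = 1.115 Å (−21794 Hz) converts fitted couplings into order
   parameters via S_met² = S_f²·S_axis², with S_f² = {P₂(cos θ)}² = 1/9 for
   ideal tetrahedral geometry.
3. **Stochastic isotopomer labelling** — replica ensembles of ¹H/²H
   assignments on explicit-hydrogen structures for the schemes above,
   theoretical masses with carbon-source impurities (3% residual
   protonation, 1% ¹²C), effective ¹H,¹H coupling descriptors
   d_j = (1/N)Σ_l √(Σ_{k≠j} d²_jkl), residue contact maps at a 5 Å cutoff,
   and the cross-peak probability P(≥2 of N sites protonated).
4. **Synthetic data** — ideal-geometry structures (including a
   clustered-core globule that bundles Leu/Val methyls like a hydrophobic
   core) and noisy forward-modelled REDOR datasets, so the whole pipeline
   is testable without external data.

## Worked example

Fit a known tensor from synthetic peak volumes:

```sh
methylrap build-grid --nmax 44 --aniso-max 9000 --out grid.npz
methylrap synth redor --aniso -6000 --eta 0.0 --noise-sd 0.01 --seed 5 --out volumes.csv
methylrap fit-redor --grid grid.npz --volumes volumes.csv --mc 200 --seed 1 --out fit.csv
```

`fit.csv` then contains (values printed by the run above):

```
site_id,delta_aniso_hz,eta,chi2,mc_sd_delta_hz,mc_sd_eta,S_met,S_axis_sq
SYN1,-6000.0,0.0,3.999,66.83,0.0425,0.2753,0.6821
```

The fitted anisotropy −6000 Hz equals the simulated truth; dividing by the
rigid-limit magnitude 21794 Hz gives the generalized methyl order parameter
S_met ≈ 0.275, and removing the fast-rotation factor S_f² = 1/9 yields the
axis order parameter S_axis² ≈ 0.68 — the amplitude of motion of the methyl
threefold axis. The Monte-Carlo spreads (≈67 Hz, ≈0.04) are 1σ parameter
uncertainties at this noise level.

Compare the proton networks of the two labelling schemes on a synthetic
clustered-core structure:

```sh
methylrap synth structure --sequence VLAVLTAVLGIM --fold clustered_core --out core.pdb
methylrap couplings --pdb core.pdb --scheme glcrap5    --n 8000 --seed 2 --out glc.csv
methylrap couplings --pdb core.pdb --scheme leuval_chd2 --n 8000 --seed 2 --out lv.csv
```

Mean effective ¹H,¹H couplings over methyl sites come out around 77 Hz
(GlcRAP) versus 183 Hz (Leu/Val) on this structure: random sparse
protonation dilutes the dipolar network far more than precursor labelling,
which concentrates protons in the bundled Leu/Val core.

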