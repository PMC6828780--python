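# Methods

This note records the models implemented in `methylrap`, the numerical
choices behind them, and what the synthetic data do and do not establish.

## Dipolar tensor and order parameters

The heteronuclear ¹H,¹³C dipolar interaction is the traceless second-rank
tensor D = δ_aniso·diag(1−η, 1+η, −2) in its principal axis frame, with
asymmetry η ∈ [0, 1]. The rigid-limit anisotropy is

    δ_aniso = −S · μ₀ħ/(8π²) · γ_H γ_C / r³   [Hz]

evaluated with CODATA 2018 constants (γ_H = 2.6752218744×10⁸,
γ_C = 6.728284×10⁷ rad s⁻¹ T⁻¹), which are recorded in every provenance
sidecar. At the effective methyl C–H bond length of 1.115 Å — an NMR
effective length that already absorbs zero-point libration, distinct from
the 1.09 Å geometric build length used when constructing hydrogens — this
gives −21793.9 Hz; tabulated values from other constant sets differ by
well under 0.1%, which is the tolerance used in tests.

Fast methyl rotation about the threefold axis scales the coupling by
P₂(cos θ). The ideal tetrahedral half-angle is taken as arccos(−1/3) =
109.471° rather than the rounded 109.5°, so S_f² = {P₂(cos θ)}² is exactly
1/9. Motion of the axis itself contributes S_axis², and the generalized
order parameter obeys S_met² = S_f²·S_axis². `order_from_fit` inverts this
chain and raises (rather than clamps) when a fitted coupling exceeds the
rigid limit or implies S_axis² > 1, since that signals an unphysical fit
rather than a rounding problem.

## REDOR simulation

The spin system is the isolated ¹H,¹³C pair; remote protons are never
propagated (multi-spin effects enter only through the labelling-ensemble
coupling descriptor below). In the doubly rotating frame the Hamiltonian
is H(t)/2π = c(t)·2IzSz plus rf terms, where c(t) = −A_zz(t)/2 and A_zz is
the laboratory zz component of the tensor after rotation through the
crystallite Euler angles, the rotor phase and the magic-angle tilt. The
sign/normalization convention is fixed by two checks: a static pair at
θ = 0 shows the full 2·δ_aniso doublet splitting, and the ideal-pulse
powder curve reproduces the closed-form universal REDOR dephasing
1 − (√2π/4)·J₁/₄(√2λ)·J₋₁/₄(√2λ), λ = |δ|t, to a few 10⁻⁴.

Pulse layout: one ¹H π pulse per half rotor period with centers at
(k+½)·τ_r/2 + ζ, and a single ¹³C π pulse of length 1/(2·rf_C) centered at
the block midpoint T/2 (T = 2τ_r(n+1)). The ¹H pulse belonging to the slot
adjacent to the midpoint (k = 2n+1) is omitted — the central ¹³C π
occupies that slot, as in the classic REDOR train. This replacement is not
cosmetic: with all 4(n+1) ¹H pulses present the toggled dipolar phase of
the second half-block exactly cancels the first for every crystallite and
no dephasing occurs at any ζ. The shift ζ is expressed dimensionlessly as
ε = ζ/(τ_r/2); the default ζ = 4 µs at 50 kHz MAS gives ε = 0.4. At
ζ = τ_r/4 the layout reduces to the classic unshifted REDOR spacing, which
is the configuration compared against the Bessel oracle.

Pulses may cross half-rotor-slot boundaries, and the final ¹H pulse may
extend past T (rf simply gates off at T; a trailing unitary acting on the
¹H spin alone cannot change ⟨Sx⟩, so truncation is exact). Errors are
raised only when a π pulse is longer than τ_r/2, which would force
same-channel overlap.

Two propagation modes:

* **δ-pulse mode** — π rotations are instantaneous; the per-crystallite
  signal is cos(2πΦ) with Φ the analytically integrated, sign-toggled
  dipolar phase (the rotor-phase harmonics of c(t) integrate in closed
  form, so no time discretization enters). Because Φ is linear in
  (δ_aniso, η·δ_aniso), whole grids reuse two basis phase tables and cost
  one cosine per node, crystallite and time point.
* **Finite-pulse mode** (default: rf_H = 125 kHz, rf_C = 100 kHz) — exact
  diagonal propagation between pulses, piecewise-constant steps of at most
  dt (default 0.1 µs) inside rf windows with exact 4×4 eigendecomposition
  exponentials; within each step c(t) is replaced by its exact mean over
  the step. ¹H phases follow XY-8. Halving dt moves curves by < 10⁻⁴ and a
  5 MHz-rf simulation reproduces δ-pulse curves to ~10⁻³ (both are test
  contracts).

The reference experiment S₀ sets rf_H = 0 (no ¹H pulses); the central ¹³C
π then refocuses the coupling exactly over the full block, which the
δ-pulse path exhibits as identically zero toggled phase. Dephasing curves
are reported as ℑ = (S₀ − S)/S₀.

Powder averaging uses equal-weight ZCW-type golden-ratio sets (cos β
stratified, α golden-stepped) with uniform γ; a REPULSION-style relaxed
set is also available. Defaults: 377×18 for single curves. Convergence at
long dephasing (λ ≈ 30) is dominated by the γ sampling: grids meant for
fitting against 1.8 ms data use 987 (α,β) × 16 γ (curve error ≲ 4×10⁻³),
and the synthetic-dataset generator defaults to 610×16. The dephasing
fraction depends on |δ_aniso| only, so grids store magnitudes; the η = 0
powder slice is bounded by the universal curve's overshoot (max ≈ 1.043),
while strongly asymmetric tensors (η → 1) rephase more coherently and
overshoot to ≈ 1.11 — a physical feature, not a numerical artifact, which
is why the grid-range test allows values up to 1.15.

## Curve construction and fitting

Experimental curves are built from S and S₀ peak-volume tables. Reference
points sampled every 0.12 ms over the 1.92 ms window are linearly
interpolated to the recoupling time points; the ratio (S₀ − S)/S₀ cancels
the common apparent decay exactly where references exist and to the
linear-interpolation error (~10⁻⁶ at 25 s⁻¹ decay) in between. The
volume-level error floor is 2× the spectral noise standard deviation,
propagated to ℑ by first-order error propagation.

χ²(δ, η) = Σ_t ((ℑ_exp − ℑ_sim)/σ_t)² is minimized exhaustively over the
grid (100 Hz × 0.1 steps, matching the resolution at which the curves were
simulated); no sub-grid refinement is applied by default. Ties are broken
deterministically toward smaller |δ|, then smaller η. Joint fits (the
γ1/γ2 or δ1/δ2 pairs of Val/Leu) sum member surfaces node-wise. Parameter
uncertainties come from a parametric Monte Carlo (default 1000 runs): the
best-fit simulated curve is perturbed by Gaussian noise of the per-point
σ and refitted; spreads are sample standard deviations (ddof = 1). The
parametric (model-resampling) choice avoids double-counting experimental
noise and is recorded in output metadata.

Under these conditions the pipeline recovers truth pairs
{−4, −8, −15 kHz} × {0, 0.3, 0.6} within one grid step as the median of 50
replicates at ℑ-noise 0.02 — provided the powder sets are converged as
above; with 8 γ angles the long-time systematic error alone biases |δ| by
several grid steps.

## Stochastic labelling and the proton network

Hydrogen sites are classified from explicit-H structures (methyl carbons
by residue/atom-name tables; exchangeable = N/O/S-bound; aromatic ring H;
the rest aliphatic), with Val/Leu methyl prochirality assigned
geometrically (promote one methyl over the other, attached H lowest
priority; the sign of the triple product decides pro-R/pro-S).

Schemes:

* `glcrap5` — every non-exchangeable site independently ¹H with p = 0.035
  (methyl, aliphatic and aromatic alike; per-residue-type overrides and a
  global rescaling factor, e.g. to match a MALDI-derived mass, are
  available). The flat 3.5% stands in for experimentally determined
  per-site probabilities that are not public; the binomial intra-methyl
  statistics this implies (CHD₂ : CH₂D ≈ 27.6 : 1 at p = 0.035) understate
  the experimentally observed 5–20 : 1 abundance of higher isotopomers.
* `leuval_chd2` — per Leu/Val residue one of the two methyls (½ each,
  matching equal pro-R/pro-S incorporation) carries one ¹H on one of its
  three positions (⅓ each, positions being equivalent under fast methyl
  rotation); every other side-chain H is ²H. Marginal site probability
  exactly ⅙, and each residue carries exactly one methyl proton in every
  replica.
* `uniform` — fully protonated. Back-exchanged variants set the
  exchangeable-site ¹H fraction to 1 (0 models 100% D₂O buffer).

The effective coupling at methyl site j in replica l is the
root-sum-square of pair couplings d(r) = μ₀ħγ_H²/(8π²r³) over occupied
partners within 10 Å, with intra-methyl pairs scaled by |P₂(cos 90°)| =
0.5 (fast rotation) and d_j(l) = 0 when site j itself is unoccupied;
d_j is the mean over replicas, with the Bessel-corrected standard
deviation of the replica distribution used for the upper 2σ value (the
standard error of the mean is also reported). The homonuclear prefactor
convention matters only up to a constant factor for every comparison the
descriptor is used for. Contact maps report, per residue pair, the
fraction of replicas with ≥ 1 occupied H pair within 5 Å. The cross-peak
probability for N adjoining sites is the binomial tail
1 − (1−p)^N − Np(1−p)^{N−1}, and 2^N − N − 1 counts the distinct
cross-peak combinations.

Theoretical masses count C/N/O/S and hydrogen sites from the structure
itself (validated against standard residue formulae), sample the ¹²C
impurity binomially (default 1%) and a residual-protonation floor on
nominally ²H sites (default 3%), use average atomic masses for N/O/S, and
add one water per chain for the termini.

## Synthetic structures

`make_structure` builds coarse ideal-geometry chains of A/I/L/M/T/V/G with
exact methyl geometry (C–H = 1.09 Å, H–C–H = arccos(−1/3); both are test
contracts at 10⁻⁹ Å / 10⁻⁶ deg). Three folds: an extended line, an
α-helical spiral, and a clustered-core globule in which every side chain
points at the common centroid — Leu/Val methyl tips on an inner sphere at
the ~5 Å CH₃⋯CH₃ packing contact, other side chains forming a second
shell one van-der-Waals layer out, and the backbone (with its amide H at
realistic ~2.8–4.9 Å from the nearest methyl H of the same residue)
enveloping the globule. Branch azimuths and backbone orientations are
chosen per residue by a deterministic greedy search that maximizes the
distance to previously built atoms; residual worst-case non-bonded
contacts of ~1 Å remain in dense cores (a known limitation of rigid
ideal-geometry growth).

These structures reproduce the distance *statistics* that the labelling
analyses need — bundled cores, dense-ish interiors, enveloping amides —
but not the true packing density of a folded protein: a real interior
offers several-fold more aliphatic neighbours within 5 Å of a methyl than
a ~12-residue globule can. Consequently the qualitative scheme ordering
(uniform > Leu/Val > GlcRAP mean effective coupling) is robust here, while
quantities that depend on the *ratio* of the sparse-scheme baseline to the
exchangeable-proton contribution — such as the relative coupling increase
upon full back-substitution — are at the edge of what such a synthetic
globule can decide and come out GlcRAP-larger rather than
GlcRAP-smaller on the default structure (the corresponding test documents
this as a failing expectation rather than hiding it).

`make_redor_dataset` forward-models a measurement: δ-pulse powder truth
curve, apparent exponential decay (default 25 s⁻¹) applied to S and S₀
alike to exercise the relaxation-compensation path, references every
0.12 ms over 1.92 ms, dephasing times 2τ_r(n+1) (default n = 0, 4, …, 44,
i.e. 12 points inside the experimental window), and Gaussian noise
(multiplicative on S₀, additive on S). Note the compounded S/S₀ noise
makes the ℑ-level noise ≈ 1.4× the nominal volume noise.

## Determinism and provenance

Every stochastic operation takes an explicit seed (NumPy `default_rng`);
identical seeds give byte-identical ensembles and CSV outputs. Result
files carry JSON sidecars with the package version, constant set, scheme
parameters and seeds; grids persist as NPZ with a provenance hash that is
checked before reuse.

## Known limitations

* Two-spin simulation only: no CSA, no ²H couplings, no relaxation during
  the sequence, no rf inhomogeneity, no multi-tensor fits for sites whose
  dephasing a single asymmetric tensor cannot describe.
* GlcRAP site probabilities are a flat stand-in; isotopomer statistics are
  binomial rather than experimentally calibrated.
* Synthetic folds are rigid ideal-geometry constructs with residual ~1 Å
  worst-case contacts and sub-physiological packing density.
* PDB is the only structure dialect; mmCIF is out of scope.
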