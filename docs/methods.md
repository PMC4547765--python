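# Methods

## Signal model and estimator

The diffusion-kurtosis signal along a unit direction `n` at weighting `b`
is modeled as

    ln[S(b)/S0] = −b·D_app + (1/6)·b²·D_app²·K_app,
    D_app = nᵀDn,     K_app = (MD²/D_app²)·Σᵢⱼₖₗ nᵢnⱼnₖnₗ Wᵢⱼₖₗ,

with `MD = trace(D)/3` and `W` the fully symmetric kurtosis tensor. With
`K_app = 0` this is the mono-exponential DTI decay. The model assumes
magnitude MR data, a single compartment per voxel, and b-values low enough
that the quartic term is negligible (the truncated cumulant expansion is
accurate roughly up to `b·D·K ≲ 3`; the default shells of 1000/1500/2000
s/mm² with tissue-like `D ≈ 1e-3 mm²/s`, `K ≲ 2` respect this).

**Default (directional) estimator.** Per voxel:

1. The `n_b0` unweighted volumes are averaged into `S0` (arithmetic mean).
   A voxel with `S0 ≤ 0` is flagged `negative-signal` and excluded.
2. Weighted signals are floored at `signal_floor·S0` (default 1e-6) before
   the log; magnitude data can reach zero after smoothing edge effects and
   the log must stay finite.
3. For each direction, `ln(S/S0)` over the shells is fit by linear least
   squares in `x₁ = D_app`, `x₂ = D_app²·K_app` (the model is linear in
   these), giving `K_app = x₂/x₁²`. A fitted `x₁ ≤ 0` marks the direction
   degenerate. `K_app` is clamped to `[0, 3]` — physically motivated
   bounds that prevent noise-driven blow-up where `D_app → 0`; clamps are
   counted and surfaced in the fit log.
4. MK is the arithmetic mean of `K_app` over non-degenerate directions;
   the number of excluded directions is recorded per voxel. A voxel with
   no usable direction is flagged `degenerate`.
5. The diffusion tensor is fit by linear least squares to the
   kurtosis-corrected per-direction `D_app` (`D_app = nᵀDn`, 6 unknowns,
   ≥ 6 spanning directions required). Eigenvalues are sorted descending;
   negative eigenvalues are clamped to 0 and counted. MD is the eigenvalue
   mean; FA = √(3/2)·‖λ−MD‖/‖λ‖, defined 0 for the all-zero tensor.

**Joint estimator** (`mode="joint"`): one linear solve per voxel in the 6
tensor components and the 15 components of `V = MD²·W` (the substitution
that keeps the 21-parameter problem linear), after which
`K_app = V_app/D_app²` per direction and the same MK/MD/FA path applies.
Both estimators agree to numerical precision on noise-free data and both
pass the forward–inverse round trip.

**Pre-smoothing.** Each volume is convolved with an isotropic 3D Gaussian
of FWHM 0.3 mm by default (SD = FWHM/2√(2 ln 2), converted to voxels per
axis so anisotropic voxels are honored), applied to the full volume before
masking. Smoothing trades resolution for SNR; at the default preclinical
voxel size (0.234 mm in-plane) the kernel SD is ≈ 0.54 voxels in-plane and
nearly nothing through-plane.

**Failure codes** are exhaustive: `ok`, `negative-signal`, `degenerate`,
`clamped`. Clamped voxels still carry usable estimates; ROI extraction
excludes only `negative-signal`/`degenerate` voxels.

## Gradient schemes

When the scanner's direction table is unavailable, direction sets are
generated by electrostatic repulsion with antipodal symmetry from a seeded
random start — the standard construction for well-conditioned encoding
sets. Any unit-norm table is accepted on input; volumes may arrive in any
order and are canonicalized (b0 block first, shells ascending, shared
direction order), which makes all maps invariant to a joint permutation of
volumes and gradient-table rows. The b0 block is replicated `n_b0` times
with independent noise in synthesis, mirroring repeated unweighted
acquisitions.

## Synthetic data: what it emulates, and what it does not

The generators produce every input class with known ground truth:

- **Phantoms** obey the forward model exactly, with Rician noise
  (`√((s+ε₁)²+ε₂²)`, the magnitude of a complex Gaussian-corrupted
  signal) as the default and additive Gaussian available for analytic
  tests. Kurtosis ground truth is either a per-voxel directional `K`
  (applied identically along every direction) or a full 15-component `W`
  tensor. The scalar form is *not* converted to a `W` tensor: for
  anisotropic `D` no single `W` yields direction-constant `K_app`, so the
  scalar is interpreted directly as the directional kurtosis. With
  isotropic `D` the two parameterizations coincide.
- **Cohort tables** follow a balanced two-arm repeated-measures design:
  cell mean + per-subject Gaussian intercept + Gaussian residual. Defaults
  (6 subjects/arm; baseline + 4 post-injury days; SDs 0.05 on a unit-mean
  measure) mirror a small-animal serial imaging study.
- **Metabolite tables** are generated at the fitted-concentration level
  (name, concentration, CRLB%), with a tCr reference row.
- **Micrographs** place exactly `round(fraction·n_pixels)` pixels at
  `multiple × background`.

Not emulated: pulse-sequence physics, eddy currents, motion, partial
volume, spatially correlated noise, FID-level spectra, or biological
variance structure beyond the random-intercept model. Passing tests
therefore demonstrate correctness of the estimators and statistics under
the stated models, not robustness to every artifact of in vivo data.

## Statistics

The split-plot ANOVA uses the classical sums-of-squares partition for a
balanced design (g groups × s subjects × t times):

    SS_total = SS_group + SS_subj(group) + SS_time + SS_group×time + SS_resid,

with `F_group = MS_group/MS_subj(group)` and the within effects tested
against `MS_resid`; dfs are g−1, g(s−1), t−1, (g−1)(t−1), g(s−1)(t−1).
No sphericity correction is applied by default, matching the uncorrected
two-way RM-ANOVA convention of the source analyses. Unbalanced or
incomplete input is rejected with the offending subjects/cells listed —
completeness is the complete-case filter's job, not the ANOVA's. The
degenerate t = 1 layout reduces to a one-way between-subject ANOVA (the
group F then equals the squared pooled t).

**Fisher's LSD** between groups at a fixed time uses the mixed error term
`MS_cell = (MS_subj(group) + (t−1)·MS_resid)/t` with Satterthwaite df —
the appropriate variance for a between-group contrast at one within level
in a split-plot design. Since the source convention for this error term
is not documented, a plain per-time unpaired t-test mode is provided as an
alternative (`mode="ttest"`); at t = 1 both reduce to the pooled t-test.
P-values are unadjusted, per the LSD convention, and α = 0.05.

**Analysis variable.** The default is the baseline-normalized value over
the post-injury times (4 within levels); a switch includes baseline as a
fifth level, since both conventions appear in practice and the
reproduction attempt should report which matches.

**Rank transform**: ascending midranks, missing values passed through —
applied before the parametric machinery for non-parametric outcomes such
as ordinal behavioural scores.

## MRS QC and histology

The CRLB gate is strict (`CRLB < threshold`, default 20%) and is applied
per table (i.e. per voxel × time point) *before* ratio computation; a
metabolite failing the gate at one time yields a missing value there
rather than being dropped study-wide, preserving the longitudinal design
(missing cells are then handled by the complete-case filter). Ratios are
taken against tCr and are invariant to global concentration scaling.

Histology thresholds at `multiplier × background` (default 2×), with the
background estimated as the **median** of an unlabeled region's intensity
histogram — chosen over the mean for robustness to stray bright pixels; a
mean switch exists. %ROI is invariant to global intensity rescaling and
non-increasing in the multiplier. The per-image background convention is
used (rather than per-batch), since staining batches are quantified from
uniformly acquired images.

## Numerical choices and problem sizes

- FWHM→SD conversion constant 2√(2 ln 2); Gaussian truncation at 6 SD.
- K_app clamp `[0, 3]`; signal floor `1e-6 × S0`; both configurable and
  logged.
- Eigenvalues descending; negative eigenvalues clamped to 0 for MD/FA.
- Phantom problem sizes in the test and acceptance runs (e.g. 16×16×8 for
  the Gaussian limit, 600 voxels at SNR 20, 2000 replicate null cohorts
  for the type-I calibration) were chosen as the smallest sizes at which
  the measured quantities are statistically stable.
- All generators are deterministic per seed; the pipeline funnels one seed
  per stage, and re-running any stage with identical config and seed
  yields byte-identical CSVs.

## Known limitations

- The directional estimator fits each direction independently; it does not
  exploit the cross-direction smoothness a full tensor prior would give,
  and MK from 30 directions is a sampled, not analytic, mean kurtosis.
- Rician bias is not corrected; at low SNR along high-b directions it
  biases `K_app` (the SNR-20 recovery numbers quantify the net effect
  after pre-smoothing).
- The spreadsheet importer is layout-configurable but cannot guess
  arbitrary layouts; unmapped columns are reported.
- No axial/radial kurtosis, tractography, distortion or motion correction,
  spectral fitting, or atlas-based ROI placement.
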