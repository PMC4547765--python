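# dkiblast

Analysis pipeline for longitudinal small-animal neuroimaging studies that
combine **diffusion kurtosis imaging (DKI)**, **proton MRS metabolite
tables** and **fluorescence histology** — the kind of design used to track
subtle brain injury (e.g. blast TBI in rats) that is invisible on
conventional T2-weighted MRI. It is aimed at imaging scientists who need a
tested, scriptable re-implementation of this analysis chain, together with
synthetic data generators that make every step verifiable without scanner
data.

## What it computes

**DKI reconstruction.** Along a gradient direction `n` at diffusion
weighting `b` (s/mm²), the multi-shell signal follows

```
ln[S(b)/S0] = −b·D_app + (1/6)·b²·D_app²·K_app
```

where `D_app = nᵀDn` is the apparent diffusivity and `K_app` the apparent
(directional) kurtosis; `K_app = 0` recovers the mono-exponential DTI
decay `ln[S(b)/S0] = −b·D_app`. Per voxel the package averages the b = 0
volumes into `S0`, fits `(D_app, K_app)` for every direction by linear
least squares, reports

- **MK** — mean kurtosis, the average of `K_app` over all directions,
- **MD / FA** — mean diffusivity and fractional anisotropy from the
  diffusion tensor fit to the per-direction `D_app`,

after 3D Gaussian pre-smoothing (default FWHM 0.3 mm). A joint
21-parameter (6 tensor + 15 kurtosis-tensor) linear mode is available as a
configuration switch.

**Longitudinal statistics.** ROI means (with bilateral averaging and
per-subject baseline normalization, complete cases only) feed a balanced
**split-plot repeated-measures ANOVA**: group tested against
subject-within-group variance, time and group×time against the residual,
with **Fisher's LSD** between-group comparisons at each time point, rank
transformation for non-parametric outcomes, and a pooled unpaired t-test
for two-sample endpoints.

**MRS QC.** Metabolite concentrations pass a Cramér–Rao lower bound gate
(CRLB < 20% by default) and are expressed relative to total creatine
(tCr).

**Histology.** Percent area with specific labeling (% ROI): pixels above
2× the background level, the background being the median of an unlabeled
region.

## Worked example

```python
import dkiblast as dk

# 30 directions x b = 1000/1500/2000 s/mm^2 + 5 b0 volumes
scheme = dk.make_scheme(30, [1000, 1500, 2000], 5, seed=1)

# two-compartment phantom: K_app = 0.6 / 1.2, Rician noise
field = dk.two_block_field((10, 10, 4), kapp_a=0.6, kapp_b=1.2)
series, truth = dk.make_phantom(field, scheme, sigma=25.0, seed=1)
maps = dk.fit_volume(dk.smooth_dwi(series, 0.3))
print(maps.MK[:5].mean(), maps.MK[5:].mean())   # 0.589, 1.172

# synthetic cohort with a d7/d14 injury effect, baseline-normalized
means = {(g, t): 1.0 + (0.25 if g == "injured" and t in ("d7", "d14") else 0.0)
         for g in ("sham", "injured")
         for t in ("baseline", "d1", "d7", "d14", "d28")}
table = dk.make_cohort_table(dk.CohortSpec(n_per_group=6, means=means, seed=1))
from dkiblast.roi import normalize_to_baseline
post = normalize_to_baseline(table).query("time != 'baseline'")
res = dk.mixed_anova(post, value_col="normalized_value")
print(res.report())
for row in dk.fisher_lsd(post, res, value_col="normalized_value"):
    print(row.time, f"p = {row.p:.4f}", "*" if row.significant else "")
```

prints

```
group: F(1,10) = 16.272, p = 0.002
time: F(3,30) = 34.180, p = 0.000
group:time: F(3,30) = 35.520, p = 0.000
d1 p = 0.1550
d7 p = 0.0000 *
d14 p = 0.0000 *
d28 p = 0.5990
```

— the fitted block MKs sit close to the 0.6/1.2 ground truth despite the
noise, the ANOVA flags the group and group×time effects built into the
cohort, and the LSD rows localize them to d7/d14 only.

The same flow is available from the shell:

```
dkiblast all --seed 7 --out demo_out
```

which simulates a full synthetic study and emits parameter maps
(NIfTI), the longitudinal CSV, ANOVA/post-hoc CSVs and a text report.
Stages (`simulate`, `fit`, `roi`, `mrs`, `histo`, `stats`) can be run
individually against the same output directory.

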