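# blotmap

Pixel-by-pixel correlation mapping of 2D gel immunoblot stacks, with ROI
densitometry and cohort statistics — built around the analysis workflow
used to relate p53 protein isoform patterns in acute myeloid leukemia
(AML) blasts to in vitro drug response and differentiation stage.

## The problem

A 2D gel immunoblot separates proteins by isoelectric point (pI, the
horizontal axis) and molecular weight (kDa, vertical), then detects one
protein family with an antibody: each patient sample yields one grayscale
image. For p53 the blot resolves the full-length protein (p53FL) as a
charge train of ~3 spots at ~53 kDa (FL1 most acidic) and the truncated
p53β/γ isoforms at lower molecular weight. Classical densitometry reduces
each gel to a handful of hand-drawn region-of-interest (ROI) values; that
discards the spatial detail in which isoform *pattern* differences live.

The pixel-wise alternative implemented here: align and normalize the
stack of gel images, then, at every pixel, rank the n per-sample
intensities against a per-sample biological variable — percent decrease
in proliferation under valproic acid (VPA), or the FAB class M0–M6
encoded as an ordinal 0–6 — and compute the Spearman rank correlation

    r  = Pearson correlation of the two midrank vectors,
    t  = r · sqrt((n − 2) / (1 − r²)),
    p  = two-sided tail of Student's t with n − 2 df.

The result is an image of correlation coefficients, rendered red where
intensity rises with the variable and blue where it falls; connected
components of significant pixels are the reported regions, each re-scored
by the same statistic on its summed intensity.

Because the original patient gels are not distributed with the package, a
first-class synthetic generator (`blotmap.synthetic`) renders gel stacks
with *known planted* region–covariate Spearman coefficients (a latent
Gaussian copula with an exact finite-n calibration), reproducing the two
study designs (n = 21 vs a continuous VPA-like response; n = 29 vs an
ordinal FAB-like class). Every analysis component is validated by
recovering the planted parameters through the full pipeline.

## Worked example

```python
from blotmap import (vpa_study_config, generate_study, preprocess_stack,
                     pixelwise_spearman, significance_mask, detect_regions)

cfg = vpa_study_config(seed=0)          # n=21, FL rho=+0.80, beta/gamma rho=-0.61
stack, cov, truth = generate_study(cfg)
prepped, offsets = preprocess_stack(stack)          # background, align, normalize
cmap = pixelwise_spearman(prepped, cov)             # per-pixel r / t / p images
masks = significance_mask(cmap, alpha=0.005)
regions = detect_regions(masks, min_area=20, stack=prepped, covariate=cov)

print(f"n = {cmap.n} samples; {int(masks.positive.sum())} positive and "
      f"{int(masks.negative.sum())} negative significant pixels at alpha = 0.005")
for reg in regions:
    print(f"{reg.sign:8s} area={reg.area:3d} bbox={reg.bbox}  "
          f"r={reg.region_r:+.3f}  t={reg.region_t:+.2f}  p={reg.region_p:.1e}")
```

Output for this seed:

```
n = 21 samples; 340 positive and 268 negative significant pixels at alpha = 0.005
positive area= 63 bbox=(88, 114, 96, 125)  r=+0.848  t=+6.98  p=1.2e-06
positive area= 52 bbox=(87, 91, 95, 100)  r=+0.851  t=+7.05  p=1.0e-06
positive area= 51 bbox=(88, 138, 95, 149)  r=+0.843  t=+6.83  p=1.6e-06
negative area= 40 bbox=(176, 93, 183, 105)  r=-0.649  t=-3.72  p=1.4e-03
negative area= 40 bbox=(183, 120, 191, 131)  r=-0.634  t=-3.57  p=2.0e-03
```

The three positive regions are the FL1/FL2/FL3 charge-train spots (their
amplitudes were planted to rise with the VPA-like covariate, population
Spearman +0.80; the realized per-study coefficient fluctuates with n=21
sampling); the two negative regions are the β and γ spots (planted
−0.61). `render_correlation_map(cmap)` produces the red/blue RGB image.

The same objects back classical analyses: `densitometry_table` gives
background-corrected FL and β/γ signals, their ratio and log2 values per
sample, and `blotmap.stats` provides Spearman/Pearson/first-order partial
correlations (e.g. response vs log2 ratio controlling for log2 FL) with
the t-approximation p-values, plus the VPA response metric
`(1 − mean treated / mean control) · 100` from triplicate counts and the
FAB ordinal encoder.

## Command line

```bash
blotmap run --seed 0 --outdir out/            # simulate -> ... -> stats
blotmap simulate --seed 0 --outdir sim/
blotmap preprocess --stack sim/stack.tif --outdir prep/
blotmap corrmap --stack prep/aligned.tif --covariates sim/covariates.csv \
        --alpha 0.005 --min-area 20 --outdir maps/
blotmap quantify --stack prep/aligned.tif --rois rois.csv --out dens.csv
blotmap stats --table merged.csv --x covariate --y ratio --control-for fl --log2
```

`run` writes all stage artifacts plus `report.json` with parameters, the
seed and per-file SHA-256 checksums; identical configs reproduce
identical outputs.

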