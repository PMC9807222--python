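# stemflex

Biomechanics and quantitative anatomy of young climbing-plant stems.

Lianas build their canopy "trellises" from slender young shoots that pass
through distinct mechanical roles: stiff **self-supporting** searchers,
**pendulous** shoots that never found a support, and attached **climbing**
and **fixed** stems that switch to compliant, lianoid (TYPE II) wood. Field
studies of this transition measure each stem segment twice — a three-point
bending test, and a traced cross-section image partitioned into pith, early
dense TYPE I wood, later compliant TYPE II wood, and cortex — and then compare
the four categories within pooled stem-diameter classes using nonparametric
statistics. `stemflex` implements that entire chain as a tested library for
researchers working with such data (or building new instruments of this
kind), plus a synthetic-data generator with exact ground truth so every stage
is verifiable without any field data.

## What it computes

- **Bending reduction** (`stemflex.mech`): from a span *l* and a force–
  deflection sequence, the slope *b* of the least-squares line gives the
  flexural stiffness *EI = l³b/48* (N·mm²); the elliptical second moment of
  area *I = (π/4)ā³b̄* (mm⁴) from caliper radii gives the structural Young's
  modulus *E = EI/I* (MPa). Includes span-to-depth screening against shear
  contamination.
- **Morphometrics** (`stemflex.morpho`): per-tissue areas (mm²) and second
  moments of area (mm⁴) about the section's centroidal bending axis from a
  labeled raster, with percent contributions to area and to *I* that sum
  exactly to 100.
- **Statistics** (`stemflex.stats`): diameter classes (narrow 1.8–3.9 mm,
  medium 3.9–5.9 mm, large > 5.9 mm), tie-corrected Kruskal–Wallis, Dunn's
  post-hoc z-tests, compact letter displays, and Spearman rank correlation
  with *t = R_s√((n−2)/(1−R_s²))*.
- **Synthetic cohorts** (`stemflex.synthgen`): nested-ellipse sections with
  category-specific tissue profiles (TYPE II wood absent, lobed, or a ring),
  composite-beam ground truth *EI = Σ E_t I_t*, Timoshenko shear and Gaussian
  noise models, and a 5–6 mm growth-threshold rule for unattached stems.
- **Pipeline + CLI** (`stemflex.pipeline`, `stemflex` command): joins
  morphometrics and mechanics, emits a trait × class × category summary table
  with KW p-values and Dunn letters, scatter exports (diameter vs. *E*;
  wood-type contribution to *I* vs. *E* with Spearman results), and box-plot
  data. Subcommands: `generate`, `measure`, `reduce`, `summarize`, `spantest`.

## Worked example

```python
import stemflex as sf

cfg = sf.CohortConfig(counts={c: 10 for c in sf.CATEGORIES}, seed=1)
res = sf.run_pipeline(cfg)

print(res.summary.query("trait == 'E_MPa' and diameter_class == 'medium'"))
for name, c in res.spearman.items():
    print(f"{name}: R_s = {c.rs:.4f}, n = {c.n}, t = {c.t:.2f}, p = {c.p:.3g}")
```

Output:

```
trait diameter_class        category        mean           sd  n letter
E_MPa         medium self-supporting 2106.536967 1.555564e+02  6     ab
E_MPa         medium       pendulous 2455.950621 9.457504e+01  6      b
E_MPa         medium        climbing 1551.344215 4.605412e+01  7     ac
E_MPa         medium           fixed 1428.988811 2.784747e-13  3      c

pct_I_wood1~E: R_s = 0.9990, n = 79, t = 194.42, p = 2.09e-105
pct_I_wood2~E: R_s = -0.8283, n = 79, t = -12.97, p = 4.64e-21
```

Reading this: among medium-diameter stems, unattached (self-supporting,
pendulous) categories have the stiffest tissue (*E* ≈ 2100–2500 MPa) while
attached (climbing, fixed) stems are markedly more compliant; the Dunn
letters show pendulous differs significantly from both attached categories.
Across the whole cohort, the percent contribution of dense TYPE I wood to the
second moment of area correlates positively with *E* and that of lianoid
TYPE II wood negatively — the signature of the stiff-to-compliant transition
triggered by attachment. (The near-perfect R_s and zero fixed-category SD
reflect the noiseless synthetic cohort; add a `NoiseModel` for realistic
scatter.)

The same flow from the shell:

```sh
stemflex generate --seed 1 --out-dir cohort/
stemflex measure cohort/sections/*.tiff --out-dir morpho/
stemflex reduce cohort/bending.csv --out-dir mech/
stemflex summarize tidy.csv --out-dir summary/
```

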