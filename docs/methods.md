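# Methods

## Scope and model

`stemflex` reproduces, as reusable code, the measurement-and-analysis chain used
in field biomechanics of young climbing-plant (liana) stems:

1. **Three-point bending reduction.** A stem segment of span *l* (mm) is loaded
   at midspan by a sequence of weights; with *b* the least-squares slope of the
   force (N) vs. deflection (mm) line, the flexural stiffness is
   *EI = l³b/48* (N·mm²). The cross section is approximated as an ellipse with
   mean vertical semi-axis *ā* (load direction) and horizontal *b̄* from three
   caliper readings (center, 25% proximal/distal), giving
   *I = (π/4)ā³b̄* (mm⁴) and the structural Young's modulus *E = EI/I* (MPa).
2. **Cross-section morphometrics.** A labeled raster (background, pith, TYPE I
   wood, TYPE II lianoid wood, cortex; one integer per pixel, physical pixel
   size in mm) is reduced to per-tissue areas and per-tissue second moments of
   area about the **horizontal axis through the whole-section centroid**, plus
   percent contributions to total area and total *I*.
3. **Diameter-class statistics.** Segments are pooled into diameter classes —
   narrow 1.8–3.9 mm, medium 3.9–5.9 mm, large > 5.9 mm — and each trait is
   compared across the four growth categories with a tie-corrected
   Kruskal–Wallis test, Dunn's pairwise z-tests on mean ranks, and a compact
   letter display; monotone trait relations use the Spearman coefficient with
   *t = R_s√((n−2)/(1−R_s²))*.

## Design choices

**Common bending axis for tissue contributions.** Per-tissue *I* is taken about
the shared section centroidal axis, not per-tissue centroids, so contributions
sum exactly to the *I* that enters *E = EI/I*; "contribution to I" is only
meaningful on a common axis. Each pixel contributes
*(y_c − ȳ)²p² + p⁴/12*; the *p⁴/12* self-inertia term removes the systematic
underestimate of coarse rasters and is exact for axis-aligned squares.
Convention: row 0 at top, y downward, pixel centers at half-integer positions.

**Slope fit with intercept.** The force–deflection line is fitted with a free
intercept (pannier settling produces an offset); only the slope enters *EI*.
Records whose fit has R² < 0.99 or whose deflections leave the 0.2–5 mm window
are flagged, not rejected — typical good tests deflect 1–3 mm, but hard
rejection would discard valid extremes.

**Regressing force on deflection** (the field's slope convention) puts the
measurement noise in the regressor, which attenuates the slope by a factor
≈ 1/(1 + σ²/Var(δ)). At the default σ = 0.02 mm and ~2.5 mm maximum
deflection this is an ~0.08 % downward bias in *EI* — far below the
specimen-to-specimen scatter, and bracketed by the Monte-Carlo confidence
interval of a 200-replicate bias check at one record per replicate.

**Span screening rule.** Shear deflection deflates the apparent modulus at
short spans. The screening analysis reduces a multi-span series and returns the
smallest tested span-to-depth ratio whose apparent *E* reaches 95 % of the
value at the largest tested span. Because the largest span always matches
itself, a plateau counts as confirmed only when a *shorter* span also reaches
it; otherwise the series is flagged inadequate and no ratio is returned. The
95 % level is configurable. Depth is the vertical (load-direction) diameter.

**Class-boundary rule.** The printed class edges overlap at 3.9 and 5.9 mm;
the package assigns 3.9 → medium and 5.9 → medium (large strictly > 5.9),
and diameters below 1.8 mm to a below-range class that downstream pooling
excludes with a logged reason.

**Dunn adjustment default: none.** Raw two-sided normal p-values, with
Bonferroni and Holm as options; whether letters derive from raw or adjusted
p-values is an explicit argument, not an assumption. The minimum group size
for inclusion in a Kruskal–Wallis cell is 3; smaller groups are excluded with
a recorded reason rather than failing the comparison.

**Compact letters.** Insert-and-absorb: start from one letter covering all
groups, split on each significant pair, absorb subset columns. Non-transitive
patterns (A≠C, A~B, B~C) yield multi-letter assignments (a / ab / b). The
invariant — two groups share a letter iff their pairwise p ≥ α — is enforced
by property tests on random p matrices.

**Spearman p-value** uses the t approximation with n−2 df, appropriate at the
cohort sizes targeted here (hundreds of segments); |R_s| = 1 is reported with
an unbounded-t flag and p pinned to 0.

**Kruskal–Wallis p-value** is the χ² tail of the tie-corrected H. At very
small n (≤ 8) the χ² tail is a good approximation to the exact permutation
null only in the moderate-H region; in the deep tail the discrete null and the
continuous tail can differ by up to ~0.1. The oracle tests compare against the
exhaustive permutation distribution in the regime where the approximation is
the intended tool.

## The synthetic generator

The generator is first-class, tested code: it defines the conditions under
which every downstream stage is verified.

**Geometry.** Tissue regions are nested similar ellipses sharing the outer
aspect ratio (default circular); boundary semi-axes follow from cumulative
area fractions, *a_i = a₄√(cum_i)*, so ring-mode layouts realize target
fractions exactly. TYPE II wood is realized as `none`, as `lobes` (arcs of the
wood annulus, uniformly spaced with a seeded random phase; the wood1/wood2
boundary is pushed inward so the arcs alone hold the TYPE II fraction), or as
a complete `ring`. Lobe extents are measured in the ellipse's parametric
angle, so sector areas and second moments have exact closed forms that the
rasterizer converges to. Rasterization labels each pixel by its center point
(no anti-aliasing) with ≥ 2 background pixels of padding; pixel size must be
≤ diameter/20, and fractions converge within 1 % by diameter/400.

**Category profiles.** Default tissue-fraction profiles per category follow
the narrow-stem field pattern: self-supporting and pendulous stems are
dominated by pith + TYPE I wood with (near-)zero TYPE II (realized as small
lobes), climbing and fixed stems carry ~10–13 % TYPE II as a ring. Per-specimen
Gaussian jitter (SD 0.03, renormalized) provides realistic spread. Diameters
are uniform on 1.8–10 mm per category; with the developmental threshold rule
on (default), unattached categories (self-supporting, pendulous) are capped at
5.9 mm, emulating the observed 5–6 mm cutoff for self-supporting growth.

**Mechanics.** Ground truth is a composite-beam rigidity
*EI = Σ_t E_t I_t* over the layout's closed-form tissue moments, with default
tissue moduli pith 300, TYPE I wood 5000, TYPE II wood 500, cortex 800 MPa —
chosen so section moduli land in the 1500–3000 MPa band observed for young
liana stems and so the stiff early wood drives *E* upward while lianoid wood
dilutes it. Weights convert to force via g = 9.81 m/s²; forces accumulate over
5–6 steps tuned to ~2.5 mm maximum deflection at span-to-depth 40. The
optional shear term is the Timoshenko midspan form
*δ_s = f_s F l/(4GA)* with f_s = 10/9 (circular) and E/G = 20 by default,
reduced via the circular relation I/A = d²/16 to
*δ_s = f_s F l (E/G) d²/(64 EI)* so it needs only the specimen depth.
A noiseless, shear-free record inverts exactly under *EI = l³b/48*
(round-trips hold to ~1e-15 relative). Noise is Gaussian on deflection
readings and caliper radii. A fixed config (including seed) reproduces the
cohort bit for bit.

**What the generator does not emulate.** Real sections are hand-traced from
photographs: boundaries are irregular, tissues are not concentric ellipses,
and lobes are not circular-arc sectors; stems taper, are curved, and violate
the prismatic-beam assumption; biological variation is not Gaussian jitter
around a category mean. Passing tests therefore demonstrate correctness of
the measurement chain and statistics on known geometry — not that field data
satisfy the model's assumptions.

## Problem sizes

Default verification runs use cohorts of 24–100 specimens, rasters of
200–400 pixels across a section (pixel = diameter/200 for cohort images,
diameter/400 for convergence oracles), 200 Monte-Carlo replicates for the
noise-bias check, and exhaustive permutation nulls at total n = 8. These
sizes make every oracle exact or statistically well-powered while keeping the
full suite fast.

## Known limitations

- Only three-point bending is reduced; four-point bending, torsion, and
  failure mechanics are out of scope.
- No automatic segmentation of color photographs: inputs are already-labeled
  rasters.
- No inverse estimation of tissue-specific moduli from section + EI data; the
  moduli map is a generator input only.
- The elliptical caliper model of *I* and the image-based *I* can disagree on
  strongly non-elliptical sections; both are reported and the choice is the
  user's.
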