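# Methods note

This note records the quantitative model implemented by `myoarch`, the
default parameter values and where they come from, the scope of the
synthetic data generator, the numerical choices that affect results, and
the known limitations.

## 1. Architectural model

**PCSA.** For muscle mass *M* (g) and mean fibre length *L*f (mm),
PCSA = *M* / (*L*f · ρ) with muscle density ρ = 0.001056 g/mm³
(`constants.RHO_MUSCLE`). Units: mm². Inputs must be strictly positive.

**Fibre-length resolution order** (`derive_architecture`): (1) mean of
attached per-fibre measurements; (2) a supplied `mean_fibre_length`;
(3) transfer from a donor specimen via the muscle:fibre ratio,
*L*f = belly length × ratio. Muscles resolving no fibre length are
excluded (reported, never silently dropped). A fibre length exceeding the
belly length raises a warning but is kept — it is biologically possible in
strap muscles and measurement artefacts should be visible, not hidden.

**Mass.** Direct mass is preferred; a volume (mm³, e.g. from
contrast-enhanced CT) converts at 1.06 kg/L = 0.00106 g/mm³
(`DENSITY_VOLUME_TO_MASS`). Staining shrinkage is summarized as
100 × (reference − stained) / reference percent; the generator's default
shrinkage distribution is 39.33 ± 9.68% (truncated below at 0).

**Functional group fractions.** Percent of total muscle mass per group
(downstroke / upstroke / elbow by default). The bundled table yields
62.0 / 19.7 / 18.3% over 13.69 g. An alternate grouping fixture places the
lesser deltoid group with the upstroke muscles, reflecting a conflict
between the table layout and the anatomical descriptions; the table layout
is the default.

## 2. Morphospace and scaling

Normalized coordinates assume geometric isometry:
*L*f / *B*^0.33 and PCSA / *B*^0.66, with *B* body mass in grams. The
exponents are stored as the literal 0.33 / 0.66 used in the source
figures (`Constants` accepts exact 1/3, 2/3 for the invariance property
tests). Division, not multiplication, is established by the printed units.

The bundled specimen's body mass is 105.0 g. No body mass is printed with
the architecture table; 105.0 g is implied jointly by the published
normalized values — only masses in ≈ 104.96–105.07 g round-trip all five
printed normalized coordinates at 2 decimals (see
`load_fixture_specimen`).

**Specialization classes.** Within a species, a median split on each
normalized axis labels muscles force (short fibres, high PCSA), power
(high/high), displacement (long fibres, low PCSA), or generalist
(low/low). Values exactly at the median count as "low". Fewer than 4
points → unclassified.

## 3. Disparity envelope

The convex hull of a species' morphospace points (scipy Qhull; duplicates
removed; degenerate clouds fall back to a segment; vertices returned CCW
starting at the lexicographic minimum) defines the envelope.
**Architectural disparity** is the mean Euclidean distance of *all*
muscle points (not just hull vertices) to a centroid. Three centroid
conventions are implemented because the choice materially changes the
number:

| convention | centroid | fixture disparity |
|---|---|---|
| `point-mean` (default) | mean of all points | 2.33 |
| `hull-mean` | mean of hull vertices | 2.62 |
| `polygon-area` | area centroid of the hull polygon | 3.24 |

The published single-species value (3.25) is reproduced by the
`polygon-area` convention; `point-mean` remains the default because it is
the standard morphometric disparity measure and uses every observation.
The pipeline exposes `--centroid` to select a convention, and the
acceptance test documents the sweep.

Outliers among the centroid distances use Tukey's fences: hinges are
medians of the median-inclusive halves, fences at hinge ± 1.5 × IQR
(outliers) and ± 3 × IQR (far outliers); whisker summaries are
mean ± 1 SD. Species are ranked by descending mean disparity, ties by
`isclose`.

## 4. Regional fibre-length heterogeneity

A balanced two-way ANOVA (compartment × depth) computed from first
principles via the cell/marginal means decomposition, vectorized over
leading batch axes so calibration experiments (2000-replicate null) run in
seconds. Requirements enforced: every cell present, balanced, n ≥ 2.
Follow-up: simple main effects of one factor within each level of the
other, tested against the pooled error term (df from the full model);
pairwise depth comparisons are t-tests on the pooled MS_error with
Bonferroni correction min(1, p·m); significance threshold α = 0.025.

The per-fibre dataset behind the published interaction F(3,152) = 11.486
is not printed anywhere reproducible, so the test suite substitutes:
a hand-computed 2×2×2 toy ANOVA (SS 32/2/0/8, F 16/1/0), the exact
sum-of-squares partition on 200 random balanced designs, a
statsmodels-OLS cross-check, and a calibrated null rejection rate
(0.025 ± 0.01 over 2000 replicates). The design shape 4 compartments × 2
depths × 20 fibres reproduces the published degrees of freedom (3, 152).

## 5. Synthetic data generator

The generator is **morphospace-first**: it draws log-normal normalized
coordinates per muscle (log *L*f/*B*^0.33 ~ N(1.28, 0.45²);
log PCSA/*B*^0.66 ~ N(0.1, 0.75²), fitted to the bundled table), then
inverts the model — mass = PCSA × *L*f × ρ, belly length = *L*f / ratio
with ratio ~ U(0.25, 0.93) — so the ground-truth sidecar (`truth.json`)
holds the *exact* normalized coordinates and point-mean disparity. At
`fibre_cv = 0` the analysis pipeline recovers truth to 1e-9.

Defaults are the study conditions: 1 species × 3 specimens × 19 muscles,
body mass log-uniform on 90–130 g, total muscle budget 13% of body mass
(PCSAs rescaled uniformly to meet it), group mix 62/19.7/18.3%, 20 fibres
per muscle at CV 8%, regional model 4 × 2 × 20 with superficial means
(58, 52, 46, 40) mm, deep offset −8 mm, noise SD 4 mm.

Experimental hooks: per-species `spread_multipliers` scale the log-space
deviation from the species centroid (disparity-ranking recovery);
`planted_outlier=(species, muscle, factor)` pushes one muscle to
`centre + factor · sign · max(|dev|, σ)` in log space, guaranteeing at
least `factor` cloud-SDs from the centroid (Tukey-fence recovery);
`generate_isometric_twin` (lengths × k, masses × k³) must leave exact-
exponent normalized coordinates unchanged; `generate_stained_twin`
applies truncated-normal mass shrinkage, leaving lengths untouched.
Reproducibility: all randomness flows from one `SeedSequence` spawned
into named streams (specimens, muscles, fibres, regional, stained);
regeneration at a seed is byte-identical.

Scope: the generator produces plausible single-session dissection
datasets for pipeline validation, not biomechanically constrained
anatomy — it does not model inter-muscle correlations, pennation, or
tendon compliance.

## 6. Numerical choices

- Exponents 0.33/0.66 are literal defaults; properties that require exact
  isometry invariance pass 1/3 and 2/3 explicitly.
- Hull computation delegates to Qhull; correctness is checked against a
  brute-force O(n⁴) oracle on integer coordinates where comparisons are
  exact.
- ANOVA p-values use `scipy.stats.f.sf`; statsmodels appears only in
  tests as an independent oracle.
- CSV readers parse with `dtype=str` + explicit numeric conversion so
  errors report the offending row; empty cells are missing values, never
  zeros.
- Reported tables round to 2 decimals only at write time
  (`write_architecture(..., decimals=2)`); all internal computation is
  double precision.

## 7. Limitations

- Reproduction of the published PCSA column is limited by the 2-decimal
  precision of the printed inputs: a 0.19 g muscle carries ~2.6% input
  rounding uncertainty, so tests assert the propagated-rounding envelope
  `PCSA · (0.005/M + 0.005/Lf) + 0.005` rather than a fixed tolerance.
- The published across-species analyses (multi-species morphospace
  overlap, the regional fibre raw data) depend on datasets that are not
  redistributable; the corresponding machinery is validated on synthetic
  data with known truth instead.
- Only balanced regional designs are supported; unbalanced data must be
  subsampled upstream.
- The ANOVA assumes independent, homoscedastic normal errors; no
  robustness alternatives are provided.
- Disparity is defined in 2-D (the *L*f–PCSA plane); higher-dimensional
  architecture spaces (e.g. adding pennation) are out of scope.
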