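# myoarch

Muscle architecture analysis for comparative anatomy, built around the
forelimb of the Egyptian fruit bat (*Rousettus aegyptiacus*). The package
derives physiological cross-sectional areas (PCSA) from dissection
measurements, places muscles in a body-size-normalized morphospace,
quantifies each species' architectural disparity envelope, tests regional
fibre-length heterogeneity with a two-way ANOVA, and generates fully
synthetic datasets with known ground truth for validating the whole
pipeline.

## Scientific background

Muscle architecture — fibre length, mass, and their combination into PCSA —
determines the trade-off between force (high PCSA, short fibres), working
range / displacement (long fibres, low PCSA), and power (both high). For a
muscle of mass *M* (g) and mean fibre length *L*f (mm), with muscle tissue
density ρ = 0.001056 g/mm³:

```
PCSA [mm²] = M / (Lf × ρ)
```

To compare muscles across body sizes, coordinates are normalized under
geometric isometry: *L*f / *B*^0.33 and PCSA / *B*^0.66, where *B* is body
mass in grams. In this normalized morphospace, a species' muscles form a
cloud whose convex hull is its **architectural envelope**; the mean
Euclidean distance of muscle points from the cloud's centroid is its
**architectural disparity**. Muscles far from the centroid (flagged by
Tukey's fences on the distance distribution) are architectural specialists;
a median split on each axis classifies them as force-, power-, or
displacement-specialized.

When fibre bundles cannot be teased from a specimen (e.g. a fluid-preserved
or stained one), a fibre length is transferred from a donor specimen via
the muscle:fibre-length ratio (*L*f / muscle belly length), and volumes
from contrast-enhanced scans convert to masses at 1.06 kg/L. Regional
heterogeneity of fibre lengths within a muscle (proximal→distal
compartments × superficial/deep depth) is tested with a balanced two-way
ANOVA, simple main effects on a pooled error term, and Bonferroni-corrected
pairwise comparisons at α = 0.025.

## Worked example

The package bundles the architecture table of an adult Egyptian fruit bat
forelimb (19 muscles, specimen "Laszlo", implied body mass 105.0 g) as a
fixture:

```python
from myoarch.architecture import derive_architecture, group_fractions
from myoarch.io import table2_records, load_fixture_specimen
from myoarch.morphospace import assemble_morphospace
from myoarch.disparity import envelope

records = table2_records()
results = derive_architecture(records)
print(f"derived {len(results)} of {len(records)} muscles")
for r in results:
    if r.muscle_code in ("PPos", "BB", "PAbd"):
        print(f"{r.muscle_code:>5}  Lf={r.mean_fibre_length:6.2f} mm  "
              f"PCSA={r.pcsa:7.2f} mm^2  ratio={r.muscle_fibre_ratio:.2f}")

comp = group_fractions(records)
print({g.value: round(v, 1) for g, v in comp.fractions.items()})

specimen = load_fixture_specimen()
points = assemble_morphospace(results, [specimen])
env = envelope(points, centroid="polygon-area")
print(f"mean architectural disparity: {env.mean_disparity:.2f}")
```

Output:

```
derived 18 of 19 muscles
 PPos  Lf= 47.18 mm  PCSA= 101.76 mm^2  ratio=0.93
 PAbd  Lf= 41.73 mm  PCSA=   4.08 mm^2  ratio=0.93
   BB  Lf= 12.42 mm  PCSA= 109.79 mm^2  ratio=0.31
{'upstroke': 19.7, 'downstroke': 62.0, 'elbow': 18.3}
mean architectural disparity: 3.24
```

The coracobrachialis (SC) is excluded because no fibre length could be
measured for it; the pectoralis pars posterior (PPos) dominates with a
PCSA of 101.76 mm², the biceps brachii is the strongest per-gram
force-specialist (109.79 mm² from only 1.44 g), and downstroke muscles
carry 62.0% of total forelimb muscle mass.

### Command line

```
myoarch simulate --seed 42 --out-dir sim/       # synthetic dataset + truth.json
myoarch run --muscles sim/muscles.csv --specimens sim/specimens.csv \
    --fibres sim/fibre_lengths.csv --regional sim/fibres_regional.csv \
    --out-dir out/
```

`out/` then contains per-specimen architecture tables, `morphospace.csv`,
`disparity.csv` + `disparity_summary.csv`, the ANOVA report (`anova.txt`,
`simple_effects.csv`, `posthoc.csv`), and `run_summary.json`. Other
subcommands: `architecture`, `morphospace`, `disparity`, `heterogeneity`.

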