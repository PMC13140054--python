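# stemvb

Microanatomical phenomics of plant stem cross-sections, built around the
maize lodging-resistance problem: the mechanical strength of a stem is
largely set by how much vascular-bundle tissue it carries and where that
tissue sits relative to the bending axis. `stemvb` turns micro-CT-like
cross-section images into a 32-trait microanatomical profile — including
engineering-mechanics descriptors of the bundle arrangement — and carries
those traits through to bending mechanics, multi-environment quantitative
genetics and machine-learning prediction of bending strength.

It is aimed at plant phenomics researchers who want a tested, fully
synthetic-data-verifiable reimplementation of this kind of pipeline: every
stage can be exercised against exact ground truth generated in code, with
no access to proprietary image archives.

## What it computes

**Segmentation.** An 8-bit cross-section image is split into the stem, then
into three concentric zones — epidermis (EZ), periphery (PZ) and inner zone
(IZ) — and vascular bundles are detected with a background-corrected,
adaptive marker-controlled watershed and filtered by area, solidity,
eccentricity and intensity.

**Traits.** Per section, 32 traits: stem size/shape (SZ_A, SZ_P, SZ_LA,
SZ_SA, SZ_LWR), zone areas and thicknesses (EZ/PZ/IZ_A, EZ/PZ/IZ_T),
bundle counts/areas/densities/ratios overall and per zone, and the
point-mass section-mechanics descriptors

    MOA  = Σ Aᵢ·yᵢ²      (moment of area about the neutral axis)
    PMOI = Σ Aᵢ·rᵢ²      (polar moment of inertia about the section centroid)

with A_i the bundle area, y_i its perpendicular distance to the neutral
axis and r_i its distance to the section centroid; PMOI decomposes exactly
into MOIAL + MOIAS about the long/short principal axes.

**Bending.** Three-point-bending load–displacement curves reduce to
BMMax = F_max·L/4 and BM10mm = F(10 mm)·L/4 (span L, moments in N·m).

**Quantitative genetics.** Multi-environment trait tables follow
Y_ikm = μ + g_i + τ_k + (gτ)_ik + δ_(k)m + ε_ikm; variance components are
estimated by REML (cross-checked against the balanced-design ANOVA closed
form), line values by BLUP (or BLUE with `--blue`), and broad-sense
heritability by H² = Vg / (Vg + V_GL/L + Ve/(L·R)).

**Prediction.** Five named feature sets (all 32 traits; stem-, zone- and
bundle-related subsets; the top-five subset VB_A, PZ_VB_A, PZ_T, PZ_A,
MOA), RFE trait ranking, and Ridge/linear/random-forest/AdaBoost/SVR/MLP
regression under fivefold cross-validation, scored by RMSE and adjusted R².

## Worked example

Simulate a full-scale synthetic section (15 µm/px, ~17 × 15 mm ellipse,
200 bundles), segment it, and compare measured traits with the exact
geometry the simulator recorded:

```python
import pandas as pd
from stemvb import SectionSpec, simulate_cross_section, truth_traits
from stemvb import segment_section, compute_section_traits

spec = SectionSpec(seed=7)
image, truth = simulate_cross_section(spec)
zones, bundles = segment_section(image)
measured = compute_section_traits(zones.labels, bundles, image.pixel_size)
oracle = truth_traits(truth, spec)
show = ["SZ_A", "PZ_T", "VB_N", "PZ_VB_A", "MOA", "PMOI"]
print(pd.DataFrame({"measured": measured[show], "truth": oracle[show]}).round(3))
```

prints

```
         measured    truth
SZ_A      195.906  195.281
PZ_T        1.995    2.000
VB_N      200.000  200.000
PZ_VB_A     9.956   10.112
MOA       281.417  285.289
PMOI      642.800  651.612
```

i.e. the section area (mm²), periphery thickness (mm), bundle count,
periphery bundle area (mm²) and moments (mm⁴) are all recovered within ~1.5%
of the analytic truth; every one of the 200 rendered bundles was detected.

The same stages are available from the shell:

```sh
stemvb simulate section --seed 7 --out-dir scratch/img
stemvb segment --in-dir scratch/img --pixel-size-um 15 --out-dir scratch/seg
stemvb traits --zones scratch/seg/section_0007.zones.png \
              --bundles scratch/seg/section_0007.bundles.csv --out traits.csv
stemvb blup --in phenotypes.csv --trait PZ_T --out-dir scratch/blup
stemvb predict --traits traits_by_sample.csv --bending moments.csv \
               --target BMMax --out-dir scratch/pred
```

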