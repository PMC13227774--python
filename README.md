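# potpheno

Geometric image-based phenotyping (IBP) and salinity-screening
statistics for pot-grown rice.

Pot-based salinity screens photograph each plant against a white studio
background, segment the shoot, and reduce it to geometric and
colorimetric traits; a two-environment trial (normal vs saline) is then
condensed into per-genotype tolerance scores and a multivariate
grouping of genotypes, cross-validated against leaf pigments, proline
and ion balance.  `potpheno` implements this entire chain as a tested
Python library with a thin CLI, for breeders and phenotyping groups who
want the workflow reproducible instead of semi-manual.

## What it computes

**Imaging** — RGB photographs are converted to an HSB stack
(H 0–360°, S/B 0–100%); a 256-bin histogram of one channel (brightness
by default) is thresholded by the triangle method — the threshold is
the bin farthest, in perpendicular distance, from the line joining the
histogram peak to its farthest nonzero tail — and the darker side
becomes the plant mask (`1` = plant).  The RGB image superimposed on
the mask is the region of interest (ROI).

**Morphometrics** — from the ROI and a ruler calibration (cm/px), the
19 standard traits: convex (hull) area, green area, saturation area,
their three ratios, perimeter (corner-corrected chain code), width,
height (bounding box), major/minor axes of the moment-matched ellipse,
Feret and MinFeret (rotating calipers on the pixel-corner hull),
integrated density, aspect ratio = major/minor,
roundness = 4·area/(π·major²), and the normalized red/green/blue
channel indices.

**Screening statistics** — on the log₁₀(x+1) scale, a nested
randomized-block ANOVA (replicates nested within salinity environment;
stress tested against replicate-within-stress, genotype and G×S
against the residual) with CV; traits with a significant stress effect
are kept.  Per-environment block-adjusted genotype means (BLUEs) feed
the stress tolerance index

    STI_g = (Y_g,normal · Y_g,saline) / mean(Y_normal)²

and relative decrease/increase metrics, including the K⁺/Na⁺ ratio
summary.

**Multivariate** — correlation-matrix PCA with deterministic sign and
biplot-quadrant assignment of genotypes, factor analysis by
principal-component extraction (optional varimax), and Pearson
trait–physiology correlations.

**Synthetic data** — a vector-geometry plant renderer with exact
ground truth (hull area, Feret widths, outline perimeter), a balanced
trial simulator with explicit stress/genotype/interaction/block
effects, and a physiology/ion generator following the canonical
tolerance-class pattern.  Every downstream stage is tested against
these generators.

## Worked example

```python
from potpheno import datasets, multivariate, screening

sti = datasets.load_sti_matrix()          # 6 genotypes x 8 traits
print(sti.mean(axis=0).round(2).to_dict())
res = multivariate.pca(sti)
print(round(res.percent_variance[0], 1), round(res.cumulative_percent[1], 1))
print(res.quadrant.to_dict())
```

prints

```
{'convex_area': 0.57, 'saturation_area': 0.27, 'perimeter': 0.42,
 'width': 0.6, 'major': 0.74, 'feret': 0.85, 'min_feret': 0.51,
 'roundness': 0.71}
48.9 77.1
{'HS4.15.1.70': 4, 'HS4.15.2.4': 4, 'HS4.45.1.66': 3,
 'Ciherang': 2, 'IR29': 2, 'Pokkali': 1}
```

The mean STI row shows every selected trait averaging below 1: even
the tolerant check Pokkali is working below its unstressed potential,
i.e. the salinity treatment was severe.  The first two components
carry ~77% of the STI variance, and the quadrant labels separate the
tolerant check (quadrant 1) from the sensitive pair (quadrant 2), the
moderate line (3) and the two tolerant breeding lines (4).

End-to-end on synthetic data:

```bash
potpheno simulate-trial -o fixtures
potpheno simulate-physio -o fixtures
potpheno run-full --traits fixtures/trial.csv --physio fixtures/physio.csv \
    --ions fixtures/ions.csv -o run
```

`run/report.json` then contains the retained trait list, the STI and
relative-change tables, PCA quadrants, factor loadings and a
provenance block (config hash, versions, seed).

## Layout

- `potpheno.imaging` — HSB conversion, triangle threshold, segmentation, ROI
- `potpheno.morphometrics` — the 19 traits + ruler calibration
- `potpheno.screening` — log transform, nested ANOVA, BLUE, STI, relative change, K⁺/Na⁺
- `potpheno.multivariate` — PCA/quadrants, factor analysis, correlation
- `potpheno.synthetic` — ground-truthed generators
- `potpheno.pipeline` / `potpheno.cli` — orchestration and the `potpheno` command
- `potpheno.datasets` — small bundled reference tables
- `docs/methods.md` — models, conventions and design choices
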