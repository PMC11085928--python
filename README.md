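# infiltra

Quantify cell migration and homing inside electrospun 3D scaffolds from
fluorescence z-stacks of stained nuclei.

Cells seeded on a fibrous scaffold (an electrospun nonwoven mat) colonise
its depth over days. A confocal z-scan of the stained nuclei — one image
every few µm — records that colonisation, but every nucleus appears in
several neighbouring focal planes: blurred above and below, sharp in
exactly one. Counting cells per layer therefore requires (1) segmenting
nuclei in every layer, (2) recognising re-appearances of the same nucleus
across layers, and (3) assigning each nucleus to its single in-focus
layer. `infiltra` implements that pipeline and the kinetic analysis built
on top of it.

## Method

**Per-layer census.** Layers are segmented (Otsu or fixed threshold →
hole filling → distance-transform watershed → area filter; large frames
processed in 1024 px tiles). Detections in consecutive layers are matched
by centroid distance and SSIM of their intensity patches, solving an
optimal one-to-one assignment per layer pair; matched chains are collapsed
to one nucleus, assigned to the member with the highest focus score
(variance of Laplacian). The result is the per-layer count `C_z` and total
`C_summ`.

**Conversion kinetics.** The cumulative conversion value

    alpha(z) = (1/C_summ) * sum_{z' <= z} C_z'

is the fraction of cells at or above depth z. Three regimes are fitted by
least squares:

| model | form | regime |
|---|---|---|
| `surface_exponential` | `alpha(z) = 1 - exp(-k z)` | cells settle on the surface |
| `depth_exponential` | `alpha(z) = 1 - exp(-k (z - z0)+)` | mass shifted deeper |
| `hill` | `alpha(z) = z^n / (K^n + z^n)` | sigmoidal colonisation of depth |

**Migration activity.** With the proliferation rate `C_summ/t_d` (cells
per day over an observation interval), the activity

    (alpha / z(alpha)^2) * (C_summ / t_d)

is evaluated at alpha = 0.1 … 0.9 in 10% increments (z(alpha) by monotone
inversion of the conversion curve); the slope of a straight-line fit
through the nine points, `(1/z^2)(C_summ/t_d)`, is the single-number
migration summary, and the area share under the activity curve quantifies
how much of the total activity the shallow fraction of cells carries.

A seeded synthetic-stack generator (ellipsoidal nuclei, defocus blur
growing with z-distance, camera noise, exact ground truth) provides test
beds for every stage, plus a small trainable encoder–decoder segmenter
(pure NumPy, dice + cross-entropy loss) as an alternative to the classical
path. Nuclear morphometrics (areas, major/minor axis ratios, log-normal
fits, Tukey HSD / Friedman group comparisons) round out the analysis.

## Worked example

```sh
python examples/01_simulate_and_count.py
```

prints (seed 42):

```
generated 14-layer stack, 60 nuclei
raw detections across all layers: 162
deduplicated nuclei:              60

layer :   0   1   2   3   4   5   6   7   8   9  10  11  12  13
found :   0   1   4   7  11   5   6   5   2   6   8   0   2   3
truth :   0   1   4   7  11   5   6   5   2   6   8   0   2   3

fraction of nuclei on their true layer: 1.000
ground-truth nuclei counted twice:      0
```

162 raw detections collapse to the 60 physical nuclei: each nucleus was
visible in ~3 focal planes, and the SSIM chaining removed every duplicate
while the focus score put each nucleus in its true layer. The other
examples cover kinetic fitting and activity slopes (`02`), training the
segmenter (`03`), and morphometrics (`04`).

The same pipeline is available from the shell:

```sh
infiltra simulate --out stack.tif --n-nuclei 60 --seed 42
infiltra run-all --input stack.tif --out results --day 4
infiltra kinetics --profiles results/profile.csv --out kin --plots
```

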