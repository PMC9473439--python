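# graincount

Counting grains is the tedious half of measuring thousand-grain weight
(TGW), a standard yield and seed-quality indicator in crop breeding.
`graincount` counts crop grains in an ordinary photograph of seeds
sprinkled on white paper — wheat, corn, mung bean, soybean, peanut,
rapeseed, and similar convex grains of very different shapes and sizes —
without per-crop tuning.

The hard part is *adhesion*: touching or overlapping grains merge into one
connected region in the binarized image. The package resolves adhesions in
two stages:

1. **Short-axis-adaptive erosion.** For each connected region the short
   axis *X* (the grain's minor-axis width, measured as the maximum of
   twice the distance-transform value over the region's medial skeleton)
   sets the erosion extent

   *e = w · X*, with *w* = 0.4 by default.

   Because the erosion scales with each region's own grain width, the same
   coefficient splits tangencies between 2 mm rapeseed and 12 mm corn
   alike, while isolated grains always survive (the removal *w·X* stays
   below the half-width *X*/2 for *w* < 0.5, and a vanish guard halves the
   extent for any region that would disappear).

2. **Concave corner-point counting.** Adhesions the erosion cannot split
   are counted through their boundary concavities. A boundary pixel whose
   13×13 neighbourhood holds a foreground fraction above 0.66, and which
   is a local maximum of that fraction, marks a concave junction point
   (*C*<sub>peak</sub>). With *C* such corners and *H* enclosed background
   holes (*R*<sub>closed</sub>), a region counts as

   *count = C / 2 − H + 1*.

   Nearly collinear overlaps can occlude a junction's corners entirely;
   such regions are recognised by an abnormally long and nearly straight
   skeleton (length > 1.5× the image mean, included angle within
   160–200°) and counted by dividing their area by the mean single-grain
   area.

Accuracy is summarised by the correct ratio CR = (1 − |N₁ − N₂|/N₁)·100
and error ratio ER = 100 − CR, where N₁ is the true and N₂ the estimated
count; series of scene accuracies get a mean M and population variance s².

Since no photo corpus is distributed with the method, the package ships a
seeded synthetic scene generator (`graincount.synthgen`) that renders the
six crop silhouettes on simulated white paper with noise, an illumination
gradient, and controllable touching pairs/triples — with exact ground
truth for every grain.

## Worked example

Generate a 60-grain wheat scene in which 30% of the grains touch, then
count it:

```console
$ graincount synth --n 60 --preset wheat --adhesion 0.3 --seed 7 \
      --px-per-mm 6 --canvas 960x1280 --out scene.png
wrote scene.png (N1=60, clusters=50)
$ graincount count scene.png --truth 60 --json out.json
graincount 0.1.0 | config a680c1e53aac | {'target_long_side': 1920, ...}
60
truth=60 CR=100.00% ER=0.00%
```

The scene's 60 grains form 50 connected clusters (10 adhesions). The
pipeline prints the image total, 60: 48 regions were counted as plain
singles, 4 split-resistant adhesions were resolved by the corner formula,
and 1 near-collinear overlap fell to the average-area correction. With
`--truth` the correct/error ratios are reported next to the count;
`--json`, `--csv` and `--annotate` write the per-region records and the
red-dot/yellow-number overlay (a red dot per region, a yellow count on
regions holding two or more grains).

The same is available as a library:

```python
from graincount import PipelineConfig, binarize, count_image, generate_scene

scene = generate_scene(n=60, preset="wheat", adhesion_frac=0.3, seed=7,
                       px_per_mm=6.0, canvas=(960, 1280))
result = count_image(binarize(scene.image), PipelineConfig())
print(result.total)   # 60
```

`graincount sweep-w` ranks erosion coefficients on a generated adhesion
benchmark and `graincount eval` compares the pipeline against plain global
erosion and watershed baselines.

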