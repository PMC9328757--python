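# shootseg

Patch-based U-net segmentation and phenotypic trait quantification for
greenhouse plant-shoot images.

High-throughput phenotyping platforms produce thousands of side- and
top-view photographs of growing plants. Extracting biological signal
from them starts with a hard segmentation problem: shoots must be
separated from colored chamber walls, pots, carriers and shadows, under
changing illumination and with stressed (brown/yellow) leaf phenotypes
that defeat simple color thresholds. `shootseg` implements a complete
pipeline for this task, aimed at phenotyping researchers and image
analysts:

* an encoder-decoder **U-net** (7x7 convolutions, batch normalization,
  3x3 stride-2 transpose convolutions with channel halving, single
  logistic output head; 2,484,721 trainable parameters in the default
  width) operating on 256x256 patches — implemented directly in NumPy,
  with FFT-based convolution arithmetic and a fully reproducible Adam
  training loop;
* lossless **pad → tile → predict → reassemble** inference for images of
  any resolution >= 256 per side, with probability thresholding at
  T = 0.6, minimum-cluster-size cleanup and RGB overlay rendering;
* **evaluation** by Dice coefficient DC = 2|P∩G| / (|P| + |G|) and
  pixel-averaged binary cross-entropy;
* a **35-trait** shoot quantification stage (area, bounding-box,
  convex-hull and color statistics groups);
* a shallow **pixel-classifier baseline** (3x3 RGB neighborhood
  features, small fully-connected network) for methodological contrast;
* a seeded **synthetic scene generator** producing greenhouse-like
  images with pixel-exact ground-truth masks, so the whole pipeline is
  trainable and testable without any proprietary data.

## Worked example

Everything below runs from a shell on generated data only.

```console
$ shootseg simulate --n 50 --seed 1 --out scenes/
wrote 50 scene/mask pairs to scenes/

$ shootseg train --data scenes/ --seed 1 --epochs 20 \
    --config reduced.yaml --out run/
final val dice: 0.9353

$ shootseg predict --model run/model.h5 --input scenes/ --out pred/
segmented 50/50 images

$ shootseg traits --images scenes/ --masks pred/ --out traits/
wrote traits for 50 images
```

The training run generates 50 synthetic greenhouse scenes, splits them
85:15 at the image level, trains the filter-reduced U-net for 20 epochs
with batch 16, and reports a held-out Dice coefficient of 0.9353 —
i.e. predicted and true shoot masks overlap by ~94% on scenes the
optimizer never saw. The first rows of the resulting trait table:

```
        id  area.plant_area_px  hull.solidity  color.mean_excess_green
scene_0000              6342.0       0.325          305.2
scene_0001              7349.0       0.374          342.8
scene_0002              5885.0       0.344          323.8
```

A projected area of ~6,000 px on a 256x256 frame is a shoot covering
about 10% of the view; solidity ~0.33 reflects an open, branching
canopy; a strongly positive excess green confirms healthy foliage
color.

`reduced.yaml` shrinks the network for desk-scale training:

```yaml
model:
  encoder_filters: [8, 16, 32]
  bridge_filters: 64
training:
  batch_size: 16
```

`run/history.csv` records per-epoch training/validation cross-entropy,
Dice and learning rate; `pred/` holds for every scene a binary mask
(`*_mask.png`, values 0/255), a 16-bit probability map and an RGB
overlay; `traits/traits.csv` has one row per image and 35 columns such
as `area.plant_area_px` (projected shoot area in pixels, the standard
biomass proxy), `hull.solidity` (shoot compactness in [0, 1]) and
`color.mean_excess_green` (2G - R - B, a greenness index).

The library mirrors the CLI one-to-one:

```python
from shootseg import (SceneConfig, generate_dataset, ModelConfig,
                      TrainingConfig, run_training, segment_image,
                      compute_traits, dice)

pairs, _ = generate_dataset(50, SceneConfig(), seed=1)
images, masks = [p[0] for p in pairs], [p[1] for p in pairs]
model, history, (val_images, val_masks) = run_training(
    images, masks,
    ModelConfig(encoder_filters=[8, 16, 32], bridge_filters=64),
    TrainingConfig(epochs=20, batch_size=16, seed=1))
pmap, mask = segment_image(model, val_images[0], threshold=0.6)
print(dice(mask, val_masks[0]))
```

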