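# acam — adaptive contrast adjustment for grayscale medical-image classification

Ultrasound image quality varies with the operator: sonographers routinely
turn the contrast knob until anatomy becomes visible, and a classifier
trained on fixed-contrast images degrades when that knob was set
differently. `acam` implements an **Adaptive Contrast Adjustment
Module** — a small, differentiable, plug-and-play block that learns to do
the knob-turning itself — together with a synthetic ultrasound-phantom
benchmark, four training modes, and standard classification metrics, so
the whole method runs and is testable on one CPU with no external data.

## The method

For a grayscale image $I(x,y)$ with mean intensity
$\mu = \frac{1}{HW}\sum_{x,y} I(x,y)$, the linear contrast transform with
gain $\alpha > 0$ is

$$I'(x,y) = \alpha\,(I(x,y) - \mu) + \mu ,$$

which preserves the mean and scales the intensity spread by $\alpha$. A
shallow *texture decision network* (two strided 3×3 convolutions, global
average pooling, one fully connected layer; ~1.4k parameters) looks at
the image and predicts $K$ pre-activations $x_1,\dots,x_K$, which are
squashed into the clinically used gain range by

$$c_k = 1 + \frac{2}{1 + e^{-x_k}} \in (1, 3).$$

Applying each gain yields a $K \times H \times W$ stack of
contrast-adjusted views of the same image ($K = 10$ by default), which is
fed to the downstream classifier as a $K$-channel input (or scored per
view with averaged logits). Every step is differentiable, so the block
trains jointly with the classifier — or in two stages: first regress the
predicted mean gain onto recorded ideal restoring gains, then freeze the
generator and train only the classifier.

Because no GPU-scale backbone or clinical dataset is assumed, the
package ships a seeded six-class phantom generator (abdomen / femur /
cervix / thorax / brain / other) with fully developed speckle, contrast
compression by a gain $g \in [1/3, 1]$ whose ideal restoring gain
$\alpha^\* = \mathrm{clip}(1/g, 1, 3)$ is recorded per sample,
brightness jitter, realistic class imbalance, and a stratified 70/30
split.

## Worked example

Train the reference backbone with and without the adaptive block on a
phantom dataset whose **test split is compressed harder (g ∈ [0.25, 0.4])
than anything seen in training (g ∈ [1/3, 1])**:

```python
import numpy as np
from acam import (PhantomSpec, generate_arrays, TextureNet,
                  generate_contrasts, TrainConfig, train_classifier, evaluate)

spec = PhantomSpec(n_samples=360, seed=0, test_gain_range=(0.25, 0.4))
_, degraded, manifest = generate_arrays(spec)
print("class counts:", manifest.class_counts)

net = TextureNet(seed=0)                  # untrained: gains start near 2
print("gains:", np.round(generate_contrasts(degraded[0], net), 3))

for mode in ("plain", "acam"):
    cfg = TrainConfig(mode=mode, epochs=20, lr=3e-3, batch_size=32, seed=0)
    bundle = train_classifier(degraded, manifest, cfg)
    report = evaluate(bundle, degraded, manifest, split="test")
    print(f"{mode}: test accuracy {report.accuracy:.3f}, "
          f"weighted F1 {report.weighted['f1']:.3f}")
```

Output:

```
class counts: (21, 30, 47, 50, 90, 122)
gains: [2.005 1.995 2.013 2.006 2.008 1.987 1.983 1.996 1.997 1.993]
plain: test accuracy 0.380, weighted F1 0.321
acam: test accuracy 0.546, weighted F1 0.435
```

The untrained generator predicts gains near 2 (the middle of the range);
after joint training the adaptive views restore the compressed test
images into the contrast regime the backbone learned on, lifting test
accuracy from 0.380 to 0.546 on this fixture.

The estimators follow the scikit-learn contract
(`AcamImageClassifier`, `AcamContrastRegressor`,
`ContrastViewTransformer`), so `clone`, `get_params`/`set_params` and
`cross_val_score` work as usual. A thin CLI covers the same ground:

```bash
acam fixtures data/ --n-samples 600 --seed 0
acam train --data data/ --mode acam --seed 0 --out model.json
acam eval --checkpoint model.json --data data/ --split test --out report.json
acam views data/test/1/00042.png views/ --n-views 10
```

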