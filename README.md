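# nucseg

Nuclei instance segmentation for H&E histopathology tiles, with
pixel-embedding clustering and Monte-Carlo-dropout uncertainty.

Individual nuclei in hematoxylin-and-eosin stained tissue images touch and
overlap, so plain semantic segmentation is not enough: each pixel needs
both a foreground decision and an identity. `nucseg` implements an
encoder / dual-decoder convolutional network whose *instance branch*
predicts, for every pixel *i*, a 2-D offset **o**ᵢ added to the pixel's
normalized coordinate **x**ᵢ to form an embedding **e**ᵢ = **x**ᵢ + **o**ᵢ
pointing at its nucleus centroid **C**ₖ, together with per-pixel margins
σ = (σₓ, σ_y); the *seed branch* predicts per-class seediness maps. An
instance-specific elliptical Gaussian turns embedding-to-centre distance
into a membership probability

    φₖ(eᵢ) = exp( −(eₓ−C_kx)²/(2σ_kx²) − (e_y−C_ky)²/(2σ_ky²) ),

and a pixel joins instance *k* when φₖ(**e**ᵢ) ≥ 0.5. At inference,
instances are recovered by sequential clustering: repeatedly take the
highest-seed unassigned pixel as the centre, absorb all pixels with
φ ≥ 0.5, and continue until no seed exceeds the threshold.

Training minimizes `L = λ_IoU·L_IoU + λ_seed·L_seed + λ_smooth·L_smooth`
with weights (1, 1, 10): a Lovász-hinge relaxation of the Jaccard loss on
the φ maps, a squared-error regression of the seed maps to φ, and an
intra-instance variance penalty pulling σ constant per nucleus.

Epistemic uncertainty is quantified by keeping the spatial-dropout layers
(p = 0.5) stochastic at inference and making T stochastic forward passes
(default T = 50): the predictive variance

    Σ̂² = (1/T) Σₜ (ŷₜ − ȳ)² + (1/T) Σₜ σ̂ₜ²

sums the sample variance of the passes (epistemic) and the mean Bernoulli
variance ŷₜ(1−ŷₜ) of the predicted foreground probability (aleatoric).

The package also includes Vahadane-style structure-preserving stain
normalization (sparse non-negative factorization of Beer–Lambert optical
density), pixel-level F1 / IoU / uncertainty-accuracy metrics with
Student-t 95% confidence intervals and Welch's t-test for comparing runs,
a 70/30 + nested k-fold experiment protocol with random-search tuning, and
a synthetic H&E scene generator so the whole pipeline is testable without
any external dataset. The network itself is implemented on numpy with
hand-written backward passes; no deep-learning framework is required.

## Worked example

```python
import numpy as np
from nucseg import (SceneConfig, TrainConfig, NetworkConfig,
                    generate_dataset, train_model, evaluate_model)

scenes = generate_dataset(SceneConfig(), 60, seed=100)   # 64x64 H&E-like
test = generate_dataset(SceneConfig(), 12, seed=999)
cfg = TrainConfig(epochs=6, batch_size=4, learning_rate=1e-3, seed=0,
                  network=NetworkConfig(num_levels=3, base_width=16))
model, log = train_model(scenes, cfg, progress=True)
report = evaluate_model(model, test, T=16, seed=7)
print(report.f1)
```

prints (exact numbers for these seeds):

```
epoch 1/6 loss 1.4202
...
epoch 6/6 loss 0.9172
MetricSummary(mean=0.5624, ci95_half_width=0.0479, n=12)
```

i.e. after six epochs the model already reaches a per-image mean pixel F1
of 0.56 ± 0.05 (Student-t 95% CI over the 12 held-out scenes); the
benchmark configuration below trains longer and passes 0.70. The same
flow is available from the shell:

```sh
nucseg synth --out data --n-images 64 --seed 1
nucseg train --data data --out run --epochs 20
nucseg evaluate --checkpoint run/checkpoint.npz --data data \
       --out report.json -t 16
nucseg uncertainty --checkpoint run/checkpoint.npz \
       --image data/images/scene_0000.png --out unc -t 50
```

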