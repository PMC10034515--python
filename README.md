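# cmpens

Ensemble fusion of pixelwise class-membership probability maps for
micrograph cell segmentation.

## The problem

A patch-based classifier decides, from a 51 × 51 × 3 window, whether the
window's center pixel belongs to a cell nucleus (foreground) or to the
background of an H&E-stained micrograph.  Training an *ensemble* of M ≈ 100
such networks — differing by initialization seed, by L1-norm filter pruning,
or by training-set size — yields M class-membership probabilities (CMPs)
p₁…p_M per pixel.  `cmpens` fuses them into one consensus decision by four
rules and quantifies how much the choice of rule matters:

* **mean** — (1/M) Σ pᵢ, thresholded at 0.5;
* **median** — the sample median, robust to the right-skew typical of CMP
  histograms;
* **majority vote** — foreground iff #{pᵢ > 0.5} > #{pᵢ ≤ 0.5};
* **alpha-stable location** — the location parameter μ of a Lévy alpha-stable
  law φ(ω) = exp(−γ|ω|^α [1 − i sign(ω) β tan(απ/2)]) · exp(iμω) fitted to
  the M CMPs of each pixel (Gaussian: α = 2, β = 0; Cauchy: α = 1).

Binarized consensus maps are scored against ground truth with
ACC = (TP+TN)/(TP+FP+TN+FN) and Dice DC = 2TP/(2TP+FP+FN), plus continuous
variants cACC = [Σaᵢbᵢ + Σ(1−aᵢ)(1−bᵢ)]/N and cDC = Σaᵢbᵢ/Σaᵢ that accept
probability-valued predictions.

The package contains everything needed to run the study end to end without
external data: a synthetic micrograph/CMP generator, the numpy patch CNN
with backpropagation and structured L1 filter pruning, the eight ensemble
recipes, the aggregation rules, the alpha-stable estimator, and the metrics.

## Worked example

```python
import numpy as np
from cmpens import aggregation, metrics, synthetic_data as sd

# a synthetic micrograph with ~15% foreground, and a noisy 100-member stack
scene = sd.SceneConfig(height=96, width=96, seed=7)
image, mask = sd.generate_micrograph(scene)
stack = sd.generate_cmp_stack(
    mask, sd.NoiseConfig(n_members=100, scale=0.30, sharpness=0.6, seed=11)
)

truth = aggregation.BinaryMask(values=mask)
for method in aggregation.AGGREGATION_METHODS:
    pred = aggregation.aggregate(stack, method)
    c = metrics.confusion_counts(pred, truth)
    print(f"{method:9s} acc={metrics.accuracy(c):.4f} dice={metrics.dice(c):.4f}")
```

prints

```
mean      acc=0.9992 dice=0.9979
median    acc=0.9984 dice=0.9954
majority  acc=0.9983 dice=0.9951
alpha     acc=0.9950 dice=0.9861
```

Even with per-member noise of standard deviation 0.30, the four rules land
within half a percent of each other: per-pixel CMP histograms are decisive
except in a thin band around object boundaries, so the fusion rule only
matters where the consensus itself is ambiguous.
The same comparison is available from the shell:

```bash
cmpens simulate --seed 7 --size 96 --members 100 --out-dir sim/
cmpens aggregate --stack sim/stack.tif --method mean --out pred.png
cmpens evaluate --pred pred.png --truth sim/mask.png --out metrics.csv
```

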