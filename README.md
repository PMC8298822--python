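# s3seg

Semi-supervised tumor segmentation for multi-sequence brain-image slices.

Expert segmentation masks are expensive, so most brain-image data sits
unlabeled. `s3seg` addresses this with a two-stage pipeline:

1. **Label propagation.** A graph-regularized semi-supervised support
   vector machine (S3VM) jointly learns a linear hyperplane `(w, b)`, an
   adaptive row-stochastic similarity matrix `s`, and a spectral embedding
   `F` by alternating minimization of

   ```
   ½ wᵀw + λ₁ Σᵢ uᵢᵢ max(0, 1 − yᵢ(wᵀxᵢ + b))
        + λ₂ (Xw)ᵀ L_s (Xw) + λ₃‖s‖² + λ₄ tr(Fᵀ L_s F),
   s.t. each row of s on the probability simplex, FᵀF = I,
   ```

   where `L_s` is the Laplacian of the symmetrized similarity and the
   labels of unlabeled samples are optimization variables (relabeled by
   the sign rule each cycle). Every block subproblem is solved exactly —
   eigenvectors for `F`, simplex projection for each row of `s`, a
   weighted soft-margin SVM in transformed features for `(w, b)` — so the
   objective never increases.

2. **Patch CNN segmentation.** An AlexNet-style patch classifier with
   overlapping max pooling applied *before* local response normalization,
   dropout-regularized fully connected layers, and a softmax head is
   trained on the completed patch labels with μ-law companded inputs,
   polynomial learning-rate decay, and a weighted cross-entropy restricted
   to hard examples (online hard example mining). Sliding-window inference
   averages window probabilities per pixel; predictions are scored with
   Jaccard, Dice (DSC), PPV, and sensitivity.

Because clinical multi-sequence MRI with expert masks cannot be shipped,
the package includes a seeded phantom generator (4-channel slices with an
elliptical brain, tumor blobs with channel-dependent contrast, a smooth
bias field, noise, and exact ground truth) that exercises the whole
pipeline end to end. See `docs/methods.md` for the full model description
and design rationale.

## Worked example

Propagate labels from a 5% labeled two-Gaussian dataset and score on a
fresh holdout:

```python
import numpy as np
from s3seg.synthetic import generate_clusters
from s3seg.s3vm import S3VMParams, fit, predict

train = generate_clusters(n=400, d=2, separation=4.0,
                          labeled_fraction=0.05, seed=42)
hold = generate_clusters(n=400, d=2, separation=4.0,
                         labeled_fraction=1.0, seed=43)
model = fit(train.X, train.labels_partial, S3VMParams())
acc = (predict(model, hold.X) == hold.labels_full).mean()
print(f"labeled samples: {train.labels_partial.l} / {train.labels_partial.n}")
print(f"objective: {model.objective_trace[0]:.3f} -> "
      f"{model.objective_trace[-1]:.3f} "
      f"({len(model.objective_trace)} block updates)")
print(f"holdout accuracy: {acc:.3f}")
```

```
labeled samples: 20 / 400
objective: 50.811 -> 12.164 (69 block updates)
holdout accuracy: 0.960
```

With only 20 of 400 labels revealed, the joint objective drops
monotonically from 50.8 to 12.2 over 69 block updates and the recovered
hyperplane classifies 96% of unseen points — comparable to what a fully
supervised SVM reaches on this geometry, and above an SVM restricted to
the 20 labeled points.

The same flow is available from the shell:

```sh
s3seg make-phantoms --n 40 --size 64 --seed 7 --out phantoms/
s3seg train-cnn --data phantoms/ --epochs 120 --out model.npz
s3seg segment --model model.npz --image phantoms/sample_000 --out pred.png
s3seg run-pipeline --seed 1 --out run/        # S3VM -> CNN -> metrics
```

`run-pipeline` generates 40 phantoms, splits them 7:3 (28 train / 12
test, stratified), reveals masks for half of the training images,
pseudo-labels the rest with the S3VM, trains the `tiny` CNN preset for
120 epochs at batch size 16, and reports held-out overlap metrics with
all seeds and the resolved configuration persisted beside the outputs.

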