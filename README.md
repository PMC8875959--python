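# uaplab

Universal adversarial perturbations (UAPs) against small image
classifiers, studied on a fully synthetic two-domain benchmark. A UAP is
a single image-agnostic perturbation `rho` that, added to arbitrary
inputs, causes systematic misclassification. The package covers the
whole workflow:

- **`uaplab.synthetic_data`** — a labelled "target-domain" texture
  classification dataset (oriented gratings + Gaussian blobs over noise,
  K configurable) and an unlabelled out-of-domain "source pool" drawn
  from a shifted generative distribution with controllable family-mixing
  bias. Everything is a pure function of `(spec, seed)`.
- **`uaplab.classifier`** — small CNNs on a NumPy backprop core, trained
  either by **transfer** (pretrain a backbone on the pool's surrogate
  texture-family task, swap the head, fine-tune) or **from scratch**
  with a 6x epoch multiplier. Exposes class prediction and exact
  input-loss gradients.
- **`uaplab.attack`** — iterative non-targeted and targeted UAP
  generation: visit the attack images in a seeded random order, add one
  FGSM step (at strength `epsilon`, under norm order `p` ∈ {2, inf}) for
  each image not yet fooled / not yet on-target, project back onto the
  Lp ball of radius `xi`. Budgets can be given as `xi` or derived from
  the relative magnitude `zeta` (ratio to the mean image norm of a
  reference set). Random-sphere UAPs of exactly norm `xi` are the
  control.
- **`uaplab.evaluation`** — fooling rate `Rf` (vs clean predictions),
  targeted success rate `Rs` with its clean baseline, row-normalized
  confusion matrices of the clean-to-adversarial prediction transition,
  dominant class, and predicted-label composition of a pool.
- **`uaplab.pipeline`** — the experiment grid: zeta sweep x UAP source
  (training images / source pool / random) x architecture x init mode x
  seeds, with summaries, Spearman trend statistics and Rf-vs-zeta
  curves. Scratch models are attacked at doubled zeta.

## CLI

One entry point with a subcommand per stage:

```sh
uaplab generate-data --spec spec.yaml --out data.npz [--domain target|source_pool]
uaplab train --data data --pool pool.npz --mode transfer|scratch --arch small|medium --out model/
uaplab attack --model model/ --source data_train.npz|pool.npz|random \
              --reference data_train.npz --zeta 0.08 --p inf --epsilon 0.005 \
              [--targeted-class 2] --out uap.npy
uaplab evaluate --model model/ --data data_test.npz --uap uap.npy --out report/
uaplab experiment --config exp.yaml --seeds 0,1,2 --out runs/
uaplab summarize --results runs/results.csv --out runs/summary/
```

## Notes

- Arrays are NHWC float64 in [0, 1]; all norms and budgets are in that
  pixel range.
- Training, attacks and data generation are bit-reproducible given the
  seeds (pure NumPy, no threading nondeterminism).
- Models are saved as an NPZ of weights plus a JSON sidecar
  (architecture, init mode, config echo, test accuracy); perturbations
  as NPY plus a JSON sidecar (p, xi, zeta, epsilon, imax, seed, source
  tag, target class).
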