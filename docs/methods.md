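# Methods

## Study design

The package reproduces, at configurable scale, a GAN-augmentation study for
four-class bladder-mucosa image classification.  The procedure is:

1. split the dataset into five stratified folds (train:test = 4:1);
2. per fold, train one DCGAN per class **on that fold's training images
   only**;
3. build four training-set variants per fold: the originals plus m ∈
   {0, 1, 5, 9} generated images per original image (cases 1–4; for a
   2020-image training fold these are 2020, 4040, 12120 and 20200 images),
   generated counts allocated per class proportionally to the class's
   training count;
4. train a CNN classifier (AlexNet- or VGG16-style) on each variant over a
   hyperparameter grid (solver ∈ {Adam, RMSprop, AdaDelta, AdaMax, AdaGrad},
   batch size ∈ {4, 8, 16, 32}, epochs 4–10);
5. score the untouched test fold, compute micro- and macro-averaged
   score-sweep ROC-AUC, aggregate the five folds into
   (mean micro AUC, mean macro AUC, σ micro, σ macro), rank grid points by
   mean micro AUC descending with σ micro ascending on ties, and summarize
   the grid population by mean/median/σ.

The leakage contract is enforced twice: `make_folds` guarantees disjoint,
covering test sets, and `run_experiment` raises `LeakageError` if any test
image carries `provenance="generated"`.  Generated images can therefore never
inflate test scores; a bad GAN can only hurt training.

## Synthetic data

The clinical images are private, so the dataset module synthesizes a
four-class stand-in with the same statistical skeleton.  Each class is

    image = base_intensity + contrast · band_field + blobs + noise, clipped to [0, 1]

where `band_field` is a unit-variance Gaussian random field band-limited
around a class-specific spatial frequency (anisotropy elliptically distorts
the passband), `blobs` are Poisson-many Gaussian bumps of random sign
(random sign keeps the image mean unbiased at `base_intensity`), and `noise`
is i.i.d. Gaussian.  Per-image seeds derive from
`SeedSequence(master_seed, class_index, image_index)`, so datasets are
pixel-identical across runs and robust to reordering.

Default class recipes separate the classes in base intensity (0.70 / 0.30 /
0.55 / 0.42), spatial frequency (2 / 9 / 5 / 13 cycles per image) and blob
density (0 / 6 / 2 / 10), with per-class counts 900/600/680/345 at 28×28
pixels.  A nearest-class-mean probe on (mean, variance, gradient energy)
reaches ≈0.99 held-out accuracy on these defaults — the classes are *easy*
by construction.  What passing tests therefore show is that the machinery
(fold hygiene, GAN training dynamics, augmentation arithmetic, metric and
ranking code) behaves correctly; they say nothing about attainable accuracy
on real endomicroscopy images, whose difficulty is unknown and surely far
higher.  Synthetic-data results must be reported as properties of this
generator, never compared against clinically derived numbers.

## Networks and training

All models run on `cystaug.nn`, a small NHWC float32 numpy engine (dense,
conv, transposed conv, batch norm, LeakyReLU slope 0.01, dropout, max-pool;
Glorot-uniform init; hand-written backward passes verified against numerical
differentiation).  Everything is single-threaded numpy, so fixed seeds give
identical training trajectories.

DCGAN specifics and the choices behind them:

- kernel size 5×5 everywhere (the customary DCGAN choice; the architecture
  description leaves it open), configurable;
- generator stage strides (1, 2, 2): the only assignment consistent with the
  (w/4, h/4, 128) → (w/2, h/2, 64) → (w, h, 1) chain;
- sigmoid generator output and [0, 1] pixel scale, matching the uniform
  [0, 1] latent convention (no symmetric [−1, 1] rescaling);
- discriminator probabilities clamped to [1e−7, 1 − 1e−7] inside the
  cross-entropies (reported in nats);
- optimizer Adam, learning rate 2·10⁻⁴, batch 32 (unreported upstream; these
  are the standard DCGAN settings), all configurable via `GanTrainConfig`;
- batch-norm running statistics (momentum 0.99) are used at generation time.

Classifier specifics: architectures follow the published tables exactly
(grayscale single-channel inputs, no pretrained weights, no local response
normalization, ReLU activations, four-class softmax).  Where a table's
feature-map column contradicts its size column, the size column wins.
Images are bilinearly resized to the network input; original and generated
images pass through the identical path.  Solver hyperparameters beyond the
name use the common framework defaults (Adam/RMSprop 1e−3, AdaMax 2e−3,
AdaGrad 1e−2, AdaDelta 1.0 with ρ = 0.95).

## Evaluation

Operating-point rates come from the confusion matrix M (rows = true,
columns = predicted; orientation chosen so the per-class TPR reads as
recall): `TPR_micro = tr(M)/G(M)`, `FPR_micro = 1 − TPR_micro`, and macro
averages of per-class one-vs-rest rates.  Two per-class FPR conventions are
kept behind a switch: the default ("paper") divides the off-diagonal of
predicted column n by `G(M) −` (column-n total); "standard" divides by
`G(M) −` (row-n total).  The default preserves the source formulation even
though the standard convention is the usual one.

AUCs are score-sweep areas (trapezoidal rule): micro pools all n·N
one-vs-rest (indicator, score) pairs into one binary sweep; macro averages
per-class binary AUCs, skipping degenerate classes with a warning.  The
operating-point rates are exposed separately as argmax-decision diagnostics
— the upstream text never states how its single-point rates became curves,
so the sweep construction (the standard one) is used for AUC.

Fold aggregation uses the population (divide-by-n) standard deviation: the
five folds are an exhaustive partition, not a sample.  Ranking ties beyond
(mean micro AUC, σ micro) are broken by mean macro AUC descending, σ macro
ascending, then input order; the score tuple's second element is the mean
macro AUC (the source prints the micro mean twice, evidently a typo).

## Numerical and scale choices

- The convolution output-size formula is implemented as
  `⌊(L − F + 2P)/S⌋ + 1`; the upstream text typesets it as `(L − F + 2P)S + 1`,
  which contradicts its own worked values (227 → 55 with F = 11, S = 4).
  "Same" padding uses the framework convention `⌈L/S⌉`, exact `L/S` for the
  even sizes used here; same-padded transposed convolution returns `L·S`
  exactly.
- Desk profile (default): 28×28 images, generator channels (32, 16, 8)
  instead of the full (256, 128, 64), reduced classifiers (two 3×3 conv/pool
  blocks, 8 and 16 filters, FC 32), GAN epochs scaled down from the
  published {100, 250, 500, 1000} schedule.  The architecture checks in the
  test suite always use the full-width plans; the desk profile exists so the
  end-to-end study runs on one CPU in minutes.  Problem sizes used by the
  shipped end-to-end run: 252 images (10% of the study counts), 50 GAN
  epochs, 5-epoch classifiers, cases 1–2.
- Checkerboard artifacts of transposed convolutions are expected in
  generated images and deliberately not mitigated.
- Degenerate inputs: empty label lists, all-zero confusion matrices,
  single-class datasets and kernel-larger-than-input geometries raise typed
  errors rather than returning NaNs; macro AUC skips (with a warning)
  classes lacking positives or negatives and errors only if every class is
  degenerate.

## Known limitations

- No photorealism: the synthetic generator emulates class separability and
  imbalance, not endomicroscopy appearance; absolute AUCs on it are close to
  ceiling and not clinically meaningful.
- The numpy engine is CPU-bound; full-width VGG16 training at 224×224 is out
  of reach here and the full profile exists for architecture fidelity and
  shape checking, not routine training.
- One GAN per class (no conditioning), no Wasserstein or spectral-norm
  variants, no architecture search — the study design is deliberately fixed.
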