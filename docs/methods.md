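# Methods

## Randomized classifiers and closed-form training

The package's core is the RVFL family of single-shot classifiers. Each
draws hidden weights once, uniform on [−1, 1], and never updates them; only
the output weights α are solved. For standardized inputs X (N samples × u
features) and one-hot targets Y (N × 2):

* **ELM**: B = s(XW + th), a single hidden layer of width h with biases th.
* **RVFLN**: B = [H X] with H = s(XW) bias-free; the identity pathway
  carrying X into the output layer is the *direct link*, and the hidden
  units are *enhancement nodes*.
* **dRVFL**: stacked bias-free layers H¹ = s(XW₁), Hˡ = s(Hˡ⁻¹Wₗ),
  B = [H¹ … H^L X].

The bias asymmetry (ELM biased, RVFLN/dRVFL bias-free) is deliberate and
mirrors how these models are conventionally written. A dRVFL with a single
layer reduces *exactly* to an RVFLN: both derive the layer's random stream
from the same (seed, "hidden", 0) tag, so the reduction is asserted as
bit-level prediction equality, not merely as a distributional statement.

Output weights solve min‖Bα − Y‖² + η‖α‖²:

* η = 0 — minimum-norm least squares via SVD pseudoinverse. Singular
  values below max(N, m)·ε·σ_max are treated as zero (the standard
  rank-revealing cutoff); the threshold is configurable.
* η > 0 — ridge, primal (BᵀB + ηI)⁻¹BᵀY or dual Bᵀ(BBᵀ + ηI)⁻¹Y. The two
  are algebraically identical; `auto` mode picks the smaller normal-equation
  system (primal when N ≥ m). The dual form here is the standard one; a
  dimensionally consistent dual requires the Gram matrix BBᵀ, not BᵀB.
  Singular normal equations raise a solver error advising a larger η
  rather than silently regularizing.

Prediction is argmax over the raw scores Bα with ties broken toward the
first class in the fixed order (benign, malignant); malignant is the
positive class everywhere, and ROC/AUC consume the raw malignant score with
no softmax. η defaults to 0 (pure pseudoinverse); sigmoid is the default
activation. Both choices are conventions of the ELM/RVFL literature rather
than constraints of the method, and both are configurable.

### Numerical and design notes

* Standardization: per-feature z-score from the training fold only, applied
  to both the enhancement path and the direct link. Zero-variance features
  pass through unscaled rather than dividing by zero.
* RNG discipline: a single user seed; every component (each hidden layer,
  the fold shuffle, dropout, each generator) draws from a substream derived
  by hashing (seed, component tag), so adding one component never shifts
  another's draws, and every artifact can be regenerated bit-for-bit.
* A width cap (default 10⁵ total hidden units) turns accidentally huge
  solves into an explicit resource error.
* Fits are O(N·m) memory with m the design width; the largest standard
  ablation point (N ≈ 3.7k, h = 1000) solves in well under a second on one
  CPU core.

## The deep-feature head

The head replaces a backbone's classification layers with
FC1000 → Dropout(0.3) → FC64 → Dropout(0.3) → FC24 → FC2 → softmax. Design
choices where the architecture's description is silent:

* **Inter-layer activation**: ReLU after each hidden FC layer. Some
  nonlinearity is required for the stack to be more than one affine map;
  ReLU is the default choice for modern FC heads.
* **Loss**: softmax cross-entropy, implied by the probabilistic softmax
  output layer.
* **Initialization**: seeded He-scaled Gaussians (σ = √(2/fan_in)), the
  standard pairing with ReLU; biases start at zero.
* **Momentum**: 0.9, the conventional SGDM default; recorded in run
  metadata since the published schedule omits it.
* **Taps**: features are read at the 24- and 64-unit layers
  *pre-activation*. Post-ReLU taps would zero roughly half the coordinates;
  the pre-activation values retain the full linear read-out and are what
  "features from the fully connected layer" most naturally denotes.

Training is plain minibatch SGD with momentum: 12 epochs, initial rate
5·10⁻⁴, batch 60, rate multiplied by 0.1 every 3 epochs (so the realized
schedule is three epochs each at 5e-4, 5e-5, 5e-6, 5e-7), reshuffled each
epoch from the seeded stream. Inverted dropout (p = 0.3) is active only in
training, so extraction is idempotent. Non-finite loss aborts with the
epoch number.

## Synthetic data: what it emulates and what it does not

The generators exist so every stage is testable without the real
mammography patch set; they emulate its *structure*, not its difficulty.

* **Feature clouds** (`gen_features`): benign ~ N(0, Σ), malignant ~
  N(separation·𝟙, Σ), Σ = (1−ρ)I + ρJ equicorrelated with unit variance.
  `separation` is the per-feature mean offset in within-class-sd units: at
  separation 4 each single feature misclassifies Φ(−2) ≈ 2.3 % of samples
  and 24 features jointly make the Bayes error negligible, which is what
  makes the ≥ 0.99 recovery benchmarks meaningful. Defaults (1000/class,
  d = 24, separation 4, ρ = 0) define the standard benchmark; separation 0
  is the null control, where any classifier must sit at chance.
* **Mass patches** (`gen_patches`): 64×64 8-bit grayscale. Benign =
  filled ellipse, Gaussian-blurred border (circumscribed, smooth); malignant
  = harmonic-modulated irregular blob plus 6–12 radiating spicules, lightly
  blurred; additive Gaussian noise (default sd 8 grey levels). The margin
  taxonomy *is* the class signal, by design, so the end-to-end pipeline has
  a learnable, interpretable target. Noise-free masks are returned alongside
  images so shape statistics (convex deficiency) can verify the classes
  differ the intended way.
* **Tiny backbone** (`tiny_backbone`): two fixed random 3×3 convolution +
  ReLU + 4×4 mean-pool stages and a fixed projection to 128-wide
  embeddings. It is never trained — it stands in for a pretrained
  backbone's role as a deterministic embedder, at desk scale.

Passing tests on these fixtures demonstrates the machinery — solvers,
reductions, folds, metrics, the training loop, the taps — is correct and
deterministic. It does **not** demonstrate clinical performance: real
mass patches have far more within-class variability, class overlap,
calibration drift and annotation noise than the generators produce, so
near-perfect synthetic accuracies carry no claim about real data.

## Evaluation harness

Stratified k-fold (default 5): per class, a seeded shuffle then round-robin
assignment. Per-class fold sizes differ by at most one, and the *multiset*
of sizes is deterministic given the class counts; which fold index receives
a remainder sample is not guaranteed, since any published alternation of
remainders is an artifact of an unstated assignment order. For 1908 benign
+ 1810 malignant and k = 5 this yields 362 malignant in every fold, benign
split 382/382/382/381/381, largest fold 744 of 3718.

Metrics (malignant positive): sensitivity tp/(tp+fn), specificity
tn/(tn+fp), precision tp/(tp+fp), F1, accuracy. Zero-denominator ratios are
reported as NaN with a warning — never coerced to 0, which would silently
inflate specificity or precision on degenerate folds. The across-fold
summary uses the sample standard deviation (k−1 divisor). The identity
accuracy = (sens·P + spec·N)/(P+N) is asserted on every evaluation.

AUC: trapezoidal area over the ROC swept at all distinct thresholds of the
raw malignant score. Grouping tied scores at one threshold makes the
trapezoid count tied (positive, negative) pairs half, so the result equals
the Mann–Whitney pair statistic exactly; a test verifies the identity
against an O(n²) pair count at 10⁻¹².

Ablation grids default to the standard sweeps: {40, 80, 100, 200, 400,
800, 1000} hidden/enhancement nodes for ELM/RVFLN and {6, 12, 18, 24}
per-layer width for the depth-3 dRVFL (three equal layers, the published
default depth; unequal widths remain supported). One fold plan is fixed
per run seed and shared across the grid.

## Problem sizes

The test suite and the acceptance script use the generators' default study
conditions: the d = 24 / separation 4 / 1000-per-class Gaussian benchmark
with its separation-0 null, 50 random solver systems spanning tall and wide
designs, 100 score sets for the AUC identity, and the 200-per-class 64×64
patch pipeline through the full 12-epoch head schedule. These sizes were
chosen as the smallest at which each claim is statistically meaningful
(e.g. chance ± 3 standard errors on 2000 held-out samples is ± 0.034).

## Known limitations

* No pretrained backbones ship with the package; the backbone contract
  accepts any user-supplied embedder, but reproducing published DDSM-scale
  results requires the external image set and a fine-tuned backbone, both
  out of scope.
* The spiking-neural-network comparison classifier is not implemented
  (no closed-form specification exists for it in this family).
* No probability calibration: scores are raw linear outputs, suitable for
  ranking (AUC) and argmax decisions, not for risk estimates.
* Gradient-based training of α (the backprop alternative the closed form
  replaces) is intentionally absent.
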