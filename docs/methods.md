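# Methods

## Problem and model

The task is binary classification of silkworm pupal sex from an image of the
intact cocoon plus the cocoon-with-pupa weight. The discriminative signal is
assumed to live in the cocoon's shape and surface texture — captured by
gradient-orientation statistics — and, weakly, in the weight. The pipeline
is: HOG descriptor → per-block Fisher compression → weight fusion →
(optional) mutual-information RFE → classifier, with boosted-tree
hyperparameters tuned by a population metaheuristic.

## HOG descriptor and the FFT acceleration

Geometry (defaults): 128×64 input, 8×8-pixel cells, 9 unsigned orientation
bins over [0°, 180°), 2×2-cell blocks with 1-cell stride, plain L2 block
normalization with ε = 1e−10 inside the square root (an all-zero block maps
to zeros, not NaN). Descriptor length is
((128/8 − 2)/1 + 1) · ((64/8 − 2)/1 + 1) · 2² · 9 = 105 · 36 = 3780.

Gradients are central differences `[-1, 0, 1]` with replicate border
padding; zero-magnitude pixels take orientation 0° by convention.

Cell pooling is reformulated as convolution so it can run in the frequency
domain: for each bin k the magnitude image is masked to pixels whose folded
orientation falls in bin k (**hard assignment**, bin width 180°/9; no
bilinear vote between neighbouring bins), then convolved with an 8×8
all-ones box filter via zero-padded FFT (no circular wrap-around), and the
result is sampled at cell anchor points. For a cell starting at row `i·c`
the full linear convolution holds its box sum at index `i·c + c − 1`; after
the centred "same" crop of `(c−1)//2` this lands at `i·c + c//2`. A direct
per-pixel accumulation path (`hog_reference`) implements the identical
contract and is used as the equivalence oracle; measured agreement is at
float round-off (~2e−16 per element), far inside the 1e−6 bound asserted in
tests. The FFT path's benefit is speed, not values; wall-clock is not
asserted in tests because it is hardware-dependent.

Two deliberate simplifications relative to the classic Dalal–Triggs
formulation: hard orientation binning (matches the mask-and-filter
construction) and plain L2 rather than L2-Hys block normalization. Both
change descriptor values slightly but none of the downstream contracts.

## Block-wise LDA compression

Each contiguous 36-feature block is compressed to one Fisher coordinate.
With binary labels LDA admits exactly one discriminant:
`w ∝ (S_W + λI)⁻¹ (μ₁ − μ₀)`, normalized to unit L2 norm. The ridge
λ = 1e−6 · tr(S_W)/36 keeps the solve well-posed when block features are
collinear (common for gradient histograms); an all-zero or otherwise
degenerate block falls back to the first canonical basis vector with a
warning. The sign is fixed so the male (label 1) mean projects at or above
the female mean, making coordinates comparable across refits. Transforms
center on the training grand mean per block, so the compressed features are
affine in the descriptor.

Compression is always fitted on training data only; the cross-validated
pipeline refits it (and the weight standardization) inside every training
fold. The weight z-score uses the sample (ddof = 1) standard deviation.

## Information gain and RFE

IG(X;Y) = H(X) − H(X|Y) with base-2 logs and 0·log 0 = 0; continuous
features are discretized into 10 equal-frequency bins (quantile edges,
deduplicated), which makes the estimate invariant under strictly monotone
transforms and robust to the heavy tails of discriminant outputs. With a
binary label IG ∈ [0, 1] bits. Constant features score 0. Ranking ties
break by ascending feature index.

RFE evaluates the current feature set by stratified k-fold CV, re-ranks the
survivors by IG (re-ranking each iteration, not one-shot), removes the
single lowest-IG feature, and runs to one remaining feature. The selected
subset maximizes recorded CV accuracy, ties resolved toward the smaller
subset — which also guarantees the selected subset is at least as accurate
as the full set. The ranking is model-agnostic: the same MI ordering drives
elimination for every classifier family, unlike coefficient-based RFE.

## Classifiers and metrics

Seven families (SVM, KNN, Gaussian naive Bayes, decision tree, random
forest, XGBoost, AdaBoost) are delegated to scikit-learn/xgboost behind a
uniform fit/predict/predict_score facade with explicit seeding; library
defaults apply unless overridden, and unknown hyperparameter names are
rejected by key. Male is the positive class. Accuracy, precision, recall
and F1 follow the standard confusion-matrix definitions, with
zero-denominator ratios reported as 0 and flagged. Cross-validation is
stratified k-fold (k = 10 default, shuffled with the run seed); reported
metrics are fold means, while AUC is the Mann–Whitney rank statistic with
midrank tie correction on the pooled out-of-fold scores (pooling gives one
well-defined ranking over all samples instead of averaging small-fold
estimates).

## Hyperparameter optimization

Search space (seven dimensions, all configurable): learning_rate
[0.01, 0.3] log-uniform, n_estimators [50, 500], max_depth [3, 10],
min_child_weight [1, 10], gamma [0, 5], subsample [0.5, 1],
colsample_bytree [0.5, 1]. Chromosomes are normalized gene vectors in
[0, 1]⁷; integers round half-up on decode. All variation operators act on
the normalized representation so the TLBO arithmetic is scale-free.
Fitness is mean stratified-CV accuracy of the decoded model, memoized per
decoded point; a training failure scores 0.

*Classical GA*: fitness-proportional (roulette) parent selection,
single-point crossover applied with probability
R(g) = R_min + (R_max − R_min)·g/G (defaults 0.6 → 0.95, linear in the
generation fraction — low early to preserve good schemata, high late),
per-gene uniform mutation (gene resampled ~ U[0,1] at rate 0.1), elitism 1.

*TLBPSGA*: a random population (default 100) is first refined by one TLBO
pass and truncated to the fittest 50. Teacher phase:
`x′ = x + r⊙(x_teacher − TF·x̄)` with r ~ U(0,1) per gene,
TF = round(1 + U(0,1)) ∈ {1, 2}, and x̄ the population mean per gene;
updates accepted on improvement, and a learner surpassing the teacher
becomes the teacher. Learner phase: each learner pairs with a random other
and moves toward it if fitter, away otherwise, again greedily accepted.
Genes are clipped to [0, 1] after every move. Parents are then drawn by
tournament selection (k = 3), and one further TLBO pass re-refines the
population each generation (disable with `refine_each_generation=False`).
Early stop after 25 generations without improvement.

Convergence speed between optimizers is compared by the **first hitting
time of a common fitness level** (`first_hitting_generation`): on a
continuous landscape an elitist optimizer keeps improving its best by float
epsilon, so "generation where the final best value was attained" measures
polishing rather than convergence. `GAResult.first_attained` (exact
attainment of the final best) remains meaningful for discrete fitness such
as CV accuracy. On the 7-D sphere benchmark (pop 30, 100 generations)
TLBPSGA typically hits the 0.99 level in generations 2–5 versus 10–42 for
the classical GA on the same seeds.

## Synthetic data generator

Each specimen is a bright ellipse (intensity 180 on background 30) on a
160×90 canvas: axis ratio ~ N(2.30, 0.08) for males vs N(2.10, 0.08) for
females with ±4° rotation jitter, modulated by a sinusoidal surface texture
(6.0 vs 4.5 cycles across the minor axis, amplitude 0.25, random phase),
plus N(0, 8) pixel noise. Weights are N(1.10, 0.20) g for males vs
N(1.16, 0.20) g for females — effect size d = 0.3, so the Bayes-optimal
single-threshold accuracy is Φ(d/2) ≈ 0.56 and weight alone is a weak
classifier by construction. Presets `fc1` (837 ♂ / 742 ♀) and `fc2`
(832 ♂ / 837 ♀) mirror the composition of the two foundation-cross rearing
batches the method targets. Everything derives from one seed; the dataset
is a pure function of its spec.

What the generator does **not** emulate: real cocoon photography
(illumination gradients, background clutter, segmentation error, intra-class
shape diversity beyond one ellipse family), load-cell measurement noise, or
the true image statistics of the rearing batches. Passing tests therefore
demonstrate that the pipeline recovers class structure of the kind it
assumes (orientation/texture differences invisible to any single pixel
statistic), not that the synthetic accuracies transfer to real cocoons; the
synthetic difficulty is a free parameter.

## Problem sizes and numerical choices

The end-to-end evaluation (tests and the acceptance script) runs the
fc1-preset batch (n = 1579) with 10-fold CV and the default XGBoost model,
without the RFE stage: elimination over 106 features costs ~10⁵ boosted
fits under full cross-validation, while the compress-fuse-classify stack
already demonstrates the image-vs-weight contrast. RFE is exercised on a
10-feature planted-signal problem (3 informative + 7 noise, n = 400) and is
available in the pipeline config and CLI for full runs. Optimizer
benchmarks use the 7-D sphere with population 30 and 100 generations over
10 paired seeds. FFT/spatial equivalence is checked on 50 seeded random
images at 1e−6 per element (measured ~2e−16).

## Known limitations

- Real-image validation is impossible here; absolute synthetic accuracies
  overstate what any method achieves on photographs.
- Hard orientation binning and plain-L2 normalization are simpler than the
  descriptor variants common in pedestrian detection; swapping them in
  would change feature values but not the architecture.
- The MI estimator's [0, 1]-bit range holds for binary targets only.
- TLBPSGA's extra TLBO evaluations make its per-generation cost roughly 3×
  the classical GA's; comparisons by generation index favour it, comparisons
  by evaluation count are closer.
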