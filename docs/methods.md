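# Methods

## Model

A point-wise linear (PWL) model classifies a feature vector x ∈ R^D with a
sample-specific linear model y = σ(ξ(x)·x). In the reallocation form,
ξ(x) ≡ w ⊙ η(x): a neural network η produces a per-sample rescaling of the
features and a single universal weight vector w (one row per class) does
the separating. The equivalent view y = σ(w·ρ), ρ = η(x) ⊙ x, shows η as a
learned change of coordinates after which the problem is linear. The
constraint that η has depth ≥ 2 layers is structural: a one-layer η makes
ξ affine in x and the model loses the ability to represent nonlinear
decision boundaries, so the spec object rejects depth 1 at construction.

Multiclass models share one η across classes and give each class its own
universal weight row, with a softmax over the class scores ξ_c·x; with two
classes a single row and a sigmoid head is used (the two heads produce the
same sample ranking, which is tested). An intercept is carried by
augmenting x with a constant 1 feature so that ξ contains a point-wise
intercept; `intercept=False` gives the strict equation form used for the
2-D toy replications.

The `straightforward` variant removes w and lets the network emit ξ(x)
directly. It is retained as the baseline the reallocation form improves
on. In this implementation, with an ordinary Glorot-initialised head and
identical training, the straightforward variant matches the reallocated
one on easy 2-D problems at most seeds and trails it slightly at the
package defaults; its characteristic failure (collapsing to chance-level
fits under weight decay or unlucky initialisation) appears only
sporadically. We therefore treat "reallocation generalises better" as a
tendency, not a theorem, and the test suite asserts only the ordering at
the fixed default configuration.

### Network topologies

* `unified` (default): every hidden block receives the raw input through a
  direct connection, and every block contributes additively to the output
  layer, so the shortest input-output path is two hops at any depth. In
  our experiments deep plain MLPs (depth ≳ 10, tanh) stall at chance level
  on the two-circles problem while the unified topology trains at depth 17
  without difficulty — this is the practical reason for the default.
* `plain`: a standard MLP, kept as a control.

The η output layer is linear (unbounded): η must be able to equal 1 (the
logistic-regression reduction) and to flip feature signs. In reallocated
mode the output layer is initialised to produce η ≡ 1 exactly (zero output
weights, unit bias), so training starts from an ordinary logistic
regression in w and departs from it smoothly. This initialisation is also
what the exact-reduction test exploits.

### Training

Full-batch cross-entropy minimised with Adam; hand-written backprop in
float64 numpy. Defaults: depth 3, width 16, tanh, 400 epochs, learning
rate 0.05, weight decay 1e-4 on weight matrices (never on biases), seed 0.
Full-batch training plus a fixed seed makes fitted parameters
bit-reproducible on a given machine. Training aborts with a diagnostic on
a non-finite loss rather than continuing from a poisoned state. These
defaults were chosen for the hundreds-of-samples regime the package
targets; the double-CV harness searches over depth, width, learning rate
and weight decay anyway, which is where the defaults matter least.

## Importance scores

Sample-wise score: s_k(n) = ξ_k(n) x_k(n) − mean_{i ∈ U(n)} ξ_k(i) x_k(i),
the sample's k-th contribution relative to its weight-space neighbourhood.
U(n) contains every sample i with ‖ξ(i) − ξ(n)‖ / ‖ξ(n)‖ ≤ 4‖σ‖/‖ξ̄‖,
where σ and ξ̄ are the element-wise standard deviation and mean of ξ over
samples. Conventions chosen here (the defining rule leaves them open):
Euclidean norms throughout; the comparison is ≤; the anchor is always a
member, so U is never empty. A zero-norm ξ̄ with non-zero σ makes the
threshold +∞ (all samples), which is logged. Note the threshold is a
multiple of a coefficient-of-variation-like ratio and is quite inclusive:
for two equal-size tight clusters of ξ rows it can be shown that mutual
exclusion of the clusters requires p(1−p) < 1/16 for the cluster-size
fractions, so small-sample "each U = its own cluster" configurations do
not exist; neighbourhoods should be read as soft locality, not clustering.

In multiclass models the target class's ξ_c block enters the score; the
intercept column is excluded (it corresponds to no gene). For sigmoid-head
binary models the single ξ block scores the second class and its negation
scores the first.

Group score v: each member votes for its ceil(0.1·D) highest-s features
(signed s, not |s|; ties broken by ascending feature index) and v_k is the
vote rate, so Σ_k v_k equals the per-sample vote count exactly. Relative
score v_rel = v_target² − v_others² ∈ [−1, 1], computed one-vs-rest per
class; ranking ties are broken by feature name for determinism.

## Deep enrichment analysis

Steps: (1) extract η (or ρ) per sample, intercept column dropped; (2)
UMAP to 1-D (defaults n_neighbors 15, min_dist 0.1, fixed seed — chosen as
the method's standard defaults, with determinism required for testing);
(3) Spearman correlation (average-rank ties) between the axis and each
gene's expression, then keep the top n_pos positively and n_neg negatively
correlated genes (defaults 250/250). A 1-D embedding is only defined up to
orientation, so the two-tailed selection makes the result flip-invariant
and individual correlation signs are not interpretable. Genes with
correlation exactly 0, and constant genes (flagged, recorded as 0), are
never selected. (4) Right-tailed Fisher exact test of the selection
against each set of a GMT collection: p = hypergeometric upper tail
P[overlap ≥ k] with the universe defaulting to the expression matrix's
genes. Raw p (reported as −log10 p) is primary; a Benjamini–Hochberg
column is included for convenience.

On reduced universes the 250/250 selection must be scaled down or it
swallows every gene (at D = 300 it selects the whole universe and all
p-values are 1); the planted-pathway recovery test uses 40/40 on a
300-gene universe, the same ~13%-per-tail fraction at which the pipeline
is discriminative.

## Evaluation harness

Double cross-validation: K outer stratified folds; inside each outer
training split, L_trials hyperparameter proposals are each scored by
M-fold stratified CV using the fold-then-class mean of one-vs-rest
per-class AUCs (rank-statistic AUC, ties counted ½; classes missing a
positive or negative in a fold are excluded from the average with a
warning). The winning proposal is refit on the full outer training split
and scored on the held-out fold. Inner loops perform exactly K·L·M
training runs (audited); refits are not part of that count. Stratification
is necessary because realistic subtype cohorts have classes too small to
populate unstratified folds.

Samplers: seeded random search, and a TPE-style sequential sampler (after
a 10-trial startup, trials are split at the γ = 0.25 quantile and the
candidate maximising the per-dimension good/bad density ratio among 24
random candidates is proposed). Both satisfy the same contract — L
sequential proposals maximising the inner objective — and both are exactly
reproducible from the run seed.

Model comparison uses Tukey's honest significance test on per-fold AUCs
(statsmodels implementation) at FWER 0.05. All-constant groups are
rejected as degenerate rather than reporting an infinite statistic.

## Synthetic data

* Two circles: points on radii 1 and `radius_ratio` (default 0.8) with
  isotropic Gaussian noise (default sd 0.05, n 500). At these defaults the
  rings overlap slightly, so test accuracy is informative; a logistic
  regression scores ≈ 0.5 and a reallocated PWL ≈ 0.98.
* XOR: uniform points in [−1,1]², class = XOR of coordinate signs —
  the canonical linearly-unsolvable problem.
* Subtype simulator: N samples in C imbalanced classes, D genes.
  Expression mode emits per-gene mean-centred Gaussians with an additive
  `effect_size` shift on each class's planted informative genes;
  copy-number mode emits integers in {−2..2} from a diploid-heavy
  multinomial, tilted toward amplification on informative genes in their
  class; paired mode adds an expression matrix with a planted pathway
  whose expression follows a class-ordered latent. A `nonlinear_xor`
  switch labels samples by the XOR of two genes' signs to exercise the
  regime where PWL beats any linear model. The `BRCA_SHAPE` preset
  reproduces the 22/406/185/131/66 five-class imbalance of the breast
  cancer cohort this family of methods was developed on.

What the simulator does *not* emulate: realistic gene–gene correlation
beyond the planted blocks, batch effects, dropout or count noise. Passing
recovery tests therefore show the pipeline is sound end to end, not that
it will rank genes correctly under real cohort covariance.

## Problem sizes and numerical choices

Tests run the toys at n = 500/2000, the recovery studies at N = 200,
D = 300 with 10 planted genes per class and a 40-gene pathway against 10
decoy sets, and the DCV audit with a no-op trainer at K = M = 10,
L = 100. Conservation (ξ·x = w·ρ) holds to 1e−6 relative by construction
and is asserted; the logistic reduction to 1e−9; Fisher/Spearman/AUC
primitives match brute-force oracles to 1e−12. TSV writes use shortest
round-tripping float representations and reads use numpy's correctly
rounded parser, so matrix round-trips are bit-exact.

## Known limitations

* η importance explains predictions through ξ but not the corrections η
  itself; the relative score cannot attribute *why* a reallocation was
  chosen.
* The neighbourhood threshold is global and inclusive (see above); on
  well-separated ξ clusters neighbourhoods will usually still span
  clusters.
* The straightforward-vs-reallocated gap on easy 2-D toys is small in this
  implementation (see Model).
* UMAP determinism is per-platform: fixed seeds reproduce bit-identically
  on one machine but not necessarily across BLAS/numba versions.
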