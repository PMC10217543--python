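# Methods

## Swarm model

The optimizer is a grasshopper swarm in a box $[lb, ub]^D$. The pairwise
social force is $S(r) = f e^{-r/l} - e^{-r}$ with defaults $f = 0.5$,
$l = 1.5$; under these, $S$ is negative (repulsive) on $(0, 3\ln 2)$,
zero at the comfort distance $3\ln 2 \approx 2.079$, positive
(attractive) beyond it, peaks at $3\ln 3 \approx 3.296$ with value
$1/54$, and decays to zero — by $r = 15$, $|S| < 10^{-3}$. Because the
force is numerically dead at the raw distances typical of wide boxes,
the swarm's pairwise Euclidean distances are affinely rescaled onto
$[1, 4]$ every iteration before evaluating $S$; when all pairwise
distances coincide the midpoint 2.5 is used. The rescaling uses the
full Euclidean distance, not per-coordinate gaps: the saturation
argument that motivates the mapping applies to the distance at which
the force is felt, and the per-coordinate direction is carried by the
unit vector $(x_j - x_i)/d_{ij}$.

The per-dimension update is target-anchored:

$$x_i^d \leftarrow c \sum_{j \ne i} c \frac{ub_d - lb_d}{2}
  S(m(d_{ij})) \frac{x_j^d - x_i^d}{d_{ij}} + \hat T_d,$$

followed by clamping to the box and re-evaluation; the target
$\hat T$ is the best position ever evaluated and its fitness is
non-increasing by construction. Gravity and wind terms that appear in
the general swarm equation are absent from this production update — the
final dynamics are purely social force plus target anchor — so no
gravity/wind constants appear in the configuration.

The comfort coefficient decays linearly,
$c(t) = (1 - t/L)\,c_{\max} + (t/L)\,c_{\min}$ for $t = 0 \dots L$
(computed as a convex combination so both endpoints are exact in
floating point), with $c_{\max} = 1$, $c_{\min} = 10^{-5}$. Since $c$
multiplies the social sum twice, the late-stage swarm sits essentially
on the target: the dynamics have no per-agent position memory (the
previous positions enter only through the social term), so the swarm
contracts to the target's neighborhood within the first iteration and
refines locally from there. On smooth objectives this is an effective
exploitation scheme (the sphere function on $D = 5$ reaches $10^{-5}$
within the default budget); on discrete, binarized landscapes it means
exploration is front-loaded — a run on a $D$-feature selection problem
typically visits a few dozen distinct masks, concentrated near the
early targets. Tests and fixtures are designed with this in mind (see
below).

Degenerate cases: a single-agent swarm copies the target exactly (empty
social sum); coincident agents (distance below `epsilon_distance`,
default $10^{-12}$) interact along a seeded random unit direction
instead of dividing by zero; a non-finite objective value aborts the
run naming the offending position. One `numpy` Generator seeded from
the config drives initialization and tie-breaks, consumed in that
fixed order, so a seed fully determines the trajectory.

## Wrapper feature selection

Selection runs GOA in the unit box, one dimension per feature. A
position becomes a mask by thresholding at 0.5 (boundary counts as
selected); an all-zero mask is repaired by keeping the largest
component, so masks are never empty and the repair does not bias
toward large subsets. A fixed threshold was preferred over
sigmoid/V-shaped transfer functions as the simplest defensible rule;
the transfer function is an extension point.

The objective is
$\alpha\,\mathrm{err}_{CV} + (1-\alpha)\,|b|/D$ with $\alpha = 0.99$:
the two terms are exactly the two stated drivers of the selection —
classification error and dimensionality — and with $\alpha = 0.99$ the
error dominates while the size term breaks ties toward smaller
subsets. $\mathrm{err}_{CV}$ is the pooled held-out error of a
stratified, seed-shuffled 5-fold cross-validation with the chosen
classifier (RBF-kernel SVM or a default-depth decision tree, library
defaults otherwise). k-fold was chosen over a single holdout to
de-noise the fitness landscape. Fitness values are cached per mask
within a run: the position-to-mask map is many-to-one and the late
swarm revisits the same masks, so caching removes redundant CV fits
without changing any value.

Note a structural consequence of $\alpha = 0.99$ worth knowing when
interpreting results: one extra feature costs $(1-\alpha)/D$ in
fitness, so a subset of the planted columns whose residual error is
below that cost can legitimately beat the full planted set. At class
separations large enough that a single column classifies almost
perfectly (e.g. $\delta = 6$, where one column's Bayes error is
$\Phi(-3) \approx 0.0013 < 1/600$ for $D = 6$), the planted pair is
*not* the fitness minimizer; the ground-truth-optimality check
therefore runs at $\delta = 5$, inside the window where the planted
subset is the analytic optimum.

## Classification metrics

The confusion matrix is tallied with a declared positive class
(cancerous by default, matching the `colon_aca` folder). The panel is
computed on the percentage scale: accuracy $(TP+TN)/\text{total}$,
sensitivity $TP/(TP+FN)$, precision $TP/(TP+FP)$, specificity
$TN/(TN+FP)$, and F1 as the harmonic mean of sensitivity and precision
(equal to $2TP/(2TP+FP+FN)$, an identity the tests assert on random
matrices alongside a cross-check against scikit-learn). A zero
denominator raises an error naming the metric — silent sentinel values
would corrupt comparative tables. Final evaluation pools the held-out
predictions of a stratified 5-fold CV into a single integer confusion
matrix whose counts sum to the table's row count.

## Synthetic generator

The generator draws two balanced classes from class-conditional
Gaussians: $k$ informative columns with class means $\pm\delta/2$ (in
noise-SD units) and $D - k$ columns of class-independent noise; rows
and column placement are shuffled with the seed, and the planted
columns are recorded as ground truth. Defaults ($n = 100$/class,
$D = 20$, $k = 5$, $\delta = 2$, noise SD 1) make selection nontrivial:
a single informative column misclassifies $\approx \Phi(-1) \approx
16\%$, so good accuracy requires combining several planted columns.
What the generator does **not** emulate: the covariance structure,
heavy tails, and redundancy of real CNN deep features, or any property
of actual histopathology images. Passing tests demonstrate that the
machinery — optimizer, wrapper, metrics, I/O — behaves correctly under
a known ground truth; they transfer no claim about accuracy on real
slide images.

## Problem sizes and numerical choices

The statistical tests use sizes at which each check has adequate power
while staying cheap: the exhaustive-oracle comparison uses $D = 6$
(63 non-empty masks) with $n = 100$/class and $\delta = 1$ — moderate
overlap keeps several subsets within a few percent of the optimum, so
the 5%-relative comparison measures convergence of the search rather
than exact-hit luck (the CV-error quantum $1/200$ is finer than the
band); at $D = 8$ and beyond, the front-loaded exploration noted above
makes oracle-level agreement seed-dependent, and the package makes no
oracle-equivalence claim there. Planted-recovery checks aggregate
several seeded runs and test against the exact convolved
hypergeometric null of uniform random masks. Mean-separation contracts
use $4\times$ standard-error bounds at $n = 500$/class, where the
two-sample $t$-test at $\alpha = 10^{-3}$ has power $\approx 1$.

Other numerics: GOA bounds for selection are always the unit box;
distances use the Euclidean norm; clamping is plain box projection;
the best-so-far trace has length $L + 1$ (initial population
included). Determinism is end-to-end: one integer seed fixes the
generator, the swarm trajectory, the CV folds, and the classifiers.

## Known limitations

- The target-anchored dynamics explore weakly on binary landscapes;
  for large $D$ the selected mask is a good local refinement of the
  best initial masks, not a global search. Restarts over seeds are the
  practical remedy and are what the multi-run checks measure.
- $\alpha$, the binarization threshold, and the classifier
  hyperparameters are exposed but not tuned; results on real feature
  tables are sensitive to them.
- The real-backbone extraction path is declared but requires a
  user-supplied inference runtime and pretrained weights; only the
  stub extractor is exercised by tests.
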