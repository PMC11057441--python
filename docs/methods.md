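# Methods

## Data model and labels

A cohort is one row per subject-visit with numeric feature columns, each
tagged with a modality (`CFA`, `IMG`, `MH_DEM`, `BLO_ApoE`, `other`), and a
Clinical Dementia Rating column. Labels derive from CDR: 0 → HC, 0.5 → MCI,
and 1/2/3 merged into AD (severe ratings are too rare to stand alone).
Rows with any missing value among the selected columns are dropped and
logged (complete-case rule — no imputation); repeat visits are independent
rows. Min-max normalization maps each feature's *training-split* min/max to
[0, 1]; new data are clipped into [0, 1] and constant features map to 0.
Fitting the normalizer on the training split only is a deliberate
leakage-safety choice: normalizing the pooled data before splitting would
leak test-set ranges into training.

## One-class detectors

All four detectors expose `fit(X_hc)`, `score_samples(X)` (higher = more
anomalous) and a threshold `t`; `classify` returns outside ⇔ score > t
(a score exactly at the threshold is accepted).

**KNN.** score(x) = ‖x − NN_k(x)‖ / ‖NN_k(x) − NN_k(NN_k(x))‖ with NN_k(p)
the *single* k-th nearest training point (Euclidean); a training point
excludes itself from its own neighbor list, so a query coinciding with a
training point measures its distance to the nearest *other* point. A zero
denominator yields +∞ when the numerator is positive, else 0. The native
threshold 1 reproduces the classical acceptance rule "accept iff the
query's k-NN distance does not exceed its neighbor's own k-NN distance".

**MoG.** Gaussian mixture Σⱼ aⱼ N(x; μⱼ, Σⱼ) with Σaⱼ = 1 and full
covariances, fitted by EM (scikit-learn backend, max 500 iterations,
tolerance 1e-7 on the per-sample lower-bound change — an absolute rather
than relative stopping rule, the one the backend provides). Covariances
carry a ridge of 1e-6·trace(cov)/d on the diagonal for conditioning.
score = −log density. Non-convergence returns the best iterate with a
warning.

**KMEANS.** Lloyd's algorithm from k-means++ starts, best of 10 restarts
(scikit-learn backend, which also re-seeds empty clusters); score =
distance to the nearest centroid.

**SVDD.** The one-class dual max Σᵢ aᵢK(xᵢ,xᵢ) − Σᵢⱼ aᵢaⱼK(xᵢ,xⱼ) subject
to Σa = 1, 0 ≤ aᵢ ≤ C is solved by a maximal-violating-pair SMO iteration
(in `_qp.py`; O(n) per step with an incrementally maintained gradient,
KKT gap tolerance 1e-8). Kernel: K(x,y) = exp(−‖x−y‖²/σ²). R² uses the
radius formula evaluated at unbounded support vectors (1e-7 < aᵢ < C−1e-7),
averaged over them for numerical stability; with none (e.g. a single
training point at C = 1) the maximal-multiplier point is used with a
warning. score(x) = ‖φ(x) − center‖² − R², so the native threshold is 0.
C defaults to 1 (no rejection pressure from the box constraint); the
kernel-width grid is expressed as base-10 exponents g ∈ [−1.5, 1.5]
(σ = 10^g), since a raw negative width is meaningless; a flag restores the
raw-width reading.

**Calibration.** For every method alike, the threshold is set to the
empirical (1 − θ) quantile (linear interpolation) of the training scores,
θ being the target false rejection rate (default 0.1). This places a θ
fraction (within 1/n) of training HC outside the boundary and makes the
operating point comparable across methods; SVDD's C stays a hyperparameter
rather than a second rejection dial.

## Decision boundary and DtB

The boundary is the level set {x : s(x) = t}. It is approximated by a
point cloud: from an interior anchor (default the training-data medoid;
it must score strictly below t), m quasi-uniform random directions are
drawn (default m = 2048) and bisection root-finds the threshold crossing
along each ray within [0, s_max] (default 10× the training-data radius).
Rays that never cross within s_max are dropped and logged; fewer than m/2
survivors is an error — the boundary is not closed enough around the
anchor. Points must satisfy |s(y) − t| ≤ tol (default 1e-6; a looser
tolerance is appropriate for the KNN score, whose denominator jumps).
Outward unit normals are normalized central-difference score gradients
(step 1e-4 per normalized-unit axis; 0.05 for KNN, where the coarser step
doubles as smoothing over the score's facets). Disconnected components —
which the KNN score produces naturally — are handled for free by the
point cloud.

DtB(x): find the nearest boundary point y\* (ties broken by lowest index)
and take the sign of the dot product between the outward normal at y\* and
x − y\*: negative dot → inside → DtB = −‖x − y\*‖, else +‖x − y\*‖. A zero
dot product defers to the score rule s(x) > t; a subject exactly on a
boundary point has DtB = 0, inside. The sign test is local, so a subject
is judged against the boundary component nearest to it.

## Severity scale

Reference DtB values of labelled subjects define cut points by quartiles
(same linear-interpolation rule as threshold calibration): Q1/Q3 of HC,
Q1 of AD, and an upper anchor Q3_AD + 1.5·IQR_AD (the boxplot outlier
fence). Bands on the DtB axis: below Q1_AD reads HC-like, [Q1_AD, Q3_HC)
is the MCI band — flagged as overlapping the HC range, which is exactly
the clinically ambiguous region — and [Q3_HC, upper] reads AD-like. When
the reference classes separate cleanly (Q3_HC < Q1_AD) the MCI band is
empty and the scale degenerates to a two-band rule. Severity 0–10 is the
affine map of [min cut, upper] clipped at both ends. The band definition
resolves an internal inconsistency in the usual verbal description of
this scale (an HC band stated as starting at 0 although HC DtB values are
negative by construction); we keep the quartile cut points and drop the
spurious 0 lower bound.

## Feature selection

Features are ranked against the class label by three filters on
min-max-normalized data: information gain ratio (base-2 entropies on
10-bin equal-frequency discretizations; a constant feature scores 0),
absolute Pearson correlation against the numeric CDR encoding
(HC = 0, MCI = 0.5, AD = 1; zero variance scores 0), and the Pearson
chi-square statistic of the discretized-feature × class table
(zero-expected cells contribute 0). Equal-frequency discretization is
positional after a stable sort — ties resolve by value order then index —
and is robust to the skewed marginals typical of clinical measurements.

The three rankings are aggregated by a Cross-Entropy Monte Carlo search
for the ordered top-K list (K = 10) minimizing the mean weighted Spearman
footrule distance to the inputs: Σ_items w_L(i)·|rank_δ(i) − rank_L(i)|,
ranks truncated at K+1, weights the min-max-normalized filter scores.
The search keeps an item×position probability matrix, samples 10·|universe|
candidate lists per iteration, retains the best ρ = 0.1 fraction, and
updates the matrix by convex combination with weight w = 0.25, stopping
after 15 iterations without improvement (these are the reference defaults
of the cited aggregation algorithm; the underlying study states none).
Exhaustive enumeration verifies optimality on small universes in the test
suite.

## Nested cross-validation

Outer loop: 5 stratified folds over all subjects; each development set is
80% of every class. Inner loop: 5 folds over the development HC only —
train on 4/5 of them, validate on the held-out fifth plus *all*
development non-HC, score by rank-based AUC (the pipeline's headline
metric; the protocol itself is metric-agnostic), and pick the grid value
with the best mean inner AUC (first best on ties). The model is then refit
on all development HC, calibrated at θ, and evaluated on the untouched
outer fold: specificity (HC inside), sensitivity per impaired class
(MCI, AD outside), and AUC pooling MCI ∪ AD as positive. Aggregates are
mean ± 1.96·sd/√5, clipped to [0, 1] (a normal approximation over folds).
Non-HC rows never enter training; normalization and optional feature
selection are fitted inside each development set. AUC is computed by
sweeping the score threshold (not by retraining per θ).

## Synthetic cohort — what it does and does not establish

The generator emulates: informative CFA-like features in which HC follow
a 2-component Gaussian mixture (component centers ±1 along an axis
orthogonal to the class-shift direction — echoing healthy-population
heterogeneity), MCI shifted Δ = 1.5 and AD 2Δ standard deviations along a
single fixed direction with equal covariance (so the HC/MCI overlap and
the HC < MCI < AD ordering hold by construction), 29 class-independent
uniform noise features, class imbalance 600/260/160, and CDR 0/0.5/1 by
class. Informative features are affinely rescaled to bounded-instrument
ranges so normalization is exercised.

It does **not** reproduce real-cohort marginals, feature correlations,
discrete/ordinal codings (ApoE, medical-history flags), or longitudinal
visit structure. A green test therefore establishes that the machinery —
scores, calibration, boundary geometry, CV hygiene, selection — behaves
as specified on a world with known ground truth; it does not certify
clinical performance levels.

## Numerical choices and edge cases

* Quantiles/quartiles: linear interpolation throughout.
* Boundary bisection: 200 iterations max, stopping on interval collapse
  (4 eps·s_max); the score tolerance is verified at the final midpoints.
* A vanishing score gradient at a boundary point falls back to the ray
  direction for the normal.
* KNN ties between equidistant neighbors follow the stable neighbor-search
  order; with continuous features these are measure-zero.
* EM and k-means are seeded and bit-reproducible; the CE aggregation and
  boundary direction sampling take explicit seeds.
* Degenerate severity references (all DtB equal, or upper ≤ lower cut)
  raise rather than emit a meaningless scale.

## Known limitations

* The boundary point cloud measures distance to sampled boundary points,
  not to the exact level set; the error decays with m (≤ 0.01 at m = 4096
  on the analytic circle fixture) but grows with dimension.
* One-class scores are not likelihood ratios; even at large class
  separations the pooled AUC saturates below the Bayes-optimal
  two-class value (on the default 4-informative-feature world with a 3-sd
  shift, the ideal density score caps near 0.95).
* The SMO solver is dense (O(n²) kernel storage), adequate to a few
  thousand training subjects.
* No missing-data handling beyond complete-case dropping; no wrapper
  (subset-search) feature selection.
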