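# Methods

## Scope and data model

fcnetopo analyzes *parcellated* resting-state BOLD signals: each subject is a
node × time matrix where nodes are atlas regions (the default emulates a
384-region functional parcellation sampled at TR = 2 s for 180 volumes).
Spatial preprocessing (realignment, normalization, segmentation, atlas
projection) is out of scope; the package begins where a node × time matrix
exists, or accepts precomputed connectivity matrices directly.

## Synthetic cohort generator

The generator emulates a three-group clinical cohort — 10 well-controlled
(WC) and 23 drug-resistant (DR) patients with idiopathic generalized
epilepsy, plus 34 controls — without modelling hemodynamics. Each group has
a block-modular population correlation matrix: `n_modules` (default 8)
contiguous modules with within-module correlation `base_within_r` (default
0.35), between-module correlation ±`base_between_r` (default 0.10, a fixed
20% of module pairs negative to exercise the signed-edge machinery). Group
effects are additive shifts to within-module correlation
(`group_connectivity_shift`, default +0.08 for both patient groups, 0 for
controls), chosen once as a moderate global-connectivity elevation in the
direction the pipeline is designed to detect; no empirical effect size at
the connectivity level was available to calibrate against, so this is a free
parameter of the simulation, not an estimate. Subject time series are
zero-mean multivariate Gaussian draws from the group matrix. Gaussian
sampling (rather than an autoregressive or band-limited process) is
deliberate: every downstream quantity is a function of Pearson correlations,
which Gaussian sampling controls exactly; the band-pass stage can still be
exercised because confounds inject structured low/high-frequency content.

Shared confound signals (a linear drift plus slow sinusoids, unit SD) are
added with node loadings centred on +1 (SD 0.5), so contamination inflates
mean pairwise correlation the way global physiological noise does; the
amplitude is expressed in multiples of each node's signal SD (default 1.0).
The exact regressor matrix is returned, which makes the
regression round trip (clean → contaminated → residualized) a strong oracle.

Block-constant correlation matrices with negative blocks can be indefinite;
the generator repairs them by eigenvalue flooring at 1e-6 followed by
re-normalization to unit diagonal, and logs every repair. All randomness
flows from one master seed; subject *i* uses `seed + i + 1`.

What the generator does **not** emulate: hemodynamic autocorrelation,
scanner drift physics, spatially correlated noise, subject-level variation
in connectivity structure within a group (all subjects of a group share one
population matrix). Passing tests therefore demonstrate the pipeline's
correctness and calibration under controlled correlation structure, not
performance on real fMRI.

## Preprocessing

Order is fixed: confound regression first, then band-pass (the two do not
commute; the chosen order keeps filtered series from re-acquiring confound
structure, and integration tests assert it). Confound regression is OLS with
an always-appended intercept — correlation is translation invariant, so the
intercept is harmless and numerically safer; residuals are exactly
orthogonal to every retained regressor, and rank-deficient confound sets are
reduced with a warning. CompCor-style extraction takes the top principal
component time courses of demeaned, variance-normalized noise-region
signals, with a deterministic sign convention (largest-magnitude loading
positive). The band-pass is a 4th-order Butterworth applied forward and
backward (zero phase, so inter-regional correlation structure is not
distorted); even-extension padding keeps edge transients from leaking
stop-band power at 180-sample lengths. Motion QC summarizes translations as
the mean per-volume displacement magnitude in mm, and excludes subjects when
any axis exceeds 3 mm translation or 1° rotation — strict inequalities, so a
volume exactly at the limit is kept.

## Connectivity and thresholding

Edges are Fisher-transformed Pearson correlations (|r| clamped to 1 − 1e-7
before atanh; diagonal stored as 0 and excluded everywhere). The edge
estimator is plain Pearson correlation on the preprocessed series — the
uniform-weight special case of a weighted linear model; no per-observation
weighting scheme is applied. Thresholding excludes the open interval
(−τ, +τ) on the **Fisher-z** scale (atanh(0.25) = 0.2554, so at the default
τ = 0.25 this is nearly indistinguishable from thresholding r; the grid
{0, 0.125, 0.25, 0.375} supports sensitivity analysis). Ties at the boundary
are excluded — measure-zero on real data, but tested. `positive_only` keeps
positive weights as-is; `absolute` rectifies first. Isolated nodes are
retained so nodal vectors always have length n.

## Graph metrics

* Strength: row sums of the weight matrix.
* Clustering: Onnela geometric-mean form, weights normalized by the graph
  maximum; degree < 2 scores 0; the average runs over all n nodes. This is
  the default weighted clustering coefficient of the standard
  brain-connectivity toolboxes; a Barrat variant is available behind a flag.
* Distances: edge length 1/w, all-pairs Dijkstra. The alternative −log(w)
  map sits behind a flag. Characteristic path length averages *finite*
  unordered-pair distances and reports the disconnected-pair count
  separately rather than propagating infinity — at τ = 0.375 fragmentation
  is common and a finite, comparable L is required.
* Betweenness: Brandes on 1/w distances, fractional counting over tied
  shortest paths, each unordered pair once. Raw values are used for
  within-study contrasts (group comparisons are scale invariant); the
  normalized variant (÷ (n−1)(n−2)/2) is always emitted alongside.
* Hubs: strength and betweenness both above mean + 1 sample SD within the
  subject's own network (conjunction, strict inequality; a zero-variance
  metric yields no hubs).

Every metric is cross-checked in the test suite against independent
brute-force implementations (Floyd–Warshall triple loop, exhaustive
simple-path enumeration, direct triangle sums) to 1e-9 on hundreds of random
small graphs.

## Surrogate normalization

The null model is Maslov–Sneppen degree-preserving double-edge rewiring
(10 attempted swaps per edge by default; insensitivity to doubling is
tested at < 2%), followed by random reassignment of the original weight
multiset to the rewired topology. Degree sequence and weight multiset are
preserved exactly. Normalized clustering and path length divide by surrogate
means over `n_surrogates` draws (default 500; benchmark tests use 100, where
the Monte-Carlo error on the small-world index is below 5%). Disconnected
surrogate pairs use the same finite-pairs exclusion as the empirical graph.
Swap-rigid graphs (e.g. complete graphs) fall back to a weight-shuffled copy
with a warning, which makes the complete-graph small-world index exactly 1.
An Erdős–Rényi same-density null is available behind a flag.

## Statistics

Three-group omnibus comparisons use Kruskal–Wallis, or a Type-II ANCOVA F on
the group factor with age as covariate when every group passes a Lilliefors
normality screen at α = 0.05. Pairwise contrasts are two-sided Mann–Whitney
(exact when min(n) ≤ 8 without ties, tie/continuity-corrected normal
approximation otherwise), Bonferroni-corrected by a factor of six (the
number of pairwise comparisons across grouping schemes). The combined
patients-vs-controls contrast is the t statistic on the group coefficient in
`metric ~ group + age` — an age-controlled t-test. The epilepsy-duration
covariate is undefined for controls and therefore enters patient-only
contrasts only. Mass-univariate nodal tests are per-node Mann–Whitney with
Benjamini–Hochberg FDR at q = 0.1 per metric family; nodes significant
before correction are reported with direction and rank-biserial effect size
(2U/(n₁n₂) − 1), the appropriate exploratory fallback when nothing survives
FDR at n ≈ 30 per group. Hub-set sizes are compared by Kruskal–Wallis
(three-group) and Mann–Whitney (combined). Demographics: per-group medians,
percent female, medication count mean/range, Kruskal–Wallis on age, Pearson
chi-square (no continuity correction) on sex.

## Pipeline and reproducibility

`run_pipeline` quarantines per-subject failures (reported, not fatal) and
aborts only when a group drops below 2 subjects. Surrogate seeds are derived
per (subject, sign mode, τ) via CRC-32 of the cell tag, so reruns with the
same master seed are bit-identical — asserted on `stats.csv` bytes. The run
log records seeds, configuration, quarantines and the deviations registry.
The nodal/hub analysis is fixed to the (absolute, τ = 0.25) cell by default,
configurable.

## Problem sizes in the tests and acceptance script

Calibration experiments use 200 replicates of the 67-subject cohort at 60
nodes — enough for a binomial check of the 5% level while keeping the suite
fast; effect recovery uses 20 replicates at the full 384-node scale.
Recovery targets average node strength, which does not depend on surrogate
normalization, so those replicates skip surrogate generation; small-world
behaviour is validated separately on benchmark graphs with 100 surrogates
per graph.

## Known limitations

* Within-group subject homogeneity in the generator makes between-subject
  variance purely sampling noise; real cohorts are more variable, so the
  power measured here overstates power on real data.
* The small-world index inherits the known density sensitivity of C and L;
  comparisons across τ levels should be read with the density column in
  hand.
* Exact Mann–Whitney p-values switch to the normal approximation in the
  presence of ties, which is conservative for tiny samples with many ties.
* The Lilliefors screen at n = 10 (smallest group) has modest power; the
  omnibus test choice can flip between Kruskal–Wallis and ANCOVA near the
  decision boundary.
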