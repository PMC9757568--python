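# Methods

`eeglevels` classifies a psychoactive-substance condition from multichannel
EEG at three abstraction levels and interprets the classifiers with
Shapley-value attributions.  This note documents the models, conventions and
design choices; everything quantitative it mentions is computed by the test
suite or by `scripts/acceptance.py`.

## The three abstraction levels

A recording session runs from 25 minutes before substance ingestion to 200
minutes after it (t = 0 at ingestion).  It is cut into three half-open
windows: window 1 (−25…50 min) is the control, class 0 — plasma concentration
of the active compound stays low until ~50 min — and windows 2 (50…125) and
3 (125…200) are the on-effect class 1.  From the windowed signals three
feature tables are built:

* **Level A — raw series.** Rows are timepoints, columns are channels.  An
  optional decimation stride keeps synthetic runs desk-scale (the stride is a
  plain subsampling; it discards rows, never averages).
* **Level B — connectivity.** One Pearson correlation matrix per
  subject-window over the full window; the strictly upper triangle is
  flattened row-major into n(n−1)/2 named pair features ("F3-PO4").  The
  diagonal and the symmetric duplicates carry no information and would
  dilute attribution, so they are dropped.  An optional epoching mode splits
  each window into contiguous equal sub-epochs, each yielding its own row —
  a sample-size amplifier for synthetic experiments where 48 observations
  are too few for a 1891-dimensional classifier.
* **Level C — graph measures.** Each connectivity matrix becomes a weighted
  graph and is summarized by 24 scalars: 17 standard measures plus 7
  community path-length statistics (below).

Every row of every table carries its subject id, so train/test splits can be
made leakage-safe (no subject on both sides).  Row-wise stratified splitting
is available behind a flag for protocol comparison, but subject-grouped
splitting is the default: adjacent timepoints are autocorrelated and a
subject's windows are far from independent, so row-wise splitting
overstates test performance.

## Graph conventions

* **Weights.** Edge weight is |r| by default.  Most of the measures are
  undefined for negative weights; a signed mode that simply drops negative
  correlations exists but is off by default.
* **Thresholding.** By default the graph is the complete weighted graph.  A
  proportional threshold retaining the top-d fraction of edges by |r| is
  available; several community detectors are slow or degenerate on complete
  graphs, so desk-scale configurations in this package use d = 0.1–0.3.
* **Distances.** Path-based measures use d = 1/w (strong association =
  short distance); 1 − |r| is available as an alternative.
* **Degrees.** Degree-based measures (mean degree, second-moment degree,
  degree entropy, nearest-neighbor degree, assortativity) use the weighted
  strength on unthresholded graphs and the binary degree on thresholded
  ones.  Transitivity, density and the k-core index are computed on edge
  presence in both modes: their weighted generalizations are not standard
  and the dense default would make them degenerate anyway.
* **Aggregation.** Node-level measures (betweenness, closeness, eigenvector
  centrality, hub score, eccentricity, nearest-neighbor degree) are
  aggregated by their unweighted mean over nodes, so each graph yields one
  scalar per measure.
* **Degenerate cases.** Assortativity of a perfectly regular graph (zero
  degree variance) is defined as 0.  Path measures of a disconnected graph
  are computed on the largest component, with a provenance note on the
  graph.  Eigenvector centrality is the Perron vector of the weight matrix
  (largest algebraic eigenvalue) — well-defined even for bipartite graphs,
  whose spectrum is symmetric; for undirected graphs the principal-
  eigenvector hub measure coincides with it, and both entries report the
  same value, as igraph's hub score does for undirected graphs.
* **"Complexity"** is the degree-heterogeneity index: second-moment degree
  divided by mean degree.  This definition is a package choice and is
  flagged here because the name is used loosely in the literature.

## Community path-length statistics (AFC, AIC, ALC, ALPC, AEBC, ASPC, AMC)

Each statistic runs one community-detection algorithm — fastgreedy, infomap,
leading eigenvector, label propagation, edge betweenness, spinglass,
multilevel — takes the community with the most nodes, induces its subgraph,
and returns the mean shortest-path distance over all ordered pairs inside it.
Conventions: communities are canonically relabeled by (size descending,
smallest member index ascending), so "largest" is deterministic under ties;
a single-node community yields 0 with a note; pairs made unreachable by
thresholding are excluded with a note.  Stochastic detectors are seeded and
run-to-run identical.  Spinglass requires a connected graph and falls back
to per-component detection on disconnected ones.  Edge-betweenness detection
removes edges by betweenness under the distance convention and then picks
the dendrogram cut with maximum modularity under the strength weights — the
two roles genuinely need different weight semantics.

## Classification protocol

A support-vector classifier with feature standardization (fitted on training
rows only), inverse-class-frequency weighting (the 1:2 window labeling is
imbalanced), a 25% held-out test set, and grid search over a small
logarithmic cost grid for linear and RBF kernels by mean 10-fold
cross-validated accuracy *within the training subset* (ties go to the first
grid point; the fold count is capped at the smallest class count on small
tables).  Metrics: accuracy, precision, recall and F1 for the positive
class and macro-averaged; row-normalized confusion matrices; per-class ROC
curves from decision scores with micro (pooled) and macro (unweighted mean)
AUC; learning curves over repeated seeded subsamples.  Probability
calibration is not used.

## Shapley attributions

The estimator is permutation sampling with background replacement: for each
sampled permutation a background row is drawn from a seeded subsample of the
training rows, the explained observation's features are switched on in
permutation order, and each feature accumulates its marginal change of the
decision score.  By construction the attributions of an observation sum
exactly to (its score − mean score of the sampled background rows), so the
efficiency identity holds to floating-point accuracy; symmetry and the
dummy-player property hold in expectation and are verified by tests against
exact enumeration, which is provided for up to 16 features.  Per-class
importance bars condition on the *true* label of each explained row.
Attributions default to test rows (capped at a seeded subsample), with
train/all available behind a flag.

## The synthetic cohort generator

Full-scale studies use real EEG; this package instead generates cohorts
with planted, fully known effects so each stage can be validated.

**Signal model.** Channels are linear mixtures of latent unit-variance AR(1)
sources (default autoregressive coefficient 0.8 at 100 Hz) plus white sensor
noise (default SD 0.5).  Channels are grouped into blocks (default 8) that
share a block source, giving a within-block correlation of 0.3 (observed at
the channel level; mixing coefficients pre-compensate the noise
attenuation).  Defaults: 16 subjects, the 62-channel montage, three
one-minute windows around t = 0 with classes (0, 1, 1) — the full-session
window layout scaled down so a cohort generates in about a second.

**Effects** are applied strictly at the mixing level, which guarantees the
implied channel correlation matrix is a Gram matrix (positive semi-definite
by construction; the generator still verifies it):

* *Amplitude*: a channel's whole mixing row, including its noise, is scaled
  by the gain in class-1 windows — standard deviation scales exactly,
  correlations are untouched.
* *Coupling (positive delta)*: the two target channels are detached from
  their blocks in **both** conditions and, in class 1, blended with a shared
  extra source so their observed correlation moves by exactly the requested
  delta.  Detaching makes the plant surgical: the pair correlation is the
  only systematic class difference, with no side effects on the channels'
  other correlations.
* *Coupling (negative delta)*: requires the pair to share a block (there
  must be correlation to remove); the blend replaces part of the shared
  component with private sources.  This attenuates the two channels'
  correlations with their block peers — an acknowledged side effect.
* *Community*: class 0 and class 1 use different block partitions, e.g.
  merging the eight source blocks into one.  After proportional
  thresholding, class-0 graphs decompose into small dense communities while
  class-1 graphs are uniform and sparse, so detected communities are larger
  and internally sparser and all seven community path lengths rise — the
  mechanism behind the directional tests.

Both class segments of a subject share one latent source draw; only the
mixing differs.  A master seed spawns per-subject substreams
(`numpy.random.SeedSequence`), so cohorts are bit-reproducible.

**What the generator does not emulate:** 1/f spectra, oscillatory peaks,
volume conduction, artifacts, and between-subject variability of the
population correlation structure.  The last point matters for interpreting
the tests: because all subjects share one population correlation matrix,
aggregate graph measures are far less noisy than in real data, and level-C
classifiers saturate on effects that would be subtle in practice.  Passing
tests demonstrate that the machinery is correct and that planted effects are
recovered where they were planted — not that real-data accuracies would
reproduce.

## Desk-scale experiment designs

The validation suite fixes these problem sizes (chosen once as realistic
desk-scale conditions):

* *Null calibration*: 16-subject cohorts, level-B features, labels permuted;
  20 seeds.  Mean test macro-AUC must sit in [0.35, 0.65], and no pair
  feature may win the attribution ranking in a majority of seeds.
  `scripts/acceptance.py` recomputes exactly this quantity.
* *Amplitude recovery*: a 24-channel montage subset, 16 subjects, stride-150
  level-A rows, gain 2.0 on one channel; the channel must rank first in
  ≥ 90% of 20 seeds.  The reduced montage keeps the row count a per-
  timepoint SVM needs within desk-scale fitting budgets.
* *Coupling recovery*: full montage, 16 subjects, one pair at +0.4; the pair
  must rank in the attribution top 3 in ≥ 90% of 20 seeds.
* *Level ordering*: "coupling-dominant" cohorts (24 disjoint pairs at +0.6,
  8 subjects); median level-B test accuracy over 20 seeds must be at least
  the level-C median.  Level B uses 4 sub-epochs per window (the sample-size
  amplifier); level C keeps its canonical one-row-per-subject-window form.
* *Community direction*: 8 subjects, blocks (8×~8) merged to (62,),
  proportional threshold 0.1.

## Known limitations

* With 48 canonical level-B rows and 1891 features, margin classifiers can
  sit near the majority-class rate even when a single feature separates the
  classes perfectly — the expected p ≫ n behavior.  Attribution still
  identifies the planted feature in that regime; the epoching option is the
  supported way to raise the row count.
* Level-C measures aggregate over all edges, so under the homogeneous
  generator they detect even single-pair effects with very large effect
  sizes; cross-level accuracy comparisons on synthetic data should be read
  with that in mind (see generator caveats above).
* The montage list contains the 62 names of the 10-10 subset used by the
  underlying study; tests planting "temporal channel" effects use T8.
* EDF reading requires the optional `mne` dependency; delimited text is the
  native format.
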