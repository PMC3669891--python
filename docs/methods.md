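# Methods

## The prediction scheme

`localqsar` is a lazy, instance-based modelling framework. Nothing is
fitted globally at training time beyond descriptor preparation: training
consists of (a) mining substructure descriptors and scoring their
association with the endpoint, and/or (b) standardizing and
SVD-compressing numeric property descriptors. At prediction time, each
query gets its own model built from its neighbors and discarded
afterwards.

The underlying assumption is the similarity principle of read-across:
compounds that share *endpoint-relevant* structural features act by
similar mechanisms and therefore have similar activities. The framework
makes "endpoint-relevant" operational by filtering descriptors on their
statistical association with the endpoint, which focuses the similarity
on biologically active parts of the molecules and mutes inert scaffolding.
The corollary assumption — and the main failure mode — is that a
biologically active substructure that is rare in the training data cannot
be scored, is treated as inert, and silently weakens predictions for
queries that contain it.

## Substructure mining

The default miner enumerates **linear fragments**: simple paths of 1..10
heavy atoms in the molecular graph, rendered as SMARTS with element
symbols (lowercase when aromatic) and explicit bond orders
(`-`, `=`, `#`, `:`), e.g. `C-N=O` or `c:c:n`. Each undirected path is
keyed by the lexicographic minimum of its two directional renderings, so
it is counted once per molecule. Charges, stereochemistry and
ring-closure patterns are outside the mined dialect. The miner is an
interface (dataset in, fragments with *p*-values out); a branched or
compressed graph miner can replace the linear default without touching
anything downstream.

Association is scored with the Pearson chi-square statistic on the 2×2
table (active/inactive × with/without fragment), 1 degree of freedom,
**without** Yates continuity correction — the uncorrected statistic is the
plain textbook test, and the choice is isolated in one function
(`chi_square_association`) should a corrected variant ever be wanted. The
*p*-value is the chi-square survival function of the statistic. A
fragment's direction is *activating* when the observed (active, with-
fragment) count exceeds its independence expectation, *deactivating*
otherwise. Fragments present in every training compound have a zero table
margin, carry no discriminating information, and are dropped before
testing; single-class datasets are rejected outright.

Mined fragments are sorted by ascending *p*-value, ties broken by
descending total support and then lexicographic SMARTS — a total,
deterministic order, so repeated runs are byte-identical.

## Similarity, neighbors, confidence

* **Weighted Tanimoto** over binary fragment fingerprints:
  `Σ w_f [f∈A∧f∈B] / Σ w_f [f∈A∨f∈B]`. Default fragment weight is 1
  (significance filtering acts purely as a cutoff); `weighting: p_value`
  switches to `w_f = 1 − p_f`. An empty union yields similarity 0.
* **SVD cosine** for numeric property vectors: columns are mean-centered
  and scaled to unit variance (constant columns dropped), the matrix is
  decomposed, and the smallest rank whose cumulative squared singular
  values reach `variance_target` (default 0.95) is retained. Similarity is
  the cosine between projected vectors, **clamped below at 0** rather than
  rescaled from [−1, 1]: anti-correlated property profiles should count as
  "not similar" (0), not as "half similar" (0.25), in the confidence mean.
  Missing feature values are imputed with the training column mean, which
  maps them to the origin after centering — the neutral choice.

A neighbor is any training compound with similarity ≥ `threshold`
(default 0.3 for both indices; the value is a configurable convention, low
enough that moderately related structures participate, high enough that
unrelated ones do not). All neighbors above threshold are used — there is
no k-nearest cap by default (`max_neighbors` exists for runtime control).
A query identical to a training structure simply appears as a
similarity-1 neighbor; cross-validation prevents self-matching by fold
construction rather than by ad-hoc exclusion.

**Confidence** is the arithmetic mean similarity of the neighbors actually
feeding the local model (configurable to average over all training
compounds instead). It is a relative applicability-domain indicator in
[0, 1], not a probability: an empty neighbor set gives confidence 0 and an
explicit *unpredicted* outcome.

## Local models

* **Majority vote** (nominal endpoints, default): per-class sums of
  neighbor similarities; the larger sum wins. The score
  `(Σ_active − Σ_inactive) / Σ_all` is a signed margin in [−1, 1] used for
  ROC ranking. An exact tie is reported unpredicted (conservative; with
  float similarities ties are essentially confined to degenerate inputs).
  `min_neighbors = 1`: any neighbor permits a prediction, so "unpredicted"
  coincides with "no neighbors".
* **Local SVM** (classification or regression): trained on the neighbors
  only (`min_neighbors_svm = 5`), with a Tanimoto kernel on fingerprints
  or an RBF kernel on projected property vectors. (C, γ) is selected on
  the 8×8 geometric grid C ∈ 2⁻²..2⁵, γ ∈ 2⁻⁷..2⁰ by inner
  cross-validation over the neighbors (5 folds, reduced to leave-one-out
  below 5 neighbors), minimizing RMSE for regression or error rate for
  classification; ties go to the smallest C, then the smallest γ. The grid
  ranges are this package's own convention — symmetric geometric ladders
  of exactly 8 values around the libsvm defaults. After selection the
  model is refitted on all neighbors. If all neighbor activities are equal
  the constant model is returned without fitting. The Tanimoto kernel has
  no width parameter, so only C is searched there. Neighbors enter the SVM
  unweighted; similarity weighting affects neighbor selection and
  confidence only. The grid search is implemented with precomputed Gram
  matrices sliced per fold (sklearn's SVC/SVR as the solver), which keeps
  the thousands of tiny per-query fits fast and the tie-break explicit.

## Cross-validation and statistics

Folds are seeded and stratified by class for nominal endpoints (plain
seeded shuffling for numeric). Endpoint-supervised descriptors — mined
fragments — are recomputed on every training fold so that no test-fold
compound ever contributes to a fragment's support or *p*-value.
Endpoint-blind physico-chemical descriptor *values* are computed once
globally; the SVD projection, although also endpoint-blind, is refitted
per training fold. Statistics are computed over predicted instances only;
unpredicted queries are a separately reported count, not errors.

R² is 1 − SS_res/SS_tot about the actual mean, which differs from squared
Pearson correlation for biased predictors; both are reported. Lin's
concordance correlation uses population (1/n) moments:
CCC = 2·cov(p,a) / (var(p) + var(a) + (mean p − mean a)²). AUC is the
rank-based Mann–Whitney statistic of the vote margin, ties counting ½;
for vote-based classifiers the margin is this package's score convention,
so AUC values are comparable within the framework rather than across
score definitions. Ratios with zero denominators (e.g. TPR with no actual
positives) are reported as missing, never as 0. Report tables round to 3
decimals (round-half-even); the JSON report keeps full precision.

The confidence curve evaluates the chosen statistic over all predictions
with confidence ≥ c for an even grid of cutoffs spanning the observed
confidences; strata with fewer than two predictions report a missing
value. Retention counts are non-increasing in the cutoff by construction.

## Synthetic fixtures

The generators produce small molecules (≤ 12 heavy atoms) from a
restricted vocabulary — C/N/O single-bond chains, optionally a benzene
ring — and plant a nitroso motif (`N=O`) in a `carrier_probability`
fraction (default 0.5). A nitroso group rather than a full nitro group is
planted because neutral nitro SMILES requires formal charges, which the
mined SMARTS dialect deliberately excludes; the motif plays the same
"activating fragment" role. The attachment point varies between the
aromatic ring and the chain terminus so that no longer fragment containing
the motif covers all carriers — the bare motif is the unique
maximal-support perfect marker and must be mined rank-1.

Classification: label = carrier flag, flipped with probability
`label_noise` (default 0.05), so the Bayes accuracy of the planted rule is
1 − noise. Regression: activity = 2.0 + 1.0·(motif count, 0–2) +
0.05·(heavy atoms) + N(0, sd), sd default 0.25 — i.e. noise at 25% of the
per-motif effect. All randomness flows through a seeded `random.Random`
using integer-indexed choices, so fixtures are byte-stable across
platforms; structures are deduplicated by canonical SMILES via rejection
sampling.

What the fixtures do **not** emulate: realistic chemical diversity,
multiple competing mechanisms, correlated toxicophores, activity cliffs,
or assay noise structure. Passing the fixture-based tests demonstrates
that the machinery (mining, similarity, local models, leakage-free
validation) is correct and that planted rules of realistic strength are
recovered; it does not certify predictive performance on real
toxicological data.

At these scales (200 compounds, 10 folds) a full classification
cross-validation takes seconds and the local-SVM regression
cross-validation about a minute on one core; sizes were chosen so the
statistics are stable while iteration stays interactive.

## Data handling choices

Structures are canonicalized with RDKit; for salts/mixtures the largest
covalent component is kept (standard QSAR practice). Duplicate canonical
structures are merged: nominal labels must be unanimous (otherwise the
compound is dropped and counted), numeric values collapse to the median —
conservative and deterministic. Unparseable structures are skipped with a
warning and counted, never fatal per-record, because large public toxicity
files routinely contain parse failures. Stereochemistry-aware
deduplication, tautomer normalization, InChI, and multi-class endpoints
are out of scope.

## Known limitations

* The linear-fragment miner cannot express branched or ring-closure
  patterns; toxicophores that are intrinsically branched (e.g. quaternary
  motifs) are only partially captured by their linear sub-paths.
* Confidence is a heuristic domain indicator; it ignores the coherence of
  neighbor activities and is not calibrated to error probability.
* Majority-vote AUC depends on the vote-margin score convention; the
  framework's AUC values should not be compared against AUCs computed
  from probabilistic scores.
* With `weighting: binary`, many weakly significant ubiquitous fragments
  can dilute the similarity signal on small noisy datasets; the
  `p_value` weighting and a higher `p_cutoff` stringency are the levers.
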