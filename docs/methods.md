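# Methods

This note documents the model, the procedures, the defaults and the design
choices behind `fsopa`, and what the synthetic benchmark does and does not
show.

## Data model

A `FeatureTable` keeps every cell as its raw string together with an
explicit missing mask; nothing is imputed, converted or normalized. This
is deliberate: the compression-distance stage operates on serialized cell
text, so any transformation would change the objects being compared. Row
order is preserved everywhere because it is the only alignment key between
per-column byte objects — two columns can only exhibit co-compression if
their cells are serialized in the same sample order. Dates are treated as
opaque strings (their formats in registry extracts are too inconsistent to
parse reliably); the `date` role exists so the redundancy filter and the
Cox stage can exclude them explicitly.

Column kinds are inferred conservatively: a column is numeric only if
every non-missing cell parses as a number; a single stray token makes it
categorical. Missing sentinels default to the empty string and `NA` and
are configurable.

## Ranking and subsets

Ranking is a stable sort on the criterion (ascending under `minimize`),
ties broken by original row index, so reruns are bit-reproducible. Subset
sizes are ⌊n/s⌋ for s ∈ {2, 4, 8}; heads and tails of one rank, hence the
nesting B8C ⊆ B4C ⊆ B2C. Rows with a missing criterion are dropped from
the rank and counted. The guard ⌊n/8⌋ ≥ `min_subset` (default 10) rejects
tables whose highest-pressure subsets would be too small to compress
meaningfully.

## Distance, tree and communities

NCD uses DEFLATE (zlib level 9) by default; `gzip` is accepted as an alias
since gzip output is DEFLATE plus a fixed header, and bz2/lzma are
available where their longer context windows pay off. Concatenation is
always in lexicographic name order, which makes the distance exactly
symmetric by construction rather than approximately so; values are clamped
at zero. Per-object compressed sizes are computed once and cached, so an
l-feature matrix costs l single + l(l−1)/2 pair compressions.

Neighbor joining is the classical Saitou–Nei algorithm with the Q
criterion; joins tie-break on the smallest index pair. Negative branch
lengths are clamped to zero with the deficit moved to the sister branch,
preserving the joined pair's total length — the downstream procedures use
edge counts only, so clamping affects reporting, not selection. On
additive matrices the implementation reproduces the generating tree metric
to ~1e-15 (checked against an independent random-tree oracle and against
scikit-bio's NJ).

Communities are computed with greedy agglomerative modularity maximization
(the Clauset–Newman–Moore realization of Newman's fast algorithm, via
networkx) and attached to each phylogram as metadata. The sensitivity
procedures do not consume them: they use the explicit middle-path split
defined below, which is the split the method itself prescribes.

## Clades, SM1 and SM2

The longest path is measured in edges, not branch lengths; endpoint ties
resolve to the lexicographically smallest (start, end) leaf pair. An
odd-length diameter has a unique middle edge; an even-length one yields
both middle candidates, and the congruence comparison arbitrates — the
candidate combination whose best clade pair shares the most leaves wins,
with remaining ties broken by fewer total symmetric-difference leaves and
then a lexicographic key chosen to be symmetric under a best/worst
exchange (so SM1's output is invariant to which tree is called "best").

Each clade is rooted at its cut point — the only rooting the cut induces —
and a leaf's sibling set is the full leaf set of the subtree hanging off
the other side of its parent. SM1 compares sibling sets for leaves present
in both clades of a pair; leaves present in only one clade cannot be
compared and are recorded as `unpaired` in provenance rather than
selected. SM2 reuses SM1's chosen splits: in each of the two clades
containing the target it takes the target plus exactly the parent's other
subtree (not any deeper ancestors), and unions the two selections. A
target isolated at the cut point contributes only itself.

## Resamplings

RS1 removes columns with missing fraction strictly above the threshold
(default 0.85, so a column at exactly 85% stays). RS2 is driven by
declared column roles rather than name heuristics, because deciding what
counts as a "date" or "code" column encodes human judgment; roles make
that judgment explicit and portable. Criterion, duration and event columns
are never dropped by either filter.

"Clade preserved" for RS3 is operationalized as the strictest checkable
reading: a feature is stable iff no dataset's SM1 ever selected it and,
for every subset label, the leaf set of its middle-split clade restricted
to the shared features is identical across datasets. An explicit drop list
can extend the result when domain judgment says more. RS4/RS5 use the
fixed ≥2-of-3 recurrence threshold; RS6 is their union, and
RS4 ∩ RS5 = ∅ by construction.

## Cox stage

Fitting goes through lifelines' `CoxPHFitter` with the Efron tie
correction — stay durations are day-granular, so ties are certain.
Categorical covariates are one-hot encoded against their most frequent
level (ties: lexicographically first); numeric covariates pass through
unchanged, since the partial likelihood is invariant to affine rescaling.
k counts estimated coefficients after encoding, not raw features. The
covariate-free null model is computed in closed form: at β = 0 the Efron
denominators reduce to (n_risk − l), so logPL₀ = −Σ_t Σ_{l<d_t}
log(n_risk(t) − l).

Forward selection is a single ordered scan from the null model; a
candidate stays iff AIC strictly decreases. The default order puts
SM1-selected features before SM2-only ones (alphabetical within groups)
because the clade comparison needs no domain knowledge while the
target-based lists presuppose one, and forward selection is
order-dependent; the order is overridable. Within one forward run the
complete-case row set is fixed across all candidates — AIC values are only
comparable on a common sample — while a standalone `cox_fit` is
complete-case for its own model. Candidates whose encoded width would
exceed one column per ten rows are skipped with a logged reason (an
id-like column with thousands of levels is not a fittable covariate), as
are candidates whose fit fails outright.

The pipeline never offers the outcome columns (criterion/duration/event)
as covariates, and also withholds date- and code-role columns from the Cox
candidate lists: the selection reports them (they can be informative about
data structure) but a date string is not a hazard covariate.

## Pareto comparison

Dominance is weak with at least one strict inequality over (number of raw
features, normalized AIC), both minimized; duplicates of a front point
remain on the front. The front itself is extracted by a sort-and-sweep and
is invariant under input permutation and positive rescaling of either
coordinate. The elbow rule is a decision of this package: min-max scale
the front, return the member closest to the ideal corner (0, 0), ties to
fewer features. Normalization divides by a reference AIC (the maximum over
the compared models by default), putting the worst model at 1.

## Synthetic registry

The generator emulates a hospital-stay registry: i.i.d. standard-normal
numeric covariates, uniform categoricals, date-like and code-like
distractor columns, and a length of stay drawn from
T = −log U / (λ · exp(Xβ)) with exponential baseline λ = 0.1 per day
(mean uncensored stay 10 days). Censoring is independent exponential; its
rate is calibrated by root-finding so the expected censored fraction
equals the request (empirically within ±3% at n = 5000). Durations are
rounded up to whole days, as stay records are, and the criterion column is
the duration itself. Missingness is applied completely at random per
feature column. Numeric cells are printed at two decimals — registry
numerics are low-precision, and the coarser alphabet also gives the
compressor realistic repetition.

The default benchmark conditions are n = 2000 samples, five informative
numeric columns with β = 1 each, fifteen noise columns (ten numeric, five
categorical) and 20% censoring. What passing shows: the best/worst tree
comparison reliably surfaces the columns that drive the hazard, and the
forward-AIC model built from them clearly beats noise-only models. What it
does not show: performance under informative missingness (the generator is
MCAR only), correlated covariates, non-proportional hazards, recurrent
stays per patient (rows are independent records), or real ICD-code
semantics — date/code columns here are pure distractors.

The continuous simulator is exposed separately (`simulate_survival`) and
is what the Cox parameter-recovery checks use, so likelihood correctness
is assessed without the day-rounding layer.

## Numerical and reproducibility notes

All randomness flows through `numpy.random.Generator` seeds; the pipeline
writes content hashes for every artifact and a rerun on identical inputs
reproduces them byte-for-byte (Newick serialization uses a canonical
rooting at the smallest leaf's neighbor and orders children by smallest
descendant name). Problem sizes in the test suite — 100 random trees for
the NJ oracle, ≤8-node graphs for exhaustive modularity enumeration
(4140 partitions), 200 ranked tables, 1000 Pareto point sets, 200 Cox
replicates at n = 2000, 25 end-to-end recovery seeds — were chosen so the
whole suite runs in a few minutes on one CPU while keeping the stochastic
assertions' error rates negligible.

Known limitations: NCD on short columns (small subsets) is dominated by
compressor overhead, which is why the `min_subset` guard exists; greedy
modularity can stop short of the true maximum on adversarial graphs (a
six-node path is a known case) — irrelevant to selection, which never
consumes communities; and the selected set r is intentionally liberal
(noise features do enter it), relying on the forward-AIC stage to prune —
the method is a sensitivity filter, not a final model.
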