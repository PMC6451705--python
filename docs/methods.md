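# Methods

## The community model

A *community* is the set of tweets carrying at least one hashtag mapped to a
health condition, together with their authors. Tweets carrying hashtags of
several conditions are counted in each of those communities: hashtag lists do
not map diseases one-to-one, and exclusive assignment would silently thin
overlapping communities (e.g. inflammatory-bowel-disease-related tags).

Each community is summarised by 24 variables in three facets.

**Engagement.** `pct_retweet` is, by default, the share of *original*
(non-retweet) tweets whose `retweet_count` ≥ 1 — a collected retweet's counts
describe its source, so counting it again would double-book engagement. A
config switch (`retweet_share_mode="corpus"`) instead reports the share of
corpus tweets that are retweets; both readings of "percentage of tweets that
have been retweeted" are defensible and both are supported. `pct_like` is the
analogous share with `like_count`; `mean_retweet_freq` averages
`retweet_count` over retweeted originals only, while `mean_like_freq`
averages `like_count` over *all* tweets (deliberately asymmetric — the two
variables are defined differently). `pct_reply` and `pct_quote` are shares of
the whole corpus.

**User.** A *new-content creator* (NCC) authored ≥ 1 non-retweet tweet
(replies and quotes count as new content); a *content propagator* (CP)
retweeted ≥ 1 time. The sets overlap — nothing forces a user into one role.
Follower counts change over a month of collection, so a user's follower count
is taken from their latest tweet in the corpus (ties and missing timestamps
resolved by file position). Outlier fractions use the Tukey fence: the share
of values above Q3 + 1.5 × IQR, with quartiles by linear interpolation
(type 7) — at small n the convention matters and is therefore fixed and
documented. A `literal` mode (v > 1.5 × Q3) is retained for sensitivity
analysis. Fewer than four values cannot support a quartile estimate; the
fraction is then 0 with a warning.

**Content.** Per-tweet means of hashtag, mention, URL and media counts plus
token statistics. Tokenisation is deliberately minimal and reproducible:
lowercase, URL substrings removed, whitespace split, edge punctuation
stripped. `mean_unique_words ≤ mean_length` always holds.

## Correlation analysis

Communities with fewer than 100 tweets or 50 users are excluded (their
statistics are unstable); the two size totals are excluded from the analysis
matrix so communities are compared regardless of size; every remaining column
is standardised to mean 0, sample SD 1 (ddof = 1; constant columns become
zeros with a warning).

Pairwise analysis reports Pearson r for each of the 6 engagement variables
against each of the 16 user/content variables.

The canonical correlation between a facet block X (n × p) and the engagement
block Y (n × q) is computed by Cholesky-whitening the block covariances and
taking the leading singular value of the whitened cross-covariance —
algebraically the generalised eigenproblem on Sxx⁻¹ Sxy Syy⁻¹ Syx. A ridge
term (default 1e-8, *relative* to each variable's variance so the result is
exactly invariant to per-column affine rescaling) guards near-collinear
blocks such as %NCC/%CP; with `ridge=0` a rank-deficient block raises an
error naming the offending columns (QR with column pivoting). Weights are
scaled so each canonical variate has unit sample variance, and both weight
vectors are sign-flipped together so the X variable with the largest |weight|
has a positive weight — results are reproducible across linear-algebra
backends. Only the first canonical pair is reported; loadings are the Pearson
correlations of each variable with its own variate. Canonical weights can
legitimately exceed 1 or be negative; they are reported raw, never rescaled.

**Significance and bias.** The analysis adds a seeded row-permutation test
(999 permutations by default). Because the leading sample canonical
correlation is biased upward — with p + q ≈ 12 variables and a few hundred
communities the null level is r ≈ 0.2 — a debiased estimate is reported:
r_adj = sqrt(max(0, (r² − m) / (1 − m))) with m the mean squared permutation
correlation, i.e. observed-minus-expected over maximum-minus-expected on the
eigenvalue scale, the same chance-adjustment form as an adjusted Rand index.
Profile variables of small communities are noisier in *both* facets; an
unrestricted permutation destroys that shared heteroscedasticity and slightly
understates the null, so by default rows are permuted within ten
equal-count community-size bands (a restricted permutation). Replicated
estimates (e.g. across generator seeds) are pooled by averaging the *signed*
adjusted squares before the square root, so replicate noise cancels rather
than folding at zero.

## Interaction networks

Per tweet: one directed edge author → u for every mentioned user u, author →
source for a retweet, author → target for a reply; a tweet with none of these
adds a self-loop for its author. Parallel same-type interactions accumulate
edge weight; mentioned users who never tweet still become nodes. Modularity
Q = Σ_c (e_cc − a_c²) is evaluated on the symmetrised weighted graph with
self-loops excluded, since the greedy agglomerative algorithm is defined for
undirected graphs.

Clustering: graphs with ≤ 8 nodes are solved *exactly* by canonical
set-partition enumeration (Bell(8) = 4140 partitions, milliseconds) — tiny
graphs deserve the true optimum, and greedy agglomeration provably misses it
on some dense little graphs. Larger graphs use Clauset–Newman–Moore greedy
agglomeration — repeatedly merge the pair of clusters with the largest
modularity gain, ties broken on the lexicographically smallest cluster-id
pair — exploring the full merge path (the gain sequence is not monotone) and
keeping the best partition seen, followed by a deterministic refinement:
single-node moves (including detaching into a singleton), then pairwise
cluster merges, repeated to a fixpoint, plus a second hill-climb started from
singletons as a tie-breaking alternative. Every step is deterministic, so
identical inputs give identical partitions.

Summaries replace qualitative network typology with numbers: the isolate
fraction (nodes with no non-self edges — authors of self-loop-only tweets
that nobody engages), descending cluster sizes, and per-cluster *hub
concentration* (largest within-cluster weighted in-degree over total
within-cluster edge weight). Clusters above 0.5 are labelled broadcast-like
(hub-and-spoke); many medium clusters with low concentration indicate
community-cluster structure.

## The synthetic-data generator

The generator emulates a month-long hashtag-filtered collection: per
condition, a log-uniform number of users between 25 and 250 (so roughly the
bottom third of communities falls under the 100-tweet/50-user filter, as in
real curated collections where many rare-disease tags are tiny), exact-quota
NCC/CP role assignment (70% / 50%, overlapping), shifted-Poisson tweets per
NCC (mean 1.8) and retweets per CP (mean 1.5), negative-binomial retweet and
like counts (dispersion 0.8 — heavy-tailed, as social counts are), log-normal
followers (median ≈ 245), Poisson mention/URL/media counts and tweet lengths,
and uniform-random vocabulary tokens. Retweet records copy the source tweet's
text, hashtags, mentions, URLs and media and carry zero retweet/like counts
of their own.

The cross-facet dependence is planted at the condition level, because the
correlation analysis operates on per-condition profiles: a content latent
z_c ~ N(0,1) and an engagement latent z_e = ρ·z_c + √(1−ρ²)·ε. All content
links (mentions, URLs, media, length) are *linear* in z_c and all engagement
links (retweet/like means, reply/quote probabilities) linear in z_e, floored
to keep rates valid, so the population canonical correlation between the two
facets equals ρ and shrinks only by within-condition sampling noise (a few
percent at these community sizes). Three design points keep the plant clean,
i.e. prevent mechanical correlation the analysis would mistake for signal:
retweets copy mentions (otherwise the originals share dilutes content and
engagement means jointly), interaction targets never self-collide (otherwise
hub authors lose mentions in proportion to retweet duplication), and retweet
*sources* are sampled uniformly over originals while the planted hub/block
structure is carried by mention and reply targeting (hub-weighted duplication
of a handful of originals would otherwise inject a large shared noise
factor).

Interaction topology per condition is drawn from a mixture of *broadcast*
(mentions/replies 75% directed at a small hub set) and *community clusters*
(4 planted blocks, 90% within-block targeting); a pure *isolates* topology
(no interactions at all) exists for testing but has zero default weight —
in real collections isolates appear as subgroups inside communities, which
these graphs already produce naturally via non-interacting tweets. A single
global seed drives one child RNG per condition (`SeedSequence(seed,
spawn_key=(i+1,))`), so datasets are byte-identical for a fixed config and
per-condition regeneration is stable under reordering.

**What the generator does not emulate:** real text (tokens are synthetic
words), temporal bursts such as awareness days, follower dynamics, bot
behaviour, or cross-condition user overlap. Passing tests therefore show the
*pipeline* is correct and the planted dependence is recoverable at realistic
sizes and noise levels — not that any particular real-world correlation
holds.

## Problem sizes and numerical choices

Tests run the recovery experiment at 500 conditions × 3 planted ρ levels ×
20 seeds with 80 stratified permutations per dataset, the solver-equivalence
check on 50 instances of 40 × (3 + 2) blocks against a Nelder–Mead
multi-restart optimiser (agreement to 1e-4), the modularity oracle on 200
random ≤ 8-node graphs against exhaustive search, and partition recovery on
50 seeded 60-node two-block graphs (p_in = 0.3, p_out = 0.01, adjusted Rand
≥ 0.9 in ≥ 96% of runs). Equality of profile fields against an independent
plain-Python recount is asserted to 1e-12 relative tolerance (identical
arithmetic up to summation order). Quartile bands are closed on the right;
rank ties break by condition name ascending; degenerate inputs (empty
corpora, constant columns, edgeless graphs, < 4 values for quartiles) raise
or warn as documented rather than returning silent NaNs.

## Known limitations

- The CCA reports the first canonical pair only; higher pairs and redundancy
  analysis are out of scope.
- The permutation test is an extension of the underlying comparative
  analysis, which reports no significance tests; its stratified form assumes
  community size is exchangeable within bands.
- Modularity clustering inherits the resolution limit of modularity
  maximisation; very small clusters attached to large graphs may be merged.
- `%Retweet` semantics on corpora where retweets were *not* collected
  (originals only) are unchanged, but `corpus` mode then reports 0.
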