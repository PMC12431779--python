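# Methods

This note documents the models, conventions, and numerical choices behind
tspscan, and what the synthetic-data generator does and does not emulate.

## Quartet Bayes factors for trans-species polymorphism

**Model.** For four alleles (two from taxon group A, two from group B) an
unrooted binary tree induces one of three quartet resolutions; exactly one
places the A pair together. Over a posterior sample of trees, the
frequency of non-monophyletic resolutions estimates `Pr(Hᶜ|D)` and the
monophyletic frequency `Pr(H|D)`. The Bayes factor is the posterior odds
for `Hᶜ` multiplied by the prior odds of `H`, which is 1/2 under a uniform
prior over the three resolutions. The prior-odds factor is exposed in the
API (`prior_odds_H`) but fixed at 1/2 by default; the interpretation of K
always depends on one's prior expectation, so the decisive threshold
(K > 100) is used only for rendering, never inside computations.

**Zero counts.** A zero topology count would give K = 0 or ∞; instead the
zero fraction is replaced by `1/(n+1)` (n = informative trees) and the
complement by `1 − 1/(n+1)`, and the result is flagged. In matrix output a
zero monophyletic count renders as `>K` (lower bound); a zero
non-monophyletic count renders as `<K`.

**Uninformative trees.** Trees whose induced quartet is a star (possible
only with polytomies) are excluded from both counts and from n. Posterior
samples from Bayesian samplers are strictly binary, so this matters only
for synthetic edge cases.

**Quartet enumeration.** All `C(|A|,2) × C(|B|,2)` quartets are tested,
unless they exceed a cap (default 10,000), in which case a seeded uniform
subsample of exactly the cap size is used. Reported is the maximum K and
the first quartet attaining it (ties broken by enumeration order, which is
lexicographic in sorted tip labels — deterministic everywhere). Cells with
fewer than two usable alleles on either side are reported blank.

**Classifier.** Monophyly of {a1,a2} in a tree holds iff some edge
separates {a1,a2} from {b1,b2}; the implementation scans per-edge leaf
sets vectorized over the whole sample. A brute-force oracle (extract the
induced 4-tip subtree, inspect its bipartitions) backs it in the tests.

## Tree-sample processing

Burn-in removes the first `floor(f·n)` trees (default f = 0.10,
configurable because absolute-state cutoffs can exceed 10% in shortened
runs); replicates are concatenated in argument order with provenance
retained, after verifying identical tip sets. The
maximum-clade-credibility summary returns the *member* tree maximizing the
product of posterior clade frequencies, counting rooted clades when trees
are rooted and unrooted bipartitions otherwise; node heights are passed
through untouched since nothing downstream consumes them. ESS uses the
autocorrelation-time estimator with initial-positive-sequence truncation
(sum autocorrelations over increasing lag until the first non-positive
value); a constant trace reports ESS = length by convention. The usual
acceptance gate for combined posteriors is ESS ≥ 100.

## Gene conversion

**Detection.** A simplified within-alignment ("global inner") runs
statistic: for each sequence pair, restrict to polymorphic columns where
both sequences are ungapped; the candidate fragment is the longest run of
consecutive matching polymorphic sites (default; a finite mismatch penalty
switches to a maximal-segment Kadane score of +1/−penalty). Significance
is the rank of the observed best score among best scores under seeded
permutations of polymorphic-column order (default 10,000 permutations),
Bonferroni-corrected across pairs; fragments with corrected p < 0.05 are
kept, with bounds mapped back to 1-based alignment columns. All sites are
used, not silent sites only — with extreme polymorphism there are too few
silent sites, at the cost of possibly overestimating tract lengths.
Identical sequence pairs match at every polymorphic site, leaving no run
structure to test, and produce no fragment.

**Direction.** A converted acceptor carries the donor's tract: inside the
fragment it clusters with the donor's relatives, outside with its own.
For each pair member we compute its nearest neighbor by p-distance
(non-gap shared columns, ties broken lexicographically) *among sequences
other than the pair*, separately over polymorphic columns inside the
fragment and outside it (within the same exon). The member whose nearest
neighbor changes while its partner's does not is the acceptor; if both or
neither change, or either side has fewer than 5 informative columns, the
direction is undetermined. Nearest neighbors exclude the partner because
the two fragment sequences are near-identical inside the tract, which
would otherwise make each the other's inside-neighbor and erase the
asymmetry the rule needs. Tree-based placement inside vs outside the
fragment would be a reasonable alternative concretization; it is not
implemented.

**Exclusion.** Acceptors are excluded from quartet analyses for the
fragment's region; undetermined pairs contribute both sequences. Exclusion
is monotone in the fragment set.

## Site rates

Rates are posterior means per alignment column (mean over states, then
log — not log-then-mean). The baseline is the mean rate of columns gapped
in *all* designated backbone sequences (`-` and `.` count as gaps), and
fold changes are `log2(mean_rate / baseline_mean)`. Two identities follow
and are tested: the mean of `2^fold_change` over baseline columns is
exactly 1, and fold changes are invariant to rescaling all rates. Two
named rapid-site presets exist: `twice` (fold change ≥ 1) and `fourfold`
(fold change > 2). Per-exon summaries count rapid sites within 1-based
disjoint exon intervals, excluding baseline columns by default (mostly-gap
columns are not sites of the focal gene), and compare each exon against
the pooled non-binding-region exons with a two-sided Fisher exact test —
an explicit choice; the counts involved are small enough that an exact
test is preferable to a chi-square approximation. Per-codon rates are the
mean of the three member columns; codons with missing or gap members are
emitted as NaN. The association regression is OLS of per-position trait
counts on rate with a two-sided t-test on the slope.

## Structure mapping

Nucleotide sequences are translated (codons containing a gap → `-`,
ambiguous → `X`, stops → `*`) and aligned globally to the structure
chain's sequence (match +1, mismatch −1, gap open −5, extend −1); aligned
identity below 30% flags a likely wrong chain. All deposited atoms are
used; alternate locations resolve to the highest-occupancy conformer
(ties by altloc letter), waters are dropped, heteroatom residues are
dropped except in explicitly declared chains, and only the first model of
multi-model files is read. Per MHC-chain residue the minimum Euclidean
distance over all (residue atom × peptide atom) pairs is computed (k-d
tree over peptide atoms; verified exactly against all-pairs brute force),
averaged over structures where the residue is resolved, and rate is
regressed on distance with OLS.

## Synthetic data

The generator emulates the *statistical* structure the pipeline needs and
nothing more:

- **Tree samples.** Monophyly: within-species allele subtrees are
  re-drawn per emitted tree (random joins with exponential branch
  lengths, scale 0.3) inside a fixed species topology (default
  human/chimp/gorilla/macaque with split depths 6/8/32 arbitrary units).
  TSP: alleles are assigned round-robin to ancient lineages whose root
  splits are ≥ 2× deeper than any species split, each lineage carrying a
  pruned copy of the species tree. Sampling noise is one random NNI per
  tree with probability ε (< 0.5, the regime where signal survives);
  branch lengths are not jittered because the Bayes factor consumes
  topology only.
- **Alignments.** Jukes–Cantor with equal base frequencies and per-column
  rate multipliers; gappy baseline columns are imposed on designated
  backbone rows. Richness of the substitution model is irrelevant
  downstream, which depends on rate ratios and topology.
- **Rate posteriors.** Truth × lognormal(0, σ) per state; the lognormal
  mean factor `exp(σ²/2)` inflates all columns equally and cancels in
  fold changes.
- **Structures.** One CA atom per residue; groove residues are placed
  < 4 Å from a straight 3.5 Å-spaced peptide, all others > 8 Å away.

Because these generators are idealized, passing tests demonstrate the
*correctness and calibration of the inference machinery*, not performance
on real MHC data: real posterior samples have correlated trees, real
alignments have indel structure and selection, and real structures have
full side chains. Default scales (3 alleles/species, 200–1,000 trees,
300–3,000 columns, 150-residue structures) keep every suite at desk
scale.

## Test and acceptance problem sizes

Calibration suites use 50 seeded replicates of 500-tree samples with
ε = 0.02; gene-conversion recovery uses 50 replicates of 300-column
6-sequence alignments with 60-column tracts and 500 permutations (the
permutation count controls only the resolution of the p-value; decisions
at α = 0.05 are stable from a few hundred permutations, while the
pipeline default remains 10,000); the quartet classifier is checked
against brute force on 1,000 random 6-tip trees. These sizes are the
package's own choices for tight, informative checks.

## Known limitations

- The gene-conversion detector is deliberately simpler than full
  Sawyer-style machinery (no outer-sequence fragments, no silent-site
  mode, no mismatch-tolerant run scoring by quality).
- The direction rule is a heuristic; symmetric topologies or conversions
  between mutual nearest neighbors stay undetermined by design.
- The MCC summary ranks only trees present in the sample.
- No multiple-comparison correction is applied across Bayes-factor matrix
  cells; the maximum over quartets is reported raw, so matrix values are
  screening statistics, not calibrated posterior probabilities.
- TSP ages in absolute time are out of scope: dating requires external
  species split times, not the quartet computation.
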