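# Methods

This note documents the models, rules and numerical choices behind each
stage of the pipeline, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Data model

The central container is a `PhasedDataset`: an ordered list of
individuals, one aligned `LocusAlignment` per locus, and an allele map
giving each individual up to two allele sequence ids per locus (either may
be missing). Consensus matrices (one IUPAC-coded row per individual),
concatenated supermatrices with per-locus column offsets, and collapsed
haplotype tables are derived views. All user-facing column coordinates are
1-based within the named locus; supermatrix columns map back through the
offsets table.

Residues are treated as sets of possible bases: IUPAC ambiguity codes
expand to their base sets, `N` to all four, and `-` (gap) to the empty
set. Two residues "match" when their sets intersect; a site is scorable
for a pair when both sets are non-empty.

### Consensus and collapsing rules

* Heterozygous sites in the two-allele consensus get the two-base
  ambiguity code; a site gapped or missing in only one allele becomes `N`
  (conservative: a gap/base conflict is not resolvable without more
  information); a shared gap stays a gap.
* Haplotype collapsing excludes every column containing `-` or `N` in
  *any* row before comparing (dataset-wide exclusion, not pairwise
  deletion). This makes the collapse transitive and idempotent, at the
  price of discarding columns that are informative for most pairs when a
  single row is gapped there.

## Exclusive synapomorphies

A substitution column is an ES for a taxon when every scorable member is
fixed for one state (under phased input, both alleles of every member must
carry it) and no individual outside the taxon possesses that state, with
IUPAC ambiguities counting as possessing each of their bases. Indels are
coded first (simple indel coding: each distinct maximal gap run, keyed by
its start and end, becomes one presence/absence character; rows partially
gapped over the span are inapplicable) and then scored the same way; a
taxon fixed for the gap is reported as a deletion, a taxon fixed for
residues while all scorable outsiders are gapped as an insertion.

The default missing-data policy is *tolerant*: `N`/gap neither confirms
nor breaks a character, but at least one taxon member must be scorable.
The *strict* alternative (any missing call at the column disqualifies it)
is a flag. Real datasets carry a small fraction of missing calls, and the
tolerant rule keeps a site diagnostic when the available evidence is
unanimous; strict mode is there for auditability.

ES counting is monotone: adding an individual that does not carry the
diagnostic state can only remove sites, never add them. Note that the
complement of a cleanly diagnosed bipartition is itself diagnosable at the
same columns (the ancestral state is fixed there), so ES counts alone do
not distinguish a clean split from its complement — the comparative table
is the point.

## Distances and NJ bootstrap

p-distances are mismatches over scorable sites with pairwise deletion by
default (complete deletion is a flag; which convention an external
program used is often unstated, so both are exposed). Neighbor joining is
Saitou–Nei agglomeration on these distances; negative branch lengths are
clamped to zero for output, leaving the topology untouched. Cluster
robustness is assessed by resampling alignment columns with replacement;
support is the percentage of replicates whose NJ tree contains the
original bipartition, and a replicate with an undefined distance (no
scorable overlap for some pair) is redrawn. Reports apply a bootstrap
threshold of 90 as the pass criterion.

In the comparative report the bootstrap runs on the consensus supermatrix
at the individual level, so every candidate taxon corresponds to a
potential clade. (Bootstrapping collapsed haplotypes instead is available
separately, but on clean data a species can collapse to a single
haplotype — a tip has no cluster support.)

## Median-joining networks

Haplotypes are compared over gap/missing-free columns only (consistent
with collapsing; mutational steps are not defined on missing characters).
The network construction follows the median-joining idea — connect the
sequence types through a minimum-spanning network and add quasi-median
(triplet consensus) vectors as inferred unsampled haplotypes — with one
deliberate strengthening: instead of committing greedily to one median at
a time, the implementation runs a bounded branching search over median
additions. All candidate medians tied for the best cost reduction are
explored, and cost-neutral medians are tried speculatively up to two per
path, because Steiner points frequently pay off only in pairs. The search
is capped by an evaluation budget (20 000 spanning-tree evaluations for
up to 12 sequence types, 2 000 above that) and by a ceiling on the number
of medians (max(32, 4x types)); when the budget is exhausted the
behaviour degrades to plain greedy. On random instances with up to 4
haplotypes and 5 sites the resulting network cost matched an exhaustive
Steiner-point search on 450/450 trials; at realistic sizes the result is
a heuristic, as all median-joining implementations are.

Final edges are the minimum-spanning network over the retained node set:
every pair whose distance is within `epsilon` of its minimax path
distance (the level at which the pair first becomes connected). The
default `epsilon = 0` matches common practice; on perfectly tree-like
data no median survives pruning and the network is the unique MST.
Minimal inter-group mutation counts are weighted shortest paths between
any cross-group pair of observed nodes.

## Haplowebs, FFRs and the conspecificity matrix

The FFR partition at a locus is exactly the connected components of the
bipartite graph linking individuals to their (collapsed) allele classes,
projected onto individuals; individuals with no scorable allele are
reported unassigned rather than forced into a group. The "remove
singletons" option on haploweb rendering only tags once-seen alleles for
display — FFR assignment always uses every allele, because dropping a
singleton could detach its only carrier from its own pool, contradicting
the definition.

Conspecificity scores count, per pair, the loci at which the pair shares
an FFR (scoring option 1: absence of sharing contributes nothing). The
per-pair count of scorable loci is kept alongside, so the conventional
ambiguity about missing individuals can be audited. The matrix is ordered
by UPGMA on the dissimilarity `L − score` (scipy average linkage; ties
break deterministically by input order — under exact ties the
agglomeration order, and hence the height multiset, is not uniquely
defined, so oracle tests assert equivalence on tie-free instances).
Candidate blocks are read by cutting the dendrogram top-down: a cluster
splits whenever the mean between-child score falls below
`min_score_fraction x L`. The default threshold of 0.5 ("a majority of
loci supports conspecificity") is a formalisation choice; block structure
is conventionally read visually from the heatmap, and the threshold is
exposed as a parameter. At threshold 1.0 a noisy matrix shatters towards
singletons — documented limit behaviour, not a bug.

## Supertree reliability indices

Each locus's bipartition table (generic TSV, or a MrBayes-style
`.parts`/`.tstat` pair) is canonicalised — the stored side is the one not
containing the reference taxon — and becomes one weighted binary
character per bipartition in the MRP supermatrix. Weights are the
posterior probabilities x100 rounded half-up (integer weights are the
norm for weighted parsimony; 0.975 -> 98). Taxa absent from a locus are
coded `?`.

MPP sums a node's PP over all loci and divides by the locus count, so a
node absent from a locus contributes zero; NRep counts loci with PP > 0
(this reproduces the convention that a node sampled once at PP = 0.03
across 21 loci reports MPP = 0.0014 ~ 0.00 and NRep = 1); Rep is
NRep/L. Reports flag nodes against SBP >= 90, MPP >= 0.1 and NRep >= 2.

SBP comes from bootstrap: characters are resampled with replacement
respecting integer weights (a multinomial draw over the weight-expanded
matrix, which keeps replicate length constant), and each replicate's
maximum-parsimony tree is sought heuristically: random-addition starting
trees, steepest descent over the combined NNI + SPR neighbourhood, and up
to 8 sideways moves onto unseen equal-length topologies to cross score
plateaus. Tree length is weighted Fitch on binary characters with `?`
carrying the full state set. Six restarts per search are the default:
validation against exhaustive enumeration on random matrices with up to 6
taxa showed rare wide local basins that three restarts occasionally
failed to escape (about 1 miss in 40 instances), while six gave 0 misses
in 300; the cost is linear and small at the matrix sizes involved. SBP is
the percentage of replicates whose best tree contains the bipartition.

## K selection

ΔK(K) = mean over replicates of |L(K+1) − 2L(K) + L(K−1)| divided by the
standard deviation (ddof = 1) of L(K) across replicates, for interior K
of a contiguous range; zero spread at any interior K is an error naming
that K rather than a silent infinity. The plateau rule makes the visual
"where does the curve flatten" reading reproducible: the selected K is
the smallest whose mean-lnP gain to K+1 falls below 5% (default) of the
total lnP range; when the gain just above the cut is within half a
threshold band of the qualifying one, the onset is ambiguous and the tied
set is returned. A flat table returns the minimum K flagged "flat"; a
curve that never flattens returns the whole range flagged "no plateau".

The consensus combiner prefers the plateau call on disagreement — ΔK is
known to be biased towards K = 2 — unless the ΔK peak exceeds 10x the
median of its own profile, in which case such an overwhelming signal
wins. Ambiguous plateau sets resolve to the smallest K by default, the
standard preference when several K explain the data about equally well.

## Synthetic data: what it emulates, and what it does not

The generator plants *exact* truth rather than expected truth: per
species and locus, a chosen number of diagnostic columns is overwritten
so that all members carry a state found in nobody else, and diagnostic
indels (1–3 column gap runs placed away from other planted features) are
fixed the same way. Downstream recovery is therefore an equality check,
not a statistical one. Background variation is shared intraspecific
polymorphism: the same two states segregate in every species, so no extra
fixed inter-species difference can arise (up to improbable joint
fixation). Missing data blanks whole allele calls to `N` at a given rate.
An optional maternally inherited locus is emitted homozygous; when an
introgression event is configured, the recipient species' haplotypes at
that locus derive from the donor's lineage plus a couple of private
substitutions — reproducing a mito-nuclear conflict in which the maternal
tree groups recipient with donor while nuclear diagnosis is untouched.

Deliberately not emulated: coalescent genealogies and incomplete lineage
sorting, recombination within loci, rate variation, and realistic allele
genealogies — polymorphic sites are drawn independently per allele, which
inflates haplotype diversity relative to real populations (at
`polymorphic_rate` ≈ 0.01 on 500 nt loci, within-species allele sharing
becomes rare and the FFR/CoMa criterion fragments, visibly in the block
count). Passing tests on these simulations therefore demonstrate
correctness of the *computations* on data with known truth, not the
statistical performance of the criteria on real populations.

Determinism: one `numpy` generator seeded from the config drives every
draw, so identical configs give byte-identical FASTA output.

## Problem sizes

Tests and the acceptance script run at desk scale by design: simulations
of 3–4 species x 5–10 diploids x 4–10 loci of 300–600 nt; oracle suites
at ≤ 50 individuals (FFR), ≤ 4 haplotypes x ≤ 5 sites (Steiner), ≤ 6
taxa (parsimony), ≤ 8 ids (UPGMA). These sizes keep every oracle
exhaustively enumerable while exercising the same code paths used at
study scale (tens of loci, low hundreds of alleles), where the pipeline
runs in minutes.

## Known limitations

* The MJ network and MP supertree searches are heuristics beyond the
  oracle scale; cost/length optimality is guaranteed only where tested.
* ES detection assumes correct alignment and phasing; neither is
  performed here (phased input is consumed, not produced).
* Model-corrected distances (e.g. GTR+I+G) are out of scope; distances
  are uncorrected proportions, which understate divergence at high
  distances.
* Multispecies-coalescent support values are external inputs: the report
  keeps their slots but never computes them.
* The conspecificity block cut is threshold-based; on matrices without
  clean block structure the result is sensitive to the threshold, and the
  UPGMA ordering under tied scores is convention-dependent.
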