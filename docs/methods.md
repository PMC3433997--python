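# Methods

This note documents the models and estimators implemented in `beeroot`,
the design decisions taken where several conventions exist, what the
synthetic-data generator does and does not emulate, and the package's known
limitations.

## Data model

A panel is a samples × loci matrix of diploid alternate-allele counts
(`0`, `1`, `2`, missing), so every locus is biallelic by construction.
Each sample belongs to a subspecies, each subspecies to one of the four
lineage groups `M`, `C`, `O`, `A`, or to an outgroup species (sheet group
`OUTGROUP`).  All samples are treated as diploid by default; an optional
`ploidy` column in the sample sheet (haploid drones contribute one
chromosome) is honoured by the θ estimator's chromosome counts.

Loci with every call missing are rejected at load time.  Monomorphic loci
are retained in the matrix — they carry no within-panel polymorphism but
still inform distances to divergent outgroups — and are simply counted in
no polymorphism class.

## Polymorphism classification

Within a unit (subspecies or group), a locus is **polymorphic** when both
alleles occur among the unit's non-missing calls; **private** when it is
polymorphic in the unit and exactly one allele is observed in all other
units; **fixed-private** when the unit is monomorphic for an allele
observed in no other unit.  Fixed-private and polymorphic are disjoint by
construction (a fixed locus is not polymorphic).  "All other units" means
the other ingroup units: outgroup species are excluded from both sides of
the comparison for ingroup units, since the summary tables describe
variation within the species.  A unit with no non-missing call at a locus
contributes nothing at that locus; there is no imputation.

The group-sharing spectrum assigns each locus to the exact subset of the
four groups in which it is polymorphic (16 buckets including "none");
bucket counts sum to the locus total by construction.

## Watterson's θ

θ_W = S / a_n with S the unit's segregating-locus count and
a_n = Σ_{i=1}^{n−1} 1/i.  Missing data make n vary by locus while the
classical estimator wants one correction per unit; the default uses the
modal per-locus chromosome count (one number per unit, matching how a
single corrected value per subspecies is usually reported), and a
per-locus-corrected mode (θ = Σ_seg 1/a_{n_locus}) is available.  On a SNP
panel there is no sequence length, so θ is reported raw and per assayed
locus, never per base pair; only relative levels across units are
meaningful, and ascertainment of the panel affects all units' values
jointly.

## Distances

**Allele sharing.** For two diploids, per-locus identity by state is
(2 − |g_i − g_j|)/2 — the shared-allele proportion obtained by counting
allele multiset overlap — averaged over loci where both calls are present;
the distance is one minus that mean (plink's `1-ibs`).  A pair with no
jointly called locus is an error naming the pair; bootstrap replicates that
produce such a pair are discarded and redrawn (with a logged count).

**Weir–Cockerham F_ST.** The two-population moment estimator with the full
a/b/c variance-component decomposition, including the heterozygosity term;
loci are combined as the ratio of sums θ̂ = Σa / Σ(a+b+c).  A locus enters
the ratio when both populations have calls, the average per-locus sample
size exceeds one, n_c > 0, and the locus is not monomorphic across the
pair.  The raw estimate is reported faithfully (it can be negative, and is
when populations are effectively identical); flooring at zero happens only
when estimates are embedded into a distance matrix for tree building, with
floored pairs recorded.  F_ST itself is used as the distance (no
−ln(1−F_ST) transform).  Outgroup species can be kept as separate
populations or pooled into one via a flag; pooling is the practical choice
when single outgroup samples would make the pairwise estimator undefined
(n̄ = 1).

## Neighbor joining

Saitou–Nei agglomeration using the Studier–Keppler criterion
Q(i,j) = (m−2)d(i,j) − r_i − r_j.  Ties in Q are broken by the
lexicographically smallest pair of subtree representative labels (the
smallest leaf label each active node subtends), making output
deterministic for any input.  Branch lengths at a join come from the usual
half-difference formula; a negative estimate is clamped to zero with the
deficit moved to the sibling branch so the joined pair's distance is
preserved (relevant for non-metric inputs such as F_ST matrices).  The
final three-branch resolution clamps negatives to zero.

## Bootstrap, consensus, compatibility filter

Bootstrap replicates resample loci (columns) with replacement to the
original panel size, recompute the requested distance and rerun NJ;
everything is reproducible from a single integer seed.  The majority-rule
consensus keeps splits present in strictly more than the threshold
fraction (default 0.5) of replicates — such splits are automatically
pairwise compatible — with percent supports and mean branch lengths;
unresolved regions become polytomies.

The compatibility filter declares a replicate tree compatible with the
consensus when every consensus split is compatible with every split of the
tree (two bipartitions are compatible iff one of their four side
intersections is empty), then builds a second majority-rule consensus from
the incompatible remainder.  Note that for fully resolved replicate trees
this predicate is equivalent to "contains every consensus split", so with
many taxa the remainder is typically large; the partition is informative
for the small engineered tree sets it is designed to dissect, and the
placement tallies are reported both over all replicates and over the
remainder.

## Outgroup placement

The outgroup leaves must form one side of some edge of the tree (a single
connected subtree); otherwise the category is `other`.  Removing that
subtree exposes the attachment node, whose two remaining subtrees
bipartition the ingroup leaves.  If one side is exactly the leaves of
group X the category is `sister_to_X`; a proper subset of a single group
gives `within_X`; the split {A∪M} vs {C∪O} gives `between_AM_and_CO`;
anything else (including a polytomy at the attachment point) is `other`.
Classification depends only on topology — it is invariant to leaf order
and branch rescaling — and the per-replicate categories aggregate into
placement frequencies whose modal category serves as the root-position
summary.

## NeighborNet

Stage one builds a circular ordering of the taxa by agglomeration: taxa
start as singleton clusters; the pair of clusters to link minimises the
Studier–Keppler Q on cluster-averaged distances, and the specific nodes to
link minimise the same criterion evaluated on the linked clusters' nodes
with every other cluster collapsed to its average (this node-selection
rule is one of several consistent readings of the published scheme; it
reduces to plain NJ selection while all clusters are singletons).  Chains
longer than two nodes are immediately contracted by the 3→2 path reduction
with weights 2/3 and 1/3, and the recorded reductions are expanded in
reverse at the end to read off the ordering.

Stage two estimates weights for all n(n−1)/2 interval splits of the
ordering by least squares under non-negativity (Lawson–Hanson NNLS; a
bounded trust-region solver takes over above ~600 splits for speed).
Splits below a configurable epsilon (default 1e−9) are dropped.  On an
additive matrix the ordering embeds the generating tree and the fit
returns exactly the tree's splits with branch-length weights; on
conflicting data incompatible splits can carry weight simultaneously.
The induced split-system metric (sum of weights of separating splits)
provides the fit diagnostic.

## Synthetic panels

The generator draws, per locus, an ancestral frequency p ~ U(0.05, 0.95),
then drifts it down a fixed hierarchy with Balding–Nichols steps
(Beta(p(1−F)/F, (1−p)(1−F)/F); F = 0 copies, F = 1 fixes): ancestor →
super-clades (A,M) and (C,O) at `clade_drift` → groups at `group_drift`
(scalar or per-group) → subspecies at `subspecies_drift`.  Genotypes are
Binomial(2, freq).  Outgroup taxa are fixed at every locus, carrying the
rarer panel allele with probability `outgroup_divergence` and the common
allele otherwise, independently per outgroup species.  An admixed
subspecies draws each locus's frequency from one of two source groups
(source 1 with probability α) and then applies its own drift.

Default study conditions: 1,000 loci; 14 subspecies in four groups
(2 M, 2 C, 4 O, 6 A); four diploids per subspecies; three outgroup
species; clade drift 0.02, group drift 0.10, subspecies drift 0.05,
outgroup divergence 0.3.  These magnitudes were chosen once to sit in the
range of published honeybee lineage differentiation (between-group F_ST
roughly 0.1–0.3) while keeping every analysis fast on one CPU.  The
canonical taxon-exclusion scenario (`headline_config`) adds the A/M
hybrid `adm` (α = 0.5, carried in group A) and trims to three diploids per
subspecies and one per outgroup species.

**Why the hybrid needs its own drift.** Balding–Nichols drift is a
martingale: every population's expected frequency equals the ancestral
frequency, so a fixed-genotype outgroup is equidistant from all ingroup
populations in expectation regardless of their drift.  Its NJ attachment
is therefore governed by tree geometry — effectively long-branch
attraction toward the taxon with the largest net divergence — not by
genuine affinity.  A plain α = 0.5 hybrid is the most central taxon (small
net divergence) and repels the attachment.  The generator therefore gives
the admixed taxon a strong local drift of its own (default 0.75),
modelling a hybrid-origin population that has also passed through a severe
founder event.  That combination makes it the attachment magnet: with it
present the outgroup roots inside group A; with it excluded the root
releases to the central A+M | C+O edge and its neighbours.  This is the
mechanism by which the package reproduces, in sign, the motivating
robustness phenomenon.

**Planted counts.** Private loci are planted as a single heterozygote in
the target subspecies with every other sample homozygous reference;
fixed-private loci fix the target subspecies for the alternate allele.
When planting is requested the generator also repairs *chance* private or
fixed-private loci (one heterozygous call added in another group), so the
planted counts are exactly the table's counts — the bookkeeping that lets
recovery be asserted exactly per seed.

**Ascertainment.** The optional filter keeps loci whose minor-allele count
within a chosen discovery panel reaches a threshold, emulating SNP
discovery restricted to an unrepresentative (e.g. European) panel; the
retained-locus mask is recorded in the ground truth.

**What the generator does not emulate:** linkage and recombination (loci
are exchangeable and independent — appropriate for an unlinked SNP panel,
wrong for dense data), mutation since divergence, selection, and any
sequence-level realism.  Genotyping error and missingness are available
only as uniform random missingness.  Passing tests on these panels shows
the estimators and the robustness pipeline behave as designed under the
stated drift model; it does not certify behaviour under linked loci,
ascertainment schemes other than the one modelled, or real hybridisation
histories.

## Numerical choices

- NJ and consensus tie-breaks are label-lexicographic; all stochastic
  steps take explicit integer seeds (numpy `default_rng`).
- Consensus supports are stored at full precision and written to Newick as
  integer-rounded percentages (the conventional encoding).
- NeighborNet drops splits below 1e−9 by default; the additive round-trip
  is exact to ~1e−6 (NNLS tolerance), NJ recovery to 1e−9.
- F_ST's informative-locus rules (n̄ > 1, n_c > 0, not monomorphic) make
  the ratio of sums well defined; a pair with no informative locus raises
  rather than returning NaN.
- Bootstrap replicates with a degenerate distance matrix are redrawn, with
  the count reported, so replicate totals always match the request.

## Limitations

- The Weir–Cockerham implementation is the two-population biallelic case;
  there is no global multi-population F_ST, F_IS/F_IT, or CI machinery.
- The compatibility filter's predicate is split-wise compatibility; other
  reasonable readings of "compatible with the majority-rule solution"
  exist and would partition large replicate sets differently.
- NeighborNet's node-selection rule within chosen clusters is a documented
  interpretation (exact on tree metrics, validated on random additive
  matrices); orderings on heavily conflicting data may differ from other
  implementations.
- The placement classifier treats the outgroup as a unit; replicates where
  the outgroup species are not monophyletic are counted as `other` rather
  than resolved further.
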