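# Methods

This note documents the models, conventions and design choices behind
`fescuecp`, and what the synthetic panel does and does not emulate.

## Variant model

An alignment is a set of equal-length sequences over `{A,C,G,T,N,-}` with a
group label (morphotype or species) per taxon. Polymorphic loci come in
three classes:

* **snp** — a column with ≥ 2 distinct bases among non-gap, non-N taxa;
* **del1** — a single column gapped in ≥ 1 (but not all) taxa;
* **indel_multi** — a maximal run of ≥ 2 adjacent columns sharing one
  identical gap presence/absence pattern, merged into a single locus.

Coordinates are 0-based half-open column spans, which keeps merged-indel
arithmetic unambiguous. One SNP column is one locus and one merged indel is
one locus; this is the unit under which the panel's class counts
(129 + 25 + 13 = 167) are internally consistent. A column can host both a
substitution (among its non-gapped taxa) and a gap event; the caller emits
both records and flags the overlap rather than guessing a precedence.

**Between-group polymorphism** uses a fixed-difference rule: a locus counts
for the pair (a, b) when the allele sets of the two groups are disjoint and
both non-empty. Loci sharing any allele across the pair do not count, so
within-group variation degrades the count conservatively (each such locus is
logged). `N` never enters an allele set: missing data cannot create a
difference. The **similarity index** is `1 − n_between/n_total` with
`n_total` the panel-wide locus count; reported values are rounded half-up to
two decimals (matching how such tables are documented) while full precision is
kept internally.

## Diagnostic markers

A diagnostic indel is a gap-class locus at which all samples of one
morphotype share one state and all of the other the alternative state; the
default minimum event length of 2 restricts to multi-base indels, the
events resolvable as band shifts on an agarose gel. The strict rule
(tolerance 0) excludes any locus with a single discordant sample.

In-silico PCR matches the forward primer exactly on the given strand and
the reverse primer exactly as its reverse complement downstream; no
mismatches or degenerate bases are modelled, since the assays are designed
from the reference genome itself. Product length runs from the first base
of the forward site to the last base of the reverse site inclusive, the
convention under which expected amplicon sizes are stated. A primer binding
twice is an error (ambiguous amplification), a missing site an absent
product. Size-based genotyping assigns a sample to the rule window within
`tolerance` bases of its product length; windows must be separated by more
than twice the tolerance.

SSR genotypes are presence/absence calls per primer × accession × fragment.
A fragment discriminates two groups when fixed-present in one and
fixed-absent in the other (up to `tolerance` violating samples); a primer
is reported at ≥ `min_fragments` such fragments (default 2). The tolerance
defaults to 0 but is exposed because SSR presence calls are noisier than
chloroplast sequence states.

## Trees

The 0/1 marker matrix encodes each biallelic locus as one column
(1 = non-reference state, reference taken from a designated taxon, falling
back to the majority state where the reference is gapped or N), one column
per non-reference allele for multiallelic SNPs, and one column per indel
locus. Which binary coding a multiallelic site should receive is genuinely
open; one-column-per-non-reference-allele is this package's choice.

Nei–Li/Dice similarity is `2a/(2a+b+c)` over shared presences; shared
absences are excluded by the coefficient's definition, and rows with no
presences at all are defined as identical. Dice distance (1 − similarity)
is non-metric; triangle violations are expected and not asserted anywhere.

TN93 distances use empirical base frequencies estimated from each pair's
shared columns and pairwise deletion of gap/N columns. Pairwise (rather
than complete) deletion is deliberate: an indel-rich amplicon alignment
would lose most of its signal under complete deletion. Saturation (a
non-positive logarithm argument) raises an error naming the pair.

UPGMA merges the closest pair, updating distances as size-weighted
arithmetic means, with node height half the merge distance — hence
ultrametric by construction (tested to 1e-9 relative). Ties are broken by
the lexicographically smallest merged leaf-label set, making topologies
platform independent. Bootstrap resamples columns with replacement and maps
supports onto the original tree's bipartitions (not a consensus tree); the
support of a node is the percentage of replicate trees containing its leaf
set or the complement. All resampling flows from one seed.

A note on the two trees: on split-clean synthetic data the Dice tree's root
bipartition depends on the reference taxon used for binary encoding — the
reference taxon's group necessarily has an all-zero marker row and thus no
shared presences with anything, so it detaches at the root. The
Mediterranean+mairei clade itself is present with 100% support regardless;
the TN93 tree, which has no polarity convention, additionally places that
clade against all other taxa at the root. Real marker matrices are not
split-clean and do not show the detachment artefact as sharply.

## Median-joining networks and rho dating

Construction iterates until stable: (i) the ε-relaxed minimum spanning
network over the current nodes under weighted Hamming distance — an edge
qualifies when its length is within ε of the minimax path cost between its
endpoints, so ε = 0 gives exactly the union of all minimum spanning trees
of the current node set; (ii) for node triplets adjacent in that network,
the quasi-median (per-character majority, well defined for binary
characters; multi-state input is binarised per segregating state) is added
as a median vector when novel and of minimal connection cost in that round
(for binary majority medians the connection cost equals half the triplet's
pairwise distance sum); (iii) median vectors of degree ≤ 2 lying on no
shortest observed–observed path are removed. The default character weight
is a uniform 10 and ε defaults to 0; multiplying all weights by a constant
changes nothing, and edge mutation counts are always unweighted
differing-character counts.

Containment caveat: once a median vector is added it can lower the minimax
threshold between two observed haplotypes, so an observed-only MST edge
need not survive into the final network. The guaranteed (and tested)
invariant is that the ε = 0 network equals the union of all MSTs over its
final node set, verified against an independent cycle-property oracle; when
no medians are introduced this reduces to containment of every MST of the
input.

The rho statistic for an ancestral node and a descendant set is the
multiplicity-weighted mean shortest-path mutation count from the ancestor,
with `sd(rho) = sqrt(Σ_e l_e n_e²)/n` computed on the shortest-path tree
(l_e = edge mutation count, n_e = descendant lineages through the edge);
for a star of n tips at d mutations this gives sd = sqrt(d/n). Ties among
equal-length shortest paths are broken toward lexicographically smaller
predecessor labels for determinism, and reticulation near the ancestor
triggers a warning, since the SD then depends on the chosen tree. Ages are
rho × mutation rate (default 20,180 years per mutation, a user-supplied
constant for grass chloroplast DNA, not an estimate of this package);
reporting is in My to two decimals, with one extra decimal for SDs below
0.1 My.

## The synthetic panel

The packaged profile plants 167 loci on a 12-accession, six-group panel in
a 20,056-column alignment. Each locus carries a *split* — the subset of
groups fixed for the derived state — so every pairwise fixed-difference
count is the sum of split weights separating the pair. The reported
15-pair count table is not jointly realisable as such a split system (it
violates cut-metric constraints; an integer program over all 31 splits
shows a minimum total deviation of 26 loci under the 167-locus total), so
the preset uses the closest integer system, exact on the four headline
pairs (117, 2, 103 and 42 fixed differences). Exactly four multi-base
indels — 47, 32, 8 and 3 bp, the documented product-size differences of the
four diagnostic assays — separate the Continental and Mediterranean
morphotypes.

The generator draws an i.i.d. uniform A/C/G/T background (base composition
is irrelevant to every statistic tested), places loci uniformly without
overlap with at least one monomorphic spacer column between consecutive
loci (so adjacent gap loci with identical carrier sets cannot merge), and
plants indels as contiguous gap runs in the carrier taxa. A single RNG
stream per profile seed makes outputs byte-identical across runs. It never
emits columns gapped in all taxa and carries no rate heterogeneity,
recombination, within-group variation or sequencing error — so passing
tests demonstrate correct recovery of clean planted signal, not robustness
to the noise of real amplicon data.

The SSR fixture plants exactly 26 discriminating primers among 144, with
per-primer fragment counts 1 + Poisson(7.4) truncated to [1, 24] (mean
≈ 8.4, reproducing a ~1,200-marker table); chance discriminating pairs in
the remaining primers are repaired by flipping one presence call. Star
genealogies give each tip Poisson(λ) private derived characters, providing
a closed-form oracle for rho recovery.

## Problem sizes used in tests

Oracle-equivalence runs use 50 random 10 × 500 alignments; MST-union
checks use 50 random ≤ 7-haplotype sets; rho recovery uses 200 seeded
100-tip stars at λ = 32.29; tree bootstraps use 200 replicates on the
12-taxon panel — all panel-scale choices that keep the planted signal
saturated while remaining quick to run.
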