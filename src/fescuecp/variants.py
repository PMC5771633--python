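"""Polymorphic-locus calling and between-group similarity.

A locus is either a single substitution column (``snp``), a single-column gap
(``del1``), or a maximal run of adjacent columns sharing one identical gap
presence/absence pattern (``indel_multi``). Counting is per locus: one SNP
column is one locus and one merged multi-base indel is one locus, so the three
class counts sum to the total number of polymorphic loci.

The similarity index between two groups is

    S(a, b) = 1 - n_between(a, b) / n_total

where ``n_between`` counts loci at which the allele sets of the two groups are
disjoint (fixed differences) and ``n_total`` is the number of polymorphic loci
over the whole panel. Reported values are rounded half-up to two decimals;
full precision is kept internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .alignment import GAP, AlignedSequenceSet
from .errors import InputError, UndefinedIndexError

logger = logging.getLogger(__name__)

SNP = "snp"
DEL1 = "del1"
INDEL_MULTI = "indel_multi"


@dataclass
class VariantLocus:
    """One classified polymorphic locus.

    ``span`` is a 0-based half-open column interval. ``alleles`` maps each
    taxon to its state string: a base for SNPs, ``del<L>`` / ``ref`` for gap
    loci; ``N`` marks missing data and ``-`` marks taxa gapped at a SNP column
    (both excluded from allele-set comparisons). ``overlaps_gap`` flags a SNP
    column that also sits inside a gap locus.
    """

    span: tuple[int, int]
    var_class: str
    alleles: dict[str, str]
    overlaps_gap: bool = False

    @property
    def start(self) -> int:
        return self.span[0]

    @property
    def end(self) -> int:
        return self.span[1]

    @property
    def length(self) -> int:
        """Event length in bases: 1 for snp/del1, run length for indels."""
        return self.span[1] - self.span[0]

    def allele_set(self, taxa: list[str]) -> frozenset[str]:
        """Observed states among ``taxa``, excluding missing (N) and, for SNP
        loci, gapped taxa (their difference is carried by the gap locus)."""
        return frozenset(
            a for t in taxa if (a := self.alleles[t]) not in ("N", GAP)
        )

    def derived_groups(self, group_of: dict[str, str]) -> dict[str, frozenset[str]]:
        """Map each non-majority state to the set of groups fixed for it."""
        counts: dict[str, int] = {}
        for a in self.alleles.values():
            if a not in ("N", GAP):
                counts[a] = counts.get(a, 0) + 1
        if not counts:
            return {}
        major = max(sorted(counts), key=lambda s: counts[s])
        out: dict[str, set[str]] = {}
        by_group: dict[str, set[str]] = {}
        for t, a in self.alleles.items():
            by_group.setdefault(group_of[t], set()).add(a)
        for state in counts:
            if state == major:
                continue
            out[state] = {
                g for g, states in by_group.items() if states == {state}
            }
        return {s: frozenset(g) for s, g in out.items()}


@dataclass
class GroupComparison:
    """One row of the pairwise polymorphism/similarity table."""

    group_a: str
    group_b: str
    n_polymorphic: int
    n_total: int
    similarity: float = field(init=False)

    def __post_init__(self) -> None:
        self.similarity = similarity_index(self.n_polymorphic, self.n_total)

    @property
    def similarity_rounded(self) -> float:
        return round_half_up(self.similarity, 2)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.375 -> 0.38), as printed tables use."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _gap_patterns(aln: AlignedSequenceSet) -> np.ndarray:
    return aln.matrix() == GAP


def call_variants(aln: AlignedSequenceSet) -> list[VariantLocus]:
    """Identify and classify every polymorphic locus in an alignment.

    Returns loci sorted by span start (gap locus before a coincident SNP).
    A column carrying both a substitution among its non-gapped taxa and gaps
    yields two records: membership in the gap locus and a ``snp`` locus
    flagged ``overlaps_gap``.
    """
    m = aln.matrix()
    n_taxa, length = m.shape
    is_gap = m == GAP
    if length and is_gap.all(axis=0).any():
        raise InputError("alignment contains a column gapped in all taxa")

    loci: list[VariantLocus] = []

    # Gap loci: maximal runs of adjacent columns with identical, non-empty
    # gap presence/absence patterns.
    any_gap = is_gap.any(axis=0)
    j = 0
    while j < length:
        if not any_gap[j]:
            j += 1
            continue
        k = j + 1
        while k < length and any_gap[k] and (is_gap[:, k] == is_gap[:, j]).all():
            k += 1
        span = (j, k)
        cls = DEL1 if k - j == 1 else INDEL_MULTI
        alleles = {
            t: (f"del{k - j}" if is_gap[i, j] else "ref")
            for i, t in enumerate(aln.taxa)
        }
        loci.append(VariantLocus(span=span, var_class=cls, alleles=alleles))
        j = k

    # SNP columns: >= 2 distinct bases among non-gap, non-N taxa.
    for j in range(length):
        col = m[:, j]
        bases = set(col) - {GAP, "N"}
        if len(bases) >= 2:
            alleles = {t: col[i] for i, t in enumerate(aln.taxa)}
            locus = VariantLocus(
                span=(j, j + 1),
                var_class=SNP,
                alleles=alleles,
                overlaps_gap=bool(any_gap[j]),
            )
            if locus.overlaps_gap:
                logger.warning(
                    "column %d hosts both a substitution and a gap locus", j
                )
            loci.append(locus)

    loci.sort(key=lambda v: (v.start, v.var_class == SNP))
    return loci


def count_between_group(
    loci: list[VariantLocus], aln: AlignedSequenceSet, group_a: str, group_b: str
) -> int:
    """Number of loci at which two groups show a fixed difference.

    A locus counts when the allele sets of the two groups are disjoint (and
    both non-empty); loci where the groups share any allele do not count.
    Within-group variable loci therefore degrade conservatively and are
    logged.
    """
    ta, tb = aln.taxa_in(group_a), aln.taxa_in(group_b)
    n = 0
    for locus in loci:
        sa, sb = locus.allele_set(ta), locus.allele_set(tb)
        if sa and sb and sa.isdisjoint(sb):
            if len(sa) > 1 or len(sb) > 1:
                logger.info(
                    "locus %s counted as fixed difference despite within-group "
                    "variation (%s=%s, %s=%s)",
                    locus.span, group_a, sorted(sa), group_b, sorted(sb),
                )
            n += 1
    return n


def similarity_index(n_between: int, n_total: int) -> float:
    """Similarity index: 1 minus the fraction of all polymorphic loci that
    are fixed differences between the two groups."""
    if n_total <= 0:
        raise UndefinedIndexError(
            "similarity index undefined with zero total polymorphic loci"
        )
    if not 0 <= n_between <= n_total:
        raise InputError(
            f"n_between={n_between} outside [0, n_total={n_total}]"
        )
    return 1.0 - n_between / n_total


def comparison_table(
    loci: list[VariantLocus],
    aln: AlignedSequenceSet,
    pairs: list[tuple[str, str]] | None = None,
) -> list[GroupComparison]:
    """Pairwise polymorphism counts and similarity indices.

    ``pairs`` defaults to all unordered pairs of declared groups; the total
    locus count (the denominator) is identical across rows.
    """
    groups = aln.groups
    if pairs is None:
        pairs = [
            (groups[i], groups[j])
            for i in range(len(groups))
            for j in range(i + 1, len(groups))
        ]
    n_total = len(loci)
    return [
        GroupComparison(a, b, count_between_group(loci, aln, a, b), n_total)
        for a, b in pairs
    ]
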