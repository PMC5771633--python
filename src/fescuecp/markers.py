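"""Morphotype-diagnostic marker discovery and in-silico PCR.

Diagnostic chloroplast indels are loci at which every sample of one group
shares one state and every sample of the other group the alternative state.
In-silico PCR predicts amplicon sizes by exact primer matching (forward on
the plus strand, reverse as its reverse complement downstream); product
length is inclusive of both primer footprints, the convention under which
expected amplicon sizes are stated. SSR primers are scored by counting
fragments fixed-present in one group and fixed-absent in the other.

Tolerances default to 0 (strict fixation) but are exposed: SSR allele
presence is noisier than chloroplast sequence states, so a caller may allow
a bounded number of violating samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .alignment import AlignedSequenceSet
from .errors import (
    AmbiguousAmplificationError,
    ConfigurationError,
    InputError,
)
from .variants import DEL1, INDEL_MULTI, VariantLocus

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PrimerPair:
    """A named PCR primer pair with its expected product size in bases."""

    name: str
    forward: str
    reverse: str
    expected_size: int

    def __post_init__(self) -> None:
        if not self.forward or not self.reverse:
            raise InputError(f"primer {self.name!r} has an empty sequence")
        bad = (set(self.forward) | set(self.reverse)) - set("ACGT")
        if bad:
            raise InputError(
                f"primer {self.name!r} contains non-ACGT symbols {sorted(bad)}"
            )
        if self.expected_size <= max(len(self.forward), len(self.reverse)):
            raise InputError(
                f"primer {self.name!r}: expected_size must exceed primer length"
            )


@dataclass
class ProductPrediction:
    """Predicted amplification product of one primer pair on one template."""

    primer: str
    template: str
    product_length: int | None
    forward_start: int | None = None
    reverse_site_start: int | None = None

    @property
    def amplified(self) -> bool:
        return self.product_length is not None


@dataclass
class DiagnosticMarkerReport:
    """A locus or primer whose states separate two groups."""

    marker: str
    state_a: str
    state_b: str
    group_a: str
    group_b: str
    discriminating: bool
    n_violations: int = 0
    n_discriminating_fragments: int | None = None
    locus: VariantLocus | None = None


def find_diagnostic_indels(
    loci: list[VariantLocus],
    aln: AlignedSequenceSet,
    group_a: str,
    group_b: str,
    min_length: int = 2,
) -> list[DiagnosticMarkerReport]:
    """Indel loci fixed within and different between two groups.

    Only gap-class loci (``del1``/``indel_multi``) of event length >=
    ``min_length`` qualify; the default of 2 restricts to multi-base indels,
    the events resolvable as band-size shifts on a gel. A single discordant
    sample disqualifies a locus (strict rule).
    """
    ta, tb = aln.taxa_in(group_a), aln.taxa_in(group_b)
    reports = []
    for locus in loci:
        if locus.var_class not in (DEL1, INDEL_MULTI) or locus.length < min_length:
            continue
        sa = {locus.alleles[t] for t in ta}
        sb = {locus.alleles[t] for t in tb}
        if len(sa) == 1 and len(sb) == 1 and sa != sb:
            reports.append(
                DiagnosticMarkerReport(
                    marker=f"indel_{locus.start}_{locus.end}",
                    state_a=next(iter(sa)),
                    state_b=next(iter(sb)),
                    group_a=group_a,
                    group_b=group_b,
                    discriminating=True,
                    locus=locus,
                )
            )
    return reports


def in_silico_pcr(
    template: str, primer: PrimerPair, template_name: str = ""
) -> ProductPrediction:
    """Predict the amplification product of a primer pair on a template.

    The forward primer must match exactly on the given strand and the reverse
    primer exactly as its reverse complement downstream of the forward site.
    Product length runs from the first base of the forward site through the
    last base of the reverse site. Either site missing -> no product; either
    site matching more than once -> ambiguous amplification.
    """
    if "-" in template:
        raise InputError("template must be gap-free")
    fwd, rev_site = primer.forward, revcomp(primer.reverse)
    f_hits = _find_all(template, fwd)
    r_hits = _find_all(template, rev_site)
    if len(f_hits) > 1 or len(r_hits) > 1:
        raise AmbiguousAmplificationError(
            f"primer {primer.name!r} binds more than once "
            f"(forward x{len(f_hits)}, reverse x{len(r_hits)})"
        )
    if not f_hits or not r_hits:
        return ProductPrediction(primer.name, template=template_name, product_length=None)
    f0, r0 = f_hits[0], r_hits[0]
    if r0 < f0 + len(fwd):
        return ProductPrediction(primer.name, template=template_name, product_length=None)
    return ProductPrediction(
        primer=primer.name,
        template=template_name,
        product_length=r0 + len(rev_site) - f0,
        forward_start=f0,
        reverse_site_start=r0,
    )


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, start = [], 0
    while (i := haystack.find(needle, start)) != -1:
        hits.append(i)
        start = i + 1
    return hits


def genotype_by_size(
    predictions: dict[str, ProductPrediction],
    rule: dict[int, str],
    tolerance: int = 0,
) -> dict[str, str]:
    """Assign each template a group from its product size.

    ``rule`` maps a band size (bp) to a group label; a template is called for
    the rule entry within ``tolerance`` bases of its product length and
    ``"unknown"`` otherwise (including absent products). Rule sizes must be
    separated by more than twice the tolerance so windows cannot overlap.
    """
    sizes = sorted(rule)
    for s, t in zip(sizes, sizes[1:]):
        if t - s <= 2 * tolerance:
            raise ConfigurationError(
                f"rule sizes {s} and {t} overlap at tolerance {tolerance}"
            )
    calls = {}
    for name, pred in predictions.items():
        call = "unknown"
        if pred.amplified:
            for size, group in rule.items():
                if abs(pred.product_length - size) <= tolerance:
                    call = group
                    break
        calls[name] = call
    return calls


def score_ssr_discrimination(
    table: pd.DataFrame,
    group_of: dict[str, str],
    group_a: str,
    group_b: str,
    min_fragments: int = 2,
    tolerance: int = 0,
) -> list[DiagnosticMarkerReport]:
    """Score SSR primers for group-discriminating fragments.

    A fragment discriminates when it is present in all ``group_a`` samples
    and absent in all ``group_b`` samples (or vice versa), allowing up to
    ``tolerance`` violating samples. A primer is reported when its count of
    discriminating fragments reaches ``min_fragments``.

    ``table`` is long-form with columns primer, accession, fragment_id,
    present; missing presence calls raise with the offending cells listed.
    """
    acc_a = [a for a, g in group_of.items() if g == group_a]
    acc_b = [a for a, g in group_of.items() if g == group_b]
    if not acc_a or not acc_b:
        raise InputError(f"groups {group_a!r}/{group_b!r} absent from grouping")
    needed = set(acc_a) | set(acc_b)
    sub = table[table["accession"].isin(needed)]
    if sub["present"].isna().any():
        bad = sub[sub["present"].isna()][["primer", "accession", "fragment_id"]]
        raise InputError(f"missing presence calls:\n{bad.to_string(index=False)}")

    wide = sub.pivot_table(
        index=["primer", "fragment_id"],
        columns="accession",
        values="present",
        aggfunc="first",
    )
    missing_cells = wide[sorted(needed & set(wide.columns))].isna()
    if len(needed - set(wide.columns)) or missing_cells.any().any():
        raise InputError(
            "incomplete SSR table for target groups; missing accessions: "
            f"{sorted(needed - set(wide.columns))}"
        )

    reports = []
    for primer, block in wide.groupby(level="primer"):
        a = block[acc_a].to_numpy(dtype=int)
        b = block[acc_b].to_numpy(dtype=int)
        # violations for "present in a / absent in b" vs the reverse pattern
        viol_ab = (a == 0).sum(axis=1) + (b == 1).sum(axis=1)
        viol_ba = (a == 1).sum(axis=1) + (b == 0).sum(axis=1)
        disc = (viol_ab <= tolerance) | (viol_ba <= tolerance)
        n_disc = int(disc.sum())
        if n_disc >= min_fragments:
            reports.append(
                DiagnosticMarkerReport(
                    marker=str(primer),
                    state_a="present",
                    state_b="absent",
                    group_a=group_a,
                    group_b=group_b,
                    discriminating=True,
                    n_violations=int(
                        sum(min(x, y) for x, y in zip(viol_ab[disc], viol_ba[disc]))
                    ),
                    n_discriminating_fragments=n_disc,
                )
            )
    return reports
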