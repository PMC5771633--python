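"""Synthetic data generation with planted truth.

Everything downstream is exercised on alignments, amplicon templates, SSR
genotype tables and genealogies generated here, each accompanied by a truth
table so recovery can be asserted exactly.

The packaged "reference_panel" preset emulates the study panel: 12 taxa in six
groups (three tall fescue morphotypes plus three related Festuca species),
a 20,056-column chloroplast amplicon alignment carrying 167 planted loci
(129 substitutions, 25 single-base deletions, 13 multi-base indels of
3-47 bp), with each locus assigned a "split" -- the subset of groups fixed
for the derived state. The pairwise polymorphism counts among the 15 Table-2
style group pairs are not jointly realisable as a split system (they violate
cut-metric constraints), so the preset carries the L1-closest integer split
system with 167 loci, exact on the four headline pairs; see docs/methods.md.

Design notes: the ancestral background is i.i.d. uniform over A/C/G/T (base
composition is irrelevant to every statistic tested downstream); multi-base
indels are planted as contiguous gap runs in the carrier taxa; planted loci
are placed without overlap and separated by at least one monomorphic spacer
column so adjacent gap loci with identical carrier sets cannot merge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .alignment import AlignedSequenceSet
from .errors import InputError, SizingError
from .markers import PrimerPair, revcomp

BASES = np.array(list("ACGT"))

SNP = "snp"
DEL1 = "del1"
INDEL_MULTI = "indel_multi"


@dataclass(frozen=True)
class LocusSpec:
    """One planted locus: class, carrier groups (the split), event length."""

    var_class: str
    carriers: tuple[str, ...]
    length: int = 1

    def __post_init__(self) -> None:
        if self.var_class not in (SNP, DEL1, INDEL_MULTI):
            raise InputError(f"unknown variant class {self.var_class!r}")
        if self.var_class in (SNP, DEL1) and self.length != 1:
            raise InputError(f"{self.var_class} loci have length 1")
        if self.var_class == INDEL_MULTI and self.length < 2:
            raise InputError("multi-base indels need length >= 2")
        if not self.carriers:
            raise InputError("a planted locus needs at least one carrier group")


@dataclass
class PlantProfile:
    """Specification of a group-structured alignment with planted variants."""

    group_of: dict[str, str]
    loci: list[LocusSpec]
    alignment_length: int
    seed: int
    indel_length_range: tuple[int, int] = (3, 47)

    def __post_init__(self) -> None:
        groups = set(self.group_of.values())
        for spec in self.loci:
            unknown = set(spec.carriers) - groups
            if unknown:
                raise InputError(f"carrier groups {sorted(unknown)} not in profile")
            if set(spec.carriers) == groups:
                raise InputError(
                    "a locus fixed in every group is monomorphic; splits must be proper"
                )
            if spec.var_class == INDEL_MULTI and not (
                self.indel_length_range[0]
                <= spec.length
                <= self.indel_length_range[1]
            ):
                raise InputError(
                    f"indel length {spec.length} outside {self.indel_length_range}"
                )

    @property
    def n_taxa(self) -> int:
        return len(self.group_of)

    @property
    def n_snp(self) -> int:
        return sum(1 for s in self.loci if s.var_class == SNP)

    @property
    def n_del1(self) -> int:
        return sum(1 for s in self.loci if s.var_class == DEL1)

    @property
    def n_indel_multi(self) -> int:
        return sum(1 for s in self.loci if s.var_class == INDEL_MULTI)

    @property
    def n_loci(self) -> int:
        return len(self.loci)


def load_profile(path_or_name: str = "reference_panel") -> PlantProfile:
    """Load a profile from a YAML file path or a packaged preset name."""
    try:
        text = open(path_or_name).read()
    except OSError:
        ref = resources.files("fescuecp") / "presets" / f"{path_or_name}.yaml"
        text = ref.read_text()
    cfg = yaml.safe_load(text)
    loci = [
        LocusSpec(
            var_class=entry["class"],
            carriers=tuple(entry["split"]),
            length=int(entry.get("length", 1)),
        )
        for entry in cfg["loci"]
        for _ in range(int(entry.get("count", 1)))
    ]
    return PlantProfile(
        group_of=dict(cfg["group_of"]),
        loci=loci,
        alignment_length=int(cfg["alignment_length"]),
        seed=int(cfg["seed"]),
        indel_length_range=tuple(cfg.get("indel_length_range", (3, 47))),
    )


def reference_panel_profile(seed: int | None = None) -> PlantProfile:
    """The packaged 12-taxon, 167-locus study-panel preset."""
    profile = load_profile("reference_panel")
    if seed is not None:
        profile.seed = seed
    return profile


def generate_alignment(
    profile: PlantProfile,
) -> tuple[AlignedSequenceSet, pd.DataFrame]:
    """Realise a profile as a gapped alignment plus its truth table.

    Every planted locus is fixed derived within its carrier groups and
    ancestral elsewhere; all other columns are monomorphic. Deterministic for
    a fixed profile and seed. The truth table has one row per planted locus
    with 0-based half-open column spans.
    """
    rng = np.random.default_rng(profile.seed)
    taxa = list(profile.group_of)
    n_loci = len(profile.loci)
    lengths = np.array([s.length for s in profile.loci], dtype=int)
    # one spacer column between consecutive loci prevents run merging
    needed = int(lengths.sum()) + max(0, n_loci - 1)
    if needed > profile.alignment_length:
        raise SizingError(
            f"{n_loci} planted loci need {needed} columns, "
            f"profile allows {profile.alignment_length}"
        )

    order = rng.permutation(n_loci) if n_loci else np.array([], dtype=int)
    free = profile.alignment_length - needed
    if n_loci:
        # stars-and-bars: distinct sorted cut positions <-> free-column gaps
        slots = np.sort(rng.choice(free + n_loci, size=n_loci, replace=False))
        extra_gap = np.diff(slots, prepend=-1) - 1  # free columns before each locus
    else:
        extra_gap = np.array([], dtype=int)

    ancestral = rng.choice(BASES, size=profile.alignment_length)
    matrix = np.tile(ancestral, (len(taxa), 1))

    records = []
    pos = 0
    for rank, locus_idx in enumerate(order):
        spec = profile.loci[locus_idx]
        pos += int(extra_gap[rank]) + (1 if rank > 0 else 0)
        start, end = pos, pos + spec.length
        carrier_rows = [
            i for i, t in enumerate(taxa) if profile.group_of[t] in spec.carriers
        ]
        if spec.var_class == SNP:
            anc = ancestral[start]
            derived = rng.choice([b for b in "ACGT" if b != anc])
            matrix[carrier_rows, start] = derived
            derived_state, anc_state = derived, anc
        else:
            matrix[np.ix_(carrier_rows, range(start, end))] = "-"
            derived_state = f"del{spec.length}"
            anc_state = "ref"
        records.append(
            {
                "start": start,
                "end": end,
                "var_class": spec.var_class,
                "length": spec.length,
                "carriers": ";".join(sorted(spec.carriers)),
                "derived_state": derived_state,
                "ancestral_state": anc_state,
            }
        )
        pos = end

    truth = (
        pd.DataFrame.from_records(
            records,
            columns=[
                "start", "end", "var_class", "length",
                "carriers", "derived_state", "ancestral_state",
            ],
        )
        .sort_values("start")
        .reset_index(drop=True)
    )
    sequences = {t: "".join(matrix[i]) for i, t in enumerate(taxa)}
    aln = AlignedSequenceSet(taxa=taxa, group_of=dict(profile.group_of), sequences=sequences)
    return aln, truth


# ---------------------------------------------------------------------------
# Amplicon templates for in-silico PCR


def generate_amplicon_templates(
    primer: PrimerPair,
    indel_length: int,
    groups: tuple[str, str],
    seed: int = 0,
    flank: int = 60,
) -> dict[str, str]:
    """Two templates identical except for an insertion between primer sites.

    The first group's template carries an insertion of ``indel_length`` bases
    strictly between the primer binding sites; the second group's product
    length equals ``primer.expected_size``. Both templates contain each primer
    site exactly once.
    """
    if indel_length < 0:
        raise InputError("indel_length must be >= 0")
    rng = np.random.default_rng(seed)
    inner_len = primer.expected_size - len(primer.forward) - len(primer.reverse)
    if inner_len < 1:
        raise InputError("expected_size leaves no room between primer sites")
    for _ in range(100):
        inner = "".join(rng.choice(BASES, size=inner_len))
        insert = "".join(rng.choice(BASES, size=indel_length))
        left = "".join(rng.choice(BASES, size=flank))
        right = "".join(rng.choice(BASES, size=flank))
        cut = inner_len // 2
        short = left + primer.forward + inner + revcomp(primer.reverse) + right
        long = (
            left
            + primer.forward
            + inner[:cut]
            + insert
            + inner[cut:]
            + revcomp(primer.reverse)
            + right
        )
        ok = all(
            t.count(site) == 1
            for t in (short, long)
            for site in (primer.forward, revcomp(primer.reverse))
        )
        if ok:
            return {groups[0]: long, groups[1]: short}
    raise SizingError("could not place unique primer sites; use longer primers")


def nftchl45_fixture(seed: int = 466687) -> tuple[PrimerPair, dict[str, str]]:
    """Synthetic stand-in for the NFTCHL45 morphotype assay.

    The real primer sequences are not reported in machine-readable form, so
    a deterministic synthetic primer pair is generated; the planted geometry
    matches the documented assay: a 703 bp Continental product and a 750 bp
    Mediterranean product (47 bp insertion between the primer sites).
    """
    rng = np.random.default_rng(seed)
    primer = PrimerPair(
        name="NFTCHL45",
        forward="".join(rng.choice(BASES, size=21)),
        reverse="".join(rng.choice(BASES, size=21)),
        expected_size=703,
    )
    templates = generate_amplicon_templates(
        primer, indel_length=47, groups=("Mediterranean", "Continental"), seed=seed
    )
    return primer, templates


# ---------------------------------------------------------------------------
# SSR genotype tables


def generate_ssr_table(
    n_primers: int,
    fragments_per_primer: tuple[int, int],
    n_discriminating_primers: int,
    grouping: dict[str, str],
    target_groups: tuple[str, str],
    seed: int,
    mean_fragments: float = 8.4,
    p_present: float = 0.55,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Presence/absence SSR genotypes with planted discriminating primers.

    Exactly ``n_discriminating_primers`` primers carry >= 2 fragments fixed
    present in one target group and fixed absent in the other; no remaining
    primer has two such fragments (chance pairs are repaired by flipping one
    presence call). Fragment counts per primer are 1 + Poisson, truncated to
    ``fragments_per_primer``; the default mean reproduces the study-scale
    table (144 primers, 1-24 fragments, ~1,212 markers).

    Returns the long-form table (primer, accession, fragment_id, size_bp,
    present) and a truth table of planted discriminating fragments.
    """
    if n_discriminating_primers > n_primers:
        raise SizingError("more discriminating primers requested than primers")
    lo, hi = fragments_per_primer
    if lo < 1 or hi < lo:
        raise SizingError(f"invalid fragment range {fragments_per_primer}")
    if n_discriminating_primers and hi < 2:
        raise SizingError("discriminating primers need >= 2 fragments")
    ga, gb = target_groups
    acc_a = [t for t, g in grouping.items() if g == ga]
    acc_b = [t for t, g in grouping.items() if g == gb]
    if not acc_a or not acc_b:
        raise InputError(f"target groups {target_groups} not found in grouping")

    rng = np.random.default_rng(seed)
    accessions = list(grouping)
    primers = [f"nffa{i + 1:03d}" for i in range(n_primers)]
    disc = set(rng.choice(n_primers, size=n_discriminating_primers, replace=False))

    rows = []
    truth_rows = []
    for p_idx, primer in enumerate(primers):
        n_frag = 1 + int(rng.poisson(mean_fragments - 1))
        n_frag = min(max(n_frag, lo), hi)
        if p_idx in disc:
            n_frag = max(n_frag, 2)
        present = rng.random((n_frag, len(accessions))) < p_present
        col = {a: i for i, a in enumerate(accessions)}
        ia = [col[a] for a in acc_a]
        ib = [col[a] for a in acc_b]

        def discriminating_fragments() -> list[int]:
            out = []
            for f in range(n_frag):
                a_all, b_all = present[f, ia].all(), present[f, ib].all()
                a_none, b_none = ~present[f, ia].any(), ~present[f, ib].any()
                if (a_all and b_none) or (b_all and a_none):
                    out.append(f)
            return out

        if p_idx in disc:
            planted = list(rng.choice(n_frag, size=2, replace=False))
            side = rng.random() < 0.5
            for f in planted:
                present[f, ia] = side
                present[f, ib] = not side
            for f in planted:
                truth_rows.append({"primer": primer, "fragment_id": f + 1})
        else:
            # repair chance pairs: a non-discriminating primer may keep at
            # most one fixed fragment
            frags = discriminating_fragments()
            while len(frags) >= 2:
                f = frags[-1]
                present[f, ia[0]] = not present[f, ia[0]]
                frags = discriminating_fragments()

        sizes = rng.choice(np.arange(100, 400), size=n_frag, replace=False)
        for f in range(n_frag):
            for a in accessions:
                rows.append(
                    {
                        "primer": primer,
                        "accession": a,
                        "fragment_id": f + 1,
                        "size_bp": int(sizes[f]),
                        "present": int(present[f, col[a]]),
                    }
                )

    table = pd.DataFrame.from_records(rows)
    truth = pd.DataFrame.from_records(
        truth_rows, columns=["primer", "fragment_id"]
    )
    return table, truth


def reference_ssr_table(seed: int = 1212) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The packaged study-scale SSR fixture: 144 primers over the 12-taxon
    panel, 26 planted Continental/Mediterranean-discriminating primers."""
    profile = reference_panel_profile()
    return generate_ssr_table(
        n_primers=144,
        fragments_per_primer=(1, 24),
        n_discriminating_primers=26,
        grouping=profile.group_of,
        target_groups=("Continental", "Mediterranean"),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Genealogies for rho recovery


def simulate_star_genealogy(
    n_tips: int,
    expected_mutations: float,
    seed: int,
    forced_counts: list[int] | None = None,
) -> pd.DataFrame:
    """Binary haplotype matrix from a star genealogy.

    Each tip carries Poisson(``expected_mutations``) private derived
    characters; the ancestor (row ``"ancestor"``) is all-ancestral. With
    ``forced_counts`` the per-tip mutation counts are fixed instead of drawn.
    """
    if n_tips < 2:
        raise InputError("a star genealogy needs at least two tips")
    rng = np.random.default_rng(seed)
    if forced_counts is not None:
        if len(forced_counts) != n_tips:
            raise InputError("forced_counts length must equal n_tips")
        counts = np.asarray(forced_counts, dtype=int)
    else:
        counts = rng.poisson(expected_mutations, size=n_tips)
    total = int(counts.sum())
    mat = np.zeros((n_tips + 1, total), dtype=int)
    offset = 0
    for i, c in enumerate(counts):
        mat[i + 1, offset : offset + c] = 1
        offset += c
    index = ["ancestor"] + [f"tip{i + 1}" for i in range(n_tips)]
    cols = [f"m{j + 1}" for j in range(total)]
    return pd.DataFrame(mat, index=index, columns=cols)
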