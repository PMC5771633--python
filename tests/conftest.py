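"""Shared fixtures: the study-panel profile and independent test oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from fescuecp import call_variants, synthetic
from fescuecp.alignment import AlignedSequenceSet

MED_MAIREI_TAXA = frozenset(
    {"Prosper", "Resolute", "FlechaMaxQ", "PI283312", "PI283313"}
)

# documented pairwise polymorphism counts and 2-dp similarity indices
PANEL_PAIR_COUNTS = [
    ("F_glaucescens", "Continental", 5, 0.97),
    ("F_glaucescens", "Rhizomatous", 2, 0.99),
    ("F_glaucescens", "Mediterranean", 100, 0.40),
    ("F_pratensis", "Continental", 42, 0.75),
    ("F_pratensis", "F_glaucescens", 44, 0.74),
    ("F_pratensis", "Rhizomatous", 45, 0.73),
    ("F_pratensis", "Mediterranean", 117, 0.30),
    ("F_mairei", "Mediterranean", 57, 0.66),
    ("F_mairei", "Rhizomatous", 101, 0.40),
    ("F_mairei", "Continental", 102, 0.39),
    ("F_mairei", "F_glaucescens", 102, 0.39),
    ("F_mairei", "F_pratensis", 106, 0.37),
    ("Continental", "Mediterranean", 103, 0.38),
    ("Rhizomatous", "Continental", 5, 0.97),
    ("Rhizomatous", "Mediterranean", 105, 0.37),
]


@pytest.fixture(scope="session")
def panel_profile():
    return synthetic.reference_panel_profile()


@pytest.fixture(scope="session")
def panel_alignment(panel_profile):
    return synthetic.generate_alignment(panel_profile)


@pytest.fixture(scope="session")
def panel_loci(panel_alignment):
    aln, _ = panel_alignment
    return call_variants(aln)


@pytest.fixture(scope="session")
def mini_profile():
    """Small, fast profile with the same six groups (one taxon each except
    two Mediterranean) and a handful of loci of every class."""
    group_of = {
        "p1": "F_pratensis",
        "m1": "F_mairei",
        "g1": "F_glaucescens",
        "r1": "Rhizomatous",
        "e1": "Mediterranean",
        "e2": "Mediterranean",
        "c1": "Continental",
    }
    loci = (
        [synthetic.LocusSpec("snp", ("Mediterranean", "F_mairei")) for _ in range(6)]
        + [synthetic.LocusSpec("snp", ("F_pratensis",)) for _ in range(3)]
        + [synthetic.LocusSpec("del1", ("Mediterranean",)) for _ in range(2)]
        + [
            synthetic.LocusSpec("indel_multi", ("Mediterranean", "F_mairei"), 5),
            synthetic.LocusSpec("indel_multi", ("F_glaucescens", "Rhizomatous"), 8),
        ]
    )
    return synthetic.PlantProfile(
        group_of=group_of, loci=loci, alignment_length=2000, seed=11
    )


def random_gappy_alignment(
    rng: np.random.Generator,
    n_taxa: int = 6,
    length: int = 200,
    p_snp: float = 0.05,
    n_gap_runs: int = 4,
    max_run: int = 6,
) -> AlignedSequenceSet:
    """Random alignment with substitutions and gap runs; no all-gap columns."""
    bases = np.array(list("ACGT"))
    anc = rng.choice(bases, size=length)
    m = np.tile(anc, (n_taxa, 1))
    for j in np.where(rng.random(length) < p_snp)[0]:
        taxon = rng.integers(n_taxa)
        m[taxon, j] = rng.choice([b for b in "ACGT" if b != anc[j]])
    for _ in range(n_gap_runs):
        t = rng.integers(n_taxa)
        run = int(rng.integers(1, max_run + 1))
        start = int(rng.integers(0, length - run))
        m[t, start : start + run] = "-"
    # repair any column that became all-gap
    for j in np.where((m == "-").all(axis=0))[0]:
        m[0, j] = anc[j]
    taxa = [f"t{i}" for i in range(n_taxa)]
    groups = {t: f"grp{i % 3}" for i, t in enumerate(taxa)}
    return AlignedSequenceSet(
        taxa=taxa,
        group_of=groups,
        sequences={t: "".join(m[i]) for i, t in enumerate(taxa)},
    )


def brute_force_variant_scan(aln: AlignedSequenceSet):
    """Independent per-column scan + run merging oracle.

    Returns a set of (start, end, class) tuples; SNP columns are scanned
    over non-gap, non-N taxa, gap loci merge adjacent columns whose set of
    gapped taxa is identical.
    """
    cols = [aln.column(j) for j in range(aln.length)]
    records = set()
    for j, col in enumerate(cols):
        bases = {b for b in col.values() if b not in "-N"}
        if len(bases) >= 2:
            records.add((j, j + 1, "snp"))
    gap_sets = [
        frozenset(t for t, b in col.items() if b == "-") for col in cols
    ]
    j = 0
    for key, grp in itertools.groupby(range(aln.length), key=lambda j: gap_sets[j]):
        block = list(grp)
        if key:
            cls = "del1" if len(block) == 1 else "indel_multi"
            records.add((block[0], block[-1] + 1, cls))
    return records
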