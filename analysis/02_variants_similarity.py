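#!/usr/bin/env python
"""Call variants and compute the pairwise similarity-index table.

Reads the panel written by 01_simulate_panel.py, classifies every
polymorphic locus (SNP / single-base deletion / merged multi-base indel),
and writes the 15-row between-group polymorphism and similarity table.

Writes results/variants.tsv and results/comparison_table.csv.
"""

from collections import Counter
from pathlib import Path

from fescuecp import call_variants, comparison_table, io

PANEL = Path("results/panel")


def main() -> None:
    aln = io.read_alignment_fasta(PANEL / "alignment.fasta", PANEL / "groups.tsv")
    loci = call_variants(aln)
    io.write_variant_table(loci, aln, "results/variants.tsv")
    counts = Counter(v.var_class for v in loci)
    print(f"{len(loci)} polymorphic loci: {dict(counts)}")

    rows = comparison_table(loci, aln)
    io.write_comparison_table(rows, "results/comparison_table.csv")
    for r in sorted(rows, key=lambda r: r.n_polymorphic):
        print(
            f"{r.group_a:>14} vs {r.group_b:<14} "
            f"{r.n_polymorphic:4d} loci  similarity {r.similarity_rounded:.2f}"
        )


if __name__ == "__main__":
    main()
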