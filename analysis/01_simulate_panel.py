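#!/usr/bin/env python
"""Generate the synthetic study panel.

Realises the packaged 12-accession profile (six groups: Continental,
Mediterranean and Rhizomatous tall fescue plus F. pratensis, F. glaucescens
and F. mairei) as a 20,056-column chloroplast-amplicon alignment carrying
167 planted loci, together with its truth table, and the 144-primer SSR
genotype fixture. Everything downstream reads these files.

Writes results/panel/{alignment.fasta, groups.tsv, truth_table.tsv,
ssr_table.tsv, ssr_truth.tsv}.
"""

from pathlib import Path

from fescuecp import io, synthetic

OUT = Path("results/panel")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    profile = synthetic.reference_panel_profile()
    aln, truth = synthetic.generate_alignment(profile)
    io.write_alignment_fasta(aln, OUT / "alignment.fasta", OUT / "groups.tsv")
    io.write_table(truth, OUT / "truth_table.tsv")
    print(
        f"alignment: {len(aln.taxa)} taxa x {aln.length} columns, "
        f"{len(truth)} planted loci "
        f"({(truth.var_class == 'snp').sum()} snp, "
        f"{(truth.var_class == 'del1').sum()} del1, "
        f"{(truth.var_class == 'indel_multi').sum()} indel_multi)"
    )
    ssr, ssr_truth = synthetic.reference_ssr_table()
    io.write_table(ssr, OUT / "ssr_table.tsv")
    io.write_table(ssr_truth, OUT / "ssr_truth.tsv")
    n_markers = len(ssr[["primer", "fragment_id"]].drop_duplicates())
    print(
        f"ssr table: {ssr['primer'].nunique()} primers, {n_markers} markers, "
        f"{ssr_truth['primer'].nunique()} planted discriminating primers"
    )


if __name__ == "__main__":
    main()
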