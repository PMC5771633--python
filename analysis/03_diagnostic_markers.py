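#!/usr/bin/env python
"""Discover morphotype-diagnostic markers and genotype a blind panel.

Three marker screens on the simulated panel:
  1. chloroplast indels fixed between the Continental and Mediterranean
     morphotypes (multi-base events a gel can resolve),
  2. an in-silico PCR assay on the packaged NFTCHL45-style fixture,
     genotyping ten blind templates plus two controls by band size,
  3. SSR primers with at least two fragments fixed-present in one
     morphotype and fixed-absent in the other.

Writes results/diagnostic_indels.tsv, results/nftchl45_calls.tsv and
results/ssr_discrimination.tsv.
"""

from pathlib import Path

import pandas as pd

from fescuecp import (
    call_variants,
    find_diagnostic_indels,
    genotype_by_size,
    in_silico_pcr,
    io,
    score_ssr_discrimination,
    synthetic,
)

PANEL = Path("results/panel")


def main() -> None:
    aln = io.read_alignment_fasta(PANEL / "alignment.fasta", PANEL / "groups.tsv")
    loci = call_variants(aln)

    reports = find_diagnostic_indels(
        loci, aln, "Continental", "Mediterranean", min_length=2
    )
    pd.DataFrame.from_records(
        [
            {
                "marker": r.marker,
                "length_bp": r.locus.length,
                "Continental": r.state_a,
                "Mediterranean": r.state_b,
            }
            for r in reports
        ]
    ).to_csv("results/diagnostic_indels.tsv", sep="\t", index=False)
    print(
        f"{len(reports)} diagnostic indels "
        f"(lengths {sorted(r.locus.length for r in reports)} bp)"
    )

    # blind-panel genotyping with the indel-spanning amplicon assay:
    # ten unknowns drawn from the Continental template plus both controls
    primer, templates = synthetic.nftchl45_fixture()
    panel = {f"unknown_{i + 1}": templates["Continental"] for i in range(10)}
    panel["control_Mediterranean"] = templates["Mediterranean"]
    panel["control_Continental"] = templates["Continental"]
    preds = {
        name: in_silico_pcr(seq, primer, template_name=name)
        for name, seq in panel.items()
    }
    calls = genotype_by_size(
        preds, rule={750: "Mediterranean", 703: "Continental"}, tolerance=2
    )
    pd.DataFrame(
        [
            {
                "sample": name,
                "product_bp": preds[name].product_length,
                "call": call,
            }
            for name, call in calls.items()
        ]
    ).to_csv("results/nftchl45_calls.tsv", sep="\t", index=False)
    n_con = sum(c == "Continental" for c in calls.values())
    print(
        f"NFTCHL45 assay: {n_con}/{len(calls)} samples called Continental "
        f"(bands {preds['control_Continental'].product_length} vs "
        f"{preds['control_Mediterranean'].product_length} bp)"
    )

    ssr = io.read_table(PANEL / "ssr_table.tsv")
    group_of = io.read_group_map(PANEL / "groups.tsv")
    ssr_reports = score_ssr_discrimination(
        ssr, group_of, "Continental", "Mediterranean", min_fragments=2, tolerance=0
    )
    pd.DataFrame.from_records(
        [
            {
                "primer": r.marker,
                "n_discriminating_fragments": r.n_discriminating_fragments,
            }
            for r in ssr_reports
        ]
    ).to_csv("results/ssr_discrimination.tsv", sep="\t", index=False)
    print(f"{len(ssr_reports)} SSR primers with >= 2 discriminating fragments")


if __name__ == "__main__":
    main()
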