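"""Standard-format input/output.

Alignments travel as gapped FASTA plus a two-column taxon/group TSV; variant
and SSR tables as TSV; comparison tables as CSV; trees as Newick with
integer support labels; networks as GML (median flags and mutation counts
preserved). Every writer/reader pair round-trips.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import dendropy

from .alignment import AlignedSequenceSet
from .errors import ParseError
from .network import HaplotypeNetwork
from .phylo import Clade, to_newick
from .variants import GroupComparison, VariantLocus


# -- alignments -------------------------------------------------------------


def read_group_map(path: str | Path) -> dict[str, str]:
    group_of = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{ln}: expected 'taxon<TAB>group'")
            group_of[parts[0]] = parts[1]
    return group_of


def write_group_map(group_of: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for taxon, group in group_of.items():
            fh.write(f"{taxon}\t{group}\n")


def read_alignment_fasta(
    fasta_path: str | Path, group_map_path: str | Path
) -> AlignedSequenceSet:
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ParseError(f"{fasta_path}: no FASTA records")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        ref = len(records[0].seq)
        bad = [r.id for r in records if len(r.seq) != ref]
        raise ParseError(
            f"{fasta_path}: ragged alignment, deviating sequences: {bad}"
        )
    group_of = read_group_map(group_map_path)
    taxa = [r.id for r in records]
    missing = [t for t in taxa if t not in group_of]
    if missing:
        raise ParseError(f"{group_map_path}: no group for taxa {missing}")
    return AlignedSequenceSet(
        taxa=taxa,
        group_of={t: group_of[t] for t in taxa},
        sequences={r.id: str(r.seq).upper() for r in records},
    )


def write_alignment_fasta(
    aln: AlignedSequenceSet, fasta_path: str | Path, group_map_path: str | Path | None = None
) -> None:
    records = [
        SeqRecord(Seq(aln.sequences[t]), id=t, description="") for t in aln.taxa
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    if group_map_path is not None:
        write_group_map(aln.group_of, group_map_path)


# -- tables -----------------------------------------------------------------


def write_variant_table(
    loci: list[VariantLocus], aln: AlignedSequenceSet, path: str | Path
) -> None:
    rows = []
    for locus in loci:
        row = {
            "span_start": locus.start,
            "span_end": locus.end,
            "class": locus.var_class,
            "overlaps_gap": int(locus.overlaps_gap),
        }
        for t in aln.taxa:
            row[t] = locus.alleles[t]
        rows.append(row)
    pd.DataFrame.from_records(rows).to_csv(path, sep="\t", index=False)


def write_comparison_table(rows: list[GroupComparison], path: str | Path) -> None:
    pd.DataFrame.from_records(
        [
            {
                "group_1": r.group_a,
                "group_2": r.group_b,
                "polymorphic_loci": r.n_polymorphic,
                "total_loci": r.n_total,
                "similarity_index": f"{r.similarity_rounded:.2f}",
            }
            for r in rows
        ]
    ).to_csv(path, index=False)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df.to_csv(path, sep=sep, index=index)


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, index_col=index_col)


# -- trees ------------------------------------------------------------------


def write_newick(tree: Clade, path: str | Path, with_support: bool = True) -> None:
    Path(path).write_text(to_newick(tree, with_support=with_support) + "\n")


def read_newick(path: str | Path) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            path=str(path), schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises assorted parse errors
        raise ParseError(f"{path}: {exc}") from exc


# -- networks ---------------------------------------------------------------


def write_gml(net: HaplotypeNetwork, path: str | Path) -> None:
    g = nx.Graph()
    for n, d in net.graph.nodes(data=True):
        g.add_node(
            n,
            is_median=int(d["is_median"]),
            taxa=";".join(d["taxa"]),
            multiplicity=int(d["multiplicity"]),
        )
    for u, v, d in net.graph.edges(data=True):
        g.add_edge(u, v, mutations=int(d["mutations"]), weight=float(d["weight"]))
    nx.write_gml(g, str(path))


def read_gml(path: str | Path) -> HaplotypeNetwork:
    g = nx.read_gml(str(path))
    out = nx.Graph()
    for n, d in g.nodes(data=True):
        taxa = [t for t in str(d.get("taxa", "")).split(";") if t]
        out.add_node(
            n,
            is_median=bool(d["is_median"]),
            taxa=taxa,
            multiplicity=int(d["multiplicity"]),
            haplotype=(),
        )
    for u, v, d in g.edges(data=True):
        out.add_edge(u, v, mutations=int(d["mutations"]), weight=float(d["weight"]))
    return HaplotypeNetwork(graph=out)


def write_network_edges(net: HaplotypeNetwork, path: str | Path) -> None:
    rows = [
        {
            "node_a": u,
            "node_b": v,
            "mutations": int(d["mutations"]),
            "a_is_median": int(net.graph.nodes[u]["is_median"]),
            "b_is_median": int(net.graph.nodes[v]["is_median"]),
        }
        for u, v, d in net.graph.edges(data=True)
    ]
    pd.DataFrame.from_records(
        rows, columns=["node_a", "node_b", "mutations", "a_is_median", "b_is_median"]
    ).to_csv(path, sep="\t", index=False)
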