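"""End-to-end orchestration.

A run is configured by a :class:`PipelineConfig` (YAML-loadable), consumes
either real inputs (alignment FASTA + group map, optionally primer and SSR
tables) or a synthetic profile, and executes the enabled stages in
dependency order:

    variants -> comparison table / diagnostic indels
    SSR table -> discrimination scoring
    variants -> binary matrix -> Dice/UPGMA bootstrap tree
    alignment -> TN93/UPGMA bootstrap tree
    binary matrix -> median-joining network -> rho clade ages

Identical configuration and seed produce byte-identical artifacts; the run
log records every parameter.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import io, synthetic
from .alignment import AlignedSequenceSet
from .errors import InputError
from .markers import find_diagnostic_indels, score_ssr_discrimination
from .network import median_joining, rho_age
from .phylo import bootstrap_support, encode_binary
from .variants import call_variants, comparison_table

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Inputs, stage toggles and parameters for one pipeline run."""

    output_dir: str = "results"
    # exactly one input mode
    alignment_fasta: str | None = None
    group_map: str | None = None
    ssr_table: str | None = None
    synthetic_profile: str | None = None  # preset name or YAML path
    # stages
    run_variants: bool = True
    run_comparisons: bool = True
    run_diagnostics: bool = True
    run_ssr: bool = True
    run_trees: bool = True
    run_network: bool = True
    # parameters
    seed: int | None = None
    bootstrap_replicates: int = 1000
    epsilon: int = 0
    weight: float = 10.0
    mutation_rate: float = 20180.0
    min_indel_length: int = 2
    ssr_min_fragments: int = 2
    ssr_tolerance: int = 0
    diagnostic_groups: tuple[str, str] = ("Continental", "Mediterranean")
    reference_taxon: str | None = None
    ancestral_node: str | None = None  # network node for dating; None = skip ages
    descendant_group: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        cfg = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(cfg) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        if "diagnostic_groups" in cfg:
            cfg["diagnostic_groups"] = tuple(cfg["diagnostic_groups"])
        return cls(**cfg)

    def validate(self) -> None:
        real = self.alignment_fasta is not None
        synth = self.synthetic_profile is not None
        if real == synth:
            raise InputError(
                "exactly one of alignment_fasta or synthetic_profile is required"
            )
        if real and self.group_map is None:
            raise InputError("group_map is required with alignment_fasta")
        stochastic = self.run_trees or (synth and self.seed is None)
        if stochastic and self.seed is None:
            raise InputError("seed is mandatory when a stochastic stage is enabled")


@dataclass
class ReportBundle:
    """Paths of the artifacts a run produced, plus its log file."""

    artifacts: dict[str, str] = field(default_factory=dict)
    log_path: str = ""


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(log_path=str(out / "run_log.json"))
    log: dict = {
        "package_version": __version__,
        "parameters": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "stages": [],
    }

    def record(stage: str, path: Path) -> None:
        log["stages"].append(stage)
        bundle.artifacts[stage] = str(path)

    try:
        aln, truth = _load_inputs(config, out, bundle, log)

        loci = None
        if config.run_variants:
            loci = call_variants(aln)
            path = out / "variants.tsv"
            io.write_variant_table(loci, aln, path)
            record("variants", path)

        if config.run_comparisons and loci is not None:
            rows = comparison_table(loci, aln)
            path = out / "comparison_table.csv"
            io.write_comparison_table(rows, path)
            record("comparisons", path)

        if config.run_diagnostics and loci is not None:
            ga, gb = config.diagnostic_groups
            reports = find_diagnostic_indels(
                loci, aln, ga, gb, min_length=config.min_indel_length
            )
            path = out / "diagnostic_indels.tsv"
            pd.DataFrame.from_records(
                [
                    {
                        "marker": r.marker,
                        f"state_{ga}": r.state_a,
                        f"state_{gb}": r.state_b,
                        "length": r.locus.length if r.locus else "",
                    }
                    for r in reports
                ],
                columns=["marker", f"state_{ga}", f"state_{gb}", "length"],
            ).to_csv(path, sep="\t", index=False)
            record("diagnostic_indels", path)

        if config.run_ssr:
            ssr = _load_ssr(config)
            if ssr is not None:
                ga, gb = config.diagnostic_groups
                reports = score_ssr_discrimination(
                    ssr,
                    aln.group_of,
                    ga,
                    gb,
                    min_fragments=config.ssr_min_fragments,
                    tolerance=config.ssr_tolerance,
                )
                path = out / "ssr_discrimination.tsv"
                pd.DataFrame.from_records(
                    [
                        {
                            "primer": r.marker,
                            "n_discriminating_fragments": r.n_discriminating_fragments,
                        }
                        for r in reports
                    ],
                    columns=["primer", "n_discriminating_fragments"],
                ).to_csv(path, sep="\t", index=False)
                record("ssr_discrimination", path)

        matrix = None
        if loci is not None:
            ref = config.reference_taxon or aln.taxa[0]
            matrix = encode_binary(loci, aln, ref)
            path = out / "binary_matrix.tsv"
            io.write_table(matrix, path, index=True)
            record("binary_matrix", path)

        if config.run_trees and matrix is not None:
            tree = bootstrap_support(
                matrix,
                builder="dice",
                n_replicates=config.bootstrap_replicates,
                seed=config.seed,
            )
            path = out / "dice_upgma.nwk"
            io.write_newick(tree, path)
            record("tree_dice", path)
            tree = bootstrap_support(
                aln,
                builder="tn93",
                n_replicates=config.bootstrap_replicates,
                seed=config.seed,
            )
            path = out / "tn93_upgma.nwk"
            io.write_newick(tree, path)
            record("tree_tn93", path)

        if config.run_network and matrix is not None:
            net = median_joining(
                matrix, epsilon=config.epsilon, weight=config.weight
            )
            path = out / "network.gml"
            io.write_gml(net, path)
            record("network", path)
            io.write_network_edges(net, out / "network_edges.tsv")
            if config.ancestral_node and config.descendant_group:
                desc = aln.taxa_in(config.descendant_group)
                est = rho_age(
                    net, config.ancestral_node, desc, config.mutation_rate
                )
                path = out / "clade_ages.tsv"
                pd.DataFrame.from_records(
                    [
                        {
                            "ancestral_node": est.ancestral_node,
                            "descendant_group": config.descendant_group,
                            "rho": est.rho,
                            "sd_rho": est.sd_rho,
                            "mutation_rate": est.mutation_rate,
                            "age_my": est.age_my_rounded,
                            "sd_my": est.sd_my_rounded,
                        }
                    ]
                ).to_csv(path, sep="\t", index=False)
                record("clade_ages", path)
    except Exception:
        # partial artifacts are preserved in output_dir for inspection
        log["status"] = "failed"
        Path(bundle.log_path).write_text(json.dumps(log, indent=2))
        raise

    log["status"] = "ok"
    Path(bundle.log_path).write_text(json.dumps(log, indent=2))
    return bundle


def _load_inputs(config, out, bundle, log):
    if config.synthetic_profile is not None:
        profile = synthetic.load_profile(config.synthetic_profile)
        if config.seed is not None:
            profile.seed = config.seed
        aln, truth = synthetic.generate_alignment(profile)
        io.write_alignment_fasta(
            aln, out / "alignment.fasta", out / "groups.tsv"
        )
        io.write_table(truth, out / "truth_table.tsv")
        bundle.artifacts["alignment"] = str(out / "alignment.fasta")
        log["stages"].append("simulate")
        return aln, truth
    aln = io.read_alignment_fasta(config.alignment_fasta, config.group_map)
    return aln, None


def _load_ssr(config) -> pd.DataFrame | None:
    if config.ssr_table is not None:
        return io.read_table(config.ssr_table)
    if config.synthetic_profile is not None:
        table, _ = synthetic.reference_ssr_table()
        return table
    return None
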