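"""End-to-end run: file ingestion -> preprocessing -> six-step
characterization -> output writing, with per-stage counters."""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

from . import io as fio
from .core import CoreConfig, characterize
from .preprocess import (
    PreprocessConfig,
    build_diploid_profiles,
    discover_additional_hsps,
    read_extra_positions,
    validate_hsps,
    validate_sbss,
)
from .types import CoverageTable, DiploidProfile, GeneInterval, SubgenomeCallTable

logger = logging.getLogger(__name__)

MAX_SUBGENOMES = 10  # no known allopolyploid has more than ten progenitors


@dataclass
class RunConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    core: CoreConfig = field(default_factory=CoreConfig)
    mapq_min: int = 20
    base_quality_min: int = 0
    genotype_rule: bool = True
    output_format: str = "both"  # vcf | tab | both
    output_header: bool = False


@dataclass
class RunReport:
    """Per-stage counts of a pipeline run."""

    counters: Dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> Dict[str, int]:
        return dict(self.counters)

    def log(self) -> None:
        for key, value in self.counters.items():
            logger.info("%s: %d", key, value)


def run_pipeline(
    alignments: str,
    hsp_vcf: str,
    gff: str,
    sbs_vcfs: Mapping[str, str],
    missing: Optional[str] = None,
    polyploid_coverage: Optional[str] = None,
    diploid_coverage: Optional[Mapping[str, str]] = None,
    extra_positions: Optional[str] = None,
    out_dir: Optional[str] = None,
    config: Optional[RunConfig] = None,
) -> Tuple[SubgenomeCallTable, RunReport]:
    """Characterize homoeallelic base identities from input files.

    ``sbs_vcfs`` maps each present diploid progenitor's label to its SBS
    VCF; ``missing`` names the (at most one) progenitor without data.  The
    subgenome set is the union of the two.  Coverage tables are optional:
    when the polyploid table is absent, HSP validation and HSP discovery at
    substitution positions are skipped.
    """
    config = config or RunConfig()
    labels = list(sbs_vcfs)
    if missing is not None:
        if missing in labels:
            raise ValueError(f"missing progenitor {missing!r} also has an SBS list")
        labels.append(missing)
    if not 2 <= len(labels) <= MAX_SUBGENOMES:
        raise ValueError(
            f"need between 2 and {MAX_SUBGENOMES} subgenomes, got {len(labels)}"
        )

    report = RunReport()
    counters = report.counters

    genes = fio.read_gene_intervals(gff)
    counters["genes"] = len(genes)
    hsps = fio.read_hsp_vcf(hsp_vcf, genotype_rule=config.genotype_rule)
    counters["hsps_input"] = len(hsps)
    sbs_by_diploid = {label: fio.read_sbs_vcf(path) for label, path in sbs_vcfs.items()}
    counters["sbs_input"] = sum(len(v) for v in sbs_by_diploid.values())

    poly_cov: Optional[CoverageTable] = (
        fio.read_coverage_table(polyploid_coverage) if polyploid_coverage else None
    )
    dip_cov: Dict[str, Optional[CoverageTable]] = {
        label: fio.read_coverage_table(diploid_coverage[label])
        if diploid_coverage and label in diploid_coverage
        else None
        for label in sbs_vcfs
    }

    hsps = validate_hsps(hsps, poly_cov, config.preprocess)
    counters["hsps_validated"] = len(hsps)
    sbs_by_diploid = {
        label: validate_sbss(records, dip_cov[label], config.preprocess)
        for label, records in sbs_by_diploid.items()
    }
    counters["sbs_validated"] = sum(len(v) for v in sbs_by_diploid.values())

    extras = read_extra_positions(extra_positions) if extra_positions else None
    if poly_cov is not None:
        hsps = discover_additional_hsps(
            sbs_by_diploid, extras, poly_cov, hsps, config.preprocess
        )
    counters["hsps_final"] = len(hsps)

    profiles = build_diploid_profiles(
        sbs_by_diploid, dip_cov, hsps, missing, config.preprocess
    )

    filter_stats = fio.FilterStats()
    fragments = fio.filter_alignments(
        alignments,
        genes,
        mapq_min=config.mapq_min,
        base_quality_min=config.base_quality_min,
        stats=filter_stats,
    )
    calls = characterize(
        fragments, hsps, genes, profiles, config.core, missing=missing, counters=counters
    )
    counters["reads_seen"] = filter_stats.reads_seen
    counters["reads_dropped_mapq"] = filter_stats.dropped_mapq
    counters["reads_dropped_orphan"] = filter_stats.dropped_orphan
    counters["reads_dropped_cross_gene"] = filter_stats.dropped_cross_gene
    counters["reads_dropped_no_gene"] = filter_stats.dropped_no_gene
    counters["fragments"] = filter_stats.fragments_out

    if out_dir is not None:
        contig_lengths = _contig_lengths(genes)
        fio.write_outputs(
            calls,
            profiles,
            contig_lengths,
            out_dir,
            fmt=config.output_format,
            header=config.output_header,
        )
        with open(os.path.join(out_dir, "run_report.json"), "w") as fh:
            json.dump(counters, fh, indent=2, sort_keys=True)
            fh.write("\n")
    report.log()
    return calls, report


def _contig_lengths(genes: List[GeneInterval]) -> Dict[str, int]:
    lengths: Dict[str, int] = {}
    for g in genes:
        lengths[g.seq_name] = max(lengths.get(g.seq_name, 0), g.end)
    return lengths
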