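"""End-to-end orchestration: inputs -> per-stage TSV reports.

The pipeline chains the stages in method order — SCNA categorisation and
burden summary, binned-profile clustering with the pair-adjacency call,
shared-mutation concordance, hypermutation calling with the LOH association
test, and the final per-pair clonality label — writing one plain TSV per
stage plus a Newick dendrogram, so every intermediate is independently
inspectable and re-runnable.  Re-running on identical inputs yields
byte-identical reports.

Chromosome lengths for binning are taken from the segment table itself (the
maximum segment end per chromosome), so no genome build metadata is needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from . import __version__
from .clonality import ClonalityCall, classify_pair, summarize_cohort
from .clustering import (
    AdjacencyResult,
    Dendrogram,
    cohort_adjacency,
    hierarchical_cluster,
    pairwise_distance,
)
from .concordance import PairConcordance, cohort_concordance
from .hypermutation import (
    HypermutationCall,
    TTestResult,
    annotate_panel_hits,
    call_hypermutated,
    loh_association,
)
from .io_formats import (
    CohortManifest,
    MutationRecord,
    SegmentRecord,
    read_manifest,
    read_mutation_table,
    read_segment_table,
)
from .panels import (
    DRIVER_PANEL,
    MISMATCH_REPAIR_PANEL,
    POLYMERASE_PANEL,
    GenePanel,
)
from .scna import DEFAULT_BIN_SIZE, ScnaSummary, build_cnv_matrix, summarize_cohort_scna

logger = logging.getLogger("clonalpair")


@dataclass
class PipelineConfig:
    """Resolved settings for one pipeline run; every field has a default."""

    mutations: str = "mutations.tsv"
    segments: str = "segments.tsv"
    manifest: str = "manifest.tsv"
    outdir: str = "clonalpair_out"
    bin_size: int = DEFAULT_BIN_SIZE
    metric: str = "euclidean"
    linkage: str = "complete"
    loh_weight: float = 1.0
    hypermutation_strategy: str = "absolute"
    hypermutation_param: float | None = None
    ttest_variant: str = "welch"
    driver_panel_file: str | None = None
    repair_panel_file: str | None = None
    polymerase_panel_file: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a key-value YAML config; unknown keys are rejected."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def resolve_panels(self) -> tuple[GenePanel, GenePanel, GenePanel]:
        driver = (
            GenePanel.from_file("crc_drivers", self.driver_panel_file)
            if self.driver_panel_file
            else DRIVER_PANEL
        )
        repair = (
            GenePanel.from_file("mismatch_repair", self.repair_panel_file)
            if self.repair_panel_file
            else MISMATCH_REPAIR_PANEL
        )
        polymerase = (
            GenePanel.from_file("dna_polymerases", self.polymerase_panel_file)
            if self.polymerase_panel_file
            else POLYMERASE_PANEL
        )
        return driver, repair, polymerase


def infer_chrom_lengths(segments: Iterable[SegmentRecord]) -> dict[str, int]:
    """Chromosome extents inferred from the segments themselves."""
    lengths: dict[str, int] = {}
    for seg in segments:
        lengths[seg.chromosome] = max(lengths.get(seg.chromosome, 0), seg.end)
    return lengths


def _write_tsv(path: Path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


@dataclass
class ReportBundle:
    """All stage outputs of one run, plus the paths they were written to."""

    summaries: list[ScnaSummary]
    tree: Dendrogram
    adjacency: AdjacencyResult
    concordances: list[PairConcordance]
    hyper_calls: list[HypermutationCall]
    association: TTestResult | None
    clonality: list[ClonalityCall]
    paths: dict[str, Path] = field(default_factory=dict)


def run_full_pipeline(
    config: PipelineConfig,
    mutations: list[MutationRecord] | None = None,
    segments: list[SegmentRecord] | None = None,
    manifest: CohortManifest | None = None,
) -> ReportBundle:
    """Run every stage and write the report TSVs to ``config.outdir``.

    Inputs may be passed in-memory (as the simulator does) or read from the
    configured paths.  Any stage failure aborts with the stage name.
    """
    driver_panel, repair_panel, polymerase_panel = config.resolve_panels()
    if mutations is None:
        mutations = read_mutation_table(config.mutations)
    if segments is None:
        segments = read_segment_table(config.segments)
    if manifest is None:
        manifest = read_manifest(config.manifest)
    if len(manifest) == 0:
        raise ValueError("manifest is empty: nothing to analyse")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _stage(name):
        logger.info("stage: %s", name)

    _stage("scna summary")
    summaries = summarize_cohort_scna(segments, manifest.tumor_ids)
    paths["scna_summary"] = outdir / "scna_summary.tsv"
    _write_tsv(
        paths["scna_summary"],
        ["sample", "one_copy_gain", "one_copy_loss", "high_copy_gain",
         "homozygous_loss", "loh", "total_scna"],
        (list(s.as_dict().values()) for s in summaries),
    )

    _stage("clustering")
    matrix = build_cnv_matrix(
        segments, manifest, infer_chrom_lengths(segments), bin_size=config.bin_size
    )
    dist = pairwise_distance(matrix, metric=config.metric, loh_weight=config.loh_weight)
    tree = hierarchical_cluster(dist, linkage=config.linkage)
    adjacency = cohort_adjacency(tree, manifest)
    paths["dendrogram"] = outdir / "dendrogram.nwk"
    paths["dendrogram"].write_text(tree.to_newick() + "\n")
    paths["adjacency"] = outdir / "adjacency.tsv"
    _write_tsv(
        paths["adjacency"],
        ["patient", "grouped"],
        ([pid, int(flag)] for pid, flag in adjacency.per_pair.items()),
    )

    _stage("mutation concordance")
    concordances = cohort_concordance(mutations, manifest, panel=driver_panel)
    paths["concordance"] = outdir / "concordance.tsv"
    _write_tsv(
        paths["concordance"],
        ["patient", "primary_mutations", "metastasis_mutations", "shared",
         "shared_pct", "shared_drivers", "discordant_drivers"],
        (
            [
                c.patient_id, c.n_primary, c.n_metastasis, c.n_shared,
                f"{c.shared_pct:.1f}",
                ",".join(sorted(c.shared_driver_genes)) or "-",
                ",".join(sorted(c.discordant_driver_genes)) or "-",
            ]
            for c in concordances
        ),
    )

    _stage("hypermutation")
    counts = {sid: 0 for sid in manifest.tumor_ids}
    for m in mutations:
        if m.sample_id in counts:
            counts[m.sample_id] += 1
    hyper_calls = annotate_panel_hits(
        call_hypermutated(
            counts, strategy=config.hypermutation_strategy,
            param=config.hypermutation_param,
        ),
        mutations,
        repair_panel,
        polymerase_panel,
    )
    paths["hypermutation"] = outdir / "hypermutation.tsv"
    _write_tsv(
        paths["hypermutation"],
        ["sample", "mutation_count", "flagged", "threshold",
         "repair_genes_hit", "polymerase_genes_hit"],
        (
            [
                c.sample_id, c.mutation_count, int(c.flagged),
                f"{c.threshold_used:g}",
                ",".join(sorted(c.repair_genes_hit)) or "-",
                ",".join(sorted(c.polymerase_genes_hit)) or "-",
            ]
            for c in hyper_calls
        ),
    )

    _stage("loh association")
    association: TTestResult | None
    try:
        association = loh_association(
            summaries, hyper_calls, variant=config.ttest_variant
        )
    except ValueError as exc:
        logger.warning("LOH association skipped: %s", exc)
        association = None
    paths["association"] = outdir / "association.tsv"
    rows = (
        [[association.variant, f"{association.t_statistic:.6g}",
          f"{association.degrees_of_freedom:.6g}", f"{association.p_value:.6g}"]]
        if association
        else [["-", "-", "-", "-"]]
    )
    _write_tsv(paths["association"], ["variant", "t", "df", "p"], rows)

    _stage("clonality classification")
    calls = [
        classify_pair(adjacency.per_pair[c.patient_id], c) for c in concordances
    ]
    summary = summarize_cohort(calls)
    paths["clonality"] = outdir / "clonality.tsv"
    with open(paths["clonality"], "w") as fh:
        fh.write("patient\tadjacent\tn_shared_drivers\tshared_pct\tlabel\tevidence\n")
        for c in calls:
            fh.write(
                f"{c.patient_id}\t{int(c.adjacent)}\t{c.n_shared_drivers}\t"
                f"{c.shared_pct:.1f}\t{c.label}\t{c.evidence}\n"
            )
        fh.write(
            f"# pairs={summary.n_pairs} related={summary.n_related} "
            f"distinct={summary.n_distinct} discordant={summary.n_discordant} "
            f"fraction_related={summary.fraction_related:.3f}\n"
        )

    paths["log"] = outdir / "run_log.txt"
    with open(paths["log"], "w") as fh:
        fh.write(f"clonalpair {__version__}\n")
        for f in dc_fields(config):
            fh.write(f"{f.name}={getattr(config, f.name)}\n")

    return ReportBundle(
        summaries=summaries,
        tree=tree,
        adjacency=adjacency,
        concordances=concordances,
        hyper_calls=hyper_calls,
        association=association,
        clonality=calls,
        paths=paths,
    )
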