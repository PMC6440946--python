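"""End-to-end orchestration: FASTQ (or clonotype table) in, clonality out.

Two entry points mirror real-world use: a full run starts from merged
UMI-tagged reads (consensus -> clonotype assembly -> network), while the
table entry point accepts pre-assembled clonotype exports from any upstream
aligner and runs the network stages only. Heavy- and light-chain groups are
processed independently and reported separately.

Every run writes a manifest (package version, all parameters, seed,
per-stage record counts); a rerun with the same inputs and manifest
parameters is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path

from . import assembly, consensus, io, network
from .reference import SegmentReference, get_default_reference

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All pipeline parameters, defaulting to the analysis conventions:
    dominance threshold 0.10, CDR3 link distance 1, minimum 2 molecules per
    cluster."""

    input_fastq: str | None = None
    input_table: str | None = None
    table_dialect: str = "native"
    sample_id: str = "sample"
    chain: str = "IGH"  # chain group of a FASTQ input: "IGH" or "light"
    out_dir: str = "bcrnet_out"
    reference_path: str | None = None
    umi_length: int = 12
    min_payload: int = 30
    mig_strategy: str = "histogram_valley"
    mig_fixed_value: int = 2
    productive_only: bool = True
    frame_offset: int = 0
    max_cdr3_distance: int = 1
    allow_indel: bool = False
    min_cluster_umis: int = 2
    dominant_fraction: float = 0.10
    network_formats: tuple[str, ...] = ("graphml", "edge_tsv")
    seed: int = 0

    def to_dict(self) -> dict:
        data = dataclasses.asdict(self)
        data["network_formats"] = list(self.network_formats)
        return data


@dataclass
class PipelineResult:
    classification: network.SampleClassification
    clusters_by_group: dict[str, list[network.ClonalCluster]]
    networks: dict[str, network.ClonalityGraph]
    clones_by_group: dict[str, list[assembly.Clone]]
    mig_stats: consensus.MigStats | None
    manifest: dict
    out_dir: Path


def _load_reference(config: PipelineConfig) -> SegmentReference:
    if config.reference_path:
        return SegmentReference.from_table(config.reference_path)
    return get_default_reference()


def run_end_to_end(config: PipelineConfig) -> PipelineResult:
    """Run every enabled stage and write all artifacts under ``out_dir``.

    Raises :class:`PipelineError` naming the failing stage; on failure no
    partial manifest is left behind (the manifest is written last).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    reference = _load_reference(config)
    mig_stats: consensus.MigStats | None = None

    if config.input_fastq is not None:
        fastq = Path(config.input_fastq)
        if not fastq.exists():
            raise PipelineError("consensus", f"input FASTQ {fastq} does not exist")
        spec = io.UmiSpec(mode="prefix", length=config.umi_length, min_payload=config.min_payload)
        fq_stats = io.FastqStats()
        try:
            consensus_reads, mig_stats = consensus.collapse_sample(
                io.read_fastq_umi(fastq, spec, fq_stats),
                strategy=config.mig_strategy,
                fixed_value=config.mig_fixed_value,
            )
        except io.FormatError as exc:
            raise PipelineError("consensus", str(exc)) from exc
        counts["raw_reads"] = fq_stats.n_reads
        counts["reads_dropped_short"] = fq_stats.n_dropped_short
        counts["migs_total"] = mig_stats.n_migs_kept + mig_stats.n_migs_dropped
        counts["migs_kept"] = mig_stats.n_migs_kept
        counts["mig_threshold"] = mig_stats.threshold
        mig_stats.to_tsv(out_dir / "mig_stats.tsv")
        io.write_fastq(
            ((f"mig_{u}", s, q) for u, s, q in consensus_reads),
            out_dir / "consensus_reads.fastq",
        )

        clones, rejections = assembly.assemble_clones(
            consensus_reads, reference, config.chain, sample_id=config.sample_id
        )
        counts["consensus_reads"] = len(consensus_reads)
        counts["reads_rejected_extraction"] = rejections.total
        rejections.to_tsv(out_dir / "rejections.tsv")
        clones_by_group = {config.chain: clones}
    elif config.input_table is not None:
        table = Path(config.input_table)
        if not table.exists():
            raise PipelineError("clones", f"input table {table} does not exist")
        try:
            records = io.read_clonotype_table(
                table, dialect=config.table_dialect, sample_id=config.sample_id
            )
        except (io.FormatError, io.UsageError) as exc:
            raise PipelineError("clones", str(exc)) from exc
        counts["table_records"] = len(records)
        clones_by_group = assembly.clones_from_records(records)
    else:
        raise PipelineError("input", "neither input_fastq nor input_table given")

    counts["clones_assembled"] = sum(len(v) for v in clones_by_group.values())
    if config.productive_only:
        clones_by_group = {
            g: assembly.productive_filter(cl, config.frame_offset)
            for g, cl in clones_by_group.items()
        }
        counts["clones_productive"] = sum(len(v) for v in clones_by_group.values())

    all_records = [
        c.record for clones in clones_by_group.values() for c in clones
    ]
    io.write_clonotype_table(all_records, out_dir / "clonotypes.tsv")

    networks: dict[str, network.ClonalityGraph] = {}
    clusters_by_group: dict[str, list[network.ClonalCluster]] = {}
    for group, clones in sorted(clones_by_group.items()):
        net = network.build_network(
            clones,
            group,
            max_distance=config.max_cdr3_distance,
            allow_indel=config.allow_indel,
        )
        clusters = network.find_clusters(net)
        counts[f"clusters_{group}"] = len(clusters)
        # singleton-molecule clusters are excluded *before* dominance scoring
        clusters = network.filter_singleton_clusters(clusters, config.min_cluster_umis)
        counts[f"clusters_{group}_kept"] = len(clusters)
        clusters = network.score_dominance(clusters, config.dominant_fraction)
        surviving = [k for c in clusters for k in c.members]
        net = net.subset(surviving)
        network.annotate_graph(net, clusters)
        networks[group] = net
        clusters_by_group[group] = clusters
        network.clusters_to_frame(clusters, net).to_csv(
            out_dir / f"clusters_{group}.tsv", sep="\t", index=False
        )
        for fmt in config.network_formats:
            ext = {"graphml": "graphml", "dot": "dot", "edge_tsv": "edges.tsv"}[fmt]
            io.write_network(net.graph, out_dir / f"network_{group}.{ext}", fmt)

    classification = network.classify_sample(clusters_by_group)
    (out_dir / "classification.json").write_text(
        json.dumps(classification.to_dict(), indent=2, sort_keys=True) + "\n"
    )

    manifest = {
        "package": "bcrnet",
        "version": _safe_version(),
        "parameters": config.to_dict(),
        "seed": config.seed,
        "stage_counts": counts,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    logger.info("pipeline finished: %s", classification.sample_label)
    return PipelineResult(
        classification=classification,
        clusters_by_group=clusters_by_group,
        networks=networks,
        clones_by_group=clones_by_group,
        mig_stats=mig_stats,
        manifest=manifest,
        out_dir=out_dir,
    )


def analyze_reads(
    umi_reads,
    chain: str = "IGH",
    reference: SegmentReference | None = None,
    sample_id: str = "sample",
    mig_strategy: str = "histogram_valley",
    mig_fixed_value: int = 2,
    productive_only: bool = True,
    max_cdr3_distance: int = 1,
    allow_indel: bool = False,
    min_cluster_umis: int = 2,
    dominant_fraction: float = 0.10,
) -> PipelineResult:
    """In-memory analysis of one chain group's ``(umi, payload, quality)``
    reads: consensus, clonotype assembly, network, classification.

    The file-free twin of :func:`run_end_to_end`, for library use (e.g.
    analyzing a simulated sample without touching disk). ``mig_stats`` and
    all cluster/network products are returned on the result object;
    ``manifest`` and ``out_dir`` are unset.
    """
    if reference is None:
        reference = get_default_reference()
    consensus_reads, mig_stats = consensus.collapse_sample(
        umi_reads, strategy=mig_strategy, fixed_value=mig_fixed_value
    )
    clones, _rejections = assembly.assemble_clones(
        consensus_reads, reference, chain, sample_id=sample_id
    )
    if productive_only:
        clones = assembly.productive_filter(clones)
    net = network.build_network(
        clones, chain, max_distance=max_cdr3_distance, allow_indel=allow_indel
    )
    clusters = network.find_clusters(net)
    clusters = network.filter_singleton_clusters(clusters, min_cluster_umis)
    clusters = network.score_dominance(clusters, dominant_fraction)
    net = net.subset([k for c in clusters for k in c.members])
    network.annotate_graph(net, clusters)
    classification = network.classify_sample({chain: clusters})
    return PipelineResult(
        classification=classification,
        clusters_by_group={chain: clusters},
        networks={chain: net},
        clones_by_group={chain: clones},
        mig_stats=mig_stats,
        manifest={},
        out_dir=Path("."),
    )


def _safe_version() -> str:
    try:
        return _pkg_version("bcrnet")
    except Exception:
        return "unknown"
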