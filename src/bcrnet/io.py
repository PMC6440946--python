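"""Readers and writers for every external representation the pipeline touches.

Clonotype tables come in three tab-separated dialects:

``native``
    this package's own export: ``sample_id  chain  v_call  j_call  cdr3_nt
    consensus_count``.
``airr``
    the AIRR Rearrangement subset: ``locus  v_call  j_call  junction
    duplicate_count`` (the junction column is taken as the CDR3 nucleotide
    string as exported).
``aligner_export``
    upstream-aligner clone exports: ``allVHitsWithScore  allJHitsWithScore
    nSeqCDR3  cloneCount``, with multi-gene calls comma-separated and
    alignment scores in trailing parentheses.

Dialects are *data*: a column-role mapping table (`DIALECTS`) that users can
override with a custom map, because column names drift across tool versions.

Counts are UMI-consensus read counts throughout: one "read" in all downstream
clonality arithmetic is one UMI-collapsed cDNA molecule.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import networkx as nx
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .reference import chain_group

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file does not conform to its declared dialect or format."""


class UsageError(ValueError):
    """An argument (dialect name, format name, parameter) is invalid."""


# ---------------------------------------------------------------------------
# clonotype tables
# ---------------------------------------------------------------------------

#: column-role maps per dialect; every listed column is mandatory.
#: roles: sample_id / chain may be absent from a dialect (sample id then comes
#: from the caller, the locus from the V gene name).
DIALECTS: dict[str, dict[str, str]] = {
    "native": {
        "sample_id": "sample_id",
        "chain": "chain",
        "v_call": "v_call",
        "j_call": "j_call",
        "cdr3": "cdr3_nt",
        "count": "consensus_count",
    },
    "airr": {
        "chain": "locus",
        "v_call": "v_call",
        "j_call": "j_call",
        "cdr3": "junction",
        "count": "duplicate_count",
    },
    "aligner_export": {
        "v_call": "allVHitsWithScore",
        "j_call": "allJHitsWithScore",
        "cdr3": "nSeqCDR3",
        "count": "cloneCount",
    },
}

_SCORE_SUFFIX = re.compile(r"\(.*?\)$")
_CDR3_ALPHABET = re.compile(r"^[ACGT]+$")


@dataclass(frozen=True)
class ClonotypeRecord:
    """A unique (chain, V, J, CDR3) clonotype with its consensus read count.

    ``v_calls``/``j_calls`` are sets because upstream aligners may report
    ambiguous multi-gene hits; the network edge rule links clones sharing at
    least one gene.
    """

    sample_id: str
    chain: str
    v_calls: frozenset[str]
    j_calls: frozenset[str]
    cdr3_nt: str
    count: int

    def key(self) -> tuple:
        return (self.chain, self.v_calls, self.j_calls, self.cdr3_nt)

    @property
    def chain_group(self) -> str:
        return chain_group(self.chain)


def parse_gene_calls(raw: str) -> frozenset[str]:
    """Split a comma-separated gene-call string, stripping score suffixes.

    ``"IGHV1*00(250),IGHV5*00(180)"`` -> ``{"IGHV1*00", "IGHV5*00"}``; allele
    suffixes (``*NN``) are kept — the edge rule compares gene identity as
    exported.
    """
    calls = frozenset(
        _SCORE_SUFFIX.sub("", part.strip()) for part in str(raw).split(",") if part.strip()
    )
    if not calls:
        raise FormatError(f"empty gene call field: {raw!r}")
    return calls


def _infer_chain(v_calls: frozenset[str]) -> str:
    prefixes = {c[:3] for c in v_calls}
    if len(prefixes) == 1:
        prefix = next(iter(prefixes))
        if prefix in ("IGH", "IGK", "IGL"):
            return prefix
    raise FormatError(f"cannot infer locus from V calls {sorted(v_calls)}")


def read_clonotype_table(
    path: str | Path,
    dialect: str = "native",
    column_map: dict[str, str] | None = None,
    sample_id: str | None = None,
) -> list[ClonotypeRecord]:
    """Read a clonotype table, returning merged, validated records.

    Rows identical in (chain, V set, J set, CDR3) are merged by summing
    counts (merges are logged). Rows whose CDR3 contains a non-ACGT character
    are rejected with a warning and counted. A missing mandatory column is a
    :class:`FormatError` naming the column.
    """
    if column_map is None:
        if dialect not in DIALECTS:
            raise UsageError(f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)}")
        column_map = DIALECTS[dialect]
    df = pd.read_csv(path, sep="\t", dtype=str)
    for role, col in column_map.items():
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r} (role {role!r}) in {path}")

    records: dict[tuple, ClonotypeRecord] = {}
    n_rejected = 0
    n_merged = 0
    for idx, row in df.iterrows():
        cdr3 = str(row[column_map["cdr3"]]).strip().upper()
        if not _CDR3_ALPHABET.match(cdr3):
            logger.warning("row %d of %s: non-ACGT CDR3 %r rejected", idx, path, cdr3)
            n_rejected += 1
            continue
        v_calls = parse_gene_calls(row[column_map["v_call"]])
        j_calls = parse_gene_calls(row[column_map["j_call"]])
        chain = (
            str(row[column_map["chain"]]).strip()
            if "chain" in column_map
            else _infer_chain(v_calls)
        )
        sid = (
            str(row[column_map["sample_id"]])
            if "sample_id" in column_map
            else (sample_id or Path(path).stem)
        )
        count = int(float(row[column_map["count"]]))
        if count < 1:
            logger.warning("row %d of %s: non-positive count %d rejected", idx, path, count)
            n_rejected += 1
            continue
        rec = ClonotypeRecord(sid, chain, v_calls, j_calls, cdr3, count)
        if rec.key() in records:
            prev = records[rec.key()]
            records[rec.key()] = ClonotypeRecord(
                prev.sample_id, prev.chain, prev.v_calls, prev.j_calls, prev.cdr3_nt,
                prev.count + rec.count,
            )
            n_merged += 1
            logger.info("merged duplicate clonotype row %d of %s", idx, path)
        else:
            records[rec.key()] = rec
    if n_rejected:
        logger.warning("%d rows rejected while reading %s", n_rejected, path)
    if n_merged:
        logger.info("%d duplicate rows merged while reading %s", n_merged, path)
    return list(records.values())


def write_clonotype_table(records: Iterable[ClonotypeRecord], path: str | Path) -> None:
    """Write records in the native dialect (round-trips through the reader)."""
    rows = [
        {
            "sample_id": r.sample_id,
            "chain": r.chain,
            "v_call": ",".join(sorted(r.v_calls)),
            "j_call": ",".join(sorted(r.j_calls)),
            "cdr3_nt": r.cdr3_nt,
            "consensus_count": r.count,
        }
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=["sample_id", "chain", "v_call", "j_call", "cdr3_nt", "consensus_count"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTQ with UMIs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UmiSpec:
    """Where the UMI lives: first ``length`` bases of the read, or a header
    tag (e.g. ``UMI:Z:``) whose value is the UMI."""

    mode: str = "prefix"  # "prefix" | "header_tag"
    length: int = 12
    tag: str = "UMI:Z:"
    min_payload: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("prefix", "header_tag"):
            raise UsageError(f"unknown UMI mode {self.mode!r}")
        if self.mode == "prefix" and self.length < 1:
            raise UsageError("UMI length must be >= 1")


@dataclass
class FastqStats:
    n_reads: int = 0
    n_dropped_short: int = 0
    n_dropped_no_tag: int = 0


def read_fastq_umi(
    path: str | Path, umi_spec: UmiSpec, stats: FastqStats | None = None
) -> Iterator[tuple[str, str, str]]:
    """Stream ``(umi, payload, quality)`` from a FASTQ file.

    Reads shorter than UMI length + minimum payload (prefix mode), or missing
    the header tag (tag mode), are dropped and counted in ``stats``.
    Gzipped input is handled by extension.
    """
    if stats is None:
        stats = FastqStats()
    opener = _open_maybe_gzip(path)
    with opener as handle:
        n = 0
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                n += 1
                stats.n_reads += 1
                if umi_spec.mode == "prefix":
                    if len(seq) < umi_spec.length + umi_spec.min_payload:
                        stats.n_dropped_short += 1
                        continue
                    yield (
                        seq[: umi_spec.length],
                        seq[umi_spec.length :],
                        qual[umi_spec.length :],
                    )
                else:
                    umi = _extract_header_tag(title, umi_spec.tag)
                    if umi is None:
                        stats.n_dropped_no_tag += 1
                        continue
                    yield umi, seq, qual
        except ValueError as exc:
            raise FormatError(
                f"malformed FASTQ record near line {n * 4 + 1} of {path}: {exc}"
            ) from exc


def _extract_header_tag(title: str, tag: str) -> str | None:
    for token in title.split():
        if token.startswith(tag):
            value = token[len(tag) :]
            if value:
                return value
    return None


def _open_maybe_gzip(path: str | Path) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        import gzip

        return gzip.open(path, "rt")
    return open(path)


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | Path) -> int:
    """Write ``(name, sequence, quality)`` triples as Phred+33 FASTQ."""
    n = 0
    with open(path, "w") as out:
        for name, seq, qual in records:
            out.write(f"@{name}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# network serialization
# ---------------------------------------------------------------------------

NETWORK_FORMATS = ("graphml", "dot", "edge_tsv")


def write_network(graph: nx.Graph, path: str | Path, fmt: str = "graphml") -> None:
    """Serialize a clonality network (undirected, attribute-carrying).

    ``graphml`` keeps all node attributes; ``dot`` quotes them as strings;
    ``edge_tsv`` is a two-column edge list in which isolated nodes appear as
    rows with an empty target, so that a round trip reproduces the node and
    edge sets exactly in every format.
    """
    if fmt == "graphml":
        nx.write_graphml(_stringify_attrs(graph), path)
    elif fmt == "dot":
        _write_dot(graph, path)
    elif fmt == "edge_tsv":
        with open(path, "w") as out:
            out.write("source\ttarget\n")
            for a, b in sorted(tuple(sorted((u, v))) for u, v in graph.edges()):
                out.write(f"{a}\t{b}\n")
            connected = {n for e in graph.edges() for n in e}
            for node in sorted(set(graph.nodes()) - connected):
                out.write(f"{node}\t\n")
    else:
        raise UsageError(f"unknown network format {fmt!r}; known: {NETWORK_FORMATS}")


def read_network(path: str | Path, fmt: str = "graphml") -> nx.Graph:
    """Read a network written by :func:`write_network`."""
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt == "dot":
        return _read_dot(path)
    if fmt == "edge_tsv":
        graph = nx.Graph()
        with open(path) as handle:
            header = handle.readline()
            if header.strip() and header.split("\t")[0].strip() != "source":
                raise FormatError(f"{path} is not an edge TSV (bad header)")
            for line in handle:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 2 or parts[1] == "":
                    graph.add_node(parts[0])
                else:
                    graph.add_edge(parts[0], parts[1])
        return graph
    raise UsageError(f"unknown network format {fmt!r}; known: {NETWORK_FORMATS}")


def _stringify_attrs(graph: nx.Graph) -> nx.Graph:
    out = nx.Graph()
    out.graph.update({k: str(v) for k, v in graph.graph.items()})
    for node, attrs in graph.nodes(data=True):
        out.add_node(node, **{k: _graphml_value(v) for k, v in attrs.items()})
    for u, v, attrs in graph.edges(data=True):
        out.add_edge(u, v, **{k: _graphml_value(val) for k, val in attrs.items()})
    return out


def _graphml_value(value):
    if isinstance(value, (bool, int, float, str)):
        return value
    if isinstance(value, (set, frozenset)):
        return ",".join(sorted(map(str, value)))
    return str(value)


def _quote(s: str) -> str:
    return '"' + str(s).replace('"', '\\"') + '"'


def _write_dot(graph: nx.Graph, path: str | Path) -> None:
    # hand-rolled writer for a plain undirected DOT dialect (no pydot in the
    # runtime environment); the companion reader parses exactly this dialect
    with open(path, "w") as out:
        out.write("graph clonality {\n")
        connected = {n for e in graph.edges() for n in e}
        for node in sorted(set(graph.nodes()) - connected):
            attrs = graph.nodes[node]
            attr_str = ", ".join(
                f"{k}={_quote(_graphml_value(v))}" for k, v in sorted(attrs.items())
            )
            out.write(f"  {_quote(node)}" + (f" [{attr_str}]" if attr_str else "") + ";\n")
        for a, b in sorted(tuple(sorted((u, v))) for u, v in graph.edges()):
            out.write(f"  {_quote(a)} -- {_quote(b)};\n")
        out.write("}\n")


_DOT_EDGE = re.compile(r'^\s*"((?:[^"\\]|\\.)*)"\s*--\s*"((?:[^"\\]|\\.)*)"\s*;')
_DOT_NODE = re.compile(r'^\s*"((?:[^"\\]|\\.)*)"\s*(?:\[[^\]]*\])?\s*;')


def _read_dot(path: str | Path) -> nx.Graph:
    graph = nx.Graph()
    with open(path) as handle:
        for line in handle:
            m = _DOT_EDGE.match(line)
            if m:
                graph.add_edge(m.group(1).replace('\\"', '"'), m.group(2).replace('\\"', '"'))
                continue
            m = _DOT_NODE.match(line)
            if m:
                graph.add_node(m.group(1).replace('\\"', '"'))
    return graph
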