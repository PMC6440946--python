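"""Clonotype assembly from consensus reads.

The CDR3 of each consensus read is located by anchor-exact matching against
the segment reference: the unique V anchor found in the read fixes the gene
call and the CDR3 start, the unique J anchor the gene call and the CDR3 end
(junction-internal convention — anchors excluded). Reads in which zero or
multiple anchors match are rejected with a reason rather than fuzzily
rescued, and rejection counts are reported.

Clones are the exact groups on (chain group, V, J, CDR3); the clone count is
its number of consensus reads, i.e. UMI-collapsed molecules, and the clone
fraction Cf = count / Tr where Tr is the chain group's total consensus read
count. The productivity filter removes out-of-frame CDR3s and in-frame stop
codons, mirroring the exclusion of non-productive mutants upstream of
clonality analysis; fractions are recomputed over the survivors.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .io import ClonotypeRecord
from .reference import SegmentReference, Segment, chain_group

logger = logging.getLogger(__name__)

STOP_CODONS = ("TAA", "TAG", "TGA")

REJECT_NO_V = "no_v_anchor"
REJECT_NO_J = "no_j_anchor"
REJECT_MULTI_V = "multiple_v_anchor"
REJECT_MULTI_J = "multiple_j_anchor"
REJECT_INVERTED = "inverted_anchors"
REJECT_CHAIN_MISMATCH = "chain_mismatch"


@dataclass(frozen=True)
class Clone:
    """A clonotype with its within-chain-group read fraction."""

    record: ClonotypeRecord
    fraction: float
    productive: bool

    @property
    def count(self) -> int:
        return self.record.count

    @property
    def cdr3_nt(self) -> str:
        return self.record.cdr3_nt


@dataclass
class RejectionReport:
    """Counts of consensus reads rejected during CDR3 extraction, by reason."""

    counts: Counter

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self.counts.items()), columns=["reason", "n_reads"]
        ).to_csv(path, sep="\t", index=False)


def _find_unique_anchor(
    read: str, segments: list[Segment]
) -> tuple[Segment, int] | str:
    """Locate the single anchor hit among ``segments``; return (segment,
    position) or ``"none"``/``"multiple"``."""
    hits: list[tuple[Segment, int]] = []
    for seg in segments:
        start = 0
        while True:
            pos = read.find(seg.anchor, start)
            if pos < 0:
                break
            hits.append((seg, pos))
            start = pos + 1
    if not hits:
        return "none"
    if len(hits) > 1:
        return "multiple"
    return hits[0]


def extract_cdr3(
    read: str, reference: SegmentReference, group: str
) -> tuple[str, str, str, str] | str:
    """Extract ``(cdr3_nt, v_call, j_call, chain)`` from a consensus read.

    On failure returns the rejection reason string. The CDR3 spans strictly
    between the V-anchor end (shifted by the V ``anchor_offset``) and the
    J-anchor start (shifted back by the J ``anchor_offset``).
    """
    v_hit = _find_unique_anchor(read, reference.group_segments(group, "V"))
    if v_hit == "none":
        return REJECT_NO_V
    if v_hit == "multiple":
        return REJECT_MULTI_V
    j_hit = _find_unique_anchor(read, reference.group_segments(group, "J"))
    if j_hit == "none":
        return REJECT_NO_J
    if j_hit == "multiple":
        return REJECT_MULTI_J
    v_seg, v_pos = v_hit
    j_seg, j_pos = j_hit
    if v_seg.chain != j_seg.chain:
        return REJECT_CHAIN_MISMATCH
    start = v_pos + len(v_seg.anchor) + v_seg.anchor_offset
    end = j_pos - j_seg.anchor_offset
    if end <= start:
        return REJECT_INVERTED
    return read[start:end], v_seg.name, j_seg.name, v_seg.chain


def assemble_clones(
    consensus_reads: Iterable[tuple[str, str, str]],
    reference: SegmentReference,
    group: str,
    sample_id: str = "sample",
) -> tuple[list[Clone], RejectionReport]:
    """Group consensus reads into clones by (chain group, V, J, CDR3).

    Rejected reads are counted by reason and excluded from the chain group
    total Tr. Clones are returned sorted by descending count (CDR3 as the
    tie-break), so the result is invariant to read order.
    """
    groups: Counter = Counter()
    rejections: Counter = Counter()
    for _umi, seq, _qual in consensus_reads:
        result = extract_cdr3(seq, reference, group)
        if isinstance(result, str):
            rejections[result] += 1
            continue
        cdr3, v_call, j_call, chain = result
        groups[(chain, v_call, j_call, cdr3)] += 1

    total = sum(groups.values())
    clones = [
        Clone(
            record=ClonotypeRecord(
                sample_id=sample_id,
                chain=chain,
                v_calls=frozenset([v_call]),
                j_calls=frozenset([j_call]),
                cdr3_nt=cdr3,
                count=count,
            ),
            fraction=count / total if total else 0.0,
            productive=is_productive(cdr3),
        )
        for (chain, v_call, j_call, cdr3), count in groups.items()
    ]
    clones.sort(key=lambda c: (-c.count, c.record.chain, c.cdr3_nt))
    if rejections:
        logger.info("rejected %d reads during CDR3 extraction: %s",
                    sum(rejections.values()), dict(rejections))
    return clones, RejectionReport(rejections)


def clones_from_records(records: Iterable[ClonotypeRecord]) -> dict[str, list[Clone]]:
    """Turn pre-assembled clonotype records into per-chain-group clone lists
    (the table entry point, for users with their own upstream aligner)."""
    by_group: dict[str, list[ClonotypeRecord]] = {}
    for rec in records:
        by_group.setdefault(rec.chain_group, []).append(rec)
    out: dict[str, list[Clone]] = {}
    for group, recs in sorted(by_group.items()):
        total = sum(r.count for r in recs)
        out[group] = sorted(
            (
                Clone(rec, rec.count / total if total else 0.0, is_productive(rec.cdr3_nt))
                for rec in recs
            ),
            key=lambda c: (-c.count, c.record.chain, c.cdr3_nt),
        )
    return out


def is_productive(cdr3_nt: str, frame_offset: int = 0) -> bool:
    """In-frame (length divisible by 3 from ``frame_offset``) and stop-free."""
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    coding = cdr3_nt[frame_offset:]
    if len(coding) % 3 != 0 or not coding:
        return False
    return all(
        coding[i : i + 3] not in STOP_CODONS for i in range(0, len(coding), 3)
    )


def productive_filter(clones: list[Clone], frame_offset: int = 0) -> list[Clone]:
    """Drop non-productive clones and renormalize fractions over survivors.

    Counts are never modified by filtering — only excluded.
    """
    kept = [c for c in clones if is_productive(c.cdr3_nt, frame_offset)]
    total = sum(c.count for c in kept)
    out = [
        Clone(c.record, c.count / total if total else 0.0, True) for c in kept
    ]
    n_removed = len(clones) - len(kept)
    if n_removed:
        logger.info("productive filter removed %d of %d clones", n_removed, len(clones))
    return out


def clones_to_records(clones: Iterable[Clone]) -> list[ClonotypeRecord]:
    return [c.record for c in clones]
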