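"""UMI-guided consensus assembly: collapse raw reads into one read per molecule.

Every cDNA molecule is tagged with a random unique molecular identifier (UMI)
before amplification; all reads carrying the same UMI form a molecular
identifier group (MIG) and are collapsed into a single consensus read. PCR
and sequencing errors present in a minority of a MIG's reads are voted away,
while true somatic variants (present in every read of a molecule) survive.

MIGs smaller than a per-sample size threshold ``t`` are discarded: size-1
"MIGs" are frequently sequencing errors inside the UMI itself, and small
groups give the consensus vote little power. The threshold is either fixed
or picked from the MIG size histogram (the valley between the error peak at
size 1 and the main amplification mode); the selected rule and value are
logged per sample.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .io import UsageError

logger = logging.getLogger(__name__)

_BASE_TO_IDX = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T byte values
_IDX_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)
_QUAL_CAP = 40


@dataclass
class MIG:
    """All reads sharing one UMI, with an optional consensus sequence."""

    umi: str
    members: list[tuple[str, str]] = field(default_factory=list)  # (payload, quality)
    consensus: str | None = None
    consensus_quality: str | None = None

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class MigStats:
    """Per-sample MIG bookkeeping: size histogram, chosen threshold, counts."""

    size_histogram: dict[int, int]
    threshold: int
    n_migs_kept: int
    n_migs_dropped: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.size_histogram.items()), columns=["mig_size", "n_migs"]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def group_by_umi(reads: Iterable[tuple[str, str, str]]) -> list[MIG]:
    """Group ``(umi, payload, quality)`` reads into one MIG per distinct UMI.

    Output is sorted by UMI so the result is independent of read order.
    """
    migs: dict[str, MIG] = {}
    for umi, payload, quality in reads:
        mig = migs.get(umi)
        if mig is None:
            mig = migs[umi] = MIG(umi)
        mig.members.append((payload, quality))
    return [migs[u] for u in sorted(migs)]


def _smoothed_log_counts(sizes: list[int], counts: list[int]) -> np.ndarray:
    """Moving-average (window 3) smoothing of log1p counts over observed sizes."""
    logs = np.log1p(np.asarray(counts, dtype=float))
    smoothed = np.empty_like(logs)
    for i in range(len(logs)):
        lo, hi = max(0, i - 1), min(len(logs), i + 2)
        smoothed[i] = logs[lo:hi].mean()
    return smoothed


def select_mig_threshold(
    size_histogram: dict[int, int],
    strategy: str = "histogram_valley",
    fixed_value: int = 2,
) -> int:
    """Choose the minimum MIG size ``t`` required to emit a consensus.

    ``fixed`` returns ``fixed_value``. ``histogram_valley`` smooths the
    log-histogram over the observed sizes, takes the main mode (largest
    smoothed mass at size > 1) and returns 1 + the size of the minimum
    strictly between the size-1 error peak and that mode; when the histogram
    has no such interior valley (unimodal or near-empty) it falls back to
    ``fixed_value``. The choice is logged.
    """
    if fixed_value < 1:
        raise UsageError("fixed_value must be >= 1")
    if not size_histogram:
        raise UsageError("size histogram is empty")
    if strategy == "fixed":
        logger.info("MIG threshold strategy=fixed t=%d", fixed_value)
        return fixed_value
    if strategy != "histogram_valley":
        raise UsageError(f"unknown threshold strategy {strategy!r}")

    sizes = sorted(s for s, c in size_histogram.items() if c > 0)
    counts = [size_histogram[s] for s in sizes]
    smoothed = _smoothed_log_counts(sizes, counts)
    above_one = [i for i, s in enumerate(sizes) if s > 1]
    if not above_one:
        logger.info("MIG threshold: histogram unimodal, falling back to t=%d", fixed_value)
        return fixed_value
    # main mode: largest smoothed mass at size > 1, ties to the larger size
    mode_i = max(above_one, key=lambda i: (smoothed[i], sizes[i]))
    candidates = [i for i, s in enumerate(sizes) if 1 < s < sizes[mode_i]]
    if not candidates:
        logger.info("MIG threshold: no interior valley, falling back to t=%d", fixed_value)
        return fixed_value
    valley_i = min(candidates, key=lambda i: (smoothed[i], sizes[i]))
    t = sizes[valley_i] + 1
    logger.info(
        "MIG threshold strategy=histogram_valley valley at size %d (mode %d) -> t=%d",
        sizes[valley_i], sizes[mode_i], t,
    )
    return t


def consensus_sequence(mig: MIG) -> tuple[str, str]:
    """Quality-weighted per-position consensus of a MIG.

    Members are restricted to the modal length (length ties break to the
    shorter). Per position, the winning base maximizes summed Phred quality;
    ties break by member count, then by alphabetical base. Returns the
    consensus and its quality string (winning summed quality, capped at 40).
    Deterministic and independent of member order.
    """
    if mig.size == 0:
        raise ValueError("cannot build a consensus from an empty MIG")
    length_counts = Counter(len(seq) for seq, _ in mig.members)
    modal_len = min(
        length_counts, key=lambda L: (-length_counts[L], L)
    )
    members = [(s, q) for s, q in mig.members if len(s) == modal_len]
    if len(members) == 1:
        seq, qual = members[0]
        return seq, "".join(chr(min(ord(c) - 33, _QUAL_CAP) + 33) for c in qual)

    seqs = np.frombuffer("".join(s for s, _ in members).encode(), dtype=np.uint8).reshape(
        len(members), modal_len
    )
    quals = (
        np.frombuffer("".join(q for _, q in members).encode(), dtype=np.uint8).reshape(
            len(members), modal_len
        )
        - 33
    ).astype(np.int64)

    qual_sums = np.zeros((4, modal_len), dtype=np.int64)
    base_counts = np.zeros((4, modal_len), dtype=np.int64)
    for idx, byte in ((0, 65), (1, 67), (2, 71), (3, 84)):
        mask = seqs == byte
        qual_sums[idx] = (quals * mask).sum(axis=0)
        base_counts[idx] = mask.sum(axis=0)
    # composite score implements the tie chain: quality, then count, then
    # alphabetically smallest base
    score = qual_sums * (1 << 32) + base_counts * (1 << 8) + np.arange(3, -1, -1)[:, None]
    winners = score.argmax(axis=0)
    cons = _IDX_TO_BASE[winners].tobytes().decode()
    win_qual = np.minimum(qual_sums[winners, np.arange(modal_len)], _QUAL_CAP)
    qual_str = (win_qual.astype(np.uint8) + 33).tobytes().decode()
    return cons, qual_str


def collapse_sample(
    reads: Iterable[tuple[str, str, str]],
    strategy: str = "histogram_valley",
    fixed_value: int = 2,
) -> tuple[list[tuple[str, str, str]], MigStats]:
    """Full per-sample collapse: group, threshold, consensus.

    Returns ``(consensus_reads, stats)`` where each consensus read is
    ``(umi, sequence, quality)``; only MIGs of size >= the selected threshold
    contribute.
    """
    migs = group_by_umi(reads)
    histogram = dict(Counter(m.size for m in migs))
    if not migs:
        return [], MigStats({}, fixed_value, 0, 0)
    t = select_mig_threshold(histogram, strategy=strategy, fixed_value=fixed_value)
    consensus_reads: list[tuple[str, str, str]] = []
    kept = 0
    for mig in migs:
        if mig.size >= t:
            mig.consensus, mig.consensus_quality = consensus_sequence(mig)
            consensus_reads.append((mig.umi, mig.consensus, mig.consensus_quality))
            kept += 1
    stats = MigStats(histogram, t, kept, len(migs) - kept)
    logger.info(
        "collapsed %d MIGs: kept %d, dropped %d (t=%d)",
        len(migs), kept, stats.n_migs_dropped, t,
    )
    return consensus_reads, stats
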