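"""V/J segment reference with CDR3 anchor motifs.

A clonotype is defined by its CDR3 — the hypervariable junction produced by
V(D)J recombination. The CDR3 of a read is located here by *anchor matching*:
each V segment carries a short anchor motif ending at the CDR3 start (the
conserved Cys codon region), each J segment an anchor beginning at the CDR3
end (the conserved Trp/Phe codon region). CDR3 coordinates are
junction-internal: the anchors themselves are excluded.

The built-in default reference is a small synthetic germline set (a handful
of V and J segments per immunoglobulin locus) generated deterministically;
it is co-designed with the repertoire simulator so that anchor-exact CDR3
extraction is lossless on error-free reads. Real-data users with their own
aligner can bypass extraction entirely and enter the pipeline at the
clonotype-table interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CHAINS = ("IGH", "IGK", "IGL")
HEAVY_GROUP = "IGH"
LIGHT_GROUP = "light"

_BASES = "ACGT"
_STOP_CODONS = ("TAA", "TAG", "TGA")

# conserved motifs the synthetic anchors are built around: the V anchor ends
# with the Tyr-Tyr-Cys codons preceding the CDR3, the J anchor starts with
# the Trp-Gly codons that terminate it
_V_MOTIF = "TATTACTGT"
_J_MOTIF = "TGGGGC"


def chain_group(chain: str) -> str:
    """Map a locus to its analysis group: IGH alone, IGK/IGL pooled as light.

    Heavy- and light-chain repertoires are analyzed separately; the two
    light-chain loci are pooled into one group while each record keeps its
    locus.
    """
    if chain == "IGH":
        return HEAVY_GROUP
    if chain in ("IGK", "IGL"):
        return LIGHT_GROUP
    raise ValueError(f"unknown chain {chain!r}")


class ReferenceError(ValueError):
    """Raised when a segment reference violates its invariants."""


@dataclass(frozen=True)
class Segment:
    """One germline V or J gene segment.

    ``anchor`` must occur exactly once in ``full_sequence``. ``anchor_offset``
    shifts the CDR3 boundary relative to the anchor end (V) or anchor start
    (J); 0 means the CDR3 starts right after the V anchor / ends right before
    the J anchor. ``cdr3_flank`` gives the germline-templated bases the
    segment contributes to the CDR3 itself (after the V anchor, or before the
    J anchor); the simulator uses it, extraction does not need it.
    """

    name: str
    segment_class: str  # "V" or "J"
    chain: str  # IGH | IGK | IGL
    full_sequence: str
    anchor: str
    anchor_offset: int = 0
    cdr3_flank: str = ""

    def __post_init__(self) -> None:
        if self.segment_class not in ("V", "J"):
            raise ReferenceError(f"segment_class must be V or J, got {self.segment_class!r}")
        if self.chain not in CHAINS:
            raise ReferenceError(f"chain must be one of {CHAINS}, got {self.chain!r}")
        if self.full_sequence.count(self.anchor) != 1:
            raise ReferenceError(
                f"anchor of {self.name} must occur exactly once in its full sequence"
            )


class SegmentReference:
    """Collection of V/J segments, indexed by chain and class."""

    def __init__(self, segments: list[Segment]):
        names = [s.name for s in segments]
        if len(set(names)) != len(names):
            raise ReferenceError("segment names must be unique")
        self.segments = list(segments)
        for chain in sorted({s.chain for s in segments}):
            for cls in ("V", "J"):
                if not self.segments_for(chain, cls):
                    raise ReferenceError(f"chain {chain} has no {cls} segments")

    def segments_for(self, chain: str, segment_class: str) -> list[Segment]:
        return [
            s for s in self.segments if s.chain == chain and s.segment_class == segment_class
        ]

    def group_segments(self, group: str, segment_class: str) -> list[Segment]:
        """All segments of a class whose locus belongs to an analysis group."""
        return [
            s
            for s in self.segments
            if s.segment_class == segment_class and chain_group(s.chain) == group
        ]

    def chains(self) -> list[str]:
        return sorted({s.chain for s in self.segments})

    def __getitem__(self, name: str) -> Segment:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(name)

    def to_table(self, path: str | Path) -> None:
        rows = [
            {
                "name": s.name,
                "segment_class": s.segment_class,
                "chain": s.chain,
                "full_sequence": s.full_sequence,
                "anchor": s.anchor,
                "anchor_offset": s.anchor_offset,
                "cdr3_flank": s.cdr3_flank,
            }
            for s in self.segments
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_table(cls, path: str | Path) -> "SegmentReference":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        segments = [
            Segment(
                name=r["name"],
                segment_class=r["segment_class"],
                chain=r["chain"],
                full_sequence=r["full_sequence"],
                anchor=r["anchor"],
                anchor_offset=int(r["anchor_offset"] or 0),
                cdr3_flank=r.get("cdr3_flank", ""),
            )
            for _, r in df.iterrows()
        ]
        return cls(segments)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def default_reference(seed: int = 20_170_303) -> SegmentReference:
    """Build the built-in synthetic germline reference.

    Per locus: a few V segments (~60 nt, anchor = distinguishing 3 nt plus
    the conserved Tyr-Tyr-Cys motif at the 3' end) and J segments (~42 nt,
    anchor = conserved Trp-Gly motif plus distinguishing 6 nt at the 5' end).
    Anchors are pairwise distinct and never occur in any other segment, so a
    single anchor hit identifies both the gene and the CDR3 boundary.
    Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    plan = {"IGH": (4, 3), "IGK": (3, 2), "IGL": (2, 2)}
    for _attempt in range(100):
        segments: list[Segment] = []
        ok = True
        for chain, (n_v, n_j) in plan.items():
            for i in range(n_v):
                anchor = _random_seq(rng, 3) + _V_MOTIF
                body = _random_seq(rng, 48)
                segments.append(
                    Segment(
                        name=f"{chain}V{i + 1}-1",
                        segment_class="V",
                        chain=chain,
                        full_sequence=body + anchor,
                        anchor=anchor,
                        cdr3_flank="GCGAGA" if chain == "IGH" else "CAGCAG",
                    )
                )
            for i in range(n_j):
                anchor = _J_MOTIF + _random_seq(rng, 6)
                body = _random_seq(rng, 30)
                segments.append(
                    Segment(
                        name=f"{chain}J{i + 1}",
                        segment_class="J",
                        chain=chain,
                        full_sequence=anchor + body,
                        anchor=anchor,
                        cdr3_flank="GACTAC" if chain == "IGH" else "TTCACT",
                    )
                )
        # cross-uniqueness: no anchor may occur in any other segment
        for s in segments:
            for t in segments:
                if s is t:
                    continue
                if s.anchor in t.full_sequence:
                    ok = False
            if any(s.anchor == t.anchor for t in segments if t is not s):
                ok = False
            for codon_start in range(0, len(s.cdr3_flank) - 2, 3):
                if s.cdr3_flank[codon_start : codon_start + 3] in _STOP_CODONS:
                    ok = False
        if ok:
            try:
                return SegmentReference(segments)
            except ReferenceError:
                continue
    raise ReferenceError("could not build a collision-free default reference")


_DEFAULT: SegmentReference | None = None


def get_default_reference() -> SegmentReference:
    """Cached built-in reference (construction is deterministic)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = default_reference()
    return _DEFAULT
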