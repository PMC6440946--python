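"""Synthetic immune-repertoire generator with full ground truth.

Emulates the observable structure of a bulk tumor B-cell-receptor library:
a handful of dominant (tumor) clones over a polyclonal background of
non-transformed B cells, somatic hypermutation (SHM) producing 1-bp CDR3
variant subclones, UMI labeling of every cDNA molecule, PCR duplication with
a heavy-tailed depth distribution, and uniform per-base sequencing error.
Reads are emitted already merged (single-end FASTQ with the UMI as a prefix).

The generative model, per sample:

1. clone roots: V and J drawn uniformly from the segment reference; root
   CDR3 = germline V flank + random NDN + germline J flank, codon-aligned
   and stop-free; roots of a shared (V, J) pair are kept >= 3 substitutions
   apart so planted clusters stay separable.
2. clone fractions: the stated dominant fractions, plus a symmetric
   Dirichlet split of the remaining mass over background clones, resampled
   until no background clone reaches the dominance threshold (so planted
   labels stay identifiable).
3. molecules: multinomial over clone fractions; each molecule's CDR3
   mutated i.i.d. per base at the SHM rate (star-like divergence from the
   root — the model reproduces 1-bp neighbor subclones, not lineage trees);
   each molecule tagged with a UMI drawn uniformly from 4^L (collisions
   possible and recorded, or suppressed with ``unique_umis``).
4. reads: per-molecule depth geometric (minimum 1) or fixed; per-base
   substitution errors at the sequencing error rate across the whole read,
   UMI included.

Everything is reproducible from the seed: identical config and seed give
byte-identical FASTQ and tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import ClonotypeRecord, UsageError, write_fastq
from .network import label_from_dominant_count
from .reference import SegmentReference, get_default_reference, LIGHT_GROUP, HEAVY_GROUP

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOP_CODONS = ("TAA", "TAG", "TGA")
_READ_QUAL_CHAR = "I"  # Phred 40


@dataclass
class SimulationConfig:
    """All knobs of the generator, with defaults for a typical tumor sample.

    ``dominant_fractions`` are the planted tumor-clone molecule fractions
    (one entry per independent rearrangement); their count determines the
    planted clonality label. ``shm_rate`` is the per-base CDR3 substitution
    probability per molecule, ``seq_error`` the per-base read error rate,
    ``pcr_mean_depth`` the mean reads per molecule.
    """

    seed: int = 0
    chain: str = HEAVY_GROUP  # "IGH" or "light"
    dominant_fractions: tuple[float, ...] = (0.9,)
    n_background_clones: int = 30
    background_concentration: float = 1.0
    n_molecules: int = 5000
    shm_rate: float = 0.005
    ndn_length_range: tuple[int, int] = (3, 33)
    umi_length: int = 12
    pcr_mean_depth: float = 5.0
    pcr_depth_model: str = "geometric"  # "geometric" | "fixed"
    seq_error: float = 0.003
    unique_umis: bool = False
    dominance_threshold: float = 0.10

    def __post_init__(self) -> None:
        self.dominant_fractions = tuple(float(f) for f in self.dominant_fractions)
        if any(not 0 < f <= 1 for f in self.dominant_fractions):
            raise UsageError("dominant fractions must lie in (0, 1]")
        if sum(self.dominant_fractions) > 1 + 1e-12:
            raise UsageError("dominant fractions must sum to at most 1")
        for name in ("shm_rate", "seq_error"):
            if not 0 <= getattr(self, name) <= 1:
                raise UsageError(f"{name} must be a probability")
        if self.chain not in (HEAVY_GROUP, LIGHT_GROUP):
            raise UsageError("chain must be 'IGH' or 'light'")
        if self.pcr_depth_model not in ("geometric", "fixed"):
            raise UsageError("pcr_depth_model must be 'geometric' or 'fixed'")
        if self.pcr_mean_depth < 1:
            raise UsageError("pcr_mean_depth must be >= 1")
        if self.n_background_clones == 0 and sum(self.dominant_fractions) < 1 - 1e-12:
            raise UsageError("without background clones, dominant fractions must sum to 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        for key in ("dominant_fractions", "ndn_length_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["dominant_fractions"] = list(self.dominant_fractions)
        data["ndn_length_range"] = list(self.ndn_length_range)
        with open(path, "w") as handle:
            yaml.safe_dump(data, handle, sort_keys=True)


@dataclass
class GroundTruth:
    """Complete provenance of a simulated sample.

    ``clones`` carries the planted rearrangements and fractions; every
    molecule maps to its clone (with its possibly SHM-mutated CDR3) and
    every read to its molecule, so recovery can be checked at any stage.
    """

    clones: pd.DataFrame  # clone_id chain v_call j_call cdr3_nt fraction is_dominant
    molecules: pd.DataFrame  # molecule_id clone_id cdr3_mut umi
    reads: pd.DataFrame  # read_id molecule_id
    label: str
    n_umi_collisions: int

    def truth_table(self, sample_id: str = "truth") -> list[ClonotypeRecord]:
        """The clonotype table a perfect pipeline would recover: molecules
        grouped by (chain, V, J, mutated CDR3)."""
        merged = self.molecules.merge(self.clones, on="clone_id")
        grouped = (
            merged.groupby(["chain", "v_call", "j_call", "cdr3_mut"], sort=True)
            .size()
            .reset_index(name="count")
        )
        return [
            ClonotypeRecord(
                sample_id=sample_id,
                chain=row["chain"],
                v_calls=frozenset([row["v_call"]]),
                j_calls=frozenset([row["j_call"]]),
                cdr3_nt=row["cdr3_mut"],
                count=int(row["count"]),
            )
            for _, row in grouped.iterrows()
        ]

    def to_dir(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.clones.to_csv(directory / "true_clones.tsv", sep="\t", index=False)
        self.molecules.to_csv(directory / "true_molecules.tsv", sep="\t", index=False)
        self.reads.to_csv(directory / "true_reads.tsv", sep="\t", index=False)


@dataclass
class SimulationResult:
    reads: list[tuple[str, str, str]]  # (name, sequence, quality)
    truth: GroundTruth
    config: SimulationConfig

    def write_fastq(self, path: str | Path) -> int:
        return write_fastq(self.reads, path)

    def umi_reads(self) -> list[tuple[str, str, str]]:
        """Reads as ``(umi, payload, quality)`` triples, i.e. what
        :func:`bcrnet.io.read_fastq_umi` would yield for the written FASTQ."""
        L = self.config.umi_length
        return [(seq[:L], seq[L:], qual[L:]) for _name, seq, qual in self.reads]


def _random_codons(rng: np.random.Generator, n_nt: int) -> str:
    """Stop-free random nucleotides, length a multiple of 3."""
    while True:
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=n_nt))
        if all(seq[i : i + 3] not in _STOP_CODONS for i in range(0, n_nt, 3)):
            return seq


def _has_stop(cdr3: str) -> bool:
    return any(cdr3[i : i + 3] in _STOP_CODONS for i in range(0, len(cdr3) - 2, 3))


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _draw_clones(
    rng: np.random.Generator, config: SimulationConfig, reference: SegmentReference
) -> pd.DataFrame:
    loci = ["IGH"] if config.chain == HEAVY_GROUP else ["IGK", "IGL"]
    fractions = _draw_fractions(rng, config)
    lo, hi = config.ndn_length_range
    ndn_choices = [n for n in range(lo, hi + 1) if n % 3 == 0]
    if not ndn_choices:
        raise UsageError("ndn_length_range contains no multiple of 3")
    rows = []
    seen: dict[tuple, list[str]] = {}
    for clone_id, fraction in enumerate(fractions):
        chain = loci[int(rng.integers(0, len(loci)))]
        v_segs = reference.segments_for(chain, "V")
        j_segs = reference.segments_for(chain, "J")
        v = v_segs[int(rng.integers(0, len(v_segs)))]
        j = j_segs[int(rng.integers(0, len(j_segs)))]
        for _attempt in range(1000):
            ndn_len = int(ndn_choices[int(rng.integers(0, len(ndn_choices)))])
            cdr3 = v.cdr3_flank + _random_codons(rng, ndn_len) + j.cdr3_flank
            if _has_stop(cdr3):
                continue
            # keep planted roots of one rearrangement >=3 substitutions apart
            # so clusters of different clones cannot touch via 1-bp variants
            neighbors = seen.get((chain, v.name, j.name, len(cdr3)), [])
            if all(_hamming(cdr3, other) >= 3 for other in neighbors):
                break
        else:
            raise UsageError("could not place a separable clone root")
        seen.setdefault((chain, v.name, j.name, len(cdr3)), []).append(cdr3)
        rows.append(
            {
                "clone_id": clone_id,
                "chain": chain,
                "v_call": v.name,
                "j_call": j.name,
                "cdr3_nt": cdr3,
                "fraction": fraction,
                "is_dominant": clone_id < len(config.dominant_fractions),
            }
        )
    return pd.DataFrame(rows)


def _draw_fractions(rng: np.random.Generator, config: SimulationConfig) -> np.ndarray:
    dom = np.asarray(config.dominant_fractions, dtype=float)
    bg_mass = 1.0 - dom.sum()
    if config.n_background_clones == 0 or bg_mass <= 0:
        return dom
    for _attempt in range(1000):
        bg = rng.dirichlet(
            np.full(config.n_background_clones, config.background_concentration)
        ) * bg_mass
        if bg.max() < config.dominance_threshold:
            return np.concatenate([dom, bg])
    raise UsageError(
        "could not draw background fractions below the dominance threshold; "
        "increase n_background_clones or background_concentration"
    )


def _mutate(rng: np.random.Generator, seq: str, n_sub: int) -> str:
    if n_sub == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    positions = rng.choice(len(arr), size=min(n_sub, len(arr)), replace=False)
    for pos in positions:
        alternatives = _BASES[_BASES != arr[pos]]
        arr[pos] = alternatives[int(rng.integers(0, 3))]
    return arr.tobytes().decode()


def _int_to_umi(value: int, length: int) -> str:
    out = []
    for _ in range(length):
        out.append("ACGT"[value & 3])
        value >>= 2
    return "".join(out)


def _draw_umis(rng: np.random.Generator, config: SimulationConfig) -> tuple[list[str], int]:
    n, L = config.n_molecules, config.umi_length
    space = 4**L
    if config.unique_umis:
        if n > space:
            raise UsageError("UMI space too small for unique UMIs")
        chosen: set[int] = set()
        values = []
        while len(values) < n:
            v = int(rng.integers(0, space))
            if v not in chosen:
                chosen.add(v)
                values.append(v)
        collisions = 0
    else:
        values = [int(v) for v in rng.integers(0, space, size=n)]
        collisions = n - len(set(values))
    return [_int_to_umi(v, L) for v in values], collisions


def simulate_repertoire(
    config: SimulationConfig, reference: SegmentReference | None = None
) -> SimulationResult:
    """Generate one sample: FASTQ-ready reads plus complete ground truth."""
    if reference is None:
        reference = get_default_reference()
    rng = np.random.default_rng(config.seed)

    clones = _draw_clones(rng, config, reference)
    counts = rng.multinomial(config.n_molecules, clones["fraction"].to_numpy())

    seg_by_name = {s.name: s for s in reference.segments}
    umis, n_collisions = _draw_umis(rng, config)

    mol_rows = []
    payloads: list[str] = []
    molecule_id = 0
    for _, clone in clones.iterrows():
        n_mol = int(counts[clone["clone_id"]])
        if n_mol == 0:
            continue
        root = clone["cdr3_nt"]
        n_subs = rng.binomial(len(root), config.shm_rate, size=n_mol)
        v_full = seg_by_name[clone["v_call"]].full_sequence
        j_full = seg_by_name[clone["j_call"]].full_sequence
        for k in n_subs:
            mutated = _mutate(rng, root, int(k))
            mol_rows.append(
                {
                    "molecule_id": molecule_id,
                    "clone_id": int(clone["clone_id"]),
                    "cdr3_mut": mutated,
                    "umi": umis[molecule_id],
                }
            )
            payloads.append(v_full + mutated + j_full)
            molecule_id += 1
    molecules = pd.DataFrame(mol_rows)

    if config.pcr_depth_model == "fixed":
        depths = np.full(molecule_id, int(round(config.pcr_mean_depth)), dtype=np.int64)
    else:
        depths = rng.geometric(1.0 / config.pcr_mean_depth, size=molecule_id)

    reads: list[tuple[str, str, str]] = []
    read_rows = []
    read_id = 0
    for mol_idx in range(molecule_id):
        base_read = umis[mol_idx] + payloads[mol_idx]
        n_err = rng.binomial(len(base_read), config.seq_error, size=int(depths[mol_idx]))
        for k in n_err:
            seq = _mutate(rng, base_read, int(k))
            reads.append(
                (f"read{read_id}|mol{mol_idx}", seq, _READ_QUAL_CHAR * len(seq))
            )
            read_rows.append({"read_id": read_id, "molecule_id": mol_idx})
            read_id += 1

    truth = GroundTruth(
        clones=clones,
        molecules=molecules,
        reads=pd.DataFrame(read_rows),
        label=planted_label(config),
        n_umi_collisions=n_collisions,
    )
    return SimulationResult(reads=reads, truth=truth, config=config)


def planted_label(config: SimulationConfig) -> str:
    """The clonality label the planted structure should yield downstream."""
    theta = config.dominance_threshold
    if any(f < theta for f in config.dominant_fractions):
        warnings.warn(
            "a planted dominant fraction is below the dominance threshold; "
            "the planted label is not guaranteed recoverable",
            stacklevel=2,
        )
    return label_from_dominant_count(len(config.dominant_fractions))
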