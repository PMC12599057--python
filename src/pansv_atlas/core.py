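"""Domain types and coordinate conventions.

All coordinates inside the package are 0-based half-open ``[start, end)``.
Conversion from the 1-based VCF/GFF conventions happens only in :mod:`pansv_atlas.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from intervaltree import IntervalTree

SV_TYPES = ("INS", "DEL", "INV", "TRA")
GENOTYPES = ("hom_ref", "het", "hom_alt", "missing")


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """Half-open genomic interval on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need end > start >= 0)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(slots=True)
class SVRecord:
    """One structural-variant call in one accession.

    ``length`` is the inserted-sequence length for INS and the reference span
    for DEL/INV; TRA records carry a 1-bp breakpoint interval.
    """

    interval: GenomicInterval
    sv_type: str
    length: int
    accession_id: str
    alt_sequence: Optional[str] = None
    qual: float = 0.0
    filter_status: str = "PASS"
    precise: bool = True
    genotype: str = "hom_alt"
    gq: int = 0
    dr: int = 0
    dv: int = 0
    allele_frequency: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.dr < 0 or self.dv < 0:
            raise ValueError("dr and dv must be >= 0")
        if (
            self.sv_type == "INS"
            and self.alt_sequence is not None
            and len(self.alt_sequence) != self.length
        ):
            raise ValueError("INS alt_sequence length must equal record length")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    def copy(self, **changes) -> "SVRecord":
        return replace(self, **changes)


@dataclass(slots=True)
class GeneModel:
    """A gene with its CDS and UTR sub-features (all half-open)."""

    gene_id: str
    interval: GenomicInterval
    strand: str = "+"
    cds: List[GenomicInterval] = field(default_factory=list)
    utr: List[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        for sub in list(self.cds) + list(self.utr):
            if not (
                sub.chrom == self.interval.chrom
                and sub.start >= self.interval.start
                and sub.end <= self.interval.end
            ):
                raise ValueError(
                    f"sub-feature {sub} outside gene {self.gene_id} {self.interval}"
                )


@dataclass(slots=True)
class ChromBins:
    """Fixed-width coverage bins on one chromosome (last bin may be partial)."""

    starts: np.ndarray  # int64, bin start positions
    depths: np.ndarray  # float64, length-weighted mean depth per bin
    widths: np.ndarray  # int64, bin widths in bp


@dataclass(slots=True)
class CoverageTrack:
    """Binned read-depth track for one accession."""

    accession_id: str
    bin_size: int
    bins: Dict[str, ChromBins] = field(default_factory=dict)

    def mean_depth(self) -> float:
        total = 0.0
        bp = 0
        for cb in self.bins.values():
            total += float(np.sum(cb.depths * cb.widths))
            bp += int(np.sum(cb.widths))
        if bp == 0:
            raise ValueError("empty coverage track")
        return total / bp


@dataclass(slots=True)
class EcotypePanel:
    """Accession -> ecotype mapping plus chromosome metadata."""

    ecotype_of: Dict[str, str]
    subgenome_of: Dict[str, str]
    chrom_lengths: Dict[str, int]

    def __post_init__(self) -> None:
        for chrom, sg in self.subgenome_of.items():
            if sg not in ("A", "C"):
                raise ValueError(f"subgenome of {chrom} must be A or C, got {sg!r}")
        missing = set(self.subgenome_of) ^ set(self.chrom_lengths)
        if missing:
            raise ValueError(f"chromosome metadata mismatch for {sorted(missing)}")

    @property
    def accessions(self) -> List[str]:
        return list(self.ecotype_of)

    def group(self, ecotype: str) -> List[str]:
        return [a for a, e in self.ecotype_of.items() if e == ecotype]

    @property
    def ecotypes(self) -> List[str]:
        seen: List[str] = []
        for e in self.ecotype_of.values():
            if e not in seen:
                seen.append(e)
        return seen


def interval_overlap(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> List[Tuple[int, int]]:
    """All index pairs (i, j) where a[i] overlaps b[j] by >= 1 bp.

    Half-open semantics: ``[100,200)`` does not overlap ``[200,300)``.
    Pairs are returned sorted by (i, j).
    """
    trees: Dict[str, IntervalTree] = {}
    for j, iv in enumerate(b):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, j)
    pairs: List[Tuple[int, int]] = []
    for i, iv in enumerate(a):
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(iv.start, iv.end):
            pairs.append((i, hit.data))
    pairs.sort()
    return pairs


def build_tree(intervals: Iterable[GenomicInterval]) -> Dict[str, IntervalTree]:
    """Per-chromosome interval trees, payload = index in input order."""
    trees: Dict[str, IntervalTree] = {}
    for idx, iv in enumerate(intervals):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, idx)
    return trees
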