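"""Per-accession SV filter cascade.

The cascade mirrors a dual-caller long-read workflow: per-caller quality and
homozygosity/precision filters, breakpoint-distance consensus between the two
callers, read-support proportional to sequencing coverage, exclusion of calls
inside large deleted segments, and PASS/<INV> selection for assembly-based
inversion call sets. All threshold comparisons are inclusive (>=).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

from intervaltree import IntervalTree

from .core import SVRecord


@dataclass(slots=True)
class FilterThresholds:
    """Quality cut-offs of the filter cascade (defaults are the pipeline's)."""

    min_qual: float = 50.0
    min_gq: int = 50
    min_dv: int = 12
    min_af: float = 0.9
    min_svlen: int = 30
    require_pass: bool = True
    require_precise: bool = True
    support_fraction: float = 0.4

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_af <= 1.0):
            raise ValueError("min_af must be in [0, 1]")
        if min(self.min_qual, self.min_gq, self.min_dv, self.min_svlen) < 0:
            raise ValueError("thresholds must be >= 0")


def min_support(mean_coverage: float, support_fraction: float = 0.4) -> int:
    """Minimum read support: ceil(support_fraction x coverage), at least 1."""
    if mean_coverage <= 0:
        raise ValueError("mean_coverage must be positive")
    return max(1, math.ceil(support_fraction * mean_coverage))


def apply_quality_filter(
    records: Sequence[SVRecord], thresholds: FilterThresholds = FilterThresholds()
) -> List[SVRecord]:
    """Retain PASS records with qual/gq/dv/length at or above threshold."""
    out = []
    for r in records:
        if thresholds.require_pass and r.filter_status != "PASS":
            continue
        if (
            r.qual >= thresholds.min_qual
            and r.gq >= thresholds.min_gq
            and r.dv >= thresholds.min_dv
            and r.length >= thresholds.min_svlen
        ):
            out.append(r)
    return out


def apply_homozygous_precise_filter(
    records: Sequence[SVRecord], thresholds: FilterThresholds = FilterThresholds()
) -> List[SVRecord]:
    """Retain precise records with allele frequency >= min_af.

    Records lacking both an AF tag and dr/dv evidence are removed (counted in
    one warning).
    """
    out = []
    undefined = 0
    for r in records:
        af = r.allele_frequency
        if af is None:
            if r.dr + r.dv > 0:
                af = r.dv / (r.dr + r.dv)
            else:
                undefined += 1
                continue
        if af >= thresholds.min_af and (r.precise or not thresholds.require_precise):
            out.append(r)
    if undefined:
        warnings.warn(f"removed {undefined} records with undefined allele frequency")
    return out


def consensus_two_callers(
    records_a: Sequence[SVRecord],
    records_b: Sequence[SVRecord],
    max_dist: int = 1000,
) -> List[SVRecord]:
    """Dual-caller consensus by breakpoint distance.

    An a-record is retained iff records_b holds an unconsumed record of the
    same sv_type on the same chromosome with start distance <= max_dist.
    Pairing is greedy nearest-first with deterministic left-to-right
    tie-breaking; each b-record is consumed at most once. Output preserves the
    order of records_a.
    """
    by_key: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
    for j, rb in enumerate(records_b):
        by_key.setdefault((rb.chrom, rb.sv_type), []).append((rb.start, j))

    candidates: List[Tuple[int, int, int, int, int]] = []
    for i, ra in enumerate(records_a):
        for start_b, j in by_key.get((ra.chrom, ra.sv_type), ()):
            dist = abs(ra.start - start_b)
            if dist <= max_dist:
                candidates.append((dist, ra.start, start_b, i, j))
    candidates.sort()

    used_a: set = set()
    used_b: set = set()
    kept: set = set()
    for _, _, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        kept.add(i)
    return [r for i, r in enumerate(records_a) if i in kept]


def remove_svs_in_deleted_segments(
    records: Sequence[SVRecord], segments: Sequence
) -> List[SVRecord]:
    """Drop records overlapping (>= 1 bp) a >=10-kbp DELETION segment.

    Duplication segments and sub-10-kbp segments never remove a record.
    """
    trees: Dict[str, IntervalTree] = {}
    for seg in segments:
        if getattr(seg, "segment_class", "DELETION") != "DELETION":
            continue
        if seg.interval.length < 10_000:
            continue
        trees.setdefault(seg.interval.chrom, IntervalTree()).addi(
            seg.interval.start, seg.interval.end
        )
    out = []
    for r in records:
        tree = trees.get(r.chrom)
        if tree is not None and tree.overlaps(r.interval.start, r.interval.end):
            continue
        out.append(r)
    return out


def filter_inversion_calls(records: Sequence[SVRecord]) -> List[SVRecord]:
    """From an assembly-alignment call set keep PASS <INV> records only."""
    return [r for r in records if r.sv_type == "INV" and r.filter_status == "PASS"]
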