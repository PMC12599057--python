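"""Read-depth calling of large deleted/duplicated segments and gene-level PAV.

A segment is a maximal run of consecutive coverage bins all deviating from
the accession's genome-wide mean depth by more than one standard deviation
(below: deletion; above: duplication), spanning at least 10 kbp. Bins above
an absolute depth cut-off (150 by default) are treated as unalignable
outliers and discarded before the mean and SD are computed; a discarded bin
splits a run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import CoverageTrack, EcotypePanel, GeneModel, GenomicInterval

PAV_STATES = ("NORMAL", "DELETED", "DUPLICATED")


@dataclass(slots=True)
class SegmentCall:
    """One >=10-kbp coverage-deviant segment in one accession."""

    accession_id: str
    interval: GenomicInterval
    segment_class: str  # DELETION or DUPLICATION
    mean_depth: float
    deviation_sd: float

    def __post_init__(self) -> None:
        if self.segment_class not in ("DELETION", "DUPLICATION"):
            raise ValueError(f"bad segment_class {self.segment_class!r}")


def call_depth_segments(
    track: CoverageTrack,
    min_len: int = 10_000,
    max_cov: float = 150.0,
    min_retained_bins: int = 100,
) -> List[SegmentCall]:
    """Call deleted/duplicated segments from a binned coverage track.

    Constant coverage (SD = 0) yields no segments. Fewer than
    ``min_retained_bins`` usable bins raises (the SD would be unstable).
    """
    if track.bin_size > 1000:
        raise ValueError("call_depth_segments expects bin_size <= 1000 bp")
    retained_depths = []
    for cb in track.bins.values():
        keep = cb.depths <= max_cov
        retained_depths.append(cb.depths[keep])
    if not retained_depths:
        raise ValueError("empty coverage track")
    all_depths = np.concatenate(retained_depths)
    if all_depths.size < min_retained_bins:
        raise ValueError(
            f"only {all_depths.size} retained bins (< {min_retained_bins}); "
            "standard deviation unstable"
        )
    mu = float(np.mean(all_depths))
    sigma = float(np.std(all_depths, ddof=1))
    if sigma == 0.0:
        return []

    calls: List[SegmentCall] = []
    for chrom, cb in track.bins.items():
        keep = cb.depths <= max_cov
        # -1 deletion-deviant, +1 duplication-deviant, 0 normal or discarded
        state = np.zeros(len(cb.depths), dtype=np.int8)
        state[keep & (cb.depths < mu - sigma)] = -1
        state[keep & (cb.depths > mu + sigma)] = 1
        state[~keep] = 0
        # maximal runs of identical nonzero state
        boundaries = np.flatnonzero(np.diff(state)) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [len(state)]))
        ends_bp = cb.starts + cb.widths
        for run_s, run_e in zip(starts, ends):
            s = state[run_s]
            if s == 0:
                continue
            seg_start = int(cb.starts[run_s])
            seg_end = int(ends_bp[run_e - 1])
            if seg_end - seg_start < min_len:
                continue
            w = cb.widths[run_s:run_e].astype(np.float64)
            mean_depth = float(np.sum(cb.depths[run_s:run_e] * w) / np.sum(w))
            calls.append(
                SegmentCall(
                    accession_id=track.accession_id,
                    interval=GenomicInterval(chrom, seg_start, seg_end),
                    segment_class="DELETION" if s < 0 else "DUPLICATION",
                    mean_depth=mean_depth,
                    deviation_sd=(mean_depth - mu) / sigma,
                )
            )
    return calls


def gene_pav_matrix(
    segments: Mapping[str, Sequence[SegmentCall]],
    genes: Sequence[GeneModel],
) -> pd.DataFrame:
    """Gene x accession PAV state matrix.

    A gene is DELETED/DUPLICATED in an accession iff it overlaps (>= 1 bp) a
    segment of that class; when both classes overlap, the class with the
    larger total overlap wins and ties go to DELETED.
    """
    accessions = list(segments)
    matrix = pd.DataFrame(
        "NORMAL", index=[g.gene_id for g in genes], columns=accessions, dtype=object
    )
    for acc in accessions:
        trees: Dict[str, IntervalTree] = {}
        for seg in segments[acc]:
            trees.setdefault(seg.interval.chrom, IntervalTree()).addi(
                seg.interval.start, seg.interval.end, seg.segment_class
            )
        for g in genes:
            tree = trees.get(g.interval.chrom)
            if tree is None:
                continue
            ov = {"DELETION": 0, "DUPLICATION": 0}
            for hit in tree.overlap(g.interval.start, g.interval.end):
                ov[hit.data] += min(hit.end, g.interval.end) - max(
                    hit.begin, g.interval.start
                )
            if ov["DELETION"] == 0 and ov["DUPLICATION"] == 0:
                continue
            state = "DELETED" if ov["DELETION"] >= ov["DUPLICATION"] else "DUPLICATED"
            matrix.at[g.gene_id, acc] = state
    return matrix


def ecotype_specific_genes(
    matrix: pd.DataFrame,
    panel: EcotypePanel,
    hi: float = 0.70,
    lo: float = 0.30,
    targets: Sequence[str] = ("WOSR", "SOSR", "EA_OSR", "SWEDE"),
    excluded_from_others: Sequence[str] = ("EA_OSR",),
) -> pd.DataFrame:
    """Genes whose PAV state tracks one ecotype.

    A (gene, state, ecotype) row is reported iff the state's fraction is
    >= hi in the target group and <= lo in the comparison set, where the
    comparison set is every other ecotype group except those in
    ``excluded_from_others`` (the semi-winter East Asian group by default,
    which is admixed with the oilseed groups).
    """
    rows = []
    cols = set(matrix.columns)
    for target in targets:
        group = [a for a in panel.group(target) if a in cols]
        if not group:
            warnings.warn(f"ecotype group {target} empty; skipped")
            continue
        others = [
            a
            for a in matrix.columns
            if panel.ecotype_of.get(a) not in excluded_from_others
            and panel.ecotype_of.get(a) != target
        ]
        if not others:
            warnings.warn(f"no comparison accessions for {target}; skipped")
            continue
        sub_t = matrix[group]
        sub_o = matrix[others]
        for state in ("DELETED", "DUPLICATED"):
            frac_t = (sub_t == state).mean(axis=1)
            frac_o = (sub_o == state).mean(axis=1)
            hit = (frac_t >= hi) & (frac_o <= lo)
            for gene_id in matrix.index[hit]:
                rows.append(
                    {
                        "gene_id": gene_id,
                        "ecotype": target,
                        "state": state,
                        "target_pct": 100.0 * frac_t[gene_id],
                        "others_pct": 100.0 * frac_o[gene_id],
                    }
                )
    return pd.DataFrame(
        rows, columns=["gene_id", "ecotype", "state", "target_pct", "others_pct"]
    )
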