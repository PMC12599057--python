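"""TE tagging of SV alleles and breakpoint flanks.

A BLASTN-like ungapped matcher: exact 11-mer seeds locate shared diagonals,
each seeded diagonal contributes its maximum-score ungapped segment
(match +1, mismatch -2), and a segment is reported only when its identity is
>= 0.99 over >= 30 bp. At most one hit (the longest valid one) is reported
per query, searching both strands. A minimum match length stands in for the
e-value cut-off.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .merge import PangenomeLocus

MATCH_SCORE = 1
MISMATCH_SCORE = -2
SEED_LEN = 11

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(slots=True)
class TEAnnotation:
    """Best TE-library match for one zone of one locus."""

    locus_id: str
    zone: str  # within | upstream_flank | downstream_flank
    te_family: str
    identity: float
    match_length: int
    strand: str = "+"


@dataclass(slots=True)
class _Hit:
    family: str
    identity: float
    length: int
    strand: str
    order: int


def best_ungapped_segment(match_mask: np.ndarray) -> Tuple[int, int, int, int]:
    """Max-score ungapped segment of a boolean match vector.

    Scores +1 per match, -2 per mismatch. Returns (score, start, end,
    n_matches); ties prefer the shorter then the leftmost segment (so an
    equal-score extension through a balanced mismatch cluster never swallows
    a pure match). Score <= 0 returns (0, 0, 0, 0).
    """
    scores = np.where(match_mask, MATCH_SCORE, MISMATCH_SCORE).astype(np.int64)
    pre = np.concatenate(([0], np.cumsum(scores)))
    minpre = np.minimum.accumulate(pre[:-1])
    # first index achieving the running minimum (leftmost segment start)
    idx = np.arange(len(pre) - 1)
    prev_min = np.concatenate(([np.iinfo(np.int64).max], minpre[:-1]))
    new_min = pre[:-1] < prev_min
    argmin = np.maximum.accumulate(np.where(new_min, idx, 0))
    seg_score = pre[1:] - minpre
    seg_len = np.arange(1, len(pre)) - argmin
    order = np.lexsort((argmin, seg_len, -seg_score))
    best = order[0]
    score = int(seg_score[best])
    if score <= 0:
        return 0, 0, 0, 0
    start, end = int(argmin[best]), int(best) + 1
    n_match = int(match_mask[start:end].sum())
    return score, start, end, n_match


class TELibraryIndex:
    """Seed index over a TE library (both strands), reusable across queries."""

    def __init__(self, library: Sequence[Tuple[str, str]], seed_len: int = SEED_LEN):
        self.library = [(name, seq.upper()) for name, seq in library]
        self.seed_len = seed_len
        self.strands: List[Tuple[int, str, str]] = []  # (lib idx, strand, seq)
        self.kmers: Dict[str, List[Tuple[int, int]]] = {}  # kmer -> (strand idx, pos)
        for li, (_, seq) in enumerate(self.library):
            for strand, s in (("+", seq), ("-", revcomp(seq))):
                si = len(self.strands)
                self.strands.append((li, strand, s))
                for pos in range(len(s) - seed_len + 1):
                    self.kmers.setdefault(s[pos : pos + seed_len], []).append((si, pos))


def te_match(
    query: str,
    te_library,
    min_identity: float = 0.99,
    min_match: int = 30,
) -> Optional[TEAnnotation]:
    """Best TE match of a query sequence, or None.

    ``te_library`` may be a list of (name, sequence) pairs or a prebuilt
    :class:`TELibraryIndex`.
    """
    if not query:
        raise ValueError("empty query sequence")
    index = (
        te_library
        if isinstance(te_library, TELibraryIndex)
        else TELibraryIndex(te_library)
    )
    if not index.library:
        return None
    q = query.upper()
    k = index.seed_len
    # seeded diagonals per library strand: diag = qpos - spos
    diagonals: Dict[Tuple[int, int], None] = {}
    for qpos in range(len(q) - k + 1):
        for si, spos in index.kmers.get(q[qpos : qpos + k], ()):
            diagonals[(si, qpos - spos)] = None
    best: Optional[_Hit] = None
    qarr = np.frombuffer(q.encode(), dtype=np.uint8)
    for si, diag in diagonals:
        li, strand, sseq = index.strands[si]
        sarr = np.frombuffer(sseq.encode(), dtype=np.uint8)
        qlo = max(0, diag)
        qhi = min(len(q), len(sseq) + diag)
        if qhi - qlo < min_match:
            continue
        mask = qarr[qlo:qhi] == sarr[qlo - diag : qhi - diag]
        score, s, e, n_match = best_ungapped_segment(mask)
        length = e - s
        if length < min_match or score <= 0:
            continue
        identity = n_match / length
        if identity < min_identity:
            continue
        cand = _Hit(index.library[li][0], identity, length, strand, li)
        if best is None or (cand.length, cand.identity, -cand.order, cand.strand) > (
            best.length,
            best.identity,
            -best.order,
            best.strand,
        ):
            best = cand
    if best is None:
        return None
    return TEAnnotation(
        locus_id="",
        zone="",
        te_family=best.family,
        identity=best.identity,
        match_length=best.length,
        strand=best.strand,
    )


def annotate_sv_te(
    loci: Sequence[PangenomeLocus],
    reference: Optional[Mapping[str, str]],
    te_library,
    flank: int = 100,
    min_identity: float = 0.99,
    min_match: int = 30,
) -> List[TEAnnotation]:
    """Tag SV alleles and +/-100-bp breakpoint flanks with TE matches.

    Zones are evaluated independently: ``within`` uses the allele sequence
    (INS) or the reference span (DEL/INV, when a reference is supplied);
    flanks come from the reference and are truncated at chromosome ends.
    """
    index = (
        te_library
        if isinstance(te_library, TELibraryIndex)
        else TELibraryIndex(te_library)
    )
    out: List[TEAnnotation] = []
    for locus in loci:
        rep = locus.representative
        zones: List[Tuple[str, str]] = []
        if rep.alt_sequence:
            zones.append(("within", rep.alt_sequence))
        elif reference is not None and rep.sv_type in ("DEL", "INV"):
            seq = reference[rep.chrom][rep.interval.start : rep.interval.end]
            if seq:
                zones.append(("within", seq))
        if reference is not None and rep.chrom in reference:
            chrom_seq = reference[rep.chrom]
            up = chrom_seq[max(0, rep.start - flank) : rep.start]
            down = chrom_seq[rep.interval.end : rep.interval.end + flank]
            if up:
                zones.append(("upstream_flank", up))
            if down:
                zones.append(("downstream_flank", down))
        for zone, seq in zones:
            hit = te_match(seq, index, min_identity=min_identity, min_match=min_match)
            if hit is not None:
                hit.locus_id = locus.locus_id
                hit.zone = zone
                out.append(hit)
    return out


def te_family_summary(
    annotations: Sequence[TEAnnotation],
    baseline: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Per-family share of annotated events and ratio to a baseline table."""
    if baseline is not None and sum(baseline.values()) > 1.0 + 1e-9:
        raise ValueError("baseline fractions must sum to <= 1")
    counts: Dict[str, int] = {}
    for ann in annotations:
        counts[ann.te_family] = counts.get(ann.te_family, 0) + 1
    total = sum(counts.values())
    rows = []
    for family in sorted(counts):
        share = counts[family] / total
        base = baseline.get(family) if baseline else None
        rows.append(
            {
                "te_family": family,
                "n": counts[family],
                "share": share,
                "baseline_share": base if base is not None else np.nan,
                "ratio_to_baseline": share / base if base else np.nan,
            }
        )
    return pd.DataFrame(
        rows, columns=["te_family", "n", "share", "baseline_share", "ratio_to_baseline"]
    )
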