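"""Cross-accession merging of filtered SV call sets into pangenome loci.

Two records merge when their start positions are close (a nonlinear distance
that scales with SV size, capped at 1000 bp) and their alleles are
compatible: >=90% sequence identity for insertions (edit distance), >=0.9
reciprocal length ratio for deletions/inversions (the deleted/inverted
reference sequence is shared by construction), and distance only for
translocations. Clustering is single-linkage per chromosome per SV type, so
the result is independent of accession input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import edlib
import numpy as np
import pandas as pd

from .core import EcotypePanel, GeneModel, SVRecord, build_tree


@dataclass(slots=True)
class PangenomeLocus:
    """One merged SV locus with its presence/absence vector."""

    locus_id: str
    representative: SVRecord
    sv_type: str
    presence: np.ndarray  # bool, aligned with `accessions`
    accessions: Tuple[str, ...]
    frequency_pct: float

    @property
    def carriers(self) -> List[str]:
        return [a for a, p in zip(self.accessions, self.presence) if p]


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _pair_distance_limit(
    len_a: int, len_b: int, max_dist: int, nonlinear: bool
) -> int:
    if not nonlinear:
        return max_dist
    return min(max_dist, max(100, int(0.5 * min(len_a, len_b))))


def _sequence_compatible(a: SVRecord, b: SVRecord, min_seq_id: float) -> bool:
    if a.sv_type == "TRA":
        return True
    la, lb = a.length, b.length
    if min(la, lb) <= 0:
        return False
    ratio = min(la, lb) / max(la, lb)
    if a.sv_type in ("DEL", "INV"):
        return ratio >= min_seq_id
    # INS: edit-distance identity; length ratio is a necessary condition
    if a.alt_sequence is None or b.alt_sequence is None:
        return ratio >= min_seq_id
    if ratio < min_seq_id:
        return False
    maxlen = max(la, lb)
    k = int(maxlen * (1.0 - min_seq_id))
    res = edlib.align(a.alt_sequence, b.alt_sequence, task="distance", k=k)
    dist = res["editDistance"]
    if dist < 0:  # beyond k
        return False
    return 1.0 - dist / maxlen >= min_seq_id


def merge_cohort(
    callsets: Mapping[str, Sequence[SVRecord]],
    max_dist: int = 1000,
    min_seq_id: float = 0.9,
    nonlinear_dist: bool = True,
    accessions: Optional[Sequence[str]] = None,
) -> List[PangenomeLocus]:
    """Single-linkage merge of per-accession call sets into pangenome loci.

    ``accessions`` fixes the presence-vector order (defaults to sorted
    callset keys; accessions with empty call sets simply carry nothing).
    At most one record per accession joins a locus (the one nearest the
    cluster's mean start). Loci are returned sorted by (chrom, start).
    """
    if accessions is None:
        accessions = sorted(callsets)
    acc_index = {a: i for i, a in enumerate(accessions)}
    acc_tuple = tuple(accessions)

    records: List[SVRecord] = []
    for acc in sorted(callsets):
        if acc not in acc_index:
            raise ValueError(f"callset accession {acc!r} missing from accession list")
        records.extend(callsets[acc])

    by_group: Dict[Tuple[str, str], List[int]] = {}
    for idx, rec in enumerate(records):
        by_group.setdefault((rec.chrom, rec.sv_type), []).append(idx)

    uf = _UnionFind(len(records))
    for key in sorted(by_group):
        idxs = by_group[key]
        # content-based sort => clustering independent of input order
        idxs.sort(
            key=lambda i: (
                records[i].start,
                records[i].length,
                records[i].accession_id,
                records[i].alt_sequence or "",
            )
        )
        for u, i in enumerate(idxs):
            ri = records[i]
            for j in idxs[u + 1 :]:
                rj = records[j]
                delta = rj.start - ri.start
                if delta > max_dist:
                    break
                if uf.find(i) == uf.find(j):
                    continue
                limit = _pair_distance_limit(
                    ri.length, rj.length, max_dist, nonlinear_dist
                )
                if delta <= limit and _sequence_compatible(ri, rj, min_seq_id):
                    uf.union(i, j)

    clusters: Dict[int, List[int]] = {}
    for idx in range(len(records)):
        clusters.setdefault(uf.find(idx), []).append(idx)

    loci: List[PangenomeLocus] = []
    for members in clusters.values():
        mean_start = float(np.mean([records[i].start for i in members]))
        # keep at most one record per accession: nearest to the cluster mean
        best: Dict[str, int] = {}
        for i in members:
            r = records[i]
            key = (
                abs(r.start - mean_start),
                r.start,
                r.length,
                r.alt_sequence or "",
            )
            cur = best.get(r.accession_id)
            if cur is None or key < (
                abs(records[cur].start - mean_start),
                records[cur].start,
                records[cur].length,
                records[cur].alt_sequence or "",
            ):
                best[r.accession_id] = i
        kept = sorted(best.values())
        rep_idx = min(kept, key=lambda i: (records[i].start, records[i].accession_id))
        rep = records[rep_idx]
        presence = np.zeros(len(acc_tuple), dtype=bool)
        for i in kept:
            presence[acc_index[records[i].accession_id]] = True
        loci.append(
            PangenomeLocus(
                locus_id="",
                representative=rep,
                sv_type=rep.sv_type,
                presence=presence,
                accessions=acc_tuple,
                frequency_pct=100.0 * presence.sum() / len(acc_tuple),
            )
        )
    loci.sort(key=lambda l: (l.representative.chrom, l.representative.start, l.sv_type))
    width = max(6, len(str(len(loci))))
    for n, locus in enumerate(loci, start=1):
        locus.locus_id = f"PSV{n:0{width}d}"
    return loci


def locus_frequencies(
    loci: Sequence[PangenomeLocus], panel: EcotypePanel
) -> pd.DataFrame:
    """Overall and per-ecotype carrier percentages per locus."""
    ecotypes = panel.ecotypes
    rows = []
    for locus in loci:
        carriers = set(locus.carriers)
        row = {
            "locus_id": locus.locus_id,
            "chrom": locus.representative.chrom,
            "start": locus.representative.start,
            "sv_type": locus.sv_type,
            "overall_pct": locus.frequency_pct,
        }
        for eco in ecotypes:
            group = panel.group(eco)
            row[f"{eco}_pct"] = (
                100.0 * sum(a in carriers for a in group) / len(group)
                if group
                else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def genes_with_sv_in_cds_utr(
    loci: Sequence[PangenomeLocus], genes: Sequence[GeneModel]
) -> pd.DataFrame:
    """Genes whose CDS or UTR overlaps a locus (intron-only overlap excluded).

    Feature class is CDS when any CDS is hit, else UTR.
    """
    features = []
    meta = []  # (gene_idx, is_cds)
    for gi, g in enumerate(genes):
        for iv in g.cds:
            features.append(iv)
            meta.append((gi, True))
        for iv in g.utr:
            features.append(iv)
            meta.append((gi, False))
    trees = build_tree(features)
    hits: Dict[int, Dict[str, bool]] = {}
    for locus in loci:
        iv = locus.representative.interval
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(iv.start, iv.end):
            gi, is_cds = meta[hit.data]
            entry = hits.setdefault(gi, {})
            prev = entry.get(locus.locus_id, False)
            entry[locus.locus_id] = prev or is_cds
    rows = []
    for gi in sorted(hits):
        locus_flags = hits[gi]
        rows.append(
            {
                "gene_id": genes[gi].gene_id,
                "locus_ids": ",".join(sorted(locus_flags)),
                "feature_class": "CDS" if any(locus_flags.values()) else "UTR",
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "locus_ids", "feature_class"])


def export_binary_matrix(
    loci: Sequence[PangenomeLocus],
    panel: EcotypePanel,
    format: str,
    path: str,
) -> None:
    """Export presence/absence for external tools.

    ``binary-alignment``: relaxed-PHYLIP 0/1 rows per accession.
    ``treemix-counts``: per-locus "carriers,non-carriers" per ecotype group.
    """
    if not loci:
        raise ValueError("empty locus list")
    accessions = list(loci[0].accessions)
    if format == "binary-alignment":
        with open(path, "w") as fh:
            fh.write(f"{len(accessions)} {len(loci)}\n")
            for ai, acc in enumerate(accessions):
                row = "".join("1" if l.presence[ai] else "0" for l in loci)
                fh.write(f"{acc}  {row}\n")
    elif format == "treemix-counts":
        groups = panel.ecotypes
        members = {g: [accessions.index(a) for a in panel.group(g)] for g in groups}
        with open(path, "w") as fh:
            fh.write(" ".join(groups) + "\n")
            for locus in loci:
                cells = []
                for g in groups:
                    idx = members[g]
                    carriers = int(sum(locus.presence[i] for i in idx))
                    cells.append(f"{carriers},{len(idx) - carriers}")
                fh.write(" ".join(cells) + "\n")
    else:
        raise ValueError(f"unknown export format {format!r}")
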