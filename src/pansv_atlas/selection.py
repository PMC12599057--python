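"""Weir-Cockerham FST on binary SV loci and the windowed selection scan.

Carriers of a locus are homozygous for the variant allele (1/1) and
non-carriers homozygous reference, matching a homozygous-only call set, so
the observed heterozygosity term of the estimator is zero. Per 50-kbp window
the weighted (ratio-of-sums) estimate sum(a)/sum(a+b+c) is computed, FST
values are standardised to z-scores over all windows of the comparison, and
windows with z >= 1.645 (one-tailed alpha = 0.05) merge into candidate
regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import GeneModel, GenomicInterval, build_tree
from .merge import PangenomeLocus

Z_CRIT_DEFAULT = 1.645


@dataclass(slots=True)
class FstComponents:
    """Variance components of the two-population Weir-Cockerham estimator."""

    locus_id: str
    a: float
    d: float  # a + b + c
    theta: Optional[float]
    n_i: Tuple[int, int]
    p_i: Tuple[float, float]
    nbar: float
    nc: float
    pbar: float
    s2: float
    hbar: float


@dataclass(slots=True)
class CandidateRegion:
    """Adjacent significant windows merged into one region."""

    interval: GenomicInterval
    peak_z: float
    label: str = ""
    genes: List[str] = field(default_factory=list)


def wc_fst_components_arrays(
    p1: np.ndarray,
    p2: np.ndarray,
    n1: int,
    n2: int,
    h1: Optional[np.ndarray] = None,
    h2: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorised a and d = a+b+c for many loci of one two-population split.

    p_i are variant-allele frequencies, n_i diploid sample sizes, h_i
    observed heterozygote frequencies (default 0: all-homozygous cohorts).
    """
    r = 2
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if h1 is None:
        h1 = np.zeros_like(p1)
    if h2 is None:
        h2 = np.zeros_like(p2)
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    pq = pbar * (1.0 - pbar)
    a = (nbar / nc) * (
        s2 - (pq - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pq - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2.0
    return a, a + b + c


def wc_fst_site(
    presence: Mapping[str, bool],
    populations: Tuple[Sequence[str], Sequence[str]],
    locus_id: str = "",
) -> FstComponents:
    """Weir-Cockerham components for one binary locus and two populations.

    ``presence`` maps accession -> carrier status (homozygous). theta is
    None for monomorphic loci (d = 0). Populations of size < 2 raise.
    """
    pop1, pop2 = populations
    n1, n2 = len(pop1), len(pop2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each population needs >= 2 accessions")
    p1 = sum(bool(presence[a]) for a in pop1) / n1
    p2 = sum(bool(presence[a]) for a in pop2) / n2
    a, d = wc_fst_components_arrays(np.array([p1]), np.array([p2]), n1, n2)
    a_val, d_val = float(a[0]), float(d[0])
    theta = a_val / d_val if d_val != 0.0 else None
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    return FstComponents(
        locus_id=locus_id,
        a=a_val,
        d=d_val,
        theta=theta,
        n_i=(n1, n2),
        p_i=(p1, p2),
        nbar=nbar,
        nc=nc,
        pbar=pbar,
        s2=s2,
        hbar=0.0,
    )


def windowed_fst(
    loci: Sequence[PangenomeLocus],
    populations: Tuple[Sequence[str], Sequence[str]],
    window: int = 50_000,
) -> pd.DataFrame:
    """Per-window weighted FST = sum(a)/sum(d) over loci starting in the window.

    Loci with d = 0 (monomorphic across both populations) are skipped;
    windows with no usable locus are omitted. A per-window mean-of-ratios
    column is emitted alongside for comparison.
    """
    pop1, pop2 = [list(p) for p in populations]
    if len(pop1) < 2 or len(pop2) < 2:
        raise ValueError("each population needs >= 2 accessions")
    if not loci:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "n_loci", "fst_weighted", "fst_mean"]
        )
    acc_order = list(loci[0].accessions)
    idx1 = [acc_order.index(a) for a in pop1]
    idx2 = [acc_order.index(a) for a in pop2]
    presence = np.stack([l.presence for l in loci])
    p1 = presence[:, idx1].mean(axis=1)
    p2 = presence[:, idx2].mean(axis=1)
    a, d = wc_fst_components_arrays(p1, p2, len(idx1), len(idx2))
    chroms = np.array([l.representative.chrom for l in loci])
    starts = np.array([l.representative.start for l in loci])
    usable = d != 0.0
    rows = []
    for chrom in sorted(set(chroms)):
        mask = usable & (chroms == chrom)
        if not mask.any():
            continue
        wbin = starts[mask] // window
        a_c, d_c = a[mask], d[mask]
        ratios = a_c / d_c
        for w in np.unique(wbin):
            sel = wbin == w
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(w) * window,
                    "end": (int(w) + 1) * window,
                    "n_loci": int(sel.sum()),
                    "fst_weighted": float(a_c[sel].sum() / d_c[sel].sum()),
                    "fst_mean": float(ratios[sel].mean()),
                }
            )
    return pd.DataFrame(rows)


def zscore_windows(
    windows: pd.DataFrame, value_col: str = "fst_weighted"
) -> pd.DataFrame:
    """Attach z = (x - mu)/sigma computed over ALL windows of the comparison.

    sigma is the sample standard deviation (n-1). Fewer than two windows or
    zero variance raise.
    """
    if len(windows) < 2:
        raise ValueError("need >= 2 windows to standardise")
    x = windows[value_col].to_numpy(dtype=float)
    mu = float(x.mean())
    sigma = float(x.std(ddof=1))
    if sigma == 0.0:
        raise ValueError("zero variance across windows; z undefined")
    out = windows.copy()
    out["z"] = (x - mu) / sigma
    return out


def candidate_regions(
    windows: pd.DataFrame,
    z_crit: float = Z_CRIT_DEFAULT,
    inclusive: bool = True,
    label: str = "",
) -> List[CandidateRegion]:
    """Merge adjacent significant windows (z >= z_crit) into regions."""
    if "z" not in windows.columns:
        raise ValueError("windows need a z column (run zscore_windows)")
    flagged = (
        windows[windows["z"] >= z_crit]
        if inclusive
        else windows[windows["z"] > z_crit]
    )
    flagged = flagged.sort_values(["chrom", "start"])
    regions: List[CandidateRegion] = []
    for _, row in flagged.iterrows():
        if (
            regions
            and regions[-1].interval.chrom == row["chrom"]
            and regions[-1].interval.end == row["start"]
        ):
            prev = regions[-1]
            regions[-1] = CandidateRegion(
                GenomicInterval(prev.interval.chrom, prev.interval.start, int(row["end"])),
                max(prev.peak_z, float(row["z"])),
                label=label,
                genes=prev.genes,
            )
        else:
            regions.append(
                CandidateRegion(
                    GenomicInterval(row["chrom"], int(row["start"]), int(row["end"])),
                    float(row["z"]),
                    label=label,
                )
            )
    return regions


def annotate_regions(
    regions: Sequence[CandidateRegion], genes: Sequence[GeneModel]
) -> List[CandidateRegion]:
    """Attach every gene overlapping a region by >= 1 bp."""
    trees = build_tree([g.interval for g in genes])
    for region in regions:
        tree = trees.get(region.interval.chrom)
        if tree is None:
            region.genes = []
            continue
        hits = tree.overlap(region.interval.start, region.interval.end)
        region.genes = sorted(genes[h.data].gene_id for h in hits)
    return list(regions)


def overlap_candidate_sets(
    regions_a: Sequence[CandidateRegion], regions_b: Sequence[CandidateRegion]
) -> pd.DataFrame:
    """Pairs of regions from the two sets overlapping by >= 1 bp."""
    rows = []
    for i, ra in enumerate(regions_a):
        for j, rb in enumerate(regions_b):
            ov = ra.interval.overlap_length(rb.interval)
            if ov > 0:
                rows.append(
                    {
                        "index_a": i,
                        "index_b": j,
                        "chrom": ra.interval.chrom,
                        "overlap_bp": ov,
                    }
                )
    return pd.DataFrame(rows, columns=["index_a", "index_b", "chrom", "overlap_bp"])
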