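"""Ecotype representation rules, Fisher/BH association tests, and saturation.

Over/under-representation uses the inclusive 70%/30% carrier-fraction rules
with the admixed East Asian group excluded from the comparison set.
Association per locus x ecotype is a two-sided Fisher exact test on the
2x2 carrier table with Benjamini-Hochberg adjustment across all tests of a
run. The saturation (accumulation) curve resamples growing accession subsets
1000 times and counts distinct genes captured.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import EcotypePanel
from .merge import PangenomeLocus


@dataclass(slots=True)
class SaturationCurve:
    """Mean/SD of distinct genes captured by k sampled genomes, k = 1..N."""

    k: np.ndarray
    mean_genes: np.ndarray
    sd_genes: np.ndarray
    iterations: int
    seed: int


def ecotype_representation(
    loci: Sequence[PangenomeLocus],
    panel: EcotypePanel,
    hi: float = 0.70,
    lo: float = 0.30,
    targets: Sequence[str] = ("WOSR", "SOSR", "EA_OSR", "SWEDE"),
    excluded_from_others: Sequence[str] = ("EA_OSR",),
) -> pd.DataFrame:
    """Over/under-represented loci per target ecotype (inclusive thresholds).

    Over: target carrier fraction >= hi and comparison fraction <= lo.
    Under: target <= lo and comparison >= hi. The comparison set excludes
    the target group and the groups in ``excluded_from_others``.
    """
    rows = []
    for locus in loci:
        carriers = set(locus.carriers)
        acc = locus.accessions
        for target in targets:
            group = [a for a in acc if panel.ecotype_of.get(a) == target]
            others = [
                a
                for a in acc
                if panel.ecotype_of.get(a) != target
                and panel.ecotype_of.get(a) not in excluded_from_others
            ]
            if not group or not others:
                continue
            ft = sum(a in carriers for a in group) / len(group)
            fo = sum(a in carriers for a in others) / len(others)
            status = None
            if ft >= hi and fo <= lo:
                status = "over"
            elif ft <= lo and fo >= hi:
                status = "under"
            if status:
                rows.append(
                    {
                        "locus_id": locus.locus_id,
                        "ecotype": target,
                        "status": status,
                        "target_pct": 100.0 * ft,
                        "others_pct": 100.0 * fo,
                    }
                )
    return pd.DataFrame(
        rows, columns=["locus_id", "ecotype", "status", "target_pct", "others_pct"]
    )


def fisher_exact_2x2(
    contingency: Sequence[Sequence[int]],
) -> Tuple[float, Optional[float]]:
    """Two-sided Fisher exact p and a Haldane-Anscombe odds ratio.

    p sums hypergeometric probabilities of all tables with the observed
    margins at most as probable as the observed one. The odds ratio is the
    sample OR (n11*n22)/(n12*n21), with 0.5 added to every cell whenever any
    cell is zero. A zero margin gives p = 1 and an undefined odds ratio.
    """
    table = np.asarray(contingency, dtype=np.int64)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("contingency must be a 2x2 table of non-negative integers")
    n11, n12 = int(table[0, 0]), int(table[0, 1])
    n21, n22 = int(table[1, 0]), int(table[1, 1])
    if min(n11 + n12, n21 + n22, n11 + n21, n12 + n22) == 0:
        return 1.0, None
    r1, r2 = n11 + n12, n21 + n22
    c1, n = n11 + n21, n11 + n12 + n21 + n22
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[n11 - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    if min(n11, n12, n21, n22) == 0:
        odds = ((n11 + 0.5) * (n22 + 0.5)) / ((n12 + 0.5) * (n21 + 0.5))
    else:
        odds = (n11 * n22) / (n12 * n21)
    return min(p, 1.0), odds


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def association_tests(
    loci: Sequence[PangenomeLocus],
    panel: EcotypePanel,
    targets: Sequence[str] = ("WOSR", "SOSR", "EA_OSR", "SWEDE"),
) -> pd.DataFrame:
    """Fisher tests of carrier status (target vs all other ecotypes) per locus.

    BH adjustment is applied globally over all locus x ecotype tests of the
    run; direction is 'enriched' for OR > 1 and 'depleted' for OR < 1.
    """
    rows = []
    cache: Dict[Tuple[int, int, int, int], Tuple[float, Optional[float]]] = {}
    for locus in loci:
        carriers = set(locus.carriers)
        for target in targets:
            group = [a for a in locus.accessions if panel.ecotype_of.get(a) == target]
            others = [
                a for a in locus.accessions if panel.ecotype_of.get(a) != target
            ]
            if not group or not others:
                continue
            n11 = sum(a in carriers for a in group)
            n12 = len(group) - n11
            n21 = sum(a in carriers for a in others)
            n22 = len(others) - n21
            key = (n11, n12, n21, n22)
            if key not in cache:  # identical tables recur across loci
                cache[key] = fisher_exact_2x2([[n11, n12], [n21, n22]])
            p, odds = cache[key]
            rows.append(
                {
                    "locus_id": locus.locus_id,
                    "ecotype": target,
                    "n11": n11,
                    "n12": n12,
                    "n21": n21,
                    "n22": n22,
                    "odds_ratio": odds if odds is not None else np.nan,
                    "p_value": p,
                    "direction": (
                        "enriched"
                        if odds is not None and odds > 1
                        else "depleted"
                        if odds is not None and odds < 1
                        else "none"
                    ),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "locus_id",
            "ecotype",
            "n11",
            "n12",
            "n21",
            "n22",
            "odds_ratio",
            "p_value",
            "direction",
        ],
    )
    if not df.empty:
        df["q_value"] = bh_adjust(df["p_value"].to_numpy())
    else:
        df["q_value"] = pd.Series(dtype=float)
    return df


def saturation_curve(
    gene_presence,
    iterations: int = 1000,
    seed: int = 0,
) -> SaturationCurve:
    """Gene-accumulation curve over random accession orderings.

    ``gene_presence`` is a gene x accession boolean matrix (DataFrame or
    array). For each of ``iterations`` random permutations the cumulative
    union of gene sets is tracked, giving mean and SD of distinct genes at
    every sample size k.
    """
    matrix = (
        gene_presence.to_numpy()
        if isinstance(gene_presence, pd.DataFrame)
        else np.asarray(gene_presence)
    ).astype(bool)
    if matrix.size == 0:
        raise ValueError("empty gene presence matrix")
    n_genes, n_acc = matrix.shape
    rng = np.random.default_rng(seed)
    counts = np.empty((iterations, n_acc), dtype=np.int64)
    for it in range(iterations):
        perm = rng.permutation(n_acc)
        cum = np.logical_or.accumulate(matrix[:, perm], axis=1)
        counts[it] = cum.sum(axis=0)
    return SaturationCurve(
        k=np.arange(1, n_acc + 1),
        mean_genes=counts.mean(axis=0),
        sd_genes=counts.std(axis=0, ddof=0),
        iterations=iterations,
        seed=seed,
    )
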