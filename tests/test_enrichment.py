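"""Representation rules, Fisher exact + BH oracles, and saturation curves."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from pansv_atlas.core import EcotypePanel, GenomicInterval, SVRecord
from pansv_atlas.enrichment import (
    association_tests,
    bh_adjust,
    ecotype_representation,
    fisher_exact_2x2,
    saturation_curve,
)
from pansv_atlas.merge import PangenomeLocus


def fisher_oracle(n11, n12, n21, n22):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration in exact
    rational arithmetic: sum P(x) over all tables with the observed margins
    whose probability does not exceed the observed one."""
    r1, r2 = n11 + n12, n21 + n22
    c1 = n11 + n21
    n = r1 + r2

    def prob(x):
        return Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), math.comb(n, c1))

    p_obs = prob(n11)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return float(sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs))


def make_locus(carriers, accessions, locus_id="L1", start=1000):
    presence = np.array([a in carriers for a in accessions])
    rec = SVRecord(
        interval=GenomicInterval("A01", start, start + 100),
        sv_type="INV",
        length=100,
        accession_id=accessions[0],
    )
    return PangenomeLocus(
        locus_id, rec, "INV", presence, tuple(accessions),
        100.0 * presence.sum() / len(accessions),
    )


def swede_panel():
    eco = {}
    for e, n in (("WOSR", 20), ("SOSR", 25), ("EA_OSR", 10), ("SWEDE", 17)):
        for i in range(n):
            eco[f"{e}{i:02d}"] = e
    return EcotypePanel(eco, {"A01": "A"}, {"A01": 10_000_000})


class TestEcotypeRepresentation:
    def test_swede_specific_inversion_over_represented(self):
        panel = swede_panel()
        accs = list(panel.ecotype_of)
        locus = make_locus(set(panel.group("SWEDE")), accs)
        out = ecotype_representation([locus], panel)
        row = out[(out.ecotype == "SWEDE")]
        assert row.iloc[0].status == "over"

    def test_inclusive_70_30_boundary(self):
        panel = swede_panel()
        accs = list(panel.ecotype_of)
        # 12/17 swedes = 70.59% >= 70; hand-pick comparison fraction:
        # carriers among WOSR+SOSR: 13/45 = 28.9% <= 30 -> over
        carriers = set(panel.group("SWEDE")[:12]) | set(panel.group("WOSR")[:13])
        out = ecotype_representation([make_locus(carriers, accs)], panel)
        assert (out[(out.ecotype == "SWEDE")].status == "over").all()
        assert len(out[(out.ecotype == "SWEDE")]) == 1
        # 14/45 = 31.1% > 30 -> not reported
        carriers = set(panel.group("SWEDE")[:12]) | set(panel.group("WOSR")[:14])
        out = ecotype_representation([make_locus(carriers, accs)], panel)
        assert out[(out.ecotype == "SWEDE")].empty

    def test_under_representation(self):
        panel = swede_panel()
        accs = list(panel.ecotype_of)
        carriers = set(panel.group("WOSR")) | set(panel.group("SOSR"))
        out = ecotype_representation([make_locus(carriers, accs)], panel)
        assert (out[out.ecotype == "SWEDE"].status == "under").all()
        assert len(out[out.ecotype == "SWEDE"]) == 1

    def test_balanced_locus_not_reported(self):
        panel = swede_panel()
        accs = list(panel.ecotype_of)
        carriers = set(accs[::2])  # ~50% everywhere
        out = ecotype_representation([make_locus(carriers, accs)], panel)
        assert out.empty

    def test_ea_osr_excluded_from_comparison(self):
        panel = swede_panel()
        accs = list(panel.ecotype_of)
        carriers = set(panel.group("SWEDE")) | set(panel.group("EA_OSR"))
        out = ecotype_representation([make_locus(carriers, accs)], panel)
        assert (out[out.ecotype == "SWEDE"].status == "over").all()
        assert len(out[out.ecotype == "SWEDE"]) == 1


class TestFisherExact:
    def test_strong_association(self):
        p, odds = fisher_exact_2x2([[10, 0], [0, 10]])
        assert p == pytest.approx(2 / 184_756, rel=1e-7)
        assert odds == pytest.approx((10.5 * 10.5) / (0.5 * 0.5))

    def test_no_association(self):
        p, odds = fisher_exact_2x2([[5, 5], [5, 5]])
        assert p == pytest.approx(1.0)
        assert odds == pytest.approx(1.0)

    def test_moderate_table(self):
        p, _ = fisher_exact_2x2([[3, 1], [1, 3]])
        assert p == pytest.approx(34 / 70, rel=1e-7)

    def test_zero_margin(self):
        p, odds = fisher_exact_2x2([[0, 0], [5, 5]])
        assert p == 1.0
        assert odds is None

    def test_haldane_correction_on_zero_cell(self):
        _, odds = fisher_exact_2x2([[8, 2], [0, 10]])
        assert odds == pytest.approx((8.5 * 10.5) / (2.5 * 0.5))

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [1, 1]])

    def test_matches_enumeration_for_all_small_tables(self):
        """Exhaustive agreement with the rational-arithmetic oracle for every
        table with total N <= 40 (the per-margin pmf is enumerated once)."""
        N_MAX = 40
        for n in range(1, N_MAX + 1):
            for r1 in range(n + 1):
                r2 = n - r1
                for c1 in range(n + 1):
                    lo, hi = max(0, c1 - r2), min(r1, c1)
                    degenerate = min(r1, r2, c1, n - c1) == 0
                    if not degenerate:
                        denom = math.comb(n, c1)
                        pmf = [
                            Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), denom)
                            for x in range(lo, hi + 1)
                        ]
                    for x in range(lo, hi + 1):
                        table = [[x, r1 - x], [c1 - x, r2 - (c1 - x)]]
                        p, _ = fisher_exact_2x2(table)
                        if degenerate:
                            assert p == 1.0
                        else:
                            p_obs = pmf[x - lo]
                            p_o = float(sum(q for q in pmf if q <= p_obs))
                            assert p == pytest.approx(p_o, rel=1e-6, abs=1e-12)

    def test_agrees_with_scipy_fisher_exact(self):
        from scipy.stats import fisher_exact as scipy_fisher

        rng = np.random.default_rng(5)
        for _ in range(300):
            table = rng.integers(0, 30, size=(2, 2))
            if min(table.sum(axis=0).min(), table.sum(axis=1).min()) == 0:
                continue
            p, _ = fisher_exact_2x2(table)
            assert p == pytest.approx(scipy_fisher(table)[1], rel=1e-6, abs=1e-12)


class TestBhAdjust:
    def test_step_up_examples(self):
        assert list(bh_adjust([0.01, 0.02, 0.03])) == pytest.approx([0.03, 0.03, 0.03])
        assert list(bh_adjust([0.05])) == pytest.approx([0.05])
        assert list(bh_adjust([0.5, 1.0])) == pytest.approx([1.0, 1.0])

    def test_returned_in_original_order(self):
        q = bh_adjust([0.9, 0.001, 0.5])
        assert q[1] == min(q)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    def test_matches_direct_formula_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(0, 1, int(rng.integers(1, 60)))
            q = bh_adjust(p)
            m = len(p)
            order = np.argsort(p)
            expected = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                expected[i] = running
            assert q == pytest.approx(expected)
            assert (q >= p - 1e-12).all()

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.uniform(0, 1, 200)
        q = bh_adjust(p)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert q == pytest.approx(q_sm)


class TestAssociationTests:
    def test_contingency_and_direction(self):
        panel = swede_panel()
        accs = list(panel.ecotype_of)
        locus = make_locus(set(panel.group("SWEDE")), accs)
        out = association_tests([locus], panel)
        swede = out[out.ecotype == "SWEDE"].iloc[0]
        assert (swede.n11, swede.n12) == (17, 0)
        assert (swede.n21, swede.n22) == (0, 55)
        assert swede.direction == "enriched"
        assert swede.q_value >= swede.p_value - 1e-15
        wosr = out[out.ecotype == "WOSR"].iloc[0]
        assert wosr.direction == "depleted"


class TestSaturationCurve:
    def test_identical_gene_sets_give_flat_curve(self):
        m = np.ones((30, 8), dtype=bool)
        m[10:, :] = False
        curve = saturation_curve(m, iterations=50, seed=0)
        assert np.allclose(curve.mean_genes, 10)
        assert np.allclose(curve.sd_genes, 0)

    def test_full_sample_reaches_union_with_zero_sd(self):
        rng = np.random.default_rng(2)
        m = rng.random((100, 12)) < 0.3
        curve = saturation_curve(m, iterations=100, seed=1)
        union = int(m.any(axis=1).sum())
        assert curve.mean_genes[-1] == pytest.approx(union)
        assert curve.sd_genes[-1] == pytest.approx(0.0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        m = rng.random((50, 10)) < 0.4
        c1 = saturation_curve(m, iterations=40, seed=7)
        c2 = saturation_curve(m, iterations=40, seed=7)
        assert np.array_equal(c1.mean_genes, c2.mean_genes)
        assert np.array_equal(c1.sd_genes, c2.sd_genes)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_mean_non_decreasing_in_k(self, seed):
        rng = np.random.default_rng(seed + 100)
        m = rng.random((200, 15)) < 0.2
        curve = saturation_curve(m, iterations=60, seed=seed)
        assert (np.diff(curve.mean_genes) >= -1e-9).all()

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            saturation_curve(np.zeros((0, 0), dtype=bool))
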