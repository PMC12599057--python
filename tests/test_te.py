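"""BLASTN-like ungapped TE matching and SV/flank annotation."""

import random

import numpy as np
import pytest

from pansv_atlas.core import GenomicInterval, SVRecord
from pansv_atlas.merge import PangenomeLocus
from pansv_atlas.te import (
    MATCH_SCORE,
    MISMATCH_SCORE,
    TELibraryIndex,
    annotate_sv_te,
    best_ungapped_segment,
    revcomp,
    te_family_summary,
    te_match,
)


def rand_seq(n, seed):
    return "".join(random.Random(seed).choices("ACGT", k=n))


def mutate(seq, rate, seed):
    rng = random.Random(seed)
    out = []
    for ch in seq:
        if rng.random() < rate:
            out.append(rng.choice([c for c in "ACGT" if c != ch]))
        else:
            out.append(ch)
    return "".join(out)


LIB = [("TEfam01#LTR/Copia", rand_seq(600, 1)), ("TEfam02#LTR/Gypsy", rand_seq(400, 2))]


class TestTeMatch:
    def test_verbatim_copy_full_identity(self):
        hit = te_match(LIB[0][1], LIB)
        assert hit is not None
        assert hit.te_family == "TEfam01#LTR/Copia"
        assert hit.identity == pytest.approx(1.0)
        assert hit.match_length == 600

    def test_five_percent_divergence_rejected(self):
        query = mutate(LIB[0][1], 0.05, 3)
        assert te_match(query, LIB) is None

    def test_short_perfect_match_below_floor(self):
        query = LIB[0][1][100:120]  # 20 bp verbatim
        assert te_match(query, LIB) is None

    def test_embedded_copy_in_random_flanks(self):
        query = rand_seq(200, 4) + LIB[1][1][50:350] + rand_seq(150, 5)
        hit = te_match(query, LIB)
        assert hit is not None
        assert hit.te_family == "TEfam02#LTR/Gypsy"
        assert hit.match_length >= 290

    def test_reverse_strand_detected(self):
        query = revcomp(LIB[0][1][100:400])
        hit = te_match(query, LIB)
        assert hit is not None
        assert hit.strand == "-"
        assert hit.te_family == "TEfam01#LTR/Copia"

    def test_empty_library(self):
        assert te_match("ACGTACGTACGT", []) is None

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            te_match("", LIB)


def oracle_best_hit(query, library, min_identity=0.99, min_match=30):
    """Quadratic oracle: every diagonal of every strand; the max-score
    ungapped segment is found by exhaustive enumeration of all (start, end)
    pairs via prefix sums (tie -> longer segment, then leftmost)."""
    best = None
    for order, (name, seq) in enumerate(library):
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            for diag in range(-len(s) + 1, len(query)):
                qlo, qhi = max(0, diag), min(len(query), len(s) + diag)
                if qhi - qlo < min_match:
                    continue
                mask = np.array(
                    [query[i] == s[i - diag] for i in range(qlo, qhi)]
                )
                scores = np.where(mask, MATCH_SCORE, MISMATCH_SCORE)
                n = len(scores)
                pre = np.concatenate(([0], np.cumsum(scores)))
                # all segments [i, j): score = pre[j] - pre[i], 0 <= i < j <= n
                i_idx, j_idx = np.meshgrid(
                    np.arange(n + 1), np.arange(n + 1), indexing="ij"
                )
                seg = (pre[j_idx] - pre[i_idx]).astype(np.int64)
                seg[j_idx <= i_idx] = np.iinfo(np.int64).min
                top = int(seg.max())
                if top <= 0:
                    continue
                cand = seg == top
                lengths = j_idx - i_idx
                best_len = int(lengths[cand].min())  # tie -> shorter
                cand &= lengths == best_len
                start = int(i_idx[cand].min())  # then leftmost
                end = start + best_len
                matches = int(mask[start:end].sum())
                identity = matches / best_len
                if best_len < min_match or identity < min_identity:
                    continue
                key = (best_len, identity, -order, strand)
                if best is None or key > best[0]:
                    best = (key, name, best_len, identity)
    return best


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_quadratic_oracle(self, seed):
        rng = random.Random(seed)
        lib = [("famA", rand_seq(160, seed + 50)), ("famB", rand_seq(130, seed + 90))]
        kind = seed % 4
        if kind == 0:  # embedded verbatim copy
            src = lib[rng.randrange(2)][1]
            a, b = sorted(rng.sample(range(len(src)), 2))
            if b - a < 40:
                a, b = 0, 100
            query = rand_seq(60, seed + 7) + src[a:b] + rand_seq(50, seed + 8)
        elif kind == 1:  # lightly mutated copy
            query = mutate(lib[0][1], 0.004, seed + 9)
        elif kind == 2:  # heavily diverged copy
            query = mutate(lib[1][1], 0.08, seed + 10)
        else:  # unrelated sequence
            query = rand_seq(220, seed + 11)
        hit = te_match(query, lib)
        oracle = oracle_best_hit(query, lib)
        if oracle is None:
            assert hit is None
        else:
            assert hit is not None
            _, name, length, identity = oracle
            assert hit.te_family == name
            assert hit.match_length == length
            assert hit.identity == pytest.approx(identity)


class TestBestUngappedSegment:
    def test_all_match(self):
        score, s, e, m = best_ungapped_segment(np.ones(50, dtype=bool))
        assert (score, s, e, m) == (50, 0, 50, 50)

    def test_all_mismatch(self):
        assert best_ungapped_segment(np.zeros(20, dtype=bool)) == (0, 0, 0, 0)

    def test_stops_at_mismatch_cluster(self):
        mask = np.ones(100, dtype=bool)
        mask[40:60] = False  # -40 penalty splits the segment
        score, s, e, m = best_ungapped_segment(mask)
        assert (s, e) == (0, 40)  # shorter-then-leftmost tie rule
        assert score == 40


def make_locus(locus_id, sv_type, start, end, alt=None, chrom="A01"):
    rec = SVRecord(
        interval=GenomicInterval(chrom, start, end),
        sv_type=sv_type,
        length=(len(alt) if alt else end - start),
        accession_id="a1",
        alt_sequence=alt,
    )
    return PangenomeLocus(locus_id, rec, sv_type, np.array([True]), ("a1",), 100.0)


class TestAnnotateSvTe:
    def test_insertion_with_embedded_te_hits_within(self):
        alt = rand_seq(100, 20) + LIB[0][1][:200] + rand_seq(100, 21)
        locus = make_locus("L1", "INS", 5000, 5001, alt=alt)
        anns = annotate_sv_te([locus], None, LIB)
        assert len(anns) == 1
        assert anns[0].zone == "within"
        assert anns[0].locus_id == "L1"

    def test_te_in_upstream_flank_only(self):
        te = LIB[1][1]
        chrom_seq = rand_seq(4950, 22) + te[:50] + rand_seq(2000, 23)
        # flank [4900, 5000) holds the TE's first 50 bp
        locus = make_locus("L2", "INS", 5000, 5001, alt=rand_seq(80, 24))
        anns = annotate_sv_te([locus], {"A01": chrom_seq}, LIB)
        assert [a.zone for a in anns] == ["upstream_flank"]

    def test_inversion_span_from_reference(self):
        te = LIB[0][1]
        chrom_seq = rand_seq(5000, 25) + te + rand_seq(2000, 26)
        locus = make_locus("L3", "INV", 5000, 5000 + len(te))
        anns = annotate_sv_te([locus], {"A01": chrom_seq}, LIB)
        zones = {a.zone for a in anns}
        assert "within" in zones

    def test_flank_truncated_at_chromosome_start(self):
        chrom_seq = rand_seq(3000, 27)
        locus = make_locus("L4", "INS", 40, 41, alt=rand_seq(60, 28))
        anns = annotate_sv_te([locus], {"A01": chrom_seq}, LIB)
        assert anns == []  # no TE anywhere; truncation must not raise

    def test_te_free_insertions_give_no_hits(self, small_cohort):
        lib = TELibraryIndex(small_cohort.reference.te_library)
        free = [
            l for l in small_cohort.truth["loci"]
            if l["sv_type"] == "INS" and l["te_family"] is None
        ][:150]
        carriers_first = []
        for tl in free:
            acc = tl["carriers"][0]
            for r in small_cohort.callsets[acc]["A"]:
                if (
                    r.sv_type == "INS"
                    and r.chrom == tl["chrom"]
                    and abs(r.start - tl["pos"]) <= small_cohort.config.jitter
                ):
                    carriers_first.append(r.alt_sequence)
                    break
        assert carriers_first
        hits = sum(te_match(seq, lib) is not None for seq in carriers_first)
        assert hits == 0

    def test_planted_te_insertions_recovered(self, small_cohort):
        lib = TELibraryIndex(small_cohort.reference.te_library)
        te_loci = [
            l for l in small_cohort.truth["loci"] if l["te_family"] is not None
        ]
        assert len(te_loci) >= 20
        found = correct_family = 0
        for tl in te_loci:
            acc = tl["carriers"][0]
            for r in small_cohort.callsets[acc]["A"]:
                if (
                    r.sv_type == "INS"
                    and r.chrom == tl["chrom"]
                    and abs(r.start - tl["pos"]) <= small_cohort.config.jitter
                ):
                    hit = te_match(r.alt_sequence, lib)
                    if hit is not None:
                        found += 1
                        correct_family += hit.te_family == tl["te_family"]
                    break
        assert found / len(te_loci) >= 0.99
        assert correct_family / len(te_loci) >= 0.95


class TestFamilySummary:
    def _anns(self):
        from pansv_atlas.te import TEAnnotation

        out = []
        for i in range(80):
            out.append(TEAnnotation(f"L{i}", "within", "LTR/Copia", 1.0, 100))
        for i in range(20):
            out.append(TEAnnotation(f"M{i}", "within", "LTR/Gypsy", 1.0, 100))
        return out

    def test_shares_and_baseline_ratio(self):
        df = te_family_summary(self._anns(), {"LTR/Copia": 0.20, "LTR/Gypsy": 0.40})
        copia = df[df.te_family == "LTR/Copia"].iloc[0]
        assert copia.share == pytest.approx(0.80)
        assert copia.ratio_to_baseline == pytest.approx(4.0)

    def test_family_missing_from_baseline(self):
        df = te_family_summary(self._anns(), {"LTR/Copia": 0.20})
        gypsy = df[df.te_family == "LTR/Gypsy"].iloc[0]
        assert np.isnan(gypsy.ratio_to_baseline)

    def test_baseline_must_sum_to_at_most_one(self):
        with pytest.raises(ValueError):
            te_family_summary(self._anns(), {"a": 0.8, "b": 0.7})
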