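"""Variant caller: screens, pileups, the six filters, contamination."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mitohet.caller import (
    CallerThresholds,
    ErrorModel,
    Pileup,
    PileupSite,
    build_pileup,
    call_variants,
    contamination_check,
    dup_concordance,
    fisher_exact_two_sided,
    loglik_score,
    major_sequence,
    poisson_error_test,
)
from mitohet.consensus import ConsensusBlock, encode_bases


def _block(rows, quals=None, mapq=None, family_size=None, seg_start=121,
           upstream=None, segment_id="s1"):
    """Tiny consensus block from sequences (canonical start = seg_start-120)."""
    bases = np.array([encode_bases(r) for r in rows])
    n, W = bases.shape
    return ConsensusBlock(
        segment_id=segment_id,
        seg_start=seg_start,
        bases=bases,
        quals=np.array(quals) if quals is not None else np.full((n, W), 40, dtype=np.int16),
        family_size=np.array(family_size) if family_size is not None else np.full(n, 2),
        mapq=np.array(mapq) if mapq is not None else np.full(n, 60),
        upstream_flag=np.array(upstream) if upstream is not None else np.zeros(n, dtype=bool),
        numts_truth=np.zeros(n, dtype=bool),
    )


class TestMajorSequence:
    def test_identical_reads_give_their_sequence(self, mini_ref):
        seq = mini_ref.sequence[:30]
        blocks = [_block([seq] * 5)]
        major, _ = major_sequence(blocks, mini_ref)
        assert major[:30] == seq
        assert major[30:] == mini_ref.sequence[30:]  # uncovered -> reference

    def test_plurality_wins(self, mini_ref):
        seq = mini_ref.sequence[:30]
        base = seq[9]
        alt = "A" if base != "A" else "G"
        mutant = seq[:9] + alt + seq[10:]
        major, _ = major_sequence([_block([mutant] * 6 + [seq] * 4)], mini_ref)
        assert major[9] == alt

    def test_exact_tie_retains_reference(self, mini_ref):
        seq = mini_ref.sequence[:30]
        base = seq[9]
        alt = "A" if base != "A" else "G"
        mutant = seq[:9] + alt + seq[10:]
        major, _ = major_sequence([_block([mutant] * 5 + [seq] * 5)], mini_ref)
        assert major[9] == base


class TestPileupScreens:
    def test_low_mapq_read_contributes_nowhere(self, mini_ref):
        seq = mini_ref.sequence[:30]
        blocks = [_block([seq] * 3, mapq=[60, 60, 19])]
        pileup, _ = build_pileup(blocks, mini_ref)
        assert pileup.depth[:30].max() == 2

    def test_low_quality_base_dropped_but_counted_pre_cut(self, mini_ref):
        seq = mini_ref.sequence[:30]
        quals = np.full((3, 30), 40)
        quals[0, 5] = 29
        pileup, _ = build_pileup([_block([seq] * 3, quals=quals)], mini_ref)
        assert pileup.depth[5] == 2
        assert pileup.baq30_den[5] == 3  # pre-cut denominator sees all bases
        assert pileup.baq30_num[5] == 2

    def test_excess_coding_mismatches_excluded(self, mini_ref):
        # segment midpoint in the coding region: mismatch cap is 5 (strict >)
        seq = mini_ref.sequence[400:460]
        def mutate(s, k):
            out = list(s)
            for i in range(k):
                out[i * 7] = "A" if out[i * 7] != "A" else "G"
            return "".join(out)
        blocks = [_block([seq] * 8 + [mutate(seq, 6)], seg_start=521)]
        pileup, _ = build_pileup(blocks, mini_ref)
        assert pileup.depth[400:460].max() == 8
        blocks = [_block([seq] * 8 + [mutate(seq, 5)], seg_start=521)]
        pileup, _ = build_pileup(blocks, mini_ref)
        assert pileup.depth[400:460].max() == 9

    def test_dloop_reads_get_looser_mismatch_cap(self, mini_ref):
        # mini D-loop wraps 1851..150; shifted positions 1.. cover its tail
        seq = mini_ref.sequence[1900:1960]
        def mutate(s, k):
            out = list(s)
            for i in range(k):
                out[i * 7] = "A" if out[i * 7] != "A" else "G"
            return "".join(out)
        base_rows = [seq] * 12
        pil8, _ = build_pileup([_block(base_rows + [mutate(seq, 8)], seg_start=2021)], mini_ref)
        pil9, _ = build_pileup([_block(base_rows + [mutate(seq, 9)], seg_start=2021)], mini_ref)
        assert pil8.depth[1900:1960].max() == 13  # 8 mismatches retained
        assert pil9.depth[1900:1960].max() == 12  # 9 excluded

    def test_numts_flagged_reads_excluded(self, mini_ref):
        seq = mini_ref.sequence[:30]
        blocks = [_block([seq] * 4, upstream=[False, False, False, True])]
        pileup, _ = build_pileup(blocks, mini_ref)
        assert pileup.depth[:30].max() == 3


class TestLoglik:
    def test_zero_minor_scores_zero(self):
        assert loglik_score(0, 4000, 0.0) == 0.0

    def test_matches_binomial_oracle(self):
        em = ErrorModel()
        for minor, depth in [(20, 4000), (5, 1000), (12, 2000)]:
            vaf = minor / depth
            expected = 10.0 * (
                sps.binom.logpmf(minor, depth, vaf)
                - sps.binom.logpmf(minor, depth, em.per_base_error_rate)
            ) / np.log(10.0)
            assert abs(loglik_score(minor, depth, vaf, em) - expected) < 1e-9

    def test_single_minor_read_below_threshold(self):
        assert loglik_score(1, 4000, 1 / 4000) < 5.0

    def test_increases_with_minor_count(self):
        scores = [loglik_score(k, 4000, k / 4000) for k in range(0, 40)]
        assert all(b >= a for a, b in zip(scores, scores[1:]))


class TestPoisson:
    def test_zero_minor_gives_p_one(self):
        assert poisson_error_test(0, 4000) == 1.0

    def test_matches_series_sum_oracle(self):
        em = ErrorModel()
        lam = em.per_base_error_rate * 4000  # 0.8
        expected = 1.0 - sum(
            np.exp(-lam) * lam**k / math.factorial(k) for k in range(5)
        )
        assert abs(poisson_error_test(5, 4000, em) - expected) < 1e-12

    def test_boundary_alpha_is_strict(self):
        """A p-value exactly equal to alpha must fail the filter."""
        p = poisson_error_test(5, 4000)
        em = ErrorModel(alpha=p)
        assert not (p < em.alpha)


class TestFisher:
    def test_matches_scipy_oracle(self, rng):
        for _ in range(300):
            a = int(rng.integers(0, 30))
            b = int(rng.integers(0, 30))
            c = int(rng.integers(0, 3000))
            d = int(rng.integers(0, 3000))
            if a + b + c + d == 0:
                continue
            mine = fisher_exact_two_sided(a, b, c, d)[0]
            _, ref_p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            assert abs(mine - ref_p) < 1e-9, (a, b, c, d)


def _site(minor_dup, depth_dup, minor_sing, depth_sing):
    return PileupSite(
        pos=100,
        allele_counts={
            "A": depth_dup + depth_sing - minor_dup - minor_sing,
            "C": minor_dup + minor_sing,
            "G": 0,
            "T": 0,
        },
        allele_counts_dup={
            "A": depth_dup - minor_dup, "C": minor_dup, "G": 0, "T": 0
        },
        frac_baq30=1.0,
    )


class TestDupConcordance:
    def test_identical_vafs_pass(self):
        r = dup_concordance(_site(10, 1000, 10, 1000), "A", "C")
        assert r.fisher_p == pytest.approx(1.0)
        assert r.fold_change == pytest.approx(1.0)
        assert r.passed

    def test_low_dup_vaf_fails_regardless_of_p(self):
        r = dup_concordance(_site(1, 1000, 1, 1000), "A", "C")  # vaf_dup 0.001
        assert r.fisher_p > 1e-4
        assert not r.passed

    def test_skewed_table_fails_by_fold_change(self):
        r = dup_concordance(_site(30, 3000, 0, 1000), "A", "C")
        _, p_ref = sps.fisher_exact([[30, 0], [2970, 1000]])
        assert abs(r.fisher_p - p_ref) < 1e-9
        assert r.fold_change == np.inf
        assert not r.passed

    def test_no_duplicate_reads_fails(self):
        r = dup_concordance(_site(0, 0, 10, 1000), "A", "C")
        assert r.vaf_dup == 0.0
        assert not r.passed


def _uniform_pileup(ref, depth, dup_share=0.6):
    """Background pileup: all reads carry the reference allele."""
    L = ref.length
    codes = encode_bases(ref.sequence)
    idx = np.arange(L)
    counts = np.zeros((L, 4), dtype=np.int64)
    counts[idx, codes] = depth
    dup = np.zeros((L, 4), dtype=np.int64)
    dup[idx, codes] = int(depth * dup_share)
    return counts, dup


class TestCallVariants:
    def _call_single_site(self, mini_ref, pos, minor, depth, dup_minor=None,
                          dup_depth=None, thresholds=CallerThresholds()):
        L = mini_ref.length
        counts, dup = _uniform_pileup(mini_ref, depth)
        i = pos - 1
        ref_code = encode_bases(mini_ref.sequence)[i]
        alt_code = (ref_code + 1) % 4
        counts[i] = 0
        counts[i, ref_code] = depth - minor
        counts[i, alt_code] = minor
        dd = dup_depth if dup_depth is not None else int(depth * 0.6)
        dm = dup_minor if dup_minor is not None else int(round(minor * 0.6))
        dup[i] = 0
        dup[i, ref_code] = dd - dm
        dup[i, alt_code] = dm
        pileup = Pileup(
            counts=counts,
            counts_dup=dup,
            baq30_num=np.full(L, depth),
            baq30_den=np.full(L, depth),
        )
        calls = call_variants(pileup, mini_ref.sequence, mini_ref,
                              thresholds=thresholds)
        return calls[calls["pos"] == pos].iloc[0]

    def test_clean_variant_called(self, mini_ref):
        row = self._call_single_site(mini_ref, 400, minor=12, depth=2000)
        assert row["called"]
        assert row["vaf"] == pytest.approx(0.006)

    def test_minor_count_boundary(self, mini_ref):
        assert not self._call_single_site(mini_ref, 400, 4, 600)["min_minor"]
        assert self._call_single_site(mini_ref, 400, 5, 600)["min_minor"]

    def test_depth_boundary(self, mini_ref):
        assert not self._call_single_site(mini_ref, 400, 5, 99)["depth_comp"]
        assert self._call_single_site(mini_ref, 400, 5, 100)["depth_comp"]

    def test_low_complexity_site_never_called(self, mini_ref):
        row = self._call_single_site(mini_ref, 65, minor=12, depth=2000)  # LC1 60..70
        assert not row["low_complexity"]
        assert not row["called"]

    def test_vaf_floor(self, mini_ref):
        row = self._call_single_site(mini_ref, 400, minor=8, depth=2000)  # VAF 0.4%
        assert not row["called"]
        assert row[["min_minor", "depth_comp"]].all()

    def test_called_is_exact_conjunction(self, mini_ref, rng):
        """On randomized pileups, 'called' equals the AND of the six
        verdicts plus the VAF floor — and every row reports all six."""
        L = mini_ref.length
        counts, dup = _uniform_pileup(mini_ref, 300)
        codes = encode_bases(mini_ref.sequence)
        sites = rng.choice(L, 400, replace=False)
        for i in sites:
            depth = int(rng.integers(50, 4000))
            minor = int(rng.integers(0, 40))
            dd = int(depth * rng.uniform(0.2, 0.8))
            dm = min(int(rng.integers(0, minor + 1)), dd)
            ref_code = codes[i]
            alt_code = (ref_code + 1) % 4
            counts[i] = 0
            counts[i, ref_code] = depth - minor
            counts[i, alt_code] = minor
            dup[i] = 0
            dup[i, ref_code] = dd - dm
            dup[i, alt_code] = dm
        pileup = Pileup(
            counts=counts, counts_dup=dup,
            baq30_num=(np.ones(L) * 300).astype(int),
            baq30_den=(np.ones(L) * 300 / rng.uniform(1.0, 2.0, L)).astype(int) + 1,
        )
        pileup.baq30_den = np.maximum(pileup.baq30_den, pileup.baq30_num)
        calls = call_variants(pileup, mini_ref.sequence, mini_ref)
        six = ["depth_comp", "low_complexity", "min_minor", "loglik_pass",
               "dup_concordance", "poisson_error"]
        assert calls[six].notna().all().all()
        expected = calls[six].all(axis=1) & (calls["vaf"] >= 0.005)
        assert (calls["called"] == expected).all()


class TestContamination:
    def _calls(self, positions):
        return pd.DataFrame(
            {"pos": positions, "called": [True] * len(positions)}
        )

    def test_eleven_polymorphic_coding_variants_flagged(self, mini_ref):
        pos = list(range(300, 311))  # coding region of the mini genome
        poly = pd.DataFrame({"pos": pos, "alt": ["A"] * len(pos)})
        n, flagged = contamination_check(self._calls(pos), poly, mini_ref)
        assert (n, flagged) == (11, True)

    def test_three_not_flagged(self, mini_ref):
        pos = [300, 400, 500]
        poly = pd.DataFrame({"pos": pos, "alt": ["A"] * 3})
        n, flagged = contamination_check(self._calls(pos), poly, mini_ref)
        assert (n, flagged) == (3, False)

    def test_dloop_polymorphic_sites_not_counted(self, mini_ref):
        pos = list(range(1, 12))  # D-loop head of the mini genome
        poly = pd.DataFrame({"pos": pos, "alt": ["A"] * len(pos)})
        n, flagged = contamination_check(self._calls(pos), poly, mini_ref)
        assert (n, flagged) == (0, False)

    def test_empty_calls(self, mini_ref):
        poly = pd.DataFrame({"pos": [5], "alt": ["A"]})
        n, flagged = contamination_check(pd.DataFrame(), poly, mini_ref)
        assert (n, flagged) == (0, False)
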