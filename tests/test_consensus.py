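"""Bayesian family consensus: likelihoods, posteriors, merge paths."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitohet.consensus import (
    ConsensusError,
    FamilyBlock,
    N_CODE,
    Read,
    ReadFamily,
    base_likelihood,
    build_consensus,
    consensus_base,
    consensus_block,
    consensus_columns,
    count_mismatches,
    decode_bases,
    encode_bases,
)

NTS = "ACGT"


def oracle_posterior(column):
    """Independent log-space evaluation of the merge over the 4 hypotheses."""
    logs = []
    for hyp in NTS:
        total = 0.0
        for base, baq in column:
            baq = max(baq, 2)
            e = 10.0 ** (-baq / 10.0)
            total += np.log((1.0 - e) if base == hyp else e / 3.0)
        logs.append(total)
    logs = np.array(logs)
    post = np.exp(logs - logs.max())
    return post / post.sum()


class TestBaseLikelihood:
    def test_match_and_mismatch_at_baq30(self):
        assert abs(base_likelihood("A", 30, "A") - 0.999) < 1e-12
        assert abs(base_likelihood("A", 30, "C") - 1.0 / 3000.0) < 1e-12

    def test_baq_zero_match_degenerates_to_zero(self):
        assert base_likelihood("A", 0, "A") == 0.0

    def test_invalid_nucleotide_rejected(self):
        with pytest.raises(ConsensusError):
            base_likelihood("X", 30, "A")


class TestConsensusBase:
    def test_singleton_returns_own_base_and_baq(self):
        nt, q, pmax = consensus_base([("A", 30)])
        assert (nt, q) == ("A", 30)
        assert abs(pmax - 0.999 / (0.999 + 0.001)) < 1e-9

    def test_two_discordant_reads(self):
        nt, q, pmax = consensus_base([("A", 30), ("C", 20)])
        assert nt == "A"
        assert q == 10
        assert abs(pmax - oracle_posterior([("A", 30), ("C", 20)]).max()) < 1e-9

    def test_symmetric_tie_yields_n(self):
        nt, q, pmax = consensus_base([("A", 30), ("C", 30)])
        assert (nt, q) == ("N", 0)
        assert abs(pmax - 0.5) < 1e-3

    def test_empty_column_rejected(self):
        with pytest.raises(ConsensusError):
            consensus_base([])

    def test_agrees_with_oracle_on_enumerated_columns(self):
        """Exhaustive check on all 2-read columns over BAQ {10,20,30,40}."""
        cells = [(b, q) for b in NTS for q in (10, 20, 30, 40)]
        for col in itertools.product(cells, repeat=2):
            post = oracle_posterior(col)
            nt, q, pmax = consensus_base(list(col))
            assert abs(pmax - post.max()) < 1e-9
            order = np.sort(post)
            if order[-1] - order[-2] < 1e-9:
                assert nt == "N"
            else:
                assert nt == NTS[int(post.argmax())]

    @given(
        col=st.lists(
            st.tuples(st.sampled_from(NTS), st.sampled_from([10, 20, 30, 40])),
            min_size=1,
            max_size=6,
        ),
        extra=st.tuples(st.sampled_from(NTS), st.sampled_from([10, 20, 30, 40])),
    )
    @settings(max_examples=200, deadline=None)
    def test_permutation_invariance_and_monotonicity(self, col, extra):
        nt, q, pmax = consensus_base(col)
        rev = consensus_base(col[::-1])
        assert (nt, q) == rev[:2] and abs(pmax - rev[2]) < 1e-12
        if nt != "N":
            # a concordant read never lowers the winning posterior; a
            # discordant read never raises the posterior of the original
            # winner (the overall max may flip to the other allele)
            concordant = consensus_base(col + [(nt, extra[1])])
            assert concordant[2] >= pmax - 1e-12
            other = NTS[(NTS.index(nt) + 1) % 4]
            p_orig = oracle_posterior(col + [(other, extra[1])])[NTS.index(nt)]
            assert p_orig <= pmax + 1e-12

    def test_posterior_sums_to_one(self, rng):
        for _ in range(100):
            col = [
                (NTS[rng.integers(0, 4)], int(rng.integers(2, 60)))
                for _ in range(rng.integers(1, 6))
            ]
            assert abs(oracle_posterior(col).sum() - 1.0) < 1e-12
            # implementation pmax equals oracle pmax
            assert abs(consensus_base(col)[2] - oracle_posterior(col).max()) < 1e-9


def _family(pairs, barcode="f1", segment="seg1"):
    return ReadFamily(barcode=barcode, segment_id=segment, pairs=pairs)


def _pair(seq1, start1, seq2, start2, baq=30):
    r1 = Read(start=start1, bases=encode_bases(seq1), baq=np.full(len(seq1), baq))
    r2 = Read(start=start2, bases=encode_bases(seq2), baq=np.full(len(seq2), baq))
    return (r1, r2)


class TestBuildConsensus:
    def test_noise_free_family_restores_molecule(self):
        fam = _family([_pair("ACGTACGT", 1, "ACGTACGT", 1) for _ in range(3)])
        cons = build_consensus(fam)
        assert cons.sequence() == "ACGTACGT"
        assert cons.family_size == 3
        assert cons.from_duplicates

    def test_single_miscall_outvoted(self):
        good = [_pair("ACGTACGT", 1, "ACGTACGT", 1) for _ in range(3)]
        bad = [_pair("ACGAACGT", 1, "ACGTACGT", 1)]  # one BAQ-30 miscall at pos 4
        cons = build_consensus(_family(good + bad))
        assert cons.sequence() == "ACGTACGT"

    def test_singleton_identity(self):
        fam = _family([_pair("ACGT", 1, "TTTT", 5)])
        cons = build_consensus(fam)
        assert cons.sequence() == "ACGTTTTT"
        assert not cons.from_duplicates
        assert list(cons.quals) == [30] * 8

    def test_mate_overlap_merged(self):
        # mates overlap at positions 3..4 and agree
        fam = _family([_pair("ACGT", 1, "GTTT", 3)])
        cons = build_consensus(fam)
        assert cons.sequence() == "ACGTTT"
        # overlap positions carry boosted quality
        assert cons.quals[2] > 30 and cons.quals[3] > 30

    def test_overlap_orders_agree_at_high_baq(self, rng):
        for _ in range(30):
            n_pairs = int(rng.integers(1, 4))
            seq = "".join(NTS[i] for i in rng.integers(0, 4, 12))
            pairs = [_pair(seq[:8], 1, seq[4:], 5, baq=40) for _ in range(n_pairs)]
            a = build_consensus(_family(pairs), overlap_order="joint")
            b = build_consensus(_family(pairs), overlap_order="overlap_first")
            assert a.sequence() == b.sequence()

    def test_empty_family_rejected(self):
        with pytest.raises(ConsensusError):
            build_consensus(_family([]))


class TestBatchAgreement:
    def test_block_path_matches_per_family_path(self, rng):
        """The vectorized segment path reproduces build_consensus exactly."""
        W = 20
        n_fam = 40
        reads_b, reads_q, starts, n_pairs = [], [], [], []
        row = 0
        for _ in range(n_fam):
            k = int(rng.integers(1, 4))
            starts.append(row)
            n_pairs.append(k)
            mol = rng.integers(0, 4, W).astype(np.int8)
            for _ in range(2 * k):
                b = mol.copy()
                err = rng.random(W) < 0.05
                b[err] = (b[err] + 1 + rng.integers(0, 3, int(err.sum()))) % 4
                uncov = rng.random(W) < 0.1
                b[uncov] = N_CODE
                q = rng.choice([10, 20, 30, 40], W).astype(float)
                q[uncov] = 0
                reads_b.append(b)
                reads_q.append(q)
                row += 1
        block = FamilyBlock(
            segment_id="s",
            seg_start=1,
            width=W,
            bases=np.array(reads_b),
            baq=np.array(reads_q),
            group_starts=np.array(starts),
            pair_index=np.zeros(row, dtype=np.int32),
            barcodes=[f"b{i}" for i in range(n_fam)],
            n_pairs=np.array(n_pairs),
            mapq=np.full(n_fam, 60),
            numts_truth=np.zeros(n_fam, dtype=bool),
            upstream_flag=np.zeros(n_fam, dtype=bool),
        )
        out = consensus_block(block)
        ends = np.append(block.group_starts[1:], row)
        for fi, (lo, hi) in enumerate(zip(block.group_starts, ends)):
            for c in range(W):
                col = [
                    (NTS[reads_b[ri][c]], reads_q[ri][c])
                    for ri in range(lo, hi)
                    if reads_b[ri][c] >= 0
                ]
                if not col:
                    assert out.bases[fi, c] == N_CODE
                    continue
                nt, q, _ = consensus_base(col)
                got = decode_bases(out.bases[fi, c : c + 1])
                assert got == nt, (fi, c, col)
                if nt != "N":
                    assert out.quals[fi, c] == q


class TestMismatchCount:
    def test_counts_hamming_over_non_n(self):
        major = encode_bases("ACGTACGTAC")
        fam = _family([_pair("ACGTA", 1, "CGTAC", 6)])
        cons = build_consensus(fam)
        assert count_mismatches(cons, major) == 0
        major2 = encode_bases("TCGTACGTAT")  # differs at 1 and 10
        assert count_mismatches(cons, major2) == 2

    def test_n_positions_invisible(self):
        fam = _family([_pair("ACGT", 1, "AGGT", 1)])  # tie at pos 2 -> N
        cons = build_consensus(fam)
        assert cons.sequence()[1] == "N"
        assert count_mismatches(cons, encode_bases("ATTT")) == 1  # only pos 3 differs
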