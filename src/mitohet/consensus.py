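"""Bayesian consensus calling for barcoded read families.

Each capture product (one mtDNA molecule) yields a *read family*: all
paired-end reads sharing one molecular barcode. The family is collapsed to a
single consensus read by combining, per reference column, the base calls of
every read under a per-read likelihood driven by the base alignment quality
(BAQ):

    p(read_i | NT) = 1 - 10^(-BAQ/10)        if the read shows NT
                   = (1/3) * 10^(-BAQ/10)    otherwise

with a uniform prior over {A, C, G, T}. The posterior-maximizing nucleotide
becomes the consensus base and its phred quality is
``round(-10 * log10(1 - pmax))``, clamped to [0, 93] so it stays
ASCII-encodable at offset 33. Products are computed in log space (the
uniform prior cancels); a posterior tie yields an 'N' with quality 0, and
'N' bases are invisible to downstream pileups.

Two code paths produce identical results: :func:`build_consensus` for a
single :class:`ReadFamily` (clarity) and :func:`consensus_columns` /
:func:`consensus_block` operating on stacked per-segment matrices (speed);
their agreement is asserted in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reference import NUCLEOTIDES, MtReference, unshift_positions

N_CODE = -1  # matrix code for 'N' / uncovered
BAQ_FLOOR = 2  # BAQ 0/1 would zero the match likelihood; floored bases are ~uninformative
MAX_PHRED = 93  # ASCII 126 at offset 33
TIE_EPS = 1e-9

_NT_ARRAY = np.frombuffer(NUCLEOTIDES.encode(), dtype=np.int8)


class ConsensusError(ValueError):
    pass


def encode_bases(seq: str) -> np.ndarray:
    """String -> int8 codes (A,C,G,T -> 0..3; anything else -> N_CODE)."""
    raw = np.frombuffer(seq.upper().encode(), dtype=np.int8)
    out = np.full(raw.shape, N_CODE, dtype=np.int8)
    for code, nt in enumerate(_NT_ARRAY):
        out[raw == nt] = code
    return out


def decode_bases(codes: np.ndarray) -> str:
    out = np.full(codes.shape, ord("N"), dtype=np.int8)
    valid = codes >= 0
    out[valid] = _NT_ARRAY[codes[valid]]
    return out.tobytes().decode()


@dataclass
class Read:
    """One aligned read: shifted-frame start plus base/BAQ arrays."""

    start: int  # 1-based, shifted frame
    bases: np.ndarray  # int8 codes, N_CODE for no-call
    baq: np.ndarray  # int, same length
    mapq: int = 60

    def __post_init__(self) -> None:
        self.bases = np.asarray(self.bases, dtype=np.int8)
        self.baq = np.asarray(self.baq)
        if self.bases.shape != self.baq.shape:
            raise ConsensusError("base and BAQ arrays differ in length")

    @property
    def end(self) -> int:  # inclusive
        return self.start + len(self.bases) - 1


@dataclass
class ReadFamily:
    """All paired-end reads sharing one molecular barcode."""

    barcode: str
    segment_id: str
    pairs: list[tuple[Read, Read]]
    upstream_numts_flag: bool = False

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def reads(self) -> list[Read]:
        return [r for pair in self.pairs for r in pair]


@dataclass
class ConsensusRead:
    """Consensus sequence of one family over its segment span."""

    segment_id: str
    start: int  # shifted frame, 1-based
    bases: np.ndarray  # int8 codes, N_CODE where no call
    quals: np.ndarray  # int16 phred, 0..93
    family_size: int  # number of read pairs
    mapq: int
    upstream_numts_flag: bool = False
    numts_flag: bool = False
    mismatch_count: int = -1  # vs the sample's major sequence; set by the caller stage

    @property
    def from_duplicates(self) -> bool:
        return self.family_size >= 2

    @property
    def end(self) -> int:
        return self.start + len(self.bases) - 1

    def sequence(self) -> str:
        return decode_bases(self.bases)


# ---------------------------------------------------------------------------
# scalar path


def base_likelihood(observed_base: str, baq: float, hypothesis_nt: str) -> float:
    """Likelihood of one read's base call under a nucleotide hypothesis."""
    if observed_base not in NUCLEOTIDES or hypothesis_nt not in NUCLEOTIDES:
        raise ConsensusError(
            f"invalid nucleotide {observed_base!r}/{hypothesis_nt!r}"
        )
    if baq < 0:
        raise ConsensusError("BAQ must be non-negative")
    err = 10.0 ** (-baq / 10.0)
    return 1.0 - err if observed_base == hypothesis_nt else err / 3.0


def consensus_base(column: list[tuple[str, float]]) -> tuple[str, int, float]:
    """Merge one pileup column of (base, BAQ) observations.

    Returns (consensus nucleotide, phred quality, pmax). BAQ values are
    floored at ``BAQ_FLOOR`` so the match likelihood stays positive; a
    posterior tie (within ``TIE_EPS``) returns ('N', 0, pmax).
    """
    if not column:
        raise ConsensusError("empty column")
    loglik = np.zeros(4)
    for base, baq in column:
        if base not in NUCLEOTIDES:
            raise ConsensusError(f"invalid nucleotide {base!r}")
        baq = max(float(baq), BAQ_FLOOR)
        err = 10.0 ** (-baq / 10.0)
        lg_match = np.log10(1.0 - err)
        lg_mis = np.log10(err / 3.0)
        obs = NUCLEOTIDES.index(base)
        loglik += lg_mis
        loglik[obs] += lg_match - lg_mis
    shifted = loglik - loglik.max()
    unnorm = 10.0**shifted
    total = unnorm.sum()
    post = unnorm / total
    order = np.argsort(post)
    best, runner = order[-1], order[-2]
    pmax = float(post[best])
    if post[best] - post[runner] < TIE_EPS:
        return "N", 0, pmax
    one_minus = (total - unnorm[best]) / total
    if one_minus <= 0:
        qual = MAX_PHRED
    else:
        qual = int(np.clip(np.rint(-10.0 * np.log10(one_minus)), 0, MAX_PHRED))
    return NUCLEOTIDES[best], qual, pmax


# ---------------------------------------------------------------------------
# vectorized path


def consensus_columns(
    bases: np.ndarray, baq: np.ndarray, group_starts: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Columnwise Bayesian merge of stacked reads, grouped into families.

    Parameters
    ----------
    bases : (n_reads, width) int8, ``N_CODE`` where a read does not cover
        or has no call.
    baq : (n_reads, width) numeric BAQ values.
    group_starts : sorted row indices at which each family's reads begin
        (reads of one family must be contiguous).

    Returns
    -------
    cons_bases : (n_families, width) int8, ``N_CODE`` for uncovered/tied.
    cons_quals : (n_families, width) int16 phred in [0, 93].
    coverage : (n_families, width) int32 number of covering calls.
    """
    bases = np.asarray(bases, dtype=np.int8)
    covered = bases >= 0
    baqf = np.maximum(np.asarray(baq, dtype=np.float32), BAQ_FLOOR)
    err = 10.0 ** (-baqf / np.float32(10.0))
    lg_match = np.log10(np.float32(1.0) - err)
    lg_mis = (-baqf / np.float32(10.0)) - np.float32(np.log10(3.0))
    # every hypothesis collects the mismatch term; the observed base's
    # hypothesis is corrected by delta — avoids a (reads, width, 4) tensor
    base_term = np.where(covered, lg_mis, np.float32(0.0))
    delta = np.where(covered, lg_match - lg_mis, np.float32(0.0))
    n_fam = len(group_starts)
    width = bases.shape[1]
    s_mis = np.add.reduceat(base_term, group_starts, axis=0)
    fam_ll = np.empty((n_fam, width, 4), dtype=np.float64)
    for h in range(4):
        dh = np.add.reduceat(
            np.where(bases == h, delta, np.float32(0.0)), group_starts, axis=0
        )
        fam_ll[:, :, h] = s_mis + dh
    coverage = np.add.reduceat(covered.astype(np.int32), group_starts, axis=0)

    fam_ll -= fam_ll.max(axis=2, keepdims=True)
    unnorm = 10.0**fam_ll
    total = unnorm.sum(axis=2)
    top2 = np.partition(unnorm, 2, axis=2)[:, :, -2:]
    second, first = top2[:, :, 0], top2[:, :, 1]
    best = np.argmax(unnorm, axis=2).astype(np.int8)
    tie = (first - second) / total < TIE_EPS
    uncovered = coverage == 0
    cons = np.where(tie | uncovered, np.int8(N_CODE), best)
    one_minus = (total - first) / total
    with np.errstate(divide="ignore"):
        q = -10.0 * np.log10(one_minus)
    quals = np.clip(np.rint(q), 0, MAX_PHRED).astype(np.int16)
    quals[tie | uncovered] = 0
    return cons, quals, coverage


def build_consensus(
    family: ReadFamily,
    ref: MtReference | None = None,
    overlap_order: str = "joint",
) -> ConsensusRead:
    """Collapse one read family into a consensus read.

    ``overlap_order`` selects how mate-pair overlap is handled:

    - ``"joint"`` (default): all reads of the family enter one log-space
      product per column. Because the likelihood product factorizes over
      reads, this equals the two-stage merge except for the intermediate
      integer rounding of the latter.
    - ``"overlap_first"``: each pair's mates are merged into a single
      pseudo-read first (consensus quality re-used as BAQ), then pairs are
      merged across the family.
    """
    reads = family.reads()
    if not reads:
        raise ConsensusError(f"family {family.barcode} has no reads")
    if overlap_order not in ("joint", "overlap_first"):
        raise ConsensusError(f"unknown overlap_order {overlap_order!r}")
    if overlap_order == "overlap_first" and family.n_pairs >= 1:
        reads = [_merge_pair(r1, r2) for r1, r2 in family.pairs]
    start = min(r.start for r in reads)
    end = max(r.end for r in reads)
    width = end - start + 1
    mat_b = np.full((len(reads), width), N_CODE, dtype=np.int8)
    mat_q = np.zeros((len(reads), width), dtype=np.float32)
    for i, r in enumerate(reads):
        off = r.start - start
        mat_b[i, off : off + len(r.bases)] = r.bases
        mat_q[i, off : off + len(r.bases)] = r.baq
    cons, quals, _cov = consensus_columns(mat_b, mat_q, np.array([0]))
    return ConsensusRead(
        segment_id=family.segment_id,
        start=start,
        bases=cons[0],
        quals=quals[0],
        family_size=family.n_pairs,
        mapq=max(r.mapq for r in family.reads()),
        upstream_numts_flag=family.upstream_numts_flag,
    )


def _merge_pair(r1: Read, r2: Read) -> Read:
    """Merge mate overlap of one pair into a single pseudo-read."""
    start = min(r1.start, r2.start)
    end = max(r1.end, r2.end)
    width = end - start + 1
    mat_b = np.full((2, width), N_CODE, dtype=np.int8)
    mat_q = np.zeros((2, width), dtype=np.float32)
    for i, r in enumerate((r1, r2)):
        off = r.start - start
        mat_b[i, off : off + len(r.bases)] = r.bases
        mat_q[i, off : off + len(r.bases)] = r.baq
    cons, quals, _ = consensus_columns(mat_b, mat_q, np.array([0]))
    return Read(start=start, bases=cons[0], baq=quals[0].astype(np.float32),
                mapq=max(r1.mapq, r2.mapq))


def count_mismatches(consensus: ConsensusRead, major_shifted: np.ndarray) -> int:
    """Hamming mismatches of a consensus read against the sample's major
    sequence (shifted-frame int8 codes), counted over non-N consensus bases."""
    span = major_shifted[consensus.start - 1 : consensus.end]
    valid = consensus.bases >= 0
    return int(np.count_nonzero(consensus.bases[valid] != span[valid]))


# ---------------------------------------------------------------------------
# block container used by the pipeline


@dataclass
class FamilyBlock:
    """All read families of one capture segment, as stacked matrices.

    Reads of one family occupy contiguous rows; ``group_starts`` indexes the
    first read of each family. All reads are laid out over the segment span
    ``[seg_start, seg_start + width - 1]`` in the shifted frame.
    """

    segment_id: str
    seg_start: int  # shifted frame, 1-based
    width: int
    bases: np.ndarray  # (n_reads, width) int8
    baq: np.ndarray  # (n_reads, width)
    group_starts: np.ndarray  # (n_families,)
    pair_index: np.ndarray  # (n_reads,) pair number of each read within its family
    barcodes: list[str]
    n_pairs: np.ndarray  # (n_families,)
    mapq: np.ndarray  # (n_families,)
    numts_truth: np.ndarray  # (n_families,) bool — simulator ground truth
    upstream_flag: np.ndarray  # (n_families,) bool

    @property
    def n_families(self) -> int:
        return len(self.group_starts)


@dataclass
class ConsensusBlock:
    """Consensus reads of one segment (one row per family)."""

    segment_id: str
    seg_start: int
    bases: np.ndarray  # (n_families, width) int8
    quals: np.ndarray  # (n_families, width) int16
    family_size: np.ndarray
    mapq: np.ndarray
    upstream_flag: np.ndarray
    numts_truth: np.ndarray
    numts_flag: np.ndarray = field(default=None)
    mismatch_count: np.ndarray = field(default=None)

    @property
    def n_families(self) -> int:
        return len(self.family_size)

    @property
    def width(self) -> int:
        return self.bases.shape[1]

    @property
    def from_duplicates(self) -> np.ndarray:
        return self.family_size >= 2

    def shifted_positions(self) -> np.ndarray:
        return np.arange(self.seg_start, self.seg_start + self.width)

    def canonical_positions(self, ref: MtReference) -> np.ndarray:
        return unshift_positions(self.shifted_positions(), ref)


def consensus_block(block: FamilyBlock) -> ConsensusBlock:
    """Vectorized consensus over every family of a segment."""
    cons, quals, _cov = consensus_columns(block.bases, block.baq, block.group_starts)
    return ConsensusBlock(
        segment_id=block.segment_id,
        seg_start=block.seg_start,
        bases=cons,
        quals=quals,
        family_size=np.asarray(block.n_pairs),
        mapq=np.asarray(block.mapq),
        upstream_flag=np.asarray(block.upstream_flag, dtype=bool),
        numts_truth=np.asarray(block.numts_truth, dtype=bool),
    )
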