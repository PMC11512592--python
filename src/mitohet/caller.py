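"""Heteroplasmy calling from consensus reads.

The caller screens consensus reads (MAPQ >= 20; excess mismatches against
the sample's major sequence, >5 in the coding region / >8 in the D-loop;
NUMT flags), builds per-site pileups of base calls with quality >= 30, and
derives each sample's *major sequence* — the per-site plurality allele —
against which minor (heteroplasmic) alleles are defined. Candidate minor
alleles then face six quality filters:

  (i)   depth >= 100 with >= 70% of covering bases at BAQ >= 30,
  (ii)  not in a low-complexity homopolymer tract,
  (iii) >= 5 minor-allele reads,
  (iv)  phred-scaled binomial log-likelihood-ratio score >= 5,
  (v)   concordant VAFs between consensus reads built with vs without PCR
        duplicates (two-sided Fisher exact P >= 1e-4, fold-change <= 5,
        duplicate-supported VAF >= 0.2%),
  (vi)  minor-allele count significantly above the platform error
        expectation (exact Poisson upper tail at rate 0.02% per base,
        P < 0.01/16569).

A variant is *called* when all six pass and its VAF is >= 0.5%. Homoplasmic
differences from the reference are the sample's haplotype, reported
separately, never as mutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import poisson as _poisson

from .consensus import ConsensusBlock, decode_bases, encode_bases
from .numts import NumtsDb, flag_numts_block
from .reference import DLOOP, NUCLEOTIDES, MtReference, unshift_position

FILTER_NAMES = (
    "depth_comp",
    "low_complexity",
    "min_minor",
    "loglik",
    "dup_concordance",
    "poisson_error",
)


@dataclass(frozen=True)
class ErrorModel:
    """Residual per-base error model of the consensus pipeline."""

    per_base_error_rate: float = 2e-4  # 0.02%
    alpha: float = 0.01 / 16569  # per-site Bonferroni over the full genome

    def __post_init__(self) -> None:
        if not 0.0 < self.per_base_error_rate < 1.0:
            raise ValueError("error rate must lie in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class CallerThresholds:
    """Printed defaults of the read screens and variant filters."""

    min_mapq: int = 20
    min_baq: int = 30
    max_mismatch_coding: int = 5  # exclusion is strict >
    max_mismatch_dloop: int = 8
    min_depth: int = 100
    min_frac_baq30: float = 0.70
    min_minor: int = 5
    min_loglik: float = 5.0
    min_fisher_p: float = 1e-4
    max_fold_change: float = 5.0
    min_vaf_dup: float = 0.002
    min_vaf: float = 0.005
    contamination_min: int = 11


@dataclass
class Pileup:
    """Per-site allele counts over one sample's qualifying consensus reads."""

    counts: np.ndarray  # (L, 4) all qualifying reads
    counts_dup: np.ndarray  # (L, 4) duplicate-built reads only
    baq30_num: np.ndarray  # (L,) covering bases with qual >= 30 (pre-cut)
    baq30_den: np.ndarray  # (L,) covering bases (pre-cut)

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def depth_dup(self) -> np.ndarray:
        return self.counts_dup.sum(axis=1)

    def frac_baq30(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(
                self.baq30_den > 0, self.baq30_num / np.maximum(self.baq30_den, 1), 0.0
            )

    def site(self, pos: int) -> "PileupSite":
        i = pos - 1
        return PileupSite(
            pos=pos,
            allele_counts={nt: int(self.counts[i, c]) for c, nt in enumerate(NUCLEOTIDES)},
            allele_counts_dup={
                nt: int(self.counts_dup[i, c]) for c, nt in enumerate(NUCLEOTIDES)
            },
            frac_baq30=float(self.frac_baq30()[i]),
        )


@dataclass
class PileupSite:
    """Single-site view used by the scalar filter operations."""

    pos: int
    allele_counts: dict[str, int]
    allele_counts_dup: dict[str, int]
    frac_baq30: float

    @property
    def depth(self) -> int:
        return sum(self.allele_counts.values())

    @property
    def depth_dup(self) -> int:
        return sum(self.allele_counts_dup.values())


# ---------------------------------------------------------------------------
# read screens and major sequence


def _read_screens(
    blocks: list[ConsensusBlock],
    major_shifted: np.ndarray,
    ref: MtReference,
    numts_db: NumtsDb | None,
    thresholds: CallerThresholds,
) -> list[dict]:
    """Per-block read-level verdicts against a given major sequence."""
    out = []
    for block in blocks:
        span = major_shifted[block.seg_start - 1 : block.seg_start - 1 + block.width]
        valid = block.bases >= 0
        mism = ((block.bases != span[None, :]) & valid).sum(axis=1)
        mid_shifted = block.seg_start + block.width // 2
        mid = unshift_position(min(mid_shifted, ref.shifted_length), ref)
        in_dloop = ref.region_codes()[mid - 1] == DLOOP
        max_mism = thresholds.max_mismatch_dloop if in_dloop else thresholds.max_mismatch_coding
        if numts_db is not None:
            numts = flag_numts_block(block, numts_db, major_shifted)
        else:
            numts = np.asarray(block.upstream_flag, dtype=bool)
        passing = (
            (np.asarray(block.mapq) >= thresholds.min_mapq)
            & ~numts
            & (mism <= max_mism)
        )
        out.append({"mismatches": mism, "numts": numts, "passing": passing})
    return out


def _accumulate_counts(
    blocks: list[ConsensusBlock],
    ref: MtReference,
    thresholds: CallerThresholds,
    row_masks: list[np.ndarray] | None = None,
) -> Pileup:
    L = ref.length
    counts = np.zeros((L, 4), dtype=np.int64)
    counts_dup = np.zeros((L, 4), dtype=np.int64)
    num30 = np.zeros(L, dtype=np.int64)
    den = np.zeros(L, dtype=np.int64)
    for bi, block in enumerate(blocks):
        rows = (
            np.asarray(block.mapq) >= thresholds.min_mapq
            if row_masks is None
            else row_masks[bi]
        )
        if not rows.any():
            continue
        b = block.bases[rows]
        q = block.quals[rows]
        dup = block.from_duplicates[rows]
        idx = block.canonical_positions(ref) - 1
        covered = b >= 0
        good = covered & (q >= thresholds.min_baq)
        np.add.at(num30, idx, good.sum(axis=0))
        np.add.at(den, idx, covered.sum(axis=0))
        flat_idx = np.broadcast_to(idx[None, :] * 4, b.shape)[good] + b[good]
        counts += np.bincount(flat_idx, minlength=4 * L).reshape(L, 4)
        good_dup = good & dup[:, None]
        flat_dup = np.broadcast_to(idx[None, :] * 4, b.shape)[good_dup] + b[good_dup]
        counts_dup += np.bincount(flat_dup, minlength=4 * L).reshape(L, 4)
    return Pileup(counts=counts, counts_dup=counts_dup, baq30_num=num30, baq30_den=den)


def _major_from_counts(counts: np.ndarray, ref: MtReference) -> str:
    """Plurality allele per site; exact ties and uncovered sites retain the
    reference allele."""
    ref_codes = encode_bases(ref.sequence)
    maxc = counts.max(axis=1)
    best = counts.argmax(axis=1).astype(np.int8)
    ref_count = counts[np.arange(len(counts)), ref_codes]
    keep_ref = (maxc == 0) | (ref_count == maxc)
    major = np.where(keep_ref, ref_codes, best)
    return decode_bases(major)


def major_sequence(
    blocks: list[ConsensusBlock],
    ref: MtReference,
    numts_db: NumtsDb | None = None,
    thresholds: CallerThresholds = CallerThresholds(),
) -> tuple[str, list[dict]]:
    """Derive the sample's major mtDNA sequence.

    Two passes: a provisional major from all MAPQ/BAQ-qualifying reads
    seeds the mismatch/NUMT screens, then the major is rebuilt from the
    reads that pass, and the screens are re-evaluated once against the
    final sequence (the verdicts the pileup will use).
    """
    pile0 = _accumulate_counts(blocks, ref, thresholds)
    major0 = _major_from_counts(pile0.counts, ref)
    major0_shifted = encode_bases(major0[ref.length - ref.shift_bp :] + major0)
    screens0 = _read_screens(blocks, major0_shifted, ref, numts_db, thresholds)
    pile1 = _accumulate_counts(
        blocks, ref, thresholds, [s["passing"] for s in screens0]
    )
    major = _major_from_counts(pile1.counts, ref)
    major_shifted = encode_bases(major[ref.length - ref.shift_bp :] + major)
    screens = _read_screens(blocks, major_shifted, ref, numts_db, thresholds)
    for block, s in zip(blocks, screens):
        block.numts_flag = s["numts"]
        block.mismatch_count = s["mismatches"]
    return major, screens


def build_pileup(
    blocks: list[ConsensusBlock],
    ref: MtReference,
    numts_db: NumtsDb | None = None,
    thresholds: CallerThresholds = CallerThresholds(),
) -> tuple[Pileup, str]:
    """QC-filtered pileup (all-reads plus duplicates-only shadow) and the
    major sequence it was screened against."""
    major, screens = major_sequence(blocks, ref, numts_db, thresholds)
    pileup = _accumulate_counts(
        blocks, ref, thresholds, [s["passing"] for s in screens]
    )
    return pileup, major


# ---------------------------------------------------------------------------
# filter statistics


def loglik_score(
    minor_count, depth, vaf, error_model: ErrorModel = ErrorModel()
):
    """Phred-scaled binomial log10 likelihood-ratio of a variant vs error.

    Compares Binomial(depth, max(vaf, rate)) against Binomial(depth, rate)
    at the observed minor count; the combinatorial factor cancels. Zero when
    the observed fraction is at or below the error rate; increasing in
    ``minor_count`` at fixed depth.
    """
    minor = np.asarray(minor_count, dtype=float)
    n = np.asarray(depth, dtype=float)
    p0 = error_model.per_base_error_rate
    p1 = np.clip(np.asarray(vaf, dtype=float), p0, 1.0 - 1e-12)
    score = 10.0 * (
        minor * (np.log10(p1) - np.log10(p0))
        + (n - minor) * (np.log10(1.0 - p1) - np.log10(1.0 - p0))
    )
    return np.maximum(score, 0.0) if score.ndim else float(max(score, 0.0))


def poisson_error_test(
    minor_count, depth, error_model: ErrorModel = ErrorModel()
):
    """Exact Poisson upper-tail p-value P(X >= minor_count),
    X ~ Poisson(rate * depth)."""
    lam = error_model.per_base_error_rate * np.asarray(depth, dtype=float)
    k = np.asarray(minor_count)
    p = _poisson.sf(k - 1, lam)
    return float(p) if p.ndim == 0 else p


def fisher_exact_two_sided(a, b, c, d) -> np.ndarray:
    """Vectorized two-sided Fisher exact test on 2x2 tables [[a, b], [c, d]].

    Sums hypergeometric point probabilities not exceeding the observed one
    (relative tolerance 1e-7, matching the conventional implementation).
    """
    a, b, c, d = (np.atleast_1d(np.asarray(x, dtype=np.int64)) for x in (a, b, c, d))
    if a.size == 0:
        return np.empty(0, dtype=float)
    N = a + b + c + d
    K = a + b  # total minor
    n = a + c  # duplicate-stratum depth
    kmin = np.maximum(0, n - (N - K))
    kmax = np.minimum(K, n)
    width = int((kmax - kmin).max()) + 1
    k = kmin[:, None] + np.arange(width)[None, :]
    valid = k <= kmax[:, None]
    kk = np.where(valid, k, kmin[:, None])

    def logc(m, j):
        return gammaln(m + 1) - gammaln(j + 1) - gammaln(m - j + 1)

    logpmf = (
        logc(K[:, None], kk)
        + logc((N - K)[:, None], n[:, None] - kk)
        - logc(N, n)[:, None]
    )
    log_obs = (logc(K, a) + logc(N - K, n - a) - logc(N, n))[:, None]
    include = valid & (logpmf <= log_obs + np.log(1.0 + 1e-7))
    p = np.exp(logpmf, where=include, out=np.zeros_like(logpmf))
    p[~include] = 0.0
    return np.minimum(p.sum(axis=1), 1.0)


@dataclass(frozen=True)
class DupConcordance:
    fisher_p: float
    fold_change: float
    vaf_dup: float
    passed: bool


def dup_concordance(
    site: PileupSite,
    major_allele: str,
    minor_allele: str,
    thresholds: CallerThresholds = CallerThresholds(),
) -> DupConcordance:
    """Filter (v): VAF concordance between duplicate-built and singleton-built
    consensus reads at one site.

    The 2x2 table is {minor, non-minor} x {duplicate-built, singleton-built}.
    A zero VAF in either stratum makes the fold-change infinite (fail); no
    duplicate coverage at all fails outright (vaf_dup undefined => 0).
    """
    minor_dup = site.allele_counts_dup.get(minor_allele, 0)
    depth_dup = site.depth_dup
    minor_all = site.allele_counts.get(minor_allele, 0)
    depth_all = site.depth
    minor_sing = minor_all - minor_dup
    depth_sing = depth_all - depth_dup
    if depth_dup == 0:
        return DupConcordance(fisher_p=1.0, fold_change=np.inf, vaf_dup=0.0, passed=False)
    vaf_dup = minor_dup / depth_dup
    vaf_sing = minor_sing / depth_sing if depth_sing > 0 else 0.0
    p = float(
        fisher_exact_two_sided(
            minor_dup, minor_sing, depth_dup - minor_dup, depth_sing - minor_sing
        )[0]
    )
    if vaf_dup == 0.0 or vaf_sing == 0.0:
        fold = np.inf
    else:
        fold = max(vaf_dup, vaf_sing) / min(vaf_dup, vaf_sing)
    passed = (
        p >= thresholds.min_fisher_p
        and fold <= thresholds.max_fold_change
        and vaf_dup >= thresholds.min_vaf_dup
    )
    return DupConcordance(fisher_p=p, fold_change=fold, vaf_dup=vaf_dup, passed=passed)


# ---------------------------------------------------------------------------
# variant calling


def call_variants(
    pileup: Pileup,
    major: str,
    ref: MtReference,
    error_model: ErrorModel = ErrorModel(),
    thresholds: CallerThresholds = CallerThresholds(),
) -> pd.DataFrame:
    """Evaluate the six filters at every site with minor-allele support.

    Returns the audit table: one row per site with ``minor_count >= 1``, the
    six verdicts, and ``called`` = conjunction of all six and VAF >= the
    calling floor. The minor allele is the most frequent allele other than
    the sample's major allele.
    """
    counts = pileup.counts
    L = len(counts)
    major_codes = encode_bases(major)
    idx = np.arange(L)
    depth = pileup.depth
    major_count = counts[idx, major_codes]
    masked = counts.copy()
    masked[idx, major_codes] = -1
    minor_code = masked.argmax(axis=1).astype(np.int8)
    minor_count = counts[idx, minor_code]

    cand = minor_count >= 1
    pos = idx[cand] + 1
    mc = minor_count[cand]
    dp = depth[cand]
    vaf = mc / dp
    dup_counts = pileup.counts_dup[cand]
    minor_dup = dup_counts[np.arange(cand.sum()), minor_code[cand]]
    depth_dup = pileup.depth_dup[cand]
    minor_sing = mc - minor_dup
    depth_sing = dp - depth_dup
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf_dup = np.where(depth_dup > 0, minor_dup / np.maximum(depth_dup, 1), 0.0)
        vaf_sing = np.where(depth_sing > 0, minor_sing / np.maximum(depth_sing, 1), 0.0)

    frac30 = pileup.frac_baq30()[cand]
    f_depth = (dp >= thresholds.min_depth) & (frac30 >= thresholds.min_frac_baq30)
    f_lowc = ~ref.lowcomp_mask()[cand]
    f_minor = mc >= thresholds.min_minor
    ll = loglik_score(mc, dp, vaf, error_model)
    f_ll = ll >= thresholds.min_loglik
    fisher_p = fisher_exact_two_sided(
        minor_dup, minor_sing, depth_dup - minor_dup, depth_sing - minor_sing
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(
            (vaf_dup > 0) & (vaf_sing > 0),
            np.maximum(vaf_dup, vaf_sing) / np.minimum(vaf_dup, vaf_sing),
            np.inf,
        )
    f_dup = (
        (depth_dup > 0)
        & (fisher_p >= thresholds.min_fisher_p)
        & (fold <= thresholds.max_fold_change)
        & (vaf_dup >= thresholds.min_vaf_dup)
    )
    poisson_p = poisson_error_test(mc, dp, error_model)
    f_poisson = poisson_p < error_model.alpha

    called = (
        f_depth & f_lowc & f_minor & f_ll & f_dup & f_poisson & (vaf >= thresholds.min_vaf)
    )
    ref_alleles = np.frombuffer(ref.sequence.encode(), dtype="S1").astype("U1")[cand]
    nts = np.array(list(NUCLEOTIDES))
    return pd.DataFrame(
        {
            "pos": pos,
            "ref": ref_alleles,
            "major": nts[major_codes[cand]],
            "minor": nts[minor_code[cand]],
            "minor_count": mc,
            "depth": dp,
            "vaf": vaf,
            "minor_dup": minor_dup,
            "depth_dup": depth_dup,
            "vaf_dup": vaf_dup,
            "frac_baq30": frac30,
            "loglik": ll,
            "fisher_p": fisher_p,
            "fold_change": fold,
            "poisson_p": poisson_p,
            "depth_comp": f_depth,
            "low_complexity": f_lowc,
            "min_minor": f_minor,
            "loglik_pass": f_ll,
            "dup_concordance": f_dup,
            "poisson_error": f_poisson,
            "called": called,
        }
    )


def haplotype_differences(major: str, ref: MtReference) -> pd.DataFrame:
    """Homoplasmic differences of the sample's major sequence from the
    reference (the haplotype; reported apart from heteroplasmic mutations)."""
    rows = [
        {"pos": i + 1, "ref": r, "alt": m}
        for i, (r, m) in enumerate(zip(ref.sequence, major))
        if r != m and m != "N"
    ]
    return pd.DataFrame(rows, columns=["pos", "ref", "alt"])


def contamination_check(
    calls: pd.DataFrame,
    polymorphisms: pd.DataFrame,
    ref: MtReference,
    min_count: int = 11,
) -> tuple[int, bool]:
    """Count called variants at known polymorphic sites in the coding region.

    An excess (>= ``min_count``) indicates low-level contamination with a
    different mtDNA haplotype; such samples are excluded from cohort
    analysis. Matching is by site, since a contaminating haplotype shows up
    at the polymorphic positions regardless of exact allele bookkeeping.
    """
    if calls.empty:
        return 0, False
    called = calls[calls["called"]] if "called" in calls else calls
    poly_sites = set(polymorphisms["pos"].astype(int))
    codes = ref.region_codes()
    n = sum(
        1
        for p in called["pos"].astype(int)
        if p in poly_sites and codes[p - 1] != DLOOP
    )
    return n, n >= min_count
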