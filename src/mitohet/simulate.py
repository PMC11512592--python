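"""Synthetic data generator for the capture design and study cohorts.

Emulates a multiplex-probe mtDNA capture: the (shifted) genome is tiled by
probe-defined segments (46 for the full-size genome), each captured molecule
founds a barcoded read family, and families carry PCR duplicates. A molecule
— not a read — carries the heteroplasmy state (it is mutant with probability
VAF), duplicates inherit it, and per-base miscalls occur at rate
``10^(-BAQ/10)`` uniformly over the three other bases. A configurable
fraction of families originates from NUMT sequences (nuclear copies of
mtDNA segments carrying a few fixed differences) instead of the sample's
mtDNA.

Defaults reflect the emulated study design: median unique-read depth
~4000x per segment, ~50% of families with PCR duplicates (duplicate count
1 + Geometric, truncated at 10 pairs), 2x250 paired-end reads, BAQ mostly
30 with a 10% mass at 20.

:func:`simulate_cohort` draws whole cohorts: per-sample mutation counts per
functional category from a Poisson model with an optional log-linear age
slope, mutation positions placed uniformly within the category's region,
and per-group fractions of pathogenic non-synonymous changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .consensus import N_CODE, FamilyBlock, encode_bases
from .reference import (
    DLOOP,
    NUCLEOTIDES,
    PROTEIN_CODING,
    MtReference,
    enumerate_effects,
)

MAX_PAIRS = 10  # duplicate-count truncation
CATEGORIES = ("dloop", "synonymous", "non_synonymous", "rna")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class ProbePanel:
    """Probe-defined capture segments tiling the shifted genome."""

    segments: tuple[tuple[str, int, int], ...]  # (segment_id, start, end) shifted, inclusive
    arm_length: int = 0

    @property
    def n_segments(self) -> int:
        return len(self.segments)


def make_panel(ref: MtReference, n_segments: int = 46, arm_length: int = 0) -> ProbePanel:
    """Tile the shifted genome with contiguous, non-overlapping segments."""
    total = ref.shifted_length
    if not 1 <= n_segments <= total:
        raise SimulationError(
            f"n_segments must be in [1, {total}], got {n_segments}"
        )
    bounds = np.linspace(0, total, n_segments + 1).astype(int)
    segments = tuple(
        (f"seg{i + 1:02d}", int(bounds[i]) + 1, int(bounds[i + 1]))
        for i in range(n_segments)
    )
    return ProbePanel(segments=segments, arm_length=arm_length)


@dataclass(frozen=True)
class Heteroplasmy:
    pos: int  # canonical, 1-based
    alt: str
    vaf: float
    category: str | None = None
    pathogenic: bool = False


@dataclass
class TruthSet:
    """Ground truth and sequencing parameters for one simulated sample."""

    sample_id: str = "sample"
    haplotype_variants: list[tuple[int, str]] = field(default_factory=list)
    heteroplasmies: list[Heteroplasmy] = field(default_factory=list)
    numts_fraction: float = 0.0
    depth: float = 4000.0
    depth_jitter_sd: float = 0.2  # lognormal sigma of per-segment depth
    duplicate_rate: float = 0.5
    baq_values: tuple[float, ...] = (30.0, 20.0)
    baq_probs: tuple[float, ...] = (0.9, 0.1)
    read_length: int = 250
    mapq: int = 60
    upstream_flag_rate: float = 0.5  # NUMT families pre-flagged by alignment
    seed: int = 0

    def __post_init__(self) -> None:
        for h in self.heteroplasmies:
            if not 0.0 < h.vaf <= 0.5:
                raise SimulationError(f"VAF {h.vaf} outside (0, 0.5]")
        if not 0.0 <= self.numts_fraction < 0.5:
            raise SimulationError("numts_fraction must lie in [0, 0.5)")
        if self.depth < 0:
            raise SimulationError("depth must be >= 0")
        if abs(sum(self.baq_probs) - 1.0) > 1e-9:
            raise SimulationError("BAQ distribution probabilities must sum to 1")


def sample_haplotype(truth: TruthSet, ref: MtReference) -> str:
    """Canonical-frame haplotype: reference plus homoplasmic variants."""
    seq = list(ref.sequence)
    for pos, alt in truth.haplotype_variants:
        if not 1 <= pos <= ref.length:
            raise SimulationError(f"haplotype variant position {pos} outside genome")
        seq[pos - 1] = alt
    return "".join(seq)


def _shifted_images(pos: int, ref: MtReference) -> list[int]:
    """Shifted-frame position(s) of a canonical position (two in the wrap copy)."""
    images = [pos + ref.shift_bp]
    if pos > ref.length - ref.shift_bp:
        images.append(pos - (ref.length - ref.shift_bp))
    return images


def simulate_families(
    truth: TruthSet,
    panel: ProbePanel,
    ref: MtReference,
    numts_db=None,
    rng: np.random.Generator | None = None,
) -> list[FamilyBlock]:
    """Generate barcoded read families for every panel segment.

    Deterministic given ``truth.seed`` (or an explicit ``rng``). Returns one
    :class:`FamilyBlock` per segment.
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    for h in truth.heteroplasmies:
        if not 1 <= h.pos <= ref.length:
            raise SimulationError(f"heteroplasmy position {h.pos} outside genome")
    hap = sample_haplotype(truth, ref)
    hap_shifted = encode_bases(hap[ref.length - ref.shift_bp :] + hap)
    rl = truth.read_length
    blocks = []
    for seg_id, s, e in panel.segments:
        W = e - s + 1
        n_fam = max(1, int(np.rint(
            truth.depth * rng.lognormal(0.0, truth.depth_jitter_sd)
        ))) if truth.depth > 0 else 1

        mol = np.tile(hap_shifted[s - 1 : e], (n_fam, 1))
        is_numts = rng.random(n_fam) < truth.numts_fraction
        for h in truth.heteroplasmies:
            for img in _shifted_images(h.pos, ref):
                if s <= img <= e:
                    mutant = rng.random(n_fam) < h.vaf
                    mol[mutant, img - s] = NUCLEOTIDES.index(h.alt)
        if is_numts.any():
            if numts_db is None:
                raise SimulationError("numts_fraction > 0 requires a NUMT database")
            entries = numts_db.segment_entries(seg_id)
            if not entries:
                raise SimulationError(f"NUMT database has no entries for {seg_id}")
            choice = rng.integers(0, len(entries), size=int(is_numts.sum()))
            codes = np.stack([encode_bases(entries[c]) for c in choice])
            mol[is_numts] = codes

        extra = rng.geometric(1.0 - truth.duplicate_rate, size=n_fam) - 1
        n_pairs = 1 + np.minimum(extra, MAX_PAIRS - 1)
        reads_per_fam = 2 * n_pairs
        n_reads = int(reads_per_fam.sum())
        fam_of_read = np.repeat(np.arange(n_fam), reads_per_fam)
        group_starts = np.concatenate([[0], np.cumsum(reads_per_fam)[:-1]])
        read_rank = np.arange(n_reads) - np.repeat(group_starts, reads_per_fam)
        pair_index = read_rank // 2
        is_r2 = (read_rank % 2).astype(bool)

        bases = mol[fam_of_read]
        cols = np.arange(W)
        cover_r1 = cols < min(rl, W)
        cover_r2 = cols >= max(0, W - rl)
        covered = np.where(is_r2[:, None], cover_r2[None, :], cover_r1[None, :])

        values = np.asarray(truth.baq_values, dtype=np.float32)
        err_values = (10.0 ** (-values / 10.0)).astype(np.float32)
        which = np.zeros((n_reads, W), dtype=np.int8)
        if len(values) > 1:
            cum = np.cumsum(np.asarray(truth.baq_probs, dtype=np.float64))[:-1]
            u = rng.random((n_reads, W), dtype=np.float32)
            for threshold in cum:  # small BAQ alphabet: direct comparisons
                which += u >= np.float32(threshold)
        baq = values[which]
        err_p = err_values[which]
        miscall = (rng.random((n_reads, W), dtype=np.float32) < err_p) & covered
        shift = rng.integers(1, 4, size=int(miscall.sum()), dtype=np.int8)
        bases = np.where(covered, bases, np.int8(N_CODE))
        bases[miscall] = (bases[miscall] + shift) % 4
        baq[~covered] = 0.0

        upstream = is_numts & (rng.random(n_fam) < truth.upstream_flag_rate)
        blocks.append(
            FamilyBlock(
                segment_id=seg_id,
                seg_start=s,
                width=W,
                bases=bases.astype(np.int8),
                baq=baq,
                group_starts=group_starts.astype(np.int64),
                pair_index=pair_index.astype(np.int32),
                barcodes=[f"{seg_id}.{i:06d}" for i in range(n_fam)],
                n_pairs=n_pairs.astype(np.int32),
                mapq=np.full(n_fam, truth.mapq, dtype=np.int32),
                numts_truth=is_numts,
                upstream_flag=upstream,
            )
        )
    return blocks


# ---------------------------------------------------------------------------
# cohort-level simulation


@dataclass
class CohortDesign:
    """Design of a simulated cohort for incidence statistics.

    ``category_means`` are expected mutation counts per sample at the
    reference age; an optional per-category log-linear ``age_slope`` (per
    year) scales them as ``mean * exp(slope * (age - age_ref))``.
    """

    groups: dict[str, int] = field(
        default_factory=lambda: {"control": 23, "premanifest": 22, "early_stage": 21}
    )
    age_range: dict[str, tuple[float, float]] | tuple[float, float] = (30.0, 60.0)
    category_means: dict[str, float] = field(
        default_factory=lambda: {
            "dloop": 3.0,
            "synonymous": 0.4,
            "non_synonymous": 0.3,
            "rna": 0.3,
        }
    )
    age_slope: dict[str, float] = field(default_factory=dict)
    age_ref: float | None = None  # defaults to the midpoint of the age range
    pathogenic_fraction: dict[str, float] | float = 0.5
    vaf_range: tuple[float, float] = (0.01, 0.10)
    n_haplotype_variants: int = 10
    seed: int = 0
    sequencing: dict = field(default_factory=dict)  # TruthSet overrides

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.groups.values()):
            raise SimulationError("group sizes must be positive")
        if any(m < 0 for m in self.category_means.values()):
            raise SimulationError("Poisson means must be >= 0")

    def group_age_range(self, group: str) -> tuple[float, float]:
        if isinstance(self.age_range, dict):
            return self.age_range[group]
        return self.age_range

    def group_pathogenic_fraction(self, group: str) -> float:
        if isinstance(self.pathogenic_fraction, dict):
            return self.pathogenic_fraction[group]
        return float(self.pathogenic_fraction)


def _category_pools(ref: MtReference) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Candidate (pos, alt-code) arrays per mutation category.

    Low-complexity positions are excluded: calls there are filtered by
    design, so the generator does not place recoverable truth in them.
    Cached on the reference object (the effect enumeration is the pricey
    part for a full-size genome).
    """
    cached = getattr(ref, "_category_pool_cache", None)
    if cached is not None:
        return cached
    eff = enumerate_effects(ref)
    codes = ref.region_codes()[eff["pos"] - 1]
    lc = ref.lowcomp_mask()[eff["pos"] - 1]
    pools = {}
    pools["dloop"] = (codes == DLOOP) & ~lc
    pools["synonymous"] = (codes == PROTEIN_CODING) & (eff["effect"] == "synonymous") & ~lc
    pools["non_synonymous"] = (
        (codes == PROTEIN_CODING) & (eff["effect"] == "non_synonymous") & ~lc
    )
    pools["rna"] = (eff["effect"] == "rna") & ~lc
    result = {
        cat: (eff["pos"][mask], eff["alt"][mask]) for cat, mask in pools.items()
    }
    ref._category_pool_cache = result
    return result


def simulate_cohort(
    design: CohortDesign, ref: MtReference
) -> tuple[list[TruthSet], pd.DataFrame]:
    """Draw a cohort of per-sample truth sets plus the true count table.

    Returns ``(truth_sets, table)`` where ``table`` has one row per sample
    with columns sample_id, group, age, one count per category, the derived
    ``coding``/``all`` totals and the ``pathogenic`` count.
    """
    rng = np.random.default_rng(design.seed)
    pools = _category_pools(ref)
    rows = []
    truths: list[TruthSet] = []
    for group, n in design.groups.items():
        lo, hi = design.group_age_range(group)
        age_ref = design.age_ref if design.age_ref is not None else (lo + hi) / 2.0
        p_path = design.group_pathogenic_fraction(group)
        for i in range(n):
            sid = f"{group}_{i + 1:03d}"
            age = float(rng.uniform(lo, hi))
            hap_pos = rng.choice(
                np.arange(1, ref.length + 1),
                size=min(design.n_haplotype_variants, ref.length),
                replace=False,
            )
            hap_vars = []
            for p in hap_pos:
                base = ref.sequence[p - 1]
                alts = [c for c in NUCLEOTIDES if c != base]
                hap_vars.append((int(p), alts[rng.integers(0, 3)]))
            taken: set[int] = {p for p, _ in hap_vars}
            muts: list[Heteroplasmy] = []
            counts = {}
            for cat in CATEGORIES:
                mean = design.category_means.get(cat, 0.0)
                slope = design.age_slope.get(cat, 0.0)
                lam = mean * np.exp(slope * (age - age_ref))
                k = int(rng.poisson(lam)) if lam > 0 else 0
                placed = 0
                cand_pos, cand_alt = pools[cat]
                attempts = 0
                while placed < k and len(cand_pos) and attempts < 100 * (k + 1):
                    attempts += 1
                    j = int(rng.integers(0, len(cand_pos)))
                    pos = int(cand_pos[j])
                    if pos in taken:
                        continue
                    taken.add(pos)
                    vaf = float(
                        np.exp(rng.uniform(*np.log(design.vaf_range)))
                    )
                    pathogenic = cat == "non_synonymous" and rng.random() < p_path
                    muts.append(
                        Heteroplasmy(
                            pos=pos,
                            alt=NUCLEOTIDES[int(cand_alt[j])],
                            vaf=vaf,
                            category=cat,
                            pathogenic=pathogenic,
                        )
                    )
                    placed += 1
                counts[cat] = placed
            truths.append(
                TruthSet(
                    sample_id=sid,
                    haplotype_variants=hap_vars,
                    heteroplasmies=muts,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    **design.sequencing,
                )
            )
            rows.append(
                {
                    "sample_id": sid,
                    "group": group,
                    "age": age,
                    **counts,
                    "coding": counts["synonymous"]
                    + counts["non_synonymous"]
                    + counts["rna"],
                    "all": sum(counts.values()),
                    "pathogenic": sum(m.pathogenic for m in muts),
                }
            )
    return truths, pd.DataFrame(rows)


def truth_mutation_table(truths: list[TruthSet]) -> pd.DataFrame:
    """Flat per-mutation truth table across a cohort."""
    rows = [
        {
            "sample_id": t.sample_id,
            "pos": m.pos,
            "alt": m.alt,
            "vaf": m.vaf,
            "category": m.category,
            "pathogenic": m.pathogenic,
        }
        for t in truths
        for m in t.heteroplasmies
    ]
    return pd.DataFrame(
        rows, columns=["sample_id", "pos", "alt", "vaf", "category", "pathogenic"]
    )


def make_annotation_tables(
    truths: list[TruthSet], ref: MtReference, rng: np.random.Generator | None = None
) -> dict[str, pd.DataFrame]:
    """Miniature lookup tables consistent with a cohort's ground truth.

    Pathogenic non-synonymous truth mutations receive a CADD phred above 20;
    other non-synonymous ones a benign score. Every haplotype variant is
    listed as a known polymorphism (they are common population variants by
    construction), which also exercises the contamination screen.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    cadd_rows, disease_rows, poly_rows = [], [], []
    seen_cadd: set[tuple[int, str]] = set()
    seen_poly: set[tuple[int, str]] = set()
    for t in truths:
        for m in t.heteroplasmies:
            if m.category != "non_synonymous" or (m.pos, m.alt) in seen_cadd:
                continue
            seen_cadd.add((m.pos, m.alt))
            phred = rng.uniform(21.0, 35.0) if m.pathogenic else rng.uniform(0.0, 15.0)
            cadd_rows.append(
                {
                    "pos": m.pos,
                    "ref": ref.sequence[m.pos - 1],
                    "alt": m.alt,
                    "phred": round(float(phred), 2),
                }
            )
        for pos, alt in t.haplotype_variants:
            if (pos, alt) in seen_poly:
                continue
            seen_poly.add((pos, alt))
            poly_rows.append(
                {"pos": pos, "alt": alt, "frequency": round(float(rng.uniform(0.01, 0.5)), 3)}
            )
    return {
        "cadd": pd.DataFrame(cadd_rows, columns=["pos", "ref", "alt", "phred"]),
        "disease": pd.DataFrame(disease_rows, columns=["pos", "alt", "source"]),
        "polymorphisms": pd.DataFrame(poly_rows, columns=["pos", "alt", "frequency"]),
    }
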