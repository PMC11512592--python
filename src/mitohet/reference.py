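"""Circular mtDNA reference model.

Coordinates are 1-based inclusive throughout ("m." notation). The capture
pipeline aligns D-loop-spanning reads against a *shifted* frame in which the
final ``shift_bp`` bases of the circle are copied to the front; that frame
exists only at ingestion and every position is normalized back to the
canonical circle immediately (:func:`unshift_position`).

Region classification distinguishes the D-loop (control region, possibly
wrapping the origin), protein-coding genes, RNA genes (tRNA/rRNA) and the
remaining "other coding" positions, with low-complexity homopolymer tracts
kept as an independent overlay. Coding effects of single-nucleotide
substitutions are computed under the vertebrate mitochondrial genetic code
(translation table 2), with light-strand genes read on the reverse
complement and incomplete stop codons completed by polyadenylation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
_NT_INDEX = {c: i for i, c in enumerate(NUCLEOTIDES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# region class codes used in the cached per-position array
DLOOP, PROTEIN_CODING, RNA_CODING, OTHER_CODING = 0, 1, 2, 3
_CLASS_NAMES = ("dloop", "protein_coding", "rna_coding", "other_coding")

_MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]
_CODON_TO_AA = dict(_MITO_TABLE.forward_table)
for _stop in _MITO_TABLE.stop_codons:
    _CODON_TO_AA[_stop] = "*"
_START_CODONS = frozenset(_MITO_TABLE.start_codons)


class ReferenceError(ValueError):
    """Malformed reference input (FASTA or region configuration)."""


class CoordinateError(ValueError):
    """Position outside the valid coordinate range."""


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return complement(seq)[::-1]


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature of the mitochondrial genome.

    ``frame_start`` is the canonical 1-based position of the first base of
    codon 1 (protein genes only); for light-strand genes this is the *end*
    of the interval, since translation proceeds along the reverse
    complement.
    """

    name: str
    kind: str  # "protein" | "tRNA" | "rRNA"
    start: int
    end: int
    strand: str  # "H" | "L"
    frame_start: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("protein", "tRNA", "rRNA"):
            raise ReferenceError(f"unknown feature kind {self.kind!r}")
        if self.strand not in ("H", "L"):
            raise ReferenceError(f"unknown strand {self.strand!r}")
        if self.kind == "protein" and self.frame_start is None:
            raise ReferenceError(f"protein gene {self.name} lacks frame_start")
        if self.kind != "protein" and self.frame_start is not None:
            raise ReferenceError(f"RNA gene {self.name} must not set a reading frame")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class RegionClass:
    """Primary region class of a position plus the low-complexity overlay."""

    primary: str  # "dloop" | "protein_coding" | "rna_coding" | "other_coding"
    low_complexity: bool = False


@dataclass
class MtReference:
    """A circular mitochondrial reference genome with its region map."""

    sequence: str
    dloop: tuple[int, int]
    low_complexity: list[tuple[int, int]] = field(default_factory=list)
    genes: list[GeneFeature] = field(default_factory=list)
    shift_bp: int = 120
    name: str = "mtDNA"

    # caches, built lazily
    _region_codes: np.ndarray | None = field(default=None, repr=False)
    _lowcomp_mask: np.ndarray | None = field(default=None, repr=False)
    _protein_index: np.ndarray | None = field(default=None, repr=False)
    _rna_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        L = len(self.sequence)
        if L == 0:
            raise ReferenceError("empty reference sequence")
        if not (0 <= self.shift_bp < L):
            raise ReferenceError("shift_bp must lie in [0, length)")
        for start, end in [self.dloop, *self.low_complexity]:
            if not (1 <= start <= L and 1 <= end <= L):
                raise ReferenceError(f"interval ({start}, {end}) outside [1, {L}]")
        for g in self.genes:
            if not (1 <= g.start <= g.end <= L):
                raise ReferenceError(
                    f"gene {g.name} interval ({g.start}, {g.end}) outside [1, {L}]"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def shifted_length(self) -> int:
        return self.length + self.shift_bp

    @property
    def shifted_sequence(self) -> str:
        """Reference in the shifted frame: final shift_bp bases copied to the front."""
        return self.sequence[self.length - self.shift_bp :] + self.sequence

    def base(self, pos: int) -> str:
        """Reference base at a canonical 1-based position."""
        if not 1 <= pos <= self.length:
            raise CoordinateError(f"position {pos} outside [1, {self.length}]")
        return self.sequence[pos - 1]

    # ---- cached per-position maps -------------------------------------

    def region_codes(self) -> np.ndarray:
        """Primary region class code per canonical position (index pos-1)."""
        if self._region_codes is None:
            self._build_maps()
        return self._region_codes

    def lowcomp_mask(self) -> np.ndarray:
        if self._lowcomp_mask is None:
            self._build_maps()
        return self._lowcomp_mask

    def protein_index(self) -> np.ndarray:
        """Index into self.genes of the protein gene covering each position, -1 if none.

        Where protein genes overlap (e.g. ATP8/ATP6) the first in config
        order wins; this is the frame used for coding-effect calls.
        """
        if self._protein_index is None:
            self._build_maps()
        return self._protein_index

    def _interval_mask(self, start: int, end: int) -> np.ndarray:
        mask = np.zeros(self.length, dtype=bool)
        if start <= end:
            mask[start - 1 : end] = True
        else:  # wraps the origin
            mask[start - 1 :] = True
            mask[:end] = True
        return mask

    def _build_maps(self) -> None:
        L = self.length
        protein = np.full(L, -1, dtype=np.int32)
        rna = np.zeros(L, dtype=bool)
        for i, g in enumerate(self.genes):
            if g.kind == "protein":
                seg = protein[g.start - 1 : g.end]
                seg[seg < 0] = i
            else:
                rna[g.start - 1 : g.end] = True
        codes = np.full(L, OTHER_CODING, dtype=np.int8)
        codes[rna] = RNA_CODING
        codes[protein >= 0] = PROTEIN_CODING
        codes[self._interval_mask(*self.dloop)] = DLOOP
        lowcomp = np.zeros(L, dtype=bool)
        for start, end in self.low_complexity:
            lowcomp |= self._interval_mask(start, end)
        self._region_codes = codes
        self._lowcomp_mask = lowcomp
        self._protein_index = protein
        self._rna_mask = rna


# ---------------------------------------------------------------------------
# loading


def _parse_region_table(rows: Iterable[dict[str, str]]):
    dloop = None
    lowcomp: list[tuple[int, int]] = []
    genes: list[GeneFeature] = []
    for row in rows:
        kind = row["kind"]
        start, end = int(row["start"]), int(row["end"])
        if kind == "dloop":
            dloop = (start, end)
        elif kind == "low_complexity":
            lowcomp.append((start, end))
        else:
            fs = row.get("frame_start", ".")
            genes.append(
                GeneFeature(
                    name=row["name"],
                    kind=kind,
                    start=start,
                    end=end,
                    strand=row["strand"],
                    frame_start=None if fs in (".", "", None) else int(fs),
                )
            )
    if dloop is None:
        raise ReferenceError("region config defines no D-loop interval")
    return dloop, lowcomp, genes


def read_region_config(path) -> tuple[tuple[int, int], list[tuple[int, int]], list[GeneFeature]]:
    """Read a region/gene configuration TSV.

    Columns: name, kind (dloop | low_complexity | protein | tRNA | rRNA),
    start, end, strand (H/L or '.'), frame_start (int or '.').
    """
    import csv

    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        return _parse_region_table(reader)


def load_reference(fasta_path, region_config_path, shift_bp: int = 120) -> MtReference:
    """Load a single-record FASTA plus its region configuration."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ReferenceError(
            f"expected exactly one FASTA record in {fasta_path}, found {len(records)}"
        )
    seq = str(records[0].seq).upper()
    dloop, lowcomp, genes = read_region_config(region_config_path)
    return MtReference(
        sequence=seq,
        dloop=dloop,
        low_complexity=lowcomp,
        genes=genes,
        shift_bp=shift_bp,
        name=records[0].id,
    )


def rcrs_region_config_path():
    """Path of the bundled rCRS-style region/gene coordinate table."""
    return resources.files("mitohet.data") / "rcrs_regions.tsv"


def synthetic_full_reference(seed: int = 0, shift_bp: int = 120) -> MtReference:
    """A full-size (16,569 bp) synthetic circular genome.

    The base composition is random under ``seed`` but the region layout —
    D-loop span, low-complexity tracts, the full 13-protein / 22-tRNA /
    2-rRNA gene map with strands and reading frames — follows the bundled
    standard human mtDNA coordinate table, so position-dependent behaviour
    matches the real capture design.
    """
    rng = np.random.default_rng(seed)
    seq = "".join(np.array(list(NUCLEOTIDES))[rng.integers(0, 4, 16569)])
    dloop, lowcomp, genes = read_region_config(rcrs_region_config_path())
    return MtReference(
        sequence=seq,
        dloop=dloop,
        low_complexity=lowcomp,
        genes=genes,
        shift_bp=shift_bp,
        name=f"synthetic_mtDNA_seed{seed}",
    )


def mini_reference() -> MtReference:
    """The bundled 2,000-bp miniature circular genome used in tests/demos."""
    fasta = resources.files("mitohet.data") / "mini_genome.fa"
    config = resources.files("mitohet.data") / "mini_regions.tsv"
    return load_reference(str(fasta), str(config), shift_bp=120)


# ---------------------------------------------------------------------------
# coordinate conversion


def unshift_position(pos_shifted: int, ref: MtReference) -> int:
    """Map a 1-based position in the shifted frame to the canonical circle."""
    s, L = ref.shift_bp, ref.length
    if not 1 <= pos_shifted <= L + s:
        raise CoordinateError(
            f"shifted position {pos_shifted} outside [1, {L + s}]"
        )
    if pos_shifted <= s:
        return L - s + pos_shifted
    return pos_shifted - s


def shift_position(pos: int, ref: MtReference) -> int:
    """Canonical position -> shifted frame (the non-duplicated image)."""
    if not 1 <= pos <= ref.length:
        raise CoordinateError(f"position {pos} outside [1, {ref.length}]")
    return pos + ref.shift_bp


def unshift_positions(pos_shifted: np.ndarray, ref: MtReference) -> np.ndarray:
    """Vectorized :func:`unshift_position` (no bounds diagnostics)."""
    pos_shifted = np.asarray(pos_shifted)
    return np.where(
        pos_shifted <= ref.shift_bp,
        ref.length - ref.shift_bp + pos_shifted,
        pos_shifted - ref.shift_bp,
    )


# ---------------------------------------------------------------------------
# region classification


def classify_region(pos: int, ref: MtReference) -> RegionClass:
    """Primary region class of a canonical position, with low-complexity overlay."""
    if not 1 <= pos <= ref.length:
        raise CoordinateError(f"position {pos} outside [1, {ref.length}]")
    code = ref.region_codes()[pos - 1]
    return RegionClass(
        primary=_CLASS_NAMES[code],
        low_complexity=bool(ref.lowcomp_mask()[pos - 1]),
    )


def is_dloop(pos: np.ndarray | int, ref: MtReference):
    """Vectorized D-loop membership test on canonical positions."""
    return ref.region_codes()[np.asarray(pos) - 1] == DLOOP


# ---------------------------------------------------------------------------
# coding effect


def _codon_positions(gene: GeneFeature, codon_index: int) -> list[int]:
    """Canonical positions (5'->3' in the reading direction) of one codon."""
    if gene.strand == "H":
        first = gene.frame_start + 3 * codon_index
        return [first, first + 1, first + 2]
    first = gene.frame_start - 3 * codon_index
    return [first, first - 1, first - 2]


def _codon_base(gene: GeneFeature, pos: int, seq: str, L: int) -> str:
    """Base contributed to a codon by canonical position ``pos`` (strand-aware).

    Positions past the annotated gene end model the incomplete stop codon,
    completed by polyadenylation: they read as 'A' in mRNA orientation.
    """
    if gene.strand == "H":
        if pos > gene.end:
            return "A"
        return seq[pos - 1]
    if pos < gene.start:
        return "A"
    return complement(seq[pos - 1])


def _translate(codon: str, is_first_codon: bool) -> str:
    if is_first_codon and codon in _START_CODONS:
        return "M"
    return _CODON_TO_AA.get(codon, "X")


def coding_effect(pos: int, ref_allele: str, alt_allele: str, ref: MtReference) -> str:
    """Effect of a single-nucleotide substitution.

    Returns one of ``synonymous``, ``non_synonymous``, ``rna``,
    ``non_coding``. Protein genes are translated with the vertebrate
    mitochondrial code; light-strand genes are read on the reverse
    complement; alternative start codons at the annotated first codon all
    read as Met.
    """
    ref_allele = ref_allele.upper()
    alt_allele = alt_allele.upper()
    if ref_allele not in _NT_INDEX or alt_allele not in _NT_INDEX:
        raise ReferenceError(f"alleles must be single A/C/G/T, got {ref_allele}/{alt_allele}")
    if ref.base(pos) != ref_allele:
        raise ReferenceError(
            f"ref allele {ref_allele} does not match reference base "
            f"{ref.base(pos)} at m.{pos}"
        )
    gi = ref.protein_index()[pos - 1]
    if gi < 0:
        if ref.region_codes()[pos - 1] == RNA_CODING:
            return "rna"
        return "non_coding"
    gene = ref.genes[gi]
    offset = (pos - gene.frame_start) if gene.strand == "H" else (gene.frame_start - pos)
    codon_index, within = divmod(offset, 3)
    positions = _codon_positions(gene, codon_index)
    codon = "".join(_codon_base(gene, p, ref.sequence, ref.length) for p in positions)
    alt_base = alt_allele if gene.strand == "H" else complement(alt_allele)
    alt_codon = codon[:within] + alt_base + codon[within + 1 :]
    first = codon_index == 0
    aa_ref = _translate(codon, first)
    aa_alt = _translate(alt_codon, first)
    return "synonymous" if aa_ref == aa_alt else "non_synonymous"


def enumerate_effects(ref: MtReference) -> dict[str, np.ndarray]:
    """Effect class of every possible substitution on the genome.

    Returns arrays ``pos`` (canonical), ``alt`` (nucleotide index 0..3) and
    ``effect`` (string), one row per (position, non-reference allele). Used
    by the simulator to place mutations of a requested functional class and
    by exhaustive annotation round-trip checks.
    """
    pos_out, alt_out, eff_out = [], [], []
    seq = ref.sequence
    for pos in range(1, ref.length + 1):
        base = seq[pos - 1]
        if base not in _NT_INDEX:
            continue
        for alt in NUCLEOTIDES:
            if alt == base:
                continue
            pos_out.append(pos)
            alt_out.append(_NT_INDEX[alt])
            eff_out.append(coding_effect(pos, base, alt, ref))
    return {
        "pos": np.array(pos_out, dtype=np.int32),
        "alt": np.array(alt_out, dtype=np.int8),
        "effect": np.array(eff_out),
    }
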