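"""Filtering of consensus reads that originate from nuclear mtDNA copies.

NUMTs (nuclear mitochondrial segments) are mtDNA-like sequences embedded in
the nuclear genome; captured at low rate, they masquerade as low-level
heteroplasmies. A consensus read is flagged as a potential NUMT when its
edit distance to any known NUMT sequence of its capture segment is strictly
lower than its distance to the sample's own major mtDNA sequence, or when
its underlying read pairs were already marked as NUMT upstream (by genomic
alignment in the real pipeline; by the simulator's ground-truth flag here).

Edit distances are unit-cost Levenshtein, computed with edlib over the
consensus segment span; positions where the consensus has an 'N' are
dropped from both strings first. Ties are *not* flagged — "lower" is
strict, so a read equidistant between its own genome and a NUMT stays in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from Bio import SeqIO

from .consensus import ConsensusBlock, ConsensusRead, encode_bases


class NumtsError(ValueError):
    pass


@dataclass
class NumtsDb:
    """Known NUMT sequences per capture segment (including common-polymorphism variants)."""

    entries: dict[str, list[str]] = field(default_factory=dict)

    def segment_entries(self, segment_id: str) -> list[str]:
        return self.entries.get(segment_id, [])

    def add(self, segment_id: str, sequence: str) -> None:
        self.entries.setdefault(segment_id, []).append(sequence.upper())

    @classmethod
    def from_fasta(cls, path) -> "NumtsDb":
        """Load a NUMT collection from FASTA; headers name the segment id."""
        db = cls()
        for rec in SeqIO.parse(str(path), "fasta"):
            db.add(rec.id.split("|")[0], str(rec.seq))
        return db

    @classmethod
    def from_tsv(cls, path) -> "NumtsDb":
        df = pd.read_csv(path, sep="\t", dtype=str)
        db = cls()
        for _, row in df.iterrows():
            db.add(row["segment_id"], row["sequence"])
        return db

    def to_tsv(self, path) -> None:
        rows = [
            {"segment_id": seg, "sequence": seq}
            for seg, seqs in self.entries.items()
            for seq in seqs
        ]
        pd.DataFrame(rows, columns=["segment_id", "sequence"]).to_csv(
            path, sep="\t", index=False
        )


def make_numts_db(
    ref,
    panel,
    rng: np.random.Generator,
    segment_fraction: float = 1.0,
    n_diffs: tuple[int, int] = (4, 10),
    polymorphic_variants: int = 1,
) -> NumtsDb:
    """Simulate a NUMT collection: per segment, the reference span with a
    few fixed substitutions, plus variant copies carrying one extra common
    polymorphism each."""
    from .reference import NUCLEOTIDES

    db = NumtsDb()
    shifted = ref.shifted_sequence
    for seg_id, s, e in panel.segments:
        if rng.random() > segment_fraction:
            continue
        base = list(shifted[s - 1 : e])
        k = int(rng.integers(n_diffs[0], n_diffs[1] + 1))
        sites = rng.choice(len(base), size=min(k, len(base)), replace=False)
        for j in sites:
            alts = [c for c in NUCLEOTIDES if c != base[j]]
            base[j] = alts[rng.integers(0, 3)]
        db.add(seg_id, "".join(base))
        for _ in range(polymorphic_variants):
            var = list(base)
            j = int(rng.integers(0, len(var)))
            alts = [c for c in NUCLEOTIDES if c != var[j]]
            var[j] = alts[rng.integers(0, 3)]
            db.add(seg_id, "".join(var))
    return db


def edit_distance(a: str, b: str) -> int:
    """Unit-cost Levenshtein distance."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b, task="distance")["editDistance"]


def _strip_n(consensus_seq: str, other: str) -> tuple[str, str]:
    """Drop positions where the consensus has an N from both strings."""
    if "N" not in consensus_seq:
        return consensus_seq, other
    keep = [i for i, c in enumerate(consensus_seq) if c != "N"]
    return (
        "".join(consensus_seq[i] for i in keep),
        "".join(other[i] for i in keep if i < len(other)),
    )


def flag_numts(
    consensus: ConsensusRead,
    numts_db: NumtsDb,
    major_sequence: str,
    upstream_flag: bool | None = None,
) -> bool:
    """Decide whether one consensus read is a potential NUMT.

    ``major_sequence`` is the sample's major mtDNA sequence over the
    consensus span (same coordinates). With no database entry for the
    segment the NUMT distance is +inf, so only the upstream flag can fire.
    """
    if upstream_flag is None:
        upstream_flag = consensus.upstream_numts_flag
    if upstream_flag:
        return True
    entries = numts_db.segment_entries(consensus.segment_id)
    if not entries:
        return False
    seq = consensus.sequence()
    seq_nn, major_nn = _strip_n(seq, major_sequence)
    d_major = edit_distance(seq_nn, major_nn)
    d_numts = min(
        edit_distance(*_strip_n(seq, entry)) for entry in entries
    )
    return d_numts < d_major


def flag_numts_block(
    block: ConsensusBlock, numts_db: NumtsDb, major_shifted: np.ndarray
) -> np.ndarray:
    """Vectorized NUMT flagging of a consensus block.

    Consensus rows are full-span, coordinate-aligned sequences over their
    segment, and the variant model is substitution-only, so the pairwise
    edit distance reduces to a Hamming count over non-N positions — which
    vectorizes across all families at once. The scalar :func:`flag_numts`
    keeps the general Levenshtein form; both agree on aligned input.
    ``major_shifted`` holds shifted-frame int8 codes of the major sequence.
    """
    flags = np.asarray(block.upstream_flag, dtype=bool).copy()
    entries = numts_db.segment_entries(block.segment_id)
    if not entries:
        return flags
    lo = block.seg_start - 1
    major_span = major_shifted[lo : lo + block.width]
    valid = block.bases >= 0
    d_major = ((block.bases != major_span[None, :]) & valid).sum(axis=1)
    d_numts = None
    for entry in entries:
        codes = encode_bases(entry)
        d = ((block.bases != codes[None, :]) & valid).sum(axis=1)
        d_numts = d if d_numts is None else np.minimum(d_numts, d)
    return flags | (d_numts < d_major)
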