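"""Readers and writers for the pipeline's tabular dialects.

Everything is plain text: a family table (one row per read, FASTQ-style
offset-33 quality strings), a consensus table, a VCF-style call file
(v4.2 columns with VAF/VAFDUP/MINOR/DEPTH INFO fields and the six filter
verdicts), mutation and cohort tables as TSV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .consensus import ConsensusBlock, FamilyBlock, N_CODE, decode_bases, encode_bases

QUAL_OFFSET = 33
MAX_Q = 93


class ParseError(ValueError):
    pass


def _encode_quals(q: np.ndarray) -> str:
    q = np.clip(np.nan_to_num(np.asarray(q, dtype=float), posinf=MAX_Q), 0, MAX_Q)
    return "".join(chr(int(round(v)) + QUAL_OFFSET) for v in q)


def _decode_quals(s: str) -> np.ndarray:
    return np.array([ord(c) - QUAL_OFFSET for c in s], dtype=np.float64)


# ---------------------------------------------------------------------------
# family table


def write_families(blocks: list[FamilyBlock], path) -> int:
    """Write read families as TSV (one row per read). Returns rows written."""
    n = 0
    with open(path, "w") as fh:
        fh.write(
            "barcode\tsegment_id\tseg_start\tpair_index\tread_start\t"
            "bases\tquals\tmapq\tnumts_truth\tupstream_flag\n"
        )
        for block in blocks:
            ends = np.append(block.group_starts[1:], block.bases.shape[0])
            for fi, (lo, hi) in enumerate(zip(block.group_starts, ends)):
                for ri in range(lo, hi):
                    row = block.bases[ri]
                    covered = np.nonzero(row >= 0)[0]
                    if len(covered) == 0:
                        continue
                    a, b = covered[0], covered[-1] + 1
                    fh.write(
                        "\t".join(
                            [
                                block.barcodes[fi],
                                block.segment_id,
                                str(block.seg_start),
                                str(int(block.pair_index[ri])),
                                str(block.seg_start + int(a)),
                                decode_bases(row[a:b]),
                                _encode_quals(block.baq[ri, a:b]),
                                str(int(block.mapq[fi])),
                                "1" if block.numts_truth[fi] else "0",
                                "1" if block.upstream_flag[fi] else "0",
                            ]
                        )
                        + "\n"
                    )
                    n += 1
    return n


def read_families(path) -> list[FamilyBlock]:
    """Read a family table back into per-segment blocks."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "barcode": str,
            "segment_id": str,
            "bases": str,
            "quals": str,
        },
    )
    required = {
        "barcode", "segment_id", "seg_start", "pair_index", "read_start",
        "bases", "quals", "mapq", "numts_truth", "upstream_flag",
    }
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"family table missing columns: {sorted(missing)}")
    blocks = []
    for seg_id, sub in df.groupby("segment_id", sort=False):
        seg_start = int(sub["seg_start"].iloc[0])
        width = int((sub["read_start"] + sub["bases"].str.len()).max()) - seg_start
        barcodes = list(dict.fromkeys(sub["barcode"]))
        fam_index = {bc: i for i, bc in enumerate(barcodes)}
        order = sub.assign(_fam=sub["barcode"].map(fam_index)).sort_values(
            ["_fam", "pair_index"], kind="stable"
        )
        n_reads = len(order)
        bases = np.full((n_reads, width), N_CODE, dtype=np.int8)
        baq = np.zeros((n_reads, width))
        fam_of_read = order["_fam"].to_numpy()
        for i, row in enumerate(order.itertuples()):
            off = int(row.read_start) - seg_start
            codes = encode_bases(row.bases)
            quals = _decode_quals(row.quals)
            if len(codes) != len(quals):
                raise ParseError(
                    f"line for {row.barcode}: base/qual length mismatch"
                )
            bases[i, off : off + len(codes)] = codes
            baq[i, off : off + len(codes)] = quals
        group_starts = np.searchsorted(fam_of_read, np.arange(len(barcodes)))
        per_fam = order.groupby("_fam", sort=True)
        n_pairs = (per_fam["pair_index"].max() + 1).to_numpy()
        mapq = per_fam["mapq"].first().to_numpy()
        numts = per_fam["numts_truth"].first().to_numpy().astype(bool)
        upstream = per_fam["upstream_flag"].first().to_numpy().astype(bool)
        blocks.append(
            FamilyBlock(
                segment_id=str(seg_id),
                seg_start=seg_start,
                width=width,
                bases=bases,
                baq=baq,
                group_starts=group_starts.astype(np.int64),
                pair_index=order["pair_index"].to_numpy(np.int32),
                barcodes=barcodes,
                n_pairs=n_pairs.astype(np.int32),
                mapq=mapq.astype(np.int32),
                numts_truth=numts,
                upstream_flag=upstream,
            )
        )
    return blocks


def write_fastq(blocks: list[FamilyBlock], path_r1, path_r2) -> int:
    """Export raw pairs as FASTQ (read name carries barcode and pair index)."""
    n = 0
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for block in blocks:
            ends = np.append(block.group_starts[1:], block.bases.shape[0])
            for fi, (lo, hi) in enumerate(zip(block.group_starts, ends)):
                for ri in range(lo, hi):
                    row = block.bases[ri]
                    covered = np.nonzero(row >= 0)[0]
                    if len(covered) == 0:
                        continue
                    a, b = covered[0], covered[-1] + 1
                    mate = int(block.pair_index[ri])
                    fh = f2 if (ri - lo) % 2 else f1
                    fh.write(
                        f"@{block.barcodes[fi]}:{mate}\n"
                        f"{decode_bases(row[a:b])}\n+\n"
                        f"{_encode_quals(block.baq[ri, a:b])}\n"
                    )
                    n += 1
    return n


# ---------------------------------------------------------------------------
# consensus table


def write_consensus(blocks: list[ConsensusBlock], path) -> int:
    n = 0
    with open(path, "w") as fh:
        fh.write(
            "segment_id\tseg_start\tfamily_size\tmapq\tnumts_flag\t"
            "mismatch_count\tbases\tquals\n"
        )
        for block in blocks:
            numts = (
                block.numts_flag
                if block.numts_flag is not None
                else np.zeros(block.n_families, dtype=bool)
            )
            mism = (
                block.mismatch_count
                if block.mismatch_count is not None
                else np.full(block.n_families, -1)
            )
            for i in range(block.n_families):
                fh.write(
                    "\t".join(
                        [
                            block.segment_id,
                            str(block.seg_start),
                            str(int(block.family_size[i])),
                            str(int(block.mapq[i])),
                            "1" if numts[i] else "0",
                            str(int(mism[i])),
                            decode_bases(block.bases[i]),
                            _encode_quals(block.quals[i]),
                        ]
                    )
                    + "\n"
                )
                n += 1
    return n


# ---------------------------------------------------------------------------
# calls


VCF_HEADER = """##fileformat=VCFv4.2
##source=mitohet
##INFO=<ID=VAF,Number=1,Type=Float,Description="Minor allele fraction (all consensus reads)">
##INFO=<ID=VAFDUP,Number=1,Type=Float,Description="Minor allele fraction (duplicate-built consensus reads)">
##INFO=<ID=MINOR,Number=1,Type=Integer,Description="Minor allele read count">
##INFO=<ID=DEPTH,Number=1,Type=Integer,Description="Qualifying consensus read depth">
##FILTER=<ID=depth_comp,Description="Depth >= 100 with >= 70% of bases at BAQ >= 30">
##FILTER=<ID=low_complexity,Description="Site in a low-complexity region">
##FILTER=<ID=min_minor,Description="Fewer than 5 minor alleles">
##FILTER=<ID=loglik,Description="Log-likelihood quality score below 5">
##FILTER=<ID=dup_concordance,Description="Discordant VAF between duplicate strata">
##FILTER=<ID=poisson_error,Description="Not above the expected error count (exact Poisson)">
##FILTER=<ID=min_vaf,Description="VAF below 0.5%">
"""

_FILTER_COLS = {
    "depth_comp": "depth_comp",
    "low_complexity": "low_complexity",
    "min_minor": "min_minor",
    "loglik": "loglik_pass",
    "dup_concordance": "dup_concordance",
    "poisson_error": "poisson_error",
}


def write_calls_vcf(calls: pd.DataFrame, contig: str, contig_length: int, path,
                    called_only: bool = False) -> int:
    """Write the audit table (or just called variants) as a VCF-dialect file."""
    n = 0
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        fh.write(f"##contig=<ID={contig},length={contig_length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        sub = calls[calls["called"]] if called_only else calls
        for row in sub.itertuples():
            failed = [
                name for name, col in _FILTER_COLS.items() if not getattr(row, col)
            ]
            if row.vaf < 0.005 and not failed:
                failed.append("min_vaf")
            filt = "PASS" if row.called else (";".join(failed) or "FAIL")
            qual = f"{row.loglik:.1f}"
            info = (
                f"VAF={row.vaf:.5f};VAFDUP={row.vaf_dup:.5f};"
                f"MINOR={int(row.minor_count)};DEPTH={int(row.depth)}"
            )
            fh.write(
                f"{contig}\t{int(row.pos)}\t.\t{row.major}\t{row.minor}\t"
                f"{qual}\t{filt}\t{info}\n"
            )
            n += 1
    return n


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
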