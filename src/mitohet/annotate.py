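"""Functional annotation and pathogenicity classification of called mutations.

Each called heteroplasmy gets its genomic region (D-loop vs coding, with the
low-complexity overlay), its coding effect under the vertebrate
mitochondrial code, and a pathogenicity verdict. The rule applies to the
protein-coding region only: a mutation is pathogenic when it is
non-synonymous, has a CADD phred score above 20 *or* a reported disease
association, and does not overlap a known population polymorphism
(allele-level match). RNA-gene mutations are therefore never labelled
pathogenic here, even when disease-associated — they are still reported
with their annotations.

Lookup knowledge (CADD-style deleteriousness scores, disease associations,
known polymorphisms) enters as versioned TSV tables keyed by (pos, alt); no
live database queries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .reference import MtReference, classify_region, coding_effect

CATEGORY_COLUMNS = (
    "all",
    "dloop",
    "coding",
    "synonymous",
    "non_synonymous",
    "rna",
    "pathogenic",
)


def _allele_map(table: pd.DataFrame, value_col: str | None = None) -> dict:
    if table is None or table.empty:
        return {}
    if value_col is None:
        return {(int(r.pos), str(r.alt)): True for r in table.itertuples()}
    return {
        (int(r.pos), str(r.alt)): getattr(r, value_col) for r in table.itertuples()
    }


def annotate_calls(
    calls: pd.DataFrame,
    ref: MtReference,
    tables: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Annotate a table of called variants (columns pos, major, minor, ...).

    ``tables`` holds 'cadd' (pos, ref, alt, phred), 'disease' (pos, alt,
    source) and 'polymorphisms' (pos, alt, frequency). A missing CADD entry
    leaves the score absent, which never satisfies the >20 criterion.
    Returns the input rows with region/effect/pathogenicity columns added.
    """
    cadd = _allele_map(tables.get("cadd"), "phred")
    disease = _allele_map(tables.get("disease"))
    poly = _allele_map(tables.get("polymorphisms"))
    out = calls.copy()
    regions, lowc, effects, cadds, dis, known, patho = [], [], [], [], [], [], []
    for row in calls.itertuples():
        pos = int(row.pos)
        alt = str(row.minor)
        rc = classify_region(pos, ref)
        ref_base = ref.sequence[pos - 1]
        # effect of carrying the minor vs the major allele, in the annotated
        # reference codon frame; when the minor allele IS the reference base
        # (back-mutation at a haplotype site) the codon change major<->minor
        # is classified via the major allele — synonymy is symmetric
        alt_for_effect = alt if alt != ref_base else str(row.major)
        eff = coding_effect(pos, ref_base, alt_for_effect, ref)
        score = cadd.get((pos, alt))
        is_dis = (pos, alt) in disease
        is_poly = (pos, alt) in poly
        is_path = (
            eff == "non_synonymous"
            and ((score is not None and score > 20.0) or is_dis)
            and not is_poly
        )
        regions.append(rc.primary)
        lowc.append(rc.low_complexity)
        effects.append(eff)
        cadds.append(score)
        dis.append(is_dis)
        known.append(is_poly)
        patho.append(is_path)
    out["region"] = regions
    out["low_complexity_site"] = lowc
    out["effect"] = effects
    out["cadd_phred"] = pd.array(
        [np.nan if c is None else float(c) for c in cadds], dtype=float
    )
    out["disease_associated"] = dis
    out["known_polymorphism"] = known
    out["pathogenic"] = patho
    return out


def annotate_call(call_row: dict, ref: MtReference, tables: dict) -> dict:
    """Annotate a single call given as a mapping with 'pos' and 'minor'."""
    df = annotate_calls(pd.DataFrame([call_row]), ref, tables)
    return df.iloc[0].to_dict()


def tabulate_sample(annotated: pd.DataFrame) -> dict[str, int]:
    """Category counts for one sample's annotated mutations.

    ``all`` = dloop + coding; ``coding`` = synonymous + non_synonymous +
    rna + other coding positions; ``pathogenic`` counts pathogenic
    non-synonymous changes only.
    """
    if annotated.empty:
        return {c: 0 for c in CATEGORY_COLUMNS}
    dloop = int((annotated["region"] == "dloop").sum())
    syn = int(
        ((annotated["effect"] == "synonymous") & (annotated["region"] != "dloop")).sum()
    )
    nonsyn = int(
        (
            (annotated["effect"] == "non_synonymous")
            & (annotated["region"] != "dloop")
        ).sum()
    )
    rna = int((annotated["effect"] == "rna").sum())
    coding = int((annotated["region"] != "dloop").sum())
    return {
        "all": len(annotated),
        "dloop": dloop,
        "coding": coding,
        "synonymous": syn,
        "non_synonymous": nonsyn,
        "rna": rna,
        "pathogenic": int(annotated["pathogenic"].sum()),
    }


def tabulate_cohort(
    annotated: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Per-sample category counts joined with cohort metadata.

    ``annotated`` needs a ``sample_id`` column; ``metadata`` provides one row
    per sample (sample_id, group, age). Samples without any mutation keep
    zero counts.
    """
    rows = []
    for sid, meta in metadata.set_index("sample_id").iterrows():
        sub = (
            annotated[annotated["sample_id"] == sid]
            if not annotated.empty
            else annotated
        )
        counts = tabulate_sample(sub)
        rows.append({"sample_id": sid, **meta.to_dict(), **counts})
    return pd.DataFrame(rows)
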