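"""End-to-end orchestration: simulate -> consensus -> call -> annotate -> stats.

Each stage is importable on its own; :func:`process_sample` is the per-sample
core (consensus blocks in, calls out) and :func:`run_pipeline` ties a whole
simulated cohort together, writing every artifact plus a machine-readable
provenance block (config hash, seeds, per-stage record counts).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as ann
from . import caller, io, numts, simulate, stats
from .config import PipelineConfig
from .consensus import ConsensusBlock, consensus_block
from .reference import MtReference, load_reference, mini_reference

log = logging.getLogger("mitohet")


@dataclass
class SampleResult:
    sample_id: str
    major: str
    pileup: caller.Pileup
    calls: pd.DataFrame
    haplotype: pd.DataFrame
    blocks: list[ConsensusBlock]

    @property
    def called(self) -> pd.DataFrame:
        return self.calls[self.calls["called"]]


def load_configured_reference(config: PipelineConfig) -> MtReference:
    if config.reference_fasta is None:
        return mini_reference()
    if config.region_config is None:
        raise FileNotFoundError(
            "reference_fasta given without region_config (stage: reference loading)"
        )
    return load_reference(
        config.reference_fasta, config.region_config, shift_bp=config.shift_bp
    )


def process_sample(
    blocks,
    ref: MtReference,
    numts_db: numts.NumtsDb | None,
    config: PipelineConfig,
    sample_id: str = "sample",
) -> SampleResult:
    """Consensus-call one sample from its family blocks."""
    cons = [consensus_block(b) for b in blocks]
    pileup, major = caller.build_pileup(cons, ref, numts_db, config.thresholds)
    calls = caller.call_variants(
        pileup, major, ref, config.error_model, config.thresholds
    )
    hap = caller.haplotype_differences(major, ref)
    return SampleResult(
        sample_id=sample_id,
        major=major,
        pileup=pileup,
        calls=calls,
        haplotype=hap,
        blocks=cons,
    )


def truth_overrides(config: PipelineConfig) -> dict:
    return {
        "depth": config.depth,
        "duplicate_rate": config.duplicate_rate,
        "numts_fraction": config.numts_fraction,
        "baq_values": config.baq_values,
        "baq_probs": config.baq_probs,
        "read_length": config.read_length,
    }


def run_pipeline(
    config: PipelineConfig,
    design: simulate.CohortDesign,
    outdir,
    write_families: bool = False,
) -> dict:
    """Run the full simulated-cohort pipeline and write all artifacts.

    Returns the provenance dictionary (also written to ``provenance.json``).
    Artifacts: per-sample call VCFs and audit TSVs, the annotated cohort
    mutation table, the per-sample count table, Table-1-style and
    Table-2-style reports.
    """
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = load_configured_reference(config)
    panel = simulate.make_panel(ref, config.n_segments)
    rng = np.random.default_rng(config.seed)
    numts_db = (
        numts.make_numts_db(ref, panel, rng) if config.numts_fraction > 0 else None
    )

    design.sequencing = {**truth_overrides(config), **design.sequencing}
    truths, truth_table = simulate.simulate_cohort(design, ref)
    tables = simulate.make_annotation_tables(truths, ref, rng)
    io.write_tsv(truth_table, outdir / "truth_counts.tsv")
    io.write_tsv(simulate.truth_mutation_table(truths), outdir / "truth_mutations.tsv")
    for name, df in tables.items():
        io.write_tsv(df, outdir / f"table_{name}.tsv")

    stage_counts = {"samples": len(truths), "segments": panel.n_segments}
    annotated_all = []
    n_calls = 0
    contaminated = []
    for truth in truths:
        blocks = simulate.simulate_families(truth, panel, ref, numts_db)
        result = process_sample(blocks, ref, numts_db, config, truth.sample_id)
        io.write_consensus(result.blocks, outdir / f"{truth.sample_id}.consensus.tsv")
        io.write_calls_vcf(
            result.calls, ref.name, ref.length, outdir / f"{truth.sample_id}.calls.vcf"
        )
        io.write_tsv(result.calls, outdir / f"{truth.sample_id}.audit.tsv")
        called = result.called
        n_calls += len(called)
        n_poly, flagged = caller.contamination_check(
            called, tables["polymorphisms"], ref, config.thresholds.contamination_min
        )
        if flagged:
            contaminated.append(truth.sample_id)
        annotated = ann.annotate_calls(called, ref, tables)
        annotated.insert(0, "sample_id", truth.sample_id)
        annotated_all.append(annotated)
        log.info(
            "sample %s: %d consensus families, %d called, %d at polymorphic sites",
            truth.sample_id,
            sum(b.n_families for b in result.blocks),
            len(called),
            n_poly,
        )
    non_empty = [df for df in annotated_all if not df.empty]
    if non_empty:
        mutations = pd.concat(non_empty, ignore_index=True)
    elif annotated_all:
        mutations = annotated_all[0].iloc[:0]
    else:
        mutations = pd.DataFrame()
    io.write_tsv(mutations, outdir / "mutations.tsv")

    metadata = truth_table[["sample_id", "group", "age"]]
    keep = metadata[~metadata["sample_id"].isin(contaminated)]
    counts = ann.tabulate_cohort(mutations, keep)
    io.write_tsv(counts, outdir / "cohort_counts.tsv")

    groups = list(design.groups)
    control_groups = [g for g in groups if "control" in g] or groups[:1]
    case_groups = [g for g in groups if g not in control_groups]
    categories = ["all", "dloop", "coding", "non_synonymous", "pathogenic"]
    report1 = stats.incidence_report(counts, categories, case_groups or control_groups,
                                     control_groups)
    io.write_tsv(report1, outdir / "report_incidence.tsv")
    group_sets = {g: [g] for g in groups}
    report2 = stats.age_trend_report(counts, categories, group_sets)
    io.write_tsv(report2, outdir / "report_age_trend.tsv")

    stage_counts.update(
        {
            "called_variants": int(n_calls),
            "annotated_mutations": int(len(mutations)),
            "contaminated_samples": contaminated,
        }
    )
    provenance = {
        "config_digest": config.digest(),
        "config": config.to_dict(),
        "seed": config.seed,
        "design_seed": design.seed,
        "stage_counts": stage_counts,
        "elapsed_s": round(time.time() - t0, 2),
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, default=str)
    return provenance
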