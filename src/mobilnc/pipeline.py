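"""End-to-end orchestration: simulate -> assign -> quantify -> call mobility.

This is the path the command-line interface and the reproduction script
drive; each stage is also usable on its own.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .assign import AssignmentParams, AssignmentSummary, PairAssignment, SeedIndex, assign_library
from .models import SPECIES, TISSUES, GenomeSet
from .overlap import ExonIndex
from .quantify import (
    CountResult,
    ExpressionMatrix,
    MobilityTable,
    build_mobility_table,
    call_transcript_mobility,
    catalog_lengths,
    compute_fpkm,
    count_fragments,
)
from .simulate import Abundances, LibrarySet, SimConfig, simulate


@dataclass
class PipelineResult:
    config: SimConfig
    genomes: GenomeSet
    abundances: Abundances
    libraries: LibrarySet
    summaries: dict[str, AssignmentSummary]
    assignments: dict[str, list[PairAssignment]]
    counts: CountResult
    expression: ExpressionMatrix
    mobility_flags: pd.Series
    mobility_table: MobilityTable

    def recovery_stats(self) -> dict[str, float]:
        """Sensitivity/specificity of the mobility calls against the emitted
        ground-truth mobile sets."""
        truth = self.libraries.emitted_mobile_sets()
        tp = fp = fn = tn = 0
        for species in SPECIES:
            for t in self.genomes.transcripts[species]:
                called = bool(self.mobility_flags.get(t.transcript_id, False))
                is_true = t.transcript_id in truth[species]
                tp += called and is_true
                fp += called and not is_true
                fn += (not called) and is_true
                tn += (not called) and not is_true
        sens = tp / (tp + fn) if tp + fn else float("nan")
        spec = tn / (tn + fp) if tn + fp else float("nan")
        return {"sensitivity": sens, "specificity": spec, "tp": tp, "fp": fp, "fn": fn, "tn": tn}


def build_indices(genomes: GenomeSet, params: AssignmentParams) -> dict[str, SeedIndex]:
    return {
        s: SeedIndex(genomes.sequences[s], params.k, species=s) for s in SPECIES
    }


def run_pipeline(
    config: SimConfig,
    params: AssignmentParams | None = None,
    min_mobile_fragments: float = 1,
) -> PipelineResult:
    params = params or AssignmentParams()
    genomes, abundances, libraries = simulate(config)
    indices = build_indices(genomes, params)
    exon_index = ExonIndex(genomes)

    summaries: dict[str, AssignmentSummary] = {}
    assignments: dict[str, list[PairAssignment]] = {}
    for tissue in TISSUES:
        summary, assigned = assign_library(
            libraries.reads[tissue],
            indices["parasite"],
            indices["host"],
            params,
            tissue=tissue,
            catalog=genomes,
            exon_index=exon_index,
        )
        summaries[tissue] = summary
        assignments[tissue] = assigned

    counts = count_fragments(assignments, genomes, exon_index)
    expression = compute_fpkm(counts.counts, catalog_lengths(genomes), counts.totals)
    flags = call_transcript_mobility(counts, genomes, min_mobile_fragments)
    table = build_mobility_table(flags, genomes)
    return PipelineResult(
        config=config,
        genomes=genomes,
        abundances=abundances,
        libraries=libraries,
        summaries=summaries,
        assignments=assignments,
        counts=counts,
        expression=expression,
        mobility_flags=flags,
        mobility_table=table,
    )
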