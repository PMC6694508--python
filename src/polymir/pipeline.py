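"""End-to-end study driver: simulated libraries through every analysis stage.

`run_study` wires the modules together the way the CLI subcommands would be
run by hand: generate (or accept) a simulated study, clean the libraries,
call miRNA loci on each genome, quantify, run the differential and
mid-parent-value analyses, and classify synteny toward the F1 and back.
Intermediate objects are kept so tests and examples can interrogate any
stage against the simulation truth.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from polymir.config import SimulationConfig
from polymir.homology import GenomeIndex
from polymir.identify import MiRNALocus, call_loci, catalog_table, presence_summary
from polymir.nonadditive import call_nonadditive, summarize_nonadditive
from polymir.preprocess import PreprocessResult, preprocess_libraries, reads_to_table
from polymir.quantify import de_contrast, de_summary, tpm_normalize
from polymir.simulate import (
    Simulation,
    simulate_expression,
    simulate_genomes,
    simulate_reads,
    write_libraries,
)
from polymir.synteny import (
    SyntenyRecord,
    call_loss_gain,
    call_syntenic,
    classify_sets,
    extract_flanks,
    subgenome_of,
)

SAMPLES = ("parent1", "parent2", "f1")


@dataclass
class StudyResult:
    sim: Simulation
    true_counts: pd.DataFrame
    preprocess: PreprocessResult
    counts: pd.DataFrame  # unique-read count table (sequence x library)
    loci: dict[str, list[MiRNALocus]]
    catalog: pd.DataFrame
    mirna_counts: pd.DataFrame  # per-mature counts over called miRNAs
    tpm: pd.DataFrame
    presence: dict[str, dict[str, set[str]]]  # class -> sample -> matures
    de: dict[tuple[str, str], pd.DataFrame]
    de_summaries: dict[tuple[str, str], dict[str, int]]
    nonadditive_calls: pd.DataFrame
    nonadditive_summary: dict[str, object]
    synteny_records: dict[str, list[SyntenyRecord]]
    events: dict[str, object]

    @property
    def libraries(self) -> dict[str, list[str]]:
        return {
            s: [c for c in self.counts.columns if c.rsplit("_rep", 1)[0] == s]
            for s in SAMPLES
        }


def run_study(
    config: SimulationConfig,
    workdir: str | Path | None = None,
    min_count: int = 5,
    run_synteny: bool = True,
) -> StudyResult:
    """Simulate one study and run the full analysis over it."""
    sim = simulate_genomes(config)
    true_counts = simulate_expression(sim.truth, config)
    libs = simulate_reads(sim, true_counts)
    if workdir is None:
        tmp = tempfile.TemporaryDirectory()
        workdir = tmp.name
    write_libraries(libs, workdir)
    pre = preprocess_libraries(
        {lib: Path(workdir) / f"{lib}.fastq" for lib in libs},
        sim.config.adapter_seq,
        sim.ncrna,
    )
    counts = reads_to_table(pre.reads, sorted(libs))
    return analyse(sim, true_counts, pre, counts, min_count=min_count, run_synteny=run_synteny)


def analyse(
    sim: Simulation,
    true_counts: pd.DataFrame,
    pre: PreprocessResult,
    counts: pd.DataFrame,
    min_count: int = 5,
    run_synteny: bool = True,
) -> StudyResult:
    loci = {
        g: call_loci(pre.reads, sim.genomes[g], sim.known_mature, min_count=min_count)
        for g in ("parent1", "parent2", "f1")
    }
    catalog = catalog_table(loci)

    libraries = {
        s: [c for c in counts.columns if c.rsplit("_rep", 1)[0] == s] for s in SAMPLES
    }
    matures = sorted({l.mature for g in loci for l in loci[g]})
    mirna_counts = counts.reindex(matures).fillna(0).astype(int)
    tpm = tpm_normalize(mirna_counts)

    presence: dict[str, dict[str, set[str]]] = {}
    for cls in ("conserved", "novel"):
        per_sample: dict[str, set[str]] = {}
        for sample in SAMPLES:
            cols = libraries[sample]
            expressed = set(mirna_counts.index[mirna_counts[cols].sum(axis=1) >= 1])
            in_class = {
                l.mature
                for g in loci
                for l in loci[g]
                if l.classification.label == cls
            }
            per_sample[sample] = expressed & in_class
        presence[cls] = per_sample
    for g, ls in loci.items():
        sample_expressed = {
            s: set(mirna_counts.index[mirna_counts[libraries[s]].sum(axis=1) >= 1])
            for s in SAMPLES
        }
        for l in ls:
            l.expressed_in = {s for s in SAMPLES if l.mature in sample_expressed[s]}

    contrasts = [("parent1", "f1"), ("parent2", "f1"), ("parent1", "parent2")]
    de = {}
    de_summaries = {}
    for control, case in contrasts:
        res = de_contrast(mirna_counts, libraries, control, case)
        de[(control, case)] = res
        de_summaries[(control, case)] = de_summary(res)

    na_calls = call_nonadditive(mirna_counts, libraries)
    na_summary = summarize_nonadditive(na_calls)

    synteny_records: dict[str, list[SyntenyRecord]] = {}
    events: dict[str, object] = {}
    if run_synteny:
        synteny_records, events = run_synteny_analysis(sim, loci)

    return StudyResult(
        sim=sim,
        true_counts=true_counts,
        preprocess=pre,
        counts=counts,
        loci=loci,
        catalog=catalog,
        mirna_counts=mirna_counts,
        tpm=tpm,
        presence=presence,
        de=de,
        de_summaries=de_summaries,
        nonadditive_calls=na_calls,
        nonadditive_summary=na_summary,
        synteny_records=synteny_records,
        events=events,
    )


def run_synteny_analysis(
    sim: Simulation, loci: dict[str, list[MiRNALocus]]
) -> tuple[dict[str, list[SyntenyRecord]], dict[str, object]]:
    """Synteny of parental loci toward the F1 and of F1 loci toward each parent."""
    indexes = {g: GenomeIndex(sim.genomes[g]) for g in ("parent1", "parent2", "f1")}
    caches: dict[tuple[str, str], dict] = {}

    def direction(source: str, target: str) -> list[SyntenyRecord]:
        cache = caches.setdefault((source, target), {})
        records = []
        for l in loci[source]:
            pre_seq = sim.genomes[source][l.chrom][l.precursor_start : l.precursor_end]
            flanks = extract_flanks(
                sim.annotations[source], sim.genomes[source], l.id, l.chrom, l.start, l.end
            )
            rec = call_syntenic(
                l.id, pre_seq, flanks, indexes[target], sim.annotations[target],
                source_genome=source, mature=l.mature,
                classification=l.classification.label,
                expected_subgenome=subgenome_of(l.chrom),
                flank_hit_cache=cache,
            )
            classify_sets(rec)
            records.append(rec)
        return records

    recs = {
        "parent1_to_f1": direction("parent1", "f1"),
        "parent2_to_f1": direction("parent2", "f1"),
        "f1_to_parent1": direction("f1", "parent1"),
        "f1_to_parent2": direction("f1", "parent2"),
    }
    events = call_loss_gain(
        recs["parent1_to_f1"] + recs["parent2_to_f1"],
        recs["f1_to_parent1"],
        recs["f1_to_parent2"],
    )
    return recs, events
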