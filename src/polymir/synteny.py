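"""Flanking-gene microsynteny of miRNA loci across the hybrid and its parents.

A miRNA is syntenic between two assemblies when one of its qualifying
genomic placements in the other assembly is accompanied, within a window, by
a homolog of at least one of its flanking protein-coding genes (up to five
per side).  Each locus is then assigned to one of four sets relative to the
other assembly:

* set1 — syntenic placement in the expected (same-lettered) subgenome;
* set2 — syntenic placement only in the opposite subgenome;
* set3 — sequence homology present but no flank support anywhere;
* set4 — no qualifying homology at all.

Parental loci falling in set4 toward the F1 are lost-in-F1 events; F1 loci
in set4 toward both parents are gained-in-F1.  Sets 1-3 feed the Circos
karyotype/link export.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from polymir.homology import (
    GENE_PARAMS,
    PRECURSOR_PARAMS,
    GenomeIndex,
    HomologyHit,
    HomologyParams,
    HomologyResult,
    homology_search,
)

DEFAULT_WINDOW = 100_000

_SUBGENOME_RE = re.compile(r"^([A-Za-z]+)")


def subgenome_of(chrom: str) -> str:
    """Subgenome label of a chromosome name ("An3" -> "An")."""
    m = _SUBGENOME_RE.match(chrom)
    return m.group(1) if m else chrom


@dataclass(frozen=True)
class FlankGene:
    gene_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    sequence: str


@dataclass
class FlankContext:
    """Up to five coding genes on each side of a miRNA, nearest first."""

    mirna_id: str
    upstream: list[FlankGene]
    downstream: list[FlankGene]


def extract_flanks(
    annotation: pd.DataFrame,
    genome: dict[str, str],
    mirna_id: str,
    chrom: str,
    start: int,
    end: int,
    n_per_side: int = 5,
) -> FlankContext:
    """Nearest coding genes on each side of a locus (0-based half-open input).

    A gene overlapping the miRNA is assigned to the side of its midpoint.
    Fewer than ``n_per_side`` genes are returned near chromosome ends.
    """
    genes = annotation[(annotation["type"] == "gene") & (annotation["seqid"] == chrom)]
    if chrom not in set(annotation["seqid"]):
        raise ValueError(f"chromosome {chrom!r} absent from annotation")
    up, down = [], []
    for row in genes.itertuples(index=False):
        gs, ge = row.start - 1, row.end  # GFF3 is 1-based inclusive
        mid = (gs + ge) / 2.0
        fg = FlankGene(row.feature_id, chrom, gs, ge, genome[chrom][gs:ge])
        if ge <= start or (gs < end and mid < (start + end) / 2.0):
            up.append((start - mid, fg))
        else:
            down.append((mid - end, fg))
    up.sort(key=lambda t: t[0])
    down.sort(key=lambda t: t[0])
    return FlankContext(
        mirna_id,
        [fg for _, fg in up[:n_per_side]],
        [fg for _, fg in down[:n_per_side]],
    )


@dataclass
class PlacementEvidence:
    hit: HomologyHit
    matched_upstream: list[str]
    matched_downstream: list[str]

    @property
    def syntenic(self) -> bool:
        return bool(self.matched_upstream or self.matched_downstream)


@dataclass
class SyntenyRecord:
    mirna_id: str
    source_genome: str
    mature: str
    classification: str  # conserved | novel | ""
    expected_subgenome: str
    placements: list[PlacementEvidence] = field(default_factory=list)
    set_label: str = "set4"
    event: str = "none"  # none | lost_in_F1 | gained_in_F1

    @property
    def syntenic(self) -> bool:
        return any(p.syntenic for p in self.placements)

    @property
    def best(self) -> PlacementEvidence | None:
        ranked = sorted(
            self.placements,
            key=lambda p: (not p.syntenic, -p.hit.score, p.hit.chrom, p.hit.start),
        )
        return ranked[0] if ranked else None


def call_syntenic(
    mirna_id: str,
    precursor_seq: str,
    flanks: FlankContext,
    target_index: GenomeIndex,
    target_annotation: pd.DataFrame,
    source_genome: str = "",
    mature: str = "",
    classification: str = "",
    expected_subgenome: str = "",
    window: int = DEFAULT_WINDOW,
    gene_params: HomologyParams = GENE_PARAMS,
    precursor_params: HomologyParams = PRECURSOR_PARAMS,
    flank_hit_cache: dict[str, HomologyResult] | None = None,
) -> SyntenyRecord:
    """Locate a miRNA in a target assembly and test its flank neighbourhood.

    For each of the top precursor placements, a flank gene counts as matched
    when one of its own qualifying homology hits overlaps an annotated
    coding gene within ``window`` bp of the placement.
    """
    rec = SyntenyRecord(mirna_id, source_genome, mature, classification, expected_subgenome)
    mir_hits = homology_search(precursor_seq, target_index, precursor_params).hits
    if not mir_hits:
        return rec
    gene_spans: dict[str, list[tuple[int, int]]] = {}
    genes = target_annotation[target_annotation["type"] == "gene"]
    for row in genes.itertuples(index=False):
        gene_spans.setdefault(row.seqid, []).append((row.start - 1, row.end))
    cache = flank_hit_cache if flank_hit_cache is not None else {}

    def flank_hits(fg: FlankGene) -> list[HomologyHit]:
        if fg.gene_id not in cache:
            cache[fg.gene_id] = homology_search(fg.sequence, target_index, gene_params)
        return cache[fg.gene_id].hits

    for hit in mir_hits:
        centre = hit.start
        matched_up, matched_down = [], []
        for side, bucket in ((flanks.upstream, matched_up), (flanks.downstream, matched_down)):
            for fg in side:
                for fh in flank_hits(fg):
                    if fh.chrom != hit.chrom or abs(fh.start - centre) > window:
                        continue
                    if any(
                        fh.start < ge and fh.start + len(fg.sequence) > gs
                        for gs, ge in gene_spans.get(fh.chrom, ())
                    ):
                        bucket.append(fg.gene_id)
                        break
        rec.placements.append(PlacementEvidence(hit, matched_up, matched_down))
    return rec


def classify_sets(record: SyntenyRecord) -> str:
    """Assign the 4-way set label from a record's placement evidence."""
    syntenic = [p for p in record.placements if p.syntenic]
    if any(subgenome_of(p.hit.chrom) == record.expected_subgenome for p in syntenic):
        label = "set1"
    elif syntenic:
        label = "set2"
    elif record.placements:
        label = "set3"
    else:
        label = "set4"
    record.set_label = label
    return label


def call_loss_gain(
    parent_records: list[SyntenyRecord],
    f1_records_vs_parent1: list[SyntenyRecord],
    f1_records_vs_parent2: list[SyntenyRecord],
) -> dict[str, object]:
    """Loss/gain events from the set labels, aggregated per mature sequence.

    A mature identifies one miRNA entity that may own several locus records
    (homoeologous copies and the two arms of a perfect stem), so events are
    decided on all records of an entity: lost when every parental placement
    is set4 toward the F1; gained when every F1 placement is set4 toward
    both parents.  The summary splits each list by conserved/novel
    classification; totals are the sum of the split.
    """

    def by_entity(records: list[SyntenyRecord]) -> dict[str, list[SyntenyRecord]]:
        groups: dict[str, list[SyntenyRecord]] = {}
        for rec in records:
            groups.setdefault(rec.mature or rec.mirna_id, []).append(rec)
        return groups

    def all_set4(records: list[SyntenyRecord]) -> bool:
        return all(r.set_label == "set4" for r in records)

    lost: dict[str, SyntenyRecord] = {}
    for key, group in by_entity(parent_records).items():
        if all_set4(group):
            lost[key] = group[0]
            for rec in group:
                rec.event = "lost_in_F1"
    vs1 = by_entity(f1_records_vs_parent1)
    vs2 = by_entity(f1_records_vs_parent2)
    gained: dict[str, SyntenyRecord] = {}
    for key, group in vs1.items():
        if all_set4(group) and key in vs2 and all_set4(vs2[key]):
            gained[key] = group[0]
            for rec in group + vs2[key]:
                rec.event = "gained_in_F1"

    def split(records: dict[str, SyntenyRecord]) -> dict[str, int]:
        n_cons = sum(1 for r in records.values() if r.classification == "conserved")
        n_nov = sum(1 for r in records.values() if r.classification == "novel")
        return {"conserved": n_cons, "novel": n_nov, "total": n_cons + n_nov}

    return {
        "lost": sorted(lost),
        "gained": sorted(gained),
        "summary": {"lost": split(lost), "gained": split(gained)},
    }


_SUBGENOME_COLORS = {"An": "blue", "Cn": "green", "Ar": "red"}


@dataclass
class CircosExport:
    karyotype: list[str]
    links: list[str]


def export_circos(
    records: list[SyntenyRecord],
    source_genome: dict[str, str],
    target_genome: dict[str, str],
    source_coords: dict[str, tuple[str, int, int]],
) -> CircosExport:
    """Circos karyotype and link files for set1-3 records.

    ``source_coords`` maps mirna_id -> (chrom, start, end) of the source
    locus (0-based half-open, as in the link lines).  One link joins each
    record's source locus to its best target placement; chromosome bands are
    colored by subgenome so the F1's An/Cn and Ar sets are distinguishable.
    """
    karyotype = []
    for label, genome in (("src", source_genome), ("tgt", target_genome)):
        for chrom in sorted(genome):
            color = _SUBGENOME_COLORS.get(subgenome_of(chrom), "grey")
            karyotype.append(f"chr - {label}_{chrom} {chrom} 0 {len(genome[chrom])} {color}")
    links = []
    for rec in records:
        if rec.set_label not in ("set1", "set2", "set3"):
            continue
        best = rec.best
        if best is None or rec.mirna_id not in source_coords:
            continue
        chrom, s, e = source_coords[rec.mirna_id]
        t = best.hit
        links.append(f"src_{chrom} {s} {e} tgt_{t.chrom} {t.start} {t.start + (e - s)}")
    return CircosExport(karyotype, links)


def records_table(records: list[SyntenyRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        best = rec.best
        rows.append(
            dict(
                mirna_id=rec.mirna_id,
                source_genome=rec.source_genome,
                classification=rec.classification,
                expected_subgenome=rec.expected_subgenome,
                syntenic=rec.syntenic,
                set_label=rec.set_label,
                event=rec.event,
                best_chrom=best.hit.chrom if best else "",
                best_start=best.hit.start if best else -1,
                best_score=round(best.hit.score, 4) if best else 0.0,
                matched_upstream=",".join(best.matched_upstream) if best else "",
                matched_downstream=",".join(best.matched_downstream) if best else "",
                n_hits=len(rec.placements),
            )
        )
    return pd.DataFrame(rows)
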