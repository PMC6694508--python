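"""miRNA locus identification: read mapping, hairpin calling, classification.

Unique cleaned reads are placed on a genome (exact placement through a
prefix-seed index; mismatch placement through a vectorized sliding scan for
small genomes), candidate precursors are excised around each placement and
folded, and placements whose hairpin satisfies the acceptance criteria become
miRNA loci.  Each mature is then classified conserved (within 2 substitutions
of a known mature under the best ungapped offset alignment) or novel, and
conserved matures inherit a family name from their best-matching known miRNA.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from polymir.fold import HairpinCall, HairpinParams, HairpinStructure, fold_hairpin, is_valid_hairpin
from polymir.io import revcomp
from polymir.preprocess import SmallRNARead

_SEED_LEN = 15


@dataclass(frozen=True)
class GenomeHit:
    """One placement of a read on a genome (0-based half-open, + or - strand)."""

    read: str
    chrom: str
    start: int
    strand: str
    mismatches: int = 0

    @property
    def end(self) -> int:
        return self.start + len(self.read)


@dataclass
class MapResult:
    hits: list[GenomeHit]
    multimapped: list[str]  # read sequences with more than max_hits placements
    rejected: list[tuple[str, str]]  # (sequence, reason)

    def by_read(self) -> dict[str, list[GenomeHit]]:
        out: dict[str, list[GenomeHit]] = defaultdict(list)
        for h in self.hits:
            out[h.read].append(h)
        return out


def map_reads(
    reads: list[str],
    genome: dict[str, str],
    max_mismatch: int = 0,
    max_hits: int = 20,
) -> MapResult:
    """Place each read on both strands of the genome with <= max_mismatch.

    Reads with more than ``max_hits`` placements are flagged multi-mapped
    (their hits are dropped); non-ACGT reads are rejected with a reason.
    """
    ok_reads = []
    rejected = []
    seen = set()
    for r in reads:
        if r in seen:
            continue
        seen.add(r)
        if not r or set(r) - set("ACGT"):
            rejected.append((r, "non-ACGT"))
        elif len(r) < _SEED_LEN and max_mismatch == 0:
            rejected.append((r, "too-short"))
        else:
            ok_reads.append(r)

    hits_by_read: dict[str, list[GenomeHit]] = {r: [] for r in ok_reads}
    if max_mismatch == 0:
        _map_exact(ok_reads, genome, hits_by_read)
    else:
        _map_mismatch(ok_reads, genome, max_mismatch, hits_by_read)

    hits: list[GenomeHit] = []
    multimapped: list[str] = []
    for r in ok_reads:
        h = hits_by_read[r]
        if len(h) > max_hits:
            multimapped.append(r)
        else:
            hits.extend(sorted(h, key=lambda x: (x.chrom, x.start, x.strand)))
    return MapResult(hits=hits, multimapped=multimapped, rejected=rejected)


def _map_exact(reads: list[str], genome: dict[str, str], out: dict[str, list[GenomeHit]]) -> None:
    seeds: dict[str, list[tuple[str, str]]] = defaultdict(list)
    for r in reads:
        seeds[r[:_SEED_LEN]].append((r, "+"))
        seeds[revcomp(r)[:_SEED_LEN]].append((r, "-"))
    for chrom, seq in genome.items():
        n = len(seq)
        for pos in range(n - _SEED_LEN + 1):
            cands = seeds.get(seq[pos : pos + _SEED_LEN])
            if not cands:
                continue
            for read, strand in cands:
                target = read if strand == "+" else revcomp(read)
                if seq.startswith(target, pos):
                    out[read].append(GenomeHit(read, chrom, pos, strand, 0))


def _map_mismatch(
    reads: list[str], genome: dict[str, str], max_mismatch: int, out: dict[str, list[GenomeHit]]
) -> None:
    """Vectorized sliding Hamming scan; quadratic, intended for small genomes."""
    arrs = {c: np.frombuffer(s.encode(), dtype=np.uint8) for c, s in genome.items()}
    for read in reads:
        for strand in "+-":
            target = read if strand == "+" else revcomp(read)
            t = np.frombuffer(target.encode(), dtype=np.uint8)
            L = t.shape[0]
            for chrom, g in arrs.items():
                if g.shape[0] < L:
                    continue
                mm = np.zeros(g.shape[0] - L + 1, dtype=np.int32)
                for j in range(L):
                    mm += g[j : g.shape[0] - L + 1 + j] != t[j]
                for pos in np.flatnonzero(mm <= max_mismatch):
                    out[read].append(GenomeHit(read, chrom, int(pos), strand, int(mm[pos])))


@dataclass(frozen=True)
class Classification:
    label: str  # "conserved" | "novel"
    known_id: str | None = None
    mismatches: int | None = None


def offset_distance(a: str, b: str) -> int:
    """Minimum substitution distance over all ungapped offsets.

    Bases of either sequence left outside the overlap count as mismatches, so
    the distance of identical sequences shifted by s is 2*s.
    """
    best = len(a) + len(b)
    for s in range(-(len(b) - 1), len(a)):
        lo, hi = max(0, s), min(len(a), s + len(b))
        if hi <= lo:
            continue
        mm = sum(1 for i in range(lo, hi) if a[i] != b[i - s])
        d = mm + (len(a) - (hi - lo)) + (len(b) - (hi - lo))
        if d < best:
            best = d
    return best


def classify_mirna(mature: str, known_set: dict[str, str], max_mismatch: int = 2) -> Classification:
    """Conserved if within ``max_mismatch`` substitutions of any known mature.

    The best-matching known id is reported (ties broken lexicographically by
    name); matures farther than the threshold from every known are novel.
    """
    mature = mature.upper().replace("U", "T")
    best_d = None
    best_id = None
    for name in sorted(known_set):
        d = offset_distance(mature, known_set[name].upper().replace("U", "T"))
        if best_d is None or d < best_d:
            best_d, best_id = d, name
    if best_d is not None and best_d <= max_mismatch:
        return Classification("conserved", best_id, best_d)
    return Classification("novel", None, best_d)


_FAMILY_RE = re.compile(r"^(?:[a-z]{3,4}-)?(miR[0-9]+(?:_[0-9]+)?)[a-z]*(?:[-._][35]p)?$", re.IGNORECASE)


def assign_family(known_name: str) -> str:
    """Family label from a miRBase-style name: drop species prefix, variant
    letter and arm tag ("ath-miR156a-5p" -> "miR156")."""
    m = _FAMILY_RE.match(known_name.strip())
    if not m:
        return "unassigned"
    fam = m.group(1)
    return "miR" + fam[3:]


@dataclass
class MiRNALocus:
    """A called miRNA locus: mature placement, precursor and its hairpin."""

    id: str
    chrom: str
    start: int  # mature span, 0-based half-open
    end: int
    strand: str
    mature: str
    precursor_start: int
    precursor_end: int
    structure: HairpinStructure
    hairpin: HairpinCall
    classification: Classification
    family: str | None = None
    expressed_in: set[str] = field(default_factory=set)


_FLANKS = (20, 50, 100, 150, 250)


def _candidate_windows(s: int, e: int, chrom_len: int) -> list[tuple[int, int]]:
    """Precursor excision windows around a mature placement.

    Tries a ladder of extensions on the 3' then 5' genomic side (mature can
    sit on either arm) from tight (20 nt) to wide (250 nt), clipped to the
    chromosome.  Ordering is tight-first so the smallest window that already
    passes the hairpin criteria is taken.
    """
    wins = []
    for f in _FLANKS:
        for a, b in ((20, f), (f, 20)):
            ws, we = max(0, s - a), min(chrom_len, e + b)
            if 60 <= we - ws <= 300 and (ws, we) not in wins:
                wins.append((ws, we))
    return wins


def call_loci(
    reads: list[SmallRNARead],
    genome: dict[str, str],
    known_set: dict[str, str] | None = None,
    min_count: int = 5,
    max_hits: int = 20,
    params: HairpinParams | None = None,
) -> list[MiRNALocus]:
    """Call miRNA loci on one genome from a unique-read table.

    Candidate matures are unique reads with summed count >= ``min_count``;
    each exact placement (multi-mapped reads excluded) is tested for an
    enclosing valid hairpin.  Every placement that passes becomes a locus;
    the same mature may therefore own several loci (homoeologous copies).
    """
    params = params or HairpinParams()
    known_set = known_set or {}
    cands = [r.sequence for r in reads if r.total >= min_count]
    result = map_reads(cands, genome, max_mismatch=0, max_hits=max_hits)
    loci: list[MiRNALocus] = []
    class_cache: dict[str, Classification] = {}
    for hit in result.hits:
        chrom_seq = genome[hit.chrom]
        found = None
        for ws, we in _candidate_windows(hit.start, hit.end, len(chrom_seq)):
            window = chrom_seq[ws:we]
            if hit.strand == "+":
                pre, off = window, hit.start - ws
            else:
                pre, off = revcomp(window), we - hit.end
            structure = fold_hairpin(pre)
            call = is_valid_hairpin(structure, (off, off + len(hit.read)), params)
            if call.valid:
                found = (ws, we, structure, call)
                break
        if found is None:
            continue
        ws, we, structure, call = found
        if hit.read not in class_cache:
            class_cache[hit.read] = classify_mirna(hit.read, known_set) if known_set else Classification("novel")
        cls = class_cache[hit.read]
        family = assign_family(cls.known_id) if cls.label == "conserved" and cls.known_id else None
        loci.append(
            MiRNALocus(
                id="",
                chrom=hit.chrom,
                start=hit.start,
                end=hit.end,
                strand=hit.strand,
                mature=hit.read,
                precursor_start=ws,
                precursor_end=we,
                structure=structure,
                hairpin=call,
                classification=cls,
                family=family,
            )
        )
    loci.sort(key=lambda l: (l.chrom, l.start, l.strand))
    for i, loc in enumerate(loci):
        loc.id = f"MIR{i + 1:04d}"
    return loci


def presence_summary(presence: dict[str, set[str]]) -> dict[str, object]:
    """Venn partition of miRNA presence across exactly three samples.

    ``presence`` maps sample name -> set of miRNA identifiers.  Returns the
    seven region counts (keys are "+"-joined sorted sample names), the union
    size, and the percentage shared by all three samples rounded to the
    nearest integer.
    """
    if len(presence) != 3:
        raise ValueError("presence_summary expects exactly three samples")
    names = sorted(presence)
    union = set().union(*presence.values())
    regions: dict[str, int] = {}
    for mask in range(1, 8):
        members = [names[i] for i in range(3) if mask >> i & 1]
        inside = set.intersection(*(presence[m] for m in members))
        outside = set().union(*(presence[m] for m in names if m not in members), set())
        regions["+".join(members)] = len(inside - outside)
    shared = len(set.intersection(*presence.values()))
    pct = int(round(100.0 * shared / len(union))) if union else 0
    return {"regions": regions, "union": len(union), "shared": shared, "shared_percent": pct}


def catalog_table(loci_by_genome: dict[str, list[MiRNALocus]]) -> pd.DataFrame:
    """Flat per-locus catalog across genomes (coordinates 1-based inclusive)."""
    rows = []
    for genome, loci in loci_by_genome.items():
        for l in loci:
            rows.append(
                dict(
                    genome=genome,
                    id=l.id,
                    chrom=l.chrom,
                    start=l.start + 1,
                    end=l.end,
                    strand=l.strand,
                    mature=l.mature,
                    precursor_start=l.precursor_start + 1,
                    precursor_end=l.precursor_end,
                    classification=l.classification.label,
                    known_id=l.classification.known_id or "",
                    mismatches=l.classification.mismatches,
                    family=l.family or "",
                )
            )
    return pd.DataFrame(rows)
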