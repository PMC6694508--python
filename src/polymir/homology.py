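"""Self-contained ungapped homology search (k-mer seed and extend).

A query qualifies at a genome offset if, aligning it base-for-base on one
strand, either the full-length identity or the best identity over a window
covering ``min_coverage`` of the query clears the identity threshold.  The
seeded search only evaluates offsets (diagonals) sharing an exact k-mer with
the query, which at the divergence levels the pipeline targets finds the
same hit set as an exhaustive scan of every offset.  Hits are ranked by
identity x coverage with a deterministic (chrom, position, strand) tie-break
and the top 5 kept.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from polymir.io import revcomp


@dataclass
class HomologyParams:
    """Qualification thresholds.  Defaults suit protein-coding flank genes
    (>=85% identity over >=60% of the query); precursor searches use
    :data:`PRECURSOR_PARAMS` (>=90% over the full length)."""

    k: int = 11
    min_identity: float = 0.85
    min_coverage: float = 0.6
    top_n: int = 5


GENE_PARAMS = HomologyParams()
PRECURSOR_PARAMS = HomologyParams(min_identity=0.90, min_coverage=1.0)


@dataclass(frozen=True)
class HomologyHit:
    chrom: str
    start: int  # 0-based offset of the aligned query on the + strand
    strand: str
    identity: float
    coverage: float

    @property
    def score(self) -> float:
        return self.identity * self.coverage


@dataclass
class HomologyResult:
    hits: list[HomologyHit]
    flagged: str = ""  # non-empty when the query could not be searched


class GenomeIndex:
    """Exact k-mer position index over a genome, built once per target."""

    def __init__(self, genome: dict[str, str], k: int = 11):
        self.genome = genome
        self.k = k
        self.arrays = {c: np.frombuffer(s.encode(), dtype=np.uint8) for c, s in genome.items()}
        self.kmers: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for chrom, seq in genome.items():
            for pos in range(len(seq) - k + 1):
                self.kmers[seq[pos : pos + k]].append((chrom, pos))


def _score_offset(
    q: np.ndarray, g: np.ndarray, d: int, params: HomologyParams
) -> tuple[float, float] | None:
    """(identity, coverage) at genome offset d, or None if not qualifying."""
    L = q.shape[0]
    if d < 0 or d + L > g.shape[0]:
        return None
    m = (q == g[d : d + L]).astype(np.int32)
    total = int(m.sum())
    if total / L >= params.min_identity:
        return total / L, 1.0
    if params.min_coverage < 1.0:
        w = int(np.ceil(params.min_coverage * L))
        cs = np.concatenate(([0], np.cumsum(m)))
        window = cs[w:] - cs[:-w]
        best = int(window.max())
        if best / w >= params.min_identity:
            return best / w, w / L
    return None


def homology_search(
    query: str,
    target: GenomeIndex | dict[str, str],
    params: HomologyParams | None = None,
) -> HomologyResult:
    """Search both strands of the target for qualifying placements of query."""
    params = params or GENE_PARAMS
    if isinstance(target, dict):
        target = GenomeIndex(target, params.k)
    query = query.upper().replace("U", "T")
    if len(query) < params.k:
        return HomologyResult([], flagged="query-shorter-than-k")
    hits: list[HomologyHit] = []
    for strand in "+-":
        qs = query if strand == "+" else revcomp(query)
        qarr = np.frombuffer(qs.encode(), dtype=np.uint8)
        diagonals: dict[str, set[int]] = defaultdict(set)
        k = target.k
        for qpos in range(len(qs) - k + 1):
            for chrom, gpos in target.kmers.get(qs[qpos : qpos + k], ()):
                diagonals[chrom].add(gpos - qpos)
        for chrom, ds in diagonals.items():
            g = target.arrays[chrom]
            for d in sorted(ds):
                scored = _score_offset(qarr, g, d, params)
                if scored is not None:
                    hits.append(HomologyHit(chrom, d, strand, scored[0], scored[1]))
    hits.sort(key=lambda h: (-h.score, h.chrom, h.start, h.strand))
    return HomologyResult(hits[: params.top_n])
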