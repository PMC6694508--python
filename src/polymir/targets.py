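"""Plant-style miRNA target prediction by complementarity penalty scoring.

Every ungapped antisense alignment of the miRNA against a transcript is
scored per position, counting from the miRNA 5' end: perfect pair 0, G:U
wobble 0.5, mismatch 1.0, with penalties doubled in the 5' functional region
(positions 2-13).  Sites at or below the penalty cutoff (default 4.0) are
reported, best site per transcript first.  Bulged duplexes are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

MATCH = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "T"), ("T", "G")}  # G:U in DNA alphabet
CORE_START, CORE_END = 2, 13  # 1-based inclusive positions with doubled penalty


@dataclass(frozen=True)
class TargetHit:
    mirna_id: str
    transcript_id: str
    start: int  # site span on the transcript, 0-based half-open
    end: int
    score: float
    annotation: str  # per miRNA position, 5'->3': "|" match, "o" G:U, "x" mismatch


def _site_score(mirna: str, site: str) -> tuple[float, str]:
    """Penalty of one ungapped duplex; site is the transcript window 5'->3'.

    miRNA position i (1-based from its 5' end) faces transcript base
    site[len - i] in the antiparallel duplex.
    """
    L = len(mirna)
    total = 0.0
    ann = []
    for i in range(L):
        m = mirna[i]
        t = site[L - 1 - i]
        if (m, t) in MATCH:
            pen, sym = 0.0, "|"
        elif (m, t) in WOBBLE:
            pen, sym = 0.5, "o"
        else:
            pen, sym = 1.0, "x"
        if CORE_START <= i + 1 <= CORE_END:
            pen *= 2.0
        total += pen
        ann.append(sym)
    return total, "".join(ann)


def score_target(
    mirna: str,
    transcript: str,
    max_score: float = 4.0,
    mirna_id: str = "",
    transcript_id: str = "",
) -> list[TargetHit]:
    """All target sites of a miRNA on one transcript at or below the cutoff.

    Scans every ungapped antisense placement; hits are sorted best score
    first with ties broken by leftmost site.
    """
    mirna = mirna.upper().replace("U", "T")
    transcript = transcript.upper().replace("U", "T")
    if not mirna or not transcript:
        raise ValueError("sequences must be non-empty")
    if not 18 <= len(mirna) <= 26:
        raise ValueError("miRNA length must be 18-26 nt")
    L = len(mirna)
    hits = []
    for t in range(0, len(transcript) - L + 1):
        score, ann = _site_score(mirna, transcript[t : t + L])
        if score <= max_score:
            hits.append(TargetHit(mirna_id, transcript_id, t, t + L, score, ann))
    hits.sort(key=lambda h: (h.score, h.start))
    return hits


def scan_transcripts(
    mirnas: dict[str, str],
    transcripts: dict[str, str],
    max_score: float = 4.0,
    best_per_transcript: bool = True,
) -> pd.DataFrame:
    """Target table over all miRNA x transcript pairs."""
    rows = []
    for mid, mseq in mirnas.items():
        if not 18 <= len(mseq) <= 26:
            continue
        for tid, tseq in transcripts.items():
            if len(tseq) < len(mseq):
                continue
            hits = score_target(mseq, tseq, max_score, mid, tid)
            if best_per_transcript and hits:
                hits = hits[:1]
            rows.extend(
                dict(
                    mirna_id=h.mirna_id,
                    transcript_id=h.transcript_id,
                    start=h.start,
                    end=h.end,
                    score=h.score,
                    annotation=h.annotation,
                )
                for h in hits
            )
    return pd.DataFrame(
        rows, columns=["mirna_id", "transcript_id", "start", "end", "score", "annotation"]
    )


def build_network(
    mirna_ids: list[str],
    hits: pd.DataFrame,
    highlight: set[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """miRNA-target bipartite network as (edge table, node table).

    Nodes carry a role (mirna/target), a highlight flag for a caller-supplied
    transcript class (e.g. transcription factors) and their degree.  miRNAs
    in ``mirna_ids`` appear even when they hit nothing (degree 0).
    """
    highlight = highlight or set()
    g = nx.MultiGraph()  # one edge per hit, so degrees count sites
    for mid in mirna_ids:
        g.add_node(mid, role="mirna")
    for row in hits.itertuples(index=False):
        g.add_node(row.mirna_id, role="mirna")
        g.add_node(row.transcript_id, role="target")
        g.add_edge(row.mirna_id, row.transcript_id)
    edges = hits[["mirna_id", "transcript_id"]].copy() if len(hits) else pd.DataFrame(
        columns=["mirna_id", "transcript_id"]
    )
    nodes = pd.DataFrame(
        [
            dict(
                node=n,
                role=g.nodes[n]["role"],
                highlight=n in highlight,
                degree=g.degree[n],
            )
            for n in g.nodes
        ]
    )
    return edges, nodes
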