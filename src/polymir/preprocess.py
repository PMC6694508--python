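"""Raw small-RNA library cleaning: adapter, quality, ncRNA and poly(A) filters.

The end product is a unique-read count table (one row per distinct trimmed
sequence, one count column per library) plus the per-library length profile
and a removal-composition table.  All filters are deterministic string rules:
3' adapter trimming by prefix match with a bounded mismatch rate, mean-Phred /
N-count quality filtering, exact-substring matching against a structural
ncRNA set (both strands) and a terminal poly(A) run rule.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from polymir.io import read_fastq, revcomp

MIN_LEN = 18
MAX_LEN = 30


@dataclass
class SmallRNARead:
    """A unique cleaned read sequence with per-library counts."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def trim_adapter(read: str, adapter: str, min_overlap: int = 8) -> str | None:
    """Remove the 3' adapter; ``None`` signals a too-short (discarded) read.

    The suffix starting at the leftmost position where a prefix of the
    adapter matches with at most one mismatch per 10 matched bases (and at
    least ``min_overlap`` matched bases) is removed.  Reads without a match
    are returned unchanged; trimmed inserts shorter than 18 nt are discarded.
    """
    if not adapter:
        raise ValueError("adapter sequence must be non-empty")
    if len(adapter) < min_overlap:
        raise ValueError("adapter shorter than min_overlap")
    read = read.upper().replace("U", "T")
    adapter = adapter.upper()
    n = len(read)
    for i in range(0, n - min_overlap + 1):
        ov = min(n - i, len(adapter))
        allowed = ov // 10
        mm = 0
        ok = True
        for k in range(ov):
            if read[i + k] != adapter[k]:
                mm += 1
                if mm > allowed:
                    ok = False
                    break
        if ok:
            return read[:i] if i >= MIN_LEN else None
    return read


def filter_low_quality(
    read: str, qualities: list[int], min_mean_q: int = 20, max_n: int = 0
) -> bool:
    """True if the read survives: mean Phred >= threshold (inclusive) and few Ns."""
    if len(qualities) != len(read):
        raise ValueError("quality string length does not match read length")
    if not read:
        return False
    if read.upper().count("N") > max_n:
        return False
    return sum(qualities) / len(qualities) >= min_mean_q


def _ncrna_class(name: str) -> str:
    low = name.lower()
    for cls in ("snorna", "snrna", "trna", "rrna"):
        if cls in low:
            return {"snorna": "snoRNA", "snrna": "snRNA", "trna": "tRNA", "rrna": "rRNA"}[cls]
    return "ncRNA"


def filter_ncrna(
    reads: dict[str, int],
    ncrna_set: dict[str, str],
    polyA_min_run: int = 8,
) -> tuple[dict[str, int], pd.DataFrame]:
    """Split {sequence: count} into kept reads and a removal table.

    A read is removed if it is a perfect substring of any ncRNA sequence on
    either strand, or ends in >= ``polyA_min_run`` consecutive A.  The
    returned removal table has columns (sequence, count, reason) with reasons
    rRNA / tRNA / snRNA / snoRNA / ncRNA / polyA.
    """
    haystacks = [
        (_ncrna_class(name), seq.upper().replace("U", "T")) for name, seq in ncrna_set.items()
    ]
    kept: dict[str, int] = {}
    removed = []
    for seq, count in reads.items():
        reason = None
        for cls, hay in haystacks:
            if seq in hay or revcomp(seq) in hay:
                reason = cls
                break
        if reason is None and len(seq) >= polyA_min_run and seq.endswith("A" * polyA_min_run):
            reason = "polyA"
        if reason is None:
            kept[seq] = count
        else:
            removed.append((seq, count, reason))
    removed_df = pd.DataFrame(removed, columns=["sequence", "count", "reason"])
    return kept, removed_df


def collapse_unique(reads_per_library: dict[str, dict[str, int]]) -> list[SmallRNARead]:
    """Merge per-library {sequence: count} maps into unique-read records."""
    merged: dict[str, SmallRNARead] = {}
    for lib, seqmap in reads_per_library.items():
        for seq, count in seqmap.items():
            if count <= 0:
                continue
            rec = merged.setdefault(seq, SmallRNARead(seq))
            rec.counts[lib] = rec.counts.get(lib, 0) + count
    return [merged[s] for s in sorted(merged)]


def length_profile(reads: list[SmallRNARead]) -> pd.DataFrame:
    """Count-weighted read-length histogram (18-30 nt) with per-library fractions.

    Returns a tidy DataFrame with columns (library, length, count, fraction);
    empty libraries simply contribute no rows.
    """
    counts: Counter[tuple[str, int]] = Counter()
    for rec in reads:
        ln = len(rec.sequence)
        for lib, c in rec.counts.items():
            counts[(lib, ln)] += c
    rows = [(lib, ln, c) for (lib, ln), c in counts.items()]
    df = pd.DataFrame(rows, columns=["library", "length", "count"])
    if df.empty:
        df["fraction"] = pd.Series(dtype=float)
        return df
    totals = df.groupby("library")["count"].transform("sum")
    df["fraction"] = df["count"] / totals
    return df.sort_values(["library", "length"]).reset_index(drop=True)


@dataclass
class PreprocessResult:
    reads: list[SmallRNARead]
    profile: pd.DataFrame
    composition: pd.DataFrame  # per-library removal/kept class counts
    stats: pd.DataFrame  # per-library input/trimmed/quality/ncrna/kept totals


def preprocess_libraries(
    fastq_paths: dict[str, str | Path],
    adapter: str,
    ncrna_set: dict[str, str] | None = None,
    min_overlap: int = 8,
    min_mean_q: int = 20,
    max_n: int = 0,
    polyA_min_run: int = 8,
) -> PreprocessResult:
    """Full cleaning pipeline from FASTQ files to a unique-read table."""
    ncrna_set = ncrna_set or {}
    per_lib: dict[str, dict[str, int]] = {}
    stat_rows = []
    comp_rows = []
    for lib, path in fastq_paths.items():
        n_in = n_short = n_lowq = 0
        trimmed: Counter[str] = Counter()
        for _, seq, qual in read_fastq(path):
            n_in += 1
            quals = [ord(c) - 33 for c in qual]
            if not filter_low_quality(seq, quals, min_mean_q, max_n):
                n_lowq += 1
                continue
            t = trim_adapter(seq, adapter, min_overlap)
            if t is None or not (MIN_LEN <= len(t) <= MAX_LEN):
                n_short += 1
                continue
            trimmed[t] += 1
        kept, removed = filter_ncrna(dict(trimmed), ncrna_set, polyA_min_run)
        per_lib[lib] = kept
        n_ncrna = int(removed["count"].sum()) if len(removed) else 0
        n_kept = sum(kept.values())
        stat_rows.append((lib, n_in, n_lowq, n_short, n_ncrna, n_kept))
        if len(removed):
            by_reason = removed.groupby("reason")["count"].sum()
            for reason, c in by_reason.items():
                comp_rows.append((lib, reason, int(c)))
        comp_rows.append((lib, "kept", n_kept))
    reads = collapse_unique(per_lib)
    return PreprocessResult(
        reads=reads,
        profile=length_profile(reads),
        composition=pd.DataFrame(comp_rows, columns=["library", "class", "count"]),
        stats=pd.DataFrame(
            stat_rows,
            columns=["library", "input", "low_quality", "length_filtered", "ncrna_polyA", "kept"],
        ),
    )


def reads_to_table(reads: list[SmallRNARead], libraries: list[str] | None = None) -> pd.DataFrame:
    """Unique-read count table: rows = sequences, one column per library."""
    if libraries is None:
        libraries = sorted({lib for r in reads for lib in r.counts})
    rows = {r.sequence: [r.counts.get(lib, 0) for lib in libraries] for r in reads}
    return pd.DataFrame.from_dict(rows, orient="index", columns=libraries).rename_axis("sequence")
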