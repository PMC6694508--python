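"""Non-additive (mid-parent-value) expression analysis of the F1 hybrid.

Under purely additive inheritance the hybrid should express each miRNA at
the mid-parent value (MPV), the mean of the two parental levels.  A miRNA is
called non-additively expressed when its F1 level deviates from the MPV more
than two-fold with P <= 0.05 (strict fold inequalities); down-regulated
calls are further partitioned by which parent expressed the miRNA more
highly, the three-way pattern the downstream summaries report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from polymir.quantify import PSEUDO_TPM, de_test


def mid_parent_value(tpm_parent1: float, tpm_parent2: float) -> float:
    """Arithmetic mean of the two parental expression values."""
    if tpm_parent1 < 0 or tpm_parent2 < 0:
        raise ValueError("TPM values must be non-negative")
    return (tpm_parent1 + tpm_parent2) / 2.0


@dataclass
class NonAdditiveCall:
    mirna_id: str
    mpv: float
    f1_tpm: float
    fold: float  # (F1 + c) / (MPV + c)
    pvalue: float
    call: str  # additive | nonadditive_up | nonadditive_down
    pattern: str = ""  # parent1_higher | parent2_higher | equal (down calls only)
    flagged_absent: bool = False


def call_nonadditive(
    counts: pd.DataFrame,
    libraries: dict[str, list[str]],
    fold_threshold: float = 2.0,
    p_max: float = 0.05,
    pattern_log2_threshold: float = 1.0,
) -> pd.DataFrame:
    """Classify every miRNA as additive or non-additive versus the MPV.

    ``counts`` is the raw count matrix; ``libraries`` maps sample names
    ("parent1", "parent2", "f1") to replicate columns.  The F1 pooled counts
    are tested against the pooled parental counts (whose rate over the summed
    parental totals is the additive expectation) with the exact count test;
    fold change is computed on replicate-mean TPMs with the 0.5 pseudocount.
    Strict inequalities: fold exactly 2 stays additive.
    """
    p1, p2, f1 = (libraries[k] for k in ("parent1", "parent2", "f1"))
    totals = counts.sum(axis=0).astype(float)

    def mean_tpm(cols: list[str]) -> pd.Series:
        t = counts[cols].div(totals[cols], axis=1) * 1e6
        return t.mean(axis=1)

    tpm1, tpm2, tpmf = mean_tpm(p1), mean_tpm(p2), mean_tpm(f1)
    tot_par = totals[p1 + p2].to_numpy()
    tot_f1 = totals[f1].to_numpy()
    rows = []
    for mid in counts.index:
        mpv = mid_parent_value(float(tpm1[mid]), float(tpm2[mid]))
        f1v = float(tpmf[mid])
        fold = (f1v + PSEUDO_TPM) / (mpv + PSEUDO_TPM)
        par_counts = counts.loc[mid, p1 + p2].to_numpy()
        f1_counts = counts.loc[mid, f1].to_numpy()
        p, _ = de_test(par_counts, f1_counts, tot_par, tot_f1)
        if fold > fold_threshold and p <= p_max:
            call = "nonadditive_up"
        elif fold < 1.0 / fold_threshold and p <= p_max:
            call = "nonadditive_down"
        else:
            call = "additive"
        pattern = ""
        if call == "nonadditive_down":
            pattern = _pattern(float(tpm1[mid]), float(tpm2[mid]), pattern_log2_threshold)
        rows.append(
            dict(
                mirna_id=mid,
                mpv=mpv,
                f1_tpm=f1v,
                fold=fold,
                pvalue=p,
                call=call,
                pattern=pattern,
                flagged_absent=bool((tpm1[mid] == 0) and (tpm2[mid] == 0) and (f1v == 0)),
            )
        )
    return pd.DataFrame(rows)


def _pattern(tpm1: float, tpm2: float, t: float) -> str:
    ratio = np.log2((tpm1 + PSEUDO_TPM) / (tpm2 + PSEUDO_TPM))
    if ratio > t:
        return "parent1_higher"
    if ratio < -t:
        return "parent2_higher"
    return "equal"


def pattern_partition(
    down_calls: pd.DataFrame,
    parental_tpm: pd.DataFrame | None = None,
    equal_log2_threshold: float = 1.0,
) -> tuple[pd.Series, dict[str, int]]:
    """Three-way parental-pattern partition of the down-regulated set.

    If ``parental_tpm`` (columns parent1, parent2 indexed by mirna_id) is
    given, patterns are recomputed from it; otherwise the ``pattern`` column
    of ``down_calls`` is used.  Returns (per-miRNA pattern, class counts);
    the three classes always partition the input.
    """
    if parental_tpm is not None:
        pat = pd.Series(
            [
                _pattern(
                    float(parental_tpm.loc[mid, "parent1"]),
                    float(parental_tpm.loc[mid, "parent2"]),
                    equal_log2_threshold,
                )
                for mid in down_calls["mirna_id"]
            ],
            index=down_calls["mirna_id"],
        )
    else:
        pat = down_calls.set_index("mirna_id")["pattern"]
    counts = {
        cls: int((pat == cls).sum())
        for cls in ("parent1_higher", "parent2_higher", "equal")
    }
    return pat, counts


def summarize_nonadditive(calls: pd.DataFrame) -> dict[str, object]:
    """Summary counts: up, down, total (= up + down) and the down-set patterns."""
    n_up = int((calls["call"] == "nonadditive_up").sum())
    n_down = int((calls["call"] == "nonadditive_down").sum())
    down = calls[calls["call"] == "nonadditive_down"]
    patterns = {
        cls: int((down["pattern"] == cls).sum())
        for cls in ("parent1_higher", "parent2_higher", "equal")
    }
    return {"up": n_up, "down": n_down, "total": n_up + n_down, "pattern": patterns}
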