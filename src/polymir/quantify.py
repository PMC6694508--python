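"""Expression quantification and differential-expression calling.

Counts are normalized to transcripts per million (TPM).  The two-group test
is an exact count comparison in the Audic-Claverie tradition: replicates on
each side are pooled, and the split of the pooled counts between the two
sides is compared against the split expected from the library totals with a
two-sided exact binomial test.  Differential calls apply the thresholds
|log2FC| > 1 with FDR < 0.001 and P < 0.01, stated relative to a named
control sample.  Sample similarity uses Pearson correlation and Euclidean
distance of log10(TPM + 1) vectors, and the comparative-CT helper implements
the 2^-ddCT fold-change formula used for qRT-PCR validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

PSEUDO_TPM = 0.5


def tpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """TPM(i, lib) = count / library total * 1e6; zero-total columns stay zero."""
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    totals = counts.sum(axis=0).astype(float)
    zero = totals == 0
    if zero.any():
        import warnings

        warnings.warn(f"libraries with zero total counts: {list(counts.columns[zero])}")
        totals = totals.replace(0, np.nan)
    tpm = counts.div(totals, axis=1) * 1e6
    return tpm.fillna(0.0)


def _minlike_pvalue(pmf: np.ndarray, x: int) -> float:
    """Two-sided exact p: total probability of outcomes no more likely than x."""
    return float(min(1.0, pmf[pmf <= pmf[x] * (1.0 + 1e-10)].sum()))


def de_test(
    counts_a: np.ndarray | list[int],
    counts_b: np.ndarray | list[int],
    totals_a: np.ndarray | list[int],
    totals_b: np.ndarray | list[int],
    dispersion: float = 0.0,
) -> tuple[float, float]:
    """Exact two-sided count comparison of pooled replicates.

    Returns (p, log2FC) where log2FC = log2((TPM_b + c) / (TPM_a + c)) with a
    pseudocount of 0.5 TPM, i.e. positive when side B is higher.  The p-value
    conditions on the pooled total x_a + x_b and asks whether its split is
    compatible with the library-size split: with ``dispersion`` 0 this is the
    two-sided minimum-likelihood exact binomial (Audic-Claverie style); with
    a negative-binomial dispersion > 0 the conditional law of the split is
    beta-binomial (the conditional of one NB given the sum of two), matched
    to the library-size proportion, which keeps the test calibrated on
    overdispersed replicates.  Both sides zero gives p = 1, log2FC = 0.
    """
    xa = int(np.sum(counts_a))
    xb = int(np.sum(counts_b))
    na = float(np.sum(totals_a))
    nb = float(np.sum(totals_b))
    if na <= 0 or nb <= 0:
        raise ValueError("library totals must be positive")
    tpm_a = xa / na * 1e6
    tpm_b = xb / nb * 1e6
    lfc = float(np.log2((tpm_b + PSEUDO_TPM) / (tpm_a + PSEUDO_TPM)))
    n = xa + xb
    if n == 0:
        return 1.0, 0.0
    p0 = na / (na + nb)
    k = np.arange(n + 1)
    if dispersion > 0:
        m = np.size(counts_a) + np.size(counts_b)  # pooled replicates
        nu = m / dispersion
        pmf = stats.betabinom.pmf(k, n, p0 * nu, (1.0 - p0) * nu)
    else:
        pmf = stats.binom.pmf(k, n, p0)
    return _minlike_pvalue(pmf, xa), lfc


def estimate_common_dispersion(counts: pd.DataFrame, groups: list[list[str]]) -> float:
    """Pooled method-of-moments NB dispersion across genes and replicate groups.

    Solves var = mu + phi * mu^2 by pooling (s^2 - m) over m^2 across all
    genes with at least two replicates in a group; clipped at zero.
    """
    num = 0.0
    den = 0.0
    for cols in groups:
        if len(cols) < 2:
            continue
        x = counts[cols].to_numpy(dtype=float)
        m = x.mean(axis=1)
        s2 = x.var(axis=1, ddof=1)
        keep = m > 0
        num += float((s2[keep] - m[keep]).sum())
        den += float((m[keep] ** 2).sum())
    if den <= 0:
        return 0.0
    return max(0.0, num / den)


def bh_fdr(pvalues: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone by construction)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEResult:
    mirna_id: str
    contrast: tuple[str, str]  # (control, case)
    log2fc: float
    pvalue: float
    fdr: float
    call: str = "unchanged"  # up | down | unchanged, relative to control


def de_contrast(
    counts: pd.DataFrame,
    libraries: dict[str, list[str]],
    control: str,
    case: str,
    dispersion: float | str = "auto",
) -> pd.DataFrame:
    """Run the exact test for every miRNA in a control-vs-case contrast.

    ``libraries`` maps sample name -> its replicate column names in
    ``counts``.  With ``dispersion="auto"`` a common negative-binomial
    dispersion is estimated from the within-sample replicate scatter and the
    overdispersion-aware test is used; pass 0.0 to force the plain binomial.
    Returns a DataFrame (mirna_id, log2fc, pvalue, fdr, call) with calls made
    by :func:`call_de` at the default thresholds.
    """
    cols_a = libraries[control]
    cols_b = libraries[case]
    if dispersion == "auto":
        dispersion = estimate_common_dispersion(counts, [cols_a, cols_b])
    tot_a = counts[cols_a].sum(axis=0).to_numpy()
    tot_b = counts[cols_b].sum(axis=0).to_numpy()
    rows = []
    for mid, row in counts.iterrows():
        p, lfc = de_test(
            row[cols_a].to_numpy(), row[cols_b].to_numpy(), tot_a, tot_b,
            dispersion=float(dispersion),
        )
        rows.append((mid, lfc, p))
    df = pd.DataFrame(rows, columns=["mirna_id", "log2fc", "pvalue"])
    df["fdr"] = bh_fdr(df["pvalue"].to_numpy())
    df["call"] = call_de(df)["call"]
    df.insert(1, "control", control)
    df.insert(2, "case", case)
    return df


def call_de(
    results: pd.DataFrame,
    min_abs_log2fc: float = 1.0,
    fdr_max: float = 0.001,
    p_max: float = 0.01,
) -> pd.DataFrame:
    """Apply the fold-change/FDR/P thresholds; strict inequalities throughout.

    Expects columns log2fc, pvalue, fdr; returns a copy with a ``call``
    column (up/down/unchanged relative to the control).
    """
    out = results.copy()
    sig = (out["fdr"] < fdr_max) & (out["pvalue"] < p_max)
    call = np.where(
        sig & (out["log2fc"] > min_abs_log2fc),
        "up",
        np.where(sig & (out["log2fc"] < -min_abs_log2fc), "down", "unchanged"),
    )
    out["call"] = call
    return out


def de_summary(calls: pd.DataFrame) -> dict[str, int]:
    """(n_up, n_down, n_total) with total defined as up + down."""
    n_up = int((calls["call"] == "up").sum())
    n_down = int((calls["call"] == "down").sum())
    return {"up": n_up, "down": n_down, "total": n_up + n_down}


@dataclass
class CorrelationResult:
    r: float | None
    defined: bool
    reason: str = ""


def sample_correlation(tpm: pd.DataFrame, pair: tuple[str, str]) -> CorrelationResult:
    """Pearson r of log10(TPM + 1) between two libraries/samples."""
    a = np.log10(tpm[pair[0]].to_numpy(dtype=float) + 1.0)
    b = np.log10(tpm[pair[1]].to_numpy(dtype=float) + 1.0)
    if np.std(a) == 0 or np.std(b) == 0:
        return CorrelationResult(None, False, "zero-variance vector")
    return CorrelationResult(float(np.corrcoef(a, b)[0, 1]), True)


def euclidean_cluster(tpm: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Euclidean distances between sample columns of log10(TPM+1), plus an
    average-linkage merge tree (scipy linkage matrix)."""
    if tpm.shape[1] < 2:
        raise ValueError("need at least two samples to cluster")
    x = np.log10(tpm.to_numpy(dtype=float).T + 1.0)
    d = pdist(x, metric="euclidean")
    dm = pd.DataFrame(squareform(d), index=tpm.columns, columns=tpm.columns)
    tree = linkage(d, method="average")
    return dm, tree


def comparative_ct(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative fold change by the comparative-CT method: 2^-ddCT."""
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))
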