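"""TPM normalization, the exact count test (with its enumeration oracle),
FDR control, DE calling thresholds, correlation and clustering."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polymir.quantify import (
    bh_fdr,
    call_de,
    comparative_ct,
    de_summary,
    de_test,
    estimate_common_dispersion,
    euclidean_cluster,
    sample_correlation,
    tpm_normalize,
)


class TestTPM:
    def test_equal_counts_split_the_million(self):
        tpm = tpm_normalize(pd.DataFrame({"lib": [5, 5]}))
        assert tpm["lib"].tolist() == [500_000.0, 500_000.0]

    def test_columns_sum_to_one_million(self, rng):
        counts = pd.DataFrame(rng.integers(0, 100, (50, 4)), columns=list("abcd"))
        counts += 1  # avoid an all-zero column
        tpm = tpm_normalize(counts)
        assert np.allclose(tpm.sum(axis=0), 1e6, rtol=1e-9)

    def test_single_count_in_a_million(self):
        counts = pd.DataFrame({"lib": [1, 10**6 - 1]})
        assert tpm_normalize(counts)["lib"].iloc[0] == pytest.approx(1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            tpm_normalize(pd.DataFrame({"lib": [-1, 5]}))

    def test_zero_total_library_warns_and_stays_zero(self):
        with pytest.warns(UserWarning):
            tpm = tpm_normalize(pd.DataFrame({"a": [1, 2], "b": [0, 0]}))
        assert tpm["b"].tolist() == [0.0, 0.0]


def binomial_minlike_oracle(xa: int, n: int, p0: float) -> float:
    """Exhaustive summation over the outcome space with explicit pmf."""
    pmf = [math.comb(n, k) * p0**k * (1 - p0) ** (n - k) for k in range(n + 1)]
    return min(1.0, sum(q for q in pmf if q <= pmf[xa] * (1 + 1e-10)))


class TestDeTest:
    def test_identical_counts_give_p_one_and_zero_lfc(self):
        p, lfc = de_test([10, 10], [10, 10], [1000, 1000], [1000, 1000])
        assert p == pytest.approx(1.0)
        assert lfc == 0.0

    def test_extreme_split_is_overwhelming(self):
        p, lfc = de_test([0], [100], [10**6], [10**6])
        assert p < 1e-20
        assert abs(lfc) > 6

    def test_both_zero(self):
        assert de_test([0], [0], [100], [100]) == (1.0, 0.0)

    def test_p_matches_exhaustive_oracle_for_small_pooled_counts(self):
        totals = ([1000], [3000])
        for n in range(0, 51, 5):
            for xa in range(0, n + 1, max(1, n // 7)):
                p, _ = de_test([xa], [n - xa], *totals)
                assert p == pytest.approx(
                    binomial_minlike_oracle(xa, n, 0.25), rel=1e-9
                ), (xa, n)

    def test_overdispersed_mode_is_less_extreme(self):
        args = ([30, 25, 35], [5, 10, 6], [1000] * 3, [1000] * 3)
        p_plain, _ = de_test(*args, dispersion=0.0)
        p_nb, _ = de_test(*args, dispersion=0.2)
        assert p_nb > p_plain

    def test_dispersion_estimator_recovers_truth(self, rng):
        mu, phi = 50.0, 0.15
        x = rng.negative_binomial(1 / phi, (1 / phi) / (1 / phi + mu), (3000, 6))
        counts = pd.DataFrame(x, columns=[f"c{i}" for i in range(6)])
        est = estimate_common_dispersion(counts, [list(counts.columns[:3]), list(counts.columns[3:])])
        assert est == pytest.approx(phi, rel=0.25)


class TestFDR:
    def test_single_p(self):
        assert bh_fdr([0.04]) == pytest.approx([0.04])

    def test_hand_computed_sequence(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_monotone_in_sorted_order(self, ps):
        fdr = bh_fdr(ps)
        order = np.argsort(ps)
        assert np.all(np.diff(fdr[order]) >= -1e-12)
        assert np.all((fdr >= 0) & (fdr <= 1))


class TestCallDE:
    @pytest.mark.parametrize(
        "n_up,n_down,total", [(13, 23, 36), (70, 85, 155), (85, 87, 172)]
    )
    def test_summary_totals(self, n_up, n_down, total):
        df = pd.DataFrame(
            dict(
                log2fc=[2.0] * n_up + [-2.0] * n_down + [0.1] * 5,
                pvalue=[1e-6] * (n_up + n_down) + [0.5] * 5,
                fdr=[1e-5] * (n_up + n_down) + [0.8] * 5,
            )
        )
        s = de_summary(call_de(df))
        assert (s["up"], s["down"], s["total"]) == (n_up, n_down, total)

    def test_thresholds_are_strict(self):
        df = pd.DataFrame(dict(log2fc=[1.0, 1.01], pvalue=[1e-6] * 2, fdr=[1e-5] * 2))
        calls = call_de(df)["call"].tolist()
        assert calls == ["unchanged", "up"]

    def test_significance_gates(self):
        df = pd.DataFrame(
            dict(log2fc=[3.0, 3.0, 3.0], pvalue=[0.5, 1e-6, 1e-6], fdr=[1e-5, 0.5, 1e-5])
        )
        assert call_de(df)["call"].tolist() == ["unchanged", "unchanged", "up"]


class TestSimilarity:
    def test_identical_columns_correlate_perfectly(self):
        tpm = pd.DataFrame({"a": [1.0, 10.0, 100.0], "b": [1.0, 10.0, 100.0]})
        assert sample_correlation(tpm, ("a", "b")).r == pytest.approx(1.0)

    def test_log_affine_columns_correlate_perfectly(self):
        a = np.array([1.0, 10.0, 100.0, 1000.0])
        tpm = pd.DataFrame({"a": a, "b": (a + 1.0) ** 2 * 10 - 1.0})
        assert sample_correlation(tpm, ("a", "b")).r == pytest.approx(1.0)

    def test_zero_variance_is_flagged_not_nan(self):
        tpm = pd.DataFrame({"a": [1.0, 2.0], "b": [5.0, 5.0]})
        res = sample_correlation(tpm, ("a", "b"))
        assert not res.defined and res.r is None

    def test_matches_direct_formula(self, rng):
        tpm = pd.DataFrame(rng.uniform(0, 1000, (50, 2)), columns=["a", "b"])
        x, y = np.log10(tpm["a"] + 1), np.log10(tpm["b"] + 1)
        direct = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert sample_correlation(tpm, ("a", "b")).r == pytest.approx(float(direct))

    def test_duplicate_samples_have_zero_distance(self):
        tpm = pd.DataFrame({"a": [1.0, 50.0], "b": [1.0, 50.0], "c": [9.0, 0.0]})
        dm, _ = euclidean_cluster(tpm)
        assert dm.loc["a", "b"] == pytest.approx(0.0)

    def test_pythagorean_distance(self):
        # log10(TPM+1) vectors are (0, 0) and (3, 4): distance 5
        tpm = pd.DataFrame({"a": [0.0, 0.0], "b": [999.0, 9999.0]})
        dm, _ = euclidean_cluster(tpm)
        assert dm.loc["a", "b"] == pytest.approx(5.0)

    def test_single_sample_raises(self):
        with pytest.raises(ValueError):
            euclidean_cluster(pd.DataFrame({"a": [1.0]}))


class TestComparativeCT:
    @pytest.mark.parametrize(
        "case,expected",
        [((20, 18, 22, 20), 1.0), ((21, 18, 22, 20), 0.5), ((20, 20, 22, 20), 4.0)],
    )
    def test_fold_change_definition(self, case, expected):
        assert comparative_ct(*case) == pytest.approx(expected)
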