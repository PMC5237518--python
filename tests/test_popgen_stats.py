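"""Diversity-statistic correctness against independent oracles and closed forms."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evopool.popgen_stats import (
    TajimaConstants,
    mean_pairwise_fst,
    minor_counts_from_freqs,
    per_snp_fst,
    pi_from_counts,
    sfs,
    site_heterozygosity,
    tajima_d_components,
    window_pi_theta_d,
    windowed_heterozygosity,
)


def brute_force_pi(haplotypes: np.ndarray) -> float:
    """Average pairwise Hamming distance over all haplotype pairs (oracle)."""
    n = haplotypes.shape[0]
    total = sum(
        np.sum(haplotypes[i] != haplotypes[j])
        for i, j in itertools.combinations(range(n), 2)
    )
    return total / (n * (n - 1) / 2)


class TestTajimaConstants:
    def test_against_symbolic_evaluation(self):
        """Constants agree with an exact-fraction evaluation of the classic formulas."""
        from fractions import Fraction

        for n in (3, 5, 10, 60):
            a1 = sum(Fraction(1, i) for i in range(1, n))
            a2 = sum(Fraction(1, i * i) for i in range(1, n))
            b1 = Fraction(n + 1, 3 * (n - 1))
            b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
            c1 = b1 - 1 / a1
            c2 = b2 - Fraction(n + 2, n) / a1 + a2 / a1**2
            e1 = c1 / a1
            e2 = c2 / (a1**2 + a2)
            c = TajimaConstants.from_n(n)
            assert c.a1 == pytest.approx(float(a1), rel=1e-12)
            assert c.e1 == pytest.approx(float(e1), rel=1e-12)
            assert c.e2 == pytest.approx(float(e2), rel=1e-12)

    def test_degenerate_pair_sample(self):
        c = TajimaConstants.from_n(2)
        assert c.e1 == pytest.approx(0.0, abs=1e-12)
        assert c.e2 == pytest.approx(0.0, abs=1e-12)

    def test_rejects_singleton(self):
        with pytest.raises(ValueError):
            TajimaConstants.from_n(1)


class TestSiteHeterozygosity:
    @pytest.mark.parametrize("p,expected", [(0.5, 0.5), (0.0, 0.0), (1.0, 0.0), (0.1, 0.18)])
    def test_known_values(self, p, expected):
        assert site_heterozygosity(p) == pytest.approx(expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            site_heterozygosity(1.5)


class TestPi:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        n=st.integers(3, 8),
        n_sites=st.integers(1, 20),
        seed=st.integers(0, 10_000),
    )
    def test_counting_formula_matches_brute_force(self, n, n_sites, seed):
        """pi from allele counts equals the average pairwise Hamming distance."""
        rng = np.random.default_rng(seed)
        hap = rng.integers(0, 2, size=(n, n_sites)).astype(np.uint8)
        counts = hap.sum(axis=0)
        assert pi_from_counts(counts, n) == pytest.approx(brute_force_pi(hap), rel=1e-12)


class TestTajimaD:
    def test_no_segregating_sites_flagged(self):
        c = TajimaConstants.from_n(10)
        S, pi, theta, D = tajima_d_components(np.array([0, 0, 10]), c)
        assert S == 0 and pi == 0 and theta == 0 and np.isnan(D)

    def test_pair_sample_flagged(self):
        """n=2 with one segregating site: pi = theta = 1, variance 0, D undefined."""
        c = TajimaConstants.from_n(2)
        S, pi, theta, D = tajima_d_components(np.array([1]), c)
        assert S == 1 and pi == pytest.approx(1.0) and theta == pytest.approx(1.0)
        assert np.isnan(D)

    def test_against_independent_evaluation(self, rng):
        """D for a constructed 10-haplotype sample equals a from-scratch evaluation."""
        hap = rng.integers(0, 2, size=(10, 40)).astype(np.uint8)
        counts = hap.sum(axis=0)
        c = TajimaConstants.from_n(10)
        S, pi, theta, D = tajima_d_components(counts, c)
        # independent path: brute-force pi, explicit harmonic sums
        n = 10
        a1 = sum(1 / i for i in range(1, n))
        seg = counts[(counts > 0) & (counts < n)]
        S_o = len(seg)
        pi_o = brute_force_pi(hap[:, (counts > 0) & (counts < n)])
        theta_o = S_o / a1
        a2 = sum(1 / i**2 for i in range(1, n))
        b1, b2 = (n + 1) / (3 * (n - 1)), 2 * (n * n + n + 3) / (9 * n * (n - 1))
        c1, c2 = b1 - 1 / a1, b2 - (n + 2) / (a1 * n) + a2 / a1**2
        D_o = (pi_o - theta_o) / np.sqrt(c1 / a1 * S_o + c2 / (a1**2 + a2) * S_o * (S_o - 1))
        assert S == S_o
        assert pi == pytest.approx(pi_o, rel=1e-12)
        assert theta == pytest.approx(theta_o, rel=1e-12)
        assert D == pytest.approx(D_o, rel=1e-12)

    def test_sign_matches_pi_minus_theta(self, rng):
        c = TajimaConstants.from_n(20)
        for _ in range(20):
            counts = rng.integers(1, 20, size=rng.integers(2, 30))
            S, pi, theta, D = tajima_d_components(counts, c)
            if np.isfinite(D) and pi != theta:
                assert np.sign(D) == np.sign(pi - theta)


class TestWindowedStats:
    def test_single_snp_heterozygosity(self):
        df = windowed_heterozygosity([250_000], [0.5], chrom_length=500_000)
        covering = df[(df.start <= 250_000) & (df.end > 250_000)]
        assert np.allclose(covering.H, 0.5)

    def test_two_snp_window_mean(self):
        df = windowed_heterozygosity([100, 200], [0.5, 0.1], window=100_000, step=100_000)
        assert df.iloc[0].H == pytest.approx(0.34)

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            windowed_heterozygosity([200, 100], [0.5, 0.5])

    def test_windowed_means_match_brute_force(self, rng):
        """Windowed H equals a direct recomputation per window (oracle)."""
        pos = np.sort(rng.choice(1_000_000, size=1000, replace=False)) + 1
        p = rng.uniform(0.01, 0.99, size=1000)
        window, step = 100_000, 10_000
        df = windowed_heterozygosity(pos, p, window=window, step=step, chrom_length=1_000_000)
        for _, row in df.sample(20, random_state=0).iterrows():
            mask = (pos >= row.start) & (pos < row.end)
            if mask.sum():
                assert row.H == pytest.approx(np.mean(2 * p[mask] * (1 - p[mask])), rel=1e-12)
                assert row.n_sites == mask.sum()
            else:
                assert np.isnan(row.H)

    def test_chunking_invariance(self, rng):
        """Statistics are identical whether sites arrive whole or in two chunks."""
        pos = np.sort(rng.choice(200_000, size=400, replace=False)) + 1
        counts = rng.integers(1, 50, size=400)
        whole = window_pi_theta_d(pos, counts, n=50, window=10_000, chrom_length=200_000)
        cut = 200
        left = window_pi_theta_d(pos[:cut], counts[:cut], n=50, window=10_000, chrom_length=200_000)
        right = window_pi_theta_d(pos[cut:], counts[cut:], n=50, window=10_000, chrom_length=200_000)
        recombined = left.set_index("start")[["S", "pi"]].add(
            right.set_index("start")[["S", "pi"]], fill_value=0
        )
        merged = whole.set_index("start")[["S", "pi"]]
        pd.testing.assert_frame_equal(
            merged, recombined.loc[merged.index].astype({"S": merged.S.dtype}), check_exact=False
        )


class TestFst:
    @pytest.mark.parametrize(
        "freqs,expected",
        [((0.0, 1.0), 1.0), ((0.3, 0.3), 0.0), ((0.2, 0.4), (0.42 - 0.40) / 0.42)],
    )
    def test_two_line_values(self, freqs, expected):
        rec = per_snp_fst(np.array(freqs).reshape(2, 1))
        assert rec.fst.iloc[0] == pytest.approx(expected)

    def test_undefined_when_ht_zero(self):
        rec = per_snp_fst(np.zeros((2, 1)))
        assert not rec.defined.iloc[0]

    def test_invariant_to_line_order(self, rng):
        f = rng.uniform(0, 1, size=(4, 50))
        a = per_snp_fst(f)["fst"]
        b = per_snp_fst(f[::-1])["fst"]
        np.testing.assert_allclose(a, b)

    def test_pairwise_table(self):
        f = np.array([[0.2, 0.5], [0.2, 0.5], [0.8, 0.5]])
        out = mean_pairwise_fst(f, ["a", "b", "c"])
        assert len(out) == 3
        ab = out[(out.line_a == "a") & (out.line_b == "b")].mean_fst.iloc[0]
        assert ab == pytest.approx(0.0)


class TestSfs:
    def test_all_intermediate_mass_in_top_bin(self):
        out = sfs([0.5] * 10, folded=True, bins=5)
        assert out["count"].iloc[-1] == 10
        assert out["count"].iloc[:-1].sum() == 0

    def test_empty_input(self):
        out = sfs([], bins=4)
        assert out["count"].sum() == 0

    def test_counts_sum_to_polymorphic_sites(self, rng):
        p = np.concatenate([rng.uniform(0, 1, 500), [0.0, 1.0]])
        out = sfs(p, bins=10)
        assert out["count"].sum() == np.sum((p > 0) & (p < 1))

    def test_rejects_too_few_bins(self):
        with pytest.raises(ValueError):
            sfs([0.5], bins=1)


class TestMinorCounts:
    def test_polymorphic_floor(self):
        counts = minor_counts_from_freqs([1e-5, 0.0, 0.5], 100)
        assert counts.tolist() == [1, 0, 50]
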