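"""Classic population-genetic diversity statistics for pooled lines and haplotype samples.

Implements the estimators of Tajima (1989) and Watterson (1975) plus expected
heterozygosity, per-SNP FST in the HT/HS form, and site-frequency spectra.
Windowed variants use half-open windows ``[start, start + window)`` on 1-based
coordinates, advancing by ``step``; the final partial window is kept and
flagged.  For pooled lines, allele counts are derived from pool allele
frequencies at a nominal sample size (optionally capped by read depth); for
simulator output, counts come directly from haplotype matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TajimaConstants",
    "site_heterozygosity",
    "windowed_heterozygosity",
    "minor_counts_from_freqs",
    "pi_from_counts",
    "tajima_d_components",
    "window_pi_theta_d",
    "per_snp_fst",
    "mean_pairwise_fst",
    "sfs",
]


@dataclass(frozen=True)
class TajimaConstants:
    """Normalising constants of Tajima's D for a sample of ``n`` haplotypes.

    With ``a1 = sum_{i<n} 1/i`` and ``a2 = sum_{i<n} 1/i**2``::

        b1 = (n+1) / (3(n-1))            c1 = b1 - 1/a1        e1 = c1/a1
        b2 = 2(n^2+n+3) / (9n(n-1))      c2 = b2 - (n+2)/(a1 n) + a2/a1^2
        e2 = c2 / (a1^2 + a2)

    For ``n = 2`` both ``e1`` and ``e2`` vanish and D is undefined.
    """

    n: int
    a1: float
    a2: float
    e1: float
    e2: float

    @classmethod
    def from_n(cls, n: int) -> "TajimaConstants":
        if n < 2:
            raise ValueError(f"sample size must be >= 2, got {n}")
        i = np.arange(1, n)
        a1 = float(np.sum(1.0 / i))
        a2 = float(np.sum(1.0 / i**2))
        b1 = (n + 1) / (3.0 * (n - 1))
        b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
        c1 = b1 - 1.0 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        return cls(n=n, a1=a1, a2=a2, e1=c1 / a1, e2=c2 / (a1**2 + a2))


def site_heterozygosity(p):
    """Expected heterozygosity ``2 p (1 - p)`` of a biallelic site."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    return 2.0 * p * (1.0 - p)


def _check_sorted(positions: np.ndarray) -> None:
    if positions.size > 1 and np.any(np.diff(positions) < 0):
        raise ValueError("site positions must be sorted in ascending order")


def _window_edges(lo: int, hi: int, window: int, step: int):
    """Window start positions covering [lo, hi] (1-based)."""
    start = 1
    starts = []
    while start <= hi:
        if start + window > lo:  # window overlaps data span
            starts.append(start)
        start += step
    return starts


def windowed_heterozygosity(
    positions: Sequence[int],
    freqs: Sequence[float],
    *,
    window: int = 100_000,
    step: int = 10_000,
    chrom_length: int | None = None,
    include_monomorphic: bool = False,
) -> pd.DataFrame:
    """Sliding-window mean expected heterozygosity.

    Each window's H is the mean of ``2p(1-p)`` over polymorphic sites
    (0 < p < 1) falling in ``[start, start + window)``; windows without
    polymorphic sites are flagged (``n_sites == 0``, ``H`` NaN) and should be
    excluded from downstream means.  With ``include_monomorphic`` every input
    site counts (fixed sites contribute 0) — the appropriate convention when
    tracking diversity loss over a fixed site set, e.g. hitchhiking around a
    sweep, where conditioning on surviving SNPs would bias H upward.
    """
    positions = np.asarray(positions, dtype=np.int64)
    freqs = np.asarray(freqs, dtype=float)
    _check_sorted(positions)
    hi = int(chrom_length) if chrom_length is not None else (int(positions[-1]) if positions.size else window)
    poly = np.ones(freqs.size, dtype=bool) if include_monomorphic else (freqs > 0) & (freqs < 1)
    pos_p, h_p = positions[poly], site_heterozygosity(freqs[poly])
    rows = []
    for start in _window_edges(positions[0] if positions.size else 1, hi, window, step):
        end = start + window
        i0, i1 = np.searchsorted(pos_p, [start, end])
        nsites = i1 - i0
        rows.append(
            {
                "start": start,
                "end": end,
                "n_sites": int(nsites),
                "H": float(np.mean(h_p[i0:i1])) if nsites else np.nan,
                "partial": end - 1 > hi,
            }
        )
    return pd.DataFrame(rows)


def minor_counts_from_freqs(freqs, n: int) -> np.ndarray:
    """Minor-allele counts at nominal sample size ``n`` from pool frequencies.

    Counts are ``round(p * n)`` folded to the minor allele, with a floor of 1
    for sites that are polymorphic in the pool (so a detected SNP never rounds
    to monomorphic).  Sites with p in {0, 1} yield count 0.
    """
    p = np.asarray(freqs, dtype=float)
    c = np.rint(p * n).astype(np.int64)
    c = np.minimum(c, n - c)
    poly = (p > 0) & (p < 1)
    c[poly] = np.maximum(c[poly], 1)
    c[~poly] = 0
    return c


def pi_from_counts(counts, n: int) -> float:
    """Mean pairwise differences: ``sum 2 i (n - i) / (n (n - 1))`` over sites."""
    i = np.asarray(counts, dtype=float)
    return float(np.sum(2.0 * i * (n - i) / (n * (n - 1))))


def tajima_d_components(counts, consts: TajimaConstants):
    """(S, pi, theta_W, D) for one collection of sites.

    ``counts`` are per-site alternate- or minor-allele counts in a sample of
    ``consts.n`` haplotypes; sites with count 0 or n are ignored.  D is NaN
    when S = 0 or the variance term is not positive (e.g. n = 2).
    """
    c = np.asarray(counts, dtype=np.int64)
    c = c[(c > 0) & (c < consts.n)]
    S = int(c.size)
    pi = pi_from_counts(c, consts.n)
    theta = S / consts.a1
    var = consts.e1 * S + consts.e2 * S * (S - 1)
    D = (pi - theta) / np.sqrt(var) if S > 0 and var > 0 else np.nan
    return S, pi, theta, D


def window_pi_theta_d(
    positions: Sequence[int],
    counts: Sequence[int] | None = None,
    *,
    haplotypes: np.ndarray | None = None,
    n: int | None = None,
    window: int = 10_000,
    step: int | None = None,
    chrom_length: int | None = None,
) -> pd.DataFrame:
    """Windowed segregating sites, pi, Watterson's theta and Tajima's D.

    Provide either per-site allele ``counts`` together with sample size ``n``,
    or a ``haplotypes`` matrix of shape (n_haplotypes, n_sites) from which
    counts are derived.  Non-overlapping windows by default (step = window).
    """
    positions = np.asarray(positions, dtype=np.int64)
    _check_sorted(positions)
    if haplotypes is not None:
        haplotypes = np.asarray(haplotypes)
        n = haplotypes.shape[0]
        counts = haplotypes.sum(axis=0)
    if n is None or counts is None:
        raise ValueError("provide counts and n, or a haplotype matrix")
    if n < 2:
        raise ValueError("sample size must be >= 2")
    counts = np.asarray(counts, dtype=np.int64)
    consts = TajimaConstants.from_n(int(n))
    step = step or window
    hi = int(chrom_length) if chrom_length is not None else (int(positions[-1]) if positions.size else window)
    rows = []
    for start in _window_edges(positions[0] if positions.size else 1, hi, window, step):
        end = start + window
        i0, i1 = np.searchsorted(positions, [start, end])
        S, pi, theta, D = tajima_d_components(counts[i0:i1], consts)
        rows.append(
            {
                "start": start,
                "end": end,
                "S": S,
                "pi": pi,
                "theta_w": theta,
                "D": D,
                "n_sites": int(i1 - i0),
                "partial": end - 1 > hi,
            }
        )
    return pd.DataFrame(rows)


def per_snp_fst(freq_matrix: np.ndarray) -> pd.DataFrame:
    """Per-site FST over a set of lines in the classic HT/HS form.

    ``freq_matrix`` has shape (n_lines, n_sites).  With ``p_bar`` the mean
    frequency across lines, ``HT = 2 p_bar (1 - p_bar)`` and ``HS`` the mean
    of within-line ``2 p_j (1 - p_j)``; ``FST = (HT - HS) / HT``.  Sites with
    HT = 0 are flagged undefined and excluded from averages.  Negative values
    are reported as computed.
    """
    f = np.asarray(freq_matrix, dtype=float)
    if f.ndim != 2 or f.shape[0] < 2:
        raise ValueError("freq_matrix must be (n_lines >= 2, n_sites)")
    pbar = f.mean(axis=0)
    ht = 2.0 * pbar * (1.0 - pbar)
    hs = (2.0 * f * (1.0 - f)).mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = (ht - hs) / ht
    defined = ht > 0
    return pd.DataFrame({"HT": ht, "HS": hs, "fst": np.where(defined, fst, np.nan), "defined": defined})


def mean_pairwise_fst(freqs: pd.DataFrame | np.ndarray, line_ids: Sequence[str]) -> pd.DataFrame:
    """Average per-SNP FST for every pair of lines.

    ``freqs`` is (n_lines, n_sites) in the order of ``line_ids``.  Returns one
    row per unordered pair with the mean FST over sites where it is defined.
    """
    f = np.asarray(freqs, dtype=float)
    rows = []
    for a in range(len(line_ids)):
        for b in range(a + 1, len(line_ids)):
            rec = per_snp_fst(f[[a, b]])
            rows.append(
                {
                    "line_a": line_ids[a],
                    "line_b": line_ids[b],
                    "mean_fst": float(rec.loc[rec.defined, "fst"].mean()),
                    "n_sites": int(rec.defined.sum()),
                }
            )
    return pd.DataFrame(rows)


def sfs(freqs, *, folded: bool = True, bins: int = 20) -> pd.DataFrame:
    """Site-frequency spectrum: histogram of allele frequencies.

    Folded (default): minor-allele frequencies binned over (0, 0.5] in
    ``bins`` equal-width bins.  Unfolded: alternate-allele frequencies over
    (0, 1).  Monomorphic sites are excluded; counts sum to the number of
    polymorphic sites.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    p = np.asarray(freqs, dtype=float)
    p = p[(p > 0) & (p < 1)]
    if folded:
        p = np.minimum(p, 1.0 - p)
        edges = np.linspace(0.0, 0.5, bins + 1)
    else:
        edges = np.linspace(0.0, 1.0, bins + 1)
    # right-closed bins so a folded frequency of exactly 0.5 lands in the top bin
    counts, _ = np.histogram(-p, bins=-edges[::-1])
    counts = counts[::-1]
    return pd.DataFrame({"bin_lo": edges[:-1], "bin_hi": edges[1:], "count": counts})
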