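"""Coding-sequence selection tests and sweep-interval summaries.

Ka/Ks follows Nei & Gojobori (1986): per-codon synonymous site fractions
from the standard genetic code, observed differences classified per codon
with equal averaging over all mutational pathways for multi-difference
codons, and an optional Jukes-Cantor correction.  The McDonald-Kreitman
test contrasts nonsynonymous/synonymous counts in polymorphism vs divergence
with Fisher's exact test.  Sweep intervals (as called by an external
HMM-based detector) are merged per line and summarised per group:
mean length +/- SEM and the base-pair intersection shared by all lines of a
group.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from scipy.stats import fisher_exact

__all__ = [
    "KaKsResult",
    "MKTable",
    "MKResult",
    "nei_gojobori",
    "mk_test",
    "sweep_summary",
    "merge_intervals",
    "intersect_intervals",
]

_CODON_AA = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)
_BASES = "ACGT"


def _aa(codon: str):
    return "*" if codon in _STOPS else _CODON_AA[codon]


def _syn_fraction(codon: str) -> float:
    """Number of synonymous sites in a codon (changes to stop count as nonsynonymous)."""
    syn = 0.0
    for i in range(3):
        s = 0
        for b in _BASES:
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1:]
            if alt not in _STOPS and _aa(alt) == _aa(codon):
                s += 1
        syn += s / 3.0
    return syn


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(nonsyn, syn) differences averaged over all mutational pathways c1 -> c2.

    Pathways passing through a stop codon are excluded; if every pathway is
    blocked, all are used regardless (degenerate but defined).
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(diff):
        cur = c1
        steps = []
        ok = True
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1:]
            steps.append((cur, nxt))
            if nxt in _STOPS:
                ok = False
            cur = nxt
        pathways.append((ok, steps))
    usable = [steps for ok, steps in pathways if ok] or [steps for _, steps in pathways]
    nd = sd = 0.0
    for steps in usable:
        for a, b in steps:
            if _aa(a) == _aa(b):
                sd += 1
            else:
                nd += 1
    return nd / len(usable), sd / len(usable)


@dataclass(frozen=True)
class KaKsResult:
    n_sites: float
    s_sites: float
    nd: float
    sd: float
    ka: float
    ks: float
    ratio: float | None  # None when Ks undefined or zero

    @property
    def defined(self) -> bool:
        return self.ratio is not None


def nei_gojobori(cds_a: str, cds_b: str, jukes_cantor: bool = False) -> KaKsResult:
    """Unweighted Nei-Gojobori Ka/Ks between two aligned coding sequences."""
    a, b = cds_a.upper(), cds_b.upper()
    if len(a) != len(b):
        raise ValueError("coding sequences differ in length")
    if len(a) % 3:
        raise ValueError("length is not a multiple of 3")
    n_codons = len(a) // 3
    s_sites = n_sites = nd = sd = 0.0
    for ci in range(n_codons):
        c1, c2 = a[3 * ci: 3 * ci + 3], b[3 * ci: 3 * ci + 3]
        for c in (c1, c2):
            if c in _STOPS:
                raise ValueError(f"internal stop codon at codon index {ci}")
        s1, s2 = _syn_fraction(c1), _syn_fraction(c2)
        s_sites += (s1 + s2) / 2.0
        n_sites += 3.0 - (s1 + s2) / 2.0
        dn, ds = _pathway_counts(c1, c2)
        nd += dn
        sd += ds
    pn = nd / n_sites if n_sites else 0.0
    ps = sd / s_sites if s_sites else 0.0
    if jukes_cantor:
        def jc(p):
            return -0.75 * np.log(1 - 4.0 * p / 3.0) if p < 0.75 else float("nan")
        ka, ks = jc(pn), jc(ps)
    else:
        ka, ks = pn, ps
    if sd == 0.0 and nd == 0.0:
        ratio = None  # identical (or fully saturated-synonymous-free) input: flagged, never a number
    elif ks == 0.0 or not np.isfinite(ks):
        ratio = None
    else:
        ratio = ka / ks
    return KaKsResult(n_sites, s_sites, nd, sd, ka, ks, ratio)


@dataclass(frozen=True)
class MKTable:
    """2x2 McDonald-Kreitman contingency table."""

    dn: int  # nonsynonymous fixed differences
    ds: int  # synonymous fixed differences
    pn: int  # nonsynonymous polymorphisms
    ps: int  # synonymous polymorphisms

    def __post_init__(self):
        if min(self.dn, self.ds, self.pn, self.ps) < 0:
            raise ValueError("MK counts must be non-negative")


@dataclass(frozen=True)
class MKResult:
    p_value: float
    neutrality_index: float | None  # (Pn/Ps)/(Dn/Ds); None on zero denominators


def mk_test(table: MKTable) -> MKResult:
    """Two-sided Fisher exact test of the MK table plus the neutrality index."""
    _, p = fisher_exact([[table.dn, table.ds], [table.pn, table.ps]], alternative="two-sided")
    if table.ps > 0 and table.ds > 0 and table.dn > 0:
        ni = (table.pn / table.ps) / (table.dn / table.ds)
    else:
        ni = None
    return MKResult(float(p), ni)


def merge_intervals(intervals) -> list[tuple[int, int]]:
    """Merge overlapping/touching half-open [start, end) intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    for s, e in ivs:
        if s >= e:
            raise ValueError("interval start must be < end")
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(m) for m in merged]


def intersect_intervals(a, b) -> list[tuple[int, int]]:
    """Intersection of two merged half-open interval lists."""
    out = []
    i = j = 0
    a, b = list(a), list(b)
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def sweep_summary(
    intervals: pd.DataFrame,
    groups=("selection", "control"),
    n_lines_per_group: int | None = None,
) -> pd.DataFrame:
    """Per-group per-chromosome sweep length summary.

    ``intervals`` needs columns line, group, chrom, start, end (half-open).
    Per line, intervals are merged before length computation; the shared
    region is the base-pair intersection of the per-line merged sets of the
    group's lines.  Returns mean_length, sem_length, total_length,
    shared_length per (group, chrom).
    """
    unknown = set(intervals["group"]) - set(groups)
    if unknown:
        raise ValueError(f"unknown group label(s): {sorted(unknown)}")
    rows = []
    for (grp, chrom), sub in intervals.groupby(["group", "chrom"]):
        per_line = {
            line: merge_intervals(zip(lsub["start"], lsub["end"]))
            for line, lsub in sub.groupby("line")
        }
        lengths = np.array(
            [e - s for ivs in per_line.values() for s, e in ivs], dtype=float
        )
        shared = None
        for ivs in per_line.values():
            shared = ivs if shared is None else intersect_intervals(shared, ivs)
        shared_len = sum(e - s for s, e in shared) if shared else 0
        # a line with no call on this chromosome contributes an empty set
        if n_lines_per_group is not None and len(per_line) < n_lines_per_group:
            shared_len = 0
        rows.append(
            {
                "group": grp,
                "chrom": chrom,
                "n_intervals": int(lengths.size),
                "mean_length": float(lengths.mean()) if lengths.size else 0.0,
                "sem_length": float(lengths.std(ddof=1) / np.sqrt(lengths.size))
                if lengths.size > 1
                else 0.0,
                "total_length": float(lengths.sum()),
                "shared_length": int(shared_len),
            }
        )
    return pd.DataFrame(rows)
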