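"""Pooled-VCF parsing, site filtering, and group-wise zygosity classification.

The filter chain reproduces the variant-level rules of the experimental
pipeline: biallelic SNPs only, per-line genotype quality above 30, per-line
depth within [10, 250], and no indel within 10 bp (boundary inclusive).  A
site failing any rule in any line is dropped globally so that all six lines
stay site-matched for FST and Tajima's D comparisons.  Removal counts are
attributed to the first failing rule in the order multiallelic -> quality ->
depth -> indel proximity; the surviving set itself is order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "VariantSite",
    "LineGroup",
    "parse_pooled_vcf",
    "apply_site_filters",
    "classify_sites_by_group",
    "sites_to_frame",
    "write_sync_tsv",
]

FILTER_ORDER = ("multiallelic", "quality", "depth", "indel_proximity")


@dataclass
class VariantSite:
    chrom: str
    pos: int                     # 1-based
    ref: str
    alt: str
    freqs: dict[str, float]      # per-line pool alternate-allele frequency
    depths: dict[str, int]
    quals: dict[str, float]      # per-line genotype quality (phred)
    is_indel: bool = False
    is_multiallelic: bool = False


@dataclass(frozen=True)
class LineGroup:
    """Disjoint, exhaustive partition of line ids into selection and control."""

    selection: tuple[str, ...]
    control: tuple[str, ...]

    def __post_init__(self):
        if set(self.selection) & set(self.control):
            raise ValueError("selection and control lines overlap")

    @property
    def all_lines(self) -> tuple[str, ...]:
        return tuple(self.selection) + tuple(self.control)

    @classmethod
    def default(cls) -> "LineGroup":
        return cls(selection=("L1", "L2", "L3"), control=("C1", "C2", "C3"))


def parse_pooled_vcf(paths, group: LineGroup) -> list[VariantSite]:
    """Read one multi-sample VCF or several per-line VCFs into VariantSites.

    Allele frequencies come from AD fields when present, else from the
    genotype call.  Indels and multiallelic records are retained and flagged;
    filtering is a separate stage.  Raises on unknown line ids.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    per_file: list[dict[tuple, VariantSite]] = []
    for path in paths:
        if not Path(path).exists():
            raise FileNotFoundError(str(path))
        vcf = VCF(str(path))
        samples = list(vcf.samples)
        unknown = set(samples) - set(group.all_lines)
        if unknown:
            raise ValueError(f"unknown line id(s) in {path}: {sorted(unknown)}")
        sites: dict[tuple, VariantSite] = {}
        for rec in vcf:
            key = (rec.CHROM, rec.POS, rec.REF, rec.ALT[0] if rec.ALT else ".")
            ad = rec.format("AD")
            dp = rec.format("DP")
            gq = rec.format("GQ")
            freqs, depths, quals = {}, {}, {}
            for i, line_id in enumerate(samples):
                if ad is not None:
                    ref_d, alt_d = int(ad[i][0]), int(ad[i][1])
                else:
                    ref_d = alt_d = 0
                if ref_d + alt_d > 0:
                    freqs[line_id] = alt_d / (ref_d + alt_d)
                else:  # fall back on the genotype call: hom-ref, het, hom-alt
                    freqs[line_id] = {0: 0.0, 1: 0.5, 3: 1.0}.get(int(rec.gt_types[i]), float("nan"))
                depths[line_id] = int(np.asarray(dp[i]).ravel()[0]) if dp is not None else ref_d + alt_d
                quals[line_id] = float(np.asarray(gq[i]).ravel()[0]) if gq is not None else (rec.QUAL or 0.0)
            sites[key] = VariantSite(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=rec.ALT[0] if rec.ALT else ".",
                freqs=freqs,
                depths=depths,
                quals=quals,
                is_indel=rec.is_indel,
                is_multiallelic=len(rec.ALT) > 1,
            )
        per_file.append(sites)

    merged: dict[tuple, VariantSite] = {}
    for sites in per_file:
        for key, site in sites.items():
            if key in merged:
                merged[key].freqs.update(site.freqs)
                merged[key].depths.update(site.depths)
                merged[key].quals.update(site.quals)
                merged[key].is_multiallelic |= site.is_multiallelic
            else:
                merged[key] = site
    return sorted(merged.values(), key=lambda s: (s.chrom, s.pos))


def apply_site_filters(
    sites: list[VariantSite],
    min_quality: float = 30.0,
    min_depth: int = 10,
    max_depth: int = 250,
    indel_margin: int = 10,
) -> tuple[list[VariantSite], dict[str, int]]:
    """Apply the site filters; returns (surviving SNPs, per-rule removal counts).

    A SNP survives iff it is biallelic, every line has genotype quality
    strictly greater than ``min_quality`` and depth within
    [min_depth, max_depth], and no indel breakpoint lies within
    ``indel_margin`` bp (inclusive).  Indel records themselves are consumed
    by the proximity rule and are not part of the output.
    """
    if min_quality <= 0 or min_depth <= 0 or max_depth <= 0:
        raise ValueError("thresholds must be positive")
    indel_pos: dict[str, np.ndarray] = {}
    for chrom in {s.chrom for s in sites}:
        pos = sorted(s.pos for s in sites if s.chrom == chrom and s.is_indel)
        indel_pos[chrom] = np.asarray(pos, dtype=np.int64)

    removed = {rule: 0 for rule in FILTER_ORDER}
    kept: list[VariantSite] = []
    for s in sites:
        if s.is_indel:
            continue
        if s.is_multiallelic:
            removed["multiallelic"] += 1
            continue
        if any(q <= min_quality for q in s.quals.values()):
            removed["quality"] += 1
            continue
        if any(d < min_depth or d > max_depth for d in s.depths.values()):
            removed["depth"] += 1
            continue
        near = indel_pos[s.chrom]
        if near.size:
            i = np.searchsorted(near, s.pos)
            dist = min(
                abs(s.pos - near[i - 1]) if i > 0 else np.inf,
                abs(near[i] - s.pos) if i < near.size else np.inf,
            )
            if dist <= indel_margin:
                removed["indel_proximity"] += 1
                continue
        kept.append(s)
    return kept, removed


def classify_sites_by_group(
    sites: list[VariantSite],
    group: LineGroup,
    het_bounds: tuple[float, float] = (0.0, 1.0),
) -> dict[str, int]:
    """Count sites by group-wise zygosity pattern of the pooled frequencies.

    A line is "heterozygous" at a site iff lo < p < hi and "fixed" iff p is
    exactly 0 or 1 (with default bounds: any polymorphism in the pool).
    """
    lo, hi = het_bounds
    counts = {
        "polymorphic": 0,
        "het_all_selection": 0,
        "het_all_control": 0,
        "fixed_selection_het_any_control": 0,
        "fixed_control_het_any_selection": 0,
        "alternatively_fixed": 0,
    }
    for s in sites:
        missing = [l for l in group.all_lines if l not in s.freqs]
        if missing:
            raise ValueError(f"site {s.chrom}:{s.pos} missing line(s) {missing}")
        p_sel = [s.freqs[l] for l in group.selection]
        p_ctl = [s.freqs[l] for l in group.control]
        het = lambda p: lo < p < hi
        fixed = lambda p: p == 0.0 or p == 1.0
        if any(het(p) for p in p_sel + p_ctl):
            counts["polymorphic"] += 1
        if all(het(p) for p in p_sel):
            counts["het_all_selection"] += 1
        if all(het(p) for p in p_ctl):
            counts["het_all_control"] += 1
        if all(fixed(p) for p in p_sel) and any(het(p) for p in p_ctl):
            counts["fixed_selection_het_any_control"] += 1
        if all(fixed(p) for p in p_ctl) and any(het(p) for p in p_sel):
            counts["fixed_control_het_any_selection"] += 1
        if (
            all(p == 1.0 for p in p_sel)
            and all(p == 0.0 for p in p_ctl)
            or all(p == 0.0 for p in p_sel)
            and all(p == 1.0 for p in p_ctl)
        ):
            counts["alternatively_fixed"] += 1
    return counts


def sites_to_frame(sites: list[VariantSite], lines) -> pd.DataFrame:
    """Tidy frame: chrom, pos, ref, alt plus one frequency/depth column per line."""
    rows = []
    for s in sites:
        row = {"chrom": s.chrom, "pos": s.pos, "ref": s.ref, "alt": s.alt}
        for line in lines:
            row[f"p_{line}"] = s.freqs.get(line, float("nan"))
            row[f"dp_{line}"] = s.depths.get(line, 0)
        rows.append(row)
    return pd.DataFrame(rows)


def write_sync_tsv(sites: list[VariantSite], lines, path) -> None:
    """Sync-style TSV: chrom, position, ref and per-line ref:alt read counts."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\t" + "\t".join(lines) + "\n")
        for s in sites:
            cells = []
            for line in lines:
                dp = s.depths.get(line, 0)
                alt = int(round(s.freqs.get(line, 0.0) * dp))
                cells.append(f"{dp - alt}:{alt}")
            fh.write(f"{s.chrom}\t{s.pos}\t{s.ref}\t" + "\t".join(cells) + "\n")
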