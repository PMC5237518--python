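"""Regional aggregation of window statistics and per-gene differential Tajima's D.

Windows are summarised by chromosome, by named/built-in regions (centromere
neighborhoods, low-recombination complexes, their complements) and by genomic
feature class.  Per gene, Tajima's D is computed over the gene span for each
line, averaged within the selection and control groups, and genes are ranked
by ``Diff_D = Selection_D - Control_D`` — the study's per-gene statistic for
an excess of intermediate-frequency variation in the selected lines.  Class
enrichment in the top of the ranking is tested with the hypergeometric upper
tail.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom

from .popgen_stats import TajimaConstants, minor_counts_from_freqs, tajima_d_components
from .synthetic_data import GeneRecord, GenomeLayout

logger = logging.getLogger(__name__)

FEATURE_PRECEDENCE = ("CDS", "5'UTR", "3'UTR", "intron", "promoter", "ncRNA", "intergenic")

__all__ = [
    "FeatureIndex",
    "assign_feature_class",
    "regional_summary",
    "percent_change",
    "gene_tajima_d",
    "class_enrichment",
    "builtin_regions",
]


class FeatureIndex:
    """Interval index over gene substructure for feature-class lookup.

    Promoters are the 1,000 bp (configurable) upstream of the transcription
    start, strand-aware: upstream of ``start`` for + genes, beyond ``end``
    for - genes.  Non-coding genes contribute an "ncRNA" interval over their
    span.  Precedence on overlap: CDS > UTR > intron > promoter > ncRNA >
    intergenic.
    """

    def __init__(self, genes: Sequence[GeneRecord], promoter_length: int = 1_000):
        self.trees: dict[str, dict[str, IntervalTree]] = {}
        self.promoter_length = promoter_length
        for g in genes:
            chrom = self.trees.setdefault(g.chrom, {})
            if g.gene_class == "protein_coding":
                for feat, s, e in g.substructure:
                    chrom.setdefault(feat, IntervalTree()).addi(s, e + 1, g.gene_id)
            else:
                chrom.setdefault("ncRNA", IntervalTree()).addi(g.start, g.end + 1, g.gene_id)
            if g.strand == "+":
                ps, pe = g.start - promoter_length, g.start - 1
            else:
                ps, pe = g.end + 1, g.end + promoter_length
            if pe >= 1:
                chrom.setdefault("promoter", IntervalTree()).addi(max(ps, 1), pe + 1, g.gene_id)

    def lookup(self, chrom: str, pos: int) -> str:
        trees = self.trees.get(chrom, {})
        for feat in FEATURE_PRECEDENCE[:-1]:
            tree = trees.get(feat)
            if tree is not None and tree.overlaps(pos):
                return feat
        return "intergenic"


def assign_feature_class(
    chrom: str,
    pos: int,
    genes: Sequence[GeneRecord] | FeatureIndex,
    layout: GenomeLayout | None = None,
    promoter_length: int = 1_000,
) -> str:
    """Feature class of a single position (build a FeatureIndex for bulk use)."""
    if layout is not None:
        length = layout.lengths.get(chrom)
        if length is None or not 1 <= pos <= length:
            raise ValueError(f"position {chrom}:{pos} is off-chromosome")
    index = genes if isinstance(genes, FeatureIndex) else FeatureIndex(genes, promoter_length)
    return index.lookup(chrom, pos)


def builtin_regions(layout: GenomeLayout) -> list[tuple[str, str, int, int]]:
    """Per-chromosome, centromere-neighborhood, named-complex regions and complements."""
    regions = []
    for chrom, length in layout.chromosomes:
        regions.append((f"chrom_{chrom}", chrom, 1, length))
    cen = []
    for chrom, length in layout.chromosomes:
        c = layout.centromere_region(chrom)
        if c is not None:
            cen.append((chrom, c[0], c[1]))
            regions.append((f"centromere_{chrom}", chrom, c[0], c[1]))
    # pooled centromeres / non-centromeres over chromosomes that have one
    for chrom, start, end in cen:
        length = layout.lengths[chrom]
        if start > 1:
            regions.append((f"noncentromere_{chrom}", chrom, 1, start - 1))
        if end < length:
            regions.append((f"noncentromere_{chrom}", chrom, end + 1, length))
    for r in layout.named_regions:
        regions.append((r.label, r.chrom, r.start, r.end))
        length = layout.lengths[r.chrom]
        if r.start > 1:
            regions.append((f"non-{r.label}", r.chrom, 1, r.start - 1))
        if r.end < length:
            regions.append((f"non-{r.label}", r.chrom, r.end + 1, length))
    return regions


def regional_summary(
    windows: pd.DataFrame,
    regions: Sequence[tuple[str, str, int, int]],
    value: str = "H",
) -> pd.DataFrame:
    """Per-region, per-group mean and SEM of a window statistic.

    ``windows`` needs columns line, group, chrom, start, end and the value
    column; a window belongs to a region when its midpoint falls inside.
    The group mean is the mean over lines of per-line window means; the SEM
    is taken across all windows of the group's lines.  Regions without
    windows are flagged absent.
    """
    mid = (windows["start"] + windows["end"] - 1) / 2
    rows = []
    for label, chrom, start, end in regions:
        sel = windows[(windows["chrom"] == chrom) & (mid >= start) & (mid <= end)]
        sel = sel.dropna(subset=[value])
        for grp, sub in sel.groupby("group"):
            line_means = sub.groupby("line")[value].mean()
            vals = sub[value].to_numpy(dtype=float)
            rows.append(
                {
                    "region": label,
                    "group": grp,
                    "mean": float(line_means.mean()),
                    "sem": float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0,
                    "n_windows": int(len(vals)),
                    "absent": False,
                }
            )
        if sel.empty:
            rows.append({"region": label, "group": None, "mean": np.nan, "sem": np.nan,
                         "n_windows": 0, "absent": True})
    out = pd.DataFrame(rows)
    # merge duplicate labels (e.g. two complement arms) by window-count weights
    def _merge(g):
        if g["absent"].all():
            return g.iloc[0]
        g = g[~g["absent"]]
        w = g["n_windows"].to_numpy(float)
        rec = g.iloc[0].copy()
        rec["mean"] = float(np.average(g["mean"], weights=w))
        rec["sem"] = float(np.sqrt(np.average(g["sem"] ** 2 * w, weights=w) / w.sum()))
        rec["n_windows"] = int(w.sum())
        return rec

    out = (
        out.groupby(["region", "group"], dropna=False, sort=False)
        .apply(_merge, include_groups=False)
        .reset_index()
    )
    return out


def percent_change(selection_mean: float, control_mean: float) -> float:
    """Signed percent difference of the selection mean relative to control."""
    if control_mean == 0 or not np.isfinite(control_mean):
        return float("nan")
    return (selection_mean - control_mean) / control_mean * 100.0


def gene_tajima_d(
    sites: pd.DataFrame,
    genes: Sequence[GeneRecord],
    group,
    nominal_n: int = 1_000,
) -> pd.DataFrame:
    """Per-gene per-group Tajima's D and the Diff_D ranking.

    ``sites`` holds chrom, pos and per-line frequency columns ``p_<line>``.
    For each line, D is computed from the sites within the gene span
    [start, end]; the group value is the mean over the group's lines (lines
    with undefined D are excluded); records are sorted by Diff_D descending
    with ties broken by gene id.  Genes with no sites are excluded and
    logged.
    """
    consts = TajimaConstants.from_n(nominal_n)
    chrom_groups = {c: sub.sort_values("pos") for c, sub in sites.groupby("chrom")}
    records = []
    skipped = 0
    for g in genes:
        sub = chrom_groups.get(g.chrom)
        if sub is None:
            skipped += 1
            continue
        pos = sub["pos"].to_numpy()
        i0, i1 = np.searchsorted(pos, [g.start, g.end + 1])
        if i1 <= i0:
            skipped += 1
            continue
        window = sub.iloc[i0:i1]
        group_d = {}
        for grp_name, lines in (("selection", group.selection), ("control", group.control)):
            ds = []
            for line in lines:
                counts = minor_counts_from_freqs(window[f"p_{line}"].to_numpy(), nominal_n)
                _, _, _, d = tajima_d_components(counts, consts)
                if np.isfinite(d):
                    ds.append(d)
            group_d[grp_name] = float(np.mean(ds)) if ds else np.nan
        if not np.isfinite(group_d["selection"]) or not np.isfinite(group_d["control"]):
            skipped += 1
            continue
        records.append(
            {
                "gene_id": g.gene_id,
                "gene_class": g.gene_class,
                "Selection_D": group_d["selection"],
                "Control_D": group_d["control"],
                "Diff_D": group_d["selection"] - group_d["control"],
            }
        )
    if skipped:
        logger.info("gene_tajima_d: %d gene(s) without usable sites excluded", skipped)
    out = pd.DataFrame(records)
    if not out.empty:
        out = out.sort_values(["Diff_D", "gene_id"], ascending=[False, True]).reset_index(drop=True)
    return out


def class_enrichment(
    ranked_genes: pd.DataFrame,
    top_k: int,
    gene_class: str,
    background_counts: dict[str, int] | None = None,
) -> dict:
    """Hypergeometric upper-tail enrichment of a gene class in the top of the ranking.

    ``background_counts`` maps class -> genome-wide gene count; when omitted
    it is taken from the ranking itself.  Returns observed count, expected
    count and the upper-tail probability P(X >= observed).
    """
    if top_k > len(ranked_genes):
        raise ValueError("top_k exceeds the number of ranked genes")
    counts = background_counts or ranked_genes["gene_class"].value_counts().to_dict()
    if gene_class not in counts:
        raise ValueError(f"class {gene_class!r} absent from background")
    M = int(sum(counts.values()))
    K = int(counts[gene_class])
    observed = int((ranked_genes.head(top_k)["gene_class"] == gene_class).sum())
    if observed > top_k:
        raise ValueError("observed exceeds top_k")
    p = float(hypergeom.sf(observed - 1, M, K, top_k))
    return {
        "observed": observed,
        "top_k": top_k,
        "expected": top_k * K / M,
        "p_value": min(p, 1.0),
    }
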