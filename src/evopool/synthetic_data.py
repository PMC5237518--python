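"""Seeded synthetic fixtures for the pool-seq evolve-and-resequence pipeline.

Generates a small genome layout with annotated genes, a founder haplotype
panel at neutral mutation-drift equilibrium (emulating an inbred reference
panel of the DGRP kind), and six evolved pooled lines (three selection, three
control) written as VCF, together with ground-truth tables.

The designed group contrast mirrors the experimental signature under study:
inside designated "balanced" regions the selection lines carry an excess of
intermediate-frequency alleles while the control lines show drift-eroded,
extreme-frequency variation; outside those regions both groups drift
neutrally (controls for ~2x more generations).  Frequencies inside designed
regions are drawn from closed-form mixtures so the expected heterozygosity
ratio between groups is an analytic design parameter, recorded in the truth
tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .popgen_stats import site_heterozygosity

NUCLEOTIDES = np.array(list("ACGT"))

GENE_CLASSES = ("protein_coding", "lncRNA", "snoRNA", "miRNA")

# span ranges (bp) by gene class; protein-coding genes get CDS/UTR/intron substructure
_GENE_SPANS = {
    "protein_coding": (2_000, 6_000),
    "lncRNA": (500, 2_000),
    "snoRNA": (100, 200),
    "miRNA": (80, 120),
}


@dataclass(frozen=True)
class NamedRegion:
    label: str
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"region {self.label}: start must be < end")


@dataclass
class GenomeLayout:
    """Chromosome geometry plus named regions of interest.

    ``centromere_anchor`` maps chromosome name to "left"/"right" (the
    proximal end where the 2 Mb centromere neighborhood sits) or None.
    """

    chromosomes: list[tuple[str, int]]
    centromere_anchor: dict[str, str | None] = field(default_factory=dict)
    named_regions: list[NamedRegion] = field(default_factory=list)
    centromere_size: int = 2_000_000

    def __post_init__(self):
        lengths = self.lengths
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        for r in self.named_regions:
            if r.chrom not in lengths:
                raise ValueError(f"region {r.label} on unknown chromosome {r.chrom}")
            if r.end > lengths[r.chrom]:
                raise ValueError(f"region {r.label} extends beyond chromosome {r.chrom}")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def centromere_region(self, chrom: str) -> tuple[int, int, bool] | None:
        """(start, end, truncated) of the centromere neighborhood, or None."""
        anchor = self.centromere_anchor.get(chrom)
        if anchor is None:
            return None
        length = self.lengths[chrom]
        size = min(self.centromere_size, length)
        truncated = length < self.centromere_size
        if anchor == "left":
            return (1, size, truncated)
        return (length - size + 1, length, truncated)


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    gene_class: str
    substructure: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        for feat, s, e in self.substructure:
            if s < self.start or e > self.end:
                raise ValueError(f"gene {self.gene_id}: feature {feat} outside gene span")


@dataclass
class HaplotypePanel:
    """Founder haplotypes over polymorphic loci (rows: haplotypes, cols: sites)."""

    chroms: np.ndarray          # per-site chromosome name
    positions: np.ndarray       # per-site 1-based position, sorted within chromosome
    haplotypes: np.ndarray      # (n_haplotypes, n_sites) uint8 derived-allele indicators

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)

    def subset(self, chrom: str, start: int | None = None, end: int | None = None) -> "HaplotypePanel":
        mask = self.chroms == chrom
        if start is not None:
            mask &= self.positions >= start
        if end is not None:
            mask &= self.positions <= end
        return HaplotypePanel(self.chroms[mask], self.positions[mask], self.haplotypes[:, mask])


@dataclass
class LayoutConfig:
    """Parameters of the synthetic genome; defaults give 5 chromosomes / 5 Mb."""

    chromosomes: list[tuple[str, int]] = field(
        default_factory=lambda: [
            ("2L", 1_100_000),
            ("2R", 1_100_000),
            ("3L", 1_100_000),
            ("3R", 1_100_000),
            ("X", 600_000),
        ]
    )
    centromere_anchor: dict[str, str | None] = field(
        default_factory=lambda: {"2L": "right", "2R": "left", "3L": "right", "3R": "left"}
    )
    # a ~71 kb low-recombination complex near the tip of X, akin to yellow-achaete-scute
    named_regions: list[NamedRegion] = field(
        default_factory=lambda: [NamedRegion("AS-C", "X", 1, 71_000)]
    )
    centromere_size: int = 200_000  # scaled to the 5 Mb fixture genome
    n_genes: int = 200
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {"protein_coding": 0.64, "lncRNA": 0.16, "snoRNA": 0.10, "miRNA": 0.10}
    )


def generate_genome_layout(config: LayoutConfig | None = None, seed: int = 0):
    """Build a GenomeLayout and a list of non-overlapping GeneRecords.

    Deterministic for a fixed seed.  Genes are placed by rejection sampling;
    class labels follow ``class_proportions`` multinomially.
    """
    config = config or LayoutConfig()
    if not config.chromosomes:
        raise ValueError("at least one chromosome required")
    props = config.class_proportions
    if abs(sum(props.values()) - 1.0) > 1e-9:
        raise ValueError("class proportions must sum to 1")
    layout = GenomeLayout(
        chromosomes=list(config.chromosomes),
        centromere_anchor=dict(config.centromere_anchor),
        named_regions=list(config.named_regions),
        centromere_size=config.centromere_size,
    )
    min_gene = min(lo for lo, _ in _GENE_SPANS.values())
    for name, length in config.chromosomes:
        if length < min_gene:
            raise ValueError(f"chromosome {name} is shorter than the smallest gene ({min_gene} bp)")

    rng = np.random.default_rng(seed)
    classes = list(props)
    labels = rng.choice(classes, size=config.n_genes, p=[props[c] for c in classes])
    chrom_names = [c for c, _ in config.chromosomes]
    chrom_weights = np.array([l for _, l in config.chromosomes], dtype=float)
    chrom_weights /= chrom_weights.sum()
    lengths = layout.lengths

    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    genes: list[GeneRecord] = []
    for gi, cls in enumerate(labels):
        lo, hi = _GENE_SPANS[cls]
        for _attempt in range(1000):
            chrom = rng.choice(chrom_names, p=chrom_weights)
            span = int(rng.integers(lo, hi + 1))
            if lengths[chrom] <= span:
                continue
            start = int(rng.integers(1, lengths[chrom] - span))
            end = start + span - 1
            if any(s <= end and start <= e for s, e in placed[chrom]):
                continue
            placed[chrom].append((start, end))
            strand = "+" if rng.random() < 0.5 else "-"
            sub = _protein_coding_substructure(start, end, rng) if cls == "protein_coding" else ()
            genes.append(
                GeneRecord(f"G{gi:04d}", chrom, start, end, strand, cls, sub)
            )
            break
        else:
            raise RuntimeError("could not place gene after 1000 attempts; genome too crowded")
    genes.sort(key=lambda g: (g.chrom, g.start))
    return layout, genes


def _protein_coding_substructure(start, end, rng):
    """5'UTR, alternating CDS/intron, 3'UTR partition of a gene span."""
    span = end - start + 1
    utr5 = min(200, span // 10)
    utr3 = min(300, span // 10)
    body_lo = start + utr5
    body_hi = end - utr3
    n_cds = int(rng.integers(2, 5))
    # cut the body into 2*n_cds-1 alternating CDS/intron chunks
    cuts = np.sort(rng.integers(body_lo + 1, body_hi, size=2 * n_cds - 2))
    bounds = [body_lo, *cuts.tolist(), body_hi]
    sub = [("5'UTR", start, body_lo - 1)]
    for k in range(2 * n_cds - 1):
        s, e = bounds[k], bounds[k + 1]
        if k % 2 == 0:
            sub.append(("CDS", s, max(s, e - 1) if k < 2 * n_cds - 2 else e))
        else:
            sub.append(("intron", s, e - 1))
    sub.append(("3'UTR", body_hi + 1, end))
    # drop degenerate chunks
    return tuple((f, s, e) for f, s, e in sub if s <= e)


def generate_founder_panel(
    n_haplotypes: int,
    n_sites: int,
    layout: GenomeLayout,
    seed: int = 0,
) -> HaplotypePanel:
    """Founder panel with derived-allele counts following the neutral 1/i law.

    Site positions are uniform over the genome; at each site the derived
    allele count i (1 <= i <= n_haplotypes - 1) is drawn with probability
    proportional to 1/i (standard neutral equilibrium site-frequency
    spectrum), and the carriers are chosen exchangeably.
    """
    if n_haplotypes < 2:
        raise ValueError("need at least 2 haplotypes")
    if n_sites < 1:
        raise ValueError("need at least 1 site")
    if n_sites > layout.total_length:
        raise ValueError("n_sites exceeds genome length")
    rng = np.random.default_rng(seed)
    # distinct uniform positions over the concatenated genome
    flat = rng.choice(layout.total_length, size=n_sites, replace=False)
    flat.sort()
    offsets = np.cumsum([0] + [l for _, l in layout.chromosomes])
    chrom_idx = np.searchsorted(offsets, flat, side="right") - 1
    names = np.array([c for c, _ in layout.chromosomes])
    chroms = names[chrom_idx]
    positions = (flat - offsets[chrom_idx] + 1).astype(np.int64)

    i_vals = np.arange(1, n_haplotypes)
    probs = (1.0 / i_vals) / np.sum(1.0 / i_vals)
    derived = rng.choice(i_vals, size=n_sites, p=probs)
    # exchangeable carrier assignment: rank a uniform matrix per site
    hap = np.zeros((n_haplotypes, n_sites), dtype=np.uint8)
    ranks = np.argsort(rng.random((n_sites, n_haplotypes)), axis=1)
    col = np.arange(n_sites)
    for j in range(n_haplotypes):
        # haplotype ranks[s, j] is a carrier at site s when j < derived[s]
        mask = j < derived
        hap[ranks[mask, j], col[mask]] = 1
    return HaplotypePanel(chroms, positions, hap)


@dataclass
class DepthModel:
    """Negative-binomial-like read depth: mean and overdispersion (NB size)."""

    mean_depth: float = 100.0
    dispersion: float = 10.0  # NB size parameter; larger -> closer to Poisson

    def sample(self, size, rng) -> np.ndarray:
        if self.mean_depth <= 0:
            raise ValueError("depth model mean must be positive")
        p = self.dispersion / (self.dispersion + self.mean_depth)
        return rng.negative_binomial(self.dispersion, p, size=size)


@dataclass
class TruthSpec:
    """Designed contrasts between the three selection and three control lines."""

    selection_lines: tuple[str, ...] = ("L1", "L2", "L3")
    control_lines: tuple[str, ...] = ("C1", "C2", "C3")
    balanced_regions: tuple[str, ...] = ("centromeres", "AS-C")
    het_ratio: float = 1.5            # designed selection/control H ratio in balanced regions
    selection_generations: int = 107  # neutral drift outside balanced regions
    control_generations: int = 201
    drift_n: int = 300                # diploid N for the drift chains
    top_gene: str | None = "auto"     # gene designed to top the Diff_D ranking
    indel_fraction: float = 0.01
    low_gq_fraction: float = 0.01
    bad_depth_fraction: float = 0.005
    multiallelic_fraction: float = 0.002
    include_monomorphic: bool = False


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside the synthetic VCFs."""

    sites: pd.DataFrame            # chrom, pos, ref, alt + true_<line> frequencies
    region_contrasts: pd.DataFrame  # region, expected H per group, designed ratio
    indels: pd.DataFrame           # chrom, pos
    top_gene: str | None
    seed: int
    sites_polymorphic: np.ndarray | None = None  # mask of sites emitted to VCF


def _drift_chain(p0: np.ndarray, generations: int, n_chrom: int, rng) -> np.ndarray:
    """Neutral Wright-Fisher allele-frequency chain (site-independent)."""
    k = rng.binomial(n_chrom, p0)
    for _ in range(generations - 1):
        k = rng.binomial(n_chrom, k / n_chrom)
    return k / n_chrom


def _balanced_region_samplers(het_ratio: float):
    """Closed-form frequency laws giving a designed heterozygosity ratio.

    Selection lines draw from Beta(8, 8): E[2p(1-p)] = 0.5 - 2*Var = 0.5 -
    0.5/17.  Control lines draw a mixture of the same Beta and a detectable
    near-fixed law Uniform(0.03, 0.12) folded to either allele, mixed so that
    E[H_sel]/E[H_ctl] equals ``het_ratio`` exactly.
    """
    h_sel = 0.5 - 2 * (0.25 / 17.0)                     # Beta(8,8)
    a, b = 0.03, 0.12
    m = (a + b) / 2
    v = (b - a) ** 2 / 12
    h_low = 2 * (m - (v + m * m))                       # folded uniform near fixation
    h_ctl_target = h_sel / het_ratio
    gamma = (h_ctl_target - h_low) / (h_sel - h_low)
    if not 0 <= gamma <= 1:
        raise ValueError(f"het_ratio {het_ratio} outside achievable range")

    def sample_selection(size, rng):
        return rng.beta(8, 8, size=size)

    def sample_control(size, rng):
        p = np.where(
            rng.random(size) < 0.5,
            rng.uniform(a, b, size=size),
            1.0 - rng.uniform(a, b, size=size),
        )
        balanced = rng.random(size) < gamma
        p[balanced] = rng.beta(8, 8, size=int(balanced.sum()))
        return p

    return sample_selection, sample_control, h_sel, h_ctl_target


def balanced_region_intervals(layout: GenomeLayout, spec: TruthSpec):
    """Resolve the TruthSpec's balanced-region labels into intervals."""
    intervals = []
    for label in spec.balanced_regions:
        if label == "centromeres":
            for chrom, _ in layout.chromosomes:
                cen = layout.centromere_region(chrom)
                if cen is not None:
                    intervals.append(("centromere_" + chrom, chrom, cen[0], cen[1]))
        else:
            for r in layout.named_regions:
                if r.label == label:
                    intervals.append((r.label, r.chrom, r.start, r.end))
    return intervals


def generate_pooled_experiment(
    layout: GenomeLayout,
    panel: HaplotypePanel,
    truth_spec: TruthSpec | None = None,
    depth_model: DepthModel | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    genes: list[GeneRecord] | None = None,
    vcf_per_line: bool = False,
):
    """Six evolved pooled lines as VCF plus the generating truth.

    Per-line true frequencies start from the founder panel frequencies and
    are evolved by independent neutral drift chains (selection lines for
    fewer generations than controls, matching the experimental gap); inside
    balanced regions they are replaced by the designed intermediate-frequency
    (selection) or drift-eroded (control) laws.  Reported allele frequencies
    are binomial read draws at the modelled depth.  Returns (vcf_paths,
    SyntheticTruth); VCFs are written only when ``out_dir`` is given.
    """
    spec = truth_spec or TruthSpec()
    depth_model = depth_model or DepthModel()
    if len(spec.selection_lines) != 3 or len(spec.control_lines) != 3:
        raise ValueError("truth_spec must name 3 selection and 3 control lines")
    if depth_model.mean_depth <= 0:
        raise ValueError("depth model mean must be positive")
    rng = np.random.default_rng(seed)
    n_sites = panel.n_sites
    p_panel = panel.frequencies()
    lines = list(spec.selection_lines) + list(spec.control_lines)
    n_chrom = 2 * spec.drift_n

    truth = {}
    for line in lines:
        gens = spec.selection_generations if line in spec.selection_lines else spec.control_generations
        truth[line] = _drift_chain(p_panel, gens, n_chrom, rng)

    intervals = balanced_region_intervals(layout, spec)
    sample_sel, sample_ctl, h_sel, h_ctl = _balanced_region_samplers(spec.het_ratio)
    in_balanced = np.zeros(n_sites, dtype=bool)
    for _, chrom, start, end in intervals:
        in_balanced |= (panel.chroms == chrom) & (panel.positions >= start) & (panel.positions <= end)
    nb = int(in_balanced.sum())
    for line in spec.selection_lines:
        truth[line][in_balanced] = sample_sel(nb, rng)
    for line in spec.control_lines:
        truth[line][in_balanced] = sample_ctl(nb, rng)

    # designed top Diff_D gene: tight intermediate frequencies in selection lines,
    # near-fixed in controls, over the gene's span
    top_gene_id = None
    if spec.top_gene is not None and genes:
        if spec.top_gene == "auto":
            candidates = [
                g
                for g in genes
                if g.gene_class == "protein_coding"
                and any(
                    g.chrom == chrom and g.start >= start and g.end <= end
                    for _, chrom, start, end in intervals
                )
            ] or [g for g in genes if g.gene_class == "protein_coding"]
            top = max(candidates, key=lambda g: g.end - g.start)
        else:
            top = next(g for g in genes if g.gene_id == spec.top_gene)
        top_gene_id = top.gene_id
        gmask = (panel.chroms == top.chrom) & (panel.positions >= top.start) & (panel.positions <= top.end)
        ng = int(gmask.sum())
        for line in spec.selection_lines:
            truth[line][gmask] = rng.beta(40, 40, size=ng)
        for line in spec.control_lines:
            lo = rng.uniform(0.01, 0.05, size=ng)
            truth[line][gmask] = np.where(rng.random(ng) < 0.5, lo, 1 - lo)

    region_rows = [
        {
            "region": label,
            "chrom": chrom,
            "start": start,
            "end": end,
            "expected_H_selection": h_sel,
            "expected_H_control": h_ctl,
            "designed_ratio": spec.het_ratio,
        }
        for label, chrom, start, end in intervals
    ]

    ref = rng.choice(4, size=n_sites)
    alt = (ref + rng.integers(1, 4, size=n_sites)) % 4

    sites = pd.DataFrame({"chrom": panel.chroms, "pos": panel.positions,
                          "ref": NUCLEOTIDES[ref], "alt": NUCLEOTIDES[alt]})
    for line in lines:
        sites[f"true_{line}"] = truth[line]

    # indels: half at random positions, half deliberately within 10 bp of a SNP
    n_indel = max(1, int(spec.indel_fraction * n_sites))
    near = rng.choice(n_sites, size=n_indel // 2, replace=False)
    indel_chrom = list(panel.chroms[near])
    indel_pos = list(panel.positions[near] + rng.integers(1, 11, size=near.size))
    offsets = np.cumsum([0] + [l for _, l in layout.chromosomes])
    flat = rng.choice(layout.total_length - 1, size=n_indel - near.size, replace=False)
    ci = np.searchsorted(offsets, flat, side="right") - 1
    names = np.array([c for c, _ in layout.chromosomes])
    indel_chrom += list(names[ci])
    indel_pos += list(flat - offsets[ci] + 1)
    indels = pd.DataFrame({"chrom": indel_chrom, "pos": np.asarray(indel_pos, dtype=np.int64)})
    indels = indels.sort_values(["chrom", "pos"]).reset_index(drop=True)

    truth_obj = SyntheticTruth(
        sites=sites,
        region_contrasts=pd.DataFrame(region_rows),
        indels=indels,
        top_gene=top_gene_id,
        seed=seed,
    )

    vcf_paths = []
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        vcf_paths = _write_vcfs(out_dir, layout, truth_obj, lines, spec, depth_model, rng, vcf_per_line)
        truth_obj.sites.to_csv(out_dir / "truth_sites.tsv", sep="\t", index=False)
        truth_obj.region_contrasts.to_csv(out_dir / "truth_regions.tsv", sep="\t", index=False)
        truth_obj.indels.to_csv(out_dir / "truth_indels.tsv", sep="\t", index=False)
    return vcf_paths, truth_obj


def _write_vcfs(out_dir, layout, truth_obj, lines, spec, depth_model, rng, vcf_per_line):
    sites = truth_obj.sites
    n_sites = len(sites)
    n_lines = len(lines)

    depth = depth_model.sample((n_lines, n_sites), rng)
    depth = np.maximum(depth, 1)
    # deliberately out-of-bounds depths to exercise the depth filter
    bad = rng.random((n_lines, n_sites)) < spec.bad_depth_fraction
    low_or_high = rng.random((n_lines, n_sites)) < 0.5
    depth[bad & low_or_high] = rng.integers(1, 10, size=int((bad & low_or_high).sum()))
    depth[bad & ~low_or_high] = rng.integers(251, 400, size=int((bad & ~low_or_high).sum()))

    true_p = np.vstack([sites[f"true_{line}"].to_numpy() for line in lines])
    alt_reads = rng.binomial(depth, true_p)
    gq = np.full((n_lines, n_sites), 60, dtype=np.int64)
    low = rng.random((n_lines, n_sites)) < spec.low_gq_fraction
    gq[low] = rng.integers(3, 31, size=int(low.sum()))
    multi = rng.random(n_sites) < spec.multiallelic_fraction

    # merge SNPs and indels into one sorted record stream
    records = []
    for idx in range(n_sites):
        records.append(("snp", sites["chrom"].iat[idx], int(sites["pos"].iat[idx]), idx))
    for _, row in truth_obj.indels.iterrows():
        records.append(("indel", row["chrom"], int(row["pos"]), -1))
    records.sort(key=lambda r: (r[1], r[2], r[0] == "snp"))

    chrom_order = [c for c, _ in layout.chromosomes]
    records.sort(key=lambda r: (chrom_order.index(r[1]), r[2], r[0] == "snp"))

    def header(sample_names):
        head = ["##fileformat=VCFv4.2", "##source=evopool-synth"]
        for name, length in layout.chromosomes:
            head.append(f"##contig=<ID={name},length={length}>")
        head += [
            '##INFO=<ID=TYPE,Number=1,Type=String,Description="Record type">',
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_names),
        ]
        return head

    def sample_field(li, idx):
        d, a, q = depth[li, idx], alt_reads[li, idx], gq[li, idx]
        if a == 0:
            gt = "0/0"
        elif a == d:
            gt = "1/1"
        else:
            gt = "0/1"
        return f"{gt}:{d - a},{a}:{d}:{q}"

    def record_lines(line_indices):
        out = []
        for kind, chrom, pos, idx in records:
            if kind == "indel":
                fields = "\t".join("0/1:30,30:60:60" for _ in line_indices)
                out.append(f"{chrom}\t{pos}\t.\tAT\tA\t60\t.\tTYPE=indel\tGT:AD:DP:GQ\t{fields}")
                continue
            if not poly[idx] and not spec.include_monomorphic:
                continue
            alt_alleles = sites["alt"].iat[idx]
            if multi[idx]:
                third = NUCLEOTIDES[(NUCLEOTIDES.tolist().index(alt_alleles) + 1) % 4]
                if third == sites["ref"].iat[idx]:
                    third = NUCLEOTIDES[(NUCLEOTIDES.tolist().index(alt_alleles) + 2) % 4]
                alt_alleles = f"{alt_alleles},{third}"
            qual = int(min(gq[li, idx] for li in line_indices))
            fields = "\t".join(sample_field(li, idx) for li in line_indices)
            out.append(
                f"{chrom}\t{pos}\t.\t{sites['ref'].iat[idx]}\t{alt_alleles}\t{qual}\t.\tTYPE=snp\tGT:AD:DP:GQ\t{fields}"
            )
        return out

    # a site is written when at least one line's pool shows both alleles
    poly = ((alt_reads > 0) & (alt_reads < depth)).any(axis=0)
    truth_obj.sites_polymorphic = poly  # attached for the writer and tests

    paths = []
    if vcf_per_line:
        for li, line in enumerate(lines):
            path = Path(out_dir) / f"{line}.vcf"
            path.write_text("\n".join(header([line]) + record_lines([li])) + "\n")
            paths.append(path)
    else:
        path = Path(out_dir) / "pooled.vcf"
        path.write_text("\n".join(header(lines) + record_lines(list(range(n_lines)))) + "\n")
        paths.append(path)
    return paths


def write_gff3(genes: list[GeneRecord], path: str | Path) -> None:
    """Write gene annotation as GFF3 (1-based closed intervals)."""
    lines = ["##gff-version 3"]
    for g in genes:
        attrs = f"ID={g.gene_id};gene_class={g.gene_class}"
        lines.append(
            f"{g.chrom}\tevopool\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}"
        )
        for feat, s, e in g.substructure:
            ftype = {"CDS": "CDS", "intron": "intron", "5'UTR": "five_prime_UTR", "3'UTR": "three_prime_UTR"}[feat]
            lines.append(f"{g.chrom}\tevopool\t{ftype}\t{s}\t{e}\t.\t{g.strand}\t.\tParent={g.gene_id}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[GeneRecord]:
    """Read gene annotation written by :func:`write_gff3`."""
    genes: dict[str, dict] = {}
    order: list[str] = []
    rev = {"five_prime_UTR": "5'UTR", "three_prime_UTR": "3'UTR", "CDS": "CDS", "intron": "intron"}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, _, ftype, start, end, _, strand, _, attrs = line.split("\t")
        kv = dict(a.split("=", 1) for a in attrs.split(";") if "=" in a)
        if ftype == "gene":
            gid = kv["ID"]
            genes[gid] = dict(
                gene_id=gid, chrom=chrom, start=int(start), end=int(end),
                strand=strand, gene_class=kv.get("gene_class", "protein_coding"), substructure=[],
            )
            order.append(gid)
        elif ftype in rev:
            genes[kv["Parent"]]["substructure"].append((rev[ftype], int(start), int(end)))
    return [
        GeneRecord(**{**g, "substructure": tuple(g["substructure"])}) for g in (genes[gid] for gid in order)
    ]


def write_bed(regions, path: str | Path) -> None:
    """Write (label, chrom, start, end) regions as BED (0-based half-open)."""
    lines = [f"{chrom}\t{start - 1}\t{end}\t{label}" for label, chrom, start, end in regions]
    Path(path).write_text("\n".join(lines) + "\n")


def read_bed(path: str | Path):
    """Read BED into (label, chrom, start, end) with 1-based closed coordinates."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        chrom, start, end = parts[0], int(parts[1]) + 1, int(parts[2])
        label = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
        out.append((label, chrom, start, end))
    return out
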