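"""End-to-end orchestration: synth -> filter -> stats -> regions -> selection.

Stages run in dependency order with per-stage seeds derived from the master
seed by stable hashing of the stage name, so a rerun with the same
configuration is byte-identical and partial reruns stay reproducible.  Every
output file is listed in a JSON manifest with a row count and checksum.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import popgen_stats, region_analysis, selection_tests, synthetic_data, variant_filters, wf_sim
from .synthetic_data import DepthModel, LayoutConfig, TruthSpec
from .variant_filters import LineGroup
from .wf_sim import ObservationModel, ScenarioConfig

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_analysis", "run_simulation_suite", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    return (master_seed * 2654435761 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    out_dir: str = "evopool_out"
    seed: int = 0
    # inputs; when vcf_paths is empty the synth stage generates them
    vcf_paths: list[str] = field(default_factory=list)
    gff3_path: str | None = None
    sweeps_bed: str | None = None
    cds_fasta_a: str | None = None
    cds_fasta_b: str | None = None
    # synth parameters
    n_sites: int = 50_000
    n_founders: int = 205
    layout: LayoutConfig = field(default_factory=LayoutConfig)
    truth: TruthSpec = field(default_factory=TruthSpec)
    depth: DepthModel = field(default_factory=DepthModel)
    # filter thresholds
    min_quality: float = 30.0
    min_depth: int = 10
    max_depth: int = 250
    indel_margin: int = 10
    # statistics
    window_h: int = 100_000
    step_h: int = 10_000
    window_d: int = 10_000
    nominal_n: int = 1_000
    sfs_bins: int = 20
    enrichment_top_k: int = 200
    enrichment_class: str = "lncRNA"
    threads: int = 1  # accepted for interface compatibility; engine is vectorised

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            val = raw[f.name]
            if f.name == "layout" and isinstance(val, dict):
                val = LayoutConfig(**val)
            elif f.name == "truth" and isinstance(val, dict):
                val = TruthSpec(**val)
            elif f.name == "depth" and isinstance(val, dict):
                val = DepthModel(**val)
            kwargs[f.name] = val
        return cls(**kwargs)


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    manifest["files"][path.name] = {
        "rows": int(len(df)),
        "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
    }


def _register(path: Path, manifest: dict, rows: int) -> None:
    manifest["files"][path.name] = {
        "rows": rows,
        "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
    }


def run_analysis(config: RunConfig) -> dict:
    """Run the variant pipeline end to end; returns the manifest (also written)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "thresholds": {
        "min_quality": config.min_quality, "min_depth": config.min_depth,
        "max_depth": config.max_depth, "indel_margin": config.indel_margin,
        "window_h": config.window_h, "step_h": config.step_h, "window_d": config.window_d,
        "nominal_n": config.nominal_n,
    }, "files": {}}
    group = LineGroup(tuple(config.truth.selection_lines), tuple(config.truth.control_lines))

    stage = "unknown"
    try:
        # ---- synth ----------------------------------------------------------
        stage = "synth"
        truth = None
        if config.vcf_paths:
            vcf_paths = [Path(p) for p in config.vcf_paths]
            if config.gff3_path:
                genes = synthetic_data.read_gff3(config.gff3_path)
                layout = config.layout and synthetic_data.GenomeLayout(
                    chromosomes=list(config.layout.chromosomes),
                    centromere_anchor=dict(config.layout.centromere_anchor),
                    named_regions=list(config.layout.named_regions),
                    centromere_size=config.layout.centromere_size,
                )
            else:
                genes, layout = [], None
        else:
            seed = stage_seed(config.seed, "synth")
            layout, genes = synthetic_data.generate_genome_layout(config.layout, seed)
            panel = synthetic_data.generate_founder_panel(
                config.n_founders, config.n_sites, layout, seed + 1
            )
            vcf_paths, truth = synthetic_data.generate_pooled_experiment(
                layout, panel, config.truth, config.depth, seed + 2,
                out_dir=out, genes=genes,
            )
            synthetic_data.write_gff3(genes, out / "genes.gff3")
            _register(out / "genes.gff3", manifest, len(genes))
            for name, df in (("truth_sites.tsv", truth.sites),
                             ("truth_regions.tsv", truth.region_contrasts),
                             ("truth_indels.tsv", truth.indels)):
                _register(out / name, manifest, len(df))
            regions = region_analysis.builtin_regions(layout)
            synthetic_data.write_bed([(r[0], r[1], r[2], r[3]) for r in regions], out / "regions.bed")
            _register(out / "regions.bed", manifest, len(regions))
            for p in vcf_paths:
                _register(Path(p), manifest, sum(1 for l in Path(p).read_text().splitlines() if not l.startswith("#")))

        # ---- filter ---------------------------------------------------------
        stage = "filter"
        sites = variant_filters.parse_pooled_vcf(vcf_paths, group)
        kept, removed = variant_filters.apply_site_filters(
            sites, config.min_quality, config.min_depth, config.max_depth, config.indel_margin
        )
        counts = variant_filters.classify_sites_by_group(kept, group)
        variant_filters.write_sync_tsv(kept, group.all_lines, out / "filtered.sync.tsv")
        _register(out / "filtered.sync.tsv", manifest, len(kept))
        report = pd.DataFrame(
            [{"rule": r, "removed": removed[r]} for r in variant_filters.FILTER_ORDER]
            + [{"rule": "surviving", "removed": len(kept)}]
        )
        _write(report, out / "filter_report.tsv", manifest)
        _write(pd.DataFrame([counts]), out / "zygosity_classes.tsv", manifest)

        frame = variant_filters.sites_to_frame(kept, group.all_lines)

        # ---- stats ----------------------------------------------------------
        stage = "stats"
        win_h_rows, win_d_rows, sfs_rows = [], [], []
        chrom_lengths = layout.lengths if layout else {}
        for line in group.all_lines:
            grp = "selection" if line in group.selection else "control"
            for chrom, sub in (frame.groupby("chrom") if len(frame) else ()):
                sub = sub.sort_values("pos")
                pos = sub["pos"].to_numpy()
                p = sub[f"p_{line}"].to_numpy(dtype=float)
                clen = chrom_lengths.get(chrom)
                h = popgen_stats.windowed_heterozygosity(
                    pos, p, window=config.window_h, step=config.step_h, chrom_length=clen
                )
                h.insert(0, "line", line); h.insert(1, "group", grp); h.insert(2, "chrom", chrom)
                win_h_rows.append(h)
                med_dp = float(np.median(sub[f"dp_{line}"])) if len(sub) else config.nominal_n
                n_eff = max(2, min(config.nominal_n, int(med_dp)))
                d = popgen_stats.window_pi_theta_d(
                    pos, popgen_stats.minor_counts_from_freqs(p, n_eff), n=n_eff,
                    window=config.window_d, chrom_length=clen,
                )
                d.insert(0, "line", line); d.insert(1, "group", grp); d.insert(2, "chrom", chrom)
                win_d_rows.append(d)
            s = popgen_stats.sfs(frame[f"p_{line}"].to_numpy(dtype=float) if len(frame) else [],
                                 bins=config.sfs_bins)
            s.insert(0, "line", line); s.insert(1, "group", grp)
            sfs_rows.append(s)
        windows_h = pd.concat(win_h_rows, ignore_index=True) if win_h_rows else pd.DataFrame(
            columns=["line", "group", "chrom", "start", "end", "n_sites", "H", "partial"])
        windows_d = pd.concat(win_d_rows, ignore_index=True) if win_d_rows else pd.DataFrame(
            columns=["line", "group", "chrom", "start", "end", "S", "pi", "theta_w", "D", "n_sites", "partial"])
        _write(windows_h, out / "windows_heterozygosity.tsv", manifest)
        _write(windows_d, out / "windows_tajima.tsv", manifest)
        _write(pd.concat(sfs_rows, ignore_index=True), out / "sfs.tsv", manifest)
        if len(frame):
            fmat = np.vstack([frame[f"p_{l}"].to_numpy(dtype=float) for l in group.all_lines])
            fst = popgen_stats.mean_pairwise_fst(fmat, group.all_lines)
            def pair_kind(row):
                a_sel = row.line_a in group.selection
                b_sel = row.line_b in group.selection
                return "within_selection" if a_sel and b_sel else (
                    "within_control" if not a_sel and not b_sel else "between_groups")
            fst["comparison"] = [pair_kind(r) for r in fst.itertuples()]
        else:
            fst = pd.DataFrame(columns=["line_a", "line_b", "mean_fst", "n_sites", "comparison"])
        _write(fst, out / "fst_pairs.tsv", manifest)

        # ---- regions --------------------------------------------------------
        stage = "regions"
        if layout is not None and len(windows_h):
            regions = region_analysis.builtin_regions(layout)
            summary_h = region_analysis.regional_summary(windows_h, regions, value="H")
            summary_d = region_analysis.regional_summary(windows_d.rename(columns={"D": "value"}),
                                                         regions, value="value")
            pct_rows = []
            for region in summary_h["region"].unique():
                sub = summary_h[summary_h.region == region]
                s = sub.loc[sub.group == "selection", "mean"]
                c = sub.loc[sub.group == "control", "mean"]
                if len(s) and len(c):
                    pct_rows.append({"region": region,
                                     "selection_mean": float(s.iloc[0]),
                                     "control_mean": float(c.iloc[0]),
                                     "percent_change": region_analysis.percent_change(
                                         float(s.iloc[0]), float(c.iloc[0]))})
            _write(summary_h, out / "regional_heterozygosity.tsv", manifest)
            _write(summary_d, out / "regional_tajima.tsv", manifest)
            _write(pd.DataFrame(pct_rows), out / "regional_percent_change.tsv", manifest)
        if genes and len(frame):
            ranked = region_analysis.gene_tajima_d(frame, genes, group, config.nominal_n)
            _write(ranked, out / "gene_diff_d.tsv", manifest)
            if len(ranked):
                background = {c: sum(1 for g in genes if g.gene_class == c)
                              for c in {g.gene_class for g in genes}}
                top_k = min(config.enrichment_top_k, len(ranked))
                if config.enrichment_class in background:
                    enr = region_analysis.class_enrichment(
                        ranked, top_k, config.enrichment_class, background)
                    _write(pd.DataFrame([enr]), out / "class_enrichment.tsv", manifest)

        # ---- selection ------------------------------------------------------
        stage = "selection"
        if config.sweeps_bed:
            bed = synthetic_data.read_bed(config.sweeps_bed)
            recs = []
            for label, chrom, start, end in bed:
                line = label.split(":")[0]
                recs.append({
                    "line": line,
                    "group": "selection" if line in group.selection else "control",
                    "chrom": chrom, "start": start - 1, "end": end,
                })
            sweeps = selection_tests.sweep_summary(pd.DataFrame(recs), n_lines_per_group=3)
            _write(sweeps, out / "sweep_summary.tsv", manifest)
        if config.cds_fasta_a and config.cds_fasta_b:
            from Bio import SeqIO
            seqs_a = {r.id: str(r.seq) for r in SeqIO.parse(config.cds_fasta_a, "fasta")}
            seqs_b = {r.id: str(r.seq) for r in SeqIO.parse(config.cds_fasta_b, "fasta")}
            rows = []
            for name in sorted(set(seqs_a) & set(seqs_b)):
                r = selection_tests.nei_gojobori(seqs_a[name], seqs_b[name])
                rows.append({"gene": name, "Ka": r.ka, "Ks": r.ks,
                             "KaKs": r.ratio if r.defined else np.nan,
                             "Nd": r.nd, "Sd": r.sd})
            _write(pd.DataFrame(rows), out / "kaks.tsv", manifest)
    except Exception as exc:  # annotate the failing stage, keep partial outputs
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        (failed / "stage.txt").write_text(f"{stage}: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if truth is not None:
        manifest["top_gene_truth"] = truth.top_gene
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def run_simulation_suite(
    neutral: ScenarioConfig | None = None,
    selection_scenarios: list[ScenarioConfig] | None = None,
    founders=None,
    layout_config: LayoutConfig | None = None,
    n_sites: int = 5_000,
    n_founders: int = 205,
    out_dir: str | Path | None = None,
    seed: int = 0,
) -> dict:
    """Run the neutral and common-allele-selection scenarios and summarise.

    When no founder panel is supplied one is generated from the layout.
    Returns {"neutral": ..., "selection": {label: ...}, "comparison": frame}.
    """
    neutral = neutral or ScenarioConfig(seed=stage_seed(seed, "sim-neutral"))
    if neutral.replicates < 1:
        raise ValueError("replicate count must be >= 1")
    if founders is None:
        layout, _ = synthetic_data.generate_genome_layout(layout_config or LayoutConfig(), stage_seed(seed, "sim-layout"))
        founders = synthetic_data.generate_founder_panel(
            n_founders, n_sites, layout, stage_seed(seed, "sim-panel")
        )
    results: dict = {"neutral": wf_sim.run_neutral_scenario(neutral, founders)}
    sel_results = {}
    if selection_scenarios:
        chrom = str(founders.chroms[0])
        region_panel = founders.subset(chrom)
        for sc in selection_scenarios:
            label = f"w{sc.w_deleterious}_lam{sc.recombination_intensity}"
            sel_results[label] = wf_sim.run_common_allele_selection_scenario(sc, region_panel)
    results["selection"] = sel_results
    if sel_results:
        comp = []
        for label, res in sel_results.items():
            for _, row in res["per_checkpoint"].iterrows():
                comp.append({"scenario": label, "generation": int(row.generation),
                             "H_mean": row.H_mean, "H_sem": row.H_sem})
        results["comparison"] = pd.DataFrame(comp)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        results["neutral"]["checkpoints"].to_csv(out / "neutral_checkpoints.tsv", sep="\t", index=False)
        results["neutral"]["per_replicate"].to_csv(out / "neutral_per_replicate.tsv", sep="\t", index=False)
        pd.DataFrame([results["neutral"]["summary"]]).to_csv(out / "neutral_summary.tsv", sep="\t", index=False)
        for label, res in sel_results.items():
            res["trajectories"].to_csv(out / f"selection_{label}_trajectories.tsv", sep="\t", index=False)
        if "comparison" in results:
            results["comparison"].to_csv(out / "selection_comparison.tsv", sep="\t", index=False)
    return results
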