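"""Regional contrasts and the per-gene Diff_D ranking via the full pipeline.

Runs the end-to-end pipeline on a synthetic fixture, then prints the
selection-vs-control percent change per region and the top genes by
Diff_D = Selection_D - Control_D, with lncRNA enrichment in the top set.
"""

import tempfile

import pandas as pd

from evopool.pipeline import RunConfig, run_analysis

out = tempfile.mkdtemp(prefix="evopool_example_")
cfg = RunConfig(out_dir=out, seed=17, n_sites=30_000, n_founders=120)
manifest = run_analysis(cfg)

pct = pd.read_csv(f"{out}/regional_percent_change.tsv", sep="\t")
interesting = pct[pct.region.str.startswith(("centromere_", "AS-C", "chrom_"))]
print("heterozygosity percent change, selection vs control:")
print(interesting.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

ranked = pd.read_csv(f"{out}/gene_diff_d.tsv", sep="\t")
print("\ntop 5 genes by Diff_D (designed top gene:", manifest["top_gene_truth"] + "):")
print(ranked.head(5).to_string(index=False, float_format=lambda v: f"{v:.3f}"))

enr = pd.read_csv(f"{out}/class_enrichment.tsv", sep="\t")
print(
    f"\nlncRNA in the top {int(enr.top_k.iloc[0])} genes: observed "
    f"{int(enr.observed.iloc[0])} vs expected {enr.expected.iloc[0]:.1f} "
    f"(hypergeometric upper-tail P = {enr.p_value.iloc[0]:.3f})"
)
print(
    "\nPositive percent change inside centromere neighborhoods and the AS-C-like "
    "complex reflects the designed balancing-selection contrast; the designed "
    "gene tops the ranking because its selection lines sit near frequency 0.5 "
    "while its control lines are nearly fixed."
)
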