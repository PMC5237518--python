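"""Generate a synthetic pooled evolve-and-resequence experiment and filter it.

Builds a 5 Mb genome with 200 annotated genes, a neutral-equilibrium founder
panel, and six evolved pooled lines (3 selection, 3 control) written as VCF;
then applies the variant filters and classifies sites by group-wise zygosity.
"""

import tempfile

from evopool.synthetic_data import (
    generate_founder_panel,
    generate_genome_layout,
    generate_pooled_experiment,
)
from evopool.variant_filters import (
    LineGroup,
    apply_site_filters,
    classify_sites_by_group,
    parse_pooled_vcf,
)

out_dir = tempfile.mkdtemp(prefix="evopool_example_")
layout, genes = generate_genome_layout(seed=1)
panel = generate_founder_panel(n_haplotypes=205, n_sites=30_000, layout=layout, seed=2)
paths, truth = generate_pooled_experiment(layout, panel, seed=3, out_dir=out_dir, genes=genes)
print(f"wrote {paths[0]}")

group = LineGroup.default()
sites = parse_pooled_vcf(paths, group)
kept, removed = apply_site_filters(sites)
print(f"parsed {len(sites)} records; {len(kept)} SNPs survive the filters")
print("removed per rule (first failing rule wins):", removed)

# Zygosity classes mirror the published site bookkeeping: a pooled line is
# "heterozygous" when both alleles are seen in its pool, "fixed" otherwise.
counts = classify_sites_by_group(kept, group)
for k, v in counts.items():
    print(f"  {k:38s} {v:7d}")
print(
    "\nThe selection lines, designed with balanced intermediate frequencies in "
    "centromere neighborhoods, stay heterozygous at more sites than the "
    "drift-eroded control lines."
)
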