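# Methods

`evopool` reimplements, as a tested library, the analysis stack of a pooled
evolve-and-resequence (E&R) study design: replicate *Drosophila*-style lines
selected for a life-history trait versus parallel controls, sequenced as
pools, contrasted with windowed diversity statistics, and benchmarked
against forward Wright–Fisher simulations.  This note records the models,
the defaults and why, the numerical conventions, and what the synthetic
fixtures do and do not establish about real data.

## Diversity statistics

All estimators are the classic forms:

- expected heterozygosity `H = 2p(1−p)` per biallelic site, averaged in
  100 kb sliding windows with 10 kb step;
- `π = Σ 2i(n−i)/(n(n−1))` over sites with allele count `i` in a sample of
  `n` haplotypes; Watterson's `θ_W = S/a1`, `a1 = Σ_{i<n} 1/i`;
- Tajima's `D = (π − θ_W)/√(e1·S + e2·S(S−1))` with the 1989 constants,
  computed per 10 kb non-overlapping window.  `D` is flagged undefined
  (NaN) when `S = 0` or the variance term vanishes (e.g. `n = 2`);
- per-SNP `FST = (HT − HS)/HT` with `HT = 2p̄(1−p̄)` and `HS` the mean
  within-line heterozygosity.  Sites with `HT = 0` are flagged and excluded
  from averages; negative values are kept as computed (clamping would bias
  pair averages upward);
- folded SFS: minor-allele frequencies binned over (0, 0.5], right-closed
  bins so frequency 0.5 lands in the top bin.

Pool-seq caveat: pooled lines yield read frequencies, not genotypes.  Allele
counts for `π`/`θ`/`D` are `round(p·n)` at a nominal sample size `n`
(default 1,000 = two chromosomes per pooled fly × 500 flies, capped by the
window's median read depth), with a floor of one copy for any site that is
polymorphic in the pool.  These are the uncorrected classical estimators,
not pool-size/coverage-corrected ones: every group contrast in the package
compares lines processed identically, so the shared bias cancels in the
selection-vs-control differences that are the object of interest.  Absolute
values should not be read as unbiased population parameters.

Windows are half-open `[start, start+window)` on 1-based coordinates; the
final partial window is kept and flagged.  Windowed values are invariant to
input chunking, verified by test.

## Variant filtering

Sites survive iff: biallelic; per-line genotype quality > 30; per-line depth
in [10, 250]; no indel breakpoint within 10 bp (inclusive — the boundary is
a convention, chosen inclusive).  A site failing in any line is dropped for
all lines, keeping the six lines site-matched for FST/D comparisons.
Removal counts are attributed to the first failing rule in a fixed order
(multiallelic → quality → depth → indel proximity); the surviving set is
order-independent.  "Heterozygous"/"fixed" for a pooled line are defined on
the pool frequency (default: any polymorphism in the pool counts as
heterozygous; bounds configurable).

## Per-gene differential Tajima's D

For each gene, D is computed over the sites in its span `[start, end]` per
line, averaged over the three lines of each group, and genes are ranked by
`Diff_D = Selection_D − Control_D` (ties broken by gene id).  The averaging
order (per-line D, then group mean) is a design choice; computing D on
group-pooled frequencies instead would weight lines by coverage.  Class
enrichment in the top k of the ranking is a hypergeometric upper tail
against genome-wide class counts — a deliberate generic substitute for
database-driven ontology enrichment.

Feature classes partition every position via precedence
CDS > UTR > intron > promoter > ncRNA > intergenic, with the promoter
defined as the 1 kb upstream of the transcription start, strand-aware.

## Selection tests

Nei–Gojobori (1986) unweighted-pathway counting: per-codon synonymous site
fractions from the standard code (changes to stop codons count as
nonsynonymous); multi-difference codons average over all mutational
orderings, excluding pathways through stops (if all are blocked the
exclusion is waived).  Jukes–Cantor correction is off by default (raw
proportions).  Ka/Ks of identical sequences is flagged undefined, never 0/0.
The McDonald–Kreitman table is tested with Fisher's exact test (two-sided,
sum of tables no more probable than observed); the neutrality index
`NI = (Pn/Ps)/(Dn/Ds)` is flagged on zero denominators.  Sweep intervals are
consumed as BED (detection is an upstream tool's job); per line they are
merged before length summaries, and the group's shared region is the
base-pair intersection across its three lines.

## Wright–Fisher engine

Discrete non-overlapping generations, N diploids.  Each offspring samples
two parents with probability ∝ fitness; fitness is per-allele
multiplicative, `w` per deleterious copy (heterozygote `w`, homozygote
`w²`).  Each transmitted gamete recombines the parental haplotypes with a
Poisson(λ) number of crossovers at uniform positions — λ is "expected
crossovers per chromosome per meiosis", so λ=2 is a moderately recombining
chromosome and λ=0.2 a low-recombination region.  No new mutations, no
migration, no sex structure: on the ~200–1,000-generation timescales
simulated, standing variation dominates and these omissions are the
standard approximation.  The central calibration, enforced by tests, is the
drift law `E[H_t] = H_0 (1 − 1/2N)^t`, plus the one-step variance
`p(1−p)/2N`, the martingale property, and fixation probability = initial
frequency.

Founders: the large mass-breeding phase that precedes the bottleneck exists
only to supply near-equilibrium variation, so by default populations are
founded directly from the synthetic equilibrium panel ("equilibrium
founders"); a literal reduced-N mass phase is available for property tests.

### Neutral baseline scenario

N = 300 (the experimental census), 201 generations, statistics at
generations 107 and 201 — the selection/control generation gap.  Statistics
are taken on the full population (n = 2N) in two ways:

1. **True frequencies** — exact haplotype counts; used for the drift-law
   heterozygosity calibration (mean `2p(1−p)` over the full founder site
   set, fixed sites contributing 0, so the analytic law applies).
2. **Pooled-sequencing observation** — per site, depth ~ negative binomial
   (mean 100, dispersion 10), alternate reads binomial at the true
   frequency, and a site is *called* only when the minor allele has ≥ 4
   supporting reads and depth is in [10, 250].  Four reads is the
   approximate support needed for a phred-30 pooled variant call, the
   quality floor the variant pipeline itself applies; the depth bounds are
   the pipeline's own.  Windowed D is then computed from the called SNPs'
   read frequencies.

The distinction matters for Tajima's D.  On true frequencies, drift from an
equilibrium founder spectrum *raises* windowed D by ~8–10% between
generations 107 and 201: rare alleles are lost fastest, and the loss is
fully visible when every haplotype is observable.  Through the observation
model the change is ≈ +2% and statistically indistinguishable from zero at
three replicates, because the rare-allele classes whose depletion drives
the rise sit below the pool-seq detection limit at both checkpoints.  Since
the study design being emulated measures D through exactly such a pipeline
(pooled reads, quality-filtered SNP calls), the observation-model value is
the one reported by the acceptance script; both are in the trajectory
tables.  Percent change is defined as `(v_201 − v_107)/|v_107| × 100` so
its sign is a direction regardless of the sign of D.

### Common-allele selection scenario

A 2 Mb low-recombination region (the stated coordinates span 2 Mb and are
used as such; the region length is configurable), 22 selected sites evenly
spaced, deleterious allele at initial frequency 0.1 assigned to haplotypes
under Hardy–Weinberg, `w ∈ {0.9, 0.999}` (strong vs weak/no selection),
λ ∈ {2, 0.2}, 1,000 generations, windowed heterozygosity of the linked
neutral loci every 100 generations.  Selecting against an allele at
frequency 0.1 is selection *for* the common allele — the constant-fitness
stand-in for positive frequency dependence.  Heterozygosity here is
averaged over the **fixed founder site set** (swept-to-fixation sites count
as 0): conditioning on surviving SNPs after a sweep would inflate H (the
survivors are the intermediate-frequency markers of the remaining haplotype
lineages) and invert the strong-vs-weak comparison into an artefact.  The
bottleneck N is 300, matching the experiment; the deterministic selection
recursion `p′ = pw/(1 − p + pw)` drives the deleterious allele below
1/(2N) within ~130 generations at w = 0.9, so it is lost in essentially all
replicates well before generation 1,000.

Default replicate counts are scaled for a desk run (the suite uses 20
replicates per scenario condition, and 3 for the headline neutral
comparison, matching the original three simulation runs); all counts are
configuration.

## Synthetic data generator

The generator emulates the study's inputs, not any particular dataset:

- **Genome**: five chromosomes totalling 5 Mb (four autosome arms with a
  200 kb "centromere neighborhood" at the proximal end — the 2 Mb
  neighborhoods of the full-size genome scaled to the fixture — plus an X
  with a 71 kb low-recombination complex at its tip).  200 genes placed
  non-overlapping by rejection sampling; class proportions default to 64%
  protein-coding, 16% lncRNA, 10% snoRNA, 10% miRNA — the lncRNA share
  matches the fraction reported among top-ranked genes, and the remainder
  is arbitrary since the genome-wide background is a free parameter.
- **Founder panel**: 205 haplotypes (the size of the inbred reference panel
  the study drew founders from), site positions uniform, derived-allele
  counts `i` drawn ∝ 1/i — the neutral equilibrium SFS — with carriers
  assigned exchangeably.  No linkage structure is simulated among founders
  (exchangeable-sites approximation); consequences below.
- **Evolved lines**: per-line true frequencies start from panel frequencies
  and drift through independent binomial Wright–Fisher chains (selection
  lines 107 generations, controls 201, N = 300).  Inside designated
  "balanced" regions (centromere neighborhoods and the X-tip complex)
  selection-line frequencies are drawn from Beta(8,8) and control-line
  frequencies from a closed-form mixture of the same Beta and a
  near-fixation law supported on [0.03, 0.12] ∪ [0.88, 0.97], mixed so the
  expected selection/control heterozygosity ratio equals the design
  parameter (default 1.5) exactly.  Support is kept ≥ 0.03 so pool-seq
  detection removes almost nothing and the designed ratio survives the
  VCF → filter → windowed-H path (verified to 10%).  One designated gene
  gets Beta(40,40) selection-line frequencies and near-fixed controls,
  making it the designed top of the Diff_D ranking.
- **Observation**: depth negative-binomial (mean 100, dispersion 10 —
  consistent with the pipeline's own 10/250 depth filter bounds), reported frequency = binomial read draw;
  QUAL/GQ/DP fields populated so every filter rule is exercisable, with
  small deliberate fractions of low-GQ, out-of-bounds-depth, multiallelic
  and near-SNP-indel records.  Monomorphic sites are omitted by default
  (the statistics operate on SNPs); a flag includes them.

What the fixtures do **not** emulate: linkage disequilibrium within the
founder panel (site-exchangeable), sequencing error beyond binomial
sampling, mapping artefacts, real gene length/density distributions, and
any real genome coordinates.  Passing the end-to-end tests therefore shows
that the pipeline recovers designed frequency structure through the full
VCF-to-report path, not that it would be unbiased on any particular real
dataset.

## Numerical conventions and degenerate inputs

Undefined statistics are NaN-flagged, never silently zero: D with `S = 0`
or zero variance, FST with `HT = 0`, Ka/Ks with `Ks = 0` or identical
sequences, percent change with a zero denominator.  Genes without usable
sites are excluded from the ranking and logged.  Empty inputs produce
empty, schema-valid outputs.  All generators and scenarios are driven by
`numpy` `SeedSequence`-spawned streams: a fixed master seed reproduces
byte-identical outputs, and per-stage seeds are derived by stable hashing
of the stage name so partial reruns agree with full runs.

## Known limitations

- Pool-size-corrected estimators are deliberately not implemented; absolute
  π/θ/D levels differ from corrected tools even though group contrasts are
  preserved.
- The observation model reduces the variant-calling stack to a
  read-support threshold; real callers' quality scores depend on error
  models not represented here.
- The simulator's whole-population sampling (n = 2N) makes checkpoint
  statistics nearly noise-free per replicate but leaves replicate-to-
  replicate variance dominated by linked drift, which is large in
  low-recombination scenarios; comparisons use replicate-level standard
  errors for that reason.
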