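"""Forward Wright-Fisher simulation of diploid populations with recombination.

The engine advances a population of N diploids (2N haplotypes over L
polymorphic loci) one non-overlapping generation at a time: each offspring
draws two parents with probability proportional to fitness, and each
transmitted gamete recombines the parental haplotypes with a Poisson(lambda)
number of crossovers at uniform positions.  Fitness is per-allele
multiplicative: an individual carrying c copies of deleterious alleles over
the selected loci has fitness w**c.  No new mutations arise, matching the
experimental-evolution timescale being modelled.

Two scenario drivers mirror the study design: a neutral-drift baseline
(bottleneck at N=300 for 201 generations, statistics compared between
generations 107 and 201) and selection for the common allele (constant
selection against an initially rare deleterious allele at 22 evenly spaced
sites in a low-recombination region, tracked for 1,000 generations).

Checkpoint statistics can be taken on the true population frequencies or
through a pooled-sequencing observation model (binomial read sampling at a
modelled depth with a minimum minor-allele read support for a site to be
called), which reproduces how the experimental pipeline actually measures
diversity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .popgen_stats import window_pi_theta_d, windowed_heterozygosity, site_heterozygosity
from .synthetic_data import HaplotypePanel

__all__ = [
    "Population",
    "FitnessModel",
    "ObservationModel",
    "ScenarioConfig",
    "advance_generation",
    "found_population",
    "run_neutral_scenario",
    "run_common_allele_selection_scenario",
]


@dataclass
class Population:
    """2N haplotypes over L biallelic loci on a single chromosome."""

    haplotypes: np.ndarray       # (2N, L) uint8
    positions: np.ndarray        # strictly increasing bp
    chrom_length: int
    generation: int = 0

    def __post_init__(self):
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] % 2:
            raise ValueError("haplotypes must be a (2N, L) matrix")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("locus positions must be strictly increasing")

    @property
    def n_diploid(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[1]

    def frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)


@dataclass
class FitnessModel:
    """Per-allele multiplicative fitness: carriers of c deleterious copies have w**c."""

    selected_loci: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    w_deleterious: float = 1.0

    def individual_fitness(self, haplotypes: np.ndarray) -> np.ndarray:
        n = haplotypes.shape[0] // 2
        if len(self.selected_loci) == 0 or self.w_deleterious == 1.0:
            return np.ones(n)
        sel = np.asarray(self.selected_loci)
        copies = haplotypes[0::2][:, sel].sum(axis=1) + haplotypes[1::2][:, sel].sum(axis=1)
        return np.power(self.w_deleterious, copies, dtype=float)


@dataclass
class ObservationModel:
    """Pooled-sequencing view of a population's allele frequencies.

    Per site, read depth is drawn around ``mean_depth`` (negative-binomial
    with the given dispersion), alternate reads are binomial at the true
    frequency, and a site is called a SNP only when the minor allele has at
    least ``min_minor_reads`` supporting reads and depth is within bounds —
    the read-support equivalent of the phred-30 genotype-quality floor the
    variant pipeline applies.
    """

    mean_depth: float = 100.0
    dispersion: float = 10.0
    min_minor_reads: int = 4
    min_depth: int = 10
    max_depth: int = 250

    def observe(self, freqs: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
        """Return (called mask, observed frequency) per site."""
        p = self.dispersion / (self.dispersion + self.mean_depth)
        depth = rng.negative_binomial(self.dispersion, p, size=freqs.size)
        alt = rng.binomial(depth, freqs)
        with np.errstate(invalid="ignore", divide="ignore"):
            phat = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
        minor = np.minimum(alt, depth - alt)
        called = (minor >= self.min_minor_reads) & (depth >= self.min_depth) & (depth <= self.max_depth)
        return called, phat


def advance_generation(
    pop: Population,
    fitness: FitnessModel | None = None,
    lam: float = 2.0,
    rng: np.random.Generator | None = None,
) -> Population:
    """One Wright-Fisher generation with selection and recombination."""
    rng = rng if rng is not None else np.random.default_rng()
    n = pop.n_diploid
    if n == 0:
        raise ValueError("population is empty")
    fit = (fitness or FitnessModel()).individual_fitness(pop.haplotypes)
    total = fit.sum()
    if total <= 0:
        raise RuntimeError("population extinct under selection: all parental fitness zero")
    parents = rng.choice(n, size=2 * n, p=fit / total)

    hap = pop.haplotypes
    n_gam = 2 * n
    L = pop.n_loci
    k = rng.poisson(lam, size=n_gam)
    start = rng.integers(0, 2, size=n_gam).astype(np.int8)
    # fast path: a crossover-free gamete is a copy of one parental haplotype
    gametes = hap[2 * parents + start]  # fancy indexing: already a fresh array
    rec = np.nonzero(k > 0)[0]
    if rec.size:
        k_rec = k[rec]
        bp = rng.uniform(0, pop.chrom_length, size=int(k_rec.sum()))
        gid = np.repeat(np.arange(rec.size), k_rec)
        loc = np.searchsorted(pop.positions, bp)
        switch = np.zeros((rec.size, L + 1), dtype=np.int8)
        np.add.at(switch, (gid, loc), 1)
        parity = (np.cumsum(switch[:, :L], axis=1) + start[rec, None]) & 1
        hap_a = hap[2 * parents[rec]]
        hap_b = hap[2 * parents[rec] + 1]
        gametes[rec] = np.where(parity == 0, hap_a, hap_b)
    return Population(gametes.astype(np.uint8), pop.positions, pop.chrom_length, pop.generation + 1)


def found_population(panel: HaplotypePanel, n_diploid: int, rng) -> Population:
    """Found a population by drawing 2N haplotypes from a panel with replacement.

    The panel must hold a single chromosome (subset it first).
    """
    chroms = np.unique(panel.chroms)
    if len(chroms) != 1:
        raise ValueError("panel must be restricted to one chromosome")
    idx = rng.integers(0, panel.n_haplotypes, size=2 * n_diploid)
    hap = panel.haplotypes[idx].copy()
    return Population(hap, panel.positions.astype(np.int64), int(panel.positions[-1]) + 1, 0)


@dataclass
class ScenarioConfig:
    """Shared configuration of the simulation scenarios."""

    main_phase_n: int = 300
    total_generations: int = 201
    sampling_generations: tuple[int, ...] = (107, 201)
    replicates: int = 3
    recombination_intensity: float = 2.0   # expected crossovers per chromosome per meiosis
    window_d: int = 10_000
    window_h: int = 100_000
    step_h: int = 10_000
    seed: int = 0
    # selection-scenario extras
    n_selected_sites: int = 22
    initial_deleterious_frequency: float = 0.1
    w_deleterious: float = 0.9
    checkpoint_every: int = 100
    observation: ObservationModel | None = field(default_factory=ObservationModel)

    def __post_init__(self):
        if any(g > self.total_generations for g in self.sampling_generations):
            raise ValueError("sampling generation beyond total_generations")
        if self.recombination_intensity < 0:
            raise ValueError("recombination intensity must be >= 0")
        if not 0 <= self.initial_deleterious_frequency <= 1:
            raise ValueError("initial deleterious frequency must be in [0, 1]")


def _checkpoint_stats(pop: Population, config: ScenarioConfig, obs_rng) -> dict:
    """Diversity statistics of the whole population (n = 2N) at one checkpoint."""
    freqs = pop.frequencies()
    n = pop.haplotypes.shape[0]
    counts = pop.haplotypes.sum(axis=0)
    d_true = window_pi_theta_d(
        pop.positions, counts, n=n, window=config.window_d, chrom_length=pop.chrom_length
    )
    h_win = windowed_heterozygosity(
        pop.positions, freqs, window=config.window_h, step=config.step_h, chrom_length=pop.chrom_length
    )
    out = {
        "generation": pop.generation,
        "mean_H_all_sites": float(np.mean(site_heterozygosity(freqs))),
        "mean_windowed_H": float(h_win["H"].mean()),
        "mean_windowed_D_true": float(d_true["D"].mean()),
        "windows_true": d_true,
        "windows_H": h_win,
    }
    if config.observation is not None:
        called, phat = config.observation.observe(freqs, obs_rng)
        pos_c = pop.positions[called]
        nominal = min(n, 1000)
        from .popgen_stats import minor_counts_from_freqs

        counts_c = minor_counts_from_freqs(phat[called], nominal)
        d_obs = window_pi_theta_d(
            pos_c, counts_c, n=nominal, window=config.window_d, chrom_length=pop.chrom_length
        )
        out["mean_windowed_D_observed"] = float(d_obs["D"].mean())
        out["n_called"] = int(called.sum())
    return out


def percent_change(later: float, earlier: float) -> float:
    """Signed percent change from ``earlier`` to ``later``, relative to |earlier|."""
    if earlier == 0:
        return float("nan")
    return (later - earlier) / abs(earlier) * 100.0


def run_neutral_scenario(config: ScenarioConfig, founders: HaplotypePanel) -> dict:
    """Neutral bottleneck scenario: drift at N for ``total_generations``.

    Each replicate founds an independent population per chromosome from the
    panel ("equilibrium founders" stand in for the large mass-breeding
    phase), advances it without selection, and records checkpoint statistics
    at each sampling generation.  Returns per-replicate checkpoint tables and
    a summary with the percent change of each statistic between the first and
    last sampling generations, averaged over replicates.
    """
    if founders.n_sites == 0 or np.all(founders.frequencies() % 1 == 0):
        raise ValueError("founder panel must be polymorphic")
    master = np.random.SeedSequence(config.seed)
    rep_seeds = master.spawn(config.replicates)
    chrom_names = [str(c) for c in pd.unique(founders.chroms)]
    fitness = FitnessModel()
    gens = sorted(config.sampling_generations)
    rows = []
    for rep, seq in enumerate(rep_seeds):
        rng = np.random.default_rng(seq)
        for chrom in chrom_names:
            sub = founders.subset(chrom)
            if sub.n_sites == 0:
                continue
            pop = found_population(sub, config.main_phase_n, rng)
            if 0 in gens:
                stats = _checkpoint_stats(pop, config, rng)
                stats.update(replicate=rep, chrom=chrom)
                rows.append(stats)
            for t in range(1, config.total_generations + 1):
                pop = advance_generation(pop, fitness, config.recombination_intensity, rng)
                if t in gens:
                    stats = _checkpoint_stats(pop, config, rng)
                    stats.update(replicate=rep, chrom=chrom)
                    rows.append(stats)

    scalar_cols = [
        "replicate", "chrom", "generation", "mean_H_all_sites", "mean_windowed_H",
        "mean_windowed_D_true",
    ] + (["mean_windowed_D_observed", "n_called"] if config.observation is not None else [])
    table = pd.DataFrame([{k: r[k] for k in scalar_cols} for r in rows])

    g0, g1 = gens[0], gens[-1]
    per_rep = []
    stats_of_interest = ["mean_H_all_sites", "mean_windowed_H", "mean_windowed_D_true"]
    if config.observation is not None:
        stats_of_interest.append("mean_windowed_D_observed")
    for rep in range(config.replicates):
        sub = table[table.replicate == rep]
        entry = {"replicate": rep}
        for stat in stats_of_interest:
            v0 = sub.loc[sub.generation == g0, stat].mean()
            v1 = sub.loc[sub.generation == g1, stat].mean()
            entry[f"{stat}_g{g0}"] = v0
            entry[f"{stat}_g{g1}"] = v1
            entry[f"{stat}_pct_change"] = 0.0 if g0 == g1 else percent_change(v1, v0)
        per_rep.append(entry)
    per_rep = pd.DataFrame(per_rep)
    summary = {
        f"{stat}_pct_change_mean": float(per_rep[f"{stat}_pct_change"].mean())
        for stat in stats_of_interest
    }
    summary.update(
        {
            f"{stat}_pct_change_sem": float(
                per_rep[f"{stat}_pct_change"].std(ddof=1) / np.sqrt(len(per_rep))
            )
            if len(per_rep) > 1
            else float("nan")
            for stat in stats_of_interest
        }
    )
    summary["H_ratio_last_over_first"] = float(
        (per_rep[f"mean_H_all_sites_g{g1}"] / per_rep[f"mean_H_all_sites_g{g0}"]).mean()
    )
    return {"checkpoints": table, "per_replicate": per_rep, "summary": summary, "windows": rows}


def run_common_allele_selection_scenario(config: ScenarioConfig, founders: HaplotypePanel) -> dict:
    """Selection for the common allele in a low-recombination region.

    Deleterious alleles start at frequency p0 at ``n_selected_sites`` evenly
    spaced loci (Hardy-Weinberg assignment to haplotypes); constant selection
    against them favours the initially common allele.  Windowed
    heterozygosity of the linked neutral loci is recorded every
    ``checkpoint_every`` generations.  Returns the trajectory table (one row
    per replicate x checkpoint x window) and per-checkpoint means.
    """
    if config.n_selected_sites < 1:
        raise ValueError("need at least one selected site")
    chroms = np.unique(founders.chroms)
    if len(chroms) != 1:
        founders = founders.subset(str(chroms[0]))
    region_len = int(founders.positions[-1]) + 1
    if region_len < config.window_h:
        raise ValueError("region shorter than the heterozygosity window")
    # evenly spaced selected sites along the region, inserted among neutral loci
    sel_pos = np.linspace(region_len / (config.n_selected_sites + 1),
                          region_len * config.n_selected_sites / (config.n_selected_sites + 1),
                          config.n_selected_sites).astype(np.int64)
    if np.unique(sel_pos).size < config.n_selected_sites:
        raise ValueError("selected sites denser than positions available")
    for _ in range(100):
        if not np.intersect1d(sel_pos, founders.positions).size:
            break
        sel_pos = sel_pos + 1  # avoid collisions with neutral loci
    else:
        raise ValueError("selected sites denser than positions available")

    master = np.random.SeedSequence(config.seed)
    rep_seeds = master.spawn(config.replicates)
    checkpoints = list(range(config.checkpoint_every, config.total_generations + 1, config.checkpoint_every))
    rows, sel_rows = [], []
    for rep, seq in enumerate(rep_seeds):
        rng = np.random.default_rng(seq)
        base = found_population(founders, config.main_phase_n, rng)
        # merge selected loci into the matrix
        all_pos = np.concatenate([base.positions, sel_pos])
        order = np.argsort(all_pos)
        n_hap = base.haplotypes.shape[0]
        sel_hap = (rng.random((n_hap, config.n_selected_sites)) < config.initial_deleterious_frequency)
        hap = np.concatenate([base.haplotypes, sel_hap.astype(np.uint8)], axis=1)[:, order]
        positions = all_pos[order]
        sel_idx = np.searchsorted(positions, sel_pos)
        neutral_mask = np.ones(positions.size, dtype=bool)
        neutral_mask[sel_idx] = False
        pop = Population(hap, positions, region_len, 0)
        fitness = FitnessModel(selected_loci=sel_idx, w_deleterious=config.w_deleterious)
        for t in range(1, config.total_generations + 1):
            pop = advance_generation(pop, fitness, config.recombination_intensity, rng)
            if t in checkpoints:
                freqs = pop.frequencies()
                # fixed site set: swept-to-fixation loci count as 0, so hitchhiking
                # shows as diversity loss rather than a survivor-conditioning artefact
                h_win = windowed_heterozygosity(
                    pop.positions[neutral_mask], freqs[neutral_mask],
                    window=config.window_h, step=config.window_h, chrom_length=region_len,
                    include_monomorphic=True,
                )
                for _, w in h_win.iterrows():
                    rows.append(
                        {
                            "replicate": rep, "generation": t, "start": int(w.start),
                            "end": int(w.end), "H": w.H, "n_sites": int(w.n_sites),
                        }
                    )
                sel_rows.append(
                    {
                        "replicate": rep, "generation": t,
                        "mean_deleterious_freq": float(freqs[sel_idx].mean()),
                        "n_segregating_selected": int(((freqs[sel_idx] > 0) & (freqs[sel_idx] < 1)).sum()),
                    }
                )
    traj = pd.DataFrame(rows)
    sel_traj = pd.DataFrame(sel_rows)
    per_checkpoint = (
        traj.groupby("generation")["H"].agg(["mean", "sem"]).rename(columns={"mean": "H_mean", "sem": "H_sem"}).reset_index()
    )
    return {"trajectories": traj, "selected_trajectories": sel_traj, "per_checkpoint": per_checkpoint}
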