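"""Forward Wright-Fisher diploid simulator with recombination.

Generates genotype panels with fully known truth for every downstream stage:
discrete non-overlapping generations; each offspring draws two distinct
parents (random mating, or monogamous couples for pedigree/relatedness work);
gametes are formed with Poisson crossover counts over the chromosome's genetic
length and uniform crossover positions (Haldane model, no interference).
Initial standing variation is seeded at linkage equilibrium from a U-shaped
(Beta(1/2, 1/2)) site-frequency proxy, recurrent symmetric mutation keeps
sites segregating, and a burn-in — 4Ne generations by default — lets LD reach
the mutation-drift-recombination equilibrium (E[r²|c] near 1/(4Nc + 2)) that
the LD-based Ne estimators assume.

A population-split scenario generator forks daughter populations from the
ancestral pool at configurable times (emulating, e.g., one deeply diverged
lineage plus two recently separated ones), and an ascertainment helper
restricts panels to markers polymorphic in a designated reference population.

All randomness flows from the single config seed; identical seeds give
bit-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genotype_io import MISSING, GenotypePanel, MarkerMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimConfig:
    """Wright-Fisher scenario description.

    ne_trajectory : ((generations_ago, Ne), ...) change-points, most recent
        first; Ne at time t is the value of the change-point with the largest
        generation <= t.  A single point means constant Ne.
    n_generations : forward generations simulated after burn-in (defaults to
        the oldest change-point generation).
    burn_in : generations at the ancestral Ne before the trajectory window
        (default 4 x ancestral Ne).
    n_segregating_target : number of markers reported per panel (sites are
        over-seeded by ``init_site_factor`` to survive drift losses, then
        ascertained at ``maf_ascertainment`` and down-sampled).
    mutation_rate : symmetric per-site allele-flip probability per transmitted
        gamete.  Recurrent mutation maintains the mutation-drift-recombination
        equilibrium in which E[r²|c] follows 1/(4Nc + 2) — the alpha = 2
        regime the Ne estimators assume; set 0 for pure standing-variation
        drift (which instead approaches the mutation-free alpha = 1 form).
    init_freq : fix every site's initial frequency (None draws Beta(1/2,1/2)).
    split_times : optional {population name: generations ago} divergence times
        for :func:`simulate_split`.
    pop_ne / pop_sample_size : per-population overrides after a split.
    """

    ne_trajectory: tuple = ((0, 100),)
    n_generations: int | None = None
    n_chromosomes: int = 2
    chromosome_length_bp: int = 50_000_000
    recomb_rate_cM_per_Mb: float = 1.0
    n_segregating_target: int = 2000
    init_site_factor: float = 3.0
    sample_size: int = 50
    mutation_rate: float = 1e-4
    missing_rate: float = 0.0
    maf_ascertainment: float = 0.05
    mating: str = "random"
    init_freq: float | None = None
    burn_in: int | None = None
    split_times: dict | None = None
    pop_ne: dict | None = None
    pop_sample_size: dict | None = None
    seed: int = 0

    def __post_init__(self):
        traj = tuple(sorted(self.ne_trajectory, key=lambda g: g[0]))
        object.__setattr__(self, "ne_trajectory", traj)
        if not traj or traj[0][0] != 0:
            raise ValueError("ne_trajectory must include a change-point at generation 0")
        if any(ne < 2 for _, ne in traj):
            raise ValueError("Ne values must be >= 2")
        if self.mating not in ("random", "monogamy"):
            raise ValueError("mating must be 'random' or 'monogamy'")
        if self.missing_rate < 0 or self.missing_rate >= 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.recomb_rate_cM_per_Mb < 0:
            raise ValueError("recombination rate must be >= 0")
        if self.sample_size > traj[0][1]:
            raise ValueError("sample_size cannot exceed the final Ne")

    def ne_at(self, t: int) -> int:
        """Ne of the generation living t generations ago."""
        ne = self.ne_trajectory[-1][1]
        for g, n in self.ne_trajectory:
            if g <= t:
                ne = n
            else:
                break
        return int(ne)

    @property
    def ancestral_ne(self) -> int:
        return int(self.ne_trajectory[-1][1])

    @property
    def span(self) -> int:
        return self.n_generations if self.n_generations is not None \
            else int(self.ne_trajectory[-1][0])

    @property
    def burn_in_generations(self) -> int:
        return self.burn_in if self.burn_in is not None else 4 * self.ancestral_ne


@dataclass
class SimTruth:
    """Everything needed to score recovery tests without re-simulation."""

    config: SimConfig
    seed: int
    realized_trajectory: list                 # (generations_ago, Ne) actually used
    split_times: dict | None
    #: {population: [per-chromosome allele-frequency arrays over ALL seeded sites]}
    true_freqs: dict
    #: {population: (mothers, fathers)} parent indices of the final generation
    pedigree: dict
    #: {population: sampled individual indices within the final generation}
    sampled_indices: dict
    #: per-chromosome indices of the ascertained (reported) sites
    kept_sites: list


# ---------------------------------------------------------------------------
# Core machinery
# ---------------------------------------------------------------------------

def _meioses(rng, hap_pool, pos_m, chrom_len_m, parent_idx, mutation_rate=0.0):
    """One gamete per parent in ``parent_idx`` (crossovers ~ Poisson)."""
    M = parent_idx.size
    L = pos_m.size
    start = rng.integers(0, 2, M).astype(np.int8)
    ind = np.repeat(start[:, None], L, axis=1)
    if chrom_len_m > 0 and L > 0:
        k = rng.poisson(chrom_len_m, M)
        for m in np.nonzero(k > 0)[0]:
            x = np.sort(rng.uniform(0.0, chrom_len_m, k[m]))
            ind[m] ^= (np.searchsorted(x, pos_m) & 1).astype(np.int8)
    a = hap_pool[2 * parent_idx]
    b = hap_pool[2 * parent_idx + 1]
    gam = np.where(ind == 0, a, b)
    if mutation_rate > 0 and L > 0:
        n_mut = rng.poisson(mutation_rate * M * L)
        if n_mut > 0:
            rows = rng.integers(0, M, n_mut)
            cols = rng.integers(0, L, n_mut)
            gam[rows, cols] ^= 1
    return gam


def _choose_parents(rng, n_parents, n_offspring, mating):
    if mating == "random":
        moms = rng.integers(0, n_parents, n_offspring)
        dads = (moms + 1 + rng.integers(0, n_parents - 1, n_offspring)) % n_parents
    else:
        n_couples = n_parents // 2
        perm = rng.permutation(n_parents)
        couple = rng.integers(0, n_couples, n_offspring)
        moms = perm[2 * couple]
        dads = perm[2 * couple + 1]
    return moms.astype(np.int64), dads.astype(np.int64)


def _advance(rng, haps, pos_m, chrom_lens_m, n_offspring, mating, mutation_rate=0.0):
    """Advance one generation; returns (new haplotype pools, mothers, fathers)."""
    n_parents = haps[0].shape[0] // 2
    moms, dads = _choose_parents(rng, n_parents, n_offspring, mating)
    new = []
    for hap, pm, clm in zip(haps, pos_m, chrom_lens_m):
        child = np.empty((2 * n_offspring, hap.shape[1]), dtype=np.int8)
        child[0::2] = _meioses(rng, hap, pm, clm, moms, mutation_rate)
        child[1::2] = _meioses(rng, hap, pm, clm, dads, mutation_rate)
        new.append(child)
    return new, moms, dads


def _drift_retention(config: SimConfig) -> float:
    """Expected fraction of initial heterozygosity surviving the whole run,
    prod_t (1 - 1/(2 Ne_t)); used to over-seed sites so that roughly
    ``n_segregating_target`` markers remain ascertainable at sampling time."""
    ret = (1.0 - 1.0 / (2.0 * config.ancestral_ne)) ** config.burn_in_generations
    span = config.span if config.split_times is None else max(config.split_times.values())
    for t in range(span):
        ret *= 1.0 - 1.0 / (2.0 * config.ne_at(t))
    return ret


def _init_population(rng, config: SimConfig, n_individuals: int):
    """Seed standing variation at linkage equilibrium."""
    factor = max(config.init_site_factor, min(1.0 / (0.5 * _drift_retention(config)), 80.0))
    n_sites_total = max(int(round(config.n_segregating_target * factor)),
                        config.n_segregating_target)
    per_chrom = [n_sites_total // config.n_chromosomes] * config.n_chromosomes
    per_chrom[0] += n_sites_total - sum(per_chrom)
    haps, positions, pos_m, chrom_lens_m = [], [], [], []
    morgans_per_bp = config.recomb_rate_cM_per_Mb * 1e-8
    for L in per_chrom:
        # distinct random bp positions without materialising the full range
        draw = rng.integers(1, config.chromosome_length_bp + 1,
                            size=int(L * 1.3) + 16)
        pos = np.unique(draw)
        while pos.size < L:
            extra = rng.integers(1, config.chromosome_length_bp + 1, size=L)
            pos = np.unique(np.concatenate([pos, extra]))
        pos = np.sort(rng.choice(pos, size=L, replace=False))
        if config.init_freq is not None:
            p0 = np.full(L, float(config.init_freq))
        else:
            lo = 1.0 / (2.0 * n_individuals)
            p0 = np.clip(rng.beta(0.5, 0.5, L), lo, 1.0 - lo)
        h = (rng.random((2 * n_individuals, L)) < p0).astype(np.int8)
        haps.append(h)
        positions.append(pos)
        pos_m.append(pos * morgans_per_bp)
        chrom_lens_m.append(config.chromosome_length_bp * morgans_per_bp)
    return haps, positions, pos_m, chrom_lens_m


def _sample_panel(rng, config, haps, positions, name, sample_size,
                  kept_sites=None, pooled_haps=None):
    """Draw a sample, ascertain markers, apply missingness, build the panel.

    If ``kept_sites`` is given, that marker set is used as-is (shared-set
    mode for split scenarios); otherwise sites are ascertained at
    ``maf_ascertainment`` in this sample and down-sampled to the target.
    Returns (panel, sampled individual indices, kept site indices).
    """
    n_ind = haps[0].shape[0] // 2
    idx = np.sort(rng.choice(n_ind, size=sample_size, replace=False))
    dos_per_chrom = [h[2 * idx] + h[2 * idx + 1] for h in haps]

    if kept_sites is None:
        asc_dos = dos_per_chrom if pooled_haps is None else \
            [h[0::2] + h[1::2] for h in pooled_haps]
        kept_sites = []
        total = 0
        for d in asc_dos:
            p = d.mean(axis=0) / 2.0
            maf = np.minimum(p, 1.0 - p)
            keep = np.nonzero(maf >= config.maf_ascertainment)[0]
            kept_sites.append(keep)
            total += keep.size
        if total > config.n_segregating_target:
            # down-sample uniformly across the pooled kept set
            flat = np.concatenate([np.stack([np.full(k.size, ci), k], axis=1)
                                   for ci, k in enumerate(kept_sites)])
            pick = np.sort(rng.choice(flat.shape[0], config.n_segregating_target,
                                      replace=False))
            sel = flat[pick]
            kept_sites = [np.sort(sel[sel[:, 0] == ci, 1])
                          for ci in range(len(kept_sites))]

    ids, chroms, poss, cols = [], [], [], []
    for ci, (d, pos, keep) in enumerate(zip(dos_per_chrom, positions, kept_sites)):
        cols.append(d[:, keep])
        chroms += [str(ci + 1)] * keep.size
        poss += [int(p) for p in pos[keep]]
        ids += [f"snp_{ci + 1}_{int(p)}" for p in pos[keep]]
    dosages = np.concatenate(cols, axis=1).astype(np.int8)
    if config.missing_rate > 0:
        miss = rng.random(dosages.shape) < config.missing_rate
        dosages[miss] = MISSING
    n = len(ids)
    marker_map = MarkerMap(
        np.asarray(ids, dtype=object),
        np.asarray(chroms, dtype=object),
        np.asarray(poss, dtype=np.int64),
        np.full(n, "A", dtype=object),
        np.full(n, "B", dtype=object),
    )
    sample_ids = [f"{name}_{i:04d}" for i in range(sample_size)]
    panel = GenotypePanel(name, sample_ids, dosages, marker_map)
    return panel, idx, kept_sites


def simulate_wf(config: SimConfig):
    """Simulate a single population and sample a genotype panel.

    Returns (panel, truth): the panel holds ``sample_size`` diploids at the
    ascertained markers; ``truth`` records the realized trajectory, true
    final-population allele frequencies at every seeded site, the final
    generation's pedigree and the sampled indices.
    """
    rng = np.random.default_rng(config.seed)
    anc = config.ancestral_ne
    haps, positions, pos_m, clens = _init_population(rng, config, anc)

    realized = []
    moms = dads = None
    for _ in range(config.burn_in_generations):
        haps, moms, dads = _advance(rng, haps, pos_m, clens, anc, config.mating,
                                    config.mutation_rate)
    for t in range(config.span - 1, -1, -1):
        ne = config.ne_at(t)
        haps, moms, dads = _advance(rng, haps, pos_m, clens, ne, config.mating,
                                    config.mutation_rate)
        realized.append((t, ne))
    if moms is None:     # zero-length run: still one generation for a pedigree
        haps, moms, dads = _advance(rng, haps, pos_m, clens, anc, config.mating,
                                    config.mutation_rate)

    name = "pop1"
    panel, idx, kept = _sample_panel(rng, config, haps, positions, name,
                                     config.sample_size)
    true_freqs = {name: [h.mean(axis=0) for h in haps]}
    truth = SimTruth(config=config, seed=config.seed,
                     realized_trajectory=realized or [(0, anc)],
                     split_times=None, true_freqs=true_freqs,
                     pedigree={name: (moms, dads)},
                     sampled_indices={name: idx}, kept_sites=kept)
    return panel, truth


def simulate_split(config: SimConfig):
    """Simulate nested population splits and sample one panel per population.

    ``config.split_times`` maps population names to divergence times
    (generations ago).  Starting from a burned-in ancestral population, each
    population branches off the shared lineage at its split time and then
    drifts independently at ``config.pop_ne[name]`` (ancestral Ne by default).
    All panels share one marker set, ascertained in the pooled sample
    (emulating a common-SNP array intersection).

    Returns (list of GenotypePanel, SimTruth).
    """
    if not config.split_times or len(config.split_times) < 2:
        raise ValueError("split_times must name at least two populations")
    times = dict(config.split_times)
    if any(t < 0 for t in times.values()):
        raise ValueError("split times must be >= 0 generations ago")
    t_max = max(times.values())
    # a bifurcating topology needs its final (most recent) split to be shared
    # by the two lineages it separates
    t_min = min(times.values())
    if sum(1 for t in times.values() if t == t_min) < 2:
        raise ValueError("non-nested split specification: the most recent "
                         "split time must be shared by at least two populations")
    pop_ne = config.pop_ne or {}
    pop_n = config.pop_sample_size or {}
    anc = config.ancestral_ne

    rng = np.random.default_rng(config.seed)
    haps, positions, pos_m, clens = _init_population(rng, config, anc)
    for _ in range(config.burn_in_generations):
        haps, _, _ = _advance(rng, haps, pos_m, clens, anc, config.mating,
                                 config.mutation_rate)

    # lineages: list of (member population names, haplotype pools, pedigree)
    lineages = [(sorted(times, key=lambda k: (-times[k], k)), haps, (None, None))]
    for t in range(t_max, -1, -1):
        new_lineages = []
        for members, pool, ped in lineages:
            splitting = [p for p in members if times[p] == t and len(members) > 1]
            staying = [p for p in members if p not in splitting]
            for p in splitting:
                new_lineages.append(([p], pool, ped))
            if staying:
                new_lineages.append((staying, pool, ped))
        lineages = []
        for members, pool, ped in new_lineages:
            ne = int(pop_ne.get(members[0], anc)) if len(members) == 1 else anc
            if t > 0:
                pool, moms, dads = _advance(rng, pool, pos_m, clens, ne,
                                            config.mating, config.mutation_rate)
                ped = (moms, dads)
            lineages.append((members, pool, ped))

    by_pop = {}
    for members, pool, ped in lineages:
        for p in members:
            by_pop[p] = (pool, ped)

    # shared ascertainment on the pooled final populations
    order = sorted(times, key=lambda k: (times[k], k))
    pooled = [np.concatenate([by_pop[p][0][ci] for p in order], axis=0)
              for ci in range(config.n_chromosomes)]
    panels, truth_freqs, pedigree, sampled = [], {}, {}, {}
    kept = None
    for p in order:
        pool, ped = by_pop[p]
        n_s = int(pop_n.get(p, config.sample_size))
        panel, idx, kept = _sample_panel(
            rng, config, pool, positions, p, n_s,
            kept_sites=kept, pooled_haps=pooled if kept is None else None)
        panels.append(panel)
        truth_freqs[p] = [h.mean(axis=0) for h in pool]
        pedigree[p] = ped
        sampled[p] = idx

    truth = SimTruth(config=config, seed=config.seed,
                     realized_trajectory=[(0, anc)], split_times=times,
                     true_freqs=truth_freqs, pedigree=pedigree,
                     sampled_indices=sampled, kept_sites=kept)
    return panels, truth


def ascertain_snps(panels, maf_threshold: float, reference: int = 0):
    """Restrict panels to markers with MAF >= threshold in a reference panel.

    ``panels`` may be a single panel or a list sharing one marker map; the
    filter is computed on ``panels[reference]`` and applied to all.  Warns if
    the result is empty.
    """
    from .qc import _maf_array

    single = isinstance(panels, GenotypePanel)
    plist = [panels] if single else list(panels)
    maf = _maf_array(plist[reference])
    keep = np.nonzero(np.nan_to_num(maf, nan=0.0) >= maf_threshold)[0]
    if keep.size == 0:
        logger.warning("ascertain_snps: no markers pass MAF >= %g", maf_threshold)
    out = [p.subset_markers(keep) for p in plist]
    return out[0] if single else out


# ---------------------------------------------------------------------------
# Truth-side summaries
# ---------------------------------------------------------------------------

def expected_heterozygosity(freqs: Sequence[np.ndarray]) -> float:
    """Mean 2p(1-p) over all seeded sites (fixed sites included)."""
    allp = np.concatenate([np.asarray(f) for f in freqs])
    return float(np.mean(2.0 * allp * (1.0 - allp)))


def fst_hudson(p1: np.ndarray, p2: np.ndarray, n1: int, n2: int) -> float:
    """Hudson's FST estimator from two populations' allele frequencies.

    Ratio-of-averages form with finite-sample correction of the numerator;
    sites fixed in both populations are excluded.
    """
    p1 = np.asarray(p1, dtype=np.float64)
    p2 = np.asarray(p2, dtype=np.float64)
    seg = ~(((p1 == 0) & (p2 == 0)) | ((p1 == 1) & (p2 == 1)))
    p1, p2 = p1[seg], p2[seg]
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return float(num.sum() / den.sum())
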