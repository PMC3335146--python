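"""Funnel-cross and introgression simulation.

Two engines share one reproduction model:

* an array engine tracking full haplotypes (numpy ``(n, 2, L)`` per
  chromosome), used for allele-frequency envelopes, LD comparisons and
  multi-marker regional likelihoods; and
* a single-locus genotype-count engine (multinomial transitions over the
  three genotype classes), used by the likelihood grid where only the focal
  marker's final frequency matters.  At one marker the two engines are
  distributionally identical; the count engine makes 10^5-scale replicate
  funnels tractable.

Reproduction follows a gamete-pool model: each offspring independently
either selfs (probability = selfing rate; both gametes from one weighted
hermaphrodite draw) or unites two gametes from independent weighted parent
draws, sampling with replacement as if gametes were in large excess.
Selection enters before mating as the sampling weight w = 1 + n*s, with n
the number of favored alleles carried (0, 1 or 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import GeneticMap, Individual, rng_stream


# ---------------------------------------------------------------------------
# Designs and selection model
# ---------------------------------------------------------------------------

@dataclass
class FunnelDesign:
    """Stage sizes for one hybridization cycle of the pairwise funnel.

    Each cycle has a cross phase (reciprocal F1 -> F2 -> F3, then the F4
    merge of reciprocals) followed by an expansion phase of
    ``expansion_generations`` generations at ``expansion_size`` with
    selfing rate ``expansion_selfing``.  A 2^k-isolate funnel runs k such
    cycles.
    """

    n_f1: int = 10
    n_f2: int = 10
    n_f3: int = 10
    n_f4: int = 20
    expansion_size: int = 1000
    expansion_generations: int = 3
    expansion_selfing: float = 0.5

    def __post_init__(self):
        for name in ("n_f1", "n_f2", "n_f3", "n_f4",
                     "expansion_size", "expansion_generations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (2 <= self.expansion_generations <= 4):
            raise ValueError("expansion_generations must be in 2..4")
        if not 0 <= self.expansion_selfing <= 1:
            raise ValueError("expansion_selfing must be a proportion")


@dataclass
class IntrogressionDesign:
    """Recurrent backcross design moving a donor allele into a recipient."""

    n_cycles: int = 10
    females_per_cycle: Sequence[int] = (53, 53, 53, 53, 53, 53, 53, 53, 105, 199)
    donor_chromosome: str = "X"
    donor_marker: int = 0
    donor_allele: int = 1

    def __post_init__(self):
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        sizes = list(self.females_per_cycle)
        if len(sizes) != self.n_cycles:
            raise ValueError("females_per_cycle must have n_cycles entries")
        if any(n < 1 for n in sizes):
            raise ValueError("cycle sizes must be >= 1")


@dataclass
class SelectionModel:
    """Single-locus additive selection: sampling weight w = 1 + n*s."""

    chromosome: str
    marker: int
    s: float
    favored_allele: int = 1

    def __post_init__(self):
        if self.s < 0:
            raise ValueError("s must be >= 0")


def fitness_weight(individual: Individual, model: Optional[SelectionModel]) -> float:
    """w = 1 + n*s for an Individual (n in 0..2; 0/1 on a hemizygous X)."""
    if model is None or model.s == 0:
        return 1.0
    g = individual.genotypes[model.chromosome]
    n = g.allele_count(model.marker, model.favored_allele)
    return 1.0 + n * model.s


# ---------------------------------------------------------------------------
# Array engine: populations as per-chromosome haplotype arrays
# ---------------------------------------------------------------------------

@dataclass
class HaplotypePool:
    """A population of n diploids as {chrom: (n, 2, L) allele arrays}."""

    maps: dict  # chrom -> GeneticMap
    haps: dict  # chrom -> np.ndarray (n, 2, L) of small ints

    def __post_init__(self):
        sizes = {h.shape[0] for h in self.haps.values()}
        if len(sizes) != 1:
            raise ValueError("inconsistent individual counts across chromosomes")

    @property
    def n(self) -> int:
        return next(iter(self.haps.values())).shape[0]

    def allele_frequencies(self, allele: int = 1) -> dict:
        """Per-chromosome frequency of `allele` at each marker."""
        return {c: (h == allele).mean(axis=(0, 1)) for c, h in self.haps.items()}

    def genotype_counts(self, chrom: str, marker: int, allele: int) -> np.ndarray:
        n_cop = (self.haps[chrom][:, :, marker] == allele).sum(axis=1)
        return np.bincount(n_cop, minlength=3)[:3]

    @classmethod
    def from_homozygote(cls, maps: dict, haplotypes: dict, n: int) -> "HaplotypePool":
        """n clonal homozygous diploids of one founder haplotype set."""
        haps = {}
        for chrom, h in haplotypes.items():
            h = np.asarray(h)
            haps[chrom] = np.broadcast_to(h, (n, 2, h.shape[-1])).copy()
        return cls(maps=maps, haps=haps)

    @classmethod
    def concatenate(cls, pools: Sequence["HaplotypePool"]) -> "HaplotypePool":
        maps = pools[0].maps
        haps = {c: np.concatenate([p.haps[c] for p in pools], axis=0)
                for c in maps}
        return cls(maps=maps, haps=haps)


def _vector_gametes(haps: np.ndarray, weights: np.ndarray, idx: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Vectorized meiosis for parents haps[idx]: one gamete per index.

    Crossover with probability 0.5, at most one per gamete, interval chosen
    with probability proportional to inter-marker cM.
    """
    m = idx.shape[0]
    L = haps.shape[2]
    ha = haps[idx, 0, :]
    hb = haps[idx, 1, :]
    start = rng.integers(0, 2, size=m)
    if L > 1 and weights.sum() > 0:
        crossed = rng.random(m) < 0.5
        cut = rng.choice(L - 1, size=m, p=weights)
    else:
        crossed = np.zeros(m, dtype=bool)
        cut = np.zeros(m, dtype=np.int64)
    pos = np.arange(L)
    switched = crossed[:, None] & (pos[None, :] > cut[:, None])
    src = start[:, None] ^ switched
    return np.where(src == 0, ha, hb)


def _selection_weights(pool: HaplotypePool,
                       model: Optional[SelectionModel]) -> Optional[np.ndarray]:
    if model is None or model.s == 0:
        return None
    h = pool.haps[model.chromosome][:, :, model.marker]
    n = (h == model.favored_allele).sum(axis=1)
    return 1.0 + n * model.s


def _draw_parents(n: int, m: int, weights: Optional[np.ndarray],
                  rng: np.random.Generator) -> np.ndarray:
    if weights is None:
        return rng.integers(0, n, size=m)
    p = weights / weights.sum()
    return rng.choice(n, size=m, p=p)


def reproduce(pool: HaplotypePool, n_offspring: int, selfing_rate: float,
              selection: Optional[SelectionModel],
              rng: np.random.Generator) -> HaplotypePool:
    """One within-population generation under the gamete-pool model."""
    w = _selection_weights(pool, selection)
    mothers = _draw_parents(pool.n, n_offspring, w, rng)
    fathers = _draw_parents(pool.n, n_offspring, w, rng)
    if selfing_rate > 0:
        selfed = rng.random(n_offspring) < selfing_rate
        fathers = np.where(selfed, mothers, fathers)
    haps = {}
    for chrom, gmap in pool.maps.items():
        ivw = gmap.interval_weights
        ga = _vector_gametes(pool.haps[chrom], ivw, mothers, rng)
        gb = _vector_gametes(pool.haps[chrom], ivw, fathers, rng)
        haps[chrom] = np.stack([ga, gb], axis=1)
    return HaplotypePool(maps=pool.maps, haps=haps)


def cross_pools(mother_pool: HaplotypePool, father_pool: HaplotypePool,
                n_offspring: int, selection: Optional[SelectionModel],
                rng: np.random.Generator) -> HaplotypePool:
    """Cross two populations: maternal gametes from one, paternal from the other."""
    wm = _selection_weights(mother_pool, selection)
    wf = _selection_weights(father_pool, selection)
    mothers = _draw_parents(mother_pool.n, n_offspring, wm, rng)
    fathers = _draw_parents(father_pool.n, n_offspring, wf, rng)
    haps = {}
    for chrom, gmap in mother_pool.maps.items():
        ivw = gmap.interval_weights
        ga = _vector_gametes(mother_pool.haps[chrom], ivw, mothers, rng)
        gb = _vector_gametes(father_pool.haps[chrom], ivw, fathers, rng)
        haps[chrom] = np.stack([ga, gb], axis=1)
    return HaplotypePool(maps=mother_pool.maps, haps=haps)


def _funnel_once(design: FunnelDesign, founders: Sequence[HaplotypePool],
                 selection: Optional[SelectionModel],
                 rng: np.random.Generator) -> HaplotypePool:
    """Run the pairwise funnel tree down to a single merged population."""
    lineages = list(founders)
    while len(lineages) > 1:
        merged = []
        for a, b in zip(lineages[0::2], lineages[1::2]):
            f1a = cross_pools(a, b, design.n_f1, selection, rng)
            f1b = cross_pools(b, a, design.n_f1, selection, rng)
            f2a = reproduce(f1a, design.n_f2, 0.0, selection, rng)
            f2b = reproduce(f1b, design.n_f2, 0.0, selection, rng)
            f3a = reproduce(f2a, design.n_f3, 0.0, selection, rng)
            f3b = reproduce(f2b, design.n_f3, 0.0, selection, rng)
            half = max(design.n_f4 // 2, 1)
            f4 = HaplotypePool.concatenate([
                cross_pools(f3a, f3b, half, selection, rng),
                cross_pools(f3b, f3a, design.n_f4 - half, selection, rng),
            ])
            pop = f4
            for _ in range(design.expansion_generations):
                pop = reproduce(pop, design.expansion_size,
                                design.expansion_selfing, selection, rng)
            merged.append(pop)
        lineages = merged
    return lineages[0]


def simulate_funnel(design: FunnelDesign, parental_haplotypes: Sequence[dict],
                    maps: dict, selection: Optional[SelectionModel],
                    n_sims: int, rng: np.random.Generator,
                    allele: int = 1, return_pools: bool = False):
    """Replicate funnel crosses from homozygous founders.

    parental_haplotypes: one {chrom: (L,) allele vector} per isolate; the
    isolate count must be a power of two.  Returns a dict
    {chrom: (n_sims, L) final allele-frequency matrix} (and the final pools
    when return_pools).
    """
    k = len(parental_haplotypes)
    if k < 2 or (k & (k - 1)) != 0:
        raise ValueError("parental isolate count must be a power of two")
    founders = [HaplotypePool.from_homozygote(maps, h, design.n_f1)
                for h in parental_haplotypes]
    freqs = {c: np.empty((n_sims, m.n_markers)) for c, m in maps.items()}
    pools = []
    for i in range(n_sims):
        final = _funnel_once(design, founders, selection, rng)
        for c, f in final.allele_frequencies(allele).items():
            freqs[c][i] = f
        if return_pools:
            pools.append(final)
    if return_pools:
        return freqs, pools
    return freqs


# ---------------------------------------------------------------------------
# Single-locus genotype-count engine (exact same reproduction model)
# ---------------------------------------------------------------------------

_MENDEL_SELF = np.array([
    [1.0, 0.0, 0.0],
    [0.25, 0.5, 0.25],
    [0.0, 0.0, 1.0],
])


def _weighted_genotype_probs(counts: np.ndarray, s: float) -> np.ndarray:
    w = np.array([1.0, 1.0 + s, 1.0 + 2.0 * s])
    wt = counts * w
    return wt / wt.sum(axis=-1, keepdims=True)


def _multinomial3(n: int, p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorized Multinomial(n, p) over leading axes of p (..., 3)."""
    p = np.clip(p, 0.0, 1.0)
    p = p / p.sum(axis=-1, keepdims=True)
    n0 = rng.binomial(n, p[..., 0])
    rest = n - n0
    denom = 1.0 - p[..., 0]
    p1 = np.divide(p[..., 1], denom, out=np.zeros_like(denom),
                   where=denom > 1e-12)
    n1 = rng.binomial(rest, np.clip(p1, 0.0, 1.0))
    return np.stack([n0, n1, rest - n1], axis=-1)


def _count_within(counts: np.ndarray, n_offspring: int, selfing: float,
                  s: float, rng: np.random.Generator) -> np.ndarray:
    """One generation of the count engine; counts shape (..., 3)."""
    q = _weighted_genotype_probs(counts, s)
    a = 0.5 * q[..., 1] + q[..., 2]
    pi_out = np.stack([(1 - a) ** 2, 2 * a * (1 - a), a ** 2], axis=-1)
    pi_self = q @ _MENDEL_SELF
    pi = selfing * pi_self + (1 - selfing) * pi_out
    return _multinomial3(n_offspring, pi, rng)


def _count_cross(counts_m: np.ndarray, counts_f: np.ndarray, n_offspring: int,
                 s: float, rng: np.random.Generator) -> np.ndarray:
    qm = _weighted_genotype_probs(counts_m, s)
    qf = _weighted_genotype_probs(counts_f, s)
    am = 0.5 * qm[..., 1] + qm[..., 2]
    af = 0.5 * qf[..., 1] + qf[..., 2]
    pi = np.stack([(1 - am) * (1 - af),
                   am * (1 - af) + (1 - am) * af,
                   am * af], axis=-1)
    return _multinomial3(n_offspring, pi, rng)


def simulate_funnel_counts(design: FunnelDesign, n_isolates: int,
                           carrier_isolates: Sequence[int], s: float,
                           n_sims: int, rng: np.random.Generator) -> np.ndarray:
    """Funnel final frequencies of a focal allele, single-locus engine.

    carrier_isolates: founders homozygous for the favored allele (others
    carry none).  Returns final allele frequencies, shape (n_sims,).
    """
    k = n_isolates
    if k < 2 or (k & (k - 1)) != 0:
        raise ValueError("isolate count must be a power of two")
    carriers = set(carrier_isolates)
    lineages = []
    for i in range(k):
        g = np.zeros((n_sims, 3), dtype=np.int64)
        g[:, 2 if i in carriers else 0] = design.n_f1
        lineages.append(g)
    while len(lineages) > 1:
        merged = []
        for a, b in zip(lineages[0::2], lineages[1::2]):
            f1a = _count_cross(a, b, design.n_f1, s, rng)
            f1b = _count_cross(b, a, design.n_f1, s, rng)
            f2a = _count_within(f1a, design.n_f2, 0.0, s, rng)
            f2b = _count_within(f1b, design.n_f2, 0.0, s, rng)
            f3a = _count_within(f2a, design.n_f3, 0.0, s, rng)
            f3b = _count_within(f2b, design.n_f3, 0.0, s, rng)
            half = max(design.n_f4 // 2, 1)
            f4 = (_count_cross(f3a, f3b, half, s, rng)
                  + _count_cross(f3b, f3a, design.n_f4 - half, s, rng))
            pop = f4
            for _ in range(design.expansion_generations):
                pop = _count_within(pop, design.expansion_size,
                                    design.expansion_selfing, s, rng)
            merged.append(pop)
        lineages = merged
    final = lineages[0]
    return (0.5 * final[:, 1] + final[:, 2]) / final.sum(axis=1)


# ---------------------------------------------------------------------------
# Introgression
# ---------------------------------------------------------------------------

def _introgression_once(design: IntrogressionDesign, recipient: HaplotypePool,
                        donor: HaplotypePool, rng: np.random.Generator,
                        f2_batch: int = 4) -> HaplotypePool:
    chrom, m, allele = (design.donor_chromosome, design.donor_marker,
                        design.donor_allele)
    line = donor
    for n_females in design.females_per_cycle:
        f1 = cross_pools(line, recipient, max(4 * n_females, 8), None, rng)
        selected = []
        n_found = 0
        for _ in range(64):  # selfing batches until enough homozygotes scored
            f2 = reproduce(f1, f2_batch * n_females, 1.0, None, rng)
            homo = (f2.haps[chrom][:, :, m] == allele).all(axis=1)
            if homo.any():
                sub = HaplotypePool(
                    maps=f2.maps,
                    haps={c: h[homo] for c, h in f2.haps.items()})
                selected.append(sub)
                n_found += sub.n
            if n_found >= n_females:
                break
        if n_found < n_females:
            raise RuntimeError("could not recover enough donor homozygotes")
        pool = HaplotypePool.concatenate(selected)
        keep = rng.choice(pool.n, size=n_females, replace=False)
        line = HaplotypePool(maps=pool.maps,
                             haps={c: h[keep] for c, h in pool.haps.items()})
    return line


def simulate_introgression(design: IntrogressionDesign,
                           recipient: HaplotypePool, donor: HaplotypePool,
                           n_sims: int, rng: np.random.Generator,
                           allele: int = 1) -> dict:
    """Replicate introgression lines; donor-allele frequencies per marker.

    Each cycle crosses donor-homozygous females to recipient males, selfs
    the F1, and retains F2 individuals homozygous for the donor allele at
    the focal locus (genotype-based truth selection).
    """
    if design.donor_chromosome not in recipient.maps:
        raise ValueError("donor chromosome absent from map")
    maps = recipient.maps
    freqs = {c: np.empty((n_sims, m.n_markers)) for c, m in maps.items()}
    for i in range(n_sims):
        final = _introgression_once(design, recipient, donor, rng)
        for c, f in final.allele_frequencies(allele).items():
            freqs[c][i] = f
    return freqs


# ---------------------------------------------------------------------------
# Envelopes and deviation classification
# ---------------------------------------------------------------------------

@dataclass
class SimulationEnvelope:
    """Per-SNP pointwise empirical frequency bounds at a coverage level."""

    lower: np.ndarray
    upper: np.ndarray
    level: float
    n_sims: int


def neutral_envelope(sims: np.ndarray, level: float = 0.95) -> SimulationEnvelope:
    """Pointwise (alpha/2, 1 - alpha/2) quantiles per SNP column."""
    sims = np.asarray(sims, dtype=float)
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if sims.shape[0] < 40:
        raise ValueError("need at least 40 simulations for an envelope")
    alpha = 1.0 - level
    lower = np.quantile(sims, alpha / 2, axis=0)
    upper = np.quantile(sims, 1 - alpha / 2, axis=0)
    return SimulationEnvelope(lower=lower, upper=upper, level=level,
                              n_sims=sims.shape[0])


def classify_deviants(observed: np.ndarray, envelope: SimulationEnvelope):
    """Flag SNPs whose observed frequency falls outside the envelope."""
    observed = np.asarray(observed, dtype=float)
    if observed.shape != envelope.lower.shape:
        raise ValueError("observed frequencies do not match envelope markers")
    flags = (observed < envelope.lower) | (observed > envelope.upper)
    return flags, float(flags.mean())


def lost_snp_fraction(observed: np.ndarray, threshold: float = 0.026) -> float:
    """Fraction of SNPs effectively lost: minor allele frequency < threshold."""
    p = np.asarray(observed, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    maf = np.minimum(p, 1 - p)
    return float((maf < threshold).mean())
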