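"""Genome representation, genetic maps, and mating primitives.

Chromosomes are modeled as ordered vectors of SNP alleles.  Meiosis follows
a full-interference model: a single crossover occurs with probability 0.5
per gamete, its position drawn between adjacent markers with probability
proportional to the inter-marker genetic distance (cM).  Males are X0 and
hermaphrodites/females XX, so X transmission through males is handled
separately from autosomal meiosis.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

MISSING = -1

HERMAPHRODITE = "hermaphrodite"
FEMALE = "female"
MALE = "male"

ANDRODIOECIOUS = "androdioecious"
DIOECIOUS = "dioecious"


# ---------------------------------------------------------------------------
# RNG plumbing: seeded, keyed substreams so replicates are independently
# reproducible.
# ---------------------------------------------------------------------------

def rng_stream(seed: int, *keys) -> np.random.Generator:
    """Return a Generator deterministic in (seed, keys).

    Keys may be ints or strings; strings are hashed with crc32 so the
    mapping is stable across sessions and platforms.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, str):
            entropy.append(zlib.crc32(k.encode("utf8")))
        else:
            entropy.append(int(k) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(entropy))


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

@dataclass
class GeneticMap:
    """Ordered SNP markers on one chromosome with bp and cM coordinates."""

    chromosome_id: str
    marker_ids: list
    positions_bp: np.ndarray
    positions_cM: np.ndarray
    total_cM: float = 50.0
    is_x: bool = False

    def __post_init__(self):
        self.positions_bp = np.asarray(self.positions_bp, dtype=np.int64)
        self.positions_cM = np.asarray(self.positions_cM, dtype=float)
        n = len(self.marker_ids)
        if n < 2:
            raise ValueError("a genetic map needs at least 2 markers")
        if len(self.positions_bp) != n or len(self.positions_cM) != n:
            raise ValueError("marker_ids, positions_bp, positions_cM must have equal length")
        if np.any(np.diff(self.positions_bp) <= 0):
            raise ValueError("positions_bp must be strictly increasing")
        if np.any(np.diff(self.positions_cM) < 0):
            raise ValueError("positions_cM must be non-decreasing")
        if self.positions_cM[-1] - self.positions_cM[0] > self.total_cM + 1e-9:
            raise ValueError("cM span exceeds total chromosome size")

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def interval_cM(self) -> np.ndarray:
        """cM distances between adjacent markers (length n_markers - 1)."""
        return np.diff(self.positions_cM)

    @property
    def interval_weights(self) -> np.ndarray:
        """Crossover placement probabilities per inter-marker interval."""
        d = self.interval_cM
        total = d.sum()
        if total <= 0:
            return np.zeros_like(d)
        return d / total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chromosome_id,
                "id": self.marker_ids,
                "bp": self.positions_bp,
                "cM": self.positions_cM,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, chromosome_id: Optional[str] = None,
                 total_cM: float = 50.0, is_x: bool = False) -> "GeneticMap":
        df = pd.read_csv(path, sep="\t")
        required = {"chrom", "id", "bp", "cM"}
        if not required.issubset(df.columns):
            raise ValueError(f"map TSV must have columns {sorted(required)}")
        if chromosome_id is not None:
            df = df[df["chrom"] == chromosome_id]
        else:
            chroms = df["chrom"].unique()
            if len(chroms) != 1:
                raise ValueError("multiple chromosomes in map TSV; pass chromosome_id")
            chromosome_id = chroms[0]
        return cls(
            chromosome_id=str(chromosome_id),
            marker_ids=list(df["id"]),
            positions_bp=df["bp"].to_numpy(),
            positions_cM=df["cM"].to_numpy(),
            total_cM=total_cM,
            is_x=is_x,
        )


def read_map_tsv(path, total_cM: float = 50.0,
                 x_chromosome: Optional[str] = None) -> dict:
    """Read a multi-chromosome map TSV into {chrom: GeneticMap}."""
    df = pd.read_csv(path, sep="\t")
    maps = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        maps[str(chrom)] = GeneticMap(
            chromosome_id=str(chrom),
            marker_ids=list(sub["id"]),
            positions_bp=sub["bp"].to_numpy(),
            positions_cM=sub["cM"].to_numpy(),
            total_cM=total_cM,
            is_x=(str(chrom) == x_chromosome),
        )
    return maps


# ---------------------------------------------------------------------------
# Individuals and populations
# ---------------------------------------------------------------------------

@dataclass
class DiploidGenotype:
    """Pair of haplotypes; hap_b is None for the hemizygous male X."""

    hap_a: np.ndarray
    hap_b: Optional[np.ndarray] = None

    def __post_init__(self):
        self.hap_a = np.asarray(self.hap_a)
        if self.hap_b is not None:
            self.hap_b = np.asarray(self.hap_b)
            if self.hap_a.shape != self.hap_b.shape:
                raise ValueError("haplotype lengths differ")

    @property
    def is_hemizygous(self) -> bool:
        return self.hap_b is None

    def allele_count(self, marker: int, allele: int) -> int:
        n = int(self.hap_a[marker] == allele)
        if self.hap_b is not None:
            n += int(self.hap_b[marker] == allele)
        return n


@dataclass
class Individual:
    sex: str
    genotypes: dict  # chromosome_id -> DiploidGenotype
    fitness_weight: float = 1.0

    def __post_init__(self):
        if self.sex not in (HERMAPHRODITE, FEMALE, MALE):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.fitness_weight < 0:
            raise ValueError("fitness_weight must be >= 0")


@dataclass
class Population:
    individuals: list
    mating_system: str = ANDRODIOECIOUS
    generation: int = 0

    def __post_init__(self):
        if self.mating_system not in (ANDRODIOECIOUS, DIOECIOUS):
            raise ValueError(f"unknown mating system {self.mating_system!r}")
        sexes = {ind.sex for ind in self.individuals}
        if self.mating_system == ANDRODIOECIOUS and FEMALE in sexes:
            raise ValueError("androdioecious populations contain no females")
        if self.mating_system == DIOECIOUS and HERMAPHRODITE in sexes:
            raise ValueError("dioecious populations contain no hermaphrodites")

    def __len__(self):
        return len(self.individuals)

    @property
    def mothers(self) -> list:
        return [i for i in self.individuals if i.sex in (HERMAPHRODITE, FEMALE)]

    @property
    def males(self) -> list:
        return [i for i in self.individuals if i.sex == MALE]

    def allele_frequency(self, chromosome_id: str, marker: int, allele: int) -> float:
        """Frequency over all segregating chromosomes (1 per male X)."""
        count = 0
        total = 0
        for ind in self.individuals:
            g = ind.genotypes[chromosome_id]
            count += g.allele_count(marker, allele)
            total += 1 if g.is_hemizygous else 2
        return count / total if total else np.nan


# ---------------------------------------------------------------------------
# Meiosis and mating
# ---------------------------------------------------------------------------

def sample_crossover(gmap: GeneticMap, rng: np.random.Generator) -> Optional[int]:
    """Draw the crossover interval for one meiosis, or None half the time.

    Returns the index i of the interval between markers i and i+1; the
    gamete switches source haplotype for markers > i.
    """
    if rng.random() >= 0.5:
        return None
    w = gmap.interval_weights
    if w.sum() <= 0:
        raise ValueError("degenerate map: all inter-marker distances are zero")
    return int(rng.choice(len(w), p=w))


def meiosis(parent: DiploidGenotype, gmap: GeneticMap,
            rng: np.random.Generator) -> np.ndarray:
    """One gamete under the single-crossover, full-interference model."""
    if parent.is_hemizygous:
        raise ValueError("hemizygous genotype: use transmit_x")
    haps = (parent.hap_a, parent.hap_b)
    start = int(rng.integers(0, 2))
    try:
        cut = sample_crossover(gmap, rng)
    except ValueError:
        cut = None  # fully linked markers: no crossover can be realized
    gamete = haps[start].copy()
    if cut is not None:
        gamete[cut + 1:] = haps[1 - start][cut + 1:]
    return gamete


def transmit_x(father: Individual, offspring_sex: str,
               x_chromosome: str = "X") -> Optional[np.ndarray]:
    """Paternal X contribution: daughters get the single X, sons get none."""
    if father.sex != MALE:
        raise ValueError("transmit_x requires a male father")
    if offspring_sex == MALE:
        return None
    return father.genotypes[x_chromosome].hap_a.copy()


def mate(mother: Individual, father: Individual, maps: dict,
         rng: np.random.Generator, offspring_female_sex: str = HERMAPHRODITE,
         x_hemizygous: bool = True) -> Individual:
    """Join parental gametes, one meiosis per chromosome per parent.

    Offspring sex is drawn 1:1 male vs hermaphrodite/female.  On a
    chromosome flagged is_x (with x_hemizygous), the father contributes via
    transmit_x and sons are hemizygous for the maternal gamete.
    """
    if mother.sex not in (HERMAPHRODITE, FEMALE) or father.sex != MALE:
        raise ValueError("mate requires a hermaphrodite/female mother and a male father")
    sex = MALE if rng.random() < 0.5 else offspring_female_sex
    genotypes = {}
    for chrom, gmap in maps.items():
        maternal = meiosis(mother.genotypes[chrom], gmap, rng)
        if gmap.is_x and x_hemizygous:
            paternal = transmit_x(father, sex, x_chromosome=chrom)
            genotypes[chrom] = DiploidGenotype(maternal, paternal)
        else:
            fg = father.genotypes[chrom]
            if fg.is_hemizygous:
                paternal = fg.hap_a.copy()
            else:
                paternal = meiosis(fg, gmap, rng)
            genotypes[chrom] = DiploidGenotype(maternal, paternal)
    return Individual(sex=sex, genotypes=genotypes)


def self_fertilize(parent: Individual, maps: dict,
                   rng: np.random.Generator) -> Individual:
    """Join two independent gametes from one hermaphrodite.

    Offspring are hermaphrodites; X non-disjunction males are not modeled
    in the derivation simulations.
    """
    if parent.sex != HERMAPHRODITE:
        raise ValueError("self_fertilize requires a hermaphrodite parent")
    genotypes = {}
    for chrom, gmap in maps.items():
        a = meiosis(parent.genotypes[chrom], gmap, rng)
        b = meiosis(parent.genotypes[chrom], gmap, rng)
        genotypes[chrom] = DiploidGenotype(a, b)
    return Individual(sex=HERMAPHRODITE, genotypes=genotypes)


def _weighted_pick(individuals: list, rng: np.random.Generator):
    w = np.array([i.fitness_weight for i in individuals], dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("all candidate parents have zero fitness weight")
    return individuals[int(rng.choice(len(individuals), p=w / total))]


def next_generation(pop: Population, maps: dict, n_offspring: int,
                    selfing_rate: float, rng: np.random.Generator,
                    x_hemizygous: bool = True) -> Population:
    """Produce n_offspring by fitness-weighted sampling with replacement.

    Each offspring independently selfs (probability selfing_rate, from a
    weighted hermaphrodite draw) or outcrosses (weighted mother x weighted
    male father), mirroring reproduction with a large excess of gametes.
    """
    if not pop.individuals:
        raise ValueError("empty population")
    if pop.mating_system == DIOECIOUS and selfing_rate > 0:
        raise ValueError("selfing is impossible in a dioecious population")
    mothers = pop.mothers
    males = pop.males
    if not males and selfing_rate < 1:
        raise ValueError("no males present but outcrossing requested")
    female_sex = FEMALE if pop.mating_system == DIOECIOUS else HERMAPHRODITE
    offspring = []
    for _ in range(n_offspring):
        if rng.random() < selfing_rate:
            parent = _weighted_pick(
                [i for i in pop.individuals if i.sex == HERMAPHRODITE], rng)
            offspring.append(self_fertilize(parent, maps, rng))
        else:
            mother = _weighted_pick(mothers, rng)
            father = _weighted_pick(males, rng)
            offspring.append(
                mate(mother, father, maps, rng,
                     offspring_female_sex=female_sex,
                     x_hemizygous=x_hemizygous))
    return Population(individuals=offspring, mating_system=pop.mating_system,
                      generation=pop.generation + 1)
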