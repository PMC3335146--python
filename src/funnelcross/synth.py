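"""Synthetic inputs with known ground truth.

Generates everything the pipeline consumes: genetic maps with
recombination-rate domains (high-rate arms, a low-rate center and
near-silent telomere caps, as mapped for C. elegans chromosomes IV and X),
panels of homozygous wild-isolate founder genotypes with a controlled
number of distinct genotypes, observed-style genotype samples with missing
calls, and plate-level sex-census tables with an imperfect male detection
probability.  Every generator is deterministic under a fixed Generator and
returns truth alongside data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import GeneticMap
from .diversity import MISSING, GenotypeMatrix

# Fractions of chromosome length per recombination domain:
# telomere, left arm, center, right arm, telomere.
DEFAULT_DOMAIN_FRACTIONS = (0.02, 0.20, 0.56, 0.20, 0.02)
TELOMERE_RATE = 0.1  # cM/Mb; telomeres recombine rarely

# Meiotic crossover rates (cM/Mb) for arm/center/arm domains.
CHROM_IV_RATES = (7.65, 1.05, 3.64)
CHROM_X_RATES = (3.81, 1.7, 5.14)

CHROM_IV_LENGTH_BP = 17_500_000
CHROM_X_LENGTH_BP = 17_700_000


@dataclass
class DomainMapSpec:
    """Recombination-rate domain structure for one chromosome."""

    chromosome_id: str = "IV"
    length_bp: int = CHROM_IV_LENGTH_BP
    arm_center_rates: Sequence[float] = CHROM_IV_RATES  # left arm, center, right arm
    domain_fractions: Sequence[float] = DEFAULT_DOMAIN_FRACTIONS
    telomere_rate: float = TELOMERE_RATE
    total_cM: float = 50.0
    is_x: bool = False

    def __post_init__(self):
        if self.length_bp <= 0:
            raise ValueError("zero-length chromosome")
        if len(self.arm_center_rates) != 3 or len(self.domain_fractions) != 5:
            raise ValueError("expect 3 arm/center rates and 5 domain fractions")
        if any(r < 0 for r in self.arm_center_rates) or self.telomere_rate < 0:
            raise ValueError("rates must be >= 0")
        if abs(sum(self.domain_fractions) - 1.0) > 1e-9:
            raise ValueError("domain fractions must sum to 1")

    @property
    def rates(self) -> np.ndarray:
        la, c, ra = self.arm_center_rates
        return np.array([self.telomere_rate, la, c, ra, self.telomere_rate])

    @property
    def boundaries_bp(self) -> np.ndarray:
        """Domain edges, length 6 (0 .. length_bp)."""
        edges = np.concatenate([[0.0], np.cumsum(self.domain_fractions)])
        return np.round(edges * self.length_bp).astype(np.int64)

    def cM_at(self, bp: np.ndarray) -> np.ndarray:
        """Cumulative genetic position: integral of rate over physical distance."""
        bp = np.asarray(bp, dtype=float)
        edges = self.boundaries_bp.astype(float)
        rates = self.rates
        cum_edges = np.concatenate(
            [[0.0], np.cumsum(rates * np.diff(edges) / 1e6)])
        dom = np.clip(np.searchsorted(edges, bp, side="right") - 1,
                      0, len(rates) - 1)
        return cum_edges[dom] + rates[dom] * (bp - edges[dom]) / 1e6


def x_map_spec() -> DomainMapSpec:
    return DomainMapSpec(chromosome_id="X", length_bp=CHROM_X_LENGTH_BP,
                         arm_center_rates=CHROM_X_RATES, is_x=True)


def make_map(spec: DomainMapSpec, n_snps: int,
             rng: np.random.Generator) -> GeneticMap:
    """SNP positions uniform along the chromosome; cM integrates the rates."""
    if n_snps < 2:
        raise ValueError("need at least 2 SNPs")
    bp = np.sort(rng.choice(np.arange(1, spec.length_bp), size=n_snps,
                            replace=False))
    cm = spec.cM_at(bp)
    if cm[-1] - cm[0] > spec.total_cM:
        raise ValueError("domain rates integrate past the total map length")
    ids = [f"{spec.chromosome_id}_snp{k:04d}" for k in range(n_snps)]
    return GeneticMap(chromosome_id=spec.chromosome_id, marker_ids=ids,
                      positions_bp=bp, positions_cM=cm,
                      total_cM=spec.total_cM, is_x=spec.is_x)


@dataclass
class PanelSpec:
    """Founder panel shape: 16 isolates sharing 14 distinct genotypes."""

    n_isolates: int = 16
    n_distinct_genotypes: int = 14
    block_snps: int = 10  # mosaic block length controlling panel LD

    def __post_init__(self):
        if not 1 <= self.n_distinct_genotypes <= self.n_isolates:
            raise ValueError("n_distinct_genotypes must be in 1..n_isolates")
        if self.block_snps < 1:
            raise ValueError("block_snps must be >= 1")


def _mosaic_haplotypes(n_distinct: int, n_snps: int, block: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Distinct haplotypes as random block mosaics, polymorphic everywhere."""
    if n_distinct > 2 ** min(n_snps, 30):
        raise ValueError("more distinct genotypes than allele strings")
    # enough blocks that n_distinct distinct mosaics exist
    min_blocks = max(1, int(np.ceil(np.log2(max(n_distinct, 2)))) + 1)
    block = max(1, min(block, n_snps // min_blocks)) if n_snps >= min_blocks else 1
    n_blocks = int(np.ceil(n_snps / block))
    n_patterns = 2 ** min(n_blocks, 30)
    for _ in range(1000):
        codes = rng.choice(n_patterns, size=n_distinct, replace=False)
        bits = ((codes[:, None] >> np.arange(n_blocks)) & 1).astype(np.int8)
        haps = np.repeat(bits, block, axis=1)[:, :n_snps]
        # every SNP polymorphic in the panel (monomorphic assays are dropped
        # in the real pipeline before analysis)
        mono_hi = haps.all(axis=0)
        mono_lo = ~haps.any(axis=0)
        for j in np.flatnonzero(mono_hi):
            haps[rng.integers(n_distinct), j] = 0
        for j in np.flatnonzero(mono_lo):
            haps[rng.integers(n_distinct), j] = 1
        if n_distinct == 1 or len({tuple(h) for h in haps}) == n_distinct:
            return haps
    raise RuntimeError("failed to draw distinct haplotypes")


def make_parental_panel(spec: PanelSpec, maps: dict,
                        rng: np.random.Generator):
    """Homozygous founder genotypes.

    Returns (parental_haplotypes, truth) where parental_haplotypes is a
    list of {chrom: (L,) allele vector}, one per isolate (duplicated
    isolates are exact copies), and truth records the assignment of
    isolates to distinct genotypes and per-SNP panel frequencies.
    """
    if spec.n_distinct_genotypes == 1:
        assignment = np.zeros(spec.n_isolates, dtype=int)
    else:
        # first n_distinct isolates get the distinct genotypes, the
        # remainder duplicate the earliest ones
        extras = rng.integers(0, spec.n_distinct_genotypes,
                              size=spec.n_isolates - spec.n_distinct_genotypes)
        assignment = np.concatenate(
            [np.arange(spec.n_distinct_genotypes), extras])
    per_chrom = {}
    for chrom, gmap in maps.items():
        per_chrom[chrom] = _mosaic_haplotypes(
            spec.n_distinct_genotypes, gmap.n_markers, spec.block_snps, rng)
    parents = [{chrom: per_chrom[chrom][g] for chrom in maps}
               for g in assignment]
    truth = {
        "assignment": assignment.tolist(),
        "n_distinct": int(len({tuple(np.concatenate([p[c] for c in maps]))
                               for p in parents})),
        "panel_frequencies": {
            chrom: per_chrom[chrom][assignment].mean(axis=0).tolist()
            for chrom in maps
        },
    }
    return parents, truth


def make_observed_sample(haps: dict, maps: dict, n_individuals: int,
                         missing_rate: float,
                         rng: np.random.Generator) -> GenotypeMatrix:
    """Sample diploids without replacement and inject missing calls.

    haps: {chrom: (n, 2, L)} population haplotype arrays (a
    HaplotypePool's ``haps``).  Calls are unphased dosages with missing
    entries at rate missing_rate, emulating a genotyping panel.
    """
    if missing_rate >= 1 or missing_rate < 0:
        raise ValueError("missing_rate must lie in [0, 1)")
    pop_n = next(iter(haps.values())).shape[0]
    if n_individuals > pop_n:
        raise ValueError("sample exceeds population size")
    pick = rng.choice(pop_n, size=n_individuals, replace=False)
    blocks = []
    frames = []
    for chrom, gmap in maps.items():
        h = haps[chrom][pick]
        blocks.append((h[:, 0, :] + h[:, 1, :]).astype(np.int8))
        frames.append(pd.DataFrame({"chrom": chrom, "id": gmap.marker_ids,
                                    "bp": gmap.positions_bp}))
    calls = np.concatenate(blocks, axis=1)
    if missing_rate > 0:
        calls[rng.random(calls.shape) < missing_rate] = MISSING
    markers = pd.concat(frames, ignore_index=True)
    samples = [f"ind{k:03d}" for k in range(n_individuals)]
    return GenotypeMatrix(calls=calls, markers=markers, samples=samples)


def make_census(true_m: float, detection: float, n_plates: int,
                rng: np.random.Generator, plate_mean: int = 1000,
                population: str = "A", replicate: int = 1,
                generation: int = 0) -> pd.DataFrame:
    """Plate-level sex census with imperfect male detection.

    Plate totals are Poisson(plate_mean); true male counts are
    Binomial(total, true_m); each male is scored as male with probability
    `detection`, and undetected males are tallied among the non-males
    (missed or misidentified), so the observed male frequency is
    true_m * detection in expectation.
    """
    if not 0 <= true_m <= 1:
        raise ValueError("true_m must lie in [0, 1]")
    if not 0 < detection <= 1:
        raise ValueError("detection must lie in (0, 1]")
    totals = rng.poisson(plate_mean, size=n_plates)
    males_true = rng.binomial(totals, true_m)
    males_seen = rng.binomial(males_true, detection)
    others = totals - males_seen
    return pd.DataFrame({
        "population": population,
        "replicate": replicate,
        "generation": generation,
        "plate": np.arange(1, n_plates + 1),
        "males": males_seen,
        "others": others,
    })
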