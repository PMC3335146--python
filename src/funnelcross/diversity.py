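"""Genotype QC, composite LD, and windowed haplotype statistics.

Genotype matrices are individuals x markers arrays of biallelic calls
coded 0 (hom-ref), 1 (het), 2 (hom-alt) with -1 for missing.  Haplotype
sets are (2n) x markers allele arrays (two consecutive rows per diploid).
Windowed statistics slide along the marker order with step 1 and are
anchored at the mean physical position of the markers in the window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Unphased diploid calls plus marker metadata (chrom, id, bp)."""

    calls: np.ndarray  # (n_individuals, n_markers), int8-ish
    markers: pd.DataFrame
    samples: list

    def __post_init__(self):
        self.calls = np.asarray(self.calls)
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise ValueError("calls shape does not match samples x markers")
        valid = np.isin(self.calls, [0, 1, 2, MISSING])
        if not valid.all():
            raise ValueError("calls must be coded 0/1/2 or -1 (missing)")

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Alt-allele frequency per marker over non-missing calls."""
        c = np.ma.masked_equal(self.calls, MISSING)
        return np.asarray(c.mean(axis=0) / 2.0)

    def minor_allele_frequencies(self) -> np.ndarray:
        p = self.allele_frequencies()
        return np.minimum(p, 1 - p)


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    removed_snps: list
    removed_individuals_missing: list
    removed_individuals_tail: list


def qc_filter(matrix: GenotypeMatrix, snp_missing_max: float = 0.8,
              ind_missing_max: float = 0.5,
              density_tail: float = 0.05):
    """Three sequential missing-data filters.

    1. drop SNPs with missing fraction > snp_missing_max;
    2. drop individuals with missing fraction > ind_missing_max;
    3. drop individuals whose remaining missing fraction exceeds the
       (1 - density_tail) quantile of the distribution (upper tail of the
       missingness density; with a flat distribution nothing is removed).
    Returns (filtered GenotypeMatrix, QCReport).
    """
    for thr in (snp_missing_max, ind_missing_max, density_tail):
        if not 0 < thr <= 1:
            raise ValueError("thresholds must lie in (0, 1]")
    calls = matrix.calls
    miss = calls == MISSING

    snp_frac = miss.mean(axis=0)
    keep_snp = snp_frac <= snp_missing_max
    removed_snps = [matrix.markers["id"].iloc[j]
                    for j in np.flatnonzero(~keep_snp)]
    calls = calls[:, keep_snp]
    if calls.shape[1] == 0:
        raise ValueError("QC step 1 (SNP missingness) removed every SNP")

    miss = calls == MISSING
    ind_frac = miss.mean(axis=1)
    keep_ind = ind_frac <= ind_missing_max
    removed_ind = [matrix.samples[i] for i in np.flatnonzero(~keep_ind)]
    calls = calls[keep_ind]
    samples = [s for s, k in zip(matrix.samples, keep_ind) if k]
    if calls.shape[0] == 0:
        raise ValueError("QC step 2 (individual missingness) removed every individual")

    ind_frac = (calls == MISSING).mean(axis=1)
    cutoff = np.quantile(ind_frac, 1 - density_tail)
    keep_tail = ind_frac <= cutoff
    removed_tail = [samples[i] for i in np.flatnonzero(~keep_tail)]
    calls = calls[keep_tail]
    samples = [s for s, k in zip(samples, keep_tail) if k]
    if calls.shape[0] == 0:
        raise ValueError("QC step 3 (upper-tail missingness) removed every individual")

    out = GenotypeMatrix(calls=calls,
                         markers=matrix.markers[keep_snp].reset_index(drop=True),
                         samples=samples)
    return out, QCReport(removed_snps=removed_snps,
                         removed_individuals_missing=removed_ind,
                         removed_individuals_tail=removed_tail)


def maf_filter(matrix_a: GenotypeMatrix, matrix_b: GenotypeMatrix,
               threshold: float = 0.05) -> np.ndarray:
    """Markers kept iff MAF >= threshold in BOTH populations.

    (A marker with low MAF in either population is removed.)  Returns a
    boolean keep-mask over the shared marker order.
    """
    if matrix_a.n_markers != matrix_b.n_markers:
        raise ValueError("matrices must share marker order")
    return ((matrix_a.minor_allele_frequencies() >= threshold)
            & (matrix_b.minor_allele_frequencies() >= threshold))


# ---------------------------------------------------------------------------
# Composite linkage disequilibrium
# ---------------------------------------------------------------------------

def composite_r2(matrix: GenotypeMatrix, i: int, j: int) -> float:
    """Burrows' composite-disequilibrium r^2 from unphased genotypes.

    Delta = (sum X*Y) / (2n) - 2 p_i p_j over pairwise-complete
    individuals, with X, Y the 0/1/2 allele-dosage calls;
    r^2 = Delta^2 / (p_i q_i p_j q_j), clipped to [0, 1].
    """
    x = matrix.calls[:, i].astype(float)
    y = matrix.calls[:, j].astype(float)
    ok = (x != MISSING) & (y != MISSING)
    x, y = x[ok], y[ok]
    if x.size == 0:
        raise ValueError("no pairwise-complete individuals")
    pi = x.mean() / 2
    pj = y.mean() / 2
    if pi in (0.0, 1.0) or pj in (0.0, 1.0):
        raise ValueError("undefined r²: monomorphic marker")
    delta = (x * y).sum() / (2 * x.size) - 2 * pi * pj
    r2 = delta ** 2 / (pi * (1 - pi) * pj * (1 - pj))
    return float(min(r2, 1.0))


def phased_to_unphased(haps: np.ndarray, markers: Optional[pd.DataFrame] = None,
                       samples: Optional[list] = None) -> GenotypeMatrix:
    """Collapse consecutive haplotype pairs to unphased dosage calls."""
    haps = np.asarray(haps)
    if haps.shape[0] % 2:
        raise ValueError("odd haplotype count; need 2 per diploid")
    a, b = haps[0::2], haps[1::2]
    calls = a + b
    calls[(a == MISSING) | (b == MISSING)] = MISSING
    n, L = calls.shape
    if markers is None:
        markers = pd.DataFrame({"chrom": "1", "id": [f"m{k}" for k in range(L)],
                                "bp": np.arange(1, L + 1)})
    if samples is None:
        samples = [f"ind{k}" for k in range(n)]
    return GenotypeMatrix(calls=calls.astype(np.int8), markers=markers,
                          samples=samples)


# ---------------------------------------------------------------------------
# Sliding windows over haplotypes
# ---------------------------------------------------------------------------

def _windows(n_markers: int, width: int, step: int = 1):
    if width > n_markers:
        raise ValueError("window width exceeds marker count")
    return [(s, s + width) for s in range(0, n_markers - width + 1, step)]


def _window_strings(haps: np.ndarray, start: int, end: int):
    """Distinct complete haplotype strings in a window (missing rows dropped)."""
    sub = haps[:, start:end]
    complete = ~(sub == MISSING).any(axis=1)
    return {tuple(row) for row in sub[complete]}


def _frame(windows, positions_bp, values) -> pd.DataFrame:
    centers = [float(np.mean(positions_bp[s:e])) for s, e in windows]
    return pd.DataFrame({
        "start": [s for s, _ in windows],
        "end": [e for _, e in windows],
        "center_bp": centers,
        "value": values,
    })


def window_haplotype_count(haps: np.ndarray, positions_bp: np.ndarray,
                           width: int = 10, step: int = 1) -> pd.DataFrame:
    """Number of distinct haplotype strings per sliding window."""
    wins = _windows(haps.shape[1], width, step)
    values = [len(_window_strings(haps, s, e)) for s, e in wins]
    values = [v if v > 0 else np.nan for v in values]
    return _frame(wins, np.asarray(positions_bp), values)


def parental_fraction(haps: np.ndarray, parental_haps: np.ndarray,
                      positions_bp: np.ndarray, width: int = 10,
                      step: int = 1) -> pd.DataFrame:
    """Fraction of distinct window haplotypes matching a parental string."""
    wins = _windows(haps.shape[1], width, step)
    values = []
    for s, e in wins:
        pop = _window_strings(haps, s, e)
        par = _window_strings(parental_haps, s, e)
        values.append(len(pop & par) / len(pop) if pop else np.nan)
    return _frame(wins, np.asarray(positions_bp), values)


def shared_fraction(haps_a: np.ndarray, haps_b: np.ndarray,
                    positions_bp: np.ndarray, width: int = 10,
                    step: int = 1) -> pd.DataFrame:
    """Proportion of the total (union) haplotypes common to both populations."""
    if haps_a.shape[1] != haps_b.shape[1]:
        raise ValueError("populations must share the marker set")
    wins = _windows(haps_a.shape[1], width, step)
    values = []
    for s, e in wins:
        sa = _window_strings(haps_a, s, e)
        sb = _window_strings(haps_b, s, e)
        union = sa | sb
        values.append(len(sa & sb) / len(union) if union else np.nan)
    return _frame(wins, np.asarray(positions_bp), values)


def _fst_from_counts(counts_a: dict, counts_b: dict) -> float:
    """Nei-style G_ST on haplotype frequency spectra of two samples.

    H = 1 - sum p_k^2; H_S is sample-size weighted; FST = (H_T - H_S)/H_T,
    defined as 0 when H_T = 0 and clipped to [0, 1].
    """
    n_a = sum(counts_a.values())
    n_b = sum(counts_b.values())
    if n_a < 2 or n_b < 2:
        return np.nan
    keys = set(counts_a) | set(counts_b)
    pa = np.array([counts_a.get(k, 0) / n_a for k in keys])
    pb = np.array([counts_b.get(k, 0) / n_b for k in keys])
    h_a = 1 - (pa ** 2).sum()
    h_b = 1 - (pb ** 2).sum()
    h_s = (n_a * h_a + n_b * h_b) / (n_a + n_b)
    pt = (n_a * pa + n_b * pb) / (n_a + n_b)
    h_t = 1 - (pt ** 2).sum()
    if h_t <= 0:
        return 0.0
    return float(np.clip((h_t - h_s) / h_t, 0.0, 1.0))


def _window_counts(haps: np.ndarray, start: int, end: int) -> dict:
    sub = haps[:, start:end]
    complete = ~(sub == MISSING).any(axis=1)
    counts = {}
    for row in sub[complete]:
        key = tuple(row)
        counts[key] = counts.get(key, 0) + 1
    return counts


def fst_window(haps_a: np.ndarray, haps_b: np.ndarray,
               positions_bp: np.ndarray, width: int = 10,
               step: int = 1) -> pd.DataFrame:
    """Multi-allelic FST on window-haplotype frequencies, per window."""
    if haps_a.shape[1] != haps_b.shape[1]:
        raise ValueError("populations must share the marker set")
    wins = _windows(haps_a.shape[1], width, step)
    values = [_fst_from_counts(_window_counts(haps_a, s, e),
                               _window_counts(haps_b, s, e))
              for s, e in wins]
    return _frame(wins, np.asarray(positions_bp), values)


def fst_permutation_threshold(haps_a: np.ndarray, haps_b: np.ndarray,
                              width: int, rng: np.random.Generator,
                              n_perm: int = 10000,
                              level: float = 0.95) -> float:
    """Chromosome-wide FST significance threshold by marker reshuffling.

    Each permutation reshuffles the marker column order (the same
    permutation applied to both populations, individuals untouched),
    recomputes all windowed FST values, and the threshold is the `level`
    quantile of the pooled permuted window values.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    L = haps_a.shape[1]
    wins = _windows(L, width, 1)
    pooled = np.empty(n_perm * len(wins))
    k = 0
    for _ in range(n_perm):
        order = rng.permutation(L)
        pa, pb = haps_a[:, order], haps_b[:, order]
        for s, e in wins:
            pooled[k] = _fst_from_counts(_window_counts(pa, s, e),
                                         _window_counts(pb, s, e))
            k += 1
    return float(np.nanquantile(pooled, level))


def jackknife_density_match(reference_haps: np.ndarray,
                            positions_bp: np.ndarray, target_markers: int,
                            rng: np.random.Generator, n_draws: int = 1000,
                            width: int = 10, level: float = 0.95):
    """Window haplotype counts on density-matched marker subsets.

    Each draw samples `target_markers` markers without replacement
    (preserving order) from a denser reference panel and recomputes window
    haplotype counts, giving counts comparable to a sparser SNP panel.
    Returns a DataFrame of per-window mean and (alpha/2, 1-alpha/2)
    quantiles across draws, plus the (n_draws, n_windows) count matrix.
    """
    L = reference_haps.shape[1]
    if target_markers > L:
        raise ValueError("target marker count exceeds reference panel")
    n_windows = target_markers - width + 1
    counts = np.empty((n_draws, n_windows))
    for d in range(n_draws):
        keep = np.sort(rng.choice(L, size=target_markers, replace=False))
        sub = reference_haps[:, keep]
        for w, (s, e) in enumerate(_windows(target_markers, width, 1)):
            counts[d, w] = len(_window_strings(sub, s, e))
    alpha = 1 - level
    summary = pd.DataFrame({
        "window": np.arange(n_windows),
        "mean": counts.mean(axis=0),
        "lower": np.quantile(counts, alpha / 2, axis=0),
        "upper": np.quantile(counts, 1 - alpha / 2, axis=0),
    })
    return summary, counts
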