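"""Mating-system analytics: sex ratios, outcrossing rates, inbreeding.

Under androdioecy, hermaphrodites cannot mate with each other, so every
cross involves a male; if the offspring sex ratio of crosses is 1:1 the
outcrossing rate is t = 2m, twice the male frequency.  Males that go
uncounted (fleeing assay plates, harder to spot) bias m downward; the
detectability correction rescales by c = observed/expected male frequency
measured in an obligately outcrossing (dioecious) control, where the true
male frequency is 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def plate_qc(census: pd.DataFrame, min_total: int = 500,
             max_total: int = 1500) -> pd.DataFrame:
    """Drop assay plates with totals outside [min_total, max_total]."""
    total = census["males"] + census["others"]
    kept = census[(total >= min_total) & (total <= max_total)]
    if kept.empty:
        raise ValueError("plate QC removed every plate")
    return kept.reset_index(drop=True)


def male_frequency(census: pd.DataFrame) -> float:
    """Pooled male frequency over plates."""
    total = (census["males"] + census["others"]).sum()
    return float(census["males"].sum() / total)


def outcrossing_rate(m: float) -> float:
    """Raw outcrossing rate t = 2m, reported to two decimals.

    Valid as a rate only for m <= 0.5; larger m clips at 1.
    """
    if not 0 <= m <= 1:
        raise ValueError("male frequency must lie in [0, 1]")
    return round(min(2 * m, 1.0), 2)


def detectability_correction(observed_dioecious_m: float,
                             expected: float = 0.5) -> float:
    """Male-detectability factor c = observed/expected dioecious frequency."""
    if observed_dioecious_m <= 0:
        raise ValueError("observed male frequency must be positive")
    if observed_dioecious_m > expected:
        raise ValueError("observed frequency exceeds the expected value")
    return observed_dioecious_m / expected


def corrected_outcrossing_rate(m: float, c: float) -> float:
    """Detectability-corrected rate min(1, 2m/c)."""
    if not 0 < c <= 1:
        raise ValueError("correction factor must lie in (0, 1]")
    if not 0 <= m <= 1:
        raise ValueError("male frequency must lie in [0, 1]")
    return min(2 * m / c, 1.0)


@dataclass
class OutcrossingEstimate:
    male_frequency: float
    raw_rate: float
    correction: float
    corrected_rate: float
    clipped: bool = False


def estimate_outcrossing(census: pd.DataFrame,
                         correction: float = 1.0) -> OutcrossingEstimate:
    """Plate-QC'd census -> raw and corrected outcrossing rates."""
    m = male_frequency(census)
    raw = outcrossing_rate(m)
    corrected = corrected_outcrossing_rate(m, correction)
    return OutcrossingEstimate(male_frequency=m, raw_rate=raw,
                               correction=correction,
                               corrected_rate=corrected,
                               clipped=(2 * m / correction > 1))


def expected_homozygosity(scheme: str, generations: int) -> float:
    """Expected homozygosity from a fully heterozygous base.

    selfing: heterozygosity halves each generation, H_t = (1/2)^t.
    full_sib: H_t = H_{t-1}/2 + H_{t-2}/4 with H_0 = H_1 = 1 (outbred
    founding pair).  Returns 1 - H_t.
    """
    if generations < 0:
        raise ValueError("generations must be >= 0")
    if scheme == "selfing":
        return 1.0 - 0.5 ** generations
    if scheme == "full_sib":
        h_prev2, h_prev1 = 1.0, 1.0
        if generations == 0:
            return 0.0
        for _ in range(generations - 1):
            h_prev2, h_prev1 = h_prev1, h_prev1 / 2 + h_prev2 / 4
        return 1.0 - h_prev1
    raise ValueError(f"unknown inbreeding scheme {scheme!r}")


def correlation_test(x, y):
    """Pearson r with a one-sided (r > 0) Student t-test on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length series with at least 3 points")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    df = x.size - 2
    if abs(r) >= 1.0:
        return r, np.inf * np.sign(r), 0.0 if r > 0 else 1.0
    t = r * np.sqrt(df) / np.sqrt(1 - r ** 2)
    p = float(stats.t.sf(t, df))
    return r, float(t), p


def offspring_sexratio_test(male_count: int, female_count: int):
    """1-df chi-squared test of a 1:1 offspring sex ratio."""
    total = male_count + female_count
    if total <= 0:
        raise ValueError("no offspring scored")
    expected = total / 2
    statistic = ((male_count - expected) ** 2 / expected
                 + (female_count - expected) ** 2 / expected)
    return float(statistic), float(stats.chi2.sf(statistic, df=1))


def nondisjunction_rate(male_counts, totals, level: float = 0.95):
    """Pooled male proportion across plates with an exact binomial CI."""
    males = int(np.sum(male_counts))
    total = int(np.sum(totals))
    if total <= 0:
        raise ValueError("totals must be positive")
    ci = stats.binomtest(males, total).proportion_ci(
        confidence_level=level, method="exact")
    return males / total, (float(ci.low), float(ci.high))
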