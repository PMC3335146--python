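"""QC filters, composite LD, windowed haplotype statistics and FST."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from funnelcross.core import rng_stream
from funnelcross.diversity import (MISSING, GenotypeMatrix, composite_r2,
                                   fst_permutation_threshold, fst_window,
                                   jackknife_density_match, maf_filter,
                                   parental_fraction, phased_to_unphased,
                                   qc_filter, shared_fraction,
                                   window_haplotype_count)
from funnelcross.diversity import _fst_from_counts


def _matrix(calls, ids=None):
    calls = np.asarray(calls, dtype=np.int8)
    n, L = calls.shape
    markers = pd.DataFrame({"chrom": "1",
                            "id": ids or [f"m{j}" for j in range(L)],
                            "bp": np.arange(1, L + 1) * 1000})
    return GenotypeMatrix(calls=calls, markers=markers,
                          samples=[f"s{i}" for i in range(n)])


class TestQCFilter:
    def test_clean_matrix_untouched(self):
        m = _matrix(np.zeros((10, 10)))
        out, report = qc_filter(m)
        assert out.calls.shape == (10, 10)
        assert not report.removed_snps
        assert not report.removed_individuals_missing
        assert not report.removed_individuals_tail

    def test_toy_matrix_removes_expected_snp_and_individual(self):
        calls = np.zeros((10, 10), dtype=np.int8)
        calls[:9, 3] = MISSING          # SNP 3: 90% missing -> step 1
        calls[7, :6] = MISSING          # individual 7: 60% missing -> step 2
        out, report = qc_filter(_matrix(calls))
        assert report.removed_snps == ["m3"]
        assert report.removed_individuals_missing == ["s7"]

    def test_step3_matches_quantile_oracle(self):
        rng = np.random.default_rng(0)
        calls = np.zeros((40, 20), dtype=np.int8)
        miss_frac = rng.uniform(0, 0.3, size=40)
        for i, f in enumerate(miss_frac):
            k = int(round(f * 20))
            calls[i, rng.choice(20, size=k, replace=False)] = MISSING
        out, report = qc_filter(_matrix(calls))
        frac = (calls == MISSING).mean(axis=1)
        cutoff = np.quantile(frac, 0.95)
        expected = {f"s{i}" for i in np.flatnonzero(frac > cutoff)}
        assert set(report.removed_individuals_tail) == expected

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        calls = rng.integers(0, 3, size=(30, 15)).astype(np.int8)
        calls[rng.random((30, 15)) < 0.2] = MISSING
        once, _ = qc_filter(_matrix(calls))
        twice, report = qc_filter(once)
        np.testing.assert_array_equal(once.calls, twice.calls)
        assert not report.removed_snps
        assert not report.removed_individuals_tail

    def test_empty_result_attributes_step(self):
        calls = np.full((4, 4), MISSING, dtype=np.int8)
        with pytest.raises(ValueError, match="step 1"):
            qc_filter(_matrix(calls))


class TestMAFFilter:
    def test_marker_dropped_when_rare_in_either_population(self):
        a = _matrix([[1, 1], [1, 0], [0, 1], [2, 0]])   # MAFs 0.5, 0.25
        calls_b = np.zeros((50, 2), dtype=np.int8)
        calls_b[:, 0] = 1
        calls_b[0, 1] = 1                               # MAF 0.01 at marker 1
        b = _matrix(calls_b)
        keep = maf_filter(a, b, 0.05)
        np.testing.assert_array_equal(keep, [True, False])

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(3)
        ca = rng.integers(0, 3, size=(30, 12)).astype(np.int8)
        cb = rng.integers(0, 3, size=(25, 12)).astype(np.int8)
        keep = maf_filter(_matrix(ca), _matrix(cb), 0.1)
        for j in range(12):
            mafs = []
            for c in (ca, cb):
                p = c[:, j].mean() / 2
                mafs.append(min(p, 1 - p))
            assert keep[j] == (min(mafs) >= 0.1)

    def test_marker_order_must_match(self):
        with pytest.raises(ValueError):
            maf_filter(_matrix(np.zeros((2, 3))), _matrix(np.zeros((2, 4))))


class TestCompositeR2:
    def test_perfectly_coupled_loci(self):
        calls = np.array([[0, 0]] * 5 + [[2, 2]] * 5)
        assert composite_r2(_matrix(calls), 0, 1) == pytest.approx(1.0)

    def test_independent_loci_at_hwe_product(self):
        # all 9 genotype combinations at HWE-product frequencies (p = 0.5):
        # counts 1:2:1 x 1:2:1 over 16 individuals
        rows = []
        for gi, ni in zip((0, 1, 2), (1, 2, 1)):
            for gj, nj in zip((0, 1, 2), (1, 2, 1)):
                rows += [[gi, gj]] * (ni * nj)
        assert composite_r2(_matrix(np.array(rows)), 0, 1) == pytest.approx(
            0.0, abs=1e-12)

    def test_toy_table_matches_burrows_counting_oracle(self):
        calls = np.array([[0, 1], [1, 1], [2, 2], [1, 0], [2, 1], [0, 0]])
        # Burrows' composite by direct genotype counting:
        # Delta = [2 n_22 + n_21 + n_12 + n_11/2]/n - 2 pA pB with n_gg'
        # counting hom-alt/het classes at each locus
        n = 6
        cnt = {}
        for x, y in calls:
            cnt[(x, y)] = cnt.get((x, y), 0) + 1
        term = (2 * cnt.get((2, 2), 0) + cnt.get((2, 1), 0)
                + cnt.get((1, 2), 0) + cnt.get((1, 1), 0) / 2)
        pa = calls[:, 0].mean() / 2
        pb = calls[:, 1].mean() / 2
        delta = term / n - 2 * pa * pb
        expected = delta ** 2 / (pa * (1 - pa) * pb * (1 - pb))
        assert composite_r2(_matrix(calls), 0, 1) == pytest.approx(expected)

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(4)
        calls = rng.integers(0, 3, size=(40, 4)).astype(np.int8)
        m = _matrix(calls)
        for i, j in [(0, 1), (1, 3), (0, 2)]:
            r = composite_r2(m, i, j)
            assert composite_r2(m, j, i) == pytest.approx(r)
            assert 0 <= r <= 1

    def test_monomorphic_marker_rejected(self):
        calls = np.array([[0, 1], [0, 1], [0, 0]])
        with pytest.raises(ValueError, match="monomorphic"):
            composite_r2(_matrix(calls), 0, 1)


class TestPhasedToUnphased:
    def test_collapses_pairs_to_dosage(self):
        haps = np.array([[0, 0], [0, 1], [1, 1], [1, 0]])
        m = phased_to_unphased(haps)
        np.testing.assert_array_equal(m.calls, [[0, 1], [2, 1]])

    def test_missing_propagates(self):
        haps = np.array([[MISSING, 0], [0, 1]])
        m = phased_to_unphased(haps)
        assert m.calls[0, 0] == MISSING and m.calls[0, 1] == 1

    def test_odd_haplotype_count_rejected(self):
        with pytest.raises(ValueError):
            phased_to_unphased(np.zeros((3, 2), dtype=int))

    def test_random_union_composite_matches_gametic_r2(self):
        # haplotypes with built-in gametic LD, paired at random: the
        # composite estimate from unphased dosages converges to the
        # gametic r^2 of the source haplotype pool
        rng = rng_stream(90, "union")
        pool = np.array([[0, 0], [0, 0], [1, 1], [1, 1], [0, 1], [1, 0]])
        draws = pool[rng.integers(0, len(pool), size=4000)]
        pa, pb = draws[:, 0].mean(), draws[:, 1].mean()
        pab = (draws[:, 0] * draws[:, 1]).mean()
        gametic_r2 = (pab - pa * pb) ** 2 / (pa * (1 - pa) * pb * (1 - pb))
        m = phased_to_unphased(draws)
        assert composite_r2(m, 0, 1) == pytest.approx(gametic_r2, abs=0.05)


def _window_count_oracle(haps, width):
    """Brute-force distinct-string count per window."""
    out = []
    for s in range(haps.shape[1] - width + 1):
        seen = set()
        for row in haps:
            w = row[s:s + width]
            if MISSING not in w:
                seen.add("".join(map(str, w)))
        out.append(len(seen))
    return out


class TestWindowHaplotypes:
    def test_identical_haplotypes_count_one(self):
        haps = np.tile(np.array([0, 1, 0, 1, 1]), (8, 1))
        res = window_haplotype_count(haps, np.arange(5) * 100, width=2)
        assert (res["value"] == 1).all()

    def test_all_distinct_haplotypes_counted(self):
        haps = np.eye(6, dtype=int)  # private mutation per haplotype
        res = window_haplotype_count(haps, np.arange(6) * 100, width=6)
        assert res["value"].iloc[0] == 6

    @pytest.mark.parametrize("width", [2, 5, 10])
    def test_toy_counts_match_string_set_oracle(self, width):
        rng = np.random.default_rng(7)
        haps = rng.integers(0, 2, size=(6, 12))
        res = window_haplotype_count(haps, np.arange(12) * 50, width=width)
        assert list(res["value"]) == _window_count_oracle(haps, width)

    def test_window_centered_at_mean_bp(self):
        haps = np.zeros((4, 4), dtype=int)
        bp = np.array([100, 200, 400, 800])
        res = window_haplotype_count(haps, bp, width=2)
        np.testing.assert_allclose(res["center_bp"], [150, 300, 600])

    def test_width_exceeding_markers_rejected(self):
        with pytest.raises(ValueError):
            window_haplotype_count(np.zeros((4, 3), dtype=int),
                                   np.arange(3), width=5)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2 ** 20 - 1))
    def test_count_never_decreases_when_window_extends(self, seed):
        rng = np.random.default_rng(seed)
        haps = rng.integers(0, 2, size=(8, 9))
        short = window_haplotype_count(haps, np.arange(9), width=4)
        wide = window_haplotype_count(haps, np.arange(9), width=5)
        for k in range(len(wide)):
            assert wide["value"].iloc[k] >= short["value"].iloc[k]


class TestParentalAndShared:
    def test_parental_panel_matches_itself(self):
        rng = np.random.default_rng(8)
        haps = rng.integers(0, 2, size=(10, 8))
        res = parental_fraction(haps, haps, np.arange(8), width=4)
        assert (res["value"] == 1.0).all()

    def test_pure_recombinants_share_nothing(self):
        parental = np.zeros((4, 6), dtype=int)
        pop = np.ones((4, 6), dtype=int)
        res = parental_fraction(pop, parental, np.arange(6), width=3)
        assert (res["value"] == 0.0).all()

    def test_shared_fraction_set_arithmetic(self):
        a = np.array([[0, 0], [0, 1], [1, 1]])
        b = np.array([[0, 1], [1, 0], [1, 1]])
        res = shared_fraction(a, b, np.array([10, 20]), width=2)
        # distinct A = {00,01,11}, distinct B = {01,10,11}: 2 shared of 4
        assert res["value"].iloc[0] == pytest.approx(0.5)

    def test_identical_and_disjoint_populations(self):
        a = np.array([[0, 0], [1, 1]])
        assert shared_fraction(a, a.copy(), np.array([1, 2]),
                               width=2)["value"].iloc[0] == 1.0
        b = np.array([[0, 1], [1, 0]])
        assert shared_fraction(a, b, np.array([1, 2]),
                               width=2)["value"].iloc[0] == 0.0


class TestFST:
    def test_identical_spectra_give_zero(self):
        a = np.array([[0, 0]] * 4 + [[1, 1]] * 4)
        res = fst_window(a, a.copy(), np.array([1, 2]), width=2)
        assert res["value"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_fixed_alternative_haplotypes_give_one(self):
        a = np.zeros((6, 2), dtype=int)
        b = np.ones((6, 2), dtype=int)
        res = fst_window(a, b, np.array([1, 2]), width=2)
        assert res["value"].iloc[0] == pytest.approx(1.0)

    def test_single_shared_haplotype_defined_as_zero(self):
        a = np.zeros((4, 2), dtype=int)
        assert _fst_from_counts({(0, 0): 4}, {(0, 0): 4}) == 0.0

    def test_two_population_spectra_match_hand_computation(self):
        # pop A: haplotype x 3, y 1; pop B: x 1, y 3
        counts_a = {"x": 3, "y": 1}
        counts_b = {"x": 1, "y": 3}
        h_a = 1 - (0.75 ** 2 + 0.25 ** 2)
        h_b = h_a
        h_s = (4 * h_a + 4 * h_b) / 8
        h_t = 1 - 2 * 0.5 ** 2
        expected = (h_t - h_s) / h_t
        assert _fst_from_counts(counts_a, counts_b) == pytest.approx(expected)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2 ** 20 - 1))
    def test_range_and_relabeling_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 2, size=(10, 4))
        b = rng.integers(0, 2, size=(12, 4))
        res = fst_window(a, b, np.arange(4), width=2)["value"].to_numpy()
        assert np.all((res >= 0) & (res <= 1))
        flipped = fst_window(1 - a, 1 - b, np.arange(4),
                             width=2)["value"].to_numpy()
        np.testing.assert_allclose(res, flipped)


class TestPermutationThreshold:
    def test_identical_populations_never_significant(self):
        rng = np.random.default_rng(11)
        a = rng.integers(0, 2, size=(20, 12))
        obs = fst_window(a, a.copy(), np.arange(12), width=4)["value"]
        thr = fst_permutation_threshold(a, a.copy(), 4,
                                        rng_stream(93, "perm"), n_perm=200)
        assert (obs <= thr).all()

    def test_differentiated_block_exceeds_threshold(self):
        rng = np.random.default_rng(12)
        base = rng.integers(0, 2, size=(20, 12))
        a = base.copy()
        b = base.copy()
        b[:, 4:8] = 1 - b[:, 4:8]  # strongly differentiated middle block
        b[:10, 4:8] = rng.integers(0, 2, size=(10, 4))
        obs = fst_window(a, b, np.arange(12), width=4)["value"].to_numpy()
        thr = fst_permutation_threshold(a, b, 4, rng_stream(94, "perm"),
                                        n_perm=200)
        block_windows = obs[3:6]
        assert block_windows.max() > thr

    def test_threshold_stable_across_seeds(self):
        rng = np.random.default_rng(13)
        a = rng.integers(0, 2, size=(15, 10))
        b = rng.integers(0, 2, size=(15, 10))
        t1 = fst_permutation_threshold(a, b, 3, rng_stream(95, "s1"),
                                       n_perm=400)
        t2 = fst_permutation_threshold(a, b, 3, rng_stream(95, "s2"),
                                       n_perm=400)
        assert t1 == pytest.approx(t2, abs=0.1)

    def test_requires_enough_permutations(self):
        a = np.zeros((4, 6), dtype=int)
        with pytest.raises(ValueError):
            fst_permutation_threshold(a, a, 2, rng_stream(1), n_perm=10)


class TestJackknife:
    def test_full_panel_target_is_deterministic(self):
        rng = np.random.default_rng(14)
        haps = rng.integers(0, 2, size=(8, 10))
        summary, counts = jackknife_density_match(
            haps, np.arange(10), target_markers=10,
            rng=rng_stream(96, "j"), n_draws=20, width=4)
        assert np.all(counts == counts[0])
        oracle = _window_count_oracle(haps, 4)
        np.testing.assert_array_equal(counts[0], oracle)

    def test_subsampling_never_increases_counts(self):
        rng = np.random.default_rng(15)
        haps = rng.integers(0, 2, size=(10, 20))
        summary, counts = jackknife_density_match(
            haps, np.arange(20), target_markers=12,
            rng=rng_stream(97, "j"), n_draws=50, width=5)
        # a subsampled window is a projection of the contiguous full-panel
        # region it spans, so it can only merge haplotype classes; replay
        # the draw stream to recover each draw's marker subset
        replay = rng_stream(97, "j")
        for d in range(50):
            keep = np.sort(replay.choice(20, size=12, replace=False))
            for w in range(12 - 5 + 1):
                cols = keep[w:w + 5]
                span = haps[:, cols[0]:cols[-1] + 1]
                full_count = len({tuple(r) for r in span})
                assert counts[d, w] <= full_count

    def test_distinct_haplotype_bound_respected(self):
        # synthetic worldwide reference carrying 41 distinct haplotypes
        rng = np.random.default_rng(16)
        distinct = rng.integers(0, 2, size=(41, 30))
        haps = distinct[rng.integers(0, 41, size=127)]
        summary, counts = jackknife_density_match(
            haps, np.arange(30), target_markers=18,
            rng=rng_stream(98, "j"), n_draws=30, width=10)
        assert counts.max() <= 41

    def test_target_exceeding_panel_rejected(self):
        with pytest.raises(ValueError):
            jackknife_density_match(np.zeros((4, 5), dtype=int),
                                    np.arange(5), target_markers=6,
                                    rng=rng_stream(99, "j"))
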