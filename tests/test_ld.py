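import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sldp_gp.genotype import compute_maf
from sldp_gp.ld import (
    MarkerPanel, PruneConfig, R2_EPS, ld_prune, mark_important, pairwise_r2,
    sldp_prune,
)

from conftest import make_gm


def greedy_prune_oracle(dosage, thr, important=()):
    """Brute-force single-window pruning oracle.

    Scans all pairs (i, j), i < j, by increasing index on an r^2 matrix
    from an independent correlation routine, applying the same retention
    and tie-break rules as the implementation.
    """
    dosage = np.asarray(dosage, dtype=float)
    m = dosage.shape[1]
    sd = dosage.std(axis=0)
    with np.errstate(invalid="ignore"):
        r2 = np.corrcoef(dosage.T) ** 2
    r2[np.isnan(r2)] = 0.0
    r2[sd == 0, :] = 0.0
    r2[:, sd == 0] = 0.0
    p = dosage.mean(axis=0) / 2.0
    maf = np.minimum(p, 1 - p)
    imp = set(important)
    alive = [True] * m
    for i in range(m):
        if not alive[i]:
            continue
        for j in range(i + 1, m):
            if not alive[i]:
                break
            if not alive[j]:
                continue
            if r2[i, j] >= thr - R2_EPS:
                if i in imp and j in imp:
                    continue
                if i in imp:
                    alive[j] = False
                elif j in imp:
                    alive[i] = False
                elif maf[i] < maf[j]:
                    alive[i] = False
                else:
                    alive[j] = False
    return np.flatnonzero(alive)


def random_ld_dosage(rng, n, m, rho=0.85):
    """Markov-correlated dosage columns for oracle fixtures."""
    haps = np.empty((2 * n, m))
    haps[:, 0] = rng.random(2 * n) < 0.5
    for j in range(1, m):
        keep = rng.random(2 * n) < rho
        haps[:, j] = np.where(keep, haps[:, j - 1], rng.random(2 * n) < 0.5)
    return haps[0::2] + haps[1::2]


class TestPairwiseR2:
    def test_self_correlation_is_one(self):
        x = np.array([0, 1, 2, 0, 1.0])
        assert pairwise_r2(x, x) == pytest.approx(1.0)

    def test_allele_flip_symmetry(self):
        x = np.array([0, 1, 2, 0, 1.0])
        assert pairwise_r2(x, 2 - x) == pytest.approx(1.0)

    def test_matches_correlation_oracle(self):
        x = np.array([0, 1, 2, 0.0])
        y = np.array([0, 1, 1, 0.0])
        expected = np.corrcoef(x, y)[0, 1] ** 2  # independent oracle
        assert pairwise_r2(x, y) == pytest.approx(expected, abs=1e-12)
        assert pairwise_r2(y, x) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_flagged_as_zero(self):
        assert pairwise_r2(np.ones(5), np.array([0, 1, 2, 1, 0.0])) == 0.0

    def test_missing_entries_mean_imputed(self):
        x = np.array([0, 1, 2, np.nan, 1.0])
        xi = np.array([0, 1, 2, 1.0, 1.0])
        y = np.array([0, 2, 2, 0, 1.0])
        assert pairwise_r2(x, y) == pytest.approx(np.corrcoef(xi, y)[0, 1] ** 2)


class TestLdPrune:
    def test_no_pair_reaches_threshold_keeps_all(self):
        rng = np.random.default_rng(0)
        gm = make_gm(rng.integers(0, 3, (100, 30)).astype(float))
        panel = ld_prune(gm, PruneConfig(r2_threshold=1.0, window_snps=30,
                                         step_snps=10))
        assert len(panel) == 30

    def test_threshold_one_removes_only_complete_ld(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 3, 80).astype(float)
        noisy = rng.integers(0, 3, (80, 3)).astype(float)
        gm = make_gm(np.column_stack([x, noisy[:, 0], x, noisy[:, 1:]]))
        panel = ld_prune(gm, PruneConfig(r2_threshold=1.0))
        # exactly one of the two duplicate columns (0 and 2) removed
        assert sum(k in panel.kept for k in (0, 2)) == 1
        assert len(panel) == 4

    @pytest.mark.parametrize("seed,thr", [(0, 0.2), (1, 0.5), (2, 0.8),
                                          (3, 0.05), (4, 1.0)])
    def test_matches_bruteforce_oracle_single_window(self, seed, thr):
        rng = np.random.default_rng(seed)
        dosage = random_ld_dosage(rng, 120, 50)
        gm = make_gm(dosage)
        panel = ld_prune(gm, PruneConfig(r2_threshold=thr, window_snps=500,
                                         step_snps=200))
        np.testing.assert_array_equal(panel.kept, greedy_prune_oracle(dosage, thr))

    def test_kept_count_monotone_in_threshold(self, small_panel):
        sizes = [len(ld_prune(small_panel, PruneConfig(r2_threshold=t)))
                 for t in np.linspace(1.0, 0.05, 20)]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_adjacent_duplicates_resolved_across_window_boundaries(self):
        # adjacent duplicate pairs are always co-windowed on first
        # evaluation, so exactly one member of each pair must fall
        rng = np.random.default_rng(7)
        base = rng.integers(0, 3, (150, 60)).astype(float)
        cols = []
        dup_pairs = []
        for j in range(60):
            cols.append(base[:, j])
            if j % 7 == 0:
                dup_pairs.append((len(cols) - 1, len(cols)))
                cols.append(base[:, j])
        gm = make_gm(np.column_stack(cols))
        panel = ld_prune(gm, PruneConfig(r2_threshold=1.0, window_snps=20,
                                         step_snps=8))
        kept = set(panel.kept)
        for a, b in dup_pairs:
            assert (a in kept) != (b in kept)


class TestSldpPrune:
    def test_empty_important_identical_to_ldp(self, small_panel):
        cfg = PruneConfig(r2_threshold=0.3)
        np.testing.assert_array_equal(
            sldp_prune(small_panel, [], cfg).kept,
            ld_prune(small_panel, cfg).kept)

    def test_important_pair_in_complete_ld_both_retained(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 3, 60).astype(float)
        gm = make_gm(np.column_stack([x, x, rng.integers(0, 3, (60, 2))]))
        panel = sldp_prune(gm, [0, 1], PruneConfig(r2_threshold=1.0))
        assert {0, 1} <= set(panel.kept)

    def test_mixed_pair_removes_ordinary_member(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 3, 60).astype(float)
        gm = make_gm(np.column_stack([x, x, rng.integers(0, 3, (60, 2))]))
        panel = sldp_prune(gm, [1], PruneConfig(r2_threshold=1.0))
        assert 1 in panel.kept and 0 not in panel.kept

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_bruteforce_oracle_with_retention(self, seed):
        rng = np.random.default_rng(100 + seed)
        dosage = random_ld_dosage(rng, 120, 50)
        important = rng.choice(50, size=8, replace=False)
        gm = make_gm(dosage)
        panel = sldp_prune(gm, important, PruneConfig(r2_threshold=0.4,
                                                      window_snps=500,
                                                      step_snps=200))
        np.testing.assert_array_equal(
            panel.kept, greedy_prune_oracle(dosage, 0.4, important))

    @given(seed=st.integers(0, 10_000), thr=st.floats(0.05, 1.0),
           n_imp=st.integers(0, 20))
    @settings(max_examples=25, deadline=None)
    def test_important_always_subset_of_panel(self, seed, thr, n_imp):
        rng = np.random.default_rng(seed)
        dosage = random_ld_dosage(rng, 40, 30)
        # guard against monomorphic importants (still must be retained)
        important = rng.choice(30, size=n_imp, replace=False)
        gm = make_gm(dosage)
        panel = sldp_prune(gm, important, PruneConfig(r2_threshold=float(thr)))
        assert set(important) <= set(panel.kept)


class TestMarkImportant:
    def _fixture(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 3, 100).astype(float)
        partner = x.copy()
        partner[:1] = 2 - partner[:1]  # r^2 ~ 0.945: high but < 1
        far = rng.integers(0, 3, (100, 2)).astype(float)
        dosage = np.column_stack([x, partner, far])
        return make_gm(dosage, pos=[1000, 2000, 3000, 2_500_000])

    def test_significant_snp_in_set(self):
        gm = self._fixture()
        p = np.array([1e-5, 0.5, 0.5, 0.5])
        assert 0 in mark_important(p, 1e-4, gm)

    def test_high_ld_partner_joins_set(self):
        gm = self._fixture()
        p = np.array([1e-5, 0.5, 0.5, 0.5])
        got = set(mark_important(p, 1e-4, gm, r2_link=0.90))
        assert 1 in got            # r^2 > 0.9 with the hit, within the window
        assert 3 not in got        # outside the 1-Mb link window

    def test_no_hits_gives_empty_set(self):
        gm = self._fixture()
        assert mark_important(np.full(4, 0.9), 1e-4, gm).size == 0

    def test_threshold_is_strict(self):
        gm = self._fixture()
        p = np.array([1e-4, 0.5, 0.5, 0.5])
        assert mark_important(p, 1e-4, gm).size == 0


def test_marker_panel_rejects_unsorted_indices():
    with pytest.raises(ValueError):
        MarkerPanel(np.array([3, 1, 2]))
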