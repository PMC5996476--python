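"""Hardy–Weinberg exact test, EM r², and the LD-decay profile."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from pearpop.cohort import CohortConfig, LDBlockSpec, simulate_cohort
from pearpop.ld import (LDFilterConfig, half_decay_distance, hwe_exact_test,
                        ld_decay_profile, pair_r2)

from conftest import make_matrix


def oracle_hwe(n_AA, n_Aa, n_aa):
    """Full enumeration of the conditional heterozygote distribution."""
    N = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    n_rare = min(n_a, 2 * N - n_a)
    if n_rare == 0:
        return 1.0
    probs = {}
    for het in range(n_rare + 1):
        if (n_rare - het) % 2:
            continue
        hom_r = (n_rare - het) // 2
        hom_c = N - het - hom_r
        if hom_c < 0:
            continue
        logp = (het * np.log(2.0) - gammaln(hom_r + 1) - gammaln(het + 1)
                - gammaln(hom_c + 1))
        probs[het] = logp
    mx = max(probs.values())
    z = sum(np.exp(v - mx) for v in probs.values())
    dist = {k: np.exp(v - mx) / z for k, v in probs.items()}
    p_obs = dist[n_Aa]
    return sum(p for p in dist.values() if p <= p_obs * (1 + 1e-12))


class TestHweExact:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(5, 0, 0) == 1.0

    def test_two_homozygotes(self):
        """(1, 0, 1): het in {0, 2} with probabilities 1/3, 2/3 -> p = 1/3."""
        assert hwe_exact_test(1, 0, 1) == pytest.approx(1 / 3, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_AA, n_Aa, n_aa = rng.integers(0, 15, size=3)
        if n_AA + n_Aa + n_aa == 0:
            n_AA = 1
        assert hwe_exact_test(int(n_AA), int(n_Aa), int(n_aa)) == pytest.approx(
            oracle_hwe(int(n_AA), int(n_Aa), int(n_aa)), abs=1e-12)

    def test_p_in_unit_interval_everywhere(self):
        for n_AA, n_Aa, n_aa in itertools.product(range(6), repeat=3):
            if n_AA + n_Aa + n_aa == 0:
                continue
            p = hwe_exact_test(n_AA, n_Aa, n_aa)
            assert 0 < p <= 1 + 1e-12


def grid_search_r2(d1, d2, n_grid=4001):
    """Maximize the multinomial likelihood over the free haplotype frequency.

    Allele frequencies are fixed at their (observed) MLEs; only p_AB is
    free, bounded by the Fréchet limits.
    """
    both = (d1 >= 0) & (d2 >= 0)
    d1, d2 = d1[both], d2[both]
    counts = np.zeros((3, 3))
    for a, b in zip(d1, d2):
        counts[a, b] += 1
    n = counts.sum()
    pA = (2 * counts[2].sum() + counts[1].sum()) / (2 * n)
    pB = (2 * counts[:, 2].sum() + counts[:, 1].sum()) / (2 * n)
    lo, hi = max(0.0, pA + pB - 1.0), min(pA, pB)

    def loglik(pAB):
        pAb, paB = pA - pAB, pB - pAB
        pab = 1 - pA - pB + pAB
        P = np.array([
            [pab**2, 2 * pab * paB, paB**2],
            [2 * pab * pAb, 2 * (pAB * pab + pAb * paB), 2 * pAB * paB],
            [pAb**2, 2 * pAB * pAb, pAB**2],
        ])
        return np.sum(counts * np.where(counts > 0, np.log(np.maximum(P, 1e-300)), 0.0))

    # coarse grid, then two local refinements around the maximizer
    for _ in range(3):
        grid = np.linspace(lo, hi, n_grid)
        lls = [loglik(x) for x in grid]
        k = int(np.argmax(lls))
        lo = grid[max(k - 2, 0)]
        hi = grid[min(k + 2, n_grid - 1)]
    pAB = grid[k]
    D = pAB - pA * pB
    return D * D / (pA * (1 - pA) * pB * (1 - pB))


class TestPairR2:
    def test_perfect_coupling(self):
        d1 = np.array([0, 0, 2, 2, 0, 2])
        rec = pair_r2(d1, d1.copy())
        assert rec.r2 == pytest.approx(1.0, abs=1e-9)

    def test_four_corner_equilibrium(self):
        """Homozygote-only data with all four combinations: D = 0, r² = 0."""
        d1 = np.array([0, 0, 2, 2])
        d2 = np.array([0, 2, 0, 2])
        rec = pair_r2(d1, d2)
        assert rec.D == pytest.approx(0.0, abs=1e-9)
        assert rec.r2 == pytest.approx(0.0, abs=1e-9)

    def test_monomorphic_flagged_missing(self):
        rec = pair_r2(np.array([0, 0, 0]), np.array([0, 1, 2]))
        assert rec.missing and np.isnan(rec.r2)

    def test_symmetric_and_label_swap_invariant(self):
        rng = np.random.default_rng(2)
        d1 = rng.integers(0, 3, 40)
        d2 = rng.integers(0, 3, 40)
        r = pair_r2(d1, d2).r2
        assert pair_r2(d2, d1).r2 == pytest.approx(r, abs=1e-9)
        assert pair_r2(2 - d1, d2).r2 == pytest.approx(r, abs=1e-9)
        assert pair_r2(d1, 2 - d2).r2 == pytest.approx(r, abs=1e-9)

    def test_loglikelihood_nondecreasing(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            d1 = rng.integers(0, 3, 30)
            d2 = np.clip(d1 + rng.integers(-1, 2, 30), 0, 2)
            _, trace = pair_r2(d1, d2, return_trace=True)
            assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))

    @pytest.mark.parametrize("seed", range(30))
    def test_em_matches_grid_search_mle(self, seed):
        """EM converges to the multinomial MLE found by grid search."""
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(10, 40))
        # generate correlated haplotypes so double hets occur
        pA, pB = rng.uniform(0.2, 0.8, 2)
        d = rng.uniform(-0.1, 0.1)
        pAB = np.clip(pA * pB + d, max(0, pA + pB - 1) + 0.01, min(pA, pB) - 0.01)
        hap_p = np.array([1 - pA - pB + pAB, pB - pAB, pA - pAB, pAB])
        if np.any(hap_p <= 0):
            hap_p = np.clip(hap_p, 1e-3, None)
            hap_p /= hap_p.sum()
        haps = rng.choice(4, size=(n, 2), p=hap_p)
        d1 = (haps >= 2).sum(axis=1)
        d2 = (haps % 2).sum(axis=1)
        rec = pair_r2(d1, d2)
        if rec.missing:
            return
        assert rec.r2 == pytest.approx(grid_search_r2(d1, d2), abs=1e-4)


@pytest.fixture(scope="module")
def block_cohort():
    cfg = CohortConfig(
        n_chromosomes=1, chrom_length=300_000, snp_density=5.0,
        group_sizes={"Asian_wild": 12, "Asian_cultivated": 12,
                     "European_wild": 2, "European_cultivated": 2},
        ld_block_spec=LDBlockSpec(block_length=2_000, n_founders=4),
        missing_rate=0.02, seed=8,
    )
    return simulate_cohort(cfg)[0]


class TestDecayProfile:
    def test_single_site_gives_empty_profile(self):
        d = np.array([[0], [1], [2], [1]], dtype=np.int8)
        m = make_matrix(d, positions=[100], chrom_length=10_000)
        profile = ld_decay_profile(m, "Asian_wild", LDFilterConfig(max_distance=5_000),
                                   max_sites_per_chrom=None)
        assert len(profile) == 0

    def test_extreme_maf_filter_empties_profile(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(8, 20)).astype(np.int8)
        m = make_matrix(d, chrom_length=1_000)
        profile = ld_decay_profile(
            m, "Asian_wild", LDFilterConfig(max_distance=1_000, min_maf=0.51),
            max_sites_per_chrom=None)
        assert len(profile) == 0

    def test_block_structure_decays(self, block_cohort):
        """Copied-haplotype blocks give high short-range r² falling with distance."""
        profile = ld_decay_profile(
            block_cohort, "Asian_wild",
            LDFilterConfig(max_distance=20_000), max_sites_per_chrom=None)
        short = profile[profile["bin_end"] <= 1_000]["mean_r2"].mean()
        mid = profile[(profile["bin_start"] >= 2_000)
                      & (profile["bin_end"] <= 6_000)]["mean_r2"].mean()
        far = profile[profile["bin_start"] >= 10_000]["mean_r2"].mean()
        assert short > mid > far

    def test_half_decay_reached_on_block_cohort(self, block_cohort):
        profile = ld_decay_profile(
            block_cohort, "Asian_wild",
            LDFilterConfig(max_distance=20_000), max_sites_per_chrom=None)
        dist = half_decay_distance(profile)
        assert 0 < dist <= 20_000


class TestHalfDecay:
    def profile(self, means):
        edges = np.arange(len(means) + 1) * 1_000
        return pd.DataFrame({
            "bin_start": edges[:-1], "bin_end": edges[1:],
            "mean_r2": means, "n_pairs": 10,
        })

    def test_first_bin_at_or_below_half_max(self):
        """(0.8, 0.6, 0.39, 0.2): 0.39 <= 0.4 puts the answer in bin 3."""
        assert half_decay_distance(self.profile([0.8, 0.6, 0.39, 0.2])) == 2_500

    def test_flat_profile_never_decays(self):
        assert np.isnan(half_decay_distance(self.profile([0.5, 0.5, 0.5])))

    def test_interior_maximum_sets_threshold(self):
        """Max in bin 2 (0.9): first bin <= 0.45 is bin 1 itself (0.4)."""
        assert half_decay_distance(self.profile([0.4, 0.9, 0.6, 0.3])) == 500

    def test_empty_profile_raises(self):
        with pytest.raises(ValueError):
            half_decay_distance(self.profile([]).iloc[:0])
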