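"""Window statistics against brute-force oracles and closed-form values."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pearpop.diversity import (SWEEP_WINDOWS, WindowSpec, diversity_by_feature,
                               evolution_rate, tajima_constants, tajima_d,
                               window_diversity, window_fst, window_rod)
from pearpop.vcfio import read_gff3
from pearpop.cohort import write_toy_gff3

from conftest import EXCLUDE_ADMIXED, make_matrix


def brute_force_pi_count(dosages):
    """Mean pairwise allele differences summed over sites, via enumeration.

    Each called genotype contributes two allele copies; per site, π is the
    fraction of differing copy pairs over all C-choose-2 pairs (pairwise
    deletion of missing genotypes).
    """
    dosages = np.asarray(dosages)
    total = 0.0
    for s in range(dosages.shape[1]):
        copies = []
        for d in dosages[:, s]:
            if d >= 0:
                copies.extend([1] * d + [0] * (2 - d))
        if len(copies) < 2:
            continue
        pairs = list(itertools.combinations(copies, 2))
        diff = sum(1 for a, b in pairs if a != b)
        total += diff / len(pairs)
    return total


def oracle_tajima_d(pi_count, S, n):
    """Independent implementation of Tajima's D from the defining formulas."""
    if S == 0:
        return np.nan
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi_count - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


def whole_span_spec(matrix):
    L = max(matrix.chrom_lengths.values())
    return WindowSpec(window_size=L, step=L)


class TestThetaPi:
    def test_single_site_example(self):
        """C=4 copies with c=2 alt: per-site π = 2/3; θπ = 6.667e-5 over 10 kb."""
        m = make_matrix([[1], [1]], positions=[5], chrom_length=10_000)
        div = window_diversity(m, "Asian_wild", WindowSpec(10_000, 10_000))
        assert div["theta_pi_count"].iloc[0] == pytest.approx(2 / 3, abs=1e-12)
        assert div["theta_pi"].iloc[0] == pytest.approx(6.667e-5, rel=1e-3)

    def test_zero_segregating_window(self):
        m = make_matrix([[0, 2], [0, 2]], chrom_length=1_000)
        div = window_diversity(m, "Asian_wild", WindowSpec(1_000, 1_000))
        row = div.iloc[0]
        assert row["S"] == 0 and row["theta_pi"] == 0 and row["theta_w"] == 0
        assert np.isnan(row["tajima_d"])

    @pytest.mark.parametrize("seed", range(25))
    def test_brute_force_oracle(self, seed):
        """θπ (count scale) equals pair enumeration with pairwise deletion."""
        rng = np.random.default_rng(seed)
        n, s = rng.integers(2, 13), rng.integers(1, 51)
        d = rng.integers(0, 3, size=(n, s)).astype(np.int8)
        d[rng.random(d.shape) < 0.15] = -1
        m = make_matrix(d, chrom_length=10_000)
        div = window_diversity(m, "Asian_wild", whole_span_spec(m))
        assert div["theta_pi_count"].sum() == pytest.approx(
            brute_force_pi_count(d), abs=1e-12)


class TestWattersonAndTajima:
    def test_watterson_example(self):
        """S=3, n=4 chromosomes, L=10 kb: θw = 3/(1+1/2+1/3)/10000."""
        # two diploids, 3 segregating sites, no missing -> C=4 everywhere
        d = np.array([[0, 0, 0], [1, 1, 1]], dtype=np.int8)
        m = make_matrix(d, chrom_length=10_000)
        div = window_diversity(m, "Asian_wild", WindowSpec(10_000, 10_000))
        assert div["theta_w"].iloc[0] == pytest.approx(3 / (11 / 6) / 10_000, rel=1e-9)
        assert div["theta_w"].iloc[0] == pytest.approx(1.636e-4, rel=1e-3)

    def test_singletons_give_negative_d(self):
        """Five singletons among 10 chromosomes depress D below zero."""
        d = np.zeros((5, 5), dtype=np.int8)
        for s in range(5):
            d[s, s] = 1
        m = make_matrix(d, chrom_length=1_000)
        div = window_diversity(m, "Asian_wild", WindowSpec(1_000, 1_000))
        assert div["tajima_d"].iloc[0] < 0

    @pytest.mark.parametrize("n,S,pi", [(4, 3, 1.2), (10, 5, 0.9), (25, 40, 12.0),
                                        (8, 1, 0.25), (50, 100, 30.0)])
    def test_matches_independent_constants(self, n, S, pi):
        assert tajima_d(pi, S, n) == pytest.approx(oracle_tajima_d(pi, S, n), abs=1e-12)

    def test_d_zero_at_numerator_identity(self):
        """D = 0 exactly when θπ(count) = S/a1."""
        n, S = 12, 7
        pi = S / tajima_constants(n)["a1"]
        assert tajima_d(pi, S, n) == pytest.approx(0.0, abs=1e-12)


class TestFst:
    def two_group_matrix(self, d1, d2):
        d = np.vstack([d1, d2]).astype(np.int8)
        groups = ["Asian_wild"] * len(d1) + ["Asian_cultivated"] * len(d2)
        return make_matrix(d, chrom_length=1_000, groups=groups)

    def test_fixed_differences_give_one(self):
        m = self.two_group_matrix(np.zeros((3, 4)), np.full((3, 4), 2))
        fst = window_fst(m, "Asian_wild", "Asian_cultivated", WindowSpec(1_000, 1_000))
        assert fst["fst"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_single_site_plug_in_value(self):
        """p1 = p2 = 0.5 with n1 = n2 = 10 copies gives −0.1111."""
        d1 = np.array([[0], [1], [1], [2], [1]])
        d2 = np.array([[1], [1], [0], [2], [1]])
        assert d1.sum() == d2.sum() == 5
        m = self.two_group_matrix(d1, d2)
        fst = window_fst(m, "Asian_wild", "Asian_cultivated", WindowSpec(1_000, 1_000))
        expected = (0 - 0.25 / 9 - 0.25 / 9) / 0.5
        assert fst["fst"].iloc[0] == pytest.approx(expected, abs=1e-12)
        assert fst["fst"].iloc[0] == pytest.approx(-0.1111, abs=1e-4)

    def test_label_permutation_null(self):
        """Random splits of one population give mean F_ST near zero."""
        rng = np.random.default_rng(7)
        n, s = 12, 400
        d = rng.binomial(2, rng.uniform(0.1, 0.9, size=s)[None, :], size=(n, s))
        means = []
        for _ in range(300):
            perm = rng.permutation(n)
            groups = np.array(["Asian_wild"] * n, dtype=object)
            groups[perm[: n // 2]] = "Asian_cultivated"
            m = make_matrix(d, chrom_length=100_000, groups=list(groups))
            fst = window_fst(m, "Asian_wild", "Asian_cultivated",
                             WindowSpec(100_000, 100_000))
            means.append(fst["fst"].iloc[0])
        se = np.std(means) / np.sqrt(len(means))
        assert abs(np.mean(means)) < 2 * se + 1e-3

    def test_wc84_close_to_hudson_on_cohort(self, default_cohort):
        """The Weir–Cockerham option tracks Hudson on real-ish windows."""
        matrix, _ = default_cohort
        h = window_fst(matrix, "Asian_cultivated", "Asian_wild", SWEEP_WINDOWS,
                       exclude_species=EXCLUDE_ADMIXED)
        w = window_fst(matrix, "Asian_cultivated", "Asian_wild", SWEEP_WINDOWS,
                       estimator="wc84", exclude_species=EXCLUDE_ADMIXED)
        both = ~(h["fst"].isna() | w["fst"].isna())
        corr = np.corrcoef(h.loc[both, "fst"], w.loc[both, "fst"])[0, 1]
        assert corr > 0.95


class TestRod:
    def grid(self, pis):
        return pd.DataFrame({
            "chrom": "chr1", "start": np.arange(len(pis)) * 10_000,
            "end": (np.arange(len(pis)) + 1) * 10_000, "theta_pi": pis,
        })

    def test_identities(self):
        rod = window_rod(self.grid([1e-3, 0.0]), self.grid([1e-3, 5e-3]))
        assert rod["rod"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert rod["rod"].iloc[1] == pytest.approx(1.0, abs=1e-12)

    def test_wild_zero_is_missing(self):
        rod = window_rod(self.grid([1e-3]), self.grid([0.0]))
        assert np.isnan(rod["rod"].iloc[0])

    def test_genomewide_asian_magnitude(self):
        """Cultivated 4.76e-3 vs wild 5.21e-3 gives ROD 0.0864."""
        rod = window_rod(self.grid([4.76e-3]), self.grid([5.21e-3]))
        assert rod["rod"].iloc[0] == pytest.approx(0.0864, abs=5e-4)

    def test_grid_mismatch_raises(self):
        other = self.grid([1e-3, 2e-3]).assign(start=[0, 20_000], end=[10_000, 30_000])
        with pytest.raises(ValueError):
            window_rod(self.grid([1e-3, 2e-3]), other)


class TestEvolutionRate:
    def test_values(self):
        assert evolution_rate(0.0, 1e6).rate == 0.0
        assert evolution_rate(0.172, 4.5e7).rate == pytest.approx(1.911e-9, rel=1e-3)

    def test_doubling_time_halves_rate(self):
        assert evolution_rate(0.1, 2e6).rate == pytest.approx(
            evolution_rate(0.1, 1e6).rate / 2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            evolution_rate(0.1, 0.0)
        with pytest.raises(ValueError):
            evolution_rate(-0.1, 1e6)


class TestDiversityByFeature:
    @pytest.fixture
    def gff(self, tmp_path):
        path = tmp_path / "genes.gff3"
        write_toy_gff3({"chr1": 100_000}, path, gene_spacing=20_000)
        return read_gff3(path)

    def test_empty_class_zero(self, gff):
        """Sites placed in intergenic space leave the CDS class empty."""
        d = np.array([[0, 1], [1, 0]], dtype=np.int8)
        m = make_matrix(d, positions=[5_000, 6_000], chrom_length=100_000)
        table = diversity_by_feature(m, "Asian_wild", gff).set_index("feature_class")
        assert table.loc["CDS", "S"] == 0 and table.loc["CDS", "theta_pi"] == 0
        assert table.loc["intergenic", "S"] == 2

    def test_denser_class_has_higher_theta_w(self, gff):
        """2 CDS SNPs in a short class beat 1 intergenic SNP in a long one."""
        # CDS of gene 1 covers 10201-11100; intergenic includes 5000-10000
        d = np.array([[0, 0, 0], [1, 1, 1]], dtype=np.int8)
        m = make_matrix(d, positions=[5_000, 10_300, 10_400], chrom_length=100_000)
        table = diversity_by_feature(m, "Asian_wild", gff).set_index("feature_class")
        assert table.loc["CDS", "S"] == 2
        assert table.loc["intergenic", "S"] == 1
        assert table.loc["CDS", "theta_w"] > table.loc["intergenic", "theta_w"]

    def test_precedence_counts_site_once(self, gff):
        """A site inside a CDS (hence also its mRNA) is counted only in CDS."""
        d = np.array([[0], [2]], dtype=np.int8)
        m = make_matrix(d, positions=[10_300], chrom_length=100_000)
        table = diversity_by_feature(m, "Asian_wild", gff).set_index("feature_class")
        assert table.loc["CDS", "S"] == 1
        assert table.drop("CDS")["S"].sum() == 0

    def test_unknown_class_raises(self, gff):
        m = make_matrix(np.array([[0], [1]], dtype=np.int8), chrom_length=100_000)
        with pytest.raises(ValueError):
            diversity_by_feature(m, "Asian_wild", gff, classes=["promoter"])


class TestCohortLevelProperties:
    def test_wild_diversity_exceeds_cultivated(self, default_cohort):
        """Domestication drift lowers cultivated θπ genome-wide."""
        matrix, _ = default_cohort
        for region in ("Asian", "European"):
            w = window_diversity(matrix, f"{region}_wild", SWEEP_WINDOWS,
                                 exclude_species=EXCLUDE_ADMIXED)
            c = window_diversity(matrix, f"{region}_cultivated", SWEEP_WINDOWS,
                                 exclude_species=EXCLUDE_ADMIXED)
            assert np.nanmean(w["theta_pi"]) > np.nanmean(c["theta_pi"])

    def test_tajima_d_centered(self, default_cohort):
        """Genome-wide D distribution centers near zero for the drift model."""
        matrix, _ = default_cohort
        d = window_diversity(matrix, "Asian_wild", SWEEP_WINDOWS,
                             exclude_species=EXCLUDE_ADMIXED)["tajima_d"]
        assert abs(np.nanmedian(d)) < 1.0
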