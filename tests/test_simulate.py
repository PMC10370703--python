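import numpy as np
import pytest
from scipy import stats

from adnakit.eigenstrat import MISSING
from adnakit.simulate import (
    DamageModel,
    PedigreeSpec,
    SexReadModel,
    drift_tree,
    pair_pedigree,
    pseudo_haploidize,
    simulate_allele_frequencies,
    simulate_damaged_reads,
    simulate_drifted_populations,
    simulate_pedigree_genotypes,
    simulate_sex_read_counts,
    split_seed,
)


class TestAlleleFrequencies:
    def test_deterministic_for_fixed_seed(self):
        f1, p1 = simulate_allele_frequencies(500, seed=42)
        f2, p2 = simulate_allele_frequencies(500, seed=42)
        assert np.array_equal(f1, f2)
        assert p1 == p2

    def test_degenerate_uniform_is_constant(self):
        f, _ = simulate_allele_frequencies(100, a=0.5, b=0.5, seed=1)
        assert np.all(f == 0.5)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            simulate_allele_frequencies(10, a=0.9, b=0.1)
        with pytest.raises(ValueError):
            simulate_allele_frequencies(10, freq_law="beta", alpha=-1)
        with pytest.raises(ValueError):
            simulate_allele_frequencies(0)

    def test_mean_heterozygosity_matches_integral(self):
        """Sample mean of 2p(1-p) vs its closed-form integral over U(a,b).

        For p ~ U(a,b): E[2p(1-p)] = 2(E[p] - E[p^2]), with
        E[p] = (a+b)/2 and E[p^2] = (a^2+ab+b^2)/3.
        """
        a, b = 0.05, 0.95
        n = 100_000
        f, _ = simulate_allele_frequencies(n, a=a, b=b, seed=7)
        h = 2 * f * (1 - f)
        expected = 2 * ((a + b) / 2 - (a * a + a * b + b * b) / 3)
        se = h.std(ddof=1) / np.sqrt(n)
        assert abs(h.mean() - expected) < 3 * se

    def test_panel_positions_increase_within_chromosomes(self):
        _, panel = simulate_allele_frequencies(1000, seed=3)
        for c in set(panel.chromosomes):
            pos = panel.positions[panel.chromosomes == c]
            assert np.all(np.diff(pos) > 0)


class TestPedigrees:
    def test_cycle_detected(self):
        with pytest.raises(ValueError, match="cycle"):
            PedigreeSpec({"a": ("b", "c"), "b": ("a", "c"), "c": None})

    def test_r_mechanism_consistency_enforced(self):
        with pytest.raises(ValueError, match="inconsistent"):
            PedigreeSpec(
                {"a": None, "b": None},
                [(("a", "b"), 0.5, "unrelated")],
            )

    def test_parent_offspring_share_an_allele_everywhere(self):
        f, panel = simulate_allele_frequencies(2000, seed=5)
        gm = simulate_pedigree_genotypes(
            f, panel, pair_pedigree("parent-offspring"), seed=6
        )
        a = gm.calls[gm.index_of("A")]
        b = gm.calls[gm.index_of("B")]
        # opposite homozygotes would violate Mendelian transmission
        assert not np.any((a == 0) & (b == 2))
        assert not np.any((a == 2) & (b == 0))

    def test_duplicate_mechanism_copies_rows(self):
        f, panel = simulate_allele_frequencies(500, seed=8)
        gm = simulate_pedigree_genotypes(f, panel, pair_pedigree("duplicate"), 9)
        assert np.array_equal(
            gm.calls[gm.index_of("A")], gm.calls[gm.index_of("B")]
        )

    def test_founders_in_hardy_weinberg(self):
        """Founder genotype counts vs (p^2, 2pq, q^2) by pooled chi-square."""
        n = 100_000
        f, panel = simulate_allele_frequencies(
            n, a=0.3, b=0.3, seed=10
        )  # constant p so counts pool cleanly
        gm = simulate_pedigree_genotypes(f, panel, pair_pedigree("unrelated"), 11)
        founder = gm.calls[0]
        q = 0.3  # alt frequency; code counts ref alleles
        expected = np.array([q * q, 2 * q * (1 - q), (1 - q) ** 2]) * n
        observed = np.array([(founder == c).sum() for c in (0, 1, 2)])
        chi2 = ((observed - expected) ** 2 / expected).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=2)


class TestPseudoHaploidize:
    def test_homozygous_sites_keep_their_allele(self, rng):
        f, panel = simulate_allele_frequencies(300, seed=12)
        gm = simulate_pedigree_genotypes(f, panel, pair_pedigree("unrelated"), 13)
        ph = pseudo_haploidize(gm, 0.0, seed=14)
        hom = gm.calls != 1
        assert np.array_equal(ph.calls[hom], gm.calls[hom])

    def test_het_sampling_and_missingness_rates(self):
        n = 100_000
        f, panel = simulate_allele_frequencies(n, a=0.5, b=0.5, seed=15)
        gm = simulate_pedigree_genotypes(f, panel, pair_pedigree("unrelated"), 16)
        ph = pseudo_haploidize(gm, 0.2, seed=17)
        # missingness: binomial oracle
        miss = (ph.calls == MISSING).mean()
        se = np.sqrt(0.2 * 0.8 / ph.calls.size)
        assert abs(miss - 0.2) < 3 * se
        # at het sites, ref sampled half the time
        het = gm.calls == 1
        sampled = ph.calls[het]
        sampled = sampled[sampled != MISSING]
        p_ref = (sampled == 2).mean()
        assert abs(p_ref - 0.5) < 3 * np.sqrt(0.25 / len(sampled))

    def test_missingness_one_rejected(self):
        f, panel = simulate_allele_frequencies(10, seed=18)
        gm = simulate_pedigree_genotypes(f, panel, pair_pedigree("unrelated"), 19)
        with pytest.raises(ValueError):
            pseudo_haploidize(gm, 1.0)


class TestSexReads:
    def test_reproducible_counts(self):
        m = SexReadModel("XX", 1_000_000)
        assert simulate_sex_read_counts(m, 20) == simulate_sex_read_counts(m, 20)

    def test_xy_halves_x_weight(self):
        xx = SexReadModel("XX", 10).effective_weights()
        xy = SexReadModel("XY", 10).effective_weights()
        assert xy["X"] == pytest.approx(xx["X"] / 2)
        assert xy["1"] == xx["1"]

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            SexReadModel("XO", 100)
        with pytest.raises(ValueError):
            SexReadModel("XX", 0)
        with pytest.raises(ValueError):
            SexReadModel("XX", 100, weights={"1": 1.0})


class TestDamagedReads:
    def test_zero_damage_zero_mismatches(self):
        reads = simulate_damaged_reads(200, DamageModel(d0=0.0), seed=21)
        for r in reads:
            assert r.read_sequence == r.reference_sequence

    def test_terminal_rates_match_binomial_oracle(self):
        d0, lam = 0.3, 0.5
        reads = simulate_damaged_reads(
            30_000, DamageModel(d0=d0, lam=lam), reverse_fraction=0.0, seed=22
        )
        for pos, expected in ((1, d0), (2, d0 * lam)):
            opp = hit = 0
            for r in reads:
                if r.reference_sequence[pos - 1] == "C":
                    opp += 1
                    hit += r.read_sequence[pos - 1] == "T"
            se = np.sqrt(expected * (1 - expected) / opp)
            assert abs(hit / opp - expected) < 3 * se

    def test_mean_read_length(self):
        """Simulated lengths track the configured mean (cf. 65-76 bp data)."""
        reads = simulate_damaged_reads(
            20_000, DamageModel(), mean_length=70, sd_length=8, seed=23
        )
        lengths = np.array([r.length for r in reads])
        se = lengths.std(ddof=1) / np.sqrt(len(lengths))
        assert abs(lengths.mean() - 70) < 3 * se

    def test_deterministic_for_seed(self):
        r1 = simulate_damaged_reads(50, DamageModel(), seed=24)
        r2 = simulate_damaged_reads(50, DamageModel(), seed=24)
        assert r1 == r2

    def test_damage_model_validation(self):
        with pytest.raises(ValueError):
            DamageModel(d0=1.5)
        with pytest.raises(ValueError):
            DamageModel(lam=1.0)


class TestDriftedPopulations:
    def test_zero_drift_everywhere_keeps_base(self):
        f, _ = simulate_allele_frequencies(1000, a=0.2, b=0.8, seed=25)
        tree = drift_tree((0.0, [("A", 0.0), ("B", 0.0)]))
        pops = simulate_drifted_populations(tree, f, seed=26)
        assert np.array_equal(pops["A"], f)
        assert np.array_equal(pops["B"], f)

    def test_f2_additivity_oracle(self):
        """Mean (a-b)^2 equals the summed path drift times mean p0 q0."""
        n = 50_000
        f, _ = simulate_allele_frequencies(n, a=0.2, b=0.8, seed=27)
        tree = drift_tree((0.0, [("A", 0.02), ("B", 0.03)]))
        pops = simulate_drifted_populations(tree, f, seed=28)
        f2 = np.mean((pops["A"] - pops["B"]) ** 2)
        expected = 0.05 * np.mean(f * (1 - f))
        assert f2 == pytest.approx(expected, rel=0.05)

    def test_malformed_tree_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            drift_tree((0.0, "oops"))
        with pytest.raises(ValueError, match="duplicate"):
            tree = drift_tree((0.0, [("A", 0.0), ("A", 0.0)]))
            simulate_drifted_populations(tree, np.array([0.5]), 1)


def test_split_seed_children_are_stable_and_bounded():
    kids = split_seed(123, 5)
    assert kids == split_seed(123, 5)
    assert all(0 <= k < 2**31 for k in kids)
    assert len(set(kids)) == 5
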