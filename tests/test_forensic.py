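"""Forensic statistic formulas against hand values, brute force, and Table 1."""

import math
from itertools import combinations_with_replacement

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strpopgen.forensic import (
    combine,
    expected_heterozygosity,
    gene_diversity,
    locus_summary,
    match_probability,
    observed_heterozygosity,
    pic,
    power_of_exclusion,
    typical_paternity_index,
)
from strpopgen.simulate import SimulationConfig, simulate_genotypes
from strpopgen.str_data import AlleleLabel, FrequencyTable, frequency_table_from_genotypes

from conftest import make_genotypes


def freq_table(ps, n2=20, locus="L"):
    return FrequencyTable(
        {locus: {AlleleLabel(8 + i): p for i, p in enumerate(ps)}}, {locus: n2}
    )


class TestHeterozygosity:
    def test_all_homozygous_is_zero(self):
        g = make_genotypes({(10, 10): 5, (11, 11): 2})
        assert observed_heterozygosity(g, "L") == 0.0

    def test_forced_arithmetic_matches_se33_row(self):
        g = make_genotypes({(10, 11): 376, (10, 10): 24})
        assert observed_heterozygosity(g, "L") == pytest.approx(0.94)

    def test_counting_oracle(self):
        from collections import Counter

        rng = np.random.default_rng(11)
        tally: Counter = Counter()
        het = 0
        for _ in range(40):
            a, b = sorted(int(x) for x in rng.integers(10, 14, 2))
            tally[(a, b)] += 1
            het += a != b
        g = make_genotypes(dict(tally))
        assert observed_heterozygosity(g, "L") == pytest.approx(het / 40)

    def test_monomorphic_expected_is_zero(self):
        f = freq_table([1.0])
        assert expected_heterozygosity(f, "L") == 0.0

    def test_unbiased_correction(self):
        f = freq_table([0.5, 0.5], n2=20)
        assert expected_heterozygosity(f, "L") == pytest.approx(20 / 19 * 0.5)
        assert gene_diversity(f, "L") == pytest.approx(0.5)

    def test_tpox_he_from_printed_frequencies(self, kuwait_freqs):
        assert expected_heterozygosity(kuwait_freqs, "TPOX") == pytest.approx(0.661, abs=0.002)


class TestPIC:
    def test_monomorphic_zero(self):
        assert pic(freq_table([1.0]), "L") == 0.0

    def test_biallelic_hand_value(self):
        assert pic(freq_table([0.5, 0.5]), "L") == pytest.approx(0.375)

    @pytest.mark.parametrize("locus,expected", [("TPOX", 0.616), ("SE33", 0.945)])
    def test_fixture_values(self, kuwait_freqs, locus, expected):
        assert pic(kuwait_freqs, locus) == pytest.approx(expected, abs=0.002)

    @given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=8))
    @settings(max_examples=60, deadline=None)
    def test_pic_never_exceeds_gene_diversity(self, raw):
        ps = [x / sum(raw) for x in raw]
        f = freq_table(ps, n2=100)
        assert pic(f, "L") <= gene_diversity(f, "L") + 1e-12


class TestMatchProbability:
    def test_single_shared_genotype(self):
        g = make_genotypes({(10, 11): 6})
        assert match_probability(g, "L") == 1.0

    def test_observed_mode_brute_force(self):
        g = make_genotypes({(10, 10): 1, (10, 11): 2, (11, 11): 1})
        assert match_probability(g, "L") == pytest.approx(0.25**2 + 0.5**2 + 0.25**2)

    def test_dp_complements_printed_rmp(self, kuwait_stats):
        for locus in kuwait_stats.columns:
            rmp = kuwait_stats.loc["RMP", locus]
            dp = kuwait_stats.loc["DP", locus]
            assert dp == pytest.approx(1 - rmp, abs=1e-9)

    @pytest.mark.parametrize("ps", [[0.5, 0.5], [0.2, 0.3, 0.5], [0.1] * 4 + [0.6]])
    def test_hwe_mode_equals_pair_enumeration(self, ps):
        f = freq_table(ps, n2=100)
        pm = match_probability(mode="hwe_expected", f=f, locus="L")
        # oracle: enumerate all unordered genotypes and square their HWE probs
        brute = 0.0
        for i, j in combinations_with_replacement(range(len(ps)), 2):
            prob = ps[i] ** 2 if i == j else 2 * ps[i] * ps[j]
            brute += prob**2
        assert pm == pytest.approx(brute, abs=1e-12)

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            match_probability(make_genotypes({(1, 1): 2}), "L", mode="nope")


class TestHoDerivedParameters:
    @pytest.mark.parametrize(
        "ho,pe", [(0.0, 0.0), (0.5, 0.25 * (1 - 2 * 0.5 * 0.25)), (0.94, 0.878)]
    )
    def test_power_of_exclusion(self, ho, pe):
        assert power_of_exclusion(ho) == pytest.approx(pe, abs=5e-4)

    @pytest.mark.parametrize("ho,tpi", [(0.0, 0.5), (0.75, 2.0), (0.94, 8.333)])
    def test_typical_paternity_index(self, ho, tpi):
        assert typical_paternity_index(ho) == pytest.approx(tpi, abs=5e-4)

    def test_tpi_undefined_at_one(self):
        with pytest.raises(ValueError):
            typical_paternity_index(1.0)

    def test_monotone_increasing_in_ho(self):
        grid = np.linspace(0.01, 0.99, 99)
        tpi = [typical_paternity_index(h) for h in grid]
        pe = [power_of_exclusion(h) for h in grid]
        assert all(b > a for a, b in zip(tpi, tpi[1:]))
        assert all(b > a for a, b in zip(pe, pe[1:]))


class TestCombine:
    def _summary(self, pm, pe=0.5):
        from strpopgen.str_data import LocusSummary

        return LocusSummary("X", 0.8, 0.8, 0.7, pm, 1 - pm, pe, 2.5, None, 5)

    def test_single_locus(self):
        c = combine([self._summary(0.1)])
        assert c.CMP == pytest.approx(0.1)

    def test_two_locus_product(self):
        c = combine([self._summary(0.1), self._summary(0.2)])
        assert c.CMP == pytest.approx(0.02)
        assert c.CDP == pytest.approx(0.98)
        assert c.CPE == pytest.approx(1 - 0.5**2)

    def test_printed_rmp_product_near_reported_cmp(self, kuwait_stats):
        cmp_ = math.prod(kuwait_stats.loc["RMP"])
        assert cmp_ == pytest.approx(7.37e-30, rel=0.10)
        assert 1 / cmp_ == pytest.approx(1.36e29, rel=0.10)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            combine([])


class TestSimulationConsistency:
    def test_simulated_statistics_match_fixture_expectations(self, kuwait_freqs):
        """Ho/He/PIC on data simulated under HWE from the fixture (n=2000)."""
        g = simulate_genotypes(SimulationConfig(kuwait_freqs, 2000, seed=8))
        f = frequency_table_from_genotypes(g)
        n = 2000
        for locus in ("TPOX", "TH01", "D18S51", "SE33"):
            he_exp = gene_diversity(kuwait_freqs, locus)
            se = math.sqrt(he_exp * (1 - he_exp) / n)
            assert abs(observed_heterozygosity(g, locus) - he_exp) < 3 * se
            assert abs(expected_heterozygosity(f, locus) - he_exp) < 3 * se
            assert abs(pic(f, locus) - pic(kuwait_freqs, locus)) < 3 * se

    def test_locus_summary_bundle(self, kuwait_freqs):
        g = simulate_genotypes(SimulationConfig(kuwait_freqs, 200, seed=2))
        f = frequency_table_from_genotypes(g)
        s = locus_summary(g, f, "TH01")
        assert s.DP == pytest.approx(1 - s.PM, abs=1e-12)
        assert 0 <= s.PM <= 1
        assert s.TPI >= 0.5
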