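"""Per-locus forensic summary statistics and combined identification parameters.

The statistics follow the conventions of forensic STR population surveys:

* observed heterozygosity ``Ho`` — fraction of called individuals carrying
  two distinct alleles;
* unbiased expected heterozygosity ``He = (2n / (2n - 1)) (1 - sum p_i^2)``;
* polymorphic information content
  ``PIC = 1 - sum p_i^2 - (sum p_i^2)^2 + sum p_i^4``;
* random match probability ``PM`` — probability that two individuals drawn at
  random share a genotype — with discrimination power ``DP = 1 - PM``;
* power of exclusion ``PE = Ho^2 (1 - 2 Ho (1 - Ho)^2)`` and typical
  paternity index ``TPI = 1 / (2 (1 - Ho))``, both functions of ``Ho`` alone.

Across statistically independent loci the parameters combine by
multiplication: combined match probability ``CMP = prod PM_l`` and combined
power of exclusion ``CPE = 1 - prod (1 - PE_l)``.

Values are kept at full precision internally; rounding half-even to a fixed
number of decimals is applied only in the reporting layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

from .str_data import FrequencyTable, GenotypeTable, LocusSummary

__all__ = [
    "observed_heterozygosity",
    "expected_heterozygosity",
    "gene_diversity",
    "pic",
    "match_probability",
    "power_of_exclusion",
    "typical_paternity_index",
    "locus_summary",
    "combine",
    "CombinedSummary",
]


def observed_heterozygosity(g: GenotypeTable, locus: str) -> float:
    samples = g.called_samples(locus)
    if not samples:
        raise ValueError(f"locus {locus!r} has no calls")
    het = sum(1 for s in samples if g.calls[s][locus][0] != g.calls[s][locus][1])
    return het / len(samples)


def gene_diversity(f: FrequencyTable, locus: str) -> float:
    """Raw gene diversity ``1 - sum p_i^2`` (no sample-size correction)."""
    p = _norm_freqs(f, locus)
    return 1.0 - sum(x * x for x in p)


def expected_heterozygosity(f: FrequencyTable, locus: str, unbiased: bool = True) -> float:
    """Expected heterozygosity; unbiased applies the ``2n/(2n-1)`` correction."""
    n2 = f.counts_2n[locus]
    if n2 < 2:
        raise ValueError(f"locus {locus!r}: 2n={n2} < 2")
    d = gene_diversity(f, locus)
    return d * n2 / (n2 - 1) if unbiased else d


def pic(f: FrequencyTable, locus: str) -> float:
    p = _norm_freqs(f, locus)
    s2 = sum(x * x for x in p)
    s4 = sum(x ** 4 for x in p)
    return 1.0 - s2 - s2 * s2 + s4


def match_probability(
    g: GenotypeTable | None = None,
    locus: str | None = None,
    mode: str = "observed",
    f: FrequencyTable | None = None,
) -> float:
    """Random match probability at one locus.

    ``mode="observed"`` (default) sums squared *observed genotype* relative
    frequencies and requires genotype data.  ``mode="hwe_expected"`` sums
    squared HWE genotype probabilities from allele frequencies
    (``sum p_i^4 + sum_{i<j} (2 p_i p_j)^2``) and requires a frequency table.
    """
    if mode == "observed":
        if g is None or locus is None:
            raise ValueError("mode='observed' needs genotype data and a locus")
        samples = g.called_samples(locus)
        if not samples:
            raise ValueError(f"locus {locus!r} has no calls")
        tally: dict[tuple, int] = {}
        for s in samples:
            key = g.calls[s][locus]
            tally[key] = tally.get(key, 0) + 1
        n = len(samples)
        return sum((c / n) ** 2 for c in tally.values())
    if mode == "hwe_expected":
        if f is None or locus is None:
            raise ValueError("mode='hwe_expected' needs a frequency table and a locus")
        p = _norm_freqs(f, locus)
        pm = sum(x ** 4 for x in p)
        pm += sum((2 * a * b) ** 2 for a, b in combinations(p, 2))
        return pm
    raise ValueError(f"unknown mode {mode!r}")


def power_of_exclusion(Ho: float) -> float:
    if not 0.0 <= Ho <= 1.0:
        raise ValueError(f"Ho={Ho} outside [0, 1]")
    return Ho * Ho * (1.0 - 2.0 * Ho * (1.0 - Ho) ** 2)


def typical_paternity_index(Ho: float) -> float:
    if not 0.0 <= Ho < 1.0:
        raise ValueError(f"TPI undefined for Ho={Ho}")
    return 1.0 / (2.0 * (1.0 - Ho))


def locus_summary(
    g: GenotypeTable,
    f: FrequencyTable,
    locus: str,
    hwe_p: float | None = None,
    pm_mode: str = "observed",
) -> LocusSummary:
    """Assemble the full statistic bundle for one locus."""
    ho = observed_heterozygosity(g, locus)
    pm = match_probability(g=g, locus=locus, mode=pm_mode, f=f)
    return LocusSummary(
        locus=locus,
        Ho=ho,
        He=expected_heterozygosity(f, locus),
        PIC=pic(f, locus),
        PM=pm,
        DP=1.0 - pm,
        PE=power_of_exclusion(ho),
        TPI=typical_paternity_index(ho),
        hwe_p=hwe_p,
        n_alleles_observed=f.n_alleles(locus),
    )


@dataclass(frozen=True)
class CombinedSummary:
    """Multi-locus identification parameters for independent loci."""

    CMP: float
    CDP: float
    CPE: float
    per_locus: tuple[LocusSummary, ...]

    @property
    def one_in(self) -> float:
        """Reciprocal of CMP, the '1 in X' form of the match probability."""
        return 1.0 / self.CMP


def combine(per_locus: list[LocusSummary]) -> CombinedSummary:
    if not per_locus:
        raise ValueError("no loci to combine")
    # accumulate in log space; 23-locus products underflow fast
    log_cmp = sum(math.log(s.PM) for s in per_locus)
    cmp_ = math.exp(log_cmp)
    cpe = 1.0 - math.exp(sum(math.log1p(-s.PE) for s in per_locus))
    return CombinedSummary(CMP=cmp_, CDP=1.0 - cmp_, CPE=cpe, per_locus=tuple(per_locus))


def combine_match_probabilities(pms: list[float]) -> float:
    """CMP from bare per-locus match probabilities."""
    if not pms:
        raise ValueError("no loci to combine")
    return math.exp(sum(math.log(p) for p in pms))


def combine_powers_of_exclusion(pes: list[float]) -> float:
    """CPE = 1 - prod(1 - PE_l) from bare per-locus exclusion powers."""
    if not pes:
        raise ValueError("no loci to combine")
    return 1.0 - math.exp(sum(math.log1p(-p) for p in pes))


def _norm_freqs(f: FrequencyTable, locus: str) -> list[float]:
    fmap = f.freqs[locus]
    if not fmap:
        raise ValueError(f"locus {locus!r} has no alleles")
    total = sum(fmap.values())
    return [p / total for p in fmap.values()]
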