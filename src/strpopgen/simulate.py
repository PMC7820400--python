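"""Synthetic genotype data with the statistical structure the analysis assumes.

Subpopulation divergence follows the Balding–Nichols model: a subpopulation's
allele frequencies at a locus are a Dirichlet draw around the ancestral
frequencies ``p`` with concentration ``p * (1 - F) / F``, so that each allele
frequency has mean ``p_i`` and variance ``F * p_i * (1 - p_i)`` — ``F`` plays
the role of Fst.  Within a (sub)population, genotypes are drawn under
Hardy–Weinberg equilibrium: the two gene copies of each individual are i.i.d.
draws from the population's frequencies.  Admixed individuals draw the
population of origin of *each gene copy* independently from their ancestry
proportions, matching the likelihood of the admixture model used for
inference.

No mutation or genotyping-error process is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .str_data import AlleleLabel, FrequencyTable, GenotypeTable

__all__ = ["SimulationConfig", "draw_subpop_frequencies", "simulate_genotypes"]


@dataclass
class SimulationConfig:
    """Recipe for one synthetic genotype table.

    ``subpop_spec`` lists ``(label, size, F)`` triples; ``admixture_spec``
    optionally lists ``(size, ancestry_vector)`` groups whose ancestry vectors
    range over the subpopulations in ``subpop_spec`` order.  Sizes must sum to
    ``n_individuals``.
    """

    base_frequencies: FrequencyTable
    n_individuals: int
    subpop_spec: list[tuple[str, int, float]] = field(default_factory=list)
    admixture_spec: list[tuple[int, list[float]]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        for label, size, F in self.subpop_spec:
            if not 0.0 <= F < 1.0:
                raise ValueError(f"subpopulation {label!r}: F={F} outside [0, 1)")
            if size < 0:
                raise ValueError(f"subpopulation {label!r}: negative size")
        total = sum(s for _, s, _ in self.subpop_spec)
        for size, q in self.admixture_spec:
            if size <= 0:
                raise ValueError("admixed group size must be positive")
            if len(q) != len(self.subpop_spec):
                raise ValueError("ancestry vector length must match number of subpopulations")
            if abs(sum(q) - 1.0) > 1e-9:
                raise ValueError("ancestry proportions must sum to 1")
            total += size
        if self.subpop_spec and total != self.n_individuals:
            raise ValueError(
                f"group sizes sum to {total}, expected n_individuals={self.n_individuals}"
            )


def draw_subpop_frequencies(
    base: FrequencyTable, F: float, seed: int | np.random.Generator
) -> FrequencyTable:
    """Draw one subpopulation's frequency table under Balding–Nichols.

    ``F = 0`` is the defined limit and returns ``base`` unchanged.
    """
    if not 0.0 <= F < 1.0:
        raise ValueError(f"F={F} outside [0, 1)")
    if F == 0.0:
        return FrequencyTable(
            {locus: dict(fmap) for locus, fmap in base.freqs.items()},
            dict(base.counts_2n),
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scale = (1.0 - F) / F
    freqs: dict[str, dict[AlleleLabel, float]] = {}
    for locus, fmap in base.freqs.items():
        alleles = sorted(fmap)
        p = np.array([fmap[a] for a in alleles], dtype=float)
        p = p / p.sum()  # printed tables round; renormalize before drawing
        drawn = rng.dirichlet(p * scale)
        # Dirichlet can underflow to exact 0 for tiny concentrations; keep the
        # support identical to the base table.
        drawn = np.clip(drawn, 1e-12, None)
        drawn = drawn / drawn.sum()
        freqs[locus] = {a: float(x) for a, x in zip(alleles, drawn)}
    return FrequencyTable(freqs, dict(base.counts_2n))


def _draw_population(
    rng: np.random.Generator,
    freq: FrequencyTable,
    loci: list[str],
    n: int,
) -> list[dict[str, tuple[AlleleLabel, AlleleLabel]]]:
    """HWE draws: both gene copies i.i.d. from the population frequencies."""
    rows: list[dict[str, tuple[AlleleLabel, AlleleLabel]]] = [dict() for _ in range(n)]
    for locus in loci:
        fmap = freq.freqs[locus]
        alleles = sorted(fmap)
        p = np.array([fmap[a] for a in alleles], dtype=float)
        p = p / p.sum()
        draws = rng.choice(len(alleles), size=(n, 2), p=p)
        for i in range(n):
            a, b = alleles[draws[i, 0]], alleles[draws[i, 1]]
            rows[i][locus] = (a, b) if a <= b else (b, a)
    return rows


def simulate_genotypes(cfg: SimulationConfig) -> GenotypeTable:
    """Simulate a genotype table; deterministic given ``cfg.seed``.

    With an empty ``subpop_spec`` all individuals are drawn from the base
    frequencies.  Admixed individuals draw each gene copy's population of
    origin from their ancestry vector, then the allele from that population.
    """
    rng = np.random.default_rng(cfg.seed)
    base = cfg.base_frequencies
    loci = base.loci
    for locus in loci:
        if not base.freqs[locus]:
            raise ValueError(f"locus {locus!r} has an empty frequency map")

    spec = cfg.subpop_spec or [("pop", cfg.n_individuals, 0.0)]
    pop_freqs = [draw_subpop_frequencies(base, F, rng) for _, _, F in spec]

    samples: list[str] = []
    calls: dict[str, dict[str, tuple[AlleleLabel, AlleleLabel]]] = {}
    subgroup: dict[str, str] = {}
    counter = 0

    for (label, size, _), freq in zip(spec, pop_freqs):
        rows = _draw_population(rng, freq, loci, size)
        for row in rows:
            counter += 1
            sid = f"S{counter:05d}"
            samples.append(sid)
            calls[sid] = row
            subgroup[sid] = label

    for gi, (size, q) in enumerate(cfg.admixture_spec):
        qv = np.asarray(q, dtype=float)
        # per-locus allele arrays for vectorized lookup
        per_pop = []
        for freq in pop_freqs:
            per_pop.append(
                {
                    locus: (
                        sorted(freq.freqs[locus]),
                        np.array(
                            [freq.freqs[locus][a] for a in sorted(freq.freqs[locus])]
                        ),
                    )
                    for locus in loci
                }
            )
        for _ in range(size):
            counter += 1
            sid = f"S{counter:05d}"
            samples.append(sid)
            subgroup[sid] = f"admixed{gi + 1}"
            row: dict[str, tuple[AlleleLabel, AlleleLabel]] = {}
            for locus in loci:
                pair = []
                for _copy in range(2):
                    k = rng.choice(len(qv), p=qv)
                    alleles, p = per_pop[k][locus]
                    p = p / p.sum()
                    pair.append(alleles[rng.choice(len(alleles), p=p)])
                a, b = pair
                row[locus] = (a, b) if a <= b else (b, a)
            calls[sid] = row

    return GenotypeTable(samples, list(loci), calls, subgroup=subgroup)
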