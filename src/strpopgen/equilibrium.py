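"""Hardy–Weinberg exact testing and pairwise linkage-disequilibrium testing.

The HWE test is the conditional exact test: given the observed allele counts
``n_i`` at a locus, the probability of a genotype array ``{n_ij}`` under
random mating is

    P({n_ij} | {n_i}) = n! * prod_i n_i! * 2^h / ((2n)! * prod_{i<=j} n_ij!)

with ``h`` the number of heterozygotes.  The p-value is the probability of
arrays no more probable than the observed one — computed by exhaustive
enumeration over all arrays compatible with the allele counts when that
enumeration is small, and otherwise by Monte-Carlo permutation: the pooled
2n gene copies are shuffled into n pairs, and the estimator adds one to both
numerator and denominator so a permutation p-value is never zero.

The LD test is a permutation G-test on the two-locus genotype contingency
table: single-locus genotypes are the categories, the null of independence
is simulated by permuting one locus's genotypes across individuals.  This
tests association between single-locus *genotypes* and needs no haplotype
phase, which none of the downstream analyses use.

All log-probabilities use ``scipy.special.gammaln``; nothing here underflows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .str_data import GenotypeTable

__all__ = [
    "TestResult",
    "hwe_exact_test",
    "ld_test",
    "bonferroni",
    "n_pairs",
    "EXHAUSTIVE_ARRAY_LIMIT",
]

#: exhaustive HWE enumeration is used when the number of distinct genotype
#: arrays compatible with the allele counts does not exceed this
EXHAUSTIVE_ARRAY_LIMIT = 100_000

DEFAULT_N_PERM = 100_000

_LOG2 = math.log(2.0)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n_permutations: int  # 0 = exhaustive enumeration
    seed: int | None
    note: str = ""

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"p_value={self.p_value} outside (0, 1]")


# ---------------------------------------------------------------------------
# Hardy–Weinberg


def _genotype_array(g: GenotypeTable, locus: str) -> tuple[np.ndarray, np.ndarray]:
    """Return (allele codes per gene copy flat, genotype count matrix)."""
    samples = g.called_samples(locus)
    if len(samples) < 2:
        raise ValueError(f"locus {locus!r}: need >= 2 called individuals")
    alleles = sorted({a for s in samples for a in g.calls[s][locus]})
    index = {a: i for i, a in enumerate(alleles)}
    k = len(alleles)
    mat = np.zeros((k, k), dtype=np.int64)
    flat = np.empty(2 * len(samples), dtype=np.int64)
    for t, s in enumerate(samples):
        a, b = g.calls[s][locus]
        i, j = index[a], index[b]
        mat[i, j] += 1
        flat[2 * t] = i
        flat[2 * t + 1] = j
    return flat, mat


def _log_array_prob(mat: np.ndarray, log_const: float) -> float:
    """log P of a genotype array; ``log_const`` carries the count-only terms."""
    h = int(mat.sum() - np.trace(mat))
    return log_const + h * _LOG2 - float(gammaln(mat[np.triu_indices_from(mat)] + 1).sum())


def _log_const(n: int, allele_counts: np.ndarray) -> float:
    return float(
        gammaln(n + 1) + gammaln(allele_counts + 1).sum() - gammaln(2 * n + 1)
    )


def _enumerate_arrays(allele_counts: np.ndarray):
    """Generate every genotype array compatible with the allele counts.

    Arrays are upper-triangular count matrices, yielded as in-place views
    (copy before storing).  Recursion fills row i with n_ii and then n_ij
    (j > i) against the remaining per-allele budgets; bounds prune every
    branch that cannot complete, so the work is proportional to the number
    of arrays generated.
    """
    k = len(allele_counts)
    mat = np.zeros((k, k), dtype=np.int64)
    rem = allele_counts.copy()

    def fill_row(i: int):
        if i == k - 1:
            if rem[i] % 2 == 0:
                mat[i, i] = rem[i] // 2
                yield mat
                mat[i, i] = 0
            return

        def fill_cols(j: int, left: int):
            if j == k:
                yield from fill_row(i + 1)
                return
            cap_after = int(rem[j + 1 : k].sum())
            lo = max(0, left - cap_after)
            hi = min(left, int(rem[j]))
            for v in range(lo, hi + 1):
                mat[i, j] = v
                rem[j] -= v
                yield from fill_cols(j + 1, left - v)
                rem[j] += v
                mat[i, j] = 0

        budget = int(rem[i])
        cap_off = int(rem[i + 1 : k].sum())
        d_min = max(0, -(-(budget - cap_off) // 2))
        for d in range(d_min, budget // 2 + 1):
            mat[i, i] = d
            rem[i] = 0
            yield from fill_cols(i + 1, budget - 2 * d)
            rem[i] = budget
            mat[i, i] = 0

    yield from fill_row(0)


def _count_arrays(allele_counts: np.ndarray, limit: int, max_steps: int = 3_000_000) -> int:
    """Count compatible genotype arrays, or -1 once ``limit`` is exceeded.

    With every allele count at its minimum of 1 the arrays are the perfect
    matchings of 2n elements, (2n-1)!!, which alone passes 10^5 by 15
    alleles — so many-allele tables short-circuit.  Otherwise a bounded
    plain recursion counts; ``max_steps`` caps the node visits so the gate
    itself stays cheap.
    """
    k = len(allele_counts)
    if k >= 15:
        return -1
    rem = [int(c) for c in allele_counts]
    state = {"count": 0, "steps": 0}

    def row(i: int) -> bool:
        state["steps"] += 1
        if state["steps"] > max_steps:
            return False
        if i == k - 1:
            if rem[i] % 2 == 0:
                state["count"] += 1
                if state["count"] > limit:
                    return False
            return True

        def cols(j: int, left: int) -> bool:
            if j == k:
                return row(i + 1)
            cap_after = sum(rem[j + 1 : k])
            lo = max(0, left - cap_after)
            hi = min(left, rem[j])
            for v in range(lo, hi + 1):
                rem[j] -= v
                ok = cols(j + 1, left - v)
                rem[j] += v
                if not ok:
                    return False
            return True

        budget = rem[i]
        cap_off = sum(rem[i + 1 : k])
        d_min = max(0, -(-(budget - cap_off) // 2))
        for d in range(d_min, budget // 2 + 1):
            rem[i] = 0
            ok = cols(i + 1, budget - 2 * d)
            rem[i] = budget
            if not ok:
                return False
        return True

    return state["count"] if row(0) else -1


def hwe_exact_test(
    g: GenotypeTable,
    locus: str,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    method: str = "auto",
) -> TestResult:
    """Exact/permutation test of Hardy–Weinberg proportions at one locus.

    ``method`` is ``"auto"`` (exhaustive when the array space is small,
    otherwise Monte-Carlo), ``"exact"`` or ``"perm"``.  Monte-Carlo requires
    a seed for reproducibility.
    """
    flat, mat = _genotype_array(g, locus)
    k = mat.shape[0]
    if k == 1:
        return TestResult(0.0, 1.0, 0, None, note="monomorphic")
    n = int(mat.sum())
    allele_counts = np.bincount(flat, minlength=k)
    log_c = _log_const(n, allele_counts)
    log_obs = _log_array_prob(mat, log_c)

    if method not in ("auto", "exact", "perm"):
        raise ValueError(f"unknown method {method!r}")

    if method in ("auto", "exact"):
        # cheap counting pass first; enumeration is abandoned at the cap
        n_arrays = _count_arrays(allele_counts, EXHAUSTIVE_ARRAY_LIMIT)
        if n_arrays < 0 and method == "exact":
            raise ValueError(
                f"locus {locus!r}: > {EXHAUSTIVE_ARRAY_LIMIT} arrays; use method='perm'"
            )
        if n_arrays > 0:
            logfact = gammaln(np.arange(n + 2) + 1.0)
            tri = np.triu_indices(k)
            lp = np.empty(n_arrays)
            for t, a in enumerate(_enumerate_arrays(allele_counts)):
                h = int(a.sum() - np.trace(a))
                lp[t] = log_c + h * _LOG2 - logfact[a[tri]].sum()
            total = np.logaddexp.reduce(lp)  # ~0 up to float error
            keep = lp <= log_obs + 1e-9
            p = float(np.exp(np.logaddexp.reduce(lp[keep]) - total))
            return TestResult(log_obs, min(p, 1.0), 0, None)

    if seed is None:
        raise ValueError("Monte-Carlo HWE test requires a seed")
    rng = np.random.default_rng(seed)
    logfact = gammaln(np.arange(n + 2) + 1.0)
    logtab = np.log(np.arange(1, n + 2))
    hits = 0
    done = 0
    chunk = max(1, min(n_perm, 500_000 // max(1, n)))
    idx = np.arange(n)[None, :]
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perms = rng.permuted(np.tile(flat, (m, 1)), axis=1)
        a = perms[:, 0::2]
        b = perms[:, 1::2]
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        codes = np.sort(lo * k + hi, axis=1)
        hcounts = (lo != hi).sum(axis=1)
        # sum of log(count!) per row via occurrence ranks within sorted runs:
        # each element of a run of length c contributes log(1), ..., log(c)
        is_new = np.ones((m, n), dtype=bool)
        is_new[:, 1:] = codes[:, 1:] != codes[:, :-1]
        start = np.where(is_new, idx, 0)
        start = np.maximum.accumulate(start, axis=1)
        occ = idx - start  # 0-based occurrence rank
        sum_logfact = logtab[occ].sum(axis=1)
        lp_rows = log_c + hcounts * _LOG2 - sum_logfact
        hits += int((lp_rows <= log_obs + 1e-9).sum())
        done += m
    p = (hits + 1) / (n_perm + 1)
    return TestResult(log_obs, p, n_perm, seed)


# ---------------------------------------------------------------------------
# linkage disequilibrium


def _g_statistic(table: np.ndarray) -> float:
    """Log-likelihood-ratio statistic of independence on a contingency table."""
    n = table.sum()
    if n == 0:
        return 0.0
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row * col / n
    mask = table > 0
    return float(2.0 * (table[mask] * np.log(table[mask] / expected[mask])).sum())


def ld_test(
    g: GenotypeTable,
    locus_a: str,
    locus_b: str,
    n_perm: int = 9_999,
    seed: int | None = None,
) -> TestResult:
    """Permutation G-test of association between genotypes at two loci."""
    shared = [s for s in g.called_samples(locus_a) if s in set(g.called_samples(locus_b))]
    if len(shared) < 2:
        raise ValueError(f"{locus_a}/{locus_b}: need >= 2 shared called individuals")
    ga = [g.calls[s][locus_a] for s in shared]
    gb = [g.calls[s][locus_b] for s in shared]
    cat_a = {c: i for i, c in enumerate(sorted(set(ga)))}
    cat_b = {c: i for i, c in enumerate(sorted(set(gb)))}
    if len(cat_a) < 2 or len(cat_b) < 2:
        return TestResult(0.0, 1.0, 0, None, note="monomorphic")
    ia = np.array([cat_a[c] for c in ga])
    ib = np.array([cat_b[c] for c in gb])
    ka, kb = len(cat_a), len(cat_b)

    def table_of(ib_perm: np.ndarray) -> np.ndarray:
        return np.bincount(ia * kb + ib_perm, minlength=ka * kb).reshape(ka, kb)

    g_obs = _g_statistic(table_of(ib))
    if seed is None:
        raise ValueError("permutation LD test requires a seed")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if _g_statistic(table_of(rng.permutation(ib))) >= g_obs - 1e-9:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return TestResult(g_obs, p, n_perm, seed)


# ---------------------------------------------------------------------------
# multiple testing


def bonferroni(alpha: float, n_tests: int) -> float:
    """Bonferroni-corrected per-test significance level ``alpha / n_tests``."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    return alpha / n_tests


def n_pairs(n_loci: int) -> int:
    """Number of unordered locus pairs, ``L (L - 1) / 2``."""
    if n_loci < 0:
        raise ValueError("n_loci must be non-negative")
    return n_loci * (n_loci - 1) // 2
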