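"""Bayesian admixture-model clustering of multilocus genotypes.

The model: each of K clusters has its own allele-frequency distributions
``P[k, l, .]`` per locus (uncorrelated across clusters, Dirichlet(lambda)
prior); each individual i has ancestry proportions ``Q[i, .]`` over clusters
(Dirichlet(alpha) prior, alpha shared across clusters); each gene copy c of
individual i at locus l originates from a latent cluster
``z ~ Categorical(Q[i])`` and its allele is a draw from that cluster's
frequencies.  Inference is by Gibbs sampling:

1. ``z``: ``Pr(z = k) proportional to Q[i, k] * P[k, l, a]``;
2. ``P``: Dirichlet(lambda + per-cluster allele counts);
3. ``Q``: Dirichlet(alpha + per-individual cluster counts);
4. ``alpha``: symmetric random-walk Metropolis on log(alpha) with a uniform
   prior on (0, alpha_max).

The model log-evidence at a given K is estimated from the post-burn-in
log-likelihood trace as ``mean - variance / 2`` (the estimator used by the
classical STRUCTURE program), and the number of clusters is selected by the
Evanno second-difference statistic ``Delta K = |L''(K)| / SD(L(K))`` across
replicate runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .str_data import GenotypeTable

__all__ = [
    "MCMCSettings",
    "StructureRun",
    "run_structure",
    "lnp_estimate",
    "EvannoTable",
    "evanno_delta_k",
    "align_clusters",
]


@dataclass(frozen=True)
class MCMCSettings:
    """Chain lengths; the defaults are desk-scale, not publication-scale."""

    burnin: int = 5_000
    iters: int = 10_000
    thin: int = 10

    def __post_init__(self) -> None:
        if self.burnin < 0 or self.iters <= 0 or self.thin <= 0:
            raise ValueError("invalid MCMC settings")


@dataclass
class StructureRun:
    K: int
    Q: np.ndarray                    # individuals x K posterior-mean ancestry
    P: dict[str, np.ndarray]         # locus -> K x n_alleles posterior mean
    alleles: dict[str, list]         # locus -> allele labels (column order of P)
    alpha: float                     # posterior-mean admixture parameter
    loglik_trace: np.ndarray         # recorded post-burn-in log-likelihoods
    lnp: float                       # Ln P(X|K) estimate
    seed: int
    samples: list[str] = field(default_factory=list)


def _encode(g: GenotypeTable):
    """Integer-code gene copies: per locus an (n, 2) array, -1 for missing."""
    alleles: dict[str, list] = {}
    codes: dict[str, np.ndarray] = {}
    for locus in g.loci:
        obs = sorted(
            {a for s in g.samples for a in (g.calls[s][locus] or ()) if not a.is_off_ladder}
        )
        index = {a: i for i, a in enumerate(obs)}
        arr = np.full((g.n_samples, 2), -1, dtype=np.int64)
        for i, s in enumerate(g.samples):
            call = g.calls[s][locus]
            if call is None or any(a.is_off_ladder for a in call):
                continue
            arr[i, 0] = index[call[0]]
            arr[i, 1] = index[call[1]]
        alleles[locus] = obs
        codes[locus] = arr
    return alleles, codes


def _log_likelihood(codes, Q, P) -> float:
    """log Pr(X | P, Q) with gene copies mixture-distributed over clusters."""
    total = 0.0
    for locus, arr in codes.items():
        pk = P[locus]  # K x A
        for c in (0, 1):
            obs = arr[:, c]
            ok = obs >= 0
            if not ok.any():
                continue
            # mixture probability of each observed gene copy
            probs = np.einsum("ik,ki->i", Q[ok], pk[:, obs[ok]])
            total += float(np.log(np.clip(probs, 1e-300, None)).sum())
    return total


def run_structure(
    g: GenotypeTable,
    K: int,
    mcmc: MCMCSettings | None = None,
    lam: float = 1.0,
    seed: int = 0,
    alpha0: float = 1.0,
    alpha_step: float = 0.05,
    alpha_max: float = 10.0,
) -> StructureRun:
    """Gibbs-sample the admixture model at a fixed number of clusters K.

    No population information is used.  Q and P are reported as posterior
    means over the recorded (post-burn-in, thinned) iterations; the
    log-likelihood trace drives :func:`lnp_estimate`.  Deterministic for a
    given seed.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    mcmc = mcmc or MCMCSettings()
    rng = np.random.default_rng(seed)
    alleles, codes = _encode(g)
    n = g.n_samples
    loci = list(codes)

    if K == 1:
        # one population: P is the posterior mean of a single Dirichlet;
        # the likelihood trace still comes from Dirichlet draws of P
        traces = []
        P_acc = {l: np.zeros((1, len(alleles[l]))) for l in loci}
        n_rec = 0
        Q = np.ones((n, 1))
        P = {}
        for l in loci:
            arr = codes[l]
            obs = arr[arr >= 0]
            cnt = np.bincount(obs, minlength=len(alleles[l])).astype(float)
            P[l] = (cnt + lam)[None, :]
            P[l] /= P[l].sum()
        for it in range(mcmc.burnin + mcmc.iters):
            Pd = {}
            for l in loci:
                arr = codes[l]
                obs = arr[arr >= 0]
                cnt = np.bincount(obs, minlength=len(alleles[l])).astype(float)
                Pd[l] = rng.dirichlet(cnt + lam)[None, :]
            if it >= mcmc.burnin and (it - mcmc.burnin) % mcmc.thin == 0:
                traces.append(_log_likelihood(codes, Q, Pd))
                for l in loci:
                    P_acc[l] += Pd[l]
                n_rec += 1
        Pmean = {l: P_acc[l] / n_rec for l in loci}
        trace = np.array(traces)
        return StructureRun(
            K=1, Q=Q, P=Pmean, alleles=alleles, alpha=float("nan"),
            loglik_trace=trace, lnp=lnp_estimate(trace), seed=seed,
            samples=list(g.samples),
        )

    # initialize
    alpha = alpha0
    Q = rng.dirichlet(np.full(K, alpha), size=n)
    P = {l: rng.dirichlet(np.full(len(alleles[l]), lam), size=K) for l in loci}
    z = {l: rng.integers(0, K, size=codes[l].shape) for l in loci}

    Q_acc = np.zeros_like(Q)
    P_acc = {l: np.zeros_like(P[l]) for l in loci}
    alpha_acc = 0.0
    traces: list[float] = []
    n_rec = 0

    lgamma = math.lgamma

    def alpha_logpost(a: float) -> float:
        # sum_i log Dirichlet(Q_i; a * 1_K), uniform prior on (0, alpha_max)
        if not 0.0 < a < alpha_max:
            return -np.inf
        return n * (lgamma(K * a) - K * lgamma(a)) + (a - 1.0) * float(
            np.log(np.clip(Q, 1e-300, None)).sum()
        )

    total_iters = mcmc.burnin + mcmc.iters
    for it in range(total_iters):
        # (i) latent origins z for every gene copy
        cluster_counts = np.zeros((n, K))
        allele_counts = {l: np.zeros_like(P[l]) for l in loci}
        for l in loci:
            arr = codes[l]
            pk = P[l]
            for c in (0, 1):
                obs = arr[:, c]
                ok = obs >= 0
                if not ok.any():
                    continue
                w = Q[ok] * pk[:, obs[ok]].T  # (n_ok, K)
                w /= w.sum(axis=1, keepdims=True)
                u = rng.random(w.shape[0])[:, None]
                knew = (w.cumsum(axis=1) < u).sum(axis=1)
                z[l][ok, c] = knew
                np.add.at(cluster_counts, (np.where(ok)[0], knew), 1.0)
                np.add.at(allele_counts[l], (knew, obs[ok]), 1.0)
        # (ii) cluster allele frequencies P
        for l in loci:
            g_draw = rng.standard_gamma(allele_counts[l] + lam)
            P[l] = g_draw / g_draw.sum(axis=1, keepdims=True)
        # (iii) ancestry proportions Q
        g_draw = rng.standard_gamma(cluster_counts + alpha)
        Q = g_draw / g_draw.sum(axis=1, keepdims=True)
        # (iv) alpha by random-walk Metropolis on log alpha
        prop = alpha * math.exp(alpha_step * rng.standard_normal())
        # Jacobian of the log transform: target density times alpha
        log_accept = (alpha_logpost(prop) + math.log(prop)) - (
            alpha_logpost(alpha) + math.log(alpha)
        )
        if math.log(rng.random()) < log_accept:
            alpha = prop

        if it >= mcmc.burnin and (it - mcmc.burnin) % mcmc.thin == 0:
            traces.append(_log_likelihood(codes, Q, P))
            Q_acc += Q
            for l in loci:
                P_acc[l] += P[l]
            alpha_acc += alpha
            n_rec += 1

    trace = np.array(traces)
    return StructureRun(
        K=K,
        Q=Q_acc / n_rec,
        P={l: P_acc[l] / n_rec for l in loci},
        alleles=alleles,
        alpha=alpha_acc / n_rec,
        loglik_trace=trace,
        lnp=lnp_estimate(trace),
        seed=seed,
        samples=list(g.samples),
    )


def lnp_estimate(trace: np.ndarray) -> float:
    """Model log-evidence estimate ``mean(trace) - var(trace) / 2``.

    ``var`` is the sample variance (ddof=1).  This is the deviance-based
    estimator the classical STRUCTURE program reports as Ln P(X|K).
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < 2:
        raise ValueError("need at least two recorded log-likelihood values")
    return float(trace.mean() - trace.var(ddof=1) / 2.0)


@dataclass
class EvannoTable:
    """Per-K evidence summaries and the Evanno second-difference statistic."""

    table: pd.DataFrame  # index K; columns mean_lnp, sd_lnp, lprime, lsecond, delta_k

    @property
    def best_k(self) -> int:
        dk = self.table["delta_k"].dropna()
        if dk.empty:
            raise ValueError("Delta K undefined everywhere")
        return int(dk.idxmax())


def evanno_delta_k(per_k_runs: dict[int, list[float]]) -> EvannoTable:
    """Evanno's Delta K from replicate Ln P(X|K) estimates per K.

    Requires a contiguous K range of length >= 3 with >= 2 runs per K.
    ``L'(K)`` and ``|L''(K)|`` are first/second differences of the mean;
    ``Delta K = |L''(K)| / SD(L(K))`` is defined only for interior K and
    reported as missing (with a warning) where the SD is zero.
    """
    ks = sorted(per_k_runs)
    if len(ks) < 3:
        raise ValueError("need at least three values of K")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("K range must be contiguous")
    for k in ks:
        if len(per_k_runs[k]) < 2:
            raise ValueError(f"K={k}: need >= 2 replicate runs")
    mean = {k: float(np.mean(per_k_runs[k])) for k in ks}
    sd = {k: float(np.std(per_k_runs[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        lprime = mean[k] - mean[k - 1] if k - 1 in mean else np.nan
        if k - 1 in mean and k + 1 in mean:
            lsecond = abs(mean[k + 1] - 2.0 * mean[k] + mean[k - 1])
            if sd[k] > 0:
                delta = lsecond / sd[k]
            else:
                import warnings

                warnings.warn(f"K={k}: zero SD, Delta K undefined")
                delta = np.nan
        else:
            lsecond, delta = np.nan, np.nan
        rows.append((k, mean[k], sd[k], lprime, lsecond, delta))
    df = pd.DataFrame(
        rows, columns=["K", "mean_lnp", "sd_lnp", "lprime", "lsecond", "delta_k"]
    ).set_index("K")
    return EvannoTable(df)


def align_clusters(reference_q: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Greedy column permutation of ``q`` to best match ``reference_q``.

    Cluster labels are arbitrary per run; for cross-run comparison columns
    are matched greedily by correlation of ancestry profiles.
    """
    if reference_q.shape != q.shape:
        raise ValueError("Q matrices must have identical shape")
    K = q.shape[1]
    sim = reference_q.T @ q
    perm = np.full(K, -1)
    used = set()
    for _ in range(K):
        flat = int(np.argmax(np.where(
            np.isin(np.arange(sim.shape[1]), list(used))[None, :] | (perm != -1)[:, None],
            -np.inf, sim,
        )))
        i, j = divmod(flat, K)
        perm[i] = j
        used.add(j)
    return q[:, perm]
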