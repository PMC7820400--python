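"""Population harmonization, Nei's DA distance, neighbour-joining, and PCA.

Nei's DA distance between two populations over ``r`` shared loci is

    DA = 1 - (1/r) * sum_loci sum_alleles sqrt(x_i * y_i)

i.e. one minus the mean per-locus Bhattacharyya affinity of the allele
frequency distributions; it averages (not sums) over loci so analyses using
different locus panels remain comparable.  Trees are built by the
Saitou–Nei neighbour-joining algorithm with the standard Q-criterion;
negative branch lengths are kept by default (an option clamps them to zero
for display).  Ordination is plain column-centered PCA via singular value
decomposition: at the population level on allele-frequency variables, at
the individual level on per-allele dosages (0/1/2 copies).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode
from sklearn.decomposition import PCA

from .str_data import AlleleLabel, FrequencyTable, GenotypeTable

__all__ = [
    "PopulationPanel",
    "DistanceMatrix",
    "harmonize",
    "nei_da",
    "nj_tree",
    "PCAResult",
    "pca_populations",
    "pca_individuals",
]


@dataclass
class PopulationPanel:
    """Frequency tables harmonized to shared loci and per-locus allele unions."""

    populations: list[str]
    shared_loci: list[str]
    alleles: dict[str, list[AlleleLabel]]
    freq: dict[str, np.ndarray]  # per locus: n_pops x n_alleles, rows sum to 1

    def distance_matrix(self) -> "DistanceMatrix":
        n = len(self.populations)
        d = np.zeros((n, n))
        r = len(self.shared_loci)
        for locus in self.shared_loci:
            f = self.freq[locus]
            s = np.sqrt(f)
            d += 1.0 - s @ s.T  # per-locus (1 - Bhattacharyya affinity)
        d /= r
        np.fill_diagonal(d, 0.0)
        d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(d, 0.0)
        return DistanceMatrix(list(self.populations), d)


def harmonize(
    tables: dict[str, FrequencyTable], loci: list[str] | None = None
) -> PopulationPanel:
    """Harmonize raw frequency tables across populations.

    Shared loci are the intersection of all tables' loci (or an explicit
    list validated as a subset of it); alleles are unioned per locus with
    absent alleles imputed frequency 0; each population's frequencies are
    renormalized per locus.
    """
    if len(tables) < 2:
        raise ValueError("need at least two populations")
    pops = list(tables)
    shared = [l for l in tables[pops[0]].loci if all(l in t.freqs for t in tables.values())]
    if loci is not None:
        missing = [l for l in loci if l not in shared]
        if missing:
            raise ValueError(f"loci not shared by all populations: {missing}")
        shared = list(loci)
    if not shared:
        raise ValueError("no loci shared by all populations")
    alleles: dict[str, list[AlleleLabel]] = {}
    freq: dict[str, np.ndarray] = {}
    for locus in shared:
        union = sorted({a for t in tables.values() for a in t.freqs[locus]})
        alleles[locus] = union
        mat = np.zeros((len(pops), len(union)))
        for i, pop in enumerate(pops):
            fmap = tables[pop].freqs[locus]
            for j, a in enumerate(union):
                mat[i, j] = fmap.get(a, 0.0)
            mat[i] /= mat[i].sum()
        freq[locus] = mat
    return PopulationPanel(pops, shared, alleles, freq)


def nei_da(x: FrequencyTable, y: FrequencyTable, shared_loci: list[str]) -> float:
    """Nei's DA between two frequency tables over ``shared_loci``."""
    r = len(shared_loci)
    if r == 0:
        raise ValueError("no shared loci")
    total = 0.0
    for locus in shared_loci:
        union = set(x.freqs[locus]) | set(y.freqs[locus])
        xs = np.array([x.freqs[locus].get(a, 0.0) for a in union])
        ys = np.array([y.freqs[locus].get(a, 0.0) for a in union])
        xs /= xs.sum()
        ys /= ys.sum()
        total += float(np.sqrt(xs * ys).sum())
    return 1.0 - total / r


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0.0):
            raise ValueError("diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        self.values = v


def nj_tree(d: DistanceMatrix, clamp_negative: bool = False) -> TreeNode:
    """Saitou–Nei neighbour-joining tree from a distance matrix.

    Ties in the Q-criterion break towards the lowest (row, column) index, so
    the topology is deterministic.  Additive matrices are recovered exactly.
    With ``clamp_negative`` the (legitimate, NJ-conventional) negative branch
    lengths are floored at zero for display.
    """
    n = len(d.labels)
    if n < 2:
        raise ValueError("need at least two taxa")
    nodes = [TreeNode(name=lab) for lab in d.labels]
    if n == 2:
        h = float(d.values[0, 1]) / 2.0
        for node in nodes:
            node.length = max(h, 0.0) if clamp_negative else h
        return TreeNode(children=nodes)

    D = d.values.astype(float).copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (row, column) tie-break: argmin scans row-major
        flat = int(np.argmin(q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        ai, aj = active[i], active[j]
        nodes[ai].length = li
        nodes[aj].length = lj
        new = TreeNode(children=[nodes[ai], nodes[aj]])
        # distances from the new node to the remaining taxa
        newrow = np.zeros(D.shape[0] + 1)
        for t, at in enumerate(active):
            if t in (i, j):
                continue
            newrow[at] = (sub[i, t] + sub[j, t] - dij) / 2.0
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(newrow) - 1] = newrow[:-1]
        D[: len(newrow) - 1, -1] = newrow[:-1]
        nodes.append(new)
        active = [a for a in active if a not in (ai, aj)] + [len(nodes) - 1]

    # three remaining nodes join at a single internal vertex
    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    nodes[a].length = (dab + dac - dbc) / 2.0
    nodes[b].length = (dab + dbc - dac) / 2.0
    nodes[c].length = (dac + dbc - dab) / 2.0
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    if clamp_negative:
        for node in root.traverse(include_self=False):
            if node.length is not None and node.length < 0:
                node.length = 0.0
    return root


@dataclass
class PCAResult:
    coordinates: np.ndarray          # rows x n_components scores
    explained_variance_ratio: np.ndarray
    row_labels: list[str]


def _fit_pca(X: np.ndarray, n_components: int, labels: list[str]) -> PCAResult:
    Xc = X - X.mean(axis=0, keepdims=True)
    rank = int(np.linalg.matrix_rank(Xc))
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds data rank {rank}")
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    return PCAResult(scores, model.explained_variance_ratio_, labels)


def pca_populations(panel: PopulationPanel, n_components: int = 2) -> PCAResult:
    """PCA of populations on centered (unscaled) allele-frequency variables."""
    cols = [panel.freq[locus] for locus in panel.shared_loci]
    X = np.hstack(cols)
    return _fit_pca(X, n_components, list(panel.populations))


def pca_individuals(g: GenotypeTable, n_components: int = 2) -> PCAResult:
    """PCA of individuals on per-allele dosage (0/1/2) variables.

    Missing calls are mean-imputed per column; a column missing in every
    individual is dropped with a warning.
    """
    columns: list[tuple[str, AlleleLabel]] = []
    for locus in g.loci:
        alleles = sorted(
            {a for s in g.samples for a in (g.calls[s][locus] or ()) if not a.is_off_ladder}
        )
        columns.extend((locus, a) for a in alleles)
    if not columns:
        warnings.warn("no called columns; nothing to ordinate")
        raise ValueError("all loci are entirely missing")
    col_index = {c: j for j, c in enumerate(columns)}
    locus_cols: dict[str, list[int]] = {}
    for (locus, _), j in col_index.items():
        locus_cols.setdefault(locus, []).append(j)
    X = np.full((g.n_samples, len(columns)), np.nan)
    for i, s in enumerate(g.samples):
        for locus in g.loci:
            call = g.calls[s][locus]
            if call is None or any(a.is_off_ladder for a in call):
                continue
            X[i, locus_cols[locus]] = 0.0
            for a in call:
                X[i, col_index[(locus, a)]] += 1.0
    col_mean = np.nanmean(X, axis=0)
    nan_cols = np.isnan(col_mean)
    if nan_cols.any():
        warnings.warn(f"dropping {int(nan_cols.sum())} all-missing dosage columns")
        X = X[:, ~nan_cols]
        col_mean = col_mean[~nan_cols]
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    return _fit_pca(X, n_components, list(g.samples))
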