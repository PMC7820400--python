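"""Nei DA identities, NJ additive-tree recovery, and PCA ordination."""

import itertools

import numpy as np
import pytest

from strpopgen.distance import (
    DistanceMatrix,
    harmonize,
    nei_da,
    nj_tree,
    pca_individuals,
    pca_populations,
)
from strpopgen.simulate import SimulationConfig, draw_subpop_frequencies, simulate_genotypes
from strpopgen.str_data import AlleleLabel, FrequencyTable

from conftest import uniform_base


def ft(locus_allele_freqs, n2=100):
    return FrequencyTable(
        {
            locus: {AlleleLabel.parse(a): p for a, p in fmap.items()}
            for locus, fmap in locus_allele_freqs.items()
        },
        {locus: n2 for locus in locus_allele_freqs},
    )


class TestHarmonize:
    def test_intersection_of_loci(self, kuwait_freqs):
        thirteen = [
            "CSF1PO", "D13S317", "D16S539", "D18S51", "D21S11", "D3S1358",
            "D5S818", "D7S820", "D8S1179", "FGA", "TH01", "TPOX", "vWA",
        ]
        small = FrequencyTable(
            {l: dict(kuwait_freqs.freqs[l]) for l in thirteen},
            {l: 400 for l in thirteen},
        )
        panel = harmonize({"full": kuwait_freqs, "partial": small})
        assert sorted(panel.shared_loci) == sorted(thirteen)

    def test_identity_harmonization(self, kuwait_freqs):
        panel = harmonize({"a": kuwait_freqs, "b": kuwait_freqs})
        assert panel.shared_loci == kuwait_freqs.loci
        for locus in panel.shared_loci:
            assert np.allclose(panel.freq[locus][0], panel.freq[locus][1])

    def test_private_allele_imputed_zero(self):
        x = ft({"L": {"10": 0.5, "11": 0.5}})
        y = ft({"L": {"10": 1.0}})
        panel = harmonize({"x": x, "y": y})
        j = panel.alleles["L"].index(AlleleLabel(11))
        assert panel.freq["L"][1, j] == 0.0

    def test_empty_intersection_is_error(self):
        with pytest.raises(ValueError):
            harmonize({"x": ft({"A": {"10": 1.0}}), "y": ft({"B": {"10": 1.0}})})


class TestNeiDA:
    def test_identical_tables_zero(self, kuwait_freqs):
        assert nei_da(kuwait_freqs, kuwait_freqs, kuwait_freqs.loci) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_allele_sets_one(self):
        x = ft({"L": {"10": 1.0}})
        y = ft({"L": {"20": 1.0}})
        assert nei_da(x, y, ["L"]) == pytest.approx(1.0)

    def test_hand_value(self):
        x = ft({"L": {"10": 0.5, "11": 0.5}})
        y = ft({"L": {"10": 0.9, "11": 0.1}})
        expected = 1 - (np.sqrt(0.45) + np.sqrt(0.05))
        assert nei_da(x, y, ["L"]) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.1056, abs=1e-4)

    def test_symmetric_and_bounded(self, kuwait_freqs):
        sub = draw_subpop_frequencies(kuwait_freqs, 0.1, seed=3)
        d1 = nei_da(kuwait_freqs, sub, kuwait_freqs.loci)
        d2 = nei_da(sub, kuwait_freqs, kuwait_freqs.loci)
        assert d1 == pytest.approx(d2, abs=1e-12)
        assert 0 < d1 < 1

    def test_da_increases_with_divergence(self, kuwait_freqs):
        means = []
        for F in (0.01, 0.05, 0.1, 0.2):
            ds = []
            for seed in range(5):
                a = draw_subpop_frequencies(kuwait_freqs, F, seed=100 + seed)
                b = draw_subpop_frequencies(kuwait_freqs, F, seed=200 + seed)
                ds.append(nei_da(a, b, kuwait_freqs.loci))
            means.append(np.mean(ds))
        assert all(b > a for a, b in zip(means, means[1:]))


def random_additive_tree(n_taxa, rng):
    """Random binary tree; returns (pairwise distance dict, labels).

    Built by repeatedly joining two clusters with fresh positive edges and
    accumulating leaf-to-leaf path lengths directly — independent of any
    tree machinery in the package.
    """
    labels = [f"t{i}" for i in range(n_taxa)]
    clusters = [{lab: 0.0} for lab in labels]
    dist = {}
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), 2, replace=False))
        e1, e2 = rng.uniform(0.1, 1.0, 2)
        a, b = clusters[i], clusters[j]
        for la, da in a.items():
            for lb, db in b.items():
                dist[frozenset((la, lb))] = da + e1 + db + e2
        merged = {la: da + e1 for la, da in a.items()}
        merged.update({lb: db + e2 for lb, db in b.items()})
        clusters = [c for t, c in enumerate(clusters) if t not in (i, j)] + [merged]
    return dist, labels


class TestNeighbourJoining:
    def test_two_taxa_single_edge(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0.0, 0.7], [0.7, 0.0]]))
        tree = nj_tree(dm)
        td = tree.tip_tip_distances()
        assert td["a", "b"] == pytest.approx(0.7)

    def test_three_equidistant_star(self):
        dm = DistanceMatrix(list("abc"), np.full((3, 3), 2.0) - 2 * np.eye(3))
        tree = nj_tree(dm)
        for tip in tree.tips():
            assert tip.length == pytest.approx(1.0)

    def test_four_taxon_known_tree(self):
        # tree ((A:1,B:2):1.5,(C:0.5,D:3)) -> additive distances
        D = np.array(
            [
                [0.0, 3.0, 3.0, 5.5],
                [3.0, 0.0, 4.0, 6.5],
                [3.0, 4.0, 0.0, 3.5],
                [5.5, 6.5, 3.5, 0.0],
            ]
        )
        tree = nj_tree(DistanceMatrix(list("ABCD"), D))
        td = tree.tip_tip_distances()
        for (i, a), (j, b) in itertools.combinations(enumerate("ABCD"), 2):
            assert td[a, b] == pytest.approx(D[i, j], abs=1e-9)

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
    def test_recovers_random_additive_matrices(self, n_taxa):
        rng = np.random.default_rng(n_taxa)
        dist, labels = random_additive_tree(n_taxa, rng)
        D = np.zeros((n_taxa, n_taxa))
        for (i, a), (j, b) in itertools.combinations(enumerate(labels), 2):
            D[i, j] = D[j, i] = dist[frozenset((a, b))]
        tree = nj_tree(DistanceMatrix(labels, D))
        td = tree.tip_tip_distances()
        for (i, a), (j, b) in itertools.combinations(enumerate(labels), 2):
            assert td[a, b] == pytest.approx(D[i, j], abs=1e-9)

    def test_agrees_with_reference_implementation(self, kuwait_freqs):
        # independent oracle: scikit-bio's own neighbour joining
        import skbio

        tables = {f"p{i}": draw_subpop_frequencies(kuwait_freqs, 0.05, seed=i)
                  for i in range(5)}
        dm = harmonize(tables).distance_matrix()
        ours = nj_tree(dm).tip_tip_distances()
        ref_dm = skbio.DistanceMatrix(dm.values, ids=dm.labels)
        theirs = skbio.tree.nj(ref_dm).tip_tip_distances()
        for a, b in itertools.combinations(dm.labels, 2):
            assert ours[a, b] == pytest.approx(theirs[a, b], abs=1e-6)

    def test_newick_round_trip(self):
        import io

        import skbio

        dm = DistanceMatrix(list("abcd"), np.array(
            [[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]], float))
        tree = nj_tree(dm)
        buf = io.StringIO()
        tree.write(buf)
        again = skbio.TreeNode.read(io.StringIO(buf.getvalue()))
        assert {t.name for t in again.tips()} == set("abcd")

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, -1.0], [-1.0, 0.0]]))


class TestPCA:
    def test_identical_populations_identical_coordinates(self, kuwait_freqs):
        sub = draw_subpop_frequencies(kuwait_freqs, 0.1, seed=1)
        panel = harmonize({"a": kuwait_freqs, "b": kuwait_freqs, "c": sub})
        res = pca_populations(panel, n_components=1)
        coords = dict(zip(res.row_labels, res.coordinates[:, 0]))
        assert coords["a"] == pytest.approx(coords["b"], abs=1e-9)

    def test_explained_variance_sums_to_one_at_full_rank(self, kuwait_freqs):
        tables = {f"p{i}": draw_subpop_frequencies(kuwait_freqs, 0.1, seed=i)
                  for i in range(4)}
        panel = harmonize(tables)
        res = pca_populations(panel, n_components=3)  # rank = n_pops - 1
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)

    def test_components_beyond_rank_rejected(self, kuwait_freqs):
        panel = harmonize({"a": kuwait_freqs,
                           "b": draw_subpop_frequencies(kuwait_freqs, 0.05, seed=2)})
        with pytest.raises(ValueError):
            pca_populations(panel, n_components=2)

    def test_outlier_population_dominates_pc1(self, kuwait_freqs):
        hits = 0
        for seed in range(20):
            tables = {f"p{i}": draw_subpop_frequencies(kuwait_freqs, 0.02, seed=1000 + 10 * seed + i)
                      for i in range(4)}
            tables["outlier"] = draw_subpop_frequencies(kuwait_freqs, 0.3, seed=2000 + seed)
            res = pca_populations(harmonize(tables), n_components=1)
            scores = dict(zip(res.row_labels, np.abs(res.coordinates[:, 0])))
            hits += max(scores, key=scores.get) == "outlier"
        assert hits >= 18

    def test_duplicate_individuals_identical_coordinates(self):
        base = uniform_base(5, 3)
        g = simulate_genotypes(SimulationConfig(base, 20, seed=1))
        dup = g.subset(g.samples)
        dup.calls[dup.samples[1]] = dict(dup.calls[dup.samples[0]])
        res = pca_individuals(dup, 2)
        assert np.allclose(res.coordinates[0], res.coordinates[1], atol=1e-9)

    def test_pc1_separates_diverged_subpopulations(self):
        base = uniform_base(23, 6)
        g = simulate_genotypes(SimulationConfig(
            base, 200, subpop_spec=[("A", 100, 0.3), ("B", 100, 0.3)], seed=3))
        res = pca_individuals(g, 2)
        labels = np.array([g.subgroup[s] == "A" for s in res.row_labels])
        pc1 = res.coordinates[:, 0]
        thr = np.median(pc1)
        acc = max(((pc1 > thr) == labels).mean(), ((pc1 <= thr) == labels).mean())
        assert acc >= 0.90

    def test_no_structure_no_separation(self):
        from sklearn.metrics import silhouette_score

        base = uniform_base(23, 6)
        g = simulate_genotypes(SimulationConfig(
            base, 200, subpop_spec=[("A", 100, 0.0), ("B", 100, 0.0)], seed=3))
        res = pca_individuals(g, 2)
        labels = [g.subgroup[s] for s in res.row_labels]
        assert abs(silhouette_score(res.coordinates, labels)) < 0.1

    def test_missing_calls_mean_imputed(self):
        base = uniform_base(4, 3)
        g = simulate_genotypes(SimulationConfig(base, 30, seed=2))
        g.calls[g.samples[0]]["L0"] = None
        res = pca_individuals(g, 2)
        assert np.isfinite(res.coordinates).all()
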