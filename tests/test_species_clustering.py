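import itertools

import numpy as np
import pytest

from genospec.io_formats import LabeledMatrix, StrainRecord
from genospec.genome_distance import build_matrix
from genospec.species_clustering import (ClusteringParams, RadiusSpec,
                                         delineate_species,
                                         delineate_subspecies,
                                         fraction_linkage_cluster,
                                         threshold_sweep,
                                         type_radius_affiliate)
from genospec.pipeline import compare_partitions


def _dist(labels, values):
    v = np.asarray(values, dtype=float)
    np.fill_diagonal(v, 0.0)
    return LabeledMatrix(list(labels), v, "distance")


def _random_dist(rng, n):
    v = rng.uniform(0, 1, (n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    return LabeledMatrix([f"s{i:02d}" for i in range(n)], v, "distance")


def _single_linkage_oracle(d, T):
    """Connected components of the link graph (union-find)."""
    n = d.shape[0]
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] <= T:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}


class TestFractionLinkage:
    def test_all_linked_single_cluster(self):
        m = _dist("abc", np.full((3, 3), 0.01))
        for F in (0.0, 0.5, 1.0):
            out = fraction_linkage_cluster(m, ClusteringParams(T=0.1, F=F))
            assert out == [{"a", "b", "c"}]

    def test_no_links_all_singletons(self):
        m = _dist("abc", np.full((3, 3), 0.9))
        for F in (0.0, 0.5, 1.0):
            out = fraction_linkage_cluster(m, ClusteringParams(T=0.1, F=F))
            assert len(out) == 3

    def test_f_zero_equals_connected_components(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 16))
            m = _random_dist(rng, n)
            T = float(rng.uniform(0.1, 0.6))
            got = fraction_linkage_cluster(m, ClusteringParams(T=T, F=0.0))
            got_idx = {frozenset(m.index[s] for s in c) for c in got}
            assert got_idx == _single_linkage_oracle(m.values, T)

    def test_f_one_complete_linkage_property(self, rng):
        """At F=1 every intra-cluster pair must be a link, and no two
        clusters may remain fully linked to each other (maximality)."""
        for _ in range(50):
            n = int(rng.integers(5, 16))
            m = _random_dist(rng, n)
            T = float(rng.uniform(0.1, 0.6))
            out = fraction_linkage_cluster(m, ClusteringParams(T=T, F=1.0))
            idx = m.index
            for c in out:
                for a, b in itertools.combinations(sorted(c), 2):
                    assert m.values[idx[a], idx[b]] <= T + 1e-9
            for c1, c2 in itertools.combinations(out, 2):
                fully = all(m.values[idx[a], idx[b]] <= T + 1e-9
                            for a in c1 for b in c2)
                assert not fully

    def test_cluster_count_monotone_in_threshold(self, rng):
        m = _random_dist(rng, 12)
        counts = [len(fraction_linkage_cluster(
            m, ClusteringParams(T=t, F=0.5))) for t in (0.1, 0.3, 0.5, 0.9)]
        assert counts == sorted(counts, reverse=True)

    def test_f_monotonicity(self, rng):
        for _ in range(10):
            m = _random_dist(rng, 10)
            n0 = len(fraction_linkage_cluster(m, ClusteringParams(T=0.4, F=0.0)))
            n1 = len(fraction_linkage_cluster(m, ClusteringParams(T=0.4, F=1.0)))
            assert n1 >= n0

    def test_deterministic(self, rng):
        m = _random_dist(rng, 10)
        p = ClusteringParams(T=0.45, F=0.5)
        assert fraction_linkage_cluster(m, p) == fraction_linkage_cluster(m, p)

    def test_partition_property(self, rng):
        m = _random_dist(rng, 10)
        out = fraction_linkage_cluster(m, ClusteringParams(T=0.4, F=0.5))
        union = set().union(*out)
        assert union == set(m.labels)
        assert sum(len(c) for c in out) == len(m.labels)

    def test_asymmetric_matrix_rejected(self):
        v = np.array([[0.0, 0.1], [0.4, 0.0]])
        m = LabeledMatrix(["a", "b"], v, "distance")
        with pytest.raises(ValueError, match="symmetric"):
            fraction_linkage_cluster(m, ClusteringParams(T=0.2))


def _sim_matrix(labels, sim):
    v = np.asarray(sim, dtype=float)
    np.fill_diagonal(v, 100.0)
    return LabeledMatrix(list(labels), v, "dDDH")


class TestTypeRadius:
    def test_no_off_type_similarity_means_all_novel(self):
        v = np.zeros((4, 4))
        m = _sim_matrix("tabc", v)
        aff, amb = type_radius_affiliate(m, [RadiusSpec("t", 70.0)])
        assert aff["t"] == {"t"}
        assert all(not aff[s] for s in "abc")
        assert amb == []

    def test_ambiguous_strain_detected(self):
        # strain 'x' within both type radii
        v = np.array([
            [100, 10, 80],
            [10, 100, 75],
            [80, 75, 100.0],
        ])
        m = _sim_matrix(["t1", "t2", "x"], v)
        aff, amb = type_radius_affiliate(
            m, [RadiusSpec("t1", 70.0), RadiusSpec("t2", 70.0)])
        assert aff["x"] == {"t1", "t2"}
        assert amb == [("x", ("t1", "t2"))]

    def test_ci_variants(self):
        v = np.array([[100, 68.0], [68.0, 100]])
        m = _sim_matrix(["t", "s"], v)
        spec = [RadiusSpec("t", 70.0, lower=67.0, upper=73.0)]
        assert type_radius_affiliate(m, spec, which="lower")[0]["s"] == {"t"}
        assert type_radius_affiliate(m, spec, which="nominal")[0]["s"] == set()

    def test_unknown_type_rejected(self):
        m = _sim_matrix(["a", "b"], np.full((2, 2), 80.0))
        with pytest.raises(KeyError):
            type_radius_affiliate(m, [RadiusSpec("zz", 70.0)])


class TestDelineate:
    def _planted(self):
        # two described species + one novel pair + one novel singleton
        labels = ["t1", "a1", "t2", "b1", "n1", "n2", "x1"]
        v = np.full((7, 7), 20.0)
        sim = {("t1", "a1"): 90, ("t2", "b1"): 88, ("n1", "n2"): 85}
        idx = {l: i for i, l in enumerate(labels)}
        for (p, q), s in sim.items():
            v[idx[p], idx[q]] = v[idx[q], idx[p]] = s
        m = _sim_matrix(labels, v)
        meta = [
            StrainRecord("t1", True, "sp1"), StrainRecord("a1"),
            StrainRecord("t2", True, "sp2"), StrainRecord("b1"),
            StrainRecord("n1"), StrainRecord("n2"), StrainRecord("x1"),
        ]
        return m, meta

    def test_constructed_case(self):
        m, meta = self._planted()
        params = ClusteringParams.from_similarity(70.0, "dDDH", F=0.5)
        part = delineate_species(m, meta, params, radius_threshold=70.0)
        assert part.n_clusters == 4
        assert part.n_novel == 2
        assert part.n_ambiguous_strains == 0
        got = {frozenset(c) for c in part.clusters}
        assert frozenset({"t1", "a1"}) in got
        assert frozenset({"n1", "n2"}) in got
        assert frozenset({"x1"}) in got
        # the PT of the novel pair captures its cluster and nothing else
        assert set(part.putative_types.values()) <= {"n1", "n2", "x1"}

    def test_planted_recovery(self, small_complex):
        genomes, truth, metadata = small_complex
        m = build_matrix(genomes, "anim")
        params = ClusteringParams.from_similarity(96.0, "ANIm", F=0.5)
        part = delineate_species(m, metadata, params, radius_threshold=96.0)
        res = compare_partitions(part, truth.species_partition())
        assert res["exact_match"]
        assert part.n_ambiguous_strains == 0

    def test_subspecies_recovery(self, subspecies_complex):
        genomes, truth, metadata = subspecies_complex
        m = build_matrix(genomes, "anim")
        params = ClusteringParams.from_similarity(96.0, "ANIm", F=0.5)
        part = delineate_species(m, metadata, params, radius_threshold=96.0)
        sub = delineate_subspecies(m, part, cutoff=98.0)
        res = compare_partitions(sub.all_subclusters(),
                                 truth.subspecies_partition())
        assert res["exact_match"]
        # the 4-strain species carries two non-trivial planted subspecies
        assert sub.nontrivial_count == 2

    def test_tight_cluster_is_single_subspecies(self):
        labels = ["t1", "a1", "a2"]
        v = np.full((3, 3), 95.0)
        m = _sim_matrix(labels, v)
        meta = [StrainRecord("t1", True, "sp1"), StrainRecord("a1"),
                StrainRecord("a2")]
        params = ClusteringParams.from_similarity(70.0, "dDDH", F=0.5)
        part = delineate_species(m, meta, params, radius_threshold=70.0)
        sub = delineate_subspecies(m, part, cutoff=79.0)
        assert sub.nontrivial_count == 1   # one 3-strain subspecies
        assert len(sub.all_subclusters()) == 1

    def test_threshold_sweep_shapes(self):
        m, meta = self._planted()
        rows = threshold_sweep(m, meta, [60.0, 70.0, 95.0])
        assert [r["threshold"] for r in rows] == [60.0, 70.0, 95.0]
        assert all({"n_clusters", "n_novel", "n_ambiguous_strains"}
                   <= set(r) for r in rows)
        counts = [r["n_clusters"] for r in rows]
        assert counts == sorted(counts)   # clusters grow as radius tightens
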