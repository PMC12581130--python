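import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibrilkit.aggregation_kinetics import (
    ClusterLabels,
    cluster_frame,
    cluster_series,
    kinetics_series,
    largest_cluster_fraction,
    midsize_fraction,
    monomer_fraction_series,
    oligomer_distribution,
    t_half,
)
from fibrilkit.io_core import ChainTopology, Frame, Residue, Trajectory


def _chains_at(positions, box=None, periodic=()):
    """One-CA-per-chain system with chains at the given points."""
    tops = []
    coords = []
    for c, p in enumerate(positions):
        tops.append(ChainTopology(str(c % 10), [Residue("GLN", 1, (("CA", "C"),))]))
        coords.append(p)
    frame = Frame(np.asarray(coords, float), box=box,
                  periodic_axes=frozenset(periodic))
    return Trajectory(tops, [frame]), frame


def _bfs_oracle(adjacency):
    """Independent cluster assignment via explicit breadth-first search."""
    n = len(adjacency)
    labels = -np.ones(n, int)
    cur = 0
    for start in range(n):
        if labels[start] >= 0:
            continue
        queue = [start]
        labels[start] = cur
        while queue:
            u = queue.pop()
            for v in range(n):
                if adjacency[u, v] and labels[v] < 0:
                    labels[v] = cur
                    queue.append(v)
        cur += 1
    return labels


def _partition(labels):
    out = {}
    for c, k in enumerate(labels):
        out.setdefault(int(k), set()).add(c)
    return sorted(map(frozenset, out.values()), key=sorted)


class TestClusterFrame:
    def test_pair_and_singleton(self):
        traj, frame = _chains_at([[0, 0, 0], [9, 0, 0], [50, 0, 0]])
        labels = cluster_series(traj)[0]
        assert labels.labels[0] == labels.labels[1]
        assert labels.labels[2] != labels.labels[0]
        assert sorted(labels.cluster_sizes().tolist()) == [1, 2]

    def test_transitivity(self):
        traj, _ = _chains_at([[0, 0, 0], [9, 0, 0], [18, 0, 0]])
        labels = cluster_series(traj)[0]
        assert len(set(labels.labels)) == 1  # A-B 9, B-C 9, A-C 18: one cluster

    def test_min_image_linking(self):
        traj, _ = _chains_at([[1, 0, 0], [49, 0, 0]], box=[50, 50, 50],
                             periodic=("X", "Y", "Z"))
        labels = cluster_series(traj)[0]
        assert len(set(labels.labels)) == 1

    def test_multi_ca_chains_use_minimum_linkage(self):
        # chains whose nearest CAs touch even though centroids are far apart
        tops = [
            ChainTopology("A", [Residue("GLN", i + 1, (("CA", "C"),)) for i in range(2)]),
            ChainTopology("B", [Residue("GLN", i + 1, (("CA", "C"),)) for i in range(2)]),
        ]
        coords = np.array([[0, 0, 0], [30, 0, 0], [38, 0, 0], [70, 0, 0]], float)
        traj = Trajectory(tops, [Frame(coords)])
        labels = cluster_series(traj)[0]
        assert len(set(labels.labels)) == 1

    def test_chain_without_ca_errors(self):
        top = ChainTopology("A", [Residue("GLN", 1, (("CB", "C"),))])
        traj = Trajectory([top], [Frame(np.zeros((1, 3)))])
        with pytest.raises(ValueError, match="CA"):
            cluster_series(traj)

    def test_matches_bfs_oracle_on_random_frames(self, rng):
        for _ in range(25):
            n = 30
            pos = rng.uniform(0, 60, (n, 3))
            traj, frame = _chains_at(pos)
            labels = cluster_series(traj)[0]
            d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
            adj = (d <= 10.0) & ~np.eye(n, dtype=bool)
            oracle = _bfs_oracle(adj)
            assert _partition(labels.labels) == _partition(oracle)

    def test_relabeling_invariance(self, rng):
        pos = rng.uniform(0, 40, (12, 3))
        perm = rng.permutation(12)
        t1, _ = _chains_at(pos)
        t2, _ = _chains_at(pos[perm])
        p1 = _partition(cluster_series(t1)[0].labels)
        p2 = [frozenset(int(perm[c]) for c in grp)
              for grp in _partition(cluster_series(t2)[0].labels)]
        assert p1 == sorted(p2, key=sorted)


class TestFractions:
    def test_all_monomers(self):
        labels = ClusterLabels(np.arange(10))
        assert largest_cluster_fraction(labels) == pytest.approx(0.1)

    def test_single_cluster(self):
        labels = ClusterLabels(np.zeros(7, int))
        assert largest_cluster_fraction(labels) == pytest.approx(1.0)

    def test_sizes_3_2_1(self):
        labels = ClusterLabels([0, 0, 0, 1, 1, 2])
        assert largest_cluster_fraction(labels, 6) == pytest.approx(0.5)

    def test_monomer_series_extremes(self):
        traj, _ = _chains_at([[0, 0, 0], [100, 0, 0], [200, 0, 0]])
        assert monomer_fraction_series(traj)[0] == pytest.approx(1.0)
        traj2, _ = _chains_at([[0, 0, 0], [5, 0, 0], [10, 0, 0]])
        assert monomer_fraction_series(traj2)[0] == pytest.approx(0.0)

    def test_conservation_and_complement(self, rng):
        for _ in range(10):
            pos = rng.uniform(0, 50, (20, 3))
            traj, _ = _chains_at(pos)
            labels = cluster_series(traj)[0]
            sizes = labels.cluster_sizes()
            assert sizes.sum() == 20
            mono = monomer_fraction_series([labels])[0]
            in_oligomers = sizes[sizes >= 2].sum() / 20
            assert mono + in_oligomers == pytest.approx(1.0)

    @settings(max_examples=30, deadline=None)
    @given(labels=st.lists(st.integers(0, 5), min_size=2, max_size=30))
    def test_largest_fraction_bounds(self, labels):
        lab = ClusterLabels(labels)
        f = largest_cluster_fraction(lab)
        assert 1.0 / len(labels) <= f <= 1.0

    def test_merging_never_shrinks_largest(self, rng):
        # adding edges (lower cutoff -> higher cutoff) only merges clusters
        pos = rng.uniform(0, 60, (15, 3))
        traj, _ = _chains_at(pos)
        fracs = [
            largest_cluster_fraction(cluster_series(traj, cutoff=c)[0])
            for c in (5.0, 10.0, 20.0, 40.0)
        ]
        assert fracs == sorted(fracs)


class TestTHalf:
    def test_linear_interpolation(self):
        assert t_half([0, 1, 2, 3], [1.0, 0.8, 0.6, 0.4]) == pytest.approx(2.5)

    def test_constant_series_flagged(self):
        with pytest.warns(UserWarning, match="never"):
            assert t_half([0, 1, 2], [0.8, 0.8, 0.8]) is None

    def test_exponential_decay_closed_form(self):
        tau = 7.0
        times = np.arange(0.0, 40.0, 0.5)
        series = np.exp(-times / tau)
        got = t_half(times, series)
        assert abs(got - tau * np.log(2)) <= 0.5  # within one frame spacing

    def test_zero_start_errors(self):
        with pytest.raises(ValueError):
            t_half([0, 1], [0.0, 0.0])


class TestOligomerDistribution:
    def test_single_frame_dimer_fraction(self):
        rep = ([0.0], [np.array([2, 2, 1])])
        before, after = oligomer_distribution([rep], t_half_value=1.0,
                                              window_length=10.0)
        assert before.fractions == {2: 1.0}

    def test_chain_weighting(self):
        rep = ([0.0], [np.array([2, 2, 1])])
        before, _ = oligomer_distribution([rep], 1.0, 10.0, weighting="chains")
        assert before.fractions[2] == pytest.approx(4 / 5)
        assert before.fractions[1] == pytest.approx(1 / 5)

    def test_fractions_sum_to_one(self, rng):
        times = np.arange(0.0, 10.0)
        sizes = [rng.integers(1, 8, size=6) for _ in times]
        before, after = oligomer_distribution([(times, sizes)], 5.0, 5.0)
        assert sum(before.fractions.values()) == pytest.approx(1.0)
        assert sum(after.fractions.values()) == pytest.approx(1.0)

    def test_identical_replicates_sem_zero(self):
        rep = (np.array([0.0, 1.0]), [np.array([2, 3]), np.array([5])])
        before, after = oligomer_distribution([rep, rep], 2.0, 10.0)
        assert all(v == 0.0 for v in before.sem.values())

    def test_window_truncation_warns(self):
        rep = (np.array([0.0, 1.0, 2.0]),
               [np.array([2]), np.array([2]), np.array([2])])
        with pytest.warns(UserWarning, match="truncat"):
            oligomer_distribution([rep], 1.0, window_length=500.0)

    def test_undefined_thalf_rejected(self):
        with pytest.raises(ValueError):
            oligomer_distribution([([0.0], [np.array([2])])], None)


class TestMidsize:
    def test_all_dimers(self):
        rep = ([0.0], [np.array([2, 2, 2])])
        before, _ = oligomer_distribution([rep], 1.0, 10.0)
        assert midsize_fraction(before) == 0.0

    def test_all_pentamers(self):
        rep = ([0.0], [np.array([5, 5])])
        before, _ = oligomer_distribution([rep], 1.0, 10.0)
        assert midsize_fraction(before) == pytest.approx(1.0)

    def test_uniform_sizes_1_to_20(self):
        rep = ([0.0], [np.arange(1, 21)])
        before, _ = oligomer_distribution([rep], 1.0, 10.0, weighting="oligomers")
        # sizes 2..20 among oligomers; 5..13 is 9 of 19
        assert midsize_fraction(before) == pytest.approx(9 / 19)

    def test_empty_distribution_warns(self):
        from fibrilkit.aggregation_kinetics import OligomerDistribution

        with pytest.warns(UserWarning, match="empty"):
            assert midsize_fraction(OligomerDistribution("BEFORE_THALF", {})) == 0.0


def test_kinetics_series_on_lattice(bt_lattice):
    traj = Trajectory(bt_lattice.topologies, [bt_lattice.frame])
    ks = kinetics_series(traj, beta=True)
    # a fibril lattice is one connected cluster with beta content
    assert ks.largest_cluster_fraction[0] == pytest.approx(1.0)
    assert ks.monomer_fraction[0] == pytest.approx(0.0)
    assert ks.beta_fraction[0] > 0.2
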