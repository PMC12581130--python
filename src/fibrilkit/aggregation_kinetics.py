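"""Aggregation statistics: chain clustering, largest-cluster and monomer
fractions, monomer-depletion half-life, oligomer-order distributions and
beta-fraction time series.

Two molecules are neighbours when the minimum over all CA-CA pairs of their
minimum-image distance is within the cutoff (10 Angstrom by default);
clusters are the connected components of that neighbour graph
(single-linkage transitive closure).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .io_core import Frame, Trajectory, pairwise_min_image_distances

__all__ = [
    "ClusterLabels",
    "KineticsSeries",
    "OligomerDistribution",
    "cluster_frame",
    "largest_cluster_fraction",
    "cluster_series",
    "monomer_fraction_series",
    "kinetics_series",
    "t_half",
    "oligomer_distribution",
    "midsize_fraction",
    "beta_fraction_series",
]

DEFAULT_CLUSTER_CUTOFF = 10.0  # Angstrom, CA-CA


@dataclass
class ClusterLabels:
    """Cluster id per chain for one frame."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, int)

    @property
    def n_chains(self) -> int:
        return len(self.labels)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.labels.max() + 1 if
                           len(self.labels) else 0)

    def cluster_sizes(self) -> np.ndarray:
        """Sizes of all clusters (unordered, only non-empty)."""
        s = self.sizes()
        return s[s > 0]


@dataclass
class KineticsSeries:
    """Time-resolved aggregation observables; fractions are per frame."""

    times: np.ndarray
    monomer_fraction: np.ndarray
    largest_cluster_fraction: np.ndarray
    beta_fraction: np.ndarray | None = None

    def __post_init__(self):
        for name in ("monomer_fraction", "largest_cluster_fraction"):
            v = getattr(self, name)
            if v is not None and (np.any(v < 0) or np.any(v > 1)):
                raise ValueError(f"{name} outside [0,1]")


@dataclass
class OligomerDistribution:
    """Cluster-size histogram pooled over a time window.

    `fractions` maps size -> fraction; normalized over oligomers (size >= 2)
    by default or over chains when weighting='chains'.  `sem` carries the
    standard error over replicates when several trajectories were pooled.
    """

    window: str  # BEFORE_THALF or AFTER_THALF
    fractions: dict
    weighting: str = "oligomers"
    sem: dict | None = None


def _chain_ca_coords(traj: Trajectory):
    slices = traj.chain_slices()
    out = []
    for c, top in enumerate(traj.topologies):
        names = top.atom_names()
        idx = [slices[c].start + k for k, n in enumerate(names) if n == "CA"]
        if not idx:
            raise ValueError(f"chain {top.chain_id} has no CA atoms")
        out.append(np.array(idx, int))
    return out


def cluster_frame(frame: Frame, ca_indices, cutoff: float = DEFAULT_CLUSTER_CUTOFF
                  ) -> ClusterLabels:
    """Connected-component clustering of chains for one frame.

    `ca_indices` is a list of per-chain CA atom index arrays (as produced by
    trajectory bookkeeping); chains i, j are linked when any CA pair is
    within `cutoff` under the minimum image convention.
    """
    n = len(ca_indices)
    pmask = frame.periodic_mask()
    rows, cols = [], []
    cas = [frame.coordinates[idx] for idx in ca_indices]
    for i in range(n):
        for j in range(i + 1, n):
            d = pairwise_min_image_distances(cas[i], cas[j], frame.box, pmask)
            if d.min() <= cutoff:
                rows.append(i)
                cols.append(j)
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    return ClusterLabels(labels)


def largest_cluster_fraction(labels: ClusterLabels, n_chains: int | None = None) -> float:
    """Size of the biggest cluster normalized by the chain count."""
    n = n_chains if n_chains is not None else labels.n_chains
    sizes = labels.cluster_sizes()
    return float(sizes.max()) / n if len(sizes) else 0.0


def cluster_series(traj: Trajectory, cutoff: float = DEFAULT_CLUSTER_CUTOFF):
    """ClusterLabels for every frame of a trajectory."""
    ca = _chain_ca_coords(traj)
    return [cluster_frame(f, ca, cutoff) for f in traj.frames]


def monomer_fraction_series(traj_or_labels, cutoff: float = DEFAULT_CLUSTER_CUTOFF
                            ) -> np.ndarray:
    """Fraction of chains in clusters of size 1, per frame."""
    labels = traj_or_labels if isinstance(traj_or_labels, list) \
        else cluster_series(traj_or_labels, cutoff)
    out = np.empty(len(labels))
    for k, lab in enumerate(labels):
        sizes = lab.sizes()
        out[k] = (sizes[lab.labels] == 1).mean()
    return out


def kinetics_series(traj: Trajectory, cutoff: float = DEFAULT_CLUSTER_CUTOFF,
                    beta: bool = False) -> KineticsSeries:
    """Monomer and largest-cluster fractions (and optionally the beta-sheet
    fraction) over time."""
    labels = cluster_series(traj, cutoff)
    mono = monomer_fraction_series(labels)
    largest = np.array([largest_cluster_fraction(l) for l in labels])
    bf = beta_fraction_series(traj) if beta else None
    return KineticsSeries(traj.times, mono, largest, bf)


def t_half(times, fractions) -> float | None:
    """First time the series crosses half its initial value, linearly
    interpolated between the bracketing frames; None when it never crosses."""
    times = np.asarray(times, float)
    f = np.asarray(fractions, float)
    if len(f) == 0 or f[0] <= 0:
        raise ValueError("series must start at a positive fraction")
    target = f[0] / 2.0
    below = np.flatnonzero(f <= target)
    if len(below) == 0:
        warnings.warn("monomer fraction never decreases to half its initial value")
        return None
    k = below[0]
    if k == 0:
        return float(times[0])
    t0, t1 = times[k - 1], times[k]
    f0, f1 = f[k - 1], f[k]
    if f1 == f0:
        return float(t1)
    return float(t0 + (f0 - target) / (f0 - f1) * (t1 - t0))


def _pool_sizes(times, size_lists, lo, hi):
    pooled = []
    for t, sizes in zip(times, size_lists):
        if lo <= t < hi:
            pooled.extend(int(s) for s in sizes)
    return pooled


def _histogram(sizes, weighting):
    if weighting == "oligomers":
        sizes = [s for s in sizes if s >= 2]
        weights = np.ones(len(sizes))
    elif weighting == "chains":
        weights = np.asarray(sizes, float)
    else:
        raise ValueError("weighting must be 'oligomers' or 'chains'")
    if not len(sizes):
        return {}
    total = weights.sum()
    out = {}
    for s, w in zip(sizes, weights):
        out[s] = out.get(s, 0.0) + w / total
    return out


def oligomer_distribution(replicates, t_half_value: float,
                          window_length: float = 200.0,
                          weighting: str = "oligomers"):
    """Oligomer-order distributions before t1/2 and in the window after it.

    `replicates` is a list of (times, per-frame cluster-size arrays) pairs,
    one per independent trajectory.  Size histograms are pooled over frames
    in [0, t_half) and [t_half, t_half + window_length]; with >= 2 replicates
    the per-size SEM across replicates is attached.  Returns the
    (before, after) OligomerDistribution pair.
    """
    if t_half_value is None:
        raise ValueError("t_half must be defined")
    results = []
    for tag, lo, hi in (
        ("BEFORE_THALF", 0.0, t_half_value),
        ("AFTER_THALF", t_half_value, t_half_value + window_length),
    ):
        per_rep = []
        for times, size_lists in replicates:
            times = np.asarray(times, float)
            if tag == "AFTER_THALF" and len(times) and hi > times[-1]:
                warnings.warn("window extends past trajectory end; truncated")
            per_rep.append(_histogram(_pool_sizes(times, size_lists, lo, hi),
                                      weighting))
        pooled = _histogram(
            [s for (times, size_lists) in replicates
             for s in _pool_sizes(times, size_lists, lo, hi)],
            weighting,
        )
        sem = None
        if len(per_rep) >= 2:
            sem = {}
            for size in pooled:
                vals = np.array([h.get(size, 0.0) for h in per_rep])
                sem[size] = float(vals.std(ddof=1) / np.sqrt(len(vals)))
        results.append(OligomerDistribution(tag, pooled, weighting, sem))
    return tuple(results)


def midsize_fraction(distribution: OligomerDistribution,
                     size_range=(5, 13)) -> float:
    """Summed fraction of oligomers in the (inclusive) size range."""
    if not distribution.fractions:
        warnings.warn("empty oligomer distribution")
        return 0.0
    lo, hi = size_range
    return float(sum(p for s, p in distribution.fractions.items() if lo <= s <= hi))


def beta_fraction_series(traj: Trajectory) -> np.ndarray:
    """Per-frame fraction of residues assigned E (beta strand), over all chains."""
    from .structure_metrics import assign_secondary_structure

    ss = assign_secondary_structure(traj)
    return ss.per_frame_fraction("E")
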