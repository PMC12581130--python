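"""Synthetic input generators standing in for MD production runs.

Provides every input the analysis pipeline needs without simulation:
random-coil monomer ensembles (optionally with a partially helical span),
Gaussian-perturbed fibril lattices, dense multi-chain packings, and a
stochastic dock-and-lock aggregation generator with two docking channels
(backbone-mediated and side-chain interlocking) plus tunable small-oligomer
stability.  The generator is an explicit stand-in for coarse-grained
dynamics: mechanisms are encoded as mass-action rates, not emergent physics,
which gives the analysis suite a ground truth to close against.

All generators take an explicit seed and are bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .fibril_builder import FibrilLattice, build_peptide_chain
from .io_core import ChainTopology, Frame, Residue, Trajectory

__all__ = [
    "CoilEnsembleSpec",
    "DockLockParams",
    "DockLockState",
    "DockLockTrajectory",
    "gen_coil_ensemble",
    "perturb_fibril",
    "simulate_dock_lock",
    "realize_coordinates",
    "recover_rates",
    "q16_like_params",
    "h16_like_params",
    "Q16_SEQUENCE",
    "H16_SEQUENCE",
    "H16_DOMAIN_SPANS",
]

#: 16-residue glutamine tract and its flanked construct
Q16_SEQUENCE = ("GLN",) * 16
H16_SEQUENCE = tuple(
    {"M": "MET", "A": "ALA", "T": "THR", "L": "LEU", "E": "GLU", "K": "LYS",
     "F": "PHE", "S": "SER"}[c] for c in "MATLEKLMKAFESLKSF"
) + ("GLN",) * 16 + ("PRO",) * 5
H16_DOMAIN_SPANS = {"N17": (1, 17), "QCORE": (18, 33), "P5": (34, 38)}

_HELIX_PHI, _HELIX_PSI = -57.0, -47.0
_CLASH_DIST = 1.8
_MAX_RETRIES = 50


@dataclass(frozen=True)
class CoilEnsembleSpec:
    """Random-coil ensemble layout.

    `persistence` (residues) sets the correlation length of the dihedral
    noise along the chain; `helical_span` (1-based, inclusive) adopts ideal
    helix dihedrals in exactly `helicity` of the frames.
    """

    n_chains: int = 1
    n_res: int = 16
    n_frames: int = 10
    persistence: float = 2.0
    sequence: tuple | None = None
    helical_span: tuple | None = None
    helicity: float = 0.0
    box: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.helicity <= 1.0:
            raise ValueError("helicity fraction must be in [0,1]")
        if self.n_chains < 1 or self.n_res < 2 or self.n_frames < 1:
            raise ValueError("invalid ensemble dimensions")
        if self.sequence is not None and len(self.sequence) != self.n_res:
            raise ValueError("sequence length must equal n_res")

    def resolved_sequence(self) -> tuple:
        return self.sequence if self.sequence is not None else ("GLN",) * self.n_res


def _smooth_noise(rng, n, persistence):
    """AR(1)-smoothed standard-normal sequence (unit variance)."""
    x = rng.standard_normal(n)
    if persistence <= 1:
        return x
    rho = np.exp(-1.0 / persistence)
    out = np.empty(n)
    out[0] = x[0]
    for i in range(1, n):
        out[i] = rho * out[i - 1] + np.sqrt(1 - rho ** 2) * x[i]
    return out


def _coil_dihedrals(rng, n_res, persistence):
    """phi/psi draws from the extended (beta/PPII) coil basin with
    persistence-correlated noise."""
    phi = -110.0 + 35.0 * _smooth_noise(rng, n_res, persistence)
    psi = 135.0 + 40.0 * _smooth_noise(rng, n_res, persistence)
    return np.clip(phi, -179.0, -30.0), np.clip(psi, 60.0, 179.0)


def _chain_clashes(coords) -> bool:
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    n = len(coords)
    i, j = np.triu_indices(n, k=4)  # skip bonded/angle neighbours
    return bool((d[i, j] < _CLASH_DIST).any())


def _coil_topologies(spec: CoilEnsembleSpec):
    seq = spec.resolved_sequence()
    rng = np.random.default_rng(spec.seed)
    phi, psi = _coil_dihedrals(rng, spec.n_res, spec.persistence)
    coords, atoms = build_peptide_chain(seq, phi, psi)
    tops = []
    from .fibril_builder import _CHAIN_IDS

    for c in range(spec.n_chains):
        residues = [Residue(seq[k], k + 1, atoms[k]) for k in range(spec.n_res)]
        tops.append(ChainTopology(_CHAIN_IDS[c % len(_CHAIN_IDS)], residues))
    return tops


def gen_coil_ensemble(spec: CoilEnsembleSpec) -> Trajectory:
    """Generate a self-avoiding random-coil ensemble.

    Each frame redraws per-residue dihedrals from the extended coil basin
    (so the ensemble is helix-free at helicity 0); when a helical span is
    requested, exactly round(helicity * n_frames) frames (chosen by the
    seeded RNG) carry ideal helix dihedrals across that span.  Chains are
    placed on a jittered grid; frames that produce intra-chain steric
    clashes are resampled up to a retry budget.
    """
    rng = np.random.default_rng(spec.seed)
    seq = spec.resolved_sequence()
    tops = _coil_topologies(spec)

    n_helical = int(round(spec.helicity * spec.n_frames))
    helical_frames = set(
        rng.choice(spec.n_frames, size=n_helical, replace=False).tolist()
    ) if spec.helical_span else set()

    # chain anchor grid: generous spacing so chains never interpenetrate
    extent = 3.6 * spec.n_res + 10.0
    side = int(np.ceil(spec.n_chains ** (1 / 3)))
    anchors = []
    for c in range(spec.n_chains):
        gx, gy, gz = c % side, (c // side) % side, c // (side * side)
        anchors.append(np.array([gx, gy, gz], float) * extent
                       + rng.uniform(-2, 2, 3))

    if spec.box is not None:
        box = np.asarray(spec.box, float)
    elif spec.n_chains > 1:
        box = np.full(3, side * extent)
    else:
        box = None

    frames = []
    for fi in range(spec.n_frames):
        frame_coords = []
        for c in range(spec.n_chains):
            for attempt in range(_MAX_RETRIES):
                phi, psi = _coil_dihedrals(rng, spec.n_res, spec.persistence)
                if fi in helical_frames:
                    lo, hi = spec.helical_span
                    phi[lo - 1 : hi] = _HELIX_PHI
                    psi[lo - 1 : hi] = _HELIX_PSI
                coords, _ = build_peptide_chain(seq, phi, psi)
                if not _chain_clashes(coords):
                    break
            else:
                raise RuntimeError(
                    f"self-avoidance unsatisfied after {_MAX_RETRIES} retries"
                )
            # random orientation, anchored on the grid
            q = rng.standard_normal(4)
            q /= np.linalg.norm(q)
            w, x, y, z = q
            R = np.array([
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ])
            coords = (coords - coords.mean(0)) @ R.T + anchors[c]
            frame_coords.append(coords)
        frames.append(Frame(np.concatenate(frame_coords), time=float(fi), box=box,
                            periodic_axes=frozenset("XYZ") if box is not None
                            else frozenset()))
    return Trajectory(tops, frames)


def perturb_fibril(lattice: FibrilLattice, sigma: float, n_frames: int,
                   seed: int = 0) -> Trajectory:
    """I.i.d. Gaussian coordinate noise per atom per frame; sigma=0
    reproduces the input lattice exactly in every frame."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    base = lattice.frame
    frames = []
    for fi in range(n_frames):
        noise = rng.normal(0.0, sigma, base.coordinates.shape) if sigma > 0 \
            else np.zeros_like(base.coordinates)
        frames.append(replace(base, coordinates=base.coordinates + noise,
                              time=float(fi)))
    return Trajectory(lattice.topologies, frames)


# --- dock-and-lock generator ---------------------------------------------------


@dataclass(frozen=True)
class DockLockParams:
    """Mass-action rates (per ns) of the dock-and-lock reaction network.

    Two docking channels add monomers to clusters: backbone-mediated
    (k_add_bb) and side-chain interlocking (k_add_sc).  Clusters of size
    <= size_s with at least one non-locked chain may shed a chain
    (k_off_small); DOCKED chains convert irreversibly to LOCKED at k_lock.
    """

    n_chains: int
    k_dim: float = 0.0
    k_add_bb: float = 0.0
    k_add_sc: float = 0.0
    k_coag: float = 0.0
    k_off_small: float = 0.0
    k_lock: float = 0.0
    size_s: int = 4
    seed: int = 0

    def __post_init__(self):
        rates = (self.k_dim, self.k_add_bb, self.k_add_sc, self.k_coag,
                 self.k_off_small, self.k_lock)
        if any(r < 0 for r in rates):
            raise ValueError("rates must be >= 0")
        if self.size_s < 2:
            raise ValueError("size_s must be >= 2")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")


COIL, DOCKED, LOCKED = "COIL", "DOCKED", "LOCKED"


def q16_like_params(n_chains: int = 80, seed: int = 0) -> "DockLockParams":
    """Illustrative (non-physical) rate set for the flanking-domain-free
    regime: small oligomers are unstable (high k_off_small), so nuclei rarely
    survive and the pre-t-half population stays dimer-rich."""
    return DockLockParams(n_chains=n_chains, k_dim=2e-4, k_add_bb=0.01,
                          k_add_sc=0.01, k_coag=0.002, k_off_small=6.0,
                          k_lock=0.005, size_s=4, seed=seed)


def h16_like_params(n_chains: int = 80, seed: int = 0) -> "DockLockParams":
    """Illustrative rate set for the flanked construct: identical to the
    Q16-like set except k_off_small -> 0, so several nuclei survive and the
    system passes through a stable midsized-oligomer population."""
    return replace(q16_like_params(n_chains, seed), k_off_small=0.0)


@dataclass
class DockLockState:
    """Sampled snapshot: cluster id and conformational state per chain."""

    time: float
    cluster_of: np.ndarray
    chain_state: np.ndarray

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.cluster_of)[np.bincount(self.cluster_of) > 0] \
            if len(self.cluster_of) else np.array([], int)

    def partition(self) -> list:
        out = {}
        for c, k in enumerate(self.cluster_of):
            out.setdefault(int(k), []).append(c)
        return sorted(out.values(), key=lambda m: (len(m), m), reverse=True)

    def monomer_fraction(self) -> float:
        sizes = np.bincount(self.cluster_of)
        return float((sizes[self.cluster_of] == 1).mean())

    def largest_cluster_fraction(self) -> float:
        return float(np.bincount(self.cluster_of).max()) / len(self.cluster_of)


@dataclass
class DockLockTrajectory:
    """Event log plus regularly sampled states of one stochastic run."""

    params: DockLockParams
    events: list  # (time, reaction name, participant chain ids)
    states: list  # DockLockState at the sample times

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.states])

    def monomer_fraction_series(self) -> np.ndarray:
        return np.array([s.monomer_fraction() for s in self.states])

    def largest_cluster_fraction_series(self) -> np.ndarray:
        return np.array([s.largest_cluster_fraction() for s in self.states])

    def size_lists(self) -> list:
        return [np.bincount(s.cluster_of)[np.bincount(s.cluster_of) > 0]
                for s in self.states]


def simulate_dock_lock(params: DockLockParams, t_end: float,
                       sample_dt: float = 1.0) -> DockLockTrajectory:
    """Exact Gillespie simulation of the dock-and-lock network.

    Reactions and propensities (M monomers, C clusters of size >= 2):
    dimerization k_dim*M*(M-1)/2; monomer addition (k_add_bb+k_add_sc)*M*C
    split between the two channels by their rates; coagulation
    k_coag*C*(C-1)/2; dissociation k_off_small per eligible cluster
    (2 <= size <= size_s, >= 1 non-locked chain); locking k_lock per DOCKED
    chain.  Chain count is conserved and LOCKED chains never revert.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    rng = np.random.default_rng(params.seed)
    n = params.n_chains
    clusters = [[c] for c in range(n)]  # list of chain-id lists
    state = np.array([COIL] * n, dtype="<U6")
    events = []
    samples = []
    sample_times = np.arange(0.0, t_end + 1e-12, sample_dt)
    next_sample = 0

    def snapshot(t):
        cluster_of = np.empty(n, int)
        for k, members in enumerate(clusters):
            for c in members:
                cluster_of[c] = k
        # compact ids
        _, compact = np.unique(cluster_of, return_inverse=True)
        return DockLockState(float(t), compact, state.copy())

    t = 0.0
    k_add = params.k_add_bb + params.k_add_sc
    while True:
        monomers = [k for k, m in enumerate(clusters) if len(m) == 1]
        multis = [k for k, m in enumerate(clusters) if len(m) >= 2]
        eligible_off = [
            k for k in multis
            if len(clusters[k]) <= params.size_s
            and any(state[c] != LOCKED for c in clusters[k])
        ]
        docked = [c for k in multis for c in clusters[k] if state[c] == DOCKED]
        M, C = len(monomers), len(multis)
        props = np.array([
            params.k_dim * M * (M - 1) / 2.0,
            k_add * M * C,
            params.k_coag * C * (C - 1) / 2.0,
            params.k_off_small * len(eligible_off),
            params.k_lock * len(docked),
        ])
        total = props.sum()
        if total <= 0:
            break
        dt = rng.exponential(1.0 / total)
        t_next = t + dt
        while next_sample < len(sample_times) and sample_times[next_sample] < t_next:
            samples.append(snapshot(sample_times[next_sample]))
            next_sample += 1
        if t_next > t_end:
            break
        t = t_next
        r = rng.choice(5, p=props / total)
        if r == 0:  # dimerization
            a, b = rng.choice(len(monomers), size=2, replace=False)
            ka, kb = monomers[a], monomers[b]
            ca, cb = clusters[ka][0], clusters[kb][0]
            clusters[ka] = clusters[ka] + clusters[kb]
            clusters[kb] = []
            for c in (ca, cb):
                if state[c] == COIL:
                    state[c] = DOCKED
            events.append((t, "dim", (ca, cb)))
        elif r == 1:  # monomer addition via one of two channels
            km = monomers[rng.integers(len(monomers))]
            kc = multis[rng.integers(len(multis))]
            c = clusters[km][0]
            clusters[kc] = clusters[kc] + clusters[km]
            clusters[km] = []
            if state[c] == COIL:
                state[c] = DOCKED
            channel = "add_bb" if rng.random() < (params.k_add_bb / k_add
                                                  if k_add > 0 else 0.5) \
                else "add_sc"
            events.append((t, channel, (c, kc)))
        elif r == 2:  # coagulation
            a, b = rng.choice(len(multis), size=2, replace=False)
            ka, kb = multis[a], multis[b]
            clusters[ka] = clusters[ka] + clusters[kb]
            clusters[kb] = []
            events.append((t, "coag", (ka, kb)))
        elif r == 3:  # dissociation of one non-locked chain
            k = eligible_off[rng.integers(len(eligible_off))]
            cands = [c for c in clusters[k] if state[c] != LOCKED]
            c = cands[rng.integers(len(cands))]
            clusters[k] = [x for x in clusters[k] if x != c]
            clusters.append([c])
            state[c] = COIL
            if len(clusters[k]) == 1:
                lone = clusters[k][0]
                if state[lone] == DOCKED:
                    state[lone] = COIL
            events.append((t, "off", (c, k)))
        else:  # locking
            c = docked[rng.integers(len(docked))]
            state[c] = LOCKED
            events.append((t, "lock", (c,)))
        clusters = [m for m in clusters if m]
    while next_sample < len(sample_times):
        samples.append(snapshot(sample_times[next_sample]))
        next_sample += 1
    return DockLockTrajectory(params, events, samples)


# --- coordinate realization ----------------------------------------------------


def realize_coordinates(dock_state: DockLockState, template_coords: np.ndarray,
                        template_topology: ChainTopology,
                        cutoff: float = 10.0, seed: int = 0,
                        box: np.ndarray | None = None):
    """Render a dock-and-lock snapshot as 3D coordinates.

    Clusters of size n become n template chains stacked at 4.8 A spacing
    (adjacent chains well within `cutoff`); cluster anchors sit on a
    shuffled 3D grid whose cell size guarantees inter-cluster separation
    > 1.5 * cutoff, so CA clustering of the realized frame recovers exactly
    the generator's partition.  Returns (topologies, Frame).
    """
    from .fibril_builder import _CHAIN_IDS

    rng = np.random.default_rng(seed)
    part = dock_state.partition()
    n_chains = len(dock_state.cluster_of)
    tpl = template_coords - template_coords.mean(axis=0)
    tpl_radius = float(np.linalg.norm(tpl, axis=1).max())
    stack = np.array([0.0, 4.8, 0.0])
    max_size = max(len(m) for m in part)
    diameter = 2 * tpl_radius + (max_size - 1) * 4.8
    cell = diameter + 1.5 * cutoff
    side = int(np.ceil(len(part) ** (1 / 3)))
    needed = side * cell
    if box is not None:
        box = np.asarray(box, float)
        if np.any(box < needed):
            raise ValueError(
                f"box {box} too small; need >= {needed:.1f} A per edge for "
                f"{len(part)} clusters"
            )
        side = int(min(box) // cell)
        if side ** 3 < len(part):
            raise ValueError("box too small for non-overlapping placement")
    else:
        box = np.full(3, needed)
    cells = [(i, j, k) for i in range(side) for j in range(side) for k in range(side)]
    rng.shuffle(cells)

    coords_per_chain = [None] * n_chains
    for members, cell_idx in zip(part, cells):
        anchor = (np.array(cell_idx, float) + 0.5) * cell
        anchor = anchor + rng.uniform(-0.5, 0.5, 3)
        for rank, chain in enumerate(members):
            offset = (rank - (len(members) - 1) / 2.0) * stack
            coords_per_chain[chain] = tpl + anchor + offset
    topologies = []
    for c in range(n_chains):
        topologies.append(ChainTopology(
            _CHAIN_IDS[c % len(_CHAIN_IDS)],
            [Residue(r.name, r.index, r.atoms, r.domain)
             for r in template_topology.residues],
        ))
    frame = Frame(np.concatenate(coords_per_chain), time=dock_state.time,
                  box=box, periodic_axes=frozenset())
    return topologies, frame


def recover_rates(replicates) -> float:
    """Least-squares estimate of k_dim from replicate monomer-count series.

    For a pure dimerization process E[dM/dt] = -k * M(M-1); pooling the
    increments over replicates gives k = sum(-dM) / sum(M(M-1) dt) over the
    early-decay window (M above half its initial value).
    """
    num = 0.0
    den = 0.0
    for times, counts in replicates:
        times = np.asarray(times, float)
        m = np.asarray(counts, float)
        if len(m) < 2 or m[0] < 2:
            raise ValueError("degenerate monomer series")
        keep = m >= m[0] / 2.0
        for k in range(len(m) - 1):
            if not (keep[k] and keep[k + 1]):
                break
            dt = times[k + 1] - times[k]
            num += m[k] - m[k + 1]
            den += m[k] * (m[k] - 1) * dt
    if den == 0:
        return 0.0
    return float(num / den)
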