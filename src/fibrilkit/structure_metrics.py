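"""Structural analysis suite: dihedral circular statistics, sheet/strand
spacings, hydrogen-bond-based secondary structure, end-to-end conformer
classification, residue contact maps, helicity profiles and radius of
gyration.

All angle averaging uses circular statistics to avoid wrap-around bias at
+/-180 degrees.  Metrics that measure through-space distances are
minimum-image aware; end-to-end and Rg computations unwrap chains first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._geom import ks_hbond_energy, reconstruct_amide_hydrogens, unit, wrap_angle
from .io_core import (
    ELEMENT_MASSES,
    Frame,
    Trajectory,
    min_image_vectors,
    pairwise_min_image_distances,
    unwrap_chains,
)

__all__ = [
    "DihedralSeries",
    "CircularStats",
    "SecondaryStructureSeries",
    "ConformerClassification",
    "SpacingMetrics",
    "backbone_and_sidechain_dihedrals",
    "circular_stats",
    "spacing_metrics",
    "assign_secondary_structure",
    "end_to_end_classify",
    "residue_contact_map",
    "helicity_profile",
    "radius_of_gyration",
]


# --- dihedrals ----------------------------------------------------------------


def _dihedral_array(p0, p1, p2, p3):
    """Vectorized signed torsions (degrees) for stacked coordinate arrays."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1u = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    m1 = np.cross(n1, b1u)
    x = (n1 * n2).sum(-1)
    y = (m1 * n2).sum(-1)
    return wrap_angle(np.degrees(np.arctan2(y, x)))


@dataclass
class DihedralSeries:
    """Per-frame, per-residue dihedral values (NaN where undefined).

    `values` maps angle name (phi/psi/chi1/chi2) to an (n_frames, n_residues)
    array over the flattened residue list of all chains; `chain_of` and
    `residue_pos` locate each column; `conformer` carries 'a'/'b'/'none'
    labels when the input was a built lattice.
    """

    values: dict
    chain_of: np.ndarray
    residue_pos: np.ndarray
    conformer: np.ndarray | None = None

    def select(self, angle: str, conformer: str | None = None,
               pairs: list | None = None) -> np.ndarray:
        """Finite values of one angle, optionally restricted to a conformer
        label or an explicit list of (chain, residue_pos) pairs."""
        v = self.values[angle]
        mask = np.ones(v.shape[1], bool)
        if conformer is not None:
            if self.conformer is None:
                raise ValueError("no conformer labels attached")
            mask &= self.conformer == conformer
        if pairs is not None:
            want = set(pairs)
            mask &= np.array([
                (c, p) in want for c, p in zip(self.chain_of, self.residue_pos)
            ])
        out = v[:, mask].ravel()
        return out[np.isfinite(out)]


def backbone_and_sidechain_dihedrals(traj: Trajectory, lattice=None) -> DihedralSeries:
    """phi/psi/chi1/chi2 per residue per frame (IUPAC convention).

    Terminal residues yield NaN phi or psi; residues missing side-chain atoms
    yield NaN chi.  If `lattice` (a FibrilLattice) is given, its per-strand
    conformer assignment is attached for downstream selection.
    """
    coords = np.stack([f.coordinates for f in traj.frames])
    n_frames = coords.shape[0]
    idx = {k: [] for k in ("N", "CA", "C", "CB", "CG", "CD")}
    chain_of, residue_pos = [], []
    offset = 0
    for c, top in enumerate(traj.topologies):
        for p, res in enumerate(top.residues):
            names = {a: offset + k for k, (a, _) in enumerate(res.atoms)}
            for key in idx:
                idx[key].append(names.get(key, -1))
            chain_of.append(c)
            residue_pos.append(p)
            offset += len(res.atoms)
    chain_of = np.array(chain_of)
    residue_pos = np.array(residue_pos)
    n_res = len(chain_of)
    ai = {k: np.array(v) for k, v in idx.items()}

    same_chain_prev = np.zeros(n_res, bool)
    same_chain_next = np.zeros(n_res, bool)
    same_chain_prev[1:] = chain_of[1:] == chain_of[:-1]
    same_chain_next[:-1] = chain_of[1:] == chain_of[:-1]

    def grab(indices):
        safe = np.clip(indices, 0, coords.shape[1] - 1)
        return coords[:, safe, :]

    out = {k: np.full((n_frames, n_res), np.nan) for k in ("phi", "psi", "chi1", "chi2")}

    has_bb = (ai["N"] >= 0) & (ai["CA"] >= 0) & (ai["C"] >= 0)
    # phi: C(i-1), N, CA, C
    ok = has_bb & same_chain_prev
    ok[1:] &= ai["C"][:-1] >= 0
    if ok.any():
        prev_c = np.roll(ai["C"], 1)
        vals = _dihedral_array(grab(prev_c), grab(ai["N"]), grab(ai["CA"]), grab(ai["C"]))
        out["phi"][:, ok] = vals[:, ok]
    # psi: N, CA, C, N(i+1)
    ok = has_bb & same_chain_next
    ok[:-1] &= ai["N"][1:] >= 0
    if ok.any():
        next_n = np.roll(ai["N"], -1)
        vals = _dihedral_array(grab(ai["N"]), grab(ai["CA"]), grab(ai["C"]), grab(next_n))
        out["psi"][:, ok] = vals[:, ok]
    # chi1: N, CA, CB, CG
    ok = (ai["N"] >= 0) & (ai["CA"] >= 0) & (ai["CB"] >= 0) & (ai["CG"] >= 0)
    if ok.any():
        vals = _dihedral_array(grab(ai["N"]), grab(ai["CA"]), grab(ai["CB"]), grab(ai["CG"]))
        out["chi1"][:, ok] = vals[:, ok]
    # chi2: CA, CB, CG, CD
    ok = (ai["CA"] >= 0) & (ai["CB"] >= 0) & (ai["CG"] >= 0) & (ai["CD"] >= 0)
    if ok.any():
        vals = _dihedral_array(grab(ai["CA"]), grab(ai["CB"]), grab(ai["CG"]), grab(ai["CD"]))
        out["chi2"][:, ok] = vals[:, ok]

    conformer = None
    if lattice is not None:
        conformer = np.array([
            lattice.conformer_of(int(c), int(p)) for c, p in zip(chain_of, residue_pos)
        ])
    return DihedralSeries(out, chain_of, residue_pos, conformer)


@dataclass(frozen=True)
class CircularStats:
    mean: float
    sd: float
    mode: float
    n: int


def circular_stats(values, bin_width: float = 5.0) -> CircularStats:
    """Circular mean/SD (degrees) plus a histogram mode on `bin_width` bins.

    Mode ties are broken toward the bin nearest the circular mean.
    """
    v = np.asarray(values, float).ravel()
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no values")
    rad = np.radians(v)
    s, c = np.sin(rad).mean(), np.cos(rad).mean()
    mean = float(wrap_angle(np.degrees(np.arctan2(s, c))))
    r = min(1.0, float(np.hypot(s, c)))
    sd = float(np.degrees(np.sqrt(-2.0 * np.log(r)))) if r > 0 else np.inf
    edges = np.arange(-180.0, 180.0 + bin_width / 2, bin_width)
    hist, _ = np.histogram(v, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    top = np.flatnonzero(hist == hist.max())
    if len(top) > 1:
        dist = np.abs(wrap_angle(centers[top] - mean))
        top = top[np.argsort(dist)]
    mode = float(centers[top[0]])
    return CircularStats(mean=mean, sd=sd, mode=mode, n=int(v.size))


# --- spacings -----------------------------------------------------------------


@dataclass(frozen=True)
class SpacingMetrics:
    strand_spacing: float | None
    strand_spacing_sd: float | None
    sheet_spacing: float | None
    sheet_spacing_sd: float | None


def _strand_ca_coords(traj: Trajectory, strands, frame_idx: int):
    """{(sheet, slot): CA coords} plus per-strand chain for one frame."""
    coords = traj.frames[frame_idx].coordinates
    slices = traj.chain_slices()
    out = {}
    for c, infos in enumerate(strands):
        top = traj.topologies[c]
        base = slices[c].start
        ca_of = {}
        off = 0
        for p, res in enumerate(top.residues):
            for k, (a, _) in enumerate(res.atoms):
                if a == "CA":
                    ca_of[p] = base + off + k
            off += len(res.atoms)
        for info in infos:
            out[(info.sheet, info.slot)] = coords[[ca_of[p] for p in info.residues]]
    return out


def spacing_metrics(source, strands=None) -> SpacingMetrics:
    """Average strand-to-strand and sheet-to-sheet distances.

    `source` is a FibrilLattice, or a Trajectory with `strands` assignment
    metadata (per chain, a list of StrandInfo).  Strand spacing is the mean
    nearest inter-strand CA-CA distance between adjacent slots of a sheet;
    sheet spacing is the mean distance between least-squares sheet planes.
    Metrics with fewer than 2 strands/sheets are None.
    """
    if strands is None:
        traj = Trajectory(source.topologies, [source.frame])
        strands = source.strands
    else:
        traj = source
    strand_vals, sheet_vals = [], []
    for fi in range(traj.n_frames):
        frame = traj.frames[fi]
        ca = _strand_ca_coords(traj, strands, fi)
        sheets = {}
        for (sheet, slot), xyz in ca.items():
            sheets.setdefault(sheet, {})[slot] = xyz
        for sheet, slots in sheets.items():
            order = sorted(slots)
            for s1, s2 in zip(order, order[1:]):
                d = pairwise_min_image_distances(
                    slots[s1], slots[s2], frame.box, frame.periodic_mask()
                )
                strand_vals.append(float(d.min(axis=1).mean()))
        order = sorted(sheets)
        centroids, normals = {}, {}
        for sheet in order:
            pts = np.concatenate(list(sheets[sheet].values()))
            cen = pts.mean(axis=0)
            _, _, vt = np.linalg.svd(pts - cen)
            centroids[sheet], normals[sheet] = cen, vt[2]
        for s1, s2 in zip(order, order[1:]):
            n = normals[s1] + (normals[s2] if np.dot(normals[s1], normals[s2]) > 0
                               else -normals[s2])
            n = unit(n)
            delta = min_image_vectors(
                centroids[s2] - centroids[s1], frame.box, frame.periodic_mask()
            )
            sheet_vals.append(abs(float(np.dot(delta, n))))

    def stats(vals):
        if not vals:
            return None, None
        arr = np.asarray(vals)
        return float(arr.mean()), float(arr.std())

    ss, ss_sd = stats(strand_vals)
    sh, sh_sd = stats(sheet_vals)
    return SpacingMetrics(ss, ss_sd, sh, sh_sd)


# --- secondary structure ------------------------------------------------------

_HB_CUTOFF = -0.5  # kcal/mol


@dataclass
class SecondaryStructureSeries:
    """Per-frame, per-residue 4-state assignment: H, E, T or C."""

    states: np.ndarray  # (n_frames, n_residues) of single characters
    chain_of: np.ndarray
    residue_pos: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.states.shape[0]

    def per_residue_fraction(self, state: str) -> np.ndarray:
        return (self.states == state).mean(axis=0)

    def per_frame_fraction(self, state: str) -> np.ndarray:
        return (self.states == state).mean(axis=1)

    def overall_fractions(self) -> dict:
        return {s: float((self.states == s).mean()) for s in "HETC"}


def _residue_backbone(traj: Trajectory):
    """Backbone atom indices per residue (global order), -1 where missing."""
    nidx, caidx, cidx, oidx, resname, chain_of = [], [], [], [], [], []
    off = 0
    for c, top in enumerate(traj.topologies):
        for res in top.residues:
            names = {a: off + k for k, (a, _) in enumerate(res.atoms)}
            nidx.append(names.get("N", -1))
            caidx.append(names.get("CA", -1))
            cidx.append(names.get("C", -1))
            oidx.append(names.get("O", -1))
            resname.append(res.name)
            chain_of.append(c)
            off += len(res.atoms)
    return (np.array(nidx), np.array(caidx), np.array(cidx), np.array(oidx),
            np.array(resname), np.array(chain_of))


def assign_secondary_structure(traj: Trajectory) -> SecondaryStructureSeries:
    """Kabsch-Sander style 4-state secondary structure (H/E/T/C).

    Amide hydrogens are reconstructed geometrically; an H-bond is any
    donor/acceptor pair with electrostatic energy below -0.5 kcal/mol.
    Helices need two consecutive i->i+4 turns, strands come from parallel or
    antiparallel bridge patterns, remaining turn-covered residues are T.
    Chains shorter than 3 residues are coil.
    """
    nidx, caidx, cidx, oidx, resname, chain_of = _residue_backbone(traj)
    n_res = len(nidx)
    complete = (nidx >= 0) & (caidx >= 0) & (cidx >= 0) & (oidx >= 0)
    chain_len = np.bincount(chain_of)
    long_enough = chain_len[chain_of] >= 3

    prev_same = np.zeros(n_res, bool)
    prev_same[1:] = chain_of[1:] == chain_of[:-1]
    next_same = np.zeros(n_res, bool)
    next_same[:-1] = prev_same[1:]

    residue_pos = np.zeros(n_res, int)
    pos = 0
    for i in range(n_res):
        pos = pos + 1 if i > 0 and chain_of[i] == chain_of[i - 1] else 0
        residue_pos[i] = pos

    states_all = np.full((traj.n_frames, n_res), "C", dtype="<U1")
    seq_i = np.arange(n_res)
    same_chain = chain_of[:, None] == chain_of[None, :]
    seq_sep = np.abs(seq_i[:, None] - seq_i[None, :])
    forbidden = same_chain & (seq_sep <= 1)

    for fi, frame in enumerate(traj.frames):
        coords = frame.coordinates
        safe = lambda idx: coords[np.clip(idx, 0, len(coords) - 1)]
        n_xyz, ca_xyz, c_xyz, o_xyz = map(safe, (nidx, caidx, cidx, oidx))
        has_prev = prev_same & complete
        has_prev[1:] &= cidx[:-1] >= 0
        c_prev = safe(np.roll(cidx, 1))
        h_xyz = reconstruct_amide_hydrogens(n_xyz, ca_xyz, c_prev, has_prev)

        energy = ks_hbond_energy(n_xyz, h_xyz, c_xyz, o_xyz)
        donor_ok = complete & (resname != "PRO") & has_prev & long_enough
        acceptor_ok = complete & long_enough
        hb = (energy < _HB_CUTOFF) & donor_ok[:, None] & acceptor_ok[None, :]
        hb &= ~forbidden

        # hbond(a, b): N-H of a donates to C=O of b
        def hbond_shift(da, db):
            """hb[i+da, j+db] aligned on (i, j), False outside chains."""
            out = np.zeros_like(hb)
            src_i = seq_i + da
            src_j = seq_i + db
            vi = (src_i >= 0) & (src_i < n_res)
            vj = (src_j >= 0) & (src_j < n_res)
            ii = np.clip(src_i, 0, n_res - 1)
            jj = np.clip(src_j, 0, n_res - 1)
            out[np.ix_(vi, vj)] = hb[np.ix_(ii[vi], jj[vj])]
            # shifted residues must stay within the same chain
            ci = (chain_of[ii] == chain_of) & vi
            cj = (chain_of[jj] == chain_of) & vj
            return out & ci[:, None] & cj[None, :]

        # n-turns: donor i+n to acceptor i
        turn = {n: np.zeros(n_res, bool) for n in (3, 4, 5)}
        for n in (3, 4, 5):
            ok = seq_i + n < n_res
            ii = np.clip(seq_i + n, 0, n_res - 1)
            t = np.zeros(n_res, bool)
            t[ok] = hb[ii[ok], seq_i[ok]] & (chain_of[ii[ok]] == chain_of[ok])
            turn[n] = t

        helix = np.zeros(n_res, bool)
        t4 = turn[4]
        start = t4 & np.concatenate([[False], t4[:-1]]) & prev_same
        for i in np.flatnonzero(start):
            helix[i : i + 4] = True

        # parallel: hbond(i-1, j) & hbond(j, i+1)  or  hbond(j-1, i) & hbond(i, j+1)
        hb_im1_j = hbond_shift(-1, 0)
        hb_j_ip1 = hbond_shift(0, +1).T  # [i,j] -> hb[j, i+1]
        hb_jm1_i = hbond_shift(-1, 0).T  # [i,j] -> hb[j-1, i]
        hb_i_jp1 = hbond_shift(0, +1)
        parallel = (hb_im1_j & hb_j_ip1) | (hb_jm1_i & hb_i_jp1)
        # antiparallel: hbond(i, j) & hbond(j, i)  or  hbond(i-1, j+1) & hbond(j-1, i+1)
        anti = (hb & hb.T) | (hbond_shift(-1, +1) & hbond_shift(-1, +1).T)
        bridge_sep_ok = ~same_chain | (seq_sep >= 3)
        bridge = (parallel | anti) & bridge_sep_ok
        strand = bridge.any(axis=1)

        turn_cover = np.zeros(n_res, bool)
        for n in (3, 4, 5):
            for i in np.flatnonzero(turn[n]):
                turn_cover[i + 1 : i + n] = True

        states = np.full(n_res, "C", dtype="<U1")
        states[turn_cover] = "T"
        states[strand] = "E"
        states[helix] = "H"
        states[~long_enough] = "C"
        states_all[fi] = states

    residue_pos_arr = residue_pos
    return SecondaryStructureSeries(states_all, chain_of, residue_pos_arr)


# --- end-to-end classification ------------------------------------------------


@dataclass
class ConformerClassification:
    """Per-frame, per-chain end-to-end distances and EXTENDED/COMPACT calls."""

    distances: np.ndarray  # (n_frames, n_chains), Angstrom
    classes: np.ndarray  # same shape, strings
    span: tuple
    cutoffs: tuple


def end_to_end_classify(traj: Trajectory, span: tuple, cutoffs=(15.0, 30.0)
                        ) -> ConformerClassification:
    """CA end-to-end distance of a residue span (1-based, inclusive) per chain,
    on unwrapped coordinates; > upper cutoff -> EXTENDED, < lower -> COMPACT,
    otherwise UNASSIGNED."""
    lo_cut, hi_cut = cutoffs
    first, last = span
    slices = traj.chain_slices()
    idx_first, idx_last = [], []
    for c, top in enumerate(traj.topologies):
        try:
            idx_first.append(slices[c].start + top.atom_index(first, "CA"))
            idx_last.append(slices[c].start + top.atom_index(last, "CA"))
        except KeyError as exc:
            raise ValueError(f"span {span} outside chain {top.chain_id}") from exc
    idx_first = np.array(idx_first)
    idx_last = np.array(idx_last)
    dist = np.empty((traj.n_frames, len(slices)))
    for fi, frame in enumerate(traj.frames):
        coords = unwrap_chains(traj.topologies, frame)
        dist[fi] = np.linalg.norm(coords[idx_last] - coords[idx_first], axis=-1)
    classes = np.full(dist.shape, "UNASSIGNED", dtype="<U10")
    classes[dist > hi_cut] = "EXTENDED"
    classes[dist < lo_cut] = "COMPACT"
    return ConformerClassification(dist, classes, span, (lo_cut, hi_cut))


# --- contacts -----------------------------------------------------------------


def _residue_atom_groups(top, heavy_only=True):
    groups, off = [], 0
    for res in top.residues:
        idx = [off + k for k, (_, e) in enumerate(res.atoms)
               if not heavy_only or e != "H"]
        groups.append(np.array(idx, int))
        off += len(res.atoms)
    return groups


def _min_res_distance_matrix(coords_a, groups_a, coords_b, groups_b, box, pmask):
    d = pairwise_min_image_distances(coords_a, coords_b, box, pmask)
    na, nb = len(groups_a), len(groups_b)
    out = np.empty((na, nb))
    for i, gi in enumerate(groups_a):
        for j, gj in enumerate(groups_b):
            out[i, j] = d[np.ix_(gi, gj)].min()
    return out


def residue_contact_map(traj: Trajectory, scope: str, cutoff: float = 6.0,
                        min_seq_sep: int = 3, inter_agg: str = "any") -> np.ndarray:
    """Residue-pair contact frequency matrix (vdW criterion: any heavy-atom
    pair within `cutoff`, minimum-image aware).

    INTRA: same-chain map averaged over chains and frames, pairs with
    |i-j| < min_seq_sep set to 0.  INTER: map over residue positions across
    distinct chain pairs; `inter_agg`='any' counts a frame as in contact when
    at least one chain pair forms it, 'mean' averages over chain pairs.
    """
    scope = scope.upper()
    if scope not in ("INTRA", "INTER"):
        raise ValueError("scope must be INTRA or INTER")
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n_res = traj.topologies[0].n_residues
    for top in traj.topologies:
        if top.n_residues != n_res:
            raise ValueError("contact maps need equal-length chains")
    slices = traj.chain_slices()
    groups = [_residue_atom_groups(t) for t in traj.topologies]
    acc = np.zeros((n_res, n_res))
    for fi, frame in enumerate(traj.frames):
        coords = frame.coordinates
        pmask = frame.periodic_mask()
        if scope == "INTRA":
            m = np.zeros((n_res, n_res))
            for c, top in enumerate(traj.topologies):
                xyz = coords[slices[c]]
                dm = _min_res_distance_matrix(xyz, groups[c], xyz, groups[c],
                                              frame.box, pmask)
                m += (dm <= cutoff)
            acc += m / len(traj.topologies)
        else:
            if len(traj.topologies) < 2:
                raise ValueError("INTER scope needs >= 2 chains")
            hit = np.zeros((n_res, n_res))
            npairs = 0
            for a in range(len(slices)):
                for b in range(a + 1, len(slices)):
                    dm = _min_res_distance_matrix(
                        coords[slices[a]], groups[a], coords[slices[b]], groups[b],
                        frame.box, pmask)
                    contact = (dm <= cutoff)
                    contact = contact | contact.T  # symmetrize residue roles
                    hit = np.maximum(hit, contact) if inter_agg == "any" \
                        else hit + contact
                    npairs += 1
            acc += hit if inter_agg == "any" else hit / npairs
    freq = acc / traj.n_frames
    if scope == "INTRA" and min_seq_sep > 0:
        i, j = np.indices(freq.shape)
        freq[np.abs(i - j) < min_seq_sep] = 0.0
    return freq


# --- profiles -----------------------------------------------------------------


def helicity_profile(traj_or_ss, n_blocks: int = 4):
    """Per-residue alpha-helix fraction with block-averaged SD, plus overall
    secondary-structure fractions.

    Returns (fraction_per_residue, sd_per_residue_or_None, overall_fractions).
    Fractions are averaged over frames and over chains at matching residue
    positions.  Block averaging is skipped (with a warning) below `n_blocks`
    frames.
    """
    ss = traj_or_ss if isinstance(traj_or_ss, SecondaryStructureSeries) \
        else assign_secondary_structure(traj_or_ss)
    n_pos = int(ss.residue_pos.max()) + 1
    is_h = (ss.states == "H").astype(float)

    def per_position(mat):
        out = np.zeros(n_pos)
        for p in range(n_pos):
            out[p] = mat[:, ss.residue_pos == p].mean()
        return out

    frac = per_position(is_h)
    sd = None
    if ss.n_frames >= n_blocks:
        blocks = np.array_split(np.arange(ss.n_frames), n_blocks)
        bvals = np.stack([per_position(is_h[b]) for b in blocks])
        sd = bvals.std(axis=0, ddof=1)
    else:
        warnings.warn(f"fewer than {n_blocks} frames; block averaging skipped")
    return frac, sd, ss.overall_fractions()


def radius_of_gyration(traj: Trajectory) -> np.ndarray:
    """Mass-weighted radius of gyration (Angstrom) per frame over heavy atoms,
    computed on unwrapped coordinates."""
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    elements = [e for t in traj.topologies for e in t.elements()]
    masses = np.array([ELEMENT_MASSES.get(e, 12.011) for e in elements])
    heavy = np.array([e != "H" for e in elements])
    m = masses[heavy]
    out = np.empty(traj.n_frames)
    for fi, frame in enumerate(traj.frames):
        xyz = unwrap_chains(traj.topologies, frame)[heavy]
        com = (m[:, None] * xyz).sum(0) / m.sum()
        out[fi] = np.sqrt((m * ((xyz - com) ** 2).sum(1)).sum() / m.sum())
    return out
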