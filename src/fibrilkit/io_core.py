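"""Topology/coordinate data model, PDB/GRO readers and writers, and
periodic-distance utilities shared by every pipeline stage.

Conventions: coordinates in Angstrom, times in ns, residue indices 1-based.
Domain labels (N17/QCORE/P5/NONE) are assigned from configuration spans, not
inferred from residue identity, so arbitrary flanking sequences work.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

import biotite.structure as struc
from biotite.structure.io import gro as _gro
from biotite.structure.io import pdb as _pdb

__all__ = [
    "DOMAIN_LABELS",
    "Residue",
    "ChainTopology",
    "Frame",
    "Trajectory",
    "ParseError",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "min_image_distance",
    "min_image_vectors",
    "pairwise_min_image_distances",
    "unwrap_chains",
    "assign_domains",
    "load_system_config",
    "ELEMENT_MASSES",
]

DOMAIN_LABELS = ("N17", "QCORE", "P5", "NONE")

#: Monoisotopic-ish average masses used for mass-weighted metrics.
ELEMENT_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}

_ELEMENT_FROM_NAME = re.compile(r"([A-Za-z])")


class ParseError(ValueError):
    """Raised when a structure file violates its format."""


def _infer_element(atom_name: str) -> str:
    m = _ELEMENT_FROM_NAME.search(atom_name)
    if not m:
        raise ParseError(f"cannot infer element from atom name {atom_name!r}")
    return m.group(1).upper()


@dataclass(frozen=True)
class Residue:
    """One residue: 3-letter name, 1-based index, (atom_name, element) pairs."""

    name: str
    index: int
    atoms: tuple[tuple[str, str], ...]
    domain: str = "NONE"

    def __post_init__(self):
        names = [a[0] for a in self.atoms]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate atom names in residue {self.name}{self.index}")
        if self.domain not in DOMAIN_LABELS:
            raise ValueError(f"unknown domain label {self.domain!r}")


@dataclass
class ChainTopology:
    """Ordered residues of one chain with per-residue domain annotation."""

    chain_id: str
    residues: list[Residue]

    def __post_init__(self):
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(f"residue indices not strictly increasing in chain {self.chain_id}")
        # domain labels must form contiguous blocks
        seen = []
        for r in self.residues:
            if not seen or seen[-1] != r.domain:
                seen.append(r.domain)
        if len(seen) != len(set(seen)):
            raise ValueError(f"domain labels not contiguous in chain {self.chain_id}")

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def atom_names(self) -> list[str]:
        return [a for r in self.residues for a, _ in r.atoms]

    def elements(self) -> list[str]:
        return [e for r in self.residues for _, e in r.atoms]

    def atom_index(self, residue_index: int, atom_name: str) -> int:
        """Flat atom index within this chain for (1-based residue, atom name)."""
        off = 0
        for r in self.residues:
            if r.index == residue_index:
                for k, (name, _) in enumerate(r.atoms):
                    if name == atom_name:
                        return off + k
                raise KeyError(f"no atom {atom_name} in residue {r.name}{r.index}")
            off += len(r.atoms)
        raise KeyError(f"no residue {residue_index} in chain {self.chain_id}")


@dataclass
class Frame:
    """Coordinates (Angstrom) for one time point with an orthorhombic box."""

    coordinates: np.ndarray
    time: float = 0.0
    box: np.ndarray | None = None
    periodic_axes: frozenset = frozenset()

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        self.periodic_axes = frozenset(str(a).upper() for a in self.periodic_axes)
        if not self.periodic_axes <= {"X", "Y", "Z"}:
            raise ValueError("periodic_axes must be a subset of {X, Y, Z}")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)
        if self.periodic_axes:
            if self.box is None:
                raise ValueError("periodic axes declared but no box given")
            for ax, L in zip("XYZ", self.box):
                if ax in self.periodic_axes and L <= 0:
                    raise ValueError(f"non-positive box edge on periodic axis {ax}")

    @property
    def n_atoms(self) -> int:
        return len(self.coordinates)

    def periodic_mask(self) -> np.ndarray:
        return np.array([ax in self.periodic_axes for ax in "XYZ"])


@dataclass
class Trajectory:
    """An ordered sequence of frames over one shared multi-chain topology."""

    topologies: list[ChainTopology]
    frames: list[Frame]

    def __post_init__(self):
        n = self.n_atoms
        for f in self.frames:
            if f.n_atoms != n:
                raise ValueError(f"frame has {f.n_atoms} atoms, topology has {n}")
        times = [f.time for f in self.frames]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("frame times must be non-decreasing")

    @property
    def n_atoms(self) -> int:
        return sum(t.n_atoms for t in self.topologies)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def chain_slices(self) -> list[slice]:
        out, off = [], 0
        for t in self.topologies:
            out.append(slice(off, off + t.n_atoms))
            off += t.n_atoms
        return out

    def atom_selection(self, atom_name: str) -> np.ndarray:
        """Boolean mask over all atoms matching `atom_name` (e.g. 'CA')."""
        return np.array([n == atom_name for t in self.topologies for n in t.atom_names()])


# --- format conversion -------------------------------------------------------


def _to_atom_array(topologies: Sequence[ChainTopology], frame: Frame) -> struc.AtomArray:
    n = sum(t.n_atoms for t in topologies)
    if frame.n_atoms != n:
        raise ValueError(f"frame has {frame.n_atoms} atoms, topologies have {n}")
    if not np.all(np.isfinite(frame.coordinates)):
        raise ValueError("coordinates must be finite")
    arr = struc.AtomArray(n)
    chain_id, res_id, res_name, atom_name, element = [], [], [], [], []
    for t in topologies:
        for r in t.residues:
            for name, elem in r.atoms:
                chain_id.append(t.chain_id)
                res_id.append(r.index)
                res_name.append(r.name)
                atom_name.append(name)
                element.append(elem)
    arr.chain_id = np.array(chain_id)
    arr.res_id = np.array(res_id)
    arr.res_name = np.array(res_name)
    arr.atom_name = np.array(atom_name)
    arr.element = np.array(element)
    arr.coord = frame.coordinates.astype(np.float32)
    if frame.box is not None:
        arr.box = np.diag(frame.box).astype(np.float32)
    return arr


def _from_atom_array(arr: struc.AtomArray, periodic_axes=()) -> tuple[list[ChainTopology], Frame]:
    topologies = []
    starts = struc.get_chain_starts(arr, add_exclusive_stop=True)
    for a, b in zip(starts, starts[1:]):
        sub = arr[a:b]
        residues: list[Residue] = []
        atoms: list[tuple[str, str]] = []
        cur = None
        for i in range(sub.array_length()):
            key = (int(sub.res_id[i]), str(sub.res_name[i]))
            if cur is not None and key != cur:
                residues.append(Residue(cur[1], cur[0], tuple(atoms)))
                atoms = []
            cur = key
            elem = str(sub.element[i]).strip().upper()
            if not elem:
                elem = _infer_element(str(sub.atom_name[i]))
            atoms.append((str(sub.atom_name[i]), elem))
        if cur is not None:
            residues.append(Residue(cur[1], cur[0], tuple(atoms)))
        topologies.append(ChainTopology(str(sub.chain_id[0]), residues))
    box = None
    if arr.box is not None:
        diag = np.diag(np.asarray(arr.box, float))
        if np.any(diag > 0):
            box = diag
    frame = Frame(
        coordinates=np.asarray(arr.coord, float),
        box=box,
        periodic_axes=frozenset(periodic_axes) if box is not None else frozenset(),
    )
    return topologies, frame


def _sniff_format(path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.upper()
    suffix = Path(path).suffix.lower()
    if suffix in {".pdb", ".ent"}:
        return "PDB"
    if suffix == ".gro":
        return "GRO"
    raise ValueError(f"cannot infer format from {path}; pass format='PDB' or 'GRO'")


def read_structure(path, format: str | None = None, periodic_axes=()):
    """Read a PDB or GRO file into (list of ChainTopology, Frame).

    Coordinates are returned in Angstrom (GRO nm values are converted); a
    missing box yields a non-periodic frame regardless of `periodic_axes`.
    """
    fmt = _sniff_format(path, format)
    try:
        if fmt == "PDB":
            arr = _pdb.PDBFile.read(str(path)).get_structure(model=1)
        elif fmt == "GRO":
            arr = _gro.GROFile.read(str(path)).get_structure(model=1)
        else:
            raise ValueError(f"unsupported format {fmt!r}")
    except struc.BadStructureError as exc:  # pragma: no cover - biotite detail
        raise ParseError(f"{path}: {exc}") from exc
    except Exception as exc:
        if isinstance(exc, (ValueError, KeyError)) and not isinstance(exc, ParseError):
            raise ParseError(f"{path}: {exc}") from exc
        raise
    return _from_atom_array(arr, periodic_axes)


def read_trajectory(path, format: str | None = None, periodic_axes=(), dt: float = 1.0,
                    t0: float = 0.0) -> Trajectory:
    """Read a multi-model PDB as a Trajectory; frame times are t0 + k*dt ns."""
    fmt = _sniff_format(path, format)
    if fmt != "PDB":
        raise ValueError("trajectories are read from multi-model PDB files")
    pf = _pdb.PDBFile.read(str(path))
    stack = pf.get_structure()  # AtomArrayStack
    topologies, first = _from_atom_array(stack[0], periodic_axes)
    frames = [
        replace(first, coordinates=np.asarray(stack.coord[k], float), time=t0 + k * dt)
        for k in range(stack.stack_depth())
    ]
    return Trajectory(topologies, frames)


def _add_ter_records(text: str) -> str:
    """Insert TER records after the final ATOM line of each chain per model."""
    out = []
    prev_chain = None
    prev_atom_line = False
    for line in text.splitlines():
        rec = line[:6]
        if rec in ("ATOM  ", "HETATM"):
            chain = line[21]
            if prev_atom_line and chain != prev_chain:
                out.append("TER")
            prev_chain = chain
            prev_atom_line = True
        else:
            if prev_atom_line:
                out.append("TER")
            prev_chain = None
            prev_atom_line = False
        out.append(line)
    if prev_atom_line:
        out.append("TER")
    return "\n".join(out) + "\n"


def write_structure(topologies: Sequence[ChainTopology], frame: Frame, path,
                    format: str | None = None) -> None:
    """Write one frame to PDB or GRO; PDB gets per-chain TER records.

    Systems beyond 99,999 atoms fall back to hybrid-36 numbering in PDB.
    """
    if not topologies:
        raise ValueError("empty chain list")
    fmt = _sniff_format(path, format)
    arr = _to_atom_array(topologies, frame)
    if fmt == "PDB":
        pf = _pdb.PDBFile()
        pf.set_structure(arr, hybrid36=arr.array_length() > 99999)
        Path(path).write_text(_add_ter_records("\n".join(pf.lines)))
    elif fmt == "GRO":
        gf = _gro.GROFile()
        gf.set_structure(arr)
        gf.write(str(path))
        lines = Path(path).read_text().splitlines()
        lines[0] = "fibrilkit structure"  # drop timestamped header for determinism
        Path(path).write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unsupported format {fmt!r}")


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a Trajectory as a multi-model PDB with TER records."""
    if not traj.frames:
        raise ValueError("trajectory has no frames")
    arrays = [_to_atom_array(traj.topologies, f) for f in traj.frames]
    stack = struc.stack(arrays)
    pf = _pdb.PDBFile()
    pf.set_structure(stack)
    Path(path).write_text(_add_ter_records("\n".join(pf.lines)))


# --- periodic-distance utilities --------------------------------------------


def min_image_vectors(diff: np.ndarray, box: np.ndarray | None, periodic_mask: np.ndarray):
    """Apply the minimum-image convention to displacement vectors along the
    periodic axes only (non-periodic axes are left untouched)."""
    diff = np.asarray(diff, float)
    if box is None or not np.any(periodic_mask):
        return diff
    box = np.asarray(box, float)
    if np.any(box[periodic_mask] <= 0):
        raise ValueError("zero or negative box edge on a periodic axis")
    out = diff.copy()
    for k in range(3):
        if periodic_mask[k]:
            out[..., k] -= box[k] * np.round(out[..., k] / box[k])
    return out


def min_image_distance(p1, p2, frame: Frame) -> float:
    """Euclidean distance minimized over periodic images of the frame's box."""
    d = np.asarray(p2, float) - np.asarray(p1, float)
    d = min_image_vectors(d, frame.box, frame.periodic_mask())
    return float(np.linalg.norm(d))


def pairwise_min_image_distances(a: np.ndarray, b: np.ndarray, box, periodic_mask) -> np.ndarray:
    """(len(a), len(b)) min-image distance matrix."""
    diff = np.asarray(a, float)[:, None, :] - np.asarray(b, float)[None, :, :]
    diff = min_image_vectors(diff, box, periodic_mask)
    return np.linalg.norm(diff, axis=-1)


def unwrap_chains(traj_or_tops, frame: Frame | None = None) -> np.ndarray | list[np.ndarray]:
    """Make each chain whole across periodic boundaries.

    Each atom is shifted by box multiples so it sits within half a box edge of
    the previous atom in the chain (walk order = file order).  Returns the
    unwrapped coordinate array for a (topologies, frame) pair, or a list of
    per-frame arrays for a Trajectory.
    """
    if isinstance(traj_or_tops, Trajectory):
        return [unwrap_chains(traj_or_tops.topologies, f) for f in traj_or_tops.frames]
    topologies = traj_or_tops
    coords = frame.coordinates.copy()
    box = frame.box
    mask = frame.periodic_mask()
    if box is None or not mask.any():
        return coords
    off = 0
    for t in topologies:
        n = t.n_atoms
        seg = coords[off : off + n]
        for i in range(1, n):
            d = seg[i] - seg[i - 1]
            for k in range(3):
                if mask[k]:
                    d[k] -= box[k] * np.round(d[k] / box[k])
            seg[i] = seg[i - 1] + d
        off += n
    return coords


# --- configuration -----------------------------------------------------------


def assign_domains(topology: ChainTopology, spans: dict) -> ChainTopology:
    """Return a copy of `topology` with domain labels set from residue spans.

    `spans` maps a domain label to an inclusive 1-based (start, end) pair,
    e.g. {"N17": (1, 17), "QCORE": (18, 33), "P5": (34, 38)}.
    """
    for label in spans:
        if label not in DOMAIN_LABELS:
            raise ValueError(f"unknown domain label {label!r}")
    residues = []
    for r in topology.residues:
        domain = "NONE"
        for label, (lo, hi) in spans.items():
            if lo <= r.index <= hi:
                domain = label
                break
        residues.append(Residue(r.name, r.index, r.atoms, domain))
    return ChainTopology(topology.chain_id, residues)


def load_system_config(path) -> dict:
    """Load a YAML system config: sequence, domain spans, box, periodic axes."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "domains" in cfg:
        cfg["domains"] = {
            str(k).upper(): (int(v[0]), int(v[1])) for k, v in cfg["domains"].items()
        }
    if "box" in cfg and cfg["box"] is not None:
        cfg["box"] = np.asarray(cfg["box"], float).reshape(3)
    if "periodic_axes" in cfg and cfg["periodic_axes"]:
        cfg["periodic_axes"] = frozenset(str(a).upper() for a in cfg["periodic_axes"])
    return cfg
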