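"""Multi-state native-contact learning and interaction-table assembly.

Contact probabilities are extracted per residue pair from ensembles of the
monomeric, dense-phase and fibril states, then merged into one table:
glutamine-core pairs above the inclusion threshold become attractive with a
single configurable epsilon (intermolecular strength equal to intramolecular),
flanking-domain pairs are sourced from the dense-phase map, every
flanking-domain/core cross pair is excluded-volume repulsive, and so is any
remaining non-native pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_core import ChainTopology, Trajectory, pairwise_min_image_distances
from .structure_metrics import _min_res_distance_matrix, _residue_atom_groups

__all__ = [
    "ContactMap",
    "ModelParameters",
    "ParamEntry",
    "extract_contacts",
    "merge_multistate",
    "write_params",
    "read_params",
    "write_contact_map",
    "read_contact_map",
]

_SOURCES = ("MONOMER", "DENSE", "FIBRIL")
_SCOPES = ("INTRA", "INTER")


@dataclass
class ContactMap:
    """Symmetric residue-pair contact probabilities from one ensemble."""

    source: str
    scope: str
    entries: dict  # (i, j) with i <= j (1-based residue indices) -> probability

    def __post_init__(self):
        if self.source not in _SOURCES:
            raise ValueError(f"source must be one of {_SOURCES}")
        if self.scope not in _SCOPES:
            raise ValueError(f"scope must be one of {_SCOPES}")
        norm = {}
        for (i, j), p in self.entries.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} for pair ({i},{j}) outside [0,1]")
            key = (min(i, j), max(i, j))
            if key in norm and norm[key] != p:
                raise ValueError(f"conflicting probabilities for pair {key}")
            norm[key] = float(p)
        self.entries = norm

    def probability(self, i: int, j: int) -> float:
        return self.entries.get((min(i, j), max(i, j)), 0.0)


@dataclass(frozen=True)
class ParamEntry:
    i: int
    j: int
    kind: str  # ATTRACTIVE or REPULSIVE
    epsilon: float  # kJ/mol, 0 for repulsive
    provenance: str


@dataclass
class ModelParameters:
    """Interaction table over residue pairs plus the global epsilon."""

    entries: list
    epsilon: float

    def lookup(self, i: int, j: int) -> ParamEntry | None:
        key = (min(i, j), max(i, j))
        for e in self.entries:
            if (e.i, e.j) == key:
                return e
        return None

    def attractive_pairs(self) -> list:
        return [e for e in self.entries if e.kind == "ATTRACTIVE"]


def extract_contacts(traj: Trajectory, scope: str, distance_cutoff: float = 6.0,
                     min_seq_sep: int = 3, inter_agg: str = "any") -> ContactMap:
    """Learn a residue-pair contact probability map from an ensemble.

    A pair is in contact in a frame when any heavy-atom pair is within
    `distance_cutoff` (minimum-image aware); the probability is the fraction
    of such frames.  INTRA maps average over chains and drop pairs closer in
    sequence than `min_seq_sep`; INTER maps aggregate over chain pairs
    ('any' by default: contact if any chain pair forms it).
    """
    scope = scope.upper()
    if scope not in _SCOPES:
        raise ValueError("scope must be INTRA or INTER")
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    if distance_cutoff <= 0:
        raise ValueError("cutoff must be positive")
    from .structure_metrics import residue_contact_map

    freq = residue_contact_map(traj, scope, cutoff=distance_cutoff,
                               min_seq_sep=min_seq_sep if scope == "INTRA" else 0,
                               inter_agg=inter_agg)
    res_index = [r.index for r in traj.topologies[0].residues]
    entries = {}
    n = len(res_index)
    for a in range(n):
        for b in range(a, n):
            p = float(freq[a, b])
            if p > 0:
                entries[(res_index[a], res_index[b])] = p
    source = "FIBRIL" if scope == "INTER" else "MONOMER"
    return ContactMap(source=source, scope=scope, entries=entries)


def _domain_of(topology: ChainTopology) -> dict:
    return {r.index: r.domain for r in topology.residues}


_FLANKING = {"N17", "P5"}


def merge_multistate(monomer_map: ContactMap | None, fibril_map: ContactMap | None,
                     dense_map: ContactMap | None, topology: ChainTopology,
                     epsilon: float, threshold: float = 0.05) -> ModelParameters:
    """Merge per-state contact maps into one interaction table.

    Glutamine-core (QCORE) pairs are learned from the fibril map (inter) and
    monomer map (intra); flanking-domain pairs (N17/P5 with N17/P5) come from
    the dense-phase map; every flanking/QCORE cross pair is repulsive
    excluded volume regardless of the inputs, as is any pair below the
    inclusion `threshold`.  Attractive entries all carry `epsilon` (kJ/mol):
    intermolecular strength equals intramolecular.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    domains = _domain_of(topology)
    res_ids = sorted(domains)
    has_flanking = any(d in _FLANKING for d in domains.values())
    if has_flanking and dense_map is None:
        raise ValueError("topology has flanking domains but no dense-phase map")

    for m in (monomer_map, fibril_map, dense_map):
        if m is None:
            continue
        for (i, j) in m.entries:
            if i not in domains or j not in domains:
                raise ValueError(
                    f"contact map references residue pair ({i},{j}) outside topology"
                )

    def prob(m, i, j):
        return 0.0 if m is None else m.probability(i, j)

    entries = []
    for ai, i in enumerate(res_ids):
        for j in res_ids[ai:]:
            di, dj = domains[i], domains[j]
            cross = (di in _FLANKING and dj == "QCORE") or \
                    (dj in _FLANKING and di == "QCORE")
            if cross:
                entries.append(ParamEntry(i, j, "REPULSIVE", 0.0, "excluded_volume"))
                continue
            if di == "QCORE" and dj == "QCORE":
                p = max(prob(fibril_map, i, j), prob(monomer_map, i, j))
                src = "fibril" if prob(fibril_map, i, j) >= prob(monomer_map, i, j) \
                    else "monomer"
            elif di in _FLANKING and dj in _FLANKING:
                p = prob(dense_map, i, j)
                src = "dense"
            else:
                p = max(prob(monomer_map, i, j), prob(dense_map, i, j))
                src = "monomer"
            if p >= threshold and p > 0:
                entries.append(ParamEntry(i, j, "ATTRACTIVE", float(epsilon), src))
            else:
                entries.append(ParamEntry(i, j, "REPULSIVE", 0.0, "non_native"))
    return ModelParameters(entries=entries, epsilon=float(epsilon))


# --- serialization -----------------------------------------------------------


def write_params(params: ModelParameters, path) -> None:
    """Write the interaction table as TSV: i, j, kind, epsilon, provenance."""
    df = pd.DataFrame(
        [(e.i, e.j, e.kind, e.epsilon, e.provenance) for e in params.entries],
        columns=["i", "j", "kind", "epsilon", "provenance"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_params(path) -> ModelParameters:
    """Inverse of write_params; validates kinds and duplicate pairs."""
    df = pd.read_csv(path, sep="\t")
    expected = ["i", "j", "kind", "epsilon", "provenance"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    entries = []
    seen = set()
    eps_values = set()
    for row in df.itertuples(index=False):
        kind = str(row.kind)
        if kind not in ("ATTRACTIVE", "REPULSIVE"):
            raise ValueError(f"{path}: unknown kind token {kind!r}")
        key = (min(row.i, row.j), max(row.i, row.j))
        if key in seen:
            raise ValueError(f"{path}: duplicate pair {key}")
        seen.add(key)
        e = ParamEntry(int(key[0]), int(key[1]), kind, float(row.epsilon),
                       str(row.provenance))
        entries.append(e)
        if kind == "ATTRACTIVE":
            eps_values.add(float(row.epsilon))
    epsilon = eps_values.pop() if len(eps_values) == 1 else 0.0
    return ModelParameters(entries=entries, epsilon=epsilon)


def write_contact_map(cmap: ContactMap, path) -> None:
    df = pd.DataFrame(
        [(i, j, p) for (i, j), p in sorted(cmap.entries.items())],
        columns=["i", "j", "probability"],
    )
    with open(path, "w") as fh:
        fh.write(f"# source={cmap.source} scope={cmap.scope}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_contact_map(path) -> ContactMap:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing contact-map header line")
        meta = dict(tok.split("=") for tok in header[1:].split())
        df = pd.read_csv(fh, sep="\t")
    entries = {(int(r.i), int(r.j)): float(r.probability)
               for r in df.itertuples(index=False)}
    return ContactMap(source=meta["source"], scope=meta["scope"], entries=entries)
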