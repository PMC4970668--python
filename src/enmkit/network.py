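"""Chemistry-typed elastic network construction and Hessian assembly.

Residue pairs are classified into interaction classes (backbone, ionic,
hydrogen bond, van der Waals, nucleotide covalent), each with its own spring
constant, around a reference conformation.  The potential is

    V = 1/2 sum_{i<j} k_ij (|x_i - x_j| - |x_i(0) - x_j(0)|)^2

and the dynamical system is M d2(delta)/dt2 + K delta = 0 with diagonal mass
matrix M (residue masses at the Calpha) and K the Hessian of V at the
reference.  Binding partners can be added as immobile anchors whose degrees
of freedom are eliminated, leaving only their spring constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy.spatial.distance import cdist

from .structures import AtomicStructure, Bead, BeadModel, coarse_grain

BACKBONE = "backbone"
IONIC = "ionic"
HYDROGEN = "hydrogen"
VDW = "vdw"
NUC_COVALENT = "nucleotide-covalent"
ANCHOR = "anchor"

#: default spring constants; ratio backbone:ionic:hydrogen:vdw = 100:20:10:1
DEFAULT_STIFFNESS = {
    BACKBONE: 100.0,
    IONIC: 20.0,
    HYDROGEN: 10.0,
    VDW: 1.0,
    NUC_COVALENT: 100.0,
    ANCHOR: 1.0,
}

#: geometric criteria (Angstrom); configurable via ClassifyCriteria
DEFAULT_CUTOFF = 8.0
IONIC_CUTOFF = 4.5
HBOND_CUTOFF = 3.5

_ACIDIC = {"ASP": ("OD1", "OD2", "CG"), "GLU": ("OE1", "OE2", "CD")}
_BASIC = {"LYS": ("NZ",), "ARG": ("NH1", "NH2", "NE", "CZ"),
          "HIS": ("ND1", "NE2")}

_CLASS_PRIORITY = {BACKBONE: 0, NUC_COVALENT: 0, IONIC: 1, HYDROGEN: 2, VDW: 3}


class StiffnessTable(dict):
    """Interaction class -> spring constant; all values must be positive."""

    def __init__(self, values: Mapping[str, float] | None = None):
        super().__init__(DEFAULT_STIFFNESS if values is None else values)
        for cls, k in self.items():
            if k <= 0:
                raise ValueError(f"stiffness for {cls!r} must be > 0, got {k}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StiffnessTable":
        import yaml

        with open(path) as fh:
            return cls(yaml.safe_load(fh))


@dataclass(frozen=True)
class SpringEdge:
    i: int
    j: int
    cls: str
    stiffness: float
    rest_length: float

    def __post_init__(self) -> None:
        if not self.i < self.j:
            raise ValueError("edge requires i < j")
        if self.rest_length <= 0:
            raise ValueError("rest length must be > 0 (coincident beads)")
        if self.stiffness <= 0:
            raise ValueError("stiffness must be > 0")


@dataclass
class SpringNetwork:
    """Typed spring network over a reference bead model.

    ``anchored`` bead indices are immobile: their degrees of freedom are
    excluded from the assembled dynamical system, but springs from mobile
    beads to them still constrain the mobile beads.  ``dim`` is the number
    of Cartesian degrees of freedom per bead (3, or 1 for the analytic
    one-dimensional chain generators).
    """

    model: BeadModel
    edges: list[SpringEdge]
    anchored: frozenset = frozenset()
    dim: int = 3

    def __post_init__(self) -> None:
        self.anchored = frozenset(self.anchored)
        seen = set()
        n = len(self.model)
        for e in self.edges:
            if (e.i, e.j) in seen:
                raise ValueError(f"duplicate edge ({e.i}, {e.j})")
            if e.j >= n:
                raise ValueError(f"edge ({e.i}, {e.j}) references missing bead")
            seen.add((e.i, e.j))

    @property
    def mobile_indices(self) -> np.ndarray:
        return np.array(
            [i for i in range(len(self.model)) if i not in self.anchored],
            dtype=int,
        )

    def with_edges(self, edges: list[SpringEdge]) -> "SpringNetwork":
        return SpringNetwork(self.model, edges, self.anchored, self.dim)

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            [(e.i, e.j, e.cls, e.stiffness, e.rest_length) for e in self.edges],
            columns=["i", "j", "class", "k", "rest_length"],
        ).to_csv(path, sep="\t", index=False)


@dataclass
class HessianSystem:
    """Stiffness matrix K and diagonal mass matrix M over mobile DOF."""

    K: np.ndarray
    masses: np.ndarray  # per-bead, mobile beads only
    model: BeadModel
    mobile: np.ndarray  # bead indices carried by K's blocks
    dim: int = 3

    @property
    def n_beads(self) -> int:
        return len(self.mobile)

    @property
    def n_dof(self) -> int:
        return self.K.shape[0]

    @property
    def M_diagonal(self) -> np.ndarray:
        return np.repeat(self.masses, self.dim)


# ---------------------------------------------------------------------------
# Contact classification
# ---------------------------------------------------------------------------

def _add_edge(cand: dict[tuple[int, int], str], i: int, j: int, cls: str) -> None:
    if i == j:
        return
    key = (min(i, j), max(i, j))
    prev = cand.get(key)
    if prev is None or _CLASS_PRIORITY[cls] < _CLASS_PRIORITY[prev]:
        cand[key] = cls


def classify_contacts(
    structure: AtomicStructure,
    model: BeadModel | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    table: StiffnessTable | None = None,
    atom_map: dict[int, np.ndarray] | None = None,
) -> SpringNetwork:
    """Classify residue-pair interactions into a typed spring network.

    Rules: consecutive residues in a chain are backbone edges; oppositely
    charged side chains (Asp/Glu vs Lys/Arg/His) with charged-group atoms
    within 4.5 A are ionic; backbone N...O pairs within 3.5 A are hydrogen
    bonds; any remaining Calpha pair within ``cutoff`` (default 8 A) is van
    der Waals.  Nucleotide moiety beads are chained by covalent edges and
    coupled to protein beads by the hydrogen/vdW rules.  One edge per pair,
    priority backbone > ionic > hydrogen > vdW.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if model is None or atom_map is None:
        model, atom_map = coarse_grain(structure)
    n = len(model)
    coords = model.coords
    cand: dict[tuple[int, int], str] = {}

    res_beads = [b for b in model.beads if b.kind == "residue"]
    nuc_beads = [b for b in model.beads if b.kind == "nucleotide-moiety"]

    # backbone: consecutive residue numbers within a chain
    by_chain: dict[str, list[Bead]] = {}
    for b in res_beads:
        by_chain.setdefault(str(b.label[0]), []).append(b)
    for beads in by_chain.values():
        beads = sorted(beads, key=lambda b: b.label[1])
        for a, b in zip(beads, beads[1:]):
            if b.label[1] - a.label[1] == 1:
                _add_edge(cand, a.index, b.index, BACKBONE)

    # nucleotide covalent chain: base-ribose-Palpha-Pbeta(-Pgamma)
    by_nuc: dict[tuple, list[Bead]] = {}
    for b in nuc_beads:
        by_nuc.setdefault((b.label[0], b.label[1]), []).append(b)
    for beads in by_nuc.values():
        for a, b in zip(beads, beads[1:]):
            _add_edge(cand, a.index, b.index, NUC_COVALENT)

    # atom-level criteria need the structure's atoms per bead
    def atoms_of(idx: int, names: Iterable[str] | None = None) -> np.ndarray:
        ai = atom_map.get(idx)
        if ai is None or len(ai) == 0:
            return np.empty((0, 3))
        if names is None:
            return structure.coord[ai]
        sel = [k for k in ai if str(structure.atom_name[k]) in names]
        return structure.coord[sel] if sel else np.empty((0, 3))

    # candidate pairs within a generous atomic radius: use bead distance
    dist = cdist(coords, coords)
    near = np.argwhere((dist <= max(cutoff, 12.0)) & (dist > 0))
    near = near[near[:, 0] < near[:, 1]]

    for i, j in near:
        bi, bj = model.beads[i], model.beads[j]
        key = (int(i), int(j))
        both_res = bi.kind == "residue" and bj.kind == "residue"
        if both_res:
            ri, rj = bi.label[2], bj.label[2]
            pair = None
            if ri in _ACIDIC and rj in _BASIC:
                pair = (_ACIDIC[ri], _BASIC[rj])
            elif rj in _ACIDIC and ri in _BASIC:
                pair = (_BASIC[ri], _ACIDIC[rj])
            if pair is not None:
                a = atoms_of(int(i), pair[0])
                b = atoms_of(int(j), pair[1])
                if a.size and b.size and cdist(a, b).min() <= IONIC_CUTOFF:
                    _add_edge(cand, *key, IONIC)
        # hydrogen bond: backbone N...O in either direction
        ni = atoms_of(int(i), ("N",))
        oi = atoms_of(int(i), ("O",))
        nj = atoms_of(int(j), ("N",))
        oj = atoms_of(int(j), ("O",))
        if not both_res:
            # nucleotide side: any of its N/O atoms can accept/donate
            if bi.kind == "nucleotide-moiety":
                alli = atoms_of(int(i))
                namesi = [str(structure.atom_name[k])
                          for k in atom_map.get(int(i), [])]
                ni = alli[[m for m, nm in enumerate(namesi) if nm.startswith("N")]] \
                    if len(alli) else ni
                oi = alli[[m for m, nm in enumerate(namesi) if nm.startswith("O")]] \
                    if len(alli) else oi
            if bj.kind == "nucleotide-moiety":
                allj = atoms_of(int(j))
                namesj = [str(structure.atom_name[k])
                          for k in atom_map.get(int(j), [])]
                nj = allj[[m for m, nm in enumerate(namesj) if nm.startswith("N")]] \
                    if len(allj) else nj
                oj = allj[[m for m, nm in enumerate(namesj) if nm.startswith("O")]] \
                    if len(allj) else oj
        hb = False
        if ni.size and oj.size and cdist(ni, oj).min() <= HBOND_CUTOFF:
            hb = True
        if oi.size and nj.size and cdist(oi, nj).min() <= HBOND_CUTOFF:
            hb = True
        if hb:
            _add_edge(cand, *key, HYDROGEN)
        if dist[i, j] <= cutoff:
            _add_edge(cand, *key, VDW)

    table = table or StiffnessTable()
    edges = [
        SpringEdge(i, j, cls, table.get(cls, 1.0), float(dist[i, j]))
        for (i, j), cls in sorted(cand.items())
    ]
    return SpringNetwork(model, edges)


def build_bead_network(
    model: BeadModel,
    cutoff: float = DEFAULT_CUTOFF,
    table: StiffnessTable | None = None,
    anchored: Iterable[int] = (),
) -> SpringNetwork:
    """Distance-based network for bead-only models (no atom records).

    Consecutive same-chain residue beads get backbone edges; every other
    pair within ``cutoff`` gets a vdW edge.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    table = table or StiffnessTable()
    coords = model.coords
    dist = cdist(coords, coords)
    cand: dict[tuple[int, int], str] = {}
    by_chain: dict[str, list[Bead]] = {}
    for b in model.beads:
        by_chain.setdefault(str(b.label[0]), []).append(b)
    for beads in by_chain.values():
        beads = sorted(beads, key=lambda b: b.label[1])
        for a, b in zip(beads, beads[1:]):
            if b.label[1] - a.label[1] == 1:
                _add_edge(cand, a.index, b.index, BACKBONE)
    for i, j in np.argwhere((dist <= cutoff) & (dist > 0)):
        if i < j:
            _add_edge(cand, int(i), int(j), VDW)
    edges = [SpringEdge(i, j, cls, table.get(cls, 1.0), float(dist[i, j]))
             for (i, j), cls in sorted(cand.items())]
    return SpringNetwork(model, edges, anchored=frozenset(anchored))


def assign_stiffness(network: SpringNetwork, table: StiffnessTable) -> SpringNetwork:
    """Re-weight every edge from its interaction class."""
    missing = {e.cls for e in network.edges} - set(table)
    if missing:
        raise KeyError(f"stiffness table missing classes: {sorted(missing)}")
    edges = [replace(e, stiffness=float(table[e.cls])) for e in network.edges]
    return network.with_edges(edges)


def add_environment_anchors(
    network: SpringNetwork,
    partners: BeadModel,
    cutoff: float = DEFAULT_CUTOFF,
    table: StiffnessTable | None = None,
    partner_structure: AtomicStructure | None = None,
) -> SpringNetwork:
    """Attach binding partners as immobile anchors.

    Partner beads are appended flagged as anchors; edges from mobile beads
    to them are classified by the bead-distance rules (vdW within the
    cutoff).  Anchor degrees of freedom never enter the assembled system,
    so the cost of the anchored model stays that of the bare model.
    """
    if len(partners) == 0:
        return network
    table = table or StiffnessTable()
    base = network.model
    n0 = len(base)
    beads = [Bead(b.index, b.position.copy(), b.mass, b.kind, b.label)
             for b in base.beads]
    for b in partners.beads:
        label = ("anchor:" + str(b.label[0]),) + tuple(b.label[1:])
        beads.append(Bead(len(beads), b.position.copy(), b.mass, "anchor", label))
    merged = BeadModel(beads, name=base.name + "+anchors")
    coords = merged.coords
    edges = list(network.edges)
    dist = cdist(coords[:n0], coords[n0:])
    for i, jo in np.argwhere((dist <= cutoff) & (dist > 0)):
        if i in network.anchored:
            continue
        edges.append(SpringEdge(int(i), n0 + int(jo), VDW,
                                float(table.get(VDW, 1.0)),
                                float(dist[i, jo])))
    anchored = frozenset(network.anchored) | frozenset(range(n0, len(merged)))
    return SpringNetwork(merged, edges, anchored=anchored, dim=network.dim)


def anchor_beads(network: SpringNetwork, indices: Iterable[int]) -> SpringNetwork:
    """Freeze existing beads (e.g. a bound terminus) as immobile anchors."""
    anchored = frozenset(network.anchored) | frozenset(int(i) for i in indices)
    return SpringNetwork(network.model, list(network.edges), anchored=anchored,
                         dim=network.dim)


# ---------------------------------------------------------------------------
# Energy and Hessian
# ---------------------------------------------------------------------------

def potential_energy(network: SpringNetwork, conformation: BeadModel) -> float:
    """Harmonic network energy of a displaced conformation.

    Evaluates 1/2 sum k_ij (|x_i - x_j| - L_ij)^2 with L_ij the rest lengths
    stored on the network's edges.
    """
    if len(conformation) != len(network.model):
        raise ValueError("conformation bead count mismatch")
    coords = conformation.coords
    if network.dim != 3:
        coords = coords[:, :network.dim]
    e = 0.0
    for edge in network.edges:
        d = np.linalg.norm(coords[edge.i] - coords[edge.j])
        e += 0.5 * edge.stiffness * (d - edge.rest_length) ** 2
    return float(e)


def build_hessian(network: SpringNetwork) -> HessianSystem:
    """Assemble the stiffness and mass matrices over mobile beads.

    Each spring contributes the rank-one block k * (d_hat d_hat^T) on its
    endpoints' diagonal blocks and its negative off-diagonal, with d_hat the
    unit vector between the reference positions.  Springs to anchors add
    only the diagonal contribution of the mobile endpoint.
    """
    mobile = network.mobile_indices
    if len(mobile) < 2:
        raise ValueError("need at least 2 mobile beads")
    pos = network.model.coords
    if network.dim != 3:
        pos = pos[:, :network.dim]
    d = network.dim
    col = {int(b): k for k, b in enumerate(mobile)}
    n = len(mobile)
    K = np.zeros((d * n, d * n))
    for e in network.edges:
        vec = pos[e.j] - pos[e.i]
        r = np.linalg.norm(vec)
        if r <= 1e-12:
            raise ValueError(f"edge ({e.i},{e.j}): coincident beads")
        dhat = vec / r
        block = e.stiffness * np.outer(dhat, dhat)
        mi, mj = col.get(e.i), col.get(e.j)
        if mi is not None:
            K[d * mi:d * mi + d, d * mi:d * mi + d] += block
        if mj is not None:
            K[d * mj:d * mj + d, d * mj:d * mj + d] += block
        if mi is not None and mj is not None:
            K[d * mi:d * mi + d, d * mj:d * mj + d] -= block
            K[d * mj:d * mj + d, d * mi:d * mi + d] -= block
    K = 0.5 * (K + K.T)
    masses = network.model.masses[mobile]
    if np.any(masses <= 0):
        raise ValueError("non-positive bead mass")
    return HessianSystem(K, masses, network.model, mobile, dim=d)
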