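"""Synthetic structures with known ground truth.

Three generator families cover the pipeline's test surface without any
structure downloads: a two-domain hinge pair with a known inter-domain
rotation (stand-in for the Ras/helical-domain opening), uniform elastic
chains and rings with closed-form spectra, and a pocket-plus-ligand cage for
nucleotide-presence experiments.  All generators are pure functions of their
spec including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .network import SpringEdge, SpringNetwork, StiffnessTable, VDW, build_bead_network
from .structures import Bead, BeadModel

#: Calpha virtual-bond spacing, Angstrom
DEFAULT_SPACING = 3.8
#: jitter bound that breaks lattice symmetry without moving contacts
JITTER = 0.1


@dataclass(frozen=True)
class HingeSpec:
    """Two rigid domains joined by a linker, opened by a known rotation."""

    beads_per_domain: int = 30
    linker_beads: int = 5
    angle_deg: float = 30.0
    spacing: float = DEFAULT_SPACING
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.angle_deg < 180.0:
            raise ValueError("hinge angle must be in (0, 180) degrees")
        if self.beads_per_domain < 4:
            raise ValueError("need >=4 beads per domain")
        if self.linker_beads < 1:
            raise ValueError("need >=1 linker bead")


def _fcc_blob(n: int, spacing: float) -> np.ndarray:
    """n points of a face-centered-cubic lattice closest to its center.

    Nearest-neighbor distance equals ``spacing``, which keeps the blob rigid
    under nearest-neighbor springs.
    """
    a = spacing * np.sqrt(2.0)  # cubic cell edge for fcc nn distance=spacing
    r = int(np.ceil((n / 4.0) ** (1 / 3))) + 2
    pts = []
    base = np.array([[0, 0, 0], [0.5, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0.5]])
    for i in range(-r, r + 1):
        for j in range(-r, r + 1):
            for k in range(-r, r + 1):
                for b in base:
                    pts.append((np.array([i, j, k]) + b) * a)
    pts = np.array(pts)
    order = np.argsort(np.linalg.norm(pts, axis=1), kind="stable")
    blob = pts[order[:n]]
    return blob - blob.mean(axis=0)


def _beads_from_coords(coords: np.ndarray, chain: str, first_res: int,
                       start_index: int, mass: float = 110.0) -> list[Bead]:
    return [
        Bead(start_index + k, coords[k].copy(), mass, "residue",
             (chain, first_res + k, "ALA"))
        for k in range(len(coords))
    ]


def make_hinge_pair(
    spec: HingeSpec = HingeSpec(),
) -> tuple[BeadModel, BeadModel, dict]:
    """Closed/open conformer pair with a known hinge rotation.

    The linker (chain L) is a column of beads along the z axis — a hinge
    pin.  Domains A and B (rigid lattice blobs) flank it in x, each within
    contact range of the pin but not of each other, so rotation of one
    domain about the pin axis is the uniquely softest elastic motion.  The
    open conformer rotates chain B by the spec angle about that axis; the
    ground truth (angle, axis, pivot) is returned.
    """
    rng = np.random.default_rng(spec.seed)
    s = spec.spacing
    blob = _fcc_blob(spec.beads_per_domain, s)
    radius = np.abs(blob[:, 0]).max()
    gap = 3.5  # pin-to-domain-surface distance; domains touch weakly at the waist

    pin_spacing = 0.7 * s  # keep the pin inside the domains' z extent
    kk = np.arange(spec.linker_beads)
    # the +-0.5 A zigzag takes every pin bead off the rotation axis, giving
    # the counter-rotation mode first-order restoring well above the
    # zero-mode tolerance while leaving it the softest elastic motion
    pin = np.column_stack([
        0.5 * (-1.0) ** kk, np.zeros(spec.linker_beads),
        (kk - (spec.linker_beads - 1) / 2.0) * pin_spacing,
    ])
    a_center = np.array([-(radius + gap), 0.0, 0.0])
    b_center = np.array([radius + gap, 0.0, 0.0])

    coords = np.concatenate([blob + a_center, pin, blob + b_center])
    coords = coords + rng.uniform(-JITTER, JITTER, size=coords.shape)

    na, nl = spec.beads_per_domain, spec.linker_beads
    beads = (
        _beads_from_coords(coords[:na], "A", 1, 0)
        + _beads_from_coords(coords[na:na + nl], "L", 1, na)
        + _beads_from_coords(coords[na + nl:], "B", 1, na + nl)
    )
    closed = BeadModel(beads, name="hinge-closed")

    pivot = np.zeros(3)
    axis = np.array([0.0, 0.0, 1.0])
    rot = Rotation.from_rotvec(np.radians(spec.angle_deg) * axis)
    open_coords = coords.copy()
    moving = np.arange(na + nl, len(coords))  # chain B only
    open_coords[moving] = rot.apply(coords[moving] - pivot) + pivot
    open_ = closed.with_coords(open_coords, name="hinge-open")
    truth = {"angle_deg": spec.angle_deg, "axis": axis, "pivot": pivot,
             "moving": moving}
    return closed, open_, truth


def hinge_domain_labels(model: BeadModel, chain: str) -> list:
    return [b.label for b in model.beads if b.label[0] == chain]


def make_elastic_chain(
    n: int, k: float = 1.0, m: float = 1.0,
    spacing: float = DEFAULT_SPACING, topology: str = "line",
) -> SpringNetwork:
    """Uniform nearest-neighbor chain with an analytic spectrum.

    ``line`` is a straight three-dimensional chain; ``ring`` is a genuinely
    one-dimensional periodic chain (one degree of freedom per bead) whose
    spectrum is exactly the circulant closed form (4k/m) sin^2(pi j / n).
    """
    if n < 2:
        raise ValueError("need n >= 2 beads")
    if topology not in ("line", "ring"):
        raise ValueError(f"unknown topology {topology!r}")
    coords = np.zeros((n, 3))
    coords[:, 0] = np.arange(n) * spacing
    beads = [Bead(i, coords[i], m, "residue", ("A", i + 1, "ALA"))
             for i in range(n)]
    model = BeadModel(beads, name=f"chain-{topology}-{n}")
    edges = [SpringEdge(i, i + 1, "backbone", k, spacing)
             for i in range(n - 1)]
    dim = 3
    if topology == "ring":
        if n > 2:
            edges.append(
                SpringEdge(0, n - 1, "backbone", k, (n - 1) * spacing)
            )
        dim = 1
    return SpringNetwork(model, edges, dim=dim)


def ring_spectrum(n: int, k: float, m: float) -> np.ndarray:
    """Closed-form eigenvalues (4k/m) sin^2(pi j/n), ascending."""
    j = np.arange(n)
    return np.sort(4.0 * k / m * np.sin(np.pi * j / n) ** 2)


def make_pocket_ligand_toy(
    pocket_beads: int = 12,
    ligand_beads: int = 1,
    attachment_stiffness: float = 1.0,
    seed: int = 0,
    cage_stiffness: float = 5.0,
    radius: float = 8.0,
) -> tuple[BeadModel, SpringNetwork]:
    """Cage of pocket beads enclosing ligand beads with tunable coupling.

    Pocket beads lie on a sphere (Fibonacci lattice) and are linked to their
    six nearest cage neighbors (a triangulated, rigid shell); ligand beads
    sit near the center and are
    linked to every pocket bead by attachment springs.  Setting the
    attachment stiffness to zero decouples the ligand (edges are dropped, so
    the protein dynamics is exactly the empty-cage dynamics).
    """
    if pocket_beads < 6:
        raise ValueError("need >=6 pocket beads to enclose the ligand")
    if ligand_beads < 1:
        raise ValueError("need >=1 ligand bead")
    if attachment_stiffness < 0:
        raise ValueError("attachment stiffness must be >= 0")
    rng = np.random.default_rng(seed)
    i = np.arange(pocket_beads)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / pocket_beads
    r = np.sqrt(1.0 - z ** 2)
    cage = radius * np.column_stack(
        [r * np.cos(golden * i), r * np.sin(golden * i), z]
    )
    cage += rng.uniform(-JITTER, JITTER, size=cage.shape)
    lig = rng.uniform(-0.5, 0.5, size=(ligand_beads, 3))
    if np.any(np.linalg.norm(lig, axis=1) >= radius):
        raise ValueError("ligand bead outside the cage")
    # heterogeneous masses give the cage a structured MSF profile (a
    # perfectly symmetric cage has a flat one, useless for correlations)
    cage_masses = rng.uniform(80.0, 180.0, size=pocket_beads)
    beads = []
    for k in range(pocket_beads):
        beads.append(Bead(k, cage[k].copy(), float(cage_masses[k]),
                          "residue", ("P", k + 1, "ALA")))
    for k in range(ligand_beads):
        beads.append(Bead(pocket_beads + k, lig[k], 400.0,
                          "nucleotide-moiety", ("X", k + 1, f"LIG:{k}")))
    model = BeadModel(beads, name="pocket-toy")
    dist = cdist(model.coords, model.coords)
    pairs: set[tuple[int, int]] = set()
    for a in range(pocket_beads):
        for b in np.argsort(dist[a, :pocket_beads], kind="stable")[1:7]:
            pairs.add((min(a, int(b)), max(a, int(b))))
    # heterogeneous spring constants give the cage a structured MSF profile
    # (a perfectly symmetric cage has a flat one, useless for correlations)
    edges = [
        SpringEdge(a, b, VDW,
                   cage_stiffness * float(rng.uniform(0.3, 3.0)),
                   float(dist[a, b]))
        for a, b in sorted(pairs)
    ]
    if attachment_stiffness > 0:
        for k in range(ligand_beads):
            j = pocket_beads + k
            for a in range(pocket_beads):
                edges.append(SpringEdge(a, j, VDW, attachment_stiffness,
                                        float(dist[a, j])))
            for k2 in range(k + 1, ligand_beads):
                j2 = pocket_beads + k2
                edges.append(SpringEdge(j, j2, "nucleotide-covalent",
                                        cage_stiffness, float(dist[j, j2])))
    return model, SpringNetwork(model, sorted(edges, key=lambda e: (e.i, e.j)))


def without_ligand(network: SpringNetwork) -> SpringNetwork:
    """Drop ligand (nucleotide-moiety) beads and their edges from a network."""
    model = network.model
    keep = [b for b in model.beads if b.kind != "nucleotide-moiety"]
    remap = {b.index: i for i, b in enumerate(keep)}
    beads = [Bead(i, b.position.copy(), b.mass, b.kind, b.label)
             for i, b in enumerate(keep)]
    edges = [
        SpringEdge(remap[e.i], remap[e.j], e.cls, e.stiffness, e.rest_length)
        for e in network.edges if e.i in remap and e.j in remap
    ]
    anchored = frozenset(remap[i] for i in network.anchored if i in remap)
    return SpringNetwork(BeadModel(beads, name=model.name + "-apo"), edges,
                         anchored=anchored, dim=network.dim)
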