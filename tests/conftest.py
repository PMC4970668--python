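"""Shared fixtures: hand-built atomic structures and synthetic models."""

import numpy as np
import pytest

from enmkit.structures import AtomicStructure, Bead, BeadModel

TRIPEPTIDE_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 10.00           C
ATOM      3  C   ALA A   1      12.685   7.182  -5.033  1.00 10.00           C
ATOM      4  O   ALA A   1      13.339   7.243  -3.992  1.00 10.00           O
ATOM      5  CB  ALA A   1      12.212   4.711  -4.844  1.00 10.00           C
ATOM      6  N   GLY A   2      12.851   8.025  -6.039  1.00 10.00           N
ATOM      7  CA AGLY A   2      13.837   9.084  -5.961  0.60 10.00           C
ATOM      8  CA BGLY A   2      13.937   9.184  -6.061  0.40 10.00           C
ATOM      9  C   GLY A   2      13.198  10.428  -5.653  1.00 10.00           C
ATOM     10  O   GLY A   2      12.021  10.512  -5.322  1.00 10.00           O
ATOM     11  N   SER A   3      13.987  11.490  -5.759  1.00 10.00           N
ATOM     12  CA  SER A   3      13.501  12.841  -5.502  1.00 10.00           C
ATOM     13  C   SER A   3      14.651  13.838  -5.479  1.00 10.00           C
ATOM     14  O   SER A   3      15.792  13.469  -5.755  1.00 10.00           O
TER
END
"""

GTP_ATOMS = [
    ("PG", "P"), ("O1G", "O"), ("O2G", "O"), ("O3G", "O"), ("O3B", "O"),
    ("PB", "P"), ("O1B", "O"), ("O2B", "O"), ("O3A", "O"),
    ("PA", "P"), ("O1A", "O"), ("O2A", "O"),
    ("O5'", "O"), ("C5'", "C"), ("C4'", "C"), ("O4'", "O"), ("C3'", "C"),
    ("O3'", "O"), ("C2'", "C"), ("O2'", "O"), ("C1'", "C"),
    ("N9", "N"), ("C8", "C"), ("N7", "N"), ("C5", "C"), ("C6", "C"),
    ("O6", "O"), ("N1", "N"), ("C2", "C"), ("N2", "N"), ("N3", "N"),
    ("C4", "C"),
]


def make_structure(rows, source="test"):
    """Build an AtomicStructure from (name, element, resname, resid, chain,
    xyz, hetero) tuples."""
    n = len(rows)
    return AtomicStructure(
        element=np.array([r[1] for r in rows], dtype="U4"),
        atom_name=np.array([r[0] for r in rows], dtype="U6"),
        res_name=np.array([r[2] for r in rows], dtype="U5"),
        res_id=np.array([r[3] for r in rows]),
        chain_id=np.array([r[4] for r in rows], dtype="U4"),
        coord=np.array([r[5] for r in rows], float),
        occupancy=np.ones(n),
        b_factor=np.zeros(n),
        hetero=np.array([r[6] for r in rows], bool),
        source=source,
    )


def bead_model(coords, chain="A", mass=110.0, first_res=1, name="toy"):
    coords = np.asarray(coords, float)
    beads = [Bead(i, coords[i].copy(), mass, "residue",
                  (chain, first_res + i, "ALA"))
             for i in range(len(coords))]
    return BeadModel(beads, name=name)


def random_bead_model(n, seed=0, box=12.0, min_sep=2.5):
    """n beads uniform in a box, rejecting near-coincident placements."""
    rng = np.random.default_rng(seed)
    pts = []
    while len(pts) < n:
        p = rng.uniform(0, box, 3)
        if all(np.linalg.norm(p - q) > min_sep for q in pts):
            pts.append(p)
    return bead_model(np.array(pts), name=f"random-{n}-{seed}")


def ligand_structure(kind="GTP", seed=5, chain="A", res_id=401):
    atoms = GTP_ATOMS if kind == "GTP" else [
        a for a in GTP_ATOMS if a[0] not in {"PG", "O1G", "O2G", "O3G"}
    ]
    rng = np.random.default_rng(seed)
    rows = [(name, elem, kind, res_id, chain, rng.uniform(0, 10, 3), True)
            for name, elem in atoms]
    return make_structure(rows, source=f"synthetic-{kind}")


@pytest.fixture(scope="session")
def tripeptide_path(tmp_path_factory):
    path = tmp_path_factory.mktemp("pdb") / "tripeptide.pdb"
    path.write_text(TRIPEPTIDE_PDB)
    return path


@pytest.fixture(scope="session")
def hinge():
    from enmkit.synthetic import HingeSpec, make_hinge_pair

    closed, open_, truth = make_hinge_pair(HingeSpec(seed=0))
    return closed, open_, truth


@pytest.fixture(scope="session")
def hinge_modes(hinge):
    from enmkit.network import build_bead_network, build_hessian
    from enmkit.nma import solve_modes

    closed, _, _ = hinge
    return solve_modes(build_hessian(build_bead_network(closed)))
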