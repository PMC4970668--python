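"""Structure I/O, coarse-graining, chimera assembly and rigid-body geometry.

Proteins are reduced to one bead per residue placed at the Calpha, carrying
the summed mass of the residue's atoms; guanine nucleotides (GTP/GDP) are
reduced to moiety beads (base, ribose and the individual phosphates) at their
mass-weighted centers.  Rigid superposition, pseudo-dihedral profiles and
inter-domain rotation angles operate on these bead models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import biotite.structure as bst
import biotite.structure.info as bstinfo
from biotite.structure.io.pdb import PDBFile


class PDBParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


BeadLabel = tuple  # (chain, residue number, residue/moiety name)


@dataclass(frozen=True)
class AtomicStructure:
    """All-atom structure: parallel arrays, one entry per atom.

    Coordinates are in Angstrom; residue numbers are kept 1-based exactly as
    in the source file.
    """

    element: np.ndarray
    atom_name: np.ndarray
    res_name: np.ndarray
    res_id: np.ndarray
    chain_id: np.ndarray
    coord: np.ndarray
    occupancy: np.ndarray
    b_factor: np.ndarray
    hetero: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coord)):
            raise ValueError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.coord)

    def select(self, mask: np.ndarray) -> "AtomicStructure":
        return AtomicStructure(
            element=self.element[mask],
            atom_name=self.atom_name[mask],
            res_name=self.res_name[mask],
            res_id=self.res_id[mask],
            chain_id=self.chain_id[mask],
            coord=self.coord[mask],
            occupancy=self.occupancy[mask],
            b_factor=self.b_factor[mask],
            hetero=self.hetero[mask],
            source=self.source,
        )

    def residue_keys(self) -> list[tuple[str, int]]:
        """Unique (chain, residue number) pairs in order of appearance."""
        seen: dict[tuple[str, int], None] = {}
        for c, r in zip(self.chain_id, self.res_id):
            seen.setdefault((str(c), int(r)), None)
        return list(seen)

    def residue_mask(self, chain: str, res_id: int) -> np.ndarray:
        return (self.chain_id == chain) & (self.res_id == res_id)


@dataclass(frozen=True)
class Bead:
    index: int
    position: np.ndarray
    mass: float
    kind: str  # "residue" | "nucleotide-moiety" | "anchor"
    label: BeadLabel

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"bead {self.label}: mass must be positive")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"bead {self.label}: non-finite position")


@dataclass
class BeadModel:
    """Ordered coarse-grained model; bead indices are contiguous from 0."""

    beads: list[Bead]
    name: str = ""

    def __post_init__(self) -> None:
        labels = [b.label for b in self.beads]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate bead labels")
        for i, b in enumerate(self.beads):
            if b.index != i:
                raise ValueError("bead indices must be contiguous from 0")

    def __len__(self) -> int:
        return len(self.beads)

    @property
    def coords(self) -> np.ndarray:
        return np.array([b.position for b in self.beads], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([b.mass for b in self.beads], dtype=float)

    @property
    def labels(self) -> list[BeadLabel]:
        return [b.label for b in self.beads]

    def label_index(self) -> dict[BeadLabel, int]:
        return {b.label: b.index for b in self.beads}

    def with_coords(self, coords: np.ndarray, name: str | None = None) -> "BeadModel":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.beads), 3):
            raise ValueError("coordinate array shape mismatch")
        beads = [
            Bead(i, coords[i].copy(), b.mass, b.kind, b.label)
            for i, b in enumerate(self.beads)
        ]
        return BeadModel(beads, name=self.name if name is None else name)

    def subset(self, labels: Iterable[BeadLabel], name: str = "") -> "BeadModel":
        wanted = set(labels)
        picked = [b for b in self.beads if b.label in wanted]
        beads = [Bead(i, b.position.copy(), b.mass, b.kind, b.label)
                 for i, b in enumerate(picked)]
        return BeadModel(beads, name=name or self.name)


@dataclass
class RegionMap:
    """Named residue regions, e.g. ``{"switch1": {("A", 177), ...}}``."""

    regions: dict[str, set[tuple[str, int]]]

    def resolve(self, name: str, model: BeadModel) -> list[int]:
        if name not in self.regions:
            raise KeyError(f"unknown region {name!r}")
        keys = self.regions[name]
        idx = [b.index for b in model.beads if (b.label[0], b.label[1]) in keys]
        if not idx:
            raise ValueError(f"region {name!r} resolves to no beads")
        return idx


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # applied as x -> R @ x + t
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _prevalidate_pdb(path: Path) -> None:
    # Coordinate records shorter than the coordinate field block cannot be
    # parsed; report the offending line number (biotite does not).
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec in ("ATOM", "HETATM") and len(line.rstrip("\n")) < 54:
                raise PDBParseError(
                    f"{path}: truncated {rec} record at line {lineno}"
                )


def read_structure(path: str | Path, model: int = 1) -> AtomicStructure:
    """Read one model from a legacy PDB file.

    Alternate locations are resolved by keeping the highest-occupancy altloc
    (alphabetic first on ties).  HETATM records are retained and flagged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prevalidate_pdb(path)
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if model < 1 or model > n_models:
        raise PDBParseError(
            f"{path}: model {model} absent (file has {n_models})"
        )
    try:
        arr = pdb.get_structure(
            model=model, altloc="occupancy",
            extra_fields=["occupancy", "b_factor"],
        )
    except Exception as exc:  # pragma: no cover - biotite error surface
        raise PDBParseError(f"{path}: {exc}") from exc
    return AtomicStructure(
        element=np.asarray(arr.element, dtype="U4"),
        atom_name=np.asarray(arr.atom_name, dtype="U6"),
        res_name=np.asarray(arr.res_name, dtype="U5"),
        res_id=np.asarray(arr.res_id, dtype=int),
        chain_id=np.asarray(arr.chain_id, dtype="U4"),
        coord=np.asarray(arr.coord, dtype=float),
        occupancy=np.asarray(arr.occupancy, dtype=float),
        b_factor=np.asarray(arr.b_factor, dtype=float),
        hetero=np.asarray(arr.hetero, dtype=bool),
        source=f"{path.name}#model{model}",
    )


def _bead_atom_array(model: BeadModel) -> bst.AtomArray:
    n = len(model)
    arr = bst.AtomArray(n)
    arr.coord = model.coords.astype(np.float32)
    for i, b in enumerate(model.beads):
        chain, res_id, name = (b.label + ("", "", ""))[:3]
        arr.chain_id[i] = str(chain)[:4] or "A"
        arr.res_id[i] = int(res_id) if str(res_id).lstrip("-").isdigit() else i + 1
        arr.res_name[i] = (str(name)[:5] or "GLY").upper()[:5]
        if b.kind == "nucleotide-moiety":
            arr.atom_name[i] = "P" if "phos" in str(name) else "C1'"
            arr.element[i] = "P" if "phos" in str(name) else "C"
            arr.hetero[i] = True
        else:
            arr.atom_name[i] = "CA"
            arr.element[i] = "C"
            arr.hetero[i] = False
    return arr


def write_bead_pdb(model: BeadModel, path: str | Path) -> None:
    """Write a bead model as a Calpha-trace PDB file."""
    pdb = PDBFile()
    pdb.set_structure(_bead_atom_array(model))
    pdb.write(str(path))


def write_trajectory_pdb(models: Sequence[BeadModel], path: str | Path) -> None:
    """Write conformations as a multi-model (MODEL/ENDMDL) PDB file."""
    if not models:
        raise ValueError("no models to write")
    template = _bead_atom_array(models[0])
    stack = bst.AtomArrayStack(len(models), len(template))
    for cat in template.get_annotation_categories():
        stack.set_annotation(cat, template.get_annotation(cat))
    stack.coord = np.stack([m.coords.astype(np.float32) for m in models])
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Coarse-graining
# ---------------------------------------------------------------------------

_NUCLEOTIDE_RES = {"GTP", "GDP", "GSP", "GNP"}  # GSP/GNP: GTPgammaS / GppNHp analogues

# Moiety membership for guanine nucleotides.  In GTP the gamma-phosphate
# group is PG + its three terminal oxygens + the beta-gamma bridging oxygen
# (O3B), so that GDP is exactly the GTP partition minus those five atoms; in
# GDP files O3B names a terminal beta-phosphate oxygen and belongs to beta.
_MOIETY_ATOMS = {
    "gamma-phosphate": {"PG", "O1G", "O2G", "O3G", "S1G", "N3B"},
    "beta-phosphate": {"PB", "O1B", "O2B", "O3A"},
    "alpha-phosphate": {"PA", "O1A", "O2A"},
    "base": {"N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4",
             "H8", "H1", "H21", "H22"},
}
_MOIETY_ORDER = ["base", "ribose", "alpha-phosphate", "beta-phosphate",
                 "gamma-phosphate"]


def atomic_mass(element: str) -> float:
    m = bstinfo.mass(element.capitalize(), is_residue=False)
    if m is None:
        raise ValueError(f"unknown element {element!r}")
    return float(m)


def _atom_masses(struct: AtomicStructure, mask: np.ndarray) -> float:
    return float(sum(atomic_mass(e) for e in struct.element[mask]))


def coarse_grain_protein(
    structure: AtomicStructure,
    strict: bool = True,
    full_residue_mass: bool = False,
    name: str = "",
) -> BeadModel:
    """One bead per amino-acid residue at its Calpha position.

    Bead mass is the summed mass of the residue's atoms present in the file
    (crystal structures routinely miss atoms); ``full_residue_mass`` switches
    to the full chemical-component mass from the internal table instead.
    With ``strict`` a residue lacking a Calpha raises; otherwise it is
    skipped with a warning.
    """
    protein = structure.select(~structure.hetero)
    beads: list[Bead] = []
    for chain, res_id in protein.residue_keys():
        mask = protein.residue_mask(chain, res_id)
        names = protein.atom_name[mask]
        ca = np.where(names == "CA")[0]
        res_name = str(protein.res_name[mask][0])
        if len(ca) == 0:
            msg = f"residue {chain}/{res_id} ({res_name}) has no Calpha"
            if strict:
                raise ValueError(msg)
            warnings.warn(msg + "; skipped", stacklevel=2)
            continue
        pos = protein.coord[mask][ca[0]].copy()
        if full_residue_mass:
            mass = bstinfo.mass(res_name, is_residue=True)
            if mass is None:
                mass = _atom_masses(protein, mask)
        else:
            mass = _atom_masses(protein, mask)
        beads.append(
            Bead(len(beads), pos, float(mass), "residue",
                 (chain, res_id, res_name))
        )
    return BeadModel(beads, name=name or structure.source)


def assign_nucleotide_moiety(atom_name: str, kind: str) -> str:
    """Map a nucleotide atom name to its moiety group."""
    name = atom_name.upper()
    if name == "O3B":
        return "beta-phosphate" if kind == "GDP" else "gamma-phosphate"
    for moiety, members in _MOIETY_ATOMS.items():
        if name in members:
            if moiety == "gamma-phosphate" and kind == "GDP":
                raise ValueError(
                    f"atom {atom_name!r} belongs to the gamma-phosphate, "
                    "absent from GDP"
                )
            return moiety
    if "'" in name or name in {"O5*", "C5*", "C4*", "O4*", "C3*", "O3*",
                               "C2*", "O2*", "C1*"}:
        return "ribose"
    raise ValueError(f"cannot assign nucleotide atom {atom_name!r} to a moiety")


def coarse_grain_nucleotide(
    ligand: AtomicStructure, kind: str, chain: str | None = None,
    res_id: int | None = None,
) -> list[Bead]:
    """Reduce a bound guanine nucleotide to moiety beads.

    GTP yields five beads (guanine base, ribose, alpha-, beta-,
    gamma-phosphate), each at the mass-weighted centroid of its atoms; GDP
    yields the same partition without the gamma-phosphate (four beads).
    """
    kind = kind.upper()
    if kind not in ("GTP", "GDP"):
        raise ValueError(f"nucleotide kind must be GTP or GDP, got {kind!r}")
    if ligand.n_atoms == 0:
        raise ValueError("empty ligand selection")
    chain = chain if chain is not None else str(ligand.chain_id[0])
    res_id = res_id if res_id is not None else int(ligand.res_id[0])
    groups: dict[str, list[int]] = {m: [] for m in _MOIETY_ORDER}
    for i, aname in enumerate(ligand.atom_name):
        groups[assign_nucleotide_moiety(str(aname), kind)].append(i)
    beads: list[Bead] = []
    order = _MOIETY_ORDER if kind == "GTP" else _MOIETY_ORDER[:-1]
    for moiety in order:
        idx = groups[moiety]
        if not idx:
            raise ValueError(f"no atoms found for moiety {moiety!r}")
        masses = np.array([atomic_mass(str(ligand.element[i])) for i in idx])
        pos = np.average(ligand.coord[idx], axis=0, weights=masses)
        beads.append(
            Bead(len(beads), pos, float(masses.sum()), "nucleotide-moiety",
                 (chain, res_id, f"{kind}:{moiety}"))
        )
    return beads


def coarse_grain(
    structure: AtomicStructure, strict: bool = True, name: str = ""
) -> tuple[BeadModel, dict[int, np.ndarray]]:
    """Coarse-grain protein residues plus any recognised bound nucleotides.

    Returns the bead model and a map bead index -> atom indices into
    ``structure`` (needed by the chemistry-aware contact classifier).
    """
    beads: list[Bead] = []
    atom_map: dict[int, np.ndarray] = {}
    protein_mask = ~structure.hetero
    for chain, res_id in structure.residue_keys():
        mask = structure.residue_mask(chain, res_id)
        res_name = str(structure.res_name[mask][0])
        is_het = bool(structure.hetero[mask][0])
        if not is_het:
            sub_mask = mask & protein_mask
            names = structure.atom_name[sub_mask]
            ca = np.where(names == "CA")[0]
            if len(ca) == 0:
                msg = f"residue {chain}/{res_id} ({res_name}) has no Calpha"
                if strict:
                    raise ValueError(msg)
                warnings.warn(msg + "; skipped", stacklevel=2)
                continue
            pos = structure.coord[sub_mask][ca[0]].copy()
            beads.append(Bead(len(beads), pos, _atom_masses(structure, sub_mask),
                              "residue", (chain, res_id, res_name)))
            atom_map[beads[-1].index] = np.where(sub_mask)[0]
        elif res_name in _NUCLEOTIDE_RES:
            kind = "GDP" if res_name == "GDP" else "GTP"
            lig = structure.select(mask)
            moieties = coarse_grain_nucleotide(lig, kind, chain, res_id)
            atom_idx = np.where(mask)[0]
            for mb in moieties:
                beads.append(Bead(len(beads), mb.position, mb.mass, mb.kind,
                                  mb.label))
                members = _moiety_member_indices(lig, mb.label[2].split(":")[1],
                                                 kind)
                atom_map[beads[-1].index] = atom_idx[members]
        # other heteroatoms (waters, ions) are not coarse-grained
    return BeadModel(beads, name=name or structure.source), atom_map


def _moiety_member_indices(lig: AtomicStructure, moiety: str, kind: str) -> np.ndarray:
    idx = [i for i, a in enumerate(lig.atom_name)
           if assign_nucleotide_moiety(str(a), kind) == moiety]
    return np.array(idx, dtype=int)


# ---------------------------------------------------------------------------
# Rigid-body geometry
# ---------------------------------------------------------------------------

def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation + translation mapping mobile onto reference."""
    mu_m = mobile.mean(axis=0)
    mu_r = reference.mean(axis=0)
    H = (mobile - mu_m).T @ (reference - mu_r)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_r - R @ mu_m
    return R, t


def _paired_coords(
    mobile: BeadModel, reference: BeadModel,
    selection: Iterable[BeadLabel] | None,
) -> tuple[np.ndarray, np.ndarray]:
    ref_idx = reference.label_index()
    mob_idx = mobile.label_index()
    if selection is None:
        labels = [l for l in mobile.labels if l in ref_idx]
    else:
        labels = [l for l in selection if l in ref_idx and l in mob_idx]
    if len(labels) < 3:
        raise ValueError(f"need >=3 paired beads, got {len(labels)}")
    mob = np.array([mobile.beads[mob_idx[l]].position for l in labels])
    ref = np.array([reference.beads[ref_idx[l]].position for l in labels])
    return mob, ref


def superpose(
    mobile: BeadModel, reference: BeadModel,
    selection: Iterable[BeadLabel] | None = None,
) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Beads are paired by label; ``selection`` restricts the pairing.
    """
    mob, ref = _paired_coords(mobile, reference, selection)
    centered = mob - mob.mean(axis=0)
    # collinearity check: rank of the centered cloud
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("selected beads are collinear; superposition ill-posed")
    R, t = _kabsch(mob, ref)
    moved = mob @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return SuperpositionResult(R, t, rmsd, len(mob))


def rmsd_between(a: BeadModel, b: BeadModel,
                 selection: Iterable[BeadLabel] | None = None) -> float:
    """Superposed RMSD between two models (paired by label)."""
    return superpose(a, b, selection).rmsd


def virtual_torsion_profile(model: BeadModel) -> list[tuple[str, int, float]]:
    """Pseudo-dihedral over bead quadruples (i-1, i, i+1, i+2) per chain.

    The angle is assigned to residue i, in degrees on (-180, 180].  Chains
    with fewer than four beads raise.
    """
    chains: dict[str, list[Bead]] = {}
    for b in model.beads:
        if b.kind != "residue":
            continue
        chains.setdefault(str(b.label[0]), []).append(b)
    out: list[tuple[str, int, float]] = []
    any_chain_ok = False
    for chain, beads in chains.items():
        if len(beads) < 4:
            continue
        any_chain_ok = True
        coords = np.array([b.position for b in beads])
        for i in range(1, len(beads) - 2):
            ang = dihedral(coords[i - 1], coords[i], coords[i + 1], coords[i + 2])
            out.append((chain, int(beads[i].label[1]), ang))
    if not any_chain_ok:
        raise ValueError("virtual torsion needs >=4 consecutive beads per chain")
    return out


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle in degrees, range (-180, 180]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(n1 @ n2)
    y = float(m1 @ n2)
    # IUPAC sign: positive when the far bond rotates clockwise viewed
    # along the central bond (right-handed helix gives +50 deg)
    ang = -np.degrees(np.arctan2(y, x))
    if ang <= -180.0 + 1e-12:
        ang += 360.0
    return float(ang)


def rotation_angle(R: np.ndarray) -> float:
    """Rotation angle of a proper rotation matrix, degrees in [0, 180]."""
    c = (np.trace(R) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def domain_rotation_angle(
    closed: BeadModel, open_: BeadModel,
    fixed: Iterable[BeadLabel], mobile: Iterable[BeadLabel],
) -> float:
    """Inter-domain rotation between two conformations.

    The open model is first superposed onto the closed one over the fixed
    selection; the returned angle is that of the best-fit rigid transform
    mapping the mobile selection from closed to open.
    """
    fixed = list(fixed)
    mobile = list(mobile)
    sup = superpose(open_, closed, fixed)
    open_aligned = open_.with_coords(sup.apply(open_.coords))
    mob_closed, mob_open = _paired_coords(closed, open_aligned, mobile)
    R, _ = _kabsch(mob_closed, mob_open)
    return rotation_angle(R)


# ---------------------------------------------------------------------------
# Chimera assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChimeraSegment:
    source: str
    chain: str
    start: int  # inclusive residue numbers
    stop: int
    target_start: int | None = None  # renumber output; None keeps source numbers


@dataclass
class ChimeraRecipe:
    """Segments to stitch together, with an anchor selection for grafting.

    Sources other than ``reference`` are rigidly superposed onto the
    reference over the shared ``anchors`` labels before their segments are
    copied.  Output residue numbering follows ``target_start`` per segment.
    """

    segments: list[ChimeraSegment]
    reference: str
    anchors: list[BeadLabel] = field(default_factory=list)
    name: str = "chimera"

    def output_ranges(self) -> list[tuple[int, int]]:
        out = []
        for seg in self.segments:
            t0 = seg.target_start if seg.target_start is not None else seg.start
            out.append((t0, t0 + (seg.stop - seg.start)))
        return out


def build_chimera(
    recipe: ChimeraRecipe, sources: Mapping[str, BeadModel]
) -> BeadModel:
    """Assemble an engineered model by grafting segments between sources.

    Grafting is by anchor superposition only: no refinement of the joined
    coordinates is performed afterwards.
    """
    ranges = recipe.output_ranges()
    for i, (a0, a1) in enumerate(ranges):
        for b0, b1 in ranges[i + 1:]:
            if a0 <= b1 and b0 <= a1:
                raise ValueError(
                    f"overlapping output residue ranges {a0}-{a1} and {b0}-{b1}"
                )
    if recipe.reference not in sources:
        raise KeyError(f"reference source {recipe.reference!r} missing")
    aligned: dict[str, BeadModel] = {recipe.reference: sources[recipe.reference]}
    for seg in recipe.segments:
        if seg.source not in sources:
            raise KeyError(f"source {seg.source!r} missing")
        if seg.source not in aligned:
            sup = superpose(sources[seg.source], sources[recipe.reference],
                            recipe.anchors or None)
            aligned[seg.source] = sources[seg.source].with_coords(
                sup.apply(sources[seg.source].coords)
            )
    beads: list[Bead] = []
    for seg in recipe.segments:
        src = aligned[seg.source]
        idx = src.label_index()
        t0 = seg.target_start if seg.target_start is not None else seg.start
        for offset, res_id in enumerate(range(seg.start, seg.stop + 1)):
            key = next(
                (l for l in src.labels
                 if l[0] == seg.chain and l[1] == res_id), None
            )
            if key is None:
                raise ValueError(
                    f"segment {seg.source}/{seg.chain}:{seg.start}-{seg.stop}: "
                    f"residue {res_id} not found in source"
                )
            b = src.beads[idx[key]]
            beads.append(Bead(len(beads), b.position.copy(), b.mass, b.kind,
                              (seg.chain, t0 + offset, b.label[2])))
    return BeadModel(beads, name=recipe.name)


def profile_to_csv(rows: list[tuple[str, int, float]], path: str | Path,
                   value_name: str = "value") -> None:
    """Write a per-residue profile as CSV (chain, residue number, value)."""
    import pandas as pd

    pd.DataFrame(rows, columns=["chain", "res_id", value_name]).to_csv(
        path, index=False
    )
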