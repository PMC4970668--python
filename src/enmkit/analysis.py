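"""Comparative mobility experiments on elastic network models.

Mobility changes between two states are reported as the difference of
within-profile percentile ranks of the mean squared fluctuations ("in
percentile"), which makes profiles with different absolute scales
comparable.  On top of that sit the paper-style experiments: which terminus
binds first (anchor one, watch the other), does the ligand's presence alter
the dynamics, and does stiffening the inter-domain linker suppress the
opening motion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr, rankdata

from .network import (
    SpringEdge,
    SpringNetwork,
    anchor_beads,
    build_hessian,
)
from .nma import MSFProfile, mean_squared_fluctuation, solve_modes
from .overlap import cumulative_square_overlap
from .structures import BeadModel, RegionMap


@dataclass
class MobilityChangeMap:
    """Per-residue percentile difference between two MSF profiles.

    Values are percentage points in [-100, 100]; positive means the residue
    became relatively more mobile in the "after" state.
    """

    labels: list
    values: np.ndarray
    before: MSFProfile
    after: MSFProfile

    def __len__(self) -> int:
        return len(self.values)

    def as_dict(self) -> dict:
        return dict(zip(self.labels, self.values))

    def to_csv(self, path) -> None:
        import pandas as pd

        rows = [(l[0], l[1], v) for l, v in zip(self.labels, self.values)]
        pd.DataFrame(rows, columns=["chain", "res_id", "percentile_change"]) \
            .to_csv(path, index=False)


def _percentiles(values: np.ndarray) -> np.ndarray:
    # average fractional rank scaled to (0, 100]
    return rankdata(values, method="average") / len(values) * 100.0


def msf_percentile_change(
    before: MSFProfile, after: MSFProfile,
    pairing: dict | None = None,
) -> MobilityChangeMap:
    """after-percentile minus before-percentile, per paired residue.

    ``pairing`` maps before-labels to after-labels; by default residues are
    paired by identical label.  Percentile ranks are computed within each
    profile over the paired residues (average ranks on ties).
    """
    if pairing is None:
        after_set = set(after.labels)
        pairing = {l: l for l in before.labels if l in after_set}
    if len(pairing) < 2:
        raise ValueError("pairing must cover >=2 residues present in both")
    b_idx = {l: i for i, l in enumerate(before.labels)}
    a_idx = {l: i for i, l in enumerate(after.labels)}
    labels = [l for l in before.labels if l in pairing and pairing[l] in a_idx]
    b_vals = np.array([before.values[b_idx[l]] for l in labels])
    a_vals = np.array([after.values[a_idx[pairing[l]]] for l in labels])
    diff = _percentiles(a_vals) - _percentiles(b_vals)
    return MobilityChangeMap(labels, diff, before, after)


def region_average_change(
    change: MobilityChangeMap, regions: RegionMap | dict,
) -> dict[str, float]:
    """Mean percentile change per named region, plus the whole-map mean.

    Region membership is (chain, residue number); a region resolving to no
    residue of the map raises.
    """
    reg = regions.regions if isinstance(regions, RegionMap) else regions
    keys = [(l[0], l[1]) for l in change.labels]
    out: dict[str, float] = {}
    for name, members in reg.items():
        mask = np.array([k in members for k in keys])
        if not mask.any():
            raise ValueError(f"region {name!r} resolves to no residues")
        out[name] = float(change.values[mask].mean())
    out["all"] = float(change.values.mean())
    return out


def _anchored_msf(network: SpringNetwork, anchors: Iterable[int]) -> MSFProfile:
    anchored = anchor_beads(network, anchors)
    return mean_squared_fluctuation(solve_modes(build_hessian(anchored)))


def binding_order_experiment(
    network: SpringNetwork,
    anchors_a: Sequence[int],
    anchors_b: Sequence[int],
    free_region_a: Sequence[int] | None = None,
    free_region_b: Sequence[int] | None = None,
) -> dict:
    """Compare two alternative first-binding scenarios.

    Each variant freezes one disjoint anchor selection (the terminus assumed
    bound first, added to whatever anchors the base network already has) and
    computes the MSF of the remaining beads.  Reported per variant: the
    whole-model average percent change of MSF against the base (the paper's
    "average decrement" is the negative of this), and the mean percentile
    change over the still-free terminus region (the beads whose mobility
    decides whether the second binding event is facilitated).

    When the base network is itself anchored (a bound binding partner), the
    whole-model MSF change is guaranteed non-positive: extra constraints can
    only reduce the fluctuations of an anchored system.
    """
    set_a, set_b = set(map(int, anchors_a)), set(map(int, anchors_b))
    if set_a & set_b:
        raise ValueError("anchor selections overlap")
    base_msf = mean_squared_fluctuation(solve_modes(build_hessian(network)))
    report: dict = {}
    for tag, anchors, free_region in (
        ("variant_a", set_a, free_region_a),
        ("variant_b", set_b, free_region_b),
    ):
        msf = _anchored_msf(network, anchors)
        change = msf_percentile_change(base_msf, msf)
        shared = set(msf.labels)
        base_mobile = np.array([v for l, v in
                                zip(base_msf.labels, base_msf.values)
                                if l in shared])
        entry = {
            "mean_msf": float(msf.values.mean()),
            "base_mean_msf": float(base_mobile.mean()),
            "mean_msf_percent_change": float(
                (msf.values.mean() - base_mobile.mean())
                / base_mobile.mean() * 100.0
            ),
            "mean_percentile_change": float(change.values.mean()),
        }
        if free_region is not None:
            region_labels = {network.model.beads[int(i)].label
                             for i in free_region}
            mask = np.array([l in region_labels for l in change.labels])
            if not mask.any():
                raise ValueError("free-terminus region resolves to no beads")
            entry["free_region_percentile_change"] = float(
                change.values[mask].mean()
            )
        report[tag] = entry
    return report


def ligand_presence_experiment(
    network_holo: SpringNetwork,
    network_apo: SpringNetwork,
    change_direction: np.ndarray | None = None,
    cso_modes: int = 10,
) -> dict:
    """Effect of a bound ligand on protein dynamics.

    The two networks must share their protein beads and differ only by
    ligand (nucleotide-moiety) beads.  Reports the Pearson correlation of
    the protein-residue MSF between the systems and, when a conformational
    change direction over the protein beads is supplied, the CSO of each
    system's lowest modes against it.
    """
    holo_protein = [b.label for b in network_holo.model.beads
                    if b.kind != "nucleotide-moiety"]
    apo_protein = [b.label for b in network_apo.model.beads
                   if b.kind != "nucleotide-moiety"]
    if holo_protein != apo_protein:
        raise ValueError("the two models differ in their protein beads")
    msf_holo = mean_squared_fluctuation(solve_modes(build_hessian(network_holo)))
    msf_apo = mean_squared_fluctuation(solve_modes(build_hessian(network_apo)))
    holo_vals = np.array([v for l, v in zip(msf_holo.labels, msf_holo.values)
                          if l in set(apo_protein)])
    apo_vals = np.array([v for l, v in zip(msf_apo.labels, msf_apo.values)
                         if l in set(apo_protein)])
    report = {
        "msf_correlation": float(pearsonr(holo_vals, apo_vals).statistic),
        "n_protein_beads": len(apo_protein),
    }
    if change_direction is not None:
        d = np.asarray(change_direction, dtype=float).ravel()
        for tag, net in (("holo", network_holo), ("apo", network_apo)):
            modes = solve_modes(build_hessian(net))
            protein_rows = [i for i, b in enumerate(net.model.beads)
                            if b.kind != "nucleotide-moiety"]
            full = np.zeros((len(net.model), 3))
            full[protein_rows] = d.reshape(len(protein_rows), 3)
            n = min(cso_modes, modes.n_modes - modes.n_zero)
            report[f"cso_{tag}"] = cumulative_square_overlap(
                modes, full[modes.mobile].ravel(), n
            )
    return report


def stiffen_around(
    network: SpringNetwork,
    linker: Sequence[int],
    factor: float,
    cutoff_scale: float = 2.0,
    base_cutoff: float = 8.0,
) -> SpringNetwork:
    """Stiffen every edge touching the linker selection.

    Edges incident to a linker bead are re-searched within
    ``base_cutoff * cutoff_scale`` (new contacts enter as vdW springs) and
    all of them get their stiffness multiplied by ``factor``.
    """
    if factor <= 0:
        raise ValueError("stiffness factor must be > 0")
    sel = set(map(int, linker))
    if not sel:
        raise ValueError("empty linker selection")
    coords = network.model.coords
    dist = cdist(coords, coords)
    edges = {(e.i, e.j): e for e in network.edges}
    wide = base_cutoff * cutoff_scale
    for i in sel:
        for j in range(len(network.model)):
            if j == i:
                continue
            a, b = min(i, j), max(i, j)
            if (a, b) not in edges and dist[a, b] <= wide:
                edges[(a, b)] = SpringEdge(a, b, "vdw", 1.0, float(dist[a, b]))
    out = []
    for (a, b), e in sorted(edges.items()):
        if a in sel or b in sel:
            e = SpringEdge(a, b, e.cls, e.stiffness * factor, e.rest_length)
        out.append(e)
    return SpringNetwork(network.model, out, anchored=network.anchored,
                         dim=network.dim)


def linker_stiffening_experiment(
    network: SpringNetwork,
    linker: Sequence[int],
    change_direction: np.ndarray,
    factor: float = 100.0,
    cutoff_scale: float = 2.0,
    cso_modes: int = 20,
) -> dict:
    """CSO against a change direction before and after linker stiffening.

    Emulates suppressing the hinge: multiplying the spring constants around
    the linker by ``factor`` (with a widened contact search) should reduce
    how much of the opening motion the lowest ``cso_modes`` modes capture.
    """
    stiff = stiffen_around(network, linker, factor, cutoff_scale)
    d = np.asarray(change_direction, dtype=float).ravel()
    out = {}
    for tag, net in (("before", network), ("after", stiff)):
        modes = solve_modes(build_hessian(net))
        n = min(cso_modes, modes.n_modes - modes.n_zero)
        delta = d
        if modes.n_beads != len(net.model):
            delta = d.reshape(len(net.model), 3)[modes.mobile].ravel()
        out[f"cso_{tag}"] = cumulative_square_overlap(modes, delta, n)
    out["factor"] = factor
    out["n_modes"] = cso_modes
    return out


def map_to_bfactor_pdb(change: MobilityChangeMap, model: BeadModel, path) -> None:
    """Write the model with the change map in the B-factor column."""
    from biotite.structure.io.pdb import PDBFile

    from .structures import _bead_atom_array

    arr = _bead_atom_array(model)
    arr.set_annotation("b_factor", np.zeros(len(model)))
    lookup = change.as_dict()
    b = np.array([lookup.get(bead.label, 0.0) for bead in model.beads])
    arr.set_annotation("b_factor", b)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))
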