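"""Mode-displacement overlap, cumulative square overlap, pathway validation.

The overlap of normal mode a_j with a conformational change vector dr is

    O_j = |a_j . dr| / (|a_j| |dr|)

computed on Cartesian mode shapes after the two structures are superposed.
The cumulative square overlap (CSO) over the lowest modes measures how much
of a conformational change the low-frequency subspace captures; an ENI
pathway is validated by the CSO of each intermediate's low modes against the
direction to the target.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np

from .network import SpringNetwork, build_hessian
from .nma import ModeSet, solve_modes
from .structures import BeadModel, superpose

#: displacements smaller than this (Angstrom, total norm) are treated as zero
ZERO_DISPLACEMENT_TOL = 1e-6

DEFAULT_MODE_FRACTION = 0.05


@dataclass
class OverlapReport:
    """Per-mode overlaps of one displacement against one mode set."""

    overlaps: np.ndarray  # O_j for each non-zero mode, ascending frequency
    mode_indices: np.ndarray
    displacement_norm: float
    provenance: str = ""

    def cso(self, count: int) -> float:
        if count < 1 or count > len(self.overlaps):
            raise ValueError(f"count must be in [1, {len(self.overlaps)}]")
        return float(np.sum(self.overlaps[:count] ** 2))

    def cso_series(self) -> np.ndarray:
        return np.cumsum(self.overlaps ** 2)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"mode": self.mode_indices, "overlap": self.overlaps,
             "cso": self.cso_series()}
        ).to_csv(path, index=False)


def displacement_vector(from_model: BeadModel, to_model: BeadModel) -> np.ndarray:
    """Superposed displacement, to-minus-from, flattened to 3N."""
    if len(from_model) != len(to_model):
        raise ValueError("bead count mismatch")
    sup = superpose(to_model, from_model)
    moved = sup.apply(to_model.coords)
    return (moved - from_model.coords).ravel()


def overlap_value(mode_shape: np.ndarray, delta: np.ndarray) -> float:
    """Absolute normalized inner product of a mode shape and a displacement."""
    a = np.asarray(mode_shape, dtype=float).ravel()
    d = np.asarray(delta, dtype=float).ravel()
    if a.shape != d.shape:
        raise ValueError("vector length mismatch")
    na, nd = np.linalg.norm(a), np.linalg.norm(d)
    if na == 0 or nd == 0:
        raise ValueError("zero-length input vector")
    return float(min(abs(a @ d) / (na * nd), 1.0))


def overlap_report(modes: ModeSet, delta: np.ndarray,
                   provenance: str = "") -> OverlapReport:
    nz = modes.nonzero_indices()
    ov = np.array([
        overlap_value(modes.cartesian_shapes[:, j], delta) for j in nz
    ])
    return OverlapReport(ov, nz, float(np.linalg.norm(delta)), provenance)


def cumulative_square_overlap(modes: ModeSet, delta: np.ndarray,
                              count: int) -> float:
    """CSO over the lowest ``count`` non-zero modes."""
    report = overlap_report(modes, delta)
    return report.cso(count)


def remove_rigid_component(modes: ModeSet, delta: np.ndarray) -> np.ndarray:
    """Project out the zero-mode (rigid body) content of a displacement.

    Uses the orthonormalized Cartesian zero-mode shapes; exact completeness
    of the remainder against the elastic modes holds for uniform masses.
    """
    if modes.n_zero == 0:
        return np.asarray(delta, dtype=float).copy()
    basis, _ = np.linalg.qr(modes.cartesian_shapes[:, :modes.n_zero])
    d = np.asarray(delta, dtype=float).copy()
    return d - basis @ (basis.T @ d)


def mode_count_for_fraction(modes: ModeSet, fraction: float) -> int:
    """'First f lowest modes' as ceil(f * n_dof), excluding zero modes."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = math.ceil(fraction * modes.n_beads * modes.dim)
    return min(n, modes.n_modes - modes.n_zero)


def validate_pathway(
    path,  # PathwayEnsemble
    target: BeadModel,
    network_builder: Callable[[BeadModel], SpringNetwork],
    mode_fraction: float = DEFAULT_MODE_FRACTION,
) -> list[dict]:
    """CSO of each intermediate's low modes against the direction to target.

    For every pathway conformation the network is rebuilt, its modes solved,
    and the CSO over the lowest ceil(fraction * 3N) non-zero modes computed
    against the superposed displacement toward ``target``.  Intermediates
    coinciding with the target are skipped with a notice.
    """
    if not 0 < mode_fraction <= 1:
        raise ValueError("mode fraction must be in (0, 1]")
    out: list[dict] = []
    for k, conf in enumerate(path.conformations):
        delta = displacement_vector(conf, target)
        if np.linalg.norm(delta) < ZERO_DISPLACEMENT_TOL:
            warnings.warn(
                f"intermediate {k} coincides with the target; skipped",
                stacklevel=2,
            )
            out.append({"index": k, "alpha": float(path.alphas[k]),
                        "cso": None, "skipped": True})
            continue
        network = network_builder(conf)
        modes = solve_modes(build_hessian(network))
        if modes.n_beads != len(conf):  # anchored system: restrict to mobile
            delta = delta.reshape(len(conf), 3)[modes.mobile].ravel()
        n_modes = mode_count_for_fraction(modes, mode_fraction)
        cso = cumulative_square_overlap(modes, delta, n_modes)
        out.append({"index": k, "alpha": float(path.alphas[k]),
                    "cso": cso, "skipped": False})
    return out


def validation_to_csv(rows: list[dict], path) -> None:
    import pandas as pd

    pd.DataFrame(rows).to_csv(path, index=False)
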