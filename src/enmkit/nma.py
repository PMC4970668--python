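"""Normal mode analysis of the mass-weighted elastic network.

Solves the generalized eigenproblem K u = lambda M u by diagonalizing the
mass-weighted Hessian M^{-1/2} K M^{-1/2}.  Eigenvalues are squared angular
frequencies in model units; the six zero modes of a free structure are the
rigid translations and rotations.  Mean squared fluctuations are the
per-bead diagonal blocks of the covariance implied by equipartition
(k_B T = 1 in model units).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.linalg
from scipy.stats import pearsonr

from .network import HessianSystem
from .structures import BeadModel

#: eigenvalues below this fraction of the largest are treated as zero modes
ZERO_MODE_RTOL = 1e-8

#: above this many beads the sparse iterative eigensolver is used
DENSE_LIMIT = 500


@dataclass
class ModeSet:
    """Eigenpairs of the mass-weighted Hessian.

    ``eigenvectors`` are the orthonormal columns of the M^{-1/2}KM^{-1/2}
    diagonalization; ``cartesian_shapes`` are M^{-1/2} times those columns
    (the real-space displacement patterns entering overlap values).
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # (n_dof, n_modes), mass-weighted, orthonormal
    cartesian_shapes: np.ndarray  # (n_dof, n_modes)
    n_zero: int
    model: BeadModel
    mobile: np.ndarray
    dim: int = 3

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    @property
    def n_beads(self) -> int:
        return len(self.mobile)

    def nonzero_indices(self) -> np.ndarray:
        return np.arange(self.n_zero, self.n_modes)

    def shape_as_beads(self, mode: int) -> np.ndarray:
        """Cartesian shape of one mode as an (n_beads, dim) array."""
        return self.cartesian_shapes[:, mode].reshape(self.n_beads, self.dim)


def solve_modes(system: HessianSystem, count: int | None = None) -> ModeSet:
    """Lowest eigenpairs of M delta'' + K delta = 0.

    ``count=None`` solves the full spectrum (dense); an integer requests the
    lowest ``count`` modes and switches to a sparse shift-invert solver for
    large systems.  Eigenvector signs are fixed so the largest-magnitude
    component is positive (deterministic output).
    """
    K = system.K
    if not np.allclose(K, K.T, atol=1e-10 * max(1.0, np.abs(K).max())):
        raise ValueError("stiffness matrix is not symmetric")
    m_diag = system.M_diagonal
    if np.any(m_diag <= 0):
        raise ValueError("non-positive mass")
    n_dof = K.shape[0]
    if count is not None and count > n_dof:
        raise ValueError(f"requested {count} modes from a {n_dof}-DOF system")
    inv_sqrt_m = 1.0 / np.sqrt(m_diag)
    A = K * np.outer(inv_sqrt_m, inv_sqrt_m)
    A = 0.5 * (A + A.T)
    if count is None or system.n_beads <= DENSE_LIMIT:
        vals, vecs = scipy.linalg.eigh(A)
        if count is not None:
            vals, vecs = vals[:count], vecs[:, :count]
    else:
        sigma = -1e-6 * max(1.0, np.abs(A).max())
        vals, vecs = scipy.sparse.linalg.eigsh(
            scipy.sparse.csr_matrix(A), k=count, sigma=sigma, which="LM"
        )
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]
    vals = np.where(np.abs(vals) < ZERO_MODE_RTOL * max(np.abs(vals).max(), 1e-300),
                    0.0, vals)
    # deterministic sign: largest-magnitude component positive
    for k in range(vecs.shape[1]):
        i = int(np.argmax(np.abs(vecs[:, k])))
        if vecs[i, k] < 0:
            vecs[:, k] = -vecs[:, k]
    n_zero = int(np.sum(vals <= ZERO_MODE_RTOL * max(vals.max(), 1e-300)))
    cart = vecs * inv_sqrt_m[:, None]
    return ModeSet(vals, vecs, cart, n_zero, system.model, system.mobile,
                   dim=system.dim)


@dataclass
class MSFProfile:
    """Per-bead mean squared fluctuation (k_B T = 1)."""

    values: np.ndarray
    labels: list
    modes_used: np.ndarray

    def __len__(self) -> int:
        return len(self.values)

    def as_dict(self) -> dict:
        return dict(zip(self.labels, self.values))

    def to_csv(self, path) -> None:
        import pandas as pd

        rows = [(l[0], l[1], v) for l, v in zip(self.labels, self.values)]
        pd.DataFrame(rows, columns=["chain", "res_id", "msf"]).to_csv(
            path, index=False
        )


def mean_squared_fluctuation(
    modes: ModeSet, selection: Iterable[int] | None = None
) -> MSFProfile:
    """MSF_i = sum over selected modes of |shape_m(i)|^2 / lambda_m.

    ``selection=None`` uses every non-zero mode.  Zero modes in the
    selection are rejected (their contribution is unbounded).
    """
    if selection is None:
        sel = modes.nonzero_indices()
    else:
        sel = np.asarray(list(selection), dtype=int)
        if np.any(modes.eigenvalues[sel] <= 0):
            raise ValueError("selection contains a zero mode")
    if len(sel) == 0:
        raise ValueError("empty mode selection")
    shapes = modes.cartesian_shapes[:, sel]
    lam = modes.eigenvalues[sel]
    per_dof = (shapes ** 2) / lam[None, :]
    msf = per_dof.sum(axis=1).reshape(modes.n_beads, modes.dim).sum(axis=1)
    labels = [modes.model.beads[i].label for i in modes.mobile]
    return MSFProfile(msf, labels, sel)


def bfactor_correlation(profile: MSFProfile, bfactors: Sequence[float]) -> float:
    """Pearson correlation between an MSF profile and experimental B-factors."""
    b = np.asarray(bfactors, dtype=float)
    if len(b) != len(profile):
        raise ValueError("length mismatch between profile and B-factors")
    if len(b) < 3:
        raise ValueError("need >=3 paired residues")
    if np.ptp(b) == 0 or np.ptp(profile.values) == 0:
        raise ValueError("constant series: correlation undefined")
    return float(pearsonr(profile.values, b).statistic)


def mode_trajectory(
    modes: ModeSet, index: int, amplitude: float, frames: int = 20
) -> list[BeadModel]:
    """Sinusoidal sweep along one mode, peak RMSD = ``amplitude`` Angstrom."""
    if index < modes.n_zero or index >= modes.n_modes:
        raise ValueError(
            f"mode {index} is a rigid-body mode or out of range "
            f"(elastic modes start at {modes.n_zero})"
        )
    if frames < 1:
        raise ValueError("need >=1 frame")
    shape = modes.shape_as_beads(index)
    rms = np.sqrt(np.mean(np.sum(shape ** 2, axis=1)))
    scale = 0.0 if amplitude == 0 else amplitude / rms
    ref = modes.model.coords[modes.mobile][:, :modes.dim]
    out = []
    base = modes.model.subset(
        [modes.model.beads[i].label for i in modes.mobile]
    )
    for t in range(frames):
        phase = np.sin(2 * np.pi * t / frames)
        coords = ref + scale * phase * shape
        full = base.coords.copy()
        full[:, :modes.dim] = coords
        out.append(base.with_coords(full, name=f"mode{index}-frame{t}"))
    return out
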