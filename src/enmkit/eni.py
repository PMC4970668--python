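"""Elastic network interpolation between two conformations.

Intermediates are generated by minimizing the distance-matching cost

    C(delta) = 1/2 sum_{i<j} gamma_ij (|x_i + delta_i - x_j - delta_j| - l_ij)^2

where the target lengths l_ij linearly interpolate the endpoint inter-bead
distances, l_ij = (1-alpha)|x_i - x_j| + alpha|chi_i - chi_j|, and gamma is
the union contact map of the two endpoints at a 12 A cutoff.  The cost is
minimized by damped Gauss-Newton iterations on the linearized residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse
from scipy.sparse.linalg import lsmr
from scipy.spatial.distance import cdist

from .structures import BeadModel, superpose

DEFAULT_ENI_CUTOFF = 12.0
DEFAULT_STEPS = 50

_GN_STEP_TOL = 1e-6  # Angstrom; Gauss-Newton convergence on the step norm
_GN_MAX_ITER = 100


@dataclass
class LinkMatrix:
    """Symmetric boolean incidence of bead pairs entering the ENI cost."""

    matrix: np.ndarray
    cutoff: float

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("link matrix must be square")
        if not np.array_equal(m, m.T):
            raise ValueError("link matrix must be symmetric")
        if np.any(np.diag(m)):
            raise ValueError("link matrix diagonal must be zero")

    @property
    def pairs(self) -> np.ndarray:
        idx = np.argwhere(np.triu(self.matrix, k=1))
        return idx


@dataclass
class PathwayEnsemble:
    """Ordered ENI intermediates with per-step diagnostics."""

    conformations: list[BeadModel]
    alphas: np.ndarray
    costs: np.ndarray  # residual cost of each conformation's own targets
    rmsds: np.ndarray  # superposed RMSD to the start conformation

    def __len__(self) -> int:
        return len(self.conformations)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"alpha": self.alphas, "cost": self.costs, "rmsd_to_start": self.rmsds}
        ).to_csv(path, index=False)


def _check_pair(a: BeadModel, b: BeadModel) -> None:
    if len(a) != len(b):
        raise ValueError("bead count mismatch between conformations")
    if a.labels != b.labels:
        raise ValueError("bead labels differ between conformations")


def union_links(a: BeadModel, b: BeadModel,
                cutoff: float = DEFAULT_ENI_CUTOFF) -> LinkMatrix:
    """Union contact map: linked iff within cutoff in either conformation."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    _check_pair(a, b)
    da = cdist(a.coords, a.coords)
    db = cdist(b.coords, b.coords)
    m = (da <= cutoff) | (db <= cutoff)
    np.fill_diagonal(m, False)
    return LinkMatrix(m, cutoff)


def interpolated_lengths(a: BeadModel, b: BeadModel, alpha: float,
                         links: LinkMatrix) -> np.ndarray:
    """Linearly interpolated target lengths on linked pairs.

    Returns a dense symmetric matrix; entries off the link map are zero and
    never consumed.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    _check_pair(a, b)
    da = cdist(a.coords, a.coords)
    db = cdist(b.coords, b.coords)
    return np.where(links.matrix, (1.0 - alpha) * da + alpha * db, 0.0)


def _cost(coords: np.ndarray, pairs: np.ndarray, targets: np.ndarray) -> float:
    d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    l = targets[pairs[:, 0], pairs[:, 1]]
    return float(0.5 * np.sum((d - l) ** 2))


def eni_step(current: BeadModel, targets: np.ndarray,
             links: LinkMatrix) -> tuple[BeadModel, float]:
    """Deform one conformation toward its interpolated target distances.

    Damped Gauss-Newton on the linearized pair-distance residuals; the
    least-squares subproblem is solved in minimal-norm sense (LSMR), which
    also handles the rigid-motion degeneracy of the cost.  Iterations never
    increase the cost (backtracking line search).
    """
    pairs = links.pairs
    if len(pairs) == 0:
        raise ValueError("empty link matrix")
    n = len(current)
    coords = current.coords.copy()
    l_t = targets[pairs[:, 0], pairs[:, 1]]
    if np.any(l_t <= 0):
        raise ValueError("non-positive target length on a linked pair")
    cost = _cost(coords, pairs, targets)
    npairs = len(pairs)
    rows = np.repeat(np.arange(npairs), 6)
    for _ in range(_GN_MAX_ITER):
        vec = coords[pairs[:, 0]] - coords[pairs[:, 1]]
        dist = np.linalg.norm(vec, axis=1)
        dhat = vec / dist[:, None]
        resid = dist - l_t
        # Jacobian of resid wrt delta: +dhat on bead i, -dhat on bead j
        cols = np.concatenate(
            [3 * pairs[:, 0:1] + np.arange(3), 3 * pairs[:, 1:2] + np.arange(3)],
            axis=1,
        ).ravel()
        data = np.concatenate([dhat, -dhat], axis=1).ravel()
        J = scipy.sparse.csr_matrix((data, (rows, cols)),
                                    shape=(npairs, 3 * n))
        delta = lsmr(J, -resid, atol=1e-10, btol=1e-10)[0]
        step_norm = float(np.linalg.norm(delta.reshape(n, 3), axis=1).max())
        if step_norm < _GN_STEP_TOL:
            break
        # backtracking: accept only non-increasing cost
        scale = 1.0
        accepted = False
        for _ in range(30):
            trial = coords + scale * delta.reshape(n, 3)
            c_trial = _cost(trial, pairs, targets)
            if c_trial <= cost:
                coords, cost = trial, c_trial
                accepted = True
                break
            scale *= 0.5
        if not accepted or scale * step_norm < _GN_STEP_TOL:
            break
    return current.with_coords(coords), cost


def generate_pathway(a: BeadModel, b: BeadModel, steps: int = DEFAULT_STEPS,
                     cutoff: float = DEFAULT_ENI_CUTOFF) -> PathwayEnsemble:
    """ENI pathway from ``a`` to ``b`` with ``steps`` interpolation steps.

    Each intermediate is produced from the previous one with targets at
    alpha = k/steps; rigid-body drift is removed by superposing every
    intermediate onto its predecessor (the cost is rigid-motion degenerate).
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    _check_pair(a, b)
    links = union_links(a, b, cutoff)
    alphas = np.arange(steps + 1) / steps
    conformations = [a]
    costs = [0.0]
    rmsds = [0.0]
    current = a
    for alpha in alphas[1:]:
        targets = interpolated_lengths(a, b, float(alpha), links)
        nxt, cost = eni_step(current, targets, links)
        sup = superpose(nxt, current)
        nxt = nxt.with_coords(sup.apply(nxt.coords),
                              name=f"{a.name}->"f"{b.name}@{alpha:.3f}")
        conformations.append(nxt)
        costs.append(cost)
        rmsds.append(superpose(nxt, a).rmsd)
        current = nxt
    return PathwayEnsemble(conformations, alphas, np.array(costs),
                           np.array(rmsds))
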