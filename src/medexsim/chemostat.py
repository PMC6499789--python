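"""Continuous-growth (chemostat) steady-state coexistence heuristic.

In a chemostat at dilution rate ``delta``, with every influence saturating,
a mediator either accumulates far above its saturation constant (then its
influence acts at full strength, indicator ``theta_l = 1``) or is held near
zero by consumption / absence of producers (``theta_l = 0``).  Under that
dichotomy the surviving sub-community grows linearly,

    dS/dt = (-delta + r0 + P Theta) S,

and steady-state coexistence corresponds to the species subset whose
effective growth matrix has the *largest leading eigenvalue with a positive
leading eigenvector* (the dilution rate matches that eigenvalue and the
eigenvector gives the steady composition).

The effective growth matrix is kept mediator-resolved: for a candidate
subset and its theta assignment, entry (i, j) collects the full influence
strength of every saturated mediator that j produces and that influences i
(plus r0 on the diagonal).  Which mediators saturate is closed as: theta_l
= 1 iff some subset member produces mediator l and no subset member
depletes it; a depleting consumer forces theta_l = 0.

This is a heuristic screen, not a theorem — it is validated against the
serial-dilution simulation on small hand-built communities.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .model_core import CommunityParameters

__all__ = [
    "ChemostatProblem",
    "effective_growth_matrix",
    "fastest_consistent_subcommunity",
]


@dataclass
class ChemostatProblem:
    """Saturated-influence view of a community for steady-state analysis.

    ``rho_net`` is the signed influence matrix (N x M); ``produces`` and
    ``depletes`` are boolean (M x N) masks of production links and of
    depleting (consumption) links.  ``delta`` is the chemostat dilution
    rate, 1/h; it is matched to the winning eigenvalue rather than imposed.
    """

    r0: np.ndarray
    rho_net: np.ndarray
    produces: np.ndarray
    depletes: np.ndarray
    delta: float = 0.0

    def __post_init__(self) -> None:
        self.r0 = np.asarray(self.r0, dtype=float).reshape(-1)
        self.rho_net = np.asarray(self.rho_net, dtype=float)
        self.produces = np.asarray(self.produces, dtype=bool)
        self.depletes = np.asarray(self.depletes, dtype=bool)
        if self.delta < 0:
            raise ValueError("delta must be nonnegative")
        n = self.r0.shape[0]
        m = self.rho_net.shape[1]
        if self.rho_net.shape != (n, m) or self.produces.shape != (m, n) \
                or self.depletes.shape != (m, n):
            raise ValueError("inconsistent matrix shapes")

    @property
    def n_species(self) -> int:
        return self.r0.shape[0]

    @property
    def n_mediators(self) -> int:
        return self.rho_net.shape[1]

    @classmethod
    def from_community(cls, params: CommunityParameters,
                       delta: float = 0.0) -> "ChemostatProblem":
        return cls(r0=params.r0.copy(), rho_net=params.rho.copy(),
                   produces=params.beta > 0,
                   depletes=(params.alpha > 0) & params.depletable,
                   delta=delta)


def theta_for_subset(problem: ChemostatProblem, subset) -> np.ndarray:
    """Saturation indicators implied by a species subset.

    theta_l = 1 iff mediator l has a producer in the subset and no subset
    member consumes/degrades it; otherwise it stays near zero concentration
    and exerts no influence.
    """
    idx = np.asarray(sorted(subset), dtype=int)
    produced = problem.produces[:, idx].any(axis=1)
    depleted = problem.depletes[:, idx].any(axis=1)
    return (produced & ~depleted).astype(float)


def effective_growth_matrix(problem: ChemostatProblem, subset,
                            theta: np.ndarray | None = None,
                            ) -> tuple[np.ndarray, float]:
    """Effective linear growth matrix of a subset and its leading eigenvalue.

    Row i, column j (both within the subset): r0_i on the diagonal plus,
    for every mediator l with theta_l = 1 that j produces, the net
    influence strength rho_net[i, l].  With no interactions the matrix is
    diagonal and the leading eigenvalue is max r0 over the subset.
    """
    idx = np.asarray(sorted(subset), dtype=int)
    if idx.size == 0:
        raise ValueError("subset must be nonempty")
    if theta is None:
        theta = theta_for_subset(problem, idx)
    theta = np.asarray(theta, dtype=float).reshape(-1)
    # influence of mediator l on i, routed to each producing member j
    prod = problem.produces[:, idx].astype(float)          # (M, k)
    contrib = (problem.rho_net[idx, :] * theta[None, :]) @ prod  # (k, k)
    matrix = np.diag(problem.r0[idx]) + contrib
    eigvals = np.linalg.eigvals(matrix)
    leading = float(np.max(eigvals.real))
    return matrix, leading


def _leading_pair(matrix: np.ndarray) -> tuple[float, np.ndarray]:
    vals, vecs = np.linalg.eig(matrix)
    k = int(np.argmax(vals.real))
    v = vecs[:, k].real
    if v.sum() < 0:
        v = -v
    return float(vals[k].real), v


def fastest_consistent_subcommunity(problem: ChemostatProblem,
                                    max_n: int = 12,
                                    tol: float = 1e-9):
    """Brute-force search for the coexisting steady-state sub-community.

    Enumerates all nonempty species subsets (N <= max_n), derives each
    subset's theta assignment, and keeps the subset whose effective growth
    matrix has the largest leading eigenvalue *and* a strictly positive
    leading eigenvector (every member present at steady state).  Ties in
    eigenvalue go to the larger subset.  If no multi-member subset is
    consistent the best single species is returned.

    Returns ``(subset, theta, eigenvalue)``.
    """
    n = problem.n_species
    if n > max_n:
        raise ValueError(f"N = {n} exceeds brute-force cap max_n = {max_n}")
    best: tuple[tuple[int, ...], np.ndarray, float] | None = None
    for k in range(1, n + 1):
        for subset in combinations(range(n), k):
            theta = theta_for_subset(problem, subset)
            matrix, _ = effective_growth_matrix(problem, subset, theta)
            eigval, vec = _leading_pair(matrix)
            if np.any(vec <= tol * max(1.0, np.abs(vec).max())):
                continue  # some member absent at steady state
            if (best is None or eigval > best[2] + tol
                    or (abs(eigval - best[2]) <= tol and k > len(best[0]))):
                best = (subset, theta, eigval)
    if best is None:  # unreachable: singletons are always consistent
        i = int(np.argmax(problem.r0))
        return {i}, theta_for_subset(problem, [i]), float(problem.r0[i])
    subset, theta, eigval = best
    return set(subset), theta, eigval
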