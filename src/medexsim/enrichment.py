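"""Serial grow–dilute enrichment with extinction and the coexistence filter.

The protocol emulates a standard enrichment experiment: all pool species are
inoculated at equal proportions (total density ``sum_S_init``), grown under
the mediator-explicit dynamics until the total density reaches the dilution
trigger ``sum_S_dil``, then diluted back to ``sum_S_init`` into fresh medium
(mediators are co-diluted by the same factor).  One round spans
log2(sum_S_dil / sum_S_init) ≈ 20 generations; ten rounds ≈ 200 generations.

Species whose density drops below the extinction threshold ``sum_S_ext``
(one cell in the inoculum volume) — during growth or at transfer — are
removed for the rest of the simulation.  After the final round, species
whose post-dilution density fell by more than 10% over the last round
(≈ the final 20 generations) are additionally removed as slow decliners;
the remaining set is the *derived community*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import CommunityParameters, CommunityState, grow_until

__all__ = [
    "EnrichmentConfig",
    "EnrichmentResult",
    "CommunityCollapse",
    "dilute",
    "run_enrichment",
    "coexistence_filter",
    "stability_check",
]


class CommunityCollapse(RuntimeError):
    """Raised when every species in a culture has gone extinct."""


@dataclass
class EnrichmentConfig:
    """Protocol constants for one enrichment experiment.

    Defaults follow the reference parameter set: dilute from 1e10 back to
    1e4 cells/ml for 10 rounds, extinction below 0.1 cells/ml, Euler step
    0.01 h.  ``t_max_per_round`` caps a round that never reaches the
    dilution trigger (the community is then scored as stalled).
    """

    sum_S_init: float = 1.0e4
    sum_S_dil: float = 1.0e10
    sum_S_ext: float = 0.1
    n_rounds: int = 10
    decline_threshold: float = 0.10
    t_max_per_round: float = 1.0e4
    dt: float = 0.01

    def __post_init__(self) -> None:
        if not (self.sum_S_ext < self.sum_S_init < self.sum_S_dil):
            raise ValueError("need sum_S_ext < sum_S_init < sum_S_dil")
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be at least 1")

    @property
    def generations_per_round(self) -> float:
        return float(np.log2(self.sum_S_dil / self.sum_S_init))

    @classmethod
    def from_dict(cls, mapping) -> "EnrichmentConfig":
        return cls(**dict(mapping))


@dataclass
class EnrichmentResult:
    """Outcome of one enrichment run (before the coexistence filter).

    ``round_snapshots`` holds the post-dilution (S, C) arrays of each
    completed round; ``extinctions`` records (species, round) events, with
    round numbers starting at 1.
    """

    survivors: set[int]
    generations_elapsed: float
    round_snapshots: list[tuple[np.ndarray, np.ndarray]]
    extinctions: list[tuple[int, int]] = field(default_factory=list)
    stalled: bool = False

    @property
    def n_rounds_completed(self) -> int:
        return len(self.round_snapshots)


def dilute(state: CommunityState, config: EnrichmentConfig) -> CommunityState:
    """Dilute a grown culture back to the initial density.

    All densities and mediator concentrations are scaled by the same factor
    (transfer into fresh medium); species landing below the extinction
    density are zeroed.
    """
    total = state.total_density
    if total <= 0:
        raise CommunityCollapse("cannot dilute a collapsed community")
    factor = config.sum_S_init / total
    S = state.S * factor
    S[S < config.sum_S_ext] = 0.0
    return CommunityState(S, state.C * factor, state.t)


def run_enrichment(params: CommunityParameters, config: EnrichmentConfig,
                   seed: int | None = None,
                   S0: np.ndarray | None = None,
                   C0: np.ndarray | None = None) -> EnrichmentResult:
    """Run the full grow–dilute protocol from equal initial proportions.

    The dynamics are deterministic; ``seed`` is accepted for interface
    symmetry with the screens and is unused.  ``S0``/``C0`` override the
    default equal-proportion, mediator-free inoculum (e.g. to continue an
    assembled community from its steady post-dilution state, or for
    perturbation-recovery probes).  Returns the survivors before the
    slow-decline filter (apply :func:`coexistence_filter` afterwards).
    """
    del seed
    n = params.n_species
    if S0 is None:
        S0 = np.full(n, config.sum_S_init / n)
    if C0 is None:
        C0 = np.zeros(params.n_mediators)
    state = CommunityState(np.asarray(S0, dtype=float),
                           np.asarray(C0, dtype=float))
    alive = state.S > 0
    snapshots: list[tuple[np.ndarray, np.ndarray]] = []
    extinctions: list[tuple[int, int]] = []
    generations = 0.0
    stalled = False
    for rnd in range(1, config.n_rounds + 1):
        state, reached = grow_until(
            params, state, config.sum_S_dil, config.t_max_per_round,
            dt=config.dt, extinction_threshold=config.sum_S_ext)
        if not reached:
            stalled = True
            newly_dead = alive & (state.S <= 0)
            extinctions.extend((int(i), rnd) for i in np.nonzero(newly_dead)[0])
            break
        pre_dilution_total = state.total_density
        generations += float(np.log2(pre_dilution_total / config.sum_S_init))
        state = dilute(state, config)
        newly_dead = alive & (state.S <= 0)
        extinctions.extend((int(i), rnd) for i in np.nonzero(newly_dead)[0])
        alive = state.S > 0
        snapshots.append((state.S.copy(), state.C.copy()))
    survivors = set(int(i) for i in np.nonzero(state.S > 0)[0])
    return EnrichmentResult(survivors=survivors,
                            generations_elapsed=generations,
                            round_snapshots=snapshots,
                            extinctions=extinctions,
                            stalled=stalled)


def coexistence_filter(result: EnrichmentResult,
                       decline_threshold: float = 0.10) -> set[int]:
    """Remove slow decliners from the survivor set.

    A surviving species is dropped when its post-dilution density at the
    final round is more than ``decline_threshold`` below its post-dilution
    density one round earlier (a window of ≈ 20 generations).  A decline of
    exactly the threshold is retained (strict comparison).  The returned set
    is the derived community.
    """
    if result.stalled:
        raise ValueError("coexistence is undefined for a stalled enrichment")
    if len(result.round_snapshots) < 2:
        return set(result.survivors)
    S_last, _ = result.round_snapshots[-1]
    S_prev, _ = result.round_snapshots[-2]
    derived = set()
    for i in result.survivors:
        if S_prev[i] <= 0:
            continue
        # removal requires a drop strictly greater than the threshold
        if not (S_prev[i] - S_last[i]) > decline_threshold * S_prev[i]:
            derived.add(i)
    return derived


def stability_check(params: CommunityParameters, derived: set[int],
                    config: EnrichmentConfig) -> bool:
    """Re-simulate the derived community alone and test self-consistency.

    The derived species restart at equal proportions (all mediators reset)
    and run through the full protocol again; the community is stable iff the
    filtered survivor set equals ``derived``.
    """
    if not derived:
        raise ValueError("derived community must be nonempty")
    members = sorted(derived)
    sub = params.subset(members)
    result = run_enrichment(sub, config)
    if result.stalled:
        return False
    final = coexistence_filter(result, config.decline_threshold)
    return {members[j] for j in final} == set(derived)
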