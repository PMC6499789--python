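"""Shared fixtures: hand-built communities and small protocol configs."""

import numpy as np
import pytest

from medexsim.enrichment import EnrichmentConfig
from medexsim.model_core import CommunityParameters


def build_community(n, m, r0, influences=(), productions=(), depletable=(),
                    **kwargs):
    """Construct a community from link lists.

    ``influences``: (species, mediator, rho) triples;
    ``productions``: (mediator, species, beta) triples;
    ``depletable``: (mediator, species) pairs consuming at alpha = 1 fmol.
    """
    rho = np.zeros((n, m))
    K = np.full((n, m), 1.0e4)
    beta = np.zeros((m, n))
    alpha = np.zeros((m, n))
    dep = np.zeros((m, n), dtype=bool)
    for i, l, v in influences:
        rho[i, l] = v
    for l, i, v in productions:
        beta[l, i] = v
    for l, i in depletable:
        dep[l, i] = True
        alpha[l, i] = 1.0
    return CommunityParameters(r0=np.asarray(r0, dtype=float), rho=rho, K=K,
                               alpha=alpha, beta=beta, depletable=dep, **kwargs)


def mutualist_pair(r0=(0.12, 0.08), rho_plus=0.2, depletable=True):
    """Obligate cross-facilitation pair: each produces the other's booster."""
    dep = [(0, 1), (1, 0)] if depletable else []
    return build_community(
        2, 2, r0,
        influences=[(1, 0, rho_plus), (0, 1, rho_plus)],
        productions=[(0, 0, 0.1), (1, 1, 0.1)],
        depletable=dep)


@pytest.fixture
def pair_depletable():
    return mutualist_pair(depletable=True)


@pytest.fixture
def pair_reusable():
    return mutualist_pair(depletable=False)


@pytest.fixture
def default_config():
    return EnrichmentConfig()


@pytest.fixture
def quick_config():
    """Shorter protocol (1e4 -> 1e8, 5 rounds) for cheap dynamical tests."""
    return EnrichmentConfig(sum_S_dil=1.0e8, n_rounds=5)
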