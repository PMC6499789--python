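"""Random species-pool generation and network perturbations.

Initial pools are *binomial* bipartite networks: each possible production
(c-) link from a species to a mediator is present independently with
probability ``q_p``, and each possible influence (f-) link from a mediator to
a species with probability ``q_c`` (Erdős–Rényi connectivity on both layers).
Link parameters follow the uniform distributions of the reference parameter
set: basal rates r0 ~ U(0.08, 0.12)/h, influence magnitudes |rho| ~
U(0, rho_max), saturation constants K ~ U(0.5, 1.5)·K_sat, production rates
beta ~ U(0.5, 1.5)·beta_mean and consumption factors alpha ~
U(0.5, 1.5)·alpha_mean on depletable links.

Influence signs are facilitative with probability ``fac_fraction`` and a
link is depletable (its recipient consumes the mediator) with probability
``depletable_fraction``; consumption is tied to influence links, so a
species only consumes mediators that affect its growth.

All randomness for one pool is drawn in a fixed order from a single
``numpy`` Generator, for the full N x M parameter matrices, before any mask
is applied.  Pools sampled with the same seed but different mask thresholds
(``fac_fraction``, ``depletable_fraction``, ``rho_max`` ...) therefore share
topology and parameter draws wherever the masks overlap — the matched-seed
coupling the comparison screens rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .model_core import CommunityParameters

__all__ = [
    "PoolSpec",
    "NetworkPerturbation",
    "sample_pool",
    "perturb",
    "knockout_link",
]


@dataclass
class PoolSpec:
    """Stochastic recipe for sampling one initial species pool.

    Defaults follow the reference parameter set (20 species, production and
    influence link probabilities 0.2, rho_max = 0.2/h, K_sat = 1e4 fmol/ml,
    alpha_mean = 1 fmol, beta_mean = 0.1 fmol/h, r0 ~ U(0.08, 0.12)/h).
    ``n_mediators`` defaults to 15, the value used by the enrichment
    screens; the reference table lists 10.
    """

    n_species: int = 20
    n_mediators: int = 15
    q_p: float = 0.2
    q_c: float = 0.2
    fac_fraction: float = 0.5
    depletable_fraction: float = 0.5
    rho_max: float = 0.2
    strength_distribution: str = "uniform"
    alpha_mean: float = 1.0
    beta_mean: float = 0.1
    K_sat: float = 1.0e4
    r0_low: float = 0.08
    r0_high: float = 0.12
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("q_p", "q_c", "fac_fraction", "depletable_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.rho_max <= 0:
            raise ValueError("rho_max must be positive")
        if self.r0_low >= self.r0_high:
            raise ValueError("r0_low must be below r0_high")
        if self.strength_distribution not in ("uniform", "alternative"):
            raise ValueError("strength_distribution must be 'uniform' or 'alternative'")

    def replace(self, **kwargs) -> "PoolSpec":
        fields = asdict(self)
        fields.update(kwargs)
        return PoolSpec(**fields)

    @classmethod
    def from_dict(cls, mapping) -> "PoolSpec":
        return cls(**dict(mapping))

    @classmethod
    def from_yaml(cls, path) -> "PoolSpec":
        import yaml

        if hasattr(path, "read"):
            data = yaml.safe_load(path.read())
        else:
            with open(path) as fh:
                data = yaml.safe_load(fh)
        return cls.from_dict(data)


@dataclass
class NetworkPerturbation:
    """Structured modification of an existing community network.

    ``flip_fraction`` of nonzero influences have their sign negated,
    all influence magnitudes are multiplied by ``scale_factor``, and the
    consumption factors are rescaled so that mean(alpha)/mean(beta) over
    nonzero entries equals ``consumption_to_production_ratio`` (None =
    leave alpha untouched).
    """

    flip_fraction: float = 0.0
    scale_factor: float = 1.0
    consumption_to_production_ratio: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.flip_fraction <= 1.0:
            raise ValueError("flip_fraction must lie in [0, 1]")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")


def sample_pool(spec: PoolSpec, seed: int | None = None) -> CommunityParameters:
    """Sample one random pool; deterministic given the seed.

    The seed argument overrides ``spec.seed`` when given.  Draw order is
    fixed (r0, production, influence, signs, magnitudes, K, depletable,
    alpha) and every matrix is drawn in full before masking, so matched
    seeds give coupled pools across differing mask parameters.
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    n, m = spec.n_species, spec.n_mediators

    r0 = rng.uniform(spec.r0_low, spec.r0_high, n)

    prod_u = rng.random((m, n))
    beta_val = rng.uniform(0.5 * spec.beta_mean, 1.5 * spec.beta_mean, (m, n))
    beta = np.where(prod_u < spec.q_p, beta_val, 0.0)

    inf_u = rng.random((n, m))
    sign_u = rng.random((n, m))
    if spec.strength_distribution == "uniform":
        mag = rng.uniform(0.0, spec.rho_max, (n, m))
    else:
        # weak-biased alternative: square of a uniform keeps the support
        # [0, rho_max] but concentrates mass at small strengths
        mag = spec.rho_max * rng.random((n, m)) ** 2
    influence = inf_u < spec.q_c
    sign = np.where(sign_u < spec.fac_fraction, 1.0, -1.0)
    rho = np.where(influence, sign * mag, 0.0)

    K = rng.uniform(0.5 * spec.K_sat, 1.5 * spec.K_sat, (n, m))

    dep_u = rng.random((n, m))
    depletable = (influence & (dep_u < spec.depletable_fraction)).T  # (M, N)
    alpha_val = rng.uniform(0.5 * spec.alpha_mean, 1.5 * spec.alpha_mean, (m, n))
    alpha = np.where(depletable, alpha_val, 0.0)

    return CommunityParameters(r0=r0, rho=rho, K=K, alpha=alpha, beta=beta,
                               depletable=depletable)


def perturb(params: CommunityParameters, pert: NetworkPerturbation,
            seed: int | None = None) -> CommunityParameters:
    """Apply a sign-flip / strength-scaling perturbation to a network copy.

    The zero pattern (topology) is unchanged: exactly
    ``round(flip_fraction * n_links)`` influences, chosen uniformly without
    replacement, change sign, and all magnitudes scale by ``scale_factor``.
    """
    out = params.copy()
    ii, ll = np.nonzero(out.rho)
    n_links = ii.size
    if n_links and pert.flip_fraction > 0:
        rng = np.random.default_rng(seed)
        n_flip = int(round(pert.flip_fraction * n_links))
        chosen = rng.choice(n_links, size=n_flip, replace=False)
        out.rho[ii[chosen], ll[chosen]] *= -1.0
    out.rho *= pert.scale_factor
    if pert.consumption_to_production_ratio is not None:
        nz_a = out.alpha[out.alpha > 0]
        nz_b = out.beta[out.beta > 0]
        if nz_a.size and nz_b.size:
            current = nz_a.mean() / nz_b.mean()
            out.alpha *= pert.consumption_to_production_ratio / current
    return out


def knockout_link(params: CommunityParameters, species: int, mediator: int,
                  remove_consumption: bool = False) -> CommunityParameters:
    """Remove one influence (f-) link, returning a copy.

    Only the growth-rate influence is deleted: the recipient keeps
    consuming/degrading the mediator (losing the receptor does not stop the
    metabolism).  Pass ``remove_consumption=True`` to also delete the tied
    consumption link.  Raises ``ValueError`` if no influence exists at
    (species, mediator).
    """
    if params.rho[species, mediator] == 0:
        raise ValueError(
            f"no influence link from mediator {mediator} to species {species}")
    out = params.copy()
    out.rho[species, mediator] = 0.0
    if remove_consumption:
        out.alpha[mediator, species] = 0.0
        out.depletable[mediator, species] = False
    return out
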