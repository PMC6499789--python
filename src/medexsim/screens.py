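"""Ensemble screens over random pools: richness, categories, knockouts.

Every screen samples many independent initial pools, runs each through the
grow–dilute enrichment protocol plus the slow-decline coexistence filter,
and aggregates statistics over the resulting derived communities:

* richness distributions and mean excess richness (MER) with bootstrap
  confidence intervals;
* how the four influence categories (self-facilitation, other-facilitation,
  self-restraint, other-inhibition) shift from initial pool to derived
  community;
* in-silico knockout experiments, removing single influence links either
  from the initial pool (effect on enrichment richness) or from the derived
  community (effect on stability);
* depletable-versus-reusable mediator comparisons and influence-strength
  sweeps on matched-seed pool ensembles.

Pool ``k`` of a screen seeded with ``seed`` always uses pool seed
``seed + k``, so two screens differing only in a swept parameter simulate
coupled pools (variance reduction; identical topology wherever the swept
masks overlap).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import EnrichmentConfig, coexistence_filter, run_enrichment
from .model_core import CommunityParameters
from .network_gen import PoolSpec, knockout_link, sample_pool

__all__ = [
    "InfluenceRecord",
    "ScreenSummary",
    "classify_influences",
    "active_influences",
    "mer",
    "derived_ensemble",
    "richness_screen",
    "category_enrichment",
    "fig_category_summary",
    "knockout_screen",
    "knockout_tallies",
    "mechanism_screen",
    "strength_sweep",
    "perturbation_recovery",
]

CATEGORIES = ("self-facilitation", "other-facilitation",
              "self-restraint", "other-inhibition")


@dataclass(frozen=True)
class InfluenceRecord:
    """One influence (f-) link, classified.

    ``locus`` is "self" iff the recipient species also produces the
    mediator (beta > 0), otherwise "other".
    """

    species: int
    mediator: int
    sign: str            # "facilitation" | "inhibition"
    locus: str           # "self" | "other"
    strength: float      # |rho|, 1/h
    depletable: bool

    @property
    def category(self) -> str:
        if self.sign == "facilitation":
            return "self-facilitation" if self.locus == "self" else "other-facilitation"
        return "self-restraint" if self.locus == "self" else "other-inhibition"


@dataclass
class ScreenSummary:
    """Aggregate statistics of one richness screen."""

    richness_counts: list[int]
    richness_pmf: dict[int, float]
    richness_sd: dict[int, float]
    mer: float
    mer_ci: tuple[float, float]
    category_fractions_initial: dict[str, float]
    category_fractions_derived: dict[str, float]
    n_pools: int


# ---------------------------------------------------------------------------
# influence classification
# ---------------------------------------------------------------------------

def classify_influences(params: CommunityParameters) -> list[InfluenceRecord]:
    """One record per nonzero influence entry of the network."""
    records = []
    ii, ll = np.nonzero(params.rho)
    for i, l in zip(ii, ll):
        rho = params.rho[i, l]
        records.append(InfluenceRecord(
            species=int(i), mediator=int(l),
            sign="facilitation" if rho > 0 else "inhibition",
            locus="self" if params.beta[l, i] > 0 else "other",
            strength=abs(float(rho)),
            depletable=bool(params.depletable[l, i])))
    return records


def active_influences(params: CommunityParameters,
                      derived: set[int]) -> list[InfluenceRecord]:
    """Influences dynamically relevant in a derived community.

    A link survives enrichment when its recipient is in the derived set and
    at least one producer of the mediator is too (otherwise the mediator is
    never made and the link is inert).
    """
    members = np.array(sorted(derived), dtype=int)
    if members.size == 0:
        return []
    has_producer = params.beta[:, members].sum(axis=1) > 0  # per mediator
    return [rec for rec in classify_influences(params)
            if rec.species in derived and has_producer[rec.mediator]]


def _category_fractions(records: list[InfluenceRecord]) -> dict[str, float]:
    total = len(records)
    counts = {cat: 0 for cat in CATEGORIES}
    for rec in records:
        counts[rec.category] += 1
    if total == 0:
        return {cat: float("nan") for cat in CATEGORIES}
    return {cat: counts[cat] / total for cat in CATEGORIES}


# ---------------------------------------------------------------------------
# mean excess richness
# ---------------------------------------------------------------------------

def mer(richness_counts, n_boot: int = 3000,
        seed: int | None = 0) -> tuple[float, tuple[float, float]]:
    """Mean excess richness with a nonparametric bootstrap 95% CI.

    MER = sum_i (i - 1) p_i over the empirical richness distribution:
    the mean number of coexisting species beyond the single survivor that
    competitive exclusion predicts.  The CI comes from 3000 resamples with
    replacement (percentile method).
    """
    values = np.asarray(list(richness_counts), dtype=float)
    if values.size == 0:
        raise ValueError("richness_counts must be nonempty")
    excess = np.maximum(values - 1.0, 0.0)
    point = float(excess.mean())
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, excess.size, size=(n_boot, excess.size))
    boot_means = excess[idx].mean(axis=1)
    lo, hi = np.percentile(boot_means, [2.5, 97.5])
    return point, (float(lo), float(hi))


# ---------------------------------------------------------------------------
# core ensemble driver
# ---------------------------------------------------------------------------

def derived_ensemble(spec: PoolSpec, config: EnrichmentConfig, n_pools: int,
                     seed: int, ratios=None, zero_interactions: bool = False):
    """Yield (pool_index, params, derived set, result) over independent pools.

    ``ratios`` optionally cycles the facilitation fraction across pools
    (e.g. the pooled 20:80 / 50:50 / 80:20 ensemble).  Stalled or collapsed
    enrichments yield an empty derived set.
    """
    for k in range(n_pools):
        pool_spec = spec
        if ratios is not None:
            pool_spec = spec.replace(fac_fraction=ratios[k % len(ratios)])
        params = sample_pool(pool_spec, seed=seed + k)
        if zero_interactions:
            params.rho[:] = 0.0
            params.alpha[:] = 0.0
            params.depletable[:] = False
        result = run_enrichment(params, config)
        if result.stalled or not result.survivors:
            derived: set[int] = set()
        else:
            derived = coexistence_filter(result, config.decline_threshold)
        yield k, params, derived, result


def richness_screen(spec: PoolSpec, config: EnrichmentConfig, n_pools: int,
                    seed: int, ratios=None,
                    zero_interactions: bool = False) -> ScreenSummary:
    """Tabulate derived-community richness over an ensemble of pools."""
    richness = []
    init_fracs = []
    derived_fracs = []
    for _, params, derived, _result in derived_ensemble(
            spec, config, n_pools, seed, ratios, zero_interactions):
        richness.append(len(derived))
        if not zero_interactions:
            init_fracs.append(_category_fractions(classify_influences(params)))
            active = active_influences(params, derived)
            if active:
                derived_fracs.append(_category_fractions(active))
    counts = np.bincount(richness)
    pmf = {i: counts[i] / n_pools for i in range(len(counts)) if counts[i]}
    sd = {i: float(np.sqrt(p * (1 - p) / n_pools)) for i, p in pmf.items()}
    point, ci = mer(richness, seed=seed)
    return ScreenSummary(
        richness_counts=richness, richness_pmf=pmf, richness_sd=sd,
        mer=point, mer_ci=ci,
        category_fractions_initial=_mean_fractions(init_fracs),
        category_fractions_derived=_mean_fractions(derived_fracs),
        n_pools=n_pools)


def _mean_fractions(dicts) -> dict[str, float]:
    if not dicts:
        return {cat: float("nan") for cat in CATEGORIES}
    return {cat: float(np.nanmean([d[cat] for d in dicts])) for cat in CATEGORIES}


# ---------------------------------------------------------------------------
# category enrichment (initial pool vs derived community)
# ---------------------------------------------------------------------------

def category_enrichment(spec: PoolSpec, config: EnrichmentConfig,
                        n_pools: int, seed: int,
                        ratios=(0.2, 0.5, 0.8)) -> pd.DataFrame:
    """Per-pool influence-category bookkeeping across an enrichment ensemble.

    Only pools whose derived community keeps at least two species are
    scored.  For each such pool the facilitation fraction and the
    self-restraint fractions (among all influences, and within inhibitory
    influences) are computed for the initial pool and for the influences
    active in the derived community.  "Favored" means the derived fraction
    strictly exceeds the initial one; ties count as unchanged.
    """
    rows = []
    for k, params, derived, _result in derived_ensemble(
            spec, config, n_pools, seed, ratios):
        if len(derived) < 2:
            continue
        initial = classify_influences(params)
        active = active_influences(params, derived)
        row = _category_row(initial, active)
        row["pool"] = k
        row["fac_fraction"] = (ratios[k % len(ratios)]
                               if ratios is not None else spec.fac_fraction)
        row["richness"] = len(derived)
        rows.append(row)
    return pd.DataFrame(rows)


def _frac(records, pred) -> float:
    if not records:
        return float("nan")
    return sum(1 for r in records if pred(r)) / len(records)


def _category_row(initial: list[InfluenceRecord],
                  active: list[InfluenceRecord]) -> dict:
    init_inh = [r for r in initial if r.sign == "inhibition"]
    act_inh = [r for r in active if r.sign == "inhibition"]
    is_fac = lambda r: r.sign == "facilitation"
    is_sr = lambda r: r.category == "self-restraint"
    row = {
        "n_initial": len(initial),
        "n_active": len(active),
        "initial_fac_frac": _frac(initial, is_fac),
        "derived_fac_frac": _frac(active, is_fac),
        "initial_sr_frac": _frac(initial, is_sr),
        "derived_sr_frac": _frac(active, is_sr),
        "initial_sr_of_inh": _frac(init_inh, is_sr),
        "derived_sr_of_inh": _frac(act_inh, is_sr),
        "derived_only_fac": bool(active) and not act_inh,
        "derived_has_inh": bool(act_inh),
        "derived_only_sr_inh": bool(act_inh) and all(is_sr(r) for r in act_inh),
    }
    row["fac_favored"] = (np.isfinite(row["derived_fac_frac"])
                          and row["derived_fac_frac"] > row["initial_fac_frac"])
    row["sr_favored"] = (np.isfinite(row["derived_sr_frac"])
                         and row["derived_sr_frac"] > row["initial_sr_frac"])
    return row


def fig_category_summary(df: pd.DataFrame) -> dict[str, float]:
    """Headline percentages of a category-enrichment screen.

    Keys (all in %): ``only_facilitation`` — derived communities whose
    active influences are all facilitative; ``only_self_restraint`` — of
    communities retaining inhibition, those where every inhibitory influence
    is self-restraint; ``fac_favored`` — pools where the facilitation
    fraction rose; ``sr_favored_when_fac_not`` — of the remainder, pools
    where the self-restraint fraction rose.
    """
    if df.empty:
        raise ValueError("no qualifying pools in the screen")
    n = len(df)
    with_inh = df[df["derived_has_inh"]]
    fac_not = df[~df["fac_favored"]]
    return {
        "n_pools_scored": float(n),
        "n_with_inhibition": float(len(with_inh)),
        "only_facilitation": 100.0 * df["derived_only_fac"].mean(),
        "only_self_restraint": (100.0 * with_inh["derived_only_sr_inh"].mean()
                                if len(with_inh) else float("nan")),
        "fac_favored": 100.0 * df["fac_favored"].mean(),
        "sr_favored_when_fac_not": (100.0 * fac_not["sr_favored"].mean()
                                    if len(fac_not) else float("nan")),
    }


# ---------------------------------------------------------------------------
# knockout screens
# ---------------------------------------------------------------------------

def _persists(sub: CommunityParameters, config: EnrichmentConfig,
              S0: np.ndarray, C0: np.ndarray) -> bool:
    """Continue a community from a given state; True iff everyone persists.

    Runs a further ``n_rounds`` of grow–dilute (≈ 200 generations) from the
    supplied post-dilution state and checks that every species survives and
    passes the slow-decline filter.
    """
    result = run_enrichment(sub, config, S0=S0, C0=C0)
    if result.stalled:
        return False
    final = coexistence_filter(result, config.decline_threshold)
    return final == set(range(sub.n_species))


def knockout_screen(ensemble, config: EnrichmentConfig,
                    mode: str = "from_derived",
                    max_links: int | None = None) -> pd.DataFrame:
    """Single-link knockout experiments over derived communities.

    ``ensemble`` is an iterable of ``(pool_index, params, derived, result)``
    as produced by :func:`derived_ensemble`; only derived communities with
    at least two species are used.

    mode "from_derived": the community continues from its final
    post-dilution state for a further ``n_rounds``; baselines that do not
    maintain themselves unperturbed are skipped, and for each active
    influence ``disrupted`` records whether deleting it makes the
    continuation lose a member.  mode "from_pool": the influence is deleted
    from the initial pool, the whole enrichment re-run from scratch, and
    ``delta_richness`` records the change in derived richness.
    """
    if mode not in ("from_derived", "from_pool"):
        raise ValueError("mode must be 'from_derived' or 'from_pool'")
    rows = []
    for k, params, derived, result in ensemble:
        if len(derived) < 2:
            continue
        members = sorted(derived)
        sub = params.subset(members)
        active = active_influences(params, derived)
        if not active:
            continue
        if mode == "from_derived":
            S_last, C_last = result.round_snapshots[-1]
            S0 = S_last[members]
            S0 = S0 * (config.sum_S_init / S0.sum())
            if not _persists(sub, config, S0, C_last):
                continue
            local = {sp: j for j, sp in enumerate(members)}
            for rec in active:
                ko = knockout_link(sub, local[rec.species], rec.mediator)
                rows.append({
                    "pool": k, "species": rec.species, "mediator": rec.mediator,
                    "category": rec.category, "mode": mode,
                    "richness": len(members),
                    "disrupted": not _persists(ko, config, S0, C_last),
                })
                if max_links is not None and len(rows) >= max_links:
                    return pd.DataFrame(rows)
        else:
            base_richness = len(derived)
            for rec in active:
                ko = knockout_link(params, rec.species, rec.mediator)
                res = run_enrichment(ko, config)
                if res.stalled:
                    new_rich = 0
                else:
                    new_rich = len(coexistence_filter(res,
                                                      config.decline_threshold))
                rows.append({
                    "pool": k, "species": rec.species, "mediator": rec.mediator,
                    "category": rec.category, "mode": mode,
                    "richness": base_richness,
                    "delta_richness": new_rich - base_richness,
                })
                if max_links is not None and len(rows) >= max_links:
                    return pd.DataFrame(rows)
    return pd.DataFrame(rows)


def knockout_tallies(df: pd.DataFrame) -> pd.DataFrame:
    """Per-category outcome rates of a knockout screen.

    For "from_derived" rows: fraction of knockouts that disrupted the
    community.  For "from_pool" rows: fractions with a richness drop,
    no change, or gain.
    """
    if df.empty:
        raise ValueError("empty knockout screen")
    out = []
    for cat, grp in df.groupby("category"):
        row = {"category": cat, "n_links": len(grp)}
        if "disrupted" in grp and grp["disrupted"].notna().any():
            row["disruption_rate"] = float(grp["disrupted"].mean())
        if "delta_richness" in grp and grp["delta_richness"].notna().any():
            d = grp["delta_richness"]
            row["frac_drop"] = float((d < 0).mean())
            row["frac_unchanged"] = float((d == 0).mean())
            row["frac_gain"] = float((d > 0).mean())
        out.append(row)
    return pd.DataFrame(out).set_index("category")


# ---------------------------------------------------------------------------
# mechanism and strength sweeps
# ---------------------------------------------------------------------------

def mechanism_screen(spec: PoolSpec, config: EnrichmentConfig,
                     depletable_fractions, n_pools: int,
                     seed: int) -> dict[float, ScreenSummary]:
    """Richness screens at several depletable-mediator fractions.

    Seeds are matched across fractions, so pool ``k`` shares its topology,
    signs, strengths and basal rates at every fraction and differs only in
    which influence links carry consumption.
    """
    return {float(f): richness_screen(spec.replace(depletable_fraction=float(f)),
                                      config, n_pools, seed)
            for f in depletable_fractions}


def strength_sweep(spec: PoolSpec, config: EnrichmentConfig,
                   strength_ratios, n_pools: int,
                   seed: int) -> dict[float, ScreenSummary]:
    """Richness screens at several mean-influence-strength ratios.

    The ratio is mean influence strength over the s.d. of basal growth
    rates; with |rho| ~ U(0, rho_max) the mean is rho_max / 2, so
    rho_max = 2 * ratio * sigma_r0.  Seeds are matched across ratios.
    """
    sigma = (spec.r0_high - spec.r0_low) / np.sqrt(12.0)
    out = {}
    for ratio in strength_ratios:
        rho_max = 2.0 * float(ratio) * sigma
        out[float(ratio)] = richness_screen(
            spec.replace(rho_max=rho_max), config, n_pools, seed)
    return out


# ---------------------------------------------------------------------------
# perturbation recovery (asymptotic stability probe)
# ---------------------------------------------------------------------------

def perturbation_recovery(params: CommunityParameters, derived: set[int],
                          kick: float, config: EnrichmentConfig,
                          tol: float = 0.02) -> bool:
    """Displace post-dilution frequencies and test return to steady state.

    The derived community is first run to its steady post-dilution pattern;
    the first member's frequency is then multiplied by ``1 + kick`` (and the
    vector renormalised to the initial density) and the protocol re-run.
    Returns True iff the survivor set is unchanged and every frequency
    returns within ``tol`` (absolute) of the unperturbed pattern.
    """
    if len(derived) < 2:
        raise ValueError("perturbation recovery needs at least two species")
    sub = params.subset(sorted(derived))
    baseline = run_enrichment(sub, config)
    if baseline.stalled:
        return False
    S_ref, _ = baseline.round_snapshots[-1]
    f_ref = S_ref / S_ref.sum()
    S_kicked = S_ref.copy()
    S_kicked[0] *= (1.0 + kick)
    S_kicked *= config.sum_S_init / S_kicked.sum()
    perturbed = run_enrichment(sub, config, S0=S_kicked)
    if perturbed.stalled:
        return False
    S_end, _ = perturbed.round_snapshots[-1]
    f_end = S_end / S_end.sum() if S_end.sum() > 0 else S_end
    if set(np.nonzero(S_end > 0)[0]) != set(np.nonzero(S_ref > 0)[0]):
        return False
    return bool(np.max(np.abs(f_end - f_ref)) <= tol)
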