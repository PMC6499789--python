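"""Mediator-explicit community dynamics.

A community of ``N`` microbial species interacts only through ``M`` chemical
mediators (metabolites, toxins, signals).  Shared external resources are
assumed to be in excess, so each species grows exponentially at a per-capita
rate set by its basal net growth rate plus the (additive) influences of the
mediator concentrations:

    dS_i/dt = [ r0_i + sum_l fac(C_l; rho+_il, K_il)
                      - sum_l inh(C_l; rho-_il, K_il) ] * S_i
    dC_l/dt = sum_i beta_li S_i - sum_i alpha_li C_l/(C_l + K_il) S_i
              - decay_l C_l

Facilitation follows a saturating Monod (or Moser) form; inhibition defaults
to a linear dose response with optional threshold and "growth inhibition"
variants.  Mediators consumed or degraded by their recipients are called
*depletable* (``alpha > 0``); *reusable* mediators influence growth without
being removed (``alpha = 0``).

Integration is explicit forward Euler at a fixed timestep (default 0.01 h).
The long grow-to-dilution phases are executed by a numba-compiled kernel that
iterates over sparse link lists; :func:`step` provides the plain-numpy
reference update, and the two paths are interchangeable.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "CommunityParameters",
    "CommunityState",
    "INHIBITION_LAWS",
    "FACILITATION_LAWS",
    "per_capita_growth_rates",
    "mediator_fluxes",
    "step",
    "grow_until",
    "simulate_trajectory",
    "write_network_csv",
    "read_network_csv",
    "write_trajectory_csv",
]

#: Default Euler timestep, hours ("cell growth update and uptake timescale").
DEFAULT_DT = 0.01

INHIBITION_LAWS = {"linear": 0, "threshold": 1, "growth_inhibition": 2}
FACILITATION_LAWS = {"monod": 0, "moser": 1}
CONSUMPTION_KINETICS = {"growth_coupled": 0, "monod": 1}


# ---------------------------------------------------------------------------
# parameter and state containers
# ---------------------------------------------------------------------------

@dataclass
class CommunityParameters:
    """All rates and matrices defining one community's dynamics.

    Parameters
    ----------
    r0 : (N,) array
        Basal net per-capita growth rate of each species, 1/h.
    rho : (N, M) array
        Signed influence strengths, 1/h.  ``rho[i, l] > 0`` means mediator
        ``l`` facilitates species ``i``; negative entries are inhibitory;
        zero means no influence link.
    K : (N, M) array
        Saturation / normalisation concentration of each influence,
        fmol/ml.  Must be positive wherever ``rho`` is nonzero.
    alpha : (M, N) array
        Maximum per-cell consumption factor of mediator ``l`` by species
        ``i``, fmol.  Zero for reusable links.
    beta : (M, N) array
        Per-cell production rate of mediator ``l`` by species ``i``,
        fmol/h.  Nonzero entries are production (c-) links.
    depletable : (M, N) bool array
        True where the influenced species consumes/degrades the mediator.
        ``alpha > 0`` implies the flag is set.
    inhibition_law : {"linear", "threshold", "growth_inhibition"}
    facilitation_law : {"monod", "moser"}
    moser_n : float
        Moser exponent; ``n = 1`` reduces to Monod.
    c_th : float
        Threshold concentration for the threshold / growth-inhibition laws,
        fmol/ml.
    decay : (M,) array, optional
        Abiotic mediator decay rate, 1/h.  Defaults to zero.
    consumption : {"growth_coupled", "monod"}
        Kinetics of mediator removal on depletable links.  The default
        treats ``alpha`` as a per-new-cell consumption factor (fmol/cell):
        removal is ``alpha * max(r_i, 0) * C/(C+K) * S_i``, i.e. cells
        consume as they grow, which matches the stated unit of the
        consumption factor.  "monod" instead reads ``alpha`` as a fixed
        maximum uptake rate (fmol/cell/h): removal is
        ``alpha * C/(C+K) * S_i`` independent of the growth rate.
    """

    r0: np.ndarray
    rho: np.ndarray
    K: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    depletable: np.ndarray
    inhibition_law: str = "linear"
    facilitation_law: str = "monod"
    moser_n: float = 1.0
    c_th: float = 0.0
    decay: np.ndarray | None = None
    consumption: str = "growth_coupled"

    def __post_init__(self) -> None:
        self.r0 = np.asarray(self.r0, dtype=float).reshape(-1)
        self.rho = np.asarray(self.rho, dtype=float)
        self.K = np.asarray(self.K, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.depletable = np.asarray(self.depletable, dtype=bool)
        n, m = self.n_species, self.n_mediators
        if self.rho.shape != (n, m):
            raise ValueError(f"rho must be (N, M) = ({n}, {m}), got {self.rho.shape}")
        if self.K.shape != (n, m):
            raise ValueError(f"K must be (N, M) = ({n}, {m}), got {self.K.shape}")
        for name, arr in (("alpha", self.alpha), ("beta", self.beta),
                          ("depletable", self.depletable)):
            if arr.shape != (m, n):
                raise ValueError(f"{name} must be (M, N) = ({m}, {n}), got {arr.shape}")
        if self.decay is None:
            self.decay = np.zeros(m)
        else:
            self.decay = np.asarray(self.decay, dtype=float).reshape(-1)
            if self.decay.shape != (m,):
                raise ValueError("decay must have length M")
        if not np.all(np.isfinite(self.r0)):
            raise ValueError("r0 must be finite")
        if np.any(self.K[self.rho != 0] <= 0):
            raise ValueError("K must be strictly positive wherever rho is nonzero")
        if np.any(self.alpha < 0) or np.any(self.beta < 0):
            raise ValueError("alpha and beta must be nonnegative")
        if np.any((self.alpha > 0) & ~self.depletable):
            raise ValueError("alpha > 0 requires the depletable flag")
        if self.inhibition_law not in INHIBITION_LAWS:
            raise ValueError(f"unknown inhibition law {self.inhibition_law!r}")
        if self.facilitation_law not in FACILITATION_LAWS:
            raise ValueError(f"unknown facilitation law {self.facilitation_law!r}")
        if self.consumption not in CONSUMPTION_KINETICS:
            raise ValueError(f"unknown consumption kinetics {self.consumption!r}")

    @property
    def n_species(self) -> int:
        return self.r0.shape[0]

    @property
    def n_mediators(self) -> int:
        return self.rho.shape[1] if self.rho.ndim == 2 else self.beta.shape[0]

    def copy(self) -> "CommunityParameters":
        return CommunityParameters(
            r0=self.r0.copy(), rho=self.rho.copy(), K=self.K.copy(),
            alpha=self.alpha.copy(), beta=self.beta.copy(),
            depletable=self.depletable.copy(),
            inhibition_law=self.inhibition_law,
            facilitation_law=self.facilitation_law,
            moser_n=self.moser_n, c_th=self.c_th, decay=self.decay.copy(),
            consumption=self.consumption)

    def subset(self, species: np.ndarray | list[int]) -> "CommunityParameters":
        """Restrict the community to the given species (all mediators kept)."""
        idx = np.asarray(sorted(species), dtype=int)
        if idx.size == 0:
            raise ValueError("species subset must be nonempty")
        return CommunityParameters(
            r0=self.r0[idx], rho=self.rho[idx, :], K=self.K[idx, :],
            alpha=self.alpha[:, idx], beta=self.beta[:, idx],
            depletable=self.depletable[:, idx],
            inhibition_law=self.inhibition_law,
            facilitation_law=self.facilitation_law,
            moser_n=self.moser_n, c_th=self.c_th, decay=self.decay.copy(),
            consumption=self.consumption)


@dataclass
class CommunityState:
    """Instantaneous community state: densities, concentrations, clock.

    ``S`` is live cell density (1/ml), ``C`` mediator concentration
    (fmol/ml), ``t`` elapsed time (h).
    """

    S: np.ndarray
    C: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float).reshape(-1)
        self.C = np.asarray(self.C, dtype=float).reshape(-1)
        if np.any(self.S < 0) or np.any(self.C < 0):
            raise ValueError("densities and concentrations must be nonnegative")

    def copy(self) -> "CommunityState":
        return CommunityState(self.S.copy(), self.C.copy(), self.t)

    @property
    def total_density(self) -> float:
        return float(self.S.sum())


# ---------------------------------------------------------------------------
# response laws and instantaneous rates (numpy reference path)
# ---------------------------------------------------------------------------

def _facilitation_term(params: CommunityParameters, C: np.ndarray) -> np.ndarray:
    """Per-species facilitation contribution, summed over mediators."""
    rho_pos = np.where(params.rho > 0, params.rho, 0.0)
    if params.facilitation_law == "monod":
        sat = C / (C + params.K)
    else:  # moser
        n = params.moser_n
        with np.errstate(divide="ignore", invalid="ignore"):
            cn = C[None, :] ** n
            sat = cn / (cn + params.K ** n)
        sat = np.where(np.isfinite(sat), sat, 1.0)
    # saturation factor is only evaluated on links (K > 0 there)
    return (rho_pos * np.where(rho_pos > 0, sat, 0.0)).sum(axis=1)


def _inhibition_term(params: CommunityParameters, C: np.ndarray) -> np.ndarray:
    """Per-species inhibition contribution (positive magnitude)."""
    mag = np.where(params.rho < 0, -params.rho, 0.0)
    law = params.inhibition_law
    with np.errstate(divide="ignore", invalid="ignore"):
        if law == "linear":
            resp = C[None, :] / params.K
        elif law == "threshold":
            resp = np.where(C[None, :] > params.c_th,
                            (C[None, :] - params.c_th) / params.K, 0.0)
        else:  # growth_inhibition
            excess = C[None, :] - params.c_th
            resp = np.where(excess > 0, 1.0 / (1.0 + params.K / excess), 0.0)
    resp = np.where(mag > 0, resp, 0.0)
    return (mag * np.nan_to_num(resp)).sum(axis=1)


def per_capita_growth_rates(params: CommunityParameters, C: np.ndarray) -> np.ndarray:
    """Instantaneous per-capita growth rate of every species, 1/h.

    Influences of different mediators are additive; rates may be negative
    (net death) when inhibition exceeds the basal rate.
    """
    C = np.asarray(C, dtype=float).reshape(-1)
    if C.shape[0] != params.n_mediators:
        raise ValueError("concentration vector length must equal n_mediators")
    if np.any(C < 0):
        raise ValueError("concentrations must be nonnegative")
    return params.r0 + _facilitation_term(params, C) - _inhibition_term(params, C)


def mediator_fluxes(params: CommunityParameters, state: CommunityState) -> np.ndarray:
    """Net production rate dC_l/dt of every mediator, fmol/ml/h.

    Production is proportional to live producer density; consumption acts
    only on depletable links, with Monod saturation in the recipient's own
    constant.  Under the default growth-coupled kinetics the uptake is
    additionally proportional to the recipient's (nonnegative) per-capita
    growth rate: cells consume the mediator as they divide.
    """
    if state.S.shape[0] != params.n_species or state.C.shape[0] != params.n_mediators:
        raise ValueError("state shape does not match parameters")
    production = params.beta @ state.S
    Kt = np.where(params.K.T > 0, params.K.T, 1.0)  # (M, N); alpha=0 off-link
    uptake = state.C[:, None] / (state.C[:, None] + Kt)
    if params.consumption == "growth_coupled":
        rates = np.maximum(per_capita_growth_rates(params, state.C), 0.0)
        consumption = (params.alpha * uptake) @ (rates * state.S)
    else:
        consumption = (params.alpha * uptake) @ state.S
    return production - consumption - params.decay * state.C


def step(params: CommunityParameters, state: CommunityState,
         dt: float = DEFAULT_DT) -> CommunityState:
    """One forward-Euler update of densities and concentrations.

    Densities update multiplicatively, ``S <- S (1 + r dt)``, floored at 0;
    concentrations that would turn negative are clamped to 0 (consumption is
    truncated at the available mass).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rates = per_capita_growth_rates(params, state.C)
    dC = mediator_fluxes(params, state)
    S = state.S * (1.0 + rates * dt)
    np.maximum(S, 0.0, out=S)
    C = state.C + dC * dt
    np.maximum(C, 0.0, out=C)
    if not (np.all(np.isfinite(S)) and np.all(np.isfinite(C))):
        raise FloatingPointError(
            f"non-finite state at t={state.t + dt:.4g} h; "
            "check parameter magnitudes and timestep")
    return CommunityState(S, C, state.t + dt)


# ---------------------------------------------------------------------------
# compiled Euler kernel over sparse link lists
# ---------------------------------------------------------------------------

@njit(cache=True)
def _integrate(S, C, r0, inf_i, inf_l, inf_rho, inf_K,
               prod_l, prod_i, prod_b, cons_l, cons_i, cons_a, cons_K,
               decay, inh_law, fac_law, moser_n, c_th, cons_mode,
               dt, stop_density, ext_threshold, max_time, max_steps):
    """Forward-Euler loop; mutates S and C in place.

    Stops when total density reaches ``stop_density`` (returns reached=True),
    when the community collapses to zero, or at ``max_time``/``max_steps``.
    Returns (elapsed time, reached flag, steps taken).
    """
    n = S.shape[0]
    m = C.shape[0]
    rate = np.empty(n)
    dC = np.empty(m)
    t = 0.0
    steps = 0
    total = 0.0
    for i in range(n):
        total += S[i]
    if total >= stop_density:
        return 0.0, True, 0
    while steps < max_steps and t < max_time - 1e-12:
        for i in range(n):
            rate[i] = r0[i]
        for k in range(inf_i.shape[0]):
            i = inf_i[k]
            if S[i] <= 0.0:
                continue
            c = C[inf_l[k]]
            r = inf_rho[k]
            kk = inf_K[k]
            if r > 0.0:
                if fac_law == 0:
                    rate[i] += r * c / (c + kk)
                else:
                    cn = c ** moser_n
                    rate[i] += r * cn / (cn + kk ** moser_n)
            else:
                mgn = -r
                if inh_law == 0:
                    rate[i] -= mgn * c / kk
                elif inh_law == 1:
                    if c > c_th:
                        rate[i] -= mgn * (c - c_th) / kk
                else:
                    if c > c_th:
                        rate[i] -= mgn / (1.0 + kk / (c - c_th))
        for l in range(m):
            dC[l] = -decay[l] * C[l]
        for k in range(prod_l.shape[0]):
            dC[prod_l[k]] += prod_b[k] * S[prod_i[k]]
        for k in range(cons_l.shape[0]):
            l = cons_l[k]
            c = C[l]
            i = cons_i[k]
            uptake = cons_a[k] * c / (c + cons_K[k]) * S[i]
            if cons_mode == 0:  # growth-coupled: fmol per new cell
                ri = rate[i]
                uptake *= ri if ri > 0.0 else 0.0
            dC[l] -= uptake
        total = 0.0
        for i in range(n):
            s = S[i] * (1.0 + rate[i] * dt)
            if s < ext_threshold or s < 0.0:
                s = 0.0
            S[i] = s
            total += s
        for l in range(m):
            c = C[l] + dC[l] * dt
            if c < 0.0:
                c = 0.0
            C[l] = c
        t += dt
        steps += 1
        if total >= stop_density:
            return t, True, steps
        if total <= 0.0:
            return t, False, steps
    return t, False, steps


def _pack(params: CommunityParameters):
    """Flatten parameters into the sparse link arrays the kernel consumes."""
    cached = params.__dict__.get("_packed")
    if cached is not None:
        return cached
    ii, ll = np.nonzero(params.rho)
    inf_i = ii.astype(np.int64)
    inf_l = ll.astype(np.int64)
    inf_rho = params.rho[ii, ll]
    inf_K = params.K[ii, ll]
    pl, pi = np.nonzero(params.beta)
    cons_mask = params.alpha > 0
    cl, ci = np.nonzero(cons_mask)
    packed = (
        params.r0, inf_i, inf_l, inf_rho, inf_K,
        pl.astype(np.int64), pi.astype(np.int64), params.beta[pl, pi],
        cl.astype(np.int64), ci.astype(np.int64), params.alpha[cl, ci],
        params.K.T[cl, ci],
        params.decay,
        INHIBITION_LAWS[params.inhibition_law],
        FACILITATION_LAWS[params.facilitation_law],
        float(params.moser_n), float(params.c_th),
        CONSUMPTION_KINETICS[params.consumption],
    )
    params.__dict__["_packed"] = packed
    return packed


def grow_until(params: CommunityParameters, state: CommunityState,
               total_density_threshold: float, t_max: float,
               dt: float = DEFAULT_DT, extinction_threshold: float = 0.0,
               ) -> tuple[CommunityState, bool]:
    """Integrate until the summed density reaches a threshold.

    Species whose density falls below ``extinction_threshold`` during growth
    are zeroed (removed).  Returns the final state and whether the threshold
    was reached before ``t_max`` elapsed (False = community stalled).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if total_density_threshold <= state.total_density:
        raise ValueError("threshold must exceed current total density")
    S = state.S.copy()
    C = state.C.copy()
    elapsed, reached, _ = _integrate(
        S, C, *_pack(params), dt, float(total_density_threshold),
        float(extinction_threshold), float(t_max), np.iinfo(np.int64).max)
    if not (np.all(np.isfinite(S)) and np.all(np.isfinite(C))):
        raise FloatingPointError("non-finite state during growth phase")
    return CommunityState(S, C, state.t + elapsed), bool(reached)


def simulate_trajectory(params: CommunityParameters, state: CommunityState,
                        t_end: float, dt: float = DEFAULT_DT,
                        sample_every: int = 100):
    """Integrate for a fixed horizon, recording periodic snapshots.

    Returns a long-format :class:`pandas.DataFrame` with columns
    ``(t, entity_type, entity_id, value)`` covering every species density and
    mediator concentration at each sampled time.
    """
    import pandas as pd

    S = state.S.copy()
    C = state.C.copy()
    packed = _pack(params)
    rows = [(state.t, S.copy(), C.copy())]
    t = state.t
    n_chunks = int(np.ceil(t_end / (dt * sample_every)))
    for _ in range(n_chunks):
        elapsed, _, nsteps = _integrate(
            S, C, *packed, dt, np.inf, 0.0,
            min(t_end - (t - state.t), dt * sample_every) + dt / 2,
            sample_every)
        t += elapsed
        rows.append((t, S.copy(), C.copy()))
        if nsteps == 0:
            break
    records = []
    for t_i, S_i, C_i in rows:
        for i, v in enumerate(S_i):
            records.append((t_i, "species", i, v))
        for l, v in enumerate(C_i):
            records.append((t_i, "mediator", l, v))
    return pd.DataFrame(records, columns=["t", "entity_type", "entity_id", "value"])


# ---------------------------------------------------------------------------
# tabular serialization
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("inhibition_law", "facilitation_law", "moser_n", "c_th",
                "consumption")


def write_network_csv(params: CommunityParameters, path) -> None:
    """Serialize a community network to a link-list CSV.

    Scalar fields and the r0/decay vectors go into ``# key=value`` header
    lines; each subsequent row is one link: production rows carry beta,
    influence rows carry the signed rho plus the link's K, alpha and
    depletable flag.
    """
    lines = ["# medexsim network v1",
             f"# n_species={params.n_species}",
             f"# n_mediators={params.n_mediators}"]
    for key in _HEADER_KEYS:
        lines.append(f"# {key}={getattr(params, key)}")
    lines.append("# r0=" + ",".join(repr(float(v)) for v in params.r0))
    lines.append("# decay=" + ",".join(repr(float(v)) for v in params.decay))
    lines.append("kind,species,mediator,value,k,depletable")
    ml, mi = np.nonzero(params.beta)
    for l, i in zip(ml, mi):
        lines.append(f"production,{i},{l},{float(params.beta[l, i])!r},,")
    ii, ll = np.nonzero(params.rho)
    for i, l in zip(ii, ll):
        dep = bool(params.depletable[l, i])
        lines.append(f"influence,{i},{l},{float(params.rho[i, l])!r},"
                     f"{float(params.K[i, l])!r},{dep}")
        if params.alpha[l, i] > 0:
            lines.append(f"consumption,{i},{l},{float(params.alpha[l, i])!r},"
                         f"{float(params.K[i, l])!r},{dep}")
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


def read_network_csv(path) -> CommunityParameters:
    """Read a community network written by :func:`write_network_csv`."""
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path) as fh:
            text = fh.read()
    header: dict[str, str] = {}
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            stripped = line.lstrip("# ").strip()
            if "=" in stripped:
                key, _, value = stripped.partition("=")
                header[key.strip()] = value.strip()
        elif line.strip():
            body_lines.append(line)
    n = int(header["n_species"])
    m = int(header["n_mediators"])
    r0 = np.array([float(v) for v in header["r0"].split(",")])
    decay = np.array([float(v) for v in header["decay"].split(",")])
    rho = np.zeros((n, m))
    K = np.ones((n, m))
    alpha = np.zeros((m, n))
    beta = np.zeros((m, n))
    depletable = np.zeros((m, n), dtype=bool)
    import csv

    for row in csv.DictReader(io.StringIO("\n".join(body_lines))):
        i = int(row["species"])
        l = int(row["mediator"])
        value = float(row["value"])
        if row["kind"] == "production":
            beta[l, i] = value
        elif row["kind"] == "influence":
            rho[i, l] = value
            K[i, l] = float(row["k"])
            depletable[l, i] = row["depletable"] == "True"
        elif row["kind"] == "consumption":
            alpha[l, i] = value
            depletable[l, i] = True
        else:
            raise ValueError(f"unknown link kind {row['kind']!r}")
    return CommunityParameters(
        r0=r0, rho=rho, K=K, alpha=alpha, beta=beta, depletable=depletable,
        inhibition_law=header.get("inhibition_law", "linear"),
        facilitation_law=header.get("facilitation_law", "monod"),
        moser_n=float(header.get("moser_n", 1.0)),
        c_th=float(header.get("c_th", 0.0)),
        decay=decay,
        consumption=header.get("consumption", "growth_coupled"))


def write_trajectory_csv(trajectory, path) -> None:
    """Write a long-format trajectory table (t, entity_type, entity_id, value)."""
    trajectory.to_csv(path, index=False)
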