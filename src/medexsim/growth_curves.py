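"""Plate-reader growth-rate extraction and dose-response fitting.

Exponential growth rates are estimated from optical-density (OD) time
series the way plate-reader assays are usually analysed: the first two
reads are discarded (condensation transients), the per-well background is
the mean of reads 3–10, and after background subtraction a line is fitted
to log(OD) against time over the window 0.002 < OD < 0.02 — high enough to
clear read noise, low enough to avoid saturation.  The slope is the growth
rate in 1/h.

Rates measured at several mediator concentrations are then fitted against
the five dose-response laws used by the community model: linear inhibition
r0 - (r_inh/K_inh)·C, its thresholded variant, the "growth inhibition"
form r0 - r_inh / (1 + K_inh/(C - C_th)), and the saturating Monod /
Moser facilitation forms r0 + r_fac·C^n / (C^n + K_fac^n).

A fixture generator produces synthetic plate series and dose-response
tables with known ground truth so that every routine here can be exercised
(and its estimator bias quantified) without instrument data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "PlateSeries",
    "DoseResponseFit",
    "DOSE_RESPONSE_LAWS",
    "growth_rate_from_od",
    "fit_dose_response",
    "make_fixture",
    "read_plate_csv",
]


@dataclass
class PlateSeries:
    """One well's OD (or fluorescence) trace.

    ``times`` in hours, strictly increasing; ``od`` raw readings including
    background.  ``group`` labels replicates of the same condition.
    """

    times: np.ndarray
    od: np.ndarray
    well_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).reshape(-1)
        self.od = np.asarray(self.od, dtype=float).reshape(-1)
        if self.times.shape != self.od.shape:
            raise ValueError("times and od must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.od)):
            raise ValueError("od readings must be finite")


# ---------------------------------------------------------------------------
# growth-rate extraction
# ---------------------------------------------------------------------------

def growth_rate_from_od(series: PlateSeries,
                        od_min: float = 0.002, od_max: float = 0.02,
                        background_points: tuple[int, int] = (2, 10),
                        n_dropped: int = 2,
                        t_cap: float | None = None) -> float | None:
    """Log-linear growth rate of one well, 1/h; None if no usable window.

    Background is the mean of readings ``background_points`` (python slice
    bounds; default reads 3–10).  The first ``n_dropped`` reads are
    excluded from the fit.  ``t_cap`` optionally restricts the fit to early
    times (e.g. the first 3 h of a fluorescence assay, before the mediator
    is depleted).  At least three in-window points are required.
    """
    if series.times.size < 10:
        raise ValueError("need at least 10 time points")
    background = float(series.od[background_points[0]:background_points[1]].mean())
    signal = series.od - background
    mask = np.zeros(series.times.size, dtype=bool)
    mask[n_dropped:] = True
    mask &= (signal > od_min) & (signal < od_max)
    if t_cap is not None:
        mask &= series.times <= t_cap
    if mask.sum() < 3:
        return None
    slope, _ = np.polyfit(series.times[mask], np.log(signal[mask]), 1)
    return float(slope)


# ---------------------------------------------------------------------------
# dose-response laws
# ---------------------------------------------------------------------------

def _linear_inhibition(c, r0, slope):
    return r0 - slope * c


def _threshold_inhibition(c, r0, slope, c_th):
    return np.where(c <= c_th, r0, r0 - slope * (c - c_th))


def _growth_inhibition(c, r0, r_inh, k_inh, c_th):
    excess = np.maximum(np.asarray(c, dtype=float) - c_th, 0.0)
    safe = np.where(excess > 0, excess, 1.0)
    return np.where(excess > 0, r0 - r_inh / (1.0 + k_inh / safe), r0)


def _monod(c, r0, r_fac, k_fac):
    return r0 + r_fac * c / (c + k_fac)


def _moser(c, r0, r_fac, k_fac, n):
    cn = c ** n
    return r0 + r_fac * cn / (cn + k_fac ** n)


#: law name -> (model function, parameter names)
DOSE_RESPONSE_LAWS = {
    "linear_inhibition": (_linear_inhibition, ("r0", "slope")),
    "threshold_inhibition": (_threshold_inhibition, ("r0", "slope", "c_th")),
    "growth_inhibition": (_growth_inhibition, ("r0", "r_inh", "k_inh", "c_th")),
    "monod": (_monod, ("r0", "r_fac", "k_fac")),
    "moser": (_moser, ("r0", "r_fac", "k_fac", "n")),
}


@dataclass
class DoseResponseFit:
    """Least-squares fit of one dose-response law."""

    law: str
    params: dict[str, float]
    rss: float
    converged: bool
    message: str = ""

    def predict(self, concentrations) -> np.ndarray:
        fn, names = DOSE_RESPONSE_LAWS[self.law]
        c = np.asarray(concentrations, dtype=float)
        return fn(c, *(self.params[p] for p in names))


def _initial_guess(law: str, c: np.ndarray, r: np.ndarray):
    """Heuristic starting point and bounds per law."""
    span = max(r.max() - r.min(), 1e-6)
    c_scale = max(np.median(c[c > 0]) if np.any(c > 0) else 1.0, 1e-12)
    if law == "linear_inhibition":
        return [r.max(), span / max(c.max(), 1e-12)], (-np.inf, np.inf)
    if law == "threshold_inhibition":
        p0 = [r.max(), span / max(c.max(), 1e-12), 0.5 * c_scale]
        return p0, ([-np.inf, 0.0, 0.0], [np.inf, np.inf, c.max()])
    if law == "growth_inhibition":
        p0 = [r.max(), span, c_scale, 0.1 * c_scale]
        return p0, ([-np.inf, 0.0, 1e-12, 0.0], [np.inf, np.inf, np.inf, c.max()])
    if law == "monod":
        return [r.min(), span, c_scale], ([-np.inf, 0.0, 1e-12], np.inf)
    if law == "moser":
        p0 = [r.min(), span, c_scale, 2.0]
        return p0, ([-np.inf, 0.0, 1e-12, 1.0], [np.inf, np.inf, np.inf, 3.0])
    raise ValueError(f"unknown dose-response law {law!r}")


def fit_dose_response(concentrations, rates, law: str) -> DoseResponseFit:
    """Fit one law to (concentration, growth-rate) pairs.

    Needs at least four pairs.  Moser's exponent is constrained to the
    admissible range 1 <= n <= 3.  Non-convergence is reported in the
    returned fit rather than raised.
    """
    c = np.asarray(concentrations, dtype=float).reshape(-1)
    r = np.asarray(rates, dtype=float).reshape(-1)
    if c.size != r.size:
        raise ValueError("concentrations and rates must have equal length")
    if c.size < 4:
        raise ValueError("need at least 4 (concentration, rate) pairs")
    fn, names = DOSE_RESPONSE_LAWS[law]
    p0, bounds = _initial_guess(law, c, r)
    try:
        popt, _ = curve_fit(fn, c, r, p0=p0, bounds=bounds, maxfev=20000)
        converged, message = True, ""
    except RuntimeError as exc:
        popt, converged, message = p0, False, str(exc)
    params = dict(zip(names, (float(v) for v in popt)))
    rss = float(np.sum((fn(c, *popt) - r) ** 2))
    return DoseResponseFit(law=law, params=params, rss=rss,
                           converged=converged, message=message)


def compare_laws(concentrations, rates, laws=None) -> pd.DataFrame:
    """Fit several laws to the same data and rank them by residual."""
    laws = list(DOSE_RESPONSE_LAWS) if laws is None else list(laws)
    fits = [fit_dose_response(concentrations, rates, law) for law in laws]
    df = pd.DataFrame({"law": [f.law for f in fits],
                       "rss": [f.rss for f in fits],
                       "converged": [f.converged for f in fits]})
    return df.sort_values("rss").reset_index(drop=True)


# ---------------------------------------------------------------------------
# synthetic fixtures
# ---------------------------------------------------------------------------

def make_fixture(law: str | None, params: dict, noise_sd: float,
                 design: dict, seed: int | None = None):
    """Generate synthetic plate series or dose-response tables.

    ``design["kind"] == "plate"`` yields a list of :class:`PlateSeries`
    with OD(t) = background + amplitude * e^{rate t} (optionally capped
    logistically at ``design["carrying_od"]``) plus Gaussian read noise;
    the generating parameters come from ``params`` (rate, background,
    amplitude) and the sampling grid from ``design`` (interval_h, t_max_h,
    n_replicates).

    ``design["kind"] == "dose_response"`` yields a DataFrame with columns
    (concentration, rate) generated from the named law at
    ``design["concentrations"]``.

    Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    kind = design.get("kind", "plate")
    if kind == "plate":
        rate = params["rate"]
        background = params.get("background", 0.09)
        amplitude = params.get("amplitude", 1e-5)
        interval = design.get("interval_h", 5.0 / 60.0)
        t_max = design.get("t_max_h", 24.0)
        n_rep = design.get("n_replicates", 1)
        carrying = design.get("carrying_od")
        times = np.arange(0.0, t_max + interval / 2, interval)
        out = []
        for rep in range(n_rep):
            growth = amplitude * np.exp(rate * times)
            if carrying is not None:
                # logistic saturation with the same early exponential rate
                growth = carrying * growth / (carrying + growth - amplitude)
            od = background + growth + rng.normal(0.0, noise_sd, times.size)
            out.append(PlateSeries(times=times, od=od,
                                   well_id=f"W{rep + 1}", group="fixture"))
        return out
    if kind == "dose_response":
        fn, names = DOSE_RESPONSE_LAWS[law]
        c = np.asarray(design["concentrations"], dtype=float)
        r = fn(c, *(params[p] for p in names))
        r = r + rng.normal(0.0, noise_sd, c.size)
        return pd.DataFrame({"concentration": c, "rate": r})
    raise ValueError(f"unknown fixture kind {kind!r}")


# ---------------------------------------------------------------------------
# plate export reader
# ---------------------------------------------------------------------------

def read_plate_csv(path, time_col: str = "time", well_col: str = "well",
                   value_col: str = "value") -> list[PlateSeries]:
    """Read a long-format plate export (one row per read) into series.

    The expected dialect is a plain CSV with a header naming at least the
    time (hours), well and value columns; any ``group`` column is carried
    through as the replicate label.
    """
    df = pd.read_csv(path)
    out = []
    for well, grp in df.groupby(well_col, sort=True):
        grp = grp.sort_values(time_col)
        out.append(PlateSeries(
            times=grp[time_col].to_numpy(dtype=float),
            od=grp[value_col].to_numpy(dtype=float),
            well_id=str(well),
            group=str(grp["group"].iloc[0]) if "group" in grp else ""))
    return out
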