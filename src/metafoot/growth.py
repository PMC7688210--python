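"""Growth-curve analysis: sigmoid OD600 fit, exponential-phase maximum
specific growth rate, generation time, and OD-to-biomass/protein
conversions.

The OD600 curve of a batch culture is fit with the same four-parameter
sigmoid as substrate curves, in the appearance direction; the fitted t50 is
the inflection point of growth.  The maximum specific growth rate mu_max is
the slope of ln(OD) versus time over the exponential phase, and the
generation time is ln(2)/mu_max.

The OD-to-biomass and OD-to-protein conversions are affine calibrations
(defaults from a filtration / Bradford calibration of the study organism):

    biomass [mg/L]            = 343.09 x OD600 - 5.38
    protein [mg BSA-eq/L]     =  67.19 x OD600 + 2.78
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fitting import FitConfig, TimeSeries, fit_sigmoid
from .kinetics import SigmoidParams

__all__ = [
    "GrowthConversion",
    "GrowthCurve",
    "GrowthRateEstimate",
    "fit_growth",
    "mu_max_loglinear",
    "od_to_biomass",
    "od_to_protein",
]

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class GrowthConversion:
    """Affine OD600 -> biomass / protein calibration constants."""

    biomass_slope: float = 343.09    # mg L^-1 per OD unit
    biomass_intercept: float = -5.38  # mg L^-1
    protein_slope: float = 67.19     # mg L^-1 BSA-eq per OD unit
    protein_intercept: float = 2.78  # mg L^-1


@dataclass
class GrowthCurve:
    """Sigmoid fit of an OD600 time course."""

    times: np.ndarray
    od600: np.ndarray
    sigmoid_fit: SigmoidParams | None
    inflection: float | None
    r2: float
    flags: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class GrowthRateEstimate:
    """Log-linear exponential-phase growth-rate estimate."""

    mu_max: float                 # h^-1
    window: tuple[float, float]   # (t_start, t_end), h
    r2: float
    generation_time: float        # h, = ln 2 / mu_max


def od_to_biomass(od: float, conv: GrowthConversion | None = None
                  ) -> tuple[float, bool]:
    """Affine OD -> biomass (mg/L).

    Returns ``(value, extrapolation_flag)``; below-zero extrapolations are
    reported as-is, flagged rather than clamped.
    """
    conv = conv or GrowthConversion()
    if od < 0:
        raise ValueError("OD must be non-negative")
    b = conv.biomass_slope * od + conv.biomass_intercept
    return b, b < 0


def od_to_protein(od: float, conv: GrowthConversion | None = None) -> float:
    """Affine OD -> cellular protein (mg BSA-equivalents / L)."""
    conv = conv or GrowthConversion()
    if od < 0:
        raise ValueError("OD must be non-negative")
    return conv.protein_slope * od + conv.protein_intercept


def plate_mu_max(df, time_col: str = "time_h", value_col: str = "absorbance",
                 well_col: str = "well", blank_wells=None,
                 r2_min: float = 0.98):
    """Per-well maximum specific growth rates from a long-form plate-reader
    table, for sole-carbon-source growth assays.

    ``blank_wells`` names uninoculated wells whose per-time mean is
    subtracted from every other well before log-linear fitting.  Returns a
    DataFrame (well, mu_max, t_start, t_end, r2, generation_time); wells
    without positive growth carry NaN.
    """
    import pandas as pd

    blank_wells = set(blank_wells or ())
    blanks = df[df[well_col].isin(blank_wells)]
    blank_mean = (blanks.groupby(time_col)[value_col].mean()
                  if len(blanks) else None)
    rows = []
    for well, g in df[~df[well_col].isin(blank_wells)].groupby(well_col):
        t = g[time_col].to_numpy(dtype=float)
        v = g[value_col].to_numpy(dtype=float)
        if blank_mean is not None:
            v = v - blank_mean.reindex(g[time_col]).to_numpy()
        keep = v > 0
        row = {"well": well, "mu_max": np.nan, "t_start": np.nan,
               "t_end": np.nan, "r2": np.nan, "generation_time": np.nan}
        try:
            est = mu_max_loglinear(t[keep], v[keep], r2_min=r2_min)
            row.update(mu_max=est.mu_max, t_start=est.window[0],
                       t_end=est.window[1], r2=est.r2,
                       generation_time=est.generation_time)
        except ValueError:
            pass
        rows.append(row)
    return pd.DataFrame(rows)


def fit_growth(times, od600, cfg: FitConfig | None = None,
               anchor: tuple[float, float] | None = None,
               anchor_weight: int = 1) -> GrowthCurve:
    """Fit an appearance-direction sigmoid to an OD600 series.

    ``times``/``od600`` may contain replicate observations (equal times).
    ``anchor`` is an optional (time, OD) pseudo-observation such as the
    starter-culture OD, entered ``anchor_weight`` times to stabilise the
    early part of the fit.  A series with no overall increase is flagged
    and carries no inflection.
    """
    times = np.asarray(times, dtype=float)
    od = np.asarray(od600, dtype=float)
    if len(times) < 4:
        raise ValueError("need at least 4 OD observations")
    if anchor is not None:
        times = np.concatenate([np.full(anchor_weight, anchor[0]), times])
        od = np.concatenate([np.full(anchor_weight, anchor[1]), od])
    order = np.argsort(times)
    times, od = times[order], od[order]
    ut = np.unique(times)
    obs = [od[times == t] for t in ut]
    ts = TimeSeries(compound="OD600", times=ut, observations=obs, unit="OD")

    means = ts.means()
    if means[-1] <= means[0]:
        return GrowthCurve(ut, means, None, None, r2=0.0,
                           flags={"no-growth-trend"})
    fit = fit_sigmoid(ts, direction="appearance", cfg=cfg)
    p = fit.params or fit.raw_params
    flags = set(fit.flags)
    if p is None:
        flags.add("fit-failed")
        return GrowthCurve(ut, means, None, None, r2=fit.r2, flags=flags)
    if fit.kinetic_type != 2:
        flags.add(f"kinetic-type-{fit.kinetic_type}")
    return GrowthCurve(ut, means, p, float(p.t50), r2=fit.r2, flags=flags)


def mu_max_loglinear(times, od600,
                     window: tuple[float, float] | None = None,
                     r2_min: float = 0.98,
                     min_points: int = 3) -> GrowthRateEstimate:
    """Maximum specific growth rate from a log-linear fit of ln(OD) vs t.

    With an explicit ``window`` the slope is fit over the points inside it.
    Otherwise every contiguous run of >= ``min_points`` points is scanned
    and the window with the largest slope subject to r2 >= ``r2_min`` is
    chosen (falling back to the best-r2 window if none qualifies).
    """
    t = np.asarray(times, dtype=float)
    od = np.asarray(od600, dtype=float)
    order = np.argsort(t)
    t, od = t[order], od[order]

    def _fit(idx: np.ndarray) -> tuple[float, float]:
        if np.any(od[idx] <= 0):
            raise ValueError("OD must be positive inside the fit window")
        ln = np.log(od[idx])
        slope, icept = np.polyfit(t[idx], ln, 1)
        pred = slope * t[idx] + icept
        ssr = float(np.sum((ln - pred) ** 2))
        sst = float(np.sum((ln - ln.mean()) ** 2))
        r2 = 1.0 - ssr / sst if sst > 0 else 1.0
        return float(slope), r2

    if window is not None:
        idx = np.flatnonzero((t >= window[0]) & (t <= window[1]))
        if len(idx) < min_points:
            raise ValueError("fewer than 3 points in the requested window")
        slope, r2 = _fit(idx)
        chosen = (float(t[idx[0]]), float(t[idx[-1]]))
    else:
        best = None  # (slope, r2, (t0, t1)) among r2-qualified windows
        fallback = None
        n = len(t)
        for i in range(n - min_points + 1):
            for j in range(i + min_points, n + 1):
                idx = np.arange(i, j)
                if np.any(od[idx] <= 0):
                    continue
                slope, r2 = _fit(idx)
                win = (float(t[i]), float(t[j - 1]))
                if fallback is None or r2 > fallback[1]:
                    fallback = (slope, r2, win)
                if r2 >= r2_min and (best is None or slope > best[0]):
                    best = (slope, r2, win)
        if best is None:
            best = fallback
        if best is None:
            raise ValueError("no usable window")
        slope, r2, chosen = best

    if slope <= 1e-12:  # flat series produce numerically-zero slopes
        raise ValueError("no exponential growth in window")
    return GrowthRateEstimate(mu_max=slope, window=chosen, r2=r2,
                              generation_time=LN2 / slope)
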