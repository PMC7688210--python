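"""Carbon-use-efficiency estimation and carbon/nitrogen budget accounting.

Carbon use efficiency (CUE, synonymous with microbial growth yield) is the
fraction of assimilated carbon converted to biomass.  In a batch culture
sampled destructively, biomass carbon at each time is the difference
between unfiltered solution C (which includes cells) and 0.2-um-filtered
solution C:

    biomass_C(t) = unfiltered_C(t) - filtered_C(t)

Two cumulative estimators are provided:

* the *literal* form  biomass_C(t) / [unfiltered_C(t-1) - unfiltered_C(t)],
  whose denominator is the carbon lost from the whole vessel — i.e.
  respired C, not assimilated C (biomass over respired, = CUE/(1-CUE)
  under exact mass balance); and
* the *mass-balance* form  biomass_C(t) / [filtered_C(0) - filtered_C(t)],
  biomass over the depletion of the dissolved pool (assimilated C), which
  is the default for reporting.

Instantaneous CUE is the per-interval ratio delta biomass_C / delta
assimilated_C, displayed at the interval midpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .chem import carbon_mass, round_half_away
from .kinetics import SigmoidParams

__all__ = [
    "CarbonPoolSample",
    "NitrogenPools",
    "CueSeries",
    "pools_from_arrays",
    "cue_eq1_literal",
    "cue_cumulative",
    "cue_instantaneous",
    "cue_series",
    "carbon_fractions",
    "nitrogen_budget",
    "substrate_c_share",
]


@dataclass(frozen=True)
class CarbonPoolSample:
    """Carbon pools at one sampling time (all mg C/L)."""

    time: float
    unfiltered_c: float
    filtered_c: float

    @property
    def biomass_c(self) -> float:
        return self.unfiltered_c - self.filtered_c

    @property
    def consistent(self) -> bool:
        return self.unfiltered_c >= self.filtered_c >= 0


@dataclass(frozen=True)
class NitrogenPools:
    """Nitrogen pools at one sampling time (all mg N/L)."""

    time: float
    tn: float
    nh4_n: float = 0.0
    ninhydrin_n: float = 0.0
    no3_n: float = 0.0
    no2_n: float = 0.0

    @property
    def components_exceed_tn(self) -> bool:
        return self.nh4_n + self.ninhydrin_n + self.no3_n + self.no2_n > self.tn


@dataclass
class CueSeries:
    """Cumulative and instantaneous CUE derived from a pool time course."""

    times: np.ndarray
    cumulative: np.ndarray
    interval_midpoints: np.ndarray
    instantaneous: np.ndarray              # NaN where undefined
    flags: set[str] = field(default_factory=set)
    sigmoid_fit: SigmoidParams | None = None


def pools_from_arrays(times, unfiltered_c, filtered_c) -> list[CarbonPoolSample]:
    return [CarbonPoolSample(float(t), float(u), float(f))
            for t, u, f in zip(times, unfiltered_c, filtered_c)]


def cue_eq1_literal(pools: list[CarbonPoolSample], t_index: int) -> float:
    """Literal biomass-over-vessel-loss ratio between consecutive samples.

    .. warning::
       The denominator, the drop in *unfiltered* C, is carbon lost from the
       vessel (respiration), not carbon assimilated; this ratio equals
       CUE/(1-CUE) under exact mass balance and exceeds 1 whenever
       CUE > 0.5.  Retained for fidelity with the as-printed definition;
       prefer :func:`cue_cumulative`.
    """
    if t_index < 1:
        raise IndexError("t_index must be >= 1 (needs a preceding sample)")
    warnings.warn(
        "literal CUE ratio is biomass over respired (not assimilated) C",
        stacklevel=2)
    denom = pools[t_index - 1].unfiltered_c - pools[t_index].unfiltered_c
    if denom <= 0:
        raise ZeroDivisionError("undefined CUE: no carbon loss over interval")
    return pools[t_index].biomass_c / denom


def cue_cumulative(pools: list[CarbonPoolSample], t_index: int,
                   filtered_c0: float | None = None) -> float:
    """Mass-balance cumulative CUE: biomass C over assimilated C.

    Assimilated C is the depletion of the 0.2-um-filtrate pool since the
    initial medium; ``filtered_c0`` defaults to the first sample's
    filtered C.
    """
    f0 = pools[0].filtered_c if filtered_c0 is None else filtered_c0
    assimilated = f0 - pools[t_index].filtered_c
    if assimilated <= 0:
        raise ZeroDivisionError("undefined CUE: non-positive assimilation")
    return pools[t_index].biomass_c / assimilated


def cue_instantaneous(pools: list[CarbonPoolSample], i: int, j: int
                      ) -> tuple[float, float]:
    """Interval CUE between samples i < j: delta biomass over delta
    assimilated, reported at the interval midpoint ``(value, midpoint)``.

    Returns ``(nan, midpoint)`` when the interval assimilation is
    non-positive (steady state or reversal).
    """
    if not 0 <= i < j < len(pools):
        raise IndexError("interval endpoints must be sampled times, i < j")
    mid = 0.5 * (pools[i].time + pools[j].time)
    d_assim = pools[i].filtered_c - pools[j].filtered_c
    if d_assim <= 0:
        return float("nan"), mid
    d_biomass = pools[j].biomass_c - pools[i].biomass_c
    return d_biomass / d_assim, mid


def cue_series(pools: list[CarbonPoolSample],
               filtered_c0: float | None = None) -> CueSeries:
    """Cumulative CUE at every post-initial sample plus interval CUEs."""
    f0 = pools[0].filtered_c if filtered_c0 is None else filtered_c0
    times, cum, flags = [], [], set()
    for k in range(1, len(pools)):
        times.append(pools[k].time)
        try:
            cum.append(cue_cumulative(pools, k, filtered_c0=f0))
        except ZeroDivisionError:
            cum.append(float("nan"))
            flags.add("undefined-cumulative")
        if not pools[k].consistent:
            flags.add("inconsistent-pools")
    mids, inst = [], []
    for k in range(1, len(pools)):
        v, mid = cue_instantaneous(pools, k - 1, k)
        mids.append(mid)
        inst.append(v)
        if np.isnan(v):
            flags.add("undefined-instantaneous")
    return CueSeries(times=np.asarray(times), cumulative=np.asarray(cum),
                     interval_midpoints=np.asarray(mids),
                     instantaneous=np.asarray(inst), flags=flags)


def carbon_fractions(initial_toc: float, assimilated: float, lost: float,
                     biomass: float | None = None) -> dict[str, float]:
    """Budget percentages (1 dp, half away from zero): assimilated and lost
    as fractions of initial TOC, lost and biomass as fractions of
    assimilated C."""
    if initial_toc <= 0:
        raise ValueError("initial TOC must be positive")
    out = {
        "assimilated_pct_toc": 100.0 * assimilated / initial_toc,
        "lost_pct_toc": 100.0 * lost / initial_toc,
    }
    if assimilated > 0:
        out["lost_pct_assimilated"] = 100.0 * lost / assimilated
        if biomass is not None:
            out["biomass_pct_assimilated"] = 100.0 * biomass / assimilated
    else:
        out["lost_pct_assimilated"] = 0.0
    return {k: round_half_away(v, 1) for k, v in out.items()}


def nitrogen_budget(total_removed: float, amino_n: float, nh4_n: float,
                    tolerance: float = 0.05) -> tuple[float, bool]:
    """Residual N (mg N/L) not explained by amino-acid and ammonium pools.

    Returns ``(residual, over_attributed)``; the flag is set when the
    attributed pools exceed the total removed by more than ``tolerance``.
    """
    if min(total_removed, amino_n, nh4_n) < 0:
        raise ValueError("nitrogen pools must be non-negative")
    residual = total_removed - amino_n - nh4_n
    return residual, residual < -tolerance


def substrate_c_share(depleted_uM: float, n_carbon: float,
                      total_assimilated_c: float) -> float:
    """Percent of total assimilated C attributable to one substrate."""
    if total_assimilated_c <= 0:
        raise ValueError("total assimilated C must be positive")
    return carbon_mass(depleted_uM, n_carbon) / total_assimilated_c * 100.0
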