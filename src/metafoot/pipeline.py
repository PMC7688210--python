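"""Pipeline assembly: readers/writers, usage-report construction, temporal
clustering of usage windows, and the end-to-end run tying the stages
together (parse -> fit -> classify -> windows/rates -> clusters -> CUE ->
budgets -> features).

All tables are plain CSV.  Times are hours from inoculation except LC
retention times, which are seconds and never share a column with hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import features as feat
from .chem import nosc, parse_formula, round_half_away
from .cue import (CueSeries, carbon_fractions, cue_series,
                  pools_from_arrays, substrate_c_share)
from .fitting import FitConfig, TimeSeries, fit_all, fit_sigmoid
from .growth import GrowthCurve, GrowthRateEstimate, fit_growth, \
    mu_max_loglinear

__all__ = [
    "read_timeseries_csv",
    "read_od_csv",
    "read_pools_csv",
    "read_features_csv",
    "assign_clusters",
    "estimate_cue_plateau",
    "run_pipeline",
    "export_usage_plot_data",
    "PipelineResult",
]


# --- I/O ------------------------------------------------------------------

def read_timeseries_csv(path) -> list[TimeSeries]:
    """Read a long-form substrate table (compound, time_h, replicate,
    value, unit) into one TimeSeries per compound."""
    df = pd.read_csv(path)
    return timeseries_from_frame(df)


def timeseries_from_frame(df: pd.DataFrame) -> list[TimeSeries]:
    return [TimeSeries.from_long(g, compound=str(name))
            for name, g in df.groupby("compound", sort=False)]


def read_od_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_pools_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_features_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_usage_report_csv(path) -> pd.DataFrame:
    """Read a usage report back with its dtypes restored (nullable integer
    cluster ids and shortest-repr floats survive the round trip
    byte-identically)."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "cluster" in df.columns:
        df["cluster"] = df["cluster"].astype("Int64")
    if "flags" in df.columns:
        df["flags"] = df["flags"].fillna("")
    return df


# --- clustering -----------------------------------------------------------

def assign_clusters(usage: pd.DataFrame, gap_h: float = 1.5) -> pd.Series:
    """Single-linkage 1-D clustering of type-2 midpoints.

    Type-1 substrates always form cluster 1 (change complete before the
    first sample); sigmoid-fit rows are sorted by t50 and split wherever
    consecutive midpoints are more than ``gap_h`` apart.  Types 3/4 get no
    cluster.  Returns a nullable-integer Series aligned to ``usage``.
    """
    cluster = pd.Series(pd.NA, index=usage.index, dtype="Int64")
    has_t1 = bool((usage["kinetic_type"] == 1).any())
    if has_t1:
        cluster[usage["kinetic_type"] == 1] = 1
    t2 = usage[usage["kinetic_type"] == 2].sort_values("t50")
    next_id = 2 if has_t1 else 1
    prev_t50 = None
    for idx, row in t2.iterrows():
        if prev_t50 is not None and row["t50"] - prev_t50 > gap_h:
            next_id += 1
        cluster[idx] = next_id
        prev_t50 = row["t50"]
    return cluster


# --- CUE plateau ----------------------------------------------------------

def estimate_cue_plateau(pools: pd.DataFrame,
                         cfg: FitConfig | None = None) -> float:
    """Plateau of an appearance sigmoid fit to per-replicate cumulative CUE.

    Cumulative CUE per replicate flask uses the single initial filtered-C
    measurement as the common baseline.  The plateau is the fitted a + o;
    if the fit does not classify as sigmoidal or leaves (0, 1], the mean
    final-time cumulative CUE is reported instead.
    """
    mean0 = pools[pools["time_h"] == pools["time_h"].min()]
    f0 = float(mean0["filtered_c"].mean())
    later = pools[pools["time_h"] > pools["time_h"].min()]
    rows = []
    for _, r in later.iterrows():
        assim = f0 - r["filtered_c"]
        if assim <= 0:
            continue
        rows.append({"time_h": r["time_h"],
                     "value": (r["unfiltered_c"] - r["filtered_c"]) / assim})
    cue_df = pd.DataFrame(rows)
    final_t = cue_df["time_h"].max()
    fallback = float(cue_df.loc[cue_df["time_h"] == final_t, "value"].mean())
    times = np.array(sorted(cue_df["time_h"].unique()))
    if len(times) < 3:
        return fallback
    obs = [np.clip(cue_df.loc[cue_df["time_h"] == t, "value"]
                   .to_numpy(), 0, None) for t in times]
    ts = TimeSeries("cumulative_cue", times, obs, unit="")
    fit = fit_sigmoid(ts, direction="appearance", cfg=cfg or FitConfig())
    p = fit.params or fit.raw_params
    if fit.kinetic_type == 2 and p is not None and 0 < p.a + p.o <= 1:
        return float(p.a + p.o)
    return fallback


# --- the end-to-end run ---------------------------------------------------

@dataclass
class PipelineResult:
    """Everything one experiment run produces."""

    usage_report: pd.DataFrame
    growth: GrowthCurve | None
    growth_rate: GrowthRateEstimate | None
    cue: CueSeries | None
    cue_plateau: float | None
    budget: dict
    feature_report: dict | None
    thresholds: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        from pathlib import Path
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.usage_report.to_csv(out / "usage_report.csv", index=False)
        if self.cue is not None:
            pd.DataFrame({
                "time_h": self.cue.times, "cumulative": self.cue.cumulative,
            }).to_csv(out / "cue_cumulative.csv", index=False)
            pd.DataFrame({
                "midpoint_h": self.cue.interval_midpoints,
                "instantaneous": self.cue.instantaneous,
            }).to_csv(out / "cue_instantaneous.csv", index=False)
        if self.feature_report is not None:
            self.feature_report["fits"].to_csv(out / "feature_fits.csv",
                                               index=False)
        import json
        summary = {
            "thresholds": self.thresholds,
            "cue_plateau": self.cue_plateau,
            "budget": self.budget,
            "growth_inflection": self.growth.inflection if self.growth
            else None,
            "mu_max": self.growth_rate.mu_max if self.growth_rate else None,
            "generation_time": self.growth_rate.generation_time
            if self.growth_rate else None,
        }
        if self.feature_report is not None:
            summary["feature_counts"] = self.feature_report["counts"]
            summary["t50_comparison"] = self.feature_report["t50_comparison"]
            summary["window_comparison"] = \
                self.feature_report["window_comparison"]
        (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                     default=float))


def run_pipeline(substrates: pd.DataFrame | None,
                 od: pd.DataFrame | None = None,
                 pools: pd.DataFrame | None = None,
                 features_table: pd.DataFrame | None = None,
                 formulas: dict[str, str] | None = None,
                 targets: pd.DataFrame | None = None,
                 fit_cfg: FitConfig | None = None,
                 feature_fit_cfg: FitConfig | None = None,
                 gap_h: float = 1.5,
                 t_window: tuple[float, float] = (0.0, 24.0),
                 thresholds: feat.FilterThresholds | None = None,
                 ) -> PipelineResult:
    """Run the full footprinting analysis on in-memory tables.

    Any of the inputs may be omitted; the corresponding report sections are
    skipped.  Every stage failure for an individual compound degrades to a
    flag in the usage report rather than aborting the batch.  The result is
    a pure function of (inputs, configs, seeds).
    """
    fit_cfg = fit_cfg or FitConfig()
    feature_fit_cfg = feature_fit_cfg or replace(fit_cfg, n_starts=100)
    thresholds = thresholds or feat.FilterThresholds()

    # substrates -> usage table
    if substrates is not None and len(substrates):
        series = timeseries_from_frame(substrates)
        usage = fit_all(series, direction="depletion", cfg=fit_cfg,
                        t_window=t_window)
        usage["cluster"] = assign_clusters(usage, gap_h=gap_h)
    else:
        usage = pd.DataFrame(columns=["compound", "kinetic_type", "cluster"])

    # growth
    growth = growth_rate = None
    if od is not None and len(od):
        growth = fit_growth(od["time_h"].to_numpy(),
                            od["od600"].to_numpy(), cfg=fit_cfg)
        means = od.groupby("time_h")["od600"].mean()
        try:
            growth_rate = mu_max_loglinear(means.index.to_numpy(),
                                           means.to_numpy())
        except ValueError:
            growth_rate = None

    # CUE and carbon budget
    cue = None
    cue_plateau = None
    budget: dict = {}
    total_assimilated = None
    if pools is not None and len(pools):
        mean_pools = pools.groupby("time_h")[
            ["unfiltered_c", "filtered_c"]].mean().reset_index()
        plist = pools_from_arrays(mean_pools["time_h"],
                                  mean_pools["unfiltered_c"],
                                  mean_pools["filtered_c"])
        cue = cue_series(plist)
        cue_plateau = estimate_cue_plateau(pools, cfg=fit_cfg)
        f0 = plist[0].filtered_c
        last = plist[-1]
        total_assimilated = f0 - last.filtered_c
        lost = plist[0].unfiltered_c - last.unfiltered_c
        budget = {
            "initial_toc": f0,
            "assimilated_c": total_assimilated,
            "lost_c": lost,
            "biomass_c": last.biomass_c,
            "fractions": carbon_fractions(f0, total_assimilated, lost,
                                          biomass=last.biomass_c),
        }

    # stoichiometric annotations
    if formulas and len(usage):
        noscs, shares = [], []
        for _, row in usage.iterrows():
            f_text = formulas.get(row["compound"])
            if f_text is None:
                noscs.append(np.nan)
                shares.append(np.nan)
                continue
            f = parse_formula(f_text, name=row["compound"])
            noscs.append(round_half_away(nosc(f), 2)
                         if f.n_carbon else np.nan)
            if total_assimilated and np.isfinite(row["a"]):
                shares.append(round_half_away(substrate_c_share(
                    row["a"], f.n_carbon, total_assimilated), 2))
            else:
                shares.append(np.nan)
        usage["nosc"] = noscs
        usage["pct_assimilated_c"] = shares

    # untargeted features
    feature_report = None
    if features_table is not None and len(features_table):
        feature_report = analyze_features(features_table, targets=targets,
                                          thresholds=thresholds,
                                          fit_cfg=feature_fit_cfg,
                                          t_window=t_window)

    used = {
        "gap_h": gap_h, "t_window": list(t_window),
        "n_starts": fit_cfg.n_starts, "seed": fit_cfg.seed,
        "early_frac": fit_cfg.early_frac, "r2_min": fit_cfg.r2_min,
        "noise_tol": fit_cfg.noise_tol,
        "ln_fc_min": thresholds.ln_fc_min, "p_max": thresholds.p_max,
        "intensity_min": thresholds.intensity_min,
    }
    return PipelineResult(usage_report=usage, growth=growth,
                          growth_rate=growth_rate, cue=cue,
                          cue_plateau=cue_plateau, budget=budget,
                          feature_report=feature_report, thresholds=used)


def _feature_series(row: pd.Series, cols: list[str]) -> TimeSeries:
    recs = []
    for c in cols:
        t = float(c.split("_")[1].rstrip("h"))
        recs.append({"time_h": t, "value": row[c]})
    df = pd.DataFrame(recs)
    times = np.array(sorted(df["time_h"].unique()))
    obs = [df.loc[df["time_h"] == t, "value"].to_numpy() for t in times]
    return TimeSeries(str(row["id"]), times, obs, unit="area")


def analyze_features(table: pd.DataFrame,
                     targets: pd.DataFrame | None = None,
                     thresholds: feat.FilterThresholds | None = None,
                     fit_cfg: FitConfig | None = None,
                     t_window: tuple[float, float] = (0.0, 24.0)) -> dict:
    """Screen a feature table, split directions, fit kinetics per feature,
    and compare decreasing vs increasing type-2 groups."""
    thresholds = thresholds or feat.FilterThresholds()
    fit_cfg = fit_cfg or FitConfig(n_starts=100)
    n_input = len(table)
    kept = feat.filter_features(table, thresholds)
    n_filtered = len(kept)
    if targets is not None:
        kept = feat.dedup_targeted(kept, targets)
    kept = feat.split_directions(kept)

    cols = feat.area_columns(kept)
    fit_rows = []
    for i, (_, row) in enumerate(kept.iterrows()):
        direction = "depletion" if row["direction"] == "decreasing" \
            else "appearance"
        if not cols:
            continue
        ts = _feature_series(row, cols)
        fit = fit_sigmoid(ts, direction=direction,
                          cfg=replace(fit_cfg, seed=fit_cfg.seed + i))
        rec = {"id": row["id"], "direction": row["direction"],
               "kinetic_type": fit.kinetic_type,
               "t50": np.nan, "w": np.nan, "width90": np.nan,
               "r2": fit.r2}
        if fit.kinetic_type == 2 and fit.params is not None:
            from .kinetics import usage_window
            win = usage_window(fit.params)
            rec.update(t50=fit.params.t50, w=fit.params.w,
                       width90=win.width90)
        fit_rows.append(rec)
    fits = pd.DataFrame(fit_rows)

    counts = {
        "n_input": n_input,
        "n_pass_filter": n_filtered,
        "n_after_dedup": len(kept),
        "n_decreasing": int((kept["direction"] == "decreasing").sum()),
        "n_increasing": int((kept["direction"] == "increasing").sum()),
    }
    t50_cmp = window_cmp = None
    if len(fits):
        dec2 = fits[(fits["direction"] == "decreasing")
                    & (fits["kinetic_type"] == 2)]
        inc2 = fits[(fits["direction"] == "increasing")
                    & (fits["kinetic_type"] == 2)]
        counts["n_fit_decreasing"] = len(dec2)
        counts["n_fit_increasing"] = len(inc2)
        if len(dec2) >= 2 and len(inc2) >= 2:
            t50_cmp = feat.compare_t50_groups(dec2["t50"], inc2["t50"])
            window_cmp = feat.compare_window_groups(dec2["width90"],
                                                    inc2["width90"])
    return {"table": kept, "fits": fits, "counts": counts,
            "t50_comparison": t50_cmp, "window_comparison": window_cmp}


def export_usage_plot_data(usage: pd.DataFrame,
                           growth_inflection: float | None = None,
                           t_clip: tuple[float, float] = (0.0, 24.0)) -> dict:
    """Plot-ready tables for a usage-window figure.

    Type-2 rows become horizontal bars [t10, t90] (clipped to the
    experiment window, never extending left of its start) with the t50
    point and a NOSC colour key; type-1 rows are listed separately for a
    pre-sampling-period histogram.
    """
    t2 = usage[usage["kinetic_type"] == 2].copy()
    bars = pd.DataFrame({
        "compound": t2["compound"],
        "t10": t2["t10"].clip(lower=t_clip[0]),
        "t50": t2["t50"],
        "t90": t2["t90"].clip(upper=t_clip[1]),
    })
    if "nosc" in t2.columns:
        bars["nosc"] = t2["nosc"].to_numpy()
    t1 = usage[usage["kinetic_type"] == 1][["compound"]].copy()
    if "nosc" in usage.columns:
        t1["nosc"] = usage.loc[usage["kinetic_type"] == 1, "nosc"].to_numpy()
    return {"bars": bars.reset_index(drop=True),
            "type1": t1.reset_index(drop=True),
            "growth_inflection": growth_inflection}
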