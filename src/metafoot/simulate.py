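"""Synthetic batch-experiment generator with known ground truth.

Emulates a time-resolved metabolic footprinting experiment on a complex,
dilute medium: logistic growth of a single heterotroph, multiauxic
substrate depletion in temporal clusters (kinetic types 1-4),
mass-conserving carbon and nitrogen pools, and an untargeted LC-MS feature
table.  Every emitted table parses through the pipeline's readers, and the
true parameters are retained so downstream fits can be scored.

Construction of the carbon pools works bottom-up so mass balance holds
exactly before noise:

1. each substrate follows its true depletion sigmoid; summed carbon
   depletion plus an "uncharacterized C" pool (closing the roster to 100%
   of assimilation) gives assimilated C over time, A(t);
2. biomass C is the integral of a time-varying instantaneous CUE profile
   (a Gaussian bump centred near the growth inflection over a baseline)
   against dA, scaled so the cumulative CUE at the end of the experiment
   equals the designed value exactly;
3. respired C is A(t) minus biomass C (non-decreasing by construction),
   the filtered pool is initial TOC minus A(t), and the unfiltered pool is
   filtered plus biomass.

Measurement noise is multiplicative log-normal, with independent replicate
flasks; the sterile initial medium is "analyzed once" (a single noisy
draw), mirroring the common practice with a limited medium batch.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.special import expit

from .chem import (CARBON_MOLAR_MASS, NITROGEN_MOLAR_MASS, parse_formula)
from .growth import GrowthConversion
from .kinetics import SigmoidParams

__all__ = [
    "SubstrateSpec",
    "ScenarioConfig",
    "FeatureScenario",
    "SyntheticExperiment",
    "paper_mimic",
    "generate",
    "generate_feature_table",
    "score_recovery",
    "RecoveryReport",
]


class ScenarioError(ValueError):
    """Raised for infeasible scenario configurations."""


@dataclass(frozen=True)
class SubstrateSpec:
    """Ground truth for one substrate in the roster."""

    name: str
    formula: str
    params: SigmoidParams          # true depletion curve (a, t50, w, o)
    kinetic_type: int              # designed type (1-4)
    cluster: int
    is_amino: bool = False

    @property
    def initial_uM(self) -> float:
        return self.params.a + self.params.o


@dataclass
class ScenarioConfig:
    """Design of a synthetic batch experiment.

    Defaults describe a 4-sampling-point destructive-harvest design (17,
    19, 22, 24 h plus the sterile medium at 0 h) with three replicate
    flasks, 5% multiplicative noise on compound concentrations, and
    sub-percent noise on bulk C/N pool and OD measurements (bulk analysers
    are far more repeatable than compound quantification).
    """

    substrates: list[SubstrateSpec]
    times: tuple[float, ...] = (0.0, 17.0, 19.0, 22.0, 24.0)
    replicates: int = 3
    od_times: tuple[float, ...] = tuple(float(t) for t in range(25))
    initial_toc: float = 183.1        # mg C/L
    tn0: float = 11.3                 # mg N/L
    designed_cue: float = 0.43
    cue_base_rel: float = 0.4         # baseline of the instantaneous-CUE shape
    cue_peak_time: float = 20.5       # h, where instantaneous CUE peaks
    cue_peak_sigma: float = 1.4       # h
    coverage: float = 0.749           # targeted fraction of total C depletion
    unchar_params: SigmoidParams = SigmoidParams(1.0, 19.0, 2.5, 0.0)
    nh4_params: SigmoidParams = SigmoidParams(1.79, 20.32, 0.78, 0.0)
    biomass_c_fraction: float = 0.5   # g C per g dry biomass
    conversion: GrowthConversion = GrowthConversion()
    noise_sd: float = 0.05            # substrates / feature areas
    pool_noise_sd: float = 0.005      # bulk C and N pools
    od_noise_sd: float = 0.015
    t_end: float = 24.0
    seed: int = 0

    def __post_init__(self) -> None:
        t2 = sorted(s.params.t50 for s in self.substrates
                    if s.kinetic_type == 2)
        first_sample = self.times[1]
        for s in self.substrates:
            if s.kinetic_type == 1 and not s.params.t50 < first_sample:
                raise ScenarioError(
                    f"type-1 substrate {s.name} must deplete before the "
                    f"first post-inoculation sample ({first_sample} h)")
            if s.kinetic_type == 4 and not s.params.t50 > self.times[-1]:
                raise ScenarioError(
                    f"type-4 substrate {s.name} must change after the last "
                    f"sample ({self.times[-1]} h)")
        if not 0 < self.designed_cue < 1:
            raise ScenarioError("designed CUE must be in (0, 1)")
        del t2


@dataclass
class FeatureScenario:
    """Design of a synthetic untargeted feature table.

    Significant features split into decreasing and increasing groups; a
    subset of each follows clean sigmoid kinetics (fittable, type 2) with
    the designed separation in midpoint times and usage-window widths.
    Fold changes and p-values are attributed to the upstream alignment
    tool, as in a real CAMERA export, so they are assigned (consistently
    signed) rather than recomputed from the simulated areas.
    """

    n_decreasing: int = 99
    n_increasing: int = 36
    n_fittable_dec: int = 21
    n_fittable_inc: int = 15
    n_decoys: int = 15                # fail at least one filter criterion
    dec_t50_range: tuple[float, float] = (17.4, 19.4)
    inc_t50_range: tuple[float, float] = (20.3, 21.3)
    dec_w_range: tuple[float, float] = (0.9, 1.5)
    inc_w_range: tuple[float, float] = (0.35, 0.55)
    times: tuple[float, ...] = (0.0, 17.0, 19.0, 22.0, 24.0)
    replicates: int = 3
    noise_sd: float = 0.03
    seed: int = 0


@dataclass
class SyntheticExperiment:
    """Generated tables plus ground truth."""

    substrates: pd.DataFrame      # compound, time_h, replicate, value, unit
    od: pd.DataFrame              # time_h, replicate, od600
    pools: pd.DataFrame           # time_h, replicate, unfiltered_c, filtered_c
    nitrogen: pd.DataFrame        # time_h, replicate, tn, nh4_n, ninhydrin_n,...
    truth: pd.DataFrame           # per-compound true params / types / clusters
    designed: dict
    config: ScenarioConfig
    features: pd.DataFrame | None = None
    feature_truth: pd.DataFrame | None = None


# --- the study-like roster ------------------------------------------------
# (name, formula, a, o, t50, w, type, amino) -- type-1 rows carry the
# observed span (a) and floor (o); their early kinetics are assigned below.
_TYPE1_ROSTER = [
    ("pyruvate", "C3H4O3", 0.37, 0.00, False),
    ("alpha-ketoglutarate", "C5H6O5", 0.43, 0.16, False),
    ("ornithine", "C5H12N2O2", 0.43, 0.53, True),
    ("methionine", "C5H11NO2S", 0.75, 0.28, True),
    ("phenylalanine", "C9H11NO2", 0.57, 0.51, True),
    ("malate", "C4H6O5", 0.93, 0.28, False),
    ("histidine", "C6H9N3O2", 1.27, 0.37, True),
    ("lysine", "C6H14N2O2", 1.19, 0.48, True),
    ("citrulline", "C6H13N3O3", 1.57, 0.67, True),
    ("arginine", "C6H14N4O2", 2.70, 0.31, True),
    ("2-keto-d-gluconate", "C6H10O7", 3.04, 0.16, False),
    ("asparagine", "C4H8N2O3", 4.24, 0.00, True),
    ("serine", "C3H7NO3", 6.00, 0.00, True),
    ("succinate", "C4H6O4", 6.57, 0.00, False),
    ("glutamine", "C5H10N2O3", 8.53, 0.52, True),
    ("aspartate", "C4H7NO4", 11.50, 0.00, True),
    ("gluconate", "C6H12O7", 17.26, 0.37, False),
    ("glutamate", "C5H9NO4", 54.92, 0.00, True),
    ("alanine", "C3H7NO2", 44.00, 26.00, True),
    ("acetate", "C2H4O2", 72.53, 23.07, False),
]
_TYPE2_ROSTER = [
    ("proline", "C5H9NO2", 0.43, 0.40, 16.29, 0.57, True),
    ("isoleucine", "C6H13NO2", 1.92, 0.02, 16.79, 0.99, True),
    ("leucine", "C6H13NO2", 9.51, 0.04, 16.93, 0.52, True),
    ("tryptophan", "C11H12N2O2", 0.62, 0.00, 17.06, 0.19, True),
    ("tyrosine", "C9H11NO3", 0.65, 0.00, 17.08, 0.08, True),
    ("citrate", "C6H8O7", 2.55, 0.04, 17.33, 0.36, False),
    ("lactate", "C3H6O3", 7.34, 17.60, 17.90, 1.09, False),
    ("threonine", "C4H9NO3", 5.91, 0.49, 17.93, 0.62, True),
    # hexose equivalents of the non-glucose reducing sugars (the bulk
    # reducing-sugar assay minus the glucose it contains)
    ("other reducing sugars", "C6H12O6", 113.53, 124.88, 20.42, 1.47, False),
    ("valine", "C5H11NO2", 168.29, 0.00, 20.52, 0.72, True),
    ("glucose", "C6H12O6", 134.82, 57.19, 21.06, 1.15, False),
]


def paper_mimic(seed: int = 0, **overrides) -> ScenarioConfig:
    """The study-like preset: 20 type-1 + 11 type-2 substrates in three
    temporal clusters, designed cumulative CUE 0.43, biomass plateau near
    21.7 mg C/L, 4 + 1 sampling times with 3 replicate flasks."""
    subs: list[SubstrateSpec] = []
    w_cycle = (0.5, 0.8, 1.1)
    n1 = len(_TYPE1_ROSTER)
    for i, (name, formula, a, o, amino) in enumerate(_TYPE1_ROSTER):
        t50 = 5.0 + 8.0 * i / (n1 - 1)      # spread over 5-13 h
        p = SigmoidParams(a=a, t50=t50, w=w_cycle[i % 3], o=o)
        subs.append(SubstrateSpec(name, formula, p, kinetic_type=1,
                                  cluster=1, is_amino=amino))
    for name, formula, a, o, t50, w, amino in _TYPE2_ROSTER:
        p = SigmoidParams(a=a, t50=t50, w=w, o=o)
        cluster = 2 if t50 < 19.0 else 3
        subs.append(SubstrateSpec(name, formula, p, kinetic_type=2,
                                  cluster=cluster, is_amino=amino))
    return ScenarioConfig(substrates=subs, seed=seed, **overrides)


def _depletion(p: SigmoidParams, t: np.ndarray) -> np.ndarray:
    """Concentration depleted since t=0 along the true curve."""
    s0 = expit(-(0.0 - p.t50) / p.w)
    st = expit(-(t - p.t50) / p.w)
    return p.a * (s0 - st)


def _true_pools(cfg: ScenarioConfig, grid: np.ndarray):
    """Noise-free pool curves on a fine grid; returns a dict of arrays."""
    n_c = {s.name: parse_formula(s.formula).n_carbon for s in cfg.substrates}
    depl_c = np.zeros_like(grid)
    for s in cfg.substrates:
        depl_c += _depletion(s.params, grid) * n_c[s.name] * \
            CARBON_MOLAR_MASS / 1000.0
    total_sub_c = depl_c[-1]
    # uncharacterized pool closes the roster to 100% of assimilation
    u_amp = total_sub_c * (1.0 / cfg.coverage - 1.0)
    u = _depletion(replace(cfg.unchar_params, a=1.0), grid)
    unchar = u_amp * u / u[-1]
    assimilated = depl_c + unchar
    if assimilated[-1] >= cfg.initial_toc:
        raise ScenarioError("infeasible mass balance: assimilation exceeds "
                            "initial TOC")

    shape = cfg.cue_base_rel + (1.0 - cfg.cue_base_rel) * np.exp(
        -((grid - cfg.cue_peak_time) / cfg.cue_peak_sigma) ** 2)
    dA = np.gradient(assimilated, grid)
    denom = np.trapezoid(shape * dA, grid)
    k = cfg.designed_cue * assimilated[-1] / denom
    if k * shape.max() > 1.0:
        raise ScenarioError("infeasible mass balance: instantaneous CUE "
                            "profile exceeds 1; lower designed_cue or widen "
                            "the assimilation course")
    biomass_c = cumulative_trapezoid(k * shape * dA, grid, initial=0.0)
    co2 = assimilated - biomass_c
    filtered = cfg.initial_toc - assimilated
    unfiltered = filtered + biomass_c

    biomass_mg = biomass_c / cfg.biomass_c_fraction
    od = (biomass_mg - cfg.conversion.biomass_intercept) \
        / cfg.conversion.biomass_slope
    inflection = float(grid[np.argmax(np.gradient(biomass_c, grid))])

    # nitrogen pools
    n_n = {s.name: parse_formula(s.formula).n_nitrogen for s in cfg.substrates}
    amino_now = np.zeros_like(grid)
    amino_depl = np.zeros_like(grid)
    for s in cfg.substrates:
        if not s.is_amino:
            continue
        factor = n_n[s.name] * NITROGEN_MOLAR_MASS / 1000.0
        d = _depletion(s.params, grid) * factor
        amino_depl += d
        c0 = s.params.a * expit(s.params.t50 / s.params.w) + s.params.o
        amino_now += c0 * factor - d
    nh4_depl = _depletion(cfg.nh4_params, grid)     # already mg N/L
    nh4_now = (cfg.nh4_params.a + cfg.nh4_params.o) - nh4_depl
    tn = cfg.tn0 - amino_depl - nh4_depl

    return {
        "assimilated": assimilated, "biomass_c": biomass_c, "co2": co2,
        "filtered": filtered, "unfiltered": unfiltered, "od": od,
        "inflection": inflection, "cue_inst": k * shape,
        "tn": tn, "nh4_n": nh4_now, "ninhydrin_n": amino_now,
        "substrate_c_depleted": depl_c, "uncharacterized": unchar,
    }


def _mult_noise(rng: np.random.Generator, value, sd: float):
    value = np.asarray(value, dtype=float)
    return value * np.exp(rng.normal(0.0, sd, size=value.shape))


def generate(cfg: ScenarioConfig) -> SyntheticExperiment:
    """Generate one full experiment; deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    grid = np.linspace(0.0, cfg.t_end, 961)
    truth_pools = _true_pools(cfg, grid)

    def at(curve: np.ndarray, t: float) -> float:
        return float(np.interp(t, grid, curve))

    # substrate concentration table
    sub_rows = []
    for s in cfg.substrates:
        p = s.params
        for t in cfg.times:
            true_c = p.a * expit(-(t - p.t50) / p.w) + p.o
            reps = [0] if t == cfg.times[0] else range(1, cfg.replicates + 1)
            for r in reps:
                sub_rows.append({
                    "compound": s.name, "time_h": t, "replicate": r,
                    "value": float(_mult_noise(rng, true_c, cfg.noise_sd)),
                    "unit": "uM",
                })
    substrates = pd.DataFrame(sub_rows)

    od_rows = []
    for t in cfg.od_times:
        true_od = at(truth_pools["od"], t)
        for r in range(1, cfg.replicates + 1):
            od_rows.append({"time_h": t, "replicate": r,
                            "od600": float(_mult_noise(rng, true_od,
                                                       cfg.od_noise_sd))})
    od = pd.DataFrame(od_rows)

    pool_rows, n_rows = [], []
    for t in cfg.times:
        reps = [0] if t == cfg.times[0] else range(1, cfg.replicates + 1)
        for r in reps:
            pool_rows.append({
                "time_h": t, "replicate": r,
                "unfiltered_c": float(_mult_noise(
                    rng, at(truth_pools["unfiltered"], t), cfg.pool_noise_sd)),
                "filtered_c": float(_mult_noise(
                    rng, at(truth_pools["filtered"], t), cfg.pool_noise_sd)),
            })
            n_rows.append({
                "time_h": t, "replicate": r,
                "tn": float(_mult_noise(rng, at(truth_pools["tn"], t),
                                        cfg.pool_noise_sd)),
                "nh4_n": float(_mult_noise(rng, at(truth_pools["nh4_n"], t),
                                           cfg.pool_noise_sd)),
                "ninhydrin_n": float(_mult_noise(
                    rng, at(truth_pools["ninhydrin_n"], t),
                    cfg.pool_noise_sd)),
                "no3_n": 0.0, "no2_n": 0.0,
            })
    pools = pd.DataFrame(pool_rows)
    nitrogen = pd.DataFrame(n_rows)

    truth = pd.DataFrame([{
        "compound": s.name, "formula": s.formula,
        "kinetic_type": s.kinetic_type, "cluster": s.cluster,
        "a": s.params.a, "t50": s.params.t50, "w": s.params.w,
        "o": s.params.o, "initial_uM": s.initial_uM, "is_amino": s.is_amino,
    } for s in cfg.substrates])

    designed = {
        "cue": cfg.designed_cue,
        "growth_inflection": truth_pools["inflection"],
        "biomass_c_plateau": float(truth_pools["biomass_c"][-1]),
        "assimilated_final": float(truth_pools["assimilated"][-1]),
        "respired_final": float(truth_pools["co2"][-1]),
        "coverage": cfg.coverage,
    }
    return SyntheticExperiment(substrates=substrates, od=od, pools=pools,
                               nitrogen=nitrogen, truth=truth,
                               designed=designed, config=cfg)


def generate_feature_table(fs: FeatureScenario
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic untargeted feature table plus its ground truth.

    All ``n_decreasing + n_increasing`` significant features pass the
    screening filter; ``n_decoys`` extra rows each fail exactly one
    criterion.  Fittable (type-2) features carry sigmoid area kinetics
    with the designed group separation in t50 and window width.
    """
    rng = np.random.default_rng(fs.seed)
    rows, truth_rows = [], []
    times = np.asarray(fs.times)
    fid = 0

    def _areas(p: SigmoidParams, sd: float) -> dict[str, float]:
        out = {}
        for t in times:
            u = p.sign * (t - p.t50) / p.w
            true_a = p.a * expit(-u) + p.o
            for r in range(1, fs.replicates + 1):
                out[f"area_{t:g}h_r{r}"] = float(
                    true_a * np.exp(rng.normal(0.0, sd)))
        return out

    def _emit(direction: str, kinetic_type: int, p: SigmoidParams,
              ln_fc: float, p_value: float, maxint: float,
              areas: dict[str, float] | None = None) -> None:
        nonlocal fid
        fid += 1
        row = {
            "id": f"F{fid:04d}",
            "mz": float(rng.uniform(80.0, 800.0)),
            "rt_s": float(rng.uniform(30.0, 900.0)),
            "ln_fc": ln_fc, "p_value": p_value, "max_intensity": maxint,
        }
        row.update(areas if areas is not None else _areas(p, fs.noise_sd))
        rows.append(row)
        truth_rows.append({
            "id": row["id"], "direction": direction,
            "kinetic_type": kinetic_type, "t50": p.t50, "w": p.w,
        })

    def _group(direction: str, n_total: int, n_fit: int,
               t50_range: tuple[float, float], w_range: tuple[float, float]
               ) -> None:
        sig = 1 if direction == "decreasing" else -1
        kin_dir = "depletion" if direction == "decreasing" else "appearance"
        n_rest = n_total - n_fit
        n_t1 = int(round(n_rest * 0.75))
        n_t3 = (n_rest - n_t1 + 1) // 2
        n_t4 = n_rest - n_t1 - n_t3
        for _ in range(n_fit):
            base = 10.0 ** rng.uniform(7.2, 8.6)
            lfc = -sig * rng.uniform(1.3, 3.0)
            lo, hi = base * np.exp(-abs(lfc)), base
            p = SigmoidParams(
                a=hi - lo, t50=float(rng.uniform(*t50_range)),
                w=float(rng.uniform(*w_range)),
                o=lo if direction == "decreasing" else lo,
                direction=kin_dir)  # type: ignore[arg-type]
            _emit(direction, 2, p, lfc, float(rng.uniform(1e-5, 0.04)), hi)
        for k, n in ((1, n_t1), (3, n_t3), (4, n_t4)):
            for _ in range(n):
                base = 10.0 ** rng.uniform(7.2, 8.6)
                lfc = -sig * rng.uniform(1.3, 3.0)
                lo, hi = base * np.exp(-abs(lfc)), base
                if k == 1:
                    p = SigmoidParams(a=hi - lo,
                                      t50=float(rng.uniform(5.0, 12.0)),
                                      w=0.6, o=lo, direction=kin_dir)
                    _emit(direction, 1, p, lfc,
                          float(rng.uniform(1e-5, 0.04)), hi)
                elif k == 4:
                    # change predominantly after the observation window:
                    # essentially no kinetic signal inside it
                    p = SigmoidParams(a=hi - lo,
                                      t50=float(rng.uniform(27.0, 31.0)),
                                      w=0.8, o=lo, direction=kin_dir)
                    _emit(direction, 4, p, lfc,
                          float(rng.uniform(1e-5, 0.04)), hi)
                else:  # V-shaped (or peaked) non-sigmoid course
                    mid = times[0] + 0.6 * (times[-1] - times[0])
                    areas = {}
                    for t in times:
                        frac = 1.0 - 0.9 * np.exp(-((t - mid) / 3.0) ** 2)
                        level = hi * frac if direction == "decreasing" \
                            else lo + (hi - lo) * (1.0 - frac)
                        for r in range(1, fs.replicates + 1):
                            areas[f"area_{t:g}h_r{r}"] = float(
                                level * np.exp(rng.normal(0, fs.noise_sd)))
                    _emit(direction, 3,
                          SigmoidParams(hi - lo, np.nan, 1.0, lo,
                                        direction=kin_dir),
                          lfc, float(rng.uniform(1e-5, 0.04)), hi, areas)

    _group("decreasing", fs.n_decreasing, fs.n_fittable_dec,
           fs.dec_t50_range, fs.dec_w_range)
    _group("increasing", fs.n_increasing, fs.n_fittable_inc,
           fs.inc_t50_range, fs.inc_w_range)

    # decoys: fail exactly one of the three screening criteria
    fail_modes = ["ln_fc", "p", "intensity"]
    for i in range(fs.n_decoys):
        mode = fail_modes[i % 3]
        direction = "decreasing" if i % 2 == 0 else "increasing"
        sig = 1 if direction == "decreasing" else -1
        base = 10.0 ** rng.uniform(7.2, 8.6)
        lfc = -sig * (0.5 if mode == "ln_fc" else rng.uniform(1.3, 3.0))
        p = SigmoidParams(a=base * 0.5, t50=float(rng.uniform(17.5, 21.0)),
                          w=1.0, o=base * 0.5,
                          direction="depletion" if sig > 0 else "appearance")
        _emit(direction, 0, p, float(lfc),
              0.3 if mode == "p" else float(rng.uniform(1e-5, 0.04)),
              1e6 if mode == "intensity" else base)
        truth_rows[-1]["kinetic_type"] = 0  # decoy marker

    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


@dataclass
class RecoveryReport:
    """Ground-truth vs fitted comparison for a generated experiment."""

    params: pd.DataFrame           # per-parameter bias / rmse (type-2 rows)
    confusion: pd.DataFrame        # true type x fitted type counts
    median_abs_t50_error: float
    cue_error: float | None = None


def score_recovery(truth: pd.DataFrame, fitted: pd.DataFrame,
                   cue_estimate: float | None = None,
                   designed_cue: float | None = None) -> RecoveryReport:
    """Score a fitted usage table against generator ground truth."""
    missing = set(truth["compound"]) ^ set(fitted["compound"])
    if missing:
        raise ValueError(f"roster mismatch, unmatched compounds: "
                         f"{sorted(missing)}")
    m = truth.merge(fitted, on="compound", suffixes=("_true", "_fit"))
    confusion = pd.crosstab(m["kinetic_type_true"], m["kinetic_type_fit"])
    both2 = m[(m["kinetic_type_true"] == 2) & (m["kinetic_type_fit"] == 2)]
    stats = []
    for par in ("a", "t50", "w", "o"):
        err = both2[f"{par}_fit"] - both2[f"{par}_true"]
        stats.append({"parameter": par, "bias": float(err.mean()),
                      "rmse": float(np.sqrt(np.mean(err ** 2))),
                      "median_abs_error": float(err.abs().median())})
    params = pd.DataFrame(stats)
    t50_med = float((both2["t50_fit"] - both2["t50_true"]).abs().median()) \
        if len(both2) else float("nan")
    cue_err = None
    if cue_estimate is not None and designed_cue is not None:
        cue_err = float(cue_estimate - designed_cue)
    return RecoveryReport(params=params, confusion=confusion,
                          median_abs_t50_error=t50_med, cue_error=cue_err)
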