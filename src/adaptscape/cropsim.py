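"""Daily wheat growth surrogate linking parameters and weather to yield.

The surrogate maps the 12 genotype-specific physiological parameters plus
daily weather and a single-bucket soil to trajectories of phenology, canopy,
biomass, water stress, and final yield. It is a deliberately minimal daily
model that preserves the causal semantics of the full cropping-systems
models used in the field — thermal-time phenology slowed by photoperiod and
vernalization sensitivity before floral initiation, radiation-limited
potential growth through an exponentially intercepting canopy, water demand
from potential growth and vapour-pressure deficit via the transpiration
efficiency coefficient, water supply as fractional extraction of
plant-available soil water, growth reduced by the supply/demand ratio, and
sink-limited grain filling — without re-implementing any published crop
model's internal algorithms.

All model constants live in :class:`CropsimConstants` and are surrogate
choices documented in the methods note, not literature values.

Update equations (state advanced once per day, in this order):

1. thermal time ``tt = max(0, (tmax+tmin)/2)``; before floral initiation the
   effective increment is ``tt * min(photoperiod_factor, vern_factor)``, and
   floral initiation additionally requires completed vernalization.
2. ``VPD = 0.75 * (svp(tmax) - svp(tmin))`` (Tetens).
3. potential growth ``dB_pot = y_rue * radn * (1 - exp(-y_extinct_coef * LAI))``
   (g m⁻²); emergence endows a small seed-reserve canopy.
4. demand ``= dB_pot * VPD / (1000 * transp_eff_cf)`` (mm); supply
   ``= kl * max(0, PAW - floor)`` with ``floor = (ll_modifier - 1) * PAWC``;
   transpiration ``= min(supply, demand, PAW)``; stress
   ``= min(1, supply/demand)`` (1 on zero-demand days).
5. actual growth ``dB = dB_pot * stress``; pre-flowering a ``y_frac_leaf``
   share becomes leaf mass driving LAI via a constant specific leaf area;
   from floral initiation (leaf turnover at stem elongation) to maturity the
   LAI decays at ``fr_lf_sen_rate`` per day (doubled when stress < 0.5).
6. at flowering, grain number ``= grains_per_gram_stem * stem biomass``
   (stem = (1 - y_frac_leaf) of pre-flowering growth); during grain fill the
   daily sink is ``grain_number * potential_grain_filling_rate`` scaled by
   a thermal factor (``tt/26``, capped at 1) and by stress (severe stress
   below 0.15 halts filling), further capped by assimilate
   (daily growth plus a retranslocation pool of 20% of stem mass), by
   ``max_grain_size``, and by a harvest-index ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .envgen import TrialEnvironment, daylength
from .genarch import PARAMETER_NAMES, ParameterSpec, default_parameter_spec

__all__ = [
    "CropsimConstants",
    "DailyTrajectory",
    "TrialResult",
    "run_trial",
    "run_trial_panel",
    "run_met",
    "svp",
    "vpd_from_minmax",
]

_P = {name: i for i, name in enumerate(PARAMETER_NAMES)}


@dataclass(frozen=True)
class CropsimConstants:
    """Surrogate model constants (one config block; not literature values)."""

    kl: float = 0.08  # soil water extraction fraction, d-1
    sla: float = 0.020  # specific leaf area, m2 g-1
    vpd_fraction: float = 0.75  # daily VPD as fraction of svp(tmax)-svp(tmin)
    tt_emergence: float = 120.0  # degC d sowing -> emergence
    tt_fi_to_heading: float = 350.0
    tt_heading_to_flowering: float = 120.0
    tt_flowering_to_maturity: float = 650.0
    photoperiod_ref_hours: float = 20.0
    photoperiod_coef: float = 0.002
    vern_base_days: float = 0.0
    vern_sens_days: float = 16.0
    vern_t_low: float = 0.0
    vern_t_high: float = 15.0
    seed_reserve_lai: float = 0.05  # canopy endowment at emergence
    seed_reserve_biomass: float = 2.0  # g m-2 at emergence
    stress_senescence_threshold: float = 0.5
    fill_stress_floor: float = 0.15  # severe stress halts grain filling
    fill_tt_ref: float = 26.0  # degC d at which filling reaches full rate
    retranslocation_fraction: float = 0.20  # of stem biomass at flowering
    harvest_index_ceiling: float = 0.62
    ratio_report_cap: float = 10.0
    demand_scale: float = 1000.0  # g->mm unit bridge in the demand equation

    # Zadoks-like codes attached to the stage thresholds for reporting
    zadoks: tuple = (("emergence", 2.1), ("floral_initiation", 3.1),
                     ("heading", 5.5), ("flowering", 6.5))


DEFAULTS = CropsimConstants()


def svp(t_celsius):
    """Saturation vapour pressure (kPa), Tetens formula."""
    t = np.asarray(t_celsius, float)
    return 0.6108 * np.exp(17.27 * t / (t + 237.3))


def vpd_from_minmax(tmin, tmax, fraction: float = DEFAULTS.vpd_fraction):
    """Daily vapour-pressure deficit (kPa) from the min/max temperatures."""
    return fraction * (svp(tmax) - svp(tmin))


@dataclass
class DailyTrajectory:
    """Per-day state for a panel of genotypes in one trial.

    Arrays are (n_days, n_geno) except the shared per-day weather-derived
    columns. ``supply_demand`` is the reported ratio capped at 10 (zero-
    demand days report the cap); ``stress`` = min(1, ratio) is the growth
    multiplier.
    """

    doy: np.ndarray
    thermal_time: np.ndarray  # cumulative effective degC d
    stage: np.ndarray  # Zadoks-like code
    lai: np.ndarray
    biomass: np.ndarray  # g m-2
    supply: np.ndarray  # mm
    demand: np.ndarray  # mm
    supply_demand: np.ndarray  # reported ratio, capped
    stress: np.ndarray  # min(1, ratio)
    paw: np.ndarray  # mm
    grain_weight: np.ndarray  # g per grain after flowering
    transpiration: np.ndarray  # mm
    runoff: np.ndarray  # mm, bucket overflow

    @property
    def n_days(self) -> int:
        return self.doy.size

    @property
    def n_geno(self) -> int:
        return self.biomass.shape[1]

    def to_long_frame(self, trial: str = "", genotypes=None) -> pd.DataFrame:
        """Long-format (genotype, trial, doy, variable, value) export."""
        if genotypes is None:
            genotypes = [f"g{i:03d}" for i in range(self.n_geno)]
        frames = []
        for var in ("biomass", "lai", "stress", "paw", "grain_weight", "stage"):
            arr = getattr(self, var)
            df = pd.DataFrame(arr, columns=genotypes)
            df["doy"] = self.doy
            df = df.melt(id_vars="doy", var_name="genotype", value_name="value")
            df["variable"] = var
            frames.append(df)
        out = pd.concat(frames, ignore_index=True)
        out["trial"] = trial
        return out[["genotype", "trial", "doy", "variable", "value"]]


@dataclass
class TrialResult:
    """Final outcomes per genotype for one trial (vectors of length n_geno)."""

    yield_kg_ha: np.ndarray
    biomass_kg_ha: np.ndarray
    heading_day: np.ndarray  # day index from sowing (-1 if never reached)
    flowering_day: np.ndarray
    maturity_day: np.ndarray
    grain_number: np.ndarray  # grains m-2
    grain_weight_mg: np.ndarray  # mean grain weight, mg
    crop_failed: np.ndarray  # bool: water exhausted before grain set

    def to_frame(self, trial: str = "", genotypes=None) -> pd.DataFrame:
        if genotypes is None:
            genotypes = [f"g{i:03d}" for i in range(self.yield_kg_ha.size)]
        return pd.DataFrame(
            {
                "genotype": genotypes, "trial": trial,
                "yield": self.yield_kg_ha, "biomass": self.biomass_kg_ha,
                "heading_day": self.heading_day,
                "flowering_day": self.flowering_day,
                "maturity_day": self.maturity_day,
                "grain_number": self.grain_number,
                "grain_weight_mg": self.grain_weight_mg,
                "crop_failed": self.crop_failed,
            }
        )


def _check_params(values: np.ndarray, spec: ParameterSpec) -> None:
    lo = spec.low - 1e-9
    hi = spec.high + 1e-9
    if np.any(values < lo) or np.any(values > hi):
        bad = np.unique(np.where((values < lo) | (values > hi))[1])
        names = [spec.names[j] for j in bad]
        raise ValueError(f"parameter(s) outside spec range: {', '.join(names)}")


def run_trial_panel(
    params: np.ndarray,
    env: TrialEnvironment,
    constants: CropsimConstants = DEFAULTS,
    spec: ParameterSpec | None = None,
    check_ranges: bool = True,
) -> tuple[DailyTrajectory, TrialResult]:
    """Run the daily surrogate for a panel of genotypes in one trial.

    ``params`` is an (n_geno, 12) array in canonical parameter order. The
    computation is deterministic: identical inputs give bit-identical
    trajectories. A crop that exhausts its water before grain set yields 0
    and is flagged, not raised.
    """
    if spec is None:
        spec = default_parameter_spec()
    params = np.atleast_2d(np.asarray(params, float))
    if params.shape[1] != 12:
        raise ValueError("params must have 12 columns")
    if check_ranges:
        _check_params(params, spec)
    c = constants
    wx = env.weather
    sow = int(env.site.sowing_doy)
    day_idx = np.flatnonzero(wx.doy >= sow)
    if day_idx.size == 0:
        raise ValueError("weather does not cover the sowing date")
    n_days = day_idx.size
    n = params.shape[0]

    p = {name: params[:, j] for name, j in _P.items()}
    tmin, tmax = wx.tmin[day_idx], wx.tmax[day_idx]
    radn, rain = wx.radn[day_idx], wx.rain[day_idx]
    dl = daylength(env.site.latitude, wx.doy[day_idx])
    tmean = 0.5 * (tmin + tmax)
    tt_day = np.maximum(0.0, tmean)
    vpd = np.maximum(vpd_from_minmax(tmin, tmax, c.vpd_fraction), 0.05)

    # photoperiod factor per day per genotype (precomputable)
    short = np.maximum(0.0, c.photoperiod_ref_hours - dl)
    pf = np.clip(
        1.0 - c.photoperiod_coef * p["photop_sens"][None, :] * (short**2)[:, None],
        0.0, 1.0,
    )
    vern_target = c.vern_sens_days * p["vern_sens"] + c.vern_base_days

    # state
    tt_eff = np.zeros(n)
    vdays = np.zeros(n)
    lai = np.zeros(n)
    biomass = np.zeros(n)
    leaf_mass = np.zeros(n)
    paw = np.full(n, float(env.initial_paw))
    grain_n = np.zeros(n)
    grain_w = np.zeros(n)
    retrans_pool = np.zeros(n)
    stem_mass = np.zeros(n)
    emerged = np.zeros(n, bool)
    fi = np.zeros(n, bool)
    headed = np.zeros(n, bool)
    flowering = np.zeros(n, bool)
    mature = np.zeros(n, bool)
    heading_day = np.full(n, -1)
    flowering_day = np.full(n, -1)
    maturity_day = np.full(n, -1)
    failed = np.zeros(n, bool)

    floor = (p["ll_modifier"] - 1.0) * env.pawc

    T = DailyTrajectory(
        doy=wx.doy[day_idx],
        thermal_time=np.zeros((n_days, n)),
        stage=np.zeros((n_days, n)),
        lai=np.zeros((n_days, n)),
        biomass=np.zeros((n_days, n)),
        supply=np.zeros((n_days, n)),
        demand=np.zeros((n_days, n)),
        supply_demand=np.zeros((n_days, n)),
        stress=np.zeros((n_days, n)),
        paw=np.zeros((n_days, n)),
        grain_weight=np.zeros((n_days, n)),
        transpiration=np.zeros((n_days, n)),
        runoff=np.zeros((n_days, n)),
    )

    tt_fi = p["tt_floral_initiation"]
    tt_head = tt_fi + c.tt_fi_to_heading
    tt_flow = tt_head + c.tt_heading_to_flowering
    tt_mat = tt_flow + c.tt_flowering_to_maturity

    for d in range(n_days):
        active = ~mature
        # --- phenology ---
        if c.vern_t_low <= tmean[d] < c.vern_t_high:
            vdays[active] += 1.0
        vf = np.clip(vdays / vern_target, 0.0, 1.0)
        factor = np.where(fi, 1.0, np.minimum(pf[d], vf))
        # pre-emergence development runs at full thermal rate
        factor = np.where(emerged, factor, 1.0)
        tt_eff = np.where(active, tt_eff + tt_day[d] * factor, tt_eff)

        newly_emerged = active & ~emerged & (tt_eff >= c.tt_emergence)
        if newly_emerged.any():
            emerged |= newly_emerged
            lai[newly_emerged] = c.seed_reserve_lai
            biomass[newly_emerged] = c.seed_reserve_biomass
        # floral initiation requires both the thermal target and completed
        # vernalization (winter habit: no floral transition unvernalized)
        fi |= active & emerged & (tt_eff >= tt_fi) & (vdays >= vern_target)
        new_head = active & fi & ~headed & (tt_eff >= tt_head)
        headed |= new_head
        heading_day[new_head] = d
        new_flower = active & headed & ~flowering & (tt_eff >= tt_flow)

        # --- potential growth and water balance ---
        grow = active & emerged
        interception = 1.0 - np.exp(-p["y_extinct_coef"] * lai)
        db_pot = np.where(grow, p["y_rue"] * radn[d] * interception, 0.0)
        demand = db_pot * vpd[d] / (c.demand_scale * p["transp_eff_cf"])
        supply = np.where(grow, c.kl * np.maximum(0.0, paw - floor), 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(demand > 0, supply / demand, c.ratio_report_cap)
        ratio = np.minimum(ratio, c.ratio_report_cap)
        stress = np.minimum(1.0, ratio)
        transp = np.minimum(np.minimum(supply, demand), paw)
        db = db_pot * stress

        # --- canopy and biomass ---
        pre_flower = grow & ~flowering & ~new_flower
        leaf_gain = np.where(pre_flower, p["y_frac_leaf"] * db, 0.0)
        leaf_mass += leaf_gain
        lai = np.where(pre_flower, lai + leaf_gain * c.sla, lai)
        sen_rate = p["fr_lf_sen_rate"] * np.where(
            stress < c.stress_senescence_threshold, 2.0, 1.0
        )
        # leaf turnover runs from stem elongation (floral initiation) onward
        senescing = grow & fi
        lai = np.where(senescing, lai * np.maximum(0.0, 1.0 - sen_rate), lai)
        biomass = np.where(grow, biomass + db, biomass)

        # --- flowering: set grain number, stem mass, retranslocation pool ---
        if new_flower.any():
            # the seed-reserve endowment is not stem tissue
            stem_at_flower = (1.0 - p["y_frac_leaf"]) * np.maximum(
                biomass - c.seed_reserve_biomass, 0.0
            )
            stem_mass = np.where(new_flower, stem_at_flower, stem_mass)
            grain_n = np.where(
                new_flower, p["grains_per_gram_stem"] * stem_at_flower, grain_n
            )
            retrans_pool = np.where(
                new_flower, c.retranslocation_fraction * stem_at_flower, retrans_pool
            )
            flowering |= new_flower
            flowering_day[new_flower] = d

        # --- grain filling ---
        filling = grow & flowering & (grain_n > 0)
        if filling.any():
            # temperature- and stress-adjusted daily filling capacity,
            # g m-2 d-1; severe stress halts filling entirely
            fill_ok = stress >= c.fill_stress_floor
            tt_factor = min(tt_day[d] / c.fill_tt_ref, 1.0)
            sink = (grain_n * p["potential_grain_filling_rate"]
                    * tt_factor * stress * fill_ok)
            assim = db + retrans_pool
            fill = np.minimum(sink, assim)
            # per-grain size cap
            with np.errstate(divide="ignore", invalid="ignore"):
                room = np.where(grain_n > 0,
                                (p["max_grain_size"] - grain_w) * grain_n, 0.0)
            fill = np.minimum(fill, np.maximum(room, 0.0))
            # harvest-index ceiling
            hi_room = np.maximum(
                0.0, c.harvest_index_ceiling * biomass - grain_w * grain_n
            )
            fill = np.minimum(fill, hi_room)
            fill = np.where(filling, fill, 0.0)
            used_retrans = np.clip(fill - db, 0.0, retrans_pool)
            retrans_pool = np.where(filling, retrans_pool - used_retrans, retrans_pool)
            grain_w = np.where(filling, grain_w + fill / np.maximum(grain_n, 1e-9),
                               grain_w)

        # --- soil water update ---
        paw_new = paw + rain[d] - np.where(grow, transp, 0.0)
        runoff = np.maximum(0.0, paw_new - env.pawc)
        paw = np.clip(paw_new, 0.0, env.pawc)

        # --- maturity ---
        grain_full = flowering & (grain_w >= p["max_grain_size"] - 1e-12)
        new_mature = active & ((tt_eff >= tt_mat) | grain_full)
        if d == n_days - 1:
            new_mature = active  # season ends with the weather record
        mature |= new_mature
        maturity_day[new_mature & (maturity_day < 0)] = d

        # crop failure: water exhausted before grain set
        failed |= emerged & ~flowering & (paw <= 1e-9) & (supply <= 1e-12) & mature

        # --- record ---
        T.thermal_time[d] = tt_eff
        T.lai[d] = lai
        T.biomass[d] = biomass
        T.supply[d] = supply
        T.demand[d] = demand
        T.supply_demand[d] = ratio
        T.stress[d] = stress
        T.paw[d] = paw
        T.grain_weight[d] = grain_w
        T.transpiration[d] = np.where(grow, transp, 0.0)
        T.runoff[d] = runoff
        stage = np.zeros(n)
        stage[emerged] = 2.1
        stage[fi] = 3.1
        stage[headed] = 5.5
        stage[flowering] = 6.5
        T.stage[d] = stage

    yield_gm2 = grain_n * grain_w
    failed |= ~flowering  # never set grain
    yield_gm2 = np.where(grain_n > 0, yield_gm2, 0.0)
    result = TrialResult(
        yield_kg_ha=yield_gm2 * 10.0,
        biomass_kg_ha=biomass * 10.0,
        heading_day=heading_day,
        flowering_day=flowering_day,
        maturity_day=maturity_day,
        grain_number=grain_n,
        grain_weight_mg=grain_w * 1000.0,
        crop_failed=failed,
    )
    return T, result


def run_trial(
    params_row: np.ndarray,
    env: TrialEnvironment,
    constants: CropsimConstants = DEFAULTS,
    spec: ParameterSpec | None = None,
    check_ranges: bool = True,
) -> tuple[DailyTrajectory, TrialResult]:
    """Single-genotype convenience wrapper around :func:`run_trial_panel`."""
    return run_trial_panel(
        np.atleast_2d(params_row), env, constants, spec, check_ranges
    )


def run_met(
    params: np.ndarray,
    trials: list[TrialEnvironment],
    constants: CropsimConstants = DEFAULTS,
    spec: ParameterSpec | None = None,
    keep_trajectories: bool = False,
):
    """Run all genotype × trial combinations of a MET.

    Returns ``(yield_matrix, biomass_matrix, results, trajectories)`` with
    genotype × trial matrices in kg/ha; ``trajectories`` is None unless
    requested (they are large).
    """
    n_geno = np.atleast_2d(params).shape[0]
    Y = np.zeros((n_geno, len(trials)))
    B = np.zeros((n_geno, len(trials)))
    results = []
    trajs = [] if keep_trajectories else None
    for j, env in enumerate(trials):
        traj, res = run_trial_panel(params, env, constants, spec)
        Y[:, j] = res.yield_kg_ha
        B[:, j] = res.biomass_kg_ha
        results.append(res)
        if keep_trajectories:
            trajs.append(traj)
    return Y, B, results, trajs
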