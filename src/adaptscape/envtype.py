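"""Environment typing from water supply/demand dynamics and covariables.

Each trial is characterized by running the growth surrogate for a reference
genotype holding the population-average (range-midpoint) value of every
parameter. The daily water-stress index (supply/demand ratio capped at 1)
is averaged in 100 °Cd thermal-time windows aligned on the reference
flowering date, from emergence to 450 °Cd after flowering; hierarchical
(Ward) clustering of the aligned curves assigns each trial to one of k
environment types (ETs), labelled in order of increasing mean stress
(ET1 = least stressed). Environmental covariables — temperature, radiation,
stress, frost and photoperiod summaries — are computed per trial over four
in-season periods bounded by the reference genotype's phenology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .cropsim import CropsimConstants, DEFAULTS, DailyTrajectory, run_trial
from .envgen import TrialEnvironment, daylength
from .genarch import ParameterSpec, default_parameter_spec

__all__ = [
    "StressCurve",
    "ETAssignment",
    "WINDOW_CD",
    "POST_FLOWERING_CD",
    "reference_trajectory",
    "stress_curve",
    "build_stress_curves",
    "classify",
    "covariables",
    "covariable_table",
    "COVARIABLE_NAMES",
    "PERIOD_NAMES",
]

WINDOW_CD = 100.0  # thermal-time window width, degC d
POST_FLOWERING_CD = 450.0  # curve extent beyond flowering

COVARIABLE_NAMES = [
    "tmean", "radsum", "radmean", "radtemp", "sd", "ct", "ft",
    "photo_max", "photo_mean",
]
PERIOD_NAMES = ["P1", "P2", "P3", "P4"]

# P3 spans flowering -> flowering + 300 degC d; P4 the remainder to maturity
P3_SPAN_CD = 300.0


@dataclass
class StressCurve:
    """Windowed stress index for one trial on the flowering-aligned grid.

    ``windows`` are integer window indices relative to flowering (window 0
    covers the flowering day); ``values`` are mean stress per window, NaN
    where the trial's season does not reach that window.
    """

    trial: str
    windows: np.ndarray
    values: np.ndarray


@dataclass
class ETAssignment:
    """Trial → environment-type labels plus the per-site frequency table."""

    labels: dict[str, str]  # trial name -> "ET1".."ETk"
    k: int
    linkage_matrix: np.ndarray
    mean_stress: dict[str, float]  # per ET, for the ordering audit

    def frequency_table(self, trials: list[TrialEnvironment]) -> pd.DataFrame:
        rows = [
            {"site": t.site.name, "et": self.labels[t.name]} for t in trials
            if t.name in self.labels
        ]
        df = pd.DataFrame(rows)
        return df.groupby(["site", "et"]).size().unstack(fill_value=0)


def reference_trajectory(
    env: TrialEnvironment,
    spec: ParameterSpec | None = None,
    constants: CropsimConstants = DEFAULTS,
) -> tuple[DailyTrajectory, dict]:
    """Run the surrogate for the average-parameter reference genotype.

    The reference genotype takes the midpoint of every parameter range; its
    flowering date defines the alignment origin for stress curves and the
    period boundaries for covariables. Returns ``(trajectory, phenology)``
    where phenology maps stage names to day indices (from sowing).
    """
    if spec is None:
        spec = default_parameter_spec()
    mid = spec.midpoint
    traj, res = run_trial(mid, env, constants, spec)
    if res.flowering_day[0] < 0:
        raise RuntimeError(f"reference crop failed to flower in trial {env.name}")
    tt = traj.thermal_time[:, 0]
    fi_day = int(np.argmax(tt >= mid[spec.index("tt_floral_initiation")]))
    phen = {
        "emergence": int(np.argmax(tt >= constants.tt_emergence)),
        "floral_initiation": fi_day,
        "heading": int(res.heading_day[0]),
        "flowering": int(res.flowering_day[0]),
        "maturity": int(res.maturity_day[0]),
    }
    return traj, phen


def stress_curve(
    env: TrialEnvironment,
    spec: ParameterSpec | None = None,
    constants: CropsimConstants = DEFAULTS,
) -> StressCurve:
    """Windowed stress-index curve for one trial on the aligned grid."""
    traj, phen = reference_trajectory(env, spec, constants)
    tt = traj.thermal_time[:, 0]
    stress = traj.stress[:, 0]
    d_emerge, d_flower = phen["emergence"], phen["flowering"]
    tt_rel = tt - tt[d_flower]
    days = np.arange(traj.n_days)
    in_span = (days >= d_emerge) & (tt_rel < POST_FLOWERING_CD) & (days <= phen["maturity"])
    win = np.floor(tt_rel / WINDOW_CD).astype(int)
    w_lo, w_hi = win[in_span].min(), win[in_span].max()
    windows = np.arange(w_lo, w_hi + 1)
    values = np.full(windows.size, np.nan)
    for i, w in enumerate(windows):
        m = in_span & (win == w)
        if m.any():
            values[i] = stress[m].mean()
    return StressCurve(trial=env.name, windows=windows, values=values)


def build_stress_curves(
    trials: list[TrialEnvironment],
    spec: ParameterSpec | None = None,
    constants: CropsimConstants = DEFAULTS,
) -> pd.DataFrame:
    """Aligned stress curves for a trial list (trials × windows, NaN-padded)."""
    curves = []
    for env in trials:
        try:
            curves.append(stress_curve(env, spec, constants))
        except RuntimeError:
            import warnings

            warnings.warn(f"reference crop failed in {env.name}; trial excluded")
    lo = min(c.windows.min() for c in curves)
    hi = max(c.windows.max() for c in curves)
    grid = np.arange(lo, hi + 1)
    M = np.full((len(curves), grid.size), np.nan)
    names = []
    for i, c in enumerate(curves):
        M[i, c.windows - lo] = c.values
        names.append(c.trial)
    return pd.DataFrame(M, index=names, columns=grid)


def classify(
    curves: pd.DataFrame,
    k: int = 4,
    method: str = "ward",
    seed: int | None = None,
) -> ETAssignment:
    """Hierarchical clustering of aligned stress curves into k ETs.

    Clustering uses Ward linkage on Euclidean distance over the window
    columns complete in every trial; labels are renamed by increasing mean
    stress so ET1 is always the least-stressed type. ``seed`` is accepted
    for interface symmetry (the procedure is deterministic).
    """
    complete = curves.columns[~curves.isna().any(axis=0)]
    if len(complete) < 2:
        raise ValueError("fewer than two complete window columns across trials")
    X = curves[complete].to_numpy()
    if X.shape[0] < k:
        raise ValueError(f"fewer complete curves ({X.shape[0]}) than k={k}")
    Z = linkage(X, method=method)
    raw = fcluster(Z, t=k, criterion="maxclust")
    # order clusters by decreasing mean stress index -> increasing stress rank
    order = sorted(np.unique(raw), key=lambda c: -X[raw == c].mean())
    rename = {c: f"ET{r + 1}" for r, c in enumerate(order)}
    labels = {t: rename[c] for t, c in zip(curves.index, raw)}
    mean_stress = {rename[c]: float(X[raw == c].mean()) for c in np.unique(raw)}
    return ETAssignment(labels=labels, k=k, linkage_matrix=Z, mean_stress=mean_stress)


def _period_slices(phen: dict, tt: np.ndarray, n_days: int) -> dict[str, slice]:
    """P1 sowing→FI, P2 FI→flowering, P3 flowering→+300 °Cd, P4 →maturity."""
    d_fi, d_flower = phen["floral_initiation"], phen["flowering"]
    d_mat = phen["maturity"]
    tt_rel = tt - tt[d_flower]
    past_p3 = np.flatnonzero(tt_rel >= P3_SPAN_CD)
    d_p3_end = int(past_p3[0]) if past_p3.size else d_mat
    d_p3_end = min(d_p3_end, d_mat)
    return {
        "P1": slice(0, d_fi + 1),
        "P2": slice(d_fi + 1, d_flower + 1),
        "P3": slice(d_flower + 1, d_p3_end + 1),
        "P4": slice(d_p3_end + 1, d_mat + 1),
    }


def covariables(
    env: TrialEnvironment,
    reference: tuple[DailyTrajectory, dict] | None = None,
    spec: ParameterSpec | None = None,
    constants: CropsimConstants = DEFAULTS,
) -> pd.DataFrame:
    """Environmental covariables per in-season period for one trial.

    Per period: tmean (mean of daily averages above 0), radsum and radmean
    (sum and mean of daily radiation), radtemp (radsum/tmean), sd (mean
    stress index), ct (absolute sum of daily minima below −4 °C), ft (count
    of days with tmin ≤ 0), photo_max and photo_mean (daylength). Empty
    periods yield NaN.
    """
    if reference is None:
        reference = reference_trajectory(env, spec, constants)
    traj, phen = reference
    tt = traj.thermal_time[:, 0]
    sow = int(env.site.sowing_doy)
    day_idx = np.flatnonzero(env.weather.doy >= sow)
    tmin = env.weather.tmin[day_idx]
    tmean = env.weather.tmean[day_idx]
    radn = env.weather.radn[day_idx]
    dl = daylength(env.site.latitude, env.weather.doy[day_idx])
    stress = traj.stress[:, 0]

    rows = []
    for pname, sl in _period_slices(phen, tt, traj.n_days).items():
        t = tmean[sl]
        if t.size == 0:
            rows.append({"period": pname, **{c: np.nan for c in COVARIABLE_NAMES}})
            continue
        t_pos = t[t > 0]
        tmean_p = t_pos.mean() if t_pos.size else np.nan
        radsum = radn[sl].sum()
        radmean = radn[sl].mean()
        mins = tmin[sl]
        rows.append(
            {
                "period": pname,
                "tmean": tmean_p,
                "radsum": radsum,
                "radmean": radmean,
                "radtemp": radsum / tmean_p if tmean_p and tmean_p > 0 else np.nan,
                "sd": stress[sl].mean(),
                "ct": float(np.abs(mins[mins < -4.0]).sum()),
                "ft": int((mins <= 0.0).sum()),
                "photo_max": dl[sl].max(),
                "photo_mean": dl[sl].mean(),
            }
        )
    return pd.DataFrame(rows).set_index("period")


def covariable_table(
    trials: list[TrialEnvironment],
    spec: ParameterSpec | None = None,
    constants: CropsimConstants = DEFAULTS,
) -> pd.DataFrame:
    """Wide trial × (covariable_period) table for a trial list."""
    rows = {}
    for env in trials:
        cov = covariables(env, None, spec, constants)
        flat = {
            f"{c}_{p}": cov.loc[p, c]
            for p in cov.index
            for c in COVARIABLE_NAMES
        }
        rows[env.name] = flat
    return pd.DataFrame.from_dict(rows, orient="index")
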