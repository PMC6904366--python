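"""G×E structure analyses of the simulated multi-environment trial.

Implements the classical toolkit: the AMMI (additive main effects and
multiplicative interaction) decomposition via SVD of the double-centered
two-way table; REML variance components for the three-way
genotype/location/year model, the environment-type-nested model, and the
simple two-way model; share summaries of the G×E partition; daily two-way
G×E and biomass autocorrelation; parameter-trait correlation panels; and a
single-locus mixed-model association scan with a leave-one-chromosome-out
polygenic background (P3D: the variance ratio is profiled once per
phenotype/kinship, then generalized least squares per SNP).

REML here exploits that in every model the fixed part is saturated in
trials, so the residual likelihood reduces exactly to a Wishart likelihood
of the trial × trial covariance with genotypes as iid replicates; the
structured covariance (a variance component per random term) is maximized
with box-constrained quasi-Newton steps, with components bounded at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .popgen import Kinship, MarkerSet, kinship as make_kinship

__all__ = [
    "METDataset",
    "AMMIResult",
    "VarCompResult",
    "GwasScan",
    "ammi",
    "varcomp",
    "gxe_shares",
    "daily_gxe",
    "autocorr",
    "trait_correlations",
    "gwas_scan",
]


@dataclass
class METDataset:
    """A genotype × trial phenotype table with trial metadata.

    ``values`` is complete (no missing cells); ``trials`` carries one row
    per column with at least site/location, year, and optionally the ET
    label; ``noise_free`` flags whether values are the deterministic
    surrogate output or have calibrated noise added.
    """

    values: np.ndarray  # (n_geno, n_trial)
    trials: pd.DataFrame  # columns: trial, location, year[, et]
    genotypes: list[str] | None = None
    noise_free: bool = True

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if len(self.trials) != self.values.shape[1]:
            raise ValueError("trial metadata must join 1:1 with columns")
        if self.genotypes is None:
            self.genotypes = [f"g{i:03d}" for i in range(self.values.shape[0])]

    @property
    def n_geno(self) -> int:
        return self.values.shape[0]

    @property
    def n_trial(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# AMMI
# ---------------------------------------------------------------------------

@dataclass
class AMMIResult:
    grand_mean: float
    genotype_effects: np.ndarray  # sum to 0
    environment_effects: np.ndarray  # sum to 0
    singular_values: np.ndarray  # first M
    genotype_scores: np.ndarray  # (n_geno, M), symmetric scaling
    environment_scores: np.ndarray  # (n_env, M)
    residual: np.ndarray  # interaction not captured by the M terms

    @property
    def interaction_ss(self) -> float:
        return float(np.sum(self.singular_values**2) + np.sum(self.residual**2))


def ammi(met: METDataset | np.ndarray, M: int = 2) -> AMMIResult:
    """AMMI decomposition of a complete two-way genotype × environment table.

    Main effects are row/column means; the interaction is the SVD of the
    double-centered residual, with symmetric score scaling (each side
    carries the square root of its singular value). Missing cells fail.
    """
    Y = met.values if isinstance(met, METDataset) else np.asarray(met, float)
    if np.isnan(Y).any():
        raise ValueError("AMMI requires a complete table (no missing cells)")
    n_g, n_e = Y.shape
    if M > min(n_g, n_e) - 1:
        raise ValueError("M exceeds min(n_geno, n_env) - 1")
    mu = Y.mean()
    g = Y.mean(axis=1) - mu
    e = Y.mean(axis=0) - mu
    Z = Y - mu - g[:, None] - e[None, :]
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    sqrt_s = np.sqrt(s[:M])
    gscores = U[:, :M] * sqrt_s[None, :]
    escores = Vt[:M].T * sqrt_s[None, :]
    resid = Z - (U[:, :M] * s[:M]) @ Vt[:M]
    return AMMIResult(
        grand_mean=float(mu), genotype_effects=g, environment_effects=e,
        singular_values=s[:M], genotype_scores=gscores,
        environment_scores=escores, residual=resid,
    )


# ---------------------------------------------------------------------------
# variance components (Wishart REML over the trial covariance)
# ---------------------------------------------------------------------------

@dataclass
class VarCompResult:
    model: str
    components: dict[str, float]
    se: dict[str, float]
    loglik: float
    n_geno: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": list(self.components),
                "variance": list(self.components.values()),
                "s.e.": [self.se[k] for k in self.components],
            }
        )


def _design_kernels(trials: pd.DataFrame, model: str) -> dict[str, np.ndarray]:
    """Trial×trial indicator kernels for each random term of the model."""
    n = len(trials)
    ones = np.ones((n, n))
    eye = np.eye(n)

    def same(col):
        v = trials[col].to_numpy()
        return (v[:, None] == v[None, :]).astype(float)

    if model == "three_way":
        return {
            "Genotype": ones,
            "Genotype.Location": same("location"),
            "Genotype.Year": same("year"),
            "Genotype.Location.Year": eye,
        }
    if model == "et_nested":
        return {
            "Genotype": ones,
            "Genotype.EnvType": same("et"),
            "Genotype.Location.Year": eye,
        }
    if model == "two_way":
        return {"Genotype": ones, "Genotype.Environment": eye}
    raise ValueError(f"unknown model {model!r}")


def _wishart_negloglik(sig2, kernels, S, df):
    V = sum(s * K for s, K in zip(sig2, kernels))
    # ensure numerical PD
    V = V + 1e-10 * np.eye(V.shape[0])
    sign, logdet = np.linalg.slogdet(V)
    if sign <= 0:
        return 1e12
    Vi = np.linalg.inv(V)
    return 0.5 * df * (logdet + np.trace(Vi @ S))


def _wishart_negloglik_grad(sig2, kernels, S, df):
    """Value and analytic gradient of the negative Wishart log-likelihood."""
    V = sum(s * K for s, K in zip(sig2, kernels)) + 1e-10 * np.eye(S.shape[0])
    sign, logdet = np.linalg.slogdet(V)
    if sign <= 0:
        return 1e12, np.zeros(len(sig2))
    Vi = np.linalg.inv(V)
    f = 0.5 * df * (logdet + np.trace(Vi @ S))
    M = Vi - Vi @ S @ Vi
    grad = np.array([0.5 * df * np.sum(M * K) for K in kernels])
    return f, grad


def varcomp(
    met: METDataset,
    model: str = "three_way",
    start: np.ndarray | None = None,
) -> VarCompResult:
    """REML variance components for the chosen G×E model.

    Models: ``three_way`` (genotype, genotype.location, genotype.year,
    genotype.location.year — the last random term absorbs the residual
    stratum), ``et_nested`` (genotype, genotype.ET, residual G×E), and
    ``two_way`` (genotype, G×E). Fixed effects are trial-saturated in every
    model, so REML is the Wishart likelihood of the genotype-centered
    trial×trial cross-products with n_geno − 1 degrees of freedom.
    Estimates are bounded at zero; standard errors come from the observed
    information at the optimum.
    """
    kernels_map = _design_kernels(met.trials, model)
    names = list(kernels_map)
    kernels = [kernels_map[k] for k in names]
    Y = met.values
    n_geno = Y.shape[0]
    if n_geno < 3:
        raise ValueError("need at least three genotypes")
    df = n_geno - 1
    Yc = Y - Y.mean(axis=0, keepdims=True)
    S = Yc.T @ Yc / df  # (n_trial, n_trial) sample covariance

    tot = float(np.trace(S)) / len(met.trials)
    x0 = np.full(len(names), max(tot / len(names), 1e-8)) if start is None else np.asarray(start, float)
    bounds = [(0.0, None)] * len(names)
    res = optimize.minimize(
        _wishart_negloglik_grad, x0, args=(kernels, S, df), method="L-BFGS-B",
        jac=True, bounds=bounds,
        options={"maxiter": 1000, "ftol": 1e-16, "gtol": 1e-12},
    )
    if not res.success and res.fun >= 1e11:
        raise RuntimeError(f"REML failed to converge: {res.message}")
    est = np.maximum(res.x, 0.0)

    # observed-information SEs (finite differences on the free components)
    se = {}
    h = np.maximum(1e-6, 1e-4 * np.abs(est))
    H = np.zeros((len(est), len(est)))
    f0 = _wishart_negloglik(est, kernels, S, df)
    for i in range(len(est)):
        for j in range(i, len(est)):
            ei = np.zeros(len(est)); ei[i] = h[i]
            ej = np.zeros(len(est)); ej[j] = h[j]
            fpp = _wishart_negloglik(np.abs(est + ei + ej), kernels, S, df)
            fp0 = _wishart_negloglik(np.abs(est + ei), kernels, S, df)
            f0p = _wishart_negloglik(np.abs(est + ej), kernels, S, df)
            H[i, j] = H[j, i] = (fpp - fp0 - f0p + f0) / (h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        diag = np.diag(cov)
        se_vals = np.sqrt(np.where(diag > 0, diag, np.nan))
    except np.linalg.LinAlgError:
        se_vals = np.full(len(est), np.nan)
    se = dict(zip(names, se_vals))
    return VarCompResult(
        model=model, components=dict(zip(names, est)), se=se,
        loglik=-float(res.fun), n_geno=n_geno,
    )


def gxe_shares(components: VarCompResult | dict[str, float]) -> dict[str, float]:
    """Share summary of a variance-component partition, in integer-rounded %.

    Returns the share of total phenotypic variance that is G×E, the share of
    G×E carried by each interaction term, and (for the ET-nested model) the
    share of G×E explained by the ET classification.
    """
    comp = components.components if isinstance(components, VarCompResult) else dict(components)
    genetic = comp.get("Genotype", 0.0)
    inter = {k: v for k, v in comp.items() if k != "Genotype"}
    gxe_total = sum(inter.values())
    total = genetic + gxe_total
    if total <= 0 or gxe_total <= 0:
        raise ValueError("all variance components are zero; shares undefined")
    out = {"gxe_pct_of_total": round(100.0 * gxe_total / total)}
    for k, v in inter.items():
        out[f"{k}_pct_of_gxe"] = round(100.0 * v / gxe_total)
    if "Genotype.EnvType" in inter:
        out["et_pct_of_gxe"] = out["Genotype.EnvType_pct_of_gxe"]
    return out


# ---------------------------------------------------------------------------
# daily G×E, autocorrelation, trait correlations
# ---------------------------------------------------------------------------

def daily_gxe(biomass_cube: np.ndarray) -> pd.DataFrame:
    """Per-day two-way variance partition over a days × genotypes × envs cube.

    For each day a two-way model (genotype random, environment fixed) is
    fitted; returns the genotype and G×E variance components and the G×E
    fraction of phenotypic variance per day.
    """
    cube = np.asarray(biomass_cube, float)
    n_days, n_geno, n_env = cube.shape
    if n_geno < 3 or n_env < 2:
        raise ValueError("need >=3 genotypes and >=2 environments")
    rows = []
    trials = pd.DataFrame({"trial": [f"e{j}" for j in range(n_env)]})
    for d in range(n_days):
        met = METDataset(values=cube[d], trials=trials)
        if np.allclose(cube[d].var(axis=0), 0):
            rows.append({"day": d, "var_G": 0.0, "var_GE": 0.0, "ge_fraction": np.nan})
            continue
        vc = varcomp(met, model="two_way")
        g = vc.components["Genotype"]
        ge = vc.components["Genotype.Environment"]
        frac = ge / (g + ge) if g + ge > 0 else np.nan
        rows.append({"day": d, "var_G": g, "var_GE": ge, "ge_fraction": frac})
    return pd.DataFrame(rows)


def autocorr(
    biomass: np.ndarray, lags: tuple[int, ...] = (5, 10, 15)
) -> pd.DataFrame:
    """Lagged Pearson autocorrelation of biomass across genotypes, per day.

    ``biomass`` is (n_days, n_geno) for a single environment; the lag-L
    value at day t correlates biomass at day t with day t − L over
    genotypes. Days before the lag horizon are missing.
    """
    B = np.asarray(biomass, float)
    n_days = B.shape[0]
    rows = []
    for lag in lags:
        for d in range(n_days):
            if d < lag:
                r = np.nan
            else:
                a, b = B[d], B[d - lag]
                if a.std() == 0 or b.std() == 0:
                    r = np.nan
                else:
                    r = float(np.corrcoef(a, b)[0, 1])
            rows.append({"day": d, "lag": lag, "r": r})
    return pd.DataFrame(rows)


def trait_correlations(
    params: np.ndarray,
    daily_trait: np.ndarray,
    final_trait: np.ndarray | None = None,
    param_names: list[str] | None = None,
) -> pd.DataFrame:
    """Pearson correlation of each parameter with a daily trait over time.

    ``params`` is (n_geno, P); ``daily_trait`` is (n_days, n_geno) for one
    environment. The optional ``final_trait`` (n_geno,) appends a final
    column (day = −1) with the parameter–final-trait correlations, the
    end-of-season panel. Zero-variance days give NaN.
    """
    P = np.atleast_2d(np.asarray(params, float))
    D = np.asarray(daily_trait, float)
    if param_names is None:
        param_names = [f"p{j}" for j in range(P.shape[1])]
    rows = []
    for d in range(D.shape[0]):
        y = D[d]
        for j, name in enumerate(param_names):
            x = P[:, j]
            if y.std() == 0 or x.std() == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(x, y)[0, 1])
            rows.append({"day": d, "parameter": name, "r": r})
    if final_trait is not None:
        y = np.asarray(final_trait, float)
        for j, name in enumerate(param_names):
            x = P[:, j]
            r = np.nan if (y.std() == 0 or x.std() == 0) else float(np.corrcoef(x, y)[0, 1])
            rows.append({"day": -1, "parameter": name, "r": r})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# single-locus mixed-model association scan (P3D, LOCO kinship)
# ---------------------------------------------------------------------------

@dataclass
class GwasScan:
    """Per-SNP effects and tests for one phenotype vector (e.g. one day)."""

    table: pd.DataFrame  # snp_id, chrom, effect, effect_pct_mean, stat, p, significant
    day: int | None = None
    kinship_scope: str = "leave-one-chromosome-out"


def _profile_delta(yr: np.ndarray, xr: np.ndarray, lam: np.ndarray) -> float:
    """Profile the residual/genetic variance ratio delta on rotated data.

    Model: y = X b + g + e with g ~ N(0, sg^2 K), e ~ N(0, se^2 I). After
    rotating by K's eigenvectors, V = sg^2 diag(lam + delta). The REML-like
    profile over delta is minimized by golden-section on log delta.
    """

    def negll(log_delta):
        delta = np.exp(log_delta)
        w = lam + delta
        # GLS intercept-only fit
        Xw = xr / w[:, None]
        beta = np.linalg.solve(xr.T @ Xw, Xw.T @ yr)
        r = yr - xr @ beta
        n = yr.size
        sg2 = float(r @ (r / w)) / n
        return n * np.log(max(sg2, 1e-300)) + np.sum(np.log(w))

    res = optimize.minimize_scalar(negll, bounds=(-8.0, 8.0), method="bounded")
    return float(np.exp(res.x))


def gwas_scan(
    markers: MarkerSet,
    phenotype: np.ndarray,
    day: int | None = None,
    kinships: dict[int, Kinship] | None = None,
    alpha: float = 0.05,
) -> GwasScan:
    """Single-locus association scan with polygenic background control.

    For each chromosome the polygenic covariance uses the kinship computed
    from all *other* chromosomes (leave one chromosome out), so the tested
    SNP never contributes to its own background. Variance components are
    profiled once per (phenotype, kinship) — the population-parameters-
    previously-determined shortcut — then each SNP is tested by GLS.
    Effects are reported raw and as a percentage of the phenotype mean;
    Bonferroni significance across SNPs is flagged at ``alpha``.
    Monomorphic SNPs are skipped with a flag.
    """
    y = np.asarray(phenotype, float)
    if y.size != markers.n_geno:
        raise ValueError("phenotype length must match the number of genotypes")
    chroms = markers.map["chrom"].to_numpy()
    mean_y = y.mean()
    rows = []
    for chrom in np.unique(chroms):
        if kinships is not None and chrom in kinships:
            K = kinships[chrom].matrix
        else:
            K = make_kinship(markers, exclude_chrom=int(chrom)).matrix
        lam, U = np.linalg.eigh(K)
        lam = np.clip(lam, 0.0, None)
        yr = U.T @ y
        ones_r = U.T @ np.ones_like(y)
        delta = _profile_delta(yr, ones_r[:, None], lam)
        w = lam + delta
        snp_idx = np.flatnonzero(chroms == chrom)
        for k in snp_idx:
            x = markers.genotypes[:, k].astype(float)
            if x.std() == 0:
                rows.append({"snp_id": markers.map["snp_id"].iloc[k], "chrom": chrom,
                             "effect": np.nan, "effect_pct_mean": np.nan,
                             "stat": np.nan, "p": np.nan, "skipped": True})
                continue
            xr = np.column_stack([ones_r, U.T @ x])
            Xw = xr / w[:, None]
            XtX = xr.T @ Xw
            beta = np.linalg.solve(XtX, Xw.T @ yr)
            r = yr - xr @ beta
            n = y.size
            sg2 = float(r @ (r / w)) / (n - 2)
            cov = sg2 * np.linalg.inv(XtX)
            eff = float(beta[1])
            se = float(np.sqrt(max(cov[1, 1], 1e-300)))
            t = eff / se
            pval = 2.0 * stats.t.sf(abs(t), df=n - 2)
            rows.append({"snp_id": markers.map["snp_id"].iloc[k], "chrom": chrom,
                         "effect": eff,
                         "effect_pct_mean": 100.0 * eff / mean_y if mean_y != 0 else np.nan,
                         "stat": t, "p": pval, "skipped": False})
    tab = pd.DataFrame(rows)
    n_tests = int((~tab["skipped"]).sum())
    tab["significant"] = tab["p"] < (alpha / max(n_tests, 1))
    return GwasScan(table=tab, day=day)
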