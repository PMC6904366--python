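"""Multi-environment genomic prediction of unobserved trials.

The deterministic surrogate phenotypes are degraded with per-trial noise
calibrated to a target within-trial heritability; training sets are drawn
stratified across environment types (ETs); four prediction models are
fitted and scored against the noise-free genotypic values:

- **ETmean** — genotype effects per ET with covariance Sigma_G (genomic
  kinship) ⊗ Sigma_E (unstructured 4×4 genetic covariance across ETs),
  fitted as a two-stage plug-in (per-ET genotype means, method-of-moments
  Sigma_E with within-ET error correction, then multivariate GBLUP);
  a validation trial is predicted from its ET's mean plus the genotype's
  ET-specific genomic prediction.
- **MeanPC / IndivPC** — fixed-effect reaction-norm models on the
  cross-products of genotypic-kinship principal components (4) and
  environmental-kinship principal components (3): a single slope on the
  averaged product vector, or one slope per product vector.
- **FReg** — factorial regression on products of (noisy) physiological
  parameters and environmental covariables, built by forward selection with
  covariable and squared covariable entered together and the square dropped
  when non-significant.

Accuracies are per-trial Pearson correlations against the noise-free
values, aggregated across training-set realizations on Fisher's z scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .gxe import METDataset
from .popgen import Kinship

__all__ = [
    "NoisyMET",
    "TrainingPlan",
    "PredictionModelResult",
    "AccuracyReport",
    "add_noise",
    "make_training_plan",
    "fit_etmean",
    "env_kinship",
    "geno_pcs",
    "env_pcs",
    "cross_products",
    "fit_meanpc",
    "fit_indivpc",
    "fit_freg",
    "accuracy",
    "fisher_z",
    "inverse_fisher_z",
]


# ---------------------------------------------------------------------------
# heritability-calibrated noise
# ---------------------------------------------------------------------------

@dataclass
class NoisyMET:
    """A MET with independent per-trial noise at a target heritability."""

    noisy: METDataset
    truth: METDataset  # the noise-free copy
    error_variances: np.ndarray  # per trial
    h2: float
    seed: int | None = None


def add_noise(met: METDataset, h2: float, seed: int | None = None) -> NoisyMET:
    """Add per-trial noise so each trial's expected heritability is ``h2``.

    The error variance in trial j is ``var_j * (1/h2 - 1)`` with ``var_j``
    the genotypic (noise-free) variance in that trial, so the ratio of
    genotypic to total variance is ``h2`` in expectation. ``h2`` = 1 leaves
    phenotypes unchanged.
    """
    if not 0 < h2 <= 1:
        raise ValueError("heritability must be in (0, 1]")
    rng = np.random.default_rng(seed)
    Y = met.values
    var_g = Y.var(axis=0, ddof=1)
    if h2 < 1 and np.any(var_g <= 0):
        bad = met.trials.iloc[int(np.argmax(var_g <= 0))]
        raise ValueError(f"zero genotypic variance in trial {bad.get('trial', '?')}")
    sigma2_e = var_g * (1.0 / h2 - 1.0)
    noise = rng.normal(0.0, np.sqrt(sigma2_e)[None, :], size=Y.shape)
    noisy = METDataset(
        values=Y + noise, trials=met.trials.copy(), genotypes=list(met.genotypes),
        noise_free=False,
    )
    return NoisyMET(noisy=noisy, truth=met, error_variances=sigma2_e, h2=h2, seed=seed)


# ---------------------------------------------------------------------------
# stratified training plans
# ---------------------------------------------------------------------------

@dataclass
class TrainingPlan:
    """Stratified training/validation splits over trials with ET labels."""

    splits: list[dict]  # each: {"train": [trial indices], "valid": [...]}
    per_et: int
    seed: int | None = None

    @property
    def n_splits(self) -> int:
        return len(self.splits)


def make_training_plan(
    trials: pd.DataFrame,
    n_splits: int = 20,
    per_et: int = 4,
    seed: int | None = None,
) -> TrainingPlan:
    """Draw stratified training sets: ``per_et`` trials from each ET.

    ``trials`` must carry an ``et`` column; validation is the complement of
    each training set. With 124 trials and 4 × 4 training trials, each
    validation set has 108 trials.
    """
    if "et" not in trials.columns:
        raise ValueError("trial metadata must carry an 'et' column")
    rng = np.random.default_rng(seed)
    groups = {et: np.flatnonzero(trials["et"].to_numpy() == et)
              for et in sorted(trials["et"].unique())}
    for et, idx in groups.items():
        if idx.size < per_et:
            raise ValueError(f"ET {et} has only {idx.size} trials (< {per_et})")
    all_idx = np.arange(len(trials))
    splits = []
    for _ in range(n_splits):
        train = np.concatenate(
            [rng.choice(idx, size=per_et, replace=False) for idx in groups.values()]
        )
        train.sort()
        valid = np.setdiff1d(all_idx, train)
        splits.append({"train": train, "valid": valid})
    return TrainingPlan(splits=splits, per_et=per_et, seed=seed)


# ---------------------------------------------------------------------------
# model results
# ---------------------------------------------------------------------------

@dataclass
class PredictionModelResult:
    model: str
    predictions: np.ndarray  # (n_geno, n_valid_trials)
    valid_trials: np.ndarray  # column indices into the MET
    fitted: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# ETmean
# ---------------------------------------------------------------------------

def _nearest_pd(M: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    vals, vecs = np.linalg.eigh(0.5 * (M + M.T))
    return (vecs * np.clip(vals, eps, None)) @ vecs.T


def fit_etmean(
    train: METDataset,
    kin: Kinship,
    valid_trials: np.ndarray,
    valid_et: np.ndarray,
) -> PredictionModelResult:
    """Two-stage ET-mean model with Sigma_G ⊗ Sigma_E genotype effects.

    Stage 1 averages each genotype's training phenotypes per ET and
    estimates the 4×4 genetic covariance across ETs by method of moments,
    subtracting the within-ET between-trial variance from the diagonal
    (projected to the nearest positive-definite matrix when needed).
    Stage 2 shrinks the per-ET means by multivariate GBLUP with the genomic
    kinship. The prediction for a validation trial is the fitted grand mean
    plus its ET's mean training effect plus the genotype's ET-specific
    genomic effect; all trials of one ET share their genotype predictions.
    """
    train_et = train.trials["et"].to_numpy()
    ets = np.sort(np.unique(train_et))
    if len(ets) < 2:
        raise ValueError("training set must contain at least two ETs")
    missing = set(np.unique(valid_et)) - set(ets)
    if missing:
        raise ValueError(f"validation ET(s) {sorted(missing)} absent from training")
    Y = train.values
    n_geno = Y.shape[0]
    A = kin.matrix

    # per-ET genotype means and within-ET residual variance of the mean
    M = np.zeros((n_geno, len(ets)))
    psi = np.zeros(len(ets))
    for t, et in enumerate(ets):
        cols = Y[:, train_et == et]
        M[:, t] = cols.mean(axis=1)
        n_t = cols.shape[1]
        if n_t > 1:
            within = (cols - cols.mean(axis=1, keepdims=True)).var(ddof=1)
            psi[t] = within / n_t

    mu_t = M.mean(axis=0)  # fixed ET means
    Mc = M - mu_t[None, :]
    Sigma_E = (Mc.T @ Mc) / (n_geno - 1) - np.diag(psi)
    Sigma_E = _nearest_pd(Sigma_E)

    # multivariate GBLUP of the ET-specific genotype effects
    # vec ordering: ET-major (stack genotypes per ET)
    C = np.kron(Sigma_E, A)
    R = np.kron(np.diag(np.maximum(psi, 1e-8)), np.eye(n_geno))
    rhs = Mc.T.reshape(-1)  # ET-major vec
    G_hat = C @ np.linalg.solve(C + R, rhs)
    G_hat = G_hat.reshape(len(ets), n_geno).T  # (n_geno, n_et)

    preds = np.zeros((n_geno, len(valid_trials)))
    for j, et in enumerate(valid_et):
        t = int(np.flatnonzero(ets == et)[0])
        preds[:, j] = mu_t[t] + G_hat[:, t]
    return PredictionModelResult(
        model="ETmean", predictions=preds, valid_trials=np.asarray(valid_trials),
        fitted={"Sigma_E": Sigma_E, "ets": ets, "G_hat": G_hat, "psi": psi},
    )


# ---------------------------------------------------------------------------
# kinship PCs and cross-products
# ---------------------------------------------------------------------------

def env_kinship(covariables: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    """Environmental kinship: Euclidean distances on standardized covariables.

    The trial × trial matrix of pairwise Euclidean distances between
    standardized covariable profiles serves as the environmental kinship
    whose leading eigenvectors feed the reaction-norm models. Unlike a
    centered cross-product matrix, the distance matrix has a dominant
    constant-sign eigenvector, so the PC cross-products retain a stable
    genotype-ranking pathway across trials. Constant covariables are
    dropped with a warning; returns the kinship matrix and the standardized
    covariable table actually used.
    """
    Z = covariables.copy()
    sd = Z.std(ddof=0)
    drop = sd[(sd == 0) | sd.isna()].index
    if len(drop):
        import warnings

        warnings.warn(f"dropping constant covariables: {list(drop)}")
        Z = Z.drop(columns=drop)
    Z = (Z - Z.mean()) / Z.std(ddof=0)
    # trials with an empty period (NaN covariable) sit at the standardized
    # mean rather than poisoning the kinship
    Z = Z.fillna(0.0)
    Zv = Z.to_numpy()
    from scipy.spatial.distance import pdist, squareform

    return squareform(pdist(Zv)), Z


def _top_pcs(M: np.ndarray, k: int) -> np.ndarray:
    vals, vecs = np.linalg.eigh(M)
    order = np.argsort(vals)[::-1][:k]
    return vecs[:, order] * np.sqrt(np.clip(vals[order], 0, None))[None, :]


def geno_pcs(kin: Kinship, k: int = 4) -> np.ndarray:
    """Leading principal components of the genotypic kinship."""
    return _top_pcs(kin.matrix, k)


def env_pcs(similarity: np.ndarray, k: int = 3) -> np.ndarray:
    """Leading principal components of the environmental kinship."""
    return _top_pcs(similarity, k)


def cross_products(gpcs: np.ndarray, epcs: np.ndarray) -> np.ndarray:
    """All genotype-PC × environment-PC product vectors.

    Returns (n_geno, n_trial, k_g * k_e): one genotype × trial sheet per
    (genotypic PC, environmental PC) pair — 12 with the default 4 × 3.
    """
    n_g, k_g = gpcs.shape
    n_e, k_e = epcs.shape
    out = np.empty((n_g, n_e, k_g * k_e))
    m = 0
    for a in range(k_g):
        for b in range(k_e):
            out[:, :, m] = np.outer(gpcs[:, a], epcs[:, b])
            m += 1
    return out


# ---------------------------------------------------------------------------
# MeanPC / IndivPC
# ---------------------------------------------------------------------------

def _fit_fixed_reaction_norm(
    train: METDataset, X_sheets: np.ndarray, train_cols: np.ndarray,
    valid_cols: np.ndarray, valid_et: np.ndarray, model: str,
) -> PredictionModelResult:
    """Shared least-squares machinery for MeanPC and IndivPC.

    Fits ``y_ij = mu + E_j + sum_m slope_m * x_m,ij`` on the training cells
    with trial main effects; validation predictions replace the unobserved
    trial effect by the mean training-trial effect of the validation
    trial's ET.
    """
    Y = train.values
    n_geno, n_train = Y.shape
    n_sheets = X_sheets.shape[2]
    # response and design over training cells
    y = Y.reshape(-1, order="F")  # column-major: trial blocks
    cols = []
    trial_dummies = np.kron(np.eye(n_train), np.ones((n_geno, 1)))
    cols.append(trial_dummies)
    covs = np.stack(
        [X_sheets[:, train_cols, m].reshape(-1, order="F") for m in range(n_sheets)],
        axis=1,
    )
    X = np.column_stack([trial_dummies, covs])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    trial_eff = beta[:n_train]
    slopes = beta[n_train:]

    mu = trial_eff.mean()
    train_et = train.trials["et"].to_numpy()
    et_eff = {et: trial_eff[train_et == et].mean() for et in np.unique(train_et)}

    preds = np.zeros((n_geno, valid_cols.size))
    for j, (col, et) in enumerate(zip(valid_cols, valid_et)):
        x = X_sheets[:, col, :]  # (n_geno, n_sheets)
        preds[:, j] = et_eff[et] + x @ slopes
    return PredictionModelResult(
        model=model, predictions=preds, valid_trials=np.asarray(valid_cols),
        fitted={"slopes": slopes, "trial_effects": trial_eff, "et_effects": et_eff},
    )


def fit_meanpc(
    train: METDataset, products: np.ndarray, train_cols: np.ndarray,
    valid_cols: np.ndarray, valid_et: np.ndarray,
) -> PredictionModelResult:
    """Single-slope model on the averaged PC cross-product vector."""
    x_star = products.mean(axis=2, keepdims=True)
    return _fit_fixed_reaction_norm(train, x_star, train_cols, valid_cols,
                                    valid_et, "MeanPC")


def fit_indivpc(
    train: METDataset, products: np.ndarray, train_cols: np.ndarray,
    valid_cols: np.ndarray, valid_et: np.ndarray,
) -> PredictionModelResult:
    """Separate-slope model on every PC cross-product vector."""
    return _fit_fixed_reaction_norm(train, products, train_cols, valid_cols,
                                    valid_et, "IndivPC")


# ---------------------------------------------------------------------------
# factorial regression with forward selection
# ---------------------------------------------------------------------------

def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if res.size:
        return float(res[0])
    r = y - X @ beta
    return float(r @ r)


def fit_freg(
    train: METDataset,
    param_phenotypes: pd.DataFrame,
    covariables: pd.DataFrame,
    train_cols: np.ndarray,
    valid_cols: np.ndarray,
    valid_et: np.ndarray,
    alpha: float = 0.01,
    max_terms: int = 10,
) -> PredictionModelResult:
    """Factorial regression on parameter × covariable products.

    Candidates are all (parameter, covariable_period) products; each round
    the candidate pair (covariable and its square entered together) with the
    smallest F-test p-value is added if it passes ``alpha``, then the
    squared term is dropped if not itself significant. Selection stops when
    no candidate passes or ``max_terms`` is reached; if nothing is selected
    in round one, the trial-effects-only model is returned flagged.

    ``param_phenotypes`` is genotype × parameter (noisy, typically H²=0.7);
    ``covariables`` is trial × covariable_period (the full MET table,
    indexed like the MET's trial names).
    """
    Y = train.values
    n_geno, n_train = Y.shape
    y = Y.reshape(-1, order="F")
    trial_dummies = np.kron(np.eye(n_train), np.ones((n_geno, 1)))

    # standardized covariables over the *training* trials
    cov_all = covariables.copy()
    cov_train = cov_all.iloc[train_cols]
    mean, sd = cov_train.mean(), cov_train.std(ddof=0)
    keep = sd[sd > 0].index
    cov_std = ((cov_all[keep] - mean[keep]) / sd[keep]).fillna(0.0)

    P = param_phenotypes.to_numpy()
    p_names = list(param_phenotypes.columns)
    c_names = list(keep)

    def sheet(p_idx, c_name, square=False):
        z = cov_std[c_name].to_numpy()
        if square:
            z = z**2
        return np.outer(P[:, p_idx], z)  # (n_geno, n_all_trials)

    def training_vec(p_idx, c_name, square=False):
        return sheet(p_idx, c_name, square)[:, train_cols].reshape(-1, order="F")

    selected: list[tuple[int, str, bool]] = []  # (param idx, covariable, squared?)
    X_base = trial_dummies
    rss_base = _ols_rss(X_base, y)
    n_obs = y.size
    flag_empty = False

    for _ in range(max_terms):
        best = None
        df_base = X_base.shape[1] + len(selected)
        for p_idx, c_name in product(range(P.shape[1]), c_names):
            if any(s[0] == p_idx and s[1] == c_name for s in selected):
                continue
            lin = training_vec(p_idx, c_name, False)
            sq = training_vec(p_idx, c_name, True)
            Xc = np.column_stack([X_base, lin, sq])
            rss = _ols_rss(Xc, y)
            q = 2
            df_resid = n_obs - Xc.shape[1]
            if df_resid <= 0 or rss <= 0:
                continue
            F = (rss_base - rss) / q / (rss / df_resid)
            pval = stats.f.sf(F, q, df_resid)
            if best is None or pval < best[0]:
                best = (pval, p_idx, c_name)
        if best is None or best[0] > alpha or alpha <= 0:
            if not selected:
                flag_empty = True
            break
        _, p_idx, c_name = best
        # enter linear + square, then test dropping the square
        lin = training_vec(p_idx, c_name, False)
        sq = training_vec(p_idx, c_name, True)
        X_with = np.column_stack([X_base, lin, sq])
        X_wo = np.column_stack([X_base, lin])
        rss_with = _ols_rss(X_with, y)
        rss_wo = _ols_rss(X_wo, y)
        df_resid = n_obs - X_with.shape[1]
        F_sq = (rss_wo - rss_with) / (rss_with / df_resid)
        p_sq = stats.f.sf(F_sq, 1, df_resid)
        if p_sq <= alpha:
            X_base = X_with
            selected.append((p_idx, c_name, False))
            selected.append((p_idx, c_name, True))
            rss_base = rss_with
        else:
            X_base = X_wo
            selected.append((p_idx, c_name, False))
            rss_base = rss_wo

    beta, *_ = np.linalg.lstsq(X_base, y, rcond=None)
    trial_eff = beta[:n_train]
    slopes = beta[n_train:]
    train_et = train.trials["et"].to_numpy()
    et_eff = {et: trial_eff[train_et == et].mean() for et in np.unique(train_et)}

    preds = np.zeros((n_geno, valid_cols.size))
    for j, (col, et) in enumerate(zip(valid_cols, valid_et)):
        x = np.column_stack(
            [sheet(p, c, s)[:, [col]] for (p, c, s) in selected]
        ) if selected else np.zeros((n_geno, 0))
        preds[:, j] = et_eff[et] + (x @ slopes if selected else 0.0)

    term_names = [
        f"{p_names[p]}.{c}" + ("^2" if s else "") for (p, c, s) in selected
    ]
    return PredictionModelResult(
        model="FReg", predictions=preds, valid_trials=np.asarray(valid_cols),
        fitted={"terms": term_names, "slopes": slopes, "empty": flag_empty,
                "et_effects": et_eff},
    )


# ---------------------------------------------------------------------------
# accuracy
# ---------------------------------------------------------------------------

def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher's variance-stabilizing transform z = arctanh(r)."""
    r = np.clip(r, -0.9999, 0.9999)
    return np.arctanh(r)


def inverse_fisher_z(z: np.ndarray | float) -> np.ndarray | float:
    """Back-transform r = tanh(z) = (exp(2z) − 1)/(exp(2z) + 1)."""
    return np.tanh(z)


@dataclass
class AccuracyReport:
    """Per-trial accuracies with Fisher-z aggregation across splits."""

    per_trial: pd.DataFrame  # split, trial, model, r
    summary: pd.DataFrame  # model, mean_r, ci_low, ci_high


def accuracy(results: list[pd.DataFrame] | pd.DataFrame) -> AccuracyReport:
    """Aggregate per-trial accuracies across training-set realizations.

    ``results`` rows need columns (split, trial, model, r). Mean and 95% CI
    are computed on the z scale and back-transformed. Undefined (NaN)
    correlations are dropped from the aggregation.
    """
    df = pd.concat(results, ignore_index=True) if isinstance(results, list) else results.copy()
    df = df.dropna(subset=["r"])
    df["z"] = fisher_z(df["r"].to_numpy())
    rows = []
    for model, grp in df.groupby("model"):
        zs = grp.groupby("split")["z"].mean()  # per-split mean accuracy
        zbar = zs.mean()
        se = zs.std(ddof=1) / np.sqrt(len(zs)) if len(zs) > 1 else 0.0
        rows.append(
            {
                "model": model,
                "mean_r": inverse_fisher_z(zbar),
                "ci_low": inverse_fisher_z(zbar - 1.96 * se),
                "ci_high": inverse_fisher_z(zbar + 1.96 * se),
                "n_splits": len(zs),
            }
        )
    return AccuracyReport(per_trial=df, summary=pd.DataFrame(rows))


def trial_accuracies(
    preds: PredictionModelResult, truth: METDataset, split: int
) -> pd.DataFrame:
    """Per-validation-trial Pearson r of predictions vs noise-free truth."""
    rows = []
    for j, col in enumerate(preds.valid_trials):
        t = truth.values[:, col]
        p = preds.predictions[:, j]
        if p.std() == 0 or t.std() == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(p, t)[0, 1])
        rows.append(
            {"split": split, "trial": truth.trials.iloc[col].get("trial", col),
             "model": preds.model, "r": r}
        )
    return pd.DataFrame(rows)
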