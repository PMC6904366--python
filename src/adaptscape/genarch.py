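"""Quantitative-genetic architecture of the crop-model parameters.

Twelve physiological parameters of the wheat growth surrogate are given an
additive genetic basis of 300 QTLs. Absolute additive effects follow gamma
marginals (fitted by maximum likelihood to empirical GWAS effects, or
package defaults); a Gaussian copula imposes correlation between the
absolute effects of designated parameter pairs; signs are allocated 50/50 at
random per parameter except for the targeted pairs, where a configurable
fraction (default 60%) of QTLs receive jointly coupled signs. Effects are
attached to randomly sampled SNPs, with the largest phenology effects
re-seated onto nine designated flowering-gene proxy loci. Genotype-specific
parameter values are the linear QTL sums rescaled to literature-based
ranges; architectures whose realized parameter correlations violate the
acceptance rules (untargeted |r| > 0.4, targeted |r − target| > 0.2) are
rejected and re-drawn from the sign-allocation step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .popgen import MarkerSet


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


__all__ = [
    "PARAMETER_NAMES",
    "ParameterSpec",
    "default_parameter_spec",
    "GammaMarginal",
    "CorrelationTarget",
    "default_targets",
    "QTLArchitecture",
    "GenotypeParameters",
    "fit_gamma",
    "sample_abs_effects",
    "allocate_signs",
    "sample_effects",
    "assign_to_snps",
    "genotype_parameters",
    "accept_architecture",
    "generate_architecture",
]

# the 12 genotype-specific parameters with literature-based population
# ranges (low, high) and the released-model default value
_PARAMETER_TABLE = [
    ("fr_lf_sen_rate", 0.028, 0.042, 0.035),
    ("grains_per_gram_stem", 20.0, 25.0, 25.0),
    ("ll_modifier", 0.9, 1.1, 1.0),
    ("max_grain_size", 0.03, 0.06, 0.041),
    ("photop_sens", 1.5, 3.0, 2.0),
    ("potential_grain_filling_rate", 0.0016, 0.0026, 0.0025),
    ("transp_eff_cf", 0.0045, 0.0065, 0.006),
    ("tt_floral_initiation", 455.0, 555.0, 555.0),
    ("vern_sens", 1.5, 2.5, 1.5),
    ("y_extinct_coef", 0.4, 0.6, 0.45),
    ("y_frac_leaf", 0.55, 0.65, 0.6),
    ("y_rue", 1.01, 1.4, 1.24),
]

PARAMETER_NAMES = [row[0] for row in _PARAMETER_TABLE]

PHENOLOGY_PARAMS = ("photop_sens", "vern_sens")

DEFAULT_N_QTL = 300
DEFAULT_JOINT_FRACTION = 0.60
UNTARGETED_MAX_ABS_R = 0.4
TARGETED_MAX_DEPARTURE = 0.2


@dataclass(frozen=True)
class ParameterSpec:
    """Ranges and defaults for the 12 genotype-specific parameters."""

    names: tuple[str, ...]
    low: np.ndarray
    high: np.ndarray
    default: np.ndarray

    def __post_init__(self):
        if len(self.names) != 12:
            raise ValueError("exactly 12 parameters expected")
        if np.any(self.low >= self.high):
            raise ValueError("low_lim must be < high_lim for every parameter")

    def index(self, name: str) -> int:
        return self.names.index(name)

    @property
    def midpoint(self) -> np.ndarray:
        """Range midpoints mu^p, the intercepts of the QTL model."""
        return 0.5 * (self.low + self.high)


def default_parameter_spec() -> ParameterSpec:
    tbl = np.array([r[1:] for r in _PARAMETER_TABLE], float)
    return ParameterSpec(
        names=tuple(PARAMETER_NAMES),
        low=tbl[:, 0],
        high=tbl[:, 1],
        default=tbl[:, 2],
    )


@dataclass(frozen=True)
class GammaMarginal:
    """Gamma marginal (shape, rate) for absolute additive effects."""

    shape: float
    rate: float

    def __post_init__(self):
        if self.shape <= 0 or self.rate <= 0:
            raise ValueError("gamma shape and rate must be positive")


# default marginal when no empirical GWAS effects are supplied: a
# leptokurtic many-small/few-large effect spectrum
DEFAULT_MARGINAL = GammaMarginal(shape=1.2, rate=25.0)


@dataclass(frozen=True)
class CorrelationTarget:
    """A targeted parameter-pair correlation with its joint-sign fraction."""

    param_a: str
    param_b: str
    target_r: float
    joint_fraction: float = DEFAULT_JOINT_FRACTION

    def __post_init__(self):
        if abs(self.target_r) > 1:
            raise ValueError("|target r| must be <= 1")
        if not 0 <= self.joint_fraction <= 1:
            raise ValueError("joint fraction must be in [0, 1]")
        for p in (self.param_a, self.param_b):
            if p not in PARAMETER_NAMES:
                raise ValueError(f"unknown parameter {p!r}")


def default_targets() -> list[CorrelationTarget]:
    """The three physiologically motivated parameter-pair correlations."""
    return [
        CorrelationTarget("transp_eff_cf", "y_rue", -0.40),
        CorrelationTarget("grains_per_gram_stem", "max_grain_size", -0.50),
        CorrelationTarget("max_grain_size", "potential_grain_filling_rate", +0.45),
    ]


@dataclass
class QTLArchitecture:
    """Sampled QTL effects with SNP assignment and realized-correlation audit."""

    snp_indices: np.ndarray  # (n_qtl,) distinct SNP column indices
    effects: np.ndarray  # (n_qtl, 12) signed additive effects
    mu: np.ndarray  # (12,) per-parameter range midpoints
    realized_corr: np.ndarray | None = None  # (12, 12)
    accepted: bool = False
    n_retries: int = 0

    @property
    def n_qtl(self) -> int:
        return self.effects.shape[0]

    def to_frame(self, markers: MarkerSet) -> pd.DataFrame:
        mp = markers.map.iloc[self.snp_indices]
        df = pd.DataFrame(
            {
                "qtl_id": np.arange(self.n_qtl),
                "snp_id": mp["snp_id"].to_numpy(),
                "chrom": mp["chrom"].to_numpy(),
                "pos_cM": mp["pos_cM"].to_numpy(),
            }
        )
        for j, name in enumerate(PARAMETER_NAMES):
            df[name] = self.effects[:, j]
        return df


@dataclass
class GenotypeParameters:
    """Genotype × parameter value matrix, rescaled to the spec ranges."""

    values: np.ndarray  # (n_geno, 12)
    spec: ParameterSpec
    architecture: QTLArchitecture | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.spec.names))

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.spec.index(name)]


# ---------------------------------------------------------------------------
# step 1: gamma marginals
# ---------------------------------------------------------------------------

def fit_gamma(effects_table: pd.DataFrame | np.ndarray) -> tuple[list[GammaMarginal], GammaMarginal]:
    """Fit gamma marginals to absolute empirical additive effects.

    ``effects_table`` holds one column of absolute additive effects per
    environment. Each column is fitted by maximum likelihood (location fixed
    at 0); the summary marginal is the element-wise median of shape and rate
    across environments.

    Returns ``(per_environment_marginals, median_marginal)``.
    """
    arr = np.asarray(effects_table, float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.size == 0:
        raise ValueError("empty effects table")
    if np.any(arr <= 0):
        raise ValueError("effects must be strictly positive absolute values")
    marginals = []
    for j in range(arr.shape[1]):
        col = arr[:, j]
        if np.ptp(col) == 0:
            raise ValueError(f"degenerate (constant) effects in column {j}")
        shape, _, scale = stats.gamma.fit(col, floc=0)
        marginals.append(GammaMarginal(shape=float(shape), rate=float(1.0 / scale)))
    med = GammaMarginal(
        shape=float(np.median([m.shape for m in marginals])),
        rate=float(np.median([m.rate for m in marginals])),
    )
    return marginals, med


# ---------------------------------------------------------------------------
# step 2: copula sampling of absolute effects + sign allocation
# ---------------------------------------------------------------------------

def _copula_correlation_matrix(targets, names) -> np.ndarray:
    """12×12 Gaussian-copula correlation: |target r| on targeted pairs."""
    R = np.eye(len(names))
    for t in targets:
        i, j = names.index(t.param_a), names.index(t.param_b)
        R[i, j] = R[j, i] = abs(t.target_r)
    # positive-definiteness check; failure names the offending pair
    try:
        np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        pairs = ", ".join(f"({t.param_a}, {t.param_b})" for t in targets)
        raise ValueError(f"copula correlation matrix not positive definite; targeted pairs: {pairs}")
    return R


def sample_abs_effects(
    marginals: list[GammaMarginal] | GammaMarginal,
    targets: list[CorrelationTarget],
    n_qtl: int = DEFAULT_N_QTL,
    seed: int | None = None,
) -> np.ndarray:
    """Sample absolute QTL effects from gamma marginals via a Gaussian copula.

    Targeted parameter pairs share copula correlation ``|target r|`` between
    their absolute effects; all other parameters are independent.
    """
    if n_qtl < 2:
        raise ValueError("n_qtl must be >= 2")
    if isinstance(marginals, GammaMarginal):
        marginals = [marginals] * 12
    if len(marginals) != 12:
        raise ValueError("one marginal per parameter (12) required")
    rng = np.random.default_rng(seed)
    R = _copula_correlation_matrix(targets, PARAMETER_NAMES)
    z = rng.multivariate_normal(np.zeros(12), R, size=n_qtl, method="cholesky")
    u = stats.norm.cdf(z)
    out = np.empty_like(u)
    for j, m in enumerate(marginals):
        out[:, j] = stats.gamma.ppf(u[:, j], a=m.shape, scale=1.0 / m.rate)
    return np.clip(out, 1e-12, None)


def allocate_signs(
    abs_effects: np.ndarray,
    targets: list[CorrelationTarget],
    seed: int | None = None,
) -> np.ndarray:
    """Attach signs to absolute effects: 50/50 random, pair-coupled for targets.

    Every parameter's signs are independent Rademacher draws, except the
    targeted pairs: a ``joint_fraction`` share of QTLs (chosen at random)
    receive coupled signs — identical for a positive target, opposite for a
    negative one — and the remainder stay independent. When a parameter sits
    in several targeted pairs it acts as the anchor: its own signs are drawn
    once, and each partner is coupled to it.
    """
    rng = np.random.default_rng(seed)
    n_qtl, n_par = abs_effects.shape
    signs = rng.choice([-1.0, 1.0], size=(n_qtl, n_par))
    # anchor ordering: parameters appearing in >1 pair keep their own signs
    counts: dict[str, int] = {}
    for t in targets:
        counts[t.param_a] = counts.get(t.param_a, 0) + 1
        counts[t.param_b] = counts.get(t.param_b, 0) + 1
    for t in targets:
        ia, ib = PARAMETER_NAMES.index(t.param_a), PARAMETER_NAMES.index(t.param_b)
        # couple the non-anchor side to the anchor side
        if counts[t.param_a] >= counts[t.param_b]:
            src, dst = ia, ib
        else:
            src, dst = ib, ia
        n_joint = int(round(t.joint_fraction * n_qtl))
        coupled = rng.choice(n_qtl, size=n_joint, replace=False)
        parity = 1.0 if t.target_r > 0 else -1.0
        signs[coupled, dst] = parity * signs[coupled, src]
    return abs_effects * signs


def sample_effects(
    marginals: list[GammaMarginal] | GammaMarginal,
    targets: list[CorrelationTarget],
    n_qtl: int = DEFAULT_N_QTL,
    seed: int | None = None,
) -> np.ndarray:
    """Signed QTL effect matrix: copula-sampled magnitudes + sign allocation."""
    ss = _as_seedseq(seed).spawn(2)
    abs_eff = sample_abs_effects(marginals, targets, n_qtl, seed=ss[0])
    return allocate_signs(abs_eff, targets, seed=ss[1])


# ---------------------------------------------------------------------------
# step 3: SNP assignment
# ---------------------------------------------------------------------------

def assign_to_snps(
    effects: np.ndarray,
    markers: MarkerSet,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Attach QTL effects to uniformly sampled SNPs.

    Returns ``(snp_indices, effects)`` where ``effects`` may have its
    phenology columns permuted: for photoperiod and vernalization
    sensitivity the nine largest-magnitude effects are re-seated onto the
    QTLs occupying the designated flowering-gene proxy loci.
    """
    n_qtl = effects.shape[0]
    if n_qtl > markers.n_snp:
        raise ValueError(f"n_qtl ({n_qtl}) exceeds number of SNPs ({markers.n_snp})")
    if markers.designated_loci.size < 9:
        raise ValueError("markers must carry 9 designated loci")
    rng = np.random.default_rng(seed)
    snp_indices = rng.choice(markers.n_snp, size=n_qtl, replace=False)
    # force the designated loci into the QTL set
    missing = np.setdiff1d(markers.designated_loci, snp_indices)
    if missing.size:
        non_designated = np.flatnonzero(~np.isin(snp_indices, markers.designated_loci))
        swap = rng.choice(non_designated, size=missing.size, replace=False)
        snp_indices[swap] = missing

    effects = effects.copy()
    designated_qtls = np.flatnonzero(np.isin(snp_indices, markers.designated_loci))
    for name in PHENOLOGY_PARAMS:
        j = PARAMETER_NAMES.index(name)
        col = effects[:, j]
        top9 = np.argsort(np.abs(col))[::-1][:9]
        # swap the top-9 magnitudes onto the designated QTLs
        others = np.setdiff1d(np.arange(n_qtl), np.union1d(top9, designated_qtls))
        new_col = col.copy()
        src = list(top9)
        dst = list(designated_qtls)
        displaced = [q for q in designated_qtls if q not in top9]
        vacated = [q for q in top9 if q not in designated_qtls]
        # place top-9 values on designated QTLs (order by magnitude)
        vals_top = col[top9]
        vals_displaced = col[displaced]
        new_col[designated_qtls] = vals_top[: len(dst)]
        new_col[vacated] = vals_displaced[: len(vacated)]
        effects[:, j] = new_col
        del src, others
    return snp_indices, effects


# ---------------------------------------------------------------------------
# steps 4-5: genotype parameter values, rescaling, acceptance
# ---------------------------------------------------------------------------

def genotype_parameters(
    markers: MarkerSet,
    architecture: QTLArchitecture,
    spec: ParameterSpec | None = None,
    force: bool = False,
    rescale: bool = True,
) -> GenotypeParameters:
    """Genotype-specific parameter values from the additive QTL model.

    ``y_i^p = mu^p + sum_q x_iq * alpha_q^p`` with ``x_iq in {-1, 0, 1}``
    (minor-allele dosage − 1); with ``rescale`` each column is affinely
    mapped so its min/max hit the spec's ``[low, high]`` range.
    """
    if spec is None:
        spec = default_parameter_spec()
    if not architecture.accepted and not force and rescale:
        raise ValueError("architecture not accepted; pass force=True to override")
    X = markers.signed_dosage()[:, architecture.snp_indices]  # (n_geno, n_qtl)
    raw = spec.midpoint[None, :] + X @ architecture.effects
    if not rescale:
        return GenotypeParameters(values=raw, spec=spec, architecture=architecture)
    lo, hi = raw.min(axis=0), raw.max(axis=0)
    span = hi - lo
    dead = span <= 0
    if np.any(dead):
        names = [spec.names[j] for j in np.flatnonzero(dead)]
        raise ValueError(f"zero genetic variance for parameter(s): {', '.join(names)}")
    scaled = spec.low + (raw - lo) / span * (spec.high - spec.low)
    return GenotypeParameters(values=scaled, spec=spec, architecture=architecture)


def accept_architecture(
    params: GenotypeParameters,
    targets: list[CorrelationTarget],
) -> tuple[bool, np.ndarray]:
    """Audit realized parameter correlations against the acceptance rules.

    Accepted iff every untargeted pair has ``|r| <= 0.4`` and every targeted
    pair is within ``±0.2`` of its target. Returns ``(accepted, corr)``.
    """
    corr = np.corrcoef(params.values, rowvar=False)
    names = list(params.spec.names)
    targeted = {frozenset((t.param_a, t.param_b)): t.target_r for t in targets}
    ok = True
    for i in range(12):
        for j in range(i + 1, 12):
            key = frozenset((names[i], names[j]))
            r = corr[i, j]
            if key in targeted:
                if abs(r - targeted[key]) > TARGETED_MAX_DEPARTURE:
                    ok = False
            elif abs(r) > UNTARGETED_MAX_ABS_R:
                ok = False
    return ok, corr


def generate_architecture(
    markers: MarkerSet,
    marginals: list[GammaMarginal] | GammaMarginal | None = None,
    targets: list[CorrelationTarget] | None = None,
    spec: ParameterSpec | None = None,
    n_qtl: int = DEFAULT_N_QTL,
    seed: int | None = None,
    max_retries: int = 200,
    on_fail: str = "raise",
) -> tuple[QTLArchitecture, GenotypeParameters]:
    """Full architecture procedure with the rejection loop.

    The copula draw of absolute effects is made once; on rejection the
    procedure re-runs from sign allocation onward (fresh signs and SNP
    assignment) until the realized correlations pass, up to ``max_retries``.
    With ``on_fail="best"`` an exhausted loop returns the attempt with the
    smallest rule violation, flagged unaccepted, instead of raising — small
    panels cannot reliably satisfy the audit because the 66 pairwise
    correlations are noisy at low genotype counts.
    """
    if marginals is None:
        marginals = DEFAULT_MARGINAL
    if targets is None:
        targets = default_targets()
    if spec is None:
        spec = default_parameter_spec()
    ss = _as_seedseq(seed)
    abs_seed, *retry_seeds = ss.spawn(2 * max_retries + 1)
    abs_eff = sample_abs_effects(marginals, targets, n_qtl, seed=abs_seed)

    names = list(spec.names)
    targeted = {frozenset((t.param_a, t.param_b)): t.target_r for t in targets}

    def violation(corr: np.ndarray) -> float:
        worst = 0.0
        for i in range(12):
            for j in range(i + 1, 12):
                key = frozenset((names[i], names[j]))
                if key in targeted:
                    worst = max(worst, abs(corr[i, j] - targeted[key]) - TARGETED_MAX_DEPARTURE)
                else:
                    worst = max(worst, abs(corr[i, j]) - UNTARGETED_MAX_ABS_R)
        return worst

    best: tuple[float, QTLArchitecture, GenotypeParameters] | None = None
    for attempt in range(max_retries):
        s_sign, s_assign = retry_seeds[2 * attempt], retry_seeds[2 * attempt + 1]
        eff = allocate_signs(abs_eff, targets, seed=s_sign)
        snp_idx, eff = assign_to_snps(eff, markers, seed=s_assign)
        arch = QTLArchitecture(
            snp_indices=snp_idx, effects=eff, mu=spec.midpoint, n_retries=attempt
        )
        params = genotype_parameters(markers, arch, spec, force=True)
        accepted, corr = accept_architecture(params, targets)
        arch.realized_corr = corr
        arch.accepted = accepted
        if accepted:
            params.architecture = arch
            return arch, params
        v = violation(corr)
        if best is None or v < best[0]:
            best = (v, arch, params)
    if on_fail == "best" and best is not None:
        _, arch, params = best
        params.architecture = arch
        return arch, params
    raise RuntimeError(
        f"architecture rejected after {max_retries} retries; last audit "
        f"violation {best[0]:.3f} beyond the rules"
    )
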