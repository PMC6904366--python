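"""Structured marker panels, kinship, population structure, and per-SNP Fst.

The marker simulator emulates an association panel with discrete
subpopulations using the Balding–Nichols model: each SNP draws an ancestral
allele frequency, and every subpopulation draws its own frequency from a Beta
distribution whose concentration is governed by a per-SNP differentiation
parameter. Kinship follows the standardized cross-product form
``A = XX' / n_m``; population structure is read off the significant
eigenvectors of ``A`` (Tracy–Widom test) followed by hierarchical clustering;
per-SNP differentiation uses the Weir–Cockerham theta estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "MarkerSet",
    "Kinship",
    "simulate_markers",
    "kinship",
    "structure_decompose",
    "snp_fst",
    "read_dosage_table",
    "write_dosage_table",
    "read_vcf",
]

# Fst differentiation targets for the nine designated flowering-gene proxy
# loci: moderate-to-large values spanning ~0.11-0.72 with median 0.50.
DESIGNATED_FST_TARGETS = np.array(
    [0.11, 0.21, 0.31, 0.40, 0.50, 0.56, 0.61, 0.67, 0.72]
)

N_DESIGNATED = 9

# Multipliers applied to the per-SNP Balding-Nichols differentiation draw.
_FST_LEVELS = {"low": 0.30, "moderate": 1.00, "high": 1.50}


@dataclass
class MarkerSet:
    """A genotype × SNP dosage panel with map and structure annotations.

    Attributes
    ----------
    genotypes : (n_geno, n_snp) int array of minor-allele dosages in {0,1,2}.
    map : DataFrame with columns snp_id, chrom, pos_cM (positions
        non-decreasing within chromosome).
    subpop : optional (n_geno,) integer subpopulation labels.
    designated_loci : indices of the nine SNPs flagged as flowering-gene
        proxies (distinct, within range).
    """

    genotypes: np.ndarray
    map: pd.DataFrame
    subpop: np.ndarray | None = None
    designated_loci: np.ndarray = field(default_factory=lambda: np.array([], int))

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        if not np.isin(self.genotypes, [0, 1, 2]).all():
            raise ValueError("dosages must be in {0, 1, 2}")
        if len(self.map) != self.n_snp:
            raise ValueError("map length does not match number of SNPs")
        d = np.asarray(self.designated_loci, dtype=int)
        if d.size and (len(np.unique(d)) != d.size or d.min() < 0 or d.max() >= self.n_snp):
            raise ValueError("designated loci must be distinct and in range")
        self.designated_loci = d
        for _, grp in self.map.groupby("chrom"):
            if not np.all(np.diff(grp["pos_cM"].to_numpy()) >= 0):
                raise ValueError("map positions must be non-decreasing within chromosome")

    @property
    def n_geno(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snp(self) -> int:
        return self.genotypes.shape[1]

    @property
    def maf(self) -> np.ndarray:
        """Per-SNP minor-allele frequency."""
        p = self.genotypes.mean(axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def signed_dosage(self) -> np.ndarray:
        """Dosage recoded to −1/0/1 (dosage − 1), the QTL design coding."""
        return self.genotypes.astype(float) - 1.0


@dataclass
class Kinship:
    """Symmetric genomic relationship matrix with the SNP scope recorded."""

    matrix: np.ndarray
    scope: str = "all-chromosomes"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("kinship must be square")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("kinship must be symmetric")
        if np.any(np.diag(m) <= 0):
            raise ValueError("kinship diagonal must be strictly positive")
        self.matrix = m

    @property
    def n_geno(self) -> int:
        return self.matrix.shape[0]


def _balding_nichols_freqs(rng, n_snp, n_subpop, fst_scale):
    """Ancestral + subpopulation allele frequencies under Balding–Nichols."""
    p_anc = rng.uniform(0.05, 0.95, size=n_snp)
    f = np.clip(fst_scale * rng.beta(1.2, 3.5, size=n_snp), 1e-4, 0.93)
    a = p_anc * (1.0 - f) / f
    b = (1.0 - p_anc) * (1.0 - f) / f
    return rng.beta(a[None, :], b[None, :], size=(n_subpop, n_snp))


def simulate_markers(
    n_geno: int = 199,
    n_snp: int = 3035,
    n_subpop: int = 5,
    fst_level: str | float = "moderate",
    maf_min: float = 0.02,
    n_chrom: int = 21,
    seed: int | None = None,
) -> MarkerSet:
    """Simulate a structured SNP panel emulating an association-mapping panel.

    Subpopulation allele frequencies follow the Balding–Nichols model;
    ``fst_level`` ("low" | "moderate" | "high", or a positive multiplier)
    scales the per-SNP differentiation draw. SNPs failing the ``maf_min``
    filter are discarded (the simulator oversamples to compensate); nine
    designated flowering-gene proxy loci are chosen so their realized Fst
    spans moderate-to-large values (~0.11–0.72).

    Raises
    ------
    ValueError
        If fewer than ``n_snp`` SNPs survive the MAF filter.
    """
    if n_subpop < 1:
        raise ValueError("n_subpop must be >= 1")
    if not 0 < maf_min < 0.5:
        raise ValueError("maf_min must be in (0, 0.5)")
    fst_scale = _FST_LEVELS[fst_level] if isinstance(fst_level, str) else float(fst_level)
    rng = np.random.default_rng(seed)

    # near-equal subpopulation sizes
    sizes = np.full(n_subpop, n_geno // n_subpop)
    sizes[: n_geno % n_subpop] += 1
    subpop = np.repeat(np.arange(n_subpop), sizes)

    n_draw = int(np.ceil(n_snp * 1.8)) + 50
    freqs = _balding_nichols_freqs(rng, n_draw, n_subpop, fst_scale)
    dos = rng.binomial(2, freqs[subpop, :])
    p = dos.mean(axis=0) / 2.0
    keep = np.minimum(p, 1 - p) >= maf_min
    if keep.sum() < n_snp:
        raise ValueError(
            f"only {keep.sum()} of {n_draw} simulated SNPs passed the MAF "
            f"filter (need {n_snp}); lower maf_min or n_snp"
        )
    idx = np.flatnonzero(keep)[:n_snp]
    dos = dos[:, idx]

    # genetic map: SNPs spread uniformly over n_chrom chromosomes
    chrom = rng.integers(1, n_chrom + 1, size=n_snp)
    pos = np.round(rng.uniform(0.0, 150.0, size=n_snp), 2)
    order = np.lexsort((pos, chrom))
    dos = dos[:, order]
    mp = pd.DataFrame(
        {
            "snp_id": [f"mk{i:04d}" for i in range(n_snp)],
            "chrom": chrom[order],
            "pos_cM": pos[order],
        }
    )

    ms = MarkerSet(genotypes=dos, map=mp, subpop=subpop)
    if n_subpop >= 2:
        fst = snp_fst(ms)
        designated = np.empty(N_DESIGNATED, dtype=int)
        taken = np.zeros(ms.n_snp, bool)
        for i, target in enumerate(DESIGNATED_FST_TARGETS):
            d = np.abs(fst - target)
            d[taken] = np.inf
            j = int(np.argmin(d))
            designated[i] = j
            taken[j] = True
        ms.designated_loci = np.sort(designated)
    else:
        # no structure: any nine distinct loci serve as the proxies
        ms.designated_loci = rng.choice(ms.n_snp, size=N_DESIGNATED, replace=False)
        ms.designated_loci.sort()
    return ms


def kinship(
    markers: MarkerSet,
    exclude_chrom: int | None = None,
    scale: str = "binomial",
) -> Kinship:
    """Genomic relationship matrix ``A = XX'/n_m`` from standardized dosages.

    Dosages are centered at ``2p`` per SNP and scaled by ``sqrt(2p(1-p))``
    (``scale="binomial"``) or by the empirical standard deviation
    (``scale="empirical"``; then trace(A) = n exactly and off-diagonal
    entries average −1/(n−1)). With ``exclude_chrom`` the SNPs of that
    chromosome are left out, giving the leave-one-chromosome-out kinship
    used as the polygenic background in GWAS.
    """
    if markers.n_geno < 2:
        raise ValueError("kinship needs at least two genotypes")
    use = np.ones(markers.n_snp, bool)
    scope = "all-chromosomes"
    if exclude_chrom is not None:
        use = markers.map["chrom"].to_numpy() != exclude_chrom
        if not use.any():
            raise ValueError(f"no SNPs remain after excluding chromosome {exclude_chrom}")
        scope = f"excluding-chromosome-{exclude_chrom}"
    G = markers.genotypes[:, use].astype(float)
    p = G.mean(axis=0) / 2.0
    if scale == "binomial":
        sd = np.sqrt(2.0 * p * (1.0 - p))
    elif scale == "empirical":
        sd = G.std(axis=0, ddof=0)
    else:
        raise ValueError("scale must be 'binomial' or 'empirical'")
    ok = sd > 0
    if not ok.all():
        warnings.warn(f"excluding {np.sum(~ok)} zero-variance SNPs from kinship")
        G, p, sd = G[:, ok], p[ok], sd[ok]
    X = (G - 2.0 * p) / sd
    A = X @ X.T / X.shape[1]
    # guard against numerically non-positive diagonal on degenerate panels
    np.fill_diagonal(A, np.maximum(np.diag(A), 1e-12))
    return Kinship(matrix=0.5 * (A + A.T), scope=scope)


# 95th / 99th / 99.9th percentiles of the Tracy-Widom (beta=1) distribution
_TW_CRITICAL = {0.05: 0.9793, 0.01: 2.0234, 0.001: 3.2724}


def _tw_significant_pcs(eigvals: np.ndarray, alpha: float) -> int:
    """Number of significant leading eigenvalues by the Tracy–Widom test.

    Follows the eigenanalysis procedure of Patterson et al.: the effective
    number of underlying variables is estimated from the moments of the
    remaining eigenvalue spectrum, the leading eigenvalue is standardized
    with the Tracy–Widom centering/scaling constants, and eigenvalues are
    peeled off while significant.
    """
    crit = _TW_CRITICAL.get(round(alpha, 4))
    if crit is None:
        raise ValueError(f"alpha must be one of {sorted(_TW_CRITICAL)}")
    lam = np.sort(eigvals[eigvals > 1e-10])[::-1]
    n_sig = 0
    while lam.size >= 3:
        m = lam.size
        s1, s2 = lam.sum(), np.sum(lam**2)
        n_hat = (m + 2) * s1**2 / (m * s2 - s1**2)
        if n_hat <= 1:
            break
        ell = m * lam[0] / s1
        sq_n, sq_m = np.sqrt(n_hat - 1), np.sqrt(m)
        mu = (sq_n + sq_m) ** 2 / n_hat
        sigma = (sq_n + sq_m) / n_hat * (1.0 / sq_n + 1.0 / sq_m) ** (1.0 / 3.0)
        if (ell - mu) / sigma <= crit:
            break
        n_sig += 1
        lam = lam[1:]
    return n_sig


def structure_decompose(
    kin: Kinship, alpha: float = 0.05
) -> tuple[np.ndarray, int, np.ndarray]:
    """Spectral decomposition of kinship with structure assignment.

    Returns ``(pcs, n_significant, labels)``: all principal component
    coordinates (columns ordered by decreasing eigenvalue and scaled by the
    square root of the eigenvalue), the Tracy–Widom count of significant
    axes, and a hierarchical (Ward) clustering of the significant axes into
    ``n_significant + 1`` groups. With no significant axis a single cluster
    is returned.
    """
    A = kin.matrix
    vals, vecs = np.linalg.eigh(A)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vals = np.clip(vals, 0.0, None)
    pcs = vecs * np.sqrt(vals)[None, :]
    n_sig = _tw_significant_pcs(vals, alpha)
    if n_sig == 0:
        labels = np.zeros(A.shape[0], dtype=int)
    else:
        Z = linkage(pcs[:, :n_sig], method="ward")
        labels = fcluster(Z, t=n_sig + 1, criterion="maxclust") - 1
    return pcs, n_sig, labels


def snp_fst(markers: MarkerSet) -> np.ndarray:
    """Per-SNP Weir–Cockerham theta across the recorded subpopulations.

    Negative estimates are clamped to 0; monomorphic SNPs get Fst 0.
    """
    if markers.subpop is None:
        raise ValueError("subpopulation labels required for Fst")
    labels = np.asarray(markers.subpop)
    pops = np.unique(labels)
    r = pops.size
    if r < 2:
        raise ValueError("at least two subpopulations required for Fst")
    G = markers.genotypes
    n_i = np.array([(labels == k).sum() for k in pops], float)  # diploid counts
    p_i = np.stack([G[labels == k].mean(axis=0) / 2.0 for k in pops])  # (r, snp)
    h_i = np.stack([(G[labels == k] == 1).mean(axis=0) for k in pops])  # obs het

    n_bar = n_i.mean()
    n_c = (r * n_bar - np.sum(n_i**2) / (r * n_bar)) / (r - 1)
    w = (n_i / (r * n_bar))[:, None]
    p_bar = np.sum(w * p_i, axis=0)
    s2 = np.sum(w * (p_i - p_bar) ** 2, axis=0) * r / (r - 1)
    h_bar = np.sum(w * h_i, axis=0)

    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4.0) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2.0
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(denom > 0, a / denom, 0.0)
    return np.clip(fst, 0.0, 1.0)


# ---------------------------------------------------------------------------
# marker I/O
# ---------------------------------------------------------------------------

def write_dosage_table(markers: MarkerSet, dosage_path, map_path) -> None:
    """Write a tab-delimited dosage table (genotypes × SNPs) and its map."""
    snp_ids = markers.map["snp_id"].tolist()
    df = pd.DataFrame(markers.genotypes, columns=snp_ids)
    df.insert(0, "genotype", [f"g{i:03d}" for i in range(markers.n_geno)])
    df.to_csv(dosage_path, sep="\t", index=False)
    markers.map.to_csv(map_path, sep="\t", index=False)


def read_dosage_table(dosage_path, map_path) -> MarkerSet:
    """Read the tab-delimited dosage table + map written by this package."""
    df = pd.read_csv(dosage_path, sep="\t")
    mp = pd.read_csv(map_path, sep="\t")
    dos = df.drop(columns=["genotype"]).to_numpy(dtype=int)
    return MarkerSet(genotypes=dos, map=mp)


def read_vcf(path, maf_min: float = 0.0) -> MarkerSet:
    """Read biallelic SNP genotypes from a VCF into minor-allele dosages.

    Positions are taken as cM directly (the package's maps are genetic).
    Requires cyvcf2 (optional dependency).
    """
    from cyvcf2 import VCF  # optional, only needed for VCF ingest

    rows, chroms, poss, ids = [], [], [], []
    for var in VCF(str(path)):
        if len(var.ALT) != 1 or not var.is_snp:
            continue
        d = np.array([g[0] + g[1] for g in var.genotypes], dtype=int)
        d = np.clip(d, 0, 2)
        p = d.mean() / 2.0
        if p > 0.5:  # recode to minor-allele dosage
            d = 2 - d
            p = 1 - p
        if p < maf_min:
            continue
        rows.append(d)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        ids.append(var.ID or f"{var.CHROM}_{var.POS}")
    if not rows:
        raise ValueError("no biallelic SNPs read from VCF")
    mp = pd.DataFrame({"snp_id": ids, "chrom": chroms, "pos_cM": poss})
    return MarkerSet(genotypes=np.stack(rows).T, map=mp)
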