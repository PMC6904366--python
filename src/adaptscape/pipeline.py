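"""Orchestration: configuration, end-to-end runs, and toy fixtures.

``run_full`` ties the seven analysis stages into a reproducible pipeline:
marker simulation → genetic architecture → TPE weather → surrogate MET →
environment typing → G×E analyses → genomic prediction. Every source of
randomness derives from the config's master seed through named
SeedSequence spawns, so a run is reproducible from the config alone; the
returned manifest records the per-stage seeds and content hashes of the
persisted tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cropsim, envgen, envtype, genarch, gxe, popgen, predict
from ._version import __version__

__all__ = ["RunConfig", "run_full", "fixture_generator", "load_config"]


@dataclass
class RunConfig:
    """Serializable configuration for an end-to-end run."""

    seed: int = 1
    # panel
    n_geno: int = 199
    n_snp: int = 3035
    n_subpop: int = 5
    fst_level: str | float = "moderate"
    maf_min: float = 0.02
    n_chrom: int = 21
    # genarch
    n_qtl: int = 300
    gamma_shape: float = 1.2
    gamma_rate: float = 25.0
    max_retries: int = 200
    arch_on_fail: str = "best"  # tiny panels cannot meet the audit rules
    # TPE
    sites: list[str] | None = None  # None -> all four archetypes
    n_years: int = 31
    # analysis / prediction
    n_ets: int = 4
    h2_yield: float = 0.5
    h2_params: float = 0.7
    n_splits: int = 20
    per_et: int = 4
    freg_alpha: float = 0.01
    out_dir: str | None = None

    def validate(self) -> "RunConfig":
        if self.n_geno < 2 or self.n_snp < self.n_qtl:
            raise ValueError("panel too small for the requested architecture")
        if not 0 < self.h2_yield <= 1 or not 0 < self.h2_params <= 1:
            raise ValueError("heritabilities must be in (0, 1]")
        if self.n_years < 1 or self.n_ets < 2:
            raise ValueError("need >=1 year and >=2 environment types")
        return self

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw).validate()


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.to_csv(index=True, float_format="%.10g").encode()
    ).hexdigest()[:16]


def _stage_seed(ss: np.random.SeedSequence, k: int) -> np.random.SeedSequence:
    return ss.spawn(k + 1)[k]


def run_full(config: RunConfig, write: bool = True) -> dict:
    """Execute the full pipeline; returns the run manifest.

    The manifest records the package version, per-stage seeds, stage
    outputs' content hashes, and headline numbers (panel shape, trial count,
    ET frequencies, G×E shares, model accuracies). With ``write`` and a
    configured output directory, stage tables are persisted as CSV.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.spawn(8)
    manifest: dict = {"version": __version__, "config": asdict(config), "stages": {}}
    out = Path(config.out_dir) if (write and config.out_dir) else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    def record(stage, **info):
        manifest["stages"][stage] = info

    # 1. markers -------------------------------------------------------------
    markers = popgen.simulate_markers(
        config.n_geno, config.n_snp, config.n_subpop, config.fst_level,
        config.maf_min, config.n_chrom, seed=seeds[0],
    )
    kin = popgen.kinship(markers)
    record("popgen", n_geno=markers.n_geno, n_snp=markers.n_snp,
           designated=markers.designated_loci.tolist())

    # 2. genetic architecture ------------------------------------------------
    marginal = genarch.GammaMarginal(config.gamma_shape, config.gamma_rate)
    arch, params = genarch.generate_architecture(
        markers, marginals=marginal, n_qtl=config.n_qtl, seed=seeds[1],
        max_retries=config.max_retries, on_fail=config.arch_on_fail,
    )
    record("genarch", n_retries=arch.n_retries, accepted=bool(arch.accepted),
           realized_target_corrs={
               f"{t.param_a}:{t.param_b}": round(float(
                   arch.realized_corr[genarch.PARAMETER_NAMES.index(t.param_a),
                                      genarch.PARAMETER_NAMES.index(t.param_b)]), 3)
               for t in genarch.default_targets()
           })
    if out:
        pf = params.to_frame()
        pf.to_csv(out / "genotype_parameters.csv", index=False)
        record("genarch", **manifest["stages"]["genarch"], hash=_hash_frame(pf))

    # 3. TPE weather ---------------------------------------------------------
    archetypes = envgen.default_archetypes()
    if config.sites:
        archetypes = [a for a in archetypes if a.name in config.sites]
    trials = envgen.build_tpe(archetypes, n_years=config.n_years,
                              master_seed=seeds[2])
    record("envgen", n_trials=len(trials), sites=[a.name for a in archetypes])

    # 4. surrogate MET -------------------------------------------------------
    Y, B, _, _ = cropsim.run_met(params.values, trials)
    trial_meta = pd.DataFrame(
        {"trial": [t.name for t in trials],
         "location": [t.site.name for t in trials],
         "year": [t.year_index for t in trials]}
    )
    record("cropsim", mean_yield=float(Y.mean()), mean_biomass=float(B.mean()))

    # 5. environment typing --------------------------------------------------
    curves = envtype.build_stress_curves(trials)
    ets = envtype.classify(curves, k=config.n_ets)
    trial_meta["et"] = [ets.labels[t.name] for t in trials]
    for t in trials:
        t.et_label = ets.labels[t.name]
    covs = envtype.covariable_table(trials)
    record("envtype", et_counts=trial_meta["et"].value_counts().to_dict())

    # 6. G×E analyses --------------------------------------------------------
    met = gxe.METDataset(values=Y, trials=trial_meta)
    am = gxe.ammi(met, M=2)
    shares = {}
    if config.n_years >= 2 and len(archetypes) >= 2:
        vc3 = gxe.varcomp(met, model="three_way")
        shares["three_way"] = gxe.gxe_shares(vc3)
    vc_et = gxe.varcomp(met, model="et_nested")
    shares["et_nested"] = gxe.gxe_shares(vc_et)
    record("gxe", singular_values=np.round(am.singular_values, 2).tolist(),
           shares=shares)

    # 7. genomic prediction --------------------------------------------------
    noisy = predict.add_noise(met, config.h2_yield, seed=seeds[3])
    plan = predict.make_training_plan(trial_meta, n_splits=config.n_splits,
                                      per_et=config.per_et, seed=seeds[4])
    sim, covs_used = predict.env_kinship(covs)
    gp = predict.geno_pcs(kin, 4)
    ep = predict.env_pcs(sim, 3)
    products = predict.cross_products(gp, ep)
    param_noisy = predict.add_noise(
        gxe.METDataset(values=params.values,
                       trials=pd.DataFrame({"trial": list(params.spec.names)})),
        config.h2_params, seed=seeds[5],
    )
    param_phen = pd.DataFrame(param_noisy.noisy.values,
                              columns=list(params.spec.names))
    accs = []
    for s, split in enumerate(plan.splits):
        tr_cols, va_cols = split["train"], split["valid"]
        train = gxe.METDataset(values=noisy.noisy.values[:, tr_cols],
                               trials=trial_meta.iloc[tr_cols].reset_index(drop=True),
                               noise_free=False)
        va_et = trial_meta["et"].to_numpy()[va_cols]
        fits = [
            predict.fit_etmean(train, kin, va_cols, va_et),
            predict.fit_meanpc(train, products, tr_cols, va_cols, va_et),
            predict.fit_indivpc(train, products, tr_cols, va_cols, va_et),
            predict.fit_freg(train, param_phen, covs, tr_cols, va_cols, va_et,
                             alpha=config.freg_alpha),
        ]
        for f in fits:
            accs.append(predict.trial_accuracies(f, met, split=s))
    report = predict.accuracy(accs)
    record("predict", summary=report.summary.round(3).to_dict("records"))

    if out:
        trial_meta.to_csv(out / "trials.csv", index=False)
        covs.to_csv(out / "covariables.csv")
        pd.DataFrame(Y).to_csv(out / "yield.csv", index=False)
        report.summary.to_csv(out / "accuracy.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return manifest


# ---------------------------------------------------------------------------
# toy fixtures shared across test suites
# ---------------------------------------------------------------------------

def fixture_generator(profile: str, seed: int = 0):
    """Small deterministic datasets for worked examples and tests.

    Profiles: ``kinship_toy`` (3 genotypes × 2 SNPs), ``ammi_toy`` (4×3
    two-way table with nonzero interaction), ``varcomp_toy`` (balanced
    genotype × location × year data with known components), ``weather_toy``
    (3-day constant weather for hand-stepping), ``freg_toy`` (planted
    parameter × covariable signal), ``gwas_toy`` (planted single-SNP
    signal).
    """
    rng = np.random.default_rng(seed)
    if profile == "kinship_toy":
        dos = np.array([[0, 2], [1, 1], [2, 0]])
        mp = pd.DataFrame({"snp_id": ["s1", "s2"], "chrom": [1, 1],
                           "pos_cM": [10.0, 20.0]})
        return popgen.MarkerSet(genotypes=dos, map=mp)
    if profile == "ammi_toy":
        g = np.array([2.0, 0.0, -1.0, -1.0])
        e = np.array([1.0, 0.0, -1.0])
        inter = np.array([[1.0, -0.5, -0.5],
                          [-1.0, 0.5, 0.5],
                          [0.5, 0.0, -0.5],
                          [-0.5, 0.0, 0.5]])
        inter -= inter.mean(axis=0, keepdims=True)
        inter -= inter.mean(axis=1, keepdims=True)
        return 10.0 + g[:, None] + e[None, :] + inter
    if profile == "varcomp_toy":
        comps = {"Genotype": 1.0, "Genotype.Location": 0.5,
                 "Genotype.Year": 0.25, "Genotype.Location.Year": 0.4}
        n_g, n_l, n_y = 40, 4, 6
        G = rng.normal(0, np.sqrt(comps["Genotype"]), n_g)
        GL = rng.normal(0, np.sqrt(comps["Genotype.Location"]), (n_g, n_l))
        GY = rng.normal(0, np.sqrt(comps["Genotype.Year"]), (n_g, n_y))
        GLY = rng.normal(0, np.sqrt(comps["Genotype.Location.Year"]),
                         (n_g, n_l, n_y))
        mu_env = rng.normal(0, 1, (n_l, n_y))
        Y = (mu_env[None] + G[:, None, None] + GL[:, :, None]
             + GY[:, None, :] + GLY)
        trials = pd.DataFrame(
            [{"trial": f"L{l}_Y{y}", "location": l, "year": y}
             for l in range(n_l) for y in range(n_y)]
        )
        met = gxe.METDataset(values=Y.reshape(n_g, n_l * n_y), trials=trials)
        return met, comps
    if profile == "weather_toy":
        arch = envgen.SiteArchetype(
            name="Toy", latitude=-30.0, annual_rain=300.0, seasonal_rain=150.0,
            rain_pattern="even", tmean=20.0, radiation=20.0, pawc=100.0,
            sowing_paw=80.0, sowing_doy=1,
        )
        n = 3
        wx = envgen.WeatherSeries(
            doy=np.arange(1, n + 1), tmin=np.full(n, 14.0),
            tmax=np.full(n, 26.0), radn=np.full(n, 20.0),
            rain=np.zeros(n), latitude=arch.latitude, site=arch.name,
        )
        return envgen.TrialEnvironment(site=arch, year_index=0, weather=wx,
                                       pawc=arch.pawc, initial_paw=80.0)
    if profile == "freg_toy":
        n_geno, n_trial = 60, 24
        y_rue = rng.normal(0, 1, n_geno)
        other = rng.normal(0, 1, (n_geno, 2))
        sd_p3 = rng.normal(0, 1, n_trial)
        noise_cov = rng.normal(0, 1, (n_trial, 3))
        Y = 2.0 * np.outer(y_rue, sd_p3) + rng.normal(0, 0.5, (n_geno, n_trial))
        params = pd.DataFrame(
            np.column_stack([y_rue, other]), columns=["y_rue", "pA", "pB"]
        )
        covs = pd.DataFrame(
            np.column_stack([sd_p3, noise_cov]),
            columns=["sd_P3", "c1", "c2", "c3"],
        )
        ets = np.tile(["ET1", "ET2", "ET3", "ET4"], n_trial // 4)
        trials = pd.DataFrame({"trial": [f"t{j}" for j in range(n_trial)],
                               "et": ets})
        met = gxe.METDataset(values=Y, trials=trials)
        return met, params, covs
    if profile == "gwas_toy":
        ms = popgen.simulate_markers(n_geno=80, n_snp=200, n_subpop=2,
                                     fst_level="low", n_chrom=4, seed=seed)
        causal = 17
        y = 2.0 * ms.genotypes[:, causal] + rng.normal(0, 0.5, ms.n_geno)
        return ms, y, causal
    raise ValueError(f"unknown fixture profile {profile!r}")
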