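"""Shared fixtures: toy datasets and one session-scoped end-to-end run."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

import adaptscape as ad
from adaptscape.pipeline import fixture_generator

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_markers():
    """80 genotypes × 400 SNPs with four subpopulations."""
    return ad.popgen.simulate_markers(
        n_geno=80, n_snp=400, n_subpop=4, fst_level="moderate", n_chrom=7, seed=101
    )


@pytest.fixture(scope="session")
def param_spec():
    return ad.genarch.default_parameter_spec()


@pytest.fixture(scope="session")
def toy_env():
    """3-day constant-weather trial for hand-stepping the surrogate."""
    return fixture_generator("weather_toy")


@pytest.fixture(scope="session")
def long_toy_env():
    """Season-length constant-weather trial (no rain, warm, bright)."""
    arch = ad.envgen.SiteArchetype(
        name="LongToy", latitude=-30.0, annual_rain=300.0, seasonal_rain=150.0,
        rain_pattern="even", tmean=20.0, radiation=20.0, pawc=150.0,
        sowing_paw=150.0, sowing_doy=1,
    )
    n = 240
    # tmean 13 degC: winter-cool, so vernal days accrue and the crop flowers
    wx = ad.envgen.WeatherSeries(
        doy=np.arange(1, n + 1), tmin=np.full(n, 6.0), tmax=np.full(n, 20.0),
        radn=np.full(n, 20.0), rain=np.zeros(n), latitude=arch.latitude,
        site=arch.name,
    )
    return ad.envgen.TrialEnvironment(site=arch, year_index=0, weather=wx,
                                      pawc=arch.pawc, initial_paw=150.0)


@pytest.fixture(scope="session")
def e2e():
    """One mid-size end-to-end run shared by the analysis-layer tests.

    80 genotypes × 600 SNPs, the four default site archetypes × 10 years
    (40 trials), with kinship, accepted architecture, surrogate MET,
    stress curves, ET labels and covariables.
    """
    markers = ad.popgen.simulate_markers(
        n_geno=80, n_snp=600, n_subpop=5, fst_level="moderate", n_chrom=7, seed=21
    )
    kin = ad.popgen.kinship(markers)
    arch, params = ad.genarch.generate_architecture(markers, seed=22)
    trials = ad.envgen.build_tpe(n_years=10, master_seed=23)
    Y, B, results, trajs = ad.cropsim.run_met(
        params.values, trials, keep_trajectories=True
    )
    curves = ad.envtype.build_stress_curves(trials)
    ets = ad.envtype.classify(curves, k=4)
    meta = pd.DataFrame(
        {
            "trial": [t.name for t in trials],
            "location": [t.site.name for t in trials],
            "year": [t.year_index for t in trials],
            "et": [ets.labels[t.name] for t in trials],
        }
    )
    covs = ad.envtype.covariable_table(trials)
    met = ad.gxe.METDataset(values=Y, trials=meta)
    return {
        "markers": markers, "kinship": kin, "architecture": arch,
        "params": params, "trials": trials, "met": met, "biomass": B,
        "results": results, "trajectories": trajs, "curves": curves,
        "ets": ets, "meta": meta, "covariables": covs,
    }
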