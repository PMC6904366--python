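"""Gamma marginals, copula sampling, sign allocation, and the rejection loop."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from adaptscape import genarch, popgen


@pytest.fixture(scope="module")
def arch_and_params(small_markers):
    return genarch.generate_architecture(small_markers, seed=55)


class TestFitGamma:
    def test_recovers_known_shape(self):
        rng = np.random.default_rng(4)
        draws = rng.gamma(2.0, 1 / 5.0, size=10_000)
        marginals, med = genarch.fit_gamma(draws)
        # MLE shape SE for gamma is ~ shape * sqrt(2/n) at this scale
        assert abs(med.shape - 2.0) < 2 * 2.0 * np.sqrt(2 / 10_000) * 2
        assert abs(med.rate - 5.0) < 0.3

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            genarch.fit_gamma(np.full(100, 0.3))

    def test_median_across_environments(self):
        rng = np.random.default_rng(8)
        a = rng.gamma(1.0, 1.0, 5000)
        b = rng.gamma(3.0, 1 / 2.0, 5000)
        marginals, med = genarch.fit_gamma(np.column_stack([a, b]))
        assert med.shape == pytest.approx(
            np.median([m.shape for m in marginals]))
        assert med.rate == pytest.approx(np.median([m.rate for m in marginals]))

    def test_nonpositive_input_fails(self):
        with pytest.raises(ValueError):
            genarch.fit_gamma(np.array([0.1, -0.2, 0.3]))


class TestSampleEffects:
    def test_sign_fractions_in_binomial_band(self):
        eff = genarch.sample_effects(
            genarch.DEFAULT_MARGINAL, genarch.default_targets(), 300, seed=1
        )
        frac_neg = (eff < 0).mean(axis=0)
        # binomial 95% band around 0.5 for n=300
        band = 1.96 * np.sqrt(0.25 / 300)
        # pair-coupled parameters may deviate; uncoupled must not
        uncoupled = [j for j, n in enumerate(genarch.PARAMETER_NAMES)
                     if n not in {"transp_eff_cf", "y_rue", "grains_per_gram_stem",
                                  "max_grain_size", "potential_grain_filling_rate"}]
        assert np.all(np.abs(frac_neg[uncoupled] - 0.5) < band + 0.03)

    def test_signs_independent_without_coupling(self):
        eff = genarch.sample_effects(genarch.DEFAULT_MARGINAL, [], 300, seed=2)
        s = np.sign(eff)
        phi = np.corrcoef(s, rowvar=False)
        off = phi[~np.eye(12, dtype=bool)]
        assert np.abs(off).max() < 0.2

    def test_copula_imposes_absolute_effect_correlation(self):
        target = genarch.CorrelationTarget("transp_eff_cf", "y_rue", -0.9)
        rhos = []
        for s in range(10):
            eff = genarch.sample_abs_effects(
                genarch.GammaMarginal(1.0, 1.0), [target], 300, seed=s
            )
            i = genarch.PARAMETER_NAMES.index("transp_eff_cf")
            j = genarch.PARAMETER_NAMES.index("y_rue")
            rhos.append(stats.spearmanr(eff[:, i], eff[:, j]).statistic)
        # Gaussian copula rho=0.9 implies Spearman 6/pi*arcsin(rho/2)
        implied = 6 / np.pi * np.arcsin(0.9 / 2)
        assert abs(np.mean(rhos) - implied) < 0.1

    def test_infeasible_copula_matrix_fails(self):
        # |r| entries (0.95, 0.95, 0.05) break positive definiteness
        targets = [
            genarch.CorrelationTarget("transp_eff_cf", "y_rue", 0.95),
            genarch.CorrelationTarget("y_rue", "max_grain_size", 0.95),
            genarch.CorrelationTarget("transp_eff_cf", "max_grain_size", 0.05),
        ]
        with pytest.raises(ValueError, match="positive definite"):
            genarch.sample_abs_effects(genarch.DEFAULT_MARGINAL, targets, 100, seed=0)


class TestAssignToSnps:
    def test_designated_loci_carry_top_phenology_effects(self, small_markers):
        eff = genarch.sample_effects(
            genarch.DEFAULT_MARGINAL, genarch.default_targets(), 300, seed=3
        )
        idx, eff2 = genarch.assign_to_snps(eff, small_markers, seed=4)
        desg = np.flatnonzero(np.isin(idx, small_markers.designated_loci))
        for name in ("photop_sens", "vern_sens"):
            col = np.abs(eff2[:, genarch.PARAMETER_NAMES.index(name)])
            top9 = set(np.argsort(col)[::-1][:9])
            assert top9 == set(desg)

    def test_reassignment_is_column_permutation(self, small_markers):
        eff = genarch.sample_effects(
            genarch.DEFAULT_MARGINAL, genarch.default_targets(), 300, seed=5
        )
        _, eff2 = genarch.assign_to_snps(eff, small_markers, seed=6)
        for j in range(12):
            assert np.allclose(np.sort(eff[:, j]), np.sort(eff2[:, j]))

    def test_full_panel_assignment_is_permutation(self, small_markers):
        n = small_markers.n_snp
        eff = genarch.sample_effects(genarch.DEFAULT_MARGINAL, [], n, seed=7)
        idx, _ = genarch.assign_to_snps(eff, small_markers, seed=8)
        assert np.array_equal(np.sort(idx), np.arange(n))

    def test_sampling_positions_roughly_uniform(self, small_markers):
        counts = np.zeros(small_markers.n_snp)
        for s in range(50):
            eff = genarch.sample_effects(genarch.DEFAULT_MARGINAL, [], 100, seed=s)
            idx, _ = genarch.assign_to_snps(eff, small_markers, seed=1000 + s)
            counts[idx] += 1
        # the nine designated loci are forced into every draw; uniformity is
        # a property of the remaining sampled positions
        free = np.setdiff1d(np.arange(small_markers.n_snp),
                            small_markers.designated_loci)
        deciles = np.array_split(counts[free], 10)
        obs = np.array([d.sum() for d in deciles])
        exp = counts[free].sum() * np.array([d.size for d in deciles]) / free.size
        chi2 = ((obs - exp) ** 2 / exp).sum()
        assert stats.chi2.sf(chi2, df=9) > 0.01

    def test_too_many_qtls_fails(self, small_markers):
        eff = genarch.sample_effects(genarch.DEFAULT_MARGINAL, [], 500, seed=9)
        with pytest.raises(ValueError, match="exceeds"):
            genarch.assign_to_snps(eff, small_markers, seed=10)


class TestGenotypeParameters:
    def test_qtl_sum_matches_hand_arithmetic(self):
        dos = np.array([[0, 2], [2, 1]])
        mp = pd.DataFrame({"snp_id": ["a", "b"], "chrom": [1, 1],
                           "pos_cM": [0.0, 1.0]})
        ms = popgen.MarkerSet(genotypes=dos, map=mp)
        eff = np.zeros((2, 12))
        eff[:, 0] = [0.5, -0.25]
        spec = genarch.default_parameter_spec()
        arch = genarch.QTLArchitecture(
            snp_indices=np.array([0, 1]), effects=eff, mu=spec.midpoint
        )
        gp = genarch.genotype_parameters(ms, arch, spec, force=True, rescale=False)
        # x = dosage - 1: genotype 0 -> (-1, 1); genotype 1 -> (1, 0)
        mu0 = spec.midpoint[0]
        assert gp.values[0, 0] == pytest.approx(mu0 - 0.5 - 0.25)
        assert gp.values[1, 0] == pytest.approx(mu0 + 0.5)

    def test_rescaling_hits_table_limits(self, arch_and_params, param_spec):
        _, params = arch_and_params
        j = param_spec.index("photop_sens")
        assert params.values[:, j].min() == pytest.approx(1.5)
        assert params.values[:, j].max() == pytest.approx(3.0)
        assert np.allclose(params.values.min(axis=0), param_spec.low)
        assert np.allclose(params.values.max(axis=0), param_spec.high)

    def test_zero_variance_column_fails_with_name(self, small_markers, param_spec):
        eff = np.zeros((50, 12))
        eff[:, 1:] = np.random.default_rng(0).normal(0, 0.1, (50, 11))
        arch = genarch.QTLArchitecture(
            snp_indices=np.arange(50), effects=eff, mu=param_spec.midpoint
        )
        with pytest.raises(ValueError, match="fr_lf_sen_rate"):
            genarch.genotype_parameters(small_markers, arch, param_spec, force=True)

    def test_linearity_of_qtl_model(self, small_markers, param_spec):
        rng = np.random.default_rng(11)
        eff = rng.normal(0, 0.1, (60, 12))
        idx = rng.choice(small_markers.n_snp, 60, replace=False)
        a1 = genarch.QTLArchitecture(snp_indices=idx, effects=eff,
                                     mu=param_spec.midpoint)
        a2 = genarch.QTLArchitecture(snp_indices=idx, effects=2 * eff,
                                     mu=param_spec.midpoint)
        g1 = genarch.genotype_parameters(small_markers, a1, param_spec,
                                         force=True, rescale=False)
        g2 = genarch.genotype_parameters(small_markers, a2, param_spec,
                                         force=True, rescale=False)
        dev1 = g1.values - param_spec.midpoint
        dev2 = g2.values - param_spec.midpoint
        assert np.allclose(dev2, 2 * dev1)

    def test_rescaling_preserves_ranking(self, small_markers, param_spec):
        rng = np.random.default_rng(12)
        eff = rng.gamma(1.2, 1 / 25, (60, 12)) * rng.choice([-1, 1], (60, 12))
        idx = rng.choice(small_markers.n_snp, 60, replace=False)
        arch = genarch.QTLArchitecture(snp_indices=idx, effects=eff,
                                       mu=param_spec.midpoint)
        raw = genarch.genotype_parameters(small_markers, arch, param_spec,
                                          force=True, rescale=False)
        scaled = genarch.genotype_parameters(small_markers, arch, param_spec,
                                             force=True)
        for j in range(12):
            r = stats.spearmanr(raw.values[:, j], scaled.values[:, j]).statistic
            assert r == pytest.approx(1.0)


class TestAcceptance:
    def test_untargeted_pair_above_threshold_rejected(self, param_spec):
        rng = np.random.default_rng(13)
        base = rng.normal(size=(100, 12))
        base[:, 1] = 0.5 * base[:, 0] + np.sqrt(1 - 0.45**2) * base[:, 1]
        vals = param_spec.low + (base - base.min(0)) / np.ptp(base, axis=0) \
            * (param_spec.high - param_spec.low)
        gp = genarch.GenotypeParameters(values=vals, spec=param_spec)
        r01 = np.corrcoef(vals[:, 0], vals[:, 1])[0, 1]
        ok, corr = genarch.accept_architecture(gp, genarch.default_targets())
        if abs(r01) > 0.4:
            assert not ok

    def test_targeted_pair_within_band_passes_rule(self):
        # rule arithmetic: |−0.25 − (−0.40)| = 0.15 <= 0.2
        assert abs(-0.25 - (-0.40)) <= genarch.TARGETED_MAX_DEPARTURE
        assert abs(0.45) > genarch.UNTARGETED_MAX_ABS_R

    def test_rejection_loop_reaches_acceptance(self, small_markers):
        arch, params = genarch.generate_architecture(small_markers, seed=77)
        assert arch.accepted
        ok, _ = genarch.accept_architecture(params, genarch.default_targets())
        assert ok

    def test_joint_fraction_monotone_in_realized_correlation(self, small_markers):
        # higher joint-sign fraction -> stronger realized |correlation|
        means = []
        for frac in (0.5, 0.8):
            rs = []
            for s in range(8):
                t = [genarch.CorrelationTarget("transp_eff_cf", "y_rue", -0.4,
                                               joint_fraction=frac)]
                eff = genarch.sample_effects(genarch.DEFAULT_MARGINAL, t, 300,
                                             seed=300 + s)
                idx, eff = genarch.assign_to_snps(eff, small_markers,
                                                  seed=400 + s)
                spec = genarch.default_parameter_spec()
                arch = genarch.QTLArchitecture(snp_indices=idx, effects=eff,
                                               mu=spec.midpoint)
                gp = genarch.genotype_parameters(small_markers, arch, spec,
                                                 force=True)
                i = spec.index("transp_eff_cf")
                j = spec.index("y_rue")
                rs.append(np.corrcoef(gp.values[:, i], gp.values[:, j])[0, 1])
            means.append(np.mean(rs))
        assert means[1] < means[0]  # more coupling -> more negative
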