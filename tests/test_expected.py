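import itertools

import numpy as np
import pytest

from sumstatsim import (CausalModel, CaseControlGenotypeDist, expected_u,
                        expected_inv_sqrt_v, expected_z_region,
                        fit_inverse_gamma, haplotype_freq_table,
                        joint_genotype_probs, solve_enrichment,
                        variance_moments, scenario_panel)
from sumstatsim.expected import DegenerateVarianceError, phenotype_variance
from sumstatsim.oracle import sample_study

from conftest import make_panel


def joint_over(panel, subset):
    return joint_genotype_probs(haplotype_freq_table(panel, subset))


# ---------------------------------------------------------------------------
# E(U_X)
# ---------------------------------------------------------------------------

class TestExpectedU:
    def test_null_model_zero(self, random_panel):
        model = CausalModel(["snp0"], [0.0], n0=1000, n1=1000)
        enr = solve_enrichment(model, joint_over(random_panel, ["snp0"]))
        for sid in random_panel.snp_ids:
            subset = ["snp0"] if sid == "snp0" else [sid, "snp0"]
            assert expected_u(sid, model, joint_over(random_panel, subset),
                              enr) == pytest.approx(0.0, abs=1e-12)

    def test_or12_maf_half(self, maf_half_panel, or12_model):
        # enumeration with C = 1.21: sum term = 0.0909090..., prefactor 499.75
        pw = joint_over(maf_half_panel, ["x"])
        enr = solve_enrichment(or12_model, pw)
        eu = expected_u("x", or12_model, pw, enr)
        assert eu == pytest.approx(499.75 * (1 / 11), rel=1e-10)
        assert eu == pytest.approx(45.4318, abs=1e-4)

    def test_matches_forward_oracle_mean_u(self, maf_half_panel):
        model = CausalModel(["x"], [np.log(1.3)], n0=300, n1=300)
        pw = joint_over(maf_half_panel, ["x"])
        enr = solve_enrichment(model, pw)
        eu = expected_u("x", model, pw, enr)
        us = []
        for r in range(2000):
            study = sample_study(maf_half_panel, model, enr, seed=r)
            g = study.genotypes[:, 0].astype(float)
            y = study.phenotypes.astype(float)
            us.append(np.sum((g - g.mean()) * (y - y.mean())))
        us = np.asarray(us)
        se = us.std(ddof=1) / np.sqrt(len(us))
        assert abs(us.mean() - eu) < 3 * se


# ---------------------------------------------------------------------------
# moments of V_X
# ---------------------------------------------------------------------------

def enumerate_moments(p0, p1, n0, n1):
    """Brute-force E(V), E(V^2) over all genotype assignments (oracle)."""
    ev = ev2 = 0.0
    for combo in itertools.product(range(3), repeat=n0 + n1):
        pr = 1.0
        for k, g in enumerate(combo):
            pr *= (p0 if k < n0 else p1)[g]
        v = np.var(combo, ddof=1)
        ev += pr * v
        ev2 += pr * v * v
    return ev, ev2


class TestVarianceMoments:
    def test_symmetric_pair_example(self):
        dist = CaseControlGenotypeDist("x", np.array([0.25, 0.5, 0.25]),
                                       np.array([0.25, 0.5, 0.25]))
        ev, ev2 = variance_moments(dist, 1, 1)
        assert ev == pytest.approx(0.5, abs=1e-12)
        assert ev2 == pytest.approx(0.625, abs=1e-12)

    @pytest.mark.parametrize("n0,n1", [(1, 1), (2, 1), (2, 2), (3, 2), (1, 5)])
    def test_exact_vs_enumeration(self, n0, n1):
        rng = np.random.default_rng(n0 * 10 + n1)
        p0 = rng.dirichlet([2, 2, 2])
        p1 = rng.dirichlet([2, 2, 2])
        dist = CaseControlGenotypeDist("x", p0, p1)
        ev, ev2 = variance_moments(dist, n0, n1)
        ev_e, ev2_e = enumerate_moments(p0, p1, n0, n1)
        assert ev == pytest.approx(ev_e, abs=1e-12)
        assert ev2 == pytest.approx(ev2_e, abs=1e-12)

    def test_degenerate_dist(self):
        d = np.array([0.0, 1.0, 0.0])
        ev, ev2 = variance_moments(CaseControlGenotypeDist("x", d, d), 5, 5)
        assert ev == pytest.approx(0.0, abs=1e-12)
        assert ev2 == pytest.approx(0.0, abs=1e-12)

    def test_unbiased_for_large_n(self):
        p = np.array([0.3, 0.5, 0.2])
        pop_var = p @ np.arange(3.0) ** 2 - (p @ np.arange(3.0)) ** 2
        dist = CaseControlGenotypeDist("x", p, p)
        ev, _ = variance_moments(dist, 5000, 5000)
        assert ev == pytest.approx(pop_var, abs=1e-4)

    def test_monte_carlo_check_larger_n(self):
        rng = np.random.default_rng(12)
        p0 = np.array([0.2, 0.5, 0.3])
        p1 = np.array([0.1, 0.4, 0.5])
        n0 = n1 = 25
        dist = CaseControlGenotypeDist("x", p0, p1)
        ev, ev2 = variance_moments(dist, n0, n1)
        g = np.concatenate([
            rng.choice(3, size=(20000, n0), p=p0),
            rng.choice(3, size=(20000, n1), p=p1)], axis=1)
        v = g.var(axis=1, ddof=1)
        for got, sample in ((ev, v), (ev2, v ** 2)):
            se = sample.std(ddof=1) / np.sqrt(len(sample))
            assert abs(sample.mean() - got) < 3.5 * se

    def test_n_below_two_rejected(self):
        d = np.array([0.25, 0.5, 0.25])
        with pytest.raises(ValueError):
            variance_moments(CaseControlGenotypeDist("x", d, d), 1, 0)


# ---------------------------------------------------------------------------
# inverse-gamma fit and its half moment
# ---------------------------------------------------------------------------

class TestInverseGammaFit:
    def test_algebraic_round_trip(self):
        assert fit_inverse_gamma(2.0, 8.0) == pytest.approx((3.0, 4.0))

    def test_plug_in_example(self):
        alpha, beta = fit_inverse_gamma(0.5, 0.625)
        assert alpha == pytest.approx(8 / 3, abs=1e-12)
        assert beta == pytest.approx(5 / 6, abs=1e-12)

    @pytest.mark.parametrize("ev,ev2", [(0.5, 0.3), (1.7, 3.4), (0.02, 0.00045)])
    def test_moment_round_trip(self, ev, ev2):
        alpha, beta = fit_inverse_gamma(ev, ev2)
        # InverseGamma mean and second moment
        assert beta / (alpha - 1) == pytest.approx(ev, rel=1e-12)
        assert beta ** 2 / ((alpha - 1) * (alpha - 2)) == pytest.approx(
            ev2, rel=1e-12)
        assert alpha > 2

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateVarianceError):
            fit_inverse_gamma(1.0, 1.0)
        with pytest.raises(DegenerateVarianceError):
            fit_inverse_gamma(0.0, 1.0)


class TestExpectedInvSqrtV:
    def test_gamma_table_value(self):
        # Gamma(2)/Gamma(1.5) = 1 / 0.8862269
        assert expected_inv_sqrt_v(1.5, 1.0) == pytest.approx(1.12838, abs=1e-5)

    def test_monte_carlo(self):
        from scipy.stats import invgamma
        alpha, beta = 4.2, 2.7
        draws = invgamma(alpha, scale=beta).rvs(
            10 ** 6, random_state=np.random.default_rng(5))
        sample = 1.0 / np.sqrt(draws)
        se = sample.std(ddof=1) / np.sqrt(len(sample))
        assert abs(sample.mean() - expected_inv_sqrt_v(alpha, beta)) < 3 * se

    def test_beta_scaling(self):
        assert expected_inv_sqrt_v(3.0, 4.0) == pytest.approx(
            expected_inv_sqrt_v(3.0, 1.0) / 2, rel=1e-12)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            expected_inv_sqrt_v(-1.0, 1.0)


# ---------------------------------------------------------------------------
# region-level expected Z
# ---------------------------------------------------------------------------

class TestExpectedZRegion:
    def test_null_model(self, random_panel):
        model = CausalModel(["snp1"], [0.0], n0=400, n1=600)
        summary = expected_z_region(model, random_panel)
        np.testing.assert_allclose(summary.ze, 0.0, atol=1e-12)
        assert summary.vy == phenotype_variance(400, 600)

    def test_single_causal_value(self, maf_half_panel, or12_model):
        summary = expected_z_region(or12_model, maf_half_panel)
        assert summary.ze[0] == pytest.approx(2.87, abs=0.02)
        assert summary.eu[0] == pytest.approx(45.43, abs=0.01)

    def test_antisymmetric_in_gamma(self, random_panel):
        # exact only to first order (the case tilt is not mirror-symmetric
        # for asymmetric genotype distributions), so tolerance is O(gamma^2)
        ids = ["snp0", "snp2", "snp4"]
        gamma = np.array([0.2, -0.1, 0.15])
        base = expected_z_region(
            CausalModel(ids, gamma, 800, 800), random_panel)
        flipped = expected_z_region(
            CausalModel(ids, -gamma, 800, 800), random_panel)
        scale = np.abs(base.ze).max()
        np.testing.assert_allclose(flipped.ze, -base.ze, atol=0.06 * scale)
        assert np.all(np.sign(flipped.ze) == -np.sign(base.ze))

    def test_sqrt_n_scaling(self, maf_half_panel):
        zs = []
        for n in (2000, 8000, 32000):
            model = CausalModel(["x"], [np.log(1.1)], n0=n // 2, n1=n // 2)
            zs.append(expected_z_region(model, maf_half_panel).ze[0])
        assert zs[1] / zs[0] == pytest.approx(2.0, rel=0.02)
        assert zs[2] / zs[1] == pytest.approx(2.0, rel=0.02)

    def test_enum_ops_independent_of_sample_size(self, random_panel):
        ops = []
        for n in (2000, 128000):
            model = CausalModel(["snp1", "snp3"], [0.1, -0.1],
                                n0=n // 2, n1=n // 2)
            ops.append(expected_z_region(model, random_panel).n_enum_ops)
        assert ops[0] == ops[1] > 0

    def test_attenuation_scenario5_below_scenario4(self):
        panel4, model4 = scenario_panel(4, n_hap=600, seed=3, n_snps=80)
        panel5, model5 = scenario_panel(5, n_hap=600, seed=3, n_snps=80)
        z4 = expected_z_region(model4, panel4)
        z5 = expected_z_region(model5, panel5)
        peak4 = max(abs(z4.ze[panel4.index_of(s)]) for s in model4.causal_ids)
        peak5 = max(abs(z5.ze[panel5.index_of(s)]) for s in model5.causal_ids)
        assert peak5 < peak4

    def test_unknown_causal_snp(self, random_panel):
        model = CausalModel(["ghost"], [0.1], n0=10, n1=10)
        with pytest.raises(KeyError):
            expected_z_region(model, random_panel)

    def test_writer_schema(self, tmp_path, maf_half_panel, or12_model):
        from sumstatsim.expected import write_expected_summary
        summary = expected_z_region(or12_model, maf_half_panel)
        out = tmp_path / "exp.tsv"
        write_expected_summary(summary, maf_half_panel, str(out))
        lines = out.read_text().strip().split("\n")
        assert lines[0].split("\t") == ["snp", "pos", "ze", "alpha", "beta",
                                        "eu"]
        assert len(lines) == 1 + maf_half_panel.n_snps
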