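import numpy as np
import pandas as pd
import pytest

import fullsib as fs
from fullsib.exceptions import DegreesOfFreedomError, RecordsError
from fullsib.model import FullSibModel

from conftest import fit_many


def _records_frame(sires, dams, orders, y):
    return pd.DataFrame(
        {
            "sire_id": sires,
            "dam_id": dams,
            "progeny_order": orders,
            "phenotype": y,
        }
    )


class TestAnovaDecomposition:
    def test_two_sire_hand_computation(self):
        # 2 sires x 1 dam x 2 progeny, y = (1,1,3,3): all spread between sires
        df = _records_frame([1, 1, 2, 2], [1, 1, 2, 2], [1, 2, 1, 2], [1.0, 1.0, 3.0, 3.0])
        # dam stratum has no df here; decompose directly on a padded design
        with pytest.raises(DegreesOfFreedomError):
            FullSibModel(df).anova_decomposition()
        # same data embedded with a second dam per sire keeps the hand values
        df2 = _records_frame(
            [1, 1, 1, 1, 2, 2, 2, 2],
            [1, 1, 2, 2, 3, 3, 4, 4],
            [1, 2, 1, 2, 1, 2, 1, 2],
            [1.0, 1.0, 1.0, 1.0, 3.0, 3.0, 3.0, 3.0],
        )
        an = FullSibModel(df2).anova_decomposition()
        assert an.ss_sires == pytest.approx(8.0)  # 8 * (offset 1)^2
        assert an.ss_dams_within == pytest.approx(0.0)
        assert an.ss_within == pytest.approx(0.0)

    def test_constant_phenotype_all_zero(self):
        d = fs.NestedDesign.balanced(3, 2, 2)
        rec = fs.simulate_full_sib(
            fs.SimulationConfig(design=d, vc=fs.VarianceComponents(0.1, 0.1, 0.8), seed=0)
        )
        rec.data["phenotype"] = 5.0
        an = FullSibModel(rec.data).anova_decomposition()
        assert an.total_ss == 0.0

    def test_sums_of_squares_partition_total(self, unbalanced_records):
        an = FullSibModel.from_records(unbalanced_records).anova_decomposition()
        y = unbalanced_records.phenotype
        total = float(((y - y.mean()) ** 2).sum())
        assert an.total_ss == pytest.approx(total, rel=1e-9)
        assert an.df_sires + an.df_dams + an.df_within == len(y) - 1


class TestAnovaEstimator:
    def test_back_solve_matches_mean_square_identities(self):
        d = fs.NestedDesign.balanced(10, 5, 4)
        rec = fs.simulate_full_sib(
            fs.SimulationConfig(design=d, vc=fs.VarianceComponents(0, 0, 1), seed=3)
        )
        res = FullSibModel.from_records(rec).fit("anova")
        an = res.anova
        lam = fs.nested_design_coefficients(d)
        expected_d = (an.ms_dams - an.ms_within) / lam.lambda1
        assert res.params.sigma_d2 == pytest.approx(expected_d)
        assert res.params.sigma_e2 == pytest.approx(an.ms_within)

    def test_unbiased_under_independence(self):
        # mean component estimates over replicates match truth within 3 SE
        vc = fs.VarianceComponents.from_h2(0.1)
        ests = fit_many(fs.design_for_total(100, 5, 4), vc, "anova", 1500, 10_000)
        se = ests.std(axis=0, ddof=1) / np.sqrt(len(ests))
        truth = (0.025, 0.025, 0.95)
        for j in range(3):
            assert abs(ests[:, j].mean() - truth[j]) < 3 * se[j]

    def test_negative_estimates_preserved(self):
        found_negative = False
        for seed in range(40):
            rec = fs.simulate_full_sib(
                fs.SimulationConfig(
                    design=fs.NestedDesign.balanced(3, 2, 2),
                    vc=fs.VarianceComponents(0.0, 0.0, 1.0),
                    seed=seed,
                )
            )
            res = FullSibModel.from_records(rec, validate=False).fit("anova")
            if res.params.sigma_s2 < 0 or res.params.sigma_d2 < 0:
                found_negative = True
                break
        assert found_negative, "null components should often yield negative estimates"


class TestLikelihoodEstimators:
    def test_reml_equals_anova_at_interior_optimum(self, balanced_records):
        anova = FullSibModel.from_records(balanced_records).fit("anova")
        reml = FullSibModel.from_records(balanced_records).fit("reml")
        assert anova.params.sigma_s2 > 0 and anova.params.sigma_d2 > 0
        for attr in ("sigma_s2", "sigma_d2", "sigma_e2"):
            assert getattr(reml.params, attr) == pytest.approx(
                getattr(anova.params, attr), abs=1e-9
            )

    def test_ml_shrinks_sire_component(self, balanced_records):
        # ML divides the sire-stratum sum of squares by s, REML by s-1
        ml = FullSibModel.from_records(balanced_records).fit("ml")
        reml = FullSibModel.from_records(balanced_records).fit("reml")
        assert ml.params.sigma_s2 < reml.params.sigma_s2
        assert ml.params.sigma_e2 == pytest.approx(reml.params.sigma_e2, rel=1e-6)

    def test_boundary_pileup_under_null_sire_component(self):
        vc = fs.VarianceComponents(0.0, 0.1, 0.9)
        ests = fit_many(fs.NestedDesign.balanced(5, 4, 3), vc, "reml", 200, 50_000)
        at_zero = (ests[:, 0] == 0.0).mean()
        assert at_zero > 0.2
        assert (ests[:, 0] >= 0).all()

    def test_optimum_at_least_as_likely_as_anova_start(self, unbalanced_records):
        m = FullSibModel.from_records(unbalanced_records)
        res = m.fit("reml")
        an = res.anova
        lam = fs.nested_design_coefficients(m.design)
        start = (
            max((an.ms_sires - an.ms_dams * lam.lambda3 / lam.lambda1
                 - an.ms_within * (1 - lam.lambda3 / lam.lambda1)) / lam.lambda2, 0.0),
            max((an.ms_dams - an.ms_within) / lam.lambda1, 0.0),
            an.ms_within,
        )
        assert res.loglik >= m.loglike(*start, reml=True) - 1e-8

    def test_general_path_matches_balanced_path(self, balanced_records):
        m = FullSibModel.from_records(balanced_records)
        fast = m.fit("reml")
        theta, ll, _, _ = m._general_likelihood_fit(True, 1.0)
        assert np.allclose(
            theta,
            (fast.params.sigma_s2, fast.params.sigma_d2, fast.params.sigma_e2),
            atol=1e-4,
        )
        assert ll == pytest.approx(fast.loglik, abs=1e-6)

    def test_reml_cross_checked_against_mixedlm(self, unbalanced_records):
        import statsmodels.api as sm

        ours = FullSibModel.from_records(unbalanced_records).fit("reml")
        md = sm.MixedLM.from_formula(
            "phenotype ~ 1",
            data=unbalanced_records.data,
            groups="sire_id",
            re_formula="1",
            vc_formula={"dam": "0 + C(dam_id)"},
        )
        theirs = md.fit(reml=True)
        assert ours.params.sigma_s2 == pytest.approx(float(theirs.cov_re.iloc[0, 0]), abs=2e-3)
        assert ours.params.sigma_d2 == pytest.approx(float(theirs.vcomp[0]), abs=2e-3)
        assert ours.params.sigma_e2 == pytest.approx(float(theirs.scale), abs=2e-3)

    def test_degenerate_data_flagged_not_crashed(self):
        df = pd.DataFrame(
            {
                "sire_id": [1, 1, 1, 1, 2, 2, 2, 2],
                "dam_id": [1, 1, 2, 2, 3, 3, 4, 4],
                "progeny_order": [1, 2, 1, 2, 1, 2, 1, 2],
                "phenotype": [2.0] * 8,
            }
        )
        res = FullSibModel(df).fit("reml")
        assert not res.converged


class TestMinque0:
    def _dense_minque0(self, model):
        # independent dense construction of S theta = q
        d = model.design
        N = d.n_total
        Zs = np.zeros((N, d.n_sires))
        Zd = np.zeros((N, d.n_dams))
        Zs[np.arange(N), model._sire_codes] = 1.0
        Zd[np.arange(N), model._dam_codes] = 1.0
        V = [Zs @ Zs.T, Zd @ Zd.T, np.eye(N)]
        M = np.eye(N) - np.ones((N, N)) / N
        S = np.array([[np.trace(M @ Va @ M @ Vb) for Vb in V] for Va in V])
        y = model.endog
        q = np.array([y @ M @ Va @ M @ y for Va in V])
        return np.linalg.solve(S, q)

    def test_matches_dense_construction(self, unbalanced_records):
        m = FullSibModel.from_records(unbalanced_records)
        res = m.fit("minque0")
        dense = self._dense_minque0(m)
        assert np.allclose(
            (res.params.sigma_s2, res.params.sigma_d2, res.params.sigma_e2),
            dense,
            rtol=1e-8,
        )

    def test_equals_anova_on_balanced_designs(self, balanced_records):
        minque = FullSibModel.from_records(balanced_records).fit("minque0")
        anova = FullSibModel.from_records(balanced_records).fit("anova")
        for attr in ("sigma_s2", "sigma_d2", "sigma_e2"):
            assert getattr(minque.params, attr) == pytest.approx(
                getattr(anova.params, attr), rel=1e-8
            )

    def test_quadratic_unbiasedness(self):
        vc = fs.VarianceComponents(0.3, 0.2, 0.5)
        design = fs.NestedDesign(((2, 3), (4, 1), (3, 2)))
        ests = fit_many(design, vc, "minque0", 4000, 70_000)
        se = ests.std(axis=0, ddof=1) / np.sqrt(len(ests))
        for j, truth in enumerate((0.3, 0.2, 0.5)):
            assert abs(ests[:, j].mean() - truth) < 3 * se[j]

    def test_pure_sire_signal_zeroes_other_components(self):
        d = fs.NestedDesign.balanced(4, 3, 2)
        from fullsib.simulate import design_id_columns

        sire_id, dam_id, order = design_id_columns(d)
        y = np.repeat([1.0, 3.0, -2.0, 5.0], 6)
        rec = fs.FullSibRecords(
            _records_frame(sire_id, dam_id, order, y), d
        )
        res = FullSibModel.from_records(rec, validate=False).fit("minque0")
        assert res.params.sigma_e2 == pytest.approx(0.0, abs=1e-10)
        assert res.params.sigma_d2 == pytest.approx(0.0, abs=1e-10)


class TestInvariances:
    @pytest.mark.parametrize("method", fs.model.METHODS)
    def test_shift_invariance(self, balanced_records, method):
        res = FullSibModel.from_records(balanced_records).fit(method)
        shifted = balanced_records.data.copy()
        shifted["phenotype"] += 1234.5
        res2 = FullSibModel(shifted).fit(method)
        for attr in ("sigma_s2", "sigma_d2", "sigma_e2"):
            assert getattr(res2.params, attr) == pytest.approx(
                getattr(res.params, attr), rel=1e-6, abs=1e-9
            )

    @pytest.mark.parametrize("method", fs.model.METHODS)
    def test_scale_equivariance(self, unbalanced_records, method):
        c = 3.7
        res = FullSibModel.from_records(unbalanced_records).fit(method)
        scaled = unbalanced_records.data.copy()
        scaled["phenotype"] *= c
        res2 = FullSibModel(scaled).fit(method)
        for attr in ("sigma_s2", "sigma_d2", "sigma_e2"):
            assert getattr(res2.params, attr) == pytest.approx(
                c**2 * getattr(res.params, attr), rel=1e-4, abs=1e-8
            )
        h1, h2 = res.heritability, res2.heritability
        assert h2.hsd2 == pytest.approx(h1.hsd2, rel=1e-4)


class TestResultsSurface:
    def test_summary_mentions_key_quantities(self, balanced_records):
        res = FullSibModel.from_records(balanced_records).fit("reml")
        text = res.summary()
        for token in ("REML", "sigma_s2", "h2 (sire+dam)", "MS_within"):
            assert token in text

    def test_estimate_heritability_composes(self, balanced_records):
        h = fs.estimate_heritability(balanced_records, "anova")
        res = FullSibModel.from_records(balanced_records).fit("anova")
        assert h == res.heritability

    def test_sampling_variance_reported_for_balanced(self, balanced_records):
        res = FullSibModel.from_records(balanced_records).fit("anova")
        v = res.sampling_variance_t()
        assert 0 <= v < 1
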