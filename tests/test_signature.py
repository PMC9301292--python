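"""ssGSEA scoring, Cox screening/stepwise selection and the ssGSEA-Cox search."""

import numpy as np
import pandas as pd
import pytest

from herbnet.signature import (
    SurvivalCohort,
    risk_split_km,
    ssgsea_cox_search,
    ssgsea_score,
    stepwise_cox,
    univariate_screen,
)
from herbnet.simulate import SimulationConfig, gen_spoiler_cohort, gen_survival_cohort

from oracles import ssgsea_running_sum


def toy_cohort(rng, n=200, betas=None, n_genes=6, censor=0.2):
    """Exponential survival driven by a linear predictor of the first genes."""
    betas = betas if betas is not None else []
    X = rng.normal(size=(n, n_genes))
    eta = X[:, : len(betas)] @ np.array(betas) if betas else np.zeros(n)
    t = -np.log(rng.uniform(size=n)) / np.exp(eta)
    e = np.ones(n, int)
    mask = rng.uniform(size=n) < censor
    t = np.where(mask, t * rng.uniform(size=n), t)
    e[mask] = 0
    expr = pd.DataFrame(X, columns=[f"G{i}" for i in range(n_genes)])
    return SurvivalCohort(expr, np.maximum(t, 1e-9), e)


class TestSsgsea:
    def test_matches_literal_running_sum_on_toy_matrix(self, rng):
        values = rng.normal(size=(3, 8))
        values[1, 2] = values[1, 5]  # exercise the tie path
        expr = pd.DataFrame(values, columns=[f"G{i}" for i in range(8)])
        members = ["G1", "G4", "G6"]
        scores = ssgsea_score(expr, members, rescale=False)
        in_set = [c in members for c in expr.columns]
        for i in range(3):
            expected = ssgsea_running_sum(values[i], in_set, tau=0.25)
            assert scores[i] == pytest.approx(expected, rel=1e-12)

    def test_top_expressed_set_scores_higher(self):
        expr = pd.DataFrame(
            [[9.0, 8.0, 3.0, 2.0, 1.0],     # set genes on top
             [1.0, 2.0, 9.0, 8.0, 7.0]],    # set genes at the bottom
            columns=list("ABCDE"))
        scores = ssgsea_score(expr, ["A", "B"], rescale=False)
        assert scores[0] > scores[1]

    def test_invariant_under_monotone_transform_of_one_sample(self, rng):
        expr = pd.DataFrame(rng.normal(size=(4, 30)),
                            columns=[f"G{i}" for i in range(30)])
        members = [f"G{i}" for i in range(0, 30, 4)]
        base = ssgsea_score(expr, members, rescale=False)
        warped = expr.copy()
        warped.iloc[2] = np.exp(2.0 * warped.iloc[2]) + 7.0
        out = ssgsea_score(warped, members, rescale=False)
        assert out[2] == pytest.approx(base[2], rel=1e-12)

    def test_rescaled_scores_span_unit_range(self, rng):
        expr = pd.DataFrame(rng.normal(size=(10, 20)),
                            columns=[f"G{i}" for i in range(20)])
        scores = ssgsea_score(expr, ["G0", "G3", "G9"])
        assert scores.max() - scores.min() == pytest.approx(1.0)

    def test_degenerate_sets_rejected(self, rng):
        expr = pd.DataFrame(rng.normal(size=(3, 5)),
                            columns=[f"G{i}" for i in range(5)])
        with pytest.raises(ValueError):
            ssgsea_score(expr, [f"G{i}" for i in range(5)])  # covers all genes
        with pytest.raises(ValueError):
            ssgsea_score(expr, ["NOPE"])
        with pytest.warns(UserWarning, match="single"):
            ssgsea_score(expr, ["G0"])


class TestUnivariateScreen:
    def test_planted_genes_detected(self):
        rng = np.random.default_rng(3)
        cohort = toy_cohort(rng, n=300, betas=[1.0] * 5, n_genes=40)
        table = univariate_screen(cohort)
        hits = set(table.loc[table.significant, "gene"])
        assert len(hits & {f"G{i}" for i in range(5)}) >= 4

    def test_null_false_positive_rate(self):
        counts = []
        for seed in range(8):
            rng = np.random.default_rng(100 + seed)
            cohort = toy_cohort(rng, n=150, betas=[], n_genes=40)
            table = univariate_screen(cohort)
            counts.append(int(table.significant.sum()))
        # binomial(40, 0.05) has mean 2; a run of eight screens stays low
        assert np.mean(counts) < 6

    def test_constant_gene_skipped_with_warning(self, rng):
        cohort = toy_cohort(rng, n=50, n_genes=3)
        cohort.expr["G0"] = 1.0
        with pytest.warns(UserWarning, match="skipped"):
            table = univariate_screen(cohort, ["G0"])
        assert table.empty


class TestStepwise:
    def test_keeps_prognostic_drops_noise(self):
        rng = np.random.default_rng(7)
        cohort = toy_cohort(rng, n=400, betas=[1.2], n_genes=4)
        fit, trace = stepwise_cox(cohort, ["G0", "G1", "G2", "G3"])
        assert "G0" in fit.covariates
        assert trace[0]["model"] == ["G0", "G1", "G2", "G3"]
        aics = [step["aic"] for step in trace]
        assert all(b <= a + 1e-9 for a, b in zip(aics, aics[1:]))

    def test_single_informative_candidate_survives_vs_null(self):
        rng = np.random.default_rng(8)
        cohort = toy_cohort(rng, n=300, betas=[1.0], n_genes=2)
        fit, _ = stepwise_cox(cohort, ["G0"])
        assert fit.covariates == ["G0"]
        assert fit.aic < -2 * fit.loglik_null

    def test_collinear_copy_eliminated(self):
        rng = np.random.default_rng(9)
        cohort = toy_cohort(rng, n=300, betas=[1.0], n_genes=3)
        cohort.expr["G0_copy"] = cohort.expr["G0"] + 1e-9 * rng.normal(size=300)
        fit, _ = stepwise_cox(cohort, ["G0", "G0_copy"])
        assert len(fit.covariates) == 1


class TestRiskSplit:
    def test_split_statistics_and_groups(self):
        rng = np.random.default_rng(11)
        cohort = toy_cohort(rng, n=300, betas=[1.5], n_genes=3)
        fit, _ = stepwise_cox(cohort, ["G0"])
        split = risk_split_km(cohort, fit)
        assert split.high.sum() + (~split.high).sum() == 300
        assert split.logrank_p < 0.01
        # high-risk group should die faster
        assert split.km_high[1][-1] <= split.km_low[1][-1]

    def test_constant_risk_raises(self, rng):
        cohort = toy_cohort(rng, n=60, n_genes=2)
        from herbnet.coxph import CoxFit
        fit = CoxFit(covariates=["G0"], beta=np.zeros(1), se=np.ones(1),
                     loglik=0.0, loglik_null=0.0, n=60, n_events=60,
                     converged=True, n_iter=1)
        cohort.expr["G0"] = 5.0
        with pytest.raises(ValueError):
            risk_split_km(cohort, fit)


class TestSearch:
    def test_admissible_full_set_returned_with_trace_of_one(self):
        cohort, truth = gen_survival_cohort(SimulationConfig(seed=1, n_samples=300))
        cands = [f"CAND{i:03d}" for i in range(20)]
        res = ssgsea_cox_search(cohort, cands)
        assert res.found
        assert res.genes == sorted(cands)
        assert res.n_tested == 1
        assert res.cox_p < 0.05

    def test_not_found_on_pure_noise(self, rng):
        cohort = toy_cohort(rng, n=80, betas=[], n_genes=8, censor=0.1)
        res = ssgsea_cox_search(cohort, ["G0", "G1", "G2", "G3"], alpha=1e-6)
        assert not res.found
        assert res.genes == []
        assert all(not step["admissible"] for step in res.trace)

    def test_trace_is_consistent_with_result(self):
        cohort, _ = gen_spoiler_cohort(seed=3)
        cands = [f"CAND{i:03d}" for i in range(62)] + ["SPOILER"]
        res = ssgsea_cox_search(cohort, cands)
        assert res.found
        sizes = [step["size"] for step in res.trace]
        # nothing larger than the winner was admissible
        for step in res.trace:
            if step["size"] > len(res.genes):
                assert not step["admissible"]
        assert max(sizes) == 63

    def test_spoiler_gene_is_dropped(self):
        """Mirror of a 63-to-62 outcome: exactly the constructed spoiler goes."""
        cohort, truth = gen_spoiler_cohort(seed=5)
        cands = truth["informative"] + [truth["spoiler"]]
        res = ssgsea_cox_search(cohort, cands)
        assert res.found
        assert sorted(res.genes) == sorted(truth["informative"])
        assert res.cox_p < 0.05

    def test_too_few_candidates_rejected(self, rng):
        cohort = toy_cohort(rng, n=50)
        with pytest.raises(ValueError):
            ssgsea_cox_search(cohort, ["G0", "G1"])
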