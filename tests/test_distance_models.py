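"""Hierarchical acoustic-distance models: priors, shrinkage, recovery."""

import numpy as np
import pandas as pd
import pytest

from vocsocial.models import (
    DyadicDistanceModel,
    SamplerConfig,
    WithinIndividualDistanceModel,
    export_summaries,
)
from vocsocial.models.base import ConvergenceWarning
from vocsocial.synthdata import simulate_dyadic_distance_data, simulate_within_distance_data

pytestmark = pytest.mark.filterwarnings("ignore::vocsocial.models.base.ConvergenceWarning")

QUICK = SamplerConfig(chains=2, warmup=400, draws=400, seed=3)


@pytest.fixture(scope="module")
def dyadic_fit():
    obs, truth = simulate_dyadic_distance_data(seed=11, n_dyads=80, obs_per_dyad=6)
    res = DyadicDistanceModel(obs).fit(QUICK)
    return obs, truth, res


class TestDyadicModel:
    def test_printed_priors_monte_carlo(self):
        # exponential(2) prior mean is 0.5; hyper-mean prior sd is 0.5
        draws = DyadicDistanceModel.sample_priors(200_000, seed=1)
        assert draws["sigma"].mean() == pytest.approx(0.5, rel=0.02)
        assert draws["sigma_dyad"].mean() == pytest.approx(0.5, rel=0.02)
        assert draws["alpha_bar"].std() == pytest.approx(0.5, rel=0.02)

    def test_recovers_generating_hyperparameters(self, dyadic_fit):
        _, truth, res = dyadic_fit
        hyp = res.hyper_estimates("original").set_index("parameter")
        for name in ("sigma", "sigma_dyad", "sigma_rec"):
            lo, hi = hyp.loc[name, ["pi89_low", "pi89_high"]]
            assert lo - 0.05 <= truth[name] <= hi + 0.05

    def test_dyad_levels_rank_correlate_with_truth(self, dyadic_fit):
        _, truth, res = dyadic_fit
        est = res.dyad_estimates().set_index("unit_id")["mean"]
        assert truth["alpha_dyad"].corr(est, method="spearman") > 0.8

    def test_posterior_shrinkage_toward_hypermean(self):
        # a dyad with few observations shrinks harder than a data-rich dyad
        # carrying the same raw mean
        rng = np.random.default_rng(0)
        rows = []
        for d, n_obs in (("rich", 40), ("poor", 2)):
            for k in range(n_obs):
                rows.append(
                    {"distance": 2.0 + rng.normal(0, 0.05), "dyad_id": d,
                     "rec_i": f"r{2*k}", "rec_j": f"r{2*k+1}"}
                )
        for d in range(30):  # background dyads establish alpha_bar near 0
            for k in range(6):
                rows.append(
                    {"distance": rng.normal(0, 0.3), "dyad_id": f"bg{d}",
                     "rec_i": f"b{2*k}", "rec_j": f"b{2*k+1}"}
                )
        res = DyadicDistanceModel(pd.DataFrame(rows)).fit(QUICK)
        est = res.dyad_estimates("standardized").set_index("unit_id")["mean"]
        a_bar = res.mean("alpha_bar")
        assert abs(est["poor"] - a_bar) < abs(est["rich"] - a_bar)

    def test_identical_distances_concentrate_sigma_dyad_near_zero(self):
        rows = [
            {"distance": 1.0, "dyad_id": f"d{k % 10}", "rec_i": f"r{k}", "rec_j": f"r{k+1}"}
            for k in range(60)
        ]
        res = DyadicDistanceModel(pd.DataFrame(rows)).fit(QUICK)
        # no dyadic variance to explain: posterior median under prior median
        assert np.median(res.stacked("sigma_dyad")) < 0.347

    def test_non_finite_distances_rejected_with_rows(self):
        obs, _ = simulate_dyadic_distance_data(seed=1, n_dyads=5, obs_per_dyad=2)
        obs.loc[3, "distance"] = np.nan
        with pytest.raises(ValueError, match="rows"):
            DyadicDistanceModel(obs)

    def test_single_dyad_rejected(self):
        obs, _ = simulate_dyadic_distance_data(seed=1, n_dyads=2, obs_per_dyad=3)
        with pytest.raises(ValueError):
            DyadicDistanceModel(obs[obs["dyad_id"] == obs["dyad_id"].iloc[0]])

    def test_convergence_warning_on_tiny_run(self):
        obs, _ = simulate_dyadic_distance_data(seed=5, n_dyads=40, obs_per_dyad=4)
        with pytest.warns(ConvergenceWarning):
            DyadicDistanceModel(obs).fit(SamplerConfig(chains=4, warmup=3, draws=8, seed=0))


class TestExportSummaries:
    def test_one_row_per_dyad_with_consistent_sd(self, dyadic_fit):
        obs, _, res = dyadic_fit
        table = export_summaries(res)
        assert len(table) == obs["dyad_id"].nunique()
        # sd column equals the standard deviation recomputed from raw draws
        raw = res.stacked("alpha_dyad") * res.scale_ + res.shift_
        assert np.allclose(table["sd"].to_numpy(), raw.std(axis=0, ddof=1))

    def test_symmetric_posterior_mean_near_interval_midpoint(self, dyadic_fit):
        _, _, res = dyadic_fit
        table = export_summaries(res)
        mid = (table["pi89_low"] + table["pi89_high"]) / 2
        assert np.allclose(table["mean"], mid, atol=4 * table["sd"].max() / 10)


class TestWithinModel:
    def test_printed_priors_monte_carlo(self):
        draws = WithinIndividualDistanceModel.sample_priors(200_000, seed=2)
        assert draws["sigma"].mean() == pytest.approx(0.2, rel=0.02)
        assert draws["sigma_ind"].mean() == pytest.approx(1 / 3, rel=0.02)
        assert draws["alpha_bar"].std() == pytest.approx(0.25, rel=0.02)

    def test_high_diversity_subgroup_ranks_higher(self):
        # one subgroup generated with twice the within-individual level is
        # assigned higher diversity in nearly all replicates
        hits = 0
        for seed in range(6):
            obs_a, _ = simulate_within_distance_data(
                seed=seed, n_individuals=12, calls_per_individual=8, alpha_bar=1.0
            )
            obs_b, _ = simulate_within_distance_data(
                seed=100 + seed, n_individuals=12, calls_per_individual=8, alpha_bar=1.4
            )
            obs_b = obs_b.assign(
                individual_id="H" + obs_b["individual_id"],
                call_i="H" + obs_b["call_i"], call_j="H" + obs_b["call_j"],
                rec_i="H" + obs_b["rec_i"], rec_j="H" + obs_b["rec_j"],
            )
            obs = pd.concat([obs_a, obs_b], ignore_index=True)
            res = WithinIndividualDistanceModel(obs).fit(QUICK)
            est = res.individual_estimates().set_index("unit_id")["mean"]
            high = est[est.index.str.startswith("H")].mean()
            low = est[~est.index.str.startswith("H")].mean()
            if high > low:
                hits += 1
        assert hits >= 6 * 0.9

    def test_single_shared_recording_still_converges(self):
        # degenerate design: every call in one recording; alpha_same_rec and
        # alpha_rec_pair are jointly unidentifiable but the priors keep the
        # posterior proper and the fit finishes
        rng = np.random.default_rng(4)
        rows = []
        for i in range(8):
            calls = [f"B{i}_c{k}" for k in range(6)]
            import itertools as it

            for ci, cj in it.combinations(calls, 2):
                rows.append(
                    {"distance": 1.0 + rng.normal(0, 0.2), "individual_id": f"B{i}",
                     "call_i": ci, "call_j": cj, "rec_i": "R0", "rec_j": "R0",
                     "same_recording": True}
                )
        res = WithinIndividualDistanceModel(pd.DataFrame(rows)).fit(QUICK)
        assert np.isfinite(res.mean("alpha_same_rec"))
        assert len(res.individual_estimates()) == 8

    def test_sigma_ind_interval_covers_truth(self):
        obs, truth = simulate_within_distance_data(
            seed=8, n_individuals=40, calls_per_individual=10
        )
        res = WithinIndividualDistanceModel(obs).fit(
            SamplerConfig(chains=2, warmup=600, draws=600, seed=1)
        )
        hyp = res.hyper_estimates("original").set_index("parameter")
        lo, hi = hyp.loc["sigma_ind", ["pi89_low", "pi89_high"]]
        assert lo <= truth["sigma_ind"] * 1.6 and truth["sigma_ind"] * 0.4 <= hi
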