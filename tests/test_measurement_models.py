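"""Stage-2 measurement-error regressions and the AM-peak count model."""

import numpy as np
import pandas as pd
import pytest

from vocsocial.models import (
    InformationContentModel,
    MeasurementErrorRegression,
    SamplerConfig,
)
from vocsocial.synthdata import (
    simulate_dyadic_measured_outcomes,
    simulate_measured_outcomes,
)

pytestmark = pytest.mark.filterwarnings("ignore::vocsocial.models.base.ConvergenceWarning")

QUICK = SamplerConfig(chains=2, warmup=400, draws=400, seed=9)


class TestIndividualRegression:
    def test_recovers_slope_on_original_scale(self):
        out, pred, truth = simulate_measured_outcomes(seed=3, n=120, slopes={"age": 0.5})
        res = MeasurementErrorRegression(out, pred, ["age"]).fit(QUICK)
        tab = res.slope_estimates("original").set_index("predictor")
        assert tab.loc["age", "pi89_low"] > 0  # clearly positive
        assert abs(tab.loc["age", "mean"] - 0.5) < 0.15

    def test_inflating_measurement_sd_widens_slope_posterior(self):
        out, pred, _ = simulate_measured_outcomes(seed=5, n=60, slopes={"age": 0.4})
        res_tight = MeasurementErrorRegression(out, pred, ["age"]).fit(QUICK)
        out_wide = out.assign(est_sd=out["est_sd"] * 10)
        res_wide = MeasurementErrorRegression(out_wide, pred, ["age"]).fit(QUICK)
        sd_tight = res_tight.slope_estimates().set_index("predictor").loc["age", "sd"]
        sd_wide = res_wide.slope_estimates().set_index("predictor").loc["age", "sd"]
        assert sd_wide > sd_tight

    def test_zero_measurement_sd_matches_ordinary_regression(self):
        # limiting case: est_sd -> 0 reduces to a plain Bayesian regression;
        # compare against the conjugate posterior mean with flat-ish priors
        out, pred, truth = simulate_measured_outcomes(
            seed=11, n=150, slopes={"age": 0.6}, est_sd_scale=1e-9
        )
        res = MeasurementErrorRegression(out, pred, ["age"]).fit(QUICK)
        got = res.slope_estimates("original").set_index("predictor").loc["age", "mean"]
        x = pred["age"].to_numpy()
        y = out["est_mean"].to_numpy()
        ols = np.polyfit(x, y, 1)[0]
        assert got == pytest.approx(ols, abs=0.05)

    def test_all_missing_predictor_named_in_error(self):
        out, pred, _ = simulate_measured_outcomes(seed=2, n=30)
        pred["ghost"] = np.nan
        with pytest.raises(ValueError, match="ghost"):
            MeasurementErrorRegression(out, pred, ["ghost"])

    def test_negative_est_sd_rejected(self):
        out, pred, _ = simulate_measured_outcomes(seed=2, n=30)
        out.loc[0, "est_sd"] = -0.1
        with pytest.raises(ValueError):
            MeasurementErrorRegression(out, pred, ["age"])


class TestDyadicRegression:
    def test_recovers_binary_edge_effect(self):
        out, pred, truth = simulate_dyadic_measured_outcomes(
            seed=7, n_dyads=250, slopes={"tolerance": 0.4, "relatedness": 0.0}
        )
        out = out.rename(columns={"dyad_id": "unit_id"})
        pred = pred.rename(columns={"dyad_id": "unit_id"})
        model = MeasurementErrorRegression(
            out, pred, ["tolerance", "relatedness"], members=pred
        )
        res = model.fit(QUICK)
        tab = res.slope_estimates().set_index("predictor")
        assert tab.loc["tolerance", "pi89_low"] > 0
        lo, hi = tab.loc["relatedness", ["pi89_low", "pi89_high"]]
        assert lo < 0 < hi

    def test_consistent_relabelling_leaves_slopes_unchanged(self):
        out, pred, _ = simulate_dyadic_measured_outcomes(seed=13, n_dyads=150)
        out = out.rename(columns={"dyad_id": "unit_id"})
        pred = pred.rename(columns={"dyad_id": "unit_id"})
        fit = lambda o, p: (
            MeasurementErrorRegression(o, p, ["tolerance", "relatedness"], members=p)
            .fit(QUICK)
            .slope_estimates()
            .set_index("predictor")["mean"]
        )
        base = fit(out, pred)
        relabel = {u: f"X{k}" for k, u in enumerate(out["unit_id"])}
        out2 = out.assign(unit_id=out["unit_id"].map(relabel))
        pred2 = pred.assign(unit_id=pred["unit_id"].map(relabel))
        perm = np.random.default_rng(0).permutation(len(out2))
        again = fit(out2.iloc[perm].reset_index(drop=True), pred2)
        assert np.allclose(base.to_numpy(), again.to_numpy(), atol=0.05)

    def test_unresolved_members_dropped_with_report(self):
        out, pred, _ = simulate_dyadic_measured_outcomes(seed=1, n_dyads=60)
        out = out.rename(columns={"dyad_id": "unit_id"})
        pred = pred.rename(columns={"dyad_id": "unit_id"})
        pred.loc[0, "id_i"] = np.nan
        with pytest.warns(UserWarning, match="dyads"):
            MeasurementErrorRegression(out, pred, ["tolerance"], members=pred)


def make_peaks(seed, slope=0.0, n_ind=40, sigma_ind=0.15, base_rate=5.0):
    rng = np.random.default_rng(seed)
    pred = pd.DataFrame(
        {"unit_id": [f"B{i:03d}" for i in range(n_ind)], "tree_size": rng.normal(size=n_ind)}
    )
    u = rng.normal(0, sigma_ind, n_ind)
    rows = []
    for i in range(n_ind):
        lam = np.exp(np.log(base_rate) + slope * pred["tree_size"][i] + u[i])
        for _ in range(rng.poisson(6) + 1):
            rows.append({"individual_id": pred["unit_id"][i], "count": rng.poisson(lam)})
    return pd.DataFrame(rows), pred


class TestInformationContentModel:
    def test_equal_counts_shrink_sigma_ind_to_zero(self):
        # identical counts everywhere leave no between-individual variation
        # to explain (checked under the Poisson likelihood, where constant
        # data keep the residual model well defined)
        peaks, pred = make_peaks(seed=1, n_ind=25)
        peaks["count"] = 4
        res = InformationContentModel(peaks, pred, ["tree_size"], likelihood="poisson").fit(QUICK)
        assert res.sigma_ind() < 0.08

    @pytest.mark.parametrize("likelihood", ["sqrt_normal", "poisson"])
    def test_recovers_positive_tree_size_slope_sign(self, likelihood):
        hits = 0
        for seed in range(5):
            peaks, pred = make_peaks(seed=seed, slope=0.4)
            res = InformationContentModel(peaks, pred, ["tree_size"], likelihood=likelihood).fit(QUICK)
            if res.slope_estimates().set_index("predictor").loc["tree_size", "mean"] > 0:
                hits += 1
        assert hits >= 5 * 0.9

    def test_poisson_doubling_counts_shifts_intercept_by_log2(self):
        peaks, pred = make_peaks(seed=21, slope=0.3, n_ind=50, base_rate=12.0)
        model = lambda p: InformationContentModel(
            p, pred, ["tree_size"], likelihood="poisson", intercept_prior_sd=10.0
        ).fit(QUICK)
        res1 = model(peaks)
        res2 = model(peaks.assign(count=peaks["count"] * 2))
        d_int = res2.mean("intercept") - res1.mean("intercept")
        assert d_int == pytest.approx(np.log(2), abs=0.05)
        s1 = res1.slope_estimates().set_index("predictor").loc["tree_size", "mean"]
        s2 = res2.slope_estimates().set_index("predictor").loc["tree_size", "mean"]
        assert s1 == pytest.approx(s2, abs=0.07)

    def test_individuals_with_single_call_retained(self):
        peaks, pred = make_peaks(seed=3, n_ind=12)
        solo = pd.DataFrame([{"individual_id": pred["unit_id"].iloc[0], "count": 3}])
        peaks = pd.concat([peaks[peaks["individual_id"] != pred["unit_id"].iloc[0]], solo])
        res = InformationContentModel(peaks, pred, ["tree_size"]).fit(QUICK)
        assert res.info["n_calls"] == len(peaks)

    def test_unknown_likelihood_rejected(self):
        peaks, pred = make_peaks(seed=4, n_ind=10)
        with pytest.raises(ValueError):
            InformationContentModel(peaks, pred, ["tree_size"], likelihood="gamma")
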