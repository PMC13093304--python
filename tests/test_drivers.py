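import numpy as np
import pandas as pd
import pytest

from ftcflux import (
    DEFAULT_HYPERPARAMS,
    build_feature_table,
    detect_events,
    event_resistance,
    exact_shapley,
    explain_model,
    fit_gbt,
    mean_abs_phi,
    shapley_dependence_table,
)
from ftcflux.drivers import encode_features

from oracles import oracle_permutation_shapley


def _random_table(n=200, seed=0, target_fn=None):
    rng = np.random.default_rng(seed)
    igbp = rng.choice(["DBF", "ENF", "MF", "GRA", "CRO"], n)
    df = pd.DataFrame({
        "duration": rng.integers(10, 160, n).astype(float),
        "elevation": rng.uniform(50, 3000, n),
        "mat": rng.uniform(-2, 14, n),
        "map": rng.uniform(400, 1300, n),
        "igbp": igbp,
    }, index=pd.Index([f"E{i}" for i in range(n)], name="event_id"))
    if target_fn is None:
        target_fn = lambda d: 0.002 * d["duration"] + 0.0001 * d["elevation"]
    df["rt_re"] = target_fn(df)
    return df


class TestBuildFeatureTable:
    def test_join_on_synthetic_network(self, recovery_network, site_records):
        events, records = [], []
        for (series, _), site in zip(recovery_network[:3], site_records):
            evs = detect_events(series)
            for ev in evs:
                rec = event_resistance(ev, series)
                records.append(rec)
            events.extend(evs)
        table = build_feature_table(records, events, site_records, target="rt_re")
        assert set(table.columns) == {"duration", "elevation", "mat", "map", "igbp", "rt_re"}
        assert len(table) == sum(r.valid for r in records)
        # metadata joined from the right site
        ev0 = events[0]
        site0 = next(s for s in site_records if s.site_id == ev0.site_id)
        assert table.loc[ev0.event_id, "elevation"] == site0.elevation
        assert table.loc[ev0.event_id, "duration"] == ev0.duration

    def test_empty_when_no_valid_records(self, site_records):
        table = build_feature_table([], [], site_records)
        assert len(table) == 0

    def test_duplicate_event_ids_rejected(self, recovery_network, site_records):
        series, _ = recovery_network[0]
        evs = detect_events(series)
        with pytest.raises(ValueError, match="duplicate"):
            build_feature_table([], evs + [evs[0]], site_records)


class TestFitGbt:
    def test_defaults_are_final_tuned_hyperparameters(self):
        assert DEFAULT_HYPERPARAMS == {"max_depth": 4, "eta": 0.5, "nrounds": 20}
        fit = fit_gbt(_random_table(80), target="rt_re", seed=1)
        assert fit.hyperparams == DEFAULT_HYPERPARAMS

    def test_noiseless_additive_target_high_oof_skill(self):
        fit = fit_gbt(_random_table(500, seed=2), target="rt_re", seed=2)
        assert fit.r2 > 0.95
        assert fit.slope == pytest.approx(1.0, abs=0.1)

    def test_constant_target_reports_zero_r2(self, caplog):
        table = _random_table(60, seed=3, target_fn=lambda d: np.full(len(d), 0.25))
        with caplog.at_level("WARNING", logger="ftcflux"):
            fit = fit_gbt(table, target="rt_re", seed=3)
        assert fit.r2 == 0.0
        assert fit.mae == pytest.approx(0.0, abs=1e-6)
        preds = fit.predict(encode_features(table)[0])
        assert np.ptp(preds) == pytest.approx(0.0, abs=1e-9)

    def test_row_order_invariance_given_seed(self):
        table = _random_table(100, seed=4,
                              target_fn=lambda d: 0.01 * d["mat"] + 0.001 * d["duration"])
        noisy = table.copy()
        rng = np.random.default_rng(5)
        noisy["rt_re"] += rng.normal(0, 0.02, len(noisy))
        fit_a = fit_gbt(noisy, seed=7)
        fit_b = fit_gbt(noisy.iloc[::-1], seed=7)
        assert fit_a.r2 == pytest.approx(fit_b.r2, abs=1e-9)
        assert fit_a.mae == pytest.approx(fit_b.mae, abs=1e-9)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            fit_gbt(_random_table(8), cv_k=5)


class TestExactShapley:
    def _background(self, n=40, seed=0, k=3):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(rng.normal(size=(n, k)), columns=[f"x{i}" for i in range(k)])

    def test_constant_predictor_all_zero(self):
        bg = self._background()
        ex = exact_shapley(lambda df: np.full(len(df), 2.5), bg, bg.iloc[0])
        assert all(abs(v) < 1e-12 for v in ex.phi.values())
        assert ex.baseline == pytest.approx(2.5)

    def test_additivity_axiom(self):
        bg = self._background()
        g = lambda df: df["x0"].to_numpy() ** 2 - 3.0 * df["x2"].to_numpy()
        inst = bg.iloc[7]
        ex = exact_shapley(g, bg, inst)
        assert ex.phi["x0"] == pytest.approx(inst["x0"] ** 2 - (bg["x0"] ** 2).mean(), abs=1e-9)
        assert ex.phi["x2"] == pytest.approx(-3.0 * (inst["x2"] - bg["x2"].mean()), abs=1e-9)
        assert ex.phi["x1"] == pytest.approx(0.0, abs=1e-12)  # dummy axiom

    def test_symmetry_axiom(self):
        bg = self._background(seed=1)
        bg["x1"] = bg["x0"]  # exchangeable columns
        f = lambda df: df["x0"].to_numpy() * df["x1"].to_numpy()
        inst = bg.iloc[3]
        ex = exact_shapley(f, bg, inst)
        assert ex.phi["x0"] == pytest.approx(ex.phi["x1"], abs=1e-9)

    def test_efficiency_on_fitted_booster(self):
        table = _random_table(120, seed=6,
                              target_fn=lambda d: 0.002 * d["duration"]
                              + 0.05 * (d["igbp"] == "ENF"))
        fit = fit_gbt(table, seed=6)
        explanations, shap_df = explain_model(fit, table.iloc[:10], background_size=50, seed=6)
        for ex in explanations:
            assert sum(ex.phi.values()) + ex.baseline == pytest.approx(ex.fx, abs=1e-6)
        assert set(shap_df["feature"]) == {"duration", "elevation", "mat", "map", "igbp"}

    def test_matches_permutation_average_oracle(self):
        """Subset-enumeration Shapley equals the mean marginal contribution
        over all feature orderings, on a nonlinear 3-feature predictor."""
        bg = self._background(n=25, seed=2)
        rng = np.random.default_rng(3)
        w = rng.normal(size=3)

        def tree_like(df):
            x = df.to_numpy()
            return np.where(x[:, 0] > 0, w[0] * x[:, 1], w[1] * x[:, 2]) + w[2] * (x[:, 0] > 0.5)

        inst = bg.iloc[11]
        players = {c: [c] for c in bg.columns}
        ex = exact_shapley(tree_like, bg, inst, players=players)
        oracle = oracle_permutation_shapley(tree_like, bg, inst, players)
        for k in players:
            assert ex.phi[k] == pytest.approx(oracle[k], abs=1e-12)

    def test_too_many_players_rejected(self):
        bg = pd.DataFrame(np.zeros((2, 16)), columns=[f"c{i}" for i in range(16)])
        with pytest.raises(ValueError, match="sampling"):
            exact_shapley(lambda df: np.zeros(len(df)), bg, bg.iloc[0])

    def test_grouped_one_hot_counts_as_single_player(self):
        table = _random_table(60, seed=8)
        fit = fit_gbt(table, seed=8)
        explanations, _ = explain_model(fit, table.iloc[:2], seed=8)
        assert set(explanations[0].phi) == {"duration", "elevation", "mat", "map", "igbp"}


class TestImportanceAndDependence:
    def test_dominant_driver_recovered(self):
        table = _random_table(150, seed=9, target_fn=lambda d: 0.01 * d["duration"])
        fit = fit_gbt(table, seed=9)
        _, shap_df = explain_model(fit, table, background_size=40, seed=9)
        ranking = mean_abs_phi(shap_df)
        assert ranking.index[0] == "duration"
        assert ranking.iloc[0] > 3 * ranking.iloc[1]

    def test_dependence_table_shape(self):
        table = _random_table(60, seed=10)
        fit = fit_gbt(table, seed=10)
        _, shap_df = explain_model(fit, table.iloc[:5], seed=10)
        dep = shapley_dependence_table(shap_df, "duration", "elevation")
        assert len(dep) == 5
        assert list(dep.columns) == ["event_id", "duration", "phi_duration", "elevation"]

    def test_unknown_feature_rejected(self):
        table = _random_table(60, seed=10)
        fit = fit_gbt(table, seed=10)
        _, shap_df = explain_model(fit, table.iloc[:2], seed=10)
        with pytest.raises(ValueError):
            shapley_dependence_table(shap_df, "slope", "mat")
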