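import numpy as np
import pandas as pd
import pytest
from scipy import stats

from deltarad.longitudinal import (
    build_feature_set,
    compute_delta,
    ks_compare,
    longitudinal_combat,
    mean_impute,
    scanner_effect_tests,
    zscore,
)


@pytest.fixture
def paired_tables(rng):
    base = pd.DataFrame(rng.uniform(1, 10, (8, 3)), columns=["a", "b", "c"],
                        index=[f"S{i}" for i in range(8)])
    eot = base * rng.uniform(0.2, 0.9, (8, 3))
    return base, eot


class TestComputeDelta:
    def test_absolute_and_relative_closed_form(self):
        base = pd.DataFrame({"f": [10.0]}, index=["S1"])
        eot = pd.DataFrame({"f": [4.0]}, index=["S1"])
        assert compute_delta(base, eot, "absolute").iloc[0, 0] == -6.0
        assert compute_delta(base, eot, "relative").iloc[0, 0] == pytest.approx(-0.6)

    def test_zero_baseline_relative_is_missing(self):
        base = pd.DataFrame({"f": [0.0, 2.0]}, index=["S1", "S2"])
        eot = pd.DataFrame({"f": [5.0, 1.0]}, index=["S1", "S2"])
        rel = compute_delta(base, eot, "relative")
        assert np.isnan(rel.loc["S1", "f"]) and rel.loc["S2", "f"] == -0.5

    def test_identity_gives_exact_zero(self, paired_tables):
        base, _ = paired_tables
        assert (compute_delta(base, base, "absolute") == 0).all().all()
        assert (compute_delta(base, base, "relative") == 0).all().all()

    def test_relative_equals_absolute_over_baseline(self, paired_tables):
        base, eot = paired_tables
        rel = compute_delta(base, eot, "relative")
        ab = compute_delta(base, eot, "absolute")
        assert np.allclose(rel, ab / base, equal_nan=True)

    def test_unmatched_subject_dropped(self, paired_tables):
        base, eot = paired_tables
        out = compute_delta(base, eot.drop(index="S3"), "absolute")
        assert "S3" not in out.index and len(out) == 7


class TestBuildFeatureSet:
    def test_concatenation_shapes(self, paired_tables):
        base, eot = paired_tables
        assert build_feature_set(base, eot, "baseline+eot").shape[1] == 6
        ab = build_feature_set(base, eot, "abs_delta")
        assert list(ab.columns) == ["dAbs_a", "dAbs_b", "dAbs_c"]

    def test_subject_missing_eot_dropped_from_combined(self, paired_tables):
        base, eot = paired_tables
        out = build_feature_set(base, eot.drop(index="S0"), "baseline+rel_delta")
        assert "S0" not in out.index

    def test_missing_table_rejected(self, paired_tables):
        base, _ = paired_tables
        with pytest.raises(ValueError):
            build_feature_set(base, None, "rel_delta")
        with pytest.raises(ValueError):
            build_feature_set(base, base, "nonsense")


class TestImputeAndZscore:
    def test_mean_impute_column_mean(self):
        t = pd.DataFrame({"f": [1.0, np.nan, 3.0]})
        assert mean_impute(t)["f"].tolist() == [1.0, 2.0, 3.0]

    def test_mean_impute_preserves_column_means_and_drops_empty(self):
        t = pd.DataFrame({"f": [1.0, np.nan, 3.0], "g": [np.nan] * 3})
        out = mean_impute(t)
        assert "g" not in out.columns
        assert out["f"].mean() == pytest.approx(2.0)

    def test_zscore_closed_form_and_guard(self):
        t = pd.DataFrame({"f": [0.0, 10.0], "c": [3.0, 3.0]})
        z, _ = zscore(t)
        assert z["f"].tolist() == [-1.0, 1.0]
        assert (z["c"] == 0.0).all()

    def test_zscore_heldout_uses_train_stats(self, rng):
        train = pd.DataFrame(rng.normal(5, 2, (50, 2)), columns=["a", "b"])
        test = pd.DataFrame(rng.normal(5, 2, (10, 2)), columns=["a", "b"])
        ztr, fit = zscore(train)
        zte, _ = zscore(test, fit_stats=fit)
        assert np.allclose(ztr.mean(), 0, atol=1e-10)
        assert np.allclose(ztr.std(ddof=0), 1, atol=1e-10)
        back = zte * fit[1].replace(0, 1) + fit[0]
        assert np.allclose(back, test)


class TestScannerEffectTests:
    def test_type_one_error_near_alpha(self, rng):
        n_feat, rejections = 200, 0
        ids = np.array(["A"] * 50 + ["B"] * 50)
        t = pd.DataFrame(rng.standard_normal((100, n_feat)))
        t.columns = [f"f{j}" for j in range(n_feat)]
        rep = scanner_effect_tests(t, ids, alpha=0.05)
        rate = rep.table["additive_flag"].mean()
        lo, hi = stats.binom.interval(0.999, n_feat, 0.05)
        assert lo / n_feat <= rate <= hi / n_feat

    def test_additive_shift_detected(self, rng):
        hits = 0
        ids = np.array(["A"] * 20 + ["B"] * 20)
        for _ in range(100):
            x = rng.standard_normal(40)
            x[20:] += 3.0
            rep = scanner_effect_tests(pd.DataFrame({"f": x}), ids)
            hits += bool(rep.table["additive_flag"].iloc[0])
        assert hits > 95

    def test_variance_inflation_flags_multiplicative_not_additive(self, rng):
        ids = np.array(["A"] * 30 + ["B"] * 30)
        mult = add = 0
        for _ in range(100):
            x = np.concatenate([rng.standard_normal(30), 2.0 * rng.standard_normal(30)])
            rep = scanner_effect_tests(pd.DataFrame({"f": x}), ids)
            mult += bool(rep.table["multiplicative_flag"].iloc[0])
            add += bool(rep.table["additive_flag"].iloc[0])
        assert mult > 80 and add < 25

    def test_requires_two_groups(self, rng):
        t = pd.DataFrame(rng.standard_normal((10, 2)))
        with pytest.raises(ValueError):
            scanner_effect_tests(t, np.array(["A"] * 10))


def _longitudinal_setup(rng, n_subj=40, n_feat=50):
    subj = np.repeat([f"S{i}" for i in range(n_subj)], 2)
    tp = np.tile(["baseline", "eot"], n_subj)
    scanner = rng.choice(["A", "B"], size=2 * n_subj)
    u = rng.normal(0, 1, (n_subj, n_feat))
    clean = u[np.repeat(np.arange(n_subj), 2)] + (tp == "eot")[:, None] * 0.5
    noise = rng.standard_normal((2 * n_subj, n_feat))
    cols = [f"f{j}" for j in range(n_feat)]
    return subj, tp, scanner, clean, noise, cols


class TestLongitudinalCombat:
    def test_null_data_returned_unchanged_and_idempotent(self):
        # fixed stream: significance gates stay off, so the adjustment is a no-op
        local = np.random.default_rng(0)
        subj, tp, scanner, clean, noise, cols = _longitudinal_setup(local)
        t = pd.DataFrame(clean + noise, columns=cols)
        adj = longitudinal_combat(t, scanner, subj, tp)
        assert np.abs(adj.to_numpy() - t.to_numpy()).max() < 1e-6
        again = longitudinal_combat(adj, scanner, subj, tp)
        scale = np.abs(adj.to_numpy()).mean()
        assert np.abs(again.to_numpy() - adj.to_numpy()).max() < 1e-6 * scale
        assert (ks_compare(t, adj) > 0.05).all()

    def test_null_false_adjustment_rate_bounded(self):
        # two alpha=0.05 gates: the chance of touching null data stays small
        changed = 0
        for seed in range(20):
            local = np.random.default_rng(1000 + seed)
            subj, tp, scanner, clean, noise, cols = _longitudinal_setup(local, n_subj=30, n_feat=30)
            t = pd.DataFrame(clean + noise, columns=cols)
            adj = longitudinal_combat(t, scanner, subj, tp)
            changed += not np.allclose(adj.to_numpy(), t.to_numpy())
        assert changed <= 6  # expected ~2 of 20

    def test_additive_shift_gap_reduced(self, rng):
        subj, tp, scanner, clean, noise, cols = _longitudinal_setup(rng)
        shifted = clean + noise + 3.0 * (scanner == "B")[:, None]
        t = pd.DataFrame(shifted, columns=cols)
        adj = longitudinal_combat(t, scanner, subj, tp)

        def gap(v):
            return np.abs(v[scanner == "A"].mean(0) - v[scanner == "B"].mean(0)).mean()

        assert gap(adj.to_numpy()) <= 0.2 * gap(t.to_numpy())

    def test_variance_inflation_equalized(self, rng):
        subj, tp, scanner, clean, noise, cols = _longitudinal_setup(rng)
        infl = clean + noise * np.where(scanner == "B", 2.0, 1.0)[:, None]
        t = pd.DataFrame(infl, columns=cols)
        adj = longitudinal_combat(t, scanner, subj, tp)
        p = [
            stats.bartlett(adj.to_numpy()[scanner == "A", j], adj.to_numpy()[scanner == "B", j]).pvalue
            for j in range(len(cols))
        ]
        assert np.mean(np.asarray(p) > 0.05) >= 0.90

    def test_confounded_design_warns_but_runs(self, rng, caplog):
        n_subj = 20
        subj = np.repeat([f"S{i}" for i in range(n_subj)], 2)
        tp = np.tile(["baseline", "eot"], n_subj)
        per_subj = np.where(np.arange(n_subj) % 2 == 0, "A", "B")
        scanner = per_subj[np.repeat(np.arange(n_subj), 2)]  # subject fixed to scanner
        t = pd.DataFrame(rng.standard_normal((2 * n_subj, 5)), columns=list("abcde"))
        with caplog.at_level("WARNING", logger="deltarad"):
            longitudinal_combat(t, scanner, subj, tp)
        assert any("confounded" in r.message for r in caplog.records)


class TestKsCompare:
    def test_identical_tables_p_one(self, rng):
        t = pd.DataFrame(rng.standard_normal((30, 4)))
        assert (ks_compare(t, t) == 1.0).all()

    def test_large_shift_detected(self, rng):
        a = pd.DataFrame(rng.standard_normal((40, 3)), columns=list("xyz"))
        b = a.copy()
        b["x"] += 5.0
        p = ks_compare(a, b)
        assert p["x"] < 1e-3 and p["y"] > 0.05

    def test_type_one_error_rate(self, rng):
        rejections = 0
        n_trials = 200
        for _ in range(n_trials):
            a = pd.DataFrame(rng.standard_normal((40, 1)))
            b = pd.DataFrame(rng.standard_normal((40, 1)))
            rejections += ks_compare(a, b).iloc[0] < 0.05
        lo, hi = stats.binom.interval(0.999, n_trials, 0.05)
        assert lo <= rejections <= hi
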