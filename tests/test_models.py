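"""Data splitting, both regressor families, and permutation importance."""

import numpy as np
import pandas as pd
import pytest

from maizephase import (RecurrentNetConfig, SplitSpec, TreeEnsembleConfig,
                        importance, predict, split_data, train_recurrent,
                        train_tree_ensemble)
from maizephase.errors import ConfigurationError, InputError
from maizephase.models import (_gru_backward, _gru_forward, _init_gru_params,
                               _r2)


def frame_with(n, seed, columns, target_fn, site_years=10):
    rng = np.random.default_rng(seed)
    data = {c: rng.uniform(0, 1, n) for c in columns}
    frame = pd.DataFrame(data)
    frame["yield"] = target_fn(frame, rng)
    frame["site"] = "s0"
    frame["year"] = rng.integers(0, site_years, n)
    return frame


class TestSplit:
    def test_nine_to_one_arithmetic(self):
        frame = frame_with(1000, 0, ["a"], lambda f, r: f["a"])
        train, test = split_data(frame, SplitSpec(seed=1))
        assert len(train) == 900 and len(test) == 100
        assert set(train.index).isdisjoint(test.index)
        assert len(train) + len(test) == len(frame)

    def test_same_seed_reproduces_partition(self):
        frame = frame_with(500, 2, ["a"], lambda f, r: f["a"])
        t1, e1 = split_data(frame, SplitSpec(seed=9))
        t2, e2 = split_data(frame, SplitSpec(seed=9))
        assert t1.index.equals(t2.index) and e1.index.equals(e2.index)
        t3, _ = split_data(frame, SplitSpec(seed=10))
        assert not t1.index.equals(t3.index)

    def test_grouped_split_keeps_site_years_together(self):
        frame = frame_with(400, 3, ["a"], lambda f, r: f["a"])
        train, test = split_data(frame, SplitSpec(seed=4, grouping="by_site_year"))
        train_groups = set(zip(train["site"], train["year"]))
        test_groups = set(zip(test["site"], test["year"]))
        assert train_groups.isdisjoint(test_groups)
        assert len(test) > 0

    def test_single_group_rejected(self):
        frame = frame_with(50, 5, ["a"], lambda f, r: f["a"], site_years=1)
        with pytest.raises(ConfigurationError):
            split_data(frame, SplitSpec(grouping="by_site_year"))


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        n_layers, units, n_feat, steps, batch = 2, 4, 3, 4, 5
        params = _init_gru_params(rng, n_layers, units, n_feat, dense_units=5,
                                  dtype=np.float64)
        x = rng.normal(size=(batch, steps, n_feat))
        y = rng.normal(size=batch)
        _, grads = _gru_backward(params, x, y, n_layers, units)
        eps = 1e-6
        for k, v in params.items():
            it = np.nditer(v, flags=["multi_index"])
            for _ in range(min(v.size, 4)):
                idx = it.multi_index
                old = v[idx]
                v[idx] = old + eps
                yp, _, _ = _gru_forward(params, x, n_layers, units)
                v[idx] = old - eps
                ym, _, _ = _gru_forward(params, x, n_layers, units)
                v[idx] = old
                num = (np.mean((yp - y) ** 2) - np.mean((ym - y) ** 2)) / (2 * eps)
                assert grads[k][idx] == pytest.approx(num, rel=1e-3, abs=1e-8)
                it.iternext()


class TestTreeEnsemble:
    def test_learns_noiseless_linear_map(self):
        frame = frame_with(1500, 1, ["a", "b"], lambda f, r: 2.0 * f["a"])
        train, test = split_data(frame, SplitSpec(seed=0))
        cfg = TreeEnsembleConfig(n_estimators_grid=(100,),
                                 max_depth_grid=(None,),
                                 max_features_grid=(1.0,), cv_folds=3)
        model = train_tree_ensemble(train, ["a", "b"], cfg)
        r2 = _r2(test["yield"].to_numpy(), predict(model, test))
        assert r2 > 0.99

    def test_independent_target_scores_near_zero(self):
        frame = frame_with(2000, 2, ["a", "b"],
                           lambda f, r: r.normal(size=len(f)))
        train, test = split_data(frame, SplitSpec(seed=0))
        cfg = TreeEnsembleConfig(n_estimators_grid=(100,), max_depth_grid=(8,),
                                 max_features_grid=(1.0,), cv_folds=3)
        model = train_tree_ensemble(train, ["a", "b"], cfg)
        r2 = _r2(test["yield"].to_numpy(), predict(model, test))
        assert abs(r2) < 0.1

    def test_single_stump_recovers_step_threshold(self):
        frame = frame_with(2000, 3, ["a"],
                           lambda f, r: (f["a"] > 0.6).astype(float))
        train, test = split_data(frame, SplitSpec(seed=0))
        cfg = TreeEnsembleConfig(n_estimators_grid=(1,), max_depth_grid=(1,),
                                 max_features_grid=(1.0,), cv_folds=3)
        model = train_tree_ensemble(train, ["a"], cfg)
        # brute-force best single split on the training set
        a = np.sort(train["a"].to_numpy())
        y = train.set_index(np.arange(len(train)))["yield"].to_numpy()
        order = np.argsort(train["a"].to_numpy())
        ys = y[order]
        best, best_err = None, np.inf
        csum = np.cumsum(ys)
        total = csum[-1]
        nn = len(ys)
        for i in range(1, nn):
            left, right = csum[i - 1], total - csum[i - 1]
            err = -(left ** 2 / i + right ** 2 / (nn - i))
            if err < best_err:
                best_err, best = err, (a[i - 1] + a[i]) / 2
        tree_threshold = model.inner.estimators_[0].tree_.threshold[0]
        lo, hi = model.x_bounds["a"]
        assert tree_threshold * (hi - lo) + lo == pytest.approx(best, abs=0.02)

    def test_degenerate_target_rejected(self):
        frame = frame_with(100, 4, ["a"], lambda f, r: np.full(len(f), 5.0))
        with pytest.raises(InputError, match="zero variance"):
            train_tree_ensemble(frame, ["a"])


def quick_rcfg(**kw):
    base = dict(n_layers=1, units=16, epochs=60, batch_size=64,
                learning_rate=5e-3, dropout=0.0, patience=30, seed=0)
    base.update(kw)
    return RecurrentNetConfig(**base)


def sequence_frame(n, seed, steps=4, width=2, target="linear"):
    rng = np.random.default_rng(seed)
    cols, layout = [], []
    for t in range(steps):
        step_cols = [f"f{w}_T{t}" for w in range(width)]
        layout.append((f"T{t}", step_cols))
        cols.extend(step_cols)
    frame = pd.DataFrame({c: rng.uniform(0, 1, n) for c in cols})
    if target == "linear":
        frame["yield"] = sum(
            (i + 1) * frame[c] for i, c in enumerate(cols)) * 100.0
    elif target == "last_step":
        frame["yield"] = 1000.0 * frame[layout[-1][1][0]]
    else:
        frame["yield"] = np.full(n, 5000.0)
    return frame, layout


class TestRecurrent:
    def test_fits_linear_four_step_target(self):
        frame, layout = sequence_frame(5000, 0)
        train, test = frame.iloc[:4500], frame.iloc[4500:]
        model = train_recurrent(train, layout, quick_rcfg())
        r2 = _r2(test["yield"].to_numpy(), predict(model, test))
        assert r2 > 0.95

    def test_constant_inputs_predict_training_mean(self):
        rng = np.random.default_rng(1)
        frame, layout = sequence_frame(300, 1)
        for _, cols in layout:
            for c in cols:
                frame[c] = 0.7
        frame["yield"] = rng.uniform(1000, 2000, len(frame))
        model = train_recurrent(frame, layout, quick_rcfg(epochs=80))
        preds = predict(model, frame)
        assert np.allclose(preds, preds[0], atol=1.0)
        assert preds[0] == pytest.approx(frame["yield"].mean(), rel=0.15)

    def test_single_step_layout_warns_but_runs(self):
        frame, layout = sequence_frame(300, 2, steps=1)
        with pytest.warns(UserWarning, match="sequence length"):
            model = train_recurrent(frame, layout, quick_rcfg(epochs=10))
        assert np.isfinite(predict(model, frame)).all()

    def test_seeded_rerun_reproduces_predictions(self):
        frame, layout = sequence_frame(600, 3)
        m1 = train_recurrent(frame, layout, quick_rcfg(epochs=15))
        m2 = train_recurrent(frame, layout, quick_rcfg(epochs=15))
        assert np.allclose(predict(m1, frame), predict(m2, frame))

    def test_mismatched_step_widths_rejected(self):
        frame, layout = sequence_frame(100, 4)
        bad = [layout[0], (layout[1][0], layout[1][1][:1])]
        with pytest.raises(ConfigurationError):
            train_recurrent(frame, bad, quick_rcfg(epochs=2))


class TestPredict:
    def test_row_permutation_permutes_outputs(self):
        frame = frame_with(400, 6, ["a", "b"], lambda f, r: 3 * f["a"] + f["b"])
        cfg = TreeEnsembleConfig(n_estimators_grid=(50,), max_depth_grid=(None,),
                                 max_features_grid=(1.0,), cv_folds=3)
        model = train_tree_ensemble(frame, ["a", "b"], cfg)
        base = predict(model, frame)
        perm = np.random.default_rng(0).permutation(len(frame))
        assert np.allclose(predict(model, frame.iloc[perm]), base[perm])

    def test_missing_columns_named_in_error(self):
        frame = frame_with(100, 7, ["a"], lambda f, r: f["a"])
        model = train_tree_ensemble(
            frame, ["a"],
            TreeEnsembleConfig(n_estimators_grid=(10,), max_depth_grid=(3,),
                               max_features_grid=(1.0,), cv_folds=2))
        with pytest.raises(InputError, match="missing columns"):
            predict(model, frame.drop(columns=["a"]).assign(b=1.0))


class TestImportance:
    def test_single_informative_feature_dominates(self):
        frame = frame_with(1500, 8, ["a", "b", "c"], lambda f, r: 10.0 * f["a"])
        train, test = split_data(frame, SplitSpec(seed=0))
        cfg = TreeEnsembleConfig(n_estimators_grid=(100,), max_depth_grid=(None,),
                                 max_features_grid=(1.0,), cv_folds=3)
        model = train_tree_ensemble(train, ["a", "b", "c"], cfg)
        imp = importance(model, test, seed=1)
        assert imp["a"] > 0.8
        assert imp["b"] < 0.1 and imp["c"] < 0.1
        assert sum(imp.values()) == pytest.approx(1.0, abs=1e-9)

    def test_recurrent_importance_concentrates_on_last_step(self):
        frame, layout = sequence_frame(2000, 9, target="last_step")
        train, test = frame.iloc[:1800], frame.iloc[1800:]
        model = train_recurrent(train, layout, quick_rcfg())
        imp = importance(model, test, seed=2)
        last_cols = layout[-1][1]
        assert imp[last_cols[0]] > 0.7
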