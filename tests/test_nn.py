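"""Constrained sigmoid network: features, backprop, thresholding, CV."""

import numpy as np
import pytest

from genevec.nn import (
    NNModel,
    TrainConfig,
    backprop_update,
    calibrate_threshold,
    criterion_evaluate,
    cross_cohort_overlap,
    exclude_high_missing,
    forward,
    kfold_cv,
    one_hot_encode,
    outputs,
    random_walk_search,
    split_half_stability,
    stratified_folds,
    train,
)
from genevec.vectors import MISSING, GeneVectorMatrix, GeneDefinition


# --------------------------------------------------------------------------
# features


def _matrix(codes_by_gene, n):
    genes = [
        GeneDefinition(g, "1", 1, 10**6, [f"{g}_s{k}" for k in range(4)])
        for g in codes_by_gene
    ]
    codes = np.column_stack([codes_by_gene[g.gene] for g in genes]).astype(np.int32)
    return GeneVectorMatrix([f"s{i}" for i in range(n)], genes, codes)


def test_one_hot_rare_patterns_pool_to_other():
    codes = [5] * 50 + [9] * 3
    m = _matrix({"g": codes}, 53)
    fm = one_hot_encode(m, ["g"], min_count=5)
    assert fm.names == ["g:5", "g:OTHER"]
    assert fm.X[0].tolist() == [1.0, 0.0]
    assert fm.X[-1].tolist() == [0.0, 1.0]  # code 9 -> OTHER


def test_one_hot_missing_vector_gives_zero_block():
    codes = [5] * 10 + [MISSING]
    m = _matrix({"g": codes}, 11)
    fm = one_hot_encode(m, ["g"], min_count=2)
    assert fm.X[-1].sum() == 0.0


def test_one_hot_block_row_sums():
    rng = np.random.default_rng(0)
    m = _matrix({"gA": rng.integers(0, 6, 200), "gB": rng.integers(0, 81, 200)}, 200)
    fm = one_hot_encode(m, ["gA", "gB"], min_count=5)
    for g in ("gA", "gB"):
        block = fm.X[:, fm.blocks[g]]
        assert set(np.unique(block.sum(axis=1))) <= {0.0, 1.0}
    with pytest.raises(ValueError):
        one_hot_encode(m, [])


def test_exclude_high_missing(small_cohort):
    table = small_cohort.genotypes
    kept = exclude_high_missing(table, cutoff=0.05)
    rates = dict(zip(table.subjects, table.missing_rate_per_subject()))
    assert all(rates[s] <= 0.05 for s in kept)
    dropped = set(table.subjects) - set(kept)
    assert all(rates[s] > 0.05 for s in dropped)
    # the generator plants ~14.5% high-missing subjects
    assert 0.02 < len(dropped) / table.n_subjects < 0.30


# --------------------------------------------------------------------------
# forward / backprop


def test_forward_zero_weights_gives_half():
    model = NNModel(np.zeros((1, 1)), np.zeros((1, 1)), alpha=1.0)
    out, hidden = forward(model, [1.0])
    assert out[0] == pytest.approx(0.5)
    assert hidden[0] == pytest.approx(0.5)


def test_forward_matches_scalar_reimplementation():
    """Independent matrix-free evaluation of the layer equations."""
    import math

    rng = np.random.default_rng(1)
    for _ in range(10):
        nk, nj = rng.integers(2, 6), rng.integers(2, 5)
        model = NNModel(rng.normal(0, 1, (nj, nk)), rng.normal(0, 1, (1, nj)))
        x = rng.normal(0, 1, nk)
        s_j = [1 / (1 + math.exp(-sum(model.w_jk[j, k] * x[k] for k in range(nk))))
               for j in range(nj)]
        s_i = 1 / (1 + math.exp(-sum(model.w_ij[0, j] * s_j[j] for j in range(nj))))
        out, hid = forward(model, x)
        assert out[0] == pytest.approx(s_i, abs=1e-12)
        assert hid == pytest.approx(s_j, abs=1e-12)


def test_forward_shape_mismatch():
    model = NNModel(np.zeros((2, 3)), np.zeros((1, 2)))
    with pytest.raises(ValueError):
        forward(model, [1.0, 2.0])


def test_backprop_hand_example():
    # 1-1-1 net, zero weights, x=1, y=1, alpha=1:
    # dw_ij = 1 * (1-0.5) * 0.5 * 0.5*(1-0.5) = 0.0625; dw_jk = 0 (w_ij = 0)
    model = NNModel(np.zeros((1, 1)), np.zeros((1, 1)), alpha=1.0)
    backprop_update(model, [1.0], [1.0])
    assert model.w_ij[0, 0] == pytest.approx(0.0625)
    assert model.w_jk[0, 0] == 0.0


def test_backprop_zero_alpha_no_update():
    rng = np.random.default_rng(2)
    model = NNModel(rng.normal(size=(3, 4)), rng.normal(size=(1, 3)))
    w1, w2 = model.w_jk.copy(), model.w_ij.copy()
    backprop_update(model, rng.normal(size=4), [1.0], alpha=0.0)
    assert np.array_equal(model.w_jk, w1) and np.array_equal(model.w_ij, w2)


def test_backprop_is_squared_error_gradient():
    """The update equals -alpha/2 times the finite-difference gradient of
    sum (y - s_i)^2 (spot check; the 100-network sweep runs in acceptance)."""

    def sse(w1, w2, x, y):
        h = 1 / (1 + np.exp(-(w1 @ x)))
        o = 1 / (1 + np.exp(-(w2 @ h)))
        return np.sum((y - o) ** 2)

    rng = np.random.default_rng(3)
    for _ in range(10):
        nk, nj, ni = rng.integers(2, 6), rng.integers(2, 5), rng.integers(1, 3)
        w1 = rng.normal(0, 0.8, (nj, nk))
        w2 = rng.normal(0, 0.8, (ni, nj))
        x = rng.normal(0, 1, nk)
        y = rng.integers(0, 2, ni).astype(float)
        model = NNModel(w1.copy(), w2.copy(), alpha=1.0)
        backprop_update(model, x, y)
        eps = 1e-6
        for W, dW, which in ((w1, model.w_jk - w1, "w1"), (w2, model.w_ij - w2, "w2")):
            num = np.zeros_like(W)
            for idx in np.ndindex(W.shape):
                Wp, Wm = W.copy(), W.copy()
                Wp[idx] += eps
                Wm[idx] -= eps
                if which == "w1":
                    fp, fm = sse(Wp, w2, x, y), sse(Wm, w2, x, y)
                else:
                    fp, fm = sse(w1, Wp, x, y), sse(w1, Wm, x, y)
                num[idx] = -(fp - fm) / (2 * eps) / 2
            np.testing.assert_allclose(dW, num, rtol=1e-5, atol=1e-9)


def test_train_loop_matches_online_updates():
    """One jitted epoch equals sequential per-probe backprop_update calls
    (with 0/1 targets so the reference arithmetic is identical)."""
    rng = np.random.default_rng(4)
    X = (rng.random((25, 8)) < 0.3).astype(float)
    y = rng.integers(0, 2, 25).astype(float)
    cfg = TrainConfig(iterations=3, eval_every=3, seed=0, n_hidden=5, alpha=0.4,
                      oscillation_tol=0, target_low=0.0, target_high=1.0)
    model, _ = train(X, y, cfg, rng=np.random.default_rng(9))
    ref = NNModel.initialize(8, 5, np.random.default_rng(9), alpha=0.4, scale=0.5)
    order_rng = np.random.default_rng(9)
    NNModel.initialize(8, 5, order_rng, alpha=0.4, scale=0.5)  # consume init draws
    for _ in range(3):
        for v in order_rng.permutation(25):
            backprop_update(ref, X[v], [y[v]], 0.4)
    np.testing.assert_allclose(model.w_jk, ref.w_jk, atol=1e-12)
    np.testing.assert_allclose(model.w_ij, ref.w_ij, atol=1e-12)


def test_train_rejects_single_class():
    X = np.ones((10, 2))
    with pytest.raises(ValueError):
        train(X, np.ones(10), TrainConfig(iterations=5))


# --------------------------------------------------------------------------
# constrained evaluation


def _model_with_outputs(targets):
    """Construct a net whose output for one-hot subject k is targets[k]."""
    n = len(targets)
    big = 50.0
    w1 = np.eye(n) * big
    h = np.where(np.eye(n) > 0, 1 / (1 + np.exp(-big)), 0.5)
    z = np.array([np.log(t / (1 - t)) for t in targets])
    w2 = np.linalg.solve(h, z).reshape(1, n)
    return NNModel(w1, w2), np.eye(n)


def test_criterion_enumeration_example():
    # outputs: non-responders {0.2, 0.4}, responders {0.3, 0.9}
    model, X = _model_with_outputs([0.2, 0.4, 0.3, 0.9])
    y = np.array([0, 0, 1, 1])
    res = criterion_evaluate(model, X, y, constraint_class=0)
    assert res.threshold == pytest.approx(0.4, abs=1e-6)
    assert res.constraint_accuracy == 1.0
    assert res.fp_count == 0
    assert res.sensitivity == 0.5  # only the 0.9 responder clears tau


def test_criterion_degenerate_equal_outputs():
    model, X = _model_with_outputs([0.4, 0.4, 0.4])
    res = criterion_evaluate(model, X, np.array([0, 1, 1]), constraint_class=0)
    assert res.sensitivity == 0.0
    assert res.constraint_accuracy == 1.0


def test_criterion_perfect_separation():
    model, X = _model_with_outputs([0.1, 0.2, 0.8, 0.9])
    res = criterion_evaluate(model, X, np.array([0, 0, 1, 1]), constraint_class=0)
    assert res.sensitivity == 1.0 and res.fp_count == 0


def test_criterion_constraint_guarantee_on_calibration(small_cohort):
    """The max+delta policy yields 100% constraint-class accuracy on its
    calibration data for any model."""
    rng = np.random.default_rng(5)
    X = (rng.random((60, 7)) < 0.3).astype(float)
    y = rng.integers(0, 2, 60)
    for _ in range(5):
        model = NNModel(rng.normal(size=(4, 7)), rng.normal(size=(1, 4)))
        res = criterion_evaluate(model, X, y, constraint_class=0)
        assert res.constraint_accuracy == 1.0
        assert res.fp_count == 0


def test_criterion_empty_constraint_class():
    model, X = _model_with_outputs([0.2, 0.8])
    with pytest.raises(ValueError):
        criterion_evaluate(model, X, np.array([1, 1]), constraint_class=0)


# --------------------------------------------------------------------------
# cross-validation


def test_stratified_folds_partition():
    y = np.array([0] * 12 + [1] * 8)
    folds = stratified_folds(y, 10, np.random.default_rng(0))
    assert len(folds) == 10
    all_idx = np.concatenate(folds)
    assert sorted(all_idx) == list(range(20))
    sizes = [len(f) for f in folds]
    assert max(sizes) - min(sizes) <= 1 and set(sizes) == {2}


def test_stratified_folds_class_balance():
    y = np.array([0] * 50 + [1] * 25)
    folds = stratified_folds(y, 5, np.random.default_rng(1))
    for f in folds:
        assert (y[f] == 1).sum() == 5


def test_kfold_pooled_counts_are_fold_sums():
    rng = np.random.default_rng(6)
    X = (rng.random((60, 10)) < 0.3).astype(float)
    y = np.array([0] * 40 + [1] * 20)
    res = kfold_cv(X, y, TrainConfig(iterations=30, k=5, seed=0, eval_every=30))
    assert res.fp_count == sum(f["fp"] for f in res.per_fold)
    assert res.tp_count == sum(f["tp"] for f in res.per_fold)
    assert res.n_positive == sum(f["n_positive"] for f in res.per_fold) == 20
    assert res.n_constraint == 40


def test_separable_toy_converges():
    """A perfectly predictive planted indicator is learned quickly: training
    criterion reaches specificity 1.0 and sensitivity 1.0."""
    rng = np.random.default_rng(7)
    X = (rng.random((80, 6)) < 0.3).astype(float)
    y = X[:, 0].copy()
    X[:, 0] = y  # planted column exactly equals the label
    cfg = TrainConfig(iterations=2000, seed=0, n_hidden=8, alpha=0.5,
                      eval_every=100, oscillation_window=5)
    model, _ = train(X, y, cfg, rng=np.random.default_rng(0))
    res = criterion_evaluate(model, X, y, constraint_class=0)
    assert res.constraint_accuracy == 1.0
    assert res.sensitivity == 1.0


def test_train_deterministic_under_seed():
    rng = np.random.default_rng(8)
    X = (rng.random((40, 6)) < 0.4).astype(float)
    y = np.array([0, 1] * 20)
    cfg = TrainConfig(iterations=50, seed=3, eval_every=25)
    m1, h1 = train(X, y, cfg, rng=np.random.default_rng(3))
    m2, h2 = train(X, y, cfg, rng=np.random.default_rng(3))
    assert np.array_equal(m1.w_jk, m2.w_jk) and h1 == h2


def test_random_walk_single_restart_matches_cv():
    rng = np.random.default_rng(9)
    X = (rng.random((50, 6)) < 0.4).astype(float)
    y = np.array([0] * 30 + [1] * 20)
    cfg = TrainConfig(iterations=40, k=5, seed=1, restarts=1, eval_every=40)
    model, best = random_walk_search(X, y, cfg)
    direct = kfold_cv(X, y, cfg, seed_offset=0)
    assert best.key == direct.key
    assert model.threshold is not None


def test_cross_cohort_overlap_bounds():
    model, X = _model_with_outputs([0.2, 0.8, 0.6])
    model.threshold = 0.5
    assert cross_cohort_overlap(model, X) == pytest.approx(2 / 3)
    assert cross_cohort_overlap(model, np.zeros((0, 3))) == 0.0
    with pytest.raises(ValueError):
        cross_cohort_overlap(model, np.zeros((2, 5)))


def test_split_half_separable_drop_near_zero():
    rng = np.random.default_rng(10)
    X = (rng.random((80, 5)) < 0.3).astype(float)
    y = X[:, 0].copy()
    cfg = TrainConfig(iterations=400, k=4, seed=0, n_hidden=6, alpha=0.5,
                      eval_every=100)
    rep = split_half_stability(X, y, cfg, repeats=4)
    assert abs(rep["mean_drop"]) < 0.1
    rep2 = split_half_stability(X, y, cfg, repeats=4)
    assert rep == rep2  # deterministic under fixed config
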