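"""Constrained multilayer sigmoid network over genotypic-pattern features.

The classifier is a fully connected feed-forward network with logistic
activations trained by online (per-probe) backpropagation of squared error:

    output:  s_i = sigma(sum_j w_ij s_j)
    hidden:  s_j = sigma(sum_k w_jk s_k)
    updates: dw_ij = alpha * eps_i * s_j * s_i (1 - s_i)
             dw_jk = alpha * sum_i eps_i * s_k * s_i (1 - s_i) * w_ij * s_j (1 - s_j)

with eps_i = y_i - s_i, exactly the gradient-descent step on squared error.
There are no bias terms.  Evaluation is Neyman-Pearson style: the decision
threshold is calibrated on training data as the maximum output over the
constraint class plus a tiny delta, which enforces 100% correct
classification of the constraint class (e.g. non-responders) on the
calibration set; model quality is then judged lexicographically by
(constraint-class accuracy, fewest false positives, highest sensitivity).

Model search follows the study design: stratified 10-fold cross-validation,
random-walk restarts from perturbed initializations to escape local minima,
and greedy forward selection of classifier genes with a stability filter
across restarts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .vectors import MISSING, GenotypeTable, GeneVectorMatrix, pattern_catalog

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (a and callable(a[0])) else a[0]


__all__ = [
    "FeatureMatrix",
    "NNModel",
    "TrainConfig",
    "CriterionResult",
    "one_hot_encode",
    "exclude_high_missing",
    "forward",
    "backprop_update",
    "train",
    "criterion_evaluate",
    "calibrate_threshold",
    "stratified_folds",
    "kfold_cv",
    "random_walk_search",
    "select_classifier_genes",
    "cross_cohort_overlap",
    "split_half_stability",
]

OTHER = "OTHER"
THRESHOLD_DELTA = 1e-9


# --------------------------------------------------------------------------
# features


@dataclass
class FeatureMatrix:
    """Binary one-hot pattern indicators, one block of columns per gene."""

    subjects: list[str]
    names: list[str]
    X: np.ndarray  # (n, f) float64 in {0, 1}
    #: feature index -> (gene, pattern code or OTHER)
    provenance: list[tuple[str, object]]
    #: gene -> column indices of its block
    blocks: dict[str, list[int]] = field(default_factory=dict)

    def subset(self, genes: list[str]) -> "FeatureMatrix":
        idx = [i for g in genes for i in self.blocks[g]]
        return FeatureMatrix(
            subjects=self.subjects,
            names=[self.names[i] for i in idx],
            X=self.X[:, idx],
            provenance=[self.provenance[i] for i in idx],
            blocks={g: list(range(sum(len(self.blocks[h]) for h in genes[:k]),
                                  sum(len(self.blocks[h]) for h in genes[:k + 1])))
                    for k, g in enumerate(genes)},
        )


def one_hot_encode(
    matrix: GeneVectorMatrix,
    genes: list[str],
    min_count: int = 5,
    vocabulary: dict[str, list[int]] | None = None,
) -> FeatureMatrix:
    """Encode gene vectors as per-gene one-hot pattern indicators.

    Per gene, every pattern with at least ``min_count`` carriers gets an
    indicator column, plus one OTHER column absorbing rarer patterns.  A
    missing vector leaves the whole block at zero.  ``vocabulary`` (gene ->
    pattern codes) fixes the columns, for aligning a second cohort to a
    trained model's feature space (unseen patterns map to OTHER).
    """
    if not genes:
        raise ValueError("empty gene list")
    n = len(matrix.subjects)
    names: list[str] = []
    prov: list[tuple[str, object]] = []
    cols: list[np.ndarray] = []
    blocks: dict[str, list[int]] = {}
    for g in genes:
        codes = matrix.gene_codes(g)
        if vocabulary is not None:
            kept = list(vocabulary[g])
        else:
            cat = pattern_catalog(matrix, g)
            kept = cat.rows.loc[cat.rows["count"] >= min_count, "code"].tolist()
        start = len(names)
        for code in kept:
            names.append(f"{g}:{code}")
            prov.append((g, int(code)))
            cols.append((codes == code).astype(float))
        names.append(f"{g}:{OTHER}")
        prov.append((g, OTHER))
        in_kept = np.isin(codes, kept)
        cols.append(((codes != MISSING) & ~in_kept).astype(float))
        blocks[g] = list(range(start, len(names)))
    X = np.column_stack(cols) if cols else np.empty((n, 0))
    return FeatureMatrix(list(matrix.subjects), names, X, prov, blocks)


def exclude_high_missing(
    table: GenotypeTable, cutoff: float = 0.05
) -> list[str]:
    """Subjects whose missing-genotype fraction is <= cutoff (default 5%)."""
    rates = table.missing_rate_per_subject()
    return [s for s, r in zip(table.subjects, rates) if r <= cutoff]


# --------------------------------------------------------------------------
# network


@dataclass
class NNModel:
    """Layered sigmoid network: input (N_k) -> hidden (N_j) -> output (N_i)."""

    w_jk: np.ndarray  # (N_j, N_k) input -> hidden
    w_ij: np.ndarray  # (N_i, N_j) hidden -> output
    alpha: float = 0.5
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.w_jk = np.asarray(self.w_jk, dtype=float)
        self.w_ij = np.asarray(self.w_ij, dtype=float)
        if self.w_ij.shape[1] != self.w_jk.shape[0]:
            raise ValueError("weight matrix shapes inconsistent")
        if self.alpha <= 0:
            raise ValueError("learning rate must be positive")

    @property
    def n_inputs(self) -> int:
        return self.w_jk.shape[1]

    @classmethod
    def initialize(cls, n_inputs: int, n_hidden: int, rng: np.random.Generator,
                   alpha: float = 0.5, scale: float = 0.5) -> "NNModel":
        return cls(
            w_jk=rng.uniform(-scale, scale, size=(n_hidden, n_inputs)),
            w_ij=rng.uniform(-scale, scale, size=(1, n_hidden)),
            alpha=alpha,
        )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def forward(model: NNModel, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One forward pass: returns (output activations s_i, hidden activations s_j)."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != model.n_inputs:
        raise ValueError(f"expected {model.n_inputs} inputs, got {x.shape[-1]}")
    s_j = _sigmoid(x @ model.w_jk.T)
    s_i = _sigmoid(s_j @ model.w_ij.T)
    return s_i, s_j


def outputs(model: NNModel, X: np.ndarray) -> np.ndarray:
    """Network outputs for a batch, flattened for the single-output case."""
    return forward(model, X)[0].reshape(len(X), -1)[:, 0]


def backprop_update(model: NNModel, x: np.ndarray, y: np.ndarray,
                    alpha: float | None = None) -> NNModel:
    """One online update for probe (x, y); modifies the model in place.

    Both weight deltas are computed from the same forward pass (old weights)
    before either matrix is touched.
    """
    alpha = model.alpha if alpha is None else alpha
    x = np.asarray(x, dtype=float)
    y = np.atleast_1d(np.asarray(y, dtype=float))
    s_i, s_j = forward(model, x)
    s_i = np.atleast_1d(s_i)
    eps = y - s_i
    gi = eps * s_i * (1.0 - s_i)  # (N_i,)
    d_w_ij = alpha * np.outer(gi, s_j)
    gj = (gi @ model.w_ij) * s_j * (1.0 - s_j)  # (N_j,)
    d_w_jk = alpha * np.outer(gj, x)
    model.w_ij += d_w_ij
    model.w_jk += d_w_jk
    return model


@njit(cache=True)
def _train_loop(w_jk, w_ij, X, y, alpha, orders):  # pragma: no cover - jitted
    n_hidden, n_in = w_jk.shape
    n_out = w_ij.shape[0]
    s_j = np.empty(n_hidden)
    s_i = np.empty(n_out)
    for e in range(orders.shape[0]):
        for t in range(orders.shape[1]):
            v = orders[e, t]
            x = X[v]
            for j in range(n_hidden):
                z = 0.0
                for k in range(n_in):
                    z += w_jk[j, k] * x[k]
                s_j[j] = 1.0 / (1.0 + np.exp(-z))
            for i in range(n_out):
                z = 0.0
                for j in range(n_hidden):
                    z += w_ij[i, j] * s_j[j]
                s_i[i] = 1.0 / (1.0 + np.exp(-z))
            # deltas from old weights: accumulate hidden-layer gradient first
            for j in range(n_hidden):
                gj = 0.0
                for i in range(n_out):
                    eps = y[v, i] - s_i[i]
                    gj += eps * s_i[i] * (1.0 - s_i[i]) * w_ij[i, j]
                gj *= s_j[j] * (1.0 - s_j[j])
                for i in range(n_out):
                    eps = y[v, i] - s_i[i]
                    w_ij[i, j] += alpha * eps * s_i[i] * (1.0 - s_i[i]) * s_j[j]
                for k in range(n_in):
                    if x[k] != 0.0:
                        w_jk[j, k] += alpha * gj * x[k]


@njit(cache=True)
def _train_loop_sparse(w_jk, w_ij, nz, nnz, y, alpha, orders):  # pragma: no cover
    """Same arithmetic as _train_loop for binary inputs, visiting only the
    active features of each probe (one-hot blocks make X very sparse)."""
    n_hidden = w_jk.shape[0]
    n_out = w_ij.shape[0]
    s_j = np.empty(n_hidden)
    s_i = np.empty(n_out)
    for e in range(orders.shape[0]):
        for t in range(orders.shape[1]):
            v = orders[e, t]
            kn = nnz[v]
            for j in range(n_hidden):
                z = 0.0
                for q in range(kn):
                    z += w_jk[j, nz[v, q]]
                s_j[j] = 1.0 / (1.0 + np.exp(-z))
            for i in range(n_out):
                z = 0.0
                for j in range(n_hidden):
                    z += w_ij[i, j] * s_j[j]
                s_i[i] = 1.0 / (1.0 + np.exp(-z))
            for j in range(n_hidden):
                gj = 0.0
                for i in range(n_out):
                    eps = y[v, i] - s_i[i]
                    gj += eps * s_i[i] * (1.0 - s_i[i]) * w_ij[i, j]
                gj *= s_j[j] * (1.0 - s_j[j])
                for i in range(n_out):
                    eps = y[v, i] - s_i[i]
                    w_ij[i, j] += alpha * eps * s_i[i] * (1.0 - s_i[i]) * s_j[j]
                for q in range(kn):
                    w_jk[j, nz[v, q]] += alpha * gj
    return


@dataclass
class TrainConfig:
    """Training policy: epoch budget, restarts, folds, stopping rule."""

    iterations: int = 2000  # one iteration = one full epoch of online updates
    restarts: int = 3
    k: int = 10
    seed: int = 0
    n_hidden: int | None = None  # default min(2 * n_features, 32)
    alpha: float = 0.5
    oscillation_window: int = 8  # criterion evaluations
    oscillation_tol: float = 1e-4  # relative SSE variation treated as steady
    eval_every: int = 25  # epochs between stopping-rule evaluations
    constraint_class: int = 0  # label value that must be 100% correct
    init_scale: float = 0.5
    #: sigmoid training targets for the two classes; keeping them off the
    #: asymptotes (0.1/0.9) prevents the squared-error gradient factor
    #: s(1-s) from vanishing, so hard constraint-class probes keep learning
    target_low: float = 0.1
    target_high: float = 0.9

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.iterations < 1:
            raise ValueError("iteration budget must be >= 1")

    def hidden_for(self, n_features: int) -> int:
        return self.n_hidden or max(2, min(2 * n_features, 32))


def _sse(model: NNModel, X: np.ndarray, y: np.ndarray) -> float:
    out = outputs(model, X)
    return float(np.sum((y - out) ** 2))


def train(
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig,
    rng: np.random.Generator | None = None,
) -> tuple[NNModel, list[float]]:
    """Online backprop over shuffled probes until steady state or budget.

    Training stops early when the squared-error criterion over the last
    ``oscillation_window`` evaluations oscillates within ``oscillation_tol``
    (relative) without further true improvement.  Returns the model and the
    SSE history (one entry per evaluation).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    rng = rng or np.random.default_rng(config.seed)
    model = NNModel.initialize(X.shape[1], config.hidden_for(X.shape[1]), rng,
                               alpha=config.alpha, scale=config.init_scale)
    y2 = np.where(y > 0, config.target_high, config.target_low).reshape(-1, 1)
    n = len(X)
    history: list[float] = []
    done = 0
    binary = bool(np.isin(X, (0.0, 1.0)).all())
    if _HAVE_NUMBA and binary:
        nnz_counts = (X != 0).sum(axis=1).astype(np.int64)
        width = max(1, int(nnz_counts.max()))
        nz = np.zeros((n, width), dtype=np.int64)
        for v in range(n):
            idx = np.flatnonzero(X[v])
            nz[v, : len(idx)] = idx

        def runner(w_jk, w_ij, Xa, ya, alpha, orders):
            _train_loop_sparse(w_jk, w_ij, nz, nnz_counts, ya, alpha, orders)
    elif _HAVE_NUMBA:
        runner = _train_loop
    else:  # pure-python fallback, identical arithmetic
        def runner(w_jk, w_ij, Xa, ya, alpha, orders):
            m = NNModel(w_jk, w_ij, alpha=alpha)
            for row in orders:
                for v in row:
                    backprop_update(m, Xa[v], ya[v], alpha)
    while done < config.iterations:
        chunk = min(config.eval_every, config.iterations - done)
        orders = np.stack([rng.permutation(n) for _ in range(chunk)]).astype(np.int64)
        runner(model.w_jk, model.w_ij, X, y2, model.alpha, orders)
        done += chunk
        history.append(_sse(model, X, y2[:, 0]))
        w = config.oscillation_window
        if len(history) >= w:
            recent = history[-w:]
            span = max(recent) - min(recent)
            scale = max(abs(min(recent)), 1e-12)
            improving = min(recent) < min(history[:-w], default=np.inf) - config.oscillation_tol * scale
            if span <= config.oscillation_tol * scale and not improving:
                break
    return model, history


# --------------------------------------------------------------------------
# constrained evaluation


@dataclass
class CriterionResult:
    """Constraint-based evaluation: 100% constraint-class accuracy by
    construction on the calibration set, then fewest false positives and
    highest sensitivity."""

    constraint_accuracy: float
    fp_count: int
    fp_rate: float
    sensitivity: float
    threshold: float
    n_positive: int
    n_constraint: int
    tp_count: int = 0
    #: mean over positive-class subjects of (output - threshold); a continuous
    #: shadow of sensitivity used to break ties when discrete counts equal
    positive_margin: float = 0.0
    #: constraint-class accuracy on the threshold's own calibration set; 1.0
    #: by construction of the max+delta policy whenever the threshold was
    #: calibrated on training data
    calibration_constraint_accuracy: float = 1.0
    per_fold: list[dict] = field(default_factory=list)

    @property
    def key(self):
        """Lexicographic comparison key (maximize).

        Order: constraint-class accuracy on the calibration set first (1.0 by
        construction when the threshold was calibrated on training data), then
        sensitivity, then fewest false positives, then the continuous margin.
        Sensitivity precedes the FP count because under the max+delta
        threshold policy the trivial all-negative classifier always attains
        zero false positives; ranking FP first would make model comparison
        degenerate (it would always prefer the model that recognizes nobody).
        """
        return (self.calibration_constraint_accuracy, self.sensitivity,
                -self.fp_count, self.positive_margin)

    @property
    def correct_fraction(self) -> float:
        n = self.n_positive + self.n_constraint
        return ((self.n_constraint - self.fp_count) + self.tp_count) / n if n else 0.0


def calibrate_threshold(model: NNModel, X: np.ndarray, y: np.ndarray,
                        constraint_class: int = 0) -> float:
    """Max output over constraint-class subjects plus a tiny delta.

    Guarantees every calibration-set constraint-class subject falls below the
    threshold, i.e. 100% constraint-class accuracy there.
    """
    y = np.asarray(y).reshape(-1)
    mask = y == constraint_class
    if not mask.any():
        raise ValueError("constraint class is empty")
    out = outputs(model, np.asarray(X, dtype=float)[mask])
    return float(out.max() + THRESHOLD_DELTA)


def criterion_evaluate(
    model: NNModel,
    X: np.ndarray,
    y: np.ndarray,
    constraint_class: int = 0,
    threshold: float | None = None,
) -> CriterionResult:
    """Evaluate at the constraint threshold (calibrated here if not given)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).reshape(-1)
    self_calibrated = threshold is None
    tau = calibrate_threshold(model, X, y, constraint_class) if self_calibrated else threshold
    out = outputs(model, X)
    pos_call = out >= tau
    is_constraint = y == constraint_class
    n_c = int(is_constraint.sum())
    n_p = int((~is_constraint).sum())
    fp = int((pos_call & is_constraint).sum())
    tp = int((pos_call & ~is_constraint).sum())
    margin = float((out[~is_constraint] - tau).mean()) if n_p else 0.0
    return CriterionResult(
        constraint_accuracy=(n_c - fp) / n_c if n_c else 1.0,
        fp_count=fp,
        fp_rate=fp / n_c if n_c else 0.0,
        sensitivity=tp / n_p if n_p else 0.0,
        threshold=tau,
        n_positive=n_p,
        n_constraint=n_c,
        tp_count=tp,
        positive_margin=margin,
        calibration_constraint_accuracy=(
            (n_c - fp) / n_c if (self_calibrated and n_c) else 1.0
        ),
    )


def stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Disjoint, exhaustive, class-stratified folds (sizes differ by <= 1 per class)."""
    y = np.asarray(y).reshape(-1)
    if len(y) < k:
        raise ValueError("n < k")
    folds: list[list[int]] = [[] for _ in range(k)]
    pos = 0  # continue dealing across classes so overall sizes differ <= 1
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(len(idx))]
        for i in idx:
            folds[pos % k].append(int(i))
            pos += 1
    return [np.array(sorted(f), dtype=int) for f in folds]


def kfold_cv(
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig,
    seed_offset: int = 0,
) -> CriterionResult:
    """Stratified k-fold cross-validation with per-training-fold thresholds.

    Each subject is tested exactly once; the threshold applied to a test fold
    is calibrated only on that fold's training data, so no subject influences
    its own threshold.  Pooled counts are sums over test folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).reshape(-1)
    rng = np.random.default_rng(config.seed + seed_offset)
    folds = stratified_folds(y, config.k, rng)
    all_idx = np.arange(len(y))
    fp = tp = n_p = n_c = 0
    per_fold = []
    thresholds = []
    margin_sum = 0.0
    for f, test in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test)
        y_tr = y[train_idx]
        if np.unique(y_tr).size < 2:
            raise ValueError(f"class absent from training fold {f}")
        model, _ = train(X[train_idx], y_tr, config,
                         rng=np.random.default_rng(config.seed + seed_offset + 1000 + f))
        tau = calibrate_threshold(model, X[train_idx], y_tr, config.constraint_class)
        res = criterion_evaluate(model, X[test], y[test], config.constraint_class, threshold=tau)
        fp += res.fp_count
        tp += res.tp_count
        n_p += res.n_positive
        n_c += res.n_constraint
        margin_sum += res.positive_margin * res.n_positive
        thresholds.append(tau)
        per_fold.append({
            "fold": f, "fp": res.fp_count, "tp": res.tp_count,
            "n_positive": res.n_positive, "n_constraint": res.n_constraint,
            "threshold": tau,
        })
    return CriterionResult(
        constraint_accuracy=(n_c - fp) / n_c if n_c else 1.0,
        fp_count=fp,
        fp_rate=fp / n_c if n_c else 0.0,
        sensitivity=tp / n_p if n_p else 0.0,
        threshold=float(np.mean(thresholds)),
        n_positive=n_p,
        n_constraint=n_c,
        tp_count=tp,
        positive_margin=margin_sum / n_p if n_p else 0.0,
        per_fold=per_fold,
    )


def random_walk_search(
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig,
) -> tuple[NNModel, CriterionResult]:
    """Random-walk restarts: independent trainings from perturbed inits.

    The best restart is chosen by the lexicographic key of its pooled CV
    result (constraint accuracy, -FP, +sensitivity); ties go to the lowest
    restart index.  The returned model is retrained on the full data with the
    winning restart's seed and carries a full-data calibrated threshold.
    """
    best_res, best_r = None, 0
    for r in range(max(1, config.restarts)):
        res = kfold_cv(X, y, config, seed_offset=r * 10_000)
        if best_res is None or res.key > best_res.key:
            best_res, best_r = res, r
    model, _ = train(X, np.asarray(y).reshape(-1), config,
                     rng=np.random.default_rng(config.seed + best_r * 10_000 + 500))
    model.threshold = calibrate_threshold(model, X, y, config.constraint_class)
    return model, best_res


def select_classifier_genes(
    features: FeatureMatrix,
    y: np.ndarray,
    config: TrainConfig,
    pool: list[str] | None = None,
    stability: float = 0.70,
    max_genes: int = 6,
) -> tuple[list[str], dict[str, float]]:
    """Greedy forward selection of classifier genes with a stability filter.

    For each of ``config.restarts`` restarts, genes from the pool are added
    greedily by the pooled-CV lexicographic criterion until no gene improves
    it or ``max_genes`` is reached (classifier subsets in this design are
    small, 5-6 genes).  A gene is retained only if selected in at least
    ``stability`` of the restarts.  Returns (retained genes, per-gene
    selection frequency).
    """
    pool = list(pool if pool is not None else features.blocks)
    if not pool:
        raise ValueError("empty gene pool")
    y = np.asarray(y).reshape(-1)
    restarts = max(1, config.restarts)
    counts = {g: 0 for g in pool}
    for r in range(restarts):
        selected: list[str] = []
        best_key = None
        while len(selected) < max_genes:
            candidate_best, candidate_key = None, None
            for g in pool:
                if g in selected:
                    continue
                sub = features.subset(selected + [g])
                res = kfold_cv(sub.X, y, config, seed_offset=r * 100_000)
                if candidate_key is None or res.key > candidate_key:
                    candidate_best, candidate_key = g, res.key
            if candidate_best is None:
                break
            if best_key is not None and candidate_key <= best_key:
                break
            selected.append(candidate_best)
            best_key = candidate_key
        for g in selected:
            counts[g] += 1
    freq = {g: c / restarts for g, c in counts.items()}
    retained = [g for g in pool if freq[g] >= stability]
    return retained, freq


def cross_cohort_overlap(model: NNModel, other_X: np.ndarray) -> float:
    """Fraction of another cohort classified positive at the model's threshold."""
    if model.threshold is None:
        raise ValueError("model has no calibrated threshold")
    other_X = np.asarray(other_X, dtype=float)
    if other_X.shape[1] != model.n_inputs:
        raise ValueError("feature space mismatch with trained model")
    if len(other_X) == 0:
        return 0.0
    return float((outputs(model, other_X) >= model.threshold).mean())


def split_half_stability(
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig,
    repeats: int = 20,
) -> dict:
    """Repeated random half-splits: train on one half, evaluate on the other.

    Reports the mean drop in the correctly-classified fraction relative to
    full-sample cross-validation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).reshape(-1)
    if len(y) < 40:
        raise ValueError("need n >= 40 for split-half stability")
    baseline = kfold_cv(X, y, config).correct_fraction
    rng = np.random.default_rng(config.seed)
    halves = []
    for rep in range(repeats):
        order = rng.permutation(len(y))
        half = len(y) // 2
        a, b = order[:half], order[half:]
        if np.unique(y[a]).size < 2 or np.unique(y[b]).size < 2:
            continue
        model, _ = train(X[a], y[a], config,
                         rng=np.random.default_rng(config.seed + 7000 + rep))
        tau = calibrate_threshold(model, X[a], y[a], config.constraint_class)
        res = criterion_evaluate(model, X[b], y[b], config.constraint_class, threshold=tau)
        halves.append(res.correct_fraction)
    mean_half = float(np.mean(halves)) if halves else float("nan")
    return {
        "full_cv_correct": baseline,
        "half_correct_mean": mean_half,
        "mean_drop": baseline - mean_half,
        "n_valid_repeats": len(halves),
    }
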