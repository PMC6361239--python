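"""Feed-forward network scoring kinase-peptide pairs, with the training,
tuning and evaluation machinery around it.

Architecture: 1638 one-hot inputs -> two softplus hidden layers -> a
2-unit softmax head; the score of a pair is the positive-class softmax
probability.  Training minimizes mean squared error against one-hot
targets with resilient backpropagation (iRprop-: sign-based per-weight
steps, eta+ = 1.2, eta- = 0.5, steps clamped to [1e-6, 50], gradient
zeroed on a sign flip), mini-batched, with a per-neuron L2 cap on
incoming weights as weight normalization.  Hyperparameters are selected
by a grid over batch size and hidden-layer widths scored by
cross-validated AUC; the per-acceptor decision thresholds are the
crossing points of the positive and negative score densities.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.stats import gaussian_kde
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .encoding import N_BITS

logger = logging.getLogger("akid")

GRID_BATCH_SIZES = (100, 200, 400, 600, 800)
GRID_LAYER1_SIZES = (10, 210, 410, 610, 810, 1010)
GRID_LAYER2_FRACTIONS = (0.25, 0.5, 0.75)

#: Reference per-acceptor thresholds from the original human training run
#: (S, T, Y).  Documented defaults; they are data-dependent and should be
#: re-derived with :func:`select_thresholds` for any new training set.
REFERENCE_THRESHOLDS = {"S": 0.545, "T": 0.517, "Y": 0.34}


@dataclass(frozen=True)
class DNNConfig:
    layer1: int = 210
    layer2: int = 53
    batch_size: int = 400
    epochs: int = 10
    learn_rate: float = 0.5  # recorded for provenance; Rprop steps are adaptive
    activation: str = "softplus"
    loss: str = "mse"
    optimizer: str = "rprop"
    seed: int = 0

    def __post_init__(self):
        if self.layer1 < 1 or self.layer2 < 1 or self.batch_size < 1:
            raise ValueError("layer and batch sizes must be >= 1")


@dataclass(frozen=True)
class ThresholdSet:
    t_S: float = REFERENCE_THRESHOLDS["S"]
    t_T: float = REFERENCE_THRESHOLDS["T"]
    t_Y: float = REFERENCE_THRESHOLDS["Y"]

    def __post_init__(self):
        for v in (self.t_S, self.t_T, self.t_Y):
            if not 0.0 <= v <= 1.0:
                raise ValueError("thresholds must lie in [0, 1]")

    def for_acceptor(self, acceptor: str) -> float:
        return {"S": self.t_S, "T": self.t_T, "Y": self.t_Y}[acceptor]


@dataclass
class ROCResult:
    points: np.ndarray  # (n, 2) of (FPR, TPR)
    auc: float


@dataclass
class TrainedModel:
    weights: list  # [(W1, b1), (W2, b2), (W3, b3)]
    config: DNNConfig
    thresholds: ThresholdSet
    training_manifest: dict
    block_order: str = "dos-then-peptide"


def _softplus(x):
    return np.logaddexp(0.0, x)


def _softmax2(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _init_weights(config: DNNConfig, n_inputs: int, rng) -> list:
    sizes = [n_inputs, config.layer1, config.layer2, 2]
    weights = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        W = rng.normal(0.0, 1.0 / math.sqrt(fan_in), size=(fan_in, fan_out))
        b = np.zeros(fan_out)
        weights.append((W, b))
    return weights


def _forward(weights, X):
    """Returns (softmax probabilities, per-layer activations)."""
    (W1, b1), (W2, b2), (W3, b3) = weights
    z1 = X @ W1 + b1
    a1 = _softplus(z1)
    z2 = a1 @ W2 + b2
    a2 = _softplus(z2)
    z3 = a2 @ W3 + b3
    return _softmax2(z3), (X, z1, a1, z2, a2)


def _gradients(weights, X, Y):
    """Gradients of mean squared error on softmax outputs vs one-hot Y."""
    (W1, b1), (W2, b2), (W3, b3) = weights
    P, (X0, z1, a1, z2, a2) = _forward(weights, X)
    n = X.shape[0]
    dP = 2.0 * (P - Y) / n  # d(mean over samples of sum_k (p-y)^2) / dP
    # softmax Jacobian: dz = P * (dP - sum(dP * P))
    dz3 = P * (dP - (dP * P).sum(axis=1, keepdims=True))
    gW3 = a2.T @ dz3
    gb3 = dz3.sum(axis=0)
    da2 = dz3 @ W3.T
    dz2 = da2 * _sigmoid(z2)
    gW2 = a1.T @ dz2
    gb2 = dz2.sum(axis=0)
    da1 = dz2 @ W2.T
    dz1 = da1 * _sigmoid(z1)
    gW1 = X0.T @ dz1
    gb1 = dz1.sum(axis=0)
    return [(gW1, gb1), (gW2, gb2), (gW3, gb3)]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


class _Rprop:
    """iRprop-: per-parameter adaptive steps driven by gradient signs."""

    ETA_PLUS, ETA_MINUS = 1.2, 0.5
    STEP_MIN, STEP_MAX = 1e-6, 50.0

    def __init__(self, weights, step0: float = 0.01):
        self.steps = [
            (np.full_like(W, step0), np.full_like(b, step0)) for W, b in weights
        ]
        self.prev = [(np.zeros_like(W), np.zeros_like(b)) for W, b in weights]

    def update(self, weights, grads):
        new_weights = []
        for (W, b), (gW, gb), (sW, sb), (pW, pb) in zip(
            weights, grads, self.steps, self.prev
        ):
            W = W - self._apply(gW, sW, pW)
            b = b - self._apply(gb, sb, pb)
            new_weights.append((W, b))
        return new_weights

    def _apply(self, g, step, prev):
        sign_change = g * prev
        np.multiply(step, self.ETA_PLUS, out=step, where=sign_change > 0)
        np.multiply(step, self.ETA_MINUS, out=step, where=sign_change < 0)
        np.clip(step, self.STEP_MIN, self.STEP_MAX, out=step)
        g = np.where(sign_change < 0, 0.0, g)  # iRprop-: drop flipped gradients
        prev[...] = g
        return np.sign(g) * step


def _normalize_weights(weights, max_norm: float = 15.0):
    """Cap the L2 norm of each neuron's incoming weight vector."""
    out = []
    for W, b in weights:
        norms = np.sqrt((W**2).sum(axis=0))
        scale = np.minimum(1.0, max_norm / np.maximum(norms, 1e-12))
        out.append((W * scale, b))
    return out


def _as_matrix(pairs) -> np.ndarray:
    if isinstance(pairs, np.ndarray):
        X = np.asarray(pairs, dtype=np.float64)
    else:
        X = np.asarray([p.bits for p in pairs], dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != N_BITS:
        raise ValueError(f"input vectors must have length {N_BITS}, got shape {X.shape}")
    return X


def _data_checksum(X, y) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(np.asarray(y)).tobytes())
    return h.hexdigest()[:16]


def train(pairs, labels, config: DNNConfig, thresholds: ThresholdSet | None = None) -> TrainedModel:
    """Fit the network on encoded pairs with binary labels (1 = true KsP).

    Deterministic given ``config.seed``: weight initialization and batch
    shuffling derive from it, and the training-data checksum is recorded
    in the model manifest.
    """
    X = _as_matrix(pairs)
    y = np.asarray(labels, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValueError("pairs and labels disagree in length")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training data must contain both classes")
    Y = np.zeros((len(y), 2))
    Y[np.arange(len(y)), y] = 1.0

    rng = np.random.default_rng(config.seed)
    weights = _init_weights(config, X.shape[1], rng)
    opt = _Rprop(weights)
    n = X.shape[0]
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            grads = _gradients(weights, X[idx], Y[idx])
            weights = opt.update(weights, grads)
            weights = _normalize_weights(weights)

    manifest = {
        "data_checksum": _data_checksum(X, y),
        "seed": config.seed,
        "n_samples": int(n),
    }
    return TrainedModel(
        weights=weights,
        config=config,
        thresholds=thresholds or ThresholdSet(),
        training_manifest=manifest,
    )


def predict(model: TrainedModel, pairs) -> np.ndarray:
    """Positive-class softmax probability for each encoded pair."""
    X = _as_matrix(pairs)
    P, _ = _forward(model.weights, X)
    return P[:, 1]


def roc_auc(scores, labels) -> ROCResult:
    """ROC points and AUC; AUC is P(random positive outscores random
    negative), ties counting one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute a ROC curve")
    fpr, tpr, _ = roc_curve(labels, scores)
    return ROCResult(points=np.column_stack([fpr, tpr]), auc=float(roc_auc_score(labels, scores)))


def cross_validate(
    pairs,
    labels,
    config: DNNConfig,
    k: int = 10,
    seed: int = 0,
    acceptors=None,
):
    """k-fold cross-validation stratified by label (and acceptor, if given).

    Every interaction is scored exactly once, by the model trained on the
    other folds.  Returns ``(per-fold ROCResults, mean fold AUC, pooled
    scores array)``.
    """
    X = _as_matrix(pairs)
    y = np.asarray(labels, dtype=int)
    n = len(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds dataset size {n}")
    strata = y.astype(str)
    if acceptors is not None:
        strata = np.array([f"{lbl}_{acc}" for lbl, acc in zip(y, acceptors)])
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_results = []
    pooled = np.empty(n)
    for fold_i, (train_idx, test_idx) in enumerate(skf.split(X, strata)):
        fold_config = replace(config, seed=config.seed + fold_i)
        model = train(X[train_idx], y[train_idx], fold_config)
        scores = predict(model, X[test_idx])
        pooled[test_idx] = scores
        fold_results.append(roc_auc(scores, y[test_idx]))
    mean_auc = float(np.mean([r.auc for r in fold_results]))
    return fold_results, mean_auc, pooled


def enumerate_grid(
    batch_sizes=GRID_BATCH_SIZES,
    layer1_sizes=GRID_LAYER1_SIZES,
    layer2_fractions=GRID_LAYER2_FRACTIONS,
) -> list:
    """All (layer1, layer2, batch_size) combinations of the search grid;
    layer2 is the ceiling of the configured fraction of layer1."""
    combos = []
    for batch in batch_sizes:
        for l1 in layer1_sizes:
            for frac in layer2_fractions:
                combos.append((l1, math.ceil(l1 * frac), batch))
    return combos


def grid_search(
    pairs,
    labels,
    seed: int = 0,
    *,
    k: int = 3,
    epochs: int = 10,
    batch_sizes=GRID_BATCH_SIZES,
    layer1_sizes=GRID_LAYER1_SIZES,
    layer2_fractions=GRID_LAYER2_FRACTIONS,
):
    """Score every grid combination by k-fold CV AUC and return the best.

    Ties break toward the smaller first hidden layer, then the smaller
    batch size.  Returns ``(best DNNConfig, table of (config, auc))``.
    """
    table = []
    for l1, l2, batch in enumerate_grid(batch_sizes, layer1_sizes, layer2_fractions):
        config = DNNConfig(layer1=l1, layer2=l2, batch_size=batch, epochs=epochs, seed=seed)
        _, auc, _ = cross_validate(pairs, labels, config, k=k, seed=seed)
        table.append((config, auc))
    best_config, _ = max(
        table, key=lambda t: (t[1], -t[0].layer1, -t[0].batch_size)
    )
    return best_config, table


def _density_crossing(pos_scores, neg_scores) -> float:
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    kde_pos = gaussian_kde(pos, bw_method="silverman")
    kde_neg = gaussian_kde(neg, bw_method="silverman")
    grid = np.linspace(0.0, 1.0, 2001)
    diff = kde_pos(grid) - kde_neg(grid)
    mode_neg = grid[int(np.argmax(kde_neg(grid)))]
    mode_pos = grid[int(np.argmax(kde_pos(grid)))]
    lo, hi = sorted((mode_neg, mode_pos))
    crossings = []
    for idx in np.nonzero(np.diff(np.sign(diff)))[0]:
        x0, x1 = grid[idx], grid[idx + 1]
        try:
            x = brentq(lambda t: kde_pos(t)[0] - kde_neg(t)[0], x0, x1)
        except ValueError:
            x = 0.5 * (x0 + x1)
        crossings.append(x)
    if not crossings:
        # densities never cross on [0,1]; fall back to the mode midpoint
        return 0.5 * (mode_neg + mode_pos)
    between = [x for x in crossings if lo <= x <= hi]
    if between:
        # the crossing between the two modes is the decision boundary
        return float(between[int(np.argmin(np.abs(np.array(between) - 0.5 * (lo + hi))))])
    return float(crossings[int(np.argmin(np.abs(np.array(crossings) - 0.5 * (lo + hi))))])


def select_thresholds(
    pos_scores_by_acceptor: dict,
    neg_scores_by_acceptor: dict,
    min_scores: int = 20,
) -> ThresholdSet:
    """Per-acceptor decision thresholds at the crossing of the score
    densities of true and false KsP (Gaussian KDE, Silverman bandwidth).

    Among multiple crossings the one between the two density modes is
    used.  Each acceptor class needs at least ``min_scores`` scores per
    label; pool acceptors upstream if a class is too small.
    """
    values = {}
    for acc in "STY":
        pos = np.asarray(pos_scores_by_acceptor[acc], dtype=float)
        neg = np.asarray(neg_scores_by_acceptor[acc], dtype=float)
        if len(pos) < min_scores or len(neg) < min_scores:
            raise ValueError(
                f"acceptor {acc}: need >= {min_scores} scores per class "
                f"(got {len(pos)} positive, {len(neg)} negative); "
                "consider pooling acceptor classes"
            )
        values[acc] = float(np.clip(_density_crossing(pos, neg), 0.0, 1.0))
    return ThresholdSet(t_S=values["S"], t_T=values["T"], t_Y=values["Y"])


def auc_by_group(scores, labels, groups) -> dict:
    """AUC within each kinase group (needs both classes in the group)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    groups = np.asarray(groups)
    out = {}
    for g in sorted(set(groups)):
        mask = groups == g
        if len(np.unique(labels[mask])) < 2:
            logger.warning("group %s lacks one class; AUC undefined", g)
            continue
        out[g] = roc_auc(scores[mask], labels[mask]).auc
    return out


def save_model(model: TrainedModel, path) -> None:
    """Persist weights, config, thresholds and manifest to an .npz archive."""
    arrays = {}
    for i, (W, b) in enumerate(model.weights):
        arrays[f"W{i}"] = W
        arrays[f"b{i}"] = b
    meta = {
        "config": vars(model.config) if not hasattr(model.config, "__dataclass_fields__") else {
            k: getattr(model.config, k) for k in model.config.__dataclass_fields__
        },
        "thresholds": {
            "t_S": model.thresholds.t_S,
            "t_T": model.thresholds.t_T,
            "t_Y": model.thresholds.t_Y,
        },
        "manifest": model.training_manifest,
        "block_order": model.block_order,
    }
    import json

    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path, *, expect_block_order: str = "dos-then-peptide") -> TrainedModel:
    import json

    data = np.load(path)
    meta = json.loads(bytes(data["meta_json"]).decode())
    if meta["block_order"] != expect_block_order:
        raise ValueError(
            f"model block order {meta['block_order']!r} does not match "
            f"expected {expect_block_order!r}"
        )
    weights = [(data[f"W{i}"], data[f"b{i}"]) for i in range(3)]
    cfg_fields = {k: meta["config"][k] for k in DNNConfig.__dataclass_fields__ if k in meta["config"]}
    return TrainedModel(
        weights=weights,
        config=DNNConfig(**cfg_fields),
        thresholds=ThresholdSet(**meta["thresholds"]),
        training_manifest=meta["manifest"],
        block_order=meta["block_order"],
    )
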