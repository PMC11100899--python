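"""Binary-classification head and joint end-to-end training.

The fingerprint of each molecule feeds a small fully-connected network
(default [fp_length → 100 → 100 → 1], ReLU hidden activations, dropout on
the hidden layers) whose sigmoid output is the hit probability. Training
minimizes binary cross-entropy with Adam; crucially, the loss gradient is
propagated *through* the fingerprint, so the convolutional fingerprint
weights and the classifier weights are optimized jointly — the fingerprint
adapts to the screening task instead of being a fixed encoding.

A grid search over {weight_decay, learning_rate, dropout, batch_size,
fp_length} trains one model per Cartesian-product combination and ranks
them; the default selection policy maximizes validation recall (the
screening priority: lose as few true binders as possible), breaking ties on
precision and then on the mean docking energy of the predicted hits being
more negative.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from . import metrics as _metrics
from .datapipe import ScreenRecord
from .molgraph import MoleculeGraph, smiles_to_graph
from .neuralfp import (
    BIAS_INIT,
    FPGradients,
    NeuralFPParams,
    fingerprint_and_cache,
    gradients_from_cache,
    init_params,
    sigmoid,
    xavier_normal,
)

GRID_KEYS = ("weight_decay", "learning_rate", "dropout", "batch_size", "fp_length")


# ---------------------------------------------------------------------------
# ANN head
# ---------------------------------------------------------------------------

@dataclass
class ANNParams:
    """Fully-connected head: layer_sizes[0] = fp_length, last = 1."""

    layer_sizes: list[int]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    dropout_rate: float = 0.0

    def flat_parameters(self) -> list[tuple[str, np.ndarray]]:
        out = []
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            out.append((f"ann_weights[{i}]", w))
            out.append((f"ann_biases[{i}]", b))
        return out


def init_ann(layer_sizes: list[int], seed: int, dropout_rate: float = 0.0) -> ANNParams:
    """Xavier-normal weights, constant-0.01 biases (same scheme as the
    fingerprint side)."""
    if layer_sizes[-1] != 1:
        raise ValueError("final ANN layer must have size 1 (binary output)")
    if not 0.0 <= dropout_rate < 1.0:
        raise ValueError(f"dropout_rate must be in [0,1), got {dropout_rate}")
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for d_in, d_out in itertools.pairwise(layer_sizes):
        weights.append(xavier_normal(rng, d_in, d_out))
        biases.append(np.full(d_out, BIAS_INIT))
    return ANNParams(list(layer_sizes), weights, biases, dropout_rate)


def ann_forward(x: np.ndarray, ann: ANNParams, training: bool = False,
                rng: np.random.Generator | None = None):
    """Single-example forward; returns (logit, cache). Dropout (inverted)
    is applied to hidden activations only when training=True."""
    if x.shape != (ann.layer_sizes[0],):
        raise ValueError(
            f"ANN input size {x.shape} != expected ({ann.layer_sizes[0]},)"
        )
    a = x
    pre_acts, acts, masks = [], [a], []
    n_layers = len(ann.weights)
    for i, (w, b) in enumerate(zip(ann.weights, ann.biases)):
        h = a @ w + b
        pre_acts.append(h)
        if i < n_layers - 1:
            a = np.maximum(h, 0.0)
            if training and ann.dropout_rate > 0.0:
                keep = 1.0 - ann.dropout_rate
                mask = (rng.random(a.shape) < keep) / keep
                a = a * mask
                masks.append(mask)
            else:
                masks.append(None)
            acts.append(a)
        else:
            a = h
    cache = {"pre": pre_acts, "acts": acts, "masks": masks}
    return float(a[0]), cache


def ann_backward(cache: dict, d_logit: float, ann: ANNParams):
    """Gradients of d_logit·logit w.r.t. ANN blocks and the input vector."""
    n_layers = len(ann.weights)
    gw = [None] * n_layers
    gb = [None] * n_layers
    da = np.array([d_logit])
    for i in range(n_layers - 1, -1, -1):
        if i < n_layers - 1:
            mask = cache["masks"][i]
            if mask is not None:
                da = da * mask
            da = da * (cache["pre"][i] > 0)
        gw[i] = np.outer(cache["acts"][i], da)
        gb[i] = da.copy()
        da = ann.weights[i] @ da
    return gw, gb, da  # da is now dLoss/dInput (the fingerprint gradient)


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, learning_rate: float, weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = learning_rate
        self.wd = weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self, named_params: list[tuple[str, np.ndarray]],
             named_grads: list[tuple[str, np.ndarray]]) -> None:
        self.t += 1
        for (name, p), (gname, g) in zip(named_params, named_grads):
            assert name == gname, f"parameter/gradient order mismatch: {name} vs {gname}"
            if self.wd:
                g = g + self.wd * p
            m = self._m.setdefault(name, np.zeros_like(p))
            v = self._v.setdefault(name, np.zeros_like(p))
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            m_hat = m / (1 - self.b1 ** self.t)
            v_hat = v / (1 - self.b2 ** self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


# ---------------------------------------------------------------------------
# Configuration / trained model containers
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    dropout: float = 0.0
    batch_size: int = 32
    fp_length: int = 512
    n_epochs: int = 30
    seed: int = 0
    classification_threshold: float = 0.5
    conv_depth: int = 3           # convolutional layers L (ECFP-radius analog)
    conv_hidden_dim: int = 64
    ann_hidden: tuple[int, ...] = (100, 100)
    patience: int = 10            # early stopping on validation loss

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be non-negative")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0,1)")
        if self.batch_size < 1 or self.fp_length < 1:
            raise ValueError("batch_size and fp_length must be positive")
        if not 0.0 < self.classification_threshold < 1.0:
            raise ValueError("classification_threshold must be in (0,1)")


@dataclass
class TrainedModel:
    fp_params: NeuralFPParams | None
    ann_params: ANNParams
    config: TrainConfig
    energy_threshold: float
    training_history: list[dict] = field(default_factory=list)
    kind: str = "neural"          # "neural" or "morgan"
    morgan_config: dict | None = None

    # -- inference ----------------------------------------------------------
    def predict_proba_graph(self, graph: MoleculeGraph) -> float:
        if self.kind != "neural":
            raise ValueError("graph inference only applies to the neural path")
        fp, _ = fingerprint_and_cache(graph, self.fp_params)
        z, _ = ann_forward(fp, self.ann_params, training=False)
        return float(sigmoid(np.array([z]))[0])

    def predict_proba(self, smiles_list: list[str]) -> np.ndarray:
        if self.kind == "neural":
            return np.array(
                [self.predict_proba_graph(smiles_to_graph(s)) for s in smiles_list]
            )
        from .baseline_morgan import MorganFPConfig, morgan_fingerprint

        cfg = MorganFPConfig(**self.morgan_config)
        out = []
        for s in smiles_list:
            x = morgan_fingerprint(s, cfg).astype(float)
            z, _ = ann_forward(x, self.ann_params, training=False)
            out.append(float(sigmoid(np.array([z]))[0]))
        return np.array(out)

    def predict_labels(self, smiles_list: list[str]) -> np.ndarray:
        p = self.predict_proba(smiles_list)
        return (p >= self.config.classification_threshold).astype(int)


def forward(graph: MoleculeGraph, model: TrainedModel) -> float:
    """Hit probability of one molecule (evaluation mode, dropout off)."""
    return model.predict_proba_graph(graph)


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def _bce_from_logit(z: float, y: float) -> tuple[float, float]:
    """Stable binary cross-entropy from the pre-sigmoid logit.

    Returns (loss, dloss/dlogit); the gradient is sigmoid(z) − y."""
    loss = max(z, 0.0) - z * y + math.log1p(math.exp(-abs(z)))
    grad = float(sigmoid(np.array([z]))[0]) - y
    return loss, grad


# ---------------------------------------------------------------------------
# Joint training
# ---------------------------------------------------------------------------

def _graphs_for(records: list[ScreenRecord], cache: dict[str, MoleculeGraph]) -> list[MoleculeGraph]:
    out = []
    for r in records:
        g = cache.get(r.smiles)
        if g is None:
            g = cache[r.smiles] = smiles_to_graph(r.smiles)
        out.append(g)
    return out


def _zero_fp_grads(p: NeuralFPParams) -> FPGradients:
    return FPGradients(
        hidden_weights=[np.zeros_like(w) for w in p.hidden_weights],
        hidden_biases=[np.zeros_like(b) for b in p.hidden_biases],
        output_weights=[np.zeros_like(w) for w in p.output_weights],
        output_biases=[np.zeros_like(b) for b in p.output_biases],
    )


def _accumulate(dst: FPGradients, src: FPGradients) -> None:
    for (_, a), (_, b) in zip(dst.flat_gradients(), src.flat_gradients()):
        a += b


def _mean_val_loss(graphs, labels, fp_params, ann) -> float:
    total = 0.0
    for g, y in zip(graphs, labels):
        fp, _ = fingerprint_and_cache(g, fp_params)
        z, _ = ann_forward(fp, ann, training=False)
        loss, _ = _bce_from_logit(z, y)
        total += loss
    return total / len(graphs)


def train(
    records: list[ScreenRecord],
    val: list[ScreenRecord],
    config: TrainConfig,
    energy_threshold: float = math.nan,
    graph_cache: dict | None = None,
) -> TrainedModel:
    """Joint end-to-end training of fingerprint + ANN on an (oversampled)
    training list, with early stopping on validation loss.

    Same seed and data reproduce the same history bit for bit.
    """
    if not records:
        raise ValueError("training set is empty")
    labels = np.array([r.label for r in records], dtype=float)
    if not np.isin(labels, (0.0, 1.0)).all():
        raise ValueError("training labels must be binary; run labeling first")
    graph_cache = graph_cache if graph_cache is not None else {}
    graphs = _graphs_for(records, graph_cache)
    val_graphs = _graphs_for(val, graph_cache) if val else []
    val_labels = np.array([r.label for r in val], dtype=float) if val else None

    fp_params = init_params(
        config.conv_depth, config.fp_length, seed=config.seed,
        hidden_dim=config.conv_hidden_dim,
    )
    ann = init_ann(
        [config.fp_length, *config.ann_hidden, 1],
        seed=config.seed + 1,
        dropout_rate=config.dropout,
    )
    opt = Adam(config.learning_rate, config.weight_decay)
    rng = np.random.default_rng(config.seed + 2)

    # Early stopping halts training when validation loss stalls but keeps the
    # final weights: the model stays calibrated to the 50/50 oversampled
    # objective instead of reverting to weights that happened to minimize
    # loss on the unbalanced validation split (which would systematically
    # shrink the hit-prediction rate and with it the recall the screening
    # objective maximizes).
    history: list[dict] = []
    best_val = math.inf
    stale = 0
    n = len(graphs)
    for epoch in range(config.n_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            fp_acc = _zero_fp_grads(fp_params)
            ann_gw = [np.zeros_like(w) for w in ann.weights]
            ann_gb = [np.zeros_like(b) for b in ann.biases]
            for idx in batch:
                g, y = graphs[idx], labels[idx]
                fp, cache = fingerprint_and_cache(g, fp_params)
                z, ann_cache = ann_forward(fp, ann, training=True, rng=rng)
                loss, dz = _bce_from_logit(z, y)
                if not math.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}: logit={z}, label={y}"
                    )
                epoch_loss += loss
                gw, gb, d_fp = ann_backward(ann_cache, dz, ann)
                for acc, grad in zip(ann_gw, gw):
                    acc += grad
                for acc, grad in zip(ann_gb, gb):
                    acc += grad
                _accumulate(fp_acc, gradients_from_cache(g, fp_params, cache, d_fp))
            scale = 1.0 / len(batch)
            named_params = fp_params.flat_parameters() + ann.flat_parameters()
            ann_named = []
            for i, (w, b) in enumerate(zip(ann_gw, ann_gb)):
                ann_named.append((f"ann_weights[{i}]", w))
                ann_named.append((f"ann_biases[{i}]", b))
            named_grads = [
                (name, grad * scale)
                for name, grad in fp_acc.flat_gradients() + ann_named
            ]
            opt.step(named_params, named_grads)
        entry = {"epoch": epoch, "train_loss": epoch_loss / n}
        if val_graphs:
            v_loss = _mean_val_loss(val_graphs, val_labels, fp_params, ann)
            entry["val_loss"] = v_loss
            if v_loss < best_val - 1e-9:
                best_val = v_loss
                stale = 0
            else:
                stale += 1
        history.append(entry)
        if val_graphs and stale > config.patience:
            break
    return TrainedModel(
        fp_params=fp_params,
        ann_params=ann,
        config=config,
        energy_threshold=energy_threshold,
        training_history=history,
        kind="neural",
    )


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def evaluate(model: TrainedModel, records: list[ScreenRecord]) -> dict:
    """Metric bundle (precision/recall/F1/ROC-AUC/PR-AUC/PEP + mean predicted-
    hit energy) for a labeled record list."""
    smiles = [r.smiles for r in records]
    true = np.array([r.label for r in records], dtype=int)
    energies = np.array([r.binding_free_energy for r in records])
    scores = model.predict_proba(smiles)
    pred = (scores >= model.config.classification_threshold).astype(int)
    report = _metrics.metrics_report(
        scores, pred, true, energies=energies,
        energy_threshold=model.energy_threshold,
    )
    hit_mask = pred == 1
    report["mean_predicted_hit_energy"] = (
        float(energies[hit_mask].mean()) if hit_mask.any() else math.nan
    )
    report["n_evaluated"] = len(records)
    return report


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------

def default_selection_key(m: dict) -> tuple:
    """Maximize recall; tie-break on precision, then on the predicted hits'
    mean docking energy being more negative. NaNs rank last."""
    rec = m.get("recall", math.nan)
    prec = m.get("precision", math.nan)
    energy = m.get("mean_predicted_hit_energy", math.nan)
    return (
        -(rec if not math.isnan(rec) else -math.inf),
        -(prec if not math.isnan(prec) else -math.inf),
        energy if not math.isnan(energy) else math.inf,
    )


def grid_search(
    grid: dict[str, list],
    train_records: list[ScreenRecord],
    val_records: list[ScreenRecord],
    base_config: TrainConfig,
    energy_threshold: float = math.nan,
    selection_key=default_selection_key,
) -> list[tuple[TrainedModel, dict]]:
    """Train one model per Cartesian-product combination; return all models
    with their validation metrics, best first."""
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    unknown = set(grid) - set(GRID_KEYS)
    if unknown:
        raise ValueError(f"unknown hyperparameter keys: {sorted(unknown)}; "
                         f"allowed: {GRID_KEYS}")
    keys = sorted(grid)
    results = []
    graph_cache: dict[str, MoleculeGraph] = {}
    for combo in itertools.product(*(grid[k] for k in keys)):
        cfg = replace(base_config, **dict(zip(keys, combo)))
        model = train(train_records, val_records, cfg,
                      energy_threshold=energy_threshold, graph_cache=graph_cache)
        val_metrics = evaluate(model, val_records)
        val_metrics["hyperparameters"] = dict(zip(keys, combo))
        results.append((model, val_metrics))
    results.sort(key=lambda pair: selection_key(pair[1]))
    return results


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: TrainedModel, path) -> None:
    """Serialize parameters + config + energy threshold; bit-exact reload."""
    arrays = {}
    if model.fp_params is not None:
        for name, arr in model.fp_params.flat_parameters():
            arrays["fp::" + name] = arr
    for name, arr in model.ann_params.flat_parameters():
        arrays["ann::" + name] = arr
    meta = {
        "kind": model.kind,
        "config": asdict(model.config),
        "energy_threshold": model.energy_threshold,
        "ann_layer_sizes": model.ann_params.layer_sizes,
        "ann_dropout": model.ann_params.dropout_rate,
        "morgan_config": model.morgan_config,
        "history": model.training_history,
        "fp_meta": None
        if model.fp_params is None
        else {
            "n_layers": model.fp_params.n_layers,
            "fp_length": model.fp_params.fp_length,
            "hidden_dim": model.fp_params.hidden_dim,
            "d_atom": model.fp_params.d_atom,
            "d_bond": model.fp_params.d_bond,
        },
    }
    with open(path, "wb") as fh:  # file handle: keep the exact path given
        np.savez(fh, __meta__=json.dumps(meta), **arrays)


def load_checkpoint(path) -> TrainedModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        arrays = {k: data[k] for k in data.files if k != "__meta__"}
    cfg_dict = meta["config"]
    cfg_dict["ann_hidden"] = tuple(cfg_dict["ann_hidden"])
    config = TrainConfig(**cfg_dict)
    fp_params = None
    if meta["fp_meta"] is not None:
        fm = meta["fp_meta"]
        fp_params = NeuralFPParams(
            n_layers=fm["n_layers"], fp_length=fm["fp_length"],
            hidden_dim=fm["hidden_dim"], d_atom=fm["d_atom"], d_bond=fm["d_bond"],
        )
        for i in range(fm["n_layers"]):
            fp_params.hidden_weights.append(arrays[f"fp::hidden_weights[{i}]"])
            fp_params.hidden_biases.append(arrays[f"fp::hidden_biases[{i}]"])
        for i in range(fm["n_layers"] + 1):
            fp_params.output_weights.append(arrays[f"fp::output_weights[{i}]"])
            fp_params.output_biases.append(arrays[f"fp::output_biases[{i}]"])
    sizes = meta["ann_layer_sizes"]
    ann = ANNParams(
        layer_sizes=sizes,
        weights=[arrays[f"ann::ann_weights[{i}]"] for i in range(len(sizes) - 1)],
        biases=[arrays[f"ann::ann_biases[{i}]"] for i in range(len(sizes) - 1)],
        dropout_rate=meta["ann_dropout"],
    )
    return TrainedModel(
        fp_params=fp_params,
        ann_params=ann,
        config=config,
        energy_threshold=meta["energy_threshold"],
        training_history=meta["history"],
        kind=meta["kind"],
        morgan_config=meta["morgan_config"],
    )
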