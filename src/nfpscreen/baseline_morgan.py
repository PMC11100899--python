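"""Fixed Morgan/ECFP baseline: hashed circular fingerprints feeding the same
ANN head, so the trainable neural fingerprint can be compared against the
standard non-trainable encoding on an identical split and threshold.

Only the classifier head trains here — the fingerprint has zero trainable
parameters, which is exactly the contrast the comparison is meant to expose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .datapipe import LabeledDataset, ScreenRecord, oversample_training
from .model import (
    Adam,
    TrainConfig,
    TrainedModel,
    _bce_from_logit,
    ann_forward,
    ann_backward,
    evaluate,
    init_ann,
    train as train_neural,
)
from .molgraph import SmilesParseError


@dataclass
class MorganFPConfig:
    radius: int = 2
    n_bits: int = 1024

    def __post_init__(self):
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if self.n_bits < 1 or (self.n_bits & (self.n_bits - 1)) != 0:
            raise ValueError(f"n_bits must be a positive power of two, got {self.n_bits}")


def morgan_fingerprint(smiles: str, config: MorganFPConfig) -> np.ndarray:
    """Deterministic hashed circular fingerprint as a 0/1 vector [n_bits]."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=config.radius, fpSize=config.n_bits
    )
    bv = gen.GetFingerprint(mol)
    arr = np.zeros(config.n_bits, dtype=np.int8)
    for bit in bv.GetOnBits():
        arr[bit] = 1
    return arr


def train_morgan(
    records: list[ScreenRecord],
    val: list[ScreenRecord],
    config: TrainConfig,
    morgan_config: MorganFPConfig | None = None,
    energy_threshold: float = math.nan,
) -> TrainedModel:
    """Train the ANN head on fixed Morgan fingerprints (Adam, BCE, early
    stopping on validation loss — the same regimen as the neural path)."""
    if not records:
        raise ValueError("training set is empty")
    morgan_config = morgan_config or MorganFPConfig()
    feat_cache: dict[str, np.ndarray] = {}

    def _feats(recs):
        out = []
        for r in recs:
            x = feat_cache.get(r.smiles)
            if x is None:
                x = feat_cache[r.smiles] = morgan_fingerprint(r.smiles, morgan_config).astype(float)
            out.append(x)
        return out

    X = _feats(records)
    y = np.array([r.label for r in records], dtype=float)
    Xv = _feats(val) if val else []
    yv = np.array([r.label for r in val], dtype=float) if val else None

    ann = init_ann(
        [morgan_config.n_bits, *config.ann_hidden, 1],
        seed=config.seed + 1,
        dropout_rate=config.dropout,
    )
    opt = Adam(config.learning_rate, config.weight_decay)
    rng = np.random.default_rng(config.seed + 2)
    # early stopping halts on stalled validation loss but keeps final weights
    # (same rationale as the neural trainer: preserve the 50/50 calibration)
    history, best_val, stale = [], math.inf, 0
    n = len(X)
    for epoch in range(config.n_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            gw = [np.zeros_like(w) for w in ann.weights]
            gb = [np.zeros_like(b) for b in ann.biases]
            for idx in batch:
                z, cache = ann_forward(X[idx], ann, training=True, rng=rng)
                loss, dz = _bce_from_logit(z, y[idx])
                if not math.isfinite(loss):
                    raise FloatingPointError(f"non-finite loss at epoch {epoch}")
                epoch_loss += loss
                w_g, b_g, _ = ann_backward(cache, dz, ann)
                for acc, grad in zip(gw, w_g):
                    acc += grad
                for acc, grad in zip(gb, b_g):
                    acc += grad
            scale = 1.0 / len(batch)
            named_grads = (
                [(f"ann_weights[{i}]", w * scale) for i, w in enumerate(gw)]
                + [(f"ann_biases[{i}]", b * scale) for i, b in enumerate(gb)]
            )
            named_params = (
                [(f"ann_weights[{i}]", w) for i, w in enumerate(ann.weights)]
                + [(f"ann_biases[{i}]", b) for i, b in enumerate(ann.biases)]
            )
            opt.step(named_params, named_grads)
        entry = {"epoch": epoch, "train_loss": epoch_loss / n}
        if Xv:
            v_loss = 0.0
            for x, yy in zip(Xv, yv):
                z, _ = ann_forward(x, ann, training=False)
                v_loss += _bce_from_logit(z, yy)[0]
            v_loss /= len(Xv)
            entry["val_loss"] = v_loss
            if v_loss < best_val - 1e-9:
                best_val, stale = v_loss, 0
            else:
                stale += 1
        history.append(entry)
        if Xv and stale > config.patience:
            break
    return TrainedModel(
        fp_params=None,
        ann_params=ann,
        config=config,
        energy_threshold=energy_threshold,
        training_history=history,
        kind="morgan",
        morgan_config={"radius": morgan_config.radius, "n_bits": morgan_config.n_bits},
    )


REPORT_METRICS = ("precision", "recall", "roc_auc")


def compare_architectures(
    dataset: LabeledDataset,
    neural_config: TrainConfig,
    morgan_config: MorganFPConfig,
    seed: int = 0,
) -> dict:
    """Head-to-head comparison on one shared split and threshold.

    Both models train on the same oversampled training list and are scored
    on the identical test set; the report carries precision, recall and
    ROC-AUC per architecture.
    """
    train_recs = dataset.subset("train")
    val_recs = dataset.subset("validation")
    test_recs = dataset.subset("test")
    if not train_recs or not test_recs:
        raise ValueError("dataset must contain non-empty train and test splits")
    balanced = oversample_training(train_recs, seed=seed)
    neural = train_neural(balanced, val_recs, neural_config,
                          energy_threshold=dataset.energy_threshold)
    morgan = train_morgan(balanced, val_recs, neural_config,
                          morgan_config=morgan_config,
                          energy_threshold=dataset.energy_threshold)
    report = {}
    for name, mdl in (("neural", neural), ("morgan", morgan)):
        full = evaluate(mdl, test_recs)
        report[name] = {k: full[k] for k in REPORT_METRICS}
    report["energy_threshold"] = dataset.energy_threshold
    return report
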