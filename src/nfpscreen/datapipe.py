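"""Score-table ingestion, percentile hit threshold, splitting, oversampling.

The raw input is a docking score table: one SMILES plus one binding free
energy ΔbindG°(aq) (kcal/mol) per row, more negative meaning tighter
binding. Records are split 70/15/15 into train/validation/test; a hit
threshold is then computed as a low-end quantile of the *training* energies
only (no leakage of validation/test quantiles), every record is labeled
hit (1) iff its energy is strictly below the threshold, and the training
split is rebalanced to 50/50 by randomly duplicating hits. Validation and
test splits are never altered.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .molgraph import SmilesParseError, canonical_smiles

logger = logging.getLogger(__name__)

SMILES_COL = "smiles"
ENERGY_COL = "dG_kcal_mol"

DEFAULT_FRACTIONS = (0.70, 0.15, 0.15)
SPLITS = ("train", "validation", "test")


@dataclass
class ScreenRecord:
    smiles: str
    binding_free_energy: float  # ΔbindG°(aq), kcal/mol
    label: int | None = None    # 1 = hit (energy strictly below threshold)
    split: str | None = None


@dataclass
class LabeledDataset:
    records: list[ScreenRecord]
    energy_threshold: float
    hit_fraction_target: float
    split_counts: tuple[int, int, int] = (0, 0, 0)
    seed: int | None = None

    def subset(self, split: str) -> list[ScreenRecord]:
        return [r for r in self.records if r.split == split]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                SMILES_COL: [r.smiles for r in self.records],
                ENERGY_COL: [r.binding_free_energy for r in self.records],
                "label": [r.label for r in self.records],
                "split": [r.split for r in self.records],
            }
        )

    def save(self, csv_path, manifest_path=None) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        if manifest_path is not None:
            manifest = {
                "energy_threshold_kcal_mol": self.energy_threshold,
                "hit_fraction_target": self.hit_fraction_target,
                "split_counts": dict(zip(SPLITS, self.split_counts)),
                "seed": self.seed,
                "n_records": len(self.records),
                "n_hits": sum(r.label or 0 for r in self.records),
            }
            with open(manifest_path, "w") as fh:
                json.dump(manifest, fh, indent=2)

    @classmethod
    def load(cls, csv_path, energy_threshold: float, hit_fraction: float) -> "LabeledDataset":
        df = pd.read_csv(csv_path)
        records = [
            ScreenRecord(r[SMILES_COL], float(r[ENERGY_COL]), int(r["label"]), r["split"])
            for _, r in df.iterrows()
        ]
        counts = tuple(sum(1 for r in records if r.split == s) for s in SPLITS)
        return cls(records, energy_threshold, hit_fraction, counts)


def load_score_table(path) -> list[tuple[str, float]]:
    """Read a (smiles, energy) table.

    Rows with unparsable SMILES or non-numeric energies are dropped and
    counted in the log; duplicate canonical SMILES keep the most negative
    (best-binding) energy.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"empty score table: {path}")
    missing = {SMILES_COL, ENERGY_COL} - set(df.columns)
    if missing:
        raise ValueError(f"score table {path} missing required columns: {sorted(missing)}")
    best: dict[str, float] = {}
    n_bad = 0
    for smi, energy in zip(df[SMILES_COL], df[ENERGY_COL]):
        try:
            canon = canonical_smiles(str(smi))
            e = float(energy)
            if not np.isfinite(e):
                raise ValueError
        except (SmilesParseError, ValueError, TypeError):
            n_bad += 1
            continue
        if canon not in best or e < best[canon]:
            best[canon] = e
    if n_bad:
        logger.warning("dropped %d unparsable/non-numeric rows from %s", n_bad, path)
    if not best:
        raise ValueError(f"no valid records in score table {path}")
    return list(best.items())


def split_dataset(
    records: list[tuple[str, float]],
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
    seed: int = 0,
) -> list[ScreenRecord]:
    """Random disjoint 70/15/15 (by default) train/validation/test assignment.

    Sizes are floor(f_train·n) / floor(f_val·n) / remainder; seeded.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {fractions}")
    n = len(records)
    if n < 3:
        raise ValueError(f"need at least 3 records to split, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(np.floor(fractions[0] * n))
    n_val = int(np.floor(fractions[1] * n))
    out = []
    for rank, idx in enumerate(order):
        split = "train" if rank < n_train else "validation" if rank < n_train + n_val else "test"
        smi, e = records[idx]
        out.append(ScreenRecord(smiles=smi, binding_free_energy=float(e), split=split))
    return out


def compute_threshold(training_energies, hit_fraction: float) -> float:
    """Hit threshold: the hit_fraction quantile from the most-negative end of
    the training energy distribution (empirical order-statistic quantile).

    A record is a hit iff energy < threshold (strict), so the realized
    training hit fraction never exceeds hit_fraction under ties.
    """
    energies = np.asarray(list(training_energies), dtype=float)
    if energies.size == 0:
        raise ValueError("cannot compute a threshold from an empty energy list")
    if not 0.0 < hit_fraction <= 1.0:
        raise ValueError(f"hit_fraction must be in (0, 1], got {hit_fraction}")
    if hit_fraction == 1.0:
        return float(np.max(energies)) + 1.0
    s = np.sort(energies)
    k = int(np.floor(hit_fraction * energies.size))
    # threshold = (k+1)-th order statistic: exactly the k most negative
    # energies fall strictly below it (absent ties)
    return float(s[k]) if k < energies.size else float(s[-1]) + 1.0


def label_records(records: list[ScreenRecord], threshold: float) -> None:
    """Assign hit labels in place with the (training-derived) threshold."""
    for r in records:
        r.label = int(r.binding_free_energy < threshold)


def oversample_training(train_records: list[ScreenRecord], seed: int = 0) -> list[ScreenRecord]:
    """Duplicate training hits uniformly at random until classes balance 50/50.

    Non-hits are untouched; every original hit is retained at multiplicity
    >= 1. If hits already outnumber non-hits the list is returned unchanged.
    """
    hits = [r for r in train_records if r.label == 1]
    non_hits = [r for r in train_records if r.label == 0]
    if not hits:
        raise ValueError(
            "training split contains no hits; increase hit_fraction so the "
            "threshold captures a non-empty low-energy tail"
        )
    if not non_hits or len(hits) >= len(non_hits):
        return list(train_records)
    rng = np.random.default_rng(seed)
    extra = rng.integers(0, len(hits), size=len(non_hits) - len(hits))
    return list(train_records) + [hits[i] for i in extra]


def prepare_dataset(
    records: list[tuple[str, float]],
    hit_fraction: float,
    seed: int = 0,
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
) -> LabeledDataset:
    """Split, threshold on the training split, and label every record."""
    split_records = split_dataset(records, fractions=fractions, seed=seed)
    train_energies = [r.binding_free_energy for r in split_records if r.split == "train"]
    threshold = compute_threshold(train_energies, hit_fraction)
    label_records(split_records, threshold)
    counts = tuple(sum(1 for r in split_records if r.split == s) for s in SPLITS)
    return LabeledDataset(
        records=split_records,
        energy_threshold=threshold,
        hit_fraction_target=hit_fraction,
        split_counts=counts,
        seed=seed,
    )
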