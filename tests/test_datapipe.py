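import numpy as np
import pandas as pd
import pytest

from nfpscreen import datapipe
from nfpscreen.datapipe import (
    ScreenRecord,
    compute_threshold,
    load_score_table,
    oversample_training,
    prepare_dataset,
    split_dataset,
)


def _write_table(tmp_path, rows, name="table.csv"):
    path = tmp_path / name
    pd.DataFrame(rows, columns=["smiles", "dG_kcal_mol"]).to_csv(path, index=False)
    return path


class TestLoadScoreTable:
    def test_well_formed_rows_all_load(self, tmp_path):
        path = _write_table(tmp_path, [("C", -5.0), ("CC", -6.0), ("CCC", -7.0),
                                       ("CCO", -8.0), ("c1ccccc1", -9.0)])
        assert len(load_score_table(path)) == 5

    def test_bad_smiles_dropped_not_fatal(self, tmp_path, caplog):
        path = _write_table(tmp_path, [("C", -5.0), ("xyzzy", -6.0), ("CC", -7.0),
                                       ("CCO", -8.0), ("CCC", -9.0)])
        with caplog.at_level("WARNING"):
            records = load_score_table(path)
        assert len(records) == 4
        assert any("dropped 1" in m for m in caplog.messages)

    def test_duplicate_molecule_keeps_most_negative_energy(self, tmp_path):
        # OCC and CCO are the same molecule
        path = _write_table(tmp_path, [("CCO", -7.0), ("OCC", -9.0), ("C", -5.0)])
        records = dict(load_score_table(path))
        assert len(records) == 2
        assert min(records.values()) == -9.0

    def test_missing_column_errors(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"smiles": ["C"]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="missing required columns"):
            load_score_table(path)

    def test_empty_file_errors(self, tmp_path):
        path = tmp_path / "empty.csv"
        pd.DataFrame(columns=["smiles", "dG_kcal_mol"]).to_csv(path, index=False)
        with pytest.raises(ValueError, match="empty"):
            load_score_table(path)


class TestSplit:
    def test_100_records_split_70_15_15(self):
        records = [(f"C{'C' * i}", -float(i)) for i in range(100)]
        out = split_dataset(records, seed=5)
        counts = {s: sum(1 for r in out if r.split == s)
                  for s in ("train", "validation", "test")}
        assert counts == {"train": 70, "validation": 15, "test": 15}

    def test_same_seed_reproduces_assignment(self):
        records = [(f"C{'C' * i}", -float(i)) for i in range(50)]
        a = split_dataset(records, seed=9)
        b = split_dataset(records, seed=9)
        assert [(r.smiles, r.split) for r in a] == [(r.smiles, r.split) for r in b]

    def test_splits_partition_the_input(self, rng):
        records = [(f"mol{i}", float(e)) for i, e in
                   enumerate(rng.normal(-7, 1, size=1000))]
        out = split_dataset(records, seed=2)
        assert sorted(r.smiles for r in out) == sorted(s for s, _ in records)
        by_split = {}
        for r in out:
            by_split.setdefault(r.split, set()).add(r.smiles)
        sets = list(by_split.values())
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                assert not sets[i] & sets[j]

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            split_dataset([("C", -1.0)] * 5, fractions=(0.8, 0.15, 0.15))


class TestThreshold:
    def test_worked_ten_value_example_marks_two_hits(self):
        energies = [-12, -11, -10, -9, -8, -7, -6, -5, -4, -3]
        thr = compute_threshold(energies, 0.20)
        hits = [e for e in energies if e < thr]
        assert hits == [-12, -11]

    def test_hit_fraction_one_labels_everything(self):
        energies = [-5.0, -6.0, -7.0]
        thr = compute_threshold(energies, 1.0)
        assert all(e < thr for e in energies)

    def test_all_equal_energies_give_zero_hits_under_strict_inequality(self):
        thr = compute_threshold([-7.0] * 10, 0.20)
        assert sum(e < thr for e in [-7.0] * 10) == 0

    def test_threshold_monotone_and_hit_sets_nested(self, rng):
        energies = rng.normal(-7, 1.5, size=500)
        thresholds = [compute_threshold(energies, f) for f in (0.05, 0.10, 0.20)]
        assert thresholds[0] <= thresholds[1] <= thresholds[2]
        hit_sets = [frozenset(np.flatnonzero(energies < t)) for t in thresholds]
        assert hit_sets[0] <= hit_sets[1] <= hit_sets[2]

    def test_empty_energies_error(self):
        with pytest.raises(ValueError, match="empty"):
            compute_threshold([], 0.2)


def _records(n_hits, n_non):
    recs = [ScreenRecord(f"hit{i}", -10.0, label=1, split="train")
            for i in range(n_hits)]
    recs += [ScreenRecord(f"non{i}", -5.0, label=0, split="train")
             for i in range(n_non)]
    return recs


class TestOversample:
    def test_20_80_becomes_50_50_of_160(self):
        out = oversample_training(_records(20, 80), seed=0)
        labels = [r.label for r in out]
        assert len(out) == 160
        assert sum(labels) == 80

    def test_balanced_input_is_fixed_point(self):
        recs = _records(50, 50)
        assert oversample_training(recs, seed=0) == recs

    def test_duplicates_drawn_from_original_hits_and_all_hits_retained(self):
        recs = _records(7, 31)
        out = oversample_training(recs, seed=3)
        hit_names = [r.smiles for r in out if r.label == 1]
        original = {f"hit{i}" for i in range(7)}
        assert set(hit_names) == original          # nothing invented, none lost
        assert all(hit_names.count(h) >= 1 for h in original)
        assert len(hit_names) == 31

    def test_zero_hits_is_an_instructive_error(self):
        with pytest.raises(ValueError, match="hit_fraction"):
            oversample_training(_records(0, 10), seed=0)


class TestPrepareDataset:
    def test_validation_and_test_labeled_with_training_threshold(self):
        # the dataset threshold must equal the training-only quantile, and
        # every split's labels must come from that one threshold (no leakage
        # of validation/test quantiles)
        rng = np.random.default_rng(4)
        pairs = [(f"m{i}", float(e)) for i, e in enumerate(rng.normal(-7, 2, 1000))]
        ds = prepare_dataset(pairs, hit_fraction=0.2, seed=0)
        train_energies = [r.binding_free_energy for r in ds.subset("train")]
        assert ds.energy_threshold == compute_threshold(train_energies, 0.2)
        for r in ds.records:
            assert r.label == int(r.binding_free_energy < ds.energy_threshold)
        # validation/test hit fractions float freely around 20%
        for split in ("validation", "test"):
            frac = np.mean([r.label for r in ds.subset(split)])
            assert 0.05 < frac < 0.45

    def test_manifest_roundtrip(self, small_dataset, tmp_path):
        csv_path = tmp_path / "labeled.csv"
        small_dataset.save(csv_path, tmp_path / "labeled.manifest.json")
        reloaded = datapipe.LabeledDataset.load(
            csv_path, small_dataset.energy_threshold,
            small_dataset.hit_fraction_target)
        assert len(reloaded.records) == len(small_dataset.records)
        assert reloaded.split_counts == small_dataset.split_counts
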