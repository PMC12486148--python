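"""Surrogate training, prediction, evaluation, grid search and comparison.

All trainings here use deliberately small models and datasets; the
full-size capability checks live in the acceptance tests.
"""

import numpy as np
import pytest

import pepanneal as pa
from pepanneal.surrogate import SurrogateConfig

TINY = SurrogateConfig(architecture="lstm", num_layers=1, hidden_dim=16,
                       epochs=8, seed=1)


def _dataset(n, seed=0, noise=0.0, n_couplings=6, weight_scale=2.0):
    ls = pa.make_landscape(seed=seed, noise_sigma=noise, n_couplings=n_couplings,
                           weight_scale=weight_scale)
    table = pa.generate_dataset(ls, n, seed=seed + 1)
    return ls, table


class _LookupModel:
    """Test stub: maps a one-hot batch back to a stored score per sequence."""

    dtype = np.float32

    def __init__(self, mapping, shift=0.0):
        self.mapping = mapping
        self.shift = shift

    def forward(self, X):
        idx = X.argmax(axis=2).astype(np.uint8)
        return np.array(
            [self.mapping[row.tobytes()] + self.shift for row in idx],
            dtype=np.float32,
        )


def _lookup_surrogate(table, shift=0.0):
    mapping = {
        pa.CANONICAL.to_indices(s).tobytes(): v
        for s, v in zip(table.sequences, table.scores)
    }
    return pa.TrainedSurrogate(
        material_label=table.material_label,
        config=TINY,
        alphabet=pa.CANONICAL,
        peptide_length=table.peptide_length,
        model=_LookupModel(mapping, shift),
    )


class TestTrainSurrogate:
    def test_constant_scores_are_fit_by_the_bias(self):
        rng = np.random.default_rng(0)
        records = [(pa.random_peptide(rng), -61.2) for _ in range(400)]
        table = pa.ScoreTable.from_records("const", records)
        tr, va, te = pa.split_table(table, seed=0)
        fitted = pa.train_surrogate(tr, va, TINY)
        assert pa.evaluate_surrogate(fitted, te).rmse < 0.1

    def test_learns_noiseless_additive_landscape(self):
        ls, table = _dataset(4000, seed=3, noise=0.0, n_couplings=0)
        tr, va, te = pa.split_table(table, seed=3)
        cfg = SurrogateConfig(architecture="rnn", num_layers=1, hidden_dim=32,
                              epochs=25, seed=2)
        fitted = pa.train_surrogate(tr, va, cfg)
        metrics = pa.evaluate_surrogate(fitted, te)
        assert metrics.r_squared >= 0.95
        # spot-check individual predictions against the generating oracle
        probe = te.sequences[:20]
        pred = fitted.predict(probe)
        truth = np.array([ls.score(p) for p in probe])
        assert np.sqrt(np.mean((pred - truth) ** 2)) < 0.25 * np.std(te.scores)

    def test_same_seed_reproduces_training_exactly(self):
        _, table = _dataset(800, seed=5, noise=0.5)
        tr, va, _ = pa.split_table(table, seed=5)
        a = pa.train_surrogate(tr, va, TINY)
        b = pa.train_surrogate(tr, va, TINY)
        assert a.history == b.history

    def test_empty_or_mismatched_tables_rejected(self):
        _, table = _dataset(100, seed=6)
        empty = pa.ScoreTable("x", table.df.iloc[:0])
        with pytest.raises(ValueError):
            pa.train_surrogate(empty, table, TINY)
        short = pa.ScoreTable.from_records(
            "y", [("AAA", -40.0), ("WWW", -50.0)]
        )
        with pytest.raises(ValueError):
            pa.train_surrogate(table, short, TINY)


class TestPredict:
    def test_batch_equals_elementwise_and_permutes(self):
        _, table = _dataset(300, seed=7)
        tr, va, _ = pa.split_table(table, seed=7)
        fitted = pa.train_surrogate(tr, va, TINY)
        peps = tr.sequences[:50]
        batch = fitted.predict(peps)
        singles = np.array([fitted.predict([p])[0] for p in peps])
        assert np.allclose(batch, singles, atol=1e-5)
        perm = np.random.default_rng(0).permutation(50)
        assert np.allclose(fitted.predict([peps[i] for i in perm]), batch[perm],
                           atol=1e-6)

    def test_wrong_length_rejected(self):
        _, table = _dataset(200, seed=8)
        tr, va, _ = pa.split_table(table, seed=8)
        fitted = pa.train_surrogate(tr, va, TINY)
        with pytest.raises(ValueError, match="length"):
            fitted.predict(["AAA"])


class TestEvaluate:
    def test_perfect_predictions(self):
        _, table = _dataset(100, seed=9, noise=0.5)
        metrics = pa.evaluate_surrogate(_lookup_surrogate(table), table)
        assert metrics.r_squared == pytest.approx(1.0, abs=1e-9)
        assert metrics.rmse == pytest.approx(0.0, abs=1e-5)

    def test_constant_offset_has_closed_form(self):
        _, table = _dataset(100, seed=9, noise=0.5)
        metrics = pa.evaluate_surrogate(_lookup_surrogate(table, shift=2.0), table)
        y = table.scores
        assert metrics.rmse == pytest.approx(2.0, abs=1e-5)
        assert metrics.r_squared == pytest.approx(1 - 4.0 / np.var(y), abs=1e-4)

    def test_mean_prediction_gives_zero_r_squared(self):
        _, table = _dataset(100, seed=9, noise=0.5)
        mean_table = pa.ScoreTable.from_records(
            "m", [(s, float(table.scores.mean())) for s in table.sequences]
        )
        metrics = pa.evaluate_surrogate(_lookup_surrogate(mean_table), table)
        assert metrics.r_squared == pytest.approx(0.0, abs=1e-6)

    def test_zero_variance_reports_nan_r_squared(self):
        rng = np.random.default_rng(1)
        const = pa.ScoreTable.from_records(
            "c", [(pa.random_peptide(rng), -40.0) for _ in range(10)]
        )
        metrics = pa.evaluate_surrogate(_lookup_surrogate(const, shift=1.0), const)
        assert np.isnan(metrics.r_squared)
        assert metrics.rmse == pytest.approx(1.0, abs=1e-5)


class TestPersistence:
    def test_artifact_round_trip_preserves_predictions(self, tmp_path):
        _, table = _dataset(300, seed=10, noise=0.5)
        tr, va, _ = pa.split_table(table, seed=10)
        fitted = pa.train_surrogate(tr, va, TINY)
        fitted.save(tmp_path / "model")
        loaded = pa.TrainedSurrogate.load(tmp_path / "model")
        probe = va.sequences[:30]
        assert np.array_equal(fitted.predict(probe), loaded.predict(probe))
        assert loaded.alphabet.letters == pa.CANONICAL.letters
        assert loaded.data_fingerprint == fitted.data_fingerprint


class TestGridSearch:
    def test_grid_has_one_cell_per_combination_and_argmax(self):
        _, table = _dataset(600, seed=11, noise=0.5)
        tr, va, _ = pa.split_table(table, seed=11)
        result = pa.grid_search(
            tr, va, layer_choices=(1, 2), hidden_choices=(8, 16),
            base_config=SurrogateConfig(epochs=4, seed=0),
        )
        assert len(result.cells) == 4
        best = result.cells[result.best]
        assert all(best >= v for v in result.cells.values() if np.isfinite(v))

    def test_capacity_effect_on_epistatic_landscape(self):
        """A hidden dimension of 2 cannot represent the landscape a width-32
        model fits easily."""
        _, table = _dataset(3000, seed=12, noise=0.0)
        tr, va, _ = pa.split_table(table, seed=12)
        cfg = SurrogateConfig(epochs=15, num_layers=1, seed=3)
        result = pa.grid_search(tr, va, layer_choices=(1,), hidden_choices=(2, 32),
                                base_config=cfg)
        assert result.cells[(1, 2)] < result.cells[(1, 32)]


class TestCompareArchitectures:
    def test_one_row_per_architecture_and_determinism(self):
        _, table = _dataset(500, seed=13, noise=0.5)
        tr, va, te = pa.split_table(table, seed=13)
        cfg = SurrogateConfig(num_layers=1, hidden_dim=16, epochs=3, seed=4)
        rows = pa.compare_architectures(tr, va, te, base_config=cfg)
        assert set(rows) == {"lstm", "bilstm", "gru", "rnn", "transformer"}
        assert all(np.isfinite(r["r_squared"]) for r in rows.values())
        again = pa.compare_architectures(tr, va, te, base_config=cfg)
        for arch in rows:
            assert rows[arch]["r_squared"] == again[arch]["r_squared"]


def test_more_training_data_does_not_hurt():
    """Median held-out R² over 3 seeds is non-decreasing in training-set
    size on a fixed landscape (scaled-down sizes)."""
    ls = pa.make_landscape(seed=14, noise_sigma=0.5)
    test = pa.generate_dataset(ls, 1000, seed=999)
    medians = []
    for n in (1000, 4000, 12000):
        r2s = []
        for seed in (0, 1, 2):
            table = pa.generate_dataset(ls, n, seed=100 + seed)
            tr, va, _ = pa.split_table(table, seed=seed)
            cfg = SurrogateConfig(architecture="lstm", num_layers=1,
                                  hidden_dim=32, epochs=12, seed=seed)
            fitted = pa.train_surrogate(tr, va, cfg)
            r2s.append(pa.evaluate_surrogate(fitted, test).r_squared)
        medians.append(float(np.median(r2s)))
    assert medians[0] <= medians[1] <= medians[2]
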