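"""Loss closed forms, optimizer behaviour, training determinism, grid
mechanics and family summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medcap._tensor import Tensor
from medcap.errors import ConfigurationError, ValidationError
from medcap.features import FeatureBundle
from medcap.fixtures import load_fixture, load_full_grid, load_grid
from medcap.optim import OPTIMIZERS, make_optimizer
from medcap.training import (ExperimentRecord, GridSpec, TrainConfig,
                             best_record, family_summary, records_to_frame,
                             sparse_cce, train)
from medcap.transcoder import build_vocabulary, encode_targets

from test_transcoder import make_model


class TestSparseCCE:
    def test_one_hot_correct_prediction_is_zero(self):
        p = np.array([[0.0, 1.0, 0.0]])
        assert sparse_cce(p, np.array([1])) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_is_log_c(self):
        p = np.full((2, 4), 0.25)
        assert sparse_cce(p, np.array([0, 3])) == pytest.approx(np.log(4), abs=1e-12)

    def test_point_seven_closed_form(self):
        p = np.array([[0.3, 0.7]])
        assert sparse_cce(p, np.array([1])) == pytest.approx(-np.log(0.7), abs=1e-12)

    def test_padding_positions_excluded(self):
        p = np.array([[0.5, 0.5], [1.0, 0.0]])
        labels = np.array([1, 0])  # second position is PAD (id 0)
        assert sparse_cce(p, labels, pad_id=0) == pytest.approx(np.log(2))

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValidationError):
            sparse_cce(np.full((1, 3), 1 / 3), np.array([3]))


class TestOptimizers:
    @pytest.mark.parametrize("name", sorted(OPTIMIZERS))
    def test_each_optimizer_descends_a_quadratic(self, name):
        p = Tensor(np.array([5.0, -3.0]))
        start = float((p.data ** 2).sum())
        opt = make_optimizer(name, [p])
        losses = []
        for _ in range(200):
            opt.zero_grad()
            loss = (p * p).sum()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        assert float((p.data ** 2).sum()) < start
        assert losses[-1] < losses[0]

    def test_unknown_optimizer_rejected(self):
        with pytest.raises(ConfigurationError):
            make_optimizer("sgdx", [])
        with pytest.raises(ConfigurationError):
            TrainConfig(optimizer="sgdx")


def _memorization_problem(n=1, seed=0, max_len=6):
    rng = np.random.default_rng(seed)
    model = make_model(seed=seed, max_len=max_len)
    feats = rng.normal(size=(n, 4, 8))
    vocab = model.vocabulary
    targets = encode_targets(vocab, [["ct", "chest", "tumor"]] * n, max_len)
    bundle = FeatureBundle([f"im{i}" for i in range(n)], feats)
    return model, bundle, targets


class TestTrain:
    def test_overfits_one_sample(self):
        model, bundle, targets = _memorization_problem()
        cfg = TrainConfig(optimizer="adam", max_epochs=200, early_stop_patience=0, seed=0)
        model, history = train(model, bundle, targets, cfg)
        assert history["train_loss"][-1] < 0.05
        from medcap.transcoder import generate_caption

        assert generate_caption(bundle.features[0], model) == ["ct", "chest", "tumor"]

    def test_same_seed_reproduces_history_exactly(self):
        cfg = TrainConfig(max_epochs=5, seed=12)
        _, h1 = train(*_memorization_problem(n=4, seed=1), cfg)
        _, h2 = train(*_memorization_problem(n=4, seed=1), cfg)
        assert h1 == h2

    def test_loss_is_tolerantly_monotone_on_memorization(self):
        model, bundle, targets = _memorization_problem(n=2, seed=3)
        cfg = TrainConfig(max_epochs=40, early_stop_patience=0, seed=3)
        _, history = train(model, bundle, targets, cfg)
        losses = history["train_loss"]
        for a, b in zip(losses[5:], losses[6:]):
            assert b <= a + 1e-3

    def test_early_stopping_respects_patience(self):
        model, bundle, targets = _memorization_problem(n=2, seed=4)
        cfg = TrainConfig(max_epochs=50, early_stop_patience=2, seed=4)
        _, history = train(model, bundle, targets, cfg)
        assert 1 <= history["epochs"] <= 50

    def test_misaligned_inputs_rejected(self):
        model, bundle, targets = _memorization_problem(n=2)
        with pytest.raises(ValidationError):
            train(model, bundle, targets[:1], TrainConfig())


class TestGrid:
    def test_cell_count_and_order(self):
        grid = GridSpec(backbones=("tiny_cnn", "tiny_cnn"),
                        optimizers=("adam", "adadelta"))
        cells = list(grid.cells())
        assert len(cells) == len(grid) == 4
        assert [c[0] for c in cells] == [1, 2, 3, 4]
        assert cells[0][2] == "adam" and cells[1][2] == "adadelta"

    def test_empty_grid_rejected(self):
        from medcap.training import run_grid

        with pytest.raises(ConfigurationError):
            run_grid(GridSpec(backbones=()), ".", TrainConfig())

    def test_best_record_on_published_densenet_family(self):
        grid = load_grid(4)
        records = [
            ExperimentRecord(int(r.ID), "densenet201", r.OPTZ, bool(r.TL),
                             bool(r.TR), bool(r.IA), loss=r.Loss, acc=r.ACC)
            for r in grid.itertuples()
        ]
        best = best_record(records)
        assert best.id == 20 and best.acc == pytest.approx(0.7610)

    def test_records_frame_has_published_header(self):
        frame = records_to_frame([ExperimentRecord(1, "tiny_cnn", "adam", 0, 0, 0)])
        assert list(frame.columns) == ["ID", "OPTZ", "TL", "TR", "IA", "Loss",
                                       "ACC", "Epochs", "Training Time (s)",
                                       "Test Time (s)"]


class TestFamilySummary:
    def test_single_value(self):
        s = family_summary([0.5])
        assert (s.mu, s.sigma) == (0.5, 0.0)

    def test_two_values_population_divisor(self):
        s = family_summary([0.7, 0.9])
        assert s.mu == pytest.approx(0.8) and s.sigma == pytest.approx(0.1)
        assert s.mu_minus_sigma == pytest.approx(0.7)
        assert s.mu_plus_sigma == pytest.approx(0.9)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            family_summary([])

    def test_population_not_sample_divisor_on_published_accuracies(self):
        acc = load_fixture("densenet_acc").payload
        s = family_summary(acc)
        assert round(s.sigma, 4) == 0.0114  # population divisor
        assert round(float(np.std(acc, ddof=1)), 4) == 0.0117  # sample divisor differs

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    def test_matches_brute_force_oracle(self, values):
        s = family_summary(values)
        a = np.asarray(values)
        assert s.mu == pytest.approx(sum(values) / len(values))
        assert s.sigma == pytest.approx(float(np.sqrt(((a - a.mean()) ** 2).mean())))
        assert s.min == min(values) and s.max == max(values)
        assert s.min - 1e-12 <= s.mu <= s.max + 1e-12 and s.sigma >= 0
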