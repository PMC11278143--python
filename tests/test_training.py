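import numpy as np
import pytest

from carotidseg.model import ResUnetConfig
from carotidseg.training import (EarlyStopping, TrainConfig, dice_loss,
                                 dice_loss_grad, lr_at, make_folds, train_fold,
                                 train_round)


class TestDiceLoss:
    def test_perfect_match_is_zero(self):
        t = np.zeros((8, 8))
        t[2:5, 2:5] = 1
        assert dice_loss(t, t, smooth=1.0) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n", [1, 5, 20])
    def test_disjoint_closed_form(self, n):
        pred = np.zeros(2 * n)
        target = np.zeros(2 * n)
        pred[:n] = 1
        target[n:] = 1
        assert dice_loss(pred, target, 1.0) == pytest.approx(
            1 - 1 / (2 * n + 1), abs=1e-12)

    def test_both_empty_is_zero(self):
        z = np.zeros((4, 4))
        assert dice_loss(z, z, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_monotone_along_interpolation_toward_target(self):
        rng = np.random.default_rng(4)
        target = (rng.random((12, 12)) > 0.7).astype(float)
        start = 1.0 - target  # fully disjoint prediction
        losses = [dice_loss(start + a * (target - start), target)
                  for a in np.linspace(0, 1, 20)]
        assert all(b < a for a, b in zip(losses, losses[1:]))

    def test_grad_matches_finite_difference(self):
        rng = np.random.default_rng(0)
        pred = rng.random((6, 6))
        target = (rng.random((6, 6)) > 0.5).astype(float)
        g = dice_loss_grad(pred, target)
        i, j = 2, 3
        eps = 1e-7
        pp, pm = pred.copy(), pred.copy()
        pp[i, j] += eps
        pm[i, j] -= eps
        num = (dice_loss(pp, target) - dice_loss(pm, target)) / (2 * eps)
        assert g[i, j] == pytest.approx(num, rel=1e-5)


class TestLrSchedule:
    @pytest.mark.parametrize("step,expected", [
        (0, 1e-4), (253, 9.6e-5), (506, 9.216e-5)])
    def test_closed_form(self, step, expected):
        assert lr_at(step, TrainConfig()) == pytest.approx(expected, abs=1e-12)

    def test_continuous_not_staircase(self):
        cfg = TrainConfig()
        mid = lr_at(126, cfg)
        assert lr_at(0, cfg) > mid > lr_at(253, cfg)

    def test_strictly_decreasing(self):
        cfg = TrainConfig()
        vals = [lr_at(s, cfg) for s in range(0, 2000, 50)]
        assert all(b < a for a, b in zip(vals, vals[1:]))


class TestFolds:
    def test_even_volume_split(self, small_dataset):
        _, pairs = small_dataset
        split = make_folds(pairs, 3, seed=0)
        counts = {}
        for f in split.volume_fold.values():
            counts[f] = counts.get(f, 0) + 1
        assert sorted(counts.values()) == [2, 2, 2]

    def test_same_seed_identical(self, small_dataset):
        _, pairs = small_dataset
        a = make_folds(pairs, 5, seed=4)
        b = make_folds(pairs, 5, seed=4)
        assert a.assignments == b.assignments

    def test_partition(self, small_dataset):
        _, pairs = small_dataset
        split = make_folds(pairs, 5, seed=1)
        all_idx = sorted(i for f in range(5) for i in split.val_indices(f))
        assert all_idx == list(range(len(pairs)))

    def test_volume_slices_share_fold(self, small_dataset):
        _, pairs = small_dataset
        split = make_folds(pairs, 5, seed=2)
        for i, p in enumerate(pairs):
            assert split.assignments[i] == split.volume_fold[p.volume_id]

    def test_too_few_volumes(self, small_dataset):
        _, pairs = small_dataset
        with pytest.raises(ValueError):
            make_folds(pairs, 7, seed=0)


class TestEarlyStopping:
    def test_constant_sequence_stops_after_patience(self):
        stopper = EarlyStopping(patience=10)
        stopped_at = None
        for epoch in range(1, 100):
            if stopper.update(0.5, epoch):
                stopped_at = epoch
                break
        assert stopped_at == 11
        assert stopper.best_epoch == 1

    def test_strictly_improving_never_stops(self):
        stopper = EarlyStopping(patience=10)
        assert not any(stopper.update(0.01 * e, e) for e in range(1, 101))

    def test_best_epoch_tracked_through_decline(self):
        stopper = EarlyStopping(patience=3)
        seq = [0.2, 0.6, 0.5, 0.4, 0.3]
        stops = [stopper.update(v, e + 1) for e, v in enumerate(seq)]
        assert stops == [False, False, False, False, True]
        assert stopper.best_epoch == 2 and stopper.best == 0.6


@pytest.fixture(scope="module")
def trained(small_dataset):
    _, pairs = small_dataset
    split = make_folds(pairs, 5, seed=0)
    cfg = TrainConfig(lr0=1e-3, max_epochs=3, patience=3, batch_size=8, seed=0)
    mcfg = ResUnetConfig(in_shape=(32, 32, 3), levels=4, base_filters=2,
                         bottleneck_filters=16, dropout_p=0.1)
    net, hist = train_fold(0, pairs, split, cfg, mcfg)
    return pairs, split, cfg, mcfg, net, hist


class TestTrainFold:
    def test_history_columns(self, trained):
        *_, hist = trained
        assert list(hist.columns) == ["epoch", "train_loss", "val_mean_iou", "lr"]
        assert len(hist) == 3

    def test_best_weights_reproduce_best_val_iou(self, trained):
        pairs, split, cfg, mcfg, net, hist = trained
        from carotidseg.training import _mean_val_iou
        best = hist.val_mean_iou.max()
        again = _mean_val_iou(net, pairs, split.val_indices(0),
                              mcfg.prob_threshold, cfg.batch_size)
        assert again == pytest.approx(best, abs=1e-12)

    def test_smoke_loss_decreases_on_phantom_slices(self, small_dataset):
        # 40 slices at 32×32 with a 64-filter bottleneck: training pushes the
        # Dice loss from its chance-level start below 0.5
        _, pairs = small_dataset
        subset = pairs[:40]
        split = make_folds(subset, 2, seed=0)
        cfg = TrainConfig(lr0=1e-3, max_epochs=15, patience=15, batch_size=8,
                          seed=0)
        mcfg = ResUnetConfig(in_shape=(32, 32, 3), levels=5, base_filters=4,
                             bottleneck_filters=64, dropout_p=0.1)
        net, hist = train_fold(0, subset, split, cfg, mcfg)
        assert hist.train_loss.iloc[0] > 0.6
        assert hist.train_loss.iloc[-1] < 0.5


class TestTrainRound:
    def test_returns_one_net_per_fold(self, small_dataset):
        _, pairs = small_dataset
        split = make_folds(pairs, 5, seed=0)
        cfg = TrainConfig(lr0=1e-3, max_epochs=1, patience=1, batch_size=8,
                          seed=0)
        mcfg = ResUnetConfig(in_shape=(32, 32, 3), levels=3, base_filters=2,
                             bottleneck_filters=8, dropout_p=0.0)
        nets, hists = train_round(pairs, split, cfg, mcfg)
        assert len(nets) == 5 and len(hists) == 5
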