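"""Loss and Dice oracles: closed forms, brute-force loops, identities."""

import numpy as np
import pandas as pd
import pytest

from ctseg.metrics import (
    LossConfig,
    aggregate_dice,
    categorical_crossentropy,
    combined_loss,
    combined_loss_grad,
    dice_score,
    tanimoto_loss,
    tanimoto_loss_per_class,
)


def random_instance(rng, n_vox=50, C=3):
    """A seeded (probability map, one-hot truth) pair as flat (C, n) arrays."""
    logits = rng.normal(size=(C, n_vox))
    pred = np.exp(logits) / np.exp(logits).sum(axis=0, keepdims=True)
    labels = rng.integers(0, C, size=n_vox)
    truth = np.zeros((C, n_vox))
    truth[labels, np.arange(n_vox)] = 1.0
    return pred, truth


def tanimoto_oracle(pred, truth, smooth):
    """Scalar-loop evaluation of the per-class smoothed Tanimoto loss."""
    C = pred.shape[0]
    out = []
    for c in range(C):
        inter = sq_p = sq_t = 0.0
        for p, t in zip(pred[c].ravel(), truth[c].ravel()):
            inter += p * t
            sq_p += p * p
            sq_t += t * t
        out.append(1.0 - (inter + smooth) / (sq_p + sq_t - inter + smooth))
    return np.array(out)


def crossentropy_oracle(pred, truth, eps=1e-12):
    total, n = 0.0, 0
    C = pred.shape[0]
    flat_p = pred.reshape(C, -1)
    flat_t = truth.reshape(C, -1)
    for v in range(flat_p.shape[1]):
        c = int(np.argmax(flat_t[:, v]))
        total += -np.log(min(max(flat_p[c, v], eps), 1.0))
        n += 1
    return total / n


class TestTanimoto:
    def test_perfect_prediction_gives_zero(self):
        truth = np.zeros((3, 10))
        truth[0, :4] = truth[1, 4:7] = truth[2, 7:] = 1.0
        assert tanimoto_loss(truth, truth) == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(tanimoto_loss_per_class(truth, truth), 0.0, atol=1e-12)

    def test_absent_class_contributes_zero_via_smooth(self):
        pred = np.zeros((3, 5))
        truth = np.zeros((3, 5))
        pred[0] = truth[0] = 1.0  # classes 1, 2 absent everywhere
        per_class = tanimoto_loss_per_class(pred, truth, smooth=1e-5)
        assert per_class[1] == pytest.approx(0.0, abs=1e-12)
        assert per_class[2] == pytest.approx(0.0, abs=1e-12)

    def test_single_voxel_total_disagreement_closed_form(self):
        smooth = 1e-5
        pred = np.array([[1.0], [0.0]])
        truth = np.array([[0.0], [1.0]])
        expected = 1.0 - smooth / (1.0 + smooth)
        per_class = tanimoto_loss_per_class(pred, truth, smooth=smooth)
        assert per_class == pytest.approx([expected, expected])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scalar_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pred, truth = random_instance(rng)
        assert tanimoto_loss_per_class(pred, truth, 1e-5) == pytest.approx(
            tanimoto_oracle(pred, truth, 1e-5), abs=1e-12)

    def test_bounded_in_unit_interval(self, rng):
        pred, truth = random_instance(rng, n_vox=200)
        assert 0.0 <= tanimoto_loss(pred, truth) <= 1.0


class TestCrossentropy:
    def test_uniform_prediction_equals_log_C(self, rng):
        for C in (2, 3, 5):
            pred = np.full((C, 40), 1.0 / C)
            _, truth = random_instance(rng, n_vox=40, C=C)
            assert categorical_crossentropy(pred, truth) == pytest.approx(np.log(C))

    def test_perfect_prediction_near_zero(self):
        truth = np.zeros((2, 6))
        truth[0, :3] = truth[1, 3:] = 1.0
        assert categorical_crossentropy(truth, truth) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_voxel_loop_oracle(self, seed):
        rng = np.random.default_rng(seed + 100)
        pred, truth = random_instance(rng)
        assert categorical_crossentropy(pred, truth) == pytest.approx(
            crossentropy_oracle(pred, truth), abs=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        pred, truth = random_instance(rng)
        with pytest.raises(ValueError):
            categorical_crossentropy(pred, truth[:, :-1])


class TestCombined:
    def test_recomposition_with_default_weights(self, rng):
        pred, truth = random_instance(rng)
        cfg = LossConfig()
        expected = 0.6 * tanimoto_loss(pred, truth, cfg.smooth) + 0.4 * categorical_crossentropy(pred, truth)
        assert combined_loss(pred, truth, cfg) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_weights_reduce_to_tanimoto(self, rng):
        pred, truth = random_instance(rng)
        cfg = LossConfig(alpha=1.0, beta=0.0)
        assert combined_loss(pred, truth, cfg) == pytest.approx(
            tanimoto_loss(pred, truth, cfg.smooth), abs=1e-15)

    def test_zero_iff_perfect(self, rng):
        truth = np.zeros((2, 6))
        truth[0, :3] = truth[1, 3:] = 1.0
        assert combined_loss(truth, truth) == pytest.approx(0.0, abs=1e-9)
        pred, t2 = random_instance(rng)
        assert combined_loss(pred, t2) > 0.0

    def test_monotone_along_path_to_truth(self, rng):
        pred, truth = random_instance(rng, n_vox=30)
        uniform = np.full_like(pred, 1.0 / pred.shape[0])
        losses = [
            combined_loss(uniform + t * (truth - uniform), truth)
            for t in np.linspace(0.0, 0.999, 11)
        ]
        assert all(b < a for a, b in zip(losses, losses[1:]))

    def test_analytic_gradient_matches_numeric(self, rng):
        pred, truth = random_instance(rng, n_vox=4)
        cfg = LossConfig()
        grad = combined_loss_grad(pred, truth, cfg)
        eps = 1e-7
        for c in range(pred.shape[0]):
            for v in range(pred.shape[1]):
                plus = pred.copy(); plus[c, v] += eps
                minus = pred.copy(); minus[c, v] -= eps
                num = (combined_loss(plus, truth, cfg) - combined_loss(minus, truth, cfg)) / (2 * eps)
                assert grad[c, v] == pytest.approx(num, abs=1e-4)


class TestDice:
    def test_forced_arithmetic(self):
        a = np.zeros((1, 2, 2), dtype=int)
        b = np.zeros((1, 2, 2), dtype=int)
        a[0, 0, :] = 1          # pred covers 2 voxels
        b[0, :, 0] = 1          # truth covers 2, overlap 1
        assert dice_score(a, b, 1) == pytest.approx(0.5)

    def test_identity_and_disjoint(self):
        a = np.zeros((1, 3, 3), dtype=int)
        a[0, 1, 1] = 1
        assert dice_score(a, a.copy(), 1) == 1.0
        b = np.zeros_like(a)
        b[0, 0, 0] = 1
        assert dice_score(a, b, 1) == 0.0

    def test_absent_class_convention(self):
        empty = np.zeros((1, 2, 2), dtype=int)
        assert dice_score(empty, empty, 1) == 1.0

    def test_symmetry_and_permutation_invariance(self, rng):
        a = rng.integers(0, 3, size=(2, 4, 4))
        b = rng.integers(0, 3, size=(2, 4, 4))
        assert dice_score(a, b, 1) == dice_score(b, a, 1)
        perm = rng.permutation(a.size)
        ap = a.ravel()[perm].reshape(a.shape)
        bp = b.ravel()[perm].reshape(b.shape)
        assert dice_score(ap, bp, 1) == pytest.approx(dice_score(a, b, 1))

    def test_tanimoto_dice_identity_on_binary_masks(self, rng):
        # T = D / (2 - D) on crisp masks as smoothing vanishes
        for _ in range(20):
            a = (rng.random((2, 30)) > 0.5).astype(float)
            a = np.stack([1 - a[0], a[0]])
            b = (rng.random(30) > 0.5).astype(float)
            truth = np.stack([1 - b, b])
            t = 1.0 - tanimoto_loss_per_class(a, truth, smooth=1e-12)
            for c, ind in ((0, 0), (1, 1)):
                d = dice_score(np.argmax(a, 0).reshape(1, 1, -1),
                               np.argmax(truth, 0).reshape(1, 1, -1), ind)
                assert t[c] == pytest.approx(d / (2.0 - d), abs=1e-6)


class TestAggregate:
    def test_identical_scores_have_zero_std(self):
        df = pd.DataFrame({"fold": [0, 0, 1, 1], "volume": list("abcd"),
                           "class": [1, 1, 1, 1], "score": [0.8] * 4})
        report = aggregate_dice(df)
        assert report.two_level.loc["1", "std"] == 0.0
        assert report.two_level.loc["1", "mean"] == pytest.approx(0.8)

    def test_two_scores_average(self):
        df = pd.DataFrame({"fold": [0, 0], "volume": ["a", "b"],
                           "class": [1, 1], "score": [0.9, 1.0]})
        assert aggregate_dice(df).pooled.loc["1", "mean"] == pytest.approx(0.95)

    def test_matches_spreadsheet_oracle(self, rng):
        rows = []
        for fold in range(3):
            for vol in range(4):
                for cls in (1, 2):
                    rows.append({"fold": fold, "volume": f"v{fold}_{vol}",
                                 "class": cls, "score": rng.random()})
        df = pd.DataFrame(rows)
        report = aggregate_dice(df)
        # oracle: totals per volume, then fold means, then mean/population-std
        fold_means = []
        for fold in range(3):
            sub = df[df["fold"] == fold]
            per_vol = [sub[sub["volume"] == v]["score"].mean() for v in sub["volume"].unique()]
            fold_means.append(np.mean(per_vol))
        assert report.two_level.loc["total", "mean"] == pytest.approx(np.mean(fold_means), abs=1e-12)
        assert report.two_level.loc["total", "std"] == pytest.approx(np.std(fold_means), abs=1e-12)
        pooled = df.groupby(["fold", "volume"])["score"].mean()
        assert report.pooled.loc["total", "mean"] == pytest.approx(pooled.mean(), abs=1e-12)
        assert report.pooled.loc["total", "std"] == pytest.approx(pooled.std(ddof=0), abs=1e-12)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            aggregate_dice(pd.DataFrame())
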