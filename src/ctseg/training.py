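"""Training loop, slice-count-sorted cross-validation folds, and inference.

Training follows the batch-sampling scheme of the framework: per step a
random batch of volumes is preprocessed (fresh slice sampling each time —
an augmentation effect in itself), passed through the CTIA augmentation
chain per policy, and the network is updated with ADAM on the combined
Tanimoto + crossentropy loss.  Cross-validation folds are *not* shuffled:
cases are sorted by slice count (ties by slice thickness, then identifier)
and split into contiguous blocks, so each fold is validated on volume
geometries unlike those it trained on — the worst-case clinical scenario.

:class:`CTSegmenter` wraps the whole pipeline as a scikit-learn style
estimator (fit on a list of cases, predict label volumes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.transform import resize, resize_local_mean
from sklearn.base import BaseEstimator

from .augment import AugmentPolicy, augment_batch
from .io import Case, CTVolume, LabelVolume
from .metrics import LossConfig, combined_loss, combined_loss_grad, dice_score
from .models import ModelSpec, SegmentationNet, build_model
from .nn import Adam, softmax, softmax_backward
from .preprocess import CTPreprocessor, SliceStack

__all__ = [
    "TrainConfig",
    "FoldAssignment",
    "TrainingDivergedError",
    "assign_folds",
    "train",
    "predict_volume",
    "CTSegmenter",
    "save_segmenter",
    "load_segmenter",
]


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite during training."""


@dataclass
class TrainConfig:
    """Hyperparameters of one training run.

    Batch size defaults to 28 for 2D networks and 1 (pure SGD) for 3D.
    An epoch is a fixed number of sampled batches (sampling is with
    replacement, so there is no natural pass over the data).
    """

    epochs: int = 5
    batches_per_epoch: int = 20
    batch_size: int | None = None
    learning_rate: float = 1e-3
    loss: LossConfig = field(default_factory=LossConfig)
    augment_policy: AugmentPolicy = field(default_factory=AugmentPolicy.disabled)
    seed: int = 0

    def resolved_batch_size(self, dims: int) -> int:
        if self.batch_size is not None:
            if self.batch_size < 1:
                raise ValueError("batch_size must be >= 1")
            return self.batch_size
        return 28 if dims == 2 else 1


@dataclass
class FoldAssignment:
    """Case-to-fold mapping from the slice-count-sorted contiguous split."""

    mapping: dict[str, int]
    k: int
    ordering: list[str]

    def fold_of(self, identifier: str) -> int:
        return self.mapping[identifier]

    def members(self, fold: int) -> list[str]:
        return [cid for cid in self.ordering if self.mapping[cid] == fold]


def _sort_key(case) -> tuple:
    if hasattr(case, "slice_count"):
        return (case.slice_count, case.slice_thickness, case.identifier)
    return (case.image.shape[0], case.image.spacing[0], case.identifier)


def assign_folds(cases, k: int = 5) -> FoldAssignment:
    """Sort by (slice count, slice thickness, identifier), chunk into k folds.

    Fold sizes differ by at most one; fold j holds the j-th contiguous block
    of the sorted sequence, so fold 0 gets the shortest volumes and fold
    k-1 the longest.
    """
    cases = list(cases)
    if len(cases) < k:
        raise ValueError(f"cohort of {len(cases)} cases cannot fill {k} folds")
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = sorted(cases, key=_sort_key)
    ids = [getattr(c, "identifier") for c in ordered]
    n = len(ids)
    base, extra = divmod(n, k)
    mapping: dict[str, int] = {}
    start = 0
    for j in range(k):
        size = base + (1 if j < extra else 0)
        for cid in ids[start : start + size]:
            mapping[cid] = j
        start += size
    return FoldAssignment(mapping=mapping, k=k, ordering=ids)


def _one_hot(labels: np.ndarray, num_classes: int) -> np.ndarray:
    """Class-first one-hot encoding of an integer label array."""
    out = np.zeros((num_classes,) + labels.shape)
    for c in range(num_classes):
        out[c] = labels == c
    return out


def _make_batch(
    stacks: list[SliceStack], dims: int, batch_size: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble (x, labels): 2D batches are single slices, 3D batches stacks."""
    if dims == 3:
        x = np.stack([s.slices for s in stacks])[:, None]
        y = np.stack([s.label_slices for s in stacks])
        return x, y
    all_slices = np.concatenate([s.slices for s in stacks])
    all_labels = np.concatenate([s.label_slices for s in stacks])
    idx = rng.choice(all_slices.shape[0], size=min(batch_size, all_slices.shape[0]), replace=False)
    return all_slices[idx][:, None], all_labels[idx]


def train(
    model: SegmentationNet,
    cases: list[Case],
    preprocessor: CTPreprocessor,
    config: TrainConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Run the training loop; returns the per-epoch loss history.

    The preprocessor must already be fitted.  Raises
    :class:`TrainingDivergedError` (with the offending batch identifiers and
    loss components) if the loss leaves the finite range.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    dims = model.spec.dims
    num_classes = model.spec.num_classes
    batch_size = config.resolved_batch_size(dims)
    opt = Adam(model.params(), lr=config.learning_rate)
    records = []
    n_volumes = 1 if dims == 3 else max(1, -(-batch_size // preprocessor.n_slices))
    for epoch in range(config.epochs):
        losses = []
        for _ in range(config.batches_per_epoch):
            pick = rng.choice(len(cases), size=min(n_volumes, len(cases)), replace=False)
            batch_cases = [cases[i] for i in pick]
            stacks = preprocessor.transform(batch_cases, rng=rng)
            stacks = augment_batch(
                stacks, config.augment_policy, rng, norm_stats=preprocessor.norm_stats_
            )
            x, labels = _make_batch(stacks, dims, batch_size, rng)
            probs = model.predict_proba(x)
            pred_cf = np.moveaxis(probs, 1, 0)
            truth_cf = _one_hot(labels, num_classes)
            loss = combined_loss(pred_cf, truth_cf, config.loss)
            if not np.isfinite(loss):
                ids = [c.identifier for c in batch_cases]
                raise TrainingDivergedError(f"non-finite loss {loss} on batch {ids}")
            dprobs = np.moveaxis(combined_loss_grad(pred_cf, truth_cf, config.loss), 0, 1)
            opt.zero_grad()
            model.backward(softmax_backward(probs, dprobs, axis=1))
            opt.step()
            losses.append(loss)
        records.append({"epoch": epoch, "mean_loss": float(np.mean(losses)),
                        "final_loss": float(losses[-1])})
    return pd.DataFrame.from_records(records)


def _resize_plane(volume: np.ndarray, target: int) -> np.ndarray:
    if volume.shape[1] == target and volume.shape[2] == target:
        return np.asarray(volume, dtype=np.float64)
    return np.stack([resize_local_mean(s, (target, target), preserve_range=True) for s in volume])


def predict_volume(
    model: SegmentationNet,
    case: Case,
    preprocessor: CTPreprocessor,
    slab_size: int | None = None,
    chunk: int = 16,
) -> tuple[np.ndarray, LabelVolume]:
    """Window + normalise a full volume and predict every voxel.

    No slice sampling and no augmentation at test time.  2D models run per
    slice; 3D models run on overlapping slabs (50% overlap) whose
    probabilities are averaged.  Returns the class-first probability map at
    the model's working resolution and the argmax label volume upsampled
    (nearest-neighbour) back to the native in-plane size.
    """
    vol = preprocessor.transform_volume(case)
    target = preprocessor.target_size
    data = _resize_plane(vol.data, target)
    S = data.shape[0]
    C = model.spec.num_classes
    if model.spec.dims == 2:
        probs = np.empty((S, C, target, target))
        for start in range(0, S, chunk):
            sl = slice(start, min(start + chunk, S))
            probs[sl] = model.predict_proba(data[sl][:, None])
        probmap = np.moveaxis(probs, 1, 0)
    else:
        L = min(slab_size or preprocessor.n_slices, S)
        step = max(1, L // 2)
        starts = sorted({min(s, S - L) for s in range(0, S - L + step, step)} | {S - L})
        acc = np.zeros((C, S, target, target))
        cnt = np.zeros(S)
        for s0 in starts:
            slab = data[s0 : s0 + L]
            p = model.predict_proba(slab[None, None])[0]
            acc[:, s0 : s0 + L] += p
            cnt[s0 : s0 + L] += 1
        probmap = acc / cnt[None, :, None, None]
    labels_small = np.argmax(probmap, axis=0)
    native = case.image.shape
    if native[1:] == (target, target):
        labels_native = labels_small
    else:
        labels_native = np.stack(
            [
                resize(
                    s.astype(np.float64), native[1:], order=0, preserve_range=True,
                    anti_aliasing=False,
                ).astype(np.int64)
                for s in labels_small
            ]
        )
    names = {c: f"class_{c}" for c in range(C)}
    names[0] = "background"
    return probmap, LabelVolume(data=labels_native.astype(np.int64), class_names=names)


class CTSegmenter(BaseEstimator):
    """End-to-end CT segmentation estimator (scikit-learn style).

    ``fit`` takes a list of labelled :class:`~ctseg.io.Case` objects,
    fits the preprocessor (windowing + normalisation statistics) and trains
    the configured backbone; ``predict`` maps cases to label volumes.

    Parameters
    ----------
    family : {"unet", "msd"}
        Backbone architecture.
    dims : {2, 3}
        Run slice-wise 2D or slab-wise 3D.
    num_classes : int
        Voxel classes including background.
    depth_or_layers, base_width : int or None
        Backbone size; None picks the family default.
    n_slices, target_size : int
        Preprocessing shape contract (slices sampled per volume; in-plane
        side after downsampling).
    lower_percentile, upper_percentile : float
        Intensity windowing quantiles.
    augment : "ctia", "none", or AugmentPolicy
        Training-time augmentation regime.
    epochs, batches_per_epoch, batch_size, learning_rate : training loop
        hyperparameters (batch_size None = 28 for 2D / 1 for 3D).
    alpha, beta, smooth : compound-loss configuration.
    random_state : int
        Seed for model init, preprocessing and training stochasticity.
    """

    def __init__(
        self,
        family: str = "unet",
        dims: int = 2,
        num_classes: int = 3,
        depth_or_layers: int | None = None,
        base_width: int | None = None,
        n_slices: int = 16,
        target_size: int = 128,
        lower_percentile: float = 0.6,
        upper_percentile: float = 0.99,
        augment: object = "ctia",
        epochs: int = 5,
        batches_per_epoch: int = 20,
        batch_size: int | None = None,
        learning_rate: float = 1e-3,
        alpha: float = 0.6,
        beta: float = 0.4,
        smooth: float = 1e-5,
        random_state: int = 0,
    ):
        self.family = family
        self.dims = dims
        self.num_classes = num_classes
        self.depth_or_layers = depth_or_layers
        self.base_width = base_width
        self.n_slices = n_slices
        self.target_size = target_size
        self.lower_percentile = lower_percentile
        self.upper_percentile = upper_percentile
        self.augment = augment
        self.epochs = epochs
        self.batches_per_epoch = batches_per_epoch
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.alpha = alpha
        self.beta = beta
        self.smooth = smooth
        self.random_state = random_state

    def _policy(self) -> AugmentPolicy:
        if isinstance(self.augment, AugmentPolicy):
            return self.augment
        if self.augment == "ctia":
            return AugmentPolicy.for_dims(self.dims)
        if self.augment == "none":
            return AugmentPolicy.disabled()
        raise ValueError(f"augment must be 'ctia', 'none' or an AugmentPolicy, got {self.augment!r}")

    def fit(self, X: list[Case], y=None) -> "CTSegmenter":
        cases = [c.as_case() if hasattr(c, "as_case") else c for c in X]
        if not cases:
            raise ValueError("cannot fit on an empty cohort")
        self.preprocessor_ = CTPreprocessor(
            lower_percentile=self.lower_percentile,
            upper_percentile=self.upper_percentile,
            n_slices=self.n_slices,
            target_size=self.target_size,
            random_state=self.random_state,
        ).fit(cases)
        spec = ModelSpec(
            family=self.family,
            dims=self.dims,
            num_classes=self.num_classes,
            depth_or_layers=self.depth_or_layers,
            base_width=self.base_width,
            seed=self.random_state,
        )
        self.model_ = build_model(spec)
        config = TrainConfig(
            epochs=self.epochs,
            batches_per_epoch=self.batches_per_epoch,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            loss=LossConfig(alpha=self.alpha, beta=self.beta, smooth=self.smooth),
            augment_policy=self._policy(),
            seed=self.random_state,
        )
        rng = np.random.default_rng(self.random_state + 10_000)
        self.history_ = train(self.model_, cases, self.preprocessor_, config, rng)
        return self

    def predict(self, X: list[Case]) -> list[LabelVolume]:
        return [self._predict_one(c)[1] for c in X]

    def predict_proba(self, X: list[Case]) -> list[np.ndarray]:
        return [self._predict_one(c)[0] for c in X]

    def _predict_one(self, case) -> tuple[np.ndarray, LabelVolume]:
        if not hasattr(self, "model_"):
            raise RuntimeError("CTSegmenter must be fitted before predicting")
        case = case.as_case() if hasattr(case, "as_case") else case
        return predict_volume(self.model_, case, self.preprocessor_)

    def score(self, X: list[Case], y=None) -> float:
        """Mean foreground-class-averaged Dice over the given labelled cases."""
        scores = []
        for case in X:
            c = case.as_case() if hasattr(case, "as_case") else case
            if c.labels is None:
                raise ValueError("score requires labelled cases")
            _, pred = self._predict_one(c)
            per_class = [
                dice_score(pred, c.labels, cls) for cls in range(1, self.num_classes)
            ]
            scores.append(float(np.mean(per_class)))
        return float(np.mean(scores))


def save_segmenter(est: CTSegmenter, prefix) -> None:
    """Persist a fitted segmenter as <prefix>.npz (weights) + <prefix>.json.

    The JSON sidecar embeds the estimator configuration, the window bounds
    and the normalisation statistics, so inference is self-contained.
    """
    import json
    from pathlib import Path

    if not hasattr(est, "model_"):
        raise RuntimeError("only fitted segmenters can be saved")
    prefix = Path(prefix)
    state = est.model_.get_state()
    np.savez(str(prefix) + ".npz", **{f"param_{i}": v for i, v in enumerate(state)})
    params = est.get_params()
    if isinstance(params.get("augment"), AugmentPolicy):
        params["augment"] = "ctia"  # policies are not JSON; regime name suffices
    meta = {
        "params": params,
        "norm_stats": {
            "mean": est.preprocessor_.norm_stats_.mean,
            "std": est.preprocessor_.norm_stats_.std,
            "n_cases_used": est.preprocessor_.norm_stats_.n_cases_used,
        },
        "bounds": est.preprocessor_.bounds_,
        "n_params": est.model_.num_params(),
    }
    with open(str(prefix) + ".json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_segmenter(prefix) -> CTSegmenter:
    """Rebuild a fitted segmenter from :func:`save_segmenter` output."""
    import json

    from .models import ModelSpec, build_model
    from .preprocess import NormStats

    with open(str(prefix) + ".json") as fh:
        meta = json.load(fh)
    est = CTSegmenter(**meta["params"])
    pre = CTPreprocessor(
        lower_percentile=est.lower_percentile,
        upper_percentile=est.upper_percentile,
        n_slices=est.n_slices,
        target_size=est.target_size,
        random_state=est.random_state,
    )
    ns = meta["norm_stats"]
    pre.norm_stats_ = NormStats(mean=ns["mean"], std=ns["std"], n_cases_used=ns["n_cases_used"])
    pre.bounds_ = tuple(meta["bounds"]) if meta["bounds"] else None
    pre._rng = np.random.default_rng(est.random_state + 1)
    est.preprocessor_ = pre
    spec = ModelSpec(
        family=est.family, dims=est.dims, num_classes=est.num_classes,
        depth_or_layers=est.depth_or_layers, base_width=est.base_width, seed=est.random_state,
    )
    est.model_ = build_model(spec)
    data = np.load(str(prefix) + ".npz")
    est.model_.set_state([data[f"param_{i}"] for i in range(len(data.files))])
    return est


def overfit_single_batch(
    spec: ModelSpec,
    stack: SliceStack,
    steps: int = 500,
    learning_rate: float = 1e-3,
    loss_config: LossConfig | None = None,
    stop_below: float | None = None,
) -> list[float]:
    """Diagnostic: repeatedly fit one fixed batch; returns the loss trace.

    Exercises the loss/gradient/optimiser/backbone plumbing end to end — a
    healthy configuration drives the combined loss toward zero on a single
    memorisable batch.  2D specs treat the stack's slices as the batch; 3D
    specs treat the whole stack as one volume.
    """
    loss_config = loss_config or LossConfig()
    model = build_model(spec)
    if spec.dims == 2:
        x = stack.slices[:, None]
        labels = stack.label_slices
    else:
        x = stack.slices[None, None]
        labels = stack.label_slices[None]
    truth = _one_hot(labels, spec.num_classes)
    opt = Adam(model.params(), lr=learning_rate)
    trace = []
    for _ in range(steps):
        probs = model.predict_proba(x)
        pred_cf = np.moveaxis(probs, 1, 0)
        loss = combined_loss(pred_cf, truth, loss_config)
        trace.append(float(loss))
        if stop_below is not None and loss < stop_below:
            break
        dprobs = np.moveaxis(combined_loss_grad(pred_cf, truth, loss_config), 0, 1)
        opt.zero_grad()
        model.backward(softmax_backward(probs, dprobs, axis=1))
        opt.step()
    return trace
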