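"""Top-k model selection, stacked-CNN fusion, and the robustness grid.

The stacked ensemble combines two specialist sets: 3D mixed-scale dense
nets trained for binary organ-vs-background localisation, and 2D U-Nets
trained for full multi-class tissue classification.  Member probability
maps are averaged within each set; a combiner then fuses the binary
foreground probability B with the multi-class map M:

* ``mask_gate`` (default, no extra training): the binary set can veto
  foreground — final background probability is max(M_bg, 1 - B); the
  remaining mass is split across foreground classes proportional to M.
* ``prob_product``: class-wise product fusion (background M_bg * (1-B),
  foreground M_c * B), renormalised.
* ``meta_learner``: a per-voxel multinomial logistic regression fitted on
  held-out cases learns the fusion weights.

``run_experiment_grid`` trains every (augmentation regime, architecture,
fold) combination with slice-count-sorted cross-validation and reports
volume-wise Dice mean +/- std per class — the robustness protocol used to
compare augmentation regimes on intensity-shifted test cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.transform import resize
from sklearn.linear_model import LogisticRegression

from .io import Case, LabelVolume
from .metrics import aggregate_dice, dice_score, DiceReport
from .training import CTSegmenter

__all__ = [
    "EnsembleSpec",
    "select_top_k",
    "stacked_predict",
    "fit_meta_learner",
    "run_experiment_grid",
    "RobustnessResult",
]


@dataclass
class EnsembleSpec:
    """Member sets and fusion rule of the stacked model.

    ``binary_members`` predict (background, foreground); ``multiclass_members``
    predict the full class set.  All members must share the working
    resolution (same ``target_size``).
    """

    binary_members: list[CTSegmenter]
    multiclass_members: list[CTSegmenter]
    k: int = 5
    combiner: str = "mask_gate"
    meta_model: LogisticRegression | None = None

    def __post_init__(self) -> None:
        if not self.binary_members or not self.multiclass_members:
            raise ValueError("both member sets must be non-empty")
        if self.combiner not in ("mask_gate", "prob_product", "meta_learner"):
            raise ValueError(f"unknown combiner {self.combiner!r}")
        for group in (self.binary_members, self.multiclass_members):
            classes = {m.num_classes for m in group}
            if len(classes) != 1:
                raise ValueError("members of one set must share the class convention")


def select_top_k(candidates: list[tuple[object, float]], k: int) -> list[object]:
    """The k models with the highest validation score.

    Ties are broken by input order (earlier training-completion first), so
    the selection is deterministic.
    """
    if len(candidates) < k:
        raise ValueError(f"need at least {k} candidates, got {len(candidates)}")
    order = sorted(range(len(candidates)), key=lambda i: (-candidates[i][1], i))
    return [candidates[i][0] for i in order[:k]]


def _mean_probs(members: list[CTSegmenter], case: Case) -> np.ndarray:
    maps = [m.predict_proba([case])[0] for m in members]
    shapes = {p.shape for p in maps}
    if len(shapes) != 1:
        raise RuntimeError(f"member outputs disagree on working resolution: {shapes}")
    return np.mean(maps, axis=0)


def _fuse(binary: np.ndarray, multi: np.ndarray, combiner: str,
          meta_model: LogisticRegression | None) -> np.ndarray:
    b_fg = binary[1]
    m_bg, m_fg = multi[0], multi[1:]
    if combiner == "mask_gate":
        bg = np.maximum(m_bg, 1.0 - b_fg)
        fg_mass = 1.0 - bg
        denom = m_fg.sum(axis=0)
        share = np.where(denom > 0, m_fg / np.where(denom > 0, denom, 1.0), 1.0 / m_fg.shape[0])
        fused = np.concatenate([bg[None], share * fg_mass[None]], axis=0)
    elif combiner == "prob_product":
        parts = np.concatenate([(m_bg * (1.0 - b_fg))[None], m_fg * b_fg[None]], axis=0)
        total = parts.sum(axis=0)
        fused = np.where(total > 0, parts / np.where(total > 0, total, 1.0), 0.0)
        fused[0] = np.where(total > 0, fused[0], 1.0)  # no evidence -> background
    else:
        if meta_model is None:
            raise ValueError("meta_learner combiner requires a fitted meta_model")
        feats = np.concatenate([b_fg[None], multi], axis=0)
        flat = feats.reshape(feats.shape[0], -1).T
        probs = meta_model.predict_proba(flat).T
        fused = probs.reshape((multi.shape[0],) + b_fg.shape)
    return fused / fused.sum(axis=0, keepdims=True)


def stacked_predict(spec: EnsembleSpec, case: Case) -> tuple[np.ndarray, LabelVolume]:
    """Fuse member predictions into one probability map + label volume."""
    case = case.as_case() if hasattr(case, "as_case") else case
    binary = _mean_probs(spec.binary_members, case)
    multi = _mean_probs(spec.multiclass_members, case)
    fused = _fuse(binary, multi, spec.combiner, spec.meta_model)
    labels_small = np.argmax(fused, axis=0)
    native = case.image.shape
    if labels_small.shape[1:] == native[1:]:
        labels = labels_small
    else:
        labels = np.stack(
            [
                resize(s.astype(np.float64), native[1:], order=0, preserve_range=True,
                       anti_aliasing=False).astype(np.int64)
                for s in labels_small
            ]
        )
    C = fused.shape[0]
    names = {c: f"class_{c}" for c in range(C)}
    names[0] = "background"
    return fused, LabelVolume(data=labels.astype(np.int64), class_names=names)


def fit_meta_learner(
    binary_members: list[CTSegmenter],
    multiclass_members: list[CTSegmenter],
    validation_cases: list[Case],
    seed: int = 0,
    max_voxels: int = 50_000,
) -> LogisticRegression:
    """Fit the per-voxel fusion model on held-out labelled cases.

    Features are (binary foreground probability, multi-class probabilities);
    targets are the true voxel classes at the working resolution.  Voxels
    are subsampled for tractability.
    """
    rng = np.random.default_rng(seed)
    feats, targets = [], []
    pre = multiclass_members[0].preprocessor_
    target = pre.target_size
    for case in validation_cases:
        c = case.as_case() if hasattr(case, "as_case") else case
        if c.labels is None:
            raise ValueError("meta-learner fitting needs labelled cases")
        b = _mean_probs(binary_members, c)
        m = _mean_probs(multiclass_members, c)
        lab = np.stack(
            [
                resize(s.astype(np.float64), (target, target), order=0, preserve_range=True,
                       anti_aliasing=False)
                for s in c.labels.data
            ]
        ).astype(np.int64)
        f = np.concatenate([b[1][None], m], axis=0).reshape(m.shape[0] + 1, -1).T
        feats.append(f)
        targets.append(lab.ravel())
    X = np.concatenate(feats)
    y = np.concatenate(targets)
    if X.shape[0] > max_voxels:
        idx = rng.choice(X.shape[0], size=max_voxels, replace=False)
        X, y = X[idx], y[idx]
    model = LogisticRegression(max_iter=200)
    model.fit(X, y)
    return model


@dataclass
class RobustnessResult:
    """Aggregated robustness table plus the raw per-volume scores."""

    table: pd.DataFrame
    raw: pd.DataFrame
    reports: dict[tuple[str, str], DiceReport] = field(default_factory=dict)
    failures: list[dict] = field(default_factory=list)


def run_experiment_grid(
    cohort,
    regimes: dict[str, object],
    estimators: dict[str, dict],
    folds,
    estimator_defaults: dict | None = None,
    test_transform=None,
    seed: int = 0,
) -> RobustnessResult:
    """Cross-validated regime x architecture comparison.

    For every (regime, architecture, fold): train on the out-of-fold cases,
    predict the in-fold cases (optionally passed through ``test_transform``,
    e.g. an intensity shift), score volume-wise Dice per foreground class,
    then aggregate mean +/- std per regime x architecture x class.  A failed
    training run marks its rows failed and the grid continues.

    ``regimes`` maps regime name to an ``augment`` value accepted by
    :class:`CTSegmenter`; ``estimators`` maps architecture name to
    constructor overrides.
    """
    defaults = dict(estimator_defaults or {})
    by_id = {c.identifier: c for c in cohort}
    rows, failures = [], []
    for ri, (regime_name, policy) in enumerate(regimes.items()):
        for si, (arch_name, overrides) in enumerate(estimators.items()):
            for fold in range(folds.k):
                test_ids = folds.members(fold)
                train_cases = [by_id[i] for i in folds.ordering if i not in set(test_ids)]
                test_cases = [by_id[i] for i in test_ids]
                if test_transform is not None:
                    test_cases = test_transform(test_cases)
                params = {**defaults, **overrides}
                params["augment"] = policy
                params["random_state"] = seed + 1009 * ri + 101 * si + fold
                est = CTSegmenter(**params)
                try:
                    est.fit(train_cases)
                    for case in test_cases:
                        c = case.as_case() if hasattr(case, "as_case") else case
                        _, pred = est._predict_one(c)
                        for cls in range(1, est.num_classes):
                            rows.append(
                                {
                                    "regime": regime_name,
                                    "architecture": arch_name,
                                    "fold": fold,
                                    "volume": c.identifier,
                                    "class": cls,
                                    "score": dice_score(pred, c.labels, cls),
                                }
                            )
                except Exception as exc:  # noqa: BLE001 - grid must survive a bad cell
                    failures.append(
                        {"regime": regime_name, "architecture": arch_name, "fold": fold,
                         "error": repr(exc)}
                    )
    raw = pd.DataFrame.from_records(rows)
    agg_rows = []
    reports: dict[tuple[str, str], DiceReport] = {}
    if len(raw):
        for (regime_name, arch_name), grp in raw.groupby(["regime", "architecture"], sort=True):
            report = aggregate_dice(grp[["fold", "volume", "class", "score"]])
            reports[(regime_name, arch_name)] = report
            pooled_by_vol = grp.groupby(["fold", "volume"])["score"].mean()
            for cls, r in report.pooled.iterrows():
                agg_rows.append(
                    {"regime": regime_name, "architecture": arch_name, "class": cls,
                     "mean_dice": float(r["mean"]), "std_dice": float(r["std"]),
                     "n_volumes": int(pooled_by_vol.size), "failed": False}
                )
    for f in failures:
        agg_rows.append(
            {"regime": f["regime"], "architecture": f["architecture"], "class": "total",
             "mean_dice": np.nan, "std_dice": np.nan, "n_volumes": 0, "failed": True}
        )
    return RobustnessResult(
        table=pd.DataFrame.from_records(agg_rows), raw=raw, reports=reports, failures=failures
    )


def ctia_robustness_experiment(
    seed: int = 0,
    n_cases: int = 20,
    k: int = 2,
    shift_hu: float = 40.0,
    scale: float = 1.05,
    estimator_params: dict | None = None,
    phantom_config=None,
) -> RobustnessResult:
    """Scaled-down CTIA vs no-augmentation robustness protocol.

    Trains the same small 2D U-Net under the CT-specific augmentation
    regime and without augmentation, in slice-count-sorted k-fold
    cross-validation on a synthetic cohort, and evaluates each fold's model
    on intensity-shifted versions of its held-out cases (a global
    ``v -> scale * v + shift_hu`` map emulating vendor/patient intensity
    variation).  The quantity of interest is the standard deviation of
    volume-wise Dice: augmentation that anticipates intensity shifts should
    stabilise it.
    """
    from .phantom import PhantomConfig, generate_cohort, perturb_cohort
    from .training import assign_folds

    if phantom_config is None:
        phantom_config = PhantomConfig(
            in_plane_size=32,
            slice_count_range=(10, 28),
            organ_radius_range=(5.0, 9.0),
            tumour_radius_range=(2.0, 4.0),
            noise_sigma=3.0,
        )
    params = {
        "family": "unet",
        "dims": 2,
        "depth_or_layers": 2,
        "base_width": 8,
        "n_slices": 8,
        "target_size": 32,
        "epochs": 4,
        "batches_per_epoch": 30,
        "batch_size": 8,
    }
    params.update(estimator_params or {})
    cohort = generate_cohort(n_cases, phantom_config, seed)
    folds = assign_folds(cohort, k)
    return run_experiment_grid(
        cohort,
        regimes={"ctia": "ctia", "none": "none"},
        estimators={"unet2d": params},
        folds=folds,
        test_transform=lambda cases: perturb_cohort(cases, shift_hu, scale, seed),
        seed=seed,
    )
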