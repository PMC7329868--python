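"""CT preprocessing: percentile windowing, z-score normalisation, foreground
slice sampling to a fixed count, and in-plane downsampling.

The chain maps an arbitrary CT case to a fixed-shape ``(n_slices, size, size)``
slice stack — the shape contract every model in the package consumes.  The
default configuration clips each volume to its (0.6, 0.99) intensity
percentiles, normalises with pooled statistics from a random cohort subset,
samples 16 foreground slices and downsamples each slice to 128x128.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize, resize_local_mean
from sklearn.base import BaseEstimator, TransformerMixin

from .io import Case, CTVolume

__all__ = [
    "WindowSpec",
    "NormStats",
    "SliceStack",
    "compute_window_bounds",
    "apply_window",
    "znormalize",
    "compute_norm_stats",
    "sample_slices",
    "downsample_stack",
    "preprocess_case",
    "CTPreprocessor",
]


@dataclass(frozen=True)
class WindowSpec:
    """Percentile window: clip intensities to the [lower, upper] quantiles.

    ``scope`` selects whether the quantiles come from each volume
    individually (default, matching per-volume clinical windowing) or are
    pooled over a cohort.
    """

    lower_percentile: float = 0.6
    upper_percentile: float = 0.99
    scope: str = "per_volume"

    def __post_init__(self) -> None:
        if not 0.0 <= self.lower_percentile < self.upper_percentile <= 1.0:
            raise ValueError(
                f"need 0 <= lower < upper <= 1, got ({self.lower_percentile}, {self.upper_percentile})"
            )
        if self.scope not in ("per_volume", "cohort"):
            raise ValueError(f"unknown scope {self.scope!r}")


@dataclass(frozen=True)
class NormStats:
    """Pooled mean/std of windowed intensities used for z-scoring."""

    mean: float
    std: float
    n_cases_used: int = 0

    def __post_init__(self) -> None:
        if self.std <= 0:
            raise ValueError(f"std must be > 0, got {self.std}")


@dataclass
class SliceStack:
    """A fixed-count stack of 2D slices with aligned labels.

    ``source_indices`` records where each slice came from in the source
    volume (sorted ascending; fractional after slice interpolation).
    """

    slices: np.ndarray
    label_slices: np.ndarray | None = None
    source_indices: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices, dtype=np.float64)
        if self.slices.ndim != 3:
            raise ValueError(f"expected (n, H, W) slices, got shape {self.slices.shape}")
        if self.label_slices is not None:
            self.label_slices = np.asarray(self.label_slices)
            if self.label_slices.shape != self.slices.shape:
                raise ValueError("label_slices shape must match slices")
        self.source_indices = np.asarray(self.source_indices, dtype=np.float64)
        if self.source_indices.size == 0:
            self.source_indices = np.arange(self.slices.shape[0], dtype=np.float64)

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    def copy(self) -> "SliceStack":
        return SliceStack(
            slices=self.slices.copy(),
            label_slices=None if self.label_slices is None else self.label_slices.copy(),
            source_indices=self.source_indices.copy(),
        )


def compute_window_bounds(values, spec: WindowSpec) -> tuple[float, float]:
    """Quantile window bounds (linear-interpolation quantile definition)."""
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise ValueError("cannot compute window bounds of an empty collection")
    lower, upper = np.quantile(
        values, [spec.lower_percentile, spec.upper_percentile], method="linear"
    )
    return float(lower), float(upper)


def apply_window(volume: CTVolume, bounds: tuple[float, float]) -> CTVolume:
    """Clip voxel intensities to [lower, upper]; idempotent."""
    lower, upper = bounds
    if lower > upper:
        raise ValueError(f"lower bound {lower} exceeds upper bound {upper}")
    return volume.with_data(np.clip(volume.data.astype(np.float64), lower, upper))


def znormalize(volume: CTVolume, stats: NormStats) -> CTVolume:
    """Voxel-wise (v - mean) / std; the result leaves the HU scale."""
    if stats.std <= 0:
        raise ValueError("std must be > 0")
    data = (volume.data.astype(np.float64) - stats.mean) / stats.std
    return volume.with_data(data, unit="zscore")


def compute_norm_stats(cohort_subset: list[CTVolume], seed: int = 0) -> NormStats:
    """Pooled mean/std over all voxels of a (windowed) volume subset."""
    if len(cohort_subset) == 0:
        raise ValueError("need at least one volume to compute normalisation stats")
    n = 0
    s = 0.0
    ss = 0.0
    for vol in cohort_subset:
        flat = vol.data.astype(np.float64).ravel()
        n += flat.size
        s += flat.sum()
        ss += np.square(flat).sum()
    mean = s / n
    var = max(ss / n - mean * mean, 0.0)
    std = float(np.sqrt(var))
    if std <= 0:
        raise ValueError("degenerate statistics: windowed subset has zero variance")
    return NormStats(mean=float(mean), std=std, n_cases_used=len(cohort_subset))


def sample_slices(
    case: Case, n: int, exclude_background: bool = True, rng: np.random.Generator | None = None
) -> SliceStack:
    """Draw ``n`` slices at random positions from a volume.

    When ``exclude_background`` is set, only slices containing at least one
    foreground voxel are candidates (background slices carry no training
    signal and are not scored at test time).  Candidates are drawn without
    replacement when possible, with replacement when the volume is shorter
    than ``n``; repeating the sampling per epoch gives a simultaneous
    augmentation effect.  Returned slices are sorted by source index.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n < 1:
        raise ValueError("n must be >= 1")
    image = case.image.data
    if exclude_background:
        if case.labels is None:
            raise ValueError("exclude_background requires labels")
        fg = np.flatnonzero((case.labels.data > 0).any(axis=(1, 2)))
        if fg.size == 0:
            raise ValueError(f"case {case.identifier!r} has no foreground slices to sample")
        candidates = fg
    else:
        candidates = np.arange(image.shape[0])
    replace = candidates.size < n
    chosen = np.sort(rng.choice(candidates, size=n, replace=replace))
    labels = None if case.labels is None else case.labels.data[chosen]
    return SliceStack(
        slices=image[chosen].astype(np.float64),
        label_slices=labels,
        source_indices=chosen.astype(np.float64),
    )


def downsample_stack(stack: SliceStack, target: int) -> SliceStack:
    """Resize every slice to target x target.

    Intensities use local-mean (area) interpolation; labels use
    nearest-neighbour so no new label values can appear.
    """
    if target < 8:
        raise ValueError("target side length must be >= 8")
    n, h, w = stack.slices.shape
    if h != w:
        raise ValueError(f"slices must be square, got {h}x{w}")
    if target == h:
        return stack.copy()
    slices = np.stack(
        [resize_local_mean(s, (target, target), preserve_range=True) for s in stack.slices]
    )
    labels = None
    if stack.label_slices is not None:
        labels = np.stack(
            [
                resize(
                    s.astype(np.float64),
                    (target, target),
                    order=0,
                    preserve_range=True,
                    anti_aliasing=False,
                ).astype(stack.label_slices.dtype)
                for s in stack.label_slices
            ]
        )
    return SliceStack(slices=slices, label_slices=labels, source_indices=stack.source_indices.copy())


def preprocess_case(
    case: Case,
    window: WindowSpec = WindowSpec(),
    stats: NormStats | None = None,
    n_slices: int = 16,
    target_size: int = 128,
    rng: np.random.Generator | None = None,
    bounds: tuple[float, float] | None = None,
    exclude_background: bool = True,
) -> SliceStack:
    """Full training-time chain: window -> z-normalise -> sample -> downsample.

    ``bounds`` must be supplied for cohort-scope windows (precomputed over
    the cohort); per-volume scope computes them from the case itself.
    ``stats=None`` skips normalisation (useful for inspecting windowed HU).
    """
    if bounds is None:
        if window.scope == "cohort":
            raise ValueError("cohort-scope windowing needs precomputed bounds")
        bounds = compute_window_bounds(case.image.data, window)
    volume = apply_window(case.image, bounds)
    if stats is not None:
        volume = znormalize(volume, stats)
    windowed = Case(image=volume, labels=case.labels, identifier=case.identifier)
    stack = sample_slices(windowed, n_slices, exclude_background=exclude_background, rng=rng)
    return downsample_stack(stack, target_size)


class CTPreprocessor(BaseEstimator, TransformerMixin):
    """Cohort-fitted preprocessing transformer (scikit-learn style).

    ``fit`` computes window bounds (when cohort-scoped) and pooled
    normalisation statistics from a random subset of at most
    ``subset_size`` windowed cases; ``transform`` maps each case to a
    fixed-shape :class:`SliceStack`.

    Parameters
    ----------
    lower_percentile, upper_percentile : float
        Windowing quantiles, default (0.6, 0.99).
    scope : str
        "per_volume" or "cohort" window bounds.
    n_slices : int
        Slices sampled per volume (default 16).
    target_size : int
        In-plane side length after downsampling (default 128).
    subset_size : int
        Maximum number of cases used for the normalisation statistics.
    exclude_background : bool
        Restrict slice sampling to slices with foreground labels.
    random_state : int
        Seed for subset selection and slice sampling.
    """

    def __init__(
        self,
        lower_percentile: float = 0.6,
        upper_percentile: float = 0.99,
        scope: str = "per_volume",
        n_slices: int = 16,
        target_size: int = 128,
        subset_size: int = 10,
        exclude_background: bool = True,
        random_state: int = 0,
    ):
        self.lower_percentile = lower_percentile
        self.upper_percentile = upper_percentile
        self.scope = scope
        self.n_slices = n_slices
        self.target_size = target_size
        self.subset_size = subset_size
        self.exclude_background = exclude_background
        self.random_state = random_state

    def _window_spec(self) -> WindowSpec:
        return WindowSpec(self.lower_percentile, self.upper_percentile, self.scope)

    def fit(self, X: list[Case], y=None) -> "CTPreprocessor":
        spec = self._window_spec()
        rng = np.random.default_rng(self.random_state)
        if len(X) == 0:
            raise ValueError("cannot fit on an empty cohort")
        self.bounds_ = None
        if spec.scope == "cohort":
            pooled = np.concatenate([c.image.data.ravel() for c in X])
            self.bounds_ = compute_window_bounds(pooled, spec)
        k = min(self.subset_size, len(X))
        subset_idx = rng.choice(len(X), size=k, replace=False)
        windowed = []
        for i in subset_idx:
            b = self.bounds_ or compute_window_bounds(X[i].image.data, spec)
            windowed.append(apply_window(X[i].image, b))
        self.norm_stats_ = compute_norm_stats(windowed)
        self._rng = np.random.default_rng(self.random_state + 1)
        return self

    def transform(self, X: list[Case], rng: np.random.Generator | None = None) -> list[SliceStack]:
        if not hasattr(self, "norm_stats_"):
            raise RuntimeError("CTPreprocessor must be fitted before transform")
        rng = rng if rng is not None else self._rng
        return [
            preprocess_case(
                case,
                window=self._window_spec(),
                stats=self.norm_stats_,
                n_slices=self.n_slices,
                target_size=self.target_size,
                rng=rng,
                bounds=self.bounds_,
                exclude_background=self.exclude_background,
            )
            for case in X
        ]

    def transform_volume(self, case: Case) -> CTVolume:
        """Test-time path: window + normalise the full volume, no sampling."""
        if not hasattr(self, "norm_stats_"):
            raise RuntimeError("CTPreprocessor must be fitted before transform")
        b = self.bounds_ or compute_window_bounds(case.image.data, self._window_spec())
        return znormalize(apply_window(case.image, b), self.norm_stats_)
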