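"""CT-specific image augmentation (CTIA).

Operators: cluster-wise voxel intensity range shift (CWVRS), slice skipping,
slice interpolation, Gaussian image noising, bounded random rotation (max
16 degrees by default) and random patch extraction.  The stochastic policy
gates augmentation per batch (80% of 3D batches, 90% of 2D batches) and
CWVRS per volume (20%).

Every operator preserves the image/label pairing (identical geometry applied
to both), never introduces label values absent from its input, and reduces
to the identity when its magnitude parameter is zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .preprocess import NormStats, SliceStack

__all__ = [
    "IntensityWindowTable",
    "AugmentPolicy",
    "DEFAULT_WINDOW_TABLE",
    "cwvrs",
    "slice_skip",
    "slice_interpolate",
    "gaussian_noise",
    "random_rotate",
    "random_patch",
    "augment_batch",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class IntensityWindowTable:
    """Ordered list of named (lower, upper) tissue intensity windows."""

    windows: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        for name, lower, upper in self.windows:
            if lower >= upper:
                raise ValueError(f"window {name!r} degenerate: ({lower}, {upper})")

    def rescaled(self, stats: NormStats) -> "IntensityWindowTable":
        """Express HU windows in z-score units after normalisation."""
        return IntensityWindowTable(
            tuple(
                (name, (lo - stats.mean) / stats.std, (hi - stats.mean) / stats.std)
                for name, lo, hi in self.windows
            )
        )

    @property
    def widths(self) -> list[float]:
        return [hi - lo for _, lo, hi in self.windows]


# Standard radiology presets for the three use cases (soft tissue/organ,
# lung, bone); applied on the HU scale before normalisation.
DEFAULT_WINDOW_TABLE = IntensityWindowTable(
    (
        ("soft_tissue", -150.0, 250.0),
        ("lung", -1000.0, -300.0),
        ("bone", 200.0, 2000.0),
    )
)


@dataclass
class AugmentPolicy:
    """Declarative description of which operators fire and how hard.

    Defaults follow the training protocol: augmentation on 90% of 2D
    batches / 80% of 3D batches, CWVRS on 20% of volumes, rotations up to
    16 degrees.
    """

    p_augment: float = 0.9
    p_cwvrs: float = 0.2
    max_rotation_deg: float = 16.0
    noise_sigma: float = 0.05
    skip_max_removed: int = 2
    interp_max_inserted: int = 2
    patch_size: int | None = None
    cwvrs_max_shift: float = 20.0
    cwvrs_max_scale_delta: float = 0.1
    window_table: IntensityWindowTable = field(default_factory=lambda: DEFAULT_WINDOW_TABLE)

    def __post_init__(self) -> None:
        for p in (self.p_augment, self.p_cwvrs):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.max_rotation_deg < 0:
            raise ValueError("max_rotation_deg must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @classmethod
    def disabled(cls) -> "AugmentPolicy":
        """A policy that never augments (the no-augmentation regime)."""
        return cls(p_augment=0.0)

    @classmethod
    def for_dims(cls, dims: int, **kwargs) -> "AugmentPolicy":
        kwargs.setdefault("p_augment", 0.8 if dims == 3 else 0.9)
        return cls(**kwargs)


def cwvrs(
    stack: SliceStack,
    table: IntensityWindowTable,
    max_shift_hu: float,
    max_scale_delta: float,
    rng: np.random.Generator,
) -> SliceStack:
    """Cluster-wise voxel intensity range shift.

    For each tissue window independently, draw a shift and a pair of bound
    perturbations (each at most ``max_scale_delta`` of the window width) and
    linearly remap voxels inside the original window onto the perturbed
    window.  Voxels outside every window are left bit-identical; labels are
    untouched.  Overlapping windows are applied in table order, each acting
    on the voxels still inside its original range in the running image.
    """
    out = stack.copy()
    img = out.slices
    for name, lo, hi in table.windows:
        width = hi - lo
        for _ in range(16):
            shift = rng.uniform(-max_shift_hu, max_shift_hu)
            d_lo = rng.uniform(-max_scale_delta, max_scale_delta) * width
            d_hi = rng.uniform(-max_scale_delta, max_scale_delta) * width
            new_lo = lo + shift + d_lo
            new_hi = hi + shift + d_hi
            if new_lo < new_hi:
                break
        else:
            log.debug("cwvrs: window %s stayed degenerate after retries, skipped", name)
            continue
        if new_lo == lo and new_hi == hi:
            continue  # exact identity; avoid a no-op remap's float round-off
        inside = (img >= lo) & (img <= hi)
        if inside.any():
            img[inside] = new_lo + (img[inside] - lo) * (new_hi - new_lo) / width
    return out


def _nonadjacent_interior_choice(
    n_slices: int, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Choose up to k pairwise non-adjacent interior slice indices."""
    pool = list(range(1, n_slices - 1))
    chosen: list[int] = []
    while pool and len(chosen) < k:
        i = int(rng.choice(pool))
        chosen.append(i)
        pool = [j for j in pool if abs(j - i) > 1]
    return np.asarray(sorted(chosen), dtype=np.int64)


def slice_skip(
    stack: SliceStack,
    max_removed: int,
    rng: np.random.Generator,
    pad_to: int | None = None,
) -> SliceStack:
    """Remove 1..max_removed random non-adjacent interior slices.

    Simulates a coarser effective slice spacing.  Image and label slices are
    removed jointly; surviving order is preserved.  With ``pad_to`` set the
    stack is re-padded to a fixed count by re-sampling survivors.  Stacks
    too short to skip from are returned unchanged (logged, not an error).
    """
    if max_removed <= 0:
        return stack.copy()
    n = stack.n_slices
    if n <= max_removed + 1 or n < 3:
        log.debug("slice_skip: stack of %d slices too short, skipped", n)
        return stack.copy()
    k = int(rng.integers(1, max_removed + 1))
    removed = _nonadjacent_interior_choice(n, k, rng)
    keep = np.setdiff1d(np.arange(n), removed)
    if pad_to is not None and keep.size < pad_to:
        extra = rng.choice(keep, size=pad_to - keep.size, replace=True)
        keep = np.sort(np.concatenate([keep, extra]))
    return SliceStack(
        slices=stack.slices[keep],
        label_slices=None if stack.label_slices is None else stack.label_slices[keep],
        source_indices=stack.source_indices[keep],
    )


def slice_interpolate(
    stack: SliceStack,
    max_inserted: int,
    rng: np.random.Generator,
    trim_to: int | None = None,
) -> SliceStack:
    """Insert 1..max_inserted interpolated slices between random adjacent pairs.

    The inserted intensity slice is the voxel-wise linear midpoint of its
    parents; the inserted label slice is a copy of one randomly chosen
    parent (labels stay integral).  Source indices become fractional for
    inserted slices.  With ``trim_to`` set, a random subset of slices is
    dropped afterwards to restore a fixed count (order preserved).
    """
    if max_inserted <= 0:
        return stack.copy()
    if stack.n_slices < 2:
        return stack.copy()
    k = int(rng.integers(1, max_inserted + 1))
    slices = list(stack.slices)
    labels = None if stack.label_slices is None else list(stack.label_slices)
    idx = list(stack.source_indices)
    for _ in range(k):
        j = int(rng.integers(0, len(slices) - 1))
        mid = 0.5 * (slices[j] + slices[j + 1])
        slices.insert(j + 1, mid)
        if labels is not None:
            parent = j if rng.random() < 0.5 else j + 1
            labels.insert(j + 1, labels[parent].copy())
        idx.insert(j + 1, 0.5 * (idx[j] + idx[j + 1]))
    out = SliceStack(
        slices=np.stack(slices),
        label_slices=None if labels is None else np.stack(labels),
        source_indices=np.asarray(idx),
    )
    if trim_to is not None and out.n_slices > trim_to:
        keep = np.sort(rng.choice(out.n_slices, size=trim_to, replace=False))
        out = SliceStack(
            slices=out.slices[keep],
            label_slices=None if out.label_slices is None else out.label_slices[keep],
            source_indices=out.source_indices[keep],
        )
    return out


def gaussian_noise(stack: SliceStack, sigma: float, rng: np.random.Generator) -> SliceStack:
    """Add an independent zero-mean normal noise map to intensities."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    out = stack.copy()
    if sigma > 0:
        out.slices = out.slices + sigma * rng.standard_normal(out.slices.shape)
    return out


def random_rotate(stack: SliceStack, max_deg: float, rng: np.random.Generator) -> SliceStack:
    """Rotate every slice in-plane by one shared random angle in [-max, +max].

    A patient rotates rigidly, so the angle is shared across slices of a
    volume.  Intensities are bilinear-interpolated, labels nearest-neighbour;
    regions rotated in from outside the frame take the stack's minimum
    intensity (the post-window lower bound) and label 0.
    """
    if max_deg < 0:
        raise ValueError("max_deg must be >= 0")
    if max_deg == 0:
        return stack.copy()
    theta = float(rng.uniform(-max_deg, max_deg))
    fill = float(stack.slices.min())
    slices = np.stack(
        [
            ndimage.rotate(s, theta, reshape=False, order=1, mode="constant", cval=fill)
            for s in stack.slices
        ]
    )
    labels = None
    if stack.label_slices is not None:
        labels = np.stack(
            [
                ndimage.rotate(
                    s.astype(np.float64), theta, reshape=False, order=0, mode="constant", cval=0
                ).astype(stack.label_slices.dtype)
                for s in stack.label_slices
            ]
        )
    return SliceStack(slices=slices, label_slices=labels, source_indices=stack.source_indices.copy())


def random_patch(stack: SliceStack, patch_size: int, rng: np.random.Generator) -> SliceStack:
    """Crop the same random patch_size x patch_size window from every slice."""
    n, h, w = stack.slices.shape
    if patch_size > min(h, w):
        raise ValueError(f"patch size {patch_size} exceeds slice side {min(h, w)}")
    r0 = int(rng.integers(0, h - patch_size + 1))
    c0 = int(rng.integers(0, w - patch_size + 1))
    sl = (slice(None), slice(r0, r0 + patch_size), slice(c0, c0 + patch_size))
    return SliceStack(
        slices=stack.slices[sl].copy(),
        label_slices=None if stack.label_slices is None else stack.label_slices[sl].copy(),
        source_indices=stack.source_indices.copy(),
    )


def augment_batch(
    batch: list[SliceStack],
    policy: AugmentPolicy,
    rng: np.random.Generator,
    norm_stats: NormStats | None = None,
) -> list[SliceStack]:
    """Apply the CTIA chain to a batch with probability ``p_augment``.

    Operator order: rotation -> patch -> slice skip/interpolate -> CWVRS ->
    noise (spatial before intensity).  CWVRS is gated per volume at
    ``p_cwvrs``; when ``norm_stats`` is given the HU window table and shift
    magnitude are expressed in z-score units first.  The realised decision
    sequence is a pure function of the rng state.
    """
    if rng.random() >= policy.p_augment:
        return [s.copy() for s in batch]
    table = policy.window_table
    max_shift = policy.cwvrs_max_shift
    if norm_stats is not None:
        table = table.rescaled(norm_stats)
        max_shift = max_shift / norm_stats.std
    out = []
    for stack in batch:
        n0 = stack.n_slices
        s = random_rotate(stack, policy.max_rotation_deg, rng)
        if policy.patch_size is not None:
            s = random_patch(s, policy.patch_size, rng)
        do_skip = policy.skip_max_removed > 0
        do_interp = policy.interp_max_inserted > 0
        if do_skip and do_interp:
            do_skip = rng.random() < 0.5
            do_interp = not do_skip
        if do_skip:
            s = slice_skip(s, policy.skip_max_removed, rng, pad_to=n0)
        elif do_interp:
            s = slice_interpolate(s, policy.interp_max_inserted, rng, trim_to=n0)
        if policy.p_cwvrs > 0 and rng.random() < policy.p_cwvrs:
            s = cwvrs(s, table, max_shift, policy.cwvrs_max_scale_delta, rng)
        s = gaussian_noise(s, policy.noise_sigma, rng)
        out.append(s)
    return out
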