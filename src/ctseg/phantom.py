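"""Synthetic HU-calibrated CT phantoms with voxel-wise ground truth.

The generator emulates the statistical structure a CT segmentation framework
has to cope with: an air background near -1000 HU, a soft-tissue body
ellipse, one organ ellipsoid, an optional tumour blob whose intensity
distribution overlaps the organ's, Gaussian acquisition noise, and — across
a cohort — widely varying slice counts and slice thicknesses.  Everything is
deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import HU_MAX, HU_MIN, Case, CTVolume, LabelVolume

__all__ = [
    "PhantomConfig",
    "PhantomCase",
    "PhantomSizingError",
    "generate_phantom",
    "generate_cohort",
    "perturb_cohort",
    "DEFAULT_PALETTE",
]

# Default tissue palette (mean HU, std HU): anchored at air -1000 and bone
# +1000; tumour/organ contrast deliberately small so that windowing matters.
# Air std is kept moderate so the -1024 HU storage floor does not truncate
# the distribution (truncation would bias the air mean above -1000).
DEFAULT_PALETTE: dict[str, tuple[float, float]] = {
    "background": (-1000.0, 10.0),
    "body": (40.0, 15.0),
    "organ": (60.0, 10.0),
    "tumour": (100.0, 10.0),
}

LABEL_BACKGROUND = 0
LABEL_ORGAN = 1
LABEL_TUMOUR = 2

_CLASS_NAMES = {0: "background", 1: "organ", 2: "tumour"}


class PhantomSizingError(RuntimeError):
    """Raised when no organ placement fits the volume within the retry budget."""


@dataclass
class PhantomConfig:
    """Parameters of the phantom distribution.

    ``tissue_palette`` maps tissue name to (mean HU, std HU) and must contain
    at least ``background``, ``body`` and ``organ``.  ``slice_thickness_range``
    is in millimetres; radii are in voxels.
    """

    in_plane_size: int = 64
    slice_count_range: tuple[int, int] = (16, 64)
    slice_thickness_range: tuple[float, float] = (1.0, 5.0)
    tissue_palette: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PALETTE)
    )
    organ_radius_range: tuple[float, float] = (8.0, 14.0)
    tumour_radius_range: tuple[float, float] = (3.0, 6.0)
    tumour_probability: float = 0.9
    noise_sigma: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.slice_count_range
        if lo < 4 or hi < lo:
            raise ValueError(f"slice_count_range must be non-empty with min >= 4, got {self.slice_count_range}")
        if self.slice_thickness_range[0] > self.slice_thickness_range[1] or self.slice_thickness_range[0] <= 0:
            raise ValueError(f"invalid slice_thickness_range {self.slice_thickness_range}")
        for rng_ in (self.organ_radius_range, self.tumour_radius_range):
            if rng_[0] > rng_[1] or rng_[0] <= 0:
                raise ValueError(f"invalid radius range {rng_}")
        if not 0.0 <= self.tumour_probability <= 1.0:
            raise ValueError("tumour_probability must be in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        required = {"background", "body", "organ"}
        missing = required - set(self.tissue_palette)
        if missing:
            raise ValueError(f"tissue_palette is missing {sorted(missing)}")
        for name, (mean, std) in self.tissue_palette.items():
            if std < 0:
                raise ValueError(f"palette std for {name!r} must be >= 0")
            if not HU_MIN <= mean <= HU_MAX:
                raise ValueError(f"palette mean for {name!r} outside [{HU_MIN}, {HU_MAX}]")


@dataclass
class PhantomCase:
    """A generated case: image + labels + acquisition metadata.

    ``body_mask`` marks voxels inside the soft-tissue body ellipse; its
    complement is pure air (useful for calibration checks).
    """

    image: CTVolume
    labels: LabelVolume
    slice_count: int
    slice_thickness: float
    seed: int
    identifier: str = "phantom"
    body_mask: np.ndarray | None = None

    def as_case(self) -> Case:
        return Case(image=self.image, labels=self.labels, identifier=self.identifier)


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (
        ((zz - center[0]) / radii[0]) ** 2
        + ((yy - center[1]) / radii[1]) ** 2
        + ((xx - center[2]) / radii[2]) ** 2
    ) <= 1.0


def generate_phantom(config: PhantomConfig, seed: int, identifier: str = "phantom") -> PhantomCase:
    """Generate one phantom case, bit-reproducible for a given (config, seed).

    The body is a soft-tissue ellipse spanning most of the field of view; the
    organ is an ellipsoid placed inside the body; an optional tumour ellipsoid
    intersects the organ.  Per-tissue intensities are Gaussian draws from the
    palette, plus global acquisition noise, clamped to the 12-bit HU range
    and stored as integers.
    """
    rng = np.random.default_rng(seed)
    n = config.in_plane_size
    n_slices = int(rng.integers(config.slice_count_range[0], config.slice_count_range[1] + 1))
    thickness = float(rng.uniform(*config.slice_thickness_range))
    shape = (n_slices, n, n)

    # Body: elliptical cylinder with slightly random in-plane semi-axes.
    yy, xx = np.ogrid[:n, :n]
    cy = cx = (n - 1) / 2.0
    ay = n * rng.uniform(0.36, 0.44)
    ax = n * rng.uniform(0.40, 0.48)
    body2d = (((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2) <= 1.0
    body = np.broadcast_to(body2d, shape).copy()

    organ = None
    for _ in range(32):
        r_in = rng.uniform(*config.organ_radius_range)
        r_z = max(2.0, rng.uniform(0.3, 0.7) * n_slices / 2.0)
        center = (
            rng.uniform(r_z, n_slices - 1 - r_z) if n_slices - 1 > 2 * r_z else (n_slices - 1) / 2.0,
            rng.uniform(cy - 0.4 * ay, cy + 0.4 * ay),
            rng.uniform(cx - 0.4 * ax, cx + 0.4 * ax),
        )
        cand = _ellipsoid_mask(shape, center, (r_z, r_in, r_in))
        if cand.any() and (cand & body).sum() >= 0.9 * cand.sum():
            organ = cand & body
            organ_center = center
            break
    if organ is None:
        raise PhantomSizingError(
            f"no organ of radius range {config.organ_radius_range} fits a "
            f"{shape} volume after 32 attempts"
        )

    labels = np.zeros(shape, dtype=np.uint8)
    labels[organ] = LABEL_ORGAN

    has_tumour = "tumour" in config.tissue_palette and rng.random() < config.tumour_probability
    if has_tumour:
        r_t = rng.uniform(*config.tumour_radius_range)
        # Offset from the organ centre so the blob intersects the organ edge.
        offset = rng.normal(size=3)
        offset /= np.linalg.norm(offset) + 1e-12
        t_center = np.asarray(organ_center) + offset * r_t
        tumour = _ellipsoid_mask(shape, t_center, (max(1.5, r_t * 0.6), r_t, r_t))
        tumour &= body
        if (tumour & organ).any():
            labels[tumour] = LABEL_TUMOUR

    image = np.empty(shape, dtype=np.float64)
    mb, sb = config.tissue_palette["background"]
    image[:] = mb + (sb * rng.standard_normal(shape) if sb > 0 else 0.0)
    for name, mask in (
        ("body", body & (labels == LABEL_BACKGROUND)),
        ("organ", labels == LABEL_ORGAN),
        ("tumour", labels == LABEL_TUMOUR),
    ):
        if name not in config.tissue_palette or not mask.any():
            continue
        mean, std = config.tissue_palette[name]
        vals = np.full(mask.sum(), mean)
        if std > 0:
            vals = vals + std * rng.standard_normal(mask.sum())
        image[mask] = vals
    if config.noise_sigma > 0:
        image += config.noise_sigma * rng.standard_normal(shape)
    image = np.clip(np.rint(image), HU_MIN, HU_MAX).astype(np.int16)

    present = set(np.unique(labels).tolist())
    names = {k: v for k, v in _CLASS_NAMES.items() if k == 0 or k in present}
    return PhantomCase(
        image=CTVolume(data=image, spacing=(thickness, 1.0, 1.0)),
        labels=LabelVolume(data=labels.astype(np.int64), class_names=names),
        slice_count=n_slices,
        slice_thickness=thickness,
        seed=seed,
        identifier=identifier,
        body_mask=body,
    )


def generate_cohort(n: int, config: PhantomConfig, seed: int) -> list[PhantomCase]:
    """Generate ``n`` cases with per-case seeds ``seed + index`` (order-stable)."""
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    return [
        generate_phantom(config, seed + i, identifier=f"phantom_{i:03d}") for i in range(n)
    ]


def perturb_cohort(
    cohort: list[PhantomCase], shift_hu: float, scale: float, seed: int = 0
) -> list[PhantomCase]:
    """Apply a vendor/patient-style global affine intensity shift.

    Each image is mapped voxel-wise ``v -> scale * v + shift_hu`` and clamped
    back to the HU range; labels are untouched.  This is the distribution
    shift the cluster-wise intensity augmentation is meant to defend against.
    """
    if scale <= 0:
        raise ValueError(f"scale must be > 0, got {scale}")
    out = []
    for case in cohort:
        data = np.clip(np.rint(case.image.data.astype(np.float64) * scale + shift_hu), HU_MIN, HU_MAX)
        image = CTVolume(
            data=data.astype(np.int16),
            spacing=case.image.spacing,
            affine=case.image.affine,
        )
        out.append(
            PhantomCase(
                image=image,
                labels=case.labels,
                slice_count=case.slice_count,
                slice_thickness=case.slice_thickness,
                seed=case.seed,
                identifier=case.identifier + "_shifted",
                body_mask=case.body_mask,
            )
        )
    return out
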