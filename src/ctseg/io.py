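"""NIfTI volume I/O and the canonical in-memory data model.

Every module in the package works on :class:`CTVolume` / :class:`LabelVolume`
pairs with a fixed axis convention: ``(slice, row, column)``, 0-based, with the
through-plane (slice) axis first.  On disk the volumes are ordinary NIfTI-1
files; the reader reorients arbitrary input to the canonical order using the
header affine, and the writer produces files that read back without any
further permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

HU_MIN = -1024
HU_MAX = 3071

__all__ = [
    "HU_MIN",
    "HU_MAX",
    "CTVolume",
    "LabelVolume",
    "Case",
    "FormatError",
    "read_case",
    "write_case",
]


class FormatError(ValueError):
    """Raised when an on-disk volume violates the format contract."""


@dataclass
class CTVolume:
    """A CT intensity volume.

    Parameters
    ----------
    data:
        3D array, axis order ``(slice, row, column)``.  Hounsfield units
        unless ``unit`` says otherwise (z-score normalisation changes it).
    spacing:
        ``(through-plane mm, row mm, column mm)``, all positive.
    affine:
        Optional 4x4 voxel-to-world matrix carried opaquely.
    unit:
        ``"HU"`` for calibrated intensities, ``"zscore"`` after normalisation.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None
    unit: str = "HU"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError(f"expected a 3D volume, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite intensities")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray, unit: str | None = None) -> "CTVolume":
        return replace(self, data=data, unit=self.unit if unit is None else unit)


@dataclass
class LabelVolume:
    """Voxel-aligned integer class map; class 0 is background by convention."""

    data: np.ndarray
    class_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D label volume, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if np.max(np.abs(self.data - rounded)) > 1e-6:
                raise FormatError("label volume contains non-integer values")
            self.data = rounded.astype(np.int64)
        if self.data.min() < 0:
            raise ValueError("label values must be non-negative")
        if not self.class_names:
            present = np.unique(self.data)
            self.class_names = {int(c): f"class_{int(c)}" for c in present}
            self.class_names[0] = "background"
        if int(self.data.max()) >= max(self.class_names) + 1 and int(
            self.data.max()
        ) not in self.class_names:
            raise ValueError("label volume contains classes without a name")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class Case:
    """An imaging case: CT volume plus optional voxel-wise annotation."""

    image: CTVolume
    labels: LabelVolume | None = None
    identifier: str = "case"

    def __post_init__(self) -> None:
        if self.labels is not None and self.labels.shape != self.image.shape:
            raise ValueError(
                f"label shape {self.labels.shape} does not match image shape {self.image.shape}"
            )


def _load_canonical(path) -> tuple[np.ndarray, tuple[float, float, float], np.ndarray]:
    """Load a NIfTI file and return (slice, row, column)-ordered data.

    ``nib.as_closest_canonical`` reorients to RAS+ (column, row, slice on
    disk); transposing then puts the through-plane axis first.
    """
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3D NIfTI, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    data = np.transpose(data, (2, 1, 0))
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return data, spacing, img.affine


def read_case(image_path, label_path=None, identifier: str | None = None) -> Case:
    """Read an image (and optionally a segmentation) into a canonical Case.

    Axes are reordered so the slice axis comes first regardless of the
    on-disk orientation; spacing is permuted consistently.  Label volumes
    must hold integer values (tolerance 1e-6).
    """
    data, spacing, affine = _load_canonical(image_path)
    image = CTVolume(data=data, spacing=spacing, affine=affine)
    labels = None
    if label_path is not None:
        ldata, _, _ = _load_canonical(label_path)
        if ldata.shape != data.shape:
            raise FormatError(
                f"image shape {data.shape} != label shape {ldata.shape} "
                f"({image_path} vs {label_path})"
            )
        labels = LabelVolume(data=ldata)
    if identifier is None:
        identifier = str(image_path)
    return Case(image=image, labels=labels, identifier=identifier)


def _save_canonical(data: np.ndarray, spacing, path, dtype) -> None:
    disk = np.transpose(np.asarray(data, dtype=dtype), (2, 1, 0))
    affine = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
    img = nib.Nifti1Image(disk, affine)
    img.header.set_zooms((spacing[2], spacing[1], spacing[0]))
    nib.save(img, str(path))


def write_case(case: Case, image_path, label_path=None) -> None:
    """Write a Case as NIfTI; lossless for integer HU and labels.

    Images are stored as int16 when on the HU scale (12-bit CT range fits),
    float32 otherwise; labels as uint8.
    """
    dtype = np.int16 if case.image.unit == "HU" else np.float32
    _save_canonical(case.image.data, case.image.spacing, image_path, dtype)
    if label_path is not None and case.labels is not None:
        if case.labels.data.max() > 255:
            raise ValueError("more than 255 classes cannot be stored as uint8")
        _save_canonical(case.labels.data, case.image.spacing, label_path, np.uint8)
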