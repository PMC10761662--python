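"""Multi-label segmentation volumes and the 2D slices measurements run on.

A :class:`LabelVolume` couples an integer voxel lattice with its physical
geometry (a 4x4 voxel-to-world affine) and a :class:`LabelSchema` that maps
anatomical structure names to label integers.  Coronal volumes carry the
prostate, membranous urethra, corpus spongiosum and the left/right obturator
internus (OIM) and levator ani (LAM) muscles; sagittal volumes carry the
prostate, bladder, corpus spongiosum and membranous urethra.

All downstream measurements are performed in world space (mm), so anisotropic
voxels (sub-millimetre in-plane, 3.0-3.5 mm through-plane) are handled
correctly by construction.  Voxel indexing is 0-based throughout.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

logger = logging.getLogger("pelvimetry")

#: Structure names a schema may map, per orientation.
CORONAL_STRUCTURES = frozenset(
    {"prostate", "urethra", "corpus_spongiosum",
     "oim_left", "oim_right", "lam_left", "lam_right"}
)
SAGITTAL_STRUCTURES = frozenset(
    {"prostate", "urethra", "corpus_spongiosum", "bladder"}
)


class SchemaError(ValueError):
    """A structure/label lookup that the schema cannot satisfy."""


class FormatError(ValueError):
    """Input file content violates the label-map contract."""


@dataclass(frozen=True)
class LabelSchema:
    """Mapping from structure names to integer labels for one orientation."""

    orientation: str
    labels: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.orientation not in ("coronal", "sagittal"):
            raise SchemaError(f"unknown orientation {self.orientation!r}")
        allowed = (CORONAL_STRUCTURES if self.orientation == "coronal"
                   else SAGITTAL_STRUCTURES)
        unknown = set(self.labels) - allowed
        if unknown:
            raise SchemaError(
                f"structures {sorted(unknown)} not valid for "
                f"{self.orientation} orientation")
        vals = list(self.labels.values())
        if len(vals) != len(set(vals)):
            raise SchemaError("label integers must be unique within a schema")
        if any((not isinstance(v, (int, np.integer))) or v <= 0 for v in vals):
            raise SchemaError("labels must be positive integers (0 = background)")

    def label_of(self, structure: str) -> int:
        try:
            return self.labels[structure]
        except KeyError:
            raise SchemaError(
                f"structure {structure!r} not in {self.orientation} schema "
                f"(has {sorted(self.labels)})") from None

    def __contains__(self, structure: str) -> bool:
        return structure in self.labels

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"orientation": self.orientation, "labels": self.labels}, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "LabelSchema":
        d = json.loads(Path(path).read_text())
        return cls(orientation=d["orientation"],
                   labels={k: int(v) for k, v in d["labels"].items()})


@dataclass
class LabelVolume:
    """3D integer label lattice plus physical geometry and its schema."""

    voxels: np.ndarray
    affine: np.ndarray
    schema: LabelSchema

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise FormatError("label volume must be 3D with non-empty axes")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise FormatError("label volume must hold integers")
        if np.any(self.voxels < 0):
            raise FormatError("labels must be non-negative")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")
        if np.any(self.spacing <= 0):
            raise FormatError("voxel spacing must be positive")

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis physical step in mm, from the affine column norms."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def orientation(self) -> str:
        return self.schema.orientation

    def present_labels(self) -> set[int]:
        return {int(v) for v in np.unique(self.voxels) if v != 0}


@dataclass
class BinaryMask3D:
    """Boolean lattice for one structure, with spacing in mm."""

    data: np.ndarray
    spacing: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.data.ndim != 3 or self.spacing.shape != (3,):
            raise ValueError("BinaryMask3D needs a 3D lattice and 3 spacings")

    @property
    def count(self) -> int:
        return int(self.data.sum())

    @property
    def is_empty(self) -> bool:
        return not self.data.any()


@dataclass
class BinaryMask2D:
    """One in-plane slice of a structure mask.

    ``slice_index`` records where along the through-plane axis the slice was
    taken; ``flags`` carries quality annotations (e.g. ``empty_mask``,
    ``slice_tie``) that propagate into measurement results.
    """

    data: np.ndarray
    spacing: np.ndarray
    slice_index: int = 0
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.data.ndim != 2 or self.spacing.shape != (2,):
            raise ValueError("BinaryMask2D needs a 2D lattice and 2 spacings")

    @property
    def count(self) -> int:
        return int(self.data.sum())

    @property
    def is_empty(self) -> bool:
        return not self.data.any()


def read_label_volume(path: str | Path, schema: LabelSchema) -> LabelVolume:
    """Read a NIfTI-1 label map and attach *schema*.

    Data must be integer-valued (a rounding tolerance of 1e-6 absorbs
    float-typed NIfTIs that store integers).  Labels present in the file but
    absent from the schema are preserved and reported with a warning.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    rounded = np.rint(data)
    if np.max(np.abs(data - rounded), initial=0.0) > 1e-6:
        raise FormatError(f"{path}: voxel values are not integers")
    vol = LabelVolume(voxels=rounded.astype(np.int16),
                      affine=img.affine, schema=schema)
    extra = vol.present_labels() - set(schema.labels.values())
    if extra:
        logger.warning("WARN labels %s in %s are not mapped by the %s schema",
                       sorted(extra), path, schema.orientation)
    return vol


def write_label_volume(vol: LabelVolume, path: str | Path) -> None:
    """Write *vol* as NIfTI-1; round-trips voxels exactly and spacing to 1e-6."""
    img = nib.Nifti1Image(vol.voxels.astype(np.int16), vol.affine)
    nib.save(img, str(path))


def extract_structure_mask(vol: LabelVolume, structure: str) -> BinaryMask3D:
    """Binary mask of one named structure (may be empty)."""
    label = vol.schema.label_of(structure)
    return BinaryMask3D(data=vol.voxels == label, spacing=vol.spacing)


def select_measurement_slice(mask: BinaryMask3D,
                             through_axis: int = 2) -> BinaryMask2D:
    """Pick the 2D slice with the largest structure area.

    The measurement protocol delineates each structure in a single mid-plane
    slice, so the slice along *through_axis* with the maximum count of true
    voxels is the measurement slice.  Ties break to the lowest slice index
    (logged); an empty 3D mask yields an empty slice at index 0 flagged
    ``empty_mask``.
    """
    if through_axis not in range(mask.data.ndim):
        raise ValueError(f"through_axis {through_axis} invalid for 3D mask")
    other_axes = tuple(a for a in range(3) if a != through_axis)
    areas = mask.data.sum(axis=other_axes)
    spacing2d = mask.spacing[list(other_axes)]
    if areas.max(initial=0) == 0:
        plane = np.take(mask.data, 0, axis=through_axis)
        return BinaryMask2D(plane, spacing2d, slice_index=0,
                            flags=("empty_mask",))
    best = int(np.argmax(areas))
    flags: tuple[str, ...] = ()
    if np.count_nonzero(areas == areas[best]) > 1:
        logger.warning("WARN slice-area tie at %d voxels; keeping lowest "
                       "index %d", int(areas[best]), best)
        flags = ("slice_tie",)
    return BinaryMask2D(np.take(mask.data, best, axis=through_axis),
                        spacing2d, slice_index=best, flags=flags)


def connected_components_2d(mask: BinaryMask2D,
                            connectivity: int = 8) -> list[BinaryMask2D]:
    """Split a 2D mask into connected components.

    Components are ordered by descending voxel count, ties by ascending row of
    the topmost voxel.  8-connectivity is the default because thin oblique
    urethra cross-sections fragment under 4-connectivity.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = (ndimage.generate_binary_structure(2, 2) if connectivity == 8
                 else ndimage.generate_binary_structure(2, 1))
    labeled, n = ndimage.label(mask.data, structure=structure)
    comps = []
    for i in range(1, n + 1):
        comp = labeled == i
        rows = np.nonzero(comp)[0]
        comps.append((int(comp.sum()), int(rows.min()), comp))
    comps.sort(key=lambda t: (-t[0], t[1]))
    return [BinaryMask2D(c, mask.spacing, slice_index=mask.slice_index,
                         flags=mask.flags)
            for _, _, c in comps]
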