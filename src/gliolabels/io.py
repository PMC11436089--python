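"""Volume and label-mask I/O for skull-stripped, co-registered brain MRI.

All volumes are NIfTI-1 (``.nii`` / ``.nii.gz``), the convention of the BraTS
challenge releases: four co-registered channels (T1, T1Gd, T2, FLAIR) resampled
to 1 mm isotropic voxels, plus integer-coded segmentation masks on the same
grid.  This module reads and writes those files, carries voxel geometry
(spacing and the index-to-mm affine) alongside the data, and translates between
on-disk integer label codes and in-memory per-class boolean masks.

Label dialects
--------------
BraTS masks do not embed a code table, and different toolchains emit different
codes for the same classes (the 2021 release uses 1 = NCR+NET, 2 = ED, 4 = AT;
some pipelines remap 4 to 3).  A *dialect* is an explicit ``{code: class}``
mapping so that no file is ever decoded by guesswork.  Any code present in a
file but absent from the dialect is an error, never silently dropped.

Geometry between co-analysed volumes must agree: shapes exactly, affines to
within :data:`GEOMETRY_ATOL_MM` millimetres.  Nothing here resamples.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "GEOMETRY_ATOL_MM",
    "BRATS_2021_DIALECT",
    "BRATS_REMAPPED_DIALECT",
    "TWO_LABEL_DIALECT",
    "GeometryError",
    "LabelDialectError",
    "VoxelGrid",
    "LabelVolume",
    "ThreeLabelSegmentation",
    "TwoLabelSegmentation",
    "read_volume",
    "read_labels",
    "write_volume",
    "decode_three_label",
    "decode_two_label",
    "encode_two_label",
    "check_same_geometry",
]

#: Tolerance (mm) when comparing affines of volumes analysed together.
GEOMETRY_ATOL_MM = 1e-3

#: BraTS 2021 on-disk codes: 1 = necrosis/non-enhancing core, 2 = oedema,
#: 4 = active enhancing tumour.
BRATS_2021_DIALECT = {1: "NCR+NET", 2: "ED", 4: "AT"}

#: Variant emitted by toolchains that compact code 4 down to 3.
BRATS_REMAPPED_DIALECT = {1: "NCR+NET", 2: "ED", 3: "AT"}

#: Output codes for the two-label postoperative protocol.
TWO_LABEL_DIALECT = {"CE": 1, "NE": 2}

_THREE_CLASSES = frozenset({"AT", "NCR+NET", "ED"})


class GeometryError(ValueError):
    """Shapes or affines of co-analysed volumes disagree."""


class LabelDialectError(ValueError):
    """A label lattice contains codes not declared in its dialect."""


@dataclass(frozen=True)
class VoxelGrid:
    """A 3-D scalar lattice with its voxel geometry.

    Parameters
    ----------
    values : numpy.ndarray
        3-D array of scalar intensities (arbitrary units).
    affine : numpy.ndarray
        4x4 voxel-index -> physical-mm mapping (NIfTI convention).
    """

    values: np.ndarray
    affine: np.ndarray = field(
        default_factory=lambda: np.eye(4),
    )

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise ValueError(f"expected a 3-D lattice, got shape {values.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {affine.shape}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "affine", affine)
        if np.any(self.spacing <= 0):
            raise ValueError(f"voxel spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel edge length in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class LabelVolume:
    """Integer-coded segmentation lattice plus the dialect decoding it."""

    codes: np.ndarray
    affine: np.ndarray
    dialect: dict[int, str]

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes)
        if codes.ndim != 3:
            raise ValueError(f"expected a 3-D label lattice, got shape {codes.shape}")
        if not np.issubdtype(codes.dtype, np.integer):
            raise ValueError(f"label codes must be integers, got dtype {codes.dtype}")
        object.__setattr__(self, "codes", codes)
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))
        undeclared = self.undeclared_codes()
        if undeclared:
            raise LabelDialectError(
                f"codes {sorted(undeclared)} present in lattice but not declared "
                f"in dialect {self.dialect}"
            )

    def undeclared_codes(self) -> set[int]:
        present = set(np.unique(self.codes).tolist())
        present.discard(0)
        return present - set(self.dialect)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.codes.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


def _as_bool_mask(mask: np.ndarray, name: str) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 3:
        raise ValueError(f"{name} must be a 3-D mask, got shape {mask.shape}")
    return mask.astype(bool, copy=False)


@dataclass(frozen=True)
class ThreeLabelSegmentation:
    """BraTS-protocol segmentation: AT, NCR+NET, ED as disjoint masks."""

    at: np.ndarray
    ncr_net: np.ndarray
    ed: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        at = _as_bool_mask(self.at, "at")
        ncr_net = _as_bool_mask(self.ncr_net, "ncr_net")
        ed = _as_bool_mask(self.ed, "ed")
        if not (at.shape == ncr_net.shape == ed.shape):
            raise GeometryError(
                f"class masks disagree in shape: {at.shape}, {ncr_net.shape}, {ed.shape}"
            )
        if np.any(at & ncr_net) or np.any(at & ed) or np.any(ncr_net & ed):
            raise ValueError("AT, NCR+NET and ED masks must be pairwise disjoint")
        object.__setattr__(self, "at", at)
        object.__setattr__(self, "ncr_net", ncr_net)
        object.__setattr__(self, "ed", ed)
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.at.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class TwoLabelSegmentation:
    """Postoperative-protocol segmentation: CE and NE as disjoint masks."""

    ce: np.ndarray
    ne: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        ce = _as_bool_mask(self.ce, "ce")
        ne = _as_bool_mask(self.ne, "ne")
        if ce.shape != ne.shape:
            raise GeometryError(f"CE and NE masks disagree in shape: {ce.shape}, {ne.shape}")
        if np.any(ce & ne):
            raise ValueError("CE and NE masks must be disjoint")
        object.__setattr__(self, "ce", ce)
        object.__setattr__(self, "ne", ne)
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.ce.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


def check_same_geometry(*volumes, atol_mm: float = GEOMETRY_ATOL_MM) -> None:
    """Raise :class:`GeometryError` unless all volumes share shape and affine.

    Shapes must match exactly; affines to within ``atol_mm`` millimetres
    (NIfTI headers store affines in float32, so bit equality is too strict).
    """
    if len(volumes) < 2:
        return
    ref = volumes[0]
    for other in volumes[1:]:
        if tuple(ref.shape) != tuple(other.shape):
            raise GeometryError(f"shape mismatch: {tuple(ref.shape)} vs {tuple(other.shape)}")
        if not np.allclose(ref.affine, other.affine, atol=atol_mm):
            raise GeometryError(
                f"affine mismatch beyond {atol_mm} mm:\n{ref.affine}\nvs\n{other.affine}"
            )


def _load_nifti(path: str | os.PathLike) -> nib.Nifti1Image:
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such volume: {path}")
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises several header/format errors
        raise ValueError(f"cannot parse {path} as a NIfTI volume: {exc}") from exc
    if len(img.shape) != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {img.shape}")
    return img


def read_volume(path: str | os.PathLike) -> VoxelGrid:
    """Read a 3-D scalar NIfTI volume, preserving its geometry."""
    img = _load_nifti(path)
    return VoxelGrid(values=np.asarray(img.dataobj), affine=img.affine)


def read_labels(
    path: str | os.PathLike,
    dialect: dict[int, str] | None = None,
) -> LabelVolume:
    """Read an integer-coded mask; ``dialect`` defaults to BraTS 2021 codes."""
    img = _load_nifti(path)
    codes = np.asarray(img.dataobj)
    if not np.issubdtype(codes.dtype, np.integer):
        rounded = np.rint(codes)
        if not np.array_equal(rounded, codes):
            raise ValueError(f"{path}: label volume contains non-integer values")
        codes = rounded.astype(np.int16)
    return LabelVolume(
        codes=codes,
        affine=img.affine,
        dialect=dict(BRATS_2021_DIALECT if dialect is None else dialect),
    )


def write_volume(grid: VoxelGrid | LabelVolume, path: str | os.PathLike) -> None:
    """Write a grid or label volume as NIfTI.

    Integer lattices round-trip bit-exactly (stored as int16); float lattices
    are stored at float32 precision.
    """
    if isinstance(grid, LabelVolume):
        data = grid.codes.astype(np.int16)
    else:
        data = grid.values
        if np.issubdtype(data.dtype, np.integer):
            data = data.astype(np.int16)
        else:
            data = data.astype(np.float32)
    img = nib.Nifti1Image(data, grid.affine)
    nib.save(img, os.fspath(path))


def decode_three_label(labels: LabelVolume) -> ThreeLabelSegmentation:
    """Split an integer lattice into AT / NCR+NET / ED masks via its dialect.

    Every nonzero code must map to one of the three BraTS classes; the masks
    are preimages of the codes and disjoint by construction.
    """
    bad = {c: n for c, n in labels.dialect.items() if n not in _THREE_CLASSES}
    if bad:
        raise LabelDialectError(
            f"dialect maps codes {sorted(bad)} to classes outside {sorted(_THREE_CLASSES)}: {bad}"
        )
    masks = {name: np.zeros(labels.shape, dtype=bool) for name in _THREE_CLASSES}
    for code, name in labels.dialect.items():
        masks[name] |= labels.codes == code
    return ThreeLabelSegmentation(
        at=masks["AT"], ncr_net=masks["NCR+NET"], ed=masks["ED"], affine=labels.affine
    )


def encode_two_label(
    seg: TwoLabelSegmentation,
    dialect: dict[str, int] | None = None,
) -> LabelVolume:
    """Encode CE/NE masks into an integer lattice (default codes CE=1, NE=2)."""
    dialect = dict(TWO_LABEL_DIALECT if dialect is None else dialect)
    missing = {"CE", "NE"} - set(dialect)
    if missing:
        raise LabelDialectError(f"output dialect must assign codes to {sorted(missing)}")
    if dialect["CE"] == dialect["NE"] or 0 in (dialect["CE"], dialect["NE"]):
        raise LabelDialectError(f"CE and NE codes must be distinct and nonzero: {dialect}")
    codes = np.zeros(seg.shape, dtype=np.int16)
    codes[seg.ce] = dialect["CE"]
    codes[seg.ne] = dialect["NE"]
    return LabelVolume(
        codes=codes,
        affine=seg.affine,
        dialect={dialect["CE"]: "CE", dialect["NE"]: "NE"},
    )


def decode_two_label(labels: LabelVolume) -> TwoLabelSegmentation:
    """Inverse of :func:`encode_two_label`: CE/NE masks from an integer lattice."""
    bad = {c: n for c, n in labels.dialect.items() if n not in {"CE", "NE"}}
    if bad:
        raise LabelDialectError(f"dialect maps codes to classes outside CE/NE: {bad}")
    ce = np.zeros(labels.shape, dtype=bool)
    ne = np.zeros(labels.shape, dtype=bool)
    for code, name in labels.dialect.items():
        (ce if name == "CE" else ne)[labels.codes == code] = True
    return TwoLabelSegmentation(ce=ce, ne=ne, affine=labels.affine)
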