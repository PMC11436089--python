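"""Automatic conversion of three-label BraTS segmentations to a two-label
postoperative protocol.

The BraTS annotation protocol labels preoperative gliomas with three classes:
active enhancing tumour (AT), merged necrosis/cysts/non-enhancing core
(NCR+NET), and oedema or infiltrated tissue (ED).  Necrotic and cystic regions
share image features with postoperative resection cavities, so a model trained
on these labels will label cavities as tumour.  The two-label protocol keeps
the contrast-enhancing tumour (CE) and the non-enhancing T2/FLAIR hyperintense
abnormality (NE = oedema plus retained non-enhancing tumour core) and drops
necrosis and cysts entirely.

The conversion is deterministic mask algebra, in this fixed order:

1. Restrict NCR+NET to a whole-tumour mask WT that excludes necrosis
   (obtained from an external segmentation model and supplied as input) —
   this becomes the initial NE.
2. Union NE with ED.
3. Remove NE connected components entirely encapsulated by AT (these typify
   necrosis inside an enhancing rim).
4. Remove NE connected clusters smaller than 50 mm³ (isolated traces of
   former necrosis).
5. Union NE with ED again, so no oedema voxel is ever lost.
6. CE is the AT mask unchanged.

Only voxels inside the input NCR+NET regions are ever removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import GeometryError, ThreeLabelSegmentation, TwoLabelSegmentation, check_same_geometry

__all__ = [
    "ConversionConfig",
    "ConversionAudit",
    "WholeTumourMask",
    "convert",
    "remove_encapsulated",
    "remove_small_clusters",
    "connectivity_structure",
]


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3-D binary structuring element for a 6-, 18- or 26-neighbourhood."""
    try:
        order = {6: 1, 18: 2, 26: 3}[connectivity]
    except KeyError:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}") from None
    return ndimage.generate_binary_structure(3, order)


@dataclass(frozen=True)
class WholeTumourMask:
    """Whole-tumour mask excluding necrosis (CE + NE of an external model)."""

    wt: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        wt = np.asarray(self.wt)
        if wt.ndim != 3:
            raise ValueError(f"whole-tumour mask must be 3-D, got shape {wt.shape}")
        object.__setattr__(self, "wt", wt.astype(bool, copy=False))
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.wt.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class ConversionConfig:
    """Tunable parameters of the conversion.

    min_cluster_mm3
        Physical volume below which an NE cluster is discarded (strictly
        ``< min_cluster_mm3`` is removed; a cluster of exactly this volume is
        kept).  Default 50 mm³.
    cluster_connectivity
        Neighbourhood (6/18/26) defining connected clusters for the size
        filter.  Default 26, the common choice for foreground lesions.
    encapsulation_connectivity
        Neighbourhood for the encapsulation boundary test.  Default 6 (face
        adjacency), the strictest notion of "entirely surrounded".
    encapsulation_method
        ``"boundary"`` — remove a component iff every outside voxel adjacent
        to it is AT (components touching the lattice border are never
        removed); ``"fill"`` — remove components lying entirely inside the
        hole-filled AT mask minus AT.  The boundary test is the default; the
        fill variant also captures regions enclosed by AT but bounded partly
        by background, and is provided for sensitivity analysis.
    """

    min_cluster_mm3: float = 50.0
    cluster_connectivity: int = 26
    encapsulation_connectivity: int = 6
    encapsulation_method: str = "boundary"

    def __post_init__(self) -> None:
        if self.min_cluster_mm3 <= 0:
            raise ValueError(f"min_cluster_mm3 must be > 0, got {self.min_cluster_mm3}")
        connectivity_structure(self.cluster_connectivity)
        connectivity_structure(self.encapsulation_connectivity)
        if self.encapsulation_method not in ("boundary", "fill"):
            raise ValueError(
                f"encapsulation_method must be 'boundary' or 'fill', "
                f"got {self.encapsulation_method!r}"
            )


@dataclass
class ConversionAudit:
    """Voxel bookkeeping of one conversion run.

    Counts reconcile as::

        output NE = |NCR+NET ∩ WT ∪ ED| - removed_encapsulated
                    - removed_small_clusters + restored_by_ed
    """

    voxels_removed_encapsulated: int
    voxels_removed_small_clusters: int
    voxels_restored_by_ed: int
    input_voxel_counts: dict[str, int]
    output_voxel_counts: dict[str, int]
    config: ConversionConfig = field(default_factory=ConversionConfig)

    def as_text(self) -> str:
        """One ``key\\tvalue`` pair per line, for the audit report file."""
        lines = [
            ("voxels_removed_encapsulated", self.voxels_removed_encapsulated),
            ("voxels_removed_small_clusters", self.voxels_removed_small_clusters),
            ("voxels_restored_by_ed", self.voxels_restored_by_ed),
        ]
        lines += [(f"input_{k}", v) for k, v in self.input_voxel_counts.items()]
        lines += [(f"output_{k}", v) for k, v in self.output_voxel_counts.items()]
        lines += [
            ("min_cluster_mm3", self.config.min_cluster_mm3),
            ("cluster_connectivity", self.config.cluster_connectivity),
            ("encapsulation_connectivity", self.config.encapsulation_connectivity),
            ("encapsulation_method", self.config.encapsulation_method),
        ]
        return "\n".join(f"{k}\t{v}" for k, v in lines) + "\n"


def remove_encapsulated(
    candidate: np.ndarray,
    at: np.ndarray,
    connectivity: int = 6,
    method: str = "boundary",
) -> np.ndarray:
    """Remove candidate components entirely encapsulated by the AT mask.

    With ``method="boundary"`` a connected component C of ``candidate``
    (components and adjacency both under ``connectivity``) is removed iff it
    does not touch the lattice border and every voxel outside C adjacent to C
    belongs to ``at``.  With ``method="fill"`` a component is removed iff it
    lies entirely inside ``binary_fill_holes(at) & ~at``.
    """
    candidate = np.asarray(candidate).astype(bool, copy=False)
    at = np.asarray(at).astype(bool, copy=False)
    if candidate.shape != at.shape:
        raise GeometryError(f"shape mismatch: {candidate.shape} vs {at.shape}")
    struct = connectivity_structure(connectivity)

    if method == "fill":
        enclosed = ndimage.binary_fill_holes(at, structure=struct) & ~at
        labels, n = ndimage.label(candidate, structure=struct)
        out = candidate.copy()
        for i in range(1, n + 1):
            comp = labels == i
            if np.all(enclosed[comp]):
                out &= ~comp
        return out
    if method != "boundary":
        raise ValueError(f"unknown encapsulation method {method!r}")

    labels, n = ndimage.label(candidate, structure=struct)
    out = candidate.copy()
    border = np.zeros(candidate.shape, dtype=bool)
    border[0, :, :] = border[-1, :, :] = True
    border[:, 0, :] = border[:, -1, :] = True
    border[:, :, 0] = border[:, :, -1] = True
    for i in range(1, n + 1):
        comp = labels == i
        if np.any(comp & border):
            continue  # reaches the lattice edge: cannot be encapsulated
        shell = ndimage.binary_dilation(comp, structure=struct) & ~comp
        if np.all(at[shell]):
            out &= ~comp
    return out


def remove_small_clusters(
    mask: np.ndarray,
    min_mm3: float,
    spacing: np.ndarray | tuple[float, float, float] = (1.0, 1.0, 1.0),
    connectivity: int = 26,
) -> np.ndarray:
    """Drop connected clusters with physical volume strictly below ``min_mm3``.

    Volume is voxel count times the voxel volume from ``spacing`` (mm), so
    anisotropic grids are handled correctly; at the BraTS 1 mm³ resolution
    volume and count coincide.
    """
    if min_mm3 <= 0:
        raise ValueError(f"min_mm3 must be > 0, got {min_mm3}")
    mask = np.asarray(mask).astype(bool, copy=False)
    voxel_volume = float(np.prod(np.asarray(spacing, dtype=float)))
    labels, n = ndimage.label(mask, structure=connectivity_structure(connectivity))
    if n == 0:
        return mask.copy()
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    keep = counts * voxel_volume >= min_mm3
    keep[0] = False
    return keep[labels]


def convert(
    seg: ThreeLabelSegmentation,
    wt: WholeTumourMask,
    config: ConversionConfig | None = None,
) -> tuple[TwoLabelSegmentation, ConversionAudit]:
    """Convert a three-label segmentation to the two-label protocol.

    Parameters
    ----------
    seg
        BraTS-style AT / NCR+NET / ED masks (pairwise disjoint, enforced by
        the type).
    wt
        Whole-tumour mask excluding necrosis, from an external model; used
        only to restrict NCR+NET in the first step.
    config
        Thresholds and connectivities; defaults follow
        :class:`ConversionConfig`.

    Returns
    -------
    (TwoLabelSegmentation, ConversionAudit)
        CE is voxelwise identical to input AT; NE is the filtered
        NCR+NET ∪ ED.  The audit records every voxel added or removed.
    """
    if config is None:
        config = ConversionConfig()
    check_same_geometry(seg, wt)
    spacing = seg.spacing

    ne = seg.ncr_net & wt.wt            # step 1: NCR+NET restricted to WT
    ne |= seg.ed                        # step 2: add oedema
    after_union = ne
    n_after_union = int(after_union.sum())

    ne = remove_encapsulated(           # step 3: drop AT-encapsulated voxels
        after_union,
        seg.at,
        connectivity=config.encapsulation_connectivity,
        method=config.encapsulation_method,
    )
    n_removed_enc = n_after_union - int(ne.sum())

    after_size = remove_small_clusters( # step 4: drop clusters < threshold
        ne,
        min_mm3=config.min_cluster_mm3,
        spacing=spacing,
        connectivity=config.cluster_connectivity,
    )
    n_removed_small = int(ne.sum()) - int(after_size.sum())

    ne = after_size | seg.ed            # step 5: re-add oedema unconditionally
    n_restored = int(ne.sum()) - int(after_size.sum())

    ce = seg.at.copy()                  # step 6: CE is AT, unchanged
    if np.any(ce & ne):
        # unreachable when input classes are disjoint; guards corrupt inputs
        raise ValueError("converted CE and NE overlap; input classes were not disjoint")

    out = TwoLabelSegmentation(ce=ce, ne=ne, affine=seg.affine)
    audit = ConversionAudit(
        voxels_removed_encapsulated=n_removed_enc,
        voxels_removed_small_clusters=n_removed_small,
        voxels_restored_by_ed=n_restored,
        input_voxel_counts={
            "at": int(seg.at.sum()),
            "ncr_net": int(seg.ncr_net.sum()),
            "ed": int(seg.ed.sum()),
            "wt": int(wt.wt.sum()),
        },
        output_voxel_counts={"ce": int(out.ce.sum()), "ne": int(out.ne.sum())},
        config=config,
    )
    return out, audit
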