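"""Deterministic synthetic phantoms for the conversion and cavity pipelines.

A phantom emulates the geometry and intensity contrasts the conversion and
the cavity detector must handle, on a small lattice so tests run in well
under a second:

* a concentric tumour: necrotic/cystic core (NCR+NET), enhancing shell (AT),
  oedema halo (ED);
* optional isolated non-enhancing tumour islands (NCR+NET away from the main
  tumour) above and below the 50 mm³ conversion threshold;
* an optional fluid-filled resection cavity whose channel intensities
  z-normalise below −1 on T1Gd, below 0 on FLAIR and above 0 on T2 with a
  construction margin of at least 0.5 standardised units.

The phantom makes no attempt at MRI physics (no bias fields, no partial
volume, no anatomy); it provides exactly the structures whose handling the
mask algebra defines, with analytically known ground truth.  Identical spec
and seed give bit-identical output.

Spheres are voxelised by centre-of-voxel inclusion (a voxel belongs to a ball
of radius r iff its centre is within r of the ball centre, in voxel units).
Structures whose exact voxel count matters (NET islands, cavities) are
specified by count: the ball of the n voxel centres nearest the structure
centre, ties broken lexicographically, so analytic volumes are reproducible
to the voxel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cavities import MultiModalStudy, CavitySet
from .conversion import WholeTumourMask
from .io import ThreeLabelSegmentation, TwoLabelSegmentation, VoxelGrid

__all__ = ["PhantomSpec", "PhantomError", "generate"]


class PhantomError(ValueError):
    """The requested phantom is geometrically or radiometrically infeasible."""


#: Mean intensity (arbitrary units) per tissue type and channel.  Chosen so
#: that, after z-normalisation over the brain, only cavity voxels satisfy the
#: cavity rule (T1Gd dark, FLAIR suppressed, T2 bright) while necrotic cores
#: fail the T2 criterion and enhancing tissue fails the T1Gd criterion.
INTENSITY_TABLE: dict[str, dict[str, float]] = {
    "t1":    {"tissue": 100.0, "core": 70.0, "shell": 105.0, "halo": 95.0,  "island": 95.0,  "cavity": 40.0},
    "t1gd":  {"tissue": 100.0, "core": 60.0, "shell": 160.0, "halo": 100.0, "island": 100.0, "cavity": 40.0},
    "t2":    {"tissue": 100.0, "core": 80.0, "shell": 140.0, "halo": 140.0, "island": 130.0, "cavity": 200.0},
    "flair": {"tissue": 100.0, "core": 80.0, "shell": 110.0, "halo": 140.0, "island": 130.0, "cavity": 40.0},
}

#: Minimum distance (standardised units) by which cavity voxels must clear
#: each z-threshold for the phantom to count as well-formed.
CAVITY_Z_MARGIN = 0.5


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic study.

    Radii are in voxel units; island and cavity sizes are exact voxel counts.
    The default 64³ lattice at 1 mm³ voxels is large enough to host a 2 cm³
    cavity with margin and small enough for sub-second generation.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0
    brain_radius: float = 28.0
    tumour_centre: tuple[int, int, int] = (32, 32, 32)
    core_radius: float = 8.0
    shell_radius: float = 10.0
    halo_radius: float = 14.0
    #: ((centre, n_voxels), ...) isolated NCR+NET islands inside the brain.
    net_islands: tuple[tuple[tuple[int, int, int], int], ...] = ()
    #: ((centre, n_voxels), ...) fluid-filled cavities.
    cavities: tuple[tuple[tuple[int, int, int], int], ...] = ()
    noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if not (0 < self.core_radius < self.shell_radius < self.halo_radius):
            raise PhantomError(
                "compartment radii must nest: 0 < core < shell < halo, got "
                f"{self.core_radius}, {self.shell_radius}, {self.halo_radius}"
            )
        if self.halo_radius > self.brain_radius:
            raise PhantomError("tumour halo must fit inside the brain")
        if any(s <= 0 for s in self.spacing):
            raise PhantomError(f"spacing must be positive, got {self.spacing}")
        if self.noise_sd < 0:
            raise PhantomError(f"noise_sd must be >= 0, got {self.noise_sd}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([*self.spacing, 1.0])
        return aff


def _distance_grid(shape: tuple[int, int, int], centre: tuple[float, float, float]) -> np.ndarray:
    idx = np.indices(shape, dtype=float)
    return np.sqrt(sum((idx[a] - centre[a]) ** 2 for a in range(3)))


def _ball(shape, centre, radius) -> np.ndarray:
    return _distance_grid(shape, centre) <= radius


def _nearest_n_ball(shape, centre, n: int) -> np.ndarray:
    """Mask of the n voxel centres nearest ``centre`` (lexicographic ties)."""
    if n < 1:
        raise PhantomError(f"structure voxel count must be >= 1, got {n}")
    dist = _distance_grid(shape, centre)
    flat = dist.ravel()
    if n > flat.size:
        raise PhantomError(f"structure of {n} voxels exceeds lattice size {flat.size}")
    # stable sort on distance = lexicographic tie-break over C-order indices
    order = np.argsort(flat, kind="stable")[:n]
    mask = np.zeros(flat.size, dtype=bool)
    mask[order] = True
    return mask.reshape(shape)


def generate(
    spec: PhantomSpec,
) -> tuple[
    MultiModalStudy,
    ThreeLabelSegmentation,
    WholeTumourMask,
    TwoLabelSegmentation,
    CavitySet,
]:
    """Generate one phantom study with its analytic ground truths.

    Returns
    -------
    study : MultiModalStudy
        Four noisy channels plus the brain mask.
    seg : ThreeLabelSegmentation
        AT = enhancing shell; NCR+NET = necrotic core plus NET islands;
        ED = oedema halo.
    wt : WholeTumourMask
        AT ∪ ED ∪ islands — the whole tumour excluding necrosis, as an
        external model would supply it.
    truth : TwoLabelSegmentation
        The conversion rules applied analytically: CE = shell; NE = halo plus
        every island of at least 50 mm³ (the core is excluded by WT and by
        AT encapsulation; sub-threshold islands by the cluster filter).
    cavity_truth : CavitySet
        The generated cavities, largest first, regardless of size — callers
        decide which clear the detector's 2 cm³ floor.

    Raises
    ------
    PhantomError
        If structures overlap, leave the brain, or the cavity contrast cannot
        clear the z-thresholds by :data:`CAVITY_Z_MARGIN` under the requested
        noise level.
    """
    shape = tuple(spec.shape)
    centre = spec.tumour_centre
    brain_centre = tuple((s - 1) / 2.0 for s in shape)
    brain = _ball(shape, brain_centre, spec.brain_radius)

    dist = _distance_grid(shape, centre)
    core = dist <= spec.core_radius
    shell = (dist > spec.core_radius) & (dist <= spec.shell_radius)
    halo = (dist > spec.shell_radius) & (dist <= spec.halo_radius)
    tumour = core | shell | halo

    islands = [_nearest_n_ball(shape, c, n) for c, n in spec.net_islands]
    cavity_masks = [_nearest_n_ball(shape, c, n) for c, n in spec.cavities]

    occupied = tumour.copy()
    for name, mask in [("NET island", m) for m in islands] + [
        ("cavity", m) for m in cavity_masks
    ]:
        if np.any(mask & occupied):
            raise PhantomError(f"{name} overlaps another structure")
        if np.any(mask & ~brain):
            raise PhantomError(f"{name} extends outside the brain")
        occupied |= mask
    if np.any(tumour & ~brain):
        raise PhantomError("tumour extends outside the brain")

    island_union = np.zeros(shape, dtype=bool)
    for m in islands:
        island_union |= m
    cavity_union = np.zeros(shape, dtype=bool)
    for m in cavity_masks:
        cavity_union |= m

    # channel synthesis: piecewise means + seeded Gaussian noise, zero outside brain
    rng = np.random.default_rng(spec.seed)
    channels: dict[str, VoxelGrid] = {}
    for name in ("t1", "t1gd", "t2", "flair"):
        table = INTENSITY_TABLE[name]
        values = np.zeros(shape, dtype=np.float64)
        values[brain] = table["tissue"]
        values[core] = table["core"]
        values[shell] = table["shell"]
        values[halo] = table["halo"]
        values[island_union] = table["island"]
        values[cavity_union] = table["cavity"]
        values[brain] += rng.normal(0.0, spec.noise_sd, size=int(brain.sum()))
        channels[name] = VoxelGrid(values=values, affine=spec.affine)

    study = MultiModalStudy(
        t1=channels["t1"],
        t1gd=channels["t1gd"],
        t2=channels["t2"],
        flair=channels["flair"],
        brain_mask=brain,
    )
    if cavity_masks:
        _check_cavity_contrast(study, cavity_union)

    seg = ThreeLabelSegmentation(
        at=shell, ncr_net=core | island_union, ed=halo, affine=spec.affine
    )
    wt = WholeTumourMask(wt=shell | halo | island_union, affine=spec.affine)

    ne = halo.copy()
    for m in islands:
        if int(m.sum()) * spec.voxel_volume_mm3 >= 50.0:
            ne |= m
    truth = TwoLabelSegmentation(ce=shell.copy(), ne=ne, affine=spec.affine)

    ordered = sorted(
        cavity_masks, key=lambda m: -int(m.sum())
    )
    cavity_truth = CavitySet(
        cavities=tuple(ordered),
        volumes_mm3=tuple(int(m.sum()) * spec.voxel_volume_mm3 for m in ordered),
        affine=spec.affine,
    )
    return study, seg, wt, truth, cavity_truth


def _check_cavity_contrast(study: MultiModalStudy, cavity_union: np.ndarray) -> None:
    """Verify the constructed contrasts actually separate cavities.

    Cavity voxels must clear each z-threshold by :data:`CAVITY_Z_MARGIN`;
    no non-cavity brain voxel may satisfy the full cavity rule.
    """
    from .cavities import znormalize  # local import to avoid cycle at module load

    z_t1gd = znormalize(study.t1gd, study.brain_mask).values
    z_flair = znormalize(study.flair, study.brain_mask).values
    z_t2 = znormalize(study.t2, study.brain_mask).values

    m = CAVITY_Z_MARGIN
    ok = (
        np.all(z_t1gd[cavity_union] < -1.0 - m)
        and np.all(z_flair[cavity_union] < 0.0 - m)
        and np.all(z_t2[cavity_union] > 0.0 + m)
    )
    if not ok:
        raise PhantomError(
            "cavity intensities do not clear the z-thresholds by the required "
            f"margin of {m}; reduce noise_sd or enlarge the brain"
        )
    rule = (z_t1gd < -1.0) & (z_flair < 0.0) & (z_t2 > 0.0) & study.brain_mask
    if np.any(rule & ~cavity_union):
        raise PhantomError(
            "non-cavity brain voxels satisfy the cavity rule; the phantom "
            "would not have an analytic cavity ground truth"
        )
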