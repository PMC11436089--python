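"""Independent brute-force reference implementations.

Everything here deliberately avoids the library code paths (scipy.ndimage
labelling, vectorised mask algebra): masks are Python sets of voxel index
tuples, connected components come from breadth-first flood fill, and the
conversion / detection rules are re-derived step by step by exhaustive voxel
iteration.  Slow but transparently correct on small lattices.
"""

from __future__ import annotations

import math
from collections import deque
from itertools import product

import numpy as np

_OFFSETS_6 = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
_OFFSETS_26 = [
    (dx, dy, dz)
    for dx, dy, dz in product((-1, 0, 1), repeat=3)
    if (dx, dy, dz) != (0, 0, 0)
]
_OFFSETS_18 = [d for d in _OFFSETS_26 if abs(d[0]) + abs(d[1]) + abs(d[2]) <= 2]

OFFSETS = {6: _OFFSETS_6, 18: _OFFSETS_18, 26: _OFFSETS_26}


def mask_to_set(mask: np.ndarray) -> set[tuple[int, int, int]]:
    return set(zip(*np.nonzero(np.asarray(mask, dtype=bool))))


def set_to_mask(voxels: set, shape) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    for v in voxels:
        out[v] = True
    return out


def flood_components(voxels: set, connectivity: int) -> list[set]:
    """Connected components of a voxel set via breadth-first flood fill."""
    offsets = OFFSETS[connectivity]
    remaining = set(voxels)
    comps = []
    while remaining:
        seed = remaining.pop()
        comp = {seed}
        queue = deque([seed])
        while queue:
            x, y, z = queue.popleft()
            for dx, dy, dz in offsets:
                nb = (x + dx, y + dy, z + dz)
                if nb in remaining:
                    remaining.remove(nb)
                    comp.add(nb)
                    queue.append(nb)
        comps.append(comp)
    return comps


def on_border(voxel, shape) -> bool:
    return any(voxel[a] == 0 or voxel[a] == shape[a] - 1 for a in range(3))


def oracle_remove_encapsulated(
    candidate: set, at: set, shape, connectivity: int
) -> set:
    """Drop candidate components whose entire adjacent exterior is AT.

    Border contact is established by checking voxel indices directly, which is
    what a flood fill from outside the lattice would conclude: a border voxel
    is reachable without crossing anything.
    """
    offsets = OFFSETS[connectivity]
    kept: set = set()
    for comp in flood_components(candidate, connectivity):
        if any(on_border(v, shape) for v in comp):
            kept |= comp
            continue
        exterior = set()
        for x, y, z in comp:
            for dx, dy, dz in offsets:
                nb = (x + dx, y + dy, z + dz)
                if nb not in comp:
                    exterior.add(nb)
        if exterior <= at:
            continue  # entirely encapsulated: removed
        kept |= comp
    return kept


def oracle_remove_small(
    mask: set, min_mm3: float, voxel_volume_mm3: float, connectivity: int
) -> set:
    kept: set = set()
    for comp in flood_components(mask, connectivity):
        if len(comp) * voxel_volume_mm3 >= min_mm3:
            kept |= comp
    return kept


def oracle_convert(
    at: np.ndarray,
    ncr_net: np.ndarray,
    ed: np.ndarray,
    wt: np.ndarray,
    spacing=(1.0, 1.0, 1.0),
    min_cluster_mm3: float = 50.0,
    cluster_connectivity: int = 26,
    encapsulation_connectivity: int = 6,
) -> tuple[np.ndarray, np.ndarray]:
    """Re-derive the three-label -> two-label conversion from first principles."""
    shape = np.asarray(at).shape
    voxvol = float(np.prod(np.asarray(spacing, dtype=float)))
    at_s = mask_to_set(at)
    ncr_s = mask_to_set(ncr_net)
    ed_s = mask_to_set(ed)
    wt_s = mask_to_set(wt)

    ne = ncr_s & wt_s
    ne = ne | ed_s
    ne = oracle_remove_encapsulated(ne, at_s, shape, encapsulation_connectivity)
    ne = oracle_remove_small(ne, min_cluster_mm3, voxvol, cluster_connectivity)
    ne = ne | ed_s
    return set_to_mask(at_s, shape), set_to_mask(ne, shape)


def oracle_znorm_values(values: np.ndarray, brain: set) -> dict:
    """Per-voxel z-scores over the brain, computed by plain Python arithmetic."""
    vals = {v: float(values[v]) for v in brain}
    n = len(vals)
    mean = sum(vals.values()) / n
    var = sum((x - mean) ** 2 for x in vals.values()) / n
    std = math.sqrt(var)
    if std == 0:
        raise ZeroDivisionError("constant intensities in brain")
    return {v: (x - mean) / std for v, x in vals.items()}


def oracle_detect(
    t1gd: np.ndarray,
    flair: np.ndarray,
    t2: np.ndarray,
    brain: np.ndarray,
    voxel_volume_mm3: float = 1.0,
    min_volume_cm3: float = 2.0,
    connectivity: int = 26,
) -> list[set]:
    """Cavity detection by exhaustive voxelwise predicate + flood fill.

    Returns component voxel sets sorted largest first.
    """
    brain_s = mask_to_set(brain)
    z1 = oracle_znorm_values(np.asarray(t1gd, dtype=float), brain_s)
    zf = oracle_znorm_values(np.asarray(flair, dtype=float), brain_s)
    z2 = oracle_znorm_values(np.asarray(t2, dtype=float), brain_s)
    candidate = {
        v for v in brain_s if z1[v] < -1.0 and zf[v] < 0.0 and z2[v] > 0.0
    }
    comps = [
        c
        for c in flood_components(candidate, connectivity)
        if len(c) * voxel_volume_mm3 >= min_volume_cm3 * 1000.0
    ]
    comps.sort(key=len, reverse=True)
    return comps


def random_conversion_masks(seed: int, shape=(32, 32, 32)):
    """Random blobby AT / NCR+NET / ED / WT masks for oracle equivalence runs.

    Smoothed Gaussian noise fields thresholded at fixed quantiles give
    organic, overlapping blobs; disjointness of the three classes is then
    enforced by priority (AT > NCR+NET > ED).  Every third seed additionally
    injects a deterministic enhancing shell with a necrotic core — with a
    one-voxel hole punched through the shell on every sixth seed — so the
    encapsulation branch and its "entirely" qualifier are both exercised.
    """
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    def blob(q, sigma):
        f = gaussian_filter(rng.standard_normal(shape), sigma)
        return f > np.quantile(f, q)

    at = blob(0.95, 3.0)
    ncr = blob(0.92, 2.5)
    ed = blob(0.90, 3.5)
    wt = blob(0.80, 4.0)

    if seed % 3 == 0:
        centre = rng.integers(10, 22, size=3)
        idx = np.indices(shape, dtype=float)
        d = np.sqrt(sum((idx[a] - centre[a]) ** 2 for a in range(3)))
        core = d <= 3.5
        shell = (d > 3.5) & (d <= 6.0)
        if seed % 6 == 0:
            hole = tuple(int(c) for c in centre + np.array([0, 0, 5]))
            shell[hole] = False
        at = at | shell
        ncr = ncr | core
        wt = wt | shell | core

    ncr = ncr & ~at
    ed = ed & ~at & ~ncr
    return at, ncr, ed, wt


def random_detection_channels(seed: int, shape=(32, 32, 32)):
    """Random smooth channels + brain ball for detector oracle equivalence.

    Every other seed carves a deterministic cold/bright blob so that large
    components above the volume floor occur regularly.
    """
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    idx = np.indices(shape, dtype=float)
    centre = (np.array(shape) - 1) / 2.0
    brain = np.sqrt(sum((idx[a] - centre[a]) ** 2 for a in range(3))) <= 14.0

    def channel(offset):
        f = gaussian_filter(rng.standard_normal(shape), 2.0)
        out = np.zeros(shape)
        out[brain] = 100.0 + offset + 30.0 * f[brain]
        return out

    t1gd = channel(0.0)
    flair = channel(0.0)
    t2 = channel(0.0)
    if seed % 2 == 0:
        c = rng.integers(12, 20, size=3)
        d = np.sqrt(sum((idx[a] - c[a]) ** 2 for a in range(3)))
        ball = (d <= rng.uniform(4.0, 7.0)) & brain
        t1gd[ball] -= 120.0
        flair[ball] -= 80.0
        t2[ball] += 120.0
    return t1gd, flair, t2, brain
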