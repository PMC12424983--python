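"""Mitochondria-ER contact quantification from 2D masks, and ER SA/V from 3D masks.

A mitochondrion perimeter pixel (a mask pixel with at least one 4-neighbor
outside the mask) is *in contact* when any ER pixel center lies within a
proximity gap (10 nm by default, i.e. 2 px at 5 nm/px, inclusive) of its
center.  Contact *sites* are runs of contiguous in-contact perimeter
pixels, traced along the boundary in order, whose length (pixel count
times pixel size) reaches a minimum (10 nm by default).  A mitochondrion
is classified as ER-*coupled* when strictly more than 5% of its perimeter
pixels belong to qualifying contact sites.

For 3D ER masks, per-object surface area is computed by exposed-face
counting (exact for voxel objects; a marching-cubes option serves smooth
surfaces) and volume by voxel counting, giving SA/V in 1/nm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

_STRUCT8 = np.ones((3, 3), dtype=bool)
# Moore neighborhood in clockwise order starting East
_MOORE = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]


@dataclass
class MaskPair:
    """Co-registered binary mitochondria and ER masks with pixel size in nm."""

    mito: np.ndarray
    er: np.ndarray
    nm_per_px: float = 5.0

    def __post_init__(self) -> None:
        self.mito = np.asarray(self.mito, dtype=bool)
        self.er = np.asarray(self.er, dtype=bool)
        if self.mito.shape != self.er.shape:
            raise ValueError("mitochondria and ER masks must have identical shapes")
        if not self.nm_per_px > 0:
            raise ValueError("nm_per_px must be positive")
        if (self.mito & self.er).any():
            raise ValueError("mitochondria and ER masks must be disjoint")


@dataclass
class ContactSite:
    """A qualifying run of in-contact perimeter pixels on one mitochondrion."""

    mito_id: int
    pixels: list[tuple[int, int]]
    length_nm: float


@dataclass
class ContactReport:
    """Per-mitochondrion contact summary plus the population coupled fraction."""

    per_mito: pd.DataFrame  # mito_id, perimeter_px, contact_px, contact_fraction, coupled
    fraction_coupled: float


def _perimeter_mask(mask: np.ndarray) -> np.ndarray:
    """Pixels of the mask with at least one 4-neighbor outside it."""
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    return mask & ~eroded


def _trace_boundary(mask: np.ndarray) -> list[tuple[int, int]]:
    """Moore-neighbor boundary trace of a single connected component.

    Returns the ordered cyclic sequence of boundary pixels (duplicates from
    revisits removed, order of first visit kept).
    """
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        return []
    if rows.size == 1:
        return [(int(rows[0]), int(cols[0]))]
    h, w = mask.shape

    def inside(r: int, c: int) -> bool:
        return 0 <= r < h and 0 <= c < w and mask[r, c]

    start = (int(rows[0]), int(cols[0]))  # first pixel in raster order
    path = [start]
    cur = start
    # the pixel West of start is outside the mask (raster order guarantees it)
    backtrack_dir = 4
    first_move = None
    guard = 8 * rows.size + 16
    while guard > 0:
        guard -= 1
        found = False
        # start scanning clockwise from the neighbor after the backtrack
        start_idx = (backtrack_dir + 1) % 8
        for k in range(8):
            d = (start_idx + k) % 8
            dr, dc = _MOORE[d]
            nr, nc = cur[0] + dr, cur[1] + dc
            if inside(nr, nc):
                # new backtrack points from the new pixel to the last empty cell scanned
                prev_d = (d - 1) % 8
                pdr, pdc = _MOORE[prev_d]
                er, ec = cur[0] + pdr, cur[1] + pdc
                backtrack_dir = _dir_from((nr, nc), (er, ec))
                move = (cur, (nr, nc))
                if first_move is None:
                    first_move = move
                elif move == first_move:
                    return _dedupe(path)
                cur = (nr, nc)
                path.append(cur)
                found = True
                break
        if not found:  # isolated pixel relative to connectivity
            return _dedupe(path)
    return _dedupe(path)


def _dir_from(a: tuple[int, int], b: tuple[int, int]) -> int:
    d = (b[0] - a[0], b[1] - a[1])
    d = (max(-1, min(1, d[0])), max(-1, min(1, d[1])))
    return _MOORE.index(d)


def _dedupe(path: list[tuple[int, int]]) -> list[tuple[int, int]]:
    seen = set()
    out = []
    for p in path:
        if p not in seen:
            seen.add(p)
            out.append(p)
    return out


def _qualifying_runs(
    flags: np.ndarray, nm_per_px: float, min_len_nm: float
) -> list[list[int]]:
    """Cyclic runs of True indices whose pixel length * nm_per_px >= min_len_nm."""
    n = len(flags)
    if n == 0 or not flags.any():
        return []
    if flags.all():
        return [list(range(n))]
    start = int(np.nonzero(~flags)[0][0]) + 1
    order = [(start + i) % n for i in range(n)]
    runs: list[list[int]] = []
    cur: list[int] = []
    for idx in order:
        if flags[idx]:
            cur.append(idx)
        elif cur:
            runs.append(cur)
            cur = []
    if cur:
        runs.append(cur)
    return [r for r in runs if len(r) * nm_per_px >= min_len_nm]


def label_mitochondria(pair: MaskPair) -> np.ndarray:
    """8-connected labels of the mitochondria mask, in raster-scan order."""
    labels, _ = ndimage.label(pair.mito, structure=_STRUCT8)
    return labels


def find_contact_sites(
    pair: MaskPair, max_gap_nm: float = 10.0, min_len_nm: float = 10.0
) -> list[ContactSite]:
    """Contact sites: boundary runs within ``max_gap_nm`` of ER, at least ``min_len_nm`` long.

    Distances are Euclidean, pixel center to pixel center, in nm; the gap
    criterion is inclusive (a center distance of exactly 10 nm counts).
    """
    if not pair.mito.any():
        return []
    labels = label_mitochondria(pair)
    if pair.er.any():
        dist_nm = ndimage.distance_transform_edt(~pair.er) * pair.nm_per_px
    else:
        dist_nm = np.full(pair.er.shape, np.inf)
    sites: list[ContactSite] = []
    for mito_id in range(1, labels.max() + 1):
        comp = labels == mito_id
        perim = _perimeter_mask(comp)
        boundary = [p for p in _trace_boundary(comp) if perim[p]]
        if not boundary:
            continue
        flags = np.array([dist_nm[p] <= max_gap_nm for p in boundary])
        for run in _qualifying_runs(flags, pair.nm_per_px, min_len_nm):
            pixels = [boundary[i] for i in run]
            sites.append(ContactSite(mito_id, pixels, len(pixels) * pair.nm_per_px))
    return sites


def classify_mitochondria(pair: MaskPair, sites: list[ContactSite]) -> ContactReport:
    """Coupled/uncoupled classification: coupled iff contact fraction > 5% (strict)."""
    labels = label_mitochondria(pair)
    n_mito = int(labels.max())
    contact_px = {m: 0 for m in range(1, n_mito + 1)}
    for site in sites:
        contact_px[site.mito_id] += len(site.pixels)
    rows = []
    for mito_id in range(1, n_mito + 1):
        comp = labels == mito_id
        perim = int(_perimeter_mask(comp).sum())
        cpx = contact_px[mito_id]
        frac = cpx / perim if perim else 0.0
        rows.append((mito_id, perim, cpx, frac, frac > 0.05))
    per_mito = pd.DataFrame(
        rows, columns=["mito_id", "perimeter_px", "contact_px", "contact_fraction", "coupled"]
    )
    frac_coupled = float(per_mito["coupled"].mean()) if n_mito else 0.0
    return ContactReport(per_mito, frac_coupled)


def nearest_distance_profile(
    pair: MaskPair, bins_nm=(0, 10, 20, 50, np.inf)
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-mitochondrion minimum perimeter-to-ER distance, binned.

    Returns (distances_nm, counts, bin_edges).  With an empty ER mask all
    distances are infinite (censored); they fall in the last bin if it is
    unbounded.
    """
    if not pair.mito.any():
        raise ValueError("mitochondria mask is empty")
    labels = label_mitochondria(pair)
    if pair.er.any():
        dist_nm = ndimage.distance_transform_edt(~pair.er) * pair.nm_per_px
    else:
        dist_nm = np.full(pair.er.shape, np.inf)
    mins = []
    for mito_id in range(1, labels.max() + 1):
        perim = _perimeter_mask(labels == mito_id)
        mins.append(float(dist_nm[perim].min()))
    distances = np.array(mins)
    edges = np.asarray(bins_nm, dtype=float)
    counts = np.array(
        [
            int(np.sum((distances >= lo) & (distances < hi)))
            if np.isfinite(hi)
            else int(np.sum(distances >= lo))
            for lo, hi in zip(edges[:-1], edges[1:])
        ]
    )
    return distances, counts, edges


def er_surface_to_volume(
    volume: np.ndarray, voxel_nm, method: str = "faces"
) -> pd.DataFrame:
    """Per-object surface area, volume, and SA/V of a 3D binary mask.

    ``voxel_nm`` is a scalar (isotropic) or length-3 spacing in nm.
    ``method`` is ``"faces"`` (exposed-face counting, exact for voxel
    objects) or ``"marching"`` (marching-cubes mesh area, better for
    smooth structures).  Volume is always the voxel count times voxel
    volume.  Returns a DataFrame with columns object_id, surface_nm2,
    volume_nm3, sav_per_nm (empty for an empty mask).
    """
    vol = np.asarray(volume).astype(bool)
    spacing = np.broadcast_to(np.asarray(voxel_nm, dtype=float), (3,))
    if np.any(spacing <= 0):
        raise ValueError("voxel size must be positive")
    if vol.ndim != 3:
        raise ValueError("volume must be 3D")
    cols = ["object_id", "surface_nm2", "volume_nm3", "sav_per_nm"]
    if not vol.any():
        return pd.DataFrame(columns=cols)
    labels, n_obj = ndimage.label(vol, structure=np.ones((3, 3, 3), dtype=bool))
    voxel_volume = float(np.prod(spacing))
    face_areas = [
        float(spacing[1] * spacing[2]),
        float(spacing[0] * spacing[2]),
        float(spacing[0] * spacing[1]),
    ]
    rows = []
    for obj in range(1, n_obj + 1):
        comp = labels == obj
        n_vox = int(comp.sum())
        v = n_vox * voxel_volume
        if method == "faces":
            # exposed faces per axis: 2*n_vox - 2*adjacent_pairs, weighted by face area
            sa = 0.0
            for axis, fa in enumerate(face_areas):
                sl_a = [slice(None)] * 3
                sl_b = [slice(None)] * 3
                sl_a[axis] = slice(None, -1)
                sl_b[axis] = slice(1, None)
                adj = int(np.sum(comp[tuple(sl_a)] & comp[tuple(sl_b)]))
                sa += (2 * n_vox - 2 * adj) * fa
        elif method == "marching":
            padded = np.pad(comp, 1).astype(float)
            verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(spacing))
            sa = float(measure.mesh_surface_area(verts, faces))
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append((obj, sa, v, sa / v))
    return pd.DataFrame(rows, columns=cols)


__all__ = [
    "MaskPair",
    "ContactSite",
    "ContactReport",
    "find_contact_sites",
    "classify_mitochondria",
    "nearest_distance_profile",
    "er_surface_to_volume",
    "label_mitochondria",
]
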