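"""Discretization and merged 3-D texture matrices.

SUV volumes are discretized with a fixed bin width anchored at SUV 0
(``bin = floor(SUV / 0.25) + 1``) and gray-level spatial structure is then
scored in three dimensions with 26-voxel connectivity into a *single merged*
matrix per texture family:

* GLCM — co-occurrences accumulated over all 13 unique direction pairs at
  Chebyshev distance 1, counted symmetrically (both orderings), summed into
  one matrix and normalized to sum 1;
* GLRLM — run lengths from the 13 directions pooled into one matrix;
* GLSZM — sizes of 26-connected equal-level zones (direction free);
* NGTDM — per-level counts and summed absolute differences from the mean of
  the in-VOI 26-neighborhood.

Merging directions into a single matrix (rather than averaging per-direction
features) makes every derived feature invariant to axis permutation on
isotropic grids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..pet_io import SUVImage, VOIMask

__all__ = [
    "DiscretizedImage",
    "TextureMatrix",
    "DIRECTIONS_13",
    "discretize",
    "glcm_merged",
    "glrlm_merged",
    "glszm",
    "ngtdm",
]

#: The 13 unique displacement vectors of the 26-neighborhood (one per
#: opposite pair), lexicographically positive.
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class DiscretizedImage:
    """Integer gray-level volume; bins are >= 1 inside the VOI, 0 outside."""

    bins: np.ndarray
    n_levels: int

    def levels_in(self, mask: np.ndarray) -> np.ndarray:
        return self.bins[mask]


def discretize(image: SUVImage, mask: VOIMask, bin_width: float = 0.25) -> DiscretizedImage:
    """Fixed-bin-size discretization anchored at SUV 0.

    ``bin = floor(SUV / bin_width) + 1`` inside the VOI, so SUV 0 falls in
    bin 1 and a value exactly on a bin edge lands in the upper bin.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    mask.check_paired(image)
    if mask.voxel_count == 0:
        raise ValueError("cannot discretize an empty VOI")
    bins = np.zeros(image.shape, dtype=np.int64)
    m = mask.values
    bins[m] = np.floor(image.values[m] / bin_width).astype(np.int64) + 1
    return DiscretizedImage(bins=bins, n_levels=int(bins[m].max()))


def _offset_slices(shape, off):
    src, dst = [], []
    for n, o in zip(shape, off):
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    return tuple(src), tuple(dst)


@dataclass
class TextureMatrix:
    """A merged texture matrix.

    ``matrix`` holds probabilities for GLCM (``normalized=True``), raw counts
    for GLRLM/GLSZM (rows = gray level, columns = run length / zone size),
    and for NGTDM a (levels x 2) array of per-level voxel counts and summed
    absolute neighborhood differences.
    """

    kind: str
    matrix: np.ndarray
    normalized: bool = False

    @property
    def n_levels(self) -> int:
        return self.matrix.shape[0]


def glcm_merged(disc: DiscretizedImage, mask: VOIMask) -> TextureMatrix:
    """Merged symmetric gray-level co-occurrence matrix, normalized to sum 1."""
    m = mask.values
    if int(m.sum()) < 2:
        raise ValueError("GLCM needs at least 2 in-VOI voxels (no neighbor pairs otherwise)")
    G = disc.n_levels
    counts = np.zeros((G, G), dtype=np.float64)
    bins = disc.bins
    for off in DIRECTIONS_13:
        src, dst = _offset_slices(bins.shape, off)
        valid = m[src] & m[dst]
        a = bins[src][valid] - 1
        b = bins[dst][valid] - 1
        np.add.at(counts, (a, b), 1.0)
        np.add.at(counts, (b, a), 1.0)
    total = counts.sum()
    if total == 0:
        raise ValueError("VOI voxels have no 26-connected neighbor pairs")
    return TextureMatrix("GLCM", counts / total, normalized=True)


def glrlm_merged(disc: DiscretizedImage, mask: VOIMask) -> TextureMatrix:
    """Gray-level run-length matrix pooled over the 13 directions (counts)."""
    m = mask.values
    if not m.any():
        raise ValueError("empty VOI")
    bins = disc.bins
    G = disc.n_levels
    shape = np.array(bins.shape)
    runs: dict[tuple[int, int], int] = {}
    coords = np.argwhere(m)
    for off in DIRECTIONS_13:
        offv = np.array(off)
        prev = coords - offv
        prev_ok = np.all((prev >= 0) & (prev < shape), axis=1)
        same_prev = np.zeros(len(coords), dtype=bool)
        pi = prev[prev_ok]
        ci = coords[prev_ok]
        same_prev[prev_ok] = (
            m[pi[:, 0], pi[:, 1], pi[:, 2]]
            & (bins[pi[:, 0], pi[:, 1], pi[:, 2]] == bins[ci[:, 0], ci[:, 1], ci[:, 2]])
        )
        starts = coords[~same_prev]
        levels = bins[starts[:, 0], starts[:, 1], starts[:, 2]]
        lengths = np.ones(len(starts), dtype=np.int64)
        cur = starts.copy()
        alive = np.arange(len(starts))
        while alive.size:
            nxt = cur[alive] + offv
            ok = np.all((nxt >= 0) & (nxt < shape), axis=1)
            cont = np.zeros(len(alive), dtype=bool)
            nok = nxt[ok]
            cont[ok] = (
                m[nok[:, 0], nok[:, 1], nok[:, 2]]
                & (bins[nok[:, 0], nok[:, 1], nok[:, 2]] == levels[alive[ok]])
            )
            lengths[alive[cont]] += 1
            cur[alive[cont]] += offv
            alive = alive[cont]
        for lev, ln in zip(levels, lengths):
            runs[(int(lev), int(ln))] = runs.get((int(lev), int(ln)), 0) + 1
    max_len = max(ln for _, ln in runs)
    mat = np.zeros((G, max_len), dtype=np.float64)
    for (lev, ln), c in runs.items():
        mat[lev - 1, ln - 1] = c
    return TextureMatrix("GLRLM", mat)


def glszm(disc: DiscretizedImage, mask: VOIMask) -> TextureMatrix:
    """Gray-level size-zone matrix from 26-connected equal-level zones (counts)."""
    m = mask.values
    if not m.any():
        raise ValueError("empty VOI")
    G = disc.n_levels
    zones: dict[tuple[int, int], int] = {}
    present = np.unique(disc.bins[m])
    for lev in present:
        lab, n = ndimage.label(m & (disc.bins == lev), structure=_STRUCT_26)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            zones[(int(lev), int(s))] = zones.get((int(lev), int(s)), 0) + 1
    max_size = max(s for _, s in zones)
    mat = np.zeros((G, max_size), dtype=np.float64)
    for (lev, s), c in zones.items():
        mat[lev - 1, s - 1] = c
    return TextureMatrix("GLSZM", mat)


def ngtdm(disc: DiscretizedImage, mask: VOIMask) -> TextureMatrix:
    """Neighborhood gray-tone difference matrix over in-VOI 26-neighborhoods.

    Returns a (levels x 2) matrix: column 0 the count ``n_i`` of valid voxels
    at level *i*, column 1 the summed absolute difference ``s_i`` between the
    voxel level and the mean level of its in-VOI neighbors.
    """
    m = mask.values
    if not m.any():
        raise ValueError("empty VOI")
    bins = disc.bins.astype(np.float64)
    kernel = _STRUCT_26.astype(np.float64).copy()
    kernel[1, 1, 1] = 0.0
    nb_sum = ndimage.convolve(bins * m, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.convolve(m.astype(np.float64), kernel, mode="constant", cval=0.0)
    valid = m & (nb_cnt > 0)
    G = disc.n_levels
    mat = np.zeros((G, 2), dtype=np.float64)
    lev = disc.bins[valid]
    diff = np.abs(bins[valid] - nb_sum[valid] / nb_cnt[valid])
    np.add.at(mat[:, 0], lev - 1, 1.0)
    np.add.at(mat[:, 1], lev - 1, diff)
    return TextureMatrix("NGTDM", mat)
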