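"""Pathology detection: thresholding, colocalisation, fragment extraction.

The detection chain mirrors the quantification workflow for pSer-129-αSyn
staining in neuron cultures: each channel is binarised with a threshold
(Otsu by default, manual override available), connected components of the
pSyn mask are kept only if they colocalise with the βIII-tubulin neurite
mask and exceed a minimum area (8 µm² by default — components *below* 8 µm²
are excluded, the boundary is kept), and surviving components become
:class:`Fragment` records with area, geodesic skeleton length, centroid,
chamber and barrier distance.  Fragments in the reverse chamber can further
be classified CFSE-positive (transported along forward-originating axons)
or CFSE-negative (transferred to reverse-native neurons).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import shortest_path
from skimage.filters import threshold_otsu
from skimage.morphology import disk, skeletonize

from .geometry import NEAR_BAND_UM, DeviceGeometry, FieldImage, distance_to_barrier

__all__ = [
    "SegmentationParams",
    "Fragment",
    "threshold_mask",
    "extract_fragments",
    "fragment_length",
    "classify_cfse",
    "fragments_to_table",
]

log = logging.getLogger(__name__)

_SQRT2 = math.sqrt(2.0)


@dataclass
class SegmentationParams:
    """Tunable detection parameters.

    Threshold levels for this assay are typically optimised manually per
    dataset; the default here is per-image Otsu with an optional manual
    level, and the applied level is always logged so runs are auditable.
    """

    threshold_method: str = "otsu"  # "otsu" | "manual"
    manual_level: float | None = None
    min_area_um2: float = 8.0
    coloc_fraction: float = 0.5
    dilation_radius_px: int = 1
    connectivity: int = 8  # 4 or 8
    cfse_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "manual"):
            raise ValueError("threshold_method must be 'otsu' or 'manual'")
        if self.threshold_method == "manual" and self.manual_level is None:
            raise ValueError("manual threshold requires manual_level")
        if not self.min_area_um2 > 0:
            raise ValueError("min_area_um2 must be > 0")
        for frac in (self.coloc_fraction, self.cfse_fraction):
            if not (0 < frac <= 1):
                raise ValueError("overlap fractions must be in (0, 1]")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class Fragment:
    """One connected pSyn-positive object that passed all filters."""

    pixels: np.ndarray  # (n, 2) int array of (row, col)
    area_um2: float
    length_um: float | None
    centroid_um: tuple[float, float]  # device (x, y), µm
    centroid_px: tuple[float, float]  # (row, col), pixel-index space
    chamber: str | None
    distance_um: float
    on_neurite: bool
    pixel_size: float
    cfse_status: str = "unevaluated"  # "positive" | "negative" | "unevaluated"
    image_id: str = ""


def _as_array(image) -> np.ndarray:
    return image.data if isinstance(image, FieldImage) else np.asarray(image)


def threshold_mask(image, params: SegmentationParams) -> np.ndarray:
    """Binarise ``image``; True where intensity passes the threshold.

    With ``method="manual"`` the mask is ``intensity >= manual_level``.
    With ``method="otsu"`` the level maximises inter-class variance and the
    mask is ``intensity > level`` (the Otsu level itself belongs to the
    background class).  A constant image cannot be thresholded by Otsu and
    yields an empty mask with a warning rather than an error.
    """
    data = _as_array(image)
    if data.size == 0:
        raise ValueError("image is empty")
    if params.threshold_method == "manual":
        level = float(params.manual_level)
        mask = data >= level
    else:
        if np.ptp(data) == 0:
            warnings.warn(
                "constant image: Otsu threshold undefined, returning empty mask",
                RuntimeWarning,
                stacklevel=2,
            )
            return np.zeros(data.shape, dtype=bool)
        level = float(threshold_otsu(data))
        mask = data > level
    log.info("threshold_mask: method=%s level=%g", params.threshold_method, level)
    return mask


def applied_threshold(image, params: SegmentationParams) -> float | None:
    """The intensity level :func:`threshold_mask` applies (None if undefined)."""
    data = _as_array(image)
    if params.threshold_method == "manual":
        return float(params.manual_level)
    if np.ptp(data) == 0:
        return None
    return float(threshold_otsu(data))


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)


def min_area_pixels(min_area_um2: float, pixel_size: float) -> int:
    """Minimum pixel count for the area filter.

    Converted by ceiling so that no fragment strictly below the µm² cutoff
    can ever pass (8 µm² at 0.325 µm/px → ceil(75.74) = 76 px).
    """
    return int(math.ceil(min_area_um2 / pixel_size**2 - 1e-9))


def extract_fragments(
    psyn_mask: np.ndarray,
    tubulin_mask: np.ndarray,
    geometry: DeviceGeometry,
    params: SegmentationParams,
    *,
    pixel_size: float | None = None,
    offset: tuple[float, float] = (0.0, 0.0),
    image_id: str = "",
    compute_length: bool = True,
) -> list[Fragment]:
    """Connected components of ``psyn_mask`` that survive both filters.

    A component is kept iff (a) the fraction of its pixels overlapping the
    neurite (βIII-tubulin) mask, dilated by ``dilation_radius_px``, is at
    least ``coloc_fraction`` and (b) its area is at least ``min_area_um2``
    (>= comparison: a fragment of exactly 8 µm² is kept).

    ``pixel_size``/``offset`` place the masks in device coordinates;
    ``pixel_size`` defaults to the geometry's calibration.
    """
    psyn_mask = np.asarray(psyn_mask, dtype=bool)
    tubulin_mask = np.asarray(tubulin_mask, dtype=bool)
    if psyn_mask.shape != tubulin_mask.shape:
        raise ValueError("psyn and tubulin masks must share shape")
    px = geometry.pixel_size if pixel_size is None else float(pixel_size)

    if params.dilation_radius_px > 0:
        neurite = ndimage.binary_dilation(tubulin_mask, disk(params.dilation_radius_px))
    else:
        neurite = tubulin_mask

    labels, n = ndimage.label(psyn_mask, structure=_structure(params.connectivity))
    if n == 0:
        return []
    min_px = min_area_pixels(params.min_area_um2, px)

    counts = np.bincount(labels.ravel(), minlength=n + 1)
    overlap_counts = np.bincount(
        labels.ravel(), weights=neurite.ravel().astype(float), minlength=n + 1
    )
    fragments: list[Fragment] = []
    slices = ndimage.find_objects(labels)
    for lab in range(1, n + 1):
        npx = int(counts[lab])
        frac = overlap_counts[lab] / npx
        if frac < params.coloc_fraction - 1e-12 or npx < min_px:
            continue
        sl = slices[lab - 1]
        local = labels[sl] == lab
        rr, cc = np.nonzero(local)
        pixels = np.column_stack([rr + sl[0].start, cc + sl[1].start])
        crow = pixels[:, 0].mean()
        ccol = pixels[:, 1].mean()
        cx = offset[0] + (ccol + 0.5) * px
        cy = offset[1] + (crow + 0.5) * px
        fragments.append(
            Fragment(
                pixels=pixels,
                area_um2=npx * px**2,
                length_um=_geodesic_length(local, px) if compute_length else None,
                centroid_um=(cx, cy),
                centroid_px=(float(crow), float(ccol)),
                chamber=geometry.chamber_of(cx),
                distance_um=distance_to_barrier(cx, geometry),
                on_neurite=True,
                pixel_size=px,
                image_id=image_id,
            )
        )
    return fragments


def _geodesic_length(local_mask: np.ndarray, pixel_size: float) -> float:
    """Longest geodesic through the morphological skeleton of a mask, µm.

    Skeleton pixels form a graph with 8-neighbour edges weighted 1 (axial)
    or √2 (diagonal) pixels; the length is the largest pairwise shortest
    path over that graph.
    """
    if local_mask.sum() <= 1:
        return 0.0
    pad = np.pad(local_mask, 1)
    skel = skeletonize(pad)
    pts = np.argwhere(skel)
    if len(pts) <= 1:
        return 0.0
    index = -np.ones(skel.shape, dtype=np.int64)
    index[pts[:, 0], pts[:, 1]] = np.arange(len(pts))
    rows, cols, weights = [], [], []
    for dr, dc in ((-1, -1), (-1, 0), (-1, 1), (0, -1)):
        nr = pts[:, 0] + dr
        nc = pts[:, 1] + dc
        ok = (nr >= 0) & (nc >= 0) & (nr < skel.shape[0]) & (nc < skel.shape[1])
        j = np.full(len(pts), -1, dtype=np.int64)
        j[ok] = index[nr[ok], nc[ok]]
        sel = j >= 0
        i = np.arange(len(pts))[sel]
        rows.append(i)
        cols.append(j[sel])
        w = _SQRT2 if dr != 0 and dc != 0 else 1.0
        weights.append(np.full(sel.sum(), w))
    if not rows or sum(len(r) for r in rows) == 0:
        return 0.0
    i = np.concatenate(rows)
    j = np.concatenate(cols)
    w = np.concatenate(weights)
    n = len(pts)
    graph = coo_matrix((w, (i, j)), shape=(n, n)).tocsr()
    # fragments are small, so the full all-pairs search is affordable and
    # stays correct for skeletons with cycles
    dist = shortest_path(graph, method="D", directed=False)
    finite = dist[np.isfinite(dist)]
    return float(finite.max()) * pixel_size if finite.size else 0.0


def fragment_length(fragment: Fragment) -> float:
    """Geodesic skeleton length of a fragment in µm (0 for a single pixel)."""
    pixels = np.asarray(fragment.pixels)
    if len(pixels) == 0:
        raise ValueError("fragment has no pixels")
    r0, c0 = pixels.min(axis=0)
    r1, c1 = pixels.max(axis=0)
    mask = np.zeros((r1 - r0 + 1, c1 - c0 + 1), dtype=bool)
    mask[pixels[:, 0] - r0, pixels[:, 1] - c0] = True
    return _geodesic_length(mask, fragment.pixel_size)


def classify_cfse(
    fragments: list[Fragment],
    cfse_mask: np.ndarray,
    params: SegmentationParams,
    band_um: tuple[float, float] = NEAR_BAND_UM,
) -> list[Fragment]:
    """Set ``cfse_status`` on reverse-chamber fragments.

    A fragment is *positive* (transported pathology, on a forward-originating
    axon) iff the fraction of its pixels overlapping the thresholded CFSE
    mask is at least ``cfse_fraction``; otherwise *negative* (transferred).
    Fragments whose centroid lies outside ``band_um`` — beyond the distance
    at which the CFSE signal has decayed away — stay ``unevaluated``.
    """
    cfse_mask = np.asarray(cfse_mask, dtype=bool)
    d0, d1 = band_um
    for frag in fragments:
        if not (d0 <= frag.distance_um <= d1):
            frag.cfse_status = "unevaluated"
            continue
        inside = cfse_mask[frag.pixels[:, 0], frag.pixels[:, 1]]
        frac = inside.mean()
        frag.cfse_status = (
            "positive" if frac >= params.cfse_fraction - 1e-12 else "negative"
        )
    return fragments


def fragments_to_table(fragments: list[Fragment]) -> pd.DataFrame:
    """Flatten fragments to the standard CSV columns."""
    rows = [
        {
            "id": i,
            "image_id": f.image_id,
            "chamber": f.chamber if f.chamber is not None else "barrier",
            "area_um2": f.area_um2,
            "length_um": f.length_um if f.length_um is not None else np.nan,
            "centroid_x_um": f.centroid_um[0],
            "centroid_y_um": f.centroid_um[1],
            "distance_um": f.distance_um,
            "on_neurite": f.on_neurite,
            "cfse_status": f.cfse_status,
        }
        for i, f in enumerate(fragments)
    ]
    columns = [
        "id", "image_id", "chamber", "area_um2", "length_um",
        "centroid_x_um", "centroid_y_um", "distance_um", "on_neurite",
        "cfse_status",
    ]
    return pd.DataFrame(rows, columns=columns)
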