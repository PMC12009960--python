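"""Device coordinate frame, geometry and region-of-interest construction.

The two-chamber microfluidic device is described in a single coordinate frame
with x running along the microchannel axis and y across it, in micrometres.
By default the microchannel barrier occupies ``[0, 1000]`` µm (the chambers
are spaced 1 mm apart) with the *forward* chamber on the low-x side, so that
retrograde motion — reverse chamber toward forward chamber — has dx/dt < 0.

Images are placed in device coordinates through their ``offset`` field; pixel
``(i, j)`` (row, column; 0-based) has its centre at
``offset + (j + 0.5, i + 0.5) * pixel_size``.  ROI distance intervals are
closed on both ends.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "DeviceGeometry",
    "RoiBand",
    "FieldImage",
    "distance_to_barrier",
    "make_roi_mask",
    "load_geometry",
    "save_geometry",
]

#: Default magnification calibration in µm per pixel.  The imaging setup
#: (20x objective, 6.5 µm camera pixels) conventionally gives 0.325 µm/px,
#: but the calibration is configuration and must be supplied for real data.
DEFAULT_PIXEL_SIZE = 0.325

CHANNELS = ("psyn", "tubulin", "cfse", "movie_frame")


@dataclass
class DeviceGeometry:
    """Two-chamber device layout: barrier, lanes, leaf dead-ends.

    Parameters
    ----------
    barrier_x_range:
        Closed x-interval occupied by the microchannel barrier, µm.
    forward_side:
        ``"left"`` if the forward chamber lies at x below the barrier
        (the default, matching forward→reverse axon growth along +x),
        ``"right"`` for the mirrored device.
    channel_lanes:
        y-intervals (µm) of individual microchannel lanes, pairwise disjoint.
    leaf_polygons:
        Polygons (sequences of (x, y) vertices, µm) of the leaf-shaped
        dead-end features, excluded from kymograph projection.  They must
        lie within the barrier x-range.
    pixel_size:
        Default µm/px calibration for images analysed against this geometry.
    """

    barrier_x_range: tuple[float, float] = (0.0, 1000.0)
    forward_side: str = "left"
    channel_lanes: list[tuple[float, float]] = field(default_factory=list)
    leaf_polygons: list[np.ndarray] = field(default_factory=list)
    pixel_size: float = DEFAULT_PIXEL_SIZE

    def __post_init__(self) -> None:
        lo, hi = self.barrier_x_range
        if not hi > lo:
            raise ValueError("barrier length must be > 0")
        if self.forward_side not in ("left", "right"):
            raise ValueError("forward_side must be 'left' or 'right'")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        lanes = sorted(self.channel_lanes)
        for (a0, a1), (b0, b1) in zip(lanes, lanes[1:]):
            if not a1 > a0 or b0 < a1:
                raise ValueError("channel lanes must be pairwise disjoint")
        polys = []
        for poly in self.leaf_polygons:
            arr = np.asarray(poly, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 3:
                raise ValueError("leaf polygons must be (N>=3, 2) arrays")
            if arr[:, 0].min() < lo - 1e-9 or arr[:, 0].max() > hi + 1e-9:
                raise ValueError("leaf polygons must lie within the barrier x-range")
            polys.append(arr)
        self.leaf_polygons = polys

    # -- chamber predicates -------------------------------------------------

    def chamber_of(self, x: float) -> str | None:
        """Chamber containing device x-coordinate ``x``.

        Returns ``"forward"``, ``"reverse"`` or ``None`` for points inside
        the barrier x-range.
        """
        lo, hi = self.barrier_x_range
        if x < lo:
            return "forward" if self.forward_side == "left" else "reverse"
        if x > hi:
            return "reverse" if self.forward_side == "left" else "forward"
        return None

    def mirrored(self) -> "DeviceGeometry":
        """Same device with forward and reverse chambers swapped."""
        side = "right" if self.forward_side == "left" else "left"
        return replace(self, forward_side=side)


@dataclass(frozen=True)
class RoiBand:
    """A chamber-side band of barrier distances, closed interval in µm.

    The main pathology analysis uses [400, 1600] µm (central chamber area);
    near-channel and CFSE analyses use [0, 400] µm.
    """

    chamber: str
    distance_range: tuple[float, float] = (400.0, 1600.0)

    def __post_init__(self) -> None:
        if self.chamber not in ("forward", "reverse"):
            raise ValueError("chamber must be 'forward' or 'reverse'")
        d0, d1 = self.distance_range
        if not (0 <= d0 < d1):
            raise ValueError("need 0 <= d_min < d_max")


#: Band used for the main chamber quantification.
MAIN_BAND_UM = (400.0, 1600.0)
#: Band used for near-channel and CFSE transport/transfer analysis.
NEAR_BAND_UM = (0.0, 400.0)


@dataclass
class FieldImage:
    """A single-channel 2D image placed in device coordinates.

    ``data`` is indexed ``[row, col]``; columns map to device x and rows to
    device y.  ``offset`` is the device coordinate (x, y) of the image
    origin (the corner of pixel (0, 0)), in µm.
    """

    data: np.ndarray
    channel: str
    pixel_size: float = DEFAULT_PIXEL_SIZE
    offset: tuple[float, float] = (0.0, 0.0)
    image_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or min(self.data.shape) < 1:
            raise ValueError("image must be 2D with dimensions >= 1x1")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def x_centers(self) -> np.ndarray:
        """Device x-coordinates of pixel-column centres, µm."""
        return self.offset[0] + (np.arange(self.shape[1]) + 0.5) * self.pixel_size

    def y_centers(self) -> np.ndarray:
        """Device y-coordinates of pixel-row centres, µm."""
        return self.offset[1] + (np.arange(self.shape[0]) + 0.5) * self.pixel_size


# -- operations --------------------------------------------------------------


def distance_to_barrier(point_um, geometry: DeviceGeometry):
    """Perpendicular distance (µm) from a point to the nearest barrier edge.

    ``point_um`` may be a scalar x-coordinate, an (x, y) pair, or an array
    of x-coordinates.  Points inside the barrier x-range are at distance 0.
    Total function: never raises for finite input.
    """
    p = np.asarray(point_um, dtype=float)
    if p.ndim == 1 and p.shape == (2,):
        x = p[0]
    else:
        x = p
    lo, hi = geometry.barrier_x_range
    d = np.maximum(np.maximum(lo - x, x - hi), 0.0)
    return float(d) if np.isscalar(x) or getattr(x, "ndim", 0) == 0 else d


def make_roi_mask(
    geometry: DeviceGeometry, band: RoiBand, image: FieldImage
) -> np.ndarray:
    """Boolean mask of pixels whose centres fall in the requested band.

    A pixel is included iff its centre lies on the requested chamber side
    and its barrier distance d satisfies ``d_min <= d <= d_max`` (closed
    interval).  An empty mask is returned with a warning, not an error.
    """
    x = image.x_centers()
    d = distance_to_barrier(x, geometry)
    lo, hi = geometry.barrier_x_range
    if band.chamber == ("forward" if geometry.forward_side == "left" else "reverse"):
        on_side = x < lo
    else:
        on_side = x > hi
    d0, d1 = band.distance_range
    cols = on_side & (d >= d0) & (d <= d1)
    mask = np.broadcast_to(cols, image.shape).copy()
    if not mask.any():
        warnings.warn(
            f"empty ROI mask for chamber={band.chamber} band={band.distance_range}",
            RuntimeWarning,
            stacklevel=2,
        )
    return mask


# -- geometry file I/O --------------------------------------------------------


def save_geometry(geometry: DeviceGeometry, path) -> None:
    payload = {
        "barrier_x_range": list(geometry.barrier_x_range),
        "forward_side": geometry.forward_side,
        "channel_lanes": [list(l) for l in geometry.channel_lanes],
        "leaf_polygons": [np.asarray(p).tolist() for p in geometry.leaf_polygons],
        "pixel_size": geometry.pixel_size,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_geometry(path) -> DeviceGeometry:
    """Read a geometry JSON file (units µm throughout)."""
    payload = json.loads(Path(path).read_text())
    return DeviceGeometry(
        barrier_x_range=tuple(payload["barrier_x_range"]),
        forward_side=payload.get("forward_side", "left"),
        channel_lanes=[tuple(l) for l in payload.get("channel_lanes", [])],
        leaf_polygons=[np.asarray(p, float) for p in payload.get("leaf_polygons", [])],
        pixel_size=float(payload["pixel_size"]),
    )
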