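"""Ground-truthed synthetic microscopy for the two-chamber assay.

Everything downstream — segmentation, quantification, kymograph tracing —
is validated against images produced here, because no raw images of the
original cultures are publicly deposited.  The generator emulates the
statistical structure the analysis assumes:

* βIII-tubulin neurite networks as persistent random walks rasterised at
  1–3 px width, plus soma blobs;
* pSer-129 pathology as elongated high-intensity segments placed *on*
  neurite skeletons, whose expected total area per 0.25 mm² grows linearly
  in time (default slope 53.828 µm² per week, intercept −137.706, truncated
  at zero), with a per-device multiplicative log-normal factor (default
  CV 30%) carrying the device-to-device scatter;
* sub-threshold (< 8 µm²) on-neurite specks and soft-edged off-neurite
  background blobs, so the area and colocalisation filters are exercised;
* a CFSE channel whose intensity on forward-originating neurites decays
  with distance from the microchannel barrier (linear to zero at 400 µm by
  default, "proportional" decay; exponential available);
* single-channel microchannel time-lapses with Gaussian puncta moving at
  constant velocity (retrograde ≈ −1.1 µm/s), 5 s frame interval over
  10 min by default.

All randomness flows from ``SynthConfig.seed`` through per-purpose child
seeds, so identical configurations give bit-identical images and truth.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.morphology import disk

from .geometry import DeviceGeometry, FieldImage, distance_to_barrier

__all__ = [
    "NeuriteParams",
    "FragmentGeom",
    "BackgroundStaining",
    "NoiseModel",
    "CfseDecay",
    "MovieParams",
    "PunctumSpec",
    "SynthConfig",
    "NeuriteTruth",
    "TruthFragment",
    "TruthTrace",
    "DeviceData",
    "StudyDataset",
    "generate_neurite_field",
    "generate_pathology_image",
    "generate_cfse_channel",
    "generate_channel_timelapse",
    "generate_study",
    "default_study_schedule",
    "make_retrograde_puncta",
    "save_config",
    "load_config",
]


# --------------------------------------------------------------------------
# configuration


@dataclass
class NeuriteParams:
    count: int = 60
    step_um: float = 4.0
    turn_sigma_rad: float = 0.25
    length_range_um: tuple[float, float] = (100.0, 500.0)
    width_px_choices: tuple[int, ...] = (1, 2, 3)
    intensity: float = 600.0
    #: fraction of neurites flagged as forward-originating (relevant for
    #: reverse-chamber fields, where they carry the CFSE label)
    forward_fraction: float = 0.5


@dataclass
class FragmentGeom:
    """Pathology fragment geometry: elongated, ~1 µm wide, 2–20 µm long."""

    length_range_um: tuple[float, float] = (2.0, 20.0)
    width_um: float = 1.0
    intensity: float = 3000.0


@dataclass
class BackgroundStaining:
    """Low-intensity soft-edged non-specific blobs, off neurites."""

    density_per_mm2: float = 40.0
    radius_um_range: tuple[float, float] = (1.0, 3.0)
    intensity: float = 350.0


@dataclass
class NoiseModel:
    """Poisson shot noise on the signal plus Gaussian read noise."""

    baseline: float = 100.0
    poisson: bool = True
    read_noise_sigma: float = 8.0

    @classmethod
    def noise_free(cls) -> "NoiseModel":
        return cls(baseline=0.0, poisson=False, read_noise_sigma=0.0)


@dataclass
class CfseDecay:
    mode: str = "linear"  # "linear" | "exponential"
    scale_um: float = 400.0
    max_intensity: float = 2000.0

    def profile(self, distance_um: np.ndarray) -> np.ndarray:
        d = np.asarray(distance_um, dtype=float)
        if self.mode == "linear":
            rel = np.clip(1.0 - d / self.scale_um, 0.0, 1.0)
        elif self.mode == "exponential":
            rel = np.exp(-d / self.scale_um)
        else:
            raise ValueError("cfse decay mode must be 'linear' or 'exponential'")
        return self.max_intensity * rel


@dataclass
class MovieParams:
    x_range_um: tuple[float, float] = (0.0, 1000.0)
    lane_width_um: float = 10.0
    spot_sigma_um: float = 0.8
    spot_intensity: float = 2000.0
    jitter_sigma_um: float = 0.2


@dataclass
class PunctumSpec:
    x0_um: float
    speed_um_s: float
    t0_s: float = 0.0


@dataclass
class SynthConfig:
    """Full generator parameterisation; defaults are the study conditions."""

    seed: int = 0
    field_size_um: tuple[float, float] = (665.6, 665.6)
    pixel_size_um: float = 0.325
    neurites: NeuriteParams = field(default_factory=NeuriteParams)
    soma_density_per_mm2: float = 25.0
    # pathology growth, per 0.25 mm² per week since PFF seeding
    growth_slope: float = 53.828
    growth_intercept: float = -137.706
    count_slope: float = 12.941
    count_intercept: float = -16.656
    growth_target: str = "area"  # "area" | "count"
    fragment_geom: FragmentGeom = field(default_factory=FragmentGeom)
    n_subthreshold: int = 6
    background: BackgroundStaining = field(default_factory=BackgroundStaining)
    cfse: CfseDecay = field(default_factory=CfseDecay)
    #: fraction of seeded pathology placed on reverse-native neurites
    #: (cell-to-cell transfer); the remainder sits on forward-originating
    #: axons and is CFSE-positive
    transfer_fraction: float = 0.2
    #: background pathology level of unseeded control devices, µm²/0.25 mm²
    control_area_per_qmm2: float = 35.0
    device_cv: float = 0.30
    noise: NoiseModel = field(default_factory=NoiseModel)
    # time-lapse parameters
    puncta: list[PunctumSpec] = field(default_factory=list)
    frame_interval_s: float = 5.0
    duration_s: float = 600.0
    movie: MovieParams = field(default_factory=MovieParams)

    def __post_init__(self) -> None:
        if self.growth_target not in ("area", "count"):
            raise ValueError("growth_target must be 'area' or 'count'")
        for rate in (
            self.soma_density_per_mm2,
            self.background.density_per_mm2,
            self.device_cv,
            self.control_area_per_qmm2,
        ):
            if rate < 0:
                raise ValueError("rates must be >= 0")
        if not (0 <= self.transfer_fraction <= 1):
            raise ValueError("transfer_fraction must be in [0, 1]")
        for p in self.puncta:
            if not np.isfinite(p.speed_um_s):
                raise ValueError("punctum speeds must be finite")

    def shape_px(self) -> tuple[int, int]:
        w, h = self.field_size_um
        return (int(round(h / self.pixel_size_um)), int(round(w / self.pixel_size_um)))

    def expected_area_per_qmm2(self, t_weeks: float) -> float:
        """Expected pathology area per 0.25 mm² at ``t_weeks``, before noise."""
        return max(0.0, self.growth_slope * t_weeks + self.growth_intercept)

    def expected_count_per_qmm2(self, t_weeks: float) -> float:
        return max(0.0, self.count_slope * t_weeks + self.count_intercept)


# --------------------------------------------------------------------------
# truth containers


@dataclass
class Neurite:
    path_px: np.ndarray  # ordered (n, 2) int (row, col), in-bounds
    forward_originating: bool
    width_px: int


@dataclass
class NeuriteTruth:
    neurites: list[Neurite]
    skeleton_mask: np.ndarray
    width_mask: np.ndarray
    shape: tuple[int, int]
    pixel_size: float
    offset: tuple[float, float]

    def total_skeleton_length_um(self) -> float:
        """Geometric length of all truth polylines (µm, diagonal-aware)."""
        total = 0.0
        for n in self.neurites:
            if len(n.path_px) < 2:
                continue
            steps = np.diff(n.path_px.astype(float), axis=0)
            total += np.sqrt((steps**2).sum(axis=1)).sum() * self.pixel_size
        return total


@dataclass
class TruthFragment:
    pixels: np.ndarray  # (n, 2) int (row, col)
    area_um2: float
    on_neurite: bool
    cfse_positive: bool
    sub_threshold: bool


@dataclass
class TruthTrace:
    x0_um: float
    speed_um_s: float
    t0_s: float
    times_s: np.ndarray
    positions_um: np.ndarray  # NaN while outside the field of view
    exit_time_s: float | None
    direction: str


# --------------------------------------------------------------------------
# helpers

_SALT_NEURITE, _SALT_PATHOLOGY, _SALT_CFSE, _SALT_MOVIE = 101, 202, 303, 404


def _rng(cfg: SynthConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, salt]))


def _apply_noise(signal: np.ndarray, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    img = np.clip(signal + noise.baseline, 0, None)
    if noise.poisson:
        img = rng.poisson(img).astype(float)
    if noise.read_noise_sigma > 0:
        img = img + rng.normal(0.0, noise.read_noise_sigma, img.shape)
    return np.clip(np.round(img), 0, 65535).astype(np.uint16)


def _gaussian_spot(canvas: np.ndarray, row: float, col: float, sigma_px: float, amp: float) -> None:
    """Add a Gaussian spot in place, evaluated on a local patch only."""
    r = int(np.ceil(4 * sigma_px))
    r0 = max(0, int(np.floor(row)) - r)
    r1 = min(canvas.shape[0], int(np.ceil(row)) + r + 1)
    c0 = max(0, int(np.floor(col)) - r)
    c1 = min(canvas.shape[1], int(np.ceil(col)) + r + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    canvas[r0:r1, c0:c1] += amp * np.exp(
        -((rr - row) ** 2 + (cc - col) ** 2) / (2 * sigma_px**2)
    )


# --------------------------------------------------------------------------
# neurite field


def generate_neurite_field(
    cfg: SynthConfig,
    geometry: DeviceGeometry | None = None,
    *,
    offset: tuple[float, float] = (0.0, 0.0),
    rng: np.random.Generator | None = None,
) -> tuple[FieldImage, NeuriteTruth]:
    """Render the βIII-tubulin channel and record the neurite skeletons.

    Neurites are persistent random walks: heading changes by N(0, σ_turn)
    per ``step_um`` step.  Forward-originating neurites (the first
    ``forward_fraction`` of the population) enter from the barrier-side
    edge of the field heading inward; the rest start anywhere with uniform
    heading.  Zero neurites is allowed and yields a noise-only field.
    """
    rng = _rng(cfg, _SALT_NEURITE) if rng is None else rng
    px = cfg.pixel_size_um
    shape = cfg.shape_px()
    h_um = shape[0] * px
    w_um = shape[1] * px

    n_forward = int(round(cfg.neurites.count * cfg.neurites.forward_fraction))
    neurites: list[Neurite] = []
    skeleton = np.zeros(shape, dtype=bool)
    for i in range(cfg.neurites.count):
        forward = i < n_forward
        length = rng.uniform(*cfg.neurites.length_range_um)
        if forward:
            start = np.array([rng.uniform(0, 0.05 * w_um), rng.uniform(0, h_um)])
            angle = rng.normal(0.0, 0.3)  # pointing away from the barrier edge
        else:
            start = np.array([rng.uniform(0, w_um), rng.uniform(0, h_um)])
            angle = rng.uniform(0, 2 * np.pi)
        n_steps = max(1, int(round(length / cfg.neurites.step_um)))
        pts = [start]
        pos = start.copy()
        for _ in range(n_steps):
            angle += rng.normal(0.0, cfg.neurites.turn_sigma_rad)
            pos = pos + cfg.neurites.step_um * np.array([np.cos(angle), np.sin(angle)])
            pts.append(pos.copy())
        path = _rasterize_polyline(np.array(pts), px, shape)
        if len(path) == 0:
            continue
        width = int(rng.choice(cfg.neurites.width_px_choices))
        neurites.append(Neurite(path_px=path, forward_originating=forward, width_px=width))
        skeleton[path[:, 0], path[:, 1]] = True

    width_mask = np.zeros(shape, dtype=bool)
    for n in neurites:
        radius = n.width_px // 2
        m = np.zeros(shape, dtype=bool)
        m[n.path_px[:, 0], n.path_px[:, 1]] = True
        if radius > 0:
            m = ndimage.binary_dilation(m, disk(radius))
        width_mask |= m

    canvas = np.zeros(shape, dtype=float)
    canvas[width_mask] = cfg.neurites.intensity
    area_mm2 = shape[0] * shape[1] * px**2 / 1e6
    n_somas = rng.poisson(cfg.soma_density_per_mm2 * area_mm2)
    for _ in range(n_somas):
        r = rng.uniform(0, shape[0])
        c = rng.uniform(0, shape[1])
        rad = rng.uniform(4.0, 8.0) / px
        rr, cc = draw_disk((r, c), rad, shape=shape)
        canvas[rr, cc] = cfg.neurites.intensity * 1.2
    canvas = ndimage.gaussian_filter(canvas, 1.0)
    image = FieldImage(
        data=_apply_noise(canvas, cfg.noise, rng),
        channel="tubulin",
        pixel_size=px,
        offset=offset,
    )
    truth = NeuriteTruth(
        neurites=neurites,
        skeleton_mask=skeleton,
        width_mask=width_mask,
        shape=shape,
        pixel_size=px,
        offset=offset,
    )
    return image, truth


def _rasterize_polyline(pts_um: np.ndarray, px: float, shape: tuple[int, int]) -> np.ndarray:
    """Dense ordered pixel path of a polyline, clipped to the field."""
    cols = np.round(pts_um[:, 0] / px - 0.5).astype(int)
    rows = np.round(pts_um[:, 1] / px - 0.5).astype(int)
    path: list[tuple[int, int]] = []
    for k in range(len(rows) - 1):
        rr, cc = draw_line(rows[k], cols[k], rows[k + 1], cols[k + 1])
        seg = list(zip(rr, cc))
        if k > 0 and seg:
            seg = seg[1:]  # avoid duplicating shared vertices
        path.extend(seg)
    keep = [
        (r, c) for r, c in path if 0 <= r < shape[0] and 0 <= c < shape[1]
    ]
    return np.asarray(keep, dtype=int).reshape(-1, 2)


# --------------------------------------------------------------------------
# pathology channel


def generate_pathology_image(
    cfg: SynthConfig,
    truth: NeuriteTruth,
    t_weeks: float,
    *,
    device_factor: float = 1.0,
    seeded: bool = True,
    rng: np.random.Generator | None = None,
) -> tuple[FieldImage, list[TruthFragment]]:
    """Render the pSer-129 channel with known fragment truth.

    With ``growth_target="area"`` fragments are placed on neurite skeletons
    until the summed truth area matches the expected
    ``max(0, slope·t + intercept) · device_factor`` µm² per 0.25 mm²
    (the last fragment is stochastically rejected so the expectation is
    unbiased).  ``"count"`` mode instead draws a Poisson number of
    fragments matching the count-growth curve.  Unseeded fields use the
    constant control background level.  Sub-threshold specks and
    off-neurite blobs are added whenever any pathology is expected.
    """
    if t_weeks < 0:
        raise ValueError("t_weeks must be >= 0")
    rng = _rng(cfg, _SALT_PATHOLOGY) if rng is None else rng
    px = truth.pixel_size
    shape = truth.shape
    field_mm2 = shape[0] * shape[1] * px**2 / 1e6

    placer = _FragmentPlacer(cfg, truth, rng)
    fragments: list[TruthFragment] = []

    if seeded:
        expected_area = cfg.expected_area_per_qmm2(t_weeks) * device_factor
        expected_count = cfg.expected_count_per_qmm2(t_weeks) * device_factor
    else:
        expected_area = cfg.control_area_per_qmm2 * device_factor
        expected_count = 0.0

    if cfg.growth_target == "area" or not seeded:
        # the growth curve describes what the assay measures: area of
        # filter-passing (>= 8 µm², on-neurite) fragments.  Short draws
        # that rasterise below the cutoff are kept as distractors but do
        # not advance the target.
        target_um2 = expected_area * field_mm2 / 0.25
        placer.set_area_target(target_um2)
        cum = 0.0
        last_counted: TruthFragment | None = None
        budget = int(target_um2 / 4) + 60
        while cum < target_um2 and budget > 0:
            budget -= 1
            length = rng.uniform(*cfg.fragment_geom.length_range_um)
            frag = placer.place(length)
            if frag is None:
                break
            fragments.append(frag)
            if not frag.sub_threshold:
                cum += frag.area_um2
                last_counted = frag
        if last_counted is not None and cum > target_um2:
            overshoot = cum - target_um2
            if rng.random() < overshoot / last_counted.area_um2:
                placer.remove(last_counted)
                fragments = [f for f in fragments if f is not last_counted]
        any_pathology = target_um2 > 0
    else:
        # count mode: the curve describes the number of filter-passing
        # fragments, so only those advance the target
        n_target = rng.poisson(expected_count * field_mm2 / 0.25)
        lo_l, hi_l = cfg.fragment_geom.length_range_um
        placer.set_area_target(
            n_target * 0.5 * (lo_l + hi_l) * (2 * placer.radius + 1) * px
        )
        n_counted = 0
        budget = 4 * n_target + 60
        while n_counted < n_target and budget > 0:
            budget -= 1
            length = rng.uniform(*cfg.fragment_geom.length_range_um)
            frag = placer.place(length)
            if frag is not None:
                fragments.append(frag)
                if not frag.sub_threshold:
                    n_counted += 1
        any_pathology = n_target > 0

    if any_pathology:
        for _ in range(cfg.n_subthreshold):
            frag = placer.place_subthreshold()
            if frag is not None:
                fragments.append(frag)

    canvas = np.zeros(shape, dtype=float)
    for frag in fragments:
        canvas[frag.pixels[:, 0], frag.pixels[:, 1]] = cfg.fragment_geom.intensity
    canvas = ndimage.gaussian_filter(canvas, 0.7)

    # soft-edged non-specific staining, kept away from neurites
    n_blobs = rng.poisson(cfg.background.density_per_mm2 * field_mm2)
    margin_px = 4 + int(np.ceil(max(cfg.background.radius_um_range) / px))
    far = ndimage.distance_transform_edt(~truth.width_mask) > margin_px
    far_idx = np.flatnonzero(far)
    for _ in range(n_blobs):
        if far_idx.size == 0:
            break
        flat = int(rng.choice(far_idx))
        r, c = divmod(flat, shape[1])
        radius = rng.uniform(*cfg.background.radius_um_range)
        _gaussian_spot(canvas, r, c, radius / px, cfg.background.intensity)

    image = FieldImage(
        data=_apply_noise(canvas, cfg.noise, rng),
        channel="psyn",
        pixel_size=px,
        offset=truth.offset,
    )
    return image, fragments


class _FragmentPlacer:
    """Places non-overlapping fragments along neurite skeleton paths."""

    SEPARATION_PX = 2
    MAX_TRIES = 40

    def __init__(self, cfg: SynthConfig, truth: NeuriteTruth, rng: np.random.Generator):
        self.cfg = cfg
        self.truth = truth
        self.rng = rng
        self.occupancy = np.zeros(truth.shape, dtype=bool)
        self.radius = max(0, int(round(cfg.fragment_geom.width_um / (2 * truth.pixel_size))))
        self._sep_disk = disk(self.SEPARATION_PX)
        self._width_disk = disk(self.radius) if self.radius > 0 else None
        self.forward_idx = [
            i for i, n in enumerate(truth.neurites) if n.forward_originating and len(n.path_px) > 2
        ]
        self.native_idx = [
            i for i, n in enumerate(truth.neurites) if not n.forward_originating and len(n.path_px) > 2
        ]
        # area placed so far on forward-originating vs reverse-native hosts;
        # a deficit controller keeps the realised transfer share close to
        # the configured fraction instead of leaving it binomial
        self.area_forward = 0.0
        self.area_native = 0.0
        # transferred fragments must be unambiguously CFSE-negative: reject
        # native placements that ride along a forward axon
        fwd_mask = np.zeros(truth.shape, dtype=bool)
        for i in self.forward_idx:
            n = truth.neurites[i]
            fwd_mask[n.path_px[:, 0], n.path_px[:, 1]] = True
        self.forward_zone = ndimage.binary_dilation(fwd_mask, disk(3))

    def set_area_target(self, target_um2: float) -> None:
        """Total filter-passing area this field aims for (both host classes)."""
        self.area_target = target_um2

    def _pick_neurite(self) -> int | None:
        # host class drawn proportionally to each class's remaining area
        # quota, so the realised transfer share tracks the configured
        # fraction instead of drifting binomially
        f = self.cfg.transfer_fraction
        target = getattr(self, "area_target", 0.0)
        d_native = max(f * target - self.area_native, 0.0)
        d_forward = max((1 - f) * target - self.area_forward, 0.0)
        if d_native + d_forward <= 0:
            use_native = self.rng.random() < f
        else:
            use_native = self.rng.random() < d_native / (d_native + d_forward)
        pool = self.native_idx if use_native else self.forward_idx
        if not pool:
            pool = self.native_idx or self.forward_idx
        if not pool:
            return None
        return int(self.rng.choice(pool))

    def _raster(self, path: np.ndarray) -> np.ndarray | None:
        mask = np.zeros(self.truth.shape, dtype=bool)
        mask[path[:, 0], path[:, 1]] = True
        if self._width_disk is not None:
            mask = ndimage.binary_dilation(mask, self._width_disk)
        test = ndimage.binary_dilation(mask, self._sep_disk)
        if (test & self.occupancy).any():
            return None
        return mask

    def place(self, length_um: float) -> TruthFragment | None:
        px = self.truth.pixel_size
        n_px = max(2, int(round(length_um / px)))
        for _ in range(self.MAX_TRIES):
            ni = self._pick_neurite()
            if ni is None:
                return None
            path = self.truth.neurites[ni].path_px
            if len(path) < 3:
                continue
            start = self.rng.integers(0, len(path))
            if self.rng.random() < 0.5:
                seg = path[start : start + n_px]
            else:
                seg = path[max(0, start - n_px) : start + 1]
            if len(seg) < 2:
                continue
            forward_host = self.truth.neurites[ni].forward_originating
            if not forward_host:
                in_zone = self.forward_zone[seg[:, 0], seg[:, 1]]
                if in_zone.mean() > 0.25:
                    continue
            mask = self._raster(seg)
            if mask is None:
                continue
            self.occupancy |= mask
            pixels = np.argwhere(mask)
            area = len(pixels) * px**2
            if area >= 8.0:
                if forward_host:
                    self.area_forward += area
                else:
                    self.area_native += area
            return TruthFragment(
                pixels=pixels,
                area_um2=area,
                on_neurite=True,
                cfse_positive=forward_host,
                sub_threshold=area < 8.0,
            )
        return None

    def place_subthreshold(self) -> TruthFragment | None:
        """A speck guaranteed below the 8 µm² cutoff."""
        px = self.truth.pixel_size
        target = self.rng.uniform(2.0, 6.0)
        width = 2 * self.radius + 1
        length = target / (width * px)
        for _ in range(5):
            frag = self.place(max(length, 2 * px))
            if frag is None:
                return None
            if frag.area_um2 < 8.0:
                frag.sub_threshold = True
                return frag
            self.remove(frag)
            length *= 0.6
        return None

    def remove(self, frag: TruthFragment) -> None:
        self.occupancy[frag.pixels[:, 0], frag.pixels[:, 1]] = False
        if not frag.sub_threshold:
            if frag.cfse_positive:
                self.area_forward -= frag.area_um2
            else:
                self.area_native -= frag.area_um2


# --------------------------------------------------------------------------
# CFSE channel


def generate_cfse_channel(
    cfg: SynthConfig,
    truth: NeuriteTruth,
    geometry: DeviceGeometry,
    *,
    rng: np.random.Generator | None = None,
) -> FieldImage:
    """Render CFSE along forward-originating neurites only.

    Intensity at a pixel follows the configured decay of its distance to
    the barrier; reverse-native neurites receive no CFSE signal.
    """
    rng = _rng(cfg, _SALT_CFSE) if rng is None else rng
    px = truth.pixel_size
    shape = truth.shape
    canvas = np.zeros(shape, dtype=float)
    for n in truth.neurites:
        if not n.forward_originating or len(n.path_px) == 0:
            continue
        mask = np.zeros(shape, dtype=bool)
        mask[n.path_px[:, 0], n.path_px[:, 1]] = True
        radius = n.width_px // 2
        if radius > 0:
            mask = ndimage.binary_dilation(mask, disk(radius))
        rr, cc = np.nonzero(mask)
        x_um = truth.offset[0] + (cc + 0.5) * px
        d = distance_to_barrier(x_um, geometry)
        np.maximum.at(canvas, (rr, cc), cfg.cfse.profile(d))
    canvas = ndimage.gaussian_filter(canvas, 1.0)
    return FieldImage(
        data=_apply_noise(canvas, cfg.noise, rng),
        channel="cfse",
        pixel_size=px,
        offset=truth.offset,
    )


# --------------------------------------------------------------------------
# microchannel time-lapse


def generate_channel_timelapse(
    cfg: SynthConfig,
    geometry: DeviceGeometry | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, list[TruthTrace]]:
    """Render a (frames, rows, cols) lane movie with known puncta kinematics.

    Each punctum is a Gaussian spot at x(t) = x₀ + v·(t − t₀) plus
    localisation jitter, rendered while inside the field of view.  Truth
    records per-frame ideal positions (NaN outside the field), the signed
    speed, direction class, and the time the punctum reaches the forward
    barrier edge, if it does within the recording.
    """
    rng = _rng(cfg, _SALT_MOVIE) if rng is None else rng
    geometry = geometry or DeviceGeometry(pixel_size=cfg.pixel_size_um)
    px = cfg.pixel_size_um
    x_lo, x_hi = cfg.movie.x_range_um
    n_cols = int(round((x_hi - x_lo) / px))
    n_rows = max(3, int(round(cfg.movie.lane_width_um / px)))
    n_frames = int(round(cfg.duration_s / cfg.frame_interval_s)) + 1
    times = np.arange(n_frames) * cfg.frame_interval_s

    for p in cfg.puncta:
        if not (x_lo <= p.x0_um <= x_hi):
            raise ValueError(f"punctum start {p.x0_um} outside field [{x_lo}, {x_hi}]")

    truths: list[TruthTrace] = []
    per_frame_positions: list[np.ndarray] = []
    for p in cfg.puncta:
        pos = np.full(n_frames, np.nan)
        active = times >= p.t0_s
        x = p.x0_um + p.speed_um_s * (times - p.t0_s)
        inside = active & (x >= x_lo) & (x <= x_hi)
        pos[inside] = x[inside]
        exit_time = None
        if p.speed_um_s < 0:
            t_exit = p.t0_s + (p.x0_um - x_lo) / -p.speed_um_s
            if t_exit <= cfg.duration_s:
                exit_time = float(t_exit)
        elif p.speed_um_s > 0:
            t_exit = p.t0_s + (x_hi - p.x0_um) / p.speed_um_s
            # leaving through the reverse side is not a barrier exit
        if abs(p.speed_um_s) < 0.1:
            direction = "stationary"
        else:
            direction = "retrograde" if p.speed_um_s < 0 else "anterograde"
        truths.append(
            TruthTrace(
                x0_um=p.x0_um,
                speed_um_s=p.speed_um_s,
                t0_s=p.t0_s,
                times_s=times,
                positions_um=pos,
                exit_time_s=exit_time,
                direction=direction,
            )
        )
        per_frame_positions.append(pos)

    movie = np.empty((n_frames, n_rows, n_cols), dtype=np.uint16)
    sigma_px = cfg.movie.spot_sigma_um / px
    row_c = (n_rows - 1) / 2.0
    for f in range(n_frames):
        canvas = np.zeros((n_rows, n_cols), dtype=float)
        for pos in per_frame_positions:
            if np.isnan(pos[f]):
                continue
            xj = pos[f] + rng.normal(0.0, cfg.movie.jitter_sigma_um)
            col = (xj - x_lo) / px - 0.5
            _gaussian_spot(canvas, row_c, col, sigma_px, cfg.movie.spot_intensity)
        movie[f] = _apply_noise(canvas, cfg.noise, rng)
    return movie, truths


def make_retrograde_puncta(
    n: int = 9,
    *,
    speed_mean_um_s: float = 1.11,
    speed_sd_um_s: float = 0.13,
    x_range_um: tuple[float, float] = (0.0, 1000.0),
    seed: int = 0,
) -> list[PunctumSpec]:
    """Retrograde puncta with speeds drawn around the transport speed.

    Start positions are spread over the inner channel so traces are
    resolvable; speeds are negative (toward the forward chamber).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 505]))
    lo, hi = x_range_um
    span = hi - lo
    starts = lo + span * (0.25 + 0.7 * np.arange(n) / max(n - 1, 1))
    speeds = -np.abs(rng.normal(speed_mean_um_s, speed_sd_um_s, n))
    return [
        PunctumSpec(x0_um=float(x), speed_um_s=float(v), t0_s=0.0)
        for x, v in zip(starts, speeds)
    ]


# --------------------------------------------------------------------------
# whole studies


@dataclass
class FieldData:
    image_id: str
    psyn: FieldImage
    tubulin: FieldImage
    fragments: list[TruthFragment]
    neurites: NeuriteTruth
    cfse: FieldImage | None = None


@dataclass
class DeviceData:
    device_id: str
    t_weeks: float
    seeded: bool
    device_factor: float
    expected_area_per_qmm2: float
    expected_count_per_qmm2: float
    fields: list[FieldData]


@dataclass
class StudyDataset:
    devices: list[DeviceData]
    config: SynthConfig

    def truth_table(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "device_id": d.device_id,
                    "t_weeks": d.t_weeks,
                    "seeded": d.seeded,
                    "device_factor": d.device_factor,
                    "expected_area_per_qmm2": d.expected_area_per_qmm2,
                    "expected_count_per_qmm2": d.expected_count_per_qmm2,
                }
                for d in self.devices
            ]
        )


def default_study_schedule(
    n_devices: int = 69,
    t_range_weeks: tuple[float, float] = (2.9, 12.6),
    *,
    seeded: bool = True,
    prefix: str = "dev",
) -> list[tuple[str, float, bool]]:
    """Evenly spaced device timepoints across the incubation range."""
    ts = np.linspace(*t_range_weeks, n_devices)
    return [(f"{prefix}{i:03d}", float(t), seeded) for i, t in enumerate(ts)]


def generate_study(
    cfg: SynthConfig,
    schedule: list[tuple[str, float, bool]],
    *,
    fields_per_chamber: int = 10,
    chamber: str = "forward",
    with_cfse: bool = False,
    geometry: DeviceGeometry | None = None,
) -> StudyDataset:
    """Generate a full synthetic study: devices × fields with truth tables.

    ``schedule`` rows are ``(device_id, t_weeks, seeded)``; duplicate device
    IDs are rejected.  Per-device and per-field seeds derive from the master
    seed via ``SeedSequence`` spawning, so the dataset is reproducible and
    independent of generation order.  Fields sit in the main [400, 1600] µm
    band of the requested chamber (the [0, 400] µm band when ``with_cfse``).
    """
    ids = [s[0] for s in schedule]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate device IDs in schedule")
    geometry = geometry or DeviceGeometry(pixel_size=cfg.pixel_size_um)
    px = cfg.pixel_size_um
    shape = cfg.shape_px()
    w_um = shape[1] * px
    lo, hi = geometry.barrier_x_range
    forward_left = geometry.forward_side == "left"
    band_start = 0.0 if with_cfse else 400.0
    if chamber == ("forward" if forward_left else "reverse"):
        offset_x = lo - band_start - w_um
    else:
        offset_x = hi + band_start

    sigma = float(np.sqrt(np.log(1 + cfg.device_cv**2)))
    devices: list[DeviceData] = []
    for di, (device_id, t_weeks, seeded) in enumerate(schedule):
        dev_ss = np.random.SeedSequence([cfg.seed, 7000 + di])
        children = dev_ss.spawn(fields_per_chamber + 1)
        dev_rng = np.random.default_rng(children[0])
        factor = float(dev_rng.lognormal(-(sigma**2) / 2, sigma)) if sigma > 0 else 1.0
        fields: list[FieldData] = []
        for fi in range(fields_per_chamber):
            f_rng = np.random.default_rng(children[fi + 1])
            offset = (offset_x, fi * 10.0)  # y offset is bookkeeping only
            tub, neur = generate_neurite_field(cfg, geometry, offset=offset, rng=f_rng)
            psyn, frags = generate_pathology_image(
                cfg, neur, t_weeks, device_factor=factor, seeded=seeded, rng=f_rng
            )
            cfse_img = (
                generate_cfse_channel(cfg, neur, geometry, rng=f_rng) if with_cfse else None
            )
            image_id = f"{device_id}_f{fi:02d}"
            tub.image_id = psyn.image_id = image_id
            fields.append(
                FieldData(
                    image_id=image_id,
                    psyn=psyn,
                    tubulin=tub,
                    fragments=frags,
                    neurites=neur,
                    cfse=cfse_img,
                )
            )
        devices.append(
            DeviceData(
                device_id=device_id,
                t_weeks=t_weeks,
                seeded=seeded,
                device_factor=factor,
                expected_area_per_qmm2=(
                    cfg.expected_area_per_qmm2(t_weeks) * factor
                    if seeded
                    else cfg.control_area_per_qmm2 * factor
                ),
                expected_count_per_qmm2=cfg.expected_count_per_qmm2(t_weeks) * factor
                if seeded
                else 0.0,
                fields=fields,
            )
        )
    return StudyDataset(devices=devices, config=cfg)


# --------------------------------------------------------------------------
# config (de)serialisation


def _listify(obj):
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    if isinstance(obj, list):
        return [_listify(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    return obj


def save_config(cfg: SynthConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_listify(asdict(cfg)), sort_keys=False))


def load_config(path) -> SynthConfig:
    raw = yaml.safe_load(Path(path).read_text())
    raw["neurites"] = NeuriteParams(**_tupled(raw.get("neurites", {})))
    raw["fragment_geom"] = FragmentGeom(**_tupled(raw.get("fragment_geom", {})))
    raw["background"] = BackgroundStaining(**_tupled(raw.get("background", {})))
    raw["cfse"] = CfseDecay(**raw.get("cfse", {}))
    raw["noise"] = NoiseModel(**raw.get("noise", {}))
    raw["movie"] = MovieParams(**_tupled(raw.get("movie", {})))
    raw["puncta"] = [PunctumSpec(**p) for p in raw.get("puncta", [])]
    raw = _tupled(raw)
    return SynthConfig(**raw)


def _tupled(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) and k.endswith(("_um", "_range_um", "_choices", "range")) else v for k, v in d.items()}
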