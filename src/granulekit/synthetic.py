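"""Synthetic microscopy data with known ground truth.

Every analysis stage in this package has a matching generator here, so the
whole pipeline can be validated by parameter recovery without raw
microscopy data:

* :func:`simulate_frap_trace` — single-exponential fluorescence recovery
  with an immobile plateau, multiplicative acquisition bleaching shared by
  focus and reference, optional photoconversion crosstalk into the
  reference focus, and additive camera noise;
* :func:`simulate_granule_field` — 2-D cell fields containing bright
  granules of controllable shape (near-circular droplets vs irregular
  aggregates) with analytic per-object truth;
* :func:`simulate_halfbleach_stack` — a droplet whose two halves exchange
  material at rate ``k`` after one half is bleached (two-compartment
  model: the half-to-half asymmetry decays as ``exp(-2 k t)``);
* :func:`simulate_dissolution_stack` — structures that decay exponentially
  after a treatment-onset frame, with per-structure time constants
  (``inf`` models a treatment-resistant structure).

All generators are seeded and bit-reproducible: the same config and seed
produce identical arrays.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import skimage.draw

from .frap import LN2, IntensityTrace

__all__ = [
    "FrapSimConfig",
    "GranuleFieldConfig",
    "HalfBleachConfig",
    "DissolutionConfig",
    "FrapGroundTruth",
    "GranuleField",
    "HalfBleachSim",
    "DissolutionSim",
    "simulate_frap_trace",
    "simulate_frap_traces",
    "simulate_granule_field",
    "simulate_halfbleach_stack",
    "simulate_dissolution_stack",
]


def _check(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"{name}: {msg}")


@dataclass
class FrapSimConfig:
    """Generative model of a FRAP/photoconversion trace.

    The focus signal is ``I_F(t) = background_level + D(t) * focus_scale * S(t)``
    with acquisition bleaching ``D(t) = exp(-acq_decay_rate * t)`` and
    recovery ``S(t) = 1`` pre-bleach,
    ``S(t) = residual_offset + plateau_A_true * (1 - exp(-ln2 * (t - t_b)/t_half_true))``
    post-bleach. The reference focus shares ``D(t)`` and optionally loses a
    ``crosstalk_fraction`` step at the bleach. Independent Gaussian noise of
    sd ``noise_sd`` is added to each channel; traces emulate ROI means, so
    ``noise_sd`` is per-trace, not per-pixel.
    """

    t_half_true: float = 22.0        # s
    plateau_A_true: float = 0.8      # mobile fraction, in (0, 1]
    residual_offset: float = 0.0     # normalized signal right after the bleach
    frame_interval: float = 1.0      # s
    n_prebleach: int = 10
    n_postbleach: int = 300
    acq_decay_rate: float = 0.002    # 1/s, shared acquisition bleaching
    crosstalk_fraction: float = 0.0  # step loss of the reference at the bleach
    focus_scale: float = 1000.0      # counts
    reference_scale: float = 1000.0  # counts
    background_level: float = 100.0  # counts
    noise_sd: float = 10.0           # counts; per-pixel SNR 20 averaged over a 5x5 ROI
    n_cells: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.t_half_true > 0, "t_half_true", "must be > 0")
        _check(0 < self.plateau_A_true <= 1, "plateau_A_true", "must be in (0, 1]")
        _check(0 <= self.residual_offset < 1, "residual_offset", "must be in [0, 1)")
        _check(self.residual_offset + self.plateau_A_true <= 1 + 1e-12,
               "residual_offset", "residual_offset + plateau_A_true must be <= 1")
        _check(self.frame_interval > 0, "frame_interval", "must be > 0")
        _check(self.n_prebleach >= 1, "n_prebleach", "must be >= 1")
        _check(self.n_postbleach >= 3, "n_postbleach", "must be >= 3")
        _check(self.acq_decay_rate >= 0, "acq_decay_rate", "must be >= 0")
        _check(0 <= self.crosstalk_fraction < 1, "crosstalk_fraction", "must be in [0, 1)")
        for name in ("focus_scale", "reference_scale", "background_level", "noise_sd"):
            _check(getattr(self, name) >= 0, name, "must be >= 0")
        _check(self.n_cells >= 1, "n_cells", "must be >= 1")


@dataclass
class FrapGroundTruth:
    """Generative parameters attached to one synthetic trace."""

    cell_id: str
    t_half_true: float
    plateau_A_true: float
    residual_offset: float
    p_true: float  # ln2 / t_half_true
    acq_decay_rate: float
    crosstalk_fraction: float
    noise_sd: float
    seed: int
    cell_index: int


def simulate_frap_trace(config: FrapSimConfig, cell_index: int = 0) -> tuple[IntensityTrace, FrapGroundTruth]:
    """Generate one FRAP trace plus its ground-truth record."""
    rng = np.random.default_rng([int(config.seed), int(cell_index)])
    n = config.n_prebleach + config.n_postbleach
    t = np.arange(n) * config.frame_interval
    t_b = config.n_prebleach * config.frame_interval

    S = np.ones(n)
    post = t >= t_b
    S[post] = config.residual_offset + config.plateau_A_true * (
        1.0 - np.exp(-LN2 * (t[post] - t_b) / config.t_half_true)
    )
    D = np.exp(-config.acq_decay_rate * t)
    I_F = config.background_level + D * config.focus_scale * S
    I_R = config.background_level + D * config.reference_scale * (
        1.0 - config.crosstalk_fraction * post.astype(float)
    )
    I_B = np.full(n, config.background_level)
    if config.noise_sd > 0:
        I_F = I_F + rng.normal(0.0, config.noise_sd, n)
        I_R = I_R + rng.normal(0.0, config.noise_sd, n)
        I_B = I_B + rng.normal(0.0, config.noise_sd, n)

    cell_id = f"cell{cell_index:03d}"
    trace = IntensityTrace(time=t, I_F=I_F, I_R=I_R, I_B=I_B,
                           bleach_index=config.n_prebleach, cell_id=cell_id)
    truth = FrapGroundTruth(
        cell_id=cell_id,
        t_half_true=config.t_half_true,
        plateau_A_true=config.plateau_A_true,
        residual_offset=config.residual_offset,
        p_true=LN2 / config.t_half_true,
        acq_decay_rate=config.acq_decay_rate,
        crosstalk_fraction=config.crosstalk_fraction,
        noise_sd=config.noise_sd,
        seed=config.seed,
        cell_index=cell_index,
    )
    return trace, truth


def simulate_frap_traces(config: FrapSimConfig) -> tuple[list[IntensityTrace], pd.DataFrame]:
    """Generate ``config.n_cells`` traces; truth records as a DataFrame."""
    traces, truths = [], []
    for i in range(config.n_cells):
        trace, truth = simulate_frap_trace(config, cell_index=i)
        traces.append(trace)
        truths.append(dataclasses.asdict(truth))
    return traces, pd.DataFrame(truths)


# --------------------------------------------------------------------------
# granule fields


@dataclass
class GranuleFieldConfig:
    """A 2-D cell containing bright granules of controllable shape.

    ``shape_class='disk'`` gives near-circular droplets (truth circularity
    exactly 1); ``'irregular'`` gives radially perturbed polygons whose
    truth area/perimeter/circularity are computed analytically on the
    polygon before rasterization, so pixelation never contaminates the
    ground truth.
    """

    image_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 0.1          # µm / pixel
    n_granules: int = 10
    radius_range: tuple[float, float] = (0.5, 1.2)  # µm
    shape_class: str = "disk"        # 'disk' | 'irregular'
    roughness: float = 0.0           # total relative radial perturbation, [0, 1)
    intensity_granule: float = 800.0
    intensity_cytoplasm: float = 300.0
    intensity_background: float = 100.0
    cell_axes_fraction: tuple[float, float] = (0.45, 0.42)  # semi-axes / image size
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        _check(len(self.image_shape) == 2 and min(self.image_shape) >= 16,
               "image_shape", "must be 2-D and at least 16x16")
        _check(self.pixel_size > 0, "pixel_size", "must be > 0")
        _check(self.n_granules >= 0, "n_granules", "must be >= 0")
        _check(0 < self.radius_range[0] <= self.radius_range[1], "radius_range", "must satisfy 0 < lo <= hi")
        _check(self.shape_class in ("disk", "irregular"), "shape_class", "must be 'disk' or 'irregular'")
        _check(0 <= self.roughness < 1, "roughness", "must be in [0, 1)")
        _check(self.intensity_granule > self.intensity_cytoplasm > self.intensity_background,
               "intensity_granule", "need granule > cytoplasm > background intensity")
        _check(self.noise_sd >= 0, "noise_sd", "must be >= 0")


@dataclass
class GranuleField:
    """One synthetic field: image, noiseless label image, cell mask, truth."""

    image: np.ndarray
    labels: np.ndarray
    cell_mask: np.ndarray
    truth: pd.DataFrame  # label, center_row, center_col, radius_px, area_px2, perimeter_px, circularity, area_um2
    config: GranuleFieldConfig


def _irregular_polygon(rng: np.random.Generator, r0: float, roughness: float,
                       n_vertices: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Radial-perturbation polygon: r(θ) = r0 (1 + Σ a_m cos(mθ + φ_m)).

    Harmonic amplitudes are drawn for m = 2..6 and rescaled so that
    Σ|a_m| = roughness, keeping the radius strictly positive.
    """
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    r = np.full_like(theta, r0)
    if roughness > 0:
        modes = np.arange(2, 7)
        amp = rng.uniform(0.3, 1.0, modes.size)
        amp *= roughness / amp.sum()
        phase = rng.uniform(0.0, 2.0 * np.pi, modes.size)
        r = r0 * (1.0 + (amp[:, None] * np.cos(modes[:, None] * theta[None, :] + phase[:, None])).sum(axis=0))
    return r * np.cos(theta), r * np.sin(theta)  # (dx, dy) around the center


def polygon_area_perimeter(xs: np.ndarray, ys: np.ndarray) -> tuple[float, float]:
    """Shoelace area and edge-sum perimeter of a closed polygon."""
    x2, y2 = np.roll(xs, -1), np.roll(ys, -1)
    area = 0.5 * abs(np.sum(xs * y2 - x2 * ys))
    perim = float(np.sum(np.hypot(x2 - xs, y2 - ys)))
    return float(area), perim


def simulate_granule_field(config: GranuleFieldConfig, max_retries: int = 200) -> GranuleField:
    """Place non-overlapping granules inside an elliptical cell and render.

    Raises
    ------
    RuntimeError
        If a granule cannot be placed without overlap within
        ``max_retries`` attempts.
    """
    rng = np.random.default_rng(int(config.seed))
    h, w = config.image_shape
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    ar, ac = config.cell_axes_fraction[0] * h, config.cell_axes_fraction[1] * w

    rows, cols = np.mgrid[0:h, 0:w]
    cell_mask = ((rows - cr) / ar) ** 2 + ((cols - cc) / ac) ** 2 <= 1.0

    labels = np.zeros((h, w), dtype=np.int32)
    placed: list[tuple[float, float, float]] = []  # (row, col, clearance radius)
    records = []
    for i in range(config.n_granules):
        r_um = rng.uniform(*config.radius_range)
        r_px = r_um / config.pixel_size
        clearance = r_px * (1.0 + config.roughness) + 2.0
        for attempt in range(max_retries):
            row = rng.uniform(cr - ar, cr + ar)
            col = rng.uniform(cc - ac, cc + ac)
            inside = ((row - cr) / max(ar - clearance, 1e-9)) ** 2 + \
                     ((col - cc) / max(ac - clearance, 1e-9)) ** 2 <= 1.0
            clash = any(np.hypot(row - pr, col - pc) < clearance + pcl for pr, pc, pcl in placed)
            if inside and not clash:
                break
        else:
            raise RuntimeError(
                f"simulate_granule_field: could not place granule {i} "
                f"without overlap after {max_retries} attempts"
            )
        placed.append((row, col, clearance))

        if config.shape_class == "disk":
            rr, cc_px = skimage.draw.disk((row, col), r_px, shape=(h, w))
            area_t = np.pi * r_px**2
            perim_t = 2.0 * np.pi * r_px
        else:
            dx, dy = _irregular_polygon(rng, r_px, config.roughness)
            area_t, perim_t = polygon_area_perimeter(dx, dy)
            rr, cc_px = skimage.draw.polygon(row + dy, col + dx, shape=(h, w))
        labels[rr, cc_px] = i + 1
        records.append({
            "label": i + 1,
            "center_row": row,
            "center_col": col,
            "radius_px": r_px,
            "area_px2": area_t,
            "perimeter_px": perim_t,
            "circularity": 4.0 * np.pi * area_t / perim_t**2,
            "area_um2": area_t * config.pixel_size**2,
        })

    image = np.full((h, w), config.intensity_background, dtype=float)
    image[cell_mask] = config.intensity_cytoplasm
    image[labels > 0] = config.intensity_granule
    if config.noise_sd > 0:
        image = image + rng.normal(0.0, config.noise_sd, image.shape)

    columns = ["label", "center_row", "center_col", "radius_px",
               "area_px2", "perimeter_px", "circularity", "area_um2"]
    truth = pd.DataFrame(records, columns=columns)
    return GranuleField(image=image, labels=labels, cell_mask=cell_mask, truth=truth, config=config)


# --------------------------------------------------------------------------
# half-bleach stacks


@dataclass
class HalfBleachConfig:
    """Two-compartment half-bleach model of a single droplet.

    After bleaching one half-plane of the droplet to a depth
    ``bleach_depth`` at frame 0, the unbleached/bleached concentrations
    u(t), b(t) exchange as d(u-b)/dt = -2k (u-b), so the half-to-half
    asymmetry decays as exp(-2 k t); ``mixing_rate`` k = 0 models a solid
    structure whose bleach boundary never heals.
    """

    droplet_radius: float = 12.0     # px
    mixing_rate: float = 0.05        # k, 1/s
    bleach_depth: float = 1.0        # fraction of the half's signal removed
    frame_interval: float = 1.0      # s
    n_frames: int = 60
    intensity: float = 1000.0        # droplet counts above background
    background_level: float = 100.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.droplet_radius >= 3, "droplet_radius", "must be >= 3 px")
        _check(self.mixing_rate >= 0, "mixing_rate", "must be >= 0")
        _check(0 < self.bleach_depth <= 1, "bleach_depth", "must be in (0, 1]")
        _check(self.frame_interval > 0, "frame_interval", "must be > 0")
        _check(self.n_frames >= 2, "n_frames", "must be >= 2")
        _check(self.noise_sd >= 0, "noise_sd", "must be >= 0")


@dataclass
class HalfBleachSim:
    stack: np.ndarray            # (n_frames, H, W); frame 0 = first post-bleach frame
    droplet_mask: np.ndarray
    bleached_mask: np.ndarray    # left half-plane of the droplet
    unbleached_mask: np.ndarray
    time: np.ndarray             # s since the bleach
    asymmetry_rate_true: float   # 2k
    config: HalfBleachConfig


def simulate_halfbleach_stack(config: HalfBleachConfig) -> HalfBleachSim:
    """Render a droplet time-lapse after bleaching its left half."""
    rng = np.random.default_rng(int(config.seed))
    rad = config.droplet_radius
    size = int(np.ceil(4 * rad)) | 1
    ctr = size // 2
    rows, cols = np.mgrid[0:size, 0:size]
    droplet = (rows - ctr) ** 2 + (cols - ctr) ** 2 <= rad**2
    bleached = droplet & (cols < ctr)
    unbleached = droplet & ~(cols < ctr)

    t = np.arange(config.n_frames) * config.frame_interval
    mean_c = 1.0 - config.bleach_depth * (bleached.sum() / droplet.sum())
    half_diff = config.bleach_depth / 2.0
    u = mean_c + half_diff * np.exp(-2.0 * config.mixing_rate * t)
    b = mean_c - half_diff * np.exp(-2.0 * config.mixing_rate * t)

    stack = np.full((config.n_frames, size, size), config.background_level, dtype=float)
    for k in range(config.n_frames):
        stack[k][unbleached] += config.intensity * u[k]
        stack[k][bleached] += config.intensity * b[k]
    if config.noise_sd > 0:
        stack = stack + rng.normal(0.0, config.noise_sd, stack.shape)
    return HalfBleachSim(
        stack=stack,
        droplet_mask=droplet,
        bleached_mask=bleached,
        unbleached_mask=unbleached,
        time=t,
        asymmetry_rate_true=2.0 * config.mixing_rate,
        config=config,
    )


# --------------------------------------------------------------------------
# dissolution stacks


@dataclass
class DissolutionConfig:
    """Structures that decay exponentially after a treatment-onset frame.

    ``decay_tau`` is either a scalar applied to every structure or one
    value per structure; ``inf`` keeps a structure at full intensity
    (treatment-resistant, e.g. an amyloid control).
    """

    n_structures: int = 6
    decay_tau: float | Sequence[float] = 60.0  # s per structure; inf = resistant
    treatment_onset_frame: int = 5
    frame_interval: float = 10.0  # s
    n_frames: int = 30
    structure_radius: float = 6.0  # px
    intensity: float = 800.0
    background_level: float = 100.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.n_structures >= 1, "n_structures", "must be >= 1")
        taus = np.atleast_1d(np.asarray(self.decay_tau, dtype=float))
        _check(taus.size in (1, self.n_structures), "decay_tau",
               f"need 1 or {self.n_structures} values, got {taus.size}")
        _check(np.all(taus > 0), "decay_tau", "time constants must be > 0 (inf allowed)")
        _check(0 <= self.treatment_onset_frame < self.n_frames, "treatment_onset_frame",
               "must be a valid frame index")
        _check(self.frame_interval > 0, "frame_interval", "must be > 0")
        _check(self.n_frames >= 2, "n_frames", "must be >= 2")
        _check(self.noise_sd >= 0, "noise_sd", "must be >= 0")

    @property
    def taus(self) -> np.ndarray:
        taus = np.atleast_1d(np.asarray(self.decay_tau, dtype=float))
        if taus.size == 1:
            taus = np.repeat(taus, self.n_structures)
        return taus


@dataclass
class DissolutionSim:
    stack: np.ndarray   # (n_frames, H, W)
    labels: np.ndarray  # structure label image (static masks)
    time: np.ndarray    # s from the first frame
    onset_frame: int
    truth: pd.DataFrame  # label, tau_s, center_row, center_col
    config: DissolutionConfig


def simulate_dissolution_stack(config: DissolutionConfig) -> DissolutionSim:
    """Render a treatment time-lapse of exponentially dissolving structures."""
    rng = np.random.default_rng(int(config.seed))
    rad = config.structure_radius
    pitch = int(np.ceil(4 * rad)) + 4
    per_row = int(np.ceil(np.sqrt(config.n_structures)))
    n_rows = int(np.ceil(config.n_structures / per_row))
    h, w = n_rows * pitch, per_row * pitch

    labels = np.zeros((h, w), dtype=np.int32)
    records = []
    for i in range(config.n_structures):
        row = (i // per_row) * pitch + pitch // 2
        col = (i % per_row) * pitch + pitch // 2
        rr, cc = skimage.draw.disk((row, col), rad, shape=(h, w))
        labels[rr, cc] = i + 1
        records.append({"label": i + 1, "tau_s": config.taus[i],
                        "center_row": row, "center_col": col})

    t = np.arange(config.n_frames) * config.frame_interval
    t_onset = config.treatment_onset_frame * config.frame_interval
    stack = np.full((config.n_frames, h, w), config.background_level, dtype=float)
    for k in range(config.n_frames):
        frame = stack[k]
        for i in range(config.n_structures):
            tau = config.taus[i]
            if t[k] <= t_onset or np.isinf(tau):
                f = 1.0
            else:
                f = float(np.exp(-(t[k] - t_onset) / tau))
            frame[labels == i + 1] += config.intensity * f
    if config.noise_sd > 0:
        stack = stack + rng.normal(0.0, config.noise_sd, stack.shape)
    return DissolutionSim(stack=stack, labels=labels, time=t,
                          onset_frame=config.treatment_onset_frame,
                          truth=pd.DataFrame(records), config=config)
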