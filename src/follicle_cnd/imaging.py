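"""Synthetic two-channel (CFP/YFP) time-lapse generator.

Renders 16-bit confocal-like frames of a flattened follicle from
simulated compartment traces: concentric oocyte / cumulus / mural
regions with a dark prophase nucleus, dark antral patches, a dim static
theca rim, autofluorescence background, spectral bleed-through of CFP
into the YFP channel, Poisson shot noise plus Gaussian read noise, and
frame-to-frame translational jitter.  Ground truth (region masks, true
ratio traces, true shifts, NEBD frame) is carried alongside the pixels
so the analysis pipeline can be validated closed-loop.

Acquisition schedule mirrors the experiments: >= 10 min of baseline,
one frame per minute for the first hour after LH, one frame every
5 min thereafter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

from .geometry import FollicleGeometry
from .model import CompartmentTraces
from .sensor import CAMPFIRE_M, SensorCalibration, ratio_from_concentration

__all__ = ["FollicleScene", "ImageStack", "frame_schedule",
           "render_frame", "render_timelapse",
           "REGION_LABELS"]

# label image codes
REGION_LABELS = {
    "background": 0,
    "theca": 1,
    "mural": 2,        # all granulosa outside the cumulus shell
    "antrum": 3,
    "cumulus": 4,
    "oocyte": 5,
    "nucleus": 6,
}

# regions whose pixels carry sensor signal driven by a compartment trace
_SENSOR_REGIONS = ("mural", "cumulus", "oocyte")


@dataclass(frozen=True)
class FollicleScene:
    """Geometry, optics, and artifact settings for one rendered follicle."""

    geometry: FollicleGeometry = field(default_factory=FollicleGeometry)
    shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.8                 # um/pixel
    center: tuple[float, float] | None = None   # (row, col); image center if None
    expression: Mapping[str, float] = None  # per-region sensor level multiplier
    cfp_background: float = 120.0           # autofluorescence counts
    yfp_background: float = 120.0
    signal_to_background: float = 6.0       # sensor counts / background counts
    bleedthrough_alpha: float = 0.23        # CFP fraction leaking into YFP
    shot_noise: bool = True
    read_noise_frac: float = 0.02           # Gaussian sd as fraction of intensity
    jitter_sd: float = 0.5                  # per-frame translation sd (pixels)
    nebd_time: float | None = None          # min; nucleus fills after this
    n_antral_patches: int = 6
    theca_width: float = 10.0               # um
    uninjected: bool = False                # autofluorescence only (background fixture)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not 3.0 <= self.signal_to_background <= 10.0:
            raise ValueError("signal_to_background must be within 3-10")
        if not 0.0 <= self.bleedthrough_alpha < 1.0:
            raise ValueError("bleedthrough_alpha must be in [0, 1)")
        if self.expression is None:
            object.__setattr__(self, "expression",
                               {"mural": 1.0, "cumulus": 1.0, "oocyte": 1.0})

    @property
    def center_px(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        return (self.shape[0] / 2.0, self.shape[1] / 2.0)

    def label_image(self, shift: tuple[int, int] = (0, 0)) -> np.ndarray:
        """Region label map, optionally translated by integer ``shift``."""
        base = _base_labels(self)
        if shift == (0, 0):
            return base
        return np.roll(base, shift, axis=(0, 1))

    def masks(self) -> dict[str, np.ndarray]:
        """Ground-truth ROI masks in the unshifted (reference) frame."""
        lab = self.label_image()
        g, px = self.geometry, self.pixel_size
        r_foll = g.follicle_diameter / 2 / px
        mural_inner = r_foll - g.mural_band_width / px
        rr = _radius_map(self.shape, self.center_px)
        return {
            "outer_mural": (lab == REGION_LABELS["mural"]) & (rr >= mural_inner),
            "cumulus": lab == REGION_LABELS["cumulus"],
            "oocyte": lab == REGION_LABELS["oocyte"],
            "nucleus": lab == REGION_LABELS["nucleus"],
            "background": lab == REGION_LABELS["background"],
        }


def _radius_map(shape: tuple[int, int], center: tuple[float, float]) -> np.ndarray:
    rows = np.arange(shape[0])[:, None] - center[0]
    cols = np.arange(shape[1])[None, :] - center[1]
    return np.hypot(rows, cols)


_LABEL_CACHE: dict[tuple, np.ndarray] = {}


def _base_labels(scene: FollicleScene) -> np.ndarray:
    key = (scene.shape, scene.pixel_size, scene.center, scene.geometry,
           scene.n_antral_patches, scene.theca_width, scene.seed)
    if key in _LABEL_CACHE:
        return _LABEL_CACHE[key]
    g, px = scene.geometry, scene.pixel_size
    rr = _radius_map(scene.shape, scene.center_px)
    r_foll = g.follicle_diameter / 2 / px
    r_ooc = g.oocyte_diameter / 2 / px
    r_nuc = g.nucleus_diameter / 2 / px
    r_cum = r_ooc + g.cumulus_band_width / px
    r_theca = r_foll + scene.theca_width / px

    lab = np.full(scene.shape, REGION_LABELS["background"], dtype=np.uint8)
    lab[rr < r_theca] = REGION_LABELS["theca"]
    lab[rr < r_foll] = REGION_LABELS["mural"]

    # antral patches: dark discs in the granulosa between cumulus and
    # the outer mural band, drawn from the scene's own rng so a scene is
    # reproducible
    rng = np.random.default_rng(scene.seed + 7919)
    zone_lo = r_cum + 6.0 / px
    zone_hi = r_foll - g.mural_band_width / px - 6.0 / px
    cy, cx = scene.center_px
    for _ in range(scene.n_antral_patches):
        if zone_hi <= zone_lo:
            break
        rad = rng.uniform(zone_lo, zone_hi)
        ang = rng.uniform(0, 2 * np.pi)
        prad = rng.uniform(8.0, 20.0) / px
        pc = (cy + rad * np.sin(ang), cx + rad * np.cos(ang))
        patch = _radius_map(scene.shape, pc) < prad
        lab[patch & (lab == REGION_LABELS["mural"])] = REGION_LABELS["antrum"]

    lab[rr < r_cum] = REGION_LABELS["cumulus"]
    lab[rr < r_ooc] = REGION_LABELS["oocyte"]
    lab[rr < r_nuc] = REGION_LABELS["nucleus"]
    _LABEL_CACHE[key] = lab
    return lab


@dataclass
class ImageStack:
    """Rendered time-lapse with ground truth."""

    frames: np.ndarray          # (T, 2, H, W) uint16; channel 0 = CFP, 1 = YFP
    frame_times: np.ndarray     # min, strictly increasing
    scene: FollicleScene
    true_shifts: np.ndarray     # (T, 2) integer (row, col) translations
    true_concentrations: dict[str, np.ndarray]  # per region, at frame times
    true_ratios: dict[str, np.ndarray]
    nebd_frame: int | None
    seed: int

    def __post_init__(self) -> None:
        if self.frames.ndim != 4 or self.frames.shape[1] != 2:
            raise ValueError("frames must have shape (T, 2, H, W)")
        if len(self.frame_times) != len(self.frames):
            raise ValueError("frame_times length must match frames")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")

    @property
    def masks(self) -> dict[str, np.ndarray]:
        return self.scene.masks()

    def save(self, out_dir: str | Path) -> None:
        """Write TIFF stacks (one per channel), label image, and sidecar."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(out / "cfp.tif", self.frames[:, 0])
        tifffile.imwrite(out / "yfp.tif", self.frames[:, 1])
        tifffile.imwrite(out / "labels.tif", self.scene.label_image())
        pd.DataFrame({"t_min": self.frame_times,
                      **{f"conc_{k}": v for k, v in self.true_concentrations.items()},
                      **{f"ratio_{k}": v for k, v in self.true_ratios.items()}
                      }).to_csv(out / "truth.csv", index=False)
        sidecar = {
            "frame_times_min": self.frame_times.tolist(),
            "true_shifts": self.true_shifts.tolist(),
            "nebd_frame": self.nebd_frame,
            "seed": self.seed,
            "bleedthrough_alpha": self.scene.bleedthrough_alpha,
            "pixel_size_um": self.scene.pixel_size,
        }
        (out / "sidecar.json").write_text(json.dumps(sidecar, indent=2))


def frame_schedule(t_end: float, baseline: float = 10.0,
                   fast_until: float = 60.0) -> np.ndarray:
    """Acquisition times: 1-min frames from -baseline until ``fast_until``
    after LH, 5-min frames thereafter, strictly below ``t_end``."""
    if baseline < 10.0:
        raise ValueError("schedule requires >= 10 min of baseline")
    fast = np.arange(-baseline, min(fast_until, t_end), 1.0)
    slow = np.arange(fast_until, t_end, 5.0) if t_end > fast_until else []
    return np.concatenate([fast, np.asarray(slow)])


def _region_intensities(scene: FollicleScene, conc: Mapping[str, float],
                        calib: SensorCalibration, t: float
                        ) -> tuple[dict[str, float], dict[str, float]]:
    """Noise-free (CFP, YFP) sensor signal per region label."""
    bg_total = scene.cfp_background + scene.yfp_background
    cfp: dict[str, float] = {}
    yfp: dict[str, float] = {}
    for region in _SENSOR_REGIONS:
        if region not in conc:
            raise ValueError(f"no concentration supplied for region '{region}'")
        level = scene.expression.get(region, 1.0)
        if scene.uninjected:
            level = 0.0
        ratio = ratio_from_concentration(conc[region], calib)
        total = scene.signal_to_background * bg_total * level
        cfp[region] = total * ratio / (1.0 + ratio)
        yfp[region] = total / (1.0 + ratio)
    # nucleus excludes the sensor until NEBD, then fills like oocyte cytoplasm
    if scene.nebd_time is not None and t >= scene.nebd_time:
        cfp["nucleus"], yfp["nucleus"] = cfp["oocyte"], yfp["oocyte"]
    else:
        cfp["nucleus"], yfp["nucleus"] = 0.0, 0.0
    # dim static theca rim, fixed ratio, immune to LH in the model
    theca_total = 0.0 if scene.uninjected else 0.5 * bg_total
    cfp["theca"] = theca_total * 0.6
    yfp["theca"] = theca_total * 0.4
    cfp["antrum"] = yfp["antrum"] = 0.0
    cfp["background"] = yfp["background"] = 0.0
    return cfp, yfp


def render_frame(scene: FollicleScene, conc: Mapping[str, float],
                 calib: SensorCalibration = CAMPFIRE_M, t: float = 0.0,
                 shift: tuple[int, int] = (0, 0),
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Render one two-channel frame (2, H, W) uint16.

    ``conc`` maps region name (mural/cumulus/oocyte) to the sensed
    nucleotide concentration in nM.  The channel split is chosen so the
    ideal corrected CFP/YFP of each region equals the calibration ratio
    exactly; bleed-through then adds ``alpha`` times the CFP sensor
    signal into YFP, and noise is applied last.
    """
    lab = scene.label_image(shift)
    cfp_sig, yfp_sig = _region_intensities(scene, conc, calib, t)
    cfp = np.full(scene.shape, scene.cfp_background, dtype=float)
    yfp = np.full(scene.shape, scene.yfp_background, dtype=float)
    for region, code in REGION_LABELS.items():
        m = lab == code
        cfp[m] += cfp_sig[region]
        yfp[m] += yfp_sig[region] + scene.bleedthrough_alpha * cfp_sig[region]
    img = np.stack([cfp, yfp])
    if rng is not None:
        if scene.shot_noise:
            img = rng.poisson(img).astype(float)
        if scene.read_noise_frac > 0:
            img = img + rng.normal(0.0, scene.read_noise_frac * np.maximum(img, 1.0))
    return np.clip(np.round(img), 0, 65535).astype(np.uint16)


def render_timelapse(scene: FollicleScene, traces: CompartmentTraces,
                     calib: SensorCalibration = CAMPFIRE_M,
                     times: np.ndarray | None = None,
                     noise: bool = True) -> ImageStack:
    """Render the full acquisition from simulated compartment traces.

    The sensed species follows the calibration (``cAMPFIRE-M`` reads
    cAMP, ``cGi500`` reads cGMP).  Deterministic for a fixed scene seed.
    """
    species = "cGMP" if calib.sensor_id == "cGi500" else "cAMP"
    if times is None:
        times = frame_schedule(float(traces.t[-1]),
                               baseline=float(-traces.t[0]))
    times = np.asarray(times, dtype=float)
    if times[0] < traces.t[0] - 1e-9 or times[-1] > traces.t[-1] + 1e-9:
        raise ValueError("traces do not cover the acquisition schedule")

    conc_t = {region: np.interp(times, traces.t, traces.series(species, region))
              for region in _SENSOR_REGIONS}
    ratio_t = {r: np.asarray(ratio_from_concentration(v, calib))
               for r, v in conc_t.items()}

    rng = np.random.default_rng(scene.seed)
    shifts = np.round(rng.normal(0.0, scene.jitter_sd, size=(len(times), 2))
                      ).astype(int) if scene.jitter_sd > 0 else \
        np.zeros((len(times), 2), dtype=int)

    frames = np.empty((len(times), 2, *scene.shape), dtype=np.uint16)
    noise_rng = np.random.default_rng(scene.seed + 1) if noise else None
    for i, t in enumerate(times):
        conc_i = {r: float(conc_t[r][i]) for r in _SENSOR_REGIONS}
        frames[i] = render_frame(scene, conc_i, calib, t=t,
                                 shift=tuple(shifts[i]), rng=noise_rng)

    nebd_frame = None
    if scene.nebd_time is not None:
        idx = np.flatnonzero(times >= scene.nebd_time)
        nebd_frame = int(idx[0]) if len(idx) else None
    return ImageStack(frames=frames, frame_times=times, scene=scene,
                      true_shifts=shifts, true_concentrations=conc_t,
                      true_ratios=ratio_t, nebd_frame=nebd_frame,
                      seed=scene.seed)
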