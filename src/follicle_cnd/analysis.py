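"""Measurement pipeline for ratiometric FRET time-lapse stacks.

Mirrors the experimental workflow: translation registration of the
stack, concentric ROI definition (outer mural band, cumulus band,
oocyte, nucleus, extra-follicular background), per-ROI channel means,
background subtraction followed by spectral-overlap correction
(YFP minus 23% of CFP by default), ratio traces, kinetic landmark
metrics, NEBD detection, and per-timepoint summaries across follicles.

The order of corrections is fixed: background first, then bleed-through
— reversing it biases the ratio because the overlap fraction applies to
sensor signal, not to autofluorescence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skimage.registration import phase_cross_correlation

from .imaging import ImageStack

__all__ = [
    "ROISet", "RatioTraces", "KineticMetrics", "MetricUndefinedError",
    "register_stack", "define_rois", "correct_channels", "extract_traces",
    "time_to_fraction_of_peak", "time_to_fractional_decline",
    "time_below_baseline", "time_to_near_minimum", "compute_kinetic_metrics",
    "detect_nebd", "summarize_traces", "nebd_histogram",
]

ROI_NAMES = ("outer_mural", "cumulus", "oocyte", "nucleus", "background")


class MetricUndefinedError(ValueError):
    """The requested kinetic landmark does not exist for this trace."""


@dataclass
class ROISet:
    masks: dict[str, np.ndarray]
    provenance: str = "geometric"

    def __post_init__(self) -> None:
        total = None
        for name, m in self.masks.items():
            if not m.any():
                raise ValueError(f"ROI '{name}' is empty")
            total = m.astype(int) if total is None else total + m.astype(int)
        if total is not None and total.max() > 1:
            raise ValueError("ROI masks must be pairwise disjoint")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]


@dataclass
class RatioTraces:
    """Corrected per-ROI ratio traces with raw means and QC flags."""

    t: np.ndarray
    ratio: dict[str, np.ndarray]
    cfp_raw: dict[str, np.ndarray]
    yfp_raw: dict[str, np.ndarray]
    qc_ok: dict[str, np.ndarray]
    alpha: float

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for roi in self.ratio:
            rows.append(pd.DataFrame({
                "t_min": self.t, "roi": roi,
                "cfp_raw": self.cfp_raw[roi], "yfp_raw": self.yfp_raw[roi],
                "ratio": self.ratio[roi], "qc_ok": self.qc_ok[roi]}))
        return pd.concat(rows, ignore_index=True)


def register_stack(stack: ImageStack, upsample: int = 1
                   ) -> tuple[ImageStack, np.ndarray]:
    """Translation-register a stack against its first frame.

    Shifts are estimated by cross-correlation on the summed-channel
    image and applied identically to both channels (integer pixels).
    A frame with zero variance cannot be registered; its shift is
    carried forward from the previous frame.
    """
    if len(stack.frames) < 2:
        raise ValueError("registration requires at least two frames")
    ref = stack.frames[0].sum(axis=0).astype(float)
    shifts = np.zeros((len(stack.frames), 2))
    aligned = stack.frames.copy()
    prev = np.zeros(2)
    for i in range(1, len(stack.frames)):
        img = stack.frames[i].sum(axis=0).astype(float)
        if img.std() == 0 or ref.std() == 0:
            shifts[i] = prev
        else:
            shift, _, _ = phase_cross_correlation(ref, img,
                                                  upsample_factor=upsample)
            shifts[i] = shift
        prev = shifts[i]
        si = np.round(shifts[i]).astype(int)
        aligned[i] = np.roll(stack.frames[i], tuple(si), axis=(1, 2))
    out = ImageStack(frames=aligned, frame_times=stack.frame_times,
                     scene=stack.scene, true_shifts=stack.true_shifts,
                     true_concentrations=stack.true_concentrations,
                     true_ratios=stack.true_ratios,
                     nebd_frame=stack.nebd_frame, seed=stack.seed)
    return out, shifts


def define_rois(shape: tuple[int, int], center: tuple[float, float],
                follicle_radius: float, oocyte_radius: float,
                nucleus_radius: float, pixel_size: float,
                mural_band_width: float = 40.0,
                cumulus_band_width: float = 25.0,
                background_margin: float = 15.0) -> ROISet:
    """Concentric geometric ROIs (all radii and widths in um).

    outer_mural is the inward band of ``mural_band_width`` from the
    follicle boundary; cumulus the outward band of ``cumulus_band_width``
    from the oocyte boundary; background everything beyond the follicle
    plus a safety margin (clear of the theca rim).
    """
    if oocyte_radius >= follicle_radius:
        raise ValueError("oocyte outline must lie inside the follicle outline")
    r_cum = oocyte_radius + cumulus_band_width
    if r_cum >= follicle_radius - mural_band_width:
        raise ValueError("cumulus and mural bands overlap: follicle too small")
    px = pixel_size
    rows = np.arange(shape[0])[:, None] - center[0]
    cols = np.arange(shape[1])[None, :] - center[1]
    rr = np.hypot(rows, cols) * px
    masks = {
        "outer_mural": (rr < follicle_radius)
                       & (rr >= follicle_radius - mural_band_width),
        "cumulus": (rr < r_cum) & (rr >= oocyte_radius),
        "oocyte": (rr < oocyte_radius) & (rr >= nucleus_radius),
        "nucleus": rr < nucleus_radius,
        "background": rr >= follicle_radius + background_margin,
    }
    return ROISet(masks=masks, provenance="geometric")


def rois_from_ground_truth(stack: ImageStack) -> ROISet:
    """ROIs taken directly from the generator's reference masks."""
    return ROISet(masks=dict(stack.masks), provenance="ground-truth")


def correct_channels(cfp_mean, yfp_mean_raw, cfp_bg, yfp_bg,
                     alpha: float = 0.23, floor: float = 10.0):
    """Background subtraction then spectral-overlap correction.

    cfp_corr = cfp - cfp_bg;  yfp_corr = (yfp - yfp_bg) - alpha*cfp_corr;
    ratio = cfp_corr / yfp_corr, flagged undefined (not raised) where
    the corrected YFP falls at or below ``floor`` counts.
    """
    if not 0.0 <= alpha < 1.0:
        raise ValueError("alpha must be in [0, 1)")
    scalar = np.ndim(cfp_mean) == 0 and np.ndim(yfp_mean_raw) == 0
    cfp_corr = np.asarray(cfp_mean, dtype=float) - cfp_bg
    yfp_corr = np.asarray(yfp_mean_raw, dtype=float) - yfp_bg - alpha * cfp_corr
    cfp_corr, yfp_corr = np.broadcast_arrays(cfp_corr, yfp_corr)
    ok = yfp_corr > floor
    ratio = np.where(ok, cfp_corr / np.where(ok, yfp_corr, 1.0), np.nan)
    if scalar:
        return float(cfp_corr), float(yfp_corr), float(ratio)
    return cfp_corr, yfp_corr, ratio


def extract_traces(stack: ImageStack, rois: ROISet,
                   alpha: float | None = None,
                   background: Mapping[str, tuple[float, float]] | None = None,
                   floor: float = 10.0) -> RatioTraces:
    """Per-frame, per-ROI corrected CFP/YFP ratio traces.

    ``background`` maps ROI name to per-region (cfp, yfp) background
    levels, as measured from uninjected follicles (see
    :func:`background_from_fixtures`); when absent, the stack's own
    background ROI provides a single per-frame background estimate.
    """
    if alpha is None:
        alpha = stack.scene.bleedthrough_alpha
    frames = stack.frames.astype(float)
    t = stack.frame_times
    signal_rois = [r for r in rois.masks if r != "background"]
    ratio, cfp_raw, yfp_raw, qc = {}, {}, {}, {}
    if background is None:
        if "background" not in rois.masks:
            raise ValueError("no background ROI and no fixture backgrounds")
        bgm = rois["background"]
        bg_cfp = frames[:, 0][:, bgm].mean(axis=1)
        bg_yfp = frames[:, 1][:, bgm].mean(axis=1)
        bg_for = lambda roi: (bg_cfp, bg_yfp)  # noqa: E731
    else:
        bg_for = lambda roi: background.get(roi, background.get("default"))  # noqa: E731
    for roi in signal_rois:
        m = rois[roi]
        cfp = frames[:, 0][:, m].mean(axis=1)
        yfp = frames[:, 1][:, m].mean(axis=1)
        b_c, b_y = bg_for(roi)
        cc, yc, rr = correct_channels(cfp, yfp, b_c, b_y, alpha, floor)
        ratio[roi], cfp_raw[roi], yfp_raw[roi] = rr, cfp, yfp
        qc[roi] = yc > floor
    return RatioTraces(t=t, ratio=ratio, cfp_raw=cfp_raw, yfp_raw=yfp_raw,
                       qc_ok=qc, alpha=alpha)


def background_from_fixtures(stacks: Iterable[ImageStack], rois: ROISet
                             ) -> dict[str, tuple[float, float]]:
    """Per-region backgrounds averaged over uninjected-follicle stacks."""
    sums: dict[str, list[tuple[float, float]]] = {}
    for stack in stacks:
        frames = stack.frames.astype(float)
        for roi, m in rois.masks.items():
            pair = (frames[:, 0][:, m].mean(), frames[:, 1][:, m].mean())
            sums.setdefault(roi, []).append(pair)
    return {roi: tuple(np.mean(v, axis=0)) for roi, v in sums.items()}


# ---------------------------------------------------------------- metrics

def _baseline(t: np.ndarray, y: np.ndarray, lh_time: float = 0.0,
              min_frames: int = 5) -> float:
    pre = y[t < lh_time]
    if len(pre) < min_frames:
        raise MetricUndefinedError(
            f"need >= {min_frames} pre-LH frames, got {len(pre)}")
    return float(pre.mean())


def _cross_up(t: np.ndarray, y: np.ndarray, thr: float, start: float) -> float:
    post = t >= start
    ti, yi = t[post], y[post]
    idx = np.flatnonzero((yi[1:] >= thr) & (yi[:-1] < thr))
    if yi[0] >= thr:
        return float(ti[0])
    if len(idx) == 0:
        raise MetricUndefinedError("threshold never crossed upward")
    i = idx[0]
    return float(ti[i] + (thr - yi[i]) / (yi[i + 1] - yi[i]) * (ti[i + 1] - ti[i]))


def _cross_down(t: np.ndarray, y: np.ndarray, thr: float, start: float) -> float:
    post = t >= start
    ti, yi = t[post], y[post]
    idx = np.flatnonzero((yi[1:] <= thr) & (yi[:-1] > thr))
    if yi[0] <= thr:
        return float(ti[0])
    if len(idx) == 0:
        raise MetricUndefinedError("threshold never crossed downward")
    i = idx[0]
    return float(ti[i] + (yi[i] - thr) / (yi[i] - yi[i + 1]) * (ti[i + 1] - ti[i]))


def time_to_fraction_of_peak(t: Sequence[float], y: Sequence[float],
                             fraction: float = 0.5,
                             lh_time: float = 0.0) -> float:
    """Time after LH to reach baseline + fraction*(peak - baseline).

    Baseline is the pre-LH mean; peak the post-LH maximum; the first
    upward crossing is linearly interpolated between samples.
    """
    t, y = np.asarray(t, float), np.asarray(y, float)
    base = _baseline(t, y, lh_time)
    peak = float(y[t >= lh_time].max())
    if peak <= base:
        raise MetricUndefinedError("no post-LH rise above baseline")
    thr = base + fraction * (peak - base)
    return _cross_up(t, y, thr, lh_time) - lh_time


def time_to_fractional_decline(t: Sequence[float], y: Sequence[float],
                               fraction: float = 0.25,
                               lh_time: float = 0.0) -> float:
    """Time after LH to decline by ``fraction`` of (baseline - post-LH min)."""
    t, y = np.asarray(t, float), np.asarray(y, float)
    base = _baseline(t, y, lh_time)
    post_min = float(y[t >= lh_time].min())
    if post_min >= base:
        raise MetricUndefinedError("post-LH minimum is not below baseline")
    thr = base - fraction * (base - post_min)
    return _cross_down(t, y, thr, lh_time) - lh_time


def time_below_baseline(t: Sequence[float], y: Sequence[float],
                        lh_time: float = 0.0) -> float | None:
    """First downward crossing through baseline after the post-LH peak."""
    t, y = np.asarray(t, float), np.asarray(y, float)
    base = _baseline(t, y, lh_time)
    post = t >= lh_time
    peak_t = float(t[post][np.argmax(y[post])])
    try:
        return _cross_down(t, y, base, peak_t) - lh_time
    except MetricUndefinedError:
        return None


def time_to_near_minimum(t: Sequence[float], y: Sequence[float],
                         fraction: float = 0.05,
                         lh_time: float = 0.0) -> float:
    """Time after LH to come within ``fraction`` of the full decline.

    The trace has reached (1 - fraction) of its baseline-to-minimum
    excursion; used as the operational 'time to reach the minimum
    level'.
    """
    t, y = np.asarray(t, float), np.asarray(y, float)
    base = _baseline(t, y, lh_time)
    post_min = float(y[t >= lh_time].min())
    if post_min >= base:
        raise MetricUndefinedError("post-LH minimum is not below baseline")
    thr = post_min + fraction * (base - post_min)
    return _cross_down(t, y, thr, lh_time) - lh_time


@dataclass(frozen=True)
class KineticMetrics:
    baseline: float
    peak_value: float
    peak_time: float
    min_value: float
    min_time: float
    t50_peak: float | None = None
    t25_decline: float | None = None
    t_below_baseline: float | None = None
    nebd_time: float | None = None


def compute_kinetic_metrics(t: Sequence[float], y: Sequence[float],
                            lh_time: float = 0.0,
                            nebd_time_value: float | None = None
                            ) -> KineticMetrics:
    """All landmark metrics for one trace; undefined landmarks are None."""
    t, y = np.asarray(t, float), np.asarray(y, float)
    base = _baseline(t, y, lh_time)
    post = t >= lh_time
    ti, yi = t[post], y[post]

    def safe(fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except MetricUndefinedError:
            return None

    return KineticMetrics(
        baseline=base,
        peak_value=float(yi.max()), peak_time=float(ti[np.argmax(yi)]),
        min_value=float(yi.min()), min_time=float(ti[np.argmin(yi)]),
        t50_peak=safe(time_to_fraction_of_peak, t, y, 0.5, lh_time),
        t25_decline=safe(time_to_fractional_decline, t, y, 0.25, lh_time),
        t_below_baseline=time_below_baseline(t, y, lh_time),
        nebd_time=nebd_time_value)


def detect_nebd(stack: ImageStack, rois: ROISet,
                high: float = 0.7, low: float = 0.4) -> float | None:
    """NEBD time from the appearance of fluorescence in the nucleus.

    Returns the time of the first frame where the background-subtracted
    nuclear mean exceeds ``high`` times the oocyte-cytoplasm mean,
    provided it was below ``low`` in all earlier frames; ``None`` if the
    nucleus never fills.
    """
    for name in ("nucleus", "oocyte"):
        if name not in rois.masks or not rois[name].any():
            raise ValueError(f"'{name}' mask missing or empty")
    frames = stack.frames.astype(float).sum(axis=1)  # summed channels
    if "background" in rois.masks:
        bg = frames[:, rois["background"]].mean(axis=1)
    else:
        bg = np.zeros(len(frames))
    nuc = frames[:, rois["nucleus"]].mean(axis=1) - bg
    ooc = frames[:, rois["oocyte"]].mean(axis=1) - bg
    rel = np.divide(nuc, ooc, out=np.zeros_like(nuc), where=ooc > 0)
    for i, r in enumerate(rel):
        if r >= high:
            if np.all(rel[:i] < low):
                return float(stack.frame_times[i])
            return None
    return None


def summarize_traces(traces: Sequence[tuple[np.ndarray, np.ndarray]],
                     grid: np.ndarray | None = None,
                     ci: float = 0.95) -> pd.DataFrame:
    """Per-timepoint mean, SEM and t-based confidence interval.

    ``traces`` is a sequence of (t, y) pairs; they are linearly
    resampled onto a common grid (the first trace's grid by default).
    """
    if len(traces) < 2:
        raise MetricUndefinedError("SEM requires at least two traces")
    if grid is None:
        grid = np.asarray(traces[0][0], dtype=float)
    ys = np.vstack([np.interp(grid, np.asarray(t, float), np.asarray(y, float))
                    for t, y in traces])
    n = ys.shape[0]
    mean = ys.mean(axis=0)
    sem = ys.std(axis=0, ddof=1) / np.sqrt(n)
    tcrit = stats.t.ppf(0.5 + ci / 2, n - 1)
    return pd.DataFrame({"t_min": grid, "mean": mean, "sem": sem, "n": n,
                         "ci_lo": mean - tcrit * sem,
                         "ci_hi": mean + tcrit * sem})


def nebd_histogram(nebd_times: Sequence[float], bin_width: float = 15.0,
                   t_max: float | None = None) -> pd.DataFrame:
    """NEBD times binned in 15-min increments with cumulative percent."""
    times = np.asarray([x for x in nebd_times if x is not None], dtype=float)
    n_total = len(list(nebd_times))
    if t_max is None:
        t_max = times.max() if len(times) else bin_width
    edges = np.arange(0.0, t_max + bin_width, bin_width)
    counts, edges = np.histogram(times, bins=edges)
    cum = np.cumsum(counts)
    return pd.DataFrame({"bin_start": edges[:-1], "bin_end": edges[1:],
                         "count": counts,
                         "cumulative_pct": 100.0 * cum / max(n_total, 1)})
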