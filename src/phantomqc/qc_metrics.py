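"""Quality-control metrics for 4D phantom EPI series.

Implements the NEMA-style static spatial noise map, temporal fluctuation
noise (TFN) and the signal-to-fluctuation-noise ratio (SFNR), the ROI
signal-to-noise ratio, the four-background-ROI ghosting ratio, percent
signal change (PSC), stimulus-detection efficiency, baseline stability,
and simple motion and k-space stability summaries.  All metrics operate
on any :class:`~phantomqc.epi_simulator.TimeSeries4D`, simulated or read
from a real scan.

Conventions: volume numbering for odd/even splits is 1-based; standard
deviations are population SDs (divide by n); ROIs are axial squares
identified by a center voxel and a side length, so "9 pixels" is a 3×3
square and "4 pixels" a 2×2 square.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict
from scipy import ndimage

from .epi_simulator import BlockDesign, TimeSeries4D, segments_volumes
from .exceptions import ConfigurationError, InputError


@dataclass(frozen=True)
class ROISpec:
    """A square axial region of interest.

    ``side`` voxels per edge centred at ``center`` = (x, y, slice); for an
    even side the square starts at the center voxel (covers [c, c+1) per
    axis for side 2).
    """

    center: tuple[int, int, int]
    side: int = 3
    label: str = "roi"

    def __post_init__(self):
        if self.side < 1:
            raise ConfigurationError("ROI side must be >= 1")

    @property
    def n_pixels(self) -> int:
        return self.side * self.side

    def slices(self) -> tuple[slice, slice, int]:
        cx, cy, cz = self.center
        half = (self.side - 1) // 2
        return (
            slice(cx - half, cx - half + self.side),
            slice(cy - half, cy - half + self.side),
            cz,
        )

    def validate_bounds(self, shape: tuple[int, ...]) -> None:
        sx, sy, cz = self.slices()
        if sx.start < 0 or sy.start < 0 or sx.stop > shape[0] or sy.stop > shape[1]:
            raise ConfigurationError(
                f"ROI '{self.label}' ({self.side}x{self.side} at {self.center}) "
                f"exceeds image bounds {shape[:2]}"
            )
        if not 0 <= cz < shape[2]:
            raise ConfigurationError(
                f"ROI '{self.label}' slice {cz} outside [0, {shape[2]})"
            )


@dataclass(frozen=True)
class TimeSignalCurve:
    """Per-volume mean signal of one ROI."""

    values: np.ndarray
    TR_ms: float
    roi: ROISpec | None = None

    def __len__(self) -> int:
        return len(self.values)


def roi_block(series: TimeSeries4D, roi: ROISpec) -> np.ndarray:
    """The (side, side, n_volumes) voxel block of an ROI."""
    roi.validate_bounds(series.shape)
    sx, sy, cz = roi.slices()
    return series.data[sx, sy, cz, :]


def roi_curve(series: TimeSeries4D, roi: ROISpec) -> TimeSignalCurve:
    """Time-signal intensity curve: ROI mean per volume."""
    block = roi_block(series, roi)
    return TimeSignalCurve(values=block.mean(axis=(0, 1)), TR_ms=series.TR_ms, roi=roi)


# ---------------------------------------------------------------------------
# Noise and SNR metrics


def static_spatial_noise(series: TimeSeries4D) -> np.ndarray:
    """NEMA-style static spatial noise map.

    Per voxel: |sum of odd-numbered volumes - sum of even-numbered
    volumes| with 1-based numbering.  An odd total volume count is
    truncated to the largest even number so the two sums have equal size.
    """
    nt = series.n_volumes
    if nt < 2:
        raise InputError("need at least 2 volumes")
    nt -= nt % 2
    data = series.data[..., :nt]
    return np.abs(data[..., 0::2].sum(axis=-1) - data[..., 1::2].sum(axis=-1))


def roi_summary(voxel_map: np.ndarray, roi: ROISpec) -> float:
    """Mean of a per-voxel map (2D axial or 3D) over an ROI."""
    sx, sy, cz = roi.slices()
    if voxel_map.ndim == 2:
        # an axial map: the ROI's slice index is irrelevant
        roi.validate_bounds((*voxel_map.shape, roi.center[2] + 1))
        patch = voxel_map[sx, sy]
    else:
        roi.validate_bounds(voxel_map.shape)
        patch = voxel_map[sx, sy, cz]
    return float(patch.mean())


def tfn_map(series: TimeSeries4D) -> np.ndarray:
    """Per-voxel temporal fluctuation noise: SD of the signal over time."""
    if series.n_volumes < 2:
        raise InputError("need at least 2 volumes")
    return series.data.std(axis=-1)  # population SD


def temporal_fluctuation_noise(series: TimeSeries4D, roi: ROISpec) -> float:
    """ROI TFN: mean over the ROI of the per-voxel temporal SDs."""
    return roi_summary(tfn_map(series), roi)


def sfnr(series: TimeSeries4D, roi: ROISpec) -> float:
    """Signal-to-fluctuation-noise ratio: ROI mean signal / ROI TFN.

    A zero TFN (noiseless constant series) is a degenerate input and is
    flagged by returning ``inf`` rather than raising.
    """
    tfn = temporal_fluctuation_noise(series, roi)
    mean_signal = roi_summary(series.data.mean(axis=-1), roi)
    if tfn == 0.0:
        return math.inf
    return mean_signal / tfn


def snr(signal_roi_mean: float, static_noise_per_timepoint: float) -> float:
    """ROI signal-to-noise ratio: Signal / sqrt(noise per time point).

    The noise argument is the static-spatial-noise ROI summary already
    expressed per time point (i.e. divided by the number of volumes that
    entered the odd/even sums); passing the raw summary instead changes
    the result by the square root of the volume count.  Zero noise is
    flagged as ``inf``.
    """
    if static_noise_per_timepoint < 0:
        raise InputError("noise must be >= 0")
    if static_noise_per_timepoint == 0.0:
        return math.inf
    return signal_roi_mean / math.sqrt(static_noise_per_timepoint)


# ---------------------------------------------------------------------------
# Phantom mask, ghosting


def phantom_mask(series: TimeSeries4D, threshold_fraction: float = 0.2) -> np.ndarray:
    """Boolean foreground mask from the time-mean image.

    A voxel is foreground when its temporal mean exceeds
    ``threshold_fraction`` times the robust (99th percentile) maximum.
    """
    mean_img = series.data.mean(axis=-1)
    thr = threshold_fraction * np.percentile(mean_img, 99)
    return mean_img > thr


def default_background_rois(
    series: TimeSeries4D, center_roi: ROISpec
) -> dict[str, ROISpec]:
    """Place up/down/left/right background ROIs outside the phantom.

    Each ROI shares the center ROI's side length and sits midway between
    the phantom edge (from the foreground mask, along the axis through the
    center ROI) and the image edge.
    """
    mask = phantom_mask(series)
    nx, ny = mask.shape[:2]
    cx, cy, cz = center_roi.center
    col = np.where(mask[cx, :, cz])[0]
    row = np.where(mask[:, cy, cz])[0]
    if len(col) == 0 or len(row) == 0:
        raise InputError("foreground mask is empty along the center ROI axes")
    out = {
        "up": ROISpec((cx, (col.max() + ny - 1) // 2, cz), center_roi.side, "bg_up"),
        "down": ROISpec((cx, col.min() // 2, cz), center_roi.side, "bg_down"),
        "right": ROISpec(((row.max() + nx - 1) // 2, cy, cz), center_roi.side, "bg_right"),
        "left": ROISpec((row.min() // 2, cy, cz), center_roi.side, "bg_left"),
    }
    return out


def _ghost_numerator_per_volume(
    series: TimeSeries4D,
    center_roi: ROISpec,
    background_rois: dict[str, ROISpec],
) -> tuple[np.ndarray, np.ndarray]:
    required = {"up", "down", "left", "right"}
    if set(background_rois) != required:
        raise ConfigurationError(
            f"background ROIs must be exactly {sorted(required)}"
        )
    mask = phantom_mask(series)
    curves = {}
    for name, roi in background_rois.items():
        if roi.side != center_roi.side:
            raise ConfigurationError(
                f"background ROI '{name}' size differs from the center ROI"
            )
        roi.validate_bounds(series.shape)
        sx, sy, cz = roi.slices()
        if mask[sx, sy, cz].any():
            raise ConfigurationError(
                f"background ROI '{name}' overlaps the phantom foreground"
            )
        curves[name] = roi_curve(series, roi).values
    num = (curves["up"] + curves["down"]) - (curves["right"] + curves["left"])
    center = roi_curve(series, center_roi).values
    return num, center


def ghosting_ratio(
    series: TimeSeries4D,
    center_roi: ROISpec,
    background_rois: dict[str, ROISpec] | None = None,
) -> float:
    """N/2 ghosting ratio in percent.

    |（up + down) - (right + left)| / (2 × center) × 100 using
    time-averaged ROI means; up/down lie along the phase-encode axis where
    the Nyquist ghost accumulates, left/right across it.
    """
    if background_rois is None:
        background_rois = default_background_rois(series, center_roi)
    num, center = _ghost_numerator_per_volume(series, center_roi, background_rois)
    return float(abs(num.mean()) / (2.0 * center.mean()) * 100.0)


def ghosting_ratio_se(
    series: TimeSeries4D,
    center_roi: ROISpec,
    background_rois: dict[str, ROISpec] | None = None,
) -> float:
    """Standard error of the ghosting ratio from its per-volume spread."""
    if background_rois is None:
        background_rois = default_background_rois(series, center_roi)
    num, center = _ghost_numerator_per_volume(series, center_roi, background_rois)
    se_num = num.std(ddof=1) / math.sqrt(len(num))
    return float(se_num / (2.0 * center.mean()) * 100.0)


# ---------------------------------------------------------------------------
# Percent signal change and stimulus detection


def _design_windows(
    curve: TimeSignalCurve, design: BlockDesign
) -> list[tuple[str, float, int, int]]:
    return segments_volumes(design, len(curve), curve.TR_ms)


def _active_indices(seg: tuple[str, float, int, int]) -> np.ndarray:
    """Volumes of an active block, dropping the first as switch transition."""
    _, _, start, stop = seg
    return np.arange(start + 1, stop) if stop - start > 1 else np.arange(start, stop)


def psc(
    curve: TimeSignalCurve,
    design: BlockDesign | None = None,
    *,
    window: int = 5,
) -> float:
    """Percent signal change |Active - Baseline| / Baseline × 100.

    With a design, Active is the mean over active-block volumes (dropping
    the first volume of each block as the switching transition) and
    Baseline the mean over all baseline-block volumes.  Without a design
    the "most obvious change" fallback is used: the contiguous window of
    ``window`` volumes whose mean deviates most from the series median is
    Active, the complement is Baseline.  A non-positive baseline is a
    degenerate input flagged as ``nan``.
    """
    v = np.asarray(curve.values, dtype=float)
    if design is not None:
        segs = _design_windows(curve, design)
        active_idx = np.concatenate(
            [_active_indices(s) for s in segs if s[0] == "active"] or [np.array([], int)]
        )
        baseline_idx = np.concatenate(
            [np.arange(s[2], s[3]) for s in segs if s[0] == "baseline"]
            or [np.array([], int)]
        )
        if len(active_idx) == 0 or len(baseline_idx) == 0:
            raise InputError("curve does not cover one full baseline/active cycle")
        active = v[active_idx].mean()
        baseline = v[baseline_idx].mean()
    else:
        if window >= len(v):
            raise InputError("window must be shorter than the curve")
        med = np.median(v)
        means = np.convolve(v, np.ones(window) / window, mode="valid")
        k = int(np.argmax(np.abs(means - med)))
        sel = np.zeros(len(v), dtype=bool)
        sel[k : k + window] = True
        active = v[sel].mean()
        baseline = v[~sel].mean()
    if baseline <= 0:
        return math.nan
    return float(abs(active - baseline) / baseline * 100.0)


def psc_per_level(
    curve: TimeSignalCurve, design: BlockDesign
) -> dict[float, float]:
    """PSC per current level when a run cycles several levels.

    Active means are grouped by the block's current; the baseline is the
    pooled mean over all baseline blocks.
    """
    v = np.asarray(curve.values, dtype=float)
    segs = _design_windows(curve, design)
    baseline_idx = np.concatenate(
        [np.arange(s[2], s[3]) for s in segs if s[0] == "baseline"]
        or [np.array([], int)]
    )
    if len(baseline_idx) == 0:
        raise InputError("curve contains no baseline volumes")
    baseline = v[baseline_idx].mean()
    out: dict[float, float] = {}
    for level in sorted({s[1] for s in segs if s[0] == "active"}):
        idx = np.concatenate(
            [_active_indices(s) for s in segs if s[0] == "active" and s[1] == level]
        )
        out[level] = (
            math.nan
            if baseline <= 0
            else float(abs(v[idx].mean() - baseline) / baseline * 100.0)
        )
    return out


def detect_stimuli(
    curve: TimeSignalCurve,
    design: BlockDesign,
    threshold_k: float = 2.0,
) -> tuple[int, list[bool]]:
    """Count stimulus blocks recovered from a time-signal curve.

    An active block is detected when the absolute difference between its
    mean (first volume dropped) and the mean of the flanking baseline
    blocks exceeds ``threshold_k`` times the baseline temporal fluctuation
    noise (SD of baseline volumes, first volume of each baseline block
    dropped).  Returns (N_actual, per-block flags).
    """
    v = np.asarray(curve.values, dtype=float)
    segs = _design_windows(curve, design)
    active_segs = [(i, s) for i, s in enumerate(segs) if s[0] == "active"]
    if not active_segs:
        raise InputError("curve covers no active block")
    baseline_vals = np.concatenate(
        [
            v[s[2] + 1 : s[3]] if s[3] - s[2] > 1 else v[s[2] : s[3]]
            for s in segs
            if s[0] == "baseline"
        ]
        or [np.array([])]
    )
    if len(baseline_vals) == 0:
        raise InputError("curve covers no baseline block")
    tfn_baseline = float(baseline_vals.std())
    flags: list[bool] = []
    for i, seg in active_segs:
        flank = []
        if i > 0 and segs[i - 1][0] == "baseline":
            s = segs[i - 1]
            flank.append(v[s[2] + 1 : s[3]] if s[3] - s[2] > 1 else v[s[2] : s[3]])
        if i + 1 < len(segs) and segs[i + 1][0] == "baseline":
            s = segs[i + 1]
            flank.append(v[s[2] + 1 : s[3]] if s[3] - s[2] > 1 else v[s[2] : s[3]])
        if not flank:
            flags.append(False)
            continue
        contrast = abs(v[_active_indices(seg)].mean() - np.concatenate(flank).mean())
        flags.append(bool(contrast > threshold_k * tfn_baseline))
    return sum(flags), flags


def sensitivity(n_actual: int, n_theoretical: int) -> float:
    """Stimulus detection efficiency (N_actual / N_theoretical) × 100."""
    if n_theoretical < 1:
        raise InputError("n_theoretical must be >= 1")
    if not 0 <= n_actual <= n_theoretical:
        raise InputError("need 0 <= n_actual <= n_theoretical")
    return n_actual / n_theoretical * 100.0


def baseline_stability(curve: TimeSignalCurve) -> tuple[float, float]:
    """Max percent deviation from the mean and the min-max range.

    Intended for a baseline-only (zero-current) curve; returns
    (max |S_t - mean| / mean × 100, max - min).
    """
    v = np.asarray(curve.values, dtype=float)
    mean = v.mean()
    if mean == 0:
        raise InputError("curve mean is zero")
    return (
        float(np.abs(v - mean).max() / mean * 100.0),
        float(v.max() - v.min()),
    )


# ---------------------------------------------------------------------------
# Motion and k-space stability


def motion_summary(series: TimeSeries4D) -> dict:
    """Rigid-motion proxy from intensity moments, per volume.

    Translation is the displacement (mm) of the foreground center of mass
    relative to the first volume.  In-plane rotation is the change in
    orientation of the principal second-moment axis of the middle slice;
    because a gel cylinder is nearly circular, the moments are computed on
    the *structure* image (the positive deviation of the time-mean from
    each volume, dominated by the signal-void wire holes), whose strong
    anisotropy conditions the angle estimate.  Returns per-volume arrays
    and their maxima.
    """
    if not phantom_mask(series).any():
        raise InputError("empty foreground; cannot summarize motion")
    mean_img = series.data.mean(axis=-1)
    thr = 0.2 * np.percentile(mean_img, 99)
    vs = np.asarray(series.voxel_size_mm)
    mid = series.shape[2] // 2
    nt = series.n_volumes
    coms = np.zeros((nt, 3))
    angles = np.zeros(nt)
    xi, yi = np.indices(series.shape[:2])
    for t in range(nt):
        vol = series.data[..., t]
        m_t = vol > thr  # per-volume mask so the foreground follows the object
        if not m_t.any():
            raise InputError(f"volume {t} has an empty foreground")
        coms[t] = ndimage.center_of_mass(np.where(m_t, vol, 0.0))
        sl = vol[:, :, mid]
        disc = ndimage.binary_fill_holes(m_t[:, :, mid])
        med = np.median(sl[disc])
        # landmarks: signal voids (wire holes) well below the gel level;
        # the 25 % margin keeps the thermal-noise floor out of the moments
        feat = np.where(disc & (sl < 0.75 * med), med - sl, 0.0)
        w = feat.sum()
        if w <= 0:  # featureless slice (no holes, no noise): no rotation signal
            angles[t] = 0.0
            continue
        mx, my = (feat * xi).sum() / w, (feat * yi).sum() / w
        cxx = (feat * (xi - mx) ** 2).sum() / w
        cyy = (feat * (yi - my) ** 2).sum() / w
        cxy = (feat * (xi - mx) * (yi - my)).sum() / w
        angles[t] = 0.5 * math.degrees(math.atan2(2.0 * cxy, cxx - cyy))
    disp = np.linalg.norm((coms - coms[0]) * vs, axis=1)
    rot = angles - angles[0]
    rot = (rot + 90.0) % 180.0 - 90.0  # principal axis is 180-deg periodic
    return {
        "translation_mm": disp,
        "rotation_deg": np.abs(rot),
        "max_translation_mm": float(disp.max()),
        "max_rotation_deg": float(np.abs(rot).max()),
    }


def kspace_stability(series: TimeSeries4D) -> dict:
    """Across-volume stability of the central k-space line.

    For each volume the middle slice is Fourier transformed; the amplitude
    profile along the central horizontal k-space line, normalized by the
    DC term (the across-volume median, so whole-volume amplitude
    transients stay visible), is tracked.  Reports the per-point max-min
    variation across volumes and its maximum — the screen for RF
    interference spikes.
    """
    mid = series.shape[2] // 2
    nx = series.shape[0]
    nt = series.n_volumes
    profiles = np.zeros((nt, nx))
    dcs = np.zeros(nt)
    for t in range(nt):
        f = np.fft.fft2(series.data[:, :, mid, t])
        dcs[t] = np.abs(f[0, 0])
        profiles[t] = np.abs(np.fft.fftshift(f, axes=0)[:, 0])
    dc_ref = np.median(dcs)
    if dc_ref > 0:
        profiles /= dc_ref
    variation = profiles.max(axis=0) - profiles.min(axis=0)
    return {
        "profiles": profiles,
        "variation": variation,
        "max_variation": float(variation.max()),
    }


# ---------------------------------------------------------------------------
# Aggregate report


class ROIReport(BaseModel):
    """Per-ROI scalar metrics."""

    model_config = ConfigDict(extra="forbid")

    label: str
    center: tuple[int, int, int]
    side: int
    n_pixels: int
    signal: float
    static_spatial_noise: float
    static_noise_per_timepoint: float
    tfn: float
    sfnr: float | None
    snr: float | None


class MotionReport(BaseModel):
    model_config = ConfigDict(extra="forbid")

    max_translation_mm: float
    max_rotation_deg: float
    translation_limit_mm: float = 0.1
    rotation_limit_deg: float = 0.1
    translation_ok: bool = True
    rotation_ok: bool = True


class QCReport(BaseModel):
    """Serializable summary of all QC metrics for one series."""

    model_config = ConfigDict(extra="forbid")

    n_volumes: int
    TR_ms: float
    voxel_size_mm: tuple[float, float, float]
    rois: list[ROIReport]
    ghosting_ratio_pct: float | None = None
    ghosting_ratio_se_pct: float | None = None
    background_roi_centers: dict[str, tuple[int, int, int]] | None = None
    psc_pct: dict[str, float] | None = None
    sensitivity_pct: float | None = None
    n_actual: int | None = None
    n_theoretical: int | None = None
    detection_threshold_k: float | None = None
    baseline_stability_pct: float | None = None
    baseline_range: float | None = None
    motion: MotionReport | None = None
    kspace_max_variation: float | None = None
    seed: int | None = None
    config_sha256: str | None = None


def _roi_report(series: TimeSeries4D, roi: ROISpec) -> ROIReport:
    noise_map = static_spatial_noise(series)
    nt_even = series.n_volumes - series.n_volumes % 2
    noise_sum = roi_summary(noise_map, roi)
    noise_per_tp = noise_sum / nt_even
    signal = roi_summary(series.data.mean(axis=-1), roi)
    ratio = sfnr(series, roi)
    snr_val = snr(signal, noise_per_tp)
    return ROIReport(
        label=roi.label,
        center=roi.center,
        side=roi.side,
        n_pixels=roi.n_pixels,
        signal=signal,
        static_spatial_noise=noise_sum,
        static_noise_per_timepoint=noise_per_tp,
        tfn=temporal_fluctuation_noise(series, roi),
        sfnr=None if math.isinf(ratio) else ratio,
        snr=None if math.isinf(snr_val) else snr_val,
    )


def compute_qc_report(
    series: TimeSeries4D,
    design: BlockDesign | None = None,
    *,
    rois: list[ROISpec] | None = None,
    psc_roi: ROISpec | None = None,
    threshold_k: float = 2.0,
    motion_limits: tuple[float, float] = (0.1, 0.1),
) -> QCReport:
    """Run every applicable metric and assemble a :class:`QCReport`.

    Without an explicit ROI list, a 3×3 ("9 pixel") and a 2×2 ("4 pixel")
    square at the image center of the middle slice are used.  PSC and
    stimulus detection need both a ``design`` and a ``psc_roi`` (an ROI
    containing/adjacent to the energized wire); baseline stability is
    evaluated over the baseline volumes of the PSC ROI curve when a design
    is given, else over the full center-ROI curve.
    """
    nx, ny, nz, _ = series.shape
    center = (nx // 2, ny // 2, nz // 2)
    if rois is None:
        rois = [ROISpec(center, 3, "center_9px"), ROISpec(center, 2, "center_4px")]
    roi_reports = [_roi_report(series, r) for r in rois]

    center_roi = rois[0]
    bg = default_background_rois(series, center_roi)
    ghost = ghosting_ratio(series, center_roi, bg)
    ghost_se = ghosting_ratio_se(series, center_roi, bg)

    psc_dict = None
    sens = n_act = n_theo = None
    stab_pct = stab_range = None
    if design is not None and psc_roi is not None:
        curve = roi_curve(series, psc_roi)
        per_level = psc_per_level(curve, design)
        psc_dict = {f"{lvl:g} mA": val for lvl, val in per_level.items()}
        n_act, _ = detect_stimuli(curve, design, threshold_k)
        segs = segments_volumes(design, len(curve), curve.TR_ms)
        n_theo = sum(1 for s in segs if s[0] == "active")
        sens = sensitivity(n_act, n_theo)
        base_idx = np.concatenate(
            [np.arange(s[2], s[3]) for s in segs if s[0] == "baseline"]
        )
        base_curve = TimeSignalCurve(
            roi_curve(series, center_roi).values[base_idx], series.TR_ms
        )
        stab_pct, stab_range = baseline_stability(base_curve)
    else:
        stab_pct, stab_range = baseline_stability(roi_curve(series, center_roi))

    motion = motion_summary(series)
    kspace = kspace_stability(series)
    return QCReport(
        n_volumes=series.n_volumes,
        TR_ms=series.TR_ms,
        voxel_size_mm=tuple(series.voxel_size_mm),
        rois=roi_reports,
        ghosting_ratio_pct=ghost,
        ghosting_ratio_se_pct=ghost_se,
        background_roi_centers={k: r.center for k, r in bg.items()},
        psc_pct=psc_dict,
        sensitivity_pct=sens,
        n_actual=n_act,
        n_theoretical=n_theo,
        detection_threshold_k=threshold_k if design is not None else None,
        baseline_stability_pct=stab_pct,
        baseline_range=stab_range,
        motion=MotionReport(
            max_translation_mm=motion["max_translation_mm"],
            max_rotation_deg=motion["max_rotation_deg"],
            translation_limit_mm=motion_limits[0],
            rotation_limit_deg=motion_limits[1],
            translation_ok=motion["max_translation_mm"] <= motion_limits[0],
            rotation_ok=motion["max_rotation_deg"] <= motion_limits[1],
        ),
        kspace_max_variation=kspace["max_variation"],
    )
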