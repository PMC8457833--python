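"""Two-channel line-scan quantification of activity-induced calcium influx.

A line scan is a repeated one-dimensional laser sweep across a dendrite or
axon, acquired simultaneously on a calcium-sensitive (green, Fluo-5F-like)
and a calcium-insensitive (red, Alexa-594-like) emission channel.  The
analysis chain implemented here is:

1. :func:`extract_roi` — partition pixels into structure vs. background
   using the time-averaged red channel.
2. :func:`ratio_trace` — background-corrected green/red ratio per line,
   which cancels laser power, dye concentration and focus drift.
3. :func:`dff` — baseline normalization against the 1.2 s window that
   immediately precedes the somatic stimulus, giving ΔF/F.
4. :func:`gaussian_smooth` — 0.5 s Gaussian-weighted moving window.
5. :func:`peak_dff` — the peak of the smoothed ΔF/F after stimulus onset.

Across bath conditions, :func:`delta_peak_percent` expresses the change in
Peak ΔF/F as a percentage of the baseline-condition response (Δ Peak ΔF/F),
and across dendritic locations :func:`attenuation_profile` /
:func:`fit_length_constant` summarize how the response decays with distance
from the soma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "LineScanRecording",
    "CalciumTrace",
    "AttenuationProfile",
    "extract_roi",
    "ratio_trace",
    "dff",
    "gaussian_smooth",
    "peak_dff",
    "analyze_recording",
    "delta_peak_percent",
    "baseline_level_change",
    "attenuation_profile",
    "fit_length_constant",
]

DEFAULT_BASELINE_S = 1.2
DEFAULT_SMOOTH_S = 0.5
UNBOUNDED_LAMBDA_CAP_UM = 1e4


@dataclass
class LineScanRecording:
    """Dual-channel photon-count raster (lines in time order x pixels).

    ``green`` and ``red`` hold per-pixel photon counts with one row per
    acquired line; time runs down the rows at ``line_rate_Hz``.
    """

    green: np.ndarray
    red: np.ndarray
    line_rate_Hz: float
    prestim_s: float
    stim_onset_s: float
    stim_duration_s: float
    distance_um: float = 0.0
    compartment: str = "dendrite"
    cell_type: str = "OT-MCN"
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.green = np.asarray(self.green)
        self.red = np.asarray(self.red)
        if self.green.shape != self.red.shape:
            raise ValueError("green and red rasters must have equal shape")
        if self.green.ndim != 2:
            raise ValueError("rasters must be 2-D (lines x pixels)")
        if (self.green < 0).any() or (self.red < 0).any():
            raise ValueError("photon counts must be non-negative")
        if self.stim_onset_s < self.prestim_s - 1e-9:
            raise ValueError("stimulus onset must not precede the "
                             "pre-stimulus window")

    @property
    def n_lines(self) -> int:
        return self.green.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.green.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_lines / self.line_rate_Hz

    @property
    def t(self) -> np.ndarray:
        """Timestamp of each line (interval start), seconds."""
        return np.arange(self.n_lines) / self.line_rate_Hz


@dataclass
class CalciumTrace:
    """A ΔF/F time series with its processing metadata."""

    t: np.ndarray
    dff: np.ndarray
    baseline_window: tuple[float, float]
    response_window: tuple[float, float]
    smooth_window_s: float = 0.0
    peak_dff: float | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.dff = np.asarray(self.dff, dtype=float)
        if self.t.shape != self.dff.shape:
            raise ValueError("t and dff must have equal length")


@dataclass
class AttenuationProfile:
    """Peak ΔF/F versus distance, as a percentage of the most proximal site."""

    distances_um: np.ndarray
    peak_percent_of_proximal: np.ndarray
    fitted_lambda_um: float | None = None

    def __post_init__(self) -> None:
        self.distances_um = np.asarray(self.distances_um, dtype=float)
        self.peak_percent_of_proximal = np.asarray(
            self.peak_percent_of_proximal, dtype=float)

    @property
    def is_unbounded(self) -> bool:
        return self.fitted_lambda_um is not None and np.isinf(self.fitted_lambda_um)


def extract_roi(rec: LineScanRecording,
                threshold_frac: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Partition pixels into structure and background.

    Structure pixels are the contiguous run (containing the brightest
    pixel) where the time-averaged red channel is at least
    ``threshold_frac`` of its maximum; everything else is background.
    The same partition applies to both channels.
    """
    if rec.red.size == 0:
        raise ValueError("red channel is empty")
    profile = rec.red.mean(axis=0)
    peak = profile.max()
    if peak <= 0:
        raise ValueError("no structure detected")
    above = profile >= threshold_frac * peak
    if not above.any():
        raise ValueError("no structure detected")
    # contiguous run containing the brightest pixel
    center = int(np.argmax(profile))
    lo = center
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = center
    while hi < len(profile) - 1 and above[hi + 1]:
        hi += 1
    structure = np.zeros(len(profile), dtype=bool)
    structure[lo:hi + 1] = True
    return structure, ~structure


def ratio_trace(rec: LineScanRecording,
                roi: tuple[np.ndarray, np.ndarray] | None = None,
                subtract_background: bool = True,
                max_invalid_frac: float = 0.05) -> np.ndarray:
    """Per-line fluorescence ratio R(t) = (G - G_bg) / (R - R_bg).

    Lines on which the background-corrected red mean is not positive are
    flagged invalid and filled by linear interpolation from their
    neighbours; if more than ``max_invalid_frac`` of lines are invalid the
    recording is rejected.
    """
    structure, background = roi if roi is not None else extract_roi(rec)
    g = rec.green[:, structure].mean(axis=1)
    r = rec.red[:, structure].mean(axis=1)
    if subtract_background and background.any():
        g = g - rec.green[:, background].mean(axis=1)
        r = r - rec.red[:, background].mean(axis=1)
    invalid = r <= 0
    n_invalid = int(invalid.sum())
    if n_invalid > max_invalid_frac * rec.n_lines:
        raise ValueError(
            f"{n_invalid}/{rec.n_lines} lines have non-positive corrected "
            "red signal; recording rejected")
    ratio = np.empty(rec.n_lines, dtype=float)
    ratio[~invalid] = g[~invalid] / r[~invalid]
    if n_invalid:
        idx = np.arange(rec.n_lines)
        ratio[invalid] = np.interp(idx[invalid], idx[~invalid],
                                   ratio[~invalid])
    return ratio


def dff(rec: LineScanRecording, ratio: np.ndarray | None = None,
        baseline_s: float = DEFAULT_BASELINE_S) -> CalciumTrace:
    """Baseline-normalized ΔF/F from a ratio trace.

    The baseline is the mean ratio over the ``baseline_s`` window ending at
    stimulus onset; ΔF/F(t) = (R(t) - R0) / R0, so the baseline-window mean
    of ΔF/F is zero by construction.
    """
    if ratio is None:
        ratio = ratio_trace(rec)
    t = rec.t
    b0, b1 = rec.stim_onset_s - baseline_s, rec.stim_onset_s
    in_baseline = (t >= b0) & (t < b1)
    if not in_baseline.any():
        raise ValueError("baseline window contains no lines")
    r0 = ratio[in_baseline].mean()
    if r0 <= 0:
        raise ValueError("non-positive baseline ratio")
    return CalciumTrace(
        t=t,
        dff=(ratio - r0) / r0,
        baseline_window=(b0, b1),
        response_window=(rec.stim_onset_s, rec.duration_s),
    )


def _gaussian_kernel(window_s: float, dt: float) -> np.ndarray:
    # total window -> support of +/- window/2, sigma = window/4
    half = int(np.floor(0.5 * window_s / dt))
    sigma = window_s / 4.0
    j = np.arange(-half, half + 1)
    return np.exp(-0.5 * (j * dt / sigma) ** 2)


def gaussian_smooth(trace: CalciumTrace,
                    window_s: float = DEFAULT_SMOOTH_S) -> CalciumTrace:
    """Gaussian-weighted moving window smoothing with edge renormalization.

    Each sample becomes the Gaussian-weighted mean of its neighbours within
    +/- ``window_s``/2 (sigma = ``window_s``/4); near the edges the weights
    are renormalized over the available samples, so a constant input is
    returned unchanged and the output has the input's length.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    dt = float(np.median(np.diff(trace.t)))
    w = _gaussian_kernel(window_s, dt)
    if len(w) < 3:
        warnings.warn("smoothing window shorter than 3 samples; "
                      "returning trace unchanged")
        return replace(trace, smooth_window_s=window_s)
    num = np.convolve(trace.dff, w, mode="same")
    den = np.convolve(np.ones_like(trace.dff), w, mode="same")
    return replace(trace, dff=num / den, smooth_window_s=window_s)


def peak_dff(trace: CalciumTrace) -> float:
    """Peak of the ΔF/F curve within the response window.

    The search window starts at stimulus onset, so pre-stimulus artifacts
    never contribute.
    """
    lo, hi = trace.response_window
    in_win = (trace.t >= lo) & (trace.t <= hi + 1e-12)
    if not in_win.any():
        raise ValueError("response window contains no samples")
    peak = float(trace.dff[in_win].max())
    trace.peak_dff = peak
    return peak


def analyze_recording(rec: LineScanRecording,
                      baseline_s: float = DEFAULT_BASELINE_S,
                      smooth_s: float = DEFAULT_SMOOTH_S) -> CalciumTrace:
    """Full chain: ROI -> ratio -> ΔF/F -> smoothing -> Peak ΔF/F."""
    trace = gaussian_smooth(dff(rec, baseline_s=baseline_s), smooth_s)
    peak_dff(trace)
    return trace


def delta_peak_percent(before: Sequence[float],
                       after: Sequence[float]) -> float:
    """Δ Peak ΔF/F: change in mean Peak ΔF/F across bath conditions,
    as a percentage of the baseline-condition mean."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.size < 1 or after.size < 1:
        raise ValueError("need at least one sweep per condition")
    mb = before.mean()
    if mb <= 0:
        raise ValueError("baseline-condition mean Peak dF/F must be positive")
    return 100.0 * (after.mean() - mb) / mb


def _baseline_ratio_mean(rec: LineScanRecording,
                         baseline_s: float = DEFAULT_BASELINE_S) -> float:
    ratio = ratio_trace(rec)
    t = rec.t
    sel = (t >= rec.stim_onset_s - baseline_s) & (t < rec.stim_onset_s)
    return float(ratio[sel].mean())


def baseline_level_change(before: LineScanRecording | Sequence[LineScanRecording],
                          after: LineScanRecording | Sequence[LineScanRecording],
                          baseline_s: float = DEFAULT_BASELINE_S) -> float:
    """Percent change of the pre-stimulus (basal) ratio across conditions.

    Monitors whether a bath manipulation changed resting calcium levels,
    independently of the activity-induced response.
    """
    def as_list(x):
        return [x] if isinstance(x, LineScanRecording) else list(x)

    mb = np.mean([_baseline_ratio_mean(r, baseline_s) for r in as_list(before)])
    ma = np.mean([_baseline_ratio_mean(r, baseline_s) for r in as_list(after)])
    if mb <= 0:
        raise ValueError("non-positive baseline ratio")
    return 100.0 * (ma - mb) / mb


def attenuation_profile(peaks_by_distance: Mapping[float, Sequence[float]]
                        ) -> AttenuationProfile:
    """Normalize per-distance mean Peak ΔF/F to the most proximal site.

    The most proximal distance is assigned 100%; output is sorted by
    distance regardless of input order.
    """
    if not peaks_by_distance:
        raise ValueError("no distances supplied")
    distances = np.asarray(sorted(peaks_by_distance), dtype=float)
    means = np.asarray([np.mean(peaks_by_distance[d]) for d in distances])
    ref = means[0]
    if ref <= 0:
        raise ValueError("most proximal mean Peak dF/F must be positive")
    return AttenuationProfile(distances_um=distances,
                              peak_percent_of_proximal=100.0 * means / ref)


def fit_length_constant(profile: AttenuationProfile,
                        cap_um: float = UNBOUNDED_LAMBDA_CAP_UM) -> float:
    """Least-squares single-exponential length constant of a profile.

    Fits ``100 * exp(-(x - x0)/lambda)`` with ``x0`` the most proximal
    distance.  Returns ``lambda`` in micrometers, or ``inf`` when the best
    fit exceeds ``cap_um`` (an effectively flat profile, as seen for axons
    or cesium-filled dendrites).  The fitted value is also stored on the
    profile.
    """
    x = profile.distances_um
    y = profile.peak_percent_of_proximal
    if len(x) < 3:
        raise ValueError("need at least 3 distances to fit a length constant")
    x0 = x[0]

    # log-linear initial guess; a non-negative slope means no decay
    with np.errstate(divide="ignore"):
        logy = np.log(np.maximum(y, 1e-12))
    slope = np.polyfit(x, logy, 1)[0]
    lam0 = min(-1.0 / slope, 10 * cap_um) if slope < 0 else 10 * cap_um

    def resid(p):
        return 100.0 * np.exp(-(x - x0) / p[0]) - y

    fit = least_squares(resid, x0=[lam0], bounds=([1e-3], [100 * cap_um]))
    lam = float(fit.x[0])
    result = np.inf if lam > cap_um else lam
    profile.fitted_lambda_um = result
    return result
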