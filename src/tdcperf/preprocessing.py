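"""From raw 4D signal to smoothed curves, a first-pass window and absolute TTP.

Absolute time-to-peak (TTP) is taken directly from the smoothed signal minimum
(equivalently the concentration maximum, since S -> C is monotone decreasing);
no curve model is fitted — the distribution-based parameters deliberately stay
on the measured time grid, with temporal precision controlled by TR alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import DscSeries, VolumeMask, SENTINEL


@dataclass
class FirstPassWindow:
    """Half-open frame interval [start_frame, end_frame) containing the first
    pass of the contrast bolus."""

    start_frame: int
    end_frame: int
    baseline_frames: int

    def __post_init__(self):
        if not (0 <= self.start_frame < self.end_frame):
            raise ValueError(
                f"invalid window [{self.start_frame}, {self.end_frame})"
            )
        if self.baseline_frames > self.start_frame:
            raise ValueError("baseline frames must precede the window start")

    @property
    def n_frames(self):
        return self.end_frame - self.start_frame


@dataclass
class TtpMap:
    """Per-voxel absolute time-to-peak on the TR grid.

    ``frames`` (integer argmin frame; -1 where undefined) is the primary
    representation; ``values`` = tr * frames in seconds with NaN where
    undefined. Keeping the integer frames makes downstream per-VOI
    standardization exactly shift-equivariant.
    """

    frames: np.ndarray
    tr: float
    defined_mask: np.ndarray
    boundary_mask: np.ndarray = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        self.defined_mask = np.asarray(self.defined_mask, dtype=bool)
        if self.boundary_mask is None:
            self.boundary_mask = np.zeros_like(self.defined_mask)

    @property
    def values(self):
        out = np.where(self.defined_mask, self.frames * self.tr, SENTINEL)
        return out

    @property
    def shape(self):
        return self.frames.shape


def smooth_curves(series: DscSeries, window: int = 3) -> DscSeries:
    """Centered moving-average ("plain mean") smoothing of every time course.

    Edges use the truncated window (the mean over the in-range part), so a
    window of 1 is the identity and constant curves are unchanged.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"smoothing window must be a positive odd integer; got {window}")
    if window == 1:
        return series.with_signal(series.signal.copy())
    x = np.asarray(series.signal, dtype=float)
    n = x.shape[-1]
    half = window // 2
    csum = np.concatenate(
        [np.zeros(x.shape[:-1] + (1,)), np.cumsum(x, axis=-1)], axis=-1
    )
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + half + 1, 0, n)
    out = (csum[..., hi] - csum[..., lo]) / (hi - lo)
    return series.with_signal(out)


def signal_to_concentration(
    series: DscSeries, baseline_frames: int, floor_frac: float = 1e-3
) -> DscSeries:
    """Convert T2*-weighted signal to contrast concentration.

    C(t) = -ln(S(t)/S0) / TE with S0 the mean over the pre-bolus baseline
    frames. Voxels with nonpositive S0 are undefined (NaN time course);
    nonpositive signal samples are clipped to ``floor_frac * S0`` before the
    logarithm.
    """
    if baseline_frames < 3:
        raise ValueError("baseline_frames must be >= 3")
    s = np.asarray(series.signal, dtype=float)
    s0 = s[..., :baseline_frames].mean(axis=-1)
    valid = s0 > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        floor = floor_frac * s0[..., None]
        clipped = np.maximum(s, floor)
        conc = -np.log(clipped / s0[..., None]) / series.te
    conc[~valid] = np.nan
    return series.with_signal(conc)


def detect_first_pass_window(
    series: DscSeries,
    brain: VolumeMask,
    k_sd: float = 2.0,
    baseline_frames: int = 8,
    smooth_window: int = 3,
) -> FirstPassWindow:
    """Find the global first-pass window from the brain-mean signal curve.

    The window starts at the first frame where the brain-mean signal drops
    more than ``k_sd`` baseline standard deviations below the baseline mean,
    and ends after the contiguous sub-threshold run, extended by one smoothing
    window. Raises if no frame crosses the threshold ("no bolus detected").
    """
    if brain.values.shape != series.spatial_shape:
        raise ValueError("brain mask does not match series grid")
    g = series.signal[brain.values].mean(axis=0)
    base = g[:baseline_frames]
    thr = base.mean() - k_sd * base.std()
    below = g < thr
    below[:baseline_frames] = False
    if not below.any():
        raise ValueError("no bolus detected: brain-mean signal never crosses the threshold")
    start = int(np.argmax(below))
    run_end = start
    while run_end < len(g) and below[run_end]:
        run_end += 1
    end = min(len(g), run_end + smooth_window)
    start = min(start, int(np.argmin(g)))  # start always precedes the global minimum
    return FirstPassWindow(start_frame=start, end_frame=end, baseline_frames=min(baseline_frames, start))


def compute_ttp_map(series: DscSeries, window: FirstPassWindow, brain: VolumeMask) -> TtpMap:
    """Per-voxel absolute TTP: tr * argmin of the smoothed signal within the
    first-pass window (ties broken toward the earliest frame).

    Voxels whose minimum falls on a window boundary are defined but flagged in
    ``boundary_mask``; voxels outside the brain mask are undefined.
    """
    if brain.values.shape != series.spatial_shape:
        raise ValueError("brain mask does not match series grid")
    if window.end_frame > series.n_frames:
        raise ValueError("first-pass window extends past the series")
    seg = series.signal[..., window.start_frame : window.end_frame]
    if seg.shape[-1] == 0:
        raise ValueError("empty first-pass window")
    finite = np.all(np.isfinite(seg), axis=-1)
    defined = brain.values & finite
    rel = np.argmin(np.where(np.isfinite(seg), seg, np.inf), axis=-1)
    frames = np.where(defined, rel + window.start_frame, -1)
    boundary = defined & (
        (frames == window.start_frame) | (frames == window.end_frame - 1)
    )
    return TtpMap(frames=frames, tr=series.tr, defined_mask=defined, boundary_mask=boundary)
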