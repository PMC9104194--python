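"""Frames -> vertical profiles -> two-feature levitation fingerprint.

The processing chain mirrors the acquisition protocol: for each frame
the vertical intensity profile is the row-wise mean over an ROI
covering the inner cuvette; profiles are background-subtracted and
normalized to the maximum intensity inside a reference window so that
exposure variations cancel.  Two scalar features summarize a run:

* starting position — intensity-weighted centroid of the first
  processed profile (peak position available as an alternative);
* levitating fraction area — integral of the normalized final-time
  profile above a sediment-exclusion cut.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .frames import FrameSeries, Roi, load_frames  # noqa: F401  (re-export)

__all__ = [
    "IntensityProfile",
    "MagLevFingerprint",
    "PipelineParams",
    "DegenerateProfileError",
    "vertical_profile",
    "subtract_background",
    "normalize_profile",
    "blank_profile",
    "series_normalization",
    "starting_position",
    "levitating_fraction_area",
    "extract_fingerprint",
    "average_replicates",
]


class DegenerateProfileError(ValueError):
    """Profile has no signal where signal is required."""


@dataclass
class IntensityProfile:
    """Vertical intensity profile at one time point.

    ``heights`` are mm from the ROI bottom, strictly increasing.
    """

    heights: np.ndarray
    intensities: np.ndarray
    time: float = 0.0
    normalized: bool = False

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.heights.shape != self.intensities.shape:
            raise ValueError("heights and intensities length mismatch")
        if len(self.heights) > 1 and not np.all(np.diff(self.heights) > 0):
            raise ValueError("heights must be strictly increasing")


@dataclass(frozen=True)
class MagLevFingerprint:
    """The 2-D feature describing one levitation run."""

    starting_position_mm: float
    levitating_area: float
    donor_id: str = ""
    replicate_id: str = ""
    n_replicates: int = 1
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.levitating_area < 0:
            raise ValueError("levitating_area must be >= 0")


@dataclass(frozen=True)
class PipelineParams:
    """Tunable parameters of the fingerprint extraction chain.

    ``reference_window`` is a (low, high) fraction of the ROI height
    used for exposure normalization; ``sediment_exclusion_frac`` cuts
    the bottom of the ROI out of the area integral.  ``start_mode``
    selects centroid or peak for the starting position.
    """

    reference_window: tuple[float, float] = (0.2, 0.8)
    sediment_exclusion_frac: float = 0.10
    final_time: float = 1200.0
    start_mode: str = "centroid"

    def __post_init__(self) -> None:
        lo, hi = self.reference_window
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("reference_window must satisfy 0 <= lo < hi <= 1")
        if not (0.0 <= self.sediment_exclusion_frac < 1.0):
            raise ValueError("sediment_exclusion_frac must be in [0, 1)")
        if self.start_mode not in ("centroid", "peak"):
            raise ValueError("start_mode must be 'centroid' or 'peak'")


def vertical_profile(
    frame: np.ndarray,
    roi: Roi,
    pixel_to_mm: float,
    time: float = 0.0,
) -> IntensityProfile:
    """Row-wise mean intensity over the ROI columns, heights bottom-up.

    The bottom ROI row maps to height 0 regardless of the image's
    row-order convention (row 0 at top).
    """
    frame = np.asarray(frame, dtype=float)
    sub = frame[roi.row_start : roi.row_stop, roi.col_start : roi.col_stop]
    if sub.size == 0:
        raise ValueError("empty ROI")
    means = sub.mean(axis=1)
    # image row order is top-down; flip so heights increase
    intensities = means[::-1].copy()
    heights = np.arange(roi.n_rows) * pixel_to_mm
    return IntensityProfile(heights=heights, intensities=intensities, time=time)


def subtract_background(
    profile: IntensityProfile, blank: IntensityProfile
) -> IntensityProfile:
    """Pointwise difference against a blank profile, floored at zero."""
    if not np.array_equal(profile.heights, blank.heights):
        raise ValueError("height grids do not match")
    diff = np.maximum(profile.intensities - blank.intensities, 0.0)
    return IntensityProfile(
        heights=profile.heights.copy(),
        intensities=diff,
        time=profile.time,
        normalized=False,
    )


def normalize_profile(
    profile: IntensityProfile,
    reference_window: tuple[float, float] | None = None,
) -> IntensityProfile:
    """Divide by the maximum intensity inside the reference window.

    ``reference_window`` is in mm (heights); default is the central 60%
    of the profile's height span.
    """
    h = profile.heights
    if reference_window is None:
        span = h[-1] - h[0]
        reference_window = (h[0] + 0.2 * span, h[0] + 0.8 * span)
    lo, hi = reference_window
    mask = (h >= lo) & (h <= hi)
    if not mask.any():
        raise ValueError("reference window does not overlap profile support")
    peak = profile.intensities[mask].max()
    if peak <= 0:
        raise DegenerateProfileError("zero maximum inside the reference window")
    return IntensityProfile(
        heights=h.copy(),
        intensities=profile.intensities / peak,
        time=profile.time,
        normalized=True,
    )


def blank_profile(series: FrameSeries) -> IntensityProfile:
    """Background estimate: per-row minimum across all frames.

    Used when no pre-injection blank frame is available; static
    background (cuvette walls, illumination) survives the minimum while
    the moving sample band does not.
    """
    profiles = np.stack(
        [
            vertical_profile(f, series.roi, series.pixel_to_mm).intensities
            for f in series.frames
        ]
    )
    heights = np.arange(series.roi.n_rows) * series.pixel_to_mm
    return IntensityProfile(heights=heights, intensities=profiles.min(axis=0))


def _subtracted_profile(
    series: FrameSeries,
    frame_index: int,
    blank: IntensityProfile,
) -> IntensityProfile:
    raw = vertical_profile(
        series.frames[frame_index],
        series.roi,
        series.pixel_to_mm,
        time=float(series.times[frame_index]),
    )
    return subtract_background(raw, blank)


def _window_mm(profile: IntensityProfile, params: PipelineParams):
    span = profile.heights[-1] - profile.heights[0]
    lo, hi = params.reference_window
    return (profile.heights[0] + lo * span, profile.heights[0] + hi * span)


def series_normalization(
    series: FrameSeries,
    params: PipelineParams,
    blank: IntensityProfile,
) -> float:
    """Exposure-normalization constant for a whole series.

    One constant per run — the maximum background-subtracted intensity
    of the first frame inside the reference window — so that late-time
    profiles scale with the amount of levitating material rather than
    being re-normalized to their own (possibly noise-dominated) peak.
    """
    first = _subtracted_profile(series, 0, blank)
    lo, hi = _window_mm(first, params)
    mask = (first.heights >= lo) & (first.heights <= hi)
    peak = first.intensities[mask].max() if mask.any() else 0.0
    if peak <= 0:
        raise DegenerateProfileError("no signal in the reference window")
    return float(peak)


def _processed_profile(
    series: FrameSeries,
    frame_index: int,
    params: PipelineParams,
    blank: IntensityProfile | None,
    norm: float | None = None,
) -> IntensityProfile:
    if blank is None:
        blank = blank_profile(series)
    if norm is None:
        norm = series_normalization(series, params, blank)
    sub = _subtracted_profile(series, frame_index, blank)
    return IntensityProfile(
        heights=sub.heights,
        intensities=sub.intensities / norm,
        time=sub.time,
        normalized=True,
    )


def starting_position(
    series: FrameSeries,
    params: PipelineParams = PipelineParams(),
    blank: IntensityProfile | None = None,
) -> float:
    """Summary position (mm from ROI bottom) of the first processed frame."""
    prof = _processed_profile(series, 0, params, blank)
    total = prof.intensities.sum()
    if total <= 0:
        raise DegenerateProfileError("first frame has no signal")
    if params.start_mode == "peak":
        return float(prof.heights[np.argmax(prof.intensities)])
    return float(np.dot(prof.heights, prof.intensities) / total)


def levitating_fraction_area(
    series: FrameSeries,
    params: PipelineParams = PipelineParams(),
    blank: IntensityProfile | None = None,
    norm: float | None = None,
) -> float:
    """Integral of the normalized final-time profile above the sediment cut.

    Trapezoidal integration over heights above
    ``sediment_exclusion_frac`` of the ROI height; units are
    normalized-intensity x mm.  ``norm`` overrides the per-series
    exposure-normalization constant (for comparing runs at a fixed
    normalization).
    """
    idx, gap = series.frame_at(params.final_time)
    if len(series.times) > 1:
        interval = float(np.median(np.diff(series.times)))
        if gap > interval:
            warnings.warn(
                f"no frame at final_time={params.final_time}s; using nearest "
                f"frame at t={series.times[idx]}s",
                stacklevel=2,
            )
    prof = _processed_profile(series, idx, params, blank, norm)
    span = prof.heights[-1] - prof.heights[0]
    cut = prof.heights[0] + params.sediment_exclusion_frac * span
    mask = prof.heights >= cut
    if mask.sum() < 2:
        raise ValueError("sediment exclusion removed the whole profile")
    return float(np.trapezoid(prof.intensities[mask], prof.heights[mask]))


def extract_fingerprint(
    series: FrameSeries,
    params: PipelineParams = PipelineParams(),
    donor_id: str = "",
    replicate_id: str = "",
) -> MagLevFingerprint:
    """Full chain: profile -> background -> normalize -> two features."""
    blank = blank_profile(series)
    pos = starting_position(series, params, blank)
    area = levitating_fraction_area(series, params, blank)
    prov = {
        "reference_window": params.reference_window,
        "sediment_exclusion_frac": params.sediment_exclusion_frac,
        "final_time": params.final_time,
        "start_mode": params.start_mode,
        "pixel_to_mm": series.pixel_to_mm,
        "n_frames": len(series),
    }
    return MagLevFingerprint(
        starting_position_mm=pos,
        levitating_area=area,
        donor_id=donor_id,
        replicate_id=replicate_id,
        provenance=prov,
    )


def average_replicates(fingerprints: list[MagLevFingerprint]) -> MagLevFingerprint:
    """Component-wise mean over replicates of one donor."""
    if not fingerprints:
        raise ValueError("need at least one fingerprint")
    donors = {fp.donor_id for fp in fingerprints}
    if len(donors) != 1:
        raise ValueError(f"mixed donors: {sorted(donors)}")
    pos = float(np.mean([fp.starting_position_mm for fp in fingerprints]))
    area = float(np.mean([fp.levitating_area for fp in fingerprints]))
    return MagLevFingerprint(
        starting_position_mm=pos,
        levitating_area=area,
        donor_id=fingerprints[0].donor_id,
        replicate_id="mean",
        n_replicates=len(fingerprints),
    )
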