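"""Noise-robust segmentation: z-score outlier-lobe rejection and smart cropping.

Real-world phonocardiograms carry bursts of high-energy noise (a child crying,
stethoscope motion) anywhere in the recording. Such a burst shows up in the
Shannon-energy envelope as a lobe with far more area than the heart-sound
lobes. With M detected lobes of areas A_i, the mean area and population
standard deviation are

    mean = (1/M) sum A_i,    sigma = sqrt((1/M) sum (A_i - mean)^2),

and a lobe is flagged as an outlier when its z-score

    z_i = (A_i - mean) / sigma

exceeds the cutoff (default 2.75). Flagged lobes are cropped out (with a small
guard margin) and each remaining clean interval is segmented independently by
the base algorithm; the labeled intervals are then merged in time order with
the cropped gaps carrying the noise state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .envelope import Lobe, compute_ase, compute_nase, detect_lobes
from .io import PCGRecording
from .preprocess import normalize, preprocess
from .segment import (
    DEFAULT_PARAMS,
    Label,
    LabeledInterval,
    Segmentation,
    SegmentationParams,
    segment_preprocessed,
)


@dataclass(frozen=True)
class OutlierStats:
    """Per-lobe area statistics and the flagged outlier indices."""

    areas: np.ndarray
    mean_area: float
    std_area: float
    zscores: np.ndarray
    cutoff: float
    outlier_idx: tuple[int, ...]

    @property
    def M(self) -> int:
        return int(self.areas.size)


@dataclass(frozen=True)
class CleanInterval:
    """A noise-free stretch of the recording, [start_s, end_s)."""

    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("clean interval must have start_s < end_s")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def outlier_stats(areas, cutoff: float = 2.75) -> OutlierStats:
    """Flag lobes whose area z-score exceeds ``cutoff``.

    Uses the population (1/M) standard deviation. When all areas are equal
    (sigma = 0) nothing is flagged.
    """
    areas = np.asarray(areas, dtype=np.float64)
    if areas.size == 0:
        raise ValueError("need at least one lobe")
    mean = float(areas.mean())
    std = float(np.sqrt(np.mean(np.square(areas - mean))))
    if std > 0:
        z = (areas - mean) / std
        flagged = tuple(int(i) for i in np.flatnonzero(z > cutoff))
    else:
        z = np.zeros_like(areas)
        flagged = ()
    return OutlierStats(
        areas=areas, mean_area=mean, std_area=std, zscores=z, cutoff=cutoff, outlier_idx=flagged
    )


def crop_noise(
    rec: PCGRecording,
    lobes: list[Lobe],
    stats: OutlierStats,
    params: SegmentationParams = DEFAULT_PARAMS,
) -> list[CleanInterval]:
    """Remove every outlier lobe (plus a guard margin) from the recording span.

    Returns the maximal disjoint clean intervals, dropping any shorter than
    ``params.min_clean_duration_s`` (too short to hold a full cardiac cycle).
    """
    total = rec.duration_s
    margin = params.crop_margin_s
    cut: list[tuple[float, float]] = []
    for i in stats.outlier_idx:
        cut.append((max(0.0, lobes[i].start_s - margin), min(total, lobes[i].end_s + margin)))
    cut.sort()
    clean: list[CleanInterval] = []
    cursor = 0.0
    for lo, hi in cut:
        if lo > cursor:
            clean.append(CleanInterval(cursor, lo))
        cursor = max(cursor, hi)
    if cursor < total:
        clean.append(CleanInterval(cursor, total))
    return [iv for iv in clean if iv.duration_s >= params.min_clean_duration_s]


def segment_noise_robust(
    rec: PCGRecording, params: SegmentationParams = DEFAULT_PARAMS
) -> Segmentation:
    """Noise-robust pipeline: detect outlier lobes, crop, segment clean parts.

    The envelope is recomputed per clean interval (after renormalizing the
    slice, so a burst's amplitude does not compress the heart sounds). Labeled
    intervals from all clean parts are merged in time order; cropped gaps are
    labeled as noise. Cycle tracking restarts per interval — alternation is
    not forced across a noise gap. A single outlier-detection pass is used by
    default (``params.iterative_outlier_pass`` enables re-flagging per pass).
    """
    try:
        prep = preprocess(rec)
        ase = compute_ase(prep)
    except ValueError:
        return Segmentation()
    nase = compute_nase(ase)
    lobes = detect_lobes(nase, prep)
    if not lobes:
        return Segmentation()
    stats = outlier_stats([lb.area for lb in lobes], cutoff=params.area_cutoff)
    if params.iterative_outlier_pass:
        stats = _iterate_outliers(stats)
    clean = crop_noise(prep, lobes, stats, params)
    if not stats.outlier_idx:
        # no-op cropping: identical to the base algorithm on the same signal
        return segment_preprocessed(prep, params)

    merged: list[LabeledInterval] = []
    any_success = False
    cycle_vals: list[float] = []
    sys_vals: list[float] = []
    prev_end = 0.0
    for iv in clean:
        i0 = int(round(iv.start_s * prep.rate))
        i1 = int(round(iv.end_s * prep.rate))
        chunk = prep.samples[i0:i1]
        if not np.any(chunk):
            continue
        sub = normalize(PCGRecording(chunk, prep.rate, prep.source_id))
        seg = segment_preprocessed(sub, params)
        if iv.start_s > prev_end:
            merged.append(LabeledInterval(prev_end, iv.start_s, Label.NOISE))
        for labeled in seg.intervals:
            merged.append(
                LabeledInterval(labeled.start_s + iv.start_s, labeled.end_s + iv.start_s, labeled.label)
            )
        if seg.success:
            any_success = True
            if np.isfinite(seg.cycle_length_s):
                cycle_vals.append(seg.cycle_length_s)
            if np.isfinite(seg.systole_s):
                sys_vals.append(seg.systole_s)
        prev_end = iv.end_s
    if prev_end < prep.duration_s and merged:
        merged.append(LabeledInterval(prev_end, prep.duration_s, Label.NOISE))
    if not any_success:
        return Segmentation()
    return Segmentation(
        intervals=tuple(merged),
        success=True,
        cycle_length_s=float(np.mean(cycle_vals)) if cycle_vals else float("nan"),
        systole_s=float(np.mean(sys_vals)) if sys_vals else float("nan"),
    )


def _iterate_outliers(stats: OutlierStats) -> OutlierStats:
    """Re-estimate statistics after each removal until no new lobe is flagged."""
    flagged: set[int] = set(stats.outlier_idx)
    areas = stats.areas
    while True:
        remaining = [i for i in range(areas.size) if i not in flagged]
        if len(remaining) < 2:
            break
        sub = outlier_stats(areas[remaining], cutoff=stats.cutoff)
        new = {remaining[i] for i in sub.outlier_idx}
        if not new - flagged:
            break
        flagged |= new
    z = stats.zscores
    return OutlierStats(areas, stats.mean_area, stats.std_area, z, stats.cutoff, tuple(sorted(flagged)))
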