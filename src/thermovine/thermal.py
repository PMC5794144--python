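"""Per-frame feature extraction: ROI cropping, wet/dry-range segmentation,
summary statistics and the CWSI / Ig thermal indices.

Two feature pipelines are supported:

* ``with_refs``    — pixels outside [t_wet, t_dry] are masked out before the
  statistics are taken, and the CWSI and Ig indices are computed from the
  segmented canopy mean;
* ``without_refs`` — statistics are taken on the raw (unsegmented) region of
  interest and no reference temperatures enter at any stage.

Per-vine features are the mean of per-frame statistics over the vine's
contiguous block of retained frames.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import numpy.ma as ma
import pandas as pd

__all__ = [
    "FrameMeta",
    "ThermalFrame",
    "RegionOfInterest",
    "ReferenceTemperatures",
    "FrameStatistics",
    "crop_roi",
    "segment_by_references",
    "frame_statistics",
    "cwsi",
    "ig",
    "partition_contiguous",
    "build_sample_table",
    "FEATURES_WITH_REFS",
    "FEATURES_WITHOUT_REFS",
]

logger = logging.getLogger(__name__)

FEATURES_WITHOUT_REFS = ["air_temp", "t_canopy_mean", "t_canopy_median", "t_canopy_sd"]
FEATURES_WITH_REFS = FEATURES_WITHOUT_REFS + ["cwsi", "ig"]

KEY_COLUMNS = ["date_index", "treatment", "block", "side", "vine"]


def feature_columns_available(df) -> list[str]:
    """The feature-set columns actually present in a features table."""
    if all(c in df.columns for c in FEATURES_WITH_REFS):
        return list(FEATURES_WITH_REFS)
    if all(c in df.columns for c in FEATURES_WITHOUT_REFS):
        return list(FEATURES_WITHOUT_REFS)
    raise ValueError("table lacks the expected feature columns")


@dataclass(frozen=True)
class FrameMeta:
    """Acquisition metadata attached to one thermal frame."""

    date_index: int
    treatment: str
    block: int
    side: str
    frame_index: int


@dataclass
class ThermalFrame:
    """A 2-D temperature matrix in degrees Celsius plus acquisition metadata."""

    pixels: np.ndarray
    meta: FrameMeta

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D matrix")
        if not np.isfinite(self.pixels).all():
            raise ValueError("frame contains non-finite temperatures")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class RegionOfInterest:
    """Half-open row band [row_start, row_end); full frame width by default."""

    row_start: int
    row_end: int
    col_start: int = 0
    col_end: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.row_start < self.row_end:
            raise ValueError("need 0 <= row_start < row_end")

    @classmethod
    def centered(cls, frame_height: int, roi_height: int = 135) -> "RegionOfInterest":
        """The vertically centred band of ``roi_height`` rows."""
        if roi_height > frame_height:
            raise ValueError("roi_height exceeds frame height")
        start = (frame_height - roi_height) // 2
        return cls(row_start=start, row_end=start + roi_height)


@dataclass(frozen=True)
class ReferenceTemperatures:
    """Per-day wet and dry artificial-leaf reference temperatures (deg C)."""

    t_wet: float
    t_dry: float
    date_index: int = 0

    def __post_init__(self) -> None:
        if not self.t_dry > self.t_wet:
            raise ValueError("t_dry must exceed t_wet")


@dataclass
class FrameStatistics:
    t_canopy_mean: float
    t_canopy_median: float
    t_canopy_sd: float
    n_pixels_used: int
    cwsi: float | None = None
    ig: float | None = None


def crop_roi(frame: ThermalFrame | np.ndarray, roi: RegionOfInterest) -> np.ndarray:
    """Extract the ROI sub-matrix without modifying values."""
    pixels = frame.pixels if isinstance(frame, ThermalFrame) else np.asanyarray(frame)
    n_rows, n_cols = pixels.shape
    col_end = n_cols if roi.col_end is None else roi.col_end
    if roi.row_end > n_rows or col_end > n_cols or roi.col_start < 0:
        raise ValueError(
            f"ROI rows [{roi.row_start},{roi.row_end}) cols [{roi.col_start},{col_end}) "
            f"outside frame {pixels.shape}"
        )
    return pixels[roi.row_start : roi.row_end, roi.col_start : col_end]


def segment_by_references(
    pixels: np.ndarray, refs: ReferenceTemperatures
) -> ma.MaskedArray:
    """Mask every pixel outside the closed interval [t_wet, t_dry].

    Returns a masked array; a fully-masked result flags a sample that must be
    excluded downstream (the caller logs and drops it).
    """
    pixels = ma.asarray(pixels)
    out = ma.masked_outside(pixels, refs.t_wet, refs.t_dry)
    if out.count() == 0:
        logger.warning(
            "segmentation left no pixels inside [%.2f, %.2f]", refs.t_wet, refs.t_dry
        )
    return out


def frame_statistics(pixels: np.ndarray | ma.MaskedArray) -> FrameStatistics:
    """Mean, median and sample (n-1) standard deviation over unmasked pixels."""
    arr = ma.asarray(pixels)
    n = int(arr.count())
    if n == 0:
        raise ValueError("no unmasked pixels")
    values = arr.compressed().astype(float)
    sd = float(values.std(ddof=1)) if n > 1 else 0.0
    return FrameStatistics(
        t_canopy_mean=float(values.mean()),
        t_canopy_median=float(np.median(values)),
        t_canopy_sd=sd,
        n_pixels_used=n,
    )


def cwsi(t_canopy: float, refs: ReferenceTemperatures) -> float:
    """Crop water stress index (T_canopy - T_wet) / (T_dry - T_wet)."""
    span = refs.t_dry - refs.t_wet
    if span == 0:
        raise ZeroDivisionError("CWSI undefined for t_dry == t_wet")
    return (t_canopy - refs.t_wet) / span


def ig(t_canopy: float, refs: ReferenceTemperatures) -> float:
    """Conductance index (T_dry - T_canopy) / (T_canopy - T_wet).

    Equals 1/CWSI - 1 wherever both are defined; undefined at
    t_canopy == t_wet (no transpiration limitation signal).
    """
    denom = t_canopy - refs.t_wet
    if denom == 0:
        raise ZeroDivisionError("Ig undefined for t_canopy == t_wet")
    return (refs.t_dry - t_canopy) / denom


def partition_contiguous(n: int, k: int) -> list[int]:
    """Sizes of k contiguous, near-equal groups of n items (larger groups first)."""
    if k <= 0 or n < 0:
        raise ValueError("need k > 0 and n >= 0")
    base, extra = divmod(n, k)
    return [base + (1 if i < extra else 0) for i in range(k)]


def _group_boundaries(sizes: Sequence[int]) -> list[tuple[int, int]]:
    bounds, start = [], 0
    for s in sizes:
        bounds.append((start, start + s))
        start += s
    return bounds


def build_sample_table(
    frames: Iterable[ThermalFrame],
    refs_by_date: Mapping[int, ReferenceTemperatures],
    weather_by_date: Mapping[int, "object"],
    truths: Sequence["object"],
    feature_set: str = "with_refs",
    roi: RegionOfInterest | None = None,
    n_vines: int = 3,
) -> pd.DataFrame:
    """One feature row per monitored vine.

    Frames are grouped per (date, treatment, block, side), ordered by frame
    index and partitioned into ``n_vines`` contiguous blocks; each measured
    vine's features are the mean of its block's per-frame statistics. Ground
    truth rows supply the target ``psi_stem``; vines whose frames all fail
    segmentation are dropped with a warning.
    """
    if feature_set not in ("with_refs", "without_refs"):
        raise ValueError("feature_set must be 'with_refs' or 'without_refs'")

    by_rep: dict[tuple, list[ThermalFrame]] = {}
    for fr in frames:
        key = (fr.meta.date_index, fr.meta.treatment, fr.meta.block, fr.meta.side)
        by_rep.setdefault(key, []).append(fr)

    truth_lookup = {
        (t.date_index, t.treatment, t.block, t.side, t.vine): t for t in truths
    }

    records: list[dict] = []
    for key in sorted(by_rep):
        date_index, treatment, block, side = key
        rep_frames = sorted(by_rep[key], key=lambda f: f.meta.frame_index)
        the_roi = roi or RegionOfInterest.centered(rep_frames[0].shape[0])
        weather = weather_by_date[date_index]
        refs = refs_by_date.get(date_index)
        if feature_set == "with_refs" and refs is None:
            raise ValueError(f"no reference temperatures for date {date_index}")

        per_frame: list[FrameStatistics | None] = []
        for fr in rep_frames:
            pix = crop_roi(fr, the_roi)
            if feature_set == "with_refs":
                seg = segment_by_references(pix, refs)
                if seg.count() == 0:
                    logger.warning("frame %s fully masked; dropped", fr.meta)
                    per_frame.append(None)
                    continue
                stats = frame_statistics(seg)
                stats.cwsi = cwsi(stats.t_canopy_mean, refs)
                try:
                    stats.ig = ig(stats.t_canopy_mean, refs)
                except ZeroDivisionError:
                    logger.warning("Ig undefined for frame %s", fr.meta)
                    stats.ig = np.nan
            else:
                stats = frame_statistics(pix)
            per_frame.append(stats)

        sizes = partition_contiguous(len(rep_frames), n_vines)
        for vine, (lo, hi) in enumerate(_group_boundaries(sizes)):
            block_stats = [s for s in per_frame[lo:hi] if s is not None]
            truth = truth_lookup.get((date_index, treatment, block, side, vine))
            if truth is None:
                raise KeyError(
                    f"no ground truth for {(date_index, treatment, block, side, vine)}"
                )
            if not block_stats:
                logger.warning(
                    "vine %s of %s has no surviving frames; record dropped", vine, key
                )
                continue
            rec = {
                "date_index": date_index,
                "treatment": treatment,
                "block": block,
                "side": side,
                "vine": vine,
                "air_temp": float(weather.air_temp),
                "t_canopy_mean": float(np.mean([s.t_canopy_mean for s in block_stats])),
                "t_canopy_median": float(
                    np.mean([s.t_canopy_median for s in block_stats])
                ),
                "t_canopy_sd": float(np.mean([s.t_canopy_sd for s in block_stats])),
            }
            if feature_set == "with_refs":
                rec["cwsi"] = float(np.mean([s.cwsi for s in block_stats]))
                igs = [s.ig for s in block_stats if np.isfinite(s.ig)]
                if not igs:
                    logger.warning("vine %s of %s has no defined Ig; dropped", vine, key)
                    continue
                rec["ig"] = float(np.mean(igs))
            rec["psi_stem"] = float(truth.psi_stem)
            records.append(rec)

    columns = KEY_COLUMNS + (
        FEATURES_WITH_REFS if feature_set == "with_refs" else FEATURES_WITHOUT_REFS
    ) + ["psi_stem"]
    table = pd.DataFrame.from_records(records, columns=columns)
    return table.sort_values(KEY_COLUMNS, ignore_index=True)
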