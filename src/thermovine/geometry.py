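"""Acquisition-geometry arithmetic for a sideways-looking moving thermal camera.

Pure functions deriving, from camera and traverse parameters: per-frame ground
coverage, frames recorded per row replication, the subsampling stride that
yields laterally non-overlapping scenes, and the centred block of frames that
covers only the monitored middle plants of a replication.

Rounding contract: frame counts use round-half-away-from-zero; the size of the
retained middle block uses floor. With the default parameters this reproduces
the reference arithmetic 1080 frames -> stride 46 -> 23 scenes -> 14 retained.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

__all__ = [
    "CameraModel",
    "TraverseSpec",
    "scene_coverage",
    "frames_per_replication",
    "nonoverlap_stride",
    "select_frames",
    "derivation_table",
]

logger = logging.getLogger(__name__)


def round_half_away(x: float) -> int:
    """Round half away from zero (5 km/h-style field arithmetic, not banker's)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class CameraModel:
    """Thermal camera intrinsics and mounting geometry."""

    fps: float = 60.0
    fov_h_deg: float = 48.0
    fov_v_deg: float = 39.0
    distance_m: float = 1.2
    height_m: float = 1.0
    resolution: tuple[int, int] = (320, 256)  # (width px, height px)

    def __post_init__(self) -> None:
        if not (0 <= self.fov_h_deg < 180 and 0 <= self.fov_v_deg < 180):
            raise ValueError("fields of view must lie in [0, 180) degrees")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.distance_m <= 0:
            raise ValueError("distance_m must be positive")
        w, h = self.resolution
        if w <= 0 or h <= 0:
            raise ValueError("resolution must be positive")


@dataclass(frozen=True)
class TraverseSpec:
    """One pass along a row replication at constant speed."""

    speed_kmh: float = 5.0
    replication_length_m: float = 25.0
    monitored_length_m: float = 15.0

    def __post_init__(self) -> None:
        if self.speed_kmh <= 0:
            raise ValueError("speed_kmh must be positive")
        if self.replication_length_m <= 0:
            raise ValueError("replication_length_m must be positive")
        if not 0 < self.monitored_length_m <= self.replication_length_m:
            raise ValueError("monitored_length_m must be in (0, replication_length_m]")

    @property
    def speed_ms(self) -> float:
        return self.speed_kmh / 3.6


def scene_coverage(camera: CameraModel) -> tuple[float, float]:
    """Ground extent (width_m, height_m) of one frame under the pinhole model.

    width = 2 d tan(fov_h / 2), height = 2 d tan(fov_v / 2).
    """
    width = 2.0 * camera.distance_m * math.tan(math.radians(camera.fov_h_deg) / 2.0)
    height = 2.0 * camera.distance_m * math.tan(math.radians(camera.fov_v_deg) / 2.0)
    return width, height


def frames_per_replication(camera: CameraModel, traverse: TraverseSpec) -> int:
    """Frames recorded while driving one replication: round(L / v * fps)."""
    return round_half_away(traverse.replication_length_m / traverse.speed_ms * camera.fps)


def nonoverlap_stride(camera: CameraModel, traverse: TraverseSpec) -> int:
    """Keep every ``stride``-th frame so retained scenes do not overlap laterally.

    stride = round(total_frames / (L / frame_width)). If a single frame already
    covers the replication the stride equals the total frame count.
    """
    width, _ = scene_coverage(camera)
    if width <= 0:
        raise ValueError("scene width must be positive")
    total = frames_per_replication(camera, traverse)
    if width >= traverse.replication_length_m:
        return total
    n_scenes = traverse.replication_length_m / width
    return round_half_away(total / n_scenes)


def n_subsampled(camera: CameraModel, traverse: TraverseSpec) -> int:
    """Number of disjoint scenes covering the replication: round(L / frame_width)."""
    width, _ = scene_coverage(camera)
    if width >= traverse.replication_length_m:
        return 1
    return round_half_away(traverse.replication_length_m / width)


def n_retained(camera: CameraModel, traverse: TraverseSpec) -> int:
    """Frames kept over the monitored middle stretch: floor(monitored / frame_width)."""
    width, _ = scene_coverage(camera)
    return max(1, int(math.floor(traverse.monitored_length_m / width)))


def select_frames(
    total_frames: int, camera: CameraModel, traverse: TraverseSpec
) -> list[int]:
    """Indices (0-based) of the retained frames of one replication recording.

    Subsamples every ``nonoverlap_stride``-th frame to get ``n_subsampled``
    laterally disjoint scenes, then keeps the centred block of ``n_retained``
    of them. When the number of frames to drop is odd the extra frame is
    dropped at the end of travel.
    """
    if total_frames <= 0:
        raise ValueError("total_frames must be positive")
    stride = nonoverlap_stride(camera, traverse)
    n_sub = n_subsampled(camera, traverse)
    subsampled = [i * stride for i in range(n_sub) if i * stride < total_frames]
    n_keep = n_retained(camera, traverse)
    if n_keep >= len(subsampled):
        if n_keep > len(subsampled):
            logger.warning(
                "monitored block (%d frames) exceeds subsample (%d); keeping all",
                n_keep,
                len(subsampled),
            )
        return subsampled
    start = (len(subsampled) - n_keep) // 2
    return subsampled[start : start + n_keep]


def derivation_table(camera: CameraModel, traverse: TraverseSpec) -> dict[str, float]:
    """All derived acquisition quantities, for audit output."""
    width, height = scene_coverage(camera)
    total = frames_per_replication(camera, traverse)
    return {
        "scene_width_m": width,
        "scene_height_m": height,
        "frames_per_replication": total,
        "nonoverlap_stride": nonoverlap_stride(camera, traverse),
        "n_subsampled": n_subsampled(camera, traverse),
        "n_retained": n_retained(camera, traverse),
    }
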