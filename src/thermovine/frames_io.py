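"""Reading and writing thermal frames (float32 TIFF or CSV matrices) plus the
campaign-level weather.csv / truth.csv tables.

Filename pattern encodes the acquisition metadata:
``d{date:02d}_t{treatment}_b{block:02d}_{side}_f{frame:04d}.{tif|csv}``.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

from thermovine.synth import DayWeather, GroundTruth
from thermovine.thermal import FrameMeta, ThermalFrame

__all__ = [
    "frame_filename",
    "parse_frame_filename",
    "write_frames",
    "read_frames",
    "write_weather",
    "read_weather",
    "write_truth",
    "read_truth",
]

_FRAME_RE = re.compile(
    r"^d(?P<date>\d+)_t(?P<treatment>[^_]+)_b(?P<block>\d+)_(?P<side>[^_]+)"
    r"_f(?P<frame>\d+)\.(?P<ext>tif|tiff|csv)$"
)


def frame_filename(meta: FrameMeta, fmt: str = "tiff") -> str:
    ext = {"tiff": "tif", "csv": "csv"}[fmt]
    return (
        f"d{meta.date_index:02d}_t{meta.treatment}_b{meta.block:02d}"
        f"_{meta.side}_f{meta.frame_index:04d}.{ext}"
    )


def parse_frame_filename(name: str) -> FrameMeta:
    m = _FRAME_RE.match(name)
    if m is None:
        raise ValueError(f"not a frame filename: {name!r}")
    return FrameMeta(
        date_index=int(m["date"]),
        treatment=m["treatment"],
        block=int(m["block"]),
        side=m["side"],
        frame_index=int(m["frame"]),
    )


def write_frames(
    frames: Iterable[ThermalFrame], out_dir: str | Path, fmt: str = "tiff"
) -> list[Path]:
    """Write each frame as a single-page float32 TIFF or a CSV matrix."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for fr in frames:
        path = out_dir / frame_filename(fr.meta, fmt)
        data = fr.pixels.astype(np.float32)
        if fmt == "tiff":
            tifffile.imwrite(path, data)
        elif fmt == "csv":
            np.savetxt(path, data, delimiter=",", fmt="%.6f")
        else:
            raise ValueError(f"unknown frame format {fmt!r}")
        paths.append(path)
    return paths


def read_frames(in_dir: str | Path) -> list[ThermalFrame]:
    """Load every frame file in a directory, metadata parsed from filenames."""
    in_dir = Path(in_dir)
    frames = []
    for path in sorted(in_dir.iterdir()):
        try:
            meta = parse_frame_filename(path.name)
        except ValueError:
            continue
        if path.suffix == ".csv":
            pixels = np.loadtxt(path, delimiter=",", dtype=np.float32)
        else:
            pixels = tifffile.imread(path)
        frames.append(ThermalFrame(pixels=pixels, meta=meta))
    if not frames:
        raise FileNotFoundError(f"no frame files found in {in_dir}")
    return frames


WEATHER_COLUMNS = [
    "date_index",
    "air_temp",
    "relative_humidity",
    "vpd",
    "irradiance",
    "t_wet",
    "t_dry",
]

TRUTH_COLUMNS = [
    "date_index",
    "treatment",
    "block",
    "side",
    "vine",
    "psi_stem",
    "true_cwsi",
]


def write_weather(weather: Sequence[DayWeather], path: str | Path) -> None:
    df = pd.DataFrame([{c: getattr(w, c) for c in WEATHER_COLUMNS} for w in weather])
    df.to_csv(path, index=False)


def read_weather(path: str | Path) -> list[DayWeather]:
    df = pd.read_csv(path)
    return [DayWeather(**{c: row[c] for c in WEATHER_COLUMNS}) for _, row in df.iterrows()]


def write_truth(truths: Sequence[GroundTruth], path: str | Path) -> None:
    df = pd.DataFrame([{c: getattr(t, c) for c in TRUTH_COLUMNS} for t in truths])
    df.to_csv(path, index=False)


def read_truth(path: str | Path) -> list[GroundTruth]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        kwargs = {c: row[c] for c in TRUTH_COLUMNS}
        for k in ("date_index", "block", "vine"):
            kwargs[k] = int(kwargs[k])
        out.append(GroundTruth(**kwargs))
    return out
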