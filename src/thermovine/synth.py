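"""Synthetic vineyard campaigns: weather, reference temperatures, ground-truth
stem water potential and rendered canopy thermal frames.

The generator is calibrated so that, at default parameters, the marginal
distribution of psi_stem has mean ~ -1.23 MPa and SD ~ 0.298 MPa over the
default design range [-2.05, -0.40] MPa.

Generative model
----------------
Each monitored vine receives a latent stress index ``true_cwsi`` drawn from a
Beta distribution whose mean depends additively on irrigation treatment
(drier treatments more stressed) and on a seasonal date trend (stronger for
drier treatments). Stem water potential follows the monotone link

    psi_stem = a + b * true_cwsi + side_effect + eps,   eps ~ N(0, sd)

with a = -0.40 and b = -1.65 so that true_cwsi in [0, 1] spans the target
psi range. Rendered frames have a sky band (below t_wet), a canopy band with
mean t_wet + true_cwsi * (t_dry - t_wet), and a warm soil/fruit band, plus
i.i.d. Gaussian pixel noise. All randomness flows from one master seed via
named substreams.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from thermovine import geometry
from thermovine._rng import substream
from thermovine.geometry import CameraModel, TraverseSpec
from thermovine.thermal import FrameMeta, ThermalFrame, partition_contiguous

__all__ = [
    "CampaignDesign",
    "DayWeather",
    "GroundTruth",
    "SynthParams",
    "vpd_from_weather",
    "expected_cwsi_mean",
    "sample_campaign",
    "render_frame_sequence",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CampaignDesign:
    """Randomized-complete-block campaign layout."""

    n_dates: int = 7
    treatments: tuple[str, ...] = ("T0", "T1", "T2")
    n_blocks: int = 4
    sides: tuple[str, ...] = ("east", "west")
    vines_per_replication: int = 3
    plants_per_replication: int = 25
    row_length_m: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_dates", "n_blocks", "vines_per_replication", "plants_per_replication"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not self.treatments or not self.sides:
            raise ValueError("treatments and sides must be non-empty")

    @property
    def samples_per_day(self) -> int:
        """Water-status measurements per day across the design (one side)."""
        return len(self.treatments) * self.n_blocks * self.vines_per_replication

    @property
    def samples_per_side(self) -> int:
        return self.n_dates * self.samples_per_day


@dataclass(frozen=True)
class DayWeather:
    """One measurement day's weather and reference temperatures."""

    date_index: int
    air_temp: float
    relative_humidity: float
    vpd: float
    irradiance: float
    t_wet: float
    t_dry: float

    def __post_init__(self) -> None:
        if not self.t_dry > self.t_wet:
            raise ValueError("t_dry must exceed t_wet")
        if not 0.0 <= self.relative_humidity <= 100.0:
            raise ValueError("relative_humidity must be in [0, 100]")
        if self.vpd < 0 or self.irradiance < 0:
            raise ValueError("vpd and irradiance must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """Ground truth for one monitored vine on one date/side."""

    date_index: int
    treatment: str
    block: int
    side: str
    vine: int
    psi_stem: float
    true_cwsi: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_cwsi <= 1.0:
            raise ValueError("true_cwsi must lie in [0, 1]")


@dataclass(frozen=True)
class SynthParams:
    """Generator parameters; defaults reproduce the target psi moments."""

    # psi link: psi = intercept + slope * cwsi (+ side effect + noise)
    psi_intercept: float = -0.40
    psi_slope: float = -1.65
    psi_range: tuple[float, float] = (-2.05, -0.40)
    psi_noise_sd: float = 0.184
    # latent stress index
    cwsi_base_mean: float = 0.83 / 1.65  # maps to mean psi of -1.23 MPa
    treatment_offset_spread: float = 0.15
    date_trend_max: float = 0.16
    cwsi_concentration: float = 60.0
    # side effects on psi (MPa), mean-zero across sides
    side_effects: tuple[tuple[str, float], ...] = (("east", 0.015), ("west", -0.015))
    # scene rendering
    sky_band_frac: float = 0.22
    soil_band_frac: float = 0.22
    sky_offset: float = -10.0  # relative to t_wet
    soil_offset: float = 5.0  # relative to t_dry
    pixel_noise_sd: float = 0.8
    # weather
    air_temp_base: float = 26.0
    air_temp_season_amp: float = 6.0
    air_temp_sd: float = 1.5
    rh_low: float = 25.0
    rh_high: float = 55.0
    irradiance_base: float = 850.0
    irradiance_season_amp: float = 80.0
    irradiance_sd: float = 60.0
    wet_depression: float = 4.0
    dry_elevation: float = 5.0
    ref_noise_sd: float = 0.4

    def side_effect(self, side: str) -> float:
        return dict(self.side_effects).get(side, 0.0)


def vpd_from_weather(air_temp: float, relative_humidity: float) -> float:
    """Vapour pressure deficit (kPa) from the Tetens saturation-pressure form.

    e_s = 0.6108 * exp(17.27 T / (T + 237.3));  vpd = e_s * (1 - RH/100).
    """
    if not 0.0 <= relative_humidity <= 100.0:
        raise ValueError("relative_humidity must be in [0, 100]")
    e_s = 0.6108 * math.exp(17.27 * air_temp / (air_temp + 237.3))
    return e_s * (1.0 - relative_humidity / 100.0)


def _treatment_offsets(params: SynthParams, n_treatments: int) -> np.ndarray:
    if n_treatments == 1:
        return np.zeros(1)
    return np.linspace(
        -params.treatment_offset_spread, params.treatment_offset_spread, n_treatments
    )


def expected_cwsi_mean(
    params: SynthParams, design: CampaignDesign, treatment_idx: int, date_index: int
) -> float:
    """Expected latent stress index for a treatment x date cell.

    Treatment offsets are evenly spread (first treatment least stressed) and
    the seasonal trend span grows with treatment dryness, centred over dates.
    """
    n_t = len(design.treatments)
    offset = _treatment_offsets(params, n_t)[treatment_idx]
    span = params.date_trend_max * (treatment_idx + 1) / n_t
    if design.n_dates > 1:
        trend = span * (date_index / (design.n_dates - 1) - 0.5)
    else:
        trend = 0.0
    return float(np.clip(params.cwsi_base_mean + offset + trend, 0.02, 0.98))


def _sample_weather(
    design: CampaignDesign, params: SynthParams, rng: np.random.Generator
) -> list[DayWeather]:
    days = []
    for d in range(design.n_dates):
        phase = (d + 0.5) / design.n_dates
        air = (
            params.air_temp_base
            + params.air_temp_season_amp * math.sin(math.pi * phase)
            + rng.normal(0.0, params.air_temp_sd)
        )
        rh = float(rng.uniform(params.rh_low, params.rh_high))
        irr = max(
            400.0,
            params.irradiance_base
            + params.irradiance_season_amp * math.sin(math.pi * phase)
            + rng.normal(0.0, params.irradiance_sd),
        )
        t_wet = air - params.wet_depression + rng.normal(0.0, params.ref_noise_sd)
        t_dry = air + params.dry_elevation + rng.normal(0.0, params.ref_noise_sd)
        days.append(
            DayWeather(
                date_index=d,
                air_temp=float(air),
                relative_humidity=rh,
                vpd=vpd_from_weather(air, rh),
                irradiance=float(irr),
                t_wet=float(t_wet),
                t_dry=float(t_dry),
            )
        )
    return days


def sample_campaign(
    design: CampaignDesign,
    params: SynthParams = SynthParams(),
    seed: int | None = None,
) -> tuple[list[DayWeather], list[GroundTruth]]:
    """Draw one campaign: per-day weather and per-vine ground truth.

    Returns ``design.samples_per_side`` GroundTruth records per canopy side
    (252 at the default design). Deterministic given the seed.
    """
    master = design.seed if seed is None else seed
    weather = _sample_weather(design, params, substream(master, "weather"))
    rng = substream(master, "truth")
    lo, hi = params.psi_range

    truths: list[GroundTruth] = []
    for d in range(design.n_dates):
        for t_idx, treatment in enumerate(design.treatments):
            m = expected_cwsi_mean(params, design, t_idx, d)
            k = params.cwsi_concentration
            for block in range(design.n_blocks):
                for side in design.sides:
                    for vine in range(design.vines_per_replication):
                        c = float(rng.beta(m * k, (1.0 - m) * k))
                        psi = (
                            params.psi_intercept
                            + params.psi_slope * c
                            + params.side_effect(side)
                            + rng.normal(0.0, params.psi_noise_sd)
                        )
                        truths.append(
                            GroundTruth(
                                date_index=d,
                                treatment=treatment,
                                block=block,
                                side=side,
                                vine=vine,
                                psi_stem=float(np.clip(psi, lo, hi)),
                                true_cwsi=c,
                            )
                        )
    return weather, truths


def _band_rows(n_rows: int, params: SynthParams) -> tuple[int, int]:
    """Row indices (sky_end, canopy_end) of the vertical scene structure."""
    sky_end = int(round(params.sky_band_frac * n_rows))
    canopy_end = n_rows - int(round(params.soil_band_frac * n_rows))
    if not 0 < sky_end < canopy_end < n_rows:
        raise ValueError("band fractions leave no room for sky/canopy/soil bands")
    return sky_end, canopy_end


def _frame_vine_map(
    n_total: int, camera: CameraModel, traverse: TraverseSpec, n_vines: int
) -> np.ndarray:
    """Vine-group index for every frame of a replication recording.

    Retained frames split into contiguous near-equal blocks (the same rule
    the feature extractor uses); other frames take the group of the nearest
    retained frame, so selected-frame round trips are exact.
    """
    selected = geometry.select_frames(n_total, camera, traverse)
    sizes = partition_contiguous(len(selected), n_vines)
    group_of_position = np.repeat(np.arange(n_vines), sizes)
    sel = np.asarray(selected)
    idx = np.arange(n_total)
    nearest = np.argmin(np.abs(idx[:, None] - sel[None, :]), axis=1)
    return group_of_position[nearest]


def render_frame_sequence(
    truths: Sequence[GroundTruth] | GroundTruth,
    weather: DayWeather,
    camera: CameraModel,
    traverse: TraverseSpec = TraverseSpec(),
    params: SynthParams = SynthParams(),
    rng: np.random.Generator | None = None,
    indices: Sequence[int] | None = None,
) -> list[ThermalFrame]:
    """Render the thermal frames of one replication traverse.

    ``truths`` holds the replication's monitored vines (same date, treatment,
    block and side). By default all ``frames_per_replication`` frames are
    rendered; pass ``indices`` to render a subset (e.g. the selected frames).
    Each frame is a float32 sky/canopy/soil band scene whose canopy mean is
    t_wet + true_cwsi * (t_dry - t_wet) for the vine the frame faces.
    """
    if isinstance(truths, GroundTruth):
        truths = [truths]
    if not truths:
        raise ValueError("need at least one ground-truth vine")
    keys = {(t.date_index, t.treatment, t.block, t.side) for t in truths}
    if len(keys) != 1:
        raise ValueError("truths must all belong to one replication")
    date_index, treatment, block, side = keys.pop()
    by_vine = {t.vine: t for t in sorted(truths, key=lambda t: t.vine)}
    if sorted(by_vine) != list(range(len(by_vine))):
        raise ValueError("vine labels must be 0..n-1")
    if not weather.t_dry > weather.t_wet:
        raise ValueError("t_dry must exceed t_wet")

    rng = rng or np.random.default_rng()
    n_cols, n_rows = camera.resolution
    sky_end, canopy_end = _band_rows(n_rows, params)
    n_total = geometry.frames_per_replication(camera, traverse)
    vine_map = _frame_vine_map(n_total, camera, traverse, len(by_vine))
    frame_indices = range(n_total) if indices is None else indices

    sky_t = weather.t_wet + params.sky_offset
    soil_t = weather.t_dry + params.soil_offset
    span = weather.t_dry - weather.t_wet

    frames = []
    for i in frame_indices:
        if not 0 <= i < n_total:
            raise ValueError(f"frame index {i} outside [0, {n_total})")
        truth = by_vine[int(vine_map[i])]
        canopy_t = weather.t_wet + truth.true_cwsi * span
        img = np.empty((n_rows, n_cols), dtype=np.float64)
        img[:sky_end] = sky_t
        img[sky_end:canopy_end] = canopy_t
        img[canopy_end:] = soil_t
        if params.pixel_noise_sd > 0:
            img += rng.normal(0.0, params.pixel_noise_sd, size=img.shape)
        frames.append(
            ThermalFrame(
                pixels=img.astype(np.float32),
                meta=FrameMeta(
                    date_index=date_index,
                    treatment=treatment,
                    block=block,
                    side=side,
                    frame_index=int(i),
                ),
            )
        )
    return frames
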