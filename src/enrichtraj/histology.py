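"""Fluorescence stain quantification and stain-behavior association.

Quantification follows the slice-level procedure used for fibrinogen and
angiogenesis stains: each channel is thresholded at its median plus two
standard deviations, and the stain-positive area is expressed as a
percentage of the lectin-labeled (perfused vessel) area. Association
statistics are ordinary least squares plus Pearson correlation between a
per-animal stain readout and a behavioral score (social-interaction
quotient or light:dark crossings).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass
class TwoChannelImage:
    """Vessel-label channel plus stain-of-interest channel, same geometry."""

    vessel_channel: np.ndarray
    stain_channel: np.ndarray
    pixel_size: float | None = None  # physical units per pixel, optional

    def __post_init__(self) -> None:
        self.vessel_channel = np.asarray(self.vessel_channel, dtype=float)
        self.stain_channel = np.asarray(self.stain_channel, dtype=float)
        if self.vessel_channel.shape != self.stain_channel.shape:
            raise ValueError(
                f"channel shapes differ: {self.vessel_channel.shape} vs "
                f"{self.stain_channel.shape}"
            )
        if (self.vessel_channel < 0).any() or (self.stain_channel < 0).any():
            raise ValueError("intensities must be non-negative")


@dataclass
class AreaQuantRecord:
    image_id: str
    vessel_area_px: int
    stain_area_px: int
    pct_positive: float          # 100 * stain_area / vessel_area; NaN if no vessel
    threshold_vessel: float
    threshold_stain: float
    undefined: bool = False      # True when vessel area is zero


@dataclass
class BehaviorRecord:
    """Per-animal behavioral scores.

    The social-interaction (SI) quotient is time investigating the cylinder
    holding the CD-1 mouse divided by time at the empty cylinder; it is
    undefined (NaN, excluded from association tests) when the empty-cylinder
    time is zero. Low SI quotients and low light:dark crossing counts index
    asocial and anxiety-like behavior.
    """

    animal_id: str
    condition: str
    time_mouse_cylinder: float
    time_empty_cylinder: float
    ld_crosses: int

    def __post_init__(self) -> None:
        if self.time_mouse_cylinder < 0 or self.time_empty_cylinder < 0:
            raise ValueError("investigation times must be >= 0")
        if self.ld_crosses < 0:
            raise ValueError("ld_crosses must be >= 0")

    @property
    def si_quotient(self) -> float:
        if self.time_empty_cylinder > 0:
            return self.time_mouse_cylinder / self.time_empty_cylinder
        return float("nan")


@dataclass
class AssociationResult:
    x_name: str
    y_name: str
    slope: float
    intercept: float
    r_squared: float
    f_stat: float
    p_regression: float
    pearson_r: float
    p_pearson: float
    n: int


def threshold_channel(channel: np.ndarray) -> tuple[np.ndarray, float]:
    """Binary mask of pixels strictly above median + 2 * SD.

    The population (ddof=0) standard deviation is taken over all pixels of
    the slice. A constant channel yields an empty mask (SD is zero and no
    pixel exceeds its own median).
    """
    channel = np.asarray(channel, dtype=float)
    if channel.size == 0:
        raise ValueError("empty channel")
    threshold = float(np.median(channel) + 2.0 * np.std(channel))
    return channel > threshold, threshold


def quantify(
    image: TwoChannelImage,
    image_id: str = "",
    roi_mask: np.ndarray | None = None,
) -> AreaQuantRecord:
    """Stain area as a percentage of vessel (lectin) area for one slice.

    Threshold statistics are computed over all pixels of each channel
    (optionally restricted to ``roi_mask``); the two masks are not required
    to overlap — total areas are divided, as in whole-slice scans.
    """
    vessel = image.vessel_channel
    stain = image.stain_channel
    if roi_mask is not None:
        roi_mask = np.asarray(roi_mask, dtype=bool)
        if roi_mask.shape != vessel.shape:
            raise ValueError("ROI mask shape does not match image")
        vmask_roi, thr_v = threshold_channel(vessel[roi_mask])
        smask_roi, thr_s = threshold_channel(stain[roi_mask])
        vessel_area = int(vmask_roi.sum())
        stain_area = int(smask_roi.sum())
    else:
        vmask, thr_v = threshold_channel(vessel)
        smask, thr_s = threshold_channel(stain)
        vessel_area = int(vmask.sum())
        stain_area = int(smask.sum())
    if vessel_area == 0:
        return AreaQuantRecord(
            image_id, 0, stain_area, float("nan"), thr_v, thr_s, undefined=True
        )
    return AreaQuantRecord(
        image_id,
        vessel_area,
        stain_area,
        100.0 * stain_area / vessel_area,
        thr_v,
        thr_s,
    )


def count_blobs(mask: np.ndarray, min_size: int = 1) -> int:
    """Count connected foreground components of at least ``min_size`` pixels.

    A convenience utility on thresholded masks. It is *not* equivalent to
    the blinded manual microbleed annotation performed on whole-slice scans;
    use it only for synthetic or exploratory mask summaries.
    """
    from skimage import measure

    labels = measure.label(np.asarray(mask, dtype=bool))
    if labels.max() == 0:
        return 0
    sizes = np.bincount(labels.ravel())[1:]
    return int((sizes >= min_size).sum())


def aggregate_by_animal(
    records: Sequence[AreaQuantRecord], image_to_animal: dict[str, str]
) -> dict[str, float]:
    """Mean pct_positive per animal over its (typically six) sections."""
    by_animal: dict[str, list[float]] = {}
    for rec in records:
        if rec.undefined or math.isnan(rec.pct_positive):
            continue
        animal = image_to_animal[rec.image_id]
        by_animal.setdefault(animal, []).append(rec.pct_positive)
    return {a: float(np.mean(v)) for a, v in by_animal.items()}


def associate(
    stain_values: dict[str, float],
    behavior: Sequence[BehaviorRecord],
    behavior_field: str = "si_quotient",
    x_name: str = "stain",
) -> AssociationResult:
    """OLS of a behavioral score on a per-animal stain readout, plus Pearson r.

    Animals are paired by id; records with an undefined SI quotient are
    excluded. For simple linear regression the F statistic of the slope is
    the squared slope t statistic and R^2 equals the squared Pearson r.
    """
    if behavior_field not in ("si_quotient", "ld_crosses"):
        raise ValueError(f"unknown behavior field {behavior_field!r}")
    xs, ys = [], []
    for rec in behavior:
        if rec.animal_id not in stain_values:
            continue
        y = float(getattr(rec, behavior_field))
        if math.isnan(y):
            continue
        xs.append(stain_values[rec.animal_id])
        ys.append(y)
    n = len(xs)
    if n < 3:
        raise ValueError(f"need >= 3 paired animals, have {n}")
    x = np.asarray(xs)
    y = np.asarray(ys)
    if np.allclose(x, x[0]):
        raise ValueError("stain values have zero variance")
    fit = sps.linregress(x, y)
    with np.errstate(divide="ignore"):
        t_slope = fit.slope / fit.stderr if fit.stderr > 0 else float("inf")
    pearson = sps.pearsonr(x, y)
    return AssociationResult(
        x_name=x_name,
        y_name=behavior_field,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        f_stat=float(t_slope**2),
        p_regression=float(fit.pvalue),
        pearson_r=float(pearson.statistic),
        p_pearson=float(pearson.pvalue),
        n=n,
    )


# ---------------------------------------------------------------------------
# image file I/O

def read_two_channel_image(
    path: str | Path, stain_path: str | Path | None = None
) -> TwoChannelImage:
    """Load a two-channel image from one multi-page TIFF or a file pair.

    With a single TIFF, pages 0 and 1 are the vessel and stain channels.
    With a pair (TIFF or PNG), the first file is the vessel channel.
    """
    path = Path(path)
    if stain_path is None:
        import tifffile

        arr = tifffile.imread(path)
        if arr.ndim != 3 or arr.shape[0] < 2:
            raise ValueError(
                f"{path}: expected a multi-page TIFF with >= 2 pages, got {arr.shape}"
            )
        return TwoChannelImage(arr[0], arr[1])
    import imageio.v3 as iio

    return TwoChannelImage(iio.imread(path), iio.imread(Path(stain_path)))


def write_two_channel_image(image: TwoChannelImage, path: str | Path) -> None:
    import tifffile

    tifffile.imwrite(
        Path(path),
        np.stack([image.vessel_channel, image.stain_channel]).astype(np.float32),
    )
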