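"""Field-level measures and their sample / observer-combination means.

Two measures summarize one analyzed field: the percentage of positive
cells, %PC = 100 * stained cells / total cells, and the staining
intensity per unit area, intensity/area = (sum of DAB channel values over
all ROI pixels) / (number of ROI pixels), in [0, 1] arbitrary units per
pixel.  Up to four representative fields per sample are averaged into a
sample value for each selector/analyzer pair, and those pair values can
be averaged again across the available observer combinations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .segmentation import LabeledCells
from .stains import StainChannels

__all__ = [
    "ImageMetrics",
    "SampleMetrics",
    "CombinationMean",
    "compute_image_metrics",
    "aggregate_sample",
    "aggregate_combinations",
]

MAX_IMAGES_PER_SAMPLE = 4


@dataclass(frozen=True)
class ImageMetrics:
    """Measures of a single field.

    ``pct_positive`` is NaN when no cells were detected: 0/0 is not the
    same observation as "no positive cells", and NaN propagates visibly
    into tabular output as a missing value.
    """

    n_cells: int
    n_positive: int
    total_intensity: float
    roi_area: int
    pct_positive: float
    intensity_per_area: float


@dataclass(frozen=True)
class SampleMetrics:
    sample_id: str
    selector: str
    analyzer: str
    n_images: int
    pct_positive: float
    intensity_per_area: float


@dataclass(frozen=True)
class CombinationMean:
    sample_id: str
    n_combinations: int
    pct_positive: float
    intensity_per_area: float


def compute_image_metrics(
    channels: StainChannels, roi: np.ndarray, cells: LabeledCells
) -> ImageMetrics:
    """Compute %PC and intensity/area for one field.

    Total intensity sums the DAB channel over *all* ROI pixels, stained
    and unstained alike, so intensity/area reflects both strength and
    spatial extent of the staining.
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != channels.dab.shape:
        raise ValueError("ROI shape does not match the stain channels")
    roi_area = int(np.count_nonzero(roi))
    if roi_area == 0:
        raise ValueError("ROI mask is empty")
    total_intensity = float(np.asarray(channels.dab, dtype=float)[roi].sum())
    n_cells = cells.n_cells
    n_positive = cells.n_positive
    pct = 100.0 * n_positive / n_cells if n_cells > 0 else math.nan
    return ImageMetrics(
        n_cells=n_cells,
        n_positive=n_positive,
        total_intensity=total_intensity,
        roi_area=roi_area,
        pct_positive=pct,
        intensity_per_area=total_intensity / roi_area,
    )


def _mean_defined(values: Iterable[float]) -> float:
    vals = [v for v in values if not math.isnan(v)]
    return sum(vals) / len(vals) if vals else math.nan


def aggregate_sample(
    metrics: Sequence[ImageMetrics],
    sample_id: str,
    selector: str,
    analyzer: str,
) -> SampleMetrics:
    """Unweighted mean of up to four field measurements for one sample.

    Fields with undefined %PC (no detected cells) are excluded from the
    %PC mean only; intensity/area always contributes.
    """
    if not 1 <= len(metrics) <= MAX_IMAGES_PER_SAMPLE:
        raise ValueError(
            f"expected 1-{MAX_IMAGES_PER_SAMPLE} field measurements, got {len(metrics)}"
        )
    return SampleMetrics(
        sample_id=sample_id,
        selector=selector,
        analyzer=analyzer,
        n_images=len(metrics),
        pct_positive=_mean_defined(m.pct_positive for m in metrics),
        intensity_per_area=_mean_defined(m.intensity_per_area for m in metrics),
    )


def aggregate_combinations(samples: Sequence[SampleMetrics]) -> CombinationMean:
    """Mean over the available selector/analyzer combinations of one sample."""
    if not samples:
        raise ValueError("no sample metrics given")
    sample_ids = {s.sample_id for s in samples}
    if len(sample_ids) != 1:
        raise ValueError(f"mixed sample ids: {sorted(sample_ids)}")
    pairs = [(s.selector, s.analyzer) for s in samples]
    if len(set(pairs)) != len(pairs):
        raise ValueError("duplicated (selector, analyzer) combination")
    if len(pairs) > 4:
        raise ValueError("more than 4 selector/analyzer combinations")
    return CombinationMean(
        sample_id=samples[0].sample_id,
        n_combinations=len(samples),
        pct_positive=_mean_defined(s.pct_positive for s in samples),
        intensity_per_area=_mean_defined(s.intensity_per_area for s in samples),
    )
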