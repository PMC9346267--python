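"""Synthetic H-DAB fields, multi-observer tables, and response tables.

Everything the pipeline and the statistics layer consume can be generated
here with known ground truth:

* :func:`generate_field` paints non-overlapping nuclei (hematoxylin) and
  whole-cell DAB staining for a chosen fraction of positive cells, then
  composes an RGB brightfield image through the Beer-Lambert forward
  model — the exact inverse of the deconvolution in :mod:`.stains` — plus
  Gaussian pixel noise.
* :func:`generate_observer_tables` draws per-sample latent truths and
  adds independent selector, analyzer and residual effects, emulating a
  two-selector x two-analyzer reproducibility design; the implied CCC
  between any two observer combinations has the closed form in
  :func:`theoretical_ccc`.
* :func:`generate_response_tables` draws (staining measure, biochemical
  response) pairs from a Gaussian copula calibrated to a target Spearman
  correlation.

All generators are fully deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats as sps
from skimage.filters import gaussian

from .segmentation import delimit_cells
from .stains import SATURATION_OD, StainChannels, StainMatrix, recombine

__all__ = [
    "FieldSpec",
    "GroundTruth",
    "ObserverModel",
    "generate_field",
    "generate_observer_tables",
    "generate_response_tables",
    "theoretical_ccc",
]


@dataclass(frozen=True)
class FieldSpec:
    """Parameters of one synthetic IHC field.

    ``dab_level`` and ``hema_level`` are fractions of the saturation OD
    (so they equal the ideal deconvolved channel values).  Positive cells
    carry DAB over the nucleus plus a perinuclear ring of ``ring_px``,
    clipped to the cell's own territory, emulating whole-cell staining.
    """

    n_cells: int = 150
    frac_positive: float = 0.5
    dab_level: float = 0.5
    hema_level: float = 0.6
    nucleus_radius_mean: float = 8.0
    nucleus_radius_sd: float = 1.0
    image_size: tuple[int, int] = (512, 512)
    noise_sd: float = 2.0  # 8-bit intensity counts
    roi_margin: int = 16
    ring_px: int = 4
    min_gap_px: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_positive <= 1.0:
            raise ValueError("frac_positive must be in [0, 1]")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    nucleus_centers: np.ndarray  # (n, 2), (row, col)
    nucleus_radii: np.ndarray
    positive_flags: np.ndarray
    true_pct_positive: float
    true_intensity_per_area: float
    nucleus_labels: np.ndarray = field(repr=False)


def _place_nuclei(spec: FieldSpec, rng: np.random.Generator):
    """Dart-throwing placement of non-overlapping nuclei inside the ROI."""
    h, w = spec.image_size
    margin = spec.roi_margin
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    max_rejections = 5000  # consecutive misses before giving up
    rejections = 0
    carr = np.empty((0, 2))
    rarr = np.empty(0)
    while len(centers) < spec.n_cells:
        if rejections >= max_rejections:
            raise ValueError(
                f"could not place {spec.n_cells} non-overlapping nuclei "
                f"in a {h}x{w} field (density infeasible)"
            )
        r = float(np.clip(rng.normal(spec.nucleus_radius_mean, spec.nucleus_radius_sd),
                          3.0, 3.0 * spec.nucleus_radius_mean))
        lo_r, hi_r = margin + r + 1, h - margin - r - 1
        lo_c, hi_c = margin + r + 1, w - margin - r - 1
        if lo_r >= hi_r or lo_c >= hi_c:
            raise ValueError("image too small for the requested nuclei")
        cy = rng.uniform(lo_r, hi_r)
        cx = rng.uniform(lo_c, hi_c)
        if carr.size:
            d = np.hypot(carr[:, 0] - cy, carr[:, 1] - cx)
            if np.any(d < rarr + r + spec.min_gap_px):
                rejections += 1
                continue
        rejections = 0
        centers.append((cy, cx))
        radii.append(r)
        carr = np.asarray(centers)
        rarr = np.asarray(radii)
    return carr.reshape(-1, 2), rarr


def generate_field(spec: FieldSpec, stains: StainMatrix | None = None):
    """Generate one synthetic field.

    Returns ``(image, roi, truth)``: an 8-bit RGB image, a boolean ROI
    mask (rectangle inset by ``roi_margin``), and the ground truth.  The
    stored ``true_intensity_per_area`` is the ROI mean of the noiseless
    DAB channel, i.e. the value an ideal pipeline would measure.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    roi = np.zeros((h, w), dtype=bool)
    m = spec.roi_margin
    roi[m : h - m, m : w - m] = True

    centers, radii = _place_nuclei(spec, rng)
    n = centers.shape[0]
    n_pos = int(round(spec.frac_positive * n))
    flags = np.zeros(n, dtype=bool)
    if n:
        flags[rng.permutation(n)[:n_pos]] = True

    labels = np.zeros((h, w), dtype=np.int32)
    rows, cols = np.ogrid[:h, :w]
    for i, ((cy, cx), r) in enumerate(zip(centers, radii), start=1):
        sl = (
            slice(max(int(cy - r) - 1, 0), min(int(cy + r) + 2, h)),
            slice(max(int(cx - r) - 1, 0), min(int(cx + r) + 2, w)),
        )
        yy, xx = np.ogrid[sl]
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        labels[sl][disk] = i

    hema = np.where(labels > 0, spec.hema_level, 0.0)
    dab = np.zeros((h, w))
    if n and flags.any():
        territory = delimit_cells(labels, np.ones((h, w), dtype=bool), spec.ring_px)
        pos_ids = np.flatnonzero(flags) + 1
        dab[np.isin(territory, pos_ids)] = spec.dab_level
    hema = gaussian(hema, sigma=1.0, preserve_range=True)
    dab = gaussian(dab, sigma=1.0, preserve_range=True)

    image = recombine(
        StainChannels(hema, dab), stains, white_point=255.0,
        saturation_od=SATURATION_OD, dtype=float,
    )
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.round(np.clip(image, 0.0, 255.0)).astype(np.uint8)

    truth = GroundTruth(
        nucleus_centers=centers,
        nucleus_radii=radii,
        positive_flags=flags,
        true_pct_positive=100.0 * flags.sum() / n if n else float("nan"),
        true_intensity_per_area=float(dab[roi].mean()),
        nucleus_labels=labels,
    )
    return image, roi, truth


@dataclass(frozen=True)
class ObserverModel:
    """Additive Gaussian observer-effect model.

    Each measurement is truth + selector effect + analyzer effect +
    residual, with the selector and analyzer effects drawn once per
    (sample, observer) and the residual per measurement; all effects are
    independent zero-mean Gaussians.
    """

    selector_sd: float = 2.0
    analyzer_sd: float = 2.0
    measurement_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.selector_sd, self.analyzer_sd, self.measurement_sd) < 0:
            raise ValueError("all effect SDs must be >= 0")


def theoretical_ccc(
    truth_var: float,
    model: ObserverModel,
    *,
    shared_selector: bool = False,
    shared_analyzer: bool = False,
) -> float:
    """Closed-form CCC between two observer combinations.

    Under the additive model both combinations have equal means and equal
    variances truth_var + s^2 + a^2 + e^2; their covariance is truth_var
    plus the variance of every shared effect, and the CCC is their ratio.
    """
    s2 = model.selector_sd**2
    a2 = model.analyzer_sd**2
    e2 = model.measurement_sd**2
    cov = truth_var + (s2 if shared_selector else 0.0) + (a2 if shared_analyzer else 0.0)
    return cov / (truth_var + s2 + a2 + e2)


def generate_observer_tables(
    n_samples: int,
    model: ObserverModel,
    *,
    truth_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    measure: str = "pct_positive",
    value_range: tuple[float, float] = (0.0, 100.0),
    selectors: tuple[str, ...] = ("S1", "S2"),
    analyzers: tuple[str, ...] = ("A1", "A2"),
) -> pd.DataFrame:
    """Long-format measurement table for a selector x analyzer design.

    Columns: sample_id, selector, analyzer, measure, value.  Values are
    clipped to ``value_range`` after noise addition (a mild attenuation
    of agreement for truths near the range limits).  The default truth
    sampler is Normal(50, 15), a mid-range %PC distribution.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(model.seed)
    if truth_sampler is None:
        truth_sampler = lambda r, size: r.normal(50.0, 15.0, size)  # noqa: E731
    truth = np.asarray(truth_sampler(rng, n_samples), dtype=float)

    rows = []
    width = len(str(n_samples))
    for i in range(n_samples):
        sid = f"P{i + 1:0{width}d}"
        s_eff = {s: rng.normal(0.0, model.selector_sd) for s in selectors}
        a_eff = {a: rng.normal(0.0, model.analyzer_sd) for a in analyzers}
        for s in selectors:
            for a in analyzers:
                v = truth[i] + s_eff[s] + a_eff[a] + rng.normal(0.0, model.measurement_sd)
                rows.append((sid, s, a, measure, float(np.clip(v, *value_range))))
    return pd.DataFrame(rows, columns=["sample_id", "selector", "analyzer", "measure", "value"])


def generate_response_tables(
    n_patients: int,
    rho_target: float,
    seed: int,
    *,
    measure_scale: float = 0.6,
    igf1_log_sd: float = 0.5,
) -> pd.DataFrame:
    """Paired staining measure and biochemical response with a target
    (negative) Spearman correlation.

    Draws from a bivariate Gaussian copula whose Pearson parameter
    r = 2 sin(pi * rho_s / 6) yields Spearman correlation ``rho_target``.
    The staining measure is uniform on (0, measure_scale) (an
    intensity/area-like scale); the response is log-normal with median 1,
    so ``normalized_flag`` (response <= 1) marks roughly half the
    patients.
    """
    if not -1.0 < rho_target <= 0.0:
        raise ValueError("rho_target must be in (-1, 0]")
    if n_patients < 2:
        raise ValueError("need at least 2 patients")
    rng = np.random.default_rng(seed)
    r = 2.0 * np.sin(np.pi * rho_target / 6.0)
    z = rng.multivariate_normal([0.0, 0.0], [[1.0, r], [r, 1.0]], size=n_patients)
    sst2 = measure_scale * sps.norm.cdf(z[:, 0])
    igf1 = np.exp(igf1_log_sd * z[:, 1])
    return pd.DataFrame(
        {
            "sample_id": [f"G{i + 1:03d}" for i in range(n_patients)],
            "sst2_measure": sst2,
            "igf1_xuln": igf1,
            "normalized_flag": igf1 <= 1.0,
        }
    )
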