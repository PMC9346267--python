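"""File formats, study manifests, and the end-to-end runners.

Tabular interchange is plain CSV; nested results are JSON.  Pixel
coordinates are 0-based, row-major (row, col) throughout the package.
Field images are 8/16-bit RGB TIFF or PNG; ROI masks are single-channel
images of the same shape with nonzero marking the inside of the
analyzer-drawn outline.

A study manifest is a CSV with one row per analyzed field:
``sample_id, selector, analyzer, image_id, image_path, roi_path`` where
``image_id`` runs 1-4 within each (sample, selector, analyzer) group —
up to four representative fields per slide and observer pair.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .config import RunConfig
from .quantify import (
    ImageMetrics,
    aggregate_combinations,
    aggregate_sample,
    compute_image_metrics,
)
from .segmentation import LabeledCells, segment_cells
from .stains import StainChannels, estimate_white_point, separate_stains
from .stats import concordance_correlation, roc_analysis, spearman_correlation

__all__ = [
    "read_image",
    "read_roi_mask",
    "read_manifest",
    "analyze_field",
    "run_quantify",
    "run_validation_report",
]

log = logging.getLogger("ihcquant")

MANIFEST_COLUMNS = ["sample_id", "selector", "analyzer", "image_id", "image_path", "roi_path"]


def read_image(path: str | Path) -> np.ndarray:
    """Read an RGB field image (TIFF or PNG, 8/16-bit)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 3 and arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError(f"{path}: expected an RGB image, got shape {arr.shape}")
    return arr


def read_roi_mask(path: str | Path, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Read a binary ROI mask (nonzero = inside)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    mask = arr > 0
    if shape is not None and mask.shape != tuple(shape):
        raise ValueError(f"{path}: ROI shape {mask.shape} does not match image {shape}")
    return mask


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate a study manifest CSV."""
    df = pd.read_csv(path, dtype={"sample_id": str, "selector": str, "analyzer": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest is missing columns: {missing}")
    if df.empty:
        raise ValueError("manifest is empty")
    key = ["sample_id", "selector", "analyzer", "image_id"]
    if df.duplicated(key).any():
        raise ValueError("manifest rows must be unique on (sample_id, selector, analyzer, image_id)")
    counts = df.groupby(["sample_id", "selector", "analyzer"]).size()
    if (counts > 4).any():
        bad = counts[counts > 4].index.tolist()
        raise ValueError(f"more than 4 fields per sample/selector/analyzer: {bad}")
    if (counts < 4).any():
        log.warning("some samples have fewer than 4 fields (small tissue); accepted")
    return df


def analyze_field(
    image: np.ndarray, roi: np.ndarray, config: RunConfig | None = None
) -> tuple[ImageMetrics, LabeledCells, StainChannels]:
    """Run the full per-field pipeline: deconvolve, segment, measure."""
    config = config or RunConfig()
    wp = estimate_white_point(image) if config.estimate_white_point else None
    channels = separate_stains(
        image, config.stains(), white_point=wp, saturation_od=config.saturation_od
    )
    cells = segment_cells(
        channels.hematoxylin,
        channels.dab,
        roi,
        nuclei_params=config.nuclei,
        expansion_px=config.expansion_px,
        positivity=config.positivity,
    )
    return compute_image_metrics(channels, roi, cells), cells, channels


@dataclass
class QuantifyRun:
    per_image: pd.DataFrame
    per_sample: pd.DataFrame
    per_combination: pd.DataFrame
    failures: list[dict]


def _manifest_hash(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()


def run_quantify(
    manifest: pd.DataFrame | str | Path,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> QuantifyRun:
    """Quantify every field in a manifest and aggregate the results.

    Per-image failures (missing file, shape mismatch, empty ROI) are
    recorded and skipped; the run continues.  When ``out_dir`` is given,
    writes ``per_image.csv``, ``per_sample.csv``, ``per_combination.csv``,
    a ``run.log`` listing failures, and a ``run_record.json`` echoing the
    configuration, package version, and input hashes.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = read_manifest(manifest)
    if manifest.empty:
        raise ValueError("manifest is empty")
    config = config or RunConfig()

    rows: list[dict] = []
    metric_objs: dict[tuple, list[ImageMetrics]] = {}
    failures: list[dict] = []
    ordered = manifest.sort_values(["sample_id", "selector", "analyzer", "image_id"])
    for rec in ordered.itertuples(index=False):
        try:
            image = read_image(rec.image_path)
            roi = read_roi_mask(rec.roi_path, shape=image.shape[:2])
            metrics, _, _ = analyze_field(image, roi, config)
        except (OSError, ValueError) as exc:
            failures.append(
                {"sample_id": rec.sample_id, "selector": rec.selector,
                 "analyzer": rec.analyzer, "image_id": rec.image_id, "reason": str(exc)}
            )
            log.warning("skipping %s/%s/%s image %s: %s",
                        rec.sample_id, rec.selector, rec.analyzer, rec.image_id, exc)
            continue
        rows.append(
            {"sample_id": rec.sample_id, "selector": rec.selector,
             "analyzer": rec.analyzer, "image_id": rec.image_id, **asdict(metrics)}
        )
        metric_objs.setdefault((rec.sample_id, rec.selector, rec.analyzer), []).append(metrics)

    per_image = pd.DataFrame(rows)
    sample_rows = [
        asdict(aggregate_sample(ms, sid, sel, ana))
        for (sid, sel, ana), ms in sorted(metric_objs.items())
    ]
    per_sample = pd.DataFrame(sample_rows)
    comb_rows = []
    if not per_sample.empty:
        from .quantify import SampleMetrics

        for sid, grp in per_sample.groupby("sample_id"):
            sms = [SampleMetrics(**r) for r in grp.to_dict("records")]
            comb_rows.append(asdict(aggregate_combinations(sms)))
    per_combination = pd.DataFrame(comb_rows)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        # shortest float representation that round-trips exactly
        lossless = lambda v: repr(float(v))  # noqa: E731
        per_image.to_csv(out / "per_image.csv", index=False, float_format=lossless)
        per_sample.to_csv(out / "per_sample.csv", index=False, float_format=lossless)
        per_combination.to_csv(out / "per_combination.csv", index=False, float_format=lossless)
        cfg = config.to_dict()
        record = {
            "package": "ihcquant",
            "version": _pkg_version("ihcquant"),
            "config": cfg,
            "config_hash": hashlib.sha256(
                json.dumps(cfg, sort_keys=True).encode()
            ).hexdigest(),
            "manifest_hash": _manifest_hash(manifest),
            "n_images": int(len(per_image)),
            "n_failures": len(failures),
        }
        (out / "run_record.json").write_text(json.dumps(record, indent=2))
        with open(out / "run.log", "w") as fh:
            for f in failures:
                fh.write(f"FAILED {f['sample_id']}/{f['selector']}/{f['analyzer']}"
                         f" image {f['image_id']}: {f['reason']}\n")
            fh.write(f"processed {len(per_image)} images, {len(failures)} failures\n")

    return QuantifyRun(per_image, per_sample, per_combination, failures)


def _pairwise_ccc(wide: pd.DataFrame) -> pd.DataFrame:
    """All pairwise CCCs between observer-combination columns.

    Each pair is labelled by which observer index differs: 'analyzer'
    (same selector), 'selector' (same analyzer), or 'both'.
    """
    combos = list(wide.columns)
    rows = []
    for i, a in enumerate(combos):
        for b in combos[i + 1:]:
            sub = wide[[a, b]].dropna()
            res = concordance_correlation(sub[a], sub[b])
            (sa, aa), (sb, ab) = a, b
            if sa == sb:
                differs = "analyzer"
            elif aa == ab:
                differs = "selector"
            else:
                differs = "both"
            rows.append(
                {"combo_a": f"{sa}-{aa}", "combo_b": f"{sb}-{ab}", "differs": differs,
                 "ccc": res.ccc, "ci_low": res.ci_low, "ci_high": res.ci_high,
                 "category": res.category, "n": res.n}
            )
    return pd.DataFrame(rows)


def run_validation_report(
    dia: pd.DataFrame | str | Path,
    irs: pd.DataFrame | str | Path,
    out_dir: str | Path | None = None,
) -> dict:
    """Validate the digital measurements against the manual score.

    ``dia``: per-sample table (sample_id, selector, analyzer,
    pct_positive, intensity_per_area), as written by :func:`run_quantify`.
    ``irs``: one row per sample with pct_score, intensity_score, irs and
    optionally outcome columns (igf1_xuln, normalized_flag).

    Produces pairwise observer CCC matrices per measure, Spearman
    correlations of DIA intensity/area vs total IRS and DIA %PC vs IRS
    %PC (per combination and for the mean of combinations), and — when an
    outcome column is present — ROC/Youden analyses and the Spearman
    correlation against the biochemical response.
    """
    if not isinstance(dia, pd.DataFrame):
        dia = pd.read_csv(dia, dtype={"sample_id": str}, float_precision="round_trip")
    if not isinstance(irs, pd.DataFrame):
        irs = pd.read_csv(irs, dtype={"sample_id": str}, float_precision="round_trip")
    overlap = set(dia["sample_id"]) & set(irs["sample_id"])
    if not overlap:
        raise ValueError("no overlapping sample_ids between DIA and IRS tables")

    report: dict = {"n_samples": len(overlap)}
    ccc_tables = {}
    spearman_rows = []
    measure_to_irs = {"intensity_per_area": "irs", "pct_positive": "pct_score"}
    for measure, irs_col in measure_to_irs.items():
        wide = dia.pivot_table(
            index="sample_id", columns=["selector", "analyzer"], values=measure
        )
        ccc_tables[measure] = _pairwise_ccc(wide)
        flat = wide.copy()
        flat.columns = [f"{s}-{a}" for s, a in wide.columns]
        combos = list(flat.columns)
        merged = flat.join(irs.set_index("sample_id")[irs_col], how="inner")
        for combo in combos:
            sub = merged[[combo, irs_col]].dropna()
            rho, p = spearman_correlation(sub[combo], sub[irs_col])
            spearman_rows.append(
                {"measure": measure, "combination": combo,
                 "vs": irs_col, "rho": rho, "p_value": p, "n": len(sub)}
            )
        mean_col = merged[combos].mean(axis=1)
        sub = pd.DataFrame({"m": mean_col, "irs": merged[irs_col]}).dropna()
        rho, p = spearman_correlation(sub["m"], sub["irs"])
        spearman_rows.append(
            {"measure": measure, "combination": "mean", "vs": irs_col,
             "rho": rho, "p_value": p, "n": len(sub)}
        )
    report["ccc"] = ccc_tables
    report["spearman"] = pd.DataFrame(spearman_rows)

    if "normalized_flag" in irs.columns:
        merged = (
            dia.pivot_table(index="sample_id", columns=["selector", "analyzer"],
                            values="intensity_per_area")
            .mean(axis=1)
            .rename("dia_intensity")
            .to_frame()
            .join(irs.set_index("sample_id"), how="inner")
            .dropna(subset=["dia_intensity", "normalized_flag"])
        )
        roc_rows = {}
        for name, col in [("dia_intensity_per_area", "dia_intensity"), ("irs", "irs")]:
            if col in merged.columns:
                res = roc_analysis(merged[col], merged["normalized_flag"].astype(int))
                roc_rows[name] = asdict(res)
        report["roc"] = roc_rows
        if "igf1_xuln" in merged.columns:
            rho, p = spearman_correlation(merged["dia_intensity"], merged["igf1_xuln"])
            report["spearman_igf1"] = {"rho": rho, "p_value": p, "n": len(merged)}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for measure, table in ccc_tables.items():
            table.to_csv(out / f"ccc_{measure}.csv", index=False)
        report["spearman"].to_csv(out / "spearman.csv", index=False)
        payload = {k: v for k, v in report.items() if k in {"n_samples", "roc", "spearman_igf1"}}
        (out / "report.json").write_text(json.dumps(payload, indent=2, default=float))
    return report
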