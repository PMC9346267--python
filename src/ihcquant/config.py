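"""Run configuration: stain vectors, segmentation and positivity knobs.

Configuration is a flat TOML file; every parameter has a deterministic
default, and the full resolved configuration is echoed verbatim into a
run-record file next to the outputs so any run can be reproduced.

Example::

    [stains]
    matrix = [0.650, 0.704, 0.286, 0.268, 0.570, 0.776, 0.711, -0.423, 0.561]
    saturation_od = 2.0

    [nuclei]
    sigma = 2.0
    min_area = 40
    max_area = 5000

    [cells]
    expansion_px = 10

    [positivity]
    threshold = 0.15
    min_frac = 0.10
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .segmentation import NucleiParams, PositivityParams
from .stains import SATURATION_OD, StainMatrix

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    stain_matrix: tuple[float, ...] | None = None  # nine floats, row-major
    saturation_od: float = SATURATION_OD
    estimate_white_point: bool = False
    nuclei: NucleiParams = field(default_factory=NucleiParams)
    expansion_px: int = 10
    positivity: PositivityParams = field(default_factory=PositivityParams)
    seed: int = 0

    def stains(self) -> StainMatrix:
        if self.stain_matrix is None:
            return StainMatrix.hdab()
        return StainMatrix.from_flat(self.stain_matrix)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stain_matrix"] = (
            list(self.stain_matrix) if self.stain_matrix is not None
            else [round(float(v), 6) for v in StainMatrix.hdab().rows.ravel()]
        )
        return d


def load_config(path: str | Path | None) -> RunConfig:
    """Load a TOML run configuration; ``None`` yields all defaults."""
    if path is None:
        return RunConfig()
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    stains = raw.get("stains", {})
    nuclei = raw.get("nuclei", {})
    cells = raw.get("cells", {})
    pos = raw.get("positivity", {})
    matrix = stains.get("matrix")
    if matrix is not None and len(matrix) != 9:
        raise ValueError("stains.matrix must hold nine floats, row-major")
    return RunConfig(
        stain_matrix=tuple(matrix) if matrix is not None else None,
        saturation_od=float(stains.get("saturation_od", SATURATION_OD)),
        estimate_white_point=bool(stains.get("estimate_white_point", False)),
        nuclei=NucleiParams(
            sigma=float(nuclei.get("sigma", 2.0)),
            min_area=int(nuclei.get("min_area", 40)),
            max_area=int(nuclei.get("max_area", 5000)),
            h_minima=float(nuclei.get("h_minima", 2.0)),
            min_otsu=float(nuclei.get("min_otsu", 0.05)),
        ),
        expansion_px=int(cells.get("expansion_px", 10)),
        positivity=PositivityParams(
            threshold=float(pos.get("threshold", 0.15)),
            min_frac=float(pos.get("min_frac", 0.10)),
        ),
        seed=int(raw.get("seed", 0)),
    )
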