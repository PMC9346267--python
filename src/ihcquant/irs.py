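"""Semi-quantitative immunoreactivity score (IRS).

The IRS combines two observer-assigned categories: a percentage-of-
positive-cells score (0: no positive cells; 1: <10%; 2: 10-50%;
3: >50-80%; 4: >80%) and a staining-intensity score (0 none, 1 weak,
2 moderate, 3 strong).  The IRS is their product, range 0-12.

The %PC bins as conventionally printed leave the open interval
(50, 51) unassigned; here the bins are closed as [10, 50] -> 2 and
(50, 80] -> 3 so the step function covers all of [0, 100] without a gap.
The intensity score is a human judgment and is always an input, never
derived from pixel values.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["IRSScore", "score_pct", "compute_irs", "irs_from_pct", "score_table"]

#: Every IRS value reachable as a product of the two category scores.
ACHIEVABLE_IRS = frozenset({0, 1, 2, 3, 4, 6, 8, 9, 12})


@dataclass(frozen=True)
class IRSScore:
    pct_score: int
    intensity_score: int
    irs: int


def score_pct(pct_positive: float) -> int:
    """Categorize a percentage of positive cells into the 0-4 IRS bins."""
    pct = float(pct_positive)
    if not 0.0 <= pct <= 100.0:
        raise ValueError(f"percentage must be in [0, 100], got {pct}")
    if pct == 0.0:
        return 0
    if pct < 10.0:
        return 1
    if pct <= 50.0:
        return 2
    if pct <= 80.0:
        return 3
    return 4


def compute_irs(pct_score: int, intensity_score: int) -> IRSScore:
    """IRS = pct_score * intensity_score (range 0-12)."""
    if pct_score not in range(5):
        raise ValueError(f"pct_score must be an integer in 0-4, got {pct_score}")
    if intensity_score not in range(4):
        raise ValueError(
            f"intensity_score must be an integer in 0-3, got {intensity_score}"
        )
    return IRSScore(
        pct_score=int(pct_score),
        intensity_score=int(intensity_score),
        irs=int(pct_score) * int(intensity_score),
    )


def irs_from_pct(pct_positive: float, intensity_score: int) -> IRSScore:
    """Convenience: bin a raw percentage, then form the product score."""
    return compute_irs(score_pct(pct_positive), intensity_score)


def score_table(table: pd.DataFrame) -> pd.DataFrame:
    """Score a table of samples.

    Expects columns ``sample_id``, ``intensity_score`` and either
    ``pct_positive`` (raw percentage, binned here) or ``pct_score``
    (pre-binned category).  Returns sample_id, pct_score, intensity_score
    and irs.
    """
    if "pct_score" in table.columns:
        pct_scores = table["pct_score"].astype(int)
    elif "pct_positive" in table.columns:
        pct_scores = table["pct_positive"].map(score_pct)
    else:
        raise ValueError("table needs a 'pct_positive' or 'pct_score' column")
    scores = [
        compute_irs(p, i) for p, i in zip(pct_scores, table["intensity_score"].astype(int))
    ]
    return pd.DataFrame(
        {
            "sample_id": table["sample_id"].to_numpy(),
            "pct_score": [s.pct_score for s in scores],
            "intensity_score": [s.intensity_score for s in scores],
            "irs": [s.irs for s in scores],
        }
    )
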