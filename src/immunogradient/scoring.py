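"""Binary strata and combined prognostic scores.

The CD8-CD20 Immunogradient score sums the two binary (high = favorable)
Center-of-Mass strata, taking values {0, 1, 2}; the immuno-interface score
(IIS) adds the binary growth-pattern term (pushing margin = favorable),
taking values {0, 1, 2, 3}. Missing inputs propagate to a missing score.
The cutoff boundary convention is strictly-greater: a value exactly at the
cutoff is in the low group.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import VocabularyError

GROWTH_PATTERNS = {"pushing": 1, "infiltrative": 0}


def binarize_indicator(
    value: float, cutoff: float, favorable_high: bool = True
) -> int | None:
    """Map an indicator value to a 0/1 stratum; None/NaN propagates."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    high = value > cutoff
    return int(high if favorable_high else not high)


def growth_pattern_bin(growth_pattern) -> int | None:
    """Pushing margin -> 1 (favorable), infiltrative margin -> 0."""
    if growth_pattern is None or (
        isinstance(growth_pattern, float) and np.isnan(growth_pattern)
    ):
        return None
    norm = str(growth_pattern).strip().lower().removesuffix(" margin")
    if norm not in GROWTH_PATTERNS:
        raise VocabularyError(
            f"unknown growth pattern {growth_pattern!r}; expected pushing/infiltrative"
        )
    return GROWTH_PATTERNS[norm]


@dataclass
class ScoreResult:
    cd8_cm_bin: int | None
    cd20_cm_bin: int | None
    growth_bin: int | None
    cd8cd20_score: int | None
    iis: int | None


def combine_scores(
    cd8_cm_bin: int | None, cd20_cm_bin: int | None, growth_bin: int | None
) -> ScoreResult:
    """Sum the binary strata into the CD8-CD20 score and the IIS."""
    if cd8_cm_bin is None or cd20_cm_bin is None:
        cd8cd20 = None
    else:
        cd8cd20 = cd8_cm_bin + cd20_cm_bin
    if cd8cd20 is None or growth_bin is None:
        iis = None
    else:
        iis = cd8cd20 + growth_bin
    return ScoreResult(cd8_cm_bin, cd20_cm_bin, growth_bin, cd8cd20, iis)


def score_cohort(
    df: pd.DataFrame,
    cd8_cm_cutoff: float,
    cd20_cm_cutoff: float,
    cd8_favorable_high: bool = True,
    cd20_favorable_high: bool = True,
    cutoff_source: str = "in_sample",
) -> pd.DataFrame:
    """Append the binary strata and combined scores to a cohort table.

    ``cutoff_source`` records whether cutoffs were learned on this cohort
    (optimistically biased) or supplied externally; it is written into the
    output for transparency.
    """
    out = df.copy()
    cd8_bins, cd20_bins, growth_bins, s2, s3 = [], [], [], [], []
    for _, row in out.iterrows():
        b8 = binarize_indicator(row["CD8_CM"], cd8_cm_cutoff, cd8_favorable_high)
        b20 = binarize_indicator(row["CD20_CM"], cd20_cm_cutoff, cd20_favorable_high)
        bg = growth_pattern_bin(row["growth_pattern"])
        res = combine_scores(b8, b20, bg)
        cd8_bins.append(res.cd8_cm_bin)
        cd20_bins.append(res.cd20_cm_bin)
        growth_bins.append(res.growth_bin)
        s2.append(res.cd8cd20_score)
        s3.append(res.iis)
    out["cd8_cm_bin"] = pd.array(cd8_bins, dtype="Int64")
    out["cd20_cm_bin"] = pd.array(cd20_bins, dtype="Int64")
    out["growth_bin"] = pd.array(growth_bins, dtype="Int64")
    out["cd8cd20_score"] = pd.array(s2, dtype="Int64")
    out["iis"] = pd.array(s3, dtype="Int64")
    out.attrs["cutoff_source"] = cutoff_source
    return out
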