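"""Neuroplasticity index (NI), NI enhancement, and responder classification.

The NI is the ratio of the serum BDNF concentration (pg/ml) to the same-day
HAMD-24 score; a higher value means more circulating neurotrophic signal per
unit of symptom burden.  NI enhancement over a treatment interval is the
signed difference of NI between the later and the earlier visit.  Treatment
response ("quasi-effective") is a HAMD-24 reduction rate from baseline of at
least 60% within four weeks; the threshold comparison is inclusive and
configurable.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .io import TrialDataset

logger = logging.getLogger(__name__)

DEFAULT_RESPONDER_THRESHOLD = 0.60


def neuroplasticity_index(bdnf: float, hamd24: float) -> float:
    """BDNF (pg/ml) divided by the HAMD-24 score, in pg/ml per scale point.

    A zero HAMD-24 (full remission) leaves the index undefined; NaN is
    returned and the caller treats the visit as missing.  Either input
    missing propagates NaN.  Negative inputs are a domain error.
    """
    if math.isnan(bdnf) or math.isnan(hamd24):
        return float("nan")
    if bdnf < 0 or hamd24 < 0:
        raise ValueError("bdnf and hamd24 must be non-negative")
    if hamd24 == 0:
        logger.info("NI undefined at HAMD-24 = 0; treated as missing")
        return float("nan")
    return bdnf / hamd24


def ni_enhancement(ni_from: float, ni_to: float) -> float:
    """Signed NI change over an interval: later minus earlier (may be negative)."""
    return ni_to - ni_from


def hamd_reduction_rate(hamd_baseline: float, hamd_final: float) -> float:
    """(baseline - final) / baseline; negative when symptoms worsened."""
    if hamd_baseline <= 0:
        raise ValueError("baseline HAMD-24 must be positive")
    return (hamd_baseline - hamd_final) / hamd_baseline


@dataclasses.dataclass
class NISeries:
    """Per-subject NI values by day plus all pairwise enhancements."""

    subject_id: str
    ni_by_day: dict[int, float]
    enhancements: dict[tuple[int, int], float]


def ni_series(dataset: TrialDataset, subject_id: str) -> NISeries:
    """NI at every day where both BDNF and a positive HAMD-24 exist.

    Enhancements are populated for every ordered pair of available days.
    """
    if subject_id not in dataset.subjects:
        raise KeyError(f"unknown subject {subject_id!r}")
    frame = dataset.frame
    rows = frame[frame["subject_id"] == subject_id].sort_values("day")
    ni_by_day: dict[int, float] = {}
    for _, row in rows.iterrows():
        ni = neuroplasticity_index(float(row["bdnf_pg_ml"]), float(row["hamd24"]))
        if not math.isnan(ni):
            ni_by_day[int(row["day"])] = ni
    enhancements = {
        (d1, d2): ni_enhancement(ni_by_day[d1], ni_by_day[d2])
        for d1, d2 in combinations(sorted(ni_by_day), 2)
    }
    return NISeries(subject_id, ni_by_day, enhancements)


def ni_table(dataset: TrialDataset) -> pd.DataFrame:
    """Tidy NI table (subject_id, arm, day, ni) across all patients, vectorised."""
    frame = dataset.frame
    pat = frame[frame["arm"] != "healthy_control"].copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ni = pat["bdnf_pg_ml"].to_numpy() / pat["hamd24"].to_numpy()
    ni[~np.isfinite(ni)] = np.nan
    pat["ni"] = ni
    out = pat.loc[pat["ni"].notna(), ["subject_id", "arm", "day", "ni"]]
    return out.reset_index(drop=True)


@dataclasses.dataclass
class ResponderLabel:
    subject_id: str
    reduction_rate: float
    responder: bool


def classify_responders(
    dataset: TrialDataset,
    baseline_day: int = 0,
    final_day: int = 28,
    threshold: float = DEFAULT_RESPONDER_THRESHOLD,
) -> list[ResponderLabel]:
    """Label each subject with HAMD-24 on both days as responder / non-responder.

    ``responder`` is ``reduction_rate >= threshold`` (inclusive boundary).
    Subjects missing either visit receive no label and are logged.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    labels: list[ResponderLabel] = []
    for sid in dataset.patients().subjects:
        h0 = dataset.value(sid, baseline_day, "hamd24")
        h1 = dataset.value(sid, final_day, "hamd24")
        if math.isnan(h0) or math.isnan(h1):
            logger.info("subject %s missing HAMD-24 on day %d or %d; no responder label",
                        sid, baseline_day, final_day)
            continue
        rate = hamd_reduction_rate(h0, h1)
        labels.append(ResponderLabel(sid, rate, rate >= threshold))
    return labels


def responders_to_frame(labels: Sequence[ResponderLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"subject_id": l.subject_id, "reduction_rate": l.reduction_rate,
             "responder": l.responder}
            for l in labels
        ],
        columns=["subject_id", "reduction_rate", "responder"],
    )
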