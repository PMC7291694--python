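"""Questionnaire scoring, clinical thresholds, and reliable-change classification.

Built-in definitions cover the PHQ-9 (9 items, 0–3 each, clinical threshold 10)
and the GAD-7 (7 items, 0–3 each, threshold 10).  "Reliable and clinically
significant change" means a drop of at least the reliable-change magnitude
(5 points for both instruments) ending below the clinical threshold at the
last observed assessment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ScaleDefinition",
    "ChangeStatus",
    "PHQ9",
    "GAD7",
    "score_scale",
    "meets_clinical_threshold",
    "classify_change",
    "classify_change_panel",
    "load_scale",
]


@dataclass(frozen=True)
class ScaleDefinition:
    """A total-score questionnaire with a clinical cut-off.

    Parameters
    ----------
    name : str
        Instrument name, e.g. ``"PHQ-9"``.
    n_items : int
        Number of items summed into the total.
    item_min, item_max : int
        Per-item response range (inclusive).
    clinical_threshold : int
        Total score at or above which symptoms are considered clinically
        significant (at least moderate severity).
    reliable_change : int
        Minimum total-score drop counted as reliable improvement.
    """

    name: str
    n_items: int
    item_min: int
    item_max: int
    clinical_threshold: int
    reliable_change: int

    def __post_init__(self) -> None:
        if self.n_items < 1:
            raise ValueError("n_items must be >= 1")
        if self.item_min > self.item_max:
            raise ValueError("item_min must not exceed item_max")
        if not (self.total_min <= self.clinical_threshold <= self.total_max):
            raise ValueError(
                f"clinical_threshold {self.clinical_threshold} outside total "
                f"score range [{self.total_min}, {self.total_max}]"
            )
        if self.reliable_change <= 0:
            raise ValueError("reliable_change must be positive")

    @property
    def total_min(self) -> int:
        return self.n_items * self.item_min

    @property
    def total_max(self) -> int:
        return self.n_items * self.item_max

    def validate_total(self, total: float, what: str = "total") -> None:
        if not (self.total_min <= total <= self.total_max):
            raise ValueError(
                f"{what} {total} outside {self.name} range "
                f"[{self.total_min}, {self.total_max}]"
            )


@dataclass(frozen=True)
class ChangeStatus:
    """Outcome of the reliable / clinically significant change rule."""

    improved: bool
    delta: float
    below_threshold_at_last: bool


# The PHQ-9 arithmetic maximum is 27 (9 items scored 0-3).
PHQ9 = ScaleDefinition("PHQ-9", n_items=9, item_min=0, item_max=3,
                       clinical_threshold=10, reliable_change=5)
GAD7 = ScaleDefinition("GAD-7", n_items=7, item_min=0, item_max=3,
                       clinical_threshold=10, reliable_change=5)


def score_scale(item_responses: Sequence[int], scale: ScaleDefinition) -> int:
    """Sum item responses into a total score.

    Raises ``ValueError`` naming the offending item for a wrong item count
    or an out-of-range response.
    """
    responses = list(item_responses)
    if len(responses) != scale.n_items:
        raise ValueError(
            f"{scale.name} expects {scale.n_items} items, got {len(responses)}"
        )
    for i, r in enumerate(responses):
        if not (scale.item_min <= r <= scale.item_max):
            raise ValueError(
                f"{scale.name} item {i + 1} response {r} outside "
                f"[{scale.item_min}, {scale.item_max}]"
            )
    return int(sum(responses))


def meets_clinical_threshold(total: float, scale: ScaleDefinition) -> bool:
    """True iff ``total`` is at or above the scale's clinical threshold."""
    scale.validate_total(total)
    return total >= scale.clinical_threshold


def classify_change(baseline: float, last_observed: float,
                    scale: ScaleDefinition) -> ChangeStatus:
    """Classify reliable and clinically significant change.

    Improvement requires a drop of at least ``scale.reliable_change`` points
    AND a last observed total strictly below the clinical threshold.
    """
    scale.validate_total(baseline, "baseline")
    scale.validate_total(last_observed, "last_observed")
    delta = last_observed - baseline
    below = last_observed < scale.clinical_threshold
    improved = (delta <= -scale.reliable_change) and below
    return ChangeStatus(improved=improved, delta=delta,
                        below_threshold_at_last=below)


def classify_change_panel(visits: pd.DataFrame, column: str,
                          scale: ScaleDefinition,
                          id_col: str = "subject_id",
                          week_col: str = "week") -> pd.DataFrame:
    """Per-subject change classification from a long-format visit table.

    The comparison is baseline (earliest observed week) versus the last
    non-missing observation of ``column`` for each subject.

    Returns a frame indexed by subject with ``baseline``, ``last_observed``,
    ``delta``, ``below_threshold_at_last`` and ``improved`` columns.
    """
    obs = visits.dropna(subset=[column]).sort_values(week_col)
    if obs.empty:
        raise ValueError(f"no observed values in column {column!r}")
    grouped = obs.groupby(id_col)[column]
    first = grouped.first()
    last = grouped.last()
    rows = {
        sid: classify_change(first[sid], last[sid], scale)
        for sid in first.index
    }
    out = pd.DataFrame(
        {
            "baseline": first,
            "last_observed": last,
            "delta": [rows[s].delta for s in first.index],
            "below_threshold_at_last": [rows[s].below_threshold_at_last
                                        for s in first.index],
            "improved": [rows[s].improved for s in first.index],
        }
    )
    out.index.name = id_col
    return out


def load_scale(path) -> ScaleDefinition:
    """Load a ScaleDefinition from a YAML config file.

    Expected keys: name, n_items, item_min, item_max, clinical_threshold,
    reliable_change.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    required = {"name", "n_items", "item_min", "item_max",
                "clinical_threshold", "reliable_change"}
    missing = required - set(raw)
    if missing:
        raise ValueError(f"scale config missing keys: {sorted(missing)}")
    return ScaleDefinition(
        name=str(raw["name"]),
        n_items=int(raw["n_items"]),
        item_min=int(raw["item_min"]),
        item_max=int(raw["item_max"]),
        clinical_threshold=int(raw["clinical_threshold"]),
        reliable_change=int(raw["reliable_change"]),
    )
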