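"""UPDRS-III motor subscores and motor-subtype classification.

Akinetic-rigid (AR) severity is the sum of the ratings (each 0-4) on
rigidity of five body parts, finger tapping and hand movements and rapid
alternating movements and leg agility (each for both sides), arising from
chair, and body bradykinesia - 15 items.  Tremor severity sums rest tremor
of the face and of both arms and legs plus action/postural tremor of both
arms - 7 items.  Higher scores mean greater severity.

Patients are classified into akinetic-rigid-dominant (ARD) and
tremor-dominant (TD) subtypes by the ratio of mean tremor item score to
mean AR item score: ARD if ratio < 0.8, TD if ratio > 1, otherwise mixed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

AR_ITEMS: tuple[str, ...] = (
    "rigidity_neck",
    "rigidity_rue",
    "rigidity_lue",
    "rigidity_rle",
    "rigidity_lle",
    "finger_tapping_r",
    "finger_tapping_l",
    "hand_movements_r",
    "hand_movements_l",
    "rapid_alternating_r",
    "rapid_alternating_l",
    "leg_agility_r",
    "leg_agility_l",
    "arising_from_chair",
    "body_bradykinesia",
)

TREMOR_ITEMS: tuple[str, ...] = (
    "rest_tremor_face",
    "rest_tremor_rue",
    "rest_tremor_lue",
    "rest_tremor_rle",
    "rest_tremor_lle",
    "action_tremor_r",
    "action_tremor_l",
)


def updrs_subscores(
    items: Mapping[str, int],
    ar_items: Sequence[str] = AR_ITEMS,
    tremor_items: Sequence[str] = TREMOR_ITEMS,
) -> tuple[int, int]:
    """(AR score, tremor score) as sums over the configured item lists.

    Raises
    ------
    ValueError
        If a listed item is missing, out of the 0-4 range, or the item
        lists overlap.
    """
    if set(ar_items) & set(tremor_items):
        raise ValueError("AR and tremor item lists must be disjoint")
    totals = []
    for label, wanted in (("AR", ar_items), ("tremor", tremor_items)):
        total = 0
        for item in wanted:
            if item not in items:
                raise ValueError(f"missing {label} item: {item!r}")
            v = int(items[item])
            if not 0 <= v <= 4:
                raise ValueError(f"item {item!r} = {v} outside 0..4")
            total += v
        totals.append(total)
    return totals[0], totals[1]


@dataclass(frozen=True)
class SubtypeLabel:
    label: str  # "ARD" | "TD" | "mixed"
    ratio: float  # mean tremor item score / mean AR item score


def classify_subtype(
    score_tremor: float,
    score_ar: float,
    n_tremor_items: int = len(TREMOR_ITEMS),
    n_ar_items: int = len(AR_ITEMS),
    ard_cutoff: float = 0.8,
    td_cutoff: float = 1.0,
) -> SubtypeLabel:
    """Classify a patient as ARD (ratio < 0.8), TD (ratio > 1), or mixed.

    A zero AR score with a positive tremor score maps to TD (ratio +inf);
    both zero maps to mixed (ratio nan).
    """
    if n_tremor_items <= 0 or n_ar_items <= 0:
        raise ValueError("item counts must be positive")
    if score_tremor < 0 or score_ar < 0:
        raise ValueError("scores must be nonnegative")
    mean_ar = score_ar / n_ar_items
    mean_tremor = score_tremor / n_tremor_items
    if mean_ar == 0:
        if mean_tremor > 0:
            return SubtypeLabel("TD", float("inf"))
        return SubtypeLabel("mixed", float("nan"))
    ratio = mean_tremor / mean_ar
    if ratio < ard_cutoff:
        return SubtypeLabel("ARD", ratio)
    if ratio > td_cutoff:
        return SubtypeLabel("TD", ratio)
    return SubtypeLabel("mixed", ratio)


def classify_cohort(score_tremor: np.ndarray, score_ar: np.ndarray, **kwargs) -> list[str]:
    """Vectorized subtype labels for a cohort."""
    return [
        classify_subtype(t, a, **kwargs).label
        for t, a in zip(np.asarray(score_tremor), np.asarray(score_ar))
    ]
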