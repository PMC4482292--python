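"""Ranking, plateau detection and plateau composition statistics.

Sorting all fitted candidates by a criterion gives an *error profile*.  Its
initial run of mutually indistinguishable models — the *plateau* — ends at
the first pair of consecutive profile values differing by more than 10 %
relative to the earlier (smaller) value.  Short plateaus mean the criterion
discriminates well between candidate structures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .criteria import ScoreCard
from .errors import CriterionError
from .model_space import SLOTS, ModelStructure

__all__ = [
    "ErrorProfile",
    "rank_models",
    "plateau_length",
    "group_stats",
    "component_frequencies",
    "PLATEAU_THRESHOLD",
]

#: relative jump between consecutive profile values that ends the plateau
PLATEAU_THRESHOLD = 0.10

GROUP_LABELS = ("COT", "IP", "NOBS", "OTHER")


def plateau_length(values: Sequence[float], threshold: float = PLATEAU_THRESHOLD) -> int:
    """Number of models in the initial plateau of a sorted profile.

    The plateau ends before the first index ``i`` with
    ``(v[i+1] - v[i]) / v[i] > threshold``; a zero value followed by a
    positive one also ends it.  Without such a jump the plateau is the whole
    profile.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) == 0:
        raise CriterionError("profile must be a non-empty 1-D sequence")
    for i in range(len(values) - 1):
        v, w = values[i], values[i + 1]
        if v == 0:
            if w > 0:
                return i + 1
        elif w - v > threshold * v:  # (w - v)/v > threshold, overflow-safe
            return i + 1
    return len(values)


@dataclass(frozen=True)
class ErrorProfile:
    """Models sorted ascending by one criterion, with the detected plateau."""

    structures: tuple[ModelStructure, ...]
    values: np.ndarray
    score_cards: tuple[ScoreCard, ...]
    criterion: str
    alpha: float
    beta: float

    @property
    def plateau(self) -> int:
        return plateau_length(self.values)

    @property
    def plateau_structures(self) -> tuple[ModelStructure, ...]:
        return self.structures[: self.plateau]

    def to_frame(self, annotation: Mapping[int, str] | None = None) -> pd.DataFrame:
        """Ranking table: rank, structure, slot choices, scores, plateau flag."""
        plateau = self.plateau
        rows = []
        for rank, (s, v, card) in enumerate(
            zip(self.structures, self.values, self.score_cards), start=1
        ):
            row = {
                "rank": rank,
                "structure_id": s.index,
                "label": s.label,
                **{slot: s.slot_choice_name(slot) for slot in SLOTS},
                "C": card.C,
                "E": card.E,
                "R": card.R,
                "X": card.X,
                self.criterion: v,
                "in_plateau": rank <= plateau,
            }
            if annotation is not None:
                row["group"] = annotation.get(s.index, "OTHER")
            rows.append(row)
        return pd.DataFrame(rows)


def rank_models(
    scored: Sequence[tuple[ModelStructure, ScoreCard]],
    criterion: str,
) -> ErrorProfile:
    """Stable ascending sort by criterion value, ties broken by canonical index."""
    if len(scored) == 0:
        raise CriterionError("no models to rank")
    missing = [s.label for s, card in scored if card is None]
    if missing:
        raise CriterionError(f"models without scores: {', '.join(missing)}")
    values = [card.value(criterion) for _, card in scored]
    order = sorted(range(len(scored)), key=lambda i: (values[i], scored[i][0].index))
    alpha = scored[0][1].alpha
    beta = scored[0][1].beta
    return ErrorProfile(
        structures=tuple(scored[i][0] for i in order),
        values=np.array([values[i] for i in order]),
        score_cards=tuple(scored[i][1] for i in order),
        criterion=criterion,
        alpha=alpha,
        beta=beta,
    )


def group_stats(
    profile: ErrorProfile, annotation: Mapping[int, str]
) -> dict[str, dict[str, float | int | None]]:
    """Count and mean 1-based rank of each group label inside the plateau.

    ``annotation`` maps canonical structure index to a group label (COT, IP,
    NOBS, OTHER).  Labels with no plateau members report count 0 and a mean
    rank of ``None``.
    """
    plateau = profile.plateau
    unlabeled = [s.label for s in profile.structures if s.index not in annotation]
    if unlabeled:
        raise CriterionError(f"unlabeled models: {', '.join(unlabeled)}")
    ranks: dict[str, list[int]] = {}
    for rank, s in enumerate(profile.structures[:plateau], start=1):
        ranks.setdefault(annotation[s.index], []).append(rank)
    labels = list(GROUP_LABELS) + sorted(set(ranks) - set(GROUP_LABELS))
    return {
        label: {
            "count": len(ranks.get(label, [])),
            "mean_rank": float(np.mean(ranks[label])) if label in ranks else None,
        }
        for label in labels
    }


def component_frequencies(structures: Sequence[ModelStructure]) -> pd.DataFrame:
    """Per-slot counts of chosen alternatives among a set of structures."""
    if len(structures) == 0:
        raise CriterionError("component frequencies need at least one structure")
    rows = []
    library = structures[0].library
    for slot in SLOTS:
        for alt in library.slots[slot]:
            count = sum(1 for s in structures if s.slot_choice_name(slot) == alt.name)
            rows.append({"slot": slot, "alternative": alt.name, "count": count})
    return pd.DataFrame(rows)
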