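"""Wintering-area state sequences and transition probabilities.

Each animal contributes an ordered sequence of wintering-area states (one
per analysis-year); fidelity is summarized by the row-stochastic matrix of
transition probabilities between consecutive years. Sequences are built at
two scales: coarse (Coastal vs Brooks) and fine (the four wintering areas).
Only strictly consecutive analysis-years form a transition; animals with a
single year of data contribute nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .winter import FINE_LABELS, REGION_MAP, WinterAssignment

__all__ = [
    "StateSequence",
    "TransitionMatrix",
    "build_sequences",
    "transition_matrix",
    "COARSE_LABELS",
]

COARSE_LABELS = ("Coastal", "Brooks")


@dataclass
class StateSequence:
    """Ordered (analysis-year, state) pairs for one animal at one scale."""

    animal_id: str
    years: list[int]
    states: list[str]
    scale: str  # coarse | fine

    def __post_init__(self) -> None:
        if list(self.years) != sorted(set(self.years)):
            raise ValueError("years must be strictly increasing")
        alphabet = COARSE_LABELS if self.scale == "coarse" else FINE_LABELS
        bad = set(self.states) - set(alphabet)
        if bad:
            raise ValueError(f"states {bad} not in the {self.scale} alphabet")

    def transitions(self, consecutive_only: bool = True) -> list[tuple[str, str]]:
        out = []
        for (y0, s0), (y1, s1) in zip(
            zip(self.years, self.states), zip(self.years[1:], self.states[1:])
        ):
            if not consecutive_only or y1 == y0 + 1:
                out.append((s0, s1))
        return out


@dataclass
class TransitionMatrix:
    """Counts and row-normalized probabilities of state transitions."""

    states: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.states), len(self.states)):
            raise ValueError("counts must be square over the state alphabet")

    @property
    def n_transitions(self) -> int:
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def probs(self) -> np.ndarray:
        """Row-stochastic probabilities; NaN rows where no transitions start."""
        rt = self.row_totals.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = self.counts / rt[:, None]
        p[rt == 0] = np.nan
        return p

    def to_frame(self, decimals: int | None = 2) -> pd.DataFrame:
        """Report table in the conventional shape: 2-dp probabilities with
        row/column sample sizes in the labels."""
        p = self.probs
        if decimals is not None:
            p = np.round(p, decimals)
        idx = [f"{s} (n = {n})" for s, n in zip(self.states, self.row_totals)]
        cols = [f"{s} (n = {n})" for s, n in zip(self.states, self.col_totals)]
        return pd.DataFrame(p, index=idx, columns=cols)


def build_sequences(
    assignments: list[WinterAssignment], scale: str = "fine"
) -> list[StateSequence]:
    """Per-animal state sequences; single-year animals are excluded."""
    if scale not in ("coarse", "fine"):
        raise ValueError("scale must be 'coarse' or 'fine'")
    by_animal: dict[str, list[WinterAssignment]] = {}
    for a in assignments:
        by_animal.setdefault(a.animal_id, []).append(a)
    out = []
    for animal_id in sorted(by_animal):
        rows = sorted(by_animal[animal_id], key=lambda a: a.year)
        if len(rows) < 2:
            continue
        states = [a.coarse_label if scale == "coarse" else a.fine_label
                  for a in rows]
        out.append(StateSequence(
            animal_id=animal_id, years=[a.year for a in rows],
            states=states, scale=scale,
        ))
    return out


def transition_matrix(
    sequences: list[StateSequence],
    scale: str | None = None,
    consecutive_only: bool = True,
) -> TransitionMatrix:
    """Tally transitions between consecutive analysis-years.

    ``consecutive_only=False`` instead pairs each year with the animal's
    next observed year regardless of gaps.
    """
    if not sequences:
        raise ValueError("no sequences provided")
    scale = scale or sequences[0].scale
    states = COARSE_LABELS if scale == "coarse" else FINE_LABELS
    index = {s: i for i, s in enumerate(states)}
    counts = np.zeros((len(states), len(states)), dtype=int)
    for seq in sequences:
        if seq.scale != scale:
            raise ValueError("mixed-scale sequences")
        for s0, s1 in seq.transitions(consecutive_only=consecutive_only):
            counts[index[s0], index[s1]] += 1
    if counts.sum() == 0:
        raise ValueError("zero transitions")
    return TransitionMatrix(states=tuple(states), counts=counts)
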