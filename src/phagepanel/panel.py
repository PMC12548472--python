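"""Greedy discriminatory host-panel selection.

Given a binary phage x strain infection matrix, the goal is a small panel
of strains whose restricted infection patterns distinguish as many phages
as possible. The objective is the number of distinct phage row-vectors
restricted to the chosen strains; strains are added greedily by marginal
gain until no strain adds a new pattern (or a panel-size cap is hit).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import InfectionMatrix

__all__ = ["PanelSelectionResult", "pattern_count", "greedy_panel"]


@dataclass
class PanelSelectionResult:
    """Ordered greedy picks with per-step marginal and cumulative pattern counts."""

    strain_ids: list[str]
    gains: list[int]
    cumulative: list[int]

    def __post_init__(self) -> None:
        if not (len(self.strain_ids) == len(self.gains) == len(self.cumulative)):
            raise ValueError("per-step lists must have equal length")
        prev = 1  # empty panel leaves all phages indistinguishable
        for gain, cum in zip(self.gains, self.cumulative):
            if cum != prev + gain:
                raise ValueError("cumulative counts inconsistent with gains")
            if gain < 0:
                raise ValueError("gains must be nonnegative")
            prev = cum

    @property
    def n_patterns(self) -> int:
        return self.cumulative[-1] if self.cumulative else 1


def pattern_count(matrix: InfectionMatrix, strains: Sequence[str]) -> int:
    """Number of distinct phage infection patterns restricted to ``strains``.

    The empty panel yields 1: all phages are indistinguishable.
    """
    idx = []
    for s in strains:
        if s not in matrix.strain_ids:
            raise ValueError(f"unknown strain id: {s!r}")
        idx.append(matrix.strain_ids.index(s))
    sub = matrix.values[:, idx]
    if sub.shape[0] == 0:
        return 0
    return np.unique(sub, axis=0).shape[0]


def greedy_panel(matrix: InfectionMatrix, max_strains: int | None = None) -> PanelSelectionResult:
    """Greedily pick strains maximizing the marginal gain in distinct patterns.

    Ties are broken by input column order; selection stops when every
    remaining strain has zero gain, or after ``max_strains`` picks.
    """
    if matrix.values.shape[0] == 0 or matrix.values.shape[1] == 0:
        raise ValueError("infection matrix must be nonempty")
    if max_strains is not None and max_strains < 1:
        raise ValueError("max_strains must be >= 1")

    selected: list[str] = []
    gains: list[int] = []
    cumulative: list[int] = []
    current = 1
    remaining = list(matrix.strain_ids)

    while remaining:
        if max_strains is not None and len(selected) >= max_strains:
            break
        best_strain, best_gain = None, 0
        for s in remaining:  # input column order -> deterministic tie-break
            gain = pattern_count(matrix, selected + [s]) - current
            if gain > best_gain:
                best_strain, best_gain = s, gain
        if best_strain is None:
            break
        selected.append(best_strain)
        remaining.remove(best_strain)
        current += best_gain
        gains.append(best_gain)
        cumulative.append(current)

    return PanelSelectionResult(selected, gains, cumulative)
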