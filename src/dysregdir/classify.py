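"""Threshold classification of adjusted one-sided p-values and the
five-color taxonomy over (overall, level-0, level-1) outcome triples.

Classification labels: ``Down`` (p < alpha/2), ``Up`` (p > 1 - alpha/2),
``NS`` (strictly inside the (band/2, 1 - band/2) band), ``INC``
(inconclusive: between a significance threshold and the band, boundary
values included), and ``NT`` (not tested: the minimum-n rule failed or all
differences were zero).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "Label",
    "Color",
    "Thresholds",
    "ColorCrosstab",
    "classify_outcome",
    "color_for",
    "crosstab_colors",
]


class Label(str, enum.Enum):
    DOWN = "Down"
    NS = "NS"
    UP = "Up"
    INC = "INC"
    NT = "NT"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Color(str, enum.Enum):
    BLUE = "blue"
    GREEN = "green"
    ORANGE = "orange"
    PURPLE = "purple"
    YELLOW = "yellow"
    NONE = "none"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class Thresholds:
    """Significance level and no-significance band for classification."""

    alpha: float = 0.05
    band: float = 0.15

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < self.band < 1.0):
            raise ValueError("thresholds must satisfy 0 < alpha < band < 1")


def classify_outcome(p_one_adj: float, thresholds: Thresholds = Thresholds()) -> Label:
    """Classify an adjusted one-sided p-value into Down / NS / Up / INC.

    Boundary values (exactly alpha/2, band/2, or their upper mirrors) are
    conservatively assigned INC.
    """
    p = float(p_one_adj)
    if not (0.0 <= p <= 1.0) or not np.isfinite(p):
        raise ValueError(f"p-value {p} outside [0, 1]")
    a2 = thresholds.alpha / 2.0
    b2 = thresholds.band / 2.0
    if p < a2:
        return Label.DOWN
    if p > 1.0 - a2:
        return Label.UP
    if b2 < p < 1.0 - b2:
        return Label.NS
    return Label.INC


_SIG = {Label.DOWN, Label.UP}
_OPP = {Label.DOWN: Label.UP, Label.UP: Label.DOWN}


def color_for(overall: Label, level0: Label, level1: Label) -> Color:
    """Color category of a fully-tested (overall, level-0, level-1) triple.

    Any INC or NT in the triple maps to ``none``, as do all-equal triples
    and overall-significant triples with one NS and one opposite level.
    The mapping is symmetric in (level0, level1).
    """
    triple = (overall, level0, level1)
    if any(t not in (Label.DOWN, Label.NS, Label.UP) for t in triple):
        return Color.NONE
    levels = (level0, level1)
    if overall in _SIG:
        n_match = sum(lv == overall for lv in levels)
        n_opp = sum(lv == _OPP[overall] for lv in levels)
        n_ns = sum(lv == Label.NS for lv in levels)
        if n_match == 1 and n_ns == 1:
            return Color.BLUE
        if n_match == 1 and n_opp == 1:
            return Color.YELLOW
    else:  # overall NS
        n_sig = sum(lv in _SIG for lv in levels)
        n_ns = sum(lv == Label.NS for lv in levels)
        if n_sig == 1 and n_ns == 1:
            return Color.GREEN
        if set(levels) == _SIG:
            return Color.ORANGE
    if level0 == level1 and level0 != overall:
        return Color.PURPLE
    return Color.NONE


_CELL_LABELS = (Label.DOWN, Label.NS, Label.UP)


@dataclass
class ColorCrosstab:
    """27-cell cross-tab of (level0, level1) x overall outcome counts.

    Rows are (level0, level1) pairs, columns the overall label; each cell
    is annotated with its color category.  Triples containing INC or NT are
    excluded from the counts.
    """

    counts: pd.DataFrame  # 9 x 3, MultiIndex rows (level0, level1)
    colors: pd.DataFrame  # same shape, Color values

    def color_totals(self) -> dict[Color, int]:
        totals = {c: 0 for c in Color}
        for row in self.counts.index:
            for col in self.counts.columns:
                totals[self.colors.loc[row, col]] += int(self.counts.loc[row, col])
        return totals

    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.copy().astype(object)
        for row in out.index:
            for col in out.columns:
                color = self.colors.loc[row, col]
                tag = "" if color is Color.NONE else f" [{color.value}]"
                out.loc[row, col] = f"{int(self.counts.loc[row, col])}{tag}"
        out.index.names = ["level0", "level1"]
        return out

    def write(self, path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep)


def crosstab_colors(records: Iterable[tuple[Label, Label, Label]]) -> ColorCrosstab:
    """Cross-tabulate (overall, level0, level1) label triples with colors.

    Only triples entirely within {Down, NS, Up} are counted.
    """
    index = pd.MultiIndex.from_product(
        [[l.value for l in _CELL_LABELS]] * 2, names=["level0", "level1"]
    )
    columns = [l.value for l in _CELL_LABELS]
    counts = pd.DataFrame(0, index=index, columns=columns)
    colors = pd.DataFrame(Color.NONE, index=index, columns=columns, dtype=object)
    for l0 in _CELL_LABELS:
        for l1 in _CELL_LABELS:
            for ov in _CELL_LABELS:
                colors.loc[(l0.value, l1.value), ov.value] = color_for(ov, l0, l1)
    for overall, level0, level1 in records:
        if all(t in _CELL_LABELS for t in (overall, level0, level1)):
            counts.loc[(level0.value, level1.value), overall.value] += 1
    return ColorCrosstab(counts=counts, colors=colors)
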