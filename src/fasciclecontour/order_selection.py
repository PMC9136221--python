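"""Model-order selection for the Fourier contour model.

Higher orders always describe a contour at least as well but add four
parameters each; the working rule is minimal complexity under accuracy
constraints: choose the smallest order whose population mean Dice is at
least 95% and whose mean relative Hausdorff error is at most 5%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .fourier_efd import efd_fit
from .metrics import DICE_MIN, HE_MAX, evaluate

__all__ = ["OrderTable", "SelectionResult", "evaluate_orders", "select_order"]


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of the minimal-order rule.

    ``order`` is None when no order in the table qualifies; ``best_row``
    then carries the closest row (highest Dice) for diagnostics.
    """

    order: int | None
    dice_min: float
    he_max: float
    best_row: pd.Series | None = None

    @property
    def qualified(self) -> bool:
        return self.order is not None


class OrderTable(pd.DataFrame):
    """Per-order metric table: index ``order`` (contiguous from 1),
    columns mean_dice (%), mean_H (pixels), mean_HE (%)."""

    _metadata: list = []

    @property
    def _constructor(self):
        return OrderTable

    @classmethod
    def from_rows(cls, mean_dice: Sequence[float], mean_H: Sequence[float],
                  mean_HE: Sequence[float]) -> "OrderTable":
        k = len(mean_dice)
        if not (len(mean_H) == len(mean_HE) == k):
            raise ValueError("metric columns must have equal length")
        df = cls({"mean_dice": np.asarray(mean_dice, dtype=float),
                  "mean_H": np.asarray(mean_H, dtype=float),
                  "mean_HE": np.asarray(mean_HE, dtype=float)},
                 index=pd.RangeIndex(1, k + 1, name="order"))
        return df


def evaluate_orders(contours: Sequence[np.ndarray], k_max: int,
                    n_recon: int | None = None) -> OrderTable:
    """Fit every contour at every order 1..k_max and average the metrics.

    Aggregation is the arithmetic mean over contours of per-contour Dice,
    H and H_E.
    """
    contours = list(contours)
    if not contours:
        raise ValueError("contour set is empty")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    rows = np.zeros((k_max, 3))
    for c in contours:
        for k in range(1, k_max + 1):
            rep = evaluate(c, efd_fit(c, k), n_recon=n_recon)
            rows[k - 1] += (rep.dice, rep.hausdorff, rep.h_e)
    rows /= len(contours)
    return OrderTable.from_rows(rows[:, 0], rows[:, 1], rows[:, 2])


def select_order(table: OrderTable, dice_min: float = DICE_MIN,
                 he_max: float = HE_MAX) -> SelectionResult:
    """Smallest order with mean Dice >= dice_min and mean H_E <= he_max."""
    ok = (table["mean_dice"] >= dice_min) & (table["mean_HE"] <= he_max)
    if ok.any():
        return SelectionResult(order=int(ok.idxmax()), dice_min=dice_min, he_max=he_max)
    best = table.loc[table["mean_dice"].idxmax()]
    return SelectionResult(order=None, dice_min=dice_min, he_max=he_max, best_row=best)
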