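"""Internal-consistency reliability (Cronbach's alpha) for the instrument."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import DEFAULT_SPEC, ITEM_COLUMNS, HBMModelSpec


@dataclass(frozen=True)
class ReliabilityReport:
    """Per-subscale and whole-scale Cronbach's alpha.

    ``alpha_mean_subscales`` averages the five subscale alphas; it is
    reported alongside ``alpha_total`` because "average reliability" of a
    multi-part questionnaire is read both ways in practice.
    """

    alpha_by_factor: dict[str, float]
    alpha_total: float
    alpha_mean_subscales: float
    n_used_by_factor: dict[str, int]
    n_used_total: int
    k_by_factor: dict[str, int]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha of a set of items.

    alpha = k/(k-1) * (1 - sum_i var(item_i) / var(total)), with sample
    variances (denominator n-1) computed after listwise deletion.  Alpha is
    invariant to positive per-item linear rescaling and can be negative for
    mutually uncorrelated or inconsistently keyed items.
    """
    arr = np.asarray(pd.DataFrame(item_matrix).dropna(), dtype=float)
    n, k = arr.shape
    if k < 2:
        raise ValueError("alpha requires at least 2 items")
    if n < 3:
        raise ValueError("alpha requires at least 3 complete rows")
    total_var = float(np.var(arr.sum(axis=1), ddof=1))
    if total_var == 0.0:
        raise ValueError("zero total-score variance")
    item_vars = np.var(arr, axis=0, ddof=1)
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def reliability_report(
    table: pd.DataFrame, spec: HBMModelSpec = DEFAULT_SPEC
) -> ReliabilityReport:
    """Alpha per subscale and for all items, with listwise deletion per scale.

    Barrier items enter on their raw 1-5 keying; alpha is unchanged by any
    consistent within-scale sign convention.
    """
    items = list(ITEM_COLUMNS[: spec.n_items])
    alpha_by_factor: dict[str, float] = {}
    n_by_factor: dict[str, int] = {}
    k_by_factor: dict[str, int] = {}
    for f in spec.factors:
        cols = [items[i] for i in spec.items_of(f)]
        sub = table[cols].dropna()
        alpha_by_factor[f] = cronbach_alpha(sub)
        n_by_factor[f] = len(sub)
        k_by_factor[f] = len(cols)
    full = table[items].dropna()
    return ReliabilityReport(
        alpha_by_factor=alpha_by_factor,
        alpha_total=cronbach_alpha(full),
        alpha_mean_subscales=float(np.mean(list(alpha_by_factor.values()))),
        n_used_by_factor=n_by_factor,
        n_used_total=len(full),
        k_by_factor=k_by_factor,
    )
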