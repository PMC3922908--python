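"""Health-belief scale scores and pre/post cohort comparison.

Two scoring rules are implemented:

* **CFA-weighted score (CFAWS)**: WHBS = sum_n W_n * IS_n, where IS_n is
  the raw 1-5 item score and W_n the item's standardized total effect from
  the fitted second-order CFA.  Barrier items carry negative weights, so
  the raw scores are used for every item and the sign lives in W.
* **Simple sum score (SSS)**: HBS = sum of raw scores over the positively
  keyed subscales minus the sum over the barrier items.

Cohorts are compared with a two-independent-sample t-test (pooled-variance
by default, Welch optional) on listwise-complete respondents.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import DEFAULT_SPEC, ITEM_COLUMNS, HBMModelSpec


@dataclass(frozen=True)
class ScoreComparison:
    """Two-sample comparison of post vs pre health-belief scores."""

    method: str                   # "cfaws" or "sss"
    n_pre: int
    n_post: int
    mean_pre: float
    mean_post: float
    sd_pre: float
    sd_post: float
    mean_difference: float        # post - pre
    ci_lower: float
    ci_upper: float
    t_statistic: float
    df: float
    p_value: float
    ttest: str                    # "pooled" or "welch"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def listwise_delete(table: pd.DataFrame, spec: HBMModelSpec = DEFAULT_SPEC) -> pd.DataFrame:
    """Drop respondents with any missing item score; row order preserved."""
    items = [c for c in table.columns if c in ITEM_COLUMNS[: spec.n_items]]
    return table.dropna(subset=items)


def _item_array(rows, spec: HBMModelSpec) -> np.ndarray:
    if isinstance(rows, pd.DataFrame):
        arr = rows[list(ITEM_COLUMNS[: spec.n_items])].to_numpy(dtype=float)
    elif isinstance(rows, pd.Series):
        arr = rows[list(ITEM_COLUMNS[: spec.n_items])].to_numpy(dtype=float)[None, :]
    else:
        arr = np.atleast_2d(np.asarray(rows, dtype=float))
    if arr.shape[1] != spec.n_items:
        raise ValueError(f"expected {spec.n_items} item scores, got {arr.shape[1]}")
    if np.isnan(arr).any():
        raise ValueError("missing item scores; apply listwise deletion first")
    return arr


def cfaws_score(rows, weights, spec: HBMModelSpec = DEFAULT_SPEC) -> np.ndarray | float:
    """CFA-weighted health-belief score(s): WHBS = sum_n W_n * IS_n.

    ``rows`` may be a single row (Series or 1-d array) or a table; raw 1-5
    scores are consumed for all items, barrier items included.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (spec.n_items,):
        raise ValueError(f"weight vector must have {spec.n_items} entries")
    if not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite")
    arr = _item_array(rows, spec)
    scores = arr @ w
    return float(scores[0]) if scores.size == 1 and np.ndim(rows) <= 1 else scores


def sss_score(rows, spec: HBMModelSpec = DEFAULT_SPEC) -> np.ndarray | float:
    """Simple sum score(s): positively keyed items minus barrier items."""
    sign = np.ones(spec.n_items)
    sign[spec.items_of("BAR")] = -1.0
    arr = _item_array(rows, spec)
    scores = arr @ sign
    return float(scores[0]) if scores.size == 1 and np.ndim(rows) <= 1 else scores


def score_table(
    table: pd.DataFrame,
    weights=None,
    method: str = "both",
    spec: HBMModelSpec = DEFAULT_SPEC,
) -> pd.DataFrame:
    """Per-respondent scores in long form (respondent_id, cohort, method, score)."""
    complete = listwise_delete(table, spec)
    frames = []
    if method in ("cfaws", "both"):
        if weights is None:
            raise ValueError("cfaws scoring requires a weight vector")
        frames.append(
            pd.DataFrame(
                {
                    "respondent_id": complete["respondent_id"].to_numpy(),
                    "cohort": complete["cohort"].to_numpy(),
                    "method": "cfaws",
                    "score": cfaws_score(complete, weights, spec),
                }
            )
        )
    if method in ("sss", "both"):
        frames.append(
            pd.DataFrame(
                {
                    "respondent_id": complete["respondent_id"].to_numpy(),
                    "cohort": complete["cohort"].to_numpy(),
                    "method": "sss",
                    "score": sss_score(complete, spec),
                }
            )
        )
    if not frames:
        raise ValueError("method must be 'cfaws', 'sss' or 'both'")
    return pd.concat(frames, ignore_index=True)


def compare_cohorts(
    pre_scores,
    post_scores,
    method: str = "cfaws",
    ttest: str = "pooled",
    alpha: float = 0.05,
) -> ScoreComparison:
    """Two-independent-sample t-test of post vs pre scores with a CI.

    The pooled-variance test is the default; ``ttest="welch"`` uses the
    unequal-variance statistic with Welch-Satterthwaite df.  The interval
    is mean_difference +/- t_{1-alpha/2, df} * SE.
    """
    x = np.asarray(pre_scores, dtype=float)
    y = np.asarray(post_scores, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each cohort needs at least 2 scores")
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    if vx == 0.0 and vy == 0.0:
        raise ValueError("both cohorts have zero score variance")
    nx, ny = x.size, y.size
    diff = float(np.mean(y) - np.mean(x))
    if ttest == "pooled":
        df = nx + ny - 2
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / df
        se = float(np.sqrt(sp2 * (1.0 / nx + 1.0 / ny)))
    elif ttest == "welch":
        se2x, se2y = vx / nx, vy / ny
        se = float(np.sqrt(se2x + se2y))
        df = (se2x + se2y) ** 2 / (se2x**2 / (nx - 1) + se2y**2 / (ny - 1))
    else:
        raise ValueError("ttest must be 'pooled' or 'welch'")
    t_stat = diff / se
    p = 2.0 * stats.t.sf(abs(t_stat), df)
    crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return ScoreComparison(
        method=method,
        n_pre=nx,
        n_post=ny,
        mean_pre=float(np.mean(x)),
        mean_post=float(np.mean(y)),
        sd_pre=float(np.sqrt(vx)),
        sd_post=float(np.sqrt(vy)),
        mean_difference=diff,
        ci_lower=diff - crit * se,
        ci_upper=diff + crit * se,
        t_statistic=float(t_stat),
        df=float(df),
        p_value=float(p),
        ttest=ttest,
    )
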