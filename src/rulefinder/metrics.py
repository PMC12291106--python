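"""Association statistics scoring rule columns against binary labels.

Each rule column predicts ``high`` where it is +1 and ``low`` where it is
-1; zeros mean the rule does not apply. With A = {i : column[i] != 0} and
correct(i) = (column[i] = +1 and label = high) or (column[i] = -1 and
label = low):

* support    = |A| / n - fraction of samples the rule applies to;
* confidence = |{i in A : correct}| / |A| - fraction of applied samples
  predicted correctly;
* baseline   = mean over i in A of the full-dataset marginal rate of the
  class the rule predicts for i (0.5 on balanced labels);
* lift       = confidence / baseline - predictive gain over guessing the
  marginal rates;
* leverage   = mean of the two directional leverages
  P(pred c & actual c) - P(pred c) P(actual c) for c in {high, low} -
  excess joint frequency over independence, in [-0.25, 0.25].

Under a label-permutation null, lift concentrates at 1 and leverage at 0.
Rules with no applied samples have confidence/lift/leverage undefined; they
are returned with an explicit ``undefined`` flag, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import labels_to_int
from .rules import FeatureMatrix

__all__ = ["RuleMetricsRow", "score_rule", "metrics_report", "report_to_frame"]


@dataclass(frozen=True)
class RuleMetricsRow:
    """Association statistics for one rule column."""

    rule_id: str
    support: float
    n_applied: int
    confidence: float | None = None
    lift: float | None = None
    leverage: float | None = None
    flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def undefined(self) -> bool:
        return "undefined" in self.flags


def _as_column(column) -> np.ndarray:
    col = np.asarray(column, dtype=int)
    if col.ndim != 1:
        raise ValueError("column must be 1-D")
    if col.size and not np.isin(col, (-1, 0, 1)).all():
        raise ValueError("column entries must be in {-1, 0, 1}")
    return col


def score_rule(column, labels: Sequence[str] | np.ndarray, rule_id: str = "") -> RuleMetricsRow:
    """Score one ternary rule column against high/low labels.

    ``labels`` may be 'high'/'low' strings or a 0/1 integer vector
    (1 = high). Raises on length mismatch or an empty dataset.
    """
    col = _as_column(column)
    y = np.asarray(labels)
    y = labels_to_int(list(y)) if y.dtype.kind in ("U", "S", "O") else y.astype(int)
    if col.shape != y.shape:
        raise ValueError(f"length mismatch: column {col.shape} vs labels {y.shape}")
    n = col.size
    if n == 0:
        raise ValueError("cannot score an empty column")

    applied = col != 0
    n_applied = int(applied.sum())
    support = n_applied / n
    if n_applied == 0:
        return RuleMetricsRow(rule_id=rule_id, support=0.0, n_applied=0, flags=("undefined",))

    p_high = float(np.mean(y == 1))
    p_low = 1.0 - p_high
    pred_high = col == 1
    pred_low = col == -1
    correct = (pred_high & (y == 1)) | (pred_low & (y == 0))
    confidence = float(correct[applied].mean())

    # marginal rate of the class predicted for each applied sample, averaged
    baseline = float(np.where(pred_high[applied], p_high, p_low).mean())
    flags: list[str] = []
    lift: float | None
    if baseline > 0:
        lift = confidence / baseline
    else:
        lift = None
        flags.append("undefined-lift")

    lev_high = float(np.mean(pred_high & (y == 1))) - float(np.mean(pred_high)) * p_high
    lev_low = float(np.mean(pred_low & (y == 0))) - float(np.mean(pred_low)) * p_low
    leverage = 0.5 * (lev_high + lev_low)

    return RuleMetricsRow(
        rule_id=rule_id,
        support=support,
        n_applied=n_applied,
        confidence=confidence,
        lift=lift,
        leverage=leverage,
        flags=tuple(flags),
    )


def metrics_report(fm: FeatureMatrix, labels) -> list[RuleMetricsRow]:
    """Score every column of a feature matrix; one row per rule, in order."""
    y = np.asarray(labels)
    if y.shape[0] != fm.shape[0]:
        raise ValueError("labels length must equal the matrix row count")
    return [score_rule(fm.values[:, j], y, rule_id=rid) for j, rid in enumerate(fm.col_ids)]


def report_to_frame(rows: Sequence[RuleMetricsRow]) -> pd.DataFrame:
    """Tabulate a metrics report (one row per rule) as a DataFrame."""
    return pd.DataFrame(
        {
            "rule_id": [r.rule_id for r in rows],
            "support": [r.support for r in rows],
            "confidence": [r.confidence for r in rows],
            "lift": [r.lift for r in rows],
            "leverage": [r.leverage for r in rows],
            "n_applied": [r.n_applied for r in rows],
            "flags": [";".join(r.flags) for r in rows],
        }
    )
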