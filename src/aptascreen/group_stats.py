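"""Group summaries and pooled two-sample t-tests for candidate-vs-control contrasts.

The screen's statistical claims are plain two-group comparisons: consensus
Z_T of ERE-derived candidates against random hairpin controls, and folding
free energies of candidates against controls.  The test form is the pooled
(equal-variance Student) t with df = n1 + n2 - 2 — identifiable from the
reported degrees of freedom — with two-sided p-values.  Group membership is
always declared in the input (candidate vs control), never inferred.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["GroupSummary", "TTestResult", "summarize", "pooled_t_test", "write_report"]


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float  # sample (n-1) standard deviation


@dataclass(frozen=True)
class TTestResult:
    """Pooled two-sample t. ``t`` is signed (group1 - group2 direction);
    ``direction`` flags which group is lower for readers of |t| reports."""

    t: float
    df: int
    p_two_sided: float
    direction: str  # 'group1_lower' | 'group2_lower' | 'equal'

    @property
    def abs_t(self) -> float:
        return abs(self.t)


def summarize(values: Sequence[float], label: str = "") -> GroupSummary:
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError(f"group {label!r}: need n >= 2 for a sample SD, got n={x.size}")
    return GroupSummary(label=label, n=int(x.size), mean=float(x.mean()), sd=float(x.std(ddof=1)))


def pooled_t_test(group1: Sequence[float], group2: Sequence[float]) -> TTestResult:
    """Pooled-variance Student t with df = n1 + n2 - 2, two-sided p."""
    x1 = np.asarray(group1, dtype=float)
    x2 = np.asarray(group2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("both groups need n >= 2")
    df = int(x1.size + x2.size - 2)
    ss = float(((x1 - x1.mean()) ** 2).sum() + ((x2 - x2.mean()) ** 2).sum())
    if ss == 0.0:
        if x1.mean() == x2.mean():
            return TTestResult(t=0.0, df=df, p_two_sided=1.0, direction="equal")
        raise ValueError("zero pooled variance with unequal means: t is undefined")
    sp2 = ss / df
    se = np.sqrt(sp2 * (1.0 / x1.size + 1.0 / x2.size))
    t = float((x1.mean() - x2.mean()) / se)
    p = float(2.0 * stats.t.sf(abs(t), df))
    if t == 0.0:
        direction = "equal"
    else:
        direction = "group1_lower" if t < 0 else "group2_lower"
    return TTestResult(t=t, df=df, p_two_sided=p, direction=direction)


def write_report(
    summaries: Sequence[GroupSummary],
    test: TTestResult,
    path: str | Path,
) -> None:
    """JSON report with both group summaries and the test result."""
    payload = {
        "groups": [asdict(s) for s in summaries],
        "t_test": asdict(test),
        "test_form": "pooled two-sample Student t, two-sided p",
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
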