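"""Consensus docking-score normalization and candidate ranking.

Each docking engine scores a candidate's 10 best binding modes on its own
scale, so raw scores are not comparable across engines.  Scores are made
commensurable with the mean-centered Z-score

    Z_i = (E_i - mean(E)) / SD(E)

over a candidate's mode set; the *most negative* mode Z is that engine's
Z-score for the candidate (an unusually deep best mode relative to the
candidate's own mode spread signals a specific binding funnel).  The total
consensus score is the plain sum over the three engines,

    Z_T = Z_AV + Z_H + Z_P,

and candidates are ranked ascending in Z_T (most negative = best).  SD is the
sample (n-1) standard deviation by default; the choice is switchable and is
recorded in written output metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._resources import data_path

__all__ = [
    "METHODS",
    "DockingScoreSet",
    "ZScoreRow",
    "RankedRow",
    "ZeroVarianceError",
    "method_zscore",
    "total_zscore",
    "rank_candidates",
    "top_k",
    "load_table2",
    "read_score_table",
    "write_ranking",
]

#: docking engines: AutoDock Vina, HADDOCK, PatchDock
METHODS = ("AV", "H", "P")


class ZeroVarianceError(ValueError):
    """All mode scores identical; the Z-score is undefined."""


@dataclass(frozen=True)
class DockingScoreSet:
    """Per-engine mode scores for one candidate, lower = better.

    Engines that natively emit higher-is-better scores (e.g. geometric shape
    complementarity) must be ingested with ``orientation="higher"``, which
    negates the scores once so that "most negative = best" holds uniformly.
    """

    candidate_id: str
    method: str
    mode_scores: tuple[float, ...]
    orientation: str = "lower"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if len(self.mode_scores) < 2:
            raise ValueError(
                f"{self.candidate_id}/{self.method}: need >= 2 binding modes, "
                f"got {len(self.mode_scores)}"
            )
        if not all(math.isfinite(s) for s in self.mode_scores):
            raise ValueError(f"{self.candidate_id}/{self.method}: non-finite score")
        if self.orientation not in ("lower", "higher"):
            raise ValueError("orientation must be 'lower' or 'higher'")

    def energy_like(self) -> "DockingScoreSet":
        """Return the lower-is-better version of this score set."""
        if self.orientation == "lower":
            return self
        return replace(
            self,
            mode_scores=tuple(-s for s in self.mode_scores),
            orientation="lower",
        )


@dataclass(frozen=True)
class ZScoreRow:
    """Per-engine Z-scores and their Z_T total for one candidate."""

    candidate_id: str
    z_av: float
    z_h: float
    z_p: float
    z_t: float
    sequence: str = ""


@dataclass(frozen=True)
class RankedRow:
    rank: int
    row: ZScoreRow


def method_zscore(scores: DockingScoreSet, ddof: int = 1) -> float:
    """Most negative mean-centered Z over a candidate's binding modes.

    ``ddof=1`` (sample SD) is the default convention; ``ddof=0`` switches to
    the population SD.
    """
    ss = scores.energy_like()
    x = np.asarray(ss.mode_scores, dtype=float)
    sd = float(x.std(ddof=ddof))
    if sd == 0.0:
        raise ZeroVarianceError(
            f"{ss.candidate_id}/{ss.method}: all {x.size} mode scores identical; "
            "Z-score undefined"
        )
    return float(((x - x.mean()) / sd).min())


def total_zscore(z_av: float | None, z_h: float | None, z_p: float | None) -> float:
    """Z_T = Z_AV + Z_H + Z_P; every engine must contribute (no 2-method sums)."""
    vals = {"AV": z_av, "H": z_h, "P": z_p}
    missing = [m for m, v in vals.items() if v is None or not math.isfinite(v)]
    if missing:
        raise ValueError(f"missing or non-finite Z-score for method(s): {', '.join(missing)}")
    return float(z_av + z_h + z_p)


def rank_candidates(rows: Sequence[ZScoreRow]) -> list[RankedRow]:
    """Ascending Z_T order (most negative first), ties by candidate id."""
    ids = [r.candidate_id for r in rows]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate candidate ids: {sorted(dupes)}")
    ordered = sorted(rows, key=lambda r: (r.z_t, r.candidate_id))
    return [RankedRow(rank=k, row=r) for k, r in enumerate(ordered, start=1)]


def top_k(ranked: Sequence[RankedRow], k: int) -> list[RankedRow]:
    if not 1 <= k <= len(ranked):
        raise ValueError(f"k must be in [1, {len(ranked)}], got {k}")
    return list(ranked[:k])


# ---------------------------------------------------------------------------
# I/O


def load_table2() -> list[ZScoreRow]:
    """The packaged 18-row fixture of printed per-engine Z-scores and Z_T."""
    df = pd.read_csv(data_path("table2_zscores.tsv"), sep="\t")
    return [
        ZScoreRow(
            candidate_id=r.candidate_id,
            z_av=float(r.z_av),
            z_h=float(r.z_h),
            z_p=float(r.z_p),
            z_t=float(r.z_t),
            sequence=r.sequence,
        )
        for r in df.itertuples(index=False)
    ]


def read_score_table(path: str | Path) -> list[DockingScoreSet]:
    """Read raw mode scores from TSV.

    Columns: candidate_id, method, orientation, score_mode_1..score_mode_m.
    """
    df = pd.read_csv(path, sep="\t")
    mode_cols = [c for c in df.columns if c.startswith("score_mode_")]
    if not mode_cols:
        raise ValueError("no score_mode_* columns found")
    mode_cols.sort(key=lambda c: int(c.rsplit("_", 1)[1]))
    out = []
    for r in df.itertuples(index=False):
        scores = tuple(float(getattr(r, c)) for c in mode_cols if pd.notna(getattr(r, c)))
        out.append(
            DockingScoreSet(
                candidate_id=str(r.candidate_id),
                method=str(r.method),
                mode_scores=scores,
                orientation=str(getattr(r, "orientation", "lower")),
            )
        )
    return out


def write_ranking(
    ranked: Iterable[RankedRow],
    path: str | Path,
    two_decimals: bool = False,
    ddof: int = 1,
) -> None:
    """Write a ranking TSV mirroring the candidate/sequence/Z columns."""
    rows = []
    for rr in ranked:
        r = rr.row
        rows.append(
            {
                "rank": rr.rank,
                "candidate_id": r.candidate_id,
                "sequence": r.sequence,
                "z_av": r.z_av,
                "z_h": r.z_h,
                "z_p": r.z_p,
                "z_t": r.z_t,
            }
        )
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write(f"# z-score convention: most negative of per-mode Z, SD ddof={ddof}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.2f" if two_decimals else None)
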