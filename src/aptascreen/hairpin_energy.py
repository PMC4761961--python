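"""Single-stem hairpin free energies from nearest-neighbor rules.

The stability score used to triage RNA candidates is the minimum free energy
over all *single contiguous stems*: a stack of Watson-Crick / G.U pairs closed
by a terminal loop of at least three unpaired bases, with optional unpaired
5'/3' tails.  The energy of a structure is

    dG = sum(stack steps) + hairpin-loop initiation(loop length)
         + terminal A.U/G.U penalty at the open helix end

with Turner 2004 dG(37 C) constants shipped as a versioned TSV and swappable
via :class:`NearestNeighborTable`.  All candidate sequences here are short
(15-20 nt) near-perfect palindromes, so restricting the structure class to
one stem (no bulges, internal loops or multiloops) loses essentially nothing
and keeps exhaustive enumeration exact and cheap.  The all-unpaired chain has
dG = 0 by convention; a sequence whose best stem is not stabilizing (dG >= 0)
folds to the open chain and reports no structure.

Magnitudes from this model are not comparable to full secondary-structure
predictors (terminal mismatches and non-canonical motifs are omitted); within
the package only orderings and signs of dG are relied upon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from ._resources import data_path
from .sequence_pool import RnaCandidate

__all__ = [
    "NearestNeighborTable",
    "HairpinStructure",
    "fold_hairpin",
    "delta_g_batch",
    "load_default_table",
    "load_table3",
]

_PAIRS = frozenset({"AU", "UA", "GC", "CG", "GU", "UG"})
_WC_PAIRS = frozenset({"AU", "UA", "GC", "CG"})
_WEAK_CLOSERS = frozenset({"AU", "UA", "GU", "UG"})

# Jacobson-Stockmayer extrapolation beyond the tabulated loop sizes,
# 1.75 * R * T at the 37 C reference of the dG table
_RT37 = 1.987e-3 * 310.15


@dataclass(frozen=True)
class NearestNeighborTable:
    """Stacking/loop/penalty constants for the single-stem hairpin model.

    ``stack_energies`` maps an ordered helix step ``(outer_pair, inner_pair)``
    — each pair written 5' base first, e.g. ``("GC", "AU")`` — to kcal/mol.
    ``hairpin_loop_initiation`` maps loop length (nt) to kcal/mol and is
    extrapolated logarithmically beyond its largest entry.
    """

    stack_energies: dict[tuple[str, str], float]
    hairpin_loop_initiation: dict[int, float]
    terminal_au_penalty: float
    version: str = "unversioned"

    def __post_init__(self) -> None:
        for (p, q), e in self.stack_energies.items():
            if p not in _PAIRS or q not in _PAIRS:
                raise ValueError(f"unknown pair in stack step {p}/{q}")
            if p in _WC_PAIRS and q in _WC_PAIRS and e > 0:
                raise ValueError(f"WC stack {p}/{q} must be <= 0, got {e}")
        lengths = sorted(self.hairpin_loop_initiation)
        if not lengths or lengths[0] > 3:
            raise ValueError("loop initiation must cover length 3")
        prev = None
        for n in lengths:
            g = self.hairpin_loop_initiation[n]
            if g < 0:
                raise ValueError(f"loop initiation for length {n} must be >= 0")
            # the published series dips around lengths 4-8; require
            # monotonicity only in the smooth large-loop regime
            if n >= 9 and prev is not None and g < prev:
                raise ValueError(f"loop initiation decreases at length {n}")
            if n >= 9:
                prev = g

    def stack(self, outer: str, inner: str) -> float:
        try:
            return self.stack_energies[(outer, inner)]
        except KeyError:
            raise KeyError(f"no stacking energy for step {outer}/{inner}") from None

    def loop_initiation(self, length: int) -> float:
        if length < 3:
            raise ValueError("hairpin loops shorter than 3 nt are disallowed")
        table = self.hairpin_loop_initiation
        if length in table:
            return table[length]
        nmax = max(table)
        return table[nmax] + 1.75 * _RT37 * math.log(length / nmax)


def load_default_table(path: str | Path | None = None) -> NearestNeighborTable:
    """Load the packaged Turner 2004 table (or any TSV in the same layout)."""
    path = data_path("nn_turner2004.tsv") if path is None else Path(path)
    stacks: dict[tuple[str, str], float] = {}
    loops: dict[int, float] = {}
    terminal_au = 0.0
    version = "unversioned"
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line.startswith("# version:"):
                version = line.split(":", 1)[1].strip()
            if not line or line.startswith("#") or line.startswith("kind\t"):
                continue
            kind, key, value = line.split("\t")
            if kind == "stack":
                outer, inner = key.split("/")
                stacks[(outer, inner)] = float(value)
            elif kind == "hairpin":
                loops[int(key)] = float(value)
            elif kind == "misc" and key == "terminal_au":
                terminal_au = float(value)
            else:
                raise ValueError(f"unknown parameter row: {line!r}")
    return NearestNeighborTable(stacks, loops, terminal_au, version=version)


@dataclass(frozen=True)
class HairpinStructure:
    """A single-stem hairpin: contiguous stack, terminal loop, dG in kcal/mol."""

    dot_bracket: str
    stem_pairs: tuple[tuple[int, int], ...]
    loop_length: int
    delta_g: float

    def __post_init__(self) -> None:
        if self.loop_length < 3:
            raise ValueError("loop_length must be >= 3")
        if not self.stem_pairs:
            raise ValueError("a hairpin needs at least one stem pair")
        i_in, j_in = self.stem_pairs[-1]
        if j_in - i_in - 1 != self.loop_length:
            raise ValueError("loop_length inconsistent with innermost pair")


def _as_seq(rna: RnaCandidate | str) -> str:
    seq = rna.rna if isinstance(rna, RnaCandidate) else rna
    seq = seq.upper().replace("T", "U")
    for pos, base in enumerate(seq, start=1):
        if base not in "ACGU":
            raise ValueError(f"invalid RNA base {base!r} at position {pos}")
    return seq


def fold_hairpin(
    rna: RnaCandidate | str,
    table: NearestNeighborTable | None = None,
    min_loop: int = 3,
) -> HairpinStructure | None:
    """Minimum-dG single-stem hairpin of a sequence, or ``None``.

    Enumerates every register: outer pair ``(i, j)`` and stem length ``s``
    such that pairs ``(i+k, j-k)``, ``k < s``, are all WC or G.U and the
    enclosed loop has at least ``min_loop`` bases.  Returns the structure of
    minimum dG, or ``None`` when no register beats the open chain (dG = 0).
    """
    table = load_default_table() if table is None else table
    seq = _as_seq(rna)
    L = len(seq)
    best_dg = 0.0
    best: tuple[int, int, int] | None = None  # (i, j, s) 0-based outer pair
    for i in range(L):
        for j in range(i + min_loop + 1, L):
            pair = seq[i] + seq[j]
            if pair not in _PAIRS:
                continue
            dg = table.loop_initiation(j - i - 1)
            if pair in _WEAK_CLOSERS:
                dg += table.terminal_au_penalty
            if dg < best_dg:
                best_dg, best = dg, (i, j, 1)
            s = 1
            while True:
                ii, jj = i + s, j - s
                if jj - ii - 1 < min_loop:
                    break
                nxt = seq[ii] + seq[jj]
                if nxt not in _PAIRS:
                    break
                s += 1
                dg = sum(
                    table.stack(seq[i + k] + seq[j - k], seq[i + k + 1] + seq[j - k - 1])
                    for k in range(s - 1)
                )
                dg += table.loop_initiation(jj - ii - 1)
                if pair in _WEAK_CLOSERS:
                    dg += table.terminal_au_penalty
                if dg < best_dg:
                    best_dg, best = dg, (i, j, s)
    if best is None:
        return None
    i, j, s = best
    pairs = tuple((i + k + 1, j - k + 1) for k in range(s))  # 1-based
    db = ["."] * L
    for a, b in pairs:
        db[a - 1] = "("
        db[b - 1] = ")"
    loop_len = (j - s + 1) - (i + s - 1) - 1
    return HairpinStructure("".join(db), pairs, loop_len, round(best_dg, 10))


def delta_g_batch(
    pool: Sequence[RnaCandidate | str],
    table: NearestNeighborTable | None = None,
) -> list[tuple[str, float]]:
    """Folding dG per candidate; 0.0 when no stabilizing hairpin exists."""
    table = load_default_table() if table is None else table
    out = []
    for k, rna in enumerate(pool):
        ident = rna.id if isinstance(rna, RnaCandidate) else f"seq{k + 1}"
        hp = fold_hairpin(rna, table)
        out.append((ident, 0.0 if hp is None else hp.delta_g))
    return out


def load_table3():
    """Packaged fixture of printed folding dG values (5 candidates, 5 controls).

    These dG values come from a different (unknown-version) energy model and
    are treated as *inputs* for the group statistics, never as values this
    module's model should reproduce numerically.
    """
    import pandas as pd

    return pd.read_csv(data_path("table3_deltag.tsv"), sep="\t")
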