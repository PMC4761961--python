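"""Candidate response-element pools and aptamer-likeness selection.

Estrogen response elements (EREs) are short palindromic DNA motifs in the
promoters of estrogen-regulated genes.  Because the two half-sites of an ERE
are an inverted repeat, the *single* sense strand can fold back on itself into
a hairpin — the structural signature of many aptamers.  This module holds the
candidate pool, detects the inverted-repeat decomposition of each sequence,
applies the aptamer-likeness selection criterion (full-length inverted repeat,
few mismatches, no extended half-site) and produces the single-stranded RNA
analogs used downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ._resources import data_path

__all__ = [
    "ResponseElement",
    "RnaCandidate",
    "InvertedRepeatDecomposition",
    "SelectionRecord",
    "SelectionResult",
    "transcribe_sense",
    "find_inverted_repeat",
    "select_aptamer_like",
    "load_table1",
    "read_fasta_pool",
    "write_fasta_pool",
    "read_pool_tsv",
]

_DNA_ALPHABET = frozenset("ACGT")
_RNA_ALPHABET = frozenset("ACGU")

#: Watson-Crick partners on a T/U-unified alphabet (keys/values use U).
_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}
#: wobble partners (G.U, or G.T at the DNA level)
_WOBBLE = {("G", "U"), ("U", "G")}


def _check_alphabet(seq: str, alphabet: frozenset[str], what: str) -> None:
    if not seq:
        raise ValueError(f"{what} sequence is empty")
    for pos, base in enumerate(seq, start=1):
        if base not in alphabet:
            raise ValueError(
                f"invalid {what} base {base!r} at position {pos} "
                f"(allowed: {''.join(sorted(alphabet))})"
            )


@dataclass(frozen=True)
class ResponseElement:
    """A named estrogen-response-element sense strand (DNA)."""

    id: str
    gene_name: str
    dna_sense: str
    source_ref: str = ""

    def __post_init__(self) -> None:
        _check_alphabet(self.dna_sense, _DNA_ALPHABET, "DNA")

    def __len__(self) -> int:
        return len(self.dna_sense)


@dataclass(frozen=True)
class RnaCandidate:
    """Single-stranded RNA analog of a response element (or a synthetic RNA)."""

    id: str
    rna: str
    parent_id: str | None = None

    def __post_init__(self) -> None:
        _check_alphabet(self.rna, _RNA_ALPHABET, "RNA")

    def __len__(self) -> int:
        return len(self.rna)


@dataclass(frozen=True)
class InvertedRepeatDecomposition:
    """Best terminal-arm inverted-repeat register of a sequence.

    ``paired_positions`` pairs position ``i`` with ``L+1-i`` (1-based) for
    ``i = 1..arm_length``; the ``loop_length`` central bases stay unpaired.
    """

    arm_length: int
    loop_length: int
    paired_positions: tuple[tuple[int, int], ...]
    n_wc_pairs: int
    n_wobble_pairs: int
    n_mismatches: int

    def __post_init__(self) -> None:
        if self.arm_length < 1:
            raise ValueError("arm_length must be >= 1")
        if self.loop_length < 3:
            raise ValueError("loop_length must be >= 3")
        if self.n_wc_pairs + self.n_wobble_pairs + self.n_mismatches != self.arm_length:
            raise ValueError("pair counts must sum to arm_length")
        for i, j in self.paired_positions:
            if not i < j:
                raise ValueError(f"paired positions must satisfy i < j, got ({i}, {j})")

    @property
    def n_matches(self) -> int:
        return self.n_wc_pairs + self.n_wobble_pairs


def transcribe_sense(element: ResponseElement) -> RnaCandidate:
    """RNA analog of a sense strand: T -> U, everything else untouched."""
    return RnaCandidate(
        id=f"{element.id}_rna",
        rna=element.dna_sense.replace("T", "U"),
        parent_id=element.id,
    )


def _pair_kind(a: str, b: str) -> str:
    """Classify a putative pair on the U-unified alphabet: wc / wobble / mismatch."""
    if _WC[a] == b:
        return "wc"
    if (a, b) in _WOBBLE:
        return "wobble"
    return "mismatch"


def find_inverted_repeat(
    seq: str,
    min_arm: int = 5,
    min_loop: int = 3,
    allow_wobble: bool = False,
) -> InvertedRepeatDecomposition | None:
    """Best full-length inverted-repeat register of ``seq``.

    Every register pairs the terminal arms (position ``i`` with ``L+1-i``)
    around a central loop, so the candidate registers are exactly the
    ``(arm, loop)`` splits with ``2*arm + loop == L`` and ``loop >= min_loop``.
    The returned register maximizes the number of Watson-Crick pairs (plus
    wobble pairs when ``allow_wobble``); ties go to the longer arm, i.e. the
    smaller loop.  Because the registers are nested, the winner always has
    the longest arm the sequence admits, with outer non-pairing positions
    recorded as mismatches — tolerating them is the selection filter's job.
    Returns ``None`` when the sequence is too short to host ``min_arm``-long
    arms around a ``min_loop`` loop, or when no register pairs anything at
    all (no complementary positions).

    Accepts DNA or RNA; pairing is evaluated on the T->U unified alphabet,
    so the wobble pair means G.U for RNA and G.T for DNA.
    """
    if min_arm < 1:
        raise ValueError("min_arm must be >= 1")
    if min_loop < 3:
        raise ValueError("min_loop must be >= 3")
    useq = seq.upper().replace("T", "U")
    _check_alphabet(useq, _RNA_ALPHABET, "nucleotide")
    L = len(useq)
    max_arm = (L - min_loop) // 2
    best: InvertedRepeatDecomposition | None = None
    best_score = -1
    for arm in range(1, max_arm + 1):
        kinds = [_pair_kind(useq[i], useq[L - 1 - i]) for i in range(arm)]
        n_wc = kinds.count("wc")
        n_wob = kinds.count("wobble")
        score = n_wc + (n_wob if allow_wobble else 0)
        # ties: prefer the longer arm (== smaller loop); registers are scanned
        # with increasing arm, so ">=" implements that preference
        if score >= best_score:
            best_score = score
            best = InvertedRepeatDecomposition(
                arm_length=arm,
                loop_length=L - 2 * arm,
                paired_positions=tuple((i + 1, L - i) for i in range(arm)),
                n_wc_pairs=n_wc,
                n_wobble_pairs=n_wob,
                n_mismatches=arm - n_wc - n_wob,
            )
    if best is None or max_arm < min_arm or best_score == 0:
        return None
    return best


@dataclass(frozen=True)
class SelectionRecord:
    """Pass/fail audit entry for one pool element."""

    id: str
    passed: bool
    reason: str
    decomposition: InvertedRepeatDecomposition | None


@dataclass(frozen=True)
class SelectionResult:
    selected: tuple[ResponseElement, ...]
    records: tuple[SelectionRecord, ...]

    def __iter__(self):
        return iter(self.selected)

    def __len__(self) -> int:
        return len(self.selected)


def select_aptamer_like(
    pool: Sequence[ResponseElement],
    min_arm: int = 5,
    max_mismatch: int = 3,
    allow_wobble: bool = False,
    min_loop: int = 3,
) -> SelectionResult:
    """Aptamer-likeness filter for response elements.

    Keeps elements whose best inverted-repeat register has arms of at least
    ``min_arm`` (so the arms cover at least ``2*min_arm`` of the sequence —
    this is also the guard against extended half-sites, whose spacer pushes
    the repeat off a full-length register) and at most ``max_mismatch``
    mismatched arm positions.  Input order is preserved; every element gets
    an audit record with the reason it passed or failed.
    """
    if not pool:
        raise ValueError("pool must be non-empty")
    selected: list[ResponseElement] = []
    records: list[SelectionRecord] = []
    for el in pool:
        dec = find_inverted_repeat(
            el.dna_sense, min_arm=min_arm, min_loop=min_loop, allow_wobble=allow_wobble
        )
        if dec is None:
            records.append(
                SelectionRecord(el.id, False, f"no register with >= {min_arm} matched pairs", None)
            )
            continue
        if dec.arm_length < min_arm:
            records.append(
                SelectionRecord(el.id, False, f"arm {dec.arm_length} < min_arm {min_arm}", dec)
            )
            continue
        if dec.n_mismatches > max_mismatch:
            records.append(
                SelectionRecord(
                    el.id, False, f"{dec.n_mismatches} mismatches > max {max_mismatch}", dec
                )
            )
            continue
        selected.append(el)
        records.append(
            SelectionRecord(
                el.id,
                True,
                f"arm {dec.arm_length}, {dec.n_mismatches} mismatches",
                dec,
            )
        )
    return SelectionResult(tuple(selected), tuple(records))


# ---------------------------------------------------------------------------
# I/O


def load_table1() -> list[ResponseElement]:
    """The packaged 18-element ERE pool, ids ERE01..ERE18 in printed order."""
    return read_pool_tsv(data_path("table1_eres.tsv"))


def read_pool_tsv(path: str | Path) -> list[ResponseElement]:
    """Read a pool from TSV with columns gene_description, sequence, reference."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for k, row in enumerate(df.itertuples(index=False), start=1):
        out.append(
            ResponseElement(
                id=f"ERE{k:02d}",
                gene_name=str(row.gene_description),
                dna_sense=str(row.sequence).strip().upper(),
                source_ref=str(row.reference),
            )
        )
    return out


def read_fasta_pool(path: str | Path) -> list[ResponseElement]:
    """Read a pool from FASTA; the description line carries ``id|gene_name``."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        head, _, gene = rec.description.partition("|")
        ident = head.split()[-1] if head.split() else rec.id
        out.append(
            ResponseElement(
                id=ident, gene_name=gene.strip(), dna_sense=str(rec.seq).upper()
            )
        )
    return out


def write_fasta_pool(pool: Iterable[ResponseElement], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(el.dna_sense), id=el.id, description=f"{el.id}|{el.gene_name}")
        for el in pool
    ]
    seqio_write(records, str(path), "fasta")
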