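"""Parsing and windowing of PSI-BLAST position-specific scoring matrices.

A PSSM is the L x 20 matrix of integer log-odds conservation scores that
PSI-BLAST writes with ``-out_ascii_pssm`` after profile search against a
large sequence database.  Scores are mapped to (0, 1) with the logistic
function 1/(1+e^-S) before any relational feature is computed, and
residue-wise samples are cut out with an odd-length sliding window
centred on the target position.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

import numpy as np
from Bio import SeqIO

#: Fixed PSI-BLAST amino-acid column ordering.
PSSM_COLUMNS = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {aa: i for i, aa in enumerate(PSSM_COLUMNS)}

#: Letters accepted in chain sequences; non-standard codes collapse to 'X'.
ALPHABET = set(PSSM_COLUMNS) | {"X"}
_NONSTANDARD = {"B": "X", "Z": "X", "U": "X", "O": "X", "J": "X", "X": "X"}

PAD_CHAR = "-"


def canonical_residue(letter: str) -> str:
    """Map a one-letter residue code to the 21-letter alphabet (20 + 'X')."""
    letter = letter.upper()
    if letter in AA_INDEX:
        return letter
    if letter in _NONSTANDARD:
        return "X"
    raise ValueError(f"unknown residue code {letter!r}")


class PssmFormatError(ValueError):
    """Raised when an ASCII PSSM stream cannot be parsed."""


class PssmMismatchError(ValueError):
    """Raised when a PSSM disagrees with the chain it should describe."""


@dataclass(frozen=True)
class ProteinChain:
    """A protein chain: identifier plus sequence over the 21-letter alphabet."""

    chain_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"chain {self.chain_id}: empty sequence")
        cleaned = "".join(canonical_residue(c) for c in self.sequence)
        object.__setattr__(self, "sequence", cleaned)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Pssm:
    """L x 20 integer log-odds conservation scores for one chain.

    ``residue_column`` is the per-row amino-acid letter as read from the
    file; ``column_order`` records the amino-acid ordering of the 20
    score columns (PSI-BLAST's fixed order unless overridden).
    """

    chain_id: str
    scores: np.ndarray
    residue_column: str
    column_order: str = PSSM_COLUMNS

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores)
        if scores.ndim != 2 or scores.shape[1] != 20:
            raise ValueError(f"PSSM for {self.chain_id}: expected L x 20 scores, got {scores.shape}")
        if scores.shape[0] != len(self.residue_column):
            raise ValueError(f"PSSM for {self.chain_id}: residue column length mismatch")
        object.__setattr__(self, "scores", scores)

    @property
    def length(self) -> int:
        return self.scores.shape[0]


@dataclass(frozen=True)
class NormalizedPssm:
    """Logistic-normalised PSSM: every score mapped to 1/(1+e^-S) in (0, 1)."""

    chain_id: str
    values: np.ndarray

    @property
    def length(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ResidueInstance:
    """One residue-wise sample: a w x 20 window of normalised scores.

    The target residue sits in the middle row.  Rows that would fall
    outside the chain are zero-filled and flagged in ``pad_mask`` so that
    they contribute nothing to relational sums; ``residues`` carries the
    window's one-letter codes with '-' at padded positions.
    """

    chain_id: str
    target_position: int
    window_size: int
    window: np.ndarray
    pad_mask: np.ndarray
    residues: str

    @property
    def half(self) -> int:
        return (self.window_size - 1) // 2

    @property
    def target_residue(self) -> str:
        return self.residues[self.half]


def read_fasta(path: str | Path) -> list[ProteinChain]:
    """Read chains from a FASTA file (record id becomes the chain id)."""
    return [ProteinChain(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def _find_header(lines: list[str], column_order: str) -> tuple[int, str]:
    for idx, line in enumerate(lines):
        tokens = line.split()
        if len(tokens) >= 20 and all(len(t) == 1 and t.isalpha() for t in tokens[:20]):
            return idx, "".join(tokens[:20])
    return -1, column_order


def parse_pssm(
    stream: TextIO | str,
    chain: ProteinChain | None = None,
    column_order: str | None = None,
) -> Pssm:
    """Parse a PSI-BLAST ASCII PSSM, keeping the first (log-odds) 20-column block.

    Parameters
    ----------
    stream:
        Open text stream or the file content itself.
    chain:
        When given, the parsed matrix is validated against the chain:
        row count must equal the chain length and the per-row residue
        letters must match the sequence ('X' matches anything).
    column_order:
        Override for non-standard column orderings; by default the order
        is read from the header line (falling back to PSI-BLAST's fixed
        order), and scores are re-ordered to ``PSSM_COLUMNS``.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lines = stream.read().splitlines()
    header_idx, file_order = _find_header(lines, column_order or PSSM_COLUMNS)
    if column_order is not None:
        file_order = column_order
    if sorted(file_order) != sorted(PSSM_COLUMNS):
        raise PssmFormatError(f"unrecognised PSSM column order {file_order!r}")

    rows: list[list[int]] = []
    residues: list[str] = []
    for lineno, line in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
        tokens = line.split()
        if not tokens:
            continue
        if not tokens[0].isdigit():
            break  # trailing K/Lambda statistics block
        if len(tokens) < 22:
            raise PssmFormatError(f"line {lineno}: expected index, residue and 20 scores, got {len(tokens)} fields")
        try:
            scores = [int(t) for t in tokens[2:22]]
        except ValueError as exc:
            raise PssmFormatError(f"line {lineno}: unparseable score field ({exc})") from exc
        residues.append(canonical_residue(tokens[1]))
        rows.append(scores)

    if not rows:
        raise PssmFormatError("no PSSM data rows found")

    scores = np.array(rows, dtype=np.int64)
    # re-order columns into the canonical PSI-BLAST order
    if file_order != PSSM_COLUMNS:
        perm = [file_order.index(aa) for aa in PSSM_COLUMNS]
        scores = scores[:, perm]

    chain_id = chain.chain_id if chain is not None else "unknown"
    if chain is not None:
        if scores.shape[0] != chain.length:
            raise PssmMismatchError(
                f"chain {chain.chain_id}: PSSM has {scores.shape[0]} rows but sequence length is {chain.length}"
            )
        bad = [
            i + 1
            for i, (a, b) in enumerate(zip(residues, chain.sequence))
            if a != b and "X" not in (a, b)
        ]
        if bad:
            raise PssmMismatchError(f"chain {chain.chain_id}: residue letters disagree at positions {bad}")
    return Pssm(chain_id, scores, "".join(residues))


def write_pssm(pssm: Pssm, path: str | Path | None = None) -> str:
    """Serialise a PSSM in the PSI-BLAST ASCII dialect (log-odds block only)."""
    out = ["", "Last position-specific scoring matrix computed, weighted observed percentages ignored"]
    out.append(" " * 11 + "  ".join(PSSM_COLUMNS))
    for i in range(pssm.length):
        row = " ".join(f"{v:3d}" for v in pssm.scores[i])
        out.append(f"{i + 1:5d} {pssm.residue_column[i]}  {row}")
    out.append("")
    text = "\n".join(out)
    if path is not None:
        Path(path).write_text(text)
    return text


def normalize(pssm: Pssm) -> NormalizedPssm:
    """Map integer log-odds scores to (0, 1) with the logistic function."""
    scores = np.asarray(pssm.scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        bad = np.argwhere(~np.isfinite(scores))
        raise ValueError(f"non-finite PSSM score at (row, col) {bad[0].tolist()}")
    with np.errstate(over="ignore"):
        values = 1.0 / (1.0 + np.exp(-scores))
    return NormalizedPssm(pssm.chain_id, values)


def extract_window(
    npssm: NormalizedPssm,
    i: int,
    w: int,
    chain: ProteinChain | None = None,
) -> ResidueInstance:
    """Cut the w x 20 window centred at 1-based position ``i``.

    Rows outside [1, L] are zero-filled and flagged in the pad mask.
    """
    if w % 2 == 0 or w < 3:
        raise ValueError(f"window size must be odd and >= 3, got {w}")
    L = npssm.length
    if not 1 <= i <= L:
        raise IndexError(f"target position {i} outside [1, {L}]")
    half = (w - 1) // 2
    window = np.zeros((w, 20), dtype=float)
    pad = np.ones(w, dtype=bool)
    letters = [PAD_CHAR] * w
    seq = chain.sequence if chain is not None else "X" * L
    for k in range(w):
        pos = i - half + k  # 1-based chain position of window row k
        if 1 <= pos <= L:
            window[k] = npssm.values[pos - 1]
            pad[k] = False
            letters[k] = seq[pos - 1]
    return ResidueInstance(npssm.chain_id, i, w, window, pad, "".join(letters))


def iter_windows(
    npssm: NormalizedPssm, w: int, chain: ProteinChain | None = None
) -> Iterable[ResidueInstance]:
    """Yield the residue instance of every position of a chain."""
    for i in range(1, npssm.length + 1):
        yield extract_window(npssm, i, w, chain)
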