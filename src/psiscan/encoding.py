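"""One-hot encodings of sequence windows, with and without structure.

Two binary representations are supported:

* **general** — each base becomes a length-4 unit row in the fixed column
  order A, U, C, G, so a window of N nucleotides becomes an (N x 4) matrix.
* **merged-seq** — each position is first paired with its dot-bracket
  symbol, giving a 12-letter alphabet (4 bases x 3 structure states), and
  the pairs are one-hot encoded into an (N x 12) matrix.

The 12 merged columns are ordered base-major: ``index(base, sym) =
3 * base_index + sym_index`` with bases in A, U, C, G order and symbols in
'.', '(', ')' order.  Any fixed order is model-equivalent; this one is the
package's documented convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets_io import SequenceWindow
from .folding import DotBracket

BASE_ORDER = "AUCG"
SYMBOL_ORDER = ".()"
MERGED_ALPHABET = [b + s for b in BASE_ORDER for s in SYMBOL_ORDER]

__all__ = [
    "EncodedMatrix",
    "MergedSequence",
    "EncodingError",
    "encode_general",
    "merge_sequence",
    "encode_merged",
    "encode_dataset",
    "decode",
]


class EncodingError(ValueError):
    pass


@dataclass(frozen=True)
class MergedSequence:
    """Positionwise (base, structure symbol) pairs for one window."""

    pairs: tuple[tuple[str, str], ...]

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class EncodedMatrix:
    """A one-hot matrix: rows are positions 5'->3', columns the alphabet."""

    values: np.ndarray
    alphabet: tuple[str, ...]
    encoding_kind: str  # "general" | "merged_seq"

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def encode_general(w: SequenceWindow) -> EncodedMatrix:
    """Encode a window into a (2*xi+1) x 4 one-hot matrix (columns A,U,C,G)."""
    idx = [BASE_ORDER.index(b) for b in w.residues]
    mat = np.zeros((len(w.residues), 4), dtype=np.float64)
    mat[np.arange(len(idx)), idx] = 1.0
    return EncodedMatrix(mat, tuple(BASE_ORDER), "general")


def merge_sequence(w: SequenceWindow, s: DotBracket) -> MergedSequence:
    """Zip a window with its structure into positionwise (base, symbol) pairs."""
    if len(w.residues) != len(s):
        raise EncodingError(
            f"window {w.id!r}: sequence length {len(w.residues)} != structure length {len(s)}"
        )
    return MergedSequence(tuple(zip(w.residues, s.symbols)))


def encode_merged(m: MergedSequence) -> EncodedMatrix:
    """Encode merged (base, symbol) pairs into an N x 12 one-hot matrix."""
    mat = np.zeros((len(m), 12), dtype=np.float64)
    for row, (base, sym) in enumerate(m.pairs):
        mat[row, 3 * BASE_ORDER.index(base) + SYMBOL_ORDER.index(sym)] = 1.0
    return EncodedMatrix(mat, tuple(MERGED_ALPHABET), "merged_seq")


def encode_dataset(
    windows,
    structures: dict[str, DotBracket] | None = None,
    kind: str = "general",
) -> np.ndarray:
    """Stack per-window encodings into an (n, rows, cols) array.

    For ``kind="merged_seq"`` a structure must be available for every window
    id in ``structures``.
    """
    mats = []
    for w in windows:
        if kind == "general":
            mats.append(encode_general(w).values)
        elif kind == "merged_seq":
            if structures is None or w.id not in structures:
                raise EncodingError(f"no structure for window {w.id!r}")
            mats.append(encode_merged(merge_sequence(w, structures[w.id])).values)
        else:
            raise EncodingError(f"unknown encoding kind {kind!r}")
    return np.stack(mats)


def decode(e: EncodedMatrix) -> str | tuple[str, str]:
    """Invert an encoding. Returns residues, or (residues, structure) for merged.

    Raises :class:`EncodingError` if any row is not a one-hot unit vector.
    """
    vals = np.asarray(e.values)
    if vals.ndim != 2 or not np.all(np.isin(vals, (0.0, 1.0))) or not np.all(
        vals.sum(axis=1) == 1
    ):
        raise EncodingError("matrix rows must each be a one-hot unit vector")
    idx = vals.argmax(axis=1)
    letters = [e.alphabet[i] for i in idx]
    if e.encoding_kind == "general":
        return "".join(letters)
    residues = "".join(p[0] for p in letters)
    structure = "".join(p[1] for p in letters)
    return residues, structure
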