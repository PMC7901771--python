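"""Secondary-structure handling: dot-bracket parsing, external folding, and a
deterministic Nussinov maximum-pairing fallback.

A dot-bracket string annotates each nucleotide as unpaired ('.') or as the
5' ('(') / 3' (')') member of a base pair; the pair set induced by matching
brackets is nested (pseudoknot-free).  Structures normally come from a
thermodynamic folder (RNAfold minimum-free-energy line); the built-in
Nussinov dynamic program provides a dependency-free deterministic stand-in
that maximizes the number of canonical pairs — it makes no claim of
thermodynamic fidelity.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field
from functools import lru_cache

STRUCTURE_ALPHABET = ".()"

#: Watson-Crick plus GU wobble.
CANONICAL_PAIRS = frozenset({"AU", "UA", "GC", "CG", "GU", "UG"})

__all__ = [
    "DotBracket",
    "StructureError",
    "FolderUnavailableError",
    "parse_dot_bracket",
    "fold_external",
    "fold_nussinov",
]


class StructureError(ValueError):
    """Malformed dot-bracket input."""


class FolderUnavailableError(RuntimeError):
    """The external folding command cannot be run; use the Nussinov fallback."""


@dataclass(frozen=True)
class DotBracket:
    """A validated dot-bracket string plus its induced base-pair index set."""

    symbols: str
    pairs: frozenset[tuple[int, int]] = field(compare=False)

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def length(self) -> int:
        return len(self.symbols)


def parse_dot_bracket(s: str) -> DotBracket:
    """Parse and validate a dot-bracket string.

    Raises :class:`StructureError` (with the offending index) on foreign
    characters or unbalanced brackets.  Loop-length policy is not enforced
    here — it applies only to the fallback folder.
    """
    if not s:
        raise StructureError("empty dot-bracket string")
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for i, ch in enumerate(s):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unmatched ')' at index {i}")
            pairs.add((stack.pop(), i))
        elif ch != ".":
            raise StructureError(f"foreign character {ch!r} at index {i}")
    if stack:
        raise StructureError(f"unmatched '(' at index {stack[0]}")
    return DotBracket(symbols=s, pairs=frozenset(pairs))


def fold_external(residues: str, folder_cmd: str = "RNAfold") -> DotBracket:
    """Fold a sequence with an external RNAfold-compatible command.

    Consumes only the MFE structure line (dot-bracket followed by an optional
    parenthesized free energy, which is stripped).  Raises
    :class:`FolderUnavailableError` if the command is missing or fails, so
    callers can fall back to :func:`fold_nussinov`.
    """
    if shutil.which(folder_cmd) is None:
        raise FolderUnavailableError(
            f"{folder_cmd!r} not found on PATH; use fold_nussinov or precomputed structures"
        )
    try:
        proc = subprocess.run(
            [folder_cmd, "--noPS"],
            input=residues + "\n",
            capture_output=True,
            text=True,
            check=True,
        )
    except subprocess.CalledProcessError as exc:
        raise FolderUnavailableError(
            f"{folder_cmd!r} exited with status {exc.returncode}: {exc.stderr.strip()}"
        ) from exc
    lines = [ln for ln in proc.stdout.splitlines() if ln.strip()]
    if len(lines) < 2:
        raise StructureError(f"unparseable folder output: {proc.stdout!r}")
    struct_line = lines[1].strip()
    symbols = struct_line.split(" ", 1)[0]
    db = parse_dot_bracket(symbols)
    if len(db) != len(residues):
        raise StructureError(
            f"folder returned structure of length {len(db)} for sequence of length {len(residues)}"
        )
    return db


def fold_nussinov(residues: str, min_loop: int = 3) -> DotBracket:
    """Maximum canonical base pairing by the Nussinov dynamic program.

    Pairs are drawn from {AU, UA, GC, CG, GU, UG} and must satisfy
    ``j - i > min_loop``.  Traceback tie-break: position ``i`` is left
    unpaired whenever that already achieves the optimum, and among pairing
    partners the smallest ``j`` wins — so the output is deterministic.
    """
    if not residues:
        raise StructureError("cannot fold an empty sequence")
    n = len(residues)
    seq = residues.upper()

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        if j - i <= min_loop:
            return 0
        score = best(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if seq[i] + seq[k] in CANONICAL_PAIRS:
                left = best(i + 1, k - 1)
                right = best(k + 1, j) if k < j else 0
                score = max(score, 1 + left + right)
        return score

    symbols = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop:
            continue
        target = best(i, j)
        if best(i + 1, j) == target:      # prefer i unpaired
            stack.append((i + 1, j))
            continue
        for k in range(i + min_loop + 1, j + 1):  # then smallest partner j
            if seq[i] + seq[k] in CANONICAL_PAIRS:
                left = best(i + 1, k - 1)
                right = best(k + 1, j) if k < j else 0
                if 1 + left + right == target:
                    symbols[i], symbols[k] = "(", ")"
                    stack.append((i + 1, k - 1))
                    if k < j:
                        stack.append((k + 1, j))
                    break
    best.cache_clear()
    return parse_dot_bracket("".join(symbols))
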