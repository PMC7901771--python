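"""Reading, writing and validating uridine-centered sequence windows.

The unit of data is a window of ``2*xi + 1`` ribonucleotides centered on a
candidate uridine: ``xi`` flanking bases on the 5' side, the central U, and
``xi`` flanking bases on the 3' side.  Benchmark-style datasets are plain
FASTA files whose headers carry the binary label as a ``label=0|1`` token;
secondary structures travel in a separate RNAfold-style file.

DNA-convention input (T instead of U) is silently normalized; ambiguity
codes such as N are rejected because the downstream one-hot encodings are
defined only over the four canonical bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .folding import DotBracket, parse_dot_bracket

RNA_ALPHABET = "AUCG"

__all__ = [
    "SequenceWindow",
    "LabeledDataset",
    "DatasetError",
    "read_dataset",
    "read_structures",
    "write_dataset",
    "write_structures",
]


class DatasetError(ValueError):
    """Raised for malformed records or windows violating the contract."""


def normalize_residues(raw: str) -> str:
    """Upper-case and convert T -> U. Raises on anything outside {A,C,G,U,T}."""
    seq = raw.strip().upper().replace("T", "U")
    for pos, ch in enumerate(seq):
        if ch not in RNA_ALPHABET:
            raise DatasetError(
                f"unknown character {ch!r} at position {pos} (only A/C/G/U/T accepted)"
            )
    return seq


@dataclass(frozen=True)
class SequenceWindow:
    """A labeled RNA window of odd length with uridine at its center.

    Attributes
    ----------
    id : record identifier.
    residues : string over {A,C,G,U}, length ``2*xi + 1``.
    xi : flank length in nucleotides; the central position is index ``xi``.
    label : 1 for a pseudouridine site, 0 for a non-site.
    species_tag : optional free-text tag (e.g. HS / SC / MM).
    """

    id: str
    residues: str
    xi: int
    label: int
    species_tag: str | None = None

    def __post_init__(self) -> None:
        n = len(self.residues)
        if n != 2 * self.xi + 1:
            raise DatasetError(
                f"window {self.id!r}: length {n} != 2*{self.xi}+1"
            )
        bad = set(self.residues) - set(RNA_ALPHABET)
        if bad:
            raise DatasetError(f"window {self.id!r}: non-canonical residues {sorted(bad)}")
        if self.residues[self.xi] != "U":
            raise DatasetError(
                f"window {self.id!r}: central position {self.xi} is "
                f"{self.residues[self.xi]!r}, expected 'U'"
            )
        if self.label not in (0, 1):
            raise DatasetError(f"window {self.id!r}: label must be 0 or 1, got {self.label}")

    @classmethod
    def from_raw(
        cls,
        id: str,
        raw_residues: str,
        label: int,
        species_tag: str | None = None,
    ) -> "SequenceWindow":
        """Build a window from unnormalized text, inferring ``xi`` from length."""
        seq = normalize_residues(raw_residues)
        if len(seq) % 2 == 0:
            raise DatasetError(f"window {id!r}: even length {len(seq)}, expected 2*xi+1")
        return cls(id=id, residues=seq, xi=len(seq) // 2, label=label, species_tag=species_tag)


@dataclass
class LabeledDataset:
    """An ordered collection of windows sharing one flank length ``xi``."""

    windows: list[SequenceWindow] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        xis = {w.xi for w in self.windows}
        if len(xis) > 1:
            raise DatasetError(f"dataset {self.name!r}: mixed flank lengths {sorted(xis)}")

    @property
    def xi(self) -> int | None:
        return self.windows[0].xi if self.windows else None

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def class_counts(self) -> tuple[int, int]:
        """(negatives, positives)."""
        pos = sum(w.label for w in self.windows)
        return len(self.windows) - pos, pos

    @property
    def labels(self) -> list[int]:
        return [w.label for w in self.windows]


def _parse_label_token(header: str, lineno: int) -> tuple[str, int]:
    """Split a FASTA header into (id, label) using the ``label=`` token."""
    body = header[1:].strip()
    tokens = body.replace("|", " ").split()
    label: int | None = None
    id_parts: list[str] = []
    for tok in tokens:
        if tok.startswith("label="):
            val = tok[len("label="):]
            if val not in ("0", "1"):
                raise DatasetError(f"line {lineno}: label token {tok!r} must be label=0 or label=1")
            label = int(val)
        else:
            id_parts.append(tok)
    if label is None:
        raise DatasetError(f"line {lineno}: header {header!r} lacks a label=0|1 token")
    if not id_parts:
        raise DatasetError(f"line {lineno}: header {header!r} lacks a record id")
    return "|".join(id_parts), label


def _iter_fasta(path: Path) -> Iterable[tuple[int, str, str]]:
    """Yield (header_lineno, header, sequence) triples from a FASTA file."""
    header = None
    header_line = 0
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    yield header_line, header, "".join(chunks)
                header, header_line, chunks = line, lineno, []
            else:
                if header is None:
                    raise DatasetError(f"line {lineno}: sequence data before any '>' header")
                chunks.append(line)
    if header is not None:
        yield header_line, header, "".join(chunks)


def read_dataset(
    path: str | Path,
    format: str = "fasta",
    label_source: str = "header_token",
    name: str | None = None,
    species_tag: str | None = None,
) -> LabeledDataset:
    """Read a labeled window dataset.

    Parameters
    ----------
    path : input file. For ``label_source="paired_files"`` this is the
        positives file and a sibling negatives file is given as a 2-tuple.
    format : ``"fasta"`` (headers carry ``label=`` tokens) or
        ``"two_column"`` (tab/space separated ``sequence  label`` lines).
    label_source : ``"header_token"`` or ``"paired_files"``.
    """
    if label_source == "paired_files":
        if not (isinstance(path, (tuple, list)) and len(path) == 2):
            raise DatasetError("paired_files label source requires (positives, negatives) paths")
        pos_path, neg_path = (Path(p) for p in path)
        windows: list[SequenceWindow] = []
        for p, lab in ((pos_path, 1), (neg_path, 0)):
            for lineno, header, seq in _iter_fasta(p):
                rec_id = header[1:].strip().split()[0]
                windows.append(SequenceWindow.from_raw(rec_id, seq, lab, species_tag))
        return LabeledDataset(windows, name or pos_path.stem)

    path = Path(path)
    if not path.exists():
        raise DatasetError(f"no such file: {path}")
    windows = []
    if format == "fasta":
        for lineno, header, seq in _iter_fasta(path):
            rec_id, label = _parse_label_token(header, lineno)
            windows.append(SequenceWindow.from_raw(rec_id, seq, label, species_tag))
    elif format == "two_column":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) != 2:
                    raise DatasetError(f"line {lineno}: expected 'sequence label', got {line!r}")
                seq, lab = parts
                if lab not in ("0", "1"):
                    raise DatasetError(f"line {lineno}: label must be 0 or 1, got {lab!r}")
                windows.append(SequenceWindow.from_raw(f"seq_{lineno}", seq, int(lab), species_tag))
    else:
        raise DatasetError(f"unknown format {format!r}")
    return LabeledDataset(windows, name or path.stem)


def read_structures(path: str | Path) -> dict[str, DotBracket]:
    """Read an RNAfold-style structure file into a record-id -> DotBracket map.

    Expected layout per record: a ``>id`` header line, the sequence line, and
    the dot-bracket line with an optional trailing ``(energy)`` field which is
    ignored.  Structure length must match sequence length and brackets must
    balance.
    """
    path = Path(path)
    out: dict[str, DotBracket] = {}
    lines = [ln.rstrip("\n") for ln in open(path)]
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.startswith(">"):
            raise DatasetError(f"line {i + 1}: expected '>' header, got {line!r}")
        rec_id = line[1:].strip().split()[0]
        if i + 2 >= len(lines):
            raise DatasetError(f"record {rec_id!r}: truncated (need sequence + structure lines)")
        seq = normalize_residues(lines[i + 1])
        struct_line = lines[i + 2].strip()
        # strip the trailing "( -3.20 )" / "(-3.20)" free-energy field
        sym_end = len(struct_line)
        for j, ch in enumerate(struct_line):
            if ch == " ":
                sym_end = j
                break
        symbols = struct_line[:sym_end]
        try:
            db = parse_dot_bracket(symbols)
        except ValueError as exc:
            raise DatasetError(f"record {rec_id!r}: {exc}") from exc
        if len(db) != len(seq):
            raise DatasetError(
                f"record {rec_id!r}: structure length {len(db)} != sequence length {len(seq)}"
            )
        out[rec_id] = db
        i += 3
    return out


def write_dataset(ds: LabeledDataset, path: str | Path, format: str = "fasta") -> None:
    """Write a dataset so that :func:`read_dataset` round-trips it exactly."""
    path = Path(path)
    with open(path, "w") as fh:
        if format == "fasta":
            for w in ds:
                fh.write(f">{w.id}|label={w.label}\n{w.residues}\n")
        elif format == "two_column":
            for w in ds:
                fh.write(f"{w.residues}\t{w.label}\n")
        else:
            raise DatasetError(f"unknown format {format!r}")


def write_structures(structures: Mapping[str, tuple[str, DotBracket]], path: str | Path) -> None:
    """Write ``id -> (sequence, structure)`` records in the RNAfold dialect."""
    with open(Path(path), "w") as fh:
        for rec_id, (seq, db) in structures.items():
            fh.write(f">{rec_id}\n{seq}\n{db.symbols}\n")
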