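"""Synthetic uridine-centered datasets with a planted, tunable motif.

The generator emulates the structure of curated pseudouridine benchmarks:
balanced classes, a fixed window length ``2*xi + 1``, and a central U in
every window (negatives too — real candidate sites are always uridines, so
the center base carries no signal).  Positives additionally carry a
consensus motif planted at a fixed offset around the center; each motif
position is drawn as the consensus base with probability ``strength`` and
uniformly over the other three bases otherwise.  At ``strength = 0.25`` the
classes are exchangeable; at ``strength = 1`` every positive contains the
exact consensus.

The default "strong" preset plants GGUUCA (a TΨC-arm-like context whose
fourth base is the central U) at offset -3 in 21-nt windows, 200 windows
per class, strength 0.95 — separable enough that a trained classifier
should approach perfect held-out accuracy, which is what makes it useful
as a parameter-recovery surface.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .datasets_io import LabeledDataset, SequenceWindow

BASES = "ACGU"

__all__ = ["GeneratorSpec", "generate", "strong_preset", "dataset_hash"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for one synthetic dataset.

    ``motif_offset`` is the signed offset of the motif start relative to the
    central position (index ``xi``); offset -3 with a length-6 motif spans
    positions xi-3 .. xi+2.  If the motif covers the center, its consensus
    base there must be U so the window invariant holds.
    """

    n_per_class: int = 200
    xi: int = 10
    motif: str = "GGUUCA"
    strength: float = 0.95
    motif_offset: int = -3
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)  # A,C,G,U
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0.25 <= self.strength <= 1.0:
            raise ValueError("strength must lie in [0.25, 1]")
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError("background probabilities must sum to 1")
        start = self.xi + self.motif_offset
        if start < 0 or start + len(self.motif) > 2 * self.xi + 1:
            raise ValueError("motif overruns the window")
        center_in_motif = self.xi - start
        if 0 <= center_in_motif < len(self.motif) and self.motif[center_in_motif] != "U":
            raise ValueError(
                "motif covers the central position but its consensus there is not U"
            )
        if set(self.motif) - set(BASES):
            raise ValueError("motif must be over A/C/G/U")

    @property
    def motif_positions(self) -> range:
        """Window indices occupied by the motif."""
        start = self.xi + self.motif_offset
        return range(start, start + len(self.motif))


def generate(spec: GeneratorSpec) -> LabeledDataset:
    """Draw a balanced labeled dataset; fully determined by ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    length = 2 * spec.xi + 1
    bg = np.asarray(spec.background)
    windows: list[SequenceWindow] = []
    for label, prefix in ((1, "pos"), (0, "neg")):
        for i in range(spec.n_per_class):
            chars = list(rng.choice(list(BASES), size=length, p=bg))
            if label == 1:
                start = spec.xi + spec.motif_offset
                for j, consensus in enumerate(spec.motif):
                    if rng.random() < spec.strength:
                        chars[start + j] = consensus
                    else:
                        others = [b for b in BASES if b != consensus]
                        chars[start + j] = others[rng.integers(3)]
            chars[spec.xi] = "U"  # center is always uridine, both classes
            windows.append(
                SequenceWindow(
                    id=f"{prefix}_{i}", residues="".join(chars), xi=spec.xi, label=label
                )
            )
    return LabeledDataset(windows, name=f"synthetic_s{spec.strength}_seed{spec.seed}")


def strong_preset() -> GeneratorSpec:
    """The fixed strongly-separable preset used by the recovery checks:
    21-nt windows, 200 per class, GGUUCA planted at offset -3 with
    strength 0.95, uniform background, seed 1."""
    return GeneratorSpec()


def dataset_hash(ds: LabeledDataset) -> str:
    """Content hash over (id, residues, label) triples — pins preset stability."""
    h = hashlib.sha256()
    for w in ds:
        h.update(f"{w.id}\t{w.residues}\t{w.label}\n".encode())
    return h.hexdigest()
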