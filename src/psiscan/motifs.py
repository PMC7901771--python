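"""Turning learned convolution kernels into sequence motifs and logos.

Each first-layer filter is scanned over a dataset; every window position
whose activation reaches a fraction of that filter's dataset-wide maximum
(half-max by default) contributes its aligned subsequence to a position
frequency matrix.  Merged-seq inputs are projected from (base, structure)
pairs down to their base before counting, so logos are always 4-letter
nucleotide logos.  Matrices can be rendered as probability logos (letter
stack heights are the probabilities) or information-content logos (stack
height is the column's IC in bits, at most 2 for a 4-letter alphabet with
a uniform background).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.font_manager import FontProperties
from matplotlib.patches import PathPatch
from matplotlib.textpath import TextPath
from matplotlib.transforms import Affine2D

from .network import MultiChannelCNN

#: Row order of every PFM.
PFM_BASES = "ACGU"

_LETTER_COLORS = {"A": "#109648", "C": "#255C99", "G": "#F7B32B", "U": "#D62839"}

__all__ = [
    "PositionFrequencyMatrix",
    "LogoSpec",
    "extract_motifs",
    "information_content",
    "pfm_from_windows",
    "render_logo",
    "write_meme",
]


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Per-position base probabilities (rows A,C,G,U) with hit support."""

    probs: np.ndarray  # shape (4, width), columns sum to 1
    support: int
    name: str = "motif"

    def __post_init__(self) -> None:
        p = np.asarray(self.probs)
        if p.shape[0] != 4 or not np.allclose(p.sum(axis=0), 1.0):
            raise ValueError("PFM must have 4 rows and unit column sums")
        if self.support < 1:
            raise ValueError("PFM support must be >= 1")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(PFM_BASES[i] for i in self.probs.argmax(axis=0))


@dataclass
class LogoSpec:
    mode: str  # "probability" | "information_content"
    matrices: list[PositionFrequencyMatrix] = field(default_factory=list)
    title: str = ""

    def __post_init__(self) -> None:
        if self.mode not in ("probability", "information_content"):
            raise ValueError(f"unknown logo mode {self.mode!r}")


def _bases_from_encoded(X: np.ndarray) -> np.ndarray:
    """Recover the base index (A,C,G,U order) at each position of an encoded
    tensor, for either the 4- or the 12-column alphabet."""
    idx = np.asarray(X).argmax(axis=2)
    if X.shape[2] == 4:
        aucg_to_acgu = np.array([0, 3, 1, 2])  # columns are A,U,C,G
        return aucg_to_acgu[idx]
    # merged: column = 3*base + symbol, bases in A,U,C,G order
    return np.array([0, 3, 1, 2])[idx // 3]


def extract_motifs(
    model: MultiChannelCNN,
    X: np.ndarray,
    activation_frac: float = 0.5,
) -> list[PositionFrequencyMatrix]:
    """Convert first-layer kernels into PFMs over a dataset.

    For each kernel, every subsequence whose activation is at least
    ``activation_frac`` times the kernel's maximum activation over ``X`` is
    counted into that kernel's PFM.  Kernels that never activate (max <= 0)
    are omitted.
    """
    if not 0 < activation_frac <= 1:
        raise ValueError("activation_frac must lie in (0, 1]")
    X = np.asarray(X)
    if len(X) == 0:
        raise ValueError("cannot extract motifs from an empty dataset")
    base_idx = _bases_from_encoded(X)  # (n, rows)
    pfms: list[PositionFrequencyMatrix] = []
    for channel, acts in enumerate(model.conv_activations(X)):
        h = model.config.filter_heights[channel]
        n, P, F = acts.shape
        for f in range(F):
            a = acts[:, :, f]
            amax = a.max()
            if amax <= 0:
                continue
            hits = np.argwhere(a >= activation_frac * amax)
            counts = np.zeros((4, h))
            for b, p in hits:
                sub = base_idx[b, p : p + h]
                counts[sub, np.arange(h)] += 1
            pfms.append(
                PositionFrequencyMatrix(
                    probs=counts / counts.sum(axis=0, keepdims=True),
                    support=len(hits),
                    name=f"ch{channel}_k{f}",
                )
            )
    return pfms


def information_content(pfm: PositionFrequencyMatrix) -> np.ndarray:
    """Per-column information content in bits: IC_j = 2 + sum_b p log2 p,
    with 0*log(0) = 0 and a uniform background."""
    p = np.asarray(pfm.probs)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return 2.0 + plogp.sum(axis=0)


def pfm_from_windows(windows) -> PositionFrequencyMatrix:
    """Dataset-level ground-truth PFM: direct per-position base frequencies."""
    seqs = [w.residues for w in windows]
    if not seqs:
        raise ValueError("no windows")
    length = len(seqs[0])
    counts = np.zeros((4, length))
    lut = {b: i for i, b in enumerate(PFM_BASES)}
    for s in seqs:
        for j, ch in enumerate(s):
            counts[lut[ch], j] += 1
    return PositionFrequencyMatrix(
        probs=counts / counts.sum(axis=0, keepdims=True),
        support=len(seqs),
        name="ground_truth",
    )


def _draw_letter(ax, letter: str, x: float, y: float, height: float) -> None:
    if height <= 0:
        return
    tp = TextPath((0, 0), letter, size=1.0, prop=FontProperties(family="monospace", weight="bold"))
    bbox = tp.get_extents()
    transform = (
        Affine2D()
        .translate(-bbox.x0, -bbox.y0)
        .scale(0.9 / bbox.width, height / bbox.height)
        .translate(x + 0.05, y)
    )
    ax.add_patch(
        PathPatch(transform.transform_path(tp), facecolor=_LETTER_COLORS[letter], edgecolor="none")
    )


def render_logo(spec: LogoSpec, path: str | Path) -> Path:
    """Render stacked-letter logos, one panel per PFM, to an image file.

    Letters are stacked smallest-first; the layout is deterministic for a
    fixed spec.
    """
    path = Path(path)
    n = len(spec.matrices)
    if n == 0:
        raise ValueError("no matrices to render")
    fig, axes = plt.subplots(n, 1, figsize=(max(4, spec.matrices[0].width * 0.4), 2.2 * n))
    if n == 1:
        axes = [axes]
    for ax, pfm in zip(axes, spec.matrices):
        if spec.mode == "probability":
            heights_mat = pfm.probs
            ymax = 1.0
            ax.set_ylabel("probability")
        else:
            heights_mat = pfm.probs * information_content(pfm)[None, :]
            ymax = 2.0
            ax.set_ylabel("bits")
        for j in range(pfm.width):
            col = sorted(zip(PFM_BASES, heights_mat[:, j]), key=lambda t: t[1])
            y = 0.0
            for letter, h in col:
                _draw_letter(ax, letter, j, y, h)
                y += h
        ax.set_xlim(0, pfm.width)
        ax.set_ylim(0, ymax)
        ax.set_xticks(np.arange(pfm.width) + 0.5)
        ax.set_xticklabels(np.arange(1, pfm.width + 1))
        ax.set_title(f"{pfm.name} (support={pfm.support})", fontsize=8)
    if spec.title:
        fig.suptitle(spec.title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def write_meme(pfms: list[PositionFrequencyMatrix], path: str | Path) -> Path:
    """Export PFMs in MEME minimal motif format (ACGU alphabet)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGU\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 U 0.25\n\n")
        for pfm in pfms:
            fh.write(f"MOTIF {pfm.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pfm.width} nsites= {pfm.support}\n"
            )
            for j in range(pfm.width):
                fh.write(" ".join(f"{pfm.probs[i, j]:.6f}" for i in range(4)) + "\n")
            fh.write("\n")
    return path
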