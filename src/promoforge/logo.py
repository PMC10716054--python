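"""Position frequency matrices and information-content sequence logos.

For an aligned, fixed-length promoter set the per-position information
content is R = 2 - H bits, where H is the Shannon entropy of the base
frequencies (optionally reduced by the Schneider small-sample correction
e_n = 3 / (2 ln2 n)); each base contributes frequency x R bits, which is
the quantity a sequence logo draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .seqdata import DNA_ALPHABET, SequenceDataset

__all__ = ["PositionFrequencyMatrix", "LogoMatrix", "build_pfm",
           "information_content", "consensus", "plot_logo"]


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Per-position base counts (columns A, C, G, T) of an aligned set."""

    counts: np.ndarray            # L x 4 non-negative integers
    n_sequences: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError("counts must be L x 4")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not (counts.sum(axis=1) == self.n_sequences).all():
            raise ValueError("every position's counts must sum to n_sequences")
        object.__setattr__(self, "counts", counts)

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    def frequencies(self) -> np.ndarray:
        return self.counts / self.n_sequences

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.counts, columns=list(DNA_ALPHABET)).to_csv(path,
                                                                     index=False)


@dataclass(frozen=True)
class LogoMatrix:
    """Per-base information contributions in bits (L x 4, each row total
    at most 2 bits for DNA)."""

    bits: np.ndarray

    def position_totals(self) -> np.ndarray:
        return self.bits.sum(axis=1)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.bits, columns=list(DNA_ALPHABET)).to_csv(path,
                                                                   index=False)


def build_pfm(dataset: SequenceDataset | list[str]) -> PositionFrequencyMatrix:
    """Count bases per position over an aligned fixed-length set."""
    seqs = dataset.sequences() if isinstance(dataset, SequenceDataset) else list(dataset)
    if not seqs:
        raise ValueError("cannot build a PFM from an empty dataset")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences have mixed lengths {sorted(lengths)}")
    length = lengths.pop()
    idx = {b: i for i, b in enumerate(DNA_ALPHABET)}
    counts = np.zeros((length, 4), dtype=int)
    for s in seqs:
        for pos, base in enumerate(s):
            counts[pos, idx[base]] += 1
    return PositionFrequencyMatrix(counts=counts, n_sequences=len(seqs))


def information_content(pfm: PositionFrequencyMatrix,
                        small_sample_correction: bool = False) -> LogoMatrix:
    """Information content per base: frequency x (2 - H - e_n), floored
    at zero bits."""
    freqs = pfm.frequencies()
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    entropy = -plogp.sum(axis=1)
    r = 2.0 - entropy
    if small_sample_correction:
        r -= 3.0 / (2.0 * math.log(2) * pfm.n_sequences)
    r = np.maximum(r, 0.0)
    return LogoMatrix(bits=freqs * r[:, None])


def consensus(pfm: PositionFrequencyMatrix) -> str:
    """Per-position majority base; ties resolve alphabetically."""
    return "".join(DNA_ALPHABET[i] for i in pfm.counts.argmax(axis=1))


def plot_logo(logo: LogoMatrix, path: str | Path, title: str = "") -> None:
    """Render a simple stacked-bar logo (bits per base per position)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"A": "#109648", "C": "#255C99", "G": "#F7B32B", "T": "#D62839"}
    length = logo.bits.shape[0]
    fig, ax = plt.subplots(figsize=(max(6, length / 5), 2.5))
    bottoms = np.zeros(length)
    for i, base in enumerate(DNA_ALPHABET):
        ax.bar(np.arange(length), logo.bits[:, i], bottom=bottoms,
               color=colors[base], width=0.9, label=base)
        bottoms += logo.bits[:, i]
    ax.set_ylim(0, 2)
    ax.set_ylabel("bits")
    ax.set_xlabel("position")
    if title:
        ax.set_title(title)
    ax.legend(ncol=4, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
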