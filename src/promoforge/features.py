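"""Numeric sequence encodings: one-hot and pseudo-dinucleotide composition.

One-hot encoding maps each base to a 4-dimensional indicator (column order
A, C, G, T) and flattens positions row-major, so a 50-bp promoter becomes a
200-dimensional binary vector.  Pseudo-dinucleotide composition (pseDNC)
augments the 16 dinucleotide frequencies with lambda autocorrelation terms
computed from standardized local structural properties of dinucleotide
steps (twist, tilt, roll, shift, slide, rise by default); the resulting
16 + lambda vector sums to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .seqdata import DNA_ALPHABET, SequenceDataset

__all__ = [
    "Encoding", "FeatureMatrix", "PseDNCParams", "one_hot_encode",
    "one_hot_decode", "one_hot_encode_dataset", "psednc", "psednc_dataset",
    "concat_features", "load_property_table", "DINUCLEOTIDES",
]

_BASE_INDEX = {b: i for i, b in enumerate(DNA_ALPHABET)}
DINUCLEOTIDES = [a + b for a in DNA_ALPHABET for b in DNA_ALPHABET]
_DINUC_INDEX = {d: i for i, d in enumerate(DINUCLEOTIDES)}


class Encoding(str, Enum):
    ONEHOT = "onehot"
    PSEDNC = "psednc"
    CONCAT = "concat"


@dataclass
class FeatureMatrix:
    """A batch of encoded sequences: n_samples x n_features."""

    values: np.ndarray
    encoding: Encoding
    sequence_length: int | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def load_property_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load the 16 x P dinucleotide property table and standardize each
    property column to mean 0, sd 1 (population sd over the 16 steps)."""
    if path is None:
        src = resources.files("promoforge").joinpath("data/dna_properties.csv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, index_col=0)
    else:
        df = pd.read_csv(path, index_col=0)
    if list(df.index) != DINUCLEOTIDES:
        df = df.reindex(DINUCLEOTIDES)
        if df.isna().any().any():
            raise ValueError("property table must cover all 16 dinucleotides")
    return (df - df.mean()) / df.std(ddof=0)


@dataclass
class PseDNCParams:
    """Parameters of the pseudo-dinucleotide composition.

    lam : number of correlation tiers (sequence must be longer than lam+1)
    weight : weight w balancing frequency vs correlation components
    property_table : standardized 16 x P table; defaults to the packaged
        six-property local-structure set.
    """

    lam: int = 3
    weight: float = 0.05
    property_table: pd.DataFrame = field(default_factory=load_property_table)

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.weight <= 0:
            raise ValueError("weight must be > 0")
        self._props = self.property_table.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# one-hot
# ---------------------------------------------------------------------------

def one_hot_encode(sequence: str) -> np.ndarray:
    """Encode a DNA string as a flattened L x 4 indicator matrix."""
    try:
        idx = np.array([_BASE_INDEX[b] for b in sequence], dtype=int)
    except KeyError as exc:
        raise ValueError(f"invalid character {exc.args[0]!r} in sequence") from None
    out = np.zeros((len(sequence), 4))
    out[np.arange(len(sequence)), idx] = 1.0
    return out.ravel()


def one_hot_decode(matrix: np.ndarray) -> str:
    """Decode an L x 4 (or flattened) real matrix back to a DNA string by
    per-position argmax; ties resolve alphabetically (A < C < G < T)."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim == 1:
        if m.size % 4:
            raise ValueError("flattened one-hot length must be a multiple of 4")
        m = m.reshape(-1, 4)
    if m.shape[1] != 4:
        raise ValueError(f"expected 4 columns (A,C,G,T), got {m.shape[1]}")
    return "".join(DNA_ALPHABET[i] for i in m.argmax(axis=1))


def one_hot_encode_dataset(dataset: SequenceDataset) -> FeatureMatrix:
    seqs = dataset.sequences()
    if not seqs:
        raise ValueError("empty dataset")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("one-hot batch encoding requires fixed-length sequences")
    values = np.stack([one_hot_encode(s) for s in seqs])
    return FeatureMatrix(values, Encoding.ONEHOT, sequence_length=lengths.pop())


# ---------------------------------------------------------------------------
# pseDNC
# ---------------------------------------------------------------------------

def _theta(params: PseDNCParams, seq_idx: np.ndarray) -> np.ndarray:
    """Tier correlations theta_1..theta_lam.

    Theta(d1, d2) is the mean over property columns of the squared
    difference; theta_j averages Theta over all dinucleotide pairs j steps
    apart along the sequence.
    """
    props = params._props
    thetas = np.empty(params.lam)
    n_dinucs = len(seq_idx)
    for j in range(1, params.lam + 1):
        diff = props[seq_idx[:n_dinucs - j]] - props[seq_idx[j:]]
        thetas[j - 1] = np.mean(diff ** 2, axis=1).mean()
    return thetas


def psednc(sequence: str, params: PseDNCParams | None = None) -> np.ndarray:
    """Pseudo-dinucleotide composition vector of length 16 + lam.

    First 16 entries: d_u = f_u / (1 + w * sum(theta)); last lam entries:
    d_{16+j} = w * theta_j / (1 + w * sum(theta)).  Components sum to 1.
    """
    params = params or PseDNCParams()
    if len(sequence) < params.lam + 2:
        raise ValueError(
            f"sequence length {len(sequence)} too short for lam={params.lam}"
        )
    try:
        seq_idx = np.array([_DINUC_INDEX[sequence[i:i + 2]]
                            for i in range(len(sequence) - 1)], dtype=int)
    except KeyError as exc:
        raise ValueError(f"invalid dinucleotide {exc.args[0]!r}") from None
    freqs = np.bincount(seq_idx, minlength=16).astype(float)
    freqs /= freqs.sum()
    thetas = _theta(params, seq_idx) if params.lam else np.empty(0)
    denom = 1.0 + params.weight * thetas.sum()
    return np.concatenate([freqs / denom, params.weight * thetas / denom])


def psednc_dataset(dataset: SequenceDataset,
                   params: PseDNCParams | None = None) -> FeatureMatrix:
    params = params or PseDNCParams()
    values = np.stack([psednc(s, params) for s in dataset.sequences()])
    return FeatureMatrix(values, Encoding.PSEDNC)


def concat_features(a: FeatureMatrix, b: FeatureMatrix) -> FeatureMatrix:
    """Horizontal concatenation of two encodings of the same sample batch."""
    if a.n_samples != b.n_samples:
        raise ValueError(
            f"sample count mismatch: {a.n_samples} vs {b.n_samples}"
        )
    return FeatureMatrix(np.hstack([a.values, b.values]), Encoding.CONCAT,
                         sequence_length=a.sequence_length)
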