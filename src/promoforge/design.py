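"""Promoter design front-ends.

* **Ndesign** (`generate_constrained`): random 50-mers with the conserved
  sigma70 hexamers fixed — TTGACA at the -35 box, TATAAT at the -10 box —
  a spacer of 16-18 bp between them, and a short downstream pad, all free
  positions i.i.d. uniform over ACGT.
* **DRSAdesign** (`drsa_screen`): the screening cascade over generated
  candidates — keep sequences a real/fake classifier calls real, then
  those a strong/weak classifier scores above 0.9, rank by predicted
  activity and keep the top 50.
* **6-mer scan** (`scan_kmers`): hold one hexamer box fixed, substitute
  each of the 4096 possible 6-mers into the other box across random
  sequence contexts, and record how often the resulting sequences are
  predicted real and strong.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .seqdata import DNA_ALPHABET, PromoterRecord, SequenceDataset
from .supervised import TrainedModel, predict_sequences

__all__ = [
    "DesignConstraints", "Candidate", "KmerReport", "generate_constrained",
    "check_constraints", "drsa_screen", "scan_kmers", "kmer_summary",
    "binding_table_comparison", "all_kmers", "write_candidates",
]


@dataclass(frozen=True)
class DesignConstraints:
    """Sigma70 layout of a designed promoter.

    Within the ``total_length``-mer the layout is::

        upstream pad | minus35 | spacer (s nt) | minus10 | downstream pad

    with the spacer length s drawn from ``spacer_lengths`` and the
    upstream pad absorbing whatever length remains.
    """

    minus35: str = "TTGACA"
    minus10: str = "TATAAT"
    spacer_lengths: tuple[int, ...] = (16, 17, 18)
    downstream_length: int = 6
    total_length: int = 50

    def __post_init__(self) -> None:
        for name in ("minus35", "minus10"):
            motif = getattr(self, name)
            if set(motif) - set(DNA_ALPHABET) or len(motif) != 6:
                raise ValueError(f"{name} must be a DNA 6-mer, got {motif!r}")
        if not self.spacer_lengths:
            raise ValueError("spacer_lengths must be non-empty")
        for s in self.spacer_lengths:
            if self.upstream_length(s) < 0:
                raise ValueError(
                    f"infeasible layout: spacer {s} leaves negative upstream pad"
                )

    def upstream_length(self, spacer: int) -> int:
        return (self.total_length - len(self.minus35) - spacer
                - len(self.minus10) - self.downstream_length)


@dataclass(frozen=True)
class Candidate:
    sequence: str
    p_real: float | None = None
    p_strong: float | None = None
    predicted_activity: float | None = None
    spacer_used: int | None = None

    def __post_init__(self) -> None:
        for name in ("p_real", "p_strong"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class KmerReport:
    kmer: str
    position_role: str                    # "minus10" or "minus35"
    n_contexts: int
    fraction_real: float
    fraction_strong: float


def all_kmers(k: int = 6) -> list[str]:
    kmers = [""]
    for _ in range(k):
        kmers = [s + b for s in kmers for b in DNA_ALPHABET]
    return kmers


# ---------------------------------------------------------------------------
# constraint-based generation
# ---------------------------------------------------------------------------

def generate_constrained(constraints: DesignConstraints | None = None,
                         n: int = 1, seed: int = 0,
                         id_prefix: str = "ndesign") -> SequenceDataset:
    """Generate ``n`` constrained sigma70 promoters (uniform spacer choice,
    uniform bases at free positions); deterministic under ``seed``."""
    constraints = constraints or DesignConstraints()
    rng = np.random.default_rng(seed)
    bases = np.array(list(DNA_ALPHABET))
    spacers = rng.choice(constraints.spacer_lengths, size=n)
    records = []
    for i, s in enumerate(spacers):
        up = constraints.upstream_length(int(s))
        n_free = up + int(s) + constraints.downstream_length
        free = bases[rng.integers(0, 4, size=n_free)]
        seq = ("".join(free[:up]) + constraints.minus35
               + "".join(free[up:up + s]) + constraints.minus10
               + "".join(free[up + s:]))
        records.append(PromoterRecord(id=f"{id_prefix}_{i}", sequence=seq,
                                      source="constrained"))
    ds = SequenceDataset(records, fixed_length=constraints.total_length)
    return ds


def check_constraints(sequence: str,
                      constraints: DesignConstraints | None = None) -> int | None:
    """Return the spacer length if the sequence matches the constrained
    layout for some allowed spacer, else None."""
    constraints = constraints or DesignConstraints()
    if len(sequence) != constraints.total_length:
        return None
    for s in constraints.spacer_lengths:
        up = constraints.upstream_length(s)
        m35 = sequence[up:up + 6]
        m10 = sequence[up + 6 + s:up + 12 + s]
        if m35 == constraints.minus35 and m10 == constraints.minus10:
            return s
    return None


# ---------------------------------------------------------------------------
# DRSAdesign screening cascade
# ---------------------------------------------------------------------------

def _scores(model, sequences: Sequence[str]) -> np.ndarray:
    if isinstance(model, TrainedModel):
        return predict_sequences(model, sequences)
    return np.asarray(model(sequences), dtype=float)


def drsa_screen(sequences: Sequence[str], promor, promos, promoa,
                real_threshold: float = 0.5, strong_threshold: float = 0.9,
                top_k: int = 50) -> list[Candidate]:
    """Filter/rank/truncate cascade over candidate promoters.

    Keep candidates whose real-score exceeds ``real_threshold``, of those
    keep strong-score > ``strong_threshold``, rank by predicted activity
    (descending, ties broken lexicographically by sequence) and keep the
    top ``top_k``.
    """
    if not sequences:
        raise ValueError("empty candidate list")
    seqs = list(sequences)
    p_real = _scores(promor, seqs)
    p_strong = _scores(promos, seqs)
    activity = _scores(promoa, seqs)
    candidates = [
        Candidate(sequence=s, p_real=float(r), p_strong=float(st),
                  predicted_activity=float(a))
        for s, r, st, a in zip(seqs, p_real, p_strong, activity)
    ]
    passing = [c for c in candidates
               if c.p_real > real_threshold and c.p_strong > strong_threshold]
    passing.sort(key=lambda c: (-c.predicted_activity, c.sequence))
    return passing[:top_k]


def write_candidates(candidates: Sequence[Candidate], fasta_path: str | Path,
                     csv_path: str | Path) -> None:
    """Write screened candidates as FASTA plus a CSV score table."""
    from .seqdata import write_fasta
    ds = SequenceDataset.from_records(
        PromoterRecord(id=f"cand_{i}", sequence=c.sequence)
        for i, c in enumerate(candidates)
    )
    write_fasta(ds, fasta_path)
    pd.DataFrame([{
        "sequence": c.sequence, "p_real": c.p_real, "p_strong": c.p_strong,
        "predicted_activity": c.predicted_activity, "spacer": c.spacer_used,
    } for c in candidates]).to_csv(csv_path, index=False)


# ---------------------------------------------------------------------------
# 6-mer functional-motif scan
# ---------------------------------------------------------------------------

def scan_kmers(position_role: str, fixed_motif: str, promor, promos,
               spacer: int = 17, n_contexts: int = 100, seed: int = 0,
               strong_threshold: float = 0.5,
               constraints: DesignConstraints | None = None,
               kmers: Sequence[str] | None = None) -> list[KmerReport]:
    """Score every 6-mer as a candidate promoter box.

    ``position_role`` names the box being varied ("minus10" or "minus35");
    ``fixed_motif`` occupies the other box.  For each 6-mer, ``n_contexts``
    random constrained sequences are built with spacer ``spacer`` and
    scored by the real/fake and strong/weak classifiers at threshold 0.5.
    """
    if position_role not in ("minus10", "minus35"):
        raise ValueError("position_role must be 'minus10' or 'minus35'")
    if len(fixed_motif) != 6 or set(fixed_motif) - set(DNA_ALPHABET):
        raise ValueError(f"fixed_motif must be a DNA 6-mer, got {fixed_motif!r}")
    base = constraints or DesignConstraints()
    kmer_list = list(kmers) if kmers is not None else all_kmers(6)
    rng = np.random.default_rng(seed)
    reports = []
    for kmer in kmer_list:
        if position_role == "minus10":
            c = DesignConstraints(minus35=fixed_motif, minus10=kmer,
                                  spacer_lengths=(spacer,),
                                  downstream_length=base.downstream_length,
                                  total_length=base.total_length)
        else:
            c = DesignConstraints(minus35=kmer, minus10=fixed_motif,
                                  spacer_lengths=(spacer,),
                                  downstream_length=base.downstream_length,
                                  total_length=base.total_length)
        ds = generate_constrained(c, n_contexts,
                                  seed=int(rng.integers(0, 2 ** 31)),
                                  id_prefix=f"scan_{kmer}")
        seqs = ds.sequences()
        frac_real = float(np.mean(_scores(promor, seqs) > 0.5))
        frac_strong = float(np.mean(_scores(promos, seqs) > strong_threshold))
        reports.append(KmerReport(kmer=kmer, position_role=position_role,
                                  n_contexts=n_contexts,
                                  fraction_real=frac_real,
                                  fraction_strong=frac_strong))
    return reports


def kmer_summary(reports: Sequence[KmerReport],
                 chance_cut: float = 0.5) -> dict[str, float]:
    """Aggregate a 6-mer scan: the fraction of k-mers whose real-promoter
    chance strictly exceeds ``chance_cut``, the mean strong-promoter
    chance inside and outside that subset, and the fraction of k-mers
    that form real promoters in every context."""
    if not reports:
        raise ValueError("no k-mer reports")
    above = [r for r in reports if r.fraction_real > chance_cut]
    below = [r for r in reports if r.fraction_real <= chance_cut]
    out = {
        "n_kmers": len(reports),
        "fraction_above_cut": len(above) / len(reports),
        "fraction_at_100pct": sum(r.fraction_real == 1.0 for r in reports)
        / len(reports),
        "mean_strong_above": float(np.mean([r.fraction_strong for r in above]))
        if above else float("nan"),
        "mean_strong_below": float(np.mean([r.fraction_strong for r in below]))
        if below else float("nan"),
    }
    return out


def binding_table_comparison(reports: Sequence[KmerReport],
                             binding_table: Mapping[str, float],
                             n_extreme: int = 20,
                             real_cut: float = 0.95) -> dict[str, dict[str, float]]:
    """Stratify scan results by an external motif-binding ranking.

    ``binding_table`` maps 6-mers to a binding strength (higher =
    stronger).  For the ``n_extreme`` strongest- and weakest-binding
    motifs, report the fraction with real-promoter chance >= ``real_cut``,
    the fraction below 0.5, and the mean strong-promoter chance.
    """
    by_kmer = {r.kmer: r for r in reports}
    missing = [k for k in binding_table if k not in by_kmer]
    if missing:
        raise KeyError(f"motifs absent from scan reports: {missing[:5]}")
    ranked = sorted(binding_table, key=binding_table.__getitem__, reverse=True)
    groups = {"strongest": ranked[:n_extreme], "weakest": ranked[-n_extreme:]}
    out = {}
    for name, motifs in groups.items():
        if not motifs:
            raise ValueError(f"empty {name} binding group")
        rs = [by_kmer[m] for m in motifs]
        out[name] = {
            "n": len(rs),
            "fraction_real_ge_cut": float(np.mean(
                [r.fraction_real >= real_cut for r in rs])),
            "fraction_real_below_half": float(np.mean(
                [r.fraction_real < 0.5 for r in rs])),
            "mean_strong": float(np.mean([r.fraction_strong for r in rs])),
        }
    return out
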