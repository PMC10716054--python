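"""Shared fixtures: small synthetic datasets and stub scoring models."""

from __future__ import annotations

import numpy as np
import pytest

from promoforge.seqdata import PromoterRecord, SequenceDataset
from promoforge.synthetic import (SyntheticSpec, consensus_pwm,
                                  simulate_activity_dataset, simulate_real_fake)


@pytest.fixture(scope="session")
def activity_dataset() -> SequenceDataset:
    """200 synthetic promoters with ground-truth linear activity."""
    return simulate_activity_dataset(SyntheticSpec(n=200, seed=5))


@pytest.fixture(scope="session")
def realfake_dataset() -> SequenceDataset:
    """400 balanced real/fake records with fully conserved planted motifs."""
    spec = SyntheticSpec(n=400,
                         minus35_pwm=consensus_pwm("TTGACA", 1.0),
                         minus10_pwm=consensus_pwm("TATAAT", 1.0), seed=3)
    return simulate_real_fake(spec)


@pytest.fixture
def tiny_fasta(tmp_path):
    path = tmp_path / "tiny.fasta"
    path.write_text(">p1\nACGTACGTAC\n>p2\nttttccccgg\n")
    return path


def make_stub(score_fn):
    """A scoring stub with the callable interface drsa_screen/rpp accept."""
    def stub(sequences):
        return np.array([score_fn(s) for s in sequences], dtype=float)
    return stub


@pytest.fixture
def constant_stub():
    return lambda value: make_stub(lambda s: value)
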