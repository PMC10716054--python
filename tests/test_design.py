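"""Constraint-based generation, the screening cascade, and 6-mer scans."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.stats import chisquare

from promoforge.design import (Candidate, DesignConstraints, KmerReport,
                               all_kmers, binding_table_comparison,
                               check_constraints, drsa_screen,
                               generate_constrained, kmer_summary, scan_kmers)


class TestConstraints:
    def test_default_layout_arithmetic(self):
        c = DesignConstraints()
        assert c.upstream_length(16) == 16
        assert c.upstream_length(18) == 14

    def test_infeasible_layout_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            DesignConstraints(total_length=30, spacer_lengths=(18,))

    def test_non_hexamer_motifs_rejected(self):
        with pytest.raises(ValueError):
            DesignConstraints(minus35="TTGAC")
        with pytest.raises(ValueError):
            DesignConstraints(minus10="TATAAN")

    def test_candidate_probability_bounds(self):
        with pytest.raises(ValueError):
            Candidate(sequence="A" * 50, p_real=1.5)


class TestGeneration:
    def test_every_output_matches_the_constraint_checker(self):
        ds = generate_constrained(n=200, seed=1)
        spacers = [check_constraints(s) for s in ds.sequences()]
        assert all(s in (16, 17, 18) for s in spacers)
        assert ds.fixed_length == 50

    def test_motifs_at_declared_offsets(self):
        c = DesignConstraints(spacer_lengths=(16,))
        ds = generate_constrained(c, n=20, seed=0)
        for seq in ds.sequences():
            assert seq[16:22] == "TTGACA"
            assert seq[38:44] == "TATAAT"

    def test_deterministic_under_seed(self):
        a = generate_constrained(n=25, seed=9).sequences()
        b = generate_constrained(n=25, seed=9).sequences()
        assert a == b

    def test_free_positions_uniform_by_chisquare(self):
        ds = generate_constrained(n=12_000, seed=2)
        counts = np.zeros(4, dtype=int)
        base_idx = {b: i for i, b in enumerate("ACGT")}
        for seq in ds.sequences():
            s = check_constraints(seq)
            up = DesignConstraints().upstream_length(s)
            free = seq[:up] + seq[up + 6:up + 6 + s] + seq[up + 12 + s:]
            for b in free:
                counts[base_idx[b]] += 1
        assert chisquare(counts).pvalue > 0.01

    def test_spacer_choice_covers_configured_set(self):
        ds = generate_constrained(n=300, seed=3)
        assert {check_constraints(s) for s in ds.sequences()} == {16, 17, 18}


class TestScreeningCascade:
    def test_filter_rank_truncate_with_stub_scores(self):
        seqs = [b * 50 for b in "ACGT"] + ["AC" * 25, "AG" * 25,
                                           "AT" * 25, "CG" * 25, "CT" * 25,
                                           "GT" * 25]
        p_real = dict(zip(seqs, [0.9, 0.9, 0.9, 0.9, 0.9, 0.9, 0.2, 0.2,
                                 0.2, 0.2]))
        p_strong = dict(zip(seqs, [0.95, 0.95, 0.95, 0.95, 0.5, 0.5, 0.95,
                                   0.95, 0.5, 0.5]))
        act = {s: i * 1.0 for i, s in enumerate(seqs)}
        out = drsa_screen(seqs,
                          lambda ss: np.array([p_real[s] for s in ss]),
                          lambda ss: np.array([p_strong[s] for s in ss]),
                          lambda ss: np.array([act[s] for s in ss]))
        assert len(out) == 4
        activities = [c.predicted_activity for c in out]
        assert activities == sorted(activities, reverse=True)

    def test_no_candidate_passes_strong_filter(self, constant_stub):
        out = drsa_screen(["A" * 50, "C" * 50], constant_stub(1.0),
                          constant_stub(0.9), constant_stub(1.0))
        assert out == []   # p_strong must strictly exceed 0.9

    def test_truncation_to_top_k(self, constant_stub):
        seqs = [f"{b1}{b2}" * 25 for b1 in "ACGT" for b2 in "ACGT"][:10]
        out = drsa_screen(seqs, constant_stub(1.0), constant_stub(1.0),
                          lambda ss: np.arange(len(ss), dtype=float),
                          top_k=3)
        assert len(out) == 3

    def test_empty_candidate_list_rejected(self, constant_stub):
        with pytest.raises(ValueError, match="empty"):
            drsa_screen([], constant_stub(1), constant_stub(1),
                        constant_stub(1))

    def test_all_threshold_crossing_patterns_of_four_candidates(
            self, constant_stub):
        """Exhaustive filter/rank/truncate contract over all 2^4 patterns
        of (passes-real, passes-strong) per candidate."""
        seqs = ["A" * 50, "C" * 50, "G" * 50, "T" * 50]
        for pattern in itertools.product([True, False], repeat=4):
            real = {s: 0.9 if ok else 0.1 for s, ok in zip(seqs, pattern)}
            for strong_pattern in itertools.product([True, False], repeat=4):
                strong = {s: 0.95 if ok else 0.5
                          for s, ok in zip(seqs, strong_pattern)}
                out = drsa_screen(
                    seqs, lambda ss: np.array([real[s] for s in ss]),
                    lambda ss: np.array([strong[s] for s in ss]),
                    lambda ss: np.array([float(len(s)) for s in ss]),
                    top_k=50)
                expected = {s for s, r, st in zip(seqs, pattern,
                                                  strong_pattern)
                            if r and st}
                assert {c.sequence for c in out} == expected
                # equal activities: ties broken lexicographically
                assert [c.sequence for c in out] == sorted(
                    c.sequence for c in out)

    def test_monotone_in_thresholds(self, constant_stub):
        rng = np.random.default_rng(0)
        seqs = [f"{a}{b}" * 25 for a in "ACGT" for b in "ACGT"]
        scores = dict(zip(seqs, rng.random(len(seqs))))
        stub = lambda ss: np.array([scores[s] for s in ss])
        loose = drsa_screen(seqs, stub, stub, stub, real_threshold=0.3,
                            strong_threshold=0.3)
        tight = drsa_screen(seqs, stub, stub, stub, real_threshold=0.6,
                            strong_threshold=0.6)
        assert {c.sequence for c in tight} <= {c.sequence for c in loose}


class TestKmerScan:
    def test_scan_reports_all_kmers_with_count_grid_fractions(self):
        kmers = ["TATAAT", "AAAAAA", "TTGACA", "CCCCCC"]
        promor = lambda ss: np.array([1.0 if "TATAAT" in s else 0.0
                                      for s in ss])
        promos = lambda ss: np.array([0.9] * len(ss))
        reports = scan_kmers("minus10", "TTGACA", promor, promos,
                             n_contexts=4, seed=0, kmers=kmers)
        assert len(reports) == 4
        by_kmer = {r.kmer: r for r in reports}
        assert by_kmer["TATAAT"].fraction_real == 1.0
        assert all(r.fraction_real in {0.0, 0.25, 0.5, 0.75, 1.0}
                   for r in reports)
        assert all(r.fraction_strong == 1.0 for r in reports)

    def test_full_enumeration_has_4096_kmers(self):
        assert len(all_kmers(6)) == 4096
        assert all_kmers(6)[0] == "AAAAAA" and all_kmers(6)[-1] == "TTTTTT"

    def test_single_context_scan_equals_brute_force(self, constant_stub):
        """With n_contexts=1 and a deterministic length-based stub the scan
        is exactly one constrained sequence per k-mer."""
        kmers = ["AAAAAA", "ACGTAC", "TTTTTT"]
        seen = []
        promor = lambda ss: (seen.extend(ss), np.ones(len(ss)))[1]
        reports = scan_kmers("minus35", "TATAAT", promor,
                             constant_stub(0.0), n_contexts=1, seed=1,
                             kmers=kmers)
        assert len(seen) == 3
        for kmer, seq in zip(kmers, seen):
            up = DesignConstraints().upstream_length(17)
            assert seq[up:up + 6] == kmer          # variable -35 box
            assert seq[up + 23:up + 29] == "TATAAT"

    def test_invalid_role_and_motif_rejected(self, constant_stub):
        with pytest.raises(ValueError, match="position_role"):
            scan_kmers("minus20", "TTGACA", constant_stub(1),
                       constant_stub(1))
        with pytest.raises(ValueError, match="6-mer"):
            scan_kmers("minus10", "TTGAC", constant_stub(1),
                       constant_stub(1))


class TestKmerSummary:
    def _report(self, kmer, fr, fs=0.5):
        return KmerReport(kmer=kmer, position_role="minus10", n_contexts=10,
                          fraction_real=fr, fraction_strong=fs)

    def test_all_real_gives_unit_fractions(self):
        reports = [self._report(k, 1.0) for k in ("AAAAAA", "CCCCCC")]
        s = kmer_summary(reports, chance_cut=0.5)
        assert s["fraction_above_cut"] == 1.0
        assert s["fraction_at_100pct"] == 1.0

    def test_counting_three_of_four(self):
        reports = [self._report("AAAAAA", 0.9), self._report("CCCCCC", 0.8),
                   self._report("GGGGGG", 0.6), self._report("TTTTTT", 0.2)]
        s = kmer_summary(reports, chance_cut=0.5)
        assert s["fraction_above_cut"] == 0.75

    def test_subset_and_complement_cover_total(self):
        rng = np.random.default_rng(1)
        reports = [self._report(k, float(f))
                   for k, f in zip(all_kmers(3), rng.random(64))]
        s = kmer_summary(reports, chance_cut=0.5)
        above = round(s["fraction_above_cut"] * 64)
        below = 64 - above
        assert above + below == s["n_kmers"] == 64

    def test_empty_reports_rejected(self):
        with pytest.raises(ValueError):
            kmer_summary([])


class TestBindingTable:
    def _reports(self):
        return [KmerReport(kmer=k, position_role="minus10", n_contexts=10,
                           fraction_real=fr, fraction_strong=0.6)
                for k, fr in [("TATAAT", 1.0), ("TATGAT", 0.9),
                              ("CCCCCC", 0.1), ("GGGGGG", 0.2)]]

    def test_stratified_groups(self):
        # synthetic binding ranking (stand-in for an external table)
        table = {"TATAAT": 4.0, "TATGAT": 3.0, "CCCCCC": 2.0, "GGGGGG": 1.0}
        out = binding_table_comparison(self._reports(), table, n_extreme=2)
        assert out["strongest"]["fraction_real_ge_cut"] == 0.5
        assert out["weakest"]["fraction_real_below_half"] == 1.0

    def test_unknown_motif_raises(self):
        with pytest.raises(KeyError, match="absent"):
            binding_table_comparison(self._reports(), {"ACGTAC": 1.0})
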