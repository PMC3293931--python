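"""Duplex scanning: energy model, global DP, placement enumeration oracle."""

import itertools

import numpy as np
import pytest

from ptaref.duplex_finder import (CandidateSite, DuplexTrace, EnergyModel,
                                  dedup_overlapping, duplex_dp,
                                  find_candidate_sites, parse_external_sites,
                                  score_trace)
from ptaref.errors import BackendUnavailableError, InvariantError
from ptaref.fixtures import make_transcripts, reverse_complement
from ptaref.sequence_io import MiRNARecord, TranscriptRecord

MODEL = EnergyModel()


def _random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def brute_force_duplex_energy(x: str, mirna: str, model: EnergyModel) -> float:
    """Minimum energy over ALL global duplex alignments, by explicit
    recursion over alignment paths with affine bulge pricing."""
    y = mirna[::-1]
    best = [float("inf")]

    def rec(i, j, prev_gap, acc):
        if i == len(x) and j == len(y):
            best[0] = min(best[0], acc)
            return
        if i < len(x) and j < len(y):
            rec(i + 1, j + 1, None, acc + model.column_energy(x[i], y[j]))
        if i < len(x):  # target base bulges (gap in miRNA strand)
            cost = model.bulge_extend if prev_gap == "t" else model.bulge_open
            rec(i + 1, j, "t", acc + cost)
        if j < len(y):  # miRNA base bulges (gap in target strand)
            cost = model.bulge_extend if prev_gap == "m" else model.bulge_open
            rec(i, j + 1, "m", acc + cost)

    rec(0, 0, None, 0.0)
    return best[0]


def enumerate_placements_naive(seq: str, mirna: str, model: EnergyModel):
    """(energy, start, end) of every ungapped and single-interior-bulge
    placement, by plain double loops (the scanner's search space)."""
    y = mirna[::-1]
    m, L = len(y), len(seq)
    out = []
    for o in range(L - m + 1):
        e = sum(model.column_energy(seq[o + k], y[k]) for k in range(m))
        out.append((e, o, o + m))
    for o in range(L - m):  # one target base bulges at window position p
        for p in range(1, m):
            e = model.bulge_open
            e += sum(model.column_energy(seq[o + k], y[k]) for k in range(p))
            e += sum(model.column_energy(seq[o + 1 + k], y[k]) for k in range(p, m))
            out.append((e, o, o + m + 1))
    for o in range(L - m + 2):  # one miRNA base (index q, 3'->5') bulges
        if o + m - 1 > L:
            continue
        for q in range(1, m - 1):
            e = model.bulge_open
            e += sum(model.column_energy(seq[o + k], y[k]) for k in range(q))
            e += sum(model.column_energy(seq[o + k], y[k + 1]) for k in range(q, m - 1))
            out.append((e, o, o + m - 1))
    return out


# ---------------------------------------------------------------------------
# duplex_dp
# ---------------------------------------------------------------------------

class TestDuplexDP:
    def test_perfect_complement_energy(self):
        trace, energy = duplex_dp("ACGU", "ACGU", MODEL)
        # antiparallel columns: A:U, C:G, G:C, U:A -> -(2+3+3+2)
        assert energy == -10.0
        assert trace.column_states() == ["M", "M", "M", "M"]

    def test_near_complement_matches_enumeration(self):
        # Best duplex of ACGU vs ACGG: one A:G mismatch plus C:G, G:C, U:A.
        trace, energy = duplex_dp("ACGU", "ACGG", MODEL)
        assert energy == brute_force_duplex_energy("ACGU", "ACGG", MODEL) == -7.0
        assert trace.column_states().count("M") == 3

    def test_empty_window_is_an_error(self):
        with pytest.raises(InvariantError):
            duplex_dp("", "ACGU", MODEL)

    def test_trace_energy_consistent_with_rescoring(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            x = _random_rna(rng, int(rng.integers(4, 16)))
            y = _random_rna(rng, int(rng.integers(4, 12)))
            trace, energy = duplex_dp(x, y, MODEL)
            assert score_trace(trace, MODEL) == pytest.approx(energy, abs=1e-9)
            assert trace.target_seq == x
            assert trace.mirna_seq_3to5 == y[::-1]

    @pytest.mark.parametrize("seed", range(8))
    def test_dp_equals_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        nx = int(rng.integers(3, 13))
        ny = int(rng.integers(3, 9))
        x, y = _random_rna(rng, nx), _random_rna(rng, ny)
        _, energy = duplex_dp(x, y, MODEL)
        assert energy == pytest.approx(brute_force_duplex_energy(x, y, MODEL), abs=1e-9)

    def test_double_gap_column_rejected(self):
        with pytest.raises(InvariantError):
            DuplexTrace("A-C", "U-G")


# ---------------------------------------------------------------------------
# find_candidate_sites
# ---------------------------------------------------------------------------

class TestFindCandidateSites:
    def test_planted_perfect_complement_found_at_exact_coordinates(self):
        rng = np.random.default_rng(7)
        mirna = MiRNARecord("mir", _random_rna(rng, 21))
        site = reverse_complement(mirna.seq)
        background = _random_rna(rng, 150)
        seq = background[:30] + site + background[51:]
        t = TranscriptRecord("t", seq)
        sites = find_candidate_sites(t, mirna)
        # the planted duplex pairs every column; recompute from the model
        expected = sum(MODEL.column_energy(a, b) for a, b in zip(site, mirna.seq[::-1]))
        planted = [s for s in sites if s.start == 30 and s.end == 51]
        assert len(planted) == 1
        assert planted[0].energy == pytest.approx(expected)
        assert planted[0].energy < -10
        assert planted[0].energy == min(s.energy for s in sites)

    def test_homopolymer_has_no_sites(self):
        t = TranscriptRecord("t", "A" * 150)
        m = MiRNARecord("m", "A" * 21)
        assert find_candidate_sites(t, m) == []

    def test_transcript_shorter_than_mirna_yields_empty(self):
        t = TranscriptRecord("t", "ACGUACGUAC")
        m = MiRNARecord("m", "ACGUACGUACGUACGUACGUA")
        assert find_candidate_sites(t, m) == []

    @pytest.mark.parametrize("seed", range(25))
    def test_minimum_energy_equals_placement_enumeration_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        t = TranscriptRecord("t", _random_rna(rng, 40))
        m = MiRNARecord("m", _random_rna(rng, 15))
        oracle = enumerate_placements_naive(t.seq, m.seq, MODEL)
        cutoff = -1e-6  # admit everything so minima are comparable
        sites = find_candidate_sites(t, m, energy_cutoff=cutoff, dedup=False)
        if not sites:
            assert min(e for e, _, _ in oracle) > cutoff
        else:
            assert min(s.energy for s in sites) == pytest.approx(
                min(e for e, _, _ in oracle), abs=1e-9)

    def test_site_energy_matches_trace_rescoring(self):
        rng = np.random.default_rng(5)
        t = TranscriptRecord("t", _random_rna(rng, 120))
        m = MiRNARecord("m", _random_rna(rng, 21))
        for s in find_candidate_sites(t, m, energy_cutoff=-3.0, dedup=False):
            assert score_trace(s.trace, MODEL) == pytest.approx(s.energy, abs=1e-9)

    def test_relaxing_cutoff_never_removes_sites(self):
        rng = np.random.default_rng(11)
        t = TranscriptRecord("t", _random_rna(rng, 200))
        m = MiRNARecord("m", _random_rna(rng, 21))
        strict = {(s.start, s.end) for s in find_candidate_sites(t, m, -10.0)}
        relaxed = {(s.start, s.end) for s in find_candidate_sites(t, m, -5.0)}
        assert strict <= relaxed

    def test_overlap_dedup_keeps_minimum_energy_representative(self):
        a = CandidateSite("t", "m", 10, 31, -20.0)
        b = CandidateSite("t", "m", 15, 36, -12.0)   # overlaps a, worse
        c = CandidateSite("t", "m", 60, 81, -11.0)   # disjoint
        kept = dedup_overlapping([b, c, a])
        assert [(s.start, s.energy) for s in kept] == [(10, -20.0), (60, -11.0)]

    def test_external_backend_requires_hybridizer(self):
        t = TranscriptRecord("t", "ACGU" * 30)
        m = MiRNARecord("m", "ACGUACGUACGUACGUACGUA")
        with pytest.raises(BackendUnavailableError):
            find_candidate_sites(t, m, backend="external")

    def test_external_records_parsed_and_filtered(self):
        t = TranscriptRecord("t", "ACGU" * 30)
        m = MiRNARecord("m", "ACGUACGUACGUACGUACGUA")
        site = "ACGUACGUACGUACGUACGUA"

        def hybridizer(transcript, mirna, cutoff):
            text = ("# comment\n"
                    f"4\t-25.0\t{site}\t{'U' * 21}\n"
                    f"40\t-6.0\t{site}\t{'U' * 21}\n")
            return parse_external_sites(text)

        sites = find_candidate_sites(t, m, backend="external", hybridizer=hybridizer)
        assert [(s.start, s.energy) for s in sites] == [(4, -25.0)]
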