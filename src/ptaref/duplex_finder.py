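"""Candidate miRNA:target site discovery under a binding free-energy cutoff.

Production pipelines often delegate hybridization to a dedicated external
tool; this module makes the stage pluggable.  The internal backend scans every placement
of the miRNA along the transcript — ungapped, or carrying a single interior
bulge on either strand — under a simple nearest-pair energy model, and keeps
placements whose total energy clears the cutoff (default -10 kcal/mol).  An
external hybridizer can be supplied instead; its per-site records are parsed
into the same :class:`CandidateSite` objects, so everything downstream
(pattern encoding, SVR scoring) is backend-agnostic.

The energy model is configuration, not biology: per-pair stabilities and
bulge penalties are stand-in defaults chosen so that a near-perfect ~21-mer
duplex passes the default cutoff comfortably while short or heavily
mismatched placements do not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import BackendUnavailableError, InvariantError
from .sequence_io import MiRNARecord, TranscriptRecord

MAX_SITE_LEN = 50  # a miRNA:target interaction stays below 50 bp

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
_WC_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
_WOBBLE_PAIRS = {("G", "U"), ("U", "G")}

GAP = "-"


@dataclass(frozen=True)
class EnergyModel:
    """Nearest-pair duplex energies in kcal/mol (negative = stabilizing).

    ``bulge_open`` is the cost of the first base of a bulge run and
    ``bulge_extend`` of each additional base.
    """

    gc: float = -3.0
    au: float = -2.0
    gu: float = -1.0
    mismatch_penalty: float = 1.0
    bulge_open: float = 3.0
    bulge_extend: float = 1.0

    def __post_init__(self) -> None:
        if not (self.gc < 0 and self.au < 0 and self.gu < 0):
            raise InvariantError("pairing energies must be negative")
        if not (self.mismatch_penalty > 0 and self.bulge_open > 0 and self.bulge_extend > 0):
            raise InvariantError("mismatch/bulge penalties must be positive")

    def column_energy(self, target_base: str, mirna_base: str) -> float:
        p = (target_base, mirna_base)
        if p in _WC_PAIRS:
            return self.gc if "G" in p else self.au
        if p in _WOBBLE_PAIRS:
            return self.gu
        return self.mismatch_penalty

    def lut(self) -> np.ndarray:
        """4x4 energy lookup table indexed by (target code, miRNA code)."""
        bases = "ACGU"
        out = np.empty((4, 4), dtype=np.float64)
        for i, t in enumerate(bases):
            for j, m in enumerate(bases):
                out[i, j] = self.column_energy(t, m)
        return out


def pair_state(target_base: str, mirna_base: str) -> str:
    """Column state for two paired bases: M (Watson-Crick), W (G:U), X."""
    p = (target_base, mirna_base)
    if p in _WC_PAIRS:
        return "M"
    if p in _WOBBLE_PAIRS:
        return "W"
    return "X"


@dataclass(frozen=True)
class DuplexTrace:
    """A gapped duplex alignment.

    ``aligned_target`` reads 5'->3'; ``aligned_mirna`` is the miRNA written
    3'->5' so that column i of one string pairs with column i of the other
    (antiparallel geometry).  No column may carry gaps on both strands.
    """

    aligned_target: str
    aligned_mirna: str

    def __post_init__(self) -> None:
        if len(self.aligned_target) != len(self.aligned_mirna):
            raise InvariantError("gapped strands differ in length")
        if not self.aligned_target or not self.aligned_mirna:
            raise InvariantError("empty duplex trace")
        for i, (t, m) in enumerate(zip(self.aligned_target, self.aligned_mirna)):
            if t == GAP and m == GAP:
                raise InvariantError(f"column {i}: gap on both strands")

    def __len__(self) -> int:
        return len(self.aligned_target)

    @property
    def target_seq(self) -> str:
        return self.aligned_target.replace(GAP, "")

    @property
    def mirna_seq_3to5(self) -> str:
        return self.aligned_mirna.replace(GAP, "")

    def column_states(self) -> List[str]:
        """Per-column states: M/W/X for paired columns, T for a gap on the
        miRNA strand (target base bulges), O for a gap on the target strand
        (miRNA base bulges)."""
        states = []
        for t, m in zip(self.aligned_target, self.aligned_mirna):
            if m == GAP:
                states.append("T")
            elif t == GAP:
                states.append("O")
            else:
                states.append(pair_state(t, m))
        return states


def score_trace(trace: DuplexTrace, model: EnergyModel) -> float:
    """Re-score a trace column by column (bulge runs priced open + extends)."""
    energy = 0.0
    prev_gap = None  # which strand the previous column's gap was on
    for t, m in zip(trace.aligned_target, trace.aligned_mirna):
        if t == GAP or m == GAP:
            side = "target" if t == GAP else "mirna"
            energy += model.bulge_extend if prev_gap == side else model.bulge_open
            prev_gap = side
        else:
            energy += model.column_energy(t, m)
            prev_gap = None
    return energy


@dataclass(frozen=True)
class CandidateSite:
    """A putative target site: transcript coordinates (0-based half-open),
    duplex free energy and the duplex trace that produced it."""

    transcript_id: str
    mirna_id: str
    start: int
    end: int
    energy: float
    trace: Optional[DuplexTrace] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise InvariantError(f"bad site coordinates [{self.start}, {self.end})")
        if self.end - self.start > MAX_SITE_LEN:
            raise InvariantError(f"site longer than {MAX_SITE_LEN} nt")


# ---------------------------------------------------------------------------
# Internal DP duplex aligner (global, affine bulges)
# ---------------------------------------------------------------------------

_INF = float("inf")


def duplex_dp(
    target_window: str,
    mirna: str,
    model: Optional[EnergyModel] = None,
) -> Tuple[DuplexTrace, float]:
    """Global antiparallel duplex alignment minimizing free energy.

    The miRNA (given 5'->3') is reversed so that aligned columns are the
    antiparallel pairing partners.  States: paired column (Watson-Crick,
    wobble or mismatch), bulge on target (gap in miRNA strand), bulge on
    miRNA (gap in target strand); bulges are affine (open + extend).  Ties
    are broken deterministically: paired column, then bulge-on-target, then
    bulge-on-miRNA.
    """
    if model is None:
        model = EnergyModel()
    if not target_window or not mirna:
        raise InvariantError("duplex_dp requires non-empty sequences")
    if len(target_window) > MAX_SITE_LEN:
        raise InvariantError(f"target window longer than {MAX_SITE_LEN} nt")

    x = target_window
    y = mirna[::-1]  # 3'->5', columns pair antiparallel
    n, m = len(x), len(y)
    op, ex = model.bulge_open, model.bulge_extend

    # M = paired column, T = gap in miRNA (target bulge), O = gap in target.
    M = np.full((n + 1, m + 1), _INF)
    T = np.full((n + 1, m + 1), _INF)
    O = np.full((n + 1, m + 1), _INF)
    # Back-pointers: state char of the predecessor.
    bM = np.empty((n + 1, m + 1), dtype="U1")
    bT = np.empty((n + 1, m + 1), dtype="U1")
    bO = np.empty((n + 1, m + 1), dtype="U1")
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        T[i, 0] = op + (i - 1) * ex
        bT[i, 0] = "T" if i > 1 else "M"
    for j in range(1, m + 1):
        O[0, j] = op + (j - 1) * ex
        bO[0, j] = "O" if j > 1 else "M"

    def _pick(cands):
        # cands: list of (value, state-char) in priority order; min with ties
        # resolved toward the earlier entry.
        best_v, best_s = cands[0]
        for v, s in cands[1:]:
            if v < best_v:
                best_v, best_s = v, s
        return best_v, best_s

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = model.column_energy(x[i - 1], y[j - 1])
            v, s = _pick([(M[i - 1, j - 1], "M"), (T[i - 1, j - 1], "T"), (O[i - 1, j - 1], "O")])
            M[i, j], bM[i, j] = v + e, s
            v, s = _pick([(M[i - 1, j] + op, "M"), (T[i - 1, j] + ex, "T"), (O[i - 1, j] + op, "O")])
            T[i, j], bT[i, j] = v, s
            v, s = _pick([(M[i, j - 1] + op, "M"), (T[i, j - 1] + op, "T"), (O[i, j - 1] + ex, "O")])
            O[i, j], bO[i, j] = v, s

    energy, state = _pick([(M[n, m], "M"), (T[n, m], "T"), (O[n, m], "O")])
    # Traceback.
    at, am = [], []
    i, j = n, m
    while i > 0 or j > 0:
        if state == "M":
            prev = bM[i, j]
            at.append(x[i - 1])
            am.append(y[j - 1])
            i, j = i - 1, j - 1
        elif state == "T":
            prev = bT[i, j]
            at.append(x[i - 1])
            am.append(GAP)
            i -= 1
        else:
            prev = bO[i, j]
            at.append(GAP)
            am.append(y[j - 1])
            j -= 1
        state = prev
    trace = DuplexTrace("".join(reversed(at)), "".join(reversed(am)))
    return trace, float(energy)


# ---------------------------------------------------------------------------
# Internal scanning backend
# ---------------------------------------------------------------------------

# A placement: (energy, start, end, kind, bulge_pos); kind 0 = ungapped,
# 1 = single target bulge, 2 = single miRNA bulge.
_Placement = Tuple[float, int, int, int, int]


def _scan_placements(tc: np.ndarray, mrev: np.ndarray, lut: np.ndarray,
                     bulge_open: float) -> List[_Placement]:
    """Energies of every ungapped and single-interior-bulge placement.

    Implemented with diagonal prefix sums over the per-column energy table;
    equivalent to naive enumeration of the same placement space.
    """
    L, m = len(tc), len(mrev)
    placements: List[_Placement] = []

    if L >= m:
        w = sliding_window_view(tc, m)                      # (L-m+1, m)
        scores = lut[w, mrev[None, :]].sum(axis=1)
        for o, s in enumerate(scores):
            placements.append((float(s), o, o + m, 0, -1))

    if L >= m + 1 and m >= 2:
        w = sliding_window_view(tc, m + 1)                  # (L-m, m+1)
        e_pre = lut[w[:, :m], mrev[None, :]]                # target o+k : mirna k
        e_post = lut[w[:, 1:], mrev[None, :]]               # target o+k+1 : mirna k
        cum_pre = np.cumsum(e_pre, axis=1)
        cum_post = np.cumsum(e_post, axis=1)
        total_post = e_post.sum(axis=1)
        for p in range(1, m):                               # interior bulge at target o+p
            s = cum_pre[:, p - 1] + (total_post - cum_post[:, p - 1]) + bulge_open
            for o, v in enumerate(s):
                placements.append((float(v), o, o + m + 1, 1, p))

    if L >= m - 1 and m >= 3:
        w = sliding_window_view(tc, m - 1)                  # (L-m+2, m-1)
        e_a = lut[w, mrev[None, :-1]]                       # target k : mirna k
        e_b = lut[w, mrev[None, 1:]]                        # target k : mirna k+1
        cum_a = np.cumsum(e_a, axis=1)
        cum_b = np.cumsum(e_b, axis=1)
        total_b = e_b.sum(axis=1)
        for q in range(1, m - 1):                           # miRNA base q (3'->5') bulges
            s = cum_a[:, q - 1] + (total_b - cum_b[:, q - 1]) + bulge_open
            for o, v in enumerate(s):
                placements.append((float(v), o, o + m - 1, 2, q))

    return placements


def _placement_trace(seq: str, mrev: str, start: int, kind: int, pos: int) -> DuplexTrace:
    m = len(mrev)
    if kind == 0:
        return DuplexTrace(seq[start:start + m], mrev)
    if kind == 1:
        return DuplexTrace(seq[start:start + m + 1], mrev[:pos] + GAP + mrev[pos:])
    window = seq[start:start + m - 1]
    return DuplexTrace(window[:pos] + GAP + window[pos:], mrev)


def dedup_overlapping(sites: Sequence[CandidateSite]) -> List[CandidateSite]:
    """Keep the minimum-energy representative among mutually overlapping
    sites (greedy from lowest energy; ties by start then end), then order
    by (start, energy)."""
    kept: List[CandidateSite] = []
    for s in sorted(sites, key=lambda s: (s.energy, s.start, s.end)):
        if all(s.end <= k.start or s.start >= k.end for k in kept):
            kept.append(s)
    kept.sort(key=lambda s: (s.start, s.energy))
    return kept


ExternalHybridizer = Callable[[TranscriptRecord, MiRNARecord, float],
                              Iterable[Tuple[int, float, str, str]]]


def parse_external_sites(text: str) -> List[Tuple[int, float, str, str]]:
    """Parse external-hybridizer output: tab-separated
    ``start  energy  aligned_target  aligned_mirna`` per site, '#' comments
    and blank lines ignored; tolerant of multi-site output."""
    out = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise InvariantError(f"unparsable external site record: {line!r}")
        out.append((int(parts[0]), float(parts[1]), parts[2], parts[3]))
    return out


def find_candidate_sites(
    transcript: TranscriptRecord,
    mirna: MiRNARecord,
    energy_cutoff: float = -10.0,
    model: Optional[EnergyModel] = None,
    backend: str = "internal",
    hybridizer: Optional[ExternalHybridizer] = None,
    dedup: bool = True,
) -> List[CandidateSite]:
    """All candidate sites for one miRNA on one transcript.

    Every returned site satisfies ``energy <= energy_cutoff``.  Overlapping
    sites are reduced to the minimum-energy representative when ``dedup``
    (the chunked pipeline defers deduplication until chunks are merged).
    A transcript shorter than the miRNA yields an empty list.
    """
    if energy_cutoff >= 0:
        raise InvariantError("energy cutoff must be negative (kcal/mol)")
    if model is None:
        model = EnergyModel()

    if backend == "external":
        if hybridizer is None:
            raise BackendUnavailableError(
                "external hybridization backend requested but no hybridizer configured"
            )
        sites = []
        for start, energy, at, am in hybridizer(transcript, mirna, energy_cutoff):
            if energy > energy_cutoff:
                continue
            trace = DuplexTrace(at, am)
            sites.append(CandidateSite(transcript.id, mirna.id, start,
                                       start + len(trace.target_seq), energy, trace))
        return dedup_overlapping(sites) if dedup else sorted(
            sites, key=lambda s: (s.start, s.energy))
    if backend != "internal":
        raise InvariantError(f"unknown backend {backend!r}")

    if len(transcript.seq) < len(mirna.seq):
        return []

    tc = np.fromiter((_BASE_CODE[b] for b in transcript.seq), dtype=np.intp,
                     count=len(transcript.seq))
    mrev_str = mirna.seq[::-1]
    mrev = np.fromiter((_BASE_CODE[b] for b in mrev_str), dtype=np.intp,
                       count=len(mrev_str))
    placements = _scan_placements(tc, mrev, model.lut(), model.bulge_open)

    # Exact-coordinate dedup: best placement per (start, end).
    best: dict = {}
    for e, start, end, kind, pos in placements:
        if e > energy_cutoff:
            continue
        key = (start, end)
        cur = best.get(key)
        if cur is None or (e, kind, pos) < (cur[0], cur[3], cur[4]):
            best[key] = (e, start, end, kind, pos)

    sites = [
        CandidateSite(transcript.id, mirna.id, start, end, e,
                      _placement_trace(transcript.seq, mrev_str, start, kind, pos))
        for e, start, end, kind, pos in best.values()
    ]
    if dedup:
        return dedup_overlapping(sites)
    sites.sort(key=lambda s: (s.start, s.energy))
    return sites
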