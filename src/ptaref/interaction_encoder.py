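"""Uniform re-alignment of duplexes and 5-state interaction-pattern matching.

A candidate duplex is refined with a Needleman-Wunsch global alignment in
which *complementarity* (not identity) is the reward: the target-site strand
is aligned against the reversed miRNA under a scoring matrix giving +5 to a
Watson-Crick pair, +5+1 to a G:U wobble (the wobble advantage) and -4 to a
mismatch, with affine gap penalties of -15 (opening, first gapped column)
and -5 (each further column).  The resulting trace is reduced to a single
string over five states:

    M  Watson-Crick pair        W  G:U wobble
    X  mismatch                 O  bulge on the miRNA strand
    T  bulge on the target strand

Predicted patterns are matched against a library of experimentally derived
patterns by edit distance (substitutions and indels over the 5-letter
alphabet), with up to four differences allowed — patterns of different
lengths (extra bulges) remain comparable, which plain Hamming distance would
not permit.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import edlib
import numpy as np

from .duplex_finder import GAP, DuplexTrace
from .errors import InvariantError, ParameterError
from .sequence_io import normalize_rna

PATTERN_ALPHABET = frozenset("MXWOT")

_WC = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
_WOBBLE = {("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class AlignmentParams:
    """Scores for the complementarity-rewarding global alignment."""

    wobble_bonus: float = 1.0
    gap_open: float = -15.0
    gap_extend: float = -5.0
    pair_match: float = 5.0
    mismatch: float = -4.0

    def __post_init__(self) -> None:
        if not (self.gap_open < self.gap_extend < 0):
            raise InvariantError("require gap_open < gap_extend < 0")
        if self.pair_match <= 0:
            raise InvariantError("pair_match must be positive")

    def column_score(self, target_base: str, mirna_base: str) -> float:
        p = (target_base, mirna_base)
        if p in _WC:
            return self.pair_match
        if p in _WOBBLE:
            return self.pair_match + self.wobble_bonus
        return self.mismatch


@dataclass(frozen=True)
class InteractionPattern:
    """Single-dimension encoding of one miRNA:target duplex."""

    states: str
    source: str = "predicted"
    species: str = ""
    mirna_id: str = ""

    def __post_init__(self) -> None:
        if not self.states:
            raise InvariantError("empty interaction pattern")
        bad = set(self.states) - PATTERN_ALPHABET
        if bad:
            raise InvariantError(f"illegal pattern states: {sorted(bad)}")
        if self.source not in ("experimental", "predicted"):
            raise InvariantError(f"unknown pattern source {self.source!r}")

    def __len__(self) -> int:
        return len(self.states)


class PatternLibrary:
    """An ordered collection of experimentally derived interaction patterns.

    TSV columns: ``pattern  species  mirna_id  source_note``; lines starting
    with '#' are comments.  Duplicate (pattern, mirna_id) entries rejected.
    """

    def __init__(self, patterns: Sequence[InteractionPattern]):
        if not patterns:
            raise InvariantError("pattern library must be non-empty")
        seen = set()
        for p in patterns:
            key = (p.states, p.mirna_id)
            if key in seen:
                raise InvariantError(f"duplicate library entry {key}")
            seen.add(key)
        self.patterns: List[InteractionPattern] = list(patterns)

    def __len__(self) -> int:
        return len(self.patterns)

    def __iter__(self):
        return iter(self.patterns)

    def __getitem__(self, i: int) -> InteractionPattern:
        return self.patterns[i]

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "PatternLibrary":
        patterns = []
        with open(path) as fh:
            for row in csv.reader(
                (l for l in fh if l.strip() and not l.startswith("#")), delimiter="\t"
            ):
                if len(row) < 3:
                    raise InvariantError(f"library row needs >=3 columns: {row!r}")
                pattern, species, mirna_id = row[0], row[1], row[2]
                patterns.append(
                    InteractionPattern(pattern, source="experimental",
                                       species=species, mirna_id=mirna_id)
                )
        return cls(patterns)

    def to_tsv(self, path: Union[str, Path]) -> None:
        with open(path, "w", newline="") as fh:
            fh.write("# pattern\tspecies\tmirna_id\tsource_note\n")
            w = csv.writer(fh, delimiter="\t")
            for p in self.patterns:
                w.writerow([p.states, p.species, p.mirna_id, p.source])


def refine_alignment(
    site_target_seq: str,
    mirna: str,
    params: Optional[AlignmentParams] = None,
) -> DuplexTrace:
    """Global alignment of the target-site strand against the reversed miRNA.

    Affine gaps: the first column of a gap run scores ``gap_open``, each
    further column ``gap_extend``.  Traceback ties are broken diagonal >
    gap-in-target > gap-in-miRNA, so the result is deterministic.
    """
    if params is None:
        params = AlignmentParams()
    x = normalize_rna(site_target_seq)
    y = normalize_rna(mirna)[::-1]
    if not x or not y:
        raise InvariantError("refine_alignment requires non-empty sequences")
    n, m = len(x), len(y)
    op, ex = params.gap_open, params.gap_extend
    NEG = float("-inf")

    # D = diagonal (paired column); GT = gap in target string (consumes
    # miRNA base); GM = gap in miRNA string (consumes target base).
    D = np.full((n + 1, m + 1), NEG)
    GT = np.full((n + 1, m + 1), NEG)
    GM = np.full((n + 1, m + 1), NEG)
    bD = np.empty((n + 1, m + 1), dtype="U2")
    bT = np.empty((n + 1, m + 1), dtype="U2")
    bM = np.empty((n + 1, m + 1), dtype="U2")
    D[0, 0] = 0.0
    for j in range(1, m + 1):
        GT[0, j] = op + (j - 1) * ex
        bT[0, j] = "GT" if j > 1 else "D"
    for i in range(1, n + 1):
        GM[i, 0] = op + (i - 1) * ex
        bM[i, 0] = "GM" if i > 1 else "D"

    def _pick(cands):
        best_v, best_s = cands[0]
        for v, s in cands[1:]:
            if v > best_v:
                best_v, best_s = v, s
        return best_v, best_s

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = params.column_score(x[i - 1], y[j - 1])
            v, st = _pick([(D[i - 1, j - 1], "D"), (GT[i - 1, j - 1], "GT"),
                           (GM[i - 1, j - 1], "GM")])
            D[i, j], bD[i, j] = v + s, st
            v, st = _pick([(D[i, j - 1] + op, "D"), (GT[i, j - 1] + ex, "GT"),
                           (GM[i, j - 1] + op, "GM")])
            GT[i, j], bT[i, j] = v, st
            v, st = _pick([(D[i - 1, j] + op, "D"), (GT[i - 1, j] + op, "GT"),
                           (GM[i - 1, j] + ex, "GM")])
            GM[i, j], bM[i, j] = v, st

    _, state = _pick([(D[n, m], "D"), (GT[n, m], "GT"), (GM[n, m], "GM")])
    at, am = [], []
    i, j = n, m
    while i > 0 or j > 0:
        if state == "D":
            prev = bD[i, j]
            at.append(x[i - 1])
            am.append(y[j - 1])
            i, j = i - 1, j - 1
        elif state == "GT":
            prev = bT[i, j]
            at.append(GAP)
            am.append(y[j - 1])
            j -= 1
        else:
            prev = bM[i, j]
            at.append(x[i - 1])
            am.append(GAP)
            i -= 1
        state = prev
    return DuplexTrace("".join(reversed(at)), "".join(reversed(am)))


def alignment_score(trace: DuplexTrace, params: Optional[AlignmentParams] = None) -> float:
    """Score of a trace under the refinement matrix (affine gap runs)."""
    if params is None:
        params = AlignmentParams()
    score = 0.0
    prev_gap = None
    for t, m in zip(trace.aligned_target, trace.aligned_mirna):
        if t == GAP or m == GAP:
            side = "t" if t == GAP else "m"
            score += params.gap_extend if prev_gap == side else params.gap_open
            prev_gap = side
        else:
            score += params.column_score(t, m)
            prev_gap = None
    return score


def encode_interaction(trace: DuplexTrace, mirna_id: str = "",
                       species: str = "") -> InteractionPattern:
    """Reduce a duplex trace to its 5-state pattern, one state per column."""
    return InteractionPattern("".join(trace.column_states()),
                              source="predicted", species=species, mirna_id=mirna_id)


def pattern_distance(a: Union[InteractionPattern, str],
                     b: Union[InteractionPattern, str]) -> int:
    """Unit-cost edit distance between two patterns (global, symmetric)."""
    sa = a.states if isinstance(a, InteractionPattern) else a
    sb = b.states if isinstance(b, InteractionPattern) else b
    return int(edlib.align(sa, sb, mode="NW", task="distance")["editDistance"])


MAX_PATTERN_DIFF = 4


def match_library(
    p: Union[InteractionPattern, str],
    lib: PatternLibrary,
    max_diff: int = MAX_PATTERN_DIFF,
) -> Optional[Tuple[InteractionPattern, int]]:
    """Nearest library pattern within ``max_diff`` edits, or None.

    Ties are broken by library order (stable), mirroring a scan of the
    experimentally validated patterns at a user-chosen mismatch level 0-4.
    """
    if not (0 <= max_diff <= MAX_PATTERN_DIFF):
        raise ParameterError(f"max_diff must be in [0, {MAX_PATTERN_DIFF}]")
    best_entry, best_d = None, None
    for entry in lib:
        d = pattern_distance(p, entry)
        if best_d is None or d < best_d:
            best_entry, best_d = entry, d
    if best_d is None or best_d > max_diff:
        return None
    return best_entry, best_d
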