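"""Synthetic data generators: every pipeline stage testable without downloads.

The generators emulate the data the method consumes in the field:

* random transcripts (uniform base composition),
* transcripts with a *planted* target site — the reverse complement of a
  miRNA carrying a controlled number of mismatch, G:U wobble and bulge
  edits, with a known truth pattern — embedded with AU-rich flanking
  sequence (A/U 0.35, C/G 0.15 each), standing in for the compositional
  bias real plant target contexts show relative to random sequence,
* negative instances from two sources: plain random sequence and
  near-complementary decoys whose duplexes miss the energy cutoff,
* a synthetic interaction-pattern library (mostly-match patterns with 0-4
  deviations, anchored by the canonical all-match pattern),
* expression matrices with a prescribed target:miRNA correlation,
* abstract labeled feature sets with a planted mean shift on a known
  feature subset.

All generators are pure functions of their seed and parameters, and each
planted construct returns a truth sidecar sufficient to score downstream
stages without re-inspecting the generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import InvariantError
from .expression_correlation import ExpressionMatrix
from .feature_extractor import FeatureConfig, FeatureVector, build_feature_vector
from .duplex_finder import CandidateSite
from .interaction_encoder import InteractionPattern, PatternLibrary
from .sequence_io import MiRNARecord, TranscriptRecord

BASES = "ACGU"
_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}
_WC_PARTNER = _COMPLEMENT
_WOBBLE_PARTNER = {"G": "U", "U": "G"}

# Flank composition for planted (positive) sites: AU-rich vs uniform background.
AU_RICH_PROBS = (0.35, 0.15, 0.15, 0.35)  # A, C, G, U
UNIFORM_PROBS = (0.25, 0.25, 0.25, 0.25)


def _random_seq(rng: np.random.Generator, length: int,
                probs: Sequence[float] = UNIFORM_PROBS) -> str:
    return "".join(rng.choice(list(BASES), size=length, p=list(probs)))


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def make_transcripts(n: int, length: int = 500, seed: int = 0,
                     prefix: str = "T") -> List[TranscriptRecord]:
    """``n`` uniform-random transcripts; deterministic per seed."""
    if n <= 0 or length <= 0:
        raise InvariantError("n and length must be positive")
    rng = np.random.default_rng(seed)
    return [TranscriptRecord(id=f"{prefix}{i + 1:04d}", seq=_random_seq(rng, length))
            for i in range(n)]


@dataclass(frozen=True)
class PlantedSiteSpec:
    mirna_len: int = 21
    n_mismatches: int = 0
    n_wobbles: int = 0
    n_bulges: int = 0
    flank_len: int = 75
    transcript_len: int = 300
    seed: int = 0
    flank_probs: Tuple[float, ...] = AU_RICH_PROBS

    def __post_init__(self) -> None:
        edits = self.n_mismatches + self.n_wobbles + self.n_bulges
        if edits > self.mirna_len // 2:
            raise InvariantError("too many edits for the miRNA length")
        if self.transcript_len < self.mirna_len + self.n_bulges + 2 * self.flank_len:
            raise InvariantError("transcript too short for site plus both flanks")


@dataclass(frozen=True)
class PlantedSite:
    """Truth sidecar: the planted transcript/miRNA pair with exact site
    coordinates and the true 5-state interaction pattern."""

    transcript: TranscriptRecord
    mirna: MiRNARecord
    start: int
    end: int
    pattern: str
    spec: PlantedSiteSpec

    def as_candidate(self) -> CandidateSite:
        return CandidateSite(self.transcript.id, self.mirna.id,
                             self.start, self.end, energy=-999.0)


def _spaced_positions(rng: np.random.Generator, count: int, lo: int, hi: int,
                      min_gap: int = 3, tries: int = 200) -> Optional[List[int]]:
    """``count`` positions in [lo, hi] pairwise >= min_gap apart, or None."""
    if count == 0:
        return []
    candidates = list(range(lo, hi + 1))
    for _ in range(tries):
        picked = sorted(rng.choice(candidates, size=count, replace=False))
        if all(b - a >= min_gap for a, b in zip(picked, picked[1:])):
            return picked
    return None


def _plant(rng: np.random.Generator, spec: PlantedSiteSpec,
           mirna: Optional[MiRNARecord] = None,
           transcript_id: str = "planted", mirna_id: str = "mir-planted"):
    m = spec.mirna_len
    n_edits = spec.n_mismatches + spec.n_wobbles + spec.n_bulges

    for _attempt in range(200):
        if mirna is None:
            mir_seq = _random_seq(rng, m)
        else:
            mir_seq = mirna.seq
            if len(mir_seq) != m:
                raise InvariantError("supplied miRNA length differs from spec.mirna_len")
        positions = _spaced_positions(rng, n_edits, 2, m - 3)
        if positions is None:
            continue
        rng.shuffle(positions)
        wobble_cols = sorted(positions[:spec.n_wobbles])
        mismatch_cols = sorted(positions[spec.n_wobbles:
                                         spec.n_wobbles + spec.n_mismatches])
        bulge_cols = sorted(positions[spec.n_wobbles + spec.n_mismatches:])

        mir = list(mir_seq)
        # Wobbles need a U or G on the miRNA strand at the paired position.
        ok = True
        for c in wobble_cols:
            b = mir[m - 1 - c]
            if b not in "UG":
                if mirna is not None:
                    ok = False  # cannot mutate a supplied miRNA; re-draw positions
                    break
                mir[m - 1 - c] = rng.choice(["U", "G"])
        if not ok:
            continue

        site = [_COMPLEMENT[mir[m - 1 - c]] for c in range(m)]
        states = ["M"] * m
        for c in wobble_cols:
            site[c] = _WOBBLE_PARTNER[mir[m - 1 - c]]
            states[c] = "W"
        for c in mismatch_cols:
            site[c] = mir[m - 1 - c]  # identical bases never pair nor wobble
            states[c] = "X"

        # Target-strand bulges: insert a base that cannot pair its miRNA
        # neighbours and differs from the flanking site bases, so the
        # refinement alignment places the gap uniquely.
        ok = True
        inserts = []
        for c in bulge_cols:
            forbidden = set()
            for mb in (mir[m - 1 - c], mir[m - c] if c >= 1 else None):
                if mb is None:
                    continue
                forbidden.add(_WC_PARTNER[mb])
                if mb in _WOBBLE_PARTNER:
                    forbidden.add(_WOBBLE_PARTNER[mb])
            forbidden.add(site[c])
            if c >= 1:
                forbidden.add(site[c - 1])
            choices = [b for b in BASES if b not in forbidden]
            if not choices:
                ok = False
                break
            inserts.append((c, rng.choice(choices)))
        if not ok:
            continue

        for c, base in sorted(inserts, reverse=True):
            site.insert(c, base)
            states.insert(c, "T")

        site_seq = "".join(site)
        pattern = "".join(states)
        mir_rec = mirna if mirna is not None else MiRNARecord(mirna_id, "".join(mir))

        # The planted duplex must be the unambiguous optimal interpretation:
        # re-derive the pattern through the refinement alignment and re-draw
        # edit positions if a bulge/mismatch interaction lets it slide.
        if n_edits > 0:
            from .interaction_encoder import encode_interaction, refine_alignment
            derived = encode_interaction(refine_alignment(site_seq, mir_rec.seq)).states
            if derived != pattern:
                continue

        site_len = len(site_seq)
        start = int(rng.integers(spec.flank_len,
                                 spec.transcript_len - site_len - spec.flank_len + 1))
        background = _random_seq(rng, spec.transcript_len)
        up = _random_seq(rng, spec.flank_len, spec.flank_probs)
        down = _random_seq(rng, spec.flank_len, spec.flank_probs)
        seq = (background[:start - spec.flank_len] + up + site_seq + down
               + background[start + site_len + spec.flank_len:])
        transcript = TranscriptRecord(transcript_id, seq)
        return PlantedSite(transcript, mir_rec, start, start + site_len, pattern, spec)

    raise InvariantError(f"could not realize planted-site spec {spec}")


def plant_site(spec: PlantedSiteSpec) -> PlantedSite:
    """A transcript with one embedded target site and its truth record."""
    return _plant(np.random.default_rng(spec.seed), spec)


def make_planted_batch(
    n_transcripts: int,
    n_mirnas: int = 3,
    seed: int = 0,
    max_mismatches: int = 2,
    max_wobbles: int = 1,
    max_bulges: int = 0,
    spec: Optional[PlantedSiteSpec] = None,
) -> Tuple[List[PlantedSite], List[MiRNARecord]]:
    """One planted site per transcript, drawn against a shared miRNA panel.

    Edit counts per site are sampled uniformly up to the given maxima.
    """
    rng = np.random.default_rng(seed)
    base = spec if spec is not None else PlantedSiteSpec()
    mirnas = [MiRNARecord(f"mir{j + 1:03d}", _random_seq(rng, base.mirna_len))
              for j in range(n_mirnas)]
    planted = []
    for i in range(n_transcripts):
        mir = mirnas[int(rng.integers(n_mirnas))]
        s = PlantedSiteSpec(
            mirna_len=base.mirna_len,
            n_mismatches=int(rng.integers(max_mismatches + 1)),
            n_wobbles=int(rng.integers(max_wobbles + 1)),
            n_bulges=int(rng.integers(max_bulges + 1)),
            flank_len=base.flank_len,
            transcript_len=base.transcript_len,
            seed=base.seed,
            flank_probs=base.flank_probs,
        )
        planted.append(_plant(rng, s, mirna=mir, transcript_id=f"PT{i + 1:04d}"))
    return planted, mirnas


def make_pattern_library(n: int, seed: int = 0, length: int = 21) -> PatternLibrary:
    """Synthetic stand-in for an experimentally derived pattern library.

    Entry 1 is the canonical all-match pattern; the rest are mostly-match
    patterns with 0-4 deviations (mismatch/wobble substitutions, occasional
    bulge-state insertions), mimicking the near-complementary duplexes of
    validated plant sites.
    """
    if n < 1:
        raise InvariantError("library size must be >= 1")
    rng = np.random.default_rng(seed)
    species_pool = ["synthA", "synthB", "synthC"]
    patterns = [InteractionPattern("M" * length, source="experimental",
                                   species="synthA", mirna_id="lib-mir000")]
    for i in range(1, n):
        states = ["M"] * length
        k = int(rng.integers(0, 5))
        cols = rng.choice(np.arange(1, length - 1), size=k, replace=False)
        for c in cols:
            states[int(c)] = str(rng.choice(["X", "X", "W", "O", "T"]))
        patterns.append(InteractionPattern(
            "".join(states), source="experimental",
            species=str(rng.choice(species_pool)), mirna_id=f"lib-mir{i:03d}"))
    return PatternLibrary(patterns)


@dataclass(frozen=True)
class TrainingSet:
    """Labeled feature matrices with a planted mean shift on a known subset."""

    pos: np.ndarray
    neg: np.ndarray
    informative: Tuple[int, ...]
    shift: float


def make_training_set(n: int = 200, shift: float = 2.0, seed: int = 0,
                      n_features: int = 160, n_informative: int = 8) -> TrainingSet:
    """``n`` instances total (half per class), standard-normal features with
    the positive class shifted by ``shift`` SD on ``n_informative`` features."""
    rng = np.random.default_rng(seed)
    per_class = n // 2
    informative = tuple(sorted(
        int(i) for i in rng.choice(n_features, size=n_informative, replace=False)))
    pos = rng.standard_normal((per_class, n_features))
    neg = rng.standard_normal((per_class, n_features))
    pos[:, list(informative)] += shift
    return TrainingSet(pos=pos, neg=neg, informative=informative, shift=shift)


def make_expression(n_pairs: int = 30, rho: float = -0.9, seed: int = 0,
                    n_conditions: int = 12) -> Tuple[ExpressionMatrix,
                                                     List[Tuple[str, str]]]:
    """Expression matrix with gene/miRNA row pairs at correlation ``rho``.

    Gaussian model: y = rho*x + sqrt(1 - rho^2)*noise with x, noise standard
    normal, so the population correlation of each pair is exactly ``rho``.
    """
    if not (-1 <= rho <= 1):
        raise InvariantError("rho must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    rows, index, pairs = [], [], []
    for i in range(n_pairs):
        x = rng.standard_normal(n_conditions)
        noise = rng.standard_normal(n_conditions)
        y = rho * x + np.sqrt(max(0.0, 1 - rho**2)) * noise
        gene, mir = f"G{i + 1:04d}", f"miR{i + 1:04d}"
        rows += [x, y]
        index += [gene, mir]
        pairs.append((gene, mir))
    frame = pd.DataFrame(rows, index=index,
                         columns=[f"cond{j + 1:02d}" for j in range(n_conditions)])
    return ExpressionMatrix(frame), pairs


def make_site_training_set(
    n_pos: int = 120,
    n_neg: int = 120,
    seed: int = 0,
    cfg: Optional[FeatureConfig] = None,
) -> Tuple[List[FeatureVector], List[FeatureVector]]:
    """Sequence-level SVR training data.

    Positives: feature vectors at planted sites (AU-rich flank context).
    Negatives, two sources mirrored from practice: random-sequence windows,
    and near-complementary decoy windows embedded in uniform flanks.
    """
    if cfg is None:
        cfg = FeatureConfig()
    rng = np.random.default_rng(seed)
    pos_vectors: List[FeatureVector] = []
    for i in range(n_pos):
        s = PlantedSiteSpec(
            n_mismatches=int(rng.integers(0, 3)),
            n_wobbles=int(rng.integers(0, 2)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        ps = plant_site(s)
        pos_vectors.append(build_feature_vector(ps.transcript, ps.as_candidate(), cfg))

    neg_vectors: List[FeatureVector] = []
    for i in range(n_neg):
        seq = _random_seq(rng, 300)
        if i % 2 == 1:
            # Decoy: a heavily degraded complement dropped into the middle.
            mir = _random_seq(rng, 21)
            decoy = list(reverse_complement(mir))
            for c in rng.choice(21, size=8, replace=False):
                decoy[int(c)] = str(rng.choice(list(BASES)))
            mid = 140
            seq = seq[:mid] + "".join(decoy) + seq[mid + 21:]
            start = mid
        else:
            start = int(rng.integers(cfg.flank_len, 300 - 21 - cfg.flank_len))
        t = TranscriptRecord(f"N{i + 1:04d}", seq)
        site = CandidateSite(t.id, "none", start, start + 21, energy=-999.0)
        neg_vectors.append(build_feature_vector(t, site, cfg))
    return pos_vectors, neg_vectors
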