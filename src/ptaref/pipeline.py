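"""Type-I/II/III prediction runs with deterministic chunk-parallel execution.

A query transcript is chopped into overlapping chunks of at least 50 nt
(the overlap equals the maximal duplex length, so any site detectable on
the full sequence lies intact within some chunk) and the thermodynamic scan
runs as a pure map over (transcript x miRNA x chunk) work items.  Chunk
results are merged by coordinate, deduplicated to minimum-energy
representatives, refined and encoded, filtered against the pattern library,
and finally SVR-scored with features recomputed from full-transcript
coordinates — so the output is byte-identical for any thread count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd
from joblib import Parallel, delayed

from .duplex_finder import (CandidateSite, EnergyModel, dedup_overlapping,
                            find_candidate_sites)
from .errors import (AmbiguousSiteError, InvariantError, ParameterError,
                     PipelineError, SiteNotFoundError)
from .feature_extractor import FeatureConfig, build_feature_vector
from .interaction_encoder import (AlignmentParams, PatternLibrary,
                                  encode_interaction, match_library,
                                  refine_alignment)
from .sequence_io import MiRNARecord, TranscriptRecord, normalize_rna
from .svr_model import Prediction, TargetScorerResults


@dataclass(frozen=True)
class PipelineConfig:
    energy_cutoff: float = -10.0
    max_pattern_diff: int = 4
    threads: int = 1
    chunk_min_len: int = 50
    chunk_overlap: int = 50
    library_filter: bool = True
    energy_model: EnergyModel = field(default_factory=EnergyModel)
    alignment_params: AlignmentParams = field(default_factory=AlignmentParams)
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)

    def __post_init__(self) -> None:
        if not (0 <= self.max_pattern_diff <= 4):
            raise ParameterError("max_pattern_diff must be in [0, 4]")
        if self.threads < 1:
            raise ParameterError("threads must be >= 1")
        if self.energy_cutoff >= 0:
            raise ParameterError("energy cutoff must be negative")


def chunk_sequence(seq: str, threads: int,
                   cfg: Optional[PipelineConfig] = None) -> List[Tuple[str, int]]:
    """Split ``seq`` into up to ``threads`` chunks of >= ``chunk_min_len`` nt
    overlapping by >= ``chunk_overlap``; offsets map chunk coordinates back
    to the transcript.  Shorter sequences come back as a single chunk."""
    if cfg is None:
        cfg = PipelineConfig()
    L = len(seq)
    if threads < 1:
        raise ParameterError("threads must be >= 1")
    ov = cfg.chunk_overlap
    n = max(1, threads)
    while n > 1:
        c = math.ceil((L + (n - 1) * ov) / n)
        if c >= max(cfg.chunk_min_len, ov + 1) and c < L:
            break
        n -= 1
    if n == 1:
        return [(seq, 0)]
    c = math.ceil((L + (n - 1) * ov) / n)
    step = c - ov
    chunks = []
    for i in range(n):
        off = min(i * step, L - c)
        chunks.append((seq[off:off + c], off))
    return chunks


def _shift_site(site: CandidateSite, offset: int) -> CandidateSite:
    if offset == 0:
        return site
    return CandidateSite(site.transcript_id, site.mirna_id,
                         site.start + offset, site.end + offset,
                         site.energy, site.trace)


def _scan_chunk(transcript_id: str, chunk: str, offset: int, mirna: MiRNARecord,
                cfg: PipelineConfig) -> List[CandidateSite]:
    chunk_rec = TranscriptRecord(transcript_id, chunk)
    sites = find_candidate_sites(chunk_rec, mirna, energy_cutoff=cfg.energy_cutoff,
                                 model=cfg.energy_model, dedup=False)
    return [_shift_site(s, offset) for s in sites]


def _score_site(transcript: TranscriptRecord, mirna: MiRNARecord,
                site: CandidateSite, cfg: PipelineConfig,
                model: TargetScorerResults,
                library: Optional[PatternLibrary]) -> Optional[Prediction]:
    site_seq = transcript.seq[site.start:site.end]
    trace = refine_alignment(site_seq, mirna.seq, cfg.alignment_params)
    pattern = encode_interaction(trace, mirna_id=mirna.id)

    lib_pattern = lib_mirna = None
    distance = None
    if library is not None and cfg.library_filter:
        match = match_library(pattern, library, cfg.max_pattern_diff)
        if match is None:
            return None
        entry, distance = match
        lib_pattern, lib_mirna = entry.states, entry.mirna_id

    fv = build_feature_vector(transcript, site, cfg.feature_config)
    values = fv.values
    if model.selected_features is not None:
        values = values[list(model.selected_features)]
    score = float(model.decision_values(values[None, :])[0])
    return Prediction(
        svr_score=score,
        call="target" if score > 0 else "non-target",
        site_ref=site,
        pattern=pattern.states,
        library_pattern=lib_pattern,
        library_mirna_id=lib_mirna,
        pattern_distance=distance,
        energy=site.energy,
    )


def run_type1(
    transcripts: Sequence[TranscriptRecord],
    mirnas: Sequence[MiRNARecord],
    cfg: Optional[PipelineConfig] = None,
    model: Optional[TargetScorerResults] = None,
    library: Optional[PatternLibrary] = None,
) -> List[Prediction]:
    """Full run: scan every transcript x miRNA from scratch.

    Chunk scans are a pure parallel map; merging, deduplication and scoring
    are deterministic, so the output does not depend on ``threads``.
    """
    if cfg is None:
        cfg = PipelineConfig()
    if model is None:
        raise PipelineError("Type-I run requires a trained SVR model")
    if library is None and cfg.library_filter:
        raise PipelineError("Type-I run requires a pattern library "
                            "(or disable library_filter)")

    tasks = []
    for ti, t in enumerate(transcripts):
        for mi, m in enumerate(mirnas):
            for chunk, offset in chunk_sequence(t.seq, cfg.threads, cfg):
                tasks.append((ti, mi, chunk, offset))
    chunk_sites = Parallel(n_jobs=cfg.threads, prefer="threads")(
        delayed(_scan_chunk)(transcripts[ti].id, chunk, offset, mirnas[mi], cfg)
        for ti, mi, chunk, offset in tasks
    )

    per_pair: Dict[Tuple[int, int], List[CandidateSite]] = {}
    for (ti, mi, _, _), sites in zip(tasks, chunk_sites):
        per_pair.setdefault((ti, mi), []).extend(sites)

    predictions: List[Prediction] = []
    for (ti, mi), raw in sorted(per_pair.items()):
        # Coordinate-keyed dedup removes chunk-overlap duplicates, then one
        # global pass keeps the minimum-energy representative per overlap.
        best: Dict[Tuple[int, int], CandidateSite] = {}
        for s in raw:
            key = (s.start, s.end)
            if key not in best or s.energy < best[key].energy:
                best[key] = s
        for site in dedup_overlapping(list(best.values())):
            pred = _score_site(transcripts[ti], mirnas[mi], site, cfg, model, library)
            if pred is not None:
                predictions.append(pred)

    predictions.sort(key=lambda p: (p.site_ref.transcript_id, p.site_ref.start,
                                    p.site_ref.mirna_id))
    return predictions


def run_type2(
    site_seq: str,
    transcript: TranscriptRecord,
    model: TargetScorerResults,
    cfg: Optional[PipelineConfig] = None,
) -> Prediction:
    """SVR-only validation of an externally predicted site.

    ``site_seq`` must occur exactly once in the transcript; zero occurrences
    raise :class:`SiteNotFoundError`, several raise
    :class:`AmbiguousSiteError` listing the positions.
    """
    if cfg is None:
        cfg = PipelineConfig()
    if model is None:
        raise PipelineError("Type-II validation requires a trained SVR model")
    needle = normalize_rna(site_seq)
    positions = []
    i = transcript.seq.find(needle)
    while i != -1:
        positions.append(i)
        i = transcript.seq.find(needle, i + 1)
    if not positions:
        raise SiteNotFoundError(
            f"site sequence not found in transcript {transcript.id!r}")
    if len(positions) > 1:
        raise AmbiguousSiteError(positions)
    start = positions[0]
    site = CandidateSite(transcript.id, "query-site", start, start + len(needle),
                         energy=float("nan"))
    fv = build_feature_vector(transcript, site, cfg.feature_config)
    values = fv.values
    if model.selected_features is not None:
        values = values[list(model.selected_features)]
    score = float(model.decision_values(values[None, :])[0])
    return Prediction(svr_score=score,
                      call="target" if score > 0 else "non-target",
                      site_ref=site)


def run_type3(
    transcripts: Sequence[TranscriptRecord],
    mirnas: Sequence[MiRNARecord],
    mirna_id: str,
    cfg: Optional[PipelineConfig] = None,
    model: Optional[TargetScorerResults] = None,
    library: Optional[PatternLibrary] = None,
) -> List[Prediction]:
    """Type-I restricted to one miRNA chosen by id from the panel."""
    chosen = [m for m in mirnas if m.id == mirna_id]
    if not chosen:
        raise PipelineError(f"unknown miRNA id {mirna_id!r}")
    return run_type1(transcripts, chosen, cfg=cfg, model=model, library=library)


TSV_COLUMNS = ["transcript_id", "site_start", "site_end", "mirna_id",
               "energy_kcal_mol", "predicted_pattern", "nearest_library_pattern",
               "pattern_distance", "svr_score", "call", "expression_r"]


def predictions_to_frame(predictions: Sequence[Prediction]) -> pd.DataFrame:
    """User-facing table; coordinates converted to 1-based inclusive here."""
    rows = []
    for p in predictions:
        s = p.site_ref
        rows.append({
            "transcript_id": s.transcript_id if s is not None else "",
            "site_start": s.start + 1 if s is not None else "",
            "site_end": s.end if s is not None else "",
            "mirna_id": s.mirna_id if s is not None else "",
            "energy_kcal_mol": "" if p.energy is None or math.isnan(p.energy)
                               else round(p.energy, 3),
            "predicted_pattern": p.pattern or "",
            "nearest_library_pattern": p.library_pattern or "",
            "pattern_distance": "" if p.pattern_distance is None else p.pattern_distance,
            "svr_score": round(p.svr_score, 6),
            "call": p.call,
            "expression_r": "" if p.expression_r is None else round(p.expression_r, 4),
        })
    return pd.DataFrame(rows, columns=TSV_COLUMNS)


def predictions_to_tsv(predictions: Sequence[Prediction],
                       path: Union[str, Path]) -> None:
    predictions_to_frame(predictions).to_csv(path, sep="\t", index=False)
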