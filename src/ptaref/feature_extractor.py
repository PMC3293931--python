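"""Position-specific dinucleotide-density-variation profiles around a site.

For each candidate site, up to 75 nt of flanking sequence on either side is
scanned with 20-nt sliding windows (step 1, 56 windows per side).  Each
window contributes 16 overlapping-dinucleotide densities (counts divided by
window length - 1, so each raw window vector sums to 1).  Windows are
ordered site-proximal to site-distal, so the profile captures how density
varies with position *relative to* the putative target site.

Two variation modes are offered.  The default ``raw`` mode keeps the
site-anchored positional densities themselves.  ``delta_from_site``
additionally subtracts the density vector of the site's own leading 20 nt
from every window; this makes homogeneous contexts exactly zero, but the
site reference is estimated from only ~20 dinucleotides (per-density SD
about 0.05, the same order as real compositional contrasts), and that
shared sampling noise measurably degrades downstream discrimination — hence
it is the ablation mode, not the default.

Window slots that would run past a transcript end are zero-filled and the
vector flagged truncated, so near-terminal sites are kept rather than
silently dropped.

The flattened layout is fixed: upstream block then downstream block, windows
proximal-first, dinucleotides lexicographic over {A,C,G,U} — 2 x 56 x 16 =
1792 values under the defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .duplex_finder import CandidateSite
from .errors import InvariantError, ParameterError
from .sequence_io import TranscriptRecord

BASES = "ACGU"
DINUCLEOTIDES = tuple(a + b for a in BASES for b in BASES)  # AA..UU lexicographic
_CODE = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class FeatureConfig:
    flank_len: int = 75
    window_len: int = 20
    window_step: int = 1
    variation_mode: str = "raw"  # or "delta_from_site"
    selected_features: Optional[Tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if self.window_len > self.flank_len:
            raise InvariantError("window_len must not exceed flank_len")
        if self.window_step < 1:
            raise InvariantError("window_step must be >= 1")
        if self.variation_mode not in ("delta_from_site", "raw"):
            raise InvariantError(f"unknown variation_mode {self.variation_mode!r}")

    @property
    def n_windows(self) -> int:
        return (self.flank_len - self.window_len) // self.window_step + 1

    @property
    def n_features(self) -> int:
        full = 2 * self.n_windows * 16
        return len(self.selected_features) if self.selected_features is not None else full

    def layout_descriptor(self) -> Tuple:
        """Hashable descriptor a model uses to refuse mismatched vectors."""
        return (self.flank_len, self.window_len, self.window_step,
                self.variation_mode, self.selected_features)


def feature_names(cfg: FeatureConfig) -> List[str]:
    """Column names in layout order, e.g. ``up_w03_GC`` (windows 0-indexed
    proximal-first)."""
    names = [
        f"{side}_w{w:02d}_{d}"
        for side in ("up", "down")
        for w in range(cfg.n_windows)
        for d in DINUCLEOTIDES
    ]
    if cfg.selected_features is not None:
        names = [names[i] for i in cfg.selected_features]
    return names


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    layout: Tuple
    site_ref: Optional[CandidateSite] = None
    truncated_upstream: bool = False
    truncated_downstream: bool = False

    def __len__(self) -> int:
        return len(self.values)


def dinucleotide_density(window: str) -> np.ndarray:
    """16 overlapping-dinucleotide densities of ``window`` (sums to 1)."""
    n = len(window)
    if n < 2:
        raise InvariantError("dinucleotide density needs a window of length >= 2")
    codes = np.fromiter((_CODE[b] for b in window), dtype=np.intp, count=n)
    idx = codes[:-1] * 4 + codes[1:]
    counts = np.bincount(idx, minlength=16)
    return counts / (n - 1)


def extract_flanks(
    transcript: TranscriptRecord,
    site: CandidateSite,
    cfg: Optional[FeatureConfig] = None,
) -> Tuple[str, str, bool, bool]:
    """Up to ``flank_len`` bases on each side of the site.

    Returns (upstream, downstream, truncated_upstream, truncated_downstream);
    a flank is truncated when the transcript end cuts it short.
    """
    if cfg is None:
        cfg = FeatureConfig()
    if not (0 <= site.start < site.end <= len(transcript.seq)):
        raise InvariantError("site does not lie within the transcript")
    up_start = max(0, site.start - cfg.flank_len)
    upstream = transcript.seq[up_start:site.start]
    downstream = transcript.seq[site.end:site.end + cfg.flank_len]
    return (upstream, downstream,
            len(upstream) < cfg.flank_len, len(downstream) < cfg.flank_len)


def _side_profile(flank: str, proximal_first: bool, cfg: FeatureConfig,
                  ref: Optional[np.ndarray]) -> np.ndarray:
    """Window densities for one flank, proximal window first; missing
    windows (truncated flank) left as zeros."""
    out = np.zeros((cfg.n_windows, 16))
    for k in range(cfg.n_windows):
        if proximal_first:
            start = k * cfg.window_step        # downstream: proximal = leftmost
            stop = start + cfg.window_len
            if stop > len(flank):
                continue
            window = flank[start:stop]
        else:
            stop = len(flank) - k * cfg.window_step  # upstream: proximal = rightmost
            start = stop - cfg.window_len
            if start < 0:
                continue
            window = flank[start:stop]
        dens = dinucleotide_density(window)
        out[k] = dens - ref if ref is not None else dens
    return out


def build_feature_vector(
    transcript: TranscriptRecord,
    site: CandidateSite,
    cfg: Optional[FeatureConfig] = None,
) -> FeatureVector:
    """The flattened density-variation profile for one site.

    Pure function of (transcript, site coordinates, cfg); repeated calls are
    bit-identical.  A site shorter than ``window_len`` uses its full length
    for the reference density in delta mode.
    """
    if cfg is None:
        cfg = FeatureConfig()
    upstream, downstream, trunc_up, trunc_down = extract_flanks(transcript, site, cfg)

    ref = None
    if cfg.variation_mode == "delta_from_site":
        site_seq = transcript.seq[site.start:site.end]
        ref = dinucleotide_density(site_seq[:cfg.window_len]
                                   if len(site_seq) >= cfg.window_len else site_seq)

    up = _side_profile(upstream, proximal_first=False, cfg=cfg, ref=ref)
    down = _side_profile(downstream, proximal_first=True, cfg=cfg, ref=ref)
    values = np.concatenate([up.ravel(), down.ravel()])
    if cfg.selected_features is not None:
        values = values[list(cfg.selected_features)]
    return FeatureVector(values=values, layout=cfg.layout_descriptor(), site_ref=site,
                         truncated_upstream=trunc_up, truncated_downstream=trunc_down)


def select_features(
    train_pos: Sequence[Union[FeatureVector, np.ndarray]],
    train_neg: Sequence[Union[FeatureVector, np.ndarray]],
    k: int,
) -> List[int]:
    """Mean-distribution feature ranking: |mean_pos - mean_neg| / pooled SD.

    Zero-SD features rank last; ties break by index; returns the top-``k``
    indices in rank order (deterministic).
    """
    if k <= 0:
        raise ParameterError("k must be positive")
    X_pos = np.asarray([v.values if isinstance(v, FeatureVector) else v for v in train_pos],
                       dtype=float)
    X_neg = np.asarray([v.values if isinstance(v, FeatureVector) else v for v in train_neg],
                       dtype=float)
    if X_pos.size == 0 or X_neg.size == 0:
        raise ParameterError("both classes must be non-empty")
    if X_pos.shape[1] != X_neg.shape[1]:
        raise InvariantError("class feature lengths differ")
    if k > X_pos.shape[1]:
        raise ParameterError("k exceeds the number of features")

    n_p, n_n = len(X_pos), len(X_neg)
    mean_p, mean_n = X_pos.mean(axis=0), X_neg.mean(axis=0)
    var_p = X_pos.var(axis=0, ddof=1) if n_p > 1 else np.zeros(X_pos.shape[1])
    var_n = X_neg.var(axis=0, ddof=1) if n_n > 1 else np.zeros(X_neg.shape[1])
    dof = max(n_p + n_n - 2, 1)
    pooled = np.sqrt(((n_p - 1) * var_p + (n_n - 1) * var_n) / dof)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.abs(mean_p - mean_n) / pooled
    score[~np.isfinite(score)] = -np.inf  # zero-SD features rank last
    order = np.lexsort((np.arange(len(score)), -score))
    return [int(i) for i in order[:k]]


def vectors_to_tsv(vectors: Sequence[FeatureVector], cfg: FeatureConfig,
                   path: Union[str, Path]) -> None:
    """Serialize vectors as TSV with one named column per feature slot."""
    df = pd.DataFrame([v.values for v in vectors], columns=feature_names(cfg))
    df.to_csv(path, sep="\t", index=False)


def vectors_from_tsv(path: Union[str, Path], cfg: FeatureConfig) -> List[FeatureVector]:
    df = pd.read_csv(path, sep="\t")
    expected = feature_names(cfg)
    if list(df.columns) != expected:
        raise InvariantError("feature TSV columns do not match the configured layout")
    return [FeatureVector(values=row.to_numpy(dtype=float), layout=cfg.layout_descriptor())
            for _, row in df.iterrows()]
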