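"""Pearson co-expression support for predicted target:miRNA pairs.

Given a pre-normalized expression matrix (rows = gene and miRNA IDs,
columns = conditions), each predicted pair is scored by the Pearson
correlation of its two expression profiles.  Strong inverse correlation
(r <= -0.8 by default) is flagged as expression-level support for
miRNA-guided transcript degradation; pairs whose IDs are missing from the
matrix are reported as data-unavailable, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvariantError, ZeroVarianceError

DEFAULT_MIN_INVERSE_R = -0.8


class ExpressionMatrix:
    """Wrapper over a pandas DataFrame with unique row IDs."""

    def __init__(self, frame: pd.DataFrame):
        if frame.index.has_duplicates:
            dupes = frame.index[frame.index.duplicated()].unique().tolist()
            raise InvariantError(f"duplicate expression row IDs: {dupes[:5]}")
        self.frame = frame.astype(float)

    @property
    def n_conditions(self) -> int:
        return self.frame.shape[1]

    def __contains__(self, row_id: str) -> bool:
        return row_id in self.frame.index

    def row(self, row_id: str) -> np.ndarray:
        return self.frame.loc[row_id].to_numpy()

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "ExpressionMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.frame.to_csv(path, sep="\t")


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; requires length >= 3 and non-zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvariantError("vectors must have equal length")
    if len(x) < 3:
        raise InvariantError("correlation needs at least 3 conditions")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class CorrelationResult:
    target_id: str
    mirna_id: str
    r: Optional[float]
    n_conditions: int
    inverse_flag: bool
    status: str  # "ok" | "missing_target" | "missing_mirna" | "zero_variance"

    def __post_init__(self) -> None:
        if self.r is not None and abs(self.r) > 1 + 1e-12:
            raise InvariantError("|r| must not exceed 1")


def correlate_pairs(
    matrix: ExpressionMatrix,
    pairs: Sequence[Tuple[str, str]],
    min_inverse_r: float = DEFAULT_MIN_INVERSE_R,
) -> List[CorrelationResult]:
    """Pearson r for each (target_id, mirna_id) pair found in the matrix.

    ``inverse_flag`` marks r <= ``min_inverse_r`` (default -0.8), the
    headline threshold for calling expression support.
    """
    out: List[CorrelationResult] = []
    for target_id, mirna_id in pairs:
        if target_id not in matrix:
            out.append(CorrelationResult(target_id, mirna_id, None,
                                         matrix.n_conditions, False, "missing_target"))
            continue
        if mirna_id not in matrix:
            out.append(CorrelationResult(target_id, mirna_id, None,
                                         matrix.n_conditions, False, "missing_mirna"))
            continue
        try:
            r = pearson(matrix.row(target_id), matrix.row(mirna_id))
        except ZeroVarianceError:
            out.append(CorrelationResult(target_id, mirna_id, None,
                                         matrix.n_conditions, False, "zero_variance"))
            continue
        out.append(CorrelationResult(target_id, mirna_id, r,
                                     matrix.n_conditions, r <= min_inverse_r, "ok"))
    return out


def results_to_tsv(results: Sequence[CorrelationResult], path: Union[str, Path]) -> None:
    pd.DataFrame([{
        "target_id": r.target_id, "mirna_id": r.mirna_id,
        "r": "" if r.r is None else round(r.r, 6),
        "n_conditions": r.n_conditions,
        "inverse_flag": r.inverse_flag, "status": r.status,
    } for r in results]).to_csv(path, sep="\t", index=False)
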