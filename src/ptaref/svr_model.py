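"""Epsilon-SVR scoring of candidate sites.

Positive and negative training instances are encoded as regression targets
+1 and -1; classification is by the sign of the regression output, and the
magnitude of the score is the confidence.  Three kernels are exposed under
their user-facing names: ``linear``, ``gaussian`` (radial basis function)
and ``polynomial``.

The API follows the model/results convention: :class:`TargetScorer` holds
the training data and configuration, ``fit()`` returns a
:class:`TargetScorerResults` carrying the support vectors, dual
coefficients, bias and diagnostics.  Scoring evaluates the kernel expansion
directly from those stored arrays, so a model saved to its versioned JSON
archive and loaded back scores bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.svm import SVR

from .errors import (InvariantError, LayoutError, ModelFormatError,
                     ParameterError, TrainingError)
from .feature_extractor import FeatureVector

MODEL_FORMAT_VERSION = "ptaref-svr-1"

_KERNEL_MAP = {"linear": "linear", "gaussian": "rbf", "polynomial": "poly"}


@dataclass(frozen=True)
class SVRConfig:
    """Hyperparameters for the epsilon-SVR scorer.

    ``gamma=None`` uses variance-scaled gamma (1 / (n_features * var(X)));
    density-delta features have magnitudes well below 1, and a fixed
    1/n_features gamma would flatten the gaussian/polynomial kernels into
    near-constants.  ``coef0`` (polynomial only) defaults to 1 so the kernel
    retains its lower-order terms.
    """

    kernel: str = "polynomial"
    C: float = 1.0
    epsilon: float = 0.1
    gamma: Optional[float] = None
    degree: int = 3
    coef0: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel not in _KERNEL_MAP:
            raise ParameterError(
                f"kernel must be one of {sorted(_KERNEL_MAP)}, got {self.kernel!r}")
        if self.C <= 0 or self.epsilon <= 0:
            raise ParameterError("C and epsilon must be positive")
        if self.gamma is not None and self.gamma <= 0:
            raise ParameterError("gamma must be positive")
        if self.degree < 2:
            raise ParameterError("polynomial degree must be >= 2")


@dataclass(frozen=True)
class Prediction:
    """A scored site: positive SVR score = predicted target."""

    svr_score: float
    call: str  # "target" | "non-target"
    site_ref: object = None
    pattern: Optional[str] = None
    library_pattern: Optional[str] = None
    library_mirna_id: Optional[str] = None
    pattern_distance: Optional[int] = None
    energy: Optional[float] = None
    expression_r: Optional[float] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.svr_score):
            raise InvariantError("SVR score must be finite")
        expected = "target" if self.svr_score > 0 else "non-target"
        if self.call != expected:
            raise InvariantError("call inconsistent with score sign")


def _as_matrix(vectors: Sequence[Union[FeatureVector, np.ndarray]]) -> np.ndarray:
    rows = [v.values if isinstance(v, FeatureVector) else np.asarray(v, dtype=float)
            for v in vectors]
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise LayoutError(f"mixed feature-vector lengths: {sorted(lengths)}")
    return np.asarray(rows, dtype=float)


class TargetScorer:
    """Epsilon-SVR model over site feature vectors (labels +1 / -1)."""

    def __init__(
        self,
        pos: Sequence[Union[FeatureVector, np.ndarray]],
        neg: Sequence[Union[FeatureVector, np.ndarray]],
        config: Optional[SVRConfig] = None,
        layout: Optional[Tuple] = None,
    ):
        if len(pos) < 2 or len(neg) < 2:
            raise TrainingError("need at least 2 instances per class")
        self.config = config if config is not None else SVRConfig()
        X_pos, X_neg = _as_matrix(pos), _as_matrix(neg)
        if X_pos.shape[1] != X_neg.shape[1]:
            raise LayoutError("positive and negative vectors differ in length")
        self.X = np.vstack([X_pos, X_neg])
        self.y = np.concatenate([np.ones(len(X_pos)), -np.ones(len(X_neg))])
        if layout is None:
            for v in list(pos) + list(neg):
                if isinstance(v, FeatureVector):
                    layout = v.layout
                    break
        self.layout = layout
        self.n_pos, self.n_neg = len(X_pos), len(X_neg)

    def fit(self) -> "TargetScorerResults":
        cfg = self.config
        gamma = cfg.gamma if cfg.gamma is not None else "scale"
        svr = SVR(kernel=_KERNEL_MAP[cfg.kernel], C=cfg.C, epsilon=cfg.epsilon,
                  gamma=gamma, degree=cfg.degree, coef0=cfg.coef0)
        svr.fit(self.X, self.y)
        resolved_gamma = float(svr._gamma) if cfg.kernel != "linear" else 1.0
        return TargetScorerResults(
            config=cfg,
            layout=self.layout,
            support_vectors=np.asarray(svr.support_vectors_, dtype=float),
            dual_coef=np.asarray(svr.dual_coef_, dtype=float).ravel(),
            intercept=float(svr.intercept_[0]),
            gamma_value=resolved_gamma,
            n_pos=self.n_pos,
            n_neg=self.n_neg,
            model=self,
        )


@dataclass
class TargetScorerResults:
    """A fitted SVR scorer: kernel expansion over support vectors."""

    config: SVRConfig
    layout: Optional[Tuple]
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    gamma_value: float
    n_pos: int
    n_neg: int
    selected_features: Optional[Tuple[int, ...]] = None
    model: Optional[TargetScorer] = None

    @property
    def n_features(self) -> int:
        return self.support_vectors.shape[1]

    def _kernel(self, X: np.ndarray) -> np.ndarray:
        sv, cfg = self.support_vectors, self.config
        if cfg.kernel == "linear":
            return X @ sv.T
        if cfg.kernel == "gaussian":
            sq = (np.sum(X**2, axis=1)[:, None] + np.sum(sv**2, axis=1)[None, :]
                  - 2.0 * X @ sv.T)
            return np.exp(-self.gamma_value * sq)
        return (self.gamma_value * (X @ sv.T) + cfg.coef0) ** cfg.degree

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise LayoutError(
                f"vector length {X.shape[1]} != model feature length {self.n_features}")
        return self._kernel(X) @ self.dual_coef + self.intercept

    def predict(self, v: Union[FeatureVector, np.ndarray]) -> Prediction:
        """Score one feature vector; call by the sign of the score."""
        if isinstance(v, FeatureVector):
            if self.layout is not None and v.layout != self.layout:
                raise LayoutError("feature-vector layout does not match the model")
            values, site = v.values, v.site_ref
        else:
            values, site = np.asarray(v, dtype=float), None
        score = float(self.decision_values(values[None, :])[0])
        return Prediction(svr_score=score,
                          call="target" if score > 0 else "non-target",
                          site_ref=site)

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Epsilon-SVR target scorer",
            "=" * 42,
            f"kernel            {cfg.kernel}",
            f"C                 {cfg.C:g}",
            f"epsilon           {cfg.epsilon:g}",
            f"gamma             {self.gamma_value:.6g}",
        ]
        if cfg.kernel == "polynomial":
            lines.append(f"degree            {cfg.degree}")
            lines.append(f"coef0             {cfg.coef0:g}")
        lines += [
            f"n features        {self.n_features}",
            f"n support vectors {len(self.dual_coef)}",
            f"training set      {self.n_pos} positive / {self.n_neg} negative",
            f"intercept         {self.intercept:.6g}",
        ]
        if self.model is not None:
            acc = float(np.mean(np.sign(self.decision_values(self.model.X)) == self.model.y))
            lines.append(f"training sign acc {100 * acc:.2f}%")
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------

    def save(self, path: Union[str, Path]) -> None:
        payload = {
            "format": MODEL_FORMAT_VERSION,
            "config": {
                "kernel": self.config.kernel, "C": self.config.C,
                "epsilon": self.config.epsilon, "gamma": self.config.gamma,
                "degree": self.config.degree, "coef0": self.config.coef0,
                "seed": self.config.seed,
            },
            "layout": _layout_to_json(self.layout),
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "gamma_value": self.gamma_value,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "selected_features": (list(self.selected_features)
                                  if self.selected_features is not None else None),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "TargetScorerResults":
        try:
            payload = json.loads(Path(path).read_text())
        except (json.JSONDecodeError, UnicodeDecodeError) as exc:
            raise ModelFormatError(f"unreadable model file {path}: {exc}") from exc
        if not isinstance(payload, dict) or payload.get("format") != MODEL_FORMAT_VERSION:
            raise ModelFormatError(
                f"unsupported model format {payload.get('format') if isinstance(payload, dict) else '?'!r}"
                f" (expected {MODEL_FORMAT_VERSION!r})")
        cfg = SVRConfig(**payload["config"])
        sel = payload.get("selected_features")
        return cls(
            config=cfg,
            layout=_layout_from_json(payload["layout"]),
            support_vectors=np.asarray(payload["support_vectors"], dtype=float),
            dual_coef=np.asarray(payload["dual_coef"], dtype=float),
            intercept=float(payload["intercept"]),
            gamma_value=float(payload["gamma_value"]),
            n_pos=int(payload["n_pos"]),
            n_neg=int(payload["n_neg"]),
            selected_features=tuple(sel) if sel is not None else None,
        )


def _layout_to_json(layout):
    if layout is None:
        return None
    flank, window, step, mode, selected = layout
    return [flank, window, step, mode, list(selected) if selected is not None else None]


def _layout_from_json(obj):
    if obj is None:
        return None
    flank, window, step, mode, selected = obj
    return (flank, window, step, mode, tuple(selected) if selected is not None else None)


# ---------------------------------------------------------------------------
# Thin functional surface
# ---------------------------------------------------------------------------

def train(pos, neg, cfg: Optional[SVRConfig] = None) -> TargetScorerResults:
    """Train an epsilon-SVR on positive/negative feature vectors."""
    return TargetScorer(pos, neg, config=cfg).fit()


def score(model: TargetScorerResults, v: Union[FeatureVector, np.ndarray]) -> Prediction:
    return model.predict(v)


def save_model(model: TargetScorerResults, path: Union[str, Path]) -> None:
    model.save(path)


def load_model(path: Union[str, Path]) -> TargetScorerResults:
    return TargetScorerResults.load(path)


def grid_search(
    pos, neg,
    kernels: Sequence[str] = ("linear", "gaussian", "polynomial"),
    Cs: Sequence[float] = (0.1, 1.0, 10.0),
    folds: int = 5,
    seed: int = 0,
) -> Tuple[SVRConfig, float]:
    """Small exhaustive grid over (kernel, C), ranked by CV AUC."""
    from .evaluation import cv_roc  # local import to avoid a cycle

    X = np.vstack([_as_matrix(pos), _as_matrix(neg)])
    y = np.concatenate([np.ones(len(pos)), -np.ones(len(neg))])
    best: Tuple[Optional[SVRConfig], float] = (None, -np.inf)
    for kernel in kernels:
        for C in Cs:
            cfg = SVRConfig(kernel=kernel, C=C, seed=seed)
            auc = cv_roc(X, y, cfg, folds=folds, seed=seed).auc
            if auc > best[1]:
                best = (cfg, auc)
    assert best[0] is not None
    return best  # type: ignore[return-value]
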