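"""Bootstrap gradient-boosting ensemble with a Chebyshev reject option.

The classifier is an ensemble of B gradient-boosted tree models
(LightGBM), each fit on a bootstrap resample of the training set.  At
prediction time the member probabilities of pathogenicity give a mean mu
and standard deviation sigma; Chebyshev's inequality guarantees that at
least 1 - 1/k^2 of any distribution lies within k standard deviations of
its mean, so with k = sqrt(1 / (1 - confidence)) the interval
mu +/- k*sigma is a distribution-free confidence band.  If the band
contains the decision boundary 0.5 the call is withheld (UV, unclassified
variant); otherwise the class follows the side of 0.5 that mu falls on.

Recursive feature elimination repeatedly fits the learner, ranks features
by total split gain, and drops the lowest-ranked 10% per round, recording
the surviving set at preset target counts.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import joblib
import numpy as np
from lightgbm import LGBMClassifier

from varitol.core import BENIGN, PATHOGENIC
from varitol.features import FeatureVector

UV = "UV"

#: Default ensemble size.
DEFAULT_B = 100

#: Default confidence for the Chebyshev band (k = sqrt(20)).
DEFAULT_CONFIDENCE = 0.95

_QUIET = {"verbose": -1}


def chebyshev_k(confidence: float) -> float:
    """Chebyshev multiplier k with 1 - 1/k^2 = confidence."""
    if not 0.0 < confidence < 1.0:
        raise ValueError(f"confidence must lie in (0, 1), got {confidence}")
    return math.sqrt(1.0 / (1.0 - confidence))


@dataclass(frozen=True)
class PredictionResult:
    """Ensemble summary and three-way decision for one variant."""

    mu: float
    sigma: float
    k: float
    decision: str
    mode: Optional[str] = None


def _decide(mu: float, sigma: float, k: float) -> str:
    lo, hi = mu - k * sigma, mu + k * sigma
    if lo <= 0.5 <= hi:  # boundary inclusive: ties go to UV
        return UV
    return PATHOGENIC if mu > 0.5 else BENIGN


@dataclass
class EnsembleModel:
    """B bootstrap-trained boosted-tree members sharing a feature order."""

    members: List[LGBMClassifier]
    feature_names: List[str]
    selected_features: Optional[List[str]] = None
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("ensemble needs at least 2 members")

    @property
    def B(self) -> int:
        return len(self.members)

    def member_probabilities(self, X: np.ndarray) -> np.ndarray:
        """(B, n) matrix of per-member pathogenicity probabilities."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        with warnings.catch_warnings():
            # LightGBM's sklearn wrapper invents column names for ndarray
            # input at fit time, then warns about their absence at predict.
            warnings.filterwarnings(
                "ignore", message="X does not have valid feature names"
            )
            return np.stack([m.predict_proba(X)[:, 1] for m in self.members])

    def checksum(self) -> str:
        h = hashlib.sha256()
        for name in self.feature_names:
            h.update(name.encode())
        h.update(repr(sorted(self.training_meta.items())).encode())
        return h.hexdigest()


def train_ensemble(
    X: np.ndarray,
    y: Sequence[int],
    B: int = DEFAULT_B,
    seed: int = 0,
    params: Optional[Mapping] = None,
    feature_names: Optional[Sequence[str]] = None,
) -> EnsembleModel:
    """Fit B members, each on a seeded bootstrap resample of (X, y).

    Member i resamples n rows with replacement using seed + i and is fit
    with learner seed seed + i; retraining with the same seed reproduces
    member predictions exactly.  Learner hyperparameters default to the
    library defaults.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("X must be a non-empty 2-D matrix")
    if X.shape[0] != len(y):
        raise ValueError("X rows and y length differ")
    if len(set(y.tolist())) < 2:
        raise ValueError("training labels contain a single class")
    if B < 2:
        raise ValueError("B must be >= 2")
    params = dict(params or {})
    n = X.shape[0]
    members = []
    for i in range(B):
        rng = np.random.default_rng(seed + i)
        idx = rng.integers(0, n, size=n)
        # bootstrap can drop a class on tiny data; redraw a few times
        for _ in range(20):
            if len(set(y[idx].tolist())) == 2:
                break
            idx = rng.integers(0, n, size=n)
        clf = LGBMClassifier(random_state=seed + i, **_QUIET, **params)
        clf.fit(X[idx], y[idx])
        members.append(clf)
    names = (
        list(feature_names)
        if feature_names is not None
        else [f"f{j}" for j in range(X.shape[1])]
    )
    meta = {"seed": seed, "B": B, "params": tuple(sorted(params.items()))}
    return EnsembleModel(members=members, feature_names=names, training_meta=meta)


def predict_with_reject(
    model: EnsembleModel,
    x,
    confidence: float = DEFAULT_CONFIDENCE,
    mode: Optional[str] = None,
) -> PredictionResult:
    """Three-way call for one variant from the member probability spread."""
    if isinstance(x, FeatureVector):
        if x.names != model.feature_names:
            raise ValueError("feature names do not match the fitted model")
        x = x.values
    probs = model.member_probabilities(np.asarray(x, dtype=float))[:, 0]
    k = chebyshev_k(confidence)
    mu = float(np.mean(probs))
    sigma = float(np.std(probs))
    return PredictionResult(mu=mu, sigma=sigma, k=k, decision=_decide(mu, sigma, k), mode=mode)


def predict_batch(
    model: EnsembleModel,
    X: np.ndarray,
    confidence: float = DEFAULT_CONFIDENCE,
    mode: Optional[str] = None,
) -> List[PredictionResult]:
    """Vectorized :func:`predict_with_reject` over the rows of X."""
    probs = model.member_probabilities(X)
    k = chebyshev_k(confidence)
    mus = probs.mean(axis=0)
    sigmas = probs.std(axis=0)
    return [
        PredictionResult(
            mu=float(m), sigma=float(s), k=k, decision=_decide(m, s, k), mode=mode
        )
        for m, s in zip(mus, sigmas)
    ]


def two_mode_predict(
    models: Mapping[str, EnsembleModel],
    x: FeatureVector,
    confidence: float = DEFAULT_CONFIDENCE,
) -> PredictionResult:
    """Route to the with-GO model iff the LR feature is available.

    ``models`` maps ``"with_go"`` / ``"without_go"`` to fitted ensembles
    (either may be missing).  The mode used is recorded in the result.
    """
    with_go = models.get("with_go")
    without_go = models.get("without_go")
    if with_go is None and without_go is None:
        raise ValueError("neither model available")
    try:
        lr_idx = x.names.index("go:lr")
        lr_available = bool(x.mask[lr_idx])
    except ValueError:
        lr_available = False
    if lr_available and with_go is not None:
        model, mode = with_go, "with_go"
    else:
        if without_go is None:
            raise ValueError(
                "variant lacks GO annotation and no without-GO model is loaded"
            )
        model, mode = without_go, "without_go"
    cols = [x.names.index(n) for n in model.feature_names]
    return predict_with_reject(model, x.values[cols], confidence, mode=mode)


def rfe_select(
    X: np.ndarray,
    y: Sequence[int],
    feature_names: Sequence[str],
    target_counts: Sequence[int] = (100, 50, 20, 10),
    seed: int = 0,
    params: Optional[Mapping] = None,
    drop_fraction: float = 0.1,
) -> Dict[int, List[str]]:
    """Recursive feature elimination by boosted-tree split gain.

    Each round fits one learner on the surviving features, ranks them by
    total split gain, and removes the lowest ``drop_fraction`` (at least
    one).  Surviving sets are snapshotted whenever the count crosses a
    target; snapshots are nested by construction.  Returned lists are
    ordered by descending importance at snapshot time.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    names = list(feature_names)
    if X.shape[1] != len(names):
        raise ValueError("feature_names length does not match X columns")
    targets = sorted(set(int(t) for t in target_counts), reverse=True)
    if targets and targets[0] >= len(names):
        raise ValueError(
            f"largest target {targets[0]} must be smaller than the "
            f"feature count {len(names)}"
        )
    params = dict(params or {})
    current = np.arange(len(names))
    snapshots: Dict[int, List[str]] = {}
    remaining = list(targets)
    while remaining:
        clf = LGBMClassifier(
            random_state=seed, importance_type="gain", **_QUIET, **params
        )
        clf.fit(X[:, current], y)
        gains = np.asarray(clf.feature_importances_, dtype=float)
        order = np.argsort(gains, kind="stable")  # ascending importance
        n_drop = max(1, int(drop_fraction * len(current)))
        n_drop = min(n_drop, len(current) - remaining[0])
        keep = np.sort(order[n_drop:])
        current = current[keep]
        if len(current) == remaining[0]:
            # order snapshot by descending gain of the final fit
            kept_gains = gains[keep]
            by_gain = np.argsort(-kept_gains, kind="stable")
            snapshots[remaining[0]] = [names[current[j]] for j in by_gain]
            remaining.pop(0)
    return snapshots


def save_model(model: EnsembleModel, path) -> None:
    """Serialize an ensemble (members, feature order, meta, checksum)."""
    payload = {
        "members": model.members,
        "feature_names": model.feature_names,
        "selected_features": model.selected_features,
        "training_meta": model.training_meta,
        "checksum": model.checksum(),
    }
    joblib.dump(payload, path)


def load_model(path) -> EnsembleModel:
    """Load a serialized ensemble, verifying its checksum."""
    payload = joblib.load(path)
    model = EnsembleModel(
        members=payload["members"],
        feature_names=payload["feature_names"],
        selected_features=payload.get("selected_features"),
        training_meta=payload.get("training_meta", {}),
    )
    if model.checksum() != payload.get("checksum"):
        raise ValueError(f"model file {path} failed its checksum")
    return model
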