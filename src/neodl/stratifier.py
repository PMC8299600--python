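"""Survival-label generation and the neoDL stratifier.

Labels come from hierarchical k-means ("hkmeans"): Ward-linkage hierarchical
clustering of the z-scored valid features is cut at k, the resulting cluster
means seed an ordinary k-means run, and the two clusters are mapped to
long-/short-term survival semantics by median overall survival. The LSTM
classifier is then trained to reproduce those cluster labels (1 = long-term).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

from .nn import DTYPE, LSTMClassifier, ModelConfig
from .survival_stats import SurvivalData

LONG_TERM = "long-term"
SHORT_TERM = "short-term"
LABEL_LONG = 1  # binary encoding used for model training
LABEL_SHORT = 0


@dataclass
class ZScaler:
    """Per-feature standardization learned from a reference cohort.

    Features with zero standard deviation map to 0 rather than NaN.
    """

    mean: np.ndarray
    std: np.ndarray
    feature_names: tuple[str, ...]

    @classmethod
    def fit(cls, X: pd.DataFrame) -> "ZScaler":
        mat = X.to_numpy(dtype=float)
        if not np.isfinite(mat).all():
            raise ValueError("feature matrix must be finite for z-scaling")
        return cls(mean=mat.mean(axis=0), std=mat.std(axis=0, ddof=0),
                   feature_names=tuple(map(str, X.columns)))

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if tuple(map(str, X.columns)) != self.feature_names:
            raise ValueError("feature list/order differs from the scaler's")
        mat = X.to_numpy(dtype=float)
        safe = np.where(self.std > 0, self.std, 1.0)
        out = (mat - self.mean) / safe
        out[:, self.std == 0] = 0.0
        return pd.DataFrame(out, index=X.index, columns=X.columns)


@dataclass
class HKMeansResult:
    """Two-cluster patient stratification with survival semantics."""

    labels: np.ndarray          # cluster ids 1..k per patient
    centroids: np.ndarray       # (k, n_features)
    semantics: dict[int, str]   # cluster id -> "long-term"/"short-term"

    def binary_labels(self) -> np.ndarray:
        """1 for the long-term cluster, 0 for the short-term cluster."""
        return np.array([LABEL_LONG if self.semantics[c] == LONG_TERM else LABEL_SHORT
                         for c in self.labels])


def hkmeans(X, k: int = 2, seed: int = 0) -> np.ndarray:
    """Hierarchical-initialized k-means cluster labels (1..k).

    Ward-linkage hierarchical clustering on Euclidean distances is cut at
    ``k``; the cut's cluster means initialize Lloyd's k-means, which runs to
    convergence. With deterministic initialization the seed only matters for
    k-means' internal tie handling and is fixed for reproducibility.
    """
    mat = np.asarray(X, dtype=float)
    if mat.ndim != 2 or not np.isfinite(mat).all():
        raise ValueError("X must be a finite 2-d matrix")
    n = mat.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}")
    if k == 1:
        return np.ones(n, dtype=int)
    tree = linkage(mat, method="ward", metric="euclidean")
    initial = fcluster(tree, t=k, criterion="maxclust")
    centroids = np.vstack([mat[initial == c].mean(axis=0) for c in range(1, k + 1)])
    km = KMeans(n_clusters=k, init=centroids, n_init=1, max_iter=300,
                random_state=seed).fit(mat)
    return km.labels_ + 1


def assign_cluster_semantics(labels, survival: SurvivalData) -> dict[int, str]:
    """Map each of two clusters to long-/short-term by median OS (mean breaks ties)."""
    lab = np.asarray(labels)
    ids = sorted(set(lab.tolist()))
    if len(ids) != 2:
        raise ValueError("semantics are defined for exactly two clusters")
    med = {c: float(np.median(survival.time[lab == c])) for c in ids}
    mean = {c: float(np.mean(survival.time[lab == c])) for c in ids}
    a, b = ids
    if med[a] != med[b]:
        long_c = a if med[a] > med[b] else b
    else:
        long_c = a if mean[a] > mean[b] else b
    return {c: (LONG_TERM if c == long_c else SHORT_TERM) for c in ids}


def hkmeans_stratify(X, survival: SurvivalData, k: int = 2, seed: int = 0) -> HKMeansResult:
    labels = hkmeans(X, k=k, seed=seed)
    mat = np.asarray(X, dtype=float)
    centroids = np.vstack([mat[labels == c].mean(axis=0) for c in sorted(set(labels))])
    return HKMeansResult(labels=labels, centroids=centroids,
                         semantics=assign_cluster_semantics(labels, survival))


# ---------------------------------------------------------------------------
# the trained model artifact
# ---------------------------------------------------------------------------

def _vocab_hash(names) -> str:
    return hashlib.sha256("\n".join(names).encode()).hexdigest()[:16]


@dataclass
class TrainedModel:
    """An LSTM stratifier plus the scaler and feature order it was trained with."""

    network: LSTMClassifier
    scaler: ZScaler
    feature_names: tuple[str, ...]
    config: ModelConfig

    def predict_scores(self, features: pd.DataFrame) -> pd.DataFrame:
        """Probabilities and thresholded labels for raw (un-scaled) features."""
        if tuple(map(str, features.columns)) != self.feature_names:
            raise ValueError("feature list/order differs from training")
        z = self.scaler.transform(features)
        proba = self.network.predict_proba(z.to_numpy(dtype=DTYPE))
        return pd.DataFrame({
            "probability": proba,
            "predicted_label": (proba > self.config.threshold).astype(int),
        }, index=features.index)

    def save(self, path) -> None:
        path = Path(path)
        meta = {
            "format": 1,
            "config": json.loads(self.network.config_json()),
            "feature_names": list(self.feature_names),
            "vocab_hash": _vocab_hash(self.feature_names),
        }
        np.savez(
            path,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            scaler_mean=self.scaler.mean,
            scaler_std=self.scaler.std,
            **self.network.state_dict(),
        )

    @classmethod
    def load(cls, path, expected_features=None) -> "TrainedModel":
        data = np.load(Path(path), allow_pickle=False)
        meta = json.loads(bytes(data["meta"]).decode())
        if meta.get("format") != 1:
            raise ValueError("unrecognized model artifact format")
        names = tuple(meta["feature_names"])
        if meta["vocab_hash"] != _vocab_hash(names):
            raise ValueError("model artifact is corrupt (vocabulary hash mismatch)")
        if expected_features is not None and tuple(expected_features) != names:
            raise ValueError("model was trained with an incompatible feature vocabulary")
        cfg = dict(meta["config"])
        cfg["hidden"] = tuple(cfg["hidden"])
        config = ModelConfig(**cfg)
        net = LSTMClassifier(len(names), config)
        net.load_state({k: data[k] for k in net._PARAM_NAMES})
        scaler = ZScaler(mean=data["scaler_mean"], std=data["scaler_std"],
                         feature_names=names)
        return cls(network=net, scaler=scaler, feature_names=names, config=config)


def train_neodl(features_z: pd.DataFrame, labels, config: ModelConfig,
                scaler: ZScaler) -> TrainedModel:
    """Train the LSTM stratifier on z-scored valid features.

    ``labels`` must be binary (1 = long-term cluster). The scaler that
    produced ``features_z`` travels with the model so it can be applied to
    raw features of new cohorts.
    """
    y = np.asarray(labels)
    if set(np.unique(y).tolist()) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if tuple(map(str, features_z.columns)) != scaler.feature_names:
        raise ValueError("feature list/order differs from the scaler's")
    net = LSTMClassifier(features_z.shape[1], config)
    net.fit(features_z.to_numpy(dtype=DTYPE), y.astype(DTYPE))
    return TrainedModel(network=net, scaler=scaler,
                        feature_names=tuple(map(str, features_z.columns)),
                        config=config)


def predict(model: TrainedModel, features: pd.DataFrame) -> pd.DataFrame:
    """Module-level convenience wrapper around :meth:`TrainedModel.predict_scores`."""
    return model.predict_scores(features)


def write_label_table(path, patient_ids, clusters, semantics: dict[int, str],
                      probabilities=None, predicted=None) -> None:
    df = pd.DataFrame({
        "patient_id": list(patient_ids),
        "cluster": np.asarray(clusters),
        "semantics": [semantics[c] for c in np.asarray(clusters)],
    })
    df["probability"] = np.nan if probabilities is None else np.asarray(probabilities)
    df["predicted_label"] = -1 if predicted is None else np.asarray(predicted)
    df.to_csv(path, sep="\t", index=False)
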