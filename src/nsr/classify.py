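"""Putative cell-type classification.

SNc units split into putative dopaminergic (wide spikes) and GABAergic
(narrow, < 800 µs) cells by spike duration. Striatal units split into
projection neurons (SPN), tonically active interneurons (TAN) and
fast-spiking interneurons (FSI) by k-means over three standardized
features — ongoing firing rate, peak-to-valley waveform width, and the
coefficient of variation of the inter-spike interval — with cluster
separation scored by the mean silhouette. Cluster-to-name mapping follows
the known physiology: SPNs have the widest waveforms and low rates, FSIs
the narrowest waveforms and high rates, TANs tonically regular firing in
between.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from sklearn.preprocessing import StandardScaler

SNC_DURATION_THRESHOLD_US = 800.0
ML_SPLIT_MM = 1.8
ML_RANGE_MM = (0.8, 2.4)

STRIATAL_LABELS = ("SPN", "TAN", "FSI")


@dataclass(frozen=True)
class UnitFeatures:
    """Per-unit classification features."""

    ongoing_rate: float
    spike_duration_us: float
    cv_isi: float
    region: str = "DMS"
    ml_position_mm: float | None = None

    def __post_init__(self) -> None:
        if self.ongoing_rate < 0 or self.cv_isi < 0 or self.spike_duration_us <= 0:
            raise ValueError("rate and CV must be >= 0; duration must be > 0")


def snc_classify(duration_us: float) -> str:
    """Spike-duration rule for SNc units: narrow (< 800 µs) ⇒ putative GABAergic."""
    if duration_us <= 0:
        raise ValueError("duration must be positive")
    return "putative_GABA" if duration_us < SNC_DURATION_THRESHOLD_US else "putative_DAN"


def mediolateral_split(ml_position_mm: float) -> str:
    """Medial (< 1.8 mm) vs lateral (≥ 1.8 mm) recording location."""
    lo, hi = ML_RANGE_MM
    if not lo <= ml_position_mm <= hi:
        raise ValueError(f"position {ml_position_mm} mm outside recorded range {ML_RANGE_MM}")
    return "medial" if ml_position_mm < ML_SPLIT_MM else "lateral"


@dataclass
class KMeansClassification:
    labels: list[str]
    cluster_index: np.ndarray
    mean_silhouette: float
    centroids: pd.DataFrame
    degenerate: bool = False


def _name_clusters(centroids_orig: np.ndarray) -> dict[int, str]:
    """Map k-means clusters to SPN/TAN/FSI by centroid physiology.

    Waveform width orders the three types (FSI narrowest, SPN widest); the
    rate and ISI-regularity columns disambiguate if widths nearly tie.
    """
    width = centroids_orig[:, 1]
    order = np.argsort(width)  # narrow -> wide
    return {int(order[0]): "FSI", int(order[1]): "TAN", int(order[2]): "SPN"}


def striatal_kmeans(
    features: list[UnitFeatures] | pd.DataFrame,
    k: int = 3,
    seed: int = 0,
    n_restarts: int = 50,
) -> KMeansClassification:
    """K-means classification of striatal units on standardized features.

    Features are z-scored before clustering (rate in Hz, width in µs and
    CV are on incompatible scales). Runs ``n_restarts`` initializations
    with a deterministic seed and keeps the best inertia. All-identical
    feature vectors are returned as a flagged degenerate classification.
    """
    if isinstance(features, pd.DataFrame):
        X = features[["ongoing_rate", "spike_duration_us", "cv_isi"]].to_numpy(dtype=float)
    else:
        X = np.array(
            [[f.ongoing_rate, f.spike_duration_us, f.cv_isi] for f in features], dtype=float
        )
    n = X.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} units, got {n}")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if np.allclose(X, X[0]):
        return KMeansClassification(
            labels=["SPN"] * n,
            cluster_index=np.zeros(n, dtype=int),
            mean_silhouette=np.nan,
            centroids=pd.DataFrame(),
            degenerate=True,
        )
    Xs = StandardScaler().fit_transform(X)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    idx = km.fit_predict(Xs)
    sil = float(silhouette_score(Xs, idx)) if len(np.unique(idx)) > 1 else np.nan
    # Centroids back on the original scale for naming and reporting.
    cent = np.vstack([X[idx == c].mean(axis=0) for c in range(k)])
    names = _name_clusters(cent) if k == 3 else {c: f"cluster{c}" for c in range(k)}
    centroids = pd.DataFrame(
        cent, columns=["ongoing_rate", "spike_duration_us", "cv_isi"]
    ).assign(label=[names[c] for c in range(k)])
    return KMeansClassification(
        labels=[names[int(c)] for c in idx],
        cluster_index=idx,
        mean_silhouette=sil,
        centroids=centroids,
    )


def classify_units(table: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Classify a mixed unit table by region.

    SNc rows get the spike-duration rule; striatal (DMS/DLS) rows get
    k-means labels fitted jointly across striatal units. Returns the table
    with ``label`` (and ``silhouette`` for striatal rows) columns added.
    """
    out = table.copy()
    out["label"] = ""
    out["silhouette"] = np.nan
    snc = out["region"] == "SNc"
    out.loc[snc, "label"] = out.loc[snc, "spike_duration_us"].map(snc_classify)
    striatal = out["region"].isin(("DMS", "DLS"))
    if striatal.sum() >= 3:
        res = striatal_kmeans(out.loc[striatal], seed=seed)
        out.loc[striatal, "label"] = res.labels
        out.loc[striatal, "silhouette"] = res.mean_silhouette
    return out
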