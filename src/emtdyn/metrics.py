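"""Morphology-based phenotype calls and colony/wound summary statistics."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .errors import ConfigError
from .imaging import FEATURES, WoundAssayResult


def classify_morphology(features: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Unsupervised E/M call from the seven shape descriptors.

    Features are standardized, projected onto the first two principal
    components and split by 2-means clustering; the cluster with the
    smaller mean cell area is labelled M (mesenchymal-like cells are
    small and compact, epithelial-like cells large and flat).  The
    mapping is therefore data-driven and invariant to per-feature
    rescaling and to observation order.  Returns one call per
    observation with the embedding coordinates used.
    """
    missing = [f for f in FEATURES if f not in features.columns]
    if missing:
        raise ConfigError(f"missing feature column(s): {', '.join(missing)}")
    X = features[FEATURES].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ConfigError("features contain non-finite values")
    if len(X) < 2:
        raise ConfigError("need at least two observations to cluster")
    if np.allclose(X.std(axis=0), 0):
        raise ConfigError("degenerate feature matrix: all observations identical")
    Xs = StandardScaler().fit_transform(X)
    emb = PCA(n_components=2, random_state=seed).fit_transform(Xs)
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(emb)
    areas = [features["area"].to_numpy()[km.labels_ == c].mean() for c in (0, 1)]
    m_cluster = int(np.argmin(areas))
    calls = np.where(km.labels_ == m_cluster, "M", "E")
    out = pd.DataFrame(
        {
            "predicted": calls,
            "pc1": emb[:, 0],
            "pc2": emb[:, 1],
        },
        index=features.index,
    )
    for col in ("cell_id", "frame", "label"):
        if col in features.columns:
            out.insert(0, col, features[col])
    return out


def clonal_efficiency(observed: int, seeded: int) -> float:
    """Percentage of seeded single cells that produced a colony.

    100 * observed / seeded; more colonies than seedings (merging or
    counting artifacts) warns but still returns the value.
    """
    if seeded <= 0:
        raise ConfigError("number of colonies seeded must be positive")
    if observed < 0:
        raise ConfigError("number of colonies observed must be non-negative")
    if observed > seeded:
        warnings.warn(
            f"observed ({observed}) exceeds seeded ({seeded}); "
            "possible colony merging or counting artifact",
            stacklevel=2,
        )
    return 100.0 * observed / seeded


def wound_closure(assay: WoundAssayResult, at_time_h: float) -> float:
    """Percent of the denuded band occupied at a given time.

    Linear interpolation between imaging frames; times outside the
    assay horizon are an error rather than an extrapolation.
    """
    t = assay.series["time_h"].to_numpy(dtype=float)
    occ = assay.series["occupancy_pct"].to_numpy(dtype=float)
    if not (t.min() <= at_time_h <= t.max()):
        raise ConfigError(
            f"time {at_time_h} h outside assay horizon [{t.min()}, {t.max()}] h"
        )
    return float(np.interp(at_time_h, t, occ))
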